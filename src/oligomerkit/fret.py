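"""FRET-based oligomerization analysis for membrane receptors.

The measured quantity is an apparent FRET efficiency per micron-sized
membrane region, together with the 2-D densities of donor- and
acceptor-labeled receptors in that region.  The forward model composes:

1. the mass-action monomer–n-mer equilibrium (:mod:`.equilibrium`), giving
   the oligomeric fraction f_n at the region's total density;
2. random donor/acceptor labeling within oligomers: a donor in an n-mer has
   k acceptor partners with probability Binom(k; n−1, x_A), where x_A is the
   region's acceptor fraction;
3. parallel energy-transfer pathways to the k acceptors, each with pairwise
   (intrinsic) efficiency Ẽ, giving a per-donor efficiency
   kẼ/(kẼ + 1 − Ẽ).

The apparent FRET is f_n · Ē with Ē the binomial average of the per-donor
efficiency.  For n = 2 this reduces exactly to FRET = f_D·x_A·Ẽ.

Nonspecific "proximity FRET" from unassociated fluorophores crowded in the
2-D membrane is modeled with the classical Wolber–Hudson random-acceptor
approximation and removed before fitting.  Fitting minimizes the mean
squared error between corrected FRET and the forward model over
(K_diss, Ẽ); comparing the minimized MSE across oligomer orders n = 1..6
selects the order that best describes the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

from .equilibrium import EquilibriumModel, half_saturation, oligomeric_fraction
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "FretRecord",
    "ProximityParams",
    "FretFit",
    "OrderSelection",
    "proximity_fret",
    "add_proximity",
    "correct_proximity",
    "pairwise_parallel_efficiency",
    "mean_donor_efficiency",
    "predict_fret",
    "fit_fret",
    "select_order",
    "binned_fraction_curve",
]


@dataclass(frozen=True)
class FretRecord:
    """One membrane region: donor/acceptor 2-D densities and measured FRET."""

    donor_conc: float  # receptors/μm²
    acceptor_conc: float  # receptors/μm²
    fret: float  # apparent FRET efficiency in [0, 1]
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.donor_conc < 0 or self.acceptor_conc < 0:
            raise InvalidInputError("receptor concentrations must be >= 0")
        if not (0.0 <= self.fret <= 1.0):
            raise InvalidInputError(f"FRET efficiency must lie in [0, 1], got {self.fret}")

    @property
    def total(self) -> float:
        return self.donor_conc + self.acceptor_conc

    @property
    def x_a(self) -> float:
        t = self.total
        return self.acceptor_conc / t if t > 0 else float("nan")

    @property
    def x_d(self) -> float:
        t = self.total
        return self.donor_conc / t if t > 0 else float("nan")


# Wolber & Hudson two-exponential fit coefficients for energy transfer to
# acceptors randomly distributed in a plane (zero exclusion distance).
_WH_A1, _WH_K1 = 0.6463, 4.7497
_WH_A2, _WH_K2 = 0.3537, 2.0618


@dataclass(frozen=True)
class ProximityParams:
    """Parameters of the nonspecific 2-D proximity-FRET model.

    foerster_radius and exclusion_radius are in nm; densities are in
    receptors/μm².  ``enabled=False`` turns both the forward contribution
    and the correction into identities.
    """

    foerster_radius: float = 5.7  # nm; mTurquoise/EYFP-like pair
    exclusion_radius: float = 1.0  # nm; closest fluorophore approach
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.foerster_radius > 0):
            raise InvalidInputError("Förster radius must be positive")
        if self.exclusion_radius < 0:
            raise InvalidInputError("exclusion radius must be >= 0")


def proximity_fret(acceptor_conc, params: ProximityParams):
    """Expected FRET of a *monomeric* donor from randomly placed 2-D acceptors.

    Wolber–Hudson approximation: with reduced acceptor density
    c = σ_A·π·(R0² − r_e²) (dimensionless, R0 and r_e converted to μm),
    E_prox = 1 − [A1·exp(−k1·c) + A2·exp(−k2·c)].  Zero at zero density,
    strictly increasing, < 1.  Vectorized over ``acceptor_conc``.
    """
    arr = np.asarray(acceptor_conc, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("acceptor density must be >= 0")
    if not params.enabled:
        out = np.zeros_like(arr)
        return float(out) if arr.ndim == 0 else out
    r0_um = params.foerster_radius * 1e-3
    re_um = params.exclusion_radius * 1e-3
    disc = max(r0_um**2 - re_um**2, 0.0)
    c = arr * math.pi * disc
    e = 1.0 - (_WH_A1 * np.exp(-_WH_K1 * c) + _WH_A2 * np.exp(-_WH_K2 * c))
    return float(e) if arr.ndim == 0 else e


def add_proximity(specific_fret, acceptor_conc, params: ProximityParams):
    """Compose oligomer-specific FRET with the proximity contribution.

    Exact inverse of :func:`correct_proximity`:
    measured = E_prox + (1 − E_prox)·specific.
    """
    e = proximity_fret(acceptor_conc, params)
    return e + (1.0 - e) * np.asarray(specific_fret, dtype=float)


def correct_proximity(record: FretRecord, params: ProximityParams) -> float:
    """Remove the proximity contribution from one record's measured FRET."""
    return float(_correct_arrays(record.fret, record.acceptor_conc, params))


def _correct_arrays(fret, acceptor_conc, params: ProximityParams):
    if not params.enabled:
        return np.asarray(fret, dtype=float)
    e = proximity_fret(acceptor_conc, params)
    return np.clip((np.asarray(fret, dtype=float) - e) / (1.0 - e), 0.0, 1.0)


def pairwise_parallel_efficiency(k, e_tilde):
    """Per-donor efficiency with k acceptor partners, parallel pathways.

    kẼ/(kẼ + 1 − Ẽ): each of k acceptors opens an independent transfer
    channel of pairwise efficiency Ẽ competing with one radiative channel.
    """
    k = np.asarray(k, dtype=float)
    denom = k * e_tilde + 1.0 - e_tilde
    return np.where(k > 0, k * e_tilde / np.where(denom > 0, denom, 1.0), 0.0)


def mean_donor_efficiency(
    n: int,
    x_a,
    e_tilde: float,
    donor_efficiency: Callable = pairwise_parallel_efficiency,
):
    """Binomial-average per-donor efficiency Ē(n, x_A, Ẽ) within an n-mer.

    Ē = Σ_{k=0}^{n−1} Binom(k; n−1, x_A)·η(k, Ẽ) with η the pluggable
    per-donor efficiency.  Zero for n = 1.  Vectorized over ``x_a``.
    """
    x = np.asarray(x_a, dtype=float)
    if n == 1:
        out = np.zeros_like(x)
        return float(out) if x.ndim == 0 else out
    ks = np.arange(n)  # 0 .. n-1 acceptor partners
    eta = donor_efficiency(ks, e_tilde)
    # binom.pmf broadcasts over x; result shape (..., n)
    w = binom.pmf(ks, n - 1, x[..., None])
    out = w @ eta
    return float(out) if x.ndim == 0 else out


def predict_fret(
    total,
    x_a,
    model: EquilibriumModel,
    e_tilde: float,
    donor_efficiency: Callable = pairwise_parallel_efficiency,
):
    """Apparent FRET of the forward model: f_n(total)·Ē(n, x_A, Ẽ).

    For n = 2 this is exactly f_D·x_A·Ẽ.  Vectorized over ``total``/``x_a``.
    """
    x = np.asarray(x_a, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise InvalidInputError("acceptor fraction x_A must lie in [0, 1]")
    if not (0.0 < e_tilde <= 1.0):
        raise InvalidInputError(f"intrinsic FRET must lie in (0, 1], got {e_tilde}")
    f = oligomeric_fraction(total, model)
    ebar = mean_donor_efficiency(model.n, x, e_tilde, donor_efficiency)
    return f * ebar


@dataclass(frozen=True)
class FretFit:
    """Least-squares fit of (K_diss, Ẽ) for one oligomer order.

    For n = 1 there are no free parameters: k_diss is +inf (no association)
    and e_tilde is reported as 1.0 by convention; mse is the mean squared
    corrected FRET.
    """

    n: int
    k_diss: float
    e_tilde: float
    mse: float
    n_records: int
    ill_conditioned: bool = False
    messages: tuple[str, ...] = field(default_factory=tuple)

    @property
    def half_saturation(self) -> float:
        """Apparent dissociation constant (density at 50% oligomeric)."""
        return half_saturation(EquilibriumModel(self.n, self.k_diss))


@dataclass(frozen=True)
class OrderSelection:
    """Per-order MSE table and the order minimizing it (ties -> smaller n)."""

    mse_by_order: dict[int, float]
    best_order: int
    fits: dict[int, FretFit] = field(default_factory=dict)


# Coarse-grid search settings preceding local refinement.
_KDISS_GRID = np.logspace(-1, 7, 49)
_ETILDE_GRID = np.linspace(0.05, 1.0, 20)
_ETILDE_MIN = 0.05


def _prepare_dataset(dataset: Sequence[FretRecord], params: ProximityParams):
    totals = np.array([r.total for r in dataset], dtype=float)
    keep = totals > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} records with zero total concentration", stacklevel=3)
    recs = [r for r, k in zip(dataset, keep) if k]
    if len(recs) < 3:
        raise InsufficientDataError(f"need >= 3 records with positive total, have {len(recs)}")
    totals = totals[keep]
    x_a = np.array([r.x_a for r in recs], dtype=float)
    acc = np.array([r.acceptor_conc for r in recs], dtype=float)
    fret = np.array([r.fret for r in recs], dtype=float)
    corrected = _correct_arrays(fret, acc, params)
    return totals, x_a, corrected, dropped


def fit_fret(
    dataset: Sequence[FretRecord],
    n: int,
    params: ProximityParams | None = None,
    donor_efficiency: Callable = pairwise_parallel_efficiency,
) -> FretFit:
    """Fit (K_diss, Ẽ) of a monomer–n-mer model to proximity-corrected FRET.

    Coarse log-grid over K_diss ∈ [1e−1, 1e7] × Ẽ ∈ [0.05, 1] followed by
    Nelder–Mead refinement from the best grid point; MSE is the mean squared
    residual on corrected FRET.  Deterministic given the dataset.
    """
    params = params or ProximityParams(enabled=False)
    totals, x_a, corrected, _ = _prepare_dataset(dataset, params)
    messages: list[str] = []

    distinct = np.unique(np.round(totals, 9))
    ill = distinct.size < 2
    if ill:
        messages.append("ill-conditioned: single total concentration; K_diss and Ẽ are not jointly identifiable")

    if n == 1:
        mse = float(np.mean(corrected**2))
        return FretFit(1, float("inf"), 1.0, mse, len(totals), ill, tuple(messages))

    # Binomial composition weights are independent of (K, Ẽ): precompute.
    ks = np.arange(n)
    w = binom.pmf(ks, n - 1, x_a[:, None])  # (N, n)
    eta_grid = np.stack([pairwise_parallel_efficiency(ks, e) for e in _ETILDE_GRID], axis=1)  # (n, nE)

    best = (np.inf, _KDISS_GRID[0], _ETILDE_GRID[0])
    for k_diss in _KDISS_GRID:
        f = oligomeric_fraction(totals, EquilibriumModel(n, k_diss))
        pred = f[:, None] * (w @ eta_grid)  # (N, nE)
        mses = np.mean((pred - corrected[:, None]) ** 2, axis=0)
        j = int(np.argmin(mses))
        if mses[j] < best[0]:
            best = (float(mses[j]), float(k_diss), float(_ETILDE_GRID[j]))

    def objective(theta):
        log_k, e_tilde = theta
        if not (math.log10(_KDISS_GRID[0]) - 2 <= log_k <= math.log10(_KDISS_GRID[-1]) + 2):
            return np.inf
        if not (_ETILDE_MIN <= e_tilde <= 1.0):
            return np.inf
        f = oligomeric_fraction(totals, EquilibriumModel(n, 10.0**log_k))
        eta = donor_efficiency(ks, e_tilde)
        pred = f * (w @ eta)
        return float(np.mean((pred - corrected) ** 2))

    res = minimize(
        objective,
        x0=[math.log10(best[1]), best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    mse, k_fit, e_fit = float(res.fun), float(10.0 ** res.x[0]), float(res.x[1])
    if mse > best[0]:  # local refinement should never lose to its start
        mse, k_fit, e_fit = best

    if np.allclose(corrected, 0.0):
        messages.append("all corrected FRET values are zero; Ẽ pinned at the lower search bound")
        e_fit = _ETILDE_MIN
        warnings.warn(messages[-1], stacklevel=2)

    return FretFit(n, k_fit, float(np.clip(e_fit, _ETILDE_MIN, 1.0)), mse, len(totals), ill, tuple(messages))


def select_order(
    dataset: Sequence[FretRecord],
    params: ProximityParams | None = None,
    orders: Sequence[int] = range(1, 7),
) -> OrderSelection:
    """Fit each candidate oligomer order and pick the one with minimal MSE.

    Ties are broken toward the smaller order (parsimony).
    """
    fits = {n: fit_fret(dataset, n, params) for n in orders}
    mse_by_order = {n: fits[n].mse for n in orders}
    best = min(sorted(mse_by_order), key=lambda n: (mse_by_order[n], n))
    return OrderSelection(mse_by_order=mse_by_order, best_order=best, fits=fits)


def binned_fraction_curve(
    dataset: Sequence[FretRecord],
    fit: FretFit,
    bins: int = 12,
    params: ProximityParams | None = None,
):
    """Binned oligomeric-fraction curve: (bin center, mean fraction, SE, m).

    Each record's fraction is inferred as corrected FRET divided by its own
    composition factor Ē(n, x_A, Ẽ), clipped to [0, 1]; records are grouped
    into log-spaced bins of total density; bins with < 2 records are
    omitted.  Returns a pandas DataFrame.
    """
    import pandas as pd

    params = params or ProximityParams(enabled=False)
    totals, x_a, corrected, _ = _prepare_dataset(dataset, params)
    ebar = mean_donor_efficiency(fit.n, x_a, fit.e_tilde) if fit.n >= 2 else np.zeros_like(x_a)
    valid = ebar > 0
    frac = np.full_like(totals, np.nan)
    frac[valid] = np.clip(corrected[valid] / ebar[valid], 0.0, 1.0)

    lo, hi = totals.min(), totals.max()
    if np.isclose(lo, hi):
        edges = np.array([lo * 0.999, hi * 1.001])
    else:
        edges = np.geomspace(lo, hi, bins + 1)
        edges[-1] *= 1 + 1e-12  # include the max
    idx = np.digitize(totals, edges) - 1

    rows = []
    for b in range(len(edges) - 1):
        sel = (idx == b) & np.isfinite(frac)
        m = int(sel.sum())
        if m < 2:
            continue
        vals = frac[sel]
        rows.append(
            {
                "bin_center": math.sqrt(edges[b] * edges[b + 1]),
                "mean_fraction": float(vals.mean()),
                "stderr": float(vals.std(ddof=1) / math.sqrt(m)),
                "n_records": m,
            }
        )
    return pd.DataFrame(rows, columns=["bin_center", "mean_fraction", "stderr", "n_records"])
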