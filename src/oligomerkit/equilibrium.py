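"""Mass-action monomer–n-mer equilibrium in a 2-D membrane.

The model: n monomers M associate into a single n-mer species M_n with a
two-dimensional dissociation constant

    K_diss = [M]^n / [M_n]        units: (receptors/μm²)^(n−1)

Given a total receptor surface density ``R_total`` (receptors/μm², counting
molecules, not particles), mass conservation reads

    [M] + n·[M]^n / K_diss = R_total

whose unique root on [0, R_total] gives the free-monomer density.  All other
quantities (oligomeric fraction, apparent dissociation constant / half-
saturation density, dimerization free energy) derive from that root.

Free energy uses the 2-D standard state of 1 receptor/nm² = 10⁶ receptors/μm²:
ΔG = R·T·ln(K_diss/10⁶), reported only for dimers (n = 2), where K_diss has
concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedOperationError

__all__ = [
    "EquilibriumModel",
    "SpeciesState",
    "ThermoConstants",
    "monomer_concentration",
    "monomer_concentration_closed_form_dimer",
    "species_state",
    "oligomeric_fraction",
    "half_saturation",
    "kdiss_from_half_saturation",
    "free_energy",
    "STANDARD_STATE",
    "GAS_CONSTANT_KCAL",
]

#: 2-D standard state: 1 receptor/nm² expressed in receptors/μm².
STANDARD_STATE = 1.0e6

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Bisection settings (monotone residual guarantees the bracket [0, total]).
_BISECT_REL_TOL = 1e-12
_BISECT_MAX_ITER = 200


@dataclass(frozen=True)
class EquilibriumModel:
    """Monomer–n-mer equilibrium parameters.

    Parameters
    ----------
    n
        Oligomer order (1 = monomeric only, 2 = dimer, 3 = trimer, ...).
    k_diss
        Dissociation constant, units (receptors/μm²)^(n−1).  For n = 1 the
        value is irrelevant (all receptors are monomeric) but must be positive.
    """

    n: int
    k_diss: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise InvalidInputError(f"oligomer order must be an integer >= 1, got {self.n}")
        if not (self.k_diss > 0):
            raise InvalidInputError(f"k_diss must be positive, got {self.k_diss}")


@dataclass(frozen=True)
class SpeciesState:
    """Resolved species composition at one total receptor density."""

    total: float
    monomer: float
    oligomer_conc: float  # n-mer particles/μm²
    oligomeric_fraction: float


@dataclass(frozen=True)
class ThermoConstants:
    """Constants entering the 2-D dimerization free energy."""

    temperature: float = 298.15  # K
    gas_constant: float = GAS_CONSTANT_KCAL  # kcal/(mol·K)
    standard_state: float = STANDARD_STATE  # receptors/μm²

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be positive, got {self.temperature}")


def monomer_concentration(total, model: EquilibriumModel):
    """Free-monomer density [M] at total density ``total``.

    Solves M + n·Mⁿ/K = total by bisection on [0, total] (the residual is
    strictly increasing in M, so the bracket is guaranteed).  Accepts scalars
    or arrays; vectorized over ``total``.
    """
    arr = np.asarray(total, dtype=float)
    scalar = arr.ndim == 0
    t = np.atleast_1d(arr)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise InvalidInputError("total receptor concentration must be finite and >= 0")

    if model.n == 1:
        m = t.copy()
    else:
        lo = np.zeros_like(t)
        hi = t.copy()
        n, k = model.n, model.k_diss
        for _ in range(_BISECT_MAX_ITER):
            mid = 0.5 * (lo + hi)
            resid = mid + n * mid**n / k - t
            high = resid > 0
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
            if np.all(hi - lo <= _BISECT_REL_TOL * t):
                break
        m = 0.5 * (lo + hi)
    return float(m[0]) if scalar else m.reshape(arr.shape)


def monomer_concentration_closed_form_dimer(total, k_diss: float):
    """Closed-form [M] for the dimer case: (K/4)·(√(1+8R/K) − 1)."""
    t = np.asarray(total, dtype=float)
    return (k_diss / 4.0) * (np.sqrt(1.0 + 8.0 * t / k_diss) - 1.0)


def species_state(total: float, model: EquilibriumModel) -> SpeciesState:
    """Full species breakdown (monomer, n-mer particles, oligomeric fraction)."""
    m = monomer_concentration(total, model)
    if model.n == 1:
        return SpeciesState(total=float(total), monomer=m, oligomer_conc=0.0, oligomeric_fraction=0.0)
    olig = (total - m) / model.n
    frac = 0.0 if total == 0 else (total - m) / total
    return SpeciesState(total=float(total), monomer=m, oligomer_conc=olig, oligomeric_fraction=float(np.clip(frac, 0.0, 1.0)))


def oligomeric_fraction(total, model: EquilibriumModel):
    """Fraction of receptor *molecules* residing in oligomers, in [0, 1].

    Defined as (total − [M])/total; the dilute limit at total = 0 is taken
    as 0.  Vectorized over ``total``.
    """
    arr = np.asarray(total, dtype=float)
    m = monomer_concentration(arr, model)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(arr > 0, (arr - m) / np.where(arr > 0, arr, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if arr.ndim == 0 else frac


def half_saturation(model: EquilibriumModel) -> float:
    """Total density at which the oligomeric fraction equals 1/2.

    At the half point [M] = R/2, so R/2 + n·(R/2)ⁿ/K = R gives the closed
    form R = 2·(K/n)^(1/(n−1)).  This is the "apparent dissociation
    constant" of an n-mer; for n = 2 it equals K_diss exactly.
    """
    if model.n < 2:
        raise UndefinedOperationError("half-saturation is undefined for a monomer-only model (n = 1)")
    return 2.0 * (model.k_diss / model.n) ** (1.0 / (model.n - 1))


def kdiss_from_half_saturation(r_half: float, n: int) -> float:
    """Dissociation constant with a prescribed half-saturation density.

    Inverse of :func:`half_saturation`: K = n·(R_half/2)^(n−1).
    """
    if n < 2:
        raise UndefinedOperationError("half-saturation is undefined for n = 1")
    if not (r_half > 0):
        raise InvalidInputError(f"half-saturation density must be positive, got {r_half}")
    return float(n) * (r_half / 2.0) ** (n - 1)


def free_energy(k_diss: float, constants: ThermoConstants | None = None) -> float:
    """Dimerization free energy ΔG = R·T·ln(K_diss/10⁶) in kcal/mol.

    ``k_diss`` must be the dimer (n = 2) dissociation constant in
    receptors/μm²; the standard state is 1 receptor/nm².  Negative whenever
    the dimer is stable at standard state (K_diss < 10⁶).
    """
    if not (k_diss > 0) or not np.isfinite(k_diss):
        raise InvalidInputError(f"k_diss must be a positive finite number, got {k_diss}")
    c = constants or ThermoConstants()
    return c.gas_constant * c.temperature * float(np.log(k_diss / c.standard_state))
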