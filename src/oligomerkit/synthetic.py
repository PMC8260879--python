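"""Synthetic data with the statistical structure the analyses assume.

Three generators, each a pure function of its truth object and seed:

* FRET datasets — per-membrane-region donor/acceptor densities and
  apparent FRET composed from the same forward model the fitter inverts
  (mass-action equilibrium + binomial labeling + optional proximity FRET),
  with Gaussian measurement noise.
* FIF image segments — compound-Poisson pixel statistics of a mixture of
  monomers and n-mers drawn from an equilibrium model: particle counts per
  pixel are Poisson in each species, photon counts are Poisson given the
  particles, so the brightness estimator's target is λ·⟨s²⟩/⟨s⟩ exactly.
* Toy trajectories — a Cα chain laid out as compact spatial clusters (the
  planted communities) whose residues share a latent motion factor, giving
  a prescribed intra-community displacement correlation, plus independent
  per-residue noise.

Concentration ranges default to 50–10,000 receptors/μm², emulating the
wide expression range of transient transfection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .equilibrium import EquilibriumModel, monomer_concentration
from .errors import InvalidInputError
from .fret import FretRecord, ProximityParams, add_proximity, predict_fret
from .structures import Structure, Trajectory, TrajectoryBundle, make_atom_table

__all__ = [
    "FretTruth",
    "FifTruth",
    "TrajTruth",
    "generate_fret_dataset",
    "generate_fif_images",
    "generate_trajectory",
]


@dataclass(frozen=True)
class FretTruth:
    """Ground truth for a synthetic FRET dataset.

    Defaults emulate an unliganded dimerizing receptor: K_diss = 1050
    receptors/μm², Ẽ = 0.55, 1:1 donor:acceptor transfection with
    cell-to-cell Beta jitter, log-uniform totals over 50–10,000
    receptors/μm², Gaussian FRET noise of sd 0.03.  The proximity term is
    off by default (the analysis consumes proximity-corrected
    efficiencies); enabling it composes the Wolber–Hudson contribution via
    the exact inverse of the corrector.
    """

    n: int = 2
    k_diss: float = 1050.0
    e_tilde: float = 0.55
    donor_acceptor_ratio: float = 1.0  # expected x_D : x_A
    conc_range: tuple[float, float] = (50.0, 10_000.0)
    fret_noise_sd: float = 0.03
    proximity: ProximityParams = field(default_factory=lambda: ProximityParams(enabled=False))
    n_records: int = 300
    seed: int = 0
    x_a_beta_concentration: float = 50.0  # Beta jitter sharpness of x_A

    def __post_init__(self) -> None:
        if self.conc_range[0] <= 0 or self.conc_range[1] < self.conc_range[0]:
            raise InvalidInputError("conc_range must satisfy 0 < min <= max")
        if self.fret_noise_sd < 0:
            raise InvalidInputError("fret_noise_sd must be >= 0")

    @property
    def nominal_x_a(self) -> float:
        return 1.0 / (1.0 + self.donor_acceptor_ratio)

    @property
    def model(self) -> EquilibriumModel:
        return EquilibriumModel(self.n, self.k_diss)


def generate_fret_dataset(truth: FretTruth) -> list[FretRecord]:
    """Draw per-region FRET records from the forward model; reproducible."""
    rng = np.random.default_rng(truth.seed)
    lo, hi = truth.conc_range
    total = np.exp(rng.uniform(math.log(lo), math.log(hi), truth.n_records))
    c = truth.x_a_beta_concentration
    xa_mean = truth.nominal_x_a
    x_a = rng.beta(xa_mean * c, (1.0 - xa_mean) * c, truth.n_records)
    specific = predict_fret(total, x_a, truth.model, truth.e_tilde)
    acceptor = x_a * total
    measured = add_proximity(specific, acceptor, truth.proximity)
    if truth.fret_noise_sd > 0:
        measured = measured + rng.normal(0.0, truth.fret_noise_sd, truth.n_records)
    measured = np.clip(measured, 0.0, 1.0)
    return [
        FretRecord(
            donor_conc=float(t - a),
            acceptor_conc=float(a),
            fret=float(f),
            cell_id=f"sim{i:04d}",
        )
        for i, (t, a, f) in enumerate(zip(total, acceptor, measured))
    ]


@dataclass(frozen=True)
class FifTruth:
    """Ground truth for synthetic FIF image segments.

    ``model`` sets the monomer–n-mer composition at each segment's total
    density (drawn log-uniformly from ``conc_range``); ``pure_order`` ≥ 1
    instead makes every particle an n-mer of that order regardless of
    density.  Pixel area defaults to 0.01 μm² (100 nm pixels); monomer
    brightness λ is in photons/frame.
    """

    model: EquilibriumModel = field(default_factory=lambda: EquilibriumModel(2, 1050.0))
    pure_order: int | None = None
    monomer_brightness: float = 1.0
    pixel_area: float = 0.01  # μm²
    segment_count: int = 2000
    segment_size: int = 15  # pixels per side
    conc_range: tuple[float, float] = (50.0, 10_000.0)
    detector: Literal["photon_counting", "analog"] = "photon_counting"
    detector_variance: float = 0.0  # analog Gaussian noise variance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monomer_brightness <= 0:
            raise InvalidInputError("monomer brightness must be positive")
        if self.segment_size * self.segment_size < 225:
            raise InvalidInputError("segments must be at least 15x15 pixels")


def generate_fif_images(truth: FifTruth):
    """Compound-Poisson segment stack plus per-segment true concentrations.

    Returns ``(stack, table)``: stack of shape (segment_count, s, s) —
    integer photon counts in photon-counting mode, floats with added
    Gaussian detector noise in analog mode — and a DataFrame with each
    segment's true total receptor concentration and species densities.
    """
    rng = np.random.default_rng(truth.seed)
    s = truth.segment_size
    lo, hi = truth.conc_range
    total = np.exp(rng.uniform(math.log(lo), math.log(hi), truth.segment_count))

    if truth.pure_order is not None:
        n = truth.pure_order
        monomer = np.zeros_like(total) if n > 1 else total
        olig = (total - monomer) / n if n > 1 else np.zeros_like(total)
    else:
        n = truth.model.n
        monomer = monomer_concentration(total, truth.model)
        olig = (total - monomer) / n if n > 1 else np.zeros_like(total)

    lam = truth.monomer_brightness
    area = truth.pixel_area
    # particles per pixel, by species, then photons given particles
    mono_counts = rng.poisson(monomer[:, None, None] * area, size=(truth.segment_count, s, s))
    olig_counts = rng.poisson(olig[:, None, None] * area, size=(truth.segment_count, s, s))
    rate = lam * (mono_counts + n * olig_counts)
    photons = rng.poisson(rate)
    if truth.detector == "analog":
        stack = photons + rng.normal(0.0, math.sqrt(truth.detector_variance), photons.shape)
    else:
        stack = photons
    table = pd.DataFrame(
        {
            "segment": np.arange(truth.segment_count),
            "total_conc": total,
            "monomer_conc": monomer,
            "oligomer_conc": olig,
            "oligomer_order": n,
        }
    )
    return stack, table


@dataclass(frozen=True)
class TrajTruth:
    """Ground truth for a toy Cα trajectory with planted communities.

    Residues are grouped into spatial clusters (``community_sizes``), each a
    ring of radius ``cluster_radius`` Å; cluster centers are
    ``cluster_spacing`` Å apart, so neighbouring clusters touch (closest
    cross-cluster Cα pair at spacing − 2·radius) and provide sparse
    bridging contacts.  Same-community residues share a latent motion
    factor giving displacement correlation ≈ ``coupling``; community
    latents are themselves correlated by ``inter_community_coupling``.
    """

    community_sizes: tuple[int, ...] = (6, 6)
    fluctuation_sd: float = 0.3  # Å per coordinate
    coupling: float = 0.9
    inter_community_coupling: float = 0.0
    frames: int = 500
    replicates: int = 3
    cluster_radius: float = 2.0
    cluster_spacing: float = 8.0
    frame_interval_ps: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2:
            raise InvalidInputError("need at least 2 frames")
        if not self.community_sizes or any(m < 1 for m in self.community_sizes):
            raise InvalidInputError("community sizes must be positive")
        for name, v in (("coupling", self.coupling), ("inter_community_coupling", self.inter_community_coupling)):
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")

    @property
    def n_residues(self) -> int:
        return sum(self.community_sizes)

    @property
    def community_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.community_sizes)), self.community_sizes)


def _reference_coords(truth: TrajTruth) -> np.ndarray:
    coords = []
    for c, m in enumerate(truth.community_sizes):
        center = np.array([c * truth.cluster_spacing, 0.0, 0.0])
        ang = 2.0 * math.pi * np.arange(m) / max(m, 1)
        # rings lie in the xy-plane so neighbouring clusters can touch along x
        ring = np.column_stack(
            [truth.cluster_radius * np.cos(ang), truth.cluster_radius * np.sin(ang), np.zeros(m)]
        )
        coords.append(center + ring)
    return np.vstack(coords)


def generate_trajectory(truth: TrajTruth) -> TrajectoryBundle:
    """Correlated-Gaussian toy trajectory bundle around the reference chain."""
    ref_xyz = _reference_coords(truth)
    n = truth.n_residues
    atoms = make_atom_table(
        chain=["A"] * n,
        res_id=np.arange(1, n + 1),
        res_name=["GLY"] * n,
        atom_name=["CA"] * n,
        element=["C"] * n,
    )
    reference = Structure(atoms, ref_xyz)
    comm = truth.community_assignment
    n_comm = len(truth.community_sizes)
    rho = truth.coupling
    kappa = truth.inter_community_coupling
    sd = truth.fluctuation_sd

    replicates = []
    for rep in range(truth.replicates):
        rng = np.random.default_rng([truth.seed, rep])
        glob = rng.standard_normal((truth.frames, 1, 3))
        latent = rng.standard_normal((truth.frames, n_comm, 3))
        latent = math.sqrt(kappa) * glob + math.sqrt(1.0 - kappa) * latent
        noise = rng.standard_normal((truth.frames, n, 3))
        disp = sd * (math.sqrt(rho) * latent[:, comm, :] + math.sqrt(1.0 - rho) * noise)
        replicates.append(Trajectory(atoms, ref_xyz[None] + disp))
    return TrajectoryBundle(
        replicates=replicates,
        reference=reference,
        frame_interval_ps=truth.frame_interval_ps,
        meta={"community_assignment": comm.tolist()},
    )
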