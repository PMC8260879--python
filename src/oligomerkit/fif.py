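"""Fluorescence intensity fluctuation (FIF) molecular-brightness analysis.

A membrane image is tiled into small square segments (default 15×15
pixels).  Within each segment the molecular brightness ε — the photon
emission rate per diffusing particle — is estimated from the
variance-to-mean ratio of the pixel intensities:

    analog detector:          ε = (σ² − σ_D²) / ⟨I⟩
    photon-counting detector: ε = σ²/⟨I⟩ − 1

where σ² is the pixel-intensity variance across the segment, σ_D² the
detector-noise variance, and ⟨I⟩ the mean intensity.  For a compound-
Poisson pixel model (Poisson particles per pixel, Poisson photons per
particle) the photon-counting estimator converges to λ·⟨s²⟩/⟨s⟩, the
particle-weighted mean oligomer size times the monomer brightness λ — so
pure dimers give 2λ and pure trimers 3λ.  Brightness histograms across
thousands of segments, optionally restricted to high receptor
concentrations where monomers are scarce, reveal the dominant oligomer
size as the position of the histogram mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "SegmentGrid",
    "BrightnessRecord",
    "BrightnessHistogram",
    "segment_image",
    "brightness",
    "brightness_records",
    "brightness_histogram",
]

Mode = Literal["analog", "photon_counting"]


@dataclass(frozen=True)
class SegmentGrid:
    """Square tiles cut from one membrane region.

    ``segments`` has shape (n_segments, s, s); border remainders of the
    source image are dropped, never padded.
    """

    segments: np.ndarray
    segment_size: int
    pixel_area: float  # μm² per pixel

    def __len__(self) -> int:
        return self.segments.shape[0]


@dataclass(frozen=True)
class BrightnessRecord:
    """Brightness and concentration estimates for one segment."""

    epsilon: float  # molecular brightness (photons/frame/particle)
    mean_intensity: float
    variance: float
    detector_variance: float
    concentration: float  # receptors/μm² (nan when no calibration given)
    mode_flag: Mode
    epsilon_monomeric: float = float("nan")  # ε/λ when λ provided


@dataclass(frozen=True)
class BrightnessHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_epsilon: float  # center of the maximal bin (ties -> lowest bin)


def segment_image(region: np.ndarray, segment_size: int = 15, pixel_area: float = 1.0) -> SegmentGrid:
    """Tile a 2-D intensity array row-major into segment_size² blocks.

    Yields ⌊H/s⌋·⌊W/s⌋ segments; partial border tiles are excluded.
    """
    region = np.asarray(region)
    if region.ndim != 2:
        raise InvalidInputError(f"expected a 2-D intensity array, got shape {region.shape}")
    h, w = region.shape
    s = int(segment_size)
    if h < s or w < s:
        raise InvalidInputError(f"region {region.shape} smaller than one {s}x{s} tile")
    nh, nw = h // s, w // s
    tiles = (
        region[: nh * s, : nw * s]
        .reshape(nh, s, nw, s)
        .transpose(0, 2, 1, 3)
        .reshape(nh * nw, s, s)
    )
    return SegmentGrid(segments=tiles, segment_size=s, pixel_area=pixel_area)


def brightness(
    segment: np.ndarray,
    mode: Mode = "photon_counting",
    detector_variance: float = 0.0,
    monomer_brightness: float | None = None,
    pixel_area: float = 1.0,
) -> BrightnessRecord:
    """Molecular brightness of one segment from its pixel statistics.

    Photon-counting mode removes the shot-noise floor analytically
    (ε = σ²/⟨I⟩ − 1); analog mode subtracts the supplied detector variance
    (ε = (σ² − σ_D²)/⟨I⟩).  When the monomer brightness λ is given, the
    brightness is also reported in monomeric units (ε/λ) and the segment
    receptor concentration is estimated as ⟨I⟩/(λ·pixel_area).

    Negative brightness can occur in dim segments and is returned as-is
    (with a warning) rather than clipped.
    """
    seg = np.asarray(segment, dtype=float).ravel()
    if seg.size == 0:
        raise InvalidInputError("empty segment")
    mean = float(seg.mean())
    var = float(seg.var(ddof=1)) if seg.size > 1 else 0.0
    if mean <= 0:
        raise InvalidInputError("mean intensity must be > 0 for a brightness estimate")
    if mode == "photon_counting":
        eps = var / mean - 1.0
    elif mode == "analog":
        eps = (var - detector_variance) / mean
    else:
        raise InvalidInputError(f"unknown detector mode {mode!r}")
    if eps < 0:
        warnings.warn(f"negative molecular brightness ({eps:.3g}) in a dim segment", stacklevel=2)
    conc = float("nan")
    eps_mono = float("nan")
    if monomer_brightness is not None:
        if monomer_brightness <= 0:
            raise InvalidInputError("monomer brightness must be positive")
        conc = mean / (monomer_brightness * pixel_area)
        eps_mono = eps / monomer_brightness
    return BrightnessRecord(
        epsilon=eps,
        mean_intensity=mean,
        variance=var,
        detector_variance=detector_variance,
        concentration=conc,
        mode_flag=mode,
        epsilon_monomeric=eps_mono,
    )


def brightness_records(
    grid: SegmentGrid,
    mode: Mode = "photon_counting",
    detector_variance: float = 0.0,
    monomer_brightness: float | None = None,
) -> list[BrightnessRecord]:
    """Per-segment brightness for a whole grid (convenience loop)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-ε warnings are per-batch noise
        return [
            brightness(seg, mode, detector_variance, monomer_brightness, grid.pixel_area)
            for seg in grid.segments
        ]


def brightness_histogram(
    records: Sequence[BrightnessRecord],
    min_concentration: float | None = None,
    bin_width: float = 0.1,
    monomeric_units: bool = True,
) -> BrightnessHistogram:
    """Histogram of per-segment brightness with optional concentration filter.

    Retains records with concentration > ``min_concentration`` (when given);
    uniform bins of ``bin_width`` starting at the data minimum.  The mode is
    the center of the maximal-count bin among bins at ε ≥ 0 (negative values
    are kept in the histogram but excluded from modal estimation); count
    ties break toward the lowest bin.
    """
    vals = np.array(
        [r.epsilon_monomeric if monomeric_units else r.epsilon for r in records], dtype=float
    )
    if monomeric_units and np.any(np.isnan(vals)):
        raise InvalidInputError("monomeric units requested but some records lack a calibration λ")
    if min_concentration is not None:
        conc = np.array([r.concentration for r in records], dtype=float)
        vals = vals[conc > min_concentration]
    if vals.size == 0:
        raise InsufficientDataError("no records retained after concentration filtering")

    lo = float(vals.min())
    n_bins = max(1, int(math.ceil((vals.max() - lo) / bin_width)) or 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= vals.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nonneg = centers >= 0
    if nonneg.any():
        sub = np.where(nonneg)[0]
        modal = centers[sub[np.argmax(counts[sub])]]
    else:
        modal = centers[int(np.argmax(counts))]
    return BrightnessHistogram(bin_edges=edges, counts=counts, modal_epsilon=float(modal))
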