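"""Core data structures shared across the mass-photometry pipeline.

Conventions used throughout the package:

* time is measured in seconds from the moment of sample addition
  (``t_addition = 0``);
* contrast is the dimensionless ratiometric reflectivity change of a single
  landing event, stored as a positive magnitude;
* lengths are integer base pairs (dsDNA) or nucleotides (ssDNA);
* pixel coordinates are 0-based, origin top-left, ``x`` = column,
  ``y`` = row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: conversion from imaging contrast to contour length for dsDNA (per bp)
DEFAULT_KAPPA_DS = 1.22e-5
#: per-nucleotide contrast for ssDNA; half the per-bp dsDNA-equivalent slope
DEFAULT_KAPPA_SS = 7.1e-6
#: mean mass of one dsDNA base pair, kDa
DEFAULT_BP_MASS_KDA = 0.649
#: diffusion scaling exponent of the binding rate with DNA length
DEFAULT_BETA = -0.72

#: instrument defaults: 955 Hz camera with 5-fold temporal averaging
EFFECTIVE_FRAME_RATE_HZ = 191.0
EFFECTIVE_PIXEL_SIZE_NM = 84.4
ACQUISITION_DURATION_S = 120.0


@dataclass(frozen=True)
class SpeciesDef:
    """One nucleic-acid species in a simulated mixture.

    Parameters
    ----------
    label:
        Human-readable species name (e.g. ``"800bp"``).
    length:
        Contour length in base pairs (dsDNA) or nucleotides (ssDNA).
    strandedness:
        ``"double"`` or ``"single"``.
    mole_fraction:
        Relative solution concentration in [0, 1]; fractions across a
        mixture must sum to 1.
    n_molecules:
        Number of molecules of this species present in solution at the
        moment of sample addition.
    """

    label: str
    length: int
    strandedness: str = "double"
    mole_fraction: float = 1.0
    n_molecules: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.strandedness not in ("double", "single"):
            raise ValueError(
                f"strandedness must be 'double' or 'single', got {self.strandedness!r}"
            )
        if not 0.0 <= self.mole_fraction <= 1.0:
            raise ValueError(f"mole_fraction must be in [0, 1], got {self.mole_fraction}")
        if self.n_molecules < 0:
            raise ValueError(f"n_molecules must be >= 0, got {self.n_molecules}")


def validate_mixture(mixture: Sequence[SpeciesDef]) -> None:
    """Check that mixture mole fractions sum to 1 (within 1e-9)."""
    if not mixture:
        return
    total = sum(s.mole_fraction for s in mixture)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture mole fractions sum to {total}, expected 1")
    labels = [s.label for s in mixture]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in mixture")


@dataclass(frozen=True)
class ContrastModel:
    """Linear contrast-versus-length model with a length-dependent spread.

    The mean contrast of a species of length ``L`` is
    ``intercept + kappa * L``.  Individual landing events scatter around the
    mean with a relative spread (coefficient of variation) that switches
    from ``cv_small`` to ``cv_large`` at ``crossover_length``, emulating the
    observed growth of peak width with molecular size.
    """

    kappa: float = DEFAULT_KAPPA_DS
    intercept: float = 0.0
    cv_small: float = 0.02
    cv_large: float = 0.06
    crossover_length: int = 400

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.cv_small < 0 or self.cv_large < 0:
            raise ValueError("contrast CVs must be >= 0")

    def cv(self, length: int) -> float:
        return self.cv_small if length <= self.crossover_length else self.cv_large

    def mean_contrast(self, length: int) -> float:
        return self.intercept + self.kappa * length

    def contrast_sd(self, length: int) -> float:
        return self.kappa * length * self.cv(length)


@dataclass(frozen=True)
class AcquisitionWindow:
    """Observation window [t0, t_final], seconds after sample addition."""

    t0: float = 15.0
    t_final: float = 135.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t0 < self.t_final:
            raise ValueError(
                f"require 0 <= t0 < t_final, got t0={self.t0}, t_final={self.t_final}"
            )

    @property
    def duration(self) -> float:
        return self.t_final - self.t0

    def observed_fraction(self, k: float) -> float:
        """Fraction of an exponential-k population landing inside the window."""
        return math.exp(-k * self.t0) - math.exp(-k * self.t_final)


@dataclass
class KineticsModel:
    """Diffusion-limited surface-binding kinetics, ``k_i = alpha * L**beta``.

    ``alpha`` is the scaling factor shared by all species; ``beta`` is the
    diffusion exponent (default -0.72 for DNA).  When the model is derived
    from data, ``k`` holds the fitted average binding rate and
    ``mean_length`` the abundance-weighted average length it refers to, and
    the invariant ``alpha == k / mean_length**beta`` is enforced.
    """

    alpha: float
    beta: float = DEFAULT_BETA
    k: Optional[float] = None
    mean_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta >= 0:
            raise ValueError("beta must be < 0")
        if self.k is not None and self.mean_length is not None:
            expected = self.k / self.mean_length**self.beta
            if abs(expected - self.alpha) > 1e-9 * max(abs(self.alpha), 1e-300):
                raise ValueError(
                    f"inconsistent kinetics: alpha={self.alpha} but "
                    f"k/mean_length**beta={expected}"
                )

    @classmethod
    def from_average_rate(
        cls, k: float, mean_length: float, beta: float = DEFAULT_BETA
    ) -> "KineticsModel":
        if k <= 0 or mean_length <= 0:
            raise ValueError("k and mean_length must be > 0")
        return cls(alpha=k / mean_length**beta, beta=beta, k=k, mean_length=mean_length)

    def rate(self, length: float) -> float:
        """Per-species binding rate constant k_i in 1/s."""
        if length < 1:
            raise ValueError(f"length must be >= 1, got {length}")
        return self.alpha * float(length) ** self.beta


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted component of the contrast histogram.

    ``A`` is the maximum height at the centroid (in count-per-bin units when
    fitted to a histogram), ``mu`` the centroid contrast, ``sigma`` the
    standard deviation.  The area follows the closed form a = A*sigma*sqrt(2*pi).
    """

    A: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def area(self) -> float:
        return self.A * self.sigma * SQRT_2PI


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-kernel density of event contrasts on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have matching shapes")


@dataclass(frozen=True)
class CalibrationFit:
    """Linear contrast-to-length calibration.

    ``r_squared`` is ``None`` when fewer than three points were fitted (a
    two-point line is exact by construction).
    """

    slope: float
    intercept: float
    r_squared: Optional[float]
    excluded_labels: tuple = ()
    n_points: int = 0
    through_origin: bool = False


@dataclass(frozen=True)
class LengthError:
    """Deviation of recovered from nominal lengths, per species and pooled.

    ``sd_error`` uses the sample convention (ddof=1) and is NaN for a single
    observation.
    """

    labels: tuple
    nominal: tuple
    estimated: tuple
    deviations: tuple
    mean_error: float
    sd_error: float


@dataclass
class AbundanceEstimate:
    """Per-species abundance before and after the diffusion correction."""

    label: str
    length: int
    raw_area: float
    k_i: float
    corrected_area: float
    mole_fraction: float = float("nan")
    near_detection_floor: bool = False


@dataclass(frozen=True)
class DetectionParams:
    """Landing-event detection parameters.

    ``threshold1`` is the amplitude criterion expressed as a multiple of the
    robust per-frame noise scale (1.4826 x median absolute deviation);
    ``threshold2`` is the minimum radial-symmetry score in [0, 1];
    ``n_binned`` is the number of raw frames averaged per batch before the
    ratiometric difference; ``psf_sigma_px`` is the matched-filter width
    used for candidate search.
    """

    n_binned: int = 8
    threshold1: float = 1.0
    threshold2: float = 0.2
    patch_radius_px: int = 5
    psf_sigma_px: float = 1.4

    def __post_init__(self) -> None:
        if self.n_binned < 1:
            raise ValueError("n_binned must be >= 1")
        if self.threshold1 < 0:
            raise ValueError("threshold1 must be >= 0")
        if not 0.0 <= self.threshold2 <= 1.0:
            raise ValueError("threshold2 must be in [0, 1]")
        if self.patch_radius_px < 1:
            raise ValueError("patch_radius_px must be >= 1")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")


@dataclass
class MovieStack:
    """A (t, y, x) reflectivity movie plus acquisition metadata.

    ``t_start`` is the timestamp of the first frame in seconds after sample
    addition.  ``ground_truth`` optionally carries the injected event table
    of a simulated stack (ignored by detection).
    """

    frames: np.ndarray
    frame_period: float = 1.0 / EFFECTIVE_FRAME_RATE_HZ
    pixel_size_nm: float = EFFECTIVE_PIXEL_SIZE_NM
    t_start: float = 15.0
    ground_truth: Optional[object] = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (t, y, x) array")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def t_end(self) -> float:
        return self.t_start + self.n_frames * self.frame_period
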