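"""Contrast-to-length calibration and length-accuracy summaries.

MP contrast is proportional to contour length, so an ordinary
least-squares line through the fitted peak means versus nominal length
converts contrast to base pairs (dsDNA) or nucleotides (ssDNA).  Species
approaching the diffraction limit can be excluded from the fit by label.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np

from .models import CalibrationFit, LengthError


def fit_contrast_vs_length(
    contrasts: Sequence[float],
    nominal_lengths: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    exclude: Sequence[str] = (),
    through_origin: bool = False,
) -> CalibrationFit:
    """OLS line of peak-mean contrast versus nominal length.

    ``exclude`` names species (by label) left out of the fit, mirroring the
    exclusion of species whose size approaches the diffraction limit.  With
    ``through_origin=True`` the intercept is constrained to zero.  R^2 is
    reported for >= 3 included points and is ``None`` for a two-point line.
    """
    c = np.asarray(contrasts, dtype=float)
    L = np.asarray(nominal_lengths, dtype=float)
    if c.shape != L.shape:
        raise ValueError("contrasts and nominal_lengths must be paired")
    if labels is None:
        labels = [str(int(l)) for l in L]
    if len(labels) != c.size:
        raise ValueError("labels must be paired with contrasts")
    unknown = set(exclude) - set(labels)
    if unknown:
        raise ValueError(f"exclude names unknown labels: {sorted(unknown)}")

    keep = np.array([lab not in set(exclude) for lab in labels])
    c, L = c[keep], L[keep]
    n = int(c.size)
    if n < 2:
        raise ValueError(f"need >= 2 included points for a linear fit, got {n}")

    if through_origin:
        slope = float(np.sum(L * c) / np.sum(L * L))
        intercept = 0.0
        fitted = slope * L
    else:
        design = np.column_stack([L, np.ones(n)])
        (slope, intercept), *_ = np.linalg.lstsq(design, c, rcond=None)
        slope, intercept = float(slope), float(intercept)
        fitted = slope * L + intercept

    if n >= 3:
        ss_res = float(np.sum((c - fitted) ** 2))
        ss_tot = float(np.sum((c - np.mean(c)) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        r_squared = None

    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        excluded_labels=tuple(exclude),
        n_points=n,
        through_origin=through_origin,
    )


def length_from_contrast(fit: CalibrationFit, contrast) -> np.ndarray | float:
    """Invert the calibration: length = (contrast - intercept) / slope.

    A contrast below the intercept yields a negative estimate, which is
    returned as-is with a warning rather than clamped.
    """
    if fit.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {fit.slope}")
    scalar = np.isscalar(contrast)
    c = np.asarray(contrast, dtype=float)
    est = (c - fit.intercept) / fit.slope
    if np.any(est < 0):
        warnings.warn(
            "contrast below the calibration intercept: negative length estimate",
            stacklevel=2,
        )
    return float(est) if scalar else est


def length_error_summary(
    estimates: Sequence[float],
    nominals: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> LengthError:
    """Deviations (estimated - nominal) with pooled mean and sample SD.

    SD uses ddof=1 and is NaN for a single observation.
    """
    est = np.asarray(estimates, dtype=float)
    nom = np.asarray(nominals, dtype=float)
    if est.shape != nom.shape:
        raise ValueError("estimates and nominals must be paired")
    if est.size == 0:
        raise ValueError("need at least one species")
    if labels is None:
        labels = [str(int(n)) for n in nom]
    dev = est - nom
    sd = float(np.std(dev, ddof=1)) if dev.size > 1 else float("nan")
    return LengthError(
        labels=tuple(labels),
        nominal=tuple(nom.tolist()),
        estimated=tuple(est.tolist()),
        deviations=tuple(dev.tolist()),
        mean_error=float(np.mean(dev)),
        sd_error=sd,
    )


def mass_contrast_ratio(fit: CalibrationFit, mass_per_unit: float) -> float:
    """Contrast per kDa from a per-length slope and a kDa-per-unit mass.

    For dsDNA the default unit mass is 0.649 kDa/bp.  For ssDNA compared on
    the per-bp scale, double the per-nt slope before calling (two
    nucleotides per base pair).
    """
    if mass_per_unit <= 0:
        raise ValueError("mass_per_unit must be > 0")
    return fit.slope / mass_per_unit
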