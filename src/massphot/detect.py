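"""Landing-event detection in ratiometric differential movies.

A reflectivity movie is reduced to an event table in four steps:

1. consecutive non-overlapping batches of ``n_binned`` frames are
   averaged and ratiometric differences between neighbouring batches
   computed, so only reflectivity *changes* (landings) survive above the
   static background;
2. candidate pixels are local maxima of the PSF-matched-filtered absolute
   differential exceeding Threshold 1 x the frame's robust noise scale
   (1.4826 x median absolute deviation);
3. each candidate's raw differential patch is scored for radial symmetry
   (fraction of gradient energy pointing at the patch centre) and kept iff
   the score reaches Threshold 2;
4. survivors are deduplicated across consecutive differential frames (a
   landing mid-batch splits between two of them) and the contrast of each
   event is quantified as the amplitude of a 2-D Gaussian fitted to the
   ratiometric difference between the batch after and the batch before the
   landing boundary, which measures the full reflectivity step regardless
   of where in a batch the molecule landed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .models import DetectionParams, MovieStack

EVENT_COLUMNS = ["time_s", "contrast", "x_px", "y_px", "symmetry_score"]


@dataclass(frozen=True)
class DifferentialStack:
    """Batch-averaged ratiometric differences of a movie.

    ``diff[j] = (batch[j+1] - batch[j]) / batch[j]`` element-wise;
    ``timestamps[j]`` is the time of the boundary between the two batches,
    seconds after sample addition.  ``batches`` keeps the averaged batch
    images for step quantification.
    """

    diff: np.ndarray
    batches: np.ndarray
    timestamps: np.ndarray
    n_binned: int


def ratiometric_stack(movie: MovieStack, n_binned: int) -> DifferentialStack:
    """Batch-average a movie and form ratiometric frame differences.

    Requires at least ``2 * n_binned`` frames; the output has
    ``floor(n_frames / n_binned) - 1`` differential frames.
    """
    if n_binned < 1:
        raise ValueError("n_binned must be >= 1")
    n_frames = movie.n_frames
    if n_frames < 2 * n_binned:
        raise ValueError(
            f"need >= {2 * n_binned} frames for n_binned={n_binned}, got {n_frames}"
        )
    m = n_frames // n_binned
    batches = (
        movie.frames[: m * n_binned]
        .reshape(m, n_binned, *movie.frames.shape[1:])
        .mean(axis=1)
    )
    diff = (batches[1:] - batches[:-1]) / batches[:-1]
    boundaries = n_binned * np.arange(1, m)
    timestamps = movie.t_start + boundaries * movie.frame_period
    return DifferentialStack(
        diff=diff.astype(np.float64),
        batches=batches.astype(np.float64),
        timestamps=timestamps,
        n_binned=n_binned,
    )


def radial_symmetry_score(patch: np.ndarray) -> float:
    """Fraction of gradient energy pointing at the patch centre, in [0, 1].

    Scores 1 for a perfectly radially symmetric patch (every local gradient
    is (anti)parallel to the radial direction) and decreases with
    asymmetry; it is invariant under 90-degree rotation of the patch.  The
    patch must be square with an odd side so the centre is a pixel.
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] % 2 == 0:
        raise ValueError(f"patch must be square with odd side, got shape {p.shape}")
    gy, gx = np.gradient(p)
    c = p.shape[0] // 2
    yy, xx = np.mgrid[: p.shape[0], : p.shape[1]]
    ry = (yy - c).astype(float)
    rx = (xx - c).astype(float)
    rnorm = np.hypot(ry, rx)
    mask = rnorm > 0
    ry, rx = ry[mask] / rnorm[mask], rx[mask] / rnorm[mask]
    gy, gx = gy[mask], gx[mask]
    energy = gy**2 + gx**2
    total = float(energy.sum())
    if total == 0:
        return 1.0  # flat patch: trivially symmetric
    aligned = float(np.sum((gy * ry + gx * rx) ** 2))
    return min(max(aligned / total, 0.0), 1.0)


def _robust_sigma(frame: np.ndarray) -> float:
    med = np.median(frame)
    return 1.4826 * float(np.median(np.abs(frame - med)))


def _fit_gaussian_amplitude(
    patch: np.ndarray, sigma0: float
) -> tuple[float, float, float]:
    """Fit A*exp(-r^2/2s^2)+offset to a patch; return (A, dx, dy) about centre."""
    n = patch.shape[0]
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    y = patch.ravel().astype(float)

    def model(p):
        A, x0, y0, s, off = p
        return A * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2).ravel() / (2 * s**2)) + off

    p0 = np.array([patch[c, c], c, c, sigma0, float(np.median(patch))])
    bounds = (
        [-np.inf, c - 2.0, c - 2.0, 0.3, -np.inf],
        [np.inf, c + 2.0, c + 2.0, n / 2.0, np.inf],
    )
    res = least_squares(lambda p: model(p) - y, p0, bounds=bounds, max_nfev=400)
    A, x0, y0, _, _ = res.x
    return float(A), float(x0 - c), float(y0 - c)


def detect_events(
    diff_stack: DifferentialStack,
    params: DetectionParams,
    max_events_per_frame: int = 200,
) -> pd.DataFrame:
    """Detect and quantify landing events in a differential stack.

    Returns an event table with columns ``time_s`` (timestamp of the
    differential frame of first appearance), ``contrast`` (positive
    magnitude of the fitted step), ``x_px``/``y_px`` (sub-pixel position)
    and ``symmetry_score``.  An empty table is a valid result.
    """
    diff = diff_stack.diff
    n_diff = diff.shape[0]
    r = params.patch_radius_px
    candidates: list[tuple[int, int, int, float, float]] = []

    for j in range(n_diff):
        frame = diff[j]
        smoothed = gaussian_filter(frame, params.psf_sigma_px, mode="reflect")
        sigma = _robust_sigma(smoothed)
        if sigma == 0:
            continue
        coords = peak_local_max(
            np.abs(smoothed),
            min_distance=r,
            threshold_abs=params.threshold1 * sigma,
            exclude_border=r,
            num_peaks=max_events_per_frame,
        )
        for yc, xc in coords:
            patch = frame[yc - r : yc + r + 1, xc - r : xc + r + 1]
            score = radial_symmetry_score(patch)
            if score >= params.threshold2:
                amp = float(np.abs(smoothed[yc, xc]))
                candidates.append((j, int(yc), int(xc), amp, score))

    # deduplicate: the same site in consecutive differential frames is one
    # landing split across a batch boundary; keep the first-appearance time
    # and the larger amplitude's position/score
    by_frame: dict[int, list] = {}
    for cand in candidates:
        by_frame.setdefault(cand[0], []).append(cand)
    events: list[dict] = []
    active: list[dict] = []
    for j in range(n_diff):
        events.extend(ev for ev in active if ev["last_frame"] < j - 1)
        active = [ev for ev in active if ev["last_frame"] == j - 1]
        for _, yc, xc, amp, score in sorted(by_frame.get(j, []), key=lambda c: -c[3]):
            merged = next(
                (
                    ev
                    for ev in active
                    if ev["last_frame"] == j - 1
                    and abs(ev["y"] - yc) <= r
                    and abs(ev["x"] - xc) <= r
                ),
                None,
            )
            if merged is not None:
                if amp > merged["amp"]:
                    merged.update({"y": yc, "x": xc, "amp": amp, "score": score})
                merged["last_frame"] = j
            else:
                active.append(
                    {
                        "first_frame": j,
                        "last_frame": j,
                        "y": yc,
                        "x": xc,
                        "amp": amp,
                        "score": score,
                    }
                )
    events.extend(active)

    batches = diff_stack.batches
    m = batches.shape[0]
    rows = []
    for ev in events:
        j0 = ev["first_frame"]
        pre = max(j0 - 1, 0)
        post = min(j0 + 2, m - 1)
        step = (batches[post] - batches[pre]) / batches[pre]
        yc, xc = ev["y"], ev["x"]
        patch = step[yc - r : yc + r + 1, xc - r : xc + r + 1]
        if patch.shape != (2 * r + 1, 2 * r + 1):
            continue  # too close to the border for quantification
        A, dx, dy = _fit_gaussian_amplitude(patch, params.psf_sigma_px)
        contrast = abs(A)
        if contrast == 0:
            continue
        rows.append(
            {
                "time_s": float(diff_stack.timestamps[j0]),
                "contrast": contrast,
                "x_px": xc + dx,
                "y_px": yc + dy,
                "symmetry_score": ev["score"],
            }
        )

    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(table):
        table = table.sort_values("time_s", kind="mergesort", ignore_index=True)
    return table


def detect_movie(
    movie: MovieStack, params: Optional[DetectionParams] = None
) -> pd.DataFrame:
    """Convenience wrapper: ratiometric processing + event detection."""
    params = params or DetectionParams()
    return detect_events(ratiometric_stack(movie, params.n_binned), params)
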