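"""Synthetic landing-event streams and movie stacks with known ground truth.

The generator reproduces the structure the downstream analysis assumes:
every molecule of species *i* independently draws a surface-binding time
from an exponential distribution with rate ``k_i = alpha * L_i**beta``
(diffusion-limited binding, beta = -0.72 for DNA), only landings inside the
acquisition window [t0, t_final] are recorded, and each recorded event's
ratiometric contrast is linear in length with a per-species Gaussian spread
that grows with molecular size.  Ground-truth species labels ride along in
a sidecar column so every downstream stage can be scored; the detection
path never reads them.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .models import (
    AcquisitionWindow,
    ContrastModel,
    KineticsModel,
    MovieStack,
    SpeciesDef,
    validate_mixture,
)

EVENT_COLUMNS = ["time_s", "contrast", "x_px", "y_px", "species_label"]

_LOW_MASS_LADDER_BP = (100, 200, 400, 800, 1200, 2000)
_100BP_LADDER_BP = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1200, 1500, 2000)
_SSDNA_NT = (4536, 6048, 7249, 8064)

PRESET_NAMES = ("low_mass_ladder", "100bp_ladder", "ssdna_set")


def ladder_preset(name: str, n_molecules: int = 5000) -> list[SpeciesDef]:
    """Return an equimolar species list for a named commercial sample.

    ``low_mass_ladder`` is the 6-fragment dsDNA ladder (100-2000 bp),
    ``100bp_ladder`` the 13-fragment dsDNA ladder (100-2000 bp), and
    ``ssdna_set`` the four circular ssDNA species (4536-8064 nt) that were
    measured in separate runs.
    """
    if name == "low_mass_ladder":
        lengths, strand, unit = _LOW_MASS_LADDER_BP, "double", "bp"
    elif name == "100bp_ladder":
        lengths, strand, unit = _100BP_LADDER_BP, "double", "bp"
    elif name == "ssdna_set":
        lengths, strand, unit = _SSDNA_NT, "single", "nt"
    else:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    frac = 1.0 / len(lengths)
    return [
        SpeciesDef(
            label=f"{length}{unit}",
            length=length,
            strandedness=strand,
            mole_fraction=frac,
            n_molecules=n_molecules,
        )
        for length in lengths
    ]


def _check_seed(seed: int) -> int:
    if seed is None or int(seed) < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    return int(seed)


def simulate_event_stream(
    mixture: Sequence[SpeciesDef],
    contrast_model: ContrastModel,
    kinetics: KineticsModel,
    window: AcquisitionWindow,
    seed: int,
    fov_shape: tuple[int, int] = (128, 128),
    border_px: float = 8.0,
) -> pd.DataFrame:
    """Simulate one acquisition and return the in-window event table.

    Each molecule binds irreversibly exactly once; its binding time is
    exponential with the species rate ``k_i`` measured from sample addition,
    and only events with ``t0 <= t <= t_final`` are emitted.  Contrast is
    ``intercept + kappa*L*(1 + eps)`` with ``eps ~ N(0, cv(L))``, stored as a
    positive magnitude.  Positions are uniform over the field of view at
    least ``border_px`` from the edge.  The table is sorted by time;
    identical seeds give identical tables.
    """
    seed = _check_seed(seed)
    validate_mixture(mixture)
    rng = np.random.default_rng(seed)

    if len(mixture) == 0:
        warnings.warn("empty mixture: returning an empty event table", stacklevel=2)
        return pd.DataFrame(columns=EVENT_COLUMNS)

    ny, nx = fov_shape
    parts = []
    for sp in mixture:
        if sp.n_molecules == 0:
            continue
        k_i = kinetics.rate(sp.length)
        times = rng.exponential(scale=1.0 / k_i, size=sp.n_molecules)
        times = times[(times >= window.t0) & (times <= window.t_final)]
        n = times.size
        if n == 0:
            continue
        eps = rng.normal(0.0, contrast_model.cv(sp.length), size=n)
        contrast = contrast_model.intercept + contrast_model.kappa * sp.length * (1.0 + eps)
        contrast = np.abs(contrast)
        x = rng.uniform(border_px, nx - 1 - border_px, size=n)
        y = rng.uniform(border_px, ny - 1 - border_px, size=n)
        parts.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "contrast": contrast,
                    "x_px": x,
                    "y_px": y,
                    "species_label": sp.label,
                }
            )
        )

    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    table = pd.concat(parts, ignore_index=True)
    table = table.sort_values("time_s", kind="mergesort", ignore_index=True)
    return table


def _psf_patch(shape, x0, y0, amplitude, sigma):
    """Gaussian PSF rendered on a local window; returns (ys, xs, patch)."""
    ny, nx = shape
    half = max(3, int(math.ceil(4 * sigma)))
    xi0, xi1 = int(math.floor(x0)) - half, int(math.floor(x0)) + half + 1
    yi0, yi1 = int(math.floor(y0)) - half, int(math.floor(y0)) + half + 1
    xi0, yi0 = max(xi0, 0), max(yi0, 0)
    xi1, yi1 = min(xi1, nx), min(yi1, ny)
    ys = np.arange(yi0, yi1)
    xs = np.arange(xi0, xi1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    patch = amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
    return slice(yi0, yi1), slice(xi0, xi1), patch


def simulate_movie(
    events: pd.DataFrame,
    psf_sigma_px: float = 1.4,
    background_rms: float = 0.01,
    photon_budget: Optional[float] = 1e6,
    frame_period: float = 0.05,
    frame_count: int = 400,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    t_start: float = 15.0,
    background_corr_px: float = 2.0,
) -> MovieStack:
    """Render an event table into a synthetic reflectivity movie.

    Frames contain a static random background (mean reflectivity 1, smooth
    roughness of RMS ``background_rms``) plus, for each event, an
    irreversible step: a 2-D Gaussian PSF of peak amplitude
    ``contrast x reference level`` appearing at the event time and
    persisting to the last frame.  Per-pixel shot noise is Gaussian with
    variance ``intensity / photon_budget`` (``photon_budget=None`` disables
    noise).  The injected event table is stored as ground truth.
    """
    seed = _check_seed(seed)
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    t_end = t_start + frame_count * frame_period
    times = np.asarray(events["time_s"], dtype=float)
    bad = np.flatnonzero((times < t_start) | (times >= t_end))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"event {i} at t={times[i]:.3f}s lies outside the movie span "
            f"[{t_start:.3f}, {t_end:.3f}) s"
        )

    rng = np.random.default_rng(seed)
    ny, nx = shape
    rough = rng.normal(0.0, 1.0, size=shape)
    rough = gaussian_filter(rough, background_corr_px, mode="reflect")
    rms = float(np.sqrt(np.mean(rough**2)))
    if rms > 0 and background_rms > 0:
        rough *= background_rms / rms
    else:
        rough[:] = 0.0
    background = 1.0 + rough

    # frame f covers [t_start + f*T, t_start + (f+1)*T); an event is visible
    # from the first frame whose start time is >= the event time (sub-frame
    # partial exposure is not modelled)
    first_frame = np.ceil((times - t_start) / frame_period).astype(int)
    order = np.argsort(first_frame, kind="mergesort")

    frames = np.empty((frame_count, ny, nx), dtype=np.float32)
    signal = np.zeros(shape, dtype=np.float64)
    ptr = 0
    ev_x = np.asarray(events["x_px"], dtype=float)
    ev_y = np.asarray(events["y_px"], dtype=float)
    ev_c = np.asarray(events["contrast"], dtype=float)
    for f in range(frame_count):
        while ptr < order.size and first_frame[order[ptr]] <= f:
            i = order[ptr]
            sy, sx, patch = _psf_patch(shape, ev_x[i], ev_y[i], ev_c[i], psf_sigma_px)
            signal[sy, sx] += patch
            ptr += 1
        clean = background + signal
        if photon_budget is not None and photon_budget > 0:
            noise_sd = np.sqrt(np.clip(clean, 0.0, None) / photon_budget)
            frames[f] = clean + rng.normal(0.0, 1.0, size=shape) * noise_sd
        else:
            frames[f] = clean

    return MovieStack(
        frames=frames,
        frame_period=frame_period,
        t_start=t_start,
        ground_truth=events.reset_index(drop=True).copy(),
    )
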