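"""Contrast-distribution analysis: KDE, peak finding, sum-of-Gaussians fit.

The contrast histogram of a ladder measurement shows one peak per species.
Peaks are located on a Gaussian kernel density estimate (absolute-bandwidth
convention, as contrast units) and then refined by a least-squares fit of a
sum of Gaussians to the binned event histogram; the fitted mean of each
component is the contrast of one DNA species and the closed-form area
a = A*sigma*sqrt(2*pi) counts the events it contains (in units of
events x bin width).  Fitting the sum of Gaussians to the KDE curve instead
of the histogram is available as an alternative target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as scipy_signal
from scipy import stats
from scipy.optimize import least_squares

from .models import DensityEstimate, GaussianPeak, SQRT_2PI

#: default KDE bandwidth, absolute contrast units
DEFAULT_BANDWIDTH = 2.1e-4
#: default histogram bin width for the mixture fit, contrast units
DEFAULT_BIN_WIDTH = 1e-4

MIN_EVENTS_FOR_FIT = 50


def kde(
    contrasts: Sequence[float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_grid: int = 512,
) -> DensityEstimate:
    """Gaussian-kernel density of event contrasts on a uniform grid.

    ``bandwidth`` is the kernel standard deviation in absolute contrast
    units.  The grid spans [min - 4*bw, max + 4*bw] with at least 512
    points and the returned density integrates to 1.
    """
    x = np.asarray(contrasts, dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 events for a density estimate, got {x.size}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    n_grid = max(int(n_grid), 512)
    grid = np.linspace(x.min() - 4 * bandwidth, x.max() + 4 * bandwidth, n_grid)

    sd = float(np.std(x, ddof=1))
    if sd > 0:
        estimator = stats.gaussian_kde(x, bw_method=bandwidth / sd)
        density = estimator(grid)
    else:
        # degenerate sample: all events identical; a single kernel
        density = stats.norm.pdf(grid, loc=x[0], scale=bandwidth)
    area = np.trapezoid(density, grid)
    density = density / area
    return DensityEstimate(grid=grid, density=density, bandwidth=bandwidth)


def find_peaks(
    density: DensityEstimate, min_prominence: float = 0.05
) -> list[tuple[float, float]]:
    """Local maxima of a density as (mu, height) pairs sorted by mu.

    Only maxima with topographic prominence of at least
    ``min_prominence x max(density)`` are returned; these seed the
    sum-of-Gaussians fit.
    """
    d = density.density
    idx, _ = scipy_signal.find_peaks(d, prominence=min_prominence * float(d.max()))
    order = np.argsort(density.grid[idx])
    return [(float(density.grid[i]), float(d[i])) for i in idx[order]]


def initial_guesses(
    density: DensityEstimate,
    n_components: Optional[int] = None,
    min_prominence: float = 0.05,
) -> list[tuple[float, float]]:
    """Peak guesses, optionally forced to a known component count.

    When ``n_components`` is given (e.g. the nominal species count of a
    ladder), the prominence threshold is relaxed progressively until at
    least that many maxima are found and the ``n_components`` most
    prominent are kept.
    """
    if n_components is None:
        return find_peaks(density, min_prominence)
    prom = min_prominence
    while True:
        d = density.density
        idx, props = scipy_signal.find_peaks(d, prominence=prom * float(d.max()))
        if idx.size >= n_components or prom < 1e-6:
            break
        prom /= 5.0
    if idx.size < n_components:
        raise ValueError(
            f"found only {idx.size} density maxima but {n_components} components "
            "were requested"
        )
    keep = idx[np.argsort(props["prominences"])[::-1][:n_components]]
    keep = np.sort(keep)
    return [(float(density.grid[i]), float(d[i])) for i in keep]


@dataclass(frozen=True)
class MixtureFit:
    """Result of the sum-of-Gaussians fit.

    ``peaks`` are sorted by centroid; ``residual_rms`` is the root mean
    square misfit in count-per-bin units; ``converged`` is False when the
    optimizer stopped at its evaluation limit (the last iterate is still
    returned, flagged, never hidden).
    """

    peaks: tuple
    residual_rms: float
    converged: bool
    n_events: int
    bin_width: float

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.peaks)


def _sum_of_gaussians(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for A, mu, sig in params.reshape(-1, 3):
        out += A * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_gaussian_mixture(
    contrasts: Sequence[float],
    init: Sequence[tuple[float, float]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    target: str = "histogram",
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> MixtureFit:
    """Least-squares fit of a sum of Gaussians to the contrast distribution.

    ``init`` holds (mu, height) guesses, one per component; the component
    count is exactly the guess count (no model selection).  With the
    default ``target="histogram"`` the model is fitted to the event
    histogram with the given ``bin_width``; with ``target="kde"`` it is
    fitted to the KDE curve rescaled to count-per-bin units, so amplitudes
    and areas follow the same convention either way (sum of areas ~=
    n_events * bin_width).
    """
    x = np.asarray(contrasts, dtype=float)
    if x.size < MIN_EVENTS_FOR_FIT:
        raise ValueError(f"need >= {MIN_EVENTS_FOR_FIT} events, got {x.size}")
    if len(init) < 1:
        raise ValueError("need >= 1 initial peak guess")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")

    mus = np.array([m for m, _ in init], dtype=float)

    if target == "histogram":
        lo = x.min() - bin_width
        n_bins = max(int(math.ceil((x.max() - lo + bin_width) / bin_width)), 4)
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        y = counts.astype(float)
    elif target == "kde":
        dens = kde(x, bandwidth=bandwidth)
        centers = dens.grid
        y = dens.density * x.size * bin_width
    else:
        raise ValueError(f"unknown target {target!r}; use 'histogram' or 'kde'")

    # per-component seeds from the events nearest each guess: sigma from
    # their spread, amplitude from their count (robust against the Poisson
    # noise of individual histogram bins); centroids are confined to their
    # own neighbourhood so components cannot swap peaks
    span = centers[-1] - centers[0]
    p0, lower, upper = [], [], []
    for mu in mus:
        gaps = np.abs(mus - mu)
        gaps = gaps[gaps > 0]
        half_gap = float(gaps.min()) / 2.0 if gaps.size else span
        sel = x[np.abs(x - mu) < min(half_gap, 4 * np.std(x) + bin_width)]
        sig0 = float(np.std(sel)) if sel.size > 5 else bin_width
        sig0 = max(sig0, bin_width / 4.0)
        A0 = max(sel.size * bin_width / (sig0 * SQRT_2PI), 1e-12)
        p0 += [A0, mu, sig0]
        lower += [0.0, mu - half_gap, bin_width / 20.0]
        upper += [np.inf, mu + half_gap, span]
    p0 = np.array(p0)
    lower, upper = np.array(lower), np.array(upper)

    # amplitudes, centroids and widths live on very different scales;
    # without per-parameter scaling the trust-region steps are ill-conditioned
    x_scale = np.maximum(np.abs(p0), np.tile([1.0, bin_width, bin_width], len(init)))
    res = least_squares(
        lambda p: _sum_of_gaussians(centers, p) - y,
        p0,
        bounds=(lower, upper),
        x_scale=x_scale,
        max_nfev=2000 * len(init),
    )
    params = res.x.reshape(-1, 3)
    order = np.argsort(params[:, 1])
    peaks = tuple(
        GaussianPeak(A=float(A), mu=float(mu), sigma=float(sig))
        for A, mu, sig in params[order]
    )
    residual_rms = float(np.sqrt(np.mean(res.fun**2)))
    return MixtureFit(
        peaks=peaks,
        residual_rms=residual_rms,
        converged=bool(res.status > 0),
        n_events=int(x.size),
        bin_width=float(bin_width),
    )


def peak_area(peak: GaussianPeak) -> float:
    """Closed-form Gaussian area a = A*sigma*sqrt(2*pi)."""
    if peak.sigma <= 0:
        raise ValueError("sigma must be > 0")
    return peak.A * peak.sigma * SQRT_2PI


def suggested_bin_width(min_sigma: float) -> float:
    """Bin width resolving the narrowest expected peak (~4 bins per sigma)."""
    if min_sigma <= 0:
        raise ValueError("min_sigma must be > 0")
    return min_sigma / 4.0
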