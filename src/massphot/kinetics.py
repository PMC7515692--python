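"""Binding-rate estimation and the finite-window diffusion correction.

Molecules reach the coverslip by diffusion, so small species bind faster
than large ones (``k_i = alpha * L_i**beta`` with beta = -0.72 for DNA) and
are preferentially depleted from solution before and during the finite
acquisition window [t0, t_final].  The correction rescales each species'
observed event count a_i to the count an infinite observation starting at
sample addition would have seen,

    a'_i = a_i * exp(k_i * t0) / (1 - exp(-k_i * (t_final - t0))),

after which the corrected counts are renormalized into mole fractions.
The average rate k is fitted on the pooled arrival times of all species by
maximum likelihood under a window-truncated exponential; alpha follows as
k / <L>**beta with <L> the abundance-weighted mean length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import AbundanceEstimate, AcquisitionWindow, KineticsModel, DEFAULT_BETA

MIN_EVENTS_FOR_RATE_FIT = 50


@dataclass(frozen=True)
class RateFit:
    """Fitted average binding rate with its asymptotic standard error.

    ``nondepleting`` flags the flat-likelihood limit (arrival times uniform
    over the window, k -> 0) in which no depletion is detectable.
    """

    k: float
    stderr: float
    n_events: int
    nondepleting: bool = False


def fit_binding_rate(
    event_times: Sequence[float],
    window: AcquisitionWindow,
    k_max: float = 10.0,
) -> RateFit:
    """Maximum-likelihood exponential rate from window-truncated arrivals.

    Times are seconds from sample addition and must all lie in the window.
    The truncated-exponential score equation ``1/k - mean(u) = L/(e^{kL}-1)``
    (u = t - t0, L = window length) is solved by bracketing; the standard
    error comes from the observed Fisher information.
    """
    t = np.asarray(event_times, dtype=float)
    if t.size < MIN_EVENTS_FOR_RATE_FIT:
        raise ValueError(
            f"need >= {MIN_EVENTS_FOR_RATE_FIT} events for a stable rate fit, got {t.size}"
        )
    if np.any((t < window.t0 - 1e-9) | (t > window.t_final + 1e-9)):
        raise ValueError("all event times must lie inside the acquisition window")
    if np.ptp(t) == 0:
        raise ValueError("all event times are equal; rate is unidentifiable")

    L = window.duration
    u_bar = float(np.mean(t)) - window.t0

    def score(k: float) -> float:
        # d(loglik)/dk per event; positive at k->0 iff u_bar < L/2
        kL = k * L
        tail = 0.0 if kL > 700 else L / math.expm1(kL)
        return 1.0 / k - u_bar - tail

    if u_bar >= L / 2.0:
        # sample mean at/after the window midpoint: MLE is at the k->0 boundary
        return RateFit(k=0.0, stderr=float("nan"), n_events=t.size, nondepleting=True)

    k_lo = 1e-9
    while score(k_max) > 0 and k_max < 1e6:
        k_max *= 10.0
    k_hat = brentq(score, k_lo, k_max, xtol=1e-12, rtol=1e-12)

    # per-event Fisher information of the truncated exponential
    ekl = math.expm1(k_hat * L)
    info = 1.0 / k_hat**2 - L**2 * (ekl + 1.0) / ekl**2
    stderr = 1.0 / math.sqrt(t.size * info) if info > 0 else float("nan")
    return RateFit(k=k_hat, stderr=stderr, n_events=t.size)


def mean_length(
    lengths: Sequence[float],
    abundances: Sequence[float],
    mode: str = "weighted",
    beta: float = DEFAULT_BETA,
) -> float:
    """Average length <L> of the species in solution.

    ``mode="weighted"`` computes the arithmetic abundance-weighted mean
    sum(L_i*a_i)/sum(a_i).  ``mode="effective"`` computes the power mean of
    order ``beta``, (sum(a_i*L_i**beta)/sum(a_i))**(1/beta); pairing the
    pooled average binding rate with this mean makes the derived scaling
    factor alpha exactly consistent with the count-weighted average of the
    per-species rates, so it is the mean the diffusion correction uses by
    default.  The ``"literal"`` mode divides by the number of species N
    instead of sum(a_i); it equals the weighted mean only when the a_i are
    already fractions, and is kept for strict fidelity to that convention.
    """
    L = np.asarray(lengths, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if L.shape != a.shape:
        raise ValueError("lengths and abundances must have equal length")
    if np.any(a < 0):
        raise ValueError("abundances must be >= 0")
    if not np.any(a > 0):
        raise ValueError("at least one abundance must be > 0")
    if mode == "weighted":
        return float(np.sum(L * a) / np.sum(a))
    if mode == "effective":
        return float((np.sum(a * L**beta) / np.sum(a)) ** (1.0 / beta))
    if mode == "literal":
        return float(np.sum(L * a) / L.size)
    raise ValueError(f"unknown mode {mode!r}; use 'weighted', 'effective' or 'literal'")


def scaling_alpha(k: float, mean_len: float, beta: float = DEFAULT_BETA) -> float:
    """Scaling factor alpha = k / <L>**beta shared by all species."""
    if k <= 0 or mean_len <= 0:
        raise ValueError("k and mean length must be > 0")
    return k / mean_len**beta


def species_rate(alpha: float, length: float, beta: float = DEFAULT_BETA) -> float:
    """Per-species binding rate constant k_i = alpha * length**beta."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return alpha * float(length) ** beta


def diffusion_correction(
    raw_area: float, k_i: float, window: AcquisitionWindow
) -> float:
    """Rescale an observed count to the full-depletion count.

    Returns ``raw_area * exp(k_i*t0) / (1 - exp(-k_i*(t_final - t0)))``.
    The factor is the reciprocal of the fraction of an exponential-k_i
    population that lands inside the window, so it is always >= 1.
    """
    if k_i <= 0:
        raise ValueError("k_i must be > 0")
    factor = math.exp(k_i * window.t0) / -math.expm1(-k_i * window.duration)
    return raw_area * factor


def mole_fractions(corrected: Sequence[AbundanceEstimate]) -> list[AbundanceEstimate]:
    """Renormalize corrected areas into mole fractions (in place and returned)."""
    if len(corrected) == 0:
        raise ValueError("need at least one species")
    total = sum(est.corrected_area for est in corrected)
    if total <= 0:
        raise ValueError("total corrected area must be > 0")
    for est in corrected:
        est.mole_fraction = est.corrected_area / total
    return list(corrected)


def correct_abundances(
    labels: Sequence[str],
    lengths: Sequence[int],
    raw_areas: Sequence[float],
    event_times: Sequence[float],
    window: AcquisitionWindow,
    beta: float = DEFAULT_BETA,
    mean_mode: str = "effective",
    iterate: bool = False,
    max_iter: int = 50,
    rate_fit: Optional[RateFit] = None,
    peak_means: Optional[Sequence[float]] = None,
    peak_sigmas: Optional[Sequence[float]] = None,
    contrast_floor: Optional[float] = None,
) -> tuple[list[AbundanceEstimate], KineticsModel]:
    """Full diffusion-correction pass from peak areas and arrival times.

    Fits the pooled average rate k, computes <L> from the raw areas,
    derives alpha and the per-species k_i, corrects each area and
    renormalizes.  With ``iterate=True`` the <L> / corrected-area pair is
    re-evaluated to a fixed point instead of the default single pass.

    No correction is applied for sub-unity detection efficiency; when the
    contrast detection floor is known, a species whose peak mean lies
    within 3 sigma of it is flagged ``near_detection_floor`` (its count,
    and hence its fraction, is likely an underestimate).
    """
    if not (len(labels) == len(lengths) == len(raw_areas)):
        raise ValueError("labels, lengths and raw_areas must be parallel lists")
    fit = rate_fit if rate_fit is not None else fit_binding_rate(event_times, window)
    if fit.nondepleting or fit.k <= 0:
        raise ValueError(
            "no depletion detectable in the arrival times (k -> 0); "
            "the diffusion correction is undefined"
        )

    areas_for_mean = np.asarray(raw_areas, dtype=float)
    for _ in range(max_iter if iterate else 1):
        mean_len = mean_length(lengths, areas_for_mean, mode=mean_mode, beta=beta)
        alpha = scaling_alpha(fit.k, mean_len, beta)
        rates = [species_rate(alpha, L, beta) for L in lengths]
        corrected = np.array(
            [
                diffusion_correction(a, k_i, window)
                for a, k_i in zip(raw_areas, rates)
            ]
        )
        if not iterate or np.allclose(corrected, areas_for_mean, rtol=1e-12, atol=0):
            break
        areas_for_mean = corrected

    flags = [False] * len(labels)
    if contrast_floor is not None and peak_means is not None:
        sigmas = peak_sigmas if peak_sigmas is not None else [0.0] * len(labels)
        flags = [
            mu - 3.0 * sig < contrast_floor
            for mu, sig in zip(peak_means, sigmas)
        ]
    estimates = [
        AbundanceEstimate(
            label=lab, length=int(L), raw_area=float(a), k_i=float(k_i),
            corrected_area=float(c), near_detection_floor=bool(flag),
        )
        for lab, L, a, k_i, c, flag in zip(
            labels, lengths, raw_areas, rates, corrected, flags
        )
    ]
    mole_fractions(estimates)
    model = KineticsModel.from_average_rate(fit.k, mean_len, beta)
    return estimates, model
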