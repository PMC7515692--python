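"""Replication studies: seeded multi-replicate simulation + analysis runs.

These are the package's canonical end-to-end experiments on synthetic
data, mirroring the protocols of the original ladder measurements: a
multi-replicate dsDNA ladder calibration, a per-species ssDNA sizing set,
an equimolar round trip through the diffusion correction, and an injected
PSF recovery study for the detection stage.  They are used both by the
test suite and by the reproduction script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import fit_contrast_vs_length, length_from_contrast
from .detect import detect_movie
from .distribution import fit_gaussian_mixture, initial_guesses, kde, suggested_bin_width
from .kinetics import correct_abundances
from .models import (
    AcquisitionWindow,
    CalibrationFit,
    ContrastModel,
    DetectionParams,
    KineticsModel,
    SpeciesDef,
    DEFAULT_KAPPA_SS,
)
from .simulate import simulate_event_stream, simulate_movie


def _replicate_seeds(seed: int, n: int) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _sized_mixture(
    lengths, kinetics: KineticsModel, window: AcquisitionWindow,
    events_per_species: int, strandedness: str = "double",
) -> list[SpeciesDef]:
    unit = "bp" if strandedness == "double" else "nt"
    frac = 1.0 / len(lengths)
    return [
        SpeciesDef(
            label=f"{L}{unit}",
            length=L,
            strandedness=strandedness,
            mole_fraction=frac,
            n_molecules=int(np.ceil(1.05 * events_per_species
                                    / window.observed_fraction(kinetics.rate(L)))),
        )
        for L in lengths
    ]


def _peak_means(contrasts: np.ndarray, n_components: int, bin_width: float,
                bandwidth: float) -> list[float]:
    dens = kde(contrasts, bandwidth=bandwidth)
    guesses = initial_guesses(dens, n_components=n_components)
    fit = fit_gaussian_mixture(contrasts, guesses, bin_width=bin_width)
    return [p.mu for p in fit.peaks]


@dataclass(frozen=True)
class CalibrationStudy:
    """Multi-replicate ladder calibration outcome."""

    lengths: tuple
    peak_means: tuple  # one tuple of peak means per replicate
    fits: tuple  # one CalibrationFit per replicate
    mean_slope: float
    mean_intercept: float
    deviations: tuple  # pooled (estimated - nominal), replicate-major
    n_events: int

    @property
    def r_squared(self) -> tuple:
        return tuple(f.r_squared for f in self.fits)

    @property
    def mean_deviation(self) -> float:
        return float(np.mean(self.deviations))


def dsdna_ladder_calibration(
    seed: int,
    lengths=(100, 200, 400, 800, 1200),
    n_replicates: int = 5,
    events_per_species: int = 2000,
    contrast_model: ContrastModel | None = None,
    kinetics: KineticsModel | None = None,
    window: AcquisitionWindow | None = None,
    bandwidth: float = 2.1e-4,
) -> CalibrationStudy:
    """Replicated dsDNA ladder measurement and contrast-to-bp calibration.

    Each replicate simulates an equimolar ladder with at least
    ``events_per_species`` in-window events per species, decomposes the
    contrast histogram into one Gaussian per species, and regresses peak
    means on nominal base pairs.  Length estimates use the
    replicate-averaged conversion (mean slope and intercept across
    replicates), matching the protocol of averaging the contrast-to-bp
    factor over repeats.
    """
    cm = contrast_model or ContrastModel(cv_small=0.02, cv_large=0.05)
    kin = kinetics or KineticsModel(alpha=0.5)
    win = window or AcquisitionWindow()
    mixture = _sized_mixture(lengths, kin, win, events_per_species)
    bin_width = suggested_bin_width(min(cm.contrast_sd(L) for L in lengths))

    peak_means, fits, n_events = [], [], 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        events = simulate_event_stream(mixture, cm, kin, win, seed=rep_seed)
        n_events += len(events)
        mus = _peak_means(events["contrast"].to_numpy(), len(lengths), bin_width, bandwidth)
        peak_means.append(tuple(mus))
        fits.append(fit_contrast_vs_length(mus, lengths))

    mean_slope = float(np.mean([f.slope for f in fits]))
    mean_intercept = float(np.mean([f.intercept for f in fits]))
    mean_fit = dataclasses.replace(fits[0], slope=mean_slope, intercept=mean_intercept)
    deviations = [
        float(length_from_contrast(mean_fit, mu)) - L
        for mus in peak_means
        for mu, L in zip(mus, lengths)
    ]
    return CalibrationStudy(
        lengths=tuple(lengths),
        peak_means=tuple(peak_means),
        fits=tuple(fits),
        mean_slope=mean_slope,
        mean_intercept=mean_intercept,
        deviations=tuple(deviations),
        n_events=n_events,
    )


def ssdna_sizing(
    seed: int,
    lengths=(4536, 6048, 7249, 8064),
    n_replicates: int = 3,
    events_per_species: int = 2000,
    contrast_model: ContrastModel | None = None,
    kinetics: KineticsModel | None = None,
    window: AcquisitionWindow | None = None,
) -> CalibrationStudy:
    """Separate single-species ssDNA runs with a shared per-nt calibration.

    Each species is simulated and analyzed as its own run (single-component
    Gaussian fit), as required by the limited purity of long ssDNA samples;
    one contrast-to-nt line is then fitted across all runs and every peak
    mean converted back to nucleotides with it.
    """
    cm = contrast_model or ContrastModel(
        kappa=DEFAULT_KAPPA_SS, cv_small=0.02, cv_large=0.05
    )
    kin = kinetics or KineticsModel(alpha=0.5)
    win = window or AcquisitionWindow()
    bandwidth = 2.1e-4

    rows = []  # (length, peak mean)
    n_events = 0
    seeds = iter(_replicate_seeds(seed, n_replicates * len(lengths)))
    for L in lengths:
        unit_mix = _sized_mixture([L], kin, win, events_per_species, strandedness="single")
        bin_width = suggested_bin_width(cm.contrast_sd(L))
        for _ in range(n_replicates):
            events = simulate_event_stream(unit_mix, cm, kin, win, seed=next(seeds))
            n_events += len(events)
            (mu,) = _peak_means(events["contrast"].to_numpy(), 1, bin_width, bandwidth)
            rows.append((L, mu))

    fit = fit_contrast_vs_length([mu for _, mu in rows], [L for L, _ in rows])
    deviations = [float(length_from_contrast(fit, mu)) - L for L, mu in rows]
    by_rep: dict[int, list] = {}
    for i, (_, mu) in enumerate(rows):
        by_rep.setdefault(i % n_replicates, []).append(mu)
    return CalibrationStudy(
        lengths=tuple(lengths),
        peak_means=tuple(tuple(v) for v in by_rep.values()),
        fits=(fit,),
        mean_slope=fit.slope,
        mean_intercept=fit.intercept,
        deviations=tuple(deviations),
        n_events=n_events,
    )


@dataclass(frozen=True)
class CorrectionStudy:
    """Equimolar round trip through the diffusion correction."""

    lengths: tuple
    raw_fractions: tuple
    corrected_fractions: tuple
    sampling_sd: tuple  # per-species SD of a corrected fraction
    k: float
    alpha: float
    n_events: int

    @property
    def raw_strictly_decreasing(self) -> bool:
        return bool(np.all(np.diff(self.raw_fractions) < 0))


def equimolar_correction_roundtrip(
    seed: int,
    lengths=(200, 400, 800, 1200),
    events_per_species: int = 2000,
    contrast_model: ContrastModel | None = None,
    kinetics: KineticsModel | None = None,
    window: AcquisitionWindow | None = None,
) -> CorrectionStudy:
    """Simulate an equimolar ladder and undo its depletion bias.

    All species start with the same number of molecules (sized so the
    rarest still yields ``events_per_species`` in-window events); raw
    in-window counts are biased toward short, fast-diffusing species, and
    the diffusion correction should return the mixture to equimolarity.
    The per-species sampling SD of a corrected fraction follows from the
    binomial variance of the in-window count: SD ~= f * sqrt((1-g)/N_obs)
    with g the in-window fraction of that species' population.
    """
    cm = contrast_model or ContrastModel()
    kin = kinetics or KineticsModel(alpha=0.5)
    win = window or AcquisitionWindow()
    g = [win.observed_fraction(kin.rate(L)) for L in lengths]
    n_mol = int(np.ceil(1.05 * events_per_species / min(g)))
    mixture = [
        SpeciesDef(f"{L}bp", L, "double", 1.0 / len(lengths), n_mol) for L in lengths
    ]
    events = simulate_event_stream(mixture, cm, kin, win, seed=seed)
    counts = events.groupby("species_label", sort=False)["time_s"].count()
    raw = np.array([counts.get(s.label, 0) for s in mixture], dtype=float)
    estimates, model = correct_abundances(
        [s.label for s in mixture], list(lengths), raw,
        events["time_s"].to_numpy(), win,
    )
    fractions = np.array([e.mole_fraction for e in estimates])
    g_hat = np.array([e.raw_area / e.corrected_area for e in estimates])
    sampling_sd = fractions * np.sqrt((1.0 - g_hat) / raw)
    return CorrectionStudy(
        lengths=tuple(lengths),
        raw_fractions=tuple(raw / raw.sum()),
        corrected_fractions=tuple(fractions),
        sampling_sd=tuple(sampling_sd),
        k=model.k,
        alpha=model.alpha,
        n_events=int(len(events)),
    )


@dataclass(frozen=True)
class RecoveryStudy:
    """Injected-PSF detection recovery outcome."""

    n_injected: int
    n_detected: int
    n_matched: int
    recall: float
    spurious_fraction: float
    contrast_rel_errors: tuple


def detection_recovery(
    seed: int,
    n_events: int = 120,
    frame_count: int = 2000,
    shape=(128, 128),
    frame_period: float = 0.05,
    n_binned: int = 8,
    photon_budget: float = 1e6,
    amplitude_over_noise: float = 8.0,
    threshold1: float = 5.0,
    threshold2: float = 0.2,
) -> RecoveryStudy:
    """Inject PSFs of known amplitude into a noisy movie and re-detect them.

    The injected contrast is ``amplitude_over_noise`` times the
    single-pixel noise RMS of a differential frame,
    sqrt(2 / (n_binned * photon_budget)).  A detection matches an injected
    event if it lies within 3 px and 3 batch periods; each injection is
    matched at most once.
    """
    rng = np.random.default_rng(seed)
    t_start = 15.0
    t_end = t_start + frame_count * frame_period
    batch_t = n_binned * frame_period
    noise_rms = float(np.sqrt(2.0 / (n_binned * photon_budget)))
    t = rng.uniform(t_start + 4 * batch_t, t_end - 4 * batch_t, n_events)
    ny, nx = shape
    x = rng.uniform(8, nx - 9, n_events)
    y = rng.uniform(8, ny - 9, n_events)
    events = pd.DataFrame(
        {
            "time_s": t,
            "contrast": amplitude_over_noise * noise_rms,
            "x_px": x,
            "y_px": y,
            "species_label": "injected",
        }
    )
    movie = simulate_movie(
        events,
        frame_period=frame_period,
        frame_count=frame_count,
        shape=shape,
        photon_budget=photon_budget,
        seed=seed + 1,
        t_start=t_start,
    )
    params = DetectionParams(
        n_binned=n_binned, threshold1=threshold1, threshold2=threshold2
    )
    detected = detect_movie(movie, params)

    used: set[int] = set()
    matched = 0
    rel_errors = []
    for _, row in detected.iterrows():
        dist = np.hypot(x - row.x_px, y - row.y_px)
        cand = [
            i
            for i in np.flatnonzero(dist < 3.0)
            if abs(t[i] - row.time_s) < 3 * batch_t and i not in used
        ]
        if cand:
            i = min(cand, key=lambda i: dist[i])
            used.add(i)
            matched += 1
            rel_errors.append(row.contrast / (amplitude_over_noise * noise_rms) - 1.0)
    return RecoveryStudy(
        n_injected=n_events,
        n_detected=int(len(detected)),
        n_matched=matched,
        recall=matched / n_events,
        spurious_fraction=(len(detected) - matched) / n_events,
        contrast_rel_errors=tuple(rel_errors),
    )
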