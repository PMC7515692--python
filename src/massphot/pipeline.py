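"""End-to-end orchestration: simulate -> (movie -> detect) -> peaks ->
calibrate -> abundance, as a pure function of configuration + seed.

Every stage persists its intermediate table under the output directory, so
any stage can be re-run from files, and an identical config + seed
reproduces every output byte for byte.  The run report (JSON) echoes the
full configuration, records per-stage event counts and points at every
artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import fit_contrast_vs_length, length_error_summary, length_from_contrast
from .detect import detect_movie
from .distribution import (
    DEFAULT_BANDWIDTH,
    fit_gaussian_mixture,
    initial_guesses,
    kde,
    suggested_bin_width,
)
from .io import write_events, write_peaks
from .kinetics import correct_abundances
from .models import (
    AcquisitionWindow,
    ContrastModel,
    DetectionParams,
    KineticsModel,
    SpeciesDef,
    DEFAULT_KAPPA_SS,
)
from .simulate import ladder_preset, simulate_event_stream, simulate_movie

log = logging.getLogger("massphot.pipeline")

#: named run presets; each is a complete RunConfig seed
RUN_PRESETS = {
    # the 6-species low-mass dsDNA ladder measurement
    "figure2_ladder": {
        "mode": "events_only",
        "mixture": "low_mass_ladder",
        "exclude": ["2000bp"],
    },
    # the 5-species calibration subset (largest species excluded at source)
    "calibration_ladder": {
        "mode": "events_only",
        "mixture": [
            {"label": f"{L}bp", "length": L, "strandedness": "double",
             "mole_fraction": 0.2, "n_molecules": 5000}
            for L in (100, 200, 400, 800, 1200)
        ],
        "exclude": [],
    },
    # four circular ssDNA species, measured separately in the original study
    "ssdna_set": {
        "mode": "events_only",
        "mixture": "ssdna_set",
        "contrast": {"kappa": DEFAULT_KAPPA_SS},
        "exclude": [],
    },
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see also YAML files via
    :func:`massphot.io.load_config`)."""

    mode: str = "events_only"  # or "full_movie"
    mixture: object = "low_mass_ladder"  # preset name or list of species dicts
    n_molecules: int = 5000
    target_events: Optional[int] = None  # in-window events/species; overrides n_molecules
    contrast: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=lambda: {"alpha": 0.5, "beta": -0.72})
    window: dict = field(default_factory=lambda: {"t0": 15.0, "t_final": 135.0})
    detection: dict = field(default_factory=dict)
    movie: dict = field(default_factory=dict)  # full_movie mode only
    bandwidth: float = DEFAULT_BANDWIDTH
    bin_width: Optional[float] = None  # None: derived from the contrast model
    exclude: list = field(default_factory=list)
    n_replicates: int = 1
    seed: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in RUN_PRESETS:
            raise ValueError(
                f"unknown run preset {name!r}; valid: {sorted(RUN_PRESETS)}"
            )
        raw = {**RUN_PRESETS[name], **overrides}
        return cls.from_dict(raw)

    # -- resolved domain objects ------------------------------------------
    def species(self) -> list[SpeciesDef]:
        if isinstance(self.mixture, str):
            mix = ladder_preset(self.mixture, n_molecules=self.n_molecules)
        else:
            mix = [SpeciesDef(**d) for d in self.mixture]
        if self.target_events is not None and mix:
            # scale every species by the same factor so the mixture
            # composition is preserved while the rarest species still
            # yields at least target_events in-window events on average
            kin = self.kinetics_model()
            win = self.acquisition_window()
            expected = [
                s.n_molecules * win.observed_fraction(kin.rate(s.length)) for s in mix
            ]
            worst = min(e for e in expected if e > 0)
            factor = self.target_events / worst
            mix = [
                dataclasses.replace(s, n_molecules=int(np.ceil(s.n_molecules * factor)))
                for s in mix
            ]
        return mix

    def contrast_model(self) -> ContrastModel:
        return ContrastModel(**self.contrast)

    def kinetics_model(self) -> KineticsModel:
        return KineticsModel(**self.kinetics)

    def acquisition_window(self) -> AcquisitionWindow:
        return AcquisitionWindow(**self.window)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def resolved_bin_width(self) -> float:
        if self.bin_width is not None:
            return float(self.bin_width)
        cm = self.contrast_model()
        species = self.species()
        if not species:
            return self.bandwidth / 4.0
        sd = cm.contrast_sd(min(s.length for s in species))
        return suggested_bin_width(sd) if sd > 0 else self.bandwidth / 4.0


def _replicate_seed(seed: int, replicate: int) -> int:
    """Stable per-replicate sub-seed derived from the run seed (< 2**31)."""
    return int(np.random.SeedSequence(seed).generate_state(replicate + 1)[-1] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages and return the run report (also written as JSON).

    Stage failures are recorded in the report (with prior outputs
    preserved) instead of aborting the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    mixture = config.species()
    labels = [s.label for s in mixture]
    lengths = [s.length for s in mixture]
    cm = config.contrast_model()
    win = config.acquisition_window()
    n_rep = int(config.n_replicates)

    # ---- stage 1: simulate (and optionally image + detect) ---------------
    event_tables: list[pd.DataFrame] = []
    try:
        kin = config.kinetics_model()
        for r in range(n_rep):
            rep_seed = _replicate_seed(config.seed, r)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                events = simulate_event_stream(mixture, cm, kin, win, seed=rep_seed)
            report["warnings"] += [str(w.message) for w in caught]
            path = out / f"events_sim_rep{r + 1}.csv"
            write_events(events, path)
            report["outputs"][f"events_sim_rep{r + 1}"] = str(path)
            if config.mode == "full_movie":
                movie_kw = dict(config.movie)
                frame_period = movie_kw.pop("frame_period", 0.05)
                frame_count = movie_kw.pop(
                    "frame_count", int(np.ceil(win.duration / frame_period)) + 16
                )
                movie = simulate_movie(
                    events,
                    frame_period=frame_period,
                    frame_count=frame_count,
                    seed=rep_seed + 1,
                    t_start=win.t0,
                    **movie_kw,
                )
                detected = detect_movie(movie, config.detection_params())
                path = out / f"events_detected_rep{r + 1}.csv"
                write_events(detected, path)
                report["outputs"][f"events_detected_rep{r + 1}"] = str(path)
                event_tables.append(detected)
            else:
                event_tables.append(events)
        report["stages"]["simulate"] = {
            "status": "ok",
            "n_replicates": n_rep,
            "events_per_replicate": [int(len(t)) for t in event_tables],
        }
    except Exception as exc:  # pragma: no cover - defensive
        report["stages"]["simulate"] = {"status": "failed", "error": str(exc)}
        _finalize(report, out)
        return report

    # ---- stage 2: contrast peaks -----------------------------------------
    peak_sets = []
    bin_width = config.resolved_bin_width()
    try:
        for r, events in enumerate(event_tables):
            if len(events) == 0:
                peak_sets.append(None)
                report["warnings"].append(f"replicate {r + 1}: no events, peaks skipped")
                continue
            dens = kde(events["contrast"].to_numpy(), bandwidth=config.bandwidth)
            guesses = initial_guesses(dens, n_components=len(mixture) or None)
            fit = fit_gaussian_mixture(
                events["contrast"].to_numpy(), guesses, bin_width=bin_width
            )
            if not fit.converged:
                report["warnings"].append(
                    f"replicate {r + 1}: mixture fit stopped at evaluation limit "
                    f"(residual rms {fit.residual_rms:.3g})"
                )
            peak_sets.append(fit)
            path = out / f"peaks_rep{r + 1}.csv"
            # ascending contrast is matched to ascending nominal length
            write_peaks(fit.peaks, path, labels=labels, nominal_lengths=lengths)
            report["outputs"][f"peaks_rep{r + 1}"] = str(path)
        report["stages"]["peaks"] = {
            "status": "ok",
            "bin_width": bin_width,
            "bandwidth": config.bandwidth,
            "n_peaks": [len(f.peaks) if f else 0 for f in peak_sets],
        }
    except Exception as exc:
        report["stages"]["peaks"] = {"status": "failed", "error": str(exc)}
        _finalize(report, out)
        return report

    fitted = [f for f in peak_sets if f is not None]
    if not fitted:
        report["stages"]["calibrate"] = {"status": "skipped", "reason": "no peaks"}
        report["stages"]["abundance"] = {"status": "skipped", "reason": "no peaks"}
        _finalize(report, out)
        return report

    # ---- stage 3: calibration --------------------------------------------
    try:
        rep_fits = []
        for f in fitted:
            mus = [p.mu for p in f.peaks]
            rep_fits.append(
                fit_contrast_vs_length(mus, lengths, labels=labels, exclude=config.exclude)
            )
        mean_slope = float(np.mean([cf.slope for cf in rep_fits]))
        mean_intercept = float(np.mean([cf.intercept for cf in rep_fits]))
        mean_fit = dataclasses.replace(
            rep_fits[0], slope=mean_slope, intercept=mean_intercept
        )
        est_rows = []
        for r, f in enumerate(fitted):
            for lab, L, p in zip(labels, lengths, f.peaks):
                if lab in set(config.exclude):
                    continue
                est_rows.append(
                    {
                        "replicate": r + 1,
                        "label": lab,
                        "nominal_length": L,
                        "estimated_length": float(length_from_contrast(mean_fit, p.mu)),
                    }
                )
        errors = pd.DataFrame(est_rows)
        errors["deviation"] = errors["estimated_length"] - errors["nominal_length"]
        summary = length_error_summary(
            errors["estimated_length"], errors["nominal_length"], errors["label"]
        )
        path = out / "length_errors.csv"
        errors.to_csv(path, index=False)
        report["outputs"]["length_errors"] = str(path)
        calib = {
            "replicate_fits": [dataclasses.asdict(cf) for cf in rep_fits],
            "mean_slope": mean_slope,
            "mean_intercept": mean_intercept,
            "excluded": list(config.exclude),
            "mean_length_error": summary.mean_error,
            "sd_length_error": summary.sd_error,
            "sd_convention": "sample (ddof=1)",
        }
        path = out / "calibration.json"
        path.write_text(json.dumps(calib, indent=1))
        report["outputs"]["calibration"] = str(path)
        report["stages"]["calibrate"] = {
            "status": "ok",
            "mean_slope": mean_slope,
            "r_squared": [cf.r_squared for cf in rep_fits],
        }
    except Exception as exc:
        report["stages"]["calibrate"] = {"status": "failed", "error": str(exc)}

    # ---- stage 4: diffusion-corrected abundances -------------------------
    try:
        frac_rows = []
        kin_summaries = []
        for r, (events, f) in enumerate(zip(event_tables, peak_sets)):
            if f is None:
                continue
            raw_areas = [p.area / f.bin_width for p in f.peaks]  # event counts
            estimates, model = correct_abundances(
                labels,
                lengths,
                raw_areas,
                events["time_s"].to_numpy(),
                win,
                beta=config.kinetics.get("beta", -0.72),
            )
            raw_total = sum(raw_areas)
            for est in estimates:
                frac_rows.append(
                    {
                        "replicate": r + 1,
                        "label": est.label,
                        "length": est.length,
                        "raw_area": est.raw_area,
                        "raw_fraction": est.raw_area / raw_total,
                        "k_i": est.k_i,
                        "corrected_area": est.corrected_area,
                        "mole_fraction": est.mole_fraction,
                    }
                )
            kin_summaries.append(
                {
                    "replicate": r + 1,
                    "k": model.k,
                    "alpha": model.alpha,
                    "beta": model.beta,
                    "mean_length": model.mean_length,
                }
            )
        abundance = pd.DataFrame(frac_rows)
        path = out / "abundance.csv"
        abundance.to_csv(path, index=False)
        report["outputs"]["abundance"] = str(path)
        path = out / "kinetics.json"
        path.write_text(json.dumps(kin_summaries, indent=1))
        report["outputs"]["kinetics"] = str(path)
        mean_fracs = (
            abundance.groupby("label", sort=False)["mole_fraction"].mean().to_dict()
        )
        report["stages"]["abundance"] = {"status": "ok", "mean_mole_fractions": mean_fracs}
    except Exception as exc:
        report["stages"]["abundance"] = {"status": "failed", "error": str(exc)}

    _finalize(report, out)
    return report


def _finalize(report: dict, out: Path) -> None:
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1, default=str))
    report["outputs"]["report"] = str(path)
    for name, stage in report["stages"].items():
        log.info("stage %s: %s", name, stage)
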