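"""Diagnostic figures for a completed pipeline run.

Produces the standard mass-photometry plots from the persisted run
artifacts: the contrast scatter/histogram of landing events, the KDE
replicate overlay, mole fractions before and after the diffusion
correction, and the contrast-versus-length calibration line with
residuals.  Figures are deterministic given the report; a missing stage
output skips the corresponding figure with a warning, and empty event
tables give annotated placeholder figures.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .distribution import kde


def _events_paths(report: dict) -> list[Path]:
    out = []
    for key, path in sorted(report.get("outputs", {}).items()):
        if key.startswith("events_detected_rep") or (
            key.startswith("events_sim_rep")
            and not any(k.startswith("events_detected_rep") for k in report["outputs"])
        ):
            out.append(Path(path))
    return out


def _placeholder(ax, message: str) -> None:
    ax.text(0.5, 0.5, message, ha="center", va="center", transform=ax.transAxes)
    ax.set_xticks([])
    ax.set_yticks([])


def make_figures(report: dict, out_dir) -> list[Path]:
    """Render all available figures; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made: list[Path] = []
    bandwidth = float(report.get("config", {}).get("bandwidth", 2.1e-4))

    event_paths = _events_paths(report)
    tables = [pd.read_csv(p) for p in event_paths if p.exists()]

    # 1. scatter + contrast histogram
    fig, (ax_sc, ax_h) = plt.subplots(
        1, 2, figsize=(9, 4), sharey=True, gridspec_kw={"width_ratios": [2, 1]}
    )
    if tables and len(tables[0]):
        ev = tables[0]
        ax_sc.plot(ev["time_s"], ev["contrast"], ".", ms=2, alpha=0.5)
        ax_h.hist(
            ev["contrast"],
            bins=100,
            orientation="horizontal",
            histtype="stepfilled",
            alpha=0.6,
        )
        if len(ev) >= 2:
            dens = kde(ev["contrast"].to_numpy(), bandwidth=bandwidth)
            scale = len(ev) * (ev["contrast"].max() - ev["contrast"].min()) / 100
            ax_h.plot(dens.density * scale, dens.grid, "r-", lw=1)
    else:
        _placeholder(ax_sc, "no data")
        _placeholder(ax_h, "no data")
    ax_sc.set_xlabel("time after sample addition (s)")
    ax_sc.set_ylabel("contrast")
    ax_h.set_xlabel("events")
    fig.tight_layout()
    path = out / "fig_scatter_histogram.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    # 2. KDE replicate overlay
    fig, ax = plt.subplots(figsize=(6, 4))
    any_curve = False
    for r, ev in enumerate(tables):
        if len(ev) < 2:
            continue
        dens = kde(ev["contrast"].to_numpy(), bandwidth=bandwidth)
        ax.plot(dens.grid, dens.density, lw=1, label=f"replicate {r + 1}")
        any_curve = True
    if not any_curve:
        _placeholder(ax, "no data")
    else:
        ax.legend(fontsize=8)
    ax.set_xlabel("contrast")
    ax.set_ylabel("kernel density")
    fig.tight_layout()
    path = out / "fig_kde_replicates.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    # 3. mole fractions before/after correction
    ab_path = report.get("outputs", {}).get("abundance")
    fig, ax = plt.subplots(figsize=(6, 4))
    if ab_path and Path(ab_path).exists() and len(pd.read_csv(ab_path)):
        ab = pd.read_csv(ab_path)
        grouped = ab.groupby("length", sort=True)[["raw_fraction", "mole_fraction"]].mean()
        ax.plot(grouped.index, grouped["raw_fraction"], "o-", label="uncorrected")
        ax.plot(grouped.index, grouped["mole_fraction"], "s-", label="diffusion corrected")
        ax.axhline(1.0 / len(grouped), color="0.6", ls="--", lw=1)
        ax.set_xlabel("length (bp or nt)")
        ax.set_ylabel("mole fraction")
        ax.legend()
    else:
        warnings.warn("abundance output missing: mole-fraction figure is a placeholder")
        _placeholder(ax, "no data")
    fig.tight_layout()
    path = out / "fig_mole_fractions.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    # 4. calibration line + residuals
    calib_path = report.get("outputs", {}).get("calibration")
    err_path = report.get("outputs", {}).get("length_errors")
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), height_ratios=[2, 1])
    if calib_path and Path(calib_path).exists():
        calib = json.loads(Path(calib_path).read_text())
        peaks_keys = sorted(
            k for k in report["outputs"] if k.startswith("peaks_rep")
        )
        for key in peaks_keys:
            pk = pd.read_csv(report["outputs"][key])
            if "nominal_length" in pk:
                ax1.plot(pk["nominal_length"], pk["mu"], "o", ms=4, alpha=0.7)
        L = np.linspace(0, 1.05 * max(
            (pd.read_csv(report["outputs"][k])["nominal_length"].max() for k in peaks_keys),
            default=1,
        ), 50)
        ax1.plot(L, calib["mean_slope"] * L + calib["mean_intercept"], "k-", lw=1)
        ax1.set_xlabel("nominal length (bp or nt)")
        ax1.set_ylabel("peak contrast")
        if err_path and Path(err_path).exists():
            err = pd.read_csv(err_path)
            ax2.axhline(0, color="0.6", lw=1)
            ax2.plot(err["nominal_length"], err["deviation"], "o", ms=4, alpha=0.7)
            ax2.set_xlabel("nominal length (bp or nt)")
            ax2.set_ylabel("length deviation")
    else:
        warnings.warn("calibration output missing: calibration figure is a placeholder")
        _placeholder(ax1, "no data")
        _placeholder(ax2, "no data")
    fig.tight_layout()
    path = out / "fig_calibration.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    made.append(path)

    return made
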