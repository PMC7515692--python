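"""Reading and writing of event tables, peak tables and movie stacks.

Event tables are plain CSV with columns ``time_s, contrast, x_px, y_px``
plus optional ``species_label`` / ``symmetry_score``; peak tables are CSV
with ``label, A, mu, sigma, area`` and optional ``nominal_length``.  Movie
stacks travel as multi-page 32-bit float TIFF with a JSON metadata sidecar
carrying the frame period, pixel size, start time and (for simulated
stacks) the ground-truth event list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .models import GaussianPeak, MovieStack

REQUIRED_EVENT_COLUMNS = ("time_s", "contrast", "x_px", "y_px")


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(REQUIRED_EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns: {sorted(missing)}")
    return table


def write_peaks(
    peaks: Sequence[GaussianPeak],
    path,
    labels: Optional[Sequence[str]] = None,
    nominal_lengths: Optional[Sequence[int]] = None,
) -> Path:
    path = Path(path)
    rows = {
        "label": list(labels) if labels is not None else [f"peak_{i+1}" for i in range(len(peaks))],
        "A": [p.A for p in peaks],
        "mu": [p.mu for p in peaks],
        "sigma": [p.sigma for p in peaks],
        "area": [p.area for p in peaks],
    }
    if nominal_lengths is not None:
        rows["nominal_length"] = list(nominal_lengths)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_peaks(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"A", "mu", "sigma"} - set(table.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns: {sorted(missing)}")
    return table


def save_movie(movie: MovieStack, path) -> Path:
    """Write a movie as multi-page float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "frame_period": movie.frame_period,
        "pixel_size_nm": movie.pixel_size_nm,
        "t_start": movie.t_start,
    }
    if movie.ground_truth is not None:
        meta["ground_truth_events"] = movie.ground_truth.to_dict(orient="list")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_movie(path) -> MovieStack:
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    gt = meta.get("ground_truth_events")
    return MovieStack(
        frames=np.asarray(frames),
        frame_period=float(meta.get("frame_period", 1.0)),
        pixel_size_nm=float(meta.get("pixel_size_nm", 84.4)),
        t_start=float(meta.get("t_start", 0.0)),
        ground_truth=pd.DataFrame(gt) if gt else None,
    )


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
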