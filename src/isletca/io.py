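"""File I/O: TIFF stacks, CSV tables, and JSON sidecars.

Movies are multi-page TIFF (written as unsigned 16-bit); traces, event
tables and reports are CSV; specs, timelines and provenance are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import Movie, RoiMap, TraceSet


def read_movie(path, rate_hz: float, px_um: float | None = None) -> Movie:
    """Read a multi-page TIFF as a Movie."""
    stack = tifffile.imread(path)
    return Movie(np.asarray(stack), rate_hz, px_um)


def write_movie(path, movie: Movie) -> None:
    """Write a movie as unsigned 16-bit multi-page TIFF (values clipped)."""
    data = np.clip(np.round(movie.stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_label_image(path) -> RoiMap:
    return RoiMap(tifffile.imread(path).astype(np.int32))


def write_label_image(path, rois: RoiMap) -> None:
    tifffile.imwrite(path, rois.labels.astype(np.int32))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def write_traces(path, traces: TraceSet) -> None:
    """Long-format CSV: roi_id, time_s, F."""
    t = traces.times_s
    frames = []
    for k, roi in enumerate(traces.roi_ids):
        frames.append(pd.DataFrame({"roi_id": int(roi), "time_s": t, "F": traces.traces[k]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> TraceSet:
    """Read a long-format trace CSV (roi_id, time_s, F)."""
    df = pd.read_csv(path)
    rois = sorted(df["roi_id"].unique())
    mats = []
    rate = None
    for roi in rois:
        sub = df[df["roi_id"] == roi].sort_values("time_s")
        mats.append(sub["F"].to_numpy())
        t = sub["time_s"].to_numpy()
        if len(t) > 1:
            rate = 1.0 / float(np.median(np.diff(t)))
    if rate is None:
        raise ValueError("trace CSV holds fewer than 2 samples per ROI")
    return TraceSet(np.vstack(mats), rate, np.asarray(rois))


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
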