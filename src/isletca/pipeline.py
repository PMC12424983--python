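"""End-to-end orchestration: movie -> ROIs -> traces -> events -> summaries.

A single RunConfig drives the chain deterministically: segmentation of the
statistical image, trace extraction, F/F0 correction, multi-timescale
event detection, the ROI-activity and halfwidth band filters, condition
assignment from a protocol timeline, per-condition medians, and (when at
least two ROIs survive) per-condition functional networks.  Every stage
writes its artifact to the output directory, and a JSON manifest records
parameters, input hashes and package version, so re-running an identical
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import events as ev
from . import io as iio
from . import network as net
from . import segmentation as seg
from . import summaries as summ

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``movie_path`` (with ``rate_hz``) or ``traces_path`` must be
    given; ``timeline_path`` is required.  Parameter blocks override module
    defaults.
    """

    out_dir: str
    timeline_path: str
    movie_path: str | None = None
    traces_path: str | None = None
    rate_hz: float = 20.0
    seed: int = 0
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.movie_path is None) == (self.traces_path is None):
            raise ValueError("exactly one of movie_path or traces_path must be set")
        if self.timeline_path is None or not Path(self.timeline_path).exists():
            raise ValueError(f"timeline_path does not exist: {self.timeline_path}")
        src = self.movie_path or self.traces_path
        if not Path(src).exists():
            raise ValueError(f"input path does not exist: {src}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    On a stage failure the report carries the stage name and cause, and
    partial outputs already written are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    # no timestamps in the manifest: identical inputs + config must produce
    # byte-identical outputs, manifest included
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": [],
    }
    for key in ("movie_path", "traces_path", "timeline_path"):
        p = getattr(config, key)
        if p:
            report["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    stage = "load"
    try:
        timeline = summ.ProtocolTimeline.from_json(config.timeline_path)
        if config.movie_path:
            movie = iio.read_movie(config.movie_path, config.rate_hz)
            stage = "segmentation"
            seg_params = {"min_area_px": 30, "max_area_px": 2000, "upper_percentile": 99.0}
            seg_params.update(config.segmentation)
            stat = seg.statistical_image(movie, seg_params["upper_percentile"])
            rois = seg.segment_rois(
                stat, seg_params["min_area_px"], seg_params["max_area_px"]
            )
            iio.write_label_image(out / "rois.tiff", rois)
            report["stages"].append({"stage": stage, "n_rois": rois.n_rois})
            stage = "extraction"
            traces = seg.extract_traces(movie, rois)
        else:
            traces = iio.read_traces(config.traces_path)
            report["stages"].append({"stage": "load_traces", "n_rois": traces.n_rois})
        iio.write_traces(out / "traces.csv", traces)

        stage = "detection"
        det = {
            "z_thresh": 4.0,
            "scales_s": ev.dyadic_scales(1.0, 256.0),
            "min_events": 5,
            "band_lo_s": 1.0,
            "band_hi_s": 10.0,
            "debleach_method": "exponential",
        }
        det.update(config.detection)
        raw_events = ev.detect_events_traceset(
            traces,
            scales_s=det["scales_s"],
            z_thresh=det["z_thresh"],
            debleach_method=det["debleach_method"],
        )
        iio.write_events(out / "events_raw.csv", raw_events)
        filtered = ev.filter_rois(raw_events, det["min_events"])
        filtered = ev.band_filter_events(filtered, det["band_lo_s"], det["band_hi_s"])
        iio.write_events(out / "events.csv", filtered)
        iio.write_json(out / "detection_params.json", det)
        report["stages"].append(
            {"stage": stage, "n_events_raw": len(raw_events), "n_events": len(filtered)}
        )

        stage = "summaries"
        labeled = summ.assign_condition(filtered, timeline)
        iio.write_events(out / "events_labeled.csv", labeled)
        medians = summ.condition_medians(
            labeled, iei_mode=config.summaries.get("iei_mode", "pooled")
        )
        medians.to_csv(out / "condition_medians.csv", index=False)
        report["stages"].append({"stage": stage, "n_conditions": len(medians)})

        stage = "network"
        net_params = {"threshold": 0.7}
        net_params.update(config.network)
        metrics_rows = []
        if traces.n_rois >= 2:
            norm = np.vstack(
                [
                    ev.debleach(traces.traces[k], traces.rate_hz, det["debleach_method"]).values
                    for k in range(traces.n_rois)
                ]
            )
            norm_set = seg.TraceSet(norm, traces.rate_hz, traces.roi_ids)
            for start, end, cond in timeline.intervals:
                end = min(end, traces.traces.shape[1] / traces.rate_hz)
                if end - start < 30.0:
                    continue
                corr = net.correlation_matrix(norm_set, (start, end))
                g = net.build_network(corr, net_params["threshold"])
                m = net.network_metrics(g)
                metrics_rows.append(
                    {
                        "condition": cond,
                        "mean_node_degree": m.mean_node_degree,
                        "average_clustering": m.average_clustering,
                        "mean_efficiency": m.mean_efficiency,
                    }
                )
        if metrics_rows:
            import pandas as pd

            pd.DataFrame(metrics_rows).to_csv(out / "network_metrics.csv", index=False)
        report["stages"].append({"stage": stage, "n_networks": len(metrics_rows)})
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        report["error"] = {"stage": stage, "cause": repr(exc)}
        iio.write_json(out / "manifest.json", report)
        raise

    iio.write_json(out / "manifest.json", report)
    return report
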