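"""End-to-end orchestration: frames + sensors in, correlation report out.

The pipeline runs the full method: learn the three chroma thresholds
from labelled patches, segment every frame, accumulate per-period
occupancy maps, compute the band-ratio activity index, aggregate the
sensor stream to per-period means with THI, and correlate activity, THI
and ammonia with Kendall's tau.  Every artefact (masks, heat maps,
count CSVs, summary and correlation CSVs) is written under the output
directory; runs are deterministic under a fixed config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as _activity
from . import envstats as _envstats
from .model import ChromaThresholdSegmenter
from .colorspace import load_image
from .segmentation import save_mask

log = logging.getLogger("broilervision")

__all__ = ["PipelineConfig", "run_pipeline", "read_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see `read_config` for the file form."""

    frames_dir: str | None = None  # dir with frames + manifest.csv
    sensor_csv: str | None = None  # raw readings, or per-period summaries
    out_dir: str = "out"
    patches: dict = field(default_factory=dict)  # label -> [(row, col), ...]
    patch_image: str | None = None  # frame to sample patches from
    patch_size: int = 20
    n_patch_samples: int = 100
    band: tuple = (10, 49)
    tau_variant: str = "tau_b"
    seed: int = 0
    eq2_verbatim: bool = False
    no_images: bool = False
    expected_frames: int = 60

    def __post_init__(self):
        lo, hi = self.band
        if lo > hi:
            raise ValueError("band_lo must not exceed band_hi")


def read_config(path) -> PipelineConfig:
    """Parse the flat KEY=VALUE config file.

    Recognised keys mirror the `PipelineConfig` fields; patch lists are
    given as e.g. ``patches.body = 10,20; 30,40`` (semicolon-separated
    row,col origins).
    """
    cfg = PipelineConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("patches."):
            label = key.split(".", 1)[1]
            origins = []
            for pair in val.split(";"):
                r, c = (int(v) for v in pair.split(","))
                origins.append((r, c))
            cfg.patches[label] = origins
        elif key == "band":
            lo, hi = (int(v) for v in val.replace(":", ",").split(","))
            cfg.band = (lo, hi)
        elif key in ("eq2_verbatim", "no_images"):
            setattr(cfg, key, val.lower() in ("1", "true", "yes"))
        elif key in ("patch_size", "n_patch_samples", "seed", "expected_frames"):
            setattr(cfg, key, int(val))
        elif key in ("frames_dir", "sensor_csv", "out_dir", "patch_image", "tau_variant"):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg.__post_init__()
    return cfg


def _read_summaries(path) -> list:
    """Accept either a raw sensor CSV or an already-aggregated summary CSV."""
    head = pd.read_csv(path, nrows=0)
    if "timestamp" in head.columns:
        readings = _envstats.read_sensor_csv(path)
        return _envstats.aggregate_periods(readings)
    return _envstats.frame_to_summaries(pd.read_csv(path))


def _segment_periods(cfg: PipelineConfig, out: Path) -> dict:
    """Learn thresholds, segment all frames, return activity per (date, period)."""
    frames_dir = Path(cfg.frames_dir)
    manifest = frames_dir / "manifest.csv"
    if manifest.exists():
        man = pd.read_csv(manifest)
    else:
        paths = sorted(p.name for p in frames_dir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        man = pd.DataFrame({"frame": range(len(paths)), "path": paths,
                            "period": "all", "date": "all"})
    if not cfg.patches or cfg.patch_image is None:
        raise FileNotFoundError("stage learn-thresholds: patch_image and patches required")
    patch_img = load_image(cfg.patch_image)
    model = ChromaThresholdSegmenter.fit_from_patches(
        patch_img, cfg.patches, patch_size=cfg.patch_size,
        n_samples=cfg.n_patch_samples, seed=cfg.seed,
        eq2_verbatim=cfg.eq2_verbatim)
    log.info("stage learn-thresholds: %s", model.thresholds_.as_dict())
    pd.DataFrame([model.thresholds_.as_dict()]).to_csv(out / "thresholds.csv",
                                                       index=False)

    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    activities = {}
    for (date, period), grp in man.groupby(["date", "period"], sort=True):
        masks = []
        for _, row in grp.iterrows():
            frame = load_image(frames_dir / row["path"])
            mask = model.segment(frame)
            save_mask(mask, mask_dir / (Path(str(row["path"])).stem + "_mask.png"))
            masks.append(mask)
        acc = _activity.accumulate(masks)
        res = _activity.activity_index(acc, *cfg.band)
        flagged = acc.n_frames < cfg.expected_frames
        if flagged:
            log.warning("period %s %s has %d frames (expected %d); flagged",
                        date, period, acc.n_frames, cfg.expected_frames)
        tag = f"{date}_{period.replace(':', '')}"
        _activity.render_heatmap(acc, out / f"heatmap_{tag}.png")
        np.savetxt(out / f"counts_{tag}.csv", acc.counts, fmt="%d", delimiter=",")
        activities[(str(date), str(period))] = (res.index, not flagged)
        log.info("stage activity: %s %s index=%.4f n_frames=%d",
                 date, period, res.index, acc.n_frames)
    return activities


def run_pipeline(cfg: PipelineConfig) -> int:
    """Run the configured pipeline; returns 0 on success.

    Missing inputs raise `FileNotFoundError` with the failing stage
    named; the CLI converts that into a nonzero exit code.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries = []
    if cfg.sensor_csv:
        if not Path(cfg.sensor_csv).exists():
            raise FileNotFoundError(f"stage aggregate: sensor CSV {cfg.sensor_csv} not found")
        summaries = _read_summaries(cfg.sensor_csv)
        log.info("stage aggregate: %d complete periods", len(summaries))

    if not cfg.no_images and cfg.frames_dir:
        if not Path(cfg.frames_dir).exists():
            raise FileNotFoundError(f"stage segment: frames dir {cfg.frames_dir} not found")
        activities = _segment_periods(cfg, out)
        by_key = {(s.date, s.period): s for s in summaries}
        for key, (idx, complete) in activities.items():
            if key in by_key:
                by_key[key].activity = idx
                by_key[key].complete = by_key[key].complete and complete
            else:
                summaries.append(_envstats.PeriodSummary(
                    date=key[0], period=key[1], activity=idx, complete=complete))

    if summaries:
        _envstats.summaries_to_frame(summaries).to_csv(out / "period_summaries.csv",
                                                       index=False)

    report_rows = []
    pairs = [("thi", "mean_nh3"), ("thi", "activity"), ("mean_nh3", "activity")]
    for var_x, var_y in pairs:
        try:
            res = _envstats.correlate_periods(summaries, var_x, var_y,
                                              variant=cfg.tau_variant)
        except ValueError:
            continue
        report_rows.append({"var_x": var_x, "var_y": var_y, "variant": res.variant,
                            "tau": res.tau, "p_value": res.p_value, "n": res.n})
        log.info("stage correlate: %s x %s tau=%.4f p=%.4g n=%d",
                 var_x, var_y, res.tau, res.p_value, res.n)
    if report_rows:
        pd.DataFrame(report_rows).to_csv(out / "correlations.csv", index=False)
    return 0
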