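"""Configuration, file formats, logging and end-to-end orchestration.

Disk layout of a run directory::

    input_dir/
      flatfield.tif            multi-page stack of raw frames (>= 60)
      scans/<name>.tif         multi-page raster scan, row-major frames
      scans/<name>.json        layout sidecar: grid, nominal_step_px,
                               pixel_size_um, channel_id, timestamp_h,
                               marker, concentration, flow_ul_h

Outputs are diff-able text or TIFF: localisations.csv, densities.csv,
series/<channel>.csv + steady_state.json (kinetics mode),
fingerprint.csv/.json (fingerprint mode), and a run manifest holding the
config hash so unchanged inputs are a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import detect as _detect
from . import fingerprint as _fingerprint
from . import kinetics as _kinetics
from . import quantify as _quantify
from .preprocess import (FLATFIELD_MIN_FRAMES, MEDIAN_KERNEL,
                         DEFAULT_PIXEL_SIZE_UM, ContrastImage, RawFrame,
                         build_flat_field, normalize_counts, preprocess_frame,
                         stitch_scan)

logger = logging.getLogger("iscatflow")


def setup_logging(level: int = logging.INFO) -> None:
    """ISO-timestamped stderr logging for pipeline runs."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their platform defaults."""

    input_dir: str = "."
    output_dir: str = "out"
    mode: str = "detect"  # detect | kinetics | fingerprint
    seed: int = 0
    snr_threshold: float = 4.0
    min_cluster: int = 3
    noise_kernel: int = 65
    inlier_factor: float = 2.5
    median_kernel: int = MEDIAN_KERNEL
    contrast_threshold: float = _quantify.CONTRAST_CUTOFF
    flatfield_min_frames: int = FLATFIELD_MIN_FRAMES
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_segments: int = _kinetics.N_SEGMENTS
    roi_halfwidth: int = 7
    merge_radius_px: float = 2.0
    control_marker: str = "IgG1"
    offset_counts: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_scan(path, frames, layout: dict) -> None:
    """Multi-page 16-bit TIFF plus a JSON layout sidecar."""
    path = Path(path)
    stack = np.stack([np.clip(np.rint(f.pixels), 0, 65535).astype(np.uint16)
                      for f in frames])
    tifffile.imwrite(path, stack)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(layout, fh, indent=1)


def read_scan(path) -> tuple[list, dict]:
    """Read a multi-page scan TIFF and its layout sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"layout sidecar {sidecar} missing for scan {path}")
    with open(sidecar) as fh:
        layout = json.load(fh)
    for key in ("grid", "nominal_step_px", "pixel_size_um"):
        if key not in layout:
            raise ValueError(f"malformed layout JSON: missing key {key!r}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    psz = float(layout["pixel_size_um"])
    frames = [RawFrame(page.astype(np.float32), pixel_size_um=psz,
                       fov_id=f"p{i}",
                       channel_id=str(layout.get("channel_id", "ch0")),
                       timestamp_h=float(layout.get("timestamp_h", 0.0)))
              for i, page in enumerate(stack)]
    return frames, layout


def write_truth_csv(path, particles) -> None:
    """Ground-truth particle list as CSV (x_um, y_um, contrast, klass,
    bind_time_h)."""
    pd.DataFrame([{
        "x_um": p.x_um, "y_um": p.y_um, "contrast": p.contrast,
        "klass": p.klass, "bind_time_h": p.bind_time_h,
    } for p in particles]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def process_scan(frames, layout, config: PipelineConfig, flat):
    """Preprocess every frame of one raster scan and stitch the results."""
    imgs = [preprocess_frame(f, flat, kernel=config.median_kernel,
                             offset_counts=config.offset_counts)
            for f in frames]
    if len(imgs) == 1:
        mosaic = stitch_scan(imgs, {"grid": [1, 1],
                                    "nominal_step_px": [0, 0]})
    else:
        mosaic = stitch_scan(imgs, layout)
    mosaic.channel_id = str(layout.get("channel_id", "ch0"))
    mosaic.timestamp_h = float(layout.get("timestamp_h", 0.0))
    return mosaic


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute preprocess -> detect -> quantify -> (kinetics | fingerprint).

    Returns a dict of output paths; re-running with unchanged inputs and
    config is a no-op (content hash check on the run manifest).
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ff_path = in_dir / "flatfield.tif"
    if not ff_path.exists():
        raise FileNotFoundError(
            f"{ff_path} not found: build flat-field source frames first "
            "(e.g. `iscatflow simulate` or `iscatflow flatfield`)")
    scan_paths = sorted((in_dir / "scans").glob("*.tif"))
    if not scan_paths:
        raise FileNotFoundError(f"no scans found under {in_dir / 'scans'}")

    hasher = hashlib.sha256(config.content_hash().encode())
    for p in [ff_path, *scan_paths]:
        hasher.update(p.read_bytes())
        sidecar = p.with_suffix(".json")
        if sidecar.exists():
            hasher.update(sidecar.read_bytes())
    run_hash = hasher.hexdigest()[:16]
    manifest_path = out_dir / "run_manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            if json.load(fh).get("run_hash") == run_hash:
                logger.info("inputs unchanged (hash %s); skipping", run_hash)
                return {"output_dir": str(out_dir), "skipped": True}

    logger.info("run start: mode=%s seed=%d config=%s", config.mode,
                config.seed, config.content_hash())

    ff_stack = tifffile.imread(ff_path)
    ff_frames = [normalize_counts(
        RawFrame(page.astype(np.float32),
                 pixel_size_um=config.pixel_size_um),
        offset_counts=config.offset_counts) for page in ff_stack]
    flat = build_flat_field(ff_frames, min_frames=config.flatfield_min_frames,
                            strict=False)

    all_locs, records = [], []
    channel_meta: dict = {}
    for path in scan_paths:
        frames, layout = read_scan(path)
        mosaic = process_scan(frames, layout, config, flat)
        locs = _detect.detect_particles(
            mosaic, snr_threshold=config.snr_threshold,
            min_cluster=config.min_cluster,
            noise_kernel=config.noise_kernel,
            inlier_factor=config.inlier_factor,
            roi_halfwidth=config.roi_halfwidth,
            merge_radius_px=config.merge_radius_px)
        locs = _quantify.classify_contrast(locs, config.contrast_threshold)
        locs.insert(0, "scan", path.stem)
        all_locs.append(locs)
        rec = _quantify.compute_density(
            locs, mosaic.scanned_area_um2,
            channel_id=mosaic.channel_id,
            threshold=config.contrast_threshold,
            timestamp_h=mosaic.timestamp_h,
            concentration=layout.get("concentration"),
            flow_ul_h=layout.get("flow_ul_h"))
        records.append(rec)
        channel_meta.setdefault(mosaic.channel_id,
                                layout.get("marker"))
        logger.info("scan %s: %d localisations, %.3f signal per 100 um^2",
                    path.stem, len(locs), rec.density_signal)

    locs_df = pd.concat(all_locs, ignore_index=True)
    locs_path = out_dir / "localisations.csv"
    locs_df.to_csv(locs_path, index=False)
    dens_path = out_dir / "densities.csv"
    _quantify.density_records_to_frame(records).to_csv(dens_path, index=False)
    outputs = {"localisations": str(locs_path), "densities": str(dens_path),
               "output_dir": str(out_dir)}

    if config.mode == "kinetics":
        series_dir = out_dir / "series"
        series_dir.mkdir(exist_ok=True)
        summary = {}
        by_channel: dict = {}
        for rec in records:
            by_channel.setdefault(rec.channel_id, []).append(rec)
        for ch, recs in by_channel.items():
            if len(recs) < 2:
                continue
            series = _kinetics.assemble_timeseries(recs)
            pd.DataFrame({"t_h": series.times_h,
                          "density_signal_per_100um2": series.density,
                          "density_err": series.density_err}).to_csv(
                series_dir / f"{ch}.csv", index=False)
            ss = _kinetics.detect_steady_state(series)
            summary[ch] = {"reached": ss.reached, "t_ss_h": ss.t_ss_h,
                           "plateau_density": ss.plateau_density}
        ss_path = out_dir / "steady_state.json"
        with open(ss_path, "w") as fh:
            json.dump(summary, fh, indent=1)
        outputs["steady_state"] = str(ss_path)

    if config.mode == "fingerprint":
        by_marker: dict = {}
        locs_by_marker: dict = {}
        t_last = max(r.timestamp_h for r in records)
        for rec, locs in zip(records, all_locs):
            marker = channel_meta.get(rec.channel_id) or rec.channel_id
            if rec.timestamp_h == t_last:
                by_marker.setdefault(marker, []).append(rec)
                locs_by_marker.setdefault(marker, []).append(locs)
        locs_by_marker = {m: pd.concat(v, ignore_index=True)
                          for m, v in locs_by_marker.items()}
        table = _fingerprint.build_fingerprint(
            by_marker, control_marker=config.control_marker,
            locs=locs_by_marker)
        table = _fingerprint.call_positive(
            table, control_marker=config.control_marker)
        fp_path = out_dir / "fingerprint.csv"
        table.to_csv(fp_path, index=False)
        with open(out_dir / "fingerprint.json", "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=1)
        outputs["fingerprint"] = str(fp_path)

    with open(manifest_path, "w") as fh:
        json.dump({"run_hash": run_hash,
                   "config": dataclasses.asdict(config)}, fh, indent=1)
    logger.info("run complete: %s", out_dir)
    return outputs
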