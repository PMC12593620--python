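"""File I/O and pipeline orchestration.

Images travel as multi-page TIFF (one channel per page, 16-bit unsigned
for photon-count data, float for noise-free renders) with a YAML sidecar
naming the channels and carrying metadata and fiducial geometry.  Tables
are UTF-8 comma-separated CSV with mandatory headers, '.' decimal and
empty fields for undefined values; pixel coordinates are 0-based with
(x = column, y = row).  Calibrations are small YAML records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import calibration as cal
from . import correlative, ratiometric, stats, synthdata, workflows

logger = logging.getLogger("redoxmap")

__all__ = [
    "read_field",
    "write_field",
    "read_calibration",
    "write_calibration",
    "read_rois",
    "write_rois",
    "run_pipeline",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_field(path, field: ratiometric.FieldImage) -> Path:
    """Write a field as multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    names = list(field.channels)
    stack = np.stack([field.channels[n] for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "channels": names,
        "pixel_size": float(field.pixel_size),
        "metadata": {k: _yaml_safe(v) for k, v in field.metadata.items()},
        "fiducials": [list(map(int, f)) for f in field.fiducials],
        "dtype": str(stack.dtype),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def _yaml_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, tuple):
        return list(v)
    return v


def read_field(path) -> ratiometric.FieldImage:
    """Read a multi-page TIFF field written by :func:`write_field`.

    Channel order and names come from the sidecar; shape and dtype are
    validated.  Missing sidecar, missing channel names or mixed channel
    shapes raise descriptive errors naming the path.
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"channel metadata sidecar missing for {path}")
    meta = yaml.safe_load(side.read_text())
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if stack.size == 0:
        raise OSError(f"cannot read image file {path}: no image data")
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channels")
    if not names or len(names) != len(stack):
        raise ValueError(
            f"{path}: sidecar names {names} do not match {len(stack)} pages"
        )
    return ratiometric.FieldImage(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size=float(meta.get("pixel_size", 1.0)),
        metadata=meta.get("metadata", {}),
        fiducials=[tuple(f) for f in meta.get("fiducials", [])],
    )


def write_calibration(path, calib: cal.CalibrationParams) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(calib)))
    return path


def read_calibration(path) -> cal.CalibrationParams:
    data = yaml.safe_load(Path(path).read_text())
    return cal.CalibrationParams(**data)


def write_rois(path, measurements: Sequence[ratiometric.RoiMeasurement]) -> Path:
    path = Path(path)
    rows = []
    for m in measurements:
        d = dataclasses.asdict(m)
        d["qc_flags"] = ";".join(sorted(m.qc_flags))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_rois(path) -> list[ratiometric.RoiMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        flags = frozenset(str(r["qc_flags"]).split(";")) if pd.notna(r["qc_flags"]) and r["qc_flags"] else frozenset()
        out.append(
            ratiometric.RoiMeasurement(
                cell_id=str(r["cell_id"]),
                x=float(r["x"]),
                y=float(r["y"]),
                radius=float(r["radius"]),
                f740_mean=float(r["f740_mean"]),
                f910_mean=float(r["f910_mean"]),
                ratio=float(r["ratio"]),
                ratio_of_means=float(r["ratio_of_means"]),
                n_valid_pixels=int(r["n_valid_pixels"]),
                qc_flags=flags,
            )
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate -> quantify -> calibrate -> OxD -> screen -> compare.

    ``config`` is a plain mapping (typically loaded from YAML) with keys
    ``seed``, optional ``scenario`` overrides (SimScenario fields),
    ``groups`` (list of {region, genotype, age_group, n_cells}) and
    optional ``calibration`` (either a triple or {"simulate": {n_ox,
    n_red}} to estimate one from synthetic endpoint recordings).

    Writes cells.csv, summary_cells.csv, summary_slices.csv,
    comparisons.csv, calib.yaml and a manifest.json listing every
    artifact with its SHA-256 hash; returns the manifest.  Every
    screening step logs input/output n with exclusion counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scen_kwargs = dict(config.get("scenario", {}))
    if "image_shape" in scen_kwargs:
        scen_kwargs["image_shape"] = tuple(scen_kwargs["image_shape"])
    scenario = synthdata.SimScenario(seed=seed, **scen_kwargs)

    calib_cfg = config.get("calibration", {})
    if "r_ox" in calib_cfg:
        calib = cal.CalibrationParams(**calib_cfg)
    else:
        sim = calib_cfg.get("simulate", {})
        calib = workflows.recover_calibration(
            n_ox=int(sim.get("n_ox", 40)),
            n_red=int(sim.get("n_red", 40)),
            seed=seed,
            scenario=synthdata.SimScenario(
                image_shape=(420, 420), seed=seed
            ),
        )
    write_calibration(out / "calib.yaml", calib)
    model = synthdata.make_fluorophore_model(calib)

    groups = config.get("groups") or [
        {"region": "CA1", "genotype": g, "age_group": a, "n_cells": 30}
        for g in ("WT", "Mecp2+/-")
        for a in ("p50", "gt_p100")
    ]
    frames = []
    seeds = workflows._seeds(seed + 1, len(groups))
    for gseed, grp in zip(seeds, groups):
        n = int(grp.get("n_cells", scenario.cells_per_field * scenario.fields_per_slice))
        n_fields = int(np.ceil(n / scenario.cells_per_field))
        fseeds = workflows._seeds(gseed, n_fields)
        remaining = n
        for i in range(n_fields):
            nc = min(scenario.cells_per_field, remaining)
            remaining -= nc
            field, _ = synthdata.simulate_field(
                scenario,
                model,
                slice_id=f"{grp['region']}_{grp['genotype']}_{grp['age_group']}_s{i // scenario.fields_per_slice}",
                region=grp["region"],
                genotype=grp["genotype"],
                age_group=grp["age_group"],
                seed=fseeds[i],
                field_id=f"f{i}",
                n_cells=nc,
            )
            meas = workflows.quantify_field(field)
            frames.append(workflows._measurements_to_cells(meas, field.metadata, calib))
    cells = pd.concat(frames, ignore_index=True)
    n0 = len(cells)
    cells = stats.filter_intact(cells)
    n1 = int(cells["included"].sum())
    logger.info("intactness screen: %d -> %d cells (%d excluded)", n0, n1, n0 - n1)
    cells = stats.apply_rout(cells)
    n2 = int(cells["included"].sum())
    logger.info("ROUT screen: %d -> %d cells (%d outliers)", n1, n2, n1 - n2)
    cells.to_csv(out / "cells.csv", index=False)

    stats.aggregate(cells, level="cell").to_csv(out / "summary_cells.csv", index=False)
    stats.aggregate(cells, level="slice").to_csv(out / "summary_slices.csv", index=False)

    comp_frames = []
    for region, sub in cells[cells["included"]].groupby("region"):
        if sub["genotype"].nunique() < 2 or sub["age_group"].nunique() < 2:
            continue
        result = stats.two_way_anova_holm_sidak(sub)
        pw = result.pairwise.copy()
        pw.insert(0, "region", region)
        comp_frames.append(pw.drop(columns=["level_a", "level_b"]))
    if comp_frames:
        pd.concat(comp_frames, ignore_index=True).to_csv(
            out / "comparisons.csv", index=False
        )

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "n_detected": n0,
        "n_after_range": n1,
        "n_after_rout": n2,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
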