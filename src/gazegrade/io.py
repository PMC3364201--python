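"""Readers and writers for the pipeline's on-disk dialects.

Rasters: 8-bit grey (or RGB) PNG/TIFF intensity images and 16-bit
single-channel PNG/TIFF label masks (0 = background). Tables: delimited
text with fixed headers — per-nucleus features, gaze logs
(``t_ms,x_px,y_px,valid``), fixations, grade and matrix-trial tables —
plus a YAML manifest and a JSON ground-truth file for synthetic cohorts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputError, ParseError
from .gaze import Fixation, GazeStream
from .morphometry import FEATURE_NAMES, LabeledField
from .synthetic import CohortConfig, SyntheticCohort

log = logging.getLogger(__name__)

FEATURE_HEADER = ["field_id", "label", "centroid_row", "centroid_col",
                  *FEATURE_NAMES]
GAZE_HEADER = ["t_ms", "x_px", "y_px", "valid"]
FIXATION_HEADER = ["rater_id", "field_id", "start_ms", "duration_ms",
                   "x_px", "y_px", "nucleus_label"]


# --------------------------------------------------------------------------
# rasters

def write_field(field: LabeledField, directory: Path) -> tuple[Path, Path]:
    """Write a field's intensity (uint8) and labels (uint16) as PNG."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ipath = directory / f"{field.field_id}_intensity.png"
    lpath = directory / f"{field.field_id}_labels.png"
    intensity = np.asarray(field.intensity)
    if intensity.dtype != np.uint8:
        intensity = np.clip(intensity, 0, 255).astype(np.uint8)
    labels = np.asarray(field.labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise InputError("label raster exceeds 16-bit range")
    iio.imwrite(ipath, intensity)
    iio.imwrite(lpath, labels.astype(np.uint16))
    return ipath, lpath


def read_field(directory: Path, field_id: str, *, condition=None,
               case_id=None, circle=None, gleason_delta_class=None) -> LabeledField:
    directory = Path(directory)
    intensity = iio.imread(directory / f"{field_id}_intensity.png")
    labels = iio.imread(directory / f"{field_id}_labels.png").astype(np.int32)
    return LabeledField(intensity=intensity, labels=labels, field_id=field_id,
                        condition=condition, case_id=case_id, circle=circle,
                        gleason_delta_class=gleason_delta_class)


# --------------------------------------------------------------------------
# gaze logs

def write_gaze_log(stream: GazeStream, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(GAZE_HEADER) + "\n")
        for t, x, y, v in zip(stream.t_ms, stream.x_px, stream.y_px,
                              stream.valid):
            fh.write(f"{t:.1f},{x:.2f},{y:.2f},{int(v)}\n")
    return path


def read_gaze_log(path: Path, rater_id: str, field_id: str) -> GazeStream:
    """Parse a gaze log, reporting the 1-based line of any bad row."""
    path = Path(path)
    t, x, y, v = [], [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",") != GAZE_HEADER:
            raise ParseError(f"bad gaze header {header!r}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"expected 4 fields, got {len(parts)}",
                                 path, lineno)
            try:
                t.append(float(parts[0]))
                x.append(float(parts[1]))
                y.append(float(parts[2]))
                v.append(bool(int(parts[3])))
            except ValueError as exc:
                raise ParseError(f"unparseable value ({exc})", path, lineno)
    try:
        return GazeStream(rater_id=rater_id, field_id=field_id,
                          t_ms=np.array(t), x_px=np.array(x),
                          y_px=np.array(y), valid=np.array(v, dtype=bool))
    except InputError as exc:
        raise ParseError(str(exc), path, None)


def write_fixations(rows: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, columns=FIXATION_HEADER)
    return path


# --------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing input table: {path}")
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# manifest + ground truth

def config_to_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # ordered list of [feature, weight] pairs: YAML mappings may be
    # re-sorted on dump, which would silently permute the tuple
    d["selection_weights"] = [list(pair) for pair in cfg.selection_weights]
    d["rater_preferences"] = (list(cfg.rater_preferences)
                              if cfg.rater_preferences is not None else None)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    sw = d.get("selection_weights")
    if sw is not None:
        pairs = sw.items() if isinstance(sw, dict) else sw
        d["selection_weights"] = tuple((str(k), float(v)) for k, v in pairs)
    for key in ("aspect_range", "fixation_samples_range", "grade_clamp"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("rater_preferences") is not None:
        d["rater_preferences"] = tuple(d["rater_preferences"])
    return CohortConfig(**d)


def write_manifest(cfg: CohortConfig, seed: int, out_dir: Path,
                   rendered: bool) -> Path:
    path = Path(out_dir) / "manifest.yaml"
    payload = {
        "gazegrade_version": __version__,
        "seed": int(seed),
        "rendered": bool(rendered),
        "config": config_to_dict(cfg),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_manifest(out_dir: Path) -> dict:
    path = Path(out_dir) / "manifest.yaml"
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["config"] = config_from_dict(payload["config"])
    return payload


def write_ground_truth(cohort: SyntheticCohort, out_dir: Path) -> Path:
    """Ground truth as structured text (JSON): rater rules, case offsets,
    fixated and matrix-displayed labels. The per-nucleus truth table is the
    ``nuclei.csv`` written beside it."""
    truth = cohort.truth
    payload = {
        "seed": cohort.seed,
        "raters": truth.raters.to_dict(orient="records"),
        "cases": truth.cases.to_dict(orient="records"),
        "fixated_labels": {f"{r}|{f}": labels
                           for (r, f), labels in truth.fixated_labels.items()},
        "matrix_labels": truth.matrix_labels,
    }
    path = Path(out_dir) / "ground_truth.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_ground_truth(out_dir: Path) -> dict:
    with open(Path(out_dir) / "ground_truth.json") as fh:
        payload = json.load(fh)
    payload["fixated_labels"] = {
        tuple(k.split("|", 1)): v
        for k, v in payload["fixated_labels"].items()}
    return payload


# --------------------------------------------------------------------------
# cohort round trip

def write_cohort(cohort: SyntheticCohort, out_dir: Path) -> Path:
    """Write a synthetic cohort in the exact dialects the pipeline consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rendered = bool(cohort.fields)
    write_manifest(cohort.cfg, cohort.seed, out_dir, rendered)
    write_table(cohort.fields_meta, out_dir / "fields.csv")
    write_table(cohort.nuclei, out_dir / "nuclei.csv")
    write_table(cohort.grades, out_dir / "grades.csv")
    write_table(cohort.matrix_trials[["rater_id", "field_id", "grade"]],
                out_dir / "matrix_trials.csv")
    matrix_rows = [{"field_id": fid, "label": lab}
                   for fid, labs in cohort.truth.matrix_labels.items()
                   for lab in labs]
    write_table(pd.DataFrame(matrix_rows), out_dir / "matrix_display.csv")
    write_table(cohort.fixated, out_dir / "fixated.csv")
    write_ground_truth(cohort, out_dir)
    if rendered:
        for field in cohort.fields.values():
            write_field(field, out_dir / "fields")
        for (rater_id, field_id), stream in cohort.gaze.items():
            write_gaze_log(stream,
                           out_dir / "gaze" / f"{rater_id}__{field_id}.csv")
    log.info("cohort written to %s (rendered=%s)", out_dir, rendered)
    return out_dir
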