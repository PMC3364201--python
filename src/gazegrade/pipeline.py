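"""End-to-end orchestration: cohort directory in, analysis tables out.

``analyze_dir`` consumes a cohort directory (as written by
:func:`gazegrade.io.write_cohort` or assembled from real exports in the
same dialects) and runs morphometry -> fixation mapping -> rater profiles
-> bias decomposition, writing every intermediate table plus a text
report. Rendered cohorts are recomputed from pixels and gaze samples;
tabular cohorts start from the per-nucleus feature table and the recorded
fixated-feature means.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as gio
from .errors import InputError, UndefinedAggregateError
from .gaze import (GazeConfig, assign_fixations, detect_fixations,
                   fixated_features)
from .model import ArchitectureBiasModel
from .morphometry import (FEATURE_NAMES, FeatureVector, NucleusRecord,
                          extract_nuclei, features_frame)
from .profiles import profiles_frame

log = logging.getLogger(__name__)


def compute_features(in_dir: Path, fields_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-nucleus features for every field, recomputed from the rasters."""
    frames = []
    for row in fields_meta.itertuples(index=False):
        circle = (row.circle_row, row.circle_col, row.circle_radius)
        field = gio.read_field(Path(in_dir) / "fields", row.field_id,
                               condition=row.condition, case_id=row.case_id,
                               circle=circle)
        records = extract_nuclei(field)
        frames.append(features_frame(records))
    feats = pd.concat(frames, ignore_index=True)
    meta = fields_meta[["field_id", "case_id", "condition"]]
    return feats.merge(meta, on="field_id", how="left")


def _records_by_field(features: pd.DataFrame) -> dict:
    out: dict = {}
    for fid, grp in features.groupby("field_id"):
        out[fid] = [
            NucleusRecord(fid, int(r.label), (r.centroid_row, r.centroid_col),
                          FeatureVector(r.size_px, r.hyperchromasia,
                                        r.heterochromasia, r.roundness))
            for r in grp.itertuples(index=False)]
    return out


def compute_fixations(in_dir: Path, fields_meta: pd.DataFrame,
                      features: pd.DataFrame,
                      gaze_cfg: GazeConfig | None = None):
    """Detect and assign fixations for every gaze log in the cohort.

    Returns ``(fixations, fixated_means)``: the per-fixation table and the
    per rater x field mean features over distinct fixated nuclei. Trials
    with no assigned fixation are logged and skipped.
    """
    gaze_cfg = gaze_cfg or GazeConfig()
    in_dir = Path(in_dir)
    meta = fields_meta.set_index("field_id")
    records = _records_by_field(features)
    label_cache: dict = {}
    fix_rows = []
    mean_rows = []
    gaze_dir = in_dir / "gaze"
    if not gaze_dir.is_dir():
        raise InputError(f"no gaze directory at {gaze_dir}")
    for path in sorted(gaze_dir.glob("*.csv")):
        rater_id, _, field_id = path.stem.partition("__")
        if not field_id or field_id not in meta.index:
            raise InputError(f"gaze log {path.name}: unknown field")
        stream = gio.read_gaze_log(path, rater_id, field_id)
        if field_id not in label_cache:
            row = meta.loc[field_id]
            field = gio.read_field(in_dir / "fields", field_id)
            label_cache[field_id] = (field.labels,
                                     (row.circle_row, row.circle_col,
                                      row.circle_radius))
        labels, circle = label_cache[field_id]
        fixations = assign_fixations(detect_fixations(stream, gaze_cfg),
                                     labels, gaze_cfg, circle)
        for f in fixations:
            fix_rows.append({
                "rater_id": rater_id, "field_id": field_id,
                "start_ms": f.start_ms, "duration_ms": f.duration_ms,
                "x_px": f.x_px, "y_px": f.y_px,
                "nucleus_label": f.nucleus_label,
            })
        try:
            fv = fixated_features(fixations, records[field_id],
                                  context=f"{rater_id}/{field_id}")
        except UndefinedAggregateError as exc:
            log.warning("skipping trial with no fixated nuclei: %s", exc)
            continue
        row = meta.loc[field_id]
        mean_rows.append({
            "rater_id": rater_id, "field_id": field_id,
            "case_id": row.case_id, "condition": row.condition,
            "n_fixated": len({f.nucleus_label for f in fixations
                              if f.assigned}),
            **fv.as_dict(),
        })
    return pd.DataFrame(fix_rows), pd.DataFrame(mean_rows)


def matrix_trial_table(matrix_grades: pd.DataFrame,
                       matrix_display: pd.DataFrame,
                       features: pd.DataFrame) -> pd.DataFrame:
    """Join matrix-trial grades with the mean features of the displayed
    nuclei (ten per field)."""
    joined = matrix_display.merge(features, on=["field_id", "label"],
                                  how="left")
    if joined[list(FEATURE_NAMES)].isna().any().any():
        missing = joined[joined["size_px"].isna()].iloc[0]
        raise InputError(
            f"matrix display references unknown nucleus "
            f"{missing['field_id']}/{int(missing['label'])}")
    per_field = joined.groupby("field_id")[list(FEATURE_NAMES)].mean()
    return matrix_grades.merge(per_field, on="field_id", how="left")


def analyze_dir(in_dir: Path, out_dir: Path | None = None,
                gaze_cfg: GazeConfig | None = None,
                rho_min: float = 0.3, p_max: float = 0.05,
                per_pair: bool = False):
    """Run the full analysis over a cohort directory; write report files.

    Returns the fitted :class:`~gazegrade.model.ArchitectureBiasResults`.
    """
    in_dir = Path(in_dir)
    out_dir = Path(out_dir) if out_dir is not None else in_dir / "analysis"
    out_dir.mkdir(parents=True, exist_ok=True)
    gaze_cfg = gaze_cfg or GazeConfig()

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("gazegrade")
    root.addHandler(handler)
    prev_level = root.level
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        manifest = gio.read_manifest(in_dir)
        log.info("gazegrade %s analyzing %s", __version__, in_dir)
        log.info("seed=%s rendered=%s", manifest.get("seed"),
                 manifest.get("rendered"))
        log.info("thresholds: rho_min=%g p_max=%g min_duration_ms=%g "
                 "dispersion_px=%g assignment_radius_px=%g",
                 rho_min, p_max, gaze_cfg.min_duration_ms,
                 gaze_cfg.dispersion_px, gaze_cfg.assignment_radius_px)

        fields_meta = gio.read_table(in_dir / "fields.csv")
        rendered = bool(manifest.get("rendered"))
        if rendered:
            features = compute_features(in_dir, fields_meta)
            fixations, fixated = compute_fixations(in_dir, fields_meta,
                                                   features, gaze_cfg)
            gio.write_table(fixations, out_dir / "fixations.csv")
        else:
            features = gio.read_table(in_dir / "nuclei.csv")
            fixated = gio.read_table(in_dir / "fixated.csv")
        gio.write_table(features, out_dir / "features.csv")
        gio.write_table(fixated, out_dir / "fixated_means.csv")

        grades = gio.read_table(in_dir / "grades.csv")
        matrix_grades = gio.read_table(in_dir / "matrix_trials.csv")
        matrix_display = gio.read_table(in_dir / "matrix_display.csv")
        matrix = matrix_trial_table(matrix_grades, matrix_display, features)

        model = ArchitectureBiasModel(grades, matrix, fixated,
                                      rho_min=rho_min, p_max=p_max,
                                      per_pair=per_pair)
        results = model.fit()

        gio.write_table(results.deltas, out_dir / "deltas.csv")
        gio.write_table(profiles_frame(results.profiles),
                        out_dir / "profiles.csv")
        gio.write_table(results.shifts, out_dir / "fixation_shifts.csv")
        gio.write_table(results.decomposition, out_dir / "decomposition.csv")
        report = results.summary()
        (out_dir / "report.txt").write_text(report)
        log.info("analysis complete: %s", out_dir)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prev_level)
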