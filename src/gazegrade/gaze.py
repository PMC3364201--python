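"""Fixation detection and fixation-to-nucleus mapping.

Raw gaze samples (a nominal 50 Hz remote eye-tracker export: timestamp plus
screen-pixel position) are reduced to fixations with the standard
dispersion-threshold algorithm (I-DT): a fixation is a maximal run of
consecutive valid samples whose bounding-box dispersion (width + height)
stays within a threshold and whose duration reaches a minimum (100 ms by
default, the recording criterion of the study design this emulates).

Each fixation is then assigned to the nucleus it rests on: the label under
its centroid pixel, or failing that the nearest labeled pixel within an
assignment radius that absorbs tracker inaccuracy (0.4 degrees of visual
angle ~ 14 px at the study geometry).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np

from .errors import InputError, UndefinedAggregateError
from .morphometry import FeatureVector, NucleusRecord, mean_features

log = logging.getLogger(__name__)

#: Sentinel for a fixation that rests on no nucleus.
UNASSIGNED = 0


@dataclass(frozen=True)
class GazeConfig:
    """Tunable constants of fixation detection and nucleus assignment.

    min_duration_ms
        Minimum fixation duration; 100 ms by default.
    dispersion_px
        I-DT bounding-box dispersion threshold (width + height), default
        40 px, roughly one degree of visual angle at the study geometry.
    assignment_radius_px
        Maximum centroid-to-mask distance for nucleus assignment, default
        14 px (~0.4 degree tracker accuracy).
    sampling_hz
        Nominal sampling rate; fixes the one-sample-interval term of the
        duration convention (5 samples at 50 Hz = exactly 100 ms).
    """

    min_duration_ms: float = 100.0
    dispersion_px: float = 40.0
    assignment_radius_px: float = 14.0
    sampling_hz: float = 50.0

    def __post_init__(self):
        for name in ("min_duration_ms", "dispersion_px", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise InputError(f"GazeConfig.{name} must be positive")
        if self.assignment_radius_px < 0:
            raise InputError("GazeConfig.assignment_radius_px must be >= 0")

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_hz


@dataclass
class GazeStream:
    """Time-ordered gaze samples for one rater viewing one field."""

    rater_id: str
    field_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise InputError("gaze sample arrays must share one length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise InputError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class Fixation:
    """A detected gaze dwell; ``nucleus_label`` is 0 until assigned."""

    start_ms: float
    duration_ms: float
    x_px: float
    y_px: float
    n_samples: int
    nucleus_label: int = UNASSIGNED

    @property
    def assigned(self) -> bool:
        return self.nucleus_label != UNASSIGNED


def _valid_runs(valid: np.ndarray):
    """Index ranges [i, j) of maximal runs of valid samples."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = 0
    for b in breaks:
        yield idx[start], idx[b] + 1
        start = b + 1
    yield idx[start], idx[-1] + 1


def detect_fixations(stream: GazeStream, cfg: GazeConfig | None = None) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Scans left to right; at each anchor the window is grown while the
    bounding-box dispersion (width + height) stays within
    ``cfg.dispersion_px``. The maximal such run is emitted as a fixation if
    its duration — last timestamp minus first plus one nominal sample
    interval — reaches ``cfg.min_duration_ms``; otherwise the anchor
    advances by one sample. Invalid samples split candidate windows; no
    interpolation is performed. Emitted fixations are therefore
    non-overlapping and time-ordered.
    """
    cfg = cfg or GazeConfig()
    interval = cfg.sample_interval_ms
    out: list[Fixation] = []
    for lo, hi in _valid_runs(stream.valid):
        t = stream.t_ms[lo:hi]
        x = stream.x_px[lo:hi]
        y = stream.y_px[lo:hi]
        n = hi - lo
        i = 0
        while i < n:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            j = i
            while j + 1 < n:
                nx_min = min(xmin, x[j + 1]); nx_max = max(xmax, x[j + 1])
                ny_min = min(ymin, y[j + 1]); ny_max = max(ymax, y[j + 1])
                if (nx_max - nx_min) + (ny_max - ny_min) > cfg.dispersion_px:
                    break
                xmin, xmax, ymin, ymax = nx_min, nx_max, ny_min, ny_max
                j += 1
            duration = t[j] - t[i] + interval
            if duration >= cfg.min_duration_ms:
                out.append(Fixation(
                    start_ms=float(t[i]),
                    duration_ms=float(duration),
                    x_px=float(x[i:j + 1].mean()),
                    y_px=float(y[i:j + 1].mean()),
                    n_samples=j - i + 1,
                ))
                i = j + 1
            else:
                i += 1
    return out


def _inside_circle(x: float, y: float, circle) -> bool:
    crow, ccol, radius = circle
    return math.hypot(y - crow, x - ccol) <= radius


def assign_fixation(fix: Fixation,
                    labels: np.ndarray,
                    cfg: GazeConfig | None = None,
                    circle: tuple | None = None) -> Fixation:
    """Assign a fixation to a nucleus label (or leave it unassigned).

    Convention: gaze x is the column and gaze y the row of the raster. If
    the centroid pixel carries a label, that nucleus wins outright; else
    the nearest labeled pixel (Euclidean, pixel centers, brute force over a
    local window) within ``cfg.assignment_radius_px``; else unassigned.
    Fixations outside the viewport ``circle`` (center_row, center_col,
    radius), when given, are never assigned.
    """
    cfg = cfg or GazeConfig()
    labels = np.asarray(labels)
    h, w = labels.shape
    row_f, col_f = fix.y_px, fix.x_px
    if circle is not None and not _inside_circle(fix.x_px, fix.y_px, circle):
        return replace(fix, nucleus_label=UNASSIGNED)
    row, col = int(round(row_f)), int(round(col_f))
    if not (0 <= row < h and 0 <= col < w):
        return replace(fix, nucleus_label=UNASSIGNED)
    if labels[row, col] > 0:
        return replace(fix, nucleus_label=int(labels[row, col]))
    r = cfg.assignment_radius_px
    if r <= 0:
        return replace(fix, nucleus_label=UNASSIGNED)
    pad = int(math.ceil(r)) + 1
    r0, r1 = max(0, row - pad), min(h, row + pad + 1)
    c0, c1 = max(0, col - pad), min(w, col + pad + 1)
    window = labels[r0:r1, c0:c1]
    rr, cc = np.nonzero(window > 0)
    if rr.size == 0:
        return replace(fix, nucleus_label=UNASSIGNED)
    d = np.hypot(rr + r0 - row_f, cc + c0 - col_f)
    k = int(np.argmin(d))
    if d[k] <= r:
        return replace(fix, nucleus_label=int(window[rr[k], cc[k]]))
    return replace(fix, nucleus_label=UNASSIGNED)


def assign_fixations(fixations: Sequence[Fixation],
                     labels: np.ndarray,
                     cfg: GazeConfig | None = None,
                     circle: tuple | None = None) -> list[Fixation]:
    """Vector convenience: :func:`assign_fixation` over a list."""
    return [assign_fixation(f, labels, cfg, circle) for f in fixations]


def fixated_features(fixations: Sequence[Fixation],
                     records: Sequence[NucleusRecord],
                     weight_by_duration: bool = False,
                     context: str = "") -> FeatureVector:
    """Mean features of the nuclei fixated at least once.

    By default every distinct fixated nucleus counts once regardless of how
    often or how long it was fixated; ``weight_by_duration`` switches to a
    total-dwell-time weighted mean.
    """
    by_label = {r.label: r for r in records}
    dwell: dict[int, float] = {}
    for f in fixations:
        if not f.assigned:
            continue
        if f.nucleus_label not in by_label:
            log.warning("fixation assigned to unknown label %d%s",
                        f.nucleus_label, f" ({context})" if context else "")
            continue
        dwell[f.nucleus_label] = dwell.get(f.nucleus_label, 0.0) + f.duration_ms
    if not dwell:
        raise UndefinedAggregateError(
            f"no assigned fixations{f' ({context})' if context else ''}")
    labels = sorted(dwell)
    arr = np.stack([by_label[l].features.as_array() for l in labels])
    if weight_by_duration:
        w = np.array([dwell[l] for l in labels], dtype=float)
        m = (arr * w[:, None]).sum(axis=0) / w.sum()
    else:
        m = arr.mean(axis=0)
    return FeatureVector(*map(float, m))


def fixated_labels(fixations: Sequence[Fixation]) -> list[int]:
    """Sorted distinct nucleus labels with at least one assigned fixation."""
    return sorted({f.nucleus_label for f in fixations if f.assigned})
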