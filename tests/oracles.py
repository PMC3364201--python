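"""Independent reference implementations used to check the package.

Everything here is deliberately written with a different algorithm (or a
different library call) than the implementation it checks: brute-force
scans, closed-form formulas, and plain-loop statistics.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats
from skimage import measure


# --------------------------------------------------------------------------
# morphometry

def contour_polygon_form_factor(mask: np.ndarray, step: int = 8) -> float:
    """Form factor from a subsampled marching-squares contour polygon.

    Independent of the Crofton estimator used by the implementation: the
    region boundary is traced at the 0.5 iso-level, the polyline is
    subsampled every ``step`` vertices (which removes the staircase bias
    of the raw trace on smooth shapes), and the polygon length is used as
    the perimeter.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    sub = np.vstack([contour[::step], contour[-1:]])
    perim = float(np.sqrt((np.diff(sub, axis=0) ** 2).sum(axis=1)).sum())
    area = int(mask.sum())
    return 4 * math.pi * area / perim**2


def ideal_form_factor(area: float, perimeter: float) -> float:
    """4*pi*A/P**2 with analytically known area and perimeter."""
    return 4 * math.pi * area / perimeter**2


# --------------------------------------------------------------------------
# fixation detection

def idt_oracle(t_ms, x_px, y_px, valid, dispersion_px, min_duration_ms,
               interval_ms):
    """Exhaustive-window dispersion-threshold fixation detection.

    For each candidate start (within maximal runs of valid samples, left
    to right) the window is extended sample by sample, recomputing the
    bounding-box dispersion from scratch each time; the maximal compliant
    window is emitted when its duration (last - first + one interval)
    reaches the minimum, and scanning resumes after it.

    Returns a list of ``(start_ms, duration_ms, cx, cy, n)`` tuples.
    """
    t = np.asarray(t_ms, float)
    x = np.asarray(x_px, float)
    y = np.asarray(y_px, float)
    valid = np.asarray(valid, bool)

    runs = []
    start = None
    for i, v in enumerate(valid):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(valid)))

    out = []
    for lo, hi in runs:
        i = lo
        while i < hi:
            j_best = None
            for j in range(i, hi):
                xs, ys = x[i:j + 1], y[i:j + 1]
                disp = (xs.max() - xs.min()) + (ys.max() - ys.min())
                if disp > dispersion_px:
                    break
                j_best = j
            if j_best is None:
                i += 1
                continue
            duration = t[j_best] - t[i] + interval_ms
            if duration >= min_duration_ms:
                out.append((float(t[i]), float(duration),
                            float(x[i:j_best + 1].mean()),
                            float(y[i:j_best + 1].mean()),
                            j_best - i + 1))
                i = j_best + 1
            else:
                i += 1
    return out


def nearest_label_bruteforce(labels: np.ndarray, x: float, y: float,
                             radius: float) -> int:
    """Scan every labeled pixel for the nearest one to gaze point (x, y).

    Returns 0 when the nearest labeled pixel (or the centroid pixel) is
    farther than ``radius``. Pixel-center convention: gaze x is column,
    gaze y is row.
    """
    labels = np.asarray(labels)
    row, col = int(round(y)), int(round(x))
    h, w = labels.shape
    if 0 <= row < h and 0 <= col < w and labels[row, col] > 0:
        return int(labels[row, col])
    best, best_d = 0, np.inf
    for r in range(h):
        for c in range(w):
            if labels[r, c] > 0:
                d = math.hypot(r - y, c - x)
                if d < best_d:
                    best, best_d = int(labels[r, c]), d
    return best if best_d <= radius else 0


# --------------------------------------------------------------------------
# statistics

def paired_t_closed_form(a, b):
    """Two-tailed paired t from the textbook formula."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * stats.t.sf(abs(t), n - 1)
    return t, n - 1, p


def spearman_manual(x, y):
    """Spearman rho from average ranks and the Pearson formula on ranks."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


# --------------------------------------------------------------------------
# whole-cohort oracle (from ground truth only)

def oracle_analysis(truth_raters, truth_cases, nuclei, fixated_labels,
                    matrix_labels, grades, matrix_grades, rho_min=0.3,
                    p_max=0.05):
    """Recompute the per-rater analysis from ground-truth tables alone.

    Implemented with plain dictionaries and loops plus direct
    ``scipy.stats.spearmanr`` / ``numpy.polyfit`` calls — no package code.
    Returns a dict keyed by rater_id with observed delta, per-feature rho,
    preferred feature, slope, predicted delta and fraction explained.
    """
    feature_names = ("size_px", "hyperchromasia", "heterochromasia",
                     "roundness")
    order = ("size_px", "hyperchromasia", "roundness", "heterochromasia")

    nuc = {}
    for row in nuclei.itertuples(index=False):
        nuc[(row.field_id, int(row.label))] = {
            f: getattr(row, f) for f in feature_names}

    field_cond = {}
    for row in nuclei.itertuples(index=False):
        field_cond[row.field_id] = row.condition

    # per-field mean features of the matrix display
    matrix_means = {}
    for fid, labs in matrix_labels.items():
        matrix_means[fid] = {
            f: float(np.mean([nuc[(fid, int(l))][f] for l in labs]))
            for f in feature_names}

    out = {}
    rater_ids = sorted(grades["rater_id"].unique())
    for rid in rater_ids:
        g = grades[grades["rater_id"] == rid]
        tub = g[g["condition"] == "tubular"]["grade"].mean()
        sol = g[g["condition"] == "solid"]["grade"].mean()
        observed = sol - tub

        mg = matrix_grades[matrix_grades["rater_id"] == rid]
        y = mg["grade"].to_numpy(float)
        rho, pval = {}, {}
        for f in feature_names:
            xv = np.array([matrix_means[fid][f] for fid in mg["field_id"]])
            r, p = stats.spearmanr(xv, y)
            rho[f], pval[f] = float(r), float(p)
        preferred, best = None, -1.0
        for f in order:
            if abs(rho[f]) > rho_min and pval[f] < p_max and abs(rho[f]) > best:
                preferred, best = f, abs(rho[f])

        predicted = 0.0
        slope = float("nan")
        if preferred is not None:
            xv = np.array([matrix_means[fid][preferred]
                           for fid in mg["field_id"]])
            slope = float(np.polyfit(xv, y, 1)[0])
            cond_means = {"tubular": [], "solid": []}
            for (r_id, fid), labs in fixated_labels.items():
                if r_id != rid:
                    continue
                vals = [nuc[(fid, int(l))][preferred] for l in labs]
                cond_means[field_cond[fid]].append(float(np.mean(vals)))
            shift = (float(np.mean(cond_means["solid"]))
                     - float(np.mean(cond_means["tubular"])))
            predicted = slope * shift
        fraction = predicted / observed if observed != 0 else None
        out[rid] = {
            "observed_delta": float(observed),
            "rho": rho, "p": pval, "preferred": preferred,
            "slope": slope, "predicted_delta": float(predicted),
            "fraction_explained": fraction,
        }
    return out
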