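"""Per-rater feature-preference profiles from isolated-nuclei matrix trials.

After grading high-power fields in context, each rater grades a series of
displays that each show ten nuclei cropped out of their architectural
context (a 2x5 matrix). Regressing those grades on the mean morphometric
features of the ten displayed nuclei reveals which feature — if any — the
rater's internal grading rule actually tracks:

* Spearman rank correlation (average ranks for ties, two-sided p) between
  grade and each of the four features over the rater's trials;
* a feature "passes" when |rho| > 0.3 and p < 0.05 (absolute value, so a
  darkness preference — lower grey level, higher grade — qualifies through
  its negative correlation);
* the passing feature with the largest |rho| becomes the rater's preferred
  feature, and an ordinary least-squares regression of grade on that
  feature yields the slope later used to convert fixated-feature shifts
  into predicted grade shifts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import InputError, SingularFitError
from .morphometry import FEATURE_NAMES, FeatureVector

log = logging.getLogger(__name__)

#: Tie-break order when two features pass with exactly equal |rho|.
PREFERENCE_ORDER = ("size_px", "hyperchromasia", "roundness", "heterochromasia")

DEFAULT_RHO_MIN = 0.3
DEFAULT_P_MAX = 0.05


@dataclass(frozen=True)
class MatrixTrial:
    """One isolated-nuclei display: its mean features and the grade given."""

    rater_id: str
    field_id: str
    mean_features: FeatureVector
    grade: float


class RegressionFit(NamedTuple):
    slope: float
    intercept: float
    slope_se: float
    df_resid: int


@dataclass
class RaterProfile:
    """A rater's correlation profile and grading rule.

    ``preferred_feature`` is ``None`` iff no feature passes both thresholds,
    in which case slope/intercept are ``None`` as well. ``degenerate`` marks
    profiles where the correlation was undefined (constant grades).
    """

    rater_id: str
    rho: dict
    p: dict
    preferred_feature: str | None = None
    slope: float | None = None
    intercept: float | None = None
    slope_se: float | None = None
    degenerate: bool = False


def _trial_matrix(trials: Sequence[MatrixTrial]):
    grades = np.array([t.grade for t in trials], dtype=float)
    feats = np.stack([t.mean_features.as_array() for t in trials])
    return grades, feats


def spearman_profile(trials: Sequence[MatrixTrial]) -> tuple[dict, dict, bool]:
    """Per-feature Spearman (rho, p) over a rater's matrix trials.

    Returns ``(rho, p, degenerate)``; with constant grades every correlation
    is undefined (NaN) and the profile is flagged degenerate rather than
    raising, so pathological synthetic raters flow through the pipeline.
    """
    if len(trials) < 5:
        raise InputError(f"spearman_profile needs >= 5 trials, got {len(trials)}")
    grades, feats = _trial_matrix(trials)
    rho: dict = {}
    p: dict = {}
    degenerate = np.ptp(grades) == 0
    for k, name in enumerate(FEATURE_NAMES):
        if degenerate or np.ptp(feats[:, k]) == 0:
            rho[name], p[name] = float("nan"), float("nan")
            continue
        res = stats.spearmanr(feats[:, k], grades)
        rho[name], p[name] = float(res.statistic), float(res.pvalue)
    if degenerate:
        log.warning("spearman_profile: constant grades; profile degenerate")
    return rho, p, degenerate


def select_preferred(rho: dict, p: dict,
                     rho_min: float = DEFAULT_RHO_MIN,
                     p_max: float = DEFAULT_P_MAX) -> str | None:
    """The passing feature with the largest |rho|, or ``None``.

    A feature passes when |rho| > rho_min and p < p_max (strict
    inequalities). Exact |rho| ties are broken by :data:`PREFERENCE_ORDER`.
    """
    best: str | None = None
    best_abs = -np.inf
    for name in PREFERENCE_ORDER:
        r, pv = rho.get(name), p.get(name)
        if r is None or pv is None or np.isnan(r) or np.isnan(pv):
            continue
        if abs(r) > rho_min and pv < p_max and abs(r) > best_abs:
            best, best_abs = name, abs(r)
    return best


def fit_grade_regression(trials: Sequence[MatrixTrial], feature: str) -> RegressionFit:
    """OLS of grade on one mean feature across a rater's matrix trials."""
    if feature not in FEATURE_NAMES:
        raise InputError(f"unknown feature {feature!r}")
    if len(trials) < 3:
        raise InputError("fit_grade_regression needs >= 3 trials")
    grades, feats = _trial_matrix(trials)
    x = feats[:, FEATURE_NAMES.index(feature)]
    if np.ptp(x) == 0:
        raise SingularFitError(f"zero variance in feature {feature!r}")
    X = sm.add_constant(x)
    fit = sm.OLS(grades, X).fit()
    return RegressionFit(slope=float(fit.params[1]),
                         intercept=float(fit.params[0]),
                         slope_se=float(fit.bse[1]),
                         df_resid=int(fit.df_resid))


def build_profile(trials: Sequence[MatrixTrial],
                  rho_min: float = DEFAULT_RHO_MIN,
                  p_max: float = DEFAULT_P_MAX) -> RaterProfile:
    """Full profile for one rater: correlations, preference, grading slope."""
    rater_id = trials[0].rater_id if trials else "?"
    rho, p, degenerate = spearman_profile(trials)
    prof = RaterProfile(rater_id=rater_id, rho=rho, p=p, degenerate=degenerate)
    if degenerate:
        return prof
    prof.preferred_feature = select_preferred(rho, p, rho_min, p_max)
    if prof.preferred_feature is not None:
        fit = fit_grade_regression(trials, prof.preferred_feature)
        prof.slope, prof.intercept = fit.slope, fit.intercept
        prof.slope_se = fit.slope_se
    return prof


def trials_from_frame(df: pd.DataFrame) -> dict[str, list[MatrixTrial]]:
    """Group a matrix-trial table into per-rater trial lists.

    Expects columns ``rater_id, field_id, grade`` plus the four feature
    columns (the mean features of the ten displayed nuclei).
    """
    missing = {"rater_id", "field_id", "grade", *FEATURE_NAMES} - set(df.columns)
    if missing:
        raise InputError(f"matrix-trial table missing columns: {sorted(missing)}")
    out: dict[str, list[MatrixTrial]] = {}
    for row in df.itertuples(index=False):
        fv = FeatureVector(row.size_px, row.hyperchromasia,
                           row.heterochromasia, row.roundness)
        out.setdefault(str(row.rater_id), []).append(
            MatrixTrial(str(row.rater_id), str(row.field_id), fv, float(row.grade)))
    return out


def profiles_frame(profiles: Sequence[RaterProfile]) -> pd.DataFrame:
    """Long-format profile table: one row per rater x feature."""
    rows = []
    for prof in profiles:
        for name in FEATURE_NAMES:
            rows.append({
                "rater_id": prof.rater_id,
                "feature": name,
                "rho": prof.rho.get(name, float("nan")),
                "p": prof.p.get(name, float("nan")),
                "selected": name == prof.preferred_feature,
                "slope": prof.slope if name == prof.preferred_feature else float("nan"),
                "intercept": prof.intercept if name == prof.preferred_feature else float("nan"),
            })
    return pd.DataFrame(rows)
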