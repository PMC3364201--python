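"""Architecture-induced grading bias: estimation and decomposition.

The experimental design shows each carcinoma twice — its high-power field
once in a tubule-rich (low Gleason) context and once in a solid (high
Gleason) context. For every rater the *observed bias* is

    observed_delta = mean(grades | solid) - mean(grades | tubular),

tested across raters with a two-tailed paired t (the rater is the unit of
inference). The *selection-predicted* component of that bias is what the
rater's own grading rule would produce purely from having fixated
different nuclei in the two conditions:

    predicted_delta = slope_preferred * (fixated-feature mean | solid
                                         - fixated-feature mean | tubular)

and ``fraction_explained = predicted_delta / observed_delta``. Raters with
no preferred feature contribute a predicted delta (hence fraction) of
zero; raters with a zero observed delta are excluded from the cohort
summary with a logged note. Fractions are reported unclipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedAggregateError, ValidationError
from .morphometry import FEATURE_NAMES
from .profiles import RaterProfile

log = logging.getLogger(__name__)

CONDITIONS = ("tubular", "solid")


class PairedT(NamedTuple):
    """Two-tailed paired t across raters; ``degenerate`` flags zero variance."""

    t: float
    df: int
    p: float
    degenerate: bool = False


class Anova(NamedTuple):
    """One-way ANOVA on per-rater deltas across groups."""

    F: float
    df_between: int
    df_within: int
    mse: float
    p: float
    degenerate: bool = False


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedT:
    """Closed-form two-tailed paired t-test of a vs b (same raters).

    Returns a degenerate result (t = 0 or NaN, flagged) instead of raising
    when the differences have zero variance, so synthetic edge cases run
    end-to-end.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("paired_t expects two equal-length 1-D arrays, n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float("inf") * np.sign(d.mean())
        log.warning("paired_t: zero-variance differences (degenerate)")
        return PairedT(t=float(t), df=n - 1, p=float("nan"), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedT(t=float(t), df=n - 1, p=float(p))


def one_way_anova(groups: Sequence[np.ndarray]) -> Anova:
    """One-way fixed-effects ANOVA with the mean-square error reported."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InputError("one_way_anova needs >= 2 nonempty groups")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_total = len(all_vals)
    k = len(groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0 or ss_within == 0:
        log.warning("one_way_anova: degenerate (zero within-group variance)")
        return Anova(F=float("nan"), df_between=df_b, df_within=max(df_w, 0),
                     mse=0.0, p=float("nan"), degenerate=True)
    ms_b = ss_between / df_b
    mse = ss_within / df_w
    F = ms_b / mse
    p = stats.f.sf(F, df_b, df_w)
    return Anova(F=float(F), df_between=df_b, df_within=df_w,
                 mse=float(mse), p=float(p))


def validate_pairing(grades: pd.DataFrame) -> None:
    """Every (rater, case) must appear exactly once per condition."""
    need = {"rater_id", "case_id", "condition", "grade"}
    missing = need - set(grades.columns)
    if missing:
        raise InputError(f"grade table missing columns: {sorted(missing)}")
    bad = set(grades["condition"]) - set(CONDITIONS)
    if bad:
        raise InputError(f"unknown condition value(s): {sorted(bad)}")
    counts = grades.groupby(["rater_id", "case_id", "condition"]).size()
    dup = counts[counts > 1]
    if len(dup):
        r, c, cond = dup.index[0]
        raise ValidationError(
            f"duplicate grade for rater {r!r}, case {c!r}, condition {cond!r}")
    wide = counts.unstack("condition")
    for cond in CONDITIONS:
        if cond not in wide.columns:
            wide[cond] = np.nan
    incomplete = wide[wide[list(CONDITIONS)].isna().any(axis=1)]
    if len(incomplete):
        r, c = incomplete.index[0]
        raise ValidationError(
            f"missing condition partner for rater {r!r}, case {c!r}")


def per_rater_deltas(grades: pd.DataFrame) -> pd.DataFrame:
    """Per-rater condition means and observed delta (solid - tubular)."""
    validate_pairing(grades)
    means = (grades.groupby(["rater_id", "condition"])["grade"]
             .mean().unstack("condition"))
    out = pd.DataFrame({
        "mean_tubular": means["tubular"],
        "mean_solid": means["solid"],
        "observed_delta": means["solid"] - means["tubular"],
    })
    return out.reset_index()


def observed_bias(grades: pd.DataFrame) -> tuple[pd.DataFrame, PairedT]:
    """Per-rater observed deltas plus the cohort paired t (rater as unit)."""
    deltas = per_rater_deltas(grades)
    test = paired_t(deltas["mean_solid"].to_numpy(),
                    deltas["mean_tubular"].to_numpy())
    return deltas, test


def stratify_bias(grades: pd.DataFrame, by: str):
    """Stratified bias analysis.

    ``by="gleason_delta_class"``: the within-rater contrast of the bias
    between case pairs whose background images differed by more vs by at
    most 1.5 Gleason points — per-stratum per-rater deltas and a paired t
    on the within-rater stratum difference.

    ``by="rater_group"`` or ``by="prostate_reader"``: per-rater deltas
    compared between independent rater groups with a one-way ANOVA.

    Returns ``(stratum_table, test)`` where the test is a :class:`PairedT`
    or :class:`Anova`.
    """
    if by == "gleason_delta_class":
        if by not in grades.columns:
            raise InputError(f"grade table has no column {by!r}")
        per_stratum = []
        for cls, sub in grades.groupby(by):
            d = per_rater_deltas(sub)
            d[by] = cls
            per_stratum.append(d)
        table = pd.concat(per_stratum, ignore_index=True)
        wide = table.pivot(index="rater_id", columns=by,
                           values="observed_delta").dropna()
        if wide.shape[1] != 2:
            raise InputError("gleason stratification needs exactly 2 classes")
        cols = sorted(wide.columns)
        test = paired_t(wide[cols[1]].to_numpy(), wide[cols[0]].to_numpy())
        return table, test
    if by in ("rater_group", "prostate_reader"):
        if by not in grades.columns:
            raise InputError(f"grade table has no column {by!r}")
        deltas = per_rater_deltas(grades)
        groups_col = grades.groupby("rater_id")[by].first()
        deltas = deltas.merge(groups_col.rename(by), on="rater_id")
        groups = [g["observed_delta"].to_numpy()
                  for _, g in deltas.groupby(by)]
        return deltas, one_way_anova(groups)
    raise InputError(f"unknown stratification {by!r}")


def fixated_condition_means(fixated: pd.DataFrame) -> pd.DataFrame:
    """Per-rater per-condition mean fixated features.

    Accepts one row per rater x field (or finer); averages within rater and
    condition. Expected columns: ``rater_id, condition`` + features.
    """
    need = {"rater_id", "condition", *FEATURE_NAMES}
    missing = need - set(fixated.columns)
    if missing:
        raise InputError(f"fixated-feature table missing columns: {sorted(missing)}")
    return (fixated.groupby(["rater_id", "condition"])[list(FEATURE_NAMES)]
            .mean().reset_index())


def fixation_shift(fixated: pd.DataFrame) -> pd.DataFrame:
    """Paired per-feature comparison of fixated-nucleus features.

    For each morphometric feature: condition means +/- SD across raters and
    a two-tailed paired t across raters of (solid - tubular). Returns one
    row per feature with columns ``mean_tubular, sd_tubular, mean_solid,
    sd_solid, shift, t, df, p``.
    """
    means = fixated_condition_means(fixated)
    wide = means.pivot(index="rater_id", columns="condition",
                       values=list(FEATURE_NAMES))
    rows = []
    for name in FEATURE_NAMES:
        tub = wide[(name, "tubular")].to_numpy()
        sol = wide[(name, "solid")].to_numpy()
        if np.isnan(tub).any() or np.isnan(sol).any():
            raise InputError(f"missing condition means for feature {name!r}")
        test = paired_t(sol, tub)
        rows.append({
            "feature": name,
            "mean_tubular": tub.mean(), "sd_tubular": tub.std(ddof=1),
            "mean_solid": sol.mean(), "sd_solid": sol.std(ddof=1),
            "shift": (sol - tub).mean(),
            "t": test.t, "df": test.df, "p": test.p,
            "degenerate": test.degenerate,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BiasDecomposition:
    """Per-rater decomposition of the observed bias."""

    rater_id: str
    observed_delta: float
    predicted_delta: float
    fraction_explained: float | None  # None when observed_delta == 0
    preferred_feature: str | None
    slope: float | None


def decompose_rater(profile: RaterProfile,
                    feature_shift: float | None,
                    observed_delta: float) -> BiasDecomposition:
    """Decompose one rater's bias given their profile and feature shift.

    ``feature_shift`` is the rater's fixated mean of the preferred feature
    under solid minus under tubular (ignored when there is no preferred
    feature, for which the predicted delta is zero by definition).
    """
    if profile.preferred_feature is None or profile.slope is None:
        predicted = 0.0
    else:
        if feature_shift is None:
            raise InputError(
                f"rater {profile.rater_id!r}: preferred feature "
                f"{profile.preferred_feature!r} but no fixated shift given")
        predicted = profile.slope * feature_shift
    if observed_delta == 0:
        log.info("rater %s: observed delta 0; fraction undefined, excluded "
                 "from cohort summary", profile.rater_id)
        fraction = None
    else:
        fraction = predicted / observed_delta
    return BiasDecomposition(
        rater_id=profile.rater_id,
        observed_delta=float(observed_delta),
        predicted_delta=float(predicted),
        fraction_explained=fraction,
        preferred_feature=profile.preferred_feature,
        slope=profile.slope,
    )


def decompose_bias(profiles: Sequence[RaterProfile],
                   fixated: pd.DataFrame,
                   deltas: pd.DataFrame,
                   per_pair: bool = False) -> pd.DataFrame:
    """Per-rater bias decomposition table.

    ``fixated`` carries per rater x field (or rater x condition) fixated
    feature means with a ``condition`` column; ``deltas`` is the output of
    :func:`per_rater_deltas`. By default the feature shift is computed from
    each rater's aggregate condition means; ``per_pair`` instead averages
    the per-case-pair shifts (requires a ``case_id`` column), which weights
    case pairs equally even when fixation counts differ.
    """
    if per_pair:
        if "case_id" not in fixated.columns:
            raise InputError("per_pair decomposition needs a case_id column")
        by_pair = (fixated.groupby(["rater_id", "case_id", "condition"])
                   [list(FEATURE_NAMES)].mean().unstack("condition"))
        shifts = {}
        for name in FEATURE_NAMES:
            diff = by_pair[(name, "solid")] - by_pair[(name, "tubular")]
            shifts[name] = diff.groupby("rater_id").mean()
        shift_frame = pd.DataFrame(shifts)
    else:
        means = fixated_condition_means(fixated)
        wide = means.pivot(index="rater_id", columns="condition",
                           values=list(FEATURE_NAMES))
        shift_frame = pd.DataFrame({
            name: wide[(name, "solid")] - wide[(name, "tubular")]
            for name in FEATURE_NAMES})
    delta_map = deltas.set_index("rater_id")["observed_delta"]
    rows = []
    for prof in profiles:
        if prof.rater_id not in delta_map.index:
            raise InputError(f"no observed delta for rater {prof.rater_id!r}")
        shift = None
        if prof.preferred_feature is not None and prof.rater_id in shift_frame.index:
            shift = float(shift_frame.loc[prof.rater_id, prof.preferred_feature])
        dec = decompose_rater(prof, shift, float(delta_map[prof.rater_id]))
        rows.append({
            "rater_id": dec.rater_id,
            "observed_delta": dec.observed_delta,
            "predicted_delta": dec.predicted_delta,
            "fraction_explained": dec.fraction_explained,
            "preferred_feature": dec.preferred_feature or "none",
            "slope": dec.slope if dec.slope is not None else float("nan"),
        })
    return pd.DataFrame(rows)


def cohort_summary(decomposition: pd.DataFrame) -> dict:
    """Cohort mean/median/range of per-rater fractions explained.

    Raters with an undefined fraction (observed delta exactly zero) are
    excluded; fractions are percentages and unclipped, with a count of any
    outside [0, 100].
    """
    frac = decomposition["fraction_explained"].dropna().astype(float) * 100.0
    if len(frac) == 0:
        raise UndefinedAggregateError("no rater has a defined fraction explained")
    out_of_band = int(((frac < 0) | (frac > 100)).sum())
    return {
        "n_raters": int(len(frac)),
        "mean_pct": float(frac.mean()),
        "median_pct": float(frac.median()),
        "min_pct": float(frac.min()),
        "max_pct": float(frac.max()),
        "n_outside_0_100": out_of_band,
    }
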