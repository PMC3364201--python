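"""Model/Results interface for the architecture-bias analysis.

:class:`ArchitectureBiasModel` bundles the three data tables the analysis
needs — paired HPF grades, isolated-nuclei matrix trials, and per-trial
fixated-nucleus feature means — and ``fit()`` runs the full chain:

1. per-rater observed bias (paired grade deltas, cohort paired t);
2. per-rater feature-preference profiles from the matrix trials
   (Spearman, strongest-|rho| selection, OLS grading slope);
3. per-feature fixated-feature shifts between conditions (paired t);
4. the slope-based decomposition of each rater's observed bias into a
   selection-predicted component and its fraction explained.

The returned :class:`ArchitectureBiasResults` carries every intermediate
table, a text ``summary()``, stratified re-analyses, and a paired-lines
plot of the headline comparison.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import profiles as prof_mod
from .bias import (Anova, PairedT, cohort_summary, decompose_bias,
                   fixation_shift, observed_bias, stratify_bias,
                   validate_pairing)
from .errors import InputError
from .morphometry import FEATURE_NAMES
from .profiles import RaterProfile, build_profile, trials_from_frame


class ArchitectureBiasModel:
    """Architecture-induced nuclear-grading bias model.

    Parameters
    ----------
    grades : DataFrame
        One row per rater x case x condition with columns ``rater_id,
        case_id, condition, grade`` (conditions ``tubular`` / ``solid``)
        and optionally ``rater_group, prostate_reader,
        gleason_delta_class`` for stratified analyses.
    matrix_trials : DataFrame
        One row per rater x isolated-nuclei display: ``rater_id, field_id,
        grade`` plus the four mean-feature columns of the ten displayed
        nuclei.
    fixated : DataFrame
        Per rater x field mean features of the fixated nuclei, with
        ``rater_id, condition`` (and ``case_id`` for per-pair mode) plus
        the feature columns.
    rho_min, p_max : float
        Feature-preference thresholds (|rho| > rho_min and p < p_max).
    per_pair : bool
        Compute fixated-feature shifts per case pair and average, instead
        of from per-rater aggregate condition means (the default).
    """

    def __init__(self, grades: pd.DataFrame, matrix_trials: pd.DataFrame,
                 fixated: pd.DataFrame, *, rho_min: float = 0.3,
                 p_max: float = 0.05, per_pair: bool = False):
        validate_pairing(grades)
        if not 0 < rho_min < 1 or not 0 < p_max < 1:
            raise InputError("rho_min and p_max must lie in (0, 1)")
        self.grades = grades
        self.matrix_trials = matrix_trials
        self.fixated = fixated
        self.rho_min = rho_min
        self.p_max = p_max
        self.per_pair = per_pair

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ArchitectureBiasModel":
        """Build directly from a :class:`~gazegrade.synthetic.SyntheticCohort`."""
        return cls(cohort.grades, cohort.matrix_trials, cohort.fixated, **kwargs)

    def fit(self) -> "ArchitectureBiasResults":
        deltas, t_obs = observed_bias(self.grades)
        trials = trials_from_frame(self.matrix_trials)
        profiles = [build_profile(ts, self.rho_min, self.p_max)
                    for _, ts in sorted(trials.items())]
        shifts = fixation_shift(self.fixated)
        decomposition = decompose_bias(profiles, self.fixated, deltas,
                                       per_pair=self.per_pair)
        return ArchitectureBiasResults(
            model=self, deltas=deltas, paired_t=t_obs, profiles=profiles,
            shifts=shifts, decomposition=decomposition)


@dataclass
class ArchitectureBiasResults:
    """Fitted results; see :class:`ArchitectureBiasModel`."""

    model: ArchitectureBiasModel
    deltas: pd.DataFrame            # per-rater condition means + observed delta
    paired_t: PairedT               # cohort test of the observed bias
    profiles: list                  # RaterProfile per rater
    shifts: pd.DataFrame            # per-feature fixated shift table
    decomposition: pd.DataFrame     # per-rater decomposition

    @property
    def fraction_summary(self) -> dict:
        """Cohort mean/median/range of per-rater fractions explained (%)."""
        return cohort_summary(self.decomposition)

    @property
    def profiles_frame(self) -> pd.DataFrame:
        return prof_mod.profiles_frame(self.profiles)

    def stratified(self, by: str):
        """Re-run the observed-bias analysis within strata (see
        :func:`gazegrade.bias.stratify_bias`)."""
        return stratify_bias(self.model.grades, by)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of every fitted quantity."""
        buf = _io.StringIO()
        w = buf.write
        d = self.deltas
        t = self.paired_t
        w("Architecture-induced nuclear grading bias\n")
        w("=" * 58 + "\n")
        w(f"raters: {len(d)}   cases: "
          f"{self.model.grades['case_id'].nunique()}\n\n")
        w("Observed bias (grade units, solid - tubular)\n")
        w(f"  mean grade tubular: {d['mean_tubular'].mean():6.3f} "
          f"+/- {d['mean_tubular'].std(ddof=1):.3f}\n")
        w(f"  mean grade solid:   {d['mean_solid'].mean():6.3f} "
          f"+/- {d['mean_solid'].std(ddof=1):.3f}\n")
        w(f"  mean delta:         {d['observed_delta'].mean():6.3f}\n")
        w(f"  paired t({t.df}) = {t.t:.2f}, p = {t.p:.2g}"
          f"{'  [degenerate]' if t.degenerate else ''}\n\n")
        w("Fixated-nucleus feature shifts (per-rater paired t)\n")
        for row in self.shifts.itertuples(index=False):
            w(f"  {row.feature:15s} {row.mean_tubular:9.2f} -> "
              f"{row.mean_solid:9.2f}  t({row.df}) = {row.t:6.2f}, "
              f"p = {row.p:.2g}\n")
        w("\nRater feature preferences\n")
        counts = self.decomposition["preferred_feature"].value_counts()
        for name, cnt in counts.items():
            w(f"  {name:15s} {cnt:2d} rater(s)\n")
        fs = self.fraction_summary
        w("\nFraction of bias explained by nucleus selection\n")
        w(f"  mean {fs['mean_pct']:.1f}%   median {fs['median_pct']:.1f}%   "
          f"range {fs['min_pct']:.1f}%-{fs['max_pct']:.1f}%  "
          f"(n = {fs['n_raters']})\n")
        if fs["n_outside_0_100"]:
            w(f"  note: {fs['n_outside_0_100']} rater fraction(s) outside "
              f"[0%, 100%]\n")
        return buf.getvalue()

    def plot_paired(self, ax=None, value: str = "grade"):
        """Paired-lines plot: one line per rater, tubular vs solid mean.

        ``value`` may be ``"grade"`` or one of the four feature names (the
        fixated-feature means).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3.2, 4))
        if value == "grade":
            wide = self.deltas.set_index("rater_id")[["mean_tubular", "mean_solid"]]
            label = "mean nuclear grade"
        elif value in FEATURE_NAMES:
            means = bias_mod.fixated_condition_means(self.model.fixated)
            wide = (means.pivot(index="rater_id", columns="condition",
                                values=value)[["tubular", "solid"]])
            wide.columns = ["mean_tubular", "mean_solid"]
            label = f"fixated {value}"
        else:
            raise InputError(f"unknown value {value!r}")
        for _, row in wide.iterrows():
            ax.plot([0, 1], [row["mean_tubular"], row["mean_solid"]],
                    "-o", color="0.4", ms=3, lw=0.8)
        ax.set_xticks([0, 1], ["tub", "solid"])
        ax.set_xlim(-0.3, 1.3)
        ax.set_ylabel(label)
        return ax
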