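"""Synthetic cohort generator with known ground truth.

Emulates the full experiment: 20 carcinoma cases, each contributing two
high-power fields (HPFs) with statistically identical nuclei, shown once in
a tubule-rich ("tubular") and once in a solid architectural context to each
of 20 raters; 8-second 50 Hz gaze streams over each HPF; isolated-nuclei
matrix trials (ten nuclei per field); and grades on the 1–3 half-step
scale.

The generative grade model for a rater r viewing field f under condition c:

    latent = intercept_r + slope_r * mean(preferred feature of fixated
             nuclei) + offset_case * [c == solid] + N(0, noise_sd)

rounded to the nearest half step and clamped to [1, 3]. ``offset_case`` is
the *direct* architecture offset (larger for case pairs whose background
images differ by more than 1.5 Gleason points); the *selection-mediated*
part of the bias arises because fixation targets are sampled with an
exponential tilt on a composite feature z-score — towards large/dark/
coarse nuclei under solid and small/pale/fine nuclei under tubular.

Two generation modes share every random choice that defines the ground
truth (which nuclei exist, which are fixated, which grades are given):

* *tabular* (``render=False``) — per-nucleus features are drawn from the
  configured distributions without rasterizing anything; fast enough for
  replicated statistical calibration studies;
* *rendered* (``render=True``) — additionally paints label + intensity
  rasters and synthesizes jittered 50 Hz gaze streams whose fixations land
  on the selected nuclei, so the raster/gaze pipeline can be validated
  end-to-end against the recorded ground truth.

The random stream is hierarchical (cohort seed -> per-case and per-rater
child seeds), so enlarging the rater panel never perturbs existing cases.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .errors import InputError
from .morphometry import (FEATURE_NAMES, FeatureVector, LabeledField,
                          NucleusRecord, form_factor)
from .gaze import GazeStream

log = logging.getLogger(__name__)

CONDITIONS = ("tubular", "solid")

#: Direction in which each feature increases with nuclear atypia: bigger,
#: darker (lower grey), coarser, less round.
ATYPIA_SIGN = {"size_px": 1.0, "hyperchromasia": -1.0,
               "heterochromasia": 1.0, "roundness": -1.0}

#: Default composition of the fixation-selection tilt (roundness plays no
#: role in selection, mirroring the null roundness shift of the design
#: this emulates).
DEFAULT_SELECTION_WEIGHTS = {"size_px": 1.0, "hyperchromasia": -1.0,
                             "heterochromasia": 1.0, "roundness": 0.0}

#: Experience groups cycled over the rater panel (4 + 4 + 4 + 8 = 20).
GROUP_PATTERN = (["junior_resident"] * 4 + ["senior_resident"] * 4
                 + ["young_faculty"] * 4 + ["senior_faculty"] * 8)

#: Preferred-feature pattern cycled over the panel: most raters grade on
#: size, a few on darkness, and some on no measurable feature at all.
PREFERENCE_PATTERN = (["size_px"] * 11 + ["hyperchromasia"] * 4 + [None] * 5)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort (except the seed).

    Feature distributions are chosen so that the cohort lands in the regime
    of the emulated study: mean nuclear size ~3200 px, mean grey ~135 with
    fixated-size condition shifts on the order of 100 px, and condition
    grade means near 2.0 (tubular) vs 2.4 (solid).
    """

    n_cases: int = 20
    n_raters: int = 20
    nuclei_per_field: int = 80

    # nucleus feature distributions
    mean_size_px: float = 3200.0
    size_cv: float = 0.25            # within-field lognormal CV of size
    case_size_cv: float = 0.08       # case-level size multiplier CV
    mean_grey: float = 135.0
    grey_sd_between: float = 10.0    # between-nucleus SD of mean grey
    case_grey_sd: float = 3.0        # case-level grey offset SD
    texture_sd_mean: float = 45.0    # mean per-nucleus pixel SD
    texture_sd_sd: float = 4.0
    roundness_mean: float = 0.88     # nominal roundness scale for z-scores
    roundness_sd: float = 0.05
    aspect_range: tuple = (1.0, 1.3)
    boundary_noise: float = 0.08     # radial contour noise amplitude (rel.)

    # rendering geometry
    field_diameter_px: int = 1704
    background_grey: float = 210.0
    background_sd: float = 6.0

    # gaze stream
    sampling_hz: float = 50.0
    trial_duration_ms: float = 8000.0
    fixations_per_trial: int = 15
    fixation_samples_range: tuple = (7, 16)  # 140–320 ms at 50 Hz
    saccade_samples: int = 2
    jitter_px: float = 2.0

    # selection and grading
    selection_strength: float = 0.15   # exponential tilt on composite z
    selection_weights: tuple = tuple(DEFAULT_SELECTION_WEIGHTS.items())
    grade_bias_delta: float = 0.36     # direct architecture offset (grade units)
    gleason_modulation: float = 0.33   # offset *(1 +/- this) by delta class
    coupling: float = 0.6              # grade units per nucleus-SD of feature
    rater_slope_cv: float = 0.2
    intercept_target: float = 2.02     # tubular condition grade mean
    rater_intercept_sd: float = 0.12
    grade_noise_sd: float = 0.15
    half_step: bool = True
    grade_clamp: tuple = (1.0, 3.0)
    matrix_nuclei: int = 10
    rater_preferences: tuple | None = None  # None -> PREFERENCE_PATTERN cycled

    def __post_init__(self):
        for name in ("n_cases", "n_raters", "nuclei_per_field",
                     "fixations_per_trial", "matrix_nuclei"):
            if getattr(self, name) <= 0:
                raise InputError(f"CohortConfig.{name} must be positive")

    def feature_scales(self) -> dict:
        """Nominal between-nucleus SD per feature (z-score denominators)."""
        return {
            "size_px": self.mean_size_px * self.size_cv,
            "hyperchromasia": self.grey_sd_between,
            "heterochromasia": self.texture_sd_sd,
            "roundness": self.roundness_sd,
        }

    def feature_means(self) -> dict:
        return {
            "size_px": self.mean_size_px,
            "hyperchromasia": self.mean_grey,
            "heterochromasia": self.texture_sd_mean,
            "roundness": self.roundness_mean,
        }

    def preferences(self) -> list:
        if self.rater_preferences is not None:
            pat = list(self.rater_preferences)
        else:
            pat = list(PREFERENCE_PATTERN)
        return [pat[i % len(pat)] for i in range(self.n_raters)]


def default_config(**overrides) -> CohortConfig:
    """The study-condition regime (architecture offset plus mild selection)."""
    return CohortConfig(**overrides)


def pure_selection_config(**overrides) -> CohortConfig:
    """No direct architecture offset: the entire bias is selection-mediated.

    Selection is strong enough that the mediated grade delta is of the
    same order as the default regime's total bias, and every rater grades
    on nuclear size so each has a well-defined linear rule.
    """
    base = dict(grade_bias_delta=0.0, selection_strength=1.0,
                rater_preferences=("size_px",))
    base.update(overrides)
    return CohortConfig(**base)


def offset_dominated_config(**overrides) -> CohortConfig:
    """Direct offset supplies ~90% of the generative bias (selection ~10%)."""
    base = dict(grade_bias_delta=0.36, selection_strength=0.10,
                rater_preferences=("size_px",))
    base.update(overrides)
    return CohortConfig(**base)


def noiseless_config(**overrides) -> CohortConfig:
    """Pure selection with no grade noise, rounding, or rater scatter.

    Grades are then an exact linear function of the fixated preferred
    feature, so the bias decomposition must recover a fraction explained
    of exactly 100% for every rater. Rater slope scatter is disabled so
    every latent grade stays strictly inside the [1, 3] clamp (a clamped
    grade would break the exact linearity this regime exists to test),
    and the selection tilt is moderate for the same reason.
    """
    base = dict(grade_bias_delta=0.0, selection_strength=0.3,
                rater_preferences=("size_px",), grade_noise_sd=0.0,
                rater_intercept_sd=0.0, rater_slope_cv=0.0,
                case_size_cv=0.0, case_grey_sd=0.0, half_step=False)
    base.update(overrides)
    return CohortConfig(**base)


# --------------------------------------------------------------------------
# ground-truth containers

@dataclass
class RaterTruth:
    rater_id: str
    preferred_feature: str | None
    slope: float
    intercept: float
    rater_group: str
    prostate_reader: bool


@dataclass
class GroundTruth:
    """Everything needed to recompute every pipeline output independently."""

    raters: pd.DataFrame          # rater_id, preferred_feature, slope, intercept, ...
    cases: pd.DataFrame           # case_id, gleason_delta_class, direct_offset
    nuclei: pd.DataFrame          # per-field per-nucleus true features
    fixated_labels: dict          # (rater_id, field_id) -> sorted list of labels
    matrix_labels: dict           # field_id -> list of displayed labels
    config: CohortConfig


@dataclass
class SyntheticCohort:
    """A generated experiment: pipeline input tables plus ground truth."""

    cfg: CohortConfig
    seed: int
    fields_meta: pd.DataFrame     # field_id, case_id, condition, gleason class
    nuclei: pd.DataFrame          # feature table (truth == measurable features)
    grades: pd.DataFrame          # rater_id, case_id, field_id, condition, grade, ...
    matrix_trials: pd.DataFrame   # rater_id, field_id, grade + mean features
    fixated: pd.DataFrame         # rater_id, field_id, case_id, condition + means
    truth: GroundTruth
    fields: dict = dc_field(default_factory=dict)   # field_id -> LabeledField
    gaze: dict = dc_field(default_factory=dict)     # (rater, field) -> GazeStream


# --------------------------------------------------------------------------
# RNG plumbing

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


_CASE, _RATER, _TRIAL, _MATRIX, _FIELD = 0, 1, 2, 3, 4


# --------------------------------------------------------------------------
# nuclei

def _sample_nucleus_params(cfg: CohortConfig, rng: np.random.Generator,
                           case_size_mult: float, case_grey_off: float) -> dict:
    """Draw per-nucleus generative parameters for one *case*.

    Both fields of a case share these draws: the emulated design verified
    that the two HPFs of each carcinoma were morphometrically identical,
    and sharing the draws realizes that exactly (only spatial arrangement
    and pixel noise differ between the pair in rendered mode). This also
    means that, with the selection tilt off, per-rater fixated-feature
    differences between conditions are exactly mean-zero.
    """
    n = cfg.nuclei_per_field
    sigma = math.sqrt(math.log(1 + cfg.size_cv**2))
    mu = math.log(cfg.mean_size_px * case_size_mult) - sigma**2 / 2
    harmonics = np.arange(2, 6)
    return {
        "sizes": rng.lognormal(mu, sigma, size=n),
        "greys": rng.normal(cfg.mean_grey + case_grey_off,
                            cfg.grey_sd_between, size=n),
        "textures": np.clip(rng.normal(cfg.texture_sd_mean,
                                       cfg.texture_sd_sd, size=n), 5.0, None),
        "aspects": rng.uniform(*cfg.aspect_range, size=n),
        "angles": rng.uniform(0, np.pi, size=n),
        # contour-noise harmonics (renderer) and the matching effective
        # amplitude used by the feature-level roundness model
        "g_amp": rng.normal(0, 1, size=(n, len(harmonics))) / harmonics,
        "g_phase": rng.uniform(0, 2 * np.pi, size=(n, len(harmonics))),
        "ff_amp": cfg.boundary_noise * rng.lognormal(0.0, 0.4, size=n),
    }


def _ellipse_form_factor(aspect: float) -> float:
    """Analytic form factor of an ellipse with the given axis ratio."""
    a, b = aspect, 1.0
    h = ((a - b) / (a + b)) ** 2
    perim = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    return 4 * math.pi * (math.pi * a * b) / perim**2


def _boundary_profile(g_amp: np.ndarray, g_phase: np.ndarray,
                      n_angles: int = 96):
    """Smooth periodic radial noise profile g(phi), unit-SD, zero mean."""
    phi = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    g = np.zeros(n_angles)
    for k, (amp, ph) in enumerate(zip(g_amp, g_phase), start=2):
        g += amp * np.cos(k * phi + ph)
    sd = g.std()
    if sd > 0:
        g /= sd
    return phi, g


def _tabular_frame(cfg: CohortConfig, params: dict, field_id: str,
                   case_id: str, condition: str) -> pd.DataFrame:
    """Feature-level view of a field: the case's shared draws, no geometry.

    The contour-noise effect on roundness enters through the per-nucleus
    effective amplitude with a quadratic penalty fitted to the renderer.
    """
    n = len(params["sizes"])
    center = cfg.field_diameter_px / 2.0
    base_ff = np.array([_ellipse_form_factor(a) for a in params["aspects"]])
    ff = np.minimum(base_ff / (1 + 14.0 * params["ff_amp"]**2), 1.0)
    return pd.DataFrame({
        "field_id": field_id, "case_id": case_id, "condition": condition,
        "label": np.arange(1, n + 1),
        "centroid_row": np.full(n, center),
        "centroid_col": np.full(n, center),
        "size_px": np.maximum(np.round(params["sizes"]).astype(int), 1),
        "hyperchromasia": params["greys"],
        "heterochromasia": params["textures"],
        "roundness": ff,
    })


def _render_field(cfg: CohortConfig, params: dict, field_id: str,
                  case_id: str, condition: str, rng: np.random.Generator):
    """Paint one field's rasters from the case's shared nucleus draws.

    Placement and pixel noise are field-specific (``rng``); the reported
    feature table carries the *measured* values computed from the painted
    pixels, which is exactly what morphometry on the written rasters will
    recover.
    """
    sizes = params["sizes"]
    greys = params["greys"]
    textures = params["textures"]
    aspects = params["aspects"]
    angles = params["angles"]
    n = len(sizes)

    D = cfg.field_diameter_px
    R = D / 2.0 - 2
    center = (D / 2.0, D / 2.0)

    rows = []
    labels = np.zeros((D, D), dtype=np.uint16)
    intensity = np.clip(rng.normal(cfg.background_grey, cfg.background_sd,
                                   size=(D, D)), 0, 255).astype(np.uint8)

    # place nuclei without overlap; generous margins keep neighbouring
    # dwell clusters well beyond the I-DT dispersion threshold
    placed = []  # (row, col, bounding_radius)
    for i in range(n):
        area = sizes[i]
        b_ax = math.sqrt(area / (math.pi * aspects[i]))
        a_ax = aspects[i] * b_ax
        rb = a_ax * (1 + 3.5 * cfg.boundary_noise) + 2
        pos = None
        for _ in range(200):
            rr = R - rb - 4
            if rr <= 0:
                break
            u = rng.uniform(0, 1)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rr * math.sqrt(u)
            cand = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
            if all((cand[0] - p[0])**2 + (cand[1] - p[1])**2 >= (rb + p[2] + 6)**2
                   for p in placed):
                pos = cand
                break
        if pos is None:
            log.info("field %s: could not place nucleus %d; skipped", field_id, i)
            continue
        placed.append((pos[0], pos[1], rb))
        label = len(placed)

        phi, g = _boundary_profile(params["g_amp"][i], params["g_phase"][i])
        # radial contour of a rotated ellipse, multiplicatively perturbed
        r_ell = (a_ax * b_ax) / np.sqrt((b_ax * np.cos(phi - angles[i]))**2
                                        + (a_ax * np.sin(phi - angles[i]))**2)
        r_prof = r_ell * np.clip(1 + cfg.boundary_noise * g, 0.3, None)

        rr_poly = pos[0] + r_prof * np.sin(phi)
        cc_poly = pos[1] + r_prof * np.cos(phi)
        pr, pc = skdraw.polygon(rr_poly, cc_poly, shape=labels.shape)
        keep = labels[pr, pc] == 0
        pr, pc = pr[keep], pc[keep]
        if pr.size < 4:
            placed.pop()
            continue
        labels[pr, pc] = label
        pix = np.clip(rng.normal(greys[i], textures[i], size=pr.size),
                      0, 255).astype(np.uint8)
        intensity[pr, pc] = pix
        mask = np.zeros(labels.shape, bool)
        mask[pr, pc] = True
        sl = (slice(pr.min(), pr.max() + 1), slice(pc.min(), pc.max() + 1))
        fv = FeatureVector(
            size_px=int(pr.size),
            hyperchromasia=float(pix.mean()),
            heterochromasia=float(pix.std(ddof=0)),
            roundness=form_factor(mask[sl]),
        )
        cr, cc_ = float(pr.mean()), float(pc.mean())
        rows.append({
            "field_id": field_id, "case_id": case_id, "condition": condition,
            "label": label, "centroid_row": cr, "centroid_col": cc_,
            **fv.as_dict(),
        })

    frame = pd.DataFrame(rows)
    lf = LabeledField(intensity=intensity, labels=labels,
                      field_id=field_id, condition=condition,
                      case_id=case_id,
                      circle=(center[0], center[1], R))
    return frame, lf


def generate_field(cfg: CohortConfig, case_id: str, condition: str,
                   rng: np.random.Generator,
                   case_size_mult: float = 1.0,
                   case_grey_off: float = 0.0):
    """Render one labeled field; returns ``(LabeledField, records)``.

    Convenience wrapper used by tests and the CLI for single fields; cohort
    generation goes through :func:`simulate_cohort`.
    """
    field_id = f"{case_id}_{'tub' if condition == 'tubular' else 'sol'}"
    params = _sample_nucleus_params(cfg, rng, case_size_mult, case_grey_off)
    frame, lf = _render_field(cfg, params, field_id, case_id, condition, rng)
    records = [NucleusRecord(field_id, int(r.label),
                             (r.centroid_row, r.centroid_col),
                             FeatureVector(r.size_px, r.hyperchromasia,
                                           r.heterochromasia, r.roundness))
               for r in frame.itertuples(index=False)]
    return lf, records


# --------------------------------------------------------------------------
# fixation-target selection

def select_fixated(cfg: CohortConfig, nuclei: pd.DataFrame, condition: str,
                   rng: np.random.Generator) -> list[int]:
    """Sample the set of nucleus labels a rater fixates in one trial.

    Sampling is without replacement with probability proportional to
    ``exp(tilt * z)`` where ``z`` is the composite atypia z-score of the
    nucleus (selection weights over feature z-scores, unit-normalized) and
    ``tilt`` is ``+selection_strength`` under solid, ``-`` under tubular.
    """
    w = dict(cfg.selection_weights)
    norm = math.sqrt(sum(v * v for v in w.values()))
    means = cfg.feature_means()
    scales = cfg.feature_scales()
    z = np.zeros(len(nuclei))
    if norm > 0:
        for name, wf in w.items():
            if wf == 0:
                continue
            z += (wf / norm) * ((nuclei[name].to_numpy() - means[name])
                                / scales[name])
    tilt = cfg.selection_strength if condition == "solid" else -cfg.selection_strength
    logits = tilt * z
    p = np.exp(logits - logits.max())
    p /= p.sum()
    k = min(cfg.fixations_per_trial, len(nuclei))
    idx = rng.choice(len(nuclei), size=k, replace=False, p=p)
    return sorted(int(nuclei["label"].iloc[i]) for i in idx)


# --------------------------------------------------------------------------
# gaze synthesis (rendered mode)

def simulate_gaze(cfg: CohortConfig, field_nuclei: pd.DataFrame,
                  fixated: Sequence[int], rater_id: str, field_id: str,
                  rng: np.random.Generator) -> GazeStream:
    """Synthesize a 50 Hz gaze stream that fixates the given nuclei.

    Each target contributes a dwell of 7–15 jittered samples around its
    centroid (>= 140 ms, comfortably above the 100 ms detection floor);
    consecutive dwells are bridged by linearly interpolated saccade
    samples. Nuclei never overlap and centers sit well apart, so each
    dwell survives dispersion-threshold detection as one fixation on its
    own nucleus.
    """
    interval = 1000.0 / cfg.sampling_hz
    cent = field_nuclei.set_index("label")
    order = list(fixated)
    rng.shuffle(order)
    xs: list[float] = []
    ys: list[float] = []
    max_samples = int(cfg.trial_duration_ms / interval)
    prev = None
    for label in order:
        row = cent.loc[label]
        cy, cx = float(row["centroid_row"]), float(row["centroid_col"])
        n_fix = int(rng.integers(*cfg.fixation_samples_range))
        if prev is not None:
            for s in range(1, cfg.saccade_samples + 1):
                f = s / (cfg.saccade_samples + 1)
                xs.append(prev[0] + f * (cx - prev[0]))
                ys.append(prev[1] + f * (cy - prev[1]))
        xs.extend(cx + rng.normal(0, cfg.jitter_px, n_fix))
        ys.extend(cy + rng.normal(0, cfg.jitter_px, n_fix))
        prev = (cx, cy)
        if len(xs) >= max_samples:
            break
    xs = xs[:max_samples]
    ys = ys[:max_samples]
    t = np.arange(len(xs)) * interval
    return GazeStream(rater_id=rater_id, field_id=field_id,
                      t_ms=t, x_px=np.array(xs), y_px=np.array(ys),
                      valid=np.ones(len(xs), bool))


# --------------------------------------------------------------------------
# grading

def round_half_step(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest 0.5; ties at .25 round up (1.25 -> 1.5)."""
    return np.floor(np.asarray(x, dtype=float) * 2 + 0.5) / 2


def _finish_grade(cfg: CohortConfig, latent):
    g = np.asarray(latent, dtype=float)
    if cfg.half_step:
        g = round_half_step(g)
    lo, hi = cfg.grade_clamp
    return np.clip(g, lo, hi)


def simulate_grade(cfg: CohortConfig, rater: RaterTruth,
                   feature_mean: float | None, direct_offset: float,
                   rng: np.random.Generator) -> float:
    """One grade from the rater's linear rule (see module docstring)."""
    latent = rater.intercept + direct_offset
    if rater.preferred_feature is not None and feature_mean is not None:
        latent += rater.slope * feature_mean
    latent += rng.normal(0, cfg.grade_noise_sd) if cfg.grade_noise_sd > 0 else 0.0
    return float(_finish_grade(cfg, latent))


# --------------------------------------------------------------------------
# cohort assembly

def _make_raters(cfg: CohortConfig, seed: int) -> list[RaterTruth]:
    prefs = cfg.preferences()
    means = cfg.feature_means()
    scales = cfg.feature_scales()
    raters = []
    for i in range(cfg.n_raters):
        rng = _rng(seed, _RATER, i)
        rid = f"r{i:02d}"
        pref = prefs[i]
        if pref is None:
            slope = 0.0
            intercept = cfg.intercept_target
        else:
            base = ATYPIA_SIGN[pref] * cfg.coupling / scales[pref]
            mult = (rng.lognormal(-cfg.rater_slope_cv**2 / 2, cfg.rater_slope_cv)
                    if cfg.rater_slope_cv > 0 else 1.0)
            slope = base * mult
            intercept = cfg.intercept_target - slope * means[pref]
        if cfg.rater_intercept_sd > 0:
            intercept += rng.normal(0, cfg.rater_intercept_sd)
        group = GROUP_PATTERN[i % len(GROUP_PATTERN)]
        raters.append(RaterTruth(
            rater_id=rid, preferred_feature=pref, slope=slope,
            intercept=intercept, rater_group=group,
            prostate_reader=(group == "senior_faculty")))
    return raters


def _case_meta(cfg: CohortConfig, i: int) -> dict:
    cls = "gt_1_5" if i % 2 == 0 else "eq_1_5"
    mod = cfg.gleason_modulation if cls == "gt_1_5" else -cfg.gleason_modulation
    return {"case_id": f"case{i:02d}", "gleason_delta_class": cls,
            "direct_offset": cfg.grade_bias_delta * (1 + mod)}


def simulate_cohort(cfg: CohortConfig, seed: int,
                    render: bool = False) -> SyntheticCohort:
    """Generate the full experiment under a single cohort seed."""
    raters = _make_raters(cfg, seed)
    cases = [_case_meta(cfg, i) for i in range(cfg.n_cases)]

    nuclei_frames = []
    fields_meta = []
    fields: dict = {}
    matrix_labels: dict = {}
    matrix_means: dict = {}
    for ci, case in enumerate(cases):
        crng = _rng(seed, _CASE, ci)
        size_mult = (crng.lognormal(-cfg.case_size_cv**2 / 2, cfg.case_size_cv)
                     if cfg.case_size_cv > 0 else 1.0)
        grey_off = (crng.normal(0, cfg.case_grey_sd)
                    if cfg.case_grey_sd > 0 else 0.0)
        params = _sample_nucleus_params(cfg, crng, size_mult, grey_off)
        for condi, cond in enumerate(CONDITIONS):
            field_id = f"{case['case_id']}_{'tub' if cond == 'tubular' else 'sol'}"
            if render:
                frng = _rng(seed, _FIELD, ci, condi)
                frame, lf = _render_field(cfg, params, field_id,
                                          case["case_id"], cond, frng)
            else:
                frame = _tabular_frame(cfg, params, field_id,
                                       case["case_id"], cond)
                lf = None
            if frame.empty:
                raise InputError(f"field {field_id}: no nuclei generated")
            nuclei_frames.append(frame)
            if lf is not None:
                lf.gleason_delta_class = case["gleason_delta_class"]
                fields[field_id] = lf
            D = cfg.field_diameter_px
            fields_meta.append({
                "field_id": field_id, "case_id": case["case_id"],
                "condition": cond,
                "gleason_delta_class": case["gleason_delta_class"],
                "circle_row": D / 2.0, "circle_col": D / 2.0,
                "circle_radius": D / 2.0 - 2,
            })
            mrng = _rng(seed, _MATRIX, ci, CONDITIONS.index(cond))
            k = min(cfg.matrix_nuclei, len(frame))
            sel = mrng.choice(len(frame), size=k, replace=False)
            labels_sel = sorted(int(frame["label"].iloc[j]) for j in sel)
            matrix_labels[field_id] = labels_sel
            sub = frame[frame["label"].isin(labels_sel)]
            matrix_means[field_id] = {f: float(sub[f].mean())
                                      for f in FEATURE_NAMES}

    nuclei = pd.concat(nuclei_frames, ignore_index=True)
    fields_meta = pd.DataFrame(fields_meta)

    grades_rows = []
    matrix_rows = []
    fixated_rows = []
    fixated_labels: dict = {}
    gaze: dict = {}
    by_field = {fid: g for fid, g in nuclei.groupby("field_id")}
    for ri, rater in enumerate(raters):
        for ci, case in enumerate(cases):
            for condi, cond in enumerate(CONDITIONS):
                field_id = (f"{case['case_id']}_"
                            f"{'tub' if cond == 'tubular' else 'sol'}")
                trng = _rng(seed, _TRIAL, ri, ci, condi)
                fn = by_field[field_id]
                chosen = select_fixated(cfg, fn, cond, trng)
                fixated_labels[(rater.rater_id, field_id)] = chosen
                sub = fn[fn["label"].isin(chosen)]
                fmeans = {f: float(sub[f].mean()) for f in FEATURE_NAMES}
                if render:
                    gaze[(rater.rater_id, field_id)] = simulate_gaze(
                        cfg, fn, chosen, rater.rater_id, field_id, trng)
                pref_mean = (fmeans[rater.preferred_feature]
                             if rater.preferred_feature else None)
                grade = simulate_grade(cfg, rater, pref_mean,
                                       case["direct_offset"] if cond == "solid"
                                       else 0.0, trng)
                grades_rows.append({
                    "rater_id": rater.rater_id, "case_id": case["case_id"],
                    "field_id": field_id, "condition": cond, "grade": grade,
                    "rater_group": rater.rater_group,
                    "prostate_reader": rater.prostate_reader,
                    "gleason_delta_class": case["gleason_delta_class"],
                })
                fixated_rows.append({
                    "rater_id": rater.rater_id, "field_id": field_id,
                    "case_id": case["case_id"], "condition": cond,
                    "n_fixated": len(chosen), **fmeans,
                })
                mm = matrix_means[field_id]
                mpref = (mm[rater.preferred_feature]
                         if rater.preferred_feature else None)
                mgrade = simulate_grade(cfg, rater, mpref, 0.0, trng)
                matrix_rows.append({
                    "rater_id": rater.rater_id, "field_id": field_id,
                    "grade": mgrade, **mm,
                })

    truth = GroundTruth(
        raters=pd.DataFrame([vars(r) for r in raters]),
        cases=pd.DataFrame(cases),
        nuclei=nuclei,
        fixated_labels=fixated_labels,
        matrix_labels=matrix_labels,
        config=cfg,
    )
    return SyntheticCohort(
        cfg=cfg, seed=seed,
        fields_meta=fields_meta, nuclei=nuclei,
        grades=pd.DataFrame(grades_rows),
        matrix_trials=pd.DataFrame(matrix_rows),
        fixated=pd.DataFrame(fixated_rows),
        truth=truth, fields=fields, gaze=gaze,
    )
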