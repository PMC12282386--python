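"""Synthetic cohort generation: labelled pullback curves plus covariates.

The source angiographic data are not public, so every downstream stage is
exercised on synthetic vessels built from the field's morphological
definitions: a *focal* lesion is a single abrupt pressure drop (≥ 0.05)
confined to a short segment (≤ 20 mm); *serial* disease is two or more
such drops separated by > 20 mm of healthy vessel; *diffuse* disease is a
gradual vessel-wide decline with no discrete lesion; *mixed* disease is a
discrete lesion superimposed on a diffuse decline.

Default class proportions and covariate marginals follow the reference
population: 343 vessels splitting 160 focal / 74 diffuse / 82 mixed / 27
serial, with class-conditional age, sex, smoking and comorbidity rates.
An eight-rater consensus-labelling emulator reproduces the adjudication
protocol (label adopted when ≥ 5 of 8 raters agree, otherwise a second
round resolved here as convergence to ground truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .curves import (
    DEFAULT_SPACING_MM,
    PATTERNS,
    PullbackCurve,
    VesselRecord,
    _interp_to_grid,
    resample_curve,
)

# ---------------------------------------------------------------------------
# reference-population defaults (counts per pattern class)

#: class proportions of the 343-vessel reference population
CLASS_PROBS = {
    "focal": 160 / 343,
    "diffuse": 74 / 343,
    "mixed": 82 / 343,
    "serial": 27 / 343,
}

#: class-conditional age mean ± sd (years)
AGE_BY_CLASS = {
    "focal": (58.0, 13.0),
    "diffuse": (68.0, 11.0),
    "mixed": (64.0, 12.0),
    "serial": (61.0, 12.0),
}

#: class-conditional probability of male sex
MALE_BY_CLASS = {
    "focal": 144 / 160,
    "diffuse": 53 / 74,
    "mixed": 61 / 82,
    "serial": 25 / 27,
}

#: class-conditional smoking-status probabilities (non, current, previous)
SMOKING_BY_CLASS = {
    "focal": (66 / 160, 71 / 160, 23 / 160),
    "diffuse": (42 / 74, 31 / 74, 1 / 74),
    "mixed": (34 / 82, 40 / 82, 8 / 82),
    "serial": (11 / 27, 12 / 27, 4 / 27),
}

#: class-conditional comorbidity probabilities
HYPERTENSION_BY_CLASS = {"focal": 95 / 160, "diffuse": 60 / 74, "mixed": 60 / 82, "serial": 23 / 27}
DIABETES_BY_CLASS = {"focal": 25 / 160, "diffuse": 18 / 74, "mixed": 27 / 82, "serial": 3 / 27}
DYSLIPIDAEMIA_BY_CLASS = {"focal": 103 / 160, "diffuse": 53 / 74, "mixed": 62 / 82, "serial": 19 / 27}

#: proximal reference diameter marginal, mean ± sd (mm), truncated positive
REFERENCE_DIAMETER = (3.61, 0.66)

SMOKING_LEVELS = ("non", "current", "previous")

# width parameter of the logistic lesion profile: the stated width contains
# 90% of the drop, so w = 4 * atanh(0.9) * tau
_W_TO_TAU = 1.0 / (4.0 * math.atanh(0.9))


@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and risk-factor covariates for one patient."""

    age: float
    sex: str
    smoking: str
    hypertension: bool
    diabetes: bool
    dyslipidaemia: bool

    def __post_init__(self):
        if not (18.0 <= self.age <= 100.0):
            raise ValueError("age must lie in [18, 100]")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"smoking must be one of {SMOKING_LEVELS}")


@dataclass(frozen=True)
class PatternParams:
    """Morphological parameters of one synthetic vessel.

    Lesions are logistic (sigmoid) pressure-drop profiles: ``lesion_widths``
    is the distance containing 90% of each drop.  ``diffuse_slope`` is the
    linear vessel-wide pressure-loss rate (per mm).
    """

    pattern: str
    vessel_length: float
    lesion_positions: Sequence[float] = ()
    lesion_drops: Sequence[float] = ()
    lesion_widths: Sequence[float] = ()
    diffuse_slope: float = 0.0
    noise_sd: float = 0.005
    taper_rate: float = 0.001
    prox_diameter: float = 3.6

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.vessel_length <= 0:
            raise ValueError("vessel_length must be > 0")
        n = len(self.lesion_positions)
        if len(self.lesion_drops) != n or len(self.lesion_widths) != n:
            raise ValueError("lesion position/drop/width lists must have equal length")
        if self.noise_sd < 0 or self.taper_rate < 0 or self.prox_diameter <= 0:
            raise ValueError("noise_sd/taper_rate must be >= 0, prox_diameter > 0")
        widths = np.asarray(self.lesion_widths, float)
        drops = np.asarray(self.lesion_drops, float)
        if self.pattern == "focal":
            if n != 1 or widths[0] > 20 or drops[0] < 0.05:
                raise ValueError(
                    "focal pattern needs exactly one lesion with width <= 20 mm and drop >= 0.05"
                )
        elif self.pattern == "serial":
            if n < 2 or np.any(widths > 20):
                raise ValueError("serial pattern needs >= 2 lesions with widths <= 20 mm")
            order = np.argsort(self.lesion_positions)
            pos = np.asarray(self.lesion_positions, float)[order]
            w = widths[order]
            gaps = (pos[1:] - w[1:] / 2) - (pos[:-1] + w[:-1] / 2)
            if np.any(gaps <= 20):
                raise ValueError("serial lesions must be separated by > 20 mm of healthy segment")
        elif self.pattern == "diffuse":
            if n != 0 or self.diffuse_slope <= 0:
                raise ValueError("diffuse pattern needs no discrete lesion and diffuse_slope > 0")
        elif self.pattern == "mixed":
            if n < 1 or self.diffuse_slope <= 0:
                raise ValueError("mixed pattern needs >= 1 lesion and diffuse_slope > 0")


@dataclass
class Cohort:
    """A simulated cohort: vessel records plus per-patient covariates."""

    records: list[VesselRecord]
    covariates: dict[str, PatientCovariates]
    truth: dict[str, str] = field(default_factory=dict)
    consensus_rounds: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.records)


def _smooth_noise(n: int, sd: float, rng: np.random.Generator, window: int = 41) -> np.ndarray:
    """Moving-average-filtered white noise, pinned to zero at both endpoints."""
    if sd == 0 or n < 3:
        return np.zeros(n)
    raw = rng.standard_normal(n + window - 1)
    smooth = np.convolve(raw, np.ones(window) / window, mode="valid")
    smooth = smooth / (np.std(smooth) + 1e-12) * sd
    # remove the linear ramp so the proximal/distal endpoints stay exact
    ramp = smooth[0] + (smooth[-1] - smooth[0]) * np.linspace(0, 1, n)
    return smooth - ramp


def _drop_profile(s: np.ndarray, params: PatternParams) -> np.ndarray:
    """Cumulative pressure loss along the vessel (before noise)."""
    drop = params.diffuse_slope * s
    for c, d, w in zip(params.lesion_positions, params.lesion_drops, params.lesion_widths):
        tau = max(w * _W_TO_TAU, 1e-6)
        drop = drop + d / (1.0 + np.exp(-(s - c) / tau))
    return drop


def _narrowing_profile(s: np.ndarray, params: PatternParams) -> np.ndarray:
    """Fractional lumen narrowing (0 = healthy) driving the MLD curve."""
    narrow = np.zeros_like(s)
    for c, d, w in zip(params.lesion_positions, params.lesion_drops, params.lesion_widths):
        depth = 0.25 + 0.5 * min(d / 0.5, 1.0)
        narrow = narrow + depth * np.exp(-(((s - c) / (w / 2.0)) ** 2))
    if params.diffuse_slope > 0:
        total = params.diffuse_slope * params.vessel_length
        narrow = narrow + 0.35 * min(total / 0.4, 1.0)
    return np.clip(narrow, 0.0, 0.85)


def simulate_vessel(
    params: PatternParams,
    rng_seed: int,
    vessel_id: str = "V0",
    patient_id: str = "P0",
) -> VesselRecord:
    """Simulate one vessel record from morphological parameters.

    The μFR curve is 1.0 minus the summed sigmoidal lesion drops and the
    linear diffuse decline, plus smooth bounded noise, clipped to [0, 1]
    and resampled at 0.35 mm.  Drops are rescaled upward if needed so the
    distal μFR is at most 0.95 (vessels above 0.95 would be excluded as
    free of functional disease).  The RVD tapers linearly from the
    proximal diameter; the MLD is the RVD scaled down inside lesions.
    """
    rng = np.random.default_rng(rng_seed)
    L = params.vessel_length
    fine = np.arange(0.0, L + 1e-9, 0.05)
    drop = _drop_profile(fine, params)
    # the resampled 0.35-mm grid ends at the last full step, so the distal
    # guarantee must hold there, not at the raw vessel end
    s_last = DEFAULT_SPACING_MM * math.floor(L / DEFAULT_SPACING_MM + 1e-9)
    idx_last = int(round(s_last / 0.05))
    total_drop = drop[idx_last]
    if total_drop < 0.05:
        # guarantee distal μFR <= 0.95 by construction
        drop = drop * (0.05 / max(total_drop, 1e-12))
    mufr = 1.0 - drop + _smooth_noise(fine.size, params.noise_sd, rng)
    mufr = np.clip(mufr, 0.0, 1.0)

    rvd = params.prox_diameter * np.clip(1.0 - params.taper_rate * fine, 0.4, 1.0)
    mld = np.maximum(rvd * (1.0 - _narrowing_profile(fine, params)), 0.3)

    curve = resample_curve(fine, mufr)
    grid, mld_g = _interp_to_grid(fine, mld, curve.spacing)
    _, rvd_g = _interp_to_grid(fine, rvd, curve.spacing)
    curve = PullbackCurve(positions=curve.positions, mufr=curve.mufr, mld=mld_g, rvd=rvd_g)

    return VesselRecord(
        vessel_id=vessel_id,
        patient_id=patient_id,
        curve=curve,
        distal_mufr=float(curve.mufr[-1]),
        reference_diameter=float(params.prox_diameter),
        label=params.pattern,
    )


def _truncnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_pattern_params(pattern: str, rng: np.random.Generator) -> PatternParams:
    """Draw morphological parameters for one vessel of the given pattern.

    Vessel lengths are uniform on 40–120 mm (60–120 mm for serial disease,
    which needs room for two separated lesions); lesion drops and diffuse
    declines are truncated normals chosen so the distal μFR marginals per
    class resemble the reference population (≈ 0.71 focal, 0.82 diffuse,
    0.74 mixed, 0.68 serial).
    """
    prox = _truncnorm(rng, *REFERENCE_DIAMETER, 1.5, 6.0)
    taper = rng.uniform(0.0005, 0.002)
    if pattern == "focal":
        L = rng.uniform(40, 120)
        w = rng.uniform(5, 18)
        c = rng.uniform(0.15 * L, 0.85 * L)
        d = _truncnorm(rng, 0.29, 0.16, 0.05, 0.85)
        return PatternParams(pattern, L, [c], [d], [w], 0.0, 0.005, taper, prox)
    if pattern == "diffuse":
        L = rng.uniform(40, 120)
        total = _truncnorm(rng, 0.18, 0.08, 0.05, 0.60)
        return PatternParams(pattern, L, (), (), (), total / L, 0.005, taper, prox)
    if pattern == "mixed":
        L = rng.uniform(40, 120)
        w = rng.uniform(5, 18)
        c = rng.uniform(0.15 * L, 0.85 * L)
        d = _truncnorm(rng, 0.14, 0.07, 0.05, 0.50)
        diffuse_total = _truncnorm(rng, 0.12, 0.06, 0.02, 0.40)
        return PatternParams(pattern, L, [c], [d], [w], diffuse_total / L, 0.005, taper, prox)
    if pattern == "serial":
        L = rng.uniform(60, 120)
        w1, w2 = rng.uniform(4, 10, size=2)
        # two lesions near the quarter points; the mid-vessel gap exceeds 20 mm
        c1 = rng.uniform(0.12 * L, 0.22 * L)
        c2 = rng.uniform(0.72 * L, 0.85 * L)
        d1 = _truncnorm(rng, 0.16, 0.08, 0.05, 0.50)
        d2 = _truncnorm(rng, 0.16, 0.08, 0.05, 0.50)
        return PatternParams(pattern, L, [c1, c2], [d1, d2], [w1, w2], 0.0, 0.005, taper, prox)
    raise ValueError(f"unknown pattern {pattern!r}")


def _sample_covariates(pattern: str, rng: np.random.Generator, age_by_class=None) -> PatientCovariates:
    mean, sd = (age_by_class or AGE_BY_CLASS)[pattern]
    return PatientCovariates(
        age=_truncnorm(rng, mean, sd, 18, 100),
        sex="male" if rng.random() < MALE_BY_CLASS[pattern] else "female",
        smoking=SMOKING_LEVELS[rng.choice(3, p=SMOKING_BY_CLASS[pattern])],
        hypertension=bool(rng.random() < HYPERTENSION_BY_CLASS[pattern]),
        diabetes=bool(rng.random() < DIABETES_BY_CLASS[pattern]),
        dyslipidaemia=bool(rng.random() < DYSLIPIDAEMIA_BY_CLASS[pattern]),
    )


def simulate_votes(truth: str, error_rate: float, rng: np.random.Generator) -> list[str]:
    """Eight independent rater votes: truth with probability 1 − error_rate,
    otherwise an adjacent-confusable class (mixed is the confusion hub)."""
    votes = []
    others = [p for p in PATTERNS if p != truth]
    for _ in range(8):
        if rng.random() >= error_rate:
            votes.append(truth)
        elif truth == "mixed":
            votes.append(others[rng.choice(len(others))])
        elif rng.random() < 0.8:
            votes.append("mixed")
        else:
            non_mixed = [p for p in others if p != "mixed"]
            votes.append(non_mixed[rng.choice(len(non_mixed))])
    return votes


def consensus_label(votes: Sequence[str], truth: str) -> tuple[str, str]:
    """Resolve eight rater votes into a consensus label.

    At least 5/8 concordant votes adopt that pattern (round ``first_full``
    when unanimous, else ``first_partial``); otherwise the vessel goes to a
    second adjudication stage, emulated as convergence to the ground truth.
    """
    if len(votes) != 8:
        raise ValueError("exactly 8 votes are required")
    labels, counts = np.unique(list(votes), return_counts=True)
    top = int(counts.max())
    if top >= 5:
        winner = str(labels[int(np.argmax(counts))])
        return winner, ("first_full" if top == 8 else "first_partial")
    return truth, "second"


def simulate_cohort(
    n_vessels: int,
    class_probs: Optional[dict[str, float]] = None,
    covariate_model: Optional[dict] = None,
    rng_seed: int = 0,
    rater_error: float = 0.1,
    apply_consensus: bool = True,
) -> Cohort:
    """Simulate a labelled cohort of vessels with one patient per vessel.

    Pattern classes are drawn i.i.d. at ``class_probs`` (default: the
    343-vessel reference proportions); covariates come from the
    class-conditional marginals (overridable per-key via
    ``covariate_model``).  When ``apply_consensus`` is set, each vessel's
    label is produced by the eight-rater consensus emulator with per-rater
    error ``rater_error``; ground truth is kept in ``Cohort.truth``.
    Identical seeds yield identical cohorts.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    probs = dict(CLASS_PROBS if class_probs is None else class_probs)
    p = np.array([probs[k] for k in PATTERNS], float)
    if abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
        raise ValueError("class_probs must be a probability vector over the four patterns")

    age_by_class = dict(AGE_BY_CLASS)
    if covariate_model and "age" in covariate_model:
        age_by_class = dict(covariate_model["age"])

    rng = np.random.default_rng(rng_seed)
    records, covariates, truth, rounds = [], {}, {}, {}
    for i in range(n_vessels):
        pattern = PATTERNS[rng.choice(4, p=p)]
        params = sample_pattern_params(pattern, rng)
        seed = int(rng.integers(2**31))
        vid, pid = f"V{i:04d}", f"P{i:04d}"
        rec = simulate_vessel(params, seed, vessel_id=vid, patient_id=pid)
        truth[vid] = pattern
        if apply_consensus:
            votes = simulate_votes(pattern, rater_error, rng)
            label, rnd = consensus_label(votes, pattern)
            rounds[vid] = rnd
        else:
            label = pattern
        records.append(
            VesselRecord(
                vessel_id=vid,
                patient_id=pid,
                curve=rec.curve,
                distal_mufr=rec.distal_mufr,
                reference_diameter=rec.reference_diameter,
                label=label,
            )
        )
        covariates[pid] = _sample_covariates(pattern, rng, age_by_class)
    return Cohort(records=records, covariates=covariates, truth=truth, consensus_rounds=rounds)
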