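"""Synthetic cohorts and lifting-motion time series.

The generator emulates the statistical structure of a patient-lifting
motion-capture study: 44 healthcare workers (16 men, 28 women; age 28 ± 12
years, height 175.11 ± 11.58 cm, weight 75.30 ± 12.58 kg) each performing
three lifting scenarios — patient not assisting, patient assisting, and
lifting with an ergonomic belt — three trials per scenario, with joint angle
and net joint moment recorded for the neck (midline) and both shoulders and
elbows.

Motion profiles are simple parametric curves, not biomechanical simulation:
each trial starts and ends in the neutral standing pose, the angle follows a
half-sine excursion and the moment a sine-squared bell whose peak scales
with body weight.  Only the *ratio structure* of the features matters to the
downstream risk model, and that structure is injected explicitly through
:class:`EffectSpec` multipliers (male range-of-motion, belt moment
reduction, readiness-group moment scaling, left/right asymmetry) plus
multiplicative trial noise.  Effect sizes have no published reference
values; the defaults are order-of-magnitude choices and labeled as such.

Randomness is fully deterministic: every subject draws from an independent
stream spawned from the top-level seed, so growing the cohort never
reshuffles existing subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import InvalidInputError
from .features import (
    SCENARIOS,
    MotionTrial,
    extract_features,
    trials_to_frame,
)
from .pipeline import SubjectRecord

#: (joint, sides, ROM amplitude deg, peak moment per kg body weight)
JOINT_PROFILES = {
    "neck": (("midline",), 40.0, 0.13),
    "shoulder": (("left", "right"), 85.0, 0.60),
    "elbow": (("left", "right"), 65.0, 0.27),
}

#: Triangular readiness-score weights over 1..10, peaking at 7.
_READINESS_WEIGHTS = np.array([1, 2, 3, 4, 5, 6, 7, 6, 5, 4], dtype=float)
DEFAULT_READINESS_DISTRIBUTION = tuple(_READINESS_WEIGHTS / _READINESS_WEIGHTS.sum())


@dataclass(frozen=True)
class CohortSpec:
    """Cohort demographics; defaults match the reference study design."""

    n_subjects: int = 44
    male_fraction: float = 16 / 44
    age_mean: float = 28.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (18.0, 70.0)
    height_mean: float = 175.11
    height_sd: float = 11.58
    weight_mean: float = 75.30
    weight_sd: float = 12.58
    readiness_distribution: Sequence[float] = DEFAULT_READINESS_DISTRIBUTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        for name in ("age_sd", "height_sd", "weight_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        probs = np.asarray(self.readiness_distribution, dtype=float)
        if len(probs) != 10 or abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                "readiness_distribution must have 10 entries summing to 1"
            )
        object.__setattr__(self, "readiness_distribution", tuple(probs))


@dataclass(frozen=True)
class EffectSpec:
    """Injected effect sizes and noise for trial generation.

    The multipliers are the generator's ground truth: downstream
    segment-to-population likelihood estimates should recover them (up to
    sampling error), which is how the pipeline is validated end to end.
    """

    male_rom_multiplier: float = 1.1
    belt_moment_multiplier: float = 0.9
    assist_moment_multiplier: float = 0.95
    readiness_moment_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.05, "medium": 1.0, "high": 0.95}
    )
    right_left_moment_ratio: float = 1.08
    trial_noise_cv: float = 0.05
    trials_per_scenario: int = 3
    trial_duration_s: float = 4.0
    sample_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        for name in ("male_rom_multiplier", "belt_moment_multiplier",
                     "assist_moment_multiplier", "right_left_moment_ratio"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if any(m <= 0 for m in self.readiness_moment_multipliers.values()):
            raise InvalidInputError("readiness multipliers must be > 0")
        if self.trial_noise_cv < 0:
            raise InvalidInputError("trial_noise_cv must be >= 0")
        if self.trials_per_scenario < 1:
            raise InvalidInputError("trials_per_scenario must be >= 1")
        object.__setattr__(
            self, "readiness_moment_multipliers",
            dict(self.readiness_moment_multipliers),
        )

    def scenario_moment_multiplier(self, scenario: str) -> float:
        if scenario == "belt":
            return self.belt_moment_multiplier
        if scenario == "patient_assist":
            return self.assist_moment_multiplier
        return 1.0


def _subject_stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(min(hi, max(lo, mean)))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(hi, max(lo, mean)))  # pathological spec; clamp


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[SubjectRecord]:
    """Deterministic synthetic cohort for a given spec.

    The male/female split is exact (not stochastically drawn) whenever
    ``n * male_fraction`` is an integer; otherwise the nearest split is used
    with a warning.
    """
    n = spec.n_subjects
    exact = n * spec.male_fraction
    n_male = round(exact)
    if abs(exact - n_male) > 1e-9:
        warnings.warn(
            f"male fraction {spec.male_fraction} of {n} is not an integer; "
            f"using nearest split {n_male}:{n - n_male}",
            UserWarning, stacklevel=2,
        )
    subjects = []
    for i in range(n):
        rng = _subject_stream(spec.seed, i)
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds)
        height = _truncated_normal(rng, spec.height_mean, spec.height_sd, 100.0, 230.0)
        weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, 35.0, 180.0)
        readiness = int(rng.choice(np.arange(1, 11), p=spec.readiness_distribution))
        subjects.append(SubjectRecord(
            id=f"S{i + 1:03d}",
            sex="male" if i < n_male else "female",
            age=age, height=height, weight=weight,
            readiness_score=readiness,
        ))
    return subjects


def generate_trials(
    subject: SubjectRecord,
    scenario: str,
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
) -> list[MotionTrial]:
    """Trials for one subject and scenario, all joints and sides.

    Angle: half-sine excursion from the neutral pose (range of motion equals
    the amplitude).  Moment: sine-squared bell with peak proportional to body
    weight, scaled by the scenario, sex-ROM, readiness and side multipliers,
    with multiplicative log-normal trial noise of the configured CV.
    """
    if scenario not in SCENARIOS:
        raise InvalidInputError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed), SCENARIOS.index(scenario)]))
    n_samples = int(round(effects.trial_duration_s * effects.sample_rate_hz)) + 1
    t = np.linspace(0.0, effects.trial_duration_s, n_samples)
    bell = np.sin(np.pi * t / effects.trial_duration_s)
    sex_rom = effects.male_rom_multiplier if subject.sex == "male" else 1.0
    ready = effects.readiness_moment_multipliers[subject.readiness_group]
    scen = effects.scenario_moment_multiplier(scenario)
    side_factor = {
        "midline": 1.0,
        "left": 1.0 / np.sqrt(effects.right_left_moment_ratio),
        "right": np.sqrt(effects.right_left_moment_ratio),
    }
    if effects.trial_noise_cv > 0:
        sigma = np.sqrt(np.log1p(effects.trial_noise_cv**2))
    else:
        sigma = 0.0

    trials = []
    for k in range(effects.trials_per_scenario):
        for joint, (sides, amp, moment_per_kg) in JOINT_PROFILES.items():
            for side in sides:
                eps_a = np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma else 1.0
                eps_m = np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma else 1.0
                amplitude = amp * sex_rom * eps_a
                peak = (moment_per_kg * subject.weight * ready * scen
                        * side_factor[side] * eps_m)
                trials.append(MotionTrial(
                    subject_id=subject.id, scenario=scenario, joint=joint,
                    side=side, trial=k,
                    time=t, angle=amplitude * bell, moment=peak * bell**2,
                ))
    return trials


def generate_cohort_trials(
    subjects: Sequence[SubjectRecord],
    effects: EffectSpec = EffectSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format trial frame for a whole cohort, one independent
    random stream per subject."""
    all_trials: list[MotionTrial] = []
    for i, s in enumerate(subjects):
        sub_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
                       % (2**31))
        for scenario in SCENARIOS:
            all_trials.extend(generate_trials(s, scenario, effects, seed=sub_seed))
    return trials_to_frame(all_trials)


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.id, "sex": s.sex, "age": s.age,
            "height_cm": s.height, "weight_kg": s.weight,
            "readiness_score": s.readiness_score,
        }
        if s.scenario_mix is not None:
            row["share_no_belt"] = s.scenario_mix.get("no_belt", 0.0)
            row["share_belt"] = s.scenario_mix.get("belt", 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_study(
    spec: CohortSpec | None = None,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (subjects, trials) frames for a full synthetic study."""
    spec = spec if spec is not None else CohortSpec()
    if seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "seed": int(seed)})
    effects = effects if effects is not None else EffectSpec()
    subjects = generate_cohort(spec)
    trials = generate_cohort_trials(subjects, effects, seed=spec.seed)
    return subjects_to_frame(subjects), trials


#: Generation settings of the committed reference fixture (kept tiny so the
#: files stay reviewable plain text).
REFERENCE_SPEC = dict(n_subjects=6, male_fraction=0.5)
REFERENCE_EFFECTS = dict(trials_per_scenario=1, trial_duration_s=2.0,
                         sample_rate_hz=5.0)


def generate_reference_bundle(out_dir, seed: int = 7) -> dict[str, Path]:
    """Write the small synthetic reference bundle (subjects, trials,
    expected features) to ``out_dir``; byte-identical for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=seed, **REFERENCE_SPEC)
    effects = EffectSpec(**REFERENCE_EFFECTS)
    subjects = generate_cohort(spec)
    trials = generate_cohort_trials(subjects, effects, seed=seed)
    paths = {
        "subjects": out / "subjects.csv",
        "trials": out / "trials.csv",
        "expected_features": out / "expected_features.csv",
    }
    subjects_to_frame(subjects).to_csv(paths["subjects"], index=False,
                                       float_format="%.6g")
    trials.to_csv(paths["trials"], index=False, float_format="%.6g")
    # features recomputed from the *written* trial precision, so the two
    # committed files are mutually consistent
    reread = pd.read_csv(paths["trials"])
    extract_features(reread).to_csv(paths["expected_features"], index=False,
                                    float_format="%.6g")
    return paths
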