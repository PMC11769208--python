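"""Subject-level risk assembly and the cohort model/results interface.

This module joins the three ingredients of the framework:

* a criteria table per region (weights + level likelihoods),
* the region's baseline age->probability curve, and
* per-subject demographics and motion features,

into per-subject risk profiles over forecast horizons (default 5/10/15
years), plus the cohort-level summaries built on them: mean +/- SD per
region and horizon, extreme-scenario bounds, the male/female risk gap, and
the share of risk variability attributable to the dynamic (motion-derived)
criteria.

The user-facing surface follows the fit/results idiom: build an
:class:`MSDRiskModel` from data, call :meth:`~MSDRiskModel.fit`, and read
everything off the returned :class:`MSDRiskResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .baseline import (
    BaselineCurve,
    evaluate_baseline,
    shift_curve,
)
from .core import (
    ClippingWarning,
    CriteriaTable,
    CriterionDef,
    CriterionKind,
    DegenerateInputError,
    ElementFactor,
    InvalidInputError,
    RiskInput,
    RoundingMode,
    blend_likelihoods,
    scenario_probability,
)
from .features import (
    LIKELIHOOD_BOUNDS,
    PARAMETRIC_METRICS,
    FeatureSet,
    derive_likelihood,
    composite_parametric_score,
    extract_features,
    feature_sets_from_frame,
    side_shares_table,
)

DEFAULT_HORIZONS = (5, 10, 15)

#: How the recorded lifting scenarios pool onto the two technique levels.
DEFAULT_SCENARIO_POOLING = {
    "no_assist": "no_belt",
    "patient_assist": "no_belt",
    "belt": "belt",
}

#: Parametric criterion name -> feature metric.
PARAMETRIC_CRITERIA = {
    "amplitude": "rom",
    "moment": "max_moment",
    "cumulative_moment": "cumulative_moment",
}

DYNAMIC_IMPACT_DEFINITION = (
    "share of the total factor-sum spread attributable to parametric "
    "(motion-derived) criteria: 100 * range(sum X | parametric varied) / "
    "range(sum X | all criteria varied), with categorical and proportional "
    "criteria varied over their level extremes"
)


class ConfigurationError(KeyError):
    """A criteria table references a level or feature the inputs lack."""


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and survey fields for one subject.

    ``readiness_score`` is the 1-10 physical-readiness rating; it maps onto
    groups low (1-6), medium (7-8) and high (9-10).  ``scenario_mix`` gives
    the subject's shares of lifting without/with the ergonomic belt; when
    absent it is derived from the subject's trials (or defaults to the
    study design of two unbelted scenarios to one belted, 2/3 : 1/3).
    """

    id: str
    sex: Literal["male", "female"]
    age: float
    height: float
    weight: float
    readiness_score: int
    scenario_mix: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be male/female, got {self.sex!r}")
        if not 0 < self.age:
            raise InvalidInputError(f"age must be positive, got {self.age}")
        if not 1 <= self.readiness_score <= 10:
            raise InvalidInputError(
                f"readiness_score must be in 1..10, got {self.readiness_score}"
            )
        if self.scenario_mix is not None:
            mix = dict(self.scenario_mix)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise InvalidInputError(f"scenario_mix must sum to 1, got {mix}")
            object.__setattr__(self, "scenario_mix", mix)

    @property
    def readiness_group(self) -> str:
        if self.readiness_score <= 6:
            return "low"
        if self.readiness_score <= 8:
            return "medium"
        return "high"


@dataclass(frozen=True)
class HorizonRisk:
    factor_sum: float
    probability: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RiskProfile:
    """Per-region risk of one subject across forecast horizons."""

    subject_id: str
    region: str
    horizons: Mapping[int, HorizonRisk]

    def probability(self, horizon: int) -> float:
        return self.horizons[horizon].probability


@dataclass(frozen=True)
class ScenarioBounds:
    """Best/worst-case risk envelope for one region, age and horizon."""

    region: str
    age: float
    horizon: float
    p_min: float
    p_max: float
    factor_min: float
    factor_max: float


def neutral_table(table: CriteriaTable) -> CriteriaTable:
    """Copy of a table with every level likelihood forced to 1 (exact mode).

    With unit likelihoods the factor sum is exactly 1 and the model returns
    the bare shifted baseline — the reference point for calibration checks.
    """
    criteria = [
        replace(c, levels={lev: 1.0 for lev in c.levels}) for c in table.criteria
    ]
    return CriteriaTable(region=table.region, criteria=criteria,
                         rounding_mode=RoundingMode.EXACT, notes=table.notes)


def _proportional_shares(
    criterion: CriterionDef,
    subject: SubjectRecord,
    features: FeatureSet | None,
    region: str,
) -> tuple[float, float]:
    """Subject's shares over a proportional criterion's two levels, in the
    level order of the table."""
    levels = [lev.lower() for lev in criterion.levels]
    if set(levels) == {"left", "right"}:
        shares = (features.side_shares if features else {}).get(region)
        if shares is None:
            raise ConfigurationError(
                f"criterion {criterion.name!r}: no side shares for region {region!r}"
            )
        by_side = dict(zip(("left", "right"), shares))
        return tuple(by_side[lev] for lev in levels)
    if set(levels) == {"w/o belt", "w belt"}:
        mix = subject.scenario_mix or {"no_belt": 2 / 3, "belt": 1 / 3}
        by_level = {"w/o belt": mix.get("no_belt", 0.0), "w belt": mix.get("belt", 0.0)}
        return tuple(by_level[lev] for lev in levels)
    raise ConfigurationError(
        f"criterion {criterion.name!r}: cannot resolve shares for levels "
        f"{list(criterion.levels)}"
    )


def _categorical_level(criterion: CriterionDef, subject: SubjectRecord) -> str:
    name = criterion.name.lower()
    if name == "sex":
        return subject.sex.capitalize()
    if name == "physical_readiness":
        return subject.readiness_group.capitalize()
    raise ConfigurationError(
        f"categorical criterion {criterion.name!r} has no resolver; "
        f"known: sex, physical_readiness"
    )


def build_element_factors(
    subject: SubjectRecord,
    features: FeatureSet | None,
    table: CriteriaTable,
    population_stats: Mapping[str, float],
    parametric_mode: Literal["independent", "composite"] = "independent",
    likelihood_bounds: tuple[float, float] = LIKELIHOOD_BOUNDS,
) -> list[ElementFactor]:
    """One element factor per criterion of ``table`` for one subject.

    Categorical criteria look up the subject's level (sex, readiness group);
    proportional criteria blend their two level likelihoods with the
    subject's shares (side distribution, belt/no-belt work mix); parametric
    criteria derive the likelihood as the subject-to-population ratio of the
    matching motion metric (``population_stats`` maps metric name to the
    cohort grand mean for this region).

    In ``composite`` mode the three parametric ratios are first combined
    into the single 1:1:2-weighted deviation score, which then stands in for
    each parametric criterion's likelihood.
    """
    region = table.region
    parametric_a: dict[str, float] = {}
    needed = [c for c in table.criteria if c.kind is CriterionKind.PARAMETRIC]
    for crit in needed:
        metric = PARAMETRIC_CRITERIA.get(crit.name.lower())
        if metric is None:
            raise ConfigurationError(
                f"parametric criterion {crit.name!r} has no metric mapping"
            )
        if features is None:
            raise ConfigurationError(
                f"criterion {crit.name!r}: subject {subject.id} has no features"
            )
        try:
            value = features.metric(region, metric)
        except KeyError as err:
            raise ConfigurationError(
                f"criterion {crit.name!r}: missing feature {metric!r} for "
                f"region {region!r}"
            ) from err
        pop = population_stats.get(metric)
        if pop is None:
            raise ConfigurationError(
                f"criterion {crit.name!r}: population mean for {metric!r} missing"
            )
        parametric_a[crit.name] = derive_likelihood(value, pop, likelihood_bounds)
    if parametric_mode == "composite" and parametric_a:
        ratios = {PARAMETRIC_CRITERIA[k.lower()]: v for k, v in parametric_a.items()}
        score = composite_parametric_score(
            ratios.get("rom", 1.0),
            ratios.get("max_moment", 1.0),
            ratios.get("cumulative_moment", 1.0),
        )
        parametric_a = {k: score for k in parametric_a}
    elif parametric_mode not in ("independent", "composite"):
        raise InvalidInputError(f"unknown parametric_mode {parametric_mode!r}")

    factors = []
    for crit in table.criteria:
        if crit.kind is CriterionKind.CATEGORICAL:
            level = _categorical_level(crit, subject)
            if level not in crit.levels:
                raise ConfigurationError(
                    f"criterion {crit.name!r}: level {level!r} not in table "
                    f"levels {list(crit.levels)}"
                )
            a = crit.levels[level]
        elif crit.kind is CriterionKind.PROPORTIONAL:
            shares = _proportional_shares(crit, subject, features, region)
            a = blend_likelihoods(tuple(crit.levels.values()), shares)
        else:
            a = parametric_a[crit.name]
        factors.append(table.element_factor_for(crit.name, a))
    return factors


def subject_risk_profile(
    subject: SubjectRecord,
    features: FeatureSet | None,
    tables: Mapping[str, CriteriaTable],
    curves: Mapping[str, BaselineCurve],
    population_stats: Mapping[str, Mapping[str, float]],
    horizons: Sequence[int] = DEFAULT_HORIZONS,
    parametric_mode: Literal["independent", "composite"] = "independent",
    likelihood_bounds: tuple[float, float] = LIKELIHOOD_BOUNDS,
) -> dict[str, RiskProfile]:
    """Risk profile per region: ``p(T) = Q(age + T) * sum(X)``.

    Subjects whose horizon-shifted age leaves the curve's validated range
    are still evaluated (the model extrapolates) but flagged.
    """
    out: dict[str, RiskProfile] = {}
    for region, table in tables.items():
        curve = curves[region]
        factors = build_element_factors(
            subject, features, table, population_stats.get(region, {}),
            parametric_mode=parametric_mode, likelihood_bounds=likelihood_bounds,
        )
        horizon_risks: dict[int, HorizonRisk] = {}
        for t in horizons:
            flags: list[str] = []
            lo, hi = curve.valid_age_range
            if not lo <= subject.age + t <= hi:
                flags.append("age_out_of_range")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base = evaluate_baseline(shift_curve(curve, t), subject.age)
                result = scenario_probability(
                    RiskInput(baseline_probability=base, factors=factors), table
                )
            if result.clipped:
                flags.append("clipped")
            horizon_risks[t] = HorizonRisk(
                factor_sum=result.factor_sum,
                probability=result.probability,
                flags=tuple(flags),
            )
        out[region] = RiskProfile(subject_id=subject.id, region=region,
                                  horizons=horizon_risks)
    return out


def profiles_to_frame(profiles: Sequence[RiskProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, h in p.horizons.items():
            rows.append({
                "subject_id": p.subject_id, "region": p.region,
                "horizon_years": t, "factor_sum": h.factor_sum,
                "probability": h.probability, "flags": ";".join(h.flags),
            })
    return pd.DataFrame(rows)


def cohort_summary(profiles: Sequence[RiskProfile] | pd.DataFrame) -> pd.DataFrame:
    """Cohort mean +/- SD of probability per region and horizon, plus the
    spread of the element-factor sum per region (sample SD, n-1)."""
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if frame["subject_id"].nunique() < 2:
        raise InvalidInputError("cohort summary needs at least 2 subjects")
    rows = []
    for (region, t), g in frame.groupby(["region", "horizon_years"], sort=True):
        p = g["probability"]
        fs = g["factor_sum"]
        rows.append({
            "region": region, "horizon_years": t,
            "prob_mean": p.mean(), "prob_sd": p.std(ddof=1),
            "factor_sum_mean": fs.mean(), "factor_sum_sd": fs.std(ddof=1),
            "factor_sum_min": fs.min(), "factor_sum_max": fs.max(),
            "n": len(g),
        })
    return pd.DataFrame(rows).set_index(["region", "horizon_years"])


def _criterion_likelihood_range(
    crit: CriterionDef, parametric_ranges: Mapping[str, tuple[float, float]]
) -> tuple[float, float]:
    if crit.kind is CriterionKind.PARAMETRIC:
        if crit.name not in parametric_ranges:
            raise InvalidInputError(
                f"no observed likelihood range for parametric criterion "
                f"{crit.name!r}"
            )
        lo, hi = parametric_ranges[crit.name]
        if hi < lo:
            raise InvalidInputError(f"range for {crit.name!r} inverted: {lo} > {hi}")
        return float(lo), float(hi)
    values = list(crit.levels.values())
    return min(values), max(values)


def extreme_scenarios(
    table: CriteriaTable,
    parametric_ranges: Mapping[str, tuple[float, float]],
    age: float,
    horizon: float,
    curve: BaselineCurve,
) -> ScenarioBounds:
    """Best/worst-case probabilities at (age, horizon).

    The minimum scenario takes the lowest-risk level (or observed parametric
    extreme) of every criterion, the maximum the highest; proportional
    criteria are pushed to a pure 100/0 share of their safer/riskier level.
    """
    f_min = f_max = 0.0
    for crit in table.criteria:
        lo, hi = _criterion_likelihood_range(crit, parametric_ranges)
        f_min += table.element_factor_for(crit.name, lo).value
        f_max += table.element_factor_for(crit.name, hi).value
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = evaluate_baseline(shift_curve(curve, horizon), age)
    return ScenarioBounds(
        region=table.region, age=age, horizon=horizon,
        p_min=min(1.0, max(0.0, base * f_min)),
        p_max=min(1.0, max(0.0, base * f_max)),
        factor_min=f_min, factor_max=f_max,
    )


def dynamic_impact(
    table: CriteriaTable,
    parametric_ranges: Mapping[str, tuple[float, float]],
) -> float:
    """Percentage of the factor-sum spread driven by dynamic parameters.

    Defined as 100 * (factor-sum range with only parametric criteria varied)
    / (factor-sum range with all criteria varied).  This is one plausible
    operationalization of "impact of dynamic parameters on risk
    variability"; results always carry this definition in their metadata so
    the number is never silently compared across definitions.
    """
    param_spread = total_spread = 0.0
    for crit in table.criteria:
        lo, hi = _criterion_likelihood_range(crit, parametric_ranges)
        spread = (table.element_factor_for(crit.name, hi).value
                  - table.element_factor_for(crit.name, lo).value)
        total_spread += spread
        if crit.kind is CriterionKind.PARAMETRIC:
            param_spread += spread
    if total_spread == 0:
        raise DegenerateInputError("all criteria are degenerate: zero total spread")
    return 100.0 * param_spread / total_spread


def sex_comparison(
    profiles: Sequence[RiskProfile] | pd.DataFrame,
    sex_by_subject: Mapping[str, str],
    horizon: int = 15,
) -> dict[str, float]:
    """Per-region percentage gap of male over female mean probability,
    ``(mean_m - mean_f) / mean_f * 100``, at one horizon."""
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    frame = frame[frame["horizon_years"] == horizon].copy()
    frame["sex"] = frame["subject_id"].map(lambda s: sex_by_subject[str(s)])
    out = {}
    for region, g in frame.groupby("region", sort=True):
        means = g.groupby("sex")["probability"].mean()
        if "male" not in means or "female" not in means:
            raise InvalidInputError(
                f"region {region}: both sexes required, got {list(means.index)}"
            )
        out[region] = float((means["male"] - means["female"]) / means["female"] * 100.0)
    return out


# -- model / results -------------------------------------------------------

class MSDRiskModel:
    """Cohort-level multicriteria MSD risk model.

    Parameters
    ----------
    subjects
        Subject records, or a frame with columns subject_id, sex, age,
        height_cm, weight_kg, readiness_score (optionally share_no_belt /
        share_belt).
    trials
        Long-format joint time series (see :mod:`msdrisk.features`); may be
        omitted when ``features`` is supplied pre-extracted.
    features
        Tidy per (subject, joint, side) feature frame, an alternative to
        raw trials.
    tables, curves
        Criteria tables and baseline curves per region; default to the
        packaged ones.
    horizons
        Forecast horizons in years, default (5, 10, 15).
    parametric_mode
        'independent' treats amplitude/moment/cumulative moment as separate
        criteria; 'composite' folds them into the 1:1:2 deviation score.

    Examples
    --------
    >>> from msdrisk import simulate
    >>> subjects, trials = simulate.generate_study(seed=7)
    >>> results = MSDRiskModel(subjects, trials=trials).fit()
    >>> results.cohort_summary()  # doctest: +SKIP
    """

    def __init__(
        self,
        subjects,
        trials: pd.DataFrame | None = None,
        features: pd.DataFrame | None = None,
        tables: Mapping[str, CriteriaTable] | None = None,
        curves: Mapping[str, BaselineCurve] | None = None,
        horizons: Sequence[int] = DEFAULT_HORIZONS,
        parametric_mode: Literal["independent", "composite"] = "independent",
        likelihood_bounds: tuple[float, float] = LIKELIHOOD_BOUNDS,
        scenario_pooling: Mapping[str, str] = DEFAULT_SCENARIO_POOLING,
    ) -> None:
        self.subjects = self._coerce_subjects(subjects)
        if trials is None and features is None:
            raise InvalidInputError("either trials or features must be supplied")
        self.trials = trials
        self._features_frame = features
        self.tables = dict(tables) if tables is not None else datasets.load_all_criteria()
        self.curves = dict(curves) if curves is not None else datasets.load_canonical_curves()
        missing = set(self.tables) - set(self.curves)
        if missing:
            raise InvalidInputError(f"no baseline curve for region(s) {sorted(missing)}")
        if any(int(t) <= 0 for t in horizons):
            raise InvalidInputError(f"horizons must be positive, got {horizons}")
        self.horizons = tuple(int(t) for t in horizons)
        self.parametric_mode = parametric_mode
        self.likelihood_bounds = likelihood_bounds
        self.scenario_pooling = dict(scenario_pooling)

    @staticmethod
    def _coerce_subjects(subjects) -> list[SubjectRecord]:
        if isinstance(subjects, pd.DataFrame):
            records = []
            for row in subjects.itertuples():
                mix = None
                if hasattr(row, "share_no_belt") and not pd.isna(row.share_no_belt):
                    mix = {"no_belt": float(row.share_no_belt),
                           "belt": float(row.share_belt)}
                records.append(SubjectRecord(
                    id=str(row.subject_id), sex=row.sex, age=float(row.age),
                    height=float(row.height_cm), weight=float(row.weight_kg),
                    readiness_score=int(row.readiness_score), scenario_mix=mix,
                ))
            return records
        return list(subjects)

    @classmethod
    def from_csv(
        cls,
        subjects_csv,
        trials_csv=None,
        criteria_json: Mapping[str, str] | None = None,
        curves_json=None,
        **kwargs,
    ) -> "MSDRiskModel":
        from .features import read_trials_csv

        subjects = pd.read_csv(subjects_csv, comment="#")
        trials = read_trials_csv(trials_csv) if trials_csv else None
        tables = None
        if criteria_json:
            tables = {region: CriteriaTable.from_json(path)
                      for region, path in criteria_json.items()}
        curves = None
        if curves_json:
            import json as _json
            from pathlib import Path as _Path

            raw = _json.loads(_Path(curves_json).read_text())
            curves = {region: BaselineCurve.from_dict(d) for region, d in raw.items()}
        return cls(subjects, trials=trials, tables=tables, curves=curves, **kwargs)

    # -- fitting ----------------------------------------------------------
    def _scenario_mix_from_trials(self, subject_id: str) -> dict[str, float] | None:
        if self.trials is None:
            return None
        g = self.trials[self.trials["subject_id"].astype(str) == subject_id]
        if g.empty:
            return None
        counts = (
            g.groupby(["scenario", "trial"]).size().reset_index()
            .groupby("scenario").size()
        )
        pooled: dict[str, float] = {}
        for scen, n in counts.items():
            pooled[self.scenario_pooling.get(scen, scen)] = (
                pooled.get(self.scenario_pooling.get(scen, scen), 0) + int(n)
            )
        total = sum(pooled.values())
        return {k: v / total for k, v in pooled.items()}

    def fit(self) -> "MSDRiskResults":
        """Extract features, derive population statistics, and profile every
        subject; returns the results object."""
        feat = self._features_frame
        if feat is None:
            feat = extract_features(self.trials)
        shares = side_shares_table(feat)
        feature_sets = feature_sets_from_frame(feat, shares)

        # grand means per region & metric over subject-level values
        population_stats: dict[str, dict[str, float]] = {}
        for region in self.tables:
            per_metric: dict[str, float] = {}
            for metric in PARAMETRIC_METRICS:
                vals = []
                for fs in feature_sets.values():
                    try:
                        vals.append(fs.metric(region, metric))
                    except KeyError:
                        pass
                if vals:
                    per_metric[metric] = float(np.mean(vals))
            population_stats[region] = per_metric

        subjects = []
        for s in self.subjects:
            if s.scenario_mix is None:
                mix = self._scenario_mix_from_trials(s.id)
                subjects.append(replace(s, scenario_mix=mix) if mix else s)
            else:
                subjects.append(s)

        profiles: list[RiskProfile] = []
        factor_rows = []
        for s in subjects:
            fs = feature_sets.get(s.id)
            for region, table in self.tables.items():
                factors = build_element_factors(
                    s, fs, table, population_stats.get(region, {}),
                    parametric_mode=self.parametric_mode,
                    likelihood_bounds=self.likelihood_bounds,
                )
                for f in factors:
                    factor_rows.append({
                        "subject_id": s.id, "region": region,
                        "criterion": f.criterion, "likelihood": f.likelihood,
                        "weight": f.weight, "value": f.value,
                    })
            profile = subject_risk_profile(
                s, fs, self.tables, self.curves, population_stats,
                horizons=self.horizons, parametric_mode=self.parametric_mode,
                likelihood_bounds=self.likelihood_bounds,
            )
            profiles.extend(profile.values())
        return MSDRiskResults(
            model=self,
            subjects=subjects,
            feature_frame=feat,
            feature_sets=feature_sets,
            population_stats=population_stats,
            profiles=profiles,
            factor_frame=pd.DataFrame(factor_rows),
        )


class MSDRiskResults:
    """Fitted cohort risk profiles and the summaries derived from them."""

    def __init__(self, model, subjects, feature_frame, feature_sets,
                 population_stats, profiles, factor_frame) -> None:
        self.model = model
        self.subjects = subjects
        self.feature_frame = feature_frame
        self.feature_sets = feature_sets
        self.population_stats = population_stats
        self.profiles = profiles
        self.factor_frame = factor_frame
        self.frame = profiles_to_frame(profiles)

    # -- metadata ---------------------------------------------------------
    @property
    def metadata(self) -> dict:
        from . import __version__

        return {
            "package_version": __version__,
            "horizons_years": list(self.model.horizons),
            "parametric_mode": self.model.parametric_mode,
            "likelihood_bounds": list(self.model.likelihood_bounds),
            "rounding_modes": {r: t.rounding_mode.value
                               for r, t in self.model.tables.items()},
            "dynamic_impact_definition": DYNAMIC_IMPACT_DEFINITION,
            "n_subjects": len(self.subjects),
        }

    # -- summaries --------------------------------------------------------
    def cohort_summary(self) -> pd.DataFrame:
        return cohort_summary(self.frame)

    def sex_comparison(self, horizon: int = 15) -> dict[str, float]:
        sex_map = {s.id: s.sex for s in self.subjects}
        return sex_comparison(self.frame, sex_map, horizon=horizon)

    def parametric_ranges(self, region: str) -> dict[str, tuple[float, float]]:
        """Observed (min, max) likelihood per parametric criterion."""
        table = self.model.tables[region]
        param = {c.name for c in table.criteria
                 if c.kind is CriterionKind.PARAMETRIC}
        g = self.factor_frame[
            (self.factor_frame["region"] == region)
            & (self.factor_frame["criterion"].isin(param))
        ]
        return {
            name: (float(gg["likelihood"].min()), float(gg["likelihood"].max()))
            for name, gg in g.groupby("criterion")
        }

    def extreme_scenarios(
        self, region: str, age: float, horizon: float,
        parametric_ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> ScenarioBounds:
        ranges = parametric_ranges if parametric_ranges is not None \
            else self.parametric_ranges(region)
        return extreme_scenarios(
            self.model.tables[region], ranges, age, horizon,
            self.model.curves[region],
        )

    def dynamic_impact(
        self, region: str,
        parametric_ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> float:
        ranges = parametric_ranges if parametric_ranges is not None \
            else self.parametric_ranges(region)
        return dynamic_impact(self.model.tables[region], ranges)

    def summary(self) -> str:
        """Human-readable cohort report."""
        lines = [
            "Multicriteria MSD risk model — cohort results",
            "=" * 46,
            f"subjects: {len(self.subjects)}   horizons: {self.model.horizons} years",
            f"parametric mode: {self.model.parametric_mode}",
            "",
            "Probability of MSD (cohort mean ± SD):",
        ]
        cs = self.cohort_summary()
        for (region, t), row in cs.iterrows():
            lines.append(
                f"  {region:<9} {t:>2} y: {row.prob_mean:.3f} ± {row.prob_sd:.3f}"
                f"   ΣX ∈ [{row.factor_sum_min:.3f}, {row.factor_sum_max:.3f}]"
            )
        lines.append("")
        lines.append("Male vs female mean probability at 15 y:")
        try:
            for region, pct in self.sex_comparison(horizon=max(self.model.horizons)).items():
                lines.append(f"  {region:<9} {pct:+.2f}%")
        except (InvalidInputError, KeyError):
            lines.append("  (needs both sexes)")
        lines.append("")
        lines.append("Dynamic-parameter impact on factor-sum spread:")
        for region in self.model.tables:
            try:
                lines.append(f"  {region:<9} {self.dynamic_impact(region):.2f}%")
            except (InvalidInputError, DegenerateInputError):
                lines.append(f"  {region:<9} (degenerate)")
        return "\n".join(lines)

    # -- export -----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path=None):
        import json as _json

        payload = {
            "metadata": self.metadata,
            "profiles": self.frame.to_dict(orient="records"),
        }
        text = _json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path as _Path

            _Path(path).write_text(text + "\n")
        return text

    def plot_age_probability(self, region: str, ax=None):
        """Scatter of subject probabilities vs age, one series per horizon,
        over the region's shifted baseline curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curves[region]
        ages = np.linspace(*curve.valid_age_range, 200)
        age_map = {s.id: s.age for s in self.subjects}
        g = self.frame[self.frame["region"] == region]
        for t in self.model.horizons:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ax.plot(ages, evaluate_baseline(shift_curve(curve, t), ages),
                        lw=1, alpha=0.6, label=f"baseline +{t} y")
            gt = g[g["horizon_years"] == t]
            ax.scatter(gt["subject_id"].map(age_map), gt["probability"],
                       s=12, label=f"subjects +{t} y")
        ax.set_xlabel("age, years")
        ax.set_ylabel(f"P(MSD, {region})")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
        return ax
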