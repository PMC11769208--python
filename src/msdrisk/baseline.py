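"""Baseline MSD prevalence curves and the time-shift prognosis transform.

Population prevalence of musculoskeletal disorders in a body region is
modeled as a quadratic function of age,

    Q(x) = a2*x^2 + a1*x + a0,

an upward-opening parabola: with aging, both declining capacity and
accumulated load raise the chance that a disorder has set in.  The package
ships one canonical curve per region (neck, shoulder, elbow) fitted from
published cross-sectional prevalence studies of healthcare workers; the
per-year^2 terms are small (order 1e-4) and the curves rise monotonically
over the working-age range.

Prognosis over a horizon of T years is a *time shift*: the risk a subject
faces T years from now is the baseline evaluated at (current age + T), i.e.
the shifted curve satisfies Q_T(x) = Q(x + T).  Shifting a quadratic gives
another quadratic, so shifted curves stay in-type and compose additively.

:func:`fit_baseline` re-derives curves from study records by weighted least
squares (weights proportional to study sample size by default).  The
canonical packaged curves are fixed published coefficients and are never
replaced by a re-fit; the exact regression behind them is under-determined
from the study table alone, so fit diagnostics report the comparison without
asserting agreement.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .core import ClippingWarning, InvalidInputError

REGIONS = ("neck", "shoulder", "elbow")

#: Plotted/valid age range of the canonical curves, years.
DEFAULT_AGE_RANGE = (20.0, 75.0)


class AgeRangeWarning(UserWarning):
    """Evaluation outside the curve's validated age range."""


@dataclass(frozen=True)
class StudyRecord:
    """One published prevalence study: sample, mean age, per-region risk."""

    label: str
    country: str
    sample_size: int
    mean_age: float
    age_sd: float
    base_risk: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise InvalidInputError(f"sample_size must be >= 1, got {self.sample_size}")
        risk = dict(self.base_risk)
        for region, p in risk.items():
            if not 0 <= p <= 1:
                raise InvalidInputError(
                    f"study {self.label!r}: base risk for {region} must be a "
                    f"probability, got {p}"
                )
        object.__setattr__(self, "base_risk", risk)


@dataclass(frozen=True)
class BaselineCurve:
    """Quadratic age->probability curve for one body region."""

    region: str
    a2: float
    a1: float
    a0: float
    valid_age_range: tuple[float, float] = DEFAULT_AGE_RANGE

    def __post_init__(self) -> None:
        if self.a2 <= 0:
            warnings.warn(
                f"{self.region} curve has a2={self.a2} <= 0: not an "
                f"upward-opening parabola",
                UserWarning,
                stacklevel=3,
            )

    def __call__(self, age):
        return evaluate_baseline(self, age)

    def shift(self, horizon: float) -> "BaselineCurve":
        return shift_curve(self, horizon)

    def coefficients(self) -> tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "a2": self.a2,
            "a1": self.a1,
            "a0": self.a0,
            "valid_age_range": list(self.valid_age_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaselineCurve":
        return cls(
            region=d["region"],
            a2=d["a2"],
            a1=d["a1"],
            a0=d["a0"],
            valid_age_range=tuple(d.get("valid_age_range", DEFAULT_AGE_RANGE)),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BaselineCurve":
        from .core import _read_json_source

        return cls.from_dict(json.loads(_read_json_source(source)))


def evaluate_baseline(curve: BaselineCurve, age):
    """Baseline probability at ``age`` (scalar or array), clipped to [0, 1].

    Ages below 0 are an error; ages outside the curve's validated range are
    evaluated with a warning (the model extrapolates freely but the fit was
    only anchored inside the range).
    """
    x = np.asarray(age, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError(f"age must be non-negative, got {age}")
    lo, hi = curve.valid_age_range
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"age {age} outside {curve.region} curve's valid range [{lo}, {hi}]",
            AgeRangeWarning,
            stacklevel=2,
        )
    y = curve.a2 * x**2 + curve.a1 * x + curve.a0
    if np.any((y < 0) | (y > 1)):
        warnings.warn(
            f"{curve.region} baseline value clipped into [0, 1]",
            ClippingWarning,
            stacklevel=2,
        )
    y = np.clip(y, 0.0, 1.0)
    return float(y) if np.isscalar(age) else y


def shift_curve(curve: BaselineCurve, horizon: float) -> BaselineCurve:
    """Curve advanced by ``horizon`` years: ``Q_T(x) = Q(x + T)``.

    The prognosis probability at a subject's current age equals the baseline
    at (age + T); a point at age 40 on the baseline appears at age 35 on the
    5-year prognosis curve.
    """
    if horizon < 0:
        raise InvalidInputError(f"horizon must be >= 0, got {horizon}")
    t = float(horizon)
    return BaselineCurve(
        region=curve.region,
        a2=curve.a2,
        a1=curve.a1 + 2.0 * curve.a2 * t,
        a0=curve.a2 * t**2 + curve.a1 * t + curve.a0,
        valid_age_range=curve.valid_age_range,
    )


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-study residuals and health flags for a baseline fit."""

    residuals: Mapping[str, float]
    weights: Mapping[str, float]
    rsquared: float
    a2_nonpositive: bool
    reference_coefficients: tuple[float, float, float] | None = None
    reference_delta: tuple[float, float, float] | None = None


def fit_baseline(
    records: Sequence[StudyRecord],
    region: str,
    weighting: Literal["none", "sample_size"] = "sample_size",
    valid_age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    reference: BaselineCurve | None = None,
) -> tuple[BaselineCurve, FitDiagnostics]:
    """Weighted least-squares quadratic fit of region prevalence vs mean age.

    Larger studies pull harder on the fit when ``weighting='sample_size'``.
    Requires at least three distinct mean ages (a quadratic has three
    coefficients).  If a ``reference`` curve is supplied, diagnostics carry
    the coefficient deltas against it — reported, never enforced.
    """
    recs = [r for r in records if region in r.base_risk]
    ages = np.array([r.mean_age for r in recs], dtype=float)
    if len(recs) < 3 or len(np.unique(ages)) < 3:
        raise InvalidInputError(
            f"need >= 3 study records with distinct mean ages for {region!r}, "
            f"got {len(np.unique(ages))} distinct"
        )
    y = np.array([r.base_risk[region] for r in recs], dtype=float)
    if weighting == "sample_size":
        w = np.array([r.sample_size for r in recs], dtype=float)
    elif weighting == "none":
        w = np.ones(len(recs))
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    import statsmodels.api as sm

    X = np.column_stack([ages**2, ages, np.ones_like(ages)])
    res = sm.WLS(y, X, weights=w).fit()
    a2, a1, a0 = (float(c) for c in res.params)

    curve = BaselineCurve(region=region, a2=a2, a1=a1, a0=a0,
                          valid_age_range=valid_age_range)
    fitted = X @ np.array([a2, a1, a0])
    diag = FitDiagnostics(
        residuals={r.label: float(yy - ff) for r, yy, ff in zip(recs, y, fitted)},
        weights={r.label: float(ww) for r, ww in zip(recs, w)},
        rsquared=float(res.rsquared) if len(recs) > 3 else float("nan"),
        a2_nonpositive=a2 <= 0,
        reference_coefficients=reference.coefficients() if reference else None,
        reference_delta=(
            tuple(np.subtract((a2, a1, a0), reference.coefficients()))
            if reference
            else None
        ),
    )
    return curve, diag


# -- study-record CSV I/O --------------------------------------------------

_STUDY_COLUMNS = ["label", "country", "sample_size", "mean_age", "age_sd",
                  "neck", "shoulder", "elbow"]


def read_study_records(path: str | Path) -> list[StudyRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                StudyRecord(
                    label=row["label"],
                    country=row["country"],
                    sample_size=int(row["sample_size"]),
                    mean_age=float(row["mean_age"]),
                    age_sd=float(row["age_sd"]),
                    base_risk={
                        region: float(row[region])
                        for region in REGIONS
                        if row.get(region) not in (None, "")
                    },
                )
            )
    return records


def write_study_records(records: Sequence[StudyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_STUDY_COLUMNS)
        writer.writeheader()
        for r in records:
            row = {
                "label": r.label,
                "country": r.country,
                "sample_size": r.sample_size,
                "mean_age": r.mean_age,
                "age_sd": r.age_sd,
            }
            row.update({region: r.base_risk.get(region, "") for region in REGIONS})
            writer.writerow(row)
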