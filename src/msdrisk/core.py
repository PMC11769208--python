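"""Weighted multicriteria probability engine.

The model scores a scenario (here: developing a musculoskeletal disorder in
one body region) as

    p(A) = Q_j * sum_i X_i,        X_i = q_i * a_ij,

where ``Q_j`` is an age-dependent baseline probability, ``q_i`` is the
normalized weight coefficient of criterion *i* derived from integer weight
scores ``B_i`` (``q_i = B_i / sum(B)``), and ``a_ij`` is the dimensionless
element likelihood of the subject's level *j* on that criterion (``a > 1``
raises risk, ``a < 1`` lowers it).  When every likelihood is 1 the factor sum
is exactly 1 and the scenario probability collapses to the baseline.

Published criteria tables print weights and factors rounded to three
decimals, and the printed cells are not reproducible under a single rounding
convention (one table renormalizes the largest coefficient so the display sums
to 1.000, another does not).  Arithmetic here is therefore exact (rational)
by default; rounding is a *presentation* concern selected via
:class:`RoundingMode`:

``exact``
    full-precision rationals/floats; coefficients sum to 1 exactly.
``display3``
    each coefficient and factor half-even rounded to 3 decimals.
``table_match``
    like ``display3``, but the last occurrence of the largest coefficient is
    adjusted so the displayed coefficients sum to 1.000 — this reproduces
    printed tables that renormalize the display.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""


class DegenerateInputError(InvalidInputError):
    """Raised when inputs are formally valid but carry no information."""


class ClippingWarning(UserWarning):
    """Emitted when a probability had to be clipped into [0, 1]."""


class RoundingMode(str, enum.Enum):
    EXACT = "exact"
    DISPLAY3 = "display3"
    TABLE_MATCH = "table_match"


class CriterionKind(str, enum.Enum):
    CATEGORICAL = "categorical"
    PARAMETRIC = "parametric"
    PROPORTIONAL = "proportional"


#: Tolerance on |sum(q) - 1| per rounding mode (display modes accumulate up to
#: one rounding unit per coefficient; 0.0015 covers every packaged table).
NORMALIZATION_TOL = {
    RoundingMode.EXACT: 1e-12,
    RoundingMode.DISPLAY3: 0.0015,
    RoundingMode.TABLE_MATCH: 0.0015,
}


def _read_json_source(source) -> str:
    """Accept either a path to a JSON file or a JSON string."""
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if not text.lstrip().startswith(("{", "[")):
        return Path(text).read_text()
    return text


def _to_decimal(x) -> Decimal:
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    if isinstance(x, Decimal):
        return x
    return Decimal(repr(float(x)))


def round_half_even(x, ndigits: int = 3) -> float:
    """Banker's rounding of ``x`` (float/Fraction/Decimal) to ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(_to_decimal(x).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class CriterionDef:
    """One risk criterion: a weight score and, for discrete criteria, the
    likelihood of each level.

    ``kind`` decides how a subject's likelihood is resolved downstream:
    categorical criteria look a level up directly, proportional criteria blend
    exactly two levels with the subject's shares, parametric criteria derive
    the likelihood as a subject-to-population ratio and carry no levels.
    """

    name: str
    weight_score: int
    kind: CriterionKind = CriterionKind.CATEGORICAL
    levels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("criterion name must be non-empty")
        if int(self.weight_score) != self.weight_score or self.weight_score < 1:
            raise InvalidInputError(
                f"criterion {self.name!r}: weight_score must be a positive "
                f"integer, got {self.weight_score!r}"
            )
        kind = CriterionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        levels = dict(self.levels)
        for lev, a in levels.items():
            if not a > 0:
                raise InvalidInputError(
                    f"criterion {self.name!r}: likelihood for level {lev!r} "
                    f"must be > 0, got {a}"
                )
        if kind is CriterionKind.PROPORTIONAL and len(levels) != 2:
            raise InvalidInputError(
                f"criterion {self.name!r}: proportional criteria need exactly "
                f"two levels, got {len(levels)}"
            )
        if kind is CriterionKind.PARAMETRIC and levels:
            raise InvalidInputError(
                f"criterion {self.name!r}: parametric criteria carry no levels"
            )
        object.__setattr__(self, "levels", levels)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "weight_score": self.weight_score,
            "kind": self.kind.value,
            "levels": dict(self.levels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CriterionDef":
        return cls(
            name=d["name"],
            weight_score=d["weight_score"],
            kind=CriterionKind(d["kind"]),
            levels=d.get("levels", {}),
        )


def compute_weight_coefficients(
    weight_scores: Sequence[int],
    rounding_mode: RoundingMode = RoundingMode.EXACT,
) -> list:
    """Normalized weight coefficients ``q_i = B_i / sum(B)``.

    In ``exact`` mode the returned values are :class:`fractions.Fraction`
    and sum to 1 exactly.  In ``display3`` mode each is half-even rounded to
    3 decimals.  In ``table_match`` mode the last occurrence of the largest
    coefficient is additionally adjusted so the displayed set sums to 1.000.
    """
    mode = RoundingMode(rounding_mode)
    if len(weight_scores) == 0:
        raise InvalidInputError("weight_scores must be non-empty")
    scores = []
    for b in weight_scores:
        if int(b) != b or b < 1:
            raise InvalidInputError(f"weight scores must be positive integers, got {b!r}")
        scores.append(int(b))
    total = sum(scores)
    exact = [Fraction(b, total) for b in scores]
    if mode is RoundingMode.EXACT:
        return exact
    displayed = [round_half_even(q) for q in exact]
    if mode is RoundingMode.TABLE_MATCH:
        # adjust the last largest entry so the 3-dp display sums to 1.000
        milli = [round(q * 1000) for q in displayed]
        deficit = 1000 - sum(milli)
        idx = max(range(len(milli)), key=lambda i: (milli[i], i))
        milli[idx] += deficit
        displayed = [m / 1000.0 for m in milli]
    return displayed


@dataclass(frozen=True)
class ElementFactor:
    """The contribution ``X = a * q`` of one criterion to the factor sum."""

    criterion: str
    likelihood: float
    weight: float
    value: float


def element_factor(
    likelihood: float,
    weight: float,
    rounding_mode: RoundingMode = RoundingMode.EXACT,
    criterion: str = "",
) -> ElementFactor:
    """Element factor ``X = a * q``; rounded to 3 decimals in display modes."""
    mode = RoundingMode(rounding_mode)
    if not likelihood > 0:
        raise InvalidInputError(f"likelihood must be > 0, got {likelihood}")
    if not 0 < weight <= 1:
        raise InvalidInputError(f"weight must be in (0, 1], got {weight}")
    if mode is RoundingMode.EXACT:
        value = float(likelihood * weight)
        weight_f = float(weight)
    else:
        value = round_half_even(_to_decimal(likelihood) * _to_decimal(weight))
        weight_f = float(weight)
    return ElementFactor(
        criterion=criterion,
        likelihood=float(likelihood),
        weight=weight_f,
        value=value,
    )


def blend_likelihoods(
    a_pair: Sequence[float], shares: Sequence[float], tol: float = 1e-9
) -> float:
    """Share-weighted mixture of two level likelihoods:
    ``a = a1*c1 + a2*c2`` with ``c1 + c2 = 1``.

    Used for criteria whose two levels a subject occupies proportionally
    (e.g. left/right movement distribution, or lifting with vs without an
    ergonomic belt across a work mix).
    """
    (a1, a2), (c1, c2) = a_pair, shares
    if c1 < 0 or c2 < 0:
        raise InvalidInputError(f"shares must be non-negative, got {shares}")
    if abs((c1 + c2) - 1.0) > tol:
        raise InvalidInputError(f"shares must sum to 1, got {c1 + c2!r}")
    return a1 * c1 + a2 * c2


@dataclass(frozen=True)
class CriteriaTable:
    """Ordered criteria for one body region plus its rounding convention."""

    region: str
    criteria: Sequence[CriterionDef]
    rounding_mode: RoundingMode = RoundingMode.EXACT
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        criteria = tuple(self.criteria)
        if not criteria:
            raise InvalidInputError("criteria table must hold at least one criterion")
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"criterion names must be unique: {names}")
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "rounding_mode", RoundingMode(self.rounding_mode))
        object.__setattr__(self, "notes", dict(self.notes))

    def __len__(self) -> int:
        return len(self.criteria)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.criteria]

    def criterion(self, name: str) -> CriterionDef:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def weight_coefficients(self, rounding_mode: RoundingMode | None = None) -> list:
        mode = RoundingMode(rounding_mode) if rounding_mode is not None else self.rounding_mode
        return compute_weight_coefficients([c.weight_score for c in self.criteria], mode)

    def weight_coefficient(self, name: str, rounding_mode: RoundingMode | None = None):
        return dict(zip(self.names, self.weight_coefficients(rounding_mode)))[name]

    def element_factor_for(
        self, name: str, likelihood: float, rounding_mode: RoundingMode | None = None
    ) -> ElementFactor:
        mode = RoundingMode(rounding_mode) if rounding_mode is not None else self.rounding_mode
        q = self.weight_coefficient(name, mode)
        return element_factor(likelihood, q, mode, criterion=name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "rounding_mode": self.rounding_mode.value,
            "criteria": [c.to_dict() for c in self.criteria],
            "notes": dict(self.notes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CriteriaTable":
        return cls(
            region=d["region"],
            criteria=[CriterionDef.from_dict(c) for c in d["criteria"]],
            rounding_mode=RoundingMode(d.get("rounding_mode", "exact")),
            notes=d.get("notes", {}),
        )

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CriteriaTable":
        text = _read_json_source(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class RiskInput:
    """Baseline probability plus one element factor per criterion."""

    baseline_probability: float
    factors: Sequence[ElementFactor]

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_probability <= 1:
            raise InvalidInputError(
                f"baseline probability must be in [0, 1], got {self.baseline_probability}"
            )
        factors = tuple(self.factors)
        if not factors:
            raise InvalidInputError("factor list must be non-empty")
        names = [f.criterion for f in factors]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"duplicate criterion in factors: {names}")
        object.__setattr__(self, "factors", factors)

    @property
    def factor_sum(self) -> float:
        return float(sum(f.value for f in self.factors))


@dataclass(frozen=True)
class ScenarioProbability:
    probability: float
    factor_sum: float
    clipped: bool


def scenario_probability(
    risk_input: RiskInput, table: CriteriaTable | None = None
) -> ScenarioProbability:
    """Scenario probability ``p = Q_j * sum(X_i)``, clipped into [0, 1].

    If ``table`` is given, the factor list must cover the table's criteria
    exactly once each.  The factor sum can push ``Q * sum(X)`` above 1 for
    unfavourable profiles; the result is clipped and flagged.
    """
    if table is not None:
        have = sorted(f.criterion for f in risk_input.factors)
        want = sorted(table.names)
        if have != want:
            raise InvalidInputError(
                f"factors {have} do not match criteria table {want}"
            )
    raw = risk_input.baseline_probability * risk_input.factor_sum
    clipped = not 0.0 <= raw <= 1.0
    if clipped:
        warnings.warn(
            f"scenario probability {raw:.4f} clipped into [0, 1]", ClippingWarning,
            stacklevel=2,
        )
    return ScenarioProbability(
        probability=min(1.0, max(0.0, raw)),
        factor_sum=risk_input.factor_sum,
        clipped=clipped,
    )


@dataclass(frozen=True)
class NormalizationCheck:
    ok: bool
    residual: float
    tolerance: float


def verify_normalization(table: CriteriaTable) -> NormalizationCheck:
    """Check the normalization condition ``sum(q_i) = 1`` for a table.

    Exact mode must hold to 1e-12; display modes may carry a residual of up
    to one or two rounding units (the residual is reported either way).
    """
    qs = table.weight_coefficients()
    total = sum(Fraction(q) if not isinstance(q, Fraction) else q for q in qs)
    residual = float(total - 1)
    tol = NORMALIZATION_TOL[table.rounding_mode]
    return NormalizationCheck(ok=abs(residual) <= tol, residual=residual, tolerance=tol)
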