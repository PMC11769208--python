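"""Input-file schema validation: every violation is reported with its file
and row so a bad dataset fails loudly before any risk number is produced."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .baseline import REGIONS, BaselineCurve
from .config import RunConfig
from .core import CriteriaTable, InvalidInputError
from .features import SCENARIOS, SIDES, JOINTS, TRIAL_COLUMNS


@dataclass
class Violation:
    file: str
    row: int | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.file}" + (f":row {self.row}" if self.row is not None else "")
        return f"{loc}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file, row, message) -> None:
        self.violations.append(Violation(str(file), row, message))

    def __str__(self) -> str:
        if self.ok:
            return "validation passed: 0 violations"
        lines = [f"validation failed: {len(self.violations)} violation(s)"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


_SUBJECT_COLUMNS = ["subject_id", "sex", "age", "height_cm", "weight_kg",
                    "readiness_score"]


def _validate_subjects(path: Path, report: ValidationReport) -> None:
    frame = pd.read_csv(path, comment="#")
    missing = set(_SUBJECT_COLUMNS) - set(frame.columns)
    if missing:
        report.add(path, None, f"missing columns: {sorted(missing)}")
        return
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # header + 1-based
        if row["sex"] not in ("male", "female"):
            report.add(path, rownum, f"sex must be male/female, got {row['sex']!r}")
        if not row["age"] > 0:
            report.add(path, rownum, f"age must be positive, got {row['age']}")
        if not 1 <= row["readiness_score"] <= 10:
            report.add(path, rownum,
                       f"readiness_score out of range 1..10: {row['readiness_score']}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        report.add(path, None, f"duplicate subject ids: {dupes}")


def _validate_trials(path: Path, report: ValidationReport) -> None:
    frame = pd.read_csv(path, comment="#")
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        report.add(path, None, f"missing columns: {sorted(missing)}")
        return
    bad_scen = set(frame["scenario"]) - set(SCENARIOS)
    if bad_scen:
        report.add(path, None, f"unknown scenario values: {sorted(bad_scen)}")
    bad_joint = set(frame["joint"]) - set(JOINTS)
    if bad_joint:
        report.add(path, None, f"unknown joint values: {sorted(bad_joint)}")
    bad_side = set(frame["side"]) - set(SIDES)
    if bad_side:
        report.add(path, None, f"unknown side values: {sorted(bad_side)}")
    keys = ["subject_id", "scenario", "joint", "side", "trial"]
    for key, g in frame.groupby(keys, sort=False):
        t = g["time_s"].to_numpy()
        if len(t) < 2:
            report.add(path, int(g.index[0]) + 2,
                       f"trial {key} has fewer than 2 samples")
            continue
        import numpy as np

        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            report.add(path, int(g.index[bad[0] + 1]) + 2,
                       f"non-monotone time in trial {key}")


def _validate_criteria(region: str, path: Path, report: ValidationReport) -> None:
    try:
        table = CriteriaTable.from_dict(json.loads(Path(path).read_text()))
    except (InvalidInputError, KeyError, json.JSONDecodeError) as err:
        report.add(path, None, f"unparseable criteria table: {err}")
        return
    if table.region != region:
        report.add(path, None,
                   f"table region {table.region!r} does not match key {region!r}")


def _validate_curves(path: Path, report: ValidationReport) -> None:
    try:
        raw = json.loads(Path(path).read_text())
        for region, d in raw.items():
            BaselineCurve.from_dict(d)
            if region not in REGIONS:
                report.add(path, None, f"unknown region {region!r}")
    except (KeyError, TypeError, json.JSONDecodeError) as err:
        report.add(path, None, f"unparseable curves file: {err}")


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema-check every file a config references; never raises on content
    problems — they all land in the report."""
    report = ValidationReport()
    for entry in config.require_files():
        report.add(entry.split(":")[1].strip(), None, "file does not exist")
    if not report.ok:
        return report
    if config.subjects is not None:
        _validate_subjects(Path(config.subjects), report)
    if config.trials is not None:
        _validate_trials(Path(config.trials), report)
    for region, path in config.criteria.items():
        _validate_criteria(region, Path(path), report)
    if config.curves is not None:
        _validate_curves(Path(config.curves), report)
    return report
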