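"""Loaders for the packaged default criteria tables, curves and study data."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .baseline import REGIONS, BaselineCurve, StudyRecord, read_study_records
from .core import CriteriaTable

_DATA = resources.files("msdrisk") / "data"


def load_criteria_table(region: str) -> CriteriaTable:
    """Packaged default criteria table for one region."""
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")
    path = _DATA / f"criteria_{region}.json"
    return CriteriaTable.from_dict(json.loads(path.read_text()))


def load_all_criteria() -> dict[str, CriteriaTable]:
    return {region: load_criteria_table(region) for region in REGIONS}


def load_baseline_curve(region: str) -> BaselineCurve:
    """Canonical published baseline curve for one region."""
    curves = json.loads((_DATA / "curves.json").read_text())
    return BaselineCurve.from_dict(curves[region])


def load_canonical_curves() -> dict[str, BaselineCurve]:
    curves = json.loads((_DATA / "curves.json").read_text())
    return {region: BaselineCurve.from_dict(d) for region, d in curves.items()}


def load_prevalence_studies() -> list[StudyRecord]:
    """The published cross-sectional prevalence studies behind the curves."""
    with resources.as_file(_DATA / "prevalence_studies.csv") as p:
        return read_study_records(p)


def load_reference_bundle() -> dict[str, pd.DataFrame]:
    """Small committed synthetic fixture: subjects, trials, expected features."""
    out = {}
    for name in ("subjects", "trials", "expected_features"):
        with resources.as_file(_DATA / "reference" / f"{name}.csv") as p:
            out[name] = pd.read_csv(p, comment="#")
    return out
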