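"""Kinematic/kinetic feature extraction from joint time series.

Each recorded lifting trial carries a joint angle (degrees) and net joint
moment (N·m) series over time.  Three parametric exposure metrics are
extracted per trial:

* range of motion — max(angle) − min(angle), degrees;
* maximum moment — peak of |moment|, N·m;
* cumulative moment — trapezoidal integral of |moment| over the trial,
  N·m·s, an accumulated-load proxy.  The magnitude is integrated so that
  flexion and extension loading do not cancel.

Per-subject values average over that subject's repeated trials.  Subject
metrics become dimensionless element likelihoods by ratio against the
population (grand) mean — a segment whose mean is 5% above the population's
gets a likelihood of 1.05, assuming a linear dose–risk relationship.  Only
ratios enter the risk model, so the absolute per-trial reporting unit
cancels; reported cumulative moments are per-trial.

Left/right loading asymmetry is summarized as the two sides' shares of
cumulative moment, ``(L, R) / (L + R)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, InvalidInputError

SCENARIOS = ("no_assist", "patient_assist", "belt")
JOINTS = ("neck", "shoulder", "elbow")
SIDES = ("left", "right", "midline")

PARAMETRIC_METRICS = ("rom", "max_moment", "cumulative_moment")

#: Default clipping bounds on derived likelihood ratios; one corrupt trial
#: must not be able to blow up the factor sum.
LIKELIHOOD_BOUNDS = (0.1, 3.0)

#: Canonical trial CSV columns (long format, dot decimal).
TRIAL_COLUMNS = ["subject_id", "scenario", "joint", "side", "trial",
                 "time_s", "angle_deg", "moment_Nm"]


class LikelihoodClippedWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MotionTrial:
    """One segmented lifting trial for one joint and side."""

    subject_id: str
    scenario: str
    joint: str
    side: str
    time: np.ndarray
    angle: np.ndarray
    moment: np.ndarray
    trial: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        m = np.asarray(self.moment, dtype=float)
        if len(t) < 2:
            raise InvalidInputError("trial needs at least 2 samples")
        if not (len(t) == len(a) == len(m)):
            raise InvalidInputError(
                f"misaligned series: time {len(t)}, angle {len(a)}, moment {len(m)}"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        for name, val in (("time", t), ("angle", a), ("moment", m)):
            object.__setattr__(self, name, val)

    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def compute_rom(angle_series) -> float:
    """Range of motion: max − min of the angle series, degrees."""
    a = np.asarray(angle_series, dtype=float)
    if a.size < 2:
        raise InvalidInputError("ROM needs at least 2 samples")
    return float(a.max() - a.min())


def compute_max_moment(moment_series) -> float:
    """Peak absolute joint moment, N·m."""
    m = np.asarray(moment_series, dtype=float)
    if m.size < 1:
        raise InvalidInputError("max moment needs at least 1 sample")
    return float(np.abs(m).max())


def compute_cumulative_moment(moment_series, time) -> float:
    """Trapezoidal integral of |moment| over time, N·m·s."""
    m = np.asarray(moment_series, dtype=float)
    t = np.asarray(time, dtype=float)
    if m.shape != t.shape:
        raise InvalidInputError(f"misaligned series: moment {m.shape}, time {t.shape}")
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time must be strictly increasing with >= 2 samples")
    return float(np.trapezoid(np.abs(m), t))


def compute_side_shares(left_cumulative: float, right_cumulative: float) -> tuple[float, float]:
    """Left/right shares of total cumulative moment, summing to 1."""
    if left_cumulative < 0 or right_cumulative < 0:
        raise InvalidInputError("cumulative moments must be non-negative")
    total = left_cumulative + right_cumulative
    if total == 0:
        raise DegenerateInputError("both sides have zero cumulative moment")
    return (left_cumulative / total, right_cumulative / total)


def derive_likelihood(
    segment_mean: float,
    population_mean: float,
    bounds: tuple[float, float] = LIKELIHOOD_BOUNDS,
) -> float:
    """Element likelihood as a segment-to-population ratio, clipped.

    A segment averaging 1.05x the population mean maps to a = 1.05 (5%
    higher likelihood), 0.9x to a = 0.9, under a linear exposure-risk
    assumption.
    """
    if not population_mean > 0:
        raise InvalidInputError(f"population mean must be > 0, got {population_mean}")
    a = segment_mean / population_mean
    lo, hi = bounds
    if a < lo or a > hi:
        warnings.warn(
            f"likelihood ratio {a:.3f} clipped into [{lo}, {hi}]",
            LikelihoodClippedWarning,
            stacklevel=2,
        )
        a = min(hi, max(lo, a))
    return float(a)


def composite_parametric_score(rom_dev: float, maxmom_dev: float, cummom_dev: float) -> float:
    """1:1:2-weighted mean of the three parametric deviation ratios.

    Cumulative moment carries double weight: over a long horizon the
    accumulated load dominates instantaneous amplitude and peak moment.
    """
    for v in (rom_dev, maxmom_dev, cummom_dev):
        if not v > 0:
            raise InvalidInputError(f"deviation ratios must be > 0, got {v}")
    return (rom_dev + maxmom_dev + 2.0 * cummom_dev) / 4.0


# -- tidy-frame plumbing ---------------------------------------------------

def trials_to_frame(trials: Sequence[MotionTrial]) -> pd.DataFrame:
    """Long-format frame of raw samples from a list of trials."""
    parts = []
    for tr in trials:
        parts.append(pd.DataFrame({
            "subject_id": tr.subject_id,
            "scenario": tr.scenario,
            "joint": tr.joint,
            "side": tr.side,
            "trial": tr.trial,
            "time_s": tr.time,
            "angle_deg": tr.angle,
            "moment_Nm": tr.moment,
        }))
    return pd.concat(parts, ignore_index=True)


def frame_to_trials(frame: pd.DataFrame) -> list[MotionTrial]:
    trials = []
    keys = ["subject_id", "scenario", "joint", "side", "trial"]
    for (sid, scen, joint, side, trial), g in frame.groupby(keys, sort=False):
        trials.append(MotionTrial(
            subject_id=str(sid), scenario=scen, joint=joint, side=side,
            trial=int(trial),
            time=g["time_s"].to_numpy(),
            angle=g["angle_deg"].to_numpy(),
            moment=g["moment_Nm"].to_numpy(),
        ))
    return trials


def read_trials_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"trial CSV missing columns: {sorted(missing)}")
    return frame


@dataclass(frozen=True)
class JointFeatures:
    rom: float
    max_moment: float
    cumulative_moment: float


@dataclass(frozen=True)
class FeatureSet:
    """Per-subject parametric features per joint/side, plus side shares."""

    subject_id: str
    joints: Mapping[tuple[str, str], JointFeatures]
    side_shares: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def metric(self, joint: str, name: str) -> float:
        """Subject-level metric for a joint, averaged over sides."""
        vals = [getattr(f, name) for (j, _s), f in self.joints.items() if j == joint]
        if not vals:
            raise KeyError(f"no features for joint {joint!r}")
        return float(np.mean(vals))


def extract_features(
    trials: pd.DataFrame | Sequence[MotionTrial],
) -> pd.DataFrame:
    """Per (subject, joint, side) features averaged over repeated trials.

    Returns a tidy frame with columns subject_id, joint, side, rom,
    max_moment, cumulative_moment, n_trials.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = trials_to_frame(trials)
    if trials.empty:
        raise InvalidInputError("no trials supplied")
    rows = []
    keys = ["subject_id", "joint", "side"]
    for (sid, joint, side), g in trials.groupby(keys, sort=True):
        per_trial = []
        for (_scen, _trial), gt in g.groupby(["scenario", "trial"], sort=True):
            gt = gt.sort_values("time_s")
            t = gt["time_s"].to_numpy()
            per_trial.append((
                compute_rom(gt["angle_deg"].to_numpy()),
                compute_max_moment(gt["moment_Nm"].to_numpy()),
                compute_cumulative_moment(gt["moment_Nm"].to_numpy(), t),
            ))
        arr = np.array(per_trial)
        rows.append({
            "subject_id": str(sid), "joint": joint, "side": side,
            "rom": arr[:, 0].mean(),
            "max_moment": arr[:, 1].mean(),
            "cumulative_moment": arr[:, 2].mean(),
            "n_trials": len(per_trial),
        })
    return pd.DataFrame(rows)


def side_shares_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, joint) left/right cumulative-moment shares.

    Joints recorded on the midline get (0.5, 0.5) by convention.
    """
    rows = []
    for (sid, joint), g in features.groupby(["subject_id", "joint"], sort=True):
        sides = dict(zip(g["side"], g["cumulative_moment"]))
        if "left" in sides and "right" in sides:
            l, r = compute_side_shares(sides["left"], sides["right"])
        else:
            l, r = 0.5, 0.5
        rows.append({"subject_id": str(sid), "joint": joint,
                     "share_left": l, "share_right": r})
    return pd.DataFrame(rows)


def feature_sets_from_frame(
    features: pd.DataFrame, shares: pd.DataFrame | None = None
) -> dict[str, FeatureSet]:
    """Bundle tidy feature rows into per-subject :class:`FeatureSet`s."""
    if shares is None:
        shares = side_shares_table(features)
    out: dict[str, FeatureSet] = {}
    share_map: dict[str, dict[str, tuple[float, float]]] = {}
    for row in shares.itertuples():
        share_map.setdefault(str(row.subject_id), {})[row.joint] = (
            row.share_left, row.share_right)
    for sid, g in features.groupby("subject_id", sort=True):
        joints = {
            (row.joint, row.side): JointFeatures(
                rom=row.rom, max_moment=row.max_moment,
                cumulative_moment=row.cumulative_moment)
            for row in g.itertuples()
        }
        out[str(sid)] = FeatureSet(
            subject_id=str(sid), joints=joints,
            side_shares=share_map.get(str(sid), {}),
        )
    return out


def segment_population(
    subject_metrics: pd.DataFrame,
    key: str,
    metrics: Sequence[str] = PARAMETRIC_METRICS,
    bounds: tuple[float, float] = LIKELIHOOD_BOUNDS,
) -> pd.DataFrame:
    """Per-segment metric means and segment-to-population likelihoods.

    ``subject_metrics`` holds one row per subject with a demographic column
    ``key`` (e.g. sex, readiness group) and one column per metric.  The
    likelihood of segment s on metric m is mean_s(m) / grand_mean(m),
    clipped to ``bounds``.  Segments with fewer than 2 subjects trigger a
    warning (their means are noise-dominated).
    """
    if subject_metrics.empty:
        raise InvalidInputError("subject_metrics is empty")
    if key not in subject_metrics.columns:
        raise InvalidInputError(f"key column {key!r} missing")
    grand = subject_metrics[list(metrics)].mean()
    rows = []
    for seg, g in subject_metrics.groupby(key, sort=True):
        if len(g) < 2:
            warnings.warn(
                f"segment {seg!r} of {key!r} has only {len(g)} subject(s)",
                UserWarning, stacklevel=2,
            )
        row = {key: seg, "n": len(g)}
        for m in metrics:
            row[f"{m}_mean"] = g[m].mean()
            row[f"{m}_likelihood"] = derive_likelihood(g[m].mean(), grand[m], bounds)
        rows.append(row)
    return pd.DataFrame(rows).set_index(key)


def split_trials(
    time,
    angle,
    rest_tolerance_deg: float = 5.0,
    min_rest_s: float = 0.5,
):
    """Convenience splitter for continuous captures: boundaries where the
    angle stays within ``rest_tolerance_deg`` of the initial neutral pose for
    at least ``min_rest_s``.  Returns a list of (start, stop) index slices
    covering the active segments.  Recorded data are normally supplied
    pre-segmented; this is a rough helper, not part of the model.
    """
    t = np.asarray(time, dtype=float)
    a = np.asarray(angle, dtype=float)
    at_rest = np.abs(a - a[0]) <= rest_tolerance_deg
    # rest runs long enough to count as boundaries
    segments = []
    i = 0
    n = len(t)
    while i < n:
        if at_rest[i]:
            j = i
            while j < n and at_rest[j]:
                j += 1
            i = j
        else:
            j = i
            while j < n and not at_rest[j]:
                j += 1
            segments.append((i, j))
            i = j
    # merge segments separated by rests shorter than min_rest_s
    merged = []
    for seg in segments:
        if merged:
            prev = merged[-1]
            gap = t[seg[0]] - t[prev[1] - 1]
            if gap < min_rest_s:
                merged[-1] = (prev[0], seg[1])
                continue
        merged.append(seg)
    return merged
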