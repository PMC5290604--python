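"""Long-format 24-h monitoring profiles: reading, QC and binned averages.

The on-disk format is a long CSV with one row per reading (subject id, time,
BP value in mmHg) plus diary wake/sleep columns and optional covariates.
Times are either ``"HH:MM"`` clock strings or numeric half-hour slots since
12:00 noon; the :class:`Schema` declares which.  Internally everything lives
on the [0, 48] half-hour axis so that a nominal complete record has 49
readings at integer slots 0..48.

QC implements the study-style inclusion rules: a minimum number of daytime
and night-time readings (night = the half-open diary interval
[sleep, wake)), and no run of consecutive missing nominal 30-min slots
longer than a configured maximum (default 4 slots = 2 hours).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ABPMProfile",
    "Schema",
    "QCReport",
    "QCRules",
    "read_profiles",
    "write_profiles",
    "classify_day_night",
    "qc_filter",
    "average_curve",
]

N_NOMINAL_SLOTS = 49  # integer slots 0..48


@dataclass(frozen=True)
class ABPMProfile:
    """One subject's 24-h record on the half-hour axis since 12:00 noon."""

    subject_id: str
    slots: np.ndarray  # strictly increasing, within [0, 48]
    values: np.ndarray  # mmHg, aligned to slots
    wake_time: float | None = None
    sleep_time: float | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        slots = np.asarray(self.slots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "slots", slots)
        object.__setattr__(self, "values", values)
        if slots.shape != values.shape:
            raise ValueError(f"{self.subject_id}: slots/values length mismatch")
        if slots.size and (slots.min() < 0 or slots.max() > 48):
            raise ValueError(f"{self.subject_id}: slots outside [0, 48]")
        if np.any(np.diff(slots) <= 0):
            raise ValueError(f"{self.subject_id}: slots not strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.subject_id}: non-finite BP values")

    @property
    def has_diary(self) -> bool:
        return self.wake_time is not None and self.sleep_time is not None

    @property
    def n_readings(self) -> int:
        return self.slots.size


@dataclass(frozen=True)
class Schema:
    """Column map for the long CSV dialect."""

    subject: str = "subject_id"
    time: str = "time"
    value: str = "sbp"
    wake: str | None = "wake_time"
    sleep: str | None = "sleep_time"
    covariates: tuple[str, ...] = ()
    time_format: str = "slot"  # "slot" (numeric half-hours) or "clock" ("HH:MM")


@dataclass(frozen=True)
class QCRules:
    min_day: int = 20
    min_night: int = 7
    max_gap_slots: int = 4  # "> two consecutive hourly intervals" = >4 half-hour slots


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    n_day: int
    n_night: int
    max_gap: int
    kept: bool
    reason: str  # "" if kept; else one primary reason code


def _clock_to_halfslots(text: str) -> float:
    hh, mm = text.strip().split(":")
    hours_since_noon = (int(hh) - 12) % 24
    return hours_since_noon * 2 + int(mm) / 30.0


def _parse_times(series: pd.Series, time_format: str) -> np.ndarray:
    if time_format == "slot":
        return pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    if time_format == "clock":
        out = np.empty(len(series), dtype=float)
        for i, v in enumerate(series):
            try:
                out[i] = _clock_to_halfslots(str(v))
            except (ValueError, AttributeError):
                out[i] = np.nan
        return out
    raise ValueError(f"unknown time_format {time_format!r}")


def read_profiles(path, schema: Schema = Schema()) -> list[ABPMProfile]:
    """Read a long-format CSV into one :class:`ABPMProfile` per subject.

    Clock times are unwrapped to the [0, 48] axis assuming readings are in
    chronological order starting at/after noon, so a final "12:00" row maps
    to slot 48 rather than 0.  Rows with missing BP or unparseable times are
    dropped with a logged warning; duplicate (subject, slot) pairs raise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    for col in (schema.subject, schema.time, schema.value):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    profiles: list[ABPMProfile] = []
    for sid, grp in df.groupby(schema.subject, sort=True):
        t = _parse_times(grp[schema.time], schema.time_format)
        y = pd.to_numeric(grp[schema.value], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(t)
        if bad.any():
            log.warning("%s: dropped %d rows with unparseable times", sid, int(bad.sum()))
        missing = ~np.isfinite(y) & ~bad
        if missing.any():
            log.warning("%s: dropped %d rows with missing BP", sid, int(missing.sum()))
        keep = np.isfinite(t) & np.isfinite(y)
        t, y = t[keep], y[keep]
        if schema.time_format == "clock":
            # unwrap: clock times repeat every 24 h; a non-increase means the
            # record crossed noon of the next day
            for i in range(1, t.size):
                if t[i] <= t[i - 1]:
                    t[i] += 48.0
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            raise ValueError(f"duplicate (subject, slot) pair: ({sid}, {t[dup[0]]})")

        def _diary(col):
            if col is None or col not in grp.columns:
                return None
            vals = grp[col].dropna()
            if vals.empty:
                return None
            if schema.time_format == "clock":
                return _clock_to_halfslots(str(vals.iloc[0]))
            return float(vals.iloc[0])

        covs = {}
        for c in schema.covariates:
            if c in grp.columns:
                v = grp[c].dropna()
                if not v.empty:
                    covs[c] = float(v.iloc[0])
        profiles.append(
            ABPMProfile(
                subject_id=str(sid),
                slots=t,
                values=y,
                wake_time=_diary(schema.wake),
                sleep_time=_diary(schema.sleep),
                covariates=covs,
            )
        )
    return profiles


def write_profiles(profiles, path, schema: Schema = Schema()) -> None:
    """Write profiles as long CSV (numeric slots; round-trips exactly)."""
    rows = []
    for p in profiles:
        for t, v in zip(p.slots, p.values):
            row = {
                schema.subject: p.subject_id,
                schema.time: t,
                schema.value: v,
                schema.wake: p.wake_time,
                schema.sleep: p.sleep_time,
            }
            for c in schema.covariates:
                row[c] = p.covariates.get(c)
            rows.append(row)
    cols = [schema.subject, schema.time, schema.value, schema.wake, schema.sleep]
    cols += list(schema.covariates)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def classify_day_night(profile: ABPMProfile) -> np.ndarray:
    """Label each reading "day" or "night" from the diary.

    Night is the half-open interval [sleep_time, wake_time): a reading
    exactly at wake time counts as day (deterministic tie-break).
    """
    if not profile.has_diary:
        raise ValueError(f"{profile.subject_id}: missing diary wake/sleep times")
    night = (profile.slots >= profile.sleep_time) & (profile.slots < profile.wake_time)
    return np.where(night, "night", "day")


def _longest_missing_run(slots: np.ndarray) -> int:
    """Longest run of consecutive unobserved nominal integer slots (0..48).

    A nominal slot is observed if some reading lies within half a slot of it.
    """
    observed = np.zeros(N_NOMINAL_SLOTS, dtype=bool)
    idx = np.clip(np.round(slots).astype(int), 0, N_NOMINAL_SLOTS - 1)
    near = np.abs(slots - idx) < 0.5 + 1e-9
    observed[idx[near]] = True
    best = run = 0
    for obs in observed:
        run = 0 if obs else run + 1
        best = max(best, run)
    return best


def qc_filter(
    profiles,
    rules: QCRules = QCRules(),
    diary_policy: str = "exclude",
) -> tuple[list[ABPMProfile], list[QCReport]]:
    """Apply the inclusion rules; returns (kept profiles, per-profile reports).

    Rules: day readings >= min_day, night readings >= min_night, and no run
    of more than ``max_gap_slots`` consecutive missing nominal 30-min slots.
    Each excluded profile carries exactly one primary reason, checked in the
    order missing_diary, min_day, min_night, max_gap.

    ``diary_policy``: "exclude" drops profiles without diary times;
    "impute_median" fills them with the cohort medians before classifying.
    """
    profiles = list(profiles)
    if diary_policy == "impute_median":
        wakes = [p.wake_time for p in profiles if p.wake_time is not None]
        sleeps = [p.sleep_time for p in profiles if p.sleep_time is not None]
        if wakes and sleeps:
            mw, ms = float(np.median(wakes)), float(np.median(sleeps))
            profiles = [
                p if p.has_diary else replace(p, wake_time=mw, sleep_time=ms)
                for p in profiles
            ]
    elif diary_policy != "exclude":
        raise ValueError(f"unknown diary policy {diary_policy!r}")

    kept, reports = [], []
    for p in profiles:
        if not p.has_diary:
            reports.append(QCReport(p.subject_id, 0, 0, _longest_missing_run(p.slots),
                                    False, "missing_diary"))
            continue
        labels = classify_day_night(p)
        n_day = int(np.sum(labels == "day"))
        n_night = int(np.sum(labels == "night"))
        gap = _longest_missing_run(p.slots)
        reason = ""
        if n_day < rules.min_day:
            reason = "min_day"
        elif n_night < rules.min_night:
            reason = "min_night"
        elif gap > rules.max_gap_slots:
            reason = "max_gap"
        ok = reason == ""
        reports.append(QCReport(p.subject_id, n_day, n_night, gap, ok, reason))
        if ok:
            kept.append(p)
    return kept, reports


def qc_report_frame(reports) -> pd.DataFrame:
    """QC reports as a tidy table (subject_id, n_day, n_night, max_gap, kept, reason)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "n_day": r.n_day,
                "n_night": r.n_night,
                "max_gap": r.max_gap,
                "kept": r.kept,
                "reason": r.reason,
            }
            for r in reports
        ]
    )


def average_curve(profiles, bin_width: float = 1.0) -> pd.DataFrame:
    """Cohort average BP in time bins: (bin midpoint, mean, n).

    Used for knot exploration: the bends of this curve motivate the common
    knot positions.  Bins with no readings are emitted with NaN mean.
    """
    profiles = list(profiles)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not profiles:
        raise ValueError("need at least one profile")
    edges = np.arange(0.0, 48.0 + bin_width, bin_width)
    if edges[-1] < 48.0:
        edges = np.append(edges, 48.0)
    t = np.concatenate([p.slots for p in profiles])
    y = np.concatenate([p.values for p in profiles])
    # final slot 48 belongs to the last bin
    which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    n = np.bincount(which, minlength=len(edges) - 1)
    sums = np.bincount(which, weights=y, minlength=len(edges) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"midpoint": (edges[:-1] + edges[1:]) / 2.0, "mean": means, "n": n}
    )
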