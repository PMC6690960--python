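"""Tumour-growth endpoints and survival analysis for the efficacy arm.

Caliper measurements (width, length, height) become ellipsoid volumes;
growth is expressed relative to the treatment-day baseline; the humane
endpoint (volume above 2000 mm³) defines the tumour-related-death event for
Kaplan–Meier curves and pairwise Mantel–Cox log-rank tests with a manual
Bonferroni correction over the pairwise comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumourTrack", "SurvivalRecord", "tumour_volume", "relative_growth",
    "doubling_event", "km_estimator", "logrank_pair", "bonferroni_threshold",
    "pairwise_logrank", "read_caliper_csv", "read_survival_csv",
]

ENDPOINT_VOLUME_MM3 = 2000.0


def tumour_volume(W: float, L: float, H: float) -> float:
    """Ellipsoid volume (4/3)π(W/2)(L/2)(H/2) = (π/6)·W·L·H, in mm³."""
    if W <= 0 or L <= 0 or H <= 0:
        raise ValueError("caliper dimensions must be positive")
    return math.pi / 6.0 * W * L * H


@dataclass
class TumourTrack:
    """Caliper series for one tumour: W/L/H in mm per measurement day."""

    animal_id: str
    group: str
    days: Sequence[float]
    W: Sequence[float]
    L: Sequence[float]
    H: Sequence[float]
    baseline_day: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        for name in ("W", "L", "H"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != d.shape:
                raise ValueError(f"{name} must align with days")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive where measured")
            setattr(self, name, v)
        self.days = d
        if self.baseline_day is None:
            self.baseline_day = float(d[0])

    def volumes(self) -> np.ndarray:
        return np.pi / 6.0 * self.W * self.L * self.H


@dataclass
class SurvivalRecord:
    """Time-to-event record: event=1 is tumour-related death, 0 censored."""

    animal_id: str
    group: str
    time_days: float
    event: int
    cause: str = ""

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def relative_growth(track: TumourTrack) -> pd.Series:
    """Volume relative to the baseline-day volume, indexed by day."""
    v = track.volumes()
    days = np.asarray(track.days)
    mask = days == track.baseline_day
    if not mask.any():
        raise ValueError(f"{track.animal_id}: no measurement on baseline day "
                         f"{track.baseline_day}")
    v0 = float(v[mask][0])
    return pd.Series(v / v0, index=days, name=track.animal_id)


def doubling_event(track: TumourTrack) -> float | None:
    """First measured day with relative growth ≥ 2, or None if never.

    The first crossing counts even if the tumour later regresses below 2×.
    """
    rg = relative_growth(track)
    hits = rg.index[rg.values >= 2.0]
    return float(hits[0]) if len(hits) else None


def km_estimator(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival curve.

    Returns a DataFrame (time, survival, at_risk) starting at S(0)=1, using
    lifelines under the hood.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    from lifelines import KaplanMeierFitter

    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(),
                         "at_risk": at_risk.to_numpy(dtype=float)})


def logrank_pair(a: Sequence[SurvivalRecord],
                 b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Mantel–Cox log-rank test between two groups.

    Returns (chi_square, p_value) from the observed-vs-expected statistic on
    the pooled risk sets, with the standard hypergeometric variance and
    pooled treatment of ties; p from χ² with 1 df.  With no events at all
    the test carries no information and returns (0, 1) with a warning.
    """
    ta = np.array([r.time_days for r in a]); ea = np.array([r.event for r in a])
    tb = np.array([r.time_days for r in b]); eb = np.array([r.event for r in b])
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d_mask = (times == t) & (events == 1)
        d = d_mask.sum()
        d1 = (d_mask & (grp == 0)).sum()
        e1 = d * n1 / n
        O_minus_E += d1 - e1
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = O_minus_E**2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold α/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def pairwise_logrank(records: Sequence[SurvivalRecord],
                     alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise log-rank tests with a Bonferroni-corrected threshold.

    The threshold is α divided by the number of pairwise comparisons
    (6 for four groups); `significant` flags p below that threshold.
    """
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    names = sorted(groups)
    pairs = list(combinations(names, 2))
    if not pairs:
        return pd.DataFrame(columns=["group_a", "group_b", "chi2", "p",
                                     "threshold", "significant"])
    thr = bonferroni_threshold(alpha, len(pairs))
    rows = []
    for ga, gb in pairs:
        chi2, p = logrank_pair(groups[ga], groups[gb])
        rows.append({"group_a": ga, "group_b": gb, "chi2": chi2, "p": p,
                     "threshold": thr, "significant": p < thr})
    return pd.DataFrame(rows)


def read_caliper_csv(path, baseline_day: float | None = None) -> list[TumourTrack]:
    """Read tumour tracks from CSV: animal_id, group, day, W_mm, L_mm, H_mm."""
    df = pd.read_csv(path)
    missing = {"animal_id", "group", "day", "W_mm", "L_mm", "H_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"caliper CSV missing columns: {sorted(missing)}")
    tracks = []
    for (animal, grp), sub in df.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("day")
        tracks.append(TumourTrack(
            animal_id=str(animal), group=str(grp),
            days=sub["day"].to_numpy(), W=sub["W_mm"].to_numpy(),
            L=sub["L_mm"].to_numpy(), H=sub["H_mm"].to_numpy(),
            baseline_day=baseline_day))
    return tracks


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read survival records from CSV: animal_id, group, time_days, event, cause."""
    df = pd.read_csv(path)
    missing = {"animal_id", "group", "time_days", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    return [SurvivalRecord(str(r["animal_id"]), str(r["group"]),
                           float(r["time_days"]), int(r["event"]),
                           str(r.get("cause", "")))
            for _, r in df.iterrows()]
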