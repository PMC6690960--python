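"""Ingrowth curve fitting and the free-daughter ratio statistic.

After an animal is sacrificed, inter-organ transport stops and the Bi-213
activity in each excised organ relaxes towards secular equilibrium with the
Ac-225 it contains.  Fitting the two-amplitude ingrowth model

    A₂(t) = A₁ (1 − e^{−λ₂ t}) + A₂(0) e^{−λ₂ t}

to the serial gamma counts gives A₂(0), the total Bi-213 present at
sacrifice (carrier-bound plus redistributed free daughter), and A₁, the
asymptote, i.e. the Bi-213 supported by the carrier-bound parent.  Their
ratio A₂(0)/A₁ is the free-daughter statistic: below 1 the organ was
shedding recoil daughters, above 1 it was collecting them from elsewhere.

The model is linear in (A₁, A₂(0)) once λ₂ is fixed, so the fit is an exact
(weighted) linear least-squares solve, never an iterative optimisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nuclides import BI213

__all__ = [
    "CountingSeries", "IngrowthFit", "RatioResult", "Classification",
    "ConditioningError", "fit_ingrowth", "extrapolate_A0", "free_ratio",
    "group_summary", "compare_groups", "read_counting_csv", "fit_cohort",
]


class ConditioningError(ValueError):
    """Raised when the counting schedule cannot separate the two amplitudes."""


class Classification(str, Enum):
    RELEASING = "releasing"
    ACCUMULATING = "accumulating"
    NEUTRAL = "neutral"


@dataclass
class CountingSeries:
    """One organ's serial gamma counts, timed from the moment of sacrifice.

    ``times_min`` are minutes since sacrifice (strictly increasing, ≥ 0);
    ``values`` are activities or count rates in one consistent unit — the
    ratio statistic is scale-invariant so the unit never matters downstream.
    """

    animal_id: str
    organ: str
    times_min: Sequence[float]
    values: Sequence[float]
    window: str = "Bi-213 380-520 keV"
    mass_g: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and the same length")
        if np.any(t < 0):
            raise ValueError("times must be >= 0 (t=0 is sacrifice)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("values must be non-negative")
        self.times_min = t
        self.values = y

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass
class IngrowthFit:
    """Fitted ingrowth amplitudes with uncertainties.

    ``A_eq_hat`` estimates the equilibrium asymptote A₁ (parent-supported
    daughter activity); ``A0_hat`` estimates A₂(0), the daughter activity at
    sacrifice.  Standard errors come from the normal-equations covariance
    scaled by the residual variance.
    """

    A_eq_hat: float
    A0_hat: float
    se_A_eq: float
    se_A0: float
    cov_A_eq_A0: float
    residual_rms: float
    n_points: int
    lambda2_used: float
    animal_id: str = ""
    organ: str = ""
    group: str | None = None


@dataclass
class RatioResult:
    """Free-daughter ratio A₂(0)/A₁ for one organ of one animal."""

    animal_id: str
    organ: str
    ratio: float
    se: float
    classification: Classification
    group: str | None = None


def fit_ingrowth(series: CountingSeries, lambda2: float | None = None,
                 weighting: str = "none") -> IngrowthFit:
    """Fit the two-amplitude ingrowth model to one counting series.

    Parameters
    ----------
    series : CountingSeries
        At least 3 points; a span shorter than 2/λ₂ triggers a warning
        because the asymptote is then poorly constrained.
    lambda2 : float, optional
        Daughter decay constant in min⁻¹.  Defaults to Bi-213.
    weighting : {"none", "poisson"}
        "poisson" weights each point by 1/max(y, 1), appropriate when values
        are raw counts.

    Returns
    -------
    IngrowthFit
    """
    if lambda2 is None:
        lambda2 = BI213.lam_per_min
    if not lambda2 > 0:
        raise ValueError("lambda2 must be positive")
    if len(series) < 3:
        raise ValueError("at least 3 points are required to fit the ingrowth model")
    t = series.times_min
    y = series.values
    span = t[-1] - t[0]
    if span < 2.0 / lambda2:
        warnings.warn(
            f"counting span {span:.1f} min is below 2/lambda2 = {2/lambda2:.1f} min; "
            "the equilibrium amplitude may be poorly constrained", stacklevel=2)

    e = np.exp(-lambda2 * t)
    X = np.column_stack([1.0 - e, e])  # columns: A_eq, A0
    if weighting == "none":
        w = np.ones_like(y)
    elif weighting == "poisson":
        w = 1.0 / np.clip(y, 1.0, None)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    sv = np.linalg.svd(Xw, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ConditioningError(
            "singular design: the schedule does not separate A0 from A_eq "
            "(all times near 0 or all far beyond 1/lambda2)")
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    resid = y - X @ beta
    n = len(y)
    dof = n - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    return IngrowthFit(
        A_eq_hat=float(beta[0]), A0_hat=float(beta[1]),
        se_A_eq=math.sqrt(max(cov[0, 0], 0.0)), se_A0=math.sqrt(max(cov[1, 1], 0.0)),
        cov_A_eq_A0=float(cov[0, 1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=n, lambda2_used=lambda2,
        animal_id=series.animal_id, organ=series.organ, group=series.group,
    )


def extrapolate_A0(fit: IngrowthFit) -> tuple[float, float]:
    """Back-extrapolated daughter activity at sacrifice, with its SE.

    This is the model evaluated at t = 0, i.e. the fitted A₂(0).  Under
    noise it can come out slightly negative; it is reported as-is (clip
    downstream if a physical bound is needed).
    """
    if fit.A0_hat < 0:
        warnings.warn(
            f"{fit.animal_id}/{fit.organ}: fitted A0 is negative "
            f"({fit.A0_hat:.3g}); plausible only as noise around zero", stacklevel=2)
    return fit.A0_hat, fit.se_A0


def free_ratio(fit: IngrowthFit, neutral_band: float = 0.0) -> RatioResult:
    """Free-daughter ratio A₂(0)/A₁ with first-order error propagation.

    Classification: releasing if ratio < 1 − band, accumulating if
    ratio > 1 + band, else neutral.  Raises if the equilibrium amplitude is
    not positive — an organ with no carrier signal has an undefined ratio and
    its A₂(0) alone should be reported.
    """
    if not fit.A_eq_hat > 0:
        raise ValueError(
            f"{fit.animal_id}/{fit.organ}: equilibrium amplitude "
            f"{fit.A_eq_hat:.3g} <= 0; ratio undefined — report A0_hat alone")
    r = fit.A0_hat / fit.A_eq_hat
    # var(a/b) ≈ r² [ (σa/a)² + (σb/b)² − 2 cov/(a b) ], guarded at a=0
    var = (fit.se_A0 / fit.A_eq_hat) ** 2 \
        + (r * fit.se_A_eq / fit.A_eq_hat) ** 2 \
        - 2.0 * r * fit.cov_A_eq_A0 / fit.A_eq_hat**2
    se = math.sqrt(max(var, 0.0))
    if r < 1.0 - neutral_band:
        cls = Classification.RELEASING
    elif r > 1.0 + neutral_band:
        cls = Classification.ACCUMULATING
    else:
        cls = Classification.NEUTRAL
    return RatioResult(animal_id=fit.animal_id, organ=fit.organ, ratio=r, se=se,
                       classification=cls, group=fit.group)


def group_summary(results: Sequence[RatioResult] | Sequence[IngrowthFit],
                  mode: str = "per_animal") -> pd.DataFrame:
    """Per-organ × group summary of the free-daughter ratio.

    mode="per_animal" (default): mean and sample SD of the per-animal
    ratios, the convention that ties the quoted uncertainty to between-mouse
    variation.  mode="pooled": ratio of the group-mean amplitudes
    mean(A₂(0))/mean(A₁), which requires `IngrowthFit` inputs; the two modes
    differ whenever per-animal amplitudes vary.
    """
    if len(results) == 0:
        raise ValueError("empty result list")
    if mode == "per_animal":
        if not isinstance(results[0], RatioResult):
            results = [free_ratio(f) for f in results]
        df = pd.DataFrame([{"group": r.group, "organ": r.organ, "ratio": r.ratio}
                           for r in results])
        out = (df.groupby(["group", "organ"], dropna=False)["ratio"]
                 .agg(mean="mean", sd="std", n="count").reset_index())
        return out
    if mode == "pooled":
        if not isinstance(results[0], IngrowthFit):
            raise ValueError("pooled mode needs IngrowthFit inputs (amplitudes)")
        df = pd.DataFrame([{"group": f.group, "organ": f.organ,
                            "A0": f.A0_hat, "A_eq": f.A_eq_hat} for f in results])
        g = df.groupby(["group", "organ"], dropna=False).agg(
            A0_mean=("A0", "mean"), A_eq_mean=("A_eq", "mean"), n=("A0", "count"))
        g["mean"] = g["A0_mean"] / g["A_eq_mean"]
        g["sd"] = float("nan")
        return g.reset_index()[["group", "organ", "mean", "sd", "n"]]
    raise ValueError(f"unknown mode {mode!r}")


def compare_groups(a: Sequence[float], b: Sequence[float],
                   mode: str = "welch") -> tuple[float, float]:
    """Two-sided t-test between two groups of per-animal values.

    Returns (p_value, t_statistic).  Modes: "welch" (default, unequal
    variances), "student" (pooled variance), "paired" (requires equal
    lengths; differences tested against zero).  Two identical
    zero-variance groups return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return (1.0, 0.0) if np.allclose(d, 0) else (0.0, math.inf)
        tstat = d.mean() / (sd / math.sqrt(len(d)))
        dof = len(d) - 1
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        if va == 0 and vb == 0:
            if a.mean() == b.mean():
                return 1.0, 0.0
            return 0.0, math.inf * math.copysign(1.0, a.mean() - b.mean())
        if mode == "student":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
            dof = na + nb - 2
        elif mode == "welch":
            se2 = va / na + vb / nb
            tstat = (a.mean() - b.mean()) / math.sqrt(se2)
            dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return float(min(p, 1.0)), float(tstat)


def read_counting_csv(path) -> list[CountingSeries]:
    """Read counting series from a tidy CSV.

    Expected columns: animal_id, group, organ, t_min, value, window (one row
    per measurement).
    """
    df = pd.read_csv(path)
    required = {"animal_id", "organ", "t_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counting CSV missing columns: {sorted(missing)}")
    out = []
    keys = ["animal_id", "organ"]
    for (animal, organ), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("t_min")
        out.append(CountingSeries(
            animal_id=str(animal), organ=str(organ),
            times_min=sub["t_min"].to_numpy(), values=sub["value"].to_numpy(),
            window=str(sub["window"].iloc[0]) if "window" in sub else "",
            group=str(sub["group"].iloc[0]) if "group" in sub else None,
        ))
    return out


def fit_cohort(series_list: Sequence[CountingSeries], lambda2: float | None = None,
               weighting: str = "none", neutral_band: float = 0.0) -> pd.DataFrame:
    """Fit every series and tabulate fits plus ratios (one row per organ/animal)."""
    rows = []
    for s in series_list:
        fit = fit_ingrowth(s, lambda2=lambda2, weighting=weighting)
        try:
            rr = free_ratio(fit, neutral_band=neutral_band)
            ratio, ratio_se, cls = rr.ratio, rr.se, rr.classification.value
        except ValueError:
            ratio, ratio_se, cls = float("nan"), float("nan"), "undefined"
        rows.append({
            "animal_id": fit.animal_id, "group": fit.group, "organ": fit.organ,
            "A_eq_hat": fit.A_eq_hat, "se_A_eq": fit.se_A_eq,
            "A0_hat": fit.A0_hat, "se_A0": fit.se_A0,
            "ratio": ratio, "ratio_se": ratio_se, "classification": cls,
            "n_points": fit.n_points, "residual_rms": fit.residual_rms,
        })
    return pd.DataFrame(rows)
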