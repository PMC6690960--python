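"""Synthetic cohorts with the statistical structure the analysis assumes.

No animal data ship with this package.  Instead, this module generates
every input the pipeline consumes — serial gamma-counting series, organ
masses, dose standards, caliper tracks and survival records — from an
explicit ground truth, so each stage can be validated by recovery tests.

The generative model:

* a carrier biodistribution assigns each organ an equilibrium %ID/g
  (daughter activity supported by carrier-bound parent);
* a single-shot redistribution step moves a per-organ fraction of daughter
  activity out of its source organ into a common pool, which splits between
  the kidneys, the urine, and the rest of the body.  This reflects the known
  fate of free Bi-213 (kidney-avid, partly excreted); no kinetic rates for
  the transport are modelled — redistribution is instantaneous at an
  effective time before sacrifice;
* post-sacrifice counting follows the two-amplitude ingrowth curve with
  Poisson counting noise on a fixed schedule (default 10-min cycles over
  18 h);
* tumours grow exponentially with between-animal lognormal variation in
  growth rate, an optional spontaneous-regression switch, and events at the
  2000 mm³ humane-endpoint volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .efficacy import ENDPOINT_VOLUME_MM3, SurvivalRecord, TumourTrack
from .ingrowth import CountingSeries
from .nuclides import BI213, LN2, ingrowth_activity

__all__ = [
    "OrganTruth", "RedistributionModel", "GroupSpec", "CohortBundle",
    "simulate_redistribution", "simulate_counting_series", "simulate_cohort",
    "simulate_tumour_cohort", "default_group_specs", "DEFAULT_SCHEDULE_MIN",
]

#: 10-min counting cycles over ~18 h, the cadence a single gamma counter
#: sustains for a small set of organ samples.
DEFAULT_SCHEDULE_MIN = np.arange(0.0, 1081.0, 10.0)

URINE = "urine"
REST = "rest"  # rest-of-body compartment (carcass); closes the mass balance


@dataclass
class OrganTruth:
    """Ground-truth activities for one organ, on the %ID/g scale.

    ``A_eq_true`` is the carrier-supported equilibrium daughter activity;
    ``A0_true`` the total daughter activity at sacrifice, i.e. retained
    carrier-bound daughter plus any redistributed free daughter.
    """

    organ: str
    A_eq_true: float
    A0_true: float
    mass_g: float

    def __post_init__(self) -> None:
        if self.A_eq_true < 0 or self.A0_true < 0 or self.mass_g <= 0:
            raise ValueError(f"{self.organ}: activities must be >= 0 and mass > 0")

    @property
    def ratio_true(self) -> float:
        return self.A0_true / self.A_eq_true if self.A_eq_true > 0 else float("nan")


@dataclass
class RedistributionModel:
    """Where released free daughter activity ends up.

    ``release_fraction`` maps each source organ to the fraction of its
    equilibrium daughter activity that escapes the carrier and leaves the
    organ before sacrifice.  The pooled free activity splits into
    kidney/urine/rest fractions, which must sum to 1.
    """

    release_fraction: Mapping[str, float]
    kidney_uptake_fraction: float = 0.40
    urine_fraction: float = 0.30
    other_fraction: float = 0.30

    def __post_init__(self) -> None:
        for organ, f in self.release_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"release fraction for {organ} not in [0, 1]")
        parts = (self.kidney_uptake_fraction, self.urine_fraction, self.other_fraction)
        if any(not 0 <= p <= 1 for p in parts):
            raise ValueError("destination fractions must be in [0, 1]")
        if abs(sum(parts) - 1.0) > 1e-9:
            raise ValueError(f"kidney+urine+other fractions sum to {sum(parts)}, not 1")


def simulate_redistribution(carrier_biodist: Mapping[str, float],
                            model: RedistributionModel,
                            masses: Mapping[str, float]) -> dict[str, OrganTruth]:
    """Apply one redistribution step to a carrier biodistribution.

    Activities are conserved: the mass-weighted total over all returned
    compartments (including urine and rest-of-body) equals the input total.

    Parameters
    ----------
    carrier_biodist : mapping organ → %ID/g at equilibrium.
    model : RedistributionModel
    masses : mapping organ → grams; may also provide masses for the
        ``urine`` and ``rest`` compartments (defaults 1 g and 15 g).
    """
    organs = list(carrier_biodist)
    totals = {}
    for o in organs:
        if o not in masses:
            raise ValueError(f"no mass given for organ {o!r}")
        if masses[o] <= 0:
            raise ValueError(f"mass for {o!r} must be positive")
        totals[o] = carrier_biodist[o] * masses[o]      # total %ID in organ

    released = {o: model.release_fraction.get(o, 0.0) * totals[o] for o in organs}
    pool = sum(released.values())
    received = {o: 0.0 for o in organs}
    for kidney_name in ("kidney", "kidneys"):
        if kidney_name in received:
            received[kidney_name] += model.kidney_uptake_fraction * pool
            break
    else:
        if model.kidney_uptake_fraction > 0 and pool > 0:
            raise ValueError("model routes activity to the kidney but no kidney organ given")

    out: dict[str, OrganTruth] = {}
    for o in organs:
        a0_total = totals[o] - released[o] + received[o]
        out[o] = OrganTruth(organ=o, A_eq_true=carrier_biodist[o],
                            A0_true=a0_total / masses[o], mass_g=masses[o])
    urine_mass = masses.get(URINE, 1.0)
    rest_mass = masses.get(REST, 15.0)
    out[URINE] = OrganTruth(URINE, 0.0, model.urine_fraction * pool / urine_mass, urine_mass)
    if REST in out:  # rest already a carrier organ: add on top
        prev = out[REST]
        out[REST] = OrganTruth(REST, prev.A_eq_true,
                               prev.A0_true + model.other_fraction * pool / prev.mass_g,
                               prev.mass_g)
    else:
        out[REST] = OrganTruth(REST, 0.0, model.other_fraction * pool / rest_mass, rest_mass)
    return out


def simulate_counting_series(truth: OrganTruth,
                             lambda2: float | None = None,
                             schedule_min: Sequence[float] = DEFAULT_SCHEDULE_MIN,
                             counts_per_unit: float | None = 200.0,
                             background_rate: float = 0.0,
                             rng: np.random.Generator | int | None = None,
                             animal_id: str = "sim", group: str | None = None,
                             ) -> CountingSeries:
    """Generate one organ's post-sacrifice counting series.

    The expected whole-organ activity follows the ingrowth curve between
    ``A0_true·mass`` and ``A_eq_true·mass``.  With ``counts_per_unit`` set,
    observed values are Poisson counts with mean
    ``expected · counts_per_unit + background_rate``; with
    ``counts_per_unit=None`` the exact expected activities are returned
    (noise-free mode).
    """
    if lambda2 is None:
        lambda2 = BI213.lam_per_min
    schedule = np.asarray(schedule_min, dtype=float)
    if schedule.size == 0:
        raise ValueError("empty counting schedule")
    a_eq = truth.A_eq_true * truth.mass_g
    a0 = truth.A0_true * truth.mass_g
    expected = ingrowth_activity(a_eq, a0, lambda2, schedule)
    if counts_per_unit is None:
        values = expected
    else:
        if not counts_per_unit > 0:
            raise ValueError("counts_per_unit must be positive")
        rng = np.random.default_rng(rng)
        values = rng.poisson(expected * counts_per_unit + background_rate).astype(float)
    return CountingSeries(animal_id=animal_id, organ=truth.organ,
                          times_min=schedule, values=values,
                          mass_g=truth.mass_g, group=group)


@dataclass
class GroupSpec:
    """Generative description of one treatment group.

    ``carrier_biodist`` are group-mean equilibrium %ID/g per organ;
    ``cv`` the between-animal lognormal coefficient of variation applied
    per animal and organ.
    """

    carrier_biodist: Mapping[str, float]
    model: RedistributionModel
    cv: float = 0.15
    masses: Mapping[str, float] = field(default_factory=dict)


#: Organ masses (g) typical for an adult mouse; blood is the total
#: collectable pool, rest-of-body closes the injected-dose balance.
DEFAULT_MASSES = {"blood": 1.7, "spleen": 0.1, "kidney": 0.4,
                  "tumour": 0.3, URINE: 1.0, REST: 15.0}


def default_group_specs() -> dict[str, GroupSpec]:
    """Two intravenous groups emulating the chelated vs co-precipitated carriers.

    Group means are chosen so the downstream free-daughter ratios come out
    near 0.06 (blood, chelated), 0.67 (spleen, chelated), 0.64 (spleen,
    co-precipitated) and several-fold accumulation in the kidney.  The
    rest-of-body compartment absorbs the remaining injected dose.
    """
    masses = dict(DEFAULT_MASSES)

    def _with_rest(biodist: dict[str, float]) -> dict[str, float]:
        used = sum(biodist[o] * masses[o] for o in biodist)
        out = dict(biodist)
        out[REST] = max(100.0 - used, 0.0) / masses[REST]
        return out

    dtpa = GroupSpec(
        carrier_biodist=_with_rest({"blood": 17.9, "spleen": 86.0, "kidney": 4.7}),
        model=RedistributionModel(
            release_fraction={"blood": 0.94, "spleen": 0.33, "kidney": 0.0, REST: 0.0}),
        cv=0.15, masses=masses)
    inpo4 = GroupSpec(
        carrier_biodist=_with_rest({"blood": 8.8, "spleen": 69.0, "kidney": 2.6}),
        model=RedistributionModel(
            release_fraction={"blood": 0.875, "spleen": 0.36, "kidney": 0.0, REST: 0.0}),
        cv=0.15, masses=masses)
    return {"DTPA": dtpa, "InPO4": inpo4}


@dataclass
class CohortBundle:
    """Everything a pipeline run consumes, as tidy DataFrames plus the truth."""

    counting: pd.DataFrame     # animal_id, group, organ, t_min, value, window
    organs: pd.DataFrame       # animal_id, group, organ, mass_g, rate_cpm, window, t_count_min
    standards: pd.DataFrame    # id, rate_cpm, fraction_of_injected, t_count_min
    truth: dict                # group → animal → organ → {A_eq, A0, mass_g}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("counting", self.counting), ("organs", self.organs),
                         ("standards", self.standards)]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        p = outdir / "truth.json"
        p.write_text(json.dumps(self.truth, indent=1))
        paths["truth"] = p
        return paths


def simulate_cohort(n_per_group: int = 5,
                    group_specs: Mapping[str, GroupSpec] | None = None,
                    seed: int | None = None,
                    schedule_min: Sequence[float] = DEFAULT_SCHEDULE_MIN,
                    counts_per_unit: float | None = 200.0,
                    measured_organs: Sequence[str] = ("blood", "spleen", "kidney"),
                    ) -> CohortBundle:
    """Simulate a full retention study: per-animal truths, counts, standards.

    Per-animal organ activities are drawn lognormally around the group means
    with the group CV, redistribution is applied per animal, and every
    measured organ gets a counting series on the shared schedule.  The dose
    standard is a 1% aliquot counted on the same scale as the organs.
    ``counts_per_unit=None`` produces noise-free series (CV still applies
    unless the group CV is 0).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if group_specs is None:
        group_specs = default_group_specs()
    rng = np.random.default_rng(seed)
    cpu = counts_per_unit if counts_per_unit is not None else 200.0

    counting_rows, organ_rows, std_rows = [], [], []
    truth: dict = {}
    for gname, spec in group_specs.items():
        truth[gname] = {}
        sigma = np.sqrt(np.log(1.0 + spec.cv**2)) if spec.cv > 0 else 0.0
        masses = {**DEFAULT_MASSES, **dict(spec.masses)}
        for k in range(n_per_group):
            animal = f"{gname}-{k + 1:02d}"
            biodist = {}
            for o, mean_pct in spec.carrier_biodist.items():
                if sigma > 0:
                    draw = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                else:
                    draw = 1.0
                biodist[o] = mean_pct * draw
            truths = simulate_redistribution(biodist, spec.model, masses)
            truth[gname][animal] = {o: {"A_eq": t.A_eq_true, "A0": t.A0_true,
                                        "mass_g": t.mass_g}
                                    for o, t in truths.items()}
            for o in measured_organs:
                t = truths[o]
                series = simulate_counting_series(
                    t, schedule_min=schedule_min, counts_per_unit=counts_per_unit,
                    rng=rng, animal_id=animal, group=gname)
                counting_rows += [{"animal_id": animal, "group": gname, "organ": o,
                                   "t_min": tm, "value": v, "window": series.window}
                                  for tm, v in zip(series.times_min, series.values)]
                # equilibrium count for the biodistribution table
                eq_rate = t.A_eq_true * t.mass_g * cpu
                organ_rows.append({"animal_id": animal, "group": gname, "organ": o,
                                   "mass_g": t.mass_g, "rate_cpm": eq_rate,
                                   "window": "Fr-221 170-270 keV",
                                   "t_count_min": float(np.max(schedule_min))})
            std_rows.append({"id": animal, "rate_cpm": cpu,
                             "fraction_of_injected": 0.01,
                             "t_count_min": float(np.max(schedule_min))})
    return CohortBundle(counting=pd.DataFrame(counting_rows),
                        organs=pd.DataFrame(organ_rows),
                        standards=pd.DataFrame(std_rows), truth=truth)


def simulate_tumour_cohort(n: int = 8,
                           growth_rate: float = LN2 / 18.0,
                           growth_cv: float = 0.5,
                           regress_prob: float = 0.25,
                           treatment_effect: float = 1.0,
                           v0_mm3: float = 100.0,
                           censor_day: float = 115.0,
                           measure_interval_days: float = 3.5,
                           group: str = "untreated",
                           seed: int | None = None,
                           ) -> tuple[list[TumourTrack], list[SurvivalRecord]]:
    """Simulate tumour growth tracks and the derived survival records.

    V(t) = V₀ e^{g·t} with per-animal lognormal g (median
    ``growth_rate · treatment_effect``); with probability ``regress_prob``
    the tumour switches to shrinkage at a random day.  The default median
    growth rate gives an untreated doubling time of 18 days; caliper
    measurements are twice weekly; the event is the first measurement day
    with volume above 2000 mm³, otherwise censoring at ``censor_day``.
    """
    if not 0 <= regress_prob <= 1:
        raise ValueError("regress_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, censor_day + 1e-9, measure_interval_days)
    sigma = np.sqrt(np.log(1.0 + growth_cv**2)) if growth_cv > 0 else 0.0
    tracks, records = [], []
    for k in range(n):
        animal = f"{group}-{k + 1:02d}"
        base = growth_rate * treatment_effect
        g = base * (rng.lognormal(0.0, sigma) if sigma > 0 else 1.0)
        regress = rng.random() < regress_prob
        switch_day = rng.uniform(14.0, 60.0) if regress else np.inf
        v = v0_mm3 * np.exp(g * days)
        if np.isfinite(switch_day):
            late = days > switch_day
            v[late] = v0_mm3 * np.exp(g * switch_day) * np.exp(-g * (days[late] - switch_day))
        d = np.cbrt(6.0 * v / np.pi)         # sphere-equivalent caliper reading
        tracks.append(TumourTrack(animal_id=animal, group=group, days=days,
                                  W=d, L=d, H=d, baseline_day=0.0))
        over = days[v > ENDPOINT_VOLUME_MM3]
        if len(over):
            records.append(SurvivalRecord(animal, group, float(over[0]), 1,
                                          cause="tumour volume > 2000 mm3"))
        else:
            records.append(SurvivalRecord(animal, group, float(censor_day), 0,
                                          cause="end of study"))
    return tracks, records
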