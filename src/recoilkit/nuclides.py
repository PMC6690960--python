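"""Decay-chain physics for alpha-emitter carrier studies.

The ²²⁵Ac decay chain (²²⁵Ac → ²²¹Fr → ²¹⁷At → ²¹³Bi → …) underlies every
computation in this package.  This module holds the nuclide constants, the
two-amplitude daughter-ingrowth model used to back-extrapolate post-sacrifice
gamma counts, generic decay correction, and an analytic Bateman solver for
arbitrary acyclic chains that serves as the simulation ground truth.

Time convention: `Nuclide` stores half-lives in seconds (SI); user-facing
kinetics helpers accept any consistent time unit because they take the decay
constant explicitly.  CSV and CLI boundaries use minutes, matching how
gamma-counter schedules are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

LN2 = math.log(2.0)

_UNIT_SECONDS = {"s": 1.0, "min": 60.0, "h": 3600.0, "d": 86400.0}


class ChainStructureError(ValueError):
    """Raised for cyclic or ill-ordered decay chains."""


def decay_constant(half_life: float) -> float:
    """Decay constant λ = ln2 / t½, in the reciprocal of the input unit.

    Parameters
    ----------
    half_life : float
        Half-life in any time unit; must be positive.
    """
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life!r}")
    return LN2 / half_life


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide with the constants needed for gamma counting.

    Attributes
    ----------
    name : str
        Conventional symbol, e.g. ``"Ac-225"``.
    half_life_s : float
        Half-life in seconds.
    gamma_line_kev : float or None
        Principal gamma line used for counting, if any.
    counting_window_kev : tuple or None
        Closed (lo, hi) energy window of the counter.
    branching_fraction : float
        Fraction of parent decays feeding this nuclide (1.0 for a root).
    """

    name: str
    half_life_s: float
    gamma_line_kev: float | None = None
    counting_window_kev: tuple[float, float] | None = None
    branching_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.half_life_s > 0:
            raise ValueError(f"{self.name}: half-life must be positive")
        if not 0 < self.branching_fraction <= 1:
            raise ValueError(f"{self.name}: branching fraction must be in (0, 1]")
        if self.counting_window_kev is not None:
            lo, hi = self.counting_window_kev
            if not lo < hi:
                raise ValueError(f"{self.name}: counting window must be a non-empty interval")

    @property
    def lam(self) -> float:
        """Decay constant in s⁻¹."""
        return decay_constant(self.half_life_s)

    @property
    def lam_per_min(self) -> float:
        """Decay constant in min⁻¹."""
        return decay_constant(self.half_life_s / 60.0)


# Printed half-lives from the study this package models: 10 d for Ac-225,
# 4.8 min for Fr-221, 45.6 min for Bi-213.  Override via a YAML nuclide table
# if evaluated-data values are preferred.
AC225 = Nuclide("Ac-225", half_life_s=10 * 86400.0)
FR221 = Nuclide("Fr-221", half_life_s=4.8 * 60.0, gamma_line_kev=218.0,
                counting_window_kev=(170.0, 270.0))
BI213 = Nuclide("Bi-213", half_life_s=45.6 * 60.0, gamma_line_kev=440.0,
                counting_window_kev=(380.0, 520.0))


@dataclass
class DecayChain:
    """An acyclic decay chain given as members plus parent→daughter edges.

    ``members`` must be topologically ordered (every parent precedes its
    daughters).  ``edges`` maps (parent_name, daughter_name) → branching
    fraction; outgoing fractions from any member must sum to ≤ 1.
    """

    members: Sequence[Nuclide]
    edges: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n.name for n in self.members]
        if len(set(names)) != len(names):
            raise ChainStructureError("duplicate nuclide names in chain")
        index = {n: i for i, n in enumerate(names)}
        outgoing: dict[str, float] = {}
        has_parent = set()
        for (p, d), bf in self.edges.items():
            if p not in index or d not in index:
                raise ChainStructureError(f"edge ({p}, {d}) references unknown member")
            if index[p] >= index[d]:
                raise ChainStructureError(
                    f"edge ({p}, {d}) violates topological order (cycle or misordering)")
            if not 0 < bf <= 1:
                raise ChainStructureError(f"edge ({p}, {d}) branching {bf} not in (0, 1]")
            outgoing[p] = outgoing.get(p, 0.0) + bf
            has_parent.add(d)
        for p, total in outgoing.items():
            if total > 1 + 1e-12:
                raise ChainStructureError(f"outgoing branching from {p} sums to {total} > 1")
        for n in names[1:]:
            if n not in has_parent:
                raise ChainStructureError(f"non-root member {n} has no parent in the chain")

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.members]

    def parents_of(self, name: str) -> list[tuple[str, float]]:
        return [(p, bf) for (p, d), bf in self.edges.items() if d == name]


def default_chain() -> DecayChain:
    """Two-member Ac-225 → Bi-213 chain used throughout the analysis.

    At-217 (sub-second half-life) is merged into the Fr-221 → Bi-213 edge and
    the chain stops at Bi-213: nothing below it is measured in a 380–520 keV
    window, and Fr-221 equilibrates within minutes.  Configure an explicit
    longer chain via :func:`load_nuclide_table` if needed.
    """
    return DecayChain(members=[AC225, BI213], edges={("Ac-225", "Bi-213"): 1.0})


def load_nuclide_table(path: str) -> list[Nuclide]:
    """Load nuclides from a YAML table.

    Each entry has keys ``name``, ``half_life_value``, ``half_life_unit``
    (s/min/h/d) and optionally ``gamma_line_kev``, ``window_kev`` ([lo, hi])
    and ``branching``.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    out = []
    for e in entries:
        unit = e["half_life_unit"]
        if unit not in _UNIT_SECONDS:
            raise ValueError(f"unknown half-life unit {unit!r}")
        window = tuple(e["window_kev"]) if e.get("window_kev") else None
        out.append(Nuclide(
            name=e["name"],
            half_life_s=float(e["half_life_value"]) * _UNIT_SECONDS[unit],
            gamma_line_kev=e.get("gamma_line_kev"),
            counting_window_kev=window,
            branching_fraction=float(e.get("branching", 1.0)),
        ))
    return out


def ingrowth_activity(A_parent: float, A_daughter_0: float, lambda2: float, t) -> np.ndarray | float:
    """Daughter activity under ingrowth towards a constant parent.

    A₂(t) = A₁ (1 − e^{−λ₂ t}) + A₂(0) e^{−λ₂ t}

    The parent activity A₁ is treated as constant over the measurement — for
    an 18 h count of Bi-213 growing towards 10-day Ac-225 the parent decays
    by ~0.5%, which is absorbed into the fitted asymptote.  Use
    :func:`bateman_activities` when parent decay matters.
    """
    if A_parent < 0 or A_daughter_0 < 0:
        raise ValueError("activities must be non-negative")
    if not lambda2 > 0:
        raise ValueError("lambda2 must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    e = np.exp(-lambda2 * t)
    out = A_parent * (1.0 - e) + A_daughter_0 * e
    return float(out) if out.ndim == 0 else out


def decay_correct(activity: float, lam: float, dt: float) -> float:
    """Reference an activity back to a time ``dt`` earlier: A · e^{+λ·dt}."""
    return activity * math.exp(lam * dt)


def equilibrium_activity_ratio(lambda1: float, lambda2: float) -> float:
    """Secular/transient equilibrium daughter:parent activity ratio λ₂/(λ₂−λ₁).

    Requires λ₂ > λ₁ > 0 (a daughter shorter-lived than its parent); for
    Bi-213 on Ac-225 the ratio is 1.003, which is why the daughter activity
    at equilibrium is read as the parent activity.
    """
    if not (lambda2 > lambda1 > 0):
        raise ValueError("requires lambda2 > lambda1 > 0")
    return lambda2 / (lambda2 - lambda1)


def bateman_activities(chain: DecayChain,
                       initial_activities: Mapping[str, float],
                       t) -> dict[str, np.ndarray | float]:
    """Exact activities of every chain member at time(s) ``t``.

    Analytic Bateman solution for an acyclic chain with branching: atom
    numbers are sums of exponentials whose coefficients are built recursively
    down the chain.  Decay constants are taken per second from the chain
    members, so ``t`` is in seconds.  Nearly-degenerate decay constants are
    perturbed by 1e-9 relative rather than switching to the confluent form.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    names = chain.names
    n = len(names)
    lams = np.array([m.lam for m in chain.members], dtype=float)
    # separate coincident decay constants (confluent case) by a tiny nudge
    order = np.argsort(lams)
    for a, b in zip(order[:-1], order[1:]):
        if abs(lams[b] - lams[a]) < 1e-9 * max(lams[a], lams[b]):
            lams[b] = lams[a] * (1.0 + 1e-9)

    A0 = np.array([float(initial_activities.get(nm, 0.0)) for nm in names])
    if np.any(A0 < 0):
        raise ValueError("initial activities must be non-negative")
    N0 = A0 / lams

    # N_i(t) = sum_j c[i, j] * exp(-lams[j] * t)
    c = np.zeros((n, n))
    parent_lists = [chain.parents_of(nm) for nm in names]
    idx = {nm: i for i, nm in enumerate(names)}
    for i in range(n):
        for pname, bf in parent_lists[i]:
            p = idx[pname]
            feed = bf * lams[p] * c[p]          # source coefficients per exponent
            for j in range(n):
                if j != i and feed[j] != 0.0:
                    c[i, j] += feed[j] / (lams[i] - lams[j])
        c[i, i] = N0[i] - (c[i].sum() - c[i, i])

    expt = np.exp(-np.outer(lams, np.atleast_1d(t)))   # (n_exponents, n_times)
    out: dict[str, np.ndarray | float] = {}
    for i, nm in enumerate(names):
        Ni = c[i] @ expt
        Ai = lams[i] * Ni
        out[nm] = float(Ai[0]) if t.ndim == 0 else Ai
    return out
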