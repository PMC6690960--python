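"""Biodistribution in %ID/g, labelling efficiencies and organ ratios.

Equilibrium gamma counts (Fr-221 window, which tracks Ac-225 once secular
equilibrium is reached) are converted to percent of injected dose per gram
of tissue against a counted dose standard, giving the carrier
biodistribution.  Loading and iTLC labelling efficiencies quantify how much
activity the carrier preparation actually captured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseStandard", "BiodistRecord", "percent_id_per_gram",
    "loading_efficiency", "itlc_labelling_efficiency", "organ_ratio",
    "biodist_table", "read_organs_csv", "read_standards_csv", "plot_biodist",
]


@dataclass(frozen=True)
class DoseStandard:
    """A counted aliquot representing a known fraction of the injected dose."""

    counts_rate: float                  # cpm of the standard
    fraction_of_injected: float         # e.g. 0.01 for a 1% aliquot
    count_time_ref_min: float = 0.0     # when it was counted, vs injection

    def __post_init__(self) -> None:
        if not self.counts_rate > 0:
            raise ValueError("standard counts_rate must be positive")
        if not 0 < self.fraction_of_injected <= 1:
            raise ValueError("fraction_of_injected must be in (0, 1]")

    @property
    def full_id_rate(self) -> float:
        """Count rate equivalent to 100% of the injected dose."""
        return self.counts_rate / self.fraction_of_injected


@dataclass
class BiodistRecord:
    """%ID/g of one organ of one animal at a stated window and time."""

    animal_id: str
    group: str
    organ: str
    mass_g: float
    pct_id_per_g: float
    nuclide_window: str = ""
    time_p_i_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.mass_g > 0:
            raise ValueError("organ mass must be positive")
        if self.pct_id_per_g < 0:
            raise ValueError("%ID/g cannot be negative")


def percent_id_per_gram(sample_rate: float, mass_g: float, standard: DoseStandard,
                        lam: float = 0.0, dt: float = 0.0) -> float:
    """Percent of injected dose per gram of tissue.

    100 · (sample_rate / full-ID rate) / mass, after decay-correcting the
    sample rate by e^{+λ·dt} to the standard's reference time (λ of the
    parent, since equilibrium windows track it).
    """
    if not mass_g > 0:
        raise ValueError("mass must be positive")
    if sample_rate < 0:
        raise ValueError("sample rate cannot be negative")
    corrected = sample_rate * math.exp(lam * dt)
    return 100.0 * (corrected / standard.full_id_rate) / mass_g


def loading_efficiency(fraction_activities: Sequence[float],
                       carrier_fraction_ids: Sequence[int]) -> float:
    """Percent of column-eluted activity found in the carrier fractions.

    ``fraction_activities`` is the activity per elution fraction;
    ``carrier_fraction_ids`` indexes the fractions that contain the carrier.
    """
    acts = np.asarray(fraction_activities, dtype=float)
    total = acts.sum()
    if not total > 0:
        raise ValueError("total activity must be positive")
    sel = list(carrier_fraction_ids)
    if not sel:
        import warnings
        warnings.warn("no carrier fractions selected; loading efficiency is 0", stacklevel=2)
        return 0.0
    return 100.0 * float(acts[sel].sum()) / float(total)


def itlc_labelling_efficiency(positions: Sequence[float], intensities: Sequence[float],
                              front_threshold: float) -> float:
    """Percent of strip activity that migrated with the mobile phase.

    Intensity at positions ≥ ``front_threshold`` counts as labelled (moved
    with the solvent front); everything else stayed at the origin.
    """
    pos = np.asarray(positions, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if pos.shape != inten.shape:
        raise ValueError("positions and intensities must align")
    total = inten.sum()
    if not total > 0:
        raise ValueError("all-zero lane profile")
    return 100.0 * float(inten[pos >= front_threshold].sum()) / float(total)


def organ_ratio(a: BiodistRecord, b: BiodistRecord) -> float:
    """Ratio of %ID/g between two organs (e.g. tumour:kidney)."""
    if not b.pct_id_per_g > 0:
        raise ValueError(f"denominator organ {b.organ} has no signal; ratio undefined")
    return a.pct_id_per_g / b.pct_id_per_g


def biodist_table(organs: pd.DataFrame, standards: Mapping[str, DoseStandard] | DoseStandard,
                  lam: float = 0.0) -> pd.DataFrame:
    """Convert an organ-count table into tidy BiodistRecord rows.

    ``organs`` columns: animal_id, group, organ, mass_g, rate_cpm, window,
    t_count_min.  ``standards`` is a single DoseStandard or a mapping
    animal_id → DoseStandard.
    """
    rows = []
    for _, r in organs.iterrows():
        std = standards if isinstance(standards, DoseStandard) else standards[str(r["animal_id"])]
        dt = std.count_time_ref_min - float(r.get("t_count_min", 0.0))
        pct = percent_id_per_gram(float(r["rate_cpm"]), float(r["mass_g"]), std,
                                  lam=lam, dt=-dt if dt < 0 else dt)
        rows.append({"animal_id": r["animal_id"], "group": r.get("group", ""),
                     "organ": r["organ"], "mass_g": float(r["mass_g"]),
                     "pct_id_per_g": pct, "window": r.get("window", ""),
                     "t_count_min": float(r.get("t_count_min", 0.0))})
    return pd.DataFrame(rows)


def read_organs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"animal_id", "organ", "mass_g", "rate_cpm"} - set(df.columns)
    if missing:
        raise ValueError(f"organ CSV missing columns: {sorted(missing)}")
    return df


def read_standards_csv(path) -> dict[str, DoseStandard]:
    df = pd.read_csv(path)
    missing = {"id", "rate_cpm", "fraction_of_injected"} - set(df.columns)
    if missing:
        raise ValueError(f"standards CSV missing columns: {sorted(missing)}")
    return {str(r["id"]): DoseStandard(float(r["rate_cpm"]),
                                       float(r["fraction_of_injected"]),
                                       float(r.get("t_count_min", 0.0)))
            for _, r in df.iterrows()}


def plot_biodist(table: pd.DataFrame, path=None):
    """Grouped bar chart of mean ± SD %ID/g per organ and group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = (table.groupby(["organ", "group"])["pct_id_per_g"]
              .agg(["mean", "std"]).reset_index())
    organs = list(g["organ"].unique())
    groups = list(g["group"].unique())
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(max(6, len(organs)), 4))
    for k, grp in enumerate(groups):
        sub = g[g["group"] == grp].set_index("organ").reindex(organs)
        x = np.arange(len(organs)) + k * width
        ax.bar(x, sub["mean"], width=width, yerr=sub["std"], capsize=3, label=str(grp))
    ax.set_xticks(np.arange(len(organs)) + 0.4 - width / 2)
    ax.set_xticklabels(organs, rotation=45, ha="right")
    ax.set_ylabel("%ID/g")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
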