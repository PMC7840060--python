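"""Group summaries, trophic-offset arithmetic and dietary endmembers.

Between a food and its consumer's collagen the heavy isotopes are enriched
by roughly constant amounts; this module applies the study's fixed offsets:

* plants → consumer collagen: +4.8 ‰ δ13C, +4.0 ‰ δ15N
* prey collagen → consumer collagen: +0.8 ‰ δ13C, +4.0 ‰ δ15N

Those offsets are used in three directions: downward to estimate the forage
eaten by herbivores (a sample of the unmanured local vegetation), upward to
place "100 % of diet from X" endmembers next to the measured humans, and as
simple spacings Δhumans−animals / Δhumans−plants between group means.

Offsets here are treated as exact constants; their uncertainty belongs to
the Bayesian mixing model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .isodata import Dataset, crop_group_of
from .plantproc import CorrectionConstants, correct_charring

PROXIES = ("d13C", "d15N", "d34S")


@dataclass(frozen=True)
class OffsetModel:
    plant_to_collagen_d13C: float = 4.8
    collagen_to_collagen_d13C: float = 0.8
    diet_to_consumer_d15N: float = 4.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.plant_to_collagen_d13C,
                               self.collagen_to_collagen_d13C,
                               self.diet_to_consumer_d15N)):
            raise ValueError("trophic offsets must be non-negative")


@dataclass
class GroupSummary:
    """n/min/max/mean/sd per proxy for one labelled group (sd uses n−1)."""

    label: str
    n: dict = field(default_factory=dict)
    min: dict = field(default_factory=dict)
    max: dict = field(default_factory=dict)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


@dataclass
class Endmember:
    """Derived consumer-collagen signature for a 100 %-of-diet source."""

    label: str
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding used in reports (0.1 ‰, half away from zero)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


# ---------------------------------------------------------------------------
# dataset → analysis frame adapters

def plant_frame(dataset: Dataset, corrected: bool = True,
                constants: Optional[CorrectionConstants] = None
                ) -> pd.DataFrame:
    """Per-plant analysis table with crop group, raw or corrected values."""
    rows = []
    for s in dataset:
        for part, m in s.measurements.items():
            mm = m
            if corrected and not m.corrected:
                mm = correct_charring(m, constants)
            rows.append({"id": s.id, "phase": s.phase, "species": s.taxon,
                         "part": part, "crop_group": crop_group_of(s.taxon),
                         "photosynthesis": mm.photosynthesis,
                         "d13C": mm.d13C, "d15N": mm.d15N,
                         "pctC": mm.pctC, "pctN": mm.pctN,
                         "CN": mm.ratio_CN})
    return pd.DataFrame(rows)


def fauna_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for s in dataset:
        m = s.measurements.get("bone")
        if m is None:
            continue
        rows.append({"id": s.id, "phase": s.phase, "site": s.site,
                     "species": s.taxon, "d13C": m.d13C, "d15N": m.d15N,
                     "d34S": m.d34S})
    return pd.DataFrame(rows)


def human_frame(dataset: Dataset, tissue: str = "bone") -> pd.DataFrame:
    """Per-human proxy table for one tissue (bone, dentine or enamel)."""
    rows = []
    for s in dataset:
        m = s.measurements.get(tissue)
        if m is None:
            continue
        row = {"id": s.id, "site": s.site, "phase": s.phase, "sex": s.sex,
               "age_class": s.age_class, "grave_goods": s.grave_goods}
        if tissue == "enamel":
            row["d13C"] = m.d13C_enamel
        else:
            row["d13C"] = m.d13C
            row["d15N"] = m.d15N
            row["d34S"] = getattr(m, "d34S", None)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations

def summarize(frame: pd.DataFrame, by=None, proxies=("d13C", "d15N"),
              label: str = "all") -> list:
    """Group summaries over a tidy frame; missing values dropped per proxy.

    With ``by=None`` a single :class:`GroupSummary` labelled ``label`` is
    returned (in a one-element list).  All statistics keep full precision;
    rounding happens only at display.
    """
    if by is None:
        groups = [(label, frame)]
    else:
        groups = [("/".join(map(str, k)) if isinstance(k, tuple) else str(k), g)
                  for k, g in frame.groupby(by, sort=True)]
    out = []
    for lab, g in groups:
        gs = GroupSummary(lab)
        for p in proxies:
            vals = g[p].dropna() if p in g else pd.Series(dtype=float)
            gs.n[p] = int(vals.size)
            if vals.size:
                gs.min[p] = float(vals.min())
                gs.max[p] = float(vals.max())
                gs.mean[p] = float(vals.mean())
                gs.sd[p] = float(vals.std(ddof=1)) if vals.size > 1 else None
            else:
                gs.min[p] = gs.max[p] = gs.mean[p] = gs.sd[p] = None
        out.append(gs)
    return out


def summaries_frame(summaries: list) -> pd.DataFrame:
    """Tidy (group, proxy) table of n/min/max/mean/sd for reports."""
    rows = []
    for gs in summaries:
        for p, n in gs.n.items():
            rows.append({"group": gs.label, "proxy": p, "n": n,
                         "min": gs.min[p], "max": gs.max[p],
                         "mean": gs.mean[p], "sd": gs.sd[p]})
    return pd.DataFrame(rows)


def estimate_forage(animal_summary: GroupSummary,
                    offsets: Optional[OffsetModel] = None) -> Endmember:
    """Forage isotopic signature implied by herbivore collagen.

    Subtracts the plant→collagen offsets; the group sd is carried through
    unchanged (the offsets are treated as exact).
    """
    o = offsets or OffsetModel()
    return Endmember(
        label=f"forage of {animal_summary.label}",
        d13C_mean=animal_summary.mean["d13C"] - o.plant_to_collagen_d13C,
        d13C_sd=animal_summary.sd["d13C"],
        d15N_mean=animal_summary.mean["d15N"] - o.diet_to_consumer_d15N,
        d15N_sd=animal_summary.sd["d15N"])


def make_endmember(source_summary: GroupSummary, source_kind: str,
                   offsets: Optional[OffsetModel] = None,
                   label: Optional[str] = None) -> Endmember:
    """Consumer-collagen signature for a diet made 100 % of this source."""
    o = offsets or OffsetModel()
    if source_kind == "plant":
        d13 = o.plant_to_collagen_d13C
    elif source_kind == "animal_collagen":
        d13 = o.collagen_to_collagen_d13C
    else:
        raise ValueError(f"unknown source kind {source_kind!r}")
    return Endmember(
        label=label or f"100% {source_summary.label}",
        d13C_mean=source_summary.mean["d13C"] + d13,
        d13C_sd=source_summary.sd["d13C"],
        d15N_mean=source_summary.mean["d15N"] + o.diet_to_consumer_d15N,
        d15N_sd=source_summary.sd["d15N"])


def group_offset(group_a: GroupSummary, group_b: GroupSummary, proxy: str,
                 rounded: bool = False) -> float:
    """Difference of group means (A − B) on one proxy, in ‰.

    ``rounded=True`` reproduces report-style arithmetic: both means are
    display-rounded to 0.1 ‰ before differencing (how spacings are usually
    quoted in the literature); the default keeps full precision.
    """
    a, b = group_a.mean[proxy], group_b.mean[proxy]
    if a is None or b is None:
        raise ValueError(f"proxy {proxy!r} missing in one group")
    if rounded:
        return round_half_up(round_half_up(a) - round_half_up(b))
    return a - b


def herbivore_diet_subset(fauna_dataset: Dataset,
                          d15N_cutoff: float = 8.0) -> Dataset:
    """Terrestrial animals whose collagen indicates a herbivore diet.

    Fish are excluded, as are omnivores (pigs) whose δ15N exceeds the
    cutoff — those animals sit a trophic level up and would bias the
    forage/endmember estimates.
    """
    def keep(s):
        m = s.measurements.get("bone")
        if m is None or m.d15N is None:
            return False
        if "esox" in s.taxon.lower():
            return False
        if "sus" in s.taxon.lower() and m.d15N > d15N_cutoff:
            return False
        return True
    return fauna_dataset.subset(keep)
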