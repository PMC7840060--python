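"""Default wiring of the study analysis: QC → corrections → offsets → mixing.

Encodes the assemblage's standing configuration: the chronology-based
manual exclusion, the phase→plant-group pairing used for trophic spacings
and mixing sources, and the pooling of herbivore-diet animals where a
phase has too few individuals.  The command-line interface and the
reproduction scripts are thin layers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import isodata, mixing, qc, stats, trophic

#: Manual exclusions applied to the packaged human table (id, reason).
MANUAL_EXCLUSIONS = [("LeB1", "chronology")]

#: Human site → plant phase providing the coeval C3 cereal group.
SITE_PLANT_PHASE = {"LaBarmaz": "EBA", "Vufflens": "MBA_FBA",
                    "Tolochenaz": "FBA"}

#: Human site → fauna phase for the herbivore-diet meat source
#: (None = pooled across phases; the middle phase has only two animals).
SITE_FAUNA_PHASE = {"LaBarmaz": "EBA", "Vufflens": None,
                    "Tolochenaz": "FBA"}

HUMAN_SITES = ("LaBarmaz", "Vufflens", "Tolochenaz")


@dataclass
class StudyData:
    """Post-QC analysis sets and the frames derived from them."""

    plants: isodata.Dataset
    fauna: isodata.Dataset
    humans: isodata.Dataset
    fauna_retained: isodata.Dataset
    humans_retained: isodata.Dataset
    qc_results: dict = field(default_factory=dict)

    @property
    def plant_corrected(self) -> pd.DataFrame:
        return trophic.plant_frame(self.plants, corrected=True)

    @property
    def plant_raw(self) -> pd.DataFrame:
        return trophic.plant_frame(self.plants, corrected=False)

    @property
    def fauna_frame(self) -> pd.DataFrame:
        return trophic.fauna_frame(self.fauna_retained)

    def human_bone(self) -> pd.DataFrame:
        return trophic.human_frame(self.humans_retained, "bone")

    def human_dentine(self) -> pd.DataFrame:
        return trophic.human_frame(self.humans_retained, "dentine")

    def human_enamel(self) -> pd.DataFrame:
        return trophic.human_frame(self.humans_retained, "enamel")


def load_study(criteria: Optional[qc.QCCriteria] = None,
               manual_exclusions=None,
               plants: Optional[isodata.Dataset] = None,
               fauna: Optional[isodata.Dataset] = None,
               humans: Optional[isodata.Dataset] = None) -> StudyData:
    """Load tables (packaged by default), run QC, build the analysis sets."""
    plants = plants if plants is not None else isodata.load_plants()
    fauna = fauna if fauna is not None else isodata.load_fauna()
    humans = humans if humans is not None else isodata.load_humans()
    results = {}
    results.update(qc.screen_dataset(plants, criteria))
    results.update(qc.screen_dataset(fauna, criteria))
    results.update(qc.screen_dataset(humans, criteria))
    manual = MANUAL_EXCLUSIONS if manual_exclusions is None \
        else manual_exclusions
    manual = [(i, r) for i, r in manual if i in set(humans.ids())]
    fauna_ret = qc.apply_exclusions(fauna, results)
    humans_ret = qc.apply_exclusions(humans, results, manual)
    return StudyData(plants, fauna, humans, fauna_ret, humans_ret, results)


def _one(frame: pd.DataFrame, label: str) -> trophic.GroupSummary:
    return trophic.summarize(frame, label=label)[0]


def cereal_summary(study: StudyData, phase: str) -> trophic.GroupSummary:
    pf = study.plant_corrected
    sel = pf[(pf.phase == phase) & pf.crop_group.isin(["wheat", "barley"])]
    return _one(sel, f"{phase} C3 cereals")


def millet_summary(study: StudyData) -> trophic.GroupSummary:
    pf = study.plant_corrected
    return _one(pf[pf.crop_group == "millet"], "C4 cereals (millet)")


def herbivore_summary(study: StudyData,
                      phase: Optional[str] = None) -> trophic.GroupSummary:
    herb = trophic.fauna_frame(
        trophic.herbivore_diet_subset(study.fauna_retained))
    if phase is not None:
        herb = herb[herb.phase == phase]
    return _one(herb, f"herbivore-diet fauna ({phase or 'pooled'})")


def pike_summary(study: StudyData) -> trophic.GroupSummary:
    ff = study.fauna_frame
    return _one(ff[ff.species == "Esox lucius"], "pike")


def consumer_summary(study: StudyData, site: str) -> trophic.GroupSummary:
    hb = study.human_bone()
    return _one(hb[hb.site == site], f"{site} humans (bone)")


def site_scenario(study: StudyData, site: str,
                  include_fish: bool = True,
                  offsets: Optional[trophic.OffsetModel] = None,
                  offset_sd: float = mixing.DEFAULT_OFFSET_SD,
                  mcmc: Optional[mixing.MCMCConfig] = None
                  ) -> mixing.MixingScenario:
    """Four-source, two-proxy mixing scenario for one human group."""
    if site not in SITE_PLANT_PHASE:
        raise KeyError(f"no scenario configuration for site {site!r}")
    sources = [
        ("C3 cereals", cereal_summary(study, SITE_PLANT_PHASE[site]),
         "plant"),
        ("C4 cereals", millet_summary(study), "plant"),
        ("herbivore/pig meat",
         herbivore_summary(study, SITE_FAUNA_PHASE[site]),
         "animal_collagen"),
    ]
    if include_fish:
        sources.append(("freshwater fish", pike_summary(study),
                        "animal_collagen"))
    return mixing.build_scenario(
        consumer_summary(study, site), sources, offsets=offsets,
        offset_sd=offset_sd, mcmc=mcmc, label=site)


def offsets_table(study: StudyData,
                  offsets: Optional[trophic.OffsetModel] = None,
                  rounded: bool = True) -> pd.DataFrame:
    """Humans−animals and humans−plants spacings per site, in ‰."""
    rows = []
    for site in HUMAN_SITES:
        cons = consumer_summary(study, site)
        animals = herbivore_summary(study, SITE_FAUNA_PHASE[site])
        plants = cereal_summary(study, SITE_PLANT_PHASE[site])
        rows.append({
            "site": site,
            "d13C_humans_animals": trophic.group_offset(
                cons, animals, "d13C", rounded),
            "d15N_humans_animals": trophic.group_offset(
                cons, animals, "d15N", rounded),
            "d13C_humans_plants": trophic.group_offset(
                cons, plants, "d13C", rounded),
            "d15N_humans_plants": trophic.group_offset(
                cons, plants, "d15N", rounded),
        })
    return pd.DataFrame(rows)


def endmembers_table(study: StudyData,
                     offsets: Optional[trophic.OffsetModel] = None
                     ) -> pd.DataFrame:
    """100 %-diet endmembers and forage estimates per phase, in ‰."""
    rows = []
    for site in HUMAN_SITES:
        plant = cereal_summary(study, SITE_PLANT_PHASE[site])
        meat = herbivore_summary(study, SITE_FAUNA_PHASE[site])
        ems = [trophic.make_endmember(plant, "plant", offsets,
                                      f"{site}: 100% C3 cereals"),
               trophic.make_endmember(meat, "animal_collagen", offsets,
                                      f"{site}: 100% herbivore/pig meat"),
               trophic.estimate_forage(meat, offsets)]
        for e in ems:
            rows.append({"label": e.label, "d13C_mean": e.d13C_mean,
                         "d13C_sd": e.d13C_sd, "d15N_mean": e.d15N_mean,
                         "d15N_sd": e.d15N_sd})
    millet = millet_summary(study)
    pike = pike_summary(study)
    for gs, kind, lab in [(millet, "plant", "100% C4 cereals"),
                          (pike, "animal_collagen", "100% pike")]:
        e = trophic.make_endmember(gs, kind, offsets, lab)
        rows.append({"label": e.label, "d13C_mean": e.d13C_mean,
                     "d13C_sd": e.d13C_sd, "d15N_mean": e.d15N_mean,
                     "d15N_sd": e.d15N_sd})
    return pd.DataFrame(rows)


def default_battery(study: StudyData, seed: int = 0,
                    kw_resamples: int = 20000) -> pd.DataFrame:
    """The study's full nonparametric comparison battery, as a tidy table.

    Kruskal–Wallis p-values use Monte-Carlo permutation (seeded); two-group
    and paired comparisons use the exact enumerated tests.  Plant group
    comparisons run on the raw (uncorrected) values, matching how the
    assemblage-level plant results are reported.
    """
    rows = []

    def add(name, res):
        rows.append({"comparison": name, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n": "/".join(map(str, res.n)), "exact": res.exact})

    def kw(frame, proxy, by):
        groups = [d[proxy].dropna().values for _, d in frame.groupby(by)]
        groups = [g for g in groups if len(g) >= 2]
        return stats.kruskal_wallis(groups, method="permutation",
                                    n_resamples=kw_resamples, seed=seed)

    pr = study.plant_raw.dropna(subset=["d15N"])
    add("plants d15N by crop group", kw(pr, "d15N", "crop_group"))
    add("plants d13C by crop group", kw(pr, "d13C", "crop_group"))
    add("C3 plants d13C by crop group",
        kw(pr[pr.photosynthesis == "C3"], "d13C", "crop_group"))

    ff = study.fauna_frame
    terr = ff[ff.species != "Esox lucius"]
    add("fauna d15N by phase", kw(terr, "d15N", "phase"))
    add("fauna d13C by phase", kw(terr, "d13C", "phase"))
    add("fauna d34S by phase", kw(terr, "d34S", "phase"))
    eba = terr[terr.phase == "EBA"].d34S.dropna()
    fba = terr[terr.phase == "FBA"].d34S.dropna()
    add("fauna d34S EBA vs FBA",
        stats.wilcoxon_rank_sum_exact(eba.values, fba.values))

    hb, hd = study.human_bone(), study.human_dentine()
    he = study.human_enamel()
    for proxy in ("d15N", "d13C", "d34S"):
        add(f"human bone {proxy} by site", kw(hb, proxy, "site"))
    for proxy in ("d15N", "d13C"):
        add(f"human dentine {proxy} by site", kw(hd, proxy, "site"))
    add("human enamel d13C by site", kw(he, "d13C", "site"))

    paired = hb.merge(hd, on="id", suffixes=("_bone", "_dent"))
    for site in HUMAN_SITES:
        d = paired[paired.site_bone == site]
        for proxy in ("d13C", "d15N"):
            add(f"{site} bone vs dentine {proxy}",
                stats.wilcoxon_signed_rank_pratt_exact(
                    d[f"{proxy}_bone"].values, d[f"{proxy}_dent"].values))
        ds = hb[(hb.site == site)].dropna(subset=["d34S"])
        add(f"{site} bone d15N vs d34S (Spearman)",
            stats.spearman(ds.d15N.values, ds.d34S.values))
    return pd.DataFrame(rows)
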