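"""Domain types and table I/O for the multi-isotope Bronze Age diet study.

The study's measurement archive consists of three per-specimen tables:
charred plant remains (seeds and chaff), animal bone collagen, and human
bone/dentine collagen plus tooth-enamel carbonate.  This module defines the
typed in-memory representation (:class:`Specimen`, the tissue measurement
records, :class:`Dataset`) and strict CSV readers/writers for the three
table dialects, plus loaders for the packaged reference tables.

Conventions
-----------
* δ13C is reported in ‰ vs V-PDB, δ15N vs AIR, δ34S vs V-CDT.
* Blank CSV cells are missing values (``None``), never zero.
* Specimen ids are unique within a dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

SITES = {"LaBarmaz", "Vufflens", "Tolochenaz", "Rances", "ChensTougues",
         "Chindrieux", "ChensPlant"}
PHASES = {"EBA", "MBA", "MBA_FBA", "FBA"}
CATEGORIES = {"human", "fauna", "plant"}
TISSUES = {"bone", "dentine", "enamel", "seed", "chaff"}
SEXES = {"M", "F", "I", "unknown"}
AGE_CLASSES = {"child", "adolescent", "young_adult", "adult", "unknown"}
GRAVE_GOODS = {"present", "absent", "not_defined"}

#: Site → chronological phase for the three human cemeteries.
HUMAN_SITE_PHASE = {"LaBarmaz": "EBA", "Vufflens": "MBA", "Tolochenaz": "FBA"}

#: Taxa using the C4 photosynthetic pathway (broomcorn/foxtail millet).
C4_TAXA_KEYWORDS = ("panicum", "setaria")


def photosynthesis_of(taxon: str) -> str:
    """C3/C4 pathway from the taxon name (millets are the only C4 crops)."""
    t = taxon.lower()
    return "C4" if any(k in t for k in C4_TAXA_KEYWORDS) else "C3"


def crop_group_of(taxon: str) -> str:
    """Crop group used for all plant statistics: wheat/barley/pulses/millet."""
    t = taxon.lower()
    if "triticum" in t:
        return "wheat"
    if "hordeum" in t:
        return "barley"
    if "panicum" in t or "setaria" in t:
        return "millet"
    return "pulses"


@dataclass
class CollagenMeasurement:
    """Bone or dentine collagen isotopic and elemental data."""

    d13C: Optional[float] = None
    d15N: Optional[float] = None
    d34S: Optional[float] = None
    pctC: Optional[float] = None
    pctN: Optional[float] = None
    pctS: Optional[float] = None
    ratio_CN: Optional[float] = None
    ratio_CS: Optional[float] = None
    ratio_NS: Optional[float] = None
    yield_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pctC", "pctN", "pctS", "yield_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("ratio_CN", "ratio_CS", "ratio_NS"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name}={v} must be positive")


@dataclass
class PlantMeasurement:
    """Charred seed or chaff bulk isotopic data.

    ``corrected`` marks whether the charring/chaff correction constants have
    been applied; the packaged tables store raw (uncorrected) values.
    """

    d13C: Optional[float] = None
    d15N: Optional[float] = None
    pctC: Optional[float] = None
    pctN: Optional[float] = None
    ratio_CN: Optional[float] = None
    part: str = "seed"
    photosynthesis: str = "C3"
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.part not in {"seed", "chaff"}:
            raise ValueError(f"part={self.part!r} not seed/chaff")
        if self.photosynthesis not in {"C3", "C4"}:
            raise ValueError(f"photosynthesis={self.photosynthesis!r}")


@dataclass
class EnamelMeasurement:
    """Tooth-enamel carbonate data (whole-diet carbon proxy)."""

    d13C_enamel: Optional[float] = None
    carbonate_content: Optional[float] = None
    sample_weight_mg: Optional[float] = None
    co2_ml: Optional[float] = None

    def __post_init__(self) -> None:
        v = self.d13C_enamel
        if v is not None and not -30 <= v <= 5:
            raise ValueError(f"d13C_enamel={v} outside [-30, 5]")


@dataclass
class Specimen:
    """One sampled individual or seed, with zero or more tissue records."""

    id: str
    site: str
    phase: str
    category: str
    taxon: str = ""
    sex: str = "unknown"
    age_class: str = "unknown"
    grave_goods: str = "not_defined"
    burial: str = ""
    element: str = ""
    tooth: str = ""
    excluded_reason: Optional[str] = None
    qc_flag: Optional[str] = None
    measurements: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("specimen id must be non-empty")
        if self.site not in SITES:
            raise ValueError(f"{self.id}: unknown site {self.site!r}")
        if self.phase not in PHASES:
            raise ValueError(f"{self.id}: unknown phase {self.phase!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.id}: unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"{self.id}: unknown age class {self.age_class!r}")
        if self.grave_goods not in GRAVE_GOODS:
            raise ValueError(f"{self.id}: unknown grave goods {self.grave_goods!r}")


@dataclass
class Dataset:
    """An ordered collection of specimens sharing a table schema."""

    specimens: list = field(default_factory=list)
    schema: str = "humans"

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[Specimen]:
        return iter(self.specimens)

    def get(self, specimen_id: str) -> Specimen:
        for s in self.specimens:
            if s.id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def ids(self) -> list:
        return [s.id for s in self.specimens]

    def subset(self, predicate) -> "Dataset":
        return Dataset([s for s in self.specimens if predicate(s)], self.schema)

    def copy(self) -> "Dataset":
        out = []
        for s in self.specimens:
            out.append(replace(s, measurements=dict(s.measurements)))
        return Dataset(out, self.schema)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-specimen table in the schema's CSV dialect."""
        return pd.DataFrame([_row_of(s, self.schema) for s in self.specimens],
                            columns=SCHEMA_COLUMNS[self.schema])


SCHEMA_COLUMNS = {
    "plants": ["id", "phase", "species", "part",
               "pctN", "d15N", "pctC", "d13C", "CN"],
    "fauna": ["id", "phase", "site", "species", "element",
              "pctN", "d15N", "pctC", "d13C", "pctS", "d34S",
              "CN", "CS", "NS"],
    "humans": ["id", "site", "burial", "grave_goods", "element", "tooth",
               "sex", "age_class",
               "bone_pctN", "bone_d15N", "bone_pctC", "bone_d13C", "bone_CN",
               "bone_pctS", "bone_d34S", "bone_CS", "bone_NS",
               "dent_pctN", "dent_d15N", "dent_pctC", "dent_d13C",
               "enamel_carbonate", "enamel_d13C"],
}

_NUMERIC = {
    "plants": ["pctN", "d15N", "pctC", "d13C", "CN"],
    "fauna": ["pctN", "d15N", "pctC", "d13C", "pctS", "d34S", "CN", "CS", "NS"],
    "humans": [c for c in SCHEMA_COLUMNS["humans"]
               if c.startswith(("bone_", "dent_", "enamel_"))],
}


def _num(cell, col: str, row_id: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s in {"", "-", "nan"}:
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"row {row_id!r}: non-numeric value {s!r} in column {col!r}") from None


def read_table(path, schema: str) -> Dataset:
    """Read one of the three study tables from CSV.

    Raises ``ValueError`` on unknown columns, non-numeric isotope cells and
    duplicate ids; blank cells become missing values.  Rows the source marks
    as unusable (all-blank measurements) are retained — exclusion is the QC
    module's job.
    """
    if schema not in SCHEMA_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SCHEMA_COLUMNS[schema]
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown or missing:
        raise ValueError(f"{path}: column mismatch for schema {schema!r}: "
                         f"unknown={unknown} missing={missing}")
    specimens, seen = [], set()
    for _, row in df.iterrows():
        rid = row["id"].strip()
        if rid in seen:
            raise ValueError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        num = {c: _num(row[c], c, rid) for c in _NUMERIC[schema]}
        if schema == "plants":
            specimens.append(_plant_specimen(row, num))
        elif schema == "fauna":
            specimens.append(_fauna_specimen(row, num))
        else:
            specimens.append(_human_specimen(row, num))
    return Dataset(specimens, schema)


def _plant_specimen(row, num) -> Specimen:
    part = row["part"].strip() or "seed"
    meas = {}
    if any(v is not None for v in num.values()):
        meas[part] = PlantMeasurement(
            d13C=num["d13C"], d15N=num["d15N"], pctC=num["pctC"],
            pctN=num["pctN"], ratio_CN=num["CN"], part=part,
            photosynthesis=photosynthesis_of(row["species"]))
    return Specimen(id=row["id"].strip(), site="ChensPlant",
                    phase=row["phase"].strip(), category="plant",
                    taxon=row["species"].strip(), measurements=meas)


def _fauna_specimen(row, num) -> Specimen:
    meas = {"bone": CollagenMeasurement(
        d13C=num["d13C"], d15N=num["d15N"], d34S=num["d34S"],
        pctC=num["pctC"], pctN=num["pctN"], pctS=num["pctS"],
        ratio_CN=num["CN"], ratio_CS=num["CS"], ratio_NS=num["NS"])}
    return Specimen(id=row["id"].strip(), site=row["site"].strip(),
                    phase=row["phase"].strip(), category="fauna",
                    taxon=row["species"].strip(), element=row["element"].strip(),
                    measurements=meas)


def _human_specimen(row, num) -> Specimen:
    site = row["site"].strip()
    meas = {}
    bone = {k.removeprefix("bone_"): v for k, v in num.items()
            if k.startswith("bone_")}
    if any(v is not None for v in bone.values()):
        meas["bone"] = CollagenMeasurement(
            d13C=bone["d13C"], d15N=bone["d15N"], d34S=bone["d34S"],
            pctC=bone["pctC"], pctN=bone["pctN"], pctS=bone["pctS"],
            ratio_CN=bone["CN"], ratio_CS=bone["CS"], ratio_NS=bone["NS"])
    dent = {k.removeprefix("dent_"): v for k, v in num.items()
            if k.startswith("dent_")}
    if any(v is not None for v in dent.values()):
        meas["dentine"] = CollagenMeasurement(
            d13C=dent["d13C"], d15N=dent["d15N"],
            pctC=dent["pctC"], pctN=dent["pctN"])
    if num["enamel_d13C"] is not None or num["enamel_carbonate"] is not None:
        meas["enamel"] = EnamelMeasurement(
            d13C_enamel=num["enamel_d13C"],
            carbonate_content=num["enamel_carbonate"])
    return Specimen(
        id=row["id"].strip(), site=site,
        phase=HUMAN_SITE_PHASE.get(site, "EBA"), category="human",
        taxon="Homo sapiens", sex=row["sex"].strip() or "unknown",
        age_class=row["age_class"].strip() or "unknown",
        grave_goods=row["grave_goods"].strip() or "not_defined",
        burial=row["burial"].strip(), element=row["element"].strip(),
        tooth=row["tooth"].strip(), measurements=meas)


def _fmt(v) -> str:
    if v is None:
        return ""
    return f"{v:g}"


def _row_of(s: Specimen, schema: str) -> dict:
    if schema == "plants":
        m = next(iter(s.measurements.values()), None)
        part = m.part if m is not None else "seed"
        return {"id": s.id, "phase": s.phase, "species": s.taxon, "part": part,
                "pctN": _fmt(m.pctN if m else None),
                "d15N": _fmt(m.d15N if m else None),
                "pctC": _fmt(m.pctC if m else None),
                "d13C": _fmt(m.d13C if m else None),
                "CN": _fmt(m.ratio_CN if m else None)}
    if schema == "fauna":
        m = s.measurements.get("bone") or CollagenMeasurement()
        return {"id": s.id, "phase": s.phase, "site": s.site,
                "species": s.taxon, "element": s.element,
                "pctN": _fmt(m.pctN), "d15N": _fmt(m.d15N),
                "pctC": _fmt(m.pctC), "d13C": _fmt(m.d13C),
                "pctS": _fmt(m.pctS), "d34S": _fmt(m.d34S),
                "CN": _fmt(m.ratio_CN), "CS": _fmt(m.ratio_CS),
                "NS": _fmt(m.ratio_NS)}
    b = s.measurements.get("bone") or CollagenMeasurement()
    d = s.measurements.get("dentine") or CollagenMeasurement()
    e = s.measurements.get("enamel") or EnamelMeasurement()
    return {"id": s.id, "site": s.site, "burial": s.burial,
            "grave_goods": s.grave_goods, "element": s.element,
            "tooth": s.tooth, "sex": s.sex, "age_class": s.age_class,
            "bone_pctN": _fmt(b.pctN), "bone_d15N": _fmt(b.d15N),
            "bone_pctC": _fmt(b.pctC), "bone_d13C": _fmt(b.d13C),
            "bone_CN": _fmt(b.ratio_CN), "bone_pctS": _fmt(b.pctS),
            "bone_d34S": _fmt(b.d34S), "bone_CS": _fmt(b.ratio_CS),
            "bone_NS": _fmt(b.ratio_NS),
            "dent_pctN": _fmt(d.pctN), "dent_d15N": _fmt(d.d15N),
            "dent_pctC": _fmt(d.pctC), "dent_d13C": _fmt(d.d13C),
            "enamel_carbonate": _fmt(e.carbonate_content),
            "enamel_d13C": _fmt(e.d13C_enamel)}


def write_table(dataset: Dataset, path) -> None:
    """Write a dataset back to CSV; ``read_table(write_table(x)) == x``."""
    dataset.to_frame().to_csv(path, index=False)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("paleodiet").joinpath(f"data/{name}"))


def load_plants() -> Dataset:
    """Packaged plant table (30 specimens; one has no measurable material)."""
    return read_table(_fixture_path("plants.csv"), "plants")


def load_fauna() -> Dataset:
    """Packaged animal bone-collagen table (22 specimens incl. 4 pike)."""
    return read_table(_fixture_path("fauna.csv"), "fauna")


def load_humans() -> Dataset:
    """Packaged human table (41 individuals across three cemeteries)."""
    return read_table(_fixture_path("humans.csv"), "humans")
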