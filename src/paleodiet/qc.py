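"""Tiered preservation screening for collagen and charred-plant samples.

Collagen that has survived burial unaltered has a narrow compositional
envelope: extraction yield ≥ 1 %, %C ≥ 30, %N ≥ 10, %S ≥ 0.15, atomic
C:N inside (2.9, 3.6), C:S near 600 ± 300 and N:S near 200 ± 100.
Published studies routinely retain samples sitting *just* outside these
bounds "with caution" rather than discarding them; this module makes that
practice explicit and reproducible with a proportional caution margin:
a breach within the margin of a bound downgrades to ``caution``,
a breach beyond it is a ``fail``.

Two deliberate asymmetries, both configurable:

* C:S and N:S breaches never fail a sample on their own (severity is capped
  at caution).  The sulfur bands describe terrestrial mammal collagen;
  well-preserved freshwater fish collagen sits far outside them, and the
  study design retains fish on elemental criteria alone.
* The C:N margin is tighter than the elemental margins, and %S looser,
  reflecting how the source study adjudicated its borderline samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .isodata import (CollagenMeasurement, Dataset, PlantMeasurement,
                      Specimen)

PASS = "pass"
CAUTION = "caution"
FAIL = "fail"
NOT_ASSESSED = "not_assessed"

_STATUS_ORDER = {PASS: 0, CAUTION: 1, FAIL: 2}


@dataclass(frozen=True)
class Violation:
    criterion: str
    observed: float
    bound: str
    severity: str  # caution | fail


@dataclass
class QCCriteria:
    """Thresholds and caution margins for preservation screening."""

    yield_min: float = 1.0
    pctC_min: float = 30.0
    pctN_min: float = 10.0
    pctS_min: float = 0.15
    CN_range: tuple = (2.9, 3.6)       # open interval
    CS_center: float = 600.0
    CS_tol: float = 300.0
    NS_center: float = 200.0
    NS_tol: float = 100.0
    caution_margin: float = 0.15
    # per-criterion margin overrides (fraction of the bound)
    margin_overrides: dict = field(
        default_factory=lambda: {"CN": 0.12, "pctS": 0.20})
    # band (C:S, N:S) breaches cap at caution unless this is True
    sulfur_bands_can_fail: bool = False
    # charred-plant thresholds; %C and C:N are advisory (cap at caution)
    plant_pctC_min: float = 30.0
    plant_pctN_min: float = 0.4
    plant_CN_range: tuple = (5.0, 50.0)

    def __post_init__(self) -> None:
        if not 0 <= self.caution_margin <= 0.5:
            raise ValueError("caution_margin must be in [0, 0.5]")
        for name in ("yield_min", "pctC_min", "pctN_min", "pctS_min",
                     "CS_center", "CS_tol", "NS_center", "NS_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def margin(self, criterion: str) -> float:
        return self.margin_overrides.get(criterion, self.caution_margin)


@dataclass
class QCResult:
    specimen_id: str
    status: str
    violations: list = field(default_factory=list)
    tissue: str = "bone"
    notes: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == PASS

    @property
    def retained(self) -> bool:
        return self.status in (PASS, CAUTION)


def _check_min(name, value, bound, margin):
    """Lower-bound check with proportional caution slack below the bound."""
    if value is None or value >= bound:
        return None
    sev = CAUTION if value >= bound * (1 - margin) else FAIL
    return Violation(name, value, f">= {bound:g}", sev)


def _check_interval(name, value, lo, hi, margin):
    if value is None or lo < value < hi:
        return None
    sev = CAUTION if lo * (1 - margin) < value < hi * (1 + margin) else FAIL
    return Violation(name, value, f"({lo:g}, {hi:g})", sev)


def _check_band(name, value, center, tol, margin, can_fail):
    """Band check: near-edge inside the band is caution; outside the band is
    caution too unless ``can_fail`` and beyond the margin extension."""
    if value is None:
        return None
    dev = abs(value - center)
    if dev <= (1 - margin) * tol:
        return None
    if dev <= tol:
        return Violation(name, value, f"{center:g} ± {tol:g} (near edge)", CAUTION)
    sev = FAIL if can_fail and dev > tol * (1 + margin) else CAUTION
    return Violation(name, value, f"{center:g} ± {tol:g}", sev)


def screen_collagen(meas: CollagenMeasurement,
                    criteria: Optional[QCCriteria] = None,
                    specimen_id: str = "", tissue: str = "bone") -> QCResult:
    """Screen one collagen record against the preservation criteria.

    Missing fields skip their criterion (an absent extraction yield is not a
    violation); a record with no assessable field at all is ``not_assessed``.
    """
    c = criteria or QCCriteria()
    fields = (meas.pctC, meas.pctN, meas.pctS, meas.ratio_CN, meas.ratio_CS,
              meas.ratio_NS, meas.yield_pct)
    if all(v is None for v in fields):
        return QCResult(specimen_id, NOT_ASSESSED, tissue=tissue)
    checks = [
        _check_min("yield", meas.yield_pct, c.yield_min, c.margin("yield")),
        _check_min("pctC", meas.pctC, c.pctC_min, c.margin("pctC")),
        _check_min("pctN", meas.pctN, c.pctN_min, c.margin("pctN")),
        _check_min("pctS", meas.pctS, c.pctS_min, c.margin("pctS")),
        _check_interval("CN", meas.ratio_CN, *c.CN_range, c.margin("CN")),
        _check_band("CS", meas.ratio_CS, c.CS_center, c.CS_tol,
                    c.margin("CS"), c.sulfur_bands_can_fail),
        _check_band("NS", meas.ratio_NS, c.NS_center, c.NS_tol,
                    c.margin("NS"), c.sulfur_bands_can_fail),
    ]
    violations = [v for v in checks if v is not None]
    return QCResult(specimen_id, _status(violations), violations, tissue)


def screen_plant(meas: PlantMeasurement,
                 criteria: Optional[QCCriteria] = None,
                 specimen_id: str = "") -> QCResult:
    """Screen one charred seed or chaff sample.

    No consensual reliability criteria exist for charred material; %C and
    C:N are advisory (they downgrade to caution, never fail), and chaff is
    exempt from the C:N check entirely since its raw C:N is structurally
    high.
    """
    c = criteria or QCCriteria()
    if meas.pctC is None and meas.pctN is None:
        return QCResult(specimen_id, NOT_ASSESSED, tissue=meas.part)
    violations = []
    v = _check_min("pctC", meas.pctC, c.plant_pctC_min, c.caution_margin)
    if v is not None:
        violations.append(Violation(v.criterion, v.observed, v.bound, CAUTION))
    v = _check_min("pctN", meas.pctN, c.plant_pctN_min, c.caution_margin)
    if v is not None:
        violations.append(v)
    notes = []
    if meas.part == "chaff":
        notes.append("chaff exempt from C:N reliability criterion")
    else:
        v = _check_interval("CN", meas.ratio_CN, *c.plant_CN_range,
                            c.caution_margin)
        if v is not None:
            violations.append(Violation(v.criterion, v.observed, v.bound,
                                        CAUTION))
    return QCResult(specimen_id, _status(violations), violations, meas.part,
                    notes)


def _status(violations) -> str:
    if not violations:
        return PASS
    return FAIL if any(v.severity == FAIL for v in violations) else CAUTION


def screen_dataset(dataset: Dataset,
                   criteria: Optional[QCCriteria] = None) -> dict:
    """QC every measurement in a dataset.

    Returns ``{(specimen_id, tissue): QCResult}``.  Screening is per tissue:
    a human whose bone collagen fails may still contribute dentine and
    enamel.  Enamel has no agreed preservation criteria and is never failed.
    """
    results = {}
    for s in dataset:
        for tissue, meas in s.measurements.items():
            if isinstance(meas, CollagenMeasurement):
                results[(s.id, tissue)] = screen_collagen(
                    meas, criteria, s.id, tissue)
            elif isinstance(meas, PlantMeasurement):
                results[(s.id, tissue)] = screen_plant(meas, criteria, s.id)
            else:
                results[(s.id, tissue)] = QCResult(s.id, PASS, tissue=tissue)
        if not s.measurements:
            results[(s.id, "none")] = QCResult(s.id, NOT_ASSESSED,
                                               tissue="none")
    return results


def apply_exclusions(dataset: Dataset, qc_results: dict,
                     manual_exclusions: Optional[list] = None) -> Dataset:
    """Build the analysis set: drop failed tissues and manual exclusions.

    ``manual_exclusions`` is a list of ``(specimen_id, reason)``; those
    specimens are removed entirely (e.g. a chronology problem).  Specimens
    whose every measurement failed (or that never produced a measurement)
    are dropped; caution-status specimens are retained and tagged via
    ``qc_flag``.
    """
    manual = dict(manual_exclusions or [])
    ids = set(dataset.ids())
    for mid in manual:
        if mid not in ids:
            raise KeyError(f"manual exclusion {mid!r} not in dataset")
    out = []
    for s in dataset:
        if s.id in manual:
            continue
        keep = {}
        flags = []
        for tissue, meas in s.measurements.items():
            res = qc_results.get((s.id, tissue))
            if res is not None and res.status == FAIL:
                continue
            keep[tissue] = meas
            if res is not None and res.status == CAUTION:
                flags.append(tissue)
        if not keep:
            continue
        s2 = Specimen(**{**s.__dict__, "measurements": keep,
                         "qc_flag": ("caution:" + ",".join(flags))
                         if flags else None})
        out.append(s2)
    return Dataset(out, dataset.schema)
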