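"""Genotypic sexing from a validated marker panel and sex-reversal flagging.

Per marker, per individual, the evidence in an XY system is:

* SD (sequence-difference) marker — heterozygous call → heterogametic
  (male) evidence; homozygous call (either allele) → homogametic (female)
  evidence; missing → no evidence.
* PA (presence/absence) marker — tag present → heterogametic evidence;
  absent → homogametic; unknown → none.

In a ZW system the heterogametic sex is female and every mapping flips.
Evidence is aggregated by strict majority of non-missing markers; ties and
thin panels (< ``min_markers`` informative markers) yield ``uncalled``,
never a guess.  A call discordant with the recorded phenotype flags a
putative sex reversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .datamodel_io import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    PRESENT,
    Dataset,
    Sex,
)
from .detectors import PATTERN_XY, PATTERN_ZW

MARKER_SD = "SD"
MARKER_PA = "PA"

GENETIC_MALE = "genetic_male"
GENETIC_FEMALE = "genetic_female"
UNCALLED = "uncalled"

EVID_HETEROGAMETIC = "heterogametic"
EVID_HOMOGAMETIC = "homogametic"
EVID_NONE = "missing"


@dataclass(frozen=True)
class PanelEntry:
    tag_id: str
    site_index: Optional[int]  # None for PA (tag-level) markers
    marker_type: str  # SD | PA
    system: str  # XY | ZW

    def __post_init__(self) -> None:
        if self.marker_type not in (MARKER_SD, MARKER_PA):
            raise ValueError(f"marker_type {self.marker_type!r} not SD/PA")
        if self.system not in (PATTERN_XY, PATTERN_ZW):
            raise ValueError(f"system {self.system!r} not XY/ZW")
        if self.marker_type == MARKER_SD and self.site_index is None:
            raise ValueError(f"{self.tag_id}: SD marker needs a site index")


@dataclass
class MarkerPanel:
    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty marker panel")
        systems = {e.system for e in self.entries}
        if len(systems) != 1:
            raise ValueError(f"panel mixes systems: {sorted(systems)}")

    @property
    def system(self) -> str:
        return self.entries[0].system


@dataclass(frozen=True)
class GenotypicSexCall:
    individual_id: str
    phenotype: Sex
    evidence: dict  # (tag_id, site_index|None) -> evidence label
    n_support_heterogametic: int
    n_support_homogametic: int
    inferred: str  # genetic_male | genetic_female | uncalled
    discordant: bool


@dataclass(frozen=True)
class ReversalSummary:
    n_individuals: int
    n_called: int
    n_discordant: int
    discordant_ids: tuple
    discordant_by_phenotype: dict
    fraction_discordant: Optional[float]  # None (NA) when nothing was called


def _marker_evidence(dataset: Dataset, entry: PanelEntry, idx: int) -> str:
    tag = dataset.tag(entry.tag_id)
    if entry.marker_type == MARKER_SD:
        for site in tag.sites:
            if site.site_index == entry.site_index:
                call = int(site.calls[idx])
                if call == HET:
                    return EVID_HETEROGAMETIC
                if call in (HOM_REF, HOM_ALT):
                    return EVID_HOMOGAMETIC
                return EVID_NONE
        raise KeyError(f"{entry.tag_id}:{entry.site_index}")
    p = int(tag.presence[idx])
    if p == PRESENT:
        return EVID_HETEROGAMETIC
    if p == ABSENT:
        return EVID_HOMOGAMETIC
    return EVID_NONE


def _validate_panel(dataset: Dataset, panel: MarkerPanel) -> None:
    missing = []
    tag_ids = {t.tag_id for t in dataset.tags}
    for e in panel.entries:
        if e.tag_id not in tag_ids:
            missing.append(e.tag_id)
            continue
        if e.marker_type == MARKER_SD:
            offsets = set(dataset.tag(e.tag_id).site_offsets)
            if e.site_index not in offsets:
                missing.append(f"{e.tag_id}:{e.site_index}")
    if missing:
        raise KeyError(f"panel markers absent from dataset: {sorted(set(missing))}")


def call_genotypic_sex(
    dataset: Dataset,
    panel: MarkerPanel,
    min_markers: int = 1,
    majority: float = 0.5,
    any_heterogametic: bool = False,
) -> list[GenotypicSexCall]:
    """Infer genetic sex per individual from the panel.

    ``majority`` is the support fraction a verdict must strictly exceed
    among non-missing markers (0.5 → strict majority).  With
    ``any_heterogametic`` a single heterogametic-evidence marker suffices
    for the heterogametic call (the "one Y is enough" reading).
    """
    _validate_panel(dataset, panel)
    if not 0.0 <= majority < 1.0:
        raise ValueError(f"majority={majority} outside [0, 1)")
    het_sex, hom_sex = (
        (GENETIC_MALE, GENETIC_FEMALE)
        if panel.system == PATTERN_XY
        else (GENETIC_FEMALE, GENETIC_MALE)
    )
    calls: list[GenotypicSexCall] = []
    for idx, ind in enumerate(dataset.individuals):
        evidence = {
            (e.tag_id, e.site_index): _marker_evidence(dataset, e, idx)
            for e in panel.entries
        }
        n_het = sum(1 for v in evidence.values() if v == EVID_HETEROGAMETIC)
        n_hom = sum(1 for v in evidence.values() if v == EVID_HOMOGAMETIC)
        total = n_het + n_hom
        if total < min_markers:
            inferred = UNCALLED
        elif any_heterogametic and n_het > 0:
            inferred = het_sex
        elif n_het > majority * total:
            inferred = het_sex
        elif n_hom > majority * total:
            inferred = hom_sex
        else:
            inferred = UNCALLED
        discordant = (
            inferred != UNCALLED
            and ind.phenotype in (Sex.MALE, Sex.FEMALE)
            and inferred != (GENETIC_MALE if ind.phenotype is Sex.MALE else GENETIC_FEMALE)
        )
        calls.append(
            GenotypicSexCall(
                ind.id, ind.phenotype, evidence, n_het, n_hom, inferred, discordant
            )
        )
    return calls


def summarize_reversals(calls: Sequence[GenotypicSexCall]) -> ReversalSummary:
    called = [c for c in calls if c.inferred != UNCALLED]
    discordant = [c for c in calls if c.discordant]
    by_phen: dict = {}
    for c in discordant:
        key = c.phenotype.value
        by_phen[key] = by_phen.get(key, 0) + 1
    fraction = len(discordant) / len(called) if called else None
    return ReversalSummary(
        n_individuals=len(calls),
        n_called=len(called),
        n_discordant=len(discordant),
        discordant_ids=tuple(c.individual_id for c in discordant),
        discordant_by_phenotype=by_phen,
        fraction_discordant=fraction,
    )


def read_panel(path) -> MarkerPanel:
    """Read a panel TSV: ``tag_id  site  marker_type  system`` with ``site``
    1-based or the literal ``tag`` for PA markers."""
    import csv

    entries = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.lower() for c in header[:4]] != [
            "tag_id", "site", "marker_type", "system",
        ]:
            raise ValueError(f"{path}: panel header must be tag_id/site/marker_type/system")
        for row in reader:
            if not row:
                continue
            site = None if row[1].strip().lower() == "tag" else int(row[1]) - 1
            entries.append(PanelEntry(row[0], site, row[2].strip().upper(), row[3].strip().upper()))
    return MarkerPanel(entries)


def write_sex_calls(calls: Sequence[GenotypicSexCall], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "individual", "phenotype", "n_heterogametic_evidence",
            "n_homogametic_evidence", "inferred", "discordant",
        ])
        for c in calls:
            w.writerow([
                c.individual_id, c.phenotype.value, c.n_support_heterogametic,
                c.n_support_homogametic, c.inferred, int(c.discordant),
            ])
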