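"""The three per-sex screening criteria, tag-level deduplication, and
heterogametic-system classification.

For an XY system the heterogametic sex is male, so:

* allele-frequency criterion — some allele has frequency >= ``f_fix`` in
  females and a (signed) female-minus-male difference >= ``d_min``;
* heterozygosity criterion — zero heterozygous females and at least a
  ``het_frac`` fraction of called males heterozygous;
* sex-limited criterion — the tag is absent from every female and present
  in every male.

The ZW pattern is the exact sex mirror of each criterion.  Threshold
comparisons are evaluated in exact rational arithmetic on the integer counts
(allele frequencies are ratios of small integers; floating-point rounding at
the published >= boundaries would otherwise be load-bearing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Union

import numpy as np

from .datamodel_io import Dataset
from .sexstats import (
    DEFAULT_MIN_CALLED,
    SiteSexStats,
    TagPresenceStats,
    _sex_masks,
    site_stats_from_masks,
    tag_presence_from_masks,
)

log = logging.getLogger(__name__)

APPROACH_FREQ = "freq_diff"
APPROACH_HET = "het_diff"
APPROACH_LIMITED = "sex_limited"
APPROACHES = (APPROACH_FREQ, APPROACH_HET, APPROACH_LIMITED)

PATTERN_XY = "XY"
PATTERN_ZW = "ZW"

SYSTEM_AMBIGUOUS = "ambiguous"


class AmbiguousPatternError(ValueError):
    """A site satisfied both the XY and the ZW reading of a criterion
    (fixed-opposite allele configurations); neither sex-chromosome model
    explains such a site and it is excluded from the catalog."""


def _as_fraction(x: float | int | Fraction) -> Fraction:
    if isinstance(x, Fraction):
        return x
    # str() round-trips the decimal literal the user wrote (0.95 -> 19/20)
    return Fraction(str(x))


@dataclass(frozen=True)
class DetectionParams:
    """Screening thresholds; all comparisons are inclusive (>=)."""

    f_fix: float = 0.95
    d_min: float = 0.4
    het_frac: float = 0.5
    min_called: int = DEFAULT_MIN_CALLED
    abs_diff: bool = False
    max_missing_presence: int = 0

    def __post_init__(self) -> None:
        for name in ("f_fix", "d_min", "het_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_called < 0 or self.max_missing_presence < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "DetectionParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class DetectionRecord:
    """One detection event: a SNP site (approaches 1–2) or a whole tag
    (approach 3), with the approach that fired and the implied pattern."""

    tag_id: str
    site_index: Optional[int]  # None for tag-level (sex-limited) records
    approach: str
    pattern: str
    stats: Union[SiteSexStats, TagPresenceStats, None] = None

    @property
    def is_tag_level(self) -> bool:
        return self.site_index is None


# --------------------------------------------------------------------------
# the three criteria
# --------------------------------------------------------------------------


def _freq_criterion(
    f_hom: Fraction, f_het: Fraction, f_fix: Fraction, d_min: Fraction, abs_diff: bool
) -> bool:
    """True when some allele is near-fixed in the homogametic sex and
    differentiated from the heterogametic sex.  ``f_*`` are ref-allele
    frequencies; both alleles of the biallelic site are examined."""
    for a_hom, a_het in ((f_hom, f_het), (1 - f_hom, 1 - f_het)):
        diff = abs(a_hom - a_het) if abs_diff else a_hom - a_het
        if a_hom >= f_fix and diff >= d_min:
            return True
    return False


def detect_by_allele_frequency(
    stats: SiteSexStats, params: DetectionParams
) -> Optional[DetectionRecord]:
    """Approach 1: between-sex allele-frequency differentiation."""
    if not stats.informative:
        return None
    ff = Fraction(stats.n_ref_f, 2 * stats.n_called_f)
    fm = Fraction(stats.n_ref_m, 2 * stats.n_called_m)
    f_fix, d_min = _as_fraction(params.f_fix), _as_fraction(params.d_min)
    xy = _freq_criterion(ff, fm, f_fix, d_min, params.abs_diff)
    zw = _freq_criterion(fm, ff, f_fix, d_min, params.abs_diff)
    if xy and zw:
        raise AmbiguousPatternError(
            f"{stats.tag_id}:{stats.site_index}: fixed-opposite alleles satisfy "
            f"both XY and ZW frequency criteria"
        )
    if xy or zw:
        return DetectionRecord(
            stats.tag_id, stats.site_index, APPROACH_FREQ,
            PATTERN_XY if xy else PATTERN_ZW, stats,
        )
    return None


def detect_by_heterozygosity(
    stats: SiteSexStats, params: DetectionParams
) -> Optional[DetectionRecord]:
    """Approach 2: homozygous throughout the homogametic sex, heterozygous in
    at least ``het_frac`` of called individuals of the heterogametic sex."""
    if not stats.informative:
        return None
    hf = _as_fraction(params.het_frac)
    xy = stats.n_het_f == 0 and stats.n_het_m >= hf * stats.n_called_m and stats.n_het_m > 0
    zw = stats.n_het_m == 0 and stats.n_het_f >= hf * stats.n_called_f and stats.n_het_f > 0
    if xy and zw:  # unreachable for het_frac > 0; guarded for completeness
        raise AmbiguousPatternError(f"{stats.tag_id}:{stats.site_index}")
    if xy or zw:
        return DetectionRecord(
            stats.tag_id, stats.site_index, APPROACH_HET,
            PATTERN_XY if xy else PATTERN_ZW, stats,
        )
    return None


def detect_by_sex_limited(
    pstats: TagPresenceStats, params: DetectionParams
) -> Optional[DetectionRecord]:
    """Approach 3: tag present in every individual of one sex and absent from
    every individual of the other.

    The criterion is absolute, so by default any unknown-presence individual
    disqualifies the tag; ``max_missing_presence`` relaxes that per sex.
    """
    if (
        pstats.n_unknown_f > params.max_missing_presence
        or pstats.n_unknown_m > params.max_missing_presence
    ):
        return None
    xy = pstats.n_present_f == 0 and pstats.n_absent_m == 0 and pstats.n_present_m > 0
    zw = pstats.n_present_m == 0 and pstats.n_absent_f == 0 and pstats.n_present_f > 0
    if xy or zw:
        return DetectionRecord(
            pstats.tag_id, None, APPROACH_LIMITED,
            PATTERN_XY if xy else PATTERN_ZW, pstats,
        )
    return None


# --------------------------------------------------------------------------
# catalog
# --------------------------------------------------------------------------


@dataclass
class MarkerCatalog:
    """Deduplicated union of detection records with approach provenance.

    A tag detected by several approaches (or at several sites) counts once in
    ``distinct_tags`` but keeps every record.  Approaches 1–2 are tallied
    both in SNPs and in tags; approach 3 exists only at tag level.
    """

    records: list[DetectionRecord] = field(default_factory=list)
    n_ambiguous_skipped: int = 0

    @property
    def distinct_tags(self) -> set[str]:
        return {r.tag_id for r in self.records}

    def tags_by_approach(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {a: set() for a in APPROACHES}
        for r in self.records:
            out[r.approach].add(r.tag_id)
        return out

    def snps_by_approach(self) -> dict[str, int]:
        out = {a: 0 for a in (APPROACH_FREQ, APPROACH_HET)}
        for r in self.records:
            if not r.is_tag_level and r.approach in out:
                out[r.approach] += 1
        return out

    def patterns_by_tag(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.tag_id, set()).add(r.pattern)
        return out

    def primary_approach(self, tag_id: str) -> str:
        """Provenance for summary partitions: a tag found by several
        approaches is attributed to the earliest in approach order 1, 2, 3
        (the shared approach-1/2 tag counts under approach 1)."""
        found = {r.approach for r in self.records if r.tag_id == tag_id}
        for a in APPROACHES:
            if a in found:
                return a
        raise KeyError(tag_id)

    def tally(self) -> dict:
        by_app = self.tags_by_approach()
        patterns = self.patterns_by_tag()
        n_xy = sum(1 for p in patterns.values() if PATTERN_XY in p)
        n_zw = sum(1 for p in patterns.values() if PATTERN_ZW in p)
        return {
            "n_records": len(self.records),
            "n_distinct_tags": len(self.distinct_tags),
            "tags_per_approach": {a: len(s) for a, s in by_app.items()},
            "snps_per_approach": self.snps_by_approach(),
            "n_xy_tags": n_xy,
            "n_zw_tags": n_zw,
        }


@dataclass(frozen=True)
class SystemCall:
    """Outcome of heterogametic-system classification over distinct tags."""

    n_xy_tags: int
    n_zw_tags: int
    fraction_xy: Optional[float]
    called_system: str  # XY | ZW | ambiguous


def build_catalog(dataset: Dataset, params: DetectionParams | None = None) -> MarkerCatalog:
    """Run all three detectors over every site and tag of the dataset."""
    params = params or DetectionParams()
    dataset.require_both_sexes()
    f_mask, m_mask = _sex_masks(dataset.individuals)
    records: list[DetectionRecord] = []
    n_ambiguous = 0
    for tag in dataset.tags:
        for site in tag.sites:
            stats = site_stats_from_masks(site, f_mask, m_mask, params.min_called)
            try:
                rec = detect_by_allele_frequency(stats, params)
                if rec is not None:
                    records.append(rec)
            except AmbiguousPatternError:
                n_ambiguous += 1
            rec = detect_by_heterozygosity(stats, params)
            if rec is not None:
                records.append(rec)
        pstats = tag_presence_from_masks(tag, f_mask, m_mask)
        rec = detect_by_sex_limited(pstats, params)
        if rec is not None:
            records.append(rec)
    if n_ambiguous:
        log.warning("skipped %d site(s) with ambiguous XY/ZW frequency pattern", n_ambiguous)
    return MarkerCatalog(records, n_ambiguous_skipped=n_ambiguous)


def classify_system(catalog: MarkerCatalog, majority: float = 0.8) -> SystemCall:
    """Call the heterogametic system from the XY/ZW pattern tallies of the
    catalog's distinct tags.

    ``fraction_xy >= majority`` calls XY, ``<= 1 - majority`` calls ZW,
    anything between (or an empty catalog) is ambiguous.
    """
    if not 0.5 <= majority <= 1.0:
        raise ValueError(f"majority={majority} outside [0.5, 1]")
    patterns = catalog.patterns_by_tag()
    n_xy = sum(1 for p in patterns.values() if PATTERN_XY in p)
    n_zw = sum(1 for p in patterns.values() if PATTERN_ZW in p)
    total = n_xy + n_zw
    if total == 0:
        return SystemCall(0, 0, None, SYSTEM_AMBIGUOUS)
    fraction_xy = n_xy / total
    if fraction_xy >= majority:
        called = PATTERN_XY
    elif fraction_xy <= 1.0 - majority:
        called = PATTERN_ZW
    else:
        called = SYSTEM_AMBIGUOUS
    return SystemCall(n_xy, n_zw, fraction_xy, called)
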