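"""Per-locus, per-sex summary statistics consumed by the three detectors.

Frequencies are genotype-based: the allele-frequency denominator is
2 × n_called, counting called individuals of the relevant phenotypic sex
only.  Unknown-sex individuals never enter any denominator.  A site (or tag)
is flagged uninformative when either sex has fewer than ``min_called``
called individuals; detectors skip uninformative loci rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel_io import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    PRESENCE_UNKNOWN,
    PRESENT,
    Dataset,
    Individual,
    Sex,
    SiteGenotypes,
    TagLocus,
)

DEFAULT_MIN_CALLED = 5


@dataclass(frozen=True)
class SiteSexStats:
    """Per-sex allele and genotype-class counts at one SNP site.

    ``n_ref_*`` counts reference alleles over 2 × n_called chromosomes, so
    exact rational frequencies are recoverable downstream.
    """

    tag_id: str
    site_index: int
    n_called_f: int
    n_called_m: int
    n_ref_f: int
    n_ref_m: int
    n_het_f: int
    n_het_m: int
    n_hom_f: int
    n_hom_m: int
    informative: bool
    reason: str | None = None

    @property
    def ref_freq_f(self) -> float:
        return self.n_ref_f / (2 * self.n_called_f) if self.n_called_f else float("nan")

    @property
    def ref_freq_m(self) -> float:
        return self.n_ref_m / (2 * self.n_called_m) if self.n_called_m else float("nan")

    def swapped(self) -> "SiteSexStats":
        """Stats as they would be with all sex labels exchanged."""
        return SiteSexStats(
            self.tag_id, self.site_index,
            n_called_f=self.n_called_m, n_called_m=self.n_called_f,
            n_ref_f=self.n_ref_m, n_ref_m=self.n_ref_f,
            n_het_f=self.n_het_m, n_het_m=self.n_het_f,
            n_hom_f=self.n_hom_m, n_hom_m=self.n_hom_f,
            informative=self.informative, reason=self.reason,
        )


@dataclass(frozen=True)
class TagPresenceStats:
    """Per-sex tag presence counts; the three counts per sex always sum to
    that sex's sample size."""

    tag_id: str
    n_present_f: int
    n_present_m: int
    n_absent_f: int
    n_absent_m: int
    n_unknown_f: int
    n_unknown_m: int

    def swapped(self) -> "TagPresenceStats":
        return TagPresenceStats(
            self.tag_id,
            n_present_f=self.n_present_m, n_present_m=self.n_present_f,
            n_absent_f=self.n_absent_m, n_absent_m=self.n_absent_f,
            n_unknown_f=self.n_unknown_m, n_unknown_m=self.n_unknown_f,
        )


def _sex_masks(individuals: Sequence[Individual]) -> tuple[np.ndarray, np.ndarray]:
    f = np.array([ind.phenotype is Sex.FEMALE for ind in individuals], dtype=bool)
    m = np.array([ind.phenotype is Sex.MALE for ind in individuals], dtype=bool)
    return f, m


def _class_counts(calls: np.ndarray, mask: np.ndarray) -> tuple[int, int, int, int]:
    """(n_called, n_ref_alleles, n_het, n_hom) within one sex."""
    sub = calls[mask]
    n_hom_ref = int(np.count_nonzero(sub == HOM_REF))
    n_het = int(np.count_nonzero(sub == HET))
    n_hom_alt = int(np.count_nonzero(sub == HOM_ALT))
    n_called = n_hom_ref + n_het + n_hom_alt
    return n_called, 2 * n_hom_ref + n_het, n_het, n_hom_ref + n_hom_alt


def compute_site_stats(
    site: SiteGenotypes,
    individuals: Sequence[Individual],
    min_called: int = DEFAULT_MIN_CALLED,
) -> SiteSexStats:
    f_mask, m_mask = _sex_masks(individuals)
    return site_stats_from_masks(site, f_mask, m_mask, min_called)


def site_stats_from_masks(
    site: SiteGenotypes,
    f_mask: np.ndarray,
    m_mask: np.ndarray,
    min_called: int = DEFAULT_MIN_CALLED,
) -> SiteSexStats:
    """Mask-reusing variant of :func:`compute_site_stats` for catalog scans."""
    ncf, nrf, nhetf, nhomf = _class_counts(site.calls, f_mask)
    ncm, nrm, nhetm, nhomm = _class_counts(site.calls, m_mask)
    informative, reason = True, None
    if ncf < min_called or ncm < min_called:
        informative, reason = False, f"fewer than {min_called} called in one sex"
    return SiteSexStats(
        site.tag_id, site.site_index,
        n_called_f=ncf, n_called_m=ncm,
        n_ref_f=nrf, n_ref_m=nrm,
        n_het_f=nhetf, n_het_m=nhetm,
        n_hom_f=nhomf, n_hom_m=nhomm,
        informative=informative, reason=reason,
    )


def compute_tag_presence(
    tag: TagLocus, individuals: Sequence[Individual]
) -> TagPresenceStats:
    f_mask, m_mask = _sex_masks(individuals)
    return tag_presence_from_masks(tag, f_mask, m_mask)


def tag_presence_from_masks(
    tag: TagLocus, f_mask: np.ndarray, m_mask: np.ndarray
) -> TagPresenceStats:
    presence = tag.presence
    if presence is None:
        presence = tag.derived_presence(len(f_mask))

    def counts(mask: np.ndarray) -> tuple[int, int, int]:
        sub = presence[mask]
        return (
            int(np.count_nonzero(sub == PRESENT)),
            int(np.count_nonzero(sub == ABSENT)),
            int(np.count_nonzero(sub == PRESENCE_UNKNOWN)),
        )

    pf, af, uf = counts(f_mask)
    pm, am, um = counts(m_mask)
    return TagPresenceStats(
        tag.tag_id,
        n_present_f=pf, n_present_m=pm,
        n_absent_f=af, n_absent_m=am,
        n_unknown_f=uf, n_unknown_m=um,
    )


def dump_site_stats(dataset: Dataset, path, min_called: int = DEFAULT_MIN_CALLED) -> None:
    """Debugging export of every site's per-sex stats as TSV."""
    import csv

    f_mask, m_mask = _sex_masks(dataset.individuals)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "tag_id", "site", "n_called_F", "n_called_M", "ref_freq_F", "ref_freq_M",
            "n_het_F", "n_het_M", "informative",
        ])
        for tag in dataset.tags:
            for site in tag.sites:
                st = site_stats_from_masks(site, f_mask, m_mask, min_called)
                w.writerow([
                    st.tag_id, st.site_index + 1, st.n_called_f, st.n_called_m,
                    f"{st.ref_freq_f:.6g}", f"{st.ref_freq_m:.6g}",
                    st.n_het_f, st.n_het_m, int(st.informative),
                ])
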