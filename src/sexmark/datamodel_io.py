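"""Domain types and file I/O shared by every pipeline stage.

The canonical in-memory unit is a :class:`Dataset`: a list of individuals with
phenotypic sex plus a list of tag loci, each carrying zero or more biallelic
SNP sites and a per-individual tag presence vector.  Genotype calls are stored
as small integer codes in numpy arrays aligned with ``Dataset.individuals``.

File dialects
-------------
* genotype table — TSV with header ``tag_id  site  ref  alt  <sample>...``;
  ``site`` is a 0-based offset within the tag; genotype tokens are
  ``0/0  0/1  1/1  ./.`` (``1/0`` is accepted on read as ``0/1``).
* sample sex map — two-column TSV ``sample  M|F|U`` (case-insensitive).
* presence matrix — TSV with header ``tag_id  <sample>...`` and cell values
  ``1`` (present), ``0`` (absent) or ``NA`` (unknown).
* BLAST tabular — 12-column ``-outfmt 6``.
* VCF — standard, GT-bearing; converted to the genotype-table model on read.

Coordinates are 0-based half-open internally and 1-based only in
human-readable report columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .confirmation import AlignmentHit
    from .detectors import MarkerCatalog

log = logging.getLogger(__name__)

# genotype call codes (int8)
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

# tag presence codes (int8)
PRESENT: int = 1
ABSENT: int = 0
PRESENCE_UNKNOWN: int = -1

_GT_TOKENS = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT, "./.": MISSING}
_TOKEN_FOR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_PRESENCE_TOKENS = {"1": PRESENT, "0": ABSENT, "NA": PRESENCE_UNKNOWN}
_PRESENCE_FOR = {PRESENT: "1", ABSENT: "0", PRESENCE_UNKNOWN: "NA"}
_NUCLEOTIDES = frozenset("ACGT")


class Sex(str, Enum):
    """Phenotypic sex of a sampled individual."""

    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


@dataclass(frozen=True)
class Individual:
    id: str
    phenotype: Sex = Sex.UNKNOWN


@dataclass
class SiteGenotypes:
    """One biallelic SNP site on a tag, with calls for every individual.

    ``calls`` is an int8 array aligned with ``Dataset.individuals`` using the
    codes ``HOM_REF/HET/HOM_ALT/MISSING``.
    """

    tag_id: str
    site_index: int
    ref_allele: str
    alt_allele: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.tag_id}:{self.site_index}: alleles must be single "
                f"nucleotides, got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.site_index < 0:
            raise ValueError(f"{self.tag_id}: negative site offset {self.site_index}")


@dataclass
class TagLocus:
    """An assembled GBS/RAD tag: an optional sequence, its SNP sites, and a
    per-individual presence vector (``PRESENT/ABSENT/PRESENCE_UNKNOWN``)."""

    tag_id: str
    sites: list[SiteGenotypes] = field(default_factory=list)
    sequence: str | None = None
    presence: np.ndarray | None = None

    def __post_init__(self) -> None:
        offsets = [s.site_index for s in self.sites]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError(f"{self.tag_id}: site offsets must be strictly increasing")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if offsets and offsets[-1] >= len(self.sequence):
                raise ValueError(
                    f"{self.tag_id}: site offset {offsets[-1]} outside sequence "
                    f"of length {len(self.sequence)}"
                )
        if self.presence is not None:
            self.presence = np.asarray(self.presence, dtype=np.int8)

    @property
    def site_offsets(self) -> list[int]:
        return [s.site_index for s in self.sites]

    def derived_presence(self, n_individuals: int) -> np.ndarray:
        """Presence inferred from genotypes: present iff >=1 non-missing call
        at any site; all-unknown for a tag with no sites."""
        if not self.sites:
            return np.full(n_individuals, PRESENCE_UNKNOWN, dtype=np.int8)
        called = np.zeros(n_individuals, dtype=bool)
        for s in self.sites:
            called |= s.calls != MISSING
        return np.where(called, PRESENT, ABSENT).astype(np.int8)


@dataclass
class Dataset:
    """Individuals plus tag loci — the unit every pipeline stage consumes."""

    individuals: list[Individual]
    tags: list[TagLocus]
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        n = len(self.individuals)
        for tag in self.tags:
            for s in tag.sites:
                if len(s.calls) != n:
                    raise ValueError(
                        f"{tag.tag_id}:{s.site_index}: {len(s.calls)} calls for "
                        f"{n} individuals"
                    )
            if tag.presence is None:
                tag.presence = tag.derived_presence(n)
            elif len(tag.presence) != n:
                raise ValueError(f"{tag.tag_id}: presence length != {n}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def sex_mask(self, sex: Sex) -> np.ndarray:
        return np.array([ind.phenotype is sex for ind in self.individuals], dtype=bool)

    @property
    def n_males(self) -> int:
        return int(self.sex_mask(Sex.MALE).sum())

    @property
    def n_females(self) -> int:
        return int(self.sex_mask(Sex.FEMALE).sum())

    def index_of(self) -> dict[str, int]:
        return {ind.id: i for i, ind in enumerate(self.individuals)}

    def tag(self, tag_id: str) -> TagLocus:
        for t in self.tags:
            if t.tag_id == tag_id:
                return t
        raise KeyError(tag_id)

    def require_both_sexes(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError(
                f"need >=1 phenotypic male and female before screening "
                f"(have {self.n_males} M, {self.n_females} F)"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sex_map(path: str | Path) -> dict[str, Sex]:
    """Read a two-column sample→sex TSV. Tokens M/F/U, case-insensitive;
    anything else is an error (silent coercion hides sample-sheet bugs)."""
    out: dict[str, Sex] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, token = parts[0].strip(), parts[1].strip().upper()
            try:
                sex = Sex(token)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: sex token {parts[1]!r} not in M/F/U"
                ) from None
            if sample in out:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            out[sample] = sex
    if not out:
        raise FormatError(f"{path}: empty sex map")
    return out


def _is_biallelic_snv(ref: str, alt: str) -> bool:
    return ref in _NUCLEOTIDES and alt in _NUCLEOTIDES and ref != alt


def read_genotype_table(
    path: str | Path,
    sex_map_path: str | Path,
    presence_path: str | Path | None = None,
) -> Dataset:
    """Read the canonical genotype-table dialect into a :class:`Dataset`.

    Rows that are not biallelic SNVs (multi-base or comma-separated alleles)
    are skipped and counted in ``dataset.notes['skipped_rows']``.  Samples
    absent from the sex map become phenotype ``unknown`` with a warning.
    """
    sex_map = read_sex_map(sex_map_path)
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty genotype table") from None
        if [c.lower() for c in header[:4]] != ["tag_id", "site", "ref", "alt"]:
            raise FormatError(
                f"{path}: header must start with tag_id/site/ref/alt, got {header[:4]}"
            )
        samples = header[4:]
        if not samples:
            raise FormatError(f"{path}: no sample columns")
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise FormatError(f"{path}: duplicated sample columns: {dupes}")

        sites_by_tag: dict[str, list[SiteGenotypes]] = {}
        tag_order: list[str] = []
        skipped = 0
        for lineno, row in enumerate(reader, 2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4 + len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {4 + len(samples)} columns, got {len(row)}"
                )
            tag_id, site_s, ref, alt = (row[0], row[1], row[2].upper(), row[3].upper())
            if not _is_biallelic_snv(ref, alt):
                skipped += 1
                continue
            calls = np.empty(len(samples), dtype=np.int8)
            for i, token in enumerate(row[4:]):
                try:
                    calls[i] = _GT_TOKENS[token.strip()]
                except KeyError:
                    raise FormatError(
                        f"{path}:{lineno}: genotype token {token!r} outside "
                        f"0/0 0/1 1/1 ./. dialect"
                    ) from None
            site = SiteGenotypes(tag_id, int(site_s), ref, alt, calls)
            if tag_id not in sites_by_tag:
                sites_by_tag[tag_id] = []
                tag_order.append(tag_id)
            sites_by_tag[tag_id].append(site)

    unmapped = [s for s in samples if s not in sex_map]
    if unmapped:
        log.warning("%d sample(s) not in sex map, set to unknown: %s", len(unmapped), unmapped)
    individuals = [Individual(s, sex_map.get(s, Sex.UNKNOWN)) for s in samples]

    presence_by_tag: dict[str, np.ndarray] = {}
    if presence_path is not None:
        presence_by_tag = _read_presence_matrix(presence_path, samples)
        for tag_id in presence_by_tag:
            if tag_id not in sites_by_tag:
                sites_by_tag[tag_id] = []
                tag_order.append(tag_id)

    tags = [
        TagLocus(
            tag_id,
            sites=sorted(sites_by_tag[tag_id], key=lambda s: s.site_index),
            presence=presence_by_tag.get(tag_id),
        )
        for tag_id in tag_order
    ]
    ds = Dataset(individuals, tags, notes={"skipped_rows": skipped})
    if skipped:
        log.warning("%s: skipped %d non-biallelic row(s)", path, skipped)
    return ds


def _read_presence_matrix(path: str | Path, samples: Sequence[str]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty presence matrix") from None
        if header[0].lower() != "tag_id":
            raise FormatError(f"{path}: first column must be tag_id")
        cols = header[1:]
        pos = {s: i for i, s in enumerate(cols)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise FormatError(f"{path}: samples missing from presence matrix: {missing}")
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != 1 + len(cols):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            vec = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                token = row[1 + pos[s]].strip().upper()
                try:
                    vec[i] = _PRESENCE_TOKENS[token]
                except KeyError:
                    raise FormatError(
                        f"{path}:{lineno}: presence token {token!r} not 1/0/NA"
                    ) from None
            out[row[0]] = vec
    return out


def read_vcf(path: str | Path, sex_map_path: str | Path) -> Dataset:
    """Read a GT-bearing VCF, retaining biallelic SNV records only.

    ``tag_id`` is taken from CHROM and the site offset from POS−1 (tags are
    assumed to be the VCF contigs, so POS is a 1-based offset within the
    tag); ``notes['coordinates']`` records the conversion.  Half-called
    genotypes are treated as missing.  Tag presence is derived: present iff
    >=1 non-missing genotype at any site of the tag.
    """
    from cyvcf2 import VCF  # local import: cyvcf2 is only needed on this path

    sex_map = read_sex_map(sex_map_path)
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT definition")
    samples = list(vcf.samples)
    if not any(s in sex_map for s in samples):
        raise FormatError(f"{path}: no overlap between VCF samples and sex map")
    unmapped = [s for s in samples if s not in sex_map]
    if unmapped:
        log.warning("%d VCF sample(s) not in sex map, set to unknown: %s", len(unmapped), unmapped)
    individuals = [Individual(s, sex_map.get(s, Sex.UNKNOWN)) for s in samples]

    sites_by_tag: dict[str, list[SiteGenotypes]] = {}
    tag_order: list[str] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not _is_biallelic_snv(v.REF, v.ALT[0]):
            skipped += 1
            continue
        calls = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                calls[i] = MISSING
            else:
                calls[i] = alleles[0] + alleles[1]
        site = SiteGenotypes(v.CHROM, v.POS - 1, v.REF, v.ALT[0], calls)
        if v.CHROM not in sites_by_tag:
            sites_by_tag[v.CHROM] = []
            tag_order.append(v.CHROM)
        sites_by_tag[v.CHROM].append(site)

    tags = [
        TagLocus(tid, sites=sorted(sites_by_tag[tid], key=lambda s: s.site_index))
        for tid in tag_order
    ]
    return Dataset(
        individuals,
        tags,
        notes={"skipped_rows": skipped, "coordinates": "vcf POS converted to 0-based"},
    )


def read_blast_tabular(path: str | Path) -> list["AlignmentHit"]:
    """Parse 12-column BLAST ``-outfmt 6`` output.

    Hits are returned grouped by query (first-appearance order) and, within a
    query, ordered by ascending E-value, then descending bitscore, then
    subject id.
    """
    from .confirmation import AlignmentHit

    by_query: dict[str, list[AlignmentHit]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hit = AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if hit.query_id not in by_query:
                by_query[hit.query_id] = []
                order.append(hit.query_id)
            by_query[hit.query_id].append(hit)
    out: list[AlignmentHit] = []
    for q in order:
        out.extend(sorted(by_query[q], key=lambda h: (h.evalue, -h.bitscore, h.subject_id)))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_genotype_table(dataset: Dataset, path: str | Path) -> None:
    """Write the canonical genotype-table dialect (round-trips with
    :func:`read_genotype_table`)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag_id", "site", "ref", "alt"] + [i.id for i in dataset.individuals])
        for tag in dataset.tags:
            for s in tag.sites:
                w.writerow(
                    [s.tag_id, s.site_index, s.ref_allele, s.alt_allele]
                    + [_TOKEN_FOR[int(c)] for c in s.calls]
                )


def write_sex_map(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for ind in dataset.individuals:
            fh.write(f"{ind.id}\t{ind.phenotype.value}\n")


def write_presence_matrix(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag_id"] + [i.id for i in dataset.individuals])
        for tag in dataset.tags:
            w.writerow([tag.tag_id] + [_PRESENCE_FOR[int(p)] for p in tag.presence])


def write_marker_report(catalog: "MarkerCatalog", path: str | Path) -> None:
    """Write one TSV row per detection record.

    Rows are sorted by (tag_id, site, approach) so repeated writes of the
    same catalog are byte-identical.  ``site`` is 1-based in this report;
    tag-level (presence/absence) records carry the literal ``tag``.
    """
    from .sexstats import SiteSexStats, TagPresenceStats

    cols = [
        "tag_id", "site", "approach", "pattern",
        "n_called_F", "n_called_M", "ref_freq_F", "ref_freq_M",
        "n_het_F", "n_het_M", "n_present_F", "n_present_M",
        "n_absent_F", "n_absent_M",
    ]

    def row_key(rec):
        site = rec.site_index if rec.site_index is not None else -1
        return (rec.tag_id, site, rec.approach)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for rec in sorted(catalog.records, key=row_key):
            site = "tag" if rec.site_index is None else str(rec.site_index + 1)
            vals: dict[str, str] = {c: "NA" for c in cols[4:]}
            st = rec.stats
            if isinstance(st, SiteSexStats):
                vals.update(
                    n_called_F=str(st.n_called_f), n_called_M=str(st.n_called_m),
                    ref_freq_F=f"{st.ref_freq_f:.6g}", ref_freq_M=f"{st.ref_freq_m:.6g}",
                    n_het_F=str(st.n_het_f), n_het_M=str(st.n_het_m),
                )
            elif isinstance(st, TagPresenceStats):
                vals.update(
                    n_present_F=str(st.n_present_f), n_present_M=str(st.n_present_m),
                    n_absent_F=str(st.n_absent_f), n_absent_M=str(st.n_absent_m),
                )
            w.writerow([rec.tag_id, site, rec.approach, rec.pattern] + [vals[c] for c in cols[4:]])


def read_marker_report(path: str | Path) -> "MarkerCatalog":
    """Re-read a marker report into a stats-free catalog (for `confirm`)."""
    from .detectors import DetectionRecord, MarkerCatalog

    records: list[DetectionRecord] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:4] != ["tag_id", "site", "approach", "pattern"]:
            raise FormatError(f"{path}: not a marker report")
        for row in reader:
            if not row:
                continue
            site = None if row[1] == "tag" else int(row[1]) - 1
            records.append(DetectionRecord(row[0], site, row[2], row[3], stats=None))
    return MarkerCatalog(records)


def write_confirmed_bed(records: Iterable, path: str | Path) -> None:
    """Write confirmed tag placements as BED (0-based half-open on the
    subject; strand from the hit's subject-coordinate orientation)."""
    rows = []
    for rec in records:
        if not rec.confirmed or rec.best_hit is None:
            continue
        h = rec.best_hit
        start, end = (h.sstart - 1, h.send) if h.sstart <= h.send else (h.send - 1, h.sstart)
        strand = "+" if h.sstart <= h.send else "-"
        rows.append((h.subject_id, start, end, rec.tag_id, h.bitscore, strand))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w", newline="") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read tag sequences from FASTA (id → uppercase sequence)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
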