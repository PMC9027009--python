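"""Seeded genotype-catalog simulator with truth tables.

Generates the post-genotyping structure the screening assumes: two
phenotypic sex classes, fully differentiated sex-linked SNPs under XY or ZW
inheritance with a per-carrier recombination-leakage probability, Y- (or W-)
limited tags, autosomal background SNPs in Hardy–Weinberg proportions,
uniform genotype-class error, missing calls, and a planted fraction of
sex-reversed individuals (phenotype label opposing genetic sex).

Phenotype labels, not genetic sexes, are what the detectors see — reversal
is the thing to be discovered downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datamodel_io import (
    ABSENT,
    HET,
    HOM_REF,
    MISSING,
    PRESENT,
    Dataset,
    Individual,
    Sex,
    SiteGenotypes,
    TagLocus,
)
from .detectors import (
    APPROACH_FREQ,
    APPROACH_HET,
    APPROACH_LIMITED,
    PATTERN_XY,
    MarkerCatalog,
)

log = logging.getLogger(__name__)

CLASS_AUTOSOMAL = "autosomal"
CLASS_SEXLINKED = "sexlinked_snp"
CLASS_LIMITED = "limited_tag"


@dataclass(frozen=True)
class SimulationConfig:
    n_males: int = 20
    n_females: int = 20
    n_autosomal_sites: int = 100
    n_sexlinked_sites: int = 20
    n_limited_tags: int = 10
    system: str = PATTERN_XY  # XY | ZW
    recomb_prob: float = 0.0  # heterogametic carrier homozygous at a site
    genotyping_error: float = 0.0  # per-call class flip
    missing_rate: float = 0.0  # per-call missing / presence dropout
    autosomal_freq_range: tuple[float, float] = (0.05, 0.95)
    reversal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recomb_prob", "genotyping_error", "missing_rate", "reversal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_males", "n_females", "n_autosomal_sites",
            "n_sexlinked_sites", "n_limited_tags",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.autosomal_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"autosomal_freq_range {self.autosomal_freq_range} invalid")
        if self.system not in ("XY", "ZW"):
            raise ValueError(f"system {self.system!r} not XY/ZW")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "autosomal_freq_range" in d:
            d["autosomal_freq_range"] = tuple(d["autosomal_freq_range"])
        return cls(**d)


@dataclass
class TruthTable:
    tag_class: dict  # tag_id -> CLASS_*
    genetic_sex: dict  # individual_id -> Sex
    reversed_ids: set

    def tags_of_class(self, cls: str) -> set[str]:
        return {t for t, c in self.tag_class.items() if c == cls}


@dataclass(frozen=True)
class DetectionMetrics:
    recall: dict  # approach -> recall on its planted class (None if no planted)
    false_positives: dict  # approach -> count among autosomal tags
    n_planted: dict  # class -> planted tag count


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Generate a dataset plus its truth table; same config → byte-identical
    output (single seeded generator, fixed draw order)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_males + config.n_females
    individuals = [Individual(f"M{i + 1:04d}", Sex.MALE) for i in range(config.n_males)] + [
        Individual(f"F{i + 1:04d}", Sex.FEMALE) for i in range(config.n_females)
    ]
    phenotype_is_male = np.array([ind.phenotype is Sex.MALE for ind in individuals])

    # floor of the exact fraction; epsilon absorbs float noise in rho*n
    n_rev = math.floor(config.reversal_fraction * n + 1e-9)
    if n_rev and not math.isclose(config.reversal_fraction * n, n_rev):
        log.info("reversal_fraction*n not integral; rounded down to %d", n_rev)
    rev_idx = rng.choice(n, size=n_rev, replace=False) if n_rev else np.array([], dtype=int)
    genetic_is_male = phenotype_is_male.copy()
    genetic_is_male[rev_idx] = ~genetic_is_male[rev_idx]

    carrier = genetic_is_male if config.system == PATTERN_XY else ~genetic_is_male

    tags: list[TagLocus] = []
    tag_class: dict = {}

    # sex-linked SNPs: homogametic sex hom_ref; carriers het unless recombinant
    S = config.n_sexlinked_sites
    if S:
        calls = np.full((S, n), HOM_REF, dtype=np.int8)
        recomb = rng.random((S, n)) < config.recomb_prob
        calls[:, carrier] = np.where(recomb[:, carrier], HOM_REF, HET)
        calls = _apply_noise(calls, rng, config.genotyping_error, config.missing_rate)
        for i in range(S):
            tid = f"sl{i + 1:05d}"
            tags.append(TagLocus(tid, sites=[SiteGenotypes(tid, 0, "A", "G", calls[i])]))
            tag_class[tid] = CLASS_SEXLINKED

    # autosomal background: HWE at a drawn frequency, same for everyone
    A = config.n_autosomal_sites
    if A:
        lo, hi = config.autosomal_freq_range
        p = rng.uniform(lo, hi, size=A)
        ref_count = (rng.random((A, n)) < p[:, None]).astype(np.int8) + (
            rng.random((A, n)) < p[:, None]
        ).astype(np.int8)
        calls = (2 - ref_count).astype(np.int8)  # 2 ref alleles -> HOM_REF
        calls = _apply_noise(calls, rng, config.genotyping_error, config.missing_rate)
        for i in range(A):
            tid = f"au{i + 1:05d}"
            tags.append(TagLocus(tid, sites=[SiteGenotypes(tid, 0, "C", "T", calls[i])]))
            tag_class[tid] = CLASS_AUTOSOMAL

    # sex-limited tags: present iff carrier, with presence dropout at rate m
    L = config.n_limited_tags
    if L:
        presence = np.where(carrier, PRESENT, ABSENT).astype(np.int8)
        presence = np.tile(presence, (L, 1))
        dropout = rng.random((L, n)) < config.missing_rate
        presence[dropout & (presence == PRESENT)] = ABSENT
        for i in range(L):
            tid = f"lt{i + 1:05d}"
            tags.append(TagLocus(tid, presence=presence[i]))
            tag_class[tid] = CLASS_LIMITED

    truth = TruthTable(
        tag_class=tag_class,
        genetic_sex={
            ind.id: (Sex.MALE if male else Sex.FEMALE)
            for ind, male in zip(individuals, genetic_is_male)
        },
        reversed_ids={individuals[i].id for i in rev_idx},
    )
    ds = Dataset(individuals, tags, notes={"simulated": True, "seed": config.seed})
    return ds, truth


def _apply_noise(
    calls: np.ndarray, rng: np.random.Generator, error: float, missing: float
) -> np.ndarray:
    """Flip each call to one of the other two classes with prob ``error``,
    then blank it with prob ``missing``."""
    out = calls.copy()
    if error > 0:
        flip = rng.random(out.shape) < error
        shift = rng.integers(1, 3, size=out.shape)  # +1 or +2 mod 3
        out[flip] = ((out[flip] + shift[flip]) % 3).astype(np.int8)
    if missing > 0:
        out[rng.random(out.shape) < missing] = MISSING
    return out


def evaluate_detection(truth: TruthTable, catalog: MarkerCatalog) -> DetectionMetrics:
    """Recall per approach on its planted class and autosomal false-positive
    counts per approach."""
    unknown = set(catalog.distinct_tags) - set(truth.tag_class)
    if unknown:
        raise ValueError(f"catalog tags not in truth table: {sorted(unknown)[:5]}")
    by_approach = catalog.tags_by_approach()
    planted = {
        CLASS_SEXLINKED: truth.tags_of_class(CLASS_SEXLINKED),
        CLASS_LIMITED: truth.tags_of_class(CLASS_LIMITED),
        CLASS_AUTOSOMAL: truth.tags_of_class(CLASS_AUTOSOMAL),
    }
    target_class = {
        APPROACH_FREQ: CLASS_SEXLINKED,
        APPROACH_HET: CLASS_SEXLINKED,
        APPROACH_LIMITED: CLASS_LIMITED,
    }
    recall: dict = {}
    fps: dict = {}
    for approach, detected in by_approach.items():
        want = planted[target_class[approach]]
        recall[approach] = len(detected & want) / len(want) if want else None
        fps[approach] = len(detected & planted[CLASS_AUTOSOMAL])
    return DetectionMetrics(
        recall=recall,
        false_positives=fps,
        n_planted={c: len(s) for c, s in planted.items()},
    )


def write_truth_table(truth: TruthTable, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "id", "value", "reversed"])
        for tid in sorted(truth.tag_class):
            w.writerow(["tag", tid, truth.tag_class[tid], ""])
        for iid in sorted(truth.genetic_sex):
            w.writerow([
                "individual", iid, truth.genetic_sex[iid].value,
                int(iid in truth.reversed_ids),
            ])
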