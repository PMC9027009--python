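"""Alignment-based confirmation of putative markers from parsed BLAST hits.

Two rules are applied, exactly as printed in their sources:

* reference confirmation — a tag is confirmed iff its best (lowest E-value)
  hit has E <= ``e_max`` (inclusive);
* gene matching — a tag matches iff its best hit has E < ``e_max`` (strict)
  AND is at least ``margin_orders`` orders of magnitude below the second
  hit (vacuously satisfied by single-hit queries).

Running the aligner is out of scope; this module consumes tabular output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .detectors import MarkerCatalog

log = logging.getLogger(__name__)

RULE_TOP_HIT = "top_hit_e"
RULE_MARGIN = "margin_rule"


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column BLAST tabular output (coordinates 1-based
    inclusive, as in the dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")


@dataclass(frozen=True)
class ConfirmationParams:
    e_max: float = 1e-20
    margin_orders: float = 5.0

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be > 0")
        if self.margin_orders < 0:
            raise ValueError("margin_orders must be >= 0")


@dataclass(frozen=True)
class ConfirmationRecord:
    tag_id: str
    confirmed: bool
    rule: str
    best_hit: Optional[AlignmentHit]
    approach: Optional[str] = None  # provenance carried from the catalog


@dataclass(frozen=True)
class ConfirmationSummary:
    n_tags: int
    n_confirmed: int
    confirmed_by_approach: dict
    percent_confirmed: Optional[float]


def group_hits(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Group hits by query, best first (E ascending, bitscore descending,
    then subject id for determinism)."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for q in by_query:
        by_query[q].sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return by_query


def _warn_orphans(by_query: dict, tags: set[str]) -> None:
    orphans = sorted(q for q in by_query if q not in tags)
    if orphans:
        log.warning("%d hit query id(s) not in catalog, ignored: %s...", len(orphans), orphans[:5])


def confirm_to_reference(
    catalog: MarkerCatalog,
    hits: Sequence[AlignmentHit],
    params: ConfirmationParams | None = None,
) -> list[ConfirmationRecord]:
    """Top-hit rule: confirmed iff the best hit's E-value <= ``e_max``.
    Tags with no hits are unconfirmed."""
    params = params or ConfirmationParams()
    by_query = group_hits(hits)
    tags = catalog.distinct_tags
    _warn_orphans(by_query, tags)
    out: list[ConfirmationRecord] = []
    for tag_id in sorted(tags):
        tag_hits = by_query.get(tag_id, [])
        best = tag_hits[0] if tag_hits else None
        confirmed = best is not None and best.evalue <= params.e_max
        out.append(
            ConfirmationRecord(
                tag_id, confirmed, RULE_TOP_HIT, best,
                approach=catalog.primary_approach(tag_id),
            )
        )
    return out


def _margin_satisfied(best: AlignmentHit, second: AlignmentHit, orders: float) -> bool:
    if best.evalue == 0.0 and second.evalue == 0.0:
        # 10^-orders arithmetic is undefined at 0; fall back to bitscore
        return best.bitscore > second.bitscore
    if best.evalue == 0.0:
        return True
    # log-space comparison with a hair of slack so exact decade boundaries
    # (1e-25 vs 1e-20 at 5 orders) are not lost to float rounding
    return math.log10(second.evalue) - math.log10(best.evalue) >= orders - 1e-9


def match_to_gene(
    catalog: MarkerCatalog,
    hits: Sequence[AlignmentHit],
    params: ConfirmationParams | None = None,
) -> list[ConfirmationRecord]:
    """Margin rule: matched iff the best hit's E-value is strictly below
    ``e_max`` and at least ``margin_orders`` orders of magnitude below the
    second hit's (single-hit queries satisfy the margin vacuously)."""
    params = params or ConfirmationParams()
    by_query = group_hits(hits)
    tags = catalog.distinct_tags
    _warn_orphans(by_query, tags)
    out: list[ConfirmationRecord] = []
    for tag_id in sorted(tags):
        tag_hits = by_query.get(tag_id, [])
        best = tag_hits[0] if tag_hits else None
        matched = False
        if best is not None and best.evalue < params.e_max:
            matched = len(tag_hits) == 1 or _margin_satisfied(
                best, tag_hits[1], params.margin_orders
            )
        out.append(
            ConfirmationRecord(
                tag_id, matched, RULE_MARGIN, best,
                approach=catalog.primary_approach(tag_id),
            )
        )
    return out


def summarize_confirmation(records: Sequence[ConfirmationRecord]) -> ConfirmationSummary:
    """Aggregate per-approach confirmed counts and the overall total."""
    by_approach: dict = {}
    n_confirmed = 0
    for r in records:
        if r.confirmed:
            n_confirmed += 1
            by_approach[r.approach] = by_approach.get(r.approach, 0) + 1
    pct = 100.0 * n_confirmed / len(records) if records else None
    return ConfirmationSummary(
        n_tags=len(records),
        n_confirmed=n_confirmed,
        confirmed_by_approach=by_approach,
        percent_confirmed=pct,
    )


def write_confirmation_report(records: Sequence[ConfirmationRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag_id", "confirmed", "rule", "approach", "subject_id", "evalue", "bitscore"])
        for r in sorted(records, key=lambda r: r.tag_id):
            h = r.best_hit
            w.writerow([
                r.tag_id, int(r.confirmed), r.rule, r.approach or "NA",
                h.subject_id if h else "NA",
                f"{h.evalue:.3g}" if h else "NA",
                f"{h.bitscore:.6g}" if h else "NA",
            ])
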