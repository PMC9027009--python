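"""Positional validation-primer design on tag sequences.

Two strategies:

* SD — both primers sit on conserved (polymorphism-free) footprints flanking
  the target SNP, so both haplotypes amplify and the SNP is read from the
  sequenced product.
* PA — allele-specific: each primer's 3′-terminal base sits exactly on a SNP
  and carries the male-specific (Y) allele (complemented on the reverse
  primer), so only the Y haplotype amplifies mismatch-free.

Placements are purely positional; no thermodynamic screening is done beyond
an informational Wallace-rule Tm.  Coordinates are 0-based half-open on the
tag; product size is the base count of the amplified span including both
primer footprints.  The reverse primer is the reverse complement of a
plus-strand window, so its 3′ terminus corresponds to the *leftmost* plus
strand position of its footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .datamodel_io import TagLocus

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def wallace_tm(seq: str) -> float:
    """2(A+T) + 4(G+C) melting-temperature estimate, informational only."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerProposal:
    tag_id: str
    kind: str  # SD | PA
    forward_start: int
    forward_end: int
    reverse_start: int
    reverse_end: int
    forward_seq: str
    reverse_seq: str
    product_size: int
    anchored_sites: Optional[tuple[int, int]] = None  # PA: (forward SNP, reverse SNP)
    forward_tm: float = 0.0
    reverse_tm: float = 0.0


def _window_clean(offsets: set[int], start: int, end: int, allow: set[int] = frozenset()) -> bool:
    return all(o < start or o >= end or o in allow for o in offsets)


def propose_sd_primers(
    tag: TagLocus,
    target_site: int,
    primer_len: int = 20,
    min_flank: int = 10,
) -> Optional[PrimerProposal]:
    """Widest conserved placement around ``target_site``: leftmost clean
    forward window ending >= ``min_flank`` bases before the SNP, rightmost
    clean reverse window starting >= ``min_flank`` bases after it.  Returns
    None when no polymorphism-free placement exists."""
    if tag.sequence is None:
        raise ValueError(f"{tag.tag_id}: no sequence available")
    seq = tag.sequence
    if not 0 <= target_site < len(seq):
        raise ValueError(f"{tag.tag_id}: target site {target_site} outside sequence")
    offsets = set(tag.site_offsets)

    fwd = None
    for fs in range(0, target_site - min_flank - primer_len + 1):
        if _window_clean(offsets, fs, fs + primer_len):
            fwd = fs
            break
    if fwd is None:
        return None
    rev = None
    for rs in range(len(seq) - primer_len, target_site + min_flank, -1):
        if _window_clean(offsets, rs, rs + primer_len):
            rev = rs
            break
    if rev is None:
        return None

    f_seq = seq[fwd : fwd + primer_len]
    r_seq = revcomp(seq[rev : rev + primer_len])
    return PrimerProposal(
        tag.tag_id, "SD",
        forward_start=fwd, forward_end=fwd + primer_len,
        reverse_start=rev, reverse_end=rev + primer_len,
        forward_seq=f_seq, reverse_seq=r_seq,
        product_size=(rev + primer_len) - fwd,
        forward_tm=wallace_tm(f_seq), reverse_tm=wallace_tm(r_seq),
    )


def propose_pa_primer(
    tag: TagLocus,
    male_alleles: Mapping[int, str],
    primer_len: int = 20,
) -> Optional[PrimerProposal]:
    """Anchor both primers' 3′ termini on male-specific SNP alleles.

    The forward primer covers ``[s1+1-len, s1+1)`` with the male allele as
    its 3′-terminal base; the reverse primer covers ``[s2, s2+len)`` on the
    plus strand, so after reverse complementing its 3′-terminal base is the
    complement of the male allele at ``s2``.  Anchors are the leftmost
    usable SNP and the rightmost usable SNP right of it; footprints must
    contain no other polymorphic site.  Returns None when the tag has < 2
    SNPs or they are too close to the ends for ``primer_len``.
    """
    if tag.sequence is None:
        raise ValueError(f"{tag.tag_id}: no sequence available")
    seq = tag.sequence
    offsets = sorted(tag.site_offsets)
    if len(offsets) < 2:
        return None
    all_offsets = set(offsets)

    s1 = next(
        (
            s for s in offsets
            if s + 1 >= primer_len
            and _window_clean(all_offsets, s + 1 - primer_len, s + 1, allow={s})
        ),
        None,
    )
    if s1 is None:
        return None
    s2 = next(
        (
            s for s in reversed(offsets)
            if s > s1
            and s + primer_len <= len(seq)
            and _window_clean(all_offsets, s, s + primer_len, allow={s})
        ),
        None,
    )
    if s2 is None:
        return None

    def male_base(site: int) -> str:
        try:
            base = male_alleles[site].upper()
        except KeyError:
            raise KeyError(f"{tag.tag_id}: no male-specific allele for anchored site {site}") from None
        if base not in "ACGT":
            raise ValueError(f"{tag.tag_id}:{site}: male allele {base!r} not a nucleotide")
        if base == seq[site]:
            raise ValueError(
                f"{tag.tag_id}:{site}: male allele equals the tag (X) base; "
                f"anchoring would not discriminate"
            )
        return base

    b1, b2 = male_base(s1), male_base(s2)
    fs, fe = s1 + 1 - primer_len, s1 + 1
    rs, re = s2, s2 + primer_len
    f_seq = seq[fs : fe - 1] + b1
    r_seq = revcomp(b2 + seq[rs + 1 : re])

    # design self-check: Y haplotype anneals exactly, X haplotype mismatches
    # at both 3' termini
    male_hap = _substitute(seq, {s1: b1, s2: b2})
    assert f_seq == male_hap[fs:fe] and revcomp(r_seq) == male_hap[rs:re]
    assert f_seq[-1] != seq[s1] and revcomp(r_seq)[0] != seq[s2]

    return PrimerProposal(
        tag.tag_id, "PA",
        forward_start=fs, forward_end=fe,
        reverse_start=rs, reverse_end=re,
        forward_seq=f_seq, reverse_seq=r_seq,
        product_size=re - fs,
        anchored_sites=(s1, s2),
        forward_tm=wallace_tm(f_seq), reverse_tm=wallace_tm(r_seq),
    )


def _substitute(seq: str, alleles: Mapping[int, str]) -> str:
    out = list(seq)
    for pos, base in alleles.items():
        out[pos] = base
    return "".join(out)


def amplifies(proposal: PrimerProposal, template: str) -> bool:
    """Exact-match annealing check of both primers against a template
    haplotype over the proposal's footprints."""
    return (
        proposal.forward_seq == template[proposal.forward_start : proposal.forward_end]
        and revcomp(proposal.reverse_seq)
        == template[proposal.reverse_start : proposal.reverse_end]
    )


def write_proposals(proposals, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "tag_id", "type", "forward_start", "forward_end", "reverse_start",
            "reverse_end", "forward_seq", "reverse_seq", "product_size",
            "anchored_sites", "forward_tm", "reverse_tm",
        ])
        for p in proposals:
            anchored = (
                ",".join(str(s + 1) for s in p.anchored_sites) if p.anchored_sites else "NA"
            )
            w.writerow([
                p.tag_id, p.kind, p.forward_start, p.forward_end, p.reverse_start,
                p.reverse_end, p.forward_seq, p.reverse_seq, p.product_size,
                anchored, f"{p.forward_tm:.1f}", f"{p.reverse_tm:.1f}",
            ])
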