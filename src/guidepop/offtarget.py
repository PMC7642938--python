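"""Mismatch-bounded off-target search and exact-match biosafety screen.

Semantics follow the convention of genome-wide PAM-gated scanners:
mismatches are counted over the spacer only, while the PAM must match its
IUPAC class exactly (a hard gate).  Windows overlapping N reference bases
are excluded — no wildcard credit.  Only mismatch budgets of 0 or 1 are
supported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .seqcore import (
    GenomeStore,
    GuideCandidate,
    PamSpec,
    _DNA,
    pam_regex,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic locus matching a guide within the mismatch budget.

    ``start`` is the 1-based leftmost forward-strand coordinate of the
    protospacer; ``site_seq`` is protospacer+PAM in protospacer
    orientation (PAM first for 5' PAMs).
    """

    contig: str
    start: int
    strand: str
    mismatches: int
    site_seq: str


def _hamming_at_most(a: str, b: str, budget: int) -> int:
    """Mismatch count if <= budget, else -1. A window containing N is
    excluded outright (no wildcard or mismatch credit)."""
    mm = 0
    for x, y in zip(a, b):
        if x == "N":
            return -1
        if x != y:
            mm += 1
            if mm > budget:
                return -1
    return mm


def offtarget_search(
    guide: GuideCandidate,
    pam: PamSpec,
    genome: GenomeStore,
    max_mismatch: int = 0,
    on_target: Optional[tuple[str, int, str]] = None,
) -> list[OffTargetHit]:
    """All loci (both strands, all contigs) where the PAM window matches its
    IUPAC class and the spacer window has <= ``max_mismatch`` substitutions
    vs the guide spacer.

    ``on_target`` — a (contig, start, strand) triple for the design site —
    is excluded from the results when given.  Hits are returned in
    deterministic order (contig name, start, '+' before '-').
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    spacer = guide.spacer.upper()
    if not spacer or any(ch not in _DNA for ch in spacer):
        raise ValueError("guide spacer must be non-empty over A/C/G/T")
    if len(genome) == 0:
        raise ValueError("empty genome")

    regex = pam_regex(pam.pattern)
    plen = len(pam.pattern)
    slen = len(spacer)
    three_prime = pam.orientation == "three_prime"
    hits: list[OffTargetHit] = []

    for contig in sorted(genome.names()):
        seq = genome.contigs[contig]
        n = len(seq)
        for strand, strand_seq in (("+", seq), ("-", reverse_complement(seq))):
            for m in regex.finditer(strand_seq):
                j = m.start()
                s0 = j - slen if three_prime else j + plen
                if s0 < 0 or s0 + slen > n:
                    continue
                window = strand_seq[s0 : s0 + slen]
                mm = _hamming_at_most(window, spacer, max_mismatch)
                if mm < 0:
                    continue
                if strand == "+":
                    start = s0 + 1
                else:
                    start = n - s0 - slen + 1
                if on_target is not None and (contig, start, strand) == on_target:
                    continue
                pam_obs = strand_seq[j : j + plen]
                site = window + pam_obs if three_prime else pam_obs + window
                hits.append(
                    OffTargetHit(
                        contig=contig,
                        start=start,
                        strand=strand,
                        mismatches=mm,
                        site_seq=site,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, 0 if h.strand == "+" else 1))
    return hits


def offtarget_counts_pooled(
    guide: GuideCandidate,
    pam: PamSpec,
    genomes: dict[str, GenomeStore],
    max_mismatch: int = 0,
) -> tuple[dict[str, int], int]:
    """Per-genome off-target hit counts plus the pooled maximum."""
    counts = {
        name: len(offtarget_search(guide, pam, g, max_mismatch))
        for name, g in genomes.items()
    }
    return counts, max(counts.values()) if counts else 0


def biosafety_hits(guide: GuideCandidate, screen_genome: GenomeStore) -> bool:
    """True iff the spacer occurs verbatim on either strand of any contig.

    Mirrors an exact-match nucleotide query of the bare spacer: no PAM is
    required in the screened genome.
    """
    if len(screen_genome) == 0:
        raise ValueError("empty screen genome")
    spacer = guide.spacer.upper()
    rc = reverse_complement(spacer)
    for seq in screen_genome.contigs.values():
        if spacer in seq or rc in seq:
            return True
    return False
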