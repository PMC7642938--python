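"""Per-strain sequence reconstruction from variant calls and
strain-coverage prediction for guides.

A strain is *covered* by a guide when its reconstructed sequence contains
the exact spacer with an adjacent PAM-class match in the correct
orientation, on either strand.  The whole reconstructed region is scanned
(substring search), so an indel upstream of an intact site does not break
coverage — the protospacer, not its coordinate, determines cutting.  A
PAM-disrupting variant does break coverage: Cas nucleases cannot cut
without a PAM.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seqcore import (
    GuideCandidate,
    PamSpec,
    _DNA,
    _validate_dna,
    iupac_match,
    reverse_complement,
)

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
HET_POLICIES = ("alt_wins", "ref_wins", "strict_hom")


class VariantApplicationError(ValueError):
    """Variant records inconsistent with the reference or each other."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant call for one strain, VCF-style.

    ``pos`` is the 1-based reference position of the first REF base;
    indels carry the usual anchor base.  Symbolic/structural alleles are
    rejected at parse time.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str = "hom_alt"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele:
                raise ValueError(f"empty {name} allele at {self.contig}:{self.pos}")
            if any(ch not in _DNA for ch in allele.upper()):
                raise ValueError(
                    f"symbolic or non-ACGT {name} allele {allele!r} at "
                    f"{self.contig}:{self.pos}"
                )
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())

    @property
    def end(self) -> int:
        """1-based inclusive end of the REF footprint."""
        return self.pos + len(self.ref_allele) - 1


@dataclass
class StrainSequence:
    """One strain's variant-applied sequence for a reference region.

    ``ambiguous`` and ``missing`` hold 0-based half-open intervals in
    strain-sequence coordinates marking sites kept at REF under
    ``strict_hom`` het policy, respectively sites with missing genotype
    calls; coverage can be made conservative over them.
    """

    strain_id: str
    region: tuple[str, int, int]
    seq: str
    n_applied: int = 0
    ambiguous: list[tuple[int, int]] = field(default_factory=list)
    missing: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CoverageReport:
    """Per-guide strain coverage: counts plus identity lists."""

    guide: GuideCandidate
    covered: list[str]
    not_covered: list[str]

    @property
    def n_covered(self) -> int:
        return len(self.covered)

    @property
    def n_strains(self) -> int:
        return len(self.covered) + len(self.not_covered)


def apply_variants(
    ref_seq: str,
    region_start: int,
    variants: Sequence[VariantRecord],
    het_policy: str = "alt_wins",
    strain_id: str = "",
    contig: str = "",
) -> StrainSequence:
    """Apply a strain's variant records to a reference region.

    ``ref_seq`` is the forward-strand reference subsequence beginning at
    1-based ``region_start``.  Records must lie inside the region, be
    sorted by position, be non-overlapping, and their REF alleles must
    match the reference (validated; mismatch raises
    :class:`VariantApplicationError` naming the site).

    hom_alt records are applied; het records follow ``het_policy``
    (``alt_wins`` applies ALT, ``ref_wins`` keeps REF, ``strict_hom``
    keeps REF and marks the footprint ambiguous); hom_ref and missing
    keep REF, with missing sites recorded for conservative coverage.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"unknown het_policy {het_policy!r}")
    ref_seq = _validate_dna(ref_seq, frozenset("ACGTN"), "reference region")
    region_end = region_start + len(ref_seq) - 1

    pieces: list[str] = []
    ambiguous: list[tuple[int, int]] = []
    missing: list[tuple[int, int]] = []
    cursor = 0  # 0-based position in ref_seq consumed so far
    out_len = 0
    n_applied = 0
    prev_end = 0  # 1-based inclusive end of previous record

    for v in variants:
        if v.pos < region_start or v.end > region_end:
            raise VariantApplicationError(
                f"variant {v.contig or contig}:{v.pos} extends outside region "
                f"{contig}:{region_start}-{region_end}"
            )
        if v.pos <= prev_end:
            raise VariantApplicationError(
                f"overlapping variant records at {v.contig or contig}:{v.pos}"
            )
        prev_end = v.end
        off = v.pos - region_start
        ref_here = ref_seq[off : off + len(v.ref_allele)]
        if ref_here != v.ref_allele:
            raise VariantApplicationError(
                f"REF allele mismatch at {v.contig or contig}:{v.pos}: "
                f"record says {v.ref_allele!r}, reference has {ref_here!r}"
            )

        apply_alt = v.genotype == "hom_alt" or (
            v.genotype == "het" and het_policy == "alt_wins"
        )
        pieces.append(ref_seq[cursor:off])
        out_len += off - cursor
        if apply_alt:
            pieces.append(v.alt_allele)
            n_applied += 1
            footprint = (out_len, out_len + len(v.alt_allele))
            out_len += len(v.alt_allele)
        else:
            pieces.append(v.ref_allele)
            footprint = (out_len, out_len + len(v.ref_allele))
            out_len += len(v.ref_allele)
            if v.genotype == "het" and het_policy == "strict_hom":
                ambiguous.append(footprint)
            elif v.genotype == "missing":
                missing.append(footprint)
        cursor = off + len(v.ref_allele)

    pieces.append(ref_seq[cursor:])
    return StrainSequence(
        strain_id=strain_id,
        region=(contig, region_start, region_end),
        seq="".join(pieces),
        n_applied=n_applied,
        ambiguous=ambiguous,
        missing=missing,
    )


def find_guide_sites(seq: str, spacer: str, pam: PamSpec) -> list[tuple[int, int]]:
    """All 0-based half-open windows of ``seq`` containing an exact spacer
    match with an adjacent PAM-class match, on either strand.

    The returned window spans spacer plus PAM in forward coordinates.
    """
    plen = len(pam.pattern)
    slen = len(spacer)
    hits: list[tuple[int, int]] = []

    def scan(target_spacer: str, pam_pattern: str, pam_left: bool) -> None:
        i = seq.find(target_spacer)
        while i != -1:
            if pam_left:
                a, b = i - plen, i
                win = (a, i + slen)
            else:
                a, b = i + slen, i + slen + plen
                win = (i, b)
            if a >= 0 and b <= len(seq):
                window = seq[a:b]
                if "N" not in window and iupac_match(pam_pattern, window):
                    hits.append(win)
            i = seq.find(target_spacer, i + 1)

    from .seqcore import reverse_complement_iupac

    if pam.orientation == "three_prime":
        # forward: spacer then PAM; reverse: rc(PAM) then rc(spacer)
        scan(spacer, pam.pattern, pam_left=False)
        scan(reverse_complement(spacer), reverse_complement_iupac(pam.pattern), pam_left=True)
    else:
        scan(spacer, pam.pattern, pam_left=True)
        scan(reverse_complement(spacer), reverse_complement_iupac(pam.pattern), pam_left=False)
    return sorted(set(hits))


def _overlaps_any(win: tuple[int, int], intervals: Iterable[tuple[int, int]]) -> bool:
    a, b = win
    return any(a < e and s < b for s, e in intervals)


def strain_coverage(
    guide: GuideCandidate,
    pam: PamSpec,
    strain_seqs: Sequence[StrainSequence],
    strict_missing: bool = False,
) -> CoverageReport:
    """Which strains carry a perfect spacer+PAM site for ``guide``.

    A match window overlapping a ``strict_hom`` ambiguous interval never
    counts; with ``strict_missing`` the same applies to missing-genotype
    footprints (conservative mode).
    """
    if not strain_seqs:
        raise ValueError("empty strain set")
    covered: list[str] = []
    not_covered: list[str] = []
    for ss in strain_seqs:
        wins = find_guide_sites(ss.seq, guide.spacer, pam)
        blocked = list(ss.ambiguous)
        if strict_missing:
            blocked += ss.missing
        if any(not _overlaps_any(w, blocked) for w in wins):
            covered.append(ss.strain_id)
        else:
            not_covered.append(ss.strain_id)
    return CoverageReport(guide=guide, covered=covered, not_covered=not_covered)


def coverage_histogram(
    guides: Sequence[GuideCandidate],
    pam: PamSpec,
    strain_seqs: Sequence[StrainSequence],
    bin_width: int = 1,
    strict_missing: bool = False,
) -> dict[int, int]:
    """Histogram of per-guide covered-strain counts.

    With ``bin_width`` > 1 the keys are bin lower edges (0, w, 2w, ...).
    Counts always sum to the number of guides.
    """
    if not guides:
        raise ValueError("empty guide list")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: Counter[int] = Counter()
    for g in guides:
        n = strain_coverage(g, pam, strain_seqs, strict_missing=strict_missing).n_covered
        counts[(n // bin_width) * bin_width] += 1
    return dict(sorted(counts.items()))


def histogram_from_reports(
    reports: Sequence[CoverageReport], bin_width: int = 1
) -> dict[int, int]:
    """Bin already-computed coverage reports by covered-strain count."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: Counter[int] = Counter()
    for r in reports:
        counts[(r.n_covered // bin_width) * bin_width] += 1
    return dict(sorted(counts.items()))
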