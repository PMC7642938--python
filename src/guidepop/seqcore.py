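"""Sequence primitives: IUPAC motif semantics, reverse complement, and
exhaustive guide (spacer + PAM) enumeration on both strands.

Coordinates are 1-based and inclusive on the forward strand throughout,
matching GFF3/VCF conventions.  A guide candidate found on the minus
strand is reported in protospacer orientation (spacer and PAM
reverse-complemented) while ``start`` remains the forward-strand leftmost
coordinate of the spacer.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

logger = logging.getLogger(__name__)

#: IUPAC degenerate nucleotide codes -> the set of bases each admits.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")

# IUPAC complement covers the full degenerate alphabet so PAM patterns can
# be mirrored onto the minus strand (R<->Y, K<->M, B<->V, D<->H, N/S/W fixed).
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the expected DNA alphabet."""


def _validate_dna(seq: str, alphabet: frozenset[str], what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i + 1} in {what}"
            )
    return seq


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` (over A/C/G/T) matches the IUPAC ``pattern``
    position by position.

    Raises ``ValueError`` on length mismatch, an invalid IUPAC code in the
    pattern, or a non-ACGT base in ``seq``.
    """
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for p, s in zip(pattern.upper(), seq.upper()):
        allowed = IUPAC_CODES.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r} in pattern")
        if s not in _DNA:
            raise InvalidSequenceError(f"invalid base {s!r} in sequence")
        if s not in allowed:
            return False
    return True


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (involution)."""
    seq = _validate_dna(seq, _DNA_N)
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of a degenerate IUPAC pattern (e.g. NGG -> CCN)."""
    pattern = pattern.upper()
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern")
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def gc_percent(spacer: str) -> float:
    """GC content of a spacer as a percentage, ``100 * (G + C) / length``."""
    if not spacer:
        raise ValueError("empty spacer")
    spacer = _validate_dna(spacer, _DNA, "spacer")
    return 100.0 * (spacer.count("G") + spacer.count("C")) / len(spacer)


def pam_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC PAM pattern into an overlapping-match regex.

    Degenerate codes expand to explicit character classes over A/C/G/T, so
    reference N bases can never satisfy a PAM position.
    """
    parts = []
    for ch in pattern.upper():
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in PAM pattern")
        bases = "".join(sorted(allowed))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(r"(?=" + "".join(parts) + r")")


@dataclass(frozen=True)
class PamSpec:
    """A PAM class: IUPAC pattern plus its orientation relative to the spacer.

    ``three_prime`` (Cas9-style, e.g. NGG) places the PAM immediately 3' of
    the spacer on the protospacer strand; ``five_prime`` (Cas12a-style,
    e.g. TTTV) places it immediately 5'.
    """

    pattern: str
    orientation: str = "three_prime"

    #: PAM patterns whose nuclease reads the motif 5' of the spacer.
    FIVE_PRIME_DEFAULTS = frozenset({"TTTV", "TTTN"})

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        if not pattern:
            raise ValueError("PAM pattern must be non-empty")
        for ch in pattern:
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {ch!r} in PAM pattern")
        if self.orientation not in ("three_prime", "five_prime"):
            raise ValueError(
                "orientation must be 'three_prime' or 'five_prime', "
                f"got {self.orientation!r}"
            )
        object.__setattr__(self, "pattern", pattern)

    @classmethod
    def with_default_orientation(cls, pattern: str, orientation: Optional[str] = None) -> "PamSpec":
        """Build a PamSpec, inferring orientation from the pattern when not given."""
        pattern = pattern.upper()
        if orientation is None:
            orientation = (
                "five_prime" if pattern in cls.FIVE_PRIME_DEFAULTS else "three_prime"
            )
        return cls(pattern=pattern, orientation=orientation)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class GuideCandidate:
    """A spacer with its observed PAM and location.

    ``start`` is the 1-based leftmost forward-strand coordinate of the
    spacer; ``gene_offset`` is the 1-based position of the spacer's 5' end
    within the target gene or custom sequence (absent when unknown).
    """

    spacer: str
    pam_observed: str
    contig: str
    start: int
    strand: str
    gene_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class GenomeStore:
    """Named contigs with strand-aware subsequence access.

    Sequences are uppercased on load; any character outside A/C/G/T/N is
    replaced by N (degenerate reference codes carry no single base and are
    treated as ambiguous).
    """

    def __init__(self, contigs: Mapping[str, str]) -> None:
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in self.contigs:
                raise ValueError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            cleaned = "".join(ch if ch in _DNA_N else "N" for ch in seq)
            self.contigs[name] = cleaned

    @classmethod
    def from_fasta(cls, path) -> "GenomeStore":
        from .io import read_fasta

        return read_fasta(path)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive subsequence; minus strand returns the reverse
        complement."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"coordinates {start}-{end} out of range for contig "
                f"{contig!r} (length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        return reverse_complement(sub) if strand == "-" else sub


def _enumerate_one_strand(
    seq: str, pam: PamSpec, spacer_len: int
) -> Iterator[tuple[int, str, str]]:
    """Yield (0-based spacer start, spacer, observed PAM) on the given
    strand's literal sequence. Candidates whose spacer overlaps N are dropped."""
    regex = pam_regex(pam.pattern)
    plen = len(pam.pattern)
    n = len(seq)
    for m in regex.finditer(seq):
        j = m.start()  # PAM start
        if pam.orientation == "three_prime":
            s0 = j - spacer_len
            if s0 < 0:
                continue
        else:
            s0 = j + plen
            if s0 + spacer_len > n:
                continue
        spacer = seq[s0 : s0 + spacer_len]
        if "N" in spacer:
            logger.debug("dropping candidate at %d: spacer overlaps N", s0)
            continue
        yield s0, spacer, seq[j : j + plen]


def enumerate_guides(
    seq: str,
    pam: PamSpec,
    spacer_len: int = 20,
    contig: str = "seq",
) -> list[GuideCandidate]:
    """Enumerate every spacer+PAM site on both strands of ``seq``.

    Returns candidates in deterministic order: ascending forward-strand
    ``start``, '+' before '-' at ties.  A sequence too short to host a
    guide yields an empty list.  ``gene_offset`` is filled with the 1-based
    position of the spacer's 5' end within ``seq``.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    seq = _validate_dna(seq, _DNA_N)
    n = len(seq)
    site_len = spacer_len + len(pam.pattern)
    if n < site_len:
        return []

    candidates: list[GuideCandidate] = []
    for s0, spacer, pam_obs in _enumerate_one_strand(seq, pam, spacer_len):
        start = s0 + 1
        candidates.append(
            GuideCandidate(
                spacer=spacer,
                pam_observed=pam_obs,
                contig=contig,
                start=start,
                strand="+",
                gene_offset=start,
            )
        )
    rc = reverse_complement(seq)
    for s0, spacer, pam_obs in _enumerate_one_strand(rc, pam, spacer_len):
        # spacer occupies rc[s0 : s0+L] -> forward positions [n-s0-L, n-s0)
        start = n - s0 - spacer_len + 1
        candidates.append(
            GuideCandidate(
                spacer=spacer,
                pam_observed=pam_obs,
                contig=contig,
                start=start,
                strand="-",
                gene_offset=start + spacer_len - 1,
            )
        )
    candidates.sort(key=lambda g: (g.start, 0 if g.strand == "+" else 1))
    return candidates
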