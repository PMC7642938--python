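"""Independent brute-force oracles for guide enumeration and off-target
search.  Deliberately naive double loops over strands and positions with
per-position IUPAC checks; they share no code with the package engines.
"""
from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def pam_ok(pattern: str, window: str) -> bool:
    if len(window) != len(pattern) or "N" in window:
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern, window))


def brute_enumerate(seq: str, pam_pattern: str, orientation: str, spacer_len: int):
    """Every (spacer, pam_observed, forward-leftmost 1-based start, strand)
    on both strands, sorted ascending start with '+' first."""
    n = len(seq)
    plen = len(pam_pattern)
    out = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for i in range(n - spacer_len - plen + 1):
            if orientation == "three_prime":
                spacer = s[i : i + spacer_len]
                pam = s[i + spacer_len : i + spacer_len + plen]
                sp0 = i
            else:
                pam = s[i : i + plen]
                spacer = s[i + plen : i + plen + spacer_len]
                sp0 = i + plen
            if "N" in spacer or not pam_ok(pam_pattern, pam):
                continue
            if strand == "+":
                start = sp0 + 1
            else:
                start = n - sp0 - spacer_len + 1
            out.append((spacer, pam, start, strand))
    out.sort(key=lambda t: (t[2], 0 if t[3] == "+" else 1))
    return out


def brute_offtarget(
    spacer: str,
    pam_pattern: str,
    orientation: str,
    contigs: dict[str, str],
    max_mismatch: int,
    exclude=None,
):
    """Every PAM-gated locus within the mismatch budget, as
    (contig, start, strand, mismatches) sorted like the engine output."""
    out = []
    slen = len(spacer)
    plen = len(pam_pattern)
    for contig in sorted(contigs):
        seq = contigs[contig]
        n = len(seq)
        for strand in ("+", "-"):
            s = seq if strand == "+" else rc(seq)
            for i in range(n - slen - plen + 1):
                if orientation == "three_prime":
                    window, pam, sp0 = s[i : i + slen], s[i + slen : i + slen + plen], i
                else:
                    pam, window, sp0 = s[i : i + plen], s[i + plen : i + plen + slen], i + plen
                if not pam_ok(pam_pattern, pam) or "N" in window:
                    continue
                mm = sum(1 for a, b in zip(window, spacer) if a != b)
                if mm > max_mismatch:
                    continue
                start = sp0 + 1 if strand == "+" else n - sp0 - slen + 1
                if exclude is not None and (contig, start, strand) == exclude:
                    continue
                out.append((contig, start, strand, mm))
    out.sort(key=lambda t: (t[0], t[1], 0 if t[2] == "+" else 1))
    return out
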