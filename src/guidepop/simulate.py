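"""Synthetic reference + population generator with planted ground truth.

Produces a small random reference genome, non-overlapping gene
annotations, and per-strain VCFs whose variants (sampled plus planted)
are recorded in a ground-truth sidecar.  Everything is a deterministic
function of the seed: the same spec yields byte-identical files.

Variants are sampled independently per strain with no shared phylogeny —
adequate for correctness testing, not a realistic population structure.
Indels are limited to length 3 so that oracle string reconstruction
stays simple.

The module also hosts the independent brute-force coverage oracle
(:func:`expected_coverage`) and a small two-allele locus fixture for
portability checks; neither shares code with the coverage engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqcore import GenomeStore, GuideCandidate, PamSpec

_BASES = "ACGT"

# local IUPAC table so the oracle does not lean on the engine's
_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class PlantedEdit:
    """A deterministic variant planted into a subset of strains."""

    strains: tuple[str, ...]
    pos: int
    ref: str
    alt: str
    contig: str = "chr1"
    genotype: str = "hom_alt"


@dataclass
class PopulationSpec:
    """Study conditions for one synthetic population."""

    n_strains: int = 20
    genome_len: int = 10_000
    n_genes: int = 3
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    planted_edits: Sequence[PlantedEdit] = field(default_factory=tuple)
    seed: int = 0
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.snp_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.genome_len < 200:
            raise ValueError("genome_len must be >= 200")
        if self.n_strains < 1:
            raise ValueError("need at least one strain")

    def strain_ids(self) -> list[str]:
        width = len(str(self.n_strains))
        return [f"s{idx:0{width}d}" for idx in range(1, self.n_strains + 1)]


@dataclass
class GroundTruthVariant:
    strain: str
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str


@dataclass
class Population:
    """Generated files plus the in-memory ground truth."""

    spec: PopulationSpec
    reference_fasta: Path
    gff3: Path
    vcfs: dict[str, Path]
    ground_truth_tsv: Path
    reference: GenomeStore
    genes: list[tuple[str, str, int, int, str]]  # (gene_id, contig, start, end, strand)
    truth: dict[str, list[GroundTruthVariant]]

    def manifest(self, path: Optional[Path] = None) -> Path:
        """Write a strain manifest next to the VCFs (or at ``path``)."""
        if path is None:
            path = self.reference_fasta.parent / "strains.tsv"
        lines = [f"{sid}\t{self.vcfs[sid].name}" for sid in self.spec.strain_ids()]
        path.write_text("\n".join(lines) + "\n")
        return path


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def _sample_strain_variants(
    rng: np.random.Generator, ref: str, spec: PopulationSpec
) -> list[GroundTruthVariant]:
    """Independent per-strain SNPs and short (<=3 bp) indels, non-overlapping."""
    out: list[GroundTruthVariant] = []
    n = len(ref)
    draws = rng.random(n)
    kinds = rng.random(n)
    prev_end = 0  # 1-based inclusive end of last accepted record
    for i in range(n):
        p = draws[i]
        pos = i + 1
        if p >= spec.snp_rate + spec.indel_rate:
            continue
        if pos <= prev_end:
            continue
        if p < spec.snp_rate:
            refb = ref[i]
            if refb not in _BASES:
                continue
            alt = _BASES[(_BASES.index(refb) + int(rng.integers(1, 4))) % 4]
            out.append(GroundTruthVariant("", spec.contig, pos, refb, alt, "hom_alt"))
            prev_end = pos
        else:
            ilen = int(rng.integers(1, 4))
            if kinds[i] < 0.5:  # deletion (anchor + ilen deleted bases)
                if i + ilen >= n:
                    continue
                ref_allele = ref[i : i + 1 + ilen]
                if "N" in ref_allele:
                    continue
                out.append(
                    GroundTruthVariant("", spec.contig, pos, ref_allele, ref[i], "hom_alt")
                )
                prev_end = pos + ilen
            else:  # insertion after the anchor base
                ins = "".join(_BASES[b] for b in rng.integers(0, 4, size=ilen))
                if ref[i] == "N":
                    continue
                out.append(
                    GroundTruthVariant("", spec.contig, pos, ref[i], ref[i] + ins, "hom_alt")
                )
                prev_end = pos
    return out


_VCF_HEADER = """##fileformat=VCFv4.2
##source=guidepop-simulate
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_GT_STRINGS = {"hom_alt": "1/1", "het": "0/1", "hom_ref": "0/0", "missing": "./."}


def _write_vcf(path: Path, spec: PopulationSpec, strain: str,
               variants: list[GroundTruthVariant]) -> None:
    lines = [_VCF_HEADER.format(contig=spec.contig, length=spec.genome_len,
                                sample=strain).rstrip("\n")]
    for v in sorted(variants, key=lambda v: v.pos):
        lines.append(
            f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{_GT_STRINGS[v.genotype]}"
        )
    path.write_text("\n".join(lines) + "\n")


def generate_population(spec: PopulationSpec, outdir) -> Population:
    """Generate reference FASTA, GFF3, per-strain VCFs and a ground-truth
    sidecar under ``outdir``.

    Planted edits are applied verbatim after sampling (sampled records
    overlapping a planted site are discarded in favour of the plant); a
    planted edit whose REF contradicts the generated reference raises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ref = _random_reference(rng, spec.genome_len)

    # validate plants against the reference before anything is written
    for pe in spec.planted_edits:
        have = ref[pe.pos - 1 : pe.pos - 1 + len(pe.ref)]
        if have != pe.ref.upper():
            raise ValueError(
                f"planted edit at {pe.contig}:{pe.pos} declares REF "
                f"{pe.ref!r} but the generated reference has {have!r}"
            )

    fasta = outdir / "reference.fa"
    wrapped = "\n".join(ref[i : i + 70] for i in range(0, len(ref), 70))
    fasta.write_text(f">{spec.contig}\n{wrapped}\n")

    # non-overlapping genes spread evenly across the contig
    genes: list[tuple[str, str, int, int, str]] = []
    slot = spec.genome_len // max(spec.n_genes, 1)
    glen = max(60, slot // 2)
    for k in range(spec.n_genes):
        start = k * slot + slot // 4 + 1
        end = min(start + glen - 1, spec.genome_len)
        strand = "+" if k % 2 == 0 else "-"
        genes.append((f"gene{k + 1}", spec.contig, start, end, strand))
    gff = outdir / "genes.gff3"
    gff_lines = ["##gff-version 3"]
    for gid, contig, start, end, strand in genes:
        gff_lines.append(
            f"{contig}\tguidepop\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid};Name={gid.upper()}"
        )
    gff.write_text("\n".join(gff_lines) + "\n")

    truth: dict[str, list[GroundTruthVariant]] = {}
    vcfs: dict[str, Path] = {}
    for strain in spec.strain_ids():
        sampled = _sample_strain_variants(rng, ref, spec)
        plants = [
            GroundTruthVariant(strain, pe.contig, pe.pos, pe.ref.upper(),
                               pe.alt.upper(), pe.genotype)
            for pe in spec.planted_edits
            if strain in pe.strains
        ]
        plant_spans = [(p.pos, p.pos + len(p.ref) - 1) for p in plants]
        kept = [
            v for v in sampled
            if not any(v.pos <= e and s <= v.pos + len(v.ref) - 1 for s, e in plant_spans)
        ]
        records = sorted(
            [GroundTruthVariant(strain, v.contig, v.pos, v.ref, v.alt, v.genotype)
             for v in kept] + plants,
            key=lambda v: v.pos,
        )
        truth[strain] = records
        vcf_path = outdir / f"{strain}.vcf"
        _write_vcf(vcf_path, spec, strain, records)
        vcfs[strain] = vcf_path

    gt_path = outdir / "ground_truth.tsv"
    gt_lines = ["strain\tcontig\tpos\tref\talt\tgenotype"]
    for strain in spec.strain_ids():
        for v in truth[strain]:
            gt_lines.append(f"{v.strain}\t{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.genotype}")
    gt_path.write_text("\n".join(gt_lines) + "\n")

    return Population(
        spec=spec,
        reference_fasta=fasta,
        gff3=gff,
        vcfs=vcfs,
        ground_truth_tsv=gt_path,
        reference=GenomeStore({spec.contig: ref}),
        genes=genes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Independent brute-force coverage oracle


def _oracle_rebuild(ref_region: str, region_start: int,
                    variants: list[GroundTruthVariant]) -> str:
    """Rebuild a strain's region string by applying edits right-to-left.

    Deliberately distinct from the engine's left-to-right piecewise
    application; only hom_alt and het records are applied (consensus
    semantics with ALT winning at het sites).
    """
    chars = list(ref_region)
    for v in sorted(variants, key=lambda v: -v.pos):
        if v.genotype not in ("hom_alt", "het"):
            continue
        i = v.pos - region_start
        if i < 0 or i + len(v.ref) > len(ref_region):
            continue
        assert "".join(chars[i : i + len(v.ref)]) == v.ref
        chars[i : i + len(v.ref)] = list(v.alt)
    return "".join(chars)


def _oracle_spacer_set(seq: str, pam: PamSpec, spacer_len: int) -> set[str]:
    """All spacers with a valid adjacent PAM anywhere on either strand.

    Enumerates every PAM-adjacent window per position (the reverse of the
    engine's find-spacer-then-check-PAM strategy), so covered/uncovered
    decisions come from an algorithmically different route.
    """
    allowed = [_ORACLE_IUPAC[c] for c in pam.pattern]
    plen = len(pam.pattern)
    found: set[str] = set()
    rc = "".join(_ORACLE_COMP[c] for c in reversed(seq))
    for s in (seq, rc):
        for i in range(len(s) - spacer_len - plen + 1):
            if pam.orientation == "three_prime":
                pm = s[i + spacer_len : i + spacer_len + plen]
                sp = s[i : i + spacer_len]
            else:
                pm = s[i : i + plen]
                sp = s[i + plen : i + plen + spacer_len]
            if all(b in a for b, a in zip(pm, allowed)) and "N" not in sp:
                found.add(sp)
    return found


def _oracle_site_present(seq: str, spacer: str, pam: PamSpec) -> bool:
    """Both-strand scan for the spacer with an adjacent PAM."""
    return spacer in _oracle_spacer_set(seq, pam, len(spacer))


def expected_coverage(
    population: Population,
    guides: Sequence[GuideCandidate],
    pam: PamSpec,
    region: tuple[str, int, int],
) -> dict[GuideCandidate, int]:
    """Ground-truth coverage per guide via independent string rebuilds.

    For each strain the region string is rebuilt from the ground-truth
    variant list (right-to-left edits) and scanned per position on both
    strands; no engine code paths are reused.
    """
    contig, start, end = region
    ref_region = population.reference.contigs[contig][start - 1 : end]
    rebuilt = {}
    for strain in population.spec.strain_ids():
        inside = [v for v in population.truth[strain]
                  if v.contig == contig and start <= v.pos and v.pos + len(v.ref) - 1 <= end]
        rebuilt[strain] = _oracle_rebuild(ref_region, start, inside)
    spacer_lens = {len(g.spacer) for g in guides}
    sets = {
        strain: {L: _oracle_spacer_set(s, pam, L) for L in spacer_lens}
        for strain, s in rebuilt.items()
    }
    return {
        g: sum(1 for strain in population.spec.strain_ids()
               if g.spacer in sets[strain][len(g.spacer)])
        for g in guides
    }


# ---------------------------------------------------------------------------
# Two-allele portability locus (synthetic)


@dataclass
class PortabilityLocus:
    """Synthetic two-allele locus for qualitative portability checks.

    A ~150 bp sequence hosting four NGG guides modelled on a knockout
    design: two 'high' guides (one per strand) away from the variant
    site, and two overlapping 'low' guides whose spacers both span a
    planted SNP that sits at position 27 of the 28 nt alignment window
    shown around them.  Carrier strains hold the SNP homozygously, so
    guides spanning it lose those strains while the others keep full
    coverage.
    """

    ref_seq: str
    snp_pos: int  # 1-based position in ref_seq
    snp_ref: str
    snp_alt: str
    high_spacers: tuple[str, str]
    low_spacers: tuple[str, str]
    window: tuple[int, int]  # 1-based inclusive 28 nt display window


def portability_locus() -> PortabilityLocus:
    """Build the packaged two-allele locus fixture (synthetic sequence)."""
    h1 = "ACTTTGGCATACGATGGAAG"
    h2 = "ACGGAGTCCGGAACTCTAGC"
    l2 = "AACAGTTGGTATATTAGGAG"          # low guides overlap, offset by one
    l1 = l2[1:] + "G"
    # minus-strand cassette for h2: revcomp(spacer + TGG PAM)
    h2_cassette = "CCA" + "GCTAGAGTTCCGGACTCCGT"
    pad5 = "TATCTAT"                      # 7 nt so the SNP lands at window pos 27
    low_cassette = pad5 + l2 + "G" + "GGG"
    seq = h1 + "AGG" + "TCTCA" + h2_cassette + "TCACT" + low_cassette + "TACTTCAAC"
    low_start = len(seq) - len(low_cassette) - len("TACTTCAAC") + 1
    window = (low_start, low_start + 27)
    snp_pos = low_start + 26              # window position 27
    assert seq[snp_pos - 1] == "G"
    return PortabilityLocus(
        ref_seq=seq,
        snp_pos=snp_pos,
        snp_ref="G",
        snp_alt="A",
        high_spacers=(h1, h2),
        low_spacers=(l1, l2),
        window=window,
    )
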