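"""End-to-end runs for the three operating modes: targeting an annotated
gene, targeting a custom sequence, and a standalone off-site search.

Every run is a deterministic function of its configuration and inputs —
there is no randomness anywhere in the pipeline — so repeated runs write
byte-identical output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import io as gio
from .io import DataError
from .offtarget import OffTargetHit, biosafety_hits, offtarget_search
from .popcov import StrainSequence, apply_variants, strain_coverage
from .scoring import DesignRow, build_design_table, get_scorer, write_table
from .seqcore import (
    GenomeStore,
    GuideCandidate,
    PamSpec,
    _validate_dna,
    enumerate_guides,
)
import dataclasses

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides its mode-specific argument."""

    reference: Optional[Path] = None
    annotation: Optional[Path] = None
    strain_manifest: Optional[Path] = None
    biosafety_genome: Optional[Path] = None
    pam_pattern: str = "NGG"
    pam_orientation: Optional[str] = None  # inferred from pattern when None
    spacer_len: int = 20
    max_mismatch: int = 0
    scorer_id: str = "gc_balance"
    score_table: Optional[Path] = None
    het_policy: str = "alt_wins"
    strict_missing: bool = False
    output: Optional[Path] = None
    format: str = "tsv"
    seed: int = 0

    def pam(self) -> PamSpec:
        return PamSpec.with_default_orientation(self.pam_pattern, self.pam_orientation)

    def scorer(self):
        return get_scorer(self.scorer_id, self.score_table)

    def metadata(self) -> dict:
        md = {
            "pam": self.pam().pattern,
            "pam_orientation": self.pam().orientation,
            "spacer_length": self.spacer_len,
            "max_mismatch": self.max_mismatch,
            "scorer": self.scorer_id,
            "het_policy": self.het_policy,
            "strict_missing": self.strict_missing,
        }
        if self.scorer_id == "gc_balance":
            md["scorer_note"] = "gc_balance is a placeholder heuristic, not a trained activity model"
        return md


@dataclass
class GeneTargetResult:
    rows: list[DesignRow]
    guides: list[GuideCandidate]
    region: tuple[str, int, int]
    strain_seqs: list[StrainSequence]
    output_text: str


def _load_strains(
    config: RunConfig,
    region: tuple[str, int, int],
    ref_region: str,
) -> list[StrainSequence]:
    contig, start, end = region
    entries = gio.read_manifest(config.strain_manifest)
    seqs: list[StrainSequence] = []
    n_variants = 0
    for strain_id, vcf_path, sample in entries:
        if not vcf_path.exists():
            raise DataError(f"VCF for strain {strain_id!r} not found: {vcf_path}")
        variants = gio.load_strain_variants(vcf_path, contig, start, end, sample=sample)
        n_variants += len(variants)
        seqs.append(
            apply_variants(
                ref_region,
                start,
                variants,
                het_policy=config.het_policy,
                strain_id=strain_id,
                contig=contig,
            )
        )
    logger.info("loaded %d strains, %d variant records in region", len(seqs), n_variants)
    return seqs


def run_gene_target(config: RunConfig, gene_id: str) -> GeneTargetResult:
    """Design guides against one annotated gene and predict strain coverage.

    Pipeline: extract the gene (plus a |PAM|+max_mismatch flank so
    boundary guides keep their PAM and mismatch context) -> enumerate
    guides on both strands -> reconstruct per-strain sequences from VCFs
    -> coverage -> off-target search vs the reference genome -> optional
    biosafety screen -> score and assemble the table.
    """
    if config.reference is None or config.annotation is None:
        raise DataError("gene targeting requires --reference and --gff")
    genome = gio.read_fasta(config.reference)
    contig, gstart, gend, gstrand = gio.read_gff_gene(config.annotation, gene_id)
    if contig not in genome:
        raise DataError(f"gene {gene_id!r} lies on contig {contig!r} absent from the reference")
    pam = config.pam()
    flank = len(pam.pattern) + config.max_mismatch
    clen = genome.length(contig)
    start = max(1, gstart - flank)
    end = min(clen, gend + flank)
    region = (contig, start, end)
    ref_region = genome.fetch(contig, start, end)

    local = enumerate_guides(ref_region, pam, config.spacer_len, contig=contig)
    guides: list[GuideCandidate] = []
    for g in local:
        genomic_start = start + g.start - 1
        five_prime = genomic_start if g.strand == "+" else genomic_start + config.spacer_len - 1
        offset = five_prime - gstart + 1 if gstrand == "+" else gend - five_prime + 1
        guides.append(dataclasses.replace(g, start=genomic_start, gene_offset=offset))
    logger.info("enumerated %d guides in %s:%d-%d", len(guides), contig, start, end)

    coverage = None
    strain_seqs: list[StrainSequence] = []
    if config.strain_manifest is not None:
        strain_seqs = _load_strains(config, region, ref_region)
        coverage = {
            g: strain_coverage(g, pam, strain_seqs, strict_missing=config.strict_missing)
            for g in guides
        }

    ot_counts = {
        g: len(
            offtarget_search(
                g, pam, genome, config.max_mismatch,
                on_target=(g.contig, g.start, g.strand),
            )
        )
        for g in guides
    }
    logger.info("off-target hits found: %d", sum(ot_counts.values()))

    bio = None
    if config.biosafety_genome is not None:
        screen = gio.read_fasta(config.biosafety_genome)
        bio = {g: biosafety_hits(g, screen) for g in guides}

    rows = build_design_table(
        guides,
        config.scorer(),
        coverage_reports=coverage,
        offtarget_counts=ot_counts,
        biosafety_flags=bio,
        mismatches_allowed=config.max_mismatch,
    )
    md = config.metadata()
    md.update({"mode": "gene_target", "gene": gene_id,
               "region": f"{contig}:{start}-{end}", "gene_strand": gstrand,
               "n_strains": len(strain_seqs)})
    text = write_table(rows, config.format, metadata=md)
    if config.output is not None:
        Path(config.output).write_text(text)
    return GeneTargetResult(rows=rows, guides=guides, region=region,
                            strain_seqs=strain_seqs, output_text=text)


@dataclass
class CustomTargetResult:
    rows: list[DesignRow]
    guides: list[GuideCandidate]
    output_text: str


def run_custom_target(config: RunConfig, seq: str) -> CustomTargetResult:
    """Design guides within a user-supplied sequence.

    Coverage columns stay empty (no strain coordinates exist for a free
    sequence); an off-target search runs against the reference genome
    when one is supplied.  A sequence too short to host a guide yields an
    empty table with a warning and success status.
    """
    seq = _validate_dna(seq, frozenset("ACGTN"), "custom sequence")
    pam = config.pam()
    guides = enumerate_guides(seq, pam, config.spacer_len, contig="custom")
    if not guides:
        logger.warning(
            "custom sequence (length %d) hosts no guide for spacer length %d + PAM %s",
            len(seq), config.spacer_len, pam.pattern,
        )
    ot_counts = None
    if config.reference is not None and guides:
        genome = gio.read_fasta(config.reference)
        ot_counts = {
            g: len(offtarget_search(g, pam, genome, config.max_mismatch))
            for g in guides
        }
    bio = None
    if config.biosafety_genome is not None and guides:
        screen = gio.read_fasta(config.biosafety_genome)
        bio = {g: biosafety_hits(g, screen) for g in guides}
    rows = build_design_table(
        guides,
        config.scorer(),
        offtarget_counts=ot_counts,
        biosafety_flags=bio,
        mismatches_allowed=config.max_mismatch,
    )
    md = config.metadata()
    md.update({"mode": "custom_target", "sequence_length": len(seq)})
    text = write_table(rows, config.format, metadata=md)
    if config.output is not None:
        Path(config.output).write_text(text)
    return CustomTargetResult(rows=rows, guides=guides, output_text=text)


NONE_FOUND_MESSAGE = "No offsite targets were found."

OFFSITE_COLUMNS = ["contig", "start", "strand", "mismatches", "site_seq"]


@dataclass
class OffsiteSearchResult:
    hits: list[OffTargetHit]
    output_text: str


def run_offsite_search(config: RunConfig, spacer: str) -> OffsiteSearchResult:
    """Search a genome for matches to an already-designed spacer."""
    if config.reference is None:
        raise DataError("offsite search requires --reference")
    spacer = _validate_dna(spacer, frozenset("ACGT"), "spacer")
    genome = gio.read_fasta(config.reference)
    pam = config.pam()
    guide = GuideCandidate(spacer=spacer, pam_observed="N" * len(pam.pattern),
                           contig="query", start=1, strand="+")
    hits = offtarget_search(guide, pam, genome, config.max_mismatch)
    if hits:
        lines = ["\t".join(OFFSITE_COLUMNS)]
        for h in hits:
            lines.append(f"{h.contig}\t{h.start}\t{h.strand}\t{h.mismatches}\t{h.site_seq}")
        text = "\n".join(lines) + "\n"
    else:
        text = NONE_FOUND_MESSAGE + "\n"
    if config.output is not None:
        Path(config.output).write_text(text)
    return OffsiteSearchResult(hits=hits, output_text=text)
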