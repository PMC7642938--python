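"""Readers for the standard formats the pipeline consumes: FASTA
references, GFF3 annotations, per-strain VCFs, and the strain manifest."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .popcov import VariantRecord
from .seqcore import GenomeStore

logger = logging.getLogger(__name__)


class DataError(Exception):
    """Input data missing, malformed, or inconsistent."""


def read_fasta(path) -> GenomeStore:
    """Load a (possibly multi-contig, wrapped, mixed-case) FASTA file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise DataError(f"duplicate contig {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise DataError(f"no sequences found in {path}")
    return GenomeStore(contigs)


def read_gff_gene(path, gene_id: str) -> tuple[str, int, int, str]:
    """Look up a gene by ID or Name attribute in a GFF3 file.

    Returns (contig, start, end, strand), 1-based inclusive.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise DataError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )
    try:
        feat = db[gene_id]
    except Exception:
        feat = None
    if feat is None:
        for f in db.all_features():
            names = f.attributes.get("Name", []) + f.attributes.get("gene", [])
            if gene_id in names:
                feat = f
                break
    if feat is None:
        raise DataError(f"gene {gene_id!r} not found by ID or Name in {path}")
    strand = feat.strand if feat.strand in ("+", "-") else "+"
    return feat.seqid, feat.start, feat.end, strand


def _classify_genotype(gt: tuple) -> tuple[str, Optional[int]]:
    """Map a VCF GT tuple to (genotype class, 1-based called ALT index).

    A call mixing two different non-reference alleles is treated as het on
    the first called ALT.
    """
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return "missing", None
    alleles = [a for a in gt]
    alts = sorted({a for a in alleles if a > 0})
    if not alts:
        return "hom_ref", None
    if 0 in alleles or len(alts) > 1:
        return "het", alts[0]
    return "hom_alt", alts[0]


def load_strain_variants(
    vcf_path,
    contig: str,
    start: int,
    end: int,
    sample: Optional[str] = None,
) -> list[VariantRecord]:
    """Parse one strain's variants inside a region from a VCF file.

    Multi-allelic records are split and only the called ALT kept.
    hom_ref calls are dropped (no-ops for consensus building); symbolic or
    non-ACGT alleles raise :class:`DataError`.  Records straddling a
    region edge are skipped (the caller's flank makes this immaterial).
    """
    import pysam

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise DataError(f"VCF file not found: {vcf_path}")
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise DataError(
                    f"{vcf_path} has {len(samples)} samples; a sample name is required"
                )
            sample = samples[0]
        elif sample not in samples:
            raise DataError(f"sample {sample!r} not present in {vcf_path}")
        for rec in vf:
            if rec.contig != contig or rec.pos < start:
                continue
            if rec.pos > end:
                continue
            gt = rec.samples[sample].get("GT")
            gclass, alt_idx = _classify_genotype(gt)
            if gclass in ("hom_ref",):
                continue
            if gclass == "missing":
                alt = rec.ref  # placeholder; footprint only
                ref = rec.ref
            else:
                if rec.alts is None or alt_idx is None or alt_idx > len(rec.alts):
                    continue
                ref, alt = rec.ref, rec.alts[alt_idx - 1]
            if "<" in (alt or "") or "<" in (ref or ""):
                raise DataError(
                    f"symbolic allele at {rec.contig}:{rec.pos} in {vcf_path}"
                )
            if rec.pos + len(ref) - 1 > end:
                continue
            try:
                out.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        genotype=gclass,
                    )
                )
            except ValueError as exc:
                raise DataError(str(exc)) from exc
    out.sort(key=lambda v: v.pos)
    return out


def read_manifest(path) -> list[tuple[str, Path, Optional[str]]]:
    """Parse a strain manifest: ``strain_id<TAB>vcf_path[<TAB>sample]``.

    Relative VCF paths resolve against the manifest's directory.  Lines
    starting with '#' are comments.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"strain manifest not found: {path}")
    entries: list[tuple[str, Path, Optional[str]]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DataError(f"{path}:{lineno}: expected strain_id<TAB>vcf_path")
        strain_id, vcf = parts[0], Path(parts[1])
        if strain_id in seen:
            raise DataError(f"{path}:{lineno}: duplicate strain {strain_id!r}")
        seen.add(strain_id)
        if not vcf.is_absolute():
            vcf = path.parent / vcf
        entries.append((strain_id, vcf, parts[2] if len(parts) > 2 else None))
    if not entries:
        raise DataError(f"strain manifest {path} lists no strains")
    return entries
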