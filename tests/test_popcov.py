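"""Tests for variant application and strain-coverage prediction."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from guidepop import (
    GuideCandidate,
    PamSpec,
    VariantRecord,
    apply_variants,
    coverage_histogram,
    histogram_from_reports,
    strain_coverage,
)
from guidepop.popcov import VariantApplicationError, find_guide_sites

from conftest import random_dna


def snp(pos, ref, alt, gt="hom_alt", contig="c1"):
    return VariantRecord(contig=contig, pos=pos, ref_allele=ref, alt_allele=alt, genotype=gt)


class TestApplyVariants:
    def test_no_variants_is_identity(self):
        assert apply_variants("ACGT", 1, []).seq == "ACGT"

    def test_single_snp(self):
        ss = apply_variants("ACGT", 1, [snp(2, "C", "G")])
        assert ss.seq == "AGGT"
        assert ss.n_applied == 1

    def test_one_base_deletion(self):
        ss = apply_variants("ACGTACGT", 1, [snp(2, "CG", "C")])
        assert ss.seq == "ACTACGT"

    def test_insertion(self):
        ss = apply_variants("ACGT", 1, [snp(2, "C", "CTT")])
        assert ss.seq == "ACTTGT"

    def test_region_offset_coordinates(self):
        # region starting at reference position 100
        ss = apply_variants("ACGT", 100, [snp(101, "C", "T")])
        assert ss.seq == "ATGT"

    def test_ref_mismatch_names_site(self):
        with pytest.raises(VariantApplicationError, match="c1:2"):
            apply_variants("ACGT", 1, [snp(2, "G", "A")])

    def test_overlapping_records_error(self):
        with pytest.raises(VariantApplicationError, match="overlap"):
            apply_variants("ACGTACGT", 1, [snp(2, "CG", "C"), snp(3, "G", "A")])

    def test_variant_outside_region_error(self):
        with pytest.raises(VariantApplicationError, match="outside"):
            apply_variants("ACGT", 1, [snp(9, "A", "T")])

    def test_het_policies(self):
        region = "ACGT"
        het = [snp(2, "C", "G", gt="het")]
        assert apply_variants(region, 1, het, het_policy="alt_wins").seq == "AGGT"
        assert apply_variants(region, 1, het, het_policy="ref_wins").seq == "ACGT"
        strict = apply_variants(region, 1, het, het_policy="strict_hom")
        assert strict.seq == "ACGT"
        assert strict.ambiguous == [(1, 2)]

    def test_missing_keeps_ref_and_records_site(self):
        ss = apply_variants("ACGT", 1, [snp(2, "C", "C", gt="missing")])
        assert ss.seq == "ACGT"
        assert ss.missing == [(1, 2)]

    @given(seq=st.text(alphabet="ACGT", min_size=5, max_size=60),
           pos=st.integers(min_value=1, max_value=5))
    @settings(derandomize=True, max_examples=50)
    def test_snp_round_trip(self, seq, pos):
        """Applying a SNP then its inverse restores the reference."""
        ref = seq[pos - 1]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        once = apply_variants(seq, 1, [snp(pos, ref, alt)]).seq
        back = apply_variants(once, 1, [snp(pos, alt, ref)]).seq
        assert back == seq


def _strain(seq, sid="s", region=("c1", 1, None)):
    from guidepop import StrainSequence

    contig, start, end = region
    return StrainSequence(strain_id=sid, region=(contig, start, end or len(seq)), seq=seq)


class TestStrainCoverage:
    def test_identical_strain_covered(self, ngg):
        site = "ACGTACGTACGTACGTACGT" + "TGG"
        seq = "TTTT" + site + "TTTT"
        guide = GuideCandidate(spacer=site[:20], pam_observed="TGG",
                               contig="c1", start=5, strand="+")
        rep = strain_coverage(guide, ngg, [_strain(seq)])
        assert rep.covered == ["s"] and rep.not_covered == []

    def test_empty_strain_set_rejected(self, ngg):
        guide = GuideCandidate(spacer="A" * 20, pam_observed="AGG",
                               contig="c1", start=1, strand="+")
        with pytest.raises(ValueError):
            strain_coverage(guide, ngg, [])

    def test_pam_disrupting_variant_breaks_coverage(self, ngg):
        spacer = "ACGTACGTACGTACGTACGT"
        ok = "TT" + spacer + "TGG" + "TT"
        broken = "TT" + spacer + "TCG" + "TT"  # GG -> CG: PAM gone
        guide = GuideCandidate(spacer=spacer, pam_observed="TGG",
                               contig="c1", start=3, strand="+")
        rep = strain_coverage(guide, ngg, [_strain(ok, "a"), _strain(broken, "b")])
        assert rep.covered == ["a"] and rep.not_covered == ["b"]

    def test_planted_snp_in_four_of_ten_strains(self, ngg):
        """Ten strains, spacer-disrupting hom_alt SNP planted in four ->
        six covered."""
        rng = random.Random(5)
        spacer = random_dna(rng, 20)
        ref = random_dna(rng, 30) + spacer + "AGG" + random_dna(rng, 30)
        strains = []
        for k in range(10):
            seq = ref
            if k < 4:
                i = 30 + 10  # inside the spacer
                base = seq[i]
                seq = seq[:i] + {"A": "C", "C": "G", "G": "T", "T": "A"}[base] + seq[i + 1:]
            strains.append(_strain(seq, f"s{k}"))
        guide = GuideCandidate(spacer=spacer, pam_observed="AGG",
                               contig="c1", start=31, strand="+")
        rep = strain_coverage(guide, ngg, strains)
        assert rep.n_covered == 6
        assert set(rep.not_covered) == {"s0", "s1", "s2", "s3"}

    def test_indel_shifted_site_still_covered(self, ngg):
        """A deletion upstream of an intact site shifts but keeps coverage."""
        spacer = "ACGTACGTACGTACGTACGT"
        ref = "TTTTTTTTTT" + spacer + "AGG" + "TTTT"
        shifted = "TTTTTTT" + spacer + "AGG" + "TTTT"  # 3 bp deleted upstream
        guide = GuideCandidate(spacer=spacer, pam_observed="AGG",
                               contig="c1", start=11, strand="+")
        rep = strain_coverage(guide, ngg, [_strain(ref, "a"), _strain(shifted, "b")])
        assert rep.covered == ["a", "b"]

    def test_minus_strand_site_found(self, ngg):
        from guidepop import reverse_complement

        spacer = "ACGTTACGATCCGGATACGT"
        fwd_site = reverse_complement(spacer + "CGG")
        seq = "TTAA" + fwd_site + "GGTT"
        guide = GuideCandidate(spacer=spacer, pam_observed="CGG",
                               contig="c1", start=5, strand="-")
        rep = strain_coverage(guide, ngg, [_strain(seq)])
        assert rep.covered == ["s"]

    def test_ambiguous_window_not_covered(self, ngg):
        spacer = "ACGTACGTACGTACGTACGT"
        seq = "TT" + spacer + "AGG" + "TT"
        ss = _strain(seq)
        ss.ambiguous = [(10, 11)]  # inside spacer window
        guide = GuideCandidate(spacer=spacer, pam_observed="AGG",
                               contig="c1", start=3, strand="+")
        assert strain_coverage(guide, ngg, [ss]).not_covered == ["s"]

    def test_strict_missing_flag(self, ngg):
        spacer = "ACGTACGTACGTACGTACGT"
        seq = "TT" + spacer + "AGG" + "TT"
        ss = _strain(seq)
        ss.missing = [(5, 6)]
        guide = GuideCandidate(spacer=spacer, pam_observed="AGG",
                               contig="c1", start=3, strand="+")
        assert strain_coverage(guide, ngg, [ss]).covered == ["s"]
        assert strain_coverage(guide, ngg, [ss], strict_missing=True).not_covered == ["s"]

    def test_locality_variants_outside_window(self, ngg):
        """A strain whose variants lie outside every spacer+PAM window is
        covered by every guide."""
        rng = random.Random(9)
        ref = random_dna(rng, 200)
        from guidepop import enumerate_guides

        guides = enumerate_guides(ref, ngg, 15)
        assert guides
        # mutate the first base only if no guide window touches it
        windows = []
        for g in guides:
            lo = g.start
            hi = g.start + 15 - 1
            if g.strand == "+":
                hi += 3
            else:
                lo -= 3
            windows.append((lo, hi))
        pos = next(p for p in range(1, 201)
                   if not any(lo <= p <= hi for lo, hi in windows))
        base = ref[pos - 1]
        mutated = ref[: pos - 1] + {"A": "C", "C": "G", "G": "T", "T": "A"}[base] + ref[pos:]
        strains = [_strain(ref, "ref"), _strain(mutated, "mut")]
        for g in guides:
            assert strain_coverage(g, ngg, strains).n_covered == 2


class TestCoverageHistogram:
    def test_all_conserved_single_bin(self, ngg):
        from guidepop import enumerate_guides

        rng = random.Random(2)
        ref = random_dna(rng, 150)
        guides = enumerate_guides(ref, ngg, 15)
        assert guides
        strains = [_strain(ref, f"s{k}") for k in range(4)]
        hist = coverage_histogram(guides, ngg, strains)
        assert hist == {4: len(guides)}

    def test_counts_sum_to_guides(self, ngg):
        rng = random.Random(3)
        ref = random_dna(rng, 300)
        from guidepop import enumerate_guides

        guides = enumerate_guides(ref, ngg, 15)
        strains = []
        for k in range(6):
            seq = ref
            for _ in range(k):
                i = rng.randrange(len(seq))
                seq = seq[:i] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]] + seq[i + 1:]
            strains.append(_strain(seq, f"s{k}"))
        hist = coverage_histogram(guides, ngg, strains)
        assert sum(hist.values()) == len(guides)
        wide = coverage_histogram(guides, ngg, strains, bin_width=100)
        assert sum(wide.values()) == len(guides)
        assert set(wide) <= {0}

    def test_empty_guides_rejected(self, ngg):
        with pytest.raises(ValueError):
            coverage_histogram([], ngg, [_strain("ACGT")])

    def test_histogram_from_reports_binning(self, ngg):
        from guidepop import CoverageReport

        g = GuideCandidate(spacer="A" * 20, pam_observed="AGG",
                           contig="c1", start=1, strand="+")
        reps = [
            CoverageReport(guide=g, covered=[f"s{i}" for i in range(n)], not_covered=[])
            for n in (0, 1, 99, 100, 250)
        ]
        assert histogram_from_reports(reps) == {0: 1, 1: 1, 99: 1, 100: 1, 250: 1}
        assert histogram_from_reports(reps, bin_width=100) == {0: 3, 100: 1, 200: 1}


class TestHetPolicyEquivalence:
    def test_hom_only_population_policy_invariant(self, ngg):
        """ref_wins and alt_wins agree when every record is homozygous."""
        rng = random.Random(13)
        ref = random_dna(rng, 400)
        from guidepop import enumerate_guides

        guides = enumerate_guides(ref, ngg, 20)
        variants = []
        for _ in range(8):
            pos = rng.randint(1, 400)
            b = ref[pos - 1]
            variants.append(snp(pos, b, {"A": "C", "C": "G", "G": "T", "T": "A"}[b]))
        variants = sorted({v.pos: v for v in variants}.values(), key=lambda v: v.pos)
        alt = apply_variants(ref, 1, variants, het_policy="alt_wins", strain_id="x")
        refw = apply_variants(ref, 1, variants, het_policy="ref_wins", strain_id="x")
        for g in guides:
            a = strain_coverage(g, ngg, [alt]).n_covered
            b = strain_coverage(g, ngg, [refw]).n_covered
            assert a == b


def test_find_guide_sites_five_prime(ngg):
    pam = PamSpec("TTTV", "five_prime")
    spacer = "ACGGATCCGGAATTCCGGAT"
    seq = "CC" + "TTTA" + spacer + "CC"
    assert find_guide_sites(seq, spacer, pam) == [(2, 26)]


def test_symbolic_allele_rejected():
    with pytest.raises(ValueError):
        VariantRecord(contig="c1", pos=5, ref_allele="A", alt_allele="<DEL>")
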