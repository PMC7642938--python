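# Methods

## Guide model and enumeration

A guide candidate is a spacer of length *L* (default 20) immediately
adjacent — zero gap — to a PAM window matching an IUPAC pattern.
Orientation is part of the PAM class: `three_prime` (Cas9-style; NGG,
NNGRRT, NCC, NNAGAAW, NNNNGATT) places the PAM 3′ of the spacer on the
protospacer strand, `five_prime` (Cas12a-style; TTTV, TTTN) places it
5′. The orientation default is inferred from the pattern and can be
overridden.

Enumeration scans both strands: PAM-class positions are located with a
compiled regex over explicit `[ACGT]` character classes (overlapping
matches via lookahead), the minus strand by running the same scan on the
reverse complement and mapping coordinates back. All reported positions
are 1-based, inclusive, forward-strand (GFF3/VCF convention); a
minus-strand candidate is reported in protospacer orientation with
`start` still the forward-strand leftmost base of the spacer.
Candidates whose spacer overlaps an ambiguous reference base (N) are
silently dropped (logged at debug level); degenerate PAM codes expand
only over A/C/G/T, so N can never satisfy a PAM position either.
Output order is deterministic: ascending start, `+` before `-` at ties.

Guides whose spacer lies at a gene edge may have their PAM just outside
the gene body; the gene region is therefore extracted with a flank of
|PAM| + max_mismatch bases per side, so boundary guides are found and
their off-target context is evaluable. This is an interpretation — an
alternative would be to require the whole site inside the annotated
feature — and `position_in_gene` for such guides can fall slightly
outside [1, gene length].

## Per-strain consensus reconstruction

Each strain's sequence for the target region is rebuilt from its VCF
records: left-to-right piecewise application with cumulative offset
tracking, after validating that records are sorted, non-overlapping,
inside the region, and that every REF allele matches the reference
(mismatch is a hard error naming contig:pos — it almost always means the
VCF belongs to a different reference build). Overlapping records are an
error rather than silently resolved, because edit order would change the
result. Multi-allelic records are split at parse time and only the
called ALT applied; a call mixing two non-reference alleles (e.g. 1/2)
is treated as het on the first called ALT — a rare case the synthetic
generator never produces. Records straddling a region edge are skipped;
the flank makes this immaterial for guides.

Diploid/heterozygous handling builds a single consensus per strain,
controlled by `het_policy`:

- `alt_wins` (default) — ALT applied at het sites; matches a
  one-consensus-per-strain workflow.
- `ref_wins` — REF kept.
- `strict_hom` — REF kept and the site's footprint marked ambiguous; a
  guide whose match window overlaps an ambiguous footprint is never
  counted as covering that strain.

Missing genotypes keep REF by default; the `--strict` flag
(`strict_missing`) instead refuses to count a match whose window
overlaps a missing-genotype footprint — a conservative mode for sparse
callsets. On hom-only populations all policies coincide (property-tested).

## Strain coverage

A strain is covered by a guide iff its reconstructed region contains
the exact spacer with an adjacent PAM-class match in the correct
orientation, on either strand. Two deliberate choices:

- **PAM is required**, although coverage is colloquially a "perfect
  match to the sgRNA": a PAM-disrupting variant abolishes cutting, so it
  must break coverage.
- **The whole region is scanned** (substring search), not just the
  design coordinate: an upstream indel shifts an intact site without
  affecting cutting, so shifted-but-intact sites count.

The coverage histogram bins per-guide covered-strain counts, with
arbitrary bin widths for reporting (width 1 and width 100 are the ones
used in practice for small and large panels).

## Off-target search and biosafety screen

Off-target semantics follow PAM-gated genome scanners: the PAM window
must match its IUPAC class exactly, mismatches are counted over the
spacer only, and only budgets 0 and 1 are supported. Windows
overlapping N are excluded outright (no wildcard or mismatch credit).
The design site itself is never reported. The implementation is the
same regex-gated linear scan as enumeration; any index structure would
be acceptable provided the hit set equals the brute-force oracle, which
the test suite enforces on hundreds of random guide/genome pairs. In
gene-target mode counts are computed against the design reference
genome; `offtarget_counts_pooled` provides per-genome counts plus the
pooled maximum when multiple genomes are supplied.

The biosafety screen is exact full-length substring search of the bare
spacer on both strands of a screening genome — for a 20-mer, an
exact-match nucleotide database query reduces to exactly this — and is
reported as the literal strings `Yes`/`No`.

## Scoring and the result table

Trained activity models are out of scope by design; the scorer is a
seam. `gc_balance` = 1 − |GC fraction − 0.5| × 2 is a placeholder
(flagged as such in output metadata) that only encodes "extreme GC is
bad"; the `table` scorer injects external model scores unchanged — no
normalisation, since external score scales are model-defined. Table
assembly is a pure join keyed by guide; rows sort by descending
activity score, ties by ascending position, stable. The `mismatches`
column reports the mismatch budget used for the off-target column.
TSV output has a fixed header order; JSON adds the covered/not_covered
identity lists and a metadata block echoing every threshold and flag
for provenance. Floats are serialized with at most four decimals so
repeated runs are byte-identical.

## Synthetic populations and oracles

The generator emulates a resequenced strain panel: a uniform-random
reference (one contig), evenly spaced non-overlapping genes on
alternating strands, and per-strain variants — SNPs at `snp_rate` and
1–3 bp indels at `indel_rate` per base, independently per strain, all
homozygous — plus verbatim planted edits with recorded ground truth.
Defaults are 20 strains, 10 kb, 3 genes, `snp_rate` 0.005 (a yeast-like
per-strain divergence from the reference, where most guides survive but
a substantial minority are disrupted somewhere in the panel) and
`indel_rate` 0.0005. Everything derives from one seed; identical specs
produce byte-identical FASTA/GFF3/VCF output, and the generator's files
round-trip through the package's own readers.

What the generator does **not** emulate: shared phylogeny or linkage
between strains, realistic mutation spectra, heterozygosity, structural
variants, or repeat structure. Passing tests therefore demonstrate
correctness of the sequence logic — variant application, PAM gating,
both-strand matching, indel shifting — not calibrated performance on
real panels, where variant density is locus-dependent and VCF quality
matters.

The coverage oracle (`expected_coverage`) is deliberately a different
algorithm from the engine: it rebuilds each strain's region by applying
edits right-to-left into a character list, then enumerates every
PAM-adjacent window per position to collect the set of validly-PAMmed
spacers, and tests membership. The engine instead finds spacer
occurrences first and checks the adjacent PAM. The enumeration and
off-target oracles in the test suite are naive per-position double
loops with their own IUPAC table. Agreement is exact (100% of guides)
across seeded populations including PAM-disrupting and indel-shifted
plants.

The packaged two-allele portability locus is a synthetic ~150 bp
sequence hosting four NGG guides: two overlapping guides (offset by one
base, as in a typical redundant design) whose spacers both span a
planted G→A SNP sitting at position 27 of the 28 nt alignment window
around them, and two guides (one per strand) clear of the site. Strains
carrying the SNP homozygously are predicted uncoverable by exactly the
spanning guides and fully coverable by the others — the qualitative
signature of strain-specific guide failure that coverage prediction
exists to catch.

## Numerical and degenerate-input choices

- Coordinates 1-based inclusive everywhere user-visible.
- Sequences uppercased on load; reference characters outside A/C/G/T/N
  become N.
- A sequence too short to host spacer+PAM yields an empty candidate
  list (and, in the CLI, an empty table with a warning and exit 0) —
  not an error.
- Empty strain sets and empty genomes are errors (an empty search space
  would silently report universal failure or safety).
- No randomness exists anywhere in the design pipeline; the only seeded
  component is the synthetic generator.
- Exit codes: 0 success (including empty results), 2 usage error,
  3 data error.

## Problem sizes

The test suite and acceptance script run on desk-scale inputs chosen as
representative conditions: 100 random sequences up to 5 kb across all
seven PAM classes and spacer lengths {15, 20, 24} for enumeration; 200
random guide/2 kb-genome pairs for the off-target oracle; 20 seeded
populations of 20 strains × 10 kb for coverage recovery. Genome-scale
panels (hundreds of strains, full genomes) use the same code paths;
the linear-scan off-target search is O(genome × guides) and is the
piece to index if that ever becomes limiting.

## Known limitations

- No bulges or gapped alignment in off-target matching; budgets > 1
  are rejected.
- No phased dual-haplotype coverage: diploids are one consensus.
- Structural/symbolic variants are rejected at parse time.
- Custom-target mode computes no strain coverage (a free sequence has
  no coordinates in the strain VCFs).
- The default activity scorer is a placeholder; real designs should
  inject scores from a trained model via the table scorer.
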