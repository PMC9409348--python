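# Methods

## Study design being modelled

The pipeline analyses a balanced two-sex cohort (5 males, 5 females) of a
polyploid fish whose reads were mapped to a related species' reference and
genotyped per sample with a diploid caller. All inputs are therefore
*downstream artifacts*: variant-only single-sample VCFs (CHROM, POS, REF,
ALT, QUAL, GT), dense per-position depth tables (`samtools depth -aa`
convention: one row per reference position, zeros included), contig
lengths (FAI), gene intervals (BED, 0-based half-open) and paired
CDS/protein FASTA for the molecular-evolution stage. Read simulation,
alignment and genotype calling are out of scope.

## Genotype-pattern filters

Per-sample records are split per ALT allele, so a multi-allelic row
becomes one biallelic key per ALT with the genotype recoded against that
ALT. Merging is an in-memory re-implementation of multi-sample VCF merge
semantics on (contig, pos, ref, alt) keys: a sample without a record at a
key is *missing*; AC counts ALT alleles over called genotypes, AN = 2 ×
called samples, and AF = AC/AN is compared as an exact rational (integer
AC = AN), never by floating-point equality. Positions where samples
disagree on REF cannot share a key and are excluded with a logged count.

**Species-fixed sites** require genotype 1/1 in every one of the n = 10
samples (AN = 2n, AF = 1); a missing genotype disqualifies.

**Sex-associated sites** implement an asymmetric design: male calls are
quality-filtered (QUAL strictly > 30; a record at exactly 30 is removed),
female calls are deliberately *not* filtered, so that any female ALT
evidence — however weak — can veto a candidate. A site qualifies when

* all five males are 1/1 at the key,
* no female is 1/1 at the position (at any ALT allele; conservative
  handling of multi-allelic positions),
* every female is 0/1, 0/0 or recordless, and
* read depth is strictly greater than 2 (i.e. ≥ 3) in all ten samples at
  the position, so that a recordless female reflects reference homozygosity
  rather than absent coverage. Variant-only callers emit no record at
  reference-homozygous positions, so "no variant (0/0)" includes absence
  of a record under a passing depth gate.

A site absent from the depth matrix is a hard error: the gate cannot be
evaluated, and silently passing it would re-introduce exactly the false
positives the gate exists to remove.

## Site-list statistics

Variant classes follow VCF left-anchoring: SNP (both alleles length 1),
insertion/deletion (length change with shared first base), and MNP-other
for everything else (excluded from SNP/indel pies, which is why class
percentages are reported over all four classes and sum to 100). Spacing
statistics use consecutive within-contig distances only — cross-contig
distances are meaningless on an unordered assembly — and the mean is
reported as absent when no contig has two variants. Segment counts use
consecutive, non-overlapping 10 kb windows anchored at position 1 of every
contig, the last partial window retained; the mean per segment is reported
both including and excluding empty windows.

## Cluster peaks and nearest genes

A peak is a window whose count reaches the threshold (default 30,
comparator ≥; a strict > comparator is exposed because one published
tally uses "more than 25"). The peak table reports the first and last
variant position inside each window. Nearest-gene assignment emulates
`bedtools closest -d -k 1 -t first`: for a 1-based query position p and a
BED gene [s, e), distance is 0 when s < p ≤ e, otherwise the gap to the
nearer boundary, min(|p − s|, |p − e|), with a bookended gene given
distance 1 so that distance 0 holds exactly when the query is inside the
gene; ties go to the coordinate-first gene; queries on contigs without
genes get an explicit no-gene assignment. Strand is ignored. The search
is bisect-based with a prefix-maximum of interval ends so nested intervals
cannot be missed; tests pin it against an all-pairs oracle.

## NG86 dN/dS

The counting method of Nei & Gojobori (1986) replaces maximum-likelihood
codon models here: the scientific use of the ratio in this pipeline —
classification against ω = 1 and a dS plausibility range — does not need
ML machinery, and counting is desk-verifiable per codon. Protein-guided
codon alignments drop every column in which either protein has a gap
(`pal2nal -nogap` semantics); terminal stop codons are stripped before
alignment and internal stops are hard errors, as are ambiguity codes
(pathway counting is undefined for ambiguous codons).

Per codon, the synonymous site count at each position is the fraction of
the three possible single-nucleotide changes that preserve the amino acid;
changes *to* stop codons count as nonsynonymous, which keeps
S + N = 3 × (codon count) exact. Differences in multi-difference codons
are averaged over all minimal substitution pathways with equal weights;
steps through stop codons count as nonsynonymous and no pathway is
discarded. Sites are averaged over both sequences; pS = Sd/S and pN = Nd/N
are corrected with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined
("saturated") at p ≥ 3/4, in which case the raw proportions are retained.
ω = dN/dS is reported only when dS > 0; an undefined ω is classified
"undefined", never silently purifying. The dS filter keeps
0.01 ≤ dS ≤ 2 inclusive (the published rule drops dS < 0.01 or > 2).
This implementation agrees with Biopython's independent NG86 routine to
≈ 1e-16 on random pairs, which the test suite uses as an external
cross-check alongside a brute-force per-codon enumeration.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults define the standard test cohort: 2 contigs ×
100 kb, 5 males / 5 females, Poisson read depth with mean 20 per sample
(the real cohort's per-sample depth was ~17–23×), three planted 10 kb
clusters of 40 sex-associated variants, background heterozygous noise at
10⁻⁴ per bp per sample (~200 records), ~0.05 % species-fixed divergence
(~100 sites, 10 % of them 1 bp indels), 50 low-QUAL decoys, and one 1 kb
sex-exclusive coverage block per sex. QUAL values for passing records are
drawn uniformly in [31, 100) and rounded to the VCF's two printed
decimals — rounding may never move a passing record onto the 30.00
boundary — while decoys are drawn in [0, 30] with one record at exactly
30 to pin the strict inequality. At planted variant sites depth is clamped
to ≥ 3 in all samples so the > 2 gate never erases planted truth; female
genotypes at sex sites split 50/50 between an explicit 0/1 record and no
record, the two non-association encodings the filters must both accept.
Truth categories are placed on pairwise disjoint positions (clusters and
exclusive blocks are reserved regions) so that recovery tests have exact
expected answers.

What the generator does **not** model: real linkage structure, mutation
spectra, mapping artefacts, octoploid dosage (genotypes are diploid-coded,
as the consumed caller output is), or depth over-dispersion. Passing the
recovery tests therefore demonstrates the *correctness of the filters and
scans*, not the field performance of the thresholds on real octoploid
data; the real-cohort headline counts (millions of inter-species variants,
thousands of sex-associated positions) require the original multi-Gb
references and ~165× aggregate coverage and are not reproduced here.

Ortholog pairs are random stop-free codon sequences (default 8 pairs of
2 001 bp) with a recorded number of synonymous-only and nonsynonymous-only
single-nucleotide codon mutations applied to distinct codons; codons with
no change of the requested class (ATG, TGG for synonymous) are skipped and
redrawn.

## Numerical and design choices

* "Depth of 10" for sex-exclusive coverage is read as ≥ 10; a strict
  equality reading would be biologically meaningless. "Coverage > 2" is
  read strictly (≥ 3); both boundaries are pinned by tests.
* "Genome coverage" is the fraction of positions with depth ≥ 1 (the
  floor is a parameter); pooled group depth is the arithmetic sum over
  member samples, consistent with pooling alignments.
* All thresholds (QUAL 30, depth gate 2, exclusive 10/3, window 10 000,
  cluster threshold 30, dS 0.01–2) live in one `RunConfig`; stage
  functions receive them explicitly, so no constant is hidden.
* Determinism: every random draw flows from `numpy.random.default_rng`
  seeded from the config seed (with a fixed stream index per generator
  stage), and all writers emit sorted rows with fixed formatting, so a
  fixed config reproduces byte-identical FASTA/BED/VCF/TSV outputs and an
  identical report hash. The report hash excludes output paths.
* Problem sizes in tests and the acceptance script (2 × 100 kb cohort,
  ≤ 40 kb oracle cohorts, 8–100 ortholog pairs of 60–2 001 bp) were chosen
  so that brute-force oracles remain feasible and exact while exercising
  every rule; the whole suite runs in well under a minute.

## Known limitations

* The merge step holds all sites in memory; at desk scale this is
  irrelevant, but multi-Gb cohorts would need an external-sort merge.
* Heterozygous genotype classes conflate many true dosages in an
  octoploid; this is a property of the consumed diploid calls and cannot
  be resolved downstream.
* NG86 with equal pathway weights and JC correction ignores
  transition/transversion bias and codon frequencies; per-gene parity with
  ML estimators on real data is not a goal.
* The published coverage percentages' depth floor is not stated by the
  source analyses; the ≥ 1 convention here is explicit and configurable.
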