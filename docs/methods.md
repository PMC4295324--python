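# Methods

## Scope and data model

The package analyses per-CpG methylation call tables: one row per cytosine
with methylated and total read counts, as produced by RRBS pipelines.
Internally all coordinates are 0-based half-open; the Bismark coverage
dialect (1-based inclusive) and the bedGraph count dialect (0-based
half-open) are converted only at the file boundary. After strand
combining, a CpG is represented by the position of its plus-strand C and
the pooled counts of both strands; combining conserves total counts over
valid CpG sites, and calls whose genomic context is not CpG (SNPs,
sequencing errors, non-CpG cytosines) are dropped with a logged count
rather than failing the run, since real data always contains them.

The depth filter keeps sites sequenced at least 8 times; the bound is
inclusive (a "minimum depth of 8×" is read as ≥ 8). The filter is applied
*after* strand combining, so a CpG covered 5×/4× on the two strands
passes. This ordering is an assumption — the alternative (filtering each
strand first) discards more data and makes the combining step order
dependent.

## CpG-island calling

Islands are detected compositionally: fixed 150 bp windows on a 25 bp
grid anchored at coordinate 0 of each chromosome, a window passing when
GC fraction > 0.55 and CpG observed/expected ratio > 0.65. The ratio uses
the Gardiner–Garden form (#CpG × L)/(#C × #G). Passing windows are
unioned (overlapping or touching windows become one block), blocks closer
than 50 bp are joined, and merged intervals longer than 250 bp (strictly)
are reported. The two-phase reading of "merge" (union, then gap-join)
reproduces maximal islands; trailing partial windows are skipped, and any
window containing an N fails. N bases are likewise excluded from
composition counts and from the effective length.

The caller is verified against a brute-force oracle that enumerates every
window with plain string counting and merges by explicit position sets;
the test suite requires exact interval-set equality on planted and on
GC-borderline random genomes.

Island categories follow a strict priority: TSS when the island midpoint
is within 1 kb of the nearest TSS; otherwise exon on ≥ 1 bp exon overlap;
otherwise intron when fully contained in an intron; otherwise intergenic.
The promoter-focused variant lowers the size cutoff to 225 bp and keeps
islands with midpoint-to-TSS distance strictly below 800 bp. Promoter
CpG-content classes use the common convention (HCP: ratio > 0.75 and
GC > 0.55; LCP: ratio < 0.48; else ICP).

## Tiles and kinetics

The unit of genome-wide comparison is a 400 bp tile on a fixed grid
anchored at 0. Grid anchoring is a determinism choice: it makes tile
identities comparable across samples without an alignment step. A tile's
methylation in a sample is the coverage-weighted (pooled-count) mean over
its covered CpGs and is defined only when ≥ 3 distinct CpGs are covered;
the same pooled rule with the same 3-CpG minimum is used for island- and
DMR-level methylation. Pooled counts rather than mean-of-ratios were
chosen because they are invariant to how counts are split across records
and give deeper CpGs their statistically appropriate weight; the test
oracles use the same rule.

Transition changes, the de novo set, slow/fast classes, the u/pm/m bands,
knockout deltas and DNMT3B targets all use strict inequalities at their
thresholds (0.20, 0.20/0.50, 0.20/0.50 at E3.5/E5.5/E8.5, 0.10/0.15/0.60,
0.10, 0.60): a value exactly at a cutoff never qualifies, and levels in
the definitional gaps (e.g. 10–15 %) are reported as unassigned rather
than guessed. Transition counts are computed over tiles present in both
samples of the pair (pairwise-present, not present-in-all-samples).

Gene metaprofiles use 10 fixed 1-kb bins per flank and 20 equal-width
bins within the gene body, oriented 5'→3' (minus-strand genes flipped),
excluding sex chromosomes; the aggregate is the unweighted mean over
genes of per-gene pooled-count bin methylation.

## Allele-level analysis

Each sequenced molecule covering ≥ 3 CpGs of an island yields a read
score (fraction of its CpGs methylated). Imprinted regions produce
bimodal score distributions (one methylated and one unmethylated allele);
partially methylated islands produce unimodal sparse distributions. The
operational decision rule — allele-specific when the mass at the score
extremes (≤ 0.2 and ≥ 0.8) exceeds 0.8 with ≥ 0.2 in each extreme;
sparse-uniform when the ≥ 0.8 mass is below 0.1 and the mean score lies
in (0.1, 0.6); indeterminate otherwise or below 10 reads — is this
package's own formalization of a contrast usually judged visually. All of
its constants are configurable arguments.

## Imprinted DMR classification

A DMR is called germline when its WT aggregate methylation stays within
the one-allele stability band (0.40–0.50 widened by a ±0.15 tolerance) at
every profiled stage *and* its final-stage level is within 0.15 of WT in
both single knockouts; somatic when it starts below 0.25 at E3.5, gains
more than 0.20 by E8.5 in WT, and sits more than 0.30 below WT in the
Dnmt3b knockout at E8.5. The qualitative criteria (stability and
knockout-insensitivity versus DNMT3B-dependent post-implantation gain)
are the science; the numeric tolerances are this package's defaults,
calibrated on the simulator, and every one is a named parameter of
`DMRClassParams`. The two templates are mutually exclusive by
construction (the E3.5 bounds cannot both hold).

Aggregate counts cannot distinguish a somatic DMR from a pmCGI — both sit
at intermediate methylation with a DNMT3B-dependent gain — so the
composite classifier (`assign_cgi_class`) consults the single-molecule
score distribution in that ambiguous zone.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
mouse sequence. Chromosomes are i.i.d. ~40 % GC background with 80 % of
CpG dinucleotides broken (CpG O/E ≈ 0.2, comfortably below any island
threshold), into which genes (6 kb, 3 exons), transposon intervals and
CpG islands are planted with 2.5–3.5 kb spacing. Planted islands
(320–650 bp) are generated by a CpG-emitting process and rejected unless
every internal 150 bp window clears the caller thresholds with margin
(GC > 0.57, O/E > 0.72), so island recovery is a property of the caller,
not of lucky placement. One chromosome can be flagged as an X surrogate.

Truth methylation probabilities per class, stage, genotype and allele are
generative stand-ins shaped to the qualitative empirical picture and
anchored at two printed figures — bulk de novo tiles at 12 % (E4.5) and
62 % (E5.5):

| class | trajectory (E3.5 → E8.5, WT) | Dnmt3bKO | Dnmt3aKO |
|---|---|---|---|
| background | 0.08, 0.12, 0.62, 0.75, 0.80, 0.82 | −0.10 | −0.10 |
| protected | 0.03 flat | — | — |
| fast | 0.05 → 0.78 (0.60 at E5.5) | −0.10 | −0.05 |
| slow | 0.05 → 0.70 (0.20 at E5.5) | held at E3.5 | — |
| pm | rising to pm_level = 0.35, both alleles | held at E3.5 | — |
| gdmr | maternal 0.95 / paternal 0.02, all stages | unchanged | unchanged |
| sdmr | maternal 0.15 → 0.90, paternal 0.05 | maternal held | — |
| xlinked | pm-like in females | held at E3.5 | — |

Counts are drawn per haplotype as Binomial(Poisson(depth/2), p) and
collapsed, so allele labels never appear in the emitted data; counts are
then split binomially over the two strands to exercise strand combining.
A symmetric read-level conversion error (default 0.4 %) perturbs every
probability as p(1−e) + (1−p)e and drives a planted panel of non-CpG
cytosine calls used for conversion QC (these are also mixed into the call
files so the context filter is exercised). Single-molecule read patterns
cover runs of 3–6 consecutive CpGs with i.i.d. per-CpG states at the
allele's probability. Sites with zero sampled depth are omitted; sites
below the 8× filter are emitted so the filter has something to do.

The sdmr maternal endpoint of 0.90 (not 1.0) keeps read-score bimodality
a property of the generative model at realistic read lengths while
leaving the aggregate (~0.475) inside the observed DMR band.

What the generator does **not** model: nucleotide-level reads and
alignment artifacts, MspI fragment representation bias (depth is per-CpG),
linkage between neighbouring CpGs beyond the read level, cell-to-cell
heterogeneity, and genuine biological variance between replicates.
Passing recovery tests therefore demonstrates correctness of the
estimators and decision rules under binomial sampling noise — not
robustness to the full error structure of real RRBS libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at desk scale
chosen once for the package: a 3 × 670 kb genome at 50× mean depth for
parameter-recovery measurements (≈ 36 planted islands, ≈ 50k CpGs per
sample), a 3 × 150 kb genome at 30× for unit-level fixtures, and a
2 × 400 kb background-only genome at 12× for the null-calibration check,
where low depth makes the binomial false-positive rate of the 20 %
transition threshold non-trivial; the observed changed-tile count is
compared against the exact per-tile binomial expectation within three
standard deviations. Recovery bounds use three binomial standard
deviations at the feature's pooled coverage.

All randomness flows from one integer seed through
`numpy.random.default_rng` with fixed per-sample stream keys, so a
sample's data is independent of which other samples are simulated, and
two runs with the same seed are byte-identical (output TSVs carry a hash
of the scientific configuration; the output directory is excluded from
the hash so the same analysis hashes identically anywhere).

## Known limitations

* Real-data mode expects pre-merged or strand-resolved per-CpG calls plus
  a genome FASTA; alignment-level artefacts (M-bias, SNP masking) are out
  of scope.
* `feature_methylation` assumes non-overlapping feature intervals (true
  for called islands and the planted annotations).
* The gDMR/sDMR tolerances are simulator-calibrated defaults; on real
  data they should be revisited against known imprints.
* The allele-mode rule needs ≥ 10 scored reads and ≥ 3 CpGs per read;
  islands with lower RRBS coverage are reported indeterminate.
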