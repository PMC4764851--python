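# Methods

This note documents the statistical models behind each component, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical/design choices made where the design was
genuinely open.

## Orthology and assembly integrity

Reciprocal best hits are computed per query as the hit with minimal e-value,
ties broken by maximal bitscore, then lexicographically smallest subject id,
so the result is deterministic and symmetric under swapping the two hit
tables. The ortholog hit ratio uses the **single best hit** of a query
against its ortholog, not merged intervals; a merged-interval variant
(`merged_hit_ratio`) is available but off by default, since merging can
reward chimeric assemblies. Subject coordinates are 1-based inclusive; the
ratio is capped at 1 so overhanging alignments cannot exceed full length.

The integrity summary admits only pairs with percent identity **strictly
above** 90 — the coverage of a diverged ortholog underestimates transcript
completeness, so only near-identical pairs are informative. The full-length
cutoff OHR ≥ 0.8 is a convention of the OHR literature, not a derived
quantity; it is a parameter (`full_length_min`) and the summary also returns
the full OHR histogram so other cutoffs can be read off.

## Expression

TPM divides each transcript's count by its effective length (nt) and
rescales each sample to 10⁶; columns therefore sum to 10⁶ exactly up to
floating error, and the measure is invariant to uniform count scaling.

### Beta-binomial proportions test

For a transcript with counts `y_i` in libraries of size `n_i`, the model is
`Var(p_i) = p(1−p)(1/n_i + θ)`: binomial sampling plus between-library
overdispersion θ (the beta-binomial variance with intraclass correlation
absorbed into θ). Per group, the weighted proportion is `p̂ = Σy_i/Σn_i` and
θ is estimated by the method of moments from the library-size-weighted
residual sum of squares, truncated at zero. The binomial component uses the
proportion pooled across both groups, so with one library per group the
statistic reduces *exactly* to the pooled two-proportion z test — the
regime of single-library contrasts (e.g. one male vs one female liver),
where the between-library term cannot be estimated at all.

With replicates the statistic is referred to Student's t with `k₁+k₂−2`
degrees of freedom, the reference distribution of the classic weighted
t-type statistic for between-library count comparisons. A
Satterthwaite-style estimated df was considered and rejected: with three
libraries per group the plug-in df makes the test measurably conservative
(empirical size ≈ 0.031–0.036 at nominal 0.05 under the beta-binomial null),
while the fixed-df form holds its size (≈ 0.042–0.053 across seeds).
Transcripts absent from every library get p = 1 by convention.

### Differential expression screen

Fold change is the signed ratio of the two weighted proportions with a
pseudo-proportion floor of `1/(total library size)`, so transcripts absent
from one group get a finite, library-size-dependent fold change (this is a
stated choice; the floor value is visible in the output). The Bonferroni
family is the set of transcripts passing a total-count reliability filter
(default ≥ 10 across samples) — low-coverage transcripts are unreliable and
are reported but not tested. Significance requires both |fold| ≥ 2 and
corrected p < 0.01.

### Enrichment and clustering

Term over-representation is the upper-tail hypergeometric probability of
drawing at least the observed number of term-annotated items; a term must
satisfy p < 10⁻⁵ and observed > 5 (both strict). Sample clustering uses
average linkage on `1 − Pearson(√TPM)`; node support is the ordinary
bootstrap probability (percentage of gene-resampled trees containing the
node's sample bipartition). The multiscale AU correction was deliberately
not implemented: at the sample counts involved (a handful of tissues) plain
bootstrap probabilities answer the same question and are simpler to
interpret; `n_boot` (default 1000) and the seed are parameters. Degenerate
bootstrap resamples with a constant sample vector are counted as supporting
no bipartition.

## Mobilome

Repeat-library filtering retains a candidate iff it is longer than 100 nt
(strict — shorter repeats cannot recruit reads reliably) and either carries
no evidence of being a real gene (no proteome hit, no domain) or carries a
whitelisted TE-diagnostic domain (reverse transcriptase, integrase,
transposase, TE endonucleases...), the re-inclusion overriding both removal
rules. The whitelist ships as an editable configuration list.

Summary tables follow RepeatMasker conventions: element counts are raw hit
counts; base-pair totals merge overlapping same-class intervals per
transcript (subfamily rows merge within the subfamily, so listed subfamilies
sum to at most their class row, with an implicit remainder); the overall
masked total counts each base once across classes, so per-class totals may
double-count rare cross-class overlaps exactly as RepeatMasker tables do.
Percentages are computed against total scanned bp and rounded half-up to
two decimals, matching the printed-table convention.

Calibrated TE activity computes, per sample, the per-million scaling factor
`S = Σ_cal count/length` over the **calibration genes only** (the "reduced
transcriptome" of unequivocal cross-species orthologs), then scales each TE
element's rate by `10⁶/S` and sums per class. This makes the statistic
invariant to library depth and to transcriptome content outside the
calibration set — the property that makes cross-species comparison
meaningful. A sample in which all calibration genes are silent is an error,
not a zero.

## Expansion scan

Redundancy reduction is greedy longest-first clustering: identity is
computed from a Needleman–Wunsch global alignment as matched columns over
all alignment columns (gap columns included, edit-distance-optimal path);
the 75% default is deliberately stringent so splice forms and alleles
collapse while paralogs survive. Alignment-column identity was chosen over
shorter-sequence-denominator identity because it penalizes length
mismatches, which is the conservative direction for redundancy removal.

The Grubbs test includes the focal value in the pooled mean and standard
deviation (classic pooling). The focal species is **designated in
advance**, so the p-value uses the exact designated-observation t transform
without the ×N Bonferroni factor of the max-outlier form; the per-domain
false-positive rate under the null is therefore α (verified by Monte
Carlo), and `expanded` additionally requires the focal value to be the
sample maximum. Domains with zero pooled variance are flagged untestable.
No correction is applied across domains; the output carries the number of
domains tested as an explicit caveat column. Counts enter the test as-is
even though they are discrete and mildly right-skewed under the
negative-binomial generator; the measured null false-positive rate (~0.06
at α = 0.05) reflects that skew.

## Molecular evolution

1:1 ortholog selection works through an anchor species: a gene is kept iff
in every species it has an unambiguous reciprocal best hit at e ≤ 10⁻⁵⁰;
two co-orthologs tied on (e-value, bitscore) disqualify the gene (not 1:1).
Column filtering removes columns whose gap/ambiguity fraction exceeds the
threshold (default 0: any missing position removes the column) — an
emulation of missing-position removal only, not of block/flank heuristics
of alignment-trimming tools. Concatenation joins rows by taxon name and
records each gene's column interval in the partition map.

Tajima's relative rate test uses amino-acid states; any site with a gap or
ambiguity (X, B, Z, ...) in any of the three rows is excluded entirely.
`m1` counts sites where ingroup 1 is unique (ingroup 2 = outgroup), `m2`
symmetrically; `χ² = (m1−m2)²/(m1+m2)` with 1 df, and `m1+m2 = 0` yields
χ² = 0, p = 1. Multi-taxon ingroups are not supported; batteries of tests
run per (focal, other, outgroup) triple.

Ka/Ks is the Nei–Gojobori counting estimator: synonymous site counts per
codon (changes to stop codons count as non-synonymous), differences averaged
over all shortest substitution paths (paths through stops excluded; if every
path is blocked all changes count as non-synonymous), Jukes–Cantor
correction `d = −¾ ln(1 − 4p/3)` on both proportions, ω = Ka/Ks undefined at
Ks = 0. This is a counting estimator, labelled as such in the output; it
supports ω < 1 vs ω > 1 classification at desk scale but is not a
maximum-likelihood estimate. Codons containing gaps or ambiguities are
skipped; an internal stop raises with its codon index; the correction
saturates (raises) at p ≥ 0.75.

The motif scanner compiles the residue pattern (x = any residue) into an
overlapping-window regular expression; the actinodin repeat C(N/D)PXXDPXC is
the default.

## Synthetic data

All generators are pure functions of (config, seed) with numpy's PCG64.

- **Transcripts**: log-normal lengths (meanlog 7.1, sdlog 0.7; ~1.6 kb mean,
  matching deep short-read assemblies) floored at 250 nt, the assembler's
  minimum contig length. TE segments (150–600 nt) are copied from a packaged
  deterministic library of synthetic consensus sequences (three per class),
  mutated at a per-segment divergence drawn from 2–25%, and recorded as
  repeat hits — so repeat-hit truth is exact by construction. Default
  per-class insertion fractions total ~6% of transcripts, the order of
  magnitude seen in transcriptome-wide repeat scans.
- **Counts**: true per-group read proportions come from log-normal base
  expression; TE transcripts are additionally scaled by per-class activity
  multipliers (LTR 4×, LINE 2×, DNA 1×, SINE 0.5×, unresolved retroelements
  0.25×, mirroring the observed activity ordering). Per sample, proportions
  are perturbed by beta draws with a constant between-library coefficient
  of variation (default 0.3, a typical biological CV between replicate
  libraries), renormalized, and counts drawn multinomially — so column sums
  equal the library size exactly. A constant-CV parameterization is used
  instead of a single shared beta-binomial ρ because a shared ρ gives CV =
  √(ρ/p), i.e. absurd noise for rare transcripts and near-determinism for
  abundant ones. The classic single-ρ beta-binomial is available separately
  (`simulate_betabinomial_counts`) for test-calibration studies.
- **DE power conditions**: planted fold changes are ±8 on 50 transcripts.
  Power is assessed at one library per group — the design of the real
  sex-contrast comparisons — where measured power is ~0.96–1.00; with
  biological CV 0.3 and three replicates per group no 8-fold change can
  clear a Bonferroni threshold under a t with 4 df, which is a property of
  the design, not a defect of the test.
- **Alignments**: a rooted tree with branch lengths in expected
  substitutions/site; per-branch substitution events are Poisson with rate
  length × lineage multiplier and each event jumps to a uniformly chosen
  different residue (20-state equal-exchangeability process). The k-event
  transition probability is applied in closed form per site. Rate-matrix
  realism is irrelevant here because the relative rate test only counts
  lineage-unique differences.
- **Domain tables**: per-domain means are log-normal around 80; reference
  counts are negative binomial with size 50 (tight dispersion); planted
  expansions inflate the focal mean 10×.
- **Ortholog pairs**: full-length pairs cover their ortholog end-to-end;
  truncated pairs (planted fraction) cover 20–75%, below the 0.8 cutoff by
  construction; identities are N(96, 2) so a ~0.1% tail falls below the >90
  identity filter.

What the generators do **not** emulate: read-level sequencing (no FASTQ, no
error model), positional coverage bias, paralogy and chimerism in ortholog
tables, correlated domain counts across species (phylogenetic signal), and
among-site rate variation. Passing tests therefore demonstrate the
correctness and calibration of the statistics under their stated models,
not robustness to assembly artifacts or model misspecification in real
data.

## Problem sizes

The test suite and the reproduction script use: 20,000-site alignments ×
100 replicates for relative-rate power/size; 2,000 replicates for the
proportions-test null; 1,000 ortholog pairs for truncation recovery; 20
replicates for activity rank recovery and expansion power; 200 tables for
the expansion null; exhaustive enumeration up to universe 12 for the
hypergeometric check; N ∈ [4, 30] for the Grubbs closed form. These sizes
give binomial standard errors small enough to make the calibration
assertions meaningful while keeping the whole suite fast.
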