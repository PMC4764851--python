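# transevol

A comparative transcriptome-evolution toolkit for non-model species whose
genome cannot (yet) be sequenced, and where a deeply sequenced reference
transcriptome has to stand in for it. The package implements, as tested
reusable components, the analyses such a transcriptome supports:

- **Assembly integrity** by reciprocal best hits (RBH) against an annotated
  reference gene set and the **Ortholog Hit Ratio** (OHR): for a transcript
  whose best hit covers residues *s*..*e* of an ortholog of length *L*,
  `OHR = (e − s + 1) / L`, capped at 1. The share of high-identity ortholog
  pairs with OHR ≥ 0.8 estimates the full-length fraction of the assembly.
- **Expression quantification and differential expression.** TPM
  normalization (`TPM_g = 10⁶ · (c_g/ℓ_g) / Σ_j (c_j/ℓ_j)`), and a
  beta-binomial weighted proportions test for two groups of libraries: the
  per-library proportion `p_i = y_i/n_i` is modelled with variance
  `p(1−p)(1/n_i + θ)`, the between-library overdispersion θ estimated by the
  method of moments; the statistic `(p̂₁ − p̂₂)/SE` is referred to t with
  `k₁+k₂−2` df (pooled two-proportion z at one library per group). A
  transcript is differentially expressed iff |weighted-proportion fold
  change| ≥ 2 and Bonferroni-corrected p < 0.01. Enrichment of annotation
  terms among flagged transcripts uses the upper-tail hypergeometric test;
  samples are clustered by average linkage on `1 − r(√TPM)` with
  gene-resampling bootstrap support.
- **Mobilome summaries.** Parsing of RepeatMasker `.out` files, repeat-library
  false-positive filtering (drop candidates with host-proteome matches or
  non-TE protein domains, re-include those with TE-diagnostic domains such as
  reverse transcriptase or integrase, keep only candidates > 100 nt), repeat
  summary tables with merged-interval base-pair accounting, and a
  cross-species **calibrated TE activity**: the per-million scaling factor is
  computed on a set of unequivocally orthologous calibration genes so that
  cumulative per-class TPMs are comparable between species.
- **Gene-family expansion.** Redundancy reduction of focal-species proteins by
  greedy clustering at 75% global amino-acid identity, then a one-sided
  Grubbs outlier test of the focal species' domain count against reference
  species: `G = (x_focal − x̄)/s`, with the exact t transform
  `t = G·√((N−2)/((N−1)²/N − G²))` giving the one-sided p-value.
- **Molecular evolution.** Selection of 1:1 orthologs across species by
  anchored reciprocal best hits (e ≤ 10⁻⁵⁰), gap-column filtering,
  concatenation into a partitioned supermatrix, **Tajima's relative rate
  test** (`χ² = (m₁−m₂)²/(m₁+m₂)` on lineage-unique substitution counts, 1
  df), Nei–Gojobori counting Ka/Ks with Jukes–Cantor correction, and a
  scanner for the 9-residue actinodin repeat motif `C(N/D)PXXDPXC`.

A `simulate` module generates every input with known ground truth —
transcripts with planted TE segments, overdispersed count matrices with
planted fold changes, ortholog hit tables with planted truncation,
domain-count tables with planted expansions, and tree-evolved protein
alignments with per-lineage rate multipliers — so every stage can be scored
against what was planted.

## Worked example

Plant a 3× rate acceleration on one lineage, evolve 20,000 amino-acid sites
on a four-branch tree, and test it:

```python
from transevol.simulate import evolve_alignment
from transevol.evolution import tajima_rrt

edges = [("root", "outgroup", 0.4), ("root", "anc", 0.05),
         ("anc", "lungfish", 0.15), ("anc", "mouse", 0.15)]
aln = evolve_alignment(edges, 20_000, seed=1, multipliers={"mouse": 3.0})
r = tajima_rrt(aln, "lungfish", "mouse", "outgroup")
print(f"m1={r.m1} m2={r.m2} n_used={r.n_used} chi2={r.chi2:.1f} p={r.p:.3g}")
```

```
m1=1303 m2=4021 n_used=20000 chi2=1387.6 p=1.05e-303
```

`m1` and `m2` count sites where only the first (resp. second) ingroup
carries a unique residue; the slowly evolving lineage accumulates ~3× fewer
unique substitutions and the rate difference is overwhelmingly significant.

Scanning a simulated domain-count table with two planted 10× expansions:

```python
from transevol.simulate import SimConfig, simulate_domain_tables
from transevol.expansion import scan_expansions

cfg = SimConfig(seed=1, n_planted_expansions=2, expansion_factor=10.0)
table, truth = simulate_domain_tables(cfg)
out = scan_expansions(table, "focal", truth.species_groups)
print(sorted(truth.expanded_domains), "->",
      sorted(out.index[out.expanded_in_all]))
```

```
['DOM0063', 'DOM0144'] -> ['DOM0015', 'DOM0018', 'DOM0043', 'DOM0057',
 'DOM0063', 'DOM0075', 'DOM0078', 'DOM0090', 'DOM0125', 'DOM0144']
```

Both planted domains are recovered; the extra calls are the expected price
of testing ~150 domains at α = 0.05 with no multiple-testing correction
(the scan reports the number of domains tested for exactly this reason).

A command-line interface mirrors the library:
`transevol simulate | integrity | expression | mobilome | expansion | rrt |
motif` (see `transevol --help`).

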