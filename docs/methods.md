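# Methods

## Model and procedure

The null hypothesis for each miRNA family is that the input gene set is,
with respect to that family's predicted targets, indistinguishable from a
uniformly drawn set of the same size *N* from the background universe (all
genes carrying at least one conserved predicted site). The test statistic
is the observed target count *m<sub>A</sub>*; its null distribution is
simulated, not derived, because the per-repetition scaling correction
couples all families through the random set's total target count.

One random set per repetition serves all families simultaneously. For a
repetition with per-family counts *z<sub>A</sub>* and total
*T<sub>rand</sub>* = Σ *z<sub>A</sub>*, family *A* scores a success when

    z_A * (T_set / T_rand) >= m_A,        T_set = sum_A m_A.

Equality counts toward the null (conservative). Internally the comparison
is evaluated as `z_A * T_set >= m_A * T_rand` in integer arithmetic, which
is exactly the same predicate without floating-point rounding; the scaled
count is never rounded to an integer, which would quantize small
backgrounds. A repetition with *T<sub>rand</sub>* = 0 defines the ratio as
0, so it counts as a success only for families with *m<sub>A</sub>* = 0.

The raw p-value is the add-one (Davison–Hinkley) estimator
(1 + successes)/(R + 1), which is never 0 and has bias O(1/R), negligible
against its Monte-Carlo standard error at the supported repetition counts.
Benjamini–Hochberg is applied across exactly the families present in the
background (the statsmodels step-up implementation with monotonicity
enforcement; an independent closed-form oracle backs it in the tests).

### Why the scaling correction

Set-level covariates — longer average 3'UTRs being the canonical one —
inflate *every* family's count in the observed set relative to random
sets. The ratio *T<sub>set</sub>*/*T<sub>rand</sub>* rescales each
repetition to the observed total, so only *relative* excess of one family
over the others registers as a success deficit. The acceptance checks
quantify this on a background where half the genes carry double target
density: null sets drawn only from the dense half produce ~70–78% of
families at FDR < 0.2 without the correction and ≲ 0.5% with it, while
unconfounded null sets keep the raw p < 0.05 rate at the nominal 5%.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_reps` | 10,000 | Monte-Carlo repetitions; CLI menu {1,000, 10,000, 100,000}. SE of p near 0.05 at 10,000 reps ≈ 0.002 |
| `fdr_cutoff` | 0.05 | BH threshold for the over-representation call; CLI range [0.005, 0.2], inclusive |
| `min_target_pct` | 0 | optional second cutoff: a family needs `ceil(pct/100 * N)` targets |
| `min_n` / `max_n` | 20 / 4000 | run bounds on *N*, both inclusive; overridable at library level so tiny test universes work |
| `window_kb` | 10 | nearest-TSS association window; CLI menu {5, 10, 20} kb |
| `promoter_upstream/downstream` | 1000 / 500 bp | core-promoter window of the ranked method, strand-aware |
| `seed` | 0 | single global seed; every random draw derives from it |

The ranked peak-gene association ranks core-promoter membership above
first-intron membership; within a rank the nearest TSS wins, and remaining
ties break to the smaller gene id. The promoter window defaults and the
promoter-over-intron priority are this package's explicit reconstruction
of the idea that functional transcription-factor binding concentrates in
the core promoter or first intron; both are configurable. A peak's
reference point is its interval midpoint (BED3-compatible; no summit
column required), and nearest-TSS distance is unsigned. When a gene model
table carries several transcripts per gene, the longest span is the
representative (ties to the smaller start). Feedback-loop distance is the
gap from the peak midpoint to the nearest edge of the miRNA gene span (a
locus is an interval, not a point), 0 inside the span. Coherent versus
incoherent feedforward labelling is out of scope: it needs the sign of the
master's regulatory edges, which the tool does not compute.

Identifier handling: symbols match case-insensitively; a token mapping to
several entrez ids contributes all of them (dropping silently would bias
against families targeting ambiguous symbols); unmapped tokens are
reported, never fatal.

## Synthetic data

The generators emulate every input at toy scale: per-transcript prediction
tables (1–3 isoforms per gene so pooling is exercised), identifier maps,
gene models spaced ≥ 100 kb on one synthetic chromosome (so the largest
menu window is unambiguous), BED peak files with planted hits and noise
peaks placed ≥ 2 windows from every TSS, miRNA loci, and gene sets drawn
as a mixture between one family's targets (weight `enrichment_prob`) and
the uniform null. A pair (family, gene) exists independently with
probability `base_density`, multiplied by `bias_factor` (capped at 1) for
a `long_utr_fraction` of genes — the long-3'UTR confounder reduced to the
only thing the statistic ever sees, per-gene target density. Defaults
(40 genes, 6 families, density 0.3, half the genes "long", bias 1) are a
deliberately small, unbiased reference condition; statistical checks use
200 genes / 20 families, 30-gene sets, 500 null sets, and bias factor 2
where confounding is the point. Every generator is a pure function of
(spec, seed) and writes a JSON manifest describing exactly what it
emitted.

What passing on these fixtures does not show: real prediction tables have
correlated family target sets (shared seed sites), non-Bernoulli density
profiles, and id-mapping noise; real peak sets have width/score structure
and chromosome-scale clustering. The tests demonstrate correctness of the
machinery and calibration under the stated generative model, not
performance on any particular organism's data.

## Numerical and design notes

- Random n-subsets are drawn by arg-partitioning iid uniforms per
  repetition, vectorised in fixed-size blocks of 8192 repetitions; block
  size is a constant, so results depend only on the seed.
- Determinism is bitwise: identical inputs, config and seed give
  byte-identical output files (floats are formatted, not repr'd).
- The exact-enumeration oracle in the tests applies the identical success
  predicate to all C(U, N) subsets; the Monte-Carlo p must match within 3
  standard errors. Under null draws the raw p-values are uniform up to the
  discreteness of the count distribution, which can only make them
  conservative — the calibration check bounds the p < 0.05 rate from
  above.
- The `correction=False` code path (ratio forced to 1) exists solely to
  measure what the correction buys; the CLI never exposes it.
- The minimum-target threshold uses `ceil(pct/100 * N)` with a 1e-9 guard
  so that e.g. 10% of 100 is 10, not 11 via float error.
- Output ordering is ascending FDR, ties by descending m_A then family
  label, enforced with a stable sort.

## Limitations

- Over-representation only; depletion is not tested.
- No GC-content or conservation matching of random sets; the total-target
  ratio is the only confounder control.
- Peak association ignores peak scores/summits and assigns each peak to at
  most one gene.
- The feedback-loop scan reports proximity of the master's peaks to miRNA
  gene spans; it does not distinguish hairpin from pri-miRNA coordinates
  beyond what the locus table provides.
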