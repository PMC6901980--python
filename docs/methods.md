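# Methods

## The problem and the model

Toxicant-induced organ injury leaves an early transcriptomic footprint.
Given replicated log-expression profiles from a treatment and a control
cohort, the pipeline asks whether predefined *injury modules* — gene sets
previously linked to histopathological endpoints such as liver fibrosis —
are activated, and whether activation in an in vitro cell model agrees
with activation in the tissue.

Everything rests on per-gene fold changes. For condition *c* with
treatment samples T and control samples C,

    fc_g = mean_{j in T}(x_gj) - mean_{j in C}(x_gj)

on the log scale, so fc is a natural-log fold change when the input is
ln-scale. Per-gene significance is a pooled-variance two-sample Student's
t-test (the input design is n = 5 vs n = 5 by default). Differential
expression uses Benjamini–Hochberg q-values with the decision rule
q ≤ 0.05 and |β| ≥ 0.41, where β is the natural-log effect size; 0.41 is
ln(1.5) rounded to two decimals, i.e. a 1.5-fold change.

Two gene-set statistics are computed over a set S with measured genes
S' ⊆ S:

* **AFC** (aggregated fold change): `sum_{g in S'} fc_g`. The sign is the
  direction of regulation. Its one-sided permutation p-value is the
  probability that a random gene set of size |S'| scores as or more
  extreme in the observed direction.
* **AAFC** (aggregate absolute fold change): `mean_{g in S'} |fc_g|`.
  Because it aggregates magnitudes, it detects modules whose genes move in
  mixed directions — the case where AFC cancels to zero. Each set gets a
  permutation p-value `p = (1 + #{null ≥ obs}) / (n_perm + 1)`, a z-score
  `z = (obs − mean(null)) / sd(null)`, and a Fisher combined p-value
  `X = −2 Σ ln p_g ~ χ²(2k)` over the set's per-gene t-test p-values,
  reported as a robustness indicator and never used as a filter.

The null draws gene subsets of size |S'| uniformly **without replacement**
from the measured universe, 10,000 draws by default, or enumerates all
C(N, k) subsets when that count is small. Downstream, modules are ranked
by z (most to least likely injury endpoint) with p < 0.01 marking
significant activation; cross-condition concordance is the squared
Pearson correlation of shared modules' z-scores (with the OLS slope
reported, because R² is sign-blind); a compound profiled under several
conditions keeps, per module, the row with the maximum activation score,
and is called high-risk when the target module (fibrosis) is significant
in that maximized table.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `q_max` | 0.05 | BH FDR bound for DEG calls |
| `beta_min` | 0.41 | natural-log effect bound (ln 1.5, two decimals) |
| `n_perm` | 10,000 | Monte-Carlo null draws per set |
| `alpha` | 0.01 | module significance threshold on p_perm |
| `min_coverage` | 0.5 | measured fraction of a set below which the result is flagged |
| `n_per_cohort` | 5 | samples per cohort in the synthetic design |
| `noise_sd` | 0.5 | per-gene Gaussian sd on the log scale |

## Design choices

* **Sum vs mean aggregation.** The activation score is reported as the
  mean of |fc| (modules) and the sum of fc (pathways), but both statistics
  are computed internally on the per-gene mean. Because set size is fixed
  in the null, sum and mean differ only by the constant |S'|, so z-scores
  and permutation p-values are provably — and in this implementation
  bit-exactly — identical under either reporting mode.
* **Log base.** Natural log internally (it matches the β definition);
  log2 input is accepted at load. Rescaling every fc by a constant leaves
  every permutation count and z unchanged up to the float rounding of the
  input multiplication itself (p-values compare identically; z agrees to
  ~1e-9 relative), so the choice of base cannot change any call.
* **DEG significance engine.** The per-gene t-test + BH replaces a
  bootstrap-based transcript-quantifier variance model; it preserves the
  decision rule (q ≤ 0.05, |β| ≥ 0.41) with a transparent, testable
  engine. β is taken as the fold change itself; a quantifier's shrunken
  effect size would differ gene by gene but ranks and signs agree.
* **Permutation conventions.** Add-one correction keeps p_perm in (0, 1]
  and valid for downstream thresholding; the plain proportion is also
  reported (`p_plain`) and is the quantity checked against exhaustive
  enumeration. Null values exactly equal to the observed statistic count
  as as-or-more extreme. Per-set null streams are keyed by (root seed,
  CRC32 of the set name), so results are independent of collection order
  and reproducible across platforms.
* **Degenerate inputs.** Zero within-cohort variance with equal means
  gives t = 0, p = 1; with unequal means, p is set to the smallest
  positive float with a warning. A null with zero spread (e.g. all |fc|
  identical) yields z = 0, p_perm = 1, and a `degenerate` flag. A p of
  exactly 0 entering Fisher's method is clamped to the smallest positive
  float. Sets sharing no gene with the matrix error when scored alone and
  produce a flagged NaN row when scored within a collection; a set
  covering the whole universe is rejected (its null has no room to vary).
* **One-sided AFC.** The pathway p-value is one-sided in the direction of
  the observed sign, with the direction reported separately; a score of
  exactly 0 reports direction "none" and uses the upper tail.

## What the generator emulates — and what it does not

`simulate_experiment` plants known activation into an i.i.d. Gaussian
log-expression background: disjoint modules drawn from a synthetic
universe, each with an effect size δ, a responder fraction, and an
up/down direction mix (default 0.5/0.5, the regime that motivates the
absolute-value statistic). It reproduces the features the statistics
actually consume — replication, log-scale additivity, known truth — and
deliberately omits count-level noise, gene–gene correlation, library-size
effects, and technical (bootstrap) variance. Passing tests therefore
demonstrate correctness and calibration of the statistics under their own
assumptions, not performance on real sequencing data; in particular,
gene–gene correlation within real modules would widen the random-set null
relative to this simulation.

## Study scales

The replicated studies in `toxmod.studies` (used by the test suite and
`scripts/acceptance.py`) run at a desk scale chosen to keep Monte-Carlo
error well below the margins being checked: null calibration over 200
replicates of a 2,000-gene, 11-module (size 20) design; recovery and
concordance over 100 replicates/pairs with 1 planted module (δ = ln 2)
and 8 decoys; 1,000 null draws per set within replicates, and 50,000
draws for the Monte-Carlo-vs-exhaustive agreement check on a 15-gene
universe.

## Known limitations

* Competitive (random-gene-set) testing only; no sample-permutation null,
  so inter-gene correlation is not absorbed into the null.
* Fisher's method treats per-gene p-values as independent, which real
  coexpressed modules violate; this is why the combined p is reported as
  an indicator rather than used as a filter.
* Gene identifiers are matched as opaque case-sensitive strings; ID
  harmonization between module lists and the matrix is the caller's
  responsibility.
* Single-factor treatment/control designs only; no covariates, batch
  terms, or multi-dose modelling beyond scoring each condition separately.
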