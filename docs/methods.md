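# Methods

This note documents the models and procedures implemented in `mullerx`,
the defaults they use, the numerical choices behind them, and what the
synthetic-data tests do and do not establish about real data.

## Gene-map construction and filtering

Inputs are translated-alignment hits (BLAT PSL) of reference gene models
against a target assembly, or precomputed placement TSVs. Two filters
produce the working table:

* **Best hit per gene** — the hit with the maximal `matches` score.
  Score ties are broken by the lexicographically smallest
  `(chromosome, start)`; any deterministic rule would do, this one is
  platform-stable.
* **Overlap removal** — two retained genes on the same chromosome may
  overlap by at most 19 bp (an overlap of exactly 20 bp is a violation,
  because retention requires < 20 bp). Conflicting pairs are resolved by
  dropping the lower-scoring member (score ties: the lexicographically
  larger gene id), iterating until clean. Coordinates are 0-based
  half-open throughout; overlap length is `max(0, min(end) − max(start))`.

Genes on unassembled scaffolds stay in the table flagged `placed=False`.
Downstream stages exclude them from margins and tests but report them
(as an `unplaced` pseudo-column in count matrices, or as `undetermined`
movement calls).

## Chromosome–element homology

With *P*₁ the proportion of shared genes on an element, *P*₂ the
proportion on a chromosome, and *N* the number of genes mapped in both
species, the independence expectation for the shared count is
*N*<sub>expected</sub> = *P*₁*P*₂*N*. A pair is called homologous when

1. observed / expected **strictly** exceeds 1.5,
2. the one-sided (greater) Fisher exact p on the 2×2 table
   (on-element ∧ on-chromosome, …) is below α = 0.05, and
3. at least 2 shared genes support the call — a single shared gene is
   never sufficient evidence of homology.

No multiple-testing correction is applied across pairs by default;
a Benjamini–Hochberg option exists (`bh_correct=True`). Unplaced genes
are excluded from both margins of the Fisher table.

### Event classification

From the homology calls, the X complement (union of elements on the
annotated X chromosomes) determines the event class: element F alone →
ancestral X; F plus other element(s) → X–autosome fusion; F absent from
the X → turnover, subdivided by the fate of F (fused to another
element's autosome, reverted to an independent autosome, or not
confidently placed). An empty X complement yields `unresolved` with a
warning.

### Fusion statistics

Independent fusion origins on a family tree are counted by parsimony
with the unfused state ancestral at the root and losses allowed; among
reconstructions minimising total changes, the reported count is the
minimum number of gain (0→1) edges, computed by a lexicographic
dynamic program over `(changes, gains)`.

The random-pairing expectation for the X-involving vs autosome–autosome
split of *n* fusions enumerates all unordered pairs of the six elements:
5 of the 15 pairs contain the single X element, so for 8 fusions the
expected split is (2.667, 5.333).

The co-option over-representation test is a max-statistic Monte-Carlo
multinomial test: under the null the observed co-option events fall
uniformly over the candidate elements, and the p-value is the
probability that the maximum per-element count reaches the observed
maximum. The construction is exact in the limit of replicates (the test
suite confirms convergence to exhaustive enumeration at small totals).

## Mk models of turnover

The turnover character (derived X present / absent) evolves under a
two-state continuous-time Markov chain with gain rate q₀₁ and reversal
rate q₁₀. The transition matrix is closed-form: with s = q₀₁ + q₁₀,
P(0→1; t) = (q₀₁/s)(1 − e^{−st}), etc. Likelihoods use Felsenstein
pruning with per-node rescaling; multifurcations are handled natively.

* **Models.** ER constrains q₀₁ = q₁₀; ARD frees both. A regime map
  assigns every branch to a rate regime; the stem branch of a focal
  clade belongs to the focal regime. Parameter counts: ER single 1,
  ARD single 2, ER two-regime 2, ARD two-regime 4.
* **Root prior.** Flat (½, ½) by default; the stationary distribution
  of the root's child-edge regime is available by flag.
* **Optimization.** L-BFGS-B on log₁₀ rates bounded in [−8, 3], with
  ≥ 5 seeded jittered starts centred on one expected change per total
  tree length; an optional extra start at supplied rates lets a nested
  alternative begin from its null's optimum, which guarantees the LRT
  statistic is non-negative. Non-convergence returns the best values
  found with `converged=False`.
* **LRT.** Statistic 2·(ℓ_alt − ℓ_null) floored at 0, compared to χ²
  with df equal to the parameter difference. An alternative likelihood
  below the null beyond tolerance raises an error (an optimizer-failure
  signal, not a p-value).

The implementation was verified against an exhaustive enumeration over
internal-state assignments (agreement to 1e-10 on trees of up to six
tips) and, during development, against an independent reference ML
implementation on a 200-tip dataset (identical rate and log-likelihood).

## Brownian-motion ancestral states

Tip values (here: percentage of mapped genes on element F) are modelled
as Brownian motion with rate σ². The ML ancestral values are obtained by
solving the weighted tree-Laplacian linear system (edge weights
1/branch-length) with tips clamped; for a Gaussian process this equals
the generalized-least-squares reconstruction under the BM tree
covariance. σ² is estimated by ML: the minimized quadratic form (which
equals the GLS residual form by the Schur-complement identity) divided
by the number of tips *n*. Per-node variances are σ̂² times the diagonal
of the inverse internal Laplacian; 95% CIs are estimate ± 1.96·√var.

Convention note: because σ̂² uses the ML denominator *n*, variances are a
factor (n−1)/n narrower than implementations that scale by n−1; node
estimates are unaffected. All branch lengths must be positive; zero
branches should be collapsed before reconstruction (the function refuses
them rather than silently regularising).

Node-set comparisons (e.g. nodes inside vs outside a clade) use a
two-sided Mann–Whitney U test on the point estimates — exact when the
pooled estimates are tie-free, asymptotic with tie correction otherwise.
This is a reimplementation choice: the comparison is a descriptive
contrast of dependent node estimates, and its p-value should be read
accordingly.

## GC windows

GC fraction is (G+C)/(A+C+G+T), case-insensitive, in windows of 100 kb
width and step by default (both configurable). N and other ambiguity
codes are excluded from the denominator to avoid masking-driven
artifacts. A window enters the X-vs-autosome comparison only when its
unambiguous bases cover ≥ 50% of the nominal window size — this also
drops short trailing windows. The comparison is a two-sided
Mann–Whitney U; direction is assigned by medians at p < 0.05. Windows on
one chromosome are not independent, so the output warns about
pseudoreplication rather than correcting for it.

## Gene movement and the size-weighted null

A trio is a focal species with a derived X plus two outgroups that
retain element F as the X. Chromosome correspondence between each
outgroup and the focal species uses the same 1.5× enrichment rule as
homology calling; each source chromosome keeps its highest-ratio
partner (two fused sources may share one target). A gene's ancestral
location is defined only when both outgroup placements map to the same
focal chromosome; disagreement, absence, or an unplaced placement in
any member leaves it `undetermined` — no imputation. Movement is called
when the focal placement differs from the ancestral location. The
X/autosome class of a chromosome is its identity in the focal species,
so a gene that never changed chromosomes counts as `none` even if its
chromosome was newly co-opted as the X.

Expected moves from chromosome *i* to *j* are proportional to
*N*<sub>i</sub>·*L*<sub>j</sub>·*f*<sub>ij</sub> over ordered pairs
(i ≠ j), with *f*<sub>ij</sub> = 0.75 for X destinations (the X is
present in 3 of 4 chromosome copies in a population with equal sex
ratio) and 1 otherwise. Proportions are binned into X→A, A→X, A→A
(and X→X when several X chromosomes exist) and scaled by the observed
move total; significance is a Pearson χ² goodness-of-fit with
df = bins − 1, warning (not failing) when an expected bin is below 5.
Per-chromosome loss fractions are normalized by the fraction of genes
on other chromosomes, so small chromosomes are not penalised for their
larger target space.

Expression of moved genes is compared per tissue to **all mapped genes
(inclusive of the moved set)** with a two-sided Wilcoxon rank-sum test.
The inclusive background makes the test slightly conservative — at a
group of 100 within 2000 the asymptotic null rejection rate at α = 0.05
is ≈ 0.039 rather than 0.050, because the group's self-overlap deflates
the z-statistic — which is accepted as part of the design rather than
corrected.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given a seed and emit truth tables
sufficient to score every downstream call.

* **Gene maps.** A reference labelling assigns genes to elements with
  default proportions F = 1% and 19.8% for each large element (a
  non-Schizophora preset puts 2.5% on F); defaults of 2000 genes per
  species, 2% mismapping and 1% unplaced rate. Genes land on the
  chromosome carrying their element, on a uniformly wrong chromosome
  (mismap), or on a private scaffold (unplaced); coordinates are laid
  out sequentially with random gaps, so tables are non-overlapping by
  construction.
* **Trees and characters.** Pure-birth (Yule) trees with unit birth
  rate; Mk tip states by exponential waiting times per branch with the
  branch's regime rates and a flat root; BM tips by accumulated normal
  increments.
* **Genomes.** i.i.d. bases at a per-chromosome GC mean, optional N
  blocks. No composition autocorrelation, isochores or repeats — enough
  to validate rank-based comparisons, not to emulate real base
  landscapes.
* **Trios.** Outgroups keep the ancestral karyotype; the focal species
  has a planted turnover. Moves are drawn from the expectation null's
  own pair weights, with a configurable multiplier on X sources (1.0
  reproduces the null exactly, used for type-I calibration; 3.0 is the
  planted-excess power condition).
* **Expression.** Log-normal values per tissue; moved genes' testis
  column multiplied by the planted effect (default 2.0), somatic
  tissues untouched as negative controls.

Passing tests on these data establish internal correctness —
likelihoods match enumeration, estimators are calibrated, planted
events are recovered at the stated noise levels. They do not establish
robustness to the failure modes of real assemblies (collinear
mis-scaffolding, biased gene loss, annotation-quality gradients with
phylogenetic distance), which the mismap/unplaced noise model only
caricatures.

## Problem sizes used by the statistical test suite

Chosen as the package's own validation conditions: likelihood oracles on
100 random trees of ≤ 6 tips; LRT type-I calibration with 500 replicates
on a 150-tip tree (rejection within [0.03, 0.07] at α = 0.05); ER rate
recovery on 100 simulated 200-tip datasets at q = 0.5 (mean within 10%);
BM-vs-GLS agreement on 50 random trees of ≤ 20 tips at 1e-8; karyotype
recovery on 200 species at 2% mismapping with ≥ 300 genes per large
element (≥ 95% correct; 100% noise-free); movement χ² type-I over 500
trio replicates and power ≥ 0.9 against a 3× out-of-X excess with 200
moves; GC shift detection (0.05 planted difference, 50 windows per side)
in ≥ 95% of 200 replicates; expression null calibration over 1000
replicates (fresh matrix each, measuring the marginal rejection rate)
and ≥ 90% detection of a 2× testis effect over 100 replicates.

## Known limitations

* Only binary turnover characters; no hidden-rate or multi-state models.
* Homology calling assumes enough shared genes per chromosome; very
  small elements (F in gene-poor assemblies) can legitimately come out
  `unresolved`.
* The movement null conditions on the observed move total and the
  ancestral gene counts; it does not model detection failure of moved
  genes.
* GC windows ignore assembly masking conventions beyond treating
  non-ACGT as missing.
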