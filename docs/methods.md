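# Methods

This note documents the models, statistics and numerical conventions behind
`mitopart`, the choices made where several reasonable definitions exist, and
what the synthetic-data generator does and does not emulate.

## Coordinates, genes and partitions

Alignment coordinates are 1-based and inclusive, matching the GenBank
flat-file convention for mitochondrial genomes. The genome is circular: an
annotation with `end < start` wraps through the origin, and extracting
`[k, k-1]` returns every column exactly once. Minus-strand genes (ND6 in
vertebrate mtDNA) are reverse-complemented on extraction so codon positions
are meaningful on the coding strand; gaps and IUPAC ambiguity codes pass
through unchanged. Overlapping genes (1–16 nt overlaps are normal in
mitogenomes) each keep their full extent — shared columns are duplicated
into both gene partitions, never deduplicated.

Codon partition schemes assign position 1/2/3 by walking each gene's sites
in reading order from its `reading_frame_offset`; terminal incomplete codons
are allowed. The four modes (`unpartitioned`, `by_gene`, `by_codon`,
`by_gene_and_codon`) give 1, *n*, 3 and 3 *n* blocks for *n* coding genes.

Haplotype counting uses exact string equality: a gap or `N` difference
creates a new haplotype. No published collapse rule exists for the summary
this reproduces; exact equality is the only convention that is fully
reproducible, and alternatives (ignore-N matching) are deliberately not
implemented.

## Distances and Neighbor-Joining

Raw p-distances use pairwise deletion: a site counts for a pair only when
both sequences show an unambiguous base. The JC69 correction
d = −(3/4) ln(1 − 4p/3) is undefined at p ≥ 3/4; such pairs are *flagged*
saturated (NaN) rather than raised, because saturation plots need them.
"Standardized" distances are interpreted as model-corrected (JC69) values
plotted against raw p-distances on common axes; no further normalization is
applied and axis scaling is left to the caller.

NJ is the standard Saitou–Nei agglomeration. Two determinism rules: negative
branch-length estimates are clamped to zero, and Q-criterion ties merge the
lexicographically smallest label pair. The implementation is cross-checked
against scikit-bio's `nj` in the test suite.

## Tree ensembles, support and topology comparison

Ensembles are ordered post-thinning samples; burn-in removal (default 10 %)
discards the first ⌊f·n⌋ samples. Clade posterior probability is **rooted**
monophyly — the clade's taxa must be exactly the leaf set below some node —
while the PH85 distance uses **unrooted** bipartitions, following its
published definition as the symmetric difference of non-trivial split sets.
This mixed convention mirrors how the two statistics are used in practice
(support is reported on rooted chronograms; topology distance is a property
of the unrooted shape). Polytomies contribute fewer splits; they are never
implicitly resolved.

The MCC tree is the *sampled* tree maximizing the product of its clades'
posterior frequencies (ties: earliest sample index), with node heights
replaced by per-clade median heights over the samples containing the clade;
medians that would violate root-to-leaf monotonicity are lifted to the
tallest child.

The 95 % credible set is keyed on the per-sample posterior density scalar:
samples whose scalar falls inside the HPD interval of that scalar at the
requested level. An alternative construction (cumulating topology
frequencies) exists, but the scalar-HPD definition is the one the containment
test is stated against, and it is what `credible_set` implements. The
containment test then asks whether any member has PH85 = 0 to the reference
topology.

## Substitution models and BIC

The model space is {JC69, K80, HKY, GTR} × {plain, +I, +G, +I+G} — 16
candidates covering the models mitochondrial alignments of this kind select
in practice. Rate matrices are scaled to mean rate 1. Discrete gamma uses 4
equal-probability categories represented by their category *means* (computed
from the regularized incomplete gamma function); with +I, the gamma rates
are rescaled by 1/(1 − p_inv) so the mixture mean stays 1. Gaps and
ambiguities are missing data (partial likelihood 1 over compatible states).
Per-node rescaling of partials keeps likelihoods finite on long trees.

Fitting optimizes the free model parameters plus a single branch-length
multiplier on a fixed guide tree (NJ on JC69 distances by default) with
bounded L-BFGS-B on log-transformed parameters, three spread starting
points, lnL tolerance ~1e-9 (scipy `ftol`). Per-branch length optimization
is out of scope: model *ranking* is robust to guide-tree detail. Kappa is
capped at 1e4; a binding cap raises a `kappa-at-bound` warning — the
signature of transition-saturated data where the transition/transversion
ratio is unidentifiable.

BIC = −2 lnL + k ln n with n = alignment sites by default. The parameter
count k is the model's free parameters (frequencies counted for HKY/GTR,
+1 for each of gamma shape and p_inv) plus one for the branch-scale
multiplier. Some tools instead pass a fixed nominal sample size (e.g. 1000);
`n_override` reproduces that convention, but site count is the default
because it is the only choice defensible from the data alone.

## Trace statistics and date estimation

* **ESS** = N / (1 + 2 Σ ρ_k) with the initial-positive-sequence truncation
  (stop at the first non-positive autocorrelation estimate); autocovariances
  via FFT. Constant traces report ESS = N with a zero-variance warning.
* **HPD** is the shortest contiguous window of sorted samples holding
  ⌈level·N⌉ points; endpoints are sample values.
* **Coefficient of rate variation** is sd/mean with the sample sd (n − 1),
  unweighted. Some samplers report a branch-time-weighted version; the
  verbal definition (sd of the rate over its mean) is implemented as stated.
* **TMRCA bias**: the reference (whole-mitogenome) node-age posterior is
  log-transformed and fitted by moments to N(μ, σ) — identical to the
  lognormal MLE, and natural logs throughout (the base cancels from the
  bias but not from reported μ, σ). Each observed draw x gets
  q = Φ((ln x − μ)/σ); bias is the fraction with q *strictly* above 0.5,
  which reduces to the fraction with ln x > μ (q = 0.5 exactly counts as
  not-over, fixing the boundary deterministically). For observed draws
  LogNormal(μ + δ, σ_o) the large-N limit is Φ(δ/σ_o): the target's σ
  cancels from the > 0.5 comparison, so the statistic measures the shift in
  units of the *observed* spread. When observed and reference spreads match
  (the usual case for posteriors of the same node), this is Φ(δ/σ).
* **ANOVA** on log-TMRCAs treats MCMC draws as independent observations, as
  is conventional for this comparison; the pseudo-replication caveat stands
  and p-values are descriptive, not frequentist guarantees.
* **Calibration cross-validation** removes one lognormal fossil prior,
  re-estimates, and reports the removed prior's probability mass inside the
  posterior's 95 % HPD interval (computed exactly from the lognormal CDF;
  offsets shift the support). "Overlapping area under the curve" is not a
  standard quantity; prior-mass-in-HPD is the operationalization used, and a
  boolean alternative (prior's central 95 % inside the HPD) is exposed as
  `hpd_containment`.

## Marginal likelihoods and Bayes factors

The harmonic-mean estimator ln m = ln N − logsumexp(−ℓ_i) is computed
strictly in log space (traces near −2·10⁴ must not overflow — enforced by
test). Burn-in removal is the caller's duty to avoid double removal. The
estimator's upward instability and bias toward richer parameterizations is
recorded in the estimate's metadata and deliberately *not* corrected: the
comparison this package reproduces used exactly this estimator, and path
sampling or stepping-stone alternatives are out of scope. Bootstrap standard
errors resample the full trace with replacement (default 1000 replicates,
seeded).

## Informative-gene selection

Support means PP strictly greater than the threshold (default 0.6). Step 1
takes every unique supporter in clade order; step 2 greedily adds the gene
covering the most uncovered clades. The tie-break order — higher PP on the
clades the gene would cover, then lower rate CoV, then lexicographic name —
is a documented reconstruction chosen so that, on the bundled killer-whale
table, clock-like CYTB beats ND1 for the Atlantic clade and ATP6 beats
ND4/ATP8 for Residents; no claim is made that it is the only defensible
order. Greedy set cover is approximate: the report records coverage, never
minimality. Exhaustive search over gene combinations is a non-goal.

## Synthetic data

The generator produces every input with known truth, at the study conditions
the pipeline targets: mitogenome haplotypes of closely related lineages.

* **Yule trees**: the pure-birth process starts at the root with two
  lineages; with k lineages a uniformly chosen one splits after an
  Exp(k·λ) wait; after the n-th lineage one further Exp(n·λ) wait separates
  the last split from the present; all times are rescaled so the root sits
  exactly at `root_age`. Relative ranked node depths are tested against an
  independent order-statistics simulation.
* **UCLN rates**: iid lognormal per branch, parameterized by real-space
  mean and CoV (σ² = ln(1 + CoV²), μ = ln m − σ²/2) so the `clock_cov`
  input plugs directly into `rate_cov` recovery tests; CoV = 0 degenerates
  to the strict clock. Rates are independent of branch lengths.
* **Sequence simulation**: root states from the base frequencies; each
  branch evolves with expected substitutions = time × branch rate × site
  rate, site rates drawn once per site from the model's gamma/invariant
  mixture. Defaults: 12 taxa, root age 2 My, clock mean 2.6 × 10⁻³
  substitutions/site/My (a typical whole-mitogenome estimate for cetaceans),
  clock CoV 0.5 (mid-range between clock-like and strongly variable genes),
  8 coding genes of 600 nt under HKY (κ = 8, mtDNA-like frequencies) with
  relative rates spanning 4× — the spread observed across mitochondrial
  coding genes.
* **Emulated posteriors**: each sample bootstraps alignment columns,
  builds an NJ tree on JC69 distances, roots it at the true root split when
  that split is present (midpoint fallback; degenerate zero-length
  replicates keep their arbitrary basal node), and becomes ultrametric by
  jittering true clade ages lognormally (sd `age_log_sd` on the log scale);
  novel clades sit just above their tallest child. The trace log carries a
  posterior scalar (the sample's JC69 data log-likelihood), rate columns and
  per-node age columns, and parses back through `read_trace`.

This emulation reproduces the *statistical shape* downstream summaries need:
clade frequencies that track signal strength, controllable node-age bias and
spread, credible sets with an ordering scalar. It is **not** an MCMC
posterior: there are no tree or clock priors, no Hastings ratios, bootstrap
support is not posterior probability, and the posterior scalar is a
likelihood, not a posterior density. Tests passing on these ensembles show
the *statistics* behave correctly, not that any sampler is well calibrated.
Real posteriors also carry correlated node ages and autocorrelated traces
that the emulation only partially mimics (ages share one jitter stream;
trace columns are white).

## Problem sizes and determinism

Default desk-scale sizes — 8–12 taxa, genes of 400–600 nt, ensembles of
100–500, 10,000 draws for scalar statistics — were chosen so every analysis
in the test suite and the acceptance script runs in seconds to a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
tolerances. One study seed fans out to per-component child seeds via
`numpy.random.SeedSequence.spawn`; every generator is bit-reproducible for a
fixed seed.

## Known limitations

* No Bayesian MCMC inference, de novo alignment, or GenBank retrieval: tree
  ensembles and traces are consumed as inputs or emulated.
* No K2P/TN93 distances, no majority-rule consensus trees (the MCC-tree
  route is deliberate — it distinguishes gene trees even when clades are
  weak), no per-branch length optimization, no codon or amino-acid models.
* The harmonic-mean marginal likelihood is known-unstable; results should be
  read as the convention being reproduced, not as the best available
  estimator.
* ESS uses a single truncation rule (initial positive sequence); no
  Gelman–Rubin or multi-chain diagnostics.
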