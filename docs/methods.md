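# Methods

`dualnet` implements a dual-network analysis of a paired, two-arm
treatment study: one co-expression network inferred from the data by
calibrated mutual information, and one externally supplied interaction
network scored from per-gene P-values.  Modules found independently in
the two networks are compared through their enriched pathways, and each
shared pathway receives an empirical permutation P-value.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Study model and baseline correction

The unit of analysis is the within-subject log2 difference
`delta_g = post_g - pre_g` for each gene g, which removes
inter-individual expression offsets.  Subjects lacking a complete
pre/post pair are dropped with a warning rather than imputed, mirroring
the exclusion of technically failed arrays in real studies.

Unexpressed genes are removed using a sex-marker gene expressed in one
sex only (an XIST-style marker): the background threshold is the median
log2 intensity of the marker in the non-expressing sex, and a gene is
kept if *any* array reaches that threshold.  Ties at the threshold count
as expressed; the marker itself passes through the same filter.  The
strict-vs-non-strict boundary is a convention (the observable behaviour
differs only on exact ties) and is fixed here as non-strict (`>=`).

## Differential expression

Per gene, `delta` is regressed by OLS on treatment arm (0/1), sex (0/1)
and standardised age.  Variances are moderated by empirical Bayes: the
prior `(d0, s0^2)` is estimated by moment matching on log residual
variances, solving for `d0` via a Newton inversion of the trigamma
function.  When the observed spread of log variances is no larger than
the sampling noise of a common variance, the moment equation has no
positive solution; `d0` is then capped at 1e6 (effectively a pooled
z-like test) with a warning.  Moderated variances are
`(d0*s0^2 + d*s_g^2)/(d0 + d)` and the moderated t is referred to a t
distribution on `d0 + d` degrees of freedom, two-sided throughout.
Multiple testing uses Benjamini–Hochberg step-up q-values.

The null calibration test (30 subjects, 2,000 independent null genes)
checks that the whole filter → delta → fit → moderate chain has type-I
error within [0.035, 0.065] at alpha = 0.05 and uniform P-values by
Kolmogorov–Smirnov.

## Mutual-information network

MI is estimated in nats with a Gaussian-kernel density estimator after a
rank transform.  Profiles are first copula-transformed to
`rank/(n+1)`; the estimator then maps these ranks through the standard
normal quantile function (van der Waerden scores) and applies kernels of
width `h` on that scale.  Three details matter and were chosen after
measuring estimator error against the closed form
`MI = -0.5*ln(1 - rho^2)` for bivariate Gaussians:

- **Normal scores rather than the unit interval.**  Kernel density
  estimation on (0,1)^2 suffers boundary and corner bias; at rho = 0.9
  the deficit reaches 0.1–0.3 nats depending on width.  On normal scores
  the joint is smooth and unbounded and the bias shrinks by an order of
  magnitude.  Rank invariance is unchanged.
- **Leave-one-out densities.**  Including the self-term (kernel value 1
  at distance 0) inflates the joint density and produces a systematic
  positive MI at independence; leave-one-out estimates remove it, so
  independent profiles score ~0 after clipping at zero.
- **First-order Jensen correction.**  `E[log fhat] = log f -
  Var(fhat)/(2 f^2) + O(Var^2)`; the variance of each leave-one-out
  density is estimated from the empirical variance of its kernel values
  and the correction added.  This halves the residual negative bias at
  moderate correlation.

The default width 0.2 is the MSE-minimising grid point at n = 1000; the
`calibrate_kernel_width` grid search recomputes the optimum for any
sample size by simulating bivariate Gaussians over a correlation grid
and scoring squared error against the closed form.  Widths shrink
(weakly) as n grows.

The irreducible sampling noise of any resubstitution MI estimate is
`sd ~= rho/sqrt(n)` (~0.028 nats at rho = 0.9, n = 1000), so accuracy
checks average a small number of pre-registered seeds per correlation
rather than scoring a single draw.

**Threshold calibration.**  Null MI values from independent profile
pairs at the study's sample size are fitted on the log-survival scale,
`ln P(MI > I0) = alpha + beta*I0`, by least squares over the upper half
of the survival curve; inverting the line converts a P-value cutoff into
an MI threshold.  The fit is per sample size (the pooled `n*I0` scaling
used by some calibrations is not assumed).  Extreme cutoffs (1e-8) are
extrapolations of this line; they are appropriate when the number of
candidate pairs is of order 1e8 (genome scale).  For the synthetic desk
scale (hundreds of genes, ~1e4 pairs) the pipeline's default is the
Bonferroni-style cutoff `0.05 / n_pairs`, which plays the same role at
the matched multiplicity.

**DPI.**  In every triangle of the thresholded graph the weakest edge is
marked when it is `<= (1 - tolerance) * min(other two)` and all marked
edges are removed afterwards.  With tolerance 0 every triangle loses its
weakest edge; exact ties mark all tied minima.  The pass is idempotent.
Whether pruning should follow thresholding is a modelling choice; DPI
defaults on with tolerance 0 and is exposed as a flag.

**Bootstrap consensus.**  B subject-resamples (default 100) each yield a
thresholded network (support counting uses the un-pruned thresholded
graphs so DPI tie-breaking noise does not perturb counts).  An edge with
support k is kept when its upper-tail binomial P-value under the
mean-density null rate, Bonferroni-corrected over all candidate edges,
falls below q (default 0.001).  A corrected support cutoff alone does
not pin down a test; the binomial-with-mean-density null is this
package's definition of the consensus contract.

**Degree diagnostic.**  The degree distribution is fitted as a power law
either by log–log regression over logarithmically binned degrees or by
discrete maximum likelihood using the Hurwitz zeta normalisation; the
MLE recovers a generating exponent of 2.0 within ±0.1 at n = 10,000.

## MCODE dense modules

The published MCODE algorithm with the plugin defaults: degree cutoff 2,
node-score percentage 0.2, haircut on, fluff off, k-core filter 2,
maximum depth 100.  A vertex weighs `k * density` of the highest k-core
of its closed neighbourhood; complexes grow breadth-first from the
heaviest unvisited seed, admitting unvisited neighbours within the
node-score percentage of the seed weight; members are exclusive to one
complex.  Haircut iterates until no member has fewer than two
within-complex neighbours.  Complexes lacking a 2-core are discarded and
the rest ranked by `density * size`.  All ties (seeding and ranking)
break on the lexicographically smallest node id, making output
independent of node insertion order.  Plugin releases differ in minor
variants; the published algorithm description is the contract here.

## Interaction-network scoring

Node P-values are modelled as the beta-uniform mixture
`f(p) = lambda + (1 - lambda) * a * p^(a-1)` (the model sometimes
labelled "binomial uniform mixture"; the fitted object is the standard
beta-uniform mixture).  The fit maximises the likelihood with a 5-start
bounded quasi-Newton search; lambda is constrained to [0.01, 0.99]
because pure-uniform data places the likelihood on an unidentifiable
ridge — the fitted signal mass `(1-lambda)*(1-a)` still vanishes there.
The FDR-controlled threshold is
`tau = (fdr*(1-lambda) / (pi - fdr*lambda))^(1/(1-a))` with
`pi = lambda + (1-lambda)*a` (clipped to 1 for large FDR), and node
scores are `(a-1)*(ln p - ln tau)`, positive exactly when `p < tau`.

The maximum-weight connected subgraph is found exactly on small graphs
(<= 30 nodes) by branch-and-bound over connected subsets, with the bound
"current score plus all remaining positive scores"; ties prefer smaller,
then lexicographically smaller sets, realised by the deterministic
exploration order.  On larger graphs a Steiner-style heuristic connects
positive-score components through the cheapest negative paths (Dijkstra
on node deficits), spans them with an MST, and prunes subtrees with
non-positive totals; the result is connected, never scores below the
best single positive component, and by construction never exceeds the
exact optimum.  On random 12-node instances it matches the exact solver
on >= 90 % of cases.

At the planted-recovery operating point (200 nodes, 15 signal nodes with
`p ~ Beta(0.1, 1)`, FDR 0.05) perfect recovery is impossible in
principle: about a fifth of Beta(0.1,1) draws exceed 0.1, so some signal
nodes are indistinguishable from background; Jaccard ~0.5–0.7 against
the planted truth is the expected regime, not a solver deficiency.

## Enrichment and filtering

Over-representation uses the upper-tail hypergeometric `P(X >= k)`
(exact; verified against full combinatorial enumeration for all valid
configurations with N <= 25).  The conditional ontology test walks the
DAG children-first and removes genes annotated to already-significant
descendants (same alpha as reporting, 0.05) from both the term's
annotation set and the overlap before testing, so ancestors are only
credited for unexplained evidence.  Multi-parent terms are conditioned
on all significant descendants regardless of path.

Pathway filtering drops terms in excluded categories (e.g. "disease")
unless explicitly excepted, drops terms supported by fewer than two
genes in the module where they were called, and then drops modules with
no genes annotated in any surviving term.  The filter is idempotent.
Term clustering orders pathways by average-linkage hierarchical
clustering under the `1 - Pearson` distance on per-module gene counts;
constant profiles get the maximal distance 2.  The linkage choice is a
convention recorded in output metadata.

## Common pathways and their permutation null

A pathway is common when significant (p < alpha) in both modules'
filtered tables.  Its chance level is the fraction of N iterations
(default 1000) in which it is common for two random gene lists of the
observed module sizes, drawn independently and without replacement from
the universe, with the identical enrichment + filter + intersection
applied inside each iteration.  Zero counts are reported as p = 0 with
the resolution floor 1/N noted, and an `(n+1)/(N+1)` corrected estimate
is emitted alongside.  The two lists per iteration are drawn
independently; restricting draws to annotation-bearing genes is done by
passing that restricted universe.  On a single-set fixture
the per-iteration common probability factorises into the product of two
exact hypergeometric tail sums, which the engine matches within binomial
99 % bounds at N = 1000.

## Synthetic data: what it emulates and what it does not

`generate_study` draws a paired pre/post study: two equal arms, random
sex (balanced) and ages 18–65, gene baselines Uniform(6, 12) on log2.
The post-minus-pre difference of a module gene follows the factor model
`delta = noise_sd * (sqrt(r)*f_m + sqrt(1-r)*eps)` with a per-subject
module factor `f_m`, giving expected within-module pairwise correlation
exactly `r`; background genes are independent noise.
Treatment-responsive genes shift by `effect_size` log2 units in the
treated arm only.  The sex-marker is Normal(10, 1) in females and
Normal(5, 0.5) in males, mimicking a bimodal single-sex marker without
claiming its exact parameters.  Defaults follow the emulated design: 32
subjects, one 150-gene module at r = 0.8, 2-fold effects.

`generate_planted_network` grows a preferential-attachment graph,
selects a connected signal subgraph by seeded breadth-first growth,
gives signal nodes `Beta(a, 1)` P-values and background nodes uniform
ones; if `(1 - lambda) * n` exceeds the signal size, extra background
nodes also draw from the beta component so the pooled P-values follow
the requested `lambda*U + (1-lambda)*Beta(a,1)` mixture exactly.  With
`signal_size = 0` all P-values are uniform regardless of lambda
(degenerate no-signal case).

Not emulated: probe-level effects, batch effects, missing values,
library-size artefacts, correlated background structure, or annotation
bias.  Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated generative
model — not robustness to the artefacts of real microarray data.

## Problem sizes and runtime

The test suite and acceptance script run everything at desk scale: 60-
to 300-gene panels, 30–32 subjects, 100–250-node interaction graphs,
100 bootstrap cycles, 1000 permutation iterations.  These sizes were
chosen as the smallest at which each statistical contract is
informative (e.g. 2,000 genes for a ±0.015 type-I band, 10,000 draws
for ±0.05 mixture recovery).  Genome-scale runs (16k genes, 1.3e8 MI
pairs) use the same code paths but are outside the scope of the bundled
data.

## Known limitations

- The exact solver's branch-and-bound is exponential in the worst case;
  the 30-node guard is deliberate.
- The BUM likelihood is non-convex; five fixed starts have sufficed on
  all tested data but a global optimum is not guaranteed.
- The null-MI survival line is linear only over the fitted tail;
  extreme extrapolation inherits that assumption.
- The bootstrap-consensus null treats edges as exchangeable
  (mean-density rate), which is generous to hub edges.
- An externally quoted hypergeometric setting (e.g. a 20,900-gene
  genome with 2,000 annotated interferon-regulated genes) is computed
  exactly for the supplied counts; published figures for such
  calculations are themselves approximate and need not match exactly.
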