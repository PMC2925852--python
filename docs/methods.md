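# Methods

## The problem

Likelihood-based phylogenetics needs an explicit nucleotide substitution
model, and practitioners choose one with a model-selection criterion.  This
package re-creates, end to end, a simulation study of the four widely used
criteria — the hierarchical likelihood-ratio test (hLRT), the Akaike
information criterion (AIC), the Bayesian information criterion (BIC) and
decision theory (DT) — by simulating data under known models, running the
full ModelTest-style selection workflow on every simulated dataset, and
scoring each criterion's ability to recover the generating model.

## Models

The model family is the GTR family: a stationary, time-reversible,
homogeneous Markov process with stationary frequencies
π = (π_A, π_C, π_G, π_T) and symmetric exchangeabilities
s = (s_AC, s_AG, s_AT, s_CG, s_CT, s_GT), with Q_ij = s_ij π_j for i ≠ j.
Q is normalised to unit mean rate, −Σ_i π_i Q_ii = 1, so branch lengths are
expected substitutions per site.  Named sub-models constrain s into equality
classes and/or force equal frequencies; we use the standard 14 base models of
the "7 schemes × 2 frequency variants" convention (JC, F81, K80, HKY, TrNef,
TrN, K81, K81uf, TIMef, TIM, TVMef, TVM, SYM, GTR).  Each base model can
carry a proportion of invariable sites (+I, parameter p_inv) and
discrete-gamma rate heterogeneity (+G, shape α, four equiprobable
categories whose rates are the means of the quantile intervals of a mean-one
gamma).  This yields the 56-model candidate set; the 24-model generating set
restricts the bases to JC, F81, K80, HKY, SYM and GTR.

κ-parameterised models (K80/HKY) are stored in exchangeability form
(transitions get rate κ, transversions 1), so a single rate-matrix builder
serves the whole family.

Convention for +I (+I+G): variable sites keep mean rate one, i.e. rates are
*not* rescaled by 1/(1 − p_inv).  The simulator and the likelihood engine
share this convention (the Seq-Gen/PAUP* convention), so inference is
consistent with the generating process.

## Generating parameter values

Two parameter sets drive all simulations (values as used throughout):

* set A — π = (.35, .22, .18, .25); s = (2.675, 7.35, 6.125, .225, 30.7, 1)
  relative to GT; κ = 2.0; α = 0.67256; p_inv = 0.25.
* set B — π = (.35, .15, .25, .25); s = (2, 4, 1.8, 1.4, 6, 1); κ = 2.0;
  α = 0.5; p_inv = 0.5.

Each generating model takes the subset of these values that it can express
(e.g. SYM uses the six rates with equal frequencies; HKY uses κ and the
frequencies).

## Guide trees

Ultrametric trees are drawn from a birth-death process conditioned on the
number of extant tips (speciation 0.1, extinction 0.1, sampling fraction
1.0; dendropy's sampler, retrying on extinction) and rescaled so the
root-to-tip height equals the condition's stated value (0.7/0.5/0.3/0.1
substitutions per site).  The non-clock tree assigns its 19 internal edges
lengths 10^(2x/18 − 3) for a random permutation of x = 0..18 and its 22
external edges 10^(2x/21 − 3) for x = 0..21, mixing branch lengths from
0.001 to 0.1 on one unrooted 22-taxon topology (drawn once, from the
birth-death sampler, topology only).  Trees are drawn once per condition,
not per replicate.

## Sequence simulation

Sites evolve independently; root states are drawn from π and propagated
tipward with P(t·r) = expm(Q t r), where r is the per-site rate (gamma
category, or 0 for invariable sites, which therefore show one π-drawn state
at every tip).  The codon condition uses the GY94 codon model: a 61×61
generator over sense codons (universal code) in which codon pairs differing
at more than one position have rate zero and single-nucleotide changes get
(target-codon frequency) × (nucleotide exchangeability), times ω when
nonsynonymous.  "Crossing" GY94 with a GTR-family generating model means the
model's exchangeabilities and (position-independent, 1×4) frequencies
parameterise the single-nucleotide term, and its +I/+G structure acts as
site-rate multipliers on codon sites.  The stated mutation rate (0.001)
scales the guide tree's branch lengths; with the default height-0.5 tree
this yields very low divergence, which is itself informative — the
selection criteria disagree most on data with little signal.  The true tree
source for the original codon simulation (a coalescent simulator) is not
recoverable; this scaling interpretation is a documented, configurable
choice.

## Model fitting

For each dataset the topology is fixed once: neighbor joining (Saitou-Nei,
deterministic tie-breaking by lowest pair index, negative branch estimates
clamped to zero) on Jukes-Cantor distances (saturated pairs capped at 5.0
substitutions/site).  The topology is *not* re-estimated per model — this
mirrors the ModelTest/PAUP* workflow and is what makes branch-length
vectors comparable across models, as DT requires.

Each of the 56 candidates is then fitted by maximum likelihood on that
topology: Felsenstein pruning over compressed site patterns with per-node
scaling; site likelihood p_inv·π_x·[constant] + (1 − p_inv)·mean over gamma
categories.  Optimisation alternates (a) coordinate-ascent sweeps over
branch lengths — each edge solved by bounded Brent on a cheap 1-D profile
built from cached inside/outside partials, with a sweep rolled back if it
fails to improve the exact log-likelihood — and (b) bounded L-BFGS-B on
transformed model parameters (log for rates and α, logit for p_inv,
log-ratios for frequencies), until the improvement between outer rounds
falls below the tolerance (1e-6 for single fits; 1e-3 when fitting the full
candidate table, where each model is warm-started from its best-fitting
nested neighbour so residual optimisation error is shared across models).

Two numerical choices matter for cross-model comparisons:

* warm starts follow the nesting partial order (each model starts from the
  best already-fitted model nested within it), and a boundary fallback
  adopts a nested model's solution (p_inv = 0, α at its ceiling) whenever
  that solution beats the optimiser's — together these enforce
  log-likelihood monotonicity across nested models to ~1e-6;
* the α ceiling is deliberately huge (1e6): at the +I / +I+G boundary the
  fitted shape diverges, and a low ceiling would break that monotonicity.

Branch-length bounds are [1e-8, 20]; exchangeability bounds [1e-4, 1e4];
p_inv ≤ 0.99.

## Selection criteria

* hLRT: a staged hierarchy of nested pairwise LRTs walked from JC at
  α = 0.01; boundary hypotheses (+I, +G) use the mixed ½χ²₀ + ½χ²₁ null.
  The exact hierarchy of the original ModelTest program is not published in
  reconstructable form, so the hierarchy is data (an ordered list of stages)
  and pluggable.  The default tests: equal frequencies (JC vs F81), ti/tv,
  equal transition rates, then the transversion-rate ladder on the
  unequal-frequency side only (TrN → TIM → GTR), then +G, then +I (last).
  Its equal-frequency branch stops at TrNef, so SYM-like models are
  structurally unreachable — matching the reported behaviour of the default
  hierarchy; an alternative hierarchy that continues TrNef → TIMef → SYM is
  provided, and `HlrtHierarchy.reachable_models()` makes the reachable set
  inspectable rather than asserted.
* AIC = −2lnL + 2K and BIC = −2lnL + K ln n, with K the number of free
  substitution-model parameters (0-10) and n the sequence length; smallest
  score wins, ties broken by fewer parameters then name (ties are logged).
  AIC (not AICc) is the default reported criterion; AICc is available.
* DT: risk R_i = Σ_j ‖B_i − B_j‖₂ · w_j over the models' branch-length
  vectors B on the shared topology, with w the BIC-derived posterior
  weights exp(−ΔBIC/2) (normalised); minimal risk wins.  The norm is
  configurable; Euclidean is the default.

## Performance statistics

Accuracy = matched/tested × 100 per generating model and criterion;
precision = the number of distinct best-fit models across a replicate set;
dissimilarity of a criterion pair = (N − m)/N × 100; the agreement profile
is the percentage of datasets on which the four criteria jointly chose
1/2/3/4 distinct models.  Model-bias tables tabulate recovered models (an
all-selections mode exists) by the four extension categories (df 3) or the
11 free-parameter classes (df 10) and compare criteria by Pearson χ²
homogeneity tests — overall r×k, then pairwise 2×k at the
Bonferroni-corrected level 0.05/6 ≈ 0.0083.  Zero-total columns are pooled
into the adjacent (left) category before testing.  Accuracy and precision
are compared across criteria by a two-way randomized-block ANOVA
(blocks = generating models, treatments = criteria) with LSD pairwise
t-tests on the error mean square; LSD decisions are additionally gated on
the omnibus F at α = 0.01.

## Seeding and reproducibility

One master seed per condition; the guide-tree seed and each dataset's seed
are derived from (master seed, run offset, model index, replicate) through
`numpy.random.SeedSequence`, so any single dataset is reproducible in
isolation and results are independent of processing order.  The third
simulation of the original design (same generating process, different
simulation program) is represented as a second independent seed offset of
the same process.  Identical master seeds give byte-identical selection
tables.

## Problem sizes used for validation

The full design (33,600 datasets × 56 ML fits each) is a cluster-scale
computation, and the original guide-tree realisations are unrecoverable, so
the printed aggregates are reproducible only in distribution.  The test
suite and the acceptance script therefore run a scaled-down profile chosen
as this package's validation standard: all 24 generating models on the
height-0.5, parameter-set-A condition with 10 taxa and 300 sites, 1-2
replicates per model, full 56-candidate fits, plus a codon run at 999 nt
and 1 replicate per model.  At this scale the study's qualitative findings
reproduce: BIC and DT are the most accurate and near-identical, AIC and
especially hLRT trail, hLRT never recovers SYM-like models, and BIC-DT /
hLRT-AIC are the least / most dissimilar pairs.  Monte-Carlo noise at this
scale is several percentage points on any single percentage.

## What the simulations do and do not show

The generator emulates exactly the study conditions: homogeneous,
stationary, time-reversible evolution with at most +I/+G rate
heterogeneity, no indels, no compositional drift across lineages, no
site-pattern correlation.  Real sequence data violate most of these
assumptions, so passing tests demonstrate correctness of the machinery and
reproduction of the study's findings under its own conditions — not that
any criterion is best on real data.  Known limitations: the hLRT hierarchy
is a reconstruction (terminal models on the equal-frequency branch differ
from the original's reported TrN/GTR-like terminals, though the SYM-like
unreachability that drives the headline result is preserved); ANOVA/LSD
p-values depend on the specific random guide trees and are not comparable
realisation-by-realisation; and the codon condition's tree scaling is an
interpretation, as documented above.
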