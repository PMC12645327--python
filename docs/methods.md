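# Methods

`traitphylo` implements Bayesian phylogenetic inference for binary
presence/absence trait matrices — lexical cognate sets, technological
character codings, and similar cultural data — together with the
comparative machinery such studies need: model comparison by marginal
likelihood, consensus summarisation, and cross-phylogeny congruence
statistics. This note records the models, the numerical choices, and what
the synthetic-data experiments do and do not establish.

## The model

**Data.** A matrix of taxa × characters with entries absent (0), present
(1) or missing (`?`). Missing entries are treated as full ambiguity in the
likelihood (a tip partial of ones over both visible states); no
ascertainment correction is applied, since presence/absence codings of
cognate sets and technical traits record absences as data rather than
discarding invariant characters. Characters may carry a *dependency level*
(1–4, where a level-k character presupposes some level-(k−1) character), a
category label, and a positive weight.

**Substitution process.** The binary covarion model: four hidden states,
{absent, present} × {fast, slow}. Within a category the visible state
flips at rates proportional to the stationary visible frequencies
(π₀, π₁) — relative rate 1 in the fast category, α ∈ (0, 1] in the slow —
while the hidden category toggles at a symmetric switch rate s, leaving
hidden categories equally frequent at stationarity. The generator is
normalised so one unit of branch length × clock rate equals one expected
*visible* substitution at stationarity; this keeps clock rates
interpretable and makes node ages identifiable given any absolute-time
calibration. At α = 1 the visible process collapses to the plain two-state
CTMC; at s = 0 the categories decouple; as s → ∞ the process again
approaches a single averaged CTMC. All three limits are verified
numerically in the test suite.

**Clocks.** Strict (one rate) or relaxed: i.i.d. mean-one lognormal
per-branch multipliers with log-sd σ, sampled as explicit MCMC parameters
rather than discretised categories — the discretisation used by some
samplers is an optimisation, not part of the model's meaning. σ is fixed
by configuration (default 0.6 when relaxed); sampling it is not currently
supported.

**Partitioned rates and weights.** Characters may be partitioned (by
dependency level, part of speech, or any labelling); each partition gets a
rate multiplier, renormalised after every proposal to character-weighted
mean 1 so partition effects are separated from the global clock rate. A
character of weight w contributes w × its log-likelihood — exactly the
likelihood of duplicating it w times (the identity is asserted to 1e-12 in
the tests), which is how 8/4/2/1 down-weighting of dependent levels is
implemented.

**Tree prior.** The fossilised birth–death (FBD) process with birth rate
λ, death rate μ, extant sampling fraction ρ and fossil sampling rate ψ;
ψ = 0 recovers the reconstructed birth–death process. Fossils are terminal
tips only; sampled ancestors are not modelled, because dated cultural
fossils (an extinct language attested in manuscripts, an archaeological
loom) enter these analyses as tips. Densities use the standard c₁/c₂
parameterisation of the per-lineage factors q(t) and p₀(t). Two
conditionings are provided:

* **root**: the density of the tree given its root age, each root-child
  subtree conditioned on leaving at least one sample. This is the
  convention for direct density evaluation and matches the pure-birth
  closed form exactly.
* **origin**: the density given the origin (stem start) age, conditioned
  on survival. The MCMC uses this form with the origin as a sampled
  parameter (exponential prior on the origin − root gap), because it
  induces a *proper* distribution over root ages — which is what lets a
  data-free chain be checked against forward simulation (below). The
  critical case λ = μ with ψ = 0 is rejected rather than handled by a
  limit expression.

Calibrations are hard uniform bounds on MRCA ages or (fossil) tip ages, in
years BP with present = 1950 CE; calendar-year (CE) bounds are converted
at configuration load, which swaps the bound order — a silent-error source
the config format makes explicit per calibration. λ, μ, ψ and the clock
and switch rates carry diffuse exponential hyperpriors; π₁ and α are
uniform on (0, 1); partition multipliers derive from i.i.d. Gamma(2)
variables pushed through the mean-one renormalisation.

## Inference

Metropolis–Hastings over tree topology, node ages, origin age, and all
model parameters. Operators: uniform node-age moves within their
parent/children bounds, root-age and whole-tree scale moves,
narrow/wide exchange, subtree-slide (with the junction-counting Hastings
correction for slides that cross nodes), Wilson–Balding (target edges
enumerated on the pruned tree, so the forward and reverse edge counts
coincide), parameter scale moves, prior-draw refresh moves for relaxed-
clock branch multipliers, and uniform redraws of calibrated fossil tip
ages. Proposal scales adapt toward ~25% acceptance during burn-in only
(default 10% of the chain), preserving detailed balance afterwards. The
cached log prior and likelihood are recomputed from scratch every 100
steps and the run aborts on any drift beyond 1e-8.

Two independent checks validate the sampler end to end:

* a data-free chain's root-age distribution matches forward birth–death
  simulation conditioned on origin age and tip count (two-sample KS);
* on a 3-taxon posterior the sampled topology frequencies and root-age
  marginal match dense numerical integration over node ages (total
  variation < 0.05).

The likelihood is Felsenstein pruning over the four covarion states,
vectorised across characters, with the root closed by the stationary
distribution (the model is reversible; root placement is informed only by
the clock and the tree prior). Transition matrices for all branches come
from one eigendecomposition of the unit-rate generator, cached on the
covarion shape parameters. Partials are rescaled every eighth internal
node — sufficient against underflow far beyond the ~100-taxon,
650-character scale this package targets, and much cheaper than per-node
scaling.

**Convergence reporting** uses effective sample sizes from Geyer's
initial-positive-sequence truncation; the pipeline flags traces with
ESS < 200. Age posteriors are summarised by median and 95% HPD (shortest
interval), with MRCA ages taken per tree so monophyly is not assumed.

## Consensus trees

Majority-rule consensus contains exactly the clades at frequency ≥ the
threshold (inclusive — a clade in exactly half the sample is kept at 0.5).
A consensus node's age is the mean MRCA age of its clade *over the trees
containing it*, so consensus trees are generally non-ultrametric; child
ages are clamped to their parent's age when means computed over different
tree subsets invert. Equal-frequency incompatible clades (possible only at
or below 0.5) resolve deterministically toward the lexicographically
smallest tip set. Mean rather than median node heights: the choice is
essentially cosmetic for display trees, and means are exact under the
clade-wise accounting used here.

## Model comparison

Marginal likelihoods by stepping-stone sampling along β values placed at
quantiles of Beta(0.3, 1) (dense near the prior, where the power-posterior
path curves fastest), K = 16 rungs by default, one chain walking the
ladder upward. The estimator's uncertainty is a moving-block bootstrap
over each rung's log-likelihood samples; fully independent replicate
estimation is available but not the default, since the bootstrap tracks
the dominant within-rung Monte-Carlo error at a fraction of the cost. A
flat likelihood yields log ML = 0 up to float accumulation, and on a
one-parameter toy the estimate agrees with dense quadrature within
estimator error (both tested).

The shared-vs-separate phylogeny comparison restricts both matrices to
taxa present in both systems, runs three estimates under identical
settings (merged matrix on one tree; each matrix alone), and reports
log BF = [log ML(a) + log ML(b)] − log ML(merged), positive favouring
separate histories, with the Kass–Raftery bands (1, 3, 5 on the natural
log scale) for wording. The merged scenario keeps one homogeneous rate, so
scenario A is genuinely "one evolutionary history", not two rates glued to
one topology.

## Congruence statistics

Patristic distance matrices come either from consensus trees or from
posterior averages: n trees subsampled without replacement, each
optionally normalised by its own depth so deep samples do not dominate,
pruned to the shared taxa, then averaged element-wise. The Mantel test
reports both the raw cross-product z over unordered pairs (scale-
dependent, but the field's conventional statistic) and the Pearson r over
the same pairs; the permutation null permutes rows and columns of one
matrix simultaneously, one-tailed for positive association, with
p = (1 + #{null ≥ observed}) / (1 + permutations). The default 999
permutations give a p floor of 0.001. Because a permutation leaves the
off-diagonal multiset intact, r is a monotone transform of z under the
null, so testing on z equals testing on r.

PCA of the binary tip data mean-imputes missing entries, column-centres,
and takes the first right singular direction with the sign fixed so the
largest-magnitude loading is positive (making scores reproducible).
Blomberg's K is computed directly from the tree's Brownian tip covariance
— no ultrametricisation, since consensus inputs are non-ultrametric by
construction — as (MSE₀/MSE) divided by its Brownian expectation
(tr V − n/Σ(V⁻¹)) / (n − 1), with the phylogenetic GLS mean. K is affine-
invariant and equals 1 identically on a star tree. Significance over a
posterior sample applies the same tip shuffles across all trees and
compares shuffled mean K to the observed mean. The implementation matches
an independent R implementation (phytools::phylosig) to 1e-9 on a fixed
fixture and averages 1 ± 0.2 under Brownian simulation on 32-tip trees.

## The synthetic-data generator

Forward Gillespie simulation of the birth–death process from a single
origin lineage, rejected until exactly n extant tips survive ρ-sampling
(matching the origin-conditioned density the priors use — the agreement is
itself a test). Fossil tips are drawn from lineage segments whose subtrees
left no sampled extant descendant, truncated at an age uniform in the
configured window. Optionally the root age is rejection-conditioned into a
window, emulating the determinate time depth that fossil and historical
calibrations impose on real datasets.

Characters evolve by exact event-driven simulation of the 4-state covarion
chain, root states from stationarity, hidden categories discarded at the
tips. Level annotations carry level-specific rate multipliers, and a
dependent character is clamped visibly absent at every node where its
parent character is absent (evolution effectively runs only on
parent-present subtrees; when a parent regains presence along a branch the
child restarts from absence). The default trait-system shape — many
independent structural characters, fewer progressively dependent ones,
with higher change rates at higher levels — mirrors the hierarchies seen
in real technical-trait codings.

**Punctuated regime.** With burst fraction f, each branch's evolutionary
duration becomes (1 − f)·Δt plus an Exponential(mean f·Δt) burst drawn
once per branch and shared by all characters. Expected change per branch
is conserved exactly; realised per-branch change becomes overdispersed
(bursts are branch-level events, so characters change together); f = 0
delegates to the gradual simulator and is bit-identical under a shared
seed. This is a deliberately minimal stand-in for change concentrated at
lineage-splitting events; no inference of evolutionary mode is built on
top of it.

## Choice of experimental regime

The recovery experiments run at a covarion rate near the *information
optimum* for binary traits. A binary character's correlation with its
state time t ago decays as exp(−t/(2π₀π₁)) — at equal frequencies, twice
as fast as the substitution rate — so pairwise signal saturates beyond
roughly half an expected substitution of separation. Balancing per-branch
change against saturation loss puts the optimum near rate × tree-depth ≈
0.25, and the reference conditions (pure-birth trees of depth ~2,
rate 0.125, π₁ = 0.5, α = 0.5, s = 0.5) sit there. Rates several-fold
higher leave binary matrices saturated and majority-rule consensus
unresolved no matter how well the sampler mixes — a property of the data
type, not of the implementation.

Clock-rate recovery additionally bounds the root age within ±10% of truth,
standing in for the absolute-time information that fossil tips and
historical calibrations provide: without any calibration only the product
rate × time is identified.

## What the synthetic experiments do and do not show

They establish that the likelihood is exact (against brute-force
enumeration), that the sampler targets its stated posterior (prior-
sampling KS and 3-taxon quadrature checks), that rates, rate ratios, and
topologies are recovered from data generated by the model, that the
congruence statistics are calibrated under their nulls, and that the
Bayes-factor machinery recovers the generating scenario's sign. They do
not address model misspecification in real cultural data — borrowing and
horizontal transfer, non-independence beyond the level hierarchy, coding
inconsistencies across compilers, or rate shifts correlated with
population history. Conclusions about real datasets inherit those caveats
exactly as any model-based analysis does.

## Problem sizes

Default experiment sizes (16–20 taxa, 300–500 characters, chains of
8,000–25,000 steps, 999 permutations, stepping-stone ladders of 8–16
rungs) are desk-scale choices: large enough that every recovery experiment
has clear expected behaviour, small enough to iterate on. All of them are
ordinary function arguments; scaling any experiment up is a matter of
passing bigger numbers.

## Known limitations

* Sampled ancestors are not modelled; a fossil that is literally ancestral
  to sampled taxa will be placed as a zero-or-short-branch sister tip.
* The relaxed clock's log-sd is fixed, not sampled.
* No Metropolis-coupled chains; strongly multimodal posteriors (very
  low-signal data) mix slowly.
* The Mantel and K permutation nulls treat taxa as exchangeable; spatially
  structured similarity (neighbour borrowing) is outside their nulls, and
  partialling out geography is deliberately not implemented.
* Stepping-stone estimates with short per-rung chains are biased toward
  underestimating marginal likelihoods on hard problems; the BF sign
  experiments size their ladders so the bias is small relative to the
  scenario separation, but absolute ML values from short runs should not
  be quoted.
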