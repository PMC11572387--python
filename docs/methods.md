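# Methods

`paleotip` implements a complete analysis chain for dated phylogenetics of
discrete morphological (here: dental) characters with fossil taxa: parsimony
under equal and implied weights, Mkv likelihood, tip-dated Bayesian inference
under the fossilized birth–death (FBD) prior, rogue-taxon pruning,
stratigraphic congruence, and ancestral-state reconstruction. This note
records the models, the numerical choices, and what the synthetic data do and
do not establish.

## Data model

A character matrix is a taxa × characters table of **state sets**. `?` and the
gap symbol map to the full per-character alphabet; `(..)`/`{..}` codings map
to the listed states. All downstream stages treat these sets as uncertainty:
any member state may be realized at no cost. This matches the handling of
polymorphic codings in the standard parsimony and likelihood software for
morphology, and it is the reason polymorphic cells surface as "ambiguous" in
parsimony character mapping. The per-character alphabet is `{0 … max observed
state}` (at least two states), so characters observed with a single state are
retained and enter the CI/RI denominators and the Mkv correction.

Tip ages are uniform intervals `[age_min, age_max]` in Ma; extant taxa carry
`[0, 0]`. First-appearance data (FADs) are interval maxima.

## Parsimony

Tree length uses Hartigan's dynamic program (the polytomy-safe
generalization of Fitch): each internal node keeps the states with the
maximal number of "votes" among its children's sets and pays
`#children − max votes` steps. This scores hard polytomies, which is required
because majority-rule consensus trees are themselves scored (consensus tree
lengths are part of the workflow's outputs).

Ensemble statistics per character: the minimum conceivable steps `m_i` is
computed exactly as (size of the smallest state set hitting every non-missing
cell) − 1, by subset enumeration over the ≤10-state alphabet — with
uncertainty-set cells this is the only definition that guarantees
`m_i ≤ s_i` on every tree. The worst-case steps `g_i` use the classical
unordered-character bound `n_scored − max state frequency`, with polymorphic
cells counted under their most frequent compatible state (ties to the lowest
state). CI = Σm/Σs, RI = (Σg − Σs)/(Σg − Σm). Implied weighting maximizes
Goloboff's total fit `Σ k/(k + h_i)` with `h_i = s_i − m_i`; the default
concavity is k = 12, the value appropriate for matrices of this size under
current recommendations.

Search is random-addition-sequence starting trees improved by
first-improvement SPR, optionally with TBR-style rerooting of the pruned
clade, to a local optimum; all distinct optimal unrooted topologies found
across starts are returned. The production heuristics of dedicated parsimony
programs (sectorial search, ratchet, tree fusing) are intentionally not
replicated: the quantity of interest is the optimum score, and for matrices
of this size multiple random-addition starts with SPR/TBR reach it. Counts
of "most parsimonious trees" are not a stable quantity — they depend on the
zero-length-branch collapse rule — and are not reported as results.
Bootstrap support resamples characters with replacement as integer weights;
each replicate's optimal trees share one vote per split.

## Mk / Mkv likelihood

The Mk model is the k-state symmetric chain scaled to one expected change per
unit branch length; transition probabilities are closed-form. Rate
heterogeneity uses a discrete gamma with 4 equal-probability categories
(category rate = mean of its quantile slice, keeping the mixture mean exactly
1; 4 categories is the default of the Bayesian software this workflow
emulates, which does not report the value). The Mkv ascertainment correction
divides each character's likelihood by P(variable) computed per observed
state count k_c, since the correction depends on k_c; "variable" (not
"parsimony-informative") conditioning is used. Underflow is controlled by
per-node rescaling of partials; the scaled log-likelihood agrees with the
unscaled computation to 1e-8 on small trees, and with full enumeration over
internal states on 4-taxon fixtures to 1e-9.

When every branch has length zero P(variable) = 0 and the conditioned
likelihood is undefined; the function returns NaN to flag the degenerate
case rather than raising mid-MCMC.

## Tip dating

**FBD prior.** The density of a dated sampled tree with speciation λ,
extinction μ, fossil sampling ψ, extant sampling ρ, conditioned on the root
age, is the standard q/p₀ form: the root contributes `q(x₁)²` (the two crown
lineages start at the root age), each further bifurcation `λ·q(xᵢ)`, each
terminal fossil `ψ·p₀(y)/q(y)`, each sampled ancestor `ψ`, and each sampled
extant tip `ρ`. At ψ = 0 this reduces exactly to the constant-rate
birth–death-with-ρ density, which the tests verify against an independently
written closed form. Sampled ancestors are represented as zero-duration
pendant fossil tips. Under the `fossiltip` (noSA) strategy such
configurations simply receive prior mass zero; under `random` they are
reachable through a reversible collapse/expand move on the fossil's
attachment age. Both strategies therefore share one density; the noSA model
is implemented as the restriction of the SA model to SA-free trees rather
than as a separately normalized process, which is adequate because only
density ratios within one strategy enter the MCMC.

**Priors.** Root age: offset-exponential (offset = oldest first appearance,
mean = offset + 8.2 My by default). Tip ages: uniform on their intervals.
Base clock rate: lognormal whose parameters come from a preceding non-clock
run — rate = median non-clock tree length / median of the root-age prior,
mean(log) = ln(rate), sd(log) = exp(rate). With the published inputs
(3.189768, 37.1) this yields 0.085978, −2.45367 and 1.08978. Note that the
operational "root prior median" of 37.1 My used in that published arithmetic
is not the analytic median of offset-exponential(33, mean 41.2), which is
33 + 8.2·ln 2 ≈ 38.68 My; the function takes the median as an explicit
argument so either convention can be reproduced, and the pipeline defaults
to the analytic median for its own derived priors. λ, μ, ψ carry
exponential(rate 10) hyperpriors (weakly informative on the events/lineage/My
scale, positive support); the gamma shape α an exponential(1); the relaxed
clock variance v an exponential(10). All are configurable.

**Clocks.** strict (`B = c·t`), IGR (branch effective lengths independent
Gamma(mean c·t, var v·t), sampled as latent variables), and TK02 (nodal log
rates, child ~ Normal(parent − v·t/2, v·t) so rates are mean-preserving;
branch rate = mean of endpoint rates; root rate pinned at c).

**Sampler.** Single-chain Metropolis–Hastings: uniform node-age slides
between the bracketing ages, a multiplier on the root's age above its older
child, independence tip-age draws within their intervals, multiplier moves
on c, v, α, λ, μ, ψ and the IGR latents, normal jitter on TK02 log rates,
and a constrained narrow-exchange topology move (an exchange is eligible
only if the resulting parent is older than the moved clade; ingroup
monophyly, when set, is enforced by rejection). Metropolis coupling is not
implemented; at the desk scales used here single chains with the default
move mix pass prior-recovery and coverage checks. Moves never act on a
sampled-ancestor attachment except the dedicated collapse/expand pair, which
keeps the mixed discrete/continuous measure coherent. Burn-in 30% and
thinning are configurable and default to the workflow's stated protocol.

Diagnostics: per-parameter effective sample size by the
initial-positive-sequence autocorrelation estimator; parameters with ESS
below 200 are flagged. HPD intervals are the shortest interval containing
95% of sorted draws. The MCC tree is the sampled tree maximizing the product
of clade frequencies, with node ages summarized as the median over matching
clades and annotated with posterior support and age HPDs.

**Marginal likelihoods.** Stepping-stone sampling over powers
β_k = (k/K)^(1/0.3) (quantiles of Beta(0.3, 1)), one chain per power,
with the standard ratio estimator. The estimator is validated against a
conjugate beta-binomial model whose marginal likelihood is available in
closed form. Bayes-factor categories: |2lnBF| ≤ 2 "barely worth
mentioning", ≤ 10 "positive", > 10 "strong".

## Non-clock Bayesian run

A separate sampler over topology, iid exponential(10) branch lengths and α
provides the posterior tree-length sample from which the clock prior is
derived. Its trees are not otherwise used.

## Consensus, rogues, pruning

Majority-rule consensus includes exactly the splits with frequency strictly
above the threshold; splits at exactly 50% are excluded so the consensus is
a function of the sample alone. Rogue detection greedily removes the taxon
whose deletion most increases the consensus information content — the sum
over retained majority splits of the split's phylogenetic information
content (−log₂ of the fraction of binary trees containing it) weighted by
its support — and stops when no single removal helps; the information trace
is asserted non-decreasing on every run. This is one criterion applied to
all tree sets; tools built on other information measures (e.g. RBIC) can
rank marginal cases differently, so rogue lists from mixed tooling are not
expected to match taxon-for-taxon. Pruning removes taxa with degree-2
suppression, merging branch durations and preserving node ages.

## Stratigraphic congruence

Non-clock topologies are dated by the 'basic' rule only (node age = oldest
descendant FAD; an optional minimum branch duration, default 0, pushes
parents up). MIG is the summed ghost-range duration, SRL the summed observed
ranges; RCI = (1 − MIG/SRL)·100, GER = 1 − (MIG − Gmin)/(Gmax − Gmin),
MSM* = Gmin/MIG. Gmin and Gmax are found by exhaustive enumeration of
labeled rooted topologies for ≤ 8 tips and by the closed forms
Gmin = max(FAD) − min(FAD), Gmax = Σ(max(FAD) − FADᵢ) otherwise (the two
routes agree on every enumerable case; the method used is flagged in the
output). Significance: tip ages permuted across tips, p = (1 + #{permuted
fit ≥ observed})/(permutations + 1), 1,000 permutations by default. When all
FADs coincide the gap-ratio indices are undefined; the result is flagged
degenerate with RCI = 100 (MIG = 0 by definition) and NaN for GER/MSM*.

## Ancestral states

Parsimony mapping uses Hartigan down/up passes; a branch carries an
unambiguous change when parent and child final sets are disjoint, an
ambiguous one when the sets differ but overlap. One concrete optimal
resolution is also produced and its change count per character equals the
character's parsimony length on that tree (asserted). Stochastic mapping
fits ER/SYM/ARD by maximum likelihood (L-BFGS-B on log rates; transition
probabilities via eigendecomposition with an expm fallback; uniform root
prior), selects by AIC = 2p − 2lnL with ties to the simpler model, then
samples full histories: node states from their conditional distributions,
branch paths by rejection sampling with the first event forced when the
endpoints differ and a uniformization bridge after 100 failed attempts.
Defaults: 1,000 maps, seeded. A fitted rate below 1e-5/My is flagged as a
boundary (no-change) fit. Synapomorphies of a clade are the changes on its
stem branch; a change is exclusive when its derived state is gained on no
other branch (census over unambiguous plus resolved changes).

## Synthetic data

The simulator produces the generative structure the analyses assume: forward
birth–death from the origin with Poisson(ψ) fossilization and ρ-sampling of
extant tips; the youngest fossil of an otherwise unsampled lineage is its
terminal tip, older fossils are sampled ancestors (kept as zero-length
pendants under `random`, discarded under `fossiltip`, since a noSA analysis
cannot represent them); Mk characters with per-character state counts drawn
from a histogram mirroring a mostly-binary dental matrix (55% binary, 25%
three-state, the rest 4–6 states), gamma rate heterogeneity, strict/IGR/TK02
clocks; constant characters redrawn when Mkv emulation is on; missing cells
(default 25%) and polymorphic cells (default 3%, union with a random other
state); uniform tip-age intervals containing the true age by construction
with half-widths up to 1.5 My (a geological-stage scale). Default FBD rates
(λ = 0.25, μ = 0.15, ψ = 0.25 per lineage per My, ρ = 2/18, origin 40 Ma)
give sampled trees of a few dozen mostly-fossil tips over a Neogene span —
the regime of the target application.

What the synthetic tests show: the estimators recover parameters generated
under their own model (coverage, prior recovery, oracle agreement). What
they do not show: robustness to correlated characters, character-coding
error, non-uniform fossilization through time, or model misspecification of
the clock — none of which the generator emulates.

## Problem sizes and reproducibility

All stochastic steps take explicit seeds and are deterministic given them.
The test suite and the acceptance script run everything at desk scale as the
package's own default study conditions: searches with a handful of
random-addition starts, MCMC runs of a few thousand generations on 7–44
taxa, 100-replicate coverage experiments, 1,000–2,000 stochastic maps.
Production-scale settings (thousands of starts, 10⁷–10⁸ generations,
metropolis-coupled chains) are reachable through the same configuration
surface but are not exercised by the tests.

## Known limitations

* The FBD 'fossiltip' variant is the SA-model restricted to SA-free trees,
  not a renormalized noSA process; marginal likelihood comparisons between
  strategies inherit this choice.
* The topology move set (constrained narrow exchange) is adequate for small
  trees; large-tree mixing would want a dated SPR move.
* Gmin/Gmax closed forms assume the basic time-scaling rule used here.
* The stepping-stone path reuses independent chains per power without
  inter-chain adaptation.
* Single-state characters make CI/RI denominators well-defined but carry no
  grouping information; their ER fits sit at the rate boundary by design.
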