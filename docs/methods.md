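# Methods

This note documents the models implemented in `baromega`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Trait evolution: Mk models on an ordinal 4-state character

The bar count (0–3) evolves as a continuous-time Markov chain on a rooted
bifurcating tree with generator Q. Six constraint schemes are available
(`mk_ancestral.MODEL_GROUPS`): ARD (12 free rates), SYM (6), ER (1), and
"biological" variants that zero every rate between non-consecutive states,
leaving a tridiagonal Q (bioARD 6, bioSYM 3, bioER 1). The biological
models encode the developmental observation that bars are gained and lost
one at a time; a 0→2 change requires passing through 1, which exp(Qt)
permits along a branch even though the instantaneous rate is zero.

Likelihoods use Felsenstein pruning with per-branch `expm(Q t)` (scaling
and squaring via `scipy.linalg.expm`; 4×4 matrices need no scaling
tricks). Models are compared by AIC = 2k − 2 lnL.

**Root prior.** Default is flat (1/4 per state); `stationary` and
`fitzjohn` (likelihood-weighted) are available. The choice matters little
for rate estimates but shifts root-state posteriors; it is surfaced in the
pipeline config rather than hidden.

**Optimization.** Log-rate parameterization, L-BFGS-B, bounds
[1e-8, 1e3], 5 random restarts by default (trait likelihoods over ~dozens
of tips are flat; restarts are cheap insurance). Tie-breaking in model
selection: lowest AIC, then fewer parameters, then lower model id.

## Stochastic maps and branch transition weights

Joint ancestral histories are sampled exactly by backward filtering /
forward sampling: pruning partials up the tree, then the root state from
prior × partial, then each node top-down from
P(child | parent) ∝ P_branch[parent, child] × partial_child. Only node
states are sampled — no within-branch dwell paths — because branches are
classified purely from endpoint states (gain if child > parent, loss if
child < parent, else same). Multiple hits within a branch therefore
collapse to their net effect; a gain followed by an equal loss on the same
branch reads as "same". With the default study settings (tree depth 12,
trait rate ≈ 0.1) double hits on one branch are rare.

Branches are classified per sample and then averaged (not the other way
round), giving per-branch gain/loss/same weights summing to one, and
weight_diff = gain_w − loss_w. 100 maps by default. A discrete G/L
labeling (majority class above a configurable cutoff, default 0.5) exists
only to pick foreground branches for the branch-site test; the weights
themselves are the primary output.

## Codon model and per-branch ω

MG94×HKY: codons change one nucleotide at a time; a step's rate is the
target-nucleotide frequency at the changed position × κ for transitions ×
ω for nonsynonymous changes. Frequencies are F3x4 by default (position-
specific, estimated from the alignment with a +1 pseudocount), F1x4 and
equal available. The generator is reversible with stationary distribution
∝ ∏ position frequencies, which the implementation exploits: symmetrize
with D^{1/2}, `eigh` once per distinct ω, and reconstruct P(t) for every
branch from the spectrum.

**Scaling convention.** When ω varies across branches or site classes, all
generators share a single scaling constant (the stationary rate at a
reference ω) instead of each being normalized to unit rate. This is the
biologically meaningful convention: a branch or site class under relaxed or
positive selection accumulates *more nonsynonymous substitutions at the
same synonymous rate*, rather than re-partitioning a fixed substitution
budget. Per-generator normalization is retained for the single-ω model,
where the two conventions coincide up to the fitted scale.

**Per-branch ω (`fit_branch_omegas`).** One free log ω per branch plus a
global tree-scale, with penalty λ Σ (log ω_b − log ω_parent(b))²; the two
root-child branches are tied to their geometric mean (the root has no
parent branch). λ = 0 gives independent branch ω; λ → ∞ collapses to the
global ω. Default λ = 1. The penalty is the MAP analogue of a Brownian
prior on log ω along the tree; posterior-mean estimation under an actual
Brownian process (MCMC) is out of scope, and the point estimates are
labeled as penalized-ML estimates. κ is profiled once from a global
(single-ω) prefit. Gradients are analytic: inside–outside partials plus
the Daleckii–Krein divided-difference derivative of the matrix exponential
in the reversible eigenbasis; the gradient is verified against central
finite differences in the test suite. Δω_b = ω_b − ω_parent(b).

**Branch-site model A (`fit_branch_site`).** Site classes 0 (ω0 < 1
everywhere), 1 (neutral), 2a/2b (ω2 ≥ 1 on foreground, background as
0/1); class proportions (p0, p1, derived p2a, p2b). The null fixes
ω2 = 1; 2(lnL1 − lnL0) is referred to χ²(df = 1) — the df = 1 reference
rather than the ½:½ boundary mixture, the conventional choice this
pipeline follows; it is conservative at the ω2 = 1 boundary. Three
implementation-level profile steps keep each gene's fit tractable:

* κ profiled once per gene from the global-ω prefit (not re-optimized
  inside H0/H1);
* mixture proportions profiled by an inner EM — the four class weights
  factor into two independent binary mixtures (background vs selected ×
  conserved vs neutral), so the M-step is closed-form;
* an overall rate-scale optimized under the null and held fixed under the
  alternative (freeing it moves lnL1 only marginally upward; holding it
  keeps the LRT on the conservative side while preserving nesting).

Best-of-n-restarts (default 3, jittered starts) per hypothesis; if the
alternative ever lands below the null, it is replaced by the null optimum
(the models are nested). NEB site posteriors are plug-in: class prior ×
class site likelihood at the MLEs, normalized; BEB's integration over
parameter uncertainty is out of scope.

## Association statistic

Per gene and per direction d ∈ {gain, loss}: OLS of Δω_b on x_b = d-weight
of branch b, two-sided t test on the slope with n − 2 df, BH step-up
across genes within each direction. The direction label comes from which
predictor was used, not from the slope sign. Degenerate cases are flagged
rather than guessed at: constant predictor → `untestable` (p = NaN,
excluded from BH's m); an exact fit → `perfect_fit` with p = 0; genes with
fewer than 10 finite Δω branches (configurable) are excluded. Weighted
least squares with the proportions as observation weights is a defensible
alternative reading of "weighted regression"; this implementation uses the
proportions as the independent variable and exposes the choice in one
place (`regress_delta_omega`).

Enrichment is a per-term one-sided hypergeometric (Fisher) test with BH
across terms — no ontology-graph decorrelation; with a DAG-structured
annotation, parent terms will partly duplicate their children's signal.

## Expression rules

TPM_g = (count_g / length_g) / Σ_h (count_h / length_h) × 10⁶ per sample;
columns sum to 10⁶ exactly (all-zero samples are flagged and set to NaN).
"Expressed" in a skin type means TPM strictly greater than 1 in at least 2
of the 3 replicates; the strict inequality matters at the boundary and is
tested. The two per-condition booleans combine into both / white_only /
orange_only / neither. Annotated gene length is used as-is (no effective-
length correction), and the module starts from a count matrix — read
mapping is upstream of this package.

## Synthetic studies

`make_study` draws, from one master seed: a Yule tree rescaled to depth 12
(ultrametric, in arbitrary "time" units sized like the ~12-unit crown age
of the motivating radiation); a Gillespie trait history under bioER Q with
rate 0.12 (chosen to match the empirical transition density of roughly 10
transition branches out of 54, i.e. several independent gains and losses
per history) starting from 3 bars; 200 genes × 200 codons by default at
baseline ω = 0.2, κ = 2, with 0.02 expected substitutions per codon per
time unit. Histories are resampled until they have ≥ 2 tip states, and —
when effect genes are requested — ≥ 2 gain branches, because a history
whose only transition is ambiguous cannot inform the association design
the study exists to exercise.

Effect genes (20% by default) have ω multiplied ×3 on each true gain
branch **with the new level persisting in all descendants** — the Brownian-
ω picture, under which Δω concentrates on the shift branches themselves.
The emitted Δω table is the true parent–child difference plus N(0, 0.1)
noise emulating estimation error; the codon alignments embody the same ω
maps, so both the fast (precomputed-Δω) and the full (codon-ML) paths of
the pipeline can be exercised against the same truth. The generator does
not emulate: indels or alignment error, GC heterogeneity, rate variation
across sites within the background class, polymorphic tip states, or
non-ultrametric trees. Passing tests therefore demonstrate correctness of
the inference chain under its own model assumptions, not robustness to the
misspecifications real data carry.

The expression matrix plants the four expression classes at 80/7/3/10%
with Poisson counts, and the annotation table enriches one term (T01)
among effect genes — enough structure to exercise the classification and
enrichment code against known truth.

## Problem sizes and determinism

Simulation-based checks run at desk scale, chosen so the full suite
completes in minutes on one core: oracle comparisons on ≤ 6-leaf trees;
stochastic-map convergence at 50,000 samples; Mk rate recovery over 100
histories of a 28-leaf tree; association calibration on two 200-gene
studies through the precomputed-Δω path (per-branch codon ML for hundreds
of genes is exercised at reduced scale in the unit tests instead);
branch-site calibration over 200 null genes (12 leaves, 200 codons, one
restart) plus 40 positively selected genes. Null genes for that
calibration are simulated under model A's own H0 — 15% of sites
foreground-relaxed with ω2 = 1 — rather than with a single ω everywhere:
the latter sits at a double boundary (p2 = 0 and ω2 = 1), puts essentially
all LRT mass at zero, and cannot exercise the ω2 constraint the test is
about. Even under the proper H0 the χ²(1) reference is conservative
(realized type-I error around 2–3% at α = 0.05), the familiar boundary
effect of this LRT. All samplers take explicit
seeds; `make_study` is byte-reproducible from its master seed, and child
seeds are drawn below 2³¹.

## Known limitations

* Δω point estimates, not posteriors; the smoothing λ is fixed, not
  estimated (no marginal-likelihood calibration of the Brownian variance).
* The branch-site κ/scale profiling slightly under-fits both hypotheses;
  with very short foreground branches the LRT is conservative.
* Endpoint-only stochastic maps cannot count multiple hits per branch.
* The association regression treats branches as independent observations;
  phylogenetic autocorrelation of Δω is absorbed into residual noise.
* Classic Fisher enrichment ignores the annotation graph structure.
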