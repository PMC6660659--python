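# Methods

## Model

Let O₁…O_T be the 96-channel categories of one chromosome's somatic
single-base substitutions, ordered by position. Two hidden variables attach to
each mutation: the signature Q_t ∈ {1…K} that emitted it and a binary
generator indicator I_t, where I_t = 0 means *chain* generation (an HMM step)
and I_t = 1 means *mixture* generation (an independent draw). The joint law
factorizes as

    Pr(O, Q, I) = Pr(Q₁) Pr(I₁)
                  ∏_{t≥2} Pr(Q_t | Q_{t−1}, I_{t−1}, I_t) Pr(I_t | I_{t−1})
                  ∏_t Pr(O_t | Q_t)

with Pr(Q₁ = j) = π_j, Pr(I₁) = ρ, Pr(I_t | I_{t−1}) = B (2×2),
Pr(O_t | Q_t = k) = E_k,O_t, and

    Pr(Q_t = j | Q_{t−1} = i, I_{t−1} = f, I_t = g) = A_ij  if f = g = 0,
                                                     π_j   otherwise.

The signature-transition CPD conditions on *both* flanking indicators. This
is the reading under which mixture-generated mutations are fully independent
draws from π and chain runs may be interspersed with mixture draws; it keeps
the free-parameter count at (K−1) + K(K−1) + 2 + 1 = K² + 2 (146 for K = 12).
The emission matrix E is a fixed input (e.g. a COSMIC v2 subset), never
learned; zero entries are floored at 1e-10 and rows renormalized so log-space
recursions stay finite.

**Spatial clamping.** The genome is partitioned at a distance threshold
(default 2000 bp): a mutation whose flanking mutations on the same chromosome
(if any) are *more than* the threshold away is sky; otherwise it is in a
cloud, and clouds are the maximal runs with consecutive gaps ≤ threshold
(each has ≥ 2 members by construction; the boundary gap equal to the
threshold joins). At sky positions the indicator is clamped to 1; at cloud
positions it is free. The likelihood is the sum of the joint law over all
admissible (Q, I) paths. Indicator-chain factors at clamped positions are
retained (they depend only on B and ρ), which keeps likelihoods of
parameterized variants directly comparable on identical partitions.

**Category-predictive score.** Because the clamped likelihood carries the
indicator-chain mass, it is not commensurable with the plain mixture model's
likelihood of the categories. For cross-family comparisons the package also
exposes a conditional score,

    conditional_loglik = log Σ_{I adm} Pr(O, I) − log Σ_{I adm} Pr(I),

i.e. log Pr(O | I admissible), computed by a 2-state indicator-only forward
pass. Within-family comparisons (full vs constrained variants) may use either
score: the subtracted term is identical.

## Training and decoding

Parameters (π, A, B, ρ) are learned per sample by Baum-Welch EM over the
2K joint states (k, f), pooling expected counts across the sample's
chromosome sequences; ρ applies at every chromosome start. Updates are the
standard expected-count ratios with these conventions:

* π counts pool every position where the signature was drawn from π: both
  initial positions and every transition whose flanking indicators are not
  both chain.
* A counts come only from the chain→chain block; a row with no expected mass
  keeps its previous value. A sample with no cloud mutations leaves A at its
  initialization entirely (warned — there is no evidence).
* B and ρ are re-estimated inside EM by default; clamped positions contribute
  their (observed) indicator transitions. `update_B=False` freezes both at
  the direct estimate from the observed sky/cloud run structure (smoothed
  label-transition counts), since it is not obvious a priori which mode one
  wants; both are exposed.
* Initialization: π and rows of A are symmetric Dirichlet(1) draws; B and ρ
  start from the observed sky/cloud layout. Restart seeds are spawned from
  the root seed by counter, so runs are bit-reproducible; the best restart by
  final training log-likelihood is kept (default 10 restarts, configurable to
  31 for robustness studies, where majority assignments are available).
* Stopping: relative log-likelihood change < 1e-6 (configurable) or 1000
  iterations, with a convergence flag and warning.

Decoding is Viterbi over the same clamped lattice. Ties are broken toward the
lower signature index, then toward the mixture indicator, applied to both the
terminal state and every backpointer — deterministic and documented. The
*sequence-dependent fraction* is the share of cloud mutations whose decoded
indicator is chain.

**Variants.** `single` clamps A to the identity (a chain run keeps one
signature); `restricted` limits chain states to a named signature set
(mixture states unrestricted). Both are enforced as state-space masks plus
fixed/blocked M-step updates, so fitting and decoding honour them exactly.

**Numerics.** All recursions run in log space; each forward/backward step
shifts by the running maximum and performs the matrix product in scaled
linear space (an exact log-sum-exp), and pairwise posteriors accumulate in
chunked log-space blocks. The exhaustive-enumeration oracle
(`brute_force_loglik` / `brute_force_decode`) evaluates every admissible
path directly from the factorization and refuses instances beyond a
4×10⁶-path budget; forward agrees with it to ~1e-15 relative on random small
instances. Degenerate inputs: empty sequences contribute zero log-likelihood;
a sample with no mutations is a validation error; duplicate positions within
a (sample, chromosome) keep the first record with a logged warning.

## Model selection

The distance threshold is chosen by leave-one-chromosome-out
cross-validation: per threshold, fold and restart, the model is trained on
the remaining chromosomes and scored on the held-out one; per-restart
fold-sums are summarized by their median across restarts. The init seed is
shared across folds of a restart, so identical chromosomes score identically
and fold × restart units can run serially or concurrently (joblib) with
identical results.

A caveat this package makes explicit: on data generated by the model itself,
the held-out score (full or conditional) is empirically monotone
non-decreasing in the threshold — enlarging clouds only relaxes clamps, and a
truly-independent mutation absorbed into a cloud costs nothing, because
neither the model nor the generator carries any distance-decay of dependency
within clouds. Threshold selection on such data is therefore upward-biased,
and the test suite asserts the resolvable property instead: thresholds below
the generating one sharply lose held-out score, and the chosen threshold is
at least the generating one. An interior optimum is expected only for data
whose dependency genuinely decays with distance.

## Synthetic cohorts

The simulator draws the genomic layout per chromosome — isolated sky
mutations and clouds interleaved uniformly, cloud sizes 2 + Geometric with
mean 2.33 by default, intra-cloud gaps uniform on [1, threshold], inter-unit
gaps uniform on (threshold, 200 kb] — so re-partitioning recovers the planted
labels exactly. Hidden chains follow ρ/B with the indicator forced to
mixture at sky positions, signatures follow the transition CPD, and
categories are emitted from E. Presets: `tiny` (demo), `small` (10 samples ×
~2,000 mutations, cloud-enriched so chain parameters are well conditioned)
and `wgs-like` (≈8% of mutations in clouds with mean cloud size ≈2.33,
echoing whole-genome cohort geometry at reduced scale). Default planted
parameters use a mildly skewed π, strong self-transition persistence
(diagonal 0.9) and a persistent indicator chain (B₀₀ = 0.9, B₁₀ = 0.7) —
processes within clustered regions persist, the regime that motivates the
model. Signature matrices are synthetic block-concentrated distributions
(`synthetic_signatures`, separation = share of mass on the signature's own
block, default 0.9); they are stand-ins constructed for testing, not derived
from any published catalogue.

What the generator does **not** emulate: real genomic sequence context (the
96-channel composition of real genomes), strand asymmetry, mappability,
distance-dependent decay of dependency within clouds, or inter-sample
heterogeneity of layout. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions, not
performance on real tumours.

## Identifiability and known biases

Two structural effects, established empirically with the simulator and worth
knowing before interpreting output:

* **Chain/mixture reattribution.** A signature switch inside a chain run can
  always be re-explained as a mixture interruption (exit, independent draw,
  re-entry). The two explanations are close in likelihood, so the MLE drifts
  toward a more diagonal A and fewer decoded chain states than the generator
  used. Consequently the Viterbi sequence-dependent fraction is a
  *conservative* estimate (undershooting a forced-clamp generator's planted
  fraction by ~0.05–0.1 even with near-deterministic emissions), and fitted
  A is reliably recovered only when the planted transitions are strongly
  diagonal or otherwise structured (e.g. preferred partner signatures) —
  the regimes the recovery tests use. Decoding at the generating parameters
  recovers the planted fraction within ±0.01.
* **Clamping vs generation of B.** The generator forces the indicator at sky
  positions while the likelihood retains B factors there, so fitted B
  reflects the observed (forced) indicator process, not the planted B. π and
  A are unaffected by this particular mismatch; B should be read as a
  descriptive segment-length parameter.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data sized
for a single CPU: oracle checks on 200 instances with T ≤ 7, parameter
recovery on one sample with ≈5,000 cloud mutations, model comparison on a
≈1,600-mutation sample pooled over four leave-one-chromosome-out folds, and
restart robustness with 31 independent fits of a ≈650-mutation sample. These
sizes were chosen so each statistical check has comfortable margin relative
to its sampling noise while the whole suite completes in about a minute.

## Limitations

Single-base substitutions only (no indels or doublets); no strand-bias
channels; signatures are refit, never discovered; one model per sample (no
joint cohort training, no priors); no external annotations (expression,
replication timing, CpG islands) — transition enrichment and exposures are
computed purely from the decoded assignments.
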