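# Methods

## Scope and data model

The package models spatial gene expression along a single one-dimensional
axis (fraction of the anterior-posterior axis, in [0, 1]). All profiles —
TF concentrations, target expression, predictions — are relative levels on
one shared grid; the default synthetic grid has 100 uniform bins. Profiles
read from TSV accept either fractional or percent coordinates. Sequence
coordinates are 0-based half-open everywhere, including BED output; 1-based
coordinates appear only in human-readable logs.

## Enhancer-level thermodynamics

Sites are annotated by scanning both strands with log-likelihood-ratio PWM
scores (Stormo-style); a site is kept when its relative affinity
`exp(llr − llr_max)` reaches a configurable floor, default 0.01. The floor is
deliberately permissive — weak sites matter in occupancy models — while
bounding ensemble size. Windows containing N are unscored. PWMs read from
count matrices get a pseudocount (default 0.5) and a uniform background,
both configurable.

The ensemble sums run over all non-overlapping subsets of annotated sites.
Concrete functional forms fixed by this package:

* Site statistical weight `q = K_tf · [TF](x) · rel_affinity`. Only the
  product is identifiable: scaling all concentrations by c and all K by 1/c
  leaves every prediction unchanged (asserted by a test), so concentrations
  are treated as relative.
* Homotypic cooperativity: a factor ω_tf for each *adjacently bound*
  same-TF pair separated by at most `coop_dist` (default 50 bp,
  edge-to-edge). Adjacent means consecutive in the bound configuration.
* DIRECT mode: `Q(σ) = ∏ α_tf` over bound sites; activators are constrained
  to α ≥ 1, repressors to α ≤ 1 at construction.
* SRR mode: repressors carry no direct α; instead, for each adjacently
  bound activator–repressor pair within `srr_range` (default 150 bp, the
  upper end of the reported short-range window) the activator's coupling is
  scaled by `(1 + (α − 1)(1 − β)) / α` per neighbouring repressor, i.e.
  full quenching (β = 1) neutralises the activator (contribution 1), β = 0
  leaves it untouched. Restricting quenching to adjacent bound pairs gives
  cooperativity and quenching one shared pair structure, which both the
  linear-time dynamic program and the brute-force oracle implement from the
  same definition. This functional form is this package's definitional
  choice; the test suite pins the DP to exhaustive enumeration at relative
  1e-9 across randomised ensembles in both modes.
* Expression is the BTM occupancy `E = Z_on/(Z_off + Z_on)` with the empty
  configuration contributing W = Q = 1 and `q_btm` the global BTM weight.

Numerical safety: the off/on recursions are rescaled jointly by a tracked
power of two whenever intermediate sums approach overflow, so the occupancy
ratio is exact at any site count (several hundred strong sites are exercised
in the tests). Joint rescaling was chosen over log-space recursions because
the two sums must stay on one scale for the ratio.

## w-PGP

For prediction p and real profile r on one grid, both in [0, 1]:

    reward  = Σ min(p_i, r_i)·r_i / Σ r_i²
    penalty = Σ max(p_i − r_i, 0)·(1 − r_i) / Σ (1 − r_i)²
    score   = clamp(reward − penalty, 0, 1)

Degenerate denominators: an all-zero real profile defines reward 1 for an
all-zero prediction and 0 otherwise; an all-one real profile defines
penalty 0. Combining reward and penalty by clamped subtraction (rather than
a ratio) is a definitional choice of this package, used consistently as the
objective everywhere. RMSE is available as a diagnostic only, never an
objective.

## Two-tiered locus training

* Stripes are maximal runs of bins with expression ≥ 0.5 (a bin exactly at
  the threshold is ON), ordered anterior to posterior.
* Phase 1 enumerates windows starting every 100 bp with lengths 500–2500 bp
  in 50 bp steps (the 50 bp step matches the architecture-sampling grid) and
  ranks them per stripe by the w-PGP of their readout against the stripe
  profile. Windows with identical site content are one candidate — the
  shortest, then leftmost, representative is kept; this both deduplicates
  the pools and prevents site-free flanks from padding winners. An optional
  BED accessibility mask excludes windows covered less than 50% by
  accessible intervals.
* Phase 2 processes stripes anterior to posterior. The running target for
  stripe i is the real profile with *later* stripes erased; inter-stripe
  valleys keep their real sub-threshold values. (Zeroing the valleys
  instead was found to reward suppressing expression below the real basal
  level, systematically selecting windows padded with 1–2 kb of repressive
  flanking sequence.) Because the target grows with i, the carried-over
  model's score is re-baselined against each new target before candidates
  are compared. A candidate is admitted only when the re-optimised fit
  improves the running best by more than δ (default 1e-4); requiring bare
  strict improvement instead admits near-duplicate windows through
  optimizer-noise-level gains from the extra degree of freedom. Candidates
  within δ of the best are treated as tied and resolved by parsimony
  (shortest window). Weight re-optimisation warm-starts from the previous
  weights plus a nonnegative-least-squares seed.
* Window weights are nonnegative and unbounded above; the aggregate is
  clipped to [0, 1] before scoring.
* After the stripe loop the weights are re-fitted once against the full
  gene profile (identical to the final stripe target except for bins beyond
  the last stripe) and that score is the model's score.
* The outer loop re-fits θ with windows and weights fixed, constrained to a
  two-fold box around the *initial* (panel-pretrained) values — not around
  the current iterate, so repeated re-fits cannot drift arbitrarily — and
  returns to Phase 1, for `outer_iters` iterations (default 100; the
  recovery studies use 5) or until the best score improves by less than δ.
  The best model seen is returned with its per-iteration score log.
* Control experiments use unconstrained estimation: the package's wide
  a-priori ranges (K ∈ [1e-2, 1e2], activator α ∈ [1, 1e2], repressor
  α ∈ [1e-3, 1], ω ∈ [1, 20], q_btm ∈ [1e-4, 10]).

All fitting uses alternating Nelder–Mead simplex and bounded L-BFGS-B (the
w-PGP objective is piecewise smooth, so a derivative-free pass is alternated
with quasi-Newton refinement), with seeded random restarts for the
enhancer-panel fit (default 5). Objective tolerance 1e-6. All runs are
deterministic given the seed.

## Architecture sampling

The MCMC state is an extended weight vector over the full window grid. A
move picks two distinct grid bits and toggles each with probability 1/2
(unchanged w.p. 1/4, Hamming-1 w.p. 1/2, Hamming-2 w.p. 1/4, uniform within
a distance class); weights over the proposed active set are drawn from a
flat Dirichlet (a Dirichlet with zero shape entries is improper, so
inactive windows carry exactly zero weight and Dir(1, …, 1) is drawn over
the active bits only); acceptance is min(1, score_new/score_old). The empty
architecture's score is floored at ε = 1e-6 to keep ratios finite. Under
this kernel the stationary bit-vector marginal is proportional to the mean
score under flat Dirichlet weights, which the test suite verifies on an
enumerable 3-window space by quadrature (total variation < 0.05 at 50k
samples).

## Knockdown network

A knockdown zeroes one TF's concentration everywhere and re-runs (never
re-fits) the trained model. Per stripe, the level change is the relative
(%) change of the prediction at the stripe's baseline peak bin; boundaries
are the half-maximum crossings on each flank, measured at half of each
profile's own stripe peak, interpolated linearly. Weakening ≥ 2% ⇒
activation edge; strengthening ≥ 2% and/or a boundary shift ≥ 1% of the
axis ⇒ repression edge. Percentages are relative (a documented choice),
and each edge records both evidence values. Stripes with zero predicted
peak are skipped with a warning.

## Cross-talk hypergraph

For every ordered pair of selected enhancers and every contiguous block of
1–5 donor sites, a new model is optimised in which the acceptor enhancer's
site set is augmented by the block: window weights are re-fitted and θ is
re-fitted within its two-fold box (full Phase-1 rescans are not repeated —
windows are fixed — for tractability). The hyperedge weight is the new
score minus the original; negative weights mark avoided interactions.
Within-enhancer hyperedges have weight zero by definition and are not
enumerated. The graph mapping averages hyperedge weights per (donor site,
acceptor enhancer) pair, giving the matrix its column-block structure; the
raw matrix is exported without any significance cutoff.

## Synthetic data

The generator emulates blastoderm-style inputs: one locus, sharp motifs, TF
gradients on the axis, and a striped target produced by the package's own
forward model so recovery is scorable against known truth.

Standard conditions (fixed defaults): 8 kb locus, i.i.d. uniform base
composition; three non-overlapping planted enhancers of 1 kb at 1000, 3500
and 6000 bp, one per stripe; 100 axis bins; four TFs = one activator with a
broad Gaussian dome (σ = 0.35, peak 1 at mid-axis) plus one repressor per
stripe whose profile is a *clearing* — high everywhere except a band
(half-width 0.07, logistic edges of scale 0.02) centred on its stripe, i.e.
the composition of one falling and one rising logistic gradient; motifs of
length 8 with 0.85 consensus probability per column, consensus words
rejection-sampled to pairwise Hamming distance ≥ 3 (incl. reverse
complements); 5 activator + 6 repressor consensus sites per enhancer at
jittered non-overlapping offsets and random strands; ground-truth
parameters K_act = 2, α_act = 5, K_rep = 3, α_rep = 0.01, ω = 1 (homotypic
cooperativity disabled in the generator's truth), q_btm = 0.02, DIRECT
mode; unit true weights. Off-target repressor sites of affinity ≥ 0.2
arising by chance inside a planted enhancer are scrubbed (one background
base redrawn), since they would silence the enhancer inside its own cleared
band and break the generator's contract that each planted enhancer drives
its stripe. Monotone-gradient and bump profile shapes are also available
per TF.

Under these conditions stripes arise from a broad activator gated by
repressive borders — a stripe cannot be produced by activator sites alone —
which is what gives the negative controls their bite. What the generator
does *not* emulate: overlapping real gap-gene domains (each stripe has a
dedicated clearing repressor), heterotypic cooperativity, non-uniform base
composition, accessibility structure, or expression noise; passing the
recovery tests therefore demonstrates correctness of the machinery on a
realisable forward model, not performance on real embryo data.

Initial θ for locus fits is the truth perturbed by seeded log-uniform
factors within 1.4-fold — the generator's stand-in for pre-training on an
external enhancer panel, whose two-fold constrained box then brackets the
truth, mirroring the constrained-estimation strategy's assumption.

Random expression controls follow the stripe-count/ON-budget construction:
stripe count uniform between half the real count and the real count, stripe
and gap widths drawn as uniform compositions (stars and bars, interior gaps
≥ 1 bin, terminal gaps may be empty), ON-bin count preserved exactly before
smoothing. The logistic edge smoothing uses steepness 100 per axis fraction
(10–90% over ≈ 0.04 axis), chosen so smoothed flanks resemble real stripe
flanks at the default 100-bin grid without materially altering ON counts.
Random sequences preserve locus length and base composition. Site-relocation
controls redraw every site's position uniformly, conserving the affinity
multiset. All control fits are unconstrained.

## Problem sizes used by the test suite

The recovery study runs ten seeded standard loci at `outer_iters = 5`
(each fit ≈ 5–20 s); the negative-control study compares twenty control
fits (ten site-relocation, ten random-sequence) against the seed-1 real
fit; oracle equivalence uses 200 randomised ensembles of ≤ 12 sites; the
MCMC checks use 10k proposals and 50k samples on an enumerable 3-window
space. These sizes are the package's chosen desk-scale operating point.

## Known limitations

* The SRR quenching form and the w-PGP normalisations are definitional
  choices of this package (documented above), not claims about other
  implementations.
* Overlapping selected windows share no credit correction; the aggregate
  simply sums them (and near-duplicate windows separated by more than δ in
  score can both be admitted).
* The knockdown network inherits the trained model's biases; edges are
  relative to the model, not causal statements about the data generator.
* Heterotypic cooperativity, TF competition beyond overlap exclusion, and
  distance-dependent activation decay are out of scope.
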