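# Methods

## Transform realization

The tunable-Q wavelet transform is implemented as an iterated
two-channel filter bank applied directly in the DFT domain on
full-length spectra (no radix-2 restriction).  Per level, a parent
signal of even length *N* splits into a low-pass branch of length
`N0 = 2·round(αN/2)` and a high-pass branch of length
`N1 = 2·round(βN/2)`; spectra use unitary normalization, the high-pass
branch maps input band [(1−β)π, π] onto [0, π] of its output, and the
two responses overlap on the transition band ((1−β)π, απ) where the
gains follow θ(ω) = ½(1+cos ω)√(2−cos ω), giving |H₀|² + |H₁|² = 1
pointwise.  Consequences, verified by the test suite: exact
perfect reconstruction (relative round-trip MSE ≈ 1e-29 at M = 2000,
including ~200-level decompositions) and energy conservation to ≈ 1e-15.

Edge cases are deterministic rather than silent: odd-length inputs are
rejected (epoching guarantees even length); at very short parent
lengths, where rounding could stall the cascade or close the transition
band, the rule clamps the low-pass length to N−2 and widens the
high-pass to keep at least one transition bin — replayed identically by
the inverse, so reconstruction stays exact.  The maximum depth
`Lmax = floor(log(M/(4(Q+1)))/log(1/α))` remains the analytic formula.

## Tuning and the flat fitness surface

The tuner minimizes the mean squared reconstruction residual of a
full-depth decomposition.  Because the bank is a Parseval frame, this
fitness is at floating-point round-off (~1e-29) for every valid (Q, r):
the surface is flat, and the minimizer is decided by the parsimony
tie-break — smallest Q, then smallest r, among all candidates within
1e-12 of the best — which with the default box (Q ∈ [1, 10],
r ∈ [3, 10]; r ≥ 3 keeps the wavelet well localized in time) always
returns the seeded start (1, 3).  The nominal start (Q, r) = (1, 1) is
clamped into the box because r = 1 gives a degenerate transition band.
This behavior is intentional: the machinery is exact, and any future
fitness with a non-trivial landscape (e.g. sparsity or partial
reconstruction) plugs into the same optimizers.

Optimizer defaults: PSO uses the standard constriction form
(Y = 0.729, a1 = a2 = 2.05) with per-component uniform random factors;
ABC uses one-coordinate neighborhood moves with κ ~ U(−1, 1),
roulette onlookers via h = 1/(1+f) (f ≥ 0) and abandonment limit
`n_agents × dims`; cuckoo search uses Mantegna Lévy steps (stability
index 1.5) scaled by 0.01·(x − best) with step size δ = 1, plus a
discovery phase in which each nest component is, with probability
pa = 0.25, moved along a biased random walk between two random nests
and accepted greedily.  The per-component discovery variant was chosen
over replacing a worst-fraction of nests because it converges an order
of magnitude further at the 50×200 budget (5e-9 vs 8e-8 on the 2-D
sphere) while keeping the best nest elitist.  All three optimizers are
driven by a single seeded generator and are bit-reproducible.

Convergence checks: at the full budget (50 agents × 200 iterations)
each optimizer reaches < 1e-6 on the 2-D sphere for every tested seed;
the reduced-budget property test uses 10 agents × 100 iterations and
requires the argmin of a unimodal quadratic within 0.1 (∞-norm) for
≥ 9/10 seeds — a budget at which all three algorithms pass with margin
(measured worst cases: PSO 4e-5, ABC 5e-12, CS 3e-2).

The uniform depth L_opt is the floor of the class-balanced mean of
per-signal Lmax values: per-class means averaged with equal weight, so
unequal class sizes do not bias the depth.

## Features

- **Hurst exponent**: the printed single-ratio definition E[r(J)/σ(J)]
  does not by itself yield a dimensionless exponent, so the estimator
  is the classical rescaled-range regression: R/S averaged over blocks
  at dyadic window sizes 16 … J/2, HE = slope of log R/S vs log window.
  Sanity bands (white noise ∈ [0.4, 0.6], random walk ∈ [0.85, 1.05] at
  J = 4096) are enforced in the suite.
- **MAV1** uses 1-based indices with *inclusive* bounds: weight 1 for
  0.25J ≤ j ≤ 0.75J, else 0.5.
- **LEE** is read literally as −Σ (log₂ p_j)² over the *energy*
  distribution p_j = y_j²/Σy² with zero-energy terms dropped (the
  alternative Σ log y_j² reading was considered and not used; the
  energy normalization makes the statistic translation-sensitive but
  bounded and scale-free).
- **Variance** uses divisor J (population form).
- Degenerate subbands (all-zero, constant, or too short for the R/S
  regression — deep subbands shrink to ~10 samples) are imputed as 0
  with a logged warning so the feature table stays rectangular.

## Channel selection

Per channel, the similarity graph is dense (all epoch pairs), with
heat-kernel bandwidth t defaulting to the mean squared pairwise
distance of that channel's points — scale-adaptive and parameter-free.
The graph Laplacian uses the positive-semidefinite sign L = D − S, so
all scores are non-negative.  Feature columns are z-scored per channel
before the graph is built: the log-energy entropy is ~1e5 times larger
than the other statistics and would otherwise own the distance metric
entirely, hiding class structure from the graph.  (The score itself is
homogeneous of degree 0 in each feature, so standardization changes
only the geometry, not the scoring rule.)

Two voting directions are supported.  A feature aligned with cluster
structure has a *small* score (its large between-cluster differences
coincide with small similarities), so `direction="lowest"` — the
classical locality-preserving choice and the pipeline default —
isolates the channel whose features carry class structure;
`direction="highest"` is the convention that matches published score
tables built with the negated Laplacian S − D, where the same channel
surfaces at the top.  Both are one flag apart; on the synthetic study
conditions the "lowest" vote recovers the informative channel in
10/10 seeded generations.

Kruskal–Wallis screening reports raw p-values with the chi-square
(1 df) approximation and flags p < 0.05; no multiple-testing correction
is applied, matching common practice in this literature.  All
observations tied degenerates to (H, p) = (0, 1) instead of a NaN.

## LS-SVM

Training solves the classical label-weighted KKT system
(Gram entries z_i z_j K(x_i, x_j) + γ⁻¹ on the diagonal, constraint row
Σ a_i z_i = 0) by a dense direct solve; the residual of the system is
checked to < 1e-8 in the suite.  Wavelet kernels (Mexican hat, Morlet)
are products of per-coordinate mother-wavelet factors and equal 1 at
u = v.  Defaults — γ = 10, σ = 1 after per-feature standardization,
degree 3, scale 1, ω₀ = 5 — are reproducible choices, not tuned values.
Standardization statistics come from training folds only and are
applied to test folds; a poisoning test verifies that altering held-out
rows leaves the fold's trained coefficients bit-identical.  A zero
decision value maps to the positive class (documented, measure-zero).
Fold confusion matrices are pooled before the metric panel; AUC uses
the midrank Mann–Whitney formulation and equals trapezoidal integration
of the swept ROC.

## Synthetic data

The generator emulates the structure the pipeline needs to be tested
against: 2000-sample epochs at 100 Hz, two balanced classes, 1/f
background noise, mu (10 Hz) and beta (20 Hz) sinusoids with uniform
random phase and a Hann-smoothed random-walk envelope (±30% slow
amplitude modulation, mean 1 — real sensorimotor rhythms wax and wane).
Exactly one channel is informative: class-2 epochs scale its rhythm
amplitude by √ratio so band power scales by the ratio exactly in
expectation.  Default study conditions: 4 channels, 30 epochs/class,
power ratio 2.5, 0 dB rhythm-to-noise.  Not emulated: volume
conduction (channels are independent), artifacts, inter-subject
variability.  Passing tests therefore demonstrate the pipeline's
mechanics — recovery of a known contrast under realistic noise — not
performance on real recordings.

## Problem sizes and numerical choices

The default suite exercises reconstruction on 200 signals × a 5×5
(Q, r) grid at M = 2000 (full analytic depth per cell), optimizer
convergence at 50 agents × 200 iterations, and the full pipeline at the
default study conditions — sizes chosen so the whole suite completes in
a couple of minutes on one core.  Tie tolerance for tuning is 1e-12;
reconstruction assertions use 1e-18 (relative MSE) and 1e-10 (energy),
both orders of magnitude above the measured errors.  0/0 metric cells
are defined as 0 with a warning.  All randomness flows from explicit
integer seeds through `numpy.random.default_rng`.

## Known limitations

- Tuning on a perfect-reconstruction fitness always returns the
  parsimony point; the metaheuristics only matter once a non-flat
  fitness is supplied.
- The Laplacian "highest" vote is kept for compatibility with published
  score tables but does not recover informative channels on data where
  the score semantics are the classical ones; use "lowest" (default in
  the pipeline).
- EDF files can be read (via mne) but not written; the native epoch
  container is npz + JSON manifest.
- Binary classification only; no probabilistic outputs or multiclass
  extension.
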