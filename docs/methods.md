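# Methods

## Model

The surrogate is a three-layer RBF regression network mapping the normalized
input vector x = (π, PPFD, T) to normalized Pn. Hidden unit i responds with
the Gaussian basis Φ_i(x) = exp(−‖x − c_i‖² / (2σ_i²)); the output is the
linear combination Φω. Training has three stages:

1. **Centers.** Lloyd's k-means on the training inputs: initial centers are
   h distinct sample rows, assignment is by minimum Euclidean distance (ties
   to the lowest center index), centers update to cluster means until no
   center moves more than `kmeans_tol` (default 1e−8) or `kmeans_max_iter`
   (100) is reached. Empty clusters are re-seeded from the sample farthest
   from its assigned center. By default the hidden count equals the training
   sample count, in which case clustering is a fixed point and is skipped:
   every sample is its own prototype and the network interpolates.
2. **Widths.** Either σ_i = spread for all units (`spread_mode="width"`,
   the default — this is the scalar the optimizers search), or
   σ_i = spread · c_max/√(2h) (`spread_mode="scale"`), where c_max is the
   maximum pairwise center distance; `spread="auto"` uses the bare
   self-organizing rule c_max/√(2h). The "width" reading is the default
   because a single scalar spread is what the sensitivity sweep and the
   optimizers operate on; the "scale" mode preserves the self-organizing
   rule for users who want the spread to act multiplicatively.
3. **Weights.** ω = argmin ‖Φω − y‖² + ridge‖ω‖². With ridge = 0 the solve
   is SVD-based (`lstsq`), tolerating rank deficiency with a minimum-norm
   solution; with ridge > 0 (default 1e−10, for conditioning at large
   spreads) the regularized normal equations are solved by Cholesky. There
   is no output bias by default; far from all prototypes the prediction
   decays to the denormalized zero of the target scale. An optional bias
   flag appends a constant column.

The GRNN baseline is a Nadaraya–Watson kernel regressor: ŷ(x) =
Σ y_i K_i / Σ K_i with K_i = exp(−‖x − x_i‖²/(2σ²)) on normalized inputs.
Exponents are max-shifted before exponentiation, so the kernel weights
remain a valid probability vector at any σ and the prediction is always a
convex combination of stored targets.

## Spread selection

The quantum genetic algorithm encodes a candidate spread as m = 20 qubits,
each an amplitude pair (α_i, β_i) initialized to (1/√2, 1/√2) so all 2^m
basis states are equally likely. Per generation, each chromosome is measured
(bit = 1 when a uniform draw exceeds α_i²), the bitstring is decoded MSB
first onto the uniform grid lo + k/(2^m − 1)·(hi − lo) over [0.1, 10]
(resolution ≈ 9.4e−6), and the fitness — mean squared error of the model
trained at that spread, evaluated on the verification set on the normalized
scale — is computed. The elitist best is replaced only by a strictly smaller
fitness. Every qubit is then rotated by the orthogonal gate
[[cos θ, −sin θ], [sin θ, cos θ]] with |θ| = 0.05π when the measured bit
differs from the best individual's bit and 0 otherwise (the full
(x, b, better)-keyed table is configurable). The rotation sign follows the
sign of α_iβ_i so the update always grows the probability of the best bit,
and is suppressed once the qubit has collapsed onto that bit
(|amplitude| < 1e−12) — this also makes repeated rotation monotone.
Defaults: population 20, at most 50 generations, stop after 10 generations
without improvement. Fitness is evaluated on the held-out verification set
rather than the training set: with one hidden unit per training sample the
network interpolates, so a training-set objective would trivially favour
spread → 0; a training-set option exists behind `fitness_on="train"`.
Candidate spreads are cached within one search, so converged populations
cost no extra model fits.

The classical GA baseline uses the same encoding and stopping rule with
tournament selection (size 2), one-point crossover (rate 0.8), bit-flip
mutation (rate 1/m) and one elite.

## Preprocessing

Replicate triples are screened with the two-sided Dixon r10 (Q) test at
α = 0.05: Q = gap/range for whichever extreme is farther from its nearest
neighbour, flagged when Q exceeds the critical value (0.970 at n = 3). A
flagged replicate deletes its whole condition group; survivors contribute
their replicate mean. Zero-range groups never flag; groups with fewer than
three replicates pass through with a warning. Note the power limit of n = 3:
the statistic is roughly M/(M + |n₁ − n₂|) for an outlier of size M, so
even a 20σ gross error is flagged only when the two inlier replicates
differ by less than ≈ 0.62σ (probability ≈ 1/3); certain detection requires
outliers of order 200σ. The test's type-I rate means roughly 5% of clean
groups are discarded as false positives.

Features and target are min–max scaled to [0, 1] with parameters fitted on
the training portion only; values outside the fitted range map outside
[0, 1] without clipping. The 80/20 split is a seeded uniform shuffle with
the training size rounded half-away-from-zero (0.8 × 675 = 540 exactly).

## Synthetic data

No measured dataset accompanies the method, so the generator emulates the
factorial campaign: the noiseless surface is

P(I, T, b) = NRH(I; α₀, P_eff, θ) − R_d,
P_eff = P_max⁰ · exp(−(T − T_opt)²/(2w_T²)) ·
        exp(−(b − b_opt − k·|T − T_opt|)²/(2w_b²)),

where NRH is the non-rectangular hyperbola
(α₀I + P − √((α₀I + P)² − 4θα₀IP))/(2θ). Defaults: P_max⁰ = 25
umol m⁻² s⁻¹, α₀ = 0.06, θ = 0.8, R_d = 1.5 umol m⁻² s⁻¹ (typical cucumber
light-response values), T_opt = 24 °C with width 8 °C spanning the 18–30 °C
design, blue-ratio optimum 0.30 with width 0.35, stress coupling k = 0.02
per °C so the preferred blue fraction rises away from the thermal optimum,
and homoscedastic Gaussian replicate noise of 0.2 umol m⁻² s⁻¹ (no error
model is published; homoscedastic Gaussian is the simplest defensible
choice). The default design uses the fifteen listed PPFD levels; a
sixteen-level variant (adding 900 umol m⁻² s⁻¹, a synthetic choice) yields
the 720-group factorial used in gross-error experiments. One seeded
generator drives each operation.

Because of the stress coupling, exact unimodality of the surface in
temperature holds for b ≤ b_opt; above b_opt the drifting blue optimum can
very slightly favour off-optimum temperatures — intended behaviour, since
increased blue-light demand under temperature stress is the feature the
coupling encodes.

What the generator does **not** emulate: CO₂ and humidity responses (held
constant in the emulated campaign), diurnal and leaf-age effects,
heteroscedastic or autocorrelated instrument noise, and any mechanistic
(Farquhar-type) biochemistry. Passing tests therefore demonstrate correct
pipeline behaviour on a smooth, factorial, Gaussian-noise world, not
field-data performance.

## Numerical choices and degenerate inputs

- Ridge default 1e−10 stabilizes the weights solve at large spreads; exact
  interpolation checks use ridge = 0.
- The constant-target reproduction property holds between training nodes
  only when the nodes sample the range densely relative to the spread (an
  RBF interpolant is exact at its nodes, not globally); it is tested in a
  dense 1-D configuration.
- k-means ties break to the lowest center index; determinism is guaranteed
  for fixed seed/config/data.
- Degenerate normalization (z_max = z_min) raises; a single RBF center with
  `spread="auto"` raises with instructions to supply an explicit spread
  (c_max is undefined).
- Non-finite optimizer fitnesses discard the candidate with a warning.
- Split sizes are clamped to leave at least one group on each side.

## Default problem sizes

Unit tests run on reduced factorial designs (tens to a few hundred groups);
the end-to-end checks and the acceptance script use the full default design
(675 groups, hidden count 540 after the split) — a full QGA search there
takes a few seconds. The six-model comparison example uses a reduced design
purely to keep the narrative script snappy.

## Known limitations

- The spread is the only hyperparameter searched; center count and ridge
  are fixed by configuration.
- The Dixon screen at n = 3 has low power (see above) and a ~5% false-alarm
  rate; it is faithful to small-replicate gas-exchange practice, not an
  optimal outlier filter.
- Wall-clock timing comparisons between models are logged but not reported
  as results (hardware-dependent).
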