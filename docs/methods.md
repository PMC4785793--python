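# Methods

## Chain model

Arms are simulated as discrete 2D worm-like chains: N = round(L_c / L_s)
segments of fixed length L_s (default 0.2 nm; any residual arc length
below L_s/2 is dropped), with independent zero-mean Gaussian deflection
angles between consecutive segments.  The angle variance is **L_s / L_p**.
This is the convention under which the tangent correlation of a chain
equilibrated in two dimensions decays as ⟨cos θ(s)⟩ = e^(−s/2L_p) and the
mean squared end-to-end distance obeys

    ⟨R²⟩ = 4 L_p L_c [1 − (2 L_p / L_c)(1 − e^(−L_c/2L_p))],

which the test suite verifies against direct numerical integration of the
tangent-correlation kernel and against simulation.  (The inverse ratio
L_p / L_s sometimes appears in print for this construction; it is
dimensionally inconsistent with the 2D closed form above, so this package
uses L_s / L_p throughout.)  Chains are ideal — no excluded volume, no
force or twist — and strictly two-dimensional, matching molecules
equilibrated on a mica surface.  The first vertex sits at the origin with
the first segment along +x; end-to-end statistics are rotation invariant,
and arms attached to a hinge receive an additional uniform random
orientation.

Single-chain simulation costs O(N); ensembles are vectorised and chunked
(20 000 chains per block) so 10⁶-chain runs stay within a small memory
footprint.

## Stiffness estimation

Two estimators are provided.

**Moment inversion** (`rivetti_estimator`): solve
⟨R²⟩_model(L_p; L_c) = ⟨R²⟩_empirical for L_p by bracketed root finding on
L_p ∈ [10⁻³, 10⁶] nm (relative tolerance 10⁻⁶; the function is strictly
increasing in L_p, so the root is unique).  It fails, by design, when the
empirical mean square reaches L_c² (rod limit).  Because it uses only the
second moment, deleting short end-to-end distances — which head-hinge
engagement does to experimental samples — biases it upward; the test suite
asserts this direction on 20 independent ensembles.

**Histogram least squares** (`fit_wlc`): the empirical distance histogram
(default 2-nm bins on [0, 60] nm, density normalised by total sample size,
half-open bins) is compared against Monte-Carlo histograms at candidate
(L_p, L_c); the score is the sum of squared per-bin density differences.
The default search is a 15 × 15 grid on L_p ∈ [1, 20] nm × L_c ∈ [20, 80]
nm followed by 3 refinement rounds, each halving both ranges re-centred on
the running minimum (clipped to the original box; a minimum within one
final grid step of the box edge sets `boundary_warning`).  Each evaluation
simulates 2 × 10⁴ chains by default — configurable up to the 10⁶ used at
full production scale — and all evaluations share one block of standard
normals (common random numbers): the heading sequence at any stiffness is
a rescaling of the same cumulative sums, so the goodness-of-fit surface is
smooth in the parameters, deterministic given the config seed, and its
argmin is not perturbed by simulation jitter.

Bin width and range are package choices (the ~25-nm open peak spans >10
bins at realistic sample sizes); densities rather than counts are compared
so samples of different sizes are commensurable.

One-SD confidence intervals (`confidence_sd`) refit parametric replicates:
`n_replicates_for_ci` (default 50) datasets of the original size are
simulated at the best-fit point and refitted with the identical config;
the SDs of the refitted parameters are reported.  Fewer than 10 replicates
is rejected as unreliable.

Identifiability: for very flexible chains (L_c / L_p ≳ 15) the
distribution approaches its Gaussian-coil limit, which depends on the
parameters mainly through the product L_p·L_c; recovery there needs the
finer default grid and low simulation noise, while stiffer chains are
well determined even at reduced settings.  The parameter-recovery test
documents this by running a denser config than the other fit tests.

## Conformational classification

Per-frame geometry uses only the three landmark positions: head-head
distance and the two head-hinge distances, all rigid-motion invariant.
The classification rule, with both engagement thresholds defaulting to
7 nm (the dip between the engaged ~2.4 nm peak and the open ~24 nm peak of
the head-hinge distance distribution):

1. both head-hinge distances ≤ threshold → **B**;
2. else head-head distance ≤ threshold → **O**;
3. else exactly one head-hinge distance ≤ threshold → **P**;
4. else → **V**.

The ordering makes the rule exhaustive and gives B precedence over O when
all three domains co-locate (geometrically unavoidable there).  Ties
exactly at a threshold count as engaged.  Frames with missing landmarks
are UNCLASSIFIED — a reported category, not an error — and break
transition-counting chains on both sides.  Movie annotation can subsample
(analyse every k-th frame), mirroring how dense movies are decimated in
practice.

Hinge opening angles are measured between chord vectors from the hinge
vertex to the point at 5 nm arc length along each traced arm (≈1.3
persistence lengths).  Chords at this scale average out tracing noise that
dominates single-segment tangents; the arc length is configurable.

Gaussian peak fitting (`gaussian_peak`) is windowed: the density histogram
restricted to a window (default bin width 0.5 nm) is fitted with
a·e^(−(x−μ)²/2σ²) by nonlinear least squares, initialised from the
in-window moments.  Fitting the *shape* rather than taking moments makes μ
robust to truncation outside (or at the edge of) the window — a sample
truncated at zero still refits to its generating mean.  Degenerate
point-mass samples (fewer than 3 occupied bins) return the in-window
moments directly.

## Synthetic movies

The generator emulates the study conditions: two independent WLC arms
(L_p = 3.8 nm, L_c = 46 nm) anchored at the hinge with uniform random
orientations; a first-order Markov state process over {V, O, B, P} at
0.1-s frame intervals (default: stay probability 0.9, off-diagonal mass
favouring O↔B exchange; the matrix is fully configurable and the
class-mixture tests use i.i.d. rows so the stationary fractions are
explicit); engaged head-head distances from N(2.5, 1.3²) nm and engaged
head-hinge distances from N(2.4, 1.9²) nm, both truncated at zero;
isotropic Gaussian localisation noise (default sd 0.5 nm) on emitted
landmarks only, with traces emitted noiseless.

Engagement is imposed by **rejection sampling of unconstrained arms**: an
engaged arm is redrawn until its end-to-end distance matches a target
drawn from the engaged distribution to within 0.5 nm.  With L_c/L_p ≈ 12
the single-arm return probability below 7 nm is a few percent, so
rejection is tractable (a per-frame proposal cap guards pathological
configurations), and it preserves the exact conditional WLC ensemble — no
pinned-end bridge construction that would distort arm statistics.  The V
acceptance predicate reuses the classifier's 7-nm thresholds, so ground
truth and classification agree by construction up to localisation noise.

What the generator does **not** emulate: AFM tip convolution and finite
domain sizes (landmarks are idealised centres), scanner drift, correlated
or anisotropic localisation error, state-dependent dwell-time structure
beyond first-order Markov, and any ATP- or DNA-dependent kinetics.
Passing round-trip tests therefore demonstrates the internal consistency
of the pipeline on data satisfying the model assumptions, not robustness
to those instrument effects.

## Numerical and design choices

* One top-level seed per operation; child streams derived via
  `SeedSequence` spawn keys, so adding operations never perturbs existing
  outputs.  Identical seeds give bit-identical results everywhere,
  including the full pipeline report.
* Histogram bins are strictly half-open [lo, hi), implemented by floor
  indexing; data outside the range are kept in the sample (they lower the
  in-range density integral) — empirical truncation near zero is treated
  as a property of data, never imposed by the fitter.
* The trace/landmark consistency bound (1 nm) is a soft check: with
  localisation noise the emitted landmark can legitimately sit farther
  from the noiseless trace endpoint, so readers log rather than reject.
* Desk-scale defaults: acceptance-grade fits use 2 × 10⁴ chains per grid
  evaluation and n = 2000 data; unit tests use reduced grids (documented
  per test).  All scale parameters are exposed in the configs.

## Known limitations

* The fitted minimum is reported at grid resolution (no sub-grid
  interpolation); the final refinement step bounds the quantisation error
  (~0.09 nm in L_p at defaults), which is folded into the replicate SD.
* The replicate-refit SD assumes the fitted model generates the data; it
  does not capture misspecification (e.g. censored input samples).
* Classification is purely distance-threshold based; frames near a
  threshold flip class under localisation noise, which bounds round-trip
  accuracy at high noise.
* The Markov default transition matrix is illustrative — dwell-time
  statistics were not fitted to data.
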