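# smcflex

Quantitative analysis of SMC (structural maintenance of chromosomes) dimer
conformations from high-speed AFM landmark data: worm-like-chain stiffness
estimation for the coiled-coil arms, and classification of the dynamic
V/O/B/P architectures the dimers adopt.

## Who this is for

Single-molecule biophysicists analysing per-frame landmark tables (head,
head, hinge positions in nm) extracted from AFM movies of condensin-like
Smc2-Smc4 dimers — or anyone who needs a tested 2D worm-like-chain
Monte-Carlo simulator with histogram-based (L_p, L_c) fitting.  Because raw
AFM movies are rarely shareable, the package ships a ground-truth synthetic
movie generator so the whole pipeline is testable end to end without any
experimental data.

## The model

Each coiled-coil arm is a two-dimensional, surface-equilibrated worm-like
chain: contour length L_c discretised into segments of length L_s = 0.2 nm
with independent Gaussian deflection angles of variance L_s / L_p between
segments.  Under this convention the tangent correlation decays as
⟨cos θ(s)⟩ = e^(−s/2L_p) and the mean squared end-to-end distance is

    ⟨R²⟩ = 4 L_p L_c [1 − (2 L_p / L_c)(1 − e^(−L_c / 2 L_p))]

The end-to-end *distribution* has no closed form, so (L_p, L_c) are fitted
by least squares between the empirical distance histogram and Monte-Carlo
histograms on a refined parameter grid, with one-SD errors from refitting
parametric replicates.  The classical moment estimator (inverting ⟨R²⟩
alone) is included for comparison; it is biased upward whenever short
end-to-end distances are censored, e.g. by head-hinge engagement.

Frames are classified from two engagement thresholds (default 7 nm, the
dip between the engaged ~2.4 nm and open ~24 nm head-hinge peaks):
**V** open (nothing engaged), **O** heads engaged with each other,
**B** both heads engaged with the hinge ("butterfly"), **P** exactly one
head engaged with the hinge.

## Worked example

`examples/simulate_stiffness.py` simulates 10⁵ arms at the measured
Smc2-Smc4 stiffness and inverts the moment estimator:

```
closed-form <R^2> at (3.8, 46):     584.0 nm^2
simulated  <R^2> (n = 1e5):         582.0 nm^2
moment estimate of L_p:              3.78 nm
same, after deleting R < 7 nm:       4.07 nm
```

The simulator matches the closed form and the estimator recovers the
generating L_p = 3.8 nm; deleting distances below 7 nm (what head-hinge
engagement does to real data) inflates the moment estimate — which is why
the histogram fit is preferred.  `examples/fit_persistence_length.py` runs
that fit on 2000 simulated distances:

```
generating parameters: L_p = 3.8 nm, L_c = 46.0 nm
recovered:             L_p = 3.83 nm, L_c = 44.8 nm
```

`examples/classify_movie.py` and `examples/full_pipeline.py` generate a
synthetic movie, classify it (98.5% agreement with ground truth at 0.5 nm
localisation noise) and recover the arm stiffness from the classified
V-state frames alone.

## Command line

A thin CLI wraps the library:

```sh
smcflex synth --seed 2 --out-prefix movie
smcflex classify --landmarks movie.landmarks.tsv --traces movie.traces.jsonl \
        --out labels.tsv --report classify.json
smcflex fit --distances distances.csv --config fit.yaml --out fit.json
smcflex run --config pipeline.yaml --out-dir results/
```

Formats: landmark TSV (`frame_id, time_s, head1_x_nm, ... hinge_y_nm`),
JSON-lines arm traces, single-column `distance_nm` CSV, JSON reports that
embed the seed and config.

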