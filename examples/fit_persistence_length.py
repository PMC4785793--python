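"""Fit (L_p, L_c) to an end-to-end distance sample by histogram least squares.

Generates 2000 arm end-to-end distances at known parameters, then recovers
them by comparing the empirical histogram against Monte-Carlo worm-like-chain
histograms on a refined (L_p, L_c) grid.  A moderate number of chains per
grid evaluation keeps this demonstration around a minute; raise
``chains_per_evaluation`` for production-quality surfaces.
"""

from smcflex import FitConfig, WLCParams, fit_wlc, simulate_end_to_end

TRUE_LP, TRUE_LC = 3.8, 46.0

data = simulate_end_to_end(
    WLCParams(persistence_length=TRUE_LP, contour_length=TRUE_LC, n_chains=2000, seed=42)
)
config = FitConfig(seed=7, grid_points_per_axis=11, refinement_rounds=3,
                   chains_per_evaluation=10_000)
result = fit_wlc(data, config)

print(f"generating parameters: L_p = {TRUE_LP} nm, L_c = {TRUE_LC} nm")
print(f"recovered:             L_p = {result.lp_hat:.2f} nm, L_c = {result.lc_hat:.1f} nm")
print(f"evaluations on the goodness-of-fit surface: {len(result.gof_surface)}")
print()
print("The fit searches a 2D grid of candidate (L_p, L_c), simulating a chain")
print("ensemble at each point and scoring the summed squared histogram")
print("difference; the recovered values should sit within a few percent of the")
print("generating ones at this sample size.")
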