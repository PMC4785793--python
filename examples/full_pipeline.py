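"""End-to-end pipeline: synthesise a movie, classify it, fit arm stiffness.

Runs the same stages a real analysis would: landmark tables are written and
re-read through the standard file formats, frames are classified, the
head-hinge distances of open (V-shaped) frames form the end-to-end sample,
and the worm-like-chain histogram fit estimates (L_p, L_c) from it.
"""

import tempfile

from smcflex import FitConfig, PipelineConfig, SynthConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(
        seed=99,
        out_dir=tmp,
        synth=SynthConfig(n_frames=400),
        fit=FitConfig(grid_points_per_axis=9, refinement_rounds=2,
                      chains_per_evaluation=5000),
    )
    artifacts = run_pipeline(config)
    results = artifacts["results"]

    print(f"frames analysed: {results['n_analyzed']}")
    print(f"class counts:    {results['class_counts']}")
    print(f"V-state end-to-end distances fitted: {results['n_v_distances']}")
    fit = results["fit"]
    print(f"fitted L_p = {fit['lp_hat_nm']:.2f} nm, L_c = {fit['lc_hat_nm']:.1f} nm")
    print()
    print("The generator's arms use L_p = 3.8 nm, L_c = 46 nm; the pipeline")
    print("recovers the stiffness from classified landmarks alone.  V-state")
    print("selection censors short distances, so the recovered L_p runs slightly")
    print("high — the same bias the moment estimator shows on real data.")
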