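"""End-to-end pipeline: synthesise -> classify -> extract V distances -> fit.

Mirrors the analysis route applied to a real movie: landmark tables are
classified into V/O/B/P states, the head-hinge distances of open (V)
frames form the end-to-end sample, and the worm-like-chain fit estimates
the arm stiffness from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as sio
from .conformations import ConformationLabel, Thresholds, annotate_movie, head_hinge_distances
from .errors import ParameterError
from .fitting import FitConfig, confidence_sd, fit_wlc
from .synthetic import SynthConfig, generate_movie
from .wlc import EndToEndSample

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline settings; one top-level seed drives every stage."""

    seed: int = 0
    out_dir: str = "."
    synth: SynthConfig = field(default_factory=SynthConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    fit: FitConfig = field(default_factory=FitConfig)
    subsample_every: int = 1
    run_ci: bool = False
    min_fit_sample: int = 50


def _child_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing artifacts under ``config.out_dir``.

    Returns a dict with the output paths, the movie annotation and (when
    enough V-state distances are available) the fit result.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = replace(config.synth, seed=_child_seed(config.seed, 0))
    fit_cfg = replace(config.fit, seed=_child_seed(config.seed, 1))

    frames, truth = generate_movie(synth_cfg)
    logger.info("synthesised %d frames", len(frames))
    paths = {
        "landmarks": out / "landmarks.tsv",
        "traces": out / "traces.jsonl",
        "truth": out / "truth.tsv",
        "labels": out / "labels.tsv",
        "distances": out / "distances.csv",
        "report": out / "report.json",
    }
    sio.write_landmarks(frames, paths["landmarks"])
    sio.write_arm_traces(frames, paths["traces"])
    sio.write_truth(truth, paths["truth"])

    # read back through the standard readers so the pipeline exercises the
    # same code path as an externally supplied movie
    movie = sio.read_movie(paths["landmarks"], paths["traces"])
    annotation = annotate_movie(movie, config.thresholds, config.subsample_every)
    sio.write_labels(annotation, movie, paths["labels"])
    counts = {lab.value: 0 for lab in ConformationLabel}
    for _, lab in annotation.labels:
        counts[lab.value] += 1
    logger.info("classified %d frames: %s", len(annotation.labels), counts)

    by_id = {f.frame_id: f for f in movie}
    v_distances = []
    for fid, lab in annotation.labels:
        if lab is ConformationLabel.V:
            v_distances.extend(head_hinge_distances(by_id[fid]))
    sample = EndToEndSample(distances=np.asarray(v_distances))
    sio.write_distances(sample, paths["distances"])
    logger.info("extracted %d end-to-end distances from V-state frames", len(sample))

    fit_result = None
    if len(sample) >= config.min_fit_sample:
        fit_result = fit_wlc(sample, fit_cfg)
        if config.run_ci and not fit_result.boundary_warning:
            confidence_sd(fit_result, sample, fit_cfg)
        logger.info(
            "fit: L_p = %.2f nm, L_c = %.1f nm (n = %d)",
            fit_result.lp_hat,
            fit_result.lc_hat,
            fit_result.n_data,
        )
    else:
        logger.warning(
            "only %d V-state distances (< %d); skipping fit", len(sample), config.min_fit_sample
        )

    results = {
        "n_frames": len(frames),
        "n_analyzed": len(annotation.labels),
        "class_counts": counts,
        "class_frequencies": {k.value: v for k, v in annotation.class_frequencies.items()},
        "transition_counts": {
            f"{a.value}->{b.value}": c for (a, b), c in sorted(annotation.transition_counts.items())
        },
        "n_v_distances": len(sample),
        "fit": fit_result.to_dict() if fit_result is not None else None,
    }
    sio.write_report(results, paths["report"], seed=config.seed, config=config)
    return {"paths": {k: str(v) for k, v in paths.items()}, "annotation": annotation,
            "fit": fit_result, "results": results}
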