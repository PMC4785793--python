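"""Synthetic dimer movies with known ground truth.

Generates per-frame landmark sets (two heads + hinge), noiseless arm
traces and a hidden conformational-state sequence, with the statistical
structure the analysis pipeline assumes:

* each coiled-coil arm is an independent 2D worm-like chain
  (defaults L_p = 3.8 nm, L_c = 46 nm, L_s = 0.2 nm) anchored at the hinge
  with a uniformly random initial direction;
* the conformational state follows a first-order Markov chain over
  {V, O, B, P} at a fixed frame interval (default 0.1 s);
* engaged head-head distances follow N(2.5, 1.3^2) nm and engaged
  head-hinge distances N(2.4, 1.9^2) nm, both truncated at zero;
* isotropic Gaussian localisation noise (default sd 0.5 nm) is added to
  the emitted landmarks only; traces are emitted noiseless.

Engagement constraints are imposed by rejection sampling of unconstrained
WLC arms, which preserves the exact conditional chain ensemble: an engaged
arm is re-drawn until its end-to-end distance matches a target drawn from
the engaged-distance distribution to within a small tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .conformations import ConformationLabel, DimerFrame, Thresholds
from .errors import GenerationError, ParameterError
from .wlc import EndToEndSample, WLCParams

__all__ = [
    "SynthConfig",
    "GroundTruthEntry",
    "GroundTruth",
    "sample_dimer_conformation",
    "generate_movie",
    "generate_end_to_end_dataset",
    "simulate_state_sequence",
    "truncated_normal",
    "stationary_distribution",
    "DEFAULT_TRANSITION_MATRIX",
]

_STREAM_MOVIE = 10
_STREAM_DATASET = 11

STATE_ORDER = (
    ConformationLabel.V,
    ConformationLabel.O,
    ConformationLabel.B,
    ConformationLabel.P,
)

# Stay probability 0.9; off-diagonal mass favours the frequent O<->B
# switching seen in head-engagement dynamics.  Rows in V, O, B, P order.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        [0.90, 0.04, 0.03, 0.03],
        [0.02, 0.90, 0.06, 0.02],
        [0.02, 0.06, 0.90, 0.02],
        [0.04, 0.03, 0.03, 0.90],
    ]
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults reproduce the study conditions."""

    arm_params: WLCParams = field(
        default_factory=lambda: WLCParams(
            persistence_length=3.8, contour_length=46.0, segment_length=0.2
        )
    )
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    initial_state: str = "stationary"  # a label name or "stationary"
    n_frames: int = 500
    frame_interval: float = 0.1
    engaged_head_head: Tuple[float, float] = (2.5, 1.3)
    engaged_head_hinge: Tuple[float, float] = (2.4, 1.9)
    localization_noise_sd: float = 0.5
    match_tolerance: float = 0.5
    rejection_cap: int = 100_000
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (4, 4) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("transition_matrix must be 4x4 row-stochastic")
        object.__setattr__(self, "transition_matrix", tm)
        for name in ("engaged_head_head", "engaged_head_hinge"):
            mu, sd = getattr(self, name)
            if not (mu > 0 and sd > 0):
                raise ParameterError(f"{name} scale parameters must be > 0")
        if self.localization_noise_sd < 0:
            raise ParameterError("localization_noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.rejection_cap < 1:
            raise ParameterError("rejection_cap must be >= 1")


@dataclass
class GroundTruthEntry:
    """True (noiseless) state and landmarks for one frame, plus sampling cost."""

    state: ConformationLabel
    head1: Tuple[float, float]
    head2: Tuple[float, float]
    hinge: Tuple[float, float]
    arm_proposals: int


@dataclass
class GroundTruth:
    entries: List[GroundTruthEntry]

    @property
    def states(self) -> List[ConformationLabel]:
        return [e.state for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def truncated_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator, lower: float = 0.0
) -> np.ndarray:
    """Draws from N(mean, sd^2) truncated below at ``lower``."""
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def stationary_distribution(tm: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(tm.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(
    config: SynthConfig, rng: np.random.Generator, n: Optional[int] = None
) -> List[ConformationLabel]:
    """Markov state sequence of length ``n`` (default ``config.n_frames``)."""
    n = config.n_frames if n is None else n
    tm = config.transition_matrix
    if config.initial_state == "stationary":
        p0 = stationary_distribution(tm)
    else:
        try:
            s0 = ConformationLabel(config.initial_state)
        except ValueError:
            raise ParameterError("initial_state must be V/O/B/P or 'stationary'")
        p0 = np.zeros(4)
        p0[STATE_ORDER.index(s0)] = 1.0
    idx = int(rng.choice(4, p=p0))
    states = []
    for _ in range(n):
        states.append(STATE_ORDER[idx])
        idx = int(rng.choice(4, p=tm[idx]))
    return states


def _arm_batch(params: WLCParams, rng: np.random.Generator, count: int) -> np.ndarray:
    """Vertices of ``count`` arms anchored at the origin with uniform random
    initial headings; shape (count, N+1, 2)."""
    n = params.n_segments
    sd = np.sqrt(params.segment_length / params.persistence_length)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, size=(count, 1))
    angles = rng.standard_normal((count, n - 1)) * sd
    headings = phi0 + np.concatenate([np.zeros((count, 1)), np.cumsum(angles, axis=1)], axis=1)
    steps = params.segment_length * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    vertices = np.concatenate([np.zeros((count, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    return vertices


class _ProposalBudget:
    def __init__(self, cap: int, state: ConformationLabel, config: SynthConfig):
        self.cap = cap
        self.used = 0
        self.state = state
        self.config = config

    def spend(self, n: int):
        self.used += n
        if self.used > self.cap:
            p = self.config.arm_params
            raise GenerationError(
                f"rejection cap {self.cap} exceeded sampling state {self.state.value} "
                f"(L_p={p.persistence_length}, L_c={p.contour_length})"
            )


def _find_arm(
    budget: _ProposalBudget,
    rng: np.random.Generator,
    config: SynthConfig,
    accept,
    batch: int = 256,
) -> np.ndarray:
    """First arm (vertex array) whose endpoint satisfies ``accept(ends) -> mask``."""
    while True:
        arms = _arm_batch(config.arm_params, rng, batch)
        mask = accept(arms[:, -1, :])
        idx = np.flatnonzero(mask)
        if idx.size:
            budget.spend(int(idx[0]) + 1)
            return arms[idx[0]]
        budget.spend(batch)


def _find_arm_pair(
    budget: _ProposalBudget,
    rng: np.random.Generator,
    config: SynthConfig,
    accept_pair,
    batch: int = 256,
) -> Tuple[np.ndarray, np.ndarray]:
    """First arm pair whose endpoints satisfy ``accept_pair(ends1, ends2) -> mask``."""
    while True:
        a1 = _arm_batch(config.arm_params, rng, batch)
        a2 = _arm_batch(config.arm_params, rng, batch)
        mask = accept_pair(a1[:, -1, :], a2[:, -1, :])
        idx = np.flatnonzero(mask)
        if idx.size:
            budget.spend(2 * (int(idx[0]) + 1))
            return a1[idx[0]], a2[idx[0]]
        budget.spend(2 * batch)


def sample_dimer_conformation(
    state: ConformationLabel,
    config: SynthConfig,
    rng: np.random.Generator,
    frame_id: int = 0,
    time: float = 0.0,
) -> Tuple[DimerFrame, GroundTruthEntry]:
    """Sample one frame in the requested conformational state.

    The hinge sits at the origin; two independent WLC arms are drawn and
    rejected until the state's engagement predicate holds (V: everything
    farther than the engagement threshold; O: head-head distance matching
    a draw from the engaged head-head distribution; B: both head-hinge
    distances matching draws from the engaged head-hinge distribution;
    P: one arm hinge-engaged, the other free with the heads apart).
    """
    if state not in STATE_ORDER:
        raise ParameterError(f"state must be one of V/O/B/P, got {state}")
    t = config.thresholds
    tol = config.match_tolerance
    budget = _ProposalBudget(config.rejection_cap, state, config)
    norm = np.linalg.norm

    if state is ConformationLabel.V:
        arm1, arm2 = _find_arm_pair(
            budget,
            rng,
            config,
            lambda e1, e2: (
                (norm(e1, axis=1) > t.head_hinge_engaged)
                & (norm(e2, axis=1) > t.head_hinge_engaged)
                & (norm(e1 - e2, axis=1) > t.head_head_engaged)
            ),
        )
    elif state is ConformationLabel.O:
        target = float(truncated_normal(*config.engaged_head_head, 1, rng)[0])
        arm1, arm2 = _find_arm_pair(
            budget,
            rng,
            config,
            lambda e1, e2: (
                (np.abs(norm(e1 - e2, axis=1) - target) <= tol)
                & (norm(e1, axis=1) > t.head_hinge_engaged)
                & (norm(e2, axis=1) > t.head_hinge_engaged)
            ),
        )
    elif state is ConformationLabel.B:
        arms = []
        for _ in range(2):
            target = float(truncated_normal(*config.engaged_head_hinge, 1, rng)[0])
            arms.append(
                _find_arm(
                    budget,
                    rng,
                    config,
                    lambda e, d=target: np.abs(norm(e, axis=1) - d) <= tol,
                )
            )
        arm1, arm2 = arms
    else:  # P
        engaged_first = bool(rng.integers(2))
        target = float(truncated_normal(*config.engaged_head_hinge, 1, rng)[0])
        engaged = _find_arm(
            budget, rng, config, lambda e: np.abs(norm(e, axis=1) - target) <= tol
        )
        anchor = engaged[-1]
        free = _find_arm(
            budget,
            rng,
            config,
            lambda e: (
                (norm(e, axis=1) > t.head_hinge_engaged)
                & (norm(e - anchor, axis=1) > t.head_head_engaged)
            ),
        )
        arm1, arm2 = (engaged, free) if engaged_first else (free, engaged)

    true_head1 = tuple(arm1[-1])
    true_head2 = tuple(arm2[-1])
    true_hinge = (0.0, 0.0)
    noise = rng.normal(0.0, config.localization_noise_sd, size=(3, 2))
    frame = DimerFrame(
        frame_id=frame_id,
        time=time,
        head1=tuple(np.asarray(true_head1) + noise[0]),
        head2=tuple(np.asarray(true_head2) + noise[1]),
        hinge=tuple(np.asarray(true_hinge) + noise[2]),
        arm1_trace=arm1,
        arm2_trace=arm2,
    )
    truth = GroundTruthEntry(
        state=state,
        head1=true_head1,
        head2=true_head2,
        hinge=true_hinge,
        arm_proposals=budget.used,
    )
    return frame, truth


def generate_movie(config: SynthConfig) -> Tuple[List[DimerFrame], GroundTruth]:
    """Generate a movie of ``config.n_frames`` frames, deterministic given the seed.

    States evolve by the configured Markov transition matrix; frame times
    are ``frame_id * frame_interval``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAM_MOVIE,)))
    states = simulate_state_sequence(config, rng)
    frames: List[DimerFrame] = []
    entries: List[GroundTruthEntry] = []
    for i, state in enumerate(states):
        frame, truth = sample_dimer_conformation(
            state, config, rng, frame_id=i, time=i * config.frame_interval
        )
        frames.append(frame)
        entries.append(truth)
    return frames, GroundTruth(entries=entries)


def generate_end_to_end_dataset(config: SynthConfig, n: int) -> EndToEndSample:
    """Noiseless head-hinge distances from ``n`` V-state frames (both arms: 2n values).

    Emulates the sample used for stiffness fitting: only open (V-shaped)
    conformations, each contributing the end-to-end distance of both
    coiled-coil arms.  Endpoint-only fast path (no traces retained).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAM_DATASET,)))
    t = config.thresholds
    p = config.arm_params
    nseg = p.n_segments
    sd = np.sqrt(p.segment_length / p.persistence_length)
    collected: List[np.ndarray] = []
    n_pairs = 0
    proposed = 0
    while n_pairs < n:
        batch = max(256, min(4096, 2 * (n - n_pairs)))
        proposed += 2 * batch
        if proposed > max(config.rejection_cap, 100 * n):
            raise GenerationError("rejection cap exceeded sampling V-state dataset")
        phi0 = rng.uniform(0.0, 2.0 * np.pi, size=(2 * batch, 1))
        theta = phi0 + np.concatenate(
            [
                np.zeros((2 * batch, 1)),
                np.cumsum(rng.standard_normal((2 * batch, nseg - 1)) * sd, axis=1),
            ],
            axis=1,
        )
        ends = p.segment_length * np.stack(
            [np.cos(theta).sum(axis=1), np.sin(theta).sum(axis=1)], axis=-1
        )
        e1, e2 = ends[:batch], ends[batch:]
        g1 = np.hypot(e1[:, 0], e1[:, 1])
        g2 = np.hypot(e2[:, 0], e2[:, 1])
        hh = np.hypot(*(e1 - e2).T)
        ok = (g1 > t.head_hinge_engaged) & (g2 > t.head_hinge_engaged) & (hh > t.head_head_engaged)
        take = np.flatnonzero(ok)[: n - n_pairs]
        collected.append(np.concatenate([g1[take], g2[take]]))
        n_pairs += take.size
    return EndToEndSample(distances=np.concatenate(collected), params_used=p)
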