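"""Two-dimensional worm-like-chain (WLC) simulation and moment-based stiffness estimation.

The coiled-coil arm of an SMC dimer adsorbed on a surface is modelled as a
2D, surface-equilibrated worm-like chain: a polymer of contour length
``L_c`` discretised into segments of length ``L_s``, with independent
Gaussian deflection angles of variance ``L_s / L_p`` between consecutive
segments.  With this convention the tangent-orientation correlation decays
as ``exp(-s / (2 L_p))`` and the mean squared end-to-end distance follows
the closed form

    <R^2> = 4 L_p L_c [1 - (2 L_p / L_c) (1 - exp(-L_c / (2 L_p)))]

so ``L_p`` is the persistence length in the standard 2D sense.  All lengths
are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .errors import EstimationError, ParameterError

__all__ = [
    "WLCParams",
    "ChainTrace",
    "EndToEndSample",
    "simulate_chain",
    "simulate_end_to_end",
    "msd_closed_form",
    "rivetti_estimator",
    "tangent_correlation",
]

# spawn keys for per-operation child RNG streams; adding a new operation
# appends a key and never perturbs existing outputs
_STREAM_END_TO_END = 0


@dataclass(frozen=True)
class WLCParams:
    """Parameters of a discretised 2D worm-like chain.

    persistence_length : L_p, nm.  Tangent correlations decay as exp(-s/2L_p).
    contour_length     : L_c, nm.  Total arc length.
    segment_length     : L_s, nm.  Discretisation step (default 0.2 nm).
    n_chains           : ensemble size for sampling operations.
    seed               : top-level seed; child streams are derived from it.
    """

    persistence_length: float
    contour_length: float
    segment_length: float = 0.2
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.persistence_length > 0):
            raise ParameterError(f"persistence_length must be > 0, got {self.persistence_length}")
        if not (self.contour_length > 0):
            raise ParameterError(f"contour_length must be > 0, got {self.contour_length}")
        if not (0 < self.segment_length <= self.contour_length):
            raise ParameterError(
                f"segment_length must satisfy 0 < L_s <= L_c, got {self.segment_length}"
            )
        if self.n_segments < 1:
            raise ParameterError("contour_length / segment_length rounds to zero segments")

    @property
    def n_segments(self) -> int:
        """N = round(L_c / L_s); residual arc length < L_s/2 is dropped."""
        return int(round(self.contour_length / self.segment_length))


@dataclass(frozen=True)
class ChainTrace:
    """Ordered 2D vertices (nm) of one simulated chain; N+1 vertices for N segments."""

    vertices: np.ndarray  # shape (N+1, 2)
    params: WLCParams

    @property
    def end_to_end(self) -> float:
        return float(np.hypot(*(self.vertices[-1] - self.vertices[0])))

    @property
    def headings(self) -> np.ndarray:
        """Tangent angle of each segment, radians, shape (N,)."""
        d = np.diff(self.vertices, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])


@dataclass(frozen=True)
class EndToEndSample:
    """End-to-end distances (nm), either simulated (params recorded) or measured."""

    distances: np.ndarray
    params_used: Union[WLCParams, str] = "measured"

    def __post_init__(self):
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        if np.any(self.distances < 0):
            raise ParameterError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.distances)


def _deflection_sd(params: WLCParams) -> float:
    # Gaussian deflection angles with variance L_s / L_p
    return float(np.sqrt(params.segment_length / params.persistence_length))


def simulate_chain(params: WLCParams, rng: np.random.Generator) -> ChainTrace:
    """Sample one chain; first vertex at the origin, first segment along +x."""
    n = params.n_segments
    angles = rng.standard_normal(n - 1) * _deflection_sd(params)
    headings = np.concatenate([[0.0], np.cumsum(angles)])
    steps = params.segment_length * np.column_stack([np.cos(headings), np.sin(headings)])
    vertices = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return ChainTrace(vertices=vertices, params=params)


def _end_to_end_batch(params: WLCParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """End-to-end distances for n chains without retaining traces."""
    nseg = params.n_segments
    theta = np.cumsum(rng.standard_normal((n, nseg - 1)) * _deflection_sd(params), axis=1)
    ls = params.segment_length
    x = ls * (1.0 + np.cos(theta).sum(axis=1))
    y = ls * np.sin(theta).sum(axis=1)
    return np.hypot(x, y)


def simulate_end_to_end(params: WLCParams, chunk: int = 20_000) -> EndToEndSample:
    """Simulate ``params.n_chains`` end-to-end distances, reproducibly from ``params.seed``.

    Chains are processed in chunks so million-chain ensembles stay within
    a modest memory footprint; the output is independent of ``chunk``
    only in distribution, and bit-reproducible for a fixed chunk size.
    """
    if params.n_chains < 1:
        raise ParameterError(f"n_chains must be >= 1, got {params.n_chains}")
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(_STREAM_END_TO_END,))
    )
    out = np.empty(params.n_chains)
    done = 0
    while done < params.n_chains:
        m = min(chunk, params.n_chains - done)
        out[done : done + m] = _end_to_end_batch(params, rng, m)
        done += m
    return EndToEndSample(distances=out, params_used=params)


def msd_closed_form(lp: float, lc: float) -> float:
    """Mean squared end-to-end distance of a 2D surface-equilibrated WLC (nm^2).

    <R^2> = 4 L_p L_c [1 - (2 L_p / L_c)(1 - e^{-L_c / 2 L_p})].
    Limits: rigid rod (L_p >> L_c) -> L_c^2; Gaussian coil (L_p << L_c) -> 4 L_p L_c.
    """
    if not lp > 0:
        raise ParameterError(f"lp must be > 0, got {lp}")
    if not lc > 0:
        raise ParameterError(f"lc must be > 0, got {lc}")
    x = lc / (2.0 * lp)
    if x < 1e-6:
        # series expansion avoids catastrophic cancellation in the rod limit
        return lc * lc * (1.0 - x / 3.0 + x * x / 12.0)
    return 4.0 * lp * lc * (1.0 - (1.0 - np.exp(-x)) / x)


def rivetti_estimator(sample: EndToEndSample, lc: float) -> float:
    """Invert the mean-square closed form for L_p given a fixed contour length.

    This is the classical moment estimator for surface-equilibrated chains:
    it uses only <R^2> and is therefore biased upward when short end-to-end
    distances are censored from the sample.
    """
    if not lc > 0:
        raise ParameterError(f"lc must be > 0, got {lc}")
    if len(sample) == 0:
        raise EstimationError("empty sample")
    msq = float(np.mean(sample.distances**2))
    if msq >= lc * lc:
        raise EstimationError(
            f"mean square end-to-end ({msq:.3g}) >= L_c^2 ({lc * lc:.3g}): "
            "no finite persistence length (rod limit)"
        )
    lo, hi = 1e-3, 1e6
    if msd_closed_form(lo, lc) > msq:
        raise EstimationError("mean square below the flexible-limit bracket")
    return float(brentq(lambda lp: msd_closed_form(lp, lc) - msq, lo, hi, rtol=1e-6))


def tangent_correlation(traces: Sequence[ChainTrace], s: float) -> float:
    """Mean cosine between tangents separated by arc length ``s`` (nm).

    Averaged over all valid positions in every chain.  Diagnostic for the
    persistence-length convention: for this model it decays as e^{-s/2L_p}.
    """
    if not traces:
        raise ParameterError("traces must be non-empty")
    params = traces[0].params
    if not (0 <= s <= params.contour_length):
        raise ParameterError(f"s must lie in [0, L_c], got {s}")
    k = int(round(s / params.segment_length))
    if k == 0:
        return 1.0
    acc = 0.0
    cnt = 0
    for tr in traces:
        if tr.params != params:
            raise ParameterError("all traces must share the same params")
        h = tr.headings
        d = h[k:] - h[:-k]
        acc += float(np.cos(d).sum())
        cnt += d.size
    return acc / cnt
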