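"""Per-frame dimer geometry, V/O/B/P classification, and movie annotation.

Each movie frame carries up to three landmarks — the two ATPase heads and
the hinge — and optionally a traced polyline for each coiled-coil arm
(hinge to head).  Frames are classified by two engagement thresholds:

* head-head distance <= threshold: the heads are engaged with each other;
* head-hinge distance <= threshold: that head is engaged with the hinge.

The four classes are V (open: nothing engaged), O (heads engaged with each
other), B ("butterfly": both heads engaged with the hinge) and P (exactly
one head engaged with the hinge).  Both thresholds default to 7 nm, the
location of the dip between the engaged peak (~2.4 nm) and the open peak
(~24 nm) in the head-hinge distance distribution.  B takes precedence over
O when all three domains co-locate; ties exactly at a threshold count as
engaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import MissingLandmarkError, ParameterError

__all__ = [
    "ConformationLabel",
    "Thresholds",
    "DimerFrame",
    "MovieAnnotation",
    "head_head_distance",
    "head_hinge_distances",
    "classify_frame",
    "classify_distances",
    "hinge_angle",
    "gaussian_peak",
    "class_frequencies",
    "annotate_movie",
]

logger = logging.getLogger(__name__)


class ConformationLabel(str, Enum):
    V = "V"
    O = "O"
    B = "B"
    P = "P"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class Thresholds:
    """Engagement thresholds (nm) and the chord arc length for hinge angles."""

    head_head_engaged: float = 7.0
    head_hinge_engaged: float = 7.0
    tangent_arc: float = 5.0

    def __post_init__(self):
        for name in ("head_head_engaged", "head_hinge_engaged", "tangent_arc"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class DimerFrame:
    """One movie frame: landmark coordinates in nm, optional arm traces.

    A missing landmark is ``None``.  Arm traces run from the hinge to the
    corresponding head; ``validate_traces`` soft-checks that correspondence
    (localisation noise on the landmarks can legitimately exceed a strict
    tolerance, so inconsistency is reported, not fatal).
    """

    frame_id: int
    time: float
    head1: Optional[Tuple[float, float]] = None
    head2: Optional[Tuple[float, float]] = None
    hinge: Optional[Tuple[float, float]] = None
    arm1_trace: Optional[np.ndarray] = None  # (M, 2), hinge -> head1
    arm2_trace: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("head1", "head2", "hinge"):
            p = getattr(self, name)
            if p is not None:
                p = (float(p[0]), float(p[1]))
                if not (math.isfinite(p[0]) and math.isfinite(p[1])):
                    raise ParameterError(f"frame {self.frame_id}: non-finite {name}")
                setattr(self, name, p)
        for name in ("arm1_trace", "arm2_trace"):
            tr = getattr(self, name)
            if tr is not None:
                tr = np.asarray(tr, dtype=float)
                if tr.ndim != 2 or tr.shape[1] != 2 or tr.shape[0] < 2:
                    raise ParameterError(f"frame {self.frame_id}: {name} must be (M>=2, 2)")
                setattr(self, name, tr)

    def validate_traces(self, tol: float = 1.0) -> bool:
        """True if every present trace starts near the hinge and ends near its head."""
        ok = True
        for tr, head in ((self.arm1_trace, self.head1), (self.arm2_trace, self.head2)):
            if tr is None:
                continue
            if self.hinge is not None and np.hypot(*(tr[0] - np.asarray(self.hinge))) > tol:
                ok = False
            if head is not None and np.hypot(*(tr[-1] - np.asarray(head))) > tol:
                ok = False
        return ok


@dataclass
class MovieAnnotation:
    """Frame labels with class frequencies and transition counts."""

    labels: List[Tuple[int, ConformationLabel]]
    class_frequencies: Dict[ConformationLabel, float]
    transition_counts: Dict[Tuple[ConformationLabel, ConformationLabel], int]
    analyzed_frame_ids: List[int]
    n_unclassified: int = 0


def _require(frame: DimerFrame, *names: str) -> list:
    vals = []
    for name in names:
        v = getattr(frame, name)
        if v is None:
            raise MissingLandmarkError(frame.frame_id, name)
        vals.append(np.asarray(v, dtype=float))
    return vals


def head_head_distance(frame: DimerFrame) -> float:
    """Euclidean head-to-head distance (nm); invariant under rigid motions."""
    h1, h2 = _require(frame, "head1", "head2")
    return float(np.hypot(*(h1 - h2)))


def head_hinge_distances(frame: DimerFrame) -> Tuple[float, float]:
    """Distances from each head to the hinge (nm), in (head1, head2) order."""
    h1, h2, g = _require(frame, "head1", "head2", "hinge")
    return float(np.hypot(*(h1 - g))), float(np.hypot(*(h2 - g)))


def classify_distances(hh: float, g1: float, g2: float, t: Thresholds) -> ConformationLabel:
    """Pure classification rule on the three pairwise distances.

    Exhaustive for any positive thresholds: B if both heads hinge-engaged;
    else O if the heads are mutually engaged; else P if exactly one head is
    hinge-engaged; else V.
    """
    e1 = g1 <= t.head_hinge_engaged
    e2 = g2 <= t.head_hinge_engaged
    if e1 and e2:
        return ConformationLabel.B
    if hh <= t.head_head_engaged:
        return ConformationLabel.O
    if e1 != e2:
        return ConformationLabel.P
    return ConformationLabel.V


def classify_frame(frame: DimerFrame, t: Thresholds = Thresholds()) -> ConformationLabel:
    """Classify one frame; frames with missing landmarks become UNCLASSIFIED."""
    try:
        hh = head_head_distance(frame)
        g1, g2 = head_hinge_distances(frame)
    except MissingLandmarkError as exc:
        logger.debug("frame %s unclassified: %s", frame.frame_id, exc)
        return ConformationLabel.UNCLASSIFIED
    return classify_distances(hh, g1, g2, t)


def _point_at_arc_length(trace: np.ndarray, s: float) -> np.ndarray:
    seg = np.diff(trace, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if s > cum[-1]:
        raise ParameterError(f"arc length {s} exceeds trace length {cum[-1]:.3g}")
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg_len) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    return trace[i] + frac * seg[i]


def hinge_angle(frame: DimerFrame, t: Thresholds = Thresholds()) -> float:
    """Opening angle (degrees, [0, 180]) between the two arms at the hinge.

    Measured between the chord vectors from the hinge vertex to the point
    at arc length ``t.tangent_arc`` along each traced arm.  Chords at a few
    nanometres are used instead of single-segment tangents, which would be
    dominated by tracing noise.
    """
    if frame.arm1_trace is None or frame.arm2_trace is None:
        raise ParameterError(f"frame {frame.frame_id}: hinge angle requires both arm traces")
    vecs = []
    for tr in (frame.arm1_trace, frame.arm2_trace):
        p = _point_at_arc_length(tr, t.tangent_arc)
        v = p - tr[0]
        norm = np.hypot(*v)
        if norm == 0:
            raise ParameterError(f"frame {frame.frame_id}: degenerate chord")
        vecs.append(v / norm)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def gaussian_peak(
    distances: Sequence[float],
    window: Tuple[float, float],
    bin_width: float = 0.5,
) -> Tuple[float, float]:
    """Fit a Gaussian profile to the binned density inside ``window``.

    Returns (mu, sigma) in nm.  Windowing isolates one mode of a bimodal
    distance distribution (engaged vs open populations), so the fitted mu
    recovers the mode location even when the sample is truncated elsewhere.
    Requires at least 20 in-window points.
    """
    d = np.asarray(distances, dtype=float)
    lo, hi = window
    inw = d[(d >= lo) & (d <= hi)]
    if inw.size < 20:
        raise ParameterError(f"only {inw.size} points inside window {window}; need >= 20")
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    counts, edges = np.histogram(inw, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (inw.size * bin_width)
    mu0 = float(np.mean(inw))
    sd0 = float(np.std(inw))
    if sd0 < bin_width / 4 or np.count_nonzero(counts) < 3:
        # effectively a point mass: the histogram carries no shape information
        return mu0, sd0

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    popt, _ = curve_fit(
        gauss, centers, dens, p0=[float(dens.max()), mu0, sd0], maxfev=10_000
    )
    return float(popt[1]), float(abs(popt[2]))


def class_frequencies(
    labels: Sequence[ConformationLabel],
) -> Dict[ConformationLabel, float]:
    """Fractions of each class among classified frames (they sum to 1)."""
    classified = [l for l in labels if l is not ConformationLabel.UNCLASSIFIED]
    if not classified:
        raise ParameterError("no classified frames")
    out: Dict[ConformationLabel, float] = {}
    for lab in (ConformationLabel.V, ConformationLabel.O, ConformationLabel.B, ConformationLabel.P):
        c = sum(1 for l in classified if l is lab)
        if c:
            out[lab] = c / len(classified)
    return out


def annotate_movie(
    frames: Sequence[DimerFrame],
    t: Thresholds = Thresholds(),
    subsample_every: int = 1,
) -> MovieAnnotation:
    """Classify every ``subsample_every``-th frame and count state transitions.

    Transitions are counted only between consecutive *analyzed* frames;
    an UNCLASSIFIED frame breaks the chain on both sides (gaps where the
    conformation could not be confidently assigned contribute nothing).
    """
    if not frames:
        raise ParameterError("empty movie")
    if subsample_every < 1:
        raise ParameterError("subsample_every must be >= 1")
    analyzed = list(frames)[::subsample_every]
    labels = [(f.frame_id, classify_frame(f, t)) for f in analyzed]
    transitions: Dict[Tuple[ConformationLabel, ConformationLabel], int] = {}
    for (_, a), (_, b) in zip(labels, labels[1:]):
        if a is ConformationLabel.UNCLASSIFIED or b is ConformationLabel.UNCLASSIFIED:
            continue
        transitions[(a, b)] = transitions.get((a, b), 0) + 1
    label_values = [l for _, l in labels]
    n_unclassified = sum(1 for l in label_values if l is ConformationLabel.UNCLASSIFIED)
    freqs = class_frequencies(label_values) if n_unclassified < len(label_values) else {}
    return MovieAnnotation(
        labels=labels,
        class_frequencies=freqs,
        transition_counts=transitions,
        analyzed_frame_ids=[f.frame_id for f in analyzed],
        n_unclassified=n_unclassified,
    )
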