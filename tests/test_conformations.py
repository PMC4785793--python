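"""Frame geometry, V/O/B/P classification, hinge angles, peak fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smcflex import (
    ConformationLabel,
    DimerFrame,
    MissingLandmarkError,
    ParameterError,
    Thresholds,
    annotate_movie,
    class_frequencies,
    classify_distances,
    classify_frame,
    gaussian_peak,
    head_head_distance,
    head_hinge_distances,
    hinge_angle,
    truncated_normal,
)

T = Thresholds()


def _frame(head1, head2, hinge, **kw):
    return DimerFrame(frame_id=0, time=0.0, head1=head1, head2=head2, hinge=hinge, **kw)


class TestDistances:
    def test_pythagorean_triple(self):
        f = _frame((0.0, 0.0), (3.0, 4.0), (0.0, 0.0))
        assert head_head_distance(f) == pytest.approx(5.0)

    def test_coincident_heads(self):
        f = _frame((1.0, 1.0), (1.0, 1.0), (0.0, 0.0))
        assert head_head_distance(f) == 0.0

    def test_head_hinge_order_follows_subunits(self):
        f = _frame((0.0, 2.4), (5.0, 0.0), (0.0, 0.0))
        g1, g2 = head_hinge_distances(f)
        assert g1 == pytest.approx(2.4)
        assert g2 == pytest.approx(5.0)
        swapped = _frame(f.head2, f.head1, f.hinge)
        assert head_hinge_distances(swapped) == (g2, g1)

    def test_missing_landmark_raises_with_frame_id(self):
        f = DimerFrame(frame_id=17, time=0.0, head1=(0.0, 0.0))
        with pytest.raises(MissingLandmarkError, match="17"):
            head_head_distance(f)

    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
        reflect=st.booleans(),
    )
    def test_isometry_invariance(self, angle, tx, ty, reflect):
        """Distances, hinge angle and the class label are unchanged by any
        rigid motion (rotation + translation + optional reflection)."""
        pts = np.array([[2.0, 1.0], [20.0, 15.0], [0.0, 0.0]])
        arm = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.0], [2.0, 6.0], [2.0, 11.0]])
        arm2 = np.array([[0.0, 0.0], [5.0, 4.0], [12.0, 9.0], [20.0, 15.0]])
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        if reflect:
            R = R @ np.array([[1.0, 0.0], [0.0, -1.0]])
        t = np.array([tx, ty])
        f0 = _frame(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]),
                    arm1_trace=arm, arm2_trace=arm2)
        f1 = _frame(tuple(pts[0] @ R.T + t), tuple(pts[1] @ R.T + t), tuple(pts[2] @ R.T + t),
                    arm1_trace=arm @ R.T + t, arm2_trace=arm2 @ R.T + t)
        assert head_head_distance(f1) == pytest.approx(head_head_distance(f0), abs=1e-9)
        assert head_hinge_distances(f1) == pytest.approx(head_hinge_distances(f0), abs=1e-9)
        assert hinge_angle(f1) == pytest.approx(hinge_angle(f0), abs=1e-7)
        assert classify_frame(f1) is classify_frame(f0)


class TestClassification:
    @pytest.mark.parametrize(
        "hh,g1,g2,expected",
        [
            (2.5, 25.0, 25.0, ConformationLabel.O),   # heads mutually engaged
            (5.0, 2.4, 2.4, ConformationLabel.B),     # both heads on the hinge
            (30.0, 2.0, 25.0, ConformationLabel.P),   # one head on the hinge
            (30.0, 25.0, 25.0, ConformationLabel.V),  # fully open
            (7.0, 7.0, 7.0, ConformationLabel.B),     # ties count as engaged
            (7.0, 25.0, 25.0, ConformationLabel.O),
        ],
    )
    def test_rule_on_distances(self, hh, g1, g2, expected):
        assert classify_distances(hh, g1, g2, T) is expected

    @given(
        hh=st.floats(0, 100),
        g1=st.floats(0, 100),
        g2=st.floats(0, 100),
        thr=st.floats(0.5, 20),
    )
    def test_quadrants_are_exhaustive_and_exclusive(self, hh, g1, g2, thr):
        t = Thresholds(head_head_engaged=thr, head_hinge_engaged=thr)
        label = classify_distances(hh, g1, g2, t)
        assert label in (
            ConformationLabel.V,
            ConformationLabel.O,
            ConformationLabel.B,
            ConformationLabel.P,
        )

    def test_geometric_frame(self):
        f = _frame((25.0, 0.0), (0.0, 25.0), (0.0, 0.0))
        assert classify_frame(f) is ConformationLabel.V

    def test_missing_landmark_is_unclassified_not_an_error(self):
        f = DimerFrame(frame_id=3, time=0.0, head1=(0.0, 0.0), hinge=(1.0, 1.0))
        assert classify_frame(f) is ConformationLabel.UNCLASSIFIED


class TestHingeAngle:
    @staticmethod
    def _straight(direction, length=10.0, n=11):
        direction = np.asarray(direction, dtype=float)
        direction /= np.linalg.norm(direction)
        return np.outer(np.linspace(0, length, n), direction)

    def test_perpendicular_arms(self):
        f = _frame((10.0, 0.0), (0.0, 10.0), (0.0, 0.0),
                   arm1_trace=self._straight([1, 0]), arm2_trace=self._straight([0, 1]))
        assert hinge_angle(f) == pytest.approx(90.0)

    def test_antiparallel_arms(self):
        f = _frame((10.0, 0.0), (-10.0, 0.0), (0.0, 0.0),
                   arm1_trace=self._straight([1, 0]), arm2_trace=self._straight([-1, 0]))
        assert hinge_angle(f) == pytest.approx(180.0)

    def test_coincident_arms(self):
        f = _frame((10.0, 0.0), (10.0, 0.0), (0.0, 0.0),
                   arm1_trace=self._straight([1, 0]), arm2_trace=self._straight([1, 0]))
        assert hinge_angle(f) == pytest.approx(0.0)

    def test_symmetric_under_arm_swap(self):
        a1, a2 = self._straight([1, 0.3]), self._straight([-0.2, 1])
        f = _frame((10.0, 3.0), (-2.0, 10.0), (0.0, 0.0), arm1_trace=a1, arm2_trace=a2)
        g = _frame((-2.0, 10.0), (10.0, 3.0), (0.0, 0.0), arm1_trace=a2, arm2_trace=a1)
        assert hinge_angle(f) == pytest.approx(hinge_angle(g))
        assert 0.0 <= hinge_angle(f) <= 180.0

    def test_requires_traces(self):
        with pytest.raises(ParameterError):
            hinge_angle(_frame((10.0, 0.0), (0.0, 10.0), (0.0, 0.0)))


class TestGaussianPeak:
    def test_recovers_engaged_peak_from_truncated_draws(self, rng):
        d = truncated_normal(2.5, 1.3, 5000, rng)
        mu, sd = gaussian_peak(d, (0.0, 10.0))
        assert mu == pytest.approx(2.5, abs=0.1)
        assert sd == pytest.approx(1.3, abs=0.15)

    def test_translation_equivariance(self, rng):
        d = truncated_normal(12.0, 1.5, 4000, rng, lower=-np.inf)
        mu0, sd0 = gaussian_peak(d, (6.0, 18.0))
        mu1, sd1 = gaussian_peak(d + 10.0, (16.0, 28.0))
        assert mu1 - mu0 == pytest.approx(10.0, abs=0.05)
        assert sd1 == pytest.approx(sd0, abs=0.05)

    def test_degenerate_point_mass(self):
        mu, sd = gaussian_peak(np.full(50, 4.2), (0.0, 10.0))
        assert mu == pytest.approx(4.2)
        assert sd < 0.5  # below the bin width

    def test_insufficient_window_data_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_peak(np.full(10, 4.2), (0.0, 10.0))


class TestFrequenciesAndAnnotation:
    def test_simple_fractions(self):
        L = ConformationLabel
        freqs = class_frequencies([L.V, L.V, L.O, L.B])
        assert freqs == {L.V: 0.5, L.O: 0.25, L.B: 0.25}

    def test_all_unclassified_rejected(self):
        with pytest.raises(ParameterError):
            class_frequencies([ConformationLabel.UNCLASSIFIED] * 3)

    @staticmethod
    def _movie_from_distances(specs):
        """Frames realising (hh, g1, g2) = spec, or None for missing landmarks."""
        frames = []
        for i, spec in enumerate(specs):
            if spec is None:
                frames.append(DimerFrame(frame_id=i, time=0.1 * i))
                continue
            hh, g1, g2 = spec
            # hinge at origin, head1 on +x; head2 placed by trilateration
            x2 = (g1**2 + g2**2 - hh**2) / (2 * g1) if g1 else 0.0
            y2 = np.sqrt(max(g2**2 - x2**2, 0.0))
            frames.append(
                DimerFrame(frame_id=i, time=0.1 * i, head1=(g1, 0.0),
                           head2=(x2, y2), hinge=(0.0, 0.0))
            )
        return frames

    def test_subsampling_every_fifth_frame(self):
        frames = self._movie_from_distances([(30.0, 25.0, 25.0)] * 50)
        ann = annotate_movie(frames, T, subsample_every=5)
        assert len(ann.analyzed_frame_ids) == 10
        assert ann.analyzed_frame_ids == list(range(0, 50, 5))

    def test_transition_counting(self):
        L = ConformationLabel
        specs = [(2.0, 25.0, 25.0), (2.0, 25.0, 25.0), (3.0, 2.0, 2.0),
                 (3.0, 2.0, 2.0), (30.0, 25.0, 25.0)]  # O O B B V
        ann = annotate_movie(self._movie_from_distances(specs), T)
        assert ann.transition_counts == {
            (L.O, L.O): 1, (L.O, L.B): 1, (L.B, L.B): 1, (L.B, L.V): 1,
        }

    def test_unclassified_gap_breaks_transition_chain(self):
        specs = [(2.0, 25.0, 25.0), None, (2.0, 25.0, 25.0)]
        ann = annotate_movie(self._movie_from_distances(specs), T)
        assert ann.transition_counts == {}
        assert ann.n_unclassified == 1

    def test_empty_movie_rejected(self):
        with pytest.raises(ParameterError):
            annotate_movie([], T)
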