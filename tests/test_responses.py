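"""ΔF/F extraction, responsiveness, directionality index, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipm.core import TrialSet
from tipm.responses import (
    NonPositiveBaselineError,
    assign_subtype,
    classify_responsiveness,
    compute_dff,
    directionality_index,
    first_second_frames,
    impulse_residual,
    phase_windows,
    response_metrics,
)


def trials_from(tonic, arr):
    return TrialSet(0, tonic, np.asarray(arr, dtype=float), tonic.frame_rate)


class TestComputeDff:
    def test_constant_trace_gives_zero_dff_everywhere(self, tonic, flat_trials):
        for phase in ("nose_down", "nose_up"):
            d = compute_dff(flat_trials, tonic, phase)
            assert np.allclose(d.dff_series, 0.0)
            assert d.baseline_value == pytest.approx(10.0)

    def test_simple_arithmetic_baseline_10_response_15(self, tonic):
        F = np.full((2, tonic.n_frames), 10.0)
        (_, _), (r_lo, r_hi) = phase_windows(tonic, "nose_down")
        F[:, r_lo:r_hi] = 15.0
        d = compute_dff(trials_from(tonic, F), tonic, "nose_down")
        assert np.allclose(d.dff_series, 0.5)

    def test_nose_up_baseline_is_last_3s_of_nose_down_response(self, tonic):
        # plant a nose-down window whose tail (12 F-units) differs from the
        # initial baseline (10); the nose-up ΔF/F must use the former
        F = np.full((1, tonic.n_frames), 10.0)
        (_, _), (nd_lo, nd_hi) = phase_windows(tonic, "nose_down")
        tail = int(3 * tonic.frame_rate)
        F[:, nd_hi - tail : nd_hi] = 12.0
        (_, _), (nu_lo, nu_hi) = phase_windows(tonic, "nose_up")
        F[:, nu_lo:nu_hi] = 18.0
        d = compute_dff(trials_from(tonic, F), tonic, "nose_up")
        # hand computation: (18 - 12) / 12 = 0.5
        assert np.allclose(d.dff_series, 0.5)
        assert d.baseline_value == pytest.approx(12.0)

    def test_window_lengths_match_protocol(self, tonic, impulse):
        for phase, seconds, proto in (
            ("nose_down", 15, tonic),
            ("nose_up", 15, tonic),
            ("impulse_1", 30, impulse),
            ("impulse_2", 30, impulse),
        ):
            (_, _), (lo, hi) = phase_windows(proto, phase)
            assert hi - lo == int(seconds * proto.frame_rate)

    def test_zero_baseline_raises_flaggable_error(self, tonic):
        F = np.zeros((2, tonic.n_frames))
        with pytest.raises(NonPositiveBaselineError):
            compute_dff(trials_from(tonic, F), tonic, "nose_down")

    def test_dff_invariant_to_positive_scaling(self, tonic, rng):
        F = rng.uniform(5.0, 15.0, (3, tonic.n_frames))
        a = compute_dff(trials_from(tonic, F), tonic, "nose_down")
        b = compute_dff(trials_from(tonic, 7.3 * F), tonic, "nose_down")
        np.testing.assert_allclose(a.dff_series, b.dff_series, atol=1e-12)


class TestResponsiveness:
    def test_flat_trials_are_unresponsive(self, tonic, flat_trials):
        assert classify_responsiveness(flat_trials, tonic, "nose_down") == (False, "none")

    @pytest.mark.parametrize("n_hot, expected", [(2, True), (1, False), (3, True)])
    def test_at_least_two_trials_criterion(self, tonic, rng, n_hot, expected):
        # baseline jitter sd ~0.1 around 10; hot trials get first-second mean
        # at baseline + 3 sd
        F = 10.0 + 0.1 * rng.standard_normal((3, tonic.n_frames))
        (b_lo, b_hi), (r_lo, _) = phase_windows(tonic, "nose_down")
        k = first_second_frames(tonic.frame_rate)
        for i in range(n_hot):
            sd = F[i, b_lo:b_hi].std()
            F[i, r_lo : r_lo + k] = F[i, b_lo:b_hi].mean() + 3 * sd
        responsive, pattern = classify_responsiveness(trials_from(tonic, F), tonic, "nose_down")
        assert responsive is expected
        assert pattern == ("excitation" if expected else "none")

    def test_zero_variance_zero_response_is_unresponsive_not_error(self, tonic, flat_trials):
        responsive, _ = classify_responsiveness(flat_trials, tonic, "nose_down")
        assert responsive is False

    def test_suppression_recovery_pattern(self, tonic):
        F = np.full((3, tonic.n_frames), 10.0)
        F += np.random.default_rng(0).normal(0, 0.05, F.shape)
        (_, _), (r_lo, r_hi) = phase_windows(tonic, "nose_down")
        k3 = int(3 * tonic.frame_rate)
        F[:, r_lo : r_lo + k3] = 8.0  # dip well below baseline
        F[:, r_hi - int(5 * tonic.frame_rate) : r_hi] = 10.8  # above-baseline recovery
        responsive, pattern = classify_responsiveness(trials_from(tonic, F), tonic, "nose_down")
        assert responsive is False
        assert pattern == "suppression_recovery"

    def test_responsiveness_uses_raw_f_not_dff(self, tonic, rng):
        # scaling the whole trace leaves both ΔF/F and the 2-sd criterion
        # unchanged (both are scale-free), but adding a constant changes
        # ΔF/F while leaving raw-F differences intact: the criterion must
        # follow the raw trace
        F = 10.0 + 0.1 * rng.standard_normal((3, tonic.n_frames))
        (b_lo, b_hi), (r_lo, _) = phase_windows(tonic, "nose_down")
        k = first_second_frames(tonic.frame_rate)
        F[:, r_lo : r_lo + k] += 1.0  # strong raw-F excursion
        shifted = F + 1000.0  # ΔF/F shrinks ~100-fold; raw criterion unaffected
        r1, _ = classify_responsiveness(trials_from(tonic, F), tonic, "nose_down")
        r2, _ = classify_responsiveness(trials_from(tonic, shifted), tonic, "nose_down")
        assert r1 is True and r2 is True


class TestDirectionalityIndex:
    @pytest.mark.parametrize(
        "up, down, expected",
        [(1.0, 1.0, 0.0), (0.0, 0.7, -1.0), (0.7, 0.0, 1.0), (0.3, 0.1, 0.5)],
    )
    def test_known_values(self, up, down, expected):
        assert directionality_index(up, down) == pytest.approx(expected)

    def test_threshold_corresponds_to_22_percent_difference(self):
        # (u - d)/(u + d) = 0.1  =>  u/d = 11/9, i.e. u exceeds d by ~22%
        u, d = 11.0, 9.0
        assert directionality_index(u, d) == pytest.approx(0.1)
        assert (u / d - 1.0) * 100 == pytest.approx(22.2, abs=0.05)

    def test_both_zero_is_undefined(self):
        assert np.isnan(directionality_index(0.0, 0.0))

    def test_suppression_floored_to_zero(self):
        assert directionality_index(-0.5, 1.0) == pytest.approx(-1.0)

    @given(
        up=st.floats(0, 1e6, allow_nan=False),
        down=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_antisymmetric(self, up, down):
        di = directionality_index(up, down)
        if up + down == 0:
            assert np.isnan(di)
        else:
            assert -1.0 <= di <= 1.0
            assert directionality_index(down, up) == pytest.approx(-di, abs=1e-12)


class TestAssignSubtype:
    @pytest.mark.parametrize(
        "di, expected",
        [
            (0.5, "nose_up"),
            (-0.5, "nose_down"),
            (0.1, "none"),  # strict inequality at the threshold
            (-0.1, "none"),
            (0.100001, "nose_up"),
            (float("nan"), "none"),
        ],
    )
    def test_threshold_logic(self, di, expected):
        assert assign_subtype(di) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            assign_subtype(0.5, threshold=-0.1)

    @pytest.mark.parametrize("threshold", [0.0, 0.2])
    def test_strongly_tuned_calls_stable_under_threshold_changes(self, threshold):
        # eliminating or doubling the threshold leaves strongly tuned calls intact
        assert assign_subtype(0.8, threshold) == "nose_up"
        assert assign_subtype(-0.8, threshold) == "nose_down"


class TestResponseMetrics:
    def test_trapezoidal_integral_unit_spacing(self):
        dff = np.array([[0.0, 1.0, 2.0]] * 2)
        m = response_metrics(dff, frame_rate=3.0)
        assert m.integral == pytest.approx(2.0)  # 0/2 + 1 + 2/2

    def test_identical_repeats_have_zero_cv(self):
        dff = np.tile(np.linspace(0, 1, 45), (3, 1))
        assert response_metrics(dff, 3.0).cv == pytest.approx(0.0)

    def test_cv_hand_computation(self):
        # first-second means 1.0, 1.2, 0.8 -> sd/mean = 0.16330/1.0
        dff = np.array([[1.0] * 3, [1.2] * 3, [0.8] * 3])
        m = response_metrics(dff, 3.0)
        assert m.cv == pytest.approx(0.16330, abs=1e-4)

    def test_literal_cv_variant_is_reciprocal(self):
        dff = np.array([[1.0] * 3, [1.2] * 3, [0.8] * 3])
        conventional = response_metrics(dff, 3.0).cv
        literal = response_metrics(dff, 3.0, literal_cv=True).cv
        assert literal == pytest.approx(1.0 / conventional)

    def test_consistency_flags_sign_flips(self):
        dff = np.array([[1.0] * 3, [-1.0] * 3])
        assert response_metrics(dff, 3.0).consistent is False


class TestImpulseResidual:
    def test_zero_impulse_gives_fraction_one(self):
        tonic = np.linspace(1, 0, 45)
        residual, frac = impulse_residual(tonic, np.zeros(45), 3.0)
        np.testing.assert_allclose(residual, tonic)
        assert frac == pytest.approx(1.0)

    def test_identical_gives_fraction_zero(self):
        tonic = np.linspace(1, 0, 45)
        residual, frac = impulse_residual(tonic, tonic, 3.0)
        assert np.allclose(residual, 0.0)
        assert frac == pytest.approx(0.0)

    def test_arithmetic_fraction(self):
        tonic = np.full(45, 2.0)
        imp = np.full(45, 0.5)
        _, frac = impulse_residual(tonic, imp, 3.0)
        assert frac == pytest.approx(0.75)

    def test_zero_tonic_flagged_nan(self):
        _, frac = impulse_residual(np.zeros(45), np.ones(45), 3.0)
        assert np.isnan(frac)
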