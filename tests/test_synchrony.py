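import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import (
    FeatureSequence,
    ReconstructionTrace,
    TrainingConfig,
    analyse_session,
    fit_slope,
    frame_rmse,
    pearson_correlation,
    summarize_group,
)
from dyadsync.synchrony import (
    DegenerateRegressionError,
    UndefinedCorrelationError,
    mean_first_difference_per_step,
)
from dyadsync.synthetic_data import DyadGeneratorConfig, generate_dyad


def trace(y, times=None):
    y = np.asarray(y, dtype=float)
    t = np.linspace(0.0, 1.0, len(y)) if times is None else np.asarray(times)
    return ReconstructionTrace(rmse=y, times=t)


class TestFrameRmse:
    def test_perfect_reconstruction_gives_zero_trace(self, toy_sequence):
        out = frame_rmse(toy_sequence, toy_sequence)
        np.testing.assert_array_equal(out.rmse, 0.0)

    def test_hand_evaluated_frame(self):
        orig = FeatureSequence(values=np.array([[0.0, 0.0]]))
        recon = FeatureSequence(values=np.array([[3.0, 4.0]]))
        out = frame_rmse(orig, recon)
        assert out.rmse[0] == pytest.approx(np.sqrt(25 / 2), abs=1e-4)  # 3.5355

    def test_one_dimensional_frame(self):
        orig = FeatureSequence(values=np.array([[1.0]]))
        recon = FeatureSequence(values=np.array([[0.0]]))
        assert frame_rmse(orig, recon).rmse[0] == 1.0

    def test_shape_mismatch_rejected(self, toy_sequence):
        other = FeatureSequence(values=toy_sequence.values[:, :2])
        with pytest.raises(ValueError, match="shape"):
            frame_rmse(toy_sequence, other)


class TestFitSlope:
    def test_constant_trace_zero_slope_both_methods(self):
        tr = trace([2.0, 2.0, 2.0, 2.0])
        assert fit_slope(tr, "ols").slope == 0.0
        assert fit_slope(tr, "mean_first_difference").slope == 0.0

    def test_exact_linear_trace(self):
        res = fit_slope(trace([0.0, 1.0, 2.0, 3.0]), "ols")
        assert res.slope == pytest.approx(3.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_checked_ols_case(self):
        res = fit_slope(trace([3.0, 1.0, 2.0, 0.0]), "ols")
        assert res.slope == pytest.approx(-2.4, abs=1e-12)

    def test_mean_first_difference_telescopes_exactly(self):
        y = np.random.default_rng(0).uniform(size=17)
        tr = trace(y)
        assert mean_first_difference_per_step(tr) == (y[-1] - y[0]) / 16
        assert fit_slope(tr, "mean_first_difference").slope == y[-1] - y[0]

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises((DegenerateRegressionError, ValueError)):
            fit_slope(trace([1.0], times=[0.0]))

    @given(st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_ols_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 1000)
        y = rng.normal(size=n)
        times = np.sort(rng.uniform(0, 100, size=n))
        times += np.arange(n) * 1e-6  # strict monotonicity
        tr = ReconstructionTrace(rmse=np.abs(y), times=times)
        res = fit_slope(tr, "ols")
        t = (times - times[0]) / (times[-1] - times[0])
        design = np.column_stack([np.ones(n), t])
        beta = np.linalg.solve(design.T @ design, design.T @ np.abs(y))
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)

    @given(st.floats(-5, 5), st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_constant_offset_changes_intercept_only(self, c, seed):
        y = np.abs(np.random.default_rng(seed).normal(size=20))
        base = fit_slope(trace(y), "ols")
        shifted = fit_slope(trace(y + abs(c)), "ols")
        assert shifted.slope == pytest.approx(base.slope, abs=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + abs(c), abs=1e-10)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (2, 1, 4, 3), 0.6),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_numpy_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 50))
            assert pearson_correlation(x, y) == pytest.approx(
                np.corrcoef(x, y)[0, 1], abs=1e-12
            )


class TestSummarizeGroup:
    def test_hand_computed_aggregate(self):
        g = summarize_group("C1", [(-0.1, -0.2), (-0.3, -0.4)])
        assert g.average_slope == pytest.approx(-0.25)
        assert g.pcc_of_pairs == pytest.approx(1.0)
        assert g.n_sessions == 2

    def test_single_session_pcc_undefined(self):
        with pytest.warns(UserWarning, match="PCC undefined"):
            g = summarize_group("C1", [(-0.1, -0.2)])
        assert g.average_slope == pytest.approx(-0.15)
        assert np.isnan(g.pcc_of_pairs)
        with pytest.raises(UndefinedCorrelationError):
            summarize_group("C1", [(-0.1, -0.2)], require_pcc=True)

    def test_antisymmetric_pairs(self):
        g = summarize_group("C1", [(-0.1, 0.1), (0.1, -0.1)])
        assert g.average_slope == pytest.approx(0.0)
        assert g.pcc_of_pairs == pytest.approx(-1.0)

    def test_invariant_to_session_order(self, rng):
        pairs = [tuple(p) for p in rng.normal(size=(6, 2))]
        a = summarize_group("g", pairs)
        b = summarize_group("g", pairs[::-1])
        assert a.average_slope == pytest.approx(b.average_slope, abs=1e-12)
        assert a.pcc_of_pairs == pytest.approx(b.pcc_of_pairs, abs=1e-12)


class TestAnalyseSession:
    EPOCHS = 32

    def _slopes(self, kappa, seeds):
        out = []
        for seed in seeds:
            session, _, _ = generate_dyad(
                DyadGeneratorConfig(convergence_rate=kappa, seed=seed)
            )
            a = analyse_session(session, TrainingConfig(epochs=self.EPOCHS, seed=seed))
            out.append(a.slope_pair)
        return np.asarray(out)

    def test_converging_dyads_yield_negative_partner_slopes(self):
        # slope of B's trace under A's model responds to B's drift toward A
        slopes = self._slopes(0.8, range(10))
        assert (slopes[:, 1] < 0).sum() >= 8

    def test_static_dyads_have_mean_slope_near_zero(self):
        slopes = self._slopes(0.0, range(10)).ravel()
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 2 * se + 0.05

    def test_mean_slope_monotone_in_convergence_rate(self):
        means = [self._slopes(k, range(6)).mean() for k in (0.0, 0.4, 0.8)]
        assert means[0] > means[1] > means[2]

    def test_traces_and_models_retrievable(self):
        session, _, _ = generate_dyad(DyadGeneratorConfig(convergence_rate=0.5, seed=0))
        a = analyse_session(session, TrainingConfig(epochs=4, seed=0))
        assert len(a.trace_b_under_a) == session.features_b.n_frames
        assert a.ae_a.architecture.input_dim == session.features_a.n_dims
        assert a.slope_b_under_a.method == "ols"
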