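import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptvmargin.correlation import (
    CohortCovarianceRow,
    PairedSeries,
    cohort_covariance,
    covariance,
    distance_correlation,
    estimate_fraction_covariance,
    pair_streams,
    patient_covariance_extrema,
    pearson,
)
from ptvmargin.exceptions import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from ptvmargin.logio import CohortLog

from conftest import make_log


def series_from_xy(x, y):
    """1-D pairs embedded in the SI direction (LR/AP carry mirrored data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return PairedSeries(
        model=np.column_stack([x, x, x]),
        prediction=np.column_stack([y, y, y]),
        pairing_rule="nearest_in_time",
    )


def dcorr_bruteforce(x, y):
    """Independent O(n^2) double-centering oracle, plain Python loops."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)] for i in range(n)]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvx * dvy))


class TestPairStreams:
    def test_nearest_tie_goes_earlier(self):
        log = make_log(
            [(1.0, 1.0, 1.0)],
            [(5.0, 5.0, 5.0), (7.0, 7.0, 7.0)],
            model_times=[60.0],
            prediction_times=[59.98, 60.02],
        )
        pairs = pair_streams(log, "nearest_in_time")
        assert pairs.n_pairs == 1
        assert pairs.prediction[0, 0] == 5.0  # earlier sample wins the tie

    def test_single_model_sample_one_pair(self):
        log = make_log([(0.5, 0.5, 0.5)], [0.1, 0.2, 0.3], model_times=[60.0])
        pairs = pair_streams(log, "nearest_in_time")
        assert pairs.n_pairs == 1

    def test_window_mean_constant_prediction(self):
        log = make_log(
            [0.1, 0.2, 0.3],
            [(0.7, 0.7, 0.7)] * 30,
            model_times=[10.0, 20.0, 30.0],
            prediction_times=[float(t + 1) for t in range(30)],
        )
        pairs = pair_streams(log, "window_mean")
        assert pairs.n_pairs == 3
        assert np.allclose(pairs.prediction, 0.7)

    def test_window_mean_exact_means(self):
        log = make_log(
            [0.0, 0.0],
            [1.0, 3.0, 5.0, 7.0],
            model_times=[2.0, 4.0],
            prediction_times=[1.0, 2.0, 3.0, 4.0],
        )
        pairs = pair_streams(log, "window_mean")
        # windows (0, 2] -> {1, 3}, (2, 4] -> {5, 7}
        assert np.allclose(pairs.prediction[:, 0], [2.0, 6.0])

    def test_empty_stream_errors(self):
        log = make_log([], [0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            pair_streams(log)

    def test_unknown_rule(self, small_log):
        with pytest.raises(DomainError):
            pair_streams(small_log, "bogus")


class TestPearson:
    def test_identity_r_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert np.allclose(pearson(series_from_xy(x, x)), 1.0)

    def test_negative_slope_r_minus_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert np.allclose(pearson(series_from_xy(x, -2 * x)), -1.0)

    def test_hand_zero_correlation(self):
        # pairs (0,0),(1,1),(2,0): cross products (-1)(-1/3) + 0 + (1)(-1/3) = 0
        r = pearson(series_from_xy([0, 1, 2], [0, 1, 0]))
        assert np.allclose(r, 0.0, atol=1e-15)

    def test_constant_marginal_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(series_from_xy([0, 1, 2], [5, 5, 5]))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            pearson(series_from_xy([0, 1], [0, 1]))

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=20),
        st.floats(0.1, 5.0),
        st.floats(-3, 3),
        st.floats(0.1, 5.0),
        st.floats(-3, 3),
    )
    def test_affine_invariance(self, y, a1, b1, a2, b2):
        x = np.arange(len(y), dtype=float)
        y = np.asarray(y)
        try:
            base = pearson(series_from_xy(x, y))
        except UndefinedCorrelationError:
            return
        pos = pearson(series_from_xy(a1 * x + b1, a2 * y + b2))
        neg = pearson(series_from_xy(a1 * x + b1, -a2 * y + b2))
        assert np.allclose(pos, base, atol=1e-8)
        assert np.allclose(neg, -base, atol=1e-8)


class TestCovariance:
    def test_zero_r(self):
        assert covariance(1.3, 2.1, 0.0) == 0.0

    def test_unit(self):
        assert covariance(1.0, 1.0, 1.0) == 1.0

    def test_hand_product(self):
        assert covariance(0.8, 0.6, -0.5) == pytest.approx(-0.24)

    def test_r_out_of_range(self):
        with pytest.raises(DomainError):
            covariance(1.0, 1.0, 1.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 5), st.floats(0, 5), st.floats(-1, 1))
    def test_cauchy_schwarz_bound(self, sm, sp, r):
        assert abs(covariance(sm, sp, r)) <= sm * sp + 1e-12


class TestDistanceCorrelation:
    def test_linear_pair_is_one(self):
        x = np.array([0.0, 0.5, 1.5, 2.0, 4.0])
        d = distance_correlation(series_from_xy(x, 3 * x + 1))
        assert np.allclose(d, 1.0, atol=1e-12)

    def test_constant_marginal_is_zero(self):
        d = distance_correlation(series_from_xy([0, 1, 2, 3], [5, 5, 5, 5]))
        assert np.allclose(d, 0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            impl = distance_correlation(series_from_xy(x, y))[0]
            oracle = dcorr_bruteforce(x.tolist(), y.tolist())
            assert impl == pytest.approx(oracle, abs=1e-10)

    def test_translation_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.3 * x
        base = distance_correlation(series_from_xy(x, y))
        moved = distance_correlation(series_from_xy(2.5 * x - 7.0, 0.2 * y + 11.0))
        assert np.allclose(base, moved, atol=1e-10)

    def test_range(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x, y = rng.normal(size=(2, 30))
            d = distance_correlation(series_from_xy(x, y))
            assert np.all(d >= 0) and np.all(d <= 1)


class TestFractionEstimate:
    def test_estimate_respects_cauchy_schwarz(self, small_log):
        est = estimate_fraction_covariance(small_log)
        assert np.all(np.abs(est.cov) <= est.sd_model * est.sd_pred + 1e-12)
        assert np.all(np.abs(est.pearson_r) <= 1)
        assert np.all((est.dcorr >= 0) & (est.dcorr <= 1))

    def test_constant_stream_reported_missing(self):
        log = make_log(
            [0.1, -0.2, 0.3, 0.0], [(0.5, 0.5, 0.5)] * 6,
            model_times=[1.0, 2.0, 3.0, 4.0],
            prediction_times=[1.0, 1.5, 2.0, 2.5, 3.0, 4.0],
        )
        est = estimate_fraction_covariance(log)
        assert np.all(np.isnan(est.pearson_r))
        assert np.all(np.isnan(est.cov))
        assert np.allclose(est.dcorr, 0.0)


class TestCohortAggregation:
    def _one_fraction_cohort(self, covs_by_patient):
        """Build a cohort whose per-fraction covariances are exactly controlled.

        Uses y = r * x data with unit-ish SDs so cov = r * sd_x * sd_y.
        """
        fracs = []
        x = np.array([-1.5, -0.5, 0.5, 1.5])
        for pid, rs in covs_by_patient.items():
            for k, r in enumerate(rs):
                y = r * x if r != 0 else np.array([0.5, -0.5, 0.5, -0.5])
                fracs.append(
                    make_log(
                        np.column_stack([x, x, x]),
                        np.column_stack([y, y, y]),
                        patient_id=pid,
                        fraction_index=k + 1,
                        model_times=[1.0, 2.0, 3.0, 4.0],
                        prediction_times=[1.0, 2.0, 3.0, 4.0],
                    )
                )
        return CohortLog(fractions=fracs)

    def test_single_patient_single_fraction(self):
        cohort = self._one_fraction_cohort({"P1": [1.0]})
        est = estimate_fraction_covariance(cohort.fractions[0])
        rows = {(r.site, r.direction): r for r in cohort_covariance(cohort)}
        row = rows[("lower_left_lung", "SI")]
        assert row.avg_max_cov == pytest.approx(est.cov[0])
        assert row.avg_max_r == pytest.approx(1.0)

    def test_sign_cancellation_across_patients(self):
        cohort = self._one_fraction_cohort({"P1": [1.0], "P2": [-1.0]})
        rows = {(r.site, r.direction): r for r in cohort_covariance(cohort)}
        assert rows[("lower_left_lung", "SI")].avg_max_cov == pytest.approx(0.0, abs=1e-12)

    def test_max_by_magnitude_keeps_sign(self):
        # enumeration oracle over per-fraction covariances {+0.1c, -0.4c, +0.2c}
        cohort = self._one_fraction_cohort({"P1": [0.1, -0.4, 0.2]})
        fracs = cohort.by_patient()["P1"]
        covs = [estimate_fraction_covariance(f).cov[0] for f in fracs]
        expected = max(covs, key=abs)
        assert expected < 0
        extrema = patient_covariance_extrema(fracs)
        assert extrema["SI"]["max_cov"] == pytest.approx(expected)
        rows = {(r.site, r.direction): r for r in cohort_covariance(cohort)}
        assert rows[("lower_left_lung", "SI")].avg_max_cov == pytest.approx(expected)

    def test_all_undefined_raises(self):
        log = make_log([(0.1, 0.1, 0.1)] * 4, [(0.5, 0.5, 0.5)] * 4)
        with pytest.raises(InsufficientDataError):
            cohort_covariance(CohortLog(fractions=[log]))
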