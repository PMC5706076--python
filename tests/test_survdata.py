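"""Partial-likelihood building blocks: risk sets, null scores, penalty grid."""

import numpy as np
import pytest

from stabselcox import (
    SurvivalDataset,
    build_failure_index,
    compute_lambda_upper,
    compute_working_response,
    make_lambda_grid,
    neg_log_partial_likelihood,
    read_survival_csv,
    write_survival_csv,
)

from conftest import random_dataset


def brute_force_scores(times, events, strict=False):
    """Literal enumeration of risk sets and prior-failure sets."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    ft = sorted(set(times[events == 1]))
    if strict:
        s = [sum(1 for y in times if y > t) for t in ft]
        in_C = lambda t, y: t < y
    else:
        s = [sum(1 for y in times if y >= t) for t in ft]
        in_C = lambda t, y: t <= y
    scores = []
    for k in range(len(times)):
        acc = float(events[k])
        for i, t in enumerate(ft):
            if in_C(t, times[k]) and s[i] > 0:
                acc -= 1.0 / s[i]
        scores.append(acc)
    return np.array(scores)


class TestFailureIndex:
    def test_two_event_case(self, two_event_dataset):
        idx = build_failure_index(two_event_dataset)
        assert idx.m == 2
        assert set(idx.risk_sets[0]) == {0, 1}
        assert set(idx.risk_sets[1]) == {1}

    def test_censored_excluded_from_failure_times(self):
        ds = SurvivalDataset(
            X=np.zeros((3, 1)), times=[1, 2, 3], events=[1, 0, 1]
        )
        idx = build_failure_index(ds)
        np.testing.assert_array_equal(idx.failure_times, [1.0, 3.0])
        assert set(idx.risk_sets[0]) == {0, 1, 2}
        assert set(idx.risk_sets[1]) == {2}

    def test_single_failure(self):
        ds = SurvivalDataset(
            X=np.zeros((4, 1)), times=[5, 1.5, 8, 0.7], events=[0, 1, 0, 0]
        )
        idx = build_failure_index(ds)
        assert idx.m == 1
        assert set(idx.risk_sets[0]) == {0, 1, 2}  # y_j >= 1.5

    def test_risk_set_nesting(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ds = random_dataset(rng, n=int(rng.integers(3, 15)), p=2)
            idx = build_failure_index(ds)
            for a, b in zip(idx.risk_sets, idx.risk_sets[1:]):
                assert set(b) <= set(a)
            for failers, risk in zip(idx.failer_index, idx.risk_sets):
                assert set(failers) <= set(risk)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no observed events"):
            SurvivalDataset(X=np.zeros((2, 1)), times=[1, 2], events=[0, 0])


class TestNegLogPartialLikelihood:
    def test_zero_beta_gives_log_risk_set_sizes(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, n=20, p=3)
        idx = build_failure_index(ds)
        expected = sum(np.log(len(r)) for r in idx.risk_sets)
        assert neg_log_partial_likelihood(ds, np.zeros(3)) == pytest.approx(
            expected
        )

    def test_two_event_hand_value(self, two_event_dataset):
        assert neg_log_partial_likelihood(
            two_event_dataset, [0.0]
        ) == pytest.approx(np.log(2))

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n=25, p=2)
        beta = np.array([0.7, -0.3])
        shifted = SurvivalDataset(
            X=ds.X + np.array([5.0, 0.0]), times=ds.times, events=ds.events
        )
        assert neg_log_partial_likelihood(ds, beta) == pytest.approx(
            neg_log_partial_likelihood(shifted, beta)
        )

    def test_nonfinite_beta_rejected(self, two_event_dataset):
        with pytest.raises(ValueError, match="non-finite"):
            neg_log_partial_likelihood(two_event_dataset, [np.nan])


class TestWorkingResponse:
    def test_hand_example(self, two_event_dataset):
        wr = compute_working_response(two_event_dataset)
        np.testing.assert_array_equal(wr.risk_counts, [2, 1])
        np.testing.assert_allclose(wr.score, [0.5, -0.5])

    def test_late_censored_observation_negative_score(self):
        ds = SurvivalDataset(
            X=np.zeros((3, 1)), times=[1, 2, 10], events=[1, 1, 0]
        )
        wr = compute_working_response(ds)
        assert wr.score[2] < 0
        assert wr.score[2] == pytest.approx(-(1 / 3 + 1 / 2))

    def test_scores_sum_to_zero_inclusive(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ds = random_dataset(rng, n=int(rng.integers(4, 30)), p=2)
            wr = compute_working_response(ds)
            assert wr.score.sum() == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_brute_force_oracle(self, strict):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            ds = random_dataset(
                rng,
                n=int(rng.integers(2, 13)),
                p=int(rng.integers(1, 5)),
                censor_frac=float(rng.uniform(0, 0.6)),
            )
            wr = compute_working_response(ds, strict=strict)
            np.testing.assert_allclose(
                wr.score,
                brute_force_scores(ds.times, ds.events, strict=strict),
                atol=1e-12,
            )

    def test_zero_weight_implies_score_is_event_flag(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ds = random_dataset(rng, n=10, p=2)
            wr = compute_working_response(ds)
            assert np.all(wr.weights >= 0)
            for k in np.flatnonzero(wr.weights == 0):
                if len(wr.prior_time_sets[k]) == 0:
                    assert wr.score[k] == ds.events[k]


class TestLambdaUpper:
    def test_hand_example(self, two_event_dataset):
        assert compute_lambda_upper(two_event_dataset) == pytest.approx(0.5)

    def test_duplicate_column_unchanged(self):
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, n=30, p=3)
        dup = SurvivalDataset(
            X=np.hstack([ds.X, ds.X[:, :1]]), times=ds.times, events=ds.events
        )
        assert compute_lambda_upper(dup) == pytest.approx(
            compute_lambda_upper(ds)
        )

    def test_zero_column_contributes_nothing(self):
        rng = np.random.default_rng(10)
        ds = random_dataset(rng, n=30, p=2)
        padded = SurvivalDataset(
            X=np.hstack([ds.X, np.zeros((30, 1))]),
            times=ds.times,
            events=ds.events,
        )
        assert compute_lambda_upper(padded) == pytest.approx(
            compute_lambda_upper(ds)
        )

    def test_degenerate_warns(self):
        ds = SurvivalDataset(
            X=np.zeros((4, 2)), times=[1, 2, 3, 4], events=[1, 1, 0, 1]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_lambda_upper(ds) == 0.0


class TestLambdaGrid:
    def test_high_dimensional_example(self):
        grid = make_lambda_grid(1.0, n=50, p=100, K=2)
        np.testing.assert_allclose(grid.values, [1.0, np.sqrt(0.05), 0.05])

    def test_low_dimensional_ratio(self):
        grid = make_lambda_grid(2.5, n=200, p=10, K=40)
        assert grid.values[-1] / grid.values[0] == pytest.approx(1e-4)

    def test_exactly_geometric(self):
        grid = make_lambda_grid(0.8, n=30, p=50, K=25)
        logs = np.log(grid.values)
        np.testing.assert_allclose(np.diff(logs), np.diff(logs)[0], rtol=1e-12)

    def test_zero_K_rejected(self):
        with pytest.raises(ValueError):
            make_lambda_grid(1.0, n=10, p=5, K=0)

    def test_truncate_appends_exact_floor(self):
        grid = make_lambda_grid(1.0, n=100, p=5, K=10)
        trunc = grid.truncate(0.123)
        assert trunc.values[-1] == pytest.approx(0.123)
        assert np.all(trunc.values >= 0.123 - 1e-12)


def test_csv_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    ds = random_dataset(rng, n=15, p=4)
    path = tmp_path / "data.csv"
    write_survival_csv(ds, path)
    back = read_survival_csv(path)
    np.testing.assert_allclose(back.X, ds.X)
    np.testing.assert_allclose(back.times, ds.times)
    np.testing.assert_array_equal(back.events, ds.events)
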