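"""Pseudo-subjects, netmats, cross-diagonals, resampling, timepoint tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocross import (
    DEFAULT_NETWORKS,
    EstimatorConfig,
    NodeTimeSeries,
    build_pseudo_subject,
    compare_timepoints,
    compute_netmat,
    cross_diagonal,
    fisher_z,
    resample_cross_group,
)
from neurocross.crossnet import Z_MAX, aggregate_trials, iter_trial_pairings
from neurocross.errors import (
    ComparisonError,
    ConfigurationError,
    EstimationError,
    PairingError,
    ResamplingError,
)

NAMES = DEFAULT_NETWORKS


def make_ts(rng, sid="s", T=305, N=7, names=NAMES):
    return NodeTimeSeries(sid, rng.standard_normal((T, N)), names[:N])


def group_ts(cohort, group):
    return [r.node_ts for r in cohort if r.group == group]


class TestBuildPseudoSubject:
    def test_shapes_and_standardization(self, rng):
        ps = build_pseudo_subject(make_ts(rng, "a"), make_ts(rng, "b"))
        assert ps.data.shape == (305, 14)
        assert np.allclose(ps.data.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(ps.data.std(axis=0), 1, atol=1e-10)
        assert ps.source_pair == ("a", "b")

    def test_identity_pairing_cross_block_is_within_correlation(self, rng):
        ts = make_ts(rng)
        ps = build_pseudo_subject(ts, ts)
        nm = compute_netmat(ps, estimator="full", fisher=False)
        within = np.corrcoef(ts.standardize().data, rowvar=False)
        assert np.allclose(nm.matrix[:7, 7:], within, atol=1e-10)
        assert np.allclose(cross_diagonal(nm), 1.0)

    def test_volume_mismatch_raises(self, rng):
        with pytest.raises(PairingError, match="volume"):
            build_pseudo_subject(make_ts(rng, T=305), make_ts(rng, T=300))

    def test_node_order_mismatch_raises_not_reorders(self, rng):
        a = make_ts(rng)
        b = NodeTimeSeries("b", rng.standard_normal((305, 7)), NAMES[::-1])
        with pytest.raises(PairingError, match="node order"):
            build_pseudo_subject(a, b)


def partial_corr_by_regression(x):
    """Independent oracle: partial correlation via residuals of OLS on the
    remaining variables."""
    n = x.shape[1]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            if others:
                Z = np.column_stack([x[:, others], np.ones(len(x))])
                ri = x[:, i] - Z @ np.linalg.lstsq(Z, x[:, i], rcond=None)[0]
                rj = x[:, j] - Z @ np.linalg.lstsq(Z, x[:, j], rcond=None)[0]
            else:
                ri, rj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestComputeNetmat:
    def test_partial_detects_conditional_dependence(self, rng):
        # x3 = x1 + x2 + noise: marginally r(x1,x2)~0 but partial strongly negative
        T = 2000
        x1, x2 = rng.standard_normal(T), rng.standard_normal(T)
        x3 = x1 + x2 + 0.1 * rng.standard_normal(T)
        x4 = rng.standard_normal(T)  # even count for the pseudo-subject API
        ts_a = NodeTimeSeries("a", np.column_stack([x1, x2]), ("n1", "n2"))
        ts_b = NodeTimeSeries("b", np.column_stack([x3, x4]), ("n1", "n2"))
        ps = build_pseudo_subject(ts_a, ts_b)
        nm = compute_netmat(ps, estimator="partial", ridge_rho=0.0, fisher=False)
        oracle = partial_corr_by_regression(ps.data)
        assert np.abs(nm.matrix - oracle).max() < 1e-8
        assert nm.matrix[0, 1] < -0.8  # x1 vs x2 given x3
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 0.1

    def test_independent_columns_have_near_zero_offdiagonals(self, rng):
        ts_a = make_ts(rng, T=10000)
        ts_b = make_ts(rng, "b", T=10000)
        nm = compute_netmat(
            build_pseudo_subject(ts_a, ts_b), estimator="full", fisher=False
        )
        off = nm.matrix[~np.eye(14, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_fisher_of_zero_is_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_fisher_clipping_keeps_values_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(Z_MAX)
        assert fisher_z(-1.0) == pytest.approx(-Z_MAX)

    def test_singular_covariance_without_ridge_raises(self, rng):
        x = rng.standard_normal((40, 7))
        dup = np.column_stack([x, x[:, 0]])  # duplicate column -> singular
        ts_a = NodeTimeSeries("a", dup[:, :4], ("a", "b", "c", "d"))
        ts_b = NodeTimeSeries("b", dup[:, 4:], ("a", "b", "c", "d"))
        ps = build_pseudo_subject(ts_a, ts_b)
        with pytest.raises(EstimationError, match="ridge"):
            compute_netmat(ps, estimator="partial", ridge_rho=0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partial_rho0_matches_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))  # halves of 2..3 nodes -> 4..6 total
        x = rng.standard_normal((1000, 2 * n)) @ rng.standard_normal((2 * n, 2 * n))
        names = tuple(f"n{i}" for i in range(n))
        ps = build_pseudo_subject(
            NodeTimeSeries("a", x[:, :n], names), NodeTimeSeries("b", x[:, n:], names)
        )
        nm = compute_netmat(ps, estimator="partial", ridge_rho=0.0, fisher=False)
        assert np.abs(nm.matrix - partial_corr_by_regression(ps.data)).max() < 1e-8


class TestCrossDiagonal:
    def test_block_matrix_indexing(self):
        M = np.arange(49, dtype=float).reshape(7, 7)
        full = np.zeros((14, 14))
        full[:7, 7:] = M
        assert np.array_equal(cross_diagonal(full), np.diag(M))

    def test_odd_dimension_raises(self):
        with pytest.raises(ConfigurationError, match="odd"):
            cross_diagonal(np.zeros((7, 7)))

    def test_attenuation_with_unit_noise(self, rng):
        # clean vs sd=1 noisy copies: E[r] = 1/sqrt(2) ~ 0.707
        vals = []
        for _ in range(100):
            x = rng.standard_normal((305, 7))
            a = NodeTimeSeries("a", x, NAMES)
            b = NodeTimeSeries("b", x + rng.standard_normal((305, 7)), NAMES)
            nm = compute_netmat(
                build_pseudo_subject(a, b), estimator="full", fisher=False
            )
            vals.append(cross_diagonal(nm))
        assert np.mean(vals) == pytest.approx(1 / np.sqrt(2), abs=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_group_swap_leaves_cross_diagonal_unchanged(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = make_ts(rng, "a", T=60, N=3, names=("x", "y", "z"))
        b = NodeTimeSeries("b", scale * rng.standard_normal((60, 3)), ("x", "y", "z"))
        d_ab = cross_diagonal(
            compute_netmat(build_pseudo_subject(a, b), "full", fisher=False)
        )
        d_ba = cross_diagonal(
            compute_netmat(build_pseudo_subject(b, a), "full", fisher=False)
        )
        assert np.allclose(d_ab, d_ba, atol=1e-10)


class TestResampling:
    def test_default_trial_count_is_128(self, experiment_cohort):
        res = resample_cross_group(
            group_ts(experiment_cohort, "FMT"),
            group_ts(experiment_cohort, "sham"),
            seed=0,
        )
        assert res.n_trials == 128
        assert res.trials.shape == (128, 7)

    def test_each_trial_drops_exactly_one_pooled_subject(self):
        for _, (da, db, pairs) in zip(
            range(128), iter_trial_pairings(6, 6, 128, seed=3)
        ):
            assert (da is None) != (db is None)
            assert len(pairs) == 5  # one group lost a subject
        # over 128 trials with 12 pooled subjects, every subject is dropped
        drops = [
            da if da is not None else 6 + db
            for da, db, _ in iter_trial_pairings(6, 6, 128, seed=3)
        ]
        assert len(set(drops)) == 12

    def test_identity_groups_hit_fisher_ceiling(self, rng):
        group = [make_ts(rng, f"s{i}") for i in range(4)]
        copies = [NodeTimeSeries(f"c{i}", g.data.copy(), g.node_names) for i, g in enumerate(group)]
        res = resample_cross_group(
            copies,
            group,
            n_trials=16,
            seed=0,
            estimator_cfg=EstimatorConfig(estimator="full", ridge_rho=0.0),
        )
        # every trial pairs some subject with... not necessarily its own copy;
        # restrict to 2 subjects so every pairing is identical or swapped
        res2 = resample_cross_group(
            copies[:2],
            group[:2],
            n_trials=16,
            seed=0,
            estimator_cfg=EstimatorConfig(estimator="full", ridge_rho=0.0),
        )
        matched = res2.trials[res2.trials > Z_MAX - 1e-9]
        assert matched.size > 0  # identity pairings reach the clipped ceiling

    def test_seed_determinism_bitwise(self, experiment_cohort):
        kw = dict(n_trials=32, seed=42)
        a = resample_cross_group(
            group_ts(experiment_cohort, "SLN"), group_ts(experiment_cohort, "sham"), **kw
        )
        b = resample_cross_group(
            group_ts(experiment_cohort, "SLN"), group_ts(experiment_cohort, "sham"), **kw
        )
        assert np.array_equal(a.trials, b.trials)
        assert np.array_equal(a.drop_index, b.drop_index)

    def test_trial_prefix_stable_when_n_trials_grows(self, experiment_cohort):
        short = resample_cross_group(
            group_ts(experiment_cohort, "SLN"),
            group_ts(experiment_cohort, "sham"),
            n_trials=16,
            seed=7,
        )
        long = resample_cross_group(
            group_ts(experiment_cohort, "SLN"),
            group_ts(experiment_cohort, "sham"),
            n_trials=32,
            seed=7,
        )
        assert np.array_equal(short.trials, long.trials[:16])

    def test_group_of_one_raises(self, rng):
        with pytest.raises(ResamplingError, match="2 subjects"):
            resample_cross_group([make_ts(rng)], [make_ts(rng), make_ts(rng)], seed=0)

    def test_independent_groups_center_near_zero(self, rng):
        # raw trial means near 0; retained means small positive
        a = [make_ts(rng, f"a{i}") for i in range(6)]
        b = [make_ts(rng, f"b{i}") for i in range(6)]
        res = resample_cross_group(
            a, b, n_trials=64, seed=1,
            estimator_cfg=EstimatorConfig(estimator="full", ridge_rho=0.0),
        )
        assert np.abs(res.trials.mean()) < 0.05
        assert np.all(res.mean >= 0)
        assert np.all(res.mean < 0.2)
        assert res.n_rejected_negative.sum() > 0

    def test_negative_rejection_bookkeeping(self):
        trials = np.array([[0.5, -0.2], [0.3, 0.4], [-0.1, 0.6]])
        res = aggregate_trials(trials, ("n1", "n2"))
        assert res.n_rejected_negative.tolist() == [1, 1]
        assert res.mean[0] == pytest.approx(0.4)
        assert res.mean[1] == pytest.approx(0.5)
        assert (res.n_rejected_negative + [2, 2]).tolist() == [3, 3]


class TestCompareTimepoints:
    def test_identical_results_give_no_flags(self, experiment_cohort):
        res = resample_cross_group(
            group_ts(experiment_cohort, "FMT"),
            group_ts(experiment_cohort, "sham"),
            n_trials=32,
            seed=5,
        )
        tab = compare_timepoints(res, res)
        assert np.allclose(tab["diff"], 0)
        assert not tab["significant"].any()

    def test_alpha_zero_never_flags(self, experiment_cohort):
        r1 = resample_cross_group(
            group_ts(experiment_cohort, "FMT"),
            group_ts(experiment_cohort, "sham"),
            n_trials=32,
            seed=5,
        )
        r2 = resample_cross_group(
            group_ts(experiment_cohort, "SLN"),
            group_ts(experiment_cohort, "sham"),
            n_trials=32,
            seed=6,
        )
        assert not compare_timepoints(r1, r2, alpha=0.0)["significant"].any()

    def test_node_mismatch_raises(self):
        a = aggregate_trials(np.ones((4, 2)), ("n1", "n2"))
        b = aggregate_trials(np.ones((4, 2)), ("n1", "n3"))
        with pytest.raises(ComparisonError, match="node sets"):
            compare_timepoints(a, b)

    def test_jackknife_requires_drop_provenance(self):
        a = aggregate_trials(np.random.default_rng(0).uniform(0.1, 1, (8, 2)), ("n1", "n2"))
        with pytest.raises(ComparisonError, match="provenance"):
            compare_timepoints(a, a, test="jackknife")

    def test_welch_mode_available(self, experiment_cohort):
        r1 = resample_cross_group(
            group_ts(experiment_cohort, "FMT"),
            group_ts(experiment_cohort, "sham"),
            n_trials=32,
            seed=5,
        )
        tab = compare_timepoints(r1, r1, test="welch")
        assert not tab["significant"].any()
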