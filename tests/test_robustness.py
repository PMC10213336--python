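import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symptomnet import (
    CovariateEffects,
    GeneratorConfig,
    case_drop_bootstrap,
    cs_coefficient,
    edge_bootstrap,
    generate_cohort,
    network_comparison_test,
    truth_from_partials,
)
from symptomnet.cohort import PHQ9_COLS
from symptomnet.robustness import StabilityResult


def _items(n=600, seed=0):
    truth = truth_from_partials(9, {(i, i + 1): 0.3 for i in range(8)})
    cfg = GeneratorConfig(n=n, truth=truth, effects=CovariateEffects(0, 0, 0), seed=seed)
    return generate_cohort(cfg).data[PHQ9_COLS]


def _stab(props, corrs):
    corrs = np.asarray(corrs, dtype=float)
    return StabilityResult(
        proportions=np.asarray(props, float),
        correlations=corrs,
        B=corrs.shape[1],
        seed=0,
        n_failed=0,
    )


class TestCsCoefficient:
    def test_all_ones_returns_grid_maximum(self):
        res = _stab([0.05, 0.25, 0.5, 0.75], np.ones((4, 50)))
        assert cs_coefficient(res) == 0.75

    def test_all_zeros_returns_zero(self):
        res = _stab([0.05, 0.25, 0.5, 0.75], np.zeros((4, 50)))
        assert cs_coefficient(res) == 0.0

    def test_constructed_cutoff_at_04(self):
        """Proportions up to 0.4 satisfy the 95%-above-0.7 criterion; larger
        ones do not."""
        props = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        corrs = np.empty((6, 100))
        for i, q in enumerate(props):
            corrs[i] = 0.9 if q <= 0.4 else 0.5
        assert cs_coefficient(_stab(props, corrs)) == 0.4

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_correlations(self, seed):
        rng = np.random.default_rng(seed)
        props = [0.1, 0.3, 0.5, 0.7]
        corrs = rng.uniform(-1, 0.99, size=(4, 40))
        lifted = np.minimum(corrs + rng.uniform(0, 0.3), 1.0)
        assert cs_coefficient(_stab(props, lifted)) >= cs_coefficient(
            _stab(props, corrs)
        )

    def test_empty_grid_rejected(self):
        res = _stab([], np.empty((0, 10)))
        with pytest.raises(ValueError, match="empty"):
            cs_coefficient(res)


class TestCaseDropBootstrap:
    def test_tiny_drop_keeps_correlations_near_one(self):
        items = _items(n=800, seed=1)
        res = case_drop_bootstrap(items, proportions=[0.02], B=25, seed=3)
        assert np.nanmedian(res.correlations) >= 0.99

    def test_duplicated_rows_fully_stable(self):
        base = _items(n=60, seed=2)
        big = pd.concat([base] * 20, ignore_index=True)
        res = case_drop_bootstrap(
            big, proportions=[0.1, 0.3, 0.5], B=20, seed=4
        )
        assert np.nanmedian(res.correlations) > 0.95

    def test_median_correlation_declines_with_drop(self):
        items = _items(n=1000, seed=5)
        res = case_drop_bootstrap(
            items, proportions=[0.1, 0.5, 0.75], B=60, seed=6
        )
        med = np.nanmedian(res.correlations, axis=1)
        assert med[0] >= med[-1]

    def test_deterministic_under_seed(self):
        items = _items(n=400, seed=7)
        a = case_drop_bootstrap(items, proportions=[0.2], B=10, seed=42)
        b = case_drop_bootstrap(items, proportions=[0.2], B=10, seed=42)
        assert np.array_equal(a.correlations, b.correlations, equal_nan=True)

    def test_excessive_drop_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            case_drop_bootstrap(_items(n=30, seed=8), proportions=[0.8], B=5)

    def test_curve_export_shapes(self):
        items = _items(n=300, seed=9)
        res = case_drop_bootstrap(items, proportions=[0.1, 0.2], B=5, seed=1)
        df = res.to_dataframe()
        assert len(df) == 10
        assert set(df.columns) == {"proportion", "replicate", "correlation"}
        assert len(res.summary_curve()) == 2


class TestEdgeBootstrap:
    def test_cis_ordered(self):
        items = _items(n=700, seed=10)
        res = edge_bootstrap(items, B=120, seed=11)
        t = res.table
        assert (t["ci_lower"] <= t["ci_upper"]).all()
        # the percentile CI always brackets the bootstrap median; the mean can
        # escape only for spike-at-zero edges, and then only marginally
        assert (t["ci_lower"] <= t["boot_median"]).all()
        assert (t["boot_median"] <= t["ci_upper"]).all()
        escape = np.maximum(
            t["ci_lower"] - t["boot_mean"], t["boot_mean"] - t["ci_upper"]
        )
        assert escape.max() < 0.01

    def test_true_zero_edges_covered(self):
        """Edges absent from the generating chain should have CIs containing
        zero nearly always."""
        items = _items(n=700, seed=12)
        res = edge_bootstrap(items, B=120, seed=13)
        t = res.table.set_index(["node_a", "node_b"])
        chain = {(f"phq9_{i}", f"phq9_{i+1}") for i in range(1, 9)}
        null_rows = t.loc[[i for i in t.index if i not in chain]]
        covered = (null_rows["ci_lower"] <= 0) & (0 <= null_rows["ci_upper"])
        assert covered.mean() >= 0.9

    def test_duplicated_data_width_set_by_resample_size(self):
        """Bootstrap width tracks the resample size, not the number of
        distinct rows: a 20x-duplicated n=50 set behaves like a genuine
        n=1000 sample."""
        base = _items(n=50, seed=14)
        big = pd.concat([base] * 20, ignore_index=True)
        genuine = _items(n=1000, seed=18)
        w_big = (
            lambda t: (t["ci_upper"] - t["ci_lower"]).mean()
        )(edge_bootstrap(big, B=100, seed=15).table)
        w_gen = (
            lambda t: (t["ci_upper"] - t["ci_lower"]).mean()
        )(edge_bootstrap(genuine, B=100, seed=15).table)
        assert w_big < 0.25
        assert 0.4 < w_big / w_gen < 2.5

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B must be"):
            edge_bootstrap(_items(n=100, seed=16), B=10)


class TestNetworkComparison:
    def test_identical_data_gives_null_result(self):
        items = _items(n=300, seed=17)
        res = network_comparison_test(items, items.copy(), n_perm=60, seed=18)
        assert res.global_strength_diff == 0.0
        assert res.max_edge_diff == 0.0
        assert res.p_global_strength == 1.0
        assert res.p_max_edge == 1.0

    def test_p_values_never_zero(self):
        a = _items(n=200, seed=19)
        b = _items(n=200, seed=20)
        res = network_comparison_test(a, b, n_perm=40, seed=21)
        assert res.p_global_strength >= 1 / 41
        assert res.p_max_edge >= 1 / 41

    def test_deterministic_under_seed(self):
        a = _items(n=200, seed=22)
        b = _items(n=200, seed=23)
        r1 = network_comparison_test(a, b, n_perm=30, seed=5)
        r2 = network_comparison_test(a, b, n_perm=30, seed=5)
        assert r1 == r2

    def test_detects_single_differing_edge(self):
        """Groups differing by one strong edge: the max-edge test rejects in
        the majority of replications."""
        chain = {(i, i + 1): 0.25 for i in range(8)}
        truth_a = truth_from_partials(9, dict(chain))
        with_extra = dict(chain)
        with_extra[(0, 4)] = 0.4
        truth_b = truth_from_partials(9, with_extra)
        hits = 0
        for s in range(5):
            a = generate_cohort(
                GeneratorConfig(n=2000, truth=truth_a, effects=CovariateEffects(0, 0, 0), seed=100 + s)
            ).data[PHQ9_COLS]
            b = generate_cohort(
                GeneratorConfig(n=2000, truth=truth_b, effects=CovariateEffects(0, 0, 0), seed=200 + s)
            ).data[PHQ9_COLS]
            res = network_comparison_test(a, b, n_perm=100, seed=300 + s)
            hits += res.p_max_edge < 0.05
        assert hits >= 3

    def test_mismatched_columns_rejected(self):
        a = _items(n=100, seed=24)
        b = a.rename(columns={"phq9_1": "other"})
        with pytest.raises(ValueError, match="same node columns"):
            network_comparison_test(a, b)

    def test_undersized_group_rejected(self):
        a = _items(n=100, seed=25)
        with pytest.raises(ValueError, match="more rows than nodes"):
            network_comparison_test(a.iloc[:5], a)
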