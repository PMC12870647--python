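import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from phenoconcord.biomarker_association import (
    bh_fdr,
    connectivity_associations,
    connectivity_matrix,
    median_split,
    median_split_tests,
    tier_label,
    tiered_correlations,
    welch_t_test,
)
from phenoconcord.instruments_io import BiomarkerTable
from phenoconcord.synthetic_data import (
    BiomarkerConfig,
    default_cohort_config,
    generate_biomarkers,
    generate_score_table,
)


def welch_oracle(x, y):
    """Closed-form Welch t, Satterthwaite df and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


class TestMedianSplit:
    def test_even_split(self):
        high = median_split(np.array([1, 2, 3, 4]))
        assert high.tolist() == [False, False, True, True]

    def test_ties_at_median_go_low(self):
        high = median_split(np.array([1, 2, 2, 3]))
        assert high.tolist() == [False, False, False, True]

    def test_rank_invariance_under_monotone_relabeling(self):
        x = np.array([3, 1, 4, 1, 5, 9, 2, 6])
        np.testing.assert_array_equal(median_split(x), median_split(x * 10 + 7))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(np.array([5, 5, 5, 5]))


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = welch_t_test(x, x.copy())
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_swapping_flips_sign(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_matches_closed_form(self):
        """Welch statistic, df and p equal the hand formula to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(2, 30))
            y = rng.normal(0.5, 2, rng.integers(2, 30))
            res = welch_t_test(x, y)
            t, df, p = welch_oracle(x, y)
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.df == pytest.approx(df, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestBH:
    def test_single_small_p_rejected(self):
        reject, adj = bh_fdr(np.array([0.01]), q=0.05)
        assert reject.tolist() == [True]

    def test_step_up_by_hand(self):
        # sorted p (0.01, 0.02, 0.30) vs i/m * q = (0.0167, 0.0333, 0.05)
        reject, adj = bh_fdr(np.array([0.01, 0.02, 0.30]), q=0.05)
        assert reject.tolist() == [True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr(np.ones(5), q=0.05)
        assert not reject.any()

    def test_empty_input(self):
        reject, adj = bh_fdr(np.array([]), q=0.05)
        assert reject.size == 0 and adj.size == 0

    def test_never_fewer_rejections_than_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            bh_count = bh_fdr(p, q=0.05)[0].sum()
            bonf_count = (p <= 0.05 / len(p)).sum()
            assert bh_count >= bonf_count

    def test_adjusted_p_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        _, adj = bh_fdr(p, q=0.05)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestTiers:
    def test_tier_boundaries(self):
        assert tier_label(0.049) == "p<0.05"
        assert tier_label(0.07) == "p<0.1"
        assert tier_label(0.12) == "p<0.15"
        assert tier_label(0.2) == "ns"

    def test_metric_copy_of_score_r_one(self, catalog, small_cohort):
        scalars = pd.DataFrame({
            "prs": 0.0,
            "metric": small_cohort.values["SRS_Aware"].astype(float),
        }, index=small_cohort.values.index)
        out = tiered_correlations(small_cohort, BiomarkerTable(scalars=scalars),
                                  scores=["SRS_Aware"], metrics=["metric"])
        assert out[0].r == pytest.approx(1.0)
        assert out[0].tier == "p<0.05"


class TestConnectivity:
    def test_eight_networks_give_28_pairs(self):
        rng = np.random.default_rng(4)
        conn = connectivity_matrix(rng.standard_normal((8, 50)))
        assert conn.unique_pairs.shape == (28,)
        assert len(conn.pair_labels()) == 28

    def test_two_networks_one_pair(self):
        rng = np.random.default_rng(5)
        conn = connectivity_matrix(rng.standard_normal((2, 10)))
        assert conn.unique_pairs.shape == (1,)

    def test_duplicated_row_perfect_correlation(self):
        rng = np.random.default_rng(6)
        ts = rng.standard_normal((3, 40))
        ts[2] = ts[0]
        conn = connectivity_matrix(ts)
        assert conn.entries[0, 2] == pytest.approx(1.0)

    def test_constant_row_named(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="net1"):
            connectivity_matrix(ts)

    def test_association_with_planted_edge(self, catalog):
        cfg = default_cohort_config(catalog, n_participants=60, seed=30)
        table = generate_score_table(cfg, catalog)
        markers = generate_biomarkers(BiomarkerConfig(T=50, seed=30), table)
        conns = {p: connectivity_matrix(ts, markers.network_labels)
                 for p, ts in markers.timeseries.items()}
        # plant: totals equal to one connectivity entry exactly
        edge = np.array([conns[p].unique_pairs[5] for p in table.participants])
        totals = pd.DataFrame({"FAKE": edge}, index=table.values.index)
        out = connectivity_associations(conns, totals)
        row = out.iloc[5]
        assert row["r"] == pytest.approx(1.0)
        assert row["tier"] == "p<0.05"
        assert len(out) == 28

    def test_misaligned_participants_rejected(self, catalog):
        totals = pd.DataFrame({"A": [1.0, 2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError, match="without connectivity"):
            connectivity_associations({}, totals)


class TestMedianSplitPipeline:
    def test_effect_recovery_power(self, catalog):
        """effect_size=0.5 at n=1000 on the severity-loaded instrument is
        detected (BH-significant at q=0.05) in >= 80% of seeds; with
        effect_size=0 the rejection rate stays <= 10%."""
        n_seeds = 25
        hits = {0.0: 0, 0.5: 0}
        for effect in hits:
            for seed in range(n_seeds):
                cfg = default_cohort_config(catalog, n_participants=1000,
                                            severity_loading=0.7, seed=seed + 100)
                table = generate_score_table(cfg, catalog)
                markers = generate_biomarkers(
                    BiomarkerConfig(effect_size=effect, T=2, seed=seed), table)
                results = median_split_tests(table, markers,
                                             instruments=["ADOS", "ADIR", "SRS"])
                if any(r.significant for r in results):
                    hits[effect] += 1
        assert hits[0.5] / n_seeds >= 0.8
        assert hits[0.0] / n_seeds <= 0.10 + 2 / n_seeds

    def test_results_annotated_with_bh(self, catalog, small_cohort):
        markers = generate_biomarkers(BiomarkerConfig(T=2, seed=0), small_cohort)
        results = median_split_tests(small_cohort, markers)
        assert all(r.p_adjusted is not None for r in results)
        assert all(r.n_low + r.n_high == small_cohort.n_participants
                   for r in results)
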