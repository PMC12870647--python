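import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from phenoconcord.semantic_similarity import wasserstein_distance
from phenoconcord.synthetic_data import (
    BiomarkerConfig,
    CohortConfig,
    SemanticSimConfig,
    bin_to_ordinal,
    example_construct_assignment,
    generate_biomarkers,
    generate_item_embeddings,
    generate_rater_pair,
    generate_score_table,
    nearest_correlation,
    total_latent_corr,
)


def binned_bivariate_r(rho, levels_x, levels_y, n=200_000, seed=12345):
    """Oracle for the binning attenuation: simulate a bivariate normal with
    correlation rho, bin both margins, return the empirical Pearson r."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    x = bin_to_ordinal(z1, *levels_x)
    y = bin_to_ordinal(z2, *levels_y)
    return pearsonr(x, y)[0]


def two_subscore_config(rho, n, seed=0, levels=((0, 10), (0, 10)), loading=0.0):
    return CohortConfig(
        n_participants=n,
        subscores=["ADOS_SocAff", "ADOS_RRB"],
        latent_corr=np.array([[1.0, rho], [rho, 1.0]]),
        score_levels={"ADOS_SocAff": levels[0], "ADOS_RRB": levels[1]},
        severity_loading=loading,
        seed=seed,
    )


class TestEmbeddingGenerator:
    def test_infinite_concentration_collapses_to_center(self, catalog):
        cfg = SemanticSimConfig(
            constructs=["soc", "comm", "rrb", "dev"],
            assignment=example_construct_assignment(),
            dim=6, concentration=np.inf, seed=0)
        clouds = generate_item_embeddings(cfg, catalog)
        # two sub-scores sharing the same sole construct coincide exactly
        assert wasserstein_distance(
            clouds.clouds["SRS_Aware"], clouds.clouds["SRS_Cog"]) == 0.0

    def test_antipodal_centers_give_cost_pi(self, catalog):
        centers = {"soc": np.array([1.0, 0.0]), "comm": np.array([-1.0, 0.0]),
                   "rrb": np.array([0.0, 1.0]), "dev": np.array([0.0, -1.0])}
        cfg = SemanticSimConfig(
            constructs=list(centers), assignment=example_construct_assignment(),
            dim=2, concentration=np.inf, centers=centers, seed=0)
        clouds = generate_item_embeddings(cfg, catalog)
        d = wasserstein_distance(clouds.clouds["ADOS_SocAff"], clouds.clouds["ADIR_B"])
        assert d == pytest.approx(np.pi)

    def test_deterministic_given_seed(self, catalog):
        cfg = SemanticSimConfig(
            constructs=["soc", "comm", "rrb", "dev"],
            assignment=example_construct_assignment(), dim=8, seed=42)
        a = generate_item_embeddings(cfg, catalog)
        b = generate_item_embeddings(cfg, catalog)
        for sub in a.subscores():
            np.testing.assert_array_equal(a.clouds[sub], b.clouds[sub])

    def test_dim_below_two_rejected(self, catalog):
        with pytest.raises(ValueError, match="dimension"):
            SemanticSimConfig(constructs=["soc"], assignment={}, dim=1)

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to"):
            SemanticSimConfig(constructs=["a"], assignment={"s": {"a": 0.5}}, dim=4)


class TestScoreGenerator:
    def test_identity_corr_gives_near_zero_empirical(self, catalog):
        cfg = two_subscore_config(0.0, n=5000, seed=7)
        table = generate_score_table(cfg, catalog)
        r = pearsonr(table.values.iloc[:, 0], table.values.iloc[:, 1])[0]
        assert abs(r) < 0.05

    def test_high_corr_recovers_attenuated_target(self, catalog):
        """Empirical r of the binned pair matches the brute-force binned
        bivariate-normal oracle within +/- 0.07."""
        cfg = two_subscore_config(0.9, n=5000, seed=8)
        table = generate_score_table(cfg, catalog)
        r = pearsonr(table.values.iloc[:, 0], table.values.iloc[:, 1])[0]
        target = binned_bivariate_r(0.9, (0, 10), (0, 10))
        assert r == pytest.approx(target, abs=0.07)

    def test_empty_cohort(self, catalog):
        table = generate_score_table(two_subscore_config(0.0, n=0), catalog)
        assert table.n_participants == 0

    def test_non_psd_latent_corr_rejected(self, catalog):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            CohortConfig(n_participants=10, subscores=["a", "b"], latent_corr=bad,
                         score_levels={"a": (0, 5), "b": (0, 5)})

    def test_determinism(self, catalog):
        cfg = two_subscore_config(0.5, n=50, seed=3)
        a = generate_score_table(cfg, catalog)
        b = generate_score_table(cfg, catalog)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_copula_binning_monotone(self):
        z = np.sort(np.random.default_rng(0).standard_normal(500))
        scores = bin_to_ordinal(z, 0, 12)
        assert (np.diff(scores) >= 0).all()
        assert scores.min() >= 0 and scores.max() <= 12

    def test_severity_raises_cross_correlation(self, catalog):
        base = two_subscore_config(0.0, n=4000, seed=5, loading=0.8)
        table = generate_score_table(base, catalog)
        r = pearsonr(table.values.iloc[:, 0], table.values.iloc[:, 1])[0]
        assert r > 0.4  # latent corr 0.64 before attenuation
        assert total_latent_corr(base)[0, 1] == pytest.approx(0.64)


class TestRaterPair:
    def test_zero_noise_identical(self, catalog):
        cfg = two_subscore_config(0.5, n=200, seed=1)
        table = generate_score_table(cfg, catalog)
        r1, r2 = generate_rater_pair(table, cfg, catalog, rater_noise_sd=0.0, seed=9)
        pd.testing.assert_frame_equal(r1.values, r2.values)
        pd.testing.assert_frame_equal(r1.values, table.values)

    def test_large_noise_destroys_agreement(self, catalog):
        cfg = two_subscore_config(0.5, n=2000, seed=2)
        table = generate_score_table(cfg, catalog)
        r1, r2 = generate_rater_pair(table, cfg, catalog, rater_noise_sd=3.0, seed=10)
        r = pearsonr(r1.totals["ADOS"], r2.totals["ADOS"])[0]
        assert r**2 < 0.3

    def test_agreement_decreases_monotonically_in_noise(self, catalog):
        cfg = two_subscore_config(0.5, n=400, seed=4)
        table = generate_score_table(cfg, catalog)
        mean_r = []
        for sd in (0.0, 0.5, 1.5, 4.0):
            rs = []
            for seed in range(20):
                r1, r2 = generate_rater_pair(table, cfg, catalog,
                                             rater_noise_sd=sd, seed=seed)
                rs.append(pearsonr(r1.totals["ADOS"], r2.totals["ADOS"])[0])
            mean_r.append(np.mean(rs))
        assert all(a > b for a, b in zip(mean_r, mean_r[1:]))


class TestBiomarkerGenerator:
    def _cohort(self, catalog, n=300, seed=0):
        cfg = two_subscore_config(0.3, n=n, seed=seed, loading=0.7)
        return generate_score_table(cfg, catalog)

    def test_identity_network_corr_near_zero_connectivity(self, catalog):
        table = self._cohort(catalog, n=2)
        cfg = BiomarkerConfig(T=5000, seed=0)
        markers = generate_biomarkers(cfg, table)
        ts = markers.timeseries[table.participants[0]]
        conn = np.corrcoef(ts)
        off = conn[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_perfect_imaging_corr(self, catalog):
        table = self._cohort(catalog)
        cfg = BiomarkerConfig(imaging_corr={"total_brain_volume": 1.0}, T=5, seed=1)
        markers = generate_biomarkers(cfg, table)
        r = pearsonr(markers.scalars["total_brain_volume"], table.severity)[0]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_effect_size_gives_uniformish_p(self, catalog):
        """With effect_size=0 the median-split Welch p-values behave like a
        null across seeds (no systematic enrichment below 0.05)."""
        from phenoconcord.biomarker_association import median_split, welch_t_test

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            table = self._cohort(catalog, n=200, seed=seed)
            cfg = BiomarkerConfig(effect_size=0.0, T=2, seed=seed)
            markers = generate_biomarkers(cfg, table)
            high = median_split(table.totals["ADOS"])
            prs = markers.scalars["prs"].to_numpy()
            if welch_t_test(prs[high], prs[~high]).p < 0.05:
                hits += 1
        assert hits / n_seeds <= 0.15

    def test_t_below_two_rejected(self):
        with pytest.raises(ValueError, match="T"):
            BiomarkerConfig(T=1)

    def test_severity_length_mismatch_rejected(self, catalog):
        table = self._cohort(catalog, n=10)
        with pytest.raises(ValueError, match="length"):
            generate_biomarkers(BiomarkerConfig(T=3), table,
                                severity=np.zeros(5))


class TestNearestCorrelation:
    def test_valid_matrix_unchanged(self):
        c = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(nearest_correlation(c), c)

    def test_indefinite_matrix_projected(self):
        c = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_correlation(c)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-10
        np.testing.assert_allclose(np.diag(fixed), 1.0)
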