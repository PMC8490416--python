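import numpy as np
import pandas as pd
import pytest

from mergetraj.merging import PhenotypeMap
from mergetraj.transcriptome import (
    RegionGeometry,
    empirical_variogram,
    make_surrogates,
    screen_genes,
    select_genes_sd,
    spatial_correlation,
    surrogate_significance,
    _variogram_bins,
)
from mergetraj.synthetic import SimExpressionSpec, gen_expression_matrix


class TestSpatialCorrelation:
    def test_copy_and_negation_give_unit_correlation(self, sa_map):
        expr = pd.DataFrame(
            [sa_map.values, -sa_map.values],
            index=["copy", "neg"],
            columns=sa_map.region_ids,
        )
        r = spatial_correlation(sa_map, expr)
        assert r["copy"] == pytest.approx(1.0)
        assert r["neg"] == pytest.approx(-1.0)

    def test_orthogonalized_gene_has_zero_correlation(self, sa_map):
        rng = np.random.default_rng(0)
        t = sa_map.values - sa_map.values.mean()
        g = rng.standard_normal(t.size)
        g = g - g.mean()
        g = g - (g @ t) / (t @ t) * t
        expr = pd.DataFrame([g], index=["orth"], columns=sa_map.region_ids)
        assert spatial_correlation(sa_map, expr)["orth"] == pytest.approx(0.0, abs=1e-12)

    def test_vectorized_matches_naive_loop(self, sa_map):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.standard_normal((200, len(sa_map.region_ids))),
            index=[f"g{i}" for i in range(200)],
            columns=sa_map.region_ids,
        )
        r = spatial_correlation(sa_map, expr)
        for g in expr.index[::23]:
            naive = np.corrcoef(sa_map.values, expr.loc[g])[0, 1]
            assert r[g] == pytest.approx(naive, abs=1e-12)

    def test_constant_map_rejected(self, geometry):
        m = PhenotypeMap(list(geometry.region_ids), np.ones(68))
        expr = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 68)),
                            columns=geometry.region_ids)
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation(m, expr)

    def test_zero_variance_gene_gets_nan(self, sa_map):
        expr = pd.DataFrame(
            [np.ones(68), sa_map.values],
            index=["flat", "ok"],
            columns=sa_map.region_ids,
        )
        r = spatial_correlation(sa_map, expr)
        assert np.isnan(r["flat"]) and np.isfinite(r["ok"])


class TestSelectGenesSd:
    def test_cutoff_arithmetic(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(5000)
        r = (r - r.mean()) / r.std(ddof=1) * 0.3  # exact mean 0, SD 0.3
        up, lo, uc, lc = select_genes_sd(pd.Series(r, index=map(str, range(5000))))
        assert uc == pytest.approx(0.588, abs=1e-9)
        assert lc == pytest.approx(-0.588, abs=1e-9)

    def test_zero_multiplier_splits_around_mean(self):
        r = pd.Series(np.linspace(-1, 1, 100), index=map(str, range(100)))
        up, lo, *_ = select_genes_sd(r, sd_multiplier=0.0)
        assert len(up) == 50 and len(lo) == 50

    def test_raising_multiplier_never_adds_genes(self):
        rng = np.random.default_rng(2)
        r = pd.Series(rng.standard_normal(500), index=map(str, range(500)))
        prev_up, prev_lo = None, None
        for mult in (0.5, 1.0, 1.96, 3.0):
            up, lo, *_ = select_genes_sd(r, sd_multiplier=mult)
            if prev_up is not None:
                assert set(up) <= prev_up and set(lo) <= prev_lo
            prev_up, prev_lo = set(up), set(lo)

    def test_disjoint_lists(self):
        rng = np.random.default_rng(3)
        r = pd.Series(rng.standard_normal(100), index=map(str, range(100)))
        up, lo, *_ = select_genes_sd(r)
        assert not (set(up) & set(lo))

    def test_zero_sd_rejected(self):
        r = pd.Series(np.zeros(50), index=map(str, range(50)))
        with pytest.raises(ValueError, match="SD"):
            select_genes_sd(r)


class TestVariogram:
    def test_three_point_hand_computation(self):
        geom = RegionGeometry(
            ["a", "b", "c"],
            np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),
            np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
        )
        v = empirical_variogram(np.array([0.0, 1.0, 2.0]), geom.distances, n_bins=2)
        assert v.semivariance[0] == pytest.approx(0.5)
        assert v.semivariance[1] == pytest.approx(2.0)

    def test_constant_map_is_zero(self, geometry):
        v = empirical_variogram(np.full(68, 3.0), geometry.distances)
        assert np.allclose(v.semivariance, 0.0)

    def test_white_noise_is_flat_at_the_sill(self, geometry):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(68)
        v = empirical_variogram(x, geometry.distances, n_bins=5)
        sill = x.var()
        assert np.all(np.abs(v.semivariance - sill) < 0.5 * sill)

    def test_fewer_pairs_than_bins_reduces_bins(self):
        d = np.array([[0.0, 1], [1, 0]])
        with pytest.warns(UserWarning, match="reducing"):
            v = empirical_variogram(np.array([0.0, 1.0]), d, n_bins=10)
        assert v.semivariance.size == 1


class TestSurrogates:
    def test_each_surrogate_is_an_exact_value_permutation(self, sa_map, geometry):
        ens = make_surrogates(sa_map, geometry, n_surrogates=20, seed=0)
        target = np.sort(sa_map.values)
        for s in ens.maps:
            assert np.array_equal(np.sort(s), target)

    def test_seeded_ensemble_is_deterministic(self, sa_map, geometry):
        a = make_surrogates(sa_map, geometry, n_surrogates=5, seed=3)
        b = make_surrogates(sa_map, geometry, n_surrogates=5, seed=3)
        assert np.array_equal(a.maps, b.maps)
        assert a.smoothing_scale_mm == b.smoothing_scale_mm

    def test_sa_map_beats_plain_permutations_on_variogram_misfit(self, sa_map, geometry):
        ens = make_surrogates(sa_map, geometry, n_surrogates=30, seed=1)
        iu = np.triu_indices(68, 1)
        bins, _ = _variogram_bins(geometry.distances[iu], 10)
        target = empirical_variogram(sa_map.values, geometry.distances,
                                     bin_assignment=bins).semivariance

        def misfit(m):
            g = empirical_variogram(m, geometry.distances, bin_assignment=bins)
            return np.mean((g.semivariance - target) ** 2)

        rng = np.random.default_rng(0)
        mis_surr = np.mean([misfit(m) for m in ens.maps])
        mis_perm = np.mean([misfit(rng.permutation(sa_map.values)) for _ in range(30)])
        assert mis_surr < mis_perm

    def test_constant_map_rejected(self, geometry):
        m = PhenotypeMap(list(geometry.region_ids), np.zeros(68))
        with pytest.raises(ValueError, match="constant"):
            make_surrogates(m, geometry, n_surrogates=2, seed=0)

    def test_nonpositive_count_rejected(self, sa_map, geometry):
        with pytest.raises(ValueError, match="n_surrogates"):
            make_surrogates(sa_map, geometry, n_surrogates=0, seed=0)


class TestSurrogateSignificance:
    def test_normal_pool_gives_plus_minus_196_sd(self, geometry):
        # white map and white genes: pooled r is approx normal with
        # SD 1/sqrt(n-1); the empirical 2.5/97.5 percentiles should sit
        # near +/-1.96 of that
        rng = np.random.default_rng(0)
        m = PhenotypeMap(list(geometry.region_ids), rng.standard_normal(68))
        expr = pd.DataFrame(rng.standard_normal((400, 68)),
                            index=[f"g{i}" for i in range(400)],
                            columns=geometry.region_ids)
        ens = make_surrogates(m, geometry, n_surrogates=300, seed=1)
        up, lo, _ = surrogate_significance(ens, expr, list(geometry.region_ids))
        expected = 1.96 / np.sqrt(68 - 1)
        assert up == pytest.approx(expected, rel=0.12)
        assert lo == pytest.approx(-expected, rel=0.12)

    def test_zero_correlation_gene_has_p_near_one(self, sa_map, geometry):
        rng = np.random.default_rng(1)
        t = sa_map.values - sa_map.values.mean()
        g = rng.standard_normal(68)
        g -= (g @ t) / (t @ t) * t
        expr = pd.DataFrame([g, sa_map.values], index=["orth", "copy"],
                            columns=sa_map.region_ids)
        ens = make_surrogates(sa_map, geometry, n_surrogates=100, seed=2)
        r = spatial_correlation(sa_map, expr)
        _, _, emp = surrogate_significance(ens, expr, list(geometry.region_ids), gene_r=r)
        assert emp["orth"] > 0.9
        assert emp["copy"] < 0.05


class TestScreenRecovery:
    def test_planted_genes_recovered_with_low_contamination(self, sa_map, geometry):
        spec = SimExpressionSpec(n_genes=500, planted_pos=10, planted_neg=10, seed=4)
        expr, labels = gen_expression_matrix(sa_map, geometry, spec)
        screen, _ = screen_genes(sa_map, expr, geometry, n_surrogates=50, seed=0)
        planted_up = {g for g, l in labels.items() if l == "planted_pos"}
        planted_lo = {g for g, l in labels.items() if l == "planted_neg"}
        assert planted_up <= set(screen.upper_genes)
        assert planted_lo <= set(screen.lower_genes)
        background = {g for g, l in labels.items() if l == "background"}
        contaminated = (set(screen.upper_genes) | set(screen.lower_genes)) & background
        assert len(contaminated) / len(background) <= 0.06
        # the +/-1.96 SD cutoffs should clear the surrogate bounds here
        assert screen.cutoffs_exceed_null
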