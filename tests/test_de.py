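import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from neurescence import (
    CountMatrix,
    emd_test,
    filter_genes,
    generate_dataset,
    hurdle_test,
    intersect_de,
    log_cpm,
    upsample_indices,
)


def _matrix(counts, **kw):
    counts = np.asarray(counts)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        cell_ids=[f"c{i}" for i in range(counts.shape[1])],
        counts=counts,
        cell_type=["A"] * counts.shape[1],
        **kw,
    )


class TestFilterGenes:
    def test_boundary_at_min_cells(self):
        counts = np.zeros((2, 300), dtype=int)
        counts[0, :200] = 1  # exactly 200 expressing cells -> kept
        counts[1, :199] = 1  # 199 -> dropped
        kept = filter_genes(_matrix(counts), min_count=1, min_cells=200)
        assert kept.gene_ids == ["g0"]

    def test_all_zero_gene_dropped(self):
        counts = np.array([[0, 0, 0], [1, 2, 0]])
        kept = filter_genes(_matrix(counts), min_cells=1)
        assert kept.gene_ids == ["g1"]

    def test_toy_hand_count(self):
        counts = np.array(
            [
                [1, 1, 0, 0],  # 2 cells -> kept
                [5, 0, 0, 0],  # 1 -> dropped
                [2, 2, 2, 0],  # 3 -> kept
                [0, 0, 0, 0],  # 0 -> dropped
                [1, 0, 1, 1],  # 3 -> kept
            ]
        )
        kept = filter_genes(_matrix(counts), min_cells=2)
        assert kept.gene_ids == ["g0", "g2", "g4"]

    def test_everything_filtered_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            filter_genes(_matrix(np.array([[1, 0]])), min_cells=5)


class TestLogCpm:
    def test_zero_count_maps_to_zero(self):
        m = _matrix(np.array([[0, 1], [10, 10]]))
        assert log_cpm(m)[0, 0] == 0.0

    def test_million_library_unit_count(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 999_999
        assert log_cpm(_matrix(counts))[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_thousand_library(self):
        counts = np.array([[10], [990]])
        expected = np.log2(1e6 * 10 / 1000 + 1)  # log2(10001) ~ 13.2879
        assert log_cpm(_matrix(counts))[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(13.28785, abs=1e-5)

    def test_zero_total_cell_named(self):
        m = _matrix(np.array([[1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="c1"):
            log_cpm(m)


class TestUpsampleIndices:
    @pytest.mark.parametrize(
        "n_min,n_maj,r",
        [(475, 16871, 36), (5, 5, 1), (3, 10, 3)],
    )
    def test_replication_factor(self, n_min, n_maj, r):
        labels = np.array([1] * n_min + [0] * n_maj)
        idx = upsample_indices(labels)
        assert (labels[idx] == 1).sum() == n_min * r
        assert (labels[idx] == 0).sum() == n_maj

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            upsample_indices(np.zeros(10))


class TestHurdleTest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        half = rng.exponential(size=(5, 20)) * (rng.random((5, 20)) > 0.3)
        expr = np.hstack([half, half])
        labels = np.array([0] * 20 + [1] * 20)
        tab = hurdle_test(expr, labels)
        np.testing.assert_allclose(tab["hurdle_stat"], 0.0, atol=1e-8)
        np.testing.assert_allclose(tab["p"], 1.0, atol=1e-8)
        np.testing.assert_allclose(tab["log2fc"], 0.0, atol=1e-12)

    def test_allzero_vs_allpositive_closed_form(self):
        """Group A all zero, group B all positive: the discrete G-statistic is
        -2 * 40 * ln(0.5) ~ 55.452 with the continuous part skipped."""
        expr = np.hstack([np.zeros((1, 20)), np.full((1, 20), 5.0)])
        labels = np.array([0] * 20 + [1] * 20)
        tab = hurdle_test(expr, labels)
        assert tab["hurdle_stat"][0] == pytest.approx(-2 * 40 * np.log(0.5), rel=1e-9)
        assert tab["df"][0] == 1.0  # continuous part needs variation

    def test_matches_numeric_mle_oracle(self):
        """Total statistic equals brute-force numeric ML fits of both parts."""
        rng = np.random.default_rng(42)
        pos = rng.random(30) > 0.35
        expr = np.where(pos, rng.normal(5, 1, 30), 0.0)[None, :]
        labels = np.array([0] * 15 + [1] * 15)
        tab = hurdle_test(expr, labels)

        det = expr[0] > 0
        g1 = labels.astype(bool)

        def binom_nll(p, k, n):
            p = min(max(p, 1e-12), 1 - 1e-12)
            return -(k * np.log(p) + (n - k) * np.log(1 - p))

        def best(k, n):
            res = scipy.optimize.minimize_scalar(
                binom_nll, bounds=(1e-9, 1 - 1e-9), args=(k, n), method="bounded",
                options={"xatol": 1e-12},
            )
            return -res.fun

        k1, k0 = det[g1].sum(), det[~g1].sum()
        disc = 2 * (best(k1, 15) + best(k0, 15) - (
            -binom_nll((k1 + k0) / 30, k1, 15) - binom_nll((k1 + k0) / 30, k0, 15)
        ))

        x1, x0 = expr[0][g1 & det], expr[0][~g1 & det]
        x = np.concatenate([x1, x0])

        def gauss_nll_null(params):
            mu, log_s = params
            s = np.exp(log_s)
            return x.size * log_s + ((x - mu) ** 2).sum() / (2 * s**2)

        def gauss_nll_alt(params):
            mu1, mu0, log_s = params
            s = np.exp(log_s)
            return x.size * log_s + (
                ((x1 - mu1) ** 2).sum() + ((x0 - mu0) ** 2).sum()
            ) / (2 * s**2)

        r0 = scipy.optimize.minimize(
            gauss_nll_null, [x.mean(), np.log(x.std())], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        r1 = scipy.optimize.minimize(
            gauss_nll_alt, [x1.mean(), x0.mean(), np.log(x.std())], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        cont = 2 * (r0.fun - r1.fun)
        assert tab["hurdle_stat"][0] == pytest.approx(disc + cont, abs=1e-6)
        assert tab["df"][0] == 2.0

    def test_undetected_gene_flagged(self):
        expr = np.zeros((1, 10))
        labels = np.array([0] * 5 + [1] * 5)
        tab = hurdle_test(expr, labels)
        assert tab["p"][0] == 1.0 and tab["log2fc"][0] == 0.0 and tab["degenerate"][0]

    def test_planted_de_genes_positive_log2fc(self, small_config):
        matrix, truth = generate_dataset(small_config, seed=5)
        kept = filter_genes(matrix, min_cells=10)
        expr = log_cpm(kept)
        tab = hurdle_test(expr, truth.senescent_mask, gene_ids=kept.gene_ids)
        de = tab[tab["gene"].isin(truth.de_genes)]
        assert len(de) > 0
        assert (de["log2fc"] > 0).mean() >= 0.99

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(3)
        expr = rng.exponential(size=(40, 30)) * (rng.random((40, 30)) > 0.3)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        tab = hurdle_test(expr, labels)
        assert (tab["padj"] >= tab["p"] - 1e-15).all()


class TestEmdTest:
    def test_identical_distributions_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0] * 2)[None, :]
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        tab = emd_test(vals, labels, n_bins=10, n_perm=199)
        assert tab["emd"][0] == pytest.approx(0.0, abs=1e-12)
        assert tab["p"][0] == pytest.approx(1.0)

    def test_point_mass_transport_distance(self):
        """All of group A in the first bin, all of B in the fifth: 4 bin units."""
        vals = np.array([[0.0] * 5 + [5.0] * 5])
        labels = np.array([0] * 5 + [1] * 5)
        tab = emd_test(vals, labels, n_bins=5, n_perm=199)
        assert tab["emd"][0] == pytest.approx(4.0, abs=1e-12)

    def test_degenerate_range(self):
        vals = np.full((1, 8), 2.5)
        labels = np.array([0] * 4 + [1] * 4)
        tab = emd_test(vals, labels, n_bins=10, n_perm=100)
        assert tab["emd"][0] == 0.0 and tab["p"][0] == 1.0

    def test_small_groups_exhaustive_equals_enumeration(self):
        """n1=n2=3: the permutation p must equal the exact enumeration over all
        20 label assignments, computed independently with an optimal-transport
        oracle."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 6))
        vals[0, 3:] += 3.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        n_bins = 8
        tab = emd_test(vals, labels, n_bins=n_bins, n_perm=99)

        for g in range(vals.shape[0]):
            x = vals[g]
            lo, hi = x.min(), x.max()
            bins = np.clip(((x - lo) / ((hi - lo) / n_bins)).astype(int), 0, n_bins - 1)

            def emd_oracle(mask):
                return scipy.stats.wasserstein_distance(
                    bins[mask], bins[~mask]
                )

            obs = emd_oracle(labels.astype(bool))
            count = total = 0
            for combo in itertools.combinations(range(6), 3):
                mask = np.zeros(6, dtype=bool)
                mask[list(combo)] = True
                count += emd_oracle(mask) >= obs - 1e-12
                total += 1
            assert total == 20
            assert tab["emd"][g] == pytest.approx(obs, abs=1e-12)
            assert tab["p"][g] == pytest.approx(count / total, abs=1e-12)

    def test_monte_carlo_p_bounds(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 40))
        labels = np.array([0] * 20 + [1] * 20)
        tab = emd_test(vals, labels, n_perm=99, seed=11)
        assert ((tab["p"] >= 1 / 100) & (tab["p"] <= 1.0)).all()

    def test_n_perm_floor(self):
        with pytest.raises(ValueError, match="n_perm"):
            emd_test(np.zeros((1, 4)), [0, 0, 1, 1], n_perm=10)


class TestIntersectDe:
    @staticmethod
    def _table(universe, significant, method):
        return pd.DataFrame(
            {"gene": universe, "significant": [g in significant for g in universe],
             "method": method}
        )

    def test_small_overlap_exact(self):
        universe = list("abcdefghij")
        h = self._table(universe, {"a", "b", "c"}, "hurdle")
        e = self._table(universe, {"b", "c", "d"}, "emd")
        genes, res = intersect_de(h, e)
        assert genes == ["b", "c"]
        assert res.p == pytest.approx(22 / 120, abs=1e-12)

    def test_disjoint_sets_p_one(self):
        universe = list("abcdefghij")
        h = self._table(universe, {"a"}, "hurdle")
        e = self._table(universe, {"j"}, "emd")
        genes, res = intersect_de(h, e)
        assert genes == [] and res.p == 1.0

    def test_mismatched_universes_rejected(self):
        h = self._table(list("abc"), set(), "hurdle")
        e = self._table(list("abd"), set(), "emd")
        with pytest.raises(ValueError, match="universe"):
            intersect_de(h, e)

    def test_reported_discovery_scale_overlap(self):
        """375- and 576-gene sets sharing 324 of 10,768 genes: the overlap
        survival probability is below 1e-205."""
        universe = [f"g{i}" for i in range(10768)]
        h = self._table(universe, set(universe[:375]), "hurdle")
        e = self._table(universe, set(universe[:324] + universe[375 : 375 + 252]), "emd")
        genes, res = intersect_de(h, e, universe_size=10768)
        assert len(genes) == 324
        assert res.log10p < -205


class TestPooledNull:
    def test_pooled_null_breaks_per_gene_resolution_floor(self):
        """With a pooled null, a strongly shifted gene's p-value drops below
        the per-gene floor of 1/(n_perm+1)."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(50, 60))
        vals[0, 30:] += 6.0  # one clear signal gene
        labels = np.array([0] * 30 + [1] * 30)
        per_gene = emd_test(vals, labels, n_perm=99, seed=1)
        pooled = emd_test(vals, labels, n_perm=99, seed=1, null="pooled")
        assert per_gene["p"][0] == pytest.approx(1 / 100)
        assert pooled["p"][0] < 1 / 100
        # observed EMDs are identical under either null
        np.testing.assert_allclose(pooled["emd"], per_gene["emd"], atol=1e-12)

    def test_unknown_null_rejected(self):
        with pytest.raises(ValueError, match="null"):
            emd_test(np.zeros((1, 4)), [0, 0, 1, 1], n_perm=99, null="bogus")
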