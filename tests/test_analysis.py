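"""Tests for the gene-set test, permutation check, and collection screen."""

import numpy as np
import pandas as pd
import pytest

from gsda import (
    Endpoint,
    GeneMatchingError,
    GeneSet,
    dcor_from_distances,
    euclidean_distance_matrix,
    gsda_screen,
    gsda_test,
    permutation_test,
    u_center,
)
from gsda.exceptions import InputError


def make_frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, columns=[f"{prefix}{j}" for j in range(values.shape[1])])


class TestGsdaTest:
    def test_perfect_single_gene_association(self, rng):
        y = rng.standard_normal(20)
        X = make_frame(y[:, None])
        res = gsda_test(X, ["g0"], Endpoint.quantitative(y))
        assert res.r_d == pytest.approx(1.0)
        assert res.p_t < 1e-100  # at the floor attainable under the clamp

    def test_reduces_to_base_distance_correlation(self, rng):
        # the quantitative case is exactly the two-matrix t-test of the engine
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        res = gsda_test(make_frame(X), [f"g{j}" for j in range(4)], Endpoint.quantitative(y))
        base = dcor_from_distances(
            euclidean_distance_matrix(X), euclidean_distance_matrix(y[:, None])
        )
        assert res.r_d == pytest.approx(base.r_d, rel=1e-14)
        assert res.p_t == pytest.approx(base.p_t, rel=1e-12)

    def test_null_pvalues_roughly_uniform(self, rng):
        pvals = [
            gsda_test(
                make_frame(rng.standard_normal((50, 5))),
                [f"g{j}" for j in range(5)],
                Endpoint.quantitative(rng.standard_normal(50)),
            ).p_t
            for _ in range(200)
        ]
        # crude uniformity: mean near 1/2 and mass spread across the range
        assert 0.4 < np.mean(pvals) < 0.6
        assert 0.15 < np.mean(np.asarray(pvals) < 0.25) < 0.35

    def test_no_matching_genes_raises(self, rng, expression_frame):
        with pytest.raises(GeneMatchingError):
            gsda_test(
                expression_frame, ["absent1", "absent2"],
                Endpoint.quantitative(rng.standard_normal(20)),
            )

    def test_differential_correlation_detected(self, rng):
        """Two genes correlated +/- by group, equal means: invisible to per-gene
        location tests, strongly visible to the distance correlation."""
        from scipy.stats import mannwhitneyu

        n = 100
        detected, per_gene_detected = 0, 0
        reps = 20
        for _ in range(reps):
            z = np.repeat([1.0, -1.0], n)
            g1 = rng.standard_normal(2 * n)
            g2 = z * 0.9 * g1 + np.sqrt(1 - 0.81) * rng.standard_normal(2 * n)
            labels = np.repeat(["grp1", "grp2"], n)
            X = make_frame(np.column_stack([g1, g2]))
            res = gsda_test(X, ["g0", "g1"], Endpoint.categorical(labels))
            detected += res.p_t < 0.05
            p_genes = [
                mannwhitneyu(g[:n], g[n:]).pvalue for g in (g1, g2)
            ]
            per_gene_detected += min(p_genes) * 2 < 0.05  # Bonferroni over 2 genes
        assert detected >= 0.8 * reps
        assert per_gene_detected <= 0.3 * reps


class TestPermutationTest:
    def _centered_pair(self, rng, n=30, effect=1.0):
        y = rng.standard_normal(n)
        X = effect * y[:, None] + rng.standard_normal((n, 3))
        Xc = u_center(euclidean_distance_matrix(X))
        Yc = u_center(euclidean_distance_matrix(y[:, None]))
        return Xc, Yc

    def test_lower_bound_when_observed_dominates(self, rng):
        Xc, Yc = self._centered_pair(rng, effect=5.0)
        p, reps = permutation_test(Xc, Yc, 99, seed=0)
        assert p == pytest.approx(1 / 100)
        assert reps.shape == (99,)

    def test_ties_count_against_observed(self, rng):
        Xc, Yc = self._centered_pair(rng)
        # an observed magnitude of zero ties with (or is beaten by) every replicate
        p, reps = permutation_test(Xc, Yc, 50, seed=1, r_observed=0.0)
        assert p == 1.0

    def test_u_centering_commutes_with_permutation(self, rng):
        # permuting the raw distances then centering == centering then permuting;
        # this is what licenses permuting the U-centered endpoint directly
        from .conftest import random_distance_matrix

        D = random_distance_matrix(rng, 9)
        perm = rng.permutation(9)
        lhs = u_center(D[np.ix_(perm, perm)])
        rhs = u_center(D)[np.ix_(perm, perm)]
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_joint_permutation_leaves_r_unchanged(self, rng):
        Xc, Yc = self._centered_pair(rng)
        from gsda import dcor

        perm = rng.permutation(Xc.shape[0])
        r1 = dcor(Xc, Yc)
        r2 = dcor(Xc[np.ix_(perm, perm)], Yc[np.ix_(perm, perm)])
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_invalid_replicate_count(self, rng):
        Xc, Yc = self._centered_pair(rng)
        with pytest.raises(InputError):
            permutation_test(Xc, Yc, 0)

    def test_seed_reproducibility(self, rng):
        Xc, Yc = self._centered_pair(rng)
        p1, r1 = permutation_test(Xc, Yc, 200, seed=7)
        p2, r2 = permutation_test(Xc, Yc, 200, seed=7)
        assert p1 == p2
        np.testing.assert_array_equal(r1, r2)


class TestScreen:
    def make_collection(self, n_sets, genes_per_set=4, n_genes=40):
        names = [f"g{j}" for j in range(n_genes)]
        return [
            GeneSet(f"set{k}", tuple(names[k * genes_per_set:(k + 1) * genes_per_set]))
            for k in range(n_sets)
        ]

    def test_planted_set_ranks_first(self, rng):
        hits = 0
        for _ in range(10):
            n = 100
            y = rng.standard_normal(n)
            X = rng.standard_normal((n, 40))
            X[:, 0:4] = 1.5 * y[:, None] + rng.standard_normal((n, 4))
            table = gsda_screen(
                make_frame(X), self.make_collection(10), Endpoint.quantitative(y),
                permutations=0,
            )
            hits += table.iloc[0]["gene_set"] == "set0"
        assert hits >= 8

    def test_textbook_bh_arithmetic(self, monkeypatch, rng):
        # p-values (0.01, 0.02, 0.5) -> BH q-values (0.03, 0.03, 0.5)
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.5], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.03, 0.03, 0.5])

    def test_screen_q_values_consistent_with_bh(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 40))
        table = gsda_screen(
            make_frame(X), self.make_collection(10), Endpoint.quantitative(y),
            permutations=0,
        )
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(table["p_t"], method="fdr_bh")[1]
        np.testing.assert_allclose(table["q_value"], expected)
        assert set(table.columns) >= {
            "gene_set", "n_matched", "r_d", "t_d", "df", "p_t", "p_perm", "q_value",
        }

    def test_degenerate_set_flagged_not_fatal(self, rng):
        y = rng.standard_normal(20)
        X = rng.standard_normal((20, 8))
        X[:, 4:] = 7.0  # constant genes -> zero distances -> degenerate
        sets = [
            GeneSet("ok", ("g0", "g1", "g2", "g3")),
            GeneSet("flat", ("g4", "g5", "g6", "g7")),
            GeneSet("missing", ("nope1", "nope2")),
        ]
        table = gsda_screen(make_frame(X), sets, Endpoint.quantitative(y), permutations=0)
        by_name = table.set_index("gene_set")
        assert by_name.loc["ok", "status"] == "ok"
        assert by_name.loc["flat", "status"].startswith("degenerate")
        assert by_name.loc["missing", "status"] == "no_genes_matched"
        assert np.isnan(by_name.loc["flat", "p_t"])

    def test_screen_reproducible_with_seed(self, rng):
        n = 60
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 40))
        X[:, :4] = y[:, None] + 0.7 * rng.standard_normal((n, 4))
        frames = [
            gsda_screen(
                make_frame(X), self.make_collection(10), Endpoint.quantitative(y),
                permutations=200, seed=11,
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(frames[0], frames[1])
        # the planted set got a permutation follow-up
        assert frames[0]["p_perm"].notna().any()
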