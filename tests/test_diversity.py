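"""Alpha indices, Bray-Curtis/PCoA, PERMANOVA vs enumeration, SIMPER identity."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from gutbrain.diversity import (
    alpha_diversity,
    bray_curtis_matrix,
    pcoa,
    permanova,
    simper,
)


class TestAlpha:
    def test_uniform_community_closed_forms(self):
        res = alpha_diversity([5, 5, 5, 5])
        assert res.richness == 4
        assert res.shannon == pytest.approx(np.log(4))
        assert res.simpson == pytest.approx(0.75)
        assert res.pielou == pytest.approx(1.0)

    def test_single_taxon(self):
        res = alpha_diversity([7, 0, 0])
        assert (res.richness, res.shannon, res.simpson) == (1, 0.0, 0.0)
        assert np.isnan(res.pielou)

    def test_hand_computed(self):
        res = alpha_diversity([1, 1, 2])
        assert res.shannon == pytest.approx(1.0397207708, abs=1e-9)
        assert res.simpson == pytest.approx(0.625)
        assert res.pielou == pytest.approx(0.9463946303, abs=1e-9)

    def test_scale_and_order_invariance(self, rng):
        counts = rng.integers(1, 100, 12)
        a = alpha_diversity(counts)
        b = alpha_diversity(counts[::-1] * 10)
        assert a.shannon == pytest.approx(b.shannon)
        assert a.simpson == pytest.approx(b.simpson)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]], index=list("abc"))
        dm = bray_curtis_matrix(t)
        assert dm["a", "b"] == 0
        assert dm["a", "c"] == 1

    def test_hand_computed(self):
        t = pd.DataFrame([[1, 1], [1, 3]], index=["x", "y"])
        assert bray_curtis_matrix(t)["x", "y"] == pytest.approx(1 / 3)

    def test_zero_total_sample_rejected(self):
        t = pd.DataFrame([[1, 1], [0, 0]], index=["x", "y"])
        with pytest.raises(ValueError, match="y"):
            bray_curtis_matrix(t)


class TestPcoa:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        coords, eigvals, _ = pcoa(dm)
        assert eigvals[0] == pytest.approx(eigvals[1])
        assert eigvals[0] > 0
        for i, j in combinations(range(3), 2):
            d = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
            assert d == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_distances_reproduced_exactly(self, rng):
        pts = rng.normal(0, 1, (6, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        coords, _, _ = pcoa(dm)
        d2 = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_coincident_samples(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
        coords, _, _ = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_matches_skbio(self, rng):
        x = rng.random((7, 10))
        dm = bray_curtis_matrix(pd.DataFrame(x))
        coords, eigvals, _ = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=0)
        np.testing.assert_allclose(
            eigvals[: coords.shape[1]][eigvals[: coords.shape[1]] > 1e-10],
            ref.eigvals.values[ref.eigvals.values > 1e-10],
            atol=1e-8,
        )


class TestPermanova:
    @staticmethod
    def _brute_force_p(dm, labels):
        """Independent oracle: recompute pseudo-F over every label split."""
        d2 = dm.data**2
        n = len(labels)
        labels = np.asarray(labels)

        def f_stat(lab):
            ss_t = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            a = len(np.unique(lab))
            return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

        f_obs = f_stat(labels)
        n_a = (labels == labels[0]).sum()
        hits = total = 0
        for idx in combinations(range(n), int(n_a)):
            lab = np.array(["b"] * n)
            lab[list(idx)] = "a"
            if f_stat(lab) >= f_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        x = rng.normal(0, 1, (6, 5))
        x[3:] += 1.0
        dm = bray_curtis_matrix(pd.DataFrame(np.abs(x)))
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, labels)
        assert res.exhaustive
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(self._brute_force_p(dm, labels))

    def test_pseudo_f_matches_skbio(self, rng):
        x = np.abs(rng.normal(1, 0.5, (12, 8)))
        dm = bray_curtis_matrix(pd.DataFrame(x))
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_clusters_attain_minimum_p(self, rng):
        x = np.vstack([rng.random((8, 5)), rng.random((8, 5)) + 50])
        dm = bray_curtis_matrix(pd.DataFrame(x))
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(dm, labels, n_perm=99, seed=1)
        if res.exhaustive:
            assert res.p_value <= 2 / res.n_permutations
        else:
            assert res.p_value == 1 / (res.n_permutations + 1)

    def test_single_group_rejected(self, rng):
        dm = bray_curtis_matrix(pd.DataFrame(rng.random((4, 3))))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 4)


class TestSimper:
    def test_two_species_hand_computed(self):
        t = pd.DataFrame([[10, 0], [10, 0], [0, 10], [0, 10]],
                         columns=["x", "y"], index=list("abcd"))
        out = simper(t, ["A", "A", "B", "B"])
        assert out["percent"].to_list() == [50.0, 50.0]
        assert out.attrs["mean_between_group_dissimilarity"] == pytest.approx(1.0)

    def test_single_differing_species_takes_all(self):
        t = pd.DataFrame([[5, 1], [5, 1], [5, 9], [5, 9]],
                         columns=["same", "diff"], index=list("abcd"))
        out = simper(t, ["A", "A", "B", "B"])
        assert out.index[0] == "diff"
        assert out.loc["diff", "percent"] == pytest.approx(100.0)

    def test_decomposition_identity_on_random_tables(self, rng):
        for _ in range(25):
            n_a, n_b, k = rng.integers(2, 6), rng.integers(2, 6), rng.integers(2, 10)
            t = pd.DataFrame(rng.random((n_a + n_b, k)) + 0.01)
            labels = ["A"] * n_a + ["B"] * n_b
            out = simper(t, labels)
            bc = bray_curtis_matrix(t).data
            between = bc[:n_a, n_a:].mean()
            assert out["contribution"].sum() == pytest.approx(between, abs=1e-9)

    def test_three_groups_rejected(self):
        t = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            simper(t, ["A", "B", "C"])


class TestDistanceProperties:
    """Bray-Curtis axioms on arbitrary abundance tables."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=500), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bray_curtis_bounded_symmetric_zero_diagonal(self, rows):
        t = pd.DataFrame(rows)
        dm = bray_curtis_matrix(t)
        d = dm.data
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
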