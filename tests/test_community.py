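import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nitracer.community import (
    alpha_diversity,
    anosim,
    bray_curtis,
    chao1,
    mantel,
    pcoa,
    scalar_to_distance,
    shannon,
    simpson,
)
from nitracer.errors import AlignmentError, DomainError
from nitracer.io import CommunityTable, DistanceMatrix


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 3, 3), 3.0),          # no singletons
            ((1, 1, 2, 5), 4.5),       # F1=2, F2=1
            ((1, 1, 1, 1), 10.0),      # F2=0 branch of the corrected form
        ],
    )
    def test_chao1_hand_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_chao1_classical_form(self):
        assert chao1((1, 1, 2, 5), bias_corrected=False) == pytest.approx(4 + 4 / 2)
        with pytest.raises(DomainError):
            chao1((1, 1, 3), bias_corrected=False)

    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1, 1, 1), np.log(4)), ((7,), 0.0), ((1, 1, 2), 1.0397207708399179)],
    )
    def test_shannon_hand_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts,expected", [((9,), 1.0), ((2, 2, 2, 2), 0.25), ((1, 1, 2), 0.375)]
    )
    def test_simpson_hand_values(self, counts, expected):
        assert simpson(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        for fn in (chao1, shannon, simpson):
            with pytest.raises(DomainError):
                fn((0, 0, 0))

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30)
        .filter(lambda c: sum(c) > 0)
    )
    @settings(max_examples=50, deadline=None)
    def test_taxon_order_invariance(self, counts):
        shuffled = list(reversed(sorted(counts)))
        for fn in (chao1, shannon, simpson):
            assert fn(counts) == pytest.approx(fn(shuffled))
        assert chao1(counts) >= sum(1 for c in counts if c > 0)

    def test_shannon_maximal_simpson_minimal_at_uniformity(self):
        uniform = (5, 5, 5, 5)
        skewed = (17, 1, 1, 1)
        assert shannon(uniform) > shannon(skewed)
        assert simpson(uniform) < simpson(skewed)

    def test_alpha_diversity_table(self, small_community):
        df = alpha_diversity(small_community)
        assert list(df.site_id) == small_community.site_ids
        assert df.loc[3, "shannon"] == pytest.approx(np.log(5))
        assert df.loc[3, "simpson"] == pytest.approx(0.2)
        np.testing.assert_allclose(df["simpson_1mD"], 1 - df["simpson"])


class TestBrayCurtis:
    def test_hand_values(self):
        t = CommunityTable(
            ["a", "b", "c"], ["t1", "t2"], np.array([[1, 2], [2, 1], [1, 2]])
        )
        d = bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(2 / 6)
        assert d.values[0, 2] == 0.0

    def test_disjoint_rows_distance_one(self):
        t = CommunityTable(["a", "b"], ["t1", "t2"], np.array([[5, 0], [0, 3]]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_matches_skbio(self, small_community):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        ours = bray_curtis(small_community)
        ref = skbio_diversity.beta_diversity(
            "braycurtis", small_community.counts, ids=small_community.site_ids
        )
        np.testing.assert_allclose(ours.values, ref.data, atol=1e-12)

    def test_zero_row_rejected(self):
        t = CommunityTable(["a", "b"], ["t1", "t2"], np.array([[0, 0], [1, 1]]))
        with pytest.raises(DomainError):
            bray_curtis(t)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0])
        d = DistanceMatrix(["a", "b", "c"], np.abs(x[:, None] - x[None, :]))
        res = pcoa(d, n_axes=2)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_equilateral_triangle_split(self):
        m = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], m), n_axes=2)
        np.testing.assert_allclose(res.proportion_explained, [0.5, 0.5], atol=1e-12)

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], d), n_axes=5)
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_matches_skbio_proportions(self, small_community):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        d = bray_curtis(small_community)
        ours = pcoa(d, n_axes=3)
        from skbio import DistanceMatrix as SkbioDM

        ref = skbio_ordination.pcoa(SkbioDM(d.values, ids=d.labels))
        np.testing.assert_allclose(
            ours.proportion_explained,
            ref.proportion_explained.to_numpy()[:3],
            atol=1e-8,
        )


class TestMantel:
    def _random_dm(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return DistanceMatrix([f"i{k}" for k in range(n)], d)

    def test_self_correlation_is_one(self):
        d = self._random_dm(8, 0)
        r, p = mantel(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_oracle_4x4(self):
        d1 = self._random_dm(4, 1)
        d2 = self._random_dm(4, 2)
        iu = np.triu_indices(4, k=1)

        def corr(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        r_obs = corr(d1.values[iu], d2.values[iu])
        hits = sum(
            corr(d1.values[iu], d2.values[np.ix_(perm, perm)][iu]) >= r_obs
            for perm in itertools.permutations(range(4))
        )
        p_exact = hits / 24  # includes the identity relabeling
        r, p = mantel(d1, d2, n_perm=999, seed=3)
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(p_exact, abs=0.05)

    def test_matches_skbio_r(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = self._random_dm(12, 3), self._random_dm(12, 4)
        r, _ = mantel(d1, d2, n_perm=9, seed=1)
        ref_r, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, ids=d1.labels),
            skbio_distance.DistanceMatrix(d2.values, ids=d2.labels),
            permutations=0,
        )
        assert r == pytest.approx(ref_r, abs=1e-12)

    def test_null_behaviour(self):
        over = 0
        for seed in range(20):
            d1 = self._random_dm(30, 100 + seed)
            d2 = self._random_dm(30, 200 + seed)
            _, p = mantel(d1, d2, n_perm=99, seed=seed)
            if p > 0.05:
                over += 1
        assert over >= 18

    def test_label_alignment(self):
        d1 = self._random_dm(5, 5)
        d2 = DistanceMatrix(list(reversed(d1.labels)), d1.values)
        r, _ = mantel(d1, d2, n_perm=9, seed=1)
        assert -1 <= r <= 1
        d3 = DistanceMatrix([f"x{k}" for k in range(5)], d1.values)
        with pytest.raises(AlignmentError):
            mantel(d1, d3, n_perm=9, seed=1)


class TestAnosim:
    def test_perfect_separation_R_one(self):
        # two tight clusters far apart
        x = np.array([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 10.2, 10.3])
        d = DistanceMatrix(
            [f"s{k}" for k in range(8)], np.abs(x[:, None] - x[None, :])
        )
        groups = ["a"] * 4 + ["b"] * 4
        R, p = anosim(d, groups, n_perm=199, seed=1)
        assert R == pytest.approx(1.0)
        # group-preserving relabelings tie with the observed R, so the
        # attainable floor is 2*(4!)^2/8! ~ 0.029 plus permutation noise
        assert p < 0.1

    def test_uninformative_distances_R_zero(self):
        m = np.ones((6, 6)) - np.eye(6)
        d = DistanceMatrix([f"s{k}" for k in range(6)], m)
        R, _ = anosim(d, ["a", "a", "a", "b", "b", "b"], n_perm=49, seed=1)
        assert R == pytest.approx(0.0)

    def test_hand_rank_arithmetic_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        pts[4:] += 3.0
        d_mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = DistanceMatrix([f"s{k}" for k in range(8)], d_mat)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        # direct loop computation of R from ranked pairwise distances
        from scipy.stats import rankdata

        pairs, within = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                pairs.append(d_mat[i, j])
                within.append(groups[i] == groups[j])
        ranks = rankdata(pairs)
        within = np.array(within)
        expected = (ranks[~within].mean() - ranks[within].mean()) / (8 * 7 / 4)
        R, _ = anosim(d, groups, n_perm=9, seed=1)
        assert R == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio_R(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 2))
        d_mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"s{k}" for k in range(10)]
        groups = ["a"] * 5 + ["b"] * 5
        R, _ = anosim(DistanceMatrix(labels, d_mat), groups, n_perm=9, seed=1)
        ref = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(d_mat, ids=labels),
            grouping=groups,
            permutations=0,
        )
        assert R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        m = np.ones((3, 3)) - np.eye(3)
        d = DistanceMatrix(["a", "b", "c"], m)
        with pytest.raises(DomainError):
            anosim(d, ["g1", "g1", "g2"], n_perm=9, seed=1)


def test_scalar_to_distance_absolute_difference():
    d = scalar_to_distance(["a", "b", "c"], [1.0, 4.0, 2.5])
    assert d.values[0, 1] == pytest.approx(3.0)
    assert d.values[1, 2] == pytest.approx(1.5)
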