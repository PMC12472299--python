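"""Rarefaction, alpha/beta diversity, ordination and permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from litterome import diversity
from litterome.containers import CommunityTable


def make_table(rows, samples=None, taxa=None, groups=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(rows.shape[1])]
    meta = None if groups is None else pd.Series(groups, index=samples)
    return CommunityTable(
        counts=pd.DataFrame(rows, index=samples, columns=taxa), metadata=meta
    )


class TestRarefy:
    def test_sample_at_depth_returned_unchanged(self):
        table = make_table([[5, 3, 2], [10, 0, 0]])
        out = diversity.rarefy(table, depth=10, seed=0)
        assert out.counts.loc["s0"].tolist() == [5, 3, 2]

    def test_single_taxon_forced_outcome(self):
        table = make_table([[100, 0, 0]])
        out = diversity.rarefy(table, depth=10, seed=1)
        assert out.counts.loc["s0"].tolist() == [10, 0, 0]

    def test_depth_above_total_names_sample(self):
        table = make_table([[5, 5], [3, 3]], samples=["ok", "shallow"])
        with pytest.raises(ValueError, match="shallow"):
            diversity.rarefy(table, depth=8)

    def test_hypergeometric_mean(self):
        """Expected rarefied count of a taxon with share p at depth d is p·d."""
        counts = np.array([60, 30, 10])
        total, depth = counts.sum(), 50
        draws = np.array(
            [
                diversity.rarefy(make_table([counts]), depth=depth, seed=s)
                .counts.to_numpy()[0]
                for s in range(1000)
            ]
        )
        expected = counts / total * depth
        var = (
            depth
            * (counts / total)
            * (1 - counts / total)
            * (total - depth)
            / (total - 1)
        )
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se).all()

    def test_support_preserved(self):
        table = make_table([[40, 0, 25, 0, 35]])
        out = diversity.rarefy(table, depth=30, seed=2)
        absent_before = table.counts.to_numpy()[0] == 0
        assert (out.counts.to_numpy()[0][absent_before] == 0).all()


class TestRelativeAbundance:
    def test_normalization(self):
        table = make_table([[2, 2], [1, 0]])
        rel = diversity.relative_abundance(table)
        assert rel.loc["s0"].tolist() == [0.5, 0.5]
        assert rel.loc["s1"].tolist() == [1.0, 0.0]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            diversity.relative_abundance(make_table([[0, 0]]))


class TestAlpha:
    def test_uniform_four_taxon_closed_forms(self):
        alpha = diversity.alpha_diversity(make_table([[5, 5, 5, 5]]))
        assert alpha["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert alpha["simpson"].iloc[0] == pytest.approx(0.75)

    def test_single_taxon_degenerate(self):
        alpha = diversity.alpha_diversity(make_table([[7, 0]]))
        assert alpha["shannon"].iloc[0] == 0.0
        assert alpha["simpson"].iloc[0] == 0.0
        assert alpha["chao1"].iloc[0] == 1.0

    def test_chao1_closed_form(self):
        # S_obs=10, F1=4, F2=2 → chao1 = 10 + 4²/(2·2) = 14
        counts = [1, 1, 1, 1, 2, 2, 3, 3, 3, 3]
        alpha = diversity.alpha_diversity(make_table([counts]))
        assert alpha["chao1"].iloc[0] == pytest.approx(14.0)

    def test_estimators_at_least_observed_richness(self, neutral_table):
        table, _ = neutral_table
        alpha = diversity.alpha_diversity(table)
        assert (alpha["chao1"] >= alpha["observed"] - 1e-9).all()
        assert (alpha["ace"] >= alpha["observed"] - 1e-9).all()


class TestBrayCurtis:
    def test_hand_cases(self):
        rel = pd.DataFrame([[2, 0], [1, 1], [2, 0]], index=list("abc"))
        dm = diversity.bray_curtis(rel)
        assert dm.loc["a", "b"] == pytest.approx(0.5)  # (1+1)/(3+1)
        assert dm.loc["a", "c"] == 0.0
        disjoint = pd.DataFrame([[1, 0], [0, 1]], index=list("xy"))
        assert diversity.bray_curtis(disjoint).loc["x", "y"] == pytest.approx(1.0)

    def test_bounded(self, neutral_table):
        table, _ = neutral_table
        dm = diversity.bray_curtis(diversity.relative_abundance(table)).to_numpy()
        assert dm.min() >= 0 and dm.max() <= 1


class TestPcoa:
    def test_equilateral_triangle(self):
        dm = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = diversity.pcoa(dm)
        positive = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1], abs=1e-9)
        coords = res.coordinates.to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_give_one_axis(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        dm = np.abs(x[:, None] - x[None, :])
        res = diversity.pcoa(pd.DataFrame(dm))
        positive = res.eigenvalues[res.eigenvalues > 1e-9]
        assert positive[0] / positive.sum() == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(10, 4))
        dm = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        res = diversity.pcoa(pd.DataFrame(dm))
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(recon - dm).max() < 1e-8


def brute_force_permanova_f(dm, codes):
    """Direct loop evaluation of Anderson's pseudo-F."""
    n = len(codes)
    a = len(set(codes))
    ss_total = sum(dm[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(codes):
        members = [i for i in range(n) if codes[i] == g]
        ss_g = sum(
            dm[i, j] ** 2 for i in members for j in members if i < j
        ) / len(members)
        ss_within += ss_g
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    @pytest.fixture
    def toy_dm(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.0
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return pd.DataFrame(dm, index=list("abcdef"), columns=list("abcdef"))

    def test_pseudo_f_matches_exhaustive_enumeration(self, toy_dm):
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=toy_dm.index)
        res = diversity.permanova(toy_dm, groups, n_perm=99, seed=0)
        d = toy_dm.to_numpy()
        f_brute = brute_force_permanova_f(d, [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(f_brute, rel=1e-12)
        # exact p from full enumeration of all 20 label assignments
        f_all = [
            brute_force_permanova_f(d, [0 if i in comb else 1 for i in range(6)])
            for comb in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean([f >= f_all[0] - 1e-12 for f in f_all])
        res_big = diversity.permanova(toy_dm, groups, n_perm=4999, seed=1)
        assert res_big.p_value == pytest.approx(p_exact, abs=0.05)

    def test_matches_skbio(self, toy_dm):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=toy_dm.index)
        ours = diversity.permanova(toy_dm, groups, n_perm=99, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(toy_dm.to_numpy(), ids=list(toy_dm.index)),
            list(groups), permutations=99,
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_perfect_separation_attains_minimum_p(self):
        pts = np.vstack([np.zeros((10, 2)), np.full((10, 2), 50.0)])
        pts += np.random.default_rng(0).normal(scale=0.01, size=pts.shape)
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = pd.DataFrame(dm)
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        res = diversity.permanova(dm, groups, n_perm=199, seed=2)
        assert res.p_value == pytest.approx(1 / 200)

    def test_single_member_group_rejected(self, toy_dm):
        groups = pd.Series(["g1"] * 5 + ["g2"], index=toy_dm.index)
        with pytest.raises(ValueError):
            diversity.permanova(toy_dm, groups)

    def test_r2_is_between_fraction(self, toy_dm):
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=toy_dm.index)
        res = diversity.permanova(toy_dm, groups, n_perm=99, seed=0)
        assert 0 <= res.r2 <= 1


class TestPermdisp:
    def test_identical_samples_have_zero_dispersion(self):
        pts = np.vstack([np.zeros((3, 2)), np.random.default_rng(1).normal(size=(3, 2))])
        dm = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        groups = pd.Series(["tight"] * 3 + ["loose"] * 3)
        z = diversity.dispersion_distances(dm, groups)
        assert np.allclose(z.iloc[:3], 0.0, atol=1e-9)

    def test_extreme_dispersion_difference_detected(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(scale=0.001, size=(6, 2)), rng.normal(scale=5.0, size=(6, 2))])
        dm = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        groups = pd.Series(["tight"] * 6 + ["loose"] * 6)
        res = diversity.permdisp(dm, groups, n_perm=199, seed=0)
        assert res.p_value <= 0.02

    def test_determinism(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        dm = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
        groups = pd.Series(["a"] * 5 + ["b"] * 5)
        r1 = diversity.permdisp(dm, groups, n_perm=99, seed=3)
        r2 = diversity.permdisp(dm, groups, n_perm=99, seed=3)
        assert r1.p_value == r2.p_value
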