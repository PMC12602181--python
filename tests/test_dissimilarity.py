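"""Dissimilarity primitives against hand calculations and a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_random_community, make_trait_space
from dissimscale.data_model import TRAIT_NAMES, PhyloDistances
from dissimscale.dissimilarity import (
    MetricConfig,
    compute_all,
    pairwise_multivariate,
    pairwise_univariate,
    phylo_dissimilarity,
    ranked_multivariate,
    ranked_univariate,
    weighted_centroid,
)
from dissimscale.errors import DegenerateInputError


class TestPrimitives:
    def test_weighted_centroid_examples(self):
        assert weighted_centroid(np.array([[1.0, 2.0, 3.0]]), np.array([17.0])) == pytest.approx(
            [1.0, 2.0, 3.0]
        )
        c = weighted_centroid(
            np.array([[1.0, 0, 0], [0, 1.0, 0]]), np.array([50.0, 50.0])
        )
        assert c == pytest.approx([0.5, 0.5, 0.0])
        c = weighted_centroid(np.array([[2.0, 0, 0], [8.0, 0, 0]]), np.array([30.0, 10.0]))
        assert c == pytest.approx([3.5, 0.0, 0.0])

    def test_weighted_centroid_empty(self):
        with pytest.raises(DegenerateInputError):
            weighted_centroid(np.empty((0, 3)), np.array([]))

    def test_ranked_multivariate_examples(self):
        others = np.array([[3.0, 4.0, 0.0]])
        assert ranked_multivariate(np.zeros(3), others, np.array([10.0])) == pytest.approx(5.0)
        others = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        d = ranked_multivariate(np.zeros(3), others, np.array([50.0, 50.0]))
        assert d == pytest.approx(np.sqrt(0.5))
        # target at the centroid -> zero
        assert ranked_multivariate(
            np.array([0.5, 0.5, 0.0]), others, np.array([50.0, 50.0])
        ) == pytest.approx(0.0)

    def test_pairwise_multivariate_examples(self):
        target = np.zeros(3)
        others = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert pairwise_multivariate(target, others) == pytest.approx(2.0)
        assert pairwise_multivariate(
            target, others, np.array([75.0, 25.0])
        ) == pytest.approx(1.5)
        assert pairwise_multivariate(target, np.array([target, target])) == 0.0

    def test_ranked_univariate_examples(self):
        # two-species community: antisymmetric leave-one-out differences
        assert ranked_univariate(3.0, np.array([7.0]), np.array([5.0])) == -4.0
        assert ranked_univariate(7.0, np.array([3.0]), np.array([5.0])) == 4.0
        assert ranked_univariate(
            4.0, np.array([2.0, 8.0]), np.array([30.0, 10.0])
        ) == pytest.approx(0.5)
        assert ranked_univariate(
            3.5, np.array([2.0, 8.0]), np.array([30.0, 10.0])
        ) == pytest.approx(0.0)

    def test_pairwise_univariate_examples(self):
        assert pairwise_univariate(4.0, np.array([2.0, 8.0])) == pytest.approx(3.0)
        assert pairwise_univariate(
            4.0, np.array([2.0, 8.0]), np.array([30.0, 10.0])
        ) == pytest.approx(2.5)
        assert pairwise_univariate(4.0, np.array([4.0, 4.0])) == 0.0

    def test_phylo_dissimilarity_examples(self):
        species = ["t", "a", "b"]
        D = np.array([[0.0, 10.0, 20.0], [10.0, 0.0, 5.0], [20.0, 5.0, 0.0]])
        pd_ = PhyloDistances(species=species, matrix=D)
        assert phylo_dissimilarity("t", ["a", "b"], np.array([75.0, 25.0]), pd_) == pytest.approx(
            12.5
        )
        assert phylo_dissimilarity("t", ["a"], np.array([3.0]), pd_) == 10.0
        # equal distances: covers do not matter
        D2 = np.array([[0.0, 7.0, 7.0], [7.0, 0.0, 1.0], [7.0, 1.0, 0.0]])
        pd2 = PhyloDistances(species=species, matrix=D2)
        for w in ([1.0, 99.0], [50.0, 50.0]):
            assert phylo_dissimilarity("t", ["a", "b"], np.array(w), pd2) == pytest.approx(7.0)


def naive_records(species, coords, traits, covers, D, include_target=False,
                  pairwise_weighted=False, phylo_weighted=True):
    """Independent brute-force implementation of every metric."""
    out = {}
    n = len(species)
    for i in range(n):
        rec = {}
        others = [j for j in range(n) if j != i or include_target]
        loo = [j for j in range(n) if j != i]
        if loo:
            sel = others if include_target else loo
            w = np.array([covers[j] for j in sel])
            cent = sum(covers[j] * coords[j] for j in sel) / w.sum()
            rec["ranked_multi"] = float(np.linalg.norm(coords[i] - cent))
            dists = np.array([np.linalg.norm(coords[i] - coords[j]) for j in sel])
            rec["pairwise_multi"] = float(
                (w * dists).sum() / w.sum() if pairwise_weighted else dists.mean()
            )
            for t in TRAIT_NAMES:
                v = np.array([traits.loc[species[j], t] for j in sel])
                rec[f"ranked_uni_{t}"] = float(
                    traits.loc[species[i], t] - (w * v).sum() / w.sum()
                )
                ad = np.abs(traits.loc[species[i], t] - v)
                rec[f"pairwise_uni_{t}"] = float(
                    (w * ad).sum() / w.sum() if pairwise_weighted else ad.mean()
                )
            pdists = np.array([D[i, j] for j in sel])
            rec["phylo_dist"] = float(
                (w * pdists).sum() / w.sum() if phylo_weighted else pdists.mean()
            )
        out[species[i]] = rec
    return out


def one_plot_cover(species, covers):
    return pd.DataFrame(
        {"field": "F1", "transect": "T1", "plot": "P1", "year": 2000,
         "species": species, "cover": covers}
    )


@pytest.mark.parametrize("include_target", [False, True])
@pytest.mark.parametrize("pairwise_weighted", [False, True])
def test_compute_all_matches_naive_oracle(include_target, pairwise_weighted):
    """30 random communities, every metric, every weighting variant, 1e-10."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        m = int(rng.integers(2, 15))
        species, coords, traits, covers, D = make_random_community(rng, m)
        space = make_trait_space(species, coords)
        phylo = PhyloDistances(species=list(species), matrix=D)
        cfg = MetricConfig(include_target=include_target, pairwise_weighted=pairwise_weighted)
        rec = compute_all(
            one_plot_cover(species, covers), space, traits, phylo, "neighborhood", cfg
        ).set_index("species")
        expected = naive_records(
            species, coords, traits, covers, D,
            include_target=include_target, pairwise_weighted=pairwise_weighted,
        )
        for s, exp in expected.items():
            for k, v in exp.items():
                assert rec.loc[s, k] == pytest.approx(v, abs=1e-10), (s, k)


class TestComputeAllStructure:
    def test_singleton_community_all_missing(self):
        rng = np.random.default_rng(1)
        species, coords, traits, covers, D = make_random_community(rng, 1)
        space = make_trait_space(species, coords)
        phylo = PhyloDistances(species=list(species), matrix=D)
        rec = compute_all(one_plot_cover(species, covers), space, traits, phylo)
        assert len(rec) == 1
        assert rec[["ranked_multi", "pairwise_multi", "phylo_dist"]].isna().all().all()

    def test_member_order_invariance(self):
        rng = np.random.default_rng(2)
        species, coords, traits, covers, D = make_random_community(rng, 8)
        space = make_trait_space(species, coords)
        phylo = PhyloDistances(species=list(species), matrix=D)
        cover = one_plot_cover(species, covers)
        a = compute_all(cover, space, traits, phylo).set_index("species").sort_index()
        b = (
            compute_all(cover.iloc[::-1].reset_index(drop=True), space, traits, phylo)
            .set_index("species").sort_index()
        )
        pd.testing.assert_frame_equal(a, b)

    def test_bare_ground_and_litter_excluded(self):
        rng = np.random.default_rng(3)
        species, coords, traits, covers, D = make_random_community(rng, 3)
        space = make_trait_space(species, coords)
        phylo = PhyloDistances(species=list(species), matrix=D)
        cover = one_plot_cover(
            list(species) + ["bare_ground", "litter"], list(covers) + [40.0, 20.0]
        )
        rec = compute_all(cover, space, traits, phylo)
        assert set(rec["species"]) == set(species)

    def test_species_off_tree_flagged_missing(self):
        rng = np.random.default_rng(4)
        species, coords, traits, covers, D = make_random_community(rng, 4)
        space = make_trait_space(species, coords)
        phylo = PhyloDistances(species=list(species[:-1]), matrix=D[:-1, :-1])
        rec = compute_all(one_plot_cover(species, covers), space, traits, phylo).set_index(
            "species"
        )
        assert np.isnan(rec.loc[species[-1], "phylo_dist"])
        assert not np.isnan(rec.loc[species[0], "phylo_dist"])
        assert not np.isnan(rec.loc[species[-1], "ranked_multi"])  # functional still defined


class TestInvariances:
    def make(self, m=9, seed=5):
        rng = np.random.default_rng(seed)
        species, coords, traits, covers, D = make_random_community(rng, m)
        phylo = PhyloDistances(species=list(species), matrix=D)
        return species, coords, traits, covers, D, phylo

    def run(self, species, coords, traits, covers, phylo, **cfg):
        space = make_trait_space(species, coords)
        return compute_all(
            one_plot_cover(species, covers), space, traits, phylo, "neighborhood",
            MetricConfig(**cfg),
        ).set_index("species").sort_index()

    def test_cover_rescaling_leaves_metrics_unchanged(self):
        species, coords, traits, covers, D, phylo = self.make()
        a = self.run(species, coords, traits, covers, phylo)
        b = self.run(species, coords, traits, covers * 7.3, phylo)
        metric_cols = [c for c in a.columns if c not in ("cover",)]
        pd.testing.assert_frame_equal(a[metric_cols], b[metric_cols], atol=1e-10)

    def test_ranked_multi_translation_and_rotation_invariant(self):
        species, coords, traits, covers, D, phylo = self.make()
        base = self.run(species, coords, traits, covers, phylo)["ranked_multi"]
        shifted = self.run(species, coords + np.array([3.0, -1.0, 2.5]), traits, covers, phylo)[
            "ranked_multi"
        ]
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = self.run(species, coords @ Q.T, traits, covers, phylo)["ranked_multi"]
        assert np.allclose(base, shifted, atol=1e-10)
        assert np.allclose(base, rotated, atol=1e-10)

    def test_jensen_bound_under_matched_weighting(self):
        species, coords, traits, covers, D, phylo = self.make(m=12, seed=9)
        rec = self.run(species, coords, traits, covers, phylo, pairwise_weighted=True)
        for t in TRAIT_NAMES:
            assert (rec[f"pairwise_uni_{t}"] >= rec[f"ranked_uni_{t}"].abs() - 1e-12).all()

    def test_phylo_dissimilarity_within_member_distance_range(self):
        species, coords, traits, covers, D, phylo = self.make(m=10, seed=10)
        rec = self.run(species, coords, traits, covers, phylo)
        for i, s in enumerate(species):
            others = [j for j in range(len(species)) if j != i]
            dists = D[i, others]
            assert dists.min() - 1e-12 <= rec.loc[s, "phylo_dist"] <= dists.max() + 1e-12
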