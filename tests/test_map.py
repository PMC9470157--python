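import numpy as np
import pytest

from lcrtools import (
    build_map,
    cluster,
    cluster_occupancy,
    composition_matrix,
    embed,
    label_clusters,
    quartile_enriched,
)
from lcrtools.calling import LcrCall
from lcrtools.io import SequenceInterval
from lcrtools.mapping import AA_LIST, CompositionMatrix

from conftest import island_calls


def call_with(seq, pid="p", index=1):
    return LcrCall(SequenceInterval(pid, 1, len(seq)), seq, index)


def comp_from_rows(rows):
    import pandas as pd

    freq = pd.DataFrame(rows, columns=AA_LIST)
    meta = pd.DataFrame(
        {
            "protein_id": [f"p{i}" for i in range(len(rows))],
            "lcr_index": 1,
            "species": "",
            "length": 20,
        }
    )
    return CompositionMatrix(freq, meta)


class TestCompositionMatrix:
    @pytest.mark.parametrize(
        "seq,expect",
        [
            ("KKKK", {"K": 1.0}),
            ("KKEE", {"K": 0.5, "E": 0.5}),
            ("KKXK", {"K": 1.0}),  # X excluded from the denominator
        ],
    )
    def test_frequencies(self, seq, expect):
        comp = composition_matrix([call_with(seq)])
        row = comp.frequencies.iloc[0]
        for aa in AA_LIST:
            assert row[aa] == pytest.approx(expect.get(aa, 0.0))

    def test_all_nonstandard_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped 1"):
            comp = composition_matrix([call_with("XXXX"), call_with("KKKK", "q")])
        assert len(comp) == 1

    def test_rows_sum_to_one(self, two_island_comp):
        assert np.allclose(two_island_comp.values.sum(axis=1), 1.0, atol=1e-9)

    def test_species_tag_carried(self):
        comp = composition_matrix([call_with("KKKK")], species="yeast")
        assert list(comp.meta["species"]) == ["yeast"]


class TestEmbed:
    def test_deterministic_given_seed(self, two_island_comp):
        a = embed(two_island_comp, seed=73)
        b = embed(two_island_comp, seed=73)
        assert np.array_equal(a, b)
        assert np.isfinite(a).all()

    def test_two_islands_are_separable(self, two_island_comp):
        from sklearn.metrics import silhouette_score

        coords = embed(two_island_comp, seed=73)
        truth = np.array([0] * 300 + [1] * 300)
        assert silhouette_score(coords, truth) > 0.8

    def test_too_few_rows_error_names_minimum(self):
        comp = composition_matrix([call_with("KKKK", f"p{i}") for i in range(5)])
        with pytest.raises(ValueError, match="16"):
            embed(comp, n_neighbors=15)


class TestCluster:
    def test_two_islands_recovered_exactly(self, two_island_comp):
        labels = cluster(two_island_comp, seed=73)
        truth = np.array([0] * 300 + [1] * 300)
        assert len(np.unique(labels)) == 2
        purity = sum(
            np.bincount(truth[labels == c]).max() for c in np.unique(labels)
        ) / len(labels)
        assert purity > 0.99

    def test_degenerate_identical_rows_one_cluster(self):
        comp = composition_matrix([call_with("KKKK", f"p{i}") for i in range(40)])
        labels = cluster(comp, n_neighbors=10, seed=73)
        assert len(np.unique(labels)) == 1
        assert len(labels) == 40

    def test_permutation_invariance(self, two_island_comp):
        labels = cluster(two_island_comp, seed=73)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(two_island_comp))
        comp_p = comp_from_rows(two_island_comp.values[perm])
        labels_p = cluster(comp_p, seed=73)
        # same partition of rows, up to label renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


class TestLabelClusters:
    def test_pure_cluster_named_by_residue(self):
        rows = np.zeros((10, 20))
        rows[:, AA_LIST.index("K")] = 1.0
        names = label_clusters(comp_from_rows(rows), np.zeros(10, dtype=int))
        assert names == {0: "K"}

    def test_two_dominant_residues_joined(self):
        rows = np.zeros((10, 20))
        rows[:, AA_LIST.index("G")] = 0.30
        rows[:, AA_LIST.index("P")] = 0.28
        rest = [i for i, a in enumerate(AA_LIST) if a not in "GP"]
        rows[:, rest] = 0.42 / len(rest)
        names = label_clusters(comp_from_rows(rows), np.zeros(10, dtype=int))
        assert names == {0: "G/P"}

    def test_name_fraction_configurable(self):
        rows = np.zeros((10, 20))
        rows[:, AA_LIST.index("G")] = 0.30
        rows[:, AA_LIST.index("P")] = 0.28
        rest = [i for i, a in enumerate(AA_LIST) if a not in "GP"]
        rows[:, rest] = 0.42 / len(rest)
        names = label_clusters(comp_from_rows(rows), np.zeros(10, dtype=int), 0.95)
        assert names == {0: "G"}


class TestQuartileEnriched:
    def test_top_quartile_of_four_values(self):
        rows = np.zeros((4, 20))
        rows[:, AA_LIST.index("E")] = [0.0, 0.1, 0.2, 0.9]
        rows[:, AA_LIST.index("K")] = 1.0 - rows[:, AA_LIST.index("E")]
        comp = comp_from_rows(rows)
        mask = quartile_enriched(comp, "E", np.ones(4, dtype=bool))
        assert mask.tolist() == [False, False, False, True]

    def test_all_equal_selects_all(self):
        rows = np.zeros((6, 20))
        rows[:, AA_LIST.index("E")] = 0.5
        rows[:, AA_LIST.index("K")] = 0.5
        mask = quartile_enriched(comp_from_rows(rows), "E", np.ones(6, dtype=bool))
        assert mask.all()

    def test_empty_reference_rejected(self):
        comp = composition_matrix([call_with("KKKK")])
        with pytest.raises(ValueError):
            quartile_enriched(comp, "E", np.zeros(1, dtype=bool))

    def test_both_enrichment_is_intersection(self):
        rows = np.zeros((8, 20))
        rows[:, AA_LIST.index("E")] = [0.1, 0.2, 0.3, 0.8, 0.8, 0.1, 0.2, 0.8]
        rows[:, AA_LIST.index("K")] = 1.0 - rows[:, AA_LIST.index("E")]
        comp = comp_from_rows(rows)
        ref = np.ones(8, dtype=bool)
        both = quartile_enriched(comp, "E", ref) & quartile_enriched(comp, "K", ref)
        assert not both.any()  # E-rich and K-rich quartiles are disjoint here


class TestClusterOccupancy:
    def test_disjoint_species_clusters_diagonal(self):
        labels = np.array([0] * 10 + [1] * 10)
        species = np.array(["human"] * 10 + ["yeast"] * 10)
        table = cluster_occupancy(labels, species)
        assert table.loc["human", 0] == 10 and table.loc["yeast", 1] == 10
        assert table.to_numpy().sum() == 20

    def test_shuffling_preserves_marginals(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=60)
        species = np.array(["a"] * 30 + ["b"] * 30)
        t1 = cluster_occupancy(labels, species)
        perm = rng.permutation(60)
        t2 = cluster_occupancy(labels[perm], species[perm])
        assert t1.sum(axis=1).equals(t2.sum(axis=1))


class TestBuildMap:
    def test_bundle_aligns_and_records_params(self, two_island_comp):
        emb = build_map(two_island_comp, seed=73)
        frame = emb.to_frame()
        assert len(frame) == len(two_island_comp)
        assert set(frame["cluster_name"]) == {"K", "E"}
        assert emb.params["seed"] == 73 and emb.params["n_neighbors"] == 15
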