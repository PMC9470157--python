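import numpy as np
import pytest

from lcrtools import (
    assign_types,
    call_lcrs,
    call_protein,
    classify_protein,
    find_type_edges,
    segment_matrix,
    total_vs_distinct_table,
    write_lcr_table,
)
from lcrtools.calling import (
    LcrCall,
    SegmentedMask,
    export_protein_graph,
    load_protein_graph,
)
from lcrtools.dotplot import IntensityMatrix
from lcrtools.io import ProteinRecord, SequenceInterval
from lcrtools.synthetic import BlockSpec, make_planted_proteome


def intensity_from(matrix):
    return IntensityMatrix("p", np.asarray(matrix, dtype=np.int16), 10)


def mask_from(label_matrix, threshold=50):
    return SegmentedMask("p", np.asarray(label_matrix, dtype=np.int32), threshold)


def diag_mask(n, segments, extra=()):
    """Labelled mask with given 1-based diagonal runs and extra labelled pixels."""
    m = np.zeros((n, n), dtype=np.int32)
    for lab, (a, b) in enumerate(segments, start=1):
        for i in range(a - 1, b):
            m[i, i] = lab
    for lab, (i, j) in extra:
        m[i - 1, j - 1] = lab
        m[j - 1, i - 1] = lab
    return mask_from(m)


class TestSegmentMatrix:
    def test_single_block_is_one_component(self):
        m = np.zeros((20, 20), dtype=int)
        m[5:9, 5:9] = 60
        assert segment_matrix(intensity_from(m), 50).n_components == 1

    def test_separated_blocks_are_two_components(self):
        m = np.zeros((20, 20), dtype=int)
        m[2:5, 2:5] = 60
        m[10:13, 10:13] = 60
        assert segment_matrix(intensity_from(m), 50).n_components == 2

    def test_corner_touching_blocks_join_under_8_connectivity(self):
        m = np.zeros((10, 10), dtype=int)
        m[2:4, 2:4] = 60
        m[4:6, 4:6] = 60  # touches only at corner (3,3)-(4,4)
        assert segment_matrix(intensity_from(m), 50).n_components == 1
        assert segment_matrix(intensity_from(m), 50, connectivity=4).n_components == 2

    def test_threshold_is_inclusive(self):
        m = np.full((5, 5), 50)
        assert (segment_matrix(intensity_from(m), 50).labels == 1).all()


class TestCallLcrs:
    def test_expansion_minus4_plus5(self):
        rec = ProteinRecord("p", "p", "A" * 100)
        mask = diag_mask(100, [(20, 40)])
        (call,) = call_lcrs(mask, rec)
        assert (call.interval.start, call.interval.stop) == (16, 45)
        assert call.sequence == rec.sequence[15:45]

    def test_clamping_at_protein_start(self):
        rec = ProteinRecord("p", "p", "A" * 100)
        (call,) = call_lcrs(diag_mask(100, [(1, 12)]), rec)
        assert (call.interval.start, call.interval.stop) == (1, 17)

    def test_clamping_at_protein_stop(self):
        rec = ProteinRecord("p", "p", "A" * 50)
        (call,) = call_lcrs(diag_mask(50, [(40, 50)]), rec)
        assert (call.interval.start, call.interval.stop) == (36, 50)

    def test_off_diagonal_component_is_not_called(self):
        rec = ProteinRecord("p", "p", "A" * 40)
        mask = diag_mask(40, [], extra=[(1, (5, 30))])
        assert call_lcrs(mask, rec) == []

    def test_colliding_expanded_intervals_merge(self):
        rec = ProteinRecord("p", "p", "A" * 100)
        # expanded: 16..45 and 42..75 overlap -> one call
        calls = call_lcrs(diag_mask(100, [(20, 40), (46, 70)]), rec)
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.stop) == (16, 75)

    def test_raw_extent_uses_diagonal_indices_only(self):
        rec = ProteinRecord("p", "p", "A" * 60)
        # component 1 has an off-diagonal lobe reaching row 50: must not widen
        mask = diag_mask(60, [(20, 30)])
        mask.labels[49, 24] = 1
        mask.labels[24, 49] = 1
        (call,) = call_lcrs(mask, rec)
        assert (call.interval.start, call.interval.stop) == (16, 35)

    def test_calls_are_sorted_n_to_c_with_indices(self):
        rec = ProteinRecord("p", "p", "A" * 200)
        calls = call_lcrs(diag_mask(200, [(100, 120), (20, 40)]), rec)
        assert [c.lcr_index for c in calls] == [1, 2]
        assert calls[0].interval.start < calls[1].interval.start


class TestTypeAssignment:
    def test_planted_identical_blocks_share_a_type(self):
        planted = make_planted_proteome(
            1, (250, 250), [BlockSpec(20, "K"), BlockSpec(20, "K")], seed=4
        )
        calls, graph = call_protein(planted.proteome[0], threshold=30)
        assert len(calls) == 2
        assert calls[0].type_id == calls[1].type_id == 1
        assert calls[0].type_copy_number == 2
        assert graph.n_types == 1

    def test_disjoint_alphabet_blocks_get_distinct_types(self):
        planted = make_planted_proteome(
            1, (250, 250), [BlockSpec(20, "K"), BlockSpec(20, "E")], seed=4
        )
        calls, graph = call_protein(planted.proteome[0], threshold=30)
        assert len(calls) == 2
        assert calls[0].type_id != calls[1].type_id
        assert {c.type_copy_number for c in calls} == {1}
        assert graph.n_types == 2

    def test_single_lcr_has_empty_edge_set(self):
        planted = make_planted_proteome(1, (200, 200), [BlockSpec(20, "K")], seed=4)
        rec = planted.proteome[0]
        calls, graph = call_protein(rec, threshold=30)
        assert len(calls) == 1 and graph.edges == set()

    def test_transitive_closure_makes_one_type(self):
        calls = [
            LcrCall(SequenceInterval("p", 1 + 30 * i, 20 + 30 * i), "K" * 20, i + 1)
            for i in range(3)
        ]
        typed, graph = assign_types(
            calls, {frozenset((1, 2)), frozenset((2, 3))}
        )
        assert all(c.type_id == 1 and c.type_copy_number == 3 for c in typed)
        assert graph.components == [[1, 2, 3]]

    def test_no_edges_gives_one_type_per_lcr(self):
        calls = [
            LcrCall(SequenceInterval("p", 1 + 30 * i, 20 + 30 * i), "K" * 20, i + 1)
            for i in range(2)
        ]
        typed, graph = assign_types(calls, set())
        assert [c.type_id for c in typed] == [1, 2]
        assert graph.n_types == 2

    def test_find_type_edges_checks_intersection_rectangle(self):
        rec_len = 100
        mask = diag_mask(rec_len, [(10, 20), (60, 70)])
        calls = [
            LcrCall(SequenceInterval("p", 6, 25), "A" * 20, 1),
            LcrCall(SequenceInterval("p", 56, 75), "A" * 20, 2),
        ]
        assert find_type_edges(mask, calls) == set()
        mask.labels[12, 64] = 1  # one segmented pixel inside rows(1) x cols(2)
        assert find_type_edges(mask, calls) == {frozenset((1, 2))}


class TestClassification:
    @pytest.mark.parametrize(
        "total,distinct,expected",
        [
            (1, 1, "single"),
            (3, 1, "multiple-same"),  # e.g. three copies of one type
            (3, 3, "multiple-distinct"),
            (22, 4, "multiple-mixed"),  # many LCRs across few types
            (2, 1, "multiple-same"),
            (2, 2, "multiple-distinct"),
        ],
    )
    def test_group_scheme(self, total, distinct, expected):
        assert classify_protein(total, distinct) == expected

    @pytest.mark.parametrize("total,distinct", [(1, 2), (3, 0), (0, 0)])
    def test_invalid_counts_rejected(self, total, distinct):
        with pytest.raises(ValueError):
            classify_protein(total, distinct)

    def test_total_vs_distinct_table_counts_proteins(self):
        def typed(pid, n_lcrs, n_types):
            calls = []
            for i in range(n_lcrs):
                calls.append(
                    LcrCall(
                        SequenceInterval(pid, 1 + 30 * i, 20 + 30 * i),
                        "K" * 20,
                        i + 1,
                        type_id=min(i + 1, n_types),
                        type_copy_number=1,
                    )
                )
            return calls

        calls = typed("a", 1, 1) + typed("b", 1, 1) + typed("c", 2, 1)
        table = total_vs_distinct_table(calls)
        as_dict = {
            (r.total_lcrs, r.distinct_types): r.n_proteins
            for r in table.itertuples(index=False)
        }
        assert as_dict == {(1, 1): 2, (2, 1): 1}
        assert table["n_proteins"].sum() == 3

    def test_empty_calls_give_empty_table(self):
        assert len(total_vs_distinct_table([])) == 0


class TestGraphExport:
    def test_round_trip_preserves_structure(self, tmp_path):
        planted = make_planted_proteome(
            1, (300, 300), [BlockSpec(18, "K"), BlockSpec(18, "K"), BlockSpec(18, "E")],
            seed=8,
        )
        calls, graph = call_protein(planted.proteome[0], threshold=30)
        path = tmp_path / "g.json"
        export_protein_graph(graph, calls, path)
        back = load_protein_graph(path)
        assert back.protein_id == graph.protein_id
        assert back.nodes == graph.nodes
        assert back.edges == graph.edges
        assert back.components == graph.components

    def test_empty_graph_exports_valid_json(self, tmp_path):
        typed, graph = assign_types([], set())
        path = tmp_path / "g.json"
        export_protein_graph(graph, typed, path)
        back = load_protein_graph(path)
        assert back.nodes == [] and back.edges == set()


class TestDeterminism:
    def test_identical_inputs_give_byte_identical_tables(self, tmp_path):
        planted = make_planted_proteome(
            5, (150, 250), [BlockSpec(16, "K")], seed=21
        )
        paths = []
        for run in range(2):
            all_calls = []
            for rec in planted.proteome:
                calls, _ = call_protein(rec, threshold=28)
                all_calls.extend(calls)
            path = tmp_path / f"run{run}.tsv"
            write_lcr_table(all_calls, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]
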