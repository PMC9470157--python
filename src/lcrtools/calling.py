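"""LCR calling from segmented dotplots, and type/copy-number assignment.

Pixels at or above the FDR-derived intensity threshold are labelled into
connected components (8-connectivity by default, since repeat signatures run
diagonally).  Components touching the main diagonal define LCRs: the raw
extent is the min..max diagonal index of the component, expanded by -4/+5 to
undo the kernel-size shrinkage and clamped to the protein ends.  Expanded
intervals that collide are merged.

Within a protein, LCRs form a graph whose edges are off-diagonal segmented
intersections between two LCRs' coordinate rectangles.  Connected components
of that graph are the LCR *types*; the size of a component is the *copy
number* of each of its members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label

from .dotplot import (
    DEFAULT_KERNEL_SIZE,
    DEFAULT_MAX_FULL_MATRIX,
    IntensityMatrix,
    threshold_mask,
)
from .io import ProteinRecord, SequenceInterval
from .stats import shannon_entropy

__all__ = [
    "SegmentedMask",
    "LcrCall",
    "LcrTypeGraph",
    "segment_matrix",
    "segment_protein",
    "call_lcrs",
    "find_type_edges",
    "assign_types",
    "call_protein",
    "classify_protein",
    "total_vs_distinct_table",
    "export_protein_graph",
    "load_protein_graph",
    "PROTEIN_GROUPS",
]

PROTEIN_GROUPS = ("single", "multiple-same", "multiple-distinct", "multiple-mixed")


@dataclass
class SegmentedMask:
    """Connected-component labelling of above-threshold dotplot pixels.

    ``labels`` is N x N int32; 0 is background, 1..K are components.
    """

    protein_id: str
    labels: np.ndarray
    threshold: int
    connectivity: int = 8

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


@dataclass
class LcrCall:
    """One called low complexity region with its within-protein typing."""

    interval: SequenceInterval
    sequence: str
    lcr_index: int = 0  # 1-based, N-terminal to C-terminal
    type_id: int | None = None  # 1-based per protein
    type_copy_number: int | None = None
    entropy_bits: float | None = None

    @property
    def protein_id(self) -> str:
        return self.interval.protein_id


@dataclass
class LcrTypeGraph:
    """Per-protein graph: nodes are lcr_index values, edges are intersections."""

    protein_id: str
    nodes: list[int]
    edges: set[frozenset[int]]
    components: list[list[int]] = field(default_factory=list)

    @property
    def n_types(self) -> int:
        return len(self.components)


def _label_mask(mask: np.ndarray, connectivity: int) -> np.ndarray:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    # skimage connectivity: 1 = edge-adjacent (4-conn), 2 = includes diagonal (8-conn)
    return _sk_label(mask, connectivity=2 if connectivity == 8 else 1).astype(np.int32)


def segment_matrix(
    m: IntensityMatrix, threshold: int, connectivity: int = 8
) -> SegmentedMask:
    """Label connected components of pixels with intensity >= threshold."""
    if not (1 <= threshold <= m.kernel_size**2):
        raise ValueError(f"threshold {threshold} outside 1..{m.kernel_size**2}")
    return SegmentedMask(
        m.protein_id, _label_mask(m.matrix >= threshold, connectivity), threshold, connectivity
    )


def segment_protein(
    record: ProteinRecord,
    threshold: int,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    connectivity: int = 8,
    max_full_matrix: int = DEFAULT_MAX_FULL_MATRIX,
) -> SegmentedMask:
    """Segment one protein directly from its sequence (blocked for long proteins)."""
    mask = threshold_mask(record, threshold, kernel_size, max_full_matrix)
    return SegmentedMask(
        record.protein_id, _label_mask(mask, connectivity), threshold, connectivity
    )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting 0-based half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def call_lcrs(
    mask: SegmentedMask,
    record: ProteinRecord,
    pad_left: int = 4,
    pad_right: int = 5,
    entropy_base: float = 2.0,
) -> list[LcrCall]:
    """Call LCRs from components that intersect the diagonal.

    Raw extent of a component is the min..max of its diagonal indices (an
    off-diagonal lobe never extends an LCR); the extent is widened by
    ``-pad_left``/``+pad_right`` residues and clamped to the protein, and
    colliding widened intervals are merged.  Calls are returned N- to
    C-terminal with ``lcr_index`` assigned; type fields stay unset.
    """
    n = len(record)
    if mask.labels.shape != (n, n):
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match protein length {n}"
        )
    diag = np.diagonal(mask.labels)
    intervals: list[tuple[int, int]] = []
    for comp in np.unique(diag[diag > 0]):
        idx = np.flatnonzero(diag == comp)
        start0 = max(int(idx.min()) - pad_left, 0)
        stop0 = min(int(idx.max()) + pad_right, n - 1) + 1  # half-open
        intervals.append((start0, stop0))
    calls = []
    for i, (start0, stop0) in enumerate(_merge_intervals(intervals), start=1):
        iv = SequenceInterval.from_zero_based(record.protein_id, start0, stop0)
        seq = record.sequence[start0:stop0]
        calls.append(
            LcrCall(
                interval=iv,
                sequence=seq,
                lcr_index=i,
                entropy_bits=shannon_entropy(seq, base=entropy_base),
            )
        )
    return calls


def find_type_edges(mask: SegmentedMask, calls: list[LcrCall]) -> set[frozenset[int]]:
    """Edges between LCRs whose off-diagonal intersection contains segmentation.

    LCRs a and b (a != b) are connected iff any labelled pixel lies in the
    rectangle rows(a) x cols(b) of the segmented matrix, using the widened
    (reported) intervals.  The mask is symmetric, so one rectangle per pair
    suffices.
    """
    edges: set[frozenset[int]] = set()
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            rect = mask.labels[a.interval.slice, b.interval.slice]
            if (rect > 0).any():
                edges.add(frozenset((a.lcr_index, b.lcr_index)))
    return edges


def assign_types(
    calls: list[LcrCall], edges: set[frozenset[int]]
) -> tuple[list[LcrCall], LcrTypeGraph]:
    """Assign type ids and copy numbers from graph connected components.

    Type ids are numbered 1..C in order of each component's most N-terminal
    member; every call's copy number is the size of its component.
    """
    if not calls:
        pid = ""
        return [], LcrTypeGraph(pid, [], set(), [])
    pid = calls[0].protein_id
    g = nx.Graph()
    g.add_nodes_from(c.lcr_index for c in calls)
    g.add_edges_from(tuple(e) for e in edges)
    components = sorted((sorted(comp) for comp in nx.connected_components(g)), key=min)
    type_of: dict[int, tuple[int, int]] = {}
    for type_id, comp in enumerate(components, start=1):
        for node in comp:
            type_of[node] = (type_id, len(comp))
    typed = [
        replace(c, type_id=type_of[c.lcr_index][0], type_copy_number=type_of[c.lcr_index][1])
        for c in calls
    ]
    graph = LcrTypeGraph(
        pid, [c.lcr_index for c in calls], set(edges), [list(c) for c in components]
    )
    assert sum(len(c) for c in graph.components) == len(graph.nodes)
    return typed, graph


def call_protein(
    record: ProteinRecord,
    threshold: int,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    connectivity: int = 8,
    pad_left: int = 4,
    pad_right: int = 5,
    entropy_base: float = 2.0,
    max_full_matrix: int = DEFAULT_MAX_FULL_MATRIX,
) -> tuple[list[LcrCall], LcrTypeGraph]:
    """Segment, call, and type the LCRs of one protein."""
    mask = segment_protein(record, threshold, kernel_size, connectivity, max_full_matrix)
    calls = call_lcrs(mask, record, pad_left, pad_right, entropy_base)
    edges = find_type_edges(mask, calls)
    return assign_types(calls, edges)


def classify_protein(total_lcrs: int, distinct_types: int) -> str:
    """Protein group from its total LCR count and distinct type count.

    single (1 LCR), multiple-same (several copies of one type),
    multiple-distinct (several types, one copy each), multiple-mixed
    (several types, at least one with several copies).
    """
    if not (1 <= distinct_types <= total_lcrs):
        raise ValueError(
            f"need 1 <= distinct ({distinct_types}) <= total ({total_lcrs})"
        )
    if total_lcrs == 1:
        return "single"
    if distinct_types == 1:
        return "multiple-same"
    if distinct_types == total_lcrs:
        return "multiple-distinct"
    return "multiple-mixed"


def total_vs_distinct_table(calls: list[LcrCall]) -> pd.DataFrame:
    """Protein counts by (total LCRs, distinct types), over LCR-containing proteins."""
    per_protein: dict[str, tuple[int, int]] = {}
    for c in calls:
        if c.type_id is None:
            raise ValueError("calls must be typed (run assign_types first)")
        total, distinct = per_protein.get(c.protein_id, (0, 0))
        per_protein[c.protein_id] = (total + 1, max(distinct, c.type_id))
    if not per_protein:
        return pd.DataFrame(columns=["total_lcrs", "distinct_types", "n_proteins"])
    counts: dict[tuple[int, int], int] = {}
    for total, distinct in per_protein.values():
        counts[(total, distinct)] = counts.get((total, distinct), 0) + 1
    df = pd.DataFrame(
        [(t, d, n) for (t, d), n in sorted(counts.items())],
        columns=["total_lcrs", "distinct_types", "n_proteins"],
    )
    assert df["n_proteins"].sum() == len(per_protein)
    return df


def export_protein_graph(
    graph: LcrTypeGraph, calls: list[LcrCall], path: str | Path
) -> None:
    """Write a per-protein LCR graph as JSON (nodes with coordinates, edges)."""
    by_index = {c.lcr_index: c for c in calls}
    payload = {
        "protein_id": graph.protein_id,
        "nodes": [
            {
                "lcr_index": i,
                "start": by_index[i].interval.start if i in by_index else None,
                "stop": by_index[i].interval.stop if i in by_index else None,
                "type_id": by_index[i].type_id if i in by_index else None,
            }
            for i in graph.nodes
        ],
        "edges": sorted(sorted(e) for e in graph.edges),
        "components": graph.components,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_protein_graph(path: str | Path) -> LcrTypeGraph:
    payload = json.loads(Path(path).read_text())
    return LcrTypeGraph(
        payload["protein_id"],
        [n["lcr_index"] for n in payload["nodes"]],
        {frozenset(e) for e in payload["edges"]},
        [list(c) for c in payload["components"]],
    )
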