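"""End-to-end orchestration: threshold -> call -> validate -> map -> enrich.

One :class:`PipelineConfig` carries every tunable constant; every artifact
written records the full configuration and all seeds, so a rerun with the
same inputs is byte-identical.  Thresholds are derived independently per
proteome (each against its own length-matched null), so adding a second
species never changes the first species' calls; the composition map pools
LCRs across all proteomes.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calling import (
    LcrCall,
    assign_types,
    call_lcrs,
    classify_protein,
    export_protein_graph,
    find_type_edges,
    segment_protein,
    total_vs_distinct_table,
)
from .io import AnnotationSet, Proteome, write_lcr_table
from .mapping import CompositionMatrix, build_map, composition_matrix
from .null_model import derive_threshold
from .stats import entropy_validation

__all__ = ["PipelineConfig", "ProteomeResult", "PipelineResult", "run_pipeline", "call_proteome"]


@dataclass
class PipelineConfig:
    kernel_size: int = 10
    target_fdr: float = 0.002
    pad_left: int = 4
    pad_right: int = 5
    connectivity: int = 8
    embed_seed: int = 73
    cluster_seed: int = 73
    n_neighbors: int = 15
    leiden_resolution: float = 1.0
    quartile_q: float = 0.75
    enrichment_alpha: float = 0.001
    null_seed: int = 0
    null_replicates: int = 1
    entropy_base: float = 2.0
    entropy_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "kernel_size", "target_fdr", "pad_left", "pad_right", "connectivity",
            "n_neighbors", "leiden_resolution", "quartile_q", "enrichment_alpha",
            "null_replicates", "entropy_base",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProteomeResult:
    proteome_name: str
    threshold: int
    fdr_at_threshold: float
    calls: list[LcrCall]
    entropy_p_value: float | None
    n_proteins: int
    n_lcr_proteins: int

    @property
    def n_lcrs(self) -> int:
        return len(self.calls)


@dataclass
class PipelineResult:
    config: PipelineConfig
    per_proteome: dict[str, ProteomeResult]
    comp: CompositionMatrix | None = None
    embedding: object | None = None
    enrichments: dict[str, object] = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "tool": f"lcrtools {__version__}",
            "config": self.config.to_dict(),
            "proteomes": {
                name: {
                    "threshold": r.threshold,
                    "fdr_at_threshold": r.fdr_at_threshold,
                    "n_proteins": r.n_proteins,
                    "n_lcrs": r.n_lcrs,
                    "n_lcr_proteins": r.n_lcr_proteins,
                    "entropy_p_value": r.entropy_p_value,
                }
                for name, r in self.per_proteome.items()
            },
            "map": dict(self.embedding.params) if self.embedding is not None else None,
        }


def call_proteome(
    proteome: Proteome,
    threshold: int,
    config: PipelineConfig,
    graph_dir: Path | None = None,
) -> tuple[list[LcrCall], int]:
    """Call and type LCRs for every protein; returns (calls, n LCR proteins)."""
    all_calls: list[LcrCall] = []
    n_lcr_proteins = 0
    for rec in proteome:
        mask = segment_protein(
            rec, threshold, config.kernel_size, config.connectivity
        )
        calls = call_lcrs(mask, rec, config.pad_left, config.pad_right, config.entropy_base)
        edges = find_type_edges(mask, calls)
        typed, graph = assign_types(calls, edges)
        if typed:
            n_lcr_proteins += 1
            all_calls.extend(typed)
            if graph_dir is not None:
                export_protein_graph(graph, typed, graph_dir / f"{rec.protein_id}.json")
    return all_calls, n_lcr_proteins


def run_pipeline(
    proteomes: list[Proteome],
    annotations: list[AnnotationSet] | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    export_graphs: bool = False,
    log=None,
) -> PipelineResult:
    """Run the full pipeline over one or more proteomes.

    Per proteome: simulate its null, derive the FDR threshold, call and type
    LCRs, validate entropy.  Across proteomes: pool compositions, embed,
    cluster, and test each annotation set for residue enrichment.  With
    ``outdir`` set, tables and metadata are written there.
    """
    if not proteomes:
        raise ValueError("at least one proteome is required")
    config = config or PipelineConfig()
    annotations = annotations or []
    log = log or (lambda msg: print(msg, file=sys.stderr))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    per_proteome: dict[str, ProteomeResult] = {}
    comp: CompositionMatrix | None = None
    for proteome in proteomes:
        stage = f"threshold[{proteome.name}]"
        try:
            thr = derive_threshold(
                proteome,
                config.target_fdr,
                config.kernel_size,
                seed=config.null_seed,
                null_replicates=config.null_replicates,
            )
            log(f"{stage}: threshold={thr.threshold} fdr={thr.fdr_at_threshold:.2e}")
            stage = f"call[{proteome.name}]"
            graph_dir = None
            if export_graphs and out is not None:
                graph_dir = out / f"{proteome.name}_graphs"
                graph_dir.mkdir(exist_ok=True)
            calls, n_lcr_proteins = call_proteome(proteome, thr.threshold, config, graph_dir)
            log(f"{stage}: {len(calls)} LCRs in {n_lcr_proteins} proteins")
            stage = f"entropy[{proteome.name}]"
            entropy_p = None
            if len(calls) >= 2:
                entropy_p = entropy_validation(
                    calls, proteome, config.entropy_seed, config.entropy_base
                ).p_value
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc
        per_proteome[proteome.name] = ProteomeResult(
            proteome.name,
            thr.threshold,
            thr.fdr_at_threshold,
            calls,
            entropy_p,
            len(proteome),
            n_lcr_proteins,
        )
        species_comp = composition_matrix(calls, species=proteome.name)
        comp = species_comp if comp is None else comp.concat(species_comp)
        if out is not None:
            write_lcr_table(calls, out / f"{proteome.name}_lcrs.tsv")
            total_vs_distinct_table(calls).to_csv(
                out / f"{proteome.name}_total_vs_distinct.tsv", sep="\t", index=False
            )

    result = PipelineResult(config, per_proteome, comp=comp)

    if comp is not None and len(comp) >= config.n_neighbors + 1:
        result.embedding = build_map(
            comp,
            n_neighbors=config.n_neighbors,
            seed=config.embed_seed,
            resolution=config.leiden_resolution,
        )
        if out is not None:
            result.embedding.to_frame().to_csv(out / "lcr_map.csv", index=False)
    else:
        log("map: skipped (too few LCRs for the neighbour graph)")

    if annotations and comp is not None:
        from .enrichment import rank_sum_enrichment

        ids = comp.meta["protein_id"].to_numpy()
        for ann in annotations:
            mask = np.array([pid in ann for pid in ids])
            if 2 <= mask.sum() <= len(mask) - 2:
                res = rank_sum_enrichment(
                    comp, mask, alpha=config.enrichment_alpha, group=ann.name
                )
                result.enrichments[ann.name] = res
                if out is not None:
                    res.table.to_csv(
                        out / f"enrichment_{ann.name}.tsv", sep="\t", index=False
                    )
            else:
                log(f"enrich[{ann.name}]: skipped (degenerate group sizes)")

    if out is not None:
        (out / "run_metadata.json").write_text(
            json.dumps(result.metadata(), indent=1) + "\n"
        )
    return result
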