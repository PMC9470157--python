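"""Amino-acid composition maps of LCRs: embedding, clustering, labelling.

Every LCR is represented by its 20-dimensional amino-acid frequency vector
(denominator: standard residues only).  A UMAP projection of these vectors
gives a 2-D map for display; Leiden community detection on the k-nearest-
neighbour graph built in the *20-D* space gives cluster labels, so the
clustering never inherits projection artifacts.  Clusters are named after
their dominant residues (all residues whose mean frequency reaches half the
cluster's top mean frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .null_model import STANDARD_AMINO_ACIDS

__all__ = [
    "CompositionMatrix",
    "CompositionEmbedding",
    "composition_matrix",
    "embed",
    "cluster",
    "build_map",
    "label_clusters",
    "quartile_enriched",
    "cluster_occupancy",
]

AA_LIST = list(STANDARD_AMINO_ACIDS)


class CompositionMatrix:
    """Per-LCR amino-acid frequency vectors with row metadata.

    ``frequencies`` is an (n_lcrs, 20) DataFrame whose rows sum to 1;
    ``meta`` carries protein_id, lcr_index, species and any annotation tags,
    aligned row for row.
    """

    def __init__(self, frequencies: pd.DataFrame, meta: pd.DataFrame):
        if list(frequencies.columns) != AA_LIST:
            raise ValueError("frequency columns must be the 20 standard amino acids")
        if len(frequencies) != len(meta):
            raise ValueError("frequencies and meta must align")
        sums = frequencies.to_numpy().sum(axis=1)
        if len(frequencies) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")
        self.frequencies = frequencies
        self.meta = meta.set_axis(frequencies.index)

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def values(self) -> np.ndarray:
        return self.frequencies.to_numpy()

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.values.astype(np.float32),
            obs=self.meta.copy(),
            var=pd.DataFrame(index=AA_LIST),
        )
        adata.obs_names = [str(i) for i in self.frequencies.index]
        return adata

    def concat(self, other: "CompositionMatrix") -> "CompositionMatrix":
        freq = pd.concat([self.frequencies, other.frequencies], ignore_index=True)
        meta = pd.concat([self.meta, other.meta], ignore_index=True)
        return CompositionMatrix(freq, meta)


def composition_matrix(calls, species: str | None = None) -> CompositionMatrix:
    """Build the 20-D composition matrix for a list of LCR calls.

    Frequencies are computed over the 20 standard residues; non-standard
    letters (X, U, O, B, Z) are excluded from the denominator.  Calls with
    no standard residue at all are dropped with a warning.
    """
    rows, meta_rows = [], []
    dropped = 0
    for c in calls:
        counts = np.array([c.sequence.count(a) for a in AA_LIST], dtype=float)
        total = counts.sum()
        if total == 0:
            dropped += 1
            continue
        rows.append(counts / total)
        meta_rows.append(
            {
                "protein_id": c.protein_id,
                "lcr_index": c.lcr_index,
                "species": species if species is not None else "",
                "length": len(c.sequence),
            }
        )
    if dropped:
        warnings.warn(f"dropped {dropped} LCRs with no standard residues")
    freq = pd.DataFrame(rows, columns=AA_LIST)
    meta = pd.DataFrame(
        meta_rows, columns=["protein_id", "lcr_index", "species", "length"]
    )
    return CompositionMatrix(freq, meta)


from contextlib import contextmanager


@contextmanager
def _single_threaded_numba():
    """Pin numba to one thread so the seeded UMAP layout is reproducible.

    The stochastic-gradient layout is only deterministic when not run in
    parallel; the thread count is restored afterwards.
    """
    import numba

    previous = numba.get_num_threads()
    numba.set_num_threads(1)
    try:
        yield
    finally:
        numba.set_num_threads(previous)


def _neighbors(adata: ad.AnnData, n_neighbors: int, seed: int) -> None:
    import scanpy as sc

    if len(adata) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} LCRs, got {len(adata)}"
        )
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X", random_state=seed)


def embed(
    comp: CompositionMatrix, n_neighbors: int = 15, seed: int = 73
) -> np.ndarray:
    """2-D UMAP coordinates of the composition vectors (deterministic per seed)."""
    import scanpy as sc

    adata = comp.to_anndata()
    _neighbors(adata, n_neighbors, seed)
    with warnings.catch_warnings(), _single_threaded_numba():
        warnings.simplefilter("ignore")
        # seeded random init: spectral init solves an ARPACK eigenproblem whose
        # starting vector is process-dependent, breaking run-to-run identity
        sc.tl.umap(adata, random_state=seed, n_components=2, init_pos="random")
    return np.asarray(adata.obsm["X_umap"], dtype=float)


def cluster(
    comp: CompositionMatrix,
    n_neighbors: int = 15,
    seed: int = 73,
    resolution: float = 1.0,
) -> np.ndarray:
    """Leiden community labels on the k-NN graph of the 20-D compositions."""
    import scanpy as sc

    adata = comp.to_anndata()
    _neighbors(adata, n_neighbors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(
            adata, random_state=seed, resolution=resolution, flavor="leidenalg"
        )
    return adata.obs["leiden"].astype(int).to_numpy()


@dataclass
class CompositionEmbedding:
    """2-D map + clustering of a composition matrix, with parameters recorded."""

    comp: CompositionMatrix
    coords: np.ndarray
    cluster_labels: np.ndarray
    cluster_names: dict[int, str]
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.comp.meta.copy().reset_index(drop=True)
        df["x"] = self.coords[:, 0]
        df["y"] = self.coords[:, 1]
        df["cluster"] = self.cluster_labels
        df["cluster_name"] = [self.cluster_names[c] for c in self.cluster_labels]
        return df


def build_map(
    comp: CompositionMatrix,
    n_neighbors: int = 15,
    seed: int = 73,
    resolution: float = 1.0,
    name_fraction: float = 0.5,
) -> CompositionEmbedding:
    """Embed, cluster and label a composition matrix in one shot."""
    import scanpy as sc

    adata = comp.to_anndata()
    _neighbors(adata, n_neighbors, seed)
    with warnings.catch_warnings(), _single_threaded_numba():
        warnings.simplefilter("ignore")
        sc.tl.umap(adata, random_state=seed, n_components=2, init_pos="random")
        sc.tl.leiden(adata, random_state=seed, resolution=resolution, flavor="leidenalg")
    coords = np.asarray(adata.obsm["X_umap"], dtype=float)
    labels = adata.obs["leiden"].astype(int).to_numpy()
    names = label_clusters(comp, labels, name_fraction)
    return CompositionEmbedding(
        comp,
        coords,
        labels,
        names,
        params={
            "n_neighbors": n_neighbors,
            "seed": seed,
            "resolution": resolution,
            "name_fraction": name_fraction,
            "n_lcrs": len(comp),
            "scanpy_version": __import__("importlib.metadata", fromlist=["version"]).version("scanpy"),
        },
    )


def label_clusters(
    comp: CompositionMatrix, labels: np.ndarray, name_fraction: float = 0.5
) -> dict[int, str]:
    """Name each cluster by its dominant residues.

    A residue is part of the name if its mean frequency in the cluster is at
    least ``name_fraction`` times the cluster's maximum mean frequency;
    residues are joined by "/" in descending frequency order.
    """
    if len(labels) != len(comp):
        raise ValueError("labels must align with composition rows")
    names: dict[int, str] = {}
    values = comp.values
    for lab in np.unique(labels):
        mean = values[labels == lab].mean(axis=0)
        cutoff = name_fraction * mean.max()
        chosen = [(mean[i], AA_LIST[i]) for i in range(20) if mean[i] >= cutoff]
        chosen.sort(key=lambda t: (-t[0], t[1]))
        names[int(lab)] = "/".join(a for _, a in chosen)
    return names


def quartile_enriched(
    comp: CompositionMatrix,
    residue: str,
    reference_mask: np.ndarray,
    q: float = 0.75,
) -> np.ndarray:
    """Mask of reference LCRs in the top (1-q) tail of a residue's frequency.

    The cutoff is the q-quantile of the residue frequency *within the
    reference rows*, computed with 'higher' interpolation (always an observed
    value, and top-25% of n values means ceil semantics), and selection uses
    >=, so ties at the cutoff are all included.  Returns a full-length
    boolean mask that is False outside the reference.
    """
    if residue not in AA_LIST:
        raise ValueError(f"unknown residue {residue!r}")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != (len(comp),):
        raise ValueError("reference mask must align with composition rows")
    if not reference_mask.any():
        raise ValueError("empty reference set")
    freqs = comp.frequencies[residue].to_numpy()
    cutoff = np.quantile(freqs[reference_mask], q, method="higher")
    return reference_mask & (freqs >= cutoff)


def cluster_occupancy(
    cluster_labels: np.ndarray, species_tags
) -> pd.DataFrame:
    """Species x cluster contingency table of LCR counts."""
    species_tags = np.asarray(species_tags)
    if len(species_tags) != len(cluster_labels):
        raise ValueError("species tags must align with cluster labels")
    df = pd.DataFrame({"species": species_tags, "cluster": cluster_labels})
    table = df.groupby(["species", "cluster"], observed=True).size().unstack(fill_value=0)
    return table
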