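"""Residue-frequency enrichment of annotated LCR sets.

For each of the 20 standard amino acids, a Wilcoxon rank-sum (Mann-Whitney U)
test compares the per-LCR frequency of that residue between an annotated
group and a reference group (the rest of the map, or a second annotation).
Reported per residue: a signed standardized statistic z (positive = enriched
in the annotated/first group), the two-sided p-value, and the
Benjamini-Hochberg adjusted p-value over the 20 tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mapping import AA_LIST, CompositionMatrix

__all__ = ["EnrichmentResult", "rank_sum_enrichment", "pairwise_enrichment"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # residue, z_score, p_value, p_adjusted, significant
    group: str
    reference: str
    alpha: float

    def significant_residues(self) -> list[str]:
        return self.table.loc[self.table["significant"], "residue"].tolist()


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal-approximation rank-sum z and two-sided p.

    z > 0 when values in x tend to be larger than in y.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return 0.0, 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def _enrichment(
    values: np.ndarray,
    mask_group: np.ndarray,
    mask_ref: np.ndarray,
    alpha: float,
    group: str,
    reference: str,
) -> EnrichmentResult:
    if mask_group.sum() < 2 or mask_ref.sum() < 2:
        raise ValueError(
            f"both groups need >= 2 LCRs (got {int(mask_group.sum())} vs "
            f"{int(mask_ref.sum())})"
        )
    zs, ps = [], []
    for j in range(20):
        z, p = _ranksum_z(values[mask_group, j], values[mask_ref, j])
        zs.append(z)
        ps.append(p)
    reject, p_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame(
        {
            "residue": AA_LIST,
            "z_score": zs,
            "p_value": ps,
            "p_adjusted": p_adj,
            "significant": reject,
        }
    )
    return EnrichmentResult(table, group, reference, alpha)


def rank_sum_enrichment(
    comp: CompositionMatrix,
    annotated_mask: np.ndarray,
    alpha: float = 0.001,
    group: str = "annotated",
) -> EnrichmentResult:
    """Annotated LCRs vs all other LCRs, per residue, BH-corrected."""
    annotated_mask = np.asarray(annotated_mask, dtype=bool)
    if annotated_mask.shape != (len(comp),):
        raise ValueError("annotated mask must align with composition rows")
    return _enrichment(
        comp.values, annotated_mask, ~annotated_mask, alpha, group, "rest"
    )


def pairwise_enrichment(
    comp: CompositionMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    alpha: float = 0.001,
    group_a: str = "A",
    group_b: str = "B",
) -> EnrichmentResult:
    """Annotation A vs annotation B (B as reference); positive z = enriched in A.

    Rows belonging to both sets are excluded (rank-sum assumes independent
    groups); the number excluded is reported via a warning.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    overlap = mask_a & mask_b
    if overlap.any():
        warnings.warn(
            f"{int(overlap.sum())} LCRs in both annotation sets were excluded"
        )
        mask_a = mask_a & ~overlap
        mask_b = mask_b & ~overlap
    return _enrichment(comp.values, mask_a, mask_b, alpha, group_a, group_b)
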