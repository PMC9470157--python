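"""Attach externally computed per-position scores (e.g. disorder predictions)
to called LCRs as per-LCR means.

The predictors themselves are external tools; this module only consumes a
generic per-position table (protein_id, position, score; position 1-based)
and averages the scores over each LCR's interval.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_position_scores", "mean_score_per_lcr"]


def read_position_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Read a TSV of (protein_id, position, score) into per-protein vectors.

    Positions must run 1..L contiguously for each protein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"positions for {pid!r} are not contiguous from 1")
        out[str(pid)] = sub["score"].to_numpy(dtype=float)
    return out


def mean_score_per_lcr(
    per_position_scores: dict[str, np.ndarray],
    calls,
    score_name: str = "score",
) -> pd.DataFrame:
    """Mean of a per-position score over each LCR's residue range.

    Score vectors must span the full protein (length checked against each
    LCR's coordinates via the interval bounds).
    """
    rows = []
    for c in calls:
        pid = c.protein_id
        if pid not in per_position_scores:
            raise KeyError(f"no scores for protein {pid!r}")
        vec = per_position_scores[pid]
        if c.interval.stop > len(vec):
            raise ValueError(
                f"score vector for {pid!r} has length {len(vec)}, "
                f"but LCR extends to {c.interval.stop}"
            )
        rows.append(
            {
                "protein_id": pid,
                "lcr_index": c.lcr_index,
                "score_name": score_name,
                "value": float(np.mean(vec[c.interval.slice])),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "lcr_index", "score_name", "value"])
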