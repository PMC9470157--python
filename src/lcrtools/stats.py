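"""Shannon entropy of sequences and length-matched random sampling.

Used to validate that called regions really are low complexity: each LCR's
entropy is compared with that of a random length-matched substring of the
concatenated proteome, and the two entropy samples are compared with a
one-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import Proteome

__all__ = [
    "shannon_entropy",
    "sample_length_matched",
    "entropy_validation",
    "EntropyComparison",
]


def shannon_entropy(sequence: str, base: float = 2.0) -> float:
    """Shannon entropy of the residue composition of ``sequence``.

    H = -sum_a f_a log(f_a) over characters present, in units of ``base``
    (base 2 gives bits).
    """
    if len(sequence) == 0:
        raise ValueError("cannot compute entropy of an empty sequence")
    _, counts = np.unique(list(sequence), return_counts=True)
    return float(sps.entropy(counts, base=base))


def _concatenation(proteome: Proteome) -> str:
    return "".join(rec.sequence for rec in proteome)


def sample_length_matched(
    proteome: Proteome,
    length: int,
    seed: int | np.random.Generator,
    n_samples: int | None = None,
    avoid_boundaries: bool = False,
) -> str | list[str]:
    """Random substring(s) of the proteome concatenation, of a given length.

    Proteins are concatenated in file order and a start position is drawn
    uniformly; a draw may span a protein boundary (set
    ``avoid_boundaries=True`` to redraw such samples).  With ``n_samples``
    a list is returned; reproducible for a given seed.
    """
    cat = _concatenation(proteome)
    total = len(cat)
    if length > total:
        raise ValueError(f"sample length {length} exceeds proteome length {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # protein end positions (0-based, exclusive) for boundary checks
    ends = np.cumsum([len(r) for r in proteome])[:-1]
    high = max(total - length, 1)  # uniform over 1..total-length (1-based starts)

    def draw() -> str:
        while True:
            start0 = int(rng.integers(0, high))
            if avoid_boundaries and len(ends) and (
                ((ends > start0) & (ends < start0 + length)).any()
            ):
                continue
            return cat[start0 : start0 + length]

    if n_samples is None:
        return draw()
    return [draw() for _ in range(n_samples)]


@dataclass
class EntropyComparison:
    """Per-LCR entropies vs length-matched random samples, with a rank-sum test."""

    lcr_entropies: np.ndarray
    matched_entropies: np.ndarray
    test_statistic: float
    p_value: float

    def summary(self) -> dict:
        return {
            "n_lcrs": int(len(self.lcr_entropies)),
            "mean_lcr_entropy_bits": float(np.mean(self.lcr_entropies)),
            "mean_matched_entropy_bits": float(np.mean(self.matched_entropies)),
            "statistic": float(self.test_statistic),
            "p_value": float(self.p_value),
        }


def entropy_validation(
    calls,
    proteome: Proteome,
    seed: int | np.random.Generator,
    base: float = 2.0,
) -> EntropyComparison:
    """Test whether called LCRs have lower entropy than random sequences.

    Draws one length-matched sample per LCR and runs a one-sided
    Mann-Whitney U test (alternative: LCR entropies are lower).  Requires at
    least two calls.
    """
    if len(calls) < 2:
        raise ValueError("entropy validation needs at least 2 LCR calls")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lcr_h = np.array([shannon_entropy(c.sequence, base) for c in calls])
    matched = [
        sample_length_matched(proteome, len(c.sequence), rng) for c in calls
    ]
    matched_h = np.array([shannon_entropy(s, base) for s in matched])
    res = sps.mannwhitneyu(lcr_h, matched_h, alternative="less")
    return EntropyComparison(lcr_h, matched_h, float(res.statistic), float(res.pvalue))
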