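"""Synthetic proteomes with planted low-complexity blocks, plus brute-force
oracles that recompute every pipeline stage by naive enumeration.

The generator emulates what the real pipeline sees: background residues
drawn from a configurable distribution (uniform over the 20 standard amino
acids by default, which makes the simulated null exactly matched) with
low-entropy blocks planted at known coordinates.  Planting two blocks of the
same composition in one protein creates a known same-type pair; blocks of
disjoint alphabets create known distinct types.

The oracles recompute dotplots, window counts, thresholding, connected
components, diagonal extraction and boundary expansion with naive loops and
flood fill — deliberately sharing no code with the production path — so the
pipeline can be checked for exact agreement on small instances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .io import ProteinRecord, Proteome, SequenceInterval
from .null_model import STANDARD_AMINO_ACIDS

__all__ = [
    "BlockSpec",
    "PlantedBlock",
    "PlantedProteome",
    "make_planted_proteome",
    "brute_force_intensities",
    "brute_force_lcr_oracle",
    "OracleResult",
]


@dataclass(frozen=True)
class BlockSpec:
    """One low-entropy block to plant: length, alphabet, optional fixed start.

    ``residues`` may contain one or two distinct letters (keeping block
    entropy <= 1 bit); with two letters the block alternates deterministically
    according to ``weights`` (default 50/50).  ``start`` is 1-based; None
    means place randomly.  ``label`` defaults to the alphabet, so blocks of
    identical composition in one protein share a planted type label.
    """

    length: int
    residues: str = "K"
    weights: tuple[float, ...] | None = None
    start: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        if not (1 <= len(set(self.residues)) <= 2):
            raise ValueError("block alphabet must have 1 or 2 distinct residues")

    @property
    def type_label(self) -> str:
        return self.label if self.label is not None else "".join(sorted(set(self.residues)))

    def materialize(self, rng: np.random.Generator) -> str:
        letters = sorted(set(self.residues))
        if len(letters) == 1:
            return letters[0] * self.length
        w = np.asarray(self.weights if self.weights is not None else (0.5, 0.5))
        w = w / w.sum()
        draws = rng.choice(len(letters), size=self.length, p=w)
        return "".join(letters[d] for d in draws)


@dataclass(frozen=True)
class PlantedBlock:
    """Ground truth for one planted block."""

    protein_id: str
    interval: SequenceInterval
    composition: str
    type_label: str


@dataclass
class PlantedProteome:
    proteome: Proteome
    truth: list[PlantedBlock] = field(default_factory=list)

    def truth_for(self, protein_id: str) -> list[PlantedBlock]:
        return [b for b in self.truth if b.protein_id == protein_id]


def _background_probs(background) -> np.ndarray:
    if background == "uniform20" or background is None:
        return np.full(20, 1 / 20)
    if isinstance(background, dict):
        probs = np.array([background.get(a, 0.0) for a in STANDARD_AMINO_ACIDS], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("background composition sums to zero")
        return probs / probs.sum()
    raise ValueError(f"unknown background {background!r}")


def make_planted_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    blocks_spec=None,
    background="uniform20",
    seed: int | np.random.Generator = 0,
    min_spacing: int = 10,
    name: str = "synthetic",
) -> PlantedProteome:
    """Generate a proteome with planted low-entropy blocks at known positions.

    ``blocks_spec`` is None, a list of :class:`BlockSpec` applied to every
    protein, or a list of such lists (one per protein).  Randomly placed
    blocks keep at least ``min_spacing`` background residues between blocks
    and from the protein ends.  Raises ``ValueError`` if a protein cannot
    accommodate its blocks.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    if blocks_spec is None:
        per_protein: list[list[BlockSpec]] = [[] for _ in range(n_proteins)]
    elif blocks_spec and isinstance(blocks_spec[0], BlockSpec):
        per_protein = [list(blocks_spec)] * n_proteins
    else:
        if len(blocks_spec) != n_proteins:
            raise ValueError("per-protein blocks_spec must have n_proteins entries")
        per_protein = [list(b) for b in blocks_spec]

    probs = _background_probs(background)
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode(), dtype=np.uint8)
    records: list[ProteinRecord] = []
    truth: list[PlantedBlock] = []
    for p in range(n_proteins):
        pid = f"{name}_{p + 1}"
        length = int(rng.integers(lo, hi + 1))
        blocks = per_protein[p]
        bg = alphabet[rng.choice(20, size=length, p=probs)].tobytes().decode()
        seq = list(bg)
        placements: list[tuple[int, BlockSpec]] = []  # (0-based start, spec)
        fixed = [b for b in blocks if b.start is not None]
        free = [b for b in blocks if b.start is None]
        for b in fixed:
            start0 = b.start - 1
            if start0 < 0 or start0 + b.length > length:
                raise ValueError(
                    f"block at {b.start} (length {b.length}) does not fit in "
                    f"protein {pid} of length {length}"
                )
            placements.append((start0, b))
        if free:
            # gaps: before, between and after the random blocks, each >= min_spacing
            needed = sum(b.length for b in free) + (len(free) + 1) * min_spacing
            if needed > length:
                raise ValueError(
                    f"blocks (need {needed} residues) do not fit in protein "
                    f"{pid} of length {length} with spacing {min_spacing}"
                )
            extra = length - needed
            gap_extra = rng.multinomial(extra, np.full(len(free) + 1, 1 / (len(free) + 1)))
            pos = 0
            for g, b in zip(gap_extra[:-1], free):
                pos += min_spacing + int(g)
                placements.append((pos, b))
                pos += b.length
        placements.sort(key=lambda t: t[0])
        prev_end = None
        for start0, b in placements:
            if prev_end is not None and start0 < prev_end:
                raise ValueError(f"planted blocks overlap in protein {pid}")
            prev_end = start0 + b.length
            block_seq = b.materialize(rng)
            seq[start0 : start0 + b.length] = block_seq
            truth.append(
                PlantedBlock(
                    pid,
                    SequenceInterval(pid, start0 + 1, start0 + b.length),
                    block_seq,
                    b.type_label,
                )
            )
        records.append(ProteinRecord(pid, f"{pid} planted", "".join(seq)))
    return PlantedProteome(Proteome(records, name=name), truth)


# ---------------------------------------------------------------------------
# Brute-force oracles (test-support; naive on purpose, O(N^2 k^2)-ish)
# ---------------------------------------------------------------------------


def brute_force_intensities(sequence: str, kernel_size: int = 10) -> np.ndarray:
    """Window dot counts by direct per-pixel window summation."""
    n = len(sequence)
    dots = np.array(
        [[1 if sequence[i] == sequence[j] else 0 for j in range(n)] for i in range(n)],
        dtype=np.int64,
    )
    lo = -((kernel_size - 1) // 2)
    hi = kernel_size // 2
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        r0, r1 = max(i + lo, 0), min(i + hi, n - 1) + 1
        for j in range(n):
            c0, c1 = max(j + lo, 0), min(j + hi, n - 1) + 1
            out[i, j] = dots[r0:r1, c0:c1].sum()
    return out


@dataclass
class OracleResult:
    mask: np.ndarray  # boolean above-threshold mask
    components: list[set[tuple[int, int]]]  # flood-fill pixel sets
    intervals: list[tuple[int, int]]  # merged expanded LCRs, 0-based half-open
    edges: set[tuple[int, int]]  # 1-based (a, b) pairs, a < b


def brute_force_lcr_oracle(
    record: ProteinRecord | str,
    threshold: int,
    kernel_size: int = 10,
    pad_left: int = 4,
    pad_right: int = 5,
) -> OracleResult:
    """Recompute LCR calling for one protein by flood fill and direct scans."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    n = len(seq)
    if n > 2000:
        raise ValueError("oracle is quadratic; use proteins of length <= 2000")
    intens = brute_force_intensities(seq, kernel_size)
    mask = intens >= threshold

    seen = np.zeros_like(mask, dtype=bool)
    components: list[set[tuple[int, int]]] = []
    for si in range(n):
        for sj in range(n):
            if mask[si, sj] and not seen[si, sj]:
                comp: set[tuple[int, int]] = set()
                queue = deque([(si, sj)])
                seen[si, sj] = True
                while queue:
                    i, j = queue.popleft()
                    comp.add((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if (
                                0 <= ii < n
                                and 0 <= jj < n
                                and mask[ii, jj]
                                and not seen[ii, jj]
                            ):
                                seen[ii, jj] = True
                                queue.append((ii, jj))
                components.append(comp)

    raw: list[tuple[int, int]] = []
    for comp in components:
        diag = [i for (i, j) in comp if i == j]
        if diag:
            start0 = max(min(diag) - pad_left, 0)
            stop0 = min(max(diag) + pad_right, n - 1) + 1
            raw.append((start0, stop0))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for start0, stop0 in raw:
        if merged and start0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop0))
        else:
            merged.append((start0, stop0))

    edges: set[tuple[int, int]] = set()
    for a in range(len(merged)):
        for b in range(a + 1, len(merged)):
            (a0, a1), (b0, b1) = merged[a], merged[b]
            hit = any(
                mask[i, j] for i in range(a0, a1) for j in range(b0, b1)
            )
            if hit:
                edges.add((a + 1, b + 1))
    return OracleResult(mask, components, merged, edges)
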