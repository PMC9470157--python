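"""Binary self-comparison dotplots and uniform-kernel convolved intensities.

A dotplot of a protein of length N is the N x N matrix with a 1 wherever two
residues are identical characters (so the diagonal is all ones).  Convolving
it with a uniform k x k kernel (default k=10) gives, at each pixel, the count
of dots inside that pixel's window — an integer intensity in [0, k^2].

Window anchoring for even kernels: the window at pixel (i, j) spans row
offsets -(k-1)//2 .. +k//2 (for k=10: -4 .. +5) in both axes, with cells
outside the matrix contributing zero.  This anchor is what makes the later
-4/+5 boundary expansion of called regions recover the original sequence
extent exactly.

Window sums are computed with an exact integer summed-area table, so results
are identical whether a protein is processed as one matrix or in row blocks
(used for very long proteins to bound peak memory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io import ProteinRecord

__all__ = [
    "BinaryDotplot",
    "IntensityMatrix",
    "build_dotplot",
    "convolve_dotplot",
    "intensity_matrix",
    "iter_intensity_rows",
    "threshold_mask",
    "encode_sequence",
    "DEFAULT_KERNEL_SIZE",
    "DEFAULT_MAX_FULL_MATRIX",
]

DEFAULT_KERNEL_SIZE = 10
# Above this protein length, full int matrices are avoided and work proceeds
# in row blocks (titin-scale proteins must not need O(N^2) peak memory twice).
DEFAULT_MAX_FULL_MATRIX = 15_000


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a sequence as a uint8 code array (one code per distinct character)."""
    return np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)


@dataclass
class BinaryDotplot:
    protein_id: str
    matrix: np.ndarray  # N x N uint8 of {0, 1}

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("dotplot matrix must be square")


@dataclass
class IntensityMatrix:
    protein_id: str
    matrix: np.ndarray  # N x N int16 in [0, kernel_size**2]
    kernel_size: int


def build_dotplot(record: ProteinRecord | str, protein_id: str = "") -> BinaryDotplot:
    """Self-comparison dotplot: matrix[i, j] = 1 iff sequence[i] == sequence[j].

    Matching is exact character equality, including non-standard letters
    (an X matches an X).
    """
    if isinstance(record, ProteinRecord):
        seq, pid = record.sequence, record.protein_id
    else:
        seq, pid = record, protein_id
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    enc = encode_sequence(seq)
    matrix = (enc[:, None] == enc[None, :]).astype(np.uint8)
    return BinaryDotplot(pid, matrix)


def _window_offsets(kernel_size: int) -> tuple[int, int]:
    """Inclusive (low, high) window offsets for a uniform kernel.

    Odd kernels are centred; even kernels take one extra cell on the high
    side (k=10 -> -4..+5).
    """
    if kernel_size < 1:
        raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
    return -((kernel_size - 1) // 2), kernel_size // 2


def _window_sums(matrix: np.ndarray, kernel_size: int) -> np.ndarray:
    """Exact k x k window sums with zero padding, via a summed-area table."""
    lo, hi = _window_offsets(kernel_size)
    n_rows, n_cols = matrix.shape
    # cumulative sums with a leading zero row/column
    sat = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
    np.cumsum(matrix, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    r0 = np.clip(np.arange(n_rows) + lo, 0, n_rows)
    r1 = np.clip(np.arange(n_rows) + hi + 1, 0, n_rows)
    c0 = np.clip(np.arange(n_cols) + lo, 0, n_cols)
    c1 = np.clip(np.arange(n_cols) + hi + 1, 0, n_cols)
    out = (
        sat[np.ix_(r1, c1)]
        - sat[np.ix_(r0, c1)]
        - sat[np.ix_(r1, c0)]
        + sat[np.ix_(r0, c0)]
    )
    return out.astype(np.int16)


def convolve_dotplot(dp: BinaryDotplot, kernel_size: int = DEFAULT_KERNEL_SIZE) -> IntensityMatrix:
    """Convolve a dotplot with a uniform kernel; same output shape, zero padding."""
    _window_offsets(kernel_size)  # validates
    return IntensityMatrix(dp.protein_id, _window_sums(dp.matrix, kernel_size), kernel_size)


def _intensity_rows_block(
    enc: np.ndarray, kernel_size: int, row_start: int, row_stop: int
) -> np.ndarray:
    """Intensities of dotplot rows [row_start, row_stop) without the full matrix.

    Builds dotplot rows for the block plus a vertical halo, takes horizontal
    window sums per row, then combines them vertically — the same arithmetic
    as the summed-area table on the full matrix.
    """
    lo, hi = _window_offsets(kernel_size)
    n = len(enc)
    halo_start = max(row_start + lo, 0)
    halo_stop = min(row_stop - 1 + hi, n - 1) + 1
    dots = (enc[halo_start:halo_stop, None] == enc[None, :])
    # horizontal window sums for each halo row
    csum = np.zeros((dots.shape[0], n + 1), dtype=np.int32)
    np.cumsum(dots, axis=1, out=csum[:, 1:])
    c0 = np.clip(np.arange(n) + lo, 0, n)
    c1 = np.clip(np.arange(n) + hi + 1, 0, n)
    hsums = csum[:, c1] - csum[:, c0]
    # vertical combination over clamped row windows
    vsum = np.zeros((hsums.shape[0] + 1, n), dtype=np.int32)
    np.cumsum(hsums, axis=0, out=vsum[1:])
    rows = np.arange(row_start, row_stop)
    r0 = np.clip(rows + lo, halo_start, halo_stop) - halo_start
    r1 = np.clip(rows + hi + 1, halo_start, halo_stop) - halo_start
    return (vsum[r1] - vsum[r0]).astype(np.int16)


def iter_intensity_rows(
    sequence: str,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    block_rows: int = 2048,
) -> Iterator[np.ndarray]:
    """Yield convolved intensity row blocks for a sequence, O(block * N) memory."""
    _window_offsets(kernel_size)
    enc = encode_sequence(sequence)
    n = len(enc)
    for start in range(0, n, block_rows):
        yield _intensity_rows_block(enc, kernel_size, start, min(start + block_rows, n))


def intensity_matrix(
    record: ProteinRecord | str,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    protein_id: str = "",
) -> IntensityMatrix:
    """Full convolved intensity matrix for one protein (dotplot built implicitly)."""
    if isinstance(record, ProteinRecord):
        seq, pid = record.sequence, record.protein_id
    else:
        seq, pid = record, protein_id
    if len(seq) < 1:
        raise ValueError("sequence must have length >= 1")
    _window_offsets(kernel_size)
    enc = encode_sequence(seq)
    return IntensityMatrix(
        pid, _intensity_rows_block(enc, kernel_size, 0, len(enc)), kernel_size
    )


def threshold_mask(
    record: ProteinRecord | str,
    threshold: int,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    max_full_matrix: int = DEFAULT_MAX_FULL_MATRIX,
    block_rows: int = 2048,
) -> np.ndarray:
    """Boolean mask of pixels with intensity >= threshold.

    For proteins longer than ``max_full_matrix`` the intensities are computed
    in row blocks so only the boolean mask is ever held whole; results are
    identical to the full-matrix path.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    n = len(seq)
    if n <= max_full_matrix:
        return intensity_matrix(record, kernel_size).matrix >= threshold
    mask = np.empty((n, n), dtype=bool)
    start = 0
    for block in iter_intensity_rows(seq, kernel_size, block_rows):
        mask[start : start + block.shape[0]] = block >= threshold
        start += block.shape[0]
    return mask


def render_dotplot(
    record: ProteinRecord,
    path,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    threshold: int | None = None,
) -> None:
    """Render raw, convolved and (optionally) segmented dotplots to one PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dp = build_dotplot(record)
    conv = convolve_dotplot(dp, kernel_size)
    panels = [("raw", dp.matrix, "Greys"), ("convolved", conv.matrix, "viridis")]
    if threshold is not None:
        panels.append(("segmented", (conv.matrix >= threshold).astype(int), "Greys"))
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 4))
    if len(panels) == 1:
        axes = [axes]
    for ax, (title, m, cmap) in zip(axes, panels):
        ax.imshow(m, cmap=cmap, interpolation="nearest")
        ax.set_title(f"{record.protein_id} {title}")
        ax.set_xlabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
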