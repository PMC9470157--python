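"""Length-matched null proteome simulation and FDR-based intensity thresholding.

The segmentation threshold is calibrated per proteome: a 'null proteome' of
the same size and lengths is simulated with residues drawn i.i.d. uniformly
over the 20 standard amino acids, convolved-intensity histograms are pooled
over all pixels of all proteins for both the real and null proteomes, and the
threshold is the lowest intensity t for which

    FDR(t) = (null pixels >= t) / (real pixels >= t + null pixels >= t)

drops to the target (default 0.002).  A uniform null makes the decision for
a given sequence independent of the composition of the proteome it sits in,
while length matching controls for the different protein-length
distributions of different species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dotplot import DEFAULT_KERNEL_SIZE, iter_intensity_rows
from .io import ProteinRecord, Proteome

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "IntensityHistogram",
    "ThresholdResult",
    "NoThresholdError",
    "generate_null_proteome",
    "proteome_intensity_histogram",
    "threshold_from_fdr",
    "derive_threshold",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class IntensityHistogram:
    """Pooled integer histogram of convolved pixel intensities.

    ``counts[v]`` is the number of pixels with intensity v, over full N x N
    matrices (diagonal and both symmetric halves) of every protein.
    """

    counts: np.ndarray  # length kernel_size**2 + 1
    kernel_size: int = DEFAULT_KERNEL_SIZE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.kernel_size**2 + 1
        if self.counts.ndim != 1 or len(self.counts) != expected:
            raise ValueError(
                f"counts must have length {expected} for kernel {self.kernel_size}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative histogram counts")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "IntensityHistogram") -> "IntensityHistogram":
        if self.kernel_size != other.kernel_size:
            raise ValueError("kernel size mismatch")
        return IntensityHistogram(self.counts + other.counts, self.kernel_size)


@dataclass
class ThresholdResult:
    threshold: int
    fdr_at_threshold: float
    fdr_curve: np.ndarray  # fdr_curve[t] = FDR at intensity t, t = 0..k^2
    target_fdr: float
    seed: int | None = None
    real_pixels_passing: int = 0
    null_pixels_passing: int = 0

    def to_dict(self) -> dict:
        return {
            "threshold": int(self.threshold),
            "fdr_at_threshold": float(self.fdr_at_threshold),
            "target_fdr": float(self.target_fdr),
            "seed": self.seed,
            "real_pixels_passing": int(self.real_pixels_passing),
            "null_pixels_passing": int(self.null_pixels_passing),
            "fdr_curve": [float(x) for x in self.fdr_curve],
        }


class NoThresholdError(ValueError):
    """No intensity satisfies the target FDR; carries the full FDR curve."""

    def __init__(self, target_fdr: float, fdr_curve: np.ndarray):
        super().__init__(f"no threshold satisfies FDR <= {target_fdr}")
        self.target_fdr = target_fdr
        self.fdr_curve = fdr_curve


def generate_null_proteome(
    lengths: Sequence[int],
    seed: int | np.random.Generator,
    name: str = "null",
) -> Proteome:
    """Simulate a length-matched proteome with i.i.d. uniform residues.

    One sequence per input length, in order; reproducible for a given seed.
    """
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(L < 1 for L in lengths):
        raise ValueError("all lengths must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = np.frombuffer(STANDARD_AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    for i, L in enumerate(lengths):
        seq = alphabet[rng.integers(0, 20, size=L)].tobytes().decode()
        records.append(ProteinRecord(f"{name}_{i + 1}", f"{name}_{i + 1} simulated", seq))
    return Proteome(records, name=name)


def proteome_intensity_histogram(
    proteome: Proteome,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    block_rows: int = 2048,
) -> IntensityHistogram:
    """Histogram of convolved intensities pooled over all pixels of all proteins."""
    n_bins = kernel_size**2 + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for rec in proteome:
        for block in iter_intensity_rows(rec.sequence, kernel_size, block_rows):
            counts += np.bincount(block.ravel(), minlength=n_bins)
    return IntensityHistogram(counts, kernel_size)


def threshold_from_fdr(
    real: IntensityHistogram,
    null: IntensityHistogram,
    target_fdr: float = 0.002,
    seed: int | None = None,
) -> ThresholdResult:
    """Lowest intensity threshold whose empirical FDR is at or below target.

    FDR(t) uses cumulative-from-above pixel counts and is defined as 0 when
    no pixel passes at all.  The search starts at t=1 (t=0 would segment
    everything).  Raises :class:`NoThresholdError` when no t qualifies.
    """
    if real.kernel_size != null.kernel_size:
        raise ValueError("kernel size mismatch between real and null histograms")
    if real.n_pixels == 0 or null.n_pixels == 0:
        raise ValueError("histograms must be non-empty")
    real_ge = np.cumsum(real.counts[::-1])[::-1]
    null_ge = np.cumsum(null.counts[::-1])[::-1]
    assert (np.diff(real_ge) <= 0).all() and (np.diff(null_ge) <= 0).all()
    denom = real_ge + null_ge
    with np.errstate(invalid="ignore"):
        fdr = np.where(denom > 0, null_ge / np.maximum(denom, 1), 0.0)
    # only thresholds some pixel actually passes are meaningful candidates;
    # zero-pass thresholds have FDR 0 only vacuously
    for t in range(1, len(fdr)):
        if denom[t] > 0 and fdr[t] <= target_fdr:
            return ThresholdResult(
                threshold=t,
                fdr_at_threshold=float(fdr[t]),
                fdr_curve=fdr,
                target_fdr=target_fdr,
                seed=seed,
                real_pixels_passing=int(real_ge[t]),
                null_pixels_passing=int(null_ge[t]),
            )
    raise NoThresholdError(target_fdr, fdr)


def derive_threshold(
    proteome: Proteome,
    target_fdr: float = 0.002,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    seed: int = 0,
    null_replicates: int = 1,
) -> ThresholdResult:
    """End-to-end threshold derivation for one proteome.

    Simulates ``null_replicates`` null proteomes (averaging their histograms
    when more than one) and returns the FDR threshold.  The single-null
    default mirrors standard use; averaging is for stability studies.
    """
    real_hist = proteome_intensity_histogram(proteome, kernel_size)
    rng = np.random.default_rng(seed)
    counts = np.zeros(kernel_size**2 + 1, dtype=np.float64)
    for _ in range(null_replicates):
        null = generate_null_proteome(proteome.lengths, rng)
        counts += proteome_intensity_histogram(null, kernel_size).counts
    null_hist = IntensityHistogram(
        np.round(counts / null_replicates).astype(np.int64), kernel_size
    )
    return threshold_from_fdr(real_hist, null_hist, target_fdr, seed=seed)
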