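"""ATAC library quality diagnostics.

Two classic checks: the fragment-length distribution, whose local maxima in
the nucleosome-free (< 120 bp), mono-nucleosome (120-250 bp) and
di-nucleosome (250-500 bp) bands reflect intact chromatin periodicity; and
the TSS enrichment score, the ratio of transposition cut-site signal at
transcription start sites to the distal-flank background.

No Tn5 +4/-5 offset correction is applied: inputs are abstract fragment
spans, not read alignments.  Both fragment endpoints count as cut sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import GeneRecord, GenomicInterval

__all__ = [
    "LengthHistogram",
    "TssProfile",
    "fragment_length_distribution",
    "tss_enrichment",
]

LEN_MIN, LEN_MAX = 20, 800
SMOOTH_WINDOW = 11
MODE_MIN_REL_HEIGHT = 0.10
BANDS = {
    "nucleosome_free": (LEN_MIN, 120),   # [20, 120)
    "mono_nucleosome": (120, 251),       # [120, 250]
    "di_nucleosome": (251, 501),         # (250, 500]
}


@dataclass
class LengthHistogram:
    """1-bp fragment-length histogram over [20, 800] with smoothed curve
    and per-band modes; lengths outside the range are tallied in
    ``overflow``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: int
    smoothed: np.ndarray
    modes: list[tuple[int, float]]


@dataclass
class TssProfile:
    """Strand-oriented mean cut-site signal per offset in [-1000, 1000]."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    enrichment_score: float
    n_genes: int


def moving_average(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; edges use the available (shorter) window."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sums / norm


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima (plateaus report their center index)."""
    idx = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            idx.append((i + j) // 2)
        i = j + 1
    return np.array(idx, dtype=int)


def fragment_length_distribution(
    fragments: list[GenomicInterval],
) -> LengthHistogram:
    """Histogram of fragment lengths with per-band mode detection.

    Modes are smoothed local maxima exceeding 10% of the global smoothed
    maximum; at most one (the highest) is reported per nucleosome band,
    sorted by position.
    """
    if not fragments:
        raise ValueError("fragment list is empty")
    lengths = np.fromiter((f.length for f in fragments), dtype=np.int64,
                          count=len(fragments))
    in_range = (lengths >= LEN_MIN) & (lengths <= LEN_MAX)
    overflow = int((~in_range).sum())
    edges = np.arange(LEN_MIN, LEN_MAX + 2)  # 1-bp bins, 20..800
    counts, _ = np.histogram(lengths[in_range], bins=edges)
    smoothed = moving_average(counts.astype(float))
    floor = MODE_MIN_REL_HEIGHT * smoothed.max()
    maxima = _local_maxima(smoothed)
    maxima = maxima[smoothed[maxima] >= floor] if len(maxima) else maxima
    modes: list[tuple[int, float]] = []
    for lo, hi in BANDS.values():
        in_band = maxima[(edges[maxima] >= lo) & (edges[maxima] < hi)]
        if len(in_band):
            best = in_band[np.argmax(smoothed[in_band])]
            modes.append((int(edges[best]), float(smoothed[best])))
    modes.sort()
    return LengthHistogram(edges, counts, overflow, smoothed, modes)


def tss_enrichment(fragments: list[GenomicInterval],
                   gene_model: list[GeneRecord],
                   flank: int = 1000,
                   chrom_sizes: dict[str, int] | None = None) -> TssProfile:
    """Aggregate cut sites (both fragment endpoints) around TSSs.

    Offsets are gene-strand oriented (negative = upstream).  The score is
    the maximum of the smoothed mean signal within +/- 50 bp of the TSS
    divided by the mean signal over the outermost 100 bp of each flank;
    a zero flank mean yields ``inf`` with a warning.
    """
    if not gene_model:
        raise ValueError("gene model is empty")
    genes = []
    for g in gene_model:
        if g.tss - flank < 0:
            continue
        if chrom_sizes is not None and g.tss + flank >= chrom_sizes.get(
                g.chrom, g.tss + flank + 1):
            continue
        genes.append(g)
    if not genes:
        raise ValueError("no gene has full flanks inside its chromosome")

    cuts_by_chrom: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).extend((f.start, f.end - 1))
    for chrom, cuts in by_chrom.items():
        cuts_by_chrom[chrom] = np.sort(np.asarray(cuts, dtype=np.int64))

    width = 2 * flank + 1
    signal = np.zeros(width)
    for g in genes:
        cuts = cuts_by_chrom.get(g.chrom)
        if cuts is None:
            continue
        lo = np.searchsorted(cuts, g.tss - flank, "left")
        hi = np.searchsorted(cuts, g.tss + flank, "right")
        offs = cuts[lo:hi] - g.tss
        if g.strand == "-":
            offs = -offs
        signal += np.bincount(offs + flank, minlength=width)[:width]
    mean_signal = signal / len(genes)

    offsets = np.arange(-flank, flank + 1)
    smoothed = moving_average(mean_signal)
    center = smoothed[(offsets >= -50) & (offsets <= 50)].max()
    flank_mask = (offsets <= -(flank - 99)) | (offsets >= flank - 99)
    flank_mean = mean_signal[flank_mask].mean()
    if flank_mean == 0:
        warnings.warn("flank signal is zero; TSS enrichment reported as inf")
        score = float("inf")
    else:
        score = float(center / flank_mean)
    return TssProfile(offsets, mean_signal, score, len(genes))
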