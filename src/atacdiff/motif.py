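"""PWM scanning and foreground-vs-background motif enrichment.

Scanning is log2-odds against a background base model (uniform by
default): the score of a window is the summed log2 ratio of motif to
background probability per position, on both strands; minus-strand hits
are scored on the reverse complement and reported in plus-strand
coordinates.  Windows containing N are skipped.

Enrichment uses ZOOPS counting (a peak either contains >= 1 hit or none)
and the upper-tail hypergeometric test: population = all peaks, successes
= peaks with a hit anywhere, draws = foreground peaks, observed =
foreground peaks with a hit, with Benjamini-Hochberg correction across
motifs.  An optional GC-matching step downsamples the background to the
foreground's GC-decile profile before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotate import bh_adjust
from .atlas import AtlasPeak
from .formats import PWM, GenomicInterval

__all__ = [
    "MotifHit",
    "scan_pwm",
    "default_threshold",
    "motif_enrichment",
    "peak_sequence",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif_name: str
    offset: int     # 0-based start within the scanned sequence, + strand coords
    strand: str
    score: float    # log2-odds bits


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()],
                        dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _logodds(pwm: PWM, background: np.ndarray) -> np.ndarray:
    return np.log2(pwm.probs / background[None, :])


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Score of every window of len(lod) on the coded + strand; windows
    containing N score -inf."""
    L = lod.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    is_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    total = lod[np.arange(L)[None, :], safe].sum(axis=1)
    total[is_n] = -np.inf
    return total


def scan_pwm(sequence: str, pwm: PWM,
             background: np.ndarray | None = None,
             threshold_bits: float = 0.0,
             peak_id: str = "") -> list[MotifHit]:
    """All offsets (both strands) scoring >= ``threshold_bits``.

    A motif longer than the sequence yields an empty result.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    codes = _encode(sequence)
    lod = _logodds(pwm, bg)
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, lod)
    # minus strand: score the reverse-complement PWM on the + sequence
    lod_rc = lod[::-1, ::-1]
    rev = _window_scores(codes, lod_rc)
    for o in np.flatnonzero(fwd >= threshold_bits):
        hits.append(MotifHit(peak_id, pwm.name, int(o), "+", float(fwd[o])))
    for o in np.flatnonzero(rev >= threshold_bits):
        hits.append(MotifHit(peak_id, pwm.name, int(o), "-", float(rev[o])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def default_threshold(pwm: PWM, background: np.ndarray | None = None,
                      fraction: float = 0.8) -> float:
    """``fraction`` times the maximum attainable (consensus) score."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    return float(fraction * _logodds(pwm, bg).max(axis=1).sum())


def peak_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    seq = genome.get(interval.chrom)
    if seq is None:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    return seq[interval.start:interval.end]


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)


def _gc_match(fg_seqs: list[str], bg_seqs: list[str],
              seed: int) -> list[int]:
    """Indices of a background subsample matching the foreground GC-decile
    histogram (proportional allocation, without replacement)."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, 11)
    fg_bins = np.clip(np.digitize([_gc_fraction(s) for s in fg_seqs],
                                  edges) - 1, 0, 9)
    bg_bins = np.clip(np.digitize([_gc_fraction(s) for s in bg_seqs],
                                  edges) - 1, 0, 9)
    fg_prop = np.bincount(fg_bins, minlength=10) / len(fg_seqs)
    by_bin = {b: np.flatnonzero(bg_bins == b) for b in range(10)}
    # largest feasible total preserving the foreground proportions
    totals = [len(by_bin[b]) / fg_prop[b]
              for b in range(10) if fg_prop[b] > 0]
    total = int(min(min(totals), len(bg_seqs)))
    chosen: list[int] = []
    for b in range(10):
        want = int(round(total * fg_prop[b]))
        if want:
            chosen.extend(rng.choice(by_bin[b], min(want, len(by_bin[b])),
                                     replace=False))
    return sorted(chosen)


def motif_enrichment(foreground: list[AtlasPeak],
                     background: list[AtlasPeak],
                     genome: dict[str, str],
                     pwms: list[PWM],
                     matching: str = "none",
                     background_freqs: np.ndarray | None = None,
                     threshold_fraction: float = 0.8,
                     threshold_source: str = "computed",
                     seed: int = 0) -> pd.DataFrame:
    """Ranked ZOOPS motif enrichment of foreground over background peaks.

    ``background`` must be disjoint from ``foreground`` (pass the atlas
    peaks not in the foreground).  ``threshold_source='file'`` uses a
    HOMER-style per-motif threshold when the PWM carries one.  Columns:
    motif, fg_with_hit, fg_total, bg_with_hit, bg_total, p, fdr, rank.
    """
    if not foreground:
        raise ValueError("foreground peak set is empty")
    if matching not in ("none", "gc"):
        raise ValueError("matching must be 'none' or 'gc'")
    fg_ids = {p.peak_id for p in foreground}
    if any(p.peak_id in fg_ids for p in background):
        raise ValueError("foreground and background peaks must be disjoint")
    fg_seqs = [peak_sequence(genome, p.interval) for p in foreground]
    bg_seqs = [peak_sequence(genome, p.interval) for p in background]
    if matching == "gc" and bg_seqs:
        keep = _gc_match(fg_seqs, bg_seqs, seed)
        bg_seqs = [bg_seqs[i] for i in keep]
    rows = []
    for pwm in pwms:
        if threshold_source == "file" and pwm.file_threshold is not None:
            thr = pwm.file_threshold
        else:
            thr = default_threshold(pwm, background_freqs,
                                    threshold_fraction)
        fg_hit = sum(
            bool(scan_pwm(s, pwm, background_freqs, thr)) for s in fg_seqs
        )
        bg_hit = sum(
            bool(scan_pwm(s, pwm, background_freqs, thr)) for s in bg_seqs
        )
        M = len(fg_seqs) + len(bg_seqs)
        n_succ = fg_hit + bg_hit
        p = float(hypergeom.sf(fg_hit - 1, M, n_succ, len(fg_seqs)))
        rows.append((pwm.name, fg_hit, len(fg_seqs), bg_hit, len(bg_seqs),
                     min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["motif", "fg_with_hit", "fg_total",
                                     "bg_with_hit", "bg_total", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["fdr", "p", "motif"], kind="mergesort"
                        ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
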