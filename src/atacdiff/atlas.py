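"""Cross-condition peak atlas: concatenate per-condition peak calls and
iteratively merge reciprocally >=75%-overlapping peaks to a fixpoint, then
count fragments per atlas peak per sample.

The merge rule is reciprocal: two same-chromosome intervals merge when the
overlap covers at least ``min_frac`` of *both* lengths (boundary
inclusive).  Merging replaces the pair with their union span and the scan
repeats until a full pass makes no merge, so no pair of output peaks is
mergeable.  The sorted left-to-right scan makes the fixpoint deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .formats import GenomicInterval, PeakCall

__all__ = [
    "AtlasPeak",
    "CountMatrix",
    "merge_predicate",
    "build_atlas",
    "count_matrix",
    "write_atlas_bed",
    "read_atlas_bed",
]


@dataclass(frozen=True)
class AtlasPeak:
    """A merged atlas peak spanning the union of its member calls."""

    peak_id: str
    interval: GenomicInterval
    members: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("atlas peak must have >= 1 member")
        iv = self.interval
        for _, m in self.members:
            if m.chrom != iv.chrom or m.start < iv.start or m.end > iv.end:
                raise ValueError("atlas peak must span all member intervals")


@dataclass
class CountMatrix:
    """Integer fragment counts, atlas peaks x samples."""

    peak_ids: list[str]
    samples: list[str]
    counts: np.ndarray
    min_overlap_bp: int = 1
    unassigned: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_ids), len(self.samples)):
            raise ValueError("counts shape inconsistent with labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise ValueError("duplicate peak IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.peak_ids,
                            columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_overlap_bp: int = 1
                   ) -> "CountMatrix":
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=np.int64), min_overlap_bp)


def merge_predicate(a: GenomicInterval, b: GenomicInterval,
                    min_frac: float = 0.75) -> bool:
    """True iff ``a`` and ``b`` overlap by >= ``min_frac`` of both lengths."""
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must be in (0, 1]")
    if a.chrom != b.chrom:
        return False
    ov = a.overlap_bp(b)
    return ov >= min_frac * a.length and ov >= min_frac * b.length


def _scan_pass(items: list[tuple[GenomicInterval, list]], min_frac: float
               ) -> tuple[list[tuple[GenomicInterval, list]], bool]:
    """One left-to-right merge pass over start-sorted items.

    The working interval is compared against every following interval it
    overlaps (not only its immediate neighbor): a mergeable pair must
    overlap, but a non-mergeable interval can sit between two mergeable
    ones, so an adjacent-only scan would stall short of the fixpoint.
    After each merge the (extended) union is re-scanned.
    """
    n = len(items)
    used = [False] * n
    out: list[tuple[GenomicInterval, list]] = []
    merged_any = False
    for i in range(n):
        if used[i]:
            continue
        cur_iv, cur_members = items[i]
        j = i + 1
        while j < n:
            if used[j]:
                j += 1
                continue
            iv, members = items[j]
            if iv.chrom != cur_iv.chrom or iv.start >= cur_iv.end:
                break
            if merge_predicate(cur_iv, iv, min_frac):
                cur_iv = GenomicInterval(cur_iv.chrom, cur_iv.start,
                                         max(cur_iv.end, iv.end))
                cur_members = cur_members + members
                used[j] = True
                merged_any = True
                j = i + 1  # the union may now reach a skipped interval
            else:
                j += 1
        out.append((cur_iv, cur_members))
    return out, merged_any


def build_atlas(peak_calls: list[PeakCall],
                min_frac: float = 0.75) -> list[AtlasPeak]:
    """Merge concatenated per-condition peak calls into atlas peaks.

    Sorts by (chrom, start, end), then repeats left-to-right scan passes —
    replacing each mergeable working/next pair with its union span — until
    a pass performs no merge.
    """
    if not peak_calls:
        return []
    items = [(c.interval, [(c.source_label, c.interval)])
             for c in sorted(peak_calls,
                             key=lambda c: (c.interval.chrom,
                                            c.interval.start,
                                            c.interval.end))]
    merged_any = True
    while merged_any:
        items, merged_any = _scan_pass(items, min_frac)
        items.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    peaks = [
        AtlasPeak(f"{iv.chrom}:{iv.start}-{iv.end}", iv, tuple(members))
        for iv, members in items
    ]
    if len({p.peak_id for p in peaks}) != len(peaks):  # pragma: no cover
        raise RuntimeError("non-unique atlas peak IDs at fixpoint")
    return peaks


def count_matrix(atlas: list[AtlasPeak],
                 fragments_by_sample: dict[str, list[GenomicInterval]],
                 min_overlap_bp: int = 1) -> CountMatrix:
    """Count fragments overlapping each atlas peak by >= ``min_overlap_bp``.

    A fragment overlapping k peaks contributes to all k.  Fragments that
    overlap no peak (including those on chromosomes absent from the atlas)
    are tallied per sample in ``unassigned``.
    """
    if not atlas:
        raise ValueError("atlas must be non-empty")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    peak_df = pd.DataFrame({
        "Chromosome": [p.interval.chrom for p in atlas],
        "Start": [p.interval.start for p in atlas],
        "End": [p.interval.end for p in atlas],
        "peak_idx": np.arange(len(atlas)),
    })
    peak_gr = pr.PyRanges(peak_df)
    samples = list(fragments_by_sample)
    counts = np.zeros((len(atlas), len(samples)), dtype=np.int64)
    unassigned = {s: 0 for s in samples}
    for j, sample in enumerate(samples):
        frags = fragments_by_sample[sample]
        if not frags:
            continue
        frag_gr = pr.PyRanges(pd.DataFrame({
            "Chromosome": [f.chrom for f in frags],
            "Start": [f.start for f in frags],
            "End": [f.end for f in frags],
            "frag_idx": np.arange(len(frags)),
        }))
        joined = frag_gr.join(peak_gr).df
        if len(joined):
            ov = (np.minimum(joined["End"], joined["End_b"])
                  - np.maximum(joined["Start"], joined["Start_b"]))
            joined = joined[ov >= min_overlap_bp]
        if len(joined):
            hits = joined.groupby("peak_idx").size()
            counts[hits.index.to_numpy(), j] = hits.to_numpy()
            unassigned[sample] = len(frags) - joined["frag_idx"].nunique()
        else:
            unassigned[sample] = len(frags)
    return CountMatrix([p.peak_id for p in atlas], samples, counts,
                       min_overlap_bp, unassigned)


def write_atlas_bed(atlas: list[AtlasPeak], path: str) -> None:
    """Atlas as BED6: name = peak_id, score = member count."""
    with open(path, "w") as fh:
        for p in atlas:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t"
                     f"{len(p.members)}\t.\n")


def read_atlas_bed(path: str) -> list[AtlasPeak]:
    """Read an atlas written by :func:`write_atlas_bed` (member spans are
    not recoverable; each peak carries itself as sole member)."""
    peaks: list[AtlasPeak] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, _ = line.rstrip("\n").split("\t")
            iv = GenomicInterval(chrom, int(start), int(end))
            peaks.append(AtlasPeak(name, iv, (("atlas", iv),)))
    return peaks
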