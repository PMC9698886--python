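"""Ground-truth evaluation of pipeline output on synthetic data.

Matches atlas peaks back to the generator's regions (by maximal interval
overlap) and scores opening/closing classification against the truth
table: sensitivity is the fraction of truly differential regions recovered
with the correct direction, precision the fraction of differential calls
whose region truly has that class.
"""

from __future__ import annotations

import pandas as pd

from .atlas import AtlasPeak
from .formats import GenomicInterval

__all__ = ["match_atlas_to_regions", "classification_metrics"]


def match_atlas_to_regions(atlas: list[AtlasPeak],
                           truth: pd.DataFrame) -> list[int | None]:
    """Truth-table row index of the region each atlas peak overlaps most,
    or None for peaks overlapping no region."""
    regions = [GenomicInterval(c, s, e)
               for c, s, e in zip(truth["chrom"], truth["start"],
                                  truth["end"])]
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((i, r))
    out: list[int | None] = []
    for peak in atlas:
        best, best_ov = None, 0
        for i, r in by_chrom.get(peak.interval.chrom, []):
            ov = peak.interval.overlap_bp(r)
            if ov > best_ov:  # ties cannot occur: regions are >= 500 bp apart
                best, best_ov = i, ov
        out.append(best)
    return out


def classification_metrics(classes: pd.Series, truth: pd.DataFrame,
                           condition: str,
                           mapping: list[int | None]) -> dict[str, float]:
    """Sensitivity/precision of opening/closing calls for one contrast."""
    true_class = truth[f"class_{condition}"].to_numpy()
    peak_region = dict(zip(classes.index, mapping))
    tp = fp = 0
    recovered: set[int] = set()
    for peak_id, label in classes.items():
        if label == "unchanged":
            continue
        ri = peak_region.get(peak_id)
        if ri is not None and true_class[ri] == label:
            tp += 1
            recovered.add(ri)
        else:
            fp += 1
    n_true = int((true_class != "unchanged").sum())
    return {
        "sensitivity": len(recovered) / n_true if n_true else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_true": n_true,
        "n_called": tp + fp,
    }
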