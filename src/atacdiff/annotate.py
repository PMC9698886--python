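"""Nearest-gene annotation of atlas peaks and gene-set overrepresentation.

A peak's position is its integer center ``floor((start + end) / 2)``; the
nearest gene is the one minimizing the absolute center-to-TSS distance on
the same chromosome (ties go to the lexicographically smaller gene id).
The signed distance is negative when the peak center lies 5' (upstream) of
the TSS in the gene's own orientation.

Overrepresentation of a query gene list in a term's gene set is the
upper-tail hypergeometric probability (population = universe, successes =
term members in the universe, draws = query size), corrected across terms
by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasPeak
from .formats import GeneRecord

__all__ = [
    "PeakAnnotation",
    "annotate_nearest",
    "geneset_enrichment",
    "bh_adjust",
]

NO_GENE = "none"


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    nearest_gene_id: str
    signed_distance: int | None


def _signed_distance(center: int, gene: GeneRecord) -> int:
    # negative = center upstream of the TSS in gene orientation
    if gene.strand == "+":
        return center - gene.tss
    return gene.tss - center


def annotate_nearest(atlas: list[AtlasPeak],
                     gene_model: list[GeneRecord]) -> list[PeakAnnotation]:
    """Nearest TSS per atlas peak; peaks on chromosomes without genes get
    the sentinel gene id ``'none'``."""
    if not gene_model:
        raise ValueError("gene model is empty")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in gene_model:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[PeakAnnotation] = []
    for peak in atlas:
        genes = by_chrom.get(peak.interval.chrom)
        if not genes:
            out.append(PeakAnnotation(peak.peak_id, NO_GENE, None))
            continue
        center = peak.interval.center
        best = min(genes,
                   key=lambda g: (abs(center - g.tss), g.gene_id))
        out.append(PeakAnnotation(peak.peak_id, best.gene_id,
                                  _signed_distance(center, best)))
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def geneset_enrichment(query_genes: list[str] | set[str],
                       universe_genes: list[str] | set[str],
                       term_map: dict[str, tuple[str, frozenset[str]]]
                       ) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query_genes`` per term.

    Term gene sets are intersected with the universe; only terms with at
    least one observed query gene are tested.  Returns a frame with
    columns term_id, term_description, observed_gene_count,
    background_gene_count, p_value, fdr — sorted by (fdr, p_value,
    term_id).
    """
    query = set(query_genes)
    universe = set(universe_genes)
    missing = sorted(query - universe)
    if missing:
        raise ValueError(f"query genes absent from universe: {missing}")
    rows = []
    M, N = len(universe), len(query)
    for term_id, (desc, members) in term_map.items():
        background = members & universe
        observed = len(background & query)
        if observed < 1:
            continue
        n = len(background)
        p = float(hypergeom.sf(observed - 1, M, n, N))
        rows.append((term_id, desc, observed, n, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "term_description",
                                     "observed_gene_count",
                                     "background_gene_count", "p_value"])
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["fdr", "p_value", "term_id"],
                            kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
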