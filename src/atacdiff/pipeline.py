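"""End-to-end orchestration: simulate -> qc -> atlas -> count -> diff ->
overlap -> annotate -> motifs -> enrich, with a run manifest.

The pipeline runs from a single structured (YAML) config whose sections
mirror the stage parameters; every resolved threshold and seed is logged
to the manifest, and every output file is recorded with a SHA-256 digest
so deterministic stages can be verified byte-identical across reruns.

Also provides a deliberately simple window-Poisson peak caller so real
fragment input can be exercised end to end without an external caller.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml
from scipy.stats import poisson

from . import __version__
from .annotate import annotate_nearest, geneset_enrichment
from .atlas import build_atlas, count_matrix, write_atlas_bed
from .diffacc import (
    classify_peaks,
    fit_dispersion,
    overlap_summary,
    pca_samples,
    random_split,
    rlog_transform,
    size_factors,
)
from .formats import GenomicInterval, PeakCall, read_gmt
from .motif import motif_enrichment
from .qc import fragment_length_distribution, tss_enrichment
from .synthio import SimConfig, builtin_motifs, simulate

__all__ = ["simple_peak_caller", "run_pipeline", "DEFAULT_STAGES",
           "load_config"]

log = logging.getLogger("atacdiff")

DEFAULT_STAGES = ("simulate", "qc", "atlas", "count", "diff", "overlap",
                  "annotate", "motifs", "enrich")

_KNOWN_SECTIONS = {
    "simulate", "qc", "atlas", "count", "diff", "pca", "split", "overlap",
    "annotate", "motifs", "enrich", "callpeaks", "seed", "outdir",
}


def simple_peak_caller(fragments: list[GenomicInterval],
                       chrom_sizes: dict[str, int],
                       window: int = 200, step: int = 50,
                       fdr: float = 0.01,
                       source_label: str = "") -> list[PeakCall]:
    """Window-Poisson peak calling on fragment midpoints.

    Per-window midpoint counts are tested against the genome-wide uniform
    rate (Poisson upper tail), BH-corrected across all windows; adjacent
    or overlapping significant windows merge into one peak whose score is
    -log10 of the best adjusted p-value.
    """
    if not fragments:
        raise ValueError("fragment list is empty")
    if not chrom_sizes:
        raise ValueError("chromosome sizes are required for the genome rate")
    genome_bp = sum(chrom_sizes.values())
    mids_by_chrom: dict[str, np.ndarray] = {}
    for f in fragments:
        mids_by_chrom.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    total = sum(len(v) for v in mids_by_chrom.values())
    lam = total / genome_bp * window
    win_chrom, win_start, win_count = [], [], []
    for chrom, size in chrom_sizes.items():
        mids = np.sort(np.asarray(mids_by_chrom.get(chrom, []), dtype=np.int64))
        starts = np.arange(0, max(size - window, 0) + 1, step)
        lo = np.searchsorted(mids, starts, "left")
        hi = np.searchsorted(mids, starts + window, "left")
        win_chrom.extend([chrom] * len(starts))
        win_start.append(starts)
        win_count.append(hi - lo)
    win_start = np.concatenate(win_start)
    win_count = np.concatenate(win_count)
    pvals = poisson.sf(win_count - 1, lam)
    from .annotate import bh_adjust

    padj = bh_adjust(pvals)
    sig = padj <= fdr
    peaks: list[PeakCall] = []
    cur = None
    for chrom, start, q in sorted(
        (win_chrom[i], int(win_start[i]), float(padj[i]))
        for i in np.flatnonzero(sig)
    ):
        end = start + window
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], end), min(cur[3], q))
        else:
            if cur is not None:
                peaks.append(_mk_peak(cur, source_label))
            cur = (chrom, start, end, q)
    if cur is not None:
        peaks.append(_mk_peak(cur, source_label))
    return peaks


def _mk_peak(cur: tuple, source_label: str) -> PeakCall:
    chrom, start, end, q = cur
    score = -math.log10(q) if q > 0 else 350.0
    return PeakCall(GenomicInterval(chrom, start, end), score=score,
                    source_label=source_label)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path_or_dict: str | dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        log.warning("unknown config keys ignored: %s", sorted(unknown))
    return cfg


def run_pipeline(config: str | dict, outdir: str,
                 stages: tuple[str, ...] | None = None) -> dict:
    """Execute the pipeline stages in dependency order; returns the run
    manifest (also written to ``<outdir>/manifest.json``)."""
    cfg = load_config(config)
    stages = tuple(stages) if stages else DEFAULT_STAGES
    bad = set(stages) - set(DEFAULT_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", cfg.get("simulate", {}).get("seed", 0)))
    sim_cfg = SimConfig(**{**{"seed": seed}, **cfg.get("simulate", {})})
    threshold_fc = float(cfg.get("diff", {}).get("threshold_fc", 1.5))
    threshold = math.log2(threshold_fc)
    min_frac = float(cfg.get("atlas", {}).get("min_frac", 0.75))
    min_overlap_bp = int(cfg.get("count", {}).get("min_overlap_bp", 1))
    top_n = int(cfg.get("pca", {}).get("top_n", 500))
    motif_fraction = float(cfg.get("motifs", {}).get("threshold_fraction", 0.8))
    motif_top = int(cfg.get("motifs", {}).get("top", 20))

    manifest: dict = {
        "tool": "atacdiff",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": {**cfg, "resolved": {
            "seed": seed, "min_frac": min_frac,
            "rlog_fc_threshold": threshold, "pca_top_n": top_n,
            "motif_threshold_fraction": motif_fraction,
        }},
        "stages": {},
        "files": {},
    }

    def record(stage: str, *paths: str) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["files"][os.path.relpath(p, outdir)] = _sha256(p)

    sim = None
    atlas = None
    counts = None
    rlog = None
    classes: dict[str, pd.Series] = {}

    try:
        if "simulate" in stages:
            log.info("stage simulate: seed=%d", seed)
            sim = simulate(sim_cfg, outdir=outdir)
            record("simulate",
                   *[os.path.join(outdir, f) for f in sorted(os.listdir(outdir))
                     if f.endswith((".fa", ".bed", ".tsv", ".gmt", ".jaspar"))])
        if sim is None:
            sim = simulate(sim_cfg)  # deterministic regeneration

        if "qc" in stages:
            rows = []
            for cond in sim.config.conditions:
                hist = fragment_length_distribution(sim.fragments[cond])
                profile = tss_enrichment(
                    sim.fragments[cond], sim.genes,
                    chrom_sizes={c: len(s) for c, s in sim.genome.items()},
                )
                rows.append({
                    "condition": cond,
                    "n_fragments": int(hist.counts.sum() + hist.overflow),
                    "modes": ";".join(f"{p}:{h:.1f}" for p, h in hist.modes),
                    "tss_enrichment": profile.enrichment_score,
                })
            qc_path = os.path.join(outdir, "qc_summary.tsv")
            pd.DataFrame(rows).to_csv(qc_path, sep="\t", index=False)
            record("qc", qc_path)

        if {"atlas", "count", "diff", "overlap", "annotate", "motifs",
                "enrich"} & set(stages):
            all_calls = [c for cond in sim.config.conditions
                         for c in sim.peak_calls[cond]]
            atlas = build_atlas(all_calls, min_frac=min_frac)
        if "atlas" in stages:
            atlas_path = os.path.join(outdir, "atlas.bed")
            write_atlas_bed(atlas, atlas_path)
            record("atlas", atlas_path)

        if {"count", "diff", "overlap", "motifs", "enrich"} & set(stages):
            counts = count_matrix(atlas, sim.fragments,
                                  min_overlap_bp=min_overlap_bp)
        if "count" in stages:
            counts_path = os.path.join(outdir, "counts.tsv")
            counts.to_frame().to_csv(counts_path, sep="\t")
            record("count", counts_path)

        if {"diff", "overlap", "motifs", "enrich"} & set(stages):
            sf = size_factors(counts)
            disp = fit_dispersion(counts, sf)
            rlog = rlog_transform(counts, sf, disp)
            for cond in sim.config.conditions[1:]:
                classes[cond] = classify_peaks(rlog, ("N", cond),
                                               threshold=threshold)
        if "diff" in stages:
            out = pd.DataFrame(index=rlog.peak_ids)
            for cond, cls in classes.items():
                out[f"rlogFC_N_{cond}"] = rlog.fold_change(("N", cond))
                out[f"class_N_{cond}"] = cls
            diff_path = os.path.join(outdir, "diff.tsv")
            out.to_csv(diff_path, sep="\t", index_label="peak_id")
            coords, var_frac = pca_samples(rlog, top_n=top_n)
            pca_path = os.path.join(outdir, "pca.tsv")
            coords.to_csv(pca_path, sep="\t", index_label="sample")
            manifest["config"]["resolved"]["pca_var_frac"] = [
                float(v) for v in var_frac
            ]
            g1, g2 = random_split(rlog.peak_ids, seed)
            split_path = os.path.join(outdir, "split.tsv")
            pd.DataFrame({
                "peak_id": rlog.peak_ids,
                "subgroup": ["1" if p in set(g1) else "2"
                             for p in rlog.peak_ids],
            }).to_csv(split_path, sep="\t", index=False)
            record("diff", diff_path, pca_path, split_path)

        if "overlap" in stages and len(classes) >= 2:
            conds = list(classes)
            summary = overlap_summary(classes[conds[0]], classes[conds[1]])
            rows = [{
                "class": k, "n_" + conds[0]: v[0], "n_shared": v[1],
                "pct_shared": v[2],
            } for k, v in summary.per_class.items()]
            overlap_path = os.path.join(outdir, "overlap.tsv")
            pd.DataFrame(rows).to_csv(overlap_path, sep="\t", index=False)
            record("overlap", overlap_path)

        anno = None
        if {"annotate", "enrich"} & set(stages) and sim.genes:
            anno = annotate_nearest(atlas, sim.genes)
        if "annotate" in stages and anno is not None:
            anno_path = os.path.join(outdir, "annotations.tsv")
            pd.DataFrame([{
                "peak_id": a.peak_id, "nearest_gene": a.nearest_gene_id,
                "signed_distance": a.signed_distance,
            } for a in anno]).to_csv(anno_path, sep="\t", index=False)
            record("annotate", anno_path)

        if "motifs" in stages:
            pwms = builtin_motifs()
            by_id = {p.peak_id: p for p in atlas}
            paths = []
            for cond, cls in classes.items():
                for klass in ("opening", "closing"):
                    fg_ids = set(cls.index[cls == klass])
                    fg = [by_id[i] for i in fg_ids]
                    bg = [p for p in atlas if p.peak_id not in fg_ids]
                    if not fg:
                        continue
                    table = motif_enrichment(
                        fg, bg, sim.genome, pwms,
                        threshold_fraction=motif_fraction, seed=seed,
                    )
                    path = os.path.join(outdir,
                                        f"motifs_{cond}_{klass}.tsv")
                    table.head(motif_top).to_csv(path, sep="\t", index=False)
                    paths.append(path)
            record("motifs", *paths)

        if "enrich" in stages and anno is not None:
            gmt_path = os.path.join(outdir, "gene_sets.gmt")
            if os.path.exists(gmt_path):
                terms = read_gmt(gmt_path)
                universe = [g.gene_id for g in sim.genes]
                gene_of = {a.peak_id: a.nearest_gene_id for a in anno}
                paths = []
                for cond, cls in classes.items():
                    for klass in ("opening", "closing"):
                        query = sorted({
                            gene_of[i] for i in cls.index[cls == klass]
                            if gene_of.get(i, "none") != "none"
                        })
                        if not query:
                            continue
                        table = geneset_enrichment(query, universe, terms)
                        path = os.path.join(
                            outdir, f"enrich_{cond}_{klass}.tsv")
                        table.to_csv(path, sep="\t", index=False)
                        paths.append(path)
                record("enrich", *paths)
    except Exception as exc:
        stage = next((s for s in stages if s not in manifest["stages"]),
                     "unknown")
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest(manifest, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
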