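"""Synthetic ATAC-like data with known ground truth.

Emulates a three-condition CD8+ T-cell design — naive (N), cytokine-primed
(CytP) and antigen-stimulated (AgS) — in which AgS carries roughly ten times
more differential accessibility regions than CytP and a stated fraction of
the CytP-differential regions is shared (same direction) with AgS.  The
generator produces a toy genome, a TSS gene model anchored to accessible
regions, per-condition fragment files with nucleosome-periodic lengths,
per-condition peak calls, and a ground-truth table, so every downstream
stage of the pipeline is testable without any external data.

Count model.  Each region r has a baseline strength ``a_rN`` drawn from a
Gamma distribution with shape ``1/nb_dispersion`` and mean 1; condition
effects multiply that shared strength (``a_rc = a_rN * 2**log2FC_rc``).
Given the strengths, per-library region counts are Poisson with mean
``depth * a_rc / sum_r a_rc``.  Marginally each count is therefore
negative-binomial with the configured dispersion, while the cross-condition
contrast for a region carries only Poisson noise — the overdispersion lives
at the region level and is shared across libraries, as strong and weak
regulatory elements are in real chromatin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    GeneRecord,
    GenomicInterval,
    PWM,
    PeakCall,
    write_bed,
    write_fasta,
    write_gene_model,
    write_peak_calls,
    write_pfm,
)

__all__ = [
    "SimConfig",
    "Simulation",
    "builtin_motifs",
    "generate_genome",
    "generate_fragments",
    "emit_peak_calls",
    "expected_region_counts",
    "simulate",
]

MIN_REGION_GAP = 500
CHROM_EDGE_MARGIN = 2000
MIN_FRAGLEN, MAX_FRAGLEN = 20, 800

# Consensus sequences for the built-in motif set (field-style namesakes).
_BUILTIN_CONSENSUS = {
    "STAT5_like": "TTCCTGGAA",
    "BATF_like": "TGACTCA",
    "ATF_like": "TGACGTCA",
    "ETS_like": "ACCGGAAGT",
    "RUNX_like": "TGTGGTTT",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def builtin_motifs(p_major: float = 0.97) -> list[PWM]:
    """PWMs built from fixed consensus sequences (probability ``p_major``
    on the consensus base, remainder spread over the other three)."""
    pwms = []
    minor = (1.0 - p_major) / 3.0
    for name, cons in _BUILTIN_CONSENSUS.items():
        probs = np.full((len(cons), 4), minor)
        for i, base in enumerate(cons):
            probs[i, "ACGT".index(base)] = p_major
        pwms.append(PWM(name, probs))
    return pwms


@dataclass
class SimConfig:
    """Parameters of the synthetic three-condition design.

    Defaults reproduce the study conditions the pipeline is validated
    under: ~500 regions, mean 200 fragments per region per condition,
    planted |log2FC| = 2, NB dispersion 0.2, AgS with 10x the CytP
    differential fraction, and CytP/AgS shared fractions of 0.33
    (opening) / 0.63 (closing).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    n_regions: int = 500
    region_width_mean: float = 400.0
    region_width_sd: float = 60.0
    conditions: tuple[str, ...] = ("N", "CytP", "AgS")
    frac_diff_per_condition: dict[str, float] = field(
        default_factory=lambda: {"CytP": 0.04, "AgS": 0.40}
    )
    opening_frac_per_condition: dict[str, float] = field(
        default_factory=lambda: {"CytP": 0.30, "AgS": 0.63}
    )
    shared_frac: dict[str, float] = field(
        default_factory=lambda: {"opening": 0.33, "closing": 0.63}
    )
    effect_log2fc: float = 2.0
    depth: float = 100_000.0
    nb_dispersion: float = 0.2
    length_mixture_weights: tuple[float, ...] = (0.5, 0.35, 0.15)
    length_mixture_means: tuple[float, ...] = (75.0, 200.0, 400.0)
    length_mixture_sds: tuple[float, ...] = (15.0, 30.0, 40.0)
    background_rate: float = 1e-4
    motif_plant: dict[str, str] = field(
        default_factory=lambda: {"CytP": "STAT5_like", "AgS": "BATF_like"}
    )
    peak_jitter_sd: float = 10.0
    peak_floor: float = 0.05
    tss_offset_max: int = 200

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name, frac in {**self.frac_diff_per_condition,
                           **self.opening_frac_per_condition,
                           **self.shared_frac}.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {name!r}={frac} outside [0, 1]")
        w = np.asarray(self.length_mixture_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("length mixture weights must be >= 0 and sum to 1")
        if not (len(self.length_mixture_weights)
                == len(self.length_mixture_means)
                == len(self.length_mixture_sds)):
            raise ValueError("length mixture components have inconsistent lengths")
        if self.conditions[0] != "N":
            raise ValueError("first condition is the naive reference 'N'")
        for cond in list(self.frac_diff_per_condition) + list(self.motif_plant):
            if cond not in self.conditions:
                raise ValueError(f"unknown condition {cond!r}")


@dataclass
class Simulation:
    """Bundle of everything one synthetic run produced."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneRecord]
    regions: list[GenomicInterval]
    truth: pd.DataFrame
    fragments: dict[str, list[GenomicInterval]] | None = None
    peak_calls: dict[str, list[PeakCall]] | None = None


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent deterministic stream per generator stage.
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _place_regions(config: SimConfig, rng: np.random.Generator
                   ) -> list[GenomicInterval]:
    per_chrom = np.full(config.n_chroms, config.n_regions // config.n_chroms)
    per_chrom[: config.n_regions % config.n_chroms] += 1
    regions: list[GenomicInterval] = []
    for ci in range(config.n_chroms):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        widths = np.maximum(
            50,
            np.round(rng.normal(config.region_width_mean,
                                config.region_width_sd, k)),
        ).astype(int)
        usable = config.chrom_length - 2 * CHROM_EDGE_MARGIN
        slack = usable - widths.sum() - MIN_REGION_GAP * (k - 1)
        if slack < 0:
            raise ValueError(
                "cannot place regions with >= 500 bp gaps; "
                "increase chrom_length or reduce n_regions"
            )
        offsets = np.sort(rng.uniform(0, slack, k))
        starts = (CHROM_EDGE_MARGIN + offsets
                  + np.concatenate(([0], np.cumsum(widths[:-1] + MIN_REGION_GAP))))
        starts = np.floor(starts).astype(int)
        for s, w in zip(starts, widths):
            regions.append(GenomicInterval(f"chr{ci + 1}", int(s), int(s + w)))
    return regions


def _assign_truth(config: SimConfig, regions: list[GenomicInterval],
                  rng: np.random.Generator) -> pd.DataFrame:
    n = len(regions)
    cols: dict[str, object] = {
        "region_id": [f"region_{i:05d}" for i in range(n)],
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
    }
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        a_base = rng.gamma(shape, config.nb_dispersion, n)
    else:
        a_base = np.ones(n)
    lfc = {c: np.zeros(n) for c in config.conditions if c != "N"}
    classes = {c: np.full(n, "unchanged", dtype=object)
               for c in config.conditions if c != "N"}

    stim = [c for c in config.conditions if c != "N"]
    # Assign the largest condition first, then draw the stated shared
    # fraction of each smaller condition's differential set from it (same
    # direction); the remainder comes from regions differential nowhere.
    stim_sorted = sorted(
        stim, key=lambda c: -config.frac_diff_per_condition.get(c, 0.0)
    )
    assigned: dict[str, dict[str, np.ndarray]] = {}
    diff_anywhere = np.zeros(n, dtype=bool)
    for cond in stim_sorted:
        n_diff = int(round(config.frac_diff_per_condition.get(cond, 0.0) * n))
        n_open = int(round(config.opening_frac_per_condition.get(cond, 0.5)
                           * n_diff))
        chosen: dict[str, np.ndarray] = {}
        for klass, k in (("opening", n_open), ("closing", n_diff - n_open)):
            pool_shared = (np.unique(np.concatenate(
                [assigned[o][klass] for o in assigned]
            )).astype(int) if assigned else np.array([], dtype=int))
            n_shared = min(int(round(config.shared_frac.get(klass, 0.0) * k)),
                           len(pool_shared))
            shared = (rng.choice(pool_shared, n_shared, replace=False)
                      if n_shared else np.array([], dtype=int))
            free = np.flatnonzero(~diff_anywhere)
            if k - n_shared > len(free):
                raise ValueError(
                    "frac_diff_per_condition too large for n_regions"
                )
            fresh = rng.choice(free, k - n_shared, replace=False)
            idx = np.sort(np.concatenate([shared, fresh])).astype(int)
            chosen[klass] = idx
            diff_anywhere[idx] = True
            sign = 1.0 if klass == "opening" else -1.0
            lfc[cond][idx] = sign * config.effect_log2fc
            classes[cond][idx] = klass
        assigned[cond] = chosen

    cols["a_N"] = a_base
    for cond in stim:
        cols[f"a_{cond}"] = a_base * 2.0 ** lfc[cond]
        cols[f"log2fc_{cond}"] = lfc[cond]
        cols[f"class_{cond}"] = classes[cond]

    # Motif planting: each stimulated condition's opening regions carry that
    # condition's motif; a region opening in several conditions carries all
    # of their motifs side by side.
    motifs = [[] for _ in range(n)]
    for cond, motif_name in config.motif_plant.items():
        if cond == "N":
            continue
        for i in np.flatnonzero(classes[cond] == "opening"):
            motifs[int(i)].append(motif_name)
    cols["planted_motifs"] = [",".join(m) for m in motifs]
    return pd.DataFrame(cols)


def _plant_motif_sites(genome: dict[str, list[str]], truth: pd.DataFrame,
                       pwms: dict[str, PWM], rng: np.random.Generator) -> None:
    """Write motif consensus sequence(s) into the genome at region centers,
    one instance per planted motif, random strand, 5 bp spacers."""
    for row in truth.itertuples():
        names = [m for m in row.planted_motifs.split(",") if m]
        if not names:
            continue
        pieces = []
        for name in names:
            cons = pwms[name].consensus
            if rng.random() < 0.5:
                cons = revcomp(cons)
            pieces.append(cons)
        insert = "AAAAA".join(pieces)
        center = (row.start + row.end) // 2
        start = center - len(insert) // 2
        seq = genome[row.chrom]
        seq[start : start + len(insert)] = list(insert)


def generate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], list[GeneRecord],
                               list[GenomicInterval], pd.DataFrame]:
    """Generate the toy genome, gene model, accessible regions and truth
    table. Deterministic given ``config.seed``."""
    config.validate()
    rng = _rng(config, 1)
    regions = _place_regions(config, rng) if config.n_regions else []
    truth = _assign_truth(config, regions, rng) if regions else pd.DataFrame(
        columns=["region_id", "chrom", "start", "end", "a_N", "planted_motifs"]
    )

    bases = np.array(list("ACGT"))
    genome_lists: dict[str, list[str]] = {}
    for ci in range(config.n_chroms):
        seq = rng.choice(bases, config.chrom_length)
        genome_lists[f"chr{ci + 1}"] = list(seq)

    pwms = {p.name: p for p in builtin_motifs()}
    for name in config.motif_plant.values():
        if name not in pwms:
            raise ValueError(f"unknown built-in motif {name!r}")
    if len(truth):
        _plant_motif_sites(genome_lists, truth, pwms, rng)

    # Genes: TSS inside or within tss_offset_max bp of a distinct region.
    genes: list[GeneRecord] = []
    if config.n_genes and regions:
        k = min(config.n_genes, len(regions))
        which = rng.choice(len(regions), k, replace=False)
        for gi, ri in enumerate(which):
            r = regions[int(ri)]
            lo = max(0, r.start - config.tss_offset_max)
            hi = min(config.chrom_length - 1, r.end + config.tss_offset_max)
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"gene_{gi:05d}", r.chrom, tss, strand))
        truth = truth.assign(gene_id="")
        region_gene = {int(ri): f"gene_{gi:05d}" for gi, ri in enumerate(which)}
        truth.loc[list(region_gene), "gene_id"] = list(region_gene.values())

    genome = {name: "".join(seq) for name, seq in genome_lists.items()}
    return genome, genes, regions, truth


def expected_region_counts(truth: pd.DataFrame, depth: float,
                           condition: str) -> np.ndarray:
    """Expected fragment count per region for one condition — the exact
    library composition used by the fragment sampler."""
    col = "a_N" if condition == "N" else f"a_{condition}"
    a = truth[col].to_numpy(dtype=float)
    return depth * a / a.sum()


def _sample_lengths(config: SimConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(len(config.length_mixture_weights), n,
                      p=np.asarray(config.length_mixture_weights))
    means = np.asarray(config.length_mixture_means)[comp]
    sds = np.asarray(config.length_mixture_sds)[comp]
    lengths = rng.normal(means, sds)
    # truncate to [20, 800] by resampling the stragglers
    bad = (lengths < MIN_FRAGLEN) | (lengths > MAX_FRAGLEN)
    while bad.any():
        lengths[bad] = rng.normal(means[bad], sds[bad])
        bad = (lengths < MIN_FRAGLEN) | (lengths > MAX_FRAGLEN)
    return np.maximum(1, np.round(lengths)).astype(int)


def _fragments_from_midpoints(chroms: np.ndarray, mids: np.ndarray,
                              lengths: np.ndarray, chrom_length: int
                              ) -> list[GenomicInterval]:
    starts = np.maximum(0, mids - lengths // 2)
    ends = np.minimum(chrom_length, starts + lengths)
    starts = np.minimum(starts, ends - 1)
    frags = [GenomicInterval(str(c), int(s), int(e))
             for c, s, e in zip(chroms, starts, ends)]
    frags.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return frags


def generate_fragments(config: SimConfig, genome: dict[str, str],
                       regions: list[GenomicInterval], truth: pd.DataFrame
                       ) -> dict[str, list[GenomicInterval]]:
    """Sample per-condition fragment lists (region + uniform background)."""
    config.validate()
    rng = _rng(config, 2)
    out: dict[str, list[GenomicInterval]] = {}
    total_bp = sum(len(s) for s in genome.values())
    chrom_names = list(genome)
    chrom_sizes = np.array([len(genome[c]) for c in chrom_names])
    for cond in config.conditions:
        chroms_acc: list[np.ndarray] = []
        mids_acc: list[np.ndarray] = []
        if len(truth):
            lam = expected_region_counts(truth, config.depth, cond)
            counts = rng.poisson(lam)
            for r, k in zip(regions, counts):
                if k == 0:
                    continue
                mids_acc.append(rng.integers(r.start, r.end, k))
                chroms_acc.append(np.full(k, r.chrom, dtype=object))
        n_bg = rng.poisson(config.background_rate * total_bp)
        if n_bg:
            which = rng.choice(len(chrom_names), n_bg,
                               p=chrom_sizes / chrom_sizes.sum())
            mids_acc.append(rng.integers(0, chrom_sizes[which]))
            chroms_acc.append(np.array(chrom_names, dtype=object)[which])
        if not mids_acc:
            out[cond] = []
            continue
        mids = np.concatenate(mids_acc)
        chroms = np.concatenate(chroms_acc)
        lengths = _sample_lengths(config, len(mids), rng)
        out[cond] = _fragments_from_midpoints(
            chroms, mids, lengths, config.chrom_length
        )
    return out


def emit_peak_calls(regions: list[GenomicInterval], truth: pd.DataFrame,
                    config: SimConfig) -> dict[str, list[PeakCall]]:
    """Per-condition peak calls: every region whose accessibility is at or
    above ``peak_floor``, boundaries jittered by N(0, peak_jitter_sd).

    Jitter draws are resampled until each emitted call keeps >= 90%
    reciprocal overlap with its source region, which guarantees (and is
    asserted) that same-region calls across conditions retain > 75%
    reciprocal overlap.
    """
    from .atlas import merge_predicate  # local import avoids a cycle

    config.validate()
    rng = _rng(config, 3)
    calls: dict[str, list[PeakCall]] = {c: [] for c in config.conditions}
    if not len(truth):
        return calls
    per_region: dict[int, list[GenomicInterval]] = {}
    for cond in config.conditions:
        col = "a_N" if cond == "N" else f"a_{cond}"
        for i, (r, a) in enumerate(zip(regions, truth[col].to_numpy())):
            if a < config.peak_floor:
                continue
            for _ in range(1000):
                if config.peak_jitter_sd > 0:
                    j = np.round(rng.normal(0, config.peak_jitter_sd, 2))
                    start = max(0, int(r.start + j[0]))
                    end = min(config.chrom_length, int(r.end + j[1]))
                else:
                    start, end = r.start, r.end
                if end <= start:
                    continue
                cand = GenomicInterval(r.chrom, start, end)
                ov = cand.overlap_bp(r)
                if ov >= 0.90 * cand.length and ov >= 0.90 * r.length:
                    break
            else:  # pragma: no cover - resampling bound
                raise RuntimeError("could not draw acceptable peak jitter")
            calls[cond].append(PeakCall(cand, score=float(a), source_label=cond))
            per_region.setdefault(i, []).append(cand)
    for ivs in per_region.values():
        for a in ivs:
            for b in ivs:
                assert merge_predicate(a, b, 0.75), (
                    "jittered same-region calls fell below 75% reciprocal "
                    "overlap; reduce peak_jitter_sd"
                )
    return calls


def _emit_gene_sets(truth: pd.DataFrame, genes: list[GeneRecord],
                    config: SimConfig, rng: np.random.Generator
                    ) -> dict[str, tuple[str, frozenset[str]]]:
    """Synthetic gene-set map: one term per condition x class collecting the
    genes of that class's regions, plus random decoy terms."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    if "gene_id" not in truth.columns or not genes:
        return terms
    all_ids = [g.gene_id for g in genes]
    for cond in config.conditions:
        if cond == "N" or f"class_{cond}" not in truth.columns:
            continue
        for klass in ("opening", "closing"):
            members = truth.loc[
                (truth[f"class_{cond}"] == klass) & (truth["gene_id"] != ""),
                "gene_id",
            ]
            if len(members):
                terms[f"{klass.upper()}_{cond}"] = (
                    f"genes at {klass} regions in {cond}",
                    frozenset(members),
                )
    for d in range(5):
        size = int(rng.integers(10, 40))
        decoy = rng.choice(all_ids, min(size, len(all_ids)), replace=False)
        terms[f"DECOY_{d}"] = ("random gene set", frozenset(decoy))
    return terms


def simulate(config: SimConfig, outdir: str | None = None) -> Simulation:
    """Run the full generator; optionally write all outputs under ``outdir``.

    Files written: ``genome.fa``, ``genes.bed``, ``regions.bed``,
    ``truth.tsv``, ``motifs.jaspar``, ``gene_sets.gmt`` and per-condition
    ``fragments_<cond>.bed`` / ``peaks_<cond>.bed``.
    """
    genome, genes, regions, truth = generate_genome(config)
    fragments = generate_fragments(config, genome, regions, truth)
    peak_calls = emit_peak_calls(regions, truth, config)
    sim = Simulation(config, genome, genes, regions, truth,
                     fragments, peak_calls)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(genome, os.path.join(outdir, "genome.fa"))
        if genes:
            write_gene_model(genes, os.path.join(outdir, "genes.bed"))
        write_bed(regions, os.path.join(outdir, "regions.bed"),
                  names=list(truth["region_id"]) if len(truth) else [])
        truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        write_pfm(builtin_motifs(), os.path.join(outdir, "motifs.jaspar"))
        for cond in config.conditions:
            write_bed(fragments[cond],
                      os.path.join(outdir, f"fragments_{cond}.bed"))
            write_peak_calls(peak_calls[cond],
                             os.path.join(outdir, f"peaks_{cond}.bed"))
        terms = _emit_gene_sets(truth, genes, config, _rng(config, 4))
        if terms:
            with open(os.path.join(outdir, "gene_sets.gmt"), "w") as fh:
                for term, (desc, members) in terms.items():
                    fh.write("\t".join([term, desc] + sorted(members)) + "\n")
    return sim
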