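import numpy as np
import pandas as pd
import pytest

from atacdiff.atlas import merge_predicate
from atacdiff.formats import GenomicInterval
from atacdiff.synthio import (
    SimConfig,
    builtin_motifs,
    emit_peak_calls,
    expected_region_counts,
    generate_fragments,
    generate_genome,
    revcomp,
    simulate,
)

SMALL = dict(n_chroms=1, chrom_length=150_000, n_genes=20, n_regions=30,
             depth=6000.0)


class TestGenerateGenome:
    def test_deterministic_given_seed(self, tmp_path):
        a = simulate(SimConfig(seed=11, **SMALL), outdir=str(tmp_path / "a"))
        b = simulate(SimConfig(seed=11, **SMALL), outdir=str(tmp_path / "b"))
        for f in ("genome.fa", "genes.bed", "regions.bed", "truth.tsv",
                  "fragments_AgS.bed", "peaks_CytP.bed"):
            assert (tmp_path / "a" / f).read_bytes() == \
                (tmp_path / "b" / f).read_bytes(), f
        c = simulate(SimConfig(seed=12, **SMALL), outdir=str(tmp_path / "c"))
        assert (tmp_path / "a" / "genome.fa").read_bytes() != \
            (tmp_path / "c" / "genome.fa").read_bytes()

    def test_no_regions_empty_truth(self):
        genome, genes, regions, truth = generate_genome(
            SimConfig(seed=0, n_regions=0, n_genes=0, n_chroms=1,
                      chrom_length=50_000))
        assert regions == [] and len(truth) == 0
        assert len(genome["chr1"]) == 50_000

    def test_region_gaps_at_least_500(self):
        cfg = SimConfig(seed=3, n_chroms=2, chrom_length=1_000_000,
                        n_regions=200, n_genes=0)
        _, _, regions, _ = generate_genome(cfg)
        assert len(regions) == 200
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda r: r.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end >= 500

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="chrom_length"):
            generate_genome(SimConfig(seed=0, n_chroms=1, chrom_length=20_000,
                                      n_regions=50, n_genes=0))

    def test_tss_near_regions(self):
        cfg = SimConfig(seed=5, **SMALL)
        _, genes, regions, truth = generate_genome(cfg)
        for g in genes:
            near = min(max(r.start - g.tss, g.tss - (r.end - 1), 0)
                       for r in regions if r.chrom == g.chrom)
            assert near <= cfg.tss_offset_max

    def test_planted_motif_written_into_genome(self):
        cfg = SimConfig(seed=5, **SMALL)
        genome, _, _, truth = generate_genome(cfg)
        pwms = {p.name: p for p in builtin_motifs()}
        planted = truth[truth.planted_motifs != ""]
        assert len(planted) > 0
        for row in planted.itertuples():
            window = genome[row.chrom][row.start:row.end]
            for name in row.planted_motifs.split(","):
                cons = pwms[name].consensus
                assert cons in window or revcomp(cons) in window


class TestTruthStructure:
    def test_ags_tenfold_and_shared_fractions(self, default_sim):
        t = default_sim.truth
        n_cytp = (t.class_CytP != "unchanged").sum()
        n_ags = (t.class_AgS != "unchanged").sum()
        assert n_ags == 10 * n_cytp == 200
        open_shared = ((t.class_CytP == "opening")
                       & (t.class_AgS == "opening")).sum()
        close_shared = ((t.class_CytP == "closing")
                        & (t.class_AgS == "closing")).sum()
        assert open_shared == round(0.33 * (t.class_CytP == "opening").sum())
        assert close_shared == round(0.63 * (t.class_CytP == "closing").sum())

    def test_class_consistent_with_log2fc(self, default_sim):
        t = default_sim.truth
        for cond in ("CytP", "AgS"):
            lfc = t[f"log2fc_{cond}"]
            cls = t[f"class_{cond}"]
            assert (cls[lfc > 0] == "opening").all()
            assert (cls[lfc < 0] == "closing").all()
            assert (cls[lfc == 0] == "unchanged").all()

    def test_accessibility_bookkeeping_exact(self, default_sim):
        t = default_sim.truth
        for cond in ("N", "CytP", "AgS"):
            lam = expected_region_counts(t, default_sim.config.depth, cond)
            assert lam.sum() == pytest.approx(default_sim.config.depth)
            col = "a_N" if cond == "N" else f"a_{cond}"
            ratio = lam / t[col].to_numpy()
            np.testing.assert_allclose(ratio, ratio[0])


class TestGenerateFragments:
    def test_null_effect_conditions_exchangeable(self):
        cfg = SimConfig(seed=21, effect_log2fc=0.0, **SMALL)
        genome, _, regions, truth = generate_genome(cfg)
        frags = generate_fragments(cfg, genome, regions, truth)
        totals = {c: len(v) for c, v in frags.items()}
        # total in-region counts are Poisson(depth)+background; 4 sigma band
        expect = cfg.depth + cfg.background_rate * cfg.chrom_length
        for c, n in totals.items():
            assert abs(n - expect) < 4 * np.sqrt(expect), (c, n)

    def test_single_component_length_mean(self):
        cfg = SimConfig(seed=22, length_mixture_weights=(1.0,),
                        length_mixture_means=(75.0,),
                        length_mixture_sds=(15.0,),
                        n_chroms=1, chrom_length=300_000, n_genes=0,
                        n_regions=50, depth=10_000.0, background_rate=0.0)
        genome, _, regions, truth = generate_genome(cfg)
        frags = generate_fragments(cfg, genome, regions, truth)["N"]
        lengths = np.array([f.length for f in frags])
        assert len(lengths) > 8000
        assert abs(lengths.mean() - 75.0) < 2.0

    def test_planted_fold_change_recovered_in_raw_counts(self, default_sim):
        """Opening regions carry ~2^2 more AgS than N fragments once the
        library-composition shift (larger total accessibility in AgS) is
        divided out."""
        t = default_sim.truth
        up = (t.class_AgS == "opening").to_numpy()
        counts = {c: np.zeros(len(t)) for c in ("N", "AgS")}
        for cond in ("N", "AgS"):
            mids: dict[str, list[int]] = {}
            for f in default_sim.fragments[cond]:
                mids.setdefault(f.chrom, []).append((f.start + f.end) // 2)
            sorted_mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
            for i, r in enumerate(default_sim.regions):
                m = sorted_mids.get(r.chrom, np.empty(0))
                counts[cond][i] = (np.searchsorted(m, r.end)
                                   - np.searchsorted(m, r.start))
        composition = t.a_AgS.sum() / t.a_N.sum()
        ratio = counts["AgS"][up].sum() / counts["N"][up].sum() * composition
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestEmitPeakCalls:
    def test_zero_jitter_reproduces_regions(self, small_sim):
        cfg = SimConfig(seed=small_sim.config.seed, peak_jitter_sd=0.0,
                        **{k: getattr(small_sim.config, k)
                           for k in ("n_chroms", "chrom_length", "n_genes",
                                     "n_regions", "depth")})
        calls = emit_peak_calls(small_sim.regions, small_sim.truth, cfg)
        for cond, cs in calls.items():
            col = "a_N" if cond == "N" else f"a_{cond}"
            kept = [r for r, a in zip(small_sim.regions,
                                      small_sim.truth[col])
                    if a >= cfg.peak_floor]
            assert [c.interval for c in cs] == kept

    def test_same_region_calls_mergeable_across_conditions(self, small_sim):
        per_region = {}
        for cond, cs in small_sim.peak_calls.items():
            for c in cs:
                key = min(
                    (r for r in small_sim.regions
                     if r.chrom == c.interval.chrom),
                    key=lambda r: -r.overlap_bp(c.interval),
                )
                per_region.setdefault((key.chrom, key.start), []).append(c)
        for calls in per_region.values():
            for a in calls:
                for b in calls:
                    assert merge_predicate(a.interval, b.interval, 0.75)

    def test_region_below_floor_only_in_open_condition(self):
        truth = pd.DataFrame({
            "region_id": ["r0"], "chrom": ["chr1"], "start": [1000],
            "end": [1400], "a_N": [0.01], "a_CytP": [0.01], "a_AgS": [0.04],
            "log2fc_CytP": [0.0], "log2fc_AgS": [2.0],
            "class_CytP": ["unchanged"], "class_AgS": ["opening"],
            "planted_motifs": [""],
        })
        cfg = SimConfig(seed=0, peak_jitter_sd=0.0, peak_floor=0.02)
        regions = [GenomicInterval("chr1", 1000, 1400)]
        calls = emit_peak_calls(regions, truth, cfg)
        assert len(calls["N"]) == 0 and len(calls["CytP"]) == 0
        assert len(calls["AgS"]) == 1
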