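"""The synthetic-data generator: determinism, configured proportions,
ground-truth consistency and file round-trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from t2dnet.core import read_bed, read_gene_table, read_tads
from t2dnet.loops import merge_loop_sets, pair_colocalization, read_bedpe
from t2dnet.simulate import (
    ANNOTATION_COLUMNS,
    SimulationConfig,
    generate_coloc_signal,
    generate_genes,
    generate_gwas,
    generate_loops,
    generate_segments,
    generate_sites,
    simulate_all,
    write_bundle,
)
from t2dnet.targets import promoter_regions


def small_config(seed=3, **overrides):
    base = dict(
        n_chromosomes=2,
        chrom_length=15_000_000,
        n_sites=800,
        n_genes=300,
        n_loops=150,
        n_signals=10,
        n_null_windows=15,
        variants_per_signal=20,
    )
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config()
        p1 = write_bundle(simulate_all(cfg), tmp_path / "a")
        p2 = write_bundle(simulate_all(cfg), tmp_path / "b")
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seed_differs(self):
        b1 = simulate_all(small_config(seed=3))
        b2 = simulate_all(small_config(seed=4))
        assert not b1.gwas["beta"].equals(b2.gwas["beta"])


class TestGenome:
    def test_segment_state_proportions_match_config(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=4, chrom_length=55_000_000,
            mean_segment_length=20_000,
        )
        segments = generate_segments(cfg)
        assert len(segments) >= 10_000
        counts = pd.Series([s.state for s in segments]).value_counts(normalize=True)
        for state, expected in cfg.state_proportions.items():
            assert counts.get(state, 0.0) == pytest.approx(expected, abs=0.02)

    def test_segments_tile_chromosomes(self):
        cfg = small_config()
        segments = generate_segments(cfg)
        for chrom in cfg.chrom_names:
            segs = sorted(
                (s.interval for s in segments if s.interval.chrom == chrom),
                key=lambda iv: iv.start,
            )
            assert segs[0].start == 0
            assert segs[-1].end == cfg.chrom_length
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.end == b.start

    def test_zero_genes_empty_but_valid(self, tmp_path):
        cfg = small_config(n_genes=0)
        genes = generate_genes(cfg)
        assert genes == []

    def test_sites_split_along_segmentation(self):
        cfg = small_config()
        segments = generate_segments(cfg)
        sites = generate_sites(cfg, segments)
        seg_lookup = {
            (s.interval.chrom, s.interval.start): s.state for s in segments
        }
        # every site element carries exactly one state and positive support
        for s in sites[:200]:
            assert s.support >= 1
            assert s.interval.width > 0


class TestLoops:
    def test_jittered_duplicates_collapse_after_merge(self):
        cfg = small_config()
        segments = generate_segments(cfg)
        sites = generate_sites(cfg, segments)
        genes = generate_genes(cfg, sites)
        promoters = promoter_regions(genes)
        loop_sets, _ = generate_loops(cfg, sites, promoters)
        total = sum(len(v) for v in loop_sets.values())
        merged = merge_loop_sets(list(loop_sets.values()))
        # pooled emits every base loop; samples re-emit jittered copies
        assert len(merged) <= len(loop_sets["pooled"])
        assert total > len(merged)

    def test_ep_enrichment_drives_state_pairing(self):
        cfg_null = small_config(seed=8, ep_loop_enrichment=1.0, n_loops=250)
        cfg_ep = small_config(seed=8, ep_loop_enrichment=4.0, n_loops=250)
        results = {}
        for name, cfg in [("null", cfg_null), ("ep", cfg_ep)]:
            segments = generate_segments(cfg)
            sites = generate_sites(cfg, segments)
            genes = generate_genes(cfg, sites)
            loop_sets, _ = generate_loops(cfg, sites, promoter_regions(genes))
            merged = merge_loop_sets(list(loop_sets.values()))
            pairs = {
                (p.state_a, p.state_b): p for p in pair_colocalization(sites, merged)
            }
            results[name] = pairs.get(("EnhA1", "TssA"))
        assert results["ep"] is not None
        assert results["ep"].odds_ratio > 1
        assert results["ep"].p_value < 0.05
        if results["null"] is not None:
            assert results["null"].odds_ratio < results["ep"].odds_ratio


class TestGwas:
    def test_causal_annotation_fraction_matches_softmax_expectation(self):
        cfg = SimulationConfig(
            seed=13, n_signals=3000, n_null_windows=0, variants_per_signal=20,
            n_chromosomes=2, chrom_length=20_000_000,
        )
        segments = generate_segments(cfg)
        gwas, X, truth = generate_gwas(cfg, segments)
        j = ANNOTATION_COLUMNS.index("EnhA1")
        vid_to_idx = {v: i for i, v in enumerate(gwas["variant_id"])}
        causal_idx = [
            vid_to_idx[v] for v in truth.causal_variant_by_window.values() if v
        ]
        observed = X[causal_idx, j].mean()
        # expectation: mean over windows of the softmax mass on the annotation
        gamma = np.array(
            [cfg.true_ln_enrichment.get(a, 0.0) for a in ANNOTATION_COLUMNS]
        )
        expected = []
        for w in range(cfg.n_signals):
            idx = np.flatnonzero(gwas["window_id"].to_numpy() == w)
            wts = np.exp(X[idx] @ gamma)
            expected.append((wts * X[idx, j]).sum() / wts.sum())
        assert observed == pytest.approx(np.mean(expected), abs=0.025)

    def test_null_enrichment_gives_uniform_causal_annotations(self):
        cfg = SimulationConfig(
            seed=14, n_signals=2000, n_null_windows=0, variants_per_signal=20,
            n_chromosomes=2, chrom_length=20_000_000,
            true_ln_enrichment={},
        )
        segments = generate_segments(cfg)
        gwas, X, truth = generate_gwas(cfg, segments)
        j = ANNOTATION_COLUMNS.index("EnhA1")
        vid_to_idx = {v: i for i, v in enumerate(gwas["variant_id"])}
        causal_idx = [
            vid_to_idx[v] for v in truth.causal_variant_by_window.values() if v
        ]
        assert X[causal_idx, j].mean() == pytest.approx(X[:, j].mean(), abs=0.025)

    def test_null_windows_have_no_causal_variant(self):
        cfg = small_config()
        gwas, _, truth = generate_gwas(cfg, generate_segments(cfg))
        for w, vid in truth.causal_variant_by_window.items():
            if w >= cfg.n_signals:
                assert vid is None
            else:
                assert vid is not None

    def test_causal_effects_conditioned_away_from_zero(self):
        cfg = small_config(n_signals=40)
        gwas, _, truth = generate_gwas(cfg, generate_segments(cfg))
        # observed beta at causal variants should rarely be tiny
        causal = set(v for v in truth.causal_variant_by_window.values() if v)
        betas = gwas.loc[gwas["variant_id"].isin(causal), "beta"].abs()
        assert betas.median() > cfg.effect_min_frac * cfg.effect_sd / 2


class TestColocGenerator:
    def test_shared_and_distinct_construction(self, rng):
        cfg = SimulationConfig(seed=1)
        b, se, zm, c1, c2 = generate_coloc_signal(cfg, rng, shared=True)
        assert c1 == c2
        assert abs(b[c1] / se[c1]) > 4  # genome-wide significant lead
        b, se, zm, c1, c2 = generate_coloc_signal(cfg, rng, shared=False)
        assert c1 != c2
        assert abs(zm[c2]) > 3


class TestRoundTrips:
    def test_all_emitted_files_parse_through_own_readers(self, tmp_path):
        bundle = simulate_all(small_config())
        paths = write_bundle(bundle, tmp_path)
        assert read_bed(paths["segments.bed"]) == bundle.segments
        assert read_bed(paths["sites.bed"]) == bundle.sites
        assert read_gene_table(paths["genes.tsv"]) == bundle.genes
        assert [t.interval for t in read_tads(paths["tads.bed"])] == [
            t.interval for t in bundle.tads
        ]
        for source, loops_ in bundle.loop_sets.items():
            got = read_bedpe(paths[f"loops_{source}.bedpe"])
            assert got == loops_
        gwas = pd.read_csv(paths["gwas.tsv"], sep="\t")
        assert len(gwas) == len(bundle.gwas)
        assert (gwas[list(ANNOTATION_COLUMNS)].to_numpy() == bundle.annotations).all()

    def test_ground_truth_json_written(self, tmp_path):
        import json

        bundle = simulate_all(small_config())
        paths = write_bundle(bundle, tmp_path)
        truth = json.loads(paths["ground_truth.json"].read_text())
        assert set(truth) >= {
            "causal_variant_by_window",
            "imbalanced_variants",
            "coloc_shared_by_signal",
        }
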