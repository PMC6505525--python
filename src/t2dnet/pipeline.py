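"""End-to-end orchestration: synthetic inputs through loop merging,
enrichment, enhancer-gene mapping, expression, fine-mapping, allelic
imbalance, eQTL testing and colocalization, with a reproducibility manifest.

Every stage writes plain TSV/JSON intermediates; a manifest records the
configuration hash and a checksum per output so identical config + seed
reruns are byte-identical. Stages can be toggled; a stage whose upstream
dependency is disabled refuses to run with an error naming the missing
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eqtl as eqtl_mod
from . import expression as expr_mod
from . import finemap as fm
from . import imbalance as imb
from .core import AnnotatedSite
from .loops import (
    anchor_enrichment,
    merge_loop_sets,
    pair_colocalization,
    write_bedpe,
)
from .simulate import (
    ANNOTATION_COLUMNS,
    SimulationConfig,
    SyntheticBundle,
    simulate_all,
    write_bundle,
)
from .targets import assign_signal_targets, degree_counts, map_enhancer_targets

logger = logging.getLogger(__name__)

CPPA_GROUPS = {
    "enhancer": ["EnhA1", "EnhA2", "EnhWk"],
    "promoter": ["TssA", "TssFlnk"],
    "ctcf": ["CTCF"],
    "transcribed": ["Txn"],
}

ALL_STAGES = (
    "loops",
    "enrichment",
    "targets",
    "expression",
    "finemap",
    "imbalance",
    "eqtl",
)

#: Upstream outputs each stage consumes.
STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "enrichment": ("loops",),
    "targets": ("loops",),
    "expression": ("targets",),
    "imbalance": ("finemap",),
    "eqtl": ("targets", "finemap"),
}


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults are the reference analysis values."""

    seed: int = 0
    merge_tolerance: int = 20_000
    n_perm: int = 7000
    anchor_window: int = 25_000
    target_flank: int = 25_000
    ln_tpm_threshold: float = 1.0
    prior_variance: float = 0.04
    eqtl_prior_variance: float = 0.0225
    credible_level: float = 0.99
    ppa_scan_threshold: float = 0.01
    imbalance_q: float = 0.1
    maf_min: float = 0.01
    r2_threshold: float = 0.5
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    kmeans_k: int = 4
    enrichment_penalty: float | None = 0.0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None

    def validate(self) -> list[str]:
        """Collect every range violation at once; empty list means ok."""
        errors = []
        if self.merge_tolerance < 0:
            errors.append("merge_tolerance must be >= 0")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        for name in ("prior_variance", "eqtl_prior_variance"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not 0 < self.credible_level < 1:
            errors.append("credible_level must be in (0, 1)")
        if not 0 < self.imbalance_q < 1:
            errors.append("imbalance_q must be in (0, 1)")
        if not 0 < self.coloc_p12 <= min(self.coloc_p1, self.coloc_p2):
            errors.append("require 0 < coloc_p12 <= min(coloc_p1, coloc_p2)")
        if self.kmeans_k < 2:
            errors.append("kmeans_k must be >= 2")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                errors.append(f"unknown stage {stage!r}")
                continue
            for dep in STAGE_DEPS.get(stage, ()):
                if dep not in self.stages:
                    errors.append(
                        f"stage {stage!r} requires the output of stage {dep!r}, "
                        "which is not enabled"
                    )
        return errors

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def validate_config(config: RunConfig) -> None:
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()


def _segment_lookup(segments: list[AnnotatedSite]):
    """Fast position -> containing state segment lookup."""
    by_chrom: dict[str, list[AnnotatedSite]] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    arrays = {}
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.interval.start)
        arrays[chrom] = (
            np.array([s.interval.start for s in segs]),
            np.array([s.interval.end for s in segs]),
            segs,
        )

    def containing(chrom: str, pos: int) -> AnnotatedSite | None:
        entry = arrays.get(chrom)
        if entry is None:
            return None
        starts, ends, segs = entry
        k = int(np.searchsorted(ends, pos, side="right"))
        if k < len(segs) and starts[k] <= pos < ends[k]:
            return segs[k]
        return None

    return containing


def run_pipeline(
    config: RunConfig, outdir: str | Path, bundle: SyntheticBundle | None = None
) -> dict:
    """Run the enabled stages on a synthetic bundle and write outputs plus
    a manifest.

    When ``bundle`` is None a bundle is simulated from
    ``config.simulation`` (or a default simulation at ``config.seed``).
    Returns a results dictionary mirroring the written files.
    """
    validate_config(config)
    stages = set(config.stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
        bundle = simulate_all(sim_cfg)
    write_bundle(bundle, outdir / "inputs")

    results: dict = {}
    outputs: dict[str, Path] = {}

    def emit_tsv(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = path

    def emit_json(name: str, payload: dict) -> None:
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        outputs[name] = path

    merged = None
    if "loops" in stages:
        merged = merge_loop_sets(
            list(bundle.loop_sets.values()), tolerance=config.merge_tolerance
        )
        path = outdir / "loops_merged.bedpe"
        write_bedpe(merged, path)
        outputs["loops_merged"] = path
        results["n_loops_merged"] = len(merged)
        results["median_loop_span"] = float(np.median([lp.span for lp in merged]))

    if "enrichment" in stages:
        enrich = anchor_enrichment(
            bundle.sites,
            merged,
            bundle.config.chrom_sizes,
            n_perm=config.n_perm,
            window=config.anchor_window,
            mode="within_window",
            rng_seed=config.seed,
        )
        enrich_df = pd.DataFrame(
            [
                {
                    "state": e.state,
                    "observed": e.observed,
                    "null_mean": e.null_mean,
                    "fold": e.fold,
                    "empirical_p": e.empirical_p,
                }
                for e in enrich
            ]
        )
        emit_tsv("anchor_enrichment", enrich_df)
        results["anchor_enrichment"] = enrich_df

        pairs = pair_colocalization(bundle.sites, merged)
        pair_df = pd.DataFrame(
            [
                {
                    "state_a": p.state_a,
                    "state_b": p.state_b,
                    "odds_ratio": p.odds_ratio,
                    "p": p.p_value,
                }
                for p in pairs
            ]
        )
        emit_tsv("pair_enrichment", pair_df)
        results["pair_enrichment"] = pair_df

    loop_counts = None
    if "targets" in stages:
        enhancers = [s for s in bundle.sites if s.state == "EnhA1"]
        edges = map_enhancer_targets(enhancers, bundle.promoters, merged, flank=0)
        gene_deg, _, gene_loops = degree_counts(edges)
        emit_tsv(
            "enhancer_gene_edges",
            pd.DataFrame(
                [
                    {
                        "chrom": e.enhancer.interval.chrom,
                        "start": e.enhancer.interval.start,
                        "end": e.enhancer.interval.end,
                        "gene_id": e.gene_id,
                        "loop_id": e.loop_id,
                        "distance": e.distance,
                    }
                    for e in edges
                ]
            ),
        )
        results["n_edges"] = len(edges)
        results["n_genes_looped"] = len(gene_deg)
        results["n_genes_multi_enhancer"] = sum(1 for v in gene_deg.values() if v > 1)
        loop_counts = pd.Series(
            {g.gene_id: gene_loops.get(g.gene_id, 0) for g in bundle.genes},
            dtype=float,
        ).sort_index()

    if "expression" in stages:
        tpm = expr_mod.rpkm_to_tpm(bundle.islet_rpkm)
        islet_tpm = tpm.mean(axis=1)
        table, chi2, chi_p = expr_mod.expression_loop_contingency(
            islet_tpm, loop_counts, ln_tpm_threshold=config.ln_tpm_threshold
        )
        rho, rho_p = expr_mod.loop_expression_spearman(islet_tpm, loop_counts)
        z = expr_mod.cross_tissue_zscores(bundle.tissue_tpm)
        reg = expr_mod.zscore_on_loopcount(z["Islets"], loop_counts)
        expr_summary = {
            "contingency_table": table.tolist(),
            "chi2": chi2,
            "chi2_p": chi_p,
            "spearman_rho": rho,
            "spearman_p": rho_p,
            "islet_z_slope": reg.beta,
            "islet_z_slope_se": reg.se,
            "islet_z_slope_p": reg.p,
        }
        emit_json("expression_summary", expr_summary)
        results["expression"] = expr_summary

    gwas = bundle.gwas
    X = bundle.annotations
    log_abf = fm.wakefield_log_abf(
        gwas["beta"].to_numpy(), gwas["se"].to_numpy(), config.prior_variance
    )
    model = None
    ppa_by_variant: dict[str, float] = {}
    if "finemap" in stages:
        windows = fm.VariantWindows(
            log_abf, X, gwas["window_id"].to_numpy(), list(ANNOTATION_COLUMNS)
        )
        model = fm.fit_enrichment(
            windows, penalty=config.enrichment_penalty, compute_ci=True
        )
        emit_json("enrichment_model", model.to_dict())
        results["enrichment_model"] = model

        sel = [list(ANNOTATION_COLUMNS).index(a) for a in model.annotation_names]
        signal_rows = []
        cppa_rows = []
        signal_ids = []
        for w in bundle.truth.signal_windows:
            mask = (gwas["window_id"] == w).to_numpy()
            priors = fm.annotation_priors(X[mask][:, sel], model)
            ppas = fm.ppa_from_log(np.log(priors), log_abf[mask])
            vids = gwas.loc[mask, "variant_id"].tolist()
            cs = fm.credible_set(vids, ppas, level=config.credible_level)
            cppa = fm.cumulative_ppa(ppas, X[mask], ANNOTATION_COLUMNS, CPPA_GROUPS)
            cppa_rows.append([cppa[g] for g in CPPA_GROUPS])
            signal_ids.append(w)
            for vid, pr, pp in zip(vids, priors, ppas):
                ppa_by_variant[vid] = float(pp)
                signal_rows.append(
                    {
                        "window_id": w,
                        "variant_id": vid,
                        "prior": float(pr),
                        "ppa": float(pp),
                        "in_credible_set": vid in cs,
                    }
                )
        signal_df = pd.DataFrame(signal_rows)
        emit_tsv("finemap_signals", signal_df)
        results["finemap_signals"] = signal_df

        cppa_matrix = np.array(cppa_rows)
        labels, enh_cluster = fm.cppa_cluster(
            cppa_matrix,
            list(CPPA_GROUPS),
            k=min(config.kmeans_k, len(signal_ids)),
            seed=config.seed,
        )
        is_enh_signal = labels == enh_cluster
        secretion = np.array(
            [bundle.truth.secretion_associated.get(w, False) for w in signal_ids]
        )
        try:
            chi_p_g, binom_p_g, gly_table = fm.glycemic_overlap_tests(
                is_enh_signal, secretion
            )
        except ValueError:
            chi_p_g, binom_p_g, gly_table = float("nan"), float("nan"), np.zeros((2, 2))
        cluster_summary = {
            "labels": labels.tolist(),
            "enhancer_cluster": int(enh_cluster),
            "n_enhancer_signals": int(is_enh_signal.sum()),
            "glycemic_chi2_p": chi_p_g,
            "glycemic_binomial_p": binom_p_g,
            "glycemic_table": np.asarray(gly_table).tolist(),
        }
        emit_json("signal_clusters", cluster_summary)
        results["clusters"] = cluster_summary

        # genome-wide scan over the non-signal windows
        null_mask = ~gwas["is_signal_window"].to_numpy()
        scan_windows = fm.VariantWindows(
            log_abf[null_mask],
            X[null_mask],
            gwas.loc[null_mask, "window_id"].to_numpy(),
            list(ANNOTATION_COLUMNS),
        )
        enh_col = list(ANNOTATION_COLUMNS).index("EnhA1")
        kept, _ = fm.genomewide_scan(
            scan_windows,
            model,
            X[null_mask][:, enh_col] > 0,
            threshold=config.ppa_scan_threshold,
        )
        results["n_scan_windows"] = len(kept)

    if "imbalance" in stages:
        atac_records = [
            imb.AlleleCountRecord(
                r.variant_id, r.sample_id, r.ref_count, r.alt_count, r.sample_depth, "ATAC"
            )
            for r in bundle.atac_counts.itertuples()
        ]
        hic_records = [
            imb.AlleleCountRecord(
                r.variant_id, r.sample_id, r.ref_count, r.alt_count, r.sample_depth, "HiC"
            )
            for r in bundle.hic_counts.itertuples()
        ]
        atac_results = imb.combine_imbalance(atac_records, imb.MIN_PER_ALLELE_ATAC)
        hic_res = imb.combine_imbalance_fisher(hic_records, imb.MIN_PER_ALLELE_HIC)
        imb_df = imb.results_frame(atac_results)
        emit_tsv("imbalance_atac", imb_df)
        results["imbalance"] = imb_df
        results["n_imbalanced"] = (
            int((imb_df["q"] < config.imbalance_q).sum()) if len(imb_df) else 0
        )

        signal_of_variant = dict(zip(gwas["variant_id"], gwas["window_id"].astype(str)))
        hic_directions = {vid: d for vid, (_, d, _) in hic_res.items()}
        try:
            conc_p, n_conc, n_total = imb.concordance_test(
                atac_results,
                hic_directions,
                signal_of_variant,
                ppa_by_variant,
                q_threshold=config.imbalance_q,
            )
        except ValueError:
            conc_p, n_conc, n_total = float("nan"), 0, 0
        results["concordance"] = {"p": conc_p, "concordant": n_conc, "n": n_total}

    if "eqtl" in stages:
        meta = eqtl_mod.meta_analyze_frame(
            bundle.eqtl_study1,
            bundle.eqtl_study2,
            bundle.config.eqtl_n[0],
            bundle.config.eqtl_n[1],
            maf_min=config.maf_min,
        )
        emit_tsv("eqtl_meta", meta)

        class_cmp = eqtl_mod.class_eqtl_comparison(bundle.class_eqtl, seed=config.seed)
        results["class_eqtl"] = {
            "medians": class_cmp["medians"],
            "tests": class_cmp["tests"],
        }

        eqtl_p = {(r.variant_id, r.gene_id): r.p_meta for r in meta.itertuples()}
        containing = _segment_lookup(bundle.segments)
        coloc_cfg = eqtl_mod.ColocConfig(
            config.coloc_p1, config.coloc_p2, config.coloc_p12
        )
        table_rows = []
        for w in bundle.truth.signal_windows:
            mask = (gwas["window_id"] == w).to_numpy()
            sub = gwas[mask]
            enh_variants = []
            for r in sub.itertuples():
                seg = containing(r.chrom, r.pos)
                if seg is not None and seg.state == "EnhA1":
                    enh_variants.append((r.variant_id, seg))
            if not enh_variants:
                continue
            # the element carried by a variant is its containing enhancer segment
            elements = [seg for _, seg in enh_variants]
            candidates = assign_signal_targets(
                elements, bundle.promoters, merged or [], flank=config.target_flank
            )
            if not candidates:
                continue
            by_ppa = sorted(
                {v for v, _ in enh_variants},
                key=lambda v: -ppa_by_variant.get(v, 0.0),
            )
            test = eqtl_mod.signal_eqtl_test(by_ppa, sorted(candidates), eqtl_p)
            if not test["tested"]:
                continue
            for gene, info in test["genes"].items():
                shared = None
                if info["significant"]:
                    sub_meta = meta[meta["gene_id"] == gene].set_index("variant_id")
                    common = [v for v in sub["variant_id"] if v in sub_meta.index]
                    if len(common) >= 2:
                        sub_idx = sub.set_index("variant_id")
                        t2d_log_abf = fm.wakefield_log_abf(
                            sub_idx.loc[common, "beta"].to_numpy(),
                            sub_idx.loc[common, "se"].to_numpy(),
                            config.prior_variance,
                        )
                        n_eff = sum(bundle.config.eqtl_n)
                        se_e = 1 / np.sqrt(n_eff)
                        z_e = sub_meta.loc[common, "z_meta"].to_numpy()
                        eqtl_log_abf = fm.wakefield_log_abf(
                            z_e * se_e,
                            np.full(len(common), se_e),
                            config.eqtl_prior_variance,
                        )
                        cres = eqtl_mod.coloc(t2d_log_abf, eqtl_log_abf, coloc_cfg)
                        shared = bool(cres.shared)
                table_rows.append(
                    {
                        "window_id": w,
                        "n_candidates": len(candidates),
                        "enhancer_variant": test["variant"],
                        "gene_id": gene,
                        "eqtl_p": info["p"],
                        "eqtl_p_corrected": info["p_corrected"],
                        "significant": info["significant"],
                        "shared_causal": shared,
                    }
                )
        target_table = pd.DataFrame(table_rows)
        emit_tsv("target_genes", target_table)
        results["target_genes"] = target_table

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": sorted(stages),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
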