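"""Synthetic-data generation with known ground truth for every pipeline
stage.

The generator emulates the statistical structure the analysis assumes:

* a chromatin-state segmentation with configurable state proportions, and
  accessible sites split along it;
* multi-resolution, multi-sample chromatin-loop calls with anchor jitter
  (to exercise merging) and a configurable preference for loops that
  connect active enhancers to gene promoters;
* GWAS summary statistics organised into windows, where a window contains
  a causal variant with known probability and the causal variant falls in
  annotated sequence with probability proportional to
  ``exp(true ln-enrichment)``;
* per-sample allele counts at heterozygous variants with a configurable
  allelic ratio for truly imbalanced variants;
* two-study eQTL summary statistics with shared or distinct causal
  variants per signal, and cross-tissue expression matrices in which the
  islet column's relative expression scales with enhancer-loop count.

All draws flow from one master seed through named substreams, so the same
configuration always produces byte-identical files. Effect sizes, sample
counts and noise levels default to the scale of real islet studies
(23 accessibility samples, 3 conformation samples, eQTL studies of 118 and
112 samples, 54 tissues, enhancer ln-enrichment 3.9, islet expression slope
0.14 per loop).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotatedSite,
    GeneModel,
    GenomicInterval,
    Tad,
    split_sites_by_state,
)
from .loops import Loop
from .targets import PromoterRegion, promoter_regions

DEFAULT_STATE_PROPORTIONS: dict[str, float] = {
    "Quies/low": 0.60,
    "Txn": 0.08,
    "EnhWk": 0.07,
    "EnhA1": 0.06,
    "TssA": 0.05,
    "TssFlnk": 0.05,
    "CTCF": 0.05,
    "EnhA2": 0.04,
}

#: Annotation columns used for GWAS variants (segmentation states minus the
#: quiescent catch-all).
ANNOTATION_COLUMNS = ("EnhA1", "EnhA2", "EnhWk", "TssA", "TssFlnk", "CTCF", "Txn")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the conditions the pipeline is designed for; see the
    methods note for the reasoning behind each.
    """

    seed: int
    # genome
    n_chromosomes: int = 4
    chrom_length: int = 30_000_000
    mean_segment_length: int = 20_000
    state_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROPORTIONS)
    )
    n_sites: int = 3000
    n_genes: int = 1200
    # loops
    n_loops: int = 600
    loop_span_log_mu: float = float(np.log(255_000))
    loop_span_log_sigma: float = 1.067  # ~10% of spans exceed 1 Mb
    ep_loop_enrichment: float = 3.0
    sample_presence: float = 0.7
    anchor_jitter: int = 8000
    # GWAS / fine-mapping
    n_signals: int = 50
    n_null_windows: int = 150
    variants_per_signal: int = 50
    signal_span: int = 1_000_000
    true_ln_enrichment: dict[str, float] = field(
        default_factory=lambda: {"EnhA1": 3.9}
    )
    effect_sd: float = 0.2  # SD of the causal log-odds effect (= sqrt(W))
    effect_min_frac: float = 0.5  # causal |beta| conditioned above this * SD
    gwas_se: float = 0.05
    # allelic imbalance
    n_samples_atac: int = 23
    n_samples_hic: int = 3
    allelic_ratio: float = 0.65
    atac_coverage_mean: float = 50.0
    hic_coverage_mean: float = 10.0
    het_rate: float = 1.0
    # eQTL / colocalization
    eqtl_n: tuple[int, int] = (118, 112)
    eqtl_effect_sd: float = 0.45  # standardized effect of a true eQTL
    coloc_lead_z: float = 6.0
    shared_fraction: float = 0.5
    # expression
    expression_loop_slope: float = 0.14
    expression_absolute_coupling: float = 1.5
    tissue_count: int = 54
    n_islet_rna_samples: int = 6
    # glycemic phenotype coupling
    secretion_rate_enhancer: float = 0.55
    secretion_rate_other: float = 0.17

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_sites",
            "n_genes",
            "n_loops",
            "n_signals",
            "variants_per_signal",
            "n_samples_atac",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_chromosomes", "chrom_length") and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("state proportions must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        digest = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng([self.seed, digest])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    causal_variant_by_window: dict[int, str | None]
    signal_windows: list[int]
    enhancer_targets: dict[str, list[str]]  # gene -> enhancer element keys
    imbalanced_variants: dict[str, float]  # variant -> allelic ratio
    coloc_shared_by_signal: dict[int, bool]
    secretion_associated: dict[int, bool]
    eqtl_gene_by_signal: dict[int, str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Genome


def generate_segments(config: SimulationConfig) -> list[AnnotatedSite]:
    rng = config.rng("segments")
    states = list(config.state_proportions)
    probs = np.array([config.state_proportions[s] for s in states])
    segments: list[AnnotatedSite] = []
    for chrom in config.chrom_names:
        pos = 0
        while pos < config.chrom_length:
            length = max(1000, int(rng.exponential(config.mean_segment_length)))
            end = min(config.chrom_length, pos + length)
            state = states[rng.choice(len(states), p=probs)]
            segments.append(AnnotatedSite(GenomicInterval(chrom, pos, end), state))
            pos = end
    return segments


def generate_sites(
    config: SimulationConfig, segments: Sequence[AnnotatedSite]
) -> list[AnnotatedSite]:
    """Accessible sites placed uniformly and split along the segmentation."""
    rng = config.rng("sites")
    raw: list[GenomicInterval] = []
    for _ in range(config.n_sites):
        chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
        length = int(rng.integers(200, 1500))
        start = int(rng.integers(0, config.chrom_length - length))
        raw.append(GenomicInterval(chrom, start, start + length))
    support = rng.integers(1, config.n_samples_atac + 1, size=len(raw))
    out: list[AnnotatedSite] = []
    for sup in np.unique(support):
        group = [iv for iv, s in zip(raw, support) if s == sup]
        out.extend(split_sites_by_state(group, segments, support=int(sup)))
    return out


def generate_genes(
    config: SimulationConfig, sites: Sequence[AnnotatedSite] | None = None
) -> list[GeneModel]:
    """Gene models; when accessible sites are supplied, a fraction of TSSs
    (60%) are placed at active-promoter (TssA) site elements, mirroring the
    co-occurrence of promoter chromatin states with transcription starts."""
    rng = config.rng("genes")
    genes = []
    biotypes = np.array(["protein_coding", "lncRNA", "other"])
    probs = np.array([0.85, 0.10, 0.05])
    tss_sites = (
        [s for s in sites if s.state == "TssA"] if sites is not None else []
    )
    for i in range(config.n_genes):
        if tss_sites and rng.random() < 0.6:
            s = tss_sites[rng.integers(len(tss_sites))]
            chrom = s.interval.chrom
            tss = int(s.interval.midpoint)
        else:
            chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
            tss = int(rng.integers(10_000, config.chrom_length - 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = str(biotypes[rng.choice(3, p=probs)])
        genes.append(GeneModel(f"GENE{i:05d}", chrom, tss, strand, biotype))
    return genes


def generate_tads(config: SimulationConfig) -> list[Tad]:
    rng = config.rng("tads")
    tads = []
    for chrom in config.chrom_names:
        pos = 0
        while pos < config.chrom_length - 500_000:
            span = int(rng.integers(400_000, 1_200_000))
            end = min(config.chrom_length, pos + span)
            tads.append(Tad(GenomicInterval(chrom, pos, end)))
            pos = end + int(rng.integers(0, 50_000))
    return tads


# ---------------------------------------------------------------------------
# Loops


def _site_midpoints_by_state(
    sites: Sequence[AnnotatedSite], state: str
) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[float]] = {}
    for s in sites:
        if s.state == state:
            by_chrom.setdefault(s.interval.chrom, []).append(s.interval.midpoint)
    return {c: np.array(v) for c, v in by_chrom.items()}


def generate_loops(
    config: SimulationConfig,
    sites: Sequence[AnnotatedSite],
    promoters: Sequence[PromoterRegion],
) -> tuple[dict[str, list[Loop]], list[tuple[GenomicInterval, str]]]:
    """Multi-sample, multi-resolution loop sets plus the true
    enhancer-promoter pairings.

    Base loops are drawn with anchor-midpoint spans log-normal around
    255 kb. With weight ``ep_loop_enrichment`` a base loop is
    enhancer-promoter directed: one anchor centred on an active-enhancer
    element, the other on a gene promoter. Each base loop is re-emitted in
    the pooled set and, with probability ``sample_presence``, in each of
    three per-sample sets with anchor jitter and a possibly coarser
    resolution, so unification must collapse the duplicates.
    """
    rng = config.rng("loops")
    enh_mids = _site_midpoints_by_state(sites, "EnhA1")
    prom_by_chrom: dict[str, list[PromoterRegion]] = {}
    for p in promoters:
        prom_by_chrom.setdefault(p.interval.chrom, []).append(p)

    ep_weight = max(1.0, config.ep_loop_enrichment)
    base: list[tuple[str, float, float]] = []  # chrom, mid1, mid2
    true_pairs: list[tuple[GenomicInterval, str]] = []
    attempts = 0
    while len(base) < config.n_loops and attempts < config.n_loops * 200:
        attempts += 1
        chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
        span = float(
            np.clip(
                rng.lognormal(config.loop_span_log_mu, config.loop_span_log_sigma),
                40_000,
                config.chrom_length / 3,
            )
        )
        ep_directed = (
            config.ep_loop_enrichment > 1.0
            and chrom in enh_mids
            and prom_by_chrom.get(chrom)
            and rng.random() < (ep_weight - 1) / ep_weight
        )
        if ep_directed:
            mids = enh_mids[chrom]
            m1 = float(mids[rng.integers(len(mids))])
            # aim for a promoter near the drawn span so enhancer-promoter
            # loops keep the configured span distribution
            target = m1 + (span if rng.random() < 0.5 else -span)
            proms = [
                p
                for p in prom_by_chrom[chrom]
                if 40_000 < abs(p.interval.midpoint - m1)
                and abs(p.interval.midpoint - target) < 150_000
            ]
            if not proms:
                continue
            prom = min(proms, key=lambda p: abs(p.interval.midpoint - target))
            m2 = prom.interval.midpoint
            if m1 > m2:
                m1, m2 = m2, m1
            base.append((chrom, m1, m2))
            enh_iv = GenomicInterval(chrom, int(m1) - 500, int(m1) + 500)
            true_pairs.append((enh_iv, prom.gene_id))
        else:
            m1 = float(rng.uniform(span, config.chrom_length - span))
            m2 = m1 + span
            if m2 >= config.chrom_length - 25_000 or m1 < 25_000:
                continue
            base.append((chrom, m1, m2))

    depths = {"pooled": 1.2e9, "s1": 4.5e8, "s2": 4.0e8, "s3": 3.5e8}
    loop_sets: dict[str, list[Loop]] = {k: [] for k in depths}
    resolutions = np.array([5000, 10000, 25000])
    for chrom, m1, m2 in base:
        for source, depth in depths.items():
            if source != "pooled" and rng.random() > config.sample_presence:
                continue
            # the pooled map is the unjittered reference call; per-sample
            # calls are jittered and possibly coarser to exercise merging
            if source == "pooled":
                res, j1, j2 = 5000, 0.0, 0.0
            else:
                res = int(resolutions[rng.integers(3)])
                j1 = float(rng.uniform(-config.anchor_jitter, config.anchor_jitter))
                j2 = float(rng.uniform(-config.anchor_jitter, config.anchor_jitter))
            a1m = max(res, min(m1 + j1, config.chrom_length - res))
            a2m = max(res, min(m2 + j2, config.chrom_length - res))
            if a2m - a1m < res:
                continue
            a1 = GenomicInterval(chrom, int(a1m - res / 2), int(a1m - res / 2) + res)
            a2 = GenomicInterval(chrom, int(a2m - res / 2), int(a2m - res / 2) + res)
            loop_sets[source].append(Loop(a1, a2, res, source, depth))
    return loop_sets, true_pairs


# ---------------------------------------------------------------------------
# GWAS summary statistics


def _annotate_positions(
    chroms: Sequence[str],
    positions: np.ndarray,
    segments: Sequence[AnnotatedSite],
) -> np.ndarray:
    """Binary (n, len(ANNOTATION_COLUMNS)) overlap matrix against the state
    segmentation."""
    seg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    by_chrom: dict[str, list[AnnotatedSite]] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.interval.start)
        seg_by_chrom[chrom] = (
            np.array([s.interval.start for s in segs]),
            np.array([s.interval.end for s in segs]),
            [s.state for s in segs],
        )
    col_idx = {a: j for j, a in enumerate(ANNOTATION_COLUMNS)}
    X = np.zeros((len(positions), len(ANNOTATION_COLUMNS)))
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        entry = seg_by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, states = entry
        k = int(np.searchsorted(ends, pos, side="right"))
        if k < len(starts) and starts[k] <= pos < ends[k]:
            state = states[k]
            if state in col_idx:
                X[i, col_idx[state]] = 1.0
    return X


def generate_gwas(
    config: SimulationConfig, segments: Sequence[AnnotatedSite]
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """GWAS summary statistics over signal and null windows.

    Each of ``n_signals`` windows carries one causal variant chosen among
    the window's variants with probability proportional to
    ``exp(true ln-enrichment . x_v)``; the observed effect is the true
    effect plus N(0, se^2) noise. ``n_null_windows`` windows contain only
    null variants. Variants are annotated by overlap with the chromatin
    state segmentation.

    Returns the summary table, the annotation matrix (columns
    ``ANNOTATION_COLUMNS``) and a partially filled ground truth.
    """
    rng = config.rng("gwas")
    n_windows = config.n_signals + config.n_null_windows
    m = config.variants_per_signal
    rows = []
    all_chroms: list[str] = []
    all_pos: list[int] = []
    for w in range(n_windows):
        chrom = config.chrom_names[rng.integers(config.n_chromosomes)]
        lo = int(rng.integers(0, config.chrom_length - config.signal_span))
        pos = np.sort(rng.integers(lo, lo + config.signal_span, size=m))
        all_chroms.extend([chrom] * m)
        all_pos.extend(int(p) for p in pos)
        for i, p in enumerate(pos):
            rows.append(
                {
                    "variant_id": f"w{w:04d}_v{i:03d}",
                    "chrom": chrom,
                    "pos": int(p),
                    "window_id": w,
                    "is_signal_window": w < config.n_signals,
                }
            )
    df = pd.DataFrame(rows)
    X = _annotate_positions(all_chroms, np.array(all_pos), segments)

    gamma = np.array(
        [config.true_ln_enrichment.get(a, 0.0) for a in ANNOTATION_COLUMNS]
    )
    beta = np.zeros(len(df))
    causal: dict[int, str | None] = {}
    min_effect = config.effect_min_frac * config.effect_sd
    for w in range(n_windows):
        idx = np.flatnonzero(df["window_id"].to_numpy() == w)
        if w >= config.n_signals:
            causal[w] = None
            continue
        weights = np.exp(X[idx] @ gamma)
        weights /= weights.sum()
        pick = idx[rng.choice(len(idx), p=weights)]
        b = 0.0
        while abs(b) < min_effect:
            b = rng.normal(0.0, config.effect_sd)
        beta[pick] = b
        causal[w] = df["variant_id"].iloc[pick]
    df["beta"] = beta + rng.normal(0.0, config.gwas_se, size=len(df))
    df["se"] = config.gwas_se
    df["maf"] = rng.uniform(0.05, 0.5, size=len(df))

    truth = GroundTruth(
        causal_variant_by_window=causal,
        signal_windows=list(range(config.n_signals)),
        enhancer_targets={},
        imbalanced_variants={},
        coloc_shared_by_signal={},
        secretion_associated={},
        eqtl_gene_by_signal={},
    )
    return df, X, truth


# ---------------------------------------------------------------------------
# Allele counts


def generate_allele_counts(
    config: SimulationConfig,
    variant_ids: Sequence[str],
    imbalanced: Mapping[str, float],
    assay: str = "ATAC",
) -> pd.DataFrame:
    """Per-sample ref/alt read-count table.

    Imbalanced variants draw alt counts at their configured allelic ratio;
    all others at 0.5. Per-sample library depths are log-normal; per
    variant-sample coverage is Poisson at the assay's mean.
    """
    rng = config.rng(f"counts_{assay}")
    n_samples = config.n_samples_atac if assay == "ATAC" else config.n_samples_hic
    cov_mean = (
        config.atac_coverage_mean if assay == "ATAC" else config.hic_coverage_mean
    )
    depths = rng.lognormal(np.log(3e7), 0.3, size=n_samples)
    rows = []
    for vid in variant_ids:
        ratio = imbalanced.get(vid, 0.5)
        for s in range(n_samples):
            if rng.random() > config.het_rate:
                continue
            cov = int(rng.poisson(cov_mean))
            if cov == 0:
                continue
            alt = int(rng.binomial(cov, ratio))
            rows.append(
                {
                    "variant_id": vid,
                    "sample_id": f"{assay.lower()}_{s:02d}",
                    "ref_count": cov - alt,
                    "alt_count": alt,
                    "sample_depth": float(depths[s]),
                    "assay": assay,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eQTL and colocalization


def generate_coloc_signal(
    config: SimulationConfig,
    rng: np.random.Generator,
    shared: bool,
    n_variants: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """One signal's per-variant (beta, se) for the disease trait and
    Z-scores for the eQTL trait, with a shared or distinct causal variant.

    Disease lead variants carry |z| around ``coloc_lead_z``, truncated below
    at 5.45 (the genome-wide significance threshold) because only
    genome-wide-significant risk signals enter colocalization; the eQTL
    causal effect is ``eqtl_effect_sd`` in standardized units across the
    two study sizes.
    Returns (t2d_beta, t2d_se, eqtl_z_meta, causal_t2d_idx, causal_eqtl_idx).
    """
    c1 = int(rng.integers(n_variants))
    c2 = c1 if shared else int((c1 + 1 + rng.integers(n_variants - 1)) % n_variants)
    z_t2d = rng.normal(0, 1, n_variants)
    lead = rng.normal(config.coloc_lead_z, 1)
    while lead < 5.45:
        lead = rng.normal(config.coloc_lead_z, 1)
    z_t2d[c1] += rng.choice([-1, 1]) * lead
    t2d_se = np.full(n_variants, config.gwas_se)
    t2d_beta = z_t2d * t2d_se

    n1, n2 = config.eqtl_n
    b = rng.choice([-1, 1]) * config.eqtl_effect_sd
    z1 = rng.normal(0, 1, n_variants)
    z2 = rng.normal(0, 1, n_variants)
    z1[c2] += b * np.sqrt(n1)
    z2[c2] += b * np.sqrt(n2)
    w1, w2 = np.sqrt(n1), np.sqrt(n2)
    z_meta = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
    return t2d_beta, t2d_se, z_meta, c1, c2


def generate_eqtl_studies(
    config: SimulationConfig,
    gwas: pd.DataFrame,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-study eQTL summary tables covering every signal window.

    Per signal one target gene (the nearest gene) receives a true eQTL
    whose causal variant either coincides with the disease causal variant
    (shared) or is a different variant at the signal (distinct), assigned
    with probability ``shared_fraction``. All other variant-gene pairs are
    null. Fills ``truth.coloc_shared_by_signal`` and
    ``truth.eqtl_gene_by_signal``.
    """
    rng = config.rng("eqtl")
    n1, n2 = config.eqtl_n
    rows1, rows2 = [], []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for w in truth.signal_windows:
        sub = gwas[gwas["window_id"] == w]
        causal_vid = truth.causal_variant_by_window.get(w)
        if causal_vid is None:
            continue
        chrom = sub["chrom"].iloc[0]
        center = int(sub["pos"].median())
        cand = genes_by_chrom.get(chrom, [])
        if not cand:
            continue
        gene = min(cand, key=lambda g: abs(g.tss - center))
        shared = bool(rng.random() < config.shared_fraction)
        truth.coloc_shared_by_signal[w] = shared
        truth.eqtl_gene_by_signal[w] = gene.gene_id
        vids = sub["variant_id"].tolist()
        if shared:
            eqtl_causal = causal_vid
        else:
            others = [v for v in vids if v != causal_vid]
            eqtl_causal = others[rng.integers(len(others))]
        b = rng.choice([-1, 1]) * config.eqtl_effect_sd
        for vid, maf, pos in zip(vids, sub["maf"], sub["pos"]):
            mu = b if vid == eqtl_causal else 0.0
            z1 = rng.normal(mu * np.sqrt(n1), 1)
            z2 = rng.normal(mu * np.sqrt(n2), 1)
            dist = abs(int(pos) - gene.tss)
            rows1.append(
                {
                    "variant_id": vid,
                    "gene_id": gene.gene_id,
                    "z": z1,
                    "maf": maf,
                    "n": n1,
                    "distance": dist,
                }
            )
            rows2.append(
                {
                    "variant_id": vid,
                    "gene_id": gene.gene_id,
                    "z": z2,
                    "maf": maf,
                    "n": n2,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows1), pd.DataFrame(rows2)


def generate_class_eqtl(
    config: SimulationConfig,
    n_per_class: int = 500,
    loop_effect: float = 1.5,
) -> pd.DataFrame:
    """Association table for the regulatory-class eQTL comparison.

    Looped enhancer-gene pairs receive a mean |z| boost of ``loop_effect``
    over no-loop pairs; looped pairs also sit at larger distances, which the
    distance-matched control must correct for.
    """
    rng = config.rng("class_eqtl")
    rows = []
    specs = {
        "TssA_proximal": (2.0, 10_000),
        "Enh_proximal": (1.5, 15_000),
        "Enh_loop": (loop_effect, 200_000),
        "Enh_no_loop": (0.0, 80_000),
    }
    for cls, (mu, dist_scale) in specs.items():
        z = rng.normal(0, 1, n_per_class) + rng.choice([-1, 1], n_per_class) * mu
        dist = rng.exponential(dist_scale, n_per_class).astype(int)
        from scipy import stats as _st

        p = 2 * _st.norm.sf(np.abs(z))
        for i in range(n_per_class):
            rows.append(
                {
                    "variant_id": f"{cls}_{i:04d}",
                    "gene_id": f"G_{cls}_{i:04d}",
                    "p_meta": float(p[i]),
                    "distance": int(dist[i]),
                    "eqtl_class": cls,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    config: SimulationConfig,
    loop_counts: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Islet RPKM matrix and cross-tissue TPM matrix.

    Cross-tissue log-expression is gene baseline plus unit-variance tissue
    noise; the islet column additionally gains
    ``expression_loop_slope * (loop count - mean)``, so after
    quantile-normalisation, log transform and per-gene standardisation the
    islet Z-score regresses on loop count with the configured slope.
    Looped genes are also more highly expressed in absolute terms: the
    baseline gains ``expression_absolute_coupling * log1p(loop count)``
    (shared across tissues, so it cancels out of the Z-scores), which
    drives the expressed-versus-looped contingency and the rank
    correlation between islet TPM and loop degree.
    """
    rng = config.rng("expression")
    genes = loop_counts.index
    n = len(genes)
    baseline = rng.normal(2.0, 2.0, n)
    baseline = baseline + config.expression_absolute_coupling * np.log1p(
        loop_counts.to_numpy(dtype=float)
    )
    tissues = ["Islets"] + [f"tissue_{t:02d}" for t in range(1, config.tissue_count)]
    log_expr = baseline[:, None] + rng.normal(0, 1, (n, config.tissue_count))
    centred = loop_counts.to_numpy(dtype=float)
    centred = centred - centred.mean()
    log_expr[:, 0] += config.expression_loop_slope * centred
    tpm_raw = np.expm1(np.clip(log_expr, 0, None))
    tissue_tpm = pd.DataFrame(tpm_raw, index=genes, columns=tissues)

    samples = [f"islet_{s}" for s in range(config.n_islet_rna_samples)]
    islet_log = log_expr[:, [0]] + rng.normal(0, 0.3, (n, len(samples)))
    rpkm = pd.DataFrame(np.expm1(np.clip(islet_log, 0, None)), index=genes, columns=samples)
    return rpkm, tissue_tpm


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    segments: list[AnnotatedSite]
    sites: list[AnnotatedSite]
    genes: list[GeneModel]
    tads: list[Tad]
    promoters: list[PromoterRegion]
    loop_sets: dict[str, list[Loop]]
    gwas: pd.DataFrame
    annotations: np.ndarray
    atac_counts: pd.DataFrame
    hic_counts: pd.DataFrame
    eqtl_study1: pd.DataFrame
    eqtl_study2: pd.DataFrame
    class_eqtl: pd.DataFrame
    islet_rpkm: pd.DataFrame
    tissue_tpm: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full synthetic input bundle with its ground truth."""
    segments = generate_segments(config)
    sites = generate_sites(config, segments)
    genes = generate_genes(config, sites)
    tads = generate_tads(config)
    promoters = promoter_regions(
        [g for g in genes if g.biotype in ("protein_coding", "lncRNA")]
    )
    loop_sets, true_pairs = generate_loops(config, sites, promoters)
    gwas, X, truth = generate_gwas(config, segments)

    targets: dict[str, list[str]] = {}
    for enh_iv, gene_id in true_pairs:
        key = f"{enh_iv.chrom}:{enh_iv.start}-{enh_iv.end}"
        targets.setdefault(gene_id, []).append(key)
    truth.enhancer_targets = targets

    # imbalance truth: enhancer-annotated variants at signal windows are the
    # tested set; the causal ones among them are imbalanced
    rng = config.rng("imbalance_truth")
    enh_col = ANNOTATION_COLUMNS.index("EnhA1")
    enh_mask = X[:, enh_col] > 0
    tested = gwas.loc[
        enh_mask & gwas["is_signal_window"].to_numpy(), "variant_id"
    ].tolist()
    causal_set = {v for v in truth.causal_variant_by_window.values() if v}
    imbalanced = {}
    for vid in tested:
        if vid in causal_set:
            ratio = config.allelic_ratio
            if rng.random() < 0.5:
                ratio = 1 - ratio
            imbalanced[vid] = ratio
    truth.imbalanced_variants = imbalanced

    atac = generate_allele_counts(config, tested, imbalanced, assay="ATAC")
    hic = generate_allele_counts(config, tested, imbalanced, assay="HiC")

    eqtl1, eqtl2 = generate_eqtl_studies(config, gwas, truth, genes)
    class_eqtl = generate_class_eqtl(config)

    # expression coupled to true enhancer-loop degree
    loop_counts = pd.Series(
        {g.gene_id: len(targets.get(g.gene_id, [])) for g in genes}
    ).sort_index()
    rpkm, tissue_tpm = generate_expression(config, loop_counts)

    # glycemic phenotype flags coupled to the causal variant's annotation
    rng_g = config.rng("glycemic")
    for w in truth.signal_windows:
        vid = truth.causal_variant_by_window.get(w)
        is_enh = False
        if vid is not None:
            i = gwas.index[gwas["variant_id"] == vid][0]
            is_enh = bool(enh_mask[i])
        rate = (
            config.secretion_rate_enhancer if is_enh else config.secretion_rate_other
        )
        truth.secretion_associated[w] = bool(rng_g.random() < rate)

    return SyntheticBundle(
        config=config,
        segments=segments,
        sites=sites,
        genes=genes,
        tads=tads,
        promoters=promoters,
        loop_sets=loop_sets,
        gwas=gwas,
        annotations=X,
        atac_counts=atac,
        hic_counts=hic,
        eqtl_study1=eqtl1,
        eqtl_study2=eqtl2,
        class_eqtl=class_eqtl,
        islet_rpkm=rpkm,
        tissue_tpm=tissue_tpm,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component as plain text; returns name -> path."""
    from .core import write_bed, write_gene_table, write_tads
    from .loops import write_bedpe

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_bed(bundle.segments, _p("segments.bed"))
    write_bed(bundle.sites, _p("sites.bed"))
    write_gene_table(bundle.genes, _p("genes.tsv"))
    write_tads(bundle.tads, _p("tads.bed"))
    for source, loops_ in bundle.loop_sets.items():
        write_bedpe(loops_, _p(f"loops_{source}.bedpe"))
    gwas = bundle.gwas.copy()
    for j, a in enumerate(ANNOTATION_COLUMNS):
        gwas[a] = bundle.annotations[:, j].astype(int)
    gwas.to_csv(_p("gwas.tsv"), sep="\t", index=False)
    bundle.atac_counts.to_csv(_p("atac_counts.tsv"), sep="\t", index=False)
    bundle.hic_counts.to_csv(_p("hic_counts.tsv"), sep="\t", index=False)
    bundle.eqtl_study1.to_csv(_p("eqtl_study1.tsv"), sep="\t", index=False)
    bundle.eqtl_study2.to_csv(_p("eqtl_study2.tsv"), sep="\t", index=False)
    bundle.class_eqtl.to_csv(_p("class_eqtl.tsv"), sep="\t", index=False)
    bundle.islet_rpkm.to_csv(_p("islet_rpkm.tsv"), sep="\t")
    bundle.tissue_tpm.to_csv(_p("tissue_tpm.tsv"), sep="\t")
    bundle.truth.to_json(_p("ground_truth.json"))
    return paths
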