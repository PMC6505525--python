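"""eQTL meta-analysis, regulatory-class comparisons, per-signal target-gene
testing, and Bayesian colocalization.

Two islet eQTL studies are combined with sample-size-weighted Z-score
meta-analysis, retaining only variant-gene pairs tested in both studies at
MAF > 0.01. Associations are LD-pruned (greedy, r^2 > 0.5 to a more
significant variant), grouped into regulatory-element classes, and compared
with rank-sum tests including a distance-matched control. Per GWAS signal,
the most probable enhancer variant is tested against each candidate target
gene with Bonferroni correction, and significant genes are checked for a
shared causal variant with the disease signal by enumerating single- and
two-variant causal configurations under stated priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class ColocConfig:
    """Priors of the colocalization model: p1 (causal for the disease),
    p2 (causal for expression), p12 (causal for both)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("require 0 < p12 <= min(p1, p2)")


@dataclass(frozen=True)
class ColocResult:
    """Posteriors over the five colocalization hypotheses.

    H0 no causal variant; H1 disease only; H2 eQTL only; H3 two distinct
    causal variants; H4 one shared causal variant.
    """

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    @property
    def shared(self) -> bool:
        return self.pp4 > self.pp3

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def meta_analyze(
    z_per_study: Sequence[float], n_per_study: Sequence[float]
) -> tuple[float, float]:
    """Sample-size-weighted Z meta-analysis.

    w_i = sqrt(n_i); z_meta = sum(w z) / sqrt(sum(w^2)); two-sided normal p.
    """
    z = np.asarray(z_per_study, dtype=float)
    n = np.asarray(n_per_study, dtype=float)
    if len(z) != len(n) or len(z) == 0:
        raise ValueError("need aligned, non-empty study vectors")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n)
    z_meta = float((w * z).sum() / np.sqrt((w**2).sum()))
    p = float(2 * stats.norm.sf(abs(z_meta)))
    return z_meta, p


def meta_analyze_frame(
    study_a: pd.DataFrame, study_b: pd.DataFrame, n_a: int, n_b: int, maf_min: float = 0.01
) -> pd.DataFrame:
    """Meta-analyze two per-study tables with columns (variant_id, gene_id,
    z[, maf]). Only pairs present in both studies and passing the MAF filter
    are retained."""
    merged = study_a.merge(
        study_b, on=["variant_id", "gene_id"], suffixes=("_a", "_b")
    )
    if "maf" in study_a.columns:
        merged = merged[merged["maf_a"] > maf_min] if "maf_a" in merged.columns else merged
    elif "maf" in merged.columns:
        merged = merged[merged["maf"] > maf_min]
    wa, wb = np.sqrt(n_a), np.sqrt(n_b)
    z_meta = (wa * merged["z_a"] + wb * merged["z_b"]) / np.sqrt(wa**2 + wb**2)
    out = merged[["variant_id", "gene_id"]].copy()
    out["z_meta"] = z_meta
    out["p_meta"] = 2 * stats.norm.sf(np.abs(z_meta))
    return out.reset_index(drop=True)


def ld_prune(
    associations: pd.DataFrame,
    ld_lookup: Mapping[frozenset, float],
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Greedy LD pruning of an association table with columns
    (variant_id, p): sort by p (ties broken by variant id), keep the best
    remaining variant and drop all variants with r^2 above the threshold to
    any kept one. Deterministic and independent of input order."""
    df = associations.sort_values(["p", "variant_id"], kind="mergesort")
    kept: list[str] = []
    kept_set: set[str] = set()
    dropped: set[str] = set()
    for vid in df["variant_id"].drop_duplicates():
        if vid in dropped or vid in kept_set:
            continue
        kept.append(vid)
        kept_set.add(vid)
        for other in df["variant_id"].drop_duplicates():
            if other in kept_set or other in dropped:
                continue
            r2 = ld_lookup.get(frozenset((vid, other)), 0.0)
            if r2 > r2_threshold:
                dropped.add(other)
    return associations[associations["variant_id"].isin(kept_set)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Regulatory-class eQTL comparison


CLASS_ORDER = (
    "TssA_proximal",
    "Enh_proximal",
    "Enh_loop",
    "Enh_no_loop",
    "Enh_no_loop_matched",
)


def match_on_distance(
    target_distances: np.ndarray,
    pool_distances: np.ndarray,
    rng: np.random.Generator,
    n_bins: int = 20,
) -> np.ndarray:
    """Indices into the pool matching the target distance distribution.

    The target distribution is cut into ``n_bins`` quantile bins; from each
    bin's pool counterpart, as many pool members are drawn (without
    replacement) as the target has in that bin, capped at pool availability.
    """
    target = np.asarray(target_distances, dtype=float)
    pool = np.asarray(pool_distances, dtype=float)
    edges = np.quantile(target, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    chosen: list[int] = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        n_target = int(((target >= lo) & (target < hi)).sum())
        pool_idx = np.flatnonzero((pool >= lo) & (pool < hi))
        if n_target == 0 or len(pool_idx) == 0:
            continue
        take = min(n_target, len(pool_idx))
        chosen.extend(rng.choice(pool_idx, size=take, replace=False).tolist())
    return np.array(sorted(chosen), dtype=int)


def class_eqtl_comparison(
    associations: pd.DataFrame,
    min_class_size: int = 10,
    n_bins: int = 20,
    seed: int = 0,
) -> dict:
    """Compare eQTL strength across regulatory-element classes.

    ``associations`` must carry columns (variant_id, gene_id, p_meta,
    distance, eqtl_class) with classes from ``CLASS_ORDER`` (the matched
    control class is derived here, not supplied). Returns per-class median
    -log10(p), rank-sum p-values for loop vs no-loop and loop vs matched,
    and the matched control's indices.
    """
    rng = np.random.default_rng(seed)
    df = associations.copy()
    df["neglog10p"] = -np.log10(df["p_meta"].clip(lower=1e-300))
    out: dict = {"medians": {}, "tests": {}, "n": {}}
    groups = {c: df[df["eqtl_class"] == c] for c in df["eqtl_class"].unique()}

    loop = groups.get("Enh_loop", df.iloc[0:0])
    noloop = groups.get("Enh_no_loop", df.iloc[0:0])
    matched_idx = np.array([], dtype=int)
    if len(loop) >= min_class_size and len(noloop) >= min_class_size:
        matched_idx = match_on_distance(
            loop["distance"].to_numpy(),
            noloop["distance"].to_numpy(),
            rng,
            n_bins=n_bins,
        )
        matched = noloop.iloc[matched_idx]
        groups["Enh_no_loop_matched"] = matched

    for cls, g in groups.items():
        out["medians"][cls] = float(g["neglog10p"].median()) if len(g) else np.nan
        out["n"][cls] = int(len(g))

    def ranksum(a: pd.DataFrame, b: pd.DataFrame, label: str) -> None:
        if len(a) < min_class_size or len(b) < min_class_size:
            warnings.warn(f"comparison {label} skipped: class too small")
            return
        stat = stats.mannwhitneyu(
            a["neglog10p"], b["neglog10p"], alternative="two-sided"
        )
        out["tests"][label] = float(stat.pvalue)

    ranksum(loop, noloop, "loop_vs_no_loop")
    if "Enh_no_loop_matched" in groups:
        ranksum(loop, groups["Enh_no_loop_matched"], "loop_vs_matched")
    out["matched_indices"] = matched_idx
    return out


# ---------------------------------------------------------------------------
# Per-signal candidate-gene testing


def signal_eqtl_test(
    enhancer_variants_by_ppa: Sequence[str],
    candidate_genes: Sequence[str],
    eqtl_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict:
    """Test a signal's candidate target genes for eQTL association.

    The test variant is the highest-PPA enhancer variant present in the
    eQTL data (``enhancer_variants_by_ppa`` is PPA-descending); when the top
    variant is absent the next most probable one is used. Per-gene p-values
    are Bonferroni-corrected by the number of candidate genes; genes with
    corrected p < ``alpha`` are significant. A signal whose variants are all
    absent from the eQTL data is reported untested.
    """
    if not candidate_genes:
        raise ValueError("no candidate genes supplied")
    tested_variant = None
    for vid in enhancer_variants_by_ppa:
        if any((vid, g) in eqtl_p for g in candidate_genes):
            tested_variant = vid
            break
    if tested_variant is None:
        return {"tested": False, "variant": None, "genes": {}}
    n = len(candidate_genes)
    genes = {}
    for g in sorted(candidate_genes):
        p = eqtl_p.get((tested_variant, g))
        if p is None:
            continue
        corrected = min(1.0, p * n)
        genes[g] = {
            "p": float(p),
            "p_corrected": float(corrected),
            "significant": bool(corrected < alpha),
        }
    return {"tested": True, "variant": tested_variant, "genes": genes}


# ---------------------------------------------------------------------------
# Bayesian colocalization


def coloc(
    log_abf_trait1: np.ndarray,
    log_abf_trait2: np.ndarray,
    config: ColocConfig = ColocConfig(),
) -> ColocResult:
    """Colocalization of two traits at a signal from per-variant log ABFs.

    Enumerates causal configurations under a one-causal-variant-per-trait
    model: H1 mass p1 * sum(BF1); H2 p2 * sum(BF2); H3 p1 p2 *
    sum_{i != j} BF1_i BF2_j; H4 p12 * sum_i BF1_i BF2_i; H0 mass 1.
    All sums are computed in log space.
    """
    l1 = np.asarray(log_abf_trait1, dtype=float)
    l2 = np.asarray(log_abf_trait2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("both traits need the same variant universe")
    if len(l1) < 2:
        raise ValueError("colocalization needs >= 2 variants (H3 undefined)")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # log(sum_{i!=j} BF1_i BF2_j) = log(S1*S2 - S12)
    log_cross = s1 + s2
    diff = s12 - log_cross
    if diff >= 0:
        # all cross mass sits on the diagonal (single shared variant)
        log_h3_sum = -np.inf
    else:
        log_h3_sum = log_cross + np.log1p(-np.exp(diff))
    log_masses = np.array(
        [
            0.0,
            np.log(config.p1) + s1,
            np.log(config.p2) + s2,
            np.log(config.p1) + np.log(config.p2) + log_h3_sum,
            np.log(config.p12) + s12,
        ]
    )
    pp = np.exp(log_masses - logsumexp(log_masses))
    return ColocResult(*[float(x) for x in pp])
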