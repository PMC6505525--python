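"""Gene expression versus enhancer-loop degree.

Links the number of chromatin loops a gene's promoter makes with active
enhancers to the gene's absolute islet expression (TPM) and to its islet
expression relative to a panel of other tissues (cross-tissue Z-scores
after within-tissue quantile normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    se: float
    p: float
    n: int


def rpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Convert an RPKM genes x samples matrix to TPM.

    TPM_i = RPKM_i / sum_j(RPKM_j) * 1e6 within each sample column, so each
    column sums to 1e6. Raises on an all-zero column.
    """
    if (matrix < 0).any().any():
        raise ValueError("RPKM values must be non-negative")
    col_sums = matrix.sum(axis=0)
    if (col_sums == 0).any():
        bad = col_sums.index[col_sums == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    return matrix / col_sums * 1e6


def expression_loop_contingency(
    islet_tpm: pd.Series,
    loop_counts: pd.Series,
    ln_tpm_threshold: float = 1.0,
    yates: bool = False,
) -> tuple[np.ndarray, float, float]:
    """2x2 chi-square test: expressed-in-islets against has-enhancer-loop.

    A gene is expressed when ln(TPM) exceeds ``ln_tpm_threshold``; it is
    looped when it has at least one enhancer loop. Returns (table, chi2, p);
    the table rows are expressed/not, columns looped/not. Pearson chi-square
    without continuity correction by default (``yates`` switches it on).
    """
    genes = islet_tpm.index.intersection(loop_counts.index)
    tpm = islet_tpm.loc[genes]
    loops = loop_counts.loc[genes]
    expressed = np.log(tpm.where(tpm > 0, np.nan)) > ln_tpm_threshold
    expressed = expressed.fillna(False)
    looped = loops >= 1
    table = np.array(
        [
            [int((expressed & looped).sum()), int((expressed & ~looped).sum())],
            [int((~expressed & looped).sum()), int((~expressed & ~looped).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return table, float(chi2), float(p)


def loop_expression_spearman(
    values: pd.Series, loop_counts: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between per-gene expression values and enhancer
    loop counts (average-rank ties, two-sided p)."""
    genes = values.index.intersection(loop_counts.index)
    x = values.loc[genes].to_numpy(dtype=float)
    y = loop_counts.loc[genes].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 genes after filtering")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns to the mean empirical distribution.

    Each column's sorted values are replaced by the mean of the sorted
    values across all columns; ties within a column receive the mean of
    their target values (average-rank convention).
    """
    arr = matrix.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (target[lo] + target[hi]) / 2
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cross_tissue_zscores(tpm_by_tissue: pd.DataFrame) -> pd.DataFrame:
    """Tissue-relative expression Z-scores.

    Quantile-normalise expression within each tissue column, log-transform
    (natural log of value + 1, admitting zeros), then standardise each gene
    row by its mean and standard deviation across tissues. Genes constant
    across tissues get a row of zeros.
    """
    if tpm_by_tissue.shape[1] < 3:
        raise ValueError("need >= 3 tissues")
    qn = quantile_normalize(tpm_by_tissue)
    logged = np.log1p(qn)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    # rows constant up to floating-point noise get z = 0
    tol = 1e-9 * np.maximum(1.0, logged.abs().max(axis=1))
    z = logged.sub(mean, axis=0).div(sd.where(sd > tol, np.inf), axis=0)
    return z


def zscore_on_loopcount(
    z_for_tissue: pd.Series, loop_counts: pd.Series
) -> RegressionResult:
    """OLS of per-gene tissue Z-scores on enhancer loop number."""
    genes = z_for_tissue.index.intersection(loop_counts.index)
    y = z_for_tissue.loc[genes].to_numpy(dtype=float)
    x = loop_counts.loc[genes].to_numpy(dtype=float)
    if len(y) <= 2:
        raise ValueError("need more than 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("loop-count predictor has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=len(y),
    )


def loopcount_bins(loop_counts: pd.Series, top: int = 6) -> pd.Series:
    """Bin loop counts 0..top-1 with a final open-ended "top or more" bin,
    mirroring the grouping used for expression-by-degree summaries."""
    binned = loop_counts.clip(upper=top)
    return binned.astype(int)
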