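"""Bayesian fine-mapping of GWAS signals with functional-annotation priors.

The chain implemented here:

1. Per-variant approximate Bayes factors (ABF) from summary statistics,
   using Wakefield's asymptotic approximation with an N(0, W) prior on the
   log-odds effect.
2. A hierarchical enrichment model over non-overlapping genomic windows:
   each window contains a causal variant with probability ``logistic(kappa)``
   and, given one, the causal variant is multinomial with weights
   ``softmax(gamma . x_v)`` over the window's variants, where ``x_v`` is a
   binary annotation vector. The marginal likelihood of a window is
   ``(1 - Pi) + Pi * sum_v pi_v * ABF_v``. Enrichment parameters are fit by
   maximum likelihood with an optional ridge penalty selected by
   cross-validated likelihood, greedy forward selection and backward
   pruning, and profile-likelihood confidence intervals.
3. Per-signal functional priors proportional to ``exp(gamma . x_v)``,
   posterior probabilities of association (PPA), and 99% credible sets.
4. Signal clustering on cumulative PPA per annotation group, association
   tests against insulin-secretion phenotypes, and a genome-wide scan that
   includes the window-level prior.

Under a single causal variant per window / signal, all computations are in
log space so arbitrarily large Bayes factors are safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_PRIOR_VARIANCE = 0.04  # N(0, 0.2^2) prior on the log-odds effect


@dataclass
class FinemapConfig:
    """Tunable constants of the fine-mapping chain."""

    prior_variance: float = DEFAULT_PRIOR_VARIANCE
    credible_level: float = 0.99
    ppa_scan_threshold: float = 0.01
    penalty_grid: tuple[float, ...] = tuple(np.round(np.arange(0, 0.51, 0.01), 2))
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must be in (0,1)")


# ---------------------------------------------------------------------------
# Wakefield approximate Bayes factors


def wakefield_log_abf(
    beta: np.ndarray, se: np.ndarray, prior_variance: float = DEFAULT_PRIOR_VARIANCE
) -> np.ndarray:
    """Natural log of the Wakefield ABF favouring association.

    With V = se^2, z = beta / se and prior variance W:
    ``ABF = sqrt(V / (V + W)) * exp(z^2 / 2 * W / (V + W))``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_variance <= 0:
        raise ValueError("prior variance must be positive")
    v = se**2
    z2 = (beta / se) ** 2
    shrink = v / (v + prior_variance)
    return 0.5 * np.log(shrink) + z2 / 2 * (1 - shrink)


def wakefield_abf(
    beta: float, se: float, prior_variance: float = DEFAULT_PRIOR_VARIANCE
) -> float:
    """Wakefield approximate Bayes factor (association vs null)."""
    return float(np.exp(wakefield_log_abf(np.array(beta), np.array(se), prior_variance)))


# ---------------------------------------------------------------------------
# Windowed variants and the hierarchical enrichment likelihood


class VariantWindows:
    """Variants partitioned into consecutive non-overlapping windows.

    Parameters
    ----------
    log_abf
        Per-variant log Bayes factors, window-contiguous.
    annotations
        Binary (n_variants, n_annotations) matrix.
    window_ids
        Integer window label per variant; variants of one window must be
        contiguous.
    annotation_names
        Column labels for ``annotations``.
    """

    def __init__(
        self,
        log_abf: np.ndarray,
        annotations: np.ndarray,
        window_ids: np.ndarray,
        annotation_names: Sequence[str],
    ):
        self.log_abf = np.asarray(log_abf, dtype=float)
        self.X = np.asarray(annotations, dtype=float)
        self.window_ids = np.asarray(window_ids)
        self.annotation_names = list(annotation_names)
        n = len(self.log_abf)
        if self.X.shape != (n, len(self.annotation_names)):
            raise ValueError("annotation matrix shape mismatch")
        if len(self.window_ids) != n:
            raise ValueError("window_ids length mismatch")
        change = np.flatnonzero(np.diff(self.window_ids) != 0) + 1
        self.starts = np.concatenate([[0], change])
        if len(np.unique(self.window_ids)) != len(self.starts):
            raise ValueError("variants of one window must be contiguous")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def subset_windows(self, window_idx: np.ndarray) -> "VariantWindows":
        bounds = np.append(self.starts, len(self.log_abf))
        keep = np.concatenate(
            [np.arange(bounds[i], bounds[i + 1]) for i in window_idx]
        )
        return VariantWindows(
            self.log_abf[keep],
            self.X[keep],
            self.window_ids[keep],
            self.annotation_names,
        )


def _segment_logsumexp(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """logsumexp over contiguous segments delimited by ``starts``."""
    seg_max = np.maximum.reduceat(values, starts)
    shifted = np.exp(values - np.repeat(seg_max, np.diff(np.append(starts, len(values)))))
    sums = np.add.reduceat(shifted, starts)
    return seg_max + np.log(sums)


def _loglik_and_grad(
    gamma: np.ndarray, kappa: float, windows: VariantWindows
) -> tuple[float, np.ndarray, float]:
    """Log-likelihood plus analytic gradient wrt (gamma, kappa).

    Per window w with Pi = logistic(kappa), prior weights pi = softmax(X g)
    and S_w = sum pi_v ABF_v, the contribution is
    ``log((1 - Pi) + Pi S_w)``; writing r_w = Pi S_w / ((1-Pi) + Pi S_w):

    d/dkappa  = r_w - Pi
    d/dgamma  = r_w (E_post[x] - E_prior[x])
    """
    starts = windows.starts
    counts = np.diff(np.append(starts, len(windows.log_abf)))
    eta = windows.X @ gamma
    log_norm = _segment_logsumexp(eta, starts)
    log_pi = eta - np.repeat(log_norm, counts)
    log_s = _segment_logsumexp(log_pi + windows.log_abf, starts)
    log_pi_term = -np.log1p(np.exp(-kappa)) if kappa > 0 else kappa - np.log1p(np.exp(kappa))
    log_1m_pi = -np.log1p(np.exp(kappa)) if kappa > 0 else -kappa - np.log1p(np.exp(-kappa))
    # log D_w = log((1-Pi) + Pi S_w), overflow-safe
    log_d = np.logaddexp(log_1m_pi, log_pi_term + log_s)
    loglik = float(log_d.sum())

    pi_prior = np.exp(log_pi)
    log_w_post = log_pi + windows.log_abf - np.repeat(log_s, counts)
    w_post = np.exp(log_w_post)
    r = np.exp(log_pi_term + log_s - log_d)  # in (0, 1)
    e_prior = np.empty((windows.n_windows, windows.X.shape[1]))
    e_post = np.empty_like(e_prior)
    for j in range(windows.X.shape[1]):
        e_prior[:, j] = np.add.reduceat(pi_prior * windows.X[:, j], starts)
        e_post[:, j] = np.add.reduceat(w_post * windows.X[:, j], starts)
    grad_gamma = (r[:, None] * (e_post - e_prior)).sum(axis=0)
    grad_kappa = float((r - expit(kappa)).sum())
    return loglik, grad_gamma, grad_kappa


def fgwas_loglik(
    gamma: np.ndarray | Mapping[str, float], kappa: float, windows: VariantWindows
) -> float:
    """Marginal log-likelihood of the hierarchical enrichment model."""
    if isinstance(gamma, Mapping):
        gamma = np.array([gamma.get(a, 0.0) for a in windows.annotation_names])
    gamma = np.asarray(gamma, dtype=float)
    ll, _, _ = _loglik_and_grad(gamma, kappa, windows)
    return ll


@dataclass
class EnrichmentModel:
    """Fitted annotation-enrichment model."""

    annotation_names: list[str]
    gamma: np.ndarray
    kappa: float
    gamma_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    penalty: float = 0.0
    loglik: float = float("nan")

    @property
    def window_prior(self) -> float:
        """Probability that a window contains a causal variant."""
        return float(expit(self.kappa))

    def gamma_of(self, name: str) -> float:
        return float(self.gamma[self.annotation_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "annotations": self.annotation_names,
            "gamma": self.gamma.tolist(),
            "gamma_ci": {k: list(v) for k, v in self.gamma_ci.items()},
            "kappa": self.kappa,
            "penalty": self.penalty,
            "loglik": self.loglik,
        }


def _fit_ml(
    windows: VariantWindows,
    annot_idx: Sequence[int],
    penalty: float = 0.0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Maximize the (optionally ridge-penalized) log-likelihood over the
    selected annotation columns and kappa. Returns (gamma_sel, kappa, loglik
    at the optimum, unpenalized)."""
    annot_idx = list(annot_idx)
    sub = VariantWindows(
        windows.log_abf,
        windows.X[:, annot_idx] if annot_idx else np.zeros((len(windows.log_abf), 0)),
        windows.window_ids,
        [windows.annotation_names[i] for i in annot_idx],
    )
    k = len(annot_idx)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        g, kap = theta[:k], theta[k]
        ll, gg, gk = _loglik_and_grad(g, kap, sub)
        obj = -ll + penalty * float(g @ g)
        grad = np.concatenate([-gg + 2 * penalty * g, [-gk]])
        return obj, grad

    if x0 is None:
        x0 = np.zeros(k + 1)
        x0[k] = -1.0
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-15, 15)] * k + [(-25, 10)],
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"enrichment fit failed: {res.message}")
    g, kap = res.x[:k], float(res.x[k])
    ll, _, _ = _loglik_and_grad(g, kap, sub)
    return g, kap, ll


def _cv_loglik(
    windows: VariantWindows,
    annot_idx: Sequence[int],
    penalty: float,
    folds: int,
) -> float:
    """Sum of held-out (unpenalized) log-likelihoods over round-robin folds."""
    n_w = windows.n_windows
    folds = min(folds, n_w)
    assign = np.arange(n_w) % folds
    total = 0.0
    for f in range(folds):
        train = windows.subset_windows(np.flatnonzero(assign != f))
        test = windows.subset_windows(np.flatnonzero(assign == f))
        g, kap, _ = _fit_ml(train, annot_idx, penalty)
        sub_test = VariantWindows(
            test.log_abf,
            test.X[:, list(annot_idx)] if annot_idx else np.zeros((len(test.log_abf), 0)),
            test.window_ids,
            [windows.annotation_names[i] for i in annot_idx],
        )
        ll, _, _ = _loglik_and_grad(g, kap, sub_test)
        total += ll
    return total


def _profile_ci(
    windows: VariantWindows,
    annot_idx: list[int],
    j_local: int,
    gamma_hat: np.ndarray,
    kappa_hat: float,
    loglik_hat: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one enrichment parameter."""
    crit = stats.chi2.ppf(level, df=1) / 2
    sub = VariantWindows(
        windows.log_abf,
        windows.X[:, annot_idx],
        windows.window_ids,
        [windows.annotation_names[i] for i in annot_idx],
    )
    k = len(annot_idx)
    free = [i for i in range(k) if i != j_local]

    def profile(gj: float) -> float:
        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            g = np.empty(k)
            g[free] = theta[:-1]
            g[j_local] = gj
            ll, gg, gk = _loglik_and_grad(g, theta[-1], sub)
            return -ll, np.concatenate([-gg[free], [-gk]])

        x0 = np.concatenate([gamma_hat[free], [kappa_hat]])
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B")
        return -res.fun

    def deficit(gj: float) -> float:
        return loglik_hat - profile(gj) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        step = 0.5
        lo = gamma_hat[j_local]
        hi = lo + direction * step
        for _ in range(40):
            if deficit(hi) > 0:
                break
            lo = hi
            hi = hi + direction * step
            step *= 1.6
        else:
            bounds.append(direction * np.inf)
            continue
        a, b = (hi, lo) if direction < 0 else (lo, hi)
        bounds.append(float(optimize.brentq(deficit, a, b, xtol=1e-4)))
    return min(bounds), max(bounds)


def fit_single_annotations(
    windows: VariantWindows, penalty: float = 0.0, compute_ci: bool = True
) -> dict[str, EnrichmentModel]:
    """Fit one single-annotation enrichment model per annotation class."""
    out: dict[str, EnrichmentModel] = {}
    for j, name in enumerate(windows.annotation_names):
        g, kap, ll = _fit_ml(windows, [j], penalty)
        model = EnrichmentModel([name], g, kap, penalty=penalty, loglik=ll)
        if compute_ci:
            model.gamma_ci[name] = _profile_ci(windows, [j], 0, g, kap, ll)
        out[name] = model
    return out


def fit_enrichment(
    windows: VariantWindows,
    penalty: float | None = None,
    cv_folds: int = 10,
    compute_ci: bool = True,
    penalty_grid: Sequence[float] | None = None,
    min_gain: float = 1.0,
) -> EnrichmentModel:
    """Fit the joint annotation-enrichment model.

    The joint model is built greedily: start from the best single
    annotation, add annotations while the maximized likelihood increases.
    When ``penalty`` is None a ridge penalty ``p * sum(gamma^2)`` is chosen
    from ``penalty_grid`` (0 to 0.5 in steps of 0.01 by default) by
    ``cv_folds``-fold cross-validated likelihood over windows, and
    annotations whose removal improves the CV likelihood are pruned.
    95% confidence intervals come from the profile likelihood. ``min_gain``
    is the log-likelihood improvement required to admit another annotation
    (1.0 by default, i.e. roughly an AIC step per added parameter, so
    annotations carrying no signal do not accumulate).
    """
    if windows.n_windows < 2:
        raise ValueError("need at least 2 windows")
    n_annot = windows.X.shape[1]
    if n_annot == 0:
        raise ValueError("no annotations to fit")

    # forward greedy selection at zero penalty
    selected: list[int] = []
    best_ll = -np.inf
    remaining = list(range(n_annot))
    while remaining:
        trial = [
            (_fit_ml(windows, selected + [j], 0.0)[2], j) for j in remaining
        ]
        ll_new, j_best = max(trial)
        if ll_new > best_ll + (min_gain if selected else 0.0):
            selected.append(j_best)
            remaining.remove(j_best)
            best_ll = ll_new
        else:
            break
    if not selected:
        selected = [max(range(n_annot), key=lambda j: _fit_ml(windows, [j], 0.0)[2])]

    # penalty selection by cross-validated likelihood
    if penalty is None:
        grid = tuple(penalty_grid) if penalty_grid is not None else tuple(
            np.round(np.arange(0, 0.51, 0.01), 2)
        )
        cv_scores = [(_cv_loglik(windows, selected, p, cv_folds), p) for p in grid]
        _, penalty = max(cv_scores)
        # backward pruning by CV likelihood
        improved = True
        base_cv = max(cv_scores)[0]
        while improved and len(selected) > 1:
            improved = False
            for j in list(selected):
                trial_sel = [i for i in selected if i != j]
                cv = _cv_loglik(windows, trial_sel, penalty, cv_folds)
                if cv > base_cv + 1e-6:
                    selected = trial_sel
                    base_cv = cv
                    improved = True
                    break

    g, kap, ll = _fit_ml(windows, selected, penalty)
    names = [windows.annotation_names[i] for i in selected]
    model = EnrichmentModel(names, g, kap, penalty=float(penalty), loglik=ll)
    if compute_ci:
        for j_local, name in enumerate(names):
            model.gamma_ci[name] = _profile_ci(windows, selected, j_local, g, kap, ll)
    return model


# ---------------------------------------------------------------------------
# Signal-level priors, PPA, credible sets


def annotation_priors(X_signal: np.ndarray, model: EnrichmentModel) -> np.ndarray:
    """Functional prior per variant at one signal.

    Each variant's relative weight is ``exp(gamma . x_v)`` (1 for
    unannotated variants); priors are the weights normalized to sum to 1.
    """
    X_signal = np.asarray(X_signal, dtype=float)
    if X_signal.shape[0] == 0:
        raise ValueError("empty signal")
    log_e = X_signal @ model.gamma
    log_prior = log_e - logsumexp(log_e)
    return np.exp(log_prior)


def ppa_from_log(log_prior: np.ndarray, log_abf: np.ndarray) -> np.ndarray:
    log_odds = log_prior + log_abf
    return np.exp(log_odds - logsumexp(log_odds))


def ppa(priors: np.ndarray, abf: np.ndarray) -> np.ndarray:
    """Posterior probability of association under one causal variant:
    prior times ABF, normalized across the signal's variants."""
    priors = np.asarray(priors, dtype=float)
    abf = np.asarray(abf, dtype=float)
    if np.any(priors < 0) or np.any(abf < 0):
        raise ValueError("priors and abf must be non-negative")
    with np.errstate(divide="ignore"):
        log_odds = np.log(priors) + np.log(abf)
    if np.all(np.isneginf(log_odds)):
        raise ValueError("all prior x ABF products are zero")
    return np.exp(log_odds - logsumexp(log_odds))


def credible_set(
    variant_ids: Sequence[str], ppa_values: np.ndarray, level: float = 0.99
) -> list[str]:
    """Smallest PPA-descending prefix whose cumulative PPA reaches ``level``.

    Ties in PPA are broken lexicographically by variant id so the set is
    deterministic.
    """
    ppa_values = np.asarray(ppa_values, dtype=float)
    if abs(ppa_values.sum() - 1.0) > 1e-6:
        raise ValueError("PPA values must sum to 1")
    order = sorted(range(len(variant_ids)), key=lambda i: (-ppa_values[i], variant_ids[i]))
    cum = 0.0
    out: list[str] = []
    for i in order:
        out.append(variant_ids[i])
        cum += ppa_values[i]
        if cum >= level - 1e-12:
            break
    return out


def cumulative_ppa(
    ppa_values: np.ndarray,
    X_signal: np.ndarray,
    annotation_names: Sequence[str],
    groups: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Cumulative PPA per annotation group: the summed PPA of all variants
    overlapping any annotation in the group."""
    name_idx = {a: j for j, a in enumerate(annotation_names)}
    out = {}
    for group, members in groups.items():
        cols = [name_idx[m] for m in members if m in name_idx]
        if not cols:
            out[group] = 0.0
            continue
        mask = np.asarray(X_signal)[:, cols].sum(axis=1) > 0
        out[group] = float(np.asarray(ppa_values)[mask].sum())
    return out


def cppa_cluster(
    cppa_matrix: np.ndarray,
    group_names: Sequence[str],
    k: int = 4,
    seed: int = 0,
    enhancer_group: str = "enhancer",
    auto_k: bool = False,
) -> tuple[np.ndarray, int]:
    """k-means clustering of signals on their cumulative-PPA vectors.

    Returns the labels and the index of the "enhancer cluster" — the
    cluster with the highest mean enhancer cPPA. With ``auto_k`` the number
    of clusters is chosen from 2..k by silhouette score.
    """
    cppa_matrix = np.asarray(cppa_matrix, dtype=float)
    n = cppa_matrix.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of signals")
    if auto_k and n > 3:
        best = None
        for kk in range(2, min(k, n - 1) + 1):
            labels = KMeans(kk, n_init=10, random_state=seed).fit_predict(cppa_matrix)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(cppa_matrix, labels)
            if best is None or score > best[0]:
                best = (score, kk)
        k = best[1] if best else k
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(cppa_matrix)
    g = list(group_names).index(enhancer_group)
    means = [
        cppa_matrix[labels == c, g].mean() if np.any(labels == c) else -np.inf
        for c in range(k)
    ]
    return labels, int(np.argmax(means))


def glycemic_overlap_tests(
    is_enhancer_signal: np.ndarray, secretion_associated: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Association between enhancer-cluster membership and insulin-secretion
    phenotype association.

    Returns (chi-square p, binomial p, 2x2 table). The chi-square is the
    uncorrected Pearson statistic on the table [enhancer vs un-annotated] x
    [secretion-associated vs not]. The binomial test asks whether the number
    of secretion-associated enhancer signals exceeds the rate seen among
    un-annotated signals.
    """
    enh = np.asarray(is_enhancer_signal, dtype=bool)
    sec = np.asarray(secretion_associated, dtype=bool)
    table = np.array(
        [
            [int((enh & sec).sum()), int((enh & ~sec).sum())],
            [int((~enh & sec).sum()), int((~enh & ~sec).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    _, chi_p, _, _ = stats.chi2_contingency(table, correction=False)
    expected_rate = table[1, 0] / table[1].sum()
    expected_rate = min(max(expected_rate, 1e-12), 1 - 1e-12)
    binom_p = stats.binomtest(int(table[0, 0]), int(table[0].sum()), expected_rate).pvalue
    return float(chi_p), float(binom_p), table


def genomewide_scan(
    windows: VariantWindows,
    model: EnrichmentModel,
    enhancer_mask: np.ndarray,
    threshold: float = 0.01,
) -> tuple[list[int], np.ndarray]:
    """Scan windows for putative risk loci driven by enhancer variants.

    Per window the prior on "variant v causal" is the window-level prior
    ``Pi = logistic(kappa)`` times the within-window functional prior; the
    null configuration keeps prior ``1 - Pi`` and Bayes factor 1. A window
    is retained when any enhancer-overlapping variant achieves PPA above
    ``threshold``. Windows overlapping known signals must be excluded by the
    caller.

    Returns the retained window indices (positions in ``windows.starts``)
    and the per-variant PPA vector.
    """
    enhancer_mask = np.asarray(enhancer_mask, dtype=bool)
    sel = [windows.annotation_names.index(a) for a in model.annotation_names]
    eta = windows.X[:, sel] @ model.gamma
    starts = windows.starts
    counts = np.diff(np.append(starts, len(windows.log_abf)))
    log_norm = _segment_logsumexp(eta, starts)
    log_pi = eta - np.repeat(log_norm, counts)
    kap = model.kappa
    log_w_prior = -np.log1p(np.exp(-kap)) if kap > 0 else kap - np.log1p(np.exp(kap))
    log_null = -np.log1p(np.exp(kap)) if kap > 0 else -kap - np.log1p(np.exp(-kap))
    log_odds = log_w_prior + log_pi + windows.log_abf
    log_s = _segment_logsumexp(log_odds, starts)
    log_denom = np.logaddexp(log_null, log_s)
    ppa_all = np.exp(log_odds - np.repeat(log_denom, counts))
    passing = ppa_all > threshold
    keep: list[int] = []
    bounds = np.append(starts, len(ppa_all))
    for w in range(windows.n_windows):
        sl = slice(bounds[w], bounds[w + 1])
        if np.any(passing[sl] & enhancer_mask[sl]):
            keep.append(w)
    return keep, ppa_all


def make_window_ids(
    chroms: Sequence[str], positions: np.ndarray, variants_per_window: int
) -> np.ndarray:
    """Assign consecutive window ids in blocks of ``variants_per_window``
    variants within each chromosome (input must be position-sorted per
    chromosome)."""
    positions = np.asarray(positions)
    out = np.empty(len(positions), dtype=int)
    wid = 0
    i = 0
    while i < len(positions):
        j = i
        while (
            j < len(positions)
            and j - i < variants_per_window
            and chroms[j] == chroms[i]
        ):
            j += 1
        out[i:j] = wid
        wid += 1
        i = j
    return out


def choose_window_size(
    chroms: Sequence[str], positions: np.ndarray, target_span: float = 1_000_000
) -> int:
    """Variants-per-window count whose mean spanned length is closest to
    ``target_span`` (1 Mb by default)."""
    best = (np.inf, 1)
    for m in (2, 5, 10, 20, 50, 100, 200, 500, 1000):
        ids = make_window_ids(chroms, positions, m)
        spans = []
        for w in np.unique(ids):
            p = positions[ids == w]
            spans.append(p.max() - p.min())
        mean_span = float(np.mean(spans))
        score = abs(mean_span - target_span)
        if score < best[0]:
            best = (score, m)
    return best[1]
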