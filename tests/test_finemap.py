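"""Wakefield Bayes factors, the hierarchical enrichment model, PPAs,
credible sets, signal clustering and the genome-wide scan."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from t2dnet import finemap as fm


def quadrature_abf(beta, se, W):
    """ABF oracle: marginal likelihood ratio by numerical integration of
    the effect-size prior against the sampling density."""
    V = se**2

    def integrand(b):
        return stats.norm.pdf(beta, b, math.sqrt(V)) * stats.norm.pdf(b, 0, math.sqrt(W))

    num, _ = integrate.quad(integrand, -10, 10, epsabs=1e-14, epsrel=1e-12)
    den = stats.norm.pdf(beta, 0, math.sqrt(V))
    return num / den


class TestWakefieldAbf:
    def test_zero_effect_collapses_to_shrinkage(self):
        assert fm.wakefield_abf(0.0, 0.1, 0.04) == pytest.approx(
            math.sqrt(0.01 / 0.05)
        )
        assert fm.wakefield_abf(0.0, 0.1, 0.04) == pytest.approx(0.4472, abs=1e-4)

    @pytest.mark.parametrize("beta", [-0.5, -0.1, 0.0, 0.05, 0.3])
    @pytest.mark.parametrize("se", [0.05, 0.1, 0.5])
    def test_matches_quadrature_oracle(self, beta, se):
        got = fm.wakefield_abf(beta, se, 0.04)
        assert got == pytest.approx(quadrature_abf(beta, se, 0.04), rel=1e-8)

    def test_monotone_in_abs_z(self):
        zs = np.linspace(0, 8, 50)
        abf = np.exp(fm.wakefield_log_abf(zs * 0.1, np.full(50, 0.1), 0.04))
        assert np.all(np.diff(abf) > 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fm.wakefield_abf(0.1, 0.0)
        with pytest.raises(ValueError):
            fm.wakefield_abf(np.nan, 0.1)
        with pytest.raises(ValueError):
            fm.wakefield_abf(0.1, 0.1, prior_variance=-1)


def _hand_loglik(gamma, kappa, log_abf, X, window_ids):
    """Direct summation oracle for the window marginal likelihood."""
    total = 0.0
    pi_w = 1 / (1 + math.exp(-kappa))
    for w in sorted(set(window_ids)):
        idx = [i for i, ww in enumerate(window_ids) if ww == w]
        weights = [math.exp(sum(g * x for g, x in zip(gamma, X[i]))) for i in idx]
        s = sum(weights)
        lik = (1 - pi_w) + pi_w * sum(
            wgt / s * math.exp(log_abf[i]) for wgt, i in zip(weights, idx)
        )
        total += math.log(lik)
    return total


class TestFgwasLoglik:
    X = np.array([[1.0], [0.0], [0.0], [1.0], [0.0]])
    LOG_ABF = np.log(np.array([50.0, 1.2, 0.8, 3.0, 1.0]))
    WID = np.array([0, 0, 0, 1, 1])

    def windows(self):
        return fm.VariantWindows(self.LOG_ABF, self.X, self.WID, ["EnhA1"])

    def test_matches_hand_expanded_sum(self):
        w = self.windows()
        for gamma, kappa in [(0.0, 0.0), (2.0, -1.0), (-1.0, 1.5), (3.9, -3.0)]:
            got = fm.fgwas_loglik(np.array([gamma]), kappa, w)
            expected = _hand_loglik([gamma], kappa, self.LOG_ABF, self.X, self.WID)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_null_limit_is_zero(self):
        got = fm.fgwas_loglik(np.array([0.0]), -40.0, self.windows())
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_raising_enrichment_on_causal_annotation_helps(self):
        w = self.windows()
        low = fm.fgwas_loglik(np.array([0.0]), 0.0, w)
        high = fm.fgwas_loglik(np.array([2.0]), 0.0, w)
        assert high > low

    def test_gradient_matches_finite_differences(self):
        w = self.windows()
        gamma, kappa = np.array([1.3]), -0.4
        ll, gg, gk = fm._loglik_and_grad(gamma, kappa, w)
        eps = 1e-6
        fd_g = (
            fm.fgwas_loglik(gamma + eps, kappa, w)
            - fm.fgwas_loglik(gamma - eps, kappa, w)
        ) / (2 * eps)
        fd_k = (
            fm.fgwas_loglik(gamma, kappa + eps, w)
            - fm.fgwas_loglik(gamma, kappa - eps, w)
        ) / (2 * eps)
        assert gg[0] == pytest.approx(fd_g, abs=1e-6)
        assert gk == pytest.approx(fd_k, abs=1e-6)


def _simulate_windows(seed, n_windows=300, m=15, gamma=2.5, pi=0.5, f_annot=0.15):
    rng = np.random.default_rng(seed)
    X = (rng.random((n_windows * m, 1)) < f_annot).astype(float)
    wid = np.repeat(np.arange(n_windows), m)
    beta = np.zeros(n_windows * m)
    for w in range(n_windows):
        if rng.random() > pi:
            continue
        idx = np.arange(w * m, (w + 1) * m)
        wts = np.exp(gamma * X[idx, 0])
        pick = rng.choice(idx, p=wts / wts.sum())
        beta[pick] = rng.normal(0, 0.2)
    se = 0.05
    obs = beta + rng.normal(0, se, len(beta))
    log_abf = fm.wakefield_log_abf(obs, np.full(len(obs), se), 0.04)
    return fm.VariantWindows(log_abf, X, wid, ["A"])


class TestFitEnrichment:
    def test_matches_grid_search_on_tiny_fixture(self):
        w = _simulate_windows(1, n_windows=40)
        model = fm.fit_enrichment(w, penalty=0.0, compute_ci=False)
        grid_best = max(
            (fm.fgwas_loglik(np.array([g]), k, w), g, k)
            for g in np.arange(-1, 6.01, 0.05)
            for k in np.arange(-4, 2.01, 0.05)
        )
        assert model.loglik >= grid_best[0] - 1e-6
        assert model.gamma[0] == pytest.approx(grid_best[1], abs=0.06)
        assert model.kappa == pytest.approx(grid_best[2], abs=0.06)

    def test_null_annotation_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        n_w, m = 400, 10
        X = (rng.random((n_w * m, 1)) < 0.2).astype(float)  # unrelated to causality
        wid = np.repeat(np.arange(n_w), m)
        beta = np.zeros(n_w * m)
        caus = rng.integers(0, m, n_w) + np.arange(n_w) * m
        beta[caus[: n_w // 2]] = rng.normal(0, 0.2, n_w // 2)
        obs = beta + rng.normal(0, 0.05, len(beta))
        log_abf = fm.wakefield_log_abf(obs, np.full(len(obs), 0.05), 0.04)
        w = fm.VariantWindows(log_abf, X, wid, ["A"])
        model = fm.fit_enrichment(w, penalty=0.0)
        lo, hi = model.gamma_ci["A"]
        assert lo <= 0.0 <= hi

    def test_cv_penalty_selection_runs(self):
        w = _simulate_windows(5, n_windows=60)
        model = fm.fit_enrichment(
            w, penalty=None, cv_folds=3, compute_ci=False,
            penalty_grid=(0.0, 0.1, 0.3),
        )
        assert model.penalty in (0.0, 0.1, 0.3)
        assert np.isfinite(model.loglik)

    def test_too_few_windows_rejected(self):
        w = _simulate_windows(1, n_windows=40)
        single = w.subset_windows(np.array([0]))
        with pytest.raises(ValueError):
            fm.fit_enrichment(single)


class TestPriorsAndPpa:
    MODEL = fm.EnrichmentModel(["A"], np.array([2.0]), kappa=0.0)

    def test_shared_annotation_gives_uniform_priors(self):
        X = np.ones((4, 1))
        assert np.allclose(fm.annotation_priors(X, self.MODEL), 0.25)

    def test_two_variant_example(self):
        X = np.array([[1.0], [0.0]])
        priors = fm.annotation_priors(X, self.MODEL)
        e2 = math.exp(2)
        assert priors == pytest.approx([e2 / (e2 + 1), 1 / (e2 + 1)])
        assert priors == pytest.approx([0.881, 0.119], abs=1e-3)

    def test_single_variant_prior_one(self):
        assert fm.annotation_priors(np.zeros((1, 1)), self.MODEL) == pytest.approx([1.0])

    def test_ppa_examples(self):
        assert np.allclose(fm.ppa(np.full(3, 1 / 3), np.full(3, 7.0)), 1 / 3)
        got = fm.ppa(np.array([0.5, 0.25, 0.25]), np.array([10.0, 10.0, 1.0]))
        assert got == pytest.approx([0.645, 0.323, 0.032], abs=1e-3)
        assert fm.ppa(np.array([1.0]), np.array([0.5])) == pytest.approx([1.0])

    def test_ppa_sums_to_one(self, rng):
        priors = rng.dirichlet(np.ones(20))
        abf = rng.lognormal(0, 3, 20)
        assert fm.ppa(priors, abf).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_products_rejected(self):
        with pytest.raises(ValueError):
            fm.ppa(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_flat_prior_equivalence_with_zero_enrichment(self, rng):
        """With gamma = 0 the functional-prior PPAs equal pure-ABF
        fine-mapping."""
        model = fm.EnrichmentModel(["A"], np.array([0.0]), kappa=0.0)
        for _ in range(20):
            n = rng.integers(3, 30)
            X = (rng.random((n, 1)) < 0.3).astype(float)
            log_abf = rng.normal(0, 4, n)
            priors = fm.annotation_priors(X, model)
            got = fm.ppa_from_log(np.log(priors), log_abf)
            pure = np.exp(log_abf - fm.logsumexp(log_abf))
            assert np.allclose(got, pure, atol=1e-12)


class TestCredibleSet:
    def test_reference_examples(self):
        assert fm.credible_set(["v1", "v2", "v3"], np.array([0.995, 0.004, 0.001])) == ["v1"]
        assert fm.credible_set(
            ["v1", "v2", "v3", "v4"], np.array([0.6, 0.3, 0.05, 0.05])
        ) == ["v1", "v2", "v3", "v4"]
        assert fm.credible_set(["v"], np.array([1.0])) == ["v"]

    def test_tie_break_lexicographic(self):
        got = fm.credible_set(["b", "a"], np.array([0.5, 0.5]), level=0.4)
        assert got == ["a"]

    def test_is_smallest_prefix(self, rng):
        for _ in range(20):
            n = rng.integers(2, 40)
            ppa = rng.dirichlet(np.ones(n))
            ids = [f"v{i}" for i in range(n)]
            cs = fm.credible_set(ids, ppa, level=0.99)
            mass = sum(ppa[ids.index(v)] for v in cs)
            assert mass >= 0.99 - 1e-9
            without_last = mass - min(ppa[ids.index(v)] for v in cs)
            assert without_last < 0.99


class TestClusteringAndGlycemic:
    def test_separated_populations_recovered(self, rng):
        enh = np.column_stack([rng.normal(0.9, 0.03, 20), rng.normal(0.05, 0.03, 20)])
        cds = np.column_stack([rng.normal(0.05, 0.03, 20), rng.normal(0.9, 0.03, 20)])
        cppa = np.clip(np.vstack([enh, cds]), 0, 1)
        labels, enh_cluster = fm.cppa_cluster(cppa, ["enhancer", "coding"], k=2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] == enh_cluster
        assert labels[20] != enh_cluster

    def test_k_exceeding_signals_rejected(self):
        with pytest.raises(ValueError):
            fm.cppa_cluster(np.zeros((3, 2)), ["enhancer", "coding"], k=5)

    def test_cppa_sums_bounded_by_one(self, rng):
        # chromatin-state annotations are mutually exclusive: one-hot rows
        ppa = rng.dirichlet(np.ones(30))
        X = np.eye(5)[rng.integers(0, 5, 30)][:, :4]  # fifth state = unannotated
        groups = {"enhancer": ["EnhA1", "EnhA2"], "promoter": ["TssA"], "ctcf": ["CTCF"]}
        cppa = fm.cumulative_ppa(ppa, X, ["EnhA1", "EnhA2", "TssA", "CTCF"], groups)
        assert sum(cppa.values()) <= 1.0 + 1e-9

    def test_glycemic_tests_match_oracles(self):
        enh = np.array([True] * 30 + [False] * 48)
        sec = np.array([True] * 13 + [False] * 17 + [True] * 8 + [False] * 40)
        chi_p, binom_p, table = fm.glycemic_overlap_tests(enh, sec)
        assert table.tolist() == [[13, 17], [8, 40]]
        # chi-square formula oracle
        t = table.astype(float)
        expected = t.sum(1, keepdims=True) @ t.sum(0, keepdims=True) / t.sum()
        chi2 = ((t - expected) ** 2 / expected).sum()
        assert chi_p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)
        # binomial tail-sum oracle at the un-annotated rate 8/48
        p0 = 8 / 48
        pmf = stats.binom.pmf(np.arange(31), 30, p0)
        expected_p = pmf[pmf <= pmf[13] * (1 + 1e-7)].sum()
        assert binom_p == pytest.approx(expected_p, rel=1e-9)

    def test_identical_rates_near_one(self):
        enh = np.array([True] * 20 + [False] * 20)
        sec = np.array(([True] * 10 + [False] * 10) * 2)
        chi_p, _, _ = fm.glycemic_overlap_tests(enh, sec)
        assert chi_p == pytest.approx(1.0)


class TestGenomewideScan:
    def test_strong_enhancer_variant_retained(self):
        model = fm.EnrichmentModel(["EnhA1"], np.array([3.9]), kappa=-3.0)
        log_abf = np.log(np.array([1e6, 1.0, 1.0, 1.0]))
        X = np.array([[1.0], [0.0], [0.0], [0.0]])
        w = fm.VariantWindows(log_abf, X, np.zeros(4, dtype=int), ["EnhA1"])
        kept, ppa_all = fm.genomewide_scan(w, model, X[:, 0] > 0, 0.01)
        assert kept == [0]
        assert ppa_all[0] > 0.9

    def test_all_null_large_window_dropped(self):
        model = fm.EnrichmentModel(["EnhA1"], np.array([0.0]), kappa=-4.0)
        n = 150
        log_abf = np.zeros(n)
        X = np.ones((n, 1))
        w = fm.VariantWindows(log_abf, X, np.zeros(n, dtype=int), ["EnhA1"])
        kept, ppa_all = fm.genomewide_scan(w, model, np.ones(n, dtype=bool), 0.01)
        assert kept == []
        assert np.all(ppa_all < 0.01)

    def test_no_enhancer_annotation_no_windows(self):
        model = fm.EnrichmentModel(["EnhA1"], np.array([3.9]), kappa=0.0)
        log_abf = np.log(np.array([1e6, 1.0]))
        X = np.array([[1.0], [0.0]])
        w = fm.VariantWindows(log_abf, X, np.zeros(2, dtype=int), ["EnhA1"])
        kept, _ = fm.genomewide_scan(w, model, np.zeros(2, dtype=bool), 0.01)
        assert kept == []


class TestWindowing:
    def test_window_ids_block_structure(self):
        chroms = ["chr1"] * 5 + ["chr2"] * 3
        pos = np.array([10, 20, 30, 40, 50, 5, 15, 25])
        ids = fm.make_window_ids(chroms, pos, 2)
        assert ids.tolist() == [0, 0, 1, 1, 2, 3, 3, 4]

    def test_choose_window_size_targets_mean_span(self, rng):
        pos = np.sort(rng.integers(0, 50_000_000, 2000))
        chroms = ["chr1"] * 2000
        m = fm.choose_window_size(chroms, pos, target_span=1_000_000)
        ids = fm.make_window_ids(chroms, pos, m)
        spans = [pos[ids == w].max() - pos[ids == w].min() for w in np.unique(ids)]
        assert 0.4e6 < np.mean(spans) < 2.5e6
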