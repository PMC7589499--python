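import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import kstest, nbinom, ttest_ind

from consensusde import (SimulationConfig, bh_adjust, estimate_common_dispersion,
                         estimate_duplicate_correlation,
                         estimate_tagwise_dispersions, fit_nb_glm,
                         gls_moderated_test, lr_test, nb_exact_test,
                         nb_exact_test_batch, simulate_dataset)
from consensusde.errors import DesignError, DomainError
from consensusde.io import StudyDesign
from conftest import first_combination_pvalues
from test_io import make_design_frame


class TestDispersionEstimation:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(100), 1.0, size=(2000, 1))
        y = rng.poisson(mu, size=(2000, 16))
        common = estimate_common_dispersion(y, ["a"] * 8 + ["b"] * 8)
        assert common <= 1e-3

    def test_recovers_known_dispersion(self):
        cfg = SimulationConfig(n_genes=2000, seed=2, frac_de=0.0, site_sd=0.0,
                               dispersion_location=float(np.log(0.2)),
                               dispersion_sd=0.0)
        counts, design, _ = simulate_dataset(cfg)
        from consensusde import filter_low_counts, pseudo_counts, rle_factors
        filt = filter_low_counts(counts)
        ps = pseudo_counts(filt, rle_factors(filt))
        common = estimate_common_dispersion(
            ps, design.table["invasion_category"].tolist())
        assert 0.17 <= common <= 0.23

    def test_constant_counts_hit_lower_bound(self):
        y = np.full((1, 8), 50)
        common = estimate_common_dispersion(y, ["a"] * 4 + ["b"] * 4)
        assert common < 1e-6

    def test_prior_df_zero_equals_genewise_mle(self):
        rng = np.random.default_rng(10)
        y = rng.negative_binomial(10, 0.1, size=(50, 8))
        labels = ["a"] * 4 + ["b"] * 4
        common = estimate_common_dispersion(y, labels)
        est = estimate_tagwise_dispersions(y, labels, common, prior_df=0.0)
        np.testing.assert_array_equal(est.shrunk, est.genewise)

    def test_infinite_prior_recovers_common(self):
        rng = np.random.default_rng(11)
        y = rng.negative_binomial(10, 0.1, size=(50, 8))
        labels = ["a"] * 4 + ["b"] * 4
        common = estimate_common_dispersion(y, labels)
        est = estimate_tagwise_dispersions(y, labels, common, prior_df=1e9)
        assert np.max(np.abs(est.shrunk - common)) < 1e-4

    def test_shrunk_estimates_preserve_dispersion_ordering(self):
        """Genes simulated at phi 0.05 vs 0.4 keep their order after shrinkage."""
        rng = np.random.default_rng(12)
        G = 400
        mu = rng.lognormal(np.log(100), 1.0, size=(G, 1))
        phi = np.r_[np.full(G // 2, 0.05), np.full(G // 2, 0.4)]
        r = 1.0 / phi
        y = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu),
                                  size=(G, 16))
        labels = ["a"] * 8 + ["b"] * 8
        common = estimate_common_dispersion(y, labels)
        est = estimate_tagwise_dispersions(y, labels, common, prior_df=10.0)
        lo, hi = est.shrunk[:G // 2], est.shrunk[G // 2:]
        assert (lo[:, None] < hi[None, :]).mean() >= 0.95


def conditional_exact_oracle(A, B, na, nb, phi):
    """Brute-force conditional null of A given T via explicit NB pmf products."""
    T = A + B
    r = 1.0 / phi
    a = np.arange(T + 1)
    # any common success probability cancels after normalization
    pmf = nbinom.pmf(a, na * r, 0.3) * nbinom.pmf(T - a, nb * r, 0.3)
    pmf = pmf / pmf.sum()
    return pmf[pmf <= pmf[A] * (1 + 1e-12)].sum()


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        _, p = nb_exact_test([5, 5], [5, 5], dispersion=0.1)
        assert p == 1.0

    def test_binomial_limit_closed_form(self):
        _, p = nb_exact_test([10], [0], dispersion=1e-8)
        assert p == pytest.approx(2 * 0.5 ** 10, rel=1e-6)

    def test_zero_total_is_degenerate(self):
        lfc, p = nb_exact_test([0, 0], [0, 0], dispersion=0.1)
        assert (lfc, p) == (0.0, 1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            na, nb = rng.integers(1, 5, size=2)
            T = int(rng.integers(1, 201))
            A = int(rng.integers(0, T + 1))
            phi = float(rng.uniform(0.01, 2.0))
            pseudo = np.zeros((1, na + nb), dtype=np.int64)
            pseudo[0, 0] = A
            pseudo[0, na] = T - A
            _, p = nb_exact_test_batch(pseudo, np.arange(na),
                                       np.arange(na, na + nb), phi)
            expected = conditional_exact_oracle(A, T - A, na, nb, phi)
            assert p[0] == pytest.approx(expected, abs=1e-10)

    def test_group_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(21)
        y = rng.negative_binomial(5, 0.05, size=(40, 8))
        ia, ib = np.arange(4), np.arange(4, 8)
        lfc1, p1 = nb_exact_test_batch(y, ia, ib, 0.2)
        lfc2, p2 = nb_exact_test_batch(y, ib, ia, 0.2)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)
        np.testing.assert_allclose(lfc1, -lfc2, rtol=1e-12)

    def test_agrees_with_edger_exact_test(self, tmp_path):
        """Independent cross-check against the reference implementation."""
        rng = np.random.default_rng(42)
        y = rng.negative_binomial(5, 0.05, size=(30, 8))
        counts_path = tmp_path / "counts.tsv"
        np.savetxt(counts_path, y, fmt="%d", delimiter="\t")
        out_path = tmp_path / "edger.tsv"
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(edgeR))
y <- as.matrix(read.table("{counts_path}"))
group <- factor(c(1,1,1,1,2,2,2,2))
d <- DGEList(counts=y, group=group, lib.size=rep(1e6,8))
d$samples$norm.factors <- rep(1,8)
res <- exactTest(d, dispersion=0.2, rejection.region="smallp")
write.table(res$table, "{out_path}", sep="\\t", quote=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        _, p = nb_exact_test_batch(y, np.arange(4), np.arange(4, 8), 0.2)
        np.testing.assert_allclose(p, ref["PValue"], atol=1e-12)


def nb_negloglik(beta, y, X, offsets, phi):
    mu = np.exp(X @ beta + offsets)
    r = 1.0 / phi
    return -(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
             + y * np.log(mu / (mu + r)) + r * np.log(r / (mu + r))).sum()


class TestNbGlm:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(50, size=8)
        offsets = np.full(8, np.log(1000.0))
        fit = fit_nb_glm(y, np.ones((8, 1)), offsets, 0.1)
        # with equal offsets the NB score equation gives the plain ratio
        assert np.exp(fit.coefficients[0, 0]) == pytest.approx(
            y.sum() / np.exp(offsets).sum(), rel=1e-8)
        assert fit.converged.all()

    def test_saturated_design_zero_deviance(self):
        y = np.array([3, 14, 15, 9])
        X = np.eye(4)
        fit = fit_nb_glm(y, X, np.zeros(4), 0.2)
        assert fit.deviance[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(30)
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        for _ in range(20):
            phi = float(rng.uniform(0.02, 0.5))
            offsets = np.log(rng.uniform(0.5, 2.0, 8) * 1e4)
            mu = rng.uniform(20, 200) * np.exp(
                X @ np.array([0.0, rng.normal(0, 1)]))
            r = 1.0 / phi
            y = rng.negative_binomial(r, r / (r + mu))
            if y.sum() == 0:
                continue
            fit = fit_nb_glm(y, X, offsets, phi)
            res = minimize(nb_negloglik, fit.coefficients[0] + 0.05,
                           args=(y, X, offsets, phi), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 10000})
            np.testing.assert_allclose(fit.coefficients[0], res.x, atol=1e-5)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(DesignError):
            fit_nb_glm(np.arange(4), X, np.zeros(4), 0.1)

    def test_deviance_never_worse_than_initial_guess(self):
        rng = np.random.default_rng(31)
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        y = rng.negative_binomial(5, 0.05, size=(100, 8))
        offsets = np.zeros(8)
        fit = fit_nb_glm(y, X, offsets, 0.2)
        from consensusde.de import _nb_deviance
        beta0 = (np.log(y + 0.5) - offsets) @ np.linalg.pinv(X).T
        mu0 = np.exp(beta0 @ X.T + offsets)
        dev0 = _nb_deviance(y.astype(float), mu0, np.full(100, 0.2))
        assert (fit.deviance <= dev0 + 1e-8).all()


class TestLrTest:
    def test_identical_fits_give_p_one(self):
        y = np.array([10, 12, 9, 11])
        X = np.ones((4, 1))
        fit = fit_nb_glm(y, X, np.zeros(4), 0.1)
        p = lr_test(fit, fit, df=1)
        assert p[0] == 1.0

    def test_chi_square_quantile(self):
        from consensusde.de import GlmFit
        full = GlmFit(np.zeros((1, 2)), np.ones((1, 4)),
                      np.array([0.0]), np.array([True]))
        red = GlmFit(np.zeros((1, 1)), np.ones((1, 4)),
                     np.array([3.841459]), np.array([True]))
        assert lr_test(full, red, 1)[0] == pytest.approx(0.05, abs=1e-6)

    def test_negative_statistic_warns(self):
        from consensusde.de import GlmFit
        full = GlmFit(np.zeros((1, 2)), np.ones((1, 4)),
                      np.array([1.0]), np.array([True]))
        red = GlmFit(np.zeros((1, 1)), np.ones((1, 4)),
                     np.array([0.5]), np.array([True]))
        with pytest.warns(RuntimeWarning):
            p = lr_test(full, red, 1)
        assert p[0] == 1.0


def bh_oracle(p):
    """Direct step-up definition, O(m^2)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_direct_definition(self):
        rng = np.random.default_rng(40)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(41)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]),
                                   atol=1e-12)

    def test_domain_validation(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


def gaussian_replicate_data(design, rho, G, seed):
    rng = np.random.default_rng(seed)
    site_eff = rng.normal(0, np.sqrt(rho) if rho > 0 else 0.0, size=(G, 8))
    noise = rng.normal(0, np.sqrt(1 - rho), size=(G, 16))
    return np.repeat(site_eff, 2, axis=1) + noise


@pytest.fixture(scope="module")
def design16():
    return StudyDesign(make_design_frame())


class TestDuplicateCorrelation:
    def test_identical_pairs_clip_near_one(self, design16):
        rng = np.random.default_rng(50)
        half = rng.normal(size=(100, 8))
        E = np.repeat(half, 2, axis=1)
        assert estimate_duplicate_correlation(E, design16) == pytest.approx(0.99)

    @pytest.mark.parametrize("rho,lo,hi", [(0.0, -0.05, 0.05),
                                           (0.5, 0.4, 0.6)])
    def test_recovers_true_correlation(self, design16, rho, lo, hi):
        E = gaussian_replicate_data(design16, rho, 2000, seed=51)
        est = estimate_duplicate_correlation(E, design16)
        assert lo <= est <= hi

    def test_unpaired_site_rejected(self, design16):
        broken = StudyDesign(make_design_frame().iloc[:15])
        E = np.zeros((10, 15))
        with pytest.raises(DesignError):
            estimate_duplicate_correlation(E, broken)


class TestGlsModeratedTest:
    def test_rho_zero_no_moderation_is_ordinary_t(self, design16):
        E = gaussian_replicate_data(design16, 0.0, 50, seed=60)
        fit = gls_moderated_test(E, design16, rho=0.0, prior_df_eb=0.0,
                                 prior_var_eb=1.0)
        cats = design16.table["invasion_category"].to_numpy()
        for g in range(0, 50, 7):
            t_ref = ttest_ind(E[g, cats == "recent"], E[g, cats == "ancient"],
                              equal_var=True)
            assert fit.moderated_t[g] == pytest.approx(t_ref.statistic,
                                                       rel=1e-10)
            assert fit.p_value[g] == pytest.approx(t_ref.pvalue, rel=1e-10)

    def test_posterior_variance_toy_instance(self):
        """s^2 = 1, s0^2 = 4, d0 = d = 4 -> posterior variance 2.5."""
        # 3 sites (6 libraries) leave 4 residual df for the 2-column design
        frame = make_design_frame().iloc[[0, 1, 2, 3, 8, 9]].reset_index(drop=True)
        design = StudyDesign(frame)
        cats = frame["invasion_category"].to_numpy()
        X = np.column_stack([np.ones(6), (cats == "recent").astype(float)])
        rng = np.random.default_rng(61)
        e = rng.normal(size=6)
        e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]   # orthogonal to design
        e *= 2.0 / np.linalg.norm(e)                    # ||e||^2 = 4 -> s^2 = 1
        y = (X @ np.array([0.0, 1.0]) + e)[None, :]
        fit = gls_moderated_test(y, design, rho=0.0, prior_df_eb=4.0,
                                 prior_var_eb=4.0)
        assert fit.residual_var[0] == pytest.approx(1.0, rel=1e-10)
        c11 = np.linalg.inv(X.T @ X)[1, 1]
        assert fit.moderated_t[0] == pytest.approx(1.0 / np.sqrt(2.5 * c11),
                                                   rel=1e-10)

    def test_infinite_prior_uses_prior_variance_everywhere(self, design16):
        E = gaussian_replicate_data(design16, 0.0, 20, seed=62)
        fit = gls_moderated_test(E, design16, rho=0.0, prior_df_eb=np.inf,
                                 prior_var_eb=2.0)
        cats = design16.table["invasion_category"].to_numpy()
        X = np.column_stack([np.ones(16), (cats == "recent").astype(float)])
        c11 = np.linalg.inv(X.T @ X)[1, 1]
        beta = fit.gls_coefficients[:, 1]
        np.testing.assert_allclose(fit.moderated_t,
                                   beta / np.sqrt(2.0 * c11), rtol=1e-10)

    def test_rho_out_of_domain_rejected(self, design16):
        E = np.zeros((5, 16))
        with pytest.raises(DomainError):
            gls_moderated_test(E, design16, rho=1.0)


class TestNullCalibration:
    def test_continuous_strategies_uniform_under_global_null(
            self, null_strategy_pvalues):
        for name in ("eightveight", "ranef"):
            assert kstest(null_strategy_pvalues[name], "uniform").pvalue > 0.01

    def test_exact_test_cdf_close_to_uniform(self, null_strategy_pvalues):
        p = np.sort(null_strategy_pvalues["fourvfour"])
        grid = np.linspace(0.01, 0.99, 99)
        emp = np.searchsorted(p, grid, side="right") / p.size
        assert np.max(np.abs(emp - grid)) <= 0.05

    def test_site_variance_spreads_4vs4_p_values_across_genes(self):
        """Site variance makes null genes heterogeneous in the 4vs4 runs.

        Site effects are shared by both replicate pools of a site, so
        replicate re-selection cannot resample them; the instability they
        cause shows up as growing between-gene dispersion of the
        combination-averaged p-values.
        """
        from consensusde import (enumerate_combinations, filter_low_counts,
                                 pseudo_counts, rle_factors)
        between_gene_vars = []
        for site_sd in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(n_genes=300, seed=70, frac_de=0.0,
                                   site_sd=site_sd)
            counts, design, _ = simulate_dataset(cfg)
            sels = enumerate_combinations(design)[::16]   # 16 spread-out picks
            pmat = {}
            for sel in sels:
                sub = counts.subset_libraries(list(sel))
                filt = filter_low_counts(sub)
                fac = rle_factors(filt)
                ps = pseudo_counts(filt, fac)
                cat = design.category_of_library()
                labels = np.array([cat[l] for l in filt.library_ids])
                common = estimate_common_dispersion(ps, labels)
                _, p = nb_exact_test_batch(ps, np.flatnonzero(labels == "ancient"),
                                           np.flatnonzero(labels == "recent"),
                                           common)
                for g, val in zip(filt.gene_ids, p):
                    pmat.setdefault(g, []).append(val)
            means = [np.mean(v) for v in pmat.values() if len(v) == len(sels)]
            between_gene_vars.append(np.var(means))
        assert between_gene_vars[0] < between_gene_vars[1] < between_gene_vars[2]
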