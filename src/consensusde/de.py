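"""Negative-binomial testing machinery for the three DE strategies.

The count model is NB with mean mu and dispersion phi, var = mu + phi*mu^2.
Dispersions are estimated by conditional maximum likelihood on library-size
equalized pseudo-counts (conditioning on group totals removes the group
means, the approximately unbiased version of profiling them out), with
empirical-Bayes shrinkage of gene-wise values toward the common value via a
weighted-likelihood penalty. Two-group comparisons use the conditional
exact test (null distribution of one group's total given the grand total);
the nested-design comparison uses a log-link NB GLM fitted by IRLS with a
likelihood-ratio test; the random-effects strategy uses generalized least
squares on log-CPM with a single shared within-site correlation and
moderated t statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import gammaln, digamma, polygamma
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist
from scipy.stats import trim_mean

from .errors import DesignError, DomainError, ParameterError
from .io import StudyDesign

DISPERSION_MIN = 1e-8
DISPERSION_MAX = 10.0

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# dispersion estimation (conditional likelihood on pseudo-counts)


@dataclass
class DispersionEstimates:
    """Common, gene-wise and shrunk NB dispersions."""

    common: float
    genewise: np.ndarray
    shrunk: np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        eps = 1e-9
        for arr in (self.genewise, self.shrunk):
            a = np.asarray(arr)
            if np.any(a < DISPERSION_MIN - eps) or np.any(a > DISPERSION_MAX + eps):
                raise ParameterError("dispersions outside allowed bounds")


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in dict.fromkeys(labels.tolist())]


def _cml_loglik(pseudo: np.ndarray, phi: np.ndarray,
                groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB log-likelihood conditional on each group's total.

    ``phi`` may be scalar or per-gene. Terms constant in phi are dropped.
    """
    r = 1.0 / np.asarray(phi, dtype=float)
    r = np.atleast_1d(r).astype(float)
    if r.ndim == 1 and r.shape[0] == 1:
        r = np.full(pseudo.shape[0], r[0])
    ll = np.zeros(pseudo.shape[0])
    for idx in groups:
        m = len(idx)
        y = pseudo[:, idx]
        t = y.sum(axis=1)
        ll += (gammaln(y + r[:, None]).sum(axis=1)
               - m * gammaln(r)
               + gammaln(m * r)
               - gammaln(t + m * r))
    return ll


def _golden_max_vec(f, lo: np.ndarray, hi: np.ndarray, tol: float = 1e-6,
                    ) -> np.ndarray:
    """Vectorized golden-section maximization of f over per-gene [lo, hi]."""
    a = lo.copy()
    b = hi.copy()
    while np.max(b - a) > tol:
        x1 = b - _INVPHI * (b - a)
        x2 = a + _INVPHI * (b - a)
        f1 = f(x1)
        f2 = f(x2)
        move_right = f2 >= f1
        a = np.where(move_right, x1, a)
        b = np.where(move_right, b, x2)
    return (a + b) / 2.0


def estimate_common_dispersion(pseudo: np.ndarray, group_labels,
                               tol: float = 1e-6) -> float:
    """Single dispersion maximizing the summed conditional log-likelihood.

    Optimized by golden-section search on log(phi) over
    [log 1e-8, log 10] to the given tolerance.
    """
    pseudo = np.asarray(pseudo)
    if pseudo.shape[1] < 2:
        raise ParameterError("need at least two libraries")
    groups = _group_indices(group_labels)

    def objective(z: np.ndarray) -> np.ndarray:
        phi = np.exp(z[0])
        val = _cml_loglik(pseudo, phi, groups).sum()
        if not np.isfinite(val):
            raise ParameterError("non-finite dispersion likelihood")
        return np.array([val])

    lo = np.array([np.log(DISPERSION_MIN)])
    hi = np.array([np.log(DISPERSION_MAX)])
    z = _golden_max_vec(objective, lo, hi, tol=tol)
    return float(np.exp(z[0]))


def estimate_tagwise_dispersions(pseudo: np.ndarray, group_labels,
                                 common: float, prior_df: float = 10.0,
                                 grid_size: int = 257) -> DispersionEstimates:
    """Gene-wise dispersions shrunk toward the common value.

    Each gene maximizes its own conditional log-likelihood plus
    ``prior_df / residual_df`` times the across-gene mean log-likelihood
    (evaluated through a cubic-spline interpolant on a dense log-phi grid).
    prior_df = 0 gives the unpenalized per-gene MLE; prior_df -> infinity
    recovers the common value for every gene.
    """
    pseudo = np.asarray(pseudo)
    n_genes, n_libs = pseudo.shape
    groups = _group_indices(group_labels)
    residual_df = n_libs - len(groups)
    if residual_df <= 0:
        raise ParameterError("no residual degrees of freedom for dispersion")
    weight = float(prior_df) / residual_df

    z_lo, z_hi = np.log(DISPERSION_MIN), np.log(DISPERSION_MAX)
    grid = np.linspace(z_lo, z_hi, grid_size)
    mean_ll_grid = np.array(
        [_cml_loglik(pseudo, np.exp(z), groups).mean() for z in grid])
    mean_ll = CubicSpline(grid, mean_ll_grid)

    lo = np.full(n_genes, z_lo)
    hi = np.full(n_genes, z_hi)

    def genewise_obj(z: np.ndarray) -> np.ndarray:
        return _cml_loglik(pseudo, np.exp(z), groups)

    def shrunk_obj(z: np.ndarray) -> np.ndarray:
        return _cml_loglik(pseudo, np.exp(z), groups) + weight * mean_ll(z)

    genewise = np.exp(_golden_max_vec(genewise_obj, lo, hi))
    if weight == 0.0:
        shrunk = genewise.copy()
    else:
        shrunk = np.exp(_golden_max_vec(shrunk_obj, lo, hi))
    return DispersionEstimates(common=float(common), genewise=genewise,
                               shrunk=shrunk, prior_df=float(prior_df))


# ---------------------------------------------------------------------------
# conditional exact test


def nb_exact_test_batch(pseudo: np.ndarray, idx_a: np.ndarray,
                        idx_b: np.ndarray, dispersion,
                        max_flat: int = 5_000_000,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-group NB test for every gene of a pseudo-count matrix.

    Group totals A, B are formed from the equalized pseudo-counts; the null
    distribution of A given T = A + B is the convolution of NB totals
    (negative hypergeometric in A, free of the unknown common mean). The
    two-sided p-value sums outcomes whose conditional probability does not
    exceed the observed one (relative tie tolerance 1 + 1e-12). Positive
    log-fold-change means higher expression in group b.
    """
    pseudo = np.asarray(pseudo)
    n_genes = pseudo.shape[0]
    na, nb = len(idx_a), len(idx_b)
    if na == 0 or nb == 0:
        raise ParameterError("both groups must be non-empty")
    A = pseudo[:, idx_a].sum(axis=1).astype(np.int64)
    B = pseudo[:, idx_b].sum(axis=1).astype(np.int64)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    phi = np.clip(phi, DISPERSION_MIN, DISPERSION_MAX)
    log_fc = np.log2(((B + 0.5) / nb) / ((A + 0.5) / na))
    p_values = np.ones(n_genes)
    log_fc = np.where(A + B == 0, 0.0, log_fc)

    live = np.flatnonzero(A + B > 0)
    # chunk genes so the flattened outcome space stays bounded in memory
    start = 0
    while start < len(live):
        lengths = (A[live] + B[live] + 1).astype(np.int64)
        csum = np.cumsum(lengths[start:])
        stop = start + int(np.searchsorted(csum, max_flat) + 1)
        chunk = live[start:stop]
        p_values[chunk] = _exact_test_chunk(A[chunk], B[chunk], phi[chunk], na, nb)
        start = stop
    return log_fc, p_values


def _exact_test_chunk(A, B, phi, na, nb) -> np.ndarray:
    T = A + B
    r = 1.0 / phi
    ra = na * r
    rb = nb * r
    lengths = T + 1
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    total = int(lengths.sum())
    gene_f = np.repeat(np.arange(len(T)), lengths)
    a_f = np.arange(total) - offsets[gene_f]
    ta_f = T[gene_f] - a_f
    # grouped so that when ra == rb the weight is bitwise symmetric in a
    u = gammaln(a_f + ra[gene_f]) - gammaln(a_f + 1.0)
    v = gammaln(ta_f + rb[gene_f]) - gammaln(ta_f + 1.0)
    logw = u + v
    m = np.maximum.reduceat(logw, offsets)
    w = np.exp(logw - m[gene_f])
    z = np.add.reduceat(w, offsets)
    w_obs = w[offsets + A]
    included = w <= w_obs[gene_f] * (1.0 + 1e-12)
    p = np.add.reduceat(np.where(included, w, 0.0), offsets) / z
    return np.minimum(p, 1.0)


def nb_exact_test(group_a_counts, group_b_counts, factors=None,
                  dispersion: float = 0.1) -> tuple[float, float]:
    """Exact test for a single gene; see :func:`nb_exact_test_batch`.

    ``factors`` (optional :class:`NormalizationFactors` covering the a then
    b libraries, in order) equalizes library sizes via rounded pseudo-counts
    before the conditional test.
    """
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    y = np.concatenate([a, b])
    if factors is not None:
        eff = np.asarray(factors.effective_lib_sizes, dtype=float)
        y = np.round(y * (eff.mean() / eff))
    pseudo = y[None, :].astype(np.int64)
    idx_a = np.arange(len(a))
    idx_b = np.arange(len(a), len(y))
    lfc, p = nb_exact_test_batch(pseudo, idx_a, idx_b, dispersion)
    return float(lfc[0]), float(p[0])


# ---------------------------------------------------------------------------
# NB generalized linear model


@dataclass
class GlmFit:
    """Per-gene NB GLM fits (arrays stacked over genes)."""

    coefficients: np.ndarray   # genes x p
    fitted_means: np.ndarray   # genes x n
    deviance: np.ndarray       # genes
    converged: np.ndarray      # genes, bool


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    r = 1.0 / np.asarray(phi, dtype=float)
    if np.ndim(r) == 1:
        r = r[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (term1 - term2).sum(axis=1)


def fit_nb_glm(counts: np.ndarray, design_matrix: np.ndarray,
               offsets: np.ndarray, dispersion, max_iter: int = 100,
               tol: float = 1e-8) -> GlmFit:
    """Log-link NB regression by IRLS with step-halving.

    ``counts`` may be a vector (one gene) or a genes × libraries matrix;
    all genes share ``design_matrix`` (n × p, full rank) and ``offsets``
    (log effective library sizes). ``dispersion`` is scalar or per-gene.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    if y.shape[1] != n:
        raise DesignError("counts and design matrix disagree on library count")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")
    offsets = np.asarray(offsets, dtype=float)
    G = y.shape[0]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()

    # initialize from a log-linear least-squares fit
    z0 = np.log(y + 0.5) - offsets[None, :]
    beta = z0 @ np.linalg.pinv(X).T
    eta = beta @ X.T + offsets[None, :]
    mu = np.exp(np.clip(eta, -60, 60))
    dev = _nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi[:, None] * mu)          # working weights
        zwork = (eta - offsets[None, :]) + (y - mu) / np.maximum(mu, 1e-300)
        XtWX = np.einsum("ni,gn,nj->gij", X, w[active], X)
        XtWz = np.einsum("ni,gn,gn->gi", X, w[active], zwork[active])
        beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]

        # step-halving where the deviance would increase
        b_old = beta[active]
        b_try = beta_new
        dev_old = dev[active]
        for _half in range(25):
            eta_try = b_try @ X.T + offsets[None, :]
            mu_try = np.exp(np.clip(eta_try, -60, 60))
            dev_try = _nb_deviance(y[active], mu_try, phi[active])
            worse = dev_try > dev_old * (1 + 1e-12) + 1e-12
            if not worse.any():
                break
            b_try = np.where(worse[:, None], (b_try + b_old) / 2.0, b_try)
        beta[active] = b_try
        eta[active] = eta_try
        mu[active] = mu_try
        rel = np.abs(dev_old - dev_try) / (np.abs(dev_old) + 1.0)
        newly = np.flatnonzero(active)[rel < tol]
        dev[active] = dev_try
        converged[newly] = True

    mu = np.maximum(mu, 1e-300)
    return GlmFit(coefficients=beta, fitted_means=mu, deviance=dev,
                  converged=converged)


def lr_test(full: GlmFit, reduced: GlmFit, df: int) -> np.ndarray:
    """Likelihood-ratio p-values: reduced minus full deviance vs chi-square."""
    stat = reduced.deviance - full.deviance
    if np.any(stat < -1e-6):
        warnings.warn("negative LR statistic beyond tolerance; "
                      "a GLM fit likely failed to converge", RuntimeWarning)
    stat = np.maximum(stat, 0.0)
    return chi2_dist.sf(stat, df)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# shared within-site correlation strategy (random-effects analogue)


def _site_pairs(design: StudyDesign) -> list[np.ndarray]:
    """Column index pairs (pool 1, pool 2) per site, in site order."""
    t = design.table
    pairs = []
    for site in design.sites:
        rows = t.index[t["site"] == site].to_numpy()
        if len(rows) != 2:
            raise DesignError(f"site {site!r} has {len(rows)} replicate pools, "
                              "expected exactly 2")
        order = np.argsort(t.loc[rows, "pool_index"].to_numpy())
        pairs.append(rows[order])
    return pairs


def estimate_duplicate_correlation(log_cpm: np.ndarray,
                                   design: StudyDesign) -> float:
    """Single correlation shared by all genes between replicate pools of a site.

    Per gene the invasion-category means are removed, the intra-site
    correlation of the residual replicate pairs is computed (moment-based
    intraclass correlation), and gene-level values are pooled on the
    Fisher-z scale with a 5%-trimmed mean.
    """
    E = np.asarray(log_cpm, dtype=float)
    pairs = _site_pairs(design)
    cats = design.table["invasion_category"].to_numpy()
    resid = E.copy()
    for cat in dict.fromkeys(cats.tolist()):
        cols = np.flatnonzero(cats == cat)
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    y1 = np.stack([resid[:, p[0]] for p in pairs], axis=1)   # genes x sites
    y2 = np.stack([resid[:, p[1]] for p in pairs], axis=1)
    n_sites = y1.shape[1]
    n_cats = len(dict.fromkeys(cats.tolist()))
    means = (y1 + y2) / 2.0
    msb = 2.0 * (means ** 2).sum(axis=1) / (n_sites - n_cats)
    msw = ((y1 - y2) ** 2 / 2.0).sum(axis=1) / n_sites
    denom = msb + msw
    icc = np.where(denom > 0, (msb - msw) / np.where(denom > 0, denom, 1.0), 0.0)
    icc = np.clip(icc, -0.9999, 0.9999)
    pooled = trim_mean(np.arctanh(icc), 0.05)
    return float(np.clip(np.tanh(pooled), -0.99, 0.99))


@dataclass
class CorrelationModelFit:
    """GLS fits with a shared within-site correlation and moderated t."""

    consensus_correlation: float
    gls_coefficients: np.ndarray   # genes x 2 (intercept, invasion contrast)
    residual_var: np.ndarray
    moderated_t: np.ndarray
    p_value: np.ndarray
    prior_df_eb: float
    prior_var_eb: float
    residual_df: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to observed sample variances.

    Works on log variances: the excess spread of log s^2 beyond the
    trigamma(df/2) sampling component determines the prior degrees of
    freedom; zero or negative excess means an effectively infinite prior.
    Genes with non-positive variance (zero residual df) are excluded.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def gls_moderated_test(log_cpm: np.ndarray, design: StudyDesign, rho: float,
                       prior_df_eb: float | None = None,
                       prior_var_eb: float | None = None) -> CorrelationModelFit:
    """Invasion-category contrast by GLS with block 2x2 replicate correlation.

    The covariance of the 16 log-CPM values of a gene is sigma_g^2 times a
    block-diagonal correlation matrix with off-diagonal ``rho`` inside each
    site's replicate pair. Data and design are whitened by the block
    Cholesky inverse, the contrast is estimated by OLS on the whitened
    system, and residual variances are shrunk toward an empirical-Bayes
    prior (moment-matched scaled-F) before forming moderated t statistics
    with d0 + d_g degrees of freedom. Passing ``prior_df_eb=0`` disables
    moderation (ordinary t).
    """
    if not -1.0 < rho < 1.0 or abs(rho) >= 1.0 - 1e-12:
        raise DomainError("rho must lie strictly inside (-1, 1)")
    E = np.asarray(log_cpm, dtype=float)
    pairs = _site_pairs(design)
    n = E.shape[1]
    cats = design.table["invasion_category"].to_numpy()
    X = np.column_stack([np.ones(n), (cats == "recent").astype(float)])

    # block Cholesky whitener: L = [[1,0],[rho, sqrt(1-rho^2)]], apply L^-1
    s = np.sqrt(1.0 - rho * rho)
    W = np.eye(n)
    for p in pairs:
        i, j = int(p[0]), int(p[1])
        W[j, i] = -rho / s
        W[j, j] = 1.0 / s
    Xw = W @ X
    Ew = E @ W.T

    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    H = XtX_inv @ Xw.T
    beta = Ew @ H.T                               # genes x 2
    resid = Ew - beta @ Xw.T
    df_resid = n - X.shape[1]
    s2 = (resid ** 2).sum(axis=1) / df_resid

    if prior_df_eb is None or prior_var_eb is None:
        d0, s0_sq = fit_f_dist(s2, df_resid)
        if prior_df_eb is not None:
            d0 = prior_df_eb
        if prior_var_eb is not None:
            s0_sq = prior_var_eb
    else:
        d0, s0_sq = prior_df_eb, prior_var_eb

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    c11 = XtX_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[:, 1] / np.sqrt(post_var * c11)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    return CorrelationModelFit(
        consensus_correlation=float(rho),
        gls_coefficients=beta,
        residual_var=s2,
        moderated_t=tstat,
        p_value=pvals,
        prior_df_eb=float(d0),
        prior_var_eb=float(s0_sq),
        residual_df=float(df_resid),
    )
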