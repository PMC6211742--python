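"""Zero-inflated negative-binomial likelihood-ratio differential expression.

For each gene the UMI counts of two cell groups are modeled as

    y_i ~ pi_i * delta_0 + (1 - pi_i) * NB(mu_i, theta)
    logit pi_i = gamma0 + gamma1 * g_i
    log mu_i   = beta0 + beta1 * g_i + offset_i

with ``g_i`` the group indicator and ``offset_i = log`` total UMIs of the
cell, so the count component models depth-adjusted expression and the
zero component models group-dependent dropout.  Differential expression is
a likelihood-ratio test of the full model against the null with
``gamma1 = beta1 = 0`` (chi-square, 2 df; 1 df when the data contain no
zeros and the zero component is disabled).

The biomarker rules applied on top of the test: adjusted p < 0.05 and
average log2 fold change > 1 define differential expression; candidate
biomarkers must additionally be detected in at least 50% of the defining
cluster with at least a 50-point detection-fraction margin over the
comparison group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from serocell.core import CountMatrix, SerocellError
from serocell.preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

_LAMBDA_FLOOR = -1e-6  # LRT statistics below this flag non-convergence


@dataclass
class ZINBFit:
    """Maximum-likelihood ZINB regression fit for one gene."""

    gamma0: float  # zero-component intercept (logit scale)
    gamma1: float  # zero-component group coefficient
    beta0: float  # count-component intercept (log scale)
    beta1: float  # count-component group coefficient
    log_theta: float
    loglik: float
    converged: bool
    zero_inflated: bool = True

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))


@dataclass
class DETestResult:
    """Per-gene differential-expression record (printed-table columns)."""

    gene: str
    avg_log2fc: float
    pct_in: float
    pct_out: float
    p_raw: float
    p_adj: float


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _nb_logpmf(y: np.ndarray, log_mu: np.ndarray, theta: float) -> np.ndarray:
    log_theta_mu = np.logaddexp(np.log(theta), log_mu)  # log(theta + mu)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (np.log(theta) - log_theta_mu)
        + y * (log_mu - log_theta_mu)
    )


def zinb_loglik(
    params: tuple,
    y: np.ndarray,
    group: np.ndarray,
    offset: np.ndarray | None = None,
    zero_inflated: bool = True,
) -> float:
    """Log-likelihood of the ZINB regression model.

    ``params`` is ``(gamma0, gamma1, beta0, beta1, theta)``; with
    ``zero_inflated=False`` the zero component is dropped (pi = 0) and
    ``params`` is ``(beta0, beta1, theta)``.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.round(y)):
        raise SerocellError("counts must be non-negative integers")
    y = y.astype(float)
    group = np.asarray(group, dtype=float)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if zero_inflated:
        gamma0, gamma1, beta0, beta1, theta = params
    else:
        beta0, beta1, theta = params
        gamma0 = gamma1 = None
    if theta <= 0:
        raise SerocellError("dispersion theta must be positive")
    log_mu = beta0 + beta1 * group + offset
    nb = _nb_logpmf(y, log_mu, theta)
    if not zero_inflated:
        return float(nb.sum())
    eta = gamma0 + gamma1 * group
    log_pi = -_softplus(-eta)
    log_1mpi = -_softplus(eta)
    zero = y == 0
    ll = np.where(
        zero,
        np.logaddexp(log_pi, log_1mpi + nb),
        log_1mpi + nb,
    )
    return float(ll.sum())


def _negll_grad(
    params: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    offset: np.ndarray,
    zero_inflated: bool,
    with_group: bool,
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in the fitting parameterization.

    Parameters are ``[gamma..., beta..., tau]`` with ``tau = log theta``;
    the gamma block is absent when ``zero_inflated`` is False and the group
    coefficients are absent when ``with_group`` is False.
    """
    i = 0
    if zero_inflated:
        gamma0 = params[i]; i += 1
        gamma1 = params[i] if with_group else 0.0
        i += with_group
    beta0 = params[i]; i += 1
    beta1 = params[i] if with_group else 0.0
    i += with_group
    tau = params[i]
    theta = np.exp(tau)

    xi = beta0 + beta1 * group + offset  # log mu
    log_theta_mu = np.logaddexp(tau, xi)
    mu_frac = np.exp(xi - log_theta_mu)  # mu / (theta + mu)
    theta_frac = np.exp(tau - log_theta_mu)  # theta / (theta + mu)

    zero = y == 0
    pos = ~zero
    yp = y[pos]

    # count component pieces
    nb0 = theta * (tau - log_theta_mu[zero])  # log NB(0 | mu, theta)
    dnb0_dxi = -theta * mu_frac[zero]
    dnb0_dtau = theta * (tau + 1.0 - log_theta_mu[zero] - theta_frac[zero])

    ll = 0.0
    dxi = np.zeros_like(y, dtype=float)
    dtau_terms = np.zeros_like(y, dtype=float)
    if yp.size:
        lp = log_theta_mu[pos]
        ll += float(
            np.sum(
                gammaln(yp + theta)
                - gammaln(theta)
                - gammaln(yp + 1)
                + theta * (tau - lp)
                + yp * (xi[pos] - lp)
            )
        )
        dxi[pos] = yp - (yp + theta) * mu_frac[pos]
        dtau_terms[pos] = theta * (
            digamma(yp + theta) - digamma(theta) + tau + 1.0 - lp - (yp + theta) * theta_frac[pos] / theta
        )

    if zero_inflated:
        eta = gamma0 + gamma1 * group
        log_pi = -_softplus(-eta)
        log_1mpi = -_softplus(eta)
        pi = np.exp(log_pi)
        deta = np.zeros_like(y, dtype=float)
        if np.any(zero):
            lz = np.logaddexp(log_pi[zero], log_1mpi[zero] + nb0)
            ll += float(lz.sum())
            w_nb = np.exp(log_1mpi[zero] + nb0 - lz)  # (1-pi) A / D
            # d/deta log D = pi (1-pi) (1 - A) / D with A = exp(nb0), D = exp(lz)
            deta[zero] = pi[zero] * (1.0 - pi[zero]) * (1.0 - np.exp(nb0)) * np.exp(-lz)
            dxi[zero] = w_nb * dnb0_dxi
            dtau_terms[zero] = w_nb * dnb0_dtau
        ll += float(log_1mpi[pos].sum())
        deta[pos] = -pi[pos]
        grad = []
        grad.append(deta.sum())
        if with_group:
            grad.append((deta * group).sum())
    else:
        if np.any(zero):
            ll += float(nb0.sum())
            dxi[zero] = dnb0_dxi
            dtau_terms[zero] = dnb0_dtau
        grad = []

    grad.append(dxi.sum())
    if with_group:
        grad.append((dxi * group).sum())
    grad.append(dtau_terms.sum())
    return -ll, -np.asarray(grad)


def _moment_start(
    y: np.ndarray, group: np.ndarray, offset: np.ndarray, with_group: bool
) -> tuple[float, float, float]:
    """Method-of-moments (beta0, beta1, tau) start."""
    rates = y / np.exp(offset)
    eps = 1e-8
    if with_group:
        m0 = rates[group == 0].mean()
        m1 = rates[group == 1].mean()
        beta0 = np.log(m0 + eps)
        beta1 = np.log(m1 + eps) - beta0
    else:
        beta0 = np.log(rates.mean() + eps)
        beta1 = 0.0
    m, v = y.mean(), y.var()
    theta = m * m / (v - m) if v > m else 100.0
    tau = float(np.log(np.clip(theta, 0.05, 1e4)))
    return float(beta0), float(beta1), tau


def fit_zinb(
    y: np.ndarray,
    group: np.ndarray,
    offset: np.ndarray | None = None,
    zero_inflated: bool | None = None,
    with_group: bool = True,
) -> ZINBFit:
    """Fit the ZINB regression by quasi-Newton maximum likelihood.

    Three deterministic starts are tried (moment-based, zero-heavy and
    NB-leaning) and the best converged fit returned.  When ``y`` contains
    no zeros the zero component is fixed at pi = 0 and a plain NB model is
    fitted.  A ``y`` of all zeros is degenerate: the returned fit is
    flagged unconverged with NaN log-likelihood.
    """
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise SerocellError("counts must be non-negative integers")
    y = y.astype(float)
    group = np.asarray(group, dtype=float)
    if with_group:
        for gval in (0, 1):
            if (group == gval).sum() < 3:
                raise SerocellError("need at least 3 observations per group")
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if not np.any(y > 0):
        return ZINBFit(0.0, 0.0, -np.inf, 0.0, 0.0, np.nan, False, True)
    if zero_inflated is None:
        zero_inflated = bool(np.any(y == 0))

    beta0, beta1, tau = _moment_start(y, group, offset, with_group)
    zero_excess = 0.3
    if zero_inflated:
        nb_zero = float(np.exp(-np.exp(tau) * np.log1p(np.exp(beta0) * np.exp(offset).mean() / np.exp(tau))))
        zero_excess = float(np.clip((y == 0).mean() - nb_zero, 0.02, 0.95))
    g0 = float(np.log(zero_excess / (1 - zero_excess)))

    if zero_inflated:
        starts = [
            [g0] + ([0.0] if with_group else []) + [beta0] + ([beta1] if with_group else []) + [tau],
            [0.0] + ([0.0] if with_group else []) + [beta0] + ([beta1] if with_group else []) + [0.0],
            [-4.0] + ([0.0] if with_group else []) + [beta0] + ([beta1] if with_group else []) + [np.log(10.0)],
        ]
    else:
        starts = [
            [beta0] + ([beta1] if with_group else []) + [tau],
            [beta0] + ([beta1] if with_group else []) + [0.0],
            [beta0] + ([beta1] if with_group else []) + [np.log(10.0)],
        ]

    n_gamma = (1 + with_group) if zero_inflated else 0
    bounds = [(-15.0, 15.0)] * n_gamma + [(-30.0, 30.0)] * (1 + with_group) + [(-7.0, 12.0)]

    best = None
    best_converged = False
    for x0 in starts:
        res = minimize(
            _negll_grad,
            np.asarray(x0, dtype=float),
            args=(y, group, offset, zero_inflated, with_group),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10 or (res.success and not best_converged and res.fun < best.fun + 1e-6):
            best = res
            best_converged = bool(res.success)
    if best is None:
        return ZINBFit(0.0, 0.0, 0.0, 0.0, 0.0, np.nan, False, zero_inflated)

    p = best.x
    i = 0
    if zero_inflated:
        gamma0 = p[i]; i += 1
        gamma1 = p[i] if with_group else 0.0
        i += with_group
    else:
        gamma0, gamma1 = -np.inf, 0.0
    beta0 = p[i]; i += 1
    beta1 = p[i] if with_group else 0.0
    i += with_group
    tau = p[i]
    return ZINBFit(
        float(gamma0),
        float(gamma1),
        float(beta0),
        float(beta1),
        float(tau),
        -float(best.fun),
        best_converged,
        zero_inflated,
    )


def _resolve_cells(barcodes: list[str], cells) -> np.ndarray:
    """Map barcode names, indices or a boolean mask to integer indices."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        return np.flatnonzero(cells)
    if np.issubdtype(cells.dtype, np.integer):
        return cells
    pos = {bc: j for j, bc in enumerate(barcodes)}
    missing = [c for c in cells if c not in pos]
    if missing:
        raise SerocellError(f"unknown barcodes: {missing[:3]}")
    return np.array([pos[c] for c in cells], dtype=int)


def lrt_de(
    counts: CountMatrix,
    norm: NormalizedMatrix,
    cluster_cells,
    comparison_cells,
    min_pct: float = 0.1,
    adjust: str = "bonferroni",
    pseudocount: float = 1.0,
) -> tuple[list[DETestResult], list[str]]:
    """ZINB likelihood-ratio DE of a cluster against a comparison group.

    Cells may be given as barcode lists, integer indices or boolean masks
    over the matrix columns.  Genes detected in fewer than ``min_pct`` of
    the cells of *both* groups are skipped and returned separately.  The
    fold change is computed from the log-normalized matrix as
    ``log2((mean(expm1 x_in) + c) / (mean(expm1 x_out) + c))`` with
    pseudocount ``c``; detection fractions come from the raw counts.

    Returns ``(results, skipped_genes)``.
    """
    idx_in = _resolve_cells(counts.barcodes, cluster_cells)
    idx_out = _resolve_cells(counts.barcodes, comparison_cells)
    if idx_in.size == 0 or idx_out.size == 0:
        raise SerocellError("both cell groups must be non-empty")
    if np.intersect1d(idx_in, idx_out).size:
        raise SerocellError("cluster and comparison groups overlap")

    norm_pos = {g: i for i, g in enumerate(norm.genes)}
    missing = [g for g in counts.genes if g not in norm_pos]
    if missing:
        raise SerocellError(f"genes absent from normalized matrix: {missing[:3]}")
    bc_pos = {bc: j for j, bc in enumerate(norm.barcodes)}
    nidx_in = np.array([bc_pos[counts.barcodes[j]] for j in idx_in])
    nidx_out = np.array([bc_pos[counts.barcodes[j]] for j in idx_out])

    sub = counts.counts[:, np.concatenate([idx_in, idx_out])].toarray()
    n_in = idx_in.size
    y_in, y_out = sub[:, :n_in], sub[:, n_in:]
    group = np.concatenate([np.ones(n_in), np.zeros(idx_out.size)])
    totals = counts.total_umis().astype(float)
    offset = np.log(np.concatenate([totals[idx_in], totals[idx_out]]))

    expr = np.expm1(norm.values)
    results: list[DETestResult] = []
    skipped: list[str] = []
    raw_p: list[float] = []
    for gi, gene in enumerate(counts.genes):
        pct_in = float((y_in[gi] > 0).mean())
        pct_out = float((y_out[gi] > 0).mean())
        if pct_in < min_pct and pct_out < min_pct:
            skipped.append(gene)
            continue
        y = sub[gi]
        zi = bool(np.any(y == 0))
        full = fit_zinb(y, group, offset, zero_inflated=zi, with_group=True)
        null = fit_zinb(y, group, offset, zero_inflated=zi, with_group=False)
        lam = 2.0 * (full.loglik - null.loglik)
        df = 2 if zi else 1
        if not np.isfinite(lam) or lam < _LAMBDA_FLOOR or not (full.converged and null.converged):
            p = np.nan
        else:
            p = float(chi2.sf(max(lam, 0.0), df))
        ni = norm_pos[gene]
        m_in = float(expr[ni, nidx_in].mean())
        m_out = float(expr[ni, nidx_out].mean())
        lfc = float(np.log2((m_in + pseudocount) / (m_out + pseudocount)))
        results.append(DETestResult(gene, lfc, pct_in, pct_out, p, np.nan))
        raw_p.append(p)

    _adjust_pvalues(results, adjust)
    if skipped:
        logger.info("lrt_de: skipped %d genes below %.0f%% detection", len(skipped), 100 * min_pct)
    return results, skipped


def _adjust_pvalues(results: list[DETestResult], method: str) -> None:
    tested = [r for r in results if np.isfinite(r.p_raw)]
    if not tested:
        return
    p = np.array([r.p_raw for r in tested])
    if method == "bonferroni":
        adj = np.minimum(p * len(tested), 1.0)
    elif method == "bh":
        adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise SerocellError(f"unknown adjustment method {method!r}")
    for r, pa in zip(tested, adj):
        r.p_adj = float(pa)


def biomarker_filter(
    results: list[DETestResult],
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    min_pct: float = 0.5,
    min_pct_diff: float = 0.5,
) -> list[DETestResult]:
    """Apply the differential-expression and biomarker thresholds.

    Keeps records with adjusted p < ``alpha``, average log2 fold change
    > ``min_lfc``, detection in at least ``min_pct`` of the defining
    cluster, and a detection-fraction margin of at least ``min_pct_diff``
    over the comparison group.  Input order is preserved; records with
    NaN p never pass.
    """
    return [
        r
        for r in results
        if np.isfinite(r.p_adj)
        and r.p_adj < alpha
        and r.avg_log2fc > min_lfc
        and r.pct_in >= min_pct
        and (r.pct_in - r.pct_out) >= min_pct_diff
    ]


def de_filter(
    results: list[DETestResult], alpha: float = 0.05, min_lfc: float = 1.0
) -> list[DETestResult]:
    """The plain DE rule (adjusted p and fold change, no detection rules)."""
    return biomarker_filter(results, alpha, min_lfc, min_pct=0.0, min_pct_diff=-1.0)
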