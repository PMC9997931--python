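"""Wald-test detector on the mean/variance-ratio NB reparameterization.

The NB is reparameterized so that ``Var = phi * mu`` with ``phi > 1``
(equivalently, canonical dispersion ``alpha = (phi - 1) / mu``); log-linear
submodels for ``mu`` (with offset) and ``phi`` are fitted by maximum
likelihood under the linear constraints ``log phi > 0`` using a log-barrier
augmented quasi-Newton scheme.  Condition coefficients are tested with Wald
statistics against ``log(fold-change threshold)``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, gammaln

from dispersim.detectors.base import DetectorResult, GroupDesign, build_design
from dispersim.preprocess import NormalizationFactors
from dispersim.simdata import CountDataset

__all__ = ["mdseq_outlier_trim", "mdseq_mean_dispersion_test"]

LN2 = np.log(2.0)
BARRIER_STAGES = (1e-1, 1e-3, 1e-5)
ETA_PHI_MIN = 1e-8  # phi > 1 boundary on the log-phi scale
BOUNDARY_TOL = 1e-3


def mdseq_outlier_trim(
    y: np.ndarray,
    size_factors: np.ndarray,
    condition: np.ndarray,
    k: float = 5.0,
    min_retained: int = 1,
) -> np.ndarray:
    """Keep-mask for one gene: drop counts above ``median + k * MAD``.

    Normalized values (count / size factor) are screened per condition;
    removal is capped so that at least ``min_retained`` samples remain per
    condition, dropping the most extreme values first.  A zero MAD disables
    trimming for that condition.
    """
    if min_retained < 1:
        raise ValueError("min_retained must be >= 1")
    y = np.asarray(y, dtype=float)
    keep = np.ones(y.size, dtype=bool)
    v = y / size_factors
    for level in np.unique(condition):
        mask = condition == level
        vals = v[mask]
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        if mad <= 0:
            continue
        over = vals > med + k * mad
        n_removable = max(int(mask.sum()) - min_retained, 0)
        if over.sum() > n_removable:
            order = np.argsort(vals)[::-1]
            allowed = set(order[:n_removable])
            over = np.array([o and i in allowed for i, o in enumerate(over)])
        idx = np.flatnonzero(mask)
        keep[idx[over]] = False
    return keep


def _negloglik_grad(params, y, X, Z, offset, barrier, Zu):
    """Penalized negative log-likelihood for the Var = phi*mu model."""
    k = X.shape[1]
    beta, gamma = params[:k], params[k:]
    eta_phi_u = Zu @ gamma
    if (eta_phi_u <= ETA_PHI_MIN).any():
        # infeasible: large value with a gradient pushing back into phi > 1
        viol = np.clip(ETA_PHI_MIN - eta_phi_u, 0, None)
        grad = np.concatenate([np.zeros(k), -(Zu.T @ (viol > 0).astype(float))])
        return 1e12 * (1.0 + viol.sum()), 1e12 * grad
    eta_mu = np.clip(X @ beta + offset, -30.0, 30.0)
    eta_phi = Z @ gamma
    mu = np.exp(eta_mu)
    phi = np.exp(eta_phi)
    r = mu / (phi - 1.0)
    ll = np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    d_mu = y / np.where(mu > 0, mu, 1.0) * (y > 0) - (y + r) / (mu + r)
    d_r = digamma(y + r) - digamma(r) + np.log(r / (r + mu)) + 1.0 - (y + r) / (r + mu)
    d_eta_mu = mu * d_mu + r * d_r
    d_eta_phi = -r * phi / (phi - 1.0) * d_r
    nll = -ll
    grad = -np.concatenate([X.T @ d_eta_mu, Z.T @ d_eta_phi])
    if barrier > 0:
        nll -= barrier * np.sum(np.log(eta_phi_u))
        grad -= barrier * np.concatenate([np.zeros(k), Zu.T @ (1.0 / eta_phi_u)])
    return float(nll), grad


def _numeric_hessian(x0, args, eps=1e-5):
    n = x0.size
    H = np.empty((n, n))
    for i in range(n):
        step = eps * max(1.0, abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (_negloglik_grad(xp, *args)[1] - _negloglik_grad(xm, *args)[1]) / (
            2 * step
        )
    return 0.5 * (H + H.T)


def _fit_gene(y, X, Z, offset, g1, g2):
    """Barrier-augmented ML fit for one gene; returns (params, cov, flags)."""
    s = np.exp(offset - offset.mean())
    v = y / s
    m1 = max(v[g1].mean(), 1e-3)
    m2 = max(v[g2].mean(), 1e-3)
    phi1 = max(v[g1].var(ddof=1) / m1 if g1.sum() > 1 else 1.5, 1.05)
    phi2 = max(v[g2].var(ddof=1) / m2 if g2.sum() > 1 else 1.5, 1.05)
    k = X.shape[1]
    beta0 = np.zeros(k)
    beta0[0] = np.log(m1) - offset.mean()
    beta0[1] = np.log(m2 / m1)
    gamma0 = np.zeros(Z.shape[1])
    gamma0[0] = np.log(phi1)
    gamma0[1] = np.log(phi2) - np.log(phi1)
    params = np.concatenate([beta0, gamma0])

    Zu = np.unique(Z, axis=0)
    # lift the dispersion intercept if the start is infeasible
    slack = (Zu @ gamma0).min()
    if slack <= ETA_PHI_MIN:
        params[k] += ETA_PHI_MIN - slack + 0.1

    res = None
    for barrier in BARRIER_STAGES:
        res = optimize.minimize(
            _negloglik_grad,
            params,
            args=(y, X, Z, offset, barrier, Zu),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-12},
        )
        params = res.x
    eta_phi_u = Zu @ params[k:]
    boundary = bool((eta_phi_u < BOUNDARY_TOL).any())
    converged = bool(np.isfinite(res.fun) and res.fun < 1e11)
    cov = None
    if converged and not boundary:
        H = _numeric_hessian(params, (y, X, Z, offset, 0.0, Zu))
        try:
            cov = np.linalg.inv(H)
            if (np.diag(cov) <= 0).any():
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    return params, cov, converged, boundary


def _threshold_wald_p(coef: float, se: float, log_threshold: float) -> float:
    """Wald p against a fold-change threshold; tau = 1 is the plain test."""
    z = (abs(coef) - log_threshold) / se
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def mdseq_mean_dispersion_test(
    dataset: CountDataset,
    factors: NormalizationFactors,
    design: GroupDesign | None = None,
    fc_threshold_mean: float = 1.0,
    fc_threshold_disp: float = 1.0,
    trim_outliers: bool = True,
    trim_k: float = 5.0,
    min_retained: int = 1,
) -> DetectorResult:
    """Per-gene Wald tests of the condition effect on mean and on variance/mean.

    ``log2_disp_fc`` is reported on the phi (variance over mean) scale.
    Constraint-boundary and non-converged fits carry p = 1 and are flagged.
    """
    if fc_threshold_mean < 1 or fc_threshold_disp < 1:
        raise ValueError("fold-change thresholds must be >= 1")
    if design is None:
        design = build_design(dataset, factors, use_batch=True)
    X = design.matrix(include_condition=True)
    Z = X.copy()
    offset = design.offset
    g1, g2 = design.group_masks()
    k = X.shape[1]
    size = np.exp(offset - offset.mean())

    n_genes = dataset.n_genes
    out = {
        name: np.zeros(n_genes)
        for name in ("log2_mean_fc", "log2_disp_fc", "stat_mean", "stat_disp")
    }
    p_mean = np.ones(n_genes)
    p_disp = np.ones(n_genes)
    converged = np.ones(n_genes, dtype=bool)

    log_tau_mean = np.log(fc_threshold_mean)
    log_tau_disp = np.log(fc_threshold_disp)

    for i in range(n_genes):
        y = dataset.counts[i].astype(float)
        if trim_outliers:
            keep = mdseq_outlier_trim(
                y, size, design.condition, k=trim_k, min_retained=min_retained
            )
        else:
            keep = np.ones(y.size, dtype=bool)
        params, cov, conv, boundary = _fit_gene(
            y[keep], X[keep], Z[keep], offset[keep], g1[keep], g2[keep]
        )
        beta_c, gamma_c = params[1], params[k + 1]
        out["log2_mean_fc"][i] = beta_c / LN2
        out["log2_disp_fc"][i] = gamma_c / LN2
        if not conv or boundary or cov is None:
            converged[i] = False
            continue
        se_mean = np.sqrt(cov[1, 1])
        se_disp = np.sqrt(cov[k + 1, k + 1])
        out["stat_mean"][i] = beta_c / se_mean
        out["stat_disp"][i] = gamma_c / se_disp
        p_mean[i] = _threshold_wald_p(beta_c, se_mean, log_tau_mean)
        p_disp[i] = _threshold_wald_p(gamma_c, se_disp, log_tau_disp)

    return DetectorResult(
        gene_ids=list(dataset.gene_ids),
        method="mdseq",
        log2_mean_fc=out["log2_mean_fc"],
        log2_disp_fc=out["log2_disp_fc"],
        stat_mean=out["stat_mean"],
        stat_disp=out["stat_disp"],
        p_mean=p_mean,
        p_disp=p_disp,
        converged=converged,
    )
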