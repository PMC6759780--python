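"""Whole-genome prediction models: multi-kernel GBLUP and BayesC.

The GBLUP family fits y = X beta + sum_k u_k + eps with u_k ~ N(0, G_k
sigma_k^2) for any combination of additive, dominance and
additive-by-additive kernels (models A, A+AA, A+D, A+D+AA), by Gibbs
sampling on the eigen-representation of each kernel: u_k = U_k
diag(sqrt(lambda_k)) alpha_k with alpha_k ~ N(0, sigma_k^2 I).  Because the
eigenvectors are orthonormal, every alpha block has a diagonal conditional
posterior and sweeps are O(n q).  Variances carry scaled-inverse-chi-square
priors (df 5, scale chosen so the prior modes split half the phenotypic
variance equally across terms, the remaining half going to the residual —
the usual default of Bayesian whole-genome regression software).  Masked
phenotypes (the testing fold) are imputed each sweep, so prediction follows
the joint-kernel masked-phenotype scheme.

A fast REML path handles the single-kernel model (profile likelihood over
heritability on the kernel eigendecomposition) and serves as the
deterministic cross-check of the sampler.  BayesC places a common-variance
spike-and-slab prior on marker effects with Beta-prior inclusion
probability; fixed effects (e.g. population-structure PCs) enter by a flat
prior in both families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kernels import Kernel
from .simdata import MISSING

__all__ = [
    "FitResult",
    "fit_multikernel_gibbs",
    "fit_gblup_reml",
    "fit_bayesc",
    "fit_g_plus_pc",
    "variance_proportions",
]


@dataclass
class FitResult:
    """Variance components, fixed effects and genetic-value predictions."""

    varcomps: dict  # component name -> posterior (or REML) mean
    gebv: pd.DataFrame  # index individual, one column per component + total
    beta: np.ndarray
    mu: float
    draws: pd.DataFrame | None = None  # thinned posterior draws of variances
    settings: dict = field(default_factory=dict)
    marker_effects: np.ndarray | None = None

    def proportions(self) -> pd.DataFrame:
        return variance_proportions(self)


def _prepare_kernels(kernels) -> list[Kernel]:
    ks = [k if isinstance(k, Kernel) else Kernel(k, [str(i) for i in range(len(k))], "additive")
          for k in kernels]
    if not ks:
        raise ValueError("at least one kernel required")
    return ks


def fit_multikernel_gibbs(
    y,
    kernels,
    X: np.ndarray | None = None,
    iters: int = 10_000,
    burnin: int = 5_000,
    thin: int = 5,
    prior_df: float = 5.0,
    seed: int | None = None,
    keep_u_draws: bool = False,
) -> FitResult:
    """Gibbs sampler for the multi-kernel GBLUP model.

    y may contain NaN for masked (testing) individuals, whose genotypes are
    present in the kernels; masked values are imputed each sweep.  Seeded
    chains are bit-reproducible.
    """
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    ks = _prepare_kernels(kernels)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if any(k.n != n for k in ks):
        raise ValueError("kernel size does not match phenotype length")
    rng = np.random.default_rng(seed)
    mask = np.isnan(y)
    obs = ~mask
    if obs.sum() < 3:
        raise ValueError("too few observed phenotypes")

    X = X if X is not None else np.ones((n, 1))
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    Lx = np.linalg.cholesky(np.linalg.inv(XtX))

    # eigen-representations; small negative eigenvalues beyond tolerance -> error
    Bs, lams = [], []
    for k in ks:
        lam, U = np.linalg.eigh(k.matrix)
        if lam[0] < -1e-6 * max(lam[-1], 1.0):
            raise ValueError(f"kernel '{k.kind}' is not positive semidefinite")
        keep = lam > 1e-10 * max(lam[-1], 1.0)
        lam = lam[keep]
        Bs.append(U[:, keep] * np.sqrt(lam)[None, :])
        lams.append(lam)

    vy = float(np.var(y[obs]))
    K = len(ks)
    s0_g = 0.5 * vy / K * (prior_df + 2.0) / prior_df
    s0_e = 0.5 * vy * (prior_df + 2.0) / prior_df

    sig = np.full(K, 0.5 * vy / K)
    sig_e = 0.5 * vy
    alphas = [np.zeros(B.shape[1]) for B in Bs]
    us = [np.zeros(n) for _ in ks]
    beta = np.zeros(X.shape[1])
    y_cur = y.copy()
    y_cur[mask] = np.nanmean(y)

    names = []
    seen: dict[str, int] = {}
    for k in ks:
        seen[k.kind] = seen.get(k.kind, 0) + 1
        names.append(k.kind if seen[k.kind] == 1 else f"{k.kind}{seen[k.kind]}")

    kept_draws = []
    u_sums = [np.zeros(n) for _ in ks]
    beta_sum = np.zeros(X.shape[1])
    n_kept_mean = 0
    u_draws: list[np.ndarray] = []

    for it in range(iters):
        fixed = X @ beta
        total_u = np.sum(us, axis=0)
        # fixed effects
        r = y_cur - total_u
        bhat = np.linalg.solve(XtX, X.T @ r)
        beta = bhat + np.sqrt(sig_e) * (Lx @ rng.standard_normal(X.shape[1]))
        fixed = X @ beta
        # kernel blocks
        for k in range(K):
            r_k = y_cur - fixed - (total_u - us[k])
            z = Bs[k].T @ r_k
            prec = lams[k] / sig_e + 1.0 / sig[k]
            mean = (z / sig_e) / prec
            alphas[k] = mean + rng.standard_normal(len(prec)) / np.sqrt(prec)
            new_u = Bs[k] @ alphas[k]
            total_u += new_u - us[k]
            us[k] = new_u
        # variances
        for k in range(K):
            ssq = float(alphas[k] @ alphas[k])
            df = prior_df + len(alphas[k])
            sig[k] = (prior_df * s0_g + ssq) / rng.chisquare(df)
        e = y_cur - fixed - total_u
        sig_e = (prior_df * s0_e + float(e @ e)) / rng.chisquare(prior_df + n)
        # impute masked phenotypes
        if mask.any():
            mu_miss = (fixed + total_u)[mask]
            y_cur[mask] = mu_miss + np.sqrt(sig_e) * rng.standard_normal(mask.sum())

        if it >= burnin and (it - burnin) % thin == 0:
            kept_draws.append(np.concatenate([sig, [sig_e]]))
            for k in range(K):
                u_sums[k] += us[k]
            beta_sum += beta
            n_kept_mean += 1
            if keep_u_draws:
                u_draws.append(total_u.copy())

    draws = pd.DataFrame(kept_draws, columns=names + ["residual"])
    varcomps = {c: float(draws[c].mean()) for c in draws.columns}
    ids = ks[0].ids
    gdf = pd.DataFrame({names[k]: u_sums[k] / n_kept_mean for k in range(K)}, index=ids)
    gdf["total"] = gdf.sum(axis=1)
    beta_mean = beta_sum / n_kept_mean
    return FitResult(
        varcomps=varcomps,
        gebv=gdf,
        beta=beta_mean,
        mu=float(beta_mean[0]),
        draws=draws,
        settings={"iters": iters, "burnin": burnin, "thin": thin,
                  "prior_df": prior_df, "seed": seed,
                  **({"u_draws": np.asarray(u_draws)} if keep_u_draws else {})},
    )


def fit_gblup_reml(y, kernel: Kernel, X: np.ndarray | None = None) -> FitResult:
    """Single-kernel GBLUP by profile REML over h2 on the eigendecomposition.

    Masked (NaN) phenotypes are predicted through the conditional Gaussian
    mean, which equals G_test,train G_train,train^{-1} u_train.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if kernel.n != n:
        raise ValueError("kernel size does not match phenotype length")
    mask = np.isnan(y)
    tr = np.flatnonzero(~mask)
    X = X if X is not None else np.ones((n, 1))
    Xt = X[tr]
    Gtt = kernel.matrix[np.ix_(tr, tr)]
    lam, U = np.linalg.eigh(Gtt)
    lam = np.maximum(lam, 0.0)
    if np.ptp(lam) < 1e-8 * max(lam[-1], 1.0):
        raise ValueError("kernel is (a multiple of) the identity: h2 unidentifiable")
    nt, p = len(tr), Xt.shape[1]
    ys = U.T @ y[tr]
    Xs = U.T @ Xt

    def negll(logit_h2):
        h2 = 1.0 / (1.0 + np.exp(-logit_h2))
        d = (1.0 - h2) / h2  # delta = sig_e / sig_g
        w = 1.0 / (lam + d)
        Xw = Xs * w[:, None]
        XtXw = Xs.T @ Xw
        bhat = np.linalg.solve(XtXw, Xw.T @ ys)
        r = ys - Xs @ bhat
        rss = float((r * r * w).sum())
        sig_g = rss / (nt - p)
        ll = -0.5 * ((nt - p) * np.log(sig_g) - np.log(w).sum()
                     + np.linalg.slogdet(XtXw)[1])
        return -ll

    grid = np.linspace(-8, 8, 33)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    res = minimize_scalar(negll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
                          method="bounded", options={"xatol": 1e-10})
    h2 = 1.0 / (1.0 + np.exp(-float(res.x)))
    d = (1.0 - h2) / h2
    w = 1.0 / (lam + d)
    Xw = Xs * w[:, None]
    bhat = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ bhat
    sig_g = float((r * r * w).sum()) / (nt - p)
    sig_e = d * sig_g

    # BLUP on training, conditional mean everywhere: u = sig_g G[:, tr] Vtt^{-1} resid
    Vinv_r = U @ (w * r) / sig_g  # (Gtt + d I)^{-1} resid / 1 -> scaled below
    u_all = kernel.matrix[:, tr] @ (U @ (w * r))
    gdf = pd.DataFrame({kernel.kind: u_all, "total": u_all},
                       index=kernel.ids)
    return FitResult(
        varcomps={kernel.kind: sig_g, "residual": sig_e},
        gebv=gdf,
        beta=bhat,
        mu=float(bhat[0]),
        settings={"method": "reml", "h2": h2},
    )


def fit_bayesc(
    y,
    X: np.ndarray | None,
    marker_matrix,
    iters: int = 3_000,
    burnin: int = 1_000,
    thin: int = 5,
    pi_prior_mean: float = 0.5,
    pi_prior_counts: float = 10.0,
    prior_df: float = 5.0,
    fix_pi: float | None = None,
    seed: int | None = None,
) -> FitResult:
    """BayesC: spike-and-slab marker effects with common slab variance.

    Marker codes (0/1/2) are centered by 2p.  Fits on the observed rows of y
    (NaN rows are the prediction set); GEBVs for everyone are Z E[u].
    Returns marker effects and posterior inclusion frequencies in settings.
    """
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    from .kernels import genotype_freqs  # local import to avoid cycle at module load

    Zraw = marker_matrix.values if hasattr(marker_matrix, "values") else np.asarray(marker_matrix)
    ids = marker_matrix.ids if hasattr(marker_matrix, "ids") else [str(i) for i in range(len(Zraw))]
    f = genotype_freqs(Zraw)
    Z = Zraw.astype(float)
    Z = np.where(Zraw == MISSING, 2.0 * f.p[None, :], Z)
    Z = Z - 2.0 * f.p[None, :]

    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    yt = y[obs]
    Zt = Z[obs]
    n, m = Zt.shape
    Xfull = X if X is not None else np.ones((len(y), 1))
    Xt = Xfull[obs]
    if np.linalg.matrix_rank(Xt.T @ Xt) < Xt.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    rng = np.random.default_rng(seed)
    vy = float(np.var(yt))
    pi0 = fix_pi if fix_pi is not None else pi_prior_mean
    msx = float((Zt ** 2).mean(axis=0).sum())
    s0_b = 0.5 * vy / max(pi0 * msx, 1e-12) * (prior_df + 2.0) / prior_df
    s0_e = 0.5 * vy * (prior_df + 2.0) / prior_df
    a_pi = pi_prior_mean * pi_prior_counts
    b_pi = (1.0 - pi_prior_mean) * pi_prior_counts

    zz = (Zt ** 2).sum(axis=0)
    beta = np.zeros(Xt.shape[1])
    u = np.zeros(m)
    incl = np.zeros(m, dtype=bool)
    sig_b = s0_b
    sig_e = 0.5 * vy
    pi = pi0
    resid = yt - Xt @ beta

    XtXinv = np.linalg.inv(Xt.T @ Xt)
    Lx = np.linalg.cholesky(XtXinv)

    u_sum = np.zeros(m)
    beta_sum = np.zeros(Xt.shape[1])
    incl_sum = np.zeros(m)
    kept_draws = []
    n_kept = 0

    for it in range(iters):
        # fixed effects (flat prior)
        resid += Xt @ beta
        bhat = XtXinv @ (Xt.T @ resid)
        beta = bhat + np.sqrt(sig_e) * (Lx @ rng.standard_normal(len(bhat)))
        resid -= Xt @ beta
        # marker effects, single-site
        log_odds_base = np.log(pi) - np.log(1.0 - pi) if 0 < pi < 1 else None
        n_in = 0
        for j in range(m):
            if zz[j] <= 0:
                continue
            if u[j] != 0.0:
                resid += Zt[:, j] * u[j]
            rj = float(Zt[:, j] @ resid)
            c = zz[j] / sig_e + 1.0 / sig_b
            mean_j = rj / sig_e / c
            # marginal log Bayes factor for inclusion
            log_bf = 0.5 * (mean_j * rj / sig_e) - 0.5 * np.log(sig_b * c)
            if pi >= 1.0:
                p_in = 1.0
            elif pi <= 0.0:
                p_in = 0.0
            else:
                t = log_odds_base + log_bf
                p_in = 1.0 / (1.0 + np.exp(-np.clip(t, -700, 700)))
            if rng.random() < p_in:
                u[j] = mean_j + rng.standard_normal() / np.sqrt(c)
                resid -= Zt[:, j] * u[j]
                incl[j] = True
                n_in += 1
            else:
                u[j] = 0.0
                incl[j] = False
        # slab variance
        ssq = float(u @ u)
        sig_b = (prior_df * s0_b + ssq) / rng.chisquare(prior_df + max(n_in, 0))
        # residual variance
        sig_e = (prior_df * s0_e + float(resid @ resid)) / rng.chisquare(prior_df + n)
        # inclusion probability
        if fix_pi is None:
            pi = rng.beta(a_pi + n_in, b_pi + m - n_in)
            pi = min(max(pi, 1e-6), 1 - 1e-6)

        if it >= burnin and (it - burnin) % thin == 0:
            u_sum += u
            beta_sum += beta
            incl_sum += incl
            kept_draws.append((sig_b, sig_e, pi, n_in))
            n_kept += 1

    u_mean = u_sum / n_kept
    beta_mean = beta_sum / n_kept
    gebv_all = Z @ u_mean
    gdf = pd.DataFrame({"markers": gebv_all, "total": gebv_all}, index=ids)
    draws = pd.DataFrame(kept_draws, columns=["slab_var", "residual", "pi", "n_included"])
    return FitResult(
        varcomps={"slab_var": float(draws["slab_var"].mean()),
                  "residual": float(draws["residual"].mean()),
                  "pi": float(draws["pi"].mean())},
        gebv=gdf,
        beta=beta_mean,
        mu=float(beta_mean[0]),
        draws=draws,
        settings={"iters": iters, "burnin": burnin, "thin": thin, "seed": seed,
                  "inclusion_freq": incl_sum / n_kept},
        marker_effects=u_mean,
    )


def fit_g_plus_pc(y, X_pc: np.ndarray, kernel, **gibbs_kwargs) -> FitResult:
    """GBLUP with population-structure PCs as fixed effects (G+PC model).

    The GEBV excludes X beta; leading kernel eigenvectors are expected to be
    partially collinear with the PCs, which is tolerated.
    """
    return fit_multikernel_gibbs(y, [kernel], X=X_pc, **gibbs_kwargs)


def variance_proportions(fit: FitResult) -> pd.DataFrame:
    """Each variance component divided by the sum of all components including
    the residual; mean and SD over posterior draws when available."""
    if fit.draws is not None and {"residual"}.issubset(fit.draws.columns):
        comp = fit.draws[[c for c in fit.draws.columns if c != "n_included" and c != "pi"]]
        props = comp.div(comp.sum(axis=1), axis=0)
        return pd.DataFrame({"proportion": props.mean(), "sd": props.std(ddof=1)})
    total = sum(fit.varcomps.values())
    return pd.DataFrame({
        "proportion": {k: v / total for k, v in fit.varcomps.items()},
        "sd": {k: np.nan for k in fit.varcomps},
    })
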