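"""Marker quality control and multi-environment phenotype analysis.

Marker filters follow the usual array-genotyping rules for diversity panels
and biparental populations: markers are dropped when the missing-call
fraction exceeds 0.10, when the minor allele frequency is not strictly
above 0.05, or (biparental populations) when a chi-square test against the
expected segregation ratio (1:1 RIL, 1:2:1 F2) rejects at P <= 0.01.  All
three thresholds are strict: a marker exactly at the boundary is removed.

Phenotypes from replicated multi-environment trials are reduced to one BLUE
per individual with the mixed model

    y_ijl = mu + g_i + e_l + ge_il + r_jl + eps_ijl

where genotype and environment are fixed (sum-to-zero) and the
genotype-by-environment interaction and replicate-within-environment terms
are random.  Variance components are estimated by REML (profiled restricted
likelihood maximized on Henderson's mixed-model equations); the genotype
BLUEs are the generalized-least-squares estimates, centered to mean zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "BlueTable",
    "filter_missingness",
    "filter_maf",
    "segregation_test",
    "marker_maf",
    "qc_report",
    "fit_blue",
    "broad_sense_h2",
    "h2_from_components",
]


# ---------------------------------------------------------------- filters

def marker_missingness(geno: GenotypeMatrix) -> np.ndarray:
    return (geno.values == MISSING).mean(axis=0)


def marker_maf(geno: GenotypeMatrix) -> np.ndarray:
    """MAF per marker on non-missing calls: min(p, 1-p), p=(2 n2 + n1)/(2 n_called)."""
    v = geno.values
    called = (v != MISSING).sum(axis=0)
    n1 = (v == 1).sum(axis=0)
    n2 = (v == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2.0 * n2 + n1) / (2.0 * called)
    return np.where(called > 0, np.minimum(p, 1.0 - p), np.nan)


def filter_missingness(geno: GenotypeMatrix, max_missing: float = 0.10) -> GenotypeMatrix:
    """Keep markers whose missing fraction is <= max_missing (strictly greater removed)."""
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if geno.n_markers == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    keep = marker_missingness(geno) <= max_missing
    return geno.take_markers(np.flatnonzero(keep))


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep markers with MAF strictly greater than min_maf."""
    if geno.n_markers == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    maf = marker_maf(geno)
    if np.isnan(maf).any():
        warnings.warn("markers with no called genotypes removed")
    keep = np.nan_to_num(maf, nan=-1.0) > min_maf
    return geno.take_markers(np.flatnonzero(keep))


def segregation_chi2(geno: GenotypeMatrix, expected_ratio) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistic and P value per marker against an expected ratio.

    expected_ratio (1, 1) tests classes {0, 2}; (1, 2, 1) tests {0, 1, 2}.
    Markers where any expected count falls below 1 get P = NaN (skipped).
    """
    ratio = np.asarray(expected_ratio, dtype=float)
    if len(ratio) == 2:
        classes = [0, 2]
    elif len(ratio) == 3:
        classes = [0, 1, 2]
    else:
        raise ValueError("expected_ratio must have 2 (RIL) or 3 (F2) classes")
    v = geno.values
    counts = np.stack([(v == c).sum(axis=0) for c in classes]).astype(float)
    n_called = counts.sum(axis=0)
    expected = ratio[:, None] / ratio.sum() * n_called[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=len(ratio) - 1)
    bad = (expected < 1.0).any(axis=0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} markers skipped (expected class count < 1)")
        pvals = np.where(bad, np.nan, pvals)
        chi2 = np.where(bad, np.nan, chi2)
    return chi2, pvals


def segregation_test(
    geno: GenotypeMatrix, expected_ratio, retain_p: float = 0.01
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Remove markers with segregation distortion; returns (filtered, P values).

    Markers with P strictly greater than retain_p are retained; skipped
    markers (NaN P) are retained unchanged.
    """
    _, pvals = segregation_chi2(geno, expected_ratio)
    keep = np.isnan(pvals) | (pvals > retain_p)
    return geno.take_markers(np.flatnonzero(keep)), pvals


def qc_report(geno: GenotypeMatrix, expected_ratio=None,
              max_missing: float = 0.10, min_maf: float = 0.05,
              retain_p: float = 0.01) -> pd.DataFrame:
    """Per-marker QC table: missing fraction, MAF, chi-square P, kept flag."""
    miss = marker_missingness(geno)
    maf = marker_maf(geno)
    kept = (miss <= max_missing) & (np.nan_to_num(maf, nan=-1.0) > min_maf)
    if expected_ratio is not None:
        _, pvals = segregation_chi2(geno, expected_ratio)
        kept &= np.isnan(pvals) | (pvals > retain_p)
    else:
        pvals = np.full(geno.n_markers, np.nan)
    return pd.DataFrame({
        "marker": geno.markers["marker"],
        "missing_frac": miss,
        "maf": maf,
        "chi2_p": pvals,
        "kept": kept,
    })


# ------------------------------------------------------------- BLUE model

@dataclass
class BlueTable:
    """Per-individual BLUEs with the fitted variance components."""

    blues: pd.DataFrame  # index individual, one column per trait
    varcomps: dict = field(default_factory=dict)  # trait -> {var_gxe, var_rep, var_resid}
    n_envs: int = 1
    n_reps: int = 1

    def trait(self, name: str) -> pd.Series:
        return self.blues[name]


def _reml_mme(y, X, Z_blocks):
    """REML for y = Xb + sum_k Z_k u_k + e via Henderson's MME.

    The restricted likelihood is profiled over the residual variance and
    maximized over the log variance ratios gamma_k = sigma_k^2/sigma_e^2;
    each evaluation is one Cholesky factorization of the coefficient matrix.
    Returns (b, [u_k], [sigma2_k], sigma2_e).
    """
    from scipy.linalg import cho_factor, cho_solve
    from scipy.optimize import minimize

    n, p = X.shape
    qs = [Z.shape[1] for Z in Z_blocks]
    nk = len(qs)
    W = np.hstack([X] + list(Z_blocks))
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    offs = np.cumsum([p] + qs)

    def solve(log_gamma):
        M = WtW.copy()
        for k, q in enumerate(qs):
            sl = slice(offs[k], offs[k] + q)
            M[sl.start:sl.stop, sl.start:sl.stop] += np.eye(q) * np.exp(-log_gamma[k])
        c, low = cho_factor(M, lower=True)
        sol = cho_solve((c, low), Wty)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        rss = max(yty - float(sol @ Wty), 1e-12)
        return sol, logdet, rss

    def neg2llr(log_gamma):
        log_gamma = np.clip(log_gamma, -18.0, 12.0)
        _, logdet, rss = solve(log_gamma)
        return ((n - p) * np.log(rss / (n - p))
                + float(np.dot(qs, log_gamma)) + logdet)

    # coarse grid start, then one Nelder-Mead refinement
    grid = [-6.0, -2.0, 0.0, 2.0]
    starts = np.array(np.meshgrid(*([grid] * nk))).reshape(nk, -1).T
    x0 = min(starts, key=neg2llr)
    res = minimize(neg2llr, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 300})
    log_gamma = np.clip(res.x, -18.0, 12.0)
    sol, _, rss = solve(log_gamma)
    sig_e = rss / (n - p)
    sig = [float(np.exp(g) * sig_e) for g in log_gamma]
    b = sol[:p]
    us = [sol[offs[k]:offs[k] + qs[k]] for k in range(nk)]
    return b, us, sig, sig_e


def fit_blue(records: pd.DataFrame, traits=None) -> BlueTable:
    """Fit the multi-environment mixed model and return centered BLUEs.

    records: long-format table (individual, env, rep, trait, value).  The
    genotype-by-environment term needs >= 2 environments and >= 2 replicates
    to be separable from the residual; the replicate-within-environment term
    needs >= 2 replicates.  With a single environment and replicate the fit
    falls back to fixed effects only (means), with a warning.
    """
    req = {"individual", "env", "rep", "trait", "value"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    records = records.dropna(subset=["value"])
    traits = traits or list(pd.unique(records["trait"]))
    all_blues = {}
    varcomps = {}
    n_envs = records["env"].nunique()
    n_reps = records["rep"].nunique()

    for tr in traits:
        df = records[records["trait"] == tr]
        inds = list(pd.unique(df["individual"]))
        envs = list(pd.unique(df["env"]))
        reps = list(pd.unique(df["rep"]))
        n_i, n_e, n_r = len(inds), len(envs), len(reps)
        ind_ix = df["individual"].map({v: i for i, v in enumerate(inds)}).to_numpy()
        env_ix = df["env"].map({v: i for i, v in enumerate(envs)}).to_numpy()
        rep_ix = df["rep"].map({v: i for i, v in enumerate(reps)}).to_numpy()
        y = df["value"].to_numpy(dtype=float)
        n = len(y)

        # fixed design: intercept + sum-to-zero genotype + sum-to-zero env
        Xg = np.zeros((n, n_i - 1))
        for i in range(n_i - 1):
            Xg[:, i] = (ind_ix == i).astype(float) - (ind_ix == n_i - 1)
        cols = [np.ones((n, 1)), Xg]
        if n_e > 1:
            Xe = np.zeros((n, n_e - 1))
            for l in range(n_e - 1):
                Xe[:, l] = (env_ix == l).astype(float) - (env_ix == n_e - 1)
            cols.append(Xe)
        X = np.hstack(cols)

        Z_blocks, names = [], []
        if n_e >= 2 and n_r >= 2:
            Zge = np.zeros((n, n_i * n_e))
            Zge[np.arange(n), ind_ix * n_e + env_ix] = 1.0
            Z_blocks.append(Zge)
            names.append("var_gxe")
        if n_r >= 2:
            Zr = np.zeros((n, n_e * n_r))
            Zr[np.arange(n), env_ix * n_r + rep_ix] = 1.0
            Z_blocks.append(Zr)
            names.append("var_rep")

        if Z_blocks:
            b, _, sig, sig_e = _reml_mme(y, X, Z_blocks)
        else:
            warnings.warn("no random terms identifiable; fixed-effects-only fit")
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            sig, sig_e = [], float("nan")
            res = y - X @ b
            if len(y) > X.shape[1]:
                sig_e = float(res @ res) / (len(y) - X.shape[1])

        g = np.empty(n_i)
        g[: n_i - 1] = b[1:n_i]
        g[n_i - 1] = -g[: n_i - 1].sum()
        g -= g.mean()  # sum-to-zero contrasts already center; guard numerics
        all_blues[tr] = pd.Series(g, index=inds)
        vc = dict(zip(names, sig))
        vc.setdefault("var_gxe", 0.0)
        vc.setdefault("var_rep", 0.0)
        vc["var_resid"] = sig_e
        varcomps[tr] = vc

    blues = pd.DataFrame(all_blues)
    return BlueTable(blues=blues, varcomps=varcomps, n_envs=n_envs, n_reps=n_reps)


def h2_from_components(var_g: float, var_gxe: float, var_resid: float,
                       n_envs: int, n_reps: int) -> float:
    """Broad-sense heritability on an entry-mean basis:
    H2 = var_g / (var_g + var_gxe/E + var_resid/(E*R))."""
    denom = var_g + var_gxe / n_envs + var_resid / (n_envs * n_reps)
    return 0.0 if denom == 0 else var_g / denom


def broad_sense_h2(blue_fit: BlueTable, n_envs: int | None = None,
                   n_reps: int | None = None) -> dict[str, float]:
    """Entry-mean H2 per trait, with var_g taken as the variance of the BLUEs."""
    n_envs = n_envs or blue_fit.n_envs
    n_reps = n_reps or blue_fit.n_reps
    out = {}
    for tr in blue_fit.blues.columns:
        var_g = float(blue_fit.blues[tr].var(ddof=1))
        vc = blue_fit.varcomps.get(tr, {})
        out[tr] = h2_from_components(
            var_g, vc.get("var_gxe", 0.0), vc.get("var_resid", 0.0), n_envs, n_reps
        )
    return out
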