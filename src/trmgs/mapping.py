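"""Association and linkage mapping, and trait-relevant-marker selection.

GWAS uses the Q+K mixed linear model y = mu + PCs a + marker b + u + e with
u ~ N(0, K sigma_u^2).  Variance components are estimated once under the
null on the eigendecomposition of K (the P3D/EMMAX approximation) and each
marker is then tested with a Wald test on the rotated data; with K = I and
no covariates this reduces exactly to the OLS F test.  Markers with
-log10(P) above 4 are declared significant.

Linkage scans use Haley-Knott regression on expected QTL genotype scores at
pseudo-positions along the bin map (composite interval mapping: background
cofactor bins chosen by forward selection and dropped within a window of
the tested position).  LOD = (n/2) log10(RSS0/RSS1).  Genome-wide LOD
thresholds come from permutation of the phenotypes; QTL support intervals
use the 1.5-LOD drop rule.

Trait-relevant markers (TRMs) are the top-k markers by the scan statistic;
random-marker baselines are drawn uniformly without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .binmap import A_HOM, B_HOM, HET, BinMap, kosambi_inverse
from .kernels import Kernel, compute_Ga, pca_scores
from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "QTLRecord",
    "TRMSet",
    "pca_matrix",
    "vanraden_kinship",
    "gwas_scan",
    "significant_hits",
    "im_genotype_expectation",
    "cim_scan",
    "permutation_threshold",
    "max_lod_many",
    "lod_support_interval",
    "bin_lod_table",
    "call_qtl",
    "integrate_pqtl",
    "select_trms",
    "select_random_markers",
    "overlap_trms",
]


# ------------------------------------------------------------------ GWAS

def pca_matrix(geno, n_pc: int) -> np.ndarray:
    """Individuals x n_pc PC score matrix of the centered genotype matrix."""
    return pca_scores(geno, n_pc)


def vanraden_kinship(geno) -> Kernel:
    """Genomic kinship for the Q+K model (same formula as the additive kernel)."""
    return compute_Ga(geno)


def _reml_delta(y, X, lam, U):
    """Profile REML over delta = sigma_e^2 / sigma_u^2 on the eigenbasis of K."""
    n, p = X.shape
    ys = U.T @ y
    Xs = U.T @ X

    def negll(log_delta):
        d = 10.0 ** log_delta
        w = 1.0 / (lam + d)
        Xw = Xs * w[:, None]
        XtX = Xs.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float((r * r * w).sum())
        sig = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(sig) - np.log(w).sum()
                     + np.linalg.slogdet(XtX)[1])
        return -ll

    grid = np.linspace(-6, 6, 49)
    vals = [negll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    return 10.0 ** float(res.x)


def gwas_scan(blues, geno: GenotypeMatrix, pcs: np.ndarray | None = None,
              K: Kernel | np.ndarray | None = None) -> pd.DataFrame:
    """Single-marker mixed-model scan; returns a table with -log10 P per marker.

    Missing genotypes are mean-imputed per marker for testing only.  Markers
    collinear with the covariates get P = 1 and a flag.
    """
    y = np.asarray(blues, dtype=float)
    n = geno.n_individuals
    if len(y) != n:
        raise ValueError("phenotype vector not aligned with genotypes")
    pcs = pcs if pcs is not None else np.empty((n, 0))
    X = np.hstack([np.ones((n, 1)), pcs])

    Km = K.matrix if isinstance(K, Kernel) else K
    if Km is None or np.allclose(Km, np.eye(n), atol=1e-12):
        U = np.eye(n)
        w = np.ones(n)
    else:
        lam, U = np.linalg.eigh(Km)
        lam = np.maximum(lam, 0.0)
        delta = _reml_delta(y, X, lam, U)
        w = 1.0 / (lam + delta)

    sw = np.sqrt(w)
    yt = sw * (U.T @ y)
    Xt = sw[:, None] * (U.T @ X)
    Q, _ = np.linalg.qr(Xt)
    y_r = yt - Q @ (Q.T @ yt)

    Z = geno.values.astype(float)
    miss = geno.values == MISSING
    if miss.any():
        colmeans = np.where(miss, np.nan, Z)
        colmeans = np.nanmean(colmeans, axis=0)
        Z = np.where(miss, colmeans[None, :], Z)
    Zt = sw[:, None] * (U.T @ Z)
    Z_r = Zt - Q @ (Q.T @ Zt)

    xx = (Z_r ** 2).sum(axis=0)
    xy = Z_r.T @ y_r
    yy = float(y_r @ y_r)
    p_fixed = X.shape[1]
    df = n - p_fixed - 1
    good = xx > 1e-10 * n
    beta = np.where(good, xy / np.where(good, xx, 1.0), 0.0)
    rss = np.maximum(yy - beta * xy, 1e-300)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / np.where(good, xx, 1.0))
    fstat = np.where(good, beta ** 2 * xx / sigma2, 0.0)
    pvals = np.where(good, stats.f.sf(fstat, 1, df), 1.0)
    neglog = -np.log10(np.maximum(pvals, 1e-300))
    pve = 100.0 * fstat / (fstat + df)

    out = geno.markers[["marker", "chrom", "pos"]].copy()
    out["stat"] = neglog
    out["pvalue"] = pvals
    out["effect_a"] = beta
    out["effect_d"] = np.nan
    out["se"] = se
    out["pve"] = pve
    out["collinear"] = ~good
    return out


def significant_hits(scan: pd.DataFrame, threshold: float = 4.0) -> list[str]:
    """Markers whose -log10 P (or LOD) exceeds the threshold."""
    return list(scan.loc[scan["stat"] > threshold, "marker"])


# --------------------------------------------------- interval-mapping design

def _chain(r: float) -> np.ndarray:
    r = min(max(float(r), 0.0), 0.5)
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


def _hap_pairs(g: int):
    """Chromatid allele pairs consistent with an observed F2 genotype code."""
    if g == 0:
        return [(0, 0)]
    if g == 2:
        return [(1, 1)]
    if g == HET:
        return [(0, 1), (1, 0)]
    return [(0, 0), (0, 1), (1, 0), (1, 1)]  # missing


def _f2_cond_table(r1: float, r2: float) -> np.ndarray:
    """P(QTL genotype | left, right flank genotypes) for an F2.

    Indices: [gL(0..3), gR(0..3), q(0..2)] with 3 = missing flank.  Each
    chromatid is an independent two-state Markov chain along the chromosome.
    """
    T1, T2 = _chain(r1), _chain(r2)
    out = np.zeros((4, 4, 3))
    for gl in range(4):
        for gr in range(4):
            acc = np.zeros(3)
            for hl in _hap_pairs(gl if gl < 3 else MISSING):
                for hr in _hap_pairs(gr if gr < 3 else MISSING):
                    wcfg = 0.25  # prior over the two chromatids' left alleles
                    pq = []
                    for c in range(2):
                        num = T1[hl[c], :] * T2[:, hr[c]]
                        s = num.sum()
                        if s <= 0:  # impossible phase configuration
                            wcfg = 0.0
                            break
                        wcfg *= s
                        pq.append(num / s)
                    if wcfg == 0.0:
                        continue
                    for q1 in range(2):
                        for q2 in range(2):
                            acc[q1 + q2] += wcfg * pq[0][q1] * pq[1][q2]
            if acc.sum() <= 0:  # contradictory flanks: fall back to the prior
                acc = np.array([0.25, 0.5, 0.25])
            out[gl, gr] = acc / acc.sum()
    return out


def _ril_cond_table(r1: float, r2: float) -> np.ndarray:
    """P(QTL state | flanks) for RILs (two-state mosaic chain at meiotic r
    mapped through the Haldane-Waddington correction R = 2r/(1+2r))."""
    def R(r):
        return 2.0 * r / (1.0 + 2.0 * r)

    T1, T2 = _chain(R(r1)), _chain(R(r2))
    out = np.zeros((4, 4, 3))
    for gl in range(4):
        for gr in range(4):
            pl = np.array([1.0, 0.0]) if gl == 0 else np.array([0.0, 1.0]) if gl == 2 \
                else np.array([0.5, 0.5])
            pr = np.array([1.0, 0.0]) if gr == 0 else np.array([0.0, 1.0]) if gr == 2 \
                else np.array([0.5, 0.5])
            num = (pl @ T1) * (T2 @ pr)
            if num.sum() <= 0:  # contradictory flanks: fall back to the prior
                num = np.array([0.5, 0.5])
            num = num / num.sum()
            out[gl, gr, 0] = num[0]
            out[gl, gr, 2] = num[1]
    return out


def im_genotype_expectation(binmap: BinMap, position_cm: float, chrom,
                            population: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Expected additive and dominance scores at a pseudo-position.

    Conditional QTL genotype probabilities come from the flanking bins via
    Kosambi-consistent recombination fractions.  additive = P(AA) - P(BB);
    dominance = P(het).
    """
    population = population or binmap.population
    idx = binmap.chrom_index(chrom)
    if len(idx) == 0:
        raise ValueError(f"no bins on chromosome {chrom}")
    cm = binmap.bins["cm"].to_numpy()[idx]
    if position_cm < cm.min() - 1e-9 or position_cm > cm.max() + 1e-9:
        raise ValueError("position outside chromosome map")
    G = binmap.genotypes[:, idx]

    right = int(np.searchsorted(cm, position_cm, side="left"))
    right = min(right, len(cm) - 1)
    left = right if abs(cm[right] - position_cm) < 1e-9 else max(right - 1, 0)
    if cm[left] > position_cm + 1e-9:
        left = right
    r1 = kosambi_inverse(max(position_cm - cm[left], 0.0))
    r2 = kosambi_inverse(max(cm[right] - position_cm, 0.0))
    table = (_f2_cond_table(r1, r2) if population == "F2"
             else _ril_cond_table(r1, r2))
    gl = G[:, left].copy()
    gr = G[:, right].copy()
    gl[gl == MISSING] = 3
    gr[gr == MISSING] = 3
    probs = table[gl, gr]  # n x 3
    additive = probs[:, 0] - probs[:, 2]
    dominance = probs[:, 1]
    return additive, dominance


def _bin_additive_codes(binmap: BinMap) -> np.ndarray:
    g = binmap.genotypes
    return ((g == A_HOM).astype(float) - (g == B_HOM).astype(float))


def _forward_cofactors(y, codes, n_cofactors):
    """Forward stepwise selection of cofactor bins by RSS reduction."""
    n = len(y)
    resid_y = y - y.mean()
    R = codes - codes.mean(axis=0)
    chosen = []
    for _ in range(n_cofactors):
        cc = (R ** 2).sum(axis=0)
        cy = R.T @ resid_y
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(cc > 1e-10 * n, cy ** 2 / cc, 0.0)
        j = int(np.argmax(gain))
        if gain[j] <= 1e-12 * float(resid_y @ resid_y + 1e-300):
            break
        chosen.append(j)
        c = R[:, j] / np.sqrt(cc[j])
        resid_y = resid_y - c * (c @ resid_y)
        R = R - np.outer(c, c @ R)
    return chosen


def _rss(y, X):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def _scan_positions(cm: np.ndarray, step_cm: float) -> np.ndarray:
    grid = np.arange(cm.min(), cm.max() + 1e-9, step_cm)
    pos = np.unique(np.concatenate([grid, cm]))
    return pos


def cim_scan(blues, binmap: BinMap, n_cofactors: int = 5, window_cm: float = 10.0,
             step_cm: float = 1.0, population: str | None = None) -> pd.DataFrame:
    """Composite interval mapping by Haley-Knott regression on the bin map.

    Cofactor bins are chosen by forward stepwise regression; at each scan
    position, cofactors within window_cm of the position (same chromosome)
    are dropped.  Returns a LOD profile table (chrom, pos_cm, pos_bp, stat,
    effect_a, effect_d, pve).
    """
    population = population or binmap.population
    y = np.asarray(blues, dtype=float)
    n = len(y)
    if y.std() == 0:
        return _flat_profile(binmap, step_cm)
    if n_cofactors >= n - 5:
        raise ValueError("too many cofactors for the sample size")
    codes = _bin_additive_codes(binmap)
    chosen = _forward_cofactors(y, codes, n_cofactors) if n_cofactors > 0 else []
    cof_cm = binmap.bins["cm"].to_numpy()[chosen] if chosen else np.empty(0)
    cof_chrom = binmap.bins["chrom"].to_numpy()[chosen] if chosen else np.empty(0, dtype=object)
    cof_cols = codes[:, chosen] if chosen else np.empty((n, 0))

    rows = []
    ones = np.ones((n, 1))
    for chrom in pd.unique(binmap.bins["chrom"]):
        idx = binmap.chrom_index(chrom)
        cm = binmap.bins["cm"].to_numpy()[idx]
        mid_bp = ((binmap.bins["start"].to_numpy() + binmap.bins["end"].to_numpy()) / 2)[idx]
        positions = _scan_positions(cm, step_cm)
        null_cache: dict[tuple, float] = {}
        for pos in positions:
            keep = np.ones(len(chosen), dtype=bool)
            if len(chosen):
                same = cof_chrom == chrom
                keep = ~(same & (np.abs(cof_cm - pos) <= window_cm))
            key = tuple(np.flatnonzero(keep))
            X0 = np.hstack([ones, cof_cols[:, keep]])
            if key not in null_cache:
                null_cache[key] = _rss(y, X0)[0]
            rss0 = null_cache[key]
            a, d = im_genotype_expectation(binmap, pos, chrom, population)
            design = [X0, a[:, None]]
            if population == "F2":
                design.append((d - d.mean())[:, None])
            X1 = np.hstack(design)
            rss1, beta = _rss(y, X1)
            rss1 = max(rss1, 1e-300)
            lod = n / 2.0 * np.log10(rss0 / rss1)
            eff_a = float(beta[X0.shape[1]])
            eff_d = float(beta[X0.shape[1] + 1]) if population == "F2" else np.nan
            pve = 100.0 * (1.0 - rss1 / rss0)
            bp = float(np.interp(pos, cm, mid_bp))
            rows.append((chrom, float(pos), bp, max(lod, 0.0), eff_a, eff_d, pve))
    return pd.DataFrame(rows, columns=["chrom", "pos_cm", "pos_bp", "stat",
                                       "effect_a", "effect_d", "pve"])


def _flat_profile(binmap: BinMap, step_cm: float) -> pd.DataFrame:
    rows = []
    for chrom in pd.unique(binmap.bins["chrom"]):
        idx = binmap.chrom_index(chrom)
        cm = binmap.bins["cm"].to_numpy()[idx]
        mid_bp = ((binmap.bins["start"].to_numpy() + binmap.bins["end"].to_numpy()) / 2)[idx]
        for pos in _scan_positions(cm, step_cm):
            rows.append((chrom, float(pos), float(np.interp(pos, cm, mid_bp)),
                         0.0, 0.0, np.nan, 0.0))
    return pd.DataFrame(rows, columns=["chrom", "pos_cm", "pos_bp", "stat",
                                       "effect_a", "effect_d", "pve"])


def permutation_threshold(blues, binmap: BinMap, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int | None = None,
                          n_cofactors: int = 0, window_cm: float = 10.0,
                          step_cm: float = 1.0,
                          population: str | None = None) -> float:
    """Genome-wide LOD threshold: the empirical (1-alpha) quantile (type 7)
    of the maximum LOD over n_perm phenotype permutations.

    With no cofactors the permutations are evaluated on precomputed
    Haley-Knott designs (fast path); with cofactors each permutation re-runs
    the full scan including cofactor selection.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    y = np.asarray(blues, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    population = population or binmap.population

    if n_cofactors > 0:
        maxlod = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            scan = cim_scan(yp, binmap, n_cofactors, window_cm, step_cm, population)
            maxlod[b] = scan["stat"].max()
        return float(np.quantile(maxlod, 1.0 - alpha))

    Y = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    maxlod = max_lod_many(Y, binmap, step_cm=step_cm, population=population)
    return float(np.quantile(maxlod, 1.0 - alpha))


def max_lod_many(Y: np.ndarray, binmap: BinMap, step_cm: float = 1.0,
                 population: str | None = None) -> np.ndarray:
    """Genome-wide maximum interval-mapping LOD for each phenotype column of
    Y (n x B), evaluated on precomputed Haley-Knott designs."""
    population = population or binmap.population
    n = Y.shape[0]
    yy = (Y ** 2).sum(axis=0)
    ybar = Y.mean(axis=0)
    rss0 = yy - n * ybar ** 2
    maxlod = np.zeros(Y.shape[1])
    ones = np.ones((n, 1))
    for chrom in pd.unique(binmap.bins["chrom"]):
        idx = binmap.chrom_index(chrom)
        cm = binmap.bins["cm"].to_numpy()[idx]
        for pos in _scan_positions(cm, step_cm):
            a, d = im_genotype_expectation(binmap, pos, chrom, population)
            cols = [ones, a[:, None]]
            if population == "F2":
                cols.append((d - d.mean())[:, None])
            X = np.hstack(cols)
            Q, _ = np.linalg.qr(X)
            proj = Q.T @ Y
            rss1 = np.maximum(yy - (proj ** 2).sum(axis=0), 1e-300)
            lod = n / 2.0 * np.log10(rss0 / rss1)
            maxlod = np.maximum(maxlod, lod)
    return maxlod


def bin_lod_table(scan: pd.DataFrame, binmap: BinMap) -> pd.DataFrame:
    """Per-bin LOD extracted from a scan profile (interpolated at each bin's
    map position), as a marker table usable for TRM selection."""
    stats_ = np.empty(binmap.n_bins)
    cm_all = binmap.bins["cm"].to_numpy()
    for chrom in pd.unique(binmap.bins["chrom"]):
        idx = binmap.chrom_index(chrom)
        sub = scan[scan["chrom"] == chrom].sort_values("pos_cm")
        stats_[idx] = np.interp(cm_all[idx], sub["pos_cm"], sub["stat"])
    return pd.DataFrame({
        "marker": binmap.bins["bin"],
        "chrom": binmap.bins["chrom"],
        "pos": binmap.bins["start"],
        "stat": stats_,
    })


def lod_support_interval(lod, peak_index: int, drop: float = 1.5) -> tuple[int, int]:
    """Index span of the LOD support interval around a peak.

    The widest contiguous region around the peak where LOD >= peak - drop,
    extended outward to the first positions crossing below; clipped at the
    profile ends.
    """
    lod = np.asarray(lod, dtype=float)
    cutoff = lod[peak_index] - drop
    left = peak_index
    while left > 0 and lod[left - 1] >= cutoff:
        left -= 1
    if left > 0:
        left -= 1  # first position crossing below
    right = peak_index
    while right < len(lod) - 1 and lod[right + 1] >= cutoff:
        right += 1
    if right < len(lod) - 1:
        right += 1
    return left, right


@dataclass
class QTLRecord:
    """One detected QTL with its 1.5-LOD support interval."""

    trait: str
    chrom: object
    peak_cm: float
    peak_bp: float
    lod: float
    interval_bp: tuple[float, float]
    interval_cm: tuple[float, float]
    pve: float
    effect_a: float
    effect_d: float = float("nan")
    population: str = ""


def call_qtl(scan: pd.DataFrame, threshold: float, trait: str = "trait",
             drop: float = 1.5, population: str = "") -> list[QTLRecord]:
    """Declare at most one QTL per chromosome: the peak above the threshold,
    with a 1.5-LOD support interval."""
    out = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        peak = int(sub["stat"].idxmax())
        if sub["stat"].iat[peak] <= threshold:
            continue
        lo, hi = lod_support_interval(sub["stat"].to_numpy(), peak, drop)
        out.append(QTLRecord(
            trait=trait, chrom=chrom,
            peak_cm=float(sub["pos_cm"].iat[peak]),
            peak_bp=float(sub["pos_bp"].iat[peak]),
            lod=float(sub["stat"].iat[peak]),
            interval_bp=(float(sub["pos_bp"].iat[lo]), float(sub["pos_bp"].iat[hi])),
            interval_cm=(float(sub["pos_cm"].iat[lo]), float(sub["pos_cm"].iat[hi])),
            pve=float(sub["pve"].iat[peak]),
            effect_a=float(sub["effect_a"].iat[peak]),
            effect_d=float(sub["effect_d"].iat[peak]),
            population=population,
        ))
    return out


def integrate_pqtl(qtls: list[QTLRecord]) -> list[dict]:
    """Group QTL whose physical intervals overlap (transitively) on the same
    chromosome; groups with >= 2 QTL from >= 2 distinct traits are pleiotropic
    QTL, reported with the union interval and member list."""
    out = []
    by_chrom: dict = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda q: q.interval_bp[0])
        group = [items[0]]
        right = items[0].interval_bp[1]
        groups = []
        for q in items[1:]:
            if q.interval_bp[0] <= right:
                group.append(q)
                right = max(right, q.interval_bp[1])
            else:
                groups.append(group)
                group = [q]
                right = q.interval_bp[1]
        groups.append(group)
        for g in groups:
            traits = {q.trait for q in g}
            if len(g) >= 2 and len(traits) >= 2:
                out.append({
                    "chrom": chrom,
                    "interval_bp": (min(q.interval_bp[0] for q in g),
                                    max(q.interval_bp[1] for q in g)),
                    "n_qtl": len(g),
                    "traits": sorted(traits),
                    "members": g,
                })
    return out


# ------------------------------------------------------------- TRM sets

@dataclass
class TRMSet:
    """Ordered trait-relevant (or random) marker set with its statistic."""

    table: pd.DataFrame  # columns marker, stat, chrom, pos; ordered
    provenance: str  # "GWAS" | "linkage" | "random"
    trait: str = ""
    fold: int | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])


def select_trms(scan: pd.DataFrame, k: int, provenance: str = "GWAS",
                trait: str = "", fold: int | None = None) -> TRMSet:
    """Top-k markers by scan statistic, regardless of significance.

    Ties are broken deterministically by (statistic desc, chrom, pos).
    """
    if k > len(scan):
        raise ValueError("k exceeds number of scanned markers")
    cols = ["marker", "stat", "chrom", "pos"] if "marker" in scan.columns else None
    df = scan.copy()
    if "marker" not in df.columns:  # LOD profile on bins: nearest bin per position
        raise ValueError("scan table must carry a 'marker' column")
    df = df.sort_values(["stat", "chrom", "pos"],
                        ascending=[False, True, True], kind="mergesort")
    return TRMSet(df.head(k)[cols].reset_index(drop=True), provenance, trait, fold)


def select_random_markers(marker_ids, k: int, seed: int | None = None,
                          trait: str = "", fold: int | None = None) -> TRMSet:
    """Uniform draw of k markers without replacement (seeded)."""
    ids = list(marker_ids)
    if k > len(ids):
        raise ValueError("k exceeds number of markers")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=k, replace=False)
    tab = pd.DataFrame({"marker": [ids[i] for i in pick],
                        "stat": np.nan, "chrom": None, "pos": None})
    return TRMSet(tab, "random", trait, fold)


def overlap_trms(trmsets) -> list[str]:
    """Marker ids common to all sets (may be empty)."""
    sets = [set(t.markers if isinstance(t, TRMSet) else t) for t in trmsets]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
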