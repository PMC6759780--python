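"""Recombination bin maps from dense biparental genotypes.

A sliding window of 15 adjacent SNPs (step 1) is scanned along each
chromosome for every individual; a window with >= 11 SNPs homozygous for
one parent is called for that parent, otherwise heterozygous.  Missing SNPs
are excluded from the count and the threshold is scaled proportionally
(ceil(11 * called / 15)); windows with fewer than 8 called SNPs inherit the
call of the nearest informative window.  Window calls are projected to
per-SNP calls, maximal runs of identical calls merged into blocks, and
breakpoints placed at the bp midpoint between runs.  The chromosome is cut
at the union of all individuals' breakpoints; each resulting segment --
within which no individual recombines -- is one *bin marker*.

Adjacent-bin recombination fractions are estimated from the bin genotypes
(RIL: Haldane-Waddington correction r = R/(2-2R); F2: maximum likelihood on
the two-locus genotype table) and converted to map distances with the
Kosambi function d = 25 ln((1+2r)/(1-2r)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "BinMap",
    "call_windows",
    "per_snp_calls",
    "merge_blocks",
    "define_bins",
    "estimate_recfrac",
    "kosambi_cm",
    "kosambi_inverse",
    "build_genetic_map",
    "make_binmap",
    "map_summary",
]

# bin genotype codes
A_HOM, HET, B_HOM = 0, 1, 2


@dataclass
class BinMap:
    """Recombination bins with genotypes and (optionally) a genetic map.

    bins : DataFrame (bin, chrom, start, end, n_snps[, cm])
    genotypes : n_individuals x n_bins codes {0:A-hom, 1:het, 2:B-hom, -1}
    """

    bins: pd.DataFrame
    genotypes: np.ndarray
    ids: list[str]
    population: str = "RIL"
    recfrac: np.ndarray | None = None  # r per adjacent pair, NaN across chromosomes

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_index(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Moving window sums along the last axis (valid mode)."""
    cs = np.cumsum(x, axis=-1, dtype=np.int32)
    out = cs[..., w - 1:].copy()
    out[..., 1:] -= cs[..., :-w]
    return out


def call_windows(
    calls: np.ndarray,
    window: int = 15,
    hom_count: int = 11,
    min_called: int = 8,
) -> np.ndarray:
    """Sliding-window parental calls for one chromosome.

    calls: (n_individuals, m) or (m,) SNP codes {0:A,1:het,2:B,-1 missing},
    pre-phased against the two parents.  Returns window calls in
    {0:A, 1:H, 2:B}; if m < window a single window over all markers is used
    with the threshold scaled to its size.
    """
    calls = np.atleast_2d(np.asarray(calls))
    m = calls.shape[1]
    if m == 0:
        raise ValueError("no markers on chromosome")
    w = min(window, m)
    thresh_base = hom_count * w / window  # scale threshold if fewer markers than window

    cnt_a = _moving_sum(calls == A_HOM, w)
    cnt_b = _moving_sum(calls == B_HOM, w)
    called = _moving_sum(calls != MISSING, w)

    thresh = np.ceil(thresh_base * called / w).astype(int)
    out = np.full(cnt_a.shape, HET, dtype=np.int8)
    out[cnt_a >= np.maximum(thresh, 1)] = A_HOM
    out[cnt_b >= np.maximum(thresh, 1)] = B_HOM

    scaled_min = int(np.ceil(min_called * w / window))
    invalid = called < scaled_min
    if invalid.any():
        n_win = out.shape[1]
        idx = np.arange(n_win)
        for i in np.flatnonzero(invalid.any(axis=1)):
            good = ~invalid[i]
            if not good.any():
                continue  # leave as-is: nothing to propagate from
            nearest = np.searchsorted(idx[good], idx, side="left")
            gpos = idx[good]
            nearest = np.clip(nearest, 0, len(gpos) - 1)
            left = np.clip(nearest - 1, 0, len(gpos) - 1)
            pick = np.where(
                np.abs(gpos[nearest] - idx) <= np.abs(idx - gpos[left]), nearest, left
            )
            row = out[i].copy()
            out[i, invalid[i]] = row[gpos[pick[invalid[i]]]]
    return out


def per_snp_calls(window_calls: np.ndarray, m: int) -> np.ndarray:
    """Project window calls to per-SNP calls: SNP s takes the call of the
    window starting at s; the trailing SNPs take the last window's call."""
    window_calls = np.atleast_2d(window_calls)
    n_win = window_calls.shape[1]
    idx = np.minimum(np.arange(m), n_win - 1)
    return window_calls[:, idx]


def resolve_transition_het(snp_calls: np.ndarray, window: int = 15) -> np.ndarray:
    """Sharpen crossover transition zones in per-SNP calls.

    Between two opposite homozygous regions the sliding window necessarily
    passes through a short stretch where neither parent reaches the count
    threshold, leaving an artificial heterozygous zone of up to ~window
    SNPs at every homozygote-to-homozygote crossover.  Heterozygous runs
    shorter than the window that are flanked by the two different
    homozygous calls are therefore split at their midpoint between the two
    flanks.  Runs flanked by identical calls (residual heterozygosity
    islands) are left untouched.
    """
    out = np.atleast_2d(snp_calls).copy()
    for i in range(out.shape[0]):
        row = out[i]
        change = np.flatnonzero(np.diff(row) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [len(row) - 1]])
        for s, e in zip(starts, ends):
            if row[s] != HET or (e - s + 1) >= window or s == 0 or e == len(row) - 1:
                continue
            left, right = row[s - 1], row[e + 1]
            if {left, right} == {A_HOM, B_HOM}:
                mid = (s + e + 1) // 2
                row[s:mid] = left
                row[mid:e + 1] = right
    return out


def merge_blocks(snp_calls_row: np.ndarray, pos: np.ndarray):
    """Blocks (maximal runs) and breakpoints for one individual.

    Returns (blocks, breakpoints): blocks as a list of (start_snp, end_snp,
    call); breakpoints as bp midpoints between the last SNP of one run and
    the first SNP of the next.
    """
    change = np.flatnonzero(np.diff(snp_calls_row) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(snp_calls_row) - 1]])
    blocks = [(int(s), int(e), int(snp_calls_row[s])) for s, e in zip(starts, ends)]
    breakpoints = [(pos[c] + pos[c + 1]) / 2.0 for c in change]
    return blocks, breakpoints


def define_bins(snp_calls: np.ndarray, markers: pd.DataFrame, ids, population="RIL") -> BinMap:
    """Cut each chromosome at the union of all individuals' breakpoints.

    snp_calls: n_individuals x n_markers per-SNP parental calls for the whole
    genome (columns ordered as in markers).  Each resulting segment is one
    bin; an individual's bin genotype is its (constant) call over the bin.
    """
    snp_calls = np.atleast_2d(snp_calls)
    rows = []
    geno_cols = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        calls_c = snp_calls[:, cols]
        pos = sub["pos"].to_numpy()
        # union of cut indices: cut after SNP s when any individual changes call
        change_any = np.flatnonzero((np.diff(calls_c, axis=1) != 0).any(axis=0))
        starts = np.concatenate([[0], change_any + 1])
        ends = np.concatenate([change_any, [calls_c.shape[1] - 1]])
        for s, e in zip(starts, ends):
            assert (calls_c[:, s] == calls_c[:, e]).all(), "breakpoint inside a bin"
            rows.append((f"{chrom}:{pos[s]}-{pos[e]}", chrom, int(pos[s]), int(pos[e]), int(e - s + 1)))
            geno_cols.append(calls_c[:, s])
    bins = pd.DataFrame(rows, columns=["bin", "chrom", "start", "end", "n_snps"])
    genotypes = np.stack(geno_cols, axis=1).astype(np.int8)
    return BinMap(bins=bins, genotypes=genotypes, ids=list(ids), population=population)


def _f2_two_locus_table(r: float) -> np.ndarray:
    """3x3 F2 genotype probabilities at recombination fraction r."""
    g = np.array([(1 - r) / 2, r / 2])  # [parental, recombinant] per gamete class
    # gamete haplotypes: (a1, a2) with probs: AB, ab parental; Ab, aB recombinant
    haps = [((0, 0), g[0]), ((1, 1), g[0]), ((0, 1), g[1]), ((1, 0), g[1])]
    tab = np.zeros((3, 3))
    for (a1, b1), p1 in haps:
        for (a2, b2), p2 in haps:
            tab[a1 + a2, b1 + b2] += p1 * p2
    return tab


def estimate_recfrac(binmap: BinMap, population: str | None = None) -> np.ndarray:
    """Recombination fraction per adjacent bin pair (NaN between chromosomes).

    RIL: observed recombinant fraction R corrected to r = R/(2-2R)
    (Haldane-Waddington); heterozygous or missing calls are excluded.
    F2: maximum-likelihood r from the two-locus genotype table.
    Monomorphic bins give an undefined r: the interval is skipped (NaN set
    to 0 when building the map) with a warning.
    """
    population = population or binmap.population
    G = binmap.genotypes
    r_out = np.full(binmap.n_bins - 1, np.nan)
    chroms = binmap.bins["chrom"].to_numpy()
    for k in range(binmap.n_bins - 1):
        if chroms[k] != chroms[k + 1]:
            continue
        g1, g2 = G[:, k], G[:, k + 1]
        if population == "RIL":
            ok = np.isin(g1, [A_HOM, B_HOM]) & np.isin(g2, [A_HOM, B_HOM])
            if ok.sum() == 0 or len(np.unique(g1[ok])) < 2 or len(np.unique(g2[ok])) < 2:
                warnings.warn(f"monomorphic bin pair at index {k}: interval skipped")
                continue
            R = float((g1[ok] != g2[ok]).mean())
            R = min(R, 0.49999)
            r = R / (2.0 - 2.0 * R)
        else:  # F2
            ok = (g1 != MISSING) & (g2 != MISSING)
            counts = np.zeros((3, 3))
            for a, b in zip(g1[ok], g2[ok]):
                counts[a, b] += 1
            if counts.sum(axis=1).max() == counts.sum() or counts.sum(axis=0).max() == counts.sum():
                warnings.warn(f"monomorphic bin pair at index {k}: interval skipped")
                continue

            def nll(rr):
                tab = _f2_two_locus_table(rr)
                return -float((counts * np.log(np.maximum(tab, 1e-300))).sum())

            res = minimize_scalar(nll, bounds=(1e-6, 0.49), method="bounded",
                                  options={"xatol": 1e-8})
            r = float(res.x)
        r_out[k] = min(max(r, 0.0), 0.49)
    return r_out


def kosambi_cm(r):
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any(r[~np.isnan(r)] >= 0.5) or np.any(r[~np.isnan(r)] < 0):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm):
    """Recombination fraction from Kosambi cM: r = tanh(d/50)/2."""
    d = np.asarray(d_cm, dtype=float)
    r = np.tanh(d / 50.0) / 2.0
    return float(r) if r.ndim == 0 else r


def build_genetic_map(binmap: BinMap, population: str | None = None) -> BinMap:
    """Assign cumulative Kosambi cM positions to bins (in place, returned)."""
    r = estimate_recfrac(binmap, population)
    binmap.recfrac = r
    cm = np.zeros(binmap.n_bins)
    chroms = binmap.bins["chrom"].to_numpy()
    for k in range(1, binmap.n_bins):
        if chroms[k] != chroms[k - 1]:
            cm[k] = 0.0
        else:
            rk = r[k - 1]
            step = 0.0 if np.isnan(rk) else kosambi_cm(rk)
            cm[k] = cm[k - 1] + step
    binmap.bins["cm"] = cm
    return binmap


def make_binmap(geno: GenotypeMatrix, window: int = 15, hom_count: int = 11,
                min_called: int = 8) -> BinMap:
    """Full bin-map construction from a biparental genotype matrix.

    Genotypes must be coded against the parents (0 = parent-A homozygote,
    2 = parent-B homozygote, 1 = heterozygote).
    """
    markers = geno.markers.reset_index(drop=True)
    snp_calls = np.empty_like(geno.values)
    for chrom, sub in markers.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        wc = call_windows(geno.values[:, cols], window, hom_count, min_called)
        snp_calls[:, cols] = resolve_transition_het(per_snp_calls(wc, len(cols)), window)
    bm = define_bins(snp_calls, markers, geno.ids, geno.population)
    return build_genetic_map(bm)


def map_summary(binmap: BinMap) -> pd.DataFrame:
    """Per-chromosome and total bin-map statistics.

    Columns: n_bins, physical_mb, map_cm, mean_interval_cm, max_interval_cm,
    frac_lt_1mb.  The total mean interval is total cM / (bins - chromosomes).
    """
    if "cm" not in binmap.bins.columns:
        raise ValueError("build_genetic_map must be run first")
    rows = []
    bins = binmap.bins
    total_cm = 0.0
    total_bins = 0
    total_mb = 0.0
    max_int_all = 0.0
    n_chrom = 0
    lt1 = ((bins["end"] - bins["start"] + 1) < 1_000_000).sum()
    for chrom, sub in bins.groupby("chrom", sort=False):
        n_chrom += 1
        cm = sub["cm"].to_numpy()
        intervals = np.diff(cm)
        length_cm = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
        mb = (sub["end"].max() - sub["start"].min() + 1) / 1e6
        mean_int = length_cm / (len(sub) - 1) if len(sub) > 1 else 0.0
        max_int = float(intervals.max()) if len(intervals) else 0.0
        rows.append((chrom, len(sub), mb, length_cm, mean_int, max_int,
                     ((sub["end"] - sub["start"] + 1) < 1_000_000).mean()))
        total_cm += length_cm
        total_bins += len(sub)
        total_mb += mb
        max_int_all = max(max_int_all, max_int)
    denom = total_bins - n_chrom
    rows.append(("Total", total_bins, total_mb, total_cm,
                 total_cm / denom if denom > 0 else 0.0, max_int_all,
                 lt1 / total_bins))
    return pd.DataFrame(rows, columns=[
        "chrom", "n_bins", "physical_mb", "map_cm",
        "mean_interval_cm", "max_interval_cm", "frac_lt_1mb",
    ])
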