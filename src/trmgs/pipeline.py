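"""Cross-validation engine: TRM discovery inside folds, marker-count sweeps,
random-marker baselines, and prediction-accuracy (r_MG) tables.

The experimental design is k-fold cross-validation (default 5) replicated
with independent shuffles.  Within every fold the mapping scan (GWAS for
the natural panel, a LOD scan on bin markers for biparental populations)
is run on the training individuals only; the top-n markers by the scan
statistic are the trait-relevant markers (TRMs) of that fold.  Kernels are
then built from the selected markers over *all* individuals — genotypes
carry no phenotype information — and the model is fitted with the testing
fold's phenotypes masked.  Accuracy is r_MG, the Pearson correlation
between predicted genetic values and the BLUEs of the testing fold.

Random-marker baselines are redrawn once per replicate (shared across the
folds of that replicate).  Bin maps are genotype-only and are computed once
on all individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import BinMap
from .kernels import Kernel, compute_D, compute_Ga, compute_Gaa, compute_Gd, pc_fixed_design
from .mapping import (TRMSet, bin_lod_table, cim_scan, gwas_scan, pca_matrix,
                      select_random_markers, select_trms, vanraden_kinship)
from .gsmodels import fit_bayesc, fit_gblup_reml, fit_multikernel_gibbs
from .simdata import GenotypeMatrix

__all__ = [
    "FoldPlan",
    "CVData",
    "make_folds",
    "run_cv_cell",
    "sweep",
    "aggregate_accuracy",
]

NATURAL_LADDER = (20, 50, 100, 500, 1_000, 5_000, 10_000, 30_000, "all")
BIPARENTAL_LADDER = (20, 50, 100, 500, 1_000, 1_500, 2_000, "all")

MODELS = ("A", "A+AA", "A+D", "A+D+AA", "BC+PC", "G+PC")


@dataclass
class FoldPlan:
    """Replicated k-fold partitions of individual indices."""

    folds: list[list[np.ndarray]]  # [replicate][fold] -> test indices
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.folds)

    @property
    def k(self) -> int:
        return len(self.folds[0])


def make_folds(ids, k: int = 5, n_reps: int = 100, seed: int | None = None) -> FoldPlan:
    """Independent seeded shuffles; within a replicate the folds partition
    all individuals with sizes differing by at most one."""
    n = len(ids)
    if k < 2 or k > n:
        raise ValueError("k must be between 2 and the number of individuals")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        reps.append([np.sort(f) for f in np.array_split(perm, k)])
    return FoldPlan(folds=reps, seed=seed)


@dataclass
class CVData:
    """Everything one population contributes to the CV engine.

    For biparental populations the bin map doubles as the marker set: the
    scan is a LOD profile over bins and kernels are built from bin
    genotypes.  For the natural panel markers are the SNPs themselves.
    """

    geno: GenotypeMatrix
    blues: pd.Series  # indexed by individual id, aligned with geno.ids
    population: str = "natural"  # natural | RIL | F2
    binmap: BinMap | None = None
    n_pc_gwas: int = 7
    n_pc_fixed: int = 7

    def __post_init__(self):
        self.blues = self.blues.reindex(self.geno.ids)
        if self.blues.isna().any():
            warnings.warn("individuals without BLUEs are skipped in CV folds")
        if self.population != "natural" and self.binmap is None:
            raise ValueError("biparental CV requires a bin map")

    @property
    def marker_ids(self) -> list[str]:
        if self.population == "natural":
            return list(self.geno.markers["marker"])
        return list(self.binmap.bins["bin"])

    def marker_codes(self, marker_ids=None) -> np.ndarray:
        """0/1/2 codes (individuals x markers) for kernel construction."""
        if self.population == "natural":
            if marker_ids is None:
                return self.geno.values
            pos = pd.Index(self.geno.markers["marker"]).get_indexer(marker_ids)
            return self.geno.values[:, pos]
        if marker_ids is None:
            return self.binmap.genotypes
        pos = pd.Index(self.binmap.bins["bin"]).get_indexer(marker_ids)
        return self.binmap.genotypes[:, pos]


def _binmap_rows(binmap: BinMap, idx: np.ndarray) -> BinMap:
    return BinMap(
        bins=binmap.bins,
        genotypes=binmap.genotypes[idx],
        ids=[binmap.ids[i] for i in idx],
        population=binmap.population,
        recfrac=binmap.recfrac,
    )


def fold_scan(data: CVData, train_idx: np.ndarray,
              scan_opts: dict | None = None) -> pd.DataFrame:
    """Mapping scan restricted to training individuals.

    Natural panel: Q+K GWAS (PCs and kinship recomputed on the training
    genotypes).  Biparental: composite-interval-mapping LOD profile on the
    population bin map, reduced to per-bin statistics.
    """
    opts = scan_opts or {}
    y_train = data.blues.to_numpy()[train_idx]
    if data.population == "natural":
        sub = data.geno.take_individuals(train_idx)
        n_pc = min(data.n_pc_gwas, len(train_idx) - 2)
        pcs = pca_matrix(sub, n_pc) if n_pc > 0 else None
        K = vanraden_kinship(sub)
        return gwas_scan(y_train, sub, pcs=pcs, K=K)
    bm = _binmap_rows(data.binmap, train_idx)
    profile = cim_scan(y_train, bm,
                       n_cofactors=opts.get("n_cofactors", 5),
                       window_cm=opts.get("window_cm", 10.0),
                       step_cm=opts.get("step_cm", 1.0),
                       population=data.population)
    return bin_lod_table(profile, bm)


def _model_kernels(model: str, codes: np.ndarray, ids) -> list[Kernel]:
    ga = compute_Ga(codes)
    ga = Kernel(ga.matrix, list(ids), "additive")
    kernels = [ga]
    if "D" in model.split("+"):
        D, _ = compute_D(codes)
        kernels.append(compute_Gd(D, ids=list(ids)))
    if "AA" in model.split("+"):
        kernels.append(compute_Gaa(ga))
    return kernels


def _fit_and_predict(model: str, y_masked: np.ndarray, codes: np.ndarray,
                     ids, gibbs_opts: dict, seed) -> np.ndarray:
    """Returns the genetic-value prediction vector for all individuals."""
    if model == "A":
        if gibbs_opts.get("force_gibbs"):
            fit = fit_multikernel_gibbs(y_masked, _model_kernels("A", codes, ids),
                                        iters=gibbs_opts["iters"],
                                        burnin=gibbs_opts["burnin"], seed=seed)
        else:
            fit = fit_gblup_reml(y_masked, _model_kernels("A", codes, ids)[0])
        return fit.gebv["total"].to_numpy()
    if model in ("A+AA", "A+D", "A+D+AA"):
        kernels = _model_kernels(model, codes, ids)
        fit = fit_multikernel_gibbs(y_masked, kernels,
                                    iters=gibbs_opts["iters"],
                                    burnin=gibbs_opts["burnin"], seed=seed)
        return fit.gebv["total"].to_numpy()
    if model == "BC+PC":
        X = pc_fixed_design(codes, gibbs_opts.get("n_pc", 7))
        fit = fit_bayesc(y_masked, X, codes, iters=gibbs_opts["iters"],
                         burnin=gibbs_opts["burnin"], seed=seed)
        return fit.gebv["total"].to_numpy()
    if model == "G+PC":
        X = pc_fixed_design(codes, gibbs_opts.get("n_pc", 7))
        kernels = _model_kernels("A", codes, ids)
        fit = fit_multikernel_gibbs(y_masked, kernels, X=X,
                                    iters=gibbs_opts["iters"],
                                    burnin=gibbs_opts["burnin"], seed=seed)
        return fit.gebv["total"].to_numpy()
    raise ValueError(f"unknown model '{model}' (choose from {MODELS})")


def _r_mg(gebv_test: np.ndarray, blue_test: np.ndarray) -> float:
    if np.std(gebv_test) == 0 or np.std(blue_test) == 0:
        warnings.warn("constant predictions in a fold: r_MG recorded as 0")
        return 0.0
    return float(np.corrcoef(gebv_test, blue_test)[0, 1])


DEFAULT_GIBBS = {"iters": 1_500, "burnin": 500}


def run_cv_cell(
    data: CVData,
    foldplan: FoldPlan,
    marker_source: str,
    n_markers,
    model: str = "A",
    seed: int | None = None,
    gibbs_opts: dict | None = None,
    scan_opts: dict | None = None,
    scan_cache: dict | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """One cell of the design: all replicates x folds at a fixed marker
    source, marker count and model.  Returns long-format accuracy rows."""
    gibbs_opts = {**DEFAULT_GIBBS, **(gibbs_opts or {})}
    scan_cache = scan_cache if scan_cache is not None else {}
    marker_ids = data.marker_ids
    m_all = len(marker_ids)
    k_markers = m_all if n_markers == "all" else int(n_markers)
    if k_markers > m_all:
        raise ValueError(f"n_markers={n_markers} exceeds available markers ({m_all})")
    y_all = data.blues.to_numpy()
    phenotyped = ~np.isnan(y_all)

    rows = []
    for rep, folds in enumerate(foldplan.folds):
        rep_seed = (0 if seed is None else seed) * 100_003 + rep
        random_set = select_random_markers(marker_ids, k_markers,
                                           seed=rep_seed % (2**31 - 1)).markers
        for fold_id, test_idx in enumerate(folds):
            test_idx = test_idx[phenotyped[test_idx]]
            if len(test_idx) == 0:
                warnings.warn("fold with no phenotyped individuals skipped")
                continue
            train_idx = np.setdiff1d(np.arange(len(y_all)), test_idx)
            train_idx = train_idx[phenotyped[train_idx]]
            if marker_source == "TRM" and k_markers < m_all:
                key = (rep, fold_id)
                if key not in scan_cache:
                    scan_cache[key] = fold_scan(data, train_idx, scan_opts)
                trms = select_trms(scan_cache[key], k_markers, trait=trait,
                                   fold=fold_id).markers
            elif marker_source == "TRM":
                trms = marker_ids
            elif marker_source == "RAN":
                trms = marker_ids if k_markers == m_all else random_set
            else:
                raise ValueError("marker_source must be 'TRM' or 'RAN'")
            codes = data.marker_codes(trms)
            y_masked = y_all.copy()
            y_masked[test_idx] = np.nan
            fit_seed = (rep_seed * 1_009 + fold_id) % (2**31 - 1)
            gebv = _fit_and_predict(model, y_masked, codes, data.geno.ids,
                                    gibbs_opts, fit_seed)
            r = _r_mg(gebv[test_idx], y_all[test_idx])
            rows.append((trait, data.population, model, marker_source,
                         n_markers, rep, fold_id, r))
    return pd.DataFrame(rows, columns=["trait", "population", "model",
                                       "marker_source", "n_markers",
                                       "replicate", "fold", "r_mg"])


def sweep(
    data: CVData,
    foldplan: FoldPlan,
    marker_ladder,
    sources=("TRM", "RAN"),
    models=("A",),
    seed: int | None = None,
    gibbs_opts: dict | None = None,
    scan_opts: dict | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Full factorial over (model, source, marker count); the per-fold scan
    is computed once and shared across all cells."""
    scan_cache: dict = {}
    tables = []
    for model in models:
        for source in sources:
            for n_markers in marker_ladder:
                tables.append(run_cv_cell(
                    data, foldplan, source, n_markers, model=model, seed=seed,
                    gibbs_opts=gibbs_opts, scan_opts=scan_opts,
                    scan_cache=scan_cache, trait=trait,
                ))
    return pd.concat(tables, ignore_index=True)


def aggregate_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of r_MG over replicates x folds per design cell."""
    g = table.groupby(["trait", "population", "model", "marker_source",
                       "n_markers"], sort=False)["r_mg"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "r_mg_mean", "std": "r_mg_sd", "count": "n_cells"})
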