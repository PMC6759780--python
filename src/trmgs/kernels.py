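"""Genomic relationship matrices: additive, dominance, additive-by-additive.

The additive kernel follows VanRaden: W = Z - 2p (column-centered marker
codes), G_a = WW' / (2 * sum_k p_k (1 - p_k)).  The dominance design matrix
uses the genotype-frequency parameterization

    d_ij = -2 p12 p22 / theta   (x = 0)
            4 p11 p22 / theta   (x = 1)
           -2 p11 p12 / theta   (x = 2)

with theta = p11 + p22 - (p11 - p22)^2, and G_d = n DD' / trace(DD') so that
trace(G_d) = n.  The additive-by-additive kernel is the Hadamard square
G_aa = G_a o G_a.  Allele frequencies are always recomputed from the matrix
supplied, so kernels built inside cross-validation use the genotypes of all
individuals (training and testing) while never touching test phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "Kernel",
    "GenotypeFreqs",
    "compute_Ga",
    "genotype_freqs",
    "compute_D",
    "compute_Gd",
    "compute_Gaa",
    "pc_fixed_design",
    "pca_scores",
]


@dataclass
class Kernel:
    """Symmetric n x n relationship matrix with individual ids."""

    matrix: np.ndarray
    ids: list[str]
    kind: str  # additive | dominance | epistatic_aa | identity

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n != len(self.ids):
            raise ValueError("kernel must be square and match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def check_psd(self, rtol: float = 1e-8) -> None:
        ev = np.linalg.eigvalsh(self.matrix)
        if ev[0] < -rtol * max(ev[-1], 1.0):
            raise ValueError(f"kernel not positive semidefinite (min eig {ev[0]:.3g})")

    def subset(self, idx) -> "Kernel":
        idx = np.asarray(idx)
        return Kernel(self.matrix[np.ix_(idx, idx)], [self.ids[i] for i in idx], self.kind)


@dataclass
class GenotypeFreqs:
    """Per-locus genotype frequencies and the dominance scale theta."""

    p11: np.ndarray  # freq of code 0
    p12: np.ndarray  # freq of code 1
    p22: np.ndarray  # freq of code 2
    p: np.ndarray    # alt allele frequency
    theta: np.ndarray


def _values(geno) -> tuple[np.ndarray, list[str]]:
    if isinstance(geno, GenotypeMatrix):
        return geno.values, list(geno.ids)
    z = np.asarray(geno)
    return z, [str(i) for i in range(z.shape[0])]


def genotype_freqs(geno) -> GenotypeFreqs:
    """Genotype-class frequencies on non-missing calls and
    theta = p11 + p22 - (p11 - p22)^2."""
    z, _ = _values(geno)
    called = (z != MISSING).sum(axis=0).astype(float)
    called = np.maximum(called, 1.0)
    p11 = (z == 0).sum(axis=0) / called
    p12 = (z == 1).sum(axis=0) / called
    p22 = (z == 2).sum(axis=0) / called
    p = p22 + p12 / 2.0
    theta = p11 + p22 - (p11 - p22) ** 2
    return GenotypeFreqs(p11=p11, p12=p12, p22=p22, p=p, theta=theta)


def compute_Ga(geno) -> Kernel:
    """VanRaden additive kernel G_a = WW' / (2 sum p(1-p)).

    Missing codes are imputed to the column mean 2p; rows of G_a sum to
    zero because frequencies come from the sample itself.
    """
    z, ids = _values(geno)
    f = genotype_freqs(z)
    denom = 2.0 * float(np.sum(f.p * (1.0 - f.p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: additive kernel undefined")
    W = z.astype(float)
    W[z == MISSING] = 0.0
    W = np.where(z == MISSING, 2.0 * f.p[None, :], W)
    W = W - 2.0 * f.p[None, :]
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return Kernel(G, ids, "additive")


def compute_D(geno, freqs: GenotypeFreqs | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Dominance design matrix; returns (D, kept_mask).

    Loci with theta = 0 (no heterozygotes or otherwise degenerate) are
    excluded and flagged in the mask; missing genotypes map to 0.
    """
    z, _ = _values(geno)
    f = freqs or genotype_freqs(z)
    kept = f.theta > 1e-12
    if not kept.any():
        raise ValueError("all loci have theta = 0: dominance matrix undefined")
    if not kept.all():
        warnings.warn(f"{int((~kept).sum())} loci with theta = 0 dropped from D")
    zk = z[:, kept].astype(float)
    p11, p12, p22, th = f.p11[kept], f.p12[kept], f.p22[kept], f.theta[kept]
    d0 = -2.0 * p12 * p22 / th
    d1 = 4.0 * p11 * p22 / th
    d2 = -2.0 * p11 * p12 / th
    D = np.zeros_like(zk)
    D = np.where(zk == 0, d0[None, :], D)
    D = np.where(zk == 1, d1[None, :], D)
    D = np.where(zk == 2, d2[None, :], D)
    D[z[:, kept] == MISSING] = 0.0
    return D, kept


def compute_Gd(D: np.ndarray, ids=None) -> Kernel:
    """Dominance kernel G_d = n DD' / trace(DD')."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    DDt = D @ D.T
    tr = float(np.trace(DDt))
    if tr <= 0:
        raise ValueError("trace(DD') = 0: dominance kernel undefined")
    G = n * DDt / tr
    G = (G + G.T) / 2.0
    ids = ids if ids is not None else [str(i) for i in range(n)]
    return Kernel(G, list(ids), "dominance")


def compute_Gaa(Ga: Kernel) -> Kernel:
    """Additive-by-additive kernel: the Hadamard square of G_a."""
    return Kernel(Ga.matrix * Ga.matrix, list(Ga.ids), "epistatic_aa")


def pca_scores(geno, n_pc: int) -> np.ndarray:
    """PC scores of the column-centered genotype matrix (SVD).

    Missing codes are mean-imputed.  Sign convention: the largest-magnitude
    loading of each component is positive.  n_pc = 0 gives an (n, 0) matrix.
    """
    z, _ = _values(geno)
    n, m = z.shape
    if n_pc >= min(n, m):
        raise ValueError("n_pc must be < min(n_individuals, n_markers)")
    if n_pc == 0:
        return np.empty((n, 0))
    X = z.astype(float)
    f = genotype_freqs(z)
    X = np.where(z == MISSING, 2.0 * f.p[None, :], X)
    X = X - X.mean(axis=0)
    if not X.any():
        raise ValueError("constant genotype matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = U * s[None, :] * signs[None, :]
    return scores[:, :n_pc]


def pc_fixed_design(trm_geno, n_pc: int = 7) -> np.ndarray:
    """Fixed-effect design X = [intercept | PC scores of the marker subset].

    PCs are computed from the supplied (TRM) genotype submatrix only.
    Components with negligible singular value are dropped with a warning.
    """
    z, _ = _values(trm_geno)
    n = z.shape[0]
    n_pc_eff = min(n_pc, min(n, z.shape[1]) - 1)
    scores = pca_scores(z, n_pc_eff) if n_pc_eff > 0 else np.empty((n, 0))
    norms = np.linalg.norm(scores, axis=0)
    keep = norms > 1e-8 * max(norms.max(initial=0.0), 1.0)
    if not keep.all() or n_pc_eff < n_pc:
        warnings.warn("rank-deficient PC design: trailing components dropped")
        scores = scores[:, keep]
    return np.hstack([np.ones((n, 1)), scores])
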