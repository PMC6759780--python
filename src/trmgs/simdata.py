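"""Simulation of experimental maize-style populations and phenotypes.

Three population designs are supported, mirroring the usual layouts of
quantitative-genetics experiments in crops:

* a **natural inbred panel** with subpopulation structure (Balding–Nichols
  allele-frequency model),
* a **RIL** population (recombinant inbred lines obtained by repeated
  selfing from an F1), and
* an **F2** population (one generation of random union of F1 gametes);
  F2:3 family phenotypes are attached to the genotype of the F2 plant.

Genotypes are coded 0/1/2 as the count of the alternate (parent-B) allele,
with ``-1`` for missing.  Phenotypes follow the multi-environment trial
model ``y_ijl = mu + g_i + e_l + ge_il + r_jl + eps_ijl`` where the genetic
value ``g_i`` is composed of additive, dominance and additive-by-additive
QTL effects; effect sizes are rescaled so that the realized variance
fractions match the requested targets on the simulated sample.

Crossovers are simulated as a Poisson process on the genetic map (no
interference), so adjacent-locus recombination follows the Haldane map
function.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "ChromSpec",
    "GenotypeMatrix",
    "Founders",
    "TraitArchitecture",
    "simulate_founders",
    "simulate_meiosis",
    "make_ril_population",
    "make_f2_population",
    "make_natural_population",
    "random_architecture",
    "simulate_phenotypes",
    "inject_missing",
    "inject_errors",
]


@dataclass(frozen=True)
class ChromSpec:
    """Physical and genetic length of one chromosome."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be positive")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: negative map length")


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes with marker metadata.

    values : int8 array, codes in {0, 1, 2, -1(missing)}
    markers : DataFrame with columns marker, chrom, pos, cm, ref, alt
    ids : individual identifiers
    population : one of "natural", "RIL", "F2"
    """

    values: np.ndarray
    markers: pd.DataFrame
    ids: list[str]
    population: str = "natural"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x markers)")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("number of rows must match number of ids")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("number of columns must match marker table")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        for _, sub in self.markers.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def take_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            self.markers.iloc[idx].reset_index(drop=True),
            list(self.ids),
            self.population,
        )

    def take_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            self.markers.copy(),
            [self.ids[i] for i in idx],
            self.population,
        )


@dataclass
class Founders:
    """Two fully homozygous parents plus ancestral allele frequencies."""

    markers: pd.DataFrame
    chromosomes: list[ChromSpec]
    parent_a: np.ndarray  # all 0 at segregating loci
    parent_b: np.ndarray  # all 2 at segregating loci
    ancestral_freq: np.ndarray  # minor (alt) allele frequency per marker

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _draw_positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """n strictly increasing integer positions in [1, length_bp]."""
    if n > length_bp:
        raise ValueError("more markers than base pairs on a chromosome")
    pos = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n] if len(pos) == n else pos


def simulate_founders(
    n_markers: int,
    chromosomes: Sequence[ChromSpec] | Sequence[tuple],
    maf_law: float | Callable[[np.random.Generator, int], np.ndarray] = 0.25,
    seed: int | None = None,
) -> Founders:
    """Lay out markers on chromosomes and create two homozygous parents.

    Markers are distributed across chromosomes proportionally to physical
    length; positions are uniform, genetic positions linear in bp.
    ``maf_law`` gives ancestral minor-allele frequencies for the natural
    panel: either a constant in (0, 0.5] or a callable ``f(rng, size)``.
    """
    chroms = [c if isinstance(c, ChromSpec) else ChromSpec(*c) for c in chromosomes]
    if len(chroms) == 0:
        raise ValueError("at least one chromosome required")
    if n_markers < len(chroms):
        raise ValueError("fewer markers than chromosomes: a chromosome would get zero markers")
    rng = np.random.default_rng(seed)

    total_bp = sum(c.length_bp for c in chroms)
    counts = np.maximum(1, np.floor([n_markers * c.length_bp / total_bp for c in chroms]).astype(int))
    while counts.sum() < n_markers:
        counts[np.argmax([c.length_bp / k for c, k in zip(chroms, counts)])] += 1
    while counts.sum() > n_markers:
        i = int(np.argmax(counts))
        counts[i] -= 1
    if (counts == 0).any():
        raise ValueError("a chromosome received zero markers")

    rows = []
    for c, k in zip(chroms, counts):
        pos = _draw_positions(rng, int(k), c.length_bp)
        cm = pos / c.length_bp * c.length_cm
        for p, d in zip(pos, cm):
            rows.append((f"{c.name}_{p}", c.name, int(p), float(d)))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cm"])
    markers["ref"] = "A"
    markers["alt"] = "B"

    m = len(markers)
    if callable(maf_law):
        freqs = np.asarray(maf_law(rng, m), dtype=float)
    else:
        freqs = np.full(m, float(maf_law))
    if np.any((freqs <= 0) | (freqs > 0.5)):
        raise ValueError("maf_law must produce frequencies in (0, 0.5]")

    return Founders(
        markers=markers,
        chromosomes=chroms,
        parent_a=np.zeros(m, dtype=np.int8),
        parent_b=np.full(m, 2, dtype=np.int8),
        ancestral_freq=freqs,
    )


def _chrom_slices(markers: pd.DataFrame) -> list[tuple[str, slice]]:
    out = []
    start = 0
    for chrom, sub in markers.groupby("chrom", sort=False):
        out.append((chrom, slice(start, start + len(sub))))
        start += len(sub)
    return out


def simulate_meiosis(
    diplotype: np.ndarray,
    markers: pd.DataFrame,
    chromosomes: Sequence[ChromSpec],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One gamete haplotype from a (2, m) diplotype of allele indicators.

    Crossover counts per chromosome are Poisson(length in Morgans) with
    uniform placement on the cM scale (no interference); the gamete switches
    parental phase at each crossover.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    diplotype = np.asarray(diplotype)
    if diplotype.shape != (2, len(markers)):
        raise ValueError("diplotype must be 2 x n_markers")
    gamete = np.empty(len(markers), dtype=diplotype.dtype)
    lengths = {c.name: c.length_cm for c in chromosomes}
    cm_all = markers["cm"].to_numpy()
    for chrom, sl in _chrom_slices(markers):
        length_cm = lengths[chrom]
        if length_cm < 0:
            raise ValueError("negative map length")
        n_xo = rng.poisson(length_cm / 100.0)
        xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo)) if n_xo else np.empty(0)
        phase0 = rng.integers(0, 2)
        phase = (phase0 + np.searchsorted(xo, cm_all[sl])) % 2
        gamete[sl] = diplotype[:, sl][phase, np.arange(sl.stop - sl.start)]
    return gamete


def _check_homozygous_parents(founders: Founders) -> None:
    if np.any(founders.parent_a == 1) or np.any(founders.parent_b == 1):
        raise ValueError("parents must be fully homozygous")


def make_ril_population(
    founders: Founders,
    n_lines: int,
    n_selfing_generations: int = 6,
    seed: int | None = None,
) -> GenotypeMatrix:
    """RILs by single-seed descent from the F1 of the two parents.

    Residual heterozygosity per locus is ~0.5**n_selfing_generations.
    """
    if n_selfing_generations < 5:
        raise ValueError("n_selfing_generations must be >= 5")
    _check_homozygous_parents(founders)
    rng = np.random.default_rng(seed)
    m = founders.n_markers
    hap_a = (founders.parent_a // 2).astype(np.int8)
    hap_b = (founders.parent_b // 2).astype(np.int8)
    values = np.empty((n_lines, m), dtype=np.int8)
    for i in range(n_lines):
        dip = np.stack([hap_a, hap_b])
        for _ in range(n_selfing_generations):
            g1 = simulate_meiosis(dip, founders.markers, founders.chromosomes, rng)
            g2 = simulate_meiosis(dip, founders.markers, founders.chromosomes, rng)
            dip = np.stack([g1, g2])
        values[i] = dip.sum(axis=0)
    ids = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(values, founders.markers.copy(), ids, "RIL")


def make_f2_population(
    founders: Founders,
    n_individuals: int,
    seed: int | None = None,
) -> GenotypeMatrix:
    """F2 plants: two independent F1 gametes each (1:2:1 per locus)."""
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    _check_homozygous_parents(founders)
    rng = np.random.default_rng(seed)
    m = founders.n_markers
    hap_a = (founders.parent_a // 2).astype(np.int8)
    hap_b = (founders.parent_b // 2).astype(np.int8)
    f1 = np.stack([hap_a, hap_b])
    values = np.empty((n_individuals, m), dtype=np.int8)
    for i in range(n_individuals):
        g1 = simulate_meiosis(f1, founders.markers, founders.chromosomes, rng)
        g2 = simulate_meiosis(f1, founders.markers, founders.chromosomes, rng)
        values[i] = g1 + g2
    ids = [f"F2_{i + 1:04d}" for i in range(n_individuals)]
    return GenotypeMatrix(values, founders.markers.copy(), ids, "F2")


def make_natural_population(
    founders: Founders,
    n_subpops: int,
    n_per_subpop: int,
    fst: float,
    seed: int | None = None,
    residual_het: float = 0.0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Structured panel of inbred lines under the Balding–Nichols model.

    Subpopulation allele frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around
    the ancestral frequency p; individuals are inbred (codes 0/2 drawn with
    the subpopulation frequency), with optional residual heterozygosity.
    Returns the genotypes and the true subpopulation labels.
    """
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = founders.ancestral_freq
    m = founders.n_markers
    n = n_subpops * n_per_subpop
    values = np.empty((n, m), dtype=np.int8)
    labels = np.repeat(np.arange(n_subpops), n_per_subpop)
    scale = (1.0 - fst) / fst
    for s in range(n_subpops):
        ps = rng.beta(p * scale, (1.0 - p) * scale)
        rows = slice(s * n_per_subpop, (s + 1) * n_per_subpop)
        values[rows] = (rng.random((n_per_subpop, m)) < ps).astype(np.int8) * 2
    if residual_het > 0:
        het = rng.random((n, m)) < residual_het
        values[het] = 1
    ids = [f"L{(i + 1):04d}" for i in range(n)]
    geno = GenotypeMatrix(values, founders.markers.copy(), ids, "natural")
    return geno, labels


@dataclass
class TraitArchitecture:
    """Ground-truth QTL architecture and variance targets for one trait.

    ``fa``, ``fd``, ``faa`` are target fractions of phenotypic variance for
    the additive, dominance and additive-by-additive components.  The four
    non-genetic variances are absolute; the phenotypic variance implied is
    ``S / (1 - fa - fd - faa)`` with ``S`` their sum.
    """

    trait: str = "trait"
    additive: list[tuple[int, float]] = field(default_factory=list)
    dominance: list[tuple[int, float]] = field(default_factory=list)
    epistasis: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    fa: float = 0.5
    fd: float = 0.0
    faa: float = 0.0
    var_env: float = 0.20
    var_gxe: float = 0.10
    var_rep: float = 0.05
    var_resid: float = 0.25

    def __post_init__(self):
        if self.fa < 0 or self.fd < 0 or self.faa < 0:
            raise ValueError("variance fractions must be non-negative")
        if self.fa + self.fd + self.faa >= 1.0:
            raise ValueError("fa + fd + faa must be < 1")
        for v in (self.var_env, self.var_gxe, self.var_rep, self.var_resid):
            if v < 0:
                raise ValueError("variance components must be non-negative")

    def validate_indices(self, n_markers: int) -> None:
        idx = [i for i, _ in self.additive] + [i for i, _ in self.dominance]
        idx += [i for pair, _ in self.epistasis for i in pair]
        if idx and (min(idx) < 0 or max(idx) >= n_markers):
            raise ValueError("architecture references a marker index out of range")


def random_architecture(
    n_markers: int,
    n_additive: int = 30,
    n_dominance: int = 0,
    n_epistatic: int = 0,
    fa: float = 0.5,
    fd: float = 0.0,
    faa: float = 0.0,
    trait: str = "trait",
    seed: int | None = None,
    effect_shape: float | None = 0.4,
    **var_kwargs,
) -> TraitArchitecture:
    """Draw a random QTL architecture: dominance acts at additive QTL, and
    epistatic pairs are sampled among the additive QTL.

    Effect magnitudes are gamma-distributed (default shape 0.4, the
    long-standing convention for crop-trait simulation) with random signs,
    giving the heavy-tailed per-QTL variance spectrum seen in QTL studies —
    a few loci at 5-20% of phenotypic variance, the rest small.  Pass
    ``effect_shape=None`` for standard-normal effects (a near-uniform
    spectrum).
    """
    rng = np.random.default_rng(seed)

    def draw(k):
        if effect_shape is None:
            return rng.normal(size=k)
        return rng.gamma(effect_shape, 1.0, size=k) * rng.choice([-1.0, 1.0], size=k)

    add_idx = rng.choice(n_markers, size=n_additive, replace=False)
    additive = [(int(i), float(e)) for i, e in zip(add_idx, draw(n_additive))]
    dom_idx = rng.choice(add_idx, size=min(n_dominance, n_additive), replace=False)
    dominance = [(int(i), float(e)) for i, e in zip(dom_idx, draw(len(dom_idx)))]
    epistasis = []
    eff_aa = draw(n_epistatic)
    for k in range(n_epistatic):
        i, j = rng.choice(add_idx, size=2, replace=False)
        epistasis.append(((int(i), int(j)), float(eff_aa[k])))
    return TraitArchitecture(
        trait=trait, additive=additive, dominance=dominance, epistasis=epistasis,
        fa=fa, fd=fd, faa=faa, **var_kwargs,
    )


def _genetic_components(geno: GenotypeMatrix, arch: TraitArchitecture):
    """Centered additive, dominance and AA component vectors (unscaled)."""
    z = geno.values.astype(float)
    # simulation operates on complete genotypes; impute any missing to column mean
    if (geno.values == MISSING).any():
        for j in np.unique(np.where(geno.values == MISSING)[1]):
            col = z[:, j]
            miss = geno.values[:, j] == MISSING
            col[miss] = col[~miss].mean()
    w = z - z.mean(axis=0)
    h = (geno.values == 1).astype(float)
    n = geno.n_individuals

    comp_a = np.zeros(n)
    for i, a in arch.additive:
        comp_a += a * w[:, i]
    comp_d = np.zeros(n)
    for i, d in arch.dominance:
        comp_d += d * (h[:, i] - h[:, i].mean())
    comp_aa = np.zeros(n)
    for (i, j), e in arch.epistasis:
        prod = w[:, i] * w[:, j]
        comp_aa += e * (prod - prod.mean())
    return comp_a, comp_d, comp_aa


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    n_envs: int = 2,
    n_reps: int = 2,
    seed: int | None = None,
    mu: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Replicated multi-environment phenotypes plus ground truth.

    Genetic component vectors are rescaled (fixed point iteration) so that
    the realized fractions var(component)/Var(y) equal the targets on this
    sample.  Returns a long-format record table (individual, env, rep,
    trait, value) and a truth dict with the component vectors and scales.
    """
    if n_envs < 1 or n_reps < 1:
        raise ValueError("n_envs and n_reps must be >= 1")
    arch.validate_indices(geno.n_markers)
    if arch.fd > 0 and not (geno.values == 1).any():
        raise ValueError("dominance fraction > 0 requested but population has no heterozygotes")
    rng = np.random.default_rng(seed)
    n = geno.n_individuals

    comps = list(_genetic_components(geno, arch))
    targets = [arch.fa, arch.fd, arch.faa]
    S = arch.var_env + arch.var_gxe + arch.var_rep + arch.var_resid
    scales = [1.0, 1.0, 1.0]
    for k in range(3):
        v = comps[k].var()
        if targets[k] > 0 and v <= 0:
            raise ValueError("a genetic component with positive target fraction has zero variance")
        if targets[k] == 0:
            comps[k] = np.zeros(n)
    for _ in range(60):
        g = comps[0] + comps[1] + comps[2]
        vp = g.var() + S
        new = []
        for k in range(3):
            if targets[k] > 0:
                new.append(np.sqrt(targets[k] * vp / comps[k].var()))
            else:
                new.append(1.0)
        comps = [c * s for c, s in zip(comps, new)]
        scales = [a * b for a, b in zip(scales, new)]
        if max(abs(s - 1.0) for s in new) < 1e-12:
            break
    g = comps[0] + comps[1] + comps[2]
    vp = g.var() + S

    env_eff = rng.normal(0.0, np.sqrt(arch.var_env), size=n_envs)
    gxe = rng.normal(0.0, np.sqrt(arch.var_gxe), size=(n, n_envs))
    rep_eff = rng.normal(0.0, np.sqrt(arch.var_rep), size=(n_envs, n_reps))
    rows = []
    for l in range(n_envs):
        for j in range(n_reps):
            eps = rng.normal(0.0, np.sqrt(arch.var_resid), size=n)
            y = mu + g + env_eff[l] + gxe[:, l] + rep_eff[l, j] + eps
            for i, ind in enumerate(geno.ids):
                rows.append((ind, f"env{l + 1}", f"rep{j + 1}", arch.trait, y[i]))
    records = pd.DataFrame(rows, columns=["individual", "env", "rep", "trait", "value"])

    truth = {
        "g_total": g,
        "g_additive": comps[0],
        "g_dominance": comps[1],
        "g_epistatic": comps[2],
        "scales": {"a": scales[0], "d": scales[1], "aa": scales[2]},
        "phenotypic_variance": vp,
        "architecture": arch,
    }
    return records, truth


def inject_missing(geno: GenotypeMatrix, rate: float = 0.02, seed: int | None = None) -> GenotypeMatrix:
    """Set a random fraction of calls to missing."""
    rng = np.random.default_rng(seed)
    values = geno.values.copy()
    mask = rng.random(values.shape) < rate
    values[mask] = MISSING
    return dataclasses.replace(geno, values=values)


def inject_errors(geno: GenotypeMatrix, rate: float = 0.005, seed: int | None = None) -> GenotypeMatrix:
    """Replace a random fraction of non-missing calls with a different code."""
    rng = np.random.default_rng(seed)
    values = geno.values.copy()
    mask = (rng.random(values.shape) < rate) & (values != MISSING)
    shift = rng.integers(1, 3, size=int(mask.sum()))
    values[mask] = ((values[mask] + shift) % 3).astype(np.int8)
    return dataclasses.replace(geno, values=values)
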