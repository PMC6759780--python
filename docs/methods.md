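# Methods

This note records the models implemented, the defaults and why, what the
simulator does and does not emulate, and the numerical choices that matter.

## Simulated populations

Two fully homozygous founders differ at every marker; markers are laid out
uniformly on user-specified chromosomes with genetic position linear in
physical position. Meiosis is a Poisson crossover process on the genetic
map (count ~ Poisson(length in Morgans), uniform placement in cM, no
interference), so adjacent-locus recombination follows the Haldane map
function. RILs descend from the F1 by single-seed selfing (default 6
generations, i.e. F7 with residual heterozygosity ≈ 0.5⁶ ≈ 1.6%; the true
residual heterozygosity of real RIL panels is rarely published, so this is
a convention, configurable). F2 individuals are two independent F1 gametes.
The natural panel draws subpopulation allele frequencies from the
Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model around ancestral
frequencies and genotypes inbred lines as 0/2 draws at those frequencies
(configurable residual heterozygosity). Missing calls and genotyping
errors are injected post hoc (defaults 2% and 0.5%) to exercise QC and bin
calling.

Default dimensions emulate a maize-style study at desk scale: 212 RILs /
304 F2 / 435 panel lines, ten chromosomes of 180 cM and 200 Mb, and 5 000
SNPs (scaled down from array densities of 10–38 K; the spatial statistics
that matter — SNPs per cM and bins per chromosome — stay in a realistic
regime).

## Phenotypes

`y_ijl = μ + g_i + e_l + ge_il + r_jl + ε_ijl`, with genetic value
`g_i = Σ a w + Σ d h + Σ (aa) w w` (w the centered additive code, h the
heterozygosity indicator, epistasis additive×additive only — the same
component structure the prediction models decompose). Environment, G×E,
replicate-within-environment and residual effects are independent
Gaussians with user-set variances. Effect sizes start as N(0,1) draws and
the three genetic component vectors are rescaled by a fixed-point
iteration until each realized fraction var(component)/Var(y) equals its
target *on the simulated sample* (tolerance 1e-12, typically <10
iterations). This makes parameter-recovery tests sharp: the truth is exact
by construction, not in expectation. The simulator does not model
selection, drift, marker ascertainment, multi-allelic loci,
spatial field trends or G×E correlation structure, so passing tests speak
to the statistical machinery, not to those features of real trials.

## QC and BLUEs

Filters use strict inequalities: markers are removed when the missing
fraction exceeds 0.10, when MAF = min(p, 1−p) with p = (2n₂+n₁)/(2n_called)
is ≤ 0.05, and (biparental) when the segregation χ² against 1:1 (RIL,
classes {0,2}) or 1:2:1 (F2) has P ≤ 0.01; ties at a boundary are removed.
Markers where any expected class count falls below 1 are skipped with a
warning rather than tested.

BLUEs come from the mixed model with genotype and environment fixed
(sum-to-zero) and G×E and replicate-within-environment random. The
restricted likelihood is profiled over the residual variance and maximized
over the log variance ratios on Henderson's mixed-model equations (coarse
grid + Nelder-Mead; one Cholesky per evaluation). The G×E term is included
only when there are ≥2 environments *and* ≥2 replicates (otherwise it is
confounded with the residual); with one environment and one replicate the
fit falls back to fixed effects (means) with a warning. Broad-sense
heritability is reported on the entry-mean basis
H² = σ²_g/(σ²_g + σ²_ge/E + σ²_ε/(ER)) with σ²_g the variance of the BLUEs.

## Bin maps

Per individual and chromosome, a 15-SNP sliding window (step 1) is called
for a parent when ≥ 11 of its 15 SNPs are homozygous for that parent,
otherwise heterozygous; missing SNPs are excluded with the threshold scaled
as ceil(11·called/15), and windows with fewer than 8 called SNPs inherit
the nearest informative window's call. Window calls are projected to
per-SNP calls (SNP s takes the call of the window starting at s). Because
window counts pass through the 5–10 band at every homozygote-to-homozygote
crossover, an artificial heterozygous zone of up to one window always
appears there; runs of heterozygous calls shorter than the window that are
flanked by the two *different* homozygous calls are therefore split at
their midpoint (runs flanked by identical calls are genuine residual
heterozygosity and are kept). Breakpoints sit at the bp midpoint between
adjacent SNPs with different calls; chromosomes are cut at the union of
all individuals' breakpoints and every resulting segment is a bin.

Resolution limits worth knowing: a true parental segment shorter than ~5
SNPs cannot change any window call and is invisible; segments of 5–10 SNPs
surface as heterozygous-call islands rather than parent switches. Against
simulated truth (collapsed at the 5-SNP limit), inferred breakpoints match
true junctions ≈ 97% 1:1 within 15 SNPs on error-free fully inbred lines.

Adjacent-bin recombination: RILs use the observed mismatch fraction with
the Haldane–Waddington correction r = R/(2−2R) (heterozygous or missing
calls excluded); F2s maximize the exact two-locus multinomial likelihood
over r ∈ [1e-6, 0.49] (bounded scalar optimization — the same MLE an EM
scheme targets, without its iteration bookkeeping). Monomorphic bins give
an undefined r; the interval is skipped with a warning and contributes 0 cM.
Map positions are cumulative Kosambi distances d = 25·ln((1+2r)/(1−2r)).
Estimated map lengths run ~25% below the simulated truth because
sub-window double crossovers are undetectable and the F∞ correction is
conservative at F7 — a property shared by any window-based bin map.

## Mapping

GWAS fits y = μ + PCs·α + marker·β + u + ε with u ~ N(0, Kσ²ᵤ). The
variance ratio is estimated once under the null by profile REML on the
eigendecomposition of K (P3D/EMMAX); each marker then gets a Wald test on
the rotated data with residual degrees of freedom, which reduces *exactly*
to the OLS F test when K = I and no covariates are used. Missing genotypes
are mean-imputed for testing only; markers collinear with the covariates
get P = 1 and a flag. The declaration threshold is −log₁₀(P) > 4; PCA uses
7 components by default (configurable — the scree test that motivated 7 is
not re-implemented).

Linkage scans use Haley–Knott regression on expected QTL genotype scores
(additive = P(AA)−P(BB), dominance = P(het)) at pseudo-positions every
1 cM plus the bin positions. Conditional genotype probabilities treat each
chromatid as a two-state Markov chain between flanking bins
(recombination fractions from inverse-Kosambi distances; RILs use the
mosaic chain at R = 2r/(1+2r); unknown phase is summed over; contradictory
flanks fall back to the prior). Composite interval mapping picks up to 5
cofactor bins by forward stepwise regression and drops cofactors within
10 cM of the tested position; LOD = (n/2)·log₁₀(RSS₀/RSS₁). Genome-wide
thresholds are the type-7 empirical (1−α) quantile of the maximum LOD over
phenotype permutations (default 1 000; a vectorized multi-phenotype path
makes the no-cofactor case fast, and the null calibration uses that
interval-mapping form). QTL get 1.5-LOD support intervals extended to the
first position crossing below; at most one QTL is declared per chromosome
(the profile peak). Pleiotropic QTL are transitive overlaps of physical
intervals with ≥ 2 QTL from ≥ 2 traits; the reported interval is the union
span.

TRMs are the top-k markers by the scan statistic, ties broken by
(statistic, chromosome, position); random baselines are uniform draws
without replacement, redrawn per CV replicate and shared across its folds.

## Kernels and prediction models

Kernel formulas are as printed above (README); allele and genotype
frequencies are always recomputed from the genotype matrix supplied, so
kernels built inside cross-validation use all individuals' genotypes
(genotypes carry no phenotype information) while test phenotypes stay
masked. Missing genotypes are imputed to 2p in W and set to 0 in D, both
preserving column centering; θ = 0 loci are dropped from D but kept in G_a.

The multi-kernel GBLUP sampler works on eigen-representations
u_k = U_k√Λ_k α_k, which makes every α-block conditional posterior
diagonal (O(nq) sweeps). Priors are scaled-inverse-χ² with df 5 and scales
set so the prior modes split half the sample phenotypic variance equally
across the genetic terms, the other half going to the residual — the
common default of Bayesian whole-genome regression software. Defaults are
10 000 iterations, 5 000 burn-in, thinning 5 (the cross-validation engine
uses 1 500/500 per fold; accuracy differences against long chains were
below Monte-Carlo noise). Masked phenotypes are imputed each sweep, so
prediction is the joint-kernel conditional expectation. Seeded chains are
bit-reproducible. Two prior-driven properties to expect: under a
pure-noise trait the posterior genetic share settles near 0.2 (the df-5
prior floor), and adding an unneeded dominance kernel costs ~0.01–0.03 in
r_MG — consistent with dominance appearing essentially free only when it
is real.

The single-kernel REML path profiles the likelihood over heritability on
the kernel eigendecomposition and predicts masked individuals by the
conditional Gaussian mean (equivalently G_test,train G⁻¹_train û). Its
BLUPs agree with the sampler's posterior-mean GEBVs at Monte-Carlo
precision; the variance components themselves differ by the prior's O(1/n)
pull, which is why the equivalence check is made on predictions.

BayesC places a common-slab spike-and-slab on marker effects (inclusion
probability π ~ Beta with mean 0.5 and prior count 10; slab scale from the
same half-variance convention divided by π₀·Σvar(z)); it trains on the
observed rows and predicts with Z·E[u]. Fixed-effect (PC) designs enter
both families by a flat-prior GLS sweep; PCs for BC+PC / G+PC are computed
from the selected-marker submatrix (default 7, configurable).

## Cross-validation engine

k-fold (default 5) × replicates (the original design uses 100; tests and
the acceptance script use 5–20, which already separate the contrasts they
check). Within a fold the scan — GWAS for the panel, CIM LOD on bins for
biparental populations — sees only training individuals' phenotypes; bin
maps are genotype-only and computed once. r_MG is the raw Pearson
correlation between total GEBV and the BLUEs of the testing fold
(constant predictions are recorded as 0 with a warning). The scan cache
shares the per-fold scan across every marker-count and source cell of a
sweep.

One empirical regularity the engine reproduces: the TRM advantage over
random markers is large when markers are few relative to map length
(random markers tag the genome at ~1 marker per tens of cM) and vanishes
as the count approaches the full map, with the TRM curve plateauing by
~500 markers. On short dense maps random markers saturate quickly and the
contrast compresses — marker spacing relative to linkage-disequilibrium
decay, not the absolute count, is what matters. For strongly oligogenic
traits the plateau can sit *above* the all-marker level: a kernel built
from 500 targeted markers concentrates on the signal, while the
genome-wide kernel dilutes it across every non-QTL segment.

Trait architectures default to gamma-distributed effect magnitudes
(shape 0.4, random signs), giving a few QTL at 5–20% of phenotypic
variance and a tail of small ones — the spectrum QTL studies of
yield-related traits report. A flat (normal) effect law is available via
``effect_shape=None``; it caps per-QTL variance near fa/n_QTL and makes
marker selection nearly worthless beyond very small panels.

## Numerical conventions

Genotype codes int8 with −1 missing; 1-based closed physical intervals;
bins inherit the bp of their first and last SNP; type-7 quantiles;
r clipped to [0, 0.49]; kernels symmetrized to 1e-10 and declared PSD down
to −1e-6 relative eigenvalue; REML optimizations bracket on a coarse grid
before bounded refinement; all stochastic entry points take explicit
seeds and the CLI derives per-step seeds from a single --seed.
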