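# Methods

This note records the statistical models implemented in `perturbdecode`,
the choices made where the design was genuinely open, what the synthetic
data do and do not emulate, and the known limitations.

## Count model and differential expression

Pseudobulk profiles are sums of raw UMI counts over all cells sharing a
(perturbation-or-guide, condition, batch) key. Per gene, a negative
binomial GLM with log link is fit to these sums,

    y ~ intercept + batch [+ condition] + group,   offset = log(library size),

and the group coefficient is Wald-tested two-sided. The NB is parameterized
mean/size: Var = μ + αμ² with α = 1/size.

Dispersion is estimated in two passes. A Poisson fit provides
method-of-moments residual dispersions, inflated by n/(n−p) to offset the
bias from fitting p design parameters; a lowess trend of these over log
mean expression pools information across genes; each gene's working
dispersion is the 50/50 blend of its own estimate and the trend. On top of
the NB fit, a quasi-likelihood layer computes the per-gene Pearson
dispersion factor s², squeezes it toward 1 with 10 prior pseudo-df, and
refers the moderated Wald statistic to a t distribution on
(prior + residual) df. Without this borrowing a six-sample design has two
residual df and no test can clear FDR 0.01; with it, null p-values are
uniform (KS-tested in the suite) and the pooled null discovery fraction at
FDR < 0.05 stays below 0.075. The fits themselves go through statsmodels
GLM; the dispersion pipeline, moderation and contract are this package's.

Benjamini–Hochberg adjustment is implemented directly (sort, scale by
n/rank, running minimum) and cross-checked in the tests against both a
hand-written step-up oracle and statsmodels.

GA signatures take the genes at FDR < 0.01 with nonzero fold change in
either culture condition, up and down separately. A gene significant in
opposite directions in the two conditions is assigned the direction of the
smaller FDR and recorded as a conflict — the direction-conflict rule had to
be chosen here; it is logged whenever it fires. Thresholds on fold change
(e.g. |log2FC| > 0.25 for the coculture-response gene sets, marker
log2FC > 0.25) are strict inequalities throughout.

## sgRNA z-scores, concordance, crossvalidation

Z_k for sgRNA k averages (P_kji − C_ji) over the observed (batch j,
condition i) strata, on pseudobulk profiles formed as the mean
log2(1 + tp100k) over member cells. Strata with no cells for sgRNA k are
skipped with the divisor adjusted; a stratum lacking control cells is an
error, not a silent skip. Concordance is the Pearson correlation of z-score
rows, stratified into same-target, different-target and control–control
pairs and compared by one-sided rank-sum tests.

The per-cell signature score z-scores each signature gene across cells and
takes mean(up) − mean(down); genes absent or constant are skipped and
counted. The score enters a one-sided t-test (held-out vs control cells)
and an AUROC computed as U/(n₁n₂) with midrank ties, hence invariant to
monotone transforms of the score (property-tested). In leave-one-sgRNA-out
crossvalidation the signature is re-derived from the target's remaining
guides; when fewer than 10 genes pass the FDR cut (the null-effect regime,
where scoring would otherwise be undefined) the 10 smallest-p genes are
used, signed by their fold change. This floor leaves the null AUROC at
chance and does not alter the estimator when signal exists.

## Hit scoring and networks

The hit rules are applied exactly as stated in the module docstring
(S_sen ≥ 2 ∧ S_res = 0, mirrored), making the two classes mutually
exclusive by construction; the implementation is checked against exhaustive
rule evaluation on a thousand random regulation tables. Hit counting uses
the same FDR < 0.01 signature membership as the network edges (one
threshold, one gene counted once per perturbation regardless of how many
conditions support it).

Ligand–receptor convergence uses a hypergeometric upper tail restricted to
the genes appearing in the pair table: population = universe, successes =
binding partners of one hit set, draws = partners of the other, observed =
their overlap. Hubs are defined operationally as connected components of
the ligand–receptor overlay that touch nodes of at least two hit classes
(CRISPRa / Perturb-seq; dual hits count as both) — the source material
describes one hub narratively and this formalization reproduces that
structure on toy data. Incoming-degree layout ranks break ties
alphabetically. Co-regulation counts pairs moved in the same direction per
perturbation; modules come from average linkage on
1 − C_gh/√(C_gg·C_hh).

## In situ preprocessing

Transcripts are assigned by label-raster lookup at their coordinates
(micron coordinates, origin top-left, y down; label 0 = background);
conservation (assigned + background = total) is exact and tested. ORF
calling sums each ORF's 1–5 barcodes and requires the top ORF to reach
`min_count` with the runner-up below it; ties yield no call.

Normalization for panel data is log2(1 + transcripts-per-thousand). The
transcript-fraction scaling follows the usual per-cell total normalization;
the scale constant 1e3 (rather than a TPM-style 1e6) is chosen for
~100–1,000-gene panels with a few hundred transcripts per cell, where a 1e6
scale would let single-count genes swing ~12 log2 units and bury every
linear model in detection noise. Rank-based statistics are unaffected by
the constant; linear-model power improves substantially.

Clustering is PCA (20 PCs, all panel genes) → shared-nearest-neighbor graph
(k = 10, Jaccard weights, every kNN edge kept with a small weight floor so
no cell is isolated) → Louvain communities (igraph's multilevel algorithm —
the original Louvain — at resolution 0.4; Leiden available behind a flag).
Stable cells are those whose subsample cluster (matched to the full-data
anchor clustering by maximal overlap) agrees with their anchor cluster in at
least 70% of 10 random 80% subsamples; these three parameters are this
package's defaults, chosen as round values that make the stable set
insensitive to ±1 subsample on well-separated data. Projection is a kNN
classifier in the reference PC space with vote-fraction confidence and the
strict > 0.8 retention rule; a query within numerical tolerance of a
reference cell inherits its label at confidence 1. This kNN transfer is a
declared substitution for anchor-based transfer toolkits; the contract
mirrored is the confidence-thresholded projection, not any particular
toolkit's score formula.

## Spatial statistics

**Zonation.** The statistic for ORF o is the mean, over cancer cells
carrying o, of the fraction of same-ORF cells among their k = 10 nearest
cancer neighbors within the slide. The neighbor graph is fixed; ORF labels
are permuted across the slide's cancer cells, which is exactly
exchangeable under the no-zonation null, and p = (1 + #{null ≥ obs})/(1 +
n_perm), bounded below by 1/(n_perm+1). The specific statistic is this
package's formalization of an "empirical permutation test" — simple and
powerful against clustered alternatives.

**Spatially aware GA.** Per gene, a linear mixed model with FOV random
intercept (REML, statsmodels MixedLM) on normalized expression with ORF and
complexity fixed effects. Inference is a Wald t with between-within style
degrees of freedom (n − p − #FOVs): with the FOV counts used here this is
indistinguishable from Satterthwaite in calibration, which is the property
the suite verifies (the gene–environment null type-I rate at p < 0.01 is
≈ 0.008 over 800 tests). A single-FOV input falls back to OLS with a loud
warning. The nonspatial baseline is a two-part hurdle model (logistic
detection + linear positive part, combined χ² on 2 df; single-part with a
flag when a gene is all-zero or all-detected).

**Micro-FOVs.** Tile mode partitions each slide into squares (default
100 µm; 250 µm used in the tests so that minority cell types reach the
per-tile minimum); neighborhood mode windows each readout cell's k nearest
cancer cells — the geometry of the original micro-FOVs is unspecified, so
both are provided. Perturbation abundance is the fraction of ORF-called
cancer cells per unit; tallies conserve cells exactly.

**pMCPs.** Partial Spearman: rank-transform, regress both rank vectors on
the other ORFs' abundances, correlate residuals; p from the t
approximation on n − 2 − #covariates df; BH within each (cell type, ORF)
family at FDR 0.1. The implementation equals the brute-force
rank→OLS→Pearson chain to 1e−10 (tested) and suppresses correlated-clone
confounding that fools marginal correlation in every simulated instance.

**Gene–environment interactions.** The mixed model
y ~ (1|FOV) + complexity + x + Σ L_i + Σ L_i·x, with L_i the indicator that
ligand i's mean expression in the cell's micro-FOV exceeds the median
across micro-FOVs. Constant indicators are dropped with a warning;
interactions are reported only where both factor levels co-occur with both
x levels. On data generated from the model itself the interaction estimate
is unbiased to ~1% with 95% CI coverage ≥ 0.9.

## Synthetic data

The generator reproduces the statistical structure the analyses assume, at
desk scale. Dissociated screens: NB counts (size r = 2) with log-normal
baseline means giving ≈ 2,000 UMIs per cell over a 400-gene panel (typical
droplet depth at panel resolution), multiplicative per-batch gene factors
(σ_log = 0.15), log-normal cell size factors (σ = 0.3), two culture
conditions with a shared ±1 log2FC response program in coculture cells,
8 targets × 3 sgRNAs + 6 NTC guides at 36 cells per guide across 3 batches
(the real screen's 61 × ~4 + 32 design shape, scaled down), planted
±1 log2FC effects on 30 genes per target plus a 2× on-target elevation,
NB guide capture (high mean for the true guide, low background) and a 5%
multiplet rate. Spatial screens: 4 tumors × 4 FOVs × 250 cells (500 µm
FOVs; 6 × 300 for the correlation-hungry pMCP analyses), three cell types,
clones assigned by Gaussian-weighted nearest clone seeds (bandwidth 80 µm,
with a uniform floor so infinite bandwidth degrades to spatial randomness),
control clones carrying a barcode but no effect, pMCP shifts (+1 log2FC) in
non-cancer cells whose 10 nearest cancer cells are ≥ 30% ORF-x, and a
receptor-ORF interaction (+1 log2FC) gated by an independent per-ligand
Gaussian-bump field. Effect sizes and rates without an external referent
were fixed once at these values as representative of strong CRISPRa
perturbations.

What the generator does **not** emulate: ambient RNA and doublet
transcriptomes (multiplets carry two clean guide programs), segmentation
errors and transcript misassignment, cell-type-dependent capture
efficiency, FOV-level technical effects in the spatial counts, T cell
killing dynamics, and any real gene identity. Passing tests therefore
demonstrate correctness and calibration of the estimators under the
declared generative assumptions — not robustness to the full messiness of
real screens. The clone bandwidth is a free parameter of the simulation,
not an estimate of real tumors.

## Problem sizes and numerical choices

Test and acceptance runs use the scales above (~1,000–7,000 cells,
120–400 genes, 199–999 permutations, 10–200 replicates per calibration
check), chosen so the full suite completes in minutes while every
calibration quantity has enough replicates to be meaningful. Degenerate
inputs are handled explicitly rather than silently: collinear DE designs
fail naming the aliased terms, zero-variance genes are excluded and
reported, empty signatures fall back as described, single-FOV and
single-cluster inputs warn, and permutation p-values respect their
attainable floor. All randomized steps take explicit seeds; no global RNG
state is used.

## Known limitations

The DE engine targets calibration, not p-value equality with any published
count-DE package; its quasi-likelihood moderation uses a fixed prior df
rather than estimating it from the data. Mixed-model df are approximate
(see above). The hurdle baseline's detection part uses an unpenalized
logistic fit capped at 50 iterations; complete separation yields a large
but finite deviance improvement rather than a Firth-corrected estimate.
Neighborhood-mode micro-FOVs overlap by construction, so their pMCP
p-values are correlated across nearby readout cells; BH is applied as if
independent, as in the tile mode.
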