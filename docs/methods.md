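# Methods

## Divergence coding

Expression (TPM or counts) is reduced per sample to normalized average
ranks in (0, 1]; ties share the mean rank. A reference population — half of
the normal samples, split deterministically from the run seed, with the
reference taking the extra sample on odd counts — defines, per gene, the
central γ empirical quantile interval of its reference ranks. Codes are +1
above the interval, −1 below, 0 inside; boundary values are inside (the
interval is closed). Defaults: γ = 0.9. The general divergence framework
also has a multivariate (gene-set) mode; only the univariate form is
implemented here, with the baseline support estimator abstracted to the
quantile interval. Because only within-sample ranks matter, the coding is
invariant to monotone per-sample transforms, so TPM vs. raw counts is
immaterial as long as the scale is monotone within a sample.

With finite reference samples the empirical quantile interval undershoots
the nominal γ coverage somewhat, so held-out normals code nonzero at a
rate a bit above 1 − γ (≈ 0.15–0.2 at 20 reference samples and γ = 0.9).
This is a property of empirical quantiles, not a defect; tests assert a
band rather than the nominal rate.

## GPR logic and reaction states

GPR rules are parsed with "and" binding tighter than "or", both
case-insensitive. Ternary gene states map to reaction states by min over
AND children and max over OR children — the standard iMAT convention; on
{0, +1} this reduces to boolean evaluation, and raising a gene state never
lowers a reaction state (both properties are tested exhaustively on small
rules). Reactions without a GPR get state 0. Genes missing from the
coding default to 0.

## FBA, FVA, deletion

FBA maximizes the model objective subject to `S v = 0` and bounds; FVA
minimizes/maximizes each reaction's flux with the objective held at a
fraction (default 0.9) of its optimum, each bound an independent LP.
Single-gene deletion closes every reaction whose GPR turns false without
the gene and re-solves; `grRatio = Z_KO / Z_WT`, clipped to [0, 1] for
reporting, with infeasible knockouts scored 0 and genes touching no GPR
kept at 1 without a solve. Genes absent from the model warn rather than
error because expression and model gene lists rarely coincide. All solves
use HiGHS (scipy); its default feasibility/optimality tolerances (~1e-9
tier) are relied on, and equality/bound residuals are asserted at 1e-7 in
tests. Solver correctness is cross-checked against a basic-feasible-
solution enumeration oracle on ≤ 8-reaction networks and against cobrapy
on an SBML export.

## iMAT context extraction

The MILP rewards, per +1-state reaction, carrying flux `|v| ≥ ε`
(default ε = 1 flux unit) and, per −1-state reaction, `|v| ≤ tol`
(default 1e-6), using big-M indicator constraints derived from the model
bounds. Rewards are soft: a −1 reaction is never forced off, so biomass
feasibility is never sacrificed. Core reactions (biomass synthesis and
the ATP-synthase-like reaction) are hard-forced active. In addition the
biomass flux is constrained to ≥ 90% (configurable) of the full model's
optimum. That retention constraint is this package's design choice for an
otherwise open detail: it guarantees every context network supports
near-optimal growth, which the downstream FVA-at-90% classification
implicitly assumes, and it removes solver-degeneracy artifacts in which a
network would otherwise retain only a low-capacity route. Reactions with
`|v| > tol` in the MILP solution, plus core reactions, are retained; the
rest are removed (the context model shrinks, but per-sample state vectors
are reported over the full reaction index for cross-sample comparability).
The MILP optimum is verified against exhaustive activity-pattern
enumeration on ≤ 12-reaction fixtures. A per-sample time limit (default
60 s) falls back to the best incumbent, flagged in the solution status.

## Activity statistics

Active/inactive calls per context network come from FVA at the configured
fraction: active iff `max(|min|, |max|) > tol`; removed reactions are
inactive. Cancer-vs-normal and cluster-vs-normal contrasts use two-sided
Fisher exact tests per reaction (probability-ordering rule: the p-value
sums hypergeometric probabilities of all same-margin tables no more
probable than observed — stated explicitly because two-sided conventions
differ), with BH-FDR across reactions. Subsystem enrichment is a Fisher
2×2 of (significant at p < 0.05) × (in subsystem), BH-corrected across
subsystems; the p < 0.05 reaction-level inclusion cut mirrors the
headline convention of the analyses this package reproduces. Knockout
contrasts use a Wilcoxon rank-sum on per-sample grRatio vectors per gene
(exact when n + m ≤ 10 and untied), the per-gene summary being the raw
grRatio values. Cluster–phenotype association uses Pearson chi-squared
with zero-margin rows/columns dropped.

## Clustering and survival

Samples are clustered on FVA max-flux profiles over the full reaction
index (absent reactions contribute 0). K-means runs on per-reaction
z-scored profiles with k-means++ and 25 restarts, seeded; labels are
identifiable only up to permutation, so tests score adjusted Rand index.
The 1 − Pearson distance matrix is provided for diagnostics, and a
`pearson-mds` mode (classical MDS embedding of that distance, then
K-means) reconciles the distance-matrix view with K-means' Euclidean
geometry; Euclidean-on-z-scores is the default. The wss elbow is reported
as the full curve plus a max-second-difference knee; the final k remains
a user decision. Normal samples are fixed as cluster 0 and excluded from
fitting. Survival contrasts are Kaplan–Meier product-limit curves per
cluster or merged cluster group; no log-rank/Cox modeling is included.

## Drug association

A sample's essential gene set (grRatio < 0.9 in its own context network
by default; a cohort-level significant set behind `gene_set=global`)
becomes a binary any-hit vector over screen cell lines, Spearman-
correlated with each drug's IC50s over pairwise-complete lines (the
screen's missing IC50s are deleted pairwise). Spearman rho is the Pearson
correlation of tie-averaged ranks; for n ≤ 8 the p-value is computed by
exact enumeration of pairings (valid under ties, e.g. binary x),
otherwise by the t approximation — at screen sizes (~100 lines) the
t-approximation's 10⁻³ tail is calibrated within binomial error, which
the tests check under a permutation null. Drugs are ranked by the count
of samples with p below an uncorrected α = 10⁻³; ties break by median
|rho| then drug id (reporting convenience only). Negative rho means
mutated lines are more sensitive.

## Methylation

CpG beta values reuse the expression machinery verbatim (rank transform,
baseline from normal methylation, ternary coding), which carries over all
coding invariants. The joint divergence proportion per CpG is the
fraction of shared tumor samples with nonzero codes in both the CpG and
its mapped gene; either direction counts by default, with a
sign-concordant mode behind a flag. CpGs are ordered by genomic position
and carry promoter flags. No numeric threshold is attached to a CpG
"showing" divergence.

## Synthetic data

The generators define the package's reference study conditions; every one
is a pure function of `SimConfig` (bitwise reproducible from the seed).

*Network.* 8 marker subsystems, each an independent substrate exchange
plus two parallel substrate → precursor paths with distinct GPRs (an
isozyme pair `a or b` and a complex `c and d`, capacity 10 each); a trunk
precursor → Q reaction gated by the AND pair `gT1, gT2`; a core biomass
sink on Q capped at 10; and a core ATP-synthase-like branch. Full-media
FBA optimum is 10, reachable through any single subsystem, so requiring
90% biomass retention never forces a particular marker subsystem on. The
trunk AND genes are the planted essential genes: every unit of biomass
crosses the trunk, so their knockout zeroes growth in every context
network — this is what makes 100% essential-gene recovery a property of
the construction rather than a tuned outcome.

*Expression.* Log-normal baseline: per-gene log-means spread N(3, 1),
per-sample log-noise SD 0.3, columns scaled to TPM. 500 background
(non-metabolic) genes are included so ranks are taken over a
transcriptome-like universe — with only the ~34 model genes, rank space
is too coarse for baseline intervals to be meaningful. Planted marker
genes sit mid-range (jitter SD 0.2 around the center) so both divergence
directions have rank headroom. Tumor cluster c (of 4, 40 samples each,
plus 40 normals) shifts its up-subsystem genes by +5 noise-SDs and its
down-subsystem genes by −5; the per-cluster gene sets are disjoint.

*Drug screen.* 100 cell lines × 20 drugs × 60 genes; Bernoulli mutations
at rate 0.15 (planted genes 0.30), unit-Gaussian IC50 noise, and a 3-SD
IC50 reduction in mutated lines for each planted (gene, drug) pair.

*Methylation.* 1–5 CpGs per gene; beta = logistic of (coupling ×
standardized log-expression + N(0, 0.5)), default coupling −0.7; the
lowest-position CpG per gene is the promoter CpG.

*Survival.* Exponential event times, hazard 5×10⁻⁴/day for clusters 1 and
4 (and normals) and 1.5×10⁻³ for clusters 2 and 3 (hazard ratio 3), with
independent exponential censoring at 3×10⁻⁴/day.

What the generators do **not** emulate: negative-binomial count noise and
library-size effects, genome-scale network size and compartment structure,
realistic 450k probe geography, drug dose–response shapes, or correlated
mutation patterns. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure at these effect sizes,
not performance on real TCGA/GDSC-scale data.

## Problem sizes and runtime choices

The reference cohort (180 samples × 29 reactions × ~534 genes, 100 cell
lines × 20 drugs) keeps a full pipeline run to tens of seconds on one
CPU: the per-sample cost is one MILP (~30 binaries), ~60 FVA LPs, and ~34
knockout LPs, all tiny. These sizes were chosen so the planted-structure
checks (ARI, essentiality, drug power) are comfortably powered while the
whole suite stays interactive.

## Known limitations

- iMAT alternate optima are not enumerated; the reported context network
  is the solver's (deterministic) optimum, and state-0 reactions may be
  retained or dropped arbitrarily within that optimum.
- Removed-reaction fluxes are compared to `tol` from a single MILP
  solution; a solution grazing the tolerance could flip a retention call.
- The Fisher-based differential-reaction test treats samples as
  independent; hierarchical or paired designs are out of scope.
- The drug score inherits GDSC-style screen assumptions (binary mutation
  calls, one IC50 per line/drug); no dose–response modeling.
- SBML support covers L3+FBC bounds, GPRs, and objectives; subsystems and
  core flags ride in notes annotations, which other tools will ignore.
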