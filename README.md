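# metapersona

Personalized, context-specific metabolic network analysis for cohorts of
tumor and normal samples.

Bulk transcriptomes are noisy and heterogeneous across people, which makes
it hard to read a single patient's metabolic state off expression values
alone. `metapersona` implements a pipeline that (1) simplifies each
sample's expression profile into a personal ternary *divergence* code
against a normal baseline, (2) integrates those codes with a genome-scale
metabolic model to extract a per-sample context-specific network, and
(3) mines the resulting networks for metabolic subtypes, essential genes,
and drugs associated with those genes in a cell-line screen. It is aimed
at computational biologists working with constraint-based models of cancer
metabolism.

## Method

**Divergence coding.** Each sample profile is replaced by within-sample
normalized ranks. For every gene, a baseline interval
`[q_{(1-γ)/2}, q_{1-(1-γ)/2}]` is estimated from the rank values of a
reference half of the normal samples (default γ = 0.9). A gene is coded
+1 / −1 / 0 in a sample if its rank lies above / below / inside the
interval. The coding is a single-sample property and is invariant to any
monotone per-sample transform of the data.

**Network integration (iMAT).** Gene codes map to reaction states through
GPR rules (AND = min, OR = max). The iMAT mixed-integer program then picks
a steady-state flux vector `v` (`S·v = 0`, bounds, media) maximizing the
number of +1 reactions with `|v| ≥ ε` plus −1 reactions with `|v| ≤ tol`.
Core reactions (biomass, ATP synthase) are hard-constrained active and the
biomass flux is held at ≥ 90% of the full model's optimum, so every
extracted network supports growth. Reactions carrying flux (plus core)
form the sample's context network.

**Downstream.** Per network: flux variability analysis (FVA) at 90% of
biomass gives max-flux profiles and active/inactive calls; K-means on the
z-scored profiles (elbow/wss for k) recovers metabolic subtypes; Fisher
tests with BH-FDR find differential reactions and enriched subsystems;
single-gene deletion flags genes with growth-rate ratio
`grRatio = Z_KO/Z_WT < 0.9`; each sample's essential gene set is scored
against a mutation × IC50 drug screen by Spearman correlation of the
"any essential gene mutated" indicator with each drug's IC50s (negative
rho = mutated lines more sensitive), ranking drugs by the number of
samples with p < 10⁻³. Optional stages code CpG methylation the same way
and summarize joint expression–methylation divergence, and contrast
cluster survival with Kaplan–Meier curves.

All LP/MILP solves use HiGHS via `scipy.optimize`; statistics go through
scipy/statsmodels/lifelines/scikit-learn.

## Worked example

Everything runs on synthetic data with planted ground truth (see
`docs/methods.md` for what is planted):

```bash
metapersona run --seed 0 --out out/
```

completes ten stages (inputs → divergence → reaction states → context
networks → clustering → activity stats → essentiality → drug scoring →
methylation → survival) in well under a minute and writes TSVs plus a
`manifest.json`. From the library:

```python
import metapersona as mp

model = mp.make_toy1_parallel()          # A -> B by two paths, uptake 10
print(mp.solve_fba(model).objective_value)
# 10.0
print(mp.fva(model, fraction=0.9).ranges)
#          min_flux  max_flux
# EX_A        -10.0      -9.0
# R1            7.0      10.0
# R2            0.0       2.0
# BIOMASS       9.0      10.0
deletion = mp.single_gene_deletion_all(mp.make_toy1_and())
print(deletion.table["gr_ratio"].to_dict())
# {'g1': 0.2, 'g2': 0.2, 'g3': 1.0, 'g4': 1.0}
print(mp.essential_genes(deletion))
# {'g1', 'g2'}
```

`R1 ∈ [7, 10]` because biomass ≥ 9 with uptake ≤ 10 and the alternate path
capped at 2; knocking out either subunit of the `g1 and g2` complex
reroutes all flux through that capacity-2 path, hence `grRatio = 0.2`.

On the default synthetic cohort (4 planted tumor clusters × 40 samples +
40 normals), the pipeline recovers the planted clusters from FVA max-flux
profiles with adjusted Rand index 1.0, places the wss elbow at k = 4,
finds the planted trunk genes essential in 100% of context networks, and
ranks the planted sensitive drug first with median Spearman rho ≈ −0.58.

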