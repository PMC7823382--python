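"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input has a generator here: a toy stoichiometric network
with GPR rules and subsystems, baseline-vs-shifted expression with planted
sample clusters, a mutation x IC50 drug screen with planted sensitivity
associations, methylation coupled to expression, and cluster-dependent
survival times.  Each generator is a pure function of a :class:`SimConfig`
(bitwise reproducible given the seed), and returns the planted truth
alongside the data so downstream stages can be scored for recovery.

The simulation network routes ``n_marker_subsystems`` independent carbon
sources into a common biomass precursor; each marker subsystem holds two
parallel paths with distinct GPR rules (an isozyme OR pair and a complex
AND pair), so expression differences translate into genuinely different
context networks.  Planted tumor clusters up-regulate one marker subsystem
and down-regulate another, with disjoint gene sets across clusters.  A
trunk reaction carrying all biomass precursor flux is gated by an AND pair
of genes — the planted essential genes: knocking either out abolishes
growth in every context network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import model_from_dict
from .model import MetabolicModel

__all__ = [
    "SimConfig",
    "make_toy1",
    "make_toy1_parallel",
    "make_toy1_and",
    "make_toy_model",
    "default_media",
    "simulate_expression",
    "simulate_drug_screen",
    "simulate_methylation",
    "simulate_survival",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults define the package's reference simulation: 4 planted tumor
    clusters of 40 samples plus 40 normals on a ~29-reaction network with
    8 marker subsystems, 5-SD expression effects, a 100-cell-line by
    20-drug screen with one planted sensitivity association at 3 SD and 30%
    mutation frequency, methylation anticorrelated with expression at -0.7,
    and exponential survival with hazard ratio 3 between merged cluster
    groups.
    """

    seed: int = 0
    # network
    n_marker_subsystems: int = 8
    path_capacity: float = 10.0
    uptake_bound: float = 10.0
    biomass_capacity: float = 10.0
    # cohort
    n_clusters: int = 4
    n_normal: int = 40
    n_tumor_per_cluster: int = 40
    n_background_genes: int = 500
    effect_sd: float = 5.0
    noise_sd: float = 0.3
    baseline_log_mean: float = 3.0
    baseline_log_spread: float = 1.0
    # drug screen
    n_cell_lines: int = 100
    n_drugs: int = 20
    n_screen_genes: int = 60
    mutation_rate: float = 0.15
    planted_mutation_rate: float = 0.3
    drug_effect_sd: float = 3.0
    planted_drug_pairs: tuple[tuple[str, str], ...] = (("gT1", "drug_01"),)
    # methylation
    meth_coupling: float = -0.7
    meth_noise_sd: float = 0.5
    max_cpgs_per_gene: int = 5
    # survival (per-day hazards; clusters 1 & 4 low-risk, 2 & 3 high-risk)
    hazard_low: float = 0.0005
    hazard_high: float = 0.0015
    censor_rate: float = 0.0003

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# hand-sized toy fixtures
# ---------------------------------------------------------------------------

def make_toy1() -> MetabolicModel:
    """Chain A -> B -> biomass with uptake capacity 10 (FBA optimum 10)."""
    return model_from_dict({
        "metabolites": [{"id": "A"}, {"id": "B"}],
        "genes": [],
        "reactions": [
            {"id": "EX_A", "mets": {"A": -1}, "lb": -10, "ub": 1000,
             "subsystem": "exchange", "objective": 0},
            {"id": "R1", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
             "subsystem": "chain", "objective": 0},
            {"id": "BIOMASS", "mets": {"B": -1}, "lb": 0, "ub": 1000,
             "subsystem": "biomass", "objective": 1, "core": True},
        ],
    })


def make_toy1_parallel() -> MetabolicModel:
    """TOY1 with two parallel A -> B paths (R1 capacity 1000, R2 capacity 2)."""
    return model_from_dict({
        "metabolites": [{"id": "A"}, {"id": "B"}],
        "genes": [],
        "reactions": [
            {"id": "EX_A", "mets": {"A": -1}, "lb": -10, "ub": 1000,
             "subsystem": "exchange", "objective": 0},
            {"id": "R1", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
             "subsystem": "chain", "objective": 0},
            {"id": "R2", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 2,
             "subsystem": "chain", "objective": 0},
            {"id": "BIOMASS", "mets": {"B": -1}, "lb": 0, "ub": 1000,
             "subsystem": "biomass", "objective": 1, "core": True},
        ],
    })


def make_toy1_and() -> MetabolicModel:
    """Parallel fixture with GPRs: R1 needs the complex g1 AND g2, R2 has
    isozymes g3 OR g4.  Deleting g1 leaves only R2 (capacity 2), so
    grRatio(g1) = 0.2."""
    m = model_from_dict({
        "metabolites": [{"id": "A"}, {"id": "B"}],
        "genes": ["g1", "g2", "g3", "g4"],
        "reactions": [
            {"id": "EX_A", "mets": {"A": -1}, "lb": -10, "ub": 1000,
             "subsystem": "exchange", "objective": 0},
            {"id": "R1", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
             "gpr": "g1 and g2", "subsystem": "chain", "objective": 0},
            {"id": "R2", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 2,
             "gpr": "g3 or g4", "subsystem": "chain", "objective": 0},
            {"id": "BIOMASS", "mets": {"B": -1}, "lb": 0, "ub": 1000,
             "subsystem": "biomass", "objective": 1, "core": True},
        ],
    })
    return m


# ---------------------------------------------------------------------------
# simulation network
# ---------------------------------------------------------------------------

def _subsystem_name(s: int) -> str:
    return f"marker_subsystem_{s:02d}"


def subsystem_genes(s: int) -> list[str]:
    return [f"g{s:02d}{x}" for x in "abcd"]


def make_toy_model(config: SimConfig | None = None) -> MetabolicModel:
    """Simulation network: per marker subsystem, an exchange plus two
    parallel substrate -> precursor paths (OR isozymes / AND complex); a
    trunk precursor -> Q reaction gated by the planted essential AND pair
    gT1, gT2; a core biomass sink on Q; and a core ATP-synthase-like branch.

    Full-media FBA optimum equals ``biomass_capacity`` (default 10)."""
    config = config or SimConfig()
    mets = [{"id": "P"}, {"id": "Q"}, {"id": "O"}, {"id": "W"}]
    reactions = []
    genes: list[str] = []
    for s in range(config.n_marker_subsystems):
        sub = _subsystem_name(s)
        ga, gb, gc, gd = subsystem_genes(s)
        genes += [ga, gb, gc, gd]
        mets.append({"id": f"S{s:02d}"})
        reactions.append({
            "id": f"EX_S{s:02d}", "mets": {f"S{s:02d}": -1},
            "lb": -config.uptake_bound, "ub": 1000,
            "subsystem": "exchange", "objective": 0})
        reactions.append({
            "id": f"P{s:02d}_OR", "mets": {f"S{s:02d}": -1, "P": 1},
            "lb": 0, "ub": config.path_capacity,
            "gpr": f"{ga} or {gb}", "subsystem": sub, "objective": 0})
        reactions.append({
            "id": f"P{s:02d}_AND", "mets": {f"S{s:02d}": -1, "P": 1},
            "lb": 0, "ub": config.path_capacity,
            "gpr": f"{gc} and {gd}", "subsystem": sub, "objective": 0})
    genes += ["gT1", "gT2"]
    reactions.append({
        "id": "TRUNK", "mets": {"P": -1, "Q": 1}, "lb": 0, "ub": 1000,
        "gpr": "gT1 and gT2", "subsystem": "trunk", "objective": 0})
    reactions.append({
        "id": "BIOMASS", "mets": {"Q": -1}, "lb": 0,
        "ub": config.biomass_capacity,
        "subsystem": "biomass", "objective": 1, "core": True})
    reactions.append({
        "id": "EX_O", "mets": {"O": -1}, "lb": -config.uptake_bound, "ub": 1000,
        "subsystem": "exchange", "objective": 0})
    reactions.append({
        "id": "ATPS", "mets": {"O": -1, "W": 1}, "lb": 0,
        "ub": config.path_capacity,
        "subsystem": "oxidative_phosphorylation", "objective": 0, "core": True})
    reactions.append({
        "id": "EX_W", "mets": {"W": -1}, "lb": 0, "ub": 1000,
        "subsystem": "exchange", "objective": 0})
    return model_from_dict({"metabolites": mets, "genes": genes,
                            "reactions": reactions})


def default_media(model: MetabolicModel,
                  uptake: float = 10.0) -> dict[str, tuple[float, float]]:
    """Full media: every exchange open to uptake at ``uptake`` units."""
    exch = model.exchange_flags & (model.objective_coeffs == 0)
    return {model.reaction_ids[j]: (-uptake, 1000.0)
            for j in np.flatnonzero(exch)}


def planted_cluster_gene_sets(config: SimConfig) -> dict[int, dict[str, list[str]]]:
    """Cluster c (1-based) up-regulates marker subsystem 2(c-1) and
    down-regulates subsystem 2(c-1)+1; gene sets are disjoint across
    clusters."""
    if config.n_marker_subsystems < 2 * config.n_clusters:
        raise ValueError("need two marker subsystems per planted cluster")
    out = {}
    for c in range(1, config.n_clusters + 1):
        out[c] = {
            "up": subsystem_genes(2 * (c - 1)),
            "down": subsystem_genes(2 * (c - 1) + 1),
        }
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(model: MetabolicModel, config: SimConfig | None = None,
                        ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """TPM-scale expression with planted clusters.

    Normals draw from a log-normal baseline (per-gene log-mean spread
    ``baseline_log_spread``, per-sample log-noise ``noise_sd``); tumors in
    cluster c shift their cluster's up/down gene sets by +/-
    ``effect_sd * noise_sd`` in log space.  Marker genes sit near the
    middle of the baseline expression range so both directions of
    divergence have rank headroom.  ``n_background_genes`` non-metabolic
    genes are included so within-sample ranks are taken over a
    transcriptome-like gene universe, as in real data, rather than over
    the model genes alone.  Returns (matrix, labels, truth) where labels
    are "normal" / cluster ints and truth records the planted sets.
    """
    config = config or SimConfig()
    rng = config.rng(1)
    genes = list(model.gene_ids) + [
        f"bg{i:04d}" for i in range(config.n_background_genes)]
    cluster_sets = planted_cluster_gene_sets(config)
    marker = {g for cs in cluster_sets.values() for grp in cs.values() for g in grp}

    mu = pd.Series(config.baseline_log_mean
                   + config.baseline_log_spread * rng.standard_normal(len(genes)),
                   index=genes)
    # keep planted markers mid-range: small jitter around the center
    for g in genes:
        if g in marker:
            mu[g] = config.baseline_log_mean + 0.2 * rng.standard_normal()

    samples = [f"N{i:03d}" for i in range(config.n_normal)]
    labels = ["normal"] * config.n_normal
    for c in range(1, config.n_clusters + 1):
        for i in range(config.n_tumor_per_cluster):
            samples.append(f"T{c}{i:03d}")
            labels.append(c)

    shift = config.effect_sd * config.noise_sd
    log_expr = np.empty((len(genes), len(samples)))
    for s, (sid, lab) in enumerate(zip(samples, labels)):
        col = mu.to_numpy() + config.noise_sd * rng.standard_normal(len(genes))
        if lab != "normal":
            up = cluster_sets[lab]["up"]
            down = cluster_sets[lab]["down"]
            gi = {g: i for i, g in enumerate(genes)}
            for g in up:
                col[gi[g]] += shift
            for g in down:
                col[gi[g]] -= shift
        log_expr[:, s] = col
    expr = np.exp(log_expr)
    expr = expr / expr.sum(axis=0, keepdims=True) * 1e6  # TPM scale
    matrix = pd.DataFrame(expr, index=genes, columns=samples)
    truth = {"cluster_gene_sets": cluster_sets,
             "essential_genes": ["gT1", "gT2"]}
    return matrix, pd.Series(labels, index=samples, name="label"), truth


# ---------------------------------------------------------------------------
# drug screen
# ---------------------------------------------------------------------------

def simulate_drug_screen(config: SimConfig | None = None,
                         ) -> tuple["pd.DataFrame", pd.DataFrame, dict]:
    """Mutation and IC50 matrices with planted sensitivity associations.

    Mutations are Bernoulli(``mutation_rate``) per (line, gene), with the
    planted genes raised to ``planted_mutation_rate``.  IC50s are unit
    Gaussian noise; for each planted (gene, drug) pair, mutated lines lose
    ``drug_effect_sd`` from that drug's IC50 (mutated lines are more
    sensitive, so the association's Spearman rho is negative).
    Returns (mutation, ic50, truth)."""
    config = config or SimConfig()
    rng = config.rng(2)
    lines = [f"CL{i:03d}" for i in range(config.n_cell_lines)]
    model_genes = ["gT1", "gT2"]
    decoys = [f"xg{i:03d}" for i in range(config.n_screen_genes - len(model_genes))]
    genes = model_genes + decoys
    planted_genes = {g for g, _ in config.planted_drug_pairs}
    rates = np.array([config.planted_mutation_rate if g in planted_genes
                      else config.mutation_rate for g in genes])
    mutation = (rng.random((len(lines), len(genes))) < rates).astype(np.int8)
    mutation = pd.DataFrame(mutation, index=lines, columns=genes)
    drugs = [f"drug_{i:02d}" for i in range(config.n_drugs)]
    ic50 = pd.DataFrame(rng.standard_normal((len(lines), len(drugs))),
                        index=lines, columns=drugs)
    for gene, drug in config.planted_drug_pairs:
        ic50[drug] -= config.drug_effect_sd * mutation[gene].to_numpy()
    truth = {"planted_pairs": list(config.planted_drug_pairs)}
    return mutation, ic50, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(expression: pd.DataFrame, config: SimConfig | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-value matrix plus CpG map coupled to expression.

    Per gene, 1..``max_cpgs_per_gene`` CpGs; each CpG's beta is the
    logistic of (coupling * standardized log-expression + noise), so a
    negative coupling gives the canonical promoter-methylation
    anticorrelation.  The lowest-position CpG of each gene is flagged as
    the promoter CpG.  Returns (beta matrix, CpG map)."""
    config = config or SimConfig()
    rng = config.rng(3)
    log_expr = np.log(expression.to_numpy(dtype=float) + 1e-9)
    z = (log_expr - log_expr.mean(axis=1, keepdims=True)) / \
        (log_expr.std(axis=1, keepdims=True) + 1e-12)
    rows = []
    betas = []
    pos_cursor = 0
    for gi, gene in enumerate(expression.index):
        n_cpg = int(rng.integers(1, config.max_cpgs_per_gene + 1))
        offsets = np.sort(rng.integers(0, 5000, size=n_cpg))
        for k in range(n_cpg):
            noise = config.meth_noise_sd * rng.standard_normal(expression.shape[1])
            logit = config.meth_coupling * z[gi] + noise
            beta = 1.0 / (1.0 + np.exp(-logit))
            betas.append(np.clip(beta, 1e-6, 1 - 1e-6))
            rows.append({
                "cpg": f"cg{len(rows):05d}", "gene": gene,
                "promoter": k == 0, "chrom": "chr1",
                "pos": pos_cursor + int(offsets[k]),
            })
        pos_cursor += 10_000
    cpg_map = pd.DataFrame(rows).set_index("cpg")
    beta = pd.DataFrame(np.vstack(betas), index=cpg_map.index,
                        columns=expression.columns)
    return beta, cpg_map


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(labels: pd.Series, config: SimConfig | None = None,
                      ) -> pd.DataFrame:
    """Exponential survival with cluster-specific hazard and independent
    exponential censoring.

    Clusters 1 and 4 get ``hazard_low``; clusters 2 and 3 get
    ``hazard_high``; normals get ``hazard_low``.  Columns: time (days),
    event (1 observed, 0 censored)."""
    config = config or SimConfig()
    rng = config.rng(4)
    low = {1, 4, "normal"}
    times = []
    events = []
    for lab in labels:
        h = config.hazard_low if lab in low else config.hazard_high
        t_event = rng.exponential(1.0 / h)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate)
        else:
            t_cens = np.inf
        times.append(min(t_event, t_cens))
        events.append(int(t_event <= t_cens))
    return pd.DataFrame({"time": times, "event": events}, index=labels.index)
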