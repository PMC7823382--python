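"""Model and media I/O.

The canonical interchange format is a small JSON dialect::

    {
      "metabolites": [{"id": "A"}, ...],
      "genes": ["g1", ...],
      "reactions": [
        {"id": "R1", "mets": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
         "gpr": "g1 and g2", "subsystem": "glycolysis",
         "objective": 0, "core": false},
        ...
      ]
    }

SBML Level 3 + FBC v2 import/export is provided as a convenience for
interoperating with constraint-based modeling toolchains; the JSON dialect
is authoritative (read∘write is the identity on it).

Media specs are YAML mappings ``reaction id -> [lower, upper]`` or
three-column TSV (``reaction\tlower\tupper``).
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import yaml

from .model import Gpr, MetabolicModel, parse_gpr

__all__ = ["read_model", "write_model", "read_media", "model_to_dict", "model_from_dict"]


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    S = model.stoichiometry.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rows = S.indices[S.indptr[j]:S.indptr[j + 1]]
        vals = S.data[S.indptr[j]:S.indptr[j + 1]]
        mets = {model.metabolite_ids[i]: float(v) for i, v in zip(rows, vals) if v != 0}
        g = model.gpr[j]
        reactions.append({
            "id": rid,
            "mets": mets,
            "lb": float(model.lower_bound[j]),
            "ub": float(model.upper_bound[j]),
            "gpr": g.to_string() if g is not None else None,
            "subsystem": model.subsystem[j],
            "objective": float(model.objective_coeffs[j]),
            "core": bool(model.core_flags[j]),
        })
    return {
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "genes": list(model.gene_ids),
        "reactions": reactions,
    }


def model_from_dict(doc: dict) -> MetabolicModel:
    met_ids = [m["id"] for m in doc["metabolites"]]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxns = doc["reactions"]
    n, m = len(rxns), len(met_ids)
    S = sp.lil_matrix((m, n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    obj = np.zeros(n)
    core = np.zeros(n, dtype=bool)
    gprs: list[Gpr | None] = []
    subsystems: list[str] = []
    for j, r in enumerate(rxns):
        for met, coef in r["mets"].items():
            if met not in met_index:
                raise ValueError(f"reaction {r['id']!r} references unknown metabolite {met!r}")
            S[met_index[met], j] = float(coef)
        lb[j] = r.get("lb", 0.0)
        ub[j] = r.get("ub", 1000.0)
        obj[j] = r.get("objective", 0.0)
        core[j] = bool(r.get("core", False))
        g = r.get("gpr")
        gprs.append(parse_gpr(g) if g else None)
        subsystems.append(r.get("subsystem", ""))
    genes = doc.get("genes")
    if genes is None:
        gene_set: set[str] = set()
        for g in gprs:
            if g is not None:
                gene_set |= g.genes()
        genes = sorted(gene_set)
    if not np.any(obj != 0):
        warnings.warn("model declares no objective reaction; objective left empty")
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=[r["id"] for r in rxns],
        stoichiometry=S.tocsc(),
        lower_bound=lb,
        upper_bound=ub,
        gpr=gprs,
        subsystem=subsystems,
        objective_coeffs=obj,
        gene_ids=list(genes),
        core_flags=core,
    )


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------

_SBML_SAFE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """SBML SId-safe identifier (prefix if starting with a digit)."""
    s = _SBML_SAFE.sub("_", raw)
    if not s or s[0].isdigit():
        s = "x_" + s
    return s


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId("model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for mid in model.metabolite_ids:
        sp_ = sbml_model.createSpecies()
        sp_.setId(_sid("M_" + mid))
        sp_.setName(mid)
        sp_.setCompartment("c")
        sp_.setHasOnlySubstanceUnits(False)
        sp_.setBoundaryCondition(False)
        sp_.setConstant(False)

    for gid in model.gene_ids:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_" + gid))
        gp.setName(gid)
        gp.setLabel(gid)

    def bound_param(value: float, j: int, which: str) -> str:
        pid = f"bnd_{which}_{j}"
        p = sbml_model.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    S = model.stoichiometry.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        rxn = sbml_model.createReaction()
        rxn.setId(_sid("R_" + rid))
        rxn.setName(rid)
        rxn.setFast(False)
        rxn.setReversible(bool(model.lower_bound[j] < 0))
        if model.subsystem[j]:
            rxn.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>SUBSYSTEM: '
                f"{model.subsystem[j]}</p></body>")
        rows = S.indices[S.indptr[j]:S.indptr[j + 1]]
        vals = S.data[S.indptr[j]:S.indptr[j + 1]]
        for i, v in zip(rows, vals):
            if v < 0:
                ref = rxn.createReactant()
            else:
                ref = rxn.createProduct()
            ref.setSpecies(_sid("M_" + model.metabolite_ids[i]))
            ref.setStoichiometry(abs(float(v)))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(model.lower_bound[j], j, "lo"))
        rplug.setUpperFluxBound(bound_param(model.upper_bound[j], j, "hi"))
        g = model.gpr[j]
        if g is not None:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(_gpr_to_fbc_infix(g))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    for j in np.flatnonzero(model.objective_coeffs):
        fo = objective.createFluxObjective()
        fo.setReaction(_sid("R_" + model.reaction_ids[j]))
        fo.setCoefficient(float(model.objective_coeffs[j]))
    mplug.setActiveObjectiveId("obj")

    if bool(np.any(model.core_flags)):
        core_ids = [model.reaction_ids[j] for j in np.flatnonzero(model.core_flags)]
        sbml_model.appendNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml"><p>CORE_REACTIONS: '
            + ",".join(core_ids) + "</p></body>")

    libsbml.writeSBMLToFile(doc, str(path))


def _gpr_to_fbc_infix(g: Gpr) -> str:
    # libsbml's infix parser resolves tokens against gene-product labels
    if g.op == "gene":
        return g.gene
    sep = " and " if g.op == "and" else " or "
    return "(" + sep.join(_gpr_to_fbc_infix(c) for c in g.children) + ")"


def _read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"SBML read error: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    mplug = sbml_model.getPlugin("fbc")

    met_sids = [sbml_model.getSpecies(i).getId() for i in range(sbml_model.getNumSpecies())]
    met_names = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        met_names[s.getId()] = s.getName() or s.getId()
    met_index = {sid: i for i, sid in enumerate(met_sids)}

    gene_ids = []
    gp_label = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getName() or gp.getId()
            gp_label[gp.getId()] = label
            gene_ids.append(label)

    n = sbml_model.getNumReactions()
    S = sp.lil_matrix((len(met_sids), n))
    lb = np.full(n, -np.inf)
    ub = np.full(n, np.inf)
    gprs: list[Gpr | None] = []
    subsystems: list[str] = []
    rxn_ids: list[str] = []
    sid_to_j: dict[str, int] = {}
    for j in range(n):
        rxn = sbml_model.getReaction(j)
        sid_to_j[rxn.getId()] = j
        rxn_ids.append(rxn.getName() or rxn.getId())
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            S[met_index[ref.getSpecies()], j] -= ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            S[met_index[ref.getSpecies()], j] += ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        if rplug is not None:
            lo_p = sbml_model.getParameter(rplug.getLowerFluxBound())
            hi_p = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lo_p is not None:
                lb[j] = lo_p.getValue()
            if hi_p is not None:
                ub[j] = hi_p.getValue()
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gprs.append(_fbc_assoc_to_gpr(gpa.getAssociation(), gp_label))
            else:
                gprs.append(None)
        else:
            gprs.append(None)
        sub = ""
        if rxn.isSetNotes():
            notes = rxn.getNotesString()
            m = re.search(r"SUBSYSTEM:\s*([^<]*)", notes)
            if m:
                sub = m.group(1).strip()
        subsystems.append(sub)

    obj = np.zeros(n)
    if mplug is not None and mplug.getActiveObjective() is not None:
        active = mplug.getActiveObjective()
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            obj[sid_to_j[fo.getReaction()]] = fo.getCoefficient()
    if not np.any(obj != 0):
        warnings.warn("SBML model has no active objective; objective left empty")

    core = np.zeros(n, dtype=bool)
    if sbml_model.isSetNotes():
        m = re.search(r"CORE_REACTIONS:\s*([^<]*)", sbml_model.getNotesString())
        if m:
            core_set = {c.strip() for c in m.group(1).split(",") if c.strip()}
            for j, rid in enumerate(rxn_ids):
                core[j] = rid in core_set

    return MetabolicModel(
        metabolite_ids=[met_names[sid] for sid in met_sids],
        reaction_ids=rxn_ids,
        stoichiometry=S.tocsc(),
        lower_bound=lb,
        upper_bound=ub,
        gpr=gprs,
        subsystem=subsystems,
        objective_coeffs=obj,
        gene_ids=gene_ids or sorted({g for gg in gprs if gg for g in gg.genes()}),
        core_flags=core,
    )


def _fbc_assoc_to_gpr(assoc, gp_label: dict[str, str]) -> Gpr:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return Gpr("gene", gene=gp_label.get(assoc.getGeneProduct(), assoc.getGeneProduct()))
    children = tuple(
        _fbc_assoc_to_gpr(assoc.getAssociation(i), gp_label)
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    return Gpr(op, children=children)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from the JSON dialect or SBML; format inferred from suffix."""
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def read_media(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a media spec from YAML (mapping id -> [lb, ub]) or TSV (3 columns)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
    media: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, lo, hi = line.split("\t")
            media[rid] = (float(lo), float(hi))
    return media
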