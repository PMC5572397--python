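"""Readers and writers: SBML (through COBRApy/libsbml), a plain tabular
model dialect, and the TSV tables for enzymes, kinetics and proteomics.

Tabular model dialect (TSV with a header row)::

    rxn_id  equation            lb    ub    gene_rule
    R1      A <=> B             -5    10    P1
    EX_A    --> A               0     10
    R3      C --> D                         P3A and P3B

* ``-->`` marks an irreversible, ``<=>`` a reversible reaction.
* Coefficients precede metabolite ids (``2 B``); 1 may be omitted.
* Blank lb/ub default to 0/-1000 (per the arrow) and 1000.
* An optional comment line ``# metabolites: A,B,C`` pre-declares the
  metabolite set; equations referencing others then fail validation.
* An optional comment line ``# objective: <rxn_id>`` names the objective.
"""

from __future__ import annotations

import re
from pathlib import Path

import cobra
import pandas as pd

from .model import (
    DEFAULT_BOUND,
    EnzymeInfo,
    KineticRecord,
    MetabolicModel,
    Metabolite,
    ProteomicsSet,
    Reaction,
    ValidationError,
)

__all__ = [
    "read_model",
    "write_model",
    "read_enzyme_table",
    "write_enzyme_table",
    "read_kinetics_table",
    "write_kinetics_table",
    "read_proteomics",
    "to_cobra",
    "from_cobra",
]

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# COBRApy bridge

def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert to a :class:`cobra.Model` (used for SBML I/O and LP solving)."""
    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, cm.reactions):
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        cr.bounds = (r.lower_bound, r.upper_bound)
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
    if model.objective:
        cm.objective = model.objective
        cm.objective_direction = model.objective_direction
    return cm


def from_cobra(cm: cobra.Model) -> MetabolicModel:
    """Convert a :class:`cobra.Model` back to the plain domain type."""
    mets = [
        Metabolite(m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    rxns = []
    objective_ids = [
        r.id for r in cm.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gene_rule=r.gene_reaction_rule or "",
                name=r.name or "",
                subsystem=r.subsystem or "",
            )
        )
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        objective=objective_ids[0] if objective_ids else "",
        objective_direction=cm.objective_direction or "max",
    )
    return model


# ---------------------------------------------------------------------------
# Models

def read_model(path: str | Path) -> MetabolicModel:
    """Read a model from SBML (``.xml``/``.sbml``) or the tabular dialect.

    Bounds absent from the file default to [0, 1000] for irreversible and
    [-1000, 1000] for reversible reactions (mmol/gDW/h).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises various types
            raise ValidationError(f"cannot parse SBML file {path}: {exc}") from exc
        model = from_cobra(cm)
    else:
        model = _read_tabular(path)
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model to SBML or the tabular dialect, by file extension."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        _write_tabular(model, path)


_ARROWS = ("<=>", "-->")


def _parse_side(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?\s+)?(\S+)$", term)
        if not m:
            raise ValidationError(f"cannot parse equation term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coeff
    return out


def _read_tabular(path: Path) -> MetabolicModel:
    declared: set[str] | None = None
    objective = ""
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("metabolites:"):
                declared = {
                    m.strip() for m in body.split(":", 1)[1].split(",") if m.strip()
                }
            elif body.lower().startswith("objective:"):
                objective = body.split(":", 1)[1].strip()
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        rows.append(dict(zip(header, (f.strip() for f in fields))))
    if header is None:
        raise ValidationError(f"{path}: empty model file")
    required = {"rxn_id", "equation"}
    if not required <= set(header):
        raise ValidationError(f"{path}: header must contain {sorted(required)}")

    reactions = []
    seen_mets: dict[str, Metabolite] = {}
    for row in rows:
        rid = row["rxn_id"]
        eq = row["equation"]
        arrow = next((a for a in _ARROWS if a in eq), None)
        if arrow is None:
            raise ValidationError(f"reaction {rid}: equation {eq!r} has no arrow")
        left, right = eq.split(arrow)
        stoich: dict[str, float] = {}
        for met, c in _parse_side(left).items():
            stoich[met] = stoich.get(met, 0.0) - c
        for met, c in _parse_side(right).items():
            stoich[met] = stoich.get(met, 0.0) + c
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        reversible = arrow == "<=>"
        lb_text = row.get("lb", "")
        ub_text = row.get("ub", "")
        lb = float(lb_text) if lb_text else (-DEFAULT_BOUND if reversible else 0.0)
        ub = float(ub_text) if ub_text else DEFAULT_BOUND
        for met in stoich:
            if declared is not None and met not in declared:
                raise ValidationError(
                    f"reaction {rid} references undeclared metabolite {met!r}"
                )
            seen_mets.setdefault(met, Metabolite(met))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=row.get("gene_rule", ""),
                subsystem=row.get("subsystem", ""),
            )
        )
    if declared is not None:
        for met in sorted(declared):
            seen_mets.setdefault(met, Metabolite(met))
    return MetabolicModel(
        id=path.stem,
        metabolites=[seen_mets[k] for k in sorted(seen_mets)],
        reactions=reactions,
        objective=objective,
    )


def _format_side(items: list[tuple[str, float]]) -> str:
    parts = []
    for met, c in items:
        if c == 1.0:
            parts.append(met)
        else:
            parts.append(f"{_FLOAT_FMT % c} {met}")
    return " + ".join(parts)


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    lines = []
    lines.append("# metabolites: " + ",".join(sorted(m.id for m in model.metabolites)))
    if model.objective:
        lines.append(f"# objective: {model.objective}")
    lines.append("rxn_id\tequation\tlb\tub\tgene_rule")
    for r in model.reactions:
        left = [(m, -c) for m, c in sorted(r.stoichiometry.items()) if c < 0]
        right = [(m, c) for m, c in sorted(r.stoichiometry.items()) if c > 0]
        arrow = "<=>" if r.reversible else "-->"
        eq = f"{_format_side(left)} {arrow} {_format_side(right)}".strip()
        lines.append(
            "\t".join(
                [
                    r.id,
                    eq,
                    _FLOAT_FMT % r.lower_bound,
                    _FLOAT_FMT % r.upper_bound,
                    r.gene_rule,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Enzyme, kinetics and proteomics tables

def read_enzyme_table(path: str | Path) -> list[EnzymeInfo]:
    """Read the enzyme annotation TSV.

    Required columns: ``protein_id``, ``gene``, ``mw_kDa``, ``ec_numbers``
    (semicolon separated, may be empty).  Optional: ``complex_id``,
    ``stoichiometry`` (defaults to 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "gene", "mw_kDa", "ec_numbers"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"enzyme table {path}: missing columns {sorted(required - set(df.columns))}"
        )
    out = []
    for _, row in df.iterrows():
        ecs = tuple(e.strip() for e in row["ec_numbers"].split(";") if e.strip())
        complex_id = row.get("complex_id", "") or None
        stoich = float(row.get("stoichiometry", "") or 1.0)
        out.append(
            EnzymeInfo(
                protein_id=row["protein_id"],
                gene=row["gene"],
                mw_kda=float(row["mw_kDa"]),
                ec_numbers=ecs,
                complex_id=complex_id,
                stoichiometry=stoich,
            )
        )
    return out


def write_enzyme_table(enzymes: list[EnzymeInfo], path: str | Path) -> None:
    rows = [
        {
            "protein_id": e.protein_id,
            "gene": e.gene,
            "mw_kDa": _FLOAT_FMT % e.mw_kda,
            "ec_numbers": ";".join(e.ec_numbers),
            "complex_id": e.complex_id or "",
            "stoichiometry": _FLOAT_FMT % e.stoichiometry,
        }
        for e in enzymes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_kinetics_table(path: str | Path) -> list[KineticRecord]:
    """Read the local kinetics TSV: columns ec, substrate, organism, kcat_per_s."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"ec", "substrate", "organism", "kcat_per_s"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"kinetics table {path}: missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    return [
        KineticRecord(
            ec=row["ec"],
            substrate=row["substrate"],
            organism=row["organism"],
            kcat_per_s=float(row["kcat_per_s"]),
        )
        for _, row in df.iterrows()
    ]


def write_kinetics_table(records: list[KineticRecord], path: str | Path) -> None:
    rows = [
        {
            "ec": r.ec,
            "substrate": r.substrate,
            "organism": r.organism,
            "kcat_per_s": _FLOAT_FMT % r.kcat_per_s,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_proteomics(
    path: str | Path,
    total_protein: float,
    min_replicates: int = 2,
) -> ProteomicsSet:
    """Read an absolute proteomics TSV into a :class:`ProteomicsSet`.

    Columns: ``protein_id`` then one column per replicate (mmol/gDW); an
    empty cell means the protein was not detected in that replicate.
    Proteins detected in fewer than ``min_replicates`` replicates are
    dropped, mirroring the replicate filter applied to triplicate data.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "protein_id" not in df.columns:
        raise ValidationError(f"proteomics table {path}: missing protein_id column")
    rep_cols = [c for c in df.columns if c != "protein_id"]
    if not rep_cols:
        raise ValidationError(f"proteomics table {path}: no replicate columns")
    abundances: dict[str, tuple[float, ...]] = {}
    for _, row in df.iterrows():
        vals = []
        for c in rep_cols:
            cell = row[c].strip()
            if cell == "":
                continue
            v = float(cell)
            if v < 0:
                raise ValidationError(
                    f"protein {row['protein_id']}: negative abundance {v}"
                )
            vals.append(v)
        if len(vals) >= min_replicates:
            abundances[row["protein_id"]] = tuple(vals)
    return ProteomicsSet(
        abundances=abundances,
        total_protein=total_protein,
        n_replicates=len(rep_cols),
    )
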