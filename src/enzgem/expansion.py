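"""The stoichiometric-matrix expansion that turns a metabolic model into an
enzyme-constrained model.

The transform is a composition of three stages:

1. :func:`split_reversible` — every reversible reaction becomes a forward
   and a ``_REV`` backward copy so each direction can carry its own kcat.
2. :func:`expand_isozymes` — a reaction catalyzed by k > 1 alternative
   enzymes (OR in the gene rule) is split into an ``arm_`` reaction that
   carries the total flux into a ``pmet_`` intermediate, plus one copy
   (``No1..Nok``) per alternative.
3. :func:`attach_enzymes` — each catalyzed reaction column consumes its
   enzyme row(s) with coefficient -(subunit stoichiometry)/(kcat in 1/h),
   and one ``draw_prot_`` usage column per enzyme supplies its row.

In the resulting matrix the upper-left block is the original stoichiometry,
the lower-left block holds the kinetic coefficients, and the lower-right
block is the identity over enzyme usages; bounding a usage reaction by the
enzyme's abundance enforces v <= kcat * [E] structurally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .kinetics import KcatAssignmentSet, group_key
from .model import (
    KCAT_S_TO_H,
    ECModel,
    EnzymeInfo,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
)

__all__ = [
    "split_reversible",
    "expand_isozymes",
    "attach_enzymes",
    "expand_model",
    "classify_model",
    "validate_ec",
    "reduce_to_metabolic",
    "rehydrate_ec",
    "ModelStats",
]

INF = float("inf")

ANN_SOURCE = "source_rxn"
ANN_DIRECTION = "direction"
ANN_GROUP = "enzyme_group"


def _is_expanded(model: MetabolicModel) -> bool:
    return isinstance(model, ECModel) or any(
        m.id.startswith(("prot_", "pmet_")) for m in model.metabolites
    )


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Split every reversible reaction into forward and ``_REV`` copies.

    A reaction with lb < 0 < ub yields ``<id>`` with bounds [0, ub] and
    ``<id>_REV`` with negated stoichiometry and bounds [0, -lb].  Pure
    backward reactions (ub <= 0 < -lb) are flipped and renamed.  All
    reactions end up irreversible (lb >= 0).
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    for r in out.reactions:
        fwd = r.copy()
        fwd.annotation.setdefault(ANN_SOURCE, r.id)
        fwd.annotation.setdefault(ANN_DIRECTION, "fwd")
        if r.lower_bound < 0 < r.upper_bound:
            bwd = r.copy()
            bwd.id = r.id + "_REV"
            bwd.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
            bwd.lower_bound, bwd.upper_bound = 0.0, -r.lower_bound
            bwd.annotation[ANN_SOURCE] = r.id
            bwd.annotation[ANN_DIRECTION] = "bwd"
            fwd.lower_bound = 0.0
            new_reactions.extend([fwd, bwd])
        elif r.upper_bound <= 0 and r.lower_bound < 0:
            fwd.id = r.id + "_REV"
            fwd.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
            fwd.lower_bound, fwd.upper_bound = (
                max(0.0, -r.upper_bound),
                -r.lower_bound,
            )
            fwd.annotation[ANN_DIRECTION] = "bwd"
            new_reactions.append(fwd)
        else:
            new_reactions.append(fwd)
    out.reactions = new_reactions
    return out


def expand_isozymes(
    model: MetabolicModel, enzymes: list[EnzymeInfo]
) -> MetabolicModel:
    """Introduce arm reactions and per-isozyme copies.

    Requires an irreversible model (run :func:`split_reversible` first).
    Gene rules are normalized to OR-of-ANDs; duplicate alternatives are
    deduplicated; copies are numbered ``No1..Nok`` over alternatives sorted
    by their protein ids.  Single-alternative and enzyme-free reactions are
    untouched apart from provenance annotation.
    """
    from .kinetics import _resolve_groups  # shared resolution logic

    enzyme_map = {e.protein_id: e for e in enzymes}
    gene_map = {e.gene: e for e in enzymes}
    out = model.copy()
    new_reactions: list[Reaction] = []
    new_mets: list[Metabolite] = list(out.metabolites)
    for r in out.reactions:
        if r.lower_bound < 0:
            raise ValidationError(
                f"reaction {r.id} is reversible; split directions before "
                f"expanding isozymes"
            )
        if not r.gene_rule:
            new_reactions.append(r)
            continue
        groups, missing = _resolve_groups(r.gene_rule, enzyme_map, gene_map)
        if not groups:
            # gene rule could not be resolved against the enzyme table;
            # the reaction stays a plain metabolic reaction
            r.annotation[ANN_GROUP] = None
            new_reactions.append(r)
            continue
        groups = sorted(groups, key=lambda g: sorted(g))
        if len(groups) == 1:
            r.annotation[ANN_GROUP] = group_key(groups[0], enzyme_map)
            new_reactions.append(r)
            continue
        pmet_id = f"pmet_{r.id}"
        new_mets.append(Metabolite(pmet_id, name=f"isozyme intermediate of {r.id}"))
        arm = Reaction(
            id=f"arm_{r.id}",
            stoichiometry={
                **{m: c for m, c in r.stoichiometry.items() if c < 0},
                pmet_id: 1.0,
            },
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            name=f"arm reaction of {r.id}",
            subsystem=r.subsystem,
            annotation={
                ANN_SOURCE: r.annotation.get(ANN_SOURCE, r.id),
                ANN_DIRECTION: r.annotation.get(ANN_DIRECTION, "fwd"),
                "arm_of": r.id,
            },
        )
        new_reactions.append(arm)
        for k, group in enumerate(groups, start=1):
            copy = Reaction(
                id=f"{r.id}No{k}",
                stoichiometry={
                    pmet_id: -1.0,
                    **{m: c for m, c in r.stoichiometry.items() if c > 0},
                },
                lower_bound=0.0,
                upper_bound=r.upper_bound,
                gene_rule=" and ".join(
                    sorted(enzyme_map[p].gene for p in group)
                ),
                name=f"{r.name or r.id} (isozyme {k})",
                subsystem=r.subsystem,
                annotation={
                    ANN_SOURCE: r.annotation.get(ANN_SOURCE, r.id),
                    ANN_DIRECTION: r.annotation.get(ANN_DIRECTION, "fwd"),
                    ANN_GROUP: group_key(group, enzyme_map),
                    "copy_of": r.id,
                },
            )
            new_reactions.append(copy)
    out.reactions = new_reactions
    out.metabolites = new_mets
    return out


def attach_enzymes(
    model: MetabolicModel,
    assignments: KcatAssignmentSet,
    enzymes: list[EnzymeInfo],
) -> ECModel:
    """Add enzyme rows, kinetic coefficients and usage reactions.

    For each catalyzed reaction the coefficient of row ``prot_<i>`` is
    -(subunit stoichiometry)_i / (kcat * 3600); complexes consume every
    subunit, promiscuous enzymes appear in several columns sharing one
    usage reaction.  Usage bounds start at [0, +inf) and are tightened by
    the constraints module.
    """
    enzyme_map = {e.protein_id: e for e in enzymes}
    lookup = assignments.lookup()
    used_proteins: set[str] = set()
    kcats_per_h: dict[tuple[str, str], float] = {}
    missing_pairs: list[tuple[str, str]] = []

    ec = ECModel(
        id=model.id + "_ec" if not model.id.endswith("_ec") else model.id,
        metabolites=list(model.metabolites),
        reactions=[r.copy() for r in model.reactions],
        objective=model.objective,
        objective_direction=model.objective_direction,
        enzymes=enzyme_map,
    )

    for r in ec.reactions:
        key = r.annotation.get(ANN_GROUP)
        if not key:
            continue
        # assignments were made on the un-expanded model: look up by the
        # direction-qualified source reaction id
        source = r.annotation.get(ANN_SOURCE, r.id)
        if r.annotation.get(ANN_DIRECTION) == "bwd" and not source.endswith("_REV"):
            source = source + "_REV"
        assignment = lookup.get((source, key))
        if assignment is None:
            missing_pairs.append((r.id, key))
            continue
        kcat_h = assignment.kcat_per_s * KCAT_S_TO_H
        members = _group_members(key, enzyme_map)
        for pid in members:
            info = enzyme_map[pid]
            r.stoichiometry[ECModel.enzyme_row(pid)] = -info.stoichiometry / kcat_h
            kcats_per_h[(r.id, pid)] = kcat_h
            used_proteins.add(pid)

    if missing_pairs:
        raise ValidationError(
            f"no kcat assignment for catalyzed pairs: {sorted(missing_pairs)}"
        )

    for pid in sorted(used_proteins):
        ec.metabolites.append(
            Metabolite(ECModel.enzyme_row(pid), name=f"enzyme {pid}")
        )
        ec.reactions.append(
            Reaction(
                id=ECModel.usage_rxn(pid),
                stoichiometry={ECModel.enzyme_row(pid): 1.0},
                lower_bound=0.0,
                upper_bound=INF,
                name=f"usage of enzyme {pid}",
                annotation={"usage_of": pid},
            )
        )
    ec.kcats_per_h = kcats_per_h
    ec.provenance = {
        "assignments": assignments,
        "n_enzymes": len(used_proteins),
    }
    ec.validate()
    return ec


def _group_members(key: str, enzyme_map: dict[str, EnzymeInfo]) -> list[str]:
    """Resolve a group key back to its member protein ids."""
    if key in enzyme_map:
        return [key]
    members = sorted(
        p for p, e in enzyme_map.items() if e.complex_id == key
    )
    if members:
        return members
    if "+" in key:
        return sorted(key.split("+"))
    raise ValidationError(f"cannot resolve enzyme group {key!r}")


def expand_model(
    model: MetabolicModel,
    enzymes: list[EnzymeInfo],
    assignments: KcatAssignmentSet,
) -> ECModel:
    """Full transform: split directions, expand isozymes, attach enzymes."""
    if _is_expanded(model):
        raise ValidationError(
            "model already contains enzyme rows or pseudo-metabolites; "
            "refusing to expand twice"
        )
    model.validate()
    split = split_reversible(model)
    with_arms = expand_isozymes(split, enzymes)
    return attach_enzymes(with_arms, assignments, enzymes)


def validate_ec(ec: ECModel, tol: float = 1e-12) -> None:
    """Check the structural invariants of an enzyme-constrained model."""
    ec.validate()
    met_ids = ec.metabolite_ids()
    enzyme_rows = set(ec.enzyme_row_ids())
    for (rid, pid), kcat_h in ec.kcats_per_h.items():
        r = ec.get_reaction(rid)
        info = ec.enzymes[pid]
        expected = -info.stoichiometry / kcat_h
        got = r.stoichiometry.get(ECModel.enzyme_row(pid))
        if got is None or abs(got - expected) > tol * max(1.0, abs(expected)):
            raise ValidationError(
                f"reaction {rid}: enzyme coefficient for {pid} is {got}, "
                f"expected {expected}"
            )
    for r in ec.reactions:
        if r.id.startswith("draw_prot_"):
            touched = set(r.stoichiometry)
            enzyme_touched = touched & enzyme_rows
            extra = touched - enzyme_rows - {ECModel.POOL_MET}
            if len(enzyme_touched) != 1 or extra:
                raise ValidationError(
                    f"usage reaction {r.id} must touch exactly one enzyme row "
                    f"(plus the pool); touches {sorted(touched)}"
                )
            if r.lower_bound < 0:
                raise ValidationError(f"usage reaction {r.id} has negative lb")
    for row in enzyme_rows | {m for m in met_ids if m.startswith("pmet_")}:
        producers = [
            r.id for r in ec.reactions if r.stoichiometry.get(row, 0) > 0
        ]
        if not producers:
            raise ValidationError(f"row {row} has no producing reaction")


def reduce_to_metabolic(ec: ECModel) -> MetabolicModel:
    """Strip enzyme rows/usages, re-merge isozyme copies and directions.

    Recovers the original metabolic stoichiometry: arm reactions and their
    copies collapse back into one reaction per direction, forward/backward
    pairs re-merge into one reversible reaction.  Used to check that the
    expansion is information-preserving on the metabolic part.
    """
    special_mets = {
        m.id
        for m in ec.metabolites
        if m.id.startswith(("prot_", "pmet_")) or m.id == ECModel.POOL_MET
    }
    by_source: dict[str, dict[str, list[Reaction]]] = {}
    for r in ec.reactions:
        if r.id.startswith("draw_prot_") or r.id == ECModel.POOL_RXN:
            continue
        source = r.annotation.get(ANN_SOURCE, r.id)
        direction = r.annotation.get(ANN_DIRECTION, "fwd")
        by_source.setdefault(source, {}).setdefault(direction, []).append(r)

    def _direction_stoich(rxns: list[Reaction]) -> tuple[dict, float, float]:
        """Net stoichiometry and bounds of one direction (arm + one copy,
        or the plain reaction)."""
        arm = next((r for r in rxns if "arm_of" in r.annotation), None)
        if arm is None:
            plain = rxns[0]
            stoich = {
                m: c for m, c in plain.stoichiometry.items()
                if m not in special_mets
            }
            return stoich, plain.lower_bound, plain.upper_bound
        copy = next(r for r in rxns if "copy_of" in r.annotation)
        stoich = {
            m: c for m, c in arm.stoichiometry.items() if m not in special_mets
        }
        for m, c in copy.stoichiometry.items():
            if m not in special_mets:
                stoich[m] = stoich.get(m, 0.0) + c
        return stoich, arm.lower_bound, arm.upper_bound

    merged = []
    for source, dirs in by_source.items():
        if "fwd" in dirs:
            stoich, f_lb, f_ub = _direction_stoich(dirs["fwd"])
            lb, ub = f_lb, f_ub
            if "bwd" in dirs:
                _, _, b_ub = _direction_stoich(dirs["bwd"])
                lb = -b_ub
        else:  # pure backward original: un-flip
            stoich, b_lb, b_ub = _direction_stoich(dirs["bwd"])
            stoich = {m: -c for m, c in stoich.items()}
            lb, ub = -b_ub, -b_lb
        template = next(iter(dirs.values()))[0]
        merged.append(
            Reaction(
                id=source,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule="",
                subsystem=template.subsystem,
            )
        )
    mets = [m for m in ec.metabolites if m.id not in special_mets]
    merged_ids = {r.id for r in merged}
    out = MetabolicModel(
        id=ec.id[:-3] if ec.id.endswith("_ec") else ec.id,
        metabolites=mets,
        reactions=sorted(merged, key=lambda r: r.id),
        objective=ec.objective if ec.objective in merged_ids else "",
        objective_direction=ec.objective_direction,
    )
    return out


_COPY_RE = re.compile(r"^(?P<base>.+)No(?P<k>\d+)$")


def rehydrate_ec(model: MetabolicModel, enzymes: list[EnzymeInfo]) -> ECModel:
    """Reconstruct an :class:`ECModel` from a structurally expanded model.

    Used when an expanded model comes back from SBML, which preserves the
    stoichiometry but not the provenance metadata.  Turnover numbers are
    recovered from the kinetic coefficients (-stoich/kcat_h), usage and
    pool wiring from the id conventions, and source/direction annotations
    from the ``_REV``/``No<k>``/``arm_`` suffixes.
    """
    enzyme_map = {e.protein_id: e for e in enzymes}
    ec = ECModel(
        id=model.id,
        metabolites=list(model.metabolites),
        reactions=[r.copy() for r in model.reactions],
        objective=model.objective,
        objective_direction=model.objective_direction,
        enzymes=enzyme_map,
    )
    prot_rows = set(ec.enzyme_row_ids())
    kcats: dict[tuple[str, str], float] = {}
    for r in ec.reactions:
        rid = r.id
        if rid.startswith("draw_prot_"):
            r.annotation["usage_of"] = rid[len("draw_prot_"):]
            continue
        if rid == ECModel.POOL_RXN:
            continue
        base = rid
        if base.startswith("arm_"):
            base = base[len("arm_"):]
            r.annotation["arm_of"] = base
        m = _COPY_RE.match(base)
        if m:
            r.annotation["copy_of"] = base
            base = m.group("base")
        if base.endswith("_REV"):
            r.annotation[ANN_DIRECTION] = "bwd"
            base = base[: -len("_REV")]
        else:
            r.annotation[ANN_DIRECTION] = "fwd"
        r.annotation[ANN_SOURCE] = base
        members = frozenset(
            m[len("prot_"):] for m in r.stoichiometry if m in prot_rows
        )
        if members:
            from .kinetics import group_key

            r.annotation[ANN_GROUP] = group_key(members, enzyme_map)
            for pid in sorted(members):
                coeff = r.stoichiometry[ECModel.enzyme_row(pid)]
                info = enzyme_map.get(pid)
                if info is None:
                    raise ValidationError(
                        f"expanded model uses enzyme {pid} missing from the "
                        f"enzyme table"
                    )
                kcats[(r.id, pid)] = -info.stoichiometry / coeff
    ec.kcats_per_h = kcats
    if any(m.id == ECModel.POOL_MET for m in ec.metabolites):
        from .constraints import PoolConfig

        pool_rxn = ec.get_reaction(ECModel.POOL_RXN)
        ec.pool = PoolConfig(p_total=pool_rxn.upper_bound, f=1.0, sigma=1.0)
    return ec


@dataclass
class ModelStats:
    """Classification counts for an enzyme-constrained model.

    Reaction classes are disjoint (priority: usage > pool exchange > arm >
    exchange > transport > enzyme-matched > unmatched) and sum to the
    reaction total; metabolite classes sum to the metabolite total.
    """

    total_reactions: int = 0
    enzyme_matched: int = 0
    unmatched_metabolic: int = 0
    transport: int = 0
    exchange: int = 0
    arm_reactions: int = 0
    usage_reactions: int = 0
    pool_reactions: int = 0

    total_metabolites: int = 0
    original_metabolites: int = 0
    enzymes: int = 0
    pseudo_metabolites: int = 0
    pool_metabolites: int = 0

    complexes: int = 0
    reactions_with_isozymes: int = 0
    promiscuous_enzymes: int = 0

    def reaction_class_sum(self) -> int:
        return (
            self.enzyme_matched
            + self.unmatched_metabolic
            + self.transport
            + self.exchange
            + self.arm_reactions
            + self.usage_reactions
            + self.pool_reactions
        )

    def metabolite_class_sum(self) -> int:
        return (
            self.original_metabolites
            + self.enzymes
            + self.pseudo_metabolites
            + self.pool_metabolites
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Number of reactions", self.total_reactions),
            ("Metabolic reactions matched with an enzyme(s)", self.enzyme_matched),
            ("Metabolic reactions not matched with an enzyme",
             self.unmatched_metabolic),
            ("Transport reactions", self.transport),
            ("Metabolite exchange reactions", self.exchange),
            ("Arm reactions introduced for isozymes", self.arm_reactions),
            ("Enzyme usages (treated as reactions)", self.usage_reactions),
            ("Pool exchange reactions", self.pool_reactions),
            ("Number of metabolites", self.total_metabolites),
            ("Original metabolites", self.original_metabolites),
            ("Enzymes", self.enzymes),
            ("Pseudo-metabolites introduced for isozymes",
             self.pseudo_metabolites),
            ("Enzyme pool pseudo-metabolites", self.pool_metabolites),
            ("Complexes", self.complexes),
            ("Reactions with isozymes", self.reactions_with_isozymes),
            ("Promiscuous enzymes", self.promiscuous_enzymes),
        ]
        return pd.DataFrame(rows, columns=["descriptor", "count"])


def _species_key(met: Metabolite) -> str:
    """Species identity across compartments (name if set, else id stem)."""
    if met.name:
        return met.name.lower()
    mid = met.id
    for sep in ("[", "_"):
        if sep in mid:
            head, _, tail = mid.rpartition(sep)
            if head and len(tail.rstrip("]")) <= 3:
                return head
    return mid


def classify_model(ec: ECModel) -> ModelStats:
    """Count the descriptor statistics of an enzyme-constrained model."""
    stats = ModelStats()
    met_map = {m.id: m for m in ec.metabolites}
    # enzyme rows and the pool are bookkeeping; pmet_ intermediates carry
    # real mass and stay part of a reaction's substrate/product structure
    special = {
        m.id for m in ec.metabolites
        if m.id.startswith("prot_") or m.id == ECModel.POOL_MET
    }
    catalyzed = {rid for rid, _ in ec.kcats_per_h}

    stats.total_reactions = len(ec.reactions)
    for r in ec.reactions:
        if r.id.startswith("draw_prot_"):
            stats.usage_reactions += 1
            continue
        if r.id == ECModel.POOL_RXN:
            stats.pool_reactions += 1
            continue
        if r.id.startswith("arm_"):
            stats.arm_reactions += 1
            continue
        ordinary = {m: c for m, c in r.stoichiometry.items() if m not in special}
        signs = {c > 0 for c in ordinary.values()}
        if len(signs) <= 1:  # all products or all substrates: boundary exchange
            stats.exchange += 1
            continue
        compartments: dict[str, set[str]] = {}
        for m in ordinary:
            met = met_map[m]
            compartments.setdefault(_species_key(met), set()).add(met.compartment)
        if any(len(comps) > 1 for comps in compartments.values()):
            stats.transport += 1
            continue
        if r.id in catalyzed:
            stats.enzyme_matched += 1
        else:
            stats.unmatched_metabolic += 1

    stats.total_metabolites = len(ec.metabolites)
    for m in ec.metabolites:
        if m.id == ECModel.POOL_MET:
            stats.pool_metabolites += 1
        elif m.id.startswith("prot_"):
            stats.enzymes += 1
        elif m.id.startswith("pmet_"):
            stats.pseudo_metabolites += 1
        else:
            stats.original_metabolites += 1

    groups = set()
    protein_reactions: dict[str, set[str]] = {}
    for r in ec.reactions:
        key = r.annotation.get(ANN_GROUP)
        if key:
            members = _group_members(key, ec.enzymes)
            if len(members) > 1:
                groups.add(key)
            source = r.annotation.get(ANN_SOURCE, r.id)
            base = source[:-4] if source.endswith("_REV") else source
            for pid in members:
                protein_reactions.setdefault(pid, set()).add(base)
    stats.complexes = len(groups)
    arm_sources = {
        r.annotation.get(ANN_SOURCE, r.id)
        for r in ec.reactions
        if r.id.startswith("arm_")
    }
    stats.reactions_with_isozymes = len(
        {s[:-4] if s.endswith("_REV") else s for s in arm_sources}
    )
    stats.promiscuous_enzymes = sum(
        1 for rxns in protein_reactions.values() if len(rxns) > 1
    )
    return stats
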