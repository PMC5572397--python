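"""Deterministic synthetic models exercising every enzyme/reaction
formalism, so the whole pipeline is testable without external databases.

``TOY1`` is a five-enzyme linear network with one reversible reaction, one
isozyme pair, one two-subunit complex and one promiscuous enzyme; every
kcat resolves from the bundled kinetics table at the exact-match level.
``OVF1`` is a two-pathway resource-allocation model whose optimum can be
derived by hand: a high-yield, enzyme-expensive respiratory route competes
with a low-yield, cheap fermentative route under a shared enzyme-mass
pool, reproducing the overflow (Crabtree-type) switch analytically.
"""

from __future__ import annotations

import numpy as np

from .constraints import PoolConfig, add_pool
from .expansion import expand_model
from .kinetics import KcatAssignment, KcatAssignmentSet, assign_kcats
from .model import (
    ECModel,
    EnzymeInfo,
    KineticRecord,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "ORGANISM",
    "make_toy_gem",
    "make_toy_ec",
    "make_overflow_model",
    "make_random_kcat_null",
]

ORGANISM = "Saccharomyces cerevisiae"

INF = float("inf")


def make_toy_gem() -> tuple[MetabolicModel, list[EnzymeInfo], list[KineticRecord]]:
    """The TOY1 bundle: model, enzyme table, kinetics table.

    Network (all coefficients 1)::

        EX_A:          -> A     [0, 10]
        R1:     A    <-> B      P1   (MW 40, kcat 10 fwd / 5 bwd)
        R2:     B     -> C      P2A or P2B  (isozymes: MW 50 kcat 20 /
                                             MW 60 kcat 4)
        R3:     C     -> D      P3A and P3B (complex CPX1, subunits x1/x2,
                                             MW 30/20, shared kcat 2)
        R4:     C     -> D      P2A  (promiscuous, kcat 1)
        GROWTH: D     ->        objective, not enzyme catalyzed

    kcats are in 1/s and chosen so the 1/h conversion gives round
    coefficients (e.g. kcat 10 -> 1/36000).  The unconstrained maximum
    growth is 10, set by the substrate uptake bound.
    """
    model = MetabolicModel(
        id="TOY1",
        metabolites=[Metabolite(m) for m in "ABCD"],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0, gene_rule="G1"),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, 1000.0,
                     gene_rule="G2A or G2B"),
            Reaction("R3", {"C": -1.0, "D": 1.0}, 0.0, 1000.0,
                     gene_rule="G3A and G3B"),
            Reaction("R4", {"C": -1.0, "D": 1.0}, 0.0, 1000.0, gene_rule="G2A"),
            Reaction("GROWTH", {"D": -1.0}, 0.0, 1000.0),
        ],
        objective="GROWTH",
    )
    enzymes = [
        EnzymeInfo("P1", "G1", 40.0, ("1.1.1.1",)),
        EnzymeInfo("P2A", "G2A", 50.0, ("2.7.1.1",)),
        EnzymeInfo("P2B", "G2B", 60.0, ("2.7.1.2",)),
        EnzymeInfo("P3A", "G3A", 30.0, ("4.1.1.1",), complex_id="CPX1",
                   stoichiometry=1.0),
        EnzymeInfo("P3B", "G3B", 20.0, ("4.1.1.2",), complex_id="CPX1",
                   stoichiometry=2.0),
    ]
    kinetics = [
        KineticRecord("1.1.1.1", "A", ORGANISM, 10.0),
        KineticRecord("1.1.1.1", "B", ORGANISM, 5.0),
        # a faster foreign-organism record that exact matching must ignore
        KineticRecord("1.1.1.1", "A", "Escherichia coli", 50.0),
        KineticRecord("2.7.1.1", "B", ORGANISM, 20.0),
        KineticRecord("2.7.1.2", "B", ORGANISM, 4.0),
        KineticRecord("4.1.1.1", "C", ORGANISM, 2.0),
        KineticRecord("2.7.1.1", "C", ORGANISM, 1.0),
    ]
    return model, enzymes, kinetics


def make_toy_ec() -> ECModel:
    """TOY1 expanded to an enzyme-constrained model (usage bounds +inf)."""
    model, enzymes, kinetics = make_toy_gem()
    assignments = assign_kcats(model, enzymes, kinetics, ORGANISM)
    return expand_model(model, enzymes, assignments)


def make_overflow_model(
    uptake: float = 1.0, pool_bound: float = 10.0
) -> ECModel:
    """The OVF1 resource-allocation model, pool-constrained.

    One substrate S can be burned by two routes::

        RESP: S -> 10 ATP   enzyme cost 10 g h/mmol (MW 10, kcat_h 1)
        FERM: S ->  2 ATP + Byp   cost 1 g h/mmol  (MW 1,  kcat_h 1)

    with uptake bounded by ``uptake`` (U) and total enzyme mass by
    ``pool_bound`` (E, g/gDW); GROWTH consumes ATP 1:1 and is maximized.
    The reduced LP is  max 10 r + 2 f  s.t.  r + f <= U,  10 r + f <= E.
    At E = 10: pure respiration (ATP = 10 U) for U <= 1; a mixed optimum
    ATP = (80 U + 100)/9 for 1 < U < 10 (r = (10 - U)/9); pure
    fermentation capped at ATP = 20 for U >= 10.
    """
    kcat_s = 1.0 / 3600.0  # kcat_h exactly 1
    model = MetabolicModel(
        id="OVF1",
        metabolites=[Metabolite("S"), Metabolite("ATP"), Metabolite("Byp")],
        reactions=[
            Reaction("EX_S", {"S": 1.0}, 0.0, uptake),
            Reaction("RESP", {"S": -1.0, "ATP": 10.0}, 0.0, 1000.0,
                     gene_rule="GR"),
            Reaction("FERM", {"S": -1.0, "ATP": 2.0, "Byp": 1.0}, 0.0, 1000.0,
                     gene_rule="GF"),
            Reaction("EX_BYP", {"Byp": -1.0}, 0.0, 1000.0),
            Reaction("GROWTH", {"ATP": -1.0}, 0.0, 1000.0),
        ],
        objective="GROWTH",
    )
    enzymes = [
        EnzymeInfo("E_RESP", "GR", 10.0, ("1.9.3.1",)),
        EnzymeInfo("E_FERM", "GF", 1.0, ("1.1.1.2",)),
    ]
    kinetics = [
        KineticRecord("1.9.3.1", "S", ORGANISM, kcat_s),
        KineticRecord("1.1.1.2", "S", ORGANISM, kcat_s),
    ]
    assignments = assign_kcats(model, enzymes, kinetics, ORGANISM)
    ec = expand_model(model, enzymes, assignments)
    return add_pool(ec, PoolConfig(p_total=pool_bound, f=1.0, sigma=1.0))


def make_random_kcat_null(
    assignments: KcatAssignmentSet, seed: int
) -> KcatAssignmentSet:
    """Permute kcat values across assignments (seeded, multiset preserved).

    A null model for asking whether a predicted behavior follows from the
    actual enzyme parameters or from the network structure alone.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assignments to permute")
    rng = np.random.default_rng(seed)
    values = [a.kcat_per_s for a in assignments]
    perm = rng.permutation(len(values))
    shuffled = [
        KcatAssignment(
            reaction_id=a.reaction_id,
            protein_id=a.protein_id,
            kcat_per_s=values[perm[i]],
            level=a.level,
            source="shuffled",
            record=None,
        )
        for i, a in enumerate(assignments)
    ]
    return KcatAssignmentSet(assignments=shuffled, gaps=list(assignments.gaps))
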