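"""Core domain types for metabolic models and enzyme data.

Units convention, fixed package-wide:

* fluxes: mmol/gDW/h
* enzyme usage: mmol/gDW
* molecular weight: kDa (numerically equal to g/mmol)
* turnover numbers: stored as 1/s in tables, converted once to 1/h
  (factor 3600) when the expanded model is assembled
* protein mass and pool bounds: g/gDW
"""

from __future__ import annotations

import ast
import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_BOUND",
    "KCAT_S_TO_H",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ECModel",
    "EnzymeInfo",
    "KineticRecord",
    "ProteomicsSet",
    "ValidationError",
    "gene_rule_dnf",
]

#: Default flux bound magnitude (mmol/gDW/h) used when a file omits bounds.
DEFAULT_BOUND = 1000.0

#: Conversion factor from kcat in 1/s to 1/h.
KCAT_S_TO_H = 3600.0

_EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")


class ValidationError(ValueError):
    """Raised when a model, table or parameter violates its contract."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A (possibly reversible) stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed).  ``gene_rule`` is a boolean AND/OR expression
    over gene ids; the empty string means "not gene associated".
    ``annotation`` carries provenance added during expansion (source
    reaction id, direction, isozyme group) and survives copies.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: str = ""
    name: str = ""
    subsystem: str = ""
    annotation: dict = field(default_factory=dict)

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            annotation=dict(self.annotation),
        )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model: S matrix, bounds, objective."""

    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: str = ""
    objective_direction: str = "max"

    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gene_rule:
                for group in gene_rule_dnf(r.gene_rule):
                    out.update(group)
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective=self.objective,
            objective_direction=self.objective_direction,
        )

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError`."""
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        declared = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ValidationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ValidationError(
                    f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            if r.gene_rule:
                gene_rule_dnf(r.gene_rule)  # raises on unparseable rules
        if self.objective and self.objective not in set(rxn_ids):
            raise ValidationError(f"objective reaction {self.objective!r} not in model")
        if self.objective_direction not in ("max", "min"):
            raise ValidationError(f"objective direction {self.objective_direction!r}")


@dataclass(frozen=True)
class EnzymeInfo:
    """One protein: accession, gene, mass, EC annotation, complex membership.

    ``stoichiometry`` is the subunit copy number within ``complex_id``
    (1 for stand-alone enzymes).
    """

    protein_id: str
    gene: str
    mw_kda: float
    ec_numbers: tuple[str, ...] = ()
    complex_id: str | None = None
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if not self.mw_kda > 0:
            raise ValidationError(
                f"enzyme {self.protein_id}: molecular weight must be positive, "
                f"got {self.mw_kda}"
            )
        if not self.stoichiometry > 0:
            raise ValidationError(
                f"enzyme {self.protein_id}: subunit stoichiometry must be positive"
            )
        for ec in self.ec_numbers:
            if not _EC_PATTERN.match(ec):
                raise ValidationError(
                    f"enzyme {self.protein_id}: malformed EC number {ec!r}"
                )


@dataclass(frozen=True)
class KineticRecord:
    """One turnover-number measurement from the local kinetics table."""

    ec: str
    substrate: str
    organism: str
    kcat_per_s: float

    def __post_init__(self) -> None:
        if not self.kcat_per_s > 0:
            raise ValidationError(f"kcat must be positive, got {self.kcat_per_s}")


@dataclass
class ProteomicsSet:
    """Per-protein replicate abundances (mmol/gDW) with summary statistics.

    ``abundances`` maps protein id to the tuple of detected replicate
    values; ``mean`` and ``sd`` are computed over detected replicates only
    (sample standard deviation, zero when a single replicate is detected).
    """

    abundances: dict[str, tuple[float, ...]]
    total_protein: float  # g/gDW
    n_replicates: int

    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.total_protein > 0:
            raise ValidationError("total protein content must be positive")
        self.mean = {}
        self.sd = {}
        for pid, vals in self.abundances.items():
            if any(v < 0 for v in vals):
                raise ValidationError(f"protein {pid}: negative abundance")
            mu = sum(vals) / len(vals)
            if len(vals) > 1:
                var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
                sd = math.sqrt(var)
            else:
                sd = 0.0
            self.mean[pid] = mu
            self.sd[pid] = sd

    def protein_ids(self) -> set[str]:
        return set(self.abundances)


@dataclass
class ECModel(MetabolicModel):
    """An enzyme-constrained model: the expanded network plus provenance.

    On top of the plain stoichiometry the model carries the enzyme table,
    the per-(reaction, protein) turnover numbers in 1/h used for the
    kinetic coefficients, and (once a pool constraint is added) the pool
    configuration.  Enzyme mass-balance rows use the ``prot_`` id prefix,
    isozyme intermediates ``pmet_``, usage reactions ``draw_prot_``.
    """

    enzymes: dict[str, EnzymeInfo] = field(default_factory=dict)
    kcats_per_h: dict[tuple[str, str], float] = field(default_factory=dict)
    pool: "object | None" = None  # PoolConfig, set by constraints.add_pool
    provenance: dict = field(default_factory=dict)

    POOL_MET = "prot_pool"
    POOL_RXN = "prot_pool_exchange"

    @staticmethod
    def enzyme_row(protein_id: str) -> str:
        return f"prot_{protein_id}"

    @staticmethod
    def usage_rxn(protein_id: str) -> str:
        return f"draw_prot_{protein_id}"

    def enzyme_row_ids(self) -> list[str]:
        return [m.id for m in self.metabolites
                if m.id.startswith("prot_") and m.id != self.POOL_MET]

    def usage_rxn_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.id.startswith("draw_prot_")]

    def copy(self) -> "ECModel":
        out = ECModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective=self.objective,
            objective_direction=self.objective_direction,
            enzymes=dict(self.enzymes),
            kcats_per_h=dict(self.kcats_per_h),
            pool=self.pool,
            provenance=dict(self.provenance),
        )
        return out


def gene_rule_dnf(rule: str) -> list[frozenset[str]]:
    """Normalize a boolean gene rule to disjunctive normal form.

    Returns the rule as a list of alternative gene groups: each group is a
    set of genes all required together (a complex), and any one group
    suffices (isozymes).  Duplicate and subsumed groups are removed, and
    the result is sorted for determinism.

    >>> gene_rule_dnf("(A and B) or C")
    [frozenset({'A', 'B'}), frozenset({'C'})]
    """
    text = rule.strip()
    if not text:
        return []
    normalized = re.sub(r"\bAND\b", "and", re.sub(r"\bOR\b", "or", text))
    normalized = normalized.replace("&&", " and ").replace("||", " or ")
    try:
        tree = ast.parse(normalized, mode="eval").body
    except SyntaxError as exc:
        raise ValidationError(f"unparseable gene rule {rule!r}: {exc}") from exc
    groups = _dnf(tree, rule)
    # drop duplicates and groups that are supersets of another group
    unique = sorted(set(groups), key=lambda g: (len(g), sorted(g)))
    minimal: list[frozenset[str]] = []
    for g in unique:
        if not any(m < g for m in minimal):
            minimal.append(g)
    return sorted(minimal, key=lambda g: sorted(g))


def _dnf(node: ast.AST, rule: str) -> list[frozenset[str]]:
    if isinstance(node, ast.Name):
        return [frozenset([node.id])]
    if isinstance(node, ast.BoolOp):
        parts = [_dnf(v, rule) for v in node.values]
        if isinstance(node.op, ast.Or):
            return [g for p in parts for g in p]
        # AND: cartesian product of the operand DNFs
        result = parts[0]
        for p in parts[1:]:
            result = [a | b for a in result for b in p]
        return result
    raise ValidationError(
        f"gene rule {rule!r}: unsupported element {ast.dump(node)}"
    )
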