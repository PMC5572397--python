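"""Turnover-number assignment by hierarchical matching against a local
kinetics table.

Every catalyzed (reaction direction, enzyme) pair is matched to a kcat by
relaxing the query step by step until records are found:

=====  =======================================================
level  criteria
=====  =======================================================
L0     EC number + substrate + organism all match
L1     EC number + substrate match, any organism
L2     EC number + organism match, any substrate
L3     EC number matches, any substrate/organism
L4     EC number with the last (serial) digit wildcarded
=====  =======================================================

At the first level with at least one hit, the MAXIMUM kcat among the hits
is taken — the fastest reported variant of the enzyme — so that the model
is not over-constrained by slow outliers.  The level order is exposed as a
parameter because substrate-vs-organism relaxation priority is a modeling
choice; the default relaxes organism before substrate, since the same
catalytic step in another organism is biologically closer than a different
substrate in the same organism.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    EnzymeInfo,
    KineticRecord,
    MetabolicModel,
    ValidationError,
    gene_rule_dnf,
)

__all__ = [
    "KcatQuery",
    "KcatAssignment",
    "KcatAssignmentSet",
    "NoKcatFound",
    "match_kcat",
    "assign_kcats",
    "apply_manual_curation",
    "read_curation_table",
    "group_key",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS = (0, 1, 2, 3, 4)

#: Provenance level for default-filled assignments.
LEVEL_DEFAULT = -1
#: Provenance level recorded when a backward direction reuses the forward kcat.
LEVEL_REUSED_FORWARD = 3


class NoKcatFound(LookupError):
    """No kinetic record matched the query at any relaxation level."""


@dataclass(frozen=True)
class KcatQuery:
    """One lookup: the enzyme's EC numbers, the consumed metabolites of the
    reaction direction being matched, and the model organism."""

    ec_numbers: tuple[str, ...]
    substrates: tuple[str, ...]
    organism: str
    direction: str = "fwd"

    def __post_init__(self) -> None:
        if not self.ec_numbers:
            raise ValidationError("kcat query requires at least one EC number")


@dataclass
class KcatAssignment:
    """A turnover number assigned to one (reaction, enzyme-group) pair.

    ``protein_id`` is the enzyme accession for stand-alone enzymes and the
    complex id (or a ``+``-joined subunit list) for complexes, which receive
    a single shared kcat.  ``level`` is the relaxation level of the match
    (-1 for default-filled pairs); ``source`` is one of ``matched``,
    ``reused_forward``, ``default``, ``curated``.
    """

    reaction_id: str
    protein_id: str
    kcat_per_s: float
    level: int
    source: str = "matched"
    record: KineticRecord | None = None

    def __post_init__(self) -> None:
        if not self.kcat_per_s > 0:
            raise ValidationError(
                f"assignment {self.reaction_id}/{self.protein_id}: "
                f"kcat must be positive, got {self.kcat_per_s}"
            )


@dataclass
class KcatAssignmentSet:
    """Assignments plus the gap report for pairs that could not be matched."""

    assignments: list[KcatAssignment] = field(default_factory=list)
    #: (reaction_id, gene_or_protein, reason) for unmatched pairs
    gaps: list[tuple[str, str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def lookup(self) -> dict[tuple[str, str], KcatAssignment]:
        return {(a.reaction_id, a.protein_id): a for a in self.assignments}

    def gap_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gaps, columns=["reaction_id", "protein_id", "reason"]
        )


def _norm(text: str) -> str:
    return text.strip().lower()


def _ec_wildcard(ec: str) -> str:
    head = ec.rsplit(".", 1)[0]
    return head + ".-"


def _hits_at_level(
    level: int, query: KcatQuery, table: list[KineticRecord]
) -> list[KineticRecord]:
    ecs = set(query.ec_numbers)
    wild = {_ec_wildcard(e) for e in query.ec_numbers}
    subs = {_norm(s) for s in query.substrates}
    org = _norm(query.organism)
    hits = []
    for rec in table:
        rec_sub = _norm(rec.substrate)
        rec_org = _norm(rec.organism)
        if level == 0:
            ok = rec.ec in ecs and rec_sub in subs and rec_org == org
        elif level == 1:
            ok = rec.ec in ecs and rec_sub in subs
        elif level == 2:
            ok = rec.ec in ecs and rec_org == org
        elif level == 3:
            ok = rec.ec in ecs
        elif level == 4:
            ok = _ec_wildcard(rec.ec) in wild or rec.ec in wild
        else:
            raise ValueError(f"unknown relaxation level {level}")
        if ok:
            hits.append(rec)
    return hits


def match_kcat(
    query: KcatQuery,
    table: list[KineticRecord],
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> tuple[float, int, KineticRecord]:
    """Match one query against the kinetics table.

    Returns ``(kcat_per_s, level, record)`` for the maximum-kcat hit at the
    first relaxation level with any hit.  Ties on kcat are broken by a
    stable sort on (EC, substrate, organism) so results are deterministic.

    Raises :class:`NoKcatFound` when no level yields a hit.
    """
    if not table:
        raise NoKcatFound("kinetics table is empty")
    for level in levels:
        hits = _hits_at_level(level, query, table)
        if hits:
            best = sorted(
                hits,
                key=lambda r: (-r.kcat_per_s, r.ec, _norm(r.substrate), _norm(r.organism)),
            )[0]
            return best.kcat_per_s, level, best
    raise NoKcatFound(
        f"no kcat for EC {list(query.ec_numbers)} at any relaxation level"
    )


def group_key(protein_ids: frozenset[str], enzymes: dict[str, EnzymeInfo]) -> str:
    """Stable identifier for an isozyme alternative (enzyme or complex).

    A multi-subunit group sharing a declared complex id uses that id;
    otherwise subunit accessions are joined with ``+``.
    """
    if len(protein_ids) == 1:
        return next(iter(protein_ids))
    cids = {enzymes[p].complex_id for p in protein_ids if p in enzymes}
    if len(cids) == 1 and None not in cids:
        return next(iter(cids))
    return "+".join(sorted(protein_ids))


def _resolve_groups(
    rule: str, enzymes: dict[str, EnzymeInfo], gene_map: dict[str, EnzymeInfo]
) -> tuple[list[frozenset[str]], list[str]]:
    """DNF-resolve a gene rule to enzyme groups; returns (groups, missing genes)."""
    groups: list[frozenset[str]] = []
    missing: list[str] = []
    for gene_group in gene_rule_dnf(rule):
        pids = set()
        ok = True
        for g in gene_group:
            if g in gene_map:
                pids.add(gene_map[g].protein_id)
            elif g in enzymes:
                pids.add(g)
            else:
                missing.append(g)
                ok = False
        if ok:
            groups.append(frozenset(pids))
    seen = set()
    unique = []
    for g in sorted(groups, key=lambda s: sorted(s)):
        if g not in seen:
            seen.add(g)
            unique.append(g)
    return unique, missing


def assign_kcats(
    model: MetabolicModel,
    enzymes: list[EnzymeInfo],
    table: list[KineticRecord],
    organism: str,
    default_policy: str | float = "median",
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> KcatAssignmentSet:
    """Assign a kcat to every (reaction direction, enzyme group) pair.

    Works on the un-expanded model: a reversible reaction yields two
    assignments, keyed ``<id>`` (forward) and ``<id>_REV`` (backward, with
    the product side as query substrates).  Complexes are queried once with
    the union of subunit EC numbers and receive one shared kcat.  When the
    backward direction finds no record of its own, the forward value is
    reused (recorded as ``reused_forward`` at level 3) rather than leaving
    the direction unconstrained.  Pairs with no match at any level are
    filled per ``default_policy``: ``"median"`` (median of all successful
    assignments) or a numeric constant, recorded at level -1.
    """
    enzyme_map = {e.protein_id: e for e in enzymes}
    gene_map = {e.gene: e for e in enzymes}
    met_names = {m.id: (m.name or m.id) for m in model.metabolites}

    out = KcatAssignmentSet()
    pending_default: list[tuple[str, str]] = []

    for rxn in model.reactions:
        if not rxn.gene_rule:
            continue
        groups, missing = _resolve_groups(rxn.gene_rule, enzyme_map, gene_map)
        for g in missing:
            out.gaps.append((rxn.id, g, "gene not in enzyme table"))
        if not groups:
            continue
        directions = []
        if rxn.upper_bound > 0:
            directions.append(("fwd", rxn.id))
        if rxn.lower_bound < 0:
            directions.append(("bwd", rxn.id + "_REV"))
        for group in groups:
            key = group_key(group, enzyme_map)
            ecs = tuple(
                sorted({ec for p in sorted(group) for ec in enzyme_map[p].ec_numbers})
            )
            fwd_result: tuple[float, int, KineticRecord] | None = None
            for direction, rid in directions:
                if direction == "fwd":
                    subs = tuple(met_names[m] for m in rxn.substrates())
                else:
                    subs = tuple(met_names[m] for m in rxn.products())
                if not ecs:
                    pending_default.append((rid, key))
                    continue
                query = KcatQuery(
                    ec_numbers=ecs, substrates=subs, organism=organism,
                    direction=direction,
                )
                try:
                    kcat, level, rec = match_kcat(query, table, levels)
                    out.assignments.append(
                        KcatAssignment(rid, key, kcat, level, "matched", rec)
                    )
                    if direction == "fwd":
                        fwd_result = (kcat, level, rec)
                except NoKcatFound:
                    if direction == "bwd" and fwd_result is not None:
                        kcat, _, rec = fwd_result
                        out.assignments.append(
                            KcatAssignment(
                                rid, key, kcat, LEVEL_REUSED_FORWARD,
                                "reused_forward", rec,
                            )
                        )
                    else:
                        pending_default.append((rid, key))

    matched_kcats = [a.kcat_per_s for a in out.assignments]
    for rid, key in pending_default:
        if isinstance(default_policy, (int, float)):
            value = float(default_policy)
        elif default_policy == "median" and matched_kcats:
            value = statistics.median(matched_kcats)
        else:
            out.gaps.append((rid, key, "no kcat found and no default available"))
            continue
        out.assignments.append(
            KcatAssignment(rid, key, value, LEVEL_DEFAULT, "default", None)
        )
    return out


def read_curation_table(path: str | Path) -> list[tuple[str, str, float]]:
    """Read manual kcat overrides: columns reaction_id, protein_id, kcat_per_s."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"reaction_id", "protein_id", "kcat_per_s"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"curation table {path}: missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    return [
        (row["reaction_id"], row["protein_id"], float(row["kcat_per_s"]))
        for _, row in df.iterrows()
    ]


def apply_manual_curation(
    assignments: KcatAssignmentSet,
    overrides: list[tuple[str, str, float]],
) -> KcatAssignmentSet:
    """Replace assigned kcats with manually curated values.

    Overrides whose (reaction, protein) key is absent raise a warning and
    are skipped; non-positive override values are rejected.
    """
    index = {(a.reaction_id, a.protein_id): a for a in assignments.assignments}
    for rid, pid, kcat in overrides:
        if not kcat > 0:
            raise ValidationError(
                f"curated kcat for {rid}/{pid} must be positive, got {kcat}"
            )
        key = (rid, pid)
        if key not in index:
            warnings.warn(
                f"curation override for unknown pair {rid}/{pid} ignored",
                stacklevel=2,
            )
            continue
        a = index[key]
        a.kcat_per_s = kcat
        a.source = "curated"
        a.record = None
    return assignments
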