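"""Abundance constraints on enzyme usage.

Three regimes are supported:

* **No proteomics** — a shared mass pool: one ``prot_pool`` row supplied by
  a single exchange bounded by sigma * f * P_total (g/gDW), with every
  usage reaction drawing MW_i grams of pool per mmol of enzyme, so that
  sum_i MW_i * e_i <= sigma * f * P_total.
* **Full proteomics** — each usage reaction bounded directly by
  mean + SD of the measured abundance (mmol/gDW).
* **Hybrid** — measured enzymes bounded directly; the unmeasured remainder
  pooled with bound sigma * f_unmeasured * (P_total - matched mass).

Parameters: P_total is total cellular protein (g/gDW); f the mass fraction
of it covered by model enzymes; sigma the average in-vivo saturation of
enzymes (a fitted scalar in (0, 1]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .model import (
    ECModel,
    EnzymeInfo,
    MetabolicModel,
    Metabolite,
    ProteomicsSet,
    Reaction,
    ValidationError,
)

__all__ = [
    "PoolConfig",
    "MassReport",
    "add_pool",
    "set_proteomics_bounds",
    "hybrid_constraints",
    "correct_complex_abundances",
    "apply_maintenance",
    "proteomics_mass_report",
]

INF = float("inf")


@dataclass(frozen=True)
class PoolConfig:
    """Shared enzyme-pool parameters; the bound is sigma * f * P_total."""

    p_total: float  # g protein / gDW
    f: float = 1.0  # enzyme mass fraction of total protein
    sigma: float = 1.0  # average saturation

    def __post_init__(self) -> None:
        if not self.p_total > 0:
            raise ValidationError("P_total must be positive")
        if not 0 < self.f <= 1:
            raise ValidationError(f"f must be in (0, 1], got {self.f}")
        if not 0 < self.sigma <= 1:
            raise ValidationError(f"sigma must be in (0, 1], got {self.sigma}")

    @property
    def bound(self) -> float:
        """Pool upper bound in g/gDW."""
        return self.sigma * self.f * self.p_total


def add_pool(
    ec: ECModel,
    cfg: PoolConfig,
    scope: set[str] | None = None,
) -> ECModel:
    """Attach the shared enzyme-mass pool to (a subset of) usage reactions.

    ``scope`` defaults to all enzymes.  In-scope usage reactions consume
    MW_i (g/mmol) of the ``prot_pool`` row per unit usage and have their
    direct upper bound released to +inf; the pool exchange is bounded by
    ``cfg.bound`` (g/gDW).  Out-of-scope usages are untouched.
    """
    out = ec.copy()
    all_enzymes = {pid for pid in out.enzymes
                   if ECModel.usage_rxn(pid) in {r.id for r in out.reactions}}
    if scope is None:
        scope = all_enzymes
    else:
        unknown = scope - set(out.enzymes)
        if unknown:
            raise ValidationError(f"pool scope outside model enzymes: {sorted(unknown)}")
    if not scope:
        warnings.warn("empty pool scope: no pool added", stacklevel=2)
        return out
    if all(m.id != ECModel.POOL_MET for m in out.metabolites):
        out.metabolites.append(
            Metabolite(ECModel.POOL_MET, name="shared enzyme mass pool")
        )
        out.reactions.append(
            Reaction(
                id=ECModel.POOL_RXN,
                stoichiometry={ECModel.POOL_MET: 1.0},
                lower_bound=0.0,
                upper_bound=cfg.bound,
                name="enzyme pool supply (g/gDW)",
            )
        )
    else:
        pool_rxn = out.get_reaction(ECModel.POOL_RXN)
        pool_rxn.upper_bound = cfg.bound
    for r in out.reactions:
        pid = r.annotation.get("usage_of")
        if pid in scope:
            r.stoichiometry[ECModel.POOL_MET] = -out.enzymes[pid].mw_kda
            r.upper_bound = INF
    out.pool = replace(cfg)
    return out


def set_proteomics_bounds(
    ec: ECModel, prot: ProteomicsSet
) -> tuple[ECModel, float, set[str]]:
    """Bound each measured enzyme usage by mean + SD of its abundance.

    Returns the constrained model, the matched protein mass
    sum MW_i * mean_i (g/gDW) over measured model enzymes, and the set of
    model enzymes without a measurement (candidates for pooling).
    """
    out = ec.copy()
    model_enzymes = {
        r.annotation.get("usage_of")
        for r in out.reactions
        if r.annotation.get("usage_of")
    }
    measured = model_enzymes & prot.protein_ids()
    if not measured:
        warnings.warn("no proteomics measurement matches any model enzyme",
                      stacklevel=2)
    matched_mass = 0.0
    for r in out.reactions:
        pid = r.annotation.get("usage_of")
        if pid in measured:
            r.upper_bound = prot.mean[pid] + prot.sd[pid]
            matched_mass += out.enzymes[pid].mw_kda * prot.mean[pid]
    unmeasured = model_enzymes - measured
    return out, matched_mass, unmeasured


@dataclass(frozen=True)
class MassReport:
    """Bookkeeping of measured vs unmeasured enzyme mass (g/gDW)."""

    p_total: float
    matched_mass: float
    remaining_mass: float       # P_total - matched
    pool_mass: float            # f_unmeasured * remaining, before sigma
    pool_bound: float           # sigma applied
    matched_fraction: float     # matched / (matched + pool_mass)


def proteomics_mass_report(
    p_total: float,
    matched_mass: float,
    f_unmeasured: float,
    sigma: float = 1.0,
) -> MassReport:
    """Compute the measured/unmeasured enzyme-mass split.

    The unmeasured pool mass is ``f_unmeasured * (P_total - matched)``;
    the operational pool bound additionally carries the saturation factor
    sigma.  Both are reported because the pre-sigma mass is the quantity
    comparable to proteome databases while the sigma-scaled value is the
    LP bound.
    """
    if matched_mass >= p_total:
        raise ValidationError(
            f"matched enzyme mass {matched_mass} g/gDW is not below total "
            f"protein {p_total} g/gDW"
        )
    remaining = p_total - matched_mass
    pool_mass = f_unmeasured * remaining
    return MassReport(
        p_total=p_total,
        matched_mass=matched_mass,
        remaining_mass=remaining,
        pool_mass=pool_mass,
        pool_bound=sigma * pool_mass,
        matched_fraction=matched_mass / (matched_mass + pool_mass),
    )


def hybrid_constraints(
    ec: ECModel,
    prot: ProteomicsSet,
    p_total: float,
    f_unmeasured: float,
    sigma: float,
) -> tuple[ECModel, MassReport]:
    """Measured enzymes bounded directly; the rest share a mass pool.

    With an empty proteomics set this reduces to :func:`add_pool` over all
    enzymes (with ``f = f_unmeasured``); with full coverage no pool row is
    added and it equals :func:`set_proteomics_bounds`.
    """
    constrained, matched_mass, unmeasured = set_proteomics_bounds(ec, prot)
    report = proteomics_mass_report(p_total, matched_mass, f_unmeasured, sigma)
    if unmeasured:
        cfg = PoolConfig(
            p_total=report.remaining_mass, f=f_unmeasured, sigma=sigma
        )
        constrained = add_pool(constrained, cfg, scope=unmeasured)
    return constrained, report


def correct_complex_abundances(
    prot: ProteomicsSet, enzymes: list[EnzymeInfo], complex_ids: set[str]
) -> ProteomicsSet:
    """Rescale subunit abundances of flagged complexes to a common level.

    Within each complex the relative abundance mean_i / stoich_i should be
    equal across subunits; measurements of large complexes often violate
    this because some subunits are detected at the noise floor.  Each
    measured subunit's mean is reset to stoich_i times the average relative
    abundance, and its SD is scaled by the same factor.
    """
    new_abund = dict(prot.abundances)
    by_complex: dict[str, list[EnzymeInfo]] = {}
    for e in enzymes:
        if e.complex_id in complex_ids:
            by_complex.setdefault(e.complex_id, []).append(e)
    for cid in sorted(complex_ids):
        subunits = by_complex.get(cid, [])
        measured = [e for e in subunits if e.protein_id in prot.abundances]
        if not measured:
            warnings.warn(f"complex {cid}: no measured subunit, left untouched",
                          stacklevel=2)
            continue
        relative = [prot.mean[e.protein_id] / e.stoichiometry for e in measured]
        mean_rel = sum(relative) / len(relative)
        for e in measured:
            old_mean = prot.mean[e.protein_id]
            new_mean = e.stoichiometry * mean_rel
            factor = new_mean / old_mean if old_mean > 0 else 1.0
            new_abund[e.protein_id] = tuple(
                v * factor for v in prot.abundances[e.protein_id]
            )
    return ProteomicsSet(
        abundances=new_abund,
        total_protein=prot.total_protein,
        n_replicates=prot.n_replicates,
    )


_ATP_SPECIES = ("atp", "adp", "pi", "h2o", "h", "phosphate", "water", "proton")


def apply_maintenance(
    model: MetabolicModel,
    gam: float,
    ngam: float,
    biomass_reaction: str | None = None,
    ngam_reaction: str = "NGAM",
    atp_species: tuple[str, ...] = _ATP_SPECIES,
) -> MetabolicModel:
    """Set growth- and non-growth-associated ATP maintenance.

    ``gam`` (mmol ATP/gDW) replaces the magnitude of the ATP-hydrolysis
    coefficients (ATP, ADP, phosphate, water, proton) in the biomass
    reaction; ``ngam`` (mmol ATP/gDW/h) becomes the lower bound of the
    maintenance reaction.  Species are recognized by name/id stem against
    ``atp_species``.
    """
    out = model.copy()
    bio_id = biomass_reaction or out.objective
    if not bio_id:
        raise ValidationError("no biomass reaction given and no objective set")
    biomass = out.get_reaction(bio_id)
    met_map = {m.id: m for m in out.metabolites}

    def _stem(met_id: str) -> str:
        met = met_map[met_id]
        name = (met.name or met.id).lower()
        for sep in ("[", "_"):
            if sep in name:
                name = name.split(sep)[0]
        return name

    atp_terms = [
        m for m in biomass.stoichiometry if _stem(m) in atp_species
    ]
    if not any(_stem(m) == "atp" for m in atp_terms):
        raise ValidationError(
            f"biomass reaction {bio_id} has no ATP hydrolysis term"
        )
    for m in atp_terms:
        sign = math.copysign(1.0, biomass.stoichiometry[m])
        biomass.stoichiometry[m] = sign * gam
    try:
        ngam_rxn = out.get_reaction(ngam_reaction)
    except KeyError:
        raise ValidationError(f"maintenance reaction {ngam_reaction!r} not in model")
    ngam_rxn.lower_bound = ngam
    if ngam_rxn.upper_bound < ngam:
        ngam_rxn.upper_bound = ngam
    return out
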