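"""Simulation recipes and analyses on enzyme-constrained models.

All linear programs are solved through COBRApy (GLPK backend).  The
lexicographic recipes fix each stage's optimum with a small relative slack
(1e-6) before optimizing the next stage, because exact equality constraints
are brittle in floating point.

Recipes implemented:

* :func:`fba` — plain flux balance analysis.
* :func:`minimize_enzyme_usage` — parsimonious enzyme allocation: minimize
  total enzyme mass sum MW_i * e_i at fixed fluxes.
* :func:`chemostat` — fix growth to the dilution rate, minimize substrate
  uptake, then minimize enzyme mass.
* :func:`batch` — open the medium, maximize growth under the pool
  constraint, then minimize uptake and enzyme mass.
* :func:`knockout` — block usage of listed enzymes.
* :func:`yield_envelope` — biomass-yield vs product-yield trade-off curve.
* :func:`fva` / :func:`fva_compare` — flux variability analysis and the
  reduction report against the unconstrained model.
* :func:`flux_control_coefficients` — relative sensitivity of a target
  flux to each enzyme's specific activity.
* :func:`fit_sigma` — bisection fit of the average saturation to an
  observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from cobra.exceptions import OptimizationError
from cobra.flux_analysis import flux_variability_analysis

from .expansion import split_reversible
from .io import to_cobra
from .model import ECModel, MetabolicModel, ValidationError

__all__ = [
    "SimResult",
    "FluxControlCoefficient",
    "fba",
    "minimize_enzyme_usage",
    "chemostat",
    "batch",
    "knockout",
    "scale_enzyme_kcats",
    "yield_envelope",
    "fva",
    "fva_compare",
    "flux_control_coefficients",
    "fit_sigma",
]

INF = float("inf")

#: Relative slack used when fixing a stage optimum in lexicographic recipes.
STAGE_SLACK = 1e-6

#: LP feasibility/optimality tolerance requested from the solver.
SOLVER_TOL = 1e-9


@dataclass
class SimResult:
    """One LP solution: objective, fluxes, enzyme usages, provenance."""

    objective_value: float | None
    status: str
    fluxes: dict[str, float] = field(default_factory=dict)
    usages: dict[str, float] = field(default_factory=dict)  # mmol/gDW
    pool_usage: float = 0.0  # g/gDW
    provenance: list[str] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxControlCoefficient:
    enzyme_id: str
    fcc: float
    delta: float


def _prepare(model: MetabolicModel):
    cm = to_cobra(model)
    cm.tolerance = SOLVER_TOL
    return cm


@dataclass
class _FailedSolution:
    status: str
    objective_value: None = None
    fluxes: None = None


def _optimize(cm):
    """Solve, reporting unbounded/infeasible as a status, never raising."""
    try:
        return cm.optimize(raise_error=False)
    except OptimizationError:
        return _FailedSolution(status=str(cm.solver.status))


def _mass_expression(ec: ECModel, cm) -> object:
    terms = []
    for r in cm.reactions:
        if r.id.startswith("draw_prot_"):
            pid = r.id[len("draw_prot_"):]
            terms.append(ec.enzymes[pid].mw_kda * r.flux_expression)
    if not terms:
        raise ValidationError("model has no enzyme usage reactions")
    return sum(terms)


def _result(model: MetabolicModel, solution, provenance: list[str]) -> SimResult:
    if solution is None or solution.status != "optimal":
        status = solution.status if solution is not None else "infeasible"
        return SimResult(None, status, provenance=provenance)
    fluxes = {r: float(v) for r, v in solution.fluxes.items()}
    usages = {
        rid[len("draw_prot_"):]: v
        for rid, v in fluxes.items()
        if rid.startswith("draw_prot_")
    }
    pool = fluxes.get(ECModel.POOL_RXN, 0.0)
    return SimResult(
        objective_value=float(solution.objective_value),
        status="optimal",
        fluxes=fluxes,
        usages=usages,
        pool_usage=pool,
        provenance=provenance,
    )


def _fix(cm, rxn_id: str, value: float) -> None:
    slack = STAGE_SLACK * max(1.0, abs(value))
    r = cm.reactions.get_by_id(rxn_id)
    r.bounds = (value - slack, value + slack)


def fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str | None = None,
) -> SimResult:
    """Plain FBA.  Infeasible or unbounded problems are reported in
    ``status`` rather than raised."""
    cm = _prepare(model)
    if objective is not None:
        cm.objective = objective
    if direction is not None:
        cm.objective_direction = direction
    obj = objective or model.objective
    solution = _optimize(cm)
    return _result(model, solution, [f"fba {cm.objective_direction} {obj}"])


def minimize_enzyme_usage(
    ec: ECModel,
    fixed: Sequence[tuple[str, float]] = (),
    mass_weighted: bool = True,
) -> SimResult:
    """Minimize total enzyme usage at the given fixed fluxes.

    With ``mass_weighted`` (default) the objective is sum MW_i * e_i in
    g/gDW — equivalently the pool draw; otherwise the unweighted sum of
    usages.  The minimized value is returned as the objective.
    """
    cm = _prepare(ec)
    provenance = []
    for rxn_id, value in fixed:
        _fix(cm, rxn_id, value)
        provenance.append(f"fixed {rxn_id}={value:g}")
    if mass_weighted:
        cm.objective = _mass_expression(ec, cm)
    else:
        cm.objective = sum(
            r.flux_expression for r in cm.reactions if r.id.startswith("draw_prot_")
        )
    cm.objective_direction = "min"
    solution = _optimize(cm)
    provenance.append(
        "minimized enzyme " + ("mass" if mass_weighted else "usage sum")
    )
    return _result(ec, solution, provenance)


def _uptake_sense(model: MetabolicModel, exchange_id: str) -> int:
    """+1 if uptake is a positive flux of the exchange, -1 otherwise.

    A source-style exchange (0 -> A) imports at positive flux; the SBML
    convention (A_e ->, run backwards) imports at negative flux.
    """
    r = model.get_reaction(exchange_id)
    ordinary = {m: c for m, c in r.stoichiometry.items()
                if not m.startswith(("prot_", "pmet_"))}
    total = sum(ordinary.values())
    return 1 if total > 0 else -1


def chemostat(
    ec: ECModel,
    dilution_rate: float,
    substrate_exchange: str,
    growth_reaction: str | None = None,
    mass_weighted: bool = True,
) -> SimResult:
    """Chemostat protocol: fix growth = D, minimize substrate uptake, fix
    the uptake, then minimize enzyme mass."""
    growth = growth_reaction or ec.objective
    sense = _uptake_sense(ec, substrate_exchange)
    cm = _prepare(ec)
    provenance = [f"fixed growth {growth}={dilution_rate:g} (dilution rate)"]
    _fix(cm, growth, dilution_rate)
    cm.objective = cm.reactions.get_by_id(substrate_exchange).flux_expression
    cm.objective_direction = "min" if sense > 0 else "max"
    s1 = _optimize(cm)
    if s1.status != "optimal":
        return SimResult(None, s1.status, provenance=provenance)
    uptake = float(s1.fluxes[substrate_exchange])
    provenance.append(f"minimized uptake {substrate_exchange} -> {uptake:g}")
    _fix(cm, substrate_exchange, uptake)
    cm.objective = (
        _mass_expression(ec, cm)
        if mass_weighted
        else sum(r.flux_expression for r in cm.reactions
                 if r.id.startswith("draw_prot_"))
    )
    cm.objective_direction = "min"
    s2 = _optimize(cm)
    provenance.append("minimized enzyme mass")
    result = _result(ec, s2, provenance)
    if result.optimal:
        # report growth as the headline objective of the recipe
        result.objective_value = result.fluxes[growth]
    return result


def batch(
    ec: ECModel,
    medium: dict[str, float],
    growth_reaction: str | None = None,
    mass_weighted: bool = True,
) -> SimResult:
    """Batch protocol: open the medium, maximize growth under the enzyme
    pool, then minimize uptake and enzyme mass.

    ``medium`` maps exchange reaction ids to their uptake caps
    (mmol/gDW/h; ``inf`` for unrestricted).  Growth is unbounded without a
    pool constraint: in that case the result status is ``unbounded`` and
    the caller should add the pool first.
    """
    growth = growth_reaction or ec.objective
    cm = _prepare(ec)
    provenance = []
    for ex_id, cap in medium.items():
        sense = _uptake_sense(ec, ex_id)
        r = cm.reactions.get_by_id(ex_id)
        if sense > 0:
            r.bounds = (0.0, cap)
        else:
            r.bounds = (-cap, max(r.upper_bound, 0.0))
        provenance.append(f"medium {ex_id} uptake cap {cap:g}")
    cm.objective = growth
    cm.objective_direction = "max"
    s1 = _optimize(cm)
    if s1.status != "optimal":
        msg = s1.status
        if s1.status == "unbounded" and ec.pool is None:
            msg = "unbounded (no enzyme pool constraint; add one first)"
        return SimResult(None, msg, provenance=provenance)
    mu = float(s1.objective_value)
    provenance.append(f"maximized growth -> {mu:g}")
    _fix(cm, growth, mu)
    uptake_expr = sum(
        _uptake_sense(ec, ex_id)
        * cm.reactions.get_by_id(ex_id).flux_expression
        for ex_id in medium
    )
    cm.objective = uptake_expr
    cm.objective_direction = "min"
    s2 = _optimize(cm)
    if s2.status != "optimal":
        return SimResult(None, s2.status, provenance=provenance)
    for ex_id in medium:
        _fix(cm, ex_id, float(s2.fluxes[ex_id]))
    provenance.append("minimized total uptake")
    cm.objective = (
        _mass_expression(ec, cm)
        if mass_weighted
        else sum(r.flux_expression for r in cm.reactions
                 if r.id.startswith("draw_prot_"))
    )
    cm.objective_direction = "min"
    s3 = _optimize(cm)
    provenance.append("minimized enzyme mass")
    result = _result(ec, s3, provenance)
    if result.optimal:
        result.objective_value = result.fluxes[growth]
    return result


def knockout(ec: ECModel, protein_ids: Sequence[str]) -> ECModel:
    """Block the usage of the listed enzymes (upper bound 0)."""
    out = ec.copy()
    usage_ids = {r.annotation.get("usage_of"): r for r in out.reactions
                 if r.annotation.get("usage_of")}
    unknown = [p for p in protein_ids if p not in usage_ids]
    if unknown:
        raise ValidationError(f"unknown enzyme ids for knockout: {unknown}")
    for pid in protein_ids:
        usage_ids[pid].upper_bound = 0.0
    return out


def scale_enzyme_kcats(ec: ECModel, protein_id: str, factor: float) -> ECModel:
    """Scale all turnover numbers of one enzyme by ``factor``.

    A promiscuous enzyme's specific activity is one property: every
    reaction it catalyzes is rescaled together.  Kinetic coefficients are
    -stoich/kcat_h, so they shrink as kcat grows.
    """
    if not factor > 0:
        raise ValidationError("kcat scale factor must be positive")
    out = ec.copy()
    row = ECModel.enzyme_row(protein_id)
    touched = False
    for r in out.reactions:
        if row in r.stoichiometry and not r.id.startswith("draw_prot_"):
            r.stoichiometry[row] /= factor
            touched = True
    if not touched:
        raise ValidationError(f"enzyme {protein_id} catalyzes no reaction")
    out.kcats_per_h = {
        key: (v * factor if key[1] == protein_id else v)
        for key, v in out.kcats_per_h.items()
    }
    return out


def yield_envelope(
    ec: ECModel,
    product_exchange: str,
    substrate_exchange: str,
    n_points: int,
    product_mw: float,
    substrate_mw: float,
    substrate_uptake: float | None = None,
    growth_reaction: str | None = None,
) -> pd.DataFrame:
    """Biomass-yield vs maximum-product-yield trade-off curve.

    Protocol per grid point (growth fractions 0..100% of the maximum):
    fix the substrate uptake, fix growth to the suboptimal value, maximize
    the product rate, then fix it and minimize enzyme usage.  Yields are
    g/g using the supplied molar masses (g/mmol).

    Returns a DataFrame with columns ``growth_fraction``, ``growth_rate``,
    ``biomass_yield``, ``product_rate``, ``product_yield``.
    """
    if n_points < 2:
        raise ValidationError("need at least 2 envelope points")
    growth = growth_reaction or ec.objective
    sense = _uptake_sense(ec, substrate_exchange)
    base = ec.copy()
    sub_rxn = base.get_reaction(substrate_exchange)
    if substrate_uptake is None:
        substrate_uptake = sub_rxn.upper_bound if sense > 0 else -sub_rxn.lower_bound
    if not math.isfinite(substrate_uptake):
        raise ValidationError("substrate uptake must be finite for yields")
    if sense > 0:
        sub_rxn.lower_bound = sub_rxn.upper_bound = substrate_uptake
    else:
        sub_rxn.lower_bound = sub_rxn.upper_bound = -substrate_uptake

    mu_max_res = fba(base, objective=growth, direction="max")
    if not mu_max_res.optimal:
        raise ValidationError(f"envelope base problem {mu_max_res.status}")
    mu_max = mu_max_res.objective_value
    sub_mass = substrate_uptake * substrate_mw  # g substrate/gDW/h

    rows = []
    for frac in np.linspace(0.0, 1.0, n_points):
        mu = frac * mu_max
        cm = _prepare(base)
        _fix(cm, growth, mu)
        cm.objective = product_exchange
        cm.objective_direction = "max"
        s1 = _optimize(cm)
        if s1.status != "optimal":
            rows.append((frac, mu, mu / sub_mass if sub_mass else 0.0, 0.0, 0.0))
            continue
        vp = float(s1.fluxes[product_exchange])
        _fix(cm, product_exchange, vp)
        try:
            cm.objective = _mass_expression(ec, cm)
            cm.objective_direction = "min"
            _optimize(cm)
        except ValidationError:
            pass  # no enzymes in model: envelope still well defined
        rows.append(
            (
                frac,
                mu,
                mu / sub_mass if sub_mass else 0.0,
                vp,
                vp * product_mw / sub_mass if sub_mass else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "growth_fraction",
            "growth_rate",
            "biomass_yield",
            "product_rate",
            "product_yield",
        ],
    )


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 0.0,
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction flux variability at a fraction of the optimum.

    Returns a DataFrame indexed by reaction id with ``minimum`` and
    ``maximum`` columns (mmol/gDW/h).
    """
    cm = _prepare(model)
    rxns = list(reactions) if reactions is not None else None
    return flux_variability_analysis(
        cm, reaction_list=rxns, fraction_of_optimum=fraction_of_optimum
    )


def fva_compare(
    original: MetabolicModel,
    ec: ECModel,
    fraction_of_optimum: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Compare flux variability before and after enzyme constraints.

    The original model is converted to irreversible format first so both
    models are compared on the same per-direction reaction set; each
    original reaction maps to its arm reaction in the expanded model when
    isozymes split it, otherwise to the same id.

    Returns the per-reaction table (original and constrained ranges, their
    difference) and a summary with the fractions of reactions whose
    variability was reduced / unchanged / increased.
    """
    irrev = split_reversible(original)
    fva_orig = fva(irrev, fraction_of_optimum)
    ec_ids = {r.id for r in ec.reactions}
    mapping = {}
    for r in irrev.reactions:
        if f"arm_{r.id}" in ec_ids:
            mapping[r.id] = f"arm_{r.id}"
        elif r.id in ec_ids:
            mapping[r.id] = r.id
    fva_ec = fva(ec, fraction_of_optimum, reactions=sorted(set(mapping.values())))

    rows = []
    for rid, ec_rid in mapping.items():
        o_min, o_max = fva_orig.loc[rid, ["minimum", "maximum"]]
        e_min, e_max = fva_ec.loc[ec_rid, ["minimum", "maximum"]]
        rows.append(
            {
                "reaction_id": rid,
                "ec_reaction_id": ec_rid,
                "min_original": o_min,
                "max_original": o_max,
                "min_ec": e_min,
                "max_ec": e_max,
                "range_original": o_max - o_min,
                "range_ec": e_max - e_min,
                "reduction": (o_max - o_min) - (e_max - e_min),
            }
        )
    table = pd.DataFrame(rows).set_index("reaction_id")
    tol = 1e-9
    n = len(table)
    summary = {
        "n_reactions": float(n),
        "fraction_reduced": float((table["reduction"] > tol).sum()) / n,
        "fraction_equal": float((table["reduction"].abs() <= tol).sum()) / n,
        "fraction_increased": float((table["reduction"] < -tol).sum()) / n,
    }
    return table, summary


def flux_control_coefficients(
    ec: ECModel,
    target_reaction: str,
    delta: float = 1e-3,
    recipe: Callable[[ECModel], SimResult] | None = None,
) -> list[FluxControlCoefficient]:
    """Flux control coefficient of every enzyme on a target flux.

    Each enzyme's kcats (in all its reactions) are scaled by (1 + delta),
    the recipe re-run, and FCC_i = ((v' - v)/v) / delta.  The default
    recipe is growth-maximizing FBA.  When the enzyme pool is the unique
    binding constraint the coefficients sum to ~1 (homogeneity of the LP).
    """
    run = recipe or (lambda m: fba(m))
    base = run(ec)
    if not base.optimal:
        raise ValidationError(f"base problem is {base.status}")
    v0 = base.fluxes.get(target_reaction)
    if v0 is None:
        raise ValidationError(f"unknown target reaction {target_reaction}")
    if v0 == 0:
        raise ValidationError(
            f"target {target_reaction} carries zero flux at the optimum; "
            f"pick a target with nonzero flux"
        )
    out = []
    catalysts = sorted({pid for _, pid in ec.kcats_per_h})
    for pid in catalysts:
        perturbed = scale_enzyme_kcats(ec, pid, 1.0 + delta)
        res = run(perturbed)
        if not res.optimal:
            raise ValidationError(
                f"perturbed problem for {pid} is {res.status}"
            )
        v1 = res.fluxes[target_reaction]
        out.append(FluxControlCoefficient(pid, ((v1 - v0) / v0) / delta, delta))
    return out


def fit_sigma(
    ec: ECModel,
    target: float,
    observable: Callable[[ECModel], float] | None = None,
    bracket: tuple[float, float] = (1e-9, 1.0),
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, list[tuple[float, float]]]:
    """Fit the average saturation sigma by bisection.

    ``observable(model)`` must be monotone increasing in sigma (growth
    under a binding pool constraint is); the default observable is the FBA
    optimum of the model objective.  Converges to
    |observable - target| <= tol; raises if the target exceeds the value
    attainable at sigma = 1.  Returns (sigma, trace of (sigma, value)).
    """
    if ec.pool is None:
        raise ValidationError("fit_sigma requires a pool-constrained model")
    cfg = ec.pool

    def evaluate(sigma: float) -> float:
        m = ec.copy()
        pool_rxn = m.get_reaction(ECModel.POOL_RXN)
        pool_rxn.upper_bound = sigma * cfg.f * cfg.p_total
        if observable is not None:
            return observable(m)
        res = fba(m)
        if not res.optimal:
            raise ValidationError(f"model {res.status} at sigma={sigma:g}")
        return res.objective_value

    trace: list[tuple[float, float]] = []
    lo, hi = bracket
    v_hi = evaluate(hi)
    trace.append((hi, v_hi))
    if v_hi < target - tol:
        raise ValidationError(
            f"target {target:g} unreachable: maximum attainable at "
            f"sigma={hi:g} is {v_hi:g}"
        )
    v_lo = evaluate(lo)
    trace.append((lo, v_lo))
    if v_lo >= target - tol:
        # target at or below the lower boundary (e.g. target 0)
        return lo, trace
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v_mid = evaluate(mid)
        trace.append((mid, v_mid))
        if abs(v_mid - target) <= tol:
            return mid, trace
        if v_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), trace
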