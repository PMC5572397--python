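"""Pool, proteomics and maintenance constraints."""

import pytest

from enzgem import (
    EnzymeInfo,
    MetabolicModel,
    Metabolite,
    PoolConfig,
    ProteomicsSet,
    Reaction,
    ValidationError,
    add_pool,
    apply_maintenance,
    correct_complex_abundances,
    fba,
    hybrid_constraints,
    proteomics_mass_report,
    set_proteomics_bounds,
)
from enzgem.expansion import expand_model
from enzgem.kinetics import assign_kcats
from enzgem.model import ECModel, KineticRecord


def _single_enzyme_ec(mw=5.0, kcat_h=1.0):
    """A -> B, one enzyme of given MW, kcat_h 1/h, uptake unbounded."""
    model = MetabolicModel(
        id="single",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 1e9),
            Reaction("R", {"A": -1, "B": 1}, 0, 1e9, gene_rule="G"),
            Reaction("OUT", {"B": -1}, 0, 1e9),
        ],
        objective="OUT",
    )
    enzymes = [EnzymeInfo("P", "G", mw, ("1.1.1.1",))]
    table = [KineticRecord("1.1.1.1", "A", "org", kcat_h / 3600.0)]
    asg = assign_kcats(model, enzymes, table, "org")
    return expand_model(model, enzymes, asg)


class TestPool:
    def test_config_contracts(self):
        with pytest.raises(ValidationError):
            PoolConfig(p_total=0.0)
        with pytest.raises(ValidationError):
            PoolConfig(p_total=1.0, f=1.5)
        with pytest.raises(ValidationError):
            PoolConfig(p_total=1.0, sigma=0.0)
        assert PoolConfig(0.448, 0.4461, 0.51).bound == pytest.approx(
            0.51 * 0.4461 * 0.448
        )

    def test_single_enzyme_max_usage(self):
        """sigma=1, f=1, P_total=10, MW 5 => at most 2 mmol/gDW of enzyme."""
        ec = _single_enzyme_ec(mw=5.0, kcat_h=1.0)
        pooled = add_pool(ec, PoolConfig(p_total=10.0))
        res = fba(pooled)
        assert res.usages["P"] == pytest.approx(2.0, rel=1e-9)
        assert res.objective_value == pytest.approx(2.0, rel=1e-9)  # kcat_h=1

    def test_pool_mass_balance_at_optimum(self, toy_ec):
        cfg = PoolConfig(p_total=0.1)
        pooled = add_pool(toy_ec, cfg)
        res = fba(pooled)
        mass = sum(
            pooled.enzymes[p].mw_kda * u for p, u in res.usages.items()
        )
        assert mass <= cfg.bound + 1e-9
        # the pool binds here (uptake alone would allow growth 10)
        assert mass == pytest.approx(cfg.bound, rel=1e-6)
        assert res.pool_usage == pytest.approx(mass, rel=1e-9)

    def test_sigma_scaling_is_linear_when_pool_binds(self, toy_ec):
        base = fba(add_pool(toy_ec, PoolConfig(0.1, sigma=0.5)))
        double = fba(add_pool(toy_ec, PoolConfig(0.1, sigma=1.0)))
        assert double.objective_value >= base.objective_value - 1e-12
        assert double.objective_value == pytest.approx(
            2 * base.objective_value, rel=1e-9
        )

    def test_empty_scope_warns_and_noops(self, toy_ec):
        with pytest.warns(UserWarning, match="empty pool scope"):
            out = add_pool(toy_ec, PoolConfig(1.0), scope=set())
        assert all(m.id != ECModel.POOL_MET for m in out.metabolites)

    def test_scope_outside_model_rejected(self, toy_ec):
        with pytest.raises(ValidationError):
            add_pool(toy_ec, PoolConfig(1.0), scope={"NOT_A_PROTEIN"})


class TestProteomicsBounds:
    def test_bound_is_mean_plus_sd(self, toy_ec):
        ps = ProteomicsSet(
            {"P2A": (1.5e-6, 2.0e-6, 2.5e-6)}, total_protein=0.448,
            n_replicates=3,
        )
        constrained, matched, unmeasured = set_proteomics_bounds(toy_ec, ps)
        bound = constrained.get_reaction("draw_prot_P2A").upper_bound
        assert bound == pytest.approx(2.0e-6 + ps.sd["P2A"])
        assert matched == pytest.approx(50.0 * 2.0e-6)
        assert unmeasured == {"P1", "P2B", "P3A", "P3B"}

    def test_zero_abundance_is_knockout_like(self, toy_ec):
        ps = ProteomicsSet(
            {"P1": (0.0, 0.0, 0.0)}, total_protein=0.448, n_replicates=3
        )
        constrained, _, _ = set_proteomics_bounds(toy_ec, ps)
        assert constrained.get_reaction("draw_prot_P1").upper_bound == 0.0
        res = fba(constrained)
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_no_overlap_warns(self, toy_ec):
        ps = ProteomicsSet(
            {"NOT_IN_MODEL": (1e-6, 1e-6)}, total_protein=0.4, n_replicates=2
        )
        with pytest.warns(UserWarning, match="no proteomics measurement"):
            set_proteomics_bounds(toy_ec, ps)


class TestMassReport:
    def test_measured_unmeasured_split(self):
        report = proteomics_mass_report(
            p_total=0.448, matched_mass=0.283, f_unmeasured=0.2154, sigma=0.46
        )
        assert report.remaining_mass == pytest.approx(0.165)
        assert round(report.pool_mass, 3) == 0.036
        # 88.7% when computed from the rounded pool mass 0.036; full
        # precision gives 88.84%, so allow the rounding granularity
        assert 100 * report.matched_fraction == pytest.approx(88.7, abs=0.2)
        assert report.pool_bound == pytest.approx(0.46 * 0.2154 * 0.165)

    def test_matched_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            proteomics_mass_report(0.448, 0.5, 0.2)


class TestHybrid:
    def test_empty_proteomics_equals_pool(self, toy_ec):
        ps = ProteomicsSet({}, total_protein=0.1, n_replicates=3)
        with pytest.warns(UserWarning):
            hybrid, report = hybrid_constraints(toy_ec, ps, 0.1, 1.0, 1.0)
        pooled = add_pool(toy_ec, PoolConfig(0.1))
        assert fba(hybrid).objective_value == pytest.approx(
            fba(pooled).objective_value, rel=1e-9
        )
        assert report.matched_mass == 0.0

    def test_full_coverage_adds_no_pool(self, toy_ec):
        ps = ProteomicsSet(
            {p: (1e-5, 1e-5) for p in ("P1", "P2A", "P2B", "P3A", "P3B")},
            total_protein=0.448,
            n_replicates=2,
        )
        hybrid, _ = hybrid_constraints(toy_ec, ps, 0.448, 0.2154, 0.46)
        assert all(m.id != ECModel.POOL_MET for m in hybrid.metabolites)
        direct, _, _ = set_proteomics_bounds(toy_ec, ps)
        assert fba(hybrid).objective_value == pytest.approx(
            fba(direct).objective_value, rel=1e-9
        )

    def test_partial_coverage_pools_the_rest(self, toy_ec):
        ps = ProteomicsSet(
            {"P1": (1e-4, 1e-4)}, total_protein=0.1, n_replicates=2
        )
        hybrid, report = hybrid_constraints(toy_ec, ps, 0.1, 0.5, 1.0)
        pool_rxn = hybrid.get_reaction(ECModel.POOL_RXN)
        assert pool_rxn.upper_bound == pytest.approx(report.pool_bound)
        # measured enzyme keeps its direct bound, no pool coupling
        draw_p1 = hybrid.get_reaction("draw_prot_P1")
        assert ECModel.POOL_MET not in draw_p1.stoichiometry
        assert draw_p1.upper_bound == pytest.approx(1e-4)
        # unmeasured enzymes draw from the pool
        draw_p2a = hybrid.get_reaction("draw_prot_P2A")
        assert draw_p2a.stoichiometry[ECModel.POOL_MET] == pytest.approx(-50.0)


class TestComplexCorrection:
    E = [
        EnzymeInfo("PA", "GA", 10.0, (), complex_id="CPX", stoichiometry=1.0),
        EnzymeInfo("PB", "GB", 10.0, (), complex_id="CPX", stoichiometry=1.0),
    ]

    def test_equal_stoichiometry_averaged(self):
        ps = ProteomicsSet(
            {"PA": (2e-6, 2e-6), "PB": (4e-6, 4e-6)},
            total_protein=0.4, n_replicates=2,
        )
        out = correct_complex_abundances(ps, self.E, {"CPX"})
        assert out.mean["PA"] == pytest.approx(3e-6)
        assert out.mean["PB"] == pytest.approx(3e-6)

    def test_proportional_abundances_unchanged(self):
        enzymes = [
            EnzymeInfo("PA", "GA", 10.0, (), complex_id="CPX", stoichiometry=1.0),
            EnzymeInfo("PB", "GB", 10.0, (), complex_id="CPX", stoichiometry=2.0),
        ]
        ps = ProteomicsSet(
            {"PA": (3e-6, 3e-6), "PB": (6e-6, 6e-6)},
            total_protein=0.4, n_replicates=2,
        )
        out = correct_complex_abundances(ps, enzymes, {"CPX"})
        assert out.mean["PA"] == pytest.approx(3e-6)
        assert out.mean["PB"] == pytest.approx(6e-6)

    def test_single_subunit_identity(self):
        enzymes = [EnzymeInfo("PA", "GA", 10.0, (), complex_id="CPX")]
        ps = ProteomicsSet(
            {"PA": (2e-6, 2e-6)}, total_protein=0.4, n_replicates=2
        )
        out = correct_complex_abundances(ps, enzymes, {"CPX"})
        assert out.mean["PA"] == pytest.approx(2e-6)

    def test_sd_scaled_with_mean(self):
        ps = ProteomicsSet(
            {"PA": (1e-6, 3e-6), "PB": (4e-6, 4e-6)},
            total_protein=0.4, n_replicates=2,
        )
        out = correct_complex_abundances(ps, self.E, {"CPX"})
        factor = out.mean["PA"] / ps.mean["PA"]
        assert out.sd["PA"] == pytest.approx(ps.sd["PA"] * factor)

    def test_unmeasured_complex_warns(self):
        ps = ProteomicsSet({}, total_protein=0.4, n_replicates=2)
        with pytest.warns(UserWarning, match="no measured subunit"):
            correct_complex_abundances(ps, self.E, {"CPX"})


class TestMaintenance:
    def _model(self):
        return MetabolicModel(
            id="m",
            metabolites=[
                Metabolite("glc"), Metabolite("atp", name="ATP"),
                Metabolite("adp", name="ADP"), Metabolite("pi", name="Pi"),
                Metabolite("h2o", name="H2O"), Metabolite("bio"),
            ],
            reactions=[
                Reaction("EX_glc", {"glc": 1}, 0, 10),
                Reaction("ENERGY", {"glc": -1, "atp": 20, "adp": -20}, 0, 1000),
                Reaction("WATER", {"h2o": 1}, 0, 1000),
                Reaction(
                    "BIOMASS",
                    {"glc": -1, "atp": -25, "h2o": -25, "adp": 25, "pi": 25,
                     "bio": 1},
                    0, 1000,
                ),
                Reaction("NGAM", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1},
                         0, 1000),
                Reaction("EX_pi", {"pi": -1}, 0, 1000),
                Reaction("EX_bio", {"bio": -1}, 0, 1000),
            ],
            objective="EX_bio",
        )

    def test_gam_coefficients_replaced(self):
        out = apply_maintenance(self._model(), gam=31.0, ngam=0.7,
                                biomass_reaction="BIOMASS")
        bio = out.get_reaction("BIOMASS")
        assert bio.stoichiometry["atp"] == -31.0
        assert bio.stoichiometry["adp"] == 31.0
        assert bio.stoichiometry["pi"] == 31.0
        assert bio.stoichiometry["glc"] == -1.0  # non-energy terms untouched
        assert out.get_reaction("NGAM").lower_bound == 0.7

    def test_growth_monotone_in_ngam(self):
        mus = []
        for ngam in (0.0, 5.0, 50.0):
            m = apply_maintenance(self._model(), gam=16.0, ngam=ngam,
                                  biomass_reaction="BIOMASS")
            mus.append(fba(m).objective_value)
        assert mus[0] >= mus[1] >= mus[2]
        assert mus[0] > mus[2]

    def test_missing_atp_term_rejected(self):
        model = self._model()
        del model.get_reaction("BIOMASS").stoichiometry["atp"]
        with pytest.raises(ValidationError, match="ATP"):
            apply_maintenance(model, 31.0, 0.7, biomass_reaction="BIOMASS")

    def test_missing_ngam_reaction_rejected(self):
        with pytest.raises(ValidationError, match="NOPE"):
            apply_maintenance(self._model(), 31.0, 0.7,
                              biomass_reaction="BIOMASS",
                              ngam_reaction="NOPE")
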