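"""Simulation recipes: FBA, parsimonious enzyme use, chemostat/batch,
knockouts, envelopes, FVA, flux control coefficients, saturation fitting."""

import math

import numpy as np
import pytest

from enzgem import (
    ValidationError,
    batch,
    chemostat,
    fba,
    fit_sigma,
    flux_control_coefficients,
    fva,
    fva_compare,
    knockout,
    minimize_enzyme_usage,
    scale_enzyme_kcats,
    yield_envelope,
)

GDW_PER_MMOL_SUB = 0.18  # nominal substrate molar mass, g/mmol


def _bounded(toy_ec, **bounds):
    m = toy_ec.copy()
    for pid, ub in bounds.items():
        m.get_reaction(f"draw_prot_{pid}").upper_bound = ub
    return m


class TestFBA:
    def test_uptake_limited_growth(self, toy_ec):
        res = fba(toy_ec)
        assert res.optimal
        assert res.objective_value == pytest.approx(10.0, rel=1e-9)

    def test_enzyme_limited_growth(self, toy_ec):
        m = _bounded(toy_ec, P2A=5e-5, P2B=0.0)
        res = fba(m)
        # capacity law: v = kcat_h * e = 72000 * 5e-5 = 3.6
        assert res.objective_value == pytest.approx(3.6, rel=1e-9)

    def test_blocked_path_gives_zero(self, toy_ec):
        m = _bounded(toy_ec, P1=0.0)
        assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported_not_raised(self, toy_ec):
        m = toy_ec.copy()
        m.get_reaction("GROWTH").lower_bound = 50.0  # beyond uptake limit
        res = fba(m)
        assert not res.optimal
        assert res.objective_value is None


class TestMinimizeEnzymeUsage:
    def test_picks_cheaper_isozyme(self, toy_ec):
        res = minimize_enzyme_usage(toy_ec, fixed=[("GROWTH", 3.6)])
        # per unit flux: P2A costs 50/72000, P2B costs 60/14400 g h/mmol
        assert res.fluxes["R2No1"] == pytest.approx(3.6, rel=1e-5)
        assert res.fluxes["R2No2"] == pytest.approx(0.0, abs=1e-9)
        expected_mass = 3.6 * (40 / 36000 + 50 / 72000 + 30 / 7200 + 2 * 20 / 7200)
        assert res.objective_value == pytest.approx(expected_mass, rel=1e-4)

    def test_nothing_fixed_gives_zero(self, toy_ec):
        res = minimize_enzyme_usage(toy_ec)
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_isozymes_unique_objective(self, toy_ec):
        # make both isozymes identical in MW/kcat cost: objective unique
        m = toy_ec.copy()
        row = "prot_P2B"
        m.get_reaction("R2No2").stoichiometry[row] = -1 / 72000
        m.enzymes = dict(m.enzymes)
        from enzgem.model import EnzymeInfo

        m.enzymes["P2B"] = EnzymeInfo("P2B", "G2B", 50.0, ("2.7.1.2",))
        m.kcats_per_h[("R2No2", "P2B")] = 72000.0
        v1 = minimize_enzyme_usage(m, fixed=[("GROWTH", 3.6)]).objective_value
        v2 = minimize_enzyme_usage(m, fixed=[("GROWTH", 3.6)]).objective_value
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestChemostat:
    def test_low_dilution_respires_only(self, overflow):
        ec = overflow(uptake=1000.0)  # substrate in excess; D decides
        res = chemostat(ec, dilution_rate=5.0, substrate_exchange="EX_S")
        assert res.optimal
        # ATP 5 is cheapest via respiration: uptake 0.5, no byproduct
        # (tolerance covers the documented 1e-6 stage-fixing slack)
        assert res.fluxes["EX_S"] == pytest.approx(0.5, rel=5e-6)
        assert res.fluxes["EX_BYP"] == pytest.approx(0.0, abs=1e-5)

    def test_high_dilution_ferments(self, overflow):
        ec = overflow(uptake=1000.0)
        # D=15 needs mixed strategy: respiration alone caps at pool/cost
        # 10 ATP per unit at cost 10 => max 10; fermentation must kick in
        res = chemostat(ec, dilution_rate=15.0, substrate_exchange="EX_S")
        assert res.optimal
        assert res.fluxes["EX_BYP"] > 1e-6

    def test_above_mu_max_infeasible(self, overflow):
        ec = overflow(uptake=1000.0)
        res = chemostat(ec, dilution_rate=25.0, substrate_exchange="EX_S")
        assert not res.optimal

    def test_zero_dilution_all_zero(self, overflow):
        ec = overflow(uptake=1000.0)
        res = chemostat(ec, dilution_rate=0.0, substrate_exchange="EX_S")
        assert res.optimal
        assert all(abs(v) <= 1e-6 for v in res.fluxes.values())


class TestBatch:
    def test_growth_set_by_pool(self, overflow):
        ec = overflow(uptake=1000.0)
        res = batch(ec, medium={"EX_S": math.inf})
        # fermentation-only allocation: 2 ATP per unit cost 1, pool 10 => 20
        assert res.objective_value == pytest.approx(20.0, rel=1e-6)

    def test_doubling_pool_doubles_growth(self, overflow):
        mu1 = batch(overflow(1000.0, pool_bound=10.0),
                    medium={"EX_S": math.inf}).objective_value
        mu2 = batch(overflow(1000.0, pool_bound=20.0),
                    medium={"EX_S": math.inf}).objective_value
        assert mu2 == pytest.approx(2 * mu1, rel=1e-6)

    def test_empty_medium_no_growth(self, overflow):
        ec = overflow(uptake=1000.0)
        res = batch(ec, medium={"EX_S": 0.0})
        assert res.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_without_pool_flagged_unbounded(self, toy_ec):
        m = toy_ec.copy()
        for r in m.reactions:  # lift the nominal flux caps everywhere
            if r.upper_bound >= 1000.0 or math.isinf(r.upper_bound):
                r.upper_bound = math.inf
        m.get_reaction("EX_A").upper_bound = math.inf
        res = batch(m, medium={"EX_A": math.inf})
        assert not res.optimal
        assert "pool" in res.status


class TestKnockout:
    def test_essential_enzyme(self, toy_ec):
        m = knockout(toy_ec, ["P1"])
        assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_isozyme_rescue(self, toy_ec):
        m = knockout(toy_ec, ["P2B"])
        assert fba(m).objective_value == pytest.approx(10.0, rel=1e-9)

    def test_complex_subunit_blocks_reaction(self, toy_ec):
        m = knockout(toy_ec, ["P3A"])
        res = fba(m)
        assert res.fluxes["R3"] == pytest.approx(0.0, abs=1e-9)
        # the promiscuous route R4 still reaches D
        assert res.objective_value > 0

    def test_unknown_id_rejected(self, toy_ec):
        with pytest.raises(ValidationError, match="NOPE"):
            knockout(toy_ec, ["NOPE"])


class TestYieldEnvelope:
    def test_corner_points(self, overflow):
        from enzgem.model import Reaction

        ec = overflow(uptake=2.0)
        # an ATP-dissipation sink (maintenance-like) so byproduct can be
        # made without growth
        ec.reactions.append(Reaction("ATPASE", {"ATP": -1.0}, 0.0, math.inf))
        table = yield_envelope(
            ec, "EX_BYP", "EX_S", n_points=2,
            product_mw=0.046, substrate_mw=GDW_PER_MMOL_SUB,
        )
        assert len(table) == 2
        assert table["growth_fraction"].tolist() == [0.0, 1.0]
        # at zero growth everything can ferment: byproduct = uptake
        assert table["product_rate"].iloc[0] == pytest.approx(2.0, rel=1e-5)

    def test_ec_envelope_inside_original(self, toy_ec, toy_bundle):
        model, _, _ = toy_bundle
        limited = _bounded(toy_ec, P2A=5e-5)
        for frac_table, ref_table in [(limited, toy_ec)]:
            env_limited = yield_envelope(
                frac_table, "GROWTH", "EX_A", 5, 0.1, 0.18
            )
            env_free = yield_envelope(ref_table, "GROWTH", "EX_A", 5, 0.1, 0.18)
            # pointwise: constrained max product never exceeds unconstrained
            for lim, free in zip(env_limited["product_rate"],
                                 env_free["product_rate"]):
                assert lim <= free + 1e-6

    def test_too_few_points_rejected(self, toy_ec):
        with pytest.raises(ValidationError):
            yield_envelope(toy_ec, "GROWTH", "EX_A", 1, 0.1, 0.18)


class TestFVA:
    def test_ec_ranges_within_original(self, toy_bundle, toy_ec):
        model, _, _ = toy_bundle
        table, summary = fva_compare(model, toy_ec, fraction_of_optimum=0.0)
        assert (table["min_ec"] >= table["min_original"] - 1e-9).all()
        assert (table["max_ec"] <= table["max_original"] + 1e-9).all()
        assert summary["fraction_increased"] == 0.0

    def test_fixed_reaction_zero_range(self, toy_ec):
        m = toy_ec.copy()
        m.get_reaction("R4").lower_bound = 0.0
        m.get_reaction("R4").upper_bound = 0.0
        table = fva(m, reactions=["R4"])
        assert table.loc["R4", "minimum"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["R4", "maximum"] == pytest.approx(0.0, abs=1e-9)

    def test_enzyme_block_zeroes_range(self, toy_bundle, toy_ec):
        model, _, _ = toy_bundle
        # blocking one isozyme zeroes its copy's range only
        m = _bounded(toy_ec, P2B=0.0)
        copy_range = fva(m, reactions=["R2No2"])
        assert copy_range.loc["R2No2", "maximum"] == pytest.approx(0, abs=1e-9)
        # blocking both isozymes zeroes the whole arm while the original
        # model keeps full variability on R2
        both = _bounded(toy_ec, P2A=0.0, P2B=0.0)
        table, _ = fva_compare(model, both)
        assert table.loc["R2", "range_ec"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["R2", "range_original"] > 1.0


class TestFCC:
    def test_sums_to_one_under_pool_limitation(self, overflow):
        ec = overflow(uptake=1e6)
        fccs = flux_control_coefficients(ec, "GROWTH", delta=1e-3)
        total = sum(f.fcc for f in fccs)
        assert total == pytest.approx(1.0, abs=2e-3)

    def test_inactive_enzyme_has_zero_control(self, overflow):
        ec = overflow(uptake=1e6)  # pure fermentation optimum
        fccs = {f.enzyme_id: f.fcc for f in
                flux_control_coefficients(ec, "GROWTH", delta=1e-3)}
        assert fccs["E_RESP"] == pytest.approx(0.0, abs=1e-9)
        assert fccs["E_FERM"] == pytest.approx(1.0, abs=2e-3)

    def test_local_linearity_in_delta(self, overflow):
        ec = overflow(uptake=1e6)
        f1 = {f.enzyme_id: f.fcc for f in
              flux_control_coefficients(ec, "GROWTH", delta=1e-3)}
        f2 = {f.enzyme_id: f.fcc for f in
              flux_control_coefficients(ec, "GROWTH", delta=2e-3)}
        for pid in f1:
            assert abs(f1[pid] - f2[pid]) < 1e-2

    def test_zero_flux_target_rejected(self, overflow):
        ec = overflow(uptake=1.0)  # pure respiration: no byproduct flux
        with pytest.raises(ValidationError, match="zero flux"):
            flux_control_coefficients(ec, "EX_BYP")

    def test_scale_enzyme_kcats_contract(self, toy_ec):
        scaled = scale_enzyme_kcats(toy_ec, "P2A", 2.0)
        assert scaled.kcats_per_h[("R2No1", "P2A")] == pytest.approx(144000.0)
        assert scaled.kcats_per_h[("R4", "P2A")] == pytest.approx(7200.0)
        # other enzymes untouched
        assert scaled.kcats_per_h[("R3", "P3A")] == toy_ec.kcats_per_h[
            ("R3", "P3A")
        ]
        with pytest.raises(ValidationError):
            scale_enzyme_kcats(toy_ec, "P2A", 0.0)


class TestFitSigma:
    def test_recovers_half_saturation_exactly(self, overflow):
        ec = overflow(uptake=1e6)
        mu_max = fba(ec).objective_value
        sigma, trace = fit_sigma(ec, target=mu_max / 2)
        # growth is exactly linear in sigma here (pool sole constraint)
        assert sigma == pytest.approx(0.5, abs=1e-4)
        assert len(trace) >= 2

    def test_unreachable_target_reports_maximum(self, overflow):
        ec = overflow(uptake=1e6)
        mu_max = fba(ec).objective_value
        with pytest.raises(ValidationError, match="unreachable"):
            fit_sigma(ec, target=2 * mu_max)

    def test_zero_target_hits_lower_boundary(self, overflow):
        ec = overflow(uptake=1e6)
        sigma, _ = fit_sigma(ec, target=0.0)
        assert sigma == pytest.approx(0.0, abs=1e-6)

    def test_requires_pool(self, toy_ec):
        with pytest.raises(ValidationError, match="pool"):
            fit_sigma(toy_ec, target=1.0)


class TestAntiMonotonicity:
    def test_constraining_never_raises_growth(self, toy_ec):
        """Tightening any usage bound can only lower the optimum."""
        rng = np.random.default_rng(7)
        base = fba(toy_ec).objective_value
        for _ in range(10):
            m = toy_ec.copy()
            for rid in m.usage_rxn_ids():
                m.get_reaction(rid).upper_bound = float(
                    rng.uniform(0, 2e-4)
                )
            res = fba(m)
            assert res.optimal
            assert res.objective_value <= base + 1e-9
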