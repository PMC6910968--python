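"""Capital scaling, NPV, annuity identity and MSP root-finding."""

import numpy as np
import pytest

from bioassess.tea import (
    CapitalCostSpec,
    CashflowModel,
    TEAError,
    annualize_capital,
    minimum_selling_price,
    npv,
    scale_capital,
)


class TestScaleCapital:
    def test_exponent_one_equal_indices_is_linear(self):
        spec = CapitalCostSpec(100.0, 10.0, 30.0, scaling_exponent=1.0)
        assert scale_capital(spec) == pytest.approx(300.0)

    def test_equal_capacities_pure_index_ratio(self):
        spec = CapitalCostSpec(100.0, 10.0, 10.0, index_base=500.0, index_target=600.0)
        assert scale_capital(spec) == pytest.approx(120.0)

    def test_biorefinery_power_law_hand_value(self):
        # $149M at 33 kt scaled to 100 kt with exponent 0.836
        spec = CapitalCostSpec(149e6, 33.0, 100.0, scaling_exponent=0.836)
        assert scale_capital(spec) == pytest.approx(149e6 * (100 / 33) ** 0.836,
                                                    rel=1e-12)
        assert scale_capital(spec) / 1e6 == pytest.approx(376.45, abs=0.01)

    def test_fermenter_ratio_uses_same_exponent(self):
        spec = CapitalCostSpec(100.0, 10.0, 10.0)
        assert scale_capital(spec, fermenter_ratio=2.0) == pytest.approx(
            100.0 * 2 ** 0.836)

    def test_invalid_capacity_rejected(self):
        with pytest.raises(TEAError):
            CapitalCostSpec(100.0, 0.0, 10.0)


class TestNPV:
    def test_zero_rate_is_plain_sum(self):
        assert npv([1.0, 2.0, 3.0], 0.0) == pytest.approx(6.0)

    def test_single_deferred_cashflow(self):
        assert npv([0.0, 110.0], 0.10) == pytest.approx(100.0)

    def test_breakeven_project(self):
        assert npv([-100.0, 110.0], 0.10) == pytest.approx(0.0, abs=1e-12)

    def test_rate_floor(self):
        with pytest.raises(TEAError):
            npv([1.0], -1.5)


class TestAnnuity:
    def test_zero_rate_limit(self):
        assert annualize_capital(1000.0, 0.0, 10) == pytest.approx(100.0)

    def test_hand_value(self):
        assert annualize_capital(1000.0, 0.10, 10) == pytest.approx(162.745, abs=1e-3)

    def test_identity_over_random_rates_and_lifespans(self, rng):
        # discounted charge stream repays the capital to 1e-9 relative
        for _ in range(1000):
            capital = rng.uniform(1e5, 1e9)
            r = rng.uniform(0.01, 0.30)
            n = int(rng.integers(1, 41))
            a = annualize_capital(capital, r, n)
            pv = sum(a / (1 + r) ** t for t in range(1, n + 1))
            assert abs(pv - capital) / capital < 1e-9


def random_cashflow_model(rng) -> CashflowModel:
    return CashflowModel(
        annual_output_kg=rng.uniform(1e6, 2e8),
        variable_opex=rng.uniform(0.2, 5.0),
        fixed_opex=rng.uniform(0.0, 5e7),
        capital=rng.uniform(0.0, 1e9),
        lifespan=int(rng.integers(5, 31)),
        discount_rate=rng.uniform(0.10, 0.24),
        construction_profile=(0.5, 0.5),
    )


def bisect_msp(model: CashflowModel, lo=0.0, hi=100.0, tol=1e-7) -> float:
    """Brute-force bisection oracle, independent of the solver under test."""
    while model.npv_at_price(hi) < 0:
        hi *= 2
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if model.npv_at_price(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestMSP:
    def test_breakeven_limit_no_capital_zero_rate(self):
        m = CashflowModel(annual_output_kg=1e6, variable_opex=2.0,
                          fixed_opex=5e5, capital=0.0, lifespan=1,
                          discount_rate=0.0, construction_profile=())
        res = minimum_selling_price(m)
        assert res.msp == pytest.approx(2.5, rel=1e-9)

    def test_msp_matches_bisection_oracle(self, rng):
        for _ in range(1000):
            m = random_cashflow_model(rng)
            res = minimum_selling_price(m)
            assert abs(res.npv_at_msp) < 1.0
            assert res.msp == pytest.approx(bisect_msp(m), abs=1e-6)

    def test_monotone_in_discount_rate_and_capital(self, rng):
        base = random_cashflow_model(rng)
        rates = np.linspace(0.10, 0.24, 5)
        msps = []
        for r in rates:
            m = CashflowModel(**{**base.__dict__, "discount_rate": r,
                                 "opex_breakdown": {}})
            msps.append(minimum_selling_price(m).msp)
        assert all(a <= b + 1e-12 for a, b in zip(msps, msps[1:]))
        m_hi = CashflowModel(**{**base.__dict__, "capital": base.capital * 2 + 1e6,
                                "opex_breakdown": {}})
        assert minimum_selling_price(m_hi).msp >= msps[0] - 1e-9

    def test_breakdown_sums_to_msp(self, rng):
        for _ in range(50):
            m = random_cashflow_model(rng)
            res = minimum_selling_price(m)
            assert sum(res.cost_breakdown.values()) == pytest.approx(res.msp,
                                                                     rel=1e-6)

    def test_itemized_breakdown_preserved(self):
        m = CashflowModel(annual_output_kg=1e7, variable_opex=1.5, fixed_opex=1e6,
                          capital=1e8, lifespan=20, discount_rate=0.12,
                          opex_breakdown={"sugar": 1.0, "power": 0.5})
        res = minimum_selling_price(m)
        assert res.cost_breakdown["sugar"] == 1.0
        assert sum(res.cost_breakdown.values()) == pytest.approx(res.msp, rel=1e-6)
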