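import numpy as np
import pytest

from metafoot.cue import (CarbonPoolSample, carbon_fractions, cue_cumulative,
                          cue_eq1_literal, cue_instantaneous, cue_series,
                          nitrogen_budget, pools_from_arrays,
                          substrate_c_share)


def balanced_pools(cue: float, assim_course=(0.0, 10.0, 25.0, 45.0, 52.0),
                   toc: float = 183.1):
    """Exactly mass-balanced pool series with constant CUE."""
    times = [0.0, 17.0, 19.0, 22.0, 24.0]
    pools = []
    for t, a in zip(times, assim_course):
        filtered = toc - a
        biomass = cue * a
        pools.append(CarbonPoolSample(t, filtered + biomass, filtered))
    return pools


class TestLiteralRatio:
    def test_endpoint_values(self):
        # biomass 21.7 over an unfiltered-pool drop of 32.5
        pools = [CarbonPoolSample(0.0, 183.1, 183.1),
                 CarbonPoolSample(24.0, 150.6, 128.9)]
        with pytest.warns(UserWarning, match="respired"):
            assert cue_eq1_literal(pools, 1) == pytest.approx(0.668, abs=5e-4)

    def test_zero_biomass(self):
        pools = [CarbonPoolSample(0.0, 100.0, 100.0),
                 CarbonPoolSample(24.0, 90.0, 90.0)]
        with pytest.warns(UserWarning):
            assert cue_eq1_literal(pools, 1) == 0.0

    def test_zero_denominator_rejected(self):
        pools = [CarbonPoolSample(0.0, 100.0, 100.0),
                 CarbonPoolSample(24.0, 100.0, 80.0)]
        with pytest.warns(UserWarning), pytest.raises(ZeroDivisionError):
            cue_eq1_literal(pools, 1)

    def test_literal_equals_cue_over_one_minus_cue_when_balanced(self):
        """Under exact mass balance the literal ratio is biomass/respired
        = CUE/(1-CUE), strictly above the mass-balance CUE."""
        for cue in (0.2, 0.43, 0.6):
            pools = balanced_pools(cue)
            cum = cue_cumulative(pools, 4)
            with pytest.warns(UserWarning):
                lit = cue_eq1_literal(
                    [pools[0], pools[4]], 1)
            assert cum == pytest.approx(cue, abs=1e-12)
            assert lit == pytest.approx(cue / (1 - cue), rel=1e-12)
            assert lit > cum


class TestCumulative:
    def test_endpoint_values(self):
        pools = [CarbonPoolSample(0.0, 183.1, 183.1),
                 CarbonPoolSample(24.0, 152.99, 131.29)]
        # biomass 21.7 over assimilated 51.81
        assert cue_cumulative(pools, 1) == pytest.approx(0.419, abs=1e-3)

    def test_perfect_efficiency_bound(self):
        pools = [CarbonPoolSample(0.0, 100.0, 100.0),
                 CarbonPoolSample(24.0, 100.0, 80.0)]
        assert cue_cumulative(pools, 1) == pytest.approx(1.0)

    def test_non_positive_assimilation_rejected(self):
        pools = [CarbonPoolSample(0.0, 100.0, 100.0),
                 CarbonPoolSample(24.0, 101.0, 101.0)]
        with pytest.raises(ZeroDivisionError):
            cue_cumulative(pools, 1)


class TestInstantaneous:
    def test_steady_state_undefined(self):
        pools = balanced_pools(0.43, assim_course=(0, 10, 10, 10, 10))
        v, mid = cue_instantaneous(pools, 1, 2)
        assert np.isnan(v)
        assert mid == pytest.approx(18.0)

    def test_perfect_interval(self):
        pools = [CarbonPoolSample(0.0, 100.0, 100.0),
                 CarbonPoolSample(17.0, 100.0, 90.0)]
        v, _ = cue_instantaneous(pools, 0, 1)
        assert v == pytest.approx(1.0)

    def test_reported_at_midpoint(self):
        pools = balanced_pools(0.43)
        series = cue_series(pools)
        np.testing.assert_allclose(series.interval_midpoints,
                                   [8.5, 18.0, 20.5, 23.0])
        np.testing.assert_allclose(series.instantaneous, 0.43, atol=1e-12)
        np.testing.assert_allclose(series.cumulative, 0.43, atol=1e-12)


class TestBudgets:
    def test_carbon_fractions_printed_values(self):
        fr = carbon_fractions(183.1, 51.8, 32.5, biomass=21.7)
        assert fr["assimilated_pct_toc"] == 28.3
        assert fr["lost_pct_toc"] == 17.7
        assert fr["lost_pct_assimilated"] == pytest.approx(62.8, abs=0.15)
        assert fr["biomass_pct_assimilated"] == pytest.approx(41.9, abs=0.1)

    def test_carbon_fractions_zero(self):
        fr = carbon_fractions(100.0, 0.0, 0.0)
        assert fr["assimilated_pct_toc"] == 0.0
        assert fr["lost_pct_toc"] == 0.0

    def test_nitrogen_budget_residual(self):
        residual, flagged = nitrogen_budget(6.7, 4.05, 1.79)
        assert residual == pytest.approx(0.86, abs=1e-12)
        assert not flagged

    def test_nitrogen_budget_complete_attribution(self):
        residual, flagged = nitrogen_budget(4.0, 4.0, 0.0)
        assert residual == 0.0
        assert not flagged

    def test_nitrogen_budget_over_attribution_flagged(self):
        residual, flagged = nitrogen_budget(5.0, 4.0, 2.0)
        assert residual == pytest.approx(-1.0)
        assert flagged

    def test_substrate_share(self):
        assert substrate_c_share(0.0, 6, 51.8) == 0.0
        # depleted glucose: 134.82 uM x 6 C
        assert substrate_c_share(134.82, 6, 51.8) == pytest.approx(18.8,
                                                                   abs=0.1)

    def test_substrate_share_requires_positive_total(self):
        with pytest.raises(ValueError):
            substrate_c_share(1.0, 6, 0.0)


def test_pools_from_arrays_consistency():
    pools = pools_from_arrays([0, 17], [183.1, 160.0], [183.1, 150.0])
    assert pools[1].biomass_c == pytest.approx(10.0)
    assert pools[0].consistent and pools[1].consistent
    assert not CarbonPoolSample(0.0, 90.0, 100.0).consistent
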