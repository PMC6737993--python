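"""Forward-engine unit and property tests: uptake branches, yield
ranges, pairwise combination, and equivalence with an independent
transcription of the four steps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quefts.core import (
    NUTRIENTS,
    CropCoefficients,
    actual_uptake,
    pairwise_yield,
    ultimate_yield,
    yield_range,
)

from oracles import ultimate_yield_oracle, uptake_oracle


def coeff_arrays(bundle):
    c = bundle.coeffs
    return c.a, c.d, c.r


class TestCropCoefficients:
    def test_rejects_accumulation_above_dilution(self):
        with pytest.raises(ValueError, match="0 < a < d"):
            CropCoefficients(a=(80, 200, 25), d=(79, 527, 117), r=(4, 0.5, 4.5))

    def test_rejects_negative_minimum_uptake(self):
        with pytest.raises(ValueError):
            CropCoefficients(a=(35, 200, 25), d=(79, 527, 117), r=(-1, 0.5, 4.5))


class TestActualUptake:
    def test_supply_at_minimum_taken_up_entirely(self, ngs):
        # supply below the dilution-limited threshold: full uptake
        u = actual_uptake(4.0, 200.0, ngs.coeffs, "N", "P")
        assert u == 4.0

    def test_branch_boundary_continuity(self, ngs):
        c = ngs.coeffs
        sj = 30.0
        sj_net = sj - c.r["P"]
        lower = c.r["N"] + sj_net * c.a["P"] / c.d["N"]
        upper = c.r["N"] + sj_net * (2 * c.d["P"] / c.a["N"] - c.a["P"] / c.d["N"])
        for s_at in (lower, upper):
            below = actual_uptake(s_at * (1 - 1e-10), sj, c, "N", "P")
            above = actual_uptake(s_at * (1 + 1e-10), sj, c, "N", "P")
            assert above == pytest.approx(below, rel=1e-9)

    def test_matches_piecewise_envelope_on_grid(self, ngs):
        # grid evaluation oracle: selected branch equals the value of the
        # explicit three-branch transcription everywhere
        c = ngs.coeffs
        for s_n in np.linspace(0.0, 400.0, 81):
            got = actual_uptake(s_n, 30.0, c, "N", "P")
            want = uptake_oracle(
                s_n, 30.0, c.a["N"], c.d["N"], c.a["P"], c.d["P"],
                c.r["N"], c.r["P"],
            )
            assert got == pytest.approx(want, abs=1e-12)
            assert got <= s_n + 1e-12

    def test_monotone_in_both_supplies(self, ngs):
        c = ngs.coeffs
        grid = np.linspace(0.0, 300.0, 61)
        for sj in (5.0, 30.0, 120.0):
            u = [actual_uptake(s, sj, c, "N", "K") for s in grid]
            assert all(b - a >= -1e-9 for a, b in zip(u, u[1:]))
        for si in (5.0, 60.0, 250.0):
            u = [actual_uptake(si, s, c, "N", "K") for s in grid]
            assert all(b - a >= -1e-9 for a, b in zip(u, u[1:]))

    def test_partner_below_minimum_degenerates(self, ngs):
        c = ngs.coeffs
        assert actual_uptake(3.0, 0.2, c, "N", "P") == 3.0
        assert actual_uptake(50.0, 0.2, c, "N", "P") == c.r["N"]

    def test_same_nutrient_pair_rejected(self, ngs):
        with pytest.raises(ValueError):
            actual_uptake(10.0, 10.0, ngs.coeffs, "N", "N")


class TestYieldRange:
    def test_zero_net_uptake_gives_zero_range(self, ngs):
        assert yield_range(ngs.coeffs.r["N"], ngs.coeffs, "N") == (0.0, 0.0)

    def test_savanna_nitrogen_example(self, ngs):
        # U_N = 54 with r_N = 4: 35*50 and 79*50
        y_a, y_d = yield_range(54.0, ngs.coeffs, "N")
        assert y_a == pytest.approx(1750.0)
        assert y_d == pytest.approx(3950.0)

    @pytest.mark.parametrize("u", [10.0, 54.0, 200.0])
    def test_ratio_identity(self, ngs, u):
        y_a, y_d = yield_range(u, ngs.coeffs, "N")
        assert y_d / y_a == pytest.approx(ngs.coeffs.d["N"] / ngs.coeffs.a["N"])

    def test_below_minimum_floors_at_zero(self, ngs):
        assert yield_range(1.0, ngs.coeffs, "N") == (0.0, 0.0)


class TestPairwiseYield:
    def test_lower_end_of_parabola(self, ngs):
        c = ngs.coeffs
        ranges = {"N": (2000.0, 5000.0), "P": (1500.0, 7000.0), "K": (1800.0, 9000.0)}
        u_n = c.r["N"] + ranges["P"][0] / c.d["N"]
        y = pairwise_yield(u_n, ranges, c, "N", "P", "K")
        assert y == pytest.approx(ranges["P"][0])

    def test_apex_hits_cap(self, ngs):
        c = ngs.coeffs
        ranges = {"N": (2000.0, 5000.0), "P": (1500.0, 7000.0), "K": (1800.0, 9000.0)}
        m = min(ranges["P"][1], ranges["K"][1], c.y_max)
        u_n = c.r["N"] + m / c.a["N"]
        y = pairwise_yield(u_n, ranges, c, "N", "P", "K")
        assert y == pytest.approx(m)

    def test_degenerate_cap_returns_partner_accumulation(self, ngs):
        c = ngs.coeffs
        ranges = {"N": (0.0, 100.0), "P": (3000.0, 7000.0), "K": (1800.0, 2500.0)}
        # cap m = Y_Kd = 2500 < Y_Pa = 3000
        assert pairwise_yield(100.0, ranges, c, "N", "P", "K") == 3000.0

    def test_all_ordered_pairs_match_oracle(self, ngs):
        from oracles import pair_yield_oracle, yield_range_oracle

        c = ngs.coeffs
        u = {"N": 100.0, "P": 15.0, "K": 90.0}
        ranges = {i: yield_range(u[i], c, i) for i in NUTRIENTS}
        for i, j in itertools.permutations(NUTRIENTS, 2):
            (k,) = set(NUTRIENTS) - {i, j}
            got = pairwise_yield(u[i], ranges, c, i, j, k)
            want = pair_yield_oracle(
                u[i], c.a[i], c.d[i], c.r[i],
                ranges[j][0], ranges[j][1], ranges[k][1], c.y_max,
            )
            assert got == pytest.approx(want, rel=1e-12)


class TestUltimateYield:
    def test_one_nutrient_at_minimum_nullifies_yield(self, ngs):
        res = ultimate_yield({"N": ngs.coeffs.r["N"], "P": 500.0, "K": 500.0}, ngs.coeffs)
        assert res.yu == 0.0

    def test_abundant_supplies_capped_at_potential(self, ngs):
        res = ultimate_yield({"N": 3000.0, "P": 600.0, "K": 3000.0}, ngs.coeffs)
        assert res.yu <= ngs.coeffs.y_max
        assert res.yu == pytest.approx(ngs.coeffs.y_max, rel=1e-6)

    def test_frozen_trace_pooled_zone(self, pooled):
        # step-by-step trace of supplies (60, 10, 50), frozen from the
        # straight-line transcription of the four steps
        res = ultimate_yield({"N": 60.0, "P": 10.0, "K": 50.0}, pooled.coeffs)
        want_yu, want_u = ultimate_yield_oracle(
            60.0, 10.0, 50.0, pooled.coeffs.a, pooled.coeffs.d, pooled.coeffs.r,
            pooled.coeffs.y_max,
        )
        assert res.yu == pytest.approx(want_yu, rel=1e-12)
        # regression values, frozen from the trace (kg/ha)
        assert res.yu == pytest.approx(2910.091794191407, rel=1e-9)
        assert res.uptake["N"] == pytest.approx(56.98237363407732, rel=1e-9)
        assert res.uptake["P"] == pytest.approx(9.474653682616315, rel=1e-9)
        assert res.uptake["K"] == pytest.approx(48.692038316356665, rel=1e-9)

    def test_doubling_potential_yield_never_decreases_estimate(self, ngs):
        c = ngs.coeffs
        c2 = c.replace(y_max=2 * c.y_max)
        for s in ({"N": 60, "P": 10, "K": 50}, {"N": 300, "P": 60, "K": 250}):
            assert ultimate_yield(s, c2).yu >= ultimate_yield(s, c).yu - 1e-9

    def test_monotone_in_each_supply(self, ngs):
        c = ngs.coeffs
        base = {"N": 80.0, "P": 12.0, "K": 70.0}
        for n in NUTRIENTS:
            prev = -1.0
            for v in np.linspace(0.0, 300.0, 41):
                s = dict(base)
                s[n] = v
                yu = ultimate_yield(s, c).yu
                assert yu >= prev - 1e-8
                prev = yu

    def test_uptake_never_exceeds_supply(self, ngs):
        for s in ({"N": 10, "P": 2, "K": 8}, {"N": 150, "P": 40, "K": 200}):
            res = ultimate_yield(s, ngs.coeffs)
            for n in NUTRIENTS:
                assert res.uptake[n] <= s[n] + 1e-9


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    sn=st.floats(0, 500), sp=st.floats(0, 120), sk=st.floats(0, 500),
)
def test_oracle_equivalence_property(sn, sp, sk):
    """The engine and the independent transcription agree everywhere."""
    from quefts import builtin_registry

    c = builtin_registry()["NGS"].coeffs
    res = ultimate_yield({"N": sn, "P": sp, "K": sk}, c)
    want_yu, want_u = ultimate_yield_oracle(sn, sp, sk, c.a, c.d, c.r, c.y_max)
    assert res.yu == pytest.approx(want_yu, rel=1e-9, abs=1e-9)
    for n in NUTRIENTS:
        assert res.uptake[n] == pytest.approx(want_u[n], rel=1e-9, abs=1e-9)
        assert res.uptake[n] <= [sn, sp, sk][NUTRIENTS.index(n)] + 1e-9
    assert 0.0 <= res.yu <= c.y_max
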