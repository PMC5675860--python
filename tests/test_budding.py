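"""Budding single-cycle operations: commitment, growth, division, cycles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizereg import (
    CellState,
    ModelConfig,
    budded_growth,
    divide_budding,
    run_cycle_budding,
    start_volume_accumulation,
    start_volume_dilution,
)


class TestStartVolumeDilution:
    @pytest.mark.parametrize(
        "Vb, Ib, expected",
        [
            (1.0, 2.0, 2.0),   # dilution threshold not yet reached
            (1.0, 0.5, 1.0),   # born below threshold: immediate Start at Vb
            (2.0, 2.0, 2.0),   # born exactly at threshold
        ],
    )
    def test_noiseless_commitment_volume(self, Vb, Ib, expected, rng, dilution_config):
        cell = CellState(volume=Vb, regulator=Ib)
        Vi, eta = start_volume_dilution(cell, dilution_config, rng)
        assert Vi == expected
        assert eta == 0.0

    def test_constraint_off_returns_raw_candidate(self, rng, dilution_config):
        config = dilution_config.replace(monotonic_constraint=False)
        cell = CellState(volume=1.0, regulator=0.5)
        Vi, _ = start_volume_dilution(cell, config, rng)
        assert Vi == 0.5  # volume allowed to decrease

    def test_constraint_off_nonpositive_candidate_raises(self, dilution_config):
        config = dilution_config.replace(monotonic_constraint=False, sigma_s=0.5)
        cell = CellState(volume=1.0, regulator=0.01)
        # force a very negative threshold draw
        class NegRng:
            def normal(self, mean, sigma):
                return -5.0
        with pytest.raises(ValueError):
            start_volume_dilution(cell, config, NegRng())


class TestStartVolumeAccumulation:
    @pytest.mark.parametrize(
        "Vb, Ab, expected",
        [
            (1.0, 0.25, 1.75),  # grow until Ac - Ab synthesized
            (1.0, 1.2, 1.0),    # born past threshold: immediate Start
            (1.0, 1.0, 1.0),    # boundary
        ],
    )
    def test_noiseless_commitment_volume(self, Vb, Ab, expected, rng, accumulation_config):
        cell = CellState(volume=Vb, regulator=Ab)
        Vi, Ac = start_volume_accumulation(cell, accumulation_config, rng)
        assert Vi == expected
        assert Ac == 1.0


class TestBuddedGrowth:
    def test_noisy_asymmetry_noiseless(self, rng):
        config = ModelConfig(mean_x=0.5)
        Vd, t_budded, lam = budded_growth(2.0, config, rng)
        assert Vd == 3.0
        assert t_budded == pytest.approx(math.log(1.5) / config.mean_lambda)
        assert lam == config.mean_lambda

    def test_noisy_timing_one_doubling(self, rng):
        config = ModelConfig(
            growth_variant="noisy_timing", mean_lambda=math.log(2), mean_t=1.0
        )
        Vd, t_budded, _ = budded_growth(1.0, config, rng)
        assert Vd == pytest.approx(2.0)
        assert t_budded == 1.0

    def test_realized_asymmetry_equals_drawn_x(self, rng):
        # r = x exactly in the noisy-asymmetry model
        config = ModelConfig(mean_x=0.5, sigma_x=0.1)
        cell = CellState(volume=1.0, regulator=1.0)
        mother, daughter, record = run_cycle_budding(cell, config, rng)
        assert daughter.volume / mother.volume == pytest.approx(
            record.r_realized, abs=1e-12
        )


class TestDivideBudding:
    @pytest.mark.parametrize(
        "Vi, Vd, R, mv, mr, dv, dr",
        [
            (2.0, 3.0, 3.0, 2.0, 2.0, 1.0, 1.0),
            (1.75, 2.625, 0.875, 1.75, 0.875 * (1.75 / 2.625), 0.875, 0.875 / 3),
        ],
    )
    def test_hand_evaluated_partitions(self, Vi, Vd, R, mv, mr, dv, dr):
        mother, daughter = divide_budding(Vi, Vd, R)
        assert mother.volume == pytest.approx(mv, abs=1e-12)
        assert mother.regulator == pytest.approx(mr, abs=1e-12)
        assert daughter.volume == pytest.approx(dv, abs=1e-12)
        assert daughter.regulator == pytest.approx(dr, abs=1e-12)
        assert mother.label == "M" and daughter.label == "D"

    def test_rejects_nonincreasing_volume(self):
        with pytest.raises(ValueError):
            divide_budding(2.0, 2.0, 1.0)

    @given(
        Vi=st.floats(0.1, 50.0),
        bud=st.floats(0.01, 50.0),
        R=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_exact(self, Vi, bud, R):
        mother, daughter = divide_budding(Vi, Vi + bud, R)
        assert mother.volume + daughter.volume == pytest.approx(Vi + bud, abs=1e-12)
        assert mother.regulator + daughter.regulator == pytest.approx(R, abs=1e-12)


class TestRunCycle:
    def test_dilution_steady_state_cycle(self, rng, dilution_config):
        # converged mother: Vi* = mean_delta/(r c1) = 2, one cycle reproduces itself
        cell = CellState(volume=2.0, regulator=2.0)
        mother, daughter, rec = run_cycle_budding(cell, dilution_config, rng)
        assert (rec.Vb, rec.Vi, rec.Vd) == (2.0, 2.0, 3.0)
        assert (mother.volume, mother.regulator) == (2.0, 2.0)
        assert (daughter.volume, daughter.regulator) == (1.0, 1.0)
        assert rec.t_G1 == 0.0

    def test_accumulation_hand_evaluated_cycle(self, rng, accumulation_config):
        cell = CellState(volume=1.0, regulator=0.25)
        mother, daughter, rec = run_cycle_budding(cell, accumulation_config, rng)
        assert (rec.Vb, rec.Vi, rec.Vd) == (1.0, 1.75, 2.625)
        assert rec.Rd == pytest.approx(0.875)  # Ad = c2 (Vd - Vi)
        assert mother.regulator == pytest.approx(0.875 * 1.75 / 2.625)
        assert rec.t_G1 > 0

    @pytest.mark.parametrize("mechanism", ["dilution", "accumulation"])
    def test_volume_monotonicity_invariant(self, mechanism):
        config = ModelConfig(
            mechanism=mechanism,
            mean_x=0.5,
            sigma_x=0.1,
            **(
                {"sigma_delta": 0.2, "sigma_s": 0.2}
                if mechanism == "dilution"
                else {"sigma_i": 0.2}
            ),
        )
        rng = np.random.default_rng(4)
        cell = CellState(volume=1.0, regulator=1.0)
        for _ in range(500):
            mother, daughter, rec = run_cycle_budding(cell, config, rng)
            assert rec.Vb <= rec.Vi <= rec.Vd
            assert (rec.t_G1 == 0.0) == (rec.Vi == rec.Vb)
            cell = mother if rng.random() < 0.5 else daughter

    def test_noisy_synthesis_rate_couples_increment_to_timing(self):
        # with sigma_K = 0 the inhibitor increment is exactly K * t_budded
        config = ModelConfig(
            synthesis_variant="noisy_synthesis_rate",
            growth_variant="noisy_timing",
            mean_K=2.0,
            sigma_t=0.1,
            mean_t=1.0,
        )
        rng = np.random.default_rng(8)
        cell = CellState(volume=1.0, regulator=1.0)
        for _ in range(50):
            _, _, rec = run_cycle_budding(cell, config, rng)
            assert rec.Rd - rec.Rb == pytest.approx(2.0 * rec.t_budded, abs=1e-12)


class TestNoiselessConvergence:
    """Mother-lineage fixed points of the noiseless recursions."""

    @pytest.mark.parametrize("start_factor", [0.1, 0.5])
    def test_dilution_converges_from_below(self, start_factor, dilution_config):
        rng = np.random.default_rng(0)
        cell = CellState(volume=2.0 * start_factor * 0.5, regulator=2.0 * start_factor)
        for _ in range(100):
            cell, _, rec = run_cycle_budding(cell, dilution_config, rng)
        assert abs(rec.Vi - 2.0) < 1e-9  # Vi* = mean_delta/(r c1)
        assert abs(rec.Rb - 2.0) < 1e-9  # Ib* = c1 Vi*

    @pytest.mark.parametrize("start_factor", [0.1, 10.0])
    @pytest.mark.parametrize(
        "mechanism, Vi_star", [("dilution", 2.0), ("accumulation", 3.0)]
    )
    def test_unclamped_recursion_converges_from_both_sides(
        self, start_factor, mechanism, Vi_star
    ):
        # without the monotonic clamp the mother map is a contraction from
        # either side of the fixed point
        config = ModelConfig(
            mechanism=mechanism, mean_x=0.5, monotonic_constraint=False
        )
        rng = np.random.default_rng(0)
        Vi0 = start_factor * Vi_star
        if mechanism == "dilution":
            cell = CellState(volume=Vi0, regulator=Vi0)  # Ib = c1 Vi
        else:
            cell = CellState(volume=Vi0, regulator=0.5 * Vi0 / 1.5)
        for _ in range(100):
            cell, _, rec = run_cycle_budding(cell, config, rng)
        assert abs(rec.Vi - Vi_star) < 1e-9

    def test_accumulation_daughter_g1_longer_than_mother(self, accumulation_config):
        # r < 1: daughters are born smaller and must grow longer before Start
        rng = np.random.default_rng(0)
        cell = CellState(volume=1.0, regulator=0.25)
        for _ in range(200):
            mother, daughter, _ = run_cycle_budding(cell, accumulation_config, rng)
            cell = mother
        _, _, mother_rec = run_cycle_budding(mother, accumulation_config, rng)
        _, _, daughter_rec = run_cycle_budding(daughter, accumulation_config, rng)
        assert daughter_rec.t_G1 > mother_rec.t_G1
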