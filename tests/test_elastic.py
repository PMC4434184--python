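"""Unit and property tests for the forced-bending energy model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from nucbend import (
    BendingGeometry,
    EnergyModel,
    StepParams,
    StepParamTable,
    accumulated_twist,
    build_param_table,
    placement_energy,
    reverse_complement,
    torque,
    total_bend_angle,
)
from nucbend.elastic import STEPS


class TestParamTable:
    @pytest.mark.parametrize(
        "step, expected",
        [
            ("AA", (0.2, 0.406, 0.76, -1.84)),
            ("CG", (0.04, 0.255, 4.25, 0.0)),
            ("TT", (0.2, 0.406, 0.76, 1.84)),  # complement of AA, tilt sign flipped
            ("GA", (0.097, 0.408, 3.87, 1.52)),  # complement of TC
        ],
    )
    def test_lookup(self, table, step, expected):
        p = table.lookup(step)
        assert (p.k_rho, p.k_tau, p.rho0, p.tau0) == pytest.approx(expected)

    def test_all_16_steps_and_strand_symmetry(self, table):
        for step in STEPS:
            rc = reverse_complement(step)
            a, b = table.lookup(step), table.lookup(rc)
            assert a.k_rho == b.k_rho
            assert a.k_tau == b.k_tau
            assert a.rho0 == b.rho0
            assert a.tau0 == -b.tau0

    def test_palindromic_steps_have_zero_tilt(self, table):
        for step in ("AT", "TA", "GC", "CG"):
            assert table.lookup(step).tau0 == 0.0

    def test_matches_independent_table(self, table):
        ref = oracle.full_table()
        for step, (kr, kt, r0, t0) in ref.items():
            p = table.lookup(step)
            assert (p.k_rho, p.k_tau, p.rho0, p.tau0) == (kr, kt, r0, t0)

    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(ValueError):
            StepParams(k_rho=0.0, k_tau=0.3, rho0=1.0, tau0=0.0)

    def test_incomplete_table_rejected(self, table):
        entries = {s: table.lookup(s) for s in STEPS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            StepParamTable(entries)

    def test_broken_symmetry_rejected(self, table):
        entries = {s: table.lookup(s) for s in STEPS}
        entries["TT"] = StepParams(0.2, 0.406, 0.76, -1.84)  # same sign as AA
        with pytest.raises(ValueError, match="symmetry"):
            StepParamTable(entries)


class TestAccumulatedTwist:
    @pytest.mark.parametrize(
        "i, expected", [(1, 17.4), (-1, -17.4), (3, 87.0), (-3, -87.0), (64, 2209.8)]
    )
    def test_values(self, i, expected):
        assert accumulated_twist(i, 34.8) == pytest.approx(expected)

    def test_step_zero_rejected(self):
        with pytest.raises(ValueError):
            accumulated_twist(0, 34.8)

    @given(i=st.integers(min_value=1, max_value=73))
    @settings(deadline=None)
    def test_antisymmetric_and_matches_literal_sum(self, i):
        assert accumulated_twist(-i, 34.8) == -accumulated_twist(i, 34.8)
        assert accumulated_twist(i, 34.8) == pytest.approx(oracle.accumulated_twist(i))


class TestGeometry:
    def test_defaults(self, geom):
        assert geom.alpha_total == 579.0
        assert geom.omega == 34.8
        assert (geom.core_len, geom.contact_len, geom.max_step_index) == (147, 129, 64)

    @pytest.mark.parametrize("kwargs", [{"contact_len": 128}, {"contact_len": 149}, {"omega": 0}])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BendingGeometry(**kwargs)


class TestPlacementEnergy:
    def test_zero_equilibrium_angles_closed_form(self, geom):
        flat = StepParamTable(
            {s: StepParams(0.1, 0.2, 0.0, 0.0) for s in STEPS}
        )
        window = "A" * 129
        denom = sum(
            math.cos(math.radians(oracle.accumulated_twist(i))) ** 2 / 0.1
            + math.sin(math.radians(oracle.accumulated_twist(i))) ** 2 / 0.2
            for i in range(-64, 65)
            if i != 0
        )
        assert torque(window, flat, geom) == pytest.approx(geom.alpha_total / denom, rel=1e-12)

    def test_polyA_matches_oracle(self, model):
        window = "A" * 129
        assert model.torque(window) == pytest.approx(oracle.torque(window), rel=1e-9)
        pe = model.placement_energy(window)
        assert pe.E_total == pytest.approx(oracle.window_energy(window), rel=1e-9)

    def test_oracle_equivalence_random_windows(self, model, random_windows):
        for window in random_windows(100):
            F_ref = oracle.torque(window)
            E_ref = oracle.window_energy(window)
            pe = model.placement_energy(window)
            assert pe.F_b == pytest.approx(F_ref, rel=1e-9)
            assert pe.E_total == pytest.approx(E_ref, rel=1e-9)
            assert pe.E_total >= 0

    def test_per_step_energies_sum_and_match_oracle(self, model, random_windows):
        (window,) = random_windows(1)
        pe = model.placement_energy(window, keep_per_step=True)
        assert len(pe.per_step) == 128
        assert sum(e for _, _, e in pe.per_step) == pytest.approx(pe.E_total, rel=1e-12)
        for i, om, e in pe.per_step[:10]:
            assert om == pytest.approx(oracle.accumulated_twist(i))
            assert e == pytest.approx(oracle.step_energy(window, i, pe.F_b), rel=1e-9)

    def test_strand_symmetry(self, model, random_windows):
        for window in random_windows(100):
            rc = reverse_complement(window)
            assert model.placement_energy(rc).E_total == pytest.approx(
                model.placement_energy(window).E_total, rel=1e-9
            )
            assert model.torque(rc) == pytest.approx(model.torque(window), rel=1e-9)

    def test_locality_outside_contact_region(self, model, rng):
        core = "".join(rng.choice(list("ACGT"), size=147))
        e_ref = model.placement_energy(core).E_total
        # scramble the 9 uncontacted bp at each end of the 147-bp footprint
        edited = "G" * 9 + core[9:138] + "C" * 9
        assert model.placement_energy(edited).E_total == e_ref

    def test_ambiguous_base_gives_nan(self, model):
        window = "A" * 64 + "N" + "A" * 64
        pe = model.placement_energy(window)
        assert math.isnan(pe.F_b) and math.isnan(pe.E_total)

    def test_short_window_rejected(self, model):
        with pytest.raises(ValueError, match="shorter"):
            model.placement_energy("ACGT" * 10)

    def test_module_level_wrappers_agree(self, table, geom, random_windows):
        (window,) = random_windows(1)
        m = EnergyModel(table, geom)
        assert torque(window, table, geom) == m.torque(window)
        assert placement_energy(window, table, geom).E_total == m.placement_energy(window).E_total


class TestBendAngleConservation:
    def test_random_windows_conserve_alpha(self, model, random_windows):
        for window in random_windows(100):
            assert model.total_bend_angle(window) == pytest.approx(579.0, abs=1e-6)

    def test_polyG_window(self, model):
        assert model.total_bend_angle("G" * 129) == pytest.approx(579.0, abs=1e-6)

    def test_matches_oracle_deformation_sum(self, model, random_windows):
        (window,) = random_windows(1)
        assert model.total_bend_angle(window) == pytest.approx(
            oracle.deformed_bend_angle(window), rel=1e-12
        )

    def test_zero_bend_geometry(self, table, random_windows):
        (window,) = random_windows(1)
        geom0 = BendingGeometry(alpha_total=0.0)
        assert total_bend_angle(window, table, geom0) == pytest.approx(0.0, abs=1e-6)


class TestSlidingEnergy:
    def test_agrees_with_per_window_energies(self, model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        sliding = model.sliding_energy(seq)
        for j in (64, 100, 235):
            window = seq[j - 64 : j + 65]
            assert sliding[j] == pytest.approx(model.placement_energy(window).E_total, rel=1e-12)
        assert np.isnan(sliding[:64]).all() and np.isnan(sliding[-64:]).all()

    def test_ambiguous_bases_propagate(self, model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seq = seq[:150] + "N" + seq[151:]
        sliding = model.sliding_energy(seq)
        assert np.isnan(sliding[86:215]).all()  # dyads whose window spans position 150
        assert np.isfinite(sliding[85]) and np.isfinite(sliding[215])
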