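"""Product-operator bookkeeping: evolution, projection, detection, cycle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codexsim.codex_engine import (
    CoherenceState,
    Component,
    apply_z_filter,
    detect,
    evolution_matrix,
    evolve_period,
    ideal_step_signals,
    initial_state_after_cp,
    phase_cycle_table,
    project_component,
    receiver_weighted_sum,
    reinsert_after_mixing,
)
from codexsim.errors import DomainError
from codexsim.spin_system import PhasePair

angles = st.floats(-6.0, 6.0, allow_nan=False)


class TestInitialState:
    @pytest.mark.parametrize(
        "a, expected",
        [
            (0.0, [1.0, 0.0, 0.0, 0.0]),
            (1.0, [0.0, 0.0, 0.0, -1.0]),
            (0.3, [0.7, 0.0, 0.0, -0.3]),
        ],
    )
    def test_linear_mixing(self, a, expected):
        state = initial_state_after_cp(a)
        np.testing.assert_allclose(state.amplitudes[0], expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            initial_state_after_cp(1.2)

    def test_spin_one_carries_level_resolved_quadruples(self):
        state = initial_state_after_cp(0.4, spin_I=1)
        assert state.levels == (-1.0, 0.0, 1.0)
        # in-phase distributed evenly, anti-phase weighted by the level
        np.testing.assert_allclose(state.amplitudes[:, 0], 0.2)
        np.testing.assert_allclose(
            state.amplitudes[:, 3], [0.4 / 3, 0.0, -0.4 / 3]
        )


class TestZFilter:
    def test_zero_delay_is_identity(self):
        state = initial_state_after_cp(0.3)
        out = apply_z_filter(state, 0.0, t1_s=100.0, t2_s=1.0)
        np.testing.assert_array_equal(out.amplitudes, state.amplitudes)

    def test_long_delay_removes_anti_phase(self):
        state = initial_state_after_cp(0.3)
        out = apply_z_filter(state, 100.0, t1_s=1e12, t2_s=1.0)
        np.testing.assert_allclose(out.amplitudes[0], [0.7, 0, 0, 0],
                                   atol=1e-12)

    def test_longitudinal_storage_decay(self):
        state = initial_state_after_cp(0.0)
        out = apply_z_filter(state, 50.0, t1_s=50.0, t2_s=1.0)
        assert out.amplitudes[0, 0] == pytest.approx(math.exp(-1.0))

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(DomainError):
            apply_z_filter(initial_state_after_cp(0.0), 1.0, -1.0, 1.0)


class TestEvolution:
    def test_zero_phases_identity(self):
        np.testing.assert_allclose(evolution_matrix(0.0, 0.0), np.eye(4),
                                   atol=1e-15)

    def test_pure_in_phase_dephasing_matches_printed_map(self):
        """Sx -> (cos cos, sin cos, -sin sin, cos sin) on
        (Sx, Sy, 2SxIz, 2SyIz)."""
        pc, pd = 0.8, 0.3
        state = evolve_period(initial_state_after_cp(0.0), PhasePair(pc, pd))
        cc, sc, cd, sd = math.cos(pc), math.sin(pc), math.cos(pd), math.sin(pd)
        np.testing.assert_allclose(
            state.amplitudes[0],
            [cc * cd, sc * cd, -sc * sd, cc * sd],
            atol=1e-14,
        )

    def test_pure_anti_phase_dephasing_matches_printed_map(self):
        """-2SyIz -> Sx cos sin + Sy sin sin + 2SxIz sin cos
        - 2SyIz cos cos."""
        pc, pd = -1.1, 0.25
        state = evolve_period(initial_state_after_cp(1.0), PhasePair(pc, pd))
        cc, sc, cd, sd = math.cos(pc), math.sin(pc), math.cos(pd), math.sin(pd)
        np.testing.assert_allclose(
            state.amplitudes[0],
            [cc * sd, sc * sd, sc * cd, -cc * cd],
            atol=1e-14,
        )

    @given(pc=angles, pd=angles)
    @settings(max_examples=60, deadline=None)
    def test_evolution_is_orthogonal(self, pc, pd):
        u = evolution_matrix(pc, pd)
        np.testing.assert_allclose(u @ u.T, np.eye(4), atol=1e-12)

    @given(pc=angles, pd=angles, seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_norm_preserved_and_inverse_undoes(self, pc, pd, seed):
        rng = np.random.default_rng(seed)
        state = CoherenceState(rng.normal(size=(1, 4)))
        phases = PhasePair(pc, pd)
        evolved = evolve_period(state, phases)
        assert evolved.norm() == pytest.approx(state.norm(), abs=1e-12)
        back = evolve_period(evolved, -phases)
        np.testing.assert_allclose(back.amplitudes, state.amplitudes,
                                   atol=1e-12)

    def test_spin_one_levels_scale_dipolar_phase(self):
        state = initial_state_after_cp(0.0, spin_I=1)
        out = evolve_period(state, PhasePair(0.0, 0.4))
        # m = -1, 0, +1 rows acquire dipolar phases -0.4, 0, +0.4
        third = 1.0 / 3.0
        np.testing.assert_allclose(
            out.amplitudes[:, 0],
            [third * math.cos(0.4), third, third * math.cos(0.4)],
            atol=1e-14,
        )
        assert out.amplitudes[1, 3] == 0.0


class TestProjectionDetection:
    def test_cos_projection_kills_y_family(self):
        state = CoherenceState(np.array([[0.0, 1.0, 0.0, 0.5]]))
        out = project_component(state, "cos")
        assert out.norm() == 0.0

    def test_cos_projection_of_dephased_in_phase(self):
        pc, pd = 0.8, 0.3
        state = evolve_period(initial_state_after_cp(0.0), PhasePair(pc, pd))
        stored = project_component(state, Component.COS)
        cc, sc, cd, sd = math.cos(pc), math.sin(pc), math.cos(pd), math.sin(pd)
        np.testing.assert_allclose(
            stored.amplitudes[0], [cc * cd, 0.0, -sc * sd, 0.0], atol=1e-14
        )

    def test_sin_projection_of_dephased_anti_phase(self):
        pc, pd = 0.8, 0.3
        state = evolve_period(initial_state_after_cp(1.0), PhasePair(pc, pd))
        stored = project_component(state, "sin")
        cc, sc, cd, sd = math.cos(pc), math.sin(pc), math.cos(pd), math.sin(pd)
        np.testing.assert_allclose(
            stored.amplitudes[0], [0.0, sc * sd, 0.0, -cc * cd], atol=1e-14
        )

    def _full_pipeline(self, a, phases1, phases2, component, reinsert):
        state = initial_state_after_cp(a)
        state = evolve_period(state, phases1)
        state = project_component(state, component)
        if reinsert:
            state = reinsert_after_mixing(state, component)
        state = evolve_period(state, phases2)
        return detect(state, component)

    @pytest.mark.parametrize("phi", [0.3, 0.9, 2.0])
    def test_cos_signal_is_cos_squared(self, phi):
        p = PhasePair(phi, 0.0)
        got = self._full_pipeline(0.0, p, p, "cos", reinsert=True)
        assert got == pytest.approx(math.cos(phi) ** 2, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.3, 0.9, 2.0])
    def test_sin_signal_is_sin_squared(self, phi):
        p = PhasePair(phi, 0.0)
        got = self._full_pipeline(0.0, p, p, "sin", reinsert=True)
        assert got == pytest.approx(math.sin(phi) ** 2, abs=1e-12)

    @pytest.mark.parametrize("phi,dphi", [(0.7, 0.4), (1.4, -0.8)])
    def test_cos_plus_sin_gives_stimulated_echo(self, phi, dphi):
        """COS + SIN = cos(delta_phi) x the short-mixing-time value."""
        p1 = PhasePair(phi, 0.0)
        p2 = PhasePair(phi + dphi, 0.0)
        total = self._full_pipeline(0.0, p1, p2, "cos", True) + \
            self._full_pipeline(0.0, p1, p2, "sin", True)
        s0 = self._full_pipeline(0.0, p1, p1, "cos", True) + \
            self._full_pipeline(0.0, p1, p1, "sin", True)
        assert s0 == pytest.approx(1.0, abs=1e-12)
        assert total == pytest.approx(math.cos(dphi), abs=1e-12)

    def test_stored_component_amplitude_expressions(self):
        """Within the stored-family bookkeeping (no readout transport) the
        detected amplitudes reproduce the printed component expressions."""
        pc, pd = 0.5, 0.2
        cc, sc, cd, sd = math.cos(pc), math.sin(pc), math.cos(pd), math.sin(pd)
        p = PhasePair(pc, pd)
        cos_in = self._full_pipeline(0.0, p, p, "cos", reinsert=False)
        assert cos_in == pytest.approx(cc**2 * cd * cd + sc**2 * sd * sd,
                                       abs=1e-12)
        sin_anti = self._full_pipeline(1.0, p, p, "sin", reinsert=False)
        assert sin_anti == pytest.approx(
            sc * cc * (sd * cd + cd * sd), abs=1e-12
        )

    def test_with_dipolar_phase_zero_flips_cannot_matter(self):
        """Any rephasing dipolar phase change leaves the signal unchanged
        when the dephasing dipolar phase is zero and the state is in-phase:
        no RIDER without a dipolar phase."""
        p1 = PhasePair(1.1, 0.0)
        base = self._full_pipeline(0.0, p1, p1, "cos", True)
        for flipped_pd in (0.0, 0.3):
            got = self._full_pipeline(
                0.0, p1, PhasePair(1.1, flipped_pd), "cos", True
            )
            # conversion to anti-phase reduces nothing at pd_dephase = 0
            assert got == pytest.approx(
                base * math.cos(flipped_pd), abs=1e-12
            )


class TestPhaseCycle:
    @pytest.mark.parametrize("component", ["cos", "sin"])
    @pytest.mark.parametrize("detection", ["direct", "indirect"])
    def test_sixty_four_steps(self, component, detection):
        table = phase_cycle_table(component, detection)
        assert len(table) == 64

    def test_components_differ_only_in_phi5_phi8(self):
        cos_t = phase_cycle_table("cos")
        sin_t = phase_cycle_table("sin")
        differing = {
            col
            for col in cos_t.columns
            if cos_t.column(col) != sin_t.column(col)
        }
        assert differing == {"phi5", "phi8"}

    def test_nested_cycle_periods(self):
        table = phase_cycle_table("cos")
        phi5 = table.column("phi5")
        assert phi5[0::2] == tuple(["y"] * 32)
        assert phi5[1::2] == tuple(["-y"] * 32)
        phi9 = table.column("phi9")
        assert phi9[:16] == tuple(["x"] * 16)
        assert phi9[16:32] == tuple(["y"] * 16)

    @pytest.mark.parametrize("detection", ["direct", "indirect"])
    def test_artifact_free_signals_add_coherently(self, detection):
        table = phase_cycle_table("cos", detection)
        signals = ideal_step_signals(table, amplitude=0.7)
        total = receiver_weighted_sum(table, signals)
        assert total == pytest.approx(64 * 0.7, abs=1e-12)

    def test_export_round_trip_text(self, tmp_path):
        table = phase_cycle_table("sin")
        text = table.to_text()
        lines = text.strip().splitlines()
        assert len(lines) == 65  # header + 64 steps
        assert lines[0].split("\t")[1:] == list(table.columns)
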