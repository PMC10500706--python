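"""Assembled CODEX experiments: curves, normalization, reference ratios."""

import math

import numpy as np
import pytest

from codexsim.codex_engine import (
    CoherenceState,
    detect,
    evolve_period,
    project_component,
)
from codexsim.errors import ConfigError, DataError, DomainError
from codexsim.experiment import (
    ISpecies,
    MixingCurve,
    SequenceConfig,
    analytic_exchange_ratios,
    analytic_rider_ratios,
    antiphase_amplitude_ratio,
    equilibrium_plateau_reference,
    simulate_mixing_curve,
    simulate_s0_vs_ntr,
    t1_normalize,
)
from codexsim.spin_system import (
    CsaTensor,
    DipolarCoupling,
    PhasePair,
    PulseTrain,
    powder_orientations,
    recoupled_phase,
)
from codexsim.stochastic_dynamics import ExchangeModel, FlipProcess


def proton(residual=0.01, flipflop=5.0):
    return ISpecies(
        coupling=DipolarCoupling(10.4, (1.2, 0.4), residual_scale=residual),
        flips=FlipProcess(spin_I=0.5, flipflop_time=flipflop),
        cp_partner=True,
    )


class TestSimulateMixingCurve:
    def test_no_dipolar_no_exchange_curves_are_flat(self):
        cfg = SequenceConfig(
            tau_m_grid=tuple(np.geomspace(1, 100, 8)),
            seed=3,
            csa=CsaTensor(6.0, 0.2),
            species=(proton(residual=0.0),),
            anti_phase_fraction=0.3,
            orientation_count=64,
            mc_draws=4000,
            t1_s=1e9,
        )
        curve = simulate_mixing_curve(cfg)
        for comp in ("cos", "sin"):
            y = curve.intensity(comp)
            err = curve.error(comp)
            spread = np.abs(y - y[0])
            assert np.all(spread < 4 * np.maximum(err + err[0], 1e-12))

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            SequenceConfig(tau_m_grid=(), seed=1)

    def test_metadata_and_components(self):
        cfg = SequenceConfig(
            tau_m_grid=(1.0, 5.0, 10.0, 20.0, 50.0),
            seed=5,
            csa=CsaTensor(6.0),
            component="cos",
            orientation_count=16,
            mc_draws=200,
        )
        curve = simulate_mixing_curve(cfg)
        assert curve.components == ("cos",)
        assert curve.metadata["seed"] == 5
        assert curve.metadata["t1_normalized"] is True

    def test_seeded_runs_are_identical(self):
        cfg = SequenceConfig(
            tau_m_grid=(1.0, 10.0, 50.0),
            seed=11,
            csa=CsaTensor(6.0),
            species=(proton(),),
            anti_phase_fraction=0.3,
            orientation_count=16,
            mc_draws=500,
        )
        a = simulate_mixing_curve(cfg)
        b = simulate_mixing_curve(cfg)
        np.testing.assert_array_equal(a.cos, b.cos)
        np.testing.assert_array_equal(a.sin, b.sin)

    def test_independent_points_match_paired_means(self):
        cfg = SequenceConfig(
            tau_m_grid=(1.0, 10.0, 50.0),
            seed=11,
            csa=CsaTensor(6.0),
            orientation_count=32,
            mc_draws=3000,
        )
        paired = simulate_mixing_curve(cfg)
        indep = simulate_mixing_curve(cfg, independent_points=True)
        assert indep.metadata["independent_points"] is True
        np.testing.assert_allclose(
            indep.cos, paired.cos,
            atol=4 * float(np.max(paired.cos_err + indep.cos_err)),
        )

    def test_exchange_plateau_matches_pair_averaged_reference(self):
        model = ExchangeModel.symmetric_two_site(0.1,
                                                 reorientation=(0, 0.2, 0))
        cfg = SequenceConfig(
            tau_m_grid=(0.1, 40.0, 80.0, 160.0),
            seed=21,
            csa=CsaTensor(12.0, 0.2),
            exchange=model,
            orientation_count=20000,
            orientation_scheme="random",
            mc_draws=20000,
            t1_s=1e9,
        )
        ref = equilibrium_plateau_reference(cfg)
        curve = simulate_mixing_curve(cfg)
        total0 = curve.cos[0] + curve.sin[0]
        total_inf = np.mean(curve.cos[1:] + curve.sin[1:])
        se = float(np.hypot(curve.cos_err, curve.sin_err).max())
        assert total_inf / total0 == pytest.approx(ref, abs=4 * se)


class TestS0VsNtr:
    def test_flat_at_one_without_interactions(self):
        cfg = SequenceConfig(
            tau_m_grid=(0.01,),
            seed=2,
            orientation_count=8,
            mc_draws=100,
        )
        curve = simulate_s0_vs_ntr(cfg, [4, 8, 16])
        np.testing.assert_allclose(curve.s0_values, 1.0, atol=1e-12)

    def test_matches_direct_powder_average_with_frozen_levels(self):
        """Dipolar variant, frozen levels: S0(NTR) equals the powder average
        of cos^2 of the recoupled dipolar phase, evaluated directly."""
        coupling = DipolarCoupling(2.0, (1.0, 0.7))
        cfg = SequenceConfig(
            tau_m_grid=(0.01,),
            seed=2,
            variant="dipolar_codex",
            component="cos",
            species=(
                ISpecies(coupling=coupling, flips=FlipProcess(spin_I=0.5),
                         cp_partner=True),
            ),
            orientation_count=32,
            mc_draws=64,
            t1_s=1e9,
        )
        n_values = [4, 8, 16]
        curve = simulate_s0_vs_ntr(cfg, n_values)
        oset = powder_orientations(32)
        for nv, s0 in zip(n_values, curve.s0_values):
            train = PulseTrain.dipolar_codex(cfg.mas_period, nv)
            phis = np.array(
                [recoupled_phase(coupling, o, train)
                 for o in oset.orientations]
            )
            assert s0 == pytest.approx(float(np.mean(np.cos(phis) ** 2)),
                                       abs=1e-10)

    def test_odd_rotor_cycles_rejected_for_dipolar(self):
        cfg = SequenceConfig(
            tau_m_grid=(0.01,), seed=2, variant="dipolar_codex",
            orientation_count=4, mc_draws=10,
        )
        with pytest.raises(ConfigError):
            simulate_s0_vs_ntr(cfg, [4, 5])


class TestT1Normalize:
    def grid(self):
        return np.array([1.0, 5.0, 20.0, 80.0])

    def test_unit_reference_is_identity(self):
        tau = self.grid()
        raw = MixingCurve(tau, cos=np.array([1.0, 0.8, 0.6, 0.5]))
        ref = MixingCurve(tau, cos=np.ones(4))
        out = t1_normalize(raw, ref)
        np.testing.assert_array_equal(out.cos, raw.cos)

    def test_exponential_cancellation_is_exact(self):
        tau = self.grid()
        f = 0.4 + 0.6 * np.exp(-tau / 15.0)
        t1 = np.exp(-tau / 300.0)
        raw = MixingCurve(tau, cos=f * t1)
        ref = MixingCurve(tau, cos=t1)
        out = t1_normalize(raw, ref)
        np.testing.assert_allclose(out.cos, f, rtol=1e-12)

    def test_error_propagation_matches_resampling(self, rng):
        """First-order quadrature propagation against a Monte-Carlo
        resampling estimate of the ratio spread."""
        tau = self.grid()
        a, b = np.array([1.0, 0.9, 0.7, 0.6]), np.array([0.95, 0.9, 0.8, 0.7])
        ea, eb = 0.02 * a, 0.01 * b
        out = t1_normalize(
            MixingCurve(tau, cos=a, cos_err=ea),
            MixingCurve(tau, cos=b, cos_err=eb),
        )
        n = 40_000
        samples = (a + rng.normal(size=(n, 4)) * ea) / (
            b + rng.normal(size=(n, 4)) * eb
        )
        mc_err = samples.std(axis=0, ddof=1)
        np.testing.assert_allclose(out.cos_err, mc_err, rtol=0.05)
        expected = np.abs(a / b) * np.sqrt((ea / a) ** 2 + (eb / b) ** 2)
        np.testing.assert_allclose(out.cos_err, expected, rtol=1e-12)

    def test_grid_mismatch_and_zero_denominator_rejected(self):
        tau = self.grid()
        raw = MixingCurve(tau, cos=np.ones(4))
        with pytest.raises(DataError):
            t1_normalize(raw, MixingCurve(tau * 2, cos=np.ones(4)))
        with pytest.raises(DataError):
            t1_normalize(raw, MixingCurve(tau, cos=np.array([1, 0, 1, 1.0])))


class TestAnalyticRatios:
    def test_zero_phase_change_gives_unity(self):
        r = analytic_exchange_ratios(0.7, 0.0)
        assert (r.classical, r.cos_ratio, r.sin_ratio) == (1.0, 1.0, 1.0)

    def test_single_ordered_pair_corrections(self):
        phi, dphi = 0.7, 0.3
        r = analytic_exchange_ratios(phi, dphi)
        assert r.classical == pytest.approx(math.cos(dphi))
        assert r.cos_ratio == pytest.approx(
            math.cos(dphi) - math.tan(phi) * math.sin(dphi)
        )
        assert r.sin_ratio == pytest.approx(
            math.cos(dphi) + math.sin(dphi) / math.tan(phi)
        )

    def test_equilibrium_average_restores_classical(self):
        """In dynamic equilibrium the phase changes come in conjugate pairs
        (delta_phi_ij = -delta_phi_ji), so the odd corrections cancel and
        all three ratios average to cos(delta_phi)."""
        phi, dphi = 0.7, 0.3
        fwd = analytic_exchange_ratios(phi, dphi)
        rev = analytic_exchange_ratios(phi, -dphi)
        for attr in ("classical", "cos_ratio", "sin_ratio"):
            avg = 0.5 * (getattr(fwd, attr) + getattr(rev, attr))
            assert avg == pytest.approx(math.cos(dphi), abs=1e-12)
        assert fwd.equilibrium_average == pytest.approx(math.cos(dphi))

    def test_singular_phases_rejected(self):
        with pytest.raises(DomainError):
            analytic_exchange_ratios(math.pi / 2, 0.1)
        with pytest.raises(DomainError):
            analytic_exchange_ratios(0.0, 0.1)

    def test_rider_sin_ratio_is_half_for_any_csa_phase(self):
        for phi in (0.05, 0.4, 1.0, 1.4):
            assert analytic_rider_ratios(phi).sin_ratio == 0.5

    def test_rider_cos_ratio_limits(self):
        assert analytic_rider_ratios(0.0).cos_ratio == pytest.approx(1.0)
        with pytest.raises(DomainError):
            analytic_rider_ratios(math.pi / 4)

    def test_rider_cos_ratio_matches_level_pair_enumeration(self):
        """Brute-force enumeration of (dephase, rephase) level pairs through
        the stored-component evolution, at phi_csa = pi/6."""
        phi_csa, phi_d = math.pi / 6, 0.23
        signals = {}
        for m0 in (0.5, -0.5):
            for m1 in (0.5, -0.5):
                state = CoherenceState(np.array([[0.0, 0, 0, -2 * m0]]))
                state = evolve_period(state, PhasePair(phi_csa, 2 * m0 * phi_d))
                state = project_component(state, "cos")
                state = evolve_period(state, PhasePair(phi_csa, 2 * m1 * phi_d))
                signals[(m0, m1)] = detect(state, "cos")
        s0 = 0.5 * (signals[(0.5, 0.5)] + signals[(-0.5, -0.5)])
        s_inf = 0.25 * sum(signals.values())
        assert s_inf / s0 == pytest.approx(
            analytic_rider_ratios(phi_csa).cos_ratio, rel=1e-12
        )


class TestAmplitudeRatio:
    def test_sin_ratio_is_twice_tan_at_small_phase(self):
        phi_d = 1e-4
        ratio = antiphase_amplitude_ratio(0.3, phi_d, "sin")
        assert ratio / math.tan(phi_d) == pytest.approx(2.0, abs=1e-6)

    def test_cos_ratio_is_tan_at_small_phases(self):
        phi_d = 1e-4
        ratio = antiphase_amplitude_ratio(0.05, phi_d, "cos")
        assert ratio / math.tan(phi_d) == pytest.approx(1.0, abs=1e-2)

    def test_exact_double_angle_structure(self):
        # anti/in = tan(2 phi_d) for SIN at any phases
        phi_d = 0.2
        ratio = antiphase_amplitude_ratio(0.9, phi_d, "sin")
        assert ratio == pytest.approx(math.tan(2 * phi_d), rel=1e-12)
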