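"""Seeded fixture generator: self-contained test inputs for every stage.

Each scenario emits a run configuration, the simulated COS/SIN curve pair
and a ground-truth parameter file, so parameter-recovery and diagnostic
tests need no external data.  The scenarios emulate the canonical
experimental situations:

* ``rigid_rider`` — rigid solid, no motion; the anti-phase coherence left
  by cross polarization plus residual S–I coupling produces a pure RIDER
  decay, stronger in SIN than in COS.
* ``z_filtered`` — same system with a long Z filter; curves become
  independent of the anti-phase fraction.
* ``protein_two_rider`` — two simultaneous RIDER channels (fast proton
  flip-flops seeding the anti-phase pathway, slow deuteron T1 flips
  modulating the in-phase dipolar phase) on top of a slow phenomenological
  spin-diffusion decay.
* ``exchange_only`` — symmetric two-site reorientational exchange with no
  dipolar phases: COS and SIN must share the same shape.
* ``dipolar_flipflop`` — dipolar-recoupling variant with flips occurring
  within the de(re)phasing periods, which suppress the stimulated-echo
  amplitude even in the COS component (the mixing-time analogue of the
  shortened recoupled Hahn-echo decay).

All defaults describe a 20 kHz MAS experiment.  The RIDER demonstrations
use an amine-like 15N CSA (anisotropy 1.2 kHz ~ 20 ppm at 60.8 MHz) with an
8-rotor-cycle de(re)phasing period, so the recoupled CSA phase stays in the
partial-wrapping regime (rms ~0.7 rad) where the isolated-pair model
expresses the COS/SIN asymmetry; the exchange scenario uses a carbonyl
13C-like CSA (12 kHz) where phase wrapping makes the component-shape
identity exact.  The one-bond N–H coupling is 10.4 kHz and the fraction
surviving CW decoupling is taken as 0.02, giving recoupled dipolar phases
of ~0.1 rad — small but appreciable.  All tensor magnitudes are
illustrative, not fitted to any measurement.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .experiment import (
    ISpecies,
    MixingCurve,
    SequenceConfig,
    equilibrium_plateau_reference,
    simulate_mixing_curve,
)
from .io import dump_config, write_curve
from .spin_system import CsaTensor, DipolarCoupling
from .stochastic_dynamics import ExchangeModel, FlipProcess

__all__ = [
    "SCENARIOS",
    "scenario_config",
    "generate_fixture",
    "model_curve",
    "model_curve_replicates",
]

# illustrative defaults (20 kHz MAS)
AMINE_CSA = CsaTensor(anisotropy=1.2, asymmetry=0.2)  # ~20 ppm 15N
CARBONYL_CSA = CsaTensor(anisotropy=12.0, asymmetry=0.2)  # ~80 ppm 13C
RIDER_ROTOR_CYCLES = 8  # 0.4 ms de(re)phasing for the RIDER demos
NH_COUPLING = 10.4  # kHz, one-bond N-H
RESIDUAL_DECOUPLING = 0.02  # surviving fraction under CW decoupling
PROTON_FLIPFLOP_MS = 10.0  # from Hahn-echo decay timescale
DEUTERON_T1_MS = 25.0  # aliphatic 2H spin-lattice relaxation
SPIN_DIFFUSION_MS = 2000.0  # slow 15N-15N spin-diffusion decay


def _proton_species(residual=RESIDUAL_DECOUPLING, flipflop=PROTON_FLIPFLOP_MS,
                    beta=1.2) -> ISpecies:
    return ISpecies(
        coupling=DipolarCoupling(
            NH_COUPLING, polar_angles=(beta, 0.4), residual_scale=residual
        ),
        flips=FlipProcess(spin_I=0.5, flipflop_time=flipflop),
        label="1H",
        cp_partner=True,
    )


def _deuteron_species() -> ISpecies:
    # remote deuterons: weak effective coupling, no decoupling applied
    return ISpecies(
        coupling=DipolarCoupling(
            0.35, polar_angles=(0.8, 1.1), residual_scale=1.0
        ),
        flips=FlipProcess(spin_I=1, t1_flip_time=DEUTERON_T1_MS),
        label="2H",
        cp_partner=False,
        on_pulse_channel=False,
    )


def _log_grid(start, stop, num):
    return tuple(np.geomspace(start, stop, num))


def scenario_config(scenario: str, seed: int) -> SequenceConfig:
    """Sequence configuration of a named scenario."""
    if scenario == "rigid_rider":
        return SequenceConfig(
            tau_m_grid=_log_grid(0.5, 150.0, 12),
            seed=seed,
            csa=AMINE_CSA,
            n_rotor_cycles=RIDER_ROTOR_CYCLES,
            species=(_proton_species(),),
            anti_phase_fraction=0.4,
            orientation_count=512,
            mc_draws=20000,
            t1_s=1e6,
        )
    if scenario == "z_filtered":
        cfg = scenario_config("rigid_rider", seed)
        return SequenceConfig(
            **{**_as_kwargs(cfg), "z_filter_delay": 100.0}
        )
    if scenario == "protein_two_rider":
        return SequenceConfig(
            tau_m_grid=_log_grid(1.0, 8000.0, 16),
            seed=seed,
            csa=AMINE_CSA,
            n_rotor_cycles=RIDER_ROTOR_CYCLES,
            species=(_proton_species(), _deuteron_species()),
            anti_phase_fraction=0.3,
            tau_sd=SPIN_DIFFUSION_MS,
            orientation_count=512,
            mc_draws=20000,
        )
    if scenario == "exchange_only":
        return SequenceConfig(
            tau_m_grid=_log_grid(0.1, 400.0, 16),
            seed=seed,
            csa=CARBONYL_CSA,
            exchange=ExchangeModel.symmetric_two_site(
                0.05, reorientation=(0.0, 0.2, 0.0)
            ),
            orientation_count=10000,
            orientation_scheme="random",
            mc_draws=10000,
            t1_s=1e6,
        )
    if scenario == "dipolar_flipflop":
        return SequenceConfig(
            tau_m_grid=_log_grid(0.5, 100.0, 6),
            seed=seed,
            variant="dipolar_codex",
            component="cos",
            csa=AMINE_CSA,
            species=(
                ISpecies(
                    coupling=DipolarCoupling(
                        NH_COUPLING, polar_angles=(1.2, 0.4),
                        residual_scale=1.0,
                    ),
                    flips=FlipProcess(
                        spin_I=0.5, flipflop_time=PROTON_FLIPFLOP_MS
                    ),
                    label="1H",
                    cp_partner=True,
                ),
            ),
            flips_within_periods=True,
            orientation_count=64,
            mc_draws=1200,
            t1_s=1e6,
        )
    raise ConfigError(f"unknown scenario {scenario!r}")


def _as_kwargs(cfg: SequenceConfig) -> dict:
    from dataclasses import fields

    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}


def _truth(scenario: str, config: SequenceConfig) -> dict:
    truth: dict = {"scenario": scenario, "seed": config.seed}
    if scenario == "exchange_only":
        truth["plateau_ratio"] = equilibrium_plateau_reference(config)
        truth["tau_c_ms"] = 1.0 / (2.0 * 0.05)
        truth["cos_sin_shapes_equal"] = True
    elif scenario in ("rigid_rider", "z_filtered"):
        truth["anti_phase_fraction"] = config.anti_phase_fraction
        truth["flipflop_time_ms"] = PROTON_FLIPFLOP_MS
        truth["rider_free"] = scenario == "z_filtered"
    elif scenario == "protein_two_rider":
        truth["tau_sd_ms"] = config.tau_sd
        truth["fast_timescales_ms"] = [PROTON_FLIPFLOP_MS / 2.0,
                                       DEUTERON_T1_MS]
    elif scenario == "dipolar_flipflop":
        truth["flipflop_time_ms"] = PROTON_FLIPFLOP_MS
        truth["ntr_ms"] = config.ntr
        truth["s0_suppressed_vs_frozen"] = True
    return truth


SCENARIOS = (
    "rigid_rider",
    "z_filtered",
    "protein_two_rider",
    "exchange_only",
    "dipolar_flipflop",
)


def generate_fixture(scenario: str, seed: int, outdir) -> dict[str, Path]:
    """Simulate a scenario and write config, curve and ground truth.

    Returns the mapping of artifact names to file paths.  All randomness
    derives from ``seed``; identical calls produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = scenario_config(scenario, seed)
    curve = simulate_mixing_curve(config)
    curve.metadata["scenario"] = scenario

    paths = {
        "config": outdir / f"{scenario}_config.yaml",
        "curve": outdir / f"{scenario}_curve.tsv",
        "truth": outdir / f"{scenario}_truth.json",
    }
    paths["config"].write_text(dump_config(config))
    write_curve(curve, paths["curve"])
    paths["truth"].write_text(
        json.dumps(_truth(scenario, config), indent=2, sort_keys=True) + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# closed-form synthetic curves for fit validation
# ---------------------------------------------------------------------------


def model_curve(
    tau_m,
    i0: float = 1.0,
    s_inf: float = 0.6,
    tau_c: float = 20.0,
    a_slow: float = 0.0,
    tau_sd: float | None = None,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    component: str = "cos",
) -> MixingCurve:
    """Plateau-exponential curve with optional slow component and noise.

    With ``a_slow > 0`` the model is
    ``i0 * [a_fast e^{-t/tau_c} + a_slow e^{-t/tau_sd} + s_inf]`` with
    ``a_fast = 1 - a_slow - s_inf``.  Gaussian noise of standard deviation
    ``noise * i0`` is added when requested (an rng is then required).
    """
    tau_m = np.asarray(tau_m, dtype=float)
    if a_slow:
        if tau_sd is None:
            raise ConfigError("a_slow > 0 requires tau_sd")
        a_fast = 1.0 - a_slow - s_inf
        y = i0 * (
            a_fast * np.exp(-tau_m / tau_c)
            + a_slow * np.exp(-tau_m / tau_sd)
            + s_inf
        )
    else:
        y = i0 * ((1.0 - s_inf) * np.exp(-tau_m / tau_c) + s_inf)
    err = None
    if noise > 0:
        if rng is None:
            raise ConfigError("noise requires a random generator")
        y = y + rng.normal(0.0, noise * i0, size=tau_m.shape)
        err = np.full(tau_m.shape, noise * i0)
    kwargs = {component: y, f"{component}_err": err}
    truth = {
        "i0": i0, "s_inf": s_inf, "tau_c": tau_c,
        "a_slow": a_slow, "tau_sd": tau_sd, "noise": noise,
    }
    return MixingCurve(tau_m, metadata={"truth": truth}, **kwargs)


def model_curve_replicates(
    n_replicates: int,
    tau_m,
    seed: int,
    **model_kwargs,
):
    """Generator of seeded noisy replicates of one model curve."""
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        yield model_curve(tau_m, rng=rng, **model_kwargs)
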