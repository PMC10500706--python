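"""Assembled CODEX experiments: mixing-time curves and S0-vs-NTR scans.

Pipeline per crystallite x Monte-Carlo draw
-------------------------------------------
1. build the post-CP state (in-phase ``1-a``, anti-phase ``-a``);
2. optional Z filter (kills anti-phase pathways, T1 decay of the stored
   in-phase part);
3. dephasing evolution under the recoupled CSA phase and the dipolar phases
   of all I species (optionally modulated by flips *within* the period);
4. storage of one component (COS or SIN);
5. mixing time: I-spin flips, site exchange, S-spin T1 decay and an optional
   phenomenological spin-diffusion decay;
6. rephasing evolution with the post-mixing levels/site and detection.

The species coupled through cross polarization (the CP partner, typically
an amide proton) is carried through the in-phase/anti-phase product-operator
bookkeeping; any further I species (e.g. remote deuterons) act as
uncorrelated stochastic local fields whose dipolar phases add to the
transverse precession.  The curve is multiplied by ``exp(-tau_m/T1S)`` and
divided back out through :func:`t1_normalize`, mirroring the experimental
T1-normalization protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import codex_engine as engine
from .codex_engine import Component
from .errors import ConfigError, DataError, DomainError
from .spin_system import (
    CsaTensor,
    DipolarCoupling,
    OrientationSet,
    PulseTrain,
    euler_matrix,
    powder_orientations,
)
from . import spin_system
from .stochastic_dynamics import ExchangeModel, FlipProcess, sample_flip_trajectory

__all__ = [
    "ISpecies",
    "SequenceConfig",
    "MixingCurve",
    "NtrCurve",
    "simulate_mixing_curve",
    "simulate_s0_vs_ntr",
    "t1_normalize",
    "analytic_exchange_ratios",
    "analytic_rider_ratios",
    "antiphase_amplitude_ratio",
    "ExchangeRatios",
    "RiderRatios",
    "equilibrium_plateau_reference",
]


@dataclass(frozen=True)
class ISpecies:
    """One I-spin species dipolar-coupled to the observed S spin.

    ``cp_partner`` marks the species whose anti-phase coherence is created
    by cross polarization (carried through the product-operator state);
    ``on_pulse_channel`` states whether the I-channel recoupling pulses of
    the dipolar variant act on this species' channel.
    """

    coupling: DipolarCoupling
    flips: FlipProcess
    label: str = "1H"
    cp_partner: bool = False
    on_pulse_channel: bool = True


@dataclass(frozen=True)
class SequenceConfig:
    """Complete description of one simulated CODEX experiment.

    Times in ms.  Defaults follow a typical 20 kHz MAS setup with a 2 ms
    de(re)phasing period (``mas_period = 0.05``, ``n_rotor_cycles = 40``)
    and a fixed read-back echo delay ``tau_r = 1`` ms (bookkeeping only).
    """

    tau_m_grid: tuple[float, ...]
    seed: int
    variant: str = "csa_codex"
    component: str = "both"
    csa: CsaTensor | None = None
    species: tuple[ISpecies, ...] = ()
    exchange: ExchangeModel | None = None
    anti_phase_fraction: float = 0.0
    z_filter_delay: float = 0.0
    t1_s: float = 5000.0
    t2_s: float = 1.0
    tau_sd: float | None = None
    tau_r: float = 1.0
    mas_period: float = 0.05
    n_rotor_cycles: int = 40
    orientation_count: int = 100
    orientation_scheme: str = "fibonacci"
    mc_draws: int = 1000
    flips_within_periods: bool = False

    def __post_init__(self):
        grid = np.asarray(self.tau_m_grid, dtype=float)
        if grid.size == 0:
            raise ConfigError("mixing-time grid must not be empty")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ConfigError("mixing-time grid must be positive and increasing")
        object.__setattr__(self, "tau_m_grid", tuple(grid))
        if self.variant not in ("csa_codex", "dipolar_codex"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.component not in ("cos", "sin", "both"):
            raise ConfigError(f"unknown component {self.component!r}")
        if self.mc_draws < 1:
            raise ConfigError("mc_draws must be >= 1")
        if self.z_filter_delay < 0:
            raise ConfigError("z_filter_delay must be >= 0")
        if not 0.0 <= self.anti_phase_fraction <= 1.0:
            raise DomainError("anti_phase_fraction must lie in [0, 1]")
        if self.t1_s <= 0 or self.t2_s <= 0:
            raise DomainError("relaxation times must be positive")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")

    def pulse_train(self) -> PulseTrain:
        if self.variant == "csa_codex":
            return PulseTrain.csa_codex(self.mas_period, self.n_rotor_cycles)
        return PulseTrain.dipolar_codex(self.mas_period, self.n_rotor_cycles)

    @property
    def ntr(self) -> float:
        return self.n_rotor_cycles * self.mas_period

    def partner_index(self) -> int | None:
        """Index of the CP-partner species (first flagged, else the first
        species when the anti-phase fraction is nonzero)."""
        for i, sp in enumerate(self.species):
            if sp.cp_partner:
                return i
        return 0 if self.species else None


@dataclass
class MixingCurve:
    """Mixing-time grid with COS and/or SIN intensities and MC errors."""

    tau_m: np.ndarray
    cos: np.ndarray | None = None
    cos_err: np.ndarray | None = None
    sin: np.ndarray | None = None
    sin_err: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau_m = np.asarray(self.tau_m, dtype=float)
        if self.tau_m.ndim != 1 or self.tau_m.size == 0:
            raise DataError("tau_m must be a nonempty 1-d grid")
        if np.any(np.diff(self.tau_m) <= 0):
            raise DataError("tau_m must be strictly increasing")
        for name in ("cos", "cos_err", "sin", "sin_err"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != self.tau_m.shape:
                    raise DataError(f"column {name} does not match the grid")
                if not np.all(np.isfinite(arr)):
                    raise DataError(f"column {name} contains non-finite values")
                setattr(self, name, arr)
        if self.cos is None and self.sin is None:
            raise DataError("curve needs at least one intensity column")

    def intensity(self, component) -> np.ndarray:
        comp = Component.coerce(component)
        arr = self.cos if comp is Component.COS else self.sin
        if arr is None:
            raise DataError(f"curve has no {comp.value} column")
        return arr

    def error(self, component) -> np.ndarray | None:
        comp = Component.coerce(component)
        return self.cos_err if comp is Component.COS else self.sin_err

    def s0(self, component="cos") -> float:
        """Intensity at the first (shortest) mixing time."""
        return float(self.intensity(component)[0])

    @property
    def components(self) -> tuple[str, ...]:
        present = []
        if self.cos is not None:
            present.append("cos")
        if self.sin is not None:
            present.append("sin")
        return tuple(present)


@dataclass
class NtrCurve:
    """Initial CODEX amplitude as a function of the de(re)phasing length."""

    ntr_values: np.ndarray  # ms
    s0_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ntr_values = np.asarray(self.ntr_values, dtype=float)
        self.s0_values = np.asarray(self.s0_values, dtype=float)
        if self.ntr_values.shape != self.s0_values.shape:
            raise DataError("NTR and S0 arrays must have matching shapes")


# ---------------------------------------------------------------------------
# phase tables
# ---------------------------------------------------------------------------


def _site_rotations(exchange: ExchangeModel | None):
    if exchange is None:
        return [np.eye(3)]
    if exchange.site_orientations is None:
        raise ConfigError("exchange model must define per-site orientations")
    return [euler_matrix(*eul) for eul in exchange.site_orientations]


def _species_train(train: PulseTrain, sp: ISpecies) -> PulseTrain:
    """Pulse train as seen by one I species: the I-channel pulses apply only
    to the species on the pulsed channel."""
    if sp.on_pulse_channel or not train.i_channel_pulses:
        return train
    return PulseTrain(
        train.mas_period,
        train.n_rotor_cycles,
        s_channel_pulses=train.s_channel_pulses,
        i_channel_pulses=(),
        variant=train.variant,
    )


class _PhaseTables:
    """Recoupled phases and Fourier coefficients per orientation x site."""

    def __init__(self, config: SequenceConfig, orientations: OrientationSet):
        train = config.pulse_train()
        site_rots = _site_rotations(config.exchange)
        n_or, n_site = len(orientations), len(site_rots)
        self.train = train
        self.n_sites = n_site

        rot_or = spin_system.euler_matrices(orientations.orientations)

        def tables(interaction, toggles):
            phases = np.zeros((n_or, n_site))
            coeffs = np.zeros((n_or, n_site, 5))
            tensor = interaction.tensor_in_crystallite()
            for j, rs in enumerate(site_rots):
                t_site = rs @ tensor @ rs.T
                rotated = np.einsum("nab,bc,ndc->nad", rot_or, t_site, rot_or)
                c = spin_system.mas_fourier_coefficients_batch(rotated)
                coeffs[:, j] = c
                phases[:, j] = spin_system.integrate_train_batch(
                    c, train.mas_period, train.duration, toggles
                )
            return phases, coeffs

        if config.csa is not None:
            self.phi_csa, self.csa_coeffs = tables(
                config.csa, train.toggle_times(config.csa)
            )
        else:
            self.phi_csa = np.zeros((n_or, n_site))
            self.csa_coeffs = None

        self.phi_d_unit = []
        self.d_coeffs = []
        self.species_toggles = []
        for sp in config.species:
            sp_train = _species_train(train, sp)
            toggles = sp_train.toggle_times(sp.coupling)
            phases, coeffs = tables(sp.coupling, toggles)
            self.phi_d_unit.append(phases)
            self.d_coeffs.append(coeffs)
            self.species_toggles.append(toggles)


# ---------------------------------------------------------------------------
# Monte-Carlo helpers
# ---------------------------------------------------------------------------


def _categorical_rows(rng, matrix, row_index):
    """Sample, for each draw, a category from the matrix row selected by
    ``row_index`` (vectorized inverse-CDF sampling)."""
    cdf = np.cumsum(matrix, axis=1)
    u = rng.uniform(size=row_index.shape[0])
    return np.argmax(u[:, None] < cdf[row_index], axis=1)


def _evolve(amps, phi_csa, phi_d):
    """Apply the de(re)phasing rotation to (n, 4) amplitude arrays."""
    u = engine.evolution_matrix(phi_csa, phi_d)
    return np.einsum("...ij,...j->...i", u, amps)


def _period_phases_with_flips(config, tables, rng, orient_idx, site_idx,
                              start_levels):
    """Per-draw dephasing/rephasing phases when flips occur within the
    period; returns (csa-like shift, partner dipolar phase, end levels)."""
    n = orient_idx.shape[0]
    partner = config.partner_index()
    duration = tables.train.duration
    shift = np.zeros(n)
    phi_d = np.zeros(n)
    end_levels = np.empty((len(config.species), n))
    for k, sp in enumerate(config.species):
        mref = sp.flips.reference_level
        toggles = tables.species_toggles[k]
        for i in range(n):
            traj = sample_flip_trajectory(
                sp.flips, duration, start_level=start_levels[k, i], rng=rng
            )
            phi = spin_system.integrate_train(
                tables.d_coeffs[k][orient_idx[i], site_idx[i]],
                tables.train.mas_period,
                duration,
                toggles,
                level_trajectory=traj,
            )
            end_levels[k, i] = traj.end_level
            if k == partner:
                phi_d[i] = phi
            else:
                shift[i] = shift[i] + phi
    return shift, phi_d, end_levels


def simulate_mixing_curve(
    config: SequenceConfig, independent_points: bool = False
) -> MixingCurve:
    """Powder- and Monte-Carlo-averaged, T1-normalized mixing-time curve.

    Both the COS and the SIN branch are propagated from the same draws when
    ``component='both'``, so their Monte-Carlo fluctuations are paired.
    Reported errors are standard errors over draws.

    With ``independent_points=True`` every grid point is simulated from a
    fresh draw set (seed derived from the configured seed), mirroring the
    experimental protocol in which each mixing time is a separate
    acquisition; point-wise errors are then statistically independent,
    which calibrates weighted fits of the resulting curve.
    """
    if independent_points and len(config.tau_m_grid) > 1:
        parts = []
        for k, tm in enumerate(config.tau_m_grid):
            sub = replace(
                config,
                tau_m_grid=(tm,),
                seed=(config.seed + 7919 * (k + 1)) % (2**31),
            )
            parts.append(simulate_mixing_curve(sub))
        first = parts[0]
        out = MixingCurve.__new__(MixingCurve)
        out.tau_m = np.asarray(config.tau_m_grid, dtype=float)
        out.metadata = dict(first.metadata)
        out.metadata["independent_points"] = True
        out.metadata["seed"] = config.seed
        for name in ("cos", "cos_err", "sin", "sin_err"):
            vals = [getattr(p, name) for p in parts]
            setattr(
                out, name,
                None if vals[0] is None else np.array([v[0] for v in vals]),
            )
        return out

    rng = np.random.default_rng(config.seed)
    orientations = powder_orientations(
        config.orientation_count, config.orientation_scheme, config.seed
    )
    tables = _PhaseTables(config, orientations)
    n = config.mc_draws
    n_or = len(orientations)
    tau = np.asarray(config.tau_m_grid)
    partner = config.partner_index()
    a = config.anti_phase_fraction

    # stratified powder assignment (uniform weights in both schemes)
    orient_idx = np.arange(n) % n_or

    if config.exchange is not None:
        site0 = rng.choice(
            config.exchange.site_count, size=n, p=config.exchange.populations
        )
    else:
        site0 = np.zeros(n, dtype=int)

    # initial I levels, uniform (stationary for the flip processes used)
    level_arrays = []
    start_levels = np.empty((len(config.species), n))
    for k, sp in enumerate(config.species):
        lv = np.array(sp.flips.levels)
        level_arrays.append(lv)
        start_levels[k] = lv[rng.integers(len(lv), size=n)]

    # --- dephasing phases ------------------------------------------------
    if config.flips_within_periods and config.species:
        shift0, phi_d0, levels_after_deph = _period_phases_with_flips(
            config, tables, rng, orient_idx, site0, start_levels
        )
    else:
        shift0 = np.zeros(n)
        phi_d0 = np.zeros(n)
        for k, sp in enumerate(config.species):
            contrib = (
                start_levels[k] / sp.flips.reference_level
            ) * tables.phi_d_unit[k][orient_idx, site0]
            if k == partner:
                phi_d0 = contrib
            else:
                shift0 = shift0 + contrib
        levels_after_deph = start_levels

    phi_csa0 = tables.phi_csa[orient_idx, site0] + shift0

    # --- initial state, Z filter, dephasing evolution --------------------
    amps = np.zeros((n, 4))
    amps[:, 0] = 1.0 - a
    if partner is not None:
        mref = config.species[partner].flips.reference_level
        # The anti-phase amplitude created by CP is odd in the orientation-
        # dependent coupling; without this correlation the pathway would
        # cancel between crystallites.  Its sign is fixed so that the
        # anti-phase interference appears as the experimentally observed
        # fast decay of the mixing-time curve.
        coupling_sign = -np.sign(tables.phi_d_unit[partner][orient_idx, site0])
        coupling_sign[coupling_sign == 0.0] = 1.0
        amps[:, 3] = -a * coupling_sign * start_levels[partner] / mref
    elif a:
        amps[:, 3] = -a
    if config.z_filter_delay > 0:
        amps[:, :2] *= math.exp(-config.z_filter_delay / config.t1_s)
        amps[:, 2:] *= math.exp(-config.z_filter_delay / config.t2_s)
    evolved = _evolve(amps, phi_csa0, phi_d0)

    # storage + readout: the stored quadrature pair re-enters on the common
    # readout axis (x family); the SIN branch therefore accumulates the
    # sine quadrature during rephasing and is detected as Sy.
    branches: dict[str, np.ndarray] = {}
    if config.component in ("cos", "both"):
        stored = evolved.copy()
        stored[:, (1, 3)] = 0.0
        branches["cos"] = stored
    if config.component in ("sin", "both"):
        stored = np.zeros_like(evolved)
        stored[:, 0] = evolved[:, 1]
        stored[:, 2] = evolved[:, 3]
        branches["sin"] = stored

    # --- mixing + rephasing per grid point -------------------------------
    results = {name: (np.empty(tau.size), np.empty(tau.size))
               for name in branches}
    level_index = [
        {m: i for i, m in enumerate(lv)} for lv in level_arrays
    ]
    for it, tm in enumerate(tau):
        if config.exchange is not None:
            p_site = config.exchange.transition_matrix(tm)
            site1 = _categorical_rows(rng, p_site, site0)
        else:
            site1 = site0

        levels_reph = np.empty_like(levels_after_deph)
        for k, sp in enumerate(config.species):
            t_lv = sp.flips.transition_matrix(tm)
            idx0 = np.array(
                [level_index[k][m] for m in levels_after_deph[k]]
            )
            idx1 = _categorical_rows(rng, t_lv, idx0)
            levels_reph[k] = level_arrays[k][idx1]

        if config.flips_within_periods and config.species:
            shift1, phi_d1, _ = _period_phases_with_flips(
                config, tables, rng, orient_idx, site1, levels_reph
            )
        else:
            shift1 = np.zeros(n)
            phi_d1 = np.zeros(n)
            for k, sp in enumerate(config.species):
                contrib = (
                    levels_reph[k] / sp.flips.reference_level
                ) * tables.phi_d_unit[k][orient_idx, site1]
                if k == partner:
                    phi_d1 = contrib
                else:
                    shift1 = shift1 + contrib

        phi_csa1 = tables.phi_csa[orient_idx, site1] + shift1

        decay = math.exp(-tm / config.t1_s)
        if config.tau_sd is not None:
            decay *= math.exp(-tm / config.tau_sd)

        for name, stored in branches.items():
            out = _evolve(stored, phi_csa1, phi_d1)
            sig = out[:, 0] if name == "cos" else out[:, 1]
            sig = sig * decay
            results[name][0][it] = sig.mean()
            results[name][1][it] = sig.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0

    metadata = {
        "variant": config.variant,
        "component": config.component,
        "ntr_ms": config.ntr,
        "mas_period_ms": config.mas_period,
        "tau_r_ms": config.tau_r,
        "seed": config.seed,
        "mc_draws": config.mc_draws,
        "orientations": config.orientation_count,
        "t1_normalized": True,
    }
    raw = MixingCurve(
        tau,
        cos=results.get("cos", (None,))[0] if "cos" in results else None,
        cos_err=results["cos"][1] if "cos" in results else None,
        sin=results["sin"][0] if "sin" in results else None,
        sin_err=results["sin"][1] if "sin" in results else None,
        metadata=metadata,
    )
    # T1-relaxation reference measured with fixed tau_r: a bare exponential
    t1_ref = MixingCurve(tau, cos=np.exp(-tau / config.t1_s),
                         sin=np.exp(-tau / config.t1_s))
    return t1_normalize(raw, t1_ref)


def simulate_s0_vs_ntr(config: SequenceConfig, n_values) -> NtrCurve:
    """Initial amplitude S0 as a function of the de(re)phasing length.

    Runs the mixing-curve pipeline at the shortest mixing time for each
    number of rotor cycles N; the resulting decay with NTR is the
    recoupled-interaction analogue of a Hahn-echo decay.
    """
    n_values = [int(v) for v in n_values]
    if config.variant == "dipolar_codex" and any(v % 2 for v in n_values):
        raise ConfigError("dipolar_codex requires even rotor-cycle counts")
    comp = "cos" if config.component == "both" else config.component
    s0 = []
    for nv in n_values:
        sub = replace(
            config,
            n_rotor_cycles=nv,
            tau_m_grid=(config.tau_m_grid[0],),
            component=comp,
        )
        curve = simulate_mixing_curve(sub)
        s0.append(curve.s0(comp))
    ntr_ms = np.array(n_values, dtype=float) * config.mas_period
    return NtrCurve(ntr_ms, np.array(s0),
                    metadata={"component": comp, "n_values": n_values})


def t1_normalize(raw: MixingCurve, t1_curve: MixingCurve) -> MixingCurve:
    """Divide a mixing-time curve by the matched T1-relaxation curve.

    Pointwise ratio per component with first-order error propagation in
    quadrature.  Grids must agree exactly.
    """
    if raw.tau_m.shape != t1_curve.tau_m.shape or not np.allclose(
        raw.tau_m, t1_curve.tau_m
    ):
        raise DataError("mixing-time grids of the two curves do not match")
    out = MixingCurve.__new__(MixingCurve)
    out.tau_m = raw.tau_m.copy()
    out.metadata = dict(raw.metadata)
    out.cos = out.cos_err = out.sin = out.sin_err = None
    for name in ("cos", "sin"):
        num = getattr(raw, name)
        if num is None:
            continue
        den = getattr(t1_curve, name)
        if den is None:
            den = t1_curve.intensity(t1_curve.components[0])
        if np.any(den == 0.0):
            raise DataError("zero denominator in T1 normalization")
        ratio = num / den
        setattr(out, name, ratio)
        num_err = getattr(raw, f"{name}_err")
        den_err = getattr(t1_curve, f"{name}_err")
        if num_err is not None or den_err is not None:
            rel_a = num_err / num if num_err is not None else 0.0
            rel_b = den_err / den if den_err is not None else 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                err = np.abs(ratio) * np.sqrt(
                    np.square(rel_a) + np.square(rel_b)
                )
            setattr(out, f"{name}_err", np.where(np.isfinite(err), err, 0.0))
    return out


# ---------------------------------------------------------------------------
# closed-form reference ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExchangeRatios:
    """Long-over-short mixing-time amplitude ratios for pure exchange."""

    classical: float  # COS + SIN
    cos_ratio: float
    sin_ratio: float
    equilibrium_average: float  # all three after averaging conjugate pairs


def analytic_exchange_ratios(phi: float, delta_phi: float) -> ExchangeRatios:
    """Plateau ratios of a single ordered site pair (phi, phi + delta_phi).

    The classical (summed) ratio is ``cos(delta_phi)`` identically.  The
    COS and SIN components carry site-antisymmetric corrections
    ``-tan(phi) sin(delta_phi)`` and ``+cot(phi) sin(delta_phi)`` that
    cancel pairwise in dynamic equilibrium, restoring ``cos(delta_phi)``
    for all three.
    """
    c, s = math.cos(phi), math.sin(phi)
    cd, sd = math.cos(delta_phi), math.sin(delta_phi)
    if abs(c) < 1e-12:
        raise DomainError("cos(phi) = 0: COS ratio undefined")
    if abs(s) < 1e-12:
        raise DomainError("sin(phi) = 0: SIN ratio undefined")
    return ExchangeRatios(
        classical=cd,
        cos_ratio=cd - (s / c) * sd,
        sin_ratio=cd + (c / s) * sd,
        equilibrium_average=cd,
    )


@dataclass(frozen=True)
class RiderRatios:
    """Plateau ratios of the anti-phase (RIDER) pathway, I = 1/2."""

    cos_ratio: float
    sin_ratio: float


def analytic_rider_ratios(phi_csa: float) -> RiderRatios:
    """Plateau ratios of a pure anti-phase initial state under I = 1/2 flips.

    The SIN ratio is 1/2 independent of the CSA phase; the COS ratio is
    ``cos^2(phi) / (cos^2(phi) - sin^2(phi))``.  The squared (rather than
    double-angle) reading of the component amplitudes is fixed by direct
    propagation through the four-operator evolution; see the brute-force
    enumeration oracle in the test suite and the methods note.
    """
    c2 = math.cos(phi_csa) ** 2
    den = 2.0 * c2 - 1.0  # cos^2 - sin^2 = cos(2 phi)
    if abs(den) < 1e-12:
        raise DomainError(
            "phi_csa = pi/4 (mod pi/2): COS plateau ratio is singular"
        )
    return RiderRatios(cos_ratio=c2 / den, sin_ratio=0.5)


def antiphase_amplitude_ratio(
    phi_csa: float, phi_d: float, component="sin"
) -> float:
    """Anti-phase over in-phase detected amplitude, per component.

    Propagates a unit in-phase and a unit anti-phase initial term through
    dephasing and rephasing at fixed phases within the stored-component
    product-operator bookkeeping (no storage transport, no mixing change)
    and returns the amplitude ratio.  In the small-phase limit the ratio is
    tan(2·phi_d) ≈ 2·tan(phi_d) for the SIN component and ≈ tan(phi_d) for
    COS: the anti-phase coherence contributes about twice as strongly to
    SIN, which is why that component is more prone to the RIDER artifact.
    """
    from .spin_system import PhasePair

    phases = PhasePair(phi_csa, phi_d)
    comp = Component.coerce(component)

    def detected(seed: np.ndarray) -> float:
        state = engine.CoherenceState(seed.reshape(1, 4).copy())
        state = engine.evolve_period(state, phases)
        state = engine.project_component(state, comp)
        state = engine.evolve_period(state, phases)
        return engine.detect(state, comp)

    in_amp = detected(np.array([1.0, 0.0, 0.0, 0.0]))
    anti_amp = detected(np.array([0.0, 0.0, 0.0, -1.0]))
    if in_amp == 0.0:
        raise DomainError("in-phase amplitude vanishes at these phases")
    return anti_amp / in_amp


def equilibrium_plateau_reference(
    config: SequenceConfig, orientation_count: int = 100_000
) -> float:
    """Deterministic equilibrium-averaged plateau ratio cos(delta_phi).

    Powder- and pair-averaged ``sum_o w_o sum_ij p_i p_j cos(phi_j - phi_i)``
    over the CSA phase tables; this is the exact long-mixing-time limit of
    the classical (COS + SIN) curve for exchange without dipolar phases.
    Evaluated on a large deterministic quasi-uniform powder so the value is
    effectively the continuous-powder limit, independent of the Monte-Carlo
    orientation sampling of the simulation it is compared against.
    """
    if config.exchange is None:
        return 1.0
    orientations = powder_orientations(orientation_count, "fibonacci")
    tables = _PhaseTables(config, orientations)
    p = np.asarray(config.exchange.populations)
    phi = tables.phi_csa  # (n_or, n_sites)
    delta = phi[:, None, :] - phi[:, :, None]
    pair = np.einsum("i,j,oij->o", p, p, np.cos(delta))
    return float(np.dot(orientations.weights, pair))
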