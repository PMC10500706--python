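"""Interaction tensors, pulse trains and recoupled precession phases.

Physical picture
----------------
Under magic-angle spinning (MAS) the first-order anisotropic frequency of a
chemical-shift-anisotropy (CSA) or heteronuclear dipolar interaction is a
trigonometric polynomial in the rotor phase with harmonics 1 and 2, which
averages to zero over a full rotor period.  A train of rotor-synchronized
pi pulses spaced by half a rotor period toggles the sign of the interaction
in the toral frame and thereby *recouples* it: the phase accumulated over
the de(re)phasing period no longer vanishes.  The phases accumulated under
the CSA and dipolar interactions during one de(re)phasing period are the two
numbers the CODEX bookkeeping needs (``PhasePair``).

Conventions
-----------
* times in ms, frequencies in kHz, phases in rad (accumulated as 2*pi*f*t);
* Euler rotations are active z-y-z: ``R(alpha, beta, gamma) = Rz(alpha) @
  Ry(beta) @ Rz(gamma)``;
* the rotor spins about its z axis, which is tilted from the static field
  by the magic angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "MAGIC_ANGLE",
    "CsaTensor",
    "DipolarCoupling",
    "PulseTrain",
    "OrientationSet",
    "PhasePair",
    "anisotropic_frequency",
    "recoupled_phase",
    "powder_orientations",
    "euler_matrix",
    "fourier_coefficients",
    "mas_fourier_coefficients",
    "integrate_train",
    "segment_phase",
]

#: arccos(1/sqrt(3)) — rotor axis tilt from the static field.
MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))

_TWO_PI = 2.0 * math.pi


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active z-y-z Euler rotation matrix."""
    return _rot_z(alpha) @ _rot_y(beta) @ _rot_z(gamma)


def _canonical_angle(angle: float) -> float:
    """Map an angle to [0, 2*pi)."""
    return float(angle) % _TWO_PI


@dataclass(frozen=True)
class CsaTensor:
    """Traceless chemical-shift-anisotropy tensor.

    Parameters
    ----------
    anisotropy:
        Largest principal value of the traceless tensor (kHz); the isotropic
        part plays no role in the recoupled phase and is omitted.
    asymmetry:
        Haeberlen asymmetry parameter, in [0, 1].
    euler_angles:
        z-y-z Euler angles (rad) carrying the tensor principal-axis system
        into the crystallite frame.
    """

    anisotropy: float
    asymmetry: float = 0.0
    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.anisotropy):
            raise DomainError("CSA anisotropy must be finite")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise DomainError(
                f"CSA asymmetry must lie in [0, 1], got {self.asymmetry}"
            )
        object.__setattr__(
            self,
            "euler_angles",
            tuple(_canonical_angle(a) for a in self.euler_angles),
        )

    def tensor_in_crystallite(self) -> np.ndarray:
        """3x3 traceless tensor expressed in the crystallite frame (kHz)."""
        d, eta = self.anisotropy, self.asymmetry
        pas = np.diag([-d * (1.0 + eta) / 2.0, -d * (1.0 - eta) / 2.0, d])
        r = euler_matrix(*self.euler_angles)
        return r @ pas @ r.T


@dataclass(frozen=True)
class DipolarCoupling:
    """Heteronuclear S–I dipolar coupling, axially symmetric by nature.

    ``residual_scale`` models imperfect heteronuclear decoupling during the
    de(re)phasing periods: the recoupled coupling that survives decoupling is
    ``residual_scale * coupling_constant``.  It is a single phenomenological
    multiplier; no explicit decoupling sequence is simulated.
    """

    coupling_constant: float  # kHz, full rigid-limit anisotropy
    polar_angles: tuple[float, float] = (0.0, 0.0)  # (beta, gamma) of S–I vector
    residual_scale: float = 1.0

    def __post_init__(self):
        if self.coupling_constant < 0:
            raise DomainError("dipolar coupling constant must be >= 0")
        if not 0.0 <= self.residual_scale <= 1.0:
            raise DomainError("residual_scale must lie in [0, 1]")
        beta, gamma = self.polar_angles
        object.__setattr__(
            self, "polar_angles", (_canonical_angle(beta), _canonical_angle(gamma))
        )

    def tensor_in_crystallite(self) -> np.ndarray:
        d = self.coupling_constant * self.residual_scale
        pas = np.diag([-d / 2.0, -d / 2.0, d])
        beta, gamma = self.polar_angles
        # internuclear vector at polar angle beta, azimuth gamma
        r = _rot_z(gamma) @ _rot_y(beta)
        return r @ pas @ r.T


Interaction = CsaTensor | DipolarCoupling


@dataclass(frozen=True)
class PulseTrain:
    """Rotor-synchronized recoupling pi-pulse geometry of one de(re)phasing
    period.

    Two variants are supported:

    * ``csa_codex`` — pi pulses on the S (observed) channel every half rotor
      period; recouples both the CSA and any residual S–I dipolar coupling.
    * ``dipolar_codex`` — pi pulses on the I channel every half rotor period
      plus a single S-channel pi pulse at the period midpoint (N even).  The
      midpoint pulse refocuses the CSA completely while the dipolar coupling
      stays recoupled.
    """

    mas_period: float  # TR, ms
    n_rotor_cycles: int  # N
    s_channel_pulses: tuple[float, ...] = ()
    i_channel_pulses: tuple[float, ...] = ()
    variant: str = "csa_codex"

    def __post_init__(self):
        if self.mas_period <= 0:
            raise ConfigError("MAS period must be positive")
        if self.n_rotor_cycles < 1:
            raise ConfigError("need at least one rotor cycle")
        dur = self.duration
        for t in (*self.s_channel_pulses, *self.i_channel_pulses):
            if not 0.0 < t < dur:
                raise ConfigError(
                    f"pulse at {t} ms lies outside the de(re)phasing period "
                    f"(0, {dur} ms)"
                )

    @property
    def duration(self) -> float:
        """N * TR in ms."""
        return self.n_rotor_cycles * self.mas_period

    @classmethod
    def csa_codex(cls, mas_period: float, n_rotor_cycles: int) -> "PulseTrain":
        """S-channel pi pulses at every half rotor period (interior)."""
        half = mas_period / 2.0
        pulses = tuple(k * half for k in range(1, 2 * n_rotor_cycles))
        return cls(mas_period, n_rotor_cycles, s_channel_pulses=pulses,
                   variant="csa_codex")

    @classmethod
    def dipolar_codex(cls, mas_period: float, n_rotor_cycles: int) -> "PulseTrain":
        """I-channel pi pulses at every half rotor period; one S-channel pi
        pulse at the midpoint.  N must be even so each half is an integer
        number of rotor periods and the CSA refocuses exactly."""
        if n_rotor_cycles % 2:
            raise ConfigError(
                "dipolar_codex requires an even number of rotor cycles"
            )
        half = mas_period / 2.0
        mid = n_rotor_cycles  # index of the midpoint in units of TR/2
        i_pulses = tuple(
            k * half for k in range(1, 2 * n_rotor_cycles) if k != mid
        )
        return cls(
            mas_period,
            n_rotor_cycles,
            s_channel_pulses=(mid * half,),
            i_channel_pulses=i_pulses,
            variant="dipolar_codex",
        )

    def toggle_times(self, interaction: Interaction) -> tuple[float, ...]:
        """Times at which the sign of the integrand toggles for the given
        interaction: S-channel pulses invert both CSA and dipolar terms,
        I-channel pulses invert the dipolar term only."""
        if isinstance(interaction, DipolarCoupling):
            return tuple(sorted((*self.s_channel_pulses, *self.i_channel_pulses)))
        return tuple(sorted(self.s_channel_pulses))


@dataclass(frozen=True)
class OrientationSet:
    """Weighted set of crystallite orientations (z-y-z Euler triples)."""

    orientations: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,), nonnegative, sums to 1

    def __post_init__(self):
        ors = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if ors.shape[0] != w.shape[0]:
            raise ConfigError("orientations and weights length mismatch")
        if np.any(w < 0):
            raise ConfigError("orientation weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ConfigError("orientation weights must not all vanish")
        object.__setattr__(self, "orientations", ors)
        object.__setattr__(self, "weights", w / total)

    def __len__(self) -> int:
        return self.orientations.shape[0]


@dataclass(frozen=True)
class PhasePair:
    """Recoupled phases (rad) acquired during one de(re)phasing period."""

    phi_csa: float
    phi_d: float

    def __post_init__(self):
        if not (np.isfinite(self.phi_csa) and np.isfinite(self.phi_d)):
            raise DomainError("phases must be finite")

    def __neg__(self) -> "PhasePair":
        return PhasePair(-self.phi_csa, -self.phi_d)


def _lab_frequency(tensor_cryst: np.ndarray, orientation, rotor_phase) -> float:
    """zz lab-frame component of the crystallite tensor at the given rotor
    phase, with the rotor axis at the magic angle."""
    r_or = euler_matrix(*orientation)
    a_rot = r_or @ tensor_cryst @ r_or.T
    r = _rot_y(MAGIC_ANGLE) @ _rot_z(rotor_phase)
    return float((r @ a_rot @ r.T)[2, 2])


def anisotropic_frequency(
    interaction: Interaction, orientation, rotor_phase: float
) -> float:
    """Instantaneous first-order anisotropic frequency (kHz) under MAS.

    Parameters
    ----------
    interaction:
        CSA tensor or dipolar coupling.
    orientation:
        Euler triple carrying the crystallite frame into the rotor frame.
    rotor_phase:
        Rotor angle in [0, 2*pi).
    """
    if not 0.0 <= rotor_phase < _TWO_PI:
        raise DomainError("rotor phase must lie in [0, 2*pi)")
    return _lab_frequency(
        interaction.tensor_in_crystallite(), tuple(orientation), rotor_phase
    )


def mas_fourier_coefficients(tensor_rotor: np.ndarray) -> np.ndarray:
    """Exact harmonic decomposition of the MAS frequency trajectory.

    ``tensor_rotor`` is the traceless interaction tensor expressed in the
    rotor frame at rotor phase zero.  Returns ``(c0, c1, s1, c2, s2)`` such
    that ``f(theta) = c0 + c1*cos(theta) + s1*sin(theta) + c2*cos(2theta)
    + s2*sin(2theta)`` with ``theta`` the rotor phase.  The trajectory is
    band-limited to the second harmonic, so 8 equidistant samples determine
    it exactly; at the magic angle ``c0`` vanishes to rounding.
    """
    thetas = _TWO_PI * np.arange(8) / 8.0
    tilt = _rot_y(MAGIC_ANGLE)
    samples = np.empty(8)
    for i, th in enumerate(thetas):
        r = tilt @ _rot_z(th)
        samples[i] = (r @ tensor_rotor @ r.T)[2, 2]
    spec = np.fft.rfft(samples) / 8.0
    c0 = spec[0].real
    c1, s1 = 2.0 * spec[1].real, -2.0 * spec[1].imag
    c2, s2 = 2.0 * spec[2].real, -2.0 * spec[2].imag
    return np.array([c0, c1, s1, c2, s2])


def fourier_coefficients(interaction: Interaction, orientation) -> np.ndarray:
    """Harmonic decomposition for an interaction at a crystallite
    orientation; see :func:`mas_fourier_coefficients`."""
    r_or = euler_matrix(*tuple(orientation))
    tensor = r_or @ interaction.tensor_in_crystallite() @ r_or.T
    return mas_fourier_coefficients(tensor)


def euler_matrices(eulers: np.ndarray) -> np.ndarray:
    """Vectorized z-y-z rotation matrices for an (n, 3) array of triples."""
    eulers = np.atleast_2d(np.asarray(eulers, dtype=float))
    a, b, g = eulers[:, 0], eulers[:, 1], eulers[:, 2]
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), \
        np.cos(g), np.sin(g)
    r = np.empty((eulers.shape[0], 3, 3))
    r[:, 0, 0] = ca * cb * cg - sa * sg
    r[:, 0, 1] = -ca * cb * sg - sa * cg
    r[:, 0, 2] = ca * sb
    r[:, 1, 0] = sa * cb * cg + ca * sg
    r[:, 1, 1] = -sa * cb * sg + ca * cg
    r[:, 1, 2] = sa * sb
    r[:, 2, 0] = -sb * cg
    r[:, 2, 1] = sb * sg
    r[:, 2, 2] = cb
    return r


def mas_fourier_coefficients_batch(tensors: np.ndarray) -> np.ndarray:
    """Batched :func:`mas_fourier_coefficients` for (n, 3, 3) rotor-frame
    tensors; returns (n, 5) harmonic coefficients."""
    thetas = _TWO_PI * np.arange(8) / 8.0
    tilt = _rot_y(MAGIC_ANGLE)
    rows = np.stack([(tilt @ _rot_z(th))[2, :] for th in thetas])  # (8, 3)
    samples = np.einsum("kb,nbc,kc->nk", rows, tensors, rows)
    spec = np.fft.rfft(samples, axis=1) / 8.0
    out = np.empty((tensors.shape[0], 5))
    out[:, 0] = spec[:, 0].real
    out[:, 1], out[:, 2] = 2.0 * spec[:, 1].real, -2.0 * spec[:, 1].imag
    out[:, 3], out[:, 4] = 2.0 * spec[:, 2].real, -2.0 * spec[:, 2].imag
    return out


def integrate_train_batch(
    coeffs: np.ndarray, mas_period: float, duration: float, toggles
) -> np.ndarray:
    """Batched :func:`integrate_train` without level trajectories.

    ``coeffs`` has shape (n, 5); returns the (n,) recoupled phases.
    """
    breakpoints = np.unique(np.concatenate(([0.0], toggles, [duration])))
    toggle_set = set(np.asarray(toggles, dtype=float))
    signs = np.empty(breakpoints.size - 1)
    s = 1.0
    for j, a in enumerate(breakpoints[:-1]):
        if a in toggle_set:
            s = -s
        signs[j] = s
    theta = breakpoints * (_TWO_PI / mas_period)
    c0, c1, s1, c2, s2 = (coeffs[:, k][:, None] for k in range(5))
    g = (
        c0 * theta
        + c1 * np.sin(theta)
        - s1 * np.cos(theta)
        + (c2 * np.sin(2.0 * theta) - s2 * np.cos(2.0 * theta)) / 2.0
    )
    return mas_period * (np.diff(g, axis=1) * signs).sum(axis=1)


def _phase_antiderivative(coeffs: np.ndarray, theta) -> np.ndarray:
    """G(theta) with dG/dtheta = f(theta); phase over [a, b] in rad equals
    ``TR * (G(theta_b) - G(theta_a))`` for times in ms, f in kHz."""
    c0, c1, s1, c2, s2 = coeffs
    theta = np.asarray(theta, dtype=float)
    return (
        c0 * theta
        + c1 * np.sin(theta)
        - s1 * np.cos(theta)
        + (c2 * np.sin(2.0 * theta) - s2 * np.cos(2.0 * theta)) / 2.0
    )


def segment_phase(
    coeffs: np.ndarray, mas_period: float, t_start, t_end
) -> np.ndarray:
    """Phase (rad) accumulated between two times (ms) of the MAS trajectory
    described by the harmonic coefficients."""
    w = _TWO_PI / mas_period
    g = _phase_antiderivative(coeffs, np.multiply(t_end, w)) - \
        _phase_antiderivative(coeffs, np.multiply(t_start, w))
    return mas_period * g


def integrate_train(
    coeffs: np.ndarray,
    mas_period: float,
    duration: float,
    toggles,
    level_trajectory=None,
) -> float:
    """Integrate a (band-limited) MAS frequency trajectory over one period.

    The integrand sign toggles at every time in ``toggles``; if a level
    trajectory is given the integrand is additionally scaled by the
    instantaneous level factor ``m(t) / |m_ref|``.  Each segment is
    evaluated from the closed-form antiderivative, so the result is exact
    for the first-order trajectory.
    """
    jumps: tuple[float, ...] = ()
    if level_trajectory is not None:
        if level_trajectory.duration < duration - 1e-12:
            raise ConfigError(
                "level trajectory must span the full de(re)phasing period"
            )
        jumps = tuple(
            t for t in level_trajectory.jump_times if 0.0 < t < duration
        )

    breakpoints = np.unique(
        np.concatenate(([0.0], toggles, jumps, [duration]))
    )
    toggle_set = set(toggles)
    sign = 1.0
    total = 0.0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if a in toggle_set:
            sign = -sign
        factor = sign
        if level_trajectory is not None:
            mid = 0.5 * (a + b)
            factor *= (
                level_trajectory.level_at(mid)
                / level_trajectory.reference_level
            )
        if factor != 0.0:
            total += factor * segment_phase(coeffs, mas_period, a, b)
    return float(total)


def recoupled_phase(
    interaction: Interaction,
    orientation,
    train: PulseTrain,
    level_trajectory=None,
) -> float:
    """Precession phase (rad) accumulated over one de(re)phasing period.

    The MAS frequency trajectory is integrated over ``N * TR`` with the sign
    of the integrand toggled at every pi pulse acting on the interaction
    (S-channel pulses toggle both CSA and dipolar terms, I-channel pulses the
    dipolar term only).  If a level trajectory is given — flips of the I spin
    occurring *within* the period — the dipolar integrand is additionally
    scaled by the instantaneous level factor ``m(t) / |m_ref|``.
    """
    if level_trajectory is not None and not isinstance(
        interaction, DipolarCoupling
    ):
        raise ConfigError(
            "level trajectories modulate only the dipolar interaction"
        )
    coeffs = fourier_coefficients(interaction, orientation)
    return integrate_train(
        coeffs,
        train.mas_period,
        train.duration,
        train.toggle_times(interaction),
        level_trajectory=level_trajectory,
    )


_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0


def powder_orientations(
    count: int, scheme: str = "fibonacci", seed: int | None = None
) -> OrientationSet:
    """Reproducible quasi-uniform crystallite orientation set.

    ``fibonacci`` (default) places the (beta, gamma) polar pairs on a
    spherical Fibonacci lattice and sweeps alpha with a second
    low-discrepancy sequence; it is deterministic and ignores the seed.
    ``random`` draws orientations from the uniform (Haar) measure with the
    given seed; it gives statistically identical powder averages.
    """
    if count < 1:
        raise ConfigError("orientation count must be >= 1")
    if scheme == "fibonacci":
        k = np.arange(count)
        z = (2.0 * k + 1.0) / count - 1.0
        beta = np.arccos(z)
        gamma = (_TWO_PI * k / _GOLDEN) % _TWO_PI
        alpha = (_TWO_PI * k * math.sqrt(2.0)) % _TWO_PI
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        alpha = rng.uniform(0.0, _TWO_PI, count)
        gamma = rng.uniform(0.0, _TWO_PI, count)
        beta = np.arccos(rng.uniform(-1.0, 1.0, count))
    else:
        raise ConfigError(f"unknown orientation scheme {scheme!r}")
    orientations = np.column_stack([alpha, beta, gamma])
    weights = np.full(count, 1.0 / count)
    return OrientationSet(orientations, weights)
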