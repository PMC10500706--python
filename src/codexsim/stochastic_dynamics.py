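"""Stochastic I-spin flip trajectories and molecular-exchange dynamics.

The RIDER artifact is driven by flips of the coupled I spin: every level
change during (or between) the de(re)phasing periods alters the dipolar
contribution to the precession phase.  Two microscopic flip channels —
spin-lattice relaxation of I and homonuclear flip-flops (spin diffusion) —
are merged into one effective Markov jump process with summed rate; they are
distinguished only by their configured timescales.

Molecular exchange (the physics CODEX is designed to detect) is modelled as
a continuous-time Markov jump process between sites in dynamic equilibrium.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import ConfigError, DomainError

__all__ = [
    "FlipProcess",
    "FlipTrajectory",
    "ExchangeModel",
    "sample_flip_trajectory",
    "mixing_phase_change",
    "sample_site_trajectory",
]


@dataclass(frozen=True)
class FlipProcess:
    """Markov jump dynamics of the I-spin level.

    ``t1_flip_time`` and ``flipflop_time`` are the characteristic times (ms)
    of the spin-lattice and flip-flop channels; either may be ``inf`` to
    switch that channel off.  The combined flip rate is the sum of the two
    channel rates.
    """

    spin_I: float = 0.5
    t1_flip_time: float = np.inf
    flipflop_time: float = np.inf
    seed: int | None = None

    def __post_init__(self):
        if self.spin_I not in (0.5, 1, 1.0):
            raise DomainError("spin I must be 1/2 or 1")
        for t in (self.t1_flip_time, self.flipflop_time):
            if t <= 0:
                raise DomainError("flip times must be positive (or inf)")

    @property
    def rate(self) -> float:
        """Summed jump rate (1/ms)."""
        return 1.0 / self.t1_flip_time + 1.0 / self.flipflop_time

    @property
    def levels(self) -> tuple[float, ...]:
        return (-0.5, 0.5) if self.spin_I == 0.5 else (-1.0, 0.0, 1.0)

    @property
    def reference_level(self) -> float:
        return max(abs(m) for m in self.levels)

    def rate_matrix(self) -> np.ndarray:
        """Generator over the level set.

        I = 1/2: symmetric two-level telegraph at the summed rate.
        I = 1: nearest-level jumps (Delta m = +-1) chosen so the stationary
        populations are uniform over the three levels.
        """
        k = self.rate
        if self.spin_I == 0.5:
            return np.array([[-k, k], [k, -k]])
        return np.array(
            [[-k, k, 0.0], [k, -2.0 * k, k], [0.0, k, -k]]
        )

    def transition_matrix(self, duration: float) -> np.ndarray:
        """Level transition probabilities over the given duration."""
        if duration < 0:
            raise DomainError("duration must be >= 0")
        if not np.isfinite(self.rate) or self.rate == 0.0:
            return np.eye(len(self.levels))
        return expm(self.rate_matrix() * duration)


@dataclass(frozen=True)
class FlipTrajectory:
    """Piecewise-constant I-spin level m(t) on [0, duration]."""

    jump_times: tuple[float, ...]
    levels: tuple[float, ...]  # level after each jump
    start_level: float
    duration: float
    reference_level: float = 0.5

    def __post_init__(self):
        if len(self.jump_times) != len(self.levels):
            raise ConfigError("one post-jump level per jump time required")
        times = np.asarray(self.jump_times)
        if times.size and (
            np.any(np.diff(times) <= 0)
            or times[0] <= 0
            or times[-1] >= self.duration
        ):
            raise ConfigError(
                "jump times must be strictly increasing within (0, duration)"
            )

    def level_at(self, t: float) -> float:
        """Level in effect at time t (start level before the first jump)."""
        idx = bisect_right(self.jump_times, t)
        return self.start_level if idx == 0 else self.levels[idx - 1]

    @property
    def end_level(self) -> float:
        return self.levels[-1] if self.levels else self.start_level

    @property
    def n_jumps(self) -> int:
        return len(self.jump_times)


def sample_flip_trajectory(
    process: FlipProcess,
    duration: float,
    start_level: float | None = None,
    rng: np.random.Generator | None = None,
) -> FlipTrajectory:
    """Draw one I-spin level trajectory.

    Jumps occur as a Markov process with exponential (inversion-sampled)
    waiting times at the state-dependent exit rate.  For I = 1/2 each jump
    inverts the level; for I = 1 jumps move the level by +-1, reflecting at
    the edges, with uniform asymptotic level populations.

    Identical ``(process, duration, start_level)`` with the same seed yield
    identical trajectories; splitting a duration into chained segments
    leaves the flip statistics unchanged.
    """
    if duration < 0:
        raise DomainError("duration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(process.seed)
    levels = process.levels
    if start_level is None:
        start_level = levels[rng.integers(len(levels))]
    elif start_level not in levels:
        raise DomainError(f"start level {start_level} invalid for I={process.spin_I}")

    base = process.rate
    jump_times: list[float] = []
    states: list[float] = []
    if base > 0 and np.isfinite(base):
        t = 0.0
        m = float(start_level)
        while True:
            # exit rate: edges of the I=1 ladder have a single jump channel
            k_exit = base if (process.spin_I == 0.5 or m != 0.0) else 2.0 * base
            t += -np.log(rng.uniform()) / k_exit
            if t >= duration:
                break
            if process.spin_I == 0.5:
                m = -m
            elif m == 0.0:
                m = 1.0 if rng.uniform() < 0.5 else -1.0
            else:
                m = 0.0
            jump_times.append(t)
            states.append(m)
    return FlipTrajectory(
        tuple(jump_times),
        tuple(states),
        float(start_level),
        float(duration),
        reference_level=process.reference_level,
    )


def mixing_phase_change(
    phi_d_dephase: float,
    level_dephase: float,
    level_rephase: float,
    phi_d_unit: float | None = None,
) -> float:
    """Change of the dipolar phase between dephasing and rephasing.

    The dipolar phase scales linearly with the I level, so
    ``delta = phi_d * (m_rephase / m_dephase - 1)``: zero without a flip and
    ``-2 * phi_d`` after a single I = 1/2 inversion.  When the dephasing
    level is 0 (possible for I = 1) the ratio is undefined and the rephasing
    phase is built from the per-unit-level phase instead, which must then be
    supplied.
    """
    if level_dephase != 0.0:
        return phi_d_dephase * (level_rephase / level_dephase - 1.0)
    if phi_d_unit is None:
        raise DomainError(
            "dephasing level 0 requires the per-unit-level phase phi_d_unit"
        )
    return level_rephase * phi_d_unit


@dataclass(frozen=True)
class ExchangeModel:
    """Markovian site exchange in dynamic equilibrium.

    ``rate_matrix`` is the generator (1/ms; rows sum to zero); the
    stationary ``populations`` must satisfy detailed balance with it — a
    violation is reported as a warning by default because slow drifts of a
    non-equilibrium model may still be worth simulating.

    ``site_orientations`` are per-site Euler triples rotating the interaction
    tensors (molecular-frame reorientation between sites); site 0 is the
    reference.
    """

    populations: tuple[float, ...]
    rate_matrix: np.ndarray
    site_orientations: tuple[tuple[float, float, float], ...] | None = None
    strict_detailed_balance: bool = False

    def __post_init__(self):
        p = np.asarray(self.populations, dtype=float)
        q = np.asarray(self.rate_matrix, dtype=float)
        n = p.size
        if q.shape != (n, n):
            raise ConfigError("rate matrix shape must match site count")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ConfigError("populations must be nonnegative and sum to 1")
        if np.any(q - np.diag(np.diag(q)) < 0):
            raise ConfigError("off-diagonal exchange rates must be >= 0")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
            raise ConfigError("rate matrix rows must sum to 0")
        flux = p[:, None] * q
        if not np.allclose(flux, flux.T, atol=1e-8 * max(1.0, np.abs(q).max())):
            msg = "exchange model violates detailed balance"
            if self.strict_detailed_balance:
                raise ConfigError(msg)
            warnings.warn(msg, stacklevel=2)
        if self.site_orientations is not None and len(self.site_orientations) != n:
            raise ConfigError("one orientation triple per site required")
        object.__setattr__(self, "populations", tuple(p))
        object.__setattr__(self, "rate_matrix", q)

    @property
    def site_count(self) -> int:
        return len(self.populations)

    def transition_matrix(self, duration: float) -> np.ndarray:
        if duration < 0:
            raise DomainError("duration must be >= 0")
        return expm(self.rate_matrix * duration)

    @classmethod
    def symmetric_two_site(
        cls, rate: float, reorientation=(0.0, 0.0, 0.0)
    ) -> "ExchangeModel":
        """Equal-population two-site jump at the given rate (1/ms); the
        second site's tensors are rotated by the given Euler triple."""
        q = np.array([[-rate, rate], [rate, -rate]])
        return cls(
            (0.5, 0.5), q,
            site_orientations=((0.0, 0.0, 0.0), tuple(reorientation)),
        )


@dataclass(frozen=True)
class SiteTrajectory:
    """Piecewise-constant site index s(t) on [0, duration]."""

    jump_times: tuple[float, ...]
    sites: tuple[int, ...]
    start_site: int
    duration: float

    def site_at(self, t: float) -> int:
        idx = bisect_right(self.jump_times, t)
        return self.start_site if idx == 0 else self.sites[idx - 1]

    @property
    def end_site(self) -> int:
        return self.sites[-1] if self.sites else self.start_site

    def occupancy(self) -> np.ndarray:
        """Fraction of the duration spent in each visited site index."""
        n = max((self.start_site, *self.sites), default=self.start_site) + 1
        occ = np.zeros(n)
        bounds = (0.0, *self.jump_times, self.duration)
        seq = (self.start_site, *self.sites)
        for s, a, b in zip(seq, bounds[:-1], bounds[1:]):
            occ[s] += b - a
        return occ / self.duration


def sample_site_trajectory(
    model: ExchangeModel,
    duration: float,
    seed: int | None = None,
    start_site: int | None = None,
    rng: np.random.Generator | None = None,
) -> SiteTrajectory:
    """Draw one continuous-time Markov site trajectory.

    The start site is drawn from the equilibrium populations unless given;
    empirical occupancies converge to the populations for long durations.
    """
    if duration < 0:
        raise DomainError("duration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    q = model.rate_matrix
    n = model.site_count
    if start_site is None:
        start_site = int(rng.choice(n, p=model.populations))
    elif not 0 <= start_site < n:
        raise ConfigError(f"start site {start_site} out of range")

    t, s = 0.0, int(start_site)
    jump_times: list[float] = []
    sites: list[int] = []
    while True:
        k_exit = -q[s, s]
        if k_exit <= 0:
            break
        t += -np.log(rng.uniform()) / k_exit
        if t >= duration:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(n, p=probs))
        jump_times.append(t)
        sites.append(s)
    return SiteTrajectory(
        tuple(jump_times), tuple(sites), int(start_site), float(duration)
    )
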