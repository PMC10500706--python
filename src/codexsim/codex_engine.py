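"""Product-operator bookkeeping of the CODEX stimulated-echo sequence.

The S-spin coherence is tracked in the four-operator basis
``{Sx, Sy, 2SxIz, 2SyIz}``.  Evolution during a de(re)phasing period is the
composition of two commuting rotations: a transverse-plane rotation by the
recoupled CSA phase and an in-phase/anti-phase mixing rotation by the
recoupled dipolar phase.  The COS component stores and detects the x family
``{Sx, 2SxIz}``; the SIN component the y family ``{Sy, 2SyIz}``.

For spin I = 1 the state carries one amplitude quadruple per I level m; the
dipolar phase of level m is scaled by ``m / |m_ref|`` and anti-phase
amplitudes are seeded with the level-odd weight of the ``2SyIz`` operator.
For I = 1/2 this reduces exactly to the single-quadruple treatment.
"""

from __future__ import annotations

import enum
import io as _io
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "BASIS_LABELS",
    "Component",
    "CoherenceState",
    "PhaseCycleTable",
    "initial_state_after_cp",
    "apply_z_filter",
    "evolve_period",
    "evolution_matrix",
    "project_component",
    "reinsert_after_mixing",
    "detect",
    "phase_cycle_table",
    "receiver_weighted_sum",
    "ideal_step_signals",
]

BASIS_LABELS = ("Sx", "Sy", "2SxIz", "2SyIz")


class Component(str, enum.Enum):
    """Which half of the stimulated echo is stored and detected."""

    COS = "cos"
    SIN = "sin"

    @classmethod
    def coerce(cls, value) -> "Component":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ConfigError(f"unknown component {value!r}") from exc


@dataclass
class CoherenceState:
    """Amplitudes of the four product-operator basis terms.

    ``amplitudes`` has shape (n_levels, 4) in the basis
    ``(Sx, Sy, 2SxIz, 2SyIz)``; ``levels`` are the I-spin magnetic quantum
    numbers the rows belong to.  Spin I = 1/2 uses a single row (the product
    operators already encode the two-level structure).
    """

    amplitudes: np.ndarray
    levels: tuple[float, ...] = (0.5,)

    def __post_init__(self):
        amps = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if amps.shape[1] != 4:
            raise DomainError("state needs 4 basis amplitudes per level")
        if amps.shape[0] != len(self.levels):
            raise DomainError("one amplitude quadruple per level required")
        if not np.all(np.isfinite(amps)):
            raise DomainError("state amplitudes must be finite")
        self.amplitudes = amps
        self.levels = tuple(float(m) for m in self.levels)

    @property
    def reference_level(self) -> float:
        return max(abs(m) for m in self.levels)

    def copy(self) -> "CoherenceState":
        return CoherenceState(self.amplitudes.copy(), self.levels)

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def total(self, label: str) -> float:
        """Summed amplitude of one basis operator over all levels."""
        return float(self.amplitudes[:, BASIS_LABELS.index(label)].sum())


def initial_state_after_cp(
    anti_phase_fraction: float, spin_I: float = 0.5
) -> CoherenceState:
    """State created by I->S cross polarization.

    Cross polarization produces an in-phase ``Sx`` term of amplitude
    ``1 - a`` and an anti-phase ``-2SyIz`` term of amplitude ``a``, where
    ``a`` is a free parameter standing in for the empirical CP-contact-time
    dependence of the anti-phase admixture.
    """
    a = anti_phase_fraction
    if not 0.0 <= a <= 1.0:
        raise DomainError("anti-phase fraction must lie in [0, 1]")
    if spin_I == 0.5:
        return CoherenceState(np.array([[1.0 - a, 0.0, 0.0, -a]]), (0.5,))
    if spin_I == 1:
        levels = (-1.0, 0.0, 1.0)
        rows = [
            [(1.0 - a) / 3.0, 0.0, 0.0, -a * m / 3.0] for m in levels
        ]
        return CoherenceState(np.array(rows), levels)
    raise DomainError("spin I must be 1/2 or 1")


def apply_z_filter(
    state: CoherenceState, delay: float, t1_s: float, t2_s: float
) -> CoherenceState:
    """Storage delay between CP and the dephasing period.

    The in-phase magnetization is stored longitudinally and decays with the
    S-spin T1; anti-phase (transverse two-spin) pathways decay with T2 and
    are eliminated once the delay is long on the T2 scale.  ``delay = 0``
    returns the state unchanged.
    """
    if delay < 0:
        raise DomainError("Z-filter delay must be >= 0")
    if t1_s <= 0 or t2_s <= 0:
        raise DomainError("relaxation times must be positive")
    out = state.copy()
    out.amplitudes[:, :2] *= math.exp(-delay / t1_s)
    out.amplitudes[:, 2:] *= math.exp(-delay / t2_s)
    return out


def evolution_matrix(phi_csa, phi_d) -> np.ndarray:
    """4x4 rotation of the basis ``(Sx, Sy, 2SxIz, 2SyIz)`` for one
    de(re)phasing period.

    Composition (in either order — the generators commute) of the
    transverse rotation by ``phi_csa`` and the in-phase/anti-phase mixing
    rotation by ``phi_d``.  Orthogonal for all phases, hence norm-preserving.
    Supports broadcasting: scalar or array phases return stacked matrices
    with shape ``phi.shape + (4, 4)``.
    """
    cc, sc = np.cos(phi_csa), np.sin(phi_csa)
    cd, sd = np.cos(phi_d), np.sin(phi_d)
    zero = np.zeros(np.broadcast(cc, cd).shape)
    cc, sc, cd, sd = np.broadcast_arrays(cc + zero, sc + zero, cd, sd)
    u = np.empty(cc.shape + (4, 4))
    # columns are images of the basis operators
    u[..., 0, 0], u[..., 1, 0], u[..., 2, 0], u[..., 3, 0] = (
        cc * cd, sc * cd, -sc * sd, cc * sd)
    u[..., 0, 1], u[..., 1, 1], u[..., 2, 1], u[..., 3, 1] = (
        -sc * cd, cc * cd, -cc * sd, -sc * sd)
    u[..., 0, 2], u[..., 1, 2], u[..., 2, 2], u[..., 3, 2] = (
        -sc * sd, cc * sd, cc * cd, sc * cd)
    u[..., 0, 3], u[..., 1, 3], u[..., 2, 3], u[..., 3, 3] = (
        -cc * sd, -sc * sd, -sc * cd, cc * cd)
    return u


def evolve_period(state: CoherenceState, phases) -> CoherenceState:
    """Evolve the state through one de(re)phasing period.

    ``phases`` is a :class:`~codexsim.spin_system.PhasePair` (or any object
    with ``phi_csa``/``phi_d``); the dipolar phase is understood as the
    phase of the reference level ``|m_ref|`` and scaled per level.
    """
    out = state.copy()
    mref = state.reference_level or 1.0
    for i, m in enumerate(state.levels):
        u = evolution_matrix(phases.phi_csa, phases.phi_d * m / mref)
        out.amplitudes[i] = u @ state.amplitudes[i]
    return out


_KEPT = {Component.COS: (0, 2), Component.SIN: (1, 3)}


def project_component(state: CoherenceState, component) -> CoherenceState:
    """Zero the basis terms not stored by the chosen component.

    Between dephasing and mixing only one transverse family survives the
    storage pulse: COS keeps ``{Sx, 2SxIz}``, SIN keeps ``{Sy, 2SyIz}``.
    """
    component = Component.coerce(component)
    out = state.copy()
    dropped = [i for i in range(4) if i not in _KEPT[component]]
    out.amplitudes[:, dropped] = 0.0
    return out


def reinsert_after_mixing(state: CoherenceState, component) -> CoherenceState:
    """Storage/readout transport of the stored component through mixing.

    The storage pulse writes the selected quadrature (and its anti-phase
    partner) to longitudinal order; the readout pulse re-excites both along
    the axis fixed by its own phase — the same axis for either component.
    For COS the stored ``{Sx, 2SxIz}`` amplitudes come back unchanged; for
    SIN the stored ``{Sy, 2SyIz}`` amplitudes re-enter on the ``{Sx, 2SxIz}``
    axes, so that the rephasing evolution accumulates the sine quadrature
    and the detected signal is proportional to sin(Phi1)·sin(Phi2).  This
    step is what makes the stimulated-echo identity COS + SIN = cos(ΔΦ)
    hold; it was validated against an exact density-matrix propagation of
    the pulse sequence.
    """
    component = Component.coerce(component)
    out = state.copy()
    if component is Component.SIN:
        out.amplitudes[:, 0] = state.amplitudes[:, 1]
        out.amplitudes[:, 2] = state.amplitudes[:, 3]
        out.amplitudes[:, 1] = 0.0
        out.amplitudes[:, 3] = 0.0
    return out


def detect(state: CoherenceState, component) -> float:
    """Observable signal amplitude after the rephasing period.

    Only single-quantum in-phase magnetization is detected: the ``Sx``
    amplitude for the COS component and ``Sy`` for SIN; anti-phase terms are
    unobservable.
    """
    component = Component.coerce(component)
    label = "Sx" if component is Component.COS else "Sy"
    return state.total(label)


# ---------------------------------------------------------------------------
# phase cycle
# ---------------------------------------------------------------------------

_PHASE_TO_ANGLE = {"x": 0.0, "y": 0.5 * math.pi,
                   "-x": math.pi, "-y": 1.5 * math.pi}

# Fixed phases and nested cycles of the 64-step scheme: 2x spin-temperature
# inversion (T1) x 2x spin-temperature inversion (mixing) x 4x CYCLOPS
# (pi/2 pulse after mixing) x 4x CYCLOPS (pi/2 pulse after the echo delay).
_CYCLE_CONSTANTS = {"phi1": "x", "phi2": "y", "phi3": "x", "phi4": "x"}
_CYCLE_LISTS_COMMON = {
    "phi6": "x,x,y,y,-x,-x,-y,-y",
    "phi7": "y,-y,-x,x,-y,y,x,-x",
    "phi9": ",".join(["x"] * 16 + ["y"] * 16 + ["-x"] * 16 + ["-y"] * 16),
    "phi10": ",".join(["y"] * 16 + ["-x"] * 16 + ["-y"] * 16 + ["x"] * 16),
    "phi11": "x,x,y,y,-x,-x,-y,-y",
}
_PHI5 = {Component.COS: "y,-y", Component.SIN: "x,-x"}
_PHI8 = {
    Component.COS: "-x,-x,-y,-y,x,x,y,y,x,x,y,y,-x,-x,-y,-y",
    Component.SIN: "y,y,-x,-x,-y,-y,x,x,-y,-y,x,x,y,y,-x,-x",
}
_REC_DIRECT = ",".join(
    ["y", "-y"] * 4 + ["-y", "y"] * 4 + ["-x", "x"] * 4 + ["x", "-x"] * 4
    + ["-y", "y"] * 4 + ["y", "-y"] * 4 + ["x", "-x"] * 4 + ["-x", "x"] * 4
)
_REC_INDIRECT = "x,-x,y,-y,-x,x,-y,y,-x,x,-y,y,x,-x,y,-y"


@dataclass(frozen=True)
class PhaseCycleTable:
    """Ordered phase assignments of the 64-step CODEX cycle."""

    component: Component
    detection: str
    columns: tuple[str, ...]
    steps: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.steps)

    def column(self, name: str) -> tuple[str, ...]:
        idx = self.columns.index(name)
        return tuple(row[idx] for row in self.steps)

    def receiver_angles(self) -> np.ndarray:
        return np.array([_PHASE_TO_ANGLE[p] for p in self.column("receiver")])

    def to_text(self) -> str:
        """One row per step, tab-delimited, with a header line."""
        buf = _io.StringIO()
        buf.write("step\t" + "\t".join(self.columns) + "\n")
        for i, row in enumerate(self.steps):
            buf.write(f"{i}\t" + "\t".join(row) + "\n")
        return buf.getvalue()


def phase_cycle_table(component, detection: str = "direct") -> PhaseCycleTable:
    """Emit the nested 64-step phase cycle for one component.

    The cycle nests 2 x 2 spin-temperature inversions with two 4-step
    CYCLOPS blocks; the COS and SIN variants differ only in the phi5 and
    phi8 columns (a pi/2 shift of the storage/readout pulses relative to
    the CP pulse).
    """
    component = Component.coerce(component)
    if detection not in ("direct", "indirect"):
        raise ConfigError(f"unknown detection mode {detection!r}")
    lists = {
        **{k: [v] for k, v in _CYCLE_CONSTANTS.items()},
        "phi5": _PHI5[component].split(","),
        **{k: v.split(",") for k, v in _CYCLE_LISTS_COMMON.items()},
        "phi8": _PHI8[component].split(","),
        "receiver": (
            _REC_DIRECT if detection == "direct" else _REC_INDIRECT
        ).split(","),
    }
    columns = (
        "phi1", "phi2", "phi3", "phi4", "phi5", "phi6", "phi7", "phi8",
        "phi9", "phi10", "phi11", "receiver",
    )
    steps = tuple(
        tuple(lists[c][i % len(lists[c])] for c in columns) for i in range(64)
    )
    return PhaseCycleTable(component, detection, columns, steps)


def ideal_step_signals(table: PhaseCycleTable, amplitude: float = 1.0):
    """Per-step complex signals of an artifact-free spin, whose phase
    follows the receiver exactly."""
    return amplitude * np.exp(1j * table.receiver_angles())


def receiver_weighted_sum(table: PhaseCycleTable, step_signals) -> complex:
    """Receiver-weighted coherent sum over the cycle.

    For an artifact-free spin every step contributes equally, so the sum is
    ``len(table)`` times the single-step signal.
    """
    signals = np.asarray(step_signals, dtype=complex)
    if signals.shape[0] != len(table):
        raise ConfigError("one signal per phase-cycle step required")
    return complex(np.sum(signals * np.exp(-1j * table.receiver_angles())))
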