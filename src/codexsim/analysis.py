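"""Fitting and diagnostics for CODEX mixing-time curves.

The workhorse model is the plateau exponential

    I(tau_m) = I(0) * [(1 - S_inf) * exp(-tau_m / tau_c) + S_inf]

whose plateau ratio ``S_inf`` equals the long-over-short mixing-time
amplitude ratio S_inf/S0.  A two-component variant separates a fast decay
(RIDER or a genuine slow motion, tens of ms) from the much slower
spin-diffusion decay (seconds):

    I(tau_m) = I(0) * [A_f exp(-tau_m/tau_c) + A_s exp(-tau_m/tau_sd) + S_inf]

with A_f + A_s + S_inf = 1.

The RIDER diagnostic compares the fitted plateau ratios of the COS and SIN
components: pure exchange (and/or spin diffusion) gives identical shapes,
whereas the RIDER pathways predict different plateaus, so a significant
difference flags the artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DataError
from .experiment import MixingCurve

__all__ = [
    "FitResult",
    "RiderVerdict",
    "fit_plateau_exponential",
    "fit_decay",
    "subtract_slow_component",
    "rider_diagnostic",
]


@dataclass
class FitResult:
    """Converged (or flagged) parameters of the plateau-exponential model."""

    i0: float
    s_inf: float
    tau_c: float
    a_fast: float | None = None
    a_slow: float | None = None
    tau_sd: float | None = None
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: tuple[str, ...] = ()
    n_components: int = 1
    component: str | None = None

    @property
    def plateau_ratio(self) -> float:
        """S_inf/S0 — equal to the fitted plateau parameter."""
        return self.s_inf

    def plateau_stderr(self) -> float | None:
        return self.stderr.get("s_inf")

    def slow_part(self, tau_m: np.ndarray) -> np.ndarray:
        """Fitted slow exponential plus plateau (two-component fits)."""
        if self.n_components != 2 or self.tau_sd is None:
            raise DataError("fit has no slow component")
        tau_m = np.asarray(tau_m, dtype=float)
        return self.i0 * (
            self.a_slow * np.exp(-tau_m / self.tau_sd) + self.s_inf
        )

    def model(self, tau_m: np.ndarray) -> np.ndarray:
        tau_m = np.asarray(tau_m, dtype=float)
        if self.n_components == 1:
            return self.i0 * (
                (1.0 - self.s_inf) * np.exp(-tau_m / self.tau_c) + self.s_inf
            )
        return self.i0 * (
            self.a_fast * np.exp(-tau_m / self.tau_c)
            + self.a_slow * np.exp(-tau_m / self.tau_sd)
            + self.s_inf
        )

    def to_text(self) -> str:
        """Key-value serialization, one parameter per line."""
        lines = [
            f"component: {self.component or '-'}",
            f"n_components: {self.n_components}",
            f"converged: {self.converged}",
            f"flags: {','.join(self.flags) or '-'}",
        ]
        for name in ("i0", "s_inf", "tau_c", "a_fast", "a_slow", "tau_sd"):
            val = getattr(self, name)
            if val is None:
                continue
            err = self.stderr.get(name)
            err_s = f" +/- {err:.6g}" if err is not None else ""
            lines.append(f"{name}: {val:.8g}{err_s}")
        return "\n".join(lines) + "\n"

    def summary_row(self) -> dict:
        row = {
            "component": self.component,
            "n_components": self.n_components,
            "converged": self.converged,
            "flags": ",".join(self.flags),
            "i0": self.i0,
            "s_inf": self.s_inf,
            "tau_c": self.tau_c,
        }
        for name in ("a_fast", "a_slow", "tau_sd"):
            row[name] = getattr(self, name)
        for name, err in self.stderr.items():
            row[f"{name}_err"] = err
        return row


def _one_component(tau, i0, s_inf, tau_c):
    return i0 * ((1.0 - s_inf) * np.exp(-tau / tau_c) + s_inf)


def _two_component(tau, i0, a_fast, a_slow, tau_c, tau_sd):
    s_inf = 1.0 - a_fast - a_slow
    return i0 * (
        a_fast * np.exp(-tau / tau_c)
        + a_slow * np.exp(-tau / tau_sd)
        + s_inf
    )


def _initial_guesses(tau, y):
    """Deterministic initialization: the plateau from the tail mean, the
    fast time constant from the log slope of the first third, I0 from the
    first point."""
    i0 = y[0] if y[0] != 0 else 1.0
    n_tail = max(1, int(0.2 * len(y)))
    s_inf = float(np.clip(np.mean(y[-n_tail:]) / i0, -0.05, 1.05))
    third = max(3, len(y) // 3)
    resid = y[:third] / i0 - s_inf
    tau_c = None
    mask = resid > 1e-3
    if mask.sum() >= 2:
        slope = np.polyfit(tau[:third][mask], np.log(resid[mask]), 1)[0]
        if slope < 0:
            tau_c = -1.0 / slope
    if tau_c is None or not np.isfinite(tau_c):
        tau_c = (tau[0] + tau[-1]) / 4.0
    return float(i0), s_inf, float(tau_c)


def fit_decay(
    tau_m,
    intensity,
    error=None,
    n_components: int = 1,
    component: str | None = None,
    slow_fast_ratio_guard: float = 5.0,
) -> FitResult:
    """Weighted least-squares fit of the plateau-exponential model.

    Weights are inverse variances when an error column with nonzero entries
    is supplied, otherwise the fit is unweighted.  Non-convergence never
    raises: the result carries ``converged=False`` and explanatory flags.
    Two-component fits whose time constants come out closer than
    ``slow_fast_ratio_guard`` are flagged ``inconclusive`` (the components
    are not identifiable).
    """
    tau = np.asarray(tau_m, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if n_components not in (1, 2):
        raise DataError("n_components must be 1 or 2")
    min_pts = 5 if n_components == 1 else 8
    if tau.size < min_pts:
        raise DataError(
            f"{n_components}-component fit needs >= {min_pts} points"
        )
    weights = None
    if error is not None:
        err = np.asarray(error, dtype=float)
        if np.all(err > 0):
            weights = 1.0 / err

    i0, s_inf0, tau_c0 = _initial_guesses(tau, y)
    t_lo, t_hi = tau[0] / 10.0, tau[-1] * 10.0
    tau_c0 = float(np.clip(tau_c0, t_lo, t_hi))

    flags: list[str] = []
    if n_components == 1:
        model = lmfit.Model(_one_component)
        params = model.make_params(i0=i0, s_inf=s_inf0, tau_c=tau_c0)
        params["s_inf"].set(min=-0.1, max=1.1)
        params["tau_c"].set(min=t_lo, max=t_hi)
    else:
        model = lmfit.Model(_two_component)
        a_tot = max(1.0 - s_inf0, 0.1)
        params = model.make_params(
            i0=i0,
            a_fast=a_tot / 2.0,
            a_slow=a_tot / 2.0,
            tau_c=min(tau_c0, tau[-1] / 10.0),
            tau_sd=tau[-1],
        )
        params["a_fast"].set(min=0.0, max=1.2)
        params["a_slow"].set(min=0.0, max=1.2)
        params["tau_c"].set(min=t_lo, max=t_hi)
        params["tau_sd"].set(min=t_lo, max=t_hi)

    try:
        # with true measurement errors as weights the unscaled covariance is
        # the calibrated one; without weights fall back to chi^2 scaling
        out = model.fit(
            y, params, tau=tau, weights=weights,
            scale_covar=weights is None,
        )
        success = bool(out.success)
    except Exception:  # numerical failure inside the optimizer
        out = None
        success = False

    if out is None:
        return FitResult(
            i0=i0, s_inf=s_inf0, tau_c=tau_c0, converged=False,
            flags=("optimizer_failure",), n_components=n_components,
            component=component,
        )

    vals = out.params.valuesdict()
    stderr = {
        name: p.stderr
        for name, p in out.params.items()
        if p.stderr is not None and np.isfinite(p.stderr)
    }
    if not success:
        flags.append("no_convergence")
    if not stderr:
        flags.append("no_covariance")

    noise = (
        float(np.median(np.asarray(error)))
        if error is not None and np.all(np.asarray(error) > 0)
        else float(np.std(y - out.best_fit)) or 0.0
    )
    if n_components == 1:
        s_inf = vals["s_inf"]
        tau_c = vals["tau_c"]
        # flat curve: the decay expressed inside the observation window is
        # indistinguishable from noise (covers both tiny amplitudes and a
        # time constant escaping to the grid bound)
        expressed = abs(
            vals["i0"] * (1.0 - s_inf)
            * (math.exp(-tau[0] / tau_c) - math.exp(-tau[-1] / tau_c))
        )
        at_bound = tau_c > 0.99 * t_hi or tau_c < 1.01 * t_lo
        if expressed < 3.0 * noise or expressed < 1e-12 or at_bound:
            flags.append("degenerate_flat")
            # the decay parameters are unidentifiable; report the robust
            # plateau estimate (tail mean over first point) instead
            s_inf, tau_c = s_inf0, tau_c0
        return FitResult(
            i0=vals["i0"], s_inf=s_inf, tau_c=tau_c, stderr=stderr,
            converged=success, flags=tuple(flags), n_components=1,
            component=component,
        )

    s_inf = 1.0 - vals["a_fast"] - vals["a_slow"]
    if "a_fast" in stderr and "a_slow" in stderr:
        stderr["s_inf"] = math.hypot(stderr["a_fast"], stderr["a_slow"])
    # identifiability guard: the components must be well separated and
    # their time constants determined
    if (
        vals["tau_sd"] < slow_fast_ratio_guard * vals["tau_c"]
        or stderr.get("tau_sd", 0.0) > 0.5 * vals["tau_sd"]
        or stderr.get("tau_c", 0.0) > 0.5 * vals["tau_c"]
    ):
        flags.append("inconclusive_timescales")
    return FitResult(
        i0=vals["i0"], s_inf=s_inf, tau_c=vals["tau_c"],
        a_fast=vals["a_fast"], a_slow=vals["a_slow"], tau_sd=vals["tau_sd"],
        stderr=stderr, converged=success, flags=tuple(flags),
        n_components=2, component=component,
    )


def fit_plateau_exponential(
    curve: MixingCurve, n_components: int = 1, component: str = "cos"
) -> FitResult:
    """Fit one component column of a mixing-time curve; see
    :func:`fit_decay`."""
    return fit_decay(
        curve.tau_m,
        curve.intensity(component),
        error=curve.error(component),
        n_components=n_components,
        component=component,
    )


def subtract_slow_component(
    curve: MixingCurve, fit: FitResult, component: str = "cos"
) -> MixingCurve:
    """Remove the fitted slow exponential + plateau and renormalize.

    Returns the residual fast component scaled so its first point is exactly
    1; used to compare the fast (RIDER) decays of different experiments on a
    common amplitude scale.
    """
    slow = fit.slow_part(curve.tau_m)
    resid = curve.intensity(component) - slow
    err = curve.error(component)
    first = resid[0]
    meta = {**curve.metadata, "slow_subtracted": True}
    if abs(first) <= 1e-9 * abs(fit.i0):
        # pure slow curve: nothing fast left to normalize
        meta["fast_component"] = "absent"
        kwargs = {component: resid, f"{component}_err": err}
        return MixingCurve(curve.tau_m.copy(), metadata=meta, **kwargs)
    scaled = resid / first
    scaled_err = np.abs(err / first) if err is not None else None
    kwargs = {component: scaled, f"{component}_err": scaled_err}
    return MixingCurve(curve.tau_m.copy(), metadata=meta, **kwargs)


@dataclass(frozen=True)
class RiderVerdict:
    """Outcome of the COS/SIN shape comparison."""

    cos_ratio: float
    sin_ratio: float
    z_score: float
    flag: str  # rider_detected | consistent | inconclusive

    def __str__(self):
        return (
            f"S_inf/S0 cos={self.cos_ratio:.4f} sin={self.sin_ratio:.4f} "
            f"z={self.z_score:.2f} -> {self.flag}"
        )


def rider_diagnostic(
    cos_fit: FitResult, sin_fit: FitResult, tolerance_z: float = 3.0
) -> RiderVerdict:
    """Compare the plateau ratios of the COS and SIN components.

    A z-test on the fitted uncertainties: ratios differing by more than
    ``tolerance_z`` joint standard errors flag the RIDER artifact; agreement
    within the tolerance is consistent with pure exchange/spin diffusion.
    Degenerate or non-converged fits yield ``inconclusive``.
    """
    rc, rs = cos_fit.plateau_ratio, sin_fit.plateau_ratio
    ec, es = cos_fit.plateau_stderr(), sin_fit.plateau_stderr()
    degenerate = (
        not cos_fit.converged
        or not sin_fit.converged
        or any("degenerate" in f or "inconclusive" in f
               for f in (*cos_fit.flags, *sin_fit.flags))
        or ec is None
        or es is None
    )
    if degenerate:
        return RiderVerdict(rc, rs, float("nan"), "inconclusive")
    joint = math.hypot(ec, es)
    if joint == 0.0:
        z = math.inf if rc != rs else 0.0
    else:
        z = abs(rc - rs) / joint
    flag = "rider_detected" if z > tolerance_z else "consistent"
    return RiderVerdict(rc, rs, z, flag)
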