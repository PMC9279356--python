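"""Accelerated-sampling toy box: boost potential, Langevin dynamics, reweighting.

The boost is the standard single-boost form

    DeltaV(V) = (E - V)^2 / (alpha + E - V)      for V < E, else 0,

which leaves the modified potential V* = V + DeltaV continuous with a
continuous first derivative at V = E; on the boosted surface forces are
the unbiased forces scaled by dV*/dV = alpha^2 / (alpha + E - V)^2.
Canonical averages are recovered by exponential reweighting with
w_i = exp(DeltaV_i / kT).

Dynamics use the BAOAB discretisation of Langevin dynamics with
Maxwell-Boltzmann initial velocities.  A reduced-units mode (kT = 1) is
provided alongside kcal/mol at 300 K for clean analytic checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

KB_KCAL = 0.0019872041  # kcal/(mol*K)


@dataclass
class ToyPotential:
    """Scalar potential with analytic gradient on R^d (d = 1 or 2)."""

    dimension: int
    V: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    def check_gradient(self, x: np.ndarray, h: float = 1e-5) -> float:
        """Max relative central-difference error of the gradient at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        g = np.atleast_1d(self.gradient(x))
        err = 0.0
        for k in range(x.size):
            e = np.zeros_like(x)
            e[k] = h
            num = (self.V(x + e) - self.V(x - e)) / (2 * h)
            scale = max(abs(num), abs(g[k]), 1.0)
            err = max(err, abs(num - g[k]) / scale)
        return err


def double_well(h: float = 6.0, tilt: float = 0.0) -> ToyPotential:
    """V(x) = h*(x^2-1)^2 + tilt*x: barrier height h between minima near +-1."""

    def V(x):
        x0 = float(np.atleast_1d(x)[0])
        return h * (x0 * x0 - 1.0) ** 2 + tilt * x0

    def grad(x):
        x0 = float(np.atleast_1d(x)[0])
        return np.array([4.0 * h * x0 * (x0 * x0 - 1.0) + tilt])

    name = "double_well" if tilt == 0 else "tilted_double_well"
    return ToyPotential(dimension=1, V=V, gradient=grad, name=name)


def harmonic(k_spring: float = 1.0) -> ToyPotential:
    def V(x):
        x = np.atleast_1d(x)
        return 0.5 * k_spring * float(np.dot(x, x))

    def grad(x):
        return k_spring * np.atleast_1d(np.asarray(x, dtype=float))

    return ToyPotential(dimension=1, V=V, gradient=grad, name="harmonic")


@dataclass(frozen=True)
class AMDParams:
    E: float  # boost threshold (energy units of the potential)
    alpha: float  # smoothing depth, > 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def boost(V_value: float, params: AMDParams) -> tuple[float, float]:
    """(DeltaV, force_scale) of the boost at potential value V.

    force_scale multiplies the unbiased force on the boosted surface.
    Above the threshold the dynamics are untouched: (0, 1).
    """
    diff = params.E - V_value
    if diff <= 0:
        return 0.0, 1.0
    denom = params.alpha + diff
    delta_v = diff * diff / denom
    force_scale = (params.alpha / denom) ** 2
    return float(delta_v), float(force_scale)


@dataclass
class LangevinSettings:
    temperature_K: float = 300.0
    dt: float = 0.002  # ps-scale analog of a 2 fs step
    friction: float = 1.0  # 1/time
    mass: float = 1.0
    n_steps: int = 10000
    seed: int = 0
    units: Literal["kcal", "reduced"] = "kcal"
    x0: np.ndarray | float = 0.0
    record_stride: int = 1

    @property
    def kT(self) -> float:
        if self.units == "reduced":
            return self.temperature_K  # temperature given directly in kT units
        return KB_KCAL * self.temperature_K

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature_K <= 0:
            raise ValueError("dt and temperature must be > 0")


@dataclass
class ToyTrajectory:
    positions: np.ndarray  # (n_recorded, d)
    V: np.ndarray
    deltaV: np.ndarray
    settings: LangevinSettings
    amd: AMDParams | None = None


def run_langevin(
    potential: ToyPotential,
    settings: LangevinSettings,
    amd: AMDParams | None = None,
) -> ToyTrajectory:
    """BAOAB Langevin sampling of a toy potential, optionally boosted.

    Initial velocities are Maxwell-Boltzmann at the target temperature.
    With ``amd`` set, forces are scaled by the boost's force_scale each
    step and DeltaV is recorded for reweighting.  Deterministic per seed.
    """
    rng = np.random.default_rng(settings.seed)
    d = potential.dimension
    kT = settings.kT
    m = settings.mass
    dt = settings.dt
    c1 = math.exp(-settings.friction * dt)
    c2 = math.sqrt(kT / m * (1.0 - c1 * c1))

    x = np.atleast_1d(np.asarray(settings.x0, dtype=float)).copy()
    if x.size != d:
        x = np.full(d, float(np.atleast_1d(settings.x0)[0]))
    v = rng.normal(0.0, math.sqrt(kT / m), size=d)
    noise = rng.normal(size=(settings.n_steps, d))

    stride = max(settings.record_stride, 1)
    n_rec = settings.n_steps // stride
    pos = np.empty((n_rec, d))
    vs = np.empty(n_rec)
    dvs = np.empty(n_rec)

    def force(xx: np.ndarray) -> tuple[np.ndarray, float, float]:
        vv = potential.V(xx)
        g = np.atleast_1d(potential.gradient(xx))
        if amd is not None:
            dv, scale = boost(vv, amd)
        else:
            dv, scale = 0.0, 1.0
        return -g * scale, vv, dv

    f, vv, dv = force(x)
    rec = 0
    for step in range(settings.n_steps):
        v = v + 0.5 * dt * f / m
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * noise[step]
        x = x + 0.5 * dt * v
        f, vv, dv = force(x)
        v = v + 0.5 * dt * f / m
        if not np.all(np.isfinite(x)) or abs(vv) > 1e12:
            raise FloatingPointError(
                "trajectory diverged; use a smaller dt or weaker potential"
            )
        if (step + 1) % stride == 0:
            pos[rec] = x
            vs[rec] = vv
            dvs[rec] = dv
            rec += 1
    return ToyTrajectory(positions=pos, V=vs, deltaV=dvs, settings=settings, amd=amd)


def reweight(
    observable: np.ndarray, deltaV: np.ndarray, kT: float
) -> float:
    """Canonical average <A> = sum A_i w_i / sum w_i with w_i = exp(dV_i/kT).

    Weights are max-shifted before exponentiation so large boosts cannot
    overflow.  With all DeltaV = 0 this is the arithmetic mean.
    """
    observable = np.asarray(observable, dtype=float)
    deltaV = np.asarray(deltaV, dtype=float)
    if observable.shape[0] != deltaV.shape[0]:
        raise ValueError("length mismatch")
    if np.any(deltaV < -1e-12):
        raise ValueError("deltaV must be >= 0")
    logw = deltaV / kT
    logw -= logw.max()
    w = np.exp(logw)
    return float(np.sum(observable * w) / np.sum(w))


def estimate_amd_params(
    v_series: np.ndarray, c1: float = 4.0, c2: float = 1.0
) -> AMDParams:
    """Boost parameters from an unbiased potential-energy series.

    E = <V> + c1*sigma_V and alpha = c2*sigma_V, mirroring the practice of
    setting the threshold from time-averaged cMD energies.  The constants
    are explicit assumptions (config-exposed defaults c1=4, c2=1).
    """
    v_series = np.asarray(v_series, dtype=float)
    if v_series.size < 100:
        raise ValueError("need >= 100 samples")
    sigma = float(v_series.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("zero-variance potential-energy series")
    mean = float(v_series.mean())
    return AMDParams(E=mean + c1 * sigma, alpha=c2 * sigma)


def count_well_transitions(
    positions: np.ndarray, left: float = -0.5, right: float = 0.5
) -> int:
    """Count left<->right well crossings of a 1-D trajectory with hysteresis."""
    x = np.asarray(positions, dtype=float).ravel()
    state = 0  # -1 left, +1 right, 0 undecided
    transitions = 0
    for xi in x:
        if xi <= left:
            if state == 1:
                transitions += 1
            state = -1
        elif xi >= right:
            if state == -1:
                transitions += 1
            state = 1
    return transitions
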