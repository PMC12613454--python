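"""Deterministic physics of the virtual pendulum with a moving pivot.

The task device renders a one-internal-DoF pendulum whose pivot is the robot
end-effector, confined to the vertical (y, z) plane.  The internal angle
``theta`` is measured from the downward vertical at the pivot, positive toward
+y, so the pendulum mass sits at ``(pivot_y + L sin(theta),
pivot_z - L cos(theta))`` with ``L`` the effective rod length.

The equation of motion for the internal DoF, driven by the pivot
accelerations (ay, az), is::

    theta_dd = -(1/L) * ((az + g) sin(theta) + ay cos(theta))
               - c / (m L^2) * theta_d

and the force the rod exerts along its axis (the haptic rendering force) is::

    F_rod = m * ((az + g) cos(theta) - ay sin(theta) + theta_d^2 L)

With the pivot at rest this reduces to the textbook pendulum and the rendered
force on the hand is the downward pull ``m g`` at static rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PendulumParams",
    "PendulumState",
    "PivotCommand",
    "step_dynamics",
    "rod_force",
    "natural_frequency",
    "simulate_free",
    "mechanical_energy",
]


@dataclass(frozen=True)
class PendulumParams:
    """Physical constants of the simulated pendulum.

    Parameters
    ----------
    m : float
        Pendulum mass (kg).
    l : float
        Nominal rod length (m).
    g : float
        Gravitational acceleration of the virtual world (m/s^2).  The game
        uses a reduced gravity to keep the task difficult.
    c : float
        Viscous damping coefficient on the internal DoF (N·m·s/rad).  The
        printed value is tiny; it barely affects the dynamics.
    sim_dt : float
        Fixed integrator step (s).  Default matches a 4 kHz control loop.
    rod_scale : float
        Dimensionless scaling of the rod length; 1.0 for the main task and
        0.7 for the dynamics transfer task.
    """

    m: float = 0.6
    l: float = 0.25
    g: float = 3.24
    c: float = 3.00e-6
    sim_dt: float = 1.0 / 4000.0
    rod_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.l <= 0 or self.g <= 0:
            raise ValueError("m, l and g must be positive")
        if self.c < 0:
            raise ValueError("damping c must be non-negative")
        if self.sim_dt <= 0:
            raise ValueError("sim_dt must be positive")
        if self.rod_scale <= 0:
            raise ValueError("rod_scale must be positive")

    @property
    def rod_length(self) -> float:
        """Effective rod length ``rod_scale * l`` (m)."""
        return self.rod_scale * self.l

    def with_rod_scale(self, rod_scale: float) -> "PendulumParams":
        return replace(self, rod_scale=rod_scale)


@dataclass
class PendulumState:
    """Instantaneous state of the pendulum and its pivot."""

    theta: float = 0.0
    theta_dot: float = 0.0
    pivot_y: float = 0.0
    pivot_z: float = 0.0
    pivot_vy: float = 0.0
    pivot_vz: float = 0.0
    t: float = 0.0

    def mass_position(self, params: PendulumParams) -> tuple[float, float]:
        """(y, z) position of the pendulum mass."""
        L = params.rod_length
        return (
            self.pivot_y + L * math.sin(self.theta),
            self.pivot_z - L * math.cos(self.theta),
        )

    def mass_velocity(self, params: PendulumParams) -> tuple[float, float]:
        L = params.rod_length
        return (
            self.pivot_vy + L * math.cos(self.theta) * self.theta_dot,
            self.pivot_vz + L * math.sin(self.theta) * self.theta_dot,
        )


@dataclass(frozen=True)
class PivotCommand:
    """Commanded pivot (end-effector) acceleration over one step (m/s^2)."""

    accel_y: float = 0.0
    accel_z: float = 0.0
    max_accel: float = float("inf")

    def clamped(self) -> tuple[float, float]:
        a = self.max_accel
        return (
            min(max(self.accel_y, -a), a),
            min(max(self.accel_z, -a), a),
        )


def _check_finite(state: PendulumState) -> None:
    for name in ("theta", "theta_dot", "pivot_y", "pivot_z", "pivot_vy", "pivot_vz", "t"):
        if not math.isfinite(getattr(state, name)):
            raise ValueError(f"non-finite state component: {name}")


def theta_ddot(
    theta: float,
    theta_dot: float,
    accel_y: float,
    accel_z: float,
    params: PendulumParams,
) -> float:
    """Angular acceleration of the internal DoF."""
    L = params.rod_length
    return (
        -((accel_z + params.g) * math.sin(theta) + accel_y * math.cos(theta)) / L
        - params.c / (params.m * L * L) * theta_dot
    )


def step_dynamics(
    state: PendulumState, cmd: PivotCommand, params: PendulumParams
) -> PendulumState:
    """Advance the coupled pendulum/pivot state by one ``sim_dt`` (RK4).

    The pivot is integrated kinematically from the commanded acceleration
    within the same RK4 step as the internal DoF, so the coupling is
    consistent at fourth order.
    """
    _check_finite(state)
    ay, az = cmd.clamped()
    if not (math.isfinite(ay) and math.isfinite(az)):
        raise ValueError("non-finite pivot command")
    dt = params.sim_dt

    def rhs(y: np.ndarray) -> np.ndarray:
        th, thd, py, pvy, pz, pvz = y
        return np.array(
            [thd, theta_ddot(th, thd, ay, az, params), pvy, ay, pvz, az]
        )

    y0 = np.array(
        [
            state.theta,
            state.theta_dot,
            state.pivot_y,
            state.pivot_vy,
            state.pivot_z,
            state.pivot_vz,
        ]
    )
    k1 = rhs(y0)
    k2 = rhs(y0 + 0.5 * dt * k1)
    k3 = rhs(y0 + 0.5 * dt * k2)
    k4 = rhs(y0 + dt * k3)
    y1 = y0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return PendulumState(
        theta=y1[0],
        theta_dot=y1[1],
        pivot_y=y1[2],
        pivot_vy=y1[3],
        pivot_z=y1[4],
        pivot_vz=y1[5],
        t=state.t + dt,
    )


def rod_force(
    state: PendulumState, cmd: PivotCommand, params: PendulumParams
) -> tuple[float, float, float]:
    """Haptic rendering force of the rod.

    Returns ``(F_rod, F_y, F_z)``: the scalar rod force and its planar
    components as felt at the hand.  The components point from the pivot
    toward the mass, so at static rest the hand feels a downward pull of
    magnitude ``m g``.
    """
    _check_finite(state)
    ay, az = cmd.clamped()
    L = params.rod_length
    F = params.m * (
        (az + params.g) * math.cos(state.theta)
        - ay * math.sin(state.theta)
        + state.theta_dot**2 * L
    )
    return F, F * math.sin(state.theta), -F * math.cos(state.theta)


def natural_frequency(params: PendulumParams) -> float:
    """Small-oscillation natural frequency (Hz): ``sqrt(g / L) / (2 pi)``."""
    L = params.rod_length
    if L <= 0:
        raise ValueError("rod length must be positive")
    return math.sqrt(params.g / L) / (2.0 * math.pi)


def mechanical_energy(state: PendulumState, params: PendulumParams) -> float:
    """Total mechanical energy for a fixed pivot (J), zero at the pivot level."""
    L = params.rod_length
    return (
        0.5 * params.m * (L * state.theta_dot) ** 2
        - params.m * params.g * L * math.cos(state.theta)
    )


def simulate_free(
    params: PendulumParams, theta0: float, duration: float
) -> list[PendulumState]:
    """Roll out a free swing with a fixed pivot and zero commands."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / params.sim_dt))
    cmd = PivotCommand()
    state = PendulumState(theta=theta0)
    out = [state]
    for _ in range(n):
        state = step_dynamics(state, cmd, params)
        out.append(state)
    return out
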