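"""Haptic guidance: optimal pivot reference trajectories enforced by a PD force.

The Experimental group's assistance has two layers.  Every time the pendulum
crosses a target wall, a reference trajectory for the pivot (robot
end-effector) is planned over the next inter-wall interval, trading off
terminal accuracy at the next target, pendulum stabilization, and pivot
acceleration effort::

    J = w_acc * (mass_y(T) - b)^2
        + w_stab * integral( |mass velocity|^2 ) dt
        + w_u * integral( accel_y^2 ) dt

subject to the pendulum dynamics, with the pivot's vertical motion held
fixed.  During the interval a PD controller pushes the end-effector toward
the reference along the y-axis only::

    F_HG = Kp * e(t) + Kd * de/dt,    e(t) = y_ref(t) - pivot_y

with gains 75.0 N/m and 15 N·s/m.  The guidance force is added on top of the
haptic rendering force; the z-axis is never guided.

Two planner backends are provided:

``optimal``
    Direct single shooting: the decision variable is the pivot y-acceleration
    profile on a uniform node grid (piecewise linear in time), rolled out
    through the nonlinear dynamics with RK4 and optimized with L-BFGS-B.
    Gradients use batched central differences, which keeps the solver exactly
    equivariant under mirroring of the problem.

``minjerk``
    A closed-form minimum-jerk pivot path whose endpoint is chosen so that
    the *linearized* pendulum–hand loop puts the mass on the target at the
    crossing time (swing compensation).  This is the cheap reference used in
    large batch simulations; the plain (uncompensated) min-jerk path to the
    target offset is retained as the documented fallback when the optimizer
    fails.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .pendulum import PendulumParams, PendulumState
from .protocol import PlanEntry, WallTarget

logger = logging.getLogger(__name__)

__all__ = [
    "PDGains",
    "CostWeights",
    "GuidanceReference",
    "LinearHandModel",
    "pd_guidance_force",
    "guidance_active",
    "plan_reference",
    "minjerk_coeffs",
    "minjerk_eval",
    "plan_compensated_endpoint",
]


@dataclass(frozen=True)
class PDGains:
    """Guidance controller gains (defaults as deployed)."""

    kp: float = 75.0  # N/m
    kd: float = 15.0  # N·s/m

    def __post_init__(self) -> None:
        if self.kp < 0 or self.kd < 0:
            raise ValueError("PD gains must be non-negative")


@dataclass(frozen=True)
class CostWeights:
    """Weights of the three planner cost terms."""

    w_acc: float = 1.0e4
    w_stab: float = 1.0
    w_u: float = 1.0e-3


@dataclass
class GuidanceReference:
    """A planned pivot path y_ref(t) on [0, horizon].

    Evaluation between grid nodes uses a cubic spline of the position
    samples; the velocity is the spline's analytic derivative.  Times
    outside the horizon clamp to the terminal sample.
    """

    horizon: float
    t_grid: np.ndarray
    y_ref: np.ndarray
    yd_ref: np.ndarray
    target_offset: float
    terminal_miss: float = float("nan")
    fallback: bool = False
    n_iter: int = 0
    cost: float = float("nan")
    _spline: CubicSpline | None = field(default=None, repr=False)

    def _ensure_spline(self) -> CubicSpline:
        if self._spline is None:
            self._spline = CubicSpline(self.t_grid, self.y_ref, bc_type="natural")
        return self._spline

    def __call__(self, t: float) -> tuple[float, float]:
        """Return (y_ref, yd_ref) at time t, clamped to the horizon."""
        if t < 0.0 or t > self.horizon:
            logger.debug("reference query at t=%.4f clamped to [0, %.3f]", t, self.horizon)
            t = min(max(t, 0.0), self.horizon)
        s = self._ensure_spline()
        return float(s(t)), float(s(t, 1))


def pd_guidance_force(
    pivot_y: float,
    pivot_vy: float,
    ref: GuidanceReference,
    t: float,
    gains: PDGains | None = None,
) -> float:
    """Guidance force on the y-axis: ``Kp e + Kd de/dt`` toward the reference."""
    gains = gains or PDGains()
    y_ref, yd_ref = ref(t)
    return gains.kp * (y_ref - pivot_y) + gains.kd * (yd_ref - pivot_vy)


def guidance_active(entry: PlanEntry, group: str) -> bool:
    """Guidance is on only for the Experimental group in non-catch training sets."""
    return (
        group == "Experimental"
        and entry.stage == "TR"
        and not entry.schedule.catch
        and entry.guidance_on
    )


# ---------------------------------------------------------------------------
# minimum-jerk primitives
# ---------------------------------------------------------------------------

def minjerk_coeffs(
    u0: float, v0: float, a0: float, uf: float, T: float
) -> np.ndarray:
    """Quintic coefficients of the minimum-jerk path (u0,v0,a0) -> (uf,0,0)."""
    if T <= 0:
        raise ValueError("move time must be positive")
    c0, c1, c2 = u0, v0, 0.5 * a0
    d = uf - u0 - v0 * T - 0.5 * a0 * T**2
    T3, T4, T5 = T**3, T**4, T**5
    # boundary: position error d, velocity 0, acceleration 0 at T
    c3 = (20 * d + 8 * v0 * T + 7 * a0 * T**2) / (2 * T3)
    c4 = -(15 * d + 7 * v0 * T + 6 * a0 * T**2) / T4
    c5 = (12 * d + 6 * v0 * T + 5 * a0 * T**2) / (2 * T5)
    return np.array([c0, c1, c2, c3, c4, c5])


def minjerk_eval(coeffs: np.ndarray, T: float, t: float) -> tuple[float, float, float]:
    """(pos, vel, acc) of the quintic at time t; constant endpoint after T."""
    if t >= T:
        pos = sum(c * T**k for k, c in enumerate(coeffs))
        return pos, 0.0, 0.0
    pos = vel = acc = 0.0
    for k, c in enumerate(coeffs):
        pos += c * t**k
        if k >= 1:
            vel += k * c * t ** (k - 1)
        if k >= 2:
            acc += k * (k - 1) * c * t ** (k - 2)
    return pos, vel, acc


# ---------------------------------------------------------------------------
# linearized hand/pendulum model for swing-compensated endpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearHandModel:
    """Linear model of the servo that will track the planned pivot path.

    The pivot (end-effector plus hand, admittance mass ``m_e``, damping
    ``b_e``) is driven by a PD toward the reference with gains ``kp, kd``;
    the pendulum mass couples back through the linearized rod force.
    """

    m_e: float = 0.5
    b_e: float = 5.0
    kp: float = 40.0
    kd: float = 12.0


def plan_compensated_endpoint(
    p0: float,
    v0: float,
    x0: float,
    vx0: float,
    target_b: float,
    params: PendulumParams,
    hand: LinearHandModel,
    horizon: float = 1.0,
    move_time: float = 0.8,
    n_steps: int = 50,
) -> tuple[float, float]:
    """Choose the min-jerk endpoint so the linearized loop hits the target.

    Rolls the 4-state linear system (pivot p, mass y-position x) driven by
    the min-jerk input twice (endpoints 0 and 1); the terminal mass position
    is affine in the endpoint, so the compensating endpoint and the endpoint
    -> miss gain ``G = dx(T)/d(uf)`` come out exactly.

    Returns ``(uf, G)``.
    """
    L = params.rod_length
    omega2 = params.g / L
    k_rod = params.m * params.g / L  # linearized rod reaction on the pivot

    def terminal_x(uf: float) -> float:
        coeffs = minjerk_coeffs(p0, v0, 0.0, uf, move_time)
        dt = horizon / n_steps
        s = np.array([p0, v0, x0, vx0])

        def rhs(t: float, s: np.ndarray) -> np.ndarray:
            p, pv, x, xv = s
            u, ud, _ = minjerk_eval(coeffs, move_time, t)
            p_acc = (
                hand.kp * (u - p)
                + hand.kd * (ud - pv)
                - hand.b_e * pv
                + k_rod * (x - p)
            ) / hand.m_e
            x_acc = -omega2 * (x - p)
            return np.array([pv, p_acc, xv, x_acc])

        t = 0.0
        for _ in range(n_steps):
            k1 = rhs(t, s)
            k2 = rhs(t + 0.5 * dt, s + 0.5 * dt * k1)
            k3 = rhs(t + 0.5 * dt, s + 0.5 * dt * k2)
            k4 = rhs(t + dt, s + dt * k3)
            s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        return s[2]

    x_at_0 = terminal_x(0.0)
    x_at_1 = terminal_x(1.0)
    G = x_at_1 - x_at_0
    if abs(G) < 1e-9:
        return target_b, 1.0
    uf = (target_b - x_at_0) / G
    return uf, G


# ---------------------------------------------------------------------------
# shooting planner
# ---------------------------------------------------------------------------

def _rollout_batch(
    accel_nodes: np.ndarray,
    state0: np.ndarray,
    params: PendulumParams,
    horizon: float,
    substeps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Roll out B acceleration profiles through the nonlinear dynamics.

    accel_nodes: (B, N+1) pivot y-accelerations, piecewise linear in time.
    state0: (theta, theta_dot, pivot_y, pivot_vy).
    Returns (mass_y_T, stab_integral, u_integral), each shape (B,).
    """
    B, n_nodes = accel_nodes.shape
    n_int = n_nodes - 1
    dt = horizon / (n_int * substeps)
    L = params.rod_length
    g, c, m = params.g, params.c, params.m

    th = np.full(B, state0[0])
    thd = np.full(B, state0[1])
    p = np.full(B, state0[2])
    pv = np.full(B, state0[3])

    stab = np.zeros(B)
    ueff = np.zeros(B)

    def accel_at(tau: float) -> np.ndarray:
        x = tau / horizon * n_int
        i = min(int(x), n_int - 1)
        w = x - i
        return accel_nodes[:, i] * (1 - w) + accel_nodes[:, i + 1] * w

    def rhs(tau, th, thd, p, pv):
        ay = accel_at(tau)
        thdd = -((g) * np.sin(th) + ay * np.cos(th)) / L - c / (m * L * L) * thd
        return thd, thdd, pv, ay

    def vel_sq(th, thd, pv):
        vy = pv + L * np.cos(th) * thd
        vz = L * np.sin(th) * thd
        return vy * vy + vz * vz

    t = 0.0
    for _ in range(n_int * substeps):
        a_now = accel_at(t)
        stab += 0.5 * dt * vel_sq(th, thd, pv)
        ueff += 0.5 * dt * a_now * a_now

        k1 = rhs(t, th, thd, p, pv)
        k2 = rhs(t + dt / 2, th + dt / 2 * k1[0], thd + dt / 2 * k1[1],
                 p + dt / 2 * k1[2], pv + dt / 2 * k1[3])
        k3 = rhs(t + dt / 2, th + dt / 2 * k2[0], thd + dt / 2 * k2[1],
                 p + dt / 2 * k2[2], pv + dt / 2 * k2[3])
        k4 = rhs(t + dt, th + dt * k3[0], thd + dt * k3[1],
                 p + dt * k3[2], pv + dt * k3[3])
        th = th + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        thd = thd + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        p = p + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        pv = pv + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        t += dt

        a_now = accel_at(min(t, horizon))
        stab += 0.5 * dt * vel_sq(th, thd, pv)
        ueff += 0.5 * dt * a_now * a_now

    mass_y = p + L * np.sin(th)
    return mass_y, stab, ueff


def _integrate_reference(
    accel_nodes: np.ndarray,
    y0: float,
    v0: float,
    horizon: float,
    n_fine: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a piecewise-linear accel profile to a (t, y, yd) path."""
    n_int = len(accel_nodes) - 1
    tg = np.linspace(0.0, horizon, n_fine + 1)
    a = np.interp(tg / horizon * n_int, np.arange(n_int + 1), accel_nodes)
    dt = horizon / n_fine
    yd = v0 + np.concatenate(([0.0], np.cumsum(0.5 * dt * (a[1:] + a[:-1]))))
    y = y0 + np.concatenate(([0.0], np.cumsum(0.5 * dt * (yd[1:] + yd[:-1]))))
    return tg, y, yd


def plan_reference(
    state_at_crossing: PendulumState,
    next_target: WallTarget,
    params: PendulumParams,
    weights: CostWeights | None = None,
    horizon: float = 1.0,
    n_nodes: int = 20,
    substeps: int = 5,
    maxiter: int = 60,
    backend: str = "optimal",
    hand: LinearHandModel | None = None,
) -> GuidanceReference:
    """Plan the guidance pivot reference for the next inter-wall interval.

    With the ``optimal`` backend the cost is minimized over pivot
    y-acceleration profiles; if the optimizer fails, the plain minimum-jerk
    point-to-point path to the target offset is used and the reference is
    flagged as a fallback (with a logged warning).  The ``minjerk`` backend
    returns the swing-compensated minimum-jerk reference directly.
    """
    weights = weights or CostWeights()
    b = next_target.offset_b
    s0 = np.array(
        [
            state_at_crossing.theta,
            state_at_crossing.theta_dot,
            state_at_crossing.pivot_y,
            state_at_crossing.pivot_vy,
        ]
    )

    if backend == "minjerk":
        hm = hand or LinearHandModel()
        L = params.rod_length
        x0 = s0[2] + L * math.sin(s0[0])
        vx0 = s0[3] + L * math.cos(s0[0]) * s0[1]
        uf, _ = plan_compensated_endpoint(
            s0[2], s0[3], x0, vx0, b, params, hm, horizon=horizon
        )
        return _minjerk_reference(s0, uf, b, horizon, params)
    if backend != "optimal":
        raise ValueError(f"unknown planner backend: {backend!r}")

    n_int = n_nodes
    # warm start: accelerations of the min-jerk path straight to the target
    move_time = 0.8 * horizon
    coeffs = minjerk_coeffs(s0[2], s0[3], 0.0, b, move_time)
    t_nodes = np.linspace(0.0, horizon, n_int + 1)
    x_init = np.array(
        [minjerk_eval(coeffs, move_time, t)[2] for t in t_nodes]
    )

    def cost_batch(profiles: np.ndarray) -> np.ndarray:
        mass_y, stab, ueff = _rollout_batch(profiles, s0, params, horizon, substeps)
        return (
            weights.w_acc * (mass_y - b) ** 2
            + weights.w_stab * stab
            + weights.w_u * ueff
        )

    h = 1e-4
    dim = n_int + 1

    def fun_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        batch = np.empty((2 * dim + 1, dim))
        batch[0] = x
        for i in range(dim):
            batch[1 + 2 * i] = x
            batch[1 + 2 * i][i] += h
            batch[2 + 2 * i] = x
            batch[2 + 2 * i][i] -= h
        f = cost_batch(batch)
        grad = (f[1::2] - f[2::2]) / (2 * h)
        return float(f[0]), grad

    try:
        res = minimize(
            fun_and_grad,
            x_init,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        ok = np.all(np.isfinite(res.x))
    except Exception:  # optimizer blew up: fall back
        res = None
        ok = False

    if not ok:
        warnings.warn("guidance planner failed; falling back to min-jerk path")
        logger.warning("planner fallback at t=%.2f", state_at_crossing.t)
        ref = _minjerk_reference(s0, b, b, horizon, params)
        ref.fallback = True
        return ref

    mass_y, _, _ = _rollout_batch(res.x[None, :], s0, params, horizon, substeps)
    tg, y, yd = _integrate_reference(res.x, s0[2], s0[3], horizon)
    return GuidanceReference(
        horizon=horizon,
        t_grid=tg,
        y_ref=y,
        yd_ref=yd,
        target_offset=b,
        terminal_miss=float(abs(mass_y[0] - b)),
        n_iter=int(res.nit),
        cost=float(res.fun),
    )


def _minjerk_reference(
    s0: np.ndarray,
    uf: float,
    b: float,
    horizon: float,
    params: PendulumParams,
    move_time_frac: float = 0.8,
) -> GuidanceReference:
    move_time = move_time_frac * horizon
    coeffs = minjerk_coeffs(s0[2], s0[3], 0.0, uf, move_time)
    tg = np.linspace(0.0, horizon, 101)
    vals = np.array([minjerk_eval(coeffs, move_time, t)[:2] for t in tg])
    return GuidanceReference(
        horizon=horizon,
        t_grid=tg,
        y_ref=vals[:, 0],
        yd_ref=vals[:, 1],
        target_offset=b,
    )
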