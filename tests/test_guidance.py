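"""Guidance planner and PD controller."""

import numpy as np
import pytest

import hapticlearn.guidance as gd
from hapticlearn.pendulum import PendulumParams, PendulumState
from hapticlearn.protocol import ProtocolConfig, WallTarget, build_protocol
from hapticlearn.guidance import (
    CostWeights,
    PDGains,
    _rollout_batch,
    guidance_active,
    minjerk_coeffs,
    minjerk_eval,
    pd_guidance_force,
    plan_reference,
)


@pytest.fixture(scope="module")
def params():
    return PendulumParams()


class TestPDForce:
    def test_zero_error_zero_force(self):
        ref = gd._minjerk_reference(np.array([0.0, 0.0, 0.1, 0.0]), 0.1, 0.1, 1.0,
                                    PendulumParams())
        assert pd_guidance_force(0.1, 0.0, ref, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_default_gains_proportional(self):
        ref = gd._minjerk_reference(np.array([0.0, 0.0, 0.01, 0.0]), 0.01, 0.01, 1.0,
                                    PendulumParams())
        # e = 0.01 m, edot = 0 at the start of a resting reference
        f = pd_guidance_force(0.0, 0.0, ref, 0.0, PDGains())
        assert f == pytest.approx(75.0 * 0.01, abs=1e-6)

    def test_query_beyond_horizon_clamps(self):
        ref = gd._minjerk_reference(np.array([0.0, 0.0, 0.05, 0.0]), 0.05, 0.05, 1.0,
                                    PendulumParams())
        y_end, yd_end = ref(1.0)
        y_late, yd_late = ref(2.5)
        assert y_late == pytest.approx(y_end)
        assert yd_late == pytest.approx(yd_end)

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            PDGains(kp=-1.0)

    def test_sinusoid_tracking_error_bounded(self):
        """A passive 0.5 kg admittance driven only by the PD tracks a 0.5 Hz
        sinusoid with steady-state error below 20 % of the amplitude."""
        amp, freq, m_e, b_e = 0.05, 0.5, 0.5, 5.0
        horizon, dt = 8.0, 1e-3
        tg = np.arange(0.0, horizon + dt / 2, dt)
        ref = gd.GuidanceReference(
            horizon=horizon, t_grid=tg,
            y_ref=amp * np.sin(2 * np.pi * freq * tg),
            yd_ref=amp * 2 * np.pi * freq * np.cos(2 * np.pi * freq * tg),
            target_offset=0.0,
        )
        y = v = 0.0
        err = []
        gains = PDGains()
        for t in tg:
            f = pd_guidance_force(y, v, ref, t, gains)
            a = (f - b_e * v) / m_e
            y += v * dt + 0.5 * a * dt**2
            v += a * dt
            if t > horizon / 2:
                err.append(abs(ref(t)[0] - y))
        assert max(err) < 0.2 * amp


class TestGuidanceActive:
    @pytest.fixture(scope="class")
    def plan(self):
        return build_protocol("Experimental", np.random.default_rng(0),
                              ProtocolConfig())

    def test_truth_table(self, plan):
        for e in plan:
            expected = (e.stage == "TR" and not e.schedule.catch)
            assert guidance_active(e, "Experimental") == expected
            assert not guidance_active(e, "Control")


class TestMinJerk:
    @pytest.mark.parametrize("u0,v0,a0,uf", [
        (0.0, 0.0, 0.0, 0.12), (-0.1, 0.5, -1.0, 0.2), (0.3, -0.2, 0.4, -0.3),
    ])
    def test_boundary_conditions(self, u0, v0, a0, uf):
        T = 0.8
        c = minjerk_coeffs(u0, v0, a0, uf, T)
        p0, vel0, acc0 = minjerk_eval(c, T, 0.0)
        assert (p0, vel0, acc0) == pytest.approx((u0, v0, a0), abs=1e-10)
        pT, velT, accT = minjerk_eval(c, T, T - 1e-12)
        assert pT == pytest.approx(uf, abs=1e-6)
        assert velT == pytest.approx(0.0, abs=1e-5)
        assert accT == pytest.approx(0.0, abs=1e-4)


class TestPlanner:
    def test_aligned_rest_is_already_optimal(self, params):
        tgt = WallTarget(0, 0.12, 1.0)
        st = PendulumState(pivot_y=0.12)
        ref = plan_reference(st, tgt, params)
        assert ref.terminal_miss < 1e-4
        assert not ref.fallback

    def test_mirror_equivariance(self, params):
        st = PendulumState(theta=0.3, theta_dot=0.5, pivot_y=-0.08, pivot_vy=0.1)
        stm = PendulumState(theta=-0.3, theta_dot=-0.5, pivot_y=0.08, pivot_vy=-0.1)
        ref = plan_reference(st, WallTarget(0, 0.12, 1.0), params)
        refm = plan_reference(stm, WallTarget(0, -0.12, 1.0), params)
        assert np.max(np.abs(ref.y_ref + refm.y_ref)) < 1e-9
        assert ref.cost == pytest.approx(refm.cost, rel=1e-9)

    def test_beats_restricted_polynomial_family(self, params):
        """Cost is within 1 % of an exhaustive search over quadratic
        acceleration profiles evaluated by forward simulation."""
        w = CostWeights()
        s0 = np.array([0.3, 0.5, -0.08, 0.1])
        st = PendulumState(theta=0.3, theta_dot=0.5, pivot_y=-0.08, pivot_vy=0.1)
        b = 0.12
        t_nodes = np.linspace(0, 1, 21)
        grid = np.linspace(-6, 6, 13)
        profs = np.array([
            c0 + c1 * t_nodes + c2 * t_nodes**2
            for c0 in grid for c1 in grid for c2 in grid
        ])
        my, stab, ueff = _rollout_batch(profs, s0, params, 1.0, 5)
        oracle = np.min(w.w_acc * (my - b) ** 2 + w.w_stab * stab + w.w_u * ueff)
        ref = plan_reference(st, WallTarget(0, b, 1.0), params, weights=w)
        assert ref.cost <= 1.01 * oracle

    def test_cost_non_increasing_with_nodes(self, params):
        st = PendulumState(theta=0.2, theta_dot=-0.4, pivot_y=0.05, pivot_vy=0.0)
        tgt = WallTarget(0, -0.12, 1.0)
        c10 = plan_reference(st, tgt, params, n_nodes=10, maxiter=300).cost
        c20 = plan_reference(st, tgt, params, n_nodes=20, maxiter=300).cost
        assert c20 <= c10 * (1 + 1e-3) + 1e-6

    def test_minjerk_backend_compensates_swing(self, params):
        st = PendulumState(theta=0.2, theta_dot=0.3, pivot_y=-0.05, pivot_vy=0.2)
        ref = plan_reference(st, WallTarget(0, 0.12, 1.0), params,
                             backend="minjerk")
        assert np.isfinite(ref.y_ref).all()
        assert abs(ref.y_ref[0] - st.pivot_y) < 1e-9

    def test_unknown_backend_rejected(self, params):
        with pytest.raises(ValueError):
            plan_reference(PendulumState(), WallTarget(0, 0.0, 1.0), params,
                           backend="magic")

    def test_optimizer_failure_falls_back_to_minjerk(self, params, monkeypatch):
        def boom(*a, **k):
            raise RuntimeError("no convergence")

        monkeypatch.setattr(gd, "minimize", boom)
        with pytest.warns(UserWarning, match="falling back"):
            ref = plan_reference(PendulumState(), WallTarget(0, 0.12, 1.0), params)
        assert ref.fallback
        assert np.isfinite(ref.y_ref).all()
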