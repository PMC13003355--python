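"""Micro-aerobic sulfide oxidation tank: PI control, aeration
correlation, steady states and sulfur bookkeeping."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from bioscrub.oxidizer import (
    OxidizerConfig,
    PIControllerConfig,
    airflow_from_kla,
    kla_from_airflow,
    pi_step,
    simulate_oxidizer,
    solve_oxidizer_steady,
)
from bioscrub.streams import LiquidStream


class TestPiStep:
    def test_zero_error_zero_integral_gives_bias(self):
        cfg = PIControllerConfig(bias=5.0, output_min=0.0, output_max=100.0)
        u, integral = pi_step(0.0, 0.0, cfg, dt=0.1)
        assert u == 5.0 and integral == 0.0

    def test_lower_bound_when_no_bias(self):
        cfg = PIControllerConfig(output_min=2.0, output_max=100.0, bias=0.0)
        u, _ = pi_step(0.0, 0.0, cfg, dt=0.1)
        assert u == 2.0

    def test_unclamped_formula(self):
        cfg = PIControllerConfig(Kp=10.0, Ki_gain=4.0, output_min=-1e9, output_max=1e9)
        u, integral = pi_step(0.3, 1.0, cfg, dt=0.5)
        assert integral == pytest.approx(1.0 + 0.3 * 0.5)
        assert u == pytest.approx(10.0 * 0.3 + 4.0 * integral)

    def test_anti_windup_freezes_integral_at_upper_bound(self):
        cfg = PIControllerConfig(Kp=1.0, Ki_gain=1.0, output_min=0.0, output_max=10.0)
        integral = 50.0
        u, new_integral = pi_step(5.0, integral, cfg, dt=1.0)
        assert u == 10.0
        assert new_integral == integral  # frozen while pinned

    def test_integral_resumes_when_error_reverses(self):
        cfg = PIControllerConfig(Kp=1.0, Ki_gain=1.0, output_min=0.0, output_max=10.0)
        _, new_integral = pi_step(-2.0, 50.0, cfg, dt=1.0)
        assert new_integral == 48.0  # unwinding allowed

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            pi_step(0.0, 0.0, PIControllerConfig(), dt=0.0)

    def test_closed_loop_matches_matrix_exponential(self):
        """Continuous PI on a first-order plant dy/dt = -a y + b u,
        u = Kp e + Ki z, dz/dt = e, e = r - y.  The closed loop is the
        linear system with the analytic solution via the matrix
        exponential (the Laplace-domain second-order response)."""
        a, b, kp, ki, r = 1.3, 0.7, 2.0, 1.5, 1.0

        def rhs(_t, s):
            y, z = s
            e = r - y
            u = kp * e + ki * z
            return [-a * y + b * u, e]

        sol = solve_ivp(rhs, (0.0, 8.0), [0.0, 0.0], rtol=1e-11, atol=1e-13, dense_output=True)
        # independent closed form: s' = A s + c, solution via expm on the
        # augmented (state + constant) system
        A = np.array([[-a - b * kp, b * ki, (b * kp + 0.0) * r], [-1.0, 0.0, r], [0.0, 0.0, 0.0]])
        for t in (0.5, 2.0, 8.0):
            phi = expm(A * t)
            s = phi @ np.array([0.0, 0.0, 1.0])
            np.testing.assert_allclose(sol.sol(t), s[:2], rtol=1e-6, atol=1e-8)


class TestKlaCorrelation:
    def test_zero_airflow(self):
        assert kla_from_airflow(0.0, 19.0, 0.8, 2277.0) == 0.0

    def test_linear_when_beta_is_one(self):
        k1 = kla_from_airflow(50.0, 3.0, 1.0, 1000.0)
        assert kla_from_airflow(100.0, 3.0, 1.0, 1000.0) == pytest.approx(2 * k1, rel=1e-12)

    @pytest.mark.parametrize("alpha,beta,q", [(19.0, 0.8, 137.0), (5.5, 1.2, 42.0)])
    def test_hand_evaluation_and_inverse(self, alpha, beta, q):
        v = 2277.0
        expected = alpha * (q / v) ** beta
        k = kla_from_airflow(q, alpha, beta, v)
        assert k == pytest.approx(expected, rel=1e-12)
        assert airflow_from_kla(k, alpha, beta, v) == pytest.approx(q, rel=1e-10)

    def test_monotone_increasing(self):
        ks = [kla_from_airflow(q, 19.0, 0.8, 2277.0) for q in (10, 50, 200, 800)]
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_config_errors(self):
        with pytest.raises(ValueError):
            kla_from_airflow(10.0, -1.0, 0.8, 100.0)
        with pytest.raises(ValueError):
            kla_from_airflow(10.0, 1.0, 0.0, 100.0)


BASE_FEED = LiquidStream(
    217.8, solutes={"sulfide": 0.25, "sulfate": 0.1, "cod": 0.3, "ic": 0.06}
)


class TestOxidizerSteady:
    def test_clean_feed_gives_no_biosulfur_and_minimal_air(self):
        feed = LiquidStream(217.8, solutes={})
        res = solve_oxidizer_steady(feed, OxidizerConfig())
        assert res.biosulfur_production == pytest.approx(0.0, abs=1e-12)
        assert res.air_demand < 2.0  # only the DO washout trickle

    def test_sulfur_balance_on_random_feasible_feeds(self):
        rng = np.random.default_rng(99)
        cfg = OxidizerConfig()
        for _ in range(5):
            feed = LiquidStream(
                float(rng.uniform(100, 300)),
                solutes={
                    "sulfide": float(rng.uniform(0.05, 0.4)),
                    "sulfate": float(rng.uniform(0, 0.2)),
                    "thiosulfate": float(rng.uniform(0, 0.05)),
                    "cod": float(rng.uniform(0, 0.5)),
                    "ic": float(rng.uniform(0, 0.1)),
                },
            )
            res = solve_oxidizer_steady(feed, cfg)
            q = feed.volumetric_flow * 1000.0  # L h-1
            s_in = sum(feed.solutes.get(k, 0.0) for k in ("sulfide", "sulfate", "thiosulfate")) * q
            e = res.effluent.solutes
            s_out = (e["sulfide"] + e["s0"] + e["thiosulfate"] + e["sulfate"]) * q
            s_gas = res.off_gas["H2S"] * 1000.0 * (32.0 / 34.0)
            assert (s_out + s_gas) == pytest.approx(s_in, rel=1e-6)

    def test_low_do_favors_elemental_sulfur(self):
        splits = []
        for sp in (0.05, 0.1, 0.5, 2.0):
            cfg = OxidizerConfig(do_setpoint=sp)
            res = solve_oxidizer_steady(BASE_FEED, cfg)
            e = res.effluent.solutes
            total = e["s0"] + e["sulfate"] - BASE_FEED.solutes["sulfate"]
            splits.append(e["s0"] / total)
        assert all(b < a for a, b in zip(splits, splits[1:]))

    def test_air_demand_nondecreasing_in_sulfide_load(self):
        airs = []
        for s in (0.05, 0.15, 0.3, 0.5):
            feed = LiquidStream(217.8, solutes={"sulfide": s})
            airs.append(solve_oxidizer_steady(feed, OxidizerConfig()).air_demand)
        assert all(b >= a for a, b in zip(airs, airs[1:]))

    def test_infeasible_control_flagged(self):
        cfg = OxidizerConfig()
        cfg.controller.output_max = 5.0  # absurdly small blower
        res = solve_oxidizer_steady(BASE_FEED, cfg)
        assert res.infeasible_control


class TestOxidizerDynamics:
    def test_do_settles_to_setpoint(self):
        res = simulate_oxidizer(BASE_FEED, OxidizerConfig(), horizon=150.0)
        assert res.do_steady == pytest.approx(0.1, abs=0.01)
        assert res.steady
        assert not res.infeasible_control
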