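"""Micro-aerobic sulfide-oxidation CSTR with PI dissolved-oxygen control.

Sulfur-oxidizing bacteria (SOB) use sulfide, elemental sulfur and
thiosulfate as electron donors in a three-step chain::

    HS-  + 1/2 O2 -> S0          (partial oxidation, low-DO step)
    S0   + 3/2 O2 -> SO4^2-      (over-oxidation, suppressed at low DO)
    S2O3 +  O2    -> SO4^2-

plus a small abiotic sulfide -> thiosulfate route and a single aerobic
heterotrophic growth process on residual COD (Activated Sludge Model
family defaults).  Selectivity toward elemental biosulfur is enforced by
holding the dissolved oxygen at a low set point (0.1 mg O2 L-1) with a
PI controller acting on the air flow; the volumetric transfer
coefficient follows a power-law correlation ``kLa = alpha (Q/V)^beta``.

Sulfur species are g S L-1, COD in g COD L-1, DO in mg O2 L-1; kinetic
rates are per day, the simulation clock is hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import chemistry
from .streams import LiquidStream

__all__ = [
    "PIControllerConfig",
    "OxidizerConfig",
    "OxidizerState",
    "OxidizerResult",
    "pi_step",
    "kla_from_airflow",
    "airflow_from_kla",
    "simulate_oxidizer",
    "solve_oxidizer_steady",
]


@dataclass
class PIControllerConfig:
    setpoint: float = 0.1  # mg O2 L-1
    Kp: float = 120.0  # m3 h-1 per mg L-1
    Ki_gain: float = 60.0  # m3 h-1 per (mg L-1 h)
    output_min: float = 0.0  # m3 h-1
    output_max: float = 2000.0  # m3 h-1
    bias: float = 0.0  # m3 h-1 added to the PI action
    anti_windup: bool = True

    def __post_init__(self) -> None:
        if self.output_min > self.output_max:
            raise ValueError("output bounds must be ordered")
        if self.Kp < 0 or self.Ki_gain < 0:
            raise ValueError("gains must be >= 0")


def pi_step(
    error: float,
    integral_state: float,
    cfg: PIControllerConfig,
    dt: float,
) -> tuple[float, float]:
    """One discrete PI update.

    Returns ``(airflow, new_integral_state)``.  Output is clamped to the
    configured bounds; with ``anti_windup`` the integral is frozen while
    the output is pinned and the update would push it further into the
    limit.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    candidate = integral_state + error * dt
    u_unclamped = cfg.bias + cfg.Kp * error + cfg.Ki_gain * candidate
    u = min(max(u_unclamped, cfg.output_min), cfg.output_max)
    if cfg.anti_windup and u != u_unclamped and (u_unclamped - u) * error > 0:
        candidate = integral_state  # freeze
        u_unclamped = cfg.bias + cfg.Kp * error + cfg.Ki_gain * candidate
        u = min(max(u_unclamped, cfg.output_min), cfg.output_max)
    return u, candidate


def kla_from_airflow(airflow: float, alpha: float, beta: float, volume: float) -> float:
    """Power-law aeration correlation, kLa (h-1) from air flow (m3 h-1)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if airflow < 0:
        raise ValueError("airflow must be >= 0")
    if airflow == 0.0:
        return 0.0
    return alpha * (airflow / volume) ** beta


def airflow_from_kla(kla: float, alpha: float, beta: float, volume: float) -> float:
    """Inverse of :func:`kla_from_airflow`."""
    if kla <= 0:
        return 0.0
    return volume * (kla / alpha) ** (1.0 / beta)


@dataclass
class OxidizerConfig:
    volume: float = 2277.0  # m3
    do_setpoint: float = 0.1  # mg O2 L-1
    do_saturation: float = 8.0  # mg O2 L-1
    # power-law aeration correlation; alpha anchored so the baseline air
    # demand is the design blower duty of 100 m3 h-1
    alpha: float = 43.297  # kLa correlation prefactor (h-1)
    beta: float = 0.8  # kLa correlation exponent
    controller: PIControllerConfig = field(default_factory=PIControllerConfig)
    # SOB kinetics: (qmax g S / g COD-biomass / d, Ks g S L-1, Ko mg O2 L-1)
    q_sulfide_s0: tuple[float, float, float] = (4.0, 0.02, 0.02)
    q_s0_sulfate: tuple[float, float, float] = (1.0, 0.30, 0.60)
    q_thio_sulfate: tuple[float, float, float] = (2.0, 0.05, 0.20)
    k_abiotic: float = 0.6  # L mg-1 d-1, sulfide + O2 -> thiosulfate
    # heterotrophs, ASM2-typical: mu_max d-1, Ks g COD L-1, yield, Ko mg L-1
    het_mu_max: float = 6.0
    het_Ks: float = 0.004
    het_yield: float = 0.63
    het_Ko: float = 0.2
    x_sob: float = 0.35  # g COD L-1 retained SOB inventory
    x_het: float = 0.20  # g COD L-1
    # stripping kLa relative to the O2 kLa; sulfide is consumed near the
    # bubble interface (bio-enhanced absorption), so its effective
    # stripping ratio is far below the CO2 one
    strip_kla_ratio_h2s: float = 0.005
    strip_kla_ratio_co2: float = 0.05
    reactor_ph: float = 7.0


# state vector ordering for the dynamic simulation
STATE_NAMES = ["sulfide", "s0", "thiosulfate", "sulfate", "cod", "ic", "do", "pi_integral"]


@dataclass
class OxidizerState:
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.concentrations.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0")


@dataclass
class OxidizerResult:
    effluent: LiquidStream
    biosulfur_production: float  # kg S h-1 (particulate S0 leaving the tank)
    air_demand: float  # m3 h-1 at steady state
    off_gas: dict[str, float]  # kg h-1: CO2, H2S
    do_steady: float  # mg O2 L-1
    do_trajectory: tuple[np.ndarray, np.ndarray] | None
    steady: bool
    infeasible_control: bool


def _rates(c: dict[str, float], do: float, cfg: OxidizerConfig) -> dict[str, float]:
    """Volumetric rates, g L-1 d-1 (S species in g S, cod in g COD, o2 in g O2)."""
    s, s0, thio, cod = c["sulfide"], c["s0"], c["thiosulfate"], c["cod"]
    q1, ks1, ko1 = cfg.q_sulfide_s0
    q2, ks2, ko2 = cfg.q_s0_sulfate
    q3, ks3, ko3 = cfg.q_thio_sulfate
    r1 = q1 * cfg.x_sob * s / (ks1 + s) * do / (ko1 + do)
    r2 = q2 * cfg.x_sob * s0 / (ks2 + s0) * do / (ko2 + do)
    r3 = q3 * cfg.x_sob * thio / (ks3 + thio) * do / (ko3 + do)
    r4 = cfg.k_abiotic * s * do
    growth = cfg.het_mu_max * cfg.x_het * cod / (cfg.het_Ks + cod) * do / (cfg.het_Ko + do)
    r_cod = growth / cfg.het_yield
    our = 0.5 * r1 + 1.5 * r2 + 1.0 * r3 + 1.0 * r4 + (1.0 - cfg.het_yield) * r_cod
    return {
        "sulfide": -(r1 + r4),
        "s0": r1 - r2,
        "thiosulfate": r4 - r3,
        "sulfate": r2 + r3,
        "cod": -r_cod,
        "ic": 0.3 * r_cod,  # mineralized COD carbon, g C L-1 d-1
        "o2": our,
    }


def _strip_fluxes(c: dict[str, float], kla_o2: float, cfg: OxidizerConfig) -> dict[str, float]:
    """Aeration stripping of H2S and CO2 (g L-1 d-1 leaving the liquid)."""
    a_h2s = float(chemistry.species_fractions(chemistry.SULFIDE, cfg.reactor_ph)[0])
    a_co2 = float(chemistry.species_fractions(chemistry.CARBONATE, cfg.reactor_ph)[0])
    return {
        "sulfide": cfg.strip_kla_ratio_h2s * kla_o2 * 24.0 * a_h2s * max(c["sulfide"], 0.0),
        "ic": cfg.strip_kla_ratio_co2 * kla_o2 * 24.0 * a_co2 * max(c["ic"], 0.0),
    }


def simulate_oxidizer(
    feed: LiquidStream,
    cfg: OxidizerConfig | None = None,
    horizon: float = 200.0,  # h
    *,
    keep_trajectory: bool = False,
    dt_control: float = 0.05,  # h, discrete PI sampling inside the ODE
) -> OxidizerResult:
    """Dynamic simulation with the PI loop active, polished to steady state.

    Feed solute keys: ``sulfide``/``s0``/``thiosulfate``/``sulfate``
    (g S L-1), ``cod`` (g COD L-1; UASB organics are lumped), ``ic``.
    """
    cfg = cfg or OxidizerConfig()
    ctrl = cfg.controller
    D = feed.volumetric_flow / cfg.volume  # h-1
    c_in = {
        "sulfide": feed.solutes.get("sulfide", 0.0),
        "s0": feed.solutes.get("s0", 0.0),
        "thiosulfate": feed.solutes.get("thiosulfate", 0.0),
        "sulfate": feed.solutes.get("sulfate", 0.0),
        "cod": feed.solutes.get("cod", sum(
            feed.solutes.get(k, 0.0)
            for k in ("glycerol", "pdo", "propionate", "butyrate", "acetate", "h2", "ch4")
        )),
        "ic": feed.solutes.get("ic", 0.0),
    }

    def rhs(_t, y, u_air):
        c = dict(zip(STATE_NAMES[:6], np.maximum(y[:6], 0.0)))
        do = max(y[6], 0.0)
        r = _rates(c, do, cfg)
        kla = kla_from_airflow(u_air, cfg.alpha, cfg.beta, cfg.volume)
        strip = _strip_fluxes(c, kla, cfg)
        dy = np.empty(7)
        for i, sp in enumerate(STATE_NAMES[:6]):
            dy[i] = D * (c_in[sp] - y[i]) + r[sp] / 24.0 - strip.get(sp, 0.0) / 24.0
        dy[6] = kla * (cfg.do_saturation - do) - r["o2"] * 1000.0 / 24.0 + D * (0.0 - do)
        return dy

    # piecewise integration with zero-order-hold PI control
    y = np.array([c_in[sp] for sp in STATE_NAMES[:6]] + [cfg.do_setpoint])
    integral = 0.0
    t_now = 0.0
    ts, dos = [0.0], [y[6]]
    n_steps = int(np.ceil(horizon / dt_control))
    u_air = ctrl.output_min
    for _ in range(n_steps):
        err = ctrl.setpoint - y[6]
        u_air, integral = pi_step(err, integral, ctrl, dt_control)
        sol = solve_ivp(
            rhs, (t_now, t_now + dt_control), y, args=(u_air,),
            method="LSODA", rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            raise ArithmeticError(f"oxidizer integration failed: {sol.message}")
        y = sol.y[:, -1]
        t_now += dt_control
        ts.append(t_now)
        dos.append(y[6])

    steady_res = solve_oxidizer_steady(feed, cfg)
    # keep the dynamic DO answer; report steady species from the polished solve
    do_final = float(y[6])
    settled = abs(do_final - ctrl.setpoint) < 0.01
    traj = (np.asarray(ts), np.asarray(dos)) if keep_trajectory else None
    return OxidizerResult(
        effluent=steady_res.effluent,
        biosulfur_production=steady_res.biosulfur_production,
        air_demand=steady_res.air_demand,
        off_gas=steady_res.off_gas,
        do_steady=do_final,
        do_trajectory=traj,
        steady=settled and steady_res.steady,
        infeasible_control=steady_res.infeasible_control,
    )


def solve_oxidizer_steady(
    feed: LiquidStream,
    cfg: OxidizerConfig | None = None,
) -> OxidizerResult:
    """Algebraic steady state with DO pinned at the set point.

    Integral action guarantees DO = setpoint whenever the required air
    flow lies inside the actuator bounds; the air flow is recovered from
    the oxygen balance and infeasibility (demand beyond the maximum
    blower capacity) is flagged, not silently absorbed.
    """
    cfg = cfg or OxidizerConfig()
    D = feed.volumetric_flow / cfg.volume  # h-1
    do = cfg.do_setpoint
    c_in = {
        "sulfide": feed.solutes.get("sulfide", 0.0),
        "s0": feed.solutes.get("s0", 0.0),
        "thiosulfate": feed.solutes.get("thiosulfate", 0.0),
        "sulfate": feed.solutes.get("sulfate", 0.0),
        "cod": feed.solutes.get("cod", sum(
            feed.solutes.get(k, 0.0)
            for k in ("glycerol", "pdo", "propionate", "butyrate", "acetate", "h2", "ch4")
        )),
        "ic": feed.solutes.get("ic", 0.0),
    }
    names = STATE_NAMES[:6]

    # stripping needs kLa which needs the O2 balance: fixed-point iterate
    kla_o2 = 1.0
    x = np.array([c_in[sp] for sp in names])
    for _ in range(60):
        def resid(v, kla_now=kla_o2):
            c = dict(zip(names, np.maximum(v, 0.0)))
            r = _rates(c, do, cfg)
            strip = _strip_fluxes(c, kla_now, cfg)
            return np.array([
                D * (c_in[sp] - v[i]) + r[sp] / 24.0 - strip.get(sp, 0.0) / 24.0
                for i, sp in enumerate(names)
            ])

        sol = root(resid, x, method="hybr", tol=1e-12)
        x = np.maximum(sol.x, 0.0)
        c = dict(zip(names, x))
        our = _rates(c, do, cfg)["o2"] * 1000.0 / 24.0  # mg L-1 h-1
        kla_new = (our + D * do) / max(cfg.do_saturation - do, 1e-9)
        if abs(kla_new - kla_o2) < 1e-12 * max(kla_new, 1.0):
            kla_o2 = kla_new
            break
        kla_o2 = kla_new

    # steadiness judged by the residual itself, not the solver's status
    # flag (hybr reports spurious xtol failures at tight tolerances)
    res_vec = resid(x, kla_o2)
    scale = np.maximum(np.abs(x) * D, 1e-12)
    is_steady = bool(np.max(np.abs(res_vec) / scale) < 1e-6)
    air = airflow_from_kla(kla_o2, cfg.alpha, cfg.beta, cfg.volume)
    infeasible = air > cfg.controller.output_max
    strip = _strip_fluxes(c, kla_o2, cfg)
    q_l_h = feed.volumetric_flow * 1000.0  # L h-1
    biosulfur = c["s0"] * q_l_h / 1000.0  # g S L-1 * L h-1 -> kg S h-1
    v_l = cfg.volume * 1000.0  # L
    off_gas = {
        "H2S": strip["sulfide"] / 24.0 * v_l / 1000.0 * (34.0 / 32.0),  # kg h-1
        "CO2": strip["ic"] / 24.0 * v_l / 1000.0 * (44.0 / 12.0),  # kg h-1
    }
    effluent = LiquidStream(
        volumetric_flow=feed.volumetric_flow,
        totals=feed.totals.copy() if feed.totals is not None else None,
        solutes={**{sp: float(c[sp]) for sp in names}},
        temperature=35.0,
    )
    return OxidizerResult(
        effluent=effluent,
        biosulfur_production=float(biosulfur),
        air_demand=float(air),
        off_gas=off_gas,
        do_steady=do,
        do_trajectory=None,
        steady=is_steady,
        infeasible_control=bool(infeasible),
    )
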