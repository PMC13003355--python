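"""Spray absorber: counter-current series of stirred stages with two-film
gas-liquid transfer of SO2 and CO2 into caustic-buffered liquor.

Each stage is a well-mixed gas/liquid contactor.  Only the neutral,
fully protonated dissolved form (SO2.H2O, H2CO3*) exerts a back
pressure; the ionic forms are held in solution by the stage pH, which is
resolved from the stage's ionic totals by the charge-balance solver.
Gas flows up (stage 0 = bottom inlet), liquid flows down.

Transfer per stage::

    T_s = kLa_s * V_stage * (C*_s - alpha0_s(pH) * total_s)   [mol h-1]
    C*_s = p_s / H_s                                          [mol L-1]

with ``H_s`` a Henry volatility constant in atm L mol-1 and ``p_s`` the
stage partial pressure.  A single dimensionless ``kla_scale`` multiplies
all kLa values; it is the one calibration scalar of the column (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import root

from . import chemistry
from .chemistry import AcidSystem, IonicTotals, solve_ph, species_fractions
from .streams import GasStream, LiquidStream

__all__ = [
    "AbsorberConfig",
    "AbsorberResult",
    "DEFAULT_HENRY",
    "SPECIES_SYSTEM",
    "equilibrium_concentration",
    "simulate_absorber",
    "calibrate_kla_scale",
]

# Henry volatility constants at 25 degC, atm L mol-1 (C* = p / H).
DEFAULT_HENRY: dict[str, float] = {
    "SO2": 0.81,
    "CO2": 29.4,
    "H2S": 9.8,
    "O2": 769.0,
    "CH4": 714.0,
    "H2": 1282.0,
}

# Which acid system buffers each transferable gas; the neutral exchanging
# species is always the fully protonated member (index 0).
SPECIES_SYSTEM: dict[str, AcidSystem] = {
    "SO2": chemistry.SULFUROUS,
    "CO2": chemistry.CARBONATE,
    "H2S": chemistry.SULFIDE,
}


@dataclass
class AbsorberConfig:
    n_stages: int = 5
    kla: dict[str, float] = field(
        default_factory=lambda: {"SO2": 150.0, "CO2": 150.0}
    )  # h-1, per stage
    kla_scale: float = 1.0  # single calibration scalar on all kLa
    stage_liquid_volume: float = 0.74  # m3 per stage (total holdup 3.7 m3 / 5)
    henry_constants: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HENRY))

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.stage_liquid_volume <= 0 or self.kla_scale < 0:
            raise ValueError("volumes and kla_scale must be positive")
        for sp, h in self.henry_constants.items():
            if h <= 0:
                raise ValueError(f"Henry constant for {sp} must be > 0")


@dataclass
class AbsorberResult:
    gas_out: GasStream
    liquid_out: LiquidStream
    absorption_efficiency: dict[str, float]  # percent, per species
    stage_ph: np.ndarray
    stage_totals: dict[str, np.ndarray]  # system totals per stage, mol L-1


def equilibrium_concentration(partial_pressure: float, henry: float) -> float:
    """Liquid-phase concentration (mol L-1) in equilibrium with ``partial_pressure``.

    Linear in the partial pressure (C* = p / H), zero at zero.
    """
    if henry <= 0:
        raise ValueError("Henry constant must be > 0")
    if partial_pressure < 0:
        raise ValueError("partial pressure must be >= 0")
    return partial_pressure / henry


def _neutral_fraction(species: str, pH: float) -> float:
    return float(species_fractions(SPECIES_SYSTEM[species], pH)[0])


def _stage_ph(base: IonicTotals, stage_totals: dict[str, float]) -> float:
    totals = base.copy()
    for sp, t in stage_totals.items():
        totals.totals_per_system[SPECIES_SYSTEM[sp]] = max(t, 0.0)
    return solve_ph(totals).pH


def simulate_absorber(
    gas_in: GasStream,
    liquid_in: LiquidStream,
    cfg: AbsorberConfig,
    horizon: float | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> AbsorberResult:
    """Steady-state counter-current column solution.

    ``horizon`` (h) optionally integrates the liquid-holdup dynamics
    before polishing to steady state; the returned state is always the
    converged steady state (the gas phase is quasi-static either way:
    its residence time is seconds against liquor minutes).
    """
    species = [sp for sp in cfg.kla if sp in SPECIES_SYSTEM]
    n = cfg.n_stages
    if liquid_in.totals is None:
        raise ValueError("absorber liquid inlet needs IonicTotals")
    L = liquid_in.volumetric_flow * 1000.0  # L h-1
    if L <= 0:
        raise ValueError("liquid flow must be > 0")
    inert = gas_in.total_molar_flow - sum(gas_in.molar_flow(sp) for sp in species)
    n_in = {sp: gas_in.molar_flow(sp) for sp in species}
    a = {
        sp: cfg.kla_scale * cfg.kla[sp] * cfg.stage_liquid_volume * 1000.0
        for sp in species
    }  # L h-1

    base = liquid_in.totals.copy()
    t_inlet = {
        sp: base.totals_per_system.get(SPECIES_SYSTEM[sp], 0.0) for sp in species
    }
    # stage liquid totals, index 0 = bottom stage (liquid outlet)
    t = {sp: np.full(n, t_inlet[sp]) for sp in species}

    if all(a[sp] == 0.0 for sp in species):
        # no transfer at all: passthrough
        eff = {sp: 0.0 for sp in species}
        ph = np.array(
            [_stage_ph(base, {sp: t_inlet[sp] for sp in species})] * n
        )
        return AbsorberResult(gas_in, liquid_in, eff, ph, {sp: t[sp].copy() for sp in species})

    def march(t_arr: dict[str, np.ndarray]):
        """Gas march bottom-up, then liquid march top-down; returns new t, gas flows."""
        # gas profile with current liquid totals
        n_gas = {sp: np.empty(n) for sp in species}
        ph = np.empty(n)
        for i in range(n):
            ph[i] = _stage_ph(base, {sp: t_arr[sp][i] for sp in species})
        for i in range(n):
            inflow = {sp: (n_gas[sp][i - 1] if i > 0 else n_in[sp]) for sp in species}
            # the stage is well mixed: its total molar flow includes the
            # species at *outlet* levels; self-consistent inner iteration
            total_gas = inert + sum(inflow.values())
            for _ in range(30):
                for sp in species:
                    c = gas_in.pressure / (total_gas * cfg.henry_constants[sp])
                    d = _neutral_fraction(sp, ph[i]) * max(t_arr[sp][i], 0.0)
                    n_gas[sp][i] = (inflow[sp] + a[sp] * d) / (1.0 + a[sp] * c)
                new_total = inert + sum(n_gas[sp][i] for sp in species)
                if abs(new_total - total_gas) < 1e-12 * total_gas:
                    total_gas = new_total
                    break
                total_gas = new_total
        # liquid march top-down with the gas profile fixed
        t_new = {sp: np.empty(n) for sp in species}
        for i in range(n - 1, -1, -1):
            above = {
                sp: (t_new[sp][i + 1] if i < n - 1 else t_inlet[sp]) for sp in species
            }
            total_gas = inert + sum(n_gas[s2][i] for s2 in species)
            p = {sp: gas_in.pressure * n_gas[sp][i] / total_gas for sp in species}

            def resid(x, above=above, p=p, i=i):
                ti = {sp: max(x[k], 0.0) for k, sp in enumerate(species)}
                ph_i = _stage_ph(base, ti)
                out = np.empty(len(species))
                for k, sp in enumerate(species):
                    cstar = equilibrium_concentration(p[sp], cfg.henry_constants[sp])
                    T = a[sp] * (cstar - _neutral_fraction(sp, ph_i) * ti[sp])
                    out[k] = above[sp] + T / L - x[k]
                return out

            x0 = np.array([t_arr[sp][i] for sp in species])
            sol = root(resid, x0, method="hybr", tol=1e-14)
            xi = np.maximum(sol.x, 0.0)
            for k, sp in enumerate(species):
                t_new[sp][i] = xi[k]
        return t_new, n_gas, ph

    if horizon is not None and horizon > 0:
        # crude explicit relaxation of liquid holdup dynamics toward steady
        # state before polishing; tau = stage holdup / liquid flow
        tau = cfg.stage_liquid_volume * 1000.0 / L
        steps = max(int(horizon / tau), 1)
        for _ in range(min(steps, 50)):
            t_next, _, _ = march(t)
            for sp in species:
                t[sp] = 0.5 * t[sp] + 0.5 * t_next[sp]

    omega = 1.0  # under-relaxation kicks in if the stage map oscillates
    err_prev = np.inf
    for it in range(max_iter):
        t_next, n_gas, ph = march(t)
        err = max(
            float(np.max(np.abs(t_next[sp] - t[sp]) / (1e-12 + np.abs(t_next[sp]))))
            for sp in species
        )
        if err > err_prev and omega > 0.3:
            omega *= 0.5
        err_prev = err
        for sp in species:
            t[sp] = t[sp] + omega * (t_next[sp] - t[sp])
        if err < tol:
            break
    else:
        raise ArithmeticError(
            f"absorber stage iteration did not converge (last rel change {err:.3e})"
        )

    gas_out = GasStream.from_molar_flows(
        {
            **{
                sp: gas_in.molar_flow(sp)
                for sp in gas_in.composition
                if sp not in species
            },
            **{sp: n_gas[sp][n - 1] for sp in species},
        },
        inert_mol_h=inert
        - sum(
            gas_in.molar_flow(sp) for sp in gas_in.composition if sp not in species
        ),
        temperature=gas_in.temperature,
        pressure=gas_in.pressure,
    )
    out_totals = base.copy()
    for sp in species:
        out_totals.totals_per_system[SPECIES_SYSTEM[sp]] = float(t[sp][0])
    liquid_out = LiquidStream(
        volumetric_flow=liquid_in.volumetric_flow,
        totals=out_totals,
        solutes=dict(liquid_in.solutes),
        temperature=liquid_in.temperature,
    )
    eff = {}
    for sp in species:
        if n_in[sp] > 0:
            eff[sp] = 100.0 * (1.0 - n_gas[sp][n - 1] / n_in[sp])
        else:
            eff[sp] = 0.0
    return AbsorberResult(gas_out, liquid_out, eff, ph, {sp: t[sp].copy() for sp in species})


def calibrate_kla_scale(
    gas_in: GasStream,
    liquid_in: LiquidStream,
    cfg: AbsorberConfig,
    target_so2_efficiency: float,
    *,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Tune the single overall ``kla_scale`` so the SO2 absorption
    efficiency (%) matches ``target_so2_efficiency`` for the given inlet
    streams.  Returns the scale; the config is not mutated."""
    from scipy.optimize import brentq

    def f(scale: float) -> float:
        res = simulate_absorber(gas_in, liquid_in, replace(cfg, kla_scale=scale))
        return res.absorption_efficiency["SO2"] - target_so2_efficiency

    return brentq(f, *bounds, xtol=1e-10, rtol=1e-12)
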