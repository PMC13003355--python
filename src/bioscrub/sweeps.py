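"""2-D sensitivity sweeps: grids of Relative Impact Ratio values for the
key environmental and cost indicators over pairs of operating
parameters (gas flow x inlet SO2; purge fraction x disposal distance),
plus orchestration of the price breakeven analysis.

Every grid cell is a full pipeline evaluation: simulate both scenarios
of the pair to steady state, build inventories, characterize, cost, and
compute the RIR per indicator.  Cells are seeded from the *baseline*
solution only (never from neighboring cells), so the result is
independent of evaluation order and bit-identical across repeat runs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lcc import LccResult, PriceTable, assess_costs, breakeven_grid
from .lcia import CharacterizationTable, characterize, classify_rir, rir
from .plant import PlantConfig, build_inventory, simulate_plant

__all__ = ["SweepAxis", "SweepSpec", "SweepResult", "sweep_2d", "export_contours"]

SWEEPABLE = ("gas_flow", "so2_ppmv", "purge_percent", "distance_km")

DEFAULT_KPIS = (
    "HCT", "FET", "MET", "FE", "TET", "GWP",
    "operational_cost", "investment_cost",
)


@dataclass
class SweepAxis:
    parameter: str
    minimum: float
    maximum: float
    n_points: int = 20
    scale: str = "linear"  # linear | log

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; choose from {SWEEPABLE}"
            )
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be linear or log")
        if self.maximum <= self.minimum:
            raise ValueError("maximum must exceed minimum")

    def values(self) -> np.ndarray:
        if self.scale == "log":
            return np.geomspace(self.minimum, self.maximum, self.n_points)
        return np.linspace(self.minimum, self.maximum, self.n_points)


@dataclass
class SweepSpec:
    axis1: SweepAxis
    axis2: SweepAxis
    kpis: tuple[str, ...] = DEFAULT_KPIS
    scenario_pair: tuple[str, str] = ("BS-PCG", "CS")  # (bio, reference)


@dataclass
class SweepResult:
    spec: SweepSpec
    grids: dict[str, np.ndarray]  # kpi -> (n1, n2) RIR values
    failures: list[dict] = field(default_factory=list)


def _scaled_config(base: PlantConfig, scenario: str, **params) -> PlantConfig:
    """Apply sweep parameters and re-size load-coupled equipment.

    Bioreactor volumes scale with the inlet S load (gas flow x SO2) and
    the absorber holdup with the gas flow, which keeps residence times
    representative across the sweep and lets investment respond to plant
    size the way linear CAPEX scaling implies.
    """
    cfg = replace(base, scenario=scenario, **params)
    flow_ratio = cfg.gas_flow / base.gas_flow if base.gas_flow else 1.0
    load_ratio = flow_ratio * (cfg.so2_ppmv / base.so2_ppmv if base.so2_ppmv else 1.0)
    cfg = replace(
        cfg,
        absorber_volume=base.absorber_volume * flow_ratio,
        uasb=replace(base.uasb, volume=base.uasb.volume * max(load_ratio, 1e-6)),
        oxidizer=replace(base.oxidizer, volume=base.oxidizer.volume * max(load_ratio, 1e-6)),
    )
    return cfg


def _kpi_values(
    cfg: PlantConfig,
    table: CharacterizationTable,
    prices: PriceTable,
    kpis: tuple[str, ...],
    warm: dict | None,
) -> tuple[dict[str, float], dict]:
    result = simulate_plant(cfg, warm_state=copy.deepcopy(warm) if warm else None)
    inv = build_inventory(result)
    impacts = characterize(inv, table).impacts
    lcc: LccResult = assess_costs(
        inv, prices, ch4_fraction=result.biogas_ch4_fraction or 1.0
    )
    values = {}
    for k in kpis:
        if k == "operational_cost":
            values[k] = -lcc.operative_total  # positive burden
        elif k == "investment_cost":
            values[k] = -lcc.investment
        else:
            values[k] = float(impacts[k])
    return values, result.warm_state


def sweep_2d(
    spec: SweepSpec,
    base: PlantConfig,
    table: CharacterizationTable,
    prices: PriceTable | None = None,
) -> SweepResult:
    """Evaluate the RIR grids for every KPI of ``spec``.

    Per-cell failures are recorded (cell indices, parameter values,
    error message) and leave NaN cells; the sweep continues.
    """
    prices = prices or PriceTable()
    v1 = spec.axis1.values()
    v2 = spec.axis2.values()
    bio_tag, ref_tag = spec.scenario_pair
    grids = {k: np.full((len(v1), len(v2)), np.nan) for k in spec.kpis}
    failures: list[dict] = []

    # baseline solves seed every cell (order-independent warm starts)
    warm_bio = simulate_plant(_scaled_config(base, bio_tag)).warm_state
    warm_ref = simulate_plant(_scaled_config(base, ref_tag)).warm_state

    for a, x1 in enumerate(v1):
        for b, x2 in enumerate(v2):
            params = {spec.axis1.parameter: float(x1), spec.axis2.parameter: float(x2)}
            try:
                kv_bio, _ = _kpi_values(
                    _scaled_config(base, bio_tag, **params), table, prices, spec.kpis, warm_bio
                )
                kv_ref, _ = _kpi_values(
                    _scaled_config(base, ref_tag, **params), table, prices, spec.kpis, warm_ref
                )
                for k in spec.kpis:
                    grids[k][a, b] = rir(kv_bio[k], kv_ref[k])
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                failures.append(
                    {"cell": (a, b), "parameters": params, "error": f"{type(exc).__name__}: {exc}"}
                )
    return SweepResult(spec=spec, grids=grids, failures=failures)


def export_contours(result: SweepResult) -> pd.DataFrame:
    """Long-format contour table: (param1, param2, kpi, rir, class)."""
    spec = result.spec
    v1, v2 = spec.axis1.values(), spec.axis2.values()
    rows = []
    for k, grid in result.grids.items():
        for a, x1 in enumerate(v1):
            for b, x2 in enumerate(v2):
                value = grid[a, b]
                rows.append(
                    {
                        spec.axis1.parameter: float(x1),
                        spec.axis2.parameter: float(x2),
                        "kpi": k,
                        "rir": float(value),
                        "class": classify_rir(value) if np.isfinite(value) else "missing",
                    }
                )
    return pd.DataFrame.from_records(rows)


def run_breakeven(
    base: PlantConfig,
    table: CharacterizationTable,  # unused; kept for a uniform orchestration signature
    prices: PriceTable | None = None,
    glycerol_prices=None,
    gas_prices=None,
) -> dict:
    """Breakeven surface for the purified-glycerol bioscrubber against
    the chemical scrubber at baseline operation."""
    prices = prices or PriceTable()
    if glycerol_prices is None:
        glycerol_prices = np.linspace(0.0, 1000.0, 21)
    if gas_prices is None:
        gas_prices = np.linspace(0.0, 300.0, 21)
    res_bs = simulate_plant(replace(base, scenario="BS-PCG"))
    res_cs = simulate_plant(replace(base, scenario="CS"))
    lcc_bs = assess_costs(
        build_inventory(res_bs), prices, ch4_fraction=res_bs.biogas_ch4_fraction or 1.0
    )
    lcc_cs = assess_costs(build_inventory(res_cs), prices)
    return breakeven_grid(lcc_bs, lcc_cs, glycerol_prices, gas_prices)
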