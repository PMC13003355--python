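"""Life-cycle impact assessment layer.

Characterization multiplies the annualized inventory by a user-supplied
factor table (impact category x inventory line); normalization divides
by per-category person-equivalent (PE) factors.  Scenario pairs are
compared with the Relative Impact Ratio

    RIR = (IC_BS - IC_CS) / max(IC_BS, IC_CS)

classified on fixed +/-0.5 thresholds (green: the reference chemical
scrubber carries the higher impact; red: the bioscrubber does; yellow:
comparable).  Licensed characterization databases are *data* here, never
code: the package ships a synthetic fixture generator keyed to the
inventory line names (see :mod:`bioscrub.fixtures`), so absolute impact
values from the synthetic tables are placeholders, while all ratio,
classification, ranking and selection logic is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plant import LINE_COMPONENTS, InventoryTable

__all__ = [
    "RECIPE_MIDPOINT_CATEGORIES",
    "CharacterizationTable",
    "ImpactResult",
    "characterize",
    "rir",
    "classify_rir",
    "normalize_and_select",
]

# the 18 ReCiPe 2016 midpoint categories (Hierarchist perspective)
RECIPE_MIDPOINT_CATEGORIES: tuple[str, ...] = (
    "GWP",   # global warming potential
    "SOD",   # stratospheric ozone depletion
    "IR",    # ionizing radiation
    "OFH",   # ozone formation, human health
    "FPMF",  # fine particulate matter formation
    "OFT",   # ozone formation, terrestrial ecosystems
    "TA",    # terrestrial acidification
    "FE",    # freshwater eutrophication
    "ME",    # marine eutrophication
    "TET",   # terrestrial ecotoxicity
    "FET",   # freshwater ecotoxicity
    "MET",   # marine ecotoxicity
    "HCT",   # human carcinogenic toxicity
    "HNCT",  # human non-carcinogenic toxicity
    "LU",    # land use
    "MRS",   # mineral resource scarcity
    "FRS",   # fossil resource scarcity
    "WC",    # water consumption
)


@dataclass
class CharacterizationTable:
    """Factors as a DataFrame: rows = impact categories, columns =
    inventory lines; ``units`` maps category -> impact unit."""

    factors: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factors.index.duplicated().any() or self.factors.columns.duplicated().any():
            raise ValueError("duplicate categories or lines in factor table")

    @classmethod
    def read_csv(cls, path) -> "CharacterizationTable":
        df = pd.read_csv(path, index_col=0)
        units = {}
        if "unit" in df.columns:
            units = df["unit"].to_dict()
            df = df.drop(columns=["unit"])
        return cls(df.astype(float), units)

    def to_csv(self, path) -> None:
        out = self.factors.copy()
        if self.units:
            out.insert(0, "unit", [self.units.get(c, "") for c in out.index])
        out.to_csv(path)

    def uncharacterized_lines(self, inventory: InventoryTable) -> list[str]:
        return [l for l in inventory.lines if l not in self.factors.columns]


@dataclass
class ImpactResult:
    scenario: str
    impacts: pd.Series  # per category, characterized units
    units: dict[str, str]
    normalized: pd.Series | None = None  # person-equivalents
    contributions: pd.DataFrame | None = None  # category x component, signed shares


def characterize(
    inventory: InventoryTable,
    table: CharacterizationTable,
    *,
    strict: bool = False,
) -> ImpactResult:
    """impact_c = sum_lines factor_{c,line} * amount_line.

    Negative inventory lines (byproducts) yield avoided impacts.  Lines
    absent from the factor table count zero unless ``strict``.
    """
    missing = table.uncharacterized_lines(inventory)
    if strict and missing:
        raise ValueError(f"uncharacterized inventory lines: {missing}")
    lines = [l for l in inventory.lines if l in table.factors.columns]
    amounts = np.array([inventory.lines[l] for l in lines])
    impacts = table.factors[lines].to_numpy() @ amounts
    series = pd.Series(impacts, index=table.factors.index)

    comp_names = sorted(set(LINE_COMPONENTS.values()))
    comp = pd.DataFrame(0.0, index=table.factors.index, columns=comp_names)
    for line in lines:
        component = LINE_COMPONENTS.get(line)
        if component is None:
            continue
        comp[component] += table.factors[line].to_numpy() * inventory.lines[line]
    # signed shares normalized by the sum of absolute component values
    denom = comp.abs().sum(axis=1).replace(0.0, np.nan)
    shares = comp.div(denom, axis=0).fillna(0.0)
    return ImpactResult(
        scenario=inventory.scenario,
        impacts=series,
        units=dict(table.units),
        contributions=shares,
    )


def rir(ic_bs: float, ic_cs: float) -> float:
    """Relative Impact Ratio of a bioscrubber impact against the
    chemical-scrubber reference.

    Bounded in [-1, 1] for non-negative inputs; with net-avoided
    (negative) impacts the same formula is applied and the result may
    leave [-1, 1] -- callers should treat such values as flagged, not
    clamped.  Both-zero inputs define RIR = 0 (equal impact).
    """
    if ic_bs == 0.0 and ic_cs == 0.0:
        return 0.0
    denom = max(ic_bs, ic_cs)
    if denom == 0.0:
        raise ZeroDivisionError("max(ic_bs, ic_cs) is zero with unequal inputs")
    return (ic_bs - ic_cs) / denom


def classify_rir(value: float) -> str:
    """Heatmap class: 'green' (RIR < -0.5, chemical scrubber worse),
    'yellow' (comparable, boundary values included), 'red' (RIR > 0.5,
    bioscrubber worse)."""
    if math.isnan(value):
        raise ValueError("cannot classify NaN")
    if value < -0.5:
        return "green"
    if value > 0.5:
        return "red"
    return "yellow"


def normalize_and_select(
    impacts: ImpactResult | pd.Series,
    norm_factors: pd.Series | dict[str, float],
    *,
    coverage: float = 0.95,
    force_include: tuple[str, ...] = ("GWP",),
) -> tuple[pd.Series, list[str]]:
    """Person-equivalent normalization and top-category selection.

    PE_c = impact_c / factor_c.  Categories are ranked by |PE| and the
    smallest prefix whose cumulative |PE| reaches ``coverage`` of the
    total is selected; ``force_include`` categories are appended if not
    already selected.  Returns (PE series, selected category list).
    """
    series = impacts.impacts if isinstance(impacts, ImpactResult) else impacts
    nf = pd.Series(norm_factors)
    missing = [c for c in series.index if c not in nf.index]
    if missing:
        raise ValueError(f"missing normalization factors for: {missing}")
    if (nf[series.index] <= 0).any():
        bad = list(nf[series.index][nf[series.index] <= 0].index)
        raise ValueError(f"normalization factors must be > 0: {bad}")
    pe = series / nf[series.index]
    total = pe.abs().sum()
    if total == 0.0:
        return pe, []
    ranked = pe.abs().sort_values(ascending=False, kind="stable")
    cum = ranked.cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), coverage * total) + 1)
    selected = list(ranked.index[:n_keep])
    for cat in force_include:
        if cat in pe.index and cat not in selected:
            selected.append(cat)
    return pe, selected
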