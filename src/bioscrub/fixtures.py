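"""Deterministic fixture generation and scenario-file handling.

Characterization and normalization factors from licensed LCIA databases
cannot be redistributed, so every assessment in this repository runs on
*synthetic* factor tables generated here: positive, seeded, keyed to the
plant inventory line names and to the 18 midpoint categories.  They
exercise the full assessment machinery deterministically; their absolute
impact values are placeholders (ratio and classification logic is
data-independent).  Prices, by contrast, are public numbers and the
generated price table carries the real market values.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lcc import PriceTable
from .lcia import RECIPE_MIDPOINT_CATEGORIES, CharacterizationTable
from .plant import INVENTORY_UNITS, LINE_COMPONENTS, PlantConfig
from .uasb import SPECIES_PROPS, ReactionKinetics, StoichiometricModel, default_glycerol_sulfate_model

__all__ = [
    "FixtureSet",
    "generate_fixtures",
    "write_fixtures",
    "load_stoichiometric_model",
    "save_stoichiometric_model",
    "ScenarioFile",
    "load_scenario",
    "config_hash",
]

# lines that represent annualized exchanges (eligible for nonzero factors);
# equipment volumes/flows and the recovery percentage are descriptive.
EXCHANGE_LINES = tuple(k for k in INVENTORY_UNITS if k in LINE_COMPONENTS)


@dataclass
class FixtureSet:
    seed: int
    characterization: CharacterizationTable
    normalization: pd.Series  # per category, PE denominators
    prices: PriceTable
    stoichiometric_model: StoichiometricModel


def generate_fixtures(seed: int) -> FixtureSet:
    """Deterministic synthetic tables; same seed -> identical fixtures."""
    rng = np.random.default_rng(int(seed))
    factors = pd.DataFrame(
        0.0, index=list(RECIPE_MIDPOINT_CATEGORIES), columns=list(INVENTORY_UNITS)
    )
    for line in EXCHANGE_LINES:
        col = rng.lognormal(mean=-2.0, sigma=1.0, size=len(RECIPE_MIDPOINT_CATEGORIES))
        # sparsify: each line touches roughly half of the categories
        mask = rng.random(len(col)) < 0.5
        col = np.where(mask, col, 0.0)
        if not mask.any():
            col[rng.integers(len(col))] = float(rng.lognormal(-2.0, 1.0))
        factors.loc[:, line] = col
    units = {c: "pt per line unit" for c in RECIPE_MIDPOINT_CATEGORIES}
    units["GWP"] = "kg CO2-eq"
    norm = pd.Series(
        rng.lognormal(mean=6.0, sigma=0.5, size=len(RECIPE_MIDPOINT_CATEGORIES)),
        index=list(RECIPE_MIDPOINT_CATEGORIES),
        name="pe_factor",
    )
    return FixtureSet(
        seed=int(seed),
        characterization=CharacterizationTable(factors, units),
        normalization=norm,
        prices=PriceTable(),
        stoichiometric_model=default_glycerol_sulfate_model(),
    )


def save_stoichiometric_model(model: StoichiometricModel, matrix_path, kinetics_path) -> None:
    mat = pd.DataFrame(
        model.stoichiometry,
        index=[k.name for k in model.kinetics],
        columns=model.species_names,
    )
    mat.to_csv(matrix_path)
    rows = []
    for k in model.kinetics:
        rows.append(
            {
                "name": k.name,
                "trophic_group": k.trophic_group,
                "substrate": k.substrate,
                "mu_max": k.mu_max,
                "Ks": k.Ks,
                "yield": k.yield_,
                "Ki_sulfide": "" if k.Ki_sulfide is None else k.Ki_sulfide,
                "inhibition_form": k.inhibition_form,
                "substrate2": k.substrate2 or "",
                "Ks2": k.Ks2,
            }
        )
    pd.DataFrame(rows).to_csv(kinetics_path, index=False)


def load_stoichiometric_model(matrix_path, kinetics_path) -> StoichiometricModel:
    """Load (and validate) a reaction matrix + kinetic parameter pair."""
    mat = pd.read_csv(matrix_path, index_col=0)
    kin_df = pd.read_csv(kinetics_path).fillna("")
    kinetics = []
    for _, r in kin_df.iterrows():
        kinetics.append(
            ReactionKinetics(
                name=str(r["name"]),
                trophic_group=str(r["trophic_group"]),
                substrate=str(r["substrate"]),
                mu_max=float(r["mu_max"]),
                Ks=float(r["Ks"]),
                yield_=float(r["yield"]),
                Ki_sulfide=(None if r["Ki_sulfide"] == "" else float(r["Ki_sulfide"])),
                inhibition_form=str(r.get("inhibition_form", "noncompetitive")),
                substrate2=(None if r["substrate2"] == "" else str(r["substrate2"])),
                Ks2=float(r["Ks2"]) if r["Ks2"] != "" else 0.0,
            )
        )
    return StoichiometricModel(
        species_names=list(mat.columns),
        stoichiometry=mat.to_numpy(dtype=float),
        kinetics=kinetics,
        species_props={sp: SPECIES_PROPS.get(sp, (0.0, 0.0)) for sp in mat.columns},
    )


def write_fixtures(fixtures: FixtureSet, out_dir) -> dict[str, Path]:
    """Write all fixture files with a seed-stamped header where the
    format allows one; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "characterization": out / "characterization.csv",
        "normalization": out / "normalization.csv",
        "prices": out / "prices.yaml",
        "stoich_matrix": out / "stoichiometry_matrix.csv",
        "stoich_kinetics": out / "stoichiometry_kinetics.csv",
    }
    fixtures.characterization.to_csv(paths["characterization"])
    fixtures.normalization.rename_axis("category").to_csv(paths["normalization"])
    with open(paths["prices"], "w") as fh:
        yaml.safe_dump(
            {"seed": fixtures.seed, **asdict(fixtures.prices)}, fh, sort_keys=False
        )
    save_stoichiometric_model(
        fixtures.stoichiometric_model, paths["stoich_matrix"], paths["stoich_kinetics"]
    )
    return paths


@dataclass
class ScenarioFile:
    """Parsed scenario configuration; file references must resolve."""

    scenario: str
    config: PlantConfig
    seed: int = 0
    prices_path: str | None = None
    characterization_path: str | None = None
    normalization_path: str | None = None
    stoichiometry_paths: tuple[str, str] | None = None


_TABLE1_KEYS = (
    "gas_flow",
    "so2_ppmv",
    "co2_ppmv",
    "gl_ratio",
    "purge_percent",
    "distance_km",
    "operating_hours",
)


def load_scenario(path) -> ScenarioFile:
    """Load a YAML scenario file, validating fields and references."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scenario" not in raw:
        raise ValueError("scenario file: missing required field 'scenario'")
    scenario = raw["scenario"]
    if scenario not in ("CS", "BS-PG", "BS-PCG"):
        raise ValueError(f"scenario file: unknown scenario tag {scenario!r}")
    kwargs = {"scenario": scenario}
    table1 = raw.get("table1", {})
    unknown = set(table1) - set(_TABLE1_KEYS)
    if unknown:
        raise ValueError(f"scenario file: unknown table1 field(s) {sorted(unknown)}")
    kwargs.update(table1)
    try:
        cfg = PlantConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"scenario file: invalid configuration: {exc}") from exc
    refs = {}
    for key in ("prices", "characterization", "normalization"):
        p = raw.get(key)
        if p is not None:
            resolved = (path.parent / p).resolve()
            if not resolved.exists():
                raise ValueError(f"scenario file: referenced {key} file not found: {p}")
            refs[f"{key}_path"] = str(resolved)
    stoich = raw.get("stoichiometry")
    stoich_paths = None
    if stoich is not None:
        for sub in ("matrix", "kinetics"):
            if sub not in stoich:
                raise ValueError(f"scenario file: stoichiometry block needs '{sub}'")
            resolved = (path.parent / stoich[sub]).resolve()
            if not resolved.exists():
                raise ValueError(
                    f"scenario file: stoichiometry {sub} file not found: {stoich[sub]}"
                )
        stoich_paths = (
            str((path.parent / stoich["matrix"]).resolve()),
            str((path.parent / stoich["kinetics"]).resolve()),
        )
    return ScenarioFile(
        scenario=scenario,
        config=cfg,
        seed=int(raw.get("seed", 0)),
        stoichiometry_paths=stoich_paths,
        **refs,
    )


def config_hash(cfg: PlantConfig) -> str:
    """Stable short hash of a plant configuration, for logs and caches."""
    buf = io.StringIO()
    for key, value in sorted(asdict(cfg).items()):
        buf.write(f"{key}={value!r};")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]
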