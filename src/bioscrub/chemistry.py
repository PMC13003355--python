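"""Acid-base speciation and pH charge-balance solver.

All liquid-phase stages of the scrubbing train (spray absorber, UASB,
micro-aerobic oxidation tank) share the same inorganic acid-base
chemistry: dissolved SO2/sulfite, CO2/carbonate and H2S/sulfide partition
between protonation states as a function of pH, and only the neutral,
fully-protonated species exchanges with the gas phase.  The solver here
resolves the pH of a liquor from its *total* (analytical) concentrations
through an electroneutrality balance, which is also how the NaOH / HCl
dose needed to hold a pH set point is quantified.

Conventions
-----------
* Concentrations are mol L-1 and are identified with activities
  (no ionic-strength correction).
* Equilibrium constants are 25 degC, zero ionic strength values;
  temperature is not a state variable of the plant model.
* ``Kw = 1e-14``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcidSystem",
    "IonicTotals",
    "SpeciationResult",
    "CARBONATE",
    "SULFIDE",
    "SULFUROUS",
    "DEFAULT_SYSTEMS",
    "species_fractions",
    "solve_ph",
    "dose_to_setpoint",
    "load_acid_systems",
]

PKW = 14.0


@dataclass(frozen=True)
class AcidSystem:
    """A polyprotic acid described by its successive pKa values.

    ``charge_fully_protonated`` is the electric charge of the most
    protonated member (0 for H2CO3*, H2S, H2SO3); each deprotonation
    step lowers the charge by one.
    """

    name: str
    pka_values: tuple[float, ...]
    charge_fully_protonated: int = 0

    def __post_init__(self) -> None:
        if len(self.pka_values) == 0:
            raise ValueError(f"{self.name}: pKa list must be non-empty")
        if any(b <= a for a, b in zip(self.pka_values, self.pka_values[1:])):
            raise ValueError(f"{self.name}: pKa values must be strictly increasing")

    @property
    def n_species(self) -> int:
        return len(self.pka_values) + 1

    def species_names(self) -> list[str]:
        return [f"{self.name}[-{k}]" if k else f"{self.name}[0]" for k in range(self.n_species)]

    def charges(self) -> np.ndarray:
        return self.charge_fully_protonated - np.arange(self.n_species)


# Standard tabulated constants, 25 degC, zero ionic strength.  The second
# sulfide ionization (pKa2 ~ 13-17, disputed) is negligible at process pH
# and is omitted.  Sulfate is handled as a fully dissociated strong anion.
CARBONATE = AcidSystem("carbonate", (6.35, 10.33))
SULFIDE = AcidSystem("sulfide", (7.05,))
SULFUROUS = AcidSystem("sulfurous", (1.85, 7.2))

DEFAULT_SYSTEMS: dict[str, AcidSystem] = {
    s.name: s for s in (CARBONATE, SULFIDE, SULFUROUS)
}


@dataclass
class IonicTotals:
    """Total analytical composition of a liquor.

    ``strong_cations`` / ``strong_anions`` are mol *charge* per litre of
    fully dissociated ions (Na+ from NaOH, Cl- from HCl, the 2- charge of
    sulfate, ...).
    """

    totals_per_system: dict[AcidSystem, float] = field(default_factory=dict)
    strong_cations: float = 0.0
    strong_anions: float = 0.0

    def __post_init__(self) -> None:
        if self.strong_cations < 0 or self.strong_anions < 0:
            raise ValueError("strong-ion concentrations must be >= 0")
        for sys_, tot in self.totals_per_system.items():
            if tot < 0:
                raise ValueError(f"total for {sys_.name} must be >= 0")

    def copy(self) -> "IonicTotals":
        return IonicTotals(dict(self.totals_per_system), self.strong_cations, self.strong_anions)


@dataclass
class SpeciationResult:
    pH: float
    species_concentrations: dict[str, float]
    charge_residual: float


def species_fractions(system: AcidSystem, pH: float) -> np.ndarray:
    """Fractions of each protonation state at a given pH.

    Returned array is ordered from fully protonated (index 0) to fully
    deprotonated; entries are in [0, 1] and sum to 1.  The closed form is
    the Boltzmann-like partition over cumulative dissociation:
    ``w_k = 10 ** sum_{j<=k} (pH - pKa_j)``, ``alpha_k = w_k / sum w``.
    """
    if not np.isfinite(pH):
        raise ValueError("pH must be finite")
    pka = np.asarray(system.pka_values, dtype=float)
    # log-space partition; subtract max for overflow safety
    logw = np.concatenate(([0.0], np.cumsum(pH - pka)))
    logw -= logw.max()
    w = 10.0 ** logw
    return w / w.sum()


def _charge_residual(pH: float, totals: IonicTotals) -> float:
    """Electroneutrality residual (mol charge / L), positive = excess cations."""
    h = 10.0 ** (-pH)
    oh = 10.0 ** (pH - PKW)
    res = totals.strong_cations - totals.strong_anions + h - oh
    for system, total in totals.totals_per_system.items():
        if total == 0.0:
            continue
        alpha = species_fractions(system, pH)
        res += total * float(alpha @ system.charges())
    return res


def solve_ph(
    totals: IonicTotals,
    *,
    residual_tol: float = 1e-10,
    ph_bounds: tuple[float, float] = (0.0, 14.0),
) -> SpeciationResult:
    """Solve electroneutrality for pH and return the full species split.

    The charge residual is strictly decreasing in pH for acids whose
    charge only drops with deprotonation, so the bracketed Brent solve on
    [0, 14] finds the unique root.
    """
    lo, hi = ph_bounds
    f_lo, f_hi = _charge_residual(lo, totals), _charge_residual(hi, totals)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            "charge balance has no root in pH "
            f"[{lo}, {hi}] (residuals {f_lo:.3g}, {f_hi:.3g}); degenerate input"
        )
    pH = brentq(_charge_residual, lo, hi, args=(totals,), xtol=1e-13, rtol=8.9e-16)
    residual = _charge_residual(pH, totals)
    if abs(residual) > residual_tol:
        raise ArithmeticError(f"charge residual {residual:.3e} above tolerance")
    species: dict[str, float] = {"H+": 10.0 ** (-pH), "OH-": 10.0 ** (pH - PKW)}
    for system, total in totals.totals_per_system.items():
        alpha = species_fractions(system, pH)
        for name, a in zip(system.species_names(), alpha):
            species[name] = total * float(a)
    return SpeciationResult(pH=pH, species_concentrations=species, charge_residual=residual)


def dose_to_setpoint(totals: IonicTotals, target_pH: float) -> float:
    """Strong-ion dose (mol charge / L) that brings the liquor to ``target_pH``.

    Positive values are base (add to ``strong_cations``, e.g. NaOH),
    negative values acid (add ``-dose`` to ``strong_anions``, e.g. HCl).
    The dose is exact: it is the negated charge residual evaluated at the
    target pH, so re-solving after dosing returns the target.
    """
    if not (0.0 < target_pH < 14.0):
        raise ValueError("target pH must be in (0, 14)")
    return -_charge_residual(target_pH, totals)


def apply_dose(totals: IonicTotals, dose: float) -> IonicTotals:
    """Return a copy of ``totals`` with a signed strong-ion dose applied."""
    out = totals.copy()
    if dose >= 0:
        out.strong_cations += dose
    else:
        out.strong_anions += -dose
    return out


def load_acid_systems(rows) -> dict[str, AcidSystem]:
    """Build acid systems from config rows.

    Each row is a mapping with keys ``name``, ``pka`` (list of floats) and
    optional ``charge_fully_protonated`` (default 0).  Accepts the parsed
    content of a YAML list or a CSV read as records.
    """
    systems = {}
    for row in rows:
        pka = row["pka"]
        if isinstance(pka, str):  # CSV cell like "6.35;10.33"
            pka = [float(x) for x in pka.split(";")]
        systems[row["name"]] = AcidSystem(
            name=row["name"],
            pka_values=tuple(float(x) for x in pka),
            charge_fully_protonated=int(row.get("charge_fully_protonated", 0)),
        )
    return systems
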