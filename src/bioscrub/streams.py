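"""Process streams exchanged between plant stages.

Gas composition is carried as ppmv of trace species on top of an inert
carrier (combustion gas); liquid streams carry either an
:class:`~bioscrub.chemistry.IonicTotals` (absorber liquor) or a mapping
of named solutes in g L-1 (biological stages), or both.

ppmv to molar conversions use the ideal-gas molar volume at 25 degC,
1 atm (24.45 L mol-1) throughout, applied consistently on the inlet and
outlet sides so that changes in total moles from absorption/stripping
are reflected in outlet ppmv.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import IonicTotals

MOLAR_VOLUME_L = 24.45  # L mol-1 at 25 degC, 1 atm
MOLAR_VOLUME_M3 = MOLAR_VOLUME_L / 1000.0  # m3 mol-1


@dataclass
class GasStream:
    """A gas stream: bulk volumetric flow plus trace-species composition."""

    volumetric_flow: float  # m3 h-1
    composition: dict[str, float] = field(default_factory=dict)  # species -> ppmv
    temperature: float = 25.0  # degC
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if self.volumetric_flow < 0:
            raise ValueError("gas flow must be >= 0")
        for sp, ppm in self.composition.items():
            if ppm < 0:
                raise ValueError(f"{sp}: ppmv must be >= 0")
        if sum(self.composition.values()) > 1e6 * (1.0 + 1e-9):
            raise ValueError("trace species exceed the whole gas")

    @property
    def total_molar_flow(self) -> float:
        """mol h-1 of the whole stream (25 degC, 1 atm basis)."""
        return self.volumetric_flow / MOLAR_VOLUME_M3

    def molar_flow(self, species: str) -> float:
        """mol h-1 of one trace species."""
        return self.total_molar_flow * self.composition.get(species, 0.0) * 1e-6

    def partial_pressure(self, species: str) -> float:
        """atm."""
        return self.pressure * self.composition.get(species, 0.0) * 1e-6

    @classmethod
    def from_molar_flows(
        cls,
        species_mol_h: dict[str, float],
        inert_mol_h: float,
        *,
        temperature: float = 25.0,
        pressure: float = 1.0,
    ) -> "GasStream":
        """Rebuild a stream from per-species molar flows plus inert carrier.

        Total-mole rebalancing happens here: outlet ppmv are relative to
        the *new* total flow, not the inlet one.
        """
        total = inert_mol_h + sum(species_mol_h.values())
        comp = {sp: 1e6 * n / total for sp, n in species_mol_h.items()}
        return cls(
            volumetric_flow=total * MOLAR_VOLUME_M3,
            composition=comp,
            temperature=temperature,
            pressure=pressure,
        )

    def inert_molar_flow(self) -> float:
        return self.total_molar_flow - sum(
            self.molar_flow(sp) for sp in self.composition
        )


@dataclass
class LiquidStream:
    """A liquid stream; ionic totals for the absorber, g/L solutes downstream."""

    volumetric_flow: float  # m3 h-1
    totals: IonicTotals | None = None
    solutes: dict[str, float] = field(default_factory=dict)  # species -> g L-1
    temperature: float = 25.0  # degC

    def __post_init__(self) -> None:
        if self.volumetric_flow < 0:
            raise ValueError("liquid flow must be >= 0")

    def mass_flow(self, species: str) -> float:
        """g h-1 of a named solute (volumetric flow in m3 h-1 x g L-1 x 1000)."""
        return self.volumetric_flow * 1000.0 * self.solutes.get(species, 0.0)
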