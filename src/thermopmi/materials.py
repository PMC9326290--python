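"""Thermal material properties for body, clothing and environment.

Default values are rounded literature figures for soft biological tissue,
subcutaneous fat, still air, a wooden support surface and bulk cotton
fabric (see the methods note for provenance).  All values are configurable
per case; the defaults exist so that a phantom study runs out of the box.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidMaterialError


@dataclass(frozen=True)
class MaterialProperties:
    """Homogeneous thermal properties of one material.

    Parameters
    ----------
    thermal_conductivity : float
        k, in W m^-1 K^-1.
    density : float
        rho, in kg m^-3.
    specific_heat_capacity : float
        c, in J kg^-1 K^-1.
    """

    thermal_conductivity: float
    density: float
    specific_heat_capacity: float

    def __post_init__(self) -> None:
        for name in ("thermal_conductivity", "density", "specific_heat_capacity"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidMaterialError(f"{name} must be strictly positive, got {value!r}")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c in J m^-3 K^-1."""
        return self.density * self.specific_heat_capacity


#: Default thermal properties.  Tissue and adipose values are averaged
#: soft-tissue / subcutaneous-fat literature figures; substrate
#: approximates a wooden table; clothing is bulk cotton fabric including
#: trapped air.  The air entry is an *effective* conductivity: the model
#: transports heat through air by conduction only, so the molecular value
#: (0.026 W/m/K) would under-predict surface cooling by roughly an order
#: of magnitude; 0.25 W/m/K makes the resolved air boundary layer deliver
#: a surface exchange of ~4-5 W/m^2/K, the textbook free-convection plus
#: radiation range for a body indoors.  Override with
#: ``MaterialTable({"air": MaterialProperties(0.026, 1.2, 1005.0)})`` to
#: model truly still, non-radiating air.
DEFAULT_MATERIALS: dict[str, MaterialProperties] = {
    "tissue": MaterialProperties(0.5, 1050.0, 3600.0),
    "adipose": MaterialProperties(0.21, 920.0, 2350.0),
    "air": MaterialProperties(0.25, 1.2, 1005.0),
    "substrate": MaterialProperties(0.2, 700.0, 1700.0),
    "clothing": MaterialProperties(0.06, 250.0, 1300.0),
}


class MaterialTable:
    """Mapping from material label to :class:`MaterialProperties`.

    Must contain at least ``tissue`` and ``air``.  Unspecified labels fall
    back to the package defaults.
    """

    def __init__(self, overrides: dict[str, MaterialProperties] | None = None):
        table = dict(DEFAULT_MATERIALS)
        if overrides:
            table.update(overrides)
        for required in ("tissue", "air"):
            if required not in table:
                raise InvalidMaterialError(f"material table must define {required!r}")
        self._table = table

    def __getitem__(self, label: str) -> MaterialProperties:
        try:
            return self._table[label]
        except KeyError:
            raise InvalidMaterialError(f"no thermal properties for material {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._table

    def labels(self) -> list[str]:
        return sorted(self._table)

    @classmethod
    def from_dict(cls, raw: dict) -> "MaterialTable":
        """Build a table from a plain config mapping.

        Each entry is ``label: {thermal_conductivity, density,
        specific_heat_capacity}`` (in SI units).
        """
        overrides = {
            label: MaterialProperties(
                float(props["thermal_conductivity"]),
                float(props["density"]),
                float(props["specific_heat_capacity"]),
            )
            for label, props in raw.items()
        }
        return cls(overrides)

    def to_dict(self) -> dict:
        return {
            label: {
                "thermal_conductivity": p.thermal_conductivity,
                "density": p.density,
                "specific_heat_capacity": p.specific_heat_capacity,
            }
            for label, p in sorted(self._table.items())
        }
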