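"""Chamber wall/window geometry and water-equivalent thickness (WET).

An ionization chamber's entrance window or wall is a stack of thin material
layers (PMMA, graphite, lacquer).  For depth-ionization measurements the
physical stack is converted to the thickness of water producing the same
energy loss for the carbon-ion beam.  The conversion used here is a
per-material scaling:

* PMMA:      ``t_wet = t * 1.16``  (path-length factor for PMMA to water)
* graphite:  ``t_wet = t * rho * (1.16 / 1.19)``  (the PMMA factor rescaled
  by the graphite/PMMA density ratio)
* lacquer / water: ``t_wet = t`` (taken as water-equivalent as-is)

The scale factors live in :data:`WET_FACTORS` so another protocol can
override them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "MaterialLayer",
    "ChamberSpec",
    "WET_FACTORS",
    "DEFAULT_DENSITIES",
    "layer_wet",
    "stack_wet",
    "builtin_chambers",
    "load_chamber",
    "load_chambers_file",
]

#: Reference densities, g/cm^3.
DEFAULT_DENSITIES: Mapping[str, float] = {
    "pmma": 1.19,
    "graphite": 1.85,
    "lacquer": 1.0,
    "water": 1.0,
}

#: Per-material WET scaling rules.  ``factor`` multiplies the physical
#: thickness; if ``density_scaled`` the layer density divided by the PMMA
#: reference density enters as an extra factor (graphite rule).
WET_FACTORS: Mapping[str, Mapping[str, float | bool]] = {
    "pmma": {"factor": 1.16, "density_scaled": False},
    "graphite": {"factor": 1.16 / 1.19, "density_scaled": True},
    "lacquer": {"factor": 1.0, "density_scaled": False},
    "water": {"factor": 1.0, "density_scaled": False},
}


class UnknownMaterialError(ValueError):
    """Raised for a material label with no WET scaling rule."""


@dataclass(frozen=True)
class MaterialLayer:
    """One homogeneous layer of a chamber wall or window.

    Parameters
    ----------
    material:
        Label with a WET rule: ``pmma``, ``graphite``, ``lacquer``, ``water``.
    thickness_mm:
        Physical thickness, mm (>= 0).
    density_g_cm3:
        Mass density, g/cm^3; defaults to the reference density of the
        material.
    """

    material: str
    thickness_mm: float
    density_g_cm3: float | None = None

    def __post_init__(self) -> None:
        mat = self.material.lower()
        object.__setattr__(self, "material", mat)
        if self.thickness_mm < 0:
            raise ValueError(f"layer thickness must be >= 0, got {self.thickness_mm}")
        if self.density_g_cm3 is None:
            object.__setattr__(
                self, "density_g_cm3", DEFAULT_DENSITIES.get(mat, 1.0)
            )
        if self.density_g_cm3 <= 0:
            raise ValueError(f"layer density must be > 0, got {self.density_g_cm3}")


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and point-of-measurement convention of an ionization chamber.

    ``pom_offset_mm`` is the distance from the chamber's physical reference
    point (entrance window or thimble tip) to its nominal point of
    measurement, e.g. 13 mm behind the tip for a Farmer thimble.
    """

    name: str
    kind: str  # "plane_parallel" | "cylindrical"
    window_layers: tuple[MaterialLayer, ...]
    inner_radius_mm: float | None = None
    active_volume_cm3: float | None = None
    pom_convention: str = ""
    pom_offset_mm: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("plane_parallel", "cylindrical"):
            raise ValueError(f"unknown chamber kind {self.kind!r}")
        if self.kind == "cylindrical":
            if self.inner_radius_mm is None or self.inner_radius_mm <= 0:
                raise ValueError(
                    "cylindrical chamber requires inner_radius_mm > 0"
                )
        if not self.window_layers:
            raise ValueError("window_layers must be non-empty")

    @property
    def wall_wet_mm(self) -> float:
        """Total water-equivalent thickness of the window/wall stack."""
        return stack_wet(self.window_layers)


def layer_wet(
    layer: MaterialLayer,
    factors: Mapping[str, Mapping[str, float | bool]] = WET_FACTORS,
) -> float:
    """Water-equivalent thickness of one layer, mm."""
    try:
        rule = factors[layer.material]
    except KeyError:
        raise UnknownMaterialError(
            f"no WET rule for material {layer.material!r}; "
            f"known: {sorted(factors)}"
        ) from None
    wet = layer.thickness_mm * float(rule["factor"])
    if rule.get("density_scaled", False):
        wet *= layer.density_g_cm3
    return wet


def stack_wet(
    layers,
    factors: Mapping[str, Mapping[str, float | bool]] = WET_FACTORS,
) -> float:
    """Total WET of a layer stack, mm.  Additive and order-independent."""
    return float(sum(layer_wet(layer, factors) for layer in layers))


def _chamber_from_record(name: str, rec: dict) -> ChamberSpec:
    layers = tuple(
        MaterialLayer(
            material=lr["material"],
            thickness_mm=float(lr["thickness_mm"]),
            density_g_cm3=lr.get("density_g_cm3"),
        )
        for lr in rec["window_layers"]
    )
    return ChamberSpec(
        name=name,
        kind=rec["kind"],
        window_layers=layers,
        inner_radius_mm=rec.get("inner_radius_mm"),
        active_volume_cm3=rec.get("active_volume_cm3"),
        pom_convention=rec.get("pom_convention", ""),
        pom_offset_mm=float(rec.get("pom_offset_mm", 0.0)),
        extra={
            k: v
            for k, v in rec.items()
            if k
            not in {
                "kind",
                "window_layers",
                "inner_radius_mm",
                "active_volume_cm3",
                "pom_convention",
                "pom_offset_mm",
            }
        },
    )


def load_chambers_file(path) -> dict[str, ChamberSpec]:
    """Load chamber records from a YAML config file (one record per name)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {name: _chamber_from_record(name, rec) for name, rec in raw.items()}


def builtin_chambers() -> dict[str, ChamberSpec]:
    """The bundled chamber records (PTW 34080, 34070, 30013)."""
    ref = resources.files("peffkit.data").joinpath("chambers.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {name: _chamber_from_record(name, rec) for name, rec in raw.items()}


def load_chamber(name: str) -> ChamberSpec:
    """Look up one bundled chamber by name."""
    chambers = builtin_chambers()
    try:
        return chambers[name]
    except KeyError:
        raise KeyError(
            f"unknown chamber {name!r}; bundled: {sorted(chambers)}"
        ) from None
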