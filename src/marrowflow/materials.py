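"""Material parameters for the six study groups.

Trabecular tissue is modelled as a uniform isotropic linear elastic solid and
marrow as a Newtonian fluid.  The six groups are a healthy control (CON), a
type-2-diabetes model (T2DM) and four verapamil dose arms (VER4..VER48,
mg/kg/day); each has its own apparent tissue modulus from nanoindentation,
while Poisson's ratio and the marrow properties are shared.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MaterialSpec", "GROUP_MODULI_GPA", "GROUP_BVTV", "material_for_group"]

#: tissue elastic modulus per group (GPa)
GROUP_MODULI_GPA = {
    "CON": 15.08,
    "T2DM": 11.28,
    "VER4": 12.00,
    "VER12": 12.60,
    "VER24": 13.63,
    "VER48": 14.43,
}

#: bone volume fraction of each group's typical sample
GROUP_BVTV = {
    "CON": 0.768,
    "T2DM": 0.237,
    "VER4": 0.1296,
    "VER12": 0.2885,
    "VER24": 0.3216,
    "VER48": 0.4906,
}


@dataclass
class MaterialSpec:
    """Solid and fluid material constants.

    E : Young's modulus (GPa); nu : Poisson's ratio; rho_fluid : marrow
    density (g/cm^3); mu_fluid : marrow dynamic viscosity (Pa s).
    """

    E: float = 15.08
    nu: float = 0.3
    rho_fluid: float = 0.95
    mu_fluid: float = 85.5
    group_label: str = "CON"

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.mu_fluid <= 0 or self.rho_fluid <= 0:
            raise ValueError("fluid density and viscosity must be positive")

    @property
    def E_pa(self) -> float:
        return self.E * 1e9


def material_for_group(group: str) -> MaterialSpec:
    """Material constants for one of the six named groups."""
    try:
        E = GROUP_MODULI_GPA[group]
    except KeyError:
        raise KeyError(
            f"unknown group {group!r}; known: {sorted(GROUP_MODULI_GPA)}"
        ) from None
    return MaterialSpec(E=E, group_label=group)
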