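"""Fluid property container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass

#: Unit conversion constant, Pa per mmHg.
PA_PER_MMHG = 133.322


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian fluid.

    Defaults correspond to blood treated as a homogeneous Newtonian
    fluid: density 1060 kg/m^3, dynamic viscosity 3.71e-3 Pa.s.
    """

    density: float = 1060.0  # kg/m^3
    viscosity: float = 3.71e-3  # Pa.s (dynamic)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, in m^2/s."""
        return self.viscosity / self.density


BLOOD = FluidProperties()
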