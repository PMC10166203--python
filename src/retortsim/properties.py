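"""Temperature-dependent thermophysical properties of the canned product.

The puree is modelled as a temperature-dependent Newtonian fluid: density,
dynamic viscosity and thermal conductivity are polynomials in absolute
temperature (kelvin), the specific heat is constant.  The built-in default
property set (``chestnut_puree``) describes a commercial chestnut puree whose
properties were measured between 30 and 95 degC and extrapolated above; the
polynomials remain physically plausible (positive, smooth) well past the
retort temperatures of interest (~121 degC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ThermoPhysicalProperties",
    "PropertyValues",
    "chestnut_puree",
    "constant_properties",
    "eval_properties",
]


class PropertyRangeError(ValueError):
    """A property evaluated to a non-physical (non-positive) value."""


@dataclass(frozen=True)
class ThermoPhysicalProperties:
    """Polynomial property correlations over absolute temperature.

    Coefficient arrays are highest-order-first (``numpy.polyval`` convention).
    ``valid_range`` is the temperature window the correlations were fitted
    for; ``extrapolation_policy`` controls behaviour outside it:

    - ``"extrapolate"``: evaluate the polynomial anyway (warn once),
    - ``"clamp"``: evaluate at the nearest range endpoint,
    - ``"error"``: raise.
    """

    name: str
    density_coeffs: tuple[float, ...]
    viscosity_coeffs: tuple[float, ...]
    conductivity_coeffs: tuple[float, ...]
    specific_heat: float  # J/(kg K)
    valid_range: tuple[float, float] = (303.15, 400.15)  # K
    extrapolation_policy: str = "extrapolate"
    _warned: list = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self):
        if self.extrapolation_policy not in ("clamp", "extrapolate", "error"):
            raise ValueError(
                f"unknown extrapolation_policy {self.extrapolation_policy!r}"
            )
        if self.specific_heat <= 0:
            raise ValueError("specific_heat must be positive")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be (low, high) with low < high")

    def _police(self, T):
        """Apply the extrapolation policy; returns the temperature to use."""
        T = np.asarray(T, dtype=float)
        if not np.all(np.isfinite(T)) or np.any(T <= 0):
            raise ValueError("temperature must be finite and positive (kelvin)")
        lo, hi = self.valid_range
        outside = (T < lo) | (T > hi)
        if not np.any(outside):
            return T
        if self.extrapolation_policy == "error":
            bad = float(np.atleast_1d(T)[np.atleast_1d(outside)][0])
            raise PropertyRangeError(
                f"T = {bad:.2f} K outside valid range [{lo}, {hi}] K "
                f"for property set {self.name!r}"
            )
        if self.extrapolation_policy == "clamp":
            return np.clip(T, lo, hi)
        if not self._warned:
            logger.warning(
                "extrapolating %s correlations outside [%g, %g] K",
                self.name, lo, hi,
            )
            self._warned.append(True)
        return T

    def density(self, T):
        """Density rho(T), kg/m^3."""
        return self._eval(self.density_coeffs, T, "density")

    def viscosity(self, T):
        """Dynamic viscosity mu(T), Pa s."""
        return self._eval(self.viscosity_coeffs, T, "viscosity")

    def conductivity(self, T):
        """Thermal conductivity k(T), W/(m K)."""
        return self._eval(self.conductivity_coeffs, T, "conductivity")

    def _eval(self, coeffs, T, what):
        Tu = self._police(T)
        val = np.polyval(coeffs, Tu)
        if np.any(val <= 0):
            bad = np.atleast_1d(Tu)[np.atleast_1d(val <= 0)][0]
            raise PropertyRangeError(
                f"{what} non-positive at T = {float(bad):.2f} K "
                f"(property set {self.name!r})"
            )
        return val if np.ndim(T) else float(val)


@dataclass(frozen=True)
class PropertyValues:
    """Property bundle at a single temperature."""

    density: float          # kg/m^3
    viscosity: float        # Pa s
    conductivity: float     # W/(m K)
    specific_heat: float    # J/(kg K)
    thermal_diffusivity: float  # m^2/s, k/(rho Cp)


def eval_properties(props: ThermoPhysicalProperties, T: float) -> PropertyValues:
    """Evaluate all properties at temperature ``T`` (kelvin)."""
    rho = props.density(T)
    mu = props.viscosity(T)
    k = props.conductivity(T)
    cp = props.specific_heat
    return PropertyValues(
        density=rho,
        viscosity=mu,
        conductivity=k,
        specific_heat=cp,
        thermal_diffusivity=k / (rho * cp),
    )


def chestnut_puree() -> ThermoPhysicalProperties:
    """The default chestnut-puree property set.

    Measured 30-95 degC, extrapolated above.  Viscosity is a quintic with a
    shallow minimum near 391.6 K; density and conductivity are quadratics.
    """
    return ThermoPhysicalProperties(
        name="chestnut_puree",
        density_coeffs=(-0.0000000035, -0.4472664761, 1225.5567102981),
        viscosity_coeffs=(
            -0.00000001387024283936,
            0.0000259069861904587,
            -0.019355480214816,
            7.23213374403098,
            -1351.86899336611,
            101200.919774749,
        ),
        conductivity_coeffs=(0.000004531, -0.00272, 0.982),
        specific_heat=3860.0,
        valid_range=(303.15, 400.15),
        extrapolation_policy="extrapolate",
    )


def constant_properties(
    density: float = 1070.0,
    viscosity: float = 35.0,
    conductivity: float = 0.58,
    specific_heat: float = 3860.0,
    name: str = "constant",
) -> ThermoPhysicalProperties:
    """A constant-coefficient property set (analytic oracles, conservation tests)."""
    return ThermoPhysicalProperties(
        name=name,
        density_coeffs=(density,),
        viscosity_coeffs=(viscosity,),
        conductivity_coeffs=(conductivity,),
        specific_heat=specific_heat,
        valid_range=(1.0, 1e4),
        extrapolation_policy="extrapolate",
    )


def from_dict(block: dict) -> ThermoPhysicalProperties:
    """Build a property set from a config mapping.

    Coefficients in config files are listed lowest-order-first and are
    reversed here to the internal highest-first convention.  Unit annotations
    (``units`` keys) are required and checked literally.
    """
    expected_units = {
        "density": "kg/m^3",
        "viscosity": "Pa.s",
        "conductivity": "W/(m.K)",
        "specific_heat": "J/(kg.K)",
    }
    for key, unit in expected_units.items():
        entry = block.get(key)
        if entry is None:
            raise KeyError(f"property config missing {key!r}")
        if entry.get("units") != unit:
            raise ValueError(
                f"{key}: expected units {unit!r}, got {entry.get('units')!r}"
            )
    rev = lambda c: tuple(reversed([float(x) for x in c]))
    return ThermoPhysicalProperties(
        name=block.get("name", "custom"),
        density_coeffs=rev(block["density"]["coeffs"]),
        viscosity_coeffs=rev(block["viscosity"]["coeffs"]),
        conductivity_coeffs=rev(block["conductivity"]["coeffs"]),
        specific_heat=float(block["specific_heat"]["value"]),
        valid_range=tuple(block.get("valid_range", (303.15, 400.15))),
        extrapolation_policy=block.get("extrapolation_policy", "extrapolate"),
    )
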