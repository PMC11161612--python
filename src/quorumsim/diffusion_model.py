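"""Steady-state autoinducer concentration fields for diffusing point sources.

A bacterial cell secreting autoinducer molecules at a constant rate P into a
medium with diffusion coefficient D is modelled as a Gaussian source of width
Ws (the cell width) in Fick's second law.  The steady state around a single
cell is

    N(r) = P / (2 pi D r) * phi(r / (sqrt(2) Ws)),

with phi the error function, which approaches the bare point-source field
P/(2 pi D r) a few cell widths away from the cell.

For a spherical colony of radius R with uniform cell density n, summing the
per-cell fields over the sphere gives the concentration at the colony centre
as a radial integral (evaluated here by adaptive quadrature, the independent
cross-check) and, in closed form,

    N_total = (P n R^2 / 2 D) * [ 1 - (Ws^2/R^2) phi(R / (sqrt(2) Ws))
                                  + sqrt((2 Ws / (pi R)) exp(-(R/2Ws)^2)) ].

The bracket tends to 1 for Ws << R, so N_total ~ P n R^2 / (2 D): total
signal grows with the square of colony size and inversely with diffusivity —
the core quantity behind every feasibility decision in this package.

Internally everything is CGS (cm, s, molecules); constructors accept the
lab-customary units (mm, µm, cells/mL) and convert once at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, special

from .units import (
    mm_to_cm,
    um_to_cm,
    molecules_per_cm3_to_nM,
    nM_to_molecules_per_cm3,
)

__all__ = [
    "ColonyParameters",
    "ConcentrationValue",
    "erf_profile",
    "single_cell_concentration",
    "single_cell_origin_limit",
    "colony_concentration_closed_form",
    "colony_concentration_quadrature",
    "to_nanomolar",
    "from_nanomolar",
    "ORIGIN_PREFACTOR_SERIES",
    "ORIGIN_PREFACTOR_TAYLOR",
]

# Prefactor of the r -> 0 limit of the single-cell field obtained by the
# small-x expansion phi(x) ~ 2x/sqrt(pi): N(0) = pref * P / (D * Ws).
ORIGIN_PREFACTOR_SERIES = 1.0 / (math.sqrt(2.0) * math.pi ** 1.5)
# Alternative Taylor-approximation prefactor 1/(2 pi)^(3/2), exactly half the
# series value; exposed for comparison, not used by the field (the series
# value keeps the profile continuous in r).
ORIGIN_PREFACTOR_TAYLOR = 1.0 / (2.0 * math.pi) ** 1.5

# Below this fraction of a cell width the closed-form ratio P/(2 pi D r) *
# phi(...) is numerically indeterminate; switch to the analytic limit.
_SMALL_RADIUS_SWITCH = 1.0e-6


@dataclass(frozen=True)
class ColonyParameters:
    """Physical inputs of the colony concentration formula, in CGS units.

    Attributes
    ----------
    production_rate : float
        Autoinducer secretion rate P, molecules per cell per second.
    cell_density : float
        Cell number density n in cells/cm^3 (numerically equal to cells/mL).
    colony_radius : float
        Radius R of the sphere enclosing all cells, in cm.
    diffusion_coefficient : float
        Medium diffusion coefficient D, cm^2/s.
    cell_width : float
        Gaussian source width Ws (bacterial cell width), in cm.

    Use :meth:`from_lab_units` to construct from mm / µm / cells-per-mL.
    """

    production_rate: float
    cell_density: float
    colony_radius: float
    diffusion_coefficient: float
    cell_width: float

    def __post_init__(self) -> None:
        for name in (
            "production_rate",
            "cell_density",
            "colony_radius",
            "diffusion_coefficient",
            "cell_width",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.colony_radius < self.cell_width:
            raise ValueError(
                "colony_radius must be >= cell_width "
                f"({self.colony_radius} < {self.cell_width} cm)"
            )

    @classmethod
    def from_lab_units(
        cls,
        production_rate: float,
        cell_density_per_ml: float,
        colony_radius_mm: float,
        diffusion_coefficient: float,
        cell_width_um: float,
    ) -> "ColonyParameters":
        """Build from the units a bench scientist quotes.

        cells/mL and cells/cm^3 coincide; mm and µm are converted to cm;
        D is already cm^2/s.
        """
        return cls(
            production_rate=production_rate,
            cell_density=cell_density_per_ml,
            colony_radius=mm_to_cm(colony_radius_mm),
            diffusion_coefficient=diffusion_coefficient,
            cell_width=um_to_cm(cell_width_um),
        )

    def with_radius_cm(self, radius_cm: float) -> "ColonyParameters":
        return replace(self, colony_radius=radius_cm)

    @property
    def colony_radius_mm(self) -> float:
        return self.colony_radius * 10.0


@dataclass(frozen=True)
class ConcentrationValue:
    """A concentration with an explicit unit tag.

    The tag prevents silently mixing the model's native number density
    (molecules/cm^3) with the user-facing molar scale (nM).
    """

    value: float
    unit: str  # "molecules/cm^3" or "nM"

    MOLECULES = "molecules/cm^3"
    NANOMOLAR = "nM"

    def __post_init__(self) -> None:
        if self.unit not in (self.MOLECULES, self.NANOMOLAR):
            raise ValueError(f"unknown concentration unit {self.unit!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {self.value!r}")


def erf_profile(x):
    """Error function phi(x) = (2/sqrt(pi)) * integral_0^x exp(-h^2) dh.

    The radial shape factor of the single-cell field: 0 at the source centre,
    monotonically increasing, -> 1 far away.  Defined for x >= 0 only.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("erf_profile requires finite input")
    if np.any(x < 0):
        raise ValueError("erf_profile is defined for x >= 0")
    out = special.erf(x)
    return float(out) if out.ndim == 0 else out


def single_cell_origin_limit(production_rate: float, diffusion_coefficient: float,
                             cell_width: float) -> float:
    """Concentration at the centre of a single cell (r -> 0 limit), CGS."""
    return ORIGIN_PREFACTOR_SERIES * production_rate / (
        diffusion_coefficient * cell_width
    )


def single_cell_concentration(
    r: float,
    production_rate: float,
    diffusion_coefficient: float,
    cell_width: float,
) -> ConcentrationValue:
    """Steady-state field of one secreting cell at radial distance r (cm).

    Returns P/(2 pi D r) * phi(r/(sqrt(2) Ws)) in molecules/cm^3.  Below
    r = 1e-6 * Ws the analytic r -> 0 limit is returned so the profile is
    continuous and monotonically non-increasing all the way to the origin.
    """
    for name, v in (
        ("production_rate", production_rate),
        ("diffusion_coefficient", diffusion_coefficient),
        ("cell_width", cell_width),
    ):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")
    if not np.isfinite(r) or r < 0:
        raise ValueError(f"radial position must be finite and >= 0, got {r!r}")

    if r < _SMALL_RADIUS_SWITCH * cell_width:
        value = single_cell_origin_limit(
            production_rate, diffusion_coefficient, cell_width
        )
    else:
        phi = erf_profile(r / (math.sqrt(2.0) * cell_width))
        value = production_rate / (2.0 * math.pi * diffusion_coefficient * r) * phi
    return ConcentrationValue(value, ConcentrationValue.MOLECULES)


def _closed_form_bracket(R: float, Ws: float) -> float:
    """The dimensionless correction bracket of the colony formula.

    Evaluated exactly as written: the last term keeps the exponential inside
    the square root with exponent (R/(2 Ws))^2; it underflows harmlessly to 0
    whenever R >> Ws.
    """
    phi = erf_profile(R / (math.sqrt(2.0) * Ws))
    with np.errstate(under="ignore"):
        tail = math.sqrt((2.0 * Ws / (math.pi * R)) * math.exp(-((R / (2.0 * Ws)) ** 2)))
    return 1.0 - (Ws**2 / R**2) * phi + tail


def colony_concentration_closed_form(params: ColonyParameters) -> ConcentrationValue:
    """Autoinducer concentration at the centre of a spherical colony.

    Closed form (P n R^2 / 2 D) * bracket, molecules/cm^3.  Accurate for
    R/Ws >~ 10 (a warning is emitted below that); cross-checked against
    :func:`colony_concentration_quadrature`.
    """
    if params.colony_radius / params.cell_width < 10.0:
        warnings.warn(
            "colony radius below 10 cell widths: closed form loses accuracy; "
            "compare with colony_concentration_quadrature",
            stacklevel=2,
        )
    bracket = _closed_form_bracket(params.colony_radius, params.cell_width)
    assert bracket > 0.0, "correction bracket must stay positive for R >= Ws"
    value = (
        params.production_rate
        * params.cell_density
        * params.colony_radius**2
        / (2.0 * params.diffusion_coefficient)
        * bracket
    )
    return ConcentrationValue(value, ConcentrationValue.MOLECULES)


def colony_concentration_quadrature(
    params: ColonyParameters, rtol: float = 1.0e-10
) -> ConcentrationValue:
    """Centre concentration by adaptive quadrature of the per-cell fields.

    Evaluates (P n / D) * integral_0^R r * phi(r/(sqrt(2) Ws)) dr directly.
    Serves as the independent numerical oracle for the closed form; raises if
    the quadrature error estimate exceeds the requested relative tolerance.
    """
    R = params.colony_radius
    Ws = params.cell_width
    a = math.sqrt(2.0) * Ws

    integral, err = integrate.quad(
        lambda r: r * special.erf(r / a), 0.0, R, epsabs=0.0, epsrel=rtol, limit=500
    )
    if integral > 0 and err / integral > max(rtol * 10, 1e-9):
        raise RuntimeError(
            f"quadrature did not converge: integral={integral:.6e}, "
            f"estimated error={err:.2e}"
        )
    value = (
        params.production_rate
        * params.cell_density
        / params.diffusion_coefficient
        * integral
    )
    return ConcentrationValue(value, ConcentrationValue.MOLECULES)


def to_nanomolar(c: ConcentrationValue) -> ConcentrationValue:
    """Convert a molecules/cm^3 concentration to nM via Avogadro's number."""
    if c.unit != ConcentrationValue.MOLECULES:
        raise ValueError(f"expected molecules/cm^3 input, got unit {c.unit!r}")
    return ConcentrationValue(
        molecules_per_cm3_to_nM(c.value), ConcentrationValue.NANOMOLAR
    )


def from_nanomolar(c: ConcentrationValue) -> ConcentrationValue:
    """Inverse of :func:`to_nanomolar`; round-trips to machine precision."""
    if c.unit != ConcentrationValue.NANOMOLAR:
        raise ValueError(f"expected nM input, got unit {c.unit!r}")
    return ConcentrationValue(
        nM_to_molecules_per_cm3(c.value), ConcentrationValue.MOLECULES
    )
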