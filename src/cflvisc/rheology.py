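"""Suspension rheology: local viscosity from local particle volume fraction.

The mapping between the local particle volume fraction ``phi_loc`` and the
local dynamic viscosity is the Einstein–Roscoe relation

    mu_loc = mu_carrier * (1 - 1.35 * phi_loc) ** (-2.5)

which is singular at ``phi_loc = 1/1.35`` (maximum packing of the crowding
term).  The relation is adequate for dilute suspensions; at volume fractions
above ~5 % it is known to over-predict the viscosity of blood, which is why
the field-assembly layer carries an adjustment factor that rescales the
profile to match the rheometer measurement (see :mod:`cflvisc.field`).

All viscosities are stored in SI (Pa·s).  Helpers accepting mPa·s carry the
unit in their name so values cannot drift silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CROWDING_FACTOR",
    "ROSCOE_EXPONENT",
    "PHI_SINGULAR",
    "PHI_VALIDATED_MAX",
    "FluidSpec",
    "RheologyError",
    "einstein_roscoe",
    "inverse_einstein_roscoe",
    "viscosity_difference",
]

#: crowding factor of the Einstein–Roscoe relation
CROWDING_FACTOR = 1.35
#: exponent of the Einstein–Roscoe relation
ROSCOE_EXPONENT = -2.5
#: volume fraction where the relation diverges
PHI_SINGULAR = 1.0 / CROWDING_FACTOR
#: upper end of the experimentally validated bulk-fraction range
PHI_VALIDATED_MAX = 0.05


class RheologyError(ValueError):
    """Invalid rheological input (out-of-domain fraction or viscosity)."""


@dataclass(frozen=True)
class FluidSpec:
    """Rheological description of a particle-laden working fluid.

    Parameters
    ----------
    mu_carrier : float
        Dynamic viscosity of the particle-free carrier fluid (plasma for
        blood), Pa·s.  This is the viscosity inside the cell-free layer.
    mu_rheo : float
        Dynamic viscosity of the bulk suspension at ``phi_bulk`` as measured
        in a rheometer, Pa·s.
    phi_bulk : float
        Bulk particle volume fraction (hematocrit for blood), dimensionless.
    density : float, optional
        Fluid density, kg/m³.  Defaults to 1050, a typical blood-like value;
        all headline dimensionless outputs of the flow solver are
        density-independent, so the default only affects dimensional
        quantities such as Pa-valued wall shear stress.
    label : str, optional
        Free-text name ("BAF", "porcine blood", ...).
    """

    mu_carrier: float
    mu_rheo: float
    phi_bulk: float
    density: float = 1050.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.mu_carrier > 0:
            raise RheologyError(f"mu_carrier must be positive, got {self.mu_carrier}")
        if self.mu_rheo < self.mu_carrier:
            raise RheologyError(
                f"mu_rheo ({self.mu_rheo}) must be >= mu_carrier ({self.mu_carrier})"
            )
        if not 0 <= self.phi_bulk < PHI_SINGULAR:
            raise RheologyError(
                f"phi_bulk must lie in [0, {PHI_SINGULAR:.4f}), got {self.phi_bulk}"
            )
        if not self.density > 0:
            raise RheologyError(f"density must be positive, got {self.density}")
        if self.phi_bulk > PHI_VALIDATED_MAX:
            warnings.warn(
                f"phi_bulk={self.phi_bulk:.3f} exceeds the validated range "
                f"(<= {PHI_VALIDATED_MAX}); the viscosity closure is "
                "extrapolated beyond its experimental support",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_mpas(
        cls,
        mu_carrier_mPa_s: float,
        mu_rheo_mPa_s: float,
        phi_bulk: float,
        density: float = 1050.0,
        label: str = "",
    ) -> "FluidSpec":
        """Build a spec from viscosities given in mPa·s (rheometer units)."""
        return cls(
            mu_carrier=mu_carrier_mPa_s * 1e-3,
            mu_rheo=mu_rheo_mPa_s * 1e-3,
            phi_bulk=phi_bulk,
            density=density,
            label=label,
        )

    @property
    def viscosity_difference(self) -> float:
        """mu_rheo - mu_carrier (Pa·s): driver of CFL stress reduction."""
        return self.mu_rheo - self.mu_carrier

    def carrier_only(self) -> "FluidSpec":
        """The particle-free reference fluid (same carrier, phi = 0)."""
        return replace(
            self,
            mu_rheo=self.mu_carrier,
            phi_bulk=0.0,
            label=(self.label + " (carrier)").strip(),
        )


def einstein_roscoe(phi_loc, mu_carrier):
    """Local suspension viscosity from local volume fraction.

    Accepts scalars or arrays (elementwise).  Strictly increasing in
    ``phi_loc`` on ``[0, 1/1.35)`` and equal to ``mu_carrier`` at zero.

    Raises
    ------
    RheologyError
        If ``phi_loc`` is negative or at/above the 1/1.35 singularity, or if
        ``mu_carrier`` is not positive.
    """
    phi = np.asarray(phi_loc, dtype=float)
    if not np.all(mu_carrier > 0):
        raise RheologyError("mu_carrier must be positive")
    if np.any(phi < 0):
        raise RheologyError("phi_loc must be non-negative")
    if np.any(phi >= PHI_SINGULAR):
        raise RheologyError(
            f"phi_loc >= {PHI_SINGULAR:.4f} lies at/above the viscosity singularity"
        )
    out = mu_carrier * (1.0 - CROWDING_FACTOR * phi) ** ROSCOE_EXPONENT
    if np.isscalar(phi_loc) or np.ndim(phi_loc) == 0:
        return float(out)
    return out


def inverse_einstein_roscoe(mu_loc, mu_carrier):
    """Volume fraction that maps to ``mu_loc`` under :func:`einstein_roscoe`.

    Closed-form inversion used when constructing synthetic particle
    distributions from target viscosity profiles; round-trips with the
    forward relation to numerical precision.
    """
    mu = np.asarray(mu_loc, dtype=float)
    if not np.all(mu_carrier > 0):
        raise RheologyError("mu_carrier must be positive")
    if np.any(mu < mu_carrier):
        raise RheologyError("mu_loc must be >= mu_carrier")
    phi = (1.0 - (mu / mu_carrier) ** (1.0 / ROSCOE_EXPONENT)) / CROWDING_FACTOR
    if np.isscalar(mu_loc) or np.ndim(mu_loc) == 0:
        return float(phi)
    return phi


def viscosity_difference(fluid: FluidSpec) -> float:
    """Bulk-minus-carrier viscosity difference (Pa·s) for a fluid spec."""
    return fluid.viscosity_difference
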