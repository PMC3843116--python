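"""qBEI mineral calibration: calcium weight fraction -> mineral volume fraction.

Backscattered-electron grey levels in cortical bone are calibrated to the
local calcium weight fraction psi_ca. Idealizing the mineral phase as
hydroxyapatite Ca10(PO4)6(OH)2, psi_ca converts stoichiometrically to the
mineral (HA) mass fraction psi_mi, and an empirical relation between mineral
mass fraction and ultrastructural mass density then yields the mineral volume
fraction of the fibril array,

    phi_mi = B * psi_mi / (psi_mi - A * rho_HA),

with A = 0.59 ml/g, B = -0.75 and rho_HA = 3.16 g/cm^3 by default. The
relation has a pole at psi_mi = A*rho_HA ~ 1.86, well above any physical mass
fraction, but the branch is guarded defensively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationDomainError, InfeasibleCompositionError, InvalidParameterError
from .fields import ScalarField

__all__ = [
    "ATOMIC_MASSES",
    "ca_mass_fraction_in_hydroxyapatite",
    "MineralCalibration",
    "ca_weight_to_mineral_mass_fraction",
    "mineral_mass_to_volume_fraction",
    "mineral_volume_to_mass_fraction",
    "calibrate_field",
]

# standard atomic masses, g/mol
ATOMIC_MASSES = {"Ca": 40.078, "P": 30.974, "O": 15.999, "H": 1.008}


def ca_mass_fraction_in_hydroxyapatite() -> float:
    """Ca mass share of Ca10(PO4)6(OH)2 from standard atomic masses (~0.3989)."""
    m = ATOMIC_MASSES
    m_ca = 10 * m["Ca"]
    m_total = m_ca + 6 * m["P"] + 26 * m["O"] + 2 * m["H"]
    return m_ca / m_total


@dataclass
class MineralCalibration:
    """Constants of the density calibration (defaults: A=0.59 ml/g, B=-0.75,
    rho_HA=3.16 g/cm^3, stoichiometric Ca share of HA)."""

    A: float = 0.59  # ml/g
    B: float = -0.75
    rho_HA: float = 3.16  # g/cm^3
    ca_mass_fraction_in_HA: float = field(default_factory=ca_mass_fraction_in_hydroxyapatite)

    def __post_init__(self):
        if not self.rho_HA > 0:
            raise InvalidParameterError("rho_HA must be positive")
        if not (0.0 < self.ca_mass_fraction_in_HA < 1.0):
            raise InvalidParameterError("Ca mass fraction in HA must lie in (0, 1)")

    @property
    def pole(self) -> float:
        """psi_mi value at which the empirical relation diverges."""
        return self.A * self.rho_HA


def ca_weight_to_mineral_mass_fraction(psi_ca, cal: MineralCalibration | None = None):
    """Convert calcium weight fraction to hydroxyapatite mass fraction."""
    cal = cal or MineralCalibration()
    psi_ca = np.asarray(psi_ca, dtype=float)
    if np.any(psi_ca < 0) or np.any(psi_ca > cal.ca_mass_fraction_in_HA + 1e-12):
        raise InfeasibleCompositionError(
            f"calcium weight fraction must lie in [0, {cal.ca_mass_fraction_in_HA:.4f}]"
        )
    out = psi_ca / cal.ca_mass_fraction_in_HA
    return float(out) if out.ndim == 0 else out


def mineral_mass_to_volume_fraction(psi_mi, cal: MineralCalibration | None = None):
    """Mineral mass fraction -> mineral volume fraction via the density relation."""
    cal = cal or MineralCalibration()
    psi_mi = np.asarray(psi_mi, dtype=float)
    if np.any(psi_mi < 0) or np.any(psi_mi >= cal.pole):
        raise CalibrationDomainError(
            f"mineral mass fraction must lie in [0, {cal.pole:.4f})"
        )
    phi = cal.B * psi_mi / (psi_mi - cal.A * cal.rho_HA)
    if np.any(phi < -1e-12) or np.any(phi > 1 + 1e-12):
        raise CalibrationDomainError("calibrated volume fraction outside [0, 1]")
    phi = np.clip(phi, 0.0, 1.0)
    return float(phi) if phi.ndim == 0 else phi


def mineral_volume_to_mass_fraction(phi_mi, cal: MineralCalibration | None = None):
    """Closed-form inverse of the density relation (round-trip identity)."""
    cal = cal or MineralCalibration()
    phi_mi = np.asarray(phi_mi, dtype=float)
    psi = phi_mi * cal.A * cal.rho_HA / (phi_mi - cal.B)
    return float(psi) if psi.ndim == 0 else psi


def calibrate_field(ca_map: ScalarField, cal: MineralCalibration | None = None) -> ScalarField:
    """Per-pixel calibration of a calcium weight-fraction raster to phi_mi.

    The validity mask is propagated unchanged. Masked-in pixels violating the
    calibration domain raise an error listing the offending pixel coordinates.
    """
    cal = cal or MineralCalibration()
    vals = ca_map.values
    mask = ca_map.mask
    bad = mask & ((vals < 0) | (vals > cal.ca_mass_fraction_in_HA))
    if np.any(bad):
        rows, cols = np.nonzero(bad)
        listing = ", ".join(f"({r},{c})" for r, c in list(zip(rows, cols))[:10])
        raise InfeasibleCompositionError(
            f"{bad.sum()} pixel(s) outside the calcium calibration domain: {listing}"
        )
    out = np.zeros_like(vals)
    if np.any(mask):
        psi = ca_weight_to_mineral_mass_fraction(vals[mask], cal)
        out[mask] = mineral_mass_to_volume_fraction(psi, cal)
    return ScalarField(
        out, ca_map.pixel_size, tuple(ca_map.origin), mask.copy(),
        quantity="mineral_volume_fraction", units="1",
    )
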