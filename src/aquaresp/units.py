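"""Oxygen unit conversions for aquatic respirometry.

Dissolved-oxygen measurements arrive as % air saturation (optode readout),
but metabolic rates need mass concentrations (mg O2 per litre) and hypoxia
thresholds are reported as partial pressures (kPa).  This module holds the
three conversions everything else builds on:

* ``o2_solubility`` — mg O2 per litre of air-saturated water as a function
  of temperature and salinity, from the Garcia & Gordon (1992) combined fit
  to the Benson & Krause data, the de-facto standard for seawater oxygen.
* ``water_vapour_pressure`` — saturation vapour pressure of water (Buck
  equation), needed to get the dry-gas O2 fraction of moist air.
* ``percent_sat_to_po2`` / ``po2_to_percent_sat`` — the affine map between
  % air saturation and PO2 in kPa at a given temperature and barometric
  pressure; exact inverses of each other.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "O2_MOLE_FRACTION",
    "o2_solubility",
    "water_vapour_pressure",
    "percent_sat_to_po2",
    "po2_to_percent_sat",
]

#: Dry-air mole fraction of O2 (dimensionless).
O2_MOLE_FRACTION = 0.2095

# Garcia & Gordon (1992) combined-fit coefficients, "mL/L" form
# (Benson-Krause scaling).  Valid for -2..40 degC, 0..42 ppt.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7

# mg O2 per mL O2 (STP): molar mass 31.9988 g/mol over real-gas molar
# volume 22.3916 L/mol.
_MG_PER_ML_O2 = 31.9988 / 22.3916


def o2_solubility(temperature: float, salinity: float) -> float:
    """Dissolved O2 at 100% air saturation, mg O2 per litre.

    Parameters
    ----------
    temperature : float
        Water temperature, degrees Celsius.  Accepted range -2..40.
    salinity : float
        Practical salinity, ppt.  Accepted range 0..40.

    Returns
    -------
    float
        mg O2 per litre at full air saturation.  Divide by 100 for the
        solubility coefficient alpha per % air saturation.

    Raises
    ------
    ValueError
        If temperature or salinity is outside the accepted range.
    """
    if not (-2.0 <= temperature <= 40.0):
        raise ValueError(f"temperature {temperature} degC outside -2..40")
    if not (0.0 <= salinity <= 40.0):
        raise ValueError(f"salinity {salinity} ppt outside 0..40")
    ts = np.log((298.15 - temperature) / (273.15 + temperature))
    ln_c = _GG_C0 * salinity * salinity
    ln_c += sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    return float(np.exp(ln_c) * _MG_PER_ML_O2)


def water_vapour_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water over a flat surface, kPa.

    Buck (1981) equation for liquid water; adequate to well under 0.01 kPa
    over the 0-40 degC respirometry range.
    """
    t = np.asarray(temperature, dtype=float)
    p = 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return float(p) if np.isscalar(temperature) else p


def _dry_o2_pressure(temperature: float, barometric_pressure: float) -> float:
    if not (80.0 <= barometric_pressure <= 110.0):
        raise ValueError(
            f"barometric pressure {barometric_pressure} kPa outside the "
            "plausible 80-110 kPa band"
        )
    return O2_MOLE_FRACTION * (barometric_pressure - water_vapour_pressure(temperature))


def percent_sat_to_po2(
    percent_sat,
    temperature: float,
    barometric_pressure: float = 101.325,
):
    """Convert % air saturation to O2 partial pressure (kPa).

    PO2 = (%sat/100) * 0.2095 * (P_bar - P_H2O(T)); water-saturated air at
    the measured barometric pressure.  Vectorised over ``percent_sat``.
    """
    ps = np.asarray(percent_sat, dtype=float)
    if np.any(ps < 0):
        raise ValueError("percent saturation must be >= 0")
    out = ps / 100.0 * _dry_o2_pressure(temperature, barometric_pressure)
    return float(out) if out.ndim == 0 else out


def po2_to_percent_sat(
    po2,
    temperature: float,
    barometric_pressure: float = 101.325,
):
    """Inverse of :func:`percent_sat_to_po2`; round-trips to machine precision."""
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("PO2 must be >= 0")
    out = p * 100.0 / _dry_o2_pressure(temperature, barometric_pressure)
    return float(out) if out.ndim == 0 else out
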