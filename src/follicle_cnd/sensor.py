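"""Ratiometric FRET sensor calibration for cAMPFIRE-M and cGi500.

Both sensors lose FRET on ligand binding, so the CFP/YFP emission ratio
rises monotonically with cyclic-nucleotide concentration.  The response
is a Hill curve

    R(c) = R_min + (R_max - R_min) * c**n / (EC50**n + c**n)

whose mid-range (with n = 1, roughly EC50/3 to 3*EC50) is close to
linear in log10(c) — the regime used for calibrating ratio traces into
concentrations.  The inverse mapping is algebraic and exact strictly
inside (R_min, R_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorCalibration", "CAMPFIRE_M", "CGI500",
           "ratio_from_concentration", "concentration_from_ratio",
           "SaturationError"]


class SaturationError(ValueError):
    """Requested ratio is at or beyond a saturated end of the curve."""


@dataclass(frozen=True)
class SensorCalibration:
    R_min: float
    R_max: float
    EC50: float
    hill_n: float
    sensor_id: str

    def __post_init__(self) -> None:
        if not self.R_max > self.R_min > 0:
            raise ValueError("require R_max > R_min > 0")
        if self.EC50 <= 0 or self.hill_n <= 0:
            raise ValueError("EC50 and hill_n must be positive")


# Defaults place the measured basal (~700 nM), minimum (~170 nM) and
# peak (~3,400 nM) cAMP levels inside the quasi-log-linear mid-range.
CAMPFIRE_M = SensorCalibration(R_min=1.0, R_max=3.0, EC50=1000.0,
                               hill_n=1.0, sensor_id="cAMPFIRE-M")
CGI500 = SensorCalibration(R_min=1.0, R_max=3.0, EC50=500.0,
                           hill_n=1.0, sensor_id="cGi500")


def ratio_from_concentration(c, calib: SensorCalibration = CAMPFIRE_M):
    """CFP/YFP emission ratio at ligand concentration ``c`` (nM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    x = c**calib.hill_n
    r = calib.R_min + (calib.R_max - calib.R_min) * x / (calib.EC50**calib.hill_n + x)
    return r if r.ndim else float(r)


def concentration_from_ratio(r, calib: SensorCalibration = CAMPFIRE_M):
    """Exact inverse of :func:`ratio_from_concentration` on (R_min, R_max)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= calib.R_min):
        raise SaturationError(
            f"ratio at or below R_min = {calib.R_min} (zero-ligand end)")
    if np.any(r >= calib.R_max):
        raise SaturationError(
            f"ratio at or above R_max = {calib.R_max} (saturated end)")
    f = (r - calib.R_min) / (calib.R_max - r)
    c = calib.EC50 * f ** (1.0 / calib.hill_n)
    return c if c.ndim else float(c)
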