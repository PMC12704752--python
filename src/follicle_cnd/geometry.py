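"""Follicle geometry and compartment volumes.

A cultured preovulatory follicle (~320-360 um diameter) flattens on the
imaging membrane to a disc ~200 um high.  The model treats it as three
well-mixed cytosolic compartments: the oocyte (a sphere), the cumulus
cell layer (a ~25 um shell around the oocyte), and the mural granulosa
(everything else inside the follicle that is not antral fluid).  Only
the volume ratios matter for the coupled dynamics; the mural compartment
is roughly two orders of magnitude larger than the oocyte, which is what
makes it an effective sink for oocyte cGMP after LH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class FollicleGeometry:
    """Geometric description of a flattened preovulatory follicle.

    Lengths are in micrometers, volumes in cubic micrometers.
    """

    follicle_diameter: float = 340.0
    disc_height: float = 200.0
    mural_band_width: float = 40.0
    cumulus_band_width: float = 25.0
    oocyte_diameter: float = 75.0
    nucleus_diameter: float = 30.0
    antral_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.antral_fraction < 1.0:
            raise ValueError("antral_fraction must be in [0, 1)")
        for name in ("follicle_diameter", "disc_height", "mural_band_width",
                     "cumulus_band_width", "oocyte_diameter", "nucleus_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nucleus_diameter >= self.oocyte_diameter:
            raise ValueError("nucleus must fit inside the oocyte")
        inner = self.oocyte_diameter / 2 + self.cumulus_band_width
        if inner + self.mural_band_width >= self.follicle_diameter / 2:
            raise ValueError("cumulus and mural bands do not fit in the follicle")
        if not self.V_m > self.V_c > self.V_o > 0:
            raise ValueError("expected V_m > V_c > V_o > 0")

    @property
    def V_o(self) -> float:
        """Oocyte cytosolic volume (sphere)."""
        r = self.oocyte_diameter / 2
        return 4.0 / 3.0 * math.pi * r**3

    @property
    def V_c(self) -> float:
        """Cumulus cell layer volume (spherical shell around the oocyte)."""
        r_in = self.oocyte_diameter / 2
        r_out = r_in + self.cumulus_band_width
        return 4.0 / 3.0 * math.pi * (r_out**3 - r_in**3)

    @property
    def V_follicle(self) -> float:
        """Total volume of the flattened follicle disc."""
        r = self.follicle_diameter / 2
        return math.pi * r**2 * self.disc_height

    @property
    def V_m(self) -> float:
        """Mural granulosa volume: disc minus antrum, oocyte and cumulus."""
        return (1.0 - self.antral_fraction) * self.V_follicle - self.V_o - self.V_c


DEFAULT_GEOMETRY = FollicleGeometry()
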