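"""Shared result container for the three measurement methods."""

from __future__ import annotations

from dataclasses import dataclass

#: Method tags as reported in cohort tables.
CETCEM = "CETCEM"
CORONAL_SLICES = "CoronalSlices"
BONY_LANDMARKS = "BonyLandmarks"

METHODS = (CETCEM, CORONAL_SLICES, BONY_LANDMARKS)


@dataclass
class MethodResult:
    """One method's maximal extrusion and where it occurred.

    ``location_ap`` is mm from the joint-line front; ``location_pct`` is the
    same position as a percentage of the AP breadth (0% = front).
    ``extruded`` applies the binary classification rule to the signed
    maximal extrusion.
    """

    method: str
    max_extrusion: float
    location_ap: float
    location_pct: float
    extruded: bool

    def as_row(self, knee_id: str) -> dict:
        return {
            "knee_id": knee_id,
            "method": self.method,
            "max_extrusion_mm": self.max_extrusion,
            "location_ap_mm": self.location_ap,
            "location_pct": self.location_pct,
            "extruded": self.extruded,
        }
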