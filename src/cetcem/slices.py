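"""Proxy measurements on simulated coronal slices.

Both clinical proxy methods measure the *horizontal* (mediolateral)
difference between the most medial meniscus point and the most medial
tibia point on a coronal slice.  Slices are simulated at 1-mm AP stations
from the front to the back of the tibial plateau:

* Coronal Slices method — report the station with the maximal horizontal
  extrusion;
* Bony Landmarks method — report the single station through the medial
  tibial spine apex.

Because a slice off the mediolateral extremum cuts the tibial and meniscal
edge circles along non-parallel chords, the horizontal distance at such a
slice exceeds the perpendicular extrusion — the geometric reason the
maximal-slice method overestimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import (
    PLATEAU_BAND_MM,
    AnatomicalFrame,
    TibialLandmarks,
    align_to_long_axis,
    locate_spine_apex,
)
from .errors import MeasurementError
from .mesh_io import KneeSpecimen
from .results import BONY_LANDMARKS, CORONAL_SLICES, MethodResult
from .stats import classify_extruded

#: Half-width (mm) of the vertex slab representing one 1-mm coronal slice.
SLAB_HALFWIDTH_MM = 0.5

#: AP spacing (mm) of the simulated slices.
STATION_INTERVAL_MM = 1.0


@dataclass
class SliceMeasurement:
    """Horizontal extrusion on one simulated coronal slice.

    ``horizontal_extrusion`` is NaN when either structure has no vertices
    in the slab (the station is missing, not zero).  ``tibia_edge_ap`` and
    ``meniscus_edge_ap`` record the AP positions of the selected vertices —
    the effective planes the measurement was actually made on.
    """

    ap_station: float
    horizontal_extrusion: float
    n_tib_pts: int
    n_men_pts: int
    tibia_edge_ap: float = math.nan
    meniscus_edge_ap: float = math.nan

    @property
    def valid(self) -> bool:
        return not math.isnan(self.horizontal_extrusion)


def _canonical_vertices(specimen: KneeSpecimen, frame: AnatomicalFrame, plateau_band_mm: float):
    tib = frame.transform_points(specimen.tibia.vertices)
    tib = tib[tib[:, 2] >= tib[:, 2].max() - plateau_band_mm - 1e-6]
    men = frame.transform_points(specimen.meniscus.vertices)
    return tib, men


def _slab_measure(
    tib: np.ndarray, men: np.ndarray, station: float, slab_halfwidth: float
) -> SliceMeasurement:
    tsel = tib[np.abs(tib[:, 1] - station) <= slab_halfwidth]
    msel = men[np.abs(men[:, 1] - station) <= slab_halfwidth]
    if len(tsel) == 0 or len(msel) == 0:
        return SliceMeasurement(station, math.nan, len(tsel), len(msel))
    it = int(np.argmax(tsel[:, 0]))
    im = int(np.argmax(msel[:, 0]))
    return SliceMeasurement(
        ap_station=station,
        horizontal_extrusion=float(msel[im, 0] - tsel[it, 0]),
        n_tib_pts=len(tsel),
        n_men_pts=len(msel),
        tibia_edge_ap=float(tsel[it, 1]),
        meniscus_edge_ap=float(msel[im, 1]),
    )


def slice_extrusion(
    specimen: KneeSpecimen,
    frame: AnatomicalFrame,
    ap_station: float,
    slab_halfwidth: float = SLAB_HALFWIDTH_MM,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> SliceMeasurement:
    """Horizontal extrusion at a single AP station.

    The slab holds vertices with ``|y - station| <= slab_halfwidth``; the
    tibia is restricted to the plateau height band.  The value is signed:
    a meniscus lateral to the tibial rim gives a negative extrusion.
    """
    tib, men = _canonical_vertices(specimen, frame, plateau_band_mm)
    return _slab_measure(tib, men, ap_station, slab_halfwidth)


def station_grid(ap_breadth: float, interval: float = STATION_INTERVAL_MM) -> np.ndarray:
    """Stations covering [0, ap_breadth] at exactly ``interval`` spacing."""
    return np.arange(0.0, ap_breadth + 1e-9, interval)


def slice_table(
    specimen: KneeSpecimen,
    frame: AnatomicalFrame | None = None,
    landmarks: TibialLandmarks | None = None,
    slab_halfwidth: float = SLAB_HALFWIDTH_MM,
    station_interval: float = STATION_INTERVAL_MM,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> list[SliceMeasurement]:
    """All simulated-slice measurements from the front to the back of the plateau."""
    if frame is None:
        frame = align_to_long_axis(specimen.tibia, specimen.side, plateau_band_mm)
    if landmarks is None:
        landmarks = locate_spine_apex(specimen.tibia, frame, plateau_band_mm)
    tib, men = _canonical_vertices(specimen, frame, plateau_band_mm)
    return [
        _slab_measure(tib, men, float(s), slab_halfwidth)
        for s in station_grid(landmarks.ap_breadth, station_interval)
    ]


def _to_result(
    method: str,
    meas: SliceMeasurement,
    ap_breadth: float,
    threshold_mm: float,
) -> MethodResult:
    return MethodResult(
        method=method,
        max_extrusion=meas.horizontal_extrusion,
        location_ap=meas.ap_station,
        location_pct=100.0 * meas.ap_station / ap_breadth,
        extruded=classify_extruded(meas.horizontal_extrusion, threshold_mm),
    )


def coronal_slices_measure(
    specimen: KneeSpecimen,
    frame: AnatomicalFrame | None = None,
    landmarks: TibialLandmarks | None = None,
    slab_halfwidth: float = SLAB_HALFWIDTH_MM,
    station_interval: float = STATION_INTERVAL_MM,
    threshold_mm: float = 3.0,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> MethodResult:
    """Maximal horizontal extrusion over all valid stations.

    Stations whose slab is empty for either structure are excluded from
    the maximum (never zero-filled); an exact tie reports the most
    anterior station.
    """
    if frame is None:
        frame = align_to_long_axis(specimen.tibia, specimen.side, plateau_band_mm)
    if landmarks is None:
        landmarks = locate_spine_apex(specimen.tibia, frame, plateau_band_mm)
    table = slice_table(
        specimen, frame, landmarks, slab_halfwidth, station_interval, plateau_band_mm
    )
    valid = [m for m in table if m.valid]
    if not valid:
        raise MeasurementError("no station has vertices of both structures in its slab")
    best = max(valid, key=lambda m: (m.horizontal_extrusion, -m.ap_station))
    return _to_result(CORONAL_SLICES, best, landmarks.ap_breadth, threshold_mm)


def bony_landmarks_measure(
    specimen: KneeSpecimen,
    frame: AnatomicalFrame | None = None,
    landmarks: TibialLandmarks | None = None,
    slab_halfwidth: float = SLAB_HALFWIDTH_MM,
    station_interval: float = STATION_INTERVAL_MM,
    threshold_mm: float = 3.0,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> MethodResult:
    """Horizontal extrusion on the slice through the medial tibial spine apex.

    The station nearest the apex is used; an exact midpoint resolves to
    the anterior station.  A missing slab at that station is an error, not
    a silent fallback to a neighbouring slice.
    """
    if frame is None:
        frame = align_to_long_axis(specimen.tibia, specimen.side, plateau_band_mm)
    if landmarks is None:
        landmarks = locate_spine_apex(specimen.tibia, frame, plateau_band_mm)
    stations = station_grid(landmarks.ap_breadth, station_interval)
    dist = np.abs(stations - landmarks.spine_apex_ap)
    # nearest station; exact midpoint ties resolve anterior (smaller station)
    best = stations[np.lexsort((stations, np.round(dist, 9)))][0]
    tib, men = _canonical_vertices(specimen, frame, plateau_band_mm)
    meas = _slab_measure(tib, men, float(best), slab_halfwidth)
    if not meas.valid:
        raise MeasurementError(
            f"slab at the spine-apex station ({best:.1f} mm) is missing "
            f"({meas.n_tib_pts} tibia / {meas.n_men_pts} meniscus vertices)"
        )
    return _to_result(BONY_LANDMARKS, meas, landmarks.ap_breadth, threshold_mm)
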