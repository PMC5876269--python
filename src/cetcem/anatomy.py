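"""Canonical anatomical frame and tibial landmarks.

Every measurement method works in a canonical knee coordinate system:
x increases medially, y is antero-posterior position (0 at the most
anterior joint-line point, increasing posteriorly), z increases proximally
along the tibial long axis.  Left knees are mirrored into this frame so a
single medial-is-+x convention serves both sides.

The frame is recovered automatically and deterministically:

* long axis — principal component of the tibial vertex cloud with the
  largest variance; the proximal end is the end with the larger
  convex-hull cross-section (the plateau beats the shaft);
* AP axis — the minor principal axis of the plateau band's in-plane
  vertex distribution (the plateau is wider mediolaterally than it is
  deep);
* medial sign — the highest plateau point (the medial tibial spine apex)
  sits just medial of the mediolateral midline;
* handedness — right knees give a right-handed (x, y, z) triple, left
  knees a mirrored one, which is exactly the left-to-canonical mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .errors import AlignmentError, LandmarkError
from .mesh_io import TriangleSurface

#: Height of the joint-line ("plateau") band below the highest tibial
#: point, in mm.  Breadth, width and the AP origin are computed over this
#: band only, which keeps the flaring shaft out of the landmarks.
PLATEAU_BAND_MM = 10.0

#: Spine-apex search band: from the ML centre to this fraction of the ML
#: width medially.
SPINE_SEARCH_FRAC = 0.25


@dataclass
class AnatomicalFrame:
    """Orthonormal map ``canonical = matrix @ world + translation``.

    ``matrix`` has determinant +1 for right knees and -1 for left knees
    (mirroring to canonical).
    """

    matrix: np.ndarray
    translation: np.ndarray
    side: str

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.matrix.T + self.translation

    def inverse_transform_points(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.translation) @ self.matrix

    def transform_surface(self, surface: TriangleSurface) -> TriangleSurface:
        return surface.transformed(self.matrix, self.translation)


@dataclass
class TibialLandmarks:
    """Plateau landmarks in canonical (frame) coordinates."""

    ap_breadth: float
    spine_apex_ap: float
    spine_apex_point: np.ndarray
    ml_width: float


def _principal_axes(surface: TriangleSurface) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of the surface, area-weighted over triangle centroids.

    Area weighting makes the axes independent of meshing density (a finely
    sampled plateau must not outvote the shaft); surfaces without faces
    fall back to uniform vertex weights.
    """
    V = surface.vertices
    if len(surface.faces):
        tri = V[surface.faces]
        centroids = tri.mean(axis=1)
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if areas.sum() <= 0:
            centroids, areas = V, np.ones(len(V))
    else:
        centroids, areas = V, np.ones(len(V))
    w = areas / areas.sum()
    mean = w @ centroids
    centred = centroids - mean
    cov = (centred * w[:, None]).T @ centred
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] < 1e-10 * max(evals[-1], 1.0):
        raise AlignmentError("degenerate (planar or linear) vertex cloud")
    return evals, evecs


def _slab_hull_area(pts2: np.ndarray) -> float:
    if len(pts2) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts2).volume)  # 2D hull "volume" is the area
    except Exception:
        return 0.0


def _inplane_minor_axis(pts2: np.ndarray) -> np.ndarray:
    """Unit in-plane direction of smallest variance (the AP direction)."""
    centred = pts2 - pts2.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] < 1e-3 * max(evals[1], 1.0):
        raise AlignmentError("in-plane axes ill-determined: plateau nearly isotropic")
    return evecs[:, 0]


def align_to_long_axis(
    tibia: TriangleSurface,
    side: str,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> AnatomicalFrame:
    """Establish the canonical frame from the tibial surface alone."""
    if side not in ("left", "right"):
        raise AlignmentError(f"side must be 'left' or 'right', got {side!r}")
    V = tibia.vertices
    if len(V) < 4:
        raise AlignmentError("too few vertices to align")
    _evals, evecs = _principal_axes(tibia)
    z_axis = evecs[:, 2]

    # proximal end = larger hull cross-section in the extreme 10% z-slabs
    s = V @ z_axis
    lo, hi = s.min(), s.max()
    if hi - lo < 1e-9:
        raise AlignmentError("zero extent along candidate long axis")
    depth = 0.10 * (hi - lo)
    basis = evecs[:, :2]
    top_area = _slab_hull_area(V[s >= hi - depth] @ basis)
    bot_area = _slab_hull_area(V[s <= lo + depth] @ basis)
    if bot_area > top_area:
        z_axis = -z_axis
        s = -s

    # plateau band and in-plane axes; the small tolerance keeps vertex
    # layers lying exactly on the band boundary inside it in every pose
    band = V[s >= s.max() - plateau_band_mm - 1e-6]
    e1 = evecs[:, 0]
    e2 = np.cross(z_axis, e1)
    e2 /= np.linalg.norm(e2)
    e1 = np.cross(e2, z_axis)
    band2 = band @ np.column_stack([e1, e2])
    ap2 = _inplane_minor_axis(band2)
    ml2 = np.array([-ap2[1], ap2[0]])
    ml_axis = ml2[0] * e1 + ml2[1] * e2

    # medial sign: the spine apex (highest band point) is medial of centre
    heights = band @ z_axis
    top = band[heights >= heights.max() - 1e-9]
    ml_coords = band @ ml_axis
    mid = 0.5 * (ml_coords.max() + ml_coords.min())
    apex_ml = float((top @ ml_axis).mean())
    if apex_ml < mid:
        ml_axis = -ml_axis
    x_axis = ml_axis
    y_axis = np.cross(z_axis, x_axis)
    if side == "left":
        y_axis = -y_axis

    M = np.vstack([x_axis, y_axis, z_axis])
    bandc = band @ M.T
    translation = -np.array(
        [
            0.5 * (bandc[:, 0].max() + bandc[:, 0].min()),
            bandc[:, 1].min(),
            bandc[:, 2].max(),
        ]
    )
    return AnatomicalFrame(matrix=M, translation=translation, side=side)


def _band(verts_c: np.ndarray, plateau_band_mm: float) -> np.ndarray:
    z = verts_c[:, 2]
    return verts_c[z >= z.max() - plateau_band_mm - 1e-6]


def measure_ap_breadth(
    tibia: TriangleSurface,
    frame: AnatomicalFrame,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> float:
    """AP depth of the tibial plateau: max minus min y over the plateau band."""
    band = _band(frame.transform_points(tibia.vertices), plateau_band_mm)
    return float(band[:, 1].max() - band[:, 1].min())


def locate_spine_apex(
    tibia: TriangleSurface,
    frame: AnatomicalFrame,
    plateau_band_mm: float = PLATEAU_BAND_MM,
    search_frac: float = SPINE_SEARCH_FRAC,
) -> TibialLandmarks:
    """Locate the medial tibial spine apex and the plateau dimensions.

    The apex is the highest vertex within the medial-paracentral search
    band (ML centre to ``search_frac`` of the ML width medially); an exact
    height tie is broken toward the more anterior vertex.
    """
    band = _band(frame.transform_points(tibia.vertices), plateau_band_mm)
    ml_lo, ml_hi = band[:, 0].min(), band[:, 0].max()
    ml_width = float(ml_hi - ml_lo)
    centre = 0.5 * (ml_lo + ml_hi)
    sel = band[(band[:, 0] >= centre) & (band[:, 0] <= centre + search_frac * ml_width)]
    if len(sel) == 0:
        raise LandmarkError("no vertices in the medial-paracentral spine search band")
    zmax = sel[:, 2].max()
    cands = sel[sel[:, 2] >= zmax - 1e-9]
    apex = cands[np.argmin(cands[:, 1])]
    return TibialLandmarks(
        ap_breadth=float(band[:, 1].max() - band[:, 1].min()),
        spine_apex_ap=float(apex[1]),
        spine_apex_point=apex.copy(),
        ml_width=ml_width,
    )


def location_percent(ap_mm: float, ap_breadth: float) -> float:
    """AP position as percent of AP breadth (0% = joint-line front), unrounded."""
    if ap_breadth <= 0:
        raise ValueError("ap_breadth must be positive")
    if not (-1e-9 <= ap_mm <= ap_breadth + 1e-9):
        raise ValueError("ap_mm must lie within [0, ap_breadth]")
    return 100.0 * ap_mm / ap_breadth
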