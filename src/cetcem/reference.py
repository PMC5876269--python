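"""Reference-standard extrusion measurement (CETCEM).

The "Circular Edge of Tibia to Circular Edge of Meniscus" procedure: the
tibia and meniscus are divided into anterior and posterior portions by the
coronal plane through the medial tibial spine apex, giving four medial-edge
regions; a circle is fitted to each region's edge; rays from each tibial
circle centre are intersected with the corresponding meniscal circle; the
perpendicular (radial) extrusion at each angle is the intersection distance
minus the tibial radius.  This is the quantity a slice-based horizontal
measurement can only approximate.

Edge picking is automated: the most-medial vertex per AP bin, with the
tibia restricted to the plateau height band.  Circles are fitted to the
raw picked points; linear interpolation fills the slice-thickness gaps in
the edges for the dense profile exports and the polyline oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import (
    PLATEAU_BAND_MM,
    AnatomicalFrame,
    TibialLandmarks,
    align_to_long_axis,
    locate_spine_apex,
)
from .errors import (
    DegenerateFitError,
    EdgeExtractionError,
    InterpolationError,
    NoOverlapError,
)
from .mesh_io import KneeSpecimen, TriangleSurface
from .results import CETCEM, MethodResult
from .stats import classify_extruded

#: Angular margin (deg) beyond the raw meniscal points within which the
#: fitted circles may be evaluated; forbids extrapolating past the horns.
SUPPORT_MARGIN_DEG = 2.0

#: Maximum |d(ml)/d(ap)| secant slope at a trace end for the points to
#: count as *medial* edge.  Where the boundary turns to run mediolaterally
#: (near the plateau's AP poles) per-AP-bin picks no longer represent the
#: medial edge and their interpolation chords would bias the circle fits,
#: so steep ends are trimmed.  2.5 corresponds to an edge tangent about
#: 68 deg around the circle from the mediolateral extremum.
MAX_EDGE_SLOPE = 2.5


@dataclass
class EdgeTrace:
    """Ordered medial-edge points of one region, in the axial plane.

    ``points`` columns are (ap_mm, ml_mm); rows are strictly increasing in
    ap_mm.
    """

    structure: str  # "tibia" | "meniscus"
    region: str  # "anterior" | "posterior"
    points: np.ndarray
    source_spacing: float

    @property
    def ap(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class FittedCircle:
    """Least-squares circle: centre (ap, ml), radius, fit quality."""

    centre_ap: float
    centre_ml: float
    radius: float
    rms_residual: float
    n_points: int

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.centre_ap, self.centre_ml])


@dataclass
class RadialExtrusionProfile:
    """Sampled perpendicular extrusion over one region's angular support.

    Angles are about the region's tibial circle centre: 0 deg points due
    medial, positive angles posterior.  Extrusion may be negative (meniscus
    inside the tibial rim).
    """

    region: str
    angle_deg: np.ndarray
    extrusion_mm: np.ndarray
    ap_mm: np.ndarray


def extract_medial_edge(
    surface: TriangleSurface,
    frame: AnatomicalFrame,
    landmarks: TibialLandmarks,
    structure: str,
    bin_mm: float = 1.0,
    plateau_band_mm: float = PLATEAU_BAND_MM,
    max_edge_slope: float = MAX_EDGE_SLOPE,
) -> tuple[EdgeTrace, EdgeTrace]:
    """Pick the most-medial vertex per AP bin and split at the spine apex.

    The tibia contributes only plateau-band vertices (so the shaft cannot
    be picked); the meniscus is taken whole.  Bins with no vertices are
    simply absent from the trace — interpolation fills them later.  Trace
    ends steeper than ``max_edge_slope`` are trimmed: there the boundary
    no longer faces medially and per-bin picks stop being medial edge.
    """
    if structure not in ("tibia", "meniscus"):
        raise ValueError(f"structure must be 'tibia' or 'meniscus', got {structure!r}")
    V = frame.transform_points(surface.vertices)
    if structure == "tibia":
        V = V[V[:, 2] >= V[:, 2].max() - plateau_band_mm - 1e-6]
    x, y = V[:, 0], V[:, 1]
    bins = np.floor(y / bin_mm).astype(np.int64)
    order = np.lexsort((x, bins))
    bins_sorted = bins[order]
    last_of_bin = np.r_[bins_sorted[1:] != bins_sorted[:-1], True]
    picked = order[last_of_bin]
    pts = np.column_stack([y[picked], x[picked]])
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    # strict AP ordering: on exact AP ties keep the most medial point
    keep = np.r_[True, np.diff(pts[:, 0]) > 0]
    for i in np.nonzero(~keep)[0]:
        if pts[i, 1] > pts[i - 1, 1]:
            pts[i - 1] = pts[i]
    pts = pts[keep]

    def _steep(i: int, j: int) -> bool:
        dap = pts[j, 0] - pts[i, 0]
        return abs(pts[j, 1] - pts[i, 1]) > max_edge_slope * abs(dap)

    lo, hi = 0, len(pts) - 1
    while hi - lo > 2 and _steep(lo, lo + 1):
        lo += 1
    while hi - lo > 2 and _steep(hi - 1, hi):
        hi -= 1
    pts = pts[lo : hi + 1]

    apex = landmarks.spine_apex_ap
    traces = []
    for region, sel in (("anterior", pts[:, 0] < apex), ("posterior", pts[:, 0] >= apex)):
        sub = pts[sel]
        if len(sub) < 3:
            raise EdgeExtractionError(
                f"{structure} {region} edge has {len(sub)} points; need at least 3"
            )
        traces.append(EdgeTrace(structure, region, sub, bin_mm))
    return traces[0], traces[1]


def interpolate_edge(trace: EdgeTrace, target_spacing: float = 0.1) -> EdgeTrace:
    """Piecewise-linear resample in AP at ``target_spacing``; endpoints kept."""
    if len(trace.points) < 2:
        raise InterpolationError("cannot interpolate a single-point trace")
    y0, y1 = trace.ap[0], trace.ap[-1]
    grid = np.arange(y0, y1, target_spacing)
    if len(grid) == 0 or y1 - grid[-1] > 1e-12:
        grid = np.append(grid, y1)
    ml = np.interp(grid, trace.ap, trace.ml)
    return EdgeTrace(trace.structure, trace.region, np.column_stack([grid, ml]), target_spacing)


def fit_circle(points: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> FittedCircle:
    """Least-squares circle fit: Kasa algebraic start, geometric refinement.

    The refinement is Gauss-Newton on orthogonal distances, iterated to a
    step of ``tol`` mm.  Near-collinear inputs (circumradius exceeding
    1e4 times the point spread) are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateFitError("circle fit needs at least 3 planar points")
    u, v = pts[:, 0], pts[:, 1]
    spread = max(np.ptp(u), np.ptp(v))
    if spread <= 0:
        raise DegenerateFitError("all points coincide")
    A = np.column_stack([2 * u, 2 * v, np.ones(len(u))])
    b = u * u + v * v
    sol, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateFitError("collinear points: circle fit is degenerate")
    cu, cv = sol[0], sol[1]
    r2 = sol[2] + cu * cu + cv * cv
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateFitError("algebraic circle fit failed")
    p = np.array([cu, cv, np.sqrt(r2)])
    if p[2] > 1e4 * spread:
        raise DegenerateFitError(
            f"points are collinear within tolerance (circumradius {p[2]:.3g} "
            f"vs spread {spread:.3g})"
        )
    for _ in range(max_iter):
        du, dv = u - p[0], v - p[1]
        d = np.hypot(du, dv)
        res = d - p[2]
        J = np.column_stack([-du / d, -dv / d, -np.ones(len(u))])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        p = p + step
        if np.max(np.abs(step)) < tol:
            break
    du, dv = u - p[0], v - p[1]
    res = np.hypot(du, dv) - p[2]
    if p[2] > 1e4 * spread:
        raise DegenerateFitError("points are collinear within tolerance")
    return FittedCircle(
        centre_ap=float(p[0]),
        centre_ml=float(p[1]),
        radius=float(p[2]),
        rms_residual=float(np.sqrt(np.mean(res * res))),
        n_points=len(u),
    )


def point_angles_deg(circle: FittedCircle, points: np.ndarray) -> np.ndarray:
    """Angles of points about a tibial circle centre (0 = medial, + = posterior)."""
    pts = np.asarray(points, dtype=float)
    return np.degrees(np.arctan2(pts[:, 0] - circle.centre_ap, pts[:, 1] - circle.centre_ml))


def radial_extrusion(
    tib_circle: FittedCircle,
    men_circle: FittedCircle,
    support_deg: tuple[float, float],
    region: str = "",
    angle_step_deg: float = 1.0,
) -> RadialExtrusionProfile:
    """Perpendicular extrusion profile by ray-casting from the tibial centre.

    For each sampled angle the ray from the tibial circle centre is
    intersected with the meniscal circle (far intersection); extrusion is
    the intersection distance minus the tibial radius — negative when the
    meniscus sits inside the tibial rim.  Angles whose ray misses the
    meniscal circle are dropped with a warning.
    """
    s0, s1 = support_deg
    if not (s0 < s1):
        raise NoOverlapError("empty angular support")
    angles = np.arange(s0, s1 + 1e-9, angle_step_deg)
    rad = np.deg2rad(angles)
    u = np.column_stack([np.sin(rad), np.cos(rad)])  # (ap, ml) direction
    c = men_circle.centre - tib_circle.centre
    uc = u @ c
    disc = uc * uc - (c @ c - men_circle.radius**2)
    ok = disc >= 0
    if not np.any(ok):
        raise NoOverlapError("no ray from the tibial centre intersects the meniscal circle")
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} angle(s) missed the meniscal circle and were dropped",
            stacklevel=2,
        )
    s = uc[ok] + np.sqrt(disc[ok])
    ap = tib_circle.centre_ap + s * np.sin(rad[ok])
    return RadialExtrusionProfile(
        region=region,
        angle_deg=angles[ok],
        extrusion_mm=s - tib_circle.radius,
        ap_mm=ap,
    )


@dataclass
class CetcemDetail:
    """Full intermediate state of one CETCEM measurement."""

    frame: AnatomicalFrame
    landmarks: TibialLandmarks
    tibia_traces: dict[str, EdgeTrace]
    meniscus_traces: dict[str, EdgeTrace]
    tibia_circles: dict[str, FittedCircle]
    meniscus_circles: dict[str, FittedCircle]
    profiles: dict[str, RadialExtrusionProfile]
    result: MethodResult


def cetcem_analyse(
    specimen: KneeSpecimen,
    bin_mm: float = 1.0,
    interp_mm: float = 0.1,
    angle_step_deg: float = 1.0,
    threshold_mm: float = 3.0,
    plateau_band_mm: float = PLATEAU_BAND_MM,
) -> CetcemDetail:
    """Run the full CETCEM chain and keep every intermediate product."""
    frame = align_to_long_axis(specimen.tibia, specimen.side, plateau_band_mm)
    landmarks = locate_spine_apex(specimen.tibia, frame, plateau_band_mm)

    tib_raw = extract_medial_edge(
        specimen.tibia, frame, landmarks, "tibia", bin_mm, plateau_band_mm
    )
    men_raw = extract_medial_edge(
        specimen.meniscus, frame, landmarks, "meniscus", bin_mm, plateau_band_mm
    )
    tib_traces = {t.region: interpolate_edge(t, interp_mm) for t in tib_raw}
    men_traces = {t.region: interpolate_edge(t, interp_mm) for t in men_raw}
    men_raw_by_region = {t.region: t for t in men_raw}

    # circles are fitted to the raw picked points (which lie on the true
    # edges); the interpolated traces fill slice gaps for the dense
    # profile exports and the polyline oracle
    tib_circles = {t.region: fit_circle(t.points) for t in tib_raw}
    men_circles = {t.region: fit_circle(t.points) for t in men_raw}

    profiles: dict[str, RadialExtrusionProfile] = {}
    for region in ("anterior", "posterior"):
        raw_angles = point_angles_deg(tib_circles[region], men_raw_by_region[region].points)
        support = (
            float(raw_angles.min() - SUPPORT_MARGIN_DEG),
            float(raw_angles.max() + SUPPORT_MARGIN_DEG),
        )
        prof = radial_extrusion(
            tib_circles[region], men_circles[region], support, region, angle_step_deg
        )
        # each region owns only its side of the dividing plane, and the
        # profile is reported only within the plateau's AP extent
        keep = (prof.ap_mm >= 0.0) & (prof.ap_mm <= landmarks.ap_breadth)
        if region == "anterior":
            keep &= prof.ap_mm <= landmarks.spine_apex_ap
        else:
            keep &= prof.ap_mm >= landmarks.spine_apex_ap
        profiles[region] = RadialExtrusionProfile(
            region, prof.angle_deg[keep], prof.extrusion_mm[keep], prof.ap_mm[keep]
        )

    # maximum over both regions; exact ties resolve posterior, then larger angle
    best = None
    for region in ("anterior", "posterior"):
        prof = profiles[region]
        if len(prof.extrusion_mm) == 0:
            continue
        for e, th, ap in zip(prof.extrusion_mm, prof.angle_deg, prof.ap_mm):
            key = (e, region == "posterior", th)
            if best is None or key > best[0]:
                best = (key, region, float(e), float(ap))
    if best is None:
        raise NoOverlapError("no extrusion samples within the tibial plateau extent")
    _, _region, max_e, loc_ap = best
    result = MethodResult(
        method=CETCEM,
        max_extrusion=max_e,
        location_ap=loc_ap,
        location_pct=100.0 * loc_ap / landmarks.ap_breadth,
        extruded=classify_extruded(max_e, threshold_mm),
    )
    return CetcemDetail(
        frame=frame,
        landmarks=landmarks,
        tibia_traces=tib_traces,
        meniscus_traces=men_traces,
        tibia_circles=tib_circles,
        meniscus_circles=men_circles,
        profiles=profiles,
        result=result,
    )


def cetcem_measure(specimen: KneeSpecimen, **kwargs) -> MethodResult:
    """Maximal perpendicular extrusion by the reference method."""
    return cetcem_analyse(specimen, **kwargs).result


def oracle_perpendicular_extrusion(
    tib_trace: EdgeTrace,
    men_trace: EdgeTrace,
    resample_mm: float = 0.02,
) -> np.ndarray:
    """Brute-force perpendicular extrusion without any circle model.

    For each meniscal edge point: the distance to the nearest point of the
    densely resampled tibial edge polyline, signed positive when the
    meniscal point lies medial to (outside) the tibial edge.  Returns an
    (n, 2) array of (ap_mm, signed_distance_mm).
    """
    tp = tib_trace.points
    seg = np.diff(tp, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.r_[0.0, np.cumsum(seg_len)]
    dense_arc = np.arange(0.0, arc[-1] + resample_mm / 2, resample_mm)
    dense = np.column_stack(
        [np.interp(dense_arc, arc, tp[:, 0]), np.interp(dense_arc, arc, tp[:, 1])]
    )
    tree = cKDTree(dense)
    _d, idx = tree.query(men_trace.points)
    # the dense samples only bracket the search; the exact perpendicular
    # foot is found on the original polyline segments near the bracket
    seg_of = np.clip(np.searchsorted(arc, dense_arc[idx], side="right") - 1, 0, len(seg) - 1)
    dist = np.empty(len(men_trace.points))
    foot = np.empty_like(men_trace.points)
    for k, (p, i) in enumerate(zip(men_trace.points, seg_of)):
        best, qbest = np.inf, tp[i]
        for j in range(max(0, i - 1), min(len(seg), i + 2)):
            a, ab = tp[j], seg[j]
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
            q = a + t * ab
            d = float(np.hypot(*(p - q)))
            if d < best:
                best, qbest = d, q
        dist[k], foot[k] = best, qbest
    origin = tp.mean(axis=0)
    r_men = np.hypot(*(men_trace.points - origin).T)
    r_tib = np.hypot(*(foot - origin).T)
    sign = np.where(r_men >= r_tib, 1.0, -1.0)
    return np.column_stack([men_trace.ap, sign * dist])
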