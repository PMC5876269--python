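"""Synthetic knee phantoms with analytically known meniscal extrusion.

A phantom emulates the geometry that segmentation of an asymptomatic knee
produces: a tibial plateau whose medial edge is built from two circular arcs
(one anterior, one posterior of the dividing coronal plane through the
medial tibial spine), a shaft that fixes the long axis, a spine apex, and a
C-shaped medial meniscus whose outer (meniscosynovial) edge sits at a
prescribed radial offset — the true perpendicular extrusion — outside the
tibial edge.

The extrusion-versus-angle function is a baseline plus a Gaussian bump:
``e(theta) = baseline + A * exp(-((theta - theta_peak)^2) / (2 sigma^2))``.
Real extrusion profiles have no published functional form; the bump gives
two interpretable parameters (peak size and location) for recovery studies,
and at the default widths it keeps the meniscal edge close to circular —
the regime the circle-fitting reference measurement assumes.

Angles are measured about the tibial circle centres: 0 deg points due
medial (+x), positive angles posterior (+y).  Vertices that carry the
measured edges are emitted in columns on coronal planes spaced
``slice_thickness`` apart (the way per-slice segmentation samples a
surface) and stacked at z-levels with the same spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, OutOfRangeError
from .mesh_io import KneeSpecimen, TriangleSurface

_POLE_TOL = 1e-6
_JOIN_TOL = 1e-9


@dataclass(frozen=True)
class Circle:
    """A circle in the axial plane: centre (ap, ml) in mm, radius in mm."""

    ap: float
    ml: float
    r: float


@dataclass(frozen=True)
class ExtrusionModel:
    """Baseline + Gaussian bump extrusion profile, all in mm / degrees."""

    baseline_mm: float = 1.5
    peak_amplitude_mm: float = 4.0
    peak_angle_deg: float = 32.0
    peak_width_deg: float = 40.0

    def __call__(self, theta_deg):
        theta_deg = np.asarray(theta_deg, dtype=float)
        if self.peak_amplitude_mm == 0.0:
            return np.broadcast_to(np.float64(self.baseline_mm), theta_deg.shape).copy()
        z = (theta_deg - self.peak_angle_deg) / self.peak_width_deg
        return self.baseline_mm + self.peak_amplitude_mm * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one phantom knee (canonical right-knee frame).

    The canonical frame has x increasing medially, y antero-posteriorly
    (0 at the most anterior joint-line point) and z proximally; the plateau
    rim sits at z = 0.
    """

    tib_ant_circle: Circle
    tib_post_circle: Circle
    ap_breadth: float
    spine_apex_ap: float
    spine_apex_height: float = 6.0
    extrusion: ExtrusionModel = field(default_factory=ExtrusionModel)
    meniscus_support_deg: tuple[float, float] = (-85.0, 42.0)
    slice_thickness: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    # secondary shape parameters
    meniscus_thickness: float = 4.0
    meniscus_body_width: float = 8.0
    lateral_extra_width: float = 20.0
    rim_depth: float = 6.0
    shaft_length: float = 140.0
    shaft_radius: float = 12.0
    spine_apex_ml: float | None = None

    @classmethod
    def standard(
        cls,
        ap_breadth: float = 52.9,
        spine_apex_ap: float = 29.8,
        r_ant: float = 26.0,
        ml_ant: float = 7.0,
        **overrides,
    ) -> "PhantomSpec":
        """Build a self-consistent spec from a few primary dimensions.

        The anterior circle is placed with its anterior pole at y = 0; the
        posterior radius is solved so the posterior pole lies at
        ``ap_breadth`` with the same ML coordinate as the anterior pole,
        which also makes the two arcs meet continuously at the dividing
        plane.
        """
        yd = spine_apex_ap
        b = ap_breadth - yd
        if b <= 0 or yd <= 0:
            raise ConfigurationError("spine_apex_ap must lie strictly inside (0, ap_breadth)")
        num = 2.0 * r_ant * yd - yd * yd + b * b
        r_post = num / (2.0 * b)
        if r_post <= 0:
            raise ConfigurationError("derived posterior radius is non-positive")
        ant = Circle(ap=r_ant, ml=ml_ant, r=r_ant)
        post = Circle(ap=ap_breadth - r_post, ml=ml_ant, r=r_post)
        return cls(
            tib_ant_circle=ant,
            tib_post_circle=post,
            ap_breadth=ap_breadth,
            spine_apex_ap=spine_apex_ap,
            **overrides,
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        a, p = self.tib_ant_circle, self.tib_post_circle
        if a.r <= 0 or p.r <= 0:
            raise ConfigurationError("circle radii must be positive")
        if self.ap_breadth <= 0:
            raise ConfigurationError("ap_breadth must be positive")
        if not (0.0 <= self.spine_apex_ap <= self.ap_breadth):
            raise ConfigurationError("spine_apex_ap must lie within [0, ap_breadth]")
        if self.slice_thickness <= 0:
            raise ConfigurationError("slice_thickness must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.spine_apex_height <= 0:
            raise ConfigurationError("spine_apex_height must be positive")
        s0, s1 = self.meniscus_support_deg
        if not (-90.0 < s0 < s1 < 90.0):
            raise ConfigurationError(
                "meniscal angular support must be a nonempty medial sector within (-90, 90) deg"
            )
        if self.extrusion.peak_amplitude_mm != 0 and self.extrusion.peak_width_deg <= 0:
            raise ConfigurationError("peak_width_deg must be positive when a peak is present")
        if abs((a.ap - a.r) - 0.0) > _POLE_TOL:
            raise ConfigurationError(
                "anterior circle's anterior pole must sit at y = 0 (the joint-line front)"
            )
        if abs((p.ap + p.r) - self.ap_breadth) > _POLE_TOL:
            raise ConfigurationError(
                "posterior circle's posterior pole must sit at y = ap_breadth"
            )
        yd = self.spine_apex_ap
        if abs(yd - a.ap) >= a.r or abs(yd - p.ap) >= p.r:
            raise ConfigurationError(
                "a tibial circle does not reach the dividing coronal plane; edges cannot join"
            )
        xa = a.ml + np.sqrt(a.r**2 - (yd - a.ap) ** 2)
        xp = p.ml + np.sqrt(p.r**2 - (yd - p.ap) ** 2)
        if abs(xa - xp) > max(_JOIN_TOL, 1e-9 * max(a.r, p.r)):
            raise ConfigurationError(
                f"tibial edges cannot join at the dividing plane: medial gap {xa - xp:.3g} mm"
            )
        emin = float(np.min(self.extrusion(np.linspace(s0, s1, 721))))
        if min(a.r, p.r) + emin <= 0:
            raise ConfigurationError("extrusion function drives the meniscal edge through the centre")


# ---------------------------------------------------------------------------
# exact edge geometry


def _junction(spec: PhantomSpec) -> tuple[float, float, tuple[float, float]]:
    """Junction of the tibial arcs at the dividing plane.

    Returns (theta about anterior centre, theta about posterior centre,
    junction point (ap, ml)).  Both circles pass through the junction, but
    the two angles differ because the centres differ.
    """
    yd = spec.spine_apex_ap
    a, p = spec.tib_ant_circle, spec.tib_post_circle
    xj = a.ml + float(np.sqrt(a.r**2 - (yd - a.ap) ** 2))
    th_a = float(np.degrees(np.arctan2(yd - a.ap, xj - a.ml)))
    th_p = float(np.degrees(np.arctan2(yd - p.ap, xj - p.ml)))
    return th_a, th_p, (yd, xj)


def _edge_point(spec: PhantomSpec, theta_deg: float, offset: bool):
    """Exact point of the tibial (offset=False) or meniscal edge at angle theta.

    Returns (ap, ml, anterior_flag).  The anterior circle owns angles up to
    its junction angle; beyond that the posterior circle takes over.
    """
    e = float(spec.extrusion(theta_deg)) if offset else 0.0
    th = np.deg2rad(theta_deg)
    th_a, _th_p, _pj = _junction(spec)
    if theta_deg <= th_a:
        a = spec.tib_ant_circle
        return a.ap + (a.r + e) * np.sin(th), a.ml + (a.r + e) * np.cos(th), True
    p = spec.tib_post_circle
    return p.ap + (p.r + e) * np.sin(th), p.ml + (p.r + e) * np.cos(th), False


@dataclass(frozen=True)
class _Branch:
    circle: Circle
    lo: float
    hi: float


def _men_branches(spec: PhantomSpec):
    """Branches and bridging chord of the composite meniscal outer edge.

    The edge follows the anterior circle's radial offset up to the tibial
    junction angle and the posterior circle's from its own junction angle.
    Because the junction angles differ per centre, the branch ends sit a
    fraction of a millimetre apart; a straight chord bridges them so the
    edge is a continuous curve (it degenerates to nothing for identical
    circles).
    """
    s0, s1 = spec.meniscus_support_deg
    th_a, th_p, _pj = _junction(spec)
    branches: list[_Branch] = []
    if s0 < min(th_a, s1):
        branches.append(_Branch(spec.tib_ant_circle, s0, min(th_a, s1)))
    if max(th_p, s0) < s1 and th_a < s1:
        branches.append(_Branch(spec.tib_post_circle, max(th_p, s0), s1))
    bridge = None
    if len(branches) == 2:
        pa = _branch_point(spec, branches[0], branches[0].hi)
        pp = _branch_point(spec, branches[1], branches[1].lo)
        if np.hypot(pa[0] - pp[0], pa[1] - pp[1]) > 1e-12:
            bridge = (pa, pp)
    return branches, bridge


def _branch_point(spec: PhantomSpec, branch: _Branch, theta_deg: float):
    e = float(spec.extrusion(theta_deg))
    th = np.deg2rad(theta_deg)
    c = branch.circle
    return (c.ap + (c.r + e) * np.sin(th), c.ml + (c.r + e) * np.cos(th))


def tibia_medial_x(spec: PhantomSpec, y) -> np.ndarray:
    """Most-medial x of the tibial edge at AP position(s) ``y`` (exact)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < -1e-9) | (y > spec.ap_breadth + 1e-9)):
        raise OutOfRangeError("AP position outside the tibial plateau")
    a, p = spec.tib_ant_circle, spec.tib_post_circle
    ant = y <= spec.spine_apex_ap
    out = np.empty_like(y, dtype=float)
    da = np.clip(a.r**2 - (y - a.ap) ** 2, 0.0, None)
    dp = np.clip(p.r**2 - (y - p.ap) ** 2, 0.0, None)
    out[ant] = a.ml + np.sqrt(da[ant])
    out[~ant] = p.ml + np.sqrt(dp[~ant])
    return out


def _branch_dense(spec: PhantomSpec, branch: _Branch, step_deg: float = 0.02):
    n = max(2, int(np.ceil((branch.hi - branch.lo) / step_deg)) + 1)
    th = np.linspace(branch.lo, branch.hi, n)
    e = spec.extrusion(th)
    rad = np.deg2rad(th)
    c = branch.circle
    return th, c.ap + (c.r + e) * np.sin(rad), c.ml + (c.r + e) * np.cos(rad)


def meniscus_medial_x(spec: PhantomSpec, y: float) -> float:
    """Most-medial x of the meniscal outer edge at AP position ``y`` (exact).

    Root-finds each branch's edge equation inside brackets located on a
    dense angular sample, then evaluates the exact offset curve, so the
    result carries no polyline interpolation error; the bridging chord is
    linear and interpolated exactly.
    """
    branches, bridge = _men_branches(spec)
    best = None
    for branch in branches:
        th, ap, _ml = _branch_dense(spec, branch)

        def ap_of(t: float, _b=branch) -> float:
            return _branch_point(spec, _b, t)[0] - y

        f = ap - y
        hits = np.nonzero((f[:-1] == 0.0) | (f[:-1] * f[1:] < 0))[0]
        for i in hits:
            t_star = th[i] if f[i] == 0.0 else brentq(ap_of, th[i], th[i + 1], xtol=1e-13)
            apv, mlv = _branch_point(spec, branch, float(t_star))
            if best is None or mlv > best:
                best = mlv
        for t_end, i_end in ((branch.lo, 0), (branch.hi, len(th) - 1)):
            apv, mlv = _branch_point(spec, branch, t_end)
            if abs(apv - y) < 1e-9 and (best is None or mlv > best):
                best = mlv
    if bridge is not None:
        (ap0, ml0), (ap1, ml1) = bridge
        lo, hi = min(ap0, ap1), max(ap0, ap1)
        if lo - 1e-12 <= y <= hi + 1e-12:
            frac = 0.0 if hi == lo else (y - ap0) / (ap1 - ap0)
            mlv = ml0 + np.clip(frac, 0.0, 1.0) * (ml1 - ml0)
            if best is None or mlv > best:
                best = float(mlv)
    if best is None:
        raise OutOfRangeError(f"AP station {y:.3f} mm outside the meniscal support's AP extent")
    return float(best)


def meniscus_ap_extent(spec: PhantomSpec) -> tuple[float, float]:
    """AP range [min, max] covered by the meniscal outer edge."""
    branches, bridge = _men_branches(spec)
    lo, hi = np.inf, -np.inf
    for branch in branches:
        _th, ap, _ml = _branch_dense(spec, branch)
        lo, hi = min(lo, ap.min()), max(hi, ap.max())
    if bridge is not None:
        for apv, _mlv in bridge:
            lo, hi = min(lo, apv), max(hi, apv)
    return float(lo), float(hi)


def analytic_slice_extrusion(spec: PhantomSpec, ap_station: float) -> float:
    """Closed-form horizontal (mediolateral) tibia-to-meniscus gap at a station.

    This is the quantity a coronal-slice measurement sees: the difference
    between the most medial meniscus and tibia points in the plane
    ``y = ap_station``, computed from the circle equations.  For a uniform
    offset it reduces to ``sqrt(R_m^2 - d^2) - sqrt(R_t^2 - d^2)`` with
    ``d`` the station's offset from the circle centre.
    """
    spec.validate()
    lo, hi = meniscus_ap_extent(spec)
    if not (lo - 1e-9 <= ap_station <= hi + 1e-9):
        raise OutOfRangeError(
            f"station {ap_station:.3f} mm outside meniscal AP extent [{lo:.3f}, {hi:.3f}]"
        )
    if not (0.0 <= ap_station <= spec.ap_breadth):
        raise OutOfRangeError("station outside the tibial plateau")
    xt = float(tibia_medial_x(spec, ap_station))
    xm = meniscus_medial_x(spec, ap_station)
    return xm - xt


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Closed-form reference values for one phantom."""

    profile_angle_deg: np.ndarray
    profile_extrusion_mm: np.ndarray
    profile_ap_mm: np.ndarray
    true_max_extrusion: float
    true_max_angle_deg: float
    true_max_ap_location: float
    slice_stations_mm: np.ndarray
    slice_extrusion_mm: np.ndarray

    @property
    def extrusion_profile(self) -> dict[float, float]:
        return dict(zip(self.profile_angle_deg.tolist(), self.profile_extrusion_mm.tolist()))

    @property
    def true_slice_extrusion(self) -> dict[float, float]:
        return dict(zip(self.slice_stations_mm.tolist(), self.slice_extrusion_mm.tolist()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "profile": [
                    {"angle_deg": float(a), "extrusion_mm": float(e), "ap_mm": float(y)}
                    for a, e, y in zip(
                        self.profile_angle_deg, self.profile_extrusion_mm, self.profile_ap_mm
                    )
                ],
                "true_max_extrusion_mm": self.true_max_extrusion,
                "true_max_angle_deg": self.true_max_angle_deg,
                "true_max_ap_location_mm": self.true_max_ap_location,
                "slice_extrusion": [
                    {"ap_station_mm": float(s), "extrusion_mm": float(e)}
                    for s, e in zip(self.slice_stations_mm, self.slice_extrusion_mm)
                ],
            },
            indent=1,
        )


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    s0, s1 = spec.meniscus_support_deg
    angles = np.arange(np.ceil(s0), s1 + 1e-9, 1.0)
    angles = np.unique(np.concatenate(([s0], angles, [s1])))
    extr = spec.extrusion(angles)
    ap = np.array([_edge_point(spec, float(t), offset=True)[0] for t in angles])

    # continuous maximiser: the bump peak if inside the support, else an endpoint
    model = spec.extrusion
    cands = [s0, s1]
    if model.peak_amplitude_mm > 0 and s0 <= model.peak_angle_deg <= s1:
        cands.append(model.peak_angle_deg)
    vals = model(np.asarray(cands))
    i = int(np.argmax(vals))
    t_max = float(cands[i])
    true_max = float(vals[i])
    ap_max = float(_edge_point(spec, t_max, offset=True)[0])

    lo, hi = meniscus_ap_extent(spec)
    st_lo = int(np.ceil(max(0.0, lo) - 1e-9))
    st_hi = int(np.floor(min(spec.ap_breadth, hi) + 1e-9))
    stations = np.arange(st_lo, st_hi + 1, dtype=float)
    slice_mm = np.array([analytic_slice_extrusion(spec, s) for s in stations])
    return GroundTruth(
        profile_angle_deg=angles,
        profile_extrusion_mm=np.asarray(extr, dtype=float),
        profile_ap_mm=ap,
        true_max_extrusion=true_max,
        true_max_angle_deg=t_max,
        true_max_ap_location=ap_max,
        slice_stations_mm=stations,
        slice_extrusion_mm=slice_mm,
    )


# ---------------------------------------------------------------------------
# meshing


class _MeshBuilder:
    def __init__(self) -> None:
        self.vertices: list[np.ndarray] = []
        self.faces: list[np.ndarray] = []
        self._n = 0

    def add_vertices(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        idx = np.arange(self._n, self._n + len(pts))
        self.vertices.append(pts)
        self._n += len(pts)
        return idx

    def add_strip(self, col_a: np.ndarray, col_b: np.ndarray) -> None:
        """Triangulate the quad strip between two equal-length index columns."""
        for j in range(len(col_a) - 1):
            self.faces.append(np.array([col_a[j], col_b[j], col_b[j + 1]]))
            self.faces.append(np.array([col_a[j], col_b[j + 1], col_a[j + 1]]))

    def add_quad(self, i0: int, i1: int, i2: int, i3: int) -> None:
        self.faces.append(np.array([i0, i1, i2]))
        self.faces.append(np.array([i0, i2, i3]))

    def build(self, label: str) -> TriangleSurface:
        verts = np.vstack(self.vertices)
        faces = np.vstack(self.faces) if self.faces else np.empty((0, 3), dtype=np.int64)
        return TriangleSurface(verts, faces, label)


def _pole_ml(spec: PhantomSpec, y: np.ndarray) -> np.ndarray:
    """ML coordinate of the pole chord (linear blend of the two pole MLs)."""
    a, p = spec.tib_ant_circle, spec.tib_post_circle
    t = np.asarray(y, dtype=float) / spec.ap_breadth
    return (1 - t) * a.ml + t * p.ml


def _lateral_x(spec: PhantomSpec, y: np.ndarray) -> np.ndarray:
    """Lateral plateau boundary: mirrored medial arcs, widened by a constant.

    Mirroring the medial boundary about the pole chord and shifting it a
    constant ``lateral_extra_width`` laterally gives the plateau its
    realistic mediolateral dominance while keeping the band's in-plane
    vertex covariance zero in the construction frame — which is what lets
    the principal-axes frame recovery reproduce the canonical axes.
    """
    return 2.0 * _pole_ml(spec, y) - tibia_medial_x(spec, y) - spec.lateral_extra_width


def _tibia_columns_y(spec: PhantomSpec) -> np.ndarray:
    t = spec.slice_thickness
    ys = np.arange(0.0, spec.ap_breadth + 1e-9, t)
    # include the exact posterior pole so the plateau's AP extremes are meshed
    if spec.ap_breadth - ys[-1] > 1e-9:
        ys = np.append(ys, spec.ap_breadth)
    return ys


def _build_tibia(spec: PhantomSpec) -> tuple[TriangleSurface, float]:
    b = _MeshBuilder()
    ys = _tibia_columns_y(spec)
    x_med = tibia_medial_x(spec, ys)
    x_lat = _lateral_x(spec, ys)

    # medial and (mirrored) lateral rim walls: columns from z = 0 down to
    # -rim_depth.  The lateral wall mirrors the medial one so the plateau
    # band's in-plane covariance stays zero in the construction frame.
    zs = -np.arange(0.0, spec.rim_depth + 1e-9, spec.slice_thickness)
    if len(zs) < 2 or zs[-1] > -spec.rim_depth + 1e-9:
        zs = np.append(zs, -spec.rim_depth)
    for xs_wall in (x_med, x_lat):
        prev = None
        for y, x in zip(ys, xs_wall):
            col = b.add_vertices(
                np.column_stack([np.full_like(zs, x), np.full_like(zs, y), zs])
            )
            if prev is not None:
                b.add_strip(prev, col)
            prev = col

    # plateau top surface at z = 0 between lateral and medial boundaries
    n_s = 25
    s = np.linspace(0.0, 1.0, n_s)
    prev = None
    for y, xl, xm in zip(ys, x_lat, x_med):
        xcol = xl + s * (xm - xl)
        col = b.add_vertices(np.column_stack([xcol, np.full(n_s, y), np.zeros(n_s)]))
        if prev is not None:
            b.add_strip(prev, col)
        prev = col

    # medial tibial spine: cone with its apex at the exact landmark
    # position, paracentral and slightly medial of the pole chord
    apex_ml = (
        spec.spine_apex_ml
        if spec.spine_apex_ml is not None
        else float(_pole_ml(spec, spec.spine_apex_ap)) + 3.0
    )
    apex = b.add_vertices([[apex_ml, spec.spine_apex_ap, spec.spine_apex_height]])[0]
    phi = np.linspace(0, 2 * np.pi, 25)[:-1]
    ring = b.add_vertices(
        np.column_stack(
            [apex_ml + 4.0 * np.cos(phi), spec.spine_apex_ap + 4.0 * np.sin(phi), np.zeros_like(phi)]
        )
    )
    for j in range(len(ring)):
        b.faces.append(np.array([apex, ring[j], ring[(j + 1) % len(ring)]]))

    # shaft below the rim.  Its axis position is solved so the total
    # area-weighted x-z and y-z covariances vanish: the frame recovery
    # diagonalises exactly this statistic, so the recovered long axis then
    # coincides with the construction z axis (the spine cone would
    # otherwise tilt it by ~0.2 deg).
    def _tri_moments(verts, faces):
        tri = verts[np.asarray(faces)]
        a = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        return a, tri.mean(axis=1)

    plateau = np.vstack(b.vertices)
    a_p, c_p = _tri_moments(plateau, np.vstack(b.faces))

    zr = -np.arange(spec.rim_depth, spec.rim_depth + spec.shaft_length + 1e-9, 10.0)
    phi = np.linspace(0, 2 * np.pi, 25)[:-1]
    n_start = b._n
    cols = []
    for z in zr:
        cols.append(
            np.column_stack(
                [
                    spec.shaft_radius * np.cos(phi),
                    spec.shaft_radius * np.sin(phi),
                    np.full_like(phi, z),
                ]
            )
        )
    shaft0 = np.vstack(cols)
    shaft_faces = []
    npz = len(phi)
    for k in range(len(zr) - 1):
        for j in range(npz):
            i0, i1 = k * npz + j, k * npz + (j + 1) % npz
            i2, i3 = i0 + npz, i1 + npz
            shaft_faces += [[i0, i1, i3], [i0, i3, i2]]
    a_s, c_s = _tri_moments(shaft0, np.asarray(shaft_faces))

    # solve Cov(axis, z) = 0 for the shaft's in-plane offset, per axis
    A = a_p.sum() + a_s.sum()
    Sz = float(a_p @ c_p[:, 2] + a_s @ c_s[:, 2])
    Szs = float(a_s @ c_s[:, 2])
    As = a_s.sum()
    offset = np.zeros(2)
    for axis in (0, 1):
        Sx = float(a_p @ c_p[:, axis] + a_s @ c_s[:, axis])
        Sxz = float(a_p @ (c_p[:, axis] * c_p[:, 2]) + a_s @ (c_s[:, axis] * c_s[:, 2]))
        denom = Szs - As * Sz / A
        offset[axis] = (Sx * Sz / A - Sxz) / denom
    shaft = shaft0 + np.array([offset[0], offset[1], 0.0])
    b.add_vertices(shaft)
    for f in shaft_faces:
        b.faces.append(n_start + np.asarray(f))
    return b.build("tibia"), apex_ml


def _build_meniscus(spec: PhantomSpec) -> TriangleSurface:
    b = _MeshBuilder()
    t = spec.slice_thickness
    lo, hi = meniscus_ap_extent(spec)
    ys = np.arange(np.ceil(lo / t) * t, hi + 1e-9, t)
    zm = np.arange(0.0, spec.meniscus_thickness + 1e-9, min(t, spec.meniscus_thickness))
    if zm[-1] < spec.meniscus_thickness - 1e-9:
        zm = np.append(zm, spec.meniscus_thickness)
    prev_out = prev_in = None
    for y in ys:
        try:
            xo = meniscus_medial_x(spec, float(y))
        except OutOfRangeError:
            prev_out = prev_in = None
            continue
        xi = xo - spec.meniscus_body_width
        out_col = b.add_vertices(np.column_stack([np.full_like(zm, xo), np.full_like(zm, y), zm]))
        in_col = b.add_vertices(np.column_stack([np.full_like(zm, xi), np.full_like(zm, y), zm]))
        if prev_out is not None:
            b.add_strip(prev_out, out_col)
            b.add_strip(prev_in, in_col)
            b.add_quad(prev_in[-1], prev_out[-1], out_col[-1], in_col[-1])  # top
            b.add_quad(prev_out[0], prev_in[0], in_col[0], out_col[0])  # bottom
        prev_out, prev_in = out_col, in_col
    return b.build("meniscus")


def make_phantom(
    spec: PhantomSpec,
) -> tuple[TriangleSurface, TriangleSurface, GroundTruth]:
    """Generate tibia and meniscus surfaces plus closed-form ground truth.

    With ``noise_sd = 0`` the output is a deterministic function of the
    spec; edge-bearing vertices lie exactly on the generating curves.
    Gaussian noise, when requested, is applied to every vertex coordinate
    after exact construction, seeded from ``spec.seed``.
    """
    spec.validate()
    tibia, _apex_ml = _build_tibia(spec)
    meniscus = _build_meniscus(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tibia = TriangleSurface(
            tibia.vertices + rng.normal(0.0, spec.noise_sd, tibia.vertices.shape),
            tibia.faces,
            tibia.label,
        )
        meniscus = TriangleSurface(
            meniscus.vertices + rng.normal(0.0, spec.noise_sd, meniscus.vertices.shape),
            meniscus.faces,
            meniscus.label,
        )
    return tibia, meniscus, _ground_truth(spec)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortDistribution:
    """Uniform parameter ranges for a simulated cohort.

    The anatomical ranges default to the spread reported for asymptomatic
    adult knees (AP breadth 47.2-61.6 mm, spine apex 28-33 mm from the
    joint-line front); extrusion parameters default to posteromedial bumps
    of 2-6 mm on a 1-2.5 mm baseline.
    """

    ap_breadth: tuple[float, float] = (47.2, 61.6)
    spine_apex_ap: tuple[float, float] = (28.0, 33.0)
    #: means and SDs for the two anatomical dimensions; they are drawn as
    #: normals truncated to the ranges above (the reported spread of
    #: asymptomatic knees), so range extremes stay appropriately rare
    ap_breadth_mean_sd: tuple[float, float] = (52.9, 3.6)
    spine_apex_mean_sd: tuple[float, float] = (29.8, 1.7)
    r_ant_frac: tuple[float, float] = (0.55, 0.60)
    baseline_mm: tuple[float, float] = (1.0, 2.5)
    peak_amplitude_mm: tuple[float, float] = (2.0, 6.0)
    peak_angle_deg: tuple[float, float] = (28.0, 36.0)
    peak_width_deg: tuple[float, float] = (35.0, 45.0)
    slice_thickness: float = 0.5
    noise_sd: float = 0.05
    meniscus_support_deg: tuple[float, float] = (-85.0, 42.0)

    def validate(self) -> None:
        for name in (
            "ap_breadth",
            "spine_apex_ap",
            "r_ant_frac",
            "baseline_mm",
            "peak_amplitude_mm",
            "peak_angle_deg",
            "peak_width_deg",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ConfigurationError(f"empty range for {name}: ({lo}, {hi})")


@dataclass
class PhantomSample:
    """One cohort member: its spec, surfaces and ground truth."""

    id: str
    spec: PhantomSpec
    tibia: TriangleSurface
    meniscus: TriangleSurface
    truth: GroundTruth

    @property
    def specimen(self) -> KneeSpecimen:
        return KneeSpecimen(id=self.id, side="right", tibia=self.tibia, meniscus=self.meniscus)


def make_cohort(
    n: int,
    distribution: CohortDistribution | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Draw ``n`` phantoms with parameters from ``distribution``, reproducibly.

    Each phantom records its own derived seed, so individual members can be
    regenerated in isolation.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be at least 1")
    dist = distribution or CohortDistribution()
    dist.validate()
    rng = np.random.default_rng(seed)

    def draw(rg: tuple[float, float]) -> float:
        lo, hi = rg
        return lo if lo == hi else float(rng.uniform(lo, hi))

    def draw_trunc(rg: tuple[float, float], mean_sd: tuple[float, float]) -> float:
        lo, hi = rg
        if lo == hi:
            return lo
        mean, sd = mean_sd
        for _ in range(1000):
            v = float(rng.normal(mean, sd))
            if lo <= v <= hi:
                return v
        return float(np.clip(mean, lo, hi))

    samples = []
    for i in range(n):
        ap = draw_trunc(dist.ap_breadth, dist.ap_breadth_mean_sd)
        apex = min(draw_trunc(dist.spine_apex_ap, dist.spine_apex_mean_sd), 0.75 * ap)
        r_ant = draw(dist.r_ant_frac) * ap
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec.standard(
            ap_breadth=ap,
            spine_apex_ap=apex,
            r_ant=r_ant,
            extrusion=ExtrusionModel(
                baseline_mm=draw(dist.baseline_mm),
                peak_amplitude_mm=draw(dist.peak_amplitude_mm),
                peak_angle_deg=draw(dist.peak_angle_deg),
                peak_width_deg=draw(dist.peak_width_deg),
            ),
            meniscus_support_deg=dist.meniscus_support_deg,
            slice_thickness=dist.slice_thickness,
            noise_sd=dist.noise_sd,
            seed=child_seed,
        )
        tibia, meniscus, truth = make_phantom(spec)
        samples.append(
            PhantomSample(id=f"phantom{i:02d}", spec=spec, tibia=tibia, meniscus=meniscus, truth=truth)
        )
    return samples


def mirrored(surface: TriangleSurface) -> TriangleSurface:
    """Mirror a surface about the x = 0 plane (right <-> left knee)."""
    v = surface.vertices.copy()
    v[:, 0] = -v[:, 0]
    return TriangleSurface(v, surface.faces[:, ::-1].copy(), surface.label)


def uniform_offset_spec(
    radius: float = 25.0,
    baseline: float = 3.0,
    ap_breadth: float | None = None,
    **overrides,
) -> PhantomSpec:
    """Spec with identical anterior/posterior circles and a constant offset.

    The meniscal edge is then a concentric circle of radius
    ``radius + baseline`` — the fully circular case with uniform true
    perpendicular extrusion, used widely as an exactness fixture.
    """
    ap = 2.0 * radius if ap_breadth is None else ap_breadth
    if abs(ap - 2.0 * radius) > 1e-9:
        raise ConfigurationError("uniform-offset spec needs ap_breadth = 2 * radius")
    extr = ExtrusionModel(baseline_mm=baseline, peak_amplitude_mm=0.0)
    spine = overrides.pop("spine_apex_ap", radius * 1.1)
    return PhantomSpec.standard(
        ap_breadth=ap, spine_apex_ap=spine, r_ant=radius, extrusion=extr, **overrides
    )
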