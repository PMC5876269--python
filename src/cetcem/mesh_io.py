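"""Triangulated surface I/O and validation.

Surfaces are exchanged as STL (ASCII or binary), the format segmentation
packages export.  STL stores one vertex triple per facet with no
connectivity, so reading welds duplicate vertices; coordinates are assumed
to be millimetres (STL itself carries no units — a scale factor is available
for data exported in other units).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshValidationError, STLParseError

#: Vertex welding tolerance in mm.  STL repeats vertices per facet; edge
#: extraction downstream needs unique points.
WELD_TOL_MM = 1e-6


@dataclass
class TriangleSurface:
    """Raw 3D geometry of one segmented structure, in millimetres.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    label : ``"tibia"``, ``"meniscus"`` or ``None`` until assigned
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def validate(self) -> None:
        """Raise :class:`MeshValidationError` on any invariant violation."""
        if self.n_vertices < 3:
            raise MeshValidationError(
                f"surface has {self.n_vertices} vertices; at least 3 required"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("surface contains non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= self.n_vertices
        ):
            raise MeshValidationError("face indices out of range")

    def transformed(self, matrix: np.ndarray, offset: np.ndarray) -> "TriangleSurface":
        """Return a copy with vertices mapped through ``matrix @ v + offset``."""
        return TriangleSurface(
            self.vertices @ np.asarray(matrix).T + np.asarray(offset),
            self.faces.copy(),
            self.label,
        )


@dataclass
class KneeSpecimen:
    """One knee: a tibia and its medial meniscus plus the declared side."""

    id: str
    side: str  # "left" | "right"
    tibia: TriangleSurface
    meniscus: TriangleSurface

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise MeshValidationError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class ValidationReport:
    """Report-only list of specimen problems (empty means clean)."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL_MM):
    """Merge vertices closer than ``tol`` (grid snap) and drop degenerate faces."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    verts = vertices[np.sort(first)]
    # remap unique rows to position of their first occurrence, keeping input order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return verts, new_faces[keep]


def _check_binary_length(path: Path, raw: bytes) -> None:
    if len(raw) < 84:
        raise STLParseError(
            f"{path}: binary STL truncated at byte {len(raw)} (header needs 84 bytes)"
        )
    (n_facets,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * n_facets
    if len(raw) != expected:
        raise STLParseError(
            f"{path}: binary STL declares {n_facets} facets "
            f"({expected} bytes) but file has {len(raw)} bytes"
        )


def _looks_ascii(raw: bytes) -> bool:
    head = raw[:512].lstrip()
    return head.startswith(b"solid") and b"facet" in raw[:4096]


def read_stl(path: str | Path, units_scale: float = 1.0) -> TriangleSurface:
    """Read an ASCII or binary STL file into a welded :class:`TriangleSurface`.

    ``units_scale`` multiplies all coordinates (use e.g. ``1000`` for files
    exported in metres).  The label is left unset.
    """
    path = Path(path)
    if not path.is_file():
        raise STLParseError(f"{path}: no such file")
    raw = path.read_bytes()
    if not raw:
        raise STLParseError(f"{path}: empty file")
    if not _looks_ascii(raw):
        _check_binary_length(path, raw)
    try:
        mesh = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise STLParseError(f"{path}: unparseable STL ({exc})") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path}: STL contains no facets")
        mesh = geoms[0]
    vertices = np.asarray(mesh.vertices, dtype=float) * units_scale
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(faces) == 0:
        raise MeshValidationError(f"{path}: STL contains no facets")
    if not np.all(np.isfinite(vertices)):
        raise STLParseError(f"{path}: non-finite coordinates in STL")
    verts, faces = _weld(vertices, faces)
    surface = TriangleSurface(verts, faces)
    surface.validate()
    return surface


def write_stl(surface: TriangleSurface, path: str | Path, encoding: str = "binary") -> None:
    """Write a surface as STL; ``encoding`` is ``"binary"`` or ``"ascii"``.

    Refuses to serialise invalid geometry (NaN coordinates, bad indices) so
    that every written file is re-readable by :func:`read_stl`.
    """
    surface.validate()
    if encoding not in ("binary", "ascii"):
        raise ValueError(f"encoding must be 'binary' or 'ascii', got {encoding!r}")
    mesh = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces, process=False)
    file_type = "stl" if encoding == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(mesh, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def validate_specimen(specimen: KneeSpecimen) -> ValidationReport:
    """Report (never raise) basic plausibility problems with a specimen."""
    report = ValidationReport()
    for name, surface in (("tibia", specimen.tibia), ("meniscus", specimen.meniscus)):
        if surface.n_vertices < 3:
            report.violations.append(f"{name}: fewer than 3 vertices")
            continue
        if not np.all(np.isfinite(surface.vertices)):
            report.violations.append(f"{name}: non-finite coordinates")
        if len(surface.faces) and (
            surface.faces.min() < 0 or surface.faces.max() >= surface.n_vertices
        ):
            report.violations.append(f"{name}: face indices out of range")
    if report.ok:
        tz = specimen.tibia.vertices[:, 2]
        mz = specimen.meniscus.vertices[:, 2]
        if mz.min() > tz.max() or mz.max() < tz.min():
            report.violations.append(
                "meniscus bounding box does not overlap tibia's in z"
            )
    return report
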