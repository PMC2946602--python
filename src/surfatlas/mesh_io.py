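"""Triangulated-surface container, ascii mesh I/O, and per-face geometry.

A surface is a :class:`TriMesh`: an ``(L, 3)`` float array of vertices and an
``(M, 3)`` int array of oriented triangle faces.  Orientation matters: the
currents metric compares surfaces through their area-weighted normals, so a
flipped face is a different current, not a cosmetic difference.

Supported file dialects are ascii OFF, ascii PLY, and legacy ascii VTK
polydata.  Parsing is strict: non-triangular faces, out-of-range indices and
zero-area faces are errors that name the offending face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "FaceGeometry",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "face_geometry",
]


class MeshFormatError(ValueError):
    """Raised for unparseable files or invalid mesh structure."""


@dataclass(frozen=True)
class TriMesh:
    """Oriented triangulated surface.

    Parameters
    ----------
    vertices : (L, 3) float array
        Vertex coordinates; length units are arbitrary but must be consistent
        across all meshes entering one estimation problem.
    faces : (M, 3) int array
        Ordered vertex-index triples.  The order encodes orientation.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (L, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError(f"faces must be (M, 3), got {f.shape}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        validate_mesh(self)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def diameter(self) -> float:
        """Bounding-box diagonal; the natural length scale of the surface."""
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same topology, new vertex positions (used by geodesic flows)."""
        return TriMesh(np.asarray(vertices, dtype=float), self.faces.copy())

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        edges = _undirected_edges(self.faces)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


@dataclass(frozen=True)
class FaceGeometry:
    """Per-face centers ``c_f`` and area-weighted normals ``N_f``.

    ``c_f`` is the arithmetic mean of the face's three vertices;
    ``N_f = ½ (x2−x1) × (x3−x1)`` has magnitude equal to the face area.
    """

    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _undirected_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def validate_mesh(mesh: TriMesh, *, check_orientation: bool = True) -> None:
    """Check index bounds, face non-degeneracy and (for closed meshes)
    consistent orientation.

    Raises :class:`MeshFormatError` with the first offending face id.  An
    inconsistently oriented *open* mesh only warns: the currents metric does
    not require closedness, but mixed orientation on a closed surface almost
    always indicates a broken file.
    """
    L = mesh.vertices.shape[0]
    f = mesh.faces
    if f.size == 0:
        return
    bad = np.flatnonzero((f < 0).any(axis=1) | (f >= L).any(axis=1))
    if bad.size:
        raise MeshFormatError(
            f"face {bad[0]} has vertex index out of range [0, {L}): {f[bad[0]].tolist()}"
        )
    rep = np.flatnonzero(
        (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    )
    if rep.size:
        raise MeshFormatError(f"face {rep[0]} repeats a vertex index: {f[rep[0]].tolist()}")
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshFormatError("non-finite vertex coordinates")
    geom = face_geometry(mesh, _validate=False)
    zero = np.flatnonzero(geom.areas <= 0.0)
    if zero.size:
        raise MeshFormatError(f"face {zero[0]} has zero area")
    if check_orientation:
        edges = _directed_edges(f)
        und = np.sort(edges, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshFormatError("an edge is shared by more than two faces")
        closed = bool(np.all(counts == 2))
        # consistent orientation <=> no directed edge occurs twice
        _, dcounts = np.unique(edges, axis=0, return_counts=True)
        consistent = bool(np.all(dcounts == 1))
        if not consistent:
            if closed:
                raise MeshFormatError(
                    "inconsistent orientation: a directed edge appears in two faces"
                )
            warnings.warn("open mesh with inconsistent face orientation", stacklevel=3)


def face_geometry(mesh: TriMesh, *, _validate: bool = True) -> FaceGeometry:
    """Face centers and area-weighted normals of ``mesh``.

    For a closed, consistently outward-oriented mesh the normals sum to zero
    (divergence theorem applied to constant fields).
    """
    v, f = mesh.vertices, mesh.faces
    p1, p2, p3 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    centers = (p1 + p2 + p3) / 3.0
    normals = 0.5 * np.cross(p2 - p1, p3 - p1)
    areas = np.linalg.norm(normals, axis=1)
    return FaceGeometry(centers=centers, normals=normals, areas=areas)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("off", "ply", "vtk")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    head = path.read_text(errors="replace")[:256].lstrip()
    if head.startswith("OFF"):
        return "off"
    if head.startswith("ply"):
        return "ply"
    if head.startswith("# vtk"):
        return "vtk"
    raise MeshFormatError(f"cannot determine mesh format of {path}")


def read_mesh(path: str | Path, format: str = "auto") -> TriMesh:
    """Read a triangulated surface from an ascii OFF / PLY / VTK file.

    Vertex order is preserved exactly as stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unknown format {format!r}")
    text = path.read_text()
    if fmt == "off":
        v, f = _parse_off(text)
    elif fmt == "ply":
        v, f = _parse_ply(text)
    else:
        v, f = _parse_vtk(text)
    return TriMesh(v, f)


def write_mesh(mesh: TriMesh, path: str | Path, format: str = "auto") -> None:
    """Write ``mesh`` so that :func:`read_mesh` round-trips it losslessly
    (vertices to float repr precision, faces exactly)."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".") if format == "auto" else format.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unknown format {format!r}")
    validate_mesh(mesh)
    if fmt == "off":
        text = _format_off(mesh)
    elif fmt == "ply":
        text = _format_ply(mesh)
    else:
        text = _format_vtk(mesh)
    path.write_text(text)


def _tokens(text: str) -> list[str]:
    out: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        out.extend(line.split())
    return out


def _read_faces(toks: list[str], pos: int, n_faces: int) -> tuple[np.ndarray, int]:
    faces = np.empty((n_faces, 3), dtype=np.int64)
    for i in range(n_faces):
        k = int(toks[pos])
        if k != 3:
            raise MeshFormatError(f"face {i} has {k} vertices; only triangles are supported")
        faces[i] = [int(toks[pos + 1]), int(toks[pos + 2]), int(toks[pos + 3])]
        pos += 4
        # OFF allows trailing per-face color values; PLY/VTK faces are bare.
    return faces, pos


def _parse_off(text: str) -> tuple[np.ndarray, np.ndarray]:
    toks = _tokens(text)
    if not toks or toks[0] != "OFF":
        raise MeshFormatError("missing OFF magic")
    try:
        nv, nf = int(toks[1]), int(toks[2])  # toks[3] is the edge count
        pos = 4
        verts = np.array(toks[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = np.empty((nf, 3), dtype=np.int64)
        for i in range(nf):
            k = int(toks[pos])
            if k != 3:
                raise MeshFormatError(
                    f"face {i} has {k} vertices; only triangles are supported"
                )
            faces[i] = [int(t) for t in toks[pos + 1 : pos + 4]]
            pos += 1 + k
    except (IndexError, ValueError) as exc:
        if isinstance(exc, MeshFormatError):
            raise
        raise MeshFormatError(f"malformed OFF file: {exc}") from exc
    return verts, faces


def _format_off(mesh: TriMesh) -> str:
    lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
    lines += [" ".join(repr(float(c)) for c in row) for row in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    return "\n".join(lines) + "\n"


def _parse_ply(text: str) -> tuple[np.ndarray, np.ndarray]:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError("missing ply magic")
    nv = nf = None
    i = 1
    n_vertex_props = 0
    in_vertex_element = False
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise MeshFormatError("only ascii PLY is supported")
        elif parts[0] == "element":
            in_vertex_element = parts[1] == "vertex"
            if parts[1] == "vertex":
                nv = int(parts[2])
            elif parts[1] == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and in_vertex_element and parts[1] != "list":
            n_vertex_props += 1
        elif parts[0] == "end_header":
            break
    else:
        raise MeshFormatError("PLY header has no end_header")
    if nv is None or nf is None:
        raise MeshFormatError("PLY header missing vertex or face element")
    if n_vertex_props < 3:
        raise MeshFormatError("PLY vertex element must carry x y z")
    try:
        verts = np.empty((nv, 3), dtype=float)
        for j in range(nv):
            vals = lines[i + j].split()
            verts[j] = [float(vals[0]), float(vals[1]), float(vals[2])]
        i += nv
        faces = np.empty((nf, 3), dtype=np.int64)
        for j in range(nf):
            vals = lines[i + j].split()
            if int(vals[0]) != 3:
                raise MeshFormatError(
                    f"face {j} has {vals[0]} vertices; only triangles are supported"
                )
            faces[j] = [int(vals[1]), int(vals[2]), int(vals[3])]
    except (IndexError, ValueError) as exc:
        if isinstance(exc, MeshFormatError):
            raise
        raise MeshFormatError(f"malformed PLY body: {exc}") from exc
    return verts, faces


def _format_ply(mesh: TriMesh) -> str:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [" ".join(repr(float(c)) for c in row) for row in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    return "\n".join(lines) + "\n"


def _parse_vtk(text: str) -> tuple[np.ndarray, np.ndarray]:
    toks = _tokens_vtk(text)
    try:
        ip = toks.index("POINTS")
        nv = int(toks[ip + 1])  # toks[ip+2] is the dtype
        pos = ip + 3
        verts = np.array(toks[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        ic = toks.index("POLYGONS")
        nf = int(toks[ic + 1])
        pos = ic + 3  # skip total size entry
        faces, _ = _read_faces(toks, pos, nf)
    except (IndexError, ValueError) as exc:
        if isinstance(exc, MeshFormatError):
            raise
        raise MeshFormatError(f"malformed VTK file: {exc}") from exc
    return verts, faces


def _tokens_vtk(text: str) -> list[str]:
    lines = text.splitlines()
    if len(lines) < 4 or not lines[0].startswith("# vtk"):
        raise MeshFormatError("missing '# vtk' magic")
    if lines[2].strip().upper() != "ASCII":
        raise MeshFormatError("only ASCII legacy VTK is supported")
    if "POLYDATA" not in lines[3].upper():
        raise MeshFormatError("only POLYDATA VTK datasets are supported")
    out: list[str] = []
    for line in lines[4:]:
        out.extend(line.split())
    return out


def _format_vtk(mesh: TriMesh) -> str:
    lines = [
        "# vtk DataFile Version 3.0",
        "surfatlas mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(repr(float(c)) for c in row) for row in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    return "\n".join(lines) + "\n"
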