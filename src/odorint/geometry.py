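"""3-D molecular geometry: alpha-shape bounding surfaces.

The "alpha-area" descriptor is the surface area (Å²) of the alpha shape of a
molecule's atomic coordinates — a concave bounding surface that tracks
molecular shape more closely than the convex hull.  The alpha parameter
follows the critical-alpha convention: the smallest alpha whose alpha complex
forms a single connected region enclosing every point.  When alpha-shape
construction fails (e.g. a numerically awkward Delaunay triangulation) the
convex hull is used as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .exceptions import DegenerateGeometryError

__all__ = ["MoleculeGeometry", "alpha_shape_area", "compute_alpha_area", "read_xyz", "read_sdf"]


@dataclass(frozen=True)
class MoleculeGeometry:
    """Atom positions (Å) of one molecule."""

    molecule_id: str
    coordinates: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        object.__setattr__(self, "coordinates", coords)


def _check_3d(points: np.ndarray) -> None:
    if len(points) < 4:
        raise DegenerateGeometryError(f"need >= 4 points for a 3-D shape, got {len(points)}")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(points).max())) < 3:
        raise DegenerateGeometryError("points are coplanar or collinear")


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron (inf for degenerate ones)."""
    radii = np.empty(len(tets))
    for i, tet in enumerate(tets):
        p = points[tet]
        a = 2.0 * (p[1:] - p[0])
        b = np.sum(p[1:] ** 2, axis=1) - np.sum(p[0] ** 2)
        try:
            center = np.linalg.solve(a, b)
            radii[i] = np.linalg.norm(p[0] - center)
        except np.linalg.LinAlgError:
            radii[i] = np.inf
    return radii


def _tet_faces(tet: np.ndarray):
    i, j, k, l = sorted(int(v) for v in tet)
    return ((i, j, k), (i, j, l), (i, k, l), (j, k, l))


def _boundary_area(points: np.ndarray, kept: np.ndarray) -> float:
    face_count: dict[tuple[int, int, int], int] = {}
    for tet in kept:
        for f in _tet_faces(tet):
            face_count[f] = face_count.get(f, 0) + 1
    area = 0.0
    for (i, j, k), cnt in face_count.items():
        if cnt == 1:
            area += 0.5 * np.linalg.norm(np.cross(points[j] - points[i], points[k] - points[i]))
    return area


def _covers_and_connected(n_points: int, kept: np.ndarray) -> bool:
    if len(kept) == 0:
        return False
    if len(np.unique(kept)) < n_points:
        return False
    # tets are connected when they share a face
    face_owner: dict[tuple[int, int, int], int] = {}
    parent = list(range(len(kept)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, tet in enumerate(kept):
        for f in _tet_faces(tet):
            if f in face_owner:
                parent[find(face_owner[f])] = find(t)
            else:
                face_owner[f] = t
    return len({find(t) for t in range(len(kept))}) == 1


def alpha_shape_area(points: np.ndarray) -> float:
    """Surface area (Å²) of the critical-alpha shape of a 3-D point set.

    Falls back to the convex hull area when the alpha complex cannot be
    built; raises DegenerateGeometryError for point sets with no volume.
    """
    points = np.asarray(points, dtype=float)
    _check_3d(points)
    try:
        tri = Delaunay(points)
        radii = _circumradii(points, tri.simplices)
        order = np.argsort(radii)
        # smallest alpha (circumradius cutoff) giving one region over all points
        for idx in range(len(order)):
            alpha = radii[order[idx]]
            kept = tri.simplices[radii <= alpha]
            if _covers_and_connected(len(points), kept):
                return _boundary_area(points, kept)
    except QhullError:
        pass
    try:
        return float(ConvexHull(points, qhull_options="QJ").area)
    except QhullError as exc:  # pragma: no cover - guarded by _check_3d
        raise DegenerateGeometryError(str(exc)) from exc


def compute_alpha_area(geom: MoleculeGeometry) -> float:
    """log10 of the alpha-shape surface area of a molecule's atoms."""
    area = alpha_shape_area(geom.coordinates)
    if area <= 0:
        raise DegenerateGeometryError(f"non-positive surface area {area!r}")
    return float(np.log10(area))


# ---------------------------------------------------------------------------
# geometry file readers


def read_xyz(path: str | Path, molecule_id: str | None = None) -> MoleculeGeometry:
    """Read a single-molecule XYZ file (count line, comment line, atom rows)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a valid XYZ file")
    n = int(lines[0].split()[0])
    coords = []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(coords) != n:
        raise ValueError(f"{path}: expected {n} atom rows, found {len(coords)}")
    name = molecule_id or (lines[1].strip() or path.stem)
    return MoleculeGeometry(name, np.array(coords))


def read_sdf(path: str | Path) -> list[MoleculeGeometry]:
    """Read all molecules with 3-D conformers from an SDF (V2000) file."""
    from rdkit import Chem  # deferred: optional dependency

    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)):
        if mol is None or mol.GetNumConformers() == 0:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        out.append(MoleculeGeometry(name, np.array(mol.GetConformer().GetPositions())))
    return out
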