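"""Morphometry of synaptic apposition surfaces (SAS).

A SAS is an open triangulated surface (possibly several disconnected
patches, possibly with interior holes).  The module measures its area
(sum of triangle areas), perimeter (total boundary-edge length over all
loops of all patches), and curvature, defined as ``1 - projected_area /
area``: 0 for a flat sheet, growing towards 1 as the sheet curves.  The
projection plane is the area-weighted orthogonal-regression (best-fit)
plane, and the projected area is the area of the planar union of the
projected triangles, so folded sheets are not double-counted.

Shape classification follows the four-way taxonomy used for synaptic
junctions: two or more disconnected patches -> fragmented; any interior
hole -> perforated; an indented projected outline (solidity below a
declared threshold) -> horseshoe; otherwise macular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon

DEFAULT_INDENTATION_THRESHOLD = 0.85


def load_mesh(path) -> trimesh.Trimesh:
    """Load a PLY/OFF surface as a raw mesh (no processing/merging)."""
    m = trimesh.load(path, force="mesh", process=False)
    return trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)


def _as_arrays(mesh) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(mesh, trimesh.Trimesh):
        v, f = np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int)
    else:
        v, f = (np.asarray(mesh[0], float), np.asarray(mesh[1], int))
    if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
        raise ValueError("mesh must provide (n,3) vertices and (m,3) faces")
    if len(f) == 0:
        raise ValueError("empty mesh")
    if f.min() < 0 or f.max() >= len(v):
        raise ValueError("face indices out of range")
    if _triangle_areas(v, f).min() <= 0.0:
        raise ValueError("mesh contains degenerate (zero-area) triangles")
    return v, f


def _triangle_areas(v: np.ndarray, f: np.ndarray) -> np.ndarray:
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def sas_area(mesh) -> float:
    """Total surface area: sum of triangle areas over all components."""
    v, f = _as_arrays(mesh)
    return float(_triangle_areas(v, f).sum())


def _boundary_edges(f: np.ndarray) -> np.ndarray:
    """Edges belonging to exactly one triangle, as (k, 2) vertex pairs."""
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    if (counts > 2).any():
        raise ValueError("non-manifold mesh: an edge is shared by >2 triangles")
    return uniq[counts == 1]


def sas_perimeter(mesh) -> float:
    """Total boundary length: outer loops plus hole loops, all components."""
    v, f = _as_arrays(mesh)
    be = _boundary_edges(f)
    if len(be) == 0:
        raise ValueError("closed surface has no boundary; not a valid SAS")
    return float(np.linalg.norm(v[be[:, 0]] - v[be[:, 1]], axis=1).sum())


def _vertex_components(v: np.ndarray, f: np.ndarray) -> tuple[int, np.ndarray]:
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(v), len(v)))
    n, labels = connected_components(g, directed=False)
    used = np.unique(f)
    # count only components that actually carry triangles
    comp_ids = np.unique(labels[used])
    remap = {c: i for i, c in enumerate(comp_ids)}
    lab = np.array([remap.get(l, -1) for l in labels])
    return len(comp_ids), lab


def count_components(mesh) -> int:
    v, f = _as_arrays(mesh)
    return _vertex_components(v, f)[0]


def count_holes(mesh) -> int:
    """Interior holes: boundary loops minus one per open component."""
    v, f = _as_arrays(mesh)
    be = _boundary_edges(f)
    if len(be) == 0:
        return 0
    n_comp, labels = _vertex_components(v, f)
    # loops = connected components of the boundary-edge graph
    g = coo_matrix((np.ones(len(be)), (be[:, 0], be[:, 1])), shape=(len(v), len(v)))
    n_all, bl = connected_components(g, directed=False)
    bverts = np.unique(be)
    loops_of_comp = np.zeros(n_comp, int)
    for loop_id in np.unique(bl[bverts]):
        vert = bverts[bl[bverts] == loop_id][0]
        loops_of_comp[labels[vert]] += 1
    return int(np.maximum(loops_of_comp - 1, 0).sum())


def fit_plane(mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Area-weighted orthogonal-regression plane through the surface.

    Returns (origin, basis_u, basis_v); the normal is the eigenvector of
    the smallest covariance eigenvalue.  Rejects (near-)collinear vertex
    sets, for which no projection plane is defined.
    """
    v, f = _as_arrays(mesh)
    w = np.repeat(_triangle_areas(v, f) / 3.0, 3)
    pts = v[f.ravel()]
    origin = (w[:, None] * pts).sum(axis=0) / w.sum()
    d = pts - origin
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise ValueError("collinear vertex set: projection plane undefined")
    return origin, evecs[:, 2], evecs[:, 1]


def projected_outline(mesh) -> shapely.Geometry:
    """Union of the triangles projected onto the best-fit plane (2D)."""
    v, f = _as_arrays(mesh)
    origin, bu, bv = fit_plane(mesh)
    uv = np.column_stack([(v - origin) @ bu, (v - origin) @ bv])
    tris = uv[f]                                   # (m, 3, 2)
    polys = [Polygon(t) for t in tris]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    return shapely.unary_union(polys)


def projected_area(mesh) -> float:
    return float(projected_outline(mesh).area)


def sas_curvature(mesh) -> float:
    """Curvature = 1 - projected_area / area, clamped to [0, 1)."""
    area = sas_area(mesh)
    c = 1.0 - projected_area(mesh) / area
    return float(min(max(c, 0.0), 1.0 - 1e-15))


def classify_shape(mesh, indentation_threshold: float = DEFAULT_INDENTATION_THRESHOLD,
                   outline: shapely.Geometry | None = None) -> str:
    """Four-way shape class from topology and projected-outline solidity.

    Decision cascade: >= 2 components -> fragmented; >= 1 interior hole
    -> perforated; projected-outline solidity (outline area over its
    convex-hull area) below ``indentation_threshold`` -> horseshoe;
    otherwise macular.
    """
    if count_components(mesh) >= 2:
        return "fragmented"
    if count_holes(mesh) >= 1:
        return "perforated"
    out = projected_outline(mesh) if outline is None else outline
    solidity = out.area / out.convex_hull.area
    return "horseshoe" if solidity < indentation_threshold else "macular"


@dataclass(frozen=True)
class MorphometryResult:
    """All SAS measurements for one surface."""

    area_nm2: float
    perimeter_nm: float
    curvature: float
    n_components: int
    n_holes: int
    shape_class: str


def measure(mesh, indentation_threshold: float = DEFAULT_INDENTATION_THRESHOLD
            ) -> MorphometryResult:
    """Compute area, perimeter, curvature, topology and shape class."""
    area = sas_area(mesh)
    perim = sas_perimeter(mesh)
    n_comp = count_components(mesh)
    n_holes = count_holes(mesh)
    outline = projected_outline(mesh)
    curv = float(min(max(1.0 - outline.area / area, 0.0), 1.0 - 1e-15))
    if n_comp >= 2:
        cls = "fragmented"
    elif n_holes >= 1:
        cls = "perforated"
    else:
        solidity = outline.area / outline.convex_hull.area
        cls = "horseshoe" if solidity < indentation_threshold else "macular"
    return MorphometryResult(area_nm2=area, perimeter_nm=perim, curvature=curv,
                             n_components=n_comp, n_holes=n_holes, shape_class=cls)
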