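"""Layered 2D cross-sectional mesh of the vocal fold and glottal-channel extraction.

The fold is meshed as a planar triangulation of a modified-M5 cross section
with four material layers (body, ligament, superficial lamina propria, and a
thin epithelium) in a hemilaryngeal configuration: the fold vibrates against a
rigid contact plane at ``x = contact_plane_x``.  Coordinates are in mm, x
medial-lateral (contact plane at larger x) and z inferior-superior with z = 0
at the glottal outlet.

The shipped geometry spec (``data/m5_geometry.json``) encodes the outline and
layer-interface polygons; :func:`build_m5_mesh` triangulates it at a requested
characteristic element size, and :func:`extract_channel` samples the deformed
air-exposed surface into a :class:`ChannelProfile` for the flow models.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import ChannelExtractionError, GeometryError, ResolutionError

LAYERS = ("body", "ligament", "SLP", "epithelium")

_BOUNDARY_TOL = 1e-6


def load_geometry_spec(path=None) -> dict:
    """Load a geometry spec; default is the shipped modified-M5 section."""
    if path is None:
        ref = resources.files("vocalfem.data").joinpath("m5_geometry.json")
        return json.loads(ref.read_text())
    with open(path) as fh:
        return json.load(fh)


@dataclass
class LayeredMesh:
    """Triangulated 2D cross-section with per-element layer labels.

    ``gamma_f`` is the ordered (inferior -> superior) node-index list of the
    fluid-loaded surface; ``gamma_fixed`` the set of nodes on the lateral and
    inferior attachment.  ``depth`` is the anterior-posterior depth (mm) used
    to convert widths to areas.
    """

    node_coords: np.ndarray          # (N, 2) mm
    triangles: np.ndarray            # (T, 3) int
    layer_of_element: np.ndarray     # (T,) str, one of LAYERS
    gamma_f: np.ndarray              # ordered node indices
    gamma_fixed: np.ndarray          # node indices (unordered)
    contact_plane_x: float
    depth: float = 14.0
    z_in: float = -3.6
    z_out: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.node_coords[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def layer_areas(self) -> dict:
        areas = self.element_areas()
        return {lay: float(areas[self.layer_of_element == lay].sum()) for lay in LAYERS}

    def min_angle_deg(self) -> float:
        p = self.node_coords[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = (a * b).sum(1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


@dataclass
class ChannelProfile:
    """Discretized glottal channel on uniform stations of the superior axis.

    ``gap`` is the (non-negative) distance from the deformed surface to the
    contact plane, ``area`` the actual cross-sectional area gap*depth, and
    ``perimeter`` the wetted perimeter under the 2D high-aspect-ratio duct
    convention S = 2*depth.  ``i_min`` is the minimum-area station (ties broken
    toward the most superior station).
    """

    z: np.ndarray
    gap: np.ndarray
    area: np.ndarray
    perimeter: np.ndarray
    depth: float
    i_min: int
    contact_plane_x: float = field(default=np.nan)

    @property
    def area_min(self) -> float:
        return float(self.area[self.i_min])

    @property
    def n_stations(self) -> int:
        return self.z.shape[0]


def _sample_polyline(vertices: np.ndarray, h: float, closed: bool) -> np.ndarray:
    """Sample a polyline at spacing <= h, keeping the original vertices."""
    pts = []
    n = len(vertices)
    m = n if closed else n - 1
    for i in range(m):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / h)))
        for j in range(k):
            pts.append(a + (b - a) * (j / k))
    if not closed:
        pts.append(vertices[-1])
    return np.asarray(pts)


def _polygon_from(coords, name: str) -> Polygon:
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"degenerate polygon for {name!r}")
    return poly


def build_m5_mesh(resolution: float, geometry_spec: dict | None = None,
                  require_all_layers: bool = True) -> LayeredMesh:
    """Triangulate the layered cross-section at characteristic size ``resolution`` (mm).

    Interior nodes are laid out on a staggered grid, combined with samples of
    the outline and layer interfaces, Delaunay-triangulated and relaxed by a
    few Laplacian smoothing passes.  Each element is assigned the layer of the
    innermost interface polygon containing its centroid.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    spec = geometry_spec if geometry_spec is not None else load_geometry_spec()
    h = float(resolution)

    outline_v = np.asarray(spec["outline"], dtype=float)
    outline = _polygon_from(outline_v, "outline")
    interfaces = {name: _polygon_from(np.asarray(c, float), name)
                  for name, c in spec["interfaces"].items()}
    for name in ("SLP", "ligament", "body"):
        if name not in interfaces:
            raise GeometryError(f"geometry spec missing interface {name!r}")
    # nesting check: body within ligament within SLP within outline
    chain = [outline, interfaces["SLP"], interfaces["ligament"], interfaces["body"]]
    for outer, inner in zip(chain, chain[1:]):
        if not inner.buffer(-1e-9).within(outer):
            raise GeometryError("layer polygons are not nested")

    fixed_pts = [_sample_polyline(outline_v, h, closed=True)]
    tree = cKDTree(fixed_pts[0])
    for name in ("SLP", "ligament", "body"):
        cand = _sample_polyline(np.asarray(interfaces[name].exterior.coords[:-1]), h, closed=True)
        d, _ = tree.query(cand)
        cand = cand[d > 0.45 * h]
        if len(cand):
            fixed_pts.append(cand)
            tree = cKDTree(np.vstack(fixed_pts))
    fixed = np.vstack(fixed_pts)

    # staggered interior grid
    xmin, zmin, xmax, zmax = outline.bounds
    rows = np.arange(zmin + 0.5 * h, zmax, h * np.sqrt(3) / 2)
    grid = []
    prepared = prep(outline)
    for irow, z in enumerate(rows):
        xs = np.arange(xmin + (0.25 + 0.5 * (irow % 2)) * h, xmax, h)
        for x in xs:
            grid.append((x, z))
    grid = np.asarray(grid) if grid else np.empty((0, 2))
    if len(grid):
        inside = np.array([prepared.contains(Point(p)) for p in grid])
        grid = grid[inside]
        d, _ = cKDTree(fixed).query(grid)
        grid = grid[d > 0.55 * h]

    points = np.vstack([fixed, grid])
    n_fixed = len(fixed)

    def triangulate(pts):
        tri = Delaunay(pts)
        return tri.simplices

    simplices = triangulate(points)
    # Laplacian smoothing of the movable interior points
    for _ in range(3):
        neigh_sum = np.zeros_like(points)
        neigh_cnt = np.zeros(len(points))
        for tri in simplices:
            for i in range(3):
                a, b = tri[i], tri[(i + 1) % 3]
                neigh_sum[a] += points[b]
                neigh_cnt[a] += 1
                neigh_sum[b] += points[a]
                neigh_cnt[b] += 1
        movable = np.arange(n_fixed, len(points))
        if movable.size == 0:
            break
        new = neigh_sum[movable] / np.maximum(neigh_cnt[movable], 1)[:, None]
        ok = np.array([prepared.contains(Point(p)) for p in new], dtype=bool)
        points[movable[ok]] = new[ok]
        simplices = triangulate(points)

    # orient CCW, drop degenerate slivers
    p = points[simplices]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    simplices = simplices[np.abs(areas) > 1e-10]

    centroids = points[simplices].mean(axis=1)
    prepared_ifaces = {k: prep(v) for k, v in interfaces.items()}
    layer = np.empty(len(simplices), dtype=object)
    for i, c in enumerate(centroids):
        pt = Point(c)
        if prepared_ifaces["body"].contains(pt):
            layer[i] = "body"
        elif prepared_ifaces["ligament"].contains(pt):
            layer[i] = "ligament"
        elif prepared_ifaces["SLP"].contains(pt):
            layer[i] = "SLP"
        else:
            layer[i] = "epithelium"
    counts = {lay: int((layer == lay).sum()) for lay in LAYERS}
    missing = [lay for lay, c in counts.items() if c == 0]
    if missing and require_all_layers:
        raise ResolutionError(
            f"resolution {h} mm too coarse: layers {missing} have no element")

    # boundary edges = edges used by exactly one triangle
    edges = {}
    for t in simplices:
        for i in range(3):
            e = (int(t[i]), int(t[(i + 1) % 3]))
            key = (min(e), max(e))
            edges[key] = edges.get(key, 0) + 1
    boundary_edges = [e for e, c in edges.items() if c == 1]
    boundary_nodes = sorted({n for e in boundary_edges for n in e})

    is_fixed = np.zeros(len(points), dtype=bool)
    for n in boundary_nodes:
        x, z = points[n]
        if x <= xmin + _BOUNDARY_TOL or z <= zmin + _BOUNDARY_TOL:
            is_fixed[n] = True

    adj: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    # junction corners: fixed boundary nodes with a free boundary neighbour
    junctions = [n for n in boundary_nodes
                 if is_fixed[n] and any(not is_fixed[m] for m in adj[n])]
    if len(junctions) != 2:
        raise GeometryError(
            f"expected 2 junctions between fixed and fluid-loaded boundary, got {len(junctions)}")
    start = min(junctions, key=lambda n: points[n][1])  # inferior corner first
    gamma_f = [start]
    prev = start
    cur = next(m for m in adj[start] if not is_fixed[m])
    while True:
        gamma_f.append(cur)
        if is_fixed[cur]:
            break
        nxt = next(m for m in adj[cur] if m != prev)
        prev, cur = cur, nxt
    gamma_f = np.asarray(gamma_f, dtype=np.int64)
    gamma_fixed = np.asarray([n for n in boundary_nodes if is_fixed[n]], dtype=np.int64)

    plane = float(spec["contact_plane_x"])
    if np.any(points[:, 0] > plane + 1e-9):
        raise GeometryError("initial geometry crosses the contact plane")

    return LayeredMesh(
        node_coords=points,
        triangles=np.asarray(simplices, dtype=np.int64),
        layer_of_element=layer,
        gamma_f=gamma_f,
        gamma_fixed=gamma_fixed,
        contact_plane_x=plane,
        depth=float(spec.get("depth", 14.0)),
        z_in=float(spec.get("channel", {}).get("z_in", -3.6)),
        z_out=float(spec.get("channel", {}).get("z_out", 0.0)),
    )


def surface_segment(mesh: LayeredMesh, z_in: float, z_out: float):
    """Indices into ``gamma_f`` of the contiguous surface slice covering [z_in, z_out].

    The slice is taken in material (reference) coordinates, consistent with the
    small-displacement kinematics of the solid model, and must be strictly
    increasing in z.
    """
    z_ref = mesh.node_coords[mesh.gamma_f, 1]
    inside = np.flatnonzero((z_ref >= z_in - 1e-12) & (z_ref <= z_out + 1e-12))
    if inside.size == 0:
        raise ChannelExtractionError("no surface nodes in the channel z-range")
    i0 = max(int(inside[0]) - 1, 0)
    i1 = min(int(inside[-1]) + 1, z_ref.size - 1)
    seg = np.arange(i0, i1 + 1)
    if np.any(np.diff(z_ref[seg]) <= 0):
        raise ChannelExtractionError(
            "fluid-loaded surface is not single-valued in z over the channel")
    return seg


def extract_channel(mesh: LayeredMesh, state=None, z_in: float | None = None,
                    z_out: float | None = None, n_stations: int = 50) -> ChannelProfile:
    """Sample the deformed surface into gap/area profiles on uniform stations.

    ``state`` provides nodal displacements (``state.theta``, interleaved
    [ux0, uz0, ...]); ``None`` means the undeformed mesh.  The surface x
    position is evaluated at material z coordinates (linearized kinematics);
    gaps are clamped at zero.
    """
    z_in = mesh.z_in if z_in is None else z_in
    z_out = mesh.z_out if z_out is None else z_out
    if not z_in < z_out:
        raise ChannelExtractionError("z_in must be below z_out")
    seg = surface_segment(mesh, z_in, z_out)
    nodes = mesh.gamma_f[seg]
    z_ref = mesh.node_coords[nodes, 1]
    x_def = mesh.node_coords[nodes, 0].copy()
    if state is not None:
        x_def += np.asarray(state.theta)[2 * nodes]
    z_st = np.linspace(z_in, z_out, n_stations)
    x_st = np.interp(z_st, z_ref, x_def)
    gap = np.clip(mesh.contact_plane_x - x_st, 0.0, None)
    area = gap * mesh.depth
    perimeter = np.full(n_stations, 2.0 * mesh.depth)
    # ties toward the most superior station
    i_min = int(n_stations - 1 - np.argmin(gap[::-1]))
    return ChannelProfile(z=z_st, gap=gap, area=area, perimeter=perimeter,
                          depth=mesh.depth, i_min=i_min,
                          contact_plane_x=mesh.contact_plane_x)
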