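"""Confluent multilayered polyhedral tissue geometry.

A stratified epithelium is represented as a space-filling assembly of
polyhedral cells that share vertices and faces (a 3D vertex model).  The
assembly is periodic in all three directions: every face is shared by
exactly two cells, and the cell volumes partition the simulation box
exactly.  Cells carry one of four type labels — basement membrane, basal,
placode or suprabasal — and per-cell mechanical targets (preferred volume
``V0`` and preferred surface area ``S0``).

Positions are stored wrapped into the box.  All geometric quantities are
evaluated after reassembling each face/cell locally through the minimum
image convention, so a cell must be smaller than half the box along every
periodic axis (guaranteed for >=3 cells per axis).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Voronoi

# cell-type codes used throughout (also in VTK export)
MEMBRANE, BASAL, PLACODE, SUPRABASAL = 0, 1, 2, 3
TYPE_NAMES = {MEMBRANE: "membrane", BASAL: "basal", PLACODE: "placode", SUPRABASAL: "suprabasal"}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

SPHERE_SHAPE_INDEX = (36.0 * np.pi) ** (1.0 / 3.0)  # isoperimetric lower bound


class GeometryError(ValueError):
    """Raised for open / inconsistently oriented / degenerate cells."""


class ConfigurationError(ValueError):
    """Raised for invalid tissue configuration requests."""


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic simulation domain (lengths in s.l.u.)."""

    lengths: tuple[float, float, float]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        L = np.asarray(self.lengths, dtype=float)
        if L.shape != (3,) or np.any(L <= 0):
            raise ConfigurationError("box lengths must be three positive reals")
        object.__setattr__(self, "lengths", tuple(float(x) for x in L))

    @property
    def L(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.L))

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L) along periodic axes."""
        x = np.asarray(x, dtype=float).copy()
        L = self.L
        for ax in range(3):
            if self.periodic[ax]:
                x[..., ax] %= L[ax]
        return x

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement for raw difference vectors ``d``."""
        d = np.asarray(d, dtype=float).copy()
        L = self.L
        for ax in range(3):
            if self.periodic[ax]:
                d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
        return d


class TissueMesh:
    """Mutable confluent polyhedral mesh.

    Attributes
    ----------
    box : PeriodicBox
    X : (Nv, 3) float array of wrapped vertex positions.
    faces : list of int arrays; ordered vertex ids of each polygonal face.
        A dead (removed) face is ``None``.
    face_owners : list of (i, j) cell-id pairs, one per face.
    cells : list of face-id lists.
    cell_types, V0, S0 : per-cell arrays.
    cell_ref : (Nc, 3) reference point inside each cell (wrapped) used to
        reassemble the cell across the periodic boundary.
    seed_points : (Nc, 3) generating seed of each cell (wrapped).
    """

    def __init__(self, box, X, faces, face_owners, cells, cell_ref, seed_points=None):
        self.box = box
        self.X = np.asarray(X, dtype=float)
        self.faces: list = [None if f is None else np.asarray(f, dtype=np.int64) for f in faces]
        self.face_owners: list = [None if o is None else tuple(o) for o in face_owners]
        self.cells: list = [list(c) for c in cells]
        n = len(self.cells)
        self.cell_ref = np.array(cell_ref, dtype=float, copy=True)
        self.seed_points = (
            np.array(seed_points, dtype=float, copy=True)
            if seed_points is not None else self.cell_ref.copy()
        )
        self.cell_types = np.full(n, BASAL, dtype=np.int64)
        self.V0 = np.ones(n, dtype=float)
        self.S0 = np.full(n, 5.4, dtype=float)
        self.alive_vertex = np.ones(len(self.X), dtype=bool)
        self._cache = None  # compiled arrays, built lazily

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_faces(self) -> int:
        return sum(1 for f in self.faces if f is not None)

    def copy(self) -> "TissueMesh":
        m = TissueMesh(
            self.box,
            self.X.copy(),
            [None if f is None else f.copy() for f in self.faces],
            list(self.face_owners),
            [list(c) for c in self.cells],
            self.cell_ref.copy(),
            self.seed_points.copy(),
        )
        m.cell_types = self.cell_types.copy()
        m.V0 = self.V0.copy()
        m.S0 = self.S0.copy()
        m.alive_vertex = self.alive_vertex.copy()
        return m

    def invalidate(self):
        self._cache = None

    def compiled(self) -> "MeshArrays":
        if self._cache is None:
            self._cache = MeshArrays.build(self)
        return self._cache

    # -- geometry queries ----------------------------------------------
    def face_coords(self, fid: int) -> np.ndarray:
        """Unwrapped coordinates of one face (relative to its first vertex's image)."""
        vids = self.faces[fid]
        q0 = self.X[vids[0]]
        d = self.box.min_image(self.X[vids] - q0)
        return q0 + d

    def cell_polyhedron(self, cid: int):
        """(points, list-of-oriented-faces) with vertices unwrapped around the cell.

        Faces are oriented outward. Vertex indices are local.
        """
        arr = self.compiled()
        loc = {}
        pts = []
        polys = []
        ref = self.cell_ref[cid]
        for fid, sign in zip(self.cells[cid], arr.cell_face_sign_of(self, cid)):
            Q = self.face_coords(fid)
            c = Q.mean(axis=0)
            shift = self.box.min_image(c - ref) - (c - ref)
            Q = Q + shift
            ids = []
            for vid, q in zip(self.faces[fid], Q):
                if vid not in loc:
                    loc[vid] = len(pts)
                    pts.append(q)
                ids.append(loc[vid])
            polys.append(ids if sign > 0 else ids[::-1])
        return np.asarray(pts), polys

    def edges(self):
        """Map {frozenset{va, vb}: [face ids]} over all live faces."""
        em: dict = {}
        for fid, f in enumerate(self.faces):
            if f is None:
                continue
            n = len(f)
            for k in range(n):
                key = frozenset((int(f[k]), int(f[(k + 1) % n])))
                em.setdefault(key, []).append(fid)
        return em

    def adjacency(self):
        """Symmetric cell-adjacency dict {cid: set(neighbour cids)}."""
        adj: dict = {i: set() for i in range(self.n_cells)}
        for o in self.face_owners:
            if o is None:
                continue
            i, j = o
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def check_closed(self, cid: int) -> bool:
        """A closed cell surface uses every edge exactly twice."""
        cnt: dict = {}
        for fid in self.cells[cid]:
            f = self.faces[fid]
            if f is None or len(f) < 3 or len(set(int(v) for v in f)) != len(f):
                return False
            n = len(f)
            for k in range(n):
                key = frozenset((int(f[k]), int(f[(k + 1) % n])))
                cnt[key] = cnt.get(key, 0) + 1
        return bool(cnt) and all(v == 2 for v in cnt.values())


class MeshArrays:
    """Flattened integer/float views of a TissueMesh for the numba kernels.

    Rebuilt whenever topology changes. Face orientation signs are fixed
    geometrically: a face is outward for a cell when its fan normal points
    away from the cell reference point.
    """

    __slots__ = (
        "fid_list", "face_vert", "face_off", "owners",
        "cell_face", "cell_off", "cell_sign", "vert_cells", "vert_off",
        "fid_index",
    )

    @staticmethod
    def build(mesh: TissueMesh) -> "MeshArrays":
        self = MeshArrays()
        fid_list = [fid for fid, f in enumerate(mesh.faces) if f is not None]
        self.fid_list = np.asarray(fid_list, dtype=np.int64)
        self.fid_index = {fid: k for k, fid in enumerate(fid_list)}
        lens = np.asarray([len(mesh.faces[fid]) for fid in fid_list], dtype=np.int64)
        self.face_vert = (np.concatenate([mesh.faces[fid] for fid in fid_list])
                          if fid_list else np.zeros(0, dtype=np.int64))
        self.face_off = np.concatenate([[0], np.cumsum(lens)])
        self.owners = np.asarray([mesh.face_owners[fid] for fid in fid_list], dtype=np.int64)

        cf, coff = [], [0]
        for fids in mesh.cells:
            cf.extend(self.fid_index[fid] for fid in fids)
            coff.append(len(cf))
        self.cell_face = np.asarray(cf, dtype=np.int64)
        self.cell_off = np.asarray(coff, dtype=np.int64)

        # orientation signs: combinatorial propagation per cell (on a
        # closed oriented surface every edge is traversed once in each
        # direction), with the overall sign fixed by requiring positive
        # volume; robust for non-convex (crumpled) cells where a
        # normal-against-centroid test can misfire
        self.cell_sign = np.ones(len(self.cell_face), dtype=np.int64)
        for cid in range(mesh.n_cells):
            lo, hi = self.cell_off[cid], self.cell_off[cid + 1]
            self.cell_sign[lo:hi] = _propagate_signs(mesh, cid, mesh.cells[cid])
        # fix each cell's overall sign by requiring positive volume
        from ._kernels import mesh_geometry

        _, V, _, _ = mesh_geometry(
            mesh.X, self.face_vert, self.face_off, self.owners,
            self.cell_face, self.cell_off, self.cell_sign,
            mesh.cell_ref, mesh.box.L)
        for cid in np.flatnonzero(V < 0):
            lo, hi = self.cell_off[cid], self.cell_off[cid + 1]
            self.cell_sign[lo:hi] *= -1

        # vertex -> owning cells (via faces), vectorized via unique pairs
        nv = len(mesh.X)
        if len(self.face_vert):
            per_face = np.repeat(self.owners, lens, axis=0)
            pairs = np.concatenate([
                np.stack([self.face_vert, per_face[:, 0]], axis=1),
                np.stack([self.face_vert, per_face[:, 1]], axis=1),
            ])
            pairs = np.unique(pairs, axis=0)
            self.vert_cells = pairs[:, 1].copy()
            self.vert_off = np.searchsorted(pairs[:, 0], np.arange(nv + 1))
        else:
            self.vert_cells = np.zeros(0, dtype=np.int64)
            self.vert_off = np.zeros(nv + 1, dtype=np.int64)
        return self

    def cell_face_sign_of(self, mesh: TissueMesh, cid: int):
        lo, hi = self.cell_off[cid], self.cell_off[cid + 1]
        return self.cell_sign[lo:hi]


def _cell_volume_with_signs(mesh: TissueMesh, cid: int, fids, signs) -> float:
    ref = mesh.cell_ref[cid]
    vol = 0.0
    for fid, s in zip(fids, signs):
        Q = mesh.face_coords(fid)
        c = Q.mean(axis=0)
        d = mesh.box.min_image(c - ref)
        P = (Q - c) + d
        P2 = np.roll(P, -1, axis=0)
        cx = P[:, 1] * P2[:, 2] - P[:, 2] * P2[:, 1]
        cy = P[:, 2] * P2[:, 0] - P[:, 0] * P2[:, 2]
        cz = P[:, 0] * P2[:, 1] - P[:, 1] * P2[:, 0]
        vol += s * float(d[0] * cx.sum() + d[1] * cy.sum() + d[2] * cz.sum()) / 6.0
    return vol


def _propagate_signs(mesh: TissueMesh, cid: int, fids) -> np.ndarray:
    """Relative orientation signs of one cell's faces (global sign free)."""
    edge_users: dict = {}
    for idx, fid in enumerate(fids):
        f = mesh.faces[fid]
        n = len(f)
        for k in range(n):
            u, v = int(f[k]), int(f[(k + 1) % n])
            edge_users.setdefault(frozenset((u, v)), []).append((idx, u < v))
    signs = np.zeros(len(fids), dtype=np.int64)
    signs[0] = 1
    stack = [0]
    adj: dict = {}
    for users in edge_users.values():
        if len(users) != 2:
            raise GeometryError(f"cell {cid} surface is not closed")
        (i, di), (j, dj) = users
        # same traversal direction -> one face must be flipped
        adj.setdefault(i, []).append((j, -1 if di == dj else 1))
        adj.setdefault(j, []).append((i, -1 if di == dj else 1))
    while stack:
        i = stack.pop()
        for j, rel in adj.get(i, ()):
            if signs[j] == 0:
                signs[j] = rel * signs[i]
                stack.append(j)
            elif signs[j] != rel * signs[i]:
                raise GeometryError(f"cell {cid} surface is not orientable")
    if np.any(signs == 0):
        raise GeometryError(f"cell {cid} surface is not connected")
    return signs


def orient_cell_faces(mesh: TissueMesh, cid: int, fids) -> np.ndarray:
    """Outward-orientation sign (+1 keep stored order, -1 reverse) for each
    face of one cell.

    Signs are propagated combinatorially (two faces sharing an edge must
    traverse it in opposite directions), then the global sign is fixed by
    requiring positive cell volume.
    """
    signs = _propagate_signs(mesh, cid, fids)
    if _cell_volume_with_signs(mesh, cid, fids, signs) < 0:
        signs = -signs
    return signs


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def _geometry(mesh: TissueMesh):
    from ._kernels import mesh_geometry

    arr = mesh.compiled()
    area, V, S, cent_off = mesh_geometry(
        mesh.X, arr.face_vert, arr.face_off, arr.owners,
        arr.cell_face, arr.cell_off, arr.cell_sign,
        mesh.cell_ref, mesh.box.L,
    )
    return arr, area, V, S, cent_off


def cell_volume(mesh: TissueMesh, cell_id: int) -> float:
    """Volume of one cell from signed fan tetrahedra about its reference point."""
    _, _, V, _, _ = _geometry(mesh)
    v = float(V[cell_id])
    if v <= 0:
        raise GeometryError(f"cell {cell_id} has non-positive volume {v}")
    if not mesh.check_closed(cell_id):
        raise GeometryError(f"cell {cell_id} surface is not closed")
    return v


def all_cell_volumes(mesh: TissueMesh) -> np.ndarray:
    _, _, V, _, _ = _geometry(mesh)
    return V.copy()


def cell_surface_area(mesh: TissueMesh, cell_id: int) -> float:
    """Total face area of one cell (fan triangulation about face centroids)."""
    if not mesh.check_closed(cell_id):
        raise GeometryError(f"cell {cell_id} surface is not closed")
    _, _, _, S, _ = _geometry(mesh)
    return float(S[cell_id])


def all_cell_areas(mesh: TissueMesh) -> np.ndarray:
    _, _, _, S, _ = _geometry(mesh)
    return S.copy()


def interface_area(mesh: TissueMesh, cell_i: int, cell_j: int) -> float:
    """Shared surface area S_ij between two cells (0 if not adjacent)."""
    arr, area, _, _, _ = _geometry(mesh)
    key = frozenset((cell_i, cell_j))
    tot = 0.0
    for k, o in enumerate(arr.owners):
        if frozenset((int(o[0]), int(o[1]))) == key:
            tot += float(area[k])
    return tot


def shape_index(mesh: TissueMesh, cell_id: int) -> float:
    """Dimensionless cell shape s = S / V^{2/3} (>= (36 pi)^{1/3})."""
    _, _, V, S, _ = _geometry(mesh)
    return float(S[cell_id] / V[cell_id] ** (2.0 / 3.0))


def all_shape_indices(mesh: TissueMesh) -> np.ndarray:
    _, _, V, S, _ = _geometry(mesh)
    return S / V ** (2.0 / 3.0)


def total_volume(mesh: TissueMesh) -> float:
    _, _, V, _, _ = _geometry(mesh)
    return float(V.sum())


# ---------------------------------------------------------------------------
# Voronoi initialization
# ---------------------------------------------------------------------------

def _canonical_vertex_key(p: np.ndarray, box: PeriodicBox, decimals: int = 6):
    w = box.wrap(p)
    # points wrapped to within tolerance of L map to 0
    L = box.L
    r = np.round(w, decimals)
    for ax in range(3):
        if abs(r[ax] - L[ax]) < 10 ** (-decimals):
            r[ax] = 0.0
    return tuple(r)


def initialize_from_voronoi(
    seed_points, box: PeriodicBox, layer_spec=None, rng_seed: int | None = None
) -> TissueMesh:
    """Build a confluent periodic mesh as the Voronoi diagram of ``seed_points``.

    The tessellation is computed on the 3x3x3 periodic tiling of the seeds
    and the faces of the central copies are extracted and deduplicated, so
    every face is registered once with its two owner cells.

    ``layer_spec`` is accepted for interface symmetry with the synthetic
    generators (layer membership is recovered later from seed z).
    """
    seeds = np.asarray(seed_points, dtype=float)
    if seeds.ndim != 2 or seeds.shape[1] != 3:
        raise ConfigurationError("seed_points must be (N, 3)")
    n = len(seeds)
    if n < 2:
        raise ConfigurationError("need at least 2 seeds")
    L = box.L
    if np.any(seeds < -1e-9) or np.any(seeds > L + 1e-9):
        raise ConfigurationError("seeds outside box")
    seeds = box.wrap(seeds)
    # degenerate (coincident) seeds
    from scipy.spatial import cKDTree

    tree = cKDTree(seeds, boxsize=L)
    dmin, _ = tree.query(seeds, k=2)
    if np.min(dmin[:, 1]) < 1e-8 * np.max(L):
        raise GeometryError("coincident seeds produce a degenerate tessellation")

    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
    )
    # place the zero shift first so image_index % n maps back to the cell id
    order = np.argsort([np.abs(s).sum() for s in shifts], kind="stable")
    shifts = shifts[order]
    tiled = (seeds[None, :, :] + (shifts[:, None, :] * L[None, None, :])).reshape(-1, 3)
    vor = Voronoi(tiled)

    vkey_to_id: dict = {}
    positions: list = []
    face_registry: dict = {}
    faces: list = []
    owners: list = []
    cells: list = [[] for _ in range(n)]

    for (pi, pj), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        ci, cj = pi % n, pj % n
        if pi >= n and pj >= n:
            continue  # face of an image cell only
        if -1 in ridge:
            raise GeometryError("unbounded Voronoi ridge touching a central cell")
        if ci == cj:
            raise ConfigurationError(
                "a cell is adjacent to its own periodic image; use >=3 seeds per axis"
            )
        pts = vor.vertices[ridge]
        # order ridge polygon by angle about the seed-separation axis
        axis = tiled[pj] - tiled[pi]
        axis = axis / np.linalg.norm(axis)
        c = pts.mean(axis=0)
        rel = pts - c
        e1 = rel[0] - np.dot(rel[0], axis) * axis
        nrm = np.linalg.norm(e1)
        if nrm < 1e-12:
            e1 = rel[1] - np.dot(rel[1], axis) * axis
            nrm = np.linalg.norm(e1)
        e1 /= nrm
        e2 = np.cross(axis, e1)
        ang = np.arctan2(rel @ e2, rel @ e1)
        order_ = np.argsort(ang)
        pts = pts[order_]

        vids = []
        for p in pts:
            key = _canonical_vertex_key(p, box)
            if key not in vkey_to_id:
                vkey_to_id[key] = len(positions)
                positions.append(box.wrap(p))
            vids.append(vkey_to_id[key])
        if len(set(vids)) < 3:
            continue  # degenerate sliver collapsed by vertex merging
        # drop consecutive duplicates caused by merging
        dedup = [v for k, v in enumerate(vids) if v != vids[(k - 1) % len(vids)]]
        if len(dedup) < 3:
            continue
        fkey = (frozenset((ci, cj)), frozenset(dedup))
        if fkey in face_registry:
            continue
        fid = len(faces)
        face_registry[fkey] = fid
        faces.append(np.asarray(dedup, dtype=np.int64))
        owners.append((int(ci), int(cj)))
        cells[ci].append(fid)
        cells[cj].append(fid)

    mesh = TissueMesh(box, np.asarray(positions), faces, owners, cells, seeds, seeds)
    for cid in range(n):
        if not mesh.check_closed(cid):
            raise GeometryError(f"Voronoi cell {cid} is not closed after deduplication")
    vol = total_volume(mesh)
    if abs(vol - box.volume) / box.volume > 1e-8:
        raise GeometryError(
            f"tessellation not confluent: sum V = {vol}, box = {box.volume}"
        )
    return mesh


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------

def layer_of_seeds(layer_spec, seeds_z: np.ndarray) -> np.ndarray:
    """Layer index of each seed from the cumulative layer thicknesses (bottom-up)."""
    bounds = np.cumsum(np.asarray(layer_spec, dtype=float))
    return np.searchsorted(bounds, seeds_z, side="right").clip(0, len(bounds) - 1)


def assign_cell_types(
    mesh: TissueMesh,
    layer_spec,
    placode_radius: float,
    placode_center_xy,
) -> TissueMesh:
    """Label cells membrane/basal/placode/suprabasal from their seed layer.

    Bottom layer is basement membrane, the next is basal, the rest are
    suprabasal.  Basal cells whose seed xy falls within ``placode_radius``
    of ``placode_center_xy`` (minimum image) become placode cells.
    """
    if len(layer_spec) < 2:
        raise ConfigurationError("need at least membrane + basal layers")
    if placode_radius < 0:
        raise ConfigurationError("placode_radius must be >= 0")
    Lxy = mesh.box.L[:2]
    diag = float(np.hypot(*Lxy))
    if 0.5 * min(Lxy) + 1e-12 < placode_radius < diag:
        # beyond the half box the minimum-image disk wraps onto itself,
        # unless the radius is so large that every basal cell is covered
        raise ConfigurationError("placode_radius spans the periodic wrap ambiguously")
    layer = layer_of_seeds(layer_spec, mesh.seed_points[:, 2])
    types = np.full(mesh.n_cells, SUPRABASAL, dtype=np.int64)
    types[layer == 0] = MEMBRANE
    basal = layer == 1
    types[basal] = BASAL
    d = mesh.seed_points[:, :2] - np.asarray(placode_center_xy, dtype=float)
    for ax in range(2):
        d[:, ax] -= Lxy[ax] * np.round(d[:, ax] / Lxy[ax])
    inside = np.hypot(d[:, 0], d[:, 1]) <= placode_radius
    types[basal & inside] = PLACODE
    if placode_radius >= np.hypot(*Lxy):
        types[basal] = PLACODE
    mesh.cell_types = types
    return mesh
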