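"""Energy, forces, active fluctuations and time stepping for the 3D vertex model.

The tissue energy is

    E = sum_i [ K_V (V_i - V0_i)^2 + K_S (S_i - S0_i)^2 ]
        + sum_{i<j} sigma_{alpha beta} S_ij
        + E_spring,

with per-type volume/surface moduli, a symmetric heterotypic tension
matrix over the four cell types, and an optional spring network decorating
the basement-membrane interface.  Vertices move by overdamped gradient
dynamics dr/dt = -mu dE/dr plus an active term v0 <n_j>, where each cell
carries a director n_j undergoing rotational diffusion on the unit sphere
with diffusivity D_r; a vertex feels the mean director of the non-membrane
cells that own it (basement-membrane "cells" model ECM and carry no
active fluctuations).

Neighbour exchanges are performed by I->H transitions (a short edge is
replaced by a small triangular face shared between the two cells that
previously met only at the edge's endpoints) and their H->I inverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import tissue_geometry as tg
from ._kernels import accumulate_forces, mesh_geometry
from .tissue_geometry import MEMBRANE, TissueMesh


class InstabilityError(RuntimeError):
    pass


@dataclass
class EnergyParams:
    """Per-type mechanical targets and the heterotypic tension matrix.

    Arrays are indexed by the cell-type codes (0 membrane, 1 basal,
    2 placode, 3 suprabasal).  ``KS_cell_scale`` optionally scales the
    surface modulus per cell (used for local basement-membrane softening).
    """

    K_V: np.ndarray = field(default_factory=lambda: np.ones(4))
    K_S: np.ndarray = field(default_factory=lambda: np.ones(4))
    V0: np.ndarray = field(default_factory=lambda: np.ones(4))
    S0: np.ndarray = field(default_factory=lambda: np.full(4, 5.4))
    sigma: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    KS_cell_scale: np.ndarray | None = None
    #: if set, the volume modulus is KV_rel / V0_cell^2 (equal energetic
    #: cost for equal relative compression regardless of cell size)
    KV_rel: float | None = None

    def __post_init__(self):
        self.K_V = np.asarray(self.K_V, dtype=float)
        self.K_S = np.asarray(self.K_S, dtype=float)
        self.V0 = np.asarray(self.V0, dtype=float)
        self.S0 = np.asarray(self.S0, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (4, 4):
            raise tg.ConfigurationError("sigma must be a 4x4 matrix")
        if not np.allclose(self.sigma, self.sigma.T):
            raise tg.ConfigurationError("sigma must be symmetric")
        if np.any(self.K_V <= 0) or np.any(self.K_S <= 0):
            raise tg.ConfigurationError("K_V and K_S must be positive")

    def per_cell(self, mesh: TissueMesh):
        """(K_V, K_S, V0, S0) arrays per cell. Mesh-level V0/S0 win if set."""
        t = mesh.cell_types
        ks = self.K_S[t].copy()
        if self.KS_cell_scale is not None:
            ks = ks * self.KS_cell_scale
        V0 = mesh.V0 if mesh.V0 is not None else self.V0[t]
        S0 = mesh.S0 if mesh.S0 is not None else self.S0[t]
        kv = self.KV_rel / V0 ** 2 if self.KV_rel is not None else self.K_V[t]
        return kv, ks, V0, S0

    def apply_targets(self, mesh: TissueMesh):
        """Set mesh per-cell V0/S0 from the per-type defaults."""
        t = mesh.cell_types
        mesh.V0 = self.V0[t].copy()
        mesh.S0 = self.S0[t].copy()
        return mesh


@dataclass
class IntegratorConfig:
    dt: float = 5e-3
    mu: float = 1.0
    n_steps: int = 1000
    l_T: float = 0.1           # reconnection edge-length threshold (s.l.u.)
    reconnect_every: int = 10
    record_every: int = 100
    pin_membrane_z: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.l_T <= 0:
            raise tg.ConfigurationError("dt and l_T must be positive")


class NoiseState:
    """Per-cell unit directors undergoing rotational diffusion."""

    def __init__(self, n_cells: int, v0: float = 0.05, D_r: float = 1.0, rng=None):
        self.v0 = float(v0)
        self.D_r = float(D_r)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        n = self.rng.standard_normal((n_cells, 3))
        self.nhat = n / np.linalg.norm(n, axis=1, keepdims=True)

    def copy(self):
        out = NoiseState.__new__(NoiseState)
        out.v0, out.D_r = self.v0, self.D_r
        out.rng = self.rng
        out.nhat = self.nhat.copy()
        return out


def update_noise(state: NoiseState, dt: float) -> NoiseState:
    """One Euler-Maruyama rotational-diffusion update (tangential kick,
    then renormalization to the unit sphere)."""
    if state.D_r > 0:
        xi = state.rng.standard_normal(state.nhat.shape)
        kick = np.sqrt(2.0 * state.D_r * dt) * xi
        kick -= np.sum(kick * state.nhat, axis=1, keepdims=True) * state.nhat
        state.nhat = state.nhat + kick
        state.nhat /= np.linalg.norm(state.nhat, axis=1, keepdims=True)
    return state


# ---------------------------------------------------------------------------
# energy / forces
# ---------------------------------------------------------------------------

def _spring_geometry(mesh: TissueMesh, springs):
    e = np.asarray(springs.edges, dtype=np.int64)
    if len(e) == 0:
        return e, np.zeros((0, 3)), np.zeros(0)
    d = mesh.box.min_image(mesh.X[e[:, 1]] - mesh.X[e[:, 0]])
    l = np.linalg.norm(d, axis=1)
    return e, d, l


def spring_energy(mesh: TissueMesh, springs) -> float:
    if springs is None:
        return 0.0
    _, _, l = _spring_geometry(mesh, springs)
    k = np.broadcast_to(np.asarray(springs.k, dtype=float), l.shape)
    return float(0.5 * np.sum(k * (l - springs.l0) ** 2))


def add_spring_forces(mesh: TissueMesh, springs, F: np.ndarray) -> np.ndarray:
    if springs is None:
        return F
    e, d, l = _spring_geometry(mesh, springs)
    if len(e) == 0:
        return F
    k = np.broadcast_to(np.asarray(springs.k, dtype=float), l.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(l[:, None] > 0, d / np.maximum(l, 1e-300)[:, None], 0.0)
    f = (k * (l - springs.l0))[:, None] * u  # pull a toward b when stretched
    np.add.at(F, e[:, 0], f)
    np.add.at(F, e[:, 1], -f)
    return F


def tissue_energy(mesh: TissueMesh, params: EnergyParams, springs=None) -> float:
    """Total vertex-model energy (bulk + interfacial + optional springs)."""
    arr = mesh.compiled()
    area, V, S, _ = mesh_geometry(
        mesh.X, arr.face_vert, arr.face_off, arr.owners,
        arr.cell_face, arr.cell_off, arr.cell_sign, mesh.cell_ref, mesh.box.L,
    )
    kv, ks, V0, S0 = params.per_cell(mesh)
    e = float(np.sum(kv * (V - V0) ** 2) + np.sum(ks * (S - S0) ** 2))
    t = mesh.cell_types
    sig = params.sigma[t[arr.owners[:, 0]], t[arr.owners[:, 1]]]
    e += float(np.sum(sig * area))
    e += spring_energy(mesh, springs)
    return e


def vertex_forces(mesh: TissueMesh, params: EnergyParams, springs=None,
                  ext_field=None) -> np.ndarray:
    """-dE/dr on every vertex (analytic), plus extrinsic body forces."""
    F, _, _, _ = _forces_and_geometry(mesh, params, springs, ext_field)
    return F


def _forces_and_geometry(mesh, params, springs=None, ext_field=None):
    arr = mesh.compiled()
    area, V, S, cent = mesh_geometry(
        mesh.X, arr.face_vert, arr.face_off, arr.owners,
        arr.cell_face, arr.cell_off, arr.cell_sign, mesh.cell_ref, mesh.box.L,
    )
    kv, ks, V0, S0 = params.per_cell(mesh)
    t = mesh.cell_types
    dEdS = 2.0 * ks * (S - S0)
    w_area = dEdS[arr.owners[:, 0]] + dEdS[arr.owners[:, 1]]
    w_area = w_area + params.sigma[t[arr.owners[:, 0]], t[arr.owners[:, 1]]]
    u_vol = 2.0 * kv * (V - V0)
    F = np.zeros_like(mesh.X)
    accumulate_forces(
        mesh.X, arr.face_vert, arr.face_off, w_area,
        arr.cell_face, arr.cell_off, arr.cell_sign, u_vol,
        mesh.cell_ref, mesh.box.L, F,
    )
    add_spring_forces(mesh, springs, F)
    if ext_field is not None:
        F = F + ext_field.vertex_forces(mesh)
    F[~mesh.alive_vertex] = 0.0
    return F, V, S, cent


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def _noise_matrix(mesh: TissueMesh) -> sp.csr_matrix:
    """Vertex-by-cell averaging matrix over non-membrane owner cells."""
    arr = mesh.compiled()
    rows, cols = [], []
    for v in range(len(mesh.X)):
        owners = arr.vert_cells[arr.vert_off[v]:arr.vert_off[v + 1]]
        owners = [c for c in owners if mesh.cell_types[c] != MEMBRANE]
        for c in owners:
            rows.append(v)
            cols.append(c)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    counts = np.bincount(rows, minlength=len(mesh.X)).astype(float)
    w = 1.0 / counts[rows]
    return sp.csr_matrix((w, (rows, cols)), shape=(len(mesh.X), mesh.n_cells))


def pinned_vertices(mesh: TissueMesh) -> np.ndarray:
    """Vertices of membrane--suprabasal wrap faces (the bottom sheet under
    z-periodicity); their z coordinate is held fixed."""
    pin = np.zeros(len(mesh.X), dtype=bool)
    t = mesh.cell_types
    for fid, o in enumerate(mesh.face_owners):
        if o is None or mesh.faces[fid] is None:
            continue
        to = {int(t[o[0]]), int(t[o[1]])}
        if to == {MEMBRANE, tg.SUPRABASAL}:
            pin[mesh.faces[fid]] = True
    return pin


def step(mesh: TissueMesh, params: EnergyParams, state: NoiseState,
         config: IntegratorConfig, springs=None, ext_field=None,
         _cache: dict | None = None) -> TissueMesh:
    """One forward-Euler step: r += dt (mu F + v0 <n>), then noise update
    and wrapping.  Raises InstabilityError on cell inversion."""
    cache = _cache if _cache is not None else {}
    arr = mesh.compiled()
    if cache.get("arr") is not arr or "noise_mat" not in cache:
        cache["noise_mat"] = _noise_matrix(mesh)
        cache["pin"] = pinned_vertices(mesh) if config.pin_membrane_z else None
        cache["arr"] = arr
    F, V, S, cent = _forces_and_geometry(mesh, params, springs, ext_field)
    if np.any(V[np.arange(mesh.n_cells)] <= 0):
        raise InstabilityError(f"cell inversion at dt={config.dt}")
    vel = config.mu * F
    if state is not None and state.v0 != 0.0:
        act = state.v0 * (cache["noise_mat"] @ state.nhat)
        act[~mesh.alive_vertex] = 0.0
        vel = vel + act
    disp = config.dt * vel
    if cache.get("pin") is not None:
        disp[cache["pin"], 2] = 0.0
    mesh.X += disp
    mesh.X = mesh.box.wrap(mesh.X)
    mesh.cell_ref = mesh.box.wrap(mesh.cell_ref + cent)
    if state is not None:
        update_noise(state, config.dt)
    return mesh


# ---------------------------------------------------------------------------
# I-H / H-I reconnections
# ---------------------------------------------------------------------------

def _vector_area(mesh: TissueMesh, vids: list[int]) -> float:
    q0 = mesh.X[vids[0]]
    Q = q0 + mesh.box.min_image(mesh.X[vids] - q0)
    P = Q - Q.mean(axis=0)
    P2 = np.roll(P, -1, axis=0)
    nx = np.sum(P[:, 1] * P2[:, 2] - P[:, 2] * P2[:, 1])
    ny = np.sum(P[:, 2] * P2[:, 0] - P[:, 0] * P2[:, 2])
    nz = np.sum(P[:, 0] * P2[:, 1] - P[:, 1] * P2[:, 0])
    return 0.5 * float(np.sqrt(nx * nx + ny * ny + nz * nz))


def _face_area(mesh: TissueMesh, fid: int) -> float:
    q0 = mesh.X[mesh.faces[fid][0]]
    Q = q0 + mesh.box.min_image(mesh.X[mesh.faces[fid]] - q0)
    P = Q - Q.mean(axis=0)
    P2 = np.roll(P, -1, axis=0)
    cx = P[:, 1] * P2[:, 2] - P[:, 2] * P2[:, 1]
    cy = P[:, 2] * P2[:, 0] - P[:, 0] * P2[:, 2]
    cz = P[:, 0] * P2[:, 1] - P[:, 1] * P2[:, 0]
    return 0.5 * float(np.sum(np.sqrt(cx * cx + cy * cy + cz * cz)))


def _replace_pair_with_one(face: np.ndarray, va: int, vb: int, w: int) -> np.ndarray:
    f = [int(v) for v in face]
    n = len(f)
    ia = f.index(va)
    if f[(ia + 1) % n] == vb:
        ib = (ia + 1) % n
    elif f[(ia - 1) % n] == vb:
        ia, ib = (ia - 1) % n, ia
    else:
        raise tg.GeometryError("edge vertices not consecutive in face")
    out = [w] + [f[(ib + 1 + k) % n] for k in range(n - 2)]
    return np.asarray(out, dtype=np.int64)


def _replace_one_with_two(mesh: TissueMesh, face: np.ndarray, v: int,
                          w1: int, w2: int) -> np.ndarray:
    f = [int(x) for x in face]
    i = f.index(v)
    cand = []
    for pair in ((w1, w2), (w2, w1)):
        g = f[:i] + list(pair) + f[i + 1:]
        cand.append(np.asarray(g, dtype=np.int64))
    # the simple (non-self-intersecting) ordering maximizes the vector area
    areas = [_vector_area(mesh, list(c)) for c in cand]
    return cand[int(np.argmax(areas))]


def _vertex_face_map(mesh: TissueMesh) -> dict:
    vf: dict = {}
    for fid, f in enumerate(mesh.faces):
        if f is None:
            continue
        for v in f:
            vf.setdefault(int(v), []).append(fid)
    return vf


def _vertex_cells(mesh: TissueMesh, v: int, vf: dict) -> set:
    s = set()
    for fid in vf.get(v, ()):
        s.update(int(x) for x in mesh.face_owners[fid])
    return s


def _faces_containing(mesh: TissueMesh, v: int, vf: dict) -> list[int]:
    return vf.get(v, [])


def _attempt_ih(mesh: TissueMesh, va: int, vb: int, l_new: float, vf: dict):
    """Edge (va, vb) -> triangular face. Returns modified copy or None."""
    key = frozenset((va, vb))
    efaces = [fid for fid in _faces_containing(mesh, va, vf)
              if key <= set(int(x) for x in mesh.faces[fid])]
    # faces that contain the edge (both endpoints consecutively)
    ring_faces = []
    for fid in efaces:
        f = [int(x) for x in mesh.faces[fid]]
        n = len(f)
        ia = f.index(va)
        if f[(ia + 1) % n] == vb or f[(ia - 1) % n] == vb:
            ring_faces.append(fid)
    if len(ring_faces) != 3:
        return None
    if any(len(mesh.faces[fid]) < 4 for fid in ring_faces):
        return None  # a triangle would degenerate to a 2-gon
    ring_cells = set()
    for fid in ring_faces:
        ring_cells.update(int(x) for x in mesh.face_owners[fid])
    if len(ring_cells) != 3:
        return None
    ca_set = _vertex_cells(mesh, va, vf) - ring_cells
    cb_set = _vertex_cells(mesh, vb, vf) - ring_cells
    if len(ca_set) != 1 or len(cb_set) != 1:
        return None
    ca, cb = ca_set.pop(), cb_set.pop()
    if ca == cb:
        return None
    # order ring cells c1,c2,c3 so that face k joins (c_k, c_{k+1})
    owner_pairs = [set(int(x) for x in mesh.face_owners[fid]) for fid in ring_faces]
    c1 = next(iter(owner_pairs[0] & owner_pairs[1]))
    c0 = next(iter(owner_pairs[0] - {c1}))
    c2 = next(iter(owner_pairs[1] - {c1}))
    order = [c0, c1, c2]  # face0=(c0,c1), face1=(c1,c2), face2=(c2,c0) check
    if owner_pairs[2] != {c2, c0}:
        return None
    # apex side faces: ga_k between ca and order[k] containing va (same for cb)
    ga, gb = [], []
    for ck in order:
        fa = [fid for fid in _faces_containing(mesh, va, vf)
              if fid not in ring_faces and set(int(x) for x in mesh.face_owners[fid]) == {ca, ck}]
        fb = [fid for fid in _faces_containing(mesh, vb, vf)
              if fid not in ring_faces and set(int(x) for x in mesh.face_owners[fid]) == {cb, ck}]
        if len(fa) != 1 or len(fb) != 1:
            return None
        ga.append(fa[0])
        gb.append(fb[0])

    m = mesh.copy()
    # geometry for new triangle: edge midpoint + offsets toward each ring face
    xa = m.X[va]
    xb = xa + m.box.min_image(m.X[vb] - xa)
    mid = 0.5 * (xa + xb)
    eax = xb - xa
    nrm = np.linalg.norm(eax)
    if nrm == 0:
        return None
    eax = eax / nrm
    wids = []
    for fid in ring_faces:
        q0 = m.X[m.faces[fid][0]]
        Q = q0 + m.box.min_image(m.X[m.faces[fid]] - q0)
        c = mid + m.box.min_image(Q.mean(axis=0) - mid)
        t = (c - mid) - np.dot(c - mid, eax) * eax
        tn = np.linalg.norm(t)
        if tn < 1e-12:
            return None
        w = len(m.X)
        m.X = np.vstack([m.X, m.box.wrap(mid + l_new * t / tn)])
        m.alive_vertex = np.append(m.alive_vertex, True)
        wids.append(w)
    # ring faces: (va,vb) -> w_k
    for fid, w in zip(ring_faces, wids):
        m.faces[fid] = _replace_pair_with_one(m.faces[fid], va, vb, w)
    # apex faces: va -> (w_{k-1}, w_k) for face between ca and c_k
    for k in range(3):
        m.faces[ga[k]] = _replace_one_with_two(m, m.faces[ga[k]], va, wids[k - 1], wids[k])
        m.faces[gb[k]] = _replace_one_with_two(m, m.faces[gb[k]], vb, wids[k - 1], wids[k])
    # new triangular face between ca and cb
    ft = len(m.faces)
    m.faces.append(np.asarray(wids, dtype=np.int64))
    m.face_owners.append((int(ca), int(cb)))
    m.cells[ca].append(ft)
    m.cells[cb].append(ft)
    m.alive_vertex[va] = False
    m.alive_vertex[vb] = False
    m.invalidate()
    affected = {ca, cb} | ring_cells
    return m, affected, ft, wids


def _attempt_hi(mesh: TissueMesh, ft: int, l_new: float, vf: dict):
    """Triangular face -> edge. Returns modified copy or None."""
    tri = [int(v) for v in mesh.faces[ft]]
    if len(tri) != 3:
        return None
    ca, cb = (int(x) for x in mesh.face_owners[ft])
    if ca == cb:
        return None
    ufaces, vfaces, sfaces = [], [], []
    for k in range(3):
        wk, wk1 = tri[k], tri[(k + 1) % 3]
        ucand = [fid for fid in _faces_containing(mesh, wk, vf)
                 if fid != ft and ca in mesh.face_owners[fid]
                 and wk1 in mesh.faces[fid]]
        vcand = [fid for fid in _faces_containing(mesh, wk, vf)
                 if fid != ft and cb in mesh.face_owners[fid]
                 and wk1 in mesh.faces[fid]]
        scand = [fid for fid in _faces_containing(mesh, wk, vf)
                 if fid != ft and ca not in mesh.face_owners[fid]
                 and cb not in mesh.face_owners[fid]]
        if len(ucand) != 1 or len(vcand) != 1 or len(scand) != 1:
            return None
        if len(mesh.faces[ucand[0]]) < 4 or len(mesh.faces[vcand[0]]) < 4:
            return None
        ufaces.append(ucand[0])
        vfaces.append(vcand[0])
        sfaces.append(scand[0])
    if len(set(ufaces)) != 3 or len(set(vfaces)) != 3 or len(set(sfaces)) != 3:
        return None

    m = mesh.copy()
    q0 = m.X[tri[0]]
    Q = q0 + m.box.min_image(m.X[np.asarray(tri)] - q0)
    cen = Q.mean(axis=0)
    nvec = np.cross(Q[1] - Q[0], Q[2] - Q[0])
    nn = np.linalg.norm(nvec)
    if nn < 1e-14:
        return None
    nvec /= nn
    # orient the new edge so va sits on the ca side
    ra = cen + m.box.min_image(m.cell_ref[ca] - cen)
    if np.dot(nvec, ra - cen) < 0:
        nvec = -nvec
    va = len(m.X)
    vb = va + 1
    m.X = np.vstack([m.X, m.box.wrap(cen + 0.5 * l_new * nvec),
                     m.box.wrap(cen - 0.5 * l_new * nvec)])
    m.alive_vertex = np.append(m.alive_vertex, [True, True])
    for k in range(3):
        wk, wk1 = tri[k], tri[(k + 1) % 3]
        m.faces[ufaces[k]] = _replace_pair_with_one(m.faces[ufaces[k]], wk, wk1, va)
        m.faces[vfaces[k]] = _replace_pair_with_one(m.faces[vfaces[k]], wk, wk1, vb)
    for k in range(3):
        m.faces[sfaces[k]] = _replace_one_with_two(m, m.faces[sfaces[k]], tri[k], va, vb)
    m.faces[ft] = None
    m.face_owners[ft] = None
    m.cells[ca].remove(ft)
    m.cells[cb].remove(ft)
    for w in tri:
        m.alive_vertex[w] = False
    m.invalidate()
    ring_cells = set()
    for fid in sfaces:
        ring_cells.update(int(x) for x in m.face_owners[fid])
    return m, {ca, cb} | ring_cells, (va, vb)


def _local_cell_volume(mesh: TissueMesh, cid: int) -> float:
    """Cell volume from its faces alone (combinatorial outward
    orientation), without touching the compiled arrays."""
    fids = mesh.cells[cid]
    signs = tg.orient_cell_faces(mesh, cid, fids)
    return tg._cell_volume_with_signs(mesh, cid, fids, signs)


def _valid_after(mesh_old: TissueMesh, m: TissueMesh, affected) -> bool:
    """A move is kept only if the affected cells stay closed, un-inverted,
    and jointly volume-conserving (confluence is a local property here:
    only the affected cells' shared region was re-triangulated)."""
    v_old, v_new = 0.0, 0.0
    for cid in affected:
        if not m.check_closed(cid):
            return False
        vo = _local_cell_volume(mesh_old, cid)
        vn = _local_cell_volume(m, cid)
        if vn <= 0:
            return False
        # a neighbour exchange is a small local rearrangement; a large
        # per-cell volume jump signals a geometrically pathological move
        if abs(vn - vo) > 0.25 * vo:
            return False
        v_old += vo
        v_new += vn
    return abs(v_new - v_old) <= 1e-8 * mesh_old.box.volume


def apply_reconnections(mesh: TissueMesh, l_T: float, max_moves: int = 15):
    """Greedy I->H on edges shorter than l_T (ascending length), then H->I
    on triangular faces below the matched area threshold.  Invalid moves
    (non-closed cells, inverted volumes) are rejected.  Newly created
    elements are immune for one subsequent sweep.

    Returns (mesh, n_moves); the returned mesh may be a new object.
    """
    immune = getattr(mesh, "immune", {})
    mesh.immune = {k: v - 1 for k, v in immune.items() if v > 1}
    count = 0
    a_T = l_T ** 2 * np.sqrt(3.0) / 4.0
    # candidates rejected at the current topology; persists between sweeps
    # and is discarded whenever a move is accepted (topology changes)
    failed: set = getattr(mesh, "_recon_failed", set())

    changed = True
    while changed and count < max_moves:
        changed = False
        vf = _vertex_face_map(mesh)
        # --- shortest sub-threshold edge first ---
        em = mesh.edges()
        keys = [tuple(sorted(key)) for key, fids in em.items() if len(fids) == 3]
        keys = [k for k in keys
                if mesh.alive_vertex[k[0]] and mesh.alive_vertex[k[1]]
                and k not in mesh.immune and ("e",) + k not in failed]
        cands = []
        if keys:
            ek = np.asarray(keys, dtype=np.int64)
            d = np.linalg.norm(
                mesh.box.min_image(mesh.X[ek[:, 1]] - mesh.X[ek[:, 0]]), axis=1)
            short = d < l_T
            cands = sorted(zip(d[short], ek[short, 0], ek[short, 1]))
        for d, va, vb in cands:
            try:
                res = _attempt_ih(mesh, va, vb, l_T, vf)
            except tg.GeometryError:
                res = None
            if res is not None and _valid_after(mesh, res[0], res[1]):
                m, _, ft, _ = res
                m.immune = dict(mesh.immune)
                m.immune[("face", ft)] = 2
                mesh = m
                count += 1
                changed = True
                failed.clear()
                break
            failed.add(("e",) + tuple(sorted((va, vb))))
        if changed:
            continue
        # --- smallest sub-threshold triangle ---
        tris = []
        for fid, f in enumerate(mesh.faces):
            if f is None or len(f) != 3:
                continue
            if ("face", fid) in mesh.immune or ("f", fid) in failed:
                continue
            a = _face_area(mesh, fid)
            if a < a_T:
                tris.append((a, fid))
        tris.sort()
        for a, fid in tris:
            try:
                res = _attempt_hi(mesh, fid, 1.5 * l_T, vf)
            except tg.GeometryError:
                res = None
            if res is not None and _valid_after(mesh, res[0], res[1]):
                m, _, (va, vb) = res
                m.immune = dict(mesh.immune)
                m.immune[tuple(sorted((va, vb)))] = 2
                mesh = m
                count += 1
                changed = True
                failed.clear()
                break
            failed.add(("f", fid))
    mesh._recon_failed = failed
    return mesh, count


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def simulate(mesh: TissueMesh, params: EnergyParams, state: NoiseState | None,
             config: IntegratorConfig, springs=None, ext_field=None,
             record=None):
    """Run ``config.n_steps`` steps with periodic reconnection sweeps.

    ``record(mesh, step_index)`` is called every ``record_every`` steps.
    Returns (mesh, log) where log is a dict of time series (step, energy,
    mean shape index, reconnection count).
    """
    log = {"step": [], "energy": [], "mean_shape_index": [], "reconnections": []}
    cache: dict = {}
    n_rec = 0
    for it in range(config.n_steps):
        mesh = step(mesh, params, state, config, springs, ext_field, _cache=cache)
        if config.reconnect_every and (it + 1) % config.reconnect_every == 0:
            mesh, moved = apply_reconnections(mesh, config.l_T)
            n_rec += moved
            if moved and springs is not None and hasattr(springs, "rebuild"):
                springs = springs.rebuild(mesh)
        if (it + 1) % config.record_every == 0 or it == config.n_steps - 1:
            log["step"].append(it + 1)
            log["energy"].append(tissue_energy(mesh, params, springs))
            s = tg.all_shape_indices(mesh)
            log["mean_shape_index"].append(float(np.mean(s)))
            log["reconnections"].append(n_rec)
            if record is not None:
                record(mesh, it + 1)
    return mesh, log
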