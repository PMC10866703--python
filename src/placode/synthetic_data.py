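"""Generators of synthetic inputs with known ground truth.

Every generator is pure given (parameters, seed) and returns
``(object, manifest)`` where the manifest records the parameters, the
seed and the analytic expectations the object was built to satisfy, so
downstream tests compare against stored truth instead of re-deriving it.
"""

from __future__ import annotations

import numpy as np

from . import tissue_geometry as tg
from .morphometrics import PointPattern2D, VectorField2D
from .tissue_geometry import PeriodicBox, TissueMesh

#: membrane, basal and two suprabasal layer thicknesses (s.l.u.)
DEFAULT_LAYERS = (0.3, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# tissue
# ---------------------------------------------------------------------------

def _prism_mesh(nx: int, ny: int, layer_spec) -> TissueMesh:
    """Exact rectangular-prism tissue (the jitter = 0 limit)."""
    th = np.asarray(layer_spec, dtype=float)
    nz = len(th)
    zb = np.concatenate([[0.0], np.cumsum(th)])  # layer boundaries
    Lz = zb[-1]
    box = PeriodicBox((float(nx), float(ny), float(Lz)))

    def vid(i, j, k):
        return (k % nz) * nx * ny + (j % ny) * nx + (i % nx)

    X = np.zeros((nx * ny * nz, 3))
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                X[vid(i, j, k)] = (i, j, zb[k])

    def cid(i, j, k):
        return k * nx * ny + j * nx + i

    faces, owners = [], []
    cells = [[] for _ in range(nx * ny * nz)]

    def add_face(vids, ca, cb):
        fid = len(faces)
        faces.append(np.asarray(vids, dtype=np.int64))
        owners.append((ca, cb))
        cells[ca].append(fid)
        cells[cb].append(fid)

    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                c = cid(i, j, k)
                # +x face (shared with (i+1, j, k))
                add_face([vid(i + 1, j, k), vid(i + 1, j + 1, k),
                          vid(i + 1, j + 1, k + 1), vid(i + 1, j, k + 1)],
                         c, cid((i + 1) % nx, j, k))
                # +y face
                add_face([vid(i, j + 1, k), vid(i, j + 1, k + 1),
                          vid(i + 1, j + 1, k + 1), vid(i + 1, j + 1, k)],
                         c, cid(i, (j + 1) % ny, k))
                # +z face
                add_face([vid(i, j, k + 1), vid(i + 1, j, k + 1),
                          vid(i + 1, j + 1, k + 1), vid(i, j + 1, k + 1)],
                         c, cid(i, j, (k + 1) % nz))

    seeds = np.zeros((nx * ny * nz, 3))
    zc = 0.5 * (zb[:-1] + zb[1:])
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                seeds[cid(i, j, k)] = (i + 0.5, j + 0.5, zc[k])
    return TissueMesh(box, X, faces, owners, cells, seeds, seeds)


def make_flat_tissue(nx: int, ny: int, layer_spec=DEFAULT_LAYERS,
                     jitter: float = 0.25, seed: int = 0,
                     membrane_split: int = 2):
    """Flat layered tissue: jittered-lattice seeds -> periodic Voronoi mesh.

    ``jitter`` is the uniform xy seed displacement in units of the lattice
    spacing; jitter = 0 returns exact rectangular prisms (one cell per
    lattice site in every layer).  The bottom (basement-membrane) layer is
    laterally refined by ``membrane_split`` x ``membrane_split`` so the
    membrane is built of small, near-isotropic solid cells rather than
    wide slabs.
    """
    if nx < 3 or ny < 3:
        raise tg.ConfigurationError("need >= 3 cells per periodic axis")
    if len(layer_spec) < 3:
        # one layer is self-adjacent through the z-wrap and two layers sit
        # exactly at the half-box minimum-image ambiguity; both break the
        # periodic reassembly of cells
        raise tg.ConfigurationError("need >= 3 layers")
    ms_eff = 1 if jitter == 0 else max(1, int(membrane_split))
    n_cells = nx * ny * (len(layer_spec) - 1) + nx * ny * ms_eff ** 2
    manifest = {
        "kind": "flat_tissue", "nx": nx, "ny": ny,
        "layer_spec": list(map(float, layer_spec)),
        "jitter": float(jitter), "seed": int(seed),
        "membrane_split": ms_eff,
        "truth": {"n_cells": n_cells,
                  "box_volume": float(nx * ny * float(np.sum(layer_spec)))},
    }
    if jitter == 0:
        return _prism_mesh(nx, ny, layer_spec), manifest
    rng = np.random.default_rng(seed)
    th = np.asarray(layer_spec, dtype=float)
    nz = len(th)
    # tessellate with uniform layer spacing (so every layer is one Voronoi
    # stratum), then squash z piecewise-linearly onto the requested layer
    # thicknesses; non-planar faces introduced by the squash are handled
    # by the fan-triangulation geometry
    ubox = PeriodicBox((float(nx), float(ny), float(nz)))
    seeds = []
    ms = max(1, int(membrane_split))
    for j in range(ny * ms):
        for i in range(nx * ms):
            dx, dy = rng.uniform(-jitter / ms, jitter / ms, 2)
            seeds.append(((i + 0.5) / ms + dx, (j + 0.5) / ms + dy, 0.5))
    for k in range(1, nz):
        for j in range(ny):
            for i in range(nx):
                dx, dy = rng.uniform(-jitter, jitter, 2)
                seeds.append((i + 0.5 + dx, j + 0.5 + dy, k + 0.5))
    seeds = ubox.wrap(np.asarray(seeds))
    mesh = tg.initialize_from_voronoi(seeds, ubox, layer_spec)

    zb = np.concatenate([[0.0], np.cumsum(th)])
    box = PeriodicBox((float(nx), float(ny), float(zb[-1])))

    def squash(z):
        k = np.clip(np.floor(z).astype(int), 0, nz - 1)
        return zb[k] + (z - k) * th[k]

    mesh.X[:, 2] = squash(mesh.X[:, 2])
    mesh.cell_ref[:, 2] = squash(mesh.cell_ref[:, 2])
    mesh.seed_points[:, 2] = squash(mesh.seed_points[:, 2])
    mesh.box = box

    # flatten the basement-membrane interfaces: the bottom layer models a
    # thin ECM sheet, so its two bounding surfaces start flat (the Voronoi
    # strata are rough on the scale of the membrane thickness)
    layer = tg.layer_of_seeds(layer_spec, mesh.seed_points[:, 2])
    n_cells_layer = nx * ny
    for fid, o in enumerate(mesh.face_owners):
        la, lb = sorted((int(layer[o[0]]), int(layer[o[1]])))
        if la == 0 and lb == nz - 1:
            mesh.X[mesh.faces[fid], 2] = 0.0
        elif la == 0 and lb == 1:
            mesh.X[mesh.faces[fid], 2] = zb[1]
    mesh.cell_ref[layer == 0, 2] = 0.5 * zb[1]
    mesh.invalidate()
    V = tg.all_cell_volumes(mesh)
    if np.any(V <= 0) or abs(V.sum() - box.volume) / box.volume > 1e-8:
        raise tg.GeometryError("layer squash produced an invalid mesh; "
                               "reduce jitter or thicken the bottom layer")
    return mesh, manifest


# ---------------------------------------------------------------------------
# curvature clouds
# ---------------------------------------------------------------------------

def make_paraboloid_cloud(R: float, n: int = 200, noise_sd: float = 0.0,
                          seed: int = 0, extent: float | None = None):
    """Points sampled from z = (x^2 + y^2) / (2R) with Gaussian z-noise.

    Ground-truth Gaussian curvature at the apex is 1/R^2 (0 for R = inf,
    a plane)."""
    rng = np.random.default_rng(seed)
    extent = extent if extent is not None else (abs(R) if np.isfinite(R) else 1.0)
    r = extent * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    x, y = r * np.cos(th), r * np.sin(th)
    z = np.zeros(n) if not np.isfinite(R) else (x ** 2 + y ** 2) / (2.0 * R)
    z = z + noise_sd * rng.standard_normal(n)
    pts = np.stack([x, y, z], axis=1)
    K = 0.0 if not np.isfinite(R) else 1.0 / R ** 2
    manifest = {"kind": "paraboloid_cloud", "R": float(R), "n": n,
                "noise_sd": float(noise_sd), "seed": int(seed),
                "truth": {"gaussian_curvature": K,
                          "a": 0.0 if not np.isfinite(R) else 1.0 / (2 * R)}}
    return pts, manifest


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

def make_flow_field(kind: str, n: int = 64, spacing: float = 1.0,
                    k: float = 0.1, u0=(1.0, 0.0), omega: float = 0.1,
                    noise: float = 0.0, seed: int = 0):
    """Gridded 2D velocity field with known divergence.

    kinds: ``uniform`` (div 0), ``radial_sink`` (v = -k (r - c), div -2k),
    ``rotational`` (solid rotation, div 0), ``composite`` (sink +
    rotational; the solenoidal part does not change the divergence).
    """
    rng = np.random.default_rng(seed)
    x = spacing * np.arange(n)
    X, Y = np.meshgrid(x, x)
    c = spacing * (n - 1) / 2.0
    vec = np.zeros((n, n, 2))
    if kind == "uniform":
        vec[..., 0], vec[..., 1] = u0[0], u0[1]
        true_div = 0.0
    elif kind == "radial_sink":
        vec[..., 0] = -k * (X - c)
        vec[..., 1] = -k * (Y - c)
        true_div = -2.0 * k
    elif kind == "rotational":
        vec[..., 0] = -omega * (Y - c)
        vec[..., 1] = omega * (X - c)
        true_div = 0.0
    elif kind == "composite":
        vec[..., 0] = -k * (X - c) - omega * (Y - c)
        vec[..., 1] = -k * (Y - c) + omega * (X - c)
        true_div = -2.0 * k
    else:
        raise ValueError(f"unknown flow kind {kind!r}")
    vec += noise * rng.standard_normal(vec.shape)
    fld = VectorField2D(origin=np.zeros(2), spacing=spacing, vec=vec)
    manifest = {"kind": f"flow_{kind}", "n": n, "spacing": spacing, "k": k,
                "omega": omega, "noise": noise, "seed": seed,
                "truth": {"divergence": true_div}}
    return fld, manifest


# ---------------------------------------------------------------------------
# ablation fields
# ---------------------------------------------------------------------------

def make_ablation_field(geometry: str = "line_cut", A: float = 1.0,
                        lam: float = 8.0, inward_fraction: float = 1.0,
                        n: int = 128, spacing: float = 1.0,
                        cut_halfwidth: int = 3, ring_radius: float | None = None,
                        seed: int = 0):
    """Synthetic post-ablation displacement field with known recoil.

    Outside the cut the tissue recoils away from it with radial magnitude
    A exp(-d / lam); inside it displaces toward the centre of the region
    with magnitude ``inward_fraction`` x A.  ``line_cut`` is a vertical
    strip; ``ring_cut`` is an annulus with a ``placode`` compartment
    inside and a ``fibroblast`` compartment outside.

    Returns (field, cut_mask, compartments, manifest).
    """
    from scipy import ndimage

    cut = np.zeros((n, n), dtype=bool)
    if geometry == "line_cut":
        mid = n // 2
        cut[:, mid - cut_halfwidth: mid + cut_halfwidth + 1] = True
        comp = {"left": np.zeros((n, n), dtype=bool),
                "right": np.zeros((n, n), dtype=bool)}
        comp["left"][:, : mid - cut_halfwidth] = True
        comp["right"][:, mid + cut_halfwidth + 1:] = True
    elif geometry == "ring_cut":
        r0 = ring_radius if ring_radius is not None else n * spacing / 4.0
        yy, xx = np.meshgrid(spacing * np.arange(n), spacing * np.arange(n),
                             indexing="ij")
        c = spacing * (n - 1) / 2.0
        rr = np.hypot(xx - c, yy - c)
        w = cut_halfwidth * spacing
        cut = np.abs(rr - r0) <= w
        comp = {"placode": rr < r0 - w, "fibroblast": rr > r0 + w}
    else:
        raise ValueError(f"unknown ablation geometry {geometry!r}")

    d_out = ndimage.distance_transform_edt(~cut, sampling=spacing)
    d_in = ndimage.distance_transform_edt(cut, sampling=spacing)
    sd = d_out - d_in
    gy, gx = np.gradient(sd, spacing)
    nrm = np.hypot(gx, gy)
    nrm[nrm == 0] = 1.0
    gx, gy = gx / nrm, gy / nrm
    mag = np.where(sd > 0, A * np.exp(-sd / lam),
                   -inward_fraction * A * np.exp(sd / lam))
    vec = np.stack([mag * gx, mag * gy], axis=-1)
    fld = VectorField2D(origin=np.zeros(2), spacing=spacing, vec=vec)
    manifest = {"kind": f"ablation_{geometry}", "A": A, "lam": lam,
                "inward_fraction": inward_fraction, "n": n,
                "spacing": spacing, "seed": seed,
                "truth": {"total": A + inward_fraction * A,
                          "profile": "A*exp(-d/lam) outward for d>0"}}
    return fld, cut, comp, manifest


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

def make_point_pattern(n: int, dispersion: str = "uniform_disk",
                       centre=(0.0, 0.0), r0: float = 20.0, sigma: float = 2.0,
                       R: float = 30.0, n_clusters: int = 3, seed: int = 0):
    """Nuclear point patterns: ``ring(r0, sigma)`` (mean distance -> r0 as
    sigma -> 0), ``uniform_disk(R)`` (expected mean distance 2R/3) or
    ``clustered`` (Gaussian blobs around the centre)."""
    rng = np.random.default_rng(seed)
    c = np.asarray(centre, dtype=float)
    if dispersion == "ring":
        r = rng.normal(r0, sigma, n)
        th = rng.uniform(0, 2 * np.pi, n)
        pts = c + np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        truth = {"mean_distance": float(r0)}
    elif dispersion == "uniform_disk":
        r = R * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = c + np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        truth = {"mean_distance": 2.0 * R / 3.0}
    elif dispersion == "clustered":
        centers = c + rng.uniform(-R / 2, R / 2, (n_clusters, 2))
        which = rng.integers(0, n_clusters, n)
        pts = centers[which] + sigma * rng.standard_normal((n, 2))
        truth = {}
    else:
        raise ValueError(f"unknown dispersion {dispersion!r}")
    pat = PointPattern2D(points=pts, center=c)
    manifest = {"kind": f"points_{dispersion}", "n": n, "r0": r0,
                "sigma": sigma, "R": R, "seed": seed, "truth": truth}
    return pat, manifest
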