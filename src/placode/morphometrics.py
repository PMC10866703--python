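"""Morphometric estimators shared between simulations and imaging-style data.

Implements the measurement side of the study: paraboloid fits of the
basal surface and the Gaussian curvature at its deepest point, placode
cell elongation, basal/apical surface ratio, divergence maps of 2D
velocity fields with circular-ROI averaging and peak-aligned traces,
laser-ablation recoil profiles and directions, and the four spatial
statistics of nuclear (Sox9-positive) point patterns.

Sign conventions: z increases from the basement membrane toward the
suprabasal surface, so an invagination (tissue bending toward the
dermis) is a bowl opening upward; its Gaussian curvature is reported
positive, an evagination negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from . import tissue_geometry as tg
from .tissue_geometry import BASAL, MEMBRANE, PLACODE, SUPRABASAL, TissueMesh


class FitError(RuntimeError):
    pass


class UndefinedRatioError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# paraboloid curvature / elongation
# ---------------------------------------------------------------------------

@dataclass
class ParaboloidFit:
    """z = a x^2 + b y^2 + c xy + d x + e y + f."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    apex: np.ndarray = field(default=None)
    residual_rms: float = 0.0
    points: np.ndarray | None = None

    def evaluate(self, x, y):
        return (self.a * x ** 2 + self.b * y ** 2 + self.c * x * y
                + self.d * x + self.e * y + self.f)


def _apex_of(a, b, c, d, e, f):
    H = np.array([[2 * a, c], [c, 2 * b]])
    try:
        xy = np.linalg.solve(H, -np.array([d, e]))
    except np.linalg.LinAlgError:
        xy = np.zeros(2)
    z = a * xy[0] ** 2 + b * xy[1] ** 2 + c * xy[0] * xy[1] + d * xy[0] + e * xy[1] + f
    return np.array([xy[0], xy[1], z])


def fit_paraboloid(points, mode: str = "full_3d") -> ParaboloidFit:
    """Least-squares quadratic surface through a 3D point set.

    ``full_3d`` fits all six coefficients to (x, y, z) points.
    ``axisymmetric_from_2d`` takes 2D cross-section points (rho, z) — or
    3D points whose y is ignored — fits z = a rho^2 + f, and builds the
    rotationally symmetric paraboloid (b = a, c = d = e = 0).
    """
    pts = np.asarray(points, dtype=float)
    if mode == "axisymmetric_from_2d":
        if pts.shape[1] == 3:
            pts = pts[:, [0, 2]]
        if len(pts) < 3:
            raise FitError("axisymmetric fit needs >=3 points")
        rho, z = pts[:, 0], pts[:, 1]
        A = np.stack([rho ** 2, np.ones_like(rho)], axis=1)
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        a, f0 = coef
        resid = z - A @ coef
        fit = ParaboloidFit(a, a, 0.0, 0.0, 0.0, f0,
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))))
        fit.apex = _apex_of(*[fit.a, fit.b, fit.c, fit.d, fit.e, fit.f])
        fit.points = np.stack([rho, np.zeros_like(rho), z], axis=1)
        return fit
    if mode != "full_3d":
        raise ValueError(f"unknown mode {mode!r}")
    if pts.shape[0] < 6 or pts.shape[1] != 3:
        raise FitError("full 3D fit needs >=6 (x, y, z) points")
    x, y, z = pts.T
    A = np.stack([x ** 2, y ** 2, x * y, x, y, np.ones_like(x)], axis=1)
    if np.linalg.matrix_rank(A) < 6:
        raise FitError("rank-deficient design (degenerate point set)")
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    resid = z - A @ coef
    fit = ParaboloidFit(*coef, residual_rms=float(np.sqrt(np.mean(resid ** 2))))
    fit.apex = _apex_of(*coef)
    fit.points = pts
    return fit


def gaussian_curvature_at_deepest(fit: ParaboloidFit) -> float:
    """Signed Gaussian curvature at the apex (stationary point), where the
    surface gradient vanishes so K = 4ab - c^2; sign(a+b) orients the
    result so bowls (invaginations) are positive, domes negative."""
    K = 4.0 * fit.a * fit.b - fit.c ** 2
    orient = np.sign(fit.a + fit.b) if (fit.a + fit.b) != 0 else 1.0
    return float(orient * abs(K)) if K >= 0 else float(K)


def paraboloid_depth(fit: ParaboloidFit, rim_fraction: float = 0.1) -> float:
    """Apex-to-rim depth of the fitted surface over its point footprint.

    The rim is the outermost ``rim_fraction`` of fitted points by
    in-plane radius about the apex; depth = mean rim z - apex z
    (positive when the apex dips below the rim, i.e. invagination).
    """
    if fit.points is None or len(fit.points) == 0:
        return 0.0
    xy = fit.points[:, :2] - fit.apex[:2]
    r = np.hypot(xy[:, 0], xy[:, 1])
    n_rim = max(1, int(np.ceil(rim_fraction * len(r))))
    rim = np.argsort(r)[-n_rim:]
    rim_z = float(np.mean(fit.evaluate(fit.points[rim, 0], fit.points[rim, 1])))
    return rim_z - float(fit.apex[2])


def placode_elongation(fit: ParaboloidFit, basal_heights) -> float:
    """Cell elongation = |paraboloid depth| + mean basal-layer cell height."""
    h = float(np.mean(np.asarray(basal_heights, dtype=float)))
    return abs(paraboloid_depth(fit)) + h


# ---------------------------------------------------------------------------
# per-cell measurements on the mesh
# ---------------------------------------------------------------------------

def basal_apical_ratio(mesh: TissueMesh, cell_id: int) -> float:
    """(Membrane-contact area) / (suprabasal-contact area) of a basal or
    placode cell."""
    from .vertex_dynamics import _face_area

    t = mesh.cell_types
    basal_a = apical_a = 0.0
    for fid in mesh.cells[cell_id]:
        o = mesh.face_owners[fid]
        other = o[1] if o[0] == cell_id else o[0]
        if t[other] == MEMBRANE:
            basal_a += _face_area(mesh, fid)
        elif t[other] == SUPRABASAL:
            apical_a += _face_area(mesh, fid)
    if apical_a == 0.0:
        raise UndefinedRatioError(f"cell {cell_id} has no suprabasal contact")
    return basal_a / apical_a


def cell_height(mesh: TissueMesh, cell_id: int) -> float:
    pts, _ = mesh.cell_polyhedron(cell_id)
    return float(pts[:, 2].max() - pts[:, 2].min())


def placode_membrane_points(mesh: TissueMesh, center_xy=None,
                            fit_radius: float | None = None) -> np.ndarray:
    """Basal-surface vertices for the curvature fit, unwrapped about the
    placode centre.

    By default these are the vertices shared between placode (or basal,
    if no placode is labelled) cells and the basement membrane.  With
    ``fit_radius`` the window also includes the basal-cell membrane
    interface within that in-plane radius of the centre: at small patch
    sizes the placode interface alone deforms as a near-flat plateau and
    the curvature lives at its shoulder.
    """
    t = mesh.cell_types
    want = PLACODE if np.any(t == PLACODE) else BASAL
    vids = set()
    halo = set()
    for fid, o in enumerate(mesh.face_owners):
        if o is None or mesh.faces[fid] is None:
            continue
        pair = {int(t[o[0]]), int(t[o[1]])}
        if pair == {MEMBRANE, want}:
            vids.update(int(v) for v in mesh.faces[fid])
        elif fit_radius is not None and pair == {MEMBRANE, BASAL}:
            halo.update(int(v) for v in mesh.faces[fid])
    if fit_radius is not None and halo:
        c = (np.asarray(center_xy, dtype=float) if center_xy is not None
             else mesh.box.L[:2] / 2.0)
        hv = np.asarray(sorted(halo - vids))
        if len(hv):
            d = mesh.X[hv, :2] - c
            for ax in range(2):
                L = mesh.box.L[ax]
                d[:, ax] -= L * np.round(d[:, ax] / L)
            vids.update(int(v) for v in hv[np.hypot(d[:, 0], d[:, 1]) <= fit_radius])
    if not vids:
        raise FitError("no placode-membrane interface vertices")
    P = mesh.X[sorted(vids)].copy()
    if center_xy is None:
        center_xy = mesh.box.L[:2] / 2.0
    d = P[:, :2] - np.asarray(center_xy, dtype=float)
    for ax in range(2):
        L = mesh.box.L[ax]
        d[:, ax] -= L * np.round(d[:, ax] / L)
    P[:, :2] = np.asarray(center_xy, dtype=float) + d
    # unwrap z about the circular mean (a deep pit can cross the z wrap)
    Lz = mesh.box.L[2]
    ang = 2.0 * np.pi * P[:, 2] / Lz
    zref = Lz / (2.0 * np.pi) * np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    P[:, 2] = zref + (P[:, 2] - zref + Lz / 2.0) % Lz - Lz / 2.0
    return P


@dataclass
class MorphologySummary:
    elongation: float
    basal_apical_ratio: float
    gaussian_curvature: float
    depth: float


def morphology_summary(mesh: TissueMesh, center_xy=None,
                       fit_radius: float | None = None) -> MorphologySummary:
    """The (elongation, basal/apical ratio, curvature) triple of a tissue."""
    pts = placode_membrane_points(mesh, center_xy, fit_radius)
    fit = fit_paraboloid(pts, "full_3d")
    K = gaussian_curvature_at_deepest(fit)
    depth = paraboloid_depth(fit)
    t = mesh.cell_types
    plac = np.flatnonzero(t == PLACODE)
    if len(plac) == 0:
        plac = np.flatnonzero(t == BASAL)
    heights = [cell_height(mesh, c) for c in plac]
    elong = placode_elongation(fit, heights)
    ratios = []
    for c in plac:
        try:
            ratios.append(basal_apical_ratio(mesh, c))
        except UndefinedRatioError:
            continue
    ratio = float(np.mean(ratios)) if ratios else np.nan
    return MorphologySummary(elong, ratio, K, depth)


# ---------------------------------------------------------------------------
# 2D vector fields: divergence, ROI averaging, alignment
# ---------------------------------------------------------------------------

@dataclass
class VectorField2D:
    """Regular-grid 2D vector field; invalid nodes are NaN in ``vec``."""

    origin: np.ndarray
    spacing: float
    vec: np.ndarray  # (ny, nx, 2)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.vec = np.asarray(self.vec, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.vec.ndim != 3 or self.vec.shape[2] != 2:
            raise ValueError("vec must be (ny, nx, 2)")

    @property
    def shape(self):
        return self.vec.shape[:2]

    def node_xy(self):
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)


def divergence_map(fld: VectorField2D) -> np.ndarray:
    """du/dx + dv/dy; central differences in the interior, one-sided at the
    edges.  NaN (masked) nodes propagate to their stencil neighbours."""
    u = fld.vec[..., 0]
    v = fld.vec[..., 1]
    dudx = np.gradient(u, fld.spacing, axis=1)
    dvdy = np.gradient(v, fld.spacing, axis=0)
    div = dudx + dvdy
    div[~(np.isfinite(u) & np.isfinite(v))] = np.nan  # masked nodes stay masked
    return div


def circular_roi(fld: VectorField2D, center_xy, radius: float) -> np.ndarray:
    X, Y = fld.node_xy()
    cx, cy = center_xy
    return (X - cx) ** 2 + (Y - cy) ** 2 <= radius ** 2


def roi_mean_divergence(div: np.ndarray, roi: np.ndarray) -> float:
    """Mean divergence over the valid nodes of a (circular) ROI."""
    sel = div[roi]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("ROI contains no valid divergence values")
    return float(np.mean(sel))


def _first_negative_peak(trace: np.ndarray) -> int | None:
    t = np.asarray(trace, dtype=float)
    thresh = np.nanmean(t) - np.nanstd(t)
    for i in range(len(t)):
        lo = t[i - 1] if i > 0 else np.inf
        hi = t[i + 1] if i < len(t) - 1 else np.inf
        if t[i] < thresh and t[i] < 0 and t[i] <= lo and t[i] <= hi:
            return i
    return None


def align_divergence_traces(traces):
    """Align traces on their first negative-divergence peak (first local
    minimum below mean - 1 s.d.) and average over the overlapping support.

    Returns (offsets, mean, sem, lags) where ``offsets`` are the aligned
    time indices relative to the peak; traces with no negative peak are
    excluded with a warning.
    """
    peaks, kept = [], []
    for k, tr in enumerate(traces):
        p = _first_negative_peak(np.asarray(tr, dtype=float))
        if p is None:
            warnings.warn(f"trace {k} has no negative-divergence peak; excluded")
            continue
        peaks.append(p)
        kept.append(np.asarray(tr, dtype=float))
    if not kept:
        raise ValueError("no trace with a negative-divergence peak")
    lo = -min(peaks)
    hi = min(len(tr) - p for tr, p in zip(kept, peaks))
    offsets = np.arange(lo, hi)
    M = np.stack([tr[p + lo: p + hi] for tr, p in zip(kept, peaks)])
    mean = M.mean(axis=0)
    sem = M.std(axis=0, ddof=1) / np.sqrt(len(M)) if len(M) > 1 else np.zeros_like(mean)
    return offsets, mean, sem, peaks


# ---------------------------------------------------------------------------
# in-silico flow from trajectories
# ---------------------------------------------------------------------------

def basal_layer_positions(mesh: TissueMesh) -> dict:
    """Tracked basal-layer vertices: ids, xy positions and placode flag."""
    arr = mesh.compiled()
    t = mesh.cell_types
    ids, plac = [], []
    for v in range(len(mesh.X)):
        if not mesh.alive_vertex[v]:
            continue
        owners = arr.vert_cells[arr.vert_off[v]:arr.vert_off[v + 1]]
        kinds = {int(t[c]) for c in owners}
        if BASAL in kinds or PLACODE in kinds:
            ids.append(v)
            plac.append(PLACODE in kinds)
    ids = np.asarray(ids, dtype=np.int64)
    return {"ids": ids, "xy": mesh.X[ids, :2].copy(),
            "placode": np.asarray(plac, dtype=bool)}


def insilico_flow(frame_a: dict, frame_b: dict, box: tg.PeriodicBox,
                  spacing: float, dt: float = 1.0,
                  drift_removal: bool = True) -> VectorField2D:
    """Bin basal-layer vertex displacements between two recorded frames
    onto a regular grid (mean per bin; empty bins NaN).

    With ``drift_removal`` the mean in-plane displacement of the
    placode-cell vertices is subtracted first (extrinsic body forces have
    a nonzero net component)."""
    common, ia, ib = np.intersect1d(frame_a["ids"], frame_b["ids"],
                                    return_indices=True)
    if len(common) == 0:
        raise ValueError("frames share no tracked vertices")
    d = frame_b["xy"][ib] - frame_a["xy"][ia]
    for ax in range(2):
        L = box.L[ax]
        d[:, ax] -= L * np.round(d[:, ax] / L)
    if drift_removal:
        sel = frame_a["placode"][ia]
        if not np.any(sel):
            sel = np.ones(len(d), dtype=bool)
        d = d - d[sel].mean(axis=0)
    pos = frame_a["xy"][ia]
    nx = max(2, int(np.ceil(box.L[0] / spacing)))
    ny = max(2, int(np.ceil(box.L[1] / spacing)))
    vec = np.full((ny, nx, 2), np.nan)
    cnt = np.zeros((ny, nx))
    acc = np.zeros((ny, nx, 2))
    j = np.clip((pos[:, 0] // spacing).astype(int), 0, nx - 1)
    i = np.clip((pos[:, 1] // spacing).astype(int), 0, ny - 1)
    np.add.at(cnt, (i, j), 1.0)
    np.add.at(acc, (i, j), d / dt)
    nz = cnt > 0
    vec[nz] = acc[nz] / cnt[nz][:, None]
    return VectorField2D(origin=np.array([spacing / 2, spacing / 2]),
                         spacing=spacing, vec=vec)


def late_time_roi_divergence(frames: list, box: tg.PeriodicBox, center_xy,
                             radius: float, dt: float = 1.0,
                             spacing: float | None = None) -> float:
    """Mean placode-ROI divergence over the last recorded interval."""
    if spacing is None:
        spacing = max(box.L[0], box.L[1]) / 8.0
    fld = insilico_flow(frames[-2], frames[-1], box, spacing, dt)
    div = divergence_map(fld)
    roi = circular_roi(fld, center_xy, radius)
    return roi_mean_divergence(div, roi)


# ---------------------------------------------------------------------------
# ablation recoil
# ---------------------------------------------------------------------------

def _signed_distance_and_normal(mask: np.ndarray, spacing: float = 1.0):
    mask = np.asarray(mask, dtype=bool)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    sd = d_out - d_in
    gy, gx = np.gradient(sd, spacing)
    nrm = np.hypot(gx, gy)
    nrm[nrm == 0] = 1.0
    return sd, gx / nrm, gy / nrm


def recoil_profile(fld: VectorField2D, ablation_mask: np.ndarray,
                   n_bins: int = 30):
    """Radial recoil profile around an ablated region.

    The radial displacement component is taken along the local outward
    normal of the mask boundary (computed from the signed distance
    transform) and averaged in bins of signed distance to the region.
    The total tissue displacement is the outer positive peak minus the
    inner negative peak of the profile.

    Returns (bin_centers, profile, total).
    """
    sd, nx_, ny_ = _signed_distance_and_normal(ablation_mask, fld.spacing)
    u, v = fld.vec[..., 0], fld.vec[..., 1]
    rad = u * nx_ + v * ny_
    ok = np.isfinite(rad)
    edges = np.linspace(np.nanmin(sd), np.nanmax(sd), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prof = np.full(n_bins, np.nan)
    which = np.digitize(sd, edges) - 1
    for b in range(n_bins):
        sel = ok & (which == b)
        if np.any(sel):
            prof[b] = float(np.mean(rad[sel]))
    outer = prof[(centers > 0) & np.isfinite(prof)]
    inner = prof[(centers <= 0) & np.isfinite(prof)]
    outer_pk = float(np.max(outer)) if outer.size else 0.0
    inner_pk = float(np.min(inner)) if inner.size else 0.0
    total = outer_pk - inner_pk
    return centers, prof, total


def recoil_direction(fld: VectorField2D, compartment_mask: np.ndarray,
                     cut_mask: np.ndarray, dilate_px: int = 75,
                     convention: str = "fibroblast") -> float:
    """Mean recoil angle of one compartment near the cut.

    The ROI is the cut mask dilated by ``dilate_px`` pixels intersected
    with the compartment mask.  The cut axis is the least-squares line
    through the cut pixels; the outward normal points from the cut toward
    the compartment.  Conventions: ``fibroblast`` reports -90 deg toward
    the cut, 0/180 parallel, +90 away; ``placode`` reports 0 toward the
    cut, +/-90 parallel to the cut, 180 away.
    """
    cut = np.asarray(cut_mask, dtype=bool)
    comp = np.asarray(compartment_mask, dtype=bool)
    dil = ndimage.binary_dilation(cut, iterations=int(dilate_px))
    roi = dil & comp
    if not np.any(roi):
        raise ValueError("dilated cut does not overlap the compartment")
    u = fld.vec[..., 0][roi]
    v = fld.vec[..., 1][roi]
    vbar = np.array([np.nanmean(u), np.nanmean(v)])
    iy, ix = np.nonzero(cut)
    pts = np.stack([ix, iy], axis=1).astype(float)
    pts -= pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts, full_matrices=False)
    chat = Vt[0] / np.linalg.norm(Vt[0])
    ry, rx = np.nonzero(roi)
    cy, cx = np.nonzero(cut)
    away = np.array([rx.mean() - cx.mean(), ry.mean() - cy.mean()])
    nhat = away - np.dot(away, chat) * chat
    nn = np.linalg.norm(nhat)
    if nn == 0:
        raise ValueError("cannot orient the outward normal")
    nhat /= nn
    p = float(np.dot(vbar, chat))
    q = float(np.dot(vbar, nhat))
    if convention == "fibroblast":
        return float(np.degrees(np.arctan2(q, p)))
    if convention == "placode":
        return float(np.degrees(np.arctan2(p, -q)))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# nuclear point patterns
# ---------------------------------------------------------------------------

@dataclass
class PointPattern2D:
    """Marked nuclear coordinates (micrometres) with a designated centre."""

    points: np.ndarray
    center: np.ndarray
    boundary_radius: float | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.center = np.asarray(self.center, dtype=float)
        if len(self.points) < 1:
            raise ValueError("need >=1 point")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("centre must be finite")


@dataclass
class Sox9Stats:
    count: int
    local_density: float      # points within 10 um of the centre / (pi 10^2)
    mean_distance: float      # mean distance to the centre (um)
    hull_area: float          # convex hull area (um^2)
    hull_degenerate: bool = False


def sox9_stats(pattern: PointPattern2D, density_radius: float = 10.0) -> Sox9Stats:
    """The four placode point-pattern statistics.

    The density disk is closed (points at exactly ``density_radius`` are
    counted).  Fewer than 3 non-collinear points yield hull_area = 0 with
    the degenerate flag set.
    """
    d = np.linalg.norm(pattern.points - pattern.center, axis=1)
    count = len(pattern.points)
    n_in = int(np.sum(d <= density_radius))
    dens = n_in / (np.pi * density_radius ** 2)
    meand = float(np.mean(d))
    degenerate = False
    if count >= 3:
        try:
            hull = ConvexHull(pattern.points)
            area = float(hull.volume)  # 2D: volume attribute is the area
        except QhullError:
            area, degenerate = 0.0, True
    else:
        area, degenerate = 0.0, True
    return Sox9Stats(count, dens, meand, area, degenerate)
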