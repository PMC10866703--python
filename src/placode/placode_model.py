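"""Placode-specific mechanics.

The relative adhesion/contractility of an interface between cell types is
summarized by a normalized total wetting coefficient

    sigma~_ij = (sigma_ij - 2 K_s S_0 + (d_im + d_jm) sigma_k)
                / (sigma_bb - 2 K_s S_{0,b}),

normalized by the coefficient on lateral basal-basal interfaces.  With
standard vertex-model parameters both numerator and denominator are
negative, so a *larger* sigma~ means the interface is energetically
*favoured* (the cell wets it); a smaller sigma~ corresponds to a higher
effective interfacial tension.  The (d_im + d_jm) sigma_k term adds the
effective tension contributed by the basement-membrane spring network
when the interface touches the membrane.

The module also provides the spring network itself (E = 1/2 k_m
sum_e (l_e - l_0)^2 over membrane-interface edges), the volumetric
dilation procedure that measures its effective surface tension sigma_k,
an exponentially decaying centripetal body force emulating the
contractile fibroblast ring, and the four simulation scenarios used to
probe placode morphogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import morphometrics as mm
from . import tissue_geometry as tg
from . import vertex_dynamics as vd
from .tissue_geometry import BASAL, MEMBRANE, PLACODE, SUPRABASAL, TissueMesh


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# wetting-coefficient algebra
# ---------------------------------------------------------------------------

def _membrane_flags(touches_membrane) -> int:
    if isinstance(touches_membrane, (tuple, list, np.ndarray)):
        return int(bool(touches_membrane[0])) + int(bool(touches_membrane[1]))
    return int(bool(touches_membrane))


def wetting_coefficient(sigma_ij: float, K_s: float, S_0: float,
                        touches_membrane, sigma_k: float, denom: float) -> float:
    """Normalized total wetting coefficient of one interface."""
    if denom == 0:
        raise tg.ConfigurationError("wetting normalization denominator is zero")
    n_m = _membrane_flags(touches_membrane)
    return (sigma_ij - 2.0 * K_s * S_0 + n_m * sigma_k) / denom


def tension_from_wetting(sigma_tilde: float, K_s: float, S_0: float,
                         touches_membrane, sigma_k: float, denom: float) -> float:
    """Heterotypic tension sigma_ij achieving a target wetting coefficient."""
    if denom == 0:
        raise tg.ConfigurationError("wetting normalization denominator is zero")
    n_m = _membrane_flags(touches_membrane)
    return sigma_tilde * denom + 2.0 * K_s * S_0 - n_m * sigma_k


# ---------------------------------------------------------------------------
# basement-membrane spring network
# ---------------------------------------------------------------------------

@dataclass
class SpringNetwork:
    """Springs decorating the membrane--basal/placode interface edges.

    ``k`` is the per-edge stiffness and ``l0`` the per-edge rest length.
    Rest lengths are set to ``rest_fraction`` x the edge length at build
    time (a uniform prestrain), so the network carries a homogeneous
    tension rather than the large self-stress a single shared rest length
    would impose on a disordered edge set.  ``k_m``, the softening rule
    and ``rest_fraction`` record the construction so the network can be
    rebuilt after topological changes (edges that persist keep their rest
    length)."""

    edges: np.ndarray
    k: np.ndarray
    l0: np.ndarray
    k_m: float = 1.0
    rest_fraction: float = 1.0
    soft_center_xy: tuple | None = None
    soft_radius: float = 0.0
    soft_factor: float = 1.0

    def rebuild(self, mesh: TissueMesh) -> "SpringNetwork":
        new = build_spring_network(
            mesh, k_m=self.k_m, rest_fraction=self.rest_fraction,
            soft_center_xy=self.soft_center_xy,
            soft_radius=self.soft_radius, soft_factor=self.soft_factor,
        )
        old = {tuple(e): l for e, l in zip(map(tuple, self.edges), self.l0)}
        for i, e in enumerate(map(tuple, new.edges)):
            if e in old:
                new.l0[i] = old[e]
        return new


def membrane_interface_faces(mesh: TissueMesh) -> list[int]:
    out = []
    t = mesh.cell_types
    for fid, o in enumerate(mesh.face_owners):
        if o is None or mesh.faces[fid] is None:
            continue
        pair = {int(t[o[0]]), int(t[o[1]])}
        if pair in ({MEMBRANE, BASAL}, {MEMBRANE, PLACODE}):
            out.append(fid)
    return out


def build_spring_network(mesh: TissueMesh, k_m: float = 1.0,
                         rest_fraction: float = 1.0,
                         soft_center_xy=None, soft_radius: float = 0.0,
                         soft_factor: float = 1.0) -> SpringNetwork:
    """Edge set of all faces whose owners are {membrane, basal} or
    {membrane, placode}, deterministically ordered."""
    if k_m < 0:
        raise tg.ConfigurationError("k_m must be >= 0")
    eset = set()
    for fid in membrane_interface_faces(mesh):
        f = mesh.faces[fid]
        n = len(f)
        for i in range(n):
            eset.add(tuple(sorted((int(f[i]), int(f[(i + 1) % n])))))
    edges = np.asarray(sorted(eset), dtype=np.int64).reshape(-1, 2)
    k = np.full(len(edges), float(k_m))
    if len(edges):
        d = mesh.box.min_image(mesh.X[edges[:, 1]] - mesh.X[edges[:, 0]])
        l0 = rest_fraction * np.linalg.norm(d, axis=1)
    else:
        l0 = np.zeros(0)
    if soft_center_xy is not None and soft_radius > 0 and len(edges):
        mid = mesh.X[edges[:, 0]] + 0.5 * mesh.box.min_image(
            mesh.X[edges[:, 1]] - mesh.X[edges[:, 0]])
        dxy = mid[:, :2] - np.asarray(soft_center_xy, dtype=float)
        for ax in range(2):
            L = mesh.box.L[ax]
            dxy[:, ax] -= L * np.round(dxy[:, ax] / L)
        k[np.hypot(dxy[:, 0], dxy[:, 1]) <= soft_radius] *= soft_factor
    return SpringNetwork(edges, k, l0, k_m, rest_fraction, soft_center_xy,
                         soft_radius, soft_factor)


def spring_energy_forces(mesh: TissueMesh, net: SpringNetwork):
    """(E_spring, per-vertex force array) for the current configuration."""
    e = vd.spring_energy(mesh, net)
    F = np.zeros_like(mesh.X)
    vd.add_spring_forces(mesh, net, F)
    return e, F


def membrane_interface_area(mesh: TissueMesh) -> float:
    from .vertex_dynamics import _face_area

    return float(sum(_face_area(mesh, fid) for fid in membrane_interface_faces(mesh)))


DEFAULT_STRAINS = (-0.03, -0.02, -0.01, 0.01, 0.02, 0.03)


def calibrate_membrane_tension(mesh: TissueMesh, net: SpringNetwork,
                               strains=DEFAULT_STRAINS) -> float:
    """Effective surface tension sigma_k of the spring network.

    The network (positions + connectivity only) is extracted from the
    configuration and dilated affinely, box L -> L (1 + eps); for each
    strain the spring energy and the total membrane-interface surface
    area are evaluated, and sigma_k is the least-squares slope of energy
    versus area.
    """
    strains = np.asarray(strains, dtype=float)
    if strains.size < 3:
        raise tg.ConfigurationError("need at least 3 strain points")
    if len(net.edges) == 0:
        return 0.0
    d = mesh.box.min_image(mesh.X[net.edges[:, 1]] - mesh.X[net.edges[:, 0]])
    l = np.linalg.norm(d, axis=1)
    k = np.broadcast_to(np.asarray(net.k, dtype=float), l.shape)
    A0 = membrane_interface_area(mesh)
    E = np.array([0.5 * np.sum(k * (l * (1 + eps) - net.l0) ** 2) for eps in strains])
    A = A0 * (1 + strains) ** 2
    slope = np.polyfit(A, E, 1)[0]
    return float(slope)


def choose_rest_length(mesh: TissueMesh, k_m: float, target_ratio: float,
                       lateral_tension: float, base_membrane_tension: float,
                       strains=DEFAULT_STRAINS, tol: float = 0.02,
                       max_iter: int = 60) -> float:
    """Mean rest length such that (base membrane tension + sigma_k) /
    lateral cell-cell tension equals ``target_ratio`` (within ``tol``).

    Rest lengths are a uniform fraction of the built edge lengths, and
    sigma_k decreases monotonically with that fraction, so the root is
    found by bisection on the fraction in [0, 1]; sigma_k is re-measured
    through the dilation procedure at every iterate.  Returns the mean
    rest length (= fraction x mean edge length).
    """
    net0 = build_spring_network(mesh, k_m=k_m, rest_fraction=1.0)
    if len(net0.edges) == 0:
        raise CalibrationError("no membrane-interface springs in this mesh")
    d = mesh.box.min_image(mesh.X[net0.edges[:, 1]] - mesh.X[net0.edges[:, 0]])
    lbar = float(np.mean(np.linalg.norm(d, axis=1)))
    need = target_ratio * lateral_tension - base_membrane_tension
    if need <= 0:
        return lbar  # no extra spring tension required

    def sigk(frac):
        net = build_spring_network(mesh, k_m=k_m, rest_fraction=frac)
        return calibrate_membrane_tension(mesh, net, strains)

    lo, hi = 0.0, 1.0
    if sigk(lo) < need:
        raise CalibrationError(
            f"k_m={k_m} too soft: max sigma_k {sigk(lo):.3g} < required {need:.3g}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = sigk(mid) - need
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
        if abs(f_mid) <= tol * max(need, 1e-12):
            return mid * lbar
    return 0.5 * (lo + hi) * lbar


# ---------------------------------------------------------------------------
# extrinsic fibroblast-ring force
# ---------------------------------------------------------------------------

@dataclass
class ExtrinsicForceField:
    """Inward-directed compressive body force on basal cells outside the
    placode: magnitude f_r exp(-(d - r_plac)/decay) at in-plane distance d
    from the placode centre, directed toward the centre."""

    f_r: float
    center: np.ndarray
    r_plac: float
    decay: float

    def __post_init__(self):
        if self.f_r < 0:
            raise tg.ConfigurationError("f_r must be >= 0")
        if self.r_plac <= 0 or self.decay <= 0:
            raise tg.ConfigurationError("r_plac and decay must be positive")
        self.center = np.asarray(self.center, dtype=float)

    def force_at(self, position, box: tg.PeriodicBox | None = None) -> np.ndarray:
        """Force vector at one position (in-plane centripetal)."""
        p = np.asarray(position, dtype=float)
        d = p[:2] - self.center[:2]
        if box is not None:
            for ax in range(2):
                L = box.L[ax]
                d[ax] -= L * np.round(d[ax] / L)
        r = float(np.hypot(d[0], d[1]))
        if r == 0.0:
            return np.zeros(3)
        mag = self.f_r * np.exp(-(r - self.r_plac) / self.decay)
        return np.array([-mag * d[0] / r, -mag * d[1] / r, 0.0])

    def vertex_forces(self, mesh: TissueMesh) -> np.ndarray:
        arr = mesh.compiled()
        F = np.zeros_like(mesh.X)
        t = mesh.cell_types
        counts = np.diff(arr.vert_off)
        owner_is_basal = t[arr.vert_cells] == BASAL
        idx = np.repeat(np.arange(len(mesh.X)), counts)
        has_basal = np.bincount(idx[owner_is_basal], minlength=len(mesh.X)) > 0
        sel = has_basal & mesh.alive_vertex
        if not np.any(sel):
            return F
        d = mesh.X[sel, :2] - self.center[:2]
        for ax in range(2):
            L = mesh.box.L[ax]
            d[:, ax] -= L * np.round(d[:, ax] / L)
        r = np.hypot(d[:, 0], d[:, 1])
        ok = r > 0
        mag = np.zeros_like(r)
        mag[ok] = self.f_r * np.exp(-(r[ok] - self.r_plac) / self.decay) / r[ok]
        F[sel, 0] = -mag * d[:, 0]
        F[sel, 1] = -mag * d[:, 1]
        return F


def extrinsic_force(position, fld: ExtrinsicForceField) -> np.ndarray:
    return fld.force_at(position)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

SCENARIO_KINDS = ("model1_intrinsic", "model2_extrinsic",
                  "membrane_softening", "apical_reduction")


@dataclass
class Scenario:
    """One simulation scenario.

    Wetting targets are expressed relative to the basal-basal lateral
    interface (sigma~ = 1 everywhere is the symmetric flat control).

    ``apical_tension_scale`` < 1 reduces the raw placode-suprabasal
    tension, which *raises* sigma~_ps under the normalization (both
    numerator and denominator are negative); this is the in-silico
    counterpart of reduced apical/suprabasal myosin activity.
    """

    kind: str = "model2_extrinsic"
    nx: int = 8
    ny: int = 8
    placode_radius: float = 1.6
    sigma_pp_t: float = 1.0          # placode lateral wetting (model 1 dial)
    sigma_ps_t: float = 0.7          # placode-suprabasal wetting
    ratio_pm_ps: float = 3.0         # sigma~_pm / sigma~_ps (shared dial)
    f_r: float = 0.0                 # extrinsic ring force (model 2 dial)
    apical_tension_scale: float = 1.0
    soft_factor: float = 1.0         # sub-placode membrane stiffness scale
    soften_KS: bool = True           # softening also scales membrane-cell K_S
    k_m: float = 60.0
    stiffness_ratio: float = 2.0     # membrane/cell-cell interface stiffness
    v0: float = 0.05
    D_r: float = 1.0
    dt: float = 1e-3
    n_steps: int = 4000
    relax_steps: int = 1500
    record_every: int = 500
    seed: int = 0
    jitter: float = 0.25

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise tg.ConfigurationError(f"unknown scenario kind {self.kind!r}")


@dataclass
class ScenarioResult:
    mesh: TissueMesh
    summary: "mm.MorphologySummary"
    series: pd.DataFrame
    log: dict
    integrity: bool
    placode_center: np.ndarray
    flow_frames: list
    roi_divergence: float


def default_energy_params(mesh: TissueMesh, sigma_k: float = 0.0,
                          K: float = 1.0, K_V_rel: float = 5.0,
                          s0=(5.0, 5.4, 5.4, 5.4), targets=None,
                          wetting: dict | None = None) -> vd.EnergyParams:
    """Energy parameters for the four-type tissue.

    The neutral tissue has no heterotypic tensions (sigma_ab = 0), which
    makes the placode mechanically identical to the basal cells.  The
    ``wetting`` dict holds the placode dials, all equal to 1 in the
    neutral state:

    ``pp``
        sigma~_pp in units of its neutral value (placode lateral wetting;
        > 1 favours lateral placode-placode contact).
    ``ps``
        sigma~_ps in units of its neutral value (placode-suprabasal
        wetting; < 1 = extra apical tension, > 1 = reduced apical
        tension).
    ``pm_ratio``
        basal-to-apical wetting bias of the placode relative to the
        basal-cell reference: sigma~_pm is offset from its neutral value
        by (pm_ratio x ps - 1) lateral-tension units, so > 1 favours
        membrane contact (invagination side) and < 1 suprabasal contact.

    V0/S0 per type are measured from the mesh (mean per type) unless a
    (V0, S0) pair is passed in ``targets``; the tension matrix entries
    are solved from the wetting targets through the normalized-wetting
    algebra with sigma_bb = 0 as reference.
    """
    t = mesh.cell_types
    if targets is not None:
        V0, S0 = (np.asarray(x, dtype=float) for x in targets)
    else:
        V = tg.all_cell_volumes(mesh)
        V0 = np.array([V[t == c].mean() if np.any(t == c) else 1.0
                       for c in range(4)])
        S0 = np.asarray(s0, dtype=float) * V0 ** (2.0 / 3.0)
    denom = 0.0 - 2.0 * K * S0[BASAL]
    sigma = np.zeros((4, 4))
    if wetting:
        w = {"pp": 1.0, "ps": 1.0, "pm_ratio": 1.0, **wetting}

        def s0ab(a, b):
            return 0.5 * (S0[a] + S0[b])

        def neutral(a, b):
            touches = (a == MEMBRANE, b == MEMBRANE)
            return wetting_coefficient(0.0, K, s0ab(a, b), touches,
                                       sigma_k, denom)

        sigma[PLACODE, PLACODE] = tension_from_wetting(
            w["pp"] * neutral(PLACODE, PLACODE), K,
            s0ab(PLACODE, PLACODE), (False, False), sigma_k, denom)
        sigma[PLACODE, SUPRABASAL] = tension_from_wetting(
            w["ps"] * neutral(PLACODE, SUPRABASAL), K,
            s0ab(PLACODE, SUPRABASAL), (False, False), sigma_k, denom)
        pm_target = neutral(PLACODE, MEMBRANE) + (w["pm_ratio"] - 1.0)
        sigma[PLACODE, MEMBRANE] = tension_from_wetting(
            pm_target, K, s0ab(PLACODE, MEMBRANE), (False, True),
            sigma_k, denom)
        sigma[SUPRABASAL, PLACODE] = sigma[PLACODE, SUPRABASAL]
        sigma[MEMBRANE, PLACODE] = sigma[PLACODE, MEMBRANE]
    # volume modulus scaled per cell so equal *relative* compression costs
    # the same energy for small membrane cells as for epithelial cells
    p = vd.EnergyParams(K_V=K_V_rel / V0 ** 2, K_S=np.full(4, K), V0=V0, S0=S0,
                        sigma=sigma, KV_rel=K_V_rel)
    return p


def setup_tissue(scn: Scenario, rng: np.random.Generator):
    """Initialize, pre-relax, type and parameterize the scenario tissue."""
    from . import synthetic_data as sd

    mesh, _ = sd.make_flat_tissue(scn.nx, scn.ny, sd.DEFAULT_LAYERS,
                                  jitter=scn.jitter,
                                  seed=int(rng.integers(2 ** 31 - 1)))
    center = np.array([mesh.box.L[0] / 2.0, mesh.box.L[1] / 2.0])
    mesh = tg.assign_cell_types(mesh, sd.DEFAULT_LAYERS, scn.placode_radius, center)

    # pre-relaxation with neutral (homotypic-only) parameters before cell
    # types matter; per-cell volume targets are quenched from the initial
    # tessellation (polydispersity is a property of the tissue, not a
    # stress source)
    flat = default_energy_params(mesh)
    Vinit = tg.all_cell_volumes(mesh)
    mesh.V0 = Vinit.copy()
    s0_by_type = np.array([5.0, 5.4, 5.4, 5.4])
    mesh.S0 = s0_by_type[mesh.cell_types] * Vinit ** (2.0 / 3.0)
    cfg = vd.IntegratorConfig(dt=scn.dt, n_steps=scn.relax_steps,
                              l_T=0.05 * float(np.mean(mesh.V0)) ** (1 / 3),
                              record_every=max(1, scn.relax_steps),
                              pin_membrane_z=False)
    noise = vd.NoiseState(mesh.n_cells, v0=scn.v0, D_r=scn.D_r, rng=rng)
    mesh, _ = vd.simulate(mesh, flat, noise, cfg)

    # springs: rest lengths calibrated for the target stiffness ratio.
    # The lateral cell-cell reference tension is the magnitude of the
    # basal-basal total wetting coefficient |sigma_bb - 2 K_s S0_b|; the
    # springs supply the remaining (ratio - 1) x lateral tension.
    lat = abs(0.0 - 2.0 * 1.0 * flat.S0[BASAL])
    base = lat
    net_probe = build_spring_network(mesh, k_m=scn.k_m, rest_fraction=1.0)
    lbar = float(np.mean(np.linalg.norm(mesh.box.min_image(
        mesh.X[net_probe.edges[:, 1]] - mesh.X[net_probe.edges[:, 0]]), axis=1)))
    try:
        l0 = choose_rest_length(mesh, scn.k_m, scn.stiffness_ratio, lat, base)
        frac = l0 / lbar
    except CalibrationError:
        frac = 0.9
    soft_xy = tuple(center) if scn.soft_factor != 1.0 else None
    springs = build_spring_network(mesh, k_m=scn.k_m, rest_fraction=frac,
                                   soft_center_xy=soft_xy,
                                   soft_radius=scn.placode_radius,
                                   soft_factor=scn.soft_factor)
    sigma_k = calibrate_membrane_tension(mesh, springs)

    # reducing the raw apical (placode-suprabasal) tension raises the
    # normalized wetting coefficient sigma~_ps (numerator and denominator
    # are both negative), which is how reduced apical myosin enters
    ps = scn.sigma_ps_t / scn.apical_tension_scale
    wetting = {"ps": ps, "pm_ratio": scn.ratio_pm_ps,
               "pp": scn.sigma_pp_t if scn.kind == "model1_intrinsic" else 1.0}
    params = default_energy_params(mesh, sigma_k=sigma_k,
                                   targets=(flat.V0, flat.S0),
                                   wetting=wetting)
    if scn.soft_factor != 1.0 and scn.soften_KS:
        scale = np.ones(mesh.n_cells)
        d = mesh.seed_points[:, :2] - center
        for ax in range(2):
            L = mesh.box.L[ax]
            d[:, ax] -= L * np.round(d[:, ax] / L)
        under = (np.hypot(d[:, 0], d[:, 1]) <= scn.placode_radius) \
            & (mesh.cell_types == MEMBRANE)
        scale[under] = scn.soft_factor
        params.KS_cell_scale = scale
    return mesh, params, springs, noise, center


def run_scenario(scenario: Scenario, mesh=None, rng=None) -> ScenarioResult:
    """Run one scenario and measure the morphology time series."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    if mesh is None:
        mesh, params, springs, noise, center = setup_tissue(scenario, rng)
    else:
        raise NotImplementedError("run_scenario builds its own tissue")

    ext = None
    if scenario.f_r > 0:
        V0b = float(mesh.V0[mesh.cell_types == BASAL].mean())
        ext = ExtrinsicForceField(
            f_r=scenario.f_r, center=np.append(center, 0.0),
            r_plac=scenario.placode_radius, decay=V0b ** (1.0 / 3.0))

    cfg = vd.IntegratorConfig(
        dt=scenario.dt, n_steps=scenario.n_steps,
        l_T=0.05 * float(np.mean(mesh.V0)) ** (1 / 3),
        record_every=scenario.record_every, pin_membrane_z=False)

    rows = []
    frames = []

    def record(m, it):
        s = mm.morphology_summary(m, center, fit_radius=2.0 * scenario.placode_radius)
        rows.append({"step": it, "elongation": s.elongation,
                     "basal_apical_ratio": s.basal_apical_ratio,
                     "curvature": s.gaussian_curvature,
                     "depth": s.depth})
        frames.append(mm.basal_layer_positions(m))

    frames.append(mm.basal_layer_positions(mesh))
    integrity = True
    try:
        mesh, log = vd.simulate(mesh, params, noise, cfg, springs=springs,
                                ext_field=ext, record=record)
    except vd.InstabilityError:
        integrity = False
        log = {"step": [], "energy": [], "mean_shape_index": [],
               "reconnections": []}
    if integrity:
        V = tg.all_cell_volumes(mesh)
        if np.any(V <= 0.05 * mesh.V0):
            integrity = False

    summary = mm.morphology_summary(mesh, center, fit_radius=2.0 * scenario.placode_radius) if integrity else \
        mm.MorphologySummary(np.nan, np.nan, np.nan, np.nan)
    series = pd.DataFrame(rows)
    roi_div = np.nan
    if integrity and len(frames) >= 3:
        roi_div = mm.late_time_roi_divergence(
            frames, mesh.box, center, scenario.placode_radius,
            dt=scenario.record_every * scenario.dt)
    return ScenarioResult(mesh, summary, series, log, integrity,
                          np.append(center, 0.0), frames, roi_div)


def phase_diagram(sweep: dict, kind: str, replicates: int = 1,
                  rng_seed: int = 0, base: Scenario | None = None) -> pd.DataFrame:
    """Grid sweep over scenario parameters.

    ``sweep`` maps Scenario field names to value lists; one output row per
    grid point per replicate (deterministic given ``rng_seed``).
    """
    base = base if base is not None else Scenario(kind=kind)
    names = list(sweep)
    grids = np.meshgrid(*[np.asarray(sweep[n]) for n in names], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1) if names else np.zeros((1, 0))
    rows = []
    for rep in range(replicates):
        for p in pts:
            over = {n: float(v) for n, v in zip(names, p)}
            scn = replace(base, kind=kind, seed=rng_seed + 1000 * rep, **over)
            res = run_scenario(scn, rng=np.random.default_rng(scn.seed))
            row = dict(over)
            row.update({
                "replicate": rep,
                "curvature": res.summary.gaussian_curvature,
                "elongation": res.summary.elongation,
                "basal_apical_ratio": res.summary.basal_apical_ratio,
                "integrity": bool(res.integrity),
            })
            rows.append(row)
    return pd.DataFrame(rows)
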