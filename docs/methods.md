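# Methods

## Model

The tissue is a confluent assembly of polyhedral cells sharing vertices
and faces, periodic in all three directions. Four cell types are
distinguished: basement membrane, basal, placode and suprabasal. The
energy is

```
E = Σ_i [ K_V,i (V_i − V0_i)² + K_S (S_i − S0_i)² ]
    + Σ_{i<j} σ_αβ S_ij
    + ½ Σ_e k_e (l_e − l0_e)²            (membrane-interface springs)
```

with per-cell volume and surface elasticity, a symmetric heterotypic
tension matrix over the four types acting on shared interface areas
S_ij, and a harmonic spring network decorating the edges of the
membrane–basal/placode interface. Vertices follow overdamped dynamics

```
dr_i/dt = −μ ∂E/∂r_i + v0 ⟨n̂_j⟩ ,
```

integrated by forward Euler; each cell carries a director n̂_j
performing rotational diffusion on the unit sphere with diffusivity D_r
(Euler–Maruyama with tangential projection and renormalization), and a
vertex feels the mean director of the non-membrane cells that own it.
Membrane cells model ECM and carry no active fluctuations.

Neighbour exchanges use the 3D generalization of T1 transitions: an edge
shorter than ℓ_T shared by exactly three faces is replaced by a small
triangular face between the two cells that previously met only at the
edge's endpoints (I→H); a triangular face with area below ℓ_T²√3/4
undergoes the inverse move (H→I). Candidates are processed shortest
first, every move is validated locally (closed, un-inverted,
volume-conserving cells; per-cell volume changes above 25 % are treated
as geometric pathologies and rejected) and newly created elements are
immune for one sweep to prevent flip-flopping. Face orientations are
maintained combinatorially: on each closed cell surface every edge must
be traversed once in each direction, and the overall sign is fixed by
positive volume. This is robust for the strongly non-convex (crumpled)
cells that transient strong-wetting states produce.

### Geometry conventions

Faces are fan-triangulated about their vertex centroid; volumes are
signed fan tetrahedra about a per-cell reference point. Because both
owners of a (possibly non-planar) shared face triangulate it
identically, cells tile space exactly: the summed cell volume equals the
box volume to machine precision, which is asserted after initialization
and after every accepted reconnection. Positions are stored wrapped;
every local object is reassembled by the minimum-image convention, which
requires at least three cells along each periodic axis (asserted by the
generators).

### Initial condition

Tissues are initialized from a periodic Voronoi tessellation (scipy/Qhull
on the 3×3×3 tiling of the seeds). The layered generator places one
jittered seed lattice per layer with uniform spacing, squashes vertex z
piecewise-linearly onto the requested layer thicknesses (default
0.3 / 1 / 1 / 1 s.l.u. for membrane/basal/suprabasal×2) and flattens the
two membrane interfaces, since the embryonic basement membrane starts
flat and the Voronoi strata are rough on the scale of the membrane
thickness. The membrane layer is laterally refined (2×2 small cells per
epithelial footprint) so its cells are near-isotropic solids rather than
wide frustrated slabs. Before cell types act, the tissue is pre-relaxed
under neutral parameters.

### Parameters

* K_S = 1 (energy/s.l.u.⁴). K_V is scaled per cell as K_V = 5 / V0²,
  i.e. equal energetic cost for equal *relative* compression; with a
  single global K_V the small membrane cells could be crushed to zero
  volume at negligible cost.
* Preferred shape index s0 = S0/V0^{2/3}: 5.4 for basal, placode and
  suprabasal cells (near the 3D rigidity transition) and 5.0 for
  membrane cells (deep in the solid regime). Per-cell targets are
  quenched from the initial tessellation: V0_i is the cell's initial
  volume, S0_i = s0 · V0_i^{2/3}, so polydispersity is a property of the
  tissue rather than a source of stress.
* Active fluctuations v0 = 0.05 s.l.u./s.t.u., D_r = 1 /s.t.u.: small
  fluctuations that anneal the quench without fluidizing the tissue.
* dt = 1–2·10⁻³ s.t.u. (chosen by stability scan on the default
  fixtures; forward Euler shows no cell inversion over 10³–10⁴ steps at
  these values), μ = 1.
* Reconnection threshold ℓ_T = 0.05 · V̄0^{1/3}, checked every 10 steps.

### Wetting coefficients

The relative adhesion/contractility of an interface is summarized by the
normalized total wetting coefficient
σ̃_ij = (σ_ij − 2 K_S S̄0 + (δ_im + δ_jm) σ_k) / (σ_bb − 2 K_S S0_b).
Numerator and denominator are negative for standard parameters, so
larger σ̃ means the interface is energetically favoured; smaller σ̃
means higher effective tension. The spring network enters interfaces
that touch the membrane through its measured effective tension σ_k.

The *neutral* tissue (σ_αβ = 0 everywhere) makes the placode
mechanically identical to the basal cells and is the flat control. The
scenario dials are deviations from neutral: `pp` and `ps` multiply the
neutral σ̃ of the placode lateral and placode–suprabasal interfaces, and
`pm_ratio` offsets σ̃_pm from its basal-cell reference by
(pm_ratio − 1) lateral-tension units, so pm_ratio > 1 favours membrane
contact (invagination side) and < 1 suprabasal contact. The paper-style
σ̃ values realized by any dial setting can be read back through the
`wetting_coefficient` algebra; exact published parameter values live in
an unavailable supplementary table, so the dial ranges were chosen once
as the widest ranges that keep tissue integrity.

### Membrane stiffness calibration

The spring network's effective surface tension σ_k is measured by
extracting positions + connectivity, dilating them affinely
(L → L(1+ε), ε ∈ ±{1,2,3} %) and taking the least-squares slope of
spring energy versus interface area. Rest lengths are a uniform fraction
γ of the built edge lengths (a homogeneous prestrain); `choose_rest_length`
bisects γ until the membrane interface is twice as stiff as the
cell–cell reference |σ_bb − 2 K_S S0_b| (within 2 %). A single shared
rest length would put large self-stress on the disordered edge set and
crush membrane cells, so the uniform prestrain realizes the same σ_k
homogeneously.

### Scenarios

* `model2_extrinsic` — fibroblast-ring compression: an inward-directed
  in-plane body force of magnitude f_r e^{−(d − r_plac)/V0^{1/3}} on all
  vertices of basal (non-placode) cells, directed toward the placode
  centre. (The printed formula's radial unit vector points outward; the
  force is implemented inward as the text describes.) Default drive
  f_r = 1.2 with σ̃_pm/σ̃_ps bias 2.
* `model1_intrinsic` — placode-autonomous lateral wetting σ̃_pp raised.
* `membrane_softening` — sub-placode membrane softening: spring
  stiffness and membrane-cell K_S are scaled below the placode footprint
  on top of the intrinsic-wetting placode state (σ̃_pm/σ̃_ps bias 2,
  σ̃_ps 0.9); softening releases the interfacial spring tension that
  limits downward deflection, deepening the invagination and elongating
  the placode cells. The dose-response saturates once the relievable
  sub-placode tension approaches the cell–cell scale (softening factor
  ≈ 0.8), and below ≈ 0.65 the interface coefficient flips from tense
  (σ_k > 2K_S S̄₀) to wetting-favoured, where it crumples instead of
  deflecting; the standard 3-point scan {1.0, 0.9, 0.8} therefore probes
  the responsive branch.
* `apical_reduction` — reduced apical/suprabasal myosin: the raw
  placode–suprabasal tension is scaled down, which raises σ̃_ps and
  lowers the basal-to-apical ratio (the evagination side of the phase
  diagram).

Scenario runs flag loss of integrity (a cell inverted or compressed
below 5 % of its target volume) instead of reporting numbers from a
broken state; sweeps outside the physiological dial ranges terminate in
this flag.

## Measurements

All estimators are applied identically to simulation output and to
synthetic imaging-style inputs.

* **Curvature** — a quadric z = ax² + by² + cxy + dx + ey + f is fitted
  by least squares to the basal-surface vertices; the Gaussian curvature
  at the apex (where the gradient vanishes) is K = 4ab − c², reported
  with invagination (bowl, z up) positive. An axisymmetric mode fits a
  2D cross-section and revolves it. In scenario summaries the fit window
  is the placode–membrane interface plus the basal–membrane interface
  within twice the placode radius: at the simulated patch size the
  placode interface alone deforms as a near-flat plateau and the
  curvature lives at its shoulder.
* **Depth / elongation** — depth is mean rim z (outermost 10 % of fitted
  points by in-plane radius) minus apex z; elongation is |depth| plus
  the mean placode-cell height.
* **Basal/apical ratio** — membrane-contact area over suprabasal-contact
  area per basal/placode cell.
* **Flow divergence** — basal-layer vertex displacements per recording
  interval, minus the mean in-plane placode displacement (extrinsic body
  forces have a nonzero net component), binned to a regular grid;
  divergence by central differences (one-sided at edges, NaN masking);
  circular-ROI means; traces aligned on the first local minimum below
  mean − 1 s.d.
* **Ablation recoil** — radial displacement along the local outward
  normal of the signed distance transform of the cut mask, binned by
  signed distance; total = outer positive peak − inner negative peak.
  Directions are measured in a cut-mask dilation ∩ compartment ROI
  against the least-squares cut axis, in both published angle
  conventions.
* **Point patterns** — count, closed-disk (10 µm) local density, mean
  centre distance, convex-hull area (degenerate sets flagged, area 0).

## Synthetic data

Every generator is pure given (parameters, seed) and emits a manifest
recording its parameters and analytic expectations (confluence/box
volume for tissues, K = 1/R² for paraboloid clouds, divergence for flow
fields, the recoil law for ablation fields, mean-distance expectations
for point patterns), so tests compare against stored truth. What the
generators deliberately do **not** emulate: imaging noise and optics,
nuclear texture, segmentation artefacts, cell divisions, or a dermal
condensate; passing tests therefore validate the estimators and the
mechanical model, not robustness to microscopy artefacts.

## Problem sizes and runtimes

The default scenario tissue is 8×8 epithelial cells per layer. The test
suite and the acceptance script run the same pipelines at 5×5 cells per
layer (175 cells, ~1300 faces) for 2000–2500 steps and the rigidity
quench at 64 cells for 4000 steps — sizes chosen so the full suite
completes in minutes on one core while every sign-level outcome is
already unambiguous at that scale. The softening comparison is made at
matched simulation times because the ring-driven invagination is a
driven process without a true steady state.

## Known limitations

* The two-cells-per-axis regime is excluded by the minimum-image
  reassembly (≥3 cells per periodic axis required).
* Very strong wetting dials (|σ̃ − neutral| ≳ 0.3 beyond the spring-held
  membrane interface) drive interface crumpling and eventual loss of
  integrity; this is flagged, not silently reported, and bounds the
  physiological dial ranges.
* Evagination amplitudes are small at the 5×5 scale (|K| ~ 10⁻³–10⁻⁴
  s.l.u.⁻²); the sign is reproducible but the magnitude is not a
  quantitative prediction.
* The in-silico flow estimator works on vertex displacements directly;
  no image-correlation PIV engine is included.
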