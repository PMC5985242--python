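# Methods

## The model

A tooth is treated as a rigid body: crown and root move together under one
proper rigid transform (rotation `R ∈ SO(3)` + translation `t`, never any
scale — CBCT renders dentofacial anatomy 1:1). The expected-root-position
(ERP) estimate for tooth *i* is

    ERP_i = T_i(M_i),   T_i = argmin Σ_k ‖T(p_k) − q_k‖²

where `M_i` is the pre-treatment crown+root mesh, the `p_k` are points on
its crown, and the `q_k` their nearest points on the progress-stage
crown-only scan. Only crown geometry enters the fit; the root's position is
purely a consequence of tooth rigidity. This assumption fails exactly where
the method must not be trusted: root resorption, fracture, or any true
shape change between the two time points.

`ERPModel` estimates one `T_i` per tooth in three stages:

1. **Landmark (N-point) registration.** ≥3 matched crown points on both
   surfaces; closed-form least-squares rigid fit (Kabsch/Umeyama without
   scale, via SVD restricted to det = +1). Exact for noiseless
   correspondences; with click noise it only needs to land ICP in the
   right basin.
2. **Optional manual pre-transform**, modeling interactive tip/torque
   corrections. The automated path must and does succeed without it on
   synthetic data; it exists for gross initialization errors.
3. **Point-to-point ICP** from a deterministic subsample of the moving
   crown's vertices to the *surface* of the target crown. Correspondences
   are exact nearest points on triangles, never nearest vertices — the two
   meshes come from different modalities with very different tessellation
   densities, and vertex matching would bias the fit toward the denser
   tessellation.

Validation ("indirect superimposition") maps a control CBCT dentition into
the scan frame with **one transform per arch**, fitted on the union of the
arch's crown surfaces: the control already has correct relative tooth
positions, so only its global pose per arch is unknown; maxilla and
mandible are always independent rigid bodies. After that, the scan itself
is discarded and ERP vs control teeth are compared directly.

## Nearest-point queries

Both ICP and the displacement maps need exact nearest-point-on-surface
queries. The implementation prunes with two KD-trees: the nearest
*referenced* vertex gives an upper bound `d_v` on the surface distance, and
since every triangle lies within radius `r_max` of its centroid, only
triangles whose centroid is within `d_v + r_max` can contain the nearest
point. Candidates are resolved by exact point-to-triangle minimization, so
the result is identical (bit for bit) to brute force over all triangles —
a property the test suite checks directly.

## Displacement analysis

Per test-mesh vertex: signed distance to the nearest point on the reference
surface, sign taken from the reference triangle's outward normal at that
point (positive = outside). Conventions, fixed and documented because the
source material leaves them open:

- **Maximum displacement** is the maximum *absolute* signed value.
- **SD** is the population SD (vertices are the complete population of a
  mesh, not a sample).
- The three-color map: `|d| ≤ 0.75 mm` green (boundary inclusive — the
  band is a tolerance, not an open interval), `d < −0.75` blue (inward),
  `d > +0.75` red (outward). Written as uchar RGB vertex colors in PLY.
- Histograms default to 0.25 mm bins over (−2, +2) mm; out-of-range values
  are clipped into the end bins so counts always sum to the vertex count.
- Per-arch tables pool per-vertex values across the arch's teeth
  unweighted; a per-tooth breakdown is emitted alongside.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| ICP `max_iterations` | 600 | – | point-to-point ICP converges only linearly when the residual is tangential sliding on a smooth crown; easy fits stop early via the tolerance |
| ICP `convergence_tol` | 1e-7 | mm ΔRMS | well below any clinically meaningful displacement; cheap because iterations are fast |
| ICP `correspondence_rejection_dist` | 1.0 | mm | excludes gross outliers (bracket/band artifacts, root points when no CEJ plane is supplied) |
| ICP `sample_count` | 5000 | vertices | caps cost on dense scans; deterministic under `seed` |
| color threshold | 0.75 | mm | the displacement-map tolerance band used throughout |
| histogram bins | 0.25 over (−2, 2) | mm | matches the displacement ranges of interest |

ICP re-estimates the full transform from the original sample set each
iteration (rather than accumulating increments), then re-orthonormalizes
via polar decomposition, so returned rotations satisfy `RᵀR = I` and
`det R = +1` to 1e-9 regardless of iteration count.

## CEJ cutting

The cemento-enamel junction is modeled as a plane per tooth (point + unit
normal oriented crown-ward), fitted to ≥3 user landmarks by least squares
(smallest principal direction of the centered points) or known exactly for
synthetic teeth. Cutting splits crossing triangles along the plane, leaves
the boundary open, and conserves total surface area to 1e-6 relative; a
plane that misses the mesh yields one empty side, flagged, not an error.
The freehand clinical cut has no algorithmic definition; a plane is the
reproducible surrogate.

## Synthetic data

`make_tooth` lofts superellipse cross-sections along the long axis: a
paraboloid-tapered root closing at an apex pole, a bulged crown profile
closing at a rounded tip, joined exactly at the planar CEJ — watertight by
construction, deterministic for a given spec. `make_arch` places idealized
adult tooth dimensions along a parabolic arch form (defaults: 68 mm wide,
54 mm deep, 0.6 mm proximal gaps) with FDI codes assigned by position and a
verified > 0.1 mm pairwise surface clearance. Movements are parameterized
clinically (tip/torque/rotation about tooth-local axes through the crown
centroid, plus translation); defaults draw up to 4°/3°/4° and 0.8 mm.
Scan degradation: crown-only cropping at the CEJ, Gaussian noise along
vertex normals (scanner error is predominantly radial to the surface;
default sd 0.05 mm for the degraded condition), and random face removal
(50% in the degraded condition) emulating incomplete coverage. Landmarks
are farthest-point samples on the crown with optional 0.3 mm isotropic
click noise.

What this does *not* emulate: anatomical crown morphology, segmentation
bias (systematic surface offsets), bracket/band artifacts (available as an
opt-in bump generator, off by default), soft tissue, or inter-tooth
contacts. Passing tests therefore demonstrate correctness of the
*algorithms* under known rigid ground truth and generic noise — not
clinical accuracy on patient meshes, which depends on segmentation quality
the generator idealizes away.

## Study sizes and numerical choices

The benchmark studies (in `erp.benchmark`, rerun by
`scripts/acceptance.py`) use: 1,000 random transforms for
landmark-registration exactness; one 14-tooth arch for ICP recovery
(movements up to 5°/1 mm, landmark noise 0.3 mm) and for end-to-end root
recovery, noiseless and degraded (noise 0.05 mm, 50% decimation); 100
random teeth for cut-area conservation. These sizes make the full suite
run in a couple of minutes while exercising every tooth type and both
quadrant geometries; results at larger meshes differ only in runtime
because all queries are exact.

Degenerate inputs are defined, not left to chance: collinear landmark sets
raise a degeneracy error; an ICP rejection gate that starves (< 3
correspondences) raises rather than silently fitting; rotationally
symmetric surfaces (spheres) converge with a non-unique rotation, flagged
only through the documented behavior that the RMS — not the transform — is
the meaningful diagnostic there. Mesh I/O writes PLY with float64
coordinates (common writers' float32 would already cost ~2e-6 mm at
arch-scale coordinates); STL output remains inherently float32 and is not
used where round-trip precision matters.

## Known limitations

- Tooth rigidity is assumed, so root resorption or apex remodeling between
  time points silently degrades the prediction; radiographs remain the
  only way to detect such pathology.
- Point-to-point ICP with a fixed rejection gate has no outlier model
  beyond the gate; heavy bracket artifacts on real scans may need
  masking before registration.
- The CEJ plane is a first-order model of a curved anatomical line; root
  vs crown statistics shift slightly with the plane's placement.
- Landmark quality bounds the initialization: grossly wrong picks (e.g.
  swapped teeth) put ICP in the wrong basin, and no global search is
  attempted by design.
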