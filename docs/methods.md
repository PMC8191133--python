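# Methods

## The model

`hydrapattern` simulates head patterning in *Hydra* as nine coupled
reaction–diffusion equations on a closed tissue surface. Three classical
activator–inhibitor (Gierer–Meinhardt) pairs act on different spatial
scales, tied together by auxiliary species:

* **Body axis** — nuclear beta-Catenin/TCF (`beta_cat`) with a fast-diffusing
  antagonist (`beta_cat_ant`, phenomenologically Dickkopf-like). Production of
  both is multiplied by the source density, and boosted by Wnt3
  (factors `1 + c1·Wnt3`, `1 + c2·Wnt3`).
* **Head organizer** — `wnt3` and a diffusive antagonist (`wnt3_ant`,
  summarizing non-cell-autonomous Wnt3 inhibition such as Sp5/HmTSP action).
  Wnt3 production follows canonical pathway activity (multiplier `beta_cat`
  by default; see *Interpretation switches*). Crucially, Wnt3 is degraded at
  rate `d3·(1 + e3·HAS)` by the astacin proteinase field.
* **Tentacle system** — `tent` and `tent_ant`, both produced proportionally
  to the source density and damped by head factors.
* **`head`** — head-specific factors downstream of Wnt3
  (`∂t head = b5·wnt3 − d5·head`), the transcriptional input to the
  proteinase.
* **`has`** — the Wnt3-cleaving proteinase: activated by `head`, locally
  repressed by Wnt3 (`b6·head/(1 + c6·wnt3)`), so that it forms a collar
  *around* an established organizer and suppresses organizer formation
  elsewhere — a negative-feedback motif for single-organizer dominance.
* **`sd`** — the source density, a slow memory store of head-forming
  potential fed by beta-Catenin (`b9·beta_cat + 3·10⁻⁵ − d9·sd`,
  `1/d9 ≈ 3.3·10⁴` time units).

All quantities are dimensionless. The default coefficient set is the
published one; it is reproduced bit-exactly by
`hydrapattern.default_parameters()` and checked against the printed decimal
values in the test suite. One printed exponent (`a9`) lacks its base and is
read as `11·10⁻⁵` by analogy with the rest of the list.

### Experimental scenarios

| scenario      | encoding                                                    |
|---------------|-------------------------------------------------------------|
| `unperturbed` | none                                                        |
| `azk`         | +2.0 offset on the initial source-density gradient (GSK-3β inhibition = systemic rise of head-forming potential) |
| `has_kd`      | `b6 = 0` (proteinase knockdown)                             |
| `has_kd_azk`  | both of the above                                           |
| `dkk_kd_azk`  | `d2` doubled (reduced antagonist activity) + AZK offset     |
| `wnt3_oe`     | constant `+0.1` added to Wnt3 production                    |

### Initial conditions

The eight molecular species start as i.i.d. per-vertex `Uniform(0, 1)` noise
(PCG64, seeded, platform-stable); the source density starts at the
deterministic gradient `sd_offset + 4·exp(s3)/e` in the unit-sphere
coordinate `s3`. Only the geometric axis and this chemical gradient carry
positional information at `t = 0`. The published work states uniform
randomness without a range; we verified that the final patterned states are
insensitive to the noise convention (amplitudes 0.01–3, antagonists started
at zero, at basal levels, or at O(1) noise all reach the same attractor), so
the simplest convention is the default and the bounds are configuration.

## Geometry

The domain is an icosphere (recursive icosahedral subdivision, level *L*
giving `10·4^L + 2` vertices; default level 4, 2562 vertices). Diffusion
acts through the cotangent-weighted Laplace–Beltrami operator with
barycentric lumped-mass normalization — the standard convergent
discretization; degree-1/2 spherical-harmonic eigenvalues are reproduced to
well under 1% at level 5, and pure diffusion conserves area-weighted mass to
machine precision by construction (zero column sums of the weak form against
the lumped masses).

`build_spheroid_mesh` supports the axial tissue deformation
`(s1, s2, s3) → (s1, s2, s3 + stretch·s3)` (default stretch 4, a 1:1:5
prolate spheroid; an `absolute-z` mode is also provided). The **scenario
pipeline, however, defaults to the undeformed unit-sphere metric**
(`stretch_factor: 0` in the packaged configuration). This is a deliberate
design decision of this package: the published model couples the chemistry
to an evolving elastic surface, which is out of scope here, and the printed
diffusion coefficients give the body-axis antagonist a competition range of
`sqrt(a2/d2) ≈ 1.7`. Global single-organizer selection — the model's central
property — therefore requires a domain whose geodesic diameter is comparable
to that range. On a *static* 1:1:5 spheroid (geodesic diameter ≈ 10.6)
several independent beta-Catenin maxima always coexist and no perturbation
is needed to produce multiple axes, which contradicts the model's own
unperturbed baseline. Freezing the chemistry on the unit sphere preserves
the axis-selection property; the stretch remains available in configuration
for sensitivity studies.

## Numerics

First-order IMEX splitting, chosen for the model's stiffness structure:

1. non-negative production terms advance explicitly;
2. diffusion is solved implicitly (`M − dt·a·L`, symmetric positive
   definite, pre-factorized once per run; species sharing a coefficient
   share a factorization and are solved in one batched call) — but only for
   species whose explicit diffusion step would be unstable by the Gershgorin
   bound; weakly diffusing species advance explicitly;
3. linear decay is pointwise-implicit (division by `1 + dt·rate`).

Step 3 is essential: the proteinase-driven Wnt3 degradation rate
`d3·(1 + e3·HAS)` reaches O(10–100) in patterned states (`e3 = 100`), so a
fully explicit reaction step would need `dt ≲ 0.02` while the splitting is
unconditionally stable and positivity-preserving for the decay part. Default
`dt = 1.0`; final patterns are indistinguishable from `dt = 0.5` and `0.1`.
Rare small negatives introduced by the implicit diffusion solve (obtuse
triangles carry negative cotangent weights) are clipped to zero and the
clipped mass is tracked.

Two further schemes exist for verification: `explicit` (plain forward Euler,
used to check the diffusion-free reduction and conservation properties) and
`rk4` (classical Runge–Kutta; matches the adaptive LSODA reaction oracle to
2·10⁻⁷ relative error over 500 time units at `dt = 0.05`).

**Stopping.** A run stops when, for every species,
`‖u(t) − u(t−50)‖₂ / (50·‖u(t)‖₂) < steady_tol` (default `5·10⁻⁵`), or at
`t_end = 20000`. The tolerance is chosen as *quasi*-stationarity: the source
density is a deliberately slow variable whose relaxation (timescale
`1/d9 ≈ 3.3·10⁴`) keeps the system drifting at ~10⁻⁵ per unit time long
after the patterns are static (from `t ≈ 3000`); a strict fixed-point
tolerance would never trigger inside any practical horizon. Default runs
stop at `t ≈ 3000–8000`.

## Regimes and what the simulations show

With the published coefficients the simulated dynamics operate in a
**shadow-organizer regime**: starting from uniform noise, the Wnt3 field is
pulled down within about one time unit by the proteinase cascade (loop gain
`(b5/d5)·(b6/d6)·e3 = 2·10⁴` through `head`), and thereafter faithfully
mirrors the beta-Catenin pattern at low amplitude. The single apical
organizer, its location in the apical cap, the proteinase collar around it,
the absence of extra axes under AZK, and the loss/creation of secondary axes
under the knockdown scenarios are all read out from this structure and are
robust across seeds and mesh levels 3–5.

Phenomena that require an O(1)-amplitude Wnt3 spot do **not** occur in this
regime: body-wide proteinase elevation under AZK (the ambient proteinase
level is set by the Wnt3 basal production and barely moves), a broadened —
rather than swamped — expression domain under `+0.1` overexpression, and
sustained ectopic body tentacles (the tentacle on-state needs local source
density ≳ 3.5, while the AZK body column sits at 2.5–3.5; transient body
tentacles appear for `t ≈ 100–400` when the tentacle antagonist starts below
its basal level, then collapse). We verified by parameter and
initial-condition scans that these gaps are not discretization artifacts
(spike amplitudes are mesh-converged) and not resolvable by any
initialization of the printed equations; they plausibly belong to the
mechano-chemical coupling or calibration details that the static-geometry
reading cannot reproduce. The corresponding end-to-end checks in
`tests/test_acceptance.py` are expected to fail and are left failing rather
than weakened.

## Pattern quantification

All readouts are operational definitions (the underlying biology reports
images):

* **Spots** — connected components of the region above
  `rel_threshold × max` (default 0.5) on the mesh edge graph, discarded
  below 3 vertices; a field with area-weighted spatial CV below `cv_min`
  (default 0.2) has no spots (a uniform elevation is not a pattern). Both
  thresholds are scale-free.
* **Axes** — single-linkage clusters of Wnt3 spot seeds with geodesic link
  distance above a quarter of the mesh diameter.
* **Ring score** — (mass fraction of the field inside an axial band) ×
  (1 − CV of the band's azimuthal mass density over 12 bins), in [0, 1].
* **Body half** — `s3 < 0.3`, separating the gastric column from the
  hypostome/tentacle zone.
* **Phenotype rule table** — no-pattern / single-organizer /
  ectopic-tentacles / secondary-axis(-with-tentacles) / broadened-organizer,
  a deterministic function of the counts (see
  `pattern_analysis.classify_phenotype`).

## Interpretation switches

Two places in the printed equations are ambiguous; both defaults are
configurable on `ModelParameters`:

* `eq34_multiplier` — the production multiplier of the Wnt3 pair typesets
  like the antagonist, but the antagonist reading keeps ambient Wnt3
  production high everywhere, which makes the proteinase field body-wide
  and provably forbids any organizer; the canonical-pathway reading
  (`beta_cat`, the default) localizes Wnt3 production to beta-Catenin
  activity and yields the proteinase collar seen in the reported patterns.
* `head_ant_source` — the head-dependent damping of the tentacle system
  (`head`, default; alternatively `wnt3_ant`).

The divisor fields (`beta_cat_ant`, `wnt3_ant`, `tent_ant`) are floored at
`eps_div = 10⁻¹²` before division; real trajectories sit far above the floor
because of the baseline productions (0.035, 0.014).

## Verification layers

* closed-form steady states (source density, tentacle antagonist baseline)
  against the multi-start root finder, residual < 10⁻¹⁰;
* Turing dispersion curves of each two-species subsystem from the analytic
  2×2 eigenvalue problem, cross-checked against the dense eigendecomposition
  of the assembled 2N×2N linearization (exact reduction, since both species
  share the discrete operator);
* diffusion-free PDE trajectories against adaptive ODE integration
  (`rtol 10⁻⁹`);
* spherical-harmonic eigenvalue and mass-conservation checks of the
  operator; first-order Richardson consistency of the IMEX splitting.

## Problem sizes

Default study conditions: level-4 mesh (2562 vertices), 10 seeds per
scenario, quasi-steady stopping (runs end at `t ≈ 3000–8000`, roughly 15–20 s
per run on one CPU). The antagonist-removal experiment uses a level-2 mesh
(162 vertices) and `t_end = 2·10⁵` to let the source-density gradient relax.
The operator checks run at level 5 (10242 vertices).

## Known limitations

* Static geometry: no Helfrich-type tissue mechanics, no moving mesh; the
  stretched spheroid is available but breaks global axis selection (above).
* The shadow-organizer regime (above): Wnt3 amplitudes are relative, not
  absolute; scenario readouts that depend on absolute Wnt3 levels are
  documented as out of reach at the printed coefficients.
* No parameter fitting, no stochastic kinetics, no bifurcation continuation.
* The synthetic scenarios emulate idealized perturbations (a clean `b6 = 0`
  knockdown, a uniform potential offset); real siRNA knockdowns are partial
  and mosaic, so passing tests demonstrate internal consistency of the
  model, not quantitative agreement with animal experiments.
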