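# Methods

This note documents the models implemented in `ecgforge`, their
assumptions, the parameters that matter, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Idealized anatomy

The package replaces image-derived anatomical cohorts with parametric
geometries that preserve the degrees of freedom the simulations need.

**Ventricles** are two truncated prolate ellipsoids voxelized on a regular
grid (default 2 mm): a thick-walled LV (outer semi-axes 34 × 34 × 48 mm,
wall 10 mm) centered at the origin with the long axis along z, and a
thinner RV shell (wall 6 mm) wrapped around the LV's septal side, both cut
at a common base plane.  Every node carries analytic universal ventricular
coordinates: transmural ρ ∈ [0, 1] measured radially between the inner and
outer ellipsoid surfaces (0 = endocardium), apico-basal z ∈ [0, 1]
(0 = apex), rotational φ ∈ [−π, π] with φ = 0 on the mid-septum and
positive φ toward the anterior wall (this orientation makes the tabulated
fascicular-site and infarct-territory ranges — septal sites near φ = 0,
lateral LCX territory at |φ| ≥ 2 — geometrically consistent), and a
chamber label.  Septal tissue belongs to the LV.  Mesh construction
rejects resolutions that resolve fewer than three elements across the
thinner wall.

**Fibers** follow the rule-based transmural rotation: helix angle
α(ρ) = 60° → −60° and sheet angle β(ρ) = −65° → 25°, both linear in ρ,
applied in the local (circumferential, apico-basal, transmural) frame
derived from the ellipsoid geometry; triads are orthonormal by
construction.

**Atria** are two spherical shells (RA radius 24 mm, LA 21 mm, wall 3 mm)
with great-circle surrogate bands for the crista terminalis (posterior-
lateral meridian of the RA), pectinate muscles (anterior of the crista)
and inferior isthmus (inferior RA cap).  A 3.5 mm-radius cylinder between
the antero-superior poles stands in for Bachmann's bundle; a thinner
posterior cylinder provides the secondary interatrial pathway.  The
sinoatrial exit site is the node set at the superior end of the crista
terminalis (the SVC-junction surrogate).  Left atrial enlargement scales
the LA radius by the cube root of the volume scale.  Shape coefficients
(bounded like statistical-shape-model eigenmode scores, [−3, 3] atrial and
[−2, 2] torso) map linearly to ±5% size change per unit — a declared
convention standing in for eigenmode geometry, since no shape model is
shipped; the extreme scores therefore move dimensions by ±15%.

**Placement.** The heart is posed inside a fixed electrode cage (10
standard electrodes on an idealized torso frame: x left, y anterior,
z superior).  A fixed anatomical base rotation orients the long axis so
that the simulated leads show the conventional polarities (positive P and
R in I/II, negative V1, positive V6); the sampled pose (rotations
±20° per axis, translations ±10 mm, applied x → y → z) composes onto it.

## Conduction and activation

Activation times solve the anisotropic Eikonal problem on a graph whose
vertices are the mesh nodes.  Edges connect lattice neighbors up to second
order — all offsets in {−2..2}³ with coprime components, 98 neighbors —
and carry the travel-time metric ‖e‖_M with M = R diag(cv_f⁻², cv_s⁻²,
cv_n⁻²) Rᵀ evaluated in the fiber frame of the voxels the edge crosses
(four samples per edge; where a sample lies on a lattice plane, the
fastest adjacent conducting voxel is used, which keeps activation maps
monotone under any tissue blocking).  Edges whose path crosses inert
tissue are removed; source delays enter through a super-source node and
one Dijkstra pass (scipy) yields the map; unreached nodes keep +∞ and
source nodes inside inert tissue are ignored.

Accuracy envelope (tested): the propagation speed is exact along lattice
axes (< 2% after the linear fit) and within 8% along arbitrary directions
(measured worst case ≈ 5% for the isotropic medium).  This stencil
approach was chosen over a PDE fast-marching discretization because it is
deterministic, exactly verifiable against closed forms, and trivially
robust on thin voxelized shells.

Ventricular conduction: 0.6 m/s along fibers with 4:2:1 ratio
(0.6/0.3/0.15); an isotropic 2.0 m/s fast endocardial layer covers
ρ ≤ 0.15 within apico-basal band z ∈ [0.1, 0.9].  Atrial conduction:
per-region transversal velocities sampled from their tabulated ranges with
fixed anisotropy ratios (bulk 1.94, interatrial connections 3, crista
2.56, pectinate 3.24, isthmus 1); the posterior connection uses the
interatrial transversal velocity but ratio 1 so that Bachmann's bundle is
always the primary route.

Fascicular sites are discs on their ρ-shell: nodes of the site's chamber
within one transmural node layer (the nominal 0.5%-of-wall disc thickness
is below mesh resolution, so a full node layer is always seeded) and
within radius r × (chamber apico-basal arc length) of the site center;
r is the site's tabulated endocardial-extent fraction.  The RV moderator
band site carries a sampled delay in [0, 10] ms; the other four activate
at 10 ms.

## Cellular model and repolarization

The two-current Mitchell–Schaeffer model drives all cellular dynamics
(dv/dt = h v²(1−v)/τ_in − v/τ_out + J_stim; gate opening τ_open below
V_gate = 0.13, closing τ_close above).  Ventricular cells use τ_in = 0.3,
τ_out = 5.4, τ_open = 80 and the affine map to physical voltage
[−86.2, +40] mV; the infarct border zone uses τ_in = 0.45, τ_out = 3.6,
τ_open = 44 with [−73.1, +12.5] mV.  Templates are integrated explicitly
at dt = 0.025 ms (satisfying dt ≤ 0.1 τ_in) and stored at 0.5 ms.

APD is measured from the maximum upstroke slope to the downstroke crossing
of V_gate — the model's own natural repolarization threshold; the time to
90% repolarization is recorded alongside and defines the ground-truth
T-wave end.  τ_close is calibrated against a target APD by inverting a
cached monotone APD(τ_close) curve with a shape-preserving interpolant
plus Newton refinement; the round-trip error is below 0.25 ms across
[150, 250] ms.  Template banks hold one trace per 1 ms of APD with linear
interpolation in between.

The APD field is s(x) = q_ρ ρ + q_v ṽ + q_φ (φ/π) + q_z z (ṽ = −1 LV,
+1 RV), min–max normalized per mesh onto [APD_min, APD_max] (sampled from
[150, 175] / [225, 250] ms); a constant s maps to the interval midpoint.
Per-mesh min–max (rather than a fixed affine range) was chosen so the
sampled gradient weights always exercise the full APD interval.

Atrial action potentials are Mitchell–Schaeffer surrogates with atrial
voltage bounds (−80/+20 mV, default APD 250 ms); fibrotic remodeling is
expressed at template level as a 0.7× upstroke amplitude and 0.85× APD.
This replaces a detailed atrial ionic model; it preserves what the forward
projection sees (upstroke timing, amplitude, plateau) but not ionic
mechanisms or rate dependence.

## Forward model

One homogeneous unbounded medium (σ_medium = σ_torso = 0.22 S/m) hosts the
elemental dipole sum with bulk intracellular conductivity σ_i = 0.34 S/m;
per-element gradients come from hexahedral vertex finite differences, and
inert elements (infarct core, removed fibrotic elements) are excluded.
The full anisotropic bidomain and torso-compartment conductivities are
recorded as metadata.  Because the two chambers' absolute amplitudes under
a homogeneous medium are not individually calibrated, the synthesis stage
rescales the QRST complex against the P wave — the same amplitude-
consistency mechanism the record assembly needs anyway.  The operator is
precomputed as a lead-field matrix (potentials = B · V_m), making a beat
one matrix product; linearity, the 1/r² far-field decay and the point-
dipole closed form are tested properties.

A ventricular beat spans 450 ms simulated at 1 ms and resampled to 500 Hz
(225 samples); the P-wave window is auto-sized to the end of atrial
activation plus margin and clamped to 150–200 ms.  Ground-truth fiducials
come from the fields themselves: QRS_on/off from the activation extrema,
T_off from max(LAT + APD90), P_on/off from the atrial activation extrema.

## Record synthesis

Clinical lead-II feature statistics (means and standard deviations of
P/R amplitude, P duration, PQ, QRS, QT, RR) parameterize three Gaussian
blocks; the correlations are not published, so the defaults (amplitudes
0.5; P duration–PQ 0.4; QRS–QT 0.4, QT–RR 0.6, QRS–RR 0.2) are declared
calibration knobs, re-fittable from any user feature table
(`MVNSpec.from_feature_table`).  Conditional draws use the closed-form
Gaussian conditioning; PQ is drawn from the conditional truncated below at
max(P duration, 200 ms under AV block) — mathematically identical to
rejection but exact arbitrarily far into the tail.

The mean heart rate derives from the beat's QT by drawing RR | QT from the
rate block, clipped to 50–90 bpm; RR series are spectrally synthesized
with a 1/f^β spectrum (β = 1, SDNN 40 ms by default).  Each beat is warped
only in [QRS_off, T_off] to its drawn QT; when a warp outgrows the drawn
RR slot the slot is widened minimally.  Sigmoid connectors (logistic,
1–99% span, endpoint-exact by affine normalization) join P to QRS and beat
to beat; records are truncated to exactly 5000 samples.

Noise is generated per electrode (baseline wander as slow sinusoids below
0.5 Hz, Poisson electrode-movement transients with exponential decay, and
1–12 Hz band-limited motion artifact with a slow envelope), combined into
leads through the same Einthoven/Goldberger/Wilson algebra — so the lead
identities hold exactly for the noisy and filtered variants too — and
scaled so the total 12-lead SNR equals the drawn value in [15, 20] dB
exactly.  The filtered variant applies the 3rd-order 0.5/150 Hz
Butterworth band-pass with zero-phase (forward-backward) filtering, chosen
so the ground-truth fiducials stay aligned in the filtered signal.

## Pathology construction

* **LBBB / RBBB** remove all fascicular sites of one ventricle; the
  blocked chamber activates trans-septally (tested: activation still
  reaches everywhere, total activation time strictly increases).
* **MI** grows a geodesic region from an artery-bounded UVC center with
  healthy myocardial velocities; the threshold time is d_co × (LV long
  axis) / cv_f, so an isotropic medium yields a Euclidean ball of that
  radius.  The region is intersected with ρ ≤ ρ_n and the LV; the
  outermost geodesic shell holding 5% of the region's elements is the
  border zone (ring-shaped, per the "outer area" reading), the remainder
  the inert core.  d_co = 0 removes the infarct entirely, recovering the
  healthy activation map bit-for-bit; the tabulated d_co is treated as a
  dimensionless radius fraction (its printed unit appears to be a
  table-formatting slip).
* **FAM** grows Voronoi-like patches from random seeds (randomized edge
  weights, multi-source Dijkstra on the element face-adjacency graph)
  until the drawn fraction (5–45%, nine levels) of the shell is covered;
  exactly half the patch elements (rounded) become passive barriers, and
  survivors conduct at 0.5× longitudinal / 0.2× transversal — an exact
  2.5× anisotropy increase — with fibrotic templates.  The interatrial
  bridges are spared so the atria stay connected.
* **IAB** sets Bachmann's bundle inert and verifies the LA remains
  reachable through the posterior pathway (connected components on the
  conducting-element graph).
* **LAE** samples the LA volume scale in [1.1, 1.6] (the healthy upper
  bound exceeded by 10–60%); conduction varies within the healthy ranges.
* **AVB** only flags the synthesis stage.

Every modifier is a pure function of its inputs and seed; records are
bit-identical under regeneration from (label, seed, anatomy pool).

## Delineation and features

The delineator is a documented derivative/threshold method, not a port of
a clinical delineation toolchain: R peaks from a 40 ms smoothed squared-
derivative energy with adaptive threshold; QRS bounds from sustained
crossings of a narrow (8 ms) energy envelope; T end from the decay of a
12 Hz-smoothed copy below 3% of the T-peak amplitude; P bounds from a
lightly smoothed copy (10 ms moving average, so the R peak does not smear
into the search window) with an 8% decay threshold; the isoelectric
baseline is the median over low-slope-energy samples.  On noise-free
synthetic records the median recovery error against generator ground
truth is below 8 ms for every fiducial type (tested at 100 records with a
10 ms bound).  Feature tables are beat-averaged per lead (11 features ×
12 leads); amplitudes are peak values against the quiet baseline.

## Scale, determinism, limitations

Default problem sizes — ~16 000 ventricular and ~4 300 atrial elements,
second-order stencils, 1 ms field evaluation — were chosen so that one
labeled record takes about 1.5 s warm on a single core and full test and
acceptance runs remain desk-scale; all sizes are configurable upward.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng` / `SeedSequence`.

What passing tests show — and what they do not: the generator reproduces
the *mechanistic structure* of the published pipeline (activation physics,
repolarization gradients, pathology transformations, synthesis coupling,
format), and its contracts are verified against closed forms and its own
ground truth.  It does not reproduce patient-derived anatomical detail,
torso inhomogeneities (lungs/blood are metadata only), a biophysically
detailed atrial ionic model, rate-dependent APD restitution, or the
feature distributions of any specific clinical cohort; absolute amplitudes
before the synthesis-stage rescaling are not comparable to measured ECGs.
Cohort-level feature summaries should therefore be read as internal
consistency checks, not clinical validation.
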