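# Methods

## The model in one paragraph

`occlustress` computes dynamic occlusal contact stress from recorded jaw
kinematics instead of simulated muscle forces. The mandibular (lower)
dentition is treated as a rigid body whose trajectory is prescribed by
two fused recordings — a high-rate 3-D displacement trace of an incisal
magnet point and low-rate per-plane rotation angles extracted from
video landmark-marker pairs — and is moved under the fixed maxillary
(upper) dentition. Contact is resolved quasi-statically per merged
trajectory segment with a penalty formulation: interpenetration of
lower-surface material points into the upper surface is converted to
contact pressure by an elastic-foundation (Winkler) layer, Coulomb
sliding friction supplies the shear traction, and the per-face maximum
principal contact stress summarises both.

## Kinematics

**Reference frame.** x = subject's right, y = superior, z = anterior;
origin at the mandibular incisal midpoint in centric occlusion (the
magnet site). All geometry in mm, angles in radians, time in seconds.

**Traces.** A `DisplacementTrace` is a uniformly sampled (nominally
1000 Hz) incisal displacement relative to the centric pose; its first
sample is (0,0,0) by convention (loaders re-base and log an offset).
Rotation angles come per anatomical plane from a fixed/movable marker
pair (sagittal: root of zygomatic process -> gonion; frontal: nasion ->
pogonion; horizontal: hyoid -> pogonion): the plane angle at frame *t*
is the signed angle between the movable-minus-fixed vector at *t* and
at frame 0, counter-clockwise positive in the plane's viewing
orientation (from the right, from anterior, from above).

**Merging.** The two streams are not synchronised at acquisition; they
are aligned by normalised task time and the common interval is split
into *n* equal bins (protocol defaults per task: centric closing 18,
protrusion 61, left excursion 29, right excursion 35). Each segment's
pose is the linearly interpolated displacement plus the three
interpolated bin-end angles, composed as an **absolute** transform from
the centric reference:

    R = R_hor(θ_hor) · R_fro(θ_fro) · R_sag(θ_sag),
    p ↦ R (p − c) + c + t .

The composition order is a fixed documented choice; at the recorded
angle magnitudes all six orders agree within 0.05 mm over a 50 mm
radius point set (tested). The rotation centre *c* defaults to the
incisal origin and is configurable; the merged translation is the raw
incisal displacement, so with the default centre the cumulative
endpoint maps the incisal point onto the recorded displacement exactly.

**Mirror trace.** Reflection about the mid-sagittal plane x = 0: dx is
negated, dy/dz kept; frontal and horizontal angles are negated,
sagittal kept; excursion labels swap sides. This is an exact involution
and commutes with time reversal.

**Angle units.** The recorded per-task angles (e.g. horizontal 0.471
for the right excursion) are treated as radians; loaders accept a
`deg` flag. Radians make the rotational contribution to posterior
tooth motion dominant, which is why the synthetic occlusion (below)
must provide guidance over a wide excursion range.

## Contact solver

**Sampling.** One material point per lower face (the face centroid).
Quads are triangulated internally by their shortest diagonal.

**Gap queries.** Signed distance of each transformed sample to the
fixed upper surface, sign from the nearest face's outward normal
(negative = penetration). Pairing is re-established from scratch every
frame (finite sliding). The spatial index (centroid KD-tree with
triangle-circumradius bounds) is exactly equivalent to exhaustive
nearest-triangle search, with equidistant ties broken toward the lowest
face index; this equivalence is asserted in the tests. Points farther
than a cutoff (default 5 mm) are classified "far" and excluded. Indices
track a mesh version counter; querying after a mesh edit raises.

**Penalty layer.** Pressure p = k · max(−g, 0) with

    k = E*/h,  E* = E/(1 − ν²)

(E in MPa, h the foundation thickness in mm). Defaults E = 84 GPa,
ν = 0.3 (enamel), μ = 0.1, h = 2 mm, giving k ≈ 46 154 N/mm³. h is a
solver parameter, not an anatomical thickness: it sets the overall
stress scale, which in a kinematically prescribed rigid model is
arbitrary — locations, orderings and time courses are the meaningful
outputs. The solver was validated against the closed-form foundation
results it should reproduce: a rigid sphere of radius R pressed δ into
a foundation-backed plane carries F = kπRδ² (within 3% at δ = 0.1 mm on
a 0.07 mm mesh, log–log F–δ slope 2.00), and flat punches of area A and
2A at equal total force halve the peak stress (exact for the discrete
flat-on-flat case).

**Friction.** "No elastic slip" rigid Coulomb sliding: where the
tangential slip speed (backward difference of the sample's in-plane
motion between frames; zero at the first frame) is positive,
τ = μ·p opposing the slip direction; at zero slip τ = 0 — a
kinematically driven model has no stick-force recovery mechanism.

**Reported stress.** σ₁ = p/2 + sqrt((p/2)² + τ²), the Mohr's-circle
major value of the local (p, τ) traction pair, reported as a positive
magnitude per lower face. In reports, "vertical stress" denotes p and
"shear stress" τ at the same site.

## Synthetic dentition

No scanned casts accompany the recordings, so the generator supplies a
parametric stand-in that preserves the *occlusal logic* rather than
crown anatomy.

* **Lower arch** — a band strip swept along an elliptic arch curve
  (half-width 27 mm, depth 50 mm, seven teeth per quadrant with
  anatomical widths), one cosine-profile cusp per tooth with a small
  flat apex plateau (0.8 mm radius — a wear-facet shape that also makes
  face-centroid sampling read the true tip height). All cusp tips lie
  on the occlusal plane y = 0. FDI labels are carried per face and are
  recoverable from the arch spec by construction.
* **Upper arch** — a continuous "guidance funnel" canopy: over each
  lower cusp a flat ceiling disc at that tooth's centric clearance,
  descending away from the fossae at a constant guidance slope
  (0.42 mm/mm lingually/medially, 0.47 buccally). This extends natural
  cusp-incline guidance over the full recorded excursion range: the
  recorded rotations displace posterior teeth by tens of mm, and the
  protocol required the teeth to stay in gliding contact, so the
  emulated occlusion must admit contact everywhere along that envelope.
  A consequence is that penetration grows roughly linearly along an
  excursion, so stresses peak at the end stage, as in the recordings.
* **Occlusal scheme** — per-tooth centric clearances (premolars
  tightest at the 0.4 mm base gap; molars +0.2 to +0.25 mm; canines
  +0.1; incisors +0.5) emulate a posterior-guided scheme with relieved
  anterior teeth. With a symmetric parameter set the generated model is
  mirror-symmetric about x = 0 to machine precision (the midline column
  is its own mirror image; optional vertex jitter is drawn on one half
  and mirrored).
* **Interference** — an optional extra-height bump (default 0.5 mm,
  plateau-capped cosine of radius 2 mm) on one tooth plants a
  balancing-side interference; `interference_modification` returns the
  carve that removes it (depth = planted height, radius 1.5× the bump
  radius because the carve's pure cosine taper must cover the plateau
  shoulder).

**What the generator does not emulate.** Real crown morphology, multi-
cusp contacts, deformable enamel/periodontium, and saturation of
guidance at anatomical incline lengths. Passing pattern tests therefore
demonstrates that the *method* (trajectory fusion + penalty contact +
reporting) reproduces interference-driven stress logic, not that any
real dentition would show these numbers.

## Simulated tasks

Preset endpoint displacements/angles follow the recorded envelope:
right excursion (6.9, −6.6, −0.3) mm with angles (0.084, 0.001,
−0.471); left excursion (−4.1, −1.9, −0.3) with (−0.052, −0.002,
0.179); protrusion (0, −1.0, 8.0) with (−0.111, 0.002, 0.001); centric
closing (0, −0.8, 0.3) with (0.104, 0.001, 0.003). Angle signs are a
documented convention (the recordings report magnitudes): the right
excursion lifts the posterior teeth sagittally while the shorter left
excursion drops them slightly — the subject's asymmetric, protective
movement strategy — and the frontal roll lifts the working side.
Because the trace convention fixes the first sample at the centric
reference, the closing preset models the terminal clench phase (first
contact → full intercuspation via hinge rotation) rather than the full
rest-to-ICP approach. Trajectories ramp with a minimum-jerk profile
over 1 s (1000 Hz displacement, 30 Hz video; a constant-rate profile is
available, and is the one for which segment-wise linear interpolation
recovers the ground truth exactly).

With these conditions the pipeline reproduces the qualitative clinical
arc: closing loads the bilateral molars with the maximum on the
interference tooth; protrusion ends with incisal loading; the left
excursion concentrates the global maximum on the balancing-side
interference (FDI 47) in every contact frame; replaying the mirrored
(longer) right-excursion trace leftward multiplies the interference
stress severalfold; and carving the interference by its planted height
removes ≥50% of its peak stress and relocates the task maximum to the
working side. Note the carve cannot create literally new contacts:
with prescribed rigid kinematics, removing material only reduces
penetrations — the "unmasking" of the working side is a statement about
where the maximum stress sits, which is also how the underlying
recordings describe it.

## Numerical choices and edge cases

* Mesh steps: lower band 0.7 mm, canopy 1.0 mm; benchmark meshes
  0.07–0.1 mm. Problem sizes (≈2 000 lower faces, ≈5 500 upper faces,
  18–61 frames per task) keep a full task under ~5 s on one core.
* Equidistant nearest-triangle ties → lowest face index. Far cutoff
  5 mm. Stale spatial indices raise rather than silently misreport.
* Smoothing (one-ring mean filter) pins open-boundary and isolated
  vertices, so a flat patch is an exact fixed point and the rim does
  not shrink; smoothed vertices are convex combinations of the old
  ones, hence the bounding box never grows.
* Degenerate inputs: empty meshes, degenerate faces, non-uniform
  sampling, coincident markers, overlapping teeth and label mismatches
  all raise typed errors naming the offending line/frame/pair.
* Determinism: a config + seed fully determines every output byte;
  reports embed a config hash and re-import from CSV bit-equal
  (`float_precision="round_trip"` on read).
* Stress units are MPa internally; the CLI can display GPa. Absolute
  magnitudes scale linearly with k = E*/h and are not calibrated to any
  measured enamel stress (see the penalty-layer note above).

## Known limitations

Rigid arches (no shell elasticity, no periodontal compliance); one
material point per face; quasi-static frames at segment resolution
(no inertial effects); idealised marker geometry (the movable landmark
rotates about the fixed one, so the pair angle equals the plane's rigid
rotation angle); guidance-funnel occlusion as described above. Upper-
side stress output exists face-wise in `ContactState` but per-tooth
reporting covers the mandibular side, matching how such results are
conventionally presented.
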