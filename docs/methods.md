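# Methods

## Physical model

Transcutaneous DC stimulation operates in the quasi-static regime: tissue is
a passive resistive volume conductor and the electric potential obeys

    ∇·(σ ∇φ) = 0,          E = −∇φ,          J = σ E,

with σ the DC conductivity (S/m) assigned per tissue from a low-frequency
dielectric catalogue (CSF 2, skin 0.1, muscle 0.202, fat 0.0122, compact
bone 0.020, cerebellum 0.0475, cord/nerve 0.0171, heart muscle 0.0537 S/m,
etc.).  Electrodes are rectangular metal pads (σ = 5.9·10⁷ S/m, 1 mm)
on saline sponges (σ = 0.3 S/m, 5 mm) of the same footprint.  The montages
are the two standard pediatric protocols modelled here: a 5×5 cm cerebellar
pad centred 2 cm below the inion with a distal return and 2 mA total
current (ctDCS), and a 5×3 cm pad over the T10 spinous process with a
right-arm return and 3 mA (tsDCS).

## Discretisation and solver

The equation is discretised on the uniform voxel lattice with a
cell-centred 7-point finite-volume scheme.  The conductance of the face
between two voxels is the harmonic mean of their conductivities times face
area over centre distance; the harmonic mean enforces current continuity at
tissue interfaces and vanishes when either voxel is air, which is exactly
the insulated skin–air condition (current parallel to the surface) in
discrete form.  Air voxels (σ = 0) are excluded from the unknown set, as are
conducting voxels not connected to the electrode pair (their potential is
undefined and stored as NaN).  Pad voxels are Dirichlet nodes at ±V/2.

The resulting symmetric positive-definite system is solved with
Jacobi-preconditioned conjugate gradients to a relative residual of 1e-8
(default; configurable), which is orders of magnitude below the sensitivity
of any reported metric.  Assembly order is fixed and nothing is randomised,
so solves are bit-reproducible.  The system is solved once at unit
inter-electrode voltage; the injected current is measured by summing face
fluxes out of the anode pad, and the solution is rescaled by linearity to
the 2 mA / 3 mA target.  On the layered-slab fixture the scheme is nodally
exact: the computed fields and total current match the one-dimensional
series-conductance closed form to solver tolerance, which is why mesh
convergence is demonstrated on a slab whose layer thicknesses are
deliberately incommensurate with the grid (the remaining error is the
voxelised interface position).

## Field derivation and metrics

E is obtained by differencing φ with central differences restricted to
same-tissue neighbours, one-sided at tissue boundaries and next to masked
voxels.  This keeps the physical field discontinuity at conductivity
interfaces from leaking into either tissue as a spurious spike.

Following the regulatory convention for low-frequency dosimetry, each
component of E is vector-averaged over a contiguous 2 mm cube restricted to
the voxel's own tissue before any statistic is computed.  The window side is
`round(2 mm / spacing)` voxels (2 at 1 mm, 1 — i.e. no averaging — at 2 mm);
at lattice edges the window shifts inward so that it always covers a full
cube, and for even sides the window cannot be voxel-centred, so it is
anchored one half-step forward.  Averaging each component (not the
magnitude) means opposing vectors cancel; the tissue-wise maximum can only
decrease.

Metrics, all computed on the averaged field:

* **Per-tissue statistics** of |E|: minimum, quartiles and the 99th
  percentile, the robust "peak" that filters staircase artifacts.
  Percentiles use linear interpolation on the sorted sample (the estimator
  is not standardised across platforms; this choice is explicit and tested
  against a brute-force oracle).
* **V50 / V70**: percentage of the target tissue at or above 50% / 70% of
  its own peak (≥, per the protocol definition); a focality measure.
* **Spread-to-structure**: percentage of a non-target structure strictly
  above 70% of the target-tissue peak.
* **Slice CV**: per transverse slice, 100 × population SD / mean of |E| over
  the tissue cross-section; slices with fewer than two voxels are excluded;
  segment means are unweighted over slices.
* **Longitudinal ratio R**: per voxel |E_z| / √(E_x² + E_y²) averaged over
  the slice (voxels with zero transverse field are excluded and counted;
  a slice with no valid voxel is undefined and left out of segment means).
  Whether the published ratio averages voxel-wise ratios or takes the ratio
  of slice means is not stated; both are implemented (`r_method`), voxel-wise
  is the default.
* **Cardiac safety margin**: 5 A/m² (average fibrillation threshold for
  large electrodes) divided by the heart's J peak.
* **Dose equivalence**: by linearity, the current reproducing a reference
  peak is `I · peak_ref / peak_obs`.

Scaling the injected current by k scales every statistic by k exactly and
leaves V50/V70, CV, R and spread percentages unchanged; this is verified at
machine precision.

## Synthetic phantoms

The study that motivates this package used licensed MRI-derived child
anatomies that cannot be redistributed.  The phantoms here are parametric
ellipsoid/cylinder constructions whose control parameters are the published
per-model anthropometrics, so the anatomy→field dependencies under study
(CSF shunting, occipital bone resistance, electrode–cord distance) are
preserved while the geometry is fully synthetic.  Voxelisation assigns each
voxel the label of the compartment containing its centre; generation is
bit-deterministic given spec + seed.

**Head** (ctDCS): fixed brain chamber (ellipsoid, semi-axes 54×68×62 mm)
wrapped, inside-out, in CSF (3 mm), skull and scalp (5 mm).  The skull
parameter is the *occipital maximum* thickness: the vault keeps a 6 mm base
and an outward posterior-inferior boss raises the bone under the cerebellar
electrode to the target value.  Building outward keeps the brain — and
every intracranial compartment — bit-identical across skull/CSF sweeps, so
sweeps vary exactly one thing.  Inside the brain: a posterior-inferior
cerebellum whose antero-posterior extent equals the preset length; a
cerebellar CSF shell whose thickness is bisected until the realised shell
volume matches the preset cerebellar CSF volume (±5%, or an error reporting
the achievable range); a midbrain/pons/medulla stack; an occipital-cortex
patch of the cortical shell; thalamus, hypothalamus and hippocampi; a
skin-wrapped muscle-equivalent arm stub below the head carrying the distal
return electrode.  An optional `csf_defect` fraction relabels seeded
patches of the cerebellar CSF shell to cerebellum, the first patch always
at a skull-adjacent site, emulating the segmentation gaps that put brain
and skull in direct contact.

**Trunk** (tsDCS): elliptic cylinder (semi-axes 80×55 mm) with skin (2 mm),
fat (5 mm) and muscle shells; a posterior vertebral column (bone) enclosing
a CSF sheath and the cord, segmented cervical/thoracic/lumbar/sacral with
per-segment cord radii and sheath thicknesses derived from the published
per-segment cord and CSF volumes (`r = √(V/πL)`; annulus closed form);
paired lateral nerve roots per enabled segment; an optional cauda equina
replacing the sacral cord; an optional lumbar cord interruption; a heart
ellipsoid anterior to the column.  The cervical segment sits in a narrow
neck around the column above the shoulder line (the thoracic top), and the
return patch sits on the right flank just below the shoulder line.  This
shoulder/neck geometry matters: it is what confines the stimulation current
to the thoracic tract, producing both the >80% cervical/sacral drop of the
cord field and the longitudinal field dominance (mean R > 1) at the
thoracic level.  With the cervical canal embedded in a full-width trunk
instead, one of the two observations is always lost.

Named presets carry the published per-model parameters (cerebellar AP
length 66–70 mm, cerebellar CSF volume 30.7–88.6 cm³, occipital skull
thickness 8.1–10.9 mm; segment lengths, cord and CSF volumes per segment;
one preset restricts nerve roots to the sacral tract, one interrupts the
lumbar cord and carries a cauda equina).

## Problem sizes and numerical choices

Default grid spacing is 1 mm (0.5 mm supported); the shipped analyses,
tests and the acceptance script run at 2 mm — about 2.6·10⁵ conducting
voxels for the head and 7·10⁵ for the trunk, solving in seconds to a couple
of minutes on one CPU at tolerance 1e-8.  At 2 mm the 2 mm averaging window
is a single voxel, i.e. the raw field; at 1 mm and finer the window is
effective.  Parameter-sweep steps should stay at or above one voxel:
sub-voxel steps change the voxelised geometry by scattered boundary voxels
and the resulting metric jitter (a few tenths of a percentage point in V50)
can mask the physical trend.

Degenerate inputs are rejected with specific errors: electrodes off the
skin or colliding, disconnected electrode pairs, unachievable cerebellar
CSF targets, overlapping trunk compartments, averaging windows below one
voxel, metrics on absent tissues.  Absent *optional* structures (nerves,
cauda equina, heart in the head phantom) degrade to warnings in the report
with the affected rows omitted.

## What the phantoms do and do not show

Passing tests demonstrate the solver against closed forms, every metric
against brute-force oracles, and the direction of the published
anatomy→field dependencies on phantoms: more cerebellar CSF → lower
cerebellar median |E|; thicker occipital bone → larger V50/V70; cord field
concentrated in the thoracic tract with R > 1; heart exposure far below the
fibrillation threshold.  The phantoms are smooth idealisations: no
gyrification or cerebellar foliation, a homogeneous cord without internal
structure, no lungs or abdominal organs, and a compact posterior fossa in
which the brainstem lies close to both the cerebellum and the current exit
path toward the return electrode.  Absolute field values and
tissue-by-tissue tables from licensed anatomies are therefore not
reproduced — in particular the spread of the field into the medulla is much
larger here than in realistic anatomies — and no clinical conclusion should
be drawn from phantom numbers.  Within one phantom family, trends across a
parameter sweep and ratios between segments are the meaningful outputs.
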