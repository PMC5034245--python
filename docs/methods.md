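# Methods

## The four-sub-helix model

A straight protein helix is modeled as four coaxial circular helices,
one per backbone atom type (N, Cα, C, O), sharing a single axis
(direction cosines **n** through reference point **P**), pitch *s*
(Å per 360° revolution) and angular turn per residue Ω (degrees,
positive for right-handed helices).  Atom A of residue *i* sits at

x_A(i) = P + (i·s·Ω/360 + t_A)·n + r_A·cos(i·Ω + φ_A)·a + r_A·sin(i·Ω + φ_A)·b

where (**a**, **b**) is an orthonormal frame normal to **n**
(a = normalize(n × c), b = n × a, with auxiliary c = +z, or +x when the
axis is within ~25° of ±z).  The axial rise per residue is s·Ω/2π with
Ω in radians, i.e. s·Ω/360 in degrees.  Each sub-helix carries its own
radius r_A, axial offset t_A relative to the Cα sub-helix (t_Cα ≡ 0 is
the axial gauge reference, never a free parameter) and phase φ_A at
residue index 0.

**Free parameters.** Exactly 19 scalars are exposed to the optimizer:
P (3), n (3 direction cosines normalized inside the forward model),
r_N r_Cα r_C r_O (4), s (1), Ω (1), t_N t_C t_O (3), φ_N φ_Cα φ_C φ_O
(4).  Representing the axis by its three direction cosines rather than
two spherical angles keeps the parameter count at the model's nominal
19, avoids polar singularities, and costs nothing: the unit-length
redundancy is a gauge direction that Levenberg–Marquardt handles
without difficulty, and the reported axis is re-normalized.

## Least-squares inversion

`fit_helix` minimizes the sum of squared distances between observed and
model atoms with `scipy.optimize.least_squares` (method "lm", ftol =
xtol = gtol = 1e-15, at most 2000·20 function evaluations).  Angles are
radians inside the optimizer and degrees everywhere else.  The starting
point is deterministic, so fits are reproducible without any seed:

- axis: principal axis of the Cα covariance, oriented from first to
  last residue; refined estimates of Ω and the rise from the slopes of
  the unwrapped Cα azimuth and of the Cα axial coordinate versus
  residue index (each clipped to a plausible range, falling back to the
  α-helical 100°/residue and 1.5 Å);
- radii from mean transverse distances; phases and axial offsets from
  closed-form circular/linear regression at the initial axis;
- P on the axis such that the initial t_Cα is exactly zero.

**Canonical gauge.**  The converged parameter vector is re-expressed by
exact algebra on the model coordinates, which makes the result immune
to whatever sign or branch the optimizer converged into: the axis is
oriented N→C; phases are measured in the deterministic basis frame of
the reported axis with residue index 0 at the segment's first residue
and wrapped to [−180°, 180°); negative fitted radii are absorbed into
phases; P is placed on the axis in the plane of the i = 0 Cα sub-helix
position, the only axial location compatible with t_Cα ≡ 0 and the
fixed index origin.  A converged fit with negative twist is a
left-handed helix; it is reported with Ω < 0 and flagged rather than
silently re-oriented.

Preconditions and failure modes: at least 5 complete residues
(12 coordinates per residue against 19 parameters makes 2 the algebraic
minimum; 5 gives a stably overdetermined fit); residues missing any
backbone atom are dropped with a warning, never imputed (imputation
would bias radii and phases); collinear inputs (second singular value
of the centered coordinates below 1e-6 Å) are rejected; optimizer
non-convergence returns the best-so-far parameters with
`converged=False` and is never silently accepted.

Residue indices keep author-numbering gaps where residues were dropped,
so phases stay registered modulo the helical repeat.  When insertion
codes make author numbers non-monotonic the extractor falls back to
sequential indices with a warning.

## Twist from backbone dihedrals

The classical relation for an ideal trans backbone,

cos Ω = −(1 + 2·cos(φ + ψ)) / 3,

maps a residue's dihedral pair to an angular turn.  It places the three
ideal forms on dihedral-sum lines: Ω = 120, 100, 80 °/residue at
φ+ψ = −75.5°, −103.9°, −139.5°.  The relation is approximate — it
assumes fixed ideal bond geometry — so the package treats 3 °/residue
as its accuracy envelope; the independent cross-check in the test suite
(build a backbone from repeated dihedrals by internal-coordinate chain
extension, fit the sub-helix model, compare twists) agrees within that
envelope.  Helix forms are classified from Ω by nearest ideal value
with boundaries at the midpoints 110 and 90 °/residue, ties resolving
to α (the overwhelmingly common form), and anything outside
[70, 130] °/residue reported as "other".

## Interhelix geometry and state-to-state motions

- *Angle*: between oriented (N→C) axes, reported in [0°, 180°).  Users
  preferring the crystallographic crossing-angle convention can fold
  values above 90°.
- *Distance*: length of the common perpendicular between the infinite
  axis lines.  If either foot falls outside the axial span of the
  fitted atoms, the closest approach between the finite segments is
  reported instead and flagged `clamped`.  Axes within 0.1° of parallel
  use point-to-line distance.
- *Torsional position*: circular mean of the four sub-helix phases.
- *State motion*: structure 2 is rigidly superposed onto structure 1
  (Kabsch, on the Cα atoms of a caller-chosen reference selection; the
  selection is recorded in the output, because no universally correct
  frame exists — the default is all configured segments, but a
  selection excluding the moving helices isolates their motion best).
  Phases of both states are then measured in the common frame built
  from the state-1 axis, projecting each state's sub-helix radial
  vectors onto the plane normal to that axis; ΔΩ = Ω₂ − Ω₁; sliding =
  (P₂ − P₁)·n₁, positive toward the C-terminus.  Gear-like relative
  torsion of a helix pair is the difference of the two helices'
  per-helix phase changes, which cancels any common-mode rotation left
  by the superposition.
- *Differential winding* of two segments of one helix is the signed
  first-minus-second difference of their fitted Ω.

Bent helices are out of scope for a single fit by design: callers split
the range and fit each part (the kink fixture demonstrates the
diagnostic signature — full-range rmsd at least 5× the half-range
rmsds).  There is no automatic kink detection.

## Spiral diagrams

Each residue is represented by the average of its four backbone atoms.
Its observed phase is the azimuth of that point's projection onto the
plane normal to the fitted axis; the fitted phase advances by exactly Ω
per residue (the four-atom average inherits the helical rotation
exactly).  Both series are offset so the fitted first residue lies at
0° on the horizontal axis.  Plotting radius grows linearly,
1.0 + 0.18 per residue (a display constant, not data), and colors cycle
black/red/green/blue.  Observed dots are solid, fitted circles open;
their coincidence is the goodness-of-fit display.  SVGs are rendered
with a fixed hash salt and no date metadata, so identical inputs give
byte-identical files.

## Synthetic fixtures

The generator shares the forward model with the fitter — one
implementation, so generator/fitter tests cannot drift apart.  Canonical
per-form constants (radii, offsets, phases) were derived once by
building ideal backbones from repeated canonical dihedral pairs —
3/10 (−49°, −26°), α (−57°, −47°), π (−70°, −69.5°) — via
internal-coordinate chain extension with standard bond lengths and
angles (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O 120.8°; ω = 180°),
fitting the model, and rounding; twist and pitch are then pinned to the
ideal values (Ω = 120, 100, 80 °/residue; s = 6.0, 5.4, 2.7 Å).  The
resulting forms reproduce the qualitative contrasts of real helices
(the π form ~1.4 Å wider in diameter than α, the 3/10 form tighter);
the π form, anchored to the −139.5° dihedral-sum line, is axially more
compressed than crystallographic π helices, which cluster at somewhat
larger twists.  These constants are test inputs chosen for internal
consistency, not measurements.

Default fixture conditions: 18 residues per helix, noise-free unless a
σ is requested (isotropic Gaussian per coordinate, seeded), α form.
Noise of σ = 0.1 Å with 100 replicates is the parameter-recovery
condition exercised by the acceptance tests (mean twist error
< 0.3 °/residue).  Two-state bundles place seven helices on a 12 Å
ring, axes parallel, residue ranges 100·k+1 onward in one chain, with
programmed per-helix changes (ΔΩ, axial shift, axis rotation, rigid
moves, tilts, kinks) recorded in a ground-truth JSON together with the
recommended superposition reference (the helices programmed to be
identical in both states).  All randomness flows from explicit seeds;
the same spec and seed give byte-identical PDB files.

What the fixtures do **not** emulate: side chains, sequence effects,
thermal anisotropy, crystal contacts, coordinate error correlated along
the chain, or genuinely curved helix axes.  Passing recovery tests on
these fixtures therefore demonstrates the correctness and numerical
behavior of the estimator and pipeline, not the accuracy achievable on
experimental structures, where coordinate error is structured and
segment boundaries are a modeling choice.

## Numerical choices and limitations

- Fit tolerances 1e-15 (relative cost/step/gradient); canonical-gauge
  algebra is exact, so round-trip recovery reaches machine precision.
- PDB output quantizes coordinates to 1e-3 Å; fits from files inherit
  that floor.
- Circular means use the vector (arctan2) definition; an exactly
  antipodal phase set has an undefined mean but cannot arise from four
  backbone phases of a real fit.
- Classification boundaries and the 0.1° parallel-axis threshold are
  conventions, stated above, not fitted quantities.
- Survey problem sizes in the shipped tests (≤ 7 helices × 2 states ×
  18 residues) were chosen as the smallest bundles that exercise every
  motion component; each least-squares fit takes ~40 ms, so surveys of
  hundreds of real chains are cheap.
- The rhodopsin segment/group configuration ships as an editable
  template: only the two middle segments (207–215, 294–301) are pinned
  by published ranges, and group membership is user-supplied
  configuration by design, since functional grouping is an expert
  judgment, not a computation.
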