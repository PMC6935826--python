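# Methods

`spineload` predicts lumbar intervertebral joint resultant forces and trunk
muscle-group activities over activity cycles (level walking, stair
climbing, trunk flexion) from spinal marker kinematics, and simulates two
interventions for patients with an altered spine rhythm: *rehabilitation*
(replacing the subject's spine rhythm with a healthy reference rhythm) and
*reconstruction* (relocating the L5S1 center of rotation).  This note
documents the model, its assumptions, the numerical choices, and what the
synthetic study conditions do and do not establish.

## Mechanical model

The spine is a serial rigid-body chain: pelvis, five lumbar vertebrae
(L5…L1), and one lumped thoracic segment (trunk above L1 plus head and
arms), linked by six spherical joints (L5S1 … T12L1) that stand in for the
intervertebral discs.  Coordinates are right-handed with X anterior, Y
superior, Z to the subject's left; the sagittal plane is X–Y and a positive
segment angle is an anterior lean (flexion).  Internally everything is in
metres, newtons and newton-metres; marker files are in millimetres and COR
offsets at the user surface are in millimetres.

A deliberate sign wrinkle: flexion *angles* are measured about the
anatomical flexion sense while *moments* use the mathematical +Z axis, so
extension moments are positive z.  By virtual work a fascicle's sagittal
moment arm then equals `+dL/dθ` (tendon excursion), which the test suite
checks against the geometric arms at 1e-6 m.

Trunk muscles are straight-line tensile-only fascicles, grouped into the
17 functional groups a trunk model conventionally reports: rectus abdominis
plus left/right pairs of erector spinae, lumbar multifidus, thoracic
multifidus, obliquus externus, obliquus internus, psoas major, quadratus
lumborum and semispinalis.  The packaged default geometry (54 fascicles) is
invented plausible adult-male anthropometry — segment mass fractions
(thorax lump 0.42, 0.011 per lumbar vertebra), 42 mm joint spacing,
attachment coordinates and strengths are *not* measurements, and the config
header says so.  Two structural features matter more than any individual
number:

* every lumbar vertebra has at least one posterior (multifidus) and one
  anterior (segmental psoas slip) insertion, so the sagittal moment at each
  joint is independently controllable — without this the six coupled
  equilibrium equations are structurally infeasible;
* the quadratus lumborum carries segmental lateral slips to every lumbar
  level, which plays the same role for frontal-plane balance in 3-D mode.

No wrapping surfaces, via points, ligaments, facet contact, intra-abdominal
pressure, or muscle dynamics (activation or force–length–velocity) are
modelled.

## Kinematics and the spine rhythm

Markers sit on T3, T7, L1, L3, L5, the two PSIS and the iliac crest,
sampled at 100 Hz, with a ≥5 s neutral-standing baseline.  Sagittal
orientations come from marker chords, all zeroed on the baseline mean:
pelvis from the IC-to-mid-PSIS chord, thorax from T7→T3, and three lumbar
chords (IC→L5, L5→L3, L3→L1).  Chord rotations are attributed to joints as
follows: IC→L5 spans L5S1; L5→L3 spans L4L5+L3L4; L3→L1 spans L2L3+L1L2;
the thorax chord closes T12L1.  Within a two-joint chord the split is a
declared convention (default equal, configurable), because three lumbar
markers cannot observe six joints: the marker measurement has four
independent rotations, and the equal split is the projection onto that
observable subspace.  Consequences, verified by tests:

* chord sums (L4L5+L3L4, L2L3+L1L2), L5S1, T12L1 and the total angle are
  recovered exactly from noise-free markers;
* a generating rhythm with unequal within-chord splits is recovered as its
  chord projection; with the true split weights supplied it is recovered
  exactly;
* exact recovery of arbitrary rhythms is established on the generator's
  ground-truth joint angles, which bypass the marker bottleneck.

The spine rhythm is the per-frame fraction of the total
thorax-relative-to-pelvis angle carried by each joint, masked where the
total is below 2° (fractions are ill-conditioned near zero motion; the
threshold is configurable) and summarised as the mean over unmasked frames.
Fractions of the baseline-referenced angle are used (not of angular range).
Rhythm substitution rescales each frame's joint angles to `total × target
fraction`, leaving the pelvis trajectory and the total motion unchanged to
machine precision.

## Loads and recruitment

Analysis is quasi-static: for each joint, the superincumbent segments'
weight and its moment about the joint center form the demand.  An optional
flag adds d'Alembert terms from central-difference COM accelerations
(point masses, no angular inertia); it is off by default because trunk
accelerations in gait contribute little and the baseline treatment is
cleaner to validate.  A per-frame external moment input exists as a simple
handle for task asymmetry (used by the stair template's frontal term).

Muscle forces solve the min-max recruitment problem

    minimize β  s.t.  Σ_i r_ij f_i = −M_j ,  0 ≤ f_i ≤ β N_i ,

with one balanced axis per joint by default (sagittal z; a flag adds the
frontal x axis; axial twist is never balanced — the near-vertical fascicle
set has negligible twist capacity and the drivers carry no twist demand).
Because the plain min-max optimum leaves sub-maximal forces non-unique, the
solution is made lexicographic by saturate-and-resolve: solve the LP
(scipy's HiGHS), freeze the fascicles saturated at β·N *at the LP's own
values* (substituting exact β·N would leak the LP tolerance into the
equality residual), move them to the right-hand side, and re-minimize the
maximum over the remainder until no activation is left.  Saturation is
detected at `a_i ≥ β − 1e-7`; every solved frame must pass a moment
residual gate of 1e-6·(1+‖M‖∞) or it is reported infeasible.  Activations
above 1 (overload) are allowed with a logged warning rather than an error,
since activities are compared across conditions, not clipped.  The final
free fascicles take the deterministic HiGHS basic solution; on every random
system tested the lexicographic solution is already unique, so no extra
minimum-norm pass is applied.

The solver is validated against a fully independent oracle
(`tests/_minimax_oracle.py`) built on the support function of the
achievable-moment zonotope: the minimax level is the zonotope gauge
`max_u (u·b)/h(u)`, and the lexicographic force vector follows the
classical level recursion with forced-fascicle detection by per-coordinate
cap-reduction feasibility — no linear programming anywhere in the oracle.
Agreement on 200 seeded random toy systems is within 1e-6 in β and 1e-3 N
in every force (observed: ~1e-15 and ~1e-6).

Joint resultant force at a joint is the full 3-D reaction from force
balance of the superincumbent body (gravity plus the pulls of every
crossing fascicle), reported as magnitude in newtons and normalized to body
weight (BW).  Group activity is the max fascicle activation within the
group per frame (a strength-weighted mean is a config alternative); the MMA
is the maximum of the 101-point normalized activity curve.

## Cycles and normalization

A gait cycle runs from one heel strike to the next of the same leg; events
are annotations (the generator writes them; no detection is attempted).
When several cycles exist the first is used by default; a cycle index can
be selected everywhere, and `fit_cycles`/`average_cycles` fit every
complete cycle and average the normalized output curves (the
average-the-outputs convention for repeated trials), with MMAs taken from
the averaged activity curves.  Solving happens on
the raw frames of the cycle; all outputs are then linearly interpolated
onto the 0–100 % grid with 101 points.  Linear interpolation is monotone
and overshoot-free, and at 100 Hz its error against a band-limited signal
is far below the solver tolerances (checked at <1e-3 of amplitude against
an analytic sine).

## Interventions

*Rehabilitation* re-solves the same subject on rhythm-substituted
kinematics with the unchanged model.  *Reconstruction* re-solves the
subject's own kinematics on a model whose L5S1 center is translated in the
sagittal plane of the sacral frame; relocating the center carries the
entire superincumbent chain with it, which slightly tilts fascicle lines in
addition to changing their lever arms (the pure-translation lever change is
tested separately with frozen geometry).  Improvement is `before − after`
at each of the 101 points, in BW; MMA deltas likewise.  A "combined" mode
(both at once) exists but is exploratory: the interaction of the two
interventions is outside the validated surface.

The COR candidate grid spans ±10 mm anterior–posterior × ±10 mm
superior–inferior at 1 mm steps (441 candidates), each driven through a
0→45° smoothstep trunk-flexion ramp under the uniform default rhythm.  A
candidate's score is the cycle-mean of the summed BW-normalized resultant
forces at L3L4+L4L5+L5S1; "significantly decreased" cannot mean a
statistical test over one deterministic simulation, so the minimal score
with deterministic tie-breaks (smallest Euclidean offset, then
lexicographic (ap, si)) selects the offset, and the full 441-row score map
is emitted so users can apply their own criterion.  Infeasible candidates
score +∞ and are logged, never fatal.  On the default geometry the search
selects an anterior–inferior offset (longer extensor levers and a smaller
flexion demand both lower the score); the package reports its own selection
and makes no claim about any particular published choice.  The
posterior-shift mechanism — shorter extensor lever, strictly larger muscle
force and compression at fixed demand — is verified on the closed-form
single-extensor case and as a direction test on the full model.

## Synthetic study conditions

The generator emulates the recording protocol without any recorded data.
Activity templates drive the total lumbar angle with low-order harmonics:
level walking 8° ± (4°, 1.5°) over 1.1 s; stair climbing 15° ± (8°, 3°)
over 1.4 s plus a 5 Nm frontal-moment amplitude; three cycles per
recording; amplitudes are invented-plausible and configurable.  Group-mean
rhythms are likewise invented: healthy (0.28, 0.24, 0.18, 0.13, 0.10, 0.07)
and LDH (0.38, 0.30, 0.14, 0.09, 0.06, 0.03) across (L5S1 … T12L1) — the
modelled condition is that patients concentrate a larger share of the total
rotation at the lower lumbar levels.  Mechanically, hinging lower displaces
the superincumbent COM further, raising lower-lumbar moments; substituting
the healthy rhythm therefore lowers the lower-lumbar loads, and this
direction is pinned by seeded regression tests, not asserted as an external
quantity.  Cohort masses and heights are drawn from adult-male group
statistics (63.5 ± 8.4 kg healthy, 67.4 ± 5.3 kg patients); per-subject
rhythms add Gaussian jitter (SD 0.02) renormalized to the simplex.

Randomness: one integer root seed feeds numpy's PCG64 `default_rng`; cohort
generation draws one child seed (< 2³¹) per subject, each owning an
independent generator, so outputs are bit-reproducible per subject and
cohorts are extensible without disturbing earlier subjects.

What passing tests show — and what they do not.  The synthetic markers are
rigid-chain consistent with the extraction convention, carry ideal events,
and have isotropic Gaussian noise at most; real recordings add soft-tissue
artifact, marker misplacement, event-detection error and out-of-plane
motion, none of which are modelled.  Tests on these conditions establish
internal correctness (recovery, equilibrium, oracle agreement, null-
intervention zeroing, direction properties), not agreement with in-vivo
loads.

## Problem sizes and performance

Default problem sizes: 101-point cycles solved from ~110–140 raw frames per
activity (one LP lexicographic solve per frame, ~2–6 ms each); the full
441-candidate grid uses an 11-frame flexion ramp (the ramp is smooth enough
that the mean-force score is insensitive to the frame count) and completes
in about a minute on one core.  The oracle comparison runs 200 toy systems
in a few seconds.

## Known limitations

* Straight-line fascicles and a single lumped thoracic segment are strong
  simplifications; absolute force magnitudes depend on the invented
  geometry and should be read comparatively (before vs after), which is
  also how the intervention reports are framed.
* The marker convention's observability limit (equal-split projection)
  biases per-joint fractions whenever true within-chord splits are uneven;
  noisy markers additionally bias the fraction ratio (noisy angle over
  noisy total), shrinking with noise level as the tests document.
* The COR score uses joint resultant forces only; facet, ligament and
  intradiscal quantities are not modelled and so cannot enter the
  criterion.
* Statistical comparison between groups is out of scope; cohort tables are
  descriptive (pointwise mean ± SD).
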