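# Methods

This note documents the models, numerical choices and limitations of
`gaitstress` in enough detail to judge what its tests do and do not show.

## Multibody model

The skeleton is a tree of planar rigid segments connected by hinge joints
(pure flexion–extension), with the trunk as the floating root.  Coordinates:
x forward, y up, angles counterclockwise-positive; each segment frame sits at
its proximal joint, and a joint angle of zero means parallel parent/child
frames.  All units are SI.

Dynamics are formulated in generalized (reduced) coordinates — three
floating-base coordinates plus one angle per hinge — so hinge anchor
coincidence holds exactly at every step rather than to a solver tolerance.
The equations of motion are assembled from centre-of-mass Jacobians,

    M(q) q̈ = Q_applied + Jᵀ m (g − a_bias),

where `a_bias` collects the centripetal accelerations (in a planar tree there
are no gyroscopic torques), and solved directly (≤ ~15 unknowns for the
bipeds shipped here).

**Integration** is fixed-step semi-implicit (symplectic) Euler:
`v ← v + dt·a`, then `q ← q + dt·v`.  This pairs well with stiff spring
contacts and keeps the energy of passive systems bounded rather than
secularly drifting; the pendulum tests verify < 0.1% energy drift over 10 s
at the default `dt = 1e-4 s`.  The biped fixtures run at `dt = 2.5e-4 s`
(`fixtures.toy_sim_config`), sized to the stiffest elements in those models
(contact springs and the force–velocity slope of strong, short-fibred
muscles).  Velocity-dependent muscle and contact forces are evaluated
explicitly, which is what bounds the usable timestep.

**Ground contact.**  Spheres attached to the feet act as one-sided
spring-dampers: normal force `max(0, k·δ + c·δ̇)` under penetration δ, zero
otherwise, so feet lift freely and the ground never pulls.  Tangential force
is regularised Coulomb friction, `−μN·tanh(v/v_reg)` with `v_reg = 0.02 m/s`,
to avoid the discontinuity at zero slip.  Fixture defaults set k for ~1–2 cm
static penetration at body weight and damping near half-critical.  Deformable
substrates and toe-off rolling geometry are not modelled.

**Joint limits** are one-sided torsional spring-dampers at the ends of each
range.  Requested stiffness defaults to `2·m_total·g` N·m/rad; per joint,
stiffness and damping are capped by the subtree inertia at the build pose
(`k ≤ 0.05·I_sub/dt²`, `c ≤ min(√(k·I_sub), 0.25·I_sub/dt)`) so the stops
cannot destabilise light distal segments at the configured timestep.  These
caps are numerical guards, not biomechanical claims.

**Falls** terminate a run when mean hip height drops below 50% of its
standing value (configurable).  Divergence (non-finite accelerations) is a
distinct termination cause and is scored as zero distance by the optimiser.

## Muscle–tendon actuators

Muscles are polyline paths of way-points fixed in segment frames (no wrapping
surfaces); path length is the summed straight-line distance, and moment arms
are −dL/dq by central difference (step 1e-5 rad), which the tests reconcile
against the engine's generalized forces via virtual work to 1e-6.

Force generation is Hill-type with the stiff-tendon approximation: fibre
length = path length − tendon slack; active force
`a·f_max·f_L(l̂)·f_v(v̂)` with a unimodal parabolic `f_L` (half-width 0.5,
`f_L(1)=1`), a Hill hyperbola `f_v` (`f_v(−1)=0`, `f_v(0)=1`, eccentric
plateau 1.5), plus passive fibre elasticity (quadratic above optimal length,
capped at 1.5·f_max); total force is clamped nonnegative and is zero whenever
the path is shorter than the tendon slack length.  An elastic series tendon
is deliberately not solved for: at these model scales the stiff-tendon
simplification is standard, and every property the rest of the package
relies on (bounded nonnegative force, correct isometric and limiting-velocity
behaviour) holds.  Maximum isometric force is either given explicitly or
derived from muscle mass via PCSA = mass/(density·fibre length) with density
1060 kg/m³ and specific tension 0.3 MPa.  Activation follows a first-order
lag (default τ = 50 ms), integrated exactly per step.

Fibre and tendon lengths are tuned from the joint-excursion range: all
crossed joints are swept on a 64-point grid per joint (8 when a muscle
crosses more than two), the optimal fibre length is a configurable fraction
(default 0.5) of the MTU length change, and tendon slack is the mid-range
length minus the fibre length.  The biped fixtures then re-slacken tendons so
the build (standing) pose is force-free — a fixture design choice that makes
quiet standing a meaningful stress baseline.

## Bone load recovery and stress

A monitored segment is split at its functional mid-point (default 50% of the
bone axis) into two bodies joined by a weld.  Mass is divided as a uniform
rod along the bone axis through the segment COM, with any excess of the true
inertia over the rod value shared by mass, so the halves recombine exactly to
the original mass, COM and inertia.  In the engine, welded bodies are
compiled into one composite link — split and unsplit models therefore produce
identical trajectories up to floating-point roundoff — and the transmitted
load is recovered by a backward Newton–Euler pass using the full dynamic
solution.  Cut loads are reported in the bone frame: axial force
(tension-positive), shear, and the bending moment about the out-of-plane
axis, which maps to the section x-axis (`M_y = 0` by planarity).

Cross-sections are closed polygon outlines.  Properties (A, centroid, Iₓ,
I_y, I_{xy}) come from exact Green's-theorem formulas; hollow sections offset
the outline inward by `cortical_fraction × mean external radius` (shapely
negative buffer; collapse points dropped; a fraction of 1, or an offset that
consumes the interior, yields a solid section).  Outer boundaries are
densified to ≥ 128 vertices so vertex evaluation resolves the extreme fibre.
Peak stress is the extremum over outer-boundary vertices of
`F/A + bending(x, y)` with the product-moment bending formula, valid for
arbitrary asymmetric sections; tension is positive and the fail metric is
`max(|σ_max|, |σ_min|)`.  Where one monitor carries several bones (tibia +
fibula), the axial force is shared in proportion to area and the bending
moment in proportion to Iₓ — an equal-curvature (parallel-beam) assumption.

Stress traces are filtered with a causal 2nd-order Butterworth low-pass at
5 Hz, state-initialised to the first sample so a constant trace passes
unchanged; filtering compensates for the absence of soft-tissue cushioning in
a rigid-body model.  The monitor runs online at the recording rate (≥ 500 Hz
in the shipped configurations) and a zero-phase (forward–backward) mode is
available for post-hoc analysis.  The fail test triggers at the first
recorded sample whose filtered |σ| exceeds the limit; the monitor is purely
observational, so raising the limit beyond reach reproduces the
unconstrained trajectory bit for bit.

## Controllers and optimisation

Controllers are cyclic: per muscle, 8 activation levels over equal phases of
a cycle whose duration is itself a gene (bounds 0.3–1.5 s).  Left–right
symmetry is on by default: right-side muscles replay the left pattern delayed
half a cycle, halving the genome.  Fitness is horizontal COM distance at
termination (full duration, fall, or stress-fail), clamped at zero; early
termination is its own penalty.  The optimiser is a generational GA —
tournament of 3, blend crossover, per-gene gaussian mutation clipped to
[0, 1], elitism of 1 — fully deterministic for a fixed seed.  Stress-limit
sweeps proceed from the most permissive limit downward, seeding each search
with the previous best plus bounded perturbations (gait morphing).

Problem sizes used by the shipped checks are deliberately small: the toy
biped (6 muscles per limb, 80 kg, 1 m legs) with populations of 8, 4–5
generations, 3 seeds and 3 s evaluations.  These searches demonstrate the
machinery — the monotone dependence of best speed on the stress limit, with
the heavily limited gait strictly slower — not converged optima; finding
polished gaits takes orders of magnitude more evaluations than a test suite
should spend.  Stress limits for the toy sweep (8 / 20 / 200 MPa) were
chosen relative to its quiet-standing stress (~2–6 MPa filtered): the low
limit is barely above standing so vigorous motion trips it, the high limit is
effectively unconstrained.

## Gait analytics

Duty factor is the fraction of a gait cycle a limb produces ground force,
averaged over complete cycles delimited by successive touchdowns of the same
foot; contact requires normal force above 0.1% of body weight to suppress
chatter.  Froude number is `v²/(g·h)` with h the standing hip height (the
quadratic convention, so 1.0 marks the inverted-pendulum walking ceiling).
Stride length is forward COM displacement per cycle.  The energy phase
statistic is the lag, as a percentage of the cycle folded into [0, 50], that
maximises the cross-correlation of the mean-removed horizontal kinetic and
gravitational potential energy series; cross-correlation between the two
series is the operation that yields a between-signal phase.  Classification:
any sampled instant with no foot contact ⇒ aerial run; otherwise phase ≥ 25%
(configurable) ⇒ walk, else grounded run.

## Fixtures and synthetic data

The fixture module generates every test input deterministically: pendulum and
double-pendulum rigs (closed-form period, chaotic energy conservation), a
drop test (static penetration `m·g/k`), cantilever rigs (statics oracles for
cut loads), a toy biped, and a tyrannosaur-scale biped.  The toy biped uses
explicit, stability-friendly muscle strengths (multiples of body weight per
functional group) and joint stops that passively support standing; the
tyrannosaur-scale fixture applies the full construction pipeline — total mass
7206.7 kg, 50% muscle mass allocated over a flexor/extensor ×
proximal/intermediate/distal table, hull-scaled inertias, hollow sections
with the published cortical wall fractions — to simplified box/ellipse
geometry.  Both are geometric stand-ins: limb mass fractions and the
muscle-allocation table are documented defaults patterned on running-bird
data (the primary sources do not print the values), and no fixture claims
anatomical fidelity to a specimen.  A synthetic replica of a published
simulator model file (15 bodies, 58 hindlimb muscles, hinge joints, foot
spheres) exercises the importer; it is labelled synthetic and is not the
published supplementary file.

Passing tests therefore show that the mechanics, load recovery, stress
fields, filtering, search machinery and analytics are implemented correctly
and behave as the theory predicts on models of this class; they do not
validate anatomical reconstructions, absolute speed predictions, or the
behaviour of the full-scale published model.

## Known limitations

* Planar (parasagittal) dynamics only; no long-axis rotation or mediolateral
  mechanics, so `M_y` at a cut is identically zero.
* Straight-line muscle paths without wrapping; moment arms degrade at extreme
  flexion.
* Stiff-tendon muscles: no series elastic energy storage, which biases
  against bouncing gaits that exploit tendon recoil.
* Beam theory at a single mid-shaft station; no finite-element stress field,
  no torsional shear.
* Explicit treatment of velocity-dependent forces bounds the timestep; very
  strong, short-fibred muscles on light segments require smaller `dt`.
* The GA is a baseline search; it demonstrates constraint behaviour, not
  globally optimal gaits.
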