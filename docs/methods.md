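# Methods

This note documents the models, numerics and design choices behind
`rvimap`, in the spirit of a solver's methods appendix: what is computed,
under which assumptions, and what the synthetic test bed does and does not
establish about real mapping data.

## The RVI metric and its map constructions

For recording sites *i*, *j* with defined activation times, *j* is a
*downstream neighbor* of *i* if AT(j) > AT(i) strictly and the Euclidean
distance between the electrodes is at most the search radius *R*.  The
pairwise index is RVI(i, j) = RT(i) − AT(j).  Ties in activation time are
excluded from the downstream relation (a simultaneous pair carries no
front/tail ordering).  Undefined sites — scar electrodes, sites without
capture — never enter a pair and are reported as "no value"; they are never
imputed.

Three interpolation schemes produce a map:

* **nearest_neighbor** (node-indexed): each pair's value is deposited on
  the mesh node nearest the arithmetic midpoint of the two electrodes
  (nearest-node ties broken by lowest node index); nodes receiving several
  pairs take the mean.
* **average** (electrode-indexed): mean of the pairwise values of site *i*.
* **minimum** (electrode-indexed): minimum of the pairwise values —
  maximally sensitive, and the only scheme that is monotone in *R*
  (enlarging *R* adds pairs, so per-site values can only decrease).

The *vulnerable region* is the set of sites with value strictly below a
threshold, 50 ms by default; its size is the sum of per-site nodal areas
(interior nodes of the regular grid own one full cell `resolution²`,
edge/corner nodes the clipped share, so areas tile the sheet exactly).
Sparse catheter grids additionally report the sub-threshold electrode
count, which is the meaningful quantity when per-electrode areas are not
defined.

Distances are Euclidean in the embedding space; geodesic surface distances
for strongly curved anatomies are out of scope.  The implementation is
KD-tree based but is required by the test suite to agree *exactly* with a
naive O(n²) re-implementation on random electrode sets, for all three
schemes.

## Idealized infarct geometry

A W × H sheet (default 40 × 40 mm) is discretized at `resolution`
(default 0.2 mm; 200 × 200 quadrilaterals, 201 × 201 nodes).  Nodes are
labeled:

* **SCAR** — inside the disc of `scar_radius` (15 mm) around the center,
  excluding an open straight band of width `isthmus_width` (4 mm) through
  the center along `isthmus_axis` (vertical by default).  The band cuts the
  disc into two scar segments separated by a conducting channel.
* **BZ** — every non-scar node within `bz_radius` (15.5 mm): the channel
  interior (the isthmus) plus the 0.5 mm transition rim around the scar.
* **MYO** — the remainder.

Labeling is node-wise; the scar is treated as necrotic, i.e. purely as a
no-flux obstacle (see below).  On the default lattice the scar-to-scar gap
across the channel and the rim width are reproduced to within one grid
step.

Recording grids: a high-density grid (every non-scar node), a linear
decapolar catheter whose "2-8-2 mm" shorthand is expanded to the explicit
9-gap sequence 2,8,2,8,2,8,2,8,2 (bipolar pairs 2 mm apart, 8 mm between
pairs), a fan of such catheters sharing an origin (each arm includes the
origin electrode; the published fan geometry is not specified, so arms are
freely configurable), and random multipolar clusters: cluster centers drawn
uniformly without replacement from the mesh nodes, each cluster a seeded
uniform sample of ⌈fraction · |ball|⌉ nodes within 1.5 mm (defaults: 50
clusters, 5%).  Electrode-to-host-node attachment is nearest-neighbor with
lowest-index tie-breaking and is verified against brute force.

## Tissue model

### Governing equations

The monodomain reaction–diffusion model is solved with explicit
operator-split time stepping.  With bulk conductivity σ (isotropic,
default 0.068 S/m), surface-to-volume ratio β = 0.14 µm⁻¹ and membrane
capacitance Cm = 1 µF/cm² (standard value), the voltage diffusivity is
D = σ/(β·Cm) ≈ 0.0486 mm²/ms.  The spatial operator is a 5-point
finite-difference Laplacian with harmonic-mean face conductivities on the
regular grid — equivalent to bilinear finite elements at this resolution —
with zero-flux sheet edges.  Scar nodes carry zero conductivity, so every
face touching scar transmits no flux: the scar is an internal no-flux
boundary.  With the membrane switched off this operator conserves the
spatial mean of the voltage to round-off, which the test suite checks.

### Ionic model

Membrane kinetics use a two-variable phenomenological model of the
Mitchell–Schaeffer family for the normalized voltage u ∈ [0, 1]
(Vm = −80 mV + 100 mV · u) and a recovery gate h:

    du/dt = h u²(1−u)/τ_in − u/τ_out + J_stim + diffusion
    dh/dt = (1−h)/τ_open   (u < u_gate),   −h/τ_close   (otherwise)

Defaults: τ_in = 0.2 ms, τ_out = 6 ms, τ_open = 80 ms, u_gate = 0.13.
The model has an explicit APD restitution — APD increases monotonically
with diastolic interval and scales almost linearly with τ_close — which is
what the RVI protocol needs from a membrane model, since the mapping
algorithm consumes only AT/RT.

**Border-zone remodelling.**  The down-regulation of repolarizing currents
in surviving border-zone myocytes is represented by two per-region
scalings:

* `bz_apd_prolongation` (default 1.725) multiplies τ_close, prolonging the
  BZ action potential;
* `bz_refractory_prolongation` (default 4.0) multiplies τ_open, prolonging
  BZ post-repolarization refractoriness.

The second factor is essential, not cosmetic.  In a two-variable model a
wavefront that meets refractory tissue does not die the way it does with
full ionic kinetics: the depolarized plateau behind the front keeps
sourcing current, and as soon as the gate ahead recovers the stalled front
re-ignites, so APD prolongation alone converts "conduction block" into
"delayed conduction".  Prolonging the BZ gate-recovery time separates the
two outcomes: a premature beat at coupling interval 220 ms arrives while
the gate is still closed and the proximal sources have repolarized (true
block, with subsequent re-entry around the scar and through the distal
isthmus mouth), while at 250 ms the gate recovers in time and the beat
captures everywhere, with conduction merely slowed inside the isthmus.
The default value 4.0 was chosen as the midpoint of the regime in which
the model reproduces both outcomes; at substantially larger values the
steady S1 train itself begins to drop beats in the border zone.

### Calibration

`calibrate_ionic_params` adjusts τ_close per region so that the APD
measured at the middle of a paced 1D strip (20 mm, three beats at the
target BCL) hits the regional target; a plane wave on the sheet reduces
exactly to the strip equation, so strip calibration transfers to the 2D
model.  The iteration is a damped proportional fixed point (APD is monotone
and nearly proportional to τ_close), deterministic, converging in a
handful of strip runs; parameters already within tolerance are returned
unchanged.  The shipped defaults correspond to targets of 176 ms
(myocardium) and 229 ms (border zone) at BCL 500 ms; on the full sheet the
steady-state means land at ≈ 179 ms (MYO) and ≈ 227 ms (isthmus),
within the targets' quoted spreads — the residual offsets come from
boundary effects and the mouth regions.

### Pacing, stimulus and numerics

The S1–S2 protocol delivers `n_s1` = 3 beats at BCL 500 ms and an optional
premature S2 (default coupling 220 ms).  The stimulus is a transmembrane
current (0.6 /ms in normalized units, ≈1.5× diastolic threshold) injected
for 2 ms into a 2 mm strip along the bottom sheet edge; the protocol can
also stimulate an explicit node set.  Simulated time defaults to
n_s1·BCL + CI + 800 ms, long enough to capture the single re-entrant
cycle.  The default step is dt = 0.02 ms, checked against the explicit
diffusive stability bound dt ≤ dx²/(4D) before running; halving dt moves
activation times by well under 1 ms.  Divergence (non-finite voltage)
aborts with the failure time.

Markers are captured online at every node: per beat window (stimulus onset
to next onset; the S2 window extends to the end), AT is the first upward
crossing of −20 mV, located by linear interpolation within the step, and
RT the first downward crossing of −70 mV after that AT.  A repolarization
still pending when the next window opens (the premature beat arrives before
the previous beat's RT at long-APD sites) is assigned to the beat that
activated it.  Under re-entrant double activation the first arrival defines
the S2 AT.  Beat-relative times are canonical; absolute times are
recoverable through the window onsets.  Voltage traces at recording
electrodes are sampled at 1 kHz.

### Variants

`make_bz_variant` produces the three border-zone electrophysiologies
studied with the model: `long_apd` (ionic remodelling: APD and
refractoriness prolonged, conduction normal), `slow_cv` (structural
remodelling: BZ conductivity reduced by 90%, BZ APD equal to myocardium)
and `homogeneous` (BZ identical to myocardium).

## Synthetic fields

The analytic generators provide ground truth without the PDE solver.  The
planar wave has AT = s/CV along the propagation direction and
RT = AT + APD, so the minimum-method map equals APD − R/CV at interior
sites up to one electrode spacing — a closed-form anchor for the radius
dependence.  The line-of-block field delays every site downstream of a
straight segment (its "shadow") by a fixed detour time, a free parameter
rather than a path-length computation, which keeps the oracle closed-form;
cross-block pairs then have RVI = APD − detour − gap/CV, and a detour
exceeding the APD produces a strip of negative RVI just proximal to the
line whose extent is known analytically (any non-shadow electrode within R
of the shadow).  A segment narrower than the grid additionally flags its
open ends, where the undelayed wave sweeps past laterally — analytically
correct, and the reason localization tests use a grid-spanning segment.

What the synthetic fields do *not* emulate: restitution dynamics, wavefront
curvature, electrotonic smoothing of markers, fractionated or noisy
electrograms (noise is injected directly on the markers as independent
zero-mean Gaussians, default 5 ms, never filtered).  Passing the synthetic
suite therefore establishes the correctness of the mapping algebra and its
radius/interpolation behavior, not the fidelity of marker extraction on
clinical signals.

## Reported benchmark tables

`rvimap.reference_tables` embeds the published vulnerable-region sizes and
lowest-RVI values of the reference idealized-2D and rabbit biventricular
studies, indexed by method and radius.  They are inputs to the reporting
path (`rvimap report`), which recomputes the minimum-method fold changes of
the vulnerable region under radius enlargement (≈8.6 for the 2D model,
R 4→16 mm; ≈6.7 for the BiV model, R 2→8 mm).  The absolute values in
those tables depend on the detailed biophysical ionic model used in the
original studies and are deliberately not reproduced by the
phenomenological simulator here.

## Problem sizes and determinism

The full default sheet (40,401 nodes) with the complete S1–S2 protocol
integrates ≈126k steps in about two minutes on one core; the test suite
reserves that size for the block/re-entry and calibration checks and runs
all other simulation tests on geometrically scaled sheets (10–20 mm,
0.25–0.5 mm resolution) with correspondingly larger dt, which the
refinement and cross-resolution tests justify.  Every stochastic component
(multipolar grids, marker noise) takes an explicit seed; the CLI derives
per-component seeds from one master seed via CRC-hashed seed sequences, so
rerunning a configuration reproduces outputs byte-for-byte.

## Known limitations

* Two-variable membrane kinetics: no biophysical currents, concentrations
  or drug effects; upstroke morphology is schematic (the −20 mV AT
  threshold is still well defined).
* The block/no-block window of a premature beat is genuinely narrow
  (30 ms of coupling interval); reproducing it required co-tuning the BZ
  refractoriness factor, and the margin to both failure modes is of order
  10 ms.
* Isotropic conductivity on a flat sheet: no fibers, curvature or
  transmural structure; the RVI core accepts arbitrary 2D/3D point sets,
  but geodesic distances are not implemented.
* Electrograms are not synthesized; markers come from the transmembrane
  voltage directly.
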