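# Methods

## The model

`laflow` decomposes the blood volume handled by the left atrium (LA) over a
cardiac cycle into six flow components by Lagrangian particle tracking
through a periodic, time-resolved velocity field:

| component | definition (ventricular phase convention) |
|---|---|
| conduit | enters at a pulmonary vein (PV) during diastole and leaves through the mitral valve (MV) within the same diastolic phase |
| reservoir | enters during systole (MV closed), leaves through the MV in the following diastole |
| delayed ejection | leaves during diastole, entered in the previous diastole or earlier |
| retained inflow | entered in the previous cycle, does not leave in the tracked window |
| residual volume | stays in the atrium across both tracked cycles |
| PV backflow | leaves the atrium retrograde through a pulmonary vein (overrides the other rules) |

Two seeding strategies cover all of this blood:

* **Volume seeding.** At the end-systolic atrial maximum (`t_mv_open`) the
  LA is filled with particles on an isotropic Cartesian lattice of pitch
  `volume_spacing` (default 2 mm, 0.008 mL per particle). Each particle is
  tracked one full cycle backward and one forward. The lattice is anchored
  at the LA centroid snapped to the mask's voxel-corner lattice: seeding is
  translation-robust but free of boundary ties, and at a pitch equal to the
  voxel size the seeds coincide with voxel centers, so the seeded total
  equals the mask volume exactly.
* **Pulmonary-vein seeding.** On each vein interface plane, a lattice of
  pitch `plane_spacing` (default 1 mm) is re-released every
  `release_interval` (default 0.025 s) over one full cycle starting at
  mitral-valve closure. A seed's represented volume is the flux through its
  patch cell during one interval, `V = A · v_norm · Δt`, with `v_norm` the
  instantaneous velocity along the plane normal at the seed point; seeds
  with `v_norm ≤ 0` are not released. Summed over a cycle, released volume
  equals the blood volume entering the atrium (flux closure).

Vein-seeded particles are tracked 1.5 cycles so late-diastolic releases can
still resolve conduit within their own diastole. De-duplication between
the strategies counts each parcel once: conduit comes only from vein
seeding (those particles enter after the snapshot instant, so they can
never be volume seeds); reservoir, delayed ejection, retained inflow and
residual volume come only from volume seeding; PV backflow combines
volume-seeded vein exits with vein-seeded returners that are either
released at/after the snapshot or complete their round trip before it —
a vein-seeded particle released before the snapshot and still inside at the
snapshot *is* a volume seed, and its vein exit is booked there. Vein
returns are only counted within one cycle of release; the extra tracking
horizon serves conduit resolution alone.

Pathlines are integrated with classical RK4 at a constant step
(`cycle_length/1000` by default; the final partial step lands exactly on
the end time). Backward tracking integrates the same field with the time
direction reversed. Velocity queries are trilinear in space and linear in
time with periodic wrap; positions outside the sampled box clamp to the
nearest sample. For large ensembles the two bracketing frames are blended
once per query time, and a compiled kernel performs the gather when numba
is available (a pure-numpy path gives identical results otherwise).

### Moving masks and crossing detection

Region masks are categorical and per frame. Classification bookkeeping and
volume curves use nearest-frame labels. For in-LA membership *during
tracking*, a particle counts as outside only when it is outside in **both**
frames bracketing the current time, with a one-voxel dilation band around
the LA: the true wall position always lies between the two discrete walls,
and nearest-frame lookup alone lags a moving wall by up to half a frame,
falsely "losing" wall-adjacent particles. The band only relabels OUTSIDE
voxels — crossings into the labelled LV or PV regions are detected
unmitigated. Crossing times are refined by bisection of the membership
predicate along the step segment; the event is attributed to an interface
plane when the crossing point lies in a patch (ties resolve to the nearer
patch center, then MV before PV_1..k), otherwise to the raw region
transition. Particles leaving through the wall beyond the tolerance band
get status `lost`; their volume is reported, never silently dropped.

### Kinetic energy and indices

Per particle, `KE(t) = ½ ρ v(t)² V` with blood density ρ = 1060 kg/m³. A
component's kinetic energy per volume at a time point is the sum over its
particles currently inside the LA divided by the volume they represent —
the volume-weighted mean of ½ρv², stored in J/m³ and converted to mJ/mL
(×10⁻³) only at the report writer. Times where no particle of a component
is inside are absent from the series (undefined, not zero); the
time-average is the mean over defined times.

Volumetric indices follow the echocardiographic conventions: LA EF
`(LAmax−LAmin)/LAmax·100`, expansion index `(LAmax−LAmin)/LAmin`, passive
EF `(LAmax−LApreA)/LAmax·100`, active EF `(LApreA−LAmin)/LApreA·100`,
absolute passive/active changes `LAmax−LApreA` and `LApreA−LAmin`, and the
volume-based conduit estimate `LVSV − (LAmax−LAmin)`. When no pre-A
(diastasis) time is given, it defaults to the minimum of |dV/dt| within
30–85 % of diastole — a detection rule of this package's own choosing,
always overridable. Group statistics use the classical pooled-variance
two-sample t test (Welch by flag) and ordinary least squares with
R² = 1 − SSres/SStot.

## The phantom family

Realism is deliberately traded for verifiability. The phantom is an
axis-aligned chamber (length L = 50 mm along x, width W = 20 mm, moving top
wall at z = H(t)) with an inlet tube (vein side) and an outlet (mitral
side). Mass conservation fixes the interior axial velocity

    u(x,t) = (Q_in(t) − (x/L)(Q_in(t) − Q_out(t))) / (W·H(t)),

and the wall-normal component `w = z·H'(t)/H(t)` is linear across the
section. The sampled field is therefore exactly divergence-free and
exactly reproduced by trilinear interpolation; the only discretization is
the 20-frame time sampling, which the ground truth shares (below).

Waveforms are half-sine lobes mirroring the physiological phasing: a
systolic inflow lobe (16 mL, the reservoir accumulation; the chamber grows
24 → 40 mL so the atrial maximum falls exactly at the seed instant), vein
inflow over early/mid diastole, a fast E-wave (18 mL) and a late A-wave
(10 mL) of mitral outflow, an optional reversed vein lobe (3 mL) alone in
late diastole, and an optional sealed stagnant pocket. The steady-channel
preset (`pure_conduit`) instead uses a trapezoidal diastolic plug waveform
whose ramps span exactly one frame interval, so linear interpolation of the
frame samples reproduces it without error; its effective steady-flow
duration is `T_d` minus one frame interval. Five presets are provided:
`pure_conduit`, `reservoir_mix`, `backflow`, `stagnant_pocket`, `full_mix`
(two veins, backflow and pocket combined).

The pocket sits two voxels away from the flow channel and the velocity is
zeroed one voxel into the wall around it, so interpolated velocity is
identically zero throughout the pocket at any seeding pitch, while the
channel-side interpolation stays exact.

The vein seed planes sit on the first tube voxel-center plane — half a
voxel upstream of the vein–atrium interface — where the plug profile is
sampled exactly; the transit length for the analytic conduit value is
therefore `L + spacing/2`.

### Ground truth: the characteristics oracle

Because the axial dynamics are one-dimensional, every component volume has
a brute-force referee: fine-step (default `T/10⁴`) RK4 integration of
`dx/dt = u(x,t)` per seed, with the same classification rules applied to
the crossing times, and the same merge/de-duplication. The oracle
evaluates `u` as the exact 1-D restriction of the sampled field — linear in
time between frames, piecewise linear in x through the axial voxel-center
samples (reproducing the tube–chamber interface smear of trilinear
lookup) — so pipeline-versus-oracle deviations measure the 3-D tracking
machinery, not a difference in field models. All seeds of an axial column
share one fate, so the oracle integrates one characteristic per column with
multiplicity; self-convergence in the step size is tested.

Analytic values exist for limiting statements: flux closure against the
exact integral of the frame-interpolated inflow; the transit-time conduit
value `Q·(T_flow − L_transit/u)` on the steady channel; the reversed-flux
integral `∫max(−Q_in,0)dt` for backflow. The discrete release interval
quantizes vein parcels at `Q·Δt_release` (≈ 2.4 mL at the steady channel's
plateau), so these continuum statements are verified with the release
interval refined (5–25×); at default resolutions the pipeline is instead
held to the oracle, which shares the quantization.

### Known limitations of the phantom

* The column degeneracy quantizes the *true* decomposition: a component
  boundary that cuts across columns moves the truth itself by up to one
  column volume (0.8–1.6 mL) when the seed pitch changes. Refinement
  stability (halving both pitches, < 2 % shift) therefore holds exactly on
  the rigid presets, while on the moving-wall presets the check is that the
  pipeline tracks the matched-resolution oracle; real 3-D flows do not
  share this degeneracy.
* The conservation identity (vein inflow − backflow = mitral outflow)
  closes to within one release parcel plus the standing inventory between
  the seed plane and the inlet (≈ 2.3 % on the steady channel at default
  release interval, ≈ 1 % when refined). This mirrors the inflow–outflow
  bias inherent to the discrete seeding method itself.
* No recirculation, no valve geometry, no left atrial appendage: stagnation
  is represented only by the sealed pocket, and retained inflow arises from
  slow axial transit, not from 3-D trapping. Passing phantom tests
  demonstrates correctness of seeding, integration, event detection and
  bookkeeping — not fidelity to patient hemodynamics.

## Numerical choices

* Tracking step `dt = cycle_length/1000`; the RK4 order and the
  forward–backward inversion are tested, and an independent fine-step Euler
  integration agrees on endpoints.
* Crossing bisection: 40 iterations on the straight step segment.
* Simultaneous patch intersections attribute to the nearer patch center;
  exact ties take MV first, then PV_1..PV_k.
* Speed records for the energy series default to every 0.025 s, aligned
  across the backward, forward and vein ensembles by rounded time keys.
* Rate/volume series bin width defaults to one frame interval; a bin width
  that does not divide the cycle shortens the last bin and flags it.
* Determinism: the analysis path contains no randomness; report files are
  written with fixed field order and `%.17g` floats, so identical inputs
  give byte-identical outputs. The only randomness in the package is the
  optional waveform jitter for synthetic cohorts, always seeded.

## Problem sizes used in the verification suite

Default phantom runs track ~3 000–5 000 volume seeds and ~10 000–19 000
vein seeds for 2–2.5 cycles at 1 000 steps per cycle; the refinement checks
use 8× volume seeds and 4× vein seeds. These sizes make every component's
truth quantization at least an order of magnitude below the tolerances they
are tested against, while keeping the full suite runnable on a laptop core
in minutes.
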