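# Methods

This note documents the model behind `quaarc`, the choices that were
genuinely open, and what the synthetic tests do and do not demonstrate.

## The verification problem

A VMAT delivery is continuous; every calculation of it is discrete.  Two
error sources separate a planned dose from a delivered one: the accuracy of
the dose calculation itself, and the gap between discrete control points
(CPs) and the continuous trajectory actually driven.  Detector arrays
sample that gap sparsely; film rolled on a cylinder samples it continuously
at every gantry angle.  The model here uses the delivery log to fix the
*geometry* of each CP (angles, apertures), and the film plus an isocenter
chamber to correct the *monitor units* attributed to each CP.

## Log discretization

The log dialect is CSV with columns
`time_s, gantry_deg, mu_cum, beam_on, leaf_a_01.., leaf_b_01..` — one row
per sample (0.25 s while the beam is on, 1 s during holds).  Parsing is
verbatim; validation enforces strictly increasing timestamps, a
non-decreasing MU counter, uncrossed leaves and gantry angles in [0, 360).

*Coarse* discretization keeps one CP per record whose cumulative MU
advanced, carrying that record's angle and leaf snapshot.  *Fine*
discretization places CP boundaries at equal cumulative-MU quanta inside
each coarse interval, `max(1, round(k·N · ΔMU_i / ΣΔMU))` sub-CPs in
interval *i* (N = coarse CP count) — inverse-transform sampling of the
normalized |ΔMU| density over the arc,
with one CP per coarse CP as floor.  The density therefore tracks the
local dose rate: sectors where MU accumulates fast get proportionally more
CPs, and the target multiplier `k` (default 3) sets the overall count.
Machine state at interior boundaries is interpolated linearly in time,
the standard assumption for dynamic MLC motion.  Both levels conserve
total MU to 1e−9 by construction (the terminal quantum absorbs the
floating-point residue of the interpolation).

Gantry angles follow IEC 61217 and are unwrapped across 0/360 so arcs may
cross north.  Angular MU binning uses right-closed bins (a CP sitting
exactly on an edge belongs to the bin below it).

## Dose engine

Full radiation-transport simulation is out of scope; what the MU
adjustment consumes is only the *linear structure* of per-CP dose.  The
engine is a deterministic divergent-beam model:

- a point source at SAD = 1000 mm rotates with the gantry; each query
  point is back-projected through the source onto the isocenter plane
  (so field edges diverge geometrically);
- the MLC aperture (leaf pairs stacked along z, travel across) transmits
  1 inside the opening, `leaf_transmission` (default 1.5 %) outside, with
  an error-function penumbra of width `kernel_sigma` (default 3 mm) —
  values representative of 6 MV MLC systems, both configurable;
- intensity decays as `exp(−μ · radiological depth)` with
  `μ = 0.005 /mm` of unit-density path.  Radiological depth comes either
  from closed-form chord lengths through a homogeneous cylinder
  (`CylinderMedium`, exact and fast — the verification phantom's natural
  medium) or from midpoint ray-marching of an arbitrary density grid
  (`GridMedium`, 2 mm steps).

No inverse-square intensity factor is applied: the engine's attenuation
law is then exactly exponential along any ray, which keeps its closed form
testable and is irrelevant to the pipeline's correctness, since the MU
adjustment only requires linearity, superposition and rotational
equivariance — all of which hold exactly by construction.  Dose is "dose
to medium"; no spectrum, head scatter or electron contamination.  The
engine is pluggable: per-CP dose grids computed elsewhere (e.g. real
Monte Carlo output) can be loaded from a raw-plus-JSON-header directory
and the rest of the pipeline is unchanged.  Monte Carlo statistical noise
is emulated as independent Gaussian perturbation with SD a fraction of
the local dose (the <1 % regime), seeded and clipped at zero.

## Phantom and scrolls

Two PMMA setups (density 1.19 g/cm³): big, ⌀300 × 300 mm; small,
⌀200 × 280 mm.  Films sit at 10 mm (outer, two films) and 60 mm (inner)
depth; the chamber at the isocenter.  "Unrolling" samples the calculated
3-D grid on the film's cylinder every 0.5° (configurable) by trilinear
interpolation — the reading of "interpolation among the nearest neighbors
in the three axes"; nearest-neighbor is available as an option.  The
azimuthal pixel width is `r · Δθ` (0.7854 mm at r = 90 mm, Δθ = 0.5°).
θ = 0 points at the gantry-zero entrance (+y), increasing clockwise seen
from the gantry, which fixes the film-to-scroll correspondence; the z
step defaults to the grid's z voxel (1 mm).

To absorb the residual frame mismatch between calculation and
measurement, the scroll is reconstructed five times — unshifted and with
the isocenter moved ±1 in-plane voxel along each axis — and averaged
(mean; the min/max envelope is retained for uncertainty reporting).  The
declared positional uncertainty is one voxel pitch, ±1.25 mm on the
default 1.25 × 1.25 × 1 mm grid.  The nominal scroll radii are used
throughout; the averaging is a smoothing operator, so on curved fields
the ensemble differs from the unshifted scroll by a curvature term of
order the voxel pitch squared (visible in the full-pipeline test).

## Film model

Sensitometric response per channel: `v(D) = a + b/(D − c)` with `b > 0`,
`c < 0` — monotone decreasing on 0–400 cGy with a closed-form inverse,
the de-facto standard form for EBT-family film.  Calibration requires
≥13 distinct dose levels including 0 (the batch protocol uses 16);
non-monotone channels are rejected with a warning, never silently
dropped.  Defaults mimic an EBT3-like batch normalized to [0, 1]:
red most sensitive at low dose, blue least.

Dose conversion is multichannel with a common-mode disturbance: each
pixel's RGB triple is explained by a dose `D` and one multiplicative
factor `(1 + Δ)` applied to all channels (thickness/scan artifacts),
minimizing `Σ_ch (v_ch − v̂_ch(D)·(1+Δ))²`.  For fixed `D` the optimal
gain is closed-form, so the 1-D dose search is a vectorized look-up on a
0.25 cGy grid with parabolic refinement.  Constraining `Δ = 0` reduces
exactly to single-channel (green) inversion.  Scanner lateral
non-uniformity is corrected per column; the longitudinal direction is
left untouched (negligible effect).  Rigid film-to-calculation
misalignment is recovered by maximizing mutual information (64-bin joint
histogram) over an exhaustive coarse grid (1 px / 1°) refined at
0.25 px / 0.25° — deterministic, no random restarts; hitting the search
boundary raises a warning.

## Comparison metrics

Percent dose difference is global: `100·(eval − ref)/D_norm` with
`D_norm` the reference maximum by default, passing when |Δ| < 3 %.
Gamma uses the standard combined criterion; the reference is upsampled
×4 by linear interpolation on an exactly aligned fine grid (fine index
`4i` coincides with coarse pixel `i`), the search is capped at 3 × DTA,
anisotropic spacing folds into the distance term, and pixels below 20 %
of the reference maximum are excluded.  γ = 1 counts as passing (the
uniform-offset boundary case is measure-zero in practice but should not
fail).  An exhaustive per-pixel oracle implements the same definition
independently and agrees with the vectorized search to ~1e−16.  The
threshold applies to the reference map; local-normalization gamma is
available as an option.

## MU adjustment

The quadratic program is solved in weight space (`x = 1` means "as
logged"): the per-MU contribution columns are scaled by the logged MU,
rows by the measurement weights (the chamber row defaults to
`n_rows/100` so one absolute point is not drowned by thousands of film
pixels).  Solver: SLSQP on the normal-equations objective (analytic
gradient) with box bounds and the total-MU equality, plus an active-set
outer loop for the dose-tolerance inequality — with thousands of
measurement rows almost every tolerance row is slack at the optimum, so
only violated rows are promoted into the constraint set.  The per-row
tolerance is `max(3 % of the local dose, 0.02 Gy)`; when the set is
infeasible (e.g. noisy measurements that no smooth dose can satisfy
row-wise) it is relaxed by ×1.5 up to 8 times, each relaxation counted
on the returned solution — never silently.  The log solution `x = 1` is
always feasible for bounds + equality, so the returned objective is
never worse than no adjustment.  Rank-deficient contribution matrices
are flagged (`degenerate`), the solution still reported.  A single
registration → solve pass is performed; no re-registration iteration.

## Synthetic scenarios: what they emulate, and what they don't

`make_arc_plan` builds a single arc of equi-spaced CPs with smoothly
varying apertures and MU (a `modulation` knob from 0 = static to 1);
scale references: 32–90 CPs, 200 MU, 360°.  `emulate_delivery` writes
4 Hz beam-on records, one per plan CP by default — a deliberately
compressed delivery timescale so the coarse discretization aligns 1:1
with plan CPs and the ground truth is defined per solved CP
(`records_per_cp` restores denser logs).  The injected error is a
*hidden per-CP output drift*: the logged counter follows the plan while
the delivered output of CP *i* is `x*_i` times its logged MU, with
`x* − 1` a sum of ≤3 random-phase sinusoids (delivery errors are
correlated along the arc — that correlation is what the lateral-overlap
adjustment exploits), amplitude-capped (default 5 %) and centered under
the MU weighting so total delivered MU matches the counter.  Leaf and
gantry jitter are optional per-record Gaussians.

Measurement rows default to 1° azimuth × 5 mm z samples on both scrolls
(~18 000 rows) plus the chamber, mirroring — at desk scale — the high
detection density that distinguishes film from detector arrays; noise
settings apply 1 % i.i.d. relative noise to the contribution matrix
(Monte Carlo statistics), 2 % to the film rows and 0.5 % to the chamber.

Not emulated: intra-CP aperture motion blur, film post-irradiation
kinetics, scanner spatial noise correlation, energy-spectrum effects and
patient heterogeneity.  Consequently, passing tests demonstrate the
*pipeline's* correctness — discretization, linear dose bookkeeping,
inversion, constrained estimation — under the stated noise model, not
the dosimetric fidelity of any clinical beam model.

## Numerical choices

- MU conservation tolerance 1e−9 MU; solver equality typically exact to
  <1e−10 of total MU.
- DVH: 0.01 Gy bins, voxel-center inclusion, cumulative by counting.
- Point-dose check is a trilinear point value (chamber-volume averaging
  off by default, matching point-dose comparison semantics).
- Film dose LUT step 0.25 cGy (+ parabolic refinement → residual
  quantization ≪ 0.1 cGy).
- Gamma upsampling ×4 (2-D default; configurable for 3-D where memory
  grows cubically), search cap 3 × DTA.
- Scenario problem sizes (48 CPs, 18k measurement rows, 50 gamma pairs,
  20 noisy seeds) run the full suite in ~2 minutes on one CPU.

## Known limitations

- The dose engine is a geometric stand-in: no scatter, no spectrum, no
  inverse square; absolute dose scales are self-consistent, not
  clinically calibrated.
- The fine-sampling density function is a declared rule (equal-MU quanta
  with a per-coarse-CP floor); vendors' exact log-reduction algorithms
  differ.
- The multichannel disturbance model is the minimal common-mode form;
  published multichannel algorithms differ in their disturbance terms.
- The printed inner-scroll pixel width (0.3523 mm) implies an effective
  radius ≈40.4 mm rather than the nominal 40 mm of the small setup at
  6 cm depth; nominal radii are used and the discrepancy is left open.
- With noisy measurements the row-wise dose tolerance is usually
  infeasible as stated and ends relaxed; the relaxation count on the
  solution is the honest record of that.
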