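# Methods

This note records the models implemented in `myorod`, their assumptions,
the parameter defaults that matter, the numerical choices that were
genuinely open, and what the synthetic-data generators do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coiled-coil builder (`cc_builder`)

### Model

A two-chain parallel coiled coil is parameterised in the Crick picture as
a helix wound on a helix. For chain A, residue *i* (0-based):

- the local helix axis point is `(R cos Φᵢ, R sin Φᵢ, h·i)` with major
  radius `R` (default 4.9 Å) and axial rise per residue `h` (default
  1.495 Å);
- the supercoil azimuth integrates a per-residue winding rate
  `ω₀(i) = 360 (1/ρ_lab − 1/p_frame(i))` deg/residue, where `ρ_lab` is the
  laboratory-frame α-helical periodicity (default 3.617 residues/turn) and
  `p_frame` the motif's frame periodicity;
- the Cα sits at minor radius `r` (default 2.3 Å, the standard α-helix Cα
  radius) from the axis point, in the horizontal plane of the local
  radial/tangential frame, with a minor phase that advances by
  `ω_lab − ω₀` per residue so the laboratory-frame periodicity is exactly
  `ρ_lab`;
- chain B is chain A rotated by the interchain rotation (default 210°)
  about the central axis. The chains are parallel and in axial register
  (no stagger), as appropriate for the myosin rod dimer.

Keeping the minor-helix offset horizontal (no axial component of the minor
wave) is a deliberate simplification: it makes the axial coordinate advance
exactly `h` per residue and keeps every generating constant recoverable in
closed form from the coordinates, at the cost of a small (±0.25 Å)
periodic modulation of consecutive Cα–Cα distances around 3.8 Å. The
builder warns, but does not refuse, when parameters are non-physical
(e.g. minor radius exceeding major radius).

### Motif grammar

Patterns tile a canonical reference span with 7-residue heptad motifs
(2 helical turns each, `p_frame = 3.5`). Two noncanonical motifs replace
four consecutive heptads each:

- **skip** motif: 29 residues, 8 turns (`p_frame = 29/8 = 3.625`) — one
  extra residue, a locally near-straight segment (the myosin skip residue);
- **deletion** motif: 27 residues, 8 turns (`p_frame = 27/8 = 3.375`) —
  one residue fewer, locally overwound, keeping the 8 turns of the span it
  replaces so the coiled coil stays left-handed and returns to register.

The four replaced heptads are chosen so the requested site is as central
as possible in the 28-residue union (ties resolve toward the N-terminus);
overlapping replacements and sites too close to a chain end are errors. A
trailing remainder shorter than 7 residues keeps canonical winding.

### Smoothing

The piecewise-constant `ω₀` profile is convolved with a Gaussian kernel of
standard deviation `b × chain length` residues (default `b = 0.03`,
i.e. ≈ 2.7 residues on a 91-residue chain). Any single-width low-pass
filter would serve; the Gaussian was chosen for smoothness and because a
single dimensionless width parameter is all the model promises. With
`b = 0` motif boundaries produce sharp kinks; builds of mutants then differ
from the canonical build only within and downstream of the noncanonical
span, which the tests exploit.

## Trajectory geometry (`traj_geometry`)

Metrics operate on `(frames × 2 chains × residues × 3)` Cα arrays read
from multi-model PDB files, reported as per-residue mean ± SD across
frames, in the trajectory's own residue numbering:

- **D_com**: per frame, the distance between the chains' 7-Cα window
  centroids (3 residues either side of the marked residue). The centroid is
  unweighted: over one 3.5-residue frame period the minor-helix offsets of
  7 consecutive Cα cancel exactly, so the centroid estimates the local
  helix axis.
- **heptad length**: mean over `j ∈ [i−3, i+3]` of `|Cα(j) − Cα(j+7)|`,
  averaged over chains. The mean-of-distances reading was chosen over
  distance-of-mean-positions; both are simple options, and the chosen one
  treats each i→i+7 vector as a heptad-length sample.
- **interheptad angle**: vertex angle at `i` of the triangle
  `Cα(i−7), Cα(i), Cα(i+7)`, averaged over chains. On an ideal build this
  is slightly below 180° and 7-periodic along the chain (the minor-helix
  phase does not cancel in a 3-point angle).
- **helicity**: a residue-frame is helical iff its backbone dihedrals fall
  in the α window, default φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]
  (configurable; per-residue dihedrals only, no run-length requirement).
  Terminal residues lacking φ or ψ are excluded from the denominator.

Burn-in removal drops frames with `t < discard` where frame *i* is at
`i × frame interval` (default 100 ps, i.e. 25,000 steps of a 4 fs
integrator). Multi-run aggregation averages per-run mean profiles and
reports the between-run SD with `ddof = 1` (runs are the sampling unit).

## Heptad register (`rod_register`)

Letters a–g cycle one per residue from a user-supplied anchor (a residue of
known register). Each skip residue consumes one extra register slot: the
skip itself keeps the letter plain cycling would give it, and every residue
beyond it is shifted back by one letter. The default skip set is the four
canonical MYH7 rod skips {1188, 1385, 1582, 1807}. With the anchor
(1280, 'd') this convention reproduces the published register letters for
A1440 (b), L1492 (e), E1507 (f), E1508 (g), E1610 (c), K1729 (c) and
R1845 (f). A1636 computes to 'a' under this convention while published
annotations print 'b'; the discrepancy is recorded here rather than
patched, and A1636 is excluded from the tests. MYH2 numbering and skips are
not configured by default.

Charge profiles use E/D = −1, K/R = +1, H = 0 (histidine is near-neutral at
physiological pH) in a centred rolling window, default 29 residues (the
rod's 28-residue charge period rounded up to odd for centring); only
positions where the full window fits are reported.

## Mant-ATP chase (`mant_atp`)

Traces are background-subtracted per image and normalised to the corrected
intensity of the last image before washout, so `y(0) = 1` exactly; traces
whose corrected t = 0 intensity is not positive are rejected. The model

    y(t) = 1 − P1 (1 − e^(−t/T1)) − P2 (1 − e^(−t/T2))

is fit unconstrained by least squares. Sums of exponentials are
ill-conditioned, so the fitter multi-starts on a T1 × T2 grid
({5, 20, 60} × {100, 200, 400} s) with amplitudes solved linearly at each
grid point (variable projection), then refines all four parameters with
nonlinear least squares, time constants in log space. Phases are relabelled
post hoc so T1 < T2 — a label swap that never changes the fitted curve. No
post-fit normalisation of P1 + P2 is applied.

Per-fiber parameters are the unweighted mean over that fiber's converged
region fits (the assay samples three regions per fiber); the region-level
SD is retained. The DRX/SRX ratio is P1/P2, undefined (NaN, flagged) when
P2 ≤ 0.

`fit_decay_batch` fits the same model to many traces on a shared time grid
via vectorised variable projection plus batched damped Gauss–Newton; it
agrees with the per-trace path to fitting tolerance and exists for
cohort-scale work (hundreds of thousands of traces across replicates).

Accuracy context, computed by the tests: with the default acquisition grid
(5 s × 5 min, 61 points), additive noise of 0.01 on the normalised scale
and the base parameters P1 = 0.25, T1 = 20 s, P2 = 0.55, T2 = 200 s, the
Fisher information of a single trace bounds the per-trace P1 standard
error at ≈ 0.022, so single-region P1 estimates carry ≈ 6 % median relative
error no matter the fitter; averaging the three sampled regions per fiber
brings the per-fiber median error under 5 %, which is what the acceptance
suite checks.

## CD analysis (`spectroscopy`)

MRE = θ_mdeg × MRW / (10 × pathlength_cm × concentration_mg/mL), the
standard mean-residue-weight form (the per-residue vs per-peptide-bond
choice is configurable through MRW). Percent helicity is
100 × |MRE₂₂₂| / 36,000; values above 100 % are reported as-is with a
warning. T_m comes from a four-parameter Boltzmann sigmoid fit (two
baselines, midpoint, slope) to the thermal scan — robust to noise and
invariant to affine rescaling of the signal; a raw 50 %-crossing
interpolation is kept as a cross-check. Curves whose transition amplitude
is below 5 % of the signal scale, or whose fitted midpoint falls outside
the scanned range, are flagged as failures rather than reported.

## Fiber mechanics (`fiber_mech`)

CSA = π (width/2)(depth/2), the elliptical estimate from width and depth;
specific force = force / CSA. The force–pCa relation uses the standard
muscle-mechanics four-parameter Hill form

    F(pCa) = F_min + (F_max − F_min) / (1 + 10^(nH (pCa − pCa50))),

with a passive offset F_min as the fourth parameter (the alternative — a
second slope — has no precedent in this assay). Optional pre-fit
normalisation divides by the measured force at the lowest pCa
(maximal activation). Flat curves and non-convergent fits are flagged, as
is a fitted pCa50 outside the pCa 4.5–9 solution range (extrapolation).

## Sarcomere profiles (`sarcomere_profile`)

Each line profile is min–max normalised per sarcomere (the simplest
normalisation consistent with spreadsheet practice) and aligned so its
M-band minimum — the dip between the two brightest bands, not the global
minimum, since the Z-disc ends of a profile are darker still — sits at
position 0. Profiles without two flanking bands and an interior dip are
rejected. Aligned profiles are resampled by linear interpolation onto a
common grid at the finest input spacing over the jointly covered range and
averaged per myofibril. The peak-to-peak distance is measured between the
highest local maxima on either side of the origin after a light 3-point
moving average (configurable); fewer than one maximum per side flags a
failure.

## Three-state SRX model (`srx_model`)

A deliberately minimal steady-state surrogate for spatially explicit
sarcomere simulators: heads occupy SRX, DRX or a force-generating (FG)
state along SRX ⇌ DRX ⇌ FG, with DRX→FG attachment gated by thin-filament
activation `a(pCa) = 1/(1 + 10^{n_a (pCa − pCa50_a)})` and isometric force
proportional to FG occupancy. Only the steady state is solved (the
measured quantities — specific force, pCa50, nH — are isometric steady
measures); occupancies come from the null space of the rate matrix with
the conservation constraint, and the closed form F = a/(a + c) with
c = (k_detach/k_attach)(1 + k₋/k₊) shows why raising the SRX→DRX bias k₊
both raises force at every activation and shifts pCa50 upward. All rate
defaults are arbitrary plausible magnitudes; the model is used for
direction-of-effect exploration only, and no attempt is made to match any
particular simulator's printed pCa50 values. Lattice geometry, filament
compliance, MyBPC and titin coupling are intentionally absent.

## Cohort statistics (`cohort_stats`)

Multiple control groups may be pooled into one reference group. The
omnibus test is a one-way ANOVA; each non-control group is compared to
control with Dunnett's many-to-one procedure, two-sided, with adjusted
p-values from the multivariate t distribution under the standard one-way
correlation structure (exact for unbalanced designs such as 73 vs 214
fibers). The quasi-Monte-Carlo evaluation of the multivariate t
probabilities is seeded for reproducibility. Singleton groups are excluded
with a warning. Fibers are treated as independent units; patient-level
clustering is not modelled (a known limitation of the fiber-level design,
mirrored rather than corrected here).

## Synthetic data (`synthetic_data`)

All generators draw from one explicit `numpy` Generator per call, seeded by
the caller, and are bit-reproducible; zero-noise outputs lie exactly on
their generating closed forms. Noise is additive i.i.d. Gaussian
everywhere — the simplest model that supports parameter-recovery testing.

- **Decay cohorts**: control fibers follow the double-exponential model at
  the supplied base parameters; patient fibers have P1 scaled by
  (1 + drx_shift) with P1 + P2 held constant (matching the observed
  pattern of P1 up / P2 down with roughly conserved total amplitude). The
  default effect size is drx_shift = 0.15, the midpoint of the 10–20 %
  DRX increase the assay is meant to resolve; the default acquisition grid
  is one frame per 5 s for 5 minutes (61 points) and the default noise SD
  is 0.01 on the normalised scale, a visually clean trace. Traces are
  dressed as raw intensities (scale 1000, constant background 100) so the
  full normalisation path is exercised. No per-fiber variance in the true
  P1/P2 is simulated — the only between-fiber variation is noise-induced —
  so recovery tests measure estimator error, not biological spread.
- **Trajectories**: frame 0 is the exact built model; later frames add
  isotropic Gaussian coordinate jitter. Real trajectories have correlated,
  anisotropic fluctuations; the jitter model only supports metric and SD
  plumbing checks, not thermodynamic claims.
- **Backbones**: N/Cα/C chains built from prescribed (φ, ψ) by standard
  internal-coordinate (NeRF) placement with ideal bond geometry and trans
  ω, for dihedral-helicity checks.
- **Melts**: two-state sigmoids between two baselines; **force–pCa**:
  Hill curves with force noise floored at zero; **sarcomere profiles**:
  two Gaussians at ± separation/2 over a baseline, with a random
  per-sarcomere position offset so alignment is actually exercised.

What passing tests show, and what they do not: the generators share the
functional forms the fitters assume, so recovery tests validate the
estimation machinery (identifiability, convergence, bias at the study's
noise levels and sample sizes), not robustness to model misspecification,
photobleaching, baseline drift or other real-instrument effects, which are
deliberately not emulated.

## Problem sizes used in the checked results

The acceptance suite uses 91-residue dimers for all geometry round-trips;
200 fibers × 3 regions for decay-recovery error; 500 seeded replicates at
73 control / 214 patient fibers for shift-detection power; 100 seeded
parameter draws for the three-state direction-of-effect sweep; 10⁶
Monte-Carlo draws for the Dunnett oracle; and 1,000 seeded replicates for
the null family-wise error rate. These sizes were chosen to make
Monte-Carlo error small relative to the margins being tested.

## Known limitations

- The builder produces Cα-only models (backbone N/C only via the synthetic
  helix generator); no side chains, no energetics, no solvent, no MD.
- The Gaussian interpretation of the smoothing width `b` is one of several
  defensible readings; only the single-width-parameter contract is
  promised, and the kernel choice is configurable in principle by editing
  one function.
- The interheptad angle and D_com of ideal builds carry small periodic
  residue-to-residue modulation from the minor helix; profiles on real
  trajectories average this with thermal noise.
- Dunnett comparisons assume normal residuals and homogeneous variance
  across groups, as in the standard one-way layout.
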