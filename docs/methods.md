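# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Anisotropy extraction

Anisotropy is computed from the mean intensities of two rectangular regions
of interest (the two beam-splitter images on the camera chip) as
FA = (I∥ − G·I⊥)/(I∥ + 2·I⊥). The G-factor defaults to 1.15, the value of
the reference instrument, and is configurable. Anisotropy is stored
dimensionless throughout; mP-style ×1000 scaling is a presentation concern
only. No background or flat-field correction is applied to ROI means — the
assay is ratiometric and the reference setup reports none. Frames with
saturated pixels, or FA outside [−0.5, 1.0], are flagged `suspect` but kept;
exclusion is left to the caller. Pixel coordinates (and all genomic
coordinates elsewhere) are 0-based, half-open.

The canonical input is a mean-intensity table per (well, cycle, plane);
TIFF-stack ingestion is a convenience wrapper that produces the same table,
decoupling optics from fitting.

## Concentration calibration

The in-gel competitor concentration is read off calibration wells
containing Nile Blue (NB), modeled as a single-site binding sensor with
ligand depletion: the bound fraction is the exact quadratic solution with
receptor = NB (5 nM) and ligand = competitor DNA, and FA_NB is linear in
bound fraction. This is the minimal physical model of a dye that "acts as a
concentration sensor"; possible fluorescence enhancement of the dye upon
intercalation is not modeled (linear mixing). The sensor parameters
(baseline, amplitude, K_D ≈ 1.7 µM) are fitted once on a conventional
titration standard curve. Because any error in this one fit propagates
into every concentration on every plate, the default simulated design is a
dense 12-point ladder bracketing the sensor K_D, in triplicate.

Inversion of the isotherm is by bracketed root-finding (the isotherm is
strictly monotone). Direct inversion is trusted only above a configurable
floor, 100 nM by default — below it the weak NB affinity makes the readout
unreliable. Per focal plane, the time course of inverted concentrations at
or above the floor is fitted with the one-dimensional diffusion profile
c(t) = c₀·erfc(w/√(t+t₀)), with c₀ and the composite width w = z/√(4D)
free and t₀ fixed. The fitted curve both extrapolates below the floor and
smooths above it. Absolute plane depth and diffusion coefficient are never
separated — only the composite width matters, so the analysis is
insensitive to gel geometry bookkeeping. The volume mismatch between gel
and competitor solution is ignored (the erf profile assumes equal volumes;
it is an approximation already in the source procedure). A fitted profile
whose modeled span over the observed times is below 0.1% of its level
cannot distinguish c₀ from width and is flagged ill-conditioned.

Across calibration wells the consensus concentration is the mean of the
per-well fitted fields; the between-well CV is reported per (plane, time)
and warned above 0.30.

## Competition model and fitting

The two-ligand, one-receptor equilibrium is evaluated two independent ways:

- the closed-form cubic solution (trig form). In double precision the
  arccos argument suffers catastrophic cancellation when the free-receptor
  concentration is small relative to d, so the trig form is evaluated in
  extended precision and polished with three Newton steps on the cubic
  R³ + dR² + eR + f itself. This keeps the evaluation purely algebraic
  (still the closed form) while restoring ~1e-15 relative accuracy; the
  arccos argument is clipped at ±1 with excursions beyond 1e-9 treated as
  non-physical parameter errors.
- a mass-action oracle: bracketed root-finding (Brent) on the receptor
  conservation law R(1 + L_ST/(K_D1+R) + L_T/(K_D2+R)) = R_T over
  R ∈ [0, R_T], at machine-precision tolerances.

The oracle generates all synthetic equilibria; the closed form is what the
fit engine evaluates. Their agreement to 1e-9 relative over random
parameter sweeps is the core correctness property of the package.

The four-parameter fit (K_D2, R_T, C, B) uses trust-region least squares
with K_D2 and R_T in log₁₀ space (affinities span six decades; linear-space
fitting is ill-conditioned), box bounds K_D2 ∈ [1e-3, 1e6] nM and
R_T ∈ [1e-2, 1e4] nM, and a multi-start over K_D2 ∈ 10^{−2..4} nM plus a
data-driven start at the half-span concentration. Initialization: B = min
FA, C = FA span, R_T = nominal protein concentration. Residuals are
unweighted by default (optional weights are accepted). Standard errors come
from the local curvature (Gauss-Newton covariance), with log-space errors
mapped back to the linear scale. Curves whose FA span is below a noise
floor (default 0.01) return a no-binding-detected flag rather than a
spurious K_D; fitted K_D2 below 0.5 nM in gradient mode is flagged
`use-dilution-series`, since the in-gel gradient cannot resolve such tight
binding and a conventional dilution titration (default: the 12-point
design 0–4000 nM) is used instead. The reference affinity K_D1 is fitted
from self-competition with the constraint K_D2 = K_D1. All planes of a
well are merged into a single titration curve (each point carries its own
concentration); replicates are aggregated by geometric mean with CV
computed on the linear scale, matching the log-normal error structure of
affinities.

An identifiability caveat, quantified by a Cramér–Rao analysis of the
default design: for weak competitors (K_D2 ≫ K_D1, R_T) the likelihood has
a ridge along constant K_D2·R_T, so K_D2 precision degrades roughly
ten-fold between K_D2 = 10 nM and K_D2 = 100 nM at fixed noise. Plate-level
calibration errors move all wells of a plate along this ridge coherently,
which is why replicate CVs computed within a plate are tighter than across
plates.

## Kinetics

Dissociation traces are fitted with FA(t) = A + B·e^{−(t−t₀)/τ_off} on
points after the competitor addition time t₀, which is an input (a
changepoint-detection helper exists but is off by default); pre-addition
points only check the plateau. Amplitudes within 2 standard errors of zero
are flagged no-decay. k_off = 1/τ_off; k_on = k_off/K_D with the exact
nM→M factor 1e-9. No mixing dead-time correction is applied. At the 300 ms
frame time, a single trace with amplitude SNR 10 determines τ ≈ 2 s only
to ~8% (Cramér–Rao); the ensemble estimate is unbiased.

## Specificity models

PWM columns are proportional to 1/K_D, with the consensus base carrying
the consensus K_D — a scale-free construction, so absolute affinity and
specificity decouple. A variant measuring stronger than the consensus
raises a consensus-not-maximal warning but the matrix is still built (the
correct response is another mutational iteration). K_Ds above the 10 µM
measurability ceiling enter at the ceiling with a flag. Information
content is the total KL divergence from a uniform background (0.25 per
base), with 0·log 0 = 0. Two pseudo-count conventions: count matrices get
+0.25 per cell (one unspecific site) then column normalization;
probability (affinity-derived) matrices get +0.01 per cell then
renormalization — the "1% uncertainty" reading is additive-then-normalize,
a choice made here since the source procedure does not pin the arithmetic.
Output formats: MEME minimal motif text and a plain probability TSV.

## Occupancy evaluation

Scanning is log₂-odds against the background over both strands (max per
offset); non-ACGT bases contribute zero. Site strength is 2^score times
the accessibility value at the site center — multiplicative weighting is
the minimal reading of an accessibility "filter" and reduces to a hard
filter for binary accessibility. Impulses at site centers are convolved
with a symmetric discretized gamma density (defaults shape 2, scale 100 bp,
truncated at 1000 bp and renormalized — a typical ChIP fragment-length
scale; the source figure states no parameters, so these are declared
defaults, not inferred values). Precision–recall is per-base: predictions
are profile ≥ threshold over all distinct profile values
(scikit-learn's sweep), with AUC by trapezoid over recall. Per-base
accounting was chosen over per-peak calls because it is deterministic and
exactly checkable against a confusion-matrix oracle.

## Simulator

The forward model composes the pieces in generative direction: erf
gradient → mass-action oracle (not the closed form — the two routes stay
independent) → linear anisotropy mixing → intensity synthesis with
multiplicative Gaussian camera noise per polarized channel → the standard
FA computation. Acquisition follows the reference protocol: 25 cycles at
7.5 min intervals, 12 planes per stack acquired bottom to top at 300 ms
per frame, wells staggered uniformly across the cycle interval.

Geometry and defaults the source does not state, chosen once:

- gel height 3000 µm, so with the stated 145 µm step and 1400 µm lowest
  plane the focal planes sit 5–1600 µm below the gel top;
- diffusion coefficient 100 µm²/s (order of magnitude for an ~18 bp duplex
  in dilute agarose; fits never depend on its absolute value since only
  the composite width enters);
- gradient time offset t₀ = 300 s (minutes between competitor addition and
  first cycle);
- top concentration c₀ = 4000 nM, matching the top of the printed dilution
  design and large enough to complete the titration for weak binders;
- anisotropy endpoints: free 0.05, bound 0.25;
- relative intensity noise 0.001 per polarized channel, i.e. a per-frame
  FA σ of ≈ 0.6 mP. This emulates the stated instrument performance —
  FA changes of 10–15 mP "accurately detected" and single-frame FA SNR
  above 10 even at ten-fold lower dye concentration — and is the noise
  level at which the pipeline reproduces the reported replicate CVs. The
  per-frame σ scales linearly with this knob, so harsher conditions are a
  parameter away;
- active fraction 1.0 by default (scenarios set 0.4–0.6 to emulate
  partially active protein preparations).

The within-cycle staggering reproduces the observation that competitor
concentrations differ by <30% between the first and last well of a cycle;
this holds in the measurable regime (it is asserted at the final cycle).
Early in the run the deep planes have concentrations that are tiny in
absolute terms, where any erf gradient has a large relative time
derivative; the analysis is unaffected because every data point carries
its own timestamp and no within-cycle matching is ever used.

The DRAQ5 cross-check is a simulator scenario: a second sensor well with
K_D ≈ 10 nM, ten-fold dimmer and proportionally noisier, whose direct
low-concentration readout validates the NB-based extrapolation below
100 nM.

What the simulator does **not** emulate: optical point-spread and
polarization aberrations, convection, photobleaching, gel swelling,
nonspecific protein–DNA binding, TF dimerization, and oligomer-length
effects on diffusivity. Passing synthetic tests therefore demonstrates the
correctness and noise behavior of the analysis chain under the stated
physical model, not robustness to these unmodeled effects in real data.

## Problem sizes in the test suite

The stochastic recovery study uses 50 simulated wells per affinity
(kd₂ ∈ {1, 10, 100} nM) spread over five plates with five calibration
wells each; replicate-CV checks use three same-plate replicates per
competitor. Occupancy checks run on multi-kilobase synthetic regions with
planted sites. These sizes give stable medians while keeping the default
test run to a few minutes on one core.

## Known limitations

- Weak-binder (≳100 nM) K_D precision is ridge-limited as described above;
  an informative prior on R_T (shared protein batch across wells) would
  break the ridge but is deliberately not imposed, keeping wells
  independent.
- The per-plane erf fits do not share c₀ across planes of a well, although
  physically they could; sharing would tighten calibration at the cost of
  coupling plane failures.
- Only single-exponential dissociation and single-site competition are
  modeled; cooperative or multi-site binding is out of scope.
- The gamma-kernel and site-strength transform of the occupancy module are
  declared defaults; evaluating real ChIP data would require calibrating
  them.
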