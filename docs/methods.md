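# Methods

## Signal model

The package models the ROI-mean transverse decay of a myocardial voxel as a
two-compartment biexponential: an intravascular blood pool of volume fraction
MBV and an extravascular tissue pool,

    S(TE) = S0 [ MBV·exp(−TE·R2b) + (1−MBV)·exp(−TE·R2t) ],

with TE in seconds inside the exponents. Slow exchange between the pools is
assumed on the T2 time scale, and the ROI is assumed homogeneous (the package
deliberately operates on ROI means, not voxels, so partial-volume and
intra-ROI heterogeneity are averaged by construction).

**Blood.** Deoxyhemoglobin is paramagnetic, so blood R2 rises with the oxygen
extraction fraction. We use the quadratic calibration

    R2b(OEF, TE) = α1 + α2·OEF + α3·OEF²,

the polynomial form of the van Zijl exchange model evaluated at 1.5 T. The
rendered functional form is exposed as a replaceable table-plus-polynomial
evaluation precisely because different renderings circulate (e.g. OEF entering
through venous saturation rather than directly); the shipped coefficients are
valid for the quadratic-in-OEF reading. The α's grow with the interecho
spacing τ, which for the default T2-preparation scheme is tied to the echo
time (τ = TE/3 with three refocusing pulses), so the table is indexed by TE.
Coefficients differ between coronary sinus (hematocrit 0.40) and myocardium
(capillary hematocrit, conventionally half the systemic value, 0.20). For
echo times between tabulated values the α's are linearly interpolated in TE;
extrapolation is refused unless explicitly enabled. A turbo-spin-echo
acquisition (fixed τ of 8 or 12 ms) requires a user-supplied table — the
shipped one is never silently reused, because its α's bake in the τ = TE/3
schedule.

**Tissue.** Water diffusing through the field gradients around deoxygenated
microvessels adds a quadratic diffusion term to the intrinsic tissue rate:

    R2t = R20t + R21t·(OEF·MBV·τ)²,    τ in seconds.

R20t (1/s) and R21t (1/s³) are subject-specific; R21t lumps the diffusion
constant, susceptibility difference and vessel geometry into a single
calibrated coefficient and is never decomposed further. Units follow the
convention: TE and τ in ms at every interface, seconds inside exponents; R2
in 1/s; R21t in 1/s³; MBV as a dimensionless mL/mL fraction with unit tissue
density (equivalently mL/g). The rest calibration is self-consistent under
any fixed τ convention because R21t absorbs scale.

## Estimation chain

1. **Apparent T2** (`fit_apparent_t2`): joint (S0, T2) trust-region least
   squares of S0·exp(−TE/T2), initialized at S0 = max intensity, T2 = 50 ms,
   objective tolerance 1e−14; deterministic given input. For exactly two
   echoes the interpolating closed form is returned. A non-decaying series
   (fitted T2 unbounded) is an error, not a clipped value.

2. **Coronary-sinus OEF** (`fit_cs_oef`): two-parameter (S0, OEF) fit of the
   pure blood-pool decay, OEF box-constrained to [0, 1], initialized at
   OEF = 0.5. Because the α's vary with TE the decay is not globally
   monoexponential; the fit uses the exact per-echo model. Boundary-pinned
   solutions are flagged in diagnostics. No baseline-offset parameter is
   estimated: magnitude ROI means of a bright-blood acquisition have no
   additive offset worth three parameters at five echoes.

3. **Rest calibration** (`calibrate_rest`): with resting OEF (from the sinus)
   and resting MBV (from perfusion) known, the two-compartment identity is
   inverted per echo for R2t(TE), which is then linear in x = (OEF·MBV·τ)²;
   ordinary least squares gives R20t (intercept) and R21t (slope). The
   unknown scale S0 is handled in one of two modes:

   * `joint` (default): S0 is a third unknown chosen to minimize the residual
     of the linear R2t-vs-x fit (bounded scalar search, initialized from the
     monoexponential fit). On model-consistent data this is exact — the
     inversion reproduces the generating R2t at every echo — which matters
     because the stress inversion is sensitive to R20t at the 1e−3 level.
   * `apparent`: both S0 and the decay come from the monoexponential fit,
     i.e. the inversion consumes the smoothed exp(−TE/T2app) representation.
     This is simpler and slightly more noise-tolerant but biased (the
     biexponential is not monoexponential): at the default operating point
     it distorts R21t by ~18% even without noise. It is retained as an
     option, not the default.

   Echoes where the blood term meets or exceeds the total signal are dropped
   with a warning when at least two echoes remain, otherwise calibration
   fails naming the offending TE. A negative fitted slope is allowed under
   noise but reported as a warning (healthy tissue has R21t > 0).

4. **Hyperemic OEF** (`fit_stress_oef`): the forward map OEF → apparent T2 is
   built by simulating the noise-free two-compartment signal at the candidate
   OEF (with calibrated R20t/R21t and the hyperemic MBV) and reducing it to
   an apparent T2 exactly as a measurement would be. The map is verified
   strictly decreasing on a 21-point scan of [0, 1] (more extraction, faster
   decay — the BOLD direction) before bisection with tolerance 1e−6. A
   measured T2 outside the attainable interval raises an error carrying that
   interval rather than silently clamping.

## Perfusion

First-pass quantification follows indicator-dilution theory: tissue =
AIF ⊛ h with h = MBF·R(t). The deconvolution represents h as a non-negative
combination of 12 decaying exponentials with time constants log-spaced over
0.5–60 s, solved by NNLS with a ridge penalty (`ridge` is relative to the
mean squared design-column norm; default 1e−4, chosen so noise-free recovery
is essentially unregularized while 5% per-curve noise still yields median MBF
error around 5%). This is a documented model-free stand-in for
consolidated-basis deconvolution: few parameters, noise-tolerant, and — unlike
a Fermi model — it does not force an idealized always-decreasing residue
(non-negativity of h is the only shape constraint).

Summaries follow central-volume practice: MBF = 60·max(h) (the peak occurs at
t = 0 for any non-negative sum of decaying exponentials), MTT = area/peak
(which equals the residue time constant for an exponential h, and the boxcar
width for a boxcar), and MBV = MBF·MTT/60, enforced as a constructor
invariant. Area-over-peak was preferred to the first moment because it closes
the central-volume identity exactly for exponential residues. The summary is
evaluated from the basis expansion on a 50× refined grid spanning the
acquisition window: on a 1 s grid the left-Riemann area overestimates the MTT
of a 2–4 s exponential by 12–26%, a pure discretization artifact.
Preprocessing subtracts the pre-contrast baseline (mean of the first five
frames), assumes signal-linear concentration at low contrast dose (a
conversion hook accepts a user function), and offers an optional moving
average (off by default).

## Synthetic data

The generator emulates a healthy rest/adenosine session: five T2-prep echoes
at 24–72 ms, resting state (OEF 0.73, MBV 0.06), hyperemic state (OEF 0.37,
MBV 0.10), R20t 24.5 1/s, R21t 1.06e5 1/s³, MBF 0.89 → 2.97 mL/g/min, and 75
one-second first-pass frames; the session MTTs are derived from MBV =
MBF·MTT/60 so the perfusion and relaxometry truths are mutually consistent.
The AIF is a peak-normalized gamma-variate (onset 10 s, shape 3, scale 1.5 s)
resembling a compact low-dose bolus — arbitrary but fixed. Multi-echo noise
is Gaussian with σ expressed as a fraction of S0 (ROI averaging makes Rician
bias negligible at ROI-mean SNR; a Rician mode exists and its bias is tested
to be <0.1% of S0 at σ = 0.5%). First-pass noise is Gaussian with σ scaled to
each curve's own peak, because the tissue enhancement is roughly an order of
magnitude weaker than the LV input and a common absolute σ would leave the
tissue curve at SNR ≈ 2 before any method sees it. All generators are pure
functions of (parameters, seed).

What the simulations do not emulate: cardiac/respiratory motion, ECG
mistriggering, flow artifacts, B0/B1 inhomogeneity, contrast extravasation
nonlinearity, and model mismatch in the α calibration itself. Passing
round-trip tests therefore demonstrates estimator correctness under the
stated model, not in-vivo accuracy.

## Precision: a known hard limit

The hyperemic inversion is well-posed but poorly conditioned at realistic
MBV: at MBV = 0.10 the forward map spans only ≈ 5.4 ms of apparent T2 across
the entire OEF domain (48.2 ms at OEF = 0 down to 42.8 ms at OEF = 1), while
2% echo noise scatters a five-echo apparent-T2 fit by ≈ 2–3 ms. The package's
Monte-Carlo (100 seeded replicates at σ = 2% of S0 on all series) gives a
median |OEF_stress error| of ≈ 0.26, and 42/100 replicates fall entirely
outside the attainable T2 interval. Useful stress-OEF precision (~0.05)
requires ROI-mean noise well below ~0.3% of S0 — achievable by averaging many
voxels, and the reason the method is defined on large ROIs. This is a
property of any estimator that reduces the stress series to an apparent T2,
not of the particular solver.

Note also that the printed functional form of the blood calibration is not
uniquely determined by its coefficient table alone; under the quadratic
reading adopted here the resting coronary-sinus apparent T2 evaluates to
≈ 42 ms at OEF 0.73 (literature reports ≈ 62 ms for the same OEF), while the
OEF round trip itself is exact. OEF, not blood T2, is the estimator contract.

## Numerical choices and degenerate inputs

All fits are deterministic: fixed initializations (S0 = max intensity,
T2 = 50 ms, OEF = 0.5), trust-region least squares with 1e−14 tolerances,
bisection with 1e−6. Ties/degeneracies: a two-echo series uses the closed
form; r21t = 0 reduces the tissue model to R20t exactly; MBV = 0 collapses
the voxel model to a monoexponential at machine precision; an all-zero
impulse response, a zero-area AIF, and a non-decaying multi-echo series are
errors, not NaNs. Rounding of reported percents happens only in reporting
code, never inside computation (the phantom-error row reproduces the
published 0 / −0.91 / 0.6 values at printed precision and computes −1.08
where −1.0 was reported — reproduced as computed, not forced).

## Problem sizes

Default test and reproduction problem sizes are the study's own: 5 echoes,
75 perfusion frames, 100-replicate Monte-Carlos, 20-case solver/oracle
comparisons, and a 1e−4 OEF grid for the exhaustive oracle. The full suite
runs in well under a minute on one CPU.
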