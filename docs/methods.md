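# Methods

## Signal model

The MPRAGE cycle is modelled as: instantaneous inversion at t = 0
(Mz → −f_inv·Mz, with inversion efficiency f_inv = 0.96 by default;
the ~20 ms adiabatic pulse duration is not modelled), free T1 relaxation
toward equilibrium (normalized to M0 = 1) outside the readout train, and
relaxation toward the driven equilibrium

    M0* = (1 − e^{−R1·TR}) / (1 − e^{−R1*·TR}),
    R1* = R1 − ln cos(fT·α_MP) / TR

inside the train. With linear phase encoding the train occupies
[TI − (TF//2)·TR, TI + (TF − TF//2)·TR] and the central k-space line is
pulse index TF//2 (0-based), i.e. exactly at TI. These two relations are
algebraically exact at pulse instants: the continuous-exponential segment
evaluated at t = k·TR equals the per-pulse recursion
Mz ← 1 + (Mz·cos α − 1)e^{−TR/T1}, which the test suite uses as an
independent oracle (agreement ~10⁻⁶, far inside the 1% contract).

The outer-loop steady state (the cycle-periodic trajectory) is found by
fixed-point iteration of the one-cycle affine map starting from Mz = +1,
at most 50 cycles, tolerance 10⁻⁹; convergence is contraction-dominated
and effectively complete after 2–3 cycles for tissue T1. No closed form is
used so that the code stays auditable against the per-pulse oracle.

The reference GRE has no preparation pulse and sits in the steady state
M0*(fT·α_GRE, T1) throughout. Units: degrees at all public interfaces
(radians internally), seconds internally (the CLI accepts `*_ms` keys).

Inversion convention: Mz → −f_inv·Mz, so f_inv = 1 is a perfect inversion
and f_inv = 0 is a saturating preparation (Mz = 0), not an identity. This
convention is what reproduces the protocol's identifiability limits.

## Lookup table and T1 inversion

The two model signals are combined as S = S_MP·S_GRE/(S_MP² + S_GRE²),
which is bounded by 0.5 (attained at equal inputs) and invariant to common
positive scaling — the algebraic reason receive sensitivity and proton
density cancel. Sequentially measured magnitudes carry no relative phase,
so the signed MPRAGE model value is truncated to its non-negative part
before combination, mirroring the magnitude-only measured data.

Default grids: T1 from 1 ms to 5 s in 1 ms steps (5000 points) and fT from
0.4 to 1.6 in steps of 0.01 (121 columns). The sub-second T1 coverage is
required for the short-T1 fold of strong-transmit columns (the lower
limit at fT = 1.6 is 810 ms); both endpoints are configurable.

**Identifiability.** Each fT column folds at short T1 where S reaches 0.5;
the uniquely invertible branch is the largest contiguous strictly
monotonic run (tolerance 10⁻¹² on consecutive differences) containing the
grid midpoint, anchoring the branch in the tissue regime. Where the signed
MPRAGE signal crosses zero inside the grid (weak transmit field, long T1),
measured magnitudes from beyond the crossing re-enter the branch's value
range; the upper limit is therefore tightened to the T1 at which the
branch value falls to the maximum of the magnitude-combined tail beyond
the crossing. This magnitude-fold criterion is the operational answer to
"where does a measured combined value stop identifying a unique T1";
the simple end of the monotonic run (the zero crossing itself) would
overstate the usable range by ~0.5 s at fT = 0.4.

**Inversion.** For each voxel the nearest fT column is selected (the 0.01
column spacing makes interpolation gains negligible) and the T1 grid point
minimizing |S_meas − S_LUT| on the unique branch is returned, ties broken
toward shorter T1. Measured values outside [0, 0.5] are clamped and
flagged; fT outside the grid is clamped to the edge column and flagged;
matches at a branch endpoint are flagged. Flags are a bitmask in a
companion volume, never silently dropped. Without a B1⁺ map the nominal
fT = 1 column is used. T1 maps are written in milliseconds as 32-bit
float NIfTI.

The LUT is persisted as `.npz` plus a JSON sidecar (grids, sequence
parameters, limits) so mapping runs are reproducible bit-for-bit.

## Normalization

The ratio image is mp/gre wherever the reference exceeds a floor
(default: 5% of the masked reference median — the handling of near-zero
reference voxels is this package's choice); floored voxels are zeroed and
flagged. Grid identity is enforced; registration and brain masks are
external inputs. Coarse references are brought onto the MPRAGE grid either
by centered Fourier zero-filling (matching scanner reconstruction; DC
preserved exactly) or trilinear resampling for non-integer ratios.
Stored-value rescaling follows the float/1000 display convention and is
exactly invertible on integer inputs.

First-order noise propagation of the ratio r = A/B gives
σ_r ≈ (σ/B)·√(1+r²), so the ratio's SNR is below the numerator's by
1/√(1+r²); both are verified by Monte-Carlo (10% tolerance at SNR ≥ 20).

## Synthetic phantom

Three nested ellipsoids emulate a CSF rim / GM shell / WM core with
T1 = 4.0 / 1.8 / 1.2 s and PD = 1.0 / 0.8 / 0.7 (PD and R2* values are
plausible round defaults, not measurements). Transmit and receive fields
are smooth mean-1 multiplicative fields (random low-order polynomial or
broad Gaussian bump; amplitude < 1 keeps them positive; >99% of spectral
energy below 5 cycles/FOV). The transmit field is quantized to the LUT's
0.01 fT step by default, so a supplied fT map is exactly resolvable by
nearest-column lookup and the noise-free round trip is exact to one grid
step; set `ft_quantum=0` for a continuous field (which adds a
column-mismatch error of up to tens of ms). An optional depressed-fT lobe
(fT = 0.3) mimics failed adiabatic inversion. Noise is Rician (magnitude
of complex Gaussian), with a single absolute σ specified relative to the
mean WM MPRAGE signal and applied to both volumes — the shared-receiver
convention; the generator's mean is validated against the closed-form
Rician mean. Multi-session stacks blend the base fields with independent
realizations, field_s = base·(1 + jitter·(indep − 1)), with per-session
seeds spawned deterministically from the master seed.

What the phantom does **not** emulate: realistic anatomy and partial
voluming, k-space artifacts (ringing, motion, parallel-imaging residuals),
point-spread blurring of the transient readout, and slab-profile /
adiabatic-pulse physics beyond the fT-lobe shortcut. Passing tests
therefore validate the algebra and inversion machinery, not robustness to
those real-data effects.

## Metrics

WM–GM contrast C = (S̄_WM − S̄_GM)/(S̄_WM + S̄_GM). CV uses the sample
(n−1) standard deviation over the mean (the denominator convention is this
package's fixed choice), reported as % in summaries and as fractions
internally; CV maps zero-and-flag voxels whose stack mean falls below
10⁻⁶ of the masked median mean. Class averages weight voxels equally
within the class mask.

## Problem sizes

The default phantom experiments run at 64³ voxels (round-trip and noisy
recovery) and 24³–32³ for multi-session reproducibility; the full LUT
(5000 × 121) builds in about one second. These sizes give tens of
thousands of voxels per tissue class, enough for stable medians and CV
summaries while keeping the whole suite fast.

## Known limitations

- The fT = 0.4 upper identifiability limit depends on the fold convention
  (monotonic-branch end vs magnitude-fold uniqueness); the package
  reports the magnitude-fold value, the conservative choice.
- Nearest-column fT lookup introduces no error only when the supplied fT
  map is resolved at the grid step; continuous maps incur a small bias.
- The Eq-for-display small-angle rescaling of reference signals assumes
  the scaling R1 matches the tissue; across T1 of 1–2 s with a fixed
  R1 = 0.83 s⁻¹ it is a windowing convenience only (deviations up to
  ~30%), not a quantitative correction.
- Complex-data (phase-aware) MP2RAGE-style combination is out of scope;
  only the magnitude-positive combination is implemented.
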