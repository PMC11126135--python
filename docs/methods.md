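# Methods

## Compartment model

The voxel is modelled as three non-exchanging pools — muscle tissue,
arterial blood and venous blood — each contributing signal proportional to
its proton-density fraction times the spin-echo relaxation weight
`w = exp(−TE/T2)·(1 − exp(−TR/T1))`. Capillary blood is not a separate
pool: its more oxygenated part is absorbed into the arterial pool and the
rest into the venous pool. The measured IVIM perfusion fraction is the
blood share of the weighted signal,

    f = (f0a·wa + f0v·wv) / (f0a·wa + f0v·wv + (1 − f0)·wm),

with f0 = f0a + f0v the proton-density-weighted (relaxation-free) blood
fraction. At a fixed venous:arterial volume ratio r = fv/fa this inverts
in closed form with the effective blood weight w_eff = (wa + r·wv)/(1+r):

    f0 = f·wm / (w_eff·(1 − f) + f·wm).

Forward and inverse round-trip to better than 1e−12 over the full
parameter range; both maps are strictly monotone. Weights are always
recomputed from (relaxation set, protocol) rather than cached, so
perturbation scans cannot desynchronise times and weights. All fractions
are dimensionless in [0, 1] internally; percent appears only at I/O
boundaries, which prevents silent 100× errors.

Estimating r from two field strengths exploits the constraint that f0 is
a tissue property: a deterministic grid scan (default 0.5–10, step 0.01;
ties to the smallest r) minimises the absolute difference of the two f0
estimates. A grid with documented tie-breaking replaces any graphical
read-off and is exactly reproducible.

### Relaxation-time fixtures

Shipped values (ms) at TE 56 / TR 2800 unless noted:

| set | T2 v/a/tissue | T1 v/a/tissue |
|---|---|---|
| `calf_0.55T` | 148 / 207 / 44 | 1122 / 1122 / 701 |
| `calf_7T` | 20 / 55 / 22 | 2090 / **2990** / 1864 |
| `calf_7T_table` | 20 / 55 / 22 | 2090 / **2290** / 1864 |
| `liver_1.5T` | 148 / 207 / 46 | 1434 / 1435 / 586 |
| `liver_3T` | 48 / 111 / 34 | 1584 / 1664 / 809 |

No blood T2 measurements exist at 0.55 T; the 1.5 T literature values are
adopted there because arterial T2 is reported field-independent between
0.55 and 1.5 T. The two 7 T variants exist because the literature source
for arterial T1 at 7 T is quoted inconsistently (2990 ms in running text
vs 2290 ms in tabulated summaries); `calf_7T` (text value) is the default.
The choice matters for the ratio scan: reconciling the measured
gastrocnemius means (7.08 % at 0.55 T, 3.84 % at 7 T) yields r ≈ 6.2 with
the tabulated variant but r ≈ 4.9 with the text variant. The
`reproduce ratio-scan` command uses `calf_7T_table`, the parameter set
under which both field strengths and both activation states agree on a
common f0; either way the data are venous-dominated (r well above 1).

The 7 T blood T2 values derive from a quadratic fit of R2 = 1000/T2
against B0 (`interp` module). The fit is purely numerical — no physical
dispersion model — and extrapolation outside the fitted field range is
flagged with a warning: below ~1 T the extrapolated venous rate goes
negative and the arterial rate nearly vanishes, which is why measured
low-field values are used instead. The shipped point sets contain only the
1.5/3/4.7 T literature points, so the three-point venous fit evaluated at
7 T gives ≈ 18.5 ms rather than the rounded 20 ms obtained when an
(unpublished here) 11.7 T point is included; user-supplied points at
further fields can be added through the same YAML schema.

### Liver cross-field check

The liver consistency check carries the measured f = 28.6 % at 1.5 T
(TE 100 ms) to 3 T by inverting at 1.5 T and re-applying the forward model
at 3 T. The original acquisition's TR is unknown, so the check runs in the
long-TR limit (`SequenceProtocol.long_tr()`), dropping the T1 factor; at
r = 4 this predicts f(1.5 T)/f(3 T) ≈ 1.26, at r = 1 it predicts
f(3 T)/f(1.5 T) ≈ 1.01 — i.e. a noticeable B0 dependence is expected only
for venous-dominated blood.

## Segmented IVIM fit

With no b-values below 50 s/mm², D* cannot be estimated; the fit is the
first step of a segmented approach: OLS of ln(S/S0) against b over
b ≥ 100 s/mm² (threshold configurable; some studies use ≥ 200), D = −slope
and f from the intercept c at b = 0. Two intercept conventions are
recorded: the default f = 1 − e^c, exact for two-compartment data with
fully suppressed pseudo-diffusion signal, and the literal linearised form
f = −c; they agree to first order (difference ≤ c²/2, under 0.3 pp at the
observed f range). Least squares is unweighted because the inputs are
per-b averaged ROI means; repetition counts are available on the protocol
if a user wants weighting.

With a finite D* = 20 µm²/ms the b = 100 s/mm² point retains
e^−2 ≈ 13.5 % of the perfusion signal, so the segmented estimates carry a
structural bias: on noise-free curves with f = 0.07, D = 1.41 µm²/ms the
fit returns D ≈ 1.435 and f ≈ 0.0570. This bias is a property of the
acquisition design, not of the implementation, and it propagates through
the model inversion (see "What passing tests show" below).

The optional biexponential fit (trust-region least squares with bounds
f ∈ [0,1), D ∈ (0,5], D* ∈ (0,200] µm²/ms, initialised from the segmented
fit) recovers exact parameters on noise-free data, but with five b-values
and none below 50 s/mm² the D* estimate is ill-conditioned — its spread
across noise realizations is of the order of the parameter itself — so
segmented estimates are used for reporting throughout.

Units: D and D* in µm²/ms (= 1e−3 mm²/s), b in s/mm²; the b·D product is
made dimensionless by an explicit 1e−3 factor in exactly one place.

## SNR and noise model

Background-ROI SNR estimators assume single-coil Rayleigh statistics:
sigma is recovered from the background mean via mean = σ√(π/2) or from
the background standard deviation via std = σ√(2 − π/2), and SNR =
tissue mean / σ. (Printed renderings of these estimators often lose the
radicals; the implementation works from the Rayleigh moment relations
directly.) On multi-channel coils both are approximations; on true
Rayleigh data they agree to within Monte-Carlo error, which is tested. An
all-zero background (integer-rounded high-field data) yields a flagged
"unmeasurable" result instead of an exception. ROI-mean SNR scales as
√N_ROI; a `paper_style` rounding mode reproduces the back-of-envelope
7·round(√23) = 35.

Rician noise is generated as √((s+n₁)² + n₂²) with independent Gaussians
n₁, n₂; its floor bias (mean noisy magnitude ≥ true magnitude) is the
mechanism by which low SNR biases IVIM parameters. No noise-floor
correction is applied to fits; at the study's effective ROI SNR (~35) it
is not needed.

## Synthetic-study generator

`simulate_study` emulates the acquisition design: 8 subjects × 2 field
arms (0.55 T and 7 T, TE 56 / TR 2800 ms) × 2 muscles × 2 activation
states × 15 slices, b = 0/50/100/500/600 s/mm² with 2/2/2/4/4 repetitions,
ROI of 23 voxels, voxel-level SNR 35 at b = 0. Ground-truth defaults:
gastrocnemius f0 = 0.031 (doubling to 0.060 with activation, matching the
model inversions of the measured means), D = 1.41 µm²/ms (+5 % with
activation, the observed temperature-consistent shift); tibialis anterior
f0 = 0.0158 (the model inversion of its measured ~3.6 % fraction),
D = 1.65, no activation response; r = 4 for both; D* = 20 µm²/ms, an order
of magnitude above D, configurable since the study measured no D*.
Between-subject variability is lognormal and median-preserving with CV
20 % on f0 and 5 % on D — invented but configurable; it exists so the
statistics stage has realistic spread. Noise is applied per voxel per
repetition before magnitude averaging and ROI averaging, reproducing the
√N SNR gain of ROI analysis. Both legs / single-leg asymmetry between the
field strengths is not emulated; the factorial is balanced.

### What passing tests show — and do not

The generator is the package's own forward model plus Rician noise; tests
against it demonstrate internal consistency (pipeline closure, effect
directions, calibration), not fidelity to real muscle. In particular:

- Noise-free closure: segmented fit + inversion recovers the configured
  f0 to within the segmented-fit bias bound (< 1.5 pp on f at D* = 20,
  threshold 100). The bias maps measured f ≈ 0.0696 → fitted ≈ 0.0567 →
  inverted f0 ≈ 0.0250 against the configured 0.031, i.e. a median f0
  deficit of ≈ 0.006. A stricter recovery demand (|median bias| < 0.005)
  is therefore not attainable at these design parameters and the
  corresponding acceptance test documents this as a failure by design
  honesty rather than being weakened. With larger D* or a lower b
  threshold the bias shrinks accordingly.
- Direction effects: with identical f0 at both fields, fitted f is lower
  at 7 T in > 95 % of paired realizations; configured f0 doubling raises
  fitted f at both fields in > 95 %. These test the sign and robustness of
  the relaxation mechanism, not its magnitude in vivo.
- Real data add partial-volume fat, vessel contamination, motion, EPI
  distortion and between-slice physiology, none of which are simulated.

## Statistics

Paired contrasts are gated on normality of the differences: Shapiro–Wilk
at alpha = 0.05 routes to the paired t-test (p ≥ alpha) or the Wilcoxon
signed-rank test. The gated procedure's type-I error is calibrated (tested
within the binomial 95 % CI of 0.05 over 1000 null simulations). Per-slice
values can be pooled as observations (matching the source analysis) or
averaged per subject first; the per-slice pooling ignores within-subject
correlation, so its p-values are anti-conservative — both groupings are
offered. No multiple-testing correction is applied, matching the source
design.

## Numerical choices

- Ratio grid default 0.5–10 step 0.01; argmin with first-hit (smallest-r)
  tie-breaking; degenerate identical-field inputs return the grid minimum.
- Round-trip tolerance 1e−12 (float64 closed forms); weight examples
  asserted at 1e−4.
- `tr = inf` is the supported long-TR limit; `te → 0, tr → ∞` drives every
  weight to 1, the proton-density limit in which f = f0 exactly.
- f0 sub-fractions are defined by difference (f0v = f0 − f0a) so
  additivity is exact in floating point.
- Segmented fits require ≥ 2 points at or above the b threshold; fit
  results on noisy data are reported unclipped (no truncation at 0) to
  keep medians unbiased; inversion call sites clamp negative fitted f to 0.
- Seeds: every stochastic component takes a `numpy.random.Generator` or an
  integer seed; identical seeds give bit-identical datasets and tables.

## Known limitations

- Relaxation weighting assumes fully non-exchanging pools and
  literature relaxation times; hematocrit and oxygenation vary between
  individuals, and the sensitivity scans (venous T2 −15 %, arterial T2
  −50 %, muscle T2 +25 %, blood −5 % with muscle +5 %) show that plausible
  relaxation-time errors move the f0 estimate substantially, especially at
  7 T where T2 of venous blood and muscle are short against TE.
- The f0 estimate at high field depends strongly on the assumed fv/fa; at
  0.55 T it is insensitive to it (venous and arterial weights nearly
  coincide), which is why low field is preferred for estimating f0.
- Oxygenation levels are not estimated (would require multi-TE/TR data);
  no capillary pool; no image-space simulation (DICOM/NIfTI, distortion,
  eddy currents) — inputs are ROI-mean tables by design.
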