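# Methods

This note documents the models and conventions implemented in
`nirsvft`: what each stage computes, the defaults and why, what the
synthetic cohorts emulate, and where the honest limits are.

## Paradigm and data model

All computations are indexed through one timing object
(`Paradigm`): a 25 s pre-task rest, three consecutive 20 s
word-generation blocks (60 s task period, no inter-block rest), and a
55 s post-task rest, sampled at 5 Hz — 700 samples per recording.
Times are seconds, sample index = round(t·fs), windows are half-open
`[start, stop)` and 0-based. A recording is a 48-channel × 700-sample
HbO₂ matrix in mmol/L·mm (concentration × pathlength, so the unknown
source–detector distance cancels); channels are grouped into nine
regions of interest (bilateral SFC, DLPFC, STC, VLPFC, and midline
mPFC). The full channel→ROI assignment is device-specific and
configurable; the shipped default is a documented plausible layout
constrained to the published anchors (channels 16 and 36 in mPFC,
channel 18 in lDLPFC) with equal left/right counts in the eight
lateral ROIs (5 channels each; 8 in mPFC). All downstream mathematics
is map-agnostic.

## Preprocessing

Fixed stage order: *(optional MBLL) → motion detection/repair →
low-pass → panning*, logged in the recording's provenance metadata.

**MBLL.** When a recording carries raw dual-wavelength intensities,
optical-density changes ΔOD_λ = −log₁₀(I/I₀) are converted to HbO₂ and
HbR by solving the 2×2 extinction system per sample. Extinction
coefficients (785 nm: 0.0735/0.1104; 825 nm: 0.0927/0.0773 per
mmol/L·mm for HbO₂/HbR) and differential pathlength factors (6.0) are
literature-typical configuration values, not device calibrations. I₀
is the stored emission reference when present (making the conversion
an exact algebraic inverse of the simulator's forward model, verified
to 1e−9) or else the mean over the first 10 s.

**Motion artifacts.** Flagged where the moving-window z-score of the
first difference exceeds 5: the centre is a 2 s moving median and the
scale a per-channel robust sd (1.4826 × MAD of all differences), so a
large spike cannot hide by inflating a local standard deviation. Flags
are dilated by half a window each side. Repair bridges each flagged
span with the cubic through the two nearest clean samples on either
side (batched 4×4 Vandermonde solve; linear at record edges). Cubic
interpolation of a linear trend is exact, which the tests assert.
Sharp spikes are therefore removed; slow baseline *steps* survive as
low-frequency content — a deliberate conservatism noted under
limitations. Both method and thresholds are configuration.

**Filtering.** 4th-order Butterworth low-pass at 0.1 Hz, applied
forward–backward (zero-phase, effectively 8th-order magnitude).
Contracts: DC gain exactly 1; a 1.1 Hz (cardiac) unit sine is
attenuated below 0.01; a 0.01 Hz sine passes above 0.99; the operator
is linear to 1e−8. No high-pass is applied by default (panning handles
offsets); an optional high-pass exists for sensitivity analyses.

**Panning.** Each channel is shifted so the minimum of the last 10 s
of the *pre-task* rest becomes exactly 0. The pre-task window was
chosen as "the baseline state" because it is the only rest preceding
the task; the operation is idempotent. Panning shifts means but no
contrast or correlation, so this choice is inferentially neutral.

**Quality.** A channel is good iff finite, not flat (sd > 1e−6, which
catches saturated or disconnected optodes), and < 20% artifact-flagged
samples. A subject enters analysis only with ≥ 36 good channels at
*both* timepoints; the boundary is inclusive (36 passes, 35 fails).
The ≥ 36 gate is fixed by the study design; the composite goodness
rule is this package's definition and is configurable.

## Activation statistics

Per subject and channel, the contrast is
mean(HbO₂ over the 60 s task window) − mean(HbO₂ over the full 25 s
pre-task rest). Group inference is always across subjects (no
single-session t-maps): paired t-tests per channel, with
Benjamini–Hochberg adjusted q-values over the 48-channel family per
(group × comparison); significance at q < 0.05. Channels missing for
all subjects shrink the family size m rather than being imputed. The
ROI table averages member-channel contrasts per subject (good channels
only), tests pre vs post within groups through the normality gate
(below), compares change scores between groups with a pooled-variance
t and Cohen's *d*, and reports raw p as primary with q alongside —
a 9-test table is conventionally read uncorrected.

The step-up rule is implemented directly
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, clipped to [0,1]) and is checked for exact
agreement with statsmodels' implementation on 1000 random vectors, for
monotonicity, and for empirical FDR control in partial-null
simulations.

## Connectivity statistics

FC is the Pearson correlation between two channels' preprocessed HbO₂
series over the task window only (300 samples). All averaging and
inference happen on the Fisher z = atanh r scale (variance
stabilisation; a raw-r switch exists for sensitivity checks), with
back-transformation for reporting: ROI-pair entries are
tanh(mean z over member channel pairs), the grand mean FC is
tanh(mean z over all 1128 unordered pairs). Bad channels are deleted
pairwise and families shrink accordingly. Change statistics are paired
t on z_post − z_pre within groups and pooled t with Cohen's *d* (on
the z scale) between groups, BH-corrected within the 1128-pair or
45-ROI-pair family; the single grand-mean comparison is uncorrected.
The brain–behaviour statistic is Pearson r between per-subject PSQI
improvement and mean-FC change, with p from t = r√((n−2)/(1−r²)) and
a Fisher 95% CI.

## Clinical-scale statistics

**Normality gate.** Shapiro–Wilk at α = 0.05 decides parametric vs
nonparametric; both samples must pass for a parametric between-group
test. **Paired:** the reported "change mean (95% CI)" is always the t
interval on change scores (df = n−1); the test is paired t or Wilcoxon
signed-rank (exact for n ≤ 10 without ties, normal approximation with
continuity correction otherwise). All-zero differences return t = 0,
p = 1, flagged; constant nonzero differences return ±∞ with p = 0,
flagged. **Between:** pooled-variance t with signed Cohen's
d = (m₁−m₂)/s_pooled and a noncentral-t CI for d (pivot on the
noncentrality parameter), or Mann–Whitney U reported as the signed
normal-approximation Z with rank effect size r = |Z|/√N. d is negative
when group 1 improves (decreases) more. **Reproduction mode** inverts
printed t intervals (sd = width/2·√n/t₀.₉₇₅,ₙ₋₁) to recover change-
score sds, letting published effect sizes be re-derived from summary
tables; this reproduces the study's printed d values to 3 decimals.
**χ².** Pearson χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without
continuity correction — the variant that reproduces all three printed
contingency statistics exactly; zero marginals are an error.
**Power.** Two-sided two-sample t power via the noncentral t
(df = 2n−2, ncp = d√(n/2)), iterating n upward to the smallest n
reaching target power; dropout inflation is multiplicative,
ceil(n·(1+rate)) per group — the rule consistent with 31 → 76 total at
20% (division by (1−rate) would give 78).

## The synthetic cohort generator

Each channel's raw signal is composed as

```
y_c(t) = a_c · x(t)                           task response
       + s · ( Σ_k w_ck L_k(t) + η_c(t) )     latent-factor structure
       + AR(1) broadband + oscillations + drift
       + spikes + baseline shifts             motion artifacts (last)
```

- **x(t)** is the three-block boxcar convolved with a canonical
  double-gamma HRF (peak 6 s, undershoot 16 s, amplitude ratio 1:6),
  rescaled to unit peak. The HRF is simulator-internal, not a claim
  about the device.
- **Amplitudes a_c** are per-(group, timepoint, ROI) means — defaults
  taken from the trial's printed per-ROI task contrasts for both
  groups and sessions — plus per-subject (sd 0.06) and per-session
  (sd 0.04) ROI-level jitter in mmol/L·mm.
- **Latents L_k** are unit-variance processes shared within
  *communities*: one global community over all 48 channels (baseline
  loading 0.75), one "executive" community spanning
  lSFC∪lDLPFC∪mPFC∪rDLPFC (0.35), and one per ROI (0.65). At the post
  timepoint each subject draws loading increments: global
  N(0.20, 0.09) intervention vs N(0.06, 0.09) control, executive
  N(0.10, 0.05) vs N(0.02, 0.05) — this is what produces the broad
  mean-FC rise plus the extra frontal ROI-pair enhancement in the
  intervention group. η_c is unit-variance idiosyncratic noise, so two
  channels sharing one latent with loading w have exactly
  r = w²/(w²+1), a law the tests verify. Each community's shared
  variance is spread over several independent latents (8/4/2),
  physiologically "global physiology is many processes"; correlations
  are unchanged. Latents and η share one spectrum (white noise shaped
  by a 2nd-order 0.08 Hz low-pass), so any linear preprocessing leaves
  their mutual correlations intact; s = 0.03 mmol/L·mm sets the scale.
- **Noise**: AR(1) broadband (innovation sd 0.05, coefficient 0.3),
  Mayer (0.10 Hz, amp 0.02), respiratory (0.25 Hz, 0.02) and cardiac
  (1.10 Hz, 0.04) sinusoids with independent random phases, and linear
  drift with slope sd 2e−4 per s — content the 0.1 Hz low-pass has
  real work against.
- **Artifacts** (injected after composition, so preprocessing must
  genuinely remove them): spikes at 1/min with amplitude sd 0.5, and
  baseline shifts at 0.05/min with amplitude sd 0.03.
- **Scales**: baselines and pre→post improvements per group follow the
  trial's printed means, with improvement sds recovered from printed
  CIs; integer scales are rounded and clipped to instrument ranges
  (PSQI 0–21, sub-dimensions 0–3, SDS/SAS index 25–100, PSS-14 14–70).

**Ground truth.** For every subject the generator records the
model-implied task contrast (amplitude × the contrast factor of the
preprocessing-filtered regressor) and the model-implied FC matrix. The
expected task-window Pearson correlation is computed component-wise:
shared-latent covariance and every variance term are integrated
numerically over frequency with the zero-phase filter's |H(f)|⁴ power
gain and a Dirichlet window factor accounting for task-window mean
removal; the filtered regressor contributes a rank-one term with its
empirical window variance. These expectations agree with long-window
simulations to within Monte-Carlo error and anchor the
parameter-recovery tests (cohort-mean contrast change and mean-z
change within 2 standard errors at n = 32/group).

**Scale coupling.** A central empirical fact shapes the design: with a
0.1 Hz band and a 60 s window, any task-window Pearson estimate has
only ~10 effective degrees of freedom, and the cohort-mean FC estimate
carries an irreducible, largely coherent sampling error of ≈ 0.1
r-units per session (≈ 0.14 per pre/post change) — splitting community
variance across more latents does not reduce it, because all pairs
share the realized latent Gram structure. Any correlation defined
against the *model-implied* FC change would therefore appear heavily
attenuated in the *measured* change. The generator consequently
couples the PSQI improvement to the **observable**: when recordings
are rendered, it runs the package's own preprocessing + task-window FC
on them, standardizes the measured mean-FC change within the group
cohort, and draws improvement = μ + σ(ρ·u + √(1−ρ²)ε). The configured
ρ (default 0.5) is then exactly the population correlation of the
quantity an analyst measures — which is also the kind of quantity
observational studies report. For scale-only cohorts (no recordings)
the coupling falls back to the model-implied change standardized by
cached Monte-Carlo moments (2048 draws).

## Numerical conventions and degenerate inputs

Fisher z clips |r| at 1−1e−12 before atanh; round-trip accuracy is
1e−12. Paired t with all-zero differences returns t = 0, p = 1 by
convention. Zero-variance channels yield missing FC rows/columns, not
zeros; missing values shrink FDR families. The noncentral-t CI solver
brackets the noncentrality parameter at t ± (20 + 2|t|) and treats
far-tail NaNs from the CDF as their limiting values. All simulator
randomness derives from one seed through named integer substreams
(seed, group, subject, stage), making reruns byte-identical.

## Problem sizes used by the test suite

Chosen as this package's verification budget: type-I calibration uses
500 null replicates × 9 ROI tests at n = 32 (tolerance 0.05 ± 0.02);
FDR control uses 500 partial-null replicates of the 48-channel family
(mean false-discovery proportion ≤ 0.07); parameter recovery uses one
full default cohort at n = 32/group; coupling recovery uses 200
simulated intervention cohorts at n = 32 with a ≥ 93% Fisher-CI
coverage criterion; oracle equivalences use 1000 random p-vectors and
100 random FC windows.

## Limitations

- **Task-window FC precision.** The ~10 effective dof per pair bound
  estimation precision for *any* analysis under this paradigm and
  filter; simulated between-subject spreads of measured mean-FC change
  (≈ 0.17) are accordingly dominated by estimation noise. This
  reproduces the magnitude reported for a control arm of such a trial
  (± 0.162) but cannot reproduce a spread several times smaller than
  the estimator's own sampling noise.
- Baseline *shift* artifacts survive repair as slow content and are
  not part of the expected-FC model; their residual effect is a small
  (few-percent) attenuation absorbed by the 2·SE recovery criteria.
- The simulator does not model scalp/skull optics, short-separation
  physiology, or independent HbR dynamics (HbR is a fixed −1/3 ratio
  of HbO₂ used only by the MBLL round trip). Passing tests demonstrate
  the statistics and signal processing, not device realism.
- The default channel→ROI map is a plausible fixture, not the vendor
  layout; analyses on real data should supply the device's map.
- Oscillation phases are independent across channels; systemic
  common-mode physiology (which inflates real FC) is represented by
  the global latent community instead.
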