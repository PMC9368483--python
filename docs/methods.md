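# Methods

`retphys` quantifies retinal vascular physiology the way a preclinical
two-group imaging study does: raw measurement signals are converted into
per-vessel quantities, aggregated into per-eye metrics, and compared across a
wild-type (WT) and a 5XFAD (Alzheimer-model) group. Because such studies
publish summary statistics rather than raw data, the package pairs the
measurement chain with a synthetic-cohort generator calibrated to the group
summaries, so every stage can be exercised and validated end to end.

## Measurement chain

**Phosphorescence-lifetime oximetry.** An oxygen-sensitive Pd-porphyrin probe
is excited with sinusoidally modulated light; the emission lags by a phase φ
with tan φ = 2πfτ, where f is the modulation frequency and τ the
phosphorescence lifetime. The phase is estimated by linear least squares on
[1, cos ωt, sin ωt] regressors — closed form and deterministic. Oxygen
quenches phosphorescence following Stern–Volmer, 1/τ = 1/τ₀ + k_q·PO₂, so
PO₂ = (τ₀/τ − 1)/(k_q·τ₀). Hemoglobin saturation uses a Hill dissociation
curve SO₂ = PO₂ⁿ/(P₅₀ⁿ + PO₂ⁿ) (evaluated as a logistic in log PO₂ for
numerical stability; SO₂(P₅₀) = 0.5 exactly), and blood oxygen content sums
the hemoglobin-bound and dissolved fractions:
content = c_Hb·[Hb]·SO₂ + α·PO₂.

Constants (defaults, configurable, identical in both groups so group
contrasts do not depend on their absolute accuracy):

| constant | default | units | note |
|---|---|---|---|
| τ₀ | 637 µs | s | unquenched Pd-porphyrin lifetime |
| k_q | 381 | mmHg⁻¹s⁻¹ | quenching constant |
| P₅₀ | 40 | mmHg | C57BL/6 mouse hemoglobin |
| n | 2.59 | — | Hill cooperativity |
| [Hb] | 15 | g/dL | assumed, not measured per animal |
| c_Hb | 1.39 | mLO₂/g | binding capacity |
| α | 0.003 | mLO₂/dL/mmHg | plasma solubility |

Lifetimes up to 2% above τ₀ (noise on an anoxic vessel) are clamped to
PO₂ = 0; larger excursions raise. The content→PO₂ inverse used by the
generator is a bracketed root find (Brent, 10⁻⁹ mmHg tolerance), valid
because content is strictly monotone in PO₂.

**Velocimetry.** Fluorescent microspheres are imaged at 104 Hz; each track's
coordinates are projected onto their principal axis (vessels treated as
locally straight) and the along-axis coordinate regressed on time. Speed is
the slope magnitude, so the estimate is invariant to frame rotation and
temporal offset. Vein velocity is the unweighted track mean; eye-level V_V
the unweighted vein mean, mirroring the unweighted vessel averaging of the
study protocol.

**Caliber.** Vessel diameter is the full width at half maximum (FWHM) of the
background-subtracted angiographic cross-profile; background is the median of
the outer 10% of samples on each edge, and crossings are linearly
interpolated, making the estimate invariant to affine intensity rescaling.
FWHM-vs-edge-gradient is a genuine convention choice; FWHM is used and
documented here.

**Flow and oxygen metrics.** Per-vein flow Q = V·(π/4)·D², i.e.
Q[µL/min] = V[mm/s]·(π/4)·D[µm]²·6×10⁻⁵; TRBF is the vein sum. O₂A and O₂V
are unweighted vessel means, O₂AV = O₂A − O₂V, and
DO₂ = TRBF·O₂A, MO₂ = TRBF·O₂AV, OEF = MO₂/DO₂ (= O₂AV/O₂A, independent of
flow), with DO₂/MO₂ in nLO₂/min via the factor 10 from µL·mLO₂/dL. All
delivery metrics are computed **per eye first** and only then averaged across
animals: the mean of a product is not the product of means, so group-level
DO₂/MO₂/OEF cannot be recovered from group-mean TRBF and contents (tested).

**Morphometry.** Ordered boundary depths from the inner limiting membrane
yield layer thicknesses by differencing. Mouse histology cannot separate the
nerve fiber and ganglion cell layers, so NFL/RGCL = IRL − (IPL + INL), where
IRL spans the ILM to the INL outer edge. Nasal and temporal records are
averaged element-wise; a missing region falls back to the other with a flag
(rather than dropping the eye). The NFL/RGCL share of the inner retina,
100·NFL_RGCL/IRL, is ≈19% at the WT calibration means.

## Cohort statistics

Two-group contrasts use unpaired two-tailed Student (pooled-variance)
t-tests; associations use Pearson r with the t-based two-tailed p.
Shapiro–Wilk is available as an advisory normality check only, and no
multiplicity correction is applied (the report records the test count).

Post-hoc power follows the conventions of dedicated power software:

- **Two-sample t:** d = |m₁−m₂|/s_pooled, noncentrality δ = d·√(n₁n₂/(n₁+n₂)),
  power = P(|T′| > t_crit) under the noncentral t with n₁+n₂−2 df. At zero
  effect this returns exactly α.
- **Correlation:** the critical sample r is r_crit = t_crit/√(n−2+t_crit²).
  The default "exact" method integrates the exact (Hotelling) density of the
  sample correlation of a bivariate normal over both rejection tails
  (hyp2f1-based density, adaptive quadrature). A bias-corrected Fisher-z
  approximation (ẑ ~ N(atanh ρ + ρ/(2(n−1)), 1/(n−3)), dominant tail) is
  provided as an option; it agrees with the exact method to <0.01 at
  moderate effects but rounds differently at the percent level (e.g. 88.4%
  vs 88.7% at ρ=0.57, n=26). Both closed forms are validated against
  Monte-Carlo rejection rates (10⁵ replicates, 3×3 effect×n grid, 3 SE).

At the calibration group summaries the package computes 98% power for the
V_V contrast and 55% for O₂V, and 89%/68% for correlations of 0.57 (n=26)
and 0.53 (n=19). The O₂A and D_V contrasts give 68% and 69% from the
rounded calibration summaries; published analyses of this design report 72%
and 53%, consistent with power software fed unrounded sample statistics —
those two values are therefore not reproducible from rounded summaries and
are not asserted anywhere.

## Synthetic-cohort generator

The generator emulates the study conditions: two groups of 13 animals, four
arteries and four veins per eye, 104 Hz sphere imaging, and group
calibration tables holding the published means/SDs for hemodynamics (D_A,
D_V, V_V), oxygen contents, six retinal layers, OCT total retinal thickness,
and retina/brain Aβ40/Aβ42. The 5XFAD IPL/INL/PRL entries reuse the WT
values (their group difference is reported as non-significant without
printed means).

**Correlation structure.** (O₂A, V_V, NFL/RGCL, O₂V) are drawn per animal
from a single-factor multivariate normal with O₂A as the factor. The
O₂A–V_V and O₂A–NFL loadings are found by 1-D root finding so that the
POOLED two-group correlations match the configured targets (−0.57, −0.53):
pooled r combines the between-group separation of means with the
within-group coupling, and is affine in the within-group correlation, so the
root is unique when the target is reachable. At the default tables the
calibrated loadings are ≈ −0.43 (V_V) and ≈ −0.53 (NFL). The O₂A–O₂V
loading (≈ +0.73) is set from the published O₂AV spread via
var(O₂AV) = var(O₂A)+var(O₂V)−2ρ·sd(O₂A)sd(O₂V); without it the generator
produces O₂AV SDs near 2.4 (published: 1.3) and ~6% of animals with
unphysical negative extraction. Remaining metrics are independent normals.

**Positivity.** Negative draws are rejected and redrawn — only the violating
metric's independent residual, so rejection cannot bias correlated metrics.
Truncation bias is then confined to metrics whose calibration puts
appreciable mass below zero: at the default tables, WT O₂V (2.8±1.9, ~7%
negative mass, truncated mean ≈ +0.2 above nominal, SD ≈ −12%) and 5XFAD
retinal Aβ42 (5.4±2.6, ~2%). This is unavoidable for any positive
distribution asked to carry those printed moments; the fidelity tests assert
the exact truncated-normal moments (quadrature oracle) rather than
pretending the bias away.

**Derived, not drawn.** TRBF, DO₂, MO₂ and OEF are computed from each
animal's vessel truths rather than drawn: four veins at the WT means imply
TRBF ≈ 1.78 µL/min, consistent with the published 1.73 ± 0.52 (kept in the
tables as a consistency reference). This is what makes the noiseless round
trip an identity.

**Raw signals.** Per-vessel values are jittered around the per-animal truth
with a 10% within-eye CV, recentred so the eye mean equals the truth
exactly. Each vessel gets a modulated phosphorescence trace (96 samples,
2 periods at 250 Hz — near-optimal modulation for a 637 µs lifetime; phase
noise 0.005 rad, equivalent to ~1.5 mmHg PO₂ reproducibility), each vein
5 microsphere tracks of 10 frames with 1 µm centroid jitter, and each vessel
a caliber cross-profile at 0.5 µm pitch. The profile model is a boxcar
convolved with a uniform 4 µm edge-spread kernel (a trapezoid): its linear
ramps put the half-maximum crossings exactly at ±D/2 under linear
interpolation at any grid alignment, which a Gaussian edge cannot do at
realistic pitch; an extra Gaussian blur is available as a config option.
Layer boundaries are emitted nasally and temporally with thicknesses
symmetric about the truth (±3% asymmetry SD), so the regional average is
exact. A histology shrinkage knob exists (default 1.0: the layer
calibrations are themselves post-shrinkage histology values, and histology
TRT ≈ 172 µm sits well below the OCT TRT calibration of 242 µm already).
OCT TRT and protein levels are truth-level only — their acquisition chains
(OCT segmentation software, ELISA) are out of scope.

**What the generator does not emulate.** Real eyes have curved vessels,
vessel-calibre-dependent velocity profiles, non-Gaussian measurement noise,
missing data from failed imaging, and biological correlations beyond the
single-factor structure. Passing tests therefore demonstrate that the
measurement chain and statistics are correct and calibrated under the stated
model, not that the model captures every property of real cohorts.

## Numerical choices and problem sizes

- Lifetime phase fit: linear least squares (no iteration, no initialisation).
- Content inverse: Brent on [0, 800] mmHg, xtol 1e-9.
- FWHM: edge-median background, peak-relative half-max, linear interpolation;
  flat profiles and missing crossings raise.
- Determinism: one root `SeedSequence` per cohort, one spawned child per
  animal, so cohorts of different sizes share their leading animals and
  re-runs are byte-identical (SHA-256 of every CSV recorded in the manifest).
- Validation suites use 10⁴ animals/group for calibration fidelity, 10⁵
  Monte-Carlo replicates for power-function checks, 10⁴ permutations for
  p-value cross-checks, and 200 seeded 13+13 cohorts for pooled-correlation
  recovery — sizes at which Monte-Carlo error is well below the asserted
  tolerances while the full suite runs in about a minute.

## Known limitations

- Probe and dissociation constants are literature defaults, not fitted; all
  absolute oxygen values inherit their uncertainty (relative group contrasts
  do not).
- Pooled-correlation recovery at n=26 carries the small-sample bias of the
  sample correlation (E[r] ≈ −0.560 for ρ = −0.57) plus mild attenuation
  from measurement noise on O₂A; the recovered mean over 200 cohorts is
  ≈ −0.56.
- The single-factor correlation structure cannot represent arbitrary
  correlation matrices; targets implying non-PSD structures are rejected
  with a message.
- With degenerate (near-zero) within-group SDs in a two-group config the
  pooled correlation is fixed at ±1 by the group means alone, so
  pooled-correlation calibration is only meaningful with nonzero
  within-group variance.
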