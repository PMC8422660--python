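# Methods

This note documents the models, conventions and design choices behind
`planrisk`, in the order data flows through the package.

## DVH representation and dosimetric metrics

A structure's dose distribution enters as a **cumulative** DVH: dose edges
(Gy, strictly increasing, starting at 0) against the volume fraction in
[0, 1] receiving at least that dose, with the absolute structure volume in
cc held alongside.  Cumulative is canonical because it is what planning
systems export; the differential view (per-bin volume at the bin-midpoint
dose, with any residual cumulative volume beyond the last edge treated as a
point mass at the last edge) is derived on demand and feeds every
dose-averaging model.  Percent and cc volume columns are exact conversions
of this form.

Interpolation is linear between tabulated points for both dose-at-volume
(Dx%) and volume-at-dose (Vx).  Two deterministic conventions close the
corner cases:

* the leading plateau at cumulative = 1 carries no information about where
  the curve starts falling, so D(f) for f at the plateau value returns the
  plateau's end — a uniform-dose structure returns its dose for every
  fraction, and D100% of a falling curve is its minimum dose;
* on an interior flat segment exactly at the requested fraction, the
  *lowest* dose achieving it is returned.

Synthetic/rasterized curves use a 0.05 Gy bin width, which keeps metric
error below ~0.1% at the 50 Gy prescription scale (the rebinning-invariance
tests bound the interpolation error directly).

HI follows ICRU 83, (D2% − D98%)/D50%, with D50% computed from the DVH.
CI and CN follow Paddick; because the prescribed-isodose volume V_rx and
the covered target volume V_PTV,rx live on the 3-D dose grid rather than in
any single DVH, they are accepted as precomputed volumes attached to the
plan, and a helper (`conformity_from_dvhs`) derives them from a body + target
DVH pair under the documented approximation that the target's
prescribed-isodose volume is read from the target DVH.

## Radiobiological models

All models act on **physical dose**; no fractionation (LQ/EQD2) correction
is applied anywhere, so parameter sets must be ones quoted for comparable
fractionation (here, 2 Gy/fraction schedules).

* **gEUD** (Σ vᵢDᵢ^a)^(1/a) over the differential view; a = 1 is the mean
  dose.  Negative exponents are rejected when any occupied bin sits below
  10⁻⁶ Gy (zero dose), where the power mean is undefined.
* **LKB NTCP** = Φ((EUD − D50)/(m·D50)) with EUD = gEUD(1/n), evaluated
  with the closed-form normal CDF rather than numeric integration of the
  Lyman integral — identical result, no quadrature tolerance.  Default lung
  pneumonitis set: D50 = 30.80 Gy, n = 0.98, m = 0.37.  With n ≈ 1 the EUD
  is nearly the mean lung dose.
* **Relative seriality NTCP** combines the per-bin Poisson response
  P(D) = 2^(−exp(e·γ(1 − D/D50))) as
  [1 − Π(1 − P(Dᵢ)ˢ)^{vᵢ}]^{1/s}.  The product is accumulated in log space
  (Σ vᵢ·log1p(−Pˢ)) so hundreds of raster bins lose no precision, and a
  fully-responding bin (−inf log-survival) short-circuits to NTCP = 1.
  Default cardiac-mortality set: D50 = 52.4 Gy, s = 1.0, γ = 1.3.
* **OED (linear model)** is identically the organ mean dose; higher-order
  response shapes (plateau, bell) are deliberately out of scope.
* **SCCP** = OED·In_org in %, with In_org = 1.68 %/Gy for lung tissue and
  0.78 %/Gy for breast.
* **EAR** = OED·β·exp(γ_e(age_x − 30) + γ_a·ln(age_a/70)) in excess cases
  per 10,000 person-years (lung: β = 7.5, γ_e = 0.002, γ_a = 4.23; breast:
  β = 9.2, γ_e = −0.037, γ_a = 1.7; attained age 75 by default).  This is
  Schneider's full form: the dose factor and the ln(age_a/70) attained-age
  term are both required for the published worked values (e.g. OED 12.6 Gy
  at age 47 → 130.9) to come out; abbreviated spellings of the formula that
  drop either term do not reproduce them.

Parameter sets live in a named registry (`lung_lkb_pneumonitis`,
`heart_seriality_mortality`, `ear_lung`, `ear_breast`, `sccp_lung`,
`sccp_breast`); every field is overridable from a YAML/JSON mapping, and the
registry fingerprint is recorded in the run log.  The organ–model pairing is
fixed on purpose (LKB for lung, seriality for heart): mixing pairings would
silently change endpoint definitions.

## Paired cohort comparison

Cohort-level NTCP/SCCP/EAR are computed **per patient and then averaged**
(mean ± sample SD, n − 1 denominator), matching the mean ± SD presentation
convention; applying the models to a cohort-mean DVH is not equivalent and
is not done.  Differences are means of per-patient (B − A), which equal the
difference of arm means; ratios are means of per-patient B/A, which do
*not* equal the ratio of arm means — for strongly varying metrics such as
heart NTCP the two diverge substantially, so the report enforces and labels
the per-patient convention.  The paired t-test (two-sided, df = n − 1) is
reported per metric with no multiple-testing correction; degenerate inputs
are flagged rather than erroring (all-zero differences → p = 1,
zero-variance nonzero differences → p = 0).  Percent reductions are
100·(A − B)/A on the arm means.

The comparison is exposed as a Model/Results pair
(`PairedPlanComparison(...).fit() → PlanComparisonResults`) with a tidy
DataFrame, sub-table views (targets / OARs / risk / efficiency), a text
`summary()` with display-only rounding (1 decimal for Gy and %, 2 for
indices and probabilities; underlying values are never rounded before
statistics), and an optional arm-mean DVH overlay plot.

## Synthetic cohort generator

The generator emulates a paired planning study at the DVH level — no
geometry, beams or optimizer.  Defaults are the study conditions: 30
patients, ages truncated-normal 47 ± 10 on [25, 65]; a chest-wall target
(D2% 54.5 / D98% 48.3 Gy around a 50 Gy prescription) and a nodal target;
OARs at reference-arm mean-dose scales 12.6 Gy (ipsilateral lung), 6.0 Gy
(heart), 2.5 / 1.5 Gy (contralateral breast/lung), 6.5 Gy (whole lung);
MU 893 ± 142 vs 611 ± 54; treatment time 7.00 ± 0.62 vs 2.00 ± 0.04 min;
CI 1.17 vs 1.10 and CN 0.78 vs 0.84.  Arm-B effects are the between-arm
mean-dose ratios (e.g. heart 5.2/6.0).  These tuned means are configuration,
not claims of distributional fidelity.

Generative form: targets are probit-shaped cumulative falls parametrised
directly by (D2%, D98%); OARs are a mixture of an in-field high-dose probit
component and an exponential low-dose scatter tail, with the dose axis
rescaled so the curve's mean equals the configured mean exactly.  Patient
variability enters as lognormal factors with unit mean (so configured means
stay unbiased): a per-structure dose-scale factor (SD set from the emulated
cohort's SD/mean), a shared latent "anatomy size" factor coupling the OARs
of one patient (the only cross-structure correlation mechanism), a per-plan
residual so that even a unit arm effect does not produce bit-identical
arms, and a volume factor.  Arm effects are **multiplicative on the dose
axis**, chosen because every implemented risk model responds monotonically
to dose scaling, which makes effect direction testable end-to-end.

Each patient draws from an independent random stream keyed by
(seed, patient index): the same seed reproduces the cohort bit-for-bit and
enlarging the cohort never perturbs existing patients.  Shape parameters
that would produce a non-monotone cumulative curve raise a generation
error; curves are never silently clipped.

What passing tests on this cohort do **not** show about real data:

* the symmetric probit target understates V100% relative to real, left-
  skewed target DVHs (a real plan with D98% = 48.3 Gy typically covers
  ~95% at 50 Gy; the probit gives ~84%), and places the mean at the
  (D2 + D98)/2 midpoint rather than slightly above it;
* scale-invariant indices (HI) are *identical* across arms by construction,
  since pure dose scaling cancels in (D2 − D98)/D50 — the report correctly
  flags those rows as degenerate; a real technique contrast changes the
  spread, not just the scale;
* absolute NTCP levels depend on the full DVH shape, not only the mean
  dose, so the simulated cohort's NTCP means need not match any specific
  clinical cohort even when mean doses do;
* joint correlations beyond the single anatomy factor (e.g. lung–heart
  overlap geometry) are absent.

## Verification strategy and problem sizes

Every model has an independent oracle: hand linear interpolation for
Dx/Vx; brute-force differential resampling at 0.002–0.005 Gy for the mean
dose (0.1%); the direct product form for seriality on small DVHs (machine
precision); closed-form probit checkpoints (NTCP = 0.5 at uniform D50 for
any n or s, 0.8413 one slope-width above); a 10⁵-draw sign-flip permutation
test for the paired t (MC-error agreement at n ≥ 15, below which the
permutation law is visibly discrete and no longer a fair reference for the
t approximation); and exact arithmetic identities for HI, CI/CN, SCCP, EAR
and percent reductions.  Parameter recovery runs on the default 30-patient
cohort at a fixed seed with a 3-standard-error band, and the configured
arm-B dose reductions must reappear as sign-consistent NTCP/SCCP/EAR
reductions across all risk rows.  All suites run in seconds on one CPU;
the end-to-end pipeline at n = 30 (seven structures, ~1200 raster bins
each) takes about a second.

## Known limitations

DICOM RT-DOSE/RT-STRUCT ingestion is an extension point, not implemented;
inputs are the plain-text DVH dialect.  CI/CN are only as good as the
supplied volumes (or the body-DVH approximation).  No TCP model, no EQD2
conversion, no nonparametric statistics — plans are compared with the
paired t only, which assumes approximately normal per-patient differences.
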