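# Methods

`milkspec` implements a mid-infrared calibration pipeline for milk mineral
traits: total, diffusible (serum-phase) and micellar (casein-associated)
Ca, P, K, Mg and Na in mg/100 mL, plus the micellar/diffusible ratio. This
note records the model, the numerical choices, and what the synthetic data
do and do not establish.

## Reference fractionation: the dilution mass balance

The wet-lab protocol rennets 10 mL of milk, collects 5 mL of whey,
adds 5 mL of water, equilibrates and measures the element concentration in
whey (C_w) and diluted whey (C_dw). Part of the milk volume — the *excluded
volume* occupied by curd solids — is inaccessible to diffusible minerals
and varies with milk composition, so no fixed correction factor is applied.
Instead the two measurements solve for the accessible serum volume V_a:

    C_dw = C_w (V_a − v_c) / (V_a − v_c + v_w)
    ⇒ V_a = v_c + r v_w / (1 − r),   r = C_dw / C_w

and the diffusible concentration referred to milk is D = C_w V_a / v_milk.
With the default 10/5/5 mL volumes this collapses to the closed form
D = C_w² / (2 (C_w − C_dw)); the general solver is primary and the closed
form is kept as a tested special case. Micellar = total − D, clamped at
zero with a flag (negative differences are expected under measurement
noise for Na, which is essentially absent from the micellar phase).
C_dw ≥ C_w has no physical solution and raises; an implied V_a above the
milk volume is flagged but returned, since noise can produce it.

## Preprocessing

Transmittance is converted to absorbance, A = log₁₀(1/T). Modelling is
restricted to the instrument's informative windows 964.5–1562.5,
1720.7–2291.7 and 2415.1–2970.7 cm⁻¹ (endpoints inclusive, since the
boundary wavenumbers are themselves part of the selected set). On a
uniform 1060-point grid over 686–5012 cm⁻¹ this keeps ≈ 422 variables; the
selected count is treated as data-driven, not fixed. Reference values are
screened once (no re-computation after removal) at ±3 SD from the trait
mean, SD with the n−1 denominator; the screen is affine-invariant.
Spectral outliers use Mahalanobis distance computed on PCA scores
retaining 95% of variance — the raw covariance of a wide spectral matrix
is singular — with a χ²(0.975) cutoff at the retained dimensionality; the
exact threshold used in the original SAS workflow is unpublished, so this
conventional choice is ours. Shapiro–Wilk normality per trait is
report-only and delegates to `scipy.stats.shapiro`. No scatter correction,
derivatives or smoothing are applied.

## PLS1, cross-validation and model size

The regression core is mean-centred single-response PLS (NIPALS), without
autoscaling: absorbance variables share one unit. Leave-one-out
cross-validation refits the model for each held-out sample with centring
recomputed inside the fold. For speed, all folds are advanced in lockstep
in cross-product form (kernel PLS with deflation carried on XᵀY only,
after Dayal & MacGregor 1997): each fold's centred XᵀX and XᵀY are
rank-one downdates of the full-data cross-products, so one matrix product
per component serves every fold. This is algebraically identical to a
literal per-fold NIPALS refit and agrees with one to ~1e−13 on
double-precision test problems; the test suite keeps an independent
textbook implementation as the oracle.

Fit statistics: PRESS = Σ(yᵢ − ŷ₍₋ᵢ₎)², RMSE_CV = √(PRESS/n),
R²_CV = 1 − PRESS/TSS with TSS about the full-sample mean (no formula is
published for R²_CV; this is the standard definition), and
RPD_CV = SD/RMSE_CV with the n−1-denominator SD of the calibration set —
the definition that reproduces the published RPDs from the published SDs
and RMSEs.

The number of latent variables (1–10) is the smallest model whose
out-of-fold squared residuals are not significantly worse than the
PRESS-minimising model's, judged by a sign-randomization test on the
paired differences in the spirit of van der Voet (1994): p is the
fraction of 1999 seeded random sign assignments whose summed difference
meets or exceeds the observed one, and models with p > 0.10 are accepted,
smallest first. This approximates the SAS CVTEST procedure used
originally; exact agreement with SAS is not claimed. A threshold of 0
degenerates to the PRESS argmin.

## Backward interval PLS

The region-filtered variables are split into 45 contiguous intervals
(sizes ⌊p/45⌋, remainder added one-per-interval from the left; 450
variables give 45 intervals of 10). Each round scores the exclusion of
every surviving interval by LOOCV PRESS — with the latent-variable count
re-selected for every candidate fit — and permanently drops the interval
whose exclusion gives the lowest PRESS, until one interval remains. The
final model is the round with minimal RMSE_CV; round 0 (all intervals) is
included in that search, so interval selection can never end worse than
its starting model. Ties, which arise with duplicated intervals, break
deterministically: lowest interval index for exclusion, earliest round
(more variables retained) for the best model. A candidate whose variables
are constant is scored +∞. ΔR²_CV = R²_CV(BiPLS) − R²_CV(PLS) measures
the selection benefit against a full-spectrum model fitted with the same
settings.

## Synthetic data

Real spectra with paired ICP reference data are not publicly deposited, so
the generator emulates the published study conditions: 93 cows by default,
a uniform 1060-point grid over 686–5012 cm⁻¹, element totals from
truncated-at-zero normals matched to the published means and SDs (e.g.
total Ca 122.07 ± 10.29 mg/100 mL), diffusible share drawn per sample
(means Ca 0.229, P 0.366, K 0.820, Mg 0.581, Na 1.0 — the published
fraction-over-total means; SDs 0.042/0.036/0.041/0.045/0 moment-matched so
the diffusible SDs reproduce the published ones) and clipped to [0, 1].
Total = diffusible + micellar holds exactly and micellar Na is identically
zero. Element totals are independent by default with an optional
correlation-matrix hook; no inter-element covariances are published, so
none are asserted.

Spectra are a fixed Gaussian-band basis (protein amide I/II at 1650/1545,
carbohydrate at 1080, lipid at 1460/1745/2850/2925 cm⁻¹) over a 0.1 AU
offset, plus a per-trait linear signal of `signal_strength` AU per
(mg/100 mL) confined to planted 10-variable intervals of the
region-filtered partition (by default one exclusive interval per element
total plus a shared protein-band interval, emulating the observed overlap
of selections on protein regions), plus i.i.d. Gaussian noise. Defaults
noise_sd = 0.003 AU and signal_strength = 1.5e−4 AU/(mg/100 mL) put the
out-of-fold accuracy of the well-determined traits in the moderate range
(R²_CV ≈ 0.7–0.9) typical of milk mineral calibration, with the error
noise-limited rather than model-limited. Whey measurements are
forward-simulated from the same mass balance with per-sample excluded
volumes (default Uniform(0.5, 2.5) mL) and optional unit-mean lognormal
multiplicative noise.

What the generator does not emulate: water absorption, instrument line
shape and detector drift, correlated (banded) spectral noise, covariance
between elements and between minerals and the major components, and any
nonlinearity between concentration and absorbance. Passing recovery tests
therefore show the algorithmic machinery is sound under the assumed
signal structure; they do not certify accuracy on real milk.

## Problem sizes in tests and the acceptance script

The interval-recovery study runs 50 generator seeds at n = 91 with 45
intervals on a 452-point grid (180 region-filtered variables, 4 per
interval), a strong planted signal (1.5e−3 AU/(mg/100 mL), ≈ 5× noise per
variable) in two intervals, candidate models searched over 1–3 latent
variables and 199 randomization draws — a scaled-down search that keeps
the full elimination structure. Full-scale demonstration runs (450
variables, 10 latent variables, 1999 draws) are exercised once per
pipeline invocation rather than per seed. The oracle-equivalence checks
use 15×8 problems where literal per-fold refits are cheap.

## Known limitations

- The published table of fit statistics is reproduced arithmetically, not
  numerically: without the original spectra, absolute R²/RMSE values on
  cow milk are out of reach.
- The printed RPDs of the four ratio (w/w) traits cannot be re-derived to
  ±0.01 from the printed SDs and RMSEs (the RMSEs are printed at 2 d.p. on
  values of 0.08–0.58), and one ratio row is internally inconsistent at
  any rounding; the reports here keep full precision and round only at
  presentation.
- The randomization test approximates, not replicates, SAS CVTEST; latent
  variable counts can differ from the original workflow on the same data.
- The generator's uniform wavenumber grid yields ≈ 422 selected variables
  where the original instrument grid yielded 450; interval sizes follow
  the data, not the printed count.
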