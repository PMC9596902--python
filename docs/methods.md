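# Methods

This note documents the statistical model, the preprocessing operators, the
synthetic cohort, and the numerical and design choices behind `cartigrade`.

## Data model

A *measurement location* is one spot on a joint surface, keyed by
cadaver → knee side → surface (femur/tibia/patella) → site index. Spectra are
absorbance traces on a wavelength grid in μm; each location carries replicate
spectra in two settings: `in_vitro` (extracted osteochondral plug, fixed in a
goniometer, reliable probe contact) and `ex_vivo` (arthroscopic acquisition
in a saline-filled joint, contact not guaranteed). Reference measurements —
proteoglycan optical density (PG OD) and the ICRS, OARSI and modified Mankin
histologic scores — exist once per location and may be non-integer because
they average sections and assessors.

Two spectrometer ranges occur: 0.35–1.10 μm at 0.6 nm and 1.00–2.50 μm at
6.4 nm. `downsample_and_merge` joins them on the coarse grid: below the cut
wavelength (default 1.05 μm, the midpoint of the 1.00–1.10 μm overlap; the
junction is not dictated by physics, so it is configurable) the fine trace is
linearly interpolated onto a coarse-step ladder starting at the visible-range
origin; at and above the cut the native coarse samples are kept verbatim.
Linear interpolation was chosen over block averaging because the ~10×
resolution ratio makes either defensible and interpolation is exactly
testable on affine data. Unsorted wavelength columns in input files are
auto-sorted with a logged warning rather than rejected.

## Preprocessing

Operators are applied in the fixed order **scatter correction → Savitzky–
Golay filter → trimming**. Trimming last keeps derivative edge artifacts away
from the interior of the retained bands.

* **SNV** standardizes each spectrum to mean 0, sample SD 1 (ddof = 1),
  removing multiplicative scatter. A constant spectrum raises an error
  rather than being silently zeroed.
* **LSNV** splits the spectrum into contiguous disjoint segments of `window`
  points (the remainder joins the final segment) and standardizes each
  segment independently. With `window ≥ len(spectrum)` it reduces exactly to
  SNV. Sliding-window variants exist in the literature; the disjoint-segment
  scheme is the simplest reproducible reading and is the documented contract
  here. Note that very small segments (2–12 points) deliberately discard
  broad-band amplitude information; on the synthetic cohort this makes plain
  SNV pipelines win the data-driven selection.
* **Savitzky–Golay** uses `scipy.signal.savgol_filter`, degree 3,
  derivative order 0/1/2, odd windows 5–47. Derivatives are per grid step;
  conversion to per-μm is left to callers. At the edges scipy's `interp`
  mode fits the polynomial over the first/last full window and evaluates it
  at the edge positions (a one-sided fit, no padding).
* **Trimming** retains closed wavelength intervals (boundary wavelengths
  kept). The four searched region sets are 0.70–1.90; 0.75–1.85;
  0.70–1.375 ∪ 1.525–1.90; 0.75–1.375 ∪ 1.525–1.85 μm. The visible range is
  excluded (endoscope light interference) and >1.90 μm is excluded (water
  absorption kills the signal-to-noise ratio).

The full search grid is 8 scatter options × 3 derivative orders × 22 windows
× 4 region sets = 2112 configurations. The default grid used by the
orchestration is a reduced 8-config set (the four published optimal model
pipelines plus no-scatter, SNV and split-band corners); the full grid is
hours-scale and sits behind an explicit flag.

## Reference QC

Score distributions are bounded and skewed, so normality is tested first:
a one-sample Kolmogorov–Smirnov test on values standardized by their own
mean/SD, with a Lilliefors-corrected option because the plain variant with
estimated parameters is mis-calibrated (in the p-value direction it is
conservative — it under-rejects). Decision level α = 0.05.

Outliers are screened with the median ± 3·MAD rule. The default MAD is the
normal-consistent scaled MAD (raw MAD × 1.4826), matching the default of
common numerical environments; a raw-MAD mode is available. Exclusion is per
property: a location excluded for Mankin remains usable for ICRS.

## Calibration (PCA-LME)

Replicate spectra of a location are averaged to one spectrum per location
per setting before modelling, because references exist per location (a
per-replicate mode would need site as a random effect; averaging is the
default, the observational unit is the location). PCA (mean-centred, full
SVD) compresses the preprocessed spectra; the LME fixed effects are an
intercept plus the leading `k ≤ 12` scores; random intercepts are nested:
cadaver, knee-within-cadaver, surface-within-knee. The measurement site is
the observational unit and is absorbed by the residual — a site-level random
intercept would be confounded with the residual at one observation per site.

Estimation is REML via `statsmodels` MixedLM (knee and surface enter as
variance components). The optimizer ladder is: statsmodels default sequence,
then Nelder–Mead + Powell, then L-BFGS, max 500 iterations. The REML surface
is flat near its optimum for these designs and optimizers frequently report
non-convergence while agreeing on the estimates to <1e-2 in log-likelihood;
a reported non-convergence with finite, best-likelihood estimates is
therefore accepted with a logged note (the convention of mixed-model
software), and only singular or non-finite fits raise. With a single cadaver
in the data the cadaver variance is structurally inestimable: a warning is
emitted and the structure degrades gracefully (ultimately to OLS, which is
also the exact reduction when all random terms are disabled).

**Component selection.** Grouped k-fold cross-validation (default 10-fold)
partitions *locations* — not raw rows — into folds (seeded shuffle, so the
assignment is reproducible). PCA is refit inside every fold; held-out
predictions use fixed effects only; RMSECV(k) is the root mean squared
held-out error using the first k scores; the selected k attains the minimum,
ties going to the smaller count.

**Validation.** Leave-one-cadaver-out: each cadaver in turn is the untouched
independent test set; component count is re-selected inside the remaining
cadavers; held-out predictions use fixed effects only (the random intercepts
of an unseen cadaver are unknown and set to their zero mean). Per-iteration
Spearman ρ (mid-ranks, asymptotic-t p; an exact permutation p is available
for n ≤ 10) and RMSE are summarized as median (IQR), with quartiles by
linear interpolation. The preprocessing config with the highest median
held-out ρ wins.

## Poor-contact screening

Labels for "poor contact" do not exist, so they are manufactured: the
calibration model predicts every ex vivo spectrum of the training cadavers;
a spectrum whose absolute error exceeds the threshold — 2× or 3× the model's
RMSECV, or the upper half of absolute errors (`half_split`, ties at the
boundary resolved by stable row order, exactly ⌈n/2⌉ flagged) — is labelled
an outlier. Features are the first 12 PCA scores of the ex vivo spectra; the
PCA is refit under the classifier's own preprocessing config on the training
cadavers' in vitro spectra (classifier preprocessing is searched
independently of the regression preprocessing, since the two tasks have
different optima).

Classifiers: `fine_knn` = 1-NN Euclidean; `weighted_knn` = 10-NN with
inverse-squared-distance weights; `svm` = RBF SVM with unit box constraint
and kernel scale set by the median heuristic on training scores (the
original presets give no kernel parameters, so this is an explicit,
configurable choice). Training accuracy and outlier-class F1 are 10-fold
stratified CV estimates.

Candidate combinations (algorithm × label rule × preprocessing) flagging
<10% or >90% of ex vivo spectra are discarded as unrealistic. Survivors are
ranked by the *same-retained-locations* (SRL) indicator: after excluding
flagged spectra of the held-out cadaver, the in vitro and ex vivo ρ over the
identical retained location set should agree; candidates are ordered by
ascending median |ρ_in_vitro − ρ_ex_vivo|, ties broken by descending F1 then
accuracy. Per-location ex vivo predictions aggregate the retained replicate
predictions by their median (robust to residual stragglers); a location is
excluded outright only when *all* its replicates are flagged (this is what
the OutlierN percentage counts; OutlierS counts flagged spectra). In this
implementation the ex vivo SRL block therefore coincides with the
after-exclusion test block — both are computed over locations with at least
one retained replicate.

## Synthetic cohort

The generator emulates the study design the pipeline assumes, not cartilage
optics. Per location a latent severity in [0, 1] is a logistic transform of
nested Gaussian intercepts — cadaver (SD 0.55), knee (0.25), surface (0.35),
site (0.80) on the logit scale — shifted by −0.8 so mild degeneration
dominates (right-skewed, clearly non-normal score distributions, as a
normality test at the full 342-location design confirms). References are
monotone maps of severity into their ranges (PG OD decreasing into
[0.2, 1.5]; ICRS/OARSI/Mankin increasing into [0,4]/[0,6]/[0,13]) plus
bounded Gaussian noise (SDs 0.05/0.15/0.25/0.50); they are continuous by
default (assessor-averaged scores are non-integer), with an integer-rounding
stress mode.

Spectra live on the merged two-spectrometer grid (337 points) and are built
from a fixed, versioned library of Gaussian bands: water at 1.40 and 1.90 μm
(amplitudes increasing with severity — tissue water rises as the matrix
degrades) and matrix bands at 0.91, 1.18, 1.45, 1.73 μm (decreasing), on a
gentle sloping baseline. Each recorded spectrum gets a per-spectrum
multiplicative scatter factor (log-normal, SD 0.06 in vitro; ex vivo adds
0.12 in quadrature) and additive noise of SD 0.010/√10 absorbance units
(emulating 10 co-added acquisitions). Defaults: 9 cadavers, both knees,
9/8/2 femur/tibia/patella sites, 15 ex vivo and 3 in vitro replicates per
location (the in vitro replicate count is not pinned by the emulated design;
3 is a realistic bench protocol), 30% ex vivo contamination.

Contamination (poor contact): a contaminated spectrum gains a water band at
1.40 μm with amplitude 0.8 × lognormal(SD 0.3) and an extra scatter draw.
This reproduces the qualitative signature — inflated 1.4 μm absorption and
inflated pointwise spectral SD — that the screening targets.

**What passing tests do and do not show.** The generator's spectra are
smooth Gaussian-band composites with linear severity dependence; real
cartilage spectra have overlapping, non-Gaussian bands, nonlinear
scattering, and instrument drift. Tests on this cohort demonstrate that the
pipeline recovers structure it is designed for (nested dependence, monotone
spectral encoding, a separable contamination mechanism) without leaking
information across cadavers — they do not certify performance numbers on
real tissue. For the same reason the LSNV-heavy optima of the original
study are not expected to be re-selected here.

## Numerical choices and degenerate inputs

* Ties in component selection → smallest count; ties in half-split labels →
  stable row order; ties in candidate ranking → higher F1, then accuracy.
* Constant spectra/segments, zero MAD, single-class labels, empty trims and
  constant correlations raise typed errors rather than returning NaNs.
* F1 with an empty positive class is reported as 0 with a warning.
* Wavelengths are stored in μm everywhere; CSV headers carry the shortest
  decimal representation that round-trips the double.
* All randomness (fold shuffles, CV splits, the generator) flows from
  explicit integer seeds; rerunning with the same seed reproduces every
  deterministic artifact bit-for-bit.

## Problem sizes

The full design (9 cadavers × 2 knees × 19 sites, 2112-config grid,
12 components, 10 folds) is hours-scale. The shipped defaults scale down
where the structure, not the size, is what matters: the orchestration's
default grid has 8 configs; the test suite exercises cohorts of 3–4 cadavers
with 7–9 sites per knee, 3-fold component selection up to 3 components; the
acceptance script uses a 5-cadaver cohort (9 sites per knee, 90 locations,
1350 ex vivo spectra), a 2-config regression grid, 2 label rules and 2
classifier algorithms. These sizes keep a complete nested search reproducible
on a single CPU in minutes while preserving every level of the hierarchy.

## Known limitations

* The LSNV segmentation scheme is one of several in use; results under a
  sliding-window LSNV may differ.
* Ex vivo SRL and after-exclusion blocks coincide by construction (see
  above), unlike reporting conventions that compute them over different
  location sets.
* The SVM kernel scale uses a subsampled median heuristic (≤500 points),
  so SVM results can change slightly with very large training sets.
* `CalibratedModel.from_dict` restores prediction capability but not the
  fixed-effect covariance (confidence intervals require refitting).
* The classifier's "test" accuracy/F1 are measured against rule-generated
  labels on the held-out cadaver, not against ground truth — on real data
  no ground truth for poor contact exists.
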