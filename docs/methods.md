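# Methods

## Problem setting

A line-scan NIR hyperspectral camera (900–1700 nm, 256 bands, ~3 nm
resolution) images mango fruit after controlled drops from 0.5, 1.0 and
1.5 m; undamaged fruit serve as controls. Fruit are imaged on days 1, 3 and
5 after impact, 20 fruit per (height, day) group. The bruised area is
outlined as a region of interest (ROI) and its mean absorbance spectrum is
the observation for that fruit. Reference chemistry per fruit: pulp firmness
(puncture test), total soluble solids (refractometry, °Brix), titratable
acidity (NaOH titration, % citric acid) and flesh chroma (CIE Δb\*).

Two tasks follow: (i) predict the four quality attributes from the spectra,
and (ii) grade damage severity from the ripening index
RPI = ln(100·PF·TA/TSS), with RPI > 7.0 slight, RPI < 5.0 serious, the
closed interval [5.0, 7.0] moderate. Endpoint assignment to "moderate" is a
package convention: the verbal definition uses strict inequalities on both
sides and leaves the endpoints unassigned, and a total, deterministic
function is required. The "absolute RPI" phrasing sometimes attached to the
slight threshold is ignored — observed RPI values are positive.

## Calibration and representation

Raw counts are calibrated per pixel and band as R = (I₀ − B)/(W − B) × 100
with a white (PTFE board) and dark (capped lens) reference; references may
be full cubes or per-line (samples × bands) frames that broadcast across
scan lines. A guard of ε = 1e-6 (raw-count units) on the denominator masks
dead/saturated pixels to NaN; masked pixels are excluded from ROI means.
Absorbance is A = log₁₀(100/R). Whether modeling uses absorbance or percent
reflectance is a config choice; the default is absorbance (the log 1/R
acquisition mode).

Pixel convention: (line, sample), 0-based; bands indexed by grid position.
The ENVI dialect supported is BIL/BIP/BSQ interleaves, little-endian uint16
or float32, wavelengths required in the header.

## Preprocessing

Three per-spectrum transforms are provided and compared:

* **S-G** (Savitzky–Golay): moving-window local polynomial least squares;
  defaults window 11, polyorder 2 (conventional values — no study-specific
  setting exists); edges are handled by the polynomial fit on the truncated
  window, not by mirroring.
* **SNV**: per-spectrum centering and scaling to unit dispersion, with the
  sample (n−1) standard deviation — one convention has to be pinned, and
  this one is asserted in the tests. SNV cancels any per-spectrum affine
  distortion exactly: snv(a + b·x) = sign(b)·snv(x).
* **MSC**: each spectrum is regressed on a reference spectrum (OLS over
  bands) and the fitted slope/offset inverted. The reference is the
  calibration-set column mean, frozen at fit time and reused for validation
  spectra so no held-out information leaks into the correction.

The pipeline default is SNV, which among the three gave the best downstream
models in the comparison experiment the pipeline reproduces; S-G and MSC
remain selectable.

## PLS regression

PLS1 via NIPALS on mean-centered X and y (no autoscaling — standard for
spectra): per component, weight w ∝ X′y, score t = Xw, loadings
p = X′t/t′t, q = y′t/t′t, then deflation X ← X − tp′, y ← y − qt. The model
is kept both in factorised form (W, P, q) and as the compact coefficient
vector b = W(P′W)⁻¹q; the two prediction routes agree to 1e-8 and both are
exposed (the equality is a standing test). At full rank the PLS solution
equals the minimum-norm least-squares solution, which is checked against a
pseudo-inverse oracle.

One model is fitted per attribute (PLS1 × 4) rather than one multi-response
model, mirroring the attribute-wise reporting of the reference results.
Component count is chosen by leave-one-out cross-validation up to A_max = 10
(capped at min(n−2, p)), ties broken toward fewer components. Calibration/
validation splits are uniform random permutations at ratio 3/5 (12/8 for a
20-fruit group) under a caller seed. Validation R² is computed about the
validation-set mean and may be negative — the convention matching the
published tables, where small-group TA models do go negative.

## CARS wavelength selection

N = 50 Monte-Carlo iterations (default), each drawing 80% of the
calibration samples and fitting an internal PLS with a fixed small
component count (5, capped by rank) on the currently retained bands.
Retention is two-stage: enforced removal keeps the ⌈r(i)·p⌉ bands of
largest |b|, where the exponentially decreasing function r(i) = a·e^(−k·i)
is pinned by r(1) = 1 and r(N) = 2/p; adaptive reweighted sampling then
draws that same count without replacement with probability ∝ |b|. Drawing
k items without replacement from k candidates changes nothing unless some
coefficients are exactly zero, so in this construction the ARS stage only
drops zero-weight bands and the stochasticity of the path comes from the
Monte-Carlo row draws — a deliberate simplification; the classical variant
resamples with replacement and shrinks faster. Each iteration's retained
set is scored by LOO RMSECV on the full calibration data (not just the
Monte-Carlo draw), and the minimal-RMSECV subset wins. The final model is
refit on the winning subset with LOO-chosen components.

CARS runs per attribute model (and once on RPI for the classifier
features); which granularity the original analysis used is not stated, so
each result is recorded in the run manifest.

## Severity classification

Fisher discriminant analysis on the preprocessed spectra restricted to
CARS-selected bands: canonical axes solve the generalized eigenproblem of
between-class versus pooled within-class scatter (unstandardized
coefficients); classification is nearest class mean in canonical space
under equal priors, ties to the earlier class in the order (slight,
moderate, serious). Priors are equal because no prior scheme is documented
for the original analysis and symmetric treatment is the neutral choice. A
ridge of 1e-6·trace/p stabilises a singular pooled covariance. Splitting is
stratified by class at ratio 3/4 — unstratified splits with three classes
and few slight fruits can drop a class entirely. Confusion matrices are
reported as row percentages over actual classes, training and testing
separately.

## Synthetic data generator

No measurement data are available, so the generator emulates the study:

* **Attributes.** Per (height, day) group, the four attributes are drawn
  jointly normal with the published group means and SDs. The published
  table gives marginals only; correlations are a simulation choice set from
  ripening physiology: firmness–TA +0.5, firmness–TSS −0.5, chroma
  uncorrelated. Draws are truncated at physical bounds (firmness, TSS ≥ 1;
  TA ≥ 0.05%). Controls have no published table; their means are the 0.5 m
  day-1 values plus half the 0.5 m day trend (slower undamaged ripening) —
  a synthetic-only construction. RPI and the severity label are derived per
  fruit.
* **Spectra.** Absorbance = linear baseline + Gaussian bands + scatter +
  noise. Bands: water at 970 nm (σ 45 nm) and 1450 nm (σ 55 nm), sugar at
  1190 nm (σ 15 nm). Depths carry the attribute signals: sugar depth affine
  in TSS (0.30 + 0.02/°Brix), the 1450 nm band affine in TA (+0.02/%) and
  decreasing in drop height, the 970 nm band decreasing in drop height,
  baseline level and tilt affine in firmness. Water bands mentioned in the
  NIR literature at 1950/2250 nm fall outside the instrument range and are
  omitted. The depth bases are large and stable relative to their
  modulation because fruit flesh is predominantly water: constituent
  signals are small perturbations on a big, stable absorbance. This matters
  numerically — SNV destroys per-spectrum scale, and if band depths vary
  strongly the linear PLS inverse of the SNV-transformed spectra hits a
  nonlinearity ceiling well below the recovery levels the chain should
  reach.
* **Severity signature.** Bruised tissue browning/water redistribution adds
  a broad band at 1350 nm (σ 60 nm) whose amplitude tracks ripening
  advancement: 0.02 AU per RPI unit below 7.0, plus a logistic component
  (amplitude 0.10 AU, midpoint RPI 5.0, width 0.06) representing
  threshold-like cell rupture in seriously damaged tissue. The graded part
  encodes the premise that spectral change correlates with damage degree;
  the rupture part reproduces the observed complete separability of the
  serious class — without it, thresholding a continuous index leaves
  boundary fruits spectrally ambiguous and no linear discriminant can grade
  them reliably.
* **Scatter and noise.** Multiplicative scatter per spectrum (slope
  ~N(1, 0.05), offset ~N(0, 0.02 AU)) and additive per-band noise of
  0.002 AU — the level appropriate for ROI-mean spectra, which average
  hundreds of pixels.
* **Cubes.** Small raw cubes (default 32×32×256) embed a fruit's latent
  spectrum in an elliptical bruise ROI through the affine instrument model
  raw = B + R/100·(W−B) with smooth per-line white/dark frames and optional
  per-pixel reflectance noise (0.5 %R); calibrating with the emitted frames
  and averaging the emitted mask recovers the spectrum to pixel noise /
  √(ROI size).

Ground-truth band centres and coefficients are stored with each dataset so
recovery tests can assert against them. All randomness flows from one seed;
a fixed seed reproduces a dataset bit-exactly.

What the generator does **not** emulate: radiative-transfer effects, spatial
bruise structure and evolution, peel/pulp layering, instrument drift, and
chroma has no direct spectral driver (it is predictable only through its
group structure). Passing recovery tests therefore demonstrate that the
chain inverts the planted linear signal model at realistic noise — not that
these accuracies transfer to real fruit.

## Pipeline and reproducibility

`run_experiment` executes: simulate (or load CSVs) → group statistics table
→ per-group (attribute × height × day) CARS–PLS regression with seeded
3/5 splits → RPI labelling of all damaged fruit pooled across groups →
CARS (on RPI, training side only) → Fisher DA with a stratified 3/4 split →
confusion tables → manifest with config snapshot, seeds and output hashes.
Whether each physical fruit was imaged on one day or repeatedly is
ambiguous in the study design; each (fruit, day) is treated as an
independent record. All stage seeds derive from the single config seed via
a SeedSequence spawn, so a rerun reproduces every CSV byte-for-byte. No
stage sees held-out rows during fitting: SNV and S-G act per spectrum, the
MSC reference is frozen on calibration rows, and CARS/PLS/DA receive
calibration or training rows only (asserted by a poisoning test).

Default problem sizes (20 fruits/group, 240 fruits, 50 CARS iterations,
LOO up to 10 components) run the full pipeline in about a minute on one
core; the test suite's heavier recovery checks use 10–20 seeded replicates
of the same sizes.

## Known limitations

* The titration formula is implemented with the dilution back-correction
  ×V₀/V₁ (the aliquot contains V₁/V₀ of the acid); the inverse orientation
  sometimes seen in print yields chemically impossible TA for mango juice.
* Firmness units are carried as metadata (N vs g conventions differ between
  sources) and never converted silently.
* Regressing RPI itself on spectra is deliberately not part of the report
  bundle: RPI is a log-composite of three noisy attributes and per-group
  models for it are unstable (negative R² territory); severity grading goes
  through classification instead.
* CARS wavelength lists are data-dependent; specific published lists are
  illustrative and not a reproduction target.
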