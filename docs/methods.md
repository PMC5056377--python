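# Methods

This note documents the models, conventions and numerical choices behind
`cystir`, in the spirit of a package methods appendix. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectral conventions

Spectra are stored on strictly monotonic, descending wavenumber grids
(4000 → 750 cm⁻¹), the FTIR display convention; ascending input files are
reversed on read and a metadata note is kept. The default working grid uses
2 cm⁻¹ spacing. Acquisition at 4 cm⁻¹ optical resolution is typically
digitized at about half that interval, and 2 cm⁻¹ makes the analysis
wavenumbers 1296 and 1280 cm⁻¹ exact grid points; the spacing is
configurable. Band lookups snap to the nearest grid point within ±1 cm⁻¹
(the quoted frequency accuracy of such instruments), ties breaking toward
the higher wavenumber.

JCAMP-DX support covers single-block `(X++(Y..Y))` tables in AFFN or
squeezed ASDF form (SQZ/DIF/DUP) and `(XY..XY)` point lists; compound
multi-block files are rejected. CSV files are two numeric columns with
`#`-prefixed metadata comments.

## Forward simulator

Components are sums of bands with peak-normalized profiles (Gaussian,
Lorentzian, or pseudo-Voigt with mixing fraction η; η = 0.5 is the default
band shape). Absorbance is exactly linear in concentration (Beer–Lambert);
film saturation is modelled separately as `min(1, capacity/amount)` — a
hard plateau once the dried film outgrows the ~1 µm evanescent sampling
depth. A 0–3 mM series of 5 µL aliquots carries at most 15 nmol, a quarter
of the ~60 nmol capacity, so calibration standards never saturate.

The default component library places cystine bands at 1296, 845 and
775 cm⁻¹ (pseudo-Voigt), urea at 1682/1627/1465 cm⁻¹ and creatinine at
1705/1493/1418 cm⁻¹ (Gaussian), liquid water as broad Gaussians at 3400 and
1640 cm⁻¹, and water vapour as a comb of 40 narrow Lorentzian lines
(FWHM 4 cm⁻¹) across 2000–1300 cm⁻¹ with deterministic pseudo-irregular
heights. Two deliberate choices:

* the broad condensed-phase bands are Gaussian because Lorentzian tails of
  the very strong water/urea bands would otherwise spread across the
  vapour-factor fit window at a magnitude real purge setups do not show;
* the vapour comb uses the 40 interior points of a 42-point division of
  [2000, 1300], so no line coincides with 1300 cm⁻¹, 4 cm⁻¹ from the
  cystine analysis band — a pathological overlap the real atmosphere does
  not impose.

True molar absorptivities of cystine, urea and creatinine at these
wavenumbers are not tabulated here; the library heights are **synthetic**
placeholders chosen for realistic signal-to-noise. The cystine 1296 cm⁻¹
height (0.035 AU/mM) makes a 3 mM film's second-derivative response ≈ 50×
the default noise SD, consistent with 0–3 mM being comfortably quantifiable.
Detector noise is i.i.d. Gaussian per point (default SD 2×10⁻⁴ AU, a
typical averaged-scan ATR noise floor); baseline drift is a random
quadratic (SD 5×10⁻⁴ AU); per-spectrum vapour factors are uniform on
[0.05, 0.4].

Cohorts default to the study structure: 22 patients + 5 controls, urea
uniform on 28–443 mM, creatinine uniform on 1–20 mM, patient insoluble
cystine zero with probability 5/22 and otherwise uniform on 0.1–3.1 mM,
controls zero. Samples are measured in triplicate (independent aliquots).
Comparators: Jaffe creatinine = truth + 1.4 mM + N(0, 1 mM²); IEC total
cystine = insoluble + soluble + N(0, 0.1 mM²). The soluble fraction is
exactly 1.0 mM (the solubility limit) for any sample that has insoluble
cystine — a suspension is saturated by definition, and this is the
chemistry the +1 mM reporting offset rests on — and uniform on [0.5, 1] mM
(patients) or [0.05, 0.3] mM (controls) otherwise. Every generator is a
pure function of (parameters, seed); per-sample streams derive from the
master seed by stable hashing of (seed, sample id, replicate).

### What the simulator does not capture

Real urine contains many more IR-active solutes (phosphate, sulfate,
glucose, proteins), scattering from microcrystals, ATR penetration-depth
dispersion, instrument drift, and correlated (1/f) noise. Passing the
closed-loop tests therefore demonstrates that the *analysis chain* is
correct and self-consistent under the stated noise model — not that the
method achieves the same accuracy on clinical specimens.

## Preprocessing

`fractional_subtract` is the exact closed-form least-squares projection
f = ⟨sample, ref⟩/⟨ref, ref⟩ on a fit window, applied across the whole
grid. The pipeline composite `subtract_atmosphere` differs in two ways,
both adopted after the plain projection proved biased:

* each factor is estimated jointly with an affine trend on the window, so
  baseline drift does not project onto the all-positive vapour comb;
* order is vapour → liquid water → one vapour refinement pass. The water
  band tail leaks into the vapour window, so the first vapour factor
  absorbs part of it; after water subtraction the refinement pass corrects
  this exactly for samples that are vapour + water on the windows.

Default windows: vapour 2000–1800 cm⁻¹, liquid water 3900–3100 cm⁻¹. The
vapour window deliberately stops above 1800 cm⁻¹ because the urea
(1682 cm⁻¹) and creatinine (1705 cm⁻¹) carbonyl/amide bands reach well into
1800–1700; fitting the vapour factor over 1900–1700 in the presence of
200 mM urea mis-scales it by an order of magnitude. Both windows are
configurable.

Second derivatives are Savitzky–Golay, window 9 points, polynomial order 3,
differentiated with respect to grid *index* (recorded in metadata). The
filter reproduces polynomials through order 3 exactly, so affine baselines
vanish and a quadratic baseline differentiates to a constant that cancels
in the two-point band response. The 9-point window at 2 cm⁻¹ spacing
preserves features separated by 16 cm⁻¹ (1296 vs 1280).

The band response is defined as d²A(1296) − d²A(1280); this raw difference
is *negative* for a growing cystine band (the second derivative is negative
at an absorption maximum), so quantitation uses its negation — the band
depth — giving positive calibration slopes. Both values are exposed
(`band_response`, `cystine_response`).

## Deconvolution

The 1510–1445 cm⁻¹ window is fitted as a non-negative combination of
unit-concentration reference spectra plus a free polynomial baseline
(order 1 default). The solver first computes the unconstrained least-squares
solution (exact) and falls back to a bounded solver only when a component
coefficient is genuinely negative; this keeps noiseless recovery exact to
machine precision. Columns are norm-scaled before solving, and a condition
number above 10⁸ raises an error naming it. Concentrations are coefficient ×
reference concentration. Urea is reported but is a plausibility check;
creatinine is the normalizer.

## Calibration and reporting

The through-origin slope Σcᵢrᵢ/Σcᵢ² is fitted with no error weighting.
Standards are simulated in triplicate per concentration: with only 7 single
points the residual-SD estimate behind the 3σ limit of detection is
unstable (one seed in development produced a residual SD 0.37× the true
response noise, letting a blank cross threshold). Prediction is
response/slope clipped at zero; values above the calibrated 3 mM range are
flagged as extrapolation, not rejected (linearity beyond the calibrated
range is unverified; literature maxima reach ~4 mM). Replicates are
summarized by mean and SEM (n−1 SD; SEM 0 for a single replicate), and
detection applies to the replicate mean — the protocol's measurement unit.

Dilution bookkeeping multiplies by resuspension/original volume (identity
for the 1 mL → 1 mL protocol). The censored interval for undetected
samples is an explicit (centre 0.5, half-width 0.5 mM) object, not a point
estimate. The cystine:creatinine ratio is µM/mM (×1000/creatinine); it is
flagged undefined, not raised, when creatinine ≤ 0.

Spot capacity is π(d/2)²h / V_mol / N_A in nmol; with d = 3 mm, h = 1 µm,
V_mol = 193 Å³ this evaluates to 60.8 nmol (quoted as ~60), equal within
rounding to a 5 µL × 12 mM aliquot.

## Method comparison

Differences are oriented (comparator − FTIR), so a comparator that reads
high gives a positive bias. Limits of agreement are bias ± 1.96 SD with the
n−1 SD (standard Bland–Altman practice); the identity is tested to 1e-12.
Censored samples enter total-cystine comparisons as 0.5 mM points with
their 0.5 mM half-width carried into plot exports as error bars; a flag
excludes them instead, since either treatment is defensible.

## Problem sizes and determinism

The shipped tests and demo run at desk scale: grids of 1626 points, cohorts
of 27 subjects in triplicate, 200-sample recovery sweeps — enough for
stable statistics while the whole suite runs in seconds. Every pipeline
run embeds the SHA-256 digest of its configuration, and repeated runs with
one seed are byte-identical.

## Known limitations

* The deconvolution design (NNLS on absorbance with a polynomial baseline)
  is one defensible choice among several; derivative-domain or band-shape
  fitting would be alternatives.
* The detection rule ties the LOD to calibration residuals, which mixes
  lack-of-fit with noise; a blank-replicate LOD would separate them.
* The saturation model is a hard plateau; a real evanescent field decays
  exponentially, so the approach to capacity is gradual.
* Censored samples contribute a ±0.5 mM structural approximation to the
  total-cystine comparison; with many censored samples the bias estimate
  reflects the censoring convention as much as the measurement.
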