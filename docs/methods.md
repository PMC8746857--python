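# Methods

This note documents the models, numerical choices and limitations behind
`oilscreen`. The package has two halves: a forward simulator that turns
fatty-acid compositions into realistic 1D ¹H NMR spectra, and the
screening pipeline (processing → binning → Pareto-PCA → confidence
ellipse) that those spectra feed.

## Forward model

### Composition and mixing

An oil is a vector of molar acyl-chain fractions over
{palmitic, stearic, oleic, linoleic, linolenic}, nonnegative and summing
to 1. Built-in compositions (`data/compositions.yaml`) are
representative retail values; they are configuration, not measurements,
and all tests rely only on qualitative contrasts (hempseed ≫ olive in
α-linolenic; high-oleic seed oils close to olive in oleate).

v/v blending treats molar volume as equal across oils, so volume
fractions act directly as chain-fraction weights. Triglyceride molar
volumes differ by a few percent at most; the error is far below the
compositional contrasts the screen exploits.

### Peak table

`data/chemistry.yaml` books protons per chain into ten functional
groups with standard triglyceride assignments. The three discriminating
groups are fixed by the science: ω-3 terminal methyls at 0.977 ppm
(3 H for linolenic chains), all other terminal methyls at 0.881 ppm,
and bis-allylic CH₂ at 2.78 ppm (2 H per linoleic, 4 H per linolenic
chain). Glycerol backbone protons are booked per chain (4/3 + 1/3).
Multiplets are first-order: binomial amplitude ratios (triplet 1:2:1;
unresolved "multiplet" rendered as a 1:4:6:4:1 quintet), J ≈ 5–7.5 Hz,
Lorentzian lines of 1.2 Hz width. Composition-independent extras —
residual CHCl₃ at 7.26 ppm and TMS at 0 ppm — are included; both fall in
blinded regions, and TMS anchors the referencing step.

### FID synthesis

The FID is the exact sum over multiplet components of
`A·exp(i2πf t − t/T₂)` sampled at the dwell time (T₂ = 1/(π·linewidth)),
evaluated by an exact block-power factorisation (an (m×C)·(C×n/m)
matrix product with m ≈ √n) rather than n·C transcendental calls —
identical to the naive sum to float rounding, ~20× faster. Complex
Gaussian noise of `noise_sigma` per quadrature is added in the time
domain; one global shift-jitter draw per FID moves all centres together
(shim/temperature drift between samples). Defaults: 400.13 MHz, 20 ppm
sweep over −3.9…16.1 ppm, 65,536 points.

### Noise level

`noise_sigma = 7.4e-4` (intensity units per quadrature point) was
calibrated once so the processed-spectrum SNR at the 0.881 ppm methyl
peak of an olive-like oil is ≈ 5×10⁴:1. The governing constraint is the
normalisation reference: in olive oil the ω-3 methyl peak is ~140×
weaker than the 0.881 peak, so this choice leaves the reference at a
usable ≈ 400:1 — the regime of a 64-scan neat-oil acquisition. A much
noisier setting would make the ω-3 reference itself noise-dominated, at
which point normalisation (and with it the whole screen) degrades in a
way the real experiment does not show.

### Panel (cultivar) variability

Between-bottle variability of a nominally identical oil is
multiplicative Gaussian jitter per acid (`cultivar_rel_sd`), with one
structural rule: the ω-3 (linolenic) share is jittered around its base
share of the whole (rel sd 0.8%), and the remaining acids are jittered
(oleate 2%, linoleate 15%, palmitate 5%, stearate 6%) and rescaled to
fill the rest. The authentic class is thus modelled as tightly
regulated in ω-3 share while its internal oleate/linoleate balance
varies freely. This is the structure implied by the screen's premise:
tight clustering of authentic oils under ω-3 normalisation can only
happen if the ω-3 share is consistent, while the wide real-world
linoleate ranges must live in the non-ω-3 block. With naive independent
jitter, every acid's variation leaks into the normalisation scale and
low-percentage adulteration becomes undetectable in principle. These
spreads were fixed at design time and define the conditions under which
the detection limits below are measured.

## Processing chain

Order: apodize → FFT → phase → reference → baseline → normalise.

* **Apodization**: multiply point k by exp(−π·lb·t_k), lb = 0.3 Hz.
* **FFT**: first point halved (half-sample offset correction),
  unnormalised FFT, descending ppm axis from the carrier at the window
  centre; Parseval holds as Σ|fid|² = Σ|spec|²/N. Non-power-of-two
  inputs are zero-filled up.
* **Automatic phasing**: Nelder–Mead over (φ0, φ1) of a heavily
  weighted negative-intensity penalty plus a derivative-entropy
  tie-break, evaluated on a ~8k-point stride, with a coarse φ0 grid of
  starts and a tight-simplex refinement stage. φ1 carries a quadratic
  regularizer: positivity landscapes are flat to ~1e−8 over ±0.2°, and
  an unpinned φ1 wanders from sample to sample, modulating small peak
  heights through the dispersion tails of large neighbours. The history
  records the phases *removed* (the spectrum is multiplied by
  exp(−iφ)). Recovery accuracy for a known rotation is well under 1°.
* **Referencing**: the TMS line is located in 0 ± 0.05 ppm, its apex
  refined with a three-point parabola, and the axis shifted so it sits
  at exactly 0 ppm. This removes the global shift jitter, which would
  otherwise shuttle intensity across bin edges and dominate
  between-sample variance — it is the single most load-bearing
  robustness step in the chain.
* **Baseline**: polynomial of order 5 on the ppm axis rescaled to
  [−1, 1], fitted iteratively; points whose residual exceeds
  3×1.4826×MAD are masked as peaks each round until the mask stabilises
  (max 20 rounds; small absolute floor on the threshold so noise-free
  spectra don't mask everything; fit on a ≤16k subsample, evaluated
  everywhere).
* **Normalisation**: `omega3_peak` divides by the height of the
  reference peak found in 0.975 ± 0.05 ppm — a window that covers the
  ω-3 triplet under either of its conventional reported positions
  (0.975/0.977 ppm). Height is measured as the parabola-refined apex
  *above a local linear baseline* through the window's outer quarters:
  the plain grid maximum under-reads by up to ~0.5% depending on where
  the digitisation grid lands, and broad offsets (residual baseline,
  dispersion tails of the 143× larger 0.881 peak) otherwise leak into
  the scale. For idealized discrete peaks on a flat background the
  refined height equals the window maximum exactly. `tallest_peak`
  divides by the global maximum height; height (not integral) is used
  in both modes. Normalisation is idempotent and purely a rescaling.

## Binning and blinding

Regular bins of 0.05 ppm with summed intensity; edges anchored at
integer multiples of the bin width (absolute grid), half-open [low,
high). Only bins fully covered by the axis are emitted, so the
referencing shift cannot change a sample's bin identity. Six regions
are blinded — the −3.9…−1.0 and 13.02…16.17 ppm noise flanks, TMS
(−0.2266…0.1892), and the CDCl₃ main and satellite lines — and a bin
overlapping a blinded region at all is dropped whole (constant bin
support across samples). For the default window this leaves exactly
264 bins, pinned by a regression test.

## Chemometrics

Pareto scaling mean-centres each bin and divides by √sd (sample, n−1);
zero-variance bins are centred, left undivided and flagged. PCA is the
SVD of the scaled matrix, with each loading column's largest-magnitude
element forced positive for reproducible score plots; scikit-learn is
used only as an independent cross-check in the tests. Projection of
new samples applies the stored means, weights and loadings, so it is
affine: training samples reproduce their scores exactly and blends
interpolate linearly.

The authenticity region is fitted on the olive class only: mean and
covariance of its PC1–PC2 scores, thresholded at the Hotelling T² bound
for a single new observation, 2(n−1)(n+1)/(n(n−2))·F₀.₉₅(2, n−2). This
form accounts for the reference mean and covariance being estimates, so
a fresh authentic sample falls inside with probability equal to the
confidence level for any panel size; as n → ∞ the threshold tends to
the χ²₂ quantile 5.991. PCA for the authenticity call is likewise
trained on the olive panel alone; pure seed-oil centroids (one
noise-free spectrum each) are projected into that plane to label
flagged samples with the oil they trend toward — a qualitative aid
that is reliable for blends but can be ambiguous for pure oils far
outside the calibrated region, where the two-component projection
compresses distances.

## Detection limits

For each v/v fraction, replicate adulterated bottles are simulated
(fresh olive draw from the panel distribution, fresh noise and jitter),
classified, and the flag rate recorded; the detection limit is the
smallest fraction flagged at ≥ 95%. At fraction 0 the flag rate is the
ellipse's false-positive rate (≈ 5% by construction). The acceptance
suite runs hazelnut {2.5–20}%, high-oleic canola {5–20}%, peanut and
high-oleic safflower {10–40}% with a 20-oil training panel and 50
replicates per condition, and verifies the normalisation contrast:
safflower is caught by 20% under ω-3 normalisation but not under
tallest-peak normalisation at the same fractions.

## Ellipse coverage measurement

Empirical coverage conditional on one finite reference panel is itself
random (sd ≈ 1.5 percentage points at n_ref = 100), so the coverage
test averages 2000 held-out olive samples over 10 independent panels,
which brings the spread of the estimate inside a 3σ binomial band
around the nominal 95%. `scripts/acceptance.py` reports the
single-panel version (100 training oils, 2000 held-out samples) as the
headline number.

## Problem sizes and seeds

One global seed; every simulated sample uses an independent substream
derived from a CRC32 hash of its sample id, so results are independent
of simulation order and reproducible per sample. Default problem
sizes: 65,536-point spectra everywhere the ω-3 reference matters (the
line is ~12 grid points wide there; at 8,192 points it is ~1.5 points
wide and apex estimation degrades, which is why unit tests that shorten
spectra only assert gross contrasts), 20-oil panels and 50 replicates
for detection limits, 100-oil panels for coverage.

## What the simulator does and does not capture

It captures: composition-driven lineshapes and intensities of the major
triglyceride resonances, first-order multiplet structure, realistic
noise and shift jitter, bottle-to-bottle compositional spread, v/v
mixing, and the full processing-parameter chain including its failure
modes (phase wobble, baseline leakage, bin-edge effects).

It does not capture: minor components (squalene, sterols, phenolics,
diacylglycerols), ¹³C satellites, second-order coupling, per-peak
differential shift drift, field inhomogeneity lineshape distortions, or
real cultivar/harvest covariance structure. Detection limits measured
here therefore characterise the pipeline under the stated synthetic
conditions — in particular the assumed tightness of the authentic
class's ω-3 share — not the field performance on real retail oils,
where minor-component signals add discriminating power and
compositional spreads differ.
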