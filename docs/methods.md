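# Methods

This note documents the models, defaults and numerical choices behind
`endospec`, and what the synthetic-data tests do and do not demonstrate.

## Wavelength grid and spectral containers

All spectra live on a uniform 380–780 nm axis at 1 nm: 401 samples, with
the two narrow-band centers (415, 540 nm) falling exactly on grid points
(indices 35 and 160). Reflectance is stored as a unitless factor. Values
outside [0, 1] are permitted in storage because regression-based
reconstruction can overshoot; `validate_reflectance` flags them and
`clip_reflectance` clips them, but nothing clips silently. Cubes are
exchanged as ENVI pairs (text header + band-sequential little-endian
float32 raw), the de facto interchange format for hyperspectral imagery;
the reader validates header/raw size consistency and requires a wavelength
list. Resampling between grids is linear interpolation with no
extrapolation — endoscopy spectra are smooth at the 1–10 nm scale, so
higher-order schemes buy nothing and can ring.

## Camera linearization

Display-encoded RGB is linearized with the sRGB inverse EOTF by default;
`gamma2.2` and `linear` are selectable because an endoscope's true transfer
function is generally unknown and may be neither. The encoding state is an
explicit flag on every image, and linearizing an already-linear image is an
error rather than a silent no-op — double linearization is a classic silent
failure in camera-characterization code.

## Calibration model

The RGB→spectrum transform is the standard checker-based estimation
pipeline:

* **Feature expansion.** Monomials RᵃGᵇBᶜ of the linearized triplet with
  a+b+c ≤ order. Default order 3 → 20 terms, ordered deterministically
  (degree ascending, reverse-lexicographic within a degree, constant term
  first). Order 3 is the usual sweet spot for 24 training points: order 2
  (10 terms) underfits saturated patches, order 4 (35 terms) exceeds the
  patch count.
* **Spectral basis.** PCA (SVD of the centered 24×401 patch matrix). With
  24 patches at most 23 components exist; the default keeps
  k = min(10, smallest k explaining ≥ 99.9 % of variance). On the synthetic
  checker this lands at k ≈ 6. Truncation is what makes the inverse problem
  well-posed: 3 camera measurements can never constrain 401 free bands
  (metamerism), so the reconstruction is a maximum-plausibility smooth
  spectrum, not a physical measurement.
* **Regression.** Ridge least squares from expanded features to basis
  coefficients, with the penalty scaled by each feature column's norm so
  one λ means the same thing across term orders. Default λ = 1e-6 — enough
  to stabilize the nearly-square 20×24 design, small enough to leave exact
  configurations exact to ~1e-11. λ = 0 gives plain least squares and a
  rank-deficiency warning when terms exceed patches.
* **Color space.** Features may be formed in linear RGB (default) or CIE
  XYZ. Any invertible linear recoding of the inputs spans the same
  polynomial feature space, so with λ = 0 predictions are invariant — this
  is tested, and is the package's reading of calibrating "across color
  spaces": the choice is a numerical convenience, not new information.

Fitted models serialize to versioned JSON. Reconstruction uses fixed
`einsum` contractions and a C-contiguous coefficient map so that a reloaded
model reproduces bit-identical spectra — floating-point summation order
would otherwise depend on array provenance.

## Narrow-band rendering

`extract_band` offers a `delta` slice (exact grid band) and a `gaussian`
mode whose normalized weights (FWHM default 30 nm, approximating commercial
NBI filter bandwidths) always sum to 1. The display composite maps the
415 nm image to the green and blue channels and the 540 nm image to red —
the conventional NBI arrangement, which renders superficial vessels warm
brown and deep vessels green/cyan. Channels are normalized jointly
(min-max over all three, preserving hue) before display gamma; a
fixed-range mode exists for cross-image comparability and for monotonicity
analyses, where a per-image min-max would move the reference frame along
with the signal.

Vessel conspicuity is reported as Weber contrast
(background − vessel)/background per channel and on Rec.709 luminance. The
display mapping constrains what hue can show: with one band feeding both G
and B, every pixel has G = B, so hue is effectively binary (red-ish vs
cyan-ish) and shallow-vessel-vs-background color differences appear as
saturation, not hue. The discriminating color test is therefore shallow
vs deep vessel hue (warm vs cold), plus the directional 415-channel drop.

## Tissue phantom

The phantom is deliberately minimal: a spatially flat, smooth, mucosa-like
background spectrum (bright, rising toward the red) crossed by polyline
vessels rasterized without anti-aliasing so masks are exact. Vessel
reflectance follows single-pass Beer–Lambert attenuation
`background · exp(−c · ε(λ) · w_depth(λ))` with:

* ε(λ): sum of Gaussians at 415/540/577 nm, σ = 13/15/10 nm, amplitudes
  10/1.0/0.9 — a hemoglobin-like absorber with the Soret:Q ratio of order
  10:1. Analytic rather than tabulated extinction data keeps the package
  self-contained; only directional contrast properties are asserted, never
  absolute optical densities.
* w_depth(λ): logistic ramps standing in for depth-dependent light
  penetration — shallow vessels see `1 − σ((λ−520)/30)` (short wavelengths
  reach them), deep vessels `σ((λ−480)/20)` (only longer wavelengths
  penetrate to the submucosa). With the default absorber this yields the
  qualitative NBI physics: shallow vessels attenuate 415 nm most, deep
  vessels 540 nm most, for every concentration c > 0.
* c (concentration × pathlength): unitless, default 0.5 — deep vessel
  attenuation ~30 %, shallow ~90 % at 415 nm, i.e. strong but unsaturated.

Overlapping vessels resolve to the shallower one (it is physically in
front), keeping masks disjoint. All generators take explicit seeds and are
bit-reproducible.

**What the phantom does not emulate:** mucosal texture and specular
highlights, lesion morphology, scattering and depth-continuous attenuation,
camera noise, and an endoscope's proprietary tone pipeline. Passing the
contrast-enhancement and depth-discrimination tests therefore shows the
pipeline's mechanics are correct and directionally faithful, not that the
same margins hold on clinical images.

The camera simulator uses Gaussian R/G/B sensitivities at 610/545/460 nm
(FWHM 60 nm), a flat illuminant, exposure normalized so a perfect reflector
maps to (1,1,1) before gamma. Real sensor curves are asymmetric and
overlapping in more complex ways; the Gaussian model keeps every quantity
in the test oracles hand-computable.

## Detection evaluation

* Boxes are half-open pixel rectangles; IoU is exact box arithmetic.
* Matching is greedy in descending confidence (stable sort, ties by input
  order) against the unmatched same-class ground truth of highest
  IoU ≥ 0.5. The threshold is the PASCAL convention and configurable.
* AP defaults to all-point interpolation (area under the precision
  envelope); 11-point is available because published scorecards often do
  not say which was used, and the report records the choice.
* Per-class accuracy is one-vs-rest over an item universe of all ground
  truths plus all false-positive detections — the convention that
  reconciles published count tables of this layout.
* Kappa is computed on the item-level class-assignment confusion from
  class-agnostic matching with a background row/column for unmatched items;
  other constructions exist, so the matrix builder is exposed separately.
* Undefined metrics (zero denominators) propagate as not-a-value, never as
  0. Percentages are rounded half-up to one decimal for display only;
  macro means are taken at full precision and rounded last.

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthetic data:
48×48 to 64×64 phantom scenes, 24-patch targets, 20-scene contrast
ensembles, 200-ranking AP oracle sweeps, and a 32×32 image for the
pixel-loop equivalence — sizes at which every brute-force oracle is exact
and the whole suite completes in seconds. Every stochastic step takes an
explicit seed; the pipeline manifest records SHA-256 hashes of all
artifacts so reruns can be verified byte-identical.

## Known limitations

* RGB→spectrum recovery is fundamentally limited by metamerism; accuracy
  claims only extend to spectra near the span of the calibration target.
* The NBI color reproduction is a display convention, not a simulation of
  any vendor's processing; only directional hue/contrast properties are
  asserted.
* The phantom's two-layer depth weighting is qualitative; it is not a
  radiative-transfer model and should not be used to infer real optical
  densities.
* The evaluation suite scores detections; it does not train or run a
  detector.
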