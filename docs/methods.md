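# Methods

This note documents the models behind `biomemap`, the defaults and why
they were chosen, what the synthetic scenes do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Spectral model and pigment classification

A reflectance spectrum is modelled (and, in the generator, rendered) as a
smooth baseline minus a sum of Gaussian absorption dips, one set per
phototroph group, each dip scaled by the group's cover fraction in the
pixel. The second derivative with respect to wavelength, δδ, suppresses
the baseline and turns each dip of depth *A* and width σ into a peak of
height *A*/σ² at its centre, flanked by negative lobes (extrema at
±√3 σ). Classification thresholds operate on δδ at the band nearest the
target wavelength:

| channel | wavelength | pigment | group | threshold |
|---|---|---|---|---|
| δδ546 | 546 nm | fucoxanthin | diatoms | > 0 |
| δδ568 | 568 nm | phycoerythrin | red algal host | > 0 |
| δδ648 | 648 nm | chlorophyll *b* | Chlorophyta | > −0.00025 |
| δδ677 | 677 nm | chlorophyll *a* | whole community | > 0 |

Thresholds are strict inequalities in δδ units of reflectance · nm⁻².
A consequence of the lenient chlorophyll-*b* cut-off worth knowing: a
pixel with δδ648 exactly 0 (e.g. unpigmented background) *passes* the
chlorophyte threshold. Group maps are therefore meaningful only inside
the community (δδ677 > 0) and the ROI; abundances and contributions are
always normalised within the community mask.

**Derivative estimator.** The default is the 3-point central difference
`(R[b−1] − 2R[b] + R[b+1])/Δλ²` at the nearest sampled band (no spectral
interpolation; the band used is recorded). On a Gaussian band this
estimator carries a known multiplicative bias `2(1−e^(−r²/2))/r²` with
`r = Δλ/σ` — about −r²/4, i.e. −2.7% at σ = 3Δλ. Where 2%-level accuracy
matters at that width, the 5-point O(Δλ⁴) stencil is available
(`stencil=5`, bias ≈ −0.2% at σ = 3Δλ). Optional Savitzky–Golay
smoothing of each spectrum precedes the finite difference; the pipeline
default for noisy data is window 7, order 2, chosen by margin analysis
(below). Pass `smoothing=None` for the bare estimator, which is exact on
noise-free synthetic data.

## Rapid-light-curve models

Per pixel, with E the step irradiance (µmol photons m⁻² s⁻¹):

- Fv/Fm = (Fm − Fo)/Fm from the dedicated dark layers; the first light
  step (E = 1) is quasi-dark but treated as an ordinary fitted point.
- ETR(E) = Fq′/Fm′ · 0.5 · E (relative units; the 0.5 assumes half the
  absorbed quanta reach PSII and is a named constant, not a measurement).
- ETR–E fit: `ETR = Ps(1 − exp(−αE/Ps)) exp(−βE/Ps)`. Default mode fixes
  β = 0 (no photoinhibition is evident in the 10-step protocol), giving
  ETRmax = Ps and Ek = ETRmax/α — the identity is exact by construction
  for every converged pixel. With β free, ETRmax uses the closed-form
  maximum `Ps [α/(α+β)] [β/(α+β)]^(β/α)`.
- NPQ(E) = (Fm − Fm′)/Fm′ per step; NPQ–E fit: Hill curve
  `NPQ = NPQmax E^n/(E50^n + E^n)` with NPQmax the asymptote and n, E50
  free. The Hill form is a modelling choice (the underlying xanthophyll-
  cycle response is sigmoidal in practice) and is recorded in the output
  metadata.

**Estimation.** All per-pixel fits run as one vectorised
Levenberg–Marquardt in log-parameter space (parameters stay positive;
relative SSE tolerance 1e-8, ≤ 200 iterations; failures yield NA, never
partial values). Initial values: α₀ from the slope of the first two
steps, Ps₀ = max observed ETR, n₀ = 2, E50₀ = median E. scipy's
independent optimiser reproduces the batched results in the test suite.

Because ETR and NPQ are *derived* from yields with multiplicative error,
their noise is strongly heteroscedastic, and the fits exploit the known
structure rather than treating points equally:

- ETR noise sd ∝ E(1 − Fq′/Fm′); the Platt fit is inverse-variance
  weighted accordingly (the proportionality constant cancels). This
  sharpens α by roughly an order of magnitude and ETRmax by ~2× at 2%
  yield noise.
- NPQ noise has per-step sd ∝ (1 + NPQ) plus a component from the single
  dark Fm that is common to all steps of a pixel. The Hill fit is
  generalised least squares with covariance ∝ diag(v²) + v vᵀ,
  v = 1 + NPQ(E), whitened in closed form (Sherman–Morrison) and
  iterated 3× with v from the current fit. The whitening depends only on
  the curve shape, not on the unknown noise level, and reaches the
  Cramér–Rao bound in simulation.

**Diagnostics.** A fit whose J′J condition number exceeds 1e8 is flagged
ill-conditioned: for an ETR curve that never saturates within the
protocol (linear in E) α is still reported but ETRmax and Ek are NA. A
Hill fit whose E50 lands beyond 80% of the highest measured irradiance is
flagged `extrapolated` — the asymptote is then an extrapolation with a
wide confidence interval. Pixels NA in *any* photophysiological
parameter are excluded from all downstream tables (`exclude_na`), so
every summary draws on one common pixel set.

## Georectification and clipping

Control-point pairs are fitted with bivariate polynomials of degree 1–3
(degree 3 default; 10 coefficients per axis, so ≥ 10 pairs required,
≥ 20 recommended), linear in their coefficients, mapping **target →
source** so that every output pixel is defined by one inverse lookup.
Coordinates are centred and scaled internally for conditioning; the fit
is exact (residual < 1e-8 px) on noise-free points generated by a
polynomial of no higher degree. Quality is summarised as the mean and
RMS Euclidean control-point residual in pixels; with 20 points and
0.3 px localisation jitter the mean residual is ≈ 0.26 px (10 residual
degrees of freedom per axis), comfortably below the 1 px working bound.

Resampling is nearest-neighbour by default — fitted parameters must not
be blended across pixels — with bilinear available for reflectance-like
data. Pixels mapping outside the source extent are NA. ROI clipping
keeps pixels whose centre lies inside the polygon; a centre exactly on
the boundary counts as inside on left/top edges (tested by nudging the
point by +1e-9 in x and y), so abutting rectangles partition pixels
without overlap.

## The contribution partition

The community value of a parameter (ETRmax or NPQmax) is divided among
groups by per-pixel derivative-amplitude share:

    w_g(p) = max(δδ_g(p), 0) / Σ_h max(δδ_h(p), 0)   over groups present at p,

    contribution_g = 100 · Σ_p w_g(p)·param(p) / Σ_p Σ_g w_g(p)·param(p).

The δδ amplitude acts as an absorption-strength proxy for how much of
the pixel each group occupies. The formula reduces to pixel-count
weighting when amplitudes are equal (that variant is available as
`weighting="count"` for sensitivity analysis), handles multi-group
pixels naturally, and guarantees group percentages sum to exactly 100.
A group below its threshold at a pixel has weight 0 there — a group that
is not detected cannot contribute.

## The synthetic world

The generator emulates one sample of a 2 shore-height × 3
epiphyte-biomass-category design, N = 4 replicates by default.

**Geometry.** A branched elongated frond mask from a random-walk
skeleton (two apical side branches) dilated to a half-width of 7 px on a
96×96 grid (0.2 mm pixels), with an along-frond coordinate s ∈ [0, 1]
from base to apical tip.

**Cover fields.** Host cover starts at 0.85 and never falls below 0.45
(the calcified host remains partly visible beneath its epiphytes —
though heavy diatom cover does measurably mask its phycoerythrin signal,
as on real fronds). Epiphytes are confined to the apical zone: on the
lower shore a contiguous diatom film over the apical half to two thirds
rising to peak cover 0.30 (medium) / 0.42 (high); on the upper shore a
sparse, patchy mixed diatom/chlorophyte community near the apex (patch
retention 0.25–0.45) — upper-shore epiphytes end up contributing well
under 20% of community productivity, as observed in the field. "Low"
categories keep epiphyte cover below 5% everywhere, by definition. Cover
below 0.10 is treated as below the optical detection floor when building
ground-truth masks; category profiles jump from 0 to ≥ 0.15 where
colonised so that presence is a well-posed classification target.

**Spectra.** Baseline reflectance is affine in wavelength (0.75 ± 0.05
across the grid) — its δδ is exactly zero, so classification is exact at
zero noise. Band models (centre, σ, dip depth per unit cover): host
phycoerythrin (568, 10, 0.70); diatom fucoxanthin (546, 7, 1.30);
chlorophyte chlorophyll-*b* (648, 9, 1.30); and in every group
chlorophyll-*a* (677, 9, 0.40) plus an accessory shoulder (630, 12,
0.55). The instruments report only derivative peaks, never absolute dip
depths, so amplitudes are free parameters of this stated world; they
were fixed once, before any end-to-end testing, by a forward margin
analysis: every channel's δδ clears its
threshold in the correct direction at zero noise, and by ≥ ~2.5 noise-sd
at 2% multiplicative reflectance noise after Savitzky–Golay (7, 2)
smoothing — the one knowingly-thin margin is host detection under dense
diatom cover (the masking effect above). The 630 nm shoulder is what
pushes δδ648 of chlorophyll-*b*-free pixels decisively below the lenient
−0.00025 threshold. Raw counts are reflectance times a halogen-like
illumination ramp; the white reference is the noise-free plate signal at
99% reflectance, so normalisation is exact at zero noise.

**Fluorescence.** Dark Fm ≡ 1, Fo = 1 − Fv/Fm. At irradiance E the true
NPQ follows the Hill curve (defaults n = 2, E50 = 150 µmol photons
m⁻² s⁻¹), Fm′ = Fm/(1 + NPQ), and Fq′/Fm′ is chosen so that ETR follows
the pixel's true saturating curve; a parameter combination implying
Fq′/Fm′ outside [0, 1] raises (with the defaults, rendered efficiencies
are in [0, 1] and non-increasing in E). Group-level parameter means
encode field-realistic photoacclimation — higher α and Fv/Fm on the
lower shore, higher ETRmax on the upper shore, strongest NPQmax in
diatoms (2.0–2.2) — mixed per pixel by cover, with a basal-to-apical
rise in α and ETRmax and smooth multiplicative spatial noise. The
fluorescence camera's view is a mild affine warp (1.5° rotation, 1%
scale, a few px shift) of the hyperspectral frame; synthetic control
points are warped frond points with 0.3 px Gaussian picking jitter.

**Noise and seeding.** Both modalities default to 2% multiplicative
Gaussian noise per band/layer. All randomness derives from a master seed
through fixed named streams (geometry, fields, cube noise, fluorescence
noise, control points), so every product is bit-reproducible from
config + seed.

**What a green test does and does not establish.** The generator shares
its band shapes and curve families with the analysis models, so
round-trip tests verify *estimator correctness and noise robustness*,
not model adequacy on real spectra. Real reflectance baselines are not
affine (calcite scattering, water film), real pigment bands overlap
vibronic structure, fluorescence kinetics within a 30 s light step are
ignored, and the warp of a real imaging-PAM is not exactly polynomial.
Radiative-transfer realism is explicitly out of scope.

## Known limitations

- **NPQmax precision floor.** With 2% independent multiplicative noise
  on every yield layer, the Cramér–Rao bound for the 3-parameter Hill
  asymptote is ≈ 5.4% median relative error at NPQmax ≈ 0.8. The GLS
  estimator sits at that bound, so scenes dominated by low-NPQ (host)
  pixels cannot beat ~5–6% median NPQmax error — a property of the
  measurement, not the code. Mixed scenes (default configuration) sit
  near 4.4%.
- **Nearest-neighbour involution.** Warp + inverse-warp with nearest
  resampling restores ≥ 99% of pixels only for near-rigid warps; the
  mismatch rate grows with |scale − 1| and rotation (double rounding).
- **Host masking.** Under peak diatom cover the host's δδ568 margin is
  ~1.4 noise-sd at 2% noise, so a few percent of dense-biofilm pixels
  lose the host flag — mirroring the epiphytic masking seen in real
  imagery. Host abundance on high-biomass lower-shore scenes can
  accordingly read ~2 percentage points low.
- **Absolute units.** ETR is relative (no absorptance measurement);
  contributions are shares, not areal carbon fluxes. Inferential
  statistics (ANOVA etc.) are deliberately left to external packages —
  the tidy CSV exports are the interface.
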