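# biomemap

Coupled hyperspectral + variable-chlorophyll-fluorescence image analysis of
macroalgal phototroph communities — who lives where on an algal frond, and
how much each group contributes to community productivity.

Intertidal calcified macroalgae such as *Corallina officinalis* host
epiphytic microalgae (diatom biofilms, filamentous green algae) whose cover
varies with shore height and along each frond. `biomemap` implements the
full desk-side analysis that turns two bench-top imaging modalities into
community-level answers:

1. **Pigment mapping from hyperspectral reflectance.** Raw cubes
   (400–1000 nm, 4.5 nm steps) are normalised against a ~99% white
   standard, and the spectral second derivative δδ is computed at
   diagnostic absorption wavelengths. An absorption dip of depth *A* and
   Gaussian width σ gives a positive δδ peak of height *A*/σ² at its
   centre, so thresholding δδ images yields per-group presence masks:
   fucoxanthin (δδ546 > 0 → diatoms), phycoerythrin (δδ568 > 0 → red
   algal host), chlorophyll *b* (δδ648 > −0.00025 → Chlorophyta) and
   chlorophyll *a* (δδ677 > 0 → whole community). Masks may overlap;
   relative abundance is pixel counts normalised to the community mask.
2. **Per-pixel photophysiology from imaging-PAM rapid light curves.**
   From fluorescence yields F and Fm′ over a 10-step irradiance protocol
   (1 … 531 µmol photons m⁻² s⁻¹): Fv/Fm = (Fm−Fo)/Fm,
   Fq′/Fm′ = (Fm′−F)/Fm′, ETR = Fq′/Fm′ × 0.5 × E, and
   NPQ = (Fm−Fm′)/Fm′. Every pixel's ETR–E curve is fitted with the
   exponential saturating model ETR(E) = Pₛ(1−e^(−αE/Pₛ))e^(−βE/Pₛ)
   (default β = 0, so ETRmax = Pₛ and Ek = ETRmax/α), and NPQ–E with a
   saturating Hill curve whose asymptote is NPQmax. Fits run as a
   vectorised Levenberg–Marquardt over all pixels at once, weighted by the
   fluorescence error model.
3. **Georectification.** The two cameras see the sample through different
   optics; ≥ 10 (recommended ≥ 20) matched control points are fitted with
   a degree-3 bivariate polynomial (target → source), fluorescence maps are
   resampled onto the hyperspectral grid (nearest-neighbour for fitted
   parameters), and both modalities are clipped to a region-of-interest
   polygon.
4. **Community synthesis.** Along-frond transects, balanced random pixel
   subsets for external statistics, and the derivative-weighted partition
   of community ETRmax/NPQmax among host, diatoms and chlorophytes: each
   pixel's parameter value is shared among the groups present in
   proportion to their positive δδ amplitude, and group sums are
   normalised to the community total (so contributions always sum to
   100%).

Because no field imagery ships with the package, a first-class
**synthetic-scene generator** renders paired cubes and fluorescence stacks
from known ground truth (branched frond geometry, apical epiphyte
gradients, per-pixel α/ETRmax/NPQmax/Fv-Fm fields, affine camera
misregistration, multiplicative sensor noise), so every stage is testable
against a recoverable answer.

## Worked example

```python
from biomemap import pipeline

# one lower-shore, high-epiphyte-biomass sample; 2% noise, warped
# fluorescence camera, 20 jittered control points
res = pipeline.run_sample(seed=1, shore_height="lower", epiphyte_category="high")

print(f"registration error: {res.transform.mean_error:.3f} px")
print({g: round(v, 1) for g, v in res.abundance.items()})
print(res.contributions[["group", "parameter", "percent"]].round(1))
```

prints

```
registration error: 0.237 px
{'diatom': 71.7, 'host': 98.5, 'chlorophyte': 0.1, 'community': 100.0}
      group parameter  percent
     diatom    etrmax     55.1
       host    etrmax     44.9
chlorophyte    etrmax      0.0
     diatom    npqmax     57.6
       host    npqmax     42.4
chlorophyte    npqmax      0.0
```

i.e. the georectification is accurate to a quarter pixel; diatoms cover
~72% of the community's pixels (the host remains detectable beneath them
on ~98%); and on this heavily colonised lower-shore frond the diatom film
carries slightly more than half of both community productivity (ETRmax
share) and photoprotective capacity (NPQmax share). `pipeline.run_study`
repeats this over the full 2 shore × 3 biomass-category × N replicate
design and aggregates tidy per-cell tables.

A CLI mirrors the library: `biomemap simulate | spectra | rlc | register |
community | pipeline` (see `biomemap --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the mean control-point residual of the degree-3
georectification (20 control points from a random degree-3 warp of a
750×750 grid, 0.3 px localisation jitter, averaged over 100 trials) and
writes it as JSON.

## Layout

- `src/biomemap/synthetic.py` — scene generator (ground truth, cube and
  fluorescence rendering, control points)
- `src/biomemap/spectral.py` — reflectance normalisation, δδ images,
  classification, abundances
- `src/biomemap/fluor.py` — quantum efficiencies, ETR/NPQ, batched
  model fitting
- `src/biomemap/register.py` — polynomial transforms, resampling, ROI
  clipping
- `src/biomemap/community.py` — transects, pixel subsets, contribution
  partitioning
- `src/biomemap/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — models, assumptions, numerical choices and known
  limitations
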