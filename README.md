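# altiband

Altitudinal diversity gradients with area correction: banding, interpolated
richness, species–area rescaling, mid-domain nulls, and spatially explicit
regression.

## The problem

Along a mountain gradient, taxon richness counted in fixed-width elevational
bands almost always shows a hump: a mid-elevation peak. But band *area* is
itself hump-shaped on most mountains, and larger bands hold more species for
sampling reasons alone — so the hump may be an area artefact, and area
covaries with temperature, precipitation and the mid-domain effect, masking
their contributions. `altiband` implements, as a tested reusable library,
the standard workflow for disentangling this:

1. **Banding.** Cut the domain into equal-elevation bands (fixed width, e.g.
   37 × 100 m over 1350–5050 m), with band area = cell area × DEM cells per
   band; or into **equal-area bands** by jittering the integer DEM values
   with U(−0.5, +0.5) and splitting the ranked cells into groups whose sizes
   differ by at most one.
2. **Richness.** Interpolate each species' presence across every band
   intersecting its recorded elevational range; count nine variables per
   band: S, G, F (species/genus/family), TS, SS, HS (tree/shrub/herb) and
   IS, IIS, IIIS (range-size groups <150 m, 150–500 m, >500 m).
3. **Method 1 — power law.** Fit S = cA^z (the log–log species–area
   relationship, selected against linear and semi-log forms by
   AICc = −2 logLik + 2K·n/(n−K−1)) and rescale: TRcor₁ = 100·TRobs/A^z.
4. **Method 2 — equal-area re-count.** Count richness again on the
   equal-area scheme; area is controlled by construction.
5. **Mid-domain null.** Place each empirical range size uniformly within
   the bounded domain (random midpoint), 1000 times; the per-band mean is
   the MDE prediction. A closed-form expectation serves as an exact check.
6. **Spatial statistics.** Regress every richness variable on elevation,
   MAT, MAP and the MDE prediction: polynomial OLS with AICc order
   selection, Moran's I correlograms of residuals
   (I = (n/S)·ΣΣ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)²), and SAR error models
   y = Xβ + u, u = λWu + ε fitted by profile maximum likelihood, with
   pseudo-R² = corr(y, ŷ)². The correction method with the larger SAR
   pseudo-R² per cell preserves the abiotic signal better.

Because real checklists and DEM extracts of this kind are rarely deposited
machine-readably, the package ships a first-class synthetic-data module
(`altiband.synthetic`) that generates mountains and floras with the needed
statistical structure — hump-shaped hypsography, linear lapse, rise–fall–rise
precipitation, nested taxonomy, three-group range-size mixture.

## Worked example

```python
import altiband as ab

config = ab.RunConfig(
    mountain=ab.MountainParams(seed=42),     # 120x120 DEM, peak area at 2700 m
    checklist=ab.ChecklistParams(seed=42),   # 2028-species flora
    n_sim=1000,
)
report = ab.run_pipeline(config)
print(round(report["species_area_fits"]["S"]["best"].slope, 3))
print(report["peaks"]["species"])
print(report["winner_counts"])
```

prints (see `examples/05_full_pipeline.py` for the full script):

```
0.509
{'obs_peak_m': 3100.0, 'cor1_peak_m': 5000.0, 'cor2_peak_m': 3611.347829758636}
{'method1': 29, 'method2': 7}
```

Read: the log–log species–area fit on the equal-elevation bands gives
z ≈ 0.51 (richness grows roughly as the square root of band area); observed
species richness peaks at 3100 m and the equal-area re-count keeps an
interior hump (3611 m), while the power-law-corrected profile peaks at the
extreme band — method 1 removed the area signal and part of the elevational
structure with it. Across the 36 comparison cells (9 richness variables × 4
predictors), the winner counts say which correction preserved more of the
abiotic predictors' explanatory power on this synthetic mountain.

The shorter scripts in `examples/` demonstrate each stage on its own
(synthetic data, banding + richness, species–area correction, the MDE null).
A thin CLI mirrors the per-stage functions:

```bash
altiband bands --dem dem.asc --mode equal_area --n-bands 37 --seed 1 --out bands.csv
altiband richness --checklist flora.csv --scheme bands.csv --out richness.csv
altiband mde --checklist flora.csv --scheme bands.csv --nsim 1000 --seed 1 --out mde.csv
altiband run --config config.yaml
```

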