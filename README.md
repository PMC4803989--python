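# ozcra — ozone comparative risk assessment

`ozcra` estimates the chronic-disease burden attributable to long-term
ground-level ozone at national scale, following the comparative risk
assessment (CRA) framework used in burden-of-disease studies. It is
aimed at environmental-health analysts who have a sparse air-quality
monitoring network, a gridded population surface, and a national
burden-of-disease table, and who need the full chain:

1. **Exposure surface** — interpolate station measurements of the
   long-term mean of annual 1-hour daily-maximum O₃ (ppb) onto a regular
   lon/lat grid, by inverse distance weighting (IDW) or ordinary kriging
   with an empirically fitted semivariogram.
2. **Model validation** — leave-one-out cross-validation (LOOCV) of both
   interpolators, scored by MAE, RMSE and Pearson *r*.
3. **Relative risk** — a log-linear concentration–response function
   RR = exp(β·Δx), where Δx = max(x − x₀, 0) is the concentration excess
   over the theoretical-minimum-risk exposure distribution (TMRED band
   33.3–41.9 ppb) and β = ln(1.040)/10 per ppb, calibrated so a 10 ppb
   increment carries a cohort relative risk of 1.040 for COPD.
4. **Attributable fraction** — the multi-category population
   attributable fraction over grid cells *i*,
   PAF = S/(S+1) with S = Σᵢ Peᵢ(RRᵢ − 1), where Peᵢ is the cell's share
   of the national population aged ≥ 25; summed per region with
   nationally normalised Pe, so regional PAFs read as fractions of the
   national burden.
5. **Attributable burden** — AB = PAF × TB (DALYs), with a national
   male:female split, rolled up into a regional report table.

A first-class synthetic-data generator (`ozcra.synthetic`) produces
every input with known ground truth — a Gaussian random field with a
specified variogram, an urban-heavy station network, a clustered
population raster, a region map, and a burden table — so the whole
pipeline is testable offline, and pipeline error can be isolated to the
interpolation stage.

## Worked example

Generate a synthetic national scenario and run the pipeline:

```sh
ozcra simulate --seed 42 --outdir data
printf 'lon0: 98.0\nlat0: 6.0\ncell_size: 0.25\nn_lon: 30\nn_lat: 40\n' > spec.yaml
ozcra interpolate --stations data/stations.csv --method kriging \
    --grid-spec spec.yaml --out surface.asc --summary summary.csv
ozcra validate --stations data/stations.csv --out xv.csv
ozcra paf --surface surface.asc --pop data/population.asc \
    --regions data/regions.asc --region-names data/regions.csv --out paf.csv
ozcra burden --paf paf.csv --burden-table data/burden.csv --out table.csv
```

The `interpolate` step prints the surface summary:

```
kriging: mean 100.91 ppb over 1200 cells
```

`validate` compares the two interpolators by LOOCV over the 52 synthetic
stations — kriging is ahead of IDW by ~27% RMSE on this seed:

```
              rmse       mae  pearson_r  rank  rmse_pct_better_than_worst
kriging   8.795832  7.173187   0.834707     1                   27.372208
idw      12.110835  9.708058   0.683121     2                    0.000000
```

and `burden` prints the regional attribution table (PAFs are fractions
of the national COPD burden; ab columns are DALYs):

```
                   paf  ab_total  ab_male  ab_female  pct_of_region_dalys
Northern      0.001928       500      394        106             0.764296
...
Total         0.271214     70383    55412      14971             0.690033
```

Here 27.1% of the national COPD burden is attributable to ozone in this
synthetic scenario (whose mean field, ~100 ppb, sits far above the
TMRED band, as in the Thai setting the generator emulates).

The same operations are available as library functions
(`ozcra.predict_grid`, `ozcra.loocv`, `ozcra.build_paf_grid`,
`ozcra.build_report`, `ozcra.make_scenario`, …).

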