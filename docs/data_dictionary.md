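# Data dictionary

All tabular artifacts are plain CSV, one header row, UTF-8.

## Plot trait table (`plots.csv`)

| column | type | units | description |
|---|---|---|---|
| plot_id | str | — | unique plot key, `<trial>-<genotype#>-r<rep>` |
| trial_id | str | — | trial label (e.g. CVT1) |
| genotype_id | str | — | genotype label, unique within and across trials |
| replicate | int | — | block number, 1..r |
| GY | float | kg/ha | grain yield |
| LAI | float | m² m⁻² | leaf area index |
| fAPAR | float | 0–1 | fraction of absorbed photosynthetically active radiation |
| fCover | float | 0–1 | fractional vegetation cover |
| LCC | float | mg m⁻² | leaf chlorophyll content |
| NDVI | float | −1–1 | ground-sensor NDVI |

Mandatory columns: `plot_id, trial_id, genotype_id, replicate`; trait
columns are free-form but must be numeric.

## Spectra table (`spectra_<mission>.csv`)

| column | type | units | description |
|---|---|---|---|
| sample_id | str | — | unique sample key |
| plot_id | str | — | plot reference; empty for bare-soil samples |
| sensor | str | — | `PS` or `P4M` |
| mission | str | — | flight-mission label |
| is_soil | bool | — | bare-soil flag |
| b\<nm\> | float | 0–1 | reflectance at the band centred at \<nm\> nm (e.g. `b840`) |

Band columns must match the declared sensor: PS = b550, b660, b735, b790;
P4M = b450, b560, b650, b730, b840.

## Zonal extraction output

`plot_id, genotype_id, replicate, soil`, one column per raster band
(named from the raster's band names), plus `n_pixels` — the number of
pixel centres inside the buffered polygon used for the mean (minimum
across bands after nodata exclusion).

## Pipeline result tables

- `gy_model_comparison.csv`: one row per (mission, model); columns
  `cv_R2, cv_RMSE, cv_nRMSE, cv_rRMSE, cv_NSE` and the same with `val_`
  prefix plus `val_AIC`.
- `biophysical_models.csv`: as above per (trait, model), plus
  `val_uncertainty_pct` for Gaussian-process models.
- `rspt.csv`: plot keys + retrieved LAI, fAPAR, fCover, LCC for all
  replicates (the remotely sensed phenotypic trait table).
- `lrt.csv` / `heritability.csv`: one row per group (each trial, Pooled),
  one column per trait (LRT statistic + `_p`, or H²).
- `genetic_correlation.csv`: per group, r_G of each trait with measured
  grain yield plus `_p` columns.
- `selection_response.csv`: rows `R`, `CR`, `CR_over_R`; columns are
  traits (MGY carries only `R`).
- `manifest.json`: config echo, per-stage timing, output SHA-256 hashes,
  collected warnings.
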