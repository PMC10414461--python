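# sharedcare

Shared care areas (SCAs) are data-driven regions of care coordination:
sets of ZCTAs delineated by community detection on hospital–patient
discharge networks.  This package implements a complete longitudinal
pipeline for studying how the **localization index** (LI) of an SCA — the
fraction of its residents' emergency discharges that occur at hospitals
inside the same SCA — relates to hospitals' **excess readmission ratios**
(ERR, the predicted-to-expected 30-day readmission ratio that triggers
Hospital Readmissions Reduction Program penalties when it exceeds 1).

It is aimed at health-services researchers working with
origin–destination discharge tables (OSHPD-style Patient Origin/Market
Share extracts), HRRP ERR files and area-level ACS covariates, and ships
a synthetic-data generator with planted SCA structure and planted
regression coefficients so the entire pipeline is testable without any
restricted data.

## What it computes

1. **Networks** — one weighted undirected graph per year: nodes are
   ZCTAs (zips normalized via a crosswalk), edge weights are total
   discharges, self-loops allowed.
2. **SCAs** — community detection with three in-house algorithms:
   Louvain (resolution 1), speaker–listener label propagation (threshold
   0.5, edge-weighted votes, crisp projection), and a two-level
   map-equation search.  All seeded and deterministic.
3. **Localization index** — per SCA-year,
   `li(s) = internal discharges of s's residents / all discharges of s's residents`.
4. **Panel + GEE** — hospital-year panel joining ERR, LI and SCA-level
   covariates; marginal Gaussian GEE with exchangeable working
   correlation and cluster-robust (sandwich) standard errors, written
   in-house and cross-checked against an independent implementation:

   `E[ERR_it] = β0 + β_li·LI_s(i),t + β_black·Black_s + β_pov·Pov_s + β_priv·Priv_s + β_hisp·Hisp_s`

5. **Quartile summaries** — median ERR and % penalized by LI (and
   %Black) quartile with 10,000-resample percentile-bootstrap CIs.
6. **Counterfactuals** — observed year-over-year LI changes define a
   shift grid (−q3…+q3); the fitted GEE predicts every hospital-year's
   ERR under each shift.  The model is affine in LI, so the median
   prediction at shift `s` is exactly `baseline median + β_li·s`.

## Worked example

Generate a planted dataset (50 SCAs, 300 hospitals, 2012–2017, planted
β_li = −0.0474, β_black = 0.4128, exchangeable ρ = 0.5), fit the adjusted
GEE, and read the result:

```python
import sharedcare as sc
from sharedcare.experiments import recovery_config

ds = sc.generate_dataset(recovery_config(seed=7))
fit = sc.fit_gee(ds.panel)            # adjusted model, cluster = hospital
print(sc.wald_inference(fit).round(4).to_string(index=False))
```

```
 coefficient    beta     se       z      p  ci_low  ci_high
   intercept  1.0882 0.0612 17.7781 0.0000  0.9683   1.2082
          li -0.0072 0.0880 -0.0815 0.9351 -0.1797   0.1654
   pct_black  0.4124 0.0622  6.6268 0.0000  0.2904   0.5344
 pct_poverty -0.0301 0.0530 -0.5680 0.5700 -0.1339   0.0737
 pct_private -0.1363 0.0204 -6.6778 0.0000 -0.1763  -0.0963
pct_hispanic  0.0106 0.0186  0.5688 0.5695 -0.0259   0.0470
```

Every 95% CI covers its planted coefficient (the LI coefficient is
weakly identified in a single replicate because planted SCAs are
statistically exchangeable — see docs/methods.md; across 100 replicates
the CI covers the planted −0.0474 about 95% of the time).  The estimated
working correlation here is α = 0.458 against the planted 0.5.

The affine-in-LI prediction identity turns a published baseline median,
coefficient and shift into a shifted median without refitting:

```python
>>> round(sc.shifted_median(0.995, -0.0474, 0.179), 3)   # LI rises by +q3
0.987
>>> round(sc.shifted_median(1.039, -0.0474, -0.167), 3)  # LI falls by -q3
1.047
```

## Analysis drivers

`analysis/01_simulate.py` … `analysis/08_counterfactual.py` run the whole
study on a 60-hospital synthetic dataset, writing tables under
`results/`: simulated inputs, yearly networks, SCA partitions for all
three algorithms (with adjusted-Rand agreement against the planted
truth), LI metrics, the linked panel, GEE fits, quartile summaries and
the counterfactual table.  Run them in order:

```sh
for s in analysis/0*.py; do python "$s"; done
```

A `sharedcare` CLI exposes the same stages (`simulate`, `build-network`,
`detect`, `li`, `link`, `fit`, `stratify`, `predict`) for shell pipelines.

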