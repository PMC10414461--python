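# Methods

`sharedcare` implements a complete pipeline for studying how shared care
areas (SCAs) — data-driven regions delineated from hospital–patient
discharge networks — relate to hospitals' excess readmission ratios
(ERRs).  This note documents the models, the numerical choices, and the
synthetic data-generating process the package is validated against.

## Discharge networks

The raw input is an origin–destination table of emergency-department
discharge counts: one row per (year, patient zip/ZCTA, hospital, hospital
zip/ZCTA).  Zip codes are normalized to ZCTAs through a many-to-one
crosswalk (strict by default — an unknown zip is an error, since silently
dropping flow biases the localization index; a lenient mode drops and
logs).  Each year becomes one weighted graph: nodes are ZCTAs, the weight
of edge (u, v) is the total discharges between them.  Edges are
undirected — flow is aggregated over direction, matching community
detection methods that operate on undirected weighted graphs — and a
hospital serving patients of its own ZCTA contributes a self-loop.  A
directed variant is exposed but not used in the analyses.  Discharge
totals are conserved at every stage (read → crosswalk → network), and
network construction is order-independent.

## Community detection

Three algorithms delineate SCAs; each assigns every ZCTA to exactly one
SCA and is deterministic given (network, configuration, seed).  Candidate
moves only ever consider *adjacent* communities, so connected components
are processed independently and isolated nodes form singleton SCAs.

**Louvain** (default resolution γ = 1) greedily maximizes weighted
modularity

    Q = Σ_c [ w_c / W − γ (s_c / 2W)² ]

(w_c internal weight with self-loops, s_c community strength, W total
weight) with the usual two phases — seeded-shuffle local moves, then
aggregation into supernodes — repeated until no move improves Q.  Only
strictly improving moves are accepted, so Q is monotone non-decreasing.

**SLPA** (speaker–listener label propagation, membership threshold 0.5)
gives each node a label memory initialized to its own label.  Each round,
listeners in seeded-shuffle order collect one label from every neighbor
(the speaker samples uniformly from its memory) and append the winning
label to memory.  Votes are weighted by edge weight: classical SLPA is
unweighted, but on discharge networks the many weak cross-SCA edges would
otherwise outvote the few strong within-SCA edges.  Post-processing keeps
labels whose memory frequency reaches the threshold; since the
localization index needs disjoint SCAs, the crisp label is the most
frequent retained one (all ties broken by seeded uniform choice; if no
label reaches the threshold the overall most frequent is used).  Memory
length equals the iteration count (default 100) plus the initial label.

**Two-level map equation** minimizes the expected per-step description
length of a random walk,

    L(M) = q H(Q) + Σ_m p_m° H(P_m),

with visit rates proportional to node strength (undirected stationary
distribution, no teleportation) and module exit rates proportional to
boundary edge weight.  The search is Louvain-style (seeded local moves
plus aggregation) with O(1) move evaluation via the four-term simplified
codelength; only strictly improving moves are accepted, so L is monotone
non-increasing.  A degree-corrected stochastic block model is deliberately
not implemented — it systematically produces SCAs with anomalously low
localization on these networks — but externally produced partitions can
be supplied as CSV and flow through the rest of the pipeline unchanged.

## Localization index

For SCA s in year t, li(s, t) = (discharges of s's residents at hospitals
inside s) / (all discharges of s's residents) ∈ [0, 1] — the classical
residence-based localization index.  An admission-based variant
(denominator: discharges *at* s's hospitals) is available; residence-based
is the default.  An SCA whose residents record no discharges has an
undefined LI (NaN sentinel) and its hospitals are dropped — with a logged
count — when the panel is built.  The resident-weighted mean of SCA LIs
equals the global internal-discharge fraction, which the tests verify by
brute force.  Hospitals inherit the SCA of their ZCTA.

## Panel and regression

The panel joins, per (hospital, year, algorithm): ERR, SCA id, LI, and
SCA-level covariates (%Black, %Hispanic, %poverty, %private insurance)
computed as population-weighted means of member-ZCTA proportions
(unweighted by flag).  Hospitals need at least two observed years
(repeated measures); `penalized` means ERR strictly greater than 1, with
boundary rows logged.  A configurable year offset aligns ERR reporting
years with discharge years if the two calendars differ.

The association model is a marginal Gaussian GEE with identity link and
exchangeable working correlation, clustered on hospital:

    E[ERR_it] = β₀ + β_li·LI_s(i),t + β_black·Black_s + β_pov·Pov_s
                + β_priv·Priv_s + β_hisp·Hisp_s,
    Corr(ERR_it, ERR_is) = α.

The solver alternates an exact generalized-least-squares solve for β
(closed-form exchangeable inverse, O(n) per cluster) with moment updates

    scale = Σ r² / (N − p),    α = [Σ_clusters Σ_{t<s} r_t r_s / scale] / (P − p),

(P = number of within-cluster pairs, p = number of coefficients;
bias-corrected denominators) until the maximum change in (β, α) falls
below 1e−8 or 100 iterations — non-convergence is flagged, never silent.
Standard errors are cluster-robust (sandwich), consistent even when the
exchangeable structure is wrong; 95% CIs use the normal quantile
(±1.959964·SE).  Clusters of size 1 contribute only to the scale; if every
cluster has size 1 the fit reduces exactly to OLS with HC0 covariance, and
freezing α = 0 reproduces pooled OLS.  The unadjusted model uses LI only.
The suite cross-checks coefficients, SEs and α against an independent GEE
implementation to 1e−6 relative on a fixed synthetic panel.  Identifiability
note: covariates are constant within SCA, so with K planted SCAs at most
K − 2 of them are identifiable next to the intercept and LI; small
demonstration datasets therefore use a reduced adjusted model (LI +
%Black), while regression validation runs on 50-SCA panels.

Per-algorithm analyses are the default; a pooled variant simply stacks
the per-algorithm panels (cluster remains the hospital).

## Quartile summaries and bootstrap

Hospitals are stratified by quartiles of LI (and of %Black), within year
by default.  Cutpoints are the 25/50/75th percentiles with linear
interpolation; intervals are closed above (a value tied with a cutpoint
falls in the lower quartile).  Per stratum the median ERR and the share
penalized are reported with percentile-bootstrap CIs — default 10,000
seeded resamples with replacement at the 95% level, resampling
hospital-year rows (a cluster bootstrap over hospitals is available by
flag).  Percentile rather than BCa intervals: the calibration check
(92–98% empirical coverage for the median of normal samples) shows the
simple method is adequate at these stratum sizes.

## Counterfactual predictions

Year-over-year LI differences (consecutive calendar years, per hospital,
zeros excluded) define the shift grid: the 25/50/75th percentiles of the
negative differences (−q3 ≤ −q2 ≤ −q1 < 0) and of the positive ones
(+q1 ≤ +q2 ≤ +q3).  These percentiles use Hazen (type-5) interpolation,
which reproduces the package's reference worked examples exactly.  The
fitted adjusted GEE then predicts each row's ERR at LI + shift.  Because
the model is affine in LI, every prediction moves by exactly β_li·shift,
so the median prediction at shift s equals the baseline median plus
β_li·s — an identity the tests check bit-for-bit, and the mechanism that
makes published shifted medians reproducible from a baseline median, a
coefficient and a shift alone.  Predictions are summarized within
quartiles of %Black (boundaries computed over SCA-year rows, applied to
hospital rows) as the median predicted ERR and the share of predictions
above 1, with bootstrap CIs over the shifted predictions; empty strata are
flagged, not dropped.  Predictions are marginal — a GEE has no
cluster-specific effects to condition on — and carry no causal claim
beyond the fitted adjustment.

## Synthetic data generator

The generator plants the truth every stage is tested against.

* **Geography.**  `n_scas` SCAs × `zctas_per_sca` ZCTAs; the first
  `hospitals_per_sca` ZCTAs of each SCA host one hospital each (a ZCTA can
  be both residence and hospital site, matching the single-node-type
  network).  Hospitals are statistically exchangeable.
* **Flows.**  Counts per (year, origin ZCTA, hospital ZCTA) are Poisson
  with mean `within_rate` (default 20) inside a planted SCA and
  `between_rate` (default 0.5) across — the simplest nonnegative-integer
  law for aggregated discharge counts.  As between_rate → 0 the realized
  LI → 1.
* **Outcome.**  ERR follows the linear model above with the *realized* LI
  (computed from the generated flows under the planted partition — never
  shortcut), a hospital random intercept (σ_b) and a residual (σ_e),
  giving exchangeable correlation ρ = σ_b²/(σ_b² + σ_e²).  Defaults
  σ_b = σ_e = 0.05 give ρ = 0.5 and an ERR SD near 0.07, typical of
  hospital-level ERR data; the planted coefficients default to the
  adjusted associations the pipeline is designed to estimate
  (β_li = −0.0474, β_black = 0.4128, β_pov = −0.0208, β_priv = −0.1317,
  β_hisp = 0.0278, intercept 1.1054).
* **Covariates.**  Drawn once per SCA, uniform on configured ranges
  (%Black 0.2–17.6%, %poverty 5–25%, %private 30–80%, %Hispanic 10–60%);
  ZCTA tables carry the SCA value at every member ZCTA so
  population-weighted aggregation recovers it exactly.
* **Determinism.**  All draws derive from one seed through independent
  substreams; identical configurations are byte-identical.

What the generator does *not* emulate: hospital volume heterogeneity,
spatial contiguity of SCAs, drift of SCA membership over years, non-Gaussian
ERR tails, and covariate variation within SCAs.  Because all SCAs are
exchangeable, the realized LI varies across SCA-years only through Poisson
noise; the LI coefficient is therefore weakly identified in any single
synthetic panel (wide CIs), and validation relies on CI *coverage* across
replicates rather than point accuracy.  Passing tests demonstrate that the
machinery recovers planted structure and coefficients under these
idealized conditions, not that real discharge data satisfy them.

## Problem sizes

The analysis drivers run 20 SCAs × 5 ZCTAs × 3 hospitals (60 hospitals,
2012–2017).  Coefficient-recovery validation uses 50 SCAs × 6 ZCTAs with
one hospital per ZCTA (300 hospitals × 6 years, `between_rate` 0.2 so the
realized LI sits near 0.67) over 100 seeded replicates; the exchangeable-α
check uses 2,000 clusters of 6.  Exhaustive community-detection optima are
verified on 8 nodes for modularity (all 4,140 partitions) and 10 nodes for
the map equation (all 2–4-block partitions).  Bootstrap calibration uses
500 outer replicates of n = 100 with 1,000 resamples.

## Known limitations

* SLPA occasionally splinters an SCA (it is stochastic even at
  convergence-friendly sizes); the paper-default threshold 0.5 is kept.
* The map-equation search, like Louvain, is greedy and can in principle
  land in local optima on large graphs; on the planted benchmarks it
  attains the exhaustive optimum.
* ERR is consumed as an input; the upstream CMS estimation of ERR from
  claims is out of scope.
* Quartile assignment requires at least 4 distinct values; degenerate
  (all-equal) strata are a hard error rather than a silent merge.
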