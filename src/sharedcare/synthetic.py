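"""Synthetic discharge flows, ERR panels, covariates and crosswalks.

The generator plants a known SCA structure and known regression
coefficients so every downstream stage — network building, community
detection, localization index, panel linkage, GEE, stratified summaries
and counterfactual prediction — can be tested against ground truth.

Structure.  ``n_scas`` shared care areas each contain ``zctas_per_sca``
ZCTAs; the first ``hospitals_per_sca`` ZCTAs of each SCA host one hospital
each.  For every (year, origin ZCTA, hospital ZCTA) pair the discharge
count is Poisson with mean ``within_rate`` when the pair shares a planted
SCA and ``between_rate`` otherwise (within_rate > between_rate), the
simplest nonnegative-integer law for aggregated discharge counts.

Outcome model.  Hospital-year excess readmission ratios follow

    ERR_it = beta0 + beta_li * LI_{s(i),t} + beta_black * Black_s
             + beta_poverty * Pov_s + beta_private * Priv_s
             + beta_hispanic * Hisp_s + b_i + e_it

with hospital random intercepts b_i ~ N(0, sigma_b^2) and residuals
e_it ~ N(0, sigma_e^2), giving an exchangeable within-hospital correlation
rho = sigma_b^2 / (sigma_b^2 + sigma_e^2).  The LI entering the model is
the *realized* LI computed from the generated flows under the planted
partition — the generator never shortcuts it — so coefficient-recovery
tests are honest.  Covariates are drawn once per SCA, uniformly on the
configured ranges; ZCTA-level covariate tables carry the SCA value at each
member ZCTA so population-weighted aggregation recovers it exactly.

The default coefficients are the adjusted associations this pipeline is
designed to estimate (LI -0.0474, %Black 0.4128, ...), and the default
noise scales give rho = 0.5 with an ERR standard deviation near 0.07,
typical of hospital-level ERR data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import Partition
from .flows import FLOW_COLUMNS
from .localization import localization_index

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_flows",
    "generate_covariates",
    "generate_panel",
    "generate_dataset",
    "write_dataset",
]

COVARIATES = ["pct_black", "pct_poverty", "pct_private", "pct_hispanic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator (defaults are the
    conditions used throughout the test-suite and analysis scripts)."""

    n_scas: int = 4
    zctas_per_sca: int = 10
    hospitals_per_sca: int = 10
    years: tuple = (2012, 2013, 2014, 2015, 2016, 2017)
    within_rate: float = 20.0
    between_rate: float = 0.5
    beta0: float = 1.1054
    beta_li: float = -0.0474
    beta_black: float = 0.4128
    beta_poverty: float = -0.0208
    beta_private: float = -0.1317
    beta_hispanic: float = 0.0278
    sigma_b: float = 0.05
    sigma_e: float = 0.05
    covariate_ranges: dict = field(
        default_factory=lambda: {
            "pct_black": (0.002, 0.176),
            "pct_poverty": (0.05, 0.25),
            "pct_private": (0.30, 0.80),
            "pct_hispanic": (0.10, 0.60),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_scas, self.zctas_per_sca, self.hospitals_per_sca) < 1:
            raise ValueError("counts must be >= 1")
        if self.hospitals_per_sca > self.zctas_per_sca:
            raise ValueError("hospitals_per_sca cannot exceed zctas_per_sca")
        if not self.within_rate > self.between_rate >= 0:
            raise ValueError("need within_rate > between_rate >= 0")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("noise scales must be >= 0")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        for name in COVARIATES:
            lo, hi = self.covariate_ranges[name]
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"covariate range for {name} must sit in [0,1]")

    @property
    def rho(self) -> float:
        """Implied exchangeable within-hospital correlation."""
        v = self.sigma_b**2 + self.sigma_e**2
        return self.sigma_b**2 / v if v > 0 else 0.0

    @property
    def n_hospitals(self) -> int:
        return self.n_scas * self.hospitals_per_sca


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the planted truth."""

    config: SyntheticConfig
    flows: pd.DataFrame
    labels: dict  # planted ZCTA -> SCA id
    hospitals: pd.DataFrame  # hospital_id, zcta, sca_id
    crosswalk: pd.DataFrame  # zip, zcta (identity)
    zcta_covariates: pd.DataFrame
    sca_covariates: pd.DataFrame
    li_table: pd.DataFrame | None = None
    panel: pd.DataFrame | None = None

    def planted_partition(self, year: int) -> Partition:
        return Partition(year=year, algorithm="planted", labels=dict(self.labels))

    @property
    def truth(self) -> dict:
        c = self.config
        return {
            "labels": self.labels,
            "beta": {
                "intercept": c.beta0,
                "li": c.beta_li,
                "pct_black": c.beta_black,
                "pct_poverty": c.beta_poverty,
                "pct_private": c.beta_private,
                "pct_hispanic": c.beta_hispanic,
            },
            "rho": c.rho,
        }


def _rngs(config: SyntheticConfig, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _geography(config: SyntheticConfig):
    n_z = config.n_scas * config.zctas_per_sca
    zctas = np.array([f"9{i:04d}" for i in range(n_z)])
    sca_of = np.repeat(np.arange(config.n_scas), config.zctas_per_sca)
    hosp_mask = (np.arange(n_z) % config.zctas_per_sca) < config.hospitals_per_sca
    hosp_idx = np.flatnonzero(hosp_mask)
    hospitals = pd.DataFrame(
        {
            "hospital_id": [f"H{i:04d}" for i in range(len(hosp_idx))],
            "zcta": zctas[hosp_idx],
            "sca_id": sca_of[hosp_idx],
        }
    )
    return zctas, sca_of, hosp_idx, hospitals


def generate_flows(config: SyntheticConfig):
    """Generate the flow table and the planted partition.

    One record per (year, origin ZCTA, hospital ZCTA); identical seeds give
    identical tables.  Returns ``(flows, labels, hospitals)``.
    """
    rng = _rngs(config, 3)[0]
    zctas, sca_of, hosp_idx, hospitals = _geography(config)
    n_z, n_h = len(zctas), len(hosp_idx)
    rates = np.where(
        sca_of[:, None] == sca_of[hosp_idx][None, :],
        config.within_rate,
        config.between_rate,
    )
    frames = []
    origin_rep = np.repeat(zctas, n_h)
    hosp_id_tile = np.tile(hospitals["hospital_id"].to_numpy(), n_z)
    hosp_z_tile = np.tile(zctas[hosp_idx], n_z)
    for year in config.years:
        counts = rng.poisson(rates).ravel()
        frames.append(
            pd.DataFrame(
                {
                    "year": year,
                    "origin_zcta": origin_rep,
                    "hospital_id": hosp_id_tile,
                    "hospital_zcta": hosp_z_tile,
                    "count": counts,
                }
            )
        )
    flows = pd.concat(frames, ignore_index=True)[FLOW_COLUMNS]
    labels = dict(zip(zctas, (int(s) for s in sca_of)))
    return flows, labels, hospitals


def generate_covariates(config: SyntheticConfig):
    """Draw SCA-level covariates once per SCA; expand to ZCTA tables.

    Every member ZCTA carries its SCA's value, with a positive integer
    population, so population-weighted aggregation is exact.  Returns
    ``(sca_covariates, zcta_covariates)``.
    """
    rng = _rngs(config, 3)[1]
    zctas, sca_of, _, _ = _geography(config)
    sca_cov = pd.DataFrame({"sca_id": np.arange(config.n_scas)})
    for name in COVARIATES:
        lo, hi = config.covariate_ranges[name]
        sca_cov[name] = rng.uniform(lo, hi, config.n_scas)
    zcta_cov = pd.DataFrame({"zcta": zctas, "sca_id": sca_of}).merge(sca_cov, on="sca_id")
    zcta_cov["population"] = rng.integers(1000, 50000, len(zctas))
    return sca_cov, zcta_cov.drop(columns="sca_id")


def generate_panel(
    config: SyntheticConfig,
    hospitals: pd.DataFrame,
    li_table: pd.DataFrame,
    sca_covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Hospital-year ERR panel from the planted linear model.

    ``li_table`` must hold the realized LI (columns year, sca_id, li)
    computed from the generated flows; the generator does not invent LI.
    """
    needed = {(y, s) for y in config.years for s in hospitals["sca_id"].unique()}
    have = set(zip(li_table["year"], li_table["sca_id"]))
    if not needed <= have:
        raise ValueError(f"li_table missing (year, sca) pairs: {sorted(needed - have)[:5]}")
    rng = _rngs(config, 3)[2]
    rows = hospitals.merge(pd.DataFrame({"year": list(config.years)}), how="cross")
    rows = rows.merge(li_table[["year", "sca_id", "li"]], on=["year", "sca_id"])
    rows = rows.merge(sca_covariates, on="sca_id")
    rows = rows.sort_values(["hospital_id", "year"]).reset_index(drop=True)
    n_h = len(hospitals)
    b = pd.Series(
        rng.normal(0.0, config.sigma_b, n_h),
        index=sorted(hospitals["hospital_id"]),
    )
    e = rng.normal(0.0, config.sigma_e, len(rows))
    rows["err"] = (
        config.beta0
        + config.beta_li * rows["li"]
        + config.beta_black * rows["pct_black"]
        + config.beta_poverty * rows["pct_poverty"]
        + config.beta_private * rows["pct_private"]
        + config.beta_hispanic * rows["pct_hispanic"]
        + rows["hospital_id"].map(b).to_numpy()
        + e
    )
    rows["penalized"] = rows["err"] > 1
    cols = [
        "hospital_id",
        "zcta",
        "year",
        "sca_id",
        "err",
        "penalized",
        "li",
    ] + COVARIATES
    return rows[cols]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the whole generator: flows -> realized LI -> panel.

    The LI table is computed by :func:`~sharedcare.localization.localization_index`
    on the generated flows under the planted partition.
    """
    flows, labels, hospitals = generate_flows(config)
    sca_cov, zcta_cov = generate_covariates(config)
    li_frames = []
    for year in config.years:
        part = Partition(year=year, algorithm="planted", labels=labels)
        li_frames.append(localization_index(flows, part))
    li_table = pd.concat(li_frames, ignore_index=True)
    panel = generate_panel(config, hospitals, li_table, sca_cov)
    crosswalk = pd.DataFrame({"zip": sorted(labels), "zcta": sorted(labels)})
    return SyntheticDataset(
        config=config,
        flows=flows,
        labels=labels,
        hospitals=hospitals,
        crosswalk=crosswalk,
        zcta_covariates=zcta_cov,
        sca_covariates=sca_cov,
        li_table=li_table,
        panel=panel,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the four input CSVs plus a JSON sidecar with the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "flows": outdir / "flows.csv",
        "err": outdir / "err_panel.csv",
        "covariates": outdir / "zcta_covariates.csv",
        "crosswalk": outdir / "crosswalk.csv",
        "truth": outdir / "truth.json",
    }
    dataset.flows.to_csv(paths["flows"], index=False)
    err = dataset.panel[["hospital_id", "zcta", "year", "err"]]
    err.to_csv(paths["err"], index=False)
    dataset.zcta_covariates.to_csv(paths["covariates"], index=False)
    dataset.crosswalk.to_csv(paths["crosswalk"], index=False)
    truth = dict(dataset.truth)
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(dataset.config).items()
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return {k: str(v) for k, v in paths.items()}
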