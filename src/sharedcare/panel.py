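"""Linking ERR records, SCA assignments, LI and covariates into the panel.

The longitudinal panel has one row per (hospital, year, algorithm) with
the hospital's ERR, the LI of its SCA that year, and the SCA-level
race/ethnicity and socioeconomic covariates.  Hospitals with fewer than
two observed years are excluded (repeated measures are required), rows in
SCAs with undefined LI are dropped with a logged count, and the
``penalized`` flag is ERR > 1 (strict inequality; boundary rows logged).
"""

from __future__ import annotations

import logging

import pandas as pd

from .detection import Partition
from .localization import assign_hospitals

logger = logging.getLogger(__name__)

__all__ = [
    "read_err",
    "aggregate_covariates",
    "hospital_assignments",
    "build_panel",
    "summarize_panel",
]

COVARIATES = ["pct_black", "pct_poverty", "pct_private", "pct_hispanic"]
PANEL_COLUMNS = [
    "hospital_id",
    "year",
    "algorithm",
    "sca_id",
    "err",
    "penalized",
    "li",
] + COVARIATES


def read_err(path) -> pd.DataFrame:
    """Read a hospital-year ERR CSV (hospital_id, zcta, year, err)."""
    df = pd.read_csv(path, dtype={"hospital_id": str, "zcta": str})
    needed = {"hospital_id", "zcta", "year", "err"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["zcta"] = df["zcta"].str.zfill(5)
    df["year"] = df["year"].astype(int)
    df["err"] = df["err"].astype(float)
    if (df["err"] <= 0).any():
        bad = df.index[df["err"] <= 0].tolist()
        raise ValueError(f"{path}: nonpositive ERR at rows {bad[:10]}")
    df["penalized"] = df["err"] > 1
    boundary = int((df["err"] == 1).sum())
    if boundary:
        logger.info("read_err: %d rows at the ERR=1 penalty boundary", boundary)
    return df[["hospital_id", "zcta", "year", "err", "penalized"]]


def aggregate_covariates(
    zcta_covariates: pd.DataFrame,
    partition: Partition,
    strict: bool = True,
    weighted: bool = True,
) -> pd.DataFrame:
    """Population-weighted mean of ZCTA proportions within each SCA.

    ``zcta_covariates`` needs columns zcta, population and the four
    proportions.  In lenient mode partition ZCTAs without covariates are
    dropped with a log message; ``weighted=False`` gives the plain mean.
    """
    needed = {"zcta", "population"} | set(COVARIATES)
    missing = needed - set(zcta_covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    df = zcta_covariates.copy()
    have = set(df["zcta"])
    lack = sorted(z for z in partition.labels if z not in have)
    if lack:
        if strict:
            raise ValueError(f"ZCTAs without covariates: {lack[:10]}")
        logger.warning("aggregate_covariates: %d ZCTAs without covariates", len(lack))
    df = df[df["zcta"].isin(partition.labels)]
    df["sca_id"] = df["zcta"].map(partition.labels)
    w = df["population"].astype(float) if weighted else pd.Series(1.0, index=df.index)
    df = df.assign(_w=w)
    out = []
    for sca, grp in df.groupby("sca_id"):
        row = {"year": partition.year, "algorithm": partition.algorithm, "sca_id": sca}
        wsum = grp["_w"].sum()
        for name in COVARIATES:
            row[name] = float((grp[name] * grp["_w"]).sum() / wsum)
        out.append(row)
    return pd.DataFrame(out)


def hospital_assignments(hospitals: pd.DataFrame, partitions) -> pd.DataFrame:
    """Hospital -> SCA per partition, as rows (hospital_id, year, algorithm, sca_id)."""
    zmap = dict(zip(hospitals["hospital_id"], hospitals["zcta"]))
    frames = []
    for part in partitions:
        assigned = assign_hospitals(zmap, part)
        frames.append(
            pd.DataFrame(
                {
                    "hospital_id": list(assigned),
                    "year": part.year,
                    "algorithm": part.algorithm,
                    "sca_id": list(assigned.values()),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_panel(
    err_records: pd.DataFrame,
    assignments: pd.DataFrame,
    sca_metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    min_years: int = 2,
    year_offset: int = 0,
) -> pd.DataFrame:
    """Inner-join ERR, assignments, LI and covariates into the panel.

    ``year_offset`` shifts ERR reporting years onto discharge years when
    the two calendars are not aligned (default 0, calendars as labelled).
    """
    err = err_records.copy()
    err["year"] = err["year"].astype(int) + year_offset
    m = err.merge(assignments, on=["hospital_id", "year"], how="inner")
    m = m.merge(
        sca_metrics[["year", "algorithm", "sca_id", "li"]],
        on=["year", "algorithm", "sca_id"],
        how="inner",
    )
    n_undef = int(m["li"].isna().sum())
    if n_undef:
        logger.warning("build_panel: dropping %d rows with undefined LI", n_undef)
        m = m.dropna(subset=["li"])
    cov_keys = [k for k in ("year", "algorithm", "sca_id") if k in covariates.columns]
    m = m.merge(covariates, on=cov_keys, how="inner")
    counts = m.groupby(["hospital_id", "algorithm"])["year"].transform("nunique")
    short = int((counts < min_years).sum())
    if short:
        logger.info("build_panel: excluding %d rows from hospitals with <%d years", short, min_years)
    m = m[counts >= min_years]
    if m.empty:
        raise ValueError("panel join produced no rows")
    if m.duplicated(["hospital_id", "year", "algorithm"]).any():
        raise ValueError("duplicate (hospital, year, algorithm) rows in panel")
    return m[PANEL_COLUMNS].sort_values(["algorithm", "hospital_id", "year"]).reset_index(drop=True)


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-year descriptives: n, % penalized, mean ERR, sample SD.

    SD is NaN for a single hospital-year (sample SD undefined).
    """
    if panel.empty:
        raise ValueError("empty panel")
    out = []
    for year, grp in panel.groupby("year"):
        out.append(
            {
                "year": year,
                "n": len(grp),
                "pct_penalized": float((grp["err"] > 1).mean()),
                "mean_err": float(grp["err"].mean()),
                "sd_err": float(grp["err"].std(ddof=1)) if len(grp) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(out)
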