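"""Quartile stratification and bootstrap CIs for medians and shares.

Hospitals are stratified by quartiles of the LI (or of the %Black of
their SCA); per quartile the median ERR and the share of penalized
hospitals (ERR > 1) are reported with percentile-bootstrap confidence
intervals (default 10,000 resamples with replacement at the 95% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "quartile_assign",
    "bootstrap_ci",
    "bootstrap_median",
    "pct_penalized",
    "quartile_table",
]

QUARTILES = ["Q1", "Q2", "Q3", "Q4"]


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 10_000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


def quartile_assign(values):
    """Assign Q1..Q4 by the 25/50/75th percentile cutpoints.

    Cutpoints use linear interpolation.  Intervals are closed above, so a
    value tied with a cutpoint falls in the lower quartile: Q1 = x <= c25,
    Q2 = (c25, c50], Q3 = (c50, c75], Q4 = x > c75.  Returns
    ``(labels, cutpoints)``; all-equal input is an error (degenerate
    quartiles), and at least 4 distinct values are required.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 4:
        raise ValueError("need at least 4 distinct values for quartiles")
    cuts = np.percentile(values, [25, 50, 75])
    idx = np.searchsorted(cuts, values, side="left")
    labels = np.array(QUARTILES)[idx]
    return labels, tuple(float(c) for c in cuts)


def bootstrap_ci(values, statistic, config: BootstrapConfig, clusters=None):
    """Percentile-bootstrap CI of ``statistic`` over seeded resamples.

    ``statistic`` maps a 2-d array (n_boot, n) to one value per row.  With
    ``clusters`` given, whole clusters are resampled with replacement
    (cluster bootstrap) instead of individual rows.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(config.seed)
    if clusters is None:
        idx = rng.integers(0, len(values), size=(config.n_boot, len(values)))
        stats_b = statistic(values[idx])
    else:
        clusters = np.asarray(clusters)
        uniq = pd.unique(clusters)
        members = [np.flatnonzero(clusters == c) for c in uniq]
        stats_b = np.empty(config.n_boot)
        for b in range(config.n_boot):
            take = rng.integers(0, len(uniq), size=len(uniq))
            rows = np.concatenate([members[t] for t in take])
            stats_b[b] = statistic(values[rows][None, :])[0]
    lo, hi = np.percentile(
        stats_b, [100 * (1 - config.level) / 2, 100 * (0.5 + config.level / 2)]
    )
    return float(lo), float(hi)


def bootstrap_median(values, config: BootstrapConfig, clusters=None):
    """Sample median with its percentile-bootstrap CI."""
    values = np.asarray(values, dtype=float)
    point = float(np.median(values))
    lo, hi = bootstrap_ci(values, lambda m: np.median(m, axis=1), config, clusters)
    return point, (lo, hi)


def pct_penalized(values, config: BootstrapConfig, clusters=None):
    """Share of ERRs above 1 with its percentile-bootstrap CI."""
    values = np.asarray(values, dtype=float)
    point = float(np.mean(values > 1))
    lo, hi = bootstrap_ci(values, lambda m: np.mean(m > 1, axis=1), config, clusters)
    return point, (lo, hi)


def quartile_table(
    panel: pd.DataFrame,
    by: str = "li",
    config: BootstrapConfig | None = None,
    per_year: bool = True,
    cluster_bootstrap: bool = False,
) -> pd.DataFrame:
    """Median ERR and % penalized per quartile of ``by`` (li or pct_black).

    Quartiles are computed within each year by default (pooled otherwise).
    Resampling is over hospital-year rows unless ``cluster_bootstrap``,
    which resamples hospitals.
    """
    if by not in panel.columns:
        raise ValueError(f"stratifier {by!r} not in panel")
    config = config or BootstrapConfig()
    groups = panel.groupby("year") if per_year else [(None, panel)]
    rows = []
    for year, grp in groups:
        labels, _ = quartile_assign(grp[by].to_numpy())
        for q in QUARTILES:
            stratum = grp[labels == q]
            errs = stratum["err"].to_numpy()
            if len(errs) == 0:
                continue
            clus = stratum["hospital_id"].to_numpy() if cluster_bootstrap else None
            med, med_ci = bootstrap_median(errs, config, clus)
            pen, pen_ci = pct_penalized(errs, config, clus)
            rows.append(
                {
                    "year": year,
                    "stratifier": by,
                    "quartile": q,
                    "n": len(errs),
                    "median_err": med,
                    "median_err_lo": med_ci[0],
                    "median_err_hi": med_ci[1],
                    "pct_penalized": pen,
                    "pct_penalized_lo": pen_ci[0],
                    "pct_penalized_hi": pen_ci[1],
                }
            )
    return pd.DataFrame(rows)
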