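"""Counterfactual ERR predictions under localization-index shifts.

Year-over-year LI differences observed in the panel define an empirical
grid of plausible LI changes: the 25/50/75th percentiles of the negative
differences (-q3 <= -q2 <= -q1 < 0) and of the positive differences
(0 < +q1 <= +q2 <= +q3).  The fitted adjusted GEE then predicts every
hospital-year's ERR after each shift; because the model is linear in LI,
each prediction moves by exactly ``beta_li * shift``, so the median
predicted ERR at shift s equals the baseline median plus ``beta_li * s``
(monotone affine transform).  Predictions are summarized within quartiles
of %Black of the SCA (median predicted ERR and share predicted > 1, with
percentile-bootstrap CIs).

Predictions are marginal (population-level) linear predictions; a GEE has
no cluster-specific effects to condition on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gee import GEEFit
from .stratify import QUARTILES, BootstrapConfig, bootstrap_ci, quartile_assign

__all__ = [
    "LIChangeQuantiles",
    "li_change_quantiles",
    "predict_shifted",
    "shifted_median",
    "counterfactual_table",
]


@dataclass(frozen=True)
class LIChangeQuantiles:
    """Percentiles of observed year-over-year LI differences by sign."""

    negative: tuple  # (-q3, -q2, -q1): 25/50/75th pct of negative diffs
    positive: tuple  # (+q1, +q2, +q3): 25/50/75th pct of positive diffs

    def grid(self) -> dict:
        nq3, nq2, nq1 = self.negative
        pq1, pq2, pq3 = self.positive
        return {
            "-q3": nq3,
            "-q2": nq2,
            "-q1": nq1,
            "0": 0.0,
            "+q1": pq1,
            "+q2": pq2,
            "+q3": pq3,
        }


def li_change_quantiles(panel: pd.DataFrame, algorithm: str | None = None) -> LIChangeQuantiles:
    """25/50/75th percentiles of consecutive-year LI differences by sign.

    Differences are taken per hospital between consecutive calendar years,
    pooled, and split by sign; exact zeros belong to neither group.
    Percentiles use Hazen (type-5) linear interpolation.  An empty sign
    group is an error naming the group.
    """
    df = panel
    if algorithm is not None:
        df = df[df["algorithm"] == algorithm]
    keys = ["algorithm", "hospital_id"] if "algorithm" in df.columns else ["hospital_id"]
    df = df.sort_values(keys + ["year"])
    diffs = []
    for _, grp in df.groupby(keys):
        years = grp["year"].to_numpy()
        li = grp["li"].to_numpy(float)
        step = np.diff(years)
        d = np.diff(li)[step == 1]
        diffs.append(d)
    pooled = np.concatenate(diffs) if diffs else np.array([])
    neg = pooled[pooled < 0]
    pos = pooled[pooled > 0]
    if len(neg) == 0:
        raise ValueError("no negative LI differences in panel")
    if len(pos) == 0:
        raise ValueError("no positive LI differences in panel")
    nq = np.percentile(neg, [25, 50, 75], method="hazen")
    pq = np.percentile(pos, [25, 50, 75], method="hazen")
    return LIChangeQuantiles(
        negative=(float(nq[0]), float(nq[1]), float(nq[2])),
        positive=(float(pq[0]), float(pq[1]), float(pq[2])),
    )


def predict_shifted(fit: GEEFit, panel: pd.DataFrame, shift: float) -> np.ndarray:
    """Predicted ERR per panel row with LI shifted by ``shift``.

    Linear predictor at (li + shift, other covariates unchanged); equal to
    the baseline prediction plus beta_li * shift for every row.
    """
    X = np.column_stack(
        [np.ones(len(panel))]
        + [
            panel[name].to_numpy(float) + (shift if name == "li" else 0.0)
            for name in fit.names[1:]
        ]
    )
    return X @ fit.beta


def shifted_median(baseline_median: float, beta_li: float, shift: float) -> float:
    """Median predicted ERR after an LI shift (affine-model identity).

    Because predictions move by exactly ``beta_li * shift``, the median
    moves by the same amount — this identity lets published baseline
    medians and coefficients be combined without refitting.
    """
    return baseline_median + beta_li * shift


def counterfactual_table(
    fit: GEEFit,
    panel: pd.DataFrame,
    quantiles: LIChangeQuantiles,
    boot: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Stratum x shift grid of median predicted ERR and % predicted > 1.

    Strata are quartiles of %Black with boundaries computed over SCA-year
    rows (each SCA counted once per year) and applied to hospital rows.
    Bootstrap resamples the shifted predictions within each stratum.  An
    empty stratum yields a flagged all-NaN row rather than being dropped.
    """
    boot = boot or BootstrapConfig()
    if "li" not in fit.names:
        raise ValueError("fit does not include an LI coefficient")
    beta_li = float(fit.params()["li"])
    sca_rows = panel.drop_duplicates(["sca_id", "year"])
    _, cuts = quartile_assign(sca_rows["pct_black"].to_numpy())
    idx = np.searchsorted(np.asarray(cuts), panel["pct_black"].to_numpy(), side="left")
    strata = np.array(QUARTILES)[idx]
    baseline = predict_shifted(fit, panel, 0.0)
    rows = []
    for q in QUARTILES:
        mask = strata == q
        for name, shift in quantiles.grid().items():
            if not mask.any():
                rows.append(
                    {
                        "black_quartile": q,
                        "shift_label": name,
                        "shift": shift,
                        "n": 0,
                        "empty": True,
                        "median_err": np.nan,
                        "median_err_lo": np.nan,
                        "median_err_hi": np.nan,
                        "pct_penalized": np.nan,
                        "pct_penalized_lo": np.nan,
                        "pct_penalized_hi": np.nan,
                    }
                )
                continue
            pred = baseline[mask] + beta_li * shift
            med = float(np.median(pred))
            med_lo, med_hi = bootstrap_ci(pred, lambda m: np.median(m, axis=1), boot)
            pen = float(np.mean(pred > 1))
            pen_lo, pen_hi = bootstrap_ci(pred, lambda m: np.mean(m > 1, axis=1), boot)
            rows.append(
                {
                    "black_quartile": q,
                    "shift_label": name,
                    "shift": shift,
                    "n": int(mask.sum()),
                    "empty": False,
                    "median_err": med,
                    "median_err_lo": med_lo,
                    "median_err_hi": med_hi,
                    "pct_penalized": pen,
                    "pct_penalized_lo": pen_lo,
                    "pct_penalized_hi": pen_hi,
                }
            )
    return pd.DataFrame(rows)
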