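"""Step 7 — quartile-stratified ERR summaries with bootstrap CIs.

Median ERR and % penalized per year within quartiles of the LI and of
%Black (10,000 bootstrap resamples), written to
results/quartile_summaries.csv.  Uses the Louvain panel.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

import sharedcare as sc

cfg = runpy.run_path(Path(__file__).parent / "00_config.py")


def main() -> None:
    panel = pd.read_csv(cfg["RESULTS"] / "panel.csv", dtype={"hospital_id": str})
    panel = panel[panel["algorithm"] == "louvain"]
    boot = sc.BootstrapConfig(n_boot=10_000, seed=cfg["SEED"])
    tables = []
    for by in ("li", "pct_black"):
        tables.append(sc.quartile_table(panel, by=by, config=boot))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(cfg["RESULTS"] / "quartile_summaries.csv", index=False)
    latest = table[table["year"] == table["year"].max()]
    for by in ("li", "pct_black"):
        sub = latest[latest["stratifier"] == by]
        print(f"\n{table['year'].max()} by {by} quartile:")
        print(sub[["quartile", "n", "median_err", "median_err_lo", "median_err_hi",
                   "pct_penalized"]].round(3).to_string(index=False))
    q1 = latest[(latest["stratifier"] == "li") & (latest["quartile"] == "Q1")]
    q4 = latest[(latest["stratifier"] == "li") & (latest["quartile"] == "Q4")]
    print(f"\nlowest-LI quartile median ERR {q1['median_err'].iloc[0]:.3f} vs "
          f"highest-LI {q4['median_err'].iloc[0]:.3f}")
    print(f"wrote {cfg['RESULTS'] / 'quartile_summaries.csv'}")


if __name__ == "__main__":
    sys.exit(main())
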