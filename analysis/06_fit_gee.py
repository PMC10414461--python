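"""Step 6 — exchangeable Gaussian GEE of ERR on LI and covariates.

Fits unadjusted (LI only) and adjusted models separately per detection
algorithm, prints coefficient tables, compares against the planted
coefficients, and writes results/gee_fits.json.
"""

import json
import runpy
import sys
from pathlib import Path

import pandas as pd

import sharedcare as sc

cfg = runpy.run_path(Path(__file__).parent / "00_config.py")


def main() -> None:
    panel = pd.read_csv(cfg["RESULTS"] / "panel.csv", dtype={"hospital_id": str})
    truth = json.loads((cfg["DATA"] / "truth.json").read_text())["beta"]
    fits = {}
    for algorithm, sub in panel.groupby("algorithm"):
        fits[algorithm] = {}
        for model, covs in (("unadjusted", sc.UNADJUSTED), ("adjusted", sc.ADJUSTED)):
            fit = sc.fit_gee(sub, covariates=covs)
            fits[algorithm][model] = fit.to_dict()
            if model == "adjusted":
                print(f"\n== {algorithm} (adjusted, alpha={fit.alpha:.3f}, "
                      f"{fit.n_clusters} hospitals) ==")
                table = sc.wald_inference(fit)
                table["planted"] = [
                    truth["intercept"], truth["li"], truth["pct_black"],
                    truth["pct_poverty"], truth["pct_private"], truth["pct_hispanic"],
                ]
                table["covered"] = (table["ci_low"] <= table["planted"]) & (
                    table["planted"] <= table["ci_high"]
                )
                print(table.round(4).to_string(index=False))
    out = cfg["RESULTS"] / "gee_fits.json"
    out.write_text(json.dumps(fits, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    sys.exit(main())
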