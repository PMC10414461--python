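"""Step 5 — link ERR, SCA assignments, LI and covariates into the panel.

Produces one stacked panel (algorithm column distinguishes the three SCA
delineations) at results/panel.csv and prints per-year descriptives.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

import sharedcare as sc

cfg = runpy.run_path(Path(__file__).parent / "00_config.py")


def main() -> None:
    data = cfg["DATA"]
    err = sc.read_err(data / "err_panel.csv")
    zcov = pd.read_csv(data / "zcta_covariates.csv", dtype={"zcta": str})
    hospitals = err[["hospital_id", "zcta"]].drop_duplicates()

    partitions = []
    for path in sorted(cfg["PARTITIONS"].glob("*_*.csv")):
        algorithm, year = path.stem.rsplit("_", 1)
        pdf = pd.read_csv(path, dtype={"zcta": str})
        partitions.append(
            sc.Partition(
                year=int(year),
                algorithm=algorithm,
                labels=dict(zip(pdf["zcta"].str.zfill(5), pdf["sca_id"].astype(int))),
            )
        )
    metrics = pd.read_csv(cfg["RESULTS"] / "li_metrics.csv")
    covariates = pd.concat(
        [sc.aggregate_covariates(zcov, p) for p in partitions], ignore_index=True
    )
    assignments = sc.hospital_assignments(hospitals, partitions)
    panel = sc.build_panel(err, assignments, metrics, covariates)
    panel.to_csv(cfg["RESULTS"] / "panel.csv", index=False)
    print(f"panel: {len(panel)} hospital-year rows, "
          f"{panel['hospital_id'].nunique()} hospitals, "
          f"{panel['algorithm'].nunique()} algorithms")
    print(sc.summarize_panel(panel[panel['algorithm'] == 'louvain']).round(4).to_string(index=False))
    print(f"wrote {cfg['RESULTS'] / 'panel.csv'}")


if __name__ == "__main__":
    sys.exit(main())
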