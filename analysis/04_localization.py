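"""Step 4 — localization index per SCA-year.

Computes the LI for every (algorithm, year) partition and writes the
stacked metrics table to results/li_metrics.csv.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

import sharedcare as sc

cfg = runpy.run_path(Path(__file__).parent / "00_config.py")


def main() -> None:
    flows = sc.read_flows(cfg["DATA"] / "flows.csv")
    frames = []
    for path in sorted(cfg["PARTITIONS"].glob("*_*.csv")):
        algorithm, year = path.stem.rsplit("_", 1)
        pdf = pd.read_csv(path, dtype={"zcta": str})
        part = sc.Partition(
            year=int(year),
            algorithm=algorithm,
            labels=dict(zip(pdf["zcta"].str.zfill(5), pdf["sca_id"].astype(int))),
        )
        frames.append(sc.localization_index(flows, part))
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(cfg["RESULTS"] / "li_metrics.csv", index=False)
    summary = metrics.groupby("algorithm")["li"].agg(["mean", "std", "min", "max"])
    print("localization index by algorithm:")
    print(summary.round(3).to_string())
    print(f"wrote {cfg['RESULTS'] / 'li_metrics.csv'}")


if __name__ == "__main__":
    sys.exit(main())
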