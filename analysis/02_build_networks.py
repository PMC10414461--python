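"""Step 2 — build the yearly discharge networks.

Reads the flow CSV back through the crosswalk (exercising the same path a
real OSHPD extract would take) and writes one GraphML per year plus a JSON
summary under results/networks/.
"""

import runpy
import sys
from pathlib import Path

import sharedcare as sc

cfg = runpy.run_path(Path(__file__).parent / "00_config.py")


def main() -> None:
    data, out = cfg["DATA"], cfg["NETWORKS"]
    out.mkdir(parents=True, exist_ok=True)
    flows = sc.read_flows(data / "flows.csv")
    xwalk = sc.read_crosswalk(data / "crosswalk.csv")
    flows = sc.apply_crosswalk(flows, xwalk)
    for year in sorted(flows["year"].unique()):
        G = sc.build_network(flows, int(year))
        sc.write_network(G, out / f"network_{year}.graphml")
        s = sc.flows.network_summary(G)
        print(f"{year}: {s['nodes']} ZCTAs, {s['edges']} links, "
              f"{s['total_weight']} discharges")
    print(f"wrote networks to {out}")


if __name__ == "__main__":
    sys.exit(main())
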