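"""Reading discharge flow tables and building yearly ZCTA networks.

The raw input emulates OSHPD Patient Origin/Market Share extracts: one row
per (year, patient zip/ZCTA, hospital, hospital zip/ZCTA) with the
aggregated number of emergency-department discharges.  Zip codes are mapped
to ZCTAs through a many-to-one crosswalk, and each year becomes one
weighted undirected network whose nodes are ZCTAs and whose edge weights
are total discharges (a hospital in the patients' own ZCTA contributes a
self-loop).  Discharge totals are conserved at every stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FLOW_COLUMNS",
    "read_flows",
    "write_flows",
    "read_crosswalk",
    "apply_crosswalk",
    "build_network",
    "write_network",
    "read_network",
    "network_summary",
]

FLOW_COLUMNS = ["year", "origin_zcta", "hospital_id", "hospital_zcta", "count"]

# accepted aliases for pre-crosswalk (zip-coded) inputs
_ALIASES = {"origin_zip": "origin_zcta", "hospital_zip": "hospital_zcta"}


def _pad(codes: pd.Series) -> pd.Series:
    """Zero-pad geographic codes to 5 characters (leading-zero CSV loss)."""
    return codes.astype(str).str.strip().str.zfill(5)


def validate_flows(flows: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FLOW_COLUMNS if c not in flows.columns]
    if missing:
        raise ValueError(f"flow table missing columns: {missing}")
    bad = flows.index[flows["count"] < 0].tolist()
    if bad:
        raise ValueError(f"negative discharge counts at rows {bad[:10]}")
    return flows


def read_flows(path) -> pd.DataFrame:
    """Read a flow CSV; malformed rows are reported with line numbers.

    Geographic codes are read as strings and zero-padded to 5 characters.
    """
    df = pd.read_csv(path, dtype=str)
    df = df.rename(columns=_ALIASES)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in ("year", "count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        # +2: header line plus 1-based numbering
        bad_lines += [(int(i) + 2, col) for i in df.index[numeric.isna()]]
        df[col] = numeric
    if bad_lines:
        raise ValueError(f"{path}: malformed rows (line, column): {bad_lines[:10]}")
    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative counts on lines {[int(i) + 2 for i in neg]}")
    df["origin_zcta"] = _pad(df["origin_zcta"])
    df["hospital_zcta"] = _pad(df["hospital_zcta"])
    return df[FLOW_COLUMNS]


def write_flows(flows: pd.DataFrame, path) -> None:
    validate_flows(flows)[FLOW_COLUMNS].to_csv(path, index=False)


def read_crosswalk(path) -> dict:
    """Read a zip -> ZCTA crosswalk CSV (columns ``zip``, ``zcta``)."""
    df = pd.read_csv(path, dtype=str)
    if not {"zip", "zcta"} <= set(df.columns):
        raise ValueError(f"{path}: crosswalk needs 'zip' and 'zcta' columns")
    zips = _pad(df["zip"])
    if zips.duplicated().any():
        dupes = sorted(zips[zips.duplicated()].unique())
        raise ValueError(f"{path}: zips mapped more than once: {dupes[:10]}")
    return dict(zip(zips, _pad(df["zcta"])))


def apply_crosswalk(flows: pd.DataFrame, crosswalk: dict, strict: bool = True) -> pd.DataFrame:
    """Replace zip codes by ZCTAs and aggregate duplicate records.

    In strict mode (default) any zip absent from the crosswalk is an error;
    in lenient mode those records are dropped and the dropped discharge
    count is logged.  Total discharges are conserved (strict mode).
    """
    validate_flows(flows)
    df = flows.copy()
    df["origin_zcta"] = _pad(df["origin_zcta"])
    df["hospital_zcta"] = _pad(df["hospital_zcta"])
    unknown = set()
    for col in ("origin_zcta", "hospital_zcta"):
        mapped = df[col].map(crosswalk)
        unknown |= set(df.loc[mapped.isna(), col])
        df[col] = mapped
    if unknown:
        if strict:
            raise ValueError(f"zips not in crosswalk: {sorted(unknown)}")
        before = int(flows["count"].sum())
        df = df.dropna(subset=["origin_zcta", "hospital_zcta"])
        logger.warning(
            "crosswalk: dropped %d discharges from %d unknown zips",
            before - int(df["count"].sum()),
            len(unknown),
        )
    out = (
        df.groupby(["year", "origin_zcta", "hospital_id", "hospital_zcta"], as_index=False)[
            "count"
        ]
        .sum()
        .sort_values(FLOW_COLUMNS[:4])
        .reset_index(drop=True)
    )
    return out[FLOW_COLUMNS]


def build_network(flows: pd.DataFrame, year: int, directed: bool = False) -> nx.Graph:
    """Build the yearly discharge network.

    Undirected by default: flow is aggregated over direction, and a
    discharge to a hospital in the patients' own ZCTA becomes a self-loop.
    Zero-weight pairs contribute nodes but no edges.  Shuffling the input
    records leaves the network unchanged.
    """
    validate_flows(flows)
    sub = flows[flows["year"] == year]
    if sub.empty:
        raise ValueError(f"no flow records for year {year}")
    G = nx.DiGraph() if directed else nx.Graph()
    G.graph["year"] = int(year)
    G.add_nodes_from(sub["origin_zcta"])
    G.add_nodes_from(sub["hospital_zcta"])
    if directed:
        pairs = sub.groupby(["origin_zcta", "hospital_zcta"])["count"].sum()
    else:
        key = pd.DataFrame(
            {
                "u": sub[["origin_zcta", "hospital_zcta"]].min(axis=1),
                "v": sub[["origin_zcta", "hospital_zcta"]].max(axis=1),
                "count": sub["count"].to_numpy(),
            }
        )
        pairs = key.groupby(["u", "v"])["count"].sum()
    for (u, v), w in pairs.items():
        if w > 0:
            G.add_edge(u, v, weight=int(w))
    return G


def network_summary(G: nx.Graph) -> dict:
    return {
        "year": G.graph.get("year"),
        "nodes": G.number_of_nodes(),
        "edges": G.number_of_edges(),
        "total_weight": int(G.size(weight="weight")),
    }


def write_network(G: nx.Graph, path) -> None:
    """Write GraphML plus a JSON sidecar with node/edge/weight totals."""
    path = Path(path)
    nx.write_graphml(G, path)
    path.with_suffix(".json").write_text(json.dumps(network_summary(G), indent=2))


def read_network(path) -> nx.Graph:
    G = nx.read_graphml(path)
    if "year" in G.graph:
        G.graph["year"] = int(G.graph["year"])
    return G
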