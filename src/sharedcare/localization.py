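"""Localization index (LI) and hospital-to-SCA assignment.

The LI of an SCA is the fraction of its residents' discharges that occur
at hospitals inside the same SCA: li(s) = internal(s) / resident(s).  A
higher LI indicates localized care coordination (patients receive care
where they live).  An SCA whose residents record no discharges carries an
undefined LI (NaN) and is excluded downstream.

Residence-based LI (denominator = discharges of the SCA's residents) is
the classical convention and the default; an admission-based variant
(denominator = discharges at the SCA's hospitals) is also available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import Partition
from .flows import validate_flows

__all__ = ["localization_index", "assign_hospitals"]

METRIC_COLUMNS = [
    "year",
    "algorithm",
    "sca_id",
    "li",
    "resident_discharges",
    "internal_discharges",
    "n_zctas",
    "n_hospitals",
]


def localization_index(
    flows: pd.DataFrame,
    partition: Partition,
    direction: str = "residence",
) -> pd.DataFrame:
    """Per-SCA localization index and flow counts for the partition's year.

    Every ZCTA appearing in the year's flows must be labelled by the
    partition.  SCAs present in the partition but without any (resident,
    for the default direction) discharges get li = NaN.
    """
    if direction not in {"residence", "admission"}:
        raise ValueError("direction must be 'residence' or 'admission'")
    validate_flows(flows)
    sub = flows[flows["year"] == partition.year].copy()
    labels = partition.labels
    present = set(sub["origin_zcta"]) | set(sub["hospital_zcta"])
    missing = sorted(z for z in present if z not in labels)
    if missing:
        raise ValueError(f"ZCTAs absent from partition: {missing[:10]}")
    sub["origin_sca"] = sub["origin_zcta"].map(labels)
    sub["hospital_sca"] = sub["hospital_zcta"].map(labels)
    internal = sub["origin_sca"] == sub["hospital_sca"]

    denom_key = "origin_sca" if direction == "residence" else "hospital_sca"
    totals = sub.groupby(denom_key)["count"].sum()
    internals = sub[internal].groupby(denom_key)["count"].sum()

    sca_ids = sorted(set(labels.values()))
    n_zctas = pd.Series(list(labels.values())).value_counts()
    hosp = sub[["hospital_id", "hospital_sca"]].drop_duplicates()
    n_hospitals = hosp.groupby("hospital_sca")["hospital_id"].nunique()

    rows = []
    for s in sca_ids:
        resident = int(totals.get(s, 0))
        inside = int(internals.get(s, 0))
        rows.append(
            {
                "year": partition.year,
                "algorithm": partition.algorithm,
                "sca_id": s,
                "li": inside / resident if resident > 0 else np.nan,
                "resident_discharges": resident,
                "internal_discharges": inside,
                "n_zctas": int(n_zctas.get(s, 0)),
                "n_hospitals": int(n_hospitals.get(s, 0)),
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def assign_hospitals(
    hospital_zctas: dict,
    partition: Partition,
    strict: bool = True,
) -> dict:
    """Map each hospital to the SCA of its ZCTA.

    ``hospital_zctas`` maps hospital_id -> ZCTA.  In strict mode a hospital
    whose ZCTA is absent from the partition is an error; in lenient mode it
    is dropped (the caller sees the smaller mapping).
    """
    out, dropped = {}, []
    for hid, zcta in hospital_zctas.items():
        if zcta in partition.labels:
            out[hid] = partition.labels[zcta]
        else:
            dropped.append(hid)
    if dropped and strict:
        raise ValueError(f"hospitals with ZCTA outside partition: {sorted(dropped)}")
    return out
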