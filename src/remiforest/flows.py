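"""Migration and remittance flow networks between origin sites and cities.

Aggregates migrants by destination city (and province), classifies
origin-destination distances into log10-km bins (short / medium / long),
and compares migrant volume and remittance intensity across bins with
one-way ANOVA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DISTANCE_BIN_EDGES, DISTANCE_BIN_LABELS


def assign_distance_bin(
    distance_km, edges=DISTANCE_BIN_EDGES, labels=DISTANCE_BIN_LABELS
):
    """Half-open log10-km bins [lower, upper); out-of-range → NaN label."""
    d = np.asarray(distance_km, float)
    with np.errstate(divide="ignore"):
        logd = np.log10(d)
    out = np.full(d.shape, None, dtype=object)
    for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
        out[(logd >= lo) & (logd < hi)] = lab
    # the top edge belongs to the last bin, matching a closed upper range
    out[logd == edges[-1]] = labels[-1]
    return out


def build_flow_table(
    migrants: pd.DataFrame, destinations: pd.DataFrame
) -> dict:
    """City-level flow records plus province aggregates and summary shares.

    Rows missing a distance are kept in the table but flagged and excluded
    from distance-bin tests.
    """
    need = {"destination_id", "site_id"}
    if not need <= set(migrants.columns):
        raise KeyError(f"migrants table needs columns {sorted(need)}")
    dest = destinations.set_index(["site_id", "destination_id"])

    grp = migrants.groupby(["site_id", "destination_id"])
    flows = grp.agg(
        n_migrants=("migrant_id", "size"),
        n_senders=("sent_remittance", "sum"),
        remittance_total=("remittance_amount_yuan", "sum"),
    ).reset_index()
    flows["remittance_per_sender"] = np.where(
        flows["n_senders"] > 0,
        flows["remittance_total"] / flows["n_senders"].replace(0, np.nan),
        np.nan,
    )
    flows["remittance_per_migrant"] = (
        flows["remittance_total"] / flows["n_migrants"]
    )
    idx = list(zip(flows["site_id"], flows["destination_id"]))
    flows["distance_km"] = [
        float(dest.loc[k, "distance_km"]) if k in dest.index else np.nan
        for k in idx
    ]
    flows["province_id"] = [
        dest.loc[k, "province_id"] if k in dest.index else None for k in idx
    ]
    flows["missing_distance"] = ~np.isfinite(flows["distance_km"])
    with np.errstate(divide="ignore"):
        flows["log10_distance"] = np.log10(flows["distance_km"])
    flows["bin"] = assign_distance_bin(flows["distance_km"])

    cities = flows.groupby("destination_id").agg(
        n_migrants=("n_migrants", "sum"), n_senders=("n_senders", "sum")
    )
    share_cities = float((cities["n_senders"] > 0).mean()) * 100.0
    provinces = (
        flows.dropna(subset=["province_id"])
        .groupby("province_id")
        .agg(
            n_migrants=("n_migrants", "sum"),
            n_senders=("n_senders", "sum"),
            remittance_total=("remittance_total", "sum"),
        )
    )
    share_prov = float((provinces["n_senders"] > 0).mean()) * 100.0
    return {
        "flows": flows,
        "provinces": provinces.reset_index(),
        "n_cities": int(cities.shape[0]),
        "share_cities_with_remittance_pct": share_cities,
        "n_provinces": int(provinces.shape[0]),
        "share_provinces_with_remittance_pct": share_prov,
    }


def distance_bin_tests(
    flows: pd.DataFrame,
    attributes=("n_migrants", "remittance_total", "remittance_per_sender"),
    labels=DISTANCE_BIN_LABELS,
) -> pd.DataFrame:
    """One-way ANOVA of each flow attribute across distance bins."""
    usable = flows[flows["bin"].notna()]
    rows = []
    for attr in attributes:
        groups = []
        for lab in labels:
            vals = usable.loc[usable["bin"] == lab, attr].dropna().to_numpy()
            if len(vals) == 0:
                warnings.warn(f"distance bin {lab!r} empty for {attr}; dropped")
                continue
            groups.append(vals)
        if len(groups) < 2:
            raise ValueError(f"fewer than 2 non-empty bins for {attr}")
        if all(len(g) < 2 for g in groups):
            raise ValueError(f"all bins degenerate for {attr}")
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]) and np.ptp(
            np.concatenate(groups)
        ) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        rows.append(
            {
                "attribute": attr,
                "F": float(f_stat),
                "p_value": float(p),
                "n_bins": len(groups),
                "n_flows": int(sum(len(g) for g in groups)),
            }
        )
    return pd.DataFrame(rows)
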