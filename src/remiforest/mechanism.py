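"""Forest-dependence mechanism indicators and tests.

The hypothesised mechanism is that remittance substitutes for natural
capital: households receiving remittance use less fuelwood, climb the
energy ladder toward modern fuels, and spend less on extracting forest
resources. Indicators are compared between remittance groups with weighted
t-tests, a χ² test on the 3-stage energy-ladder composition, and OLS
slopes on log10 remittance amount.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.weightstats import DescrStatsW

from .constants import FUELWOOD_PRICE_YUAN_PER_KG

# default stage boundaries on the fuelwood share (survey-style energy ladder)
LADDER_BOUNDS = (0.4, 0.6)

# indicators restricted to one site in the survey design
SITE_RESTRICTED = {"livestock": "by_site", "extraction_cost_yuan": ["TTZ"]}

CONTINUOUS_INDICATORS = [
    "fuelwood_share",
    "fuelwood_share_cooking",
    "livestock",
    "extraction_cost_yuan",
]


def fuelwood_share(
    fuelwood_value: float | np.ndarray, gas_cost: float | np.ndarray
):
    """Share of fuelwood value in fuelwood + gas spending; NaN if both 0."""
    fv = np.asarray(fuelwood_value, float)
    gc = np.asarray(gas_cost, float)
    if np.any(fv < 0) or np.any(gc < 0):
        raise ValueError("fuelwood value and gas cost must be non-negative")
    total = fv + gc
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, fv / np.where(total > 0, total, 1.0), np.nan)
    return share if share.ndim else float(share)


def fuelwood_value(kg: float | np.ndarray) -> float | np.ndarray:
    return FUELWOOD_PRICE_YUAN_PER_KG * np.asarray(kg, float)


def ladder_stage(share, bounds=LADDER_BOUNDS):
    """1 = fuelwood/coal main, 2 = half-half, 3 = modern fuels main."""
    share = np.asarray(share, float)
    return np.where(share > bounds[1], 1, np.where(share >= bounds[0], 2, 3))


def _effective_n(w: np.ndarray) -> float:
    """Kish effective sample size of a weight vector."""
    return float(w.sum() ** 2 / np.sum(w**2))


def weighted_ladder_chi2(
    stages: np.ndarray, groups: np.ndarray, weights: np.ndarray
):
    """χ² test on the energy-ladder composition between two groups.

    Weighted stage shares are scaled to each group's effective sample size
    and rounded before the χ² contingency test. Stages empty in both
    groups are dropped with a warning.
    """
    stages = np.asarray(stages)
    levels = np.unique(stages)
    table = []
    for g in (1, 0):
        m = groups == g
        w = weights[m]
        n_eff = _effective_n(w)
        shares = np.array(
            [np.sum(w[stages[m] == s]) / w.sum() for s in levels]
        )
        table.append(np.round(shares * n_eff))
    table = np.asarray(table)
    empty = table.sum(axis=0) == 0
    if empty.any():
        warnings.warn(
            f"dropping ladder stage(s) empty in both groups: {levels[empty]}"
        )
        table = table[:, ~empty]
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        return 0.0, 1.0, table
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p), table


def compare_groups(
    energy: pd.DataFrame,
    households: pd.DataFrame,
    weighted: bool = True,
    indicators: list[str] | None = None,
    site_restricted: dict | None = None,
) -> pd.DataFrame:
    """Mechanism-indicator comparison between remittance groups.

    For each indicator: weighted means per group, a Welch t-test on the
    difference, and the weighted OLS coefficient of the indicator on log10
    remittance amount among receiving households. The energy-ladder
    composition row reports the χ² statistic instead.
    """
    if indicators is None:
        indicators = [c for c in CONTINUOUS_INDICATORS if c in energy.columns]
    if site_restricted is None:
        site_restricted = SITE_RESTRICTED
    df = energy.merge(
        households[
            [
                "household_id",
                "site_id",
                "remittance_received",
                "remittance_total_yuan",
                "sampling_weight",
            ]
        ],
        on="household_id",
    )
    if df["remittance_received"].nunique() < 2:
        raise ValueError("both remittance groups must be non-empty")
    w_all = (
        df["sampling_weight"].to_numpy(float)
        if weighted
        else np.ones(len(df))
    )

    rows = []

    def _one(sub: pd.DataFrame, col: str, label: str):
        sub = sub[sub[col].notna()]
        g1 = sub[sub["remittance_received"] == 1]
        g0 = sub[sub["remittance_received"] == 0]
        if len(g1) < 2 or len(g0) < 2:
            return
        wt = (
            (g1["sampling_weight"].to_numpy(), g0["sampling_weight"].to_numpy())
            if weighted
            else (np.ones(len(g1)), np.ones(len(g0)))
        )
        d1 = DescrStatsW(g1[col].to_numpy(float), weights=wt[0])
        d0 = DescrStatsW(g0[col].to_numpy(float), weights=wt[1])
        t, p, _ = d1.get_compare(d0).ttest_ind(usevar="unequal")
        recv = sub[sub["remittance_total_yuan"] > 0]
        if len(recv) >= 3 and recv[col].nunique() > 1:
            X = sm.add_constant(np.log10(recv["remittance_total_yuan"]))
            wr = (
                recv["sampling_weight"].to_numpy()
                if weighted
                else np.ones(len(recv))
            )
            ols = sm.WLS(recv[col].astype(float), X, weights=wr).fit()
            coef, coef_se = float(ols.params.iloc[1]), float(ols.bse.iloc[1])
        else:
            coef, coef_se = np.nan, np.nan
        rows.append(
            {
                "indicator": label,
                "mean_1": d1.mean,
                "mean_0": d0.mean,
                "difference": d1.mean - d0.mean,
                "statistic": float(t),
                "p_value": float(p),
                "ols_coef": coef,
                "ols_se": coef_se,
            }
        )

    for col in indicators:
        rule = site_restricted.get(col)
        if rule == "by_site":
            for site in sorted(df["site_id"].unique()):
                _one(df[df["site_id"] == site], col, f"{col} ({site})")
        elif isinstance(rule, list):
            for site in rule:
                _one(df[df["site_id"] == site], col, f"{col} ({site})")
        else:
            _one(df, col, col)

    chi2, p, _ = weighted_ladder_chi2(
        df["ladder_stage"].to_numpy(),
        df["remittance_received"].to_numpy(),
        w_all,
    )
    rows.append(
        {
            "indicator": "energy_ladder_composition",
            "mean_1": np.nan,
            "mean_0": np.nan,
            "difference": np.nan,
            "statistic": chi2,
            "p_value": p,
            "ols_coef": np.nan,
            "ols_se": np.nan,
        }
    )
    return pd.DataFrame(rows)
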