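"""Bootstrap treatment effects of remittance on buffer forest change.

Pairwise bootstrap over matched (treated, control) households: each
replicate draws 60% of the pairs (with replacement by default; a plain
subsample mode is available) and runs three t-tests per buffer radius:

* H1 — the paired treated-minus-control difference is positive;
* H2 — forest change around treated households exceeds zero;
* H3 — forest change around control households is at or below zero
  (scored both as "significantly negative" and "not significant").

Each hypothesis records the share of replicates with p < 0.05 in the
hypothesised direction (its occurrence of significance) alongside the raw
two-sided p < 0.05 rate. OLS associations of buffer change with log10
remittance reuse the same resampling scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ALPHA = 0.05


@dataclass
class ATEResult:
    radius: float
    metric: str  # delta_forest | delta_evi
    n_pairs: int
    mean_diff: float  # full-sample mean treated-minus-control
    boot_mean: float
    boot_sd: float
    occurrence_h1: float  # % replicates: p<0.05 and diff > 0
    occurrence_h2: float  # % replicates: p<0.05 and treated mean > 0
    occurrence_h3_negative: float  # % replicates: p<0.05 and control mean < 0
    occurrence_h3_nonsig: float  # % replicates: control not significant
    significance_rate_h1: float  # % replicates with two-sided p<0.05, any sign
    significance_rate_h2: float
    significance_rate_h3: float


@dataclass
class AssociationResult:
    level: str
    metric: str
    n: int
    slope: float
    se: float
    p_value: float
    boot_mean: float
    boot_sd: float
    occurrence: float  # % replicates with two-sided p < 0.05
    occurrence_signed: float  # % replicates with p < 0.05 and slope > 0


def _collapsed_one_sample(x: np.ndarray, codes: np.ndarray):
    """One-sample t (mean = 0) after collapsing duplicate households.

    Values sharing a household code are averaged first (a treated
    household reused across pairs counts once, matching the inverse-
    multiplicity weighting of the matched design); the t statistic is
    then computed on the independent per-household aggregates.
    """
    counts = np.bincount(codes)
    present = counts > 0
    agg = np.bincount(codes, weights=x)[present] / counts[present]
    n = len(agg)
    if n < 2:
        return float(agg.mean()) if n else np.nan, np.nan, 1.0
    m = agg.mean()
    s = agg.std(ddof=1)
    if s == 0:
        return float(m), np.nan, 1.0 if m == 0 else 0.0
    t = m / (s / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(m), float(t), float(p)


def _draw_indices(rng, n, n_reps, frac, replace):
    m = int(np.ceil(frac * n))
    if replace:
        return rng.integers(0, n, size=(n_reps, m))
    return np.stack(
        [rng.permutation(n)[:m] for _ in range(n_reps)], axis=0
    )


def bootstrap_ate(
    pairs: pd.DataFrame,
    changes: pd.DataFrame,
    metric: str = "delta_forest",
    radii=None,
    n_reps: int = 1000,
    frac: float = 0.6,
    seed: int = 0,
    replace: bool = True,
) -> list[ATEResult]:
    """Pairwise-bootstrap average treatment effect per buffer radius.

    ``pairs`` must carry control_id/treated_id; ``changes`` is the
    household × radius table from the buffer stage.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 matched pairs")
    if radii is None:
        radii = sorted(changes["radius"].unique())
    rng = np.random.default_rng(seed)
    out = []
    for r in radii:
        sub = changes[changes["radius"] == r].set_index("unit_id")[metric]
        tr = sub.reindex(pairs["treated_id"]).to_numpy(float)
        co = sub.reindex(pairs["control_id"]).to_numpy(float)
        t_codes = pd.factorize(pairs["treated_id"])[0]
        c_codes = pd.factorize(pairs["control_id"])[0]
        ok = np.isfinite(tr) & np.isfinite(co)
        if ok.sum() < 5:
            raise ValueError(f"fewer than 5 complete pairs at radius {r}")
        tr, co = tr[ok], co[ok]
        t_codes, c_codes = t_codes[ok], c_codes[ok]
        diff = tr - co
        n = len(diff)
        idx = _draw_indices(rng, n, n_reps, frac, replace)

        md = np.empty(n_reps)
        pd_ = np.empty(n_reps)
        mt = np.empty(n_reps)
        pt = np.empty(n_reps)
        mc = np.empty(n_reps)
        pc = np.empty(n_reps)
        for i in range(n_reps):
            sel = idx[i]
            md[i], _, pd_[i] = _collapsed_one_sample(diff[sel], t_codes[sel])
            mt[i], _, pt[i] = _collapsed_one_sample(tr[sel], t_codes[sel])
            mc[i], _, pc[i] = _collapsed_one_sample(co[sel], c_codes[sel])

        w_full = 1.0 / np.bincount(t_codes)[t_codes]
        out.append(
            ATEResult(
                radius=float(r),
                metric=metric,
                n_pairs=n,
                mean_diff=float(np.average(diff, weights=w_full)),
                boot_mean=float(md.mean()),
                boot_sd=float(md.std(ddof=1)),
                occurrence_h1=100.0 * float(np.mean((pd_ < ALPHA) & (md > 0))),
                occurrence_h2=100.0 * float(np.mean((pt < ALPHA) & (mt > 0))),
                occurrence_h3_negative=100.0
                * float(np.mean((pc < ALPHA) & (mc < 0))),
                occurrence_h3_nonsig=100.0 * float(np.mean(pc >= ALPHA)),
                significance_rate_h1=100.0 * float(np.mean(pd_ < ALPHA)),
                significance_rate_h2=100.0 * float(np.mean(pt < ALPHA)),
                significance_rate_h3=100.0 * float(np.mean(pc < ALPHA)),
            )
        )
    return out


def ate_table(results: list[ATEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# remittance-forest association (household level)
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray):
    X = np.column_stack([np.ones(len(x)), x])
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def remittance_forest_ols(
    households: pd.DataFrame,
    changes: pd.DataFrame,
    radius: float,
    metric: str = "delta_forest",
    level: str = "household_total",
    n_reps: int = 1000,
    frac: float = 0.6,
    seed: int = 0,
    replace: bool = True,
    log1p: bool = False,
) -> AssociationResult:
    """OLS slope of buffer change on log10 remittance, with bootstrap.

    ``level`` selects the remittance indicator: the household total or the
    per-migrant average. The slope is per log10 unit, i.e. the effect of a
    10-times increase in remittance.
    """
    h = households.set_index("household_id")
    rem = h["remittance_total_yuan"].astype(float)
    if level == "per_migrant":
        rem = rem / h["n_migrants"].clip(lower=1)
    elif level != "household_total":
        raise ValueError(f"unknown level {level!r}")
    if log1p:
        x_all = np.log10(1.0 + rem)
    else:
        rem = rem[rem > 0]
        x_all = np.log10(rem)

    sub = changes[changes["radius"] == radius].set_index("unit_id")[metric]
    common = x_all.index.intersection(sub.index)
    x = x_all.loc[common].to_numpy(float)
    y = sub.loc[common].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct remittance values")

    slope, se, p = _ols_slope(x, y)
    rng = np.random.default_rng(seed)
    idx = _draw_indices(rng, len(x), n_reps, frac, replace)
    slopes = np.empty(n_reps)
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        xi, yi = x[idx[i]], y[idx[i]]
        if len(np.unique(xi)) < 3:
            slopes[i], pvals[i] = np.nan, 1.0
            continue
        slopes[i], _, pvals[i] = _ols_slope(xi, yi)
    good = np.isfinite(slopes)
    return AssociationResult(
        level=level,
        metric=metric,
        n=len(x),
        slope=slope,
        se=se,
        p_value=p,
        boot_mean=float(np.nanmean(slopes)),
        boot_sd=float(np.nanstd(slopes, ddof=1)),
        occurrence=100.0 * float(np.mean(pvals[good] < ALPHA)),
        occurrence_signed=100.0
        * float(np.mean((pvals[good] < ALPHA) & (slopes[good] > 0))),
    )


# ---------------------------------------------------------------------------
# group-level ring association with outlier screening
# ---------------------------------------------------------------------------

def group_association(
    ring_table: pd.DataFrame,
    metric: str = "delta_forest",
    outlier_threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-ring OLS of group forest change on log10 group remittance.

    Two fits per ring: all groups, and groups after excluding points with
    |studentised residual| above the threshold (the robustness trend line).
    Returns one row per ring label with both slopes.
    """
    if ring_table["unit_id"].nunique() < 10:
        raise ValueError("need at least 10 resident groups")
    rows = []
    for label, sub in ring_table.groupby("label", sort=False):
        sub = sub[
            (sub["group_remittance_total"] > 0) & sub[metric].notna()
        ]
        x = np.log10(sub["group_remittance_total"].to_numpy(float))
        y = sub[metric].to_numpy(float)
        if len(x) < 3:
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        infl = fit.get_influence().resid_studentized_internal
        keep = np.abs(infl) <= outlier_threshold
        if keep.sum() == 0:
            raise ValueError(f"all points are outliers in ring {label!r}")
        if keep.all():
            fit2 = fit
        else:
            fit2 = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
        rows.append(
            {
                "label": label,
                "metric": metric,
                "n_groups": len(x),
                "n_outliers": int((~keep).sum()),
                "slope_all": float(fit.params[1]),
                "p_all": float(fit.pvalues[1]),
                "slope_robust": float(fit2.params[1]),
                "p_robust": float(fit2.pvalues[1]),
            }
        )
    return pd.DataFrame(rows)


def group_scatter(ring_table: pd.DataFrame, metric: str = "delta_forest") -> pd.DataFrame:
    """Scatter data (log10 remittance vs change) for plotting exports."""
    sub = ring_table[ring_table["group_remittance_total"] > 0].copy()
    sub["log10_remittance"] = np.log10(sub["group_remittance_total"])
    return sub[["unit_id", "label", "log10_remittance", metric]]
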