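"""Propensity-score matching of remittance households.

Households receiving remittance form the treated group; households with
migrants but no remittance are the controls. A logistic propensity model
predicts receipt from household covariates; each control is matched to the
treated household with the nearest score (treated households are reusable,
and carry weight 1/m when matched m times). Balance is assessed by a t-test
on matched score gaps and by absolute standardised mean differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = [
    "site_is_ttz",
    "elevation_m",
    "slope_deg",
    "market_distance_km",
    "cropland_area_mu",
    "house_score",
    "farm_tool_score",
    "transport_score",
    "head_education_years",
]


class PropensityError(ValueError):
    """Propensity model could not be estimated (e.g. separation)."""


@dataclass
class PropensityResult:
    scores: pd.Series  # indexed by household_id, in (0,1)
    accuracy: float  # share of (score>=0.5) == treated
    params: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # control_id, treated_id, score_gap, weight
    caliper: float
    n_matched: int
    unmatched_controls: list[str]
    treated_multiplicity: pd.Series  # times each treated was used

    def treated_weight(self, treated_id: str) -> float:
        return 1.0 / float(self.treated_multiplicity.get(treated_id, np.nan))


def _prepare_covariates(households: pd.DataFrame, covariates=None):
    df = households.copy()
    if "site_is_ttz" not in df.columns and "site_id" in df.columns:
        sites = sorted(df["site_id"].unique())
        df["site_is_ttz"] = (df["site_id"] == sites[-1]).astype(int)
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in df.columns]
    return df, list(covariates)


def estimate_propensity(
    households: pd.DataFrame,
    covariates: list[str] | None = None,
    treatment: str = "remittance_received",
) -> PropensityResult:
    """Logistic propensity of receiving remittance given covariates.

    Constant covariates are dropped with a warning; separation raises
    :class:`PropensityError` suggesting covariate pruning.
    """
    df, covariates = _prepare_covariates(households, covariates)
    missing = [c for c in covariates + [treatment] if c not in df.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")
    dropped = [c for c in covariates if df[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}")
        covariates = [c for c in covariates if c not in dropped]

    X = sm.add_constant(df[covariates].astype(float))
    y = df[treatment].astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise PropensityError(
            f"propensity model failed ({exc}); consider pruning covariates"
        ) from exc
    if not np.all(np.isfinite(fit.params)) or np.max(np.abs(fit.params)) > 50:
        raise PropensityError(
            "separation suspected in propensity model; prune covariates"
        )
    scores = pd.Series(
        np.asarray(fit.predict(X)), index=df["household_id"].to_numpy()
    )
    accuracy = float(((scores.to_numpy() >= 0.5) == y.to_numpy()).mean())
    return PropensityResult(
        scores=scores, accuracy=accuracy, params=fit.params, dropped=dropped
    )


def match_controls(
    scores: pd.Series,
    treatment: pd.Series,
    caliper: float = np.inf,
) -> MatchResult:
    """Nearest-score one-to-one matching of controls to treated households.

    Treated households may be reused (multiplicity weight 1/m); controls
    are used at most once. Ties in score distance break on the smallest
    treated household_id, and controls are processed in id order, making
    the result invariant to input row order.
    """
    if not caliper > 0:
        raise ValueError("caliper must be positive")
    treatment = treatment.reindex(scores.index)
    t_ids = sorted(scores.index[treatment == 1])
    c_ids = sorted(scores.index[treatment == 0])
    if not t_ids or not c_ids:
        raise ValueError("both treated and control groups must be non-empty")

    t_scores = scores.loc[t_ids].to_numpy(float)
    order = np.lexsort((np.asarray(t_ids, dtype=object), t_scores))
    ts = t_scores[order]
    tid_sorted = np.asarray(t_ids, dtype=object)[order]

    rows = []
    unmatched = []
    for cid in c_ids:
        s = float(scores.loc[cid])
        j = np.searchsorted(ts, s)
        cand = [k for k in (j - 1, j) if 0 <= k < len(ts)]
        best = min(
            cand, key=lambda k: (abs(ts[k] - s), str(tid_sorted[k]))
        )
        gap = abs(ts[best] - s)
        if gap <= caliper:
            rows.append(
                {
                    "control_id": cid,
                    "treated_id": tid_sorted[best],
                    "score_gap": gap,
                    "signed_gap": ts[best] - s,
                }
            )
        else:
            unmatched.append(cid)
    pairs = pd.DataFrame(
        rows, columns=["control_id", "treated_id", "score_gap", "signed_gap"]
    )
    mult = (
        pairs["treated_id"].value_counts()
        if len(pairs)
        else pd.Series(dtype=int)
    )
    pairs["weight"] = (
        pairs["treated_id"].map(lambda t: 1.0 / mult[t]) if len(pairs) else []
    )
    return MatchResult(
        pairs=pairs,
        caliper=float(caliper),
        n_matched=len(pairs),
        unmatched_controls=unmatched,
        treated_multiplicity=mult,
    )


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def _smd(a: np.ndarray, b: np.ndarray, wa=None, wb=None) -> float:
    """|standardised mean difference| (|proportion diff| for binary)."""
    wa = np.ones(len(a)) if wa is None else np.asarray(wa, float)
    wb = np.ones(len(b)) if wb is None else np.asarray(wb, float)
    ma = np.average(a, weights=wa)
    mb = np.average(b, weights=wb)
    vals = set(np.unique(np.concatenate([a, b])))
    if vals <= {0.0, 1.0}:
        return abs(ma - mb)
    va = np.average((a - ma) ** 2, weights=wa)
    vb = np.average((b - mb) ** 2, weights=wb)
    pooled = np.sqrt((va + vb) / 2.0)
    return abs(ma - mb) / pooled if pooled > 0 else 0.0


def balance_check(
    match: MatchResult,
    households: pd.DataFrame,
    covariates: list[str] | None = None,
    treatment: str = "remittance_received",
) -> dict:
    """Matched-gap t-test plus per-covariate |SMD| before/after matching."""
    if len(match.pairs) == 0:
        raise ValueError("no matched pairs to diagnose")
    df, covariates = _prepare_covariates(households, covariates)
    df = df.set_index("household_id")
    gaps = match.pairs["signed_gap"].to_numpy()
    if np.allclose(gaps, 0):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_1samp(gaps, 0.0)
    treated_all = df.index[df[treatment] == 1]
    control_all = df.index[df[treatment] == 0]
    t_matched = match.pairs["treated_id"]
    c_matched = match.pairs["control_id"]
    w_matched = match.pairs["weight"].to_numpy()

    rows = []
    for cov in covariates:
        before = _smd(
            df.loc[treated_all, cov].to_numpy(float),
            df.loc[control_all, cov].to_numpy(float),
        )
        after = _smd(
            df.loc[t_matched, cov].to_numpy(float),
            df.loc[c_matched, cov].to_numpy(float),
            wa=w_matched,
        )
        rows.append({"covariate": cov, "smd_before": before, "smd_after": after})
    return {
        "gap_t": float(t_stat),
        "gap_p": float(p_val),
        "balance": pd.DataFrame(rows),
    }


def caliper_sweep(
    scores: pd.Series,
    treatment: pd.Series,
    calipers,
    effect_fn=None,
) -> pd.DataFrame:
    """Matched count (and optional downstream effect) per caliper value.

    ``effect_fn(match) -> dict`` lets the caller attach e.g. the bootstrap
    treatment effect for each caliper's matched set.
    """
    calipers = list(calipers)
    if any(c <= 0 for c in calipers) or sorted(calipers) != calipers:
        raise ValueError("calipers must be positive and sorted")
    rows = []
    for c in calipers:
        m = match_controls(scores, treatment, caliper=c)
        row = {"caliper": c, "n_matched": m.n_matched}
        if effect_fn is not None:
            row.update(effect_fn(m))
        rows.append(row)
    return pd.DataFrame(rows)
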