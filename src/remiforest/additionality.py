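"""Socioeconomic and ecological additionality of PES payments via remittance.

The socioeconomic additionality G_Econ% is the ratio of payment-stimulated
remittance to the payments themselves::

    G_Econ% = Σ_i 10^(β̂ · M_i · P_i / 1000) / Σ_h P_h × 100%

with β̂ the payment coefficient of the log10 remittance-amount model
(log10-Yuan per 1,000 Yuan), M_i migration years and P_i the annual payment
exposure of migrant i. The ecological additionality G_Ecol% converts each
household's attributable remittance L_h (log10 of the summed 10^ terms of
its migrants) into forest area via the remittance-forest slope γ̂ and the
buffer area A, against the enrolled area Σ_h P_h / λ::

    G_Ecol% = Σ_h γ̂ · L_h · A / (Σ_h P_h / λ_site(h)) × 100%

Uncertainty: β̂ ± σ̂_β for G_Econ; for G_Ecol the lower (upper) bounds of
both estimators multiply together. Households whose model-attributable
remittance is an extreme outlier among receivers (z-score above a
threshold) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import NATIONAL, YUAN_PER_USD

DEFAULT_BUFFER_AREA = np.pi * 100.0**2  # 100-m disc, m^2
DEFAULT_Z_THRESHOLD = 10.0


@dataclass
class AdditionalityResult:
    g_econ_pct: float
    g_econ_bounds: tuple[float, float]
    g_ecol_pct: float
    g_ecol_bounds: tuple[float, float]
    beta: float
    sigma_beta: float
    gamma: float
    sigma_gamma: float
    buffer_area_m2: float
    n_individuals: int
    n_households: int
    excluded_households: list[str] = field(default_factory=list)
    degenerate_beta: bool = False  # β = 0: each 10^ term collapses to 1

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        d["g_econ_bounds"] = list(self.g_econ_bounds)
        d["g_ecol_bounds"] = list(self.g_ecol_bounds)
        return d


def _attributable_terms(migrants: pd.DataFrame, beta: float) -> pd.Series:
    """10^(β·M_i·P_i/1000) per migrant, payment-exposed migrants only."""
    m = migrants[migrants["payment_annual_yuan"] > 0]
    expo = (
        beta
        * m["migration_years"].to_numpy(float)
        * m["payment_annual_yuan"].to_numpy(float)
        / 1000.0
    )
    return pd.Series(10.0**expo, index=m.index), m["household_id"]


def _excluded_ids(
    migrants: pd.DataFrame,
    households: pd.DataFrame,
    beta: float,
    z_threshold: float,
) -> list[str]:
    """Receiving households whose attributable remittance is a gross outlier."""
    terms, hh_ids = _attributable_terms(migrants, beta)
    pred = terms.groupby(hh_ids.to_numpy()).sum()
    recv = households.loc[
        households["remittance_received"] == 1, "household_id"
    ]
    pred = pred.reindex(recv).dropna()
    if len(pred) < 3 or pred.std(ddof=0) == 0:
        return []
    z = (pred - pred.mean()) / pred.std(ddof=0)
    return sorted(z.index[z > z_threshold])


def econ_additionality(
    migrants: pd.DataFrame,
    households: pd.DataFrame,
    beta: float,
    sigma_beta: float,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    participants_only: bool = True,
) -> dict:
    """G_Econ% with β̂ ± σ̂_β bounds.

    ``participants_only`` (default) restricts the numerator to migrants
    with payment exposure; the literal formula, which awards 10^0 = 1 Yuan
    to every unexposed migrant, is available with ``False``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    denom = float(
        households.loc[
            households["payment_annual_yuan"] > 0, "payment_annual_yuan"
        ].sum()
    )
    if denom == 0:
        raise ValueError("no participating households: Σ P_h = 0")
    excluded = _excluded_ids(migrants, households, beta, z_threshold)

    def value(b: float) -> float:
        mig = migrants[~migrants["household_id"].isin(excluded)]
        if participants_only:
            terms, _ = _attributable_terms(mig, b)
            num = float(terms.sum())
        else:
            expo = (
                b
                * mig["migration_years"].to_numpy(float)
                * mig["payment_annual_yuan"].to_numpy(float)
                / 1000.0
            )
            num = float(np.sum(10.0**expo))
        return num / denom * 100.0

    return {
        "g_econ_pct": value(beta),
        "bounds": (value(beta - sigma_beta), value(beta + sigma_beta)),
        "excluded": excluded,
        "degenerate_beta": beta == 0.0,
        "n_individuals": int((migrants["payment_annual_yuan"] > 0).sum()),
    }


def household_log_attributable(
    migrants: pd.DataFrame, beta: float
) -> pd.Series:
    """L_h = log10 Σ_{i∈S_h} 10^(β·M_i·P_i/1000); 0 with no exposed migrant."""
    terms, hh_ids = _attributable_terms(migrants, beta)
    agg = terms.groupby(hh_ids.to_numpy()).sum()
    out = pd.Series(0.0, index=migrants["household_id"].unique())
    out.loc[agg.index] = np.log10(agg)
    return out


def ecol_additionality(
    migrants: pd.DataFrame,
    households: pd.DataFrame,
    beta: float,
    gamma: float,
    sigma_beta: float,
    sigma_gamma: float,
    lambda_by_site: dict[str, float],
    buffer_area_m2: float = DEFAULT_BUFFER_AREA,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> dict:
    """G_Ecol% with joint lower/upper bounds from both estimators."""
    if not (np.isfinite(beta) and np.isfinite(gamma)):
        raise ValueError("beta and gamma must be finite")
    if buffer_area_m2 <= 0:
        raise ValueError("buffer area must be positive")
    part = households[households["payment_annual_yuan"] > 0]
    lam = part["site_id"].map(lambda_by_site)
    if lam.isna().any() or (lam <= 0).any():
        raise ValueError("every participating site needs a positive λ")
    denom = float((part["payment_annual_yuan"] / lam).sum())  # enrolled m^2
    if denom == 0:
        raise ValueError("zero enrolled area")
    excluded = _excluded_ids(migrants, households, beta, z_threshold)
    mig = migrants[~migrants["household_id"].isin(excluded)]

    def value(b: float, g: float) -> float:
        lh = household_log_attributable(mig, b)
        return float(g * lh.sum() * buffer_area_m2) / denom * 100.0

    return {
        "g_ecol_pct": value(beta, gamma),
        "bounds": (
            value(beta - sigma_beta, gamma - sigma_gamma),
            value(beta + sigma_beta, gamma + sigma_gamma),
        ),
        "excluded": excluded,
        "enrolled_area_m2": denom,
        "n_households": int(len(part)),
    }


def additionality(
    migrants: pd.DataFrame,
    households: pd.DataFrame,
    beta: float,
    sigma_beta: float,
    gamma: float,
    sigma_gamma: float,
    lambda_by_site: dict[str, float],
    buffer_area_m2: float = DEFAULT_BUFFER_AREA,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> AdditionalityResult:
    """Both additionality estimators with shared exclusions."""
    econ = econ_additionality(
        migrants, households, beta, sigma_beta, z_threshold=z_threshold
    )
    ecol = ecol_additionality(
        migrants,
        households,
        beta,
        gamma,
        sigma_beta,
        sigma_gamma,
        lambda_by_site,
        buffer_area_m2=buffer_area_m2,
        z_threshold=z_threshold,
    )
    return AdditionalityResult(
        g_econ_pct=econ["g_econ_pct"],
        g_econ_bounds=econ["bounds"],
        g_ecol_pct=ecol["g_ecol_pct"],
        g_ecol_bounds=ecol["bounds"],
        beta=beta,
        sigma_beta=sigma_beta,
        gamma=gamma,
        sigma_gamma=sigma_gamma,
        buffer_area_m2=buffer_area_m2,
        n_individuals=econ["n_individuals"],
        n_households=ecol["n_households"],
        excluded_households=sorted(set(econ["excluded"]) | set(ecol["excluded"])),
        degenerate_beta=econ["degenerate_beta"],
    )


def scale_national(
    g_econ_bounds_pct: tuple[float, float],
    g_ecol_bounds_pct: tuple[float, float],
    total_investment_usd: float | None = None,
    enrolled_area_ha: float | None = None,
    yuan_per_usd: float = YUAN_PER_USD,
) -> dict:
    """Apply additionality percentages to program-level totals.

    Returns the stimulated remittance flow (USD and Yuan) and the
    remittance-induced forest area (ha), each as [lower, upper].
    """
    if total_investment_usd is None:
        total_investment_usd = NATIONAL["total_investment_usd"]
    if enrolled_area_ha is None:
        enrolled_area_ha = NATIONAL["enrolled_area_ha"]
    if total_investment_usd is None or enrolled_area_ha is None:
        raise ValueError("program totals are required")
    remit_usd = [total_investment_usd * g / 100.0 for g in g_econ_bounds_pct]
    forest_ha = [enrolled_area_ha * g / 100.0 for g in g_ecol_bounds_pct]
    return {
        "remittance_usd": remit_usd,
        "remittance_yuan": [v * yuan_per_usd for v in remit_usd],
        "forest_ha": forest_ha,
    }
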