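"""Scenario configuration for the synthetic two-site study generator.

A :class:`ScenarioConfig` fixes every planted parameter of the synthetic
study: sample sizes, the CCFP payment process, the true coefficients that
link payments to remittance and remittance to forest change, and the raster
geometry. Identical ``(seed, config)`` pairs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .constants import PAYMENT_RATE


@dataclass
class ScenarioConfig:
    """Planted parameters of a synthetic study scenario.

    The defaults emulate the published two-site survey structure: a
    semi-arid northern site ("JC", 22 resident groups) and a subtropical
    southern site ("TTZ", 41 groups), 458 migrant households with 767
    out-migrants, ~36% of migrants sending remittance, and CCFP payment
    rates of 0.135 / 0.1875 Yuan/year/m2.
    """

    seed: int = 7

    # --- sites and sampling structure ---
    site_ids: tuple[str, str] = ("JC", "TTZ")
    n_households_per_site: tuple[int, int] = (160, 298)
    n_groups_per_site: tuple[int, int] = (22, 41)
    n_migrants_total: int | None = 767  # None -> draw ~ truncated Poisson
    mean_migrants_per_household: float = 1.7

    # --- CCFP payment process ---
    ccfp_participation_rate: float = 0.57
    payment_rate_per_site: tuple[float, float] = (
        PAYMENT_RATE["JC"],
        PAYMENT_RATE["TTZ"],
    )
    # enrolled area ~ 10**N(log10_mu, log10_sd) m2, participants only
    enrolled_area_log10_mean: float = 3.30
    enrolled_area_log10_sd: float = 0.35

    # --- planted remittance model (truth for recovery tests) ---
    beta_ccfp_logit: float = 0.10  # log-odds per 1,000 Yuan cumulative payment
    beta_ccfp_amount: float = 0.099  # log10-Yuan per 1,000 Yuan
    logit_intercept: float = -1.10  # targets ~36% senders
    amount_intercept: float = 3.65  # log10 Yuan; sender amounts ~ 16k Yuan
    logit_group_sd: float = 0.5
    amount_group_sd: float = 0.15
    amount_noise_sd: float = 0.45
    confound_strength: float = 2.4  # household covariates -> remittance logit

    # --- planted forest response (truth for ATE / OLS recovery) ---
    remit_forest_slope: float = 0.011  # forest fraction per log10-Yuan
    remit_evi_slope: float = 0.005  # EVI per log10-Yuan
    migrant_drift: float = -0.015  # forest fraction near zero-remittance migrants
    evi_migrant_drift: float = -0.005  # EVI counterpart of migrant_drift
    background_flip_rate: float = 0.02  # spontaneous gain/loss outside effects
    effect_radius: float = 100.0  # metres
    evi_noise_sd: float = 0.01

    # --- raster geometry ---
    cell_size: float = 30.0  # metres
    raster_extent: float = 6000.0  # metres, square per site
    group_scatter_sd: float = 200.0  # household scatter around group centre, m
    min_house_separation: float = 150.0  # dispersed hamlet settlement, m

    # --- energy / mechanism coupling ---
    fuelwood_remit_coupling: float = 0.08  # log10 kg drop per log10(1+Yuan)
    gas_remit_coupling: float = 0.10  # log10 Yuan rise per log10(1+Yuan)

    # --- migration flow network ---
    n_destination_cities: int = 87
    n_destination_provinces: int = 36
    distance_log10_range: tuple[float, float] = (1.7, 3.2)  # km

    # --- sampling weights (disproportionate stratified design) ---
    weight_participant: float = 0.7
    weight_nonparticipant: float = 1.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccfp_participation_rate <= 1.0:
            raise ValueError("ccfp_participation_rate must be in [0, 1]")
        if any(n <= 0 for n in self.n_households_per_site):
            raise ValueError("household counts must be positive")
        if any(n <= 0 for n in self.n_groups_per_site):
            raise ValueError("group counts must be positive")
        if any(r <= 0 for r in self.payment_rate_per_site):
            raise ValueError("payment rates must be strictly positive")
        if self.effect_radius <= 0 or self.cell_size <= 0:
            raise ValueError("radii and cell size must be strictly positive")
        if self.raster_extent < 2 * max(self.effect_radius, 200.0):
            raise ValueError(
                "raster_extent smaller than twice the maximum buffer radius"
            )
        if self.n_migrants_total is not None:
            n_hh = sum(self.n_households_per_site)
            if self.n_migrants_total < n_hh:
                raise ValueError(
                    "n_migrants_total below one migrant per migrant household"
                )
        for g, h in zip(self.n_groups_per_site, self.n_households_per_site):
            if g > h:
                raise ValueError("more groups than households at a site")
        if min(self.weight_participant, self.weight_nonparticipant) <= 0:
            raise ValueError("sampling weights must be positive")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.to_dict().items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        fields = {f for f in cls.__dataclass_fields__}
        clean = {}
        for k, v in data.items():
            if k not in fields:
                raise ValueError(f"unknown config field: {k!r}")
            default = cls.__dataclass_fields__[k].default
            if isinstance(default, tuple) and isinstance(v, list):
                v = tuple(v)
            clean[k] = v
        return cls(**clean)
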