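"""Synthetic two-site study generator.

Emulates the structure of a two-site rural household survey around a
payments-for-ecosystem-services (PES) program, with planted parameters so
every downstream stage of the pipeline is testable without any real data:

* households clustered into resident groups at two sites, with covariates,
  CCFP enrolment, cumulative payments and stratified sampling weights;
* out-migrants per household whose remittance behaviour follows a
  random-intercept logistic (sending) and log10-normal (amount) model whose
  payment coefficients are the planted truth;
* raster pairs (forest indicator + EVI at two dates) in which forest gain
  within ``effect_radius`` of a house increases with the household's
  log10 remittance, and shrinks near migrant households without remittance;
* energy-use profiles and a migration-destination network for the
  mechanism and flow analyses.

All randomness derives from one master seed through fixed substream
offsets, so identical ``(seed, config)`` pairs give byte-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .config import ScenarioConfig
from .types import RasterPair, ResidentGroup, ScenarioBundle, SyntheticTruth

# substream offsets from the master seed
_STREAM_LAYOUT = 0
_STREAM_HOUSEHOLD = 1
_STREAM_MIGRANT = 2
_STREAM_RASTER = 3
_STREAM_ENERGY = 4

# fixed covariate effects on the remittance linear predictors
_IND_LOGIT_EFFECTS = {
    "gender": 0.20,
    "age_years": -0.015,  # centred at 35
    "education_years": 0.04,  # centred at 9
    "outside_province": 0.25,
}
_IND_AMOUNT_EFFECTS = {
    "education_years": 0.03,  # centred at 9
    "outside_province": 0.10,
}


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# layout: groups and household locations
# ---------------------------------------------------------------------------

def _generate_layout(config: ScenarioConfig, rng: np.random.Generator):
    margin = 450.0  # keep house + 200 m buffers and group rings on the raster
    rows = []
    group_rows = []
    for s, site in enumerate(config.site_ids):
        n_hh = config.n_households_per_site[s]
        n_grp = config.n_groups_per_site[s]
        lo, hi = margin, config.raster_extent - margin
        # group centres with mutual spacing where the extent allows it
        centres = np.empty((n_grp, 2))
        for g in range(n_grp):
            for attempt in range(200):
                cand = rng.uniform(lo, hi, size=2)
                if g == 0 or np.min(
                    np.hypot(*(centres[:g] - cand).T)
                ) >= 500.0 - 2.0 * attempt:
                    break
            centres[g] = cand
        # round-robin seeds each group with 3 members, remainder at random
        assignment = np.concatenate(
            [
                np.tile(np.arange(n_grp), 3)[: min(3 * n_grp, n_hh)],
                rng.integers(0, n_grp, size=max(0, n_hh - 3 * n_grp)),
            ]
        )
        # dart-throwing with a minimum inter-house separation so each
        # house's effect disc is essentially its own
        placed = np.empty((n_hh, 2))
        min_sep = config.min_house_separation
        for j in range(n_hh):
            g = assignment[j]
            for attempt in range(120):
                sd = config.group_scatter_sd * (1.0 + 0.04 * attempt)
                cand = np.clip(
                    centres[g] + rng.normal(0.0, sd, 2),
                    margin / 2,
                    config.raster_extent - margin / 2,
                )
                if j == 0 or np.min(
                    np.hypot(*(placed[:j] - cand).T)
                ) >= min_sep:
                    break
            placed[j] = cand
        for j in range(n_hh):
            g = assignment[j]
            rows.append(
                {
                    "site_id": site,
                    "group_id": f"{site}-G{g + 1:02d}",
                    "x": placed[j, 0],
                    "y": placed[j, 1],
                }
            )
        for g in range(n_grp):
            group_rows.append(
                {"site_id": site, "group_id": f"{site}-G{g + 1:02d}"}
            )
    df = pd.DataFrame(rows)
    df.insert(0, "household_id", [f"H{i + 1:04d}" for i in range(len(df))])
    return df, pd.DataFrame(group_rows)


# ---------------------------------------------------------------------------
# households
# ---------------------------------------------------------------------------

def _generate_households(
    config: ScenarioConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    df = layout.copy()
    n = len(df)
    site_index = df["site_id"].map(
        {s: i for i, s in enumerate(config.site_ids)}
    )

    df["ccfp_participant"] = (
        rng.random(n) < config.ccfp_participation_rate
    ).astype(int)
    # truncated so cumulative payments span the observed ~0-12k Yuan range
    area = np.clip(
        10.0
        ** rng.normal(
            config.enrolled_area_log10_mean, config.enrolled_area_log10_sd, n
        ),
        300.0,
        6000.0,
    )
    df["enrolled_area_m2"] = np.where(
        df["ccfp_participant"] == 1, np.round(area, 1), 0.0
    )
    lam = np.asarray(config.payment_rate_per_site)[site_index]
    df["payment_rate"] = lam
    df["payment_annual_yuan"] = df["enrolled_area_m2"] * lam

    # covariate block (site-contrasted where the two regions differ)
    is_ttz = (site_index == 1).to_numpy()
    df["cropland_area_mu"] = np.round(
        np.clip(rng.lognormal(1.2, 0.5, n), 0.2, 30.0), 2
    )
    df["house_score"] = np.clip(rng.normal(3.0, 1.0, n), 1.0, 5.0).round(2)
    df["farm_tool_score"] = np.clip(rng.normal(2.8, 0.9, n), 1.0, 5.0).round(2)
    df["transport_score"] = np.clip(rng.normal(2.5, 1.0, n), 1.0, 5.0).round(2)
    df["head_education_years"] = np.clip(
        rng.normal(6.5, 2.5, n).round(), 0, 16
    ).astype(int)
    df["market_distance_km"] = np.round(
        np.clip(rng.lognormal(1.0, 0.6, n), 0.2, 25.0), 2
    )
    df["elevation_m"] = np.round(
        np.where(is_ttz, rng.normal(700, 150, n), rng.normal(1150, 180, n)), 0
    )
    df["slope_deg"] = np.round(np.clip(rng.normal(18, 7, n), 0, 45), 1)

    w = np.where(
        df["ccfp_participant"] == 1,
        config.weight_participant,
        config.weight_nonparticipant,
    )
    df["sampling_weight"] = w / w.mean()
    return df


def _household_confounder_shift(
    config: ScenarioConfig, households: pd.DataFrame
) -> np.ndarray:
    """Household-level covariate shift on the remittance log-odds.

    These covariates confound remittance receipt, so that the propensity
    model is genuinely informative (accuracy well above the base rate) and
    matching has real work to do.
    """
    h = households
    shift = (
        0.25 * (h["house_score"] - 3.0)
        - 0.10 * (h["market_distance_km"] - h["market_distance_km"].mean())
        + 0.05 * (h["head_education_years"] - 6.0)
        + 0.10 * (h["transport_score"] - 2.5)
    )
    return config.confound_strength * shift.to_numpy()


# ---------------------------------------------------------------------------
# migrants and remittance
# ---------------------------------------------------------------------------

def _migrant_counts(
    config: ScenarioConfig, n_households: int, rng: np.random.Generator
) -> np.ndarray:
    counts = 1 + rng.poisson(
        config.mean_migrants_per_household - 1.0, n_households
    )
    if config.n_migrants_total is None:
        return counts
    # repair the draw to hit the configured total exactly, keeping min 1
    diff = int(config.n_migrants_total - counts.sum())
    while diff != 0:
        j = rng.integers(0, n_households)
        if diff > 0:
            counts[j] += 1
            diff -= 1
        elif counts[j] > 1:
            counts[j] -= 1
            diff += 1
    return counts


def _generate_migrants(
    config: ScenarioConfig,
    households: pd.DataFrame,
    rng: np.random.Generator,
):
    counts = _migrant_counts(config, len(households), rng)
    hh = households.loc[households.index.repeat(counts)].reset_index(drop=True)
    n = len(hh)

    m = pd.DataFrame(
        {
            "migrant_id": [f"M{i + 1:04d}" for i in range(n)],
            "household_id": hh["household_id"],
            "site_id": hh["site_id"],
            "group_id": hh["group_id"],
        }
    )
    m["gender"] = rng.integers(0, 2, n)
    m["age_years"] = rng.integers(16, 60, n)
    m["education_years"] = np.clip(rng.normal(9, 2.5, n).round(), 2, 16).astype(int)
    m["outside_province"] = (rng.random(n) < 0.45).astype(int)
    # at least six consecutive months away
    m["migration_years"] = np.round(
        np.clip(rng.gamma(2.5, 2.4, n), 0.5, 12.0), 1
    )
    m["payment_annual_yuan"] = hh["payment_annual_yuan"].to_numpy()
    m["payment_cum_kyuan"] = (
        m["payment_annual_yuan"] * m["migration_years"] / 1000.0
    )
    m["sampling_weight"] = hh["sampling_weight"].to_numpy()

    # group random intercepts
    all_groups = households["group_id"].unique()
    u_send = dict(
        zip(all_groups, rng.normal(0.0, config.logit_group_sd, len(all_groups)))
    )
    u_amount = dict(
        zip(all_groups, rng.normal(0.0, config.amount_group_sd, len(all_groups)))
    )

    confound = _household_confounder_shift(config, hh)
    eta = (
        config.logit_intercept
        + config.beta_ccfp_logit * m["payment_cum_kyuan"].to_numpy()
        + _IND_LOGIT_EFFECTS["gender"] * m["gender"].to_numpy()
        + _IND_LOGIT_EFFECTS["age_years"] * (m["age_years"].to_numpy() - 35.0)
        + _IND_LOGIT_EFFECTS["education_years"]
        * (m["education_years"].to_numpy() - 9.0)
        + _IND_LOGIT_EFFECTS["outside_province"] * m["outside_province"].to_numpy()
        + confound
        + m["group_id"].map(u_send).to_numpy()
    )
    p_send = _sigmoid(eta)
    m["sent_remittance"] = (rng.random(n) < p_send).astype(int)

    log_amount = (
        config.amount_intercept
        + config.beta_ccfp_amount * m["payment_cum_kyuan"].to_numpy()
        + _IND_AMOUNT_EFFECTS["education_years"]
        * (m["education_years"].to_numpy() - 9.0)
        + _IND_AMOUNT_EFFECTS["outside_province"]
        * m["outside_province"].to_numpy()
        + m["group_id"].map(u_amount).to_numpy()
        + rng.normal(0.0, config.amount_noise_sd, n)
    )
    m["remittance_amount_yuan"] = np.where(
        m["sent_remittance"] == 1, np.round(10.0 ** log_amount, 0), 0.0
    )
    return m, pd.Series(p_send, index=m["migrant_id"].to_numpy())


def _aggregate_to_households(
    households: pd.DataFrame, migrants: pd.DataFrame
) -> pd.DataFrame:
    df = households.copy()
    agg = migrants.groupby("household_id").agg(
        n_migrants=("migrant_id", "size"),
        remittance_total_yuan=("remittance_amount_yuan", "sum"),
        max_migration_years=("migration_years", "max"),
    )
    df = df.merge(agg, left_on="household_id", right_index=True, how="left")
    df["n_migrants"] = df["n_migrants"].fillna(0).astype(int)
    df["remittance_total_yuan"] = df["remittance_total_yuan"].fillna(0.0)
    df["max_migration_years"] = df["max_migration_years"].fillna(0.0)
    df["remittance_received"] = (df["remittance_total_yuan"] > 0).astype(int)
    df["cumulative_payment_yuan"] = (
        df["payment_annual_yuan"] * df["max_migration_years"]
    )
    return df


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return g / g.std()


def _influence_grid(
    config: ScenarioConfig, households: pd.DataFrame, n_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forest and EVI change targets per cell (nearest-household attribution).

    Every cell within ``effect_radius`` of its nearest migrant household
    responds to that household's remittance; overlap between neighbouring
    households is resolved by proximity so planted slopes are not
    double-counted.
    """
    cs = config.cell_size
    centres = (np.arange(n_cells) + 0.5) * cs
    cx, cy = np.meshgrid(centres, centres)  # row-major: cy rows, cx cols
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    tree = cKDTree(households[["x", "y"]].to_numpy())
    dist, idx = tree.query(pts, distance_upper_bound=config.effect_radius)
    inside = np.isfinite(dist)
    rem = households["remittance_total_yuan"].to_numpy()

    t_forest = np.zeros(len(pts))
    t_evi = np.zeros(len(pts))
    owner = np.where(inside, idx, -1)
    has_rem = np.zeros(len(pts), dtype=bool)
    has_rem[inside] = rem[owner[inside]] > 0
    logrem = np.zeros(len(pts))
    logrem[has_rem] = np.log10(rem[owner[has_rem]])

    t_forest[inside] = config.migrant_drift
    t_forest[has_rem] += config.remit_forest_slope * logrem[has_rem]
    t_evi[inside] = config.evi_migrant_drift
    t_evi[has_rem] += config.remit_evi_slope * logrem[has_rem]
    return t_forest.reshape(n_cells, n_cells), t_evi.reshape(n_cells, n_cells)


def generate_rasters(
    households: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Generate one site's forest/EVI raster pair around its households.

    Returns a :class:`RasterPair` (or ``(pair, truth_frame)`` with
    ``return_truth=True``, where the frame holds each household's expected
    ΔForest/ΔEVI over its effect-radius disc on the planted probability
    fields). Raises if households span several sites (each site owns one
    raster) or fall outside the configured extent.
    """
    sites = households["site_id"].unique()
    if len(sites) != 1:
        raise ValueError(
            f"households span sites {list(sites)}; one raster per site"
        )
    xy = households[["x", "y"]].to_numpy()
    if xy.min() < 0 or xy.max() > config.raster_extent:
        raise ValueError("household coordinates outside the raster extent")
    if rng is None:
        rng = _rng(config, _STREAM_RASTER)

    n = int(round(config.raster_extent / config.cell_size))
    base = _smooth_field(rng, (n, n), sigma=3.0)
    p0 = np.clip(0.5 + 0.25 * base, 0.05, 0.95)
    k0 = (rng.random((n, n)) < p0).astype(np.uint8)
    fbar = float(k0.mean())

    t_forest, t_evi = _influence_grid(config, households, n)
    bg = config.background_flip_rate
    # directional flips keep E[ΔForest|cell] at the planted target; the
    # background turnover is balanced per cell (loss rate scaled by the
    # gain/loss odds) so that absent remittance effects the expected net
    # change is exactly zero given the landscape
    p_gain = np.clip(bg + np.maximum(t_forest, 0.0) / max(1 - fbar, 0.05), 0, 1)
    p_loss = np.clip(
        bg * (1 - p0) / p0 + np.maximum(-t_forest, 0.0) / max(fbar, 0.05), 0, 1
    )
    u = rng.random((n, n))
    k1 = np.where(k0 == 1, (u >= p_loss), (u < p_gain)).astype(np.uint8)

    green = _smooth_field(rng, (n, n), sigma=4.0)
    evi0 = np.clip(
        0.25 + 0.30 * (p0 - 0.5) + 0.12 * green + rng.normal(0, 0.02, (n, n)),
        -1.0,
        1.0,
    )
    evi1 = np.clip(
        evi0 + t_evi + rng.normal(0.0, config.evi_noise_sd, (n, n)), -1.0, 1.0
    )
    pair = RasterPair(
        forest_t0=k0,
        forest_t1=k1,
        evi_t0=evi0,
        evi_t1=evi1,
        cell_size=config.cell_size,
        origin=(0.0, 0.0),
        site_id=str(sites[0]),
    )
    if not return_truth:
        return pair
    # expected change per cell on the probability fields, integrated over
    # each household's buffer with the same fractional-overlap kernel the
    # metrics use: the realised planted estimand of the measurement
    from .buffers import disc, overlap_weights

    exp_cell = (1 - p0) * p_gain - p0 * p_loss
    rows = []
    for _, hh in households.iterrows():
        rr, cc, w = overlap_weights(
            disc(hh["x"], hh["y"], config.effect_radius), pair
        )
        wsum = w.sum()
        rows.append(
            {
                "household_id": hh["household_id"],
                "expected_delta_forest": float((w * exp_cell[rr, cc]).sum() / wsum),
                "expected_delta_evi": float((w * t_evi[rr, cc]).sum() / wsum),
            }
        )
    return pair, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# energy profiles and migration flows
# ---------------------------------------------------------------------------

def generate_energy_and_flows(
    households: pd.DataFrame,
    migrants: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
):
    """Energy-use columns plus the migrant destination network.

    Fuelwood use falls and gas spending rises with household remittance
    (planted couplings); each migrant is assigned a destination city whose
    distance lies in the configured log10 range.

    Returns ``(energy, destinations, migrants)`` where ``migrants`` carries
    the new ``destination_id`` / ``distance_km`` columns.
    """
    if rng is None:
        rng = _rng(config, _STREAM_ENERGY)
    h = households
    n = len(h)
    logrem = np.log10(1.0 + h["remittance_total_yuan"].to_numpy())

    fuel_kg = 10.0 ** (
        3.0
        - config.fuelwood_remit_coupling * logrem
        + rng.normal(0, 0.15, n)
    )
    gas_cost = 10.0 ** (
        1.7 + config.gas_remit_coupling * logrem + rng.normal(0, 0.2, n)
    )
    from .constants import FUELWOOD_PRICE_YUAN_PER_KG

    fuel_value = FUELWOOD_PRICE_YUAN_PER_KG * fuel_kg
    share = fuel_value / (fuel_value + gas_cost)
    cook = np.clip(share + rng.normal(0, 0.03, n), 0.0, 1.0)
    stage = np.where(share > 0.6, 1, np.where(share >= 0.4, 2, 3))
    is_ttz = (h["site_id"] == config.site_ids[1]).to_numpy()
    p_livestock = np.clip(
        np.where(is_ttz, 0.79, 0.37) - 0.01 * logrem, 0.0, 1.0
    )
    livestock = (rng.random(n) < p_livestock).astype(int)
    extraction = np.where(
        is_ttz,
        10.0 ** (3.3 - 0.15 * logrem + rng.normal(0, 0.3, n)),
        np.nan,
    )
    energy = pd.DataFrame(
        {
            "household_id": h["household_id"].to_numpy(),
            "fuelwood_kg_per_year": np.round(fuel_kg, 1),
            "fuelwood_value_yuan": np.round(fuel_value, 1),
            "gas_cost_yuan": np.round(gas_cost, 1),
            "fuelwood_share": share,
            "fuelwood_share_cooking": cook,
            "ladder_stage": stage,
            "livestock": livestock,
            "extraction_cost_yuan": np.round(extraction, 1),
        }
    )

    # destination network: cities in provinces, log10 distance per site-city
    n_city = config.n_destination_cities
    n_prov = config.n_destination_provinces
    province = np.concatenate(
        [
            np.arange(min(n_prov, n_city)),
            rng.integers(0, n_prov, max(0, n_city - n_prov)),
        ]
    )
    lo, hi = config.distance_log10_range
    dest_rows = []
    for site in config.site_ids:
        log10d = rng.uniform(lo, hi, n_city)
        for c in range(n_city):
            dest_rows.append(
                {
                    "site_id": site,
                    "destination_id": f"D{c + 1:02d}",
                    "province_id": f"P{province[c] + 1:02d}",
                    "distance_km": round(10.0 ** log10d[c], 1),
                }
            )
    destinations = pd.DataFrame(dest_rows)

    migrants = migrants.copy()
    mig_city = np.empty(len(migrants), dtype=int)
    for site in config.site_ids:
        mask = (migrants["site_id"] == site).to_numpy()
        d = destinations.loc[
            destinations["site_id"] == site, "distance_km"
        ].to_numpy()
        # heavy-tailed popularity with mild short-distance preference
        pop = rng.dirichlet(np.full(n_city, 0.3))
        w = pop * 10.0 ** (-0.6 * (np.log10(d) - lo))
        w /= w.sum()
        mig_city[mask] = rng.choice(n_city, size=mask.sum(), p=w)
    migrants["destination_id"] = [f"D{c + 1:02d}" for c in mig_city]
    key = destinations.set_index(["site_id", "destination_id"])["distance_km"]
    migrants["distance_km"] = [
        key.loc[(s, d)]
        for s, d in zip(migrants["site_id"], migrants["destination_id"])
    ]
    return energy, destinations, migrants


# ---------------------------------------------------------------------------
# resident-group polygons and full bundle
# ---------------------------------------------------------------------------

def _build_groups(households: pd.DataFrame) -> list[ResidentGroup]:
    groups = []
    for (site, gid), sub in households.groupby(["site_id", "group_id"]):
        hull = MultiPoint(
            list(zip(sub["x"], sub["y"]))
        ).convex_hull.buffer(25.0, quad_segs=16)
        groups.append(
            ResidentGroup(
                group_id=gid,
                site_id=site,
                boundary=hull,
                member_household_ids=list(sub["household_id"]),
                group_remittance_total=float(sub["remittance_total_yuan"].sum()),
            )
        )
    return groups


def _build_truth(
    config: ScenarioConfig,
    households: pd.DataFrame,
    p_send: pd.Series,
    site_bg_term: dict[str, float],
    raster_truth: pd.DataFrame | None = None,
) -> SyntheticTruth:
    rem = households["remittance_total_yuan"].to_numpy()
    target = np.full(len(households), config.migrant_drift)
    recv = rem > 0
    target[recv] += config.remit_forest_slope * np.log10(rem[recv])
    bg = households["site_id"].map(site_bg_term).fillna(0.0).to_numpy()
    expected = pd.Series(
        target + bg, index=households["household_id"].to_numpy()
    )
    realized_f = realized_e = None
    if raster_truth is not None and len(raster_truth):
        rt = raster_truth.set_index("household_id").reindex(
            households["household_id"]
        )
        expected = pd.Series(
            rt["expected_delta_forest"].to_numpy(),
            index=households["household_id"].to_numpy(),
        )
        ef = rt["expected_delta_forest"].to_numpy()
        ee = rt["expected_delta_evi"].to_numpy()
        realized_f = float(ef[recv].mean() - ef[~recv].mean())
        realized_e = float(ee[recv].mean() - ee[~recv].mean())
    contrast_f = float(
        config.remit_forest_slope * np.log10(rem[recv]).mean()
    ) if recv.any() else 0.0
    contrast_e = float(
        config.remit_evi_slope * np.log10(rem[recv]).mean()
    ) if recv.any() else 0.0
    return SyntheticTruth(
        planted={
            "beta_ccfp_logit": config.beta_ccfp_logit,
            "beta_ccfp_amount": config.beta_ccfp_amount,
            "remit_forest_slope": config.remit_forest_slope,
            "remit_evi_slope": config.remit_evi_slope,
            "migrant_drift": config.migrant_drift,
        },
        expected_delta_forest=expected,
        remit_probability=p_send,
        planted_contrast_forest=contrast_f,
        planted_contrast_evi=contrast_e,
        background_drift=float(np.mean(list(site_bg_term.values())))
        if site_bg_term
        else 0.0,
        realized_contrast_forest=realized_f,
        realized_contrast_evi=realized_e,
    )


def generate_scenario(
    config: ScenarioConfig | None = None,
    include_rasters: bool = True,
    include_energy_flows: bool = True,
) -> ScenarioBundle:
    """Generate a complete synthetic study dataset with known truth.

    Set ``include_rasters=False`` for table-only replicates (model-recovery
    simulations that never touch the raster stage).
    """
    if config is None:
        config = ScenarioConfig()

    layout, _ = _generate_layout(config, _rng(config, _STREAM_LAYOUT))
    households = _generate_households(
        config, layout, _rng(config, _STREAM_HOUSEHOLD)
    )
    migrants, p_send = _generate_migrants(
        config, households, _rng(config, _STREAM_MIGRANT)
    )
    households = _aggregate_to_households(households, migrants)

    rasters: dict[str, RasterPair] = {}
    site_bg_term: dict[str, float] = {}
    raster_truth = None
    if include_rasters:
        raster_rng = _rng(config, _STREAM_RASTER)
        truth_frames = []
        for site in config.site_ids:
            pair, tf = generate_rasters(
                households[households["site_id"] == site],
                config,
                raster_rng,
                return_truth=True,
            )
            rasters[site] = pair
            truth_frames.append(tf)
            # balanced background turnover: zero expected net drift
            site_bg_term[site] = 0.0
        raster_truth = pd.concat(truth_frames, ignore_index=True)

    energy = destinations = None
    if include_energy_flows:
        energy, destinations, migrants = generate_energy_and_flows(
            households, migrants, config, _rng(config, _STREAM_ENERGY)
        )

    return ScenarioBundle(
        households=households,
        migrants=migrants,
        groups=_build_groups(households),
        rasters=rasters,
        destinations=destinations,
        energy=energy,
        truth=_build_truth(
            config, households, p_send, site_bg_term, raster_truth
        ),
        config=config,
    )
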