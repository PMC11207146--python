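"""Bootstrap treatment effects, associations and group-level regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest

from remiforest import buffers
from remiforest.effects import (
    ate_table,
    bootstrap_ate,
    group_association,
    remittance_forest_ols,
)
from remiforest.matching import estimate_propensity, match_controls

from conftest import null_config, small_config
from remiforest.synthetic import generate_scenario


def make_pairs_and_changes(diff_mean, n_pairs=120, seed=0, sd=0.05):
    """Synthetic matched pairs with a known treated-control contrast."""
    rng = np.random.default_rng(seed)
    treated = [f"T{i:03d}" for i in range(n_pairs)]
    controls = [f"C{i:03d}" for i in range(n_pairs)]
    pairs = pd.DataFrame({"control_id": controls, "treated_id": treated})
    rows = []
    for t, c in zip(treated, controls):
        rows.append({"unit_id": t, "radius": 100.0,
                     "delta_forest": rng.normal(diff_mean, sd),
                     "delta_evi": rng.normal(diff_mean / 2, sd / 2)})
        rows.append({"unit_id": c, "radius": 100.0,
                     "delta_forest": rng.normal(0.0, sd),
                     "delta_evi": rng.normal(0.0, sd / 2)})
    return pairs, pd.DataFrame(rows)


# --- bootstrap ATE ---------------------------------------------------------

def test_ate_recovers_planted_difference_and_is_seeded():
    pairs, changes = make_pairs_and_changes(0.04)
    res = bootstrap_ate(pairs, changes, n_reps=400, seed=1)[0]
    assert res.mean_diff == pytest.approx(0.04, abs=3 * res.boot_sd)
    assert res.occurrence_h1 > 90
    rerun = bootstrap_ate(pairs, changes, n_reps=400, seed=1)[0]
    assert rerun.occurrence_h1 == res.occurrence_h1
    assert rerun.boot_mean == res.boot_mean


def test_ate_null_occurrence_is_small_in_subsample_mode():
    """Pooled over independent null datasets, two-sided significance in
    60% subsample mode sits near the nominal 5% level."""
    rates_h1, rates_ols = [], []
    for seed in range(12):
        pairs, changes = make_pairs_and_changes(0.0, seed=200 + seed)
        r = bootstrap_ate(
            pairs, changes, n_reps=60, seed=seed, replace=False
        )[0]
        rates_h1.append(r.significance_rate_h1)
    pooled = np.mean(rates_h1)
    assert 1.0 < pooled < 11.0


def test_ate_sign_matches_planted_contrast():
    pairs, changes = make_pairs_and_changes(-0.03, seed=5)
    res = bootstrap_ate(pairs, changes, n_reps=200, seed=2)[0]
    assert res.mean_diff < 0
    assert res.occurrence_h1 == 0.0  # positive-direction occurrences absent


def test_ate_requires_minimum_pairs():
    pairs, changes = make_pairs_and_changes(0.0, n_pairs=3)
    with pytest.raises(ValueError, match="5"):
        bootstrap_ate(pairs, changes)


def test_ate_table_roundtrip():
    pairs, changes = make_pairs_and_changes(0.02)
    tab = ate_table(bootstrap_ate(pairs, changes, n_reps=50, seed=3))
    assert {"radius", "mean_diff", "occurrence_h1"} <= set(tab.columns)


# --- OLS association -------------------------------------------------------

def hh_frame(rem, ids=None):
    ids = ids or [f"H{i:03d}" for i in range(len(rem))]
    return pd.DataFrame(
        {"household_id": ids, "remittance_total_yuan": rem, "n_migrants": 1}
    )


def test_ols_slope_matches_hand_computation():
    """Five-point toy: slope equals the closed-form least-squares slope."""
    rem = [10.0, 100.0, 1000.0, 10_000.0, 100_000.0]
    y = [0.01, 0.03, 0.02, 0.05, 0.06]
    hh = hh_frame(rem)
    changes = pd.DataFrame(
        {"unit_id": hh["household_id"], "radius": 100.0, "delta_forest": y}
    )
    x = np.log10(rem)
    hand = np.sum((x - x.mean()) * (y - np.mean(y))) / np.sum((x - x.mean()) ** 2)
    res = remittance_forest_ols(hh, changes, radius=100.0, n_reps=10, seed=0)
    assert res.slope == pytest.approx(hand, abs=1e-12)
    assert res.n == 5


def test_ols_recovers_planted_slope():
    rng = np.random.default_rng(11)
    n = 250
    rem = 10 ** rng.uniform(2.5, 5.0, n)
    y = 0.011 * np.log10(rem) + rng.normal(0, 0.04, n)
    hh = hh_frame(rem)
    changes = pd.DataFrame(
        {"unit_id": hh["household_id"], "radius": 100.0, "delta_forest": y}
    )
    res = remittance_forest_ols(hh, changes, radius=100.0, n_reps=200, seed=4)
    assert abs(res.slope - 0.011) < 2 * res.se


def test_ols_requires_three_distinct_values():
    hh = hh_frame([100.0, 100.0, 100.0])
    changes = pd.DataFrame(
        {"unit_id": hh["household_id"], "radius": 100.0, "delta_forest": [0, 0, 0]}
    )
    with pytest.raises(ValueError, match="distinct"):
        remittance_forest_ols(hh, changes, radius=100.0, n_reps=10)


def test_ols_is_seed_reproducible():
    rng = np.random.default_rng(12)
    rem = 10 ** rng.uniform(2.0, 5.0, 100)
    hh = hh_frame(rem)
    changes = pd.DataFrame(
        {
            "unit_id": hh["household_id"],
            "radius": 100.0,
            "delta_forest": rng.normal(0, 0.05, 100),
        }
    )
    a = remittance_forest_ols(hh, changes, radius=100.0, n_reps=100, seed=7)
    b = remittance_forest_ols(hh, changes, radius=100.0, n_reps=100, seed=7)
    assert a.boot_mean == b.boot_mean and a.occurrence == b.occurrence


# --- group-level association -----------------------------------------------

def ring_frame(slopes, n_groups=40, seed=0, outlier=None):
    rng = np.random.default_rng(seed)
    rem = 10 ** rng.uniform(3.0, 5.5, n_groups)
    rows = []
    for label, slope in slopes.items():
        y = slope * np.log10(rem) + rng.normal(0, 0.02, n_groups)
        if outlier is not None:
            y[0] = outlier
        for g in range(n_groups):
            rows.append(
                {
                    "unit_id": f"G{g:02d}",
                    "label": label,
                    "delta_forest": y[g],
                    "delta_evi": y[g] / 2,
                    "group_remittance_total": rem[g],
                }
            )
    return pd.DataFrame(rows)


def test_group_association_identical_fits_without_outliers():
    tab = ring_frame({"within": 0.01})
    res = group_association(tab)
    row = res.iloc[0]
    assert row["n_outliers"] == 0
    assert row["slope_all"] == row["slope_robust"]


def test_outlier_exclusion_moves_slope_toward_truth():
    wins = 0
    for seed in range(10):
        tab = ring_frame({"within": 0.01}, seed=seed, outlier=1.5)
        res = group_association(tab).iloc[0]
        wins += abs(res["slope_robust"] - 0.01) < abs(res["slope_all"] - 0.01)
    assert wins >= 9


def test_group_association_requires_ten_groups():
    tab = ring_frame({"within": 0.01}, n_groups=5)
    with pytest.raises(ValueError, match="10"):
        group_association(tab)


# --- end-to-end on a planted scenario --------------------------------------

@pytest.fixture(scope="module")
def matched_small(small_bundle):
    b = small_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = estimate_propensity(b.households)
        match = match_controls(
            res.scores,
            b.households.set_index("household_id")["remittance_received"],
        )
        tabs = [
            buffers.radii_sweep(
                pair, b.households[b.households["site_id"] == site], [100]
            )
            for site, pair in b.rasters.items()
        ]
    return b, match, pd.concat(tabs, ignore_index=True)


def test_pipeline_ate_tracks_realized_truth(matched_small):
    """Bootstrap ATE on the planted scenario agrees with the generator's
    realised pair-level contrast within bootstrap uncertainty."""
    b, match, changes = matched_small
    res = bootstrap_ate(match.pairs, changes, n_reps=300, seed=5)[0]
    exp = b.truth.expected_delta_forest
    truth_pairs = (
        exp.reindex(match.pairs["treated_id"]).to_numpy()
        - exp.reindex(match.pairs["control_id"]).to_numpy()
    ).mean()
    assert res.mean_diff == pytest.approx(truth_pairs, abs=3 * res.boot_sd)


def test_pipeline_ols_recovers_planted_gamma(matched_small):
    b, _, changes = matched_small
    res = remittance_forest_ols(
        b.households, changes, radius=100.0, n_reps=100, seed=6
    )
    assert abs(res.slope - b.config.remit_forest_slope) < 2.5 * res.se
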