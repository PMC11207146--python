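"""Reading, validation and writing of all pipeline inputs and outputs.

Tables travel as CSV, resident-group polygons as GeoJSON, rasters as ESRI
ASCII grids (one ``.asc`` file per band: forest_t0, forest_t1, evi_t0,
evi_t1), configuration as YAML and results as JSON. Validation is total:
downstream stages never see orphan IDs, negative weights, inconsistent
remittance flags or unit-ambiguous areas (areas given in mu are converted
to m², 1 mu = 666.7 m²).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .constants import M2_PER_MU
from .types import RasterPair, ResidentGroup, ScenarioBundle

NODATA = -9999.0

HOUSEHOLD_REQUIRED = [
    "household_id",
    "site_id",
    "group_id",
    "x",
    "y",
    "sampling_weight",
    "ccfp_participant",
    "remittance_received",
    "remittance_total_yuan",
]
MIGRANT_REQUIRED = [
    "migrant_id",
    "household_id",
    "migration_years",
    "sent_remittance",
    "remittance_amount_yuan",
]


class ValidationError(ValueError):
    """Input tables violate the schema or referential integrity."""


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: list[str], name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table missing columns: {missing}")


def validate_tables(
    households: pd.DataFrame,
    migrants: pd.DataFrame,
    groups: list[ResidentGroup] | None = None,
) -> None:
    """Raise :class:`ValidationError` describing every integrity breach."""
    _check_columns(households, HOUSEHOLD_REQUIRED, "households")
    _check_columns(migrants, MIGRANT_REQUIRED, "migrants")
    problems = []

    dup = households["household_id"][households["household_id"].duplicated()]
    if len(dup):
        problems.append(f"duplicate household ids: {sorted(dup)[:5]}")
    dup = migrants["migrant_id"][migrants["migrant_id"].duplicated()]
    if len(dup):
        problems.append(f"duplicate migrant ids: {sorted(dup)[:5]}")

    orphans = sorted(
        set(migrants["household_id"]) - set(households["household_id"])
    )
    if orphans:
        problems.append(
            f"migrants reference absent households: {orphans[:5]}"
        )
    bad_w = households.loc[
        households["sampling_weight"] <= 0, "household_id"
    ]
    if len(bad_w):
        problems.append(f"non-positive sampling weights: {sorted(bad_w)[:5]}")

    flag = households["remittance_received"].astype(int)
    tot = households["remittance_total_yuan"].astype(float)
    bad = households.loc[(tot > 0) != (flag == 1), "household_id"]
    if len(bad):
        problems.append(
            f"remittance_total/flag mismatch for households: {sorted(bad)[:5]}"
        )
    mflag = migrants["sent_remittance"].astype(int)
    mamt = migrants["remittance_amount_yuan"].astype(float)
    bad = migrants.loc[(mamt > 0) != (mflag == 1), "migrant_id"]
    if len(bad):
        problems.append(
            f"remittance amount/flag mismatch for migrants: {sorted(bad)[:5]}"
        )
    if (migrants["migration_years"].astype(float) < 0.5).any():
        bad = migrants.loc[
            migrants["migration_years"].astype(float) < 0.5, "migrant_id"
        ]
        problems.append(
            f"migration under six months for migrants: {sorted(bad)[:5]}"
        )
    if "payment_annual_yuan" in households.columns:
        bad = households.loc[
            (households["ccfp_participant"] == 0)
            & (households["payment_annual_yuan"] > 0),
            "household_id",
        ]
        if len(bad):
            problems.append(
                f"non-participants with payments: {sorted(bad)[:5]}"
            )
    if groups is not None:
        known = {g.group_id for g in groups}
        bad = sorted(set(households["group_id"]) - known)
        if bad:
            problems.append(f"households reference absent groups: {bad[:5]}")
    if problems:
        raise ValidationError("; ".join(problems))


def normalise_units(households: pd.DataFrame) -> pd.DataFrame:
    """Convert any *_mu area column to m² (keeps the mu column as-is)."""
    df = households.copy()
    if "enrolled_area_mu" in df.columns and "enrolled_area_m2" not in df.columns:
        df["enrolled_area_m2"] = df["enrolled_area_mu"].astype(float) * M2_PER_MU
    return df


def load_tables(
    households_path: str | Path,
    migrants_path: str | Path,
    groups_path: str | Path | None = None,
) -> dict:
    """Load and validate the table bundle from CSV/GeoJSON files."""
    households = normalise_units(pd.read_csv(households_path))
    migrants = pd.read_csv(migrants_path)
    groups = read_groups(groups_path) if groups_path else None
    validate_tables(households, migrants, groups)
    out = {"households": households, "migrants": migrants}
    if groups is not None:
        out["groups"] = groups
    return out


# ---------------------------------------------------------------------------
# rasters: ESRI ASCII grids, one per band
# ---------------------------------------------------------------------------

def _write_asc(path: Path, grid: np.ndarray, cell_size: float, origin):
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\n"
        f"cellsize {cell_size:.6f}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    data = np.where(np.isnan(grid.astype(float)), NODATA, grid)
    # ASC rows run north->south; row 0 of our grids is the southern edge
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data[::-1], fmt="%.6g")


def _read_asc(path: Path):
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    data[data == header.get("nodata_value", NODATA)] = np.nan
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(f"grid shape mismatch in {path}")
    return data, header["cellsize"], (header["xllcorner"], header["yllcorner"])


def write_raster_pair(pair: RasterPair, directory: str | Path, prefix: str):
    """Write the four bands as ``{prefix}_{band}.asc`` text grids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for band in RasterPair.BAND_NAMES:
        _write_asc(
            directory / f"{prefix}_{band}.asc",
            pair.band(band),
            pair.cell_size,
            pair.origin,
        )


def read_raster_pair(
    directory: str | Path, prefix: str, site_id: str | None = None
) -> RasterPair:
    """Read a 4-band raster pair; checks alignment and K-band binariness."""
    directory = Path(directory)
    grids = {}
    meta = None
    for band in RasterPair.BAND_NAMES:
        path = directory / f"{prefix}_{band}.asc"
        if not path.exists():
            raise ValidationError(
                f"raster pair {prefix!r} incomplete: missing band {band}"
            )
        grid, cs, origin = _read_asc(path)
        if meta is None:
            meta = (cs, origin, grid.shape)
        elif (cs, origin, grid.shape) != meta:
            raise ValidationError(
                f"band {band} georeferencing disagrees with the other bands"
            )
        grids[band] = grid
    for band in ("forest_t0", "forest_t1"):
        vals = np.unique(grids[band][~np.isnan(grids[band])])
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValidationError(
                f"forest band {band} is not binary (values {vals[:5]})"
            )
        grids[band] = np.nan_to_num(grids[band]).astype(np.uint8)
    return RasterPair(
        forest_t0=grids["forest_t0"],
        forest_t1=grids["forest_t1"],
        evi_t0=grids["evi_t0"],
        evi_t1=grids["evi_t1"],
        cell_size=meta[0],
        origin=meta[1],
        site_id=site_id or prefix,
    )


# ---------------------------------------------------------------------------
# resident-group polygons (GeoJSON)
# ---------------------------------------------------------------------------

def write_groups(groups: list[ResidentGroup], path: str | Path):
    features = [
        {
            "type": "Feature",
            "geometry": mapping(g.boundary),
            "properties": {
                "group_id": g.group_id,
                "site_id": g.site_id,
                "member_household_ids": g.member_household_ids,
                "group_remittance_total": g.group_remittance_total,
            },
        }
        for g in groups
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_groups(path: str | Path) -> list[ResidentGroup]:
    doc = json.loads(Path(path).read_text())
    groups = []
    for feat in doc["features"]:
        props = feat["properties"]
        groups.append(
            ResidentGroup(
                group_id=props["group_id"],
                site_id=props["site_id"],
                boundary=shape(feat["geometry"]),
                member_household_ids=list(props["member_household_ids"]),
                group_remittance_total=float(
                    props.get("group_remittance_total", 0.0)
                ),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# bundle round-trip
# ---------------------------------------------------------------------------

def write_bundle(bundle: ScenarioBundle, directory: str | Path) -> Path:
    """Write a scenario bundle (tables, polygons, rasters, truth, config)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.households.to_csv(directory / "households.csv", index=False)
    bundle.migrants.to_csv(directory / "migrants.csv", index=False)
    if bundle.destinations is not None:
        bundle.destinations.to_csv(directory / "destinations.csv", index=False)
    if bundle.energy is not None:
        bundle.energy.to_csv(directory / "energy.csv", index=False)
    write_groups(bundle.groups, directory / "groups.geojson")
    for site, pair in bundle.rasters.items():
        write_raster_pair(pair, directory / "rasters", site)
    if bundle.truth is not None:
        (directory / "truth.json").write_text(
            json.dumps(bundle.truth.to_jsonable(), indent=1)
        )
    if bundle.config is not None:
        bundle.config.to_yaml(directory / "config.yml")
    return directory


def load_bundle(directory: str | Path) -> ScenarioBundle:
    """Load a bundle written by :func:`write_bundle` (truth not reloaded)."""
    directory = Path(directory)
    tables = load_tables(
        directory / "households.csv",
        directory / "migrants.csv",
        directory / "groups.geojson",
    )
    rasters = {}
    raster_dir = directory / "rasters"
    if raster_dir.exists():
        prefixes = sorted(
            {p.name.rsplit("_", 2)[0] for p in raster_dir.glob("*_forest_t0.asc")}
        )
        for prefix in prefixes:
            rasters[prefix] = read_raster_pair(raster_dir, prefix, prefix)
    destinations = None
    if (directory / "destinations.csv").exists():
        destinations = pd.read_csv(directory / "destinations.csv")
    energy = None
    if (directory / "energy.csv").exists():
        energy = pd.read_csv(directory / "energy.csv")
    config = None
    if (directory / "config.yml").exists():
        from .config import ScenarioConfig

        config = ScenarioConfig.from_yaml(directory / "config.yml")
    return ScenarioBundle(
        households=tables["households"],
        migrants=tables["migrants"],
        groups=tables["groups"],
        rasters=rasters,
        destinations=destinations,
        energy=energy,
        config=config,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):  # pragma: no cover - thin shim
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path: str | Path):
    Path(path).write_text(json.dumps(data, indent=1, cls=_NumpyEncoder))
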