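"""Occurrence-record cleaning and per-species climatic summaries.

The cleaning chain mirrors standard museum-record hygiene: coordinates are
checked against the reported country and repaired by trying sign flips and
an axis swap in a fixed order; off-land and wrong-country points are
rejected with a reason code; records are reduced to one per unique
(species, latitude, longitude); records missing any required variable are
dropped; and each species is summarized by per-variable medians
(temperature-family variables converted from tenths of degrees to degrees
Celsius by dividing by 10) plus its proportions of unique records per biome
and per realm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import ALL_VARIABLES, TEMPERATURE_VARIABLES, WorldSpec

__all__ = [
    "validate_record",
    "validate_table",
    "dedupe_unique",
    "filter_complete",
    "summarize_species",
    "SpeciesSummaries",
]

# candidate coordinate variants, in fixed trial order: as given, latitude
# sign flip, longitude sign flip, both flips, then the same four after
# swapping latitude and longitude
_VARIANTS = [
    lambda lat, lon: (lat, lon),
    lambda lat, lon: (-lat, lon),
    lambda lat, lon: (lat, -lon),
    lambda lat, lon: (-lat, -lon),
    lambda lat, lon: (lon, lat),
    lambda lat, lon: (-lon, lat),
    lambda lat, lon: (lon, -lat),
    lambda lat, lon: (-lon, -lat),
]


def validate_record(
    lat: float,
    lon: float,
    country: str,
    world: WorldSpec,
    tolerance: float = 1.0,
) -> tuple[tuple[float, float] | None, str | None]:
    """Repair or reject one coordinate pair.

    Returns ``((lat, lon), None)`` for the first variant that lies on land
    and within ``tolerance`` degrees of the reported country, else
    ``(None, reason)`` with reason ``unknown-country``, ``wrong-country``
    (some variant was on land but none near the reported country) or
    ``off-land``.
    """
    if country not in world.countries:
        return None, "unknown-country"
    saw_land = False
    for variant in _VARIANTS:
        vlat, vlon = variant(lat, lon)
        if not (-90.0 <= vlat <= 90.0 and -180.0 <= vlon <= 180.0):
            continue
        if not world.is_land(vlat, vlon):
            continue
        saw_land = True
        if world.country_distance(country, vlat, vlon) <= tolerance:
            return (vlat, vlon), None
    return None, ("wrong-country" if saw_land else "off-land")


def validate_table(
    records: pd.DataFrame, world: WorldSpec, tolerance: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized wrapper over ``validate_record``.

    Returns ``(repaired records, rejection log)``; the rejection log has
    columns ``record_id`` (if present), ``species`` and ``reason``.
    """
    kept_rows = []
    rejects = []
    for idx, row in records.iterrows():
        coords, reason = validate_record(
            float(row["lat"]), float(row["lon"]), row["country"], world, tolerance
        )
        if coords is None:
            rej = {"species": row["species"], "reason": reason}
            if "record_id" in row:
                rej["record_id"] = row["record_id"]
            rejects.append(rej)
        else:
            new = row.copy()
            new["lat"], new["lon"] = coords
            kept_rows.append(new)
    kept = pd.DataFrame(kept_rows).reset_index(drop=True) if kept_rows else \
        records.iloc[0:0].copy()
    rej_df = pd.DataFrame(rejects) if rejects else \
        pd.DataFrame(columns=["species", "reason"])
    return kept, rej_df


def dedupe_unique(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the first record per distinct (species, lat, lon) triple."""
    return records.drop_duplicates(subset=["species", "lat", "lon"],
                                   keep="first").reset_index(drop=True)


def filter_complete(
    records: pd.DataFrame, required_variables: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop records missing any required environmental variable.

    Returns ``(retained records, number dropped)``.
    """
    required = required_variables if required_variables is not None else ALL_VARIABLES
    if not required:
        raise ValueError("required_variables must be non-empty")
    mask = records[list(required)].notna().all(axis=1)
    return records[mask].reset_index(drop=True), int((~mask).sum())


@dataclass
class SpeciesSummaries:
    """Per-species medians and occupancy proportions.

    ``medians`` is indexed by species with an ``n_records`` column plus one
    column per variable (temperature-family variables in degrees Celsius);
    ``biome_props`` and ``realm_props`` are species x label tables of
    proportions of unique records, each row summing to 1.
    """

    medians: pd.DataFrame
    biome_props: pd.DataFrame
    realm_props: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.medians.index)


def summarize_species(
    records: pd.DataFrame,
    variables: list[str] | None = None,
    temperature_variables: list[str] | None = None,
) -> SpeciesSummaries:
    """Reduce validated, deduplicated, complete records to species summaries.

    Medians are taken per variable over the species' records; variables in
    ``temperature_variables`` (default: the tenths-of-a-degree bioclim
    layers) are divided by 10 before the median is taken, so reported
    medians are in degrees Celsius.  Biome and realm proportions are
    tabulated over the same unique records.  Species with zero records are
    simply absent from the output.
    """
    variables = variables if variables is not None else ALL_VARIABLES
    temps = (temperature_variables if temperature_variables is not None
             else TEMPERATURE_VARIABLES)
    work = records.copy()
    for var in temps:
        if var in work.columns:
            work[var] = work[var] / 10.0
    grouped = work.groupby("species", sort=True)
    med = grouped[list(variables)].median()
    med.insert(0, "n_records", grouped.size())
    biome = pd.crosstab(work["species"], work["biome"], normalize="index")
    realm = pd.crosstab(work["species"], work["realm"], normalize="index")
    return SpeciesSummaries(medians=med, biome_props=biome, realm_props=realm)
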