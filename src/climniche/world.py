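"""A deterministic toy world for exercising the occurrence pipeline.

The real analysis extracts country, biome, realm and 36 environmental
variables from GIS layers at museum-record coordinates.  Nothing about the
cleaning logic (country matching, coordinate swap/flip repair, land checks,
per-species summaries) depends on the map itself, so here the world is a
block of axis-aligned rectangular countries in an ocean, each country tiled
by biome patches carrying one Olson-style biome and one realm, with smooth
deterministic climate fields defined everywhere on land.  Temperature-family
variables are generated in tenths of degrees Celsius, as the raw bioclim
layers store them.

The land block occupies latitudes 2..28 and longitudes 35..95; any swap or
sign-flip of a land coordinate therefore leaves the land block, which is
what makes the repair logic exactly invertible on this world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WorldSpec",
    "toy_world",
    "generate_occurrences",
    "OLSON_BIOMES",
    "REALMS",
    "ALL_VARIABLES",
    "TEMPERATURE_VARIABLES",
]

OLSON_BIOMES = [
    "Tropical & Subtropical Moist Broadleaf Forests",
    "Tropical & Subtropical Dry Broadleaf Forests",
    "Tropical & Subtropical Coniferous Forests",
    "Temperate Broadleaf & Mixed Forests",
    "Temperate Conifer Forests",
    "Boreal Forests/Taiga",
    "Tropical & Subtropical Grasslands, Savannas & Shrublands",
    "Temperate Grasslands, Savannas & Shrublands",
    "Flooded Grasslands & Savannas",
    "Montane Grasslands & Shrublands",
    "Tundra",
    "Mediterranean Forests, Woodlands & Scrub",
    "Deserts & Xeric Shrublands",
    "Mangroves",
]

REALMS = [
    "Afrotropic",
    "Australasia",
    "Indomalaya",
    "Nearctic",
    "Neotropic",
    "Oceania",
    "Palearctic",
    "Antarctic",
]

SOIL_VARIABLES = [
    "gravel",
    "sand",
    "silt",
    "clay",
    "bulk_density",
    "org_carbon",
    "ph",
    "cec",
    "bs",
    "teb",
    "caco3",
    "caso4",
    "esp",
    "ece",
]

ALL_VARIABLES = (
    [f"BIO{i}" for i in range(1, 20)] + ["npp", "pet", "elev"] + SOIL_VARIABLES
)

# bioclim layers storing tenths of degrees C (indices, not the BIO3 index
# nor BIO4, a standard deviation x100 left on its native scale)
TEMPERATURE_VARIABLES = ["BIO1", "BIO2", "BIO5", "BIO6", "BIO7", "BIO8", "BIO9",
                         "BIO10", "BIO11"]


@dataclass(frozen=True)
class Rect:
    lat0: float
    lat1: float
    lon0: float
    lon1: float

    def contains(self, lat: float, lon: float) -> bool:
        return self.lat0 <= lat < self.lat1 and self.lon0 <= lon < self.lon1

    def distance(self, lat: float, lon: float) -> float:
        """Degrees from a point to the rectangle (0 inside)."""
        dlat = max(self.lat0 - lat, 0.0, lat - self.lat1)
        dlon = max(self.lon0 - lon, 0.0, lon - self.lon1)
        return math.hypot(dlat, dlon)


@dataclass(frozen=True)
class BiomePatch:
    rect: Rect
    biome: str
    realm: str
    country: str


@dataclass
class WorldSpec:
    """Rectangular-country world with biome patches and climate fields."""

    countries: dict[str, Rect]
    patches: list[BiomePatch]
    coeffs: dict[str, tuple[float, float, float, float, float]]
    seed: int = 0
    _realm_of: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self._realm_of = {}
        for p in self.patches:
            self._realm_of.setdefault(p.country, p.realm)

    # -- lookups -----------------------------------------------------------
    def country_at(self, lat: float, lon: float) -> str | None:
        for name, rect in self.countries.items():
            if rect.contains(lat, lon):
                return name
        return None

    def is_land(self, lat: float, lon: float) -> bool:
        return self.country_at(lat, lon) is not None

    def patch_at(self, lat: float, lon: float) -> BiomePatch | None:
        for p in self.patches:
            if p.rect.contains(lat, lon):
                return p
        return None

    def country_distance(self, name: str, lat: float, lon: float) -> float:
        if name not in self.countries:
            raise KeyError(name)
        return self.countries[name].distance(lat, lon)

    def climate_at(self, lat: float, lon: float) -> dict[str, float]:
        """Smooth deterministic fields; defined for every point (used only on
        land)."""
        out = {}
        for var, (base, blat, blon, amp, phase) in self.coeffs.items():
            out[var] = (
                base
                + blat * lat
                + blon * lon
                + amp * math.sin(lat / 7.0 + phase)
                + 0.5 * amp * math.cos(lon / 11.0 - phase)
            )
        return out


def toy_world(seed: int = 0) -> WorldSpec:
    """Six rectangular countries tiling the land block, each split into two
    biome patches; realms assigned per country.  Climate-field coefficients
    are drawn once from ``seed`` and are thereafter deterministic."""
    lat_rows = [(2.0, 15.0), (15.0, 28.0)]
    lon_cols = [(35.0, 55.0), (55.0, 75.0), (75.0, 95.0)]
    names = ["Aridia", "Sylvania", "Camponia", "Myrmecia", "Pheidolia", "Dolicia"]
    realms = ["Afrotropic", "Indomalaya", "Australasia",
              "Palearctic", "Indomalaya", "Neotropic"]
    # two biomes per country: (southern patch, northern or western half)
    biome_pairs = [
        ("Deserts & Xeric Shrublands",
         "Tropical & Subtropical Grasslands, Savannas & Shrublands"),
        ("Tropical & Subtropical Moist Broadleaf Forests",
         "Tropical & Subtropical Dry Broadleaf Forests"),
        ("Temperate Broadleaf & Mixed Forests",
         "Temperate Grasslands, Savannas & Shrublands"),
        ("Mediterranean Forests, Woodlands & Scrub",
         "Deserts & Xeric Shrublands"),
        ("Tropical & Subtropical Moist Broadleaf Forests",
         "Montane Grasslands & Shrublands"),
        ("Temperate Conifer Forests", "Tundra"),
    ]
    countries: dict[str, Rect] = {}
    patches: list[BiomePatch] = []
    i = 0
    for lat0, lat1 in lat_rows:
        for lon0, lon1 in lon_cols:
            name = names[i]
            realm = realms[i]
            rect = Rect(lat0, lat1, lon0, lon1)
            countries[name] = rect
            mid = 0.5 * (lat0 + lat1)
            b_lo, b_hi = biome_pairs[i]
            patches.append(BiomePatch(Rect(lat0, mid, lon0, lon1), b_lo, realm, name))
            patches.append(BiomePatch(Rect(mid, lat1, lon0, lon1), b_hi, realm, name))
            i += 1

    rng = np.random.default_rng(seed)
    coeffs: dict[str, tuple[float, float, float, float, float]] = {}
    # anchors keep the six focal variables on realistic raw scales
    anchor = {
        "BIO1": (260.0, -3.0),   # tenths deg C
        "BIO4": (600.0, 15.0),   # sd x 100, native scale
        "BIO6": (160.0, -4.0),
        "BIO7": (180.0, 5.0),
        "BIO11": (220.0, -4.0),
        "BIO12": (1600.0, -20.0),
    }
    for var in ALL_VARIABLES:
        base, blat = anchor.get(var, (float(rng.uniform(10, 300)),
                                      float(rng.uniform(-3, 3))))
        blon = float(rng.uniform(-1, 1))
        amp = float(rng.uniform(2, 25))
        phase = float(rng.uniform(0, 2 * np.pi))
        coeffs[var] = (base, blat, blon, amp, phase)
    return WorldSpec(countries=countries, patches=patches, coeffs=coeffs, seed=seed)


def generate_occurrences(
    tree_tips: list[str],
    world: WorldSpec,
    n_per_species: int | tuple[int, int] = (3, 30),
    error_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw occurrence records for each species and corrupt a fraction.

    Each species lives in one or two biome patches; records are uniform
    within the patch and carry the true country/biome/realm/climate of the
    point.  Corruption (applied per record at ``error_rates`` with keys
    ``swap``, ``sign_flip``, ``offshore``) alters only the stored
    coordinates; the truth table retains the uncorrupted values.

    Returns ``(records, truth)`` where ``truth`` has one row per record with
    the true coordinates and the corruption applied (``none`` / ``swap`` /
    ``sign_flip`` / ``offshore``).
    """
    if not tree_tips:
        raise ValueError("species list is empty")
    rates = {"swap": 0.0, "sign_flip": 0.0, "offshore": 0.0}
    if error_rates:
        rates.update(error_rates)
    for key, val in rates.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"error rate {key}={val} outside [0, 1]")
    if sum(rates.values()) > 1.0:
        raise ValueError("error rates must sum to <= 1")
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    rec_id = 0
    for sp in tree_tips:
        if isinstance(n_per_species, int):
            n = n_per_species
        else:
            n = int(rng.integers(n_per_species[0], n_per_species[1] + 1))
        n_home = 1 if rng.random() < 0.7 else 2
        home = rng.choice(len(world.patches), size=n_home, replace=False)
        for _ in range(n):
            patch = world.patches[int(rng.choice(home))]
            r = patch.rect
            lat = float(rng.uniform(r.lat0 + 1e-6, r.lat1 - 1e-6))
            lon = float(rng.uniform(r.lon0 + 1e-6, r.lon1 - 1e-6))
            env = world.climate_at(lat, lon)
            u = rng.random()
            if u < rates["swap"]:
                corrupt, clat, clon = "swap", lon, lat
            elif u < rates["swap"] + rates["sign_flip"]:
                corrupt, clat, clon = "sign_flip", -lat, lon
            elif u < sum(rates.values()):
                corrupt, clat, clon = "offshore", -45.0 - 10.0 * rng.random(), lon
            else:
                corrupt, clat, clon = "none", lat, lon
            row = {
                "record_id": rec_id,
                "species": sp,
                "lat": clat,
                "lon": clon,
                "country": patch.country,
                "biome": patch.biome,
                "realm": patch.realm,
            }
            row.update(env)
            rows.append(row)
            truth_rows.append(
                {
                    "record_id": rec_id,
                    "species": sp,
                    "true_lat": lat,
                    "true_lon": lon,
                    "corruption": corrupt,
                }
            )
            rec_id += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
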