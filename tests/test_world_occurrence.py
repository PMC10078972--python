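import numpy as np
import pandas as pd
import pytest

from climniche import (
    dedupe_unique,
    filter_complete,
    generate_occurrences,
    summarize_species,
    toy_world,
    validate_record,
    validate_table,
)
from climniche.world import ALL_VARIABLES

SPECIES = [f"sp{i}" for i in range(12)]


@pytest.fixture(scope="module")
def world():
    return toy_world(seed=0)


class TestWorld:
    def test_land_points_have_unique_country_and_biome(self, world):
        rng = np.random.default_rng(1)
        for _ in range(200):
            lat = rng.uniform(2.01, 27.99)
            lon = rng.uniform(35.01, 94.99)
            hits = [n for n, r in world.countries.items() if r.contains(lat, lon)]
            assert len(hits) == 1
            patches = [p for p in world.patches if p.rect.contains(lat, lon)]
            assert len(patches) == 1
            assert patches[0].country == hits[0]
            clim = world.climate_at(lat, lon)
            assert set(clim) == set(ALL_VARIABLES)
            assert all(np.isfinite(v) for v in clim.values())

    def test_sea_is_not_land(self, world):
        assert world.country_at(-10.0, 50.0) is None
        assert world.country_at(10.0, 150.0) is None

    def test_world_determinism(self):
        a, b = toy_world(3), toy_world(3)
        assert a.coeffs == b.coeffs


class TestValidateRecord:
    def test_clean_record_identity(self, world):
        coords, reason = validate_record(10.0, 40.0, "Aridia", world)
        assert reason is None
        assert coords == (10.0, 40.0)

    def test_swap_repair(self, world):
        coords, reason = validate_record(40.0, 10.0, "Aridia", world)
        assert reason is None
        assert coords == (10.0, 40.0)

    def test_sign_flip_repair(self, world):
        coords, reason = validate_record(-10.0, 40.0, "Aridia", world)
        assert coords == (10.0, 40.0) and reason is None

    def test_ocean_everywhere_rejected(self, world):
        coords, reason = validate_record(-50.0, 50.0, "Aridia", world)
        assert coords is None and reason == "off-land"

    def test_wrong_country(self, world):
        # valid land point, but the reported country is a distant rectangle
        coords, reason = validate_record(10.0, 40.0, "Camponia", world)
        assert coords is None and reason == "wrong-country"

    def test_unknown_country(self, world):
        coords, reason = validate_record(10.0, 40.0, "Atlantis", world)
        assert coords is None and reason == "unknown-country"


class TestGenerateAndClean:
    def test_error_free_records_validate_unchanged(self, world):
        records, truth = generate_occurrences(SPECIES, world, (2, 6), {}, seed=5)
        kept, rejects = validate_table(records, world)
        assert len(rejects) == 0
        np.testing.assert_allclose(kept["lat"], truth["true_lat"])
        np.testing.assert_allclose(kept["lon"], truth["true_lon"])

    def test_swap_corruption_fully_repaired(self, world):
        records, truth = generate_occurrences(
            SPECIES, world, (2, 6), {"swap": 1.0}, seed=6
        )
        assert (truth["corruption"] == "swap").all()
        kept, rejects = validate_table(records, world)
        assert len(rejects) == 0  # recovery rate 1.0 on this world
        np.testing.assert_allclose(kept["lat"], truth["true_lat"])
        np.testing.assert_allclose(kept["lon"], truth["true_lon"])

    def test_offshore_corruption_rejected(self, world):
        records, truth = generate_occurrences(
            SPECIES, world, 4, {"offshore": 1.0}, seed=7
        )
        kept, rejects = validate_table(records, world)
        assert len(kept) == 0
        assert (rejects["reason"] == "off-land").all()

    def test_generator_determinism_and_empty_species(self, world):
        a, _ = generate_occurrences(SPECIES, world, (2, 6), {"swap": 0.3}, seed=8)
        b, _ = generate_occurrences(SPECIES, world, (2, 6), {"swap": 0.3}, seed=8)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            generate_occurrences([], world, 3, {}, seed=0)


class TestDedupeFilter:
    def test_dedupe_keeps_first(self):
        df = pd.DataFrame(
            {
                "species": ["x", "x", "x", "y"],
                "lat": [1.0, 1.0, 1.0, 1.0],
                "lon": [2.0, 2.0, 3.0, 2.0],
                "tag": ["first", "dup", "keep", "other-species"],
            }
        )
        out = dedupe_unique(df)
        assert list(out["tag"]) == ["first", "keep", "other-species"]

    def test_dedupe_matches_set_oracle(self, world):
        records, _ = generate_occurrences(SPECIES, world, (2, 6), {}, seed=9)
        # force duplicates by rounding coordinates coarsely
        records["lat"] = records["lat"].round(0)
        records["lon"] = records["lon"].round(0)
        out = dedupe_unique(records)
        oracle = {(s, la, lo) for s, la, lo in
                  zip(records["species"], records["lat"], records["lon"])}
        assert len(out) == len(oracle)

    def test_filter_complete_row_scan_oracle(self, world):
        records, _ = generate_occurrences(SPECIES, world, 5, {}, seed=10)
        rng = np.random.default_rng(0)
        for col in ["BIO1", "npp", "clay"]:
            rows = rng.choice(len(records), size=4, replace=False)
            records.loc[rows, col] = np.nan
        kept, n_dropped = filter_complete(records)
        oracle = records[ALL_VARIABLES].notna().all(axis=1)
        assert n_dropped == int((~oracle).sum())
        assert list(kept["record_id"]) == list(records.loc[oracle, "record_id"])

    def test_no_missing_is_identity(self, world):
        records, _ = generate_occurrences(SPECIES, world, 3, {}, seed=11)
        kept, n_dropped = filter_complete(records)
        assert n_dropped == 0 and len(kept) == len(records)


class TestSummaries:
    def _single_record_df(self, bio1):
        row = {"species": "x", "lat": 1.0, "lon": 2.0, "country": "A",
               "biome": "Tundra", "realm": "Palearctic"}
        row.update({v: 0.0 for v in ALL_VARIABLES})
        row["BIO1"] = bio1
        return pd.DataFrame([row])

    def test_temperature_tenths_conversion(self):
        out = summarize_species(self._single_record_df(215.0))
        assert out.medians.loc["x", "BIO1"] == pytest.approx(21.5)
        assert out.medians.loc["x", "n_records"] == 1

    def test_median_of_three(self):
        rows = []
        for v in [100.0, 300.0, 200.0]:
            df = self._single_record_df(0.0)
            df["BIO12"] = v
            rows.append(df)
        out = summarize_species(pd.concat(rows, ignore_index=True))
        assert out.medians.loc["x", "BIO12"] == pytest.approx(200.0)

    def test_biome_proportions(self):
        rows = []
        for i in range(10):
            df = self._single_record_df(0.0)
            df["biome"] = ("Deserts & Xeric Shrublands" if i < 4
                           else "Mangroves")
            rows.append(df)
        out = summarize_species(pd.concat(rows, ignore_index=True))
        assert out.biome_props.loc["x", "Deserts & Xeric Shrublands"] == pytest.approx(0.4)
        assert out.biome_props.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_pipeline_idempotent_and_matches_truth(self, world):
        records, truth = generate_occurrences(SPECIES, world, (2, 8),
                                              {"swap": 0.5}, seed=12)

        def chain(df):
            kept, _ = validate_table(df, world)
            kept, _ = filter_complete(dedupe_unique(kept))
            return kept

        once = chain(records)
        twice = chain(once)
        s1 = summarize_species(once)
        s2 = summarize_species(twice)
        pd.testing.assert_frame_equal(s1.medians, s2.medians)
        pd.testing.assert_frame_equal(s1.biome_props, s2.biome_props)
        # corruption-free reconstruction: medians equal direct computation
        # from the true coordinates' climate
        direct = {}
        for sp, grp in once.groupby("species"):
            direct[sp] = np.median(grp["BIO12"])
        for sp, val in direct.items():
            assert s1.medians.loc[sp, "BIO12"] == pytest.approx(val)
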