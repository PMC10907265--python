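import logging

import numpy as np
import pandas as pd
import pytest

from fertgrowth import (
    ModelDataset,
    PredictorSpec,
    ValidationError,
    build_model_subset,
    read_records,
    standardize,
    validate_records,
    write_records,
)


class TestReadWrite:
    def test_round_trip_preserves_cells(self, toy_records, toy_meta, tmp_path):
        p = tmp_path / "data.csv"
        write_records(toy_records, p)
        records, meta = read_records(p, None, [PredictorSpec("livestock", "log1p_then_zscore")])
        pd.testing.assert_frame_equal(records, toy_records)
        # re-serialize and diff at the byte level
        p2 = tmp_path / "data2.csv"
        write_records(records, p2)
        assert p.read_text() == p2.read_text()

    def test_parities_and_raw_predictors_preserved(self, toy_records, tmp_path):
        p = tmp_path / "d.csv"
        write_records(toy_records, p)
        records, _ = read_records(p)
        assert records["live_births"].tolist() == [1, 4, 7]
        assert records["livestock"].tolist() == [0.0, 5.0, 50.0]
        assert "livestock__z" not in records.columns  # transform deferred

    def test_missing_cells_preserved_not_imputed(self, toy_records, tmp_path):
        toy = toy_records.copy()
        toy.loc[1, "livestock"] = np.nan
        p = tmp_path / "d.csv"
        write_records(toy, p)
        records, _ = read_records(p)
        assert records["livestock"].isna().tolist() == [False, True, False]


class TestValidation:
    def test_negative_parity_rejected_naming_row(self, toy_records):
        bad = toy_records.copy()
        bad.loc[2, "live_births"] = -1
        with pytest.raises(ValidationError, match=r"live_births.*\[2\]"):
            validate_records(bad)

    def test_age_below_maturity_rejected_with_woman_id(self, toy_records):
        bad = toy_records.copy()
        bad.loc[0, "age"] = 12.0
        with pytest.raises(ValidationError, match="age below 14.*w1"):
            validate_records(bad)

    def test_unknown_population_rejected(self, toy_records, toy_meta):
        bad = toy_records.copy()
        bad.loc[0, "population_id"] = "Z"
        with pytest.raises(ValidationError, match="unknown population"):
            validate_records(bad, toy_meta)

    def test_proportion_predictor_bounds(self, toy_records):
        bad = toy_records.assign(diet_farmed=[0.2, 1.4, 0.5])
        with pytest.raises(ValidationError, match="diet_farmed"):
            validate_records(bad, specs=[PredictorSpec("diet_farmed", "zscore")])

    def test_malformed_csv_names_file(self, tmp_path):
        p = tmp_path / "broken.csv"
        p.write_text('woman_id,population_id,age,live_births\n"w1,A,20,1\nw2,A')
        with pytest.raises(ValidationError, match="broken.csv"):
            read_records(p)


class TestStandardize:
    def test_log1p_then_zscore_hand_computed(self):
        # raw {0, e-1, e^2-1} -> log1p {0, 1, 2} -> sample-SD z {-1, 0, 1}
        df = pd.DataFrame(
            {
                "woman_id": list("abc"),
                "population_id": ["P"] * 3,
                "age": [20.0, 30.0, 40.0],
                "live_births": [1, 2, 3],
                "livestock": [0.0, np.e - 1, np.e**2 - 1],
            }
        )
        out = standardize(df, PredictorSpec("livestock", "log1p_then_zscore"))
        np.testing.assert_allclose(out["livestock__z"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_zscore_moments_within_population(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "woman_id": [f"w{i}" for i in range(n)],
                "population_id": rng.choice(["A", "B", "C"], n),
                "age": rng.uniform(14, 80, n),
                "live_births": rng.poisson(3, n),
                "diet_farmed": rng.random(n),
            }
        )
        out = standardize(df, PredictorSpec("diet_farmed", "zscore"))
        for _, grp in out.groupby("population_id"):
            assert abs(grp["diet_farmed__z"].mean()) < 1e-10
            assert abs(grp["diet_farmed__z"].std(ddof=1) - 1) < 1e-10

    def test_within_population_scoping_ignores_scale_shifts(self, rng):
        # two populations on disjoint raw scales yield identical z-vectors
        base = rng.random(80)
        df = pd.DataFrame(
            {
                "woman_id": [f"w{i}" for i in range(160)],
                "population_id": ["A"] * 80 + ["B"] * 80,
                "age": 30.0,
                "live_births": 2,
                "x": np.concatenate([base, base * 50 + 1000]),
            }
        )
        out = standardize(df, PredictorSpec("x", "zscore"))
        za = np.sort(out.loc[out.population_id == "A", "x__z"].to_numpy())
        zb = np.sort(out.loc[out.population_id == "B", "x__z"].to_numpy())
        np.testing.assert_allclose(za, zb, atol=1e-9)

    def test_zero_variance_population_dropped_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "woman_id": list("abcd"),
                "population_id": ["A", "A", "B", "B"],
                "age": 30.0,
                "live_births": 2,
                "x": [0.3, 0.3, 0.1, 0.9],
            }
        )
        with caplog.at_level(logging.WARNING):
            out = standardize(df, PredictorSpec("x", "zscore"))
        assert "zero within-population variance" in caplog.text
        assert out.loc[out.population_id == "A", "x__z"].isna().all()
        assert out.loc[out.population_id == "B", "x__z"].notna().all()

    def test_binary_passthrough(self):
        df = pd.DataFrame(
            {
                "woman_id": list("ab"),
                "population_id": ["A", "A"],
                "age": 30.0,
                "live_births": 2,
                "urban": [0.0, 1.0],
            }
        )
        out = standardize(df, PredictorSpec("urban", "binary"))
        assert out["urban__z"].tolist() == [0.0, 1.0]


class TestModelSubset:
    def _records(self, pops, missing_pops, n_per=10):
        rows = []
        for p in pops:
            for i in range(n_per):
                rows.append(
                    dict(
                        woman_id=f"{p}{i}",
                        population_id=p,
                        age=20.0 + i,
                        live_births=i % 5,
                        x=np.nan if p in missing_pops else 0.1 * i,
                    )
                )
        return pd.DataFrame(rows)

    def test_subset_keeps_only_populations_with_data(self):
        pops = [f"p{i}" for i in range(5)]
        df = self._records(pops, missing_pops={"p4"})
        ds = build_model_subset(df, None, PredictorSpec("x", "zscore"))
        assert ds.pop_ids == pops[:4]
        assert ds.n == 40

    def test_predictor_everywhere_keeps_everything(self):
        df = self._records(["a", "b"], missing_pops=set())
        ds = build_model_subset(df, None, PredictorSpec("x", "zscore"))
        assert ds.n == len(df)

    def test_empty_subset_raises(self):
        df = self._records(["a"], missing_pops={"a"})
        with pytest.raises(ValueError, match="no populations provide"):
            build_model_subset(df, None, PredictorSpec("x", "zscore"))

    def test_subset_monotone_under_added_missingness(self):
        pops = [f"p{i}" for i in range(5)]
        df = self._records(pops, missing_pops=set())
        sizes = []
        for k in range(4):
            df2 = df.copy()
            df2.loc[df2.population_id.isin(pops[:k]), "x"] = np.nan
            sizes.append(build_model_subset(df2, None, PredictorSpec("x", "zscore")).n)
        assert sizes == sorted(sizes, reverse=True)

    def test_group_index_orders_mi_levels(self, toy_records, toy_meta):
        ds = build_model_subset(toy_records, toy_meta, None)
        codes, levels = ds.group_index("market_integration")
        assert levels == ["low", "high"]
        assert codes.tolist() == [0, 1]  # pop A low, pop B high
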