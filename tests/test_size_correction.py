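import numpy as np
import pandas as pd
import pytest

import trussmorph as tm
from trussmorph.errors import ValidationError
from trussmorph.landmark_io import TraitTable
from trussmorph.size_correction import (
    SizeCorrectionModel,
    fit_allometric_slopes,
    m_transform,
    ratio_log_transform,
)
from trussmorph.truss import DistanceTable


def make_traits(rows, roles, species):
    data = pd.DataFrame(rows)
    data.index = pd.Index([f"s{i}" for i in range(len(data))], name="specimen_id")
    return TraitTable(
        data=data,
        species=pd.Series(species, index=data.index, name="species"),
        roles=roles,
    )


def make_distances(values: dict, species, sl=None, sl_edge="SLv"):
    df = pd.DataFrame(values)
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="specimen_id")
    sp = pd.Series(list(species), index=df.index, name="species")
    return DistanceTable(values=df, species=sp, sl_edge=sl_edge if sl_edge in df else None)


class TestRatioLog:
    def test_sl_ratio_value(self):
        t = make_traits(
            {"SL": [10.0, 10.0], "MBD": [2.0, 2.0]},
            {"SL": "morphometric", "MBD": "morphometric"},
            ["A", "A"],
        )
        out = ratio_log_transform(t, {"MBD": "SL"})
        assert out.values["MBD"].iloc[0] == pytest.approx(np.log10(0.2), abs=1e-9)
        assert out.values["MBD"].iloc[0] == pytest.approx(-0.698970, abs=1e-6)

    def test_hl_ratio_value(self):
        t = make_traits(
            {"SL": [10.0, 12.0], "HL": [2.0, 2.0], "ED": [1.0, 1.0]},
            {"SL": "morphometric", "HL": "morphometric", "ED": "morphometric"},
            ["A", "A"],
        )
        out = ratio_log_transform(t, {"ED": "HL", "HL": "SL"})
        assert out.values["ED"].iloc[0] == pytest.approx(np.log10(0.5))

    def test_sl_dropped_and_meristics_pass_through(self):
        t = make_traits(
            {"SL": [10.0, 20.0], "MBD": [2.0, 4.0], "DFR": [9, 9]},
            {"SL": "morphometric", "MBD": "morphometric", "DFR": "meristic"},
            ["A", "B"],
        )
        out = ratio_log_transform(t, {"MBD": "SL"})
        assert "SL" not in out.variables
        np.testing.assert_allclose(out.values["DFR"], np.log10(9))

    def test_variable_equal_to_denominator_flagged_zero_variance(self):
        t = make_traits(
            {"SL": [10.0, 20.0], "X": [10.0, 20.0]},
            {"SL": "morphometric", "X": "morphometric"},
            ["A", "A"],
        )
        out = ratio_log_transform(t, {"X": "SL"})
        np.testing.assert_allclose(out.values["X"], 0.0)
        assert out.zero_variance == ["X"]

    def test_zero_denominator_names_specimen(self):
        t = make_traits(
            {"SL": [10.0, 0.0], "MBD": [2.0, 2.0]},
            {"SL": "morphometric", "MBD": "morphometric"},
            ["A", "A"],
        )
        with pytest.raises(ValidationError, match="s1"):
            ratio_log_transform(t, {"MBD": "SL"})


class TestFitAllometricSlopes:
    def test_isometry_gives_slope_one(self):
        sl = pd.Series([5.0, 8.0, 11.0, 6.0, 9.0, 12.0])
        values = {"d1": (0.4 * sl).tolist(), "d2": (0.07 * sl).tolist()}
        table = make_distances(values, ["A"] * 3 + ["B"] * 3)
        sl.index = table.values.index
        model = fit_allometric_slopes(table, sl_values=sl)
        assert model.b["d1"] == pytest.approx(1.0, abs=1e-12)
        assert model.b["d2"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_measurement_gives_slope_zero(self):
        sl = pd.Series([5.0, 8.0, 11.0])
        table = make_distances({"d1": [2.0, 2.0, 2.0]}, ["A"] * 3)
        sl.index = table.values.index
        model = fit_allometric_slopes(table, sl_values=sl)
        assert model.b["d1"] == pytest.approx(0.0, abs=1e-12)

    def test_sl_mean_is_arithmetic_mean(self):
        sl = pd.Series([5.0, 15.0, 10.0])
        table = make_distances({"d1": [1.0, 2.0, 3.0]}, ["A"] * 3)
        sl.index = table.values.index
        model = fit_allometric_slopes(table, sl_values=sl)
        assert model.sl_mean == pytest.approx(10.0)
        assert model.log_sl_mean == pytest.approx(1.0)

    def test_recovers_known_exponent(self):
        """Generated data with allometric exponent 0.8 yields b within 0.8 ± 0.05."""
        models = tm.default_barbinae_models(shape_sd=0.001)
        for m in models:
            m.allometric_b = 0.8
        ds = tm.generate(
            tm.GeneratorConfig(species=models, n_per_species=[40] * 5, seed=11)
        )
        scheme = tm.full_truss_scheme(14)
        dist = tm.compute_distances(ds.configurations, scheme)
        reduced = tm.exclude_sl_edge(dist)
        sl = ds.ground_truth["sl"]
        model = fit_allometric_slopes(reduced, sl_values=sl)
        fitted = np.array(list(model.b.values()))
        assert abs(fitted.mean() - 0.8) < 0.05
        assert np.all(np.abs(fitted - 0.8) < 0.05)

    def test_zero_within_group_sl_variance_errors(self):
        sl = pd.Series([5.0, 5.0, 5.0])
        table = make_distances({"d1": [1.0, 2.0, 3.0]}, ["A"] * 3)
        sl.index = table.values.index
        with pytest.raises(ValidationError, match="log SL"):
            fit_allometric_slopes(table, sl_values=sl)


class TestMTransform:
    def _table_and_sl(self):
        table = make_distances({"d1": [10.0, 20.0, 15.0]}, ["A"] * 3)
        sl = pd.Series([20.0, 10.0, 5.0], index=table.values.index)
        return table, sl

    def test_b_zero_is_plain_log(self):
        table, sl = self._table_and_sl()
        model = SizeCorrectionModel(
            method="m_transform", b={"d1": 0.0}, sl_mean=10.0, log_sl_mean=1.0
        )
        out = m_transform(table, model, sl_values=sl)
        np.testing.assert_allclose(out.values["d1"], np.log10(table.values["d1"]))

    def test_specimen_at_mean_sl_unchanged(self):
        table, sl = self._table_and_sl()
        model = SizeCorrectionModel(
            method="m_transform", b={"d1": 2.7}, sl_mean=10.0, log_sl_mean=1.0
        )
        out = m_transform(table, model, sl_values=sl)
        # second specimen has SL == sl_mean
        assert out.values["d1"].iloc[1] == pytest.approx(np.log10(20.0))

    def test_direct_evaluation(self):
        table, sl = self._table_and_sl()
        model = SizeCorrectionModel(
            method="m_transform", b={"d1": 1.0}, sl_mean=10.0, log_sl_mean=1.0
        )
        out = m_transform(table, model, sl_values=sl)
        # M = 10, b = 1, SL = 20, SL_mean = 10 -> 1 - log10(2)
        assert out.values["d1"].iloc[0] == pytest.approx(1 - np.log10(2))
        assert out.values["d1"].iloc[0] == pytest.approx(0.698970, abs=1e-6)

    def test_nonpositive_measurement_errors(self):
        table = make_distances({"d1": [1.0, 0.0]}, ["A", "A"])
        sl = pd.Series([5.0, 6.0], index=table.values.index)
        model = SizeCorrectionModel(
            method="m_transform", b={"d1": 1.0}, sl_mean=5.5, log_sl_mean=np.log10(5.5)
        )
        with pytest.raises(ValidationError):
            m_transform(table, model, sl_values=sl)


class TestSizeFreeProperty:
    def test_self_fitted_correction_removes_size(self, rng):
        """Pooled within-group correlation of every corrected variable with
        log SL is zero to numerical tolerance after self-fitted m-transform."""
        n = 60
        species = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        sl = pd.Series(rng.uniform(5, 25, n))
        values = {}
        for j in range(6):
            b_true = rng.uniform(0.6, 1.4)
            noise = rng.normal(0, 0.01, n)
            values[f"d{j}"] = (0.3 * sl**b_true * 10**noise).tolist()
        table = make_distances(values, species)
        sl.index = table.values.index
        model = fit_allometric_slopes(table, sl_values=sl)
        out = m_transform(table, model, sl_values=sl)

        log_sl = np.log10(sl)
        x = log_sl - log_sl.groupby(out.species).transform("mean")
        for var in out.variables:
            y = out.values[var]
            y = y - y.groupby(out.species).transform("mean")
            assert abs(float((x * y).sum())) < 1e-8

    def test_order_invariance(self, rng):
        n = 12
        species = ["A"] * 6 + ["B"] * 6
        sl = pd.Series(rng.uniform(5, 25, n))
        table = make_distances({"d1": (0.5 * sl**0.9).tolist()}, species)
        sl.index = table.values.index
        model = fit_allometric_slopes(table, sl_values=sl)
        out = m_transform(table, model, sl_values=sl)

        perm = rng.permutation(n)
        idx = table.values.index[perm]
        shuffled = DistanceTable(
            values=table.values.loc[idx], species=table.species.loc[idx], sl_edge=None
        )
        model2 = fit_allometric_slopes(shuffled, sl_values=sl.loc[idx])
        out2 = m_transform(shuffled, model2, sl_values=sl.loc[idx])
        assert model2.b["d1"] == pytest.approx(model.b["d1"], rel=1e-12)
        pd.testing.assert_frame_equal(out2.values.sort_index(), out.values.sort_index())
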