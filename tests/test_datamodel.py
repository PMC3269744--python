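"""Descriptor/activity loading, the packaged fixture, and pIC50 conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svrqsar as q
from svrqsar.datamodel import DataValidationError, read_activity_table


class TestReadDescriptorTable:
    def test_well_formed_csv(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound,a,b,c\n" +
                        "\n".join(f"m{i},{i},{i * 2},{i * 0.5}" for i in range(5)))
        mat = q.read_descriptor_table(path)
        assert mat.n_compounds == 5
        assert mat.n_descriptors == 3
        assert mat.descriptor_names == ["a", "b", "c"]

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("compound\ta\tb\nm1\t1\t2\nm2\t3\t4\n")
        mat = q.read_descriptor_table(path)
        assert mat.values.tolist() == [[1.0, 2.0], [3.0, 4.0]]

    def test_duplicate_descriptor_header_names_offender(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound,a,a\nm1,1,2\n")
        with pytest.raises(DataValidationError, match="a"):
            q.read_descriptor_table(path)

    def test_duplicate_compound_id_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound,a\nm1,1\nm1,2\n")
        with pytest.raises(DataValidationError, match="m1"):
            q.read_descriptor_table(path)

    def test_non_numeric_cell_names_column(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound,a,b\nm1,1,x\nm2,2,3\n")
        with pytest.raises(DataValidationError, match="'b'"):
            q.read_descriptor_table(path)

    def test_missing_value_rejected_not_imputed(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("compound,a,b\nm1,1,\nm2,2,3\n")
        with pytest.raises(DataValidationError, match="missing"):
            q.read_descriptor_table(path)

    def test_round_trip_lossless(self, tmp_path, rng):
        frame = pd.DataFrame(rng.standard_normal((20, 500)),
                             index=[f"m{i}" for i in range(20)],
                             columns=[f"d{j}" for j in range(500)])
        mat = q.DescriptorMatrix(frame)
        path = tmp_path / "big.csv"
        q.write_descriptor_table(mat, path)
        back = q.read_descriptor_table(path)
        assert back.descriptor_names == mat.descriptor_names
        assert np.allclose(back.values, mat.values, atol=1e-12, rtol=0)


class TestArc111Fixture:
    def test_counts(self):
        table = q.load_arc111_fixture()
        assert len(table.train_ids) == 18
        assert len(table.test_ids) == 4
        assert len(table.ids("theoretical")) == 12

    def test_activity_range(self):
        table = q.load_arc111_fixture()
        expt = table.frame[table.frame["split"] != "theoretical"]["pIC50"]
        assert expt.min() == 6.071
        assert expt.max() == 9.523

    def test_known_compound_activity(self):
        table = q.load_arc111_fixture()
        assert table.frame.loc["9", "pIC50"] == 9.523

    def test_test_set_membership(self):
        table = q.load_arc111_fixture()
        assert sorted(table.test_ids) == ["10", "15", "20", "8"]

    def test_theoretical_predictions_are_metadata_not_targets(self):
        table = q.load_arc111_fixture()
        theo = table.frame[table.frame["split"] == "theoretical"]
        assert theo["pIC50"].isna().all()
        assert np.isfinite(theo["reference_pred"]).all()


class TestPic50Conversion:
    @pytest.mark.parametrize("ic50_um,expected", [(1.0, 6.0), (1e-3, 9.0), (100.0, 4.0)])
    def test_molar_log_convention(self, ic50_um, expected):
        assert q.ic50_to_pic50(ic50_um) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            q.ic50_to_pic50(0.0)
        with pytest.raises(ValueError):
            q.ic50_to_pic50(-1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_round_trip_inverse(self, x):
        assert q.pic50_to_ic50(q.ic50_to_pic50(x)) == pytest.approx(x, rel=1e-12)


class TestMakeModelingDataset:
    def _toy(self, rng, n=10):
        ids = [f"m{i}" for i in range(n)]
        frame = pd.DataFrame(rng.standard_normal((n, 4)), index=ids,
                             columns=["a", "b", "c", "d"])
        split = ["test" if i < 2 else "train" for i in range(n)]
        act = q.ActivityTable(pd.DataFrame(
            {"pIC50": rng.standard_normal(n), "split": split},
            index=pd.Index(ids, name="compound")))
        return q.DescriptorMatrix(frame), act

    def test_constant_column_removed_and_logged(self, rng, caplog):
        mat, act = self._toy(rng)
        mat.frame.loc[act.train_ids, "c"] = 3.0  # constant on training rows only
        import logging
        with caplog.at_level(logging.INFO, logger="svrqsar.datamodel"):
            data = q.make_modeling_dataset(mat, act)
        assert data.removed_constant == ["c"]
        assert "c" not in data.descriptor_names
        assert any("constant" in rec.message for rec in caplog.records)

    def test_training_columns_standardized(self, rng):
        mat, act = self._toy(rng)
        data = q.make_modeling_dataset(mat, act, scale=True)
        assert np.allclose(data.X_train.mean(), 0.0, atol=1e-10)
        assert np.allclose(data.X_train.std(ddof=0), 1.0, atol=1e-10)

    def test_test_rows_scaled_with_training_parameters_only(self, rng):
        mat, act = self._toy(rng, n=20)
        data = q.make_modeling_dataset(mat, act, scale=True)
        raw_test = mat.frame.loc[act.test_ids]
        # a scaler refit on the test rows must give different values
        refit = (raw_test - raw_test.mean()) / raw_test.std(ddof=0)
        assert not np.allclose(data.X_test.to_numpy(), refit.to_numpy())
        train_stats = (raw_test - data.scaler.center) / data.scaler.scale
        assert np.allclose(data.X_test.to_numpy(), train_stats.to_numpy())

    def test_missing_compound_named_in_error(self, rng):
        mat, act = self._toy(rng)
        mat = q.DescriptorMatrix(mat.frame.drop(index="m5"))
        with pytest.raises(DataValidationError, match="m5"):
            q.make_modeling_dataset(mat, act)


def test_activity_table_round_trip(tmp_path):
    table = q.load_arc111_fixture()
    path = tmp_path / "a.csv"
    from svrqsar.datamodel import write_activity_table
    write_activity_table(table, path)
    back = read_activity_table(path)
    assert back.frame["split"].tolist() == table.frame["split"].tolist()
    pd.testing.assert_series_equal(back.frame["pIC50"].astype(float),
                                   table.frame["pIC50"].astype(float),
                                   check_index_type=False)
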