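import numpy as np
import pandas as pd
import pytest

from ubafit import (
    Constants,
    DilutionSeries,
    FormatError,
    PRETable,
    TitrationSeries,
    ValidationError,
    read_dilution_table,
    read_pre_table,
    read_titration_table,
    write_fit_report,
)
from ubafit.peak_io import (
    REPORT_COLUMNS,
    write_dilution_table,
    write_pre_table,
    write_titration_table,
)


def small_dilution():
    return DilutionSeries(
        residues=("G405", "W412sc"),
        concentrations=np.array([20.0, 100.0, 500.0]),
        volume_monomer=np.array([[0.6, 0.55], [0.3, 0.28], [0.1, 0.12]]),
        volume_dimer=np.array([[0.4, 0.45], [0.7, 0.72], [0.9, 0.88]]),
    )


def small_titration():
    ligs = np.array([0.0, 25.0, 50.0, 100.0, 150.0, 200.0, 300.0, 400.0])
    n = ligs.size
    dh = np.linspace(0, 0.1, n)[:, None] * np.ones((1, 2))
    dn = np.linspace(0, 0.4, n)[:, None] * np.ones((1, 2))
    return TitrationSeries(("G410", "T419"), 200.0, ligs, dh, dn)


class TestDilutionIO:
    def test_round_trip_preserves_all_numeric_fields(self, tmp_path):
        series = small_dilution()
        path = tmp_path / "dil.csv"
        write_dilution_table(series, path)
        back = read_dilution_table(path)
        assert back.residues == series.residues
        np.testing.assert_array_equal(back.concentrations, series.concentrations)
        np.testing.assert_array_equal(back.volume_monomer, series.volume_monomer)
        np.testing.assert_array_equal(back.volume_dimer, series.volume_dimer)

    def test_missing_column_is_a_format_error_naming_it(self, tmp_path):
        df = small_dilution().to_frame().drop(columns=["volume_dimer"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="volume_dimer"):
            read_dilution_table(path)

    def test_residue_missing_at_one_concentration_names_it(self, tmp_path):
        df = small_dilution().to_frame()
        df = df[~((df.residue == "G405") & (df.conc_total_uM == 20.0))]
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="G405"):
            read_dilution_table(path)

    def test_non_positive_concentration_rejected(self, tmp_path):
        df = small_dilution().to_frame()
        df.loc[df.conc_total_uM == 20.0, "conc_total_uM"] = -5.0
        path = tmp_path / "neg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_dilution_table(path)

    def test_zero_total_volume_rejected(self):
        with pytest.raises(ValidationError, match="zero total peak volume"):
            DilutionSeries(
                ("A",),
                np.array([20.0, 100.0]),
                np.array([[0.0], [0.5]]),
                np.array([[0.0], [0.5]]),
            )

    def test_single_concentration_rejected(self):
        with pytest.raises(ValidationError):
            DilutionSeries(
                ("A",), np.array([100.0]), np.array([[0.5]]), np.array([[0.5]])
            )


class TestTitrationIO:
    def test_round_trip(self, tmp_path):
        series = small_titration()
        path = tmp_path / "tit.csv"
        write_titration_table(series, path)
        back = read_titration_table(path)
        assert back.n_points == 8
        assert back.protein_total == 200.0
        np.testing.assert_array_equal(back.delta_h, series.delta_h)
        np.testing.assert_array_equal(back.delta_n, series.delta_n)

    def test_missing_reference_row_rejected(self, tmp_path):
        df = small_titration().to_frame()
        df = df[df.ligand_total_uM > 0]
        path = tmp_path / "noref.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="reference"):
            read_titration_table(path)

    def test_duplicate_ligand_row_rejected(self, tmp_path):
        df = small_titration().to_frame()
        df = pd.concat([df, df.iloc[[4]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            read_titration_table(path)

    def test_inconsistent_protein_total_rejected(self, tmp_path):
        df = small_titration().to_frame()
        df.loc[df.index[-1], "protein_total_uM"] = 150.0
        path = tmp_path / "prot.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="protein_total"):
            read_titration_table(path)

    def test_decreasing_ligand_series_rejected(self):
        with pytest.raises(ValidationError):
            TitrationSeries(
                ("A",),
                200.0,
                np.array([0.0, 50.0, 25.0]),
                np.zeros((3, 1)),
                np.zeros((3, 1)),
            )


class TestPREIO:
    def test_round_trip(self, tmp_path):
        table = PRETable(
            ("A", "B"),
            np.array([1.0, 0.9]),
            np.array([0.4, 0.5]),
            np.array([1.0, 1.1]),
            np.array([0.7, 0.8]),
        )
        path = tmp_path / "pre.csv"
        write_pre_table(table, path)
        back = read_pre_table(path)
        np.testing.assert_array_equal(back.i_para_b, table.i_para_b)
        assert back.delay == 0.012

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValidationError):
            PRETable(
                ("A",),
                np.array([1.0]),
                np.array([0.0]),
                np.array([1.0]),
                np.array([0.7]),
            )


class TestFitReport:
    def test_empty_results_give_header_only_file(self, tmp_path):
        path = tmp_path / "report.csv"
        write_fit_report([], path)
        df = pd.read_csv(path)
        assert list(df.columns) == list(REPORT_COLUMNS)
        assert len(df) == 0

    def test_two_variants_two_rows_stable_column_order(self, tmp_path, wt_dilution):
        from ubafit import fit_kd_dimer

        res = fit_kd_dimer(wt_dilution, n_boot=0)
        path = tmp_path / "report.csv"
        write_fit_report([("WT", res, None), ("K435Q", res, None)], path)
        df = pd.read_csv(path)
        assert list(df.columns) == list(REPORT_COLUMNS)
        assert list(df.variant) == ["WT", "K435Q"]
        assert df.KD_dimer_uM.notna().all()
        assert df.KD_complex_uM.isna().all()


def test_constants_reject_non_positive_temperature():
    with pytest.raises(ValidationError):
        Constants(temperature=0.0)
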