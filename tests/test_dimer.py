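import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ubafit import (
    NonIdentifiableError,
    SimulationConfig,
    UndefinedEquilibriumError,
    ValidationError,
    additivity_gap,
    delta_g_from_kd,
    fit_kd_dimer,
    fold_destabilization,
    kd_from_delta_g,
    kd_single_point,
    monomer_conc,
    monomer_fraction,
    simulate_dilution,
    species_from_volumes,
)
from conftest import VARIANT_TABLE

pos_conc = st.floats(min_value=1.0, max_value=1e3)
pos_kd = st.floats(min_value=0.1, max_value=1e3)


def monomer_brute_force(total, kd):
    """Independent oracle: root of the dimer mass-balance residual."""
    if kd == 0:
        return 0.0
    return brentq(lambda m: 2 * m**2 / (total - m) - kd, 1e-15, total * (1 - 1e-12))


class TestSpeciesFromVolumes:
    @pytest.mark.parametrize(
        "total, vm, vd, expected",
        [
            (100.0, 0.2, 0.8, (20.0, 40.0)),
            (100.0, 1.0, 0.0, (100.0, 0.0)),
            (100.0, 0.0, 1.0, (0.0, 50.0)),
        ],
    )
    def test_examples(self, total, vm, vd, expected):
        assert species_from_volumes(total, vm, vd) == pytest.approx(expected)

    def test_both_volumes_zero_rejected(self):
        with pytest.raises(ValidationError):
            species_from_volumes(100.0, 0.0, 0.0)

    @given(
        total=pos_conc,
        vm=st.floats(min_value=0, max_value=10),
        vd=st.floats(min_value=0.001, max_value=10),
    )
    def test_mass_conservation_exact(self, total, vm, vd):
        m, d = species_from_volumes(total, vm, vd)
        assert m + 2 * d == pytest.approx(total, rel=1e-14)

    @given(total=pos_conc, vm=st.floats(0.01, 10), vd=st.floats(0.01, 10),
           scale=st.floats(0.01, 100))
    def test_only_the_volume_ratio_matters(self, total, vm, vd, scale):
        assert species_from_volumes(total, vm, vd) == pytest.approx(
            species_from_volumes(total, scale * vm, scale * vd), rel=1e-12
        )


class TestKdSinglePoint:
    @pytest.mark.parametrize(
        "total, vm, vd, expected",
        [(100.0, 0.2, 0.8, 10.0), (200.0, 0.5, 0.5, 200.0)],
    )
    def test_examples(self, total, vm, vd, expected):
        assert kd_single_point(total, vm, vd) == pytest.approx(expected)

    def test_all_dimer_point_has_kd_zero(self):
        assert kd_single_point(100.0, 0.0, 1.0) == 0.0

    def test_no_dimer_signal_is_undefined(self):
        with pytest.raises(UndefinedEquilibriumError):
            kd_single_point(100.0, 1.0, 0.0)


class TestMonomerFraction:
    def test_derived_wt_value_at_200uM(self):
        # quadratic root computed independently via brute force
        assert monomer_conc(200.0, 6.8) == pytest.approx(24.4322, abs=1e-3)
        assert monomer_fraction(200.0, 6.8) == pytest.approx(0.12216, abs=1e-4)

    def test_all_dimer_and_all_monomer_limits(self):
        assert monomer_fraction(100.0, 0.0) == 0.0
        assert monomer_fraction(20.0, 1e6) == pytest.approx(1.0, abs=1e-3)

    @given(total=pos_conc, kd=pos_kd)
    def test_matches_brute_force_root(self, total, kd):
        assert monomer_conc(total, kd) == pytest.approx(
            monomer_brute_force(total, kd), rel=1e-8
        )

    @given(total=pos_conc, kd=pos_kd)
    def test_mass_balance_residual_closed_loop(self, total, kd):
        m = monomer_conc(total, kd)
        # plugged back into the definition K = 2[M]^2 / (total - [M])
        assert 2 * m**2 / (total - m) == pytest.approx(kd, rel=1e-8)

    @given(total=pos_conc, kd=pos_kd)
    def test_monotone_in_kd_and_total(self, total, kd):
        f = monomer_fraction(total, kd)
        assert monomer_fraction(total, kd * 1.5) > f
        assert monomer_fraction(total * 1.5, kd) < f


class TestDeltaG:
    @pytest.mark.parametrize(
        "kd, printed",
        [(kd, dg) for kd, dg, _ in VARIANT_TABLE.values()],
    )
    def test_reference_free_energies(self, kd, printed):
        dg = delta_g_from_kd(kd)
        assert round(dg, 1) == printed
        assert abs(dg - printed) <= 0.05

    def test_one_molar_standard_state_is_zero(self):
        assert delta_g_from_kd(1e6) == pytest.approx(0.0, abs=1e-12)

    @given(kd=st.floats(min_value=1e-3, max_value=1e9))
    def test_round_trip_to_ten_digits(self, kd):
        assert kd_from_delta_g(delta_g_from_kd(kd)) == pytest.approx(kd, rel=1e-10)

    def test_non_positive_kd_rejected(self):
        with pytest.raises(ValidationError):
            delta_g_from_kd(0.0)


class TestFoldAndAdditivity:
    def test_fold_changes_match_reference_ratios(self):
        wt = VARIANT_TABLE["WT"][0]
        assert fold_destabilization(41.2, wt) == pytest.approx(6.06, abs=0.01)
        assert round(fold_destabilization(41.2, wt)) == 6
        assert fold_destabilization(15.5, wt) == pytest.approx(2.28, abs=0.01)
        assert fold_destabilization(wt, wt) == 1.0

    def test_additivity_gap_from_reference_free_energies(self):
        # |(4.5 + 2.1) - 6.8| = 0.2 from the printed dG column
        assert additivity_gap(-29.5, -25.0, -27.4, -22.7) == pytest.approx(0.2)
        assert additivity_gap(-30.0, -30.0, -30.0, -30.0) == 0.0
        assert additivity_gap(-30.0, -28.0, -27.0, -25.0) == 0.0


class TestFitKdDimer:
    def test_noiseless_fit_is_exact(self, wt_dilution):
        res = fit_kd_dimer(wt_dilution, n_boot=0)
        assert res.kd_dimer == pytest.approx(6.8, rel=1e-4)
        assert res.n_residues_used == 8
        np.testing.assert_allclose(
            res.fraction_fitted, res.fraction_observed, rtol=1e-6
        )

    @pytest.mark.parametrize("kd_true", [6.8, 106.3])
    def test_noisy_recovery_within_20_percent(self, kd_true):
        cfg = SimulationConfig(kd_dimer=kd_true)
        fits = [
            fit_kd_dimer(simulate_dilution(cfg, seed=s), n_boot=0).kd_dimer
            for s in range(1, 26)
        ]
        assert np.mean(fits) == pytest.approx(kd_true, rel=0.20)

    def test_bootstrap_uncertainty_is_positive_and_sane(self):
        cfg = SimulationConfig(kd_dimer=106.3)
        series = simulate_dilution(cfg, seed=7)
        res = fit_kd_dimer(series, n_boot=50, seed=7)
        assert res.kd_sd > 0
        assert res.kd_sd < res.kd_dimer  # not absurdly uncertain
        assert res.delta_g_sd == pytest.approx(
            8.314 * 298.0 * res.kd_sd / res.kd_dimer / 1000.0
        )

    def test_residue_include_list(self, wt_dilution):
        res = fit_kd_dimer(wt_dilution, residues=["S399", "W412"], n_boot=0)
        assert res.residues_used == ("S399", "W412")
        assert res.kd_dimer == pytest.approx(6.8, rel=1e-4)

    def test_fully_monomeric_series_not_identifiable(self):
        from ubafit import DilutionSeries

        series = DilutionSeries(
            ("A",),
            np.array([20.0, 100.0]),
            np.array([[1.0], [1.0]]),
            np.array([[0.0], [0.0]]),
        )
        with pytest.raises(NonIdentifiableError):
            fit_kd_dimer(series, n_boot=0)

    def test_per_point_estimates_match_truth_without_noise(self, wt_dilution):
        res = fit_kd_dimer(wt_dilution, n_boot=0)
        np.testing.assert_allclose(res.per_point_kd, 6.8, rtol=1e-8)


@pytest.mark.parametrize("kd_true", [6.8, 15.5, 41.2, 106.3])
def test_recovery_distribution_over_100_replicates(kd_true):
    """At 5% volume noise: median fitted K_D within 5% of truth and 95%
    of single-series fits within 25%."""
    cfg = SimulationConfig(kd_dimer=kd_true)
    fits = np.array(
        [
            fit_kd_dimer(simulate_dilution(cfg, seed=s), n_boot=0).kd_dimer
            for s in range(100)
        ]
    )
    assert np.median(fits) == pytest.approx(kd_true, rel=0.05)
    rel_err = np.abs(fits / kd_true - 1.0)
    assert np.mean(rel_err <= 0.25) >= 0.95
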