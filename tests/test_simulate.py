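"""Forward-model physics: lineshapes, modulation, RC filtering, cohorts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import epr_oximetry as eo
from epr_oximetry import (
    AcquisitionSettings,
    CohortDesign,
    OutOfSweepWindowError,
    ProbeModel,
    ValidationError,
    apply_field_modulation,
    lorentzian_absorption,
    lorentzian_derivative,
    rc_alpha,
    rc_smooth,
    simulate_cohort,
    simulate_cohort_table,
    simulate_spectrum,
)

from conftest import probe_with_width


def dense_extrema(field: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    return float(field[np.argmax(y)]), float(field[np.argmin(y)])


class TestLorentzianDerivative:
    def test_extrema_at_half_peak_to_peak_width(self):
        """Dense-grid argmax/argmin sit at centre +- delta_bpp/2."""
        field = np.linspace(-3, 3, 600001)
        for dbpp in (0.11547, 0.5, 1.2):
            y = lorentzian_derivative(field, 0.0, dbpp)
            pmax, pmin = dense_extrema(field, y)
            assert pmax == pytest.approx(-dbpp / 2, abs=2e-5)
            assert pmin == pytest.approx(+dbpp / 2, abs=2e-5)

    def test_matches_hwhm_parametrisation(self):
        """A Lorentzian of HWHM 0.10 G has dBpp = 2*0.10/sqrt(3) = 0.11547 G."""
        gamma = 0.10
        dbpp = 2 * gamma / np.sqrt(3)
        assert dbpp == pytest.approx(0.11547, abs=1e-5)
        field = np.linspace(-2, 2, 400001)
        absorption = lorentzian_absorption(field, 0.0, dbpp)
        half_idx = np.argmin(np.abs(absorption[field > 0] - 0.5))
        assert field[field > 0][half_idx] == pytest.approx(gamma, abs=1e-4)

    def test_odd_symmetry_and_linearity(self):
        field = np.linspace(-2, 2, 4001)
        y = lorentzian_derivative(field, 0.0, 0.4, amplitude=1.5)
        assert y[2000] == pytest.approx(0.0, abs=1e-14)  # zero at centre
        np.testing.assert_allclose(y, -y[::-1], atol=1e-12)
        np.testing.assert_allclose(
            lorentzian_derivative(field, 0.0, 0.4, amplitude=3.0), 2 * y, rtol=1e-12
        )
        assert y.max() == pytest.approx(1.5, rel=1e-6)  # amplitude convention

    def test_invalid_width_rejected(self):
        with pytest.raises(ValidationError):
            lorentzian_derivative(np.linspace(-1, 1, 100), 0.0, -0.1)
        with pytest.raises(ValidationError):
            lorentzian_derivative(np.linspace(-1, 1, 100), 0.0, 0.0)


class TestFieldModulation:
    field = np.linspace(-3, 3, 6001)

    @staticmethod
    def absorption(b):
        return lorentzian_absorption(b, 0.0, 0.5)

    def test_zero_modulation_is_exact_derivative(self):
        out = apply_field_modulation(self.absorption, 0.0, self.field)
        # finite-difference fallback against the analytic derivative
        ref = lorentzian_derivative(self.field, 0.0, 0.5)
        np.testing.assert_allclose(out / np.max(np.abs(out)),
                                   ref / np.max(np.abs(ref)), atol=1e-8)

    def test_small_modulation_converges_to_derivative(self):
        ref = lorentzian_derivative(self.field, 0.0, 0.5)
        ref = ref / np.max(np.abs(ref))
        out = apply_field_modulation(self.absorption, 0.005, self.field)
        out = out / np.max(np.abs(out))
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_small_modulation_width_within_one_percent(self):
        """Bm = 0.1 G on a 0.5 G line broadens the apparent width < 1%."""
        out = apply_field_modulation(self.absorption, 0.1, self.field,
                                     n_harmonic_points=480)
        pmax, pmin = dense_extrema(self.field, out)
        assert (pmin - pmax) == pytest.approx(0.5, rel=0.01)

    def test_overmodulation_broadens(self):
        """Bm = 1.0 G on a 0.5 G line gives apparent width > true width."""
        out = apply_field_modulation(self.absorption, 1.0, self.field,
                                     n_harmonic_points=480)
        pmax, pmin = dense_extrema(self.field, out)
        assert (pmin - pmax) > 0.5

    def test_broadening_monotone_in_modulation(self):
        """Apparent width is non-decreasing in Bm over Bm/dBpp in [0, 4]."""
        widths = []
        for ratio in np.linspace(0.0, 4.0, 9):
            out = apply_field_modulation(self.absorption, ratio * 0.5, self.field)
            pmax, pmin = dense_extrema(self.field, out)
            widths.append(pmin - pmax)
        assert np.all(np.diff(widths) >= -1e-9)


class TestRCFilter:
    def test_alpha_closed_form(self, paper_settings):
        """tau 20.48 ms / 10 s sweep / 512 points: dt ~ 19.57 ms, alpha ~ 0.3846."""
        dt = paper_settings.dwell_time
        assert dt == pytest.approx(10.0 / 511, rel=1e-12)
        assert rc_alpha(paper_settings.time_constant, dt) == pytest.approx(
            np.exp(-dt / 0.02048), rel=1e-12
        )
        assert rc_alpha(0.02048, dt) == pytest.approx(0.3846, abs=1e-4)

    def test_zero_tau_is_identity_and_dc_invariance(self, rng):
        x = rng.normal(size=256)
        np.testing.assert_array_equal(rc_smooth(x, 0.0, 0.01), x)
        const = np.full(256, 3.7)
        for mode in ("causal", "zero_phase"):
            np.testing.assert_allclose(rc_smooth(const, 0.05, 0.01, mode), const,
                                       rtol=1e-12)

    def test_causal_shifts_zero_phase_does_not(self, clean_settings):
        tr = simulate_spectrum([probe_with_width(0.4)], clean_settings)
        dwell = clean_settings.dwell_time
        shifts = []
        for k in (1, 2, 4):
            y = rc_smooth(tr.intensity, k * dwell, dwell, mode="causal")
            shifts.append(tr.field[np.argmax(y)] - tr.field[np.argmax(tr.intensity)])
        assert shifts[0] >= 0 and np.all(np.diff(shifts) >= 0) and shifts[-1] > 0
        yz = rc_smooth(tr.intensity, 2 * dwell, dwell, mode="zero_phase")
        assert abs(tr.field[np.argmax(yz)] - tr.field[np.argmax(tr.intensity)]) \
            <= clean_settings.grid_spacing / 10


class TestSimulateSpectrum:
    def test_gradient_separates_probes_by_one_gauss(self, paper_settings):
        s = paper_settings.replace(gradient=1.0)
        probes = [
            probe_with_width(0.3, position=0.0),
            probe_with_width(0.3, position=1.0),
        ]
        tr = simulate_spectrum(probes, s)
        # the two positive lobes sit 1 G apart
        mid = tr.field.size // 2
        left = tr.field[np.argmax(tr.intensity[:mid])]
        right = tr.field[mid + np.argmax(tr.intensity[mid:])]
        assert right - left == pytest.approx(1.0, abs=2 * s.grid_spacing)

    def test_empty_resonator_is_silent(self, paper_settings):
        tr = simulate_spectrum([], paper_settings, noise_sd=0.0)
        assert np.all(tr.intensity == 0.0)

    def test_probe_outside_window_raises(self, paper_settings):
        s = paper_settings.replace(gradient=1.0)
        with pytest.raises(OutOfSweepWindowError):
            simulate_spectrum([ProbeModel(position=2.0, pO2_true=10.0)], s)

    def test_same_seed_bit_identical(self, paper_settings):
        a = simulate_spectrum([probe_with_width(0.3)], paper_settings, noise_sd=1.0)
        b = simulate_spectrum([probe_with_width(0.3)], paper_settings, noise_sd=1.0)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_noise_scales_as_inverse_sqrt_averages(self, paper_settings):
        """Empirical sd over 200 realisations within 10% of sd/sqrt(n)."""
        for n_avg in (1, 16):
            s = paper_settings.replace(n_averages=n_avg)
            rng = np.random.default_rng(99)
            sds = [
                np.std(simulate_spectrum([], s, noise_sd=1.0, rng=rng).intensity)
                for _ in range(200)
            ]
            assert np.mean(sds) == pytest.approx(1.0 / np.sqrt(n_avg), rel=0.10)

    def test_baseline_polynomial_added(self, paper_settings):
        tr = simulate_spectrum([], paper_settings, baseline=(1.0, 2.0))
        expected = 1.0 + 2.0 * (tr.field - paper_settings.centre_field)
        np.testing.assert_allclose(tr.intensity, expected, rtol=1e-12)

    @given(st.floats(0.1, 1.0), st.floats(0.5, 3.0))
    def test_amplitude_linearity(self, dbpp, scale):
        s = AcquisitionSettings()
        base = simulate_spectrum([probe_with_width(dbpp)], s)
        scaled = simulate_spectrum(
            [probe_with_width(dbpp, amplitude=scale)], s
        )
        np.testing.assert_allclose(scaled.intensity, scale * base.intensity,
                                   rtol=1e-9, atol=1e-12)


class TestCohort:
    def test_degenerate_noise_gives_exact_means(self):
        d = CohortDesign(pO2_between_animal_sd=0.0, pO2_within_animal_sd=0.0)
        table = simulate_cohort_table(d)
        control = table[table.group == "control"]["pO2_true_mmHg"]
        treated = table[table.group == "treated"]["pO2_true_mmHg"]
        assert np.all(control == d.control_pO2_mean)
        assert np.all(treated == d.treated_pO2_mean)

    def test_mean_ratio_converges_to_design(self):
        """Law of large numbers: treated/control -> 1.5 at n = 500/group."""
        d = CohortDesign(n_animals_per_group=250, rng_seed=7)
        table = simulate_cohort_table(d)
        per_tumour = table.drop_duplicates("tumour_id")
        means = per_tumour.groupby("group")["pO2_true_mmHg"].mean()
        assert means["treated"] / means["control"] == pytest.approx(1.5, abs=0.03)

    def test_same_seed_identical_cohort(self, paper_settings):
        s = paper_settings.replace(gradient=1.0)
        d = CohortDesign(n_animals_per_group=2, rng_seed=11)
        t1, tr1 = simulate_cohort(d, s)
        t2, tr2 = simulate_cohort(d, s)
        assert t1.equals(t2)
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_truth_width_is_affine_in_po2(self):
        p = ProbeModel(pO2_true=25.0)
        assert p.delta_bpp == pytest.approx(
            p.anoxic_linewidth + p.oxygen_sensitivity * 25.0, rel=1e-12
        )

    def test_design_validation(self):
        with pytest.raises(ValidationError):
            CohortDesign(tumours_per_animal=3)
        with pytest.raises(ValidationError):
            CohortDesign(control_pO2_mean=-1.0)

    def test_realised_snr_matches_target(self):
        s = AcquisitionSettings(gradient=1.0)
        d = CohortDesign(n_animals_per_group=1, target_snr=10.0, rng_seed=4)
        _, traces = simulate_cohort(d, s)
        clean = simulate_cohort(
            dataclasses.replace(d, target_snr=None), s
        )[1][0]
        noise = traces[0].intensity - clean.intensity
        # subtract the random linear baseline before estimating noise sd
        coeffs = np.polynomial.polynomial.polyfit(traces[0].field, noise, 1)
        resid = noise - np.polynomial.polynomial.polyval(traces[0].field, coeffs)
        snr = np.abs(clean.intensity).max() / np.std(resid)
        assert snr == pytest.approx(10.0, rel=0.2)


def test_simulated_slope_recovered_on_po2_ladder(paper_settings):
    """Round trip recovers the oxygen sensitivity within 2% on a noise-free
    5-point pO2 ladder (linewidth additivity of the truth model)."""
    po2_levels = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
    widths = []
    for po2 in po2_levels:
        tr = simulate_spectrum([ProbeModel(pO2_true=po2)], paper_settings)
        res = eo.analyze_spectrum(tr, eo.PipelineConfig(n_probes=1))
        widths.append(res.lines[0].linewidth_corrected)
    slope = np.polyfit(po2_levels, widths, 1)[0]
    assert slope == pytest.approx(0.006, rel=0.02)
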