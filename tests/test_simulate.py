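"""Synthetic generator: speciation solver, schedules, spectra, constructs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import camfret as cf
from camfret.errors import ConfigurationError, OutOfRangeError, ScheduleError
from camfret.simulate import (
    DONOR_BAND,
    ACCEPTOR_BAND,
    _channels_at_fraction,
    _cumulative_totals,
    design_schedule,
    total_from_free_ca,
)


def grid_bisection_free_ca(ca_total, buffers, iters=60):
    """Independent bisection oracle on the Ca2+ mass balance."""
    if ca_total == 0:
        return 0.0
    lo, hi = 0.0, ca_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        bound = sum(b.n_sites * b.total * mid / (b.kd_ca + mid) for b in buffers)
        if mid + bound < ca_total:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSolveFreeCa:
    def test_no_buffers_returns_total(self):
        assert cf.solve_free_ca(3.7, []) == 3.7

    def test_zero_total(self):
        assert cf.solve_free_ca(0.0, [cf.BufferSpecies("b", 10.0, 1.0)]) == 0.0

    def test_single_buffer_derived_value(self):
        # frozen from the bisection oracle: 10 µM 1:1 buffer, kd 1, total Ca 5
        buffers = [cf.BufferSpecies("b", 10.0, 1.0)]
        x = cf.solve_free_ca(5.0, buffers)
        assert x == pytest.approx(0.741657, abs=1e-5)
        assert x == pytest.approx(grid_bisection_free_ca(5.0, buffers), rel=1e-9)

    def test_three_buffer_mixture_matches_oracle(self):
        buffers = [cf.BufferSpecies("BAPTA", 2000.0, 0.16),
                   cf.BufferSpecies("indicator", 2.0, 1.6),
                   cf.BufferSpecies("CaM", 20.0, 10.0, n_sites=4)]
        for total in np.geomspace(0.01, 1e4, 25):
            x = cf.solve_free_ca(total, buffers)
            ref = grid_bisection_free_ca(total, buffers, iters=80)
            assert x == pytest.approx(ref, rel=1e-6, abs=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=5000.0),
                    min_size=2, max_size=2, unique=True))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_total(self, totals):
        buffers = [cf.BufferSpecies("b", 100.0, 0.5),
                   cf.BufferSpecies("c", 5.0, 2.0, n_sites=4)]
        lo, hi = sorted(totals)
        assert cf.solve_free_ca(lo, buffers) <= cf.solve_free_ca(hi, buffers)

    def test_monotone_in_buffer_total(self):
        x = [cf.solve_free_ca(50.0, [cf.BufferSpecies("b", t, 1.0)])
             for t in (0.0, 10.0, 100.0, 1000.0)]
        assert all(b <= a for a, b in zip(x, x[1:]))

    def test_negative_total_rejected(self):
        with pytest.raises(ConfigurationError):
            cf.solve_free_ca(-1.0, [])


def test_design_schedule_reaches_targets():
    targets = np.geomspace(0.01, 100.0, 20)
    schedule = design_schedule(targets, initial_volume=2000.0)
    _, totals = _cumulative_totals(schedule, 2000.0)
    assert np.allclose(totals, targets, rtol=1e-9)


def test_total_from_free_inverts_solver():
    buffers = [cf.BufferSpecies("b", 100.0, 0.5)]
    for x in (0.01, 1.0, 30.0):
        assert cf.solve_free_ca(total_from_free_ca(x, buffers), buffers) == \
            pytest.approx(x, rel=1e-9)


class TestSimulateCamTitration:
    def test_deterministic_given_seed(self):
        cfg = dict(true_kd=1.0, noise_sigma=0.02, seed=11)
        a = cf.simulate_cam_titration(cf.GeneratorConfig(**cfg))
        b = cf.simulate_cam_titration(cf.GeneratorConfig(**cfg))
        assert a.points == b.points

    def test_seed_changes_noise(self):
        a = cf.simulate_cam_titration(cf.GeneratorConfig(true_kd=1.0, noise_sigma=0.02, seed=1))
        b = cf.simulate_cam_titration(cf.GeneratorConfig(true_kd=1.0, noise_sigma=0.02, seed=2))
        assert a.points != b.points

    def test_zero_amplitude_is_flat(self):
        cfg = cf.GeneratorConfig(true_kd=1.0, r_min=1.5, r_max=1.5)
        series = cf.simulate_cam_titration(cfg)
        assert np.allclose(series.ratios, 1.5, rtol=1e-12)

    def test_schedule_overflow_rejected(self):
        cfg = cf.GeneratorConfig(true_kd=1.0, max_volume=2001.0)
        with pytest.raises(ScheduleError):
            cf.simulate_cam_titration(cfg)

    def test_noiseless_dynamic_range_matches_generator(self):
        cfg = cf.GeneratorConfig(true_kd=0.44, r_min=1.2, r_max=3.0)
        fit = cf.fit_binding(
            cf.apply_dilution_correction(cf.simulate_cam_titration(cfg)),
            cfg.bs_total, model="quadratic")
        assert fit.dynamic_range == pytest.approx(3.0 / 1.2, rel=1e-9)


class TestSpectra:
    def test_endpoints_exact(self):
        cfg = cf.GeneratorConfig(true_kd=1.0, mode="spectral")
        wl0, s0 = cf.synthesize_spectrum(0.0, cfg)
        _, s1 = cf.synthesize_spectrum(1.0, cfg)
        _, smid = cf.synthesize_spectrum(0.5, cfg)
        assert np.allclose(smid, 0.5 * (s0 + s1), rtol=1e-12)
        assert wl0[0] == 450.0 and wl0[-1] == 600.0

    def test_band_integrals_match_channels(self):
        cfg = cf.GeneratorConfig(true_kd=1.0, mode="spectral")
        for f in (0.0, 0.3, 0.8, 1.0):
            wl, inten = cf.synthesize_spectrum(f, cfg)
            c475, c535 = _channels_at_fraction(f, cfg)
            md = (wl >= DONOR_BAND[0]) & (wl <= DONOR_BAND[1])
            ma = (wl >= ACCEPTOR_BAND[0]) & (wl <= ACCEPTOR_BAND[1])
            assert np.trapezoid(inten[md], wl[md]) == pytest.approx(c475, rel=5e-3)
            assert np.trapezoid(inten[ma], wl[ma]) == pytest.approx(c535, rel=5e-3)

    def test_peak_ratio_strictly_increasing_in_fraction(self):
        cfg = cf.GeneratorConfig(true_kd=1.0, mode="spectral")
        fr = np.linspace(0.0, 1.0, 21)
        f475, f535 = _channels_at_fraction(fr, cfg)
        assert np.all(np.diff(f475 / f535) > 0)

    def test_fraction_out_of_range(self):
        with pytest.raises(ConfigurationError):
            cf.synthesize_spectrum(1.2, cf.GeneratorConfig(true_kd=1.0))


class TestSimulateCaAssay:
    def test_deterministic(self):
        kw = dict(hill_species=[cf.HillSpecies(2.38, 1.21)], noise_sigma=0.01,
                  seed=5, n_points=15)
        a = cf.simulate_ca_assay(cf.GeneratorConfig(**kw))
        b = cf.simulate_ca_assay(cf.GeneratorConfig(**kw))
        assert a.points == b.points

    def test_unbuffered_free_equals_total(self):
        """With no chelator and no CaM buffering, the generator's free Ca2+
        equals the dilution-corrected total: inverting the indicator channel
        with the true calibration endpoints recovers the totals exactly."""
        cfg = cf.GeneratorConfig(hill_species=[cf.HillSpecies(2.0, 1.2)], n_points=10)
        assay = cf.simulate_ca_assay(cfg, buffers=[],
                                     indicator_f_min=100.0, indicator_f_max=1000.0)
        vols = np.cumsum([p.added_volume for p in assay.points])
        factor = (cfg.initial_volume + vols) / cfg.initial_volume
        f_corr = assay.f_indicator * factor
        free = cf.free_calcium(f_corr, 100.0, 1000.0, assay.indicator_kd)
        totals = _cumulative_totals(
            [(p.added_volume, p.stock_concentration) for p in assay.points[1:]],
            cfg.initial_volume)[1]
        assert np.allclose(free[1:], totals, rtol=1e-9)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            cf.GeneratorConfig(hill_species=[cf.HillSpecies(1.0, 1.0, 0.5)])


class TestConstructs:
    def test_smd4_truncation_set(self):
        base = cf.BiosensorConstruct(330, 375, smd=4)
        out = cf.enumerate_constructs(base, [345, 351, 361, 375])
        assert [c.name for c in out] == [
            "BSGPER330-345", "BSGPER330-351", "BSGPER330-361", "BSGPER330-375"]

    def test_glycine_flank_naming(self):
        base = cf.BiosensorConstruct(83, 93, smd=1)
        out = cf.enumerate_constructs(base, [93], gly_flank_options=[3])
        assert out[0].name == "BSGPERGGG83-93GGG"

    def test_empty_truncation_list_returns_base(self):
        base = cf.BiosensorConstruct(150, 175, smd=2)
        out = cf.enumerate_constructs(base)
        assert len(out) == 1 and out[0].name == "BSGPER150-175"

    def test_end_outside_range_rejected(self):
        base = cf.BiosensorConstruct(330, 375, smd=4)
        with pytest.raises(OutOfRangeError):
            cf.enumerate_constructs(base, [400])
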