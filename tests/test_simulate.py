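import numpy as np
import pytest
from scipy import stats

from tastechip.recording import StimulusLabel, TASTANT_UNITS, Tastant
from tastechip.simulate import (
    CellType,
    CellTypeProfile,
    assign_electrodes,
    build_default_model,
    default_conditions,
    expected_lognormal_max,
    simulate_channel,
    simulate_experiment,
    solve_amplitude_sigma,
)

from conftest import acetic_label


def label(tastant, conc):
    return StimulusLabel(tastant, conc, TASTANT_UNITS[tastant])


class TestDefaultModel:
    def test_acetic_rate_ladder_matches_reported_values(self, default_model):
        expected = {25.0: 0.25, 12.5: 0.09, 6.25: 0.06, 3.125: 0.05, 1.5625: 0.001}
        for conc, rate in expected.items():
            p = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(conc))
            assert p.spike_rate_hz == pytest.approx(rate)

    def test_acetic_amplitude_means_match_reported_values(self, default_model):
        expected = {25.0: 64.16, 12.5: 61.47, 6.25: 54.45, 3.125: 32.63}
        for conc, mean in expected.items():
            p = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(conc))
            assert p.mean_amplitude_uv == pytest.approx(mean, rel=1e-6)

    def test_amplitude_spread_solves_the_expected_maximum(self, default_model):
        p = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(25.0))
        e_max = expected_lognormal_max(p.amp_logmean, p.amp_logsd, 45)
        assert e_max == pytest.approx(293.40, rel=1e-4)

    def test_subthreshold_conditions_equal_baseline(self, default_model):
        cases = [
            (CellType.TYPE_II_SWEET, label(Tastant.SWEET_SUCROSE, 0.125)),
            (CellType.TYPE_II_BITTER, label(Tastant.BITTER_PTC, 0.001)),
            (CellType.SALT_SENSOR, label(Tastant.SALTY_NACL, 0.75)),
            (CellType.SALT_SENSOR, label(Tastant.SALTY_NACL, 1.5)),
        ]
        for ct, stim in cases:
            assert default_model.resolve(ct, stim) == default_model.baseline[ct]

    def test_lowest_acetic_pair_profiles_differ(self, default_model):
        low = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(1.5625))
        nxt = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(3.125))
        assert low != nxt

    def test_cross_tastant_stimuli_resolve_to_baseline(self, default_model):
        p = default_model.resolve(
            CellType.TYPE_III_SOUR, label(Tastant.SWEET_SUCROSE, 0.75)
        )
        assert p == default_model.baseline[CellType.TYPE_III_SOUR]

    def test_unknown_concentration_rejected(self, default_model):
        with pytest.raises(KeyError, match="condition not in model"):
            default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(99.0))

    def test_table_round_trip(self, default_model, tmp_path):
        default_model.to_table(tmp_path / "model.csv")
        from tastechip.simulate import TasteResponseModel

        back = TasteResponseModel.from_table(tmp_path / "model.csv")
        p0 = default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(25.0))
        p1 = back.resolve(CellType.TYPE_III_SOUR, acetic_label(25.0))
        assert p1.spike_rate_hz == pytest.approx(p0.spike_rate_hz)
        assert p1.band_gain == pytest.approx(p0.band_gain)


def test_expected_max_quadrature_matches_monte_carlo():
    mu, sigma = solve_amplitude_sigma(50.0, 120.0, 20)
    rng = np.random.default_rng(0)
    draws = rng.lognormal(mu, sigma, size=(40_000, 20)).max(axis=1)
    se = draws.std() / np.sqrt(len(draws))
    assert abs(draws.mean() - 120.0) < 3 * se + 1e-9 * 120


class TestAssignElectrodes:
    def test_equal_fifths_largest_remainder(self):
        emap = assign_electrodes(64, seed=0)
        counts = sorted(
            sum(1 for v in emap.assignment.values() if v == ct) for ct in CellType
        )
        assert counts == [12, 13, 13, 13, 13]

    def test_single_type(self):
        emap = assign_electrodes(4, {CellType.SALT_SENSOR: 1.0}, seed=1)
        assert set(emap.assignment.values()) == {CellType.SALT_SENSOR}

    def test_deterministic_in_seed(self):
        assert assign_electrodes(64, seed=5).assignment == assign_electrodes(
            64, seed=5
        ).assignment

    def test_invalid_proportions(self):
        with pytest.raises(ValueError, match="invalid proportions"):
            assign_electrodes(10, {CellType.SALT_SENSOR: 0.5}, seed=0)


class TestSimulateChannel:
    def test_silent_profile_gives_zero_signal(self):
        p = CellTypeProfile(0.0, 1.0, 0.1, (0, 0, 0, 0, 0), 0.0)
        sig, gt = simulate_channel(p, 2.0, 1000.0, seed=0)
        assert np.all(sig == 0)
        assert len(gt.spike_times_s) == 0

    def test_spike_counts_are_poisson(self, sour_top_profile):
        counts = [
            len(simulate_channel(sour_top_profile, 180.0, 1000.0, seed=s)[1].spike_times_s)
            for s in range(200)
        ]
        lam = 0.25 * 180
        se_mean = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se_mean
        # variance of a Poisson count: SE(var) ~ sqrt(2/199)*var + skew term
        assert abs(np.var(counts, ddof=1) - lam) < 4 * lam * np.sqrt(2 / 199)

    def test_amplitude_draws_recover_lognormal_mean(self, sour_top_profile):
        amps = np.concatenate(
            [
                simulate_channel(sour_top_profile, 180.0, 1000.0, seed=s)[1].spike_amplitudes_uv
                for s in range(60)
            ]
        )
        target = sour_top_profile.mean_amplitude_uv
        se = amps.std() / np.sqrt(len(amps))
        assert abs(amps.mean() - target) < 3 * se

    def test_noise_floor_standard_deviation(self):
        p = CellTypeProfile(0.0, 1.0, 0.1, (0, 0, 0, 0, 0), 5.0)
        sig, _ = simulate_channel(p, 180.0, 1000.0, seed=3)
        assert sig.std() == pytest.approx(5.0, abs=0.2)

    def test_band_component_variance_matches_gain(self):
        p = CellTypeProfile(0.0, 1.0, 0.1, (2.0, 0, 0, 0, 0), 0.0)
        sig, _ = simulate_channel(p, 60.0, 1000.0, seed=4)
        assert sig.std() == pytest.approx(2.0, abs=0.01)

    def test_low_sampling_rate_rejected(self, sour_top_profile):
        with pytest.raises(ValueError, match="fs too low"):
            simulate_channel(sour_top_profile, 1.0, 150.0, seed=0)

    def test_deterministic_in_seed(self, sour_top_profile):
        a, _ = simulate_channel(sour_top_profile, 5.0, 1000.0, seed=9)
        b, _ = simulate_channel(sour_top_profile, 5.0, 1000.0, seed=9)
        assert np.array_equal(a, b)


class TestSimulateExperiment:
    def test_bookkeeping(self, default_model):
        emap = assign_electrodes(8, seed=0)
        conds = default_conditions(Tastant.SALTY_NACL)
        sims = simulate_experiment(
            default_model, emap, conds, duration_s=2.0, fs=1000.0,
            n_replicates=3, seed=1,
        )
        assert len(sims) == 18
        rec, gt = sims[0]
        assert rec.samples.shape == (8, 2000)
        assert set(gt) == set(rec.channel_ids)

    def test_control_conditions_use_baseline(self, default_model):
        emap = assign_electrodes(4, seed=0)
        sims = simulate_experiment(
            default_model, emap, [StimulusLabel()], 1.0, 1000.0, 1, seed=2,
            chip_cv=0.0, chip_cv_gain=0.0,
        )
        _, gt = sims[0]
        for ch, truth in gt.items():
            assert truth.profile == default_model.baseline[emap.assignment[ch]]

    def test_bit_identical_under_fixed_seed(self, default_model):
        emap = assign_electrodes(4, seed=0)
        conds = default_conditions(Tastant.BITTER_PTC)[:2]
        a = simulate_experiment(default_model, emap, conds, 1.0, 1000.0, 2, seed=7)
        b = simulate_experiment(default_model, emap, conds, 1.0, 1000.0, 2, seed=7)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_unresolvable_condition_fails_fast(self, default_model):
        emap = assign_electrodes(4, seed=0)
        with pytest.raises(KeyError, match="condition not in model"):
            simulate_experiment(
                default_model, emap, [acetic_label(42.0)], 1.0, 1000.0, 1, seed=0
            )


def test_cross_tastant_band_power_silence(default_model):
    """A sour-sensing channel under sucrose is statistically at baseline."""
    from tastechip.spectral import METHODS_BANDS, band_power, compute_spectrogram

    sour = CellType.TYPE_III_SOUR
    sucrose = label(Tastant.SWEET_SUCROSE, 0.75)
    base, cross = [], []
    for seed in range(20):
        p_b = default_model.resolve(sour, StimulusLabel())
        p_x = default_model.resolve(sour, sucrose)
        sig_b, _ = simulate_channel(p_b, 30.0, 1000.0, seed=seed)
        sig_x, _ = simulate_channel(p_x, 30.0, 1000.0, seed=1000 + seed)
        sb = compute_spectrogram(sig_b, 1000.0)
        sx = compute_spectrogram(sig_x, 1000.0)
        base.append([band_power(sb, b) for b in METHODS_BANDS])
        cross.append([band_power(sx, b) for b in METHODS_BANDS])
    base, cross = np.array(base), np.array(cross)
    for j in range(5):
        p = stats.mannwhitneyu(base[:, j], cross[:, j]).pvalue
        assert p > 0.01
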