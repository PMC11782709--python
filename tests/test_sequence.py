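"""Tests of the triggered PC-GRE schedules and phase-contrast extraction."""

import warnings

import numpy as np
import pytest

from pcss.bloch import TissueProperties, hard_pulse
from pcss.sequence import (
    BackgroundPhase,
    SequenceConfig,
    SignalTrace,
    encoding_labels,
    ideal_spoiled_reference,
    phase_contrast,
    rf_phase_schedule,
    run_sequence,
    steady_state_deviation,
    sweep_background,
    sweep_relaxation,
)
from pcss.bloch import ernst_signal


class TestConfig:
    def test_contrast_and_rf_increment_coupled(self):
        assert SequenceConfig(contrast="FISP").rf_spoil_increment_deg == 0.0
        assert SequenceConfig(contrast="FLASH").rf_spoil_increment_deg == 50.0
        with pytest.raises(ValueError):
            SequenceConfig(contrast="FISP", rf_spoil_increment_deg=50.0)
        with pytest.raises(ValueError):
            SequenceConfig(contrast="FLASH", rf_spoil_increment_deg=0.0)

    def test_te_defaults_to_half_tr(self):
        assert SequenceConfig(tr_ms=6.8).te_ms == pytest.approx(3.4)
        with pytest.raises(ValueError):
            SequenceConfig(tr_ms=5.0, te_ms=5.0)

    def test_replace_rederives_dependent_fields(self):
        cfg = SequenceConfig(contrast="FISP").replace(contrast="FLASH")
        assert cfg.rf_spoil_increment_deg == 50.0


class TestSchedulesAndLabels:
    def test_quadratic_rf_schedule_recurrence(self):
        """phi_k = phi_{k-1} + k * 50 gives 0, 50, 150, 300, 500 (= 140 mod 360)."""
        phases = rf_phase_schedule(5, 50.0)
        np.testing.assert_allclose(phases, [0, 50, 150, 300, 500])
        assert phases[4] % 360 == pytest.approx(140.0)
        # independent direct recurrence oracle
        phi, acc = 0.0, [0.0]
        for k in range(1, 12):
            phi += k * 50.0
            acc.append(phi)
        np.testing.assert_allclose(rf_phase_schedule(12, 50.0), acc)

    def test_tr_mode_alternates_every_tr_including_trigger(self):
        cfg = SequenceConfig(interleave="TR", n_tr_per_cycle=6, n_trigger_tr=2,
                             n_cycles=2)
        _, tic, enc = encoding_labels(cfg)
        np.testing.assert_array_equal(enc, tic % 2 == 1)

    def test_ecg_mode_holds_label_per_cycle(self):
        cfg = SequenceConfig(interleave="ECG", n_tr_per_cycle=6, n_trigger_tr=2,
                             n_cycles=4)
        cyc, _, enc = encoding_labels(cfg)
        np.testing.assert_array_equal(enc, cyc % 2 == 1)

    def test_each_cycle_has_exactly_n_trigger_leading_out_of_window_trs(self):
        cfg = SequenceConfig(n_tr_per_cycle=10, n_trigger_tr=3, n_cycles=3)
        trace = run_sequence(
            cfg.replace(n_slice=1, n_spoiler=1), TissueProperties(100, 50),
            BackgroundPhase(0.0),
        )
        for c in range(3):
            sel = trace.cycle == c
            assert (~trace.in_window[sel]).sum() == 3
            assert not trace.in_window[sel][:3].any()


def synthetic_trace(cfg: SequenceConfig) -> SignalTrace:
    """Trace whose signal phase encodes the global TR index."""
    cyc, tic, enc = encoding_labels(cfg)
    k = np.arange(cfg.n_tr_total)
    return SignalTrace(
        cycle=cyc,
        tr_in_cycle=tic,
        encoded=enc,
        in_window=tic >= cfg.n_trigger_tr,
        signal=np.exp(1j * 0.001 * k),
        config=cfg,
    )


class TestPairing:
    def test_ecg_pairing_matches_hand_enumeration(self):
        """n_tr_per_cycle=6, n_trigger_tr=2, 4 cycles: encoded cycles 1 and 3
        pair TR-by-TR with cycles 0 and 2."""
        cfg = SequenceConfig(interleave="ECG", n_tr_per_cycle=6, n_trigger_tr=2,
                             n_cycles=4)
        series = phase_contrast(synthetic_trace(cfg), cfg, discard_cycles=0)
        expected_pairs = [(0 * 6 + j, 1 * 6 + j) for j in range(2, 6)] + [
            (2 * 6 + j, 3 * 6 + j) for j in range(2, 6)
        ]
        assert len(series) == len(expected_pairs)
        np.testing.assert_allclose(
            series.dphi_rad, [0.001 * (b - a) for a, b in expected_pairs], atol=1e-12
        )
        np.testing.assert_array_equal(series.cycle, [1] * 4 + [3] * 4)

    def test_tr_pairing_consecutive_comp_enc(self):
        cfg = SequenceConfig(interleave="TR", n_tr_per_cycle=6, n_trigger_tr=2,
                             n_cycles=1)
        series = phase_contrast(synthetic_trace(cfg), cfg, discard_cycles=0)
        # in-window TRs 2..5 -> pairs (2,3) and (4,5)
        np.testing.assert_allclose(series.dphi_rad, [0.001, 0.001], atol=1e-12)

    def test_unpaired_trailing_sample_warns(self):
        cfg = SequenceConfig(interleave="TR", n_tr_per_cycle=7, n_trigger_tr=2,
                             n_cycles=1)
        with pytest.warns(UserWarning, match="unpaired"):
            series = phase_contrast(synthetic_trace(cfg), cfg, discard_cycles=0)
        assert len(series) == 2

    def test_ecg_mode_requires_two_cycles(self):
        cfg = SequenceConfig(interleave="ECG", n_cycles=1, n_slice=1, n_spoiler=1)
        with pytest.raises(ValueError, match="n_cycles"):
            run_sequence(cfg, TissueProperties(100, 50), BackgroundPhase(0.0))


class TestZeroAndPerfectLimits:
    @pytest.mark.parametrize("interleave", ["TR", "ECG"])
    def test_zero_background_gives_zero_phase_contrast_fisp(self, interleave):
        """Without RF spoiling the two encodings are strictly identical at
        zero input phase, so the phase contrast vanishes exactly."""
        cfg = SequenceConfig(
            contrast="FISP", interleave=interleave, n_tr_per_cycle=20,
            n_trigger_tr=4, n_cycles=6, n_slice=5, n_spoiler=10,
        )
        series = phase_contrast(
            run_sequence(cfg, TissueProperties(300.0, 80.0), BackgroundPhase(0.0)),
            cfg, discard_cycles=5,
        )
        assert np.abs(series.dphi_rad).max() < 1e-10

    @pytest.mark.parametrize("interleave", ["TR", "ECG"])
    def test_zero_background_flash_residual_ripple_is_small(self, interleave, p2):
        """RF spoiling leaves a small TR-to-TR ripple in the demodulated
        signal, so the zero-input phase contrast is only approximately zero
        (well below the FISP deviations at nonzero input)."""
        cfg = SequenceConfig(
            contrast="FLASH", interleave=interleave,
            n_cycles=4 if interleave == "TR" else 6,
        )
        series = phase_contrast(run_sequence(cfg, p2, BackgroundPhase(0.0)), cfg)
        assert np.abs(series.pct_venc).max() < 0.2

    def test_perfect_spoiling_reproduces_injected_phase_exactly(self):
        cfg = SequenceConfig(
            interleave="TR", n_tr_per_cycle=20, n_trigger_tr=2, n_cycles=3,
            n_slice=3, n_spoiler=4, perfect_spoiling=True,
        )
        bg = BackgroundPhase(5.0)
        series = phase_contrast(run_sequence(cfg, TissueProperties(300, 80), bg), cfg)
        np.testing.assert_allclose(series.dphi_rad, 0.05 * np.pi, atol=1e-12)

    def test_deviation_requires_enough_pairs(self):
        cfg = SequenceConfig(
            interleave="TR", n_tr_per_cycle=12, n_trigger_tr=2, n_cycles=3,
            n_slice=1, n_spoiler=4,
        )
        bg = BackgroundPhase(5.0)
        series = phase_contrast(run_sequence(cfg, TissueProperties(300, 80), bg), cfg)
        with pytest.raises(ValueError):
            steady_state_deviation(series, bg, n_avg=len(series) + 1)
        dev = steady_state_deviation(series, bg, n_avg=2)
        assert np.isfinite(dev)


class TestSteadyStateStructure:
    def test_fisp_tr_phase_contrast_reaches_steady_state_within_a_cycle(self, p2):
        cfg = SequenceConfig(contrast="FISP", interleave="TR", n_cycles=6,
                             n_slice=17, n_spoiler=100)
        series = phase_contrast(run_sequence(cfg, p2, BackgroundPhase(5.0)), cfg)
        last = series.last_cycles(1)
        assert np.abs(np.diff(last.dphi_rad)).max() < 1e-6

    def test_flash_tr_pairwise_variation_is_bounded(self, p2):
        # RF spoiling leaves a small residual oscillation between pairs
        cfg = SequenceConfig(contrast="FLASH", interleave="TR", n_cycles=6,
                             n_slice=17, n_spoiler=100)
        series = phase_contrast(run_sequence(cfg, p2, BackgroundPhase(5.0)), cfg)
        last = series.last_cycles(1)
        assert np.abs(np.diff(last.pct_venc)).max() < 0.5  # %venc

    def test_ecg_fisp_does_not_recover_input_phase_within_cycle(self, p1, p2,
                                                                fast_ecg_config):
        for tissue in (p1, p2):
            series = phase_contrast(
                run_sequence(fast_ecg_config, tissue, BackgroundPhase(10.0)),
                fast_ecg_config,
            )
            last = series.last_cycles(1)
            assert abs(last.pct_venc[-1] - 10.0) > 0.05

    def test_p2_perturbation_stronger_than_p1(self, p1, p2, fast_ecg_config):
        amps = {}
        for name, tissue in (("P1", p1), ("P2", p2)):
            series = phase_contrast(
                run_sequence(fast_ecg_config, tissue, BackgroundPhase(10.0)),
                fast_ecg_config,
            )
            dev = series.last_cycles(1).pct_venc - 10.0
            amps[name] = np.abs(dev).max()
        assert amps["P2"] > amps["P1"]

    def test_very_short_relaxation_suppresses_perturbation(self, p2,
                                                           fast_ecg_config):
        bg = BackgroundPhase(10.0)
        with pytest.warns(UserWarning):  # the T1=10/T2=160 combination is skipped
            table = sweep_relaxation(
                fast_ecg_config, [10.0, p2.t1_ms], [10.0, p2.t2_ms], bg
            )
        short = table[(table.t1_ms == 10.0) & (table.t2_ms == 10.0)].iloc[0]
        long = table[(table.t1_ms == p2.t1_ms) & (table.t2_ms == p2.t2_ms)].iloc[0]
        assert short.amplitude_pct_venc < 0.1 * long.amplitude_pct_venc

    def test_sweep_relaxation_skips_unphysical_pairs_with_warning(
        self, fast_tr_config
    ):
        with pytest.warns(UserWarning, match="T1"):
            table = sweep_relaxation(
                fast_tr_config, [100.0], [50.0, 200.0], BackgroundPhase(5.0)
            )
        assert len(table) == 1

    def test_sweep_single_pair_consistent_with_direct_run(self, fast_tr_config, p2):
        bg = BackgroundPhase(5.0)
        table = sweep_relaxation(fast_tr_config, [p2.t1_ms], [p2.t2_ms], bg)
        direct = steady_state_deviation(
            phase_contrast(run_sequence(fast_tr_config, p2, bg), fast_tr_config), bg
        )
        assert table.iloc[0].deviation_pct_venc == pytest.approx(direct, abs=1e-12)


class TestSweepSymmetryAndOrdering:
    def test_fisp_deviation_curve_is_odd(self, fast_tr_config, p2):
        table = sweep_background(fast_tr_config, p2, [-10.0, 10.0])
        devs = table.deviation_pct_venc.to_numpy()
        assert devs[0] == pytest.approx(-devs[1], abs=1e-9)

    def test_flash_deviation_curve_approximately_odd(self, p2):
        # RF spoiling breaks the exact phase-conjugation symmetry; the
        # residual asymmetry is tiny once the spoiler axis is converged
        cfg = SequenceConfig(contrast="FLASH", interleave="TR", n_cycles=4)
        table = sweep_background(cfg, p2, [-10.0, 10.0])
        devs = table.deviation_pct_venc.to_numpy()
        assert devs[0] == pytest.approx(-devs[1], abs=5e-3)

    @pytest.mark.parametrize("tissue_name", ["p1", "p2"])
    def test_fisp_deviation_exceeds_flash_at_every_nonzero_phi(
        self, tissue_name, request
    ):
        tissue = request.getfixturevalue(tissue_name)
        phis = [-20.0, -10.0, -5.0, 5.0, 10.0, 20.0]
        devs = {}
        for contrast in ("FISP", "FLASH"):
            cfg = SequenceConfig(contrast=contrast, interleave="TR", n_slice=17,
                                 n_spoiler=50, n_cycles=4)
            devs[contrast] = np.abs(
                sweep_background(cfg, tissue, phis).deviation_pct_venc.to_numpy()
            )
        assert (devs["FISP"] > devs["FLASH"]).all()

    def test_pct_venc_is_venc_independent(self, p2):
        series = {}
        for venc in (30.0, 60.0):
            cfg = SequenceConfig(interleave="TR", venc_cms=venc, n_slice=9,
                                 n_spoiler=20, n_cycles=3)
            series[venc] = phase_contrast(
                run_sequence(cfg, p2, BackgroundPhase(5.0)), cfg
            )
        np.testing.assert_allclose(
            series[30.0].pct_venc, series[60.0].pct_venc, atol=1e-12
        )
        np.testing.assert_allclose(
            2 * series[30.0].velocity_cms, series[60.0].velocity_cms, atol=1e-12
        )


class TestIdealReference:
    def test_phase_equals_injected_and_magnitude_closed_form(self, p2):
        cfg = SequenceConfig(interleave="TR")
        bg = BackgroundPhase(7.0)
        ref = ideal_spoiled_reference(cfg, p2, bg)
        np.testing.assert_allclose(ref.dphi_rad, 0.07 * np.pi, atol=1e-15)
        expected = ernst_signal(cfg.flip_deg, cfg.tr_ms, p2) * np.exp(
            -cfg.te_ms / p2.t2_ms
        )
        np.testing.assert_allclose(ref.magnitude, expected, atol=1e-12)

    def test_series_length_matches_window_pairs(self):
        cfg = SequenceConfig(interleave="TR", n_tr_per_cycle=20, n_trigger_tr=4)
        ref = ideal_spoiled_reference(cfg, TissueProperties(100, 50),
                                      BackgroundPhase(0.0))
        assert len(ref) == 8
        cfg = cfg.replace(interleave="ECG")
        ref = ideal_spoiled_reference(cfg, TissueProperties(100, 50),
                                      BackgroundPhase(0.0))
        assert len(ref) == 16
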