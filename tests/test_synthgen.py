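"""Generator unit tests: signal model, quantisation, determinism, pairing."""

import numpy as np
import pytest

from accethogram.synthgen import (
    default_cohort_config,
    simulate_cohort,
    simulate_individual,
    write_fixture,
)
from accethogram.ingest import read_accel_csv, read_annotation_csv
from accethogram.types import BehaviourSpec, CohortConfig, PositionEffect

from conftest import single_behaviour_config


def _still(name="still", **kw):
    defaults = dict(pitch_deg=0, roll_deg=0, osc_freq_hz=0, osc_amp_g=0, noise_sd_g=0,
                    bout_mean_s=20, bout_min_s=5)
    defaults.update(kw)
    return BehaviourSpec(name, **defaults)


class TestSignalModel:
    def test_gravity_only_identity(self):
        """Flat, motionless, noise-free behaviour reads (0, 0, 1) g exactly
        (0 and near-1 are on the quantisation grid to within half a step)."""
        cfg = single_behaviour_config(_still(), resolution_bits=16)
        trace, _ = simulate_individual(cfg, "a", "scute3", seed=1)
        assert np.all(trace.ax == 0)
        assert np.all(trace.ay == 0)
        assert np.allclose(trace.az, 1.0, atol=cfg.dynamic_range_g / 2**16)

    def test_posture_rotation(self):
        """Pitch/roll rotations put gravity where the downstream atan2
        convention recovers the configured angles."""
        cfg = single_behaviour_config(_still(pitch_deg=30, roll_deg=-20), resolution_bits=20)
        trace, _ = simulate_individual(cfg, "a", "scute3", seed=1)
        pitch = np.degrees(np.arctan2(trace.ax, np.hypot(trace.ay, trace.az)))
        roll = np.degrees(np.arctan2(trace.ay, trace.az))
        assert np.allclose(pitch, 30, atol=1e-3)
        assert np.allclose(roll, -20, atol=1e-3)

    def test_mean_abs_sine_oracle(self):
        """Mean |dynamic surge| of a 1 Hz, 0.5 g oscillation over whole
        cycles approaches 2*0.5/pi (closed-form mean of |sin|, checked by
        dense numerical integration)."""
        amp, freq = 0.5, 1.0
        tt = np.linspace(0, 1, 2_000_001)
        oracle = np.trapezoid(np.abs(amp * np.sin(2 * np.pi * freq * tt)), tt)
        assert oracle == pytest.approx(2 * amp / np.pi, rel=1e-6)
        cfg = single_behaviour_config(
            _still(osc_freq_hz=freq, osc_amp_g=amp, bout_mean_s=25, bout_min_s=20),
            duration_s=50, resolution_bits=16,
        )
        trace, _ = simulate_individual(cfg, "a", "scute3", seed=3)
        n_cycles = int(freq * 10)
        seg = trace.ax[: int(n_cycles * cfg.sample_rate_hz / freq)]
        assert np.mean(np.abs(seg - seg.mean())) == pytest.approx(oracle, rel=0.01)


class TestQuantisation:
    def test_grid_and_bound(self):
        """8-bit samples sit on the 256-level grid over ±2 g and within the
        half-step quantisation bound of the ideal signal."""
        cfg = single_behaviour_config(
            _still(pitch_deg=37, noise_sd_g=0.05), dynamic_range_g=2.0, resolution_bits=8
        )
        trace, _ = simulate_individual(cfg, "a", "scute3", seed=2)
        step = 2.0 / 128  # R / 2^(b-1)
        for arr in (trace.ax, trace.ay, trace.az):
            levels = np.round(arr / step)
            assert np.allclose(arr, levels * step, atol=1e-12)
            assert levels.min() >= -128 and levels.max() <= 127
            assert np.abs(arr).max() <= 2.0

    @pytest.mark.parametrize("rng_g", [2.0, 4.0])
    def test_clipping_respects_dynamic_range(self, rng_g):
        cfg = single_behaviour_config(
            _still(osc_freq_hz=1, osc_amp_g=5.0, noise_sd_g=0.2),
            dynamic_range_g=rng_g,
        )
        trace, _ = simulate_individual(cfg, "a", "scute3", seed=4)
        assert np.abs(trace.ax).max() <= rng_g


class TestCohort:
    def test_counts(self):
        cfg = default_cohort_config(seed=0, n_individuals=8, duration_s=120)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 16
        assert len({ann.individual_id for _, ann in cohort}) == 8

    def test_determinism_bit_identical(self):
        cfg = default_cohort_config(seed=5, n_individuals=4, duration_s=100)
        c1 = simulate_cohort(cfg)
        c2 = simulate_cohort(default_cohort_config(seed=5, n_individuals=4, duration_s=100))
        for (t1, a1), (t2, a2) in zip(c1, c2):
            assert np.array_equal(t1.ax, t2.ax)
            assert np.array_equal(t1.az, t2.az)
            assert a1.bouts == a2.bouts

    def test_null_position_effect_identity(self):
        """With individual_sd=0 and no position effect the two positions of
        one individual are the same trace (paired noise streams)."""
        cfg = default_cohort_config(
            seed=3, n_individuals=4, duration_s=100,
            scute1_gain=1.0, scute1_extra_noise_g=0.0, individual_sd=0.0,
        )
        cohort = simulate_cohort(cfg)
        by_ind = {}
        for tr, _ in cohort:
            by_ind.setdefault(tr.individual_id, []).append(tr)
        for trs in by_ind.values():
            a, b = trs
            assert np.array_equal(a.ax, b.ax)
            assert np.array_equal(a.ay, b.ay)
            assert np.array_equal(a.az, b.az)

    def test_positions_share_behaviour_sequence(self, small_cohort):
        _, cohort = small_cohort
        by_ind = {}
        for tr, ann in cohort:
            by_ind.setdefault(tr.individual_id, []).append(ann)
        for anns in by_ind.values():
            assert anns[0].bouts == anns[1].bouts

    def test_bouts_tile_recording(self, small_cohort):
        """Bout spans tile [start, start+duration] without gaps or overlap."""
        cfg, cohort = small_cohort
        for _, ann in cohort:
            starts = [s for _, s, _ in ann.bouts]
            ends = [e for _, _, e in ann.bouts]
            assert starts[0] == pytest.approx(cfg.start_utc)
            assert ends[-1] == pytest.approx(cfg.start_utc + cfg.duration_s)
            assert np.allclose(ends[:-1], starts[1:])
            assert ann.total_duration_s == pytest.approx(cfg.duration_s)


class TestValidationErrors:
    def test_non_square_transition_matrix(self):
        with pytest.raises(ValueError, match="square"):
            CohortConfig(
                species="t", n_individuals=4,
                behaviours=[_still("a"), _still("b")],
                transition_weights=np.ones((2, 3)),
            )

    def test_duration_too_short(self):
        cfg = single_behaviour_config(_still(bout_mean_s=40), duration_s=50)
        with pytest.raises(ValueError, match="too short"):
            simulate_individual(cfg, "a", "scute3", seed=0)


class TestFixtureIO:
    def test_round_trip(self, tmp_path, small_cohort):
        _, cohort = small_cohort
        write_fixture(cohort[:2], tmp_path)
        for trace, ann in cohort[:2]:
            back = read_accel_csv(tmp_path / f"{trace.individual_id}_{trace.position}.csv")
            assert np.allclose(back.ax, trace.ax, atol=1e-6)
            assert np.allclose(back.az, trace.az, atol=1e-6)
            assert back.individual_id == trace.individual_id
            assert back.position == trace.position
            ann_back = read_annotation_csv(tmp_path / f"{ann.individual_id}_annotations.csv")
            assert [b for b, _, _ in ann_back.bouts] == [b for b, _, _ in ann.bouts]
            got = np.array([(s, e) for _, s, e in ann_back.bouts])
            want = np.array([(s, e) for _, s, e in ann.bouts])
            assert np.allclose(got, want, atol=1e-3)  # ms timestamp precision

    def test_row_count(self, tmp_path):
        cfg = single_behaviour_config(_still(), duration_s=50)
        trace, ann = simulate_individual(cfg, "a", "scute3", seed=0)
        write_fixture([(trace, ann)], tmp_path)
        lines = (tmp_path / "a_scute3.csv").read_text().strip().splitlines()
        assert len(lines) - 1 == 50 * 100

    def test_empty_cohort(self, tmp_path):
        assert write_fixture([], tmp_path / "empty") == []
        assert list((tmp_path / "empty").iterdir()) == []
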