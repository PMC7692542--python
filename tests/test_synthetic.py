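"""Generator properties: determinism, coupling structure, cohort balance."""

import numpy as np
import pytest

from dyadsync.config import ConfigError, SynthConfig
from dyadsync.core import Condition
from dyadsync.synthetic import (
    GroundTruth,
    generate_blendshape_pair,
    generate_cohort,
    generate_drive_pair,
    generate_questionnaires,
    generate_session,
    generate_skeleton_pair,
)


def _lagged_corr(a, b, k):
    if k >= 0:
        return np.corrcoef(a[: len(a) - k or None], b[k:])[0, 1]
    return np.corrcoef(a[-k:], b[: len(b) + k])[0, 1]


class TestDrivePair:
    def test_uncoupled_drives_uncorrelated(self):
        cfg = SynthConfig(duration_s=400, coupling_alpha=0.0)
        a, b = generate_drive_pair(cfg, seed=1)
        # band-limited series carry ~2*bandwidth independent values per
        # second, not one per sample, so the null SE uses that count
        n_eff = cfg.duration_s * 2 * cfg.drive_bandwidth_hz
        for k in (-30, -3, 0, 3, 30):
            assert abs(_lagged_corr(a, b, k)) < 3 / np.sqrt(n_eff)

    def test_full_coupling_peaks_at_zero_lag(self):
        cfg = SynthConfig(duration_s=400, coupling_alpha=1.0, coupling_lag_s=0.0)
        a, b = generate_drive_pair(cfg, seed=2)
        r0 = _lagged_corr(a, b, 0)
        assert r0 > 0.6
        assert all(r0 >= _lagged_corr(a, b, k) for k in (-60, -15, 15, 60))

    def test_peak_lag_and_strength_match_monte_carlo_oracle(self):
        """Estimated peak lag/height vs direct simulation of the same model."""
        cfg = SynthConfig(duration_s=340, coupling_alpha=0.8, coupling_lag_s=0.5)
        rate = int(cfg.nominal_rate_hz)
        grid = range(-5 * rate, 5 * rate + 1, 3)

        def peak(seed):
            a, b = generate_drive_pair(cfg, seed)
            rs = [(k, _lagged_corr(a, b, k)) for k in grid]
            k_best, r_best = max(rs, key=lambda t: t[1])
            return k_best / rate, r_best

        oracle = np.array([peak(7000 + i) for i in range(30)])
        assert abs(np.mean(oracle[:, 0]) - 0.5) <= 0.1
        lag, r = peak(123)
        assert abs(lag - 0.5) <= 0.1
        assert abs(r - np.mean(oracle[:, 1])) <= 0.05

    def test_drives_nonnegative(self):
        cfg = SynthConfig(duration_s=60)
        a, b = generate_drive_pair(cfg, seed=3)
        assert (a >= 0).all() and (b >= 0).all()

    def test_excessive_lag_rejected(self):
        with pytest.raises(ConfigError):
            generate_drive_pair(
                SynthConfig(duration_s=10, coupling_lag_s=9.0), seed=0
            )


class TestSkeletonPair:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(duration_s=20)
        a1, b1 = generate_skeleton_pair(cfg, seed=9)
        a2, b2 = generate_skeleton_pair(cfg, seed=9)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(a1.timestamps, a2.timestamps)
        assert np.array_equal(b1.values, b2.values)

    def test_timestamps_strictly_increasing(self):
        cfg = SynthConfig(duration_s=30, dropout_fraction=0.1)
        a, b = generate_skeleton_pair(cfg, seed=4)
        assert np.all(np.diff(a.timestamps) > 0)
        assert np.all(np.diff(b.timestamps) > 0)

    def test_dropout_fraction_near_configured(self):
        cfg = SynthConfig(duration_s=240, dropout_fraction=0.2)
        missing = []
        for seed in range(6):
            a, b = generate_skeleton_pair(cfg, seed=seed)
            n_nominal = int(cfg.duration_s * cfg.nominal_rate_hz)
            missing += [1 - len(a) / n_nominal, 1 - len(b) / n_nominal]
        assert abs(np.mean(missing) - 0.2) < 0.03

    def test_joint_count_and_bounds(self):
        cfg = SynthConfig(duration_s=10)
        a, _ = generate_skeleton_pair(cfg, seed=5)
        assert a.values.shape[1] == 51
        assert np.abs(a.values).max() < 10.0


class TestBlendshapes:
    def test_values_within_unit_interval_with_clipping(self):
        cfg = SynthConfig(
            duration_s=120, blendshape_event_rate_hz=0.6,
            blendshape_event_amplitude=1.4,
        )
        a, b = generate_blendshape_pair(cfg, seed=6)
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0
        assert a.values.max() == 1.0  # clipped overlapping events

    def test_zero_event_rate_gives_silence(self):
        cfg = SynthConfig(duration_s=30, blendshape_event_rate_hz=0.0)
        a, b = generate_blendshape_pair(cfg, seed=7)
        assert np.all(a.values == 0) and np.all(b.values == 0)


class TestQuestionnaires:
    def _truth(self, n=4, scale_mean=4.0):
        import pandas as pd
        rows = []
        for i in range(n):
            row = {
                "participant_id": f"p{i}", "dyad_id": f"d{i // 2}",
                "latent_attraction": 0.0, "attraction_class": "low",
                "attraction_scale_mean": scale_mean, "gender": "F",
            }
            row.update({f"trait_{k}": 4.0 for k in range(1, 16)})
            rows.append(row)
        return GroundTruth(pd.DataFrame(), pd.DataFrame(rows))

    def test_midpoint_zero_noise_gives_all_fours(self):
        cfg = SynthConfig(duration_s=10, attraction_item_noise_sd=0.0)
        recs = generate_questionnaires(self._truth(scale_mean=4.0), cfg, seed=1)
        for r in recs:
            assert np.all(r.attraction_items == 4)

    def test_zero_observer_noise_reproduces_self_profile(self):
        cfg = SynthConfig(duration_s=10, bfi_observer_noise_sd=0.0,
                          bfi_missing_prob=0.0)
        recs = generate_questionnaires(self._truth(), cfg, seed=2)
        for r in recs:
            np.testing.assert_array_equal(r.bfi_observer, r.bfi_self)

    def test_higher_latent_attraction_raises_item_means(self):
        import pandas as pd
        cfg = SynthConfig(duration_s=10, attraction_item_noise_sd=0.5)
        lo = generate_questionnaires(self._truth(n=60, scale_mean=3.5), cfg, 3)
        hi = generate_questionnaires(self._truth(n=60, scale_mean=5.0), cfg, 3)
        mean_lo = np.mean([r.attraction_items.mean() for r in lo])
        mean_hi = np.mean([r.attraction_items.mean() for r in hi])
        assert mean_hi - mean_lo > 1.0


class TestCohort:
    def test_conditions_balanced(self):
        cfg = SynthConfig(duration_s=8)
        sessions, _, truth = generate_cohort(8, cfg, seed=11)
        names = [s.condition.name for s in sessions]
        assert all(names.count(c.name) == 2 for c in
                   (Condition(True, True), Condition(False, False),
                    Condition(True, False), Condition(False, True)))

    def test_gender_balanced_within_cells(self):
        cfg = SynthConfig(duration_s=8)
        sessions, _, _ = generate_cohort(8, cfg, seed=11)
        by_cell = {}
        for s in sessions:
            by_cell.setdefault(s.condition.name, []).append(s.gender)
        for genders in by_cell.values():
            assert sorted(genders) == ["F", "M"]

    def test_same_seed_identical_truth(self):
        cfg = SynthConfig(duration_s=8)
        _, _, t1 = generate_cohort(6, cfg, seed=3)
        _, _, t2 = generate_cohort(6, cfg, seed=3)
        assert t1.dyads.equals(t2.dyads)
        assert t1.participants.equals(t2.participants)

    def test_attraction_class_is_median_split_of_latents(self):
        cfg = SynthConfig(duration_s=8)
        _, _, truth = generate_cohort(10, cfg, seed=4)
        med = truth.dyads["latent_attraction"].median()
        expected = np.where(truth.dyads["latent_attraction"] > med, "high", "low")
        assert list(truth.dyads["attraction_class"]) == list(expected)
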