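"""Behavioral raster I/O, binned summaries and the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from mauthner.behavior import (
    DEFAULT_PROFILES,
    GroupProfile,
    ResponseRaster,
    binned_percent_response,
    fit_habituation_curve,
    generate_raster,
    latency_summary,
    pooled_block_rates,
    read_raster,
    write_raster,
)


def small_raster(latencies=False):
    responses = np.array([
        [1, 1, 1, 1, 1, 0, 0, 0],
        [1, 0, 1, 0, 1, 0, 1, 0],
        [1, 1, 0, 0, 1, 1, 0, 0],
    ])
    lat = None
    if latencies:
        lat = np.where(responses == 1, 5.0, np.nan)
    return ResponseRaster(responses=responses,
                          groups=np.array(["dominant", "subordinate", "communal"],
                                          dtype=object),
                          frequency_hz=1.0, latencies=lat)


class TestRasterIO:
    def test_round_trip_identity(self, tmp_path):
        raster = generate_raster(n_animals=4, seed=7)
        path = tmp_path / "raster.csv"
        write_raster(raster, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.responses, raster.responses)
        np.testing.assert_array_equal(back.groups, raster.groups)
        np.testing.assert_allclose(back.latencies, raster.latencies, equal_nan=True)
        assert back.frequency_hz == raster.frequency_hz

    def test_non_binary_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "animal_id,group,frequency_hz,s01,s02\n"
            "a001,dominant,1.0,1,0\n"
            "a002,dominant,1.0,2,0\n"
        )
        with pytest.raises(ValueError, match=r"row 3.*s01"):
            read_raster(path)

    def test_unknown_group_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "animal_id,group,frequency_hz,s01\na001,alpha,1.0,1\n")
        with pytest.raises(ValueError, match="unknown group"):
            read_raster(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("animal_id,group,frequency_hz,s01\n")
        with pytest.raises(ValueError, match="empty"):
            read_raster(path)

    def test_invalid_matrix_rejected_at_construction(self):
        with pytest.raises(ValueError, match="binary"):
            ResponseRaster(responses=np.array([[0, 2]]),
                           groups=np.array(["dominant"], dtype=object),
                           frequency_hz=1.0)
        with pytest.raises(ValueError, match="latency"):
            ResponseRaster(responses=np.array([[0, 1]]),
                           groups=np.array(["dominant"], dtype=object),
                           frequency_hz=1.0,
                           latencies=np.array([[5.0, np.nan]]))


class TestBinnedPercentResponse:
    def test_all_ones_gives_hundred_percent_everywhere(self):
        raster = ResponseRaster(responses=np.ones((5, 8), dtype=int),
                                groups=np.array(["communal"] * 5, dtype=object),
                                frequency_hz=1.0)
        out = binned_percent_response(raster, stimuli_per_bin=2)
        assert (out["mean_percent"] == 100.0).all()
        assert (out["sem"] == 0.0).all()

    def test_two_animal_arithmetic(self):
        # bin of 2: animal A responds (1,1) -> 100%, animal B (1,0) -> 50%
        raster = ResponseRaster(responses=np.array([[1, 1], [1, 0]]),
                                groups=np.array(["dominant"] * 2, dtype=object),
                                frequency_hz=1.0)
        out = binned_percent_response(raster, stimuli_per_bin=2)
        assert out.loc[0, "mean_percent"] == pytest.approx(75.0)
        # SEM of {100, 50} = sd/sqrt(2) = 35.36/1.414 = 25
        assert out.loc[0, "sem"] == pytest.approx(25.0)

    def test_alternating_pattern_gives_fifty_percent(self):
        responses = np.tile([1, 0], (3, 4))
        raster = ResponseRaster(responses=responses,
                                groups=np.array(["subordinate"] * 3, dtype=object),
                                frequency_hz=1.0)
        out = binned_percent_response(raster, stimuli_per_bin=2)
        assert (out["mean_percent"] == 50.0).all()

    def test_bin_must_divide(self):
        with pytest.raises(ValueError):
            binned_percent_response(small_raster(), stimuli_per_bin=3)

    def test_counts_conserved_for_constant_raster(self):
        # an all-k raster yields exactly 100k percent in every bin
        for k in (0, 1):
            raster = ResponseRaster(responses=np.full((4, 8), k, dtype=int),
                                    groups=np.array(["communal"] * 4, dtype=object),
                                    frequency_hz=0.2)
            out = binned_percent_response(raster, 2)
            assert (out["mean_percent"] == 100.0 * k).all()


class TestPooledBlockRates:
    def test_monotone_habituator(self):
        responses = np.zeros((1, 40), dtype=int)
        responses[0, :5] = 1
        raster = ResponseRaster(responses=responses,
                                groups=np.array(["dominant"], dtype=object),
                                frequency_hz=1.0)
        out = pooled_block_rates(raster, block=5)
        assert out.loc[0, "rate"] == 1.0
        assert (out.loc[1:, "rate"] == 0.0).all()

    def test_uniform_bernoulli_blocks_near_half(self):
        rng = np.random.default_rng(42)
        responses = (rng.random((200, 40)) < 0.5).astype(int)
        raster = ResponseRaster(responses=responses,
                                groups=np.array(["communal"] * 200, dtype=object),
                                frequency_hz=1.0)
        out = pooled_block_rates(raster)
        assert np.allclose(out["rate"], 0.5, atol=0.06)

    def test_first_block_highest_on_generator_defaults(self):
        raster = generate_raster(n_animals=40, seed=3)
        out = pooled_block_rates(raster)
        for group, sub in out.groupby("group"):
            rates = sub.sort_values("block")["rate"].to_numpy()
            assert rates[0] >= rates[-1]


class TestGenerator:
    def test_identical_seeds_identical_rasters(self):
        a = generate_raster(seed=11)
        b = generate_raster(seed=11)
        np.testing.assert_array_equal(a.responses, b.responses)
        np.testing.assert_allclose(a.latencies, b.latencies, equal_nan=True)

    def test_flat_profile_recovers_rate(self):
        # degenerate profile p0 = plateau = p: empirical rate ~ Binomial mean
        profiles = {"communal": GroupProfile(p0=0.3, plateau=0.3, decay_constant=1e9)}
        raster = generate_raster(profiles=profiles, n_animals=200, seed=5)
        rate = raster.responses.mean()
        # 3 sigma binomial CI at n = 200 * 40 draws
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (200 * 40))

    def test_status_ordering_at_default_profiles(self):
        raster = generate_raster(n_animals=20, seed=2)
        rates = {g: raster.responses[raster.group_mask(g)].mean()
                 for g in raster.present_groups()}
        assert rates["subordinate"] > rates["dominant"]

    def test_frequency_effect_direction(self):
        hi = generate_raster(n_animals=50, frequency_hz=1.0, seed=8)
        lo = generate_raster(n_animals=50, frequency_hz=0.2, seed=8)
        for g in ("dominant", "communal", "subordinate"):
            assert (lo.responses[lo.group_mask(g)].mean()
                    > hi.responses[hi.group_mask(g)].mean())

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            GroupProfile(p0=1.2, plateau=0.5, decay_constant=3.0)
        with pytest.raises(ValueError):
            GroupProfile(p0=1.0, plateau=0.5, decay_constant=0.0)


class TestLatencySummary:
    def test_two_value_arithmetic(self):
        responses = np.array([[1, 1]])
        lat = np.array([[4.0, 6.0]])
        raster = ResponseRaster(responses=responses,
                                groups=np.array(["communal"], dtype=object),
                                frequency_hz=1.0, latencies=lat)
        out = latency_summary(raster)
        assert out.loc[0, "mean_ms"] == pytest.approx(5.0)
        assert out.loc[0, "sem_ms"] == pytest.approx(1.0)

    def test_single_trial_flagged_with_zero_sem(self):
        responses = np.array([[1, 0]])
        lat = np.array([[5.0, np.nan]])
        raster = ResponseRaster(responses=responses,
                                groups=np.array(["dominant"], dtype=object),
                                frequency_hz=1.0, latencies=lat)
        out = latency_summary(raster)
        assert out.loc[0, "mean_ms"] == 5.0
        assert out.loc[0, "sem_ms"] == 0.0
        assert bool(out.loc[0, "single_trial"])

    def test_gaussian_latencies_recovered(self):
        raster = generate_raster(n_animals=100, seed=9,
                                 latency_mean=5.7, latency_sd=1.0)
        out = latency_summary(raster)
        assert np.allclose(out["mean_ms"], 5.7, atol=0.15)

    def test_missing_latency_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            latency_summary(small_raster(latencies=False))


class TestCurveRecovery:
    def test_generator_parameters_recovered_at_large_n(self):
        # least squares on per-stimulus group means, 200 animals per group
        raster = generate_raster(n_animals=200, seed=17)
        for group in ("dominant", "communal", "subordinate"):
            truth = DEFAULT_PROFILES[(group, 1.0)]
            fit = fit_habituation_curve(raster, group)
            assert abs(fit.p0 - truth.p0) <= 0.05
            assert abs(fit.plateau - truth.plateau) <= 0.05
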