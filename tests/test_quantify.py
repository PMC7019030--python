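"""Relative punctal fluorescence, dendrite normalization, pooling."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_punctal_fluorescence
from punctakit import (
    AlignmentError,
    LinescanSeries,
    NormalizationError,
    SimParams,
    TranslocationSeries,
    bleach_correct,
    detect_puncta,
    group_summary,
    pool_dendrites,
    punctal_fluorescence,
    simulate_linescan_dataset,
    timepoint_table,
    translocation_series,
)
from punctakit.detect import PunctaSet, Punctum


def puncta_set(regions, length):
    return PunctaSet(
        positions=np.arange(length),
        quotients=np.ones(length),
        flags=np.zeros(length, dtype=bool),
        puncta=[Punctum(start=a, end=b, center=(a + b) // 2, center_quotient=1.5)
                for a, b in regions],
        profile_length=length,
    )


class TestPunctalFluorescence:
    def test_fraction_of_total(self):
        profile = np.full(100, 5.0)  # total 500
        ps = puncta_set([(10, 20)], 100)  # region sums to 50
        np.testing.assert_allclose(punctal_fluorescence(profile, ps), [0.1])

    def test_whole_profile_punctum_is_one(self, rng):
        profile = rng.uniform(1, 10, 50)
        ps = puncta_set([(0, 50)], 50)
        np.testing.assert_allclose(punctal_fluorescence(profile, ps), [1.0], rtol=1e-12)

    def test_empty_set_gives_empty_array(self, rng):
        assert punctal_fluorescence(rng.uniform(1, 2, 40), puncta_set([], 40)).size == 0

    def test_matches_brute_force_slice_sums(self, rng):
        for _ in range(30):
            profile = rng.uniform(0.1, 100, size=80)
            edges = np.sort(rng.choice(np.arange(1, 80), size=6, replace=False))
            regions = [(int(edges[i]), int(edges[i + 1])) for i in range(0, 6, 2)]
            got = punctal_fluorescence(profile, puncta_set(regions, 80))
            want = brute_punctal_fluorescence(list(profile), regions)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_relative_values_sum_below_one(self, rng):
        profile = rng.uniform(0.1, 100, size=80)
        regions = [(0, 20), (25, 40), (60, 79)]
        assert punctal_fluorescence(profile, puncta_set(regions, 80)).sum() <= 1.0


class TestTranslocationSeries:
    def _series(self, profiles):
        profiles = np.asarray(profiles, dtype=float)
        return LinescanSeries(profiles=profiles, times=np.arange(len(profiles)) * 30.0)

    def test_identical_frames_self_normalize_to_one(self):
        profile = np.full(60, 100.0)
        profile[28:33] = 220.0
        series = self._series([profile, profile, profile])
        pbf = [detect_puncta(p) for p in series.profiles]
        ts = translocation_series(series, pbf)
        np.testing.assert_allclose(ts.rel_fluor, 1.0, rtol=1e-12)

    def test_rel_fluor_is_value_over_initial(self):
        ts = TranslocationSeries("d0", np.array([0.0, 30, 60]), np.array([1.0, 1.2, 1.5]))
        np.testing.assert_allclose(ts.rel_fluor, [1.0, 1.2, 1.5])

    def test_no_initial_puncta_raises_normalization_error(self):
        flat = np.full(60, 100.0)
        bright = flat.copy()
        bright[28:33] = 250.0
        series = self._series([flat, bright])
        pbf = [detect_puncta(p) for p in series.profiles]
        with pytest.raises(NormalizationError):
            translocation_series(series, pbf)

    def test_rescaling_frames_leaves_rel_fluor_unchanged(self):
        # relative-to-total cancels any per-frame scalar (hence bleach correction)
        ds = simulate_linescan_dataset(SimParams(bleach_tau=180.0, seed=5), 1)
        raw = ds.traces[0]
        corrected, _ = bleach_correct(raw)
        pbf_raw = [detect_puncta(p) for p in raw.profiles]
        pbf_cor = [detect_puncta(p) for p in corrected.profiles]
        a = translocation_series(raw, pbf_raw)
        b = translocation_series(corrected, pbf_cor)
        np.testing.assert_allclose(a.rel_fluor, b.rel_fluor, rtol=1e-10)


class TestPooling:
    def _ts(self, did, rel, condition="vehicle"):
        return TranslocationSeries(did, np.arange(len(rel)) * 30.0, np.array(rel),
                                   condition=condition)

    def test_single_series_round_trips(self):
        table = pool_dendrites([self._ts("d0", [1.0, 1.2, 1.4])])
        summary = group_summary(table)
        np.testing.assert_allclose(summary["mean"], [1.0, 1.2, 1.4])

    def test_identical_series_have_zero_sem(self):
        table = pool_dendrites([self._ts("d0", [1.0, 1.3]), self._ts("d1", [1.0, 1.3])])
        summary = group_summary(table)
        np.testing.assert_allclose(summary["sem"], 0.0, atol=1e-15)

    def test_mismatched_time_grids_rejected(self):
        a = self._ts("d0", [1.0, 1.2, 1.4])
        b = TranslocationSeries("d1", np.array([0.0, 40.0, 80.0]), np.array([1.0, 1.1, 1.2]))
        with pytest.raises(AlignmentError):
            pool_dendrites([a, b])

    def test_group_mean_recovers_known_plateau(self, rng):
        # 20 simulated dendrites with known plateau 1.5: mean at 360 s within 3 SEM
        plateau = 1.5
        series = []
        times = np.arange(13) * 30.0
        s01 = 1.0 / (1.0 + np.exp(-(times - 150.0) / 30.0))
        s01 = (s01 - s01[0]) / (s01[-1] - s01[0])
        for i in range(20):
            rel = 1.0 + (plateau - 1.0) * s01 + rng.normal(0, 0.05, 13)
            rel[0] = 1.0
            series.append(self._ts(f"d{i}", rel))
        summary = group_summary(pool_dendrites(series))
        last = summary[summary["time_s"] == 360.0].iloc[0]
        assert abs(last["mean"] - plateau) < 3 * last["sem"] + 1e-9

    def test_timepoint_table_returns_exact_report_times(self):
        table = pool_dendrites([self._ts("d0", list(np.linspace(1, 2, 13)))])
        sub = timepoint_table(table, [90.0, 240.0, 360.0])
        assert sorted(sub["time_s"].unique()) == [90.0, 240.0, 360.0]
        with pytest.raises(AlignmentError):
            timepoint_table(table, [95.0])
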