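"""Unit and property tests for the per-frame / per-participant measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import laryngodyn as ld
from laryngodyn.measures import Direction, frames_long_table
from tests.conftest import make_series

finite_coord = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite_coord, finite_coord, finite_coord)


class TestComputeIad:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((0, 0, 0), (0, 0, 0), 0.0),
            ((0, 0, 0), (3, 4, 0), 5.0),
            ((1, 1, 1), (2, 3, 2), math.sqrt(6)),
        ],
    )
    def test_euclidean_distance(self, left, right, expected):
        assert ld.compute_iad(left, right) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ld.compute_iad((0, 0, np.nan), (1, 1, 1))
        with pytest.raises(ValueError):
            ld.compute_iad((0, 0, 0), (np.inf, 0, 0))

    @given(a=point, b=point)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_nonnegative_zero_iff_coincident(self, a, b):
        d = ld.compute_iad(a, b)
        assert d >= 0
        assert d == ld.compute_iad(b, a)
        if a == b:
            assert d == 0
        elif max(abs(x - y) for x, y in zip(a, b)) > 1e-100:
            # separations far below 1e-150 underflow when squared
            assert d > 0

    @given(a=point, b=point, shift=point,
           angle=st.floats(0, 2 * math.pi, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_rigid_transform_invariance(self, a, b, shift, angle):
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        ta = rot @ np.array(a) + shift
        tb = rot @ np.array(b) + shift
        assert ld.compute_iad(ta, tb) == pytest.approx(
            ld.compute_iad(a, b), abs=1e-9
        )


class TestComputeIai:
    @pytest.mark.parametrize(
        "ga, iad, expected",
        [(5.0, 2.0, 2.5), (0.0, 3.0, 0.0), (4.2, 1.4, 3.0)],
    )
    def test_ratio(self, ga, iad, expected):
        assert ld.compute_iai(ga, iad) == pytest.approx(expected, abs=1e-12)

    def test_undefined_for_nonpositive_iad(self):
        with pytest.raises(ValueError):
            ld.compute_iai(5.0, 0.0)
        with pytest.raises(ValueError):
            ld.compute_iai(5.0, -1.0)

    @given(ga=st.floats(0, 1e3), iad=st.floats(1e-3, 1e2))
    @settings(max_examples=300, deadline=None)
    def test_product_identity(self, ga, iad):
        assert abs(ld.compute_iai(ga, iad) * iad - ga) <= 1e-9


class TestArytenoidVelocity:
    def _frame(self, idx, left, right):
        return ld.FiducialFrame(
            frame_index=idx, time_ms=idx * 100.0,
            left_marker=left, right_marker=right,
        )

    def test_stationary_when_unmoved(self):
        a = self._frame(0, (-2, 0, 0), (2, 0, 0))
        b = self._frame(1, (-2, 0, 0), (2, 0, 0))
        av, direction = ld.arytenoid_velocity(a, b)
        assert av == 0.0
        assert direction is Direction.STATIONARY

    def test_sum_of_displacements_adduction(self):
        a = self._frame(0, (-3, 0, 0), (3, 0, 0))
        b = self._frame(1, (-2, 0, 0), (1, 0, 0))  # left +1, right -2: IAD 6->3
        av, direction = ld.arytenoid_velocity(a, b)
        assert av == pytest.approx(3.0)
        assert direction is Direction.ADDUCTION

    def test_symmetric_abduction(self):
        a = self._frame(0, (-1, 0, 0), (1, 0, 0))
        b = self._frame(1, (-1.5, 0, 0), (1.5, 0, 0))
        av, direction = ld.arytenoid_velocity(a, b)
        assert av == pytest.approx(1.0)
        assert direction is Direction.ABDUCTION

    def test_iad_delta_variant(self):
        a = self._frame(0, (-3, 0, 0), (3, 0, 0))
        b = self._frame(1, (-2, 0, 0), (1, 0, 0))
        av, _ = ld.arytenoid_velocity(a, b, variant="iad-delta")
        assert av == pytest.approx(3.0)  # IAD 6 -> 3

    def test_rejects_non_successive_frames(self):
        a = self._frame(0, (-1, 0, 0), (1, 0, 0))
        b = self._frame(2, (-1, 0, 0), (1, 0, 0))
        with pytest.raises(ValueError):
            ld.arytenoid_velocity(a, b)


class TestTrimToVocalization:
    def test_trims_leading_and_trailing_open_runs(self):
        ga = [200.0] * 5 + [20.0] * 20 + [200.0] * 5
        trimmed = ld.trim_to_vocalization(make_series(ga), 2.0)
        expected = np.array([False] * 5 + [True] * 20 + [False] * 5)
        assert (trimmed.vocalization_mask == expected).all()

    def test_interior_spikes_are_kept(self):
        ga = [200.0] * 3 + [20.0] * 5 + [300.0, 20.0] * 5 + [200.0] * 3
        trimmed = ld.trim_to_vocalization(make_series(ga), 2.0)
        assert trimmed.vocalization_mask[3:-3].all()

    def test_nothing_to_trim(self):
        ga = [20.0, 21.0, 19.0, 20.0]
        trimmed = ld.trim_to_vocalization(make_series(ga), 2.0)
        assert trimmed.vocalization_mask.all()

    def test_everything_above_threshold_is_an_error(self):
        # constant GA with a sub-unity factor: every frame exceeds the cut
        series = make_series([4.0] * 6)
        with pytest.raises(ld.UnusableSeriesError):
            ld.trim_to_vocalization(series, 0.5)

    def test_no_ga_at_all_is_an_error(self):
        series = make_series([None] * 4)
        with pytest.raises(ld.UnusableSeriesError):
            ld.trim_to_vocalization(series)


class TestEffectiveExtreme:
    @pytest.mark.parametrize(
        "values, k, mode, expected",
        [
            (list(range(1, 11)), 5, "min", 3.0),
            ([4, 4, 4, 4, 4, 4], 5, "min", 4.0),
            ([4, 4, 4, 4, 4, 4], 5, "max", 4.0),
            ([10, 1, 7, 3, 9, 2, 8], 5, "max", 8.0),
        ],
    )
    def test_examples(self, values, k, mode, expected):
        assert ld.effective_extreme(values, k=k, mode=mode) == expected

    def test_short_list_uses_all_with_warning(self):
        with pytest.warns(UserWarning):
            assert ld.effective_extreme([2.0, 4.0], k=5, mode="min") == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ld.effective_extreme([], k=5)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_brackets_the_median(self, values):
        lo = ld.effective_extreme(values, mode="min")
        hi = ld.effective_extreme(values, mode="max")
        med = float(np.median(values))
        assert lo <= med + 1e-12
        assert hi >= med - 1e-12

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30),
           st.sampled_from(["min", "max"]))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_order_statistics(self, values, mode):
        k = min(5, len(values))
        ordered = sorted(values)
        chosen = ordered[:k] if mode == "min" else ordered[-k:]
        expected = float(np.median(chosen))
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = ld.effective_extreme(values, mode=mode)
        assert got == pytest.approx(expected, abs=1e-12)


class TestSummarizeParticipant:
    def test_constant_series(self):
        series = make_series([6.0] * 10, [3.0] * 10)
        s = ld.summarize_participant(series)
        assert s.mean_ga == s.eff_min_ga == 6.0
        assert s.mean_iad == s.eff_min_iad == 3.0
        assert s.mean_iai == s.eff_max_iai == 2.0
        assert s.mean_av == 0.0 and s.eff_max_av == 0.0
        # no frame pair ever adducts or abducts
        assert math.isnan(s.eff_max_abv) and math.isnan(s.eff_max_adv)

    def test_missingness_bookkeeping(self):
        ga = [5.0] * 9 + [None]
        s = ld.summarize_participant(make_series(ga, list(range(2, 12))))
        assert s.n_frames_ga == s.n_frames_iad - 1
        assert s.n_frames_iai == s.n_frames_ga

    def test_only_vocalizing_frames_contribute(self):
        ga = [100.0, 10.0, 10.0, 100.0]
        mask = [False, True, True, False]
        s = ld.summarize_participant(make_series(ga, mask=mask))
        assert s.n_frames_ga == 2
        assert s.mean_ga == 10.0

    def test_no_vocalizing_frames_is_an_error(self):
        series = make_series([5.0] * 4, mask=[False] * 4)
        with pytest.raises(ld.UnusableSeriesError):
            ld.summarize_participant(series)

    def test_velocity_direction_partition(self, small_cohort):
        _, cohort = small_cohort
        for _, series in cohort[:4]:
            trimmed = ld.trim_to_vocalization(series)
            mask = trimmed.vocalization_mask
            # pairs = vocalizing frames minus one per contiguous run
            runs = np.diff(np.flatnonzero(
                np.diff(np.r_[0, mask.astype(int), 0]))
            )[::2]
            n_pairs = int(sum(r - 1 for r in runs))
            s = ld.summarize_participant(trimmed)
            assert s.n_velocity_pairs == n_pairs

    def test_matches_independent_recomputation_on_true_values(self):
        """Noise-free generator series: summary equals a from-scratch
        recomputation on the stored ground-truth channels."""
        cfg = ld.SyntheticCohortConfig(
            marker_noise_sd=0.0, ga_noise_sd=0.0, participant_iad_sd=0.0,
            rng_seed=3,
        )
        series = ld.generate_phonation_trace(
            cfg, 60.0, np.random.default_rng(3)
        )
        s = ld.summarize_participant(series)  # generator truth mask
        m = series.vocalization_mask
        iad = series.true_iad[m]
        ga = series.true_ga[m]
        assert s.mean_iad == pytest.approx(np.mean(iad), abs=1e-9)
        assert s.mean_ga == pytest.approx(np.mean(ga), abs=1e-9)
        assert s.mean_iai == pytest.approx(np.mean(ga / iad), abs=1e-9)
        assert s.eff_min_iad == pytest.approx(
            np.median(np.sort(iad)[:5]), abs=1e-9
        )
        assert s.eff_min_ga == pytest.approx(
            np.median(np.sort(ga)[:5]), abs=1e-9
        )
        assert s.eff_max_iai == pytest.approx(
            np.median(np.sort(ga / iad)[-5:]), abs=1e-9
        )
        # symmetric mediolateral motion: summed displacement = |delta IAD|
        votes = np.abs(np.diff(iad))
        assert s.mean_av == pytest.approx(np.mean(votes), abs=1e-9)
        assert s.eff_max_av == pytest.approx(
            np.median(np.sort(votes)[-5:]), abs=1e-9
        )


class TestFramesLongTable:
    def test_shape_and_nan_propagation(self):
        ga = [5.0, None, 7.0]
        table = frames_long_table([make_series(ga, [2.0, 2.0, 2.0])])
        assert list(table.columns) == [
            "participant_id", "frame_index", "time_ms", "iad", "ga", "iai"
        ]
        assert len(table) == 3
        assert math.isnan(table.loc[1, "ga"]) and math.isnan(table.loc[1, "iai"])
        assert table.loc[2, "iai"] == pytest.approx(3.5)

    def test_vocalizing_only_filter(self):
        series = make_series([5.0] * 4, mask=[False, True, True, False])
        assert len(frames_long_table([series])) == 2
        assert len(frames_long_table([series], vocalizing_only=False)) == 4
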