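"""Map generation: segmentation arithmetic, windowed RMS, normalization."""

import itertools

import numpy as np
import pytest

import semgmap as sm
from semgmap.exceptions import DegenerateInputError, ValidationError
from semgmap.maps import DEFAULT_OVERLAPS_PCT, DEFAULT_WINDOWS_MS


def _rec_from(data, fs=2048.0):
    return sm.Recording(data=np.asarray(data, float), fs_hz=fs, grid=sm.ElectrodeGrid())


def brute_force_starts(L, N, R):
    """Oracle: enumerate every admissible window start."""
    return [s for s in range(0, L, R) if s + N <= L][: (L - N) // R + 1 if L >= N else 0]


class TestScheme:
    @pytest.mark.parametrize(
        "window_ms,overlap,expected_n,expected_r",
        [
            (1000, 0, 2048, 2048),
            (500, 50, 1024, 512),
            (50, 90, 102, 10),
            (50, 0, 102, 102),
        ],
    )
    def test_sample_counts(self, window_ms, overlap, expected_n, expected_r):
        scheme = sm.scheme_from(window_ms, overlap, 2048)
        assert (scheme.N, scheme.R) == (expected_n, expected_r)

    def test_sub_sample_window_rejected(self):
        with pytest.raises(ValidationError):
            sm.scheme_from(0.2, 0, 2048)

    @pytest.mark.parametrize("overlap", [-1, 100, 150])
    def test_overlap_range_enforced(self, overlap):
        with pytest.raises(ValidationError):
            sm.scheme_from(100, overlap, 2048)


class TestCountWindows:
    @pytest.mark.parametrize(
        "window_ms,overlap",
        list(itertools.product(DEFAULT_WINDOWS_MS, DEFAULT_OVERLAPS_PCT)),
    )
    def test_matches_brute_force_enumeration(self, window_ms, overlap):
        scheme = sm.scheme_from(window_ms, overlap, 2048)
        L = 10_240
        assert sm.count_windows(L, scheme) == len(
            brute_force_starts(L, scheme.N, scheme.R)
        )

    def test_single_full_window(self):
        scheme = sm.scheme_from(100, 50, 2048)
        assert sm.count_windows(scheme.N, scheme) == 1

    def test_short_signal_yields_zero(self):
        scheme = sm.scheme_from(100, 0, 2048)
        assert sm.count_windows(scheme.N - 1, scheme) == 0

    def test_known_condition_counts(self):
        # 0%, 50% and 90% overlap of the 50 ms window at L = 10,240
        for overlap, expected in [(0, 100), (50, 199), (90, 1014)]:
            scheme = sm.scheme_from(50, overlap, 2048)
            assert sm.count_windows(10_240, scheme) == expected


class TestComputeStack:
    def test_constant_signal_closed_form(self):
        scheme = sm.scheme_from(100, 0, 2048)
        c = 3.0
        rec = _rec_from(np.full((2048, 64), c))
        stack = sm.compute_stack(rec, scheme)
        expected = c * np.sqrt(scheme.N / (scheme.N - 1))
        np.testing.assert_allclose(stack.maps, expected, rtol=1e-12)

    def test_sine_rms_near_inverse_sqrt2(self):
        fs = 2048.0
        scheme = sm.scheme_from(1000, 0, fs)  # 2048-sample window
        t = np.arange(4096) / fs
        data = np.tile(np.sin(2 * np.pi * 64 * t)[:, None], (1, 64))
        stack = sm.compute_stack(_rec_from(data), scheme)
        np.testing.assert_allclose(stack.maps, 1 / np.sqrt(2), rtol=0.01)

    def test_matches_naive_loop_oracle(self, rng, grid):
        data = rng.normal(size=(2048, 64))
        scheme = sm.scheme_from(150, 75, 2048)
        stack = sm.compute_stack(_rec_from(data), scheme)
        t = sm.count_windows(2048, scheme)
        for k in range(t):
            win = data[k * scheme.R : k * scheme.R + scheme.N]
            oracle = np.sqrt((win**2).sum(axis=0) / (scheme.N - 1))
            np.testing.assert_allclose(
                grid.to_channels(stack.maps[k]), oracle, atol=1e-12
            )

    def test_mean_square_mode_is_square_of_rms(self, rng):
        data = rng.normal(size=(1024, 64))
        scheme = sm.scheme_from(100, 25, 2048)
        rms = sm.compute_stack(_rec_from(data), scheme, intensity="rms")
        ms = sm.compute_stack(_rec_from(data), scheme, intensity="mean_square")
        np.testing.assert_allclose(ms.maps, rms.maps**2, rtol=1e-12)

    def test_unknown_intensity_rejected(self, rng):
        rec = _rec_from(rng.normal(size=(1024, 64)))
        with pytest.raises(ValidationError):
            sm.compute_stack(rec, sm.scheme_from(100, 0, 2048), intensity="peak")

    def test_zero_overlap_tiles_signal_prefix(self, rng):
        data = rng.normal(size=(1000, 64))
        scheme = sm.scheme_from(100, 0, 2048)  # N = R = 205
        t = sm.count_windows(1000, scheme)
        starts = [k * scheme.R for k in range(t)]
        covered = sorted(
            s for start in starts for s in range(start, start + scheme.N)
        )
        assert covered == list(range(t * scheme.N))  # each sample exactly once


class TestNormalizeStack:
    def test_scales_by_global_max(self, rng):
        data = rng.normal(size=(1024, 64))
        stack = sm.compute_stack(_rec_from(data), sm.scheme_from(100, 50, 2048))
        normed = sm.normalize_stack(stack)
        assert normed.maps.max() == pytest.approx(1.0)
        np.testing.assert_allclose(normed.maps * stack.maps.max(), stack.maps, rtol=1e-12)

    def test_idempotent(self, rng):
        data = rng.normal(size=(1024, 64))
        stack = sm.compute_stack(_rec_from(data), sm.scheme_from(100, 50, 2048))
        once = sm.normalize_stack(stack)
        twice = sm.normalize_stack(once)
        np.testing.assert_allclose(twice.maps, once.maps, rtol=1e-15)

    def test_all_zero_stack_rejected(self):
        rec = _rec_from(np.zeros((1024, 64)))
        stack = sm.compute_stack(rec, sm.scheme_from(100, 50, 2048))
        with pytest.raises(DegenerateInputError):
            sm.normalize_stack(stack)


class TestGridSearch:
    def test_full_design_yields_30_stacks(self, clean_plateau):
        stacks = sm.grid_search(clean_plateau)
        assert len(stacks) == 30
        conds = [(s.scheme.window_ms, s.scheme.overlap_pct) for s in stacks]
        assert conds == [
            (w, o)
            for w in DEFAULT_WINDOWS_MS
            for o in DEFAULT_OVERLAPS_PCT
        ]

    def test_total_map_count_consistent(self, clean_plateau):
        stacks = sm.grid_search(clean_plateau)
        L = clean_plateau.n_samples
        expected = sum(
            sm.count_windows(L, sm.scheme_from(w, o, clean_plateau.fs_hz))
            for w in DEFAULT_WINDOWS_MS
            for o in DEFAULT_OVERLAPS_PCT
        )
        assert sum(s.n_maps for s in stacks) == expected

    def test_map_count_monotonicity(self, clean_plateau):
        stacks = sm.grid_search(clean_plateau)
        counts = {
            (s.scheme.window_ms, s.scheme.overlap_pct): s.n_maps for s in stacks
        }
        for w in DEFAULT_WINDOWS_MS:
            by_overlap = [counts[(w, o)] for o in sorted(DEFAULT_OVERLAPS_PCT)]
            assert all(a <= b for a, b in zip(by_overlap, by_overlap[1:]))
        for o in DEFAULT_OVERLAPS_PCT:
            by_window = [counts[(w, o)] for w in sorted(DEFAULT_WINDOWS_MS)]
            assert all(a >= b for a, b in zip(by_window, by_window[1:]))

    def test_offending_condition_named(self, clean_plateau):
        with pytest.raises(ValidationError, match="window=0.2"):
            sm.grid_search(clean_plateau, [0.2], [0])

    def test_smoothness_decreases_with_overlap(self, clean_plateau):
        values = []
        for overlap in (0, 50, 90):
            scheme = sm.scheme_from(100, overlap, clean_plateau.fs_hz)
            stack = sm.compute_stack(clean_plateau, scheme)
            values.append(sm.stack_smoothness(sm.normalize_stack(stack)))
        assert values[0] > values[1] > values[2]
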