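import numpy as np
import pytest

import kernelfc as kfc
from kernelfc.fc import (
    connectivity_tensor,
    cross_correlation_fc,
    devectorize,
    feature_index_map,
    gaussian_kernel_fc,
    median_sigma,
    pair_index,
    phase_locking_fc,
    vectorize,
)

from conftest import random_segments


class TestPairIndex:
    def test_three_channels(self):
        assert pair_index(3) == [(0, 1), (0, 2), (1, 2)]

    def test_22_channels_has_231_pairs(self):
        assert len(pair_index(22)) == 231

    def test_round_trip_with_upper_triangle(self):
        pairs = pair_index(10)
        iu, ju = np.triu_indices(10, k=1)
        assert pairs == list(zip(iu.tolist(), ju.tolist()))

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            pair_index(1)


class TestMedianSigma:
    def test_forced_construction_gives_offset_norm(self):
        # two identical channels plus one offset by a constant vector of norm d
        length = 16
        d = 3.0
        base = np.zeros((3, length))
        base[2] += d / np.sqrt(length)
        values = np.broadcast_to(base, (2, 2, 2, 3, length)).copy()
        seg = kfc.TFSegments(
            values=values,
            fs=16.0,
            bands=((4, 8), (8, 12)),
            window_starts=np.array([0, 4]),
            tau=1.0,
        )
        est = median_sigma(seg)
        assert est.sigma == pytest.approx(d, abs=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        seg = random_segments(rng, r=3, b=2, w=2, c=6, length=32)
        est = median_sigma(seg)
        medians = []
        for r in range(3):
            for b in range(2):
                for w in range(2):
                    x = seg.values[r, b, w]
                    dists = [
                        np.linalg.norm(x[c] - x[cp]) for c, cp in pair_index(6)
                    ]
                    medians.append(np.median(dists))
        assert est.sigma == pytest.approx(np.mean(medians), abs=1e-12)

    def test_homogeneous_in_amplitude(self, rng):
        seg = random_segments(rng, c=4)
        scaled = kfc.TFSegments(
            values=3.5 * seg.values,
            fs=seg.fs,
            bands=seg.bands,
            window_starts=seg.window_starts,
            tau=seg.tau,
        )
        assert median_sigma(scaled).sigma == pytest.approx(
            3.5 * median_sigma(seg).sigma, rel=1e-12
        )

    def test_all_zero_input_rejected(self):
        seg = kfc.TFSegments(
            values=np.zeros((2, 1, 1, 3, 16)),
            fs=16.0,
            bands=((4, 8),),
            window_starts=np.array([0]),
            tau=1.0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            median_sigma(seg)

    def test_training_mask_restricts_pooling(self, rng):
        seg = random_segments(rng, r=6, c=4)
        mask = np.array([True, True, True, False, False, False])
        sub = kfc.TFSegments(
            values=seg.values[:3],
            fs=seg.fs,
            bands=seg.bands,
            window_starts=seg.window_starts,
            tau=seg.tau,
        )
        assert median_sigma(seg, mask).sigma == pytest.approx(
            median_sigma(sub).sigma, abs=1e-14
        )


class TestGaussianKernel:
    def test_identical_channels_give_one(self):
        x = np.vstack([np.sin(np.arange(32.0))] * 2)
        k = gaussian_kernel_fc(x, sigma=2.0)
        assert k[0, 1] == pytest.approx(1.0)

    def test_closed_form_at_distance_sqrt2_sigma(self):
        sigma = 1.7
        x = np.zeros((2, 8))
        x[1, 0] = np.sqrt(2.0) * sigma  # squared distance = 2 sigma^2
        assert gaussian_kernel_fc(x, sigma)[0, 1] == pytest.approx(np.exp(-1.0))

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((8, 64))
        sigma = 1.3
        k = gaussian_kernel_fc(x, sigma)
        for c, cp in pair_index(8):
            expected = np.exp(
                -np.sum((x[c] - x[cp]) ** 2) / (2 * sigma**2)
            )
            assert k[c, cp] == pytest.approx(expected, abs=1e-12)
            assert k[cp, c] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(np.diag(k), 1.0)

    def test_monotone_decreasing_in_distance(self):
        sigma = 2.0
        entries = []
        for d in [0.5, 1.0, 2.0, 4.0]:
            x = np.zeros((2, 4))
            x[1, 0] = d
            entries.append(gaussian_kernel_fc(x, sigma)[0, 1])
        assert all(a > b for a, b in zip(entries, entries[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gaussian_kernel_fc(np.zeros((2, 8)), sigma=0.0)
        with pytest.raises(ValueError, match="non-finite"):
            gaussian_kernel_fc(np.full((2, 8), np.nan), sigma=1.0)


class TestCrossCorrelation:
    def test_sign_extremes(self, rng):
        x = rng.standard_normal(64)
        assert cross_correlation_fc(np.vstack([x, x]))[0, 1] == pytest.approx(1.0)
        assert cross_correlation_fc(np.vstack([x, -x]))[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal((6, 128))
        got = cross_correlation_fc(x)
        np.testing.assert_allclose(got, np.corrcoef(x), atol=1e-12)

    def test_zero_variance_channel_named(self):
        x = np.ones((3, 32))
        x[0] = np.sin(np.arange(32.0))
        x[2] = np.cos(np.arange(32.0))
        with pytest.raises(ValueError, match=r"\[1\]"):
            cross_correlation_fc(x)


class TestPhaseLocking:
    def test_identical_channels_lock_perfectly(self):
        t = np.arange(256) / 64.0
        x = np.sin(2 * np.pi * 10 * t)
        assert phase_locking_fc(np.vstack([x, x]))[0, 1] == pytest.approx(1.0)

    def test_constant_phase_shift_locks(self):
        t = np.arange(512) / 128.0
        a = np.sin(2 * np.pi * 10 * t)
        b = np.sin(2 * np.pi * 10 * t + 1.1)
        assert phase_locking_fc(np.vstack([a, b]))[0, 1] > 0.99

    def test_independent_white_noise_has_low_plv(self):
        rng = np.random.default_rng(77)
        vals = [
            phase_locking_fc(rng.standard_normal((2, 512)))[0, 1]
            for _ in range(200)
        ]
        assert np.mean(vals) < 0.15

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="8 samples"):
            phase_locking_fc(np.random.default_rng(0).standard_normal((2, 4)))


class TestConnectivityTensor:
    def test_shape_contract(self, rng):
        seg = random_segments(rng, r=4, b=2, w=3, c=5, length=32)
        ct = connectivity_tensor(seg, "ccf")
        assert ct.values.shape == (4, 2, 3, 10)

    def test_duplicated_channels_give_unit_gfc(self):
        base = np.sin(np.arange(32.0))
        values = np.broadcast_to(base, (2, 1, 2, 4, 32)).copy()
        seg = kfc.TFSegments(
            values=values, fs=16.0, bands=((4, 8),),
            window_starts=np.array([0, 8]), tau=2.0,
        )
        ct = connectivity_tensor(seg, "gfc", sigma=1.0)
        np.testing.assert_allclose(ct.values, 1.0)

    @pytest.mark.parametrize("measure", ["gfc", "ccf", "plv"])
    def test_equals_per_window_loop_oracle(self, rng, measure):
        seg = random_segments(rng, r=2, b=2, w=2, c=4, length=64)
        sigma = kfc.SigmaEstimate(1.9) if measure == "gfc" else None
        ct = connectivity_tensor(seg, measure, sigma=sigma)
        per_window = {
            "gfc": lambda x: gaussian_kernel_fc(x, 1.9),
            "ccf": cross_correlation_fc,
            "plv": phase_locking_fc,
        }[measure]
        iu, ju = np.triu_indices(4, k=1)
        for r in range(2):
            for b in range(2):
                for w in range(2):
                    expected = per_window(seg.values[r, b, w])[iu, ju]
                    np.testing.assert_allclose(
                        ct.values[r, b, w], expected, atol=1e-10
                    )

    def test_gfc_requires_sigma(self, rng):
        with pytest.raises(ValueError, match="sigma"):
            connectivity_tensor(random_segments(rng), "gfc")


class TestVectorize:
    def test_shape_and_round_trip(self, rng):
        seg = random_segments(rng, r=4, b=2, w=3, c=5, length=32)
        ct = connectivity_tensor(seg, "ccf")
        X, index_map = vectorize(ct)
        assert X.shape == (4, 60)
        np.testing.assert_array_equal(
            devectorize(X, 2, 3, 10), ct.values
        )

    def test_column_metadata_matches_unravel(self):
        index_map = feature_index_map(3, 4, 5)
        for k in range(3 * 4 * 5):
            np.testing.assert_array_equal(
                index_map[k], np.unravel_index(k, (3, 4, 5))
            )


class TestMeasureInvariances:
    def _relabeled(self, seg, perm):
        return kfc.TFSegments(
            values=seg.values[:, :, :, perm, :],
            fs=seg.fs, bands=seg.bands,
            window_starts=seg.window_starts, tau=seg.tau,
        )

    @pytest.mark.parametrize("measure", ["gfc", "ccf", "plv"])
    def test_channel_relabeling_permutes_pairs(self, rng, measure):
        seg = random_segments(rng, r=2, b=1, w=1, c=5, length=64)
        perm = np.array([2, 0, 4, 1, 3])
        sigma = 1.5 if measure == "gfc" else None
        orig = connectivity_tensor(seg, measure, sigma=sigma).values
        perm_vals = connectivity_tensor(
            self._relabeled(seg, perm), measure, sigma=sigma
        ).values
        pairs = pair_index(5)
        pos = {p: i for i, p in enumerate(pairs)}
        for i, (c, cp) in enumerate(pairs):
            a, b = perm[c], perm[cp]
            j = pos[(min(a, b), max(a, b))]
            np.testing.assert_allclose(perm_vals[..., i], orig[..., j], atol=1e-10)

    def test_gfc_invariant_to_common_offset(self, rng):
        x = rng.standard_normal((2, 32))
        shift = rng.standard_normal(32)
        k1 = gaussian_kernel_fc(x, 1.0)[0, 1]
        k2 = gaussian_kernel_fc(x + shift, 1.0)[0, 1]
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_ccf_invariant_to_positive_affine_maps(self, rng):
        x = rng.standard_normal((2, 64))
        mapped = np.vstack([3.0 * x[0] + 7.0, 0.2 * x[1] - 4.0])
        np.testing.assert_allclose(
            cross_correlation_fc(mapped), cross_correlation_fc(x), atol=1e-10
        )

    def test_plv_invariant_to_amplitude_scaling(self, rng):
        x = rng.standard_normal((2, 128))
        scaled = np.vstack([5.0 * x[0], 0.3 * x[1]])
        assert phase_locking_fc(scaled)[0, 1] == pytest.approx(
            phase_locking_fc(x)[0, 1], abs=1e-12
        )

    def test_bounds_on_fuzzed_windows(self, rng):
        seg = random_segments(rng, r=10, b=10, w=10, c=3, length=32)
        gfc = connectivity_tensor(seg, "gfc", sigma=median_sigma(seg)).values
        ccf = connectivity_tensor(seg, "ccf").values
        plv = connectivity_tensor(seg, "plv").values
        assert gfc.size == 3000  # 1000 windows x 3 pairs
        assert (gfc > 0).all() and (gfc <= 1).all()
        assert (ccf >= -1).all() and (ccf <= 1).all()
        assert (plv >= 0).all() and (plv <= 1).all()
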