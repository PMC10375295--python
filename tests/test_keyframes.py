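import numpy as np
import pytest
from scipy import ndimage

from siliqueseg.keyframes import (BilateralConfig, ImageFrame, KeyframeParams,
                                  MatchResult, frame_similarity,
                                  select_keyframes, sharpness_score,
                                  to_grayscale, LAPLACIAN_KERNEL)
from siliqueseg.synthetic import make_frame_sequence


def _sharpness_oracle(pixels, config=None):
    """Direct evaluation of the blur score: same bilateral preprocessing,
    then explicit double-loop Laplacian convolution (reflect borders) and
    an explicit variance sum."""
    from skimage.restoration import denoise_bilateral

    config = config or BilateralConfig()
    img = np.asarray(pixels, dtype=float) / 255.0
    filtered = denoise_bilateral(
        img, win_size=config.win_size, sigma_color=config.sigma_color,
        sigma_spatial=config.sigma_spatial,
        channel_axis=-1 if img.ndim == 3 else None)
    gray = to_grayscale(filtered * 255.0)
    padded = np.pad(gray, 1, mode="symmetric")
    rows, cols = gray.shape
    conv = np.empty_like(gray)
    for i in range(rows):
        for j in range(cols):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    acc += LAPLACIAN_KERNEL[1 + di, 1 + dj] \
                        * padded[1 + i + di, 1 + j + dj]
            conv[i, j] = acc
    mean = conv.sum() / (rows * cols)
    return float(((conv - mean) ** 2).sum() / (rows * cols))


class TestSharpness:
    def test_constant_image_scores_zero(self):
        assert sharpness_score(np.full((16, 16), 128, dtype=np.uint8)) == 0.0

    def test_blur_lowers_score(self, rng):
        img = (rng.random((64, 64)) * 255).astype(np.uint8)
        blurred = ndimage.gaussian_filter(img.astype(float), 4.0)
        assert sharpness_score(img) > sharpness_score(blurred)

    def test_checkerboard_matches_direct_loop_oracle(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255
        assert sharpness_score(board) == pytest.approx(
            _sharpness_oracle(board), rel=1e-9)

    def test_oracle_agreement_on_random_images(self, rng):
        img = (rng.random((12, 15)) * 255).astype(np.uint8)
        assert sharpness_score(img) == pytest.approx(
            _sharpness_oracle(img), rel=1e-9)

    def test_invariant_under_channel_permutation_of_gray_color(self, rng):
        gray = (rng.random((20, 20)) * 255).astype(np.uint8)
        color = np.stack([gray, gray, gray], axis=-1)
        permuted = color[..., [2, 0, 1]]
        assert sharpness_score(color) == pytest.approx(
            sharpness_score(permuted), rel=1e-12)

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            sharpness_score(np.zeros((2, 5)))


class TestSimilarity:
    def test_identical_frames_near_100(self):
        frames, _ = make_frame_sequence(1, texture_seed=2)
        result = frame_similarity(frames[0], frames[0])
        assert result.similarity >= 95

    def test_independent_noise_low_similarity(self):
        rng = np.random.default_rng(5)
        a = ImageFrame(0, (rng.random((128, 128)) * 255).astype(np.uint8))
        b = ImageFrame(1, (rng.random((128, 128)) * 255).astype(np.uint8))
        assert frame_similarity(a, b).similarity < 20

    def test_similarity_arithmetic(self):
        assert MatchResult(50, 35, 70.0).similarity == 70.0
        with pytest.raises(ValueError):
            MatchResult(10, 11, 50.0)

    def test_ratio_threshold_one_passes_everything(self):
        frames, _ = make_frame_sequence(5, texture_seed=3)
        result = frame_similarity(frames[0], frames[3],
                                  ratio_threshold=1.0)
        assert result.match_num == result.matches

    def test_featureless_frames_warn_not_raise(self):
        flat = ImageFrame(0, np.full((64, 64), 200, dtype=np.uint8))
        with pytest.warns(UserWarning):
            result = frame_similarity(flat, flat)
        assert result == MatchResult(0, 0, 0.0)


def _stub_similarity(decay=3.0):
    """Similarity falls linearly with index distance: 100 - decay*|i-j|."""
    return lambda a, b: max(0.0, 100.0 - decay * abs(a.index - b.index))


def _flat_frames(n, sharpness=1.0):
    pixels = np.zeros((4, 4), dtype=np.uint8)
    return [ImageFrame(i, pixels, sharpness=sharpness) for i in range(n)]


class TestSelection:
    def test_identical_frames_select_only_first(self):
        frames = _flat_frames(10)
        params = KeyframeParams(interval_k=3, s1=20, s2=90, step_i=1,
                                blur_threshold=0.0)
        chosen = select_keyframes(frames, params,
                                  similarity_fn=lambda a, b: 100.0)
        assert chosen == [0]

    def test_in_band_stride_selects_every_kth(self):
        frames = _flat_frames(30)
        params = KeyframeParams(interval_k=5, s1=80, s2=90, step_i=1,
                                blur_threshold=0.0)
        # distance 5 -> 85 (in band); shorter -> too similar, longer -> below
        chosen = select_keyframes(frames, params,
                                  similarity_fn=_stub_similarity(3.0))
        assert chosen == [0, 5, 10, 15, 20, 25]

    def test_all_blurred_returns_empty_with_warning(self):
        frames = _flat_frames(5, sharpness=0.0)
        params = KeyframeParams(interval_k=2, s1=20, s2=80, step_i=1,
                                blur_threshold=1.0)
        with pytest.warns(UserWarning):
            assert select_keyframes(frames, params) == []

    def test_blurred_frames_never_selected(self):
        frames, truth = make_frame_sequence(60, {5, 17}, texture_seed=0)
        params = KeyframeParams(interval_k=4, s1=20, s2=90, step_i=1)
        chosen = select_keyframes(frames, params)
        assert set(chosen).isdisjoint(truth["blur_indices"])
        assert chosen == sorted(set(chosen))

    def test_monotone_and_sharp_over_random_configs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            frames = _flat_frames(n)
            blurred = set(rng.choice(n, size=n // 5, replace=False).tolist())
            for i in blurred:
                frames[i].sharpness = 0.0
            k = int(rng.integers(2, 8))
            s1 = float(rng.uniform(10, 40))
            s2 = float(rng.uniform(s1 + 10, 95))
            params = KeyframeParams(interval_k=k, s1=s1, s2=s2,
                                    step_i=max(1, k // 2),
                                    blur_threshold=0.5)
            decay = float(rng.uniform(1.0, 8.0))
            chosen = select_keyframes(frames, params,
                                      similarity_fn=_stub_similarity(decay))
            assert all(a < b for a, b in zip(chosen, chosen[1:]))
            assert set(chosen).isdisjoint(blurred)

    def test_suffix_locality(self):
        """Dropping a frame after the last selected index leaves the
        selection unchanged."""
        frames = _flat_frames(32)
        params = KeyframeParams(interval_k=5, s1=80, s2=90, step_i=1,
                                blur_threshold=0.0)
        sim = _stub_similarity(3.0)
        chosen = select_keyframes(frames, params, similarity_fn=sim)
        shorter = select_keyframes(frames[:-1], params, similarity_fn=sim)
        assert chosen == shorter
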