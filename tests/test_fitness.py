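"""Thresholding, variance decomposition, fitness and memory persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slns.fitness import (
    FitnessParams,
    SelfLearningMemory,
    fuzzy_entropy_threshold,
    interclass_variance,
    intraclass_correlation,
    segment_fitness,
    total_variance,
    update_class_weights,
)


def otsu_oracle(hist: np.ndarray) -> int:
    """Exhaustive within-class-variance minimizer (independent oracle)."""
    levels = np.arange(256.0)
    best, best_wv = 0, np.inf
    for t in range(1, 256):
        w1, w2 = hist[:t].sum(), hist[t:].sum()
        if w1 <= 0 or w2 <= 0:
            continue
        m1 = (hist[:t] * levels[:t]).sum() / w1
        m2 = (hist[t:] * levels[t:]).sum() / w2
        wv = (hist[:t] * (levels[:t] - m1) ** 2).sum() + (hist[t:] * (levels[t:] - m2) ** 2).sum()
        if wv < best_wv:
            best_wv, best = wv, t
    return best


def test_interclass_variance_hand_example_and_degenerate():
    h = np.zeros(256)
    h[50] = h[200] = 0.5
    assert interclass_variance(h, 128) == pytest.approx(5625.0)
    single = np.zeros(256)
    single[77] = 1.0
    assert all(interclass_variance(single, t) == 0.0 for t in (0, 77, 200))
    with pytest.raises(ValueError):
        interclass_variance(np.ones(256), 10)


def test_interclass_argmax_matches_otsu_duality_oracle():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        h = rng.random(256)
        h /= h.sum()
        ours = int(np.argmax([interclass_variance(h, t) for t in range(256)]))
        assert ours == otsu_oracle(h)


def test_between_class_never_exceeds_total_variance():
    rng = np.random.default_rng(0)
    for _ in range(20):
        h = rng.random(256)
        h /= h.sum()
        tot = total_variance(h)
        assert max(interclass_variance(h, t) for t in range(256)) <= tot + 1e-9


def test_fuzzy_entropy_bimodal_threshold_between_modes():
    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(64, 10, 4000), rng.normal(192, 10, 4000)])
    h = np.bincount(np.clip(v.astype(int), 0, 255), minlength=256).astype(float)
    h /= h.sum()
    ft = fuzzy_entropy_threshold(h)
    assert 64 < ft.threshold < 192
    # exhaustive scan oracle over the same membership construction
    from scipy.special import expit

    def theta(t: int) -> float:
        s = 0.0
        for i in range(256):
            mu = expit((i - t) / ft.bandwidth)
            m = mu if i <= t else 1 - mu
            s += -h[i] * m * np.log2(m) if m > 0 else 0.0
        return s

    scores = [theta(t) for t in range(256)]
    assert ft.threshold == int(np.argmax(scores))
    assert ft.entropy == pytest.approx(max(scores), rel=1e-9)


def test_fuzzy_entropy_mirror_symmetry_and_nonnegativity():
    rng = np.random.default_rng(2)
    v = np.concatenate([rng.normal(80, 12, 3000), rng.normal(190, 8, 5000)])
    h = np.bincount(np.clip(v.astype(int), 0, 255), minlength=256).astype(float)
    h /= h.sum()
    t = fuzzy_entropy_threshold(h)
    t_mirror = fuzzy_entropy_threshold(h[::-1].copy())
    assert abs(t_mirror.threshold - (255 - t.threshold)) <= 1
    assert t.entropy >= 0
    with pytest.raises(ValueError):
        single = np.zeros(256)
        single[5] = 1.0
        fuzzy_entropy_threshold(single)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.1, 100.0))
def test_fuzzy_entropy_invariant_to_histogram_rescaling(seed, scale):
    rng = np.random.default_rng(seed)
    h = rng.random(256) + 1e-3
    h /= h.sum()
    a = fuzzy_entropy_threshold(h).threshold
    h2 = h * scale
    h2 /= h2.sum()
    assert fuzzy_entropy_threshold(h2).threshold == a


def test_intraclass_correlation_closed_forms(rng):
    img = rng.normal(100, 20, 1000)
    assert intraclass_correlation(img, img) == pytest.approx(0.5)
    assert intraclass_correlation(np.full(50, 7.0), img) == 0.0
    assert intraclass_correlation(np.full(5, 1.0), np.full(9, 1.0)) == 0.0
    seg = rng.choice(img, 200)
    expected = seg.var() / (seg.var() + img.var())
    assert intraclass_correlation(seg, img) == pytest.approx(expected, abs=1e-12)


def test_segment_fitness_arithmetic_and_linearity():
    n = 228 * 228
    assert segment_fitness(n, [n // 4] * 4, params=FitnessParams(p=1, q=0)) == pytest.approx(12996.0)
    # q-term: seed points = segments, equal sizes
    k, size = 4, 100
    got = segment_fitness(k * size, [size] * k, params=FitnessParams(p=0, q=1))
    assert got == pytest.approx(sum(k / size for _ in range(k)))
    f1 = segment_fitness(n, [100, 200, 300], params=FitnessParams(p=1, q=1))
    f2 = segment_fitness(n, [100, 200, 300], params=FitnessParams(p=2, q=1))
    q_term = segment_fitness(n, [100, 200, 300], params=FitnessParams(p=0, q=1))
    assert f2 - q_term == pytest.approx(2 * (f1 - q_term))
    with pytest.raises(ValueError):
        segment_fitness(n, [10, 0, 5])


def test_class_weights_equal_distributions_near_one(rng):
    feats = np.concatenate([rng.normal(128, 20, 4000), rng.normal(128, 20, 4000)])
    labels = np.r_[np.zeros(4000, int), np.ones(4000, int)]
    mem = update_class_weights(SelfLearningMemory(), feats, labels)
    assert mem.w_p == pytest.approx(1.0, abs=0.15)


def test_class_weights_separated_distributions_large_ratio(rng):
    feats = np.concatenate([rng.normal(60, 5, 2000), rng.normal(200, 5, 2000)])
    labels = np.r_[np.zeros(2000, int), np.ones(2000, int)]
    mem = update_class_weights(SelfLearningMemory(), feats, labels)
    assert mem.w_p > 10.0


def test_class_weights_single_class_unchanged(rng, caplog):
    mem = SelfLearningMemory(w_p=2.0, w_q=3.0)
    out = update_class_weights(mem, rng.normal(100, 5, 100), np.ones(100, int))
    assert out.w_p == 2.0 and out.w_q == 3.0


def test_memory_roundtrip_lossless(tmp_path):
    mem = SelfLearningMemory(w_p=1.5, w_q=0.25)
    mem.log_run("r1", 4, 0.8, 0.09, start_w_p=1.0)
    mem.log_run("r2", 5, 0.6, 0.08)
    path = tmp_path / "memory.json"
    mem.save(path)
    back = SelfLearningMemory.load(path)
    assert back == mem
    assert back.gb_fitness == 0.8  # max over logged fitness entries
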