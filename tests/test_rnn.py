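"""Bidirectional recurrence fidelity, patch encoding and training."""

import numpy as np
import pytest
from scipy.special import expit

from slns.fitness import SelfLearningMemory
from slns.image import LabelMask, MRImage
from slns.phantom import PhantomSpec, generate_dataset, generate_phantom
from slns.rnn import (
    ClassifierConfig,
    PatchSequence,
    RNNWeights,
    classify,
    encode_patches,
    forward_pass,
    label_segments,
    probability_map,
    train_classifier,
)


def unrolled_oracle(x, wx, wh, b):
    """Hand-unrolled forward recurrence (independent oracle)."""
    h = np.zeros(wh.shape[0])
    out = []
    for t in range(len(x)):
        h = expit(wx @ x[t] + wh @ h + b)
        out.append(h.copy())
    return np.array(out)


def test_zero_weights_give_half_activations():
    w = RNNWeights.init(4, hidden_dim=3, seed=0)
    for name in ("wx_f", "wh_f", "b_f", "wx_b", "wh_b", "b_b"):
        setattr(w, name, np.zeros_like(getattr(w, name)))
    ff, fb = forward_pass(np.ones((5, 4)), w)
    assert np.all(ff == 0.5) and np.all(fb == 0.5)


def test_recurrence_matches_hand_unrolled_oracle(rng):
    w = RNNWeights.init(2, hidden_dim=3, seed=1)
    x = rng.normal(size=(3, 2))
    ff, fb = forward_pass(x, w)
    assert np.allclose(ff, unrolled_oracle(x, w.wx_f, w.wh_f, w.b_f), atol=1e-12)
    assert np.allclose(fb, unrolled_oracle(x[::-1], w.wx_b, w.wh_b, w.b_b)[::-1], atol=1e-12)


def test_sequence_reversal_swaps_directions_exactly(rng):
    w = RNNWeights.init(4, hidden_dim=5, seed=2)
    x = rng.normal(size=(7, 4))
    ff, fb = forward_pass(x, w)
    swapped = RNNWeights(
        wx_f=w.wx_b, wh_f=w.wh_b, b_f=w.b_b,
        wx_b=w.wx_f, wh_b=w.wh_f, b_b=w.b_f,
        w_out=w.w_out, b_out=w.b_out,
    )
    ff_r, fb_r = forward_pass(x[::-1], swapped)
    assert np.allclose(ff_r, fb[::-1], atol=1e-12)
    assert np.allclose(fb_r, ff[::-1], atol=1e-12)


def test_activations_bounded(rng):
    w = RNNWeights.init(3, hidden_dim=4, seed=3)
    ff, fb = forward_pass(rng.normal(0, 10, (20, 3)), w)
    for arr in (ff, fb):
        assert np.all(arr > 0) and np.all(arr < 1)


def test_classify_probabilities_sum_to_one_and_symmetric_readout(rng):
    w = RNNWeights.init(3, hidden_dim=4, seed=4)
    for _ in range(100):
        p_t, p_n = classify(rng.normal(size=(6, 3)), w)
        assert p_t + p_n == pytest.approx(1.0, abs=1e-12)
    w.w_out = np.tile(w.w_out[0], (2, 1))
    w.b_out = np.zeros(2)
    p_t, p_n = classify(rng.normal(size=(6, 3)), w)
    assert (p_t, p_n) == pytest.approx((0.5, 0.5))


def test_patch_grid_count_and_labels(tumor_phantom):
    img, mask = tumor_phantom
    patches = encode_patches(img, None, patch_size=12, stride=12)
    assert len(patches) == 19 * 19
    all_tumor = LabelMask(np.full(img.shape, 3, dtype=np.int64))
    labeled = encode_patches(img, all_tumor, patch_size=12, stride=12)
    assert all(p.label == 1 for p in labeled)


def test_balanced_sampling(tumor_phantom):
    img, mask = tumor_phantom
    patches = encode_patches(img, mask, patch_size=12, stride=4, balanced=True, seed=0)
    labels = [p.label for p in patches]
    assert abs(labels.count(1) - labels.count(0)) <= 1
    assert labels.count(1) > 0


def test_linearly_separable_toy_problem_trains_to_high_accuracy(rng):
    # two Gaussian classes, means +-3, unit variance, 4-step sequences
    def make(n, seed):
        g = np.random.default_rng(seed)
        seqs, ys = [], []
        for i in range(n):
            y = i % 2
            mu = 3.0 if y else -3.0
            seqs.append(PatchSequence(g.normal(mu, 1.0, (4, 2)), y, 0, 0, 4))
            ys.append(y)
        return seqs

    train_set = make(200, 0)
    test_set = make(100, 1)
    w, _, trace = train_classifier(train_set, ClassifierConfig(epochs=20, seed=0))
    acc = np.mean([(classify(p, w)[0] >= 0.5) == p.label for p in test_set])
    assert acc >= 0.95
    assert trace[-1] < trace[0]


def test_learning_rate_schedule_non_increasing():
    cfg = ClassifierConfig()
    lrs = [cfg.lr(e) for e in range(50)]
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
    assert lrs[0] == pytest.approx(0.1)
    assert lrs[37] <= 0.08  # decayed to the documented level by epoch 38


def test_single_class_dataset_rejected(rng):
    seqs = [PatchSequence(rng.normal(size=(4, 2)), 1, 0, 0, 4) for _ in range(10)]
    with pytest.raises(ValueError):
        train_classifier(seqs, ClassifierConfig(epochs=1))


def test_training_resumes_from_persisted_memory(tmp_path, rng):
    def toy(n, seed):
        g = np.random.default_rng(seed)
        return [
            PatchSequence(g.normal(3.0 if i % 2 else -3.0, 1.0, (4, 2)), i % 2, 0, 0, 4)
            for i in range(n)
        ]

    mem = SelfLearningMemory()
    _, mem, _ = train_classifier(toy(60, 0), ClassifierConfig(epochs=3, seed=0), mem)
    path = tmp_path / "state.json"
    mem.save(path)
    loaded = SelfLearningMemory.load(path)
    assert loaded == mem
    _, mem2, _ = train_classifier(toy(60, 1), ClassifierConfig(epochs=3, seed=1), loaded)
    entry = mem2.run_log[-1]
    assert entry["start_w_p"] == mem.w_p
    assert entry["start_w_q"] == mem.w_q
    assert entry["start_gb_fitness"] == mem.gb_fitness


def test_probability_map_and_segment_fusion(tumor_phantom):
    img, mask = tumor_phantom
    data = generate_dataset(PhantomSpec(), 4, jitter=0.1, seed=50)
    patches = []
    for i, (im, m) in enumerate(data):
        patches += encode_patches(im, m, patch_size=12, stride=6, seed=i, balanced=True)
    w, _, _ = train_classifier(patches, ClassifierConfig(epochs=10, seed=0))
    prob = probability_map(img, w, stride=6)
    assert prob.shape == img.shape
    assert prob.min() >= 0 and prob.max() <= 1
    fused = label_segments(mask.labels, prob)  # ground-truth segments as regions
    truth = mask.whole_tumor
    overlap = np.sum(fused & truth) / truth.sum()
    assert overlap > 0.9
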