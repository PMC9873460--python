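"""Bidirectional sigmoid-recurrent tumor/non-tumor patch classifier.

Each image patch becomes a sequence: one timestep per patch row, the row's
intensities plus four patch-level GLCM statistics as the feature vector.
Two Elman-style recurrences run over the sequence,

    ff_t = sigmoid(Wx_f x_t + Wh_f ff_{t-1} + b_f)      (left to right)
    fb_t = sigmoid(Wx_b x_t + Wh_b fb_{t+1} + b_b)      (right to left)

and a softmax readout on the concatenated full-context states
``(ff_last, fb_first)`` yields the two class probabilities.  This is a
plain sigmoid recurrence, trained by backpropagation through time with
stochastic gradient descent under a monotonically decaying learning rate;
the per-class loss is weighted by the self-learning memory's class weights,
and each training run is appended to that memory.

Per-pixel tumor probability maps are obtained by averaging the votes of
overlapping patches; a segment-level fusion utility labels whole segments
by their mean patch probability, combining the classifier's decisions with
the segmentation's pixel-accurate boundaries.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .fitness import SelfLearningMemory, update_class_weights
from .image import LabelMask, MRImage, TUMOR_LABELS
from .texture import GLCMConfig, compute_glcm, texture_stats

logger = logging.getLogger(__name__)

__all__ = [
    "RNNWeights",
    "PatchSequence",
    "ClassifierConfig",
    "encode_patches",
    "forward_pass",
    "classify",
    "train_classifier",
    "probability_map",
    "label_segments",
]


@dataclass
class RNNWeights:
    wx_f: np.ndarray
    wh_f: np.ndarray
    b_f: np.ndarray
    wx_b: np.ndarray
    wh_b: np.ndarray
    b_b: np.ndarray
    w_out: np.ndarray  # (2, 2*hidden)
    b_out: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.wh_f.shape[0]

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int = 16, seed: int = 0) -> "RNNWeights":
        rng = np.random.default_rng(seed)

        def w(shape: tuple[int, ...], fan: int) -> np.ndarray:
            return rng.normal(0.0, 1.0 / np.sqrt(fan), shape)

        return cls(
            wx_f=w((hidden_dim, input_dim), input_dim),
            wh_f=w((hidden_dim, hidden_dim), hidden_dim),
            b_f=np.zeros(hidden_dim),
            wx_b=w((hidden_dim, input_dim), input_dim),
            wh_b=w((hidden_dim, hidden_dim), hidden_dim),
            b_b=np.zeros(hidden_dim),
            w_out=w((2, 2 * hidden_dim), 2 * hidden_dim),
            b_out=np.zeros(2),
        )


@dataclass
class PatchSequence:
    """Row-major feature sequence from one image patch."""

    features: np.ndarray  # (T, d)
    label: int | None  # 1 = tumor, 0 = non-tumor, None = unknown
    row: int
    col: int
    size: int


@dataclass(frozen=True)
class ClassifierConfig:
    epochs: int = 30
    batch_size: int = 64
    hidden_dim: int = 16
    lr0: float = 0.1
    lr_decay: float = 0.01  # lr_epoch = lr0 / (1 + lr_decay * epoch)
    seed: int = 0

    def lr(self, epoch: int) -> float:
        return self.lr0 / (1.0 + self.lr_decay * epoch)


# ---------------------------------------------------------------------------
# Patch encoding
# ---------------------------------------------------------------------------

_PATCH_GLCM = GLCMConfig(levels=16, displacement=(0, 1), symmetric=True)


def _patch_features(patch: np.ndarray) -> np.ndarray:
    stats = texture_stats(compute_glcm(patch, _PATCH_GLCM))
    extra = np.array(
        [
            stats["contrast"] / 50.0,
            stats["energy"],
            stats["homogeneity"],
            stats["entropy"] / 6.0,
        ]
    )
    rows = patch / 255.0
    return np.hstack([rows, np.tile(extra, (patch.shape[0], 1))])


def encode_patches(
    img: MRImage,
    mask: LabelMask | None = None,
    patch_size: int = 12,
    stride: int | None = None,
    seed: int = 0,
    balanced: bool = False,
    max_patches: int | None = None,
) -> list[PatchSequence]:
    """Extract labeled patch sequences on a regular grid.

    With a mask, only patches whose center lies in brain tissue are kept and
    each patch is labeled tumor when at least half its pixels carry a tumor
    label.  ``balanced=True`` subsamples equal counts per class (seeded).
    """
    h, w = img.shape
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds image side")
    stride = stride or patch_size
    tumor = mask.region(*TUMOR_LABELS) if mask is not None else None
    brain = mask.brain if mask is not None else None
    if mask is not None and not brain.any():
        raise ValueError("mask contains no brain pixels")
    out: list[PatchSequence] = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            if brain is not None and not brain[r + patch_size // 2, c + patch_size // 2]:
                continue
            patch = img.data[r : r + patch_size, c : c + patch_size]
            label: int | None = None
            if tumor is not None:
                label = int(tumor[r : r + patch_size, c : c + patch_size].mean() >= 0.5)
            out.append(PatchSequence(_patch_features(patch), label, r, c, patch_size))
    rng = np.random.default_rng(seed)
    if balanced and mask is not None:
        pos = [p for p in out if p.label == 1]
        neg = [p for p in out if p.label == 0]
        n = min(len(pos), len(neg))
        pos = [pos[i] for i in rng.choice(len(pos), n, replace=False)] if len(pos) > n else pos
        neg = [neg[i] for i in rng.choice(len(neg), n, replace=False)] if len(neg) > n else neg
        out = pos + neg
    if max_patches is not None and len(out) > max_patches:
        out = [out[i] for i in sorted(rng.choice(len(out), max_patches, replace=False))]
    return out


# ---------------------------------------------------------------------------
# Forward / classify
# ---------------------------------------------------------------------------


def _forward_batch(
    x: np.ndarray, w: RNNWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Run both recurrences on a (B, T, d) batch; returns ff, fb (B, T, h)."""
    b, t, _ = x.shape
    hdim = w.hidden_dim
    ff = np.zeros((b, t, hdim))
    prev = np.zeros((b, hdim))
    for i in range(t):
        prev = expit(x[:, i] @ w.wx_f.T + prev @ w.wh_f.T + w.b_f)
        ff[:, i] = prev
    fb = np.zeros((b, t, hdim))
    nxt = np.zeros((b, hdim))
    for i in range(t - 1, -1, -1):
        nxt = expit(x[:, i] @ w.wx_b.T + nxt @ w.wh_b.T + w.b_b)
        fb[:, i] = nxt
    return ff, fb


def forward_pass(seq: PatchSequence | np.ndarray, weights: RNNWeights) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward activation sequences for one patch, each (T, h).

    All activations lie strictly in (0, 1); NaN propagation raises with the
    offending step index.
    """
    x = seq.features if isinstance(seq, PatchSequence) else np.asarray(seq, dtype=np.float64)
    ff, fb = _forward_batch(x[None], weights)
    for name, arr in (("forward", ff), ("backward", fb)):
        bad = ~np.isfinite(arr[0])
        if bad.any():
            step = int(np.argwhere(bad.any(axis=1))[0][0])
            raise FloatingPointError(f"NaN in {name} recurrence at step {step}")
    return ff[0], fb[0]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _readout(ff: np.ndarray, fb: np.ndarray, w: RNNWeights) -> np.ndarray:
    state = np.concatenate([ff[:, -1], fb[:, 0]], axis=1)
    return _softmax(state @ w.w_out.T + w.b_out)


def classify(seq: PatchSequence | np.ndarray, weights: RNNWeights) -> tuple[float, float]:
    """``(p_tumor, p_non_tumor)`` for one patch sequence; sums to 1."""
    x = seq.features if isinstance(seq, PatchSequence) else np.asarray(seq, dtype=np.float64)
    ff, fb = _forward_batch(x[None], weights)
    p = _readout(ff, fb, weights)[0]
    return float(p[1]), float(p[0])


# ---------------------------------------------------------------------------
# Training (BPTT + SGD with decaying learning rate)
# ---------------------------------------------------------------------------


def _bptt(
    x: np.ndarray, y: np.ndarray, w: RNNWeights, class_w: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    b, t, _ = x.shape
    ff, fb = _forward_batch(x, w)
    state = np.concatenate([ff[:, -1], fb[:, 0]], axis=1)
    probs = _softmax(state @ w.w_out.T + w.b_out)
    sw = class_w[y]
    loss = float(np.mean(-sw * np.log(np.clip(probs[np.arange(b), y], 1e-12, None))))
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits *= (sw / b)[:, None]
    g = {
        "w_out": dlogits.T @ state,
        "b_out": dlogits.sum(axis=0),
    }
    dstate = dlogits @ w.w_out
    hdim = w.hidden_dim
    dff_last = dstate[:, :hdim]
    dfb_first = dstate[:, hdim:]
    # forward recurrence BPTT
    g["wx_f"] = np.zeros_like(w.wx_f)
    g["wh_f"] = np.zeros_like(w.wh_f)
    g["b_f"] = np.zeros_like(w.b_f)
    dh = dff_last
    for i in range(t - 1, -1, -1):
        a = ff[:, i]
        dpre = dh * a * (1 - a)
        g["wx_f"] += dpre.T @ x[:, i]
        g["wh_f"] += dpre.T @ (ff[:, i - 1] if i > 0 else np.zeros((b, hdim)))
        g["b_f"] += dpre.sum(axis=0)
        dh = dpre @ w.wh_f
    # backward recurrence BPTT (mirror image)
    g["wx_b"] = np.zeros_like(w.wx_b)
    g["wh_b"] = np.zeros_like(w.wh_b)
    g["b_b"] = np.zeros_like(w.b_b)
    dh = dfb_first
    for i in range(t):
        a = fb[:, i]
        dpre = dh * a * (1 - a)
        g["wx_b"] += dpre.T @ x[:, i]
        g["wh_b"] += dpre.T @ (fb[:, i + 1] if i < t - 1 else np.zeros((b, hdim)))
        g["b_b"] += dpre.sum(axis=0)
        dh = dpre @ w.wh_b
    return loss, g


def train_classifier(
    patches: list[PatchSequence],
    cfg: ClassifierConfig | None = None,
    memory: SelfLearningMemory | None = None,
) -> tuple[RNNWeights, SelfLearningMemory, list[float]]:
    """Train the bidirectional classifier on labeled patches.

    The per-class cross-entropy is weighted by the memory's stored class
    weights (w_p for non-tumor, w_q for tumor, normalized to mean 1); the
    learning rate decays monotonically across epochs.  After training the
    class weights are re-estimated from the patch mean intensities and the
    run (with its *starting* weights and global-best fitness) is appended
    to the memory log.  Returns ``(weights, memory, loss trace)``.
    """
    cfg = cfg or ClassifierConfig()
    memory = memory or SelfLearningMemory()
    labels = np.array([p.label for p in patches])
    if None in [p.label for p in patches]:
        raise ValueError("all training patches must be labeled")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    x = np.stack([p.features for p in patches])
    start_wp, start_wq, start_gb = memory.w_p, memory.w_q, memory.gb_fitness
    cw = np.array([memory.w_p, memory.w_q])
    cw = cw / cw.mean()
    rng = np.random.default_rng(cfg.seed)
    w = RNNWeights.init(x.shape[2], cfg.hidden_dim, seed=cfg.seed)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr(epoch)
        order = rng.permutation(len(x))
        losses = []
        for s in range(0, len(x), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            loss, g = _bptt(x[idx], labels[idx], w, cw)
            for key, grad in g.items():
                arr = getattr(w, key)
                setattr(w, key, arr - lr * grad)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    mean_int = np.array([255.0 * p.features[:, : p.size].mean() for p in patches])
    update_class_weights(memory, mean_int, labels)
    memory.log_run(
        run_id=f"train-{int(time.time())}",
        n_segments=2,
        fitness=float(1.0 / (1.0 + trace[-1])),
        learning_factor=cfg.lr(cfg.epochs - 1),
        start_w_p=start_wp,
        start_w_q=start_wq,
        start_gb_fitness=start_gb,
    )
    return w, memory, trace


# ---------------------------------------------------------------------------
# Whole-image inference
# ---------------------------------------------------------------------------


def probability_map(
    img: MRImage,
    weights: RNNWeights,
    patch_size: int = 12,
    stride: int = 4,
    mask: LabelMask | None = None,
) -> np.ndarray:
    """Per-pixel tumor probability by averaging overlapping patch votes.

    Pixels covered by no patch get probability 0.
    """
    patches = encode_patches(img, mask, patch_size=patch_size, stride=stride)
    if not patches:
        return np.zeros(img.shape)
    x = np.stack([p.features for p in patches])
    ff, fb = _forward_batch(x, weights)
    probs = _readout(ff, fb, weights)[:, 1]
    acc = np.zeros(img.shape)
    cnt = np.zeros(img.shape)
    for p, pt in zip(patches, probs):
        acc[p.row : p.row + p.size, p.col : p.col + p.size] += pt
        cnt[p.row : p.row + p.size, p.col : p.col + p.size] += 1.0
    out = np.zeros(img.shape)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


def label_segments(
    segment_labels: np.ndarray, prob: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Tumor mask from segment-level fusion of the probability map.

    Each segment (id >= 0) is called tumor when the mean patch-vote
    probability over its pixels reaches ``threshold``; the returned mask is
    the union of tumor segments, so boundaries stay segmentation-accurate.
    """
    out = np.zeros(segment_labels.shape, dtype=bool)
    for sid in np.unique(segment_labels):
        if sid < 0:
            continue
        sel = segment_labels == sid
        if prob[sel].mean() >= threshold:
            out |= sel
    return out
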