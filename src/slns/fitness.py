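"""Fitness, thresholding and class-weight machinery.

Four ingredients feed the segmentation loop and the classifier:

* Otsu-style between-class variance ``w1 w2 (mu1 - mu2)^2`` over the image
  histogram, used as the interclass separability term.
* Fuzzy-entropy threshold selection: for each candidate level the grey
  levels get complementary S-/Z-shaped memberships to the tumor and
  non-tumor classes and the histogram-weighted Shannon entropy of those
  memberships is maximized.
* Intraclass correlation ``var_seg / (var_seg + var_img)`` of a segment
  against the whole image.
* A two-term segment fitness ``p * N / k + q * sum_seg(S / n_seg)`` trading
  segment granularity against segment size.

The self-learning memory persists class weights (empirical likelihood-ratio
weights between the non-tumor and tumor feature densities), the global-best
seed-point fitness and a per-run log across executions as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessParams",
    "FuzzyThreshold",
    "SelfLearningMemory",
    "interclass_variance",
    "fuzzy_entropy_threshold",
    "intraclass_correlation",
    "segment_fitness",
    "update_class_weights",
]

N_LEVELS = 256


@dataclass(frozen=True)
class FitnessParams:
    """Coefficients of the two-term fitness (one code path serves both the
    (p, q) accuracy/efficiency pair and the segmentation loop's (alpha, beta)
    pair, which share the same functional shape)."""

    p: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("fitness coefficients must be >= 0")


@dataclass
class FuzzyThreshold:
    threshold: int
    entropy: float
    mu_tumor: np.ndarray
    mu_non_tumor: np.ndarray
    bandwidth: float


def _check_hist(hist: np.ndarray) -> np.ndarray:
    h = np.asarray(hist, dtype=np.float64)
    if h.ndim != 1 or h.size != N_LEVELS:
        raise ValueError(f"histogram must have {N_LEVELS} bins")
    if np.any(h < 0):
        raise ValueError("histogram must be non-negative")
    if abs(h.sum() - 1.0) > 1e-6:
        raise ValueError("histogram must be normalized to sum 1")
    return h


def interclass_variance(hist: np.ndarray, threshold: int) -> float:
    """Between-class (Otsu) variance of the split at ``threshold``.

    Class 1 holds levels ``i < threshold``, class 2 levels
    ``i >= threshold``; returns ``w1 w2 (mu1 - mu2)^2``, 0 when either
    class is empty.
    """
    h = _check_hist(hist)
    if not (0 <= threshold < N_LEVELS):
        raise ValueError("threshold must lie in [0, 256)")
    levels = np.arange(N_LEVELS, dtype=np.float64)
    w1 = h[:threshold].sum()
    w2 = h[threshold:].sum()
    if w1 <= 0 or w2 <= 0:
        return 0.0
    mu1 = (h[:threshold] * levels[:threshold]).sum() / w1
    mu2 = (h[threshold:] * levels[threshold:]).sum() / w2
    return float(w1 * w2 * (mu1 - mu2) ** 2)


def total_variance(hist: np.ndarray) -> float:
    """Global intensity variance of the histogram."""
    h = _check_hist(hist)
    levels = np.arange(N_LEVELS, dtype=np.float64)
    mu = (h * levels).sum()
    return float((h * (levels - mu) ** 2).sum())


def _mode_bandwidth(h: np.ndarray, fallback: float = 32.0) -> float:
    """Half the distance between the two most prominent histogram modes."""
    smooth = gaussian_filter1d(h, 3.0, mode="nearest")
    peaks, props = find_peaks(smooth, prominence=0.0)
    if len(peaks) < 2:
        return fallback
    order = np.argsort(props["prominences"])[::-1]
    a, b = sorted(peaks[order[:2]])
    if b - a < 2:
        return fallback
    return (b - a) / 2.0


def fuzzy_entropy_threshold(hist: np.ndarray) -> FuzzyThreshold:
    """Select the grey level maximizing the fuzzy Shannon entropy.

    For a candidate level ``t`` the tumor-class membership of level ``i`` is
    the logistic S-curve ``expit((i - t) / b)`` with bandwidth ``b`` = half
    the inter-mode distance of the histogram (fallback 32); the non-tumor
    membership is its complement.  The score is

        theta(t) = - sum_{i<=t} p_i mu_tum(i)  log2 mu_tum(i)
                   - sum_{i>t}  p_i mu_non(i) log2 mu_non(i)

    and the smallest maximizing ``t`` is returned.
    """
    h = _check_hist(hist)
    if np.count_nonzero(h) < 2:
        raise ValueError("histogram needs >= 2 nonzero bins")
    b = _mode_bandwidth(h)
    i = np.arange(N_LEVELS, dtype=np.float64)
    # memberships for every candidate t at once: mu[t, i]
    mu_tum = expit((i[None, :] - i[:, None]) / b)
    mu_non = 1.0 - mu_tum

    def h2(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = -x[nz] * np.log2(x[nz])
        return out

    lower = np.tril(np.ones((N_LEVELS, N_LEVELS)))  # i <= t
    theta = (h[None, :] * (h2(mu_tum) * lower + h2(mu_non) * (1.0 - lower))).sum(axis=1)
    t = int(np.argmax(theta))  # argmax takes the smallest index on ties
    return FuzzyThreshold(
        threshold=t,
        entropy=float(theta[t]),
        mu_tumor=mu_tum[t],
        mu_non_tumor=mu_non[t],
        bandwidth=b,
    )


def intraclass_correlation(segment_values: np.ndarray, image_values: np.ndarray) -> float:
    """``var_seg / (var_seg + var_img)`` in [0, 1].

    The segment variance is computed locally on the member pixels, the image
    variance globally.  The doubly-degenerate case (both variances zero) is
    defined as 0 and logged.
    """
    seg = np.asarray(segment_values, dtype=np.float64).ravel()
    img = np.asarray(image_values, dtype=np.float64).ravel()
    if seg.size == 0:
        raise ValueError("segment must be non-empty")
    v_seg = float(np.var(seg))
    v_img = float(np.var(img))
    if v_seg == 0.0 and v_img == 0.0:
        logger.warning("intraclass_correlation: zero-variance segment and image; returning 0")
        return 0.0
    return v_seg / (v_seg + v_img)


def segment_fitness(
    total_pixels: int,
    segment_sizes: list[int] | np.ndarray,
    n_seed_points: int | None = None,
    params: FitnessParams | None = None,
) -> float:
    """Two-term fitness ``p * N/k + q * sum_seg(S / n_seg)``.

    ``N`` is the image pixel count, ``k`` the segment count, ``S`` the seed
    point count (defaults to the current segment-centroid count ``k``) and
    ``n_seg`` each segment's size.
    """
    params = params or FitnessParams()
    sizes = np.asarray(segment_sizes, dtype=np.float64)
    if sizes.size < 1:
        raise ValueError("at least one segment required")
    for idx, s in enumerate(sizes):
        if s <= 0:
            raise ValueError(f"segment {idx} is empty")
    k = sizes.size
    sp = k if n_seed_points is None else n_seed_points
    return float(params.p * total_pixels / k + params.q * np.sum(sp / sizes))


# ---------------------------------------------------------------------------
# Self-learning memory
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1
_EPS = 1e-6


@dataclass
class SelfLearningMemory:
    """Cross-run record of class weights and global-best fitness.

    ``w_p`` weights the non-tumor class, ``w_q`` the tumor class; they are
    estimated as empirical class-conditional density ratios/masses (see
    :func:`update_class_weights`).  ``gb_fitness`` is the best seed-point
    fitness seen over all logged runs.
    """

    w_p: float = 1.0
    w_q: float = 1.0
    gb_fitness: float = 0.0
    run_log: list[dict] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def log_run(
        self, run_id: str, n_segments: int, fitness: float, learning_factor: float, **extra: float
    ) -> None:
        self.run_log.append(
            {
                "run_id": run_id,
                "n_segments": int(n_segments),
                "fitness": float(fitness),
                "learning_factor": float(learning_factor),
                **{k: float(v) for k, v in extra.items()},
            }
        )
        self.gb_fitness = max([e["fitness"] for e in self.run_log], default=0.0)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SelfLearningMemory":
        raw = json.loads(Path(path).read_text())
        version = raw.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported memory schema_version {version!r}")
        return cls(**raw)


def _class_density(values: np.ndarray) -> np.ndarray:
    """Smoothed 256-bin class-conditional density of a [0,255] feature."""
    idx = np.clip(np.floor(values).astype(int), 0, N_LEVELS - 1)
    h = np.bincount(idx, minlength=N_LEVELS).astype(np.float64) + _EPS
    return h / h.sum()


def update_class_weights(
    memory: SelfLearningMemory,
    features: np.ndarray,
    labels: np.ndarray,
) -> SelfLearningMemory:
    """Re-estimate the class weights from labeled feature samples.

    ``w_p`` = mean likelihood ratio of the non-tumor density to the tumor
    density over all labeled samples; ``w_q`` = mean tumor density mass at
    the samples (scaled by the number of levels so a uniform density gives
    1).  Both are estimated from smoothed class-conditional histograms of
    the scalar classifier feature on the [0, 255] scale.  If one class is
    absent the weights are left unchanged and a warning is logged.
    """
    features = np.asarray(features, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if features.shape != labels.shape:
        raise ValueError("features and labels must have matching length")
    tumor = features[labels == 1]
    non_tumor = features[labels == 0]
    if tumor.size == 0 or non_tumor.size == 0:
        logger.warning("update_class_weights: one class absent; weights unchanged")
        return memory
    f_tum = _class_density(tumor)
    f_non = _class_density(non_tumor)
    idx = np.clip(np.floor(features).astype(int), 0, N_LEVELS - 1)
    # per-sample ratios are clipped so near-disjoint supports give a large
    # but usable weight instead of a degenerate one
    ratio = np.clip(f_non[idx] / f_tum[idx], 1e-2, 1e2)
    memory.w_p = float(np.mean(ratio))
    memory.w_q = float(np.mean(f_tum[idx]) * N_LEVELS)
    return memory
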