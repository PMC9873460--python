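"""HARIS: heuristic two-objective image segmentation.

The loop couples two objectives:

* **Objective I** — assign every pixel to the segment minimizing the
  Mahalanobis distance in feature space (intensity, optionally local GLCM
  contrast/homogeneity), then score the partition with the two-term fitness
  ``f = alpha * sum_r N / n_r + beta * sum_r k / n_r`` where ``alpha`` is an
  intraclass-correlation coefficient and ``beta`` the class-probability
  weighted within-segment variance.
* **Objective II** — a stochastic seed-point refinement: per-segment
  seed-point fitness ``sp_i = rand * f_prev + rand * (gb - f_prev)`` pulls
  the centroids a configurable step toward the best configuration seen so
  far; the global best is the running maximum.

The initial segment count comes from an elbow scan: optimal 1-D clustering
of the intensity histogram (dynamic programming, L1 cost) for j = 1..23,
then the maximum-curvature point of the within-cluster distance curve.
Between iterations a fitness-change signal can add a segment (split the
highest-variance one at its farthest member) or remove one (merge the two
nearest centroids); inside :func:`run_haris` a tentative split/merge is only
kept when it moves the pooled within-segment variance past a significance
tolerance, which keeps the count from collapsing or exploding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import MRImage
from .texture import quantize

logger = logging.getLogger(__name__)

__all__ = [
    "HarisConfig",
    "SegmentStats",
    "Segmentation",
    "SeedPointState",
    "ElbowState",
    "cluster_histogram_1d",
    "estimate_initial_segments",
    "build_features",
    "mahalanobis_d2",
    "assign_pixels",
    "objective1",
    "adapt_segment_count",
    "objective2_refine",
    "run_haris",
]


@dataclass(frozen=True)
class HarisConfig:
    alpha_weight: float = 1.0
    beta_weight: float = 1.0
    max_iters: int = 50
    plateau_tol: float = 1e-4
    initial_j: int = 23
    feature_set: str = "intensity+texture"  # or "intensity"
    refine_step: float = 0.1
    adapt: bool = True
    split_bimodality: float = 0.6  # min relative 2-cluster cost drop to keep a split
    adapt_merge_loss: float = 0.05  # max relative within-variance rise to keep a merge
    elbow_tol: float = 0.01  # "no significant change" tolerance on the elbow curve
    texture_window: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.plateau_tol <= 0:
            raise ValueError("plateau_tol must be > 0")
        if self.feature_set not in ("intensity", "intensity+texture"):
            raise ValueError("feature_set must be 'intensity' or 'intensity+texture'")


@dataclass
class SegmentStats:
    """Per-segment feature statistics used for Mahalanobis assignment."""

    centroid: np.ndarray
    covariance: np.ndarray
    inv_covariance: np.ndarray
    pixel_count: int
    std: float  # intensity std
    contrast_index: float  # RMS / mean of member intensities

    @classmethod
    def from_members(cls, feats: np.ndarray) -> "SegmentStats":
        """Estimate stats from the member feature rows (column 0 = intensity)."""
        mu = feats.mean(axis=0)
        d = feats.shape[1]
        diff = feats - mu
        cov = diff.T @ diff / max(len(feats), 1)
        eps = 1e-6 * max(np.trace(cov), 1e-12) / d
        cov_r = cov + eps * np.eye(d)
        inv = np.linalg.inv(cov_r)
        intens = feats[:, 0]
        mean_i = float(intens.mean())
        rms = float(np.sqrt(np.mean(intens**2)))
        contrast = rms / mean_i if mean_i > 0 else 0.0
        return cls(
            centroid=mu,
            covariance=cov_r,
            inv_covariance=inv,
            pixel_count=len(feats),
            std=float(intens.std()),
            contrast_index=contrast,
        )


@dataclass
class Segmentation:
    labels: np.ndarray  # (H, W) contiguous ids from 0
    segments: list[SegmentStats]
    fitness: float = np.nan
    alpha: float = np.nan
    beta: float = np.nan
    trace: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class SeedPointState:
    sp: np.ndarray
    prev_fitness: float
    gb_fitness: float
    rng_seed: int


@dataclass
class ElbowState:
    j: int
    curve: list[tuple[int, float]]  # (j, within-cluster L1 distance sum)


# ---------------------------------------------------------------------------
# Elbow estimation: optimal 1-D histogram clustering by dynamic programming
# ---------------------------------------------------------------------------


def _l1_cost_matrix(weights: np.ndarray) -> np.ndarray:
    """cost[i, j] = minimal weighted L1 deviation of bins i..j from their
    weighted median, for a 256-bin histogram."""
    g = len(weights)
    x = np.arange(g, dtype=np.float64)
    cw = np.concatenate([[0.0], np.cumsum(weights)])
    cwx = np.concatenate([[0.0], np.cumsum(weights * x)])
    cost = np.zeros((g, g))
    for i in range(g):
        j = np.arange(i, g)
        w_tot = cw[j + 1] - cw[i]
        target = cw[i] + w_tot / 2.0
        m = np.searchsorted(cw[1:], target, side="left")
        m = np.clip(m, i, j)
        xm = x[m]
        left = xm * (cw[m + 1] - cw[i]) - (cwx[m + 1] - cwx[i])
        right = (cwx[j + 1] - cwx[m + 1]) - xm * (cw[j + 1] - cw[m + 1])
        cost[i, i:] = left + right
    return cost


def cluster_histogram_1d(weights: np.ndarray, k_max: int) -> tuple[np.ndarray, list[list[int]]]:
    """Optimal L1 clustering of a 256-bin intensity histogram.

    Returns ``(within, boundaries)`` where ``within[k-1]`` is the optimal
    within-cluster distance sum using ``k`` clusters, and ``boundaries[k-1]``
    the first bin of each cluster.  Optimality makes the curve monotone
    non-increasing in ``k`` by construction.
    """
    w = np.asarray(weights, dtype=np.float64)
    g = len(w)
    cost = _l1_cost_matrix(w)
    dp = np.full((k_max, g), np.inf)
    split = np.zeros((k_max, g), dtype=int)
    dp[0] = cost[0]
    for k in range(1, k_max):
        for j in range(k, g):
            cand = dp[k - 1, k - 1 : j] + cost[k : j + 1, j]
            i = int(np.argmin(cand))
            dp[k, j] = cand[i]
            split[k, j] = i + k
    within = dp[:, g - 1].copy()
    boundaries: list[list[int]] = []
    for k in range(k_max):
        cuts = []
        j = g - 1
        for kk in range(k, 0, -1):
            s = split[kk, j]
            cuts.append(s)
            j = s - 1
        boundaries.append([0] + cuts[::-1])
    return within, boundaries


def _elbow_index(curve: np.ndarray) -> int:
    """Maximum-curvature (kneedle) index of a non-increasing curve.

    ``curve[k-1]`` is the value at ``k`` clusters; returns ``k``.
    """
    n = len(curve)
    w0 = curve[0]
    if w0 <= 0:
        return 1
    y = curve / w0
    x = np.linspace(0.0, 1.0, n)
    chord = y[0] + (y[-1] - y[0]) * x
    gap = chord - y
    return int(np.argmax(gap)) + 1


def estimate_initial_segments(
    img: MRImage, cfg: HarisConfig | None = None
) -> tuple[int, ElbowState]:
    """Elbow-based segment-count estimate from the intensity histogram.

    Scans j = 1..initial_j cluster counts with optimal 1-D clustering,
    records the within-cluster L1 distance curve and returns its
    maximum-curvature point.  A constant image returns 1 with a warning.
    """
    cfg = cfg or HarisConfig()
    q = np.clip(np.round(img.data).astype(int), 0, 255)
    hist = np.bincount(q.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        logger.warning("estimate_initial_segments: constant image; returning 1 segment")
        state = ElbowState(j=1, curve=[(1, 0.0)])
        return 1, state
    within, _ = cluster_histogram_1d(hist, cfg.initial_j)
    j = _elbow_index(within)
    state = ElbowState(j=j, curve=[(k + 1, float(v)) for k, v in enumerate(within)])
    return j, state


# ---------------------------------------------------------------------------
# Features and assignment
# ---------------------------------------------------------------------------


def build_features(img: MRImage, cfg: HarisConfig | None = None) -> np.ndarray:
    """Per-pixel feature grid, shape (H, W, d).

    Column 0 is always raw intensity.  With ``intensity+texture`` two local
    co-occurrence statistics are appended: the mean squared difference of
    horizontally adjacent quantized levels over a sliding window (local GLCM
    contrast) and the matching homogeneity ``mean 1/(1+diff^2)``.
    """
    cfg = cfg or HarisConfig()
    arr = img.data
    feats = [arr]
    if cfg.feature_set == "intensity+texture":
        q = quantize(arr, 32).astype(np.float64)
        d2 = np.zeros_like(arr)
        d2[:, :-1] = (q[:, 1:] - q[:, :-1]) ** 2
        d2[:, -1] = d2[:, -2]
        win = cfg.texture_window
        contrast = ndimage.uniform_filter(d2, win, mode="reflect")
        homog = ndimage.uniform_filter(1.0 / (1.0 + d2), win, mode="reflect")
        # bring texture channels to an intensity-comparable scale
        feats += [contrast * 4.0, homog * 100.0]
    return np.stack(feats, axis=-1)


def mahalanobis_d2(x: np.ndarray, stats: SegmentStats) -> np.ndarray | float:
    """Squared Mahalanobis distance ``(x - mu)^T S^-1 (x - mu)``.

    ``x`` may be a single feature vector or an (N, d) batch.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = stats.centroid
    single = x.ndim == 1
    pts = x[None, :] if single else x
    if pts.shape[1] != mu.shape[0]:
        raise ValueError(f"feature dim {pts.shape[1]} != centroid dim {mu.shape[0]}")
    diff = pts - mu
    d2 = np.einsum("ni,ij,nj->n", diff, stats.inv_covariance, diff)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


def assign_pixels(
    features: np.ndarray, segments: list[SegmentStats]
) -> tuple[np.ndarray, list[SegmentStats]]:
    """Assign every pixel to its Mahalanobis-nearest segment.

    Ties go to the lowest segment id; per-segment stats are recomputed from
    the new membership and empty segments are dropped with id compaction.
    Returns ``(labels, new_segments)`` with labels shaped like the grid.
    """
    if len(segments) < 1:
        raise ValueError("at least one segment required")
    shape = features.shape[:-1]
    d = features.shape[-1]
    flat = features.reshape(-1, d)
    dist = np.stack([mahalanobis_d2(flat, s) for s in segments], axis=1)
    labels = np.argmin(dist, axis=1)
    new_segments: list[SegmentStats] = []
    remap = np.full(len(segments), -1)
    for sid in range(len(segments)):
        members = flat[labels == sid]
        if len(members) == 0:
            continue
        remap[sid] = len(new_segments)
        new_segments.append(SegmentStats.from_members(members))
    labels = remap[labels]
    return labels.reshape(shape), new_segments


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


def _variance_components(intensity: np.ndarray, labels: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Pooled within-segment and between-segment intensity variances."""
    flat_i = intensity.ravel()
    flat_l = labels.ravel()
    k = int(flat_l.max()) + 1
    sizes = np.bincount(flat_l, minlength=k).astype(np.float64)
    if np.any(sizes == 0):
        raise ValueError("empty segment in labeling")
    sums = np.bincount(flat_l, weights=flat_i, minlength=k)
    means = sums / sizes
    sq = np.bincount(flat_l, weights=flat_i**2, minlength=k)
    var_within = sq / sizes - means**2
    var_within = np.maximum(var_within, 0.0)
    weights = sizes / sizes.sum()
    pooled = float(np.sum(weights * var_within))
    mu = float(flat_i.mean())
    between = float(np.sum(weights * (means - mu) ** 2))
    return pooled, between, sizes, var_within


def objective1(
    img: MRImage | np.ndarray, labels: np.ndarray, cfg: HarisConfig | None = None
) -> tuple[float, float, float]:
    """Objective-I fitness of a partition.

    ``alpha = sigma_i^2 / ((sigma_i^2 + sigma_e^2)/2)`` from the intraclass
    (pooled within) and interclass (between) variance components;
    ``beta = sum_r w_r sigma_r^2`` (class-probability weighted within-class
    variance, i.e. the pooled within-segment variance); and

        f = sum_r alpha * N / n_r  +  sum_r beta * k / n_r.

    Returns ``(f, alpha, beta)``.
    """
    cfg = cfg or HarisConfig()
    intensity = img.data if isinstance(img, MRImage) else np.asarray(img, dtype=np.float64)
    pooled, between, sizes, _ = _variance_components(intensity, labels)
    denom = (pooled + between) / 2.0
    alpha = pooled / denom if denom > 0 else 0.0
    beta = pooled
    n = intensity.size
    k = len(sizes)
    inv_sizes = np.sum(1.0 / sizes)
    f = cfg.alpha_weight * alpha * n * inv_sizes + cfg.beta_weight * beta * k * inv_sizes
    return float(f), float(alpha), float(beta)


def adaptation_signal(delta_f: float) -> float:
    """Map the iteration-to-iteration fitness change to the adapt signal.

    Improvement (fitness decreased) gives a positive signal, worsening a
    negative one; the magnitude is the relative change.
    """
    return float(delta_f)


def adapt_segment_count(
    signal: float, features: np.ndarray, segmentation: Segmentation
) -> Segmentation:
    """Add or remove one segment according to the fitness signal.

    ``signal < 0`` splits the segment with the highest within-segment
    intensity variance, seeding the new centroid at its farthest member;
    ``signal > 0`` (with k > 2) merges the two segments with the nearest
    centroids; ``signal == 0`` returns the segmentation unchanged.  Pixels
    are reassigned after the change.
    """
    segs = segmentation.segments
    k = len(segs)
    if signal == 0:
        return segmentation
    d = features.shape[-1]
    flat = features.reshape(-1, d)
    flat_l = segmentation.labels.ravel()
    if signal < 0:
        worst = int(np.argmax([s.std for s in segs]))
        members = flat[flat_l == worst]
        far = members[int(np.argmax(mahalanobis_d2(members, segs[worst])))]
        centroids = [s.centroid for s in segs] + [far]
    else:
        if k <= 2:
            return segmentation
        cents = np.stack([s.centroid for s in segs])
        d2 = np.sum((cents[:, None, :] - cents[None, :, :]) ** 2, axis=-1)
        d2[np.diag_indices(k)] = np.inf
        a, b = np.unravel_index(np.argmin(d2), d2.shape)
        na, nb = segs[a].pixel_count, segs[b].pixel_count
        merged = (segs[a].centroid * na + segs[b].centroid * nb) / (na + nb)
        centroids = [s.centroid for i, s in enumerate(segs) if i not in (a, b)] + [merged]
    shared = pooled_metric(segs)[0]
    proto = []
    for c in centroids:
        s = _stats_at(c, d)
        s.covariance, s.inv_covariance = shared.covariance, shared.inv_covariance
        proto.append(s)
    labels, new_segs = assign_pixels(features, proto)
    return Segmentation(labels=labels, segments=new_segs, trace=segmentation.trace)


def _stats_at(centroid: np.ndarray, dim: int) -> SegmentStats:
    """Identity-covariance placeholder stats at a given centroid."""
    return SegmentStats(
        centroid=np.asarray(centroid, dtype=np.float64),
        covariance=np.eye(dim),
        inv_covariance=np.eye(dim),
        pixel_count=0,
        std=0.0,
        contrast_index=0.0,
    )


def pooled_metric(segments: list[SegmentStats]) -> list[SegmentStats]:
    """Segments with their covariance replaced by the pooled (pixel-count
    weighted) within-segment covariance.

    A shared metric keeps the Mahalanobis assignment a proper whitened
    k-means: per-segment metrics let large-covariance segments swallow
    their neighbours and the iteration degenerates.  Per-segment
    covariances remain available on the recomputed stats after assignment.
    """
    weights = np.array([max(s.pixel_count, 1) for s in segments], dtype=np.float64)
    covs = np.stack([s.covariance for s in segments])
    pooled = np.einsum("k,kij->ij", weights / weights.sum(), covs)
    d = pooled.shape[0]
    eps = 1e-6 * max(np.trace(pooled), 1e-12) / d
    inv = np.linalg.inv(pooled + eps * np.eye(d))
    return [
        SegmentStats(
            centroid=s.centroid,
            covariance=pooled,
            inv_covariance=inv,
            pixel_count=s.pixel_count,
            std=s.std,
            contrast_index=s.contrast_index,
        )
        for s in segments
    ]


def objective2_refine(
    state: SeedPointState,
    segments: list[SegmentStats],
    best_centroids: np.ndarray | None,
    rng: np.random.Generator,
    step: float = 0.1,
) -> tuple[SeedPointState, list[SegmentStats]]:
    """Stochastic seed-point refinement toward the global best.

    Per segment ``sp_i = rand(0,1) * f_prev + rand(0,1) * (gb - f_prev)``;
    centroids are nudged toward the best configuration seen so far by
    ``step * sp_i / max(gb, eps)``.  The global best is updated to the
    running maximum, hence non-decreasing.
    """
    k = len(segments)
    r1 = rng.random(k)
    r2 = rng.random(k)
    sp = r1 * state.prev_fitness + r2 * (state.gb_fitness - state.prev_fitness)
    gb = max(state.gb_fitness, float(np.max(sp)) if k else state.gb_fitness)
    new_segments = segments
    if best_centroids is not None and len(best_centroids) == k and gb > 0:
        coef = step * np.clip(sp / gb, 0.0, 1.0)
        new_segments = []
        for i, s in enumerate(segments):
            c = s.centroid + coef[i] * (best_centroids[i] - s.centroid)
            ns = SegmentStats(
                centroid=c,
                covariance=s.covariance,
                inv_covariance=s.inv_covariance,
                pixel_count=s.pixel_count,
                std=s.std,
                contrast_index=s.contrast_index,
            )
            new_segments.append(ns)
    new_state = SeedPointState(
        sp=sp, prev_fitness=state.prev_fitness, gb_fitness=gb, rng_seed=state.rng_seed
    )
    return new_state, new_segments


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def _init_segments(intensity: np.ndarray, flat_feats: np.ndarray, k: int) -> list[SegmentStats]:
    """Deterministic init: optimal 1-D intensity clustering into k bands,
    segment stats from the band members."""
    q = np.clip(np.round(intensity).astype(int), 0, 255)
    hist = np.bincount(q, minlength=256).astype(np.float64)
    _, boundaries = cluster_histogram_1d(hist, max(k, 1))
    cuts = boundaries[k - 1] + [256]
    segs = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        members = flat_feats[(q >= lo) & (q < hi)]
        if len(members):
            segs.append(SegmentStats.from_members(members))
    return segs


def run_haris(
    img: MRImage,
    cfg: HarisConfig | None = None,
    exclude_mask: np.ndarray | None = None,
) -> Segmentation:
    """Full HARIS loop: elbow init, assign, score, adapt, refine, repeat.

    ``exclude_mask`` marks non-brain pixels (background/skull) to exclude
    from clustering; excluded pixels get label -1 in the result.  Stops when
    the relative fitness change stays below ``plateau_tol`` (after an
    exploratory adaptation attempt) or at ``max_iters``.  Final segment ids
    are sorted by ascending centroid intensity.
    """
    cfg = cfg or HarisConfig()
    rng = np.random.default_rng(cfg.seed)
    grid_feats = build_features(img, cfg)
    h, w, d = grid_feats.shape
    include = np.ones((h, w), dtype=bool) if exclude_mask is None else ~exclude_mask
    if not include.any():
        raise ValueError("exclude_mask leaves no pixels to segment")
    flat_feats = grid_feats[include]
    intensity = img.data[include]
    sub = MRImage(intensity.reshape(1, -1), metadata=dict(img.metadata))
    k0, _elbow = estimate_initial_segments(sub, cfg)
    segments = _init_segments(intensity, flat_feats, max(k0, 1))
    trace: list[dict] = []
    prev_f: float | None = None
    best_f = np.inf
    best_centroids: np.ndarray | None = None
    best_labels: np.ndarray | None = None
    best_segments: list[SegmentStats] | None = None
    sp_state = SeedPointState(
        sp=np.zeros(len(segments)), prev_fitness=0.0, gb_fitness=0.0, rng_seed=cfg.seed
    )
    plateau = 0
    adapt_budget = cfg.initial_j
    converged = False
    labels = np.zeros(len(flat_feats), dtype=int)
    f = np.inf
    for it in range(cfg.max_iters):
        labels, segments = assign_pixels(flat_feats, pooled_metric(segments))
        f, alpha, beta = objective1(intensity, labels, cfg)
        trace.append({"iter": it, "k": len(segments), "fitness": f, "alpha": alpha, "beta": beta})
        if f < best_f:
            best_f = f
            best_centroids = np.stack([s.centroid for s in segments])
            best_labels = labels.copy()
            best_segments = list(segments)
        if prev_f is not None:
            delta = prev_f - f
            rel = abs(delta) / max(abs(prev_f), 1e-12)
            plateau = plateau + 1 if rel < cfg.plateau_tol else 0
            if plateau >= 1 and cfg.adapt and adapt_budget > 0:
                adapt_budget -= 1
                seg_obj = Segmentation(labels=labels, segments=segments)
                accepted = _guarded_adapt(intensity, flat_feats, seg_obj, cfg)
                if accepted is not None:
                    labels, segments = accepted.labels, accepted.segments
                    prev_f = None
                    plateau = 0
                    trace.append({"iter": it, "event": "adapt", "k": len(segments)})
                    continue
            if plateau >= 2:
                converged = True
                break
        sp_state = SeedPointState(
            sp=sp_state.sp, prev_fitness=f, gb_fitness=sp_state.gb_fitness, rng_seed=cfg.seed
        )
        # decaying step: stochastic exploration early, convergence late
        sp_state, segments = objective2_refine(
            sp_state, segments, best_centroids, rng, cfg.refine_step / (1.0 + it)
        )
        prev_f = f
    if not converged:
        logger.warning(
            "run_haris: no plateau within max_iters=%d; returning best-so-far", cfg.max_iters
        )
        if best_labels is not None:
            labels, segments = best_labels, best_segments
    # final deterministic id order: ascending centroid intensity
    order = np.argsort([s.centroid[0] for s in segments], kind="stable")
    remap = np.empty(len(segments), dtype=int)
    remap[order] = np.arange(len(segments))
    labels = remap[labels]
    segments = [segments[i] for i in order]
    f, alpha, beta = objective1(intensity, labels, cfg)
    full = np.full((h, w), -1, dtype=int)
    full[include] = labels
    return Segmentation(
        labels=full,
        segments=segments,
        fitness=f,
        alpha=alpha,
        beta=beta,
        trace=trace,
        converged=converged,
    )


def _bimodality(intensity: np.ndarray) -> float:
    """Relative cost drop of the optimal 1-D 2-clustering of a pixel set.

    ~0.45 for a single Gaussian; close to 1 for well-separated bimodal
    intensities.  Used to decide whether a segment genuinely contains two
    populations before accepting a split.
    """
    q = np.clip(np.round(intensity).astype(int), 0, 255)
    hist = np.bincount(q, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        return 0.0
    within, _ = cluster_histogram_1d(hist, 2)
    if within[0] <= 0:
        return 0.0
    return float(1.0 - within[1] / within[0])


def _guarded_adapt(
    intensity: np.ndarray, flat_feats: np.ndarray, seg: Segmentation, cfg: HarisConfig
) -> Segmentation | None:
    """Try an exploratory split (then a merge) and gate the acceptance.

    A split is kept only when the targeted segment's intensities are
    genuinely bimodal (optimal 2-cluster cost drop above
    ``cfg.split_bimodality``) and the pooled within-segment variance
    improves; a merge is kept only when it costs almost nothing
    (relative pooled-variance rise below ``cfg.adapt_merge_loss``).
    """
    pooled, _, _, _ = _variance_components(intensity, seg.labels)
    if pooled > 1e-9 and seg.n_segments >= 1:
        target = int(np.argmax([s.std for s in seg.segments]))
        members = intensity[seg.labels.ravel() == target]
        if _bimodality(members) > cfg.split_bimodality:
            cand = adapt_segment_count(-1.0, flat_feats, seg)
            if cand.n_segments > seg.n_segments:
                new_pooled, _, _, _ = _variance_components(intensity, cand.labels)
                if new_pooled < pooled:
                    return cand
    if seg.n_segments > 2:
        cand = adapt_segment_count(+1.0, flat_feats, seg)
        if cand.n_segments < seg.n_segments:
            new_pooled, _, _, _ = _variance_components(intensity, cand.labels)
            if pooled <= 1e-9:
                if new_pooled <= 1e-9:
                    return cand
            elif new_pooled <= pooled * (1.0 + cfg.adapt_merge_loss):
                return cand
    return None
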