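"""Grey-level co-occurrence matrix (GLCM) features.

The GLCM counts how often a pair of quantized intensities occurs at a fixed
pixel displacement; normalizing the counts turns frequencies into a joint
probability table from which Haralick-style texture statistics (contrast,
energy, homogeneity, entropy) are derived.  This is the feature engine for
both the segmentation stage and the tumor impact indices.

Grey levels default to G=32 bins over [0, 255], which keeps the matrix
well-populated on a 228x228 slice.  Out-of-bounds pixel pairs are skipped
(standard GLCM convention), never wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import MRImage

__all__ = ["GLCMConfig", "GLCMatrix", "quantize", "compute_glcm", "texture_stats"]


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 32
    displacement: tuple[int, int] = (0, 1)  # (d_row, d_col)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.displacement == (0, 0):
            raise ValueError("displacement must be nonzero")


@dataclass
class GLCMatrix:
    """Co-occurrence counts and their probability normalization."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        t = self.counts.sum()
        if t == 0:
            raise ValueError("empty GLCM has no probability normalization")
        return self.counts / t


def quantize(img: MRImage | np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin [0, 255] intensities into ``levels`` integer bins.

    Bin index is ``floor(v * levels / 256)`` clipped to [0, levels); with
    levels=256 this is the identity on 8-bit data.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    data = img.data if isinstance(img, MRImage) else np.asarray(img, dtype=np.float64)
    idx = np.floor(data * levels / 256.0).astype(np.int64)
    return np.clip(idx, 0, levels - 1)


def compute_glcm(img: MRImage | np.ndarray, cfg: GLCMConfig) -> GLCMatrix:
    """Count co-occurring quantized intensity pairs at ``cfg.displacement``.

    ``counts[x, y]`` is the number of in-bounds pixel pairs
    ``(p, q), (p + d_row, q + d_col)`` whose quantized values are ``(x, y)``;
    with ``symmetric=True`` both orderings of each pair are counted.
    """
    q = quantize(img, cfg.levels)
    h, w = q.shape
    dr, dc = cfg.displacement
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"displacement {cfg.displacement} exceeds image shape {q.shape}")
    # Slice the two co-occurring views of the image.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    g = cfg.levels
    counts = np.bincount(a * g + b, minlength=g * g).reshape(g, g)
    if cfg.symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts)


def texture_stats(glcm: GLCMatrix | np.ndarray) -> dict[str, float]:
    """Haralick-style scalars from the normalized GLCM.

    contrast = sum p(i,j) (i-j)^2; energy = sum p^2;
    homogeneity = sum p / (1 + (i-j)^2); entropy = -sum p ln p (0 ln 0 := 0).
    """
    p = glcm.probs if isinstance(glcm, GLCMatrix) else np.asarray(glcm, dtype=np.float64)
    if p.sum() <= 0:
        raise ValueError("all-zero GLCM has no texture statistics")
    g = p.shape[0]
    i, j = np.mgrid[0:g, 0:g]
    diff2 = (i - j) ** 2
    nz = p[p > 0]
    return {
        "contrast": float(np.sum(p * diff2)),
        "energy": float(np.sum(p * p)),
        "homogeneity": float(np.sum(p / (1.0 + diff2))),
        "entropy": float(-np.sum(nz * np.log(nz))),
    }
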