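"""Synthetic 2-D brain-MRI phantom generator with exact ground truth.

The phantom emulates an axial T1-like slice: an elliptical skull ring, brain
parenchyma inside it, a circular tumor core and an enhancing rim around the
core, on a dark background.  Every generated image comes with a pixel-exact
label mask, so segmentation and classification stages can be benchmarked
without any external dataset.

Noise models: additive Gaussian, or Rician (the magnitude-MRI noise model,
implemented as the modulus of a complex Gaussian perturbation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .image import ConfigurationError, LabelMask, MRImage

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "generate_multiregion"]

REGIONS = ("background", "skull", "brain", "core", "rim")

DEFAULT_MEANS = {
    "background": 5.0,
    "skull": 230.0,
    "brain": 100.0,
    "core": 180.0,
    "rim": 140.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one phantom slice.

    All lengths are in pixels; the brain ellipse is centred on the image.
    Region mean intensities must be pairwise distinct by at least 10
    intensity units (the separability contract every downstream stage
    relies on).
    """

    height: int = 228
    width: int = 228
    brain_axes: tuple[float, float] = (90.0, 74.0)  # (row, col) semi-axes
    skull_thickness: float = 6.0
    core_center: tuple[float, float] = (104.0, 138.0)
    core_radius: float = 22.0
    rim_width: float = 6.0
    intensity_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_model: str = "gaussian"
    noise_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ConfigurationError("height/width must be at least 16 pixels")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if set(self.intensity_means) != set(REGIONS):
            raise ConfigurationError(
                f"intensity_means must define exactly {REGIONS}"
            )
        means = [self.intensity_means[r] for r in REGIONS]
        if min(means) < 0 or max(means) > 255:
            raise ConfigurationError("intensity_means must lie in [0, 255]")
        for i, a in enumerate(REGIONS):
            for b in REGIONS[i + 1 :]:
                if abs(self.intensity_means[a] - self.intensity_means[b]) < 10:
                    raise ConfigurationError(
                        f"intensity_means for {a!r} and {b!r} differ by < 10"
                    )
        if self.core_radius <= 0 or self.rim_width < 0 or self.skull_thickness <= 0:
            raise ConfigurationError("core_radius/skull_thickness must be > 0, rim_width >= 0")
        # Tumor (core + rim) must fit strictly inside the brain ellipse.
        cr, cc = self.core_center
        r0, c0 = (self.height - 1) / 2.0, (self.width - 1) / 2.0
        a, b = self.brain_axes
        reach = self.core_radius + self.rim_width
        # Worst-case point of the tumor disk in the ellipse's normalized metric.
        norm = np.hypot((cr - r0) / a, (cc - c0) / b) + reach / min(a, b)
        if norm >= 1.0:
            raise ConfigurationError(
                "core_center/core_radius/rim_width: tumor disk does not fit "
                "inside brain_axes ellipse"
            )


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    r0, c0 = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    a, b = spec.brain_axes
    inner = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    outer = ((rr - r0) / (a + spec.skull_thickness)) ** 2 + (
        (cc - c0) / (b + spec.skull_thickness)
    ) ** 2 <= 1.0
    d_core = np.hypot(rr - spec.core_center[0], cc - spec.core_center[1])
    labels = np.zeros((spec.height, spec.width), dtype=np.int64)
    labels[outer] = 1
    labels[inner] = 2
    labels[inner & (d_core <= spec.core_radius + spec.rim_width)] = 4
    labels[inner & (d_core <= spec.core_radius)] = 3
    return labels


def _apply_noise(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma == 0:
        return clean.copy()
    if spec.noise_model == "gaussian":
        noisy = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
    else:  # rician: modulus of a complex Gaussian perturbation
        re = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
        im = rng.normal(0.0, spec.noise_sigma, clean.shape)
        noisy = np.hypot(re, im)
    return noisy


def generate_phantom(spec: PhantomSpec) -> tuple[MRImage, LabelMask]:
    """Generate one phantom slice and its exact ground-truth mask.

    Deterministic: the same ``spec`` (including ``spec.seed``) always yields
    bit-identical arrays.  Intensities are clamped to [0, 255] after noise;
    the clamping rate is logged and recorded in the image metadata.
    """
    spec.validate()
    labels = _region_labels(spec)
    clean = np.zeros(labels.shape, dtype=np.float64)
    for value, name in enumerate(REGIONS):
        clean[labels == value] = spec.intensity_means[name]
    rng = np.random.default_rng(spec.seed)
    noisy = _apply_noise(clean, spec, rng)
    clamped = np.clip(noisy, 0.0, 255.0)
    clamp_rate = float(np.mean(noisy != clamped))
    if clamp_rate > 0:
        logger.debug("phantom seed=%d: clamped %.3f%% of pixels", spec.seed, 100 * clamp_rate)
    img = MRImage(
        clamped,
        metadata={
            "source": "phantom",
            "seed": spec.seed,
            "noise_model": spec.noise_model,
            "noise_sigma": spec.noise_sigma,
            "clamp_rate": clamp_rate,
            "synthetic": True,
        },
    )
    return img, LabelMask(labels)


def _jittered(spec: PhantomSpec, jitter: float, rng: np.random.Generator, seed: int) -> PhantomSpec:
    def j(x: float) -> float:
        return float(x * (1.0 + rng.uniform(-jitter, jitter)))

    means = {k: float(np.clip(j(v), 0, 255)) for k, v in spec.intensity_means.items()}
    return replace(
        spec,
        brain_axes=(j(spec.brain_axes[0]), j(spec.brain_axes[1])),
        core_center=(j(spec.core_center[0]), j(spec.core_center[1])),
        core_radius=j(spec.core_radius),
        rim_width=j(spec.rim_width),
        skull_thickness=j(spec.skull_thickness),
        intensity_means=means,
        seed=seed,
    )


def generate_dataset(
    spec: PhantomSpec, n: int, jitter: float = 0.0, seed: int = 0, max_retries: int = 25
) -> list[tuple[MRImage, LabelMask]]:
    """Generate ``n`` phantoms with per-sample geometry/intensity jitter.

    ``jitter`` is the half-width of a relative uniform perturbation applied
    to geometry and mean intensities of each sample.  Samples whose jittered
    geometry violates the spec invariants are re-drawn (bounded retries).
    Per-sample seeds derive deterministically from the master ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= jitter < 0.5):
        raise ValueError("jitter must lie in [0, 0.5)")
    master = np.random.SeedSequence(seed)
    out: list[tuple[MRImage, LabelMask]] = []
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        sample_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for attempt in range(max_retries):
            cand = (
                replace(spec, seed=sample_seed)
                if jitter == 0.0
                else _jittered(spec, jitter, rng, sample_seed)
            )
            try:
                cand.validate()
            except ConfigurationError:
                continue
            out.append(generate_phantom(cand))
            break
        else:
            raise ConfigurationError(
                f"sample {i}: no valid geometry after {max_retries} jitter draws"
            )
    return out


def generate_multiregion(
    k: int,
    size: int = 228,
    noise_sigma: float = 0.0,
    seed: int = 0,
    lo: float = 20.0,
    hi: float = 230.0,
) -> tuple[MRImage, np.ndarray]:
    """Phantom with ``k`` concentric equal-area bands of distinct intensity.

    A deliberately simple target for cluster-count estimation: ``k``
    separated intensity levels evenly spaced in [lo, hi], each occupying a
    comparable pixel area (nested ellipses with radii proportional to
    sqrt(band index)).  Returns the image and an integer band-label grid
    (0..k-1), not the five-label tumor legend.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rr, cc = np.mgrid[0:size, 0:size]
    r0 = (size - 1) / 2.0
    a, b = 0.49 * size, 0.42 * size
    # Normalized elliptical radius in [0, ~1.6]; bands chosen equal-area
    # inside the unit ellipse, band 0 = everything outside.
    rho2 = ((rr - r0) / a) ** 2 + ((cc - r0) / b) ** 2
    labels = np.zeros((size, size), dtype=np.int64)
    if k > 1:
        # k-1 nested bands inside the ellipse + outside band 0
        edges = np.linspace(0.0, 1.0, k)  # rho^2 cuts -> equal areas
        inside = rho2 <= 1.0
        band = np.searchsorted(edges[1:], rho2, side="right")  # 0..k-2
        labels[inside] = (k - 1) - band[inside]  # innermost brightest index
    levels = np.linspace(lo, hi, k) if k > 1 else np.array([lo])
    clean = levels[labels]
    rng = np.random.default_rng(seed)
    img = clean if noise_sigma == 0 else clean + rng.normal(0, noise_sigma, clean.shape)
    img = np.clip(img, 0, 255)
    return (
        MRImage(img, metadata={"source": "multiregion", "k": k, "seed": seed, "synthetic": True}),
        labels,
    )
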