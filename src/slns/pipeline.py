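"""End-to-end orchestration: denoise -> segment -> classify -> impact.

The pipeline ties the stages together the way the benchmark protocol runs
them: a brain mask from simple intensity morphology excludes background and
skull, HARIS segments the brain tissue, the recurrent classifier votes on
overlapping patches, segment-level fusion produces the tumor mask, and the
impact module reports the burden.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .denoise import DenoiseParams, denoise_image
from .fitness import SelfLearningMemory
from .haris import HarisConfig, run_haris
from .image import LabelMask, MRImage
from .impact import compute_report
from .phantom import PhantomSpec, generate_dataset
from .rnn import ClassifierConfig, RNNWeights, encode_patches, label_segments, probability_map, train_classifier

logger = logging.getLogger(__name__)

__all__ = ["brain_mask", "train_pipeline_classifier", "run_single"]

PATCH_SIZE = 12
TRAIN_STRIDE = 6
INFER_STRIDE = 4


def brain_mask(img: MRImage, floor: float = 30.0, erode: int = 10) -> np.ndarray:
    """Boolean brain-tissue mask from intensity morphology.

    Foreground above ``floor`` is hole-filled and eroded by ``erode`` pixels,
    which strips the skull ring and leaves the parenchyma (with tumor).
    """
    fg = img.data > floor
    filled = ndimage.binary_fill_holes(fg)
    return ndimage.binary_erosion(filled, iterations=erode) if erode else filled


def _mask_to_label(brain: np.ndarray) -> LabelMask:
    return LabelMask(np.where(brain, 2, 0).astype(np.int64))


def train_pipeline_classifier(
    spec: PhantomSpec,
    n_images: int = 12,
    jitter: float = 0.1,
    seed: int = 0,
    memory: SelfLearningMemory | None = None,
    cfg: ClassifierConfig | None = None,
    denoise_params: DenoiseParams | None = None,
) -> tuple[RNNWeights, SelfLearningMemory]:
    """Train the patch classifier on jittered phantoms with ground truth."""
    memory = memory or SelfLearningMemory()
    cfg = cfg or ClassifierConfig(seed=seed)
    patches = []
    for i, (img, mask) in enumerate(generate_dataset(spec, n_images, jitter=jitter, seed=seed)):
        den = denoise_image(img, denoise_params)
        patches += encode_patches(
            den, mask, patch_size=PATCH_SIZE, stride=TRAIN_STRIDE, seed=seed + i, balanced=True
        )
    logger.info("training classifier on %d balanced patches", len(patches))
    weights, memory, _trace = train_classifier(patches, cfg, memory)
    return weights, memory


def run_single(
    img: MRImage,
    weights: RNNWeights,
    memory: SelfLearningMemory | None = None,
    haris_cfg: HarisConfig | None = None,
    denoise_params: DenoiseParams | None = None,
    seed: int = 0,
) -> dict:
    """Process one slice; returns segmentation, probability map, tumor mask
    and impact report in a dict."""
    den = denoise_image(img, denoise_params)
    brain = brain_mask(den)
    if not brain.any():
        raise ValueError("brain mask is empty; check intensity floor")
    seg = run_haris(den, haris_cfg or HarisConfig(seed=seed), exclude_mask=~brain)
    prob = probability_map(
        den, weights, patch_size=PATCH_SIZE, stride=INFER_STRIDE, mask=_mask_to_label(brain)
    )
    tumor = label_segments(seg.labels, prob, threshold=0.5)
    report = compute_report(np.where(tumor, prob, 0.0), den, seed=seed)
    return {
        "denoised": den,
        "segmentation": seg,
        "probability": prob,
        "tumor_mask": tumor,
        "report": report,
    }
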