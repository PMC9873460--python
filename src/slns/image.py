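"""Core in-memory containers shared by every stage of the toolkit.

Images are 2-D ``float64`` grids on the 8-bit intensity scale [0, 255],
row-major with 0-based ``(row, col)`` coordinates.  Label masks use a fixed
five-value legend covering background, skull/non-brain, brain parenchyma,
tumor core and the enhancing rim around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MRImage",
    "LabelMask",
    "LEGEND",
    "TUMOR_LABELS",
    "ConfigurationError",
]

#: Fixed label legend used everywhere in the package.
LEGEND: dict[int, str] = {
    0: "background",
    1: "skull",
    2: "brain",
    3: "core",
    4: "rim",
}

#: Labels that together make up the whole tumor.
TUMOR_LABELS: tuple[int, int] = (3, 4)


class ConfigurationError(ValueError):
    """Raised when a spec/config violates its geometric or numeric invariants."""


@dataclass
class MRImage:
    """A single 2-D grayscale MRI slice.

    Parameters
    ----------
    data
        2-D float array of intensities in [0, 255].
    metadata
        Free-form provenance (seed, noise model, synthetic flag, ...).
    """

    data: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"MRImage expects a 2-D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MRImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """Integer label grid with the fixed :data:`LEGEND`."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integer-valued")
        extra = set(np.unique(self.labels)) - set(self.legend)
        if extra:
            raise ValueError(f"labels outside legend: {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region(self, *labels: int) -> np.ndarray:
        """Boolean mask of the union of the given labels."""
        return np.isin(self.labels, labels)

    @property
    def whole_tumor(self) -> np.ndarray:
        return self.region(*TUMOR_LABELS)

    @property
    def brain(self) -> np.ndarray:
        """Brain tissue including tumor (everything except background/skull)."""
        return self.region(2, 3, 4)
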