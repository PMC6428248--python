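"""Shared voxel-lattice containers: duration-preference label maps.

A :class:`LabelMap` is the common currency of the topography metrics: a
lattice of per-voxel preferred durations (seconds; NaN where the voxel is
unlabeled) together with the statistic that produced each label (a GLM
t-value or a pRF goodness of fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabelMap:
    label: np.ndarray          # preferred duration (s) per voxel, NaN = unlabeled
    stat: np.ndarray           # winning statistic per voxel (t or R^2)
    source: str = "glm"        # {"glm", "prf"}
    voxel_size: float = 1.0    # mm, isotropic

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=float)
        self.stat = np.asarray(self.stat, dtype=float)
        if self.label.shape != self.stat.shape:
            raise ValueError("label and stat shapes differ")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label.shape

    @property
    def labeled(self) -> np.ndarray:
        """Boolean mask of labeled voxels."""
        return np.isfinite(self.label)

    def present_labels(self) -> np.ndarray:
        """Sorted unique durations present in the map."""
        return np.unique(self.label[self.labeled])

    def count(self, label: float) -> int:
        return int(np.sum(self.mask_of(label)))

    def mask_of(self, label: float) -> np.ndarray:
        return self.labeled & np.isclose(self.label, label)
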