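"""CT intensity thresholding into the 3-class training labels.

Segmenting background, soft tissue and bone in CT is straightforward by
Hounsfield-unit thresholding: air sits at -1,000 HU, water at 0 HU and
cortical bone between +700 and +3,000 HU. The default cutpoints are
-400 HU (air/soft) and +100 HU (soft/bone); +100 HU matches the usual
upper bound for non-contrast soft tissue. Both are configurable — no
downstream result should depend on their precise values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import AIR, BONE, SOFT, ScalarVolume

__all__ = ["HuThresholds", "label_ct"]


@dataclass(frozen=True)
class HuThresholds:
    """HU cutpoints; a voxel exactly at a cutpoint goes to the denser class."""

    air_upper: float = -400.0
    bone_lower: float = 100.0

    def __post_init__(self) -> None:
        if not self.air_upper < self.bone_lower:
            raise ValueError(
                f"need air_upper < bone_lower, got ({self.air_upper}, {self.bone_lower})"
            )


def label_ct(ct: ScalarVolume, thr: HuThresholds | None = None) -> ScalarVolume:
    """Partition a CT volume: HU <= air_upper -> air, HU >= bone_lower ->
    bone, everything between -> soft tissue."""
    thr = thr or HuThresholds()
    hu = ct.values
    labels = np.full(hu.shape, SOFT, dtype=np.int16)
    labels[hu <= thr.air_upper] = AIR
    labels[hu >= thr.bone_lower] = BONE
    return ScalarVolume(ct.grid, labels, "label")
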