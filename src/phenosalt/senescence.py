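"""Senescent shoot area from top-view fluorescence images.

Healthy tissue fluoresces red (chlorophyll), senescent tissue yellow; the
same nearest-neighbour colour classifier used for RGB segmentation splits
the shoot into the two tissue classes, and senescence is reported as the
percentage of senescent pixels relative to the total shoot area of the
top-view image (healthy + senescent pixels of that image — not the RGB
projected shoot area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import LabelMask, NearestColorClassifier, _open_binary

__all__ = ["SenescenceResult", "classify_fluor", "senescence_fraction",
           "FLUOR_CLASSES"]

FLUOR_CLASSES = ("background", "healthy", "senescent")


@dataclass(frozen=True)
class SenescenceResult:
    """Pixel bookkeeping for one fluorescence image.

    ``senescent_percent`` is None (flagged, not 0) when the image contains
    no plant pixels at all.
    """

    healthy_px: int
    senescent_px: int
    senescent_percent: float | None

    @property
    def plant_px(self) -> int:
        return self.healthy_px + self.senescent_px


def classify_fluor(
    image: np.ndarray,
    clf: NearestColorClassifier,
    cleanup: bool = True,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    min_size: int = 50,
) -> LabelMask:
    """Three-class (background/healthy/senescent) fluorescence mask.

    Morphological cleanup follows the shoot-object-first order: the plant
    union (healthy + senescent) is opened and size-filtered as one object,
    removed pixels are relabelled background, and the surviving pixels keep
    their tissue class. Cleaning the union rather than each tissue class
    separately leaves the internal healthy/senescent boundary untouched,
    so the senescent fraction is not biased by the noise-removal step.
    Pass ``cleanup=False`` for the raw classification.
    """
    required = {"healthy", "senescent", "background"}
    missing = required - set(clf.priority_)
    if missing:
        raise ValueError(f"classifier lacks required classes: {sorted(missing)}")
    mask = clf.predict_image(image)
    if not cleanup:
        return mask
    union = mask.class_mask("healthy") | mask.class_mask("senescent")
    cleaned = _open_binary(union, erosion_radius, dilation_radius) & union
    if min_size > 0:
        comp, n = ndimage.label(cleaned, structure=np.ones((3, 3), bool))
        if n:
            sizes = np.bincount(comp.ravel())
            small = sizes < min_size
            small[0] = False
            cleaned[small[comp]] = False
    labels = mask.labels.copy()
    labels[union & ~cleaned] = mask.class_index("background")
    return LabelMask(labels, mask.classes)


def senescence_fraction(mask: LabelMask) -> SenescenceResult:
    """Senescent percentage of total top-view shoot area."""
    counts = mask.counts()
    healthy = counts.get("healthy", 0)
    senescent = counts.get("senescent", 0)
    total = healthy + senescent
    percent = 100.0 * senescent / total if total > 0 else None
    return SenescenceResult(healthy, senescent, percent)
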