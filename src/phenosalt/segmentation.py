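"""Plant/background separation in RGB images.

The measurement chain mirrors a standard phenomics image pipeline: each
pixel is assigned a class by 1-nearest-neighbour colour classification
against a small set of labelled reference colours, noise is removed by a
morphological opening plus a connected-component size filter, and every
surviving plant component is composed into a single object whose pixel
area and bounding-box height are the measured quantities.

The classifier is a scikit-learn estimator operating on pixels as samples
(n x 3 uint8 RGB rows); :func:`classify_pixels` applies it to whole images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LabelMask",
    "PlantObject",
    "NearestColorClassifier",
    "train_color_classifier",
    "classify_pixels",
    "clean_mask",
    "compose_plant_object",
]

# Pixel chunk size for the vectorised distance computation; bounds peak
# memory at chunk * n_samples int64 entries.
_CHUNK = 1 << 16


@dataclass(frozen=True)
class LabelMask:
    """A per-pixel class assignment for one image.

    ``labels`` holds integer indices into ``classes`` (tie-priority order,
    background first by default), same shape as the source image plane.
    """

    labels: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label array must be 2-D (rows x cols)")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.classes)
        ):
            raise ValueError("labels outside the declared class set")

    def class_index(self, name: str) -> int:
        return self.classes.index(name)

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of pixels assigned to class ``name``."""
        return self.labels == self.class_index(name)

    def counts(self) -> dict[str, int]:
        n = np.bincount(self.labels.ravel(), minlength=len(self.classes))
        return {c: int(n[i]) for i, c in enumerate(self.classes)}


@dataclass(frozen=True)
class PlantObject:
    """All plant pixels of a cleaned mask composed into one object.

    ``height_px`` is the row span of the union bounding box; an image with
    no plant pixels yields a valid empty object (``pixel_count == 0``),
    never an exception.
    """

    pixel_count: int
    bounding_box: tuple[int, int, int, int] | None
    height_px: int
    component_count_before_compose: int

    @property
    def is_empty(self) -> bool:
        return self.pixel_count == 0


def _as_rgb_samples(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of RGB triples")
    if X.size and (X.min() < 0 or X.max() > 255):
        raise ValueError("channel values must lie in [0, 255]")
    return X.astype(np.int64)


class NearestColorClassifier(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbour colour classifier with a deterministic tie rule.

    A query pixel receives the class of its nearest training colour under
    Euclidean distance in RGB. Squared distances are computed in exact
    integer arithmetic, so ties are well defined; an exact tie between
    samples of different classes is resolved in favour of the class listed
    first in ``tie_priority`` (by default the background class, then the
    remaining classes in order of first appearance during :meth:`fit`).

    Parameters
    ----------
    tie_priority : sequence of str, optional
        Explicit class ordering used both for tie resolution and for the
        index order of classes in emitted label masks.
    background_label : str
        Class pushed to the front of the default priority when
        ``tie_priority`` is not given.
    """

    def __init__(
        self,
        tie_priority: Sequence[str] | None = None,
        background_label: str = "background",
    ) -> None:
        self.tie_priority = tie_priority
        self.background_label = background_label

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "NearestColorClassifier":
        X = _as_rgb_samples(X)
        y = np.asarray(list(y), dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("at least one training colour is required")

        # Reject conflicting duplicates, drop redundant ones.
        seen: dict[tuple[int, int, int], str] = {}
        keep: list[int] = []
        for i, (rgb, lab) in enumerate(zip(map(tuple, X), y)):
            if rgb in seen:
                if seen[rgb] != lab:
                    raise ValueError(
                        f"colour {rgb} mapped to both {seen[rgb]!r} and {lab!r}"
                    )
                continue
            seen[rgb] = lab
            keep.append(i)
        X, y = X[keep], y[keep]

        first_seen: list[str] = []
        for lab in y:
            if lab not in first_seen:
                first_seen.append(lab)
        if self.tie_priority is not None:
            priority = list(self.tie_priority)
            missing = set(first_seen) - set(priority)
            if missing:
                raise ValueError(f"tie_priority omits classes: {sorted(missing)}")
        else:
            priority = sorted(
                first_seen,
                key=lambda c: (c != self.background_label, first_seen.index(c)),
            )
        # classes ordered by tie priority; every declared class has >=1 sample
        self.priority_ = tuple(c for c in priority if c in first_seen)
        self.classes_ = np.asarray(self.priority_, dtype=object)
        rank = {c: i for i, c in enumerate(self.priority_)}
        self.samples_ = X
        self.sample_class_idx_ = np.asarray([rank[c] for c in y], dtype=np.int64)
        return self

    def _decide(self, X: np.ndarray) -> np.ndarray:
        """Class index (priority order) per query row."""
        n_classes = len(self.priority_)
        out = np.empty(len(X), dtype=np.int64)
        for start in range(0, len(X), _CHUNK):
            block = X[start : start + _CHUNK]
            d2 = ((block[:, None, :] - self.samples_[None, :, :]) ** 2).sum(axis=2)
            # lexicographic (distance, class priority) via integer packing;
            # d2 <= 3*255^2 so the packed key fits comfortably in int64
            key = d2 * n_classes + self.sample_class_idx_[None, :]
            out[start : start + len(block)] = self.sample_class_idx_[
                np.argmin(key, axis=1)
            ]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "samples_")
        X = _as_rgb_samples(X)
        return self.classes_[self._decide(X)]

    def predict_image(self, image: np.ndarray) -> LabelMask:
        """Classify every pixel of an (rows, cols, 3) image."""
        check_is_fitted(self, "samples_")
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an (rows, cols, 3) image")
        flat = _as_rgb_samples(image.reshape(-1, 3))
        idx = self._decide(flat)
        return LabelMask(idx.reshape(image.shape[:2]), self.priority_)


def train_color_classifier(
    samples: Iterable[tuple[Sequence[int], str]],
    tie_priority: Sequence[str] | None = None,
) -> NearestColorClassifier:
    """Fit a :class:`NearestColorClassifier` from (RGB, label) pairs."""
    pairs = list(samples)
    if not pairs:
        raise ValueError("no training samples given")
    X = np.asarray([p[0] for p in pairs])
    y = [p[1] for p in pairs]
    return NearestColorClassifier(tie_priority=tie_priority).fit(X, y)


def classify_pixels(image: np.ndarray, clf: NearestColorClassifier) -> LabelMask:
    """Label every pixel of ``image`` with its nearest reference colour class."""
    return clf.predict_image(image)


def _open_binary(mask: np.ndarray, erosion_radius: int, dilation_radius: int) -> np.ndarray:
    out = mask
    if erosion_radius > 0:
        out = ndimage.binary_erosion(out, structure=disk(erosion_radius), border_value=0)
    if dilation_radius > 0:
        out = ndimage.binary_dilation(out, structure=disk(dilation_radius), border_value=0)
    return out


def clean_mask(
    mask: LabelMask,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    min_size: int = 50,
    plant_classes: Sequence[str] = ("plant",),
    background_label: str = "background",
    connectivity: int = 2,
) -> LabelMask:
    """Remove classification noise from the plant class(es).

    Each plant class is eroded then dilated (a morphological opening with a
    disk structuring element; pixels outside the image count as background),
    and connected plant components smaller than ``min_size`` pixels are
    dropped. Removed pixels are relabelled as background. With zero radii
    and ``min_size=0`` this is the identity. Dilation may only reclaim
    pixels that are currently background, so distinct plant classes never
    overwrite each other.
    """
    if erosion_radius < 0 or dilation_radius < 0 or min_size < 0:
        raise ValueError("radii and min_size must be non-negative")
    labels = mask.labels.copy()
    bg = mask.class_index(background_label)
    structure = np.ones((3, 3), bool) if connectivity == 2 else ndimage.generate_binary_structure(2, 1)

    for cls in plant_classes:
        idx = mask.class_index(cls)
        binary = labels == idx
        # only background pixels may be converted into plant by the dilation
        cleaned = _open_binary(binary, erosion_radius, dilation_radius) & (
            binary | (labels == bg)
        )
        if min_size > 0:
            comp, n = ndimage.label(cleaned, structure=structure)
            if n:
                sizes = np.bincount(comp.ravel())
                small = sizes < min_size
                small[0] = False
                cleaned[small[comp]] = False
        labels[binary & ~cleaned] = bg
        labels[cleaned] = idx
    return LabelMask(labels, mask.classes)


def compose_plant_object(
    mask: LabelMask,
    plant_classes: Sequence[str] = ("plant",),
    connectivity: int = 2,
) -> PlantObject:
    """Compose all remaining plant components into a single measured object."""
    union = np.zeros(mask.labels.shape, bool)
    for cls in plant_classes:
        union |= mask.class_mask(cls)
    structure = np.ones((3, 3), bool) if connectivity == 2 else ndimage.generate_binary_structure(2, 1)
    _, n_components = ndimage.label(union, structure=structure)
    count = int(union.sum())
    if count == 0:
        return PlantObject(0, None, 0, 0)
    rows, cols = np.nonzero(union)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
    height = bbox[2] - bbox[0] + 1
    return PlantObject(count, bbox, height, int(n_components))
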