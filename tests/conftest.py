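import numpy as np
import pytest

import phenosalt as ps
from phenosalt.cli import default_fluor_reference, default_rgb_reference
from phenosalt.synthetic import SyntheticPlantSpec


@pytest.fixture(scope="session")
def rgb_classifier():
    """Classifier trained on the default RGB scene palette."""
    return ps.train_color_classifier(default_rgb_reference(SyntheticPlantSpec()))


@pytest.fixture(scope="session")
def fluor_classifier():
    """Classifier for fluorescence images (background/healthy/senescent)."""
    return ps.train_color_classifier(default_fluor_reference(SyntheticPlantSpec()))


def nn_oracle(image, samples, labels, priority):
    """Brute-force per-pixel 1-NN with (distance, priority) tie rule.

    Independent of the package implementation: plain python loops over
    pixels and training samples, exact integer arithmetic.
    """
    rank = {lab: i for i, lab in enumerate(priority)}
    rows, cols = image.shape[:2]
    out = np.empty((rows, cols), dtype=object)
    for r in range(rows):
        for c in range(cols):
            px = [int(v) for v in image[r, c]]
            best = None
            for (sr, sg, sb), lab in zip(samples, labels):
                d2 = (px[0] - sr) ** 2 + (px[1] - sg) ** 2 + (px[2] - sb) ** 2
                key = (d2, rank[lab])
                if best is None or key < best[0]:
                    best = (key, lab)
            out[r, c] = best[1]
    return out


def erosion_oracle(mask, structure):
    """Brute-force binary erosion; pixels outside the image count as empty."""
    rows, cols = mask.shape
    sr, sc = structure.shape
    orr, occ = sr // 2, sc // 2
    out = np.zeros_like(mask)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr in range(sr):
                for dc in range(sc):
                    if not structure[dr, dc]:
                        continue
                    rr, cc = r + dr - orr, c + dc - occ
                    if not (0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]):
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def dilation_oracle(mask, structure):
    rows, cols = mask.shape
    sr, sc = structure.shape
    orr, occ = sr // 2, sc // 2
    out = np.zeros_like(mask)
    for r in range(rows):
        for c in range(cols):
            hit = False
            for dr in range(sr):
                for dc in range(sc):
                    if not structure[dr, dc]:
                        continue
                    rr, cc = r - (dr - orr), c - (dc - occ)
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                        hit = True
                        break
                if hit:
                    break
            out[r, c] = hit
    return out
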