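"""Synthetic imaging and growth data with known ground truth.

Everything downstream of image capture is testable against these
generators: they render rice-like shoots (green strokes over a blue-pellet
/ white-pot / grey-frame background, matching the imaging setup the
pipeline targets), top-view steady-state fluorescence images (red healthy
tissue, yellow senescent tissue on a dark background), exponential growth
trajectories with a salt-dose-dependent growth-rate penalty that starts
only after a lag phase, and replicate leaf ion tables.

Colour palettes are chosen to be class-separable under the default image
noise, not to match any particular camera. Growth defaults encode the
observed dynamics for rice under salinity: no growth penalty during the
first ten days after salt application (the osmotic window), then a
dose-proportional reduction of relative growth rate, with senescence
accruing only above a dose threshold.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.morphology import disk

__all__ = [
    "SyntheticPlantSpec",
    "SyntheticGrowthParams",
    "DEFAULT_CULTIVAR_PARAMS",
    "make_leaf_geometry",
    "random_plant_spec",
    "render_rgb_views",
    "render_fluor_image",
    "simulate_growth",
    "simulate_ion_table",
]

RGB = tuple[int, int, int]

# Default palette: separable classes, loosely matching the physical scene
# (blue pellets on the soil, white pot, grey imaging frame).
PLANT_GREEN: RGB = (30, 160, 40)
PELLET_BLUE: RGB = (40, 60, 200)
POT_WHITE: RGB = (245, 245, 245)
FRAME_GREY: RGB = (128, 128, 128)
HEALTHY_RED: RGB = (200, 30, 30)
SENESCENT_YELLOW: RGB = (220, 210, 40)
FLUOR_BACKGROUND: RGB = (10, 10, 16)


def _check_color(c: Sequence[int], name: str) -> RGB:
    c = tuple(int(v) for v in c)
    if len(c) != 3 or any(v < 0 or v > 255 for v in c):
        raise ValueError(f"{name} must be an 8-bit RGB triple, got {c}")
    return c  # type: ignore[return-value]


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Geometry, palette and noise model for one synthetic plant.

    ``leaf_geometry`` is a list of ``(polyline, width)`` strokes in the
    side-view plane, each polyline an (n, 2) array of (row, col) vertices.
    ``seed`` drives only the pixel noise: two specs differing only in seed
    render identical ground-truth masks under different noise fields.
    """

    image_size: tuple[int, int] = (150, 200)
    n_leaves: int = 5
    leaf_geometry: tuple[tuple[np.ndarray, int], ...] = ()
    plant_color: RGB = PLANT_GREEN
    pellet_color: RGB = PELLET_BLUE
    pot_color: RGB = POT_WHITE
    frame_color: RGB = FRAME_GREY
    healthy_color: RGB = HEALTHY_RED
    senescent_color: RGB = SENESCENT_YELLOW
    fluor_background_color: RGB = FLUOR_BACKGROUND
    noise_sd: float = 8.0
    senescent_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 1 or cols < 1:
            raise ValueError("image_size must be positive")
        if not 0.0 <= self.senescent_fraction <= 1.0:
            raise ValueError("senescent_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in (
            "plant_color", "pellet_color", "pot_color", "frame_color",
            "healthy_color", "senescent_color", "fluor_background_color",
        ):
            _check_color(getattr(self, name), name)
        for poly, width in self.leaf_geometry:
            pts = np.asarray(poly)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise ValueError("each stroke needs >=2 (row, col) vertices")
            if width < 1:
                raise ValueError("stroke width must be >=1 px")
            if np.all(pts == pts[0]):
                raise ValueError("degenerate zero-length stroke")


def make_leaf_geometry(
    rng: np.random.Generator,
    n_leaves: int,
    image_size: tuple[int, int],
    width: int = 3,
    margin: int = 6,
) -> tuple[tuple[np.ndarray, int], ...]:
    """Draw ``n_leaves`` arching strokes from a basal crown point.

    The margin keeps strokes clear of the image border so morphological
    cleanup has no edge effects; width 3 (a line dilated by a unit disk)
    makes every stroke invariant under the default radius-1 opening.
    """
    rows, cols = image_size
    base = np.array([rows - margin - rows // 6, cols // 2])
    strokes = []
    for _ in range(n_leaves):
        angle = rng.uniform(-1.1, 1.1)  # rad from vertical
        length = rng.uniform(0.45, 0.8) * (rows - 2 * margin)
        tip = base + length * np.array([-np.cos(angle), np.sin(angle)])
        mid = 0.5 * (base + tip) + rng.normal(0, 3, 2)
        pts = np.stack([base, mid, tip])
        pts[:, 0] = np.clip(pts[:, 0], margin, rows - 1 - margin)
        pts[:, 1] = np.clip(pts[:, 1], margin, cols - 1 - margin)
        strokes.append((np.round(pts).astype(int), width))
    return tuple(strokes)


def random_plant_spec(
    geometry_seed: int,
    n_leaves: int = 5,
    image_size: tuple[int, int] = (150, 200),
    noise_sd: float = 8.0,
    senescent_fraction: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SyntheticPlantSpec:
    """Convenience constructor with randomised leaf geometry."""
    rng = np.random.default_rng(geometry_seed)
    geom = make_leaf_geometry(rng, n_leaves, image_size)
    return SyntheticPlantSpec(
        image_size=image_size,
        n_leaves=n_leaves,
        leaf_geometry=geom,
        noise_sd=noise_sd,
        senescent_fraction=senescent_fraction,
        seed=seed,
        **overrides,
    )


def _rasterise_strokes(
    strokes: Sequence[tuple[np.ndarray, int]], shape: tuple[int, int]
) -> np.ndarray:
    mask = np.zeros(shape, bool)
    for poly, width in strokes:
        pts = np.asarray(poly, int)
        stroke = np.zeros(shape, bool)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            stroke[rr[keep], cc[keep]] = True
        radius = (width - 1) // 2
        if radius > 0:
            stroke = ndimage.binary_dilation(stroke, structure=disk(radius))
        mask |= stroke
    return mask


def _side_background(spec: SyntheticPlantSpec) -> np.ndarray:
    rows, cols = spec.image_size
    img = np.empty((rows, cols, 3), np.uint8)
    img[:] = spec.frame_color
    pot_top = rows - max(rows // 5, 1)
    half = max(cols // 3, 1)
    c0, c1 = cols // 2 - half, cols // 2 + half
    img[pot_top:, c0:c1] = spec.pot_color
    pellet_rows = max(rows // 40, 1)
    img[pot_top : pot_top + pellet_rows, c0:c1] = spec.pellet_color
    return img


def _top_background(
    spec: SyntheticPlantSpec,
    base: RGB | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    rows, cols = shape if shape is not None else spec.image_size
    img = np.empty((rows, cols, 3), np.uint8)
    img[:] = base if base is not None else spec.frame_color
    rr, cc = np.mgrid[0:rows, 0:cols]
    r2 = (rr - rows / 2) ** 2 + (cc - cols / 2) ** 2
    if base is None:
        img[r2 <= (0.45 * min(rows, cols)) ** 2] = spec.pot_color
        img[r2 <= (0.38 * min(rows, cols)) ** 2] = spec.pellet_color
    return img


def _add_noise(img: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return img.copy()
    noisy = img.astype(np.float64) + rng.normal(0.0, sd, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _view_masks(spec: SyntheticPlantSpec) -> dict[str, np.ndarray]:
    shape = spec.image_size
    side1 = _rasterise_strokes(spec.leaf_geometry, shape)
    side2 = side1[:, ::-1].copy()  # orthogonal view approximated by mirroring
    # the top camera sees the side-plane strokes rotated into the pot plane:
    # coordinates transpose, so the top canvas has the transposed shape
    top_strokes = tuple(
        (np.asarray(poly)[:, ::-1], w) for poly, w in spec.leaf_geometry
    )
    top = _rasterise_strokes(top_strokes, (shape[1], shape[0]))
    return {"side1": side1, "side2": side2, "top": top}


def _empty_view_masks(spec: SyntheticPlantSpec) -> dict[str, np.ndarray]:
    rows, cols = spec.image_size
    return {
        "side1": np.zeros((rows, cols), bool),
        "side2": np.zeros((rows, cols), bool),
        "top": np.zeros((cols, rows), bool),
    }


def render_rgb_views(
    spec: SyntheticPlantSpec,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Render side1/side2/top RGB images plus exact ground-truth masks.

    At ``noise_sd=0`` the set of pixels carrying ``plant_color`` equals the
    returned boolean mask exactly, per view.
    """
    spec.validate()
    if spec.n_leaves > 0 and not spec.leaf_geometry:
        raise ValueError("n_leaves > 0 requires leaf_geometry (see random_plant_spec)")
    masks = _view_masks(spec) if spec.leaf_geometry else _empty_view_masks(spec)
    rng = np.random.default_rng(spec.seed)
    images = {}
    for view in ("side1", "side2", "top"):
        bg = (
            _side_background(spec)
            if view.startswith("side")
            else _top_background(spec, shape=masks["top"].shape)
        )
        bg[masks[view]] = spec.plant_color
        images[view] = _add_noise(bg, spec.noise_sd, rng)
    return images, masks


def _senescent_patch(plant: np.ndarray, target: int) -> np.ndarray:
    """Best-first region growth from the most distal plant pixel.

    Produces one contiguous patch biased toward leaf tips (largest distance
    from the plant centroid), emulating tip-first senescence. Deterministic:
    ties break on (row, col).
    """
    out = np.zeros_like(plant)
    if target <= 0:
        return out
    rows, cols = np.nonzero(plant)
    centroid = np.array([rows.mean(), cols.mean()])
    score = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
    dist = np.full(plant.shape, -1.0)
    dist[rows, cols] = score
    start = np.argmax(score)
    heap = [(-score[start], int(rows[start]), int(cols[start]))]
    visited = np.zeros_like(plant)
    visited[rows[start], cols[start]] = True
    taken = 0
    while heap and taken < target:
        _, r, c = heapq.heappop(heap)
        out[r, c] = True
        taken += 1
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < plant.shape[0]
                    and 0 <= cc < plant.shape[1]
                    and plant[rr, cc]
                    and not visited[rr, cc]
                ):
                    visited[rr, cc] = True
                    heapq.heappush(heap, (-dist[rr, cc], rr, cc))
    # disconnected leftovers (multiple blades): restart from the next tip
    if taken < target:
        remaining = plant & ~out
        if remaining.any():
            out |= _senescent_patch(remaining, target - taken)
    return out


def render_fluor_image(
    spec: SyntheticPlantSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the top-view fluorescence image and healthy/senescent masks.

    A fraction ``spec.senescent_fraction`` of the plant pixels (rounded to
    the nearest pixel; the remainder stays healthy) is rendered in the
    senescent colour as contiguous tip patches; the rest takes the healthy
    colour. Returns ``(image, healthy_mask, senescent_mask)``.
    """
    spec.validate()
    if spec.n_leaves > 0 and not spec.leaf_geometry:
        raise ValueError("n_leaves > 0 requires leaf_geometry (see random_plant_spec)")
    plant = (
        _view_masks(spec)["top"]
        if spec.leaf_geometry
        else _empty_view_masks(spec)["top"]
    )
    rng = np.random.default_rng(spec.seed)
    n_plant = int(plant.sum())
    target = int(round(spec.senescent_fraction * n_plant))
    senescent = _senescent_patch(plant, target) if n_plant else np.zeros_like(plant)
    healthy = plant & ~senescent
    img = _top_background(spec, base=spec.fluor_background_color, shape=plant.shape)
    img[healthy] = spec.healthy_color
    img[senescent] = spec.senescent_color
    return _add_noise(img, spec.noise_sd, rng), healthy, senescent


@dataclass(frozen=True)
class SyntheticGrowthParams:
    """Parameters of the lagged exponential growth model.

    Projected area grows as ``A0 * exp(r * t)`` with relative growth rate
    ``r = r_control`` until ``lag_days`` after salt application and
    ``r_control * (1 - penalty_per_mM * dose)`` afterwards. Observation
    noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` (mean one), so areas stay positive.
    """

    A0: float = 1000.0
    r_control: float = 0.1
    lag_days: float = 10.0
    penalty_per_mM: float = 0.0037
    senescence_onset_mM: float = 75.0
    noise_cv: float = 0.1
    seed: int = 0

    def validate(self, doses: Sequence[float] = ()) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if self.r_control <= 0:
            raise ValueError("r_control must be positive")
        if self.lag_days < 0:
            raise ValueError("lag_days must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for d in doses:
            if d < 0:
                raise ValueError("doses must be non-negative")
            if self.r_control * (1 - self.penalty_per_mM * d) < 0:
                raise ValueError(f"penalty yields negative growth rate at {d} mM")

    def effective_rate(self, dose_mM: float) -> float:
        return self.r_control * (1.0 - self.penalty_per_mM * dose_mM)

    def expected_area(self, dose_mM: float, day: float) -> float:
        """Noise-free area at ``day`` (days after salt application)."""
        pre = min(day, self.lag_days)
        post = max(0.0, day - self.lag_days)
        return self.A0 * np.exp(self.r_control * pre + self.effective_rate(dose_mM) * post)


def simulate_growth(
    params: SyntheticGrowthParams,
    doses: Sequence[float],
    days: Sequence[float],
    n_reps: int,
    cultivar: str = "synthA",
) -> pd.DataFrame:
    """Simulate per-replicate projected-area trajectories.

    Returns a tidy frame with columns plant_id, cultivar, dose_mM, day,
    area_px, truth_area_px.
    """
    days = list(days)
    if sorted(days) != days:
        raise ValueError("days must be sorted ascending")
    if 0 not in days:
        raise ValueError("days must include day 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >=1")
    params.validate(doses)
    rng = np.random.default_rng(params.seed)
    sigma = np.sqrt(np.log1p(params.noise_cv**2))
    rows = []
    for dose in doses:
        for rep in range(n_reps):
            pid = f"{cultivar}_d{dose:g}_r{rep + 1}"
            for day in days:
                truth = params.expected_area(dose, day)
                noise = (
                    np.exp(rng.normal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0
                )
                rows.append((pid, cultivar, dose, day, truth * noise, truth))
    return pd.DataFrame(
        rows,
        columns=["plant_id", "cultivar", "dose_mM", "day", "area_px", "truth_area_px"],
    )


#: Per-cultivar ion/senescence response defaults. Slopes and baselines are
#: set so that simulated tables reproduce the magnitudes reported for the
#: two rice cultivars the pipeline was developed on: the tissue-tolerant
#: cultivar accumulates more leaf Na+ yet senesces little (~4% at 200 mM),
#: the sensitive one less Na+ but heavy senescence (~23% at 200 mM).
DEFAULT_CULTIVAR_PARAMS: Mapping[str, Mapping[str, float]] = {
    "sensitive": dict(
        na_baseline_mM=1.5, na_slope_mM_per_mM=0.020, na_sd=0.4,
        k_baseline_mM=290.0, k_slope_mM_per_mM=0.50, k_sd=15.0,
        sens_onset_mM=75.0, sens_percent_per_mM=0.18, sens_sd=1.0,
        fresh_weight_g=0.5, dry_matter_fraction=0.2,
    ),
    "tolerant": dict(
        na_baseline_mM=2.5, na_slope_mM_per_mM=0.050, na_sd=0.5,
        k_baseline_mM=340.0, k_slope_mM_per_mM=0.40, k_sd=15.0,
        sens_onset_mM=75.0, sens_percent_per_mM=0.032, sens_sd=0.5,
        fresh_weight_g=0.5, dry_matter_fraction=0.2,
    ),
}


def simulate_ion_table(
    doses: Sequence[float],
    cultivar_params: Mapping[str, Mapping[str, float]] = DEFAULT_CULTIVAR_PARAMS,
    n_reps: int = 7,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate leaf Na+/K+ and senescence measurements.

    Na+ rises linearly with dose (per-cultivar slope); K+ rises mildly;
    senescence accrues above a dose threshold. Replicate noise is Gaussian,
    truncated so concentrations stay positive. K+/Na+ is computed per
    replicate (the convention used for reporting group means of ratios).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >=2 (replicate variance undefined)")
    for d in doses:
        if d < 0:
            raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for cultivar, p in cultivar_params.items():
        for dose in doses:
            na_mean = p["na_baseline_mM"] + p["na_slope_mM_per_mM"] * dose
            k_mean = p["k_baseline_mM"] + p["k_slope_mM_per_mM"] * dose
            sens_mean = max(0.0, dose - p["sens_onset_mM"]) * p["sens_percent_per_mM"]
            for rep in range(n_reps):
                na = max(1e-3, na_mean + rng.normal(0, p["na_sd"]))
                k = max(1e-3, k_mean + rng.normal(0, p["k_sd"]))
                sens = float(np.clip(sens_mean + rng.normal(0, p["sens_sd"]), 0, 100))
                fw = p["fresh_weight_g"]
                dw = fw * p["dry_matter_fraction"]
                rows.append(
                    (
                        f"{cultivar}_d{dose:g}_r{rep + 1}",
                        cultivar, dose, na, k, k / na, sens, fw, dw,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plant_id", "cultivar", "dose_mM", "na_mM", "k_mM",
            "k_na_ratio", "senescent_percent", "fresh_weight_g", "dry_weight_g",
        ],
    )
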