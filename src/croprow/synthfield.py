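"""Seeded synthetic field scenes: image, crop-row mask, and row ground truth.

The generator emulates the structure of early-season row-crop imagery as seen
from a field robot: several quasi-parallel plant rows (straight or gently
curved), individual plant canopies rendered as lobed blobs, missing seedlings
(gaps), scattered weed clutter, and an illumination gradient.  Weeds appear
in the *image only* — the mask foreground is exactly the union of crop
canopies, matching the labelling convention in which inter-plant soil and
weeds are background.

Geometry is image-plane only (no camera model).  The default pixel scale is
2 px/cm, so an agronomic 60 cm row spacing becomes the default 120 px and a
28 cm plant spacing becomes 56 px.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Scene palette (RGB in [0,1]).  Weeds are a paler, yellower green than crop
# canopies, as young broadleaf weeds typically read against maize seedlings.
_SOIL = np.array([0.44, 0.35, 0.23], dtype=np.float32)
_CROP = np.array([0.18, 0.46, 0.14], dtype=np.float32)
_WEED = np.array([0.47, 0.58, 0.24], dtype=np.float32)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Distances are in pixels at the generator's 2 px/cm default scale.
    ``row_curvature`` is the quadratic coefficient of the row centerline
    ``x(y) = x0 + slope*y + curvature*(y - H/2)^2``; zero means straight rows.
    """

    image_height: int = 512
    image_width: int = 512
    n_rows: int = 3
    row_spacing: float = 120.0
    row_curvature: float = 0.0
    row_slope_range: tuple[float, float] = (0.0, 0.0)
    plant_spacing: float = 56.0
    plant_radius_range: tuple[float, float] = (12.0, 20.0)
    gap_probability: float = 0.0
    weed_density: float = 5.0
    illumination_gradient: tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_rows < 0:
            raise ValueError("n_rows must be >= 0")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise ValueError("gap_probability must lie in [0, 1]")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class RowTruth:
    """Ground truth for one generated row.

    ``centerline`` holds normalised line coefficients (a, b, c) with
    a^2 + b^2 = 1 and a*x + b*y + c = 0 for straight rows; for curved rows it
    is a sampled (x, y) polyline and ``centerline_coeffs`` is None.
    """

    row_index: int
    centerline: tuple[float, float, float] | np.ndarray
    plant_centers: list[tuple[float, float]]
    gap_positions: list[tuple[float, float]]
    is_straight: bool

    def x_at(self, y: np.ndarray) -> np.ndarray:
        """Centerline x position at heights ``y``."""
        if self.is_straight:
            a, b, c = self.centerline
            return -(b * np.asarray(y, dtype=float) + c) / a
        poly = np.asarray(self.centerline)
        return np.interp(np.asarray(y, dtype=float), poly[:, 1], poly[:, 0])


@dataclass
class FieldScene:
    image: np.ndarray          # H x W x 3, float32 in [0,1]
    mask: np.ndarray           # H x W, uint8 {0,1}; 1 = crop row
    rows: list[RowTruth]
    config: SceneConfig
    row_labels: np.ndarray = field(default=None)  # H x W int16, 0 = background


def _lobed_blob(cx: float, cy: float, r0: float, rng: np.random.Generator,
                h: int, w: int) -> np.ndarray | None:
    """Rasterise a randomly perturbed lobed ellipse mimicking a leaf canopy.

    Radius as a function of polar angle is ``r0 * (1 + sum_k a_k cos(k t + phi_k))``
    with 3-6 lobes, so anchor-centroid extraction always faces non-circular
    shapes.  Returns a boolean H x W array, or None if fully off-image.
    """
    n_lobes = int(rng.integers(3, 7))
    amp = rng.uniform(0.10, 0.25)
    phase = rng.uniform(0, 2 * np.pi)
    stretch = rng.uniform(0.8, 1.25)  # mild anisotropy

    rmax = r0 * (1 + amp) * max(stretch, 1.0) + 1.0
    x0, x1 = int(np.floor(cx - rmax)), int(np.ceil(cx + rmax)) + 1
    y0, y1 = int(np.floor(cy - rmax)), int(np.ceil(cy + rmax)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = (xs - cx) / stretch
    dy = ys - cy
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = r0 * (1 + amp * np.cos(n_lobes * theta + phase))
    blob = np.zeros((h, w), dtype=bool)
    blob[y0:y1, x0:x1] = rr <= boundary
    return blob if blob.any() else None


def generate_scene(config: SceneConfig) -> FieldScene:
    """Render one seeded scene; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    mask = np.zeros((h, w), dtype=np.uint8)
    labels = np.zeros((h, w), dtype=np.int16)
    rows: list[RowTruth] = []

    x_center = (w - 1) / 2.0
    for i in range(config.n_rows):
        x0 = x_center + (i - (config.n_rows - 1) / 2.0) * config.row_spacing
        slope = rng.uniform(*config.row_slope_range)
        curv = config.row_curvature

        def row_x(y):
            return x0 + slope * y + curv * (np.asarray(y, dtype=float) - h / 2.0) ** 2

        straight = curv == 0.0
        if straight:
            # x - slope*y - x0 = 0, normalised
            norm = float(np.hypot(1.0, slope))
            centerline = (1.0 / norm, -slope / norm, -x0 / norm)
        else:
            ys = np.arange(0, h, 4.0)
            centerline = np.column_stack([row_x(ys), ys])

        plant_centers: list[tuple[float, float]] = []
        gap_positions: list[tuple[float, float]] = []
        margin = config.plant_radius_range[1]
        y = margin + rng.uniform(0, config.plant_spacing)
        while y < h - margin:
            cx, cy = float(row_x(y)), float(y)
            # draws below are consumed regardless of omission, so gap
            # patterns stay reproducible per seed
            r0 = rng.uniform(*config.plant_radius_range)
            omit = rng.uniform() < config.gap_probability
            if 0 <= cx < w:
                if omit:
                    gap_positions.append((cx, cy))
                else:
                    blob = _lobed_blob(cx, cy, r0, rng, h, w)
                    if blob is not None:
                        mask[blob] = 1
                        labels[blob] = i + 1
                    plant_centers.append((cx, cy))
            y += config.plant_spacing
        rows.append(RowTruth(row_index=i, centerline=centerline,
                             plant_centers=plant_centers,
                             gap_positions=gap_positions, is_straight=straight))

    # --- image: soil texture, crop canopies, weed clutter, illumination ---
    image = np.empty((h, w, 3), dtype=np.float32)
    soil_noise = rng.normal(0.0, 0.035, size=(h, w, 1)).astype(np.float32)
    image[:] = _SOIL + soil_noise

    n_weeds = rng.poisson(config.weed_density)
    for _ in range(n_weeds):
        wx = rng.uniform(0, w)
        wy = rng.uniform(0, h)
        wr = rng.uniform(3.0, 8.0)
        blob = _lobed_blob(wx, wy, wr, rng, h, w)
        if blob is not None:
            image[blob] = _WEED + rng.normal(0, 0.02, 3).astype(np.float32)

    fg = mask.astype(bool)
    crop_jitter = rng.normal(0.0, 0.03, size=(h, w, 1)).astype(np.float32)
    image[fg] = (_CROP + crop_jitter)[fg]

    g0, g1 = config.illumination_gradient
    gradient = np.linspace(g0, g1, w, dtype=np.float32)[None, :, None]
    image *= gradient
    np.clip(image, 0.0, 1.0, out=image)

    return FieldScene(image=image, mask=mask, rows=rows, config=config,
                      row_labels=labels)


def generate_batch(n: int, config: SceneConfig) -> list[FieldScene]:
    """Generate ``n`` scenes with seeds ``config.seed, seed+1, ...``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return [generate_scene(dataclasses.replace(config, seed=config.seed + i))
            for i in range(n)]


def save_scene(scene: FieldScene, out_dir: str | Path, index: int) -> None:
    """Write image_####.png, mask_####.png and truth_####.json."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img8 = (scene.image * 255).round().astype(np.uint8)
    Image.fromarray(img8).save(out / f"image_{index:04d}.png")
    Image.fromarray(scene.mask * 255).save(out / f"mask_{index:04d}.png")
    truth = {
        "config": dataclasses.asdict(scene.config),
        "rows": [
            {
                "row_index": r.row_index,
                "is_straight": r.is_straight,
                "centerline": (list(r.centerline) if r.is_straight
                               else np.asarray(r.centerline).tolist()),
                "plant_centers": [list(p) for p in r.plant_centers],
                "gap_positions": [list(p) for p in r.gap_positions],
            }
            for r in scene.rows
        ],
    }
    (out / f"truth_{index:04d}.json").write_text(json.dumps(truth, indent=1))
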