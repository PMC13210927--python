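"""Binary crop-row mask -> per-row navigation lines.

Pipeline: (1) foreground pixels are summarised per horizontal band by
connected-component centroids, and the centroid x-coordinates are clustered
with DBSCAN (eps 30 px, min_samples 5) into row instances; (2) each instance
mask is vertically closed to bridge inter-plant gaps; (3) anchor points are
sampled at equidistant heights as mask-moment centroids of the instance
slices; (4) heights with no foreground are repaired by copying the x of the
nearest detected anchor (up--down search, ties toward smaller y); (5) a
seeded RANSAC (K=100 iterations, inlier threshold T=5 px, minimum Min=10
inliers) fits a line a*x + b*y + c = 0 per instance, refit on its inliers by
total least squares; (6) a spatial-consistency filter drops inliers isolated
from the rest of the row by more than 3x the median inter-anchor gap.

Coordinates are 0-based image coordinates: x rightward, y downward.  Anchor
heights are the centers of ``n_anchor_rows`` equal-height bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Row-instance clustering and anchor-sampling parameters (pixels)."""

    eps: float = 30.0
    min_samples: int = 5
    n_bands: int = 20
    closing_height: int = 15
    n_anchor_rows: int = 10
    max_rows_kept: int = 3
    canny_sigma: float = 1.0
    min_anchor_support: int = 12  # px per band; smaller slices are treated
    #   as missing (a few edge pixels of a lobed canopy give wild centroids)

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.n_anchor_rows < 2:
            raise ValueError("n_anchor_rows must be >= 2")


@dataclass
class RowInstance:
    """One clustered crop-row instance."""

    instance_id: int
    pixels: np.ndarray            # (N, 2) array of (x, y), original mask pixels
    repaired_mask: np.ndarray     # H x W bool, after vertical closing
    edges: np.ndarray | None = None  # Canny boundary diagnostics

    @property
    def mean_x(self) -> float:
        return float(self.pixels[:, 0].mean())


@dataclass(frozen=True)
class AnchorPoint:
    x: float
    y: float
    row_id: int
    source: str  # "detected" | "repaired"


@dataclass(frozen=True)
class RansacConfig:
    """Two-point RANSAC parameters: K iterations, inlier threshold T (px),
    minimum inlier count Min."""

    max_iterations: int = 100
    inlier_threshold: float = 5.0
    min_inliers: int = 10

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be > 0")
        if self.min_inliers < 2:
            raise ValueError("min_inliers must be >= 2")


@dataclass
class LineModel:
    """Normalised line a*x + b*y + c = 0 with a^2 + b^2 = 1."""

    a: float
    b: float
    c: float
    inliers: list[AnchorPoint] = field(default_factory=list)

    @property
    def inlier_count(self) -> int:
        return len(self.inliers)

    def distance(self, x, y) -> np.ndarray:
        return np.abs(self.a * np.asarray(x, dtype=float)
                      + self.b * np.asarray(y, dtype=float) + self.c)

    def x_at(self, y) -> np.ndarray:
        if abs(self.a) < 1e-12:
            raise ValueError("horizontal line: x(y) undefined")
        return -(self.b * np.asarray(y, dtype=float) + self.c) / self.a


@dataclass
class NavigationLine:
    """A fitted row line with its positional label and provenance."""

    line: LineModel
    label: str                   # "left" | "middle" | "right"
    instance_id: int
    anchors: list[AnchorPoint] = field(default_factory=list)


def _normalize(a: float, b: float, c: float) -> tuple[float, float, float]:
    norm = float(np.hypot(a, b))
    if norm == 0:
        raise ValueError("degenerate line coefficients")
    a, b, c = a / norm, b / norm, c / norm
    if a < 0 or (a == 0 and b < 0):  # canonical sign
        a, b, c = -a, -b, -c
    return a, b, c


# ---------------------------------------------------------------------------
# 1. clustering
# ---------------------------------------------------------------------------

def cluster_rows(mask: np.ndarray, config: ClusterConfig = ClusterConfig()
                 ) -> list[RowInstance]:
    """Group mask foreground into row instances.

    Per horizontal band, connected components are reduced to centroid
    representatives; DBSCAN on the representatives' x-coordinates assigns
    instance identifiers (noise representatives are discarded); every
    component's pixels inherit its representative's instance.  Instance masks
    are then closed with a vertical structuring element to bridge gaps.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    h, w = m.shape
    band_edges = np.linspace(0, h, config.n_bands + 1).astype(int)

    reps_x: list[float] = []
    comp_pixels: list[np.ndarray] = []  # (N,2) (x, y) arrays per component
    for b0, b1 in zip(band_edges[:-1], band_edges[1:]):
        if b1 <= b0:
            continue
        band = m[b0:b1]
        labels, n = ndimage.label(band)
        if n == 0:
            continue
        for comp in range(1, n + 1):
            ys, xs = np.nonzero(labels == comp)
            reps_x.append(float(xs.mean()))
            comp_pixels.append(np.column_stack([xs, ys + b0]))

    x_arr = np.asarray(reps_x).reshape(-1, 1)
    labels = DBSCAN(eps=config.eps, min_samples=config.min_samples).fit_predict(x_arr)

    instances: list[RowInstance] = []
    struct = np.ones((max(config.closing_height, 1), 1), dtype=bool)
    for inst_id, cluster in enumerate(sorted(set(labels) - {-1})):
        members = [comp_pixels[i] for i in np.nonzero(labels == cluster)[0]]
        pixels = np.vstack(members)
        inst_mask = np.zeros((h, w), dtype=bool)
        inst_mask[pixels[:, 1], pixels[:, 0]] = True
        repaired = ndimage.binary_closing(inst_mask, structure=struct)
        edges = skfeature.canny(inst_mask.astype(float), sigma=config.canny_sigma)
        instances.append(RowInstance(instance_id=inst_id, pixels=pixels,
                                     repaired_mask=repaired, edges=edges))
    return instances


# ---------------------------------------------------------------------------
# 2. anchors
# ---------------------------------------------------------------------------

def anchor_heights(image_height: int, n_anchor_rows: int) -> np.ndarray:
    """Centers of the equidistant vertical sampling bands."""
    edges = np.linspace(0, image_height, n_anchor_rows + 1)
    return (edges[:-1] + edges[1:]) / 2.0


def extract_anchors(instance: RowInstance,
                    config: ClusterConfig = ClusterConfig()) -> list[AnchorPoint]:
    """Mask-moment centroid x at each equidistant height with foreground.

    The centroid uses the zeroth and first moments of the (repaired) instance
    mask restricted to the band; bands with no foreground (or with fewer than
    ``min_anchor_support`` pixels, which cannot carry a stable centroid)
    yield no detected anchor and are left to gap repair.
    """
    m = instance.repaired_mask
    h = m.shape[0]
    edges = np.linspace(0, h, config.n_anchor_rows + 1).astype(int)
    heights = anchor_heights(h, config.n_anchor_rows)
    anchors: list[AnchorPoint] = []
    for k, (b0, b1) in enumerate(zip(edges[:-1], edges[1:])):
        band = m[b0:b1]
        m00 = band.sum()
        if m00 == 0 or m00 < config.min_anchor_support:
            continue
        xs = np.nonzero(band)[1]
        anchors.append(AnchorPoint(x=float(xs.mean()), y=float(heights[k]),
                                   row_id=instance.instance_id,
                                   source="detected"))
    return anchors


def repair_anchors(anchors: list[AnchorPoint], instance: RowInstance,
                   config: ClusterConfig = ClusterConfig()
                   ) -> list[AnchorPoint]:
    """Fill missing heights from the nearest detected anchor in |dy|.

    The up--down search copies the nearest valid centroid x; equidistant
    candidates resolve toward the smaller y.  Returns exactly
    ``n_anchor_rows`` anchors ordered by y.
    """
    if not anchors:
        logger.warning("instance %d has no detected anchors; dropped",
                       instance.instance_id)
        raise ValueError("cannot repair an instance with zero detected anchors")
    heights = anchor_heights(instance.repaired_mask.shape[0],
                             config.n_anchor_rows)
    detected = {round(a.y, 6): a for a in anchors}
    det_sorted = sorted(anchors, key=lambda a: a.y)
    out: list[AnchorPoint] = []
    for y in heights:
        key = round(float(y), 6)
        if key in detected:
            out.append(detected[key])
            continue
        best = min(det_sorted, key=lambda a: (abs(a.y - y), a.y))
        out.append(AnchorPoint(x=best.x, y=float(y),
                               row_id=instance.instance_id, source="repaired"))
    return out


# ---------------------------------------------------------------------------
# 3. RANSAC
# ---------------------------------------------------------------------------

def _tls_fit(points: np.ndarray) -> tuple[float, float, float]:
    """Total-least-squares line through (x, y) points: the normal is the
    minor principal axis of the centred coordinates."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    a, b = vt[-1]  # normal direction = smallest singular vector
    c = -(a * centroid[0] + b * centroid[1])
    return _normalize(a, b, c)


def ransac_fit(anchors: list[AnchorPoint], config: RansacConfig = RansacConfig(),
               seed: int = 0) -> LineModel | None:
    """Seeded two-point RANSAC with TLS refit on the best inlier set.

    Returns None when no sampled model reaches ``min_inliers`` inliers.
    Duplicate (coincident) sampled points are redrawn without consuming the
    iteration's validity.
    """
    if len(anchors) < 2:
        raise ValueError("RANSAC needs at least 2 anchors")
    pts = np.array([[a.x, a.y] for a in anchors], dtype=float)
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = 0
    distinct = len(np.unique(pts, axis=0)) >= 2
    if not distinct:
        return None

    for _ in range(config.max_iterations):
        while True:
            i, j = rng.choice(len(pts), size=2, replace=False)
            p1, p2 = pts[i], pts[j]
            if not np.allclose(p1, p2):
                break
        dx, dy = p2 - p1
        try:
            a, b, c = _normalize(dy, -dx, dx * p1[1] - dy * p1[0])
        except ValueError:
            continue
        dist = np.abs(a * pts[:, 0] + b * pts[:, 1] + c)
        inliers = dist < config.inlier_threshold
        count = int(inliers.sum())
        if count > best_count and count >= config.min_inliers:
            best_count = count
            best_inliers = inliers

    if best_inliers is None:
        return None
    a, b, c = _tls_fit(pts[best_inliers])
    # inlier set re-audited against the refit line so the stored anchors
    # always satisfy the distance bound
    dist = np.abs(a * pts[:, 0] + b * pts[:, 1] + c)
    final = dist <= config.inlier_threshold
    if int(final.sum()) < 2:
        final = best_inliers
    return LineModel(a=a, b=b, c=c,
                     inliers=[anchors[k] for k in np.nonzero(final)[0]])


def consistency_filter(line: LineModel) -> LineModel:
    """Drop inliers spatially isolated along the line, then refit.

    Inliers are ordered by their projection on the line direction; a point
    whose gap to the previously retained point exceeds 3x the median
    inter-anchor gap is removed.  With fewer than 3 inliers there is no
    meaningful gap statistic and the line is returned unchanged.
    """
    if line.inlier_count < 3:
        return line
    pts = np.array([[p.x, p.y] for p in line.inliers], dtype=float)
    proj = -line.b * pts[:, 0] + line.a * pts[:, 1]  # along direction (-b, a)
    order = np.argsort(proj)
    proj_sorted = proj[order]
    gaps = np.diff(proj_sorted)
    med = float(np.median(gaps))
    if med <= 0:
        return line
    keep = [order[0]]
    last = proj_sorted[0]
    for idx, t in zip(order[1:], proj_sorted[1:]):
        if t - last <= 3.0 * med:  # gap to the previous retained point
            keep.append(idx)
            last = t
    if len(keep) == len(line.inliers) or len(keep) < 2:
        return line
    kept_anchors = [line.inliers[i] for i in sorted(keep)]
    a, b, c = _tls_fit(pts[sorted(keep)])
    return LineModel(a=a, b=b, c=c, inliers=kept_anchors)


# ---------------------------------------------------------------------------
# 4. full pipeline
# ---------------------------------------------------------------------------

def extract_navigation_lines(mask: np.ndarray,
                             cluster_config: ClusterConfig = ClusterConfig(),
                             ransac_config: RansacConfig = RansacConfig(),
                             seed: int = 0) -> list[NavigationLine]:
    """cluster -> anchors -> repair -> RANSAC -> consistency filter.

    Instances are ranked by mean x; the middle ``max_rows_kept`` receive
    positional labels left/middle/right (fewer instances keep a centred
    subset of those labels).
    """
    instances = cluster_rows(mask, cluster_config)
    fitted: list[tuple[RowInstance, LineModel, list[AnchorPoint]]] = []
    for inst in instances:
        detected = extract_anchors(inst, cluster_config)
        if not detected:
            logger.warning("instance %d produced no anchors; skipped",
                           inst.instance_id)
            continue
        anchors = repair_anchors(detected, inst, cluster_config)
        line = ransac_fit(anchors, ransac_config,
                          seed=seed + inst.instance_id)
        if line is None:
            logger.warning("instance %d: RANSAC found no consensus; skipped",
                           inst.instance_id)
            continue
        fitted.append((inst, consistency_filter(line), anchors))

    fitted.sort(key=lambda item: item[0].mean_x)
    k = min(cluster_config.max_rows_kept, len(fitted))
    start = (len(fitted) - k) // 2
    kept = fitted[start:start + k]
    labels = {1: ["middle"], 2: ["left", "right"],
              3: ["left", "middle", "right"]}.get(k, [str(i) for i in range(k)])
    return [NavigationLine(line=line, label=labels[i],
                           instance_id=inst.instance_id, anchors=anchors)
            for i, (inst, line, anchors) in enumerate(kept)]
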