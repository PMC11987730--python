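"""Image masking: enhancement, soma detection, dendrite masking, tracing.

The chain mirrors how cultured-neuron micrographs are quantified by the
microscope's masking workflow: the image is contrast-stretched and
sharpened, foreground is separated from background, cell bodies are
registered as circles, the remaining thin (< 0.06 mm wide) structures are
masked as dendrites, and the dendrite mask is skeletonized into traces
with physical lengths and soma attachments.

Interpretation of the 0.06 mm "threshold thickness": it is the *maximum*
local width for a structure to count as a dendrite — anything wider is a
body or debris and is excluded from the dendrite mask.  Local width is
estimated as twice the Euclidean distance-transform value, a standard
resolution-independent width estimator.

Coordinates: pixel indices are 0-based row-major; the physical position
of pixel (row, col) is its center, ((col + 0.5)·s, (row + 0.5)·s) with s
the pixel size.  All reported geometry is in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import unsharp_mask
from skimage.measure import label, regionprops
from skimage.morphology import thin

from .errors import (
    ConfigurationError,
    DegenerateThresholdError,
    ValidationError,
)
from .simulate import INTENSITY_RANGE

__all__ = [
    "EnhanceParams",
    "MaskingConfig",
    "SomaDetection",
    "DendriteTrace",
    "enhance",
    "segment_foreground",
    "detect_cell_bodies",
    "mask_dendrites",
    "trace_dendrites",
    "soma_detection_f1",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Percent contrast increase and percent sharpening."""

    contrast_pct: float = 30.0
    sharpen_pct: float = 45.0
    sharpen_radius_px: float = 1.0

    def __post_init__(self):
        if self.contrast_pct < 0 or self.sharpen_pct < 0:
            raise ValidationError("enhancement percentages must be >= 0")


@dataclass(frozen=True)
class MaskingConfig:
    """Thresholds of the masking chain, in physical units.

    ``pixel_size_um`` has no default on purpose: the physical pixel scale
    must always be supplied, never silently assumed.
    """

    pixel_size_um: float
    dendrite_width_threshold_mm: float = 0.06
    threshold_strategy: str = "otsu"  # or "fixed"
    fixed_threshold: Optional[float] = None
    soma_opening_radius_um: float = 4.0
    min_soma_area_um2: float = 40.0
    min_circularity: float = 0.6
    attachment_tolerance_um: float = 5.0
    clump_area_multiple: float = 3.0
    count_clumps_as_one: bool = False
    soma_subtraction_pad_um: float = 1.5
    min_dendrite_area_px: int = 3

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        for name in ("dendrite_width_threshold_mm", "soma_opening_radius_um",
                     "min_soma_area_um2", "attachment_tolerance_um",
                     "clump_area_multiple"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.threshold_strategy not in ("otsu", "fixed"):
            raise ConfigurationError(
                f"unknown threshold strategy {self.threshold_strategy!r}")
        if self.threshold_strategy == "fixed" and self.fixed_threshold is None:
            raise ConfigurationError(
                "fixed threshold strategy requires fixed_threshold")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0


@dataclass(frozen=True)
class SomaDetection:
    """A cell body registered as a circle."""

    id: int
    x_mm: float
    y_mm: float
    radius_mm: float
    circularity: float
    is_clump: bool = False
    estimated_cell_count: int = 1


@dataclass(frozen=True)
class DendriteTrace:
    """A skeletonized neurite with physical length and soma attachments."""

    id: int
    polyline_mm: np.ndarray  # ordered (x, y) points in mm
    length_mm: float
    mean_width_mm: float
    attachments: tuple[int, ...]  # 0-2 soma ids


def _check_2d(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2D grayscale image, got {image.ndim}D")
    return image


def enhance(image: np.ndarray, params: EnhanceParams = EnhanceParams()
            ) -> np.ndarray:
    """Contrast stretch then unsharp-mask an image.

    The contrast step scales deviations from the image mean by
    (1 + contrast_pct/100) and clips to the valid intensity range; the
    sharpening step applies unsharp masking with amount sharpen_pct/100
    and a Gaussian radius of ``sharpen_radius_px``.
    """
    image = _check_2d(image).astype(np.float64)
    lo, hi = INTENSITY_RANGE
    mean = image.mean() if image.size else 0.0
    out = mean + (1.0 + params.contrast_pct / 100.0) * (image - mean)
    out = np.clip(out, lo, hi)
    if params.sharpen_pct > 0 and out.size:
        out = unsharp_mask(out, radius=params.sharpen_radius_px,
                           amount=params.sharpen_pct / 100.0,
                           preserve_range=True)
        out = np.clip(out, lo, hi)
    return out


def _otsu_threshold(image: np.ndarray, nbins: int = 4096) -> float:
    """Global Otsu threshold (maximal between-class variance).

    The threshold is returned as the *upper edge* of the optimal bin, so
    an arbitrarily narrow background mode sitting inside that bin is
    still classified as background under the ``image > threshold``
    convention (bin-center thresholds misclassify such modes).
    """
    if image.size == 0 or float(image.max()) == float(image.min()):
        raise DegenerateThresholdError(
            "Otsu threshold undefined for a constant image")
    hist, edges = np.histogram(image, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist / hist.sum()
    omega0 = np.cumsum(w)
    mu = np.cumsum(w * centers)
    mu_total = mu[-1]
    valid = (omega0 > 0) & (omega0 < 1)
    sb = np.full(nbins, -np.inf)
    sb[valid] = ((mu_total * omega0[valid] - mu[valid]) ** 2
                 / (omega0[valid] * (1.0 - omega0[valid])))
    idx = int(np.argmax(sb))
    return float(edges[idx + 1])


def segment_foreground(image: np.ndarray, config: MaskingConfig) -> np.ndarray:
    """Binary foreground mask via global Otsu or a fixed threshold."""
    image = _check_2d(image)
    if config.threshold_strategy == "fixed":
        thr = config.fixed_threshold
    else:
        thr = _otsu_threshold(image)
    return image > thr


def _binary_opening_disc(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological opening with a Euclidean disc via two EDTs."""
    if radius_px <= 0:
        return mask.copy()
    core = ndi.distance_transform_edt(mask) > radius_px
    if not core.any():
        return np.zeros_like(mask)
    return ndi.distance_transform_edt(~core) <= radius_px


def detect_cell_bodies(mask: np.ndarray, image: np.ndarray,
                       config: MaskingConfig) -> list[SomaDetection]:
    """Register cell bodies as circles.

    A morphological opening at ``soma_opening_radius_um`` removes every
    structure thinner than twice that radius (i.e. all dendrites), so the
    surviving connected regions are cell bodies.  Each is registered as a
    circle at its centroid with the equivalent-area radius.  Regions
    larger than ``clump_area_multiple`` × the median single-body area are
    flagged as clumps, with the cell count estimated from the area ratio.
    Detections are sorted by position (x, then y) and get ids 0..n-1.
    """
    mask = np.asarray(mask, dtype=bool)
    px_mm = config.pixel_size_mm
    px_um = config.pixel_size_um
    opened = _binary_opening_disc(mask, config.soma_opening_radius_um / px_um)
    if not opened.any():
        return []
    lab = label(opened, connectivity=2)
    regions = regionprops(lab)
    min_area_px = config.min_soma_area_um2 / (px_um * px_um)
    regions = [r for r in regions if r.area >= min_area_px]
    if not regions:
        return []
    areas = np.array([r.area for r in regions], dtype=float)
    median_area = float(np.median(areas))

    raw = []
    for r in regions:
        area = float(r.area)
        perim = max(float(r.perimeter), 1.0)
        circ = min(1.0, 4.0 * math.pi * area / (perim * perim))
        is_clump = area > config.clump_area_multiple * median_area
        if not is_clump and circ < config.min_circularity:
            continue
        cy, cx = r.centroid
        est = max(1, int(round(area / median_area))) if is_clump else 1
        if config.count_clumps_as_one:
            est = 1
        raw.append((
            (cx + 0.5) * px_mm,
            (cy + 0.5) * px_mm,
            math.sqrt(area / math.pi) * px_mm,
            circ, is_clump, est,
        ))
    raw.sort(key=lambda t: (t[0], t[1]))
    return [SomaDetection(i, x, y, rad, c, k, e)
            for i, (x, y, rad, c, k, e) in enumerate(raw)]


def _render_discs(shape: tuple[int, int], somata: list[SomaDetection],
                  pad_mm: float, px_mm: float) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    from .simulate import _disc_pixels
    for s in somata:
        _disc_pixels(out, s.x_mm, s.y_mm, s.radius_mm + pad_mm, px_mm)
    return out


def mask_dendrites(mask: np.ndarray, somata: list[SomaDetection],
                   config: MaskingConfig) -> np.ndarray:
    """Retain thin foreground structures outside the soma discs.

    Foreground minus the detected soma discs is kept where the local
    structure width stays at or below ``dendrite_width_threshold_mm``
    (0.06 mm by default); any connected structure containing a wider core
    is excluded whole.  Tiny speckle below ``min_dendrite_area_px`` is
    dropped.
    """
    mask = np.asarray(mask, dtype=bool)
    px_mm = config.pixel_size_mm
    soma_px = _render_discs(mask.shape, somata,
                            config.soma_subtraction_pad_um / 1000.0, px_mm)
    residual = mask & ~soma_px
    if not residual.any():
        return residual
    half_thr_px = config.dendrite_width_threshold_mm / 2.0 / px_mm
    dt = ndi.distance_transform_edt(residual)
    lab = label(residual, connectivity=2)
    wide_labels = np.unique(lab[dt > half_thr_px])
    wide_labels = wide_labels[wide_labels != 0]
    keep = residual.copy()
    if wide_labels.size:
        keep &= ~np.isin(lab, wide_labels)
    if config.min_dendrite_area_px > 1:
        lab2, n2 = ndi.label(keep, structure=np.ones((3, 3), dtype=int))
        if n2:
            sizes = ndi.sum_labels(keep, lab2, index=np.arange(1, n2 + 1))
            small = np.flatnonzero(sizes < config.min_dendrite_area_px) + 1
            if small.size:
                keep &= ~np.isin(lab2, small)
    return keep


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1),
                     (0, -1), (0, 1),
                     (1, -1), (1, 0), (1, 1)]


def _longest_skeleton_path(pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Principal (diameter) path through a skeleton pixel set.

    Two passes of BFS: from an arbitrary pixel to the farthest pixel, then
    from there to its farthest pixel; exact on trees (skeletons of simple
    strokes), a good principal path otherwise.
    """
    pixset = set(pixels)

    def bfs(start):
        import collections
        prev = {start: None}
        queue = collections.deque([start])
        last = start
        while queue:
            cur = queue.popleft()
            last = cur
            for dy, dx in _NEIGHBOR_OFFSETS:
                nxt = (cur[0] + dy, cur[1] + dx)
                if nxt in pixset and nxt not in prev:
                    prev[nxt] = cur
                    queue.append(nxt)
        return last, prev

    a, _ = bfs(pixels[0])
    b, prev = bfs(a)
    path = []
    cur = b
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path


def trace_dendrites(dendrite_mask: np.ndarray, somata: list[SomaDetection],
                    config: MaskingConfig) -> list[DendriteTrace]:
    """Skeletonize the dendrite mask and trace each neurite.

    Each connected component of the mask yields one trace: the longest
    path through its skeleton (robust to short skeleton spurs).  A path
    endpoint lying within ``attachment_tolerance_um`` of a soma circle
    (or inside it) is attached to the nearest soma; equidistant ties
    resolve to the lower soma id.  Lengths are summed segment lengths in
    mm; mean width is twice the mean distance-transform value along the
    path.
    """
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    if not dendrite_mask.any():
        return []
    px_mm = config.pixel_size_mm
    tol_mm = config.attachment_tolerance_um / 1000.0
    # thinning preserves stroke tips; Zhang skeletonization
    # retracts the ends of thin diagonal strokes by many pixels
    skel = thin(dendrite_mask)
    dt = ndi.distance_transform_edt(dendrite_mask)
    lab, n_comp = ndi.label(dendrite_mask, structure=np.ones((3, 3), dtype=int))

    centers = np.array([[s.x_mm, s.y_mm] for s in somata]) if somata else \
        np.empty((0, 2))
    radii = np.array([s.radius_mm for s in somata]) if somata else np.empty(0)

    def attach(pt_mm: np.ndarray) -> Optional[int]:
        if not len(centers):
            return None
        d = np.hypot(centers[:, 0] - pt_mm[0], centers[:, 1] - pt_mm[1])
        boundary = np.abs(d - radii)
        inside_or_near = d <= radii + tol_mm
        if not inside_or_near.any():
            return None
        cand = np.flatnonzero(inside_or_near)
        # nearest by boundary distance; ties go to the lower id
        best = cand[np.lexsort((cand, boundary[cand]))[0]]
        return int(somata[best].id)

    traces: list[DendriteTrace] = []
    for comp in range(1, n_comp + 1):
        comp_mask = lab == comp
        comp_skel = skel & comp_mask
        coords = np.argwhere(comp_skel)
        if coords.size == 0:
            # component too small to skeletonize to anything; use its pixels
            coords = np.argwhere(comp_mask)
        pixels = [tuple(rc) for rc in coords]
        path = _longest_skeleton_path(pixels)
        arr = np.array(path, dtype=float)  # (k, 2) as (row, col)
        poly_mm = np.column_stack([(arr[:, 1] + 0.5) * px_mm,
                                   (arr[:, 0] + 0.5) * px_mm])
        if len(poly_mm) > 1:
            seg = np.diff(poly_mm, axis=0)
            length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        else:
            length = 0.0
        widths = 2.0 * dt[tuple(np.array(path).T)] * px_mm
        mean_width = float(np.mean(widths)) if len(widths) else 0.0
        atts = []
        for end in (poly_mm[0], poly_mm[-1]):
            a = attach(end)
            if a is not None:
                atts.append(a)
        traces.append(DendriteTrace(
            id=len(traces),
            polyline_mm=poly_mm,
            length_mm=length,
            mean_width_mm=mean_width,
            attachments=tuple(atts),
        ))
    return traces


def soma_detection_f1(detections: list[SomaDetection], somata,
                      match_tolerance_um: float = 10.0) -> float:
    """F1 of detections against ground-truth somata.

    Greedy one-to-one matching by center distance within the tolerance.
    ``somata`` is a sequence of objects with ``x_mm``/``y_mm`` attributes
    (e.g. ground-truth :class:`~neurocult.simulate.Soma`).
    """
    if not detections and not somata:
        return 1.0
    if not detections or not somata:
        return 0.0
    tol_mm = match_tolerance_um / 1000.0
    det = np.array([[d.x_mm, d.y_mm] for d in detections])
    tru = np.array([[s.x_mm, s.y_mm] for s in somata])
    dists = np.hypot(det[:, None, 0] - tru[None, :, 0],
                     det[:, None, 1] - tru[None, :, 1])
    pairs = np.argwhere(dists <= tol_mm)
    order = np.argsort(dists[pairs[:, 0], pairs[:, 1]])
    used_d, used_t = set(), set()
    tp = 0
    for i in order:
        di, ti = pairs[i]
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        tp += 1
    precision = tp / len(detections)
    recall = tp / len(somata)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
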