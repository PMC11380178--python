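"""Primitive raster operators used by the segmentation pipelines.

These are the building blocks of the classic desktop-tool macro workflow
for fluorescence micrographs: Gaussian smoothing, Otsu thresholding,
despeckling, binary morphology with a 3x3 square structuring element,
hole filling, distance-transform watershed splitting of touching objects,
and size-filtered connected-component ("particle") labeling.

Conventions
-----------
* Rasters are 2-D numpy arrays indexed ``[row, col]`` (0-based).
* Binary masks are boolean arrays; ``True`` is foreground.
* Pixels outside the raster are treated as background by every binary
  operator (Minkowski operations clipped to the image window).
* Label maps use 0 for background and contiguous labels ``1..n_labels``.
* Areas are in px^2, centroids are arithmetic means of pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed as _skimage_watershed

__all__ = [
    "Micrograph",
    "ThresholdResult",
    "LabelMap",
    "SQUARE_SE",
    "gaussian_blur",
    "otsu_threshold",
    "despeckle",
    "binary_dilate",
    "binary_erode",
    "binary_close",
    "fill_holes",
    "watershed_split",
    "label_particles",
    "size_filter",
]

#: 3x3 square structuring element used by all binary morphology here.
SQUARE_SE = np.ones((3, 3), dtype=bool)


@dataclass
class Micrograph:
    """Two-channel fluorescence micrograph with channel-role metadata.

    ``channels`` is an array of shape ``(2, H, W)``; ``channel_roles``
    maps the roles ``"nuclei"`` (DAPI) and ``"myotubes"`` (MF20, i.e.
    sarcomeric myosin heavy chain) to channel indices.
    """

    channels: np.ndarray
    channel_roles: Mapping[str, int]
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] < 2:
            raise ValueError("channels must have shape (n_channels>=2, H, W)")
        roles = set(self.channel_roles)
        if roles != {"nuclei", "myotubes"}:
            raise ValueError(f"channel_roles must map exactly nuclei and myotubes, got {roles}")
        idx = [self.channel_roles["nuclei"], self.channel_roles["myotubes"]]
        if idx[0] == idx[1]:
            raise ValueError("nuclei and myotubes must map to distinct channels")
        for i in idx:
            if not 0 <= i < self.channels.shape[0]:
                raise IndexError(f"channel index {i} out of range for {self.channels.shape[0]} channels")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the raster for a channel role (``nuclei`` or ``myotubes``)."""
        if role not in self.channel_roles:
            raise KeyError(f"no channel mapped for role {role!r}")
        return self.channels[self.channel_roles[role]]


@dataclass
class ThresholdResult:
    """Otsu threshold plus the resulting foreground mask.

    ``mask`` is exactly ``image > threshold``.  ``degenerate`` flags a
    constant input, for which no meaningful split exists and the mask is
    all-background.
    """

    threshold: float
    mask: np.ndarray
    degenerate: bool = False


@dataclass
class LabelMap:
    """Integer-labeled segmentation raster; 0 is background.

    Labels form the contiguous set ``1..n_labels``.
    """

    raster: np.ndarray
    n_labels: int = field(default=-1)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ValueError("label raster must be 2-D")
        present = np.unique(self.raster)
        present = present[present > 0]
        inferred = int(present.max()) if present.size else 0
        if self.n_labels < 0:
            self.n_labels = inferred
        if present.size != self.n_labels or (present.size and present[-1] != self.n_labels):
            raise ValueError("labels must be the contiguous set 1..n_labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean support of one label, or of all foreground if ``label`` is None."""
        if label is None:
            return self.raster > 0
        return self.raster == label


def _as_float(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float64)


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth with a normalized, truncated Gaussian kernel (reflect boundary).

    ``sigma`` is in pixels; ``sigma == 0`` returns the input unchanged.
    The kernel is sampled out to ``round(4 * sigma)`` and renormalized, so
    a constant image is mapped to itself.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    image = _as_float(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if sigma == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma=sigma, mode="reflect", truncate=4.0)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> ThresholdResult:
    """Otsu's method: the histogram cut maximizing between-class variance.

    The intensity histogram uses ``n_bins`` equal bins over the observed
    range.  Ties are broken toward the smallest qualifying cut.  The
    returned ``threshold`` is the largest background-class pixel value, so
    that ``mask = image > threshold`` reproduces the class split exactly.
    A constant image yields an empty mask with ``degenerate=True`` rather
    than an exception.
    """
    image = _as_float(image)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        return ThresholdResult(threshold=lo, mask=np.zeros(image.shape, dtype=bool), degenerate=True)
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)                       # weight of bins 0..t
    m0 = np.cumsum(counts * centers)             # unnormalized class-0 mean
    w1 = total - w0
    m_total = m0[-1]
    # between-class variance for cuts after bin t = 0..n_bins-2
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0[:-1] / w0[:-1]
        mu1 = (m_total - m0[:-1]) / w1[:-1]
        sigma_b = w0[:-1] * w1[:-1] * (mu0 - mu1) ** 2
    sigma_b = np.where(valid, sigma_b, -np.inf)
    t = int(np.argmax(sigma_b))                  # argmax returns the first (smallest) maximizer
    cut = edges[t + 1]
    # np.histogram bins are right-open (last closed): background is image < cut.
    background = image < cut
    threshold = float(image[background].max()) if background.any() else lo
    mask = image > threshold
    return ThresholdResult(threshold=threshold, mask=mask)


def despeckle(mask_or_image: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication (desktop-tool "despeckle").

    Works on binary masks and on gray-scale rasters alike; removes isolated
    minority pixels and is idempotent on its own fixed points.
    """
    arr = np.asarray(mask_or_image)
    out = ndi.median_filter(arr.astype(np.float64), size=3, mode="nearest")
    if arr.dtype == bool:
        return out > 0.5
    return out.astype(arr.dtype)


def _check_iterations(iterations: int) -> int:
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    return int(iterations)


def binary_dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Iterated Minkowski dilation with the 3x3 square SE, clipped to the raster."""
    iterations = _check_iterations(iterations)
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=SQUARE_SE, iterations=iterations)


def binary_erode(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Iterated Minkowski erosion with the 3x3 square SE; outside pixels count as background."""
    iterations = _check_iterations(iterations)
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=SQUARE_SE, iterations=iterations, border_value=0)


def binary_close(mask: np.ndarray) -> np.ndarray:
    """One dilation followed by one erosion (3x3 square); bridges sub-SE gaps."""
    return binary_erode(binary_dilate(mask, 1), 1)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not 4-connected to the raster border."""
    mask = np.asarray(mask, dtype=bool)
    # default cross-shaped structure gives 4-connectivity for the background flood
    return ndi.binary_fill_holes(mask)


#: scale-relative prominence rule for seed detection: a distance-map maximum of
#: height p keeps its own seed only if the saddle toward any higher maximum is
#: below (1 - _SEED_REL) * p - _SEED_ABS.  The relative term merges the shallow
#: ridge jitter of discretized elongated shapes (a few percent of a large
#: half-width) while the same rule keeps the much deeper relative necks between
#: touching nuclei separate; the absolute term guards the tiny-object limit.
_SEED_REL = 0.08
_SEED_ABS = 0.3


def watershed_split(mask: np.ndarray, min_seed_separation: float) -> LabelMap:
    """Split touching convex-ish objects via a distance-transform watershed.

    Seeds are the regional maxima of the Euclidean distance transform,
    merged under a scale-relative prominence rule: a maximum of height p
    survives as its own seed only if it is separated from higher ground
    by a saddle below ``0.92 * p - 0.3`` (computed by grayscale
    reconstruction).  This collapses the jittery near-constant ridge of
    an elongated object into a single seed while keeping the deep necks
    between touching rounded objects as genuine splits.  Of any two
    surviving seeds closer than ``min_seed_separation`` only the one with
    the larger distance value is kept.  The watershed flood is restricted
    to the mask and the 1-px watershed lines are assigned to background,
    so split objects come out disconnected.  An object that yields a
    single seed keeps a single label; a component whose every maximum was
    suppressed is re-seeded at its distance argmax so no object is lost.
    This emulates the classic ultimate-eroded-points binary watershed; it
    is not a bit-exact port.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), 0)
    distance = ndi.distance_transform_edt(mask)
    maxima = _prominent_maxima(distance) & mask
    seed_labels, n_seeds = ndi.label(maxima, structure=SQUARE_SE)
    markers = np.zeros(mask.shape, dtype=np.int32)
    if n_seeds:
        # greedy separation enforcement: strongest seeds win
        objs = ndi.find_objects(seed_labels)
        heights = ndi.maximum(distance, labels=seed_labels, index=np.arange(1, n_seeds + 1))
        centroids = np.array(ndi.center_of_mass(maxima, seed_labels, np.arange(1, n_seeds + 1)))
        accepted: list[int] = []
        for i in np.argsort(-np.atleast_1d(heights), kind="stable"):
            c = centroids[i]
            if all(np.hypot(*(c - centroids[j])) >= min_seed_separation for j in accepted):
                accepted.append(int(i))
        for k, i in enumerate(accepted, start=1):
            sl = objs[i]
            markers[sl][seed_labels[sl] == i + 1] = k
    # re-seed any component left without a marker
    comp_labels, n_comp = ndi.label(mask, structure=SQUARE_SE)
    if n_comp:
        has_marker = np.bincount(comp_labels[markers > 0], minlength=n_comp + 1) > 0
        next_marker = int(markers.max()) + 1
        for comp in range(1, n_comp + 1):
            if not has_marker[comp]:
                inside = comp_labels == comp
                flat = np.where(inside, distance, -1.0)
                r, c = np.unravel_index(int(np.argmax(flat)), flat.shape)
                markers[r, c] = next_marker
                next_marker += 1
    labels = _skimage_watershed(-distance, markers=markers, mask=mask, watershed_line=True)
    return _relabel_scan_order(labels)


def _prominent_maxima(distance: np.ndarray) -> np.ndarray:
    """Regional maxima surviving the scale-relative prominence rule.

    Grayscale reconstruction of ``(1 - _SEED_REL) * d - _SEED_ABS`` under
    ``d`` levels every maximum down to the higher of its own scaled height
    and its connecting saddles; the regional maxima of the reconstruction
    are exactly the maxima whose separating saddle lies below their scaled
    height, with shallower neighbors absorbed.
    """
    from skimage.morphology import local_maxima, reconstruction

    seed_img = np.maximum((1.0 - _SEED_REL) * distance - _SEED_ABS, 0.0)
    reconstructed = reconstruction(seed_img, distance, method="dilation")
    return local_maxima(reconstructed, connectivity=2)


def label_particles(
    mask: np.ndarray,
    connectivity: int = 8,
    min_area_px: float = 0.0,
    max_area_px: float = np.inf,
) -> LabelMap:
    """Connected-component labeling with size filtering (particle analysis).

    ``connectivity`` is 4 or 8 (pixel neighborhood for foreground).
    Components with area outside ``[min_area_px, max_area_px]`` are
    removed; survivors are re-indexed contiguously from 1 in raster-scan
    order of each component's first pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if min_area_px > max_area_px:
        raise ValueError("min_area_px must be <= max_area_px")
    mask = np.asarray(mask, dtype=bool)
    structure = SQUARE_SE if connectivity == 8 else ndi.generate_binary_structure(2, 1)
    labels, n = ndi.label(mask, structure=structure)
    if n:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        bad = (areas < min_area_px) | (areas > max_area_px)
        bad[0] = False
        labels[bad[labels]] = 0
    return _relabel_scan_order(labels)


def size_filter(labels: LabelMap, min_area_px: float = 0.0,
                max_area_px: float = np.inf) -> LabelMap:
    """Drop labels with area outside ``[min_area_px, max_area_px]``; relabel contiguously.

    Operates on the labels themselves (unlike :func:`label_particles`,
    which re-derives connected components from a mask), so objects split
    by watershed lines stay split even where they touch diagonally.
    """
    if min_area_px > max_area_px:
        raise ValueError("min_area_px must be <= max_area_px")
    raster = labels.raster.copy()
    if labels.n_labels:
        areas = np.bincount(raster.ravel(), minlength=labels.n_labels + 1)
        bad = (areas < min_area_px) | (areas > max_area_px)
        bad[0] = False
        raster[bad[raster]] = 0
    return _relabel_scan_order(raster)


def _relabel_scan_order(labels: np.ndarray) -> LabelMap:
    """Re-index labels contiguously from 1, ordered by each label's first raster-scan pixel."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    present, first = np.unique(flat, return_index=True)
    keep = present > 0
    present, first = present[keep], first[keep]
    order = np.argsort(first, kind="stable")
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=np.int32)
    lut[present[order]] = np.arange(1, len(present) + 1, dtype=np.int32)
    return LabelMap(lut[labels], len(present))
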