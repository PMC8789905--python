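"""Image preparation: background correction, outlier (hot-puncta) removal,
nuclear and sender-territory segmentation, and label dilation.

These are the steps upstream of both profilers.  Nuclei are segmented
classically (smooth, Otsu, watershed on the distance transform); dilated
nuclear labels approximate whole-cell territories so cytoplasmic mRNA is
captured when quantifying FISH-like channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "LabelImage",
    "subtract_background",
    "remove_outliers",
    "segment_nuclei",
    "dilate_labels",
    "segment_sender_mask",
]


@dataclass
class LabelImage:
    """Integer label array (0 = background) plus provenance.

    ``provenance`` records what the labels delineate: ``nuclear``,
    ``cytoplasmic`` (dilated nuclei) or ``sender``.
    """

    labels: np.ndarray
    um_per_px: float
    provenance: str = "nuclear"

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def centroids_um(self) -> np.ndarray:
        """(n, 2) label centroids as (x, y) in um, ordered by label id."""
        if self.n_labels == 0:
            return np.empty((0, 2))
        cyx = ndimage.center_of_mass(
            np.ones_like(self.labels), self.labels,
            index=np.arange(1, self.n_labels + 1),
        )
        cyx = np.asarray(cyx)
        return (cyx[:, ::-1] + 0.5) * self.um_per_px


def subtract_background(
    image: np.ndarray,
    um_per_px: float,
    method: str = "morphological_open",
    radius_um: float = 50.0,
    percentile: float = 50.0,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate and subtract a smooth background; result clipped at 0.

    ``morphological_open``: grayscale opening (of a lightly smoothed copy,
    so shot noise does not drag the estimate to the local minimum) with a
    disc larger than any nucleus — appropriate for spotty foregrounds like
    nuclei or FISH puncta, but it flattens smooth gradients, so use
    ``percentile`` for colony-scale signal channels.

    ``percentile``: a single flat level, the given percentile (default the
    median, which is unbiased for symmetric shot noise) of the image, or
    of the pixels outside ``exclude_mask`` when the foreground footprint
    is known (e.g. the detected colony mask).
    """
    image = np.asarray(image, float)
    radius_px = radius_um / um_per_px
    if radius_px < 2:
        raise ValueError(
            f"background radius {radius_um} um is {radius_px:.2f} px; "
            "must be at least 2 px"
        )
    if method == "morphological_open":
        smoothed = ndimage.gaussian_filter(image, max(1.0, radius_px / 16))
        bg = morphology.opening(smoothed, morphology.disk(int(round(radius_px))))
    elif method == "percentile":
        pool = image if exclude_mask is None else image[~np.asarray(exclude_mask, bool)]
        bg = np.percentile(pool, percentile)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(image - bg, 0.0, None)


def remove_outliers(
    image: np.ndarray, radius_px: int = 2, k_sd: float = 5.0
) -> np.ndarray:
    """Replace pixels far from their local median by that median.

    A pixel is an outlier when it deviates from the local median by more
    than ``k_sd`` robust standard deviations, the robust SD being the
    MAD-scaled local deviation (1.4826 * local median absolute deviation).
    Everything else is returned bit-identical; ``k_sd = inf`` is the
    identity.
    """
    image = np.asarray(image, float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    out = image.copy()
    if np.isinf(k_sd):
        return out
    size = 2 * int(radius_px) + 1
    local_med = ndimage.median_filter(image, size=size, mode="nearest")
    dev = image - local_med
    mad = ndimage.median_filter(np.abs(dev), size=size, mode="nearest")
    robust_sd = 1.4826 * mad
    outlier = np.abs(dev) > k_sd * robust_sd
    out[outlier] = local_med[outlier]
    return out


def segment_nuclei(
    nuclear_channel: np.ndarray,
    um_per_px: float,
    min_diam_um: float = 4.0,
    max_diam_um: float = 20.0,
    smooth_sigma_um: float = 1.0,
) -> LabelImage:
    """Classical nuclear segmentation.

    Gaussian smoothing, Otsu threshold, watershed on the Euclidean
    distance transform to split touching nuclei, then a size gate on
    equivalent diameter.  A blank (constant) image yields zero labels.
    """
    img = np.asarray(nuclear_channel, float)
    if img.max() == img.min():
        return LabelImage(np.zeros(img.shape, np.int32), um_per_px)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma_um / um_per_px)
    mask = smoothed > filters.threshold_otsu(smoothed)
    min_area_px = max(1, int(np.pi * (min_diam_um / 2 / um_per_px) ** 2))
    comp = measure.label(mask)
    areas = np.bincount(comp.ravel())
    areas[0] = 0
    mask = (areas >= min_area_px)[comp]
    if not mask.any():
        return LabelImage(np.zeros(img.shape, np.int32), um_per_px)

    dist = ndimage.distance_transform_edt(mask)
    min_sep_px = max(1, int(0.7 * min_diam_um / um_per_px))
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        dist, min_distance=min_sep_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=mask)

    # size gate by equivalent diameter, then relabel contiguously
    keep = np.zeros(labels.max() + 1, bool)
    for region in measure.regionprops(labels):
        diam_um = region.equivalent_diameter_area * um_per_px
        keep[region.label] = min_diam_um <= diam_um <= max_diam_um
    gated = np.where(keep[labels], labels, 0)
    relabeled, _, _ = segmentation.relabel_sequential(gated)
    return LabelImage(relabeled.astype(np.int32), um_per_px, "nuclear")


def dilate_labels(label_image: LabelImage, radius_um: float) -> LabelImage:
    """Grow every label isotropically by ``radius_um``.

    Collisions are resolved by nearest-seed assignment (each contested
    pixel joins the closest original label), so output labels stay
    disjoint and are supersets of the input labels.  Radius 0 is the
    identity.
    """
    if radius_um < 0:
        raise ValueError("dilation radius must be nonnegative")
    if radius_um == 0:
        return LabelImage(
            label_image.labels.copy(), label_image.um_per_px, "cytoplasmic"
        )
    grown = segmentation.expand_labels(
        label_image.labels, distance=radius_um / label_image.um_per_px
    )
    return LabelImage(
        grown.astype(np.int32), label_image.um_per_px, "cytoplasmic"
    )


def segment_sender_mask(
    marker_channel: np.ndarray,
    threshold_method: str = "otsu",
    closing_radius_px: int = 3,
) -> np.ndarray:
    """Binary sender-territory mask from the membrane/marker channel.

    Threshold (Otsu or a numeric value), morphological closing, then keep
    the largest connected component.  Raises if nothing survives
    thresholding — with no sender territory there is no border to measure
    distance from.
    """
    img = np.asarray(marker_channel, float)
    if threshold_method == "otsu":
        if img.max() == img.min():
            raise ValueError("constant marker channel: no sender territory found")
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold_method)
    mask = img > thr
    if closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius_px))
    if not mask.any():
        raise ValueError("empty sender mask after thresholding")
    labels = measure.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest
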