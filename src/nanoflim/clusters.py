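"""Nanocluster detection and quantification in surface-illumination images.

The detection pipeline mirrors a standard particle-analysis workflow for
punctate membrane images: rolling-ball background subtraction, a band-pass
step (subtraction of a 2 µm Gaussian blur), a fixed intensity threshold, and
8-connected component labelling with a minimum-area cut that removes single
stray pixels.  Densities (clusters/µm²) and mean cluster sizes (µm²) are
aggregated per image and per treatment, and the ratio of receptor density to
nanocluster density yields the average number of receptors per nanocluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw, measure, restoration

from .containers import BleachTrace, FrameStack

__all__ = [
    "ClusterRecord",
    "ClusterSet",
    "ClusterSummary",
    "rolling_ball_subtract",
    "bandpass_subtract",
    "threshold_label",
    "summarize_clusters",
    "pool_summaries",
    "receptors_per_cluster",
    "roi_bleach_trace",
    "detect_clusters",
]


@dataclass
class ClusterRecord:
    """One detected nanocluster."""

    label: int
    area_px: int
    area_um2: float
    centroid_px: tuple[float, float]  # (row, col)
    equivalent_diameter_nm: float
    integrated_intensity: float


@dataclass
class ClusterSet:
    """All clusters detected in one frame."""

    records: list[ClusterRecord]
    label_image: np.ndarray
    pixel_size_nm: float
    roi_area_um2: float

    def __len__(self) -> int:
        return len(self.records)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([r.area_um2 for r in self.records])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([r.centroid_px for r in self.records]).reshape(-1, 2)


@dataclass
class ClusterSummary:
    """Density and size statistics of one or more analysed images."""

    n_clusters: int
    roi_area_um2: float
    density_per_um2: float
    mean_size_um2: float
    sem_size_um2: float
    sem_density_per_um2: float | None = None
    n_images: int = 1


def rolling_ball_subtract(frame: np.ndarray, radius: int = 50) -> np.ndarray:
    """Remove smooth background with a morphological rolling ball.

    A ball of the given radius (pixels) is rolled under the intensity
    surface; the traced background is subtracted and the result clipped at
    zero.  If the radius is at least as large as the image, the background
    degenerates to the global minimum.
    """
    frame = np.asarray(frame, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(frame.shape):
        background = np.full_like(frame, frame.min())
    else:
        background = restoration.rolling_ball(frame, radius=radius)
    return np.clip(frame - background, 0.0, None)


def bandpass_subtract(
    frame: np.ndarray, sigma_um: float = 2.0, pixel_size_nm: float = 130.0
) -> np.ndarray:
    """Subtract a large-sigma Gaussian blur of the image from the image.

    With the default 2 µm sigma (about 15.4 px at 130 nm pixels) this acts
    as a high-pass filter that flattens residual background while leaving
    diffraction-limited spots nearly untouched.  The output may contain
    negative values; thresholding clips them.
    """
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    frame = np.asarray(frame, dtype=float)
    sigma_px = sigma_um * 1000.0 / pixel_size_nm
    return frame - gaussian_filter(frame, sigma_px)


def _roi_mask(shape: tuple[int, int], roi: np.ndarray | None) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=float)
    if roi.ndim == 2 and roi.shape[1] == 2:  # polygon vertices (row, col)
        return draw.polygon2mask(shape, roi)
    return np.asarray(roi, dtype=bool)


def threshold_label(
    frame: np.ndarray,
    threshold: float = 80.0,
    min_area: int = 2,
    connectivity: int = 2,
    roi: np.ndarray | None = None,
    pixel_size_nm: float = 130.0,
) -> ClusterSet:
    """Threshold a band-pass frame and label connected particles.

    ``roi`` restricts the analysis to a region of interest, given either as
    a boolean mask or as a polygon of (row, col) vertices; by default the
    whole frame is analysed.  Components smaller than ``min_area`` pixels
    are discarded (min_area 2 removes single, non-connected pixels).
    ``connectivity=2`` is 8-neighbour labelling.
    """
    frame = np.clip(np.asarray(frame, dtype=float), 0.0, None)
    mask = _roi_mask(frame.shape, roi)
    binary = (frame >= threshold) & mask
    labels = measure.label(binary, connectivity=connectivity)
    px_um2 = (pixel_size_nm / 1000.0) ** 2
    records = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            labels[labels == region.label] = 0
            continue
        area_um2 = region.area * px_um2
        records.append(
            ClusterRecord(
                label=region.label,
                area_px=int(region.area),
                area_um2=float(area_um2),
                centroid_px=tuple(region.centroid),
                equivalent_diameter_nm=2e3 * np.sqrt(area_um2 / np.pi),
                integrated_intensity=float(region.image_intensity.sum()),
            )
        )
    roi_area_um2 = float(mask.sum() * px_um2)
    return ClusterSet(records, labels, pixel_size_nm, roi_area_um2)


def summarize_clusters(
    clusters: ClusterSet, roi_area_um2: float | None = None
) -> ClusterSummary:
    """Density and mean size of one analysed frame."""
    area = roi_area_um2 if roi_area_um2 is not None else clusters.roi_area_um2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    n = len(clusters)
    sizes = clusters.areas_um2
    mean_size = float(sizes.mean()) if n else 0.0
    sem_size = float(sizes.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ClusterSummary(
        n_clusters=n,
        roi_area_um2=float(area),
        density_per_um2=n / area,
        mean_size_um2=mean_size,
        sem_size_um2=sem_size,
    )


def pool_summaries(summaries: list[ClusterSummary]) -> ClusterSummary:
    """Pool per-image summaries into a per-treatment summary.

    The density mean and SEM are taken over images (each image is one
    observation, matching how replicate images are averaged); sizes are
    pooled over all clusters weighted by cluster count.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    dens = np.array([s.density_per_um2 for s in summaries])
    n_total = sum(s.n_clusters for s in summaries)
    area_total = sum(s.roi_area_um2 for s in summaries)
    if n_total:
        mean_size = sum(s.mean_size_um2 * s.n_clusters for s in summaries) / n_total
    else:
        mean_size = 0.0
    sizes_sem = np.array([s.sem_size_um2 for s in summaries if s.n_clusters > 1])
    return ClusterSummary(
        n_clusters=n_total,
        roi_area_um2=area_total,
        density_per_um2=float(dens.mean()),
        mean_size_um2=float(mean_size),
        sem_size_um2=float(sizes_sem.mean()) if sizes_sem.size else 0.0,
        sem_density_per_um2=float(dens.std(ddof=1) / np.sqrt(dens.size))
        if dens.size > 1
        else None,
        n_images=len(summaries),
    )


def receptors_per_cluster(
    receptor_density: float,
    cluster_density: float,
    receptor_sem: float | None = None,
    cluster_sem: float | None = None,
) -> tuple[int, float | None]:
    """Average number of receptors per nanocluster.

    The ratio of the receptor surface density to the nanocluster density,
    rounded to the nearest integer; the SEM is propagated to first order
    from the two input SEMs when both are given.
    """
    if cluster_density <= 0:
        raise ValueError("cluster density must be positive")
    ratio = receptor_density / cluster_density
    sem = None
    if receptor_sem is not None and cluster_sem is not None:
        if receptor_density == 0:
            sem = receptor_sem / cluster_density
        else:
            sem = abs(ratio) * np.sqrt(
                (receptor_sem / receptor_density) ** 2
                + (cluster_sem / cluster_density) ** 2
            )
    return int(round(ratio)), sem


def roi_bleach_trace(
    stack: FrameStack, center_px: tuple[int, int], size: int = 5
) -> BleachTrace:
    """Mean intensity of a ``size x size`` ROI in every frame.

    The ROI must lie fully inside the image; a window clipped at the border
    is rejected.
    """
    row, col = int(center_px[0]), int(center_px[1])
    half = size // 2
    ny, nx = stack.shape
    if not (half <= row < ny - half and half <= col < nx - half):
        raise ValueError("ROI window extends beyond the image")
    window = stack.data[:, row - half : row + half + 1, col - half : col + half + 1]
    return BleachTrace(
        window.mean(axis=(1, 2)), frame_interval_ms=stack.frame_interval_ms
    )


def detect_clusters(
    stack: FrameStack,
    frame: int = 0,
    rolling_ball_radius: int | None = 50,
    sigma_um: float | None = 2.0,
    threshold: float = 80.0,
    min_area: int = 2,
    connectivity: int = 2,
    roi: np.ndarray | None = None,
) -> ClusterSet:
    """Full detection pipeline on one frame of a calibrated stack.

    Rolling-ball background subtraction and the Gaussian band-pass are each
    skipped when their parameter is None, so either step can be disabled
    independently.
    """
    img = np.asarray(stack.data[frame], dtype=float)
    if rolling_ball_radius is not None:
        img = rolling_ball_subtract(img, rolling_ball_radius)
    if sigma_um is not None:
        img = bandpass_subtract(img, sigma_um, stack.pixel_size_nm)
    return threshold_label(
        img,
        threshold=threshold,
        min_area=min_area,
        connectivity=connectivity,
        roi=roi,
        pixel_size_nm=stack.pixel_size_nm,
    )
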