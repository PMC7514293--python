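"""Stack conversion, threshold segmentation, and object size statistics.

Image stacks are converted to 8-bit, segmented by a gray-level band (an
interval, because DIC objects carry both dark cores and bright fringes),
labeled with 8-connectivity, and reduced to a per-frame detection table of
centroids in µm.  A sensitivity helper reruns the full tracking + fit chain
over a set of bands and reports the spread of the resulting diffusion
parameters.

Coordinate convention: pixel centers at integer coordinates, origin at the
top-left pixel, x = column·pixel_size, y = row·pixel_size; all downstream
math is in µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from diffent import tracking

logger = logging.getLogger(__name__)

#: Columns of a detection table.
DETECTION_COLUMNS = ["frame", "x_um", "y_um", "area_px", "area_um2", "eq_diam_um"]

DetectionTable = pd.DataFrame


@dataclass
class ImageStack:
    """A grayscale stack with its acquisition metadata."""

    frames: np.ndarray            # (n_frames, height, width)
    dt_frame: float = 0.3         # s
    pixel_size: float = 0.1       # µm / pixel
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (frame, row, col) array")
        if self.dt_frame <= 0 or self.pixel_size <= 0:
            raise ValueError("dt_frame and pixel_size must be positive")

    @classmethod
    def from_tiff(cls, path, dt_frame: float = 0.3,
                  pixel_size: float = 0.1) -> "ImageStack":
        arr = tifffile.imread(path)
        return cls(frames=arr, dt_frame=dt_frame, pixel_size=pixel_size,
                   bit_depth=arr.dtype.itemsize * 8)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames)


def to_8bit(stack: ImageStack | np.ndarray) -> ImageStack:
    """Linear min–max rescale of the whole stack to integer [0, 255].

    Rounding is round-half-even (numpy ``rint``).  A constant stack has no
    dynamic range and maps to all zeros.
    """
    arr = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        out = np.zeros(arr.shape, dtype=np.uint8)
    else:
        out = np.rint((arr.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)
    if isinstance(stack, ImageStack):
        return ImageStack(out, stack.dt_frame, stack.pixel_size, bit_depth=8)
    return ImageStack(out, bit_depth=8)


def _resolve_band(frames: np.ndarray, band) -> tuple[int, int]:
    if isinstance(band, str):
        if band != "otsu":
            raise ValueError(f"unknown band mode {band!r}")
        t = int(threshold_otsu(frames.ravel()))
        # foreground = the sparser side of the cut (objects are a minority)
        below = int((frames <= t).sum())
        if below <= frames.size - below:
            return (0, t)
        return (t + 1, 255)
    lo, hi = int(band[0]), int(band[1])
    if lo > hi:
        raise ValueError("empty threshold band")
    return lo, hi


def threshold_segment(stack: ImageStack, band="otsu",
                      min_area: int = 4):
    """Band-threshold an 8-bit stack and extract per-frame detections.

    Pixels with gray level inside the inclusive band are foreground;
    8-connected components smaller than ``min_area`` pixels are discarded.
    Centroids are intensity-unweighted component centroids converted to µm.
    Returns ``(binary_stack, detections)``.
    """
    frames = stack.frames
    if frames.dtype != np.uint8:
        raise ValueError("threshold_segment expects an 8-bit stack; "
                         "run to_8bit first")
    lo, hi = _resolve_band(frames, band)
    binary = (frames >= lo) & (frames <= hi)
    frac = binary.mean()
    if frac > 0.5:
        logger.warning("band (%d, %d) selects %.0f%% of pixels; over-wide "
                       "bands thicken and merge object contours", lo, hi,
                       100 * frac)
    rows = []
    px = stack.pixel_size
    for f in range(binary.shape[0]):
        labels = label(binary[f], connectivity=2)
        for region in regionprops(labels):
            if region.area < min_area:
                continue
            r, c = region.centroid
            area_um2 = region.area * px * px
            rows.append((f, c * px, r * px, int(region.area), area_um2,
                         2.0 * np.sqrt(area_um2 / np.pi)))
    det = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return binary, det


def size_distribution(detections: DetectionTable, bins=20):
    """Histogram of equivalent diameters 2·sqrt(area/π) in µm.

    Returns ``(counts, bin_edges)``; an empty table yields empty counts
    rather than an error.
    """
    if len(detections) == 0:
        if np.isscalar(bins):
            return np.zeros(int(bins), dtype=int), np.linspace(0.0, 1.0, int(bins) + 1)
        edges = np.asarray(bins, dtype=float)
        return np.zeros(edges.size - 1, dtype=int), edges
    counts, edges = np.histogram(detections["eq_diam_um"], bins=bins)
    return counts, edges


@dataclass
class ThresholdSensitivity:
    """Diffusion-fit spread across segmentation bands."""

    table: pd.DataFrame            # band_lo, band_hi, n_trajectories, k_alpha, alpha
    sd_k_alpha: float
    sd_alpha: float


def threshold_sensitivity(stack: ImageStack, band_set, max_disp: float = 1.0,
                          min_len: int = 11, k_max: int = 10,
                          min_area: int = 4, min_particles: int = 1,
                          n_dims: int = 2) -> ThresholdSensitivity:
    """Rerun segmentation → linking → MSD → power fit for each band.

    Bands yielding fewer than ``min_particles`` trajectories are excluded
    (and logged).  The SDs of K_α and α across the surviving bands bound the
    segmentation-induced uncertainty of the diffusion parameters.
    """
    band_set = list(band_set)
    if len(band_set) < 2:
        logger.info("single band: sensitivity SDs are 0 by definition")
    rows = []
    for band in band_set:
        lo, hi = _resolve_band(stack.frames, band)
        _, det = threshold_segment(stack, (lo, hi), min_area=min_area)
        trajs = tracking.link(det, max_disp=max_disp, min_len=min_len,
                              dt_frame=stack.dt_frame)
        if len(trajs) < min_particles:
            logger.warning("band (%d, %d) produced %d trajectories "
                           "(< %d); excluded", lo, hi, len(trajs),
                           min_particles)
            continue
        curve = tracking.compute_msd(trajs, k_max=k_max,
                                     dt_frame=stack.dt_frame)
        fit = tracking.fit_power_law(curve, n_dims=n_dims)
        rows.append((lo, hi, len(trajs), fit.k_alpha, fit.alpha))
    table = pd.DataFrame(rows, columns=["band_lo", "band_hi",
                                        "n_trajectories", "k_alpha", "alpha"])
    if len(table) >= 2:
        sd_k = float(table["k_alpha"].std(ddof=1))
        sd_a = float(table["alpha"].std(ddof=1))
    else:
        sd_k = sd_a = 0.0
    return ThresholdSensitivity(table=table, sd_k_alpha=sd_k, sd_alpha=sd_a)


def flood_fill_components(binary: np.ndarray) -> np.ndarray:
    """Label 8-connected components by explicit flood fill (oracle)."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack_ = [start]
        labels[start] = current
        while stack_:
            r, c = stack_.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                            and binary[rr, cc] and not labels[rr, cc]):
                        labels[rr, cc] = current
                        stack_.append((rr, cc))
    return labels
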