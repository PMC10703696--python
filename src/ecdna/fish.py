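"""FISH spot counting and copy-number heterogeneity statistics.

Spots are detected by convolving the image with a sampled Gaussian kernel
(sd 3 px, 7x7), thresholding the smoothed image at 15 on the 0-255 scale,
keeping 8-connected components whose peak raw brightness exceeds the image
mean plus one standard deviation, and discarding components below a minimum
area. Each surviving component is one hybridization spot; a cell whose spot
count exceeds five is classified as amplified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class SpotCallParams:
    gaussian_sd: float = 3.0
    kernel_size: int = 7
    fixed_threshold: float = 15.0
    relative_sds: float = 1.0
    min_area: int = 4

    def __post_init__(self) -> None:
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not (0 < self.fixed_threshold < 255):
            raise ValueError("fixed_threshold must be in (0, 255)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass(frozen=True)
class CellSpotCount:
    cell_id: int
    spot_count: int
    amplified: bool


@dataclass
class HeterogeneityReport:
    """Per-sample spot-count summaries plus location/scale tests vs a reference."""

    per_sample: dict[str, dict] = field(default_factory=dict)
    reference_name: str = "reference"


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Map an image onto the 0-255 scale.

    8-bit input passes through unchanged; wider integer or real input is
    linearly rescaled so its minimum maps to 0 and maximum to 255. A constant
    image is returned unchanged with a warning (no spots can be found).
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if raw.dtype == np.uint8:
        return raw.astype(float)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        warnings.warn("constant image: no spots will be found", stacklevel=2)
        return raw.astype(float)
    return (raw.astype(float) - lo) * (255.0 / (hi - lo))


def gaussian_kernel(sd: float, size: int) -> np.ndarray:
    """Sampled 2-D Gaussian kernel, normalized to sum 1."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sd**2))
    return k / k.sum()


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def detect_spots(
    image: np.ndarray, params: SpotCallParams = SpotCallParams()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect hybridization spots in a normalized (0-255) image.

    Returns a labeled spot raster (0 = background) and a table with one row
    per spot: label, centroid row/col, area in px, and peak raw intensity.
    """
    image = np.asarray(image, dtype=float)
    kernel = gaussian_kernel(params.gaussian_sd, params.kernel_size)
    smoothed = ndimage.convolve(image, kernel, mode="reflect")
    binary = smoothed > params.fixed_threshold
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)

    empty = pd.DataFrame(
        columns=["label", "centroid_r", "centroid_c", "area", "peak"]
    ).astype({"label": int, "area": int})
    if n == 0:
        return labels, empty

    idx = np.arange(1, n + 1)
    peaks = ndimage.maximum(image, labels, index=idx)
    areas = ndimage.sum_labels(binary, labels, index=idx)
    brightness_floor = image.mean() + params.relative_sds * image.std()
    keep = (peaks > brightness_floor) & (areas >= params.min_area)

    # relabel surviving components 1..k
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[idx[keep]] = np.arange(1, keep.sum() + 1)
    spot_labels = remap[labels]
    if not keep.any():
        return spot_labels, empty

    kept_idx = np.arange(1, keep.sum() + 1)
    centroids = ndimage.center_of_mass(binary, spot_labels, index=kept_idx)
    table = pd.DataFrame(
        {
            "label": kept_idx,
            "centroid_r": [c[0] for c in centroids],
            "centroid_c": [c[1] for c in centroids],
            "area": areas[keep].astype(int),
            "peak": peaks[keep],
        }
    )
    return spot_labels, table


def count_spots_per_cell(
    spots: pd.DataFrame,
    mask: np.ndarray,
    amplified_threshold: int = 5,
) -> list[CellSpotCount]:
    """Assign each spot to the cell containing its centroid pixel.

    Spots whose centroid falls on background (label 0) are dropped. Every cell
    in the mask appears in the output, including zero-spot cells. A cell is
    amplified when its count strictly exceeds ``amplified_threshold``.
    """
    mask = np.asarray(mask)
    cell_ids = np.unique(mask)
    cell_ids = cell_ids[cell_ids > 0]
    tally: dict[int, int] = {int(c): 0 for c in cell_ids}
    for row in spots.itertuples(index=False):
        r = int(round(row.centroid_r))
        c = int(round(row.centroid_c))
        r = min(max(r, 0), mask.shape[0] - 1)
        c = min(max(c, 0), mask.shape[1] - 1)
        owner = int(mask[r, c])
        if owner > 0:
            tally[owner] = tally.get(owner, 0) + 1
    return [
        CellSpotCount(cell_id=cid, spot_count=cnt, amplified=cnt > amplified_threshold)
        for cid, cnt in sorted(tally.items())
    ]


def quantify_image(
    image: np.ndarray,
    mask: np.ndarray,
    params: SpotCallParams = SpotCallParams(),
    amplified_threshold: int = 5,
) -> list[CellSpotCount]:
    """Normalize, detect spots and count per segmented cell in one call."""
    norm = normalize_image(image)
    _, table = detect_spots(norm, params)
    return count_spots_per_cell(table, mask, amplified_threshold)


def compare_heterogeneity(
    sample_counts: Mapping[str, Sequence[int]],
    reference: Sequence[int],
    amplified_threshold: int = 5,
    reference_name: str = "reference",
) -> HeterogeneityReport:
    """Compare each sample's per-cell copy-number distribution to a reference.

    Location: two-sided Mann-Whitney rank-sum test (normal approximation with
    tie correction, continuity correction on). Scale: Levene test centered at
    the mean. Each sample additionally reports n, mean, variance and the
    fraction of amplified cells.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 cells")
    report = HeterogeneityReport(reference_name=reference_name)
    report.per_sample[reference_name] = _group_summary(ref, amplified_threshold)
    for name, counts in sample_counts.items():
        arr = np.asarray(counts, dtype=float)
        if arr.size < 2:
            raise ValueError(f"sample {name!r} needs >= 2 cells")
        entry = _group_summary(arr, amplified_threshold)
        if np.array_equal(np.sort(arr), np.sort(ref)):
            # identical samples: rank-sum p is 1 by symmetry, Levene stat is 0
            entry["ranksum_stat"], entry["ranksum_p"] = float(arr.size**2 / 2), 1.0
            entry["levene_stat"], entry["levene_p"] = 0.0, 1.0
        else:
            u, up = stats.mannwhitneyu(
                arr, ref, alternative="two-sided", use_continuity=True,
                method="asymptotic",
            )
            if arr.var() == 0 and ref.var() == 0:
                # two constant groups: no spread to compare anywhere
                lv, lp = 0.0, 1.0
            else:
                lv, lp = stats.levene(arr, ref, center="mean")
            entry["ranksum_stat"], entry["ranksum_p"] = float(u), float(up)
            entry["levene_stat"], entry["levene_p"] = float(lv), float(lp)
        report.per_sample[name] = entry
    return report


def _group_summary(arr: np.ndarray, amplified_threshold: int) -> dict:
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "variance": float(arr.var(ddof=1)),
        "fraction_amplified": float(np.mean(arr > amplified_threshold)),
    }


def fallback_segment(image: np.ndarray, min_nucleus_area: int = 500) -> np.ndarray:
    """Threshold-based nucleus segmentation for synthetic fixtures.

    Otsu threshold on the normalized DAPI channel, hole filling, 8-connected
    labeling, then removal of components below the minimum nucleus area
    (default 500 px). Touching nuclei may merge into one label; intended for
    smoke tests, not production segmentation.
    """
    norm = normalize_image(image)
    if norm.max() == norm.min():
        return np.zeros_like(norm, dtype=np.int32)
    binary = norm > threshold_otsu(norm)
    filled = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(filled, structure=_EIGHT_CONN)
    if n == 0:
        return labels
    areas = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    keep = areas >= min_nucleus_area
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[np.arange(1, n + 1)[keep]] = np.arange(1, keep.sum() + 1)
    return remap[labels]
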