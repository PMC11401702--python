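"""Vertical strip extraction from OCT B-scans.

A candidate lesion mapped to column ``c`` of a B-scan is represented by a
30-pixel-wide vertical bar around that column, trimmed top and bottom to
a 170-row region of interest containing the retinal layers, giving a
fixed 170x30 strip.  Normal (lesion-free) strips are sampled the same
way at columns whose windows do not overlap any lesion window.

Coordinate convention (used throughout the package): 0-based
``(row, column)`` indices, origin at the top-left, half-open crops.
The 30-column window around center ``c`` is ``[c - 15, c + 15)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

#: strip geometry: rows x columns of every extracted strip
STRIP_HEIGHT = 170
STRIP_WIDTH = 30
HALF_WIDTH = STRIP_WIDTH // 2

#: nominal B-scan geometry (depth rows x lateral columns), 31 scans per eye
BSCAN_HEIGHT = 496
BSCAN_WIDTH = 768
BSCANS_PER_EYE = 31


@dataclass
class BScan:
    """One grayscale OCT cross-section (depth rows x lateral columns)."""

    image: np.ndarray
    eye_id: str = "synthetic"
    index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("B-scan image must be 2-D grayscale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class Strip:
    """A 170x30 crop labeled MA / normal / unknown.

    ``roi_top`` is the row offset of the crop inside the source B-scan,
    so ``bscan.image[roi_top:roi_top+170, center_column-15:center_column+15]``
    reproduces ``image`` exactly.
    """

    image: np.ndarray
    label: str = "unknown"
    eye_id: str = "synthetic"
    bscan_index: int = 0
    center_column: int = 0
    roi_top: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.shape != (STRIP_HEIGHT, STRIP_WIDTH):
            raise ValueError(
                f"strip must be {STRIP_HEIGHT}x{STRIP_WIDTH}, got {self.image.shape}"
            )
        if self.label not in ("MA", "normal", "unknown"):
            raise ValueError(f"unknown strip label {self.label!r}")


def trim_roi(column_window: np.ndarray, smooth_sigma: float = 5.0) -> tuple[np.ndarray, int]:
    """Trim a full-height column window to the 170-row retinal ROI.

    The retina is the bright horizontal band of the window; the ROI is
    located as the 170-row window maximizing the sum of the smoothed
    row-mean intensity profile, clamped to the image bounds.  A flat
    profile (no retinal signal) falls back to the centered window with a
    logged warning.

    Returns ``(roi_image, roi_top)``.
    """
    window = np.asarray(column_window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("column window must be 2-D")
    height = window.shape[0]
    if height < STRIP_HEIGHT:
        raise ValueError(f"window height {height} < ROI height {STRIP_HEIGHT}")
    if height == STRIP_HEIGHT:
        return window.copy(), 0

    profile = window.mean(axis=1)
    if np.ptp(profile) < 1e-9:
        roi_top = (height - STRIP_HEIGHT) // 2
        logger.warning("flat intensity profile, centering %d-row ROI at %d", STRIP_HEIGHT, roi_top)
        return window[roi_top : roi_top + STRIP_HEIGHT].copy(), roi_top

    smoothed = gaussian_filter1d(profile, smooth_sigma, mode="nearest")
    csum = np.concatenate([[0.0], np.cumsum(smoothed)])
    window_sums = csum[STRIP_HEIGHT:] - csum[: height - STRIP_HEIGHT + 1]
    roi_top = int(np.argmax(window_sums))
    return window[roi_top : roi_top + STRIP_HEIGHT].copy(), roi_top


def crop_strip(bscan: BScan, center_column: int, label: str = "unknown") -> Strip:
    """Cut the 170x30 strip around ``center_column`` from a B-scan.

    The 30-column window is ``[center-15, center+15)``; it must fit
    inside the B-scan width, otherwise a ``ValueError`` is raised.
    """
    height, width = bscan.shape
    c0 = center_column - HALF_WIDTH
    c1 = center_column + HALF_WIDTH
    if c0 < 0 or c1 > width:
        raise ValueError(
            f"strip out of bounds: window [{c0}, {c1}) exceeds B-scan width {width}"
        )
    roi, roi_top = trim_roi(bscan.image[:, c0:c1])
    return Strip(
        image=roi,
        label=label,
        eye_id=bscan.eye_id,
        bscan_index=bscan.index,
        center_column=int(center_column),
        roi_top=roi_top,
    )


def _window_overlaps(c_a: int, c_b: int) -> bool:
    # half-open windows [c-15, c+15) intersect iff |c_a - c_b| < 30
    return abs(int(c_a) - int(c_b)) < STRIP_WIDTH


def sample_normal_columns(
    bscan: BScan,
    exclusion_columns: list[int],
    n: int,
    rng: np.random.Generator,
) -> list[int]:
    """Sample ``n`` center columns for normal strips, avoiding MA windows.

    Candidate centers are those whose 30-px window fits in the B-scan
    and does not overlap the window of any excluded (MA) column.  Drawn
    without replacement; raises if fewer than ``n`` candidates exist.
    """
    width = bscan.shape[1]
    candidates = [
        c
        for c in range(HALF_WIDTH, width - HALF_WIDTH + 1)
        if not any(_window_overlaps(c, e) for e in exclusion_columns)
    ]
    if n > len(candidates):
        raise ValueError(
            f"requested {n} normal columns but only {len(candidates)} "
            "non-overlapping positions are available"
        )
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in chosen]
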