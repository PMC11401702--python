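"""Two-phase FA -> SLO registration.

Microaneurysm annotations live on the fluorescein angiogram; the OCT
B-scan stack is pixel-aligned to the device SLO image.  Registering FA
to SLO therefore maps every annotated MA point to a (B-scan index,
column) pair.

Phase I (rigid): vessel maps are extracted from both modalities with a
multiscale ridge (Frangi) filter, and normalized cross-correlation of
the maps is maximized over a coarse-to-fine grid of rotations and
scales, with the translation read off the correlation peak at each grid
point.

Phase II (local): around each MA point a patch of the affinely aligned
FA is shifted against the SLO over successively finer integer steps
(translation only), refining the mapping where it matters.

All rotations/scales act about the image center; points are (x, y) =
(column, row).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import frangi
from skimage.transform import AffineTransform, downscale_local_mean, warp

logger = logging.getLogger(__name__)


@dataclass
class VesselMap:
    """Soft vesselness map on the grid of its source image."""

    image: np.ndarray
    source: str  # "FA" or "SLO"


@dataclass
class AffineParams:
    """Similarity transform p_slo = c + s R (p_fa - c) + t, with the
    correlation score achieved at these parameters."""

    rotation: float  # degrees
    scale: float
    translation: tuple[float, float]  # (dx, dy) pixels
    correlation_score: float
    center: tuple[float, float] = (0.0, 0.0)  # (cx, cy)

    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation)
        s = self.scale
        cx, cy = self.center
        dx, dy = self.translation
        rs = np.array([[s * np.cos(th), -s * np.sin(th)], [s * np.sin(th), s * np.cos(th)]])
        m = np.eye(3)
        m[:2, :2] = rs
        m[:2, 2] = np.array([cx + dx, cy + dy]) - rs @ np.array([cx, cy])
        return m

    def forward(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=np.float64)
        m = self.matrix()
        return xy @ m[:2, :2].T + m[:2, 2]


@dataclass
class PatchResult:
    fa_point: tuple[float, float]
    center: tuple[float, float]  # mapped point in SLO coords, before refinement
    patch_size: int
    displacement: tuple[int, int]  # (dx, dy)
    score: float
    skipped: bool = False


@dataclass
class LocalRefinement:
    patches: list[PatchResult]
    resolution_schedule: tuple[int, ...]
    search_radius: int

    def displacement_for(self, fa_point) -> tuple[float, float]:
        """Displacement of the refinement patch recorded for ``fa_point``
        (nearest recorded point; (0, 0) if none was processed)."""
        pts = [p for p in self.patches if not p.skipped]
        if not pts:
            return (0.0, 0.0)
        q = np.asarray(fa_point, dtype=np.float64)
        dists = [np.hypot(p.fa_point[0] - q[0], p.fa_point[1] - q[1]) for p in pts]
        return pts[int(np.argmin(dists))].displacement


@dataclass
class MappedAnnotation:
    fa_point: tuple[float, float]
    bscan_index: int
    column: int


@dataclass
class StackGeometry:
    """SLO rows of the 31 B-scan acquisition lines, plus the SLO grid."""

    bscan_rows: np.ndarray
    image_shape: tuple[int, int]  # SLO (height, width)

    def __post_init__(self) -> None:
        self.bscan_rows = np.asarray(self.bscan_rows, dtype=np.float64)


@dataclass
class SearchGrid:
    """Coarse-to-fine rotation/scale grid for phase-I registration.

    The coarse grid is scanned first (optionally on downsampled maps);
    a mid grid one coarse step wide then a fine grid one mid step wide
    zoom in around the running best, so the effective resolution is the
    fine step while only a few hundred candidates are evaluated.
    """

    rotations: np.ndarray = field(default_factory=lambda: np.arange(-10.0, 10.0 + 1e-9, 1.0))
    scales: np.ndarray = field(default_factory=lambda: np.arange(0.90, 1.10 + 1e-9, 0.02))
    mid_rotation_step: float = 0.2
    mid_scale_step: float = 0.01
    fine_rotation_step: float = 0.1
    fine_scale_step: float = 0.005
    coarse_downsample: int = 4
    mid_downsample: int = 2
    max_translation: float | None = None


def extract_vessel_map(image: np.ndarray, modality: str = "FA") -> VesselMap:
    """Multiscale ridge (Frangi) vesselness of an en-face image.

    FA vessels are bright on dark; SLO vessels dark on bright, handled
    by the modality flag.  A constant image yields an all-zero map.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    modality = modality.upper()
    if modality not in ("FA", "SLO"):
        raise ValueError(f"unknown modality {modality!r}")
    if np.ptp(img) < 1e-12:
        return VesselMap(image=np.zeros_like(img), source=modality)
    vmap = frangi(
        img,
        sigmas=(1.0, 1.5, 2.0, 2.5),
        black_ridges=(modality == "SLO"),
        mode="reflect",
    )
    if vmap.max() > 0:
        vmap = vmap / vmap.max()
    return VesselMap(image=vmap, source=modality)


class _CorrReference:
    """Fixed image of the translation search, with its FFT cached."""

    def __init__(self, b: np.ndarray, max_translation: float | None = None):
        from scipy.fft import next_fast_len, rfft2

        self.shape = b.shape
        b0 = b - b.mean()
        self.bnorm = np.linalg.norm(b0)
        self.full_shape = (2 * b.shape[0] - 1, 2 * b.shape[1] - 1)
        self.fshape = (next_fast_len(self.full_shape[0]), next_fast_len(self.full_shape[1]))
        self.B = rfft2(b0, s=self.fshape)
        self.max_translation = max_translation

    def best_shift(self, a: np.ndarray):
        """Best integer shift (dy, dx) with ``b(y, x) ~ a(y-dy, x-dx)``,
        and the globally normalized zero-mean correlation score."""
        from scipy.fft import irfft2, rfft2

        a0 = a - a.mean()
        denom = np.linalg.norm(a0) * self.bnorm
        if denom == 0:
            return 0, 0, 0.0
        A = rfft2(a0[::-1, ::-1], s=self.fshape)
        c = irfft2(A * self.B, s=self.fshape)[: self.full_shape[0], : self.full_shape[1]]
        if self.max_translation is not None:
            ky = np.arange(c.shape[0]) - (a.shape[0] - 1)
            kx = np.arange(c.shape[1]) - (a.shape[1] - 1)
            mask = (np.abs(ky)[:, None] > self.max_translation) | (
                np.abs(kx)[None, :] > self.max_translation
            )
            c = np.where(mask, -np.inf, c)
        idx = np.unravel_index(np.argmax(c), c.shape)
        dy = int(idx[0] - (a.shape[0] - 1))
        dx = int(idx[1] - (a.shape[1] - 1))
        return dy, dx, float(c[idx] / denom)


def _xcorr_translation(a: np.ndarray, b: np.ndarray, max_translation: float | None = None):
    return _CorrReference(b, max_translation).best_shift(a)


def _warp_rot_scale(img: np.ndarray, rotation_deg: float, scale: float) -> np.ndarray:
    """Apply the translation-free similarity about the image center."""
    h, w = img.shape
    params = AffineParams(rotation_deg, scale, (0.0, 0.0), 0.0, center=(w / 2.0, h / 2.0))
    inv = np.linalg.inv(params.matrix())
    return warp(img, AffineTransform(matrix=inv), order=1, mode="constant", cval=0.0)


def _scan_grid(fa: np.ndarray, ref: _CorrReference, rotations, scales):
    best = None
    for rot in rotations:
        for sc in scales:
            fa_w = _warp_rot_scale(fa, rot, sc)
            dy, dx, score = ref.best_shift(fa_w)
            if best is None or score > best[0]:
                best = (score, float(rot), float(sc), dx, dy)
    return best


def _centered_range(center: float, half_width: float, step: float) -> np.ndarray:
    k = int(round(half_width / step))
    return center + np.arange(-k, k + 1) * step


def phase1_rigid(fa_map: VesselMap, slo_map: VesselMap, grid: SearchGrid = SearchGrid()) -> AffineParams:
    """Coarse-to-fine similarity search maximizing vessel-map correlation.

    Three passes: the full coarse grid (downsampled maps), a mid grid
    one coarse step wide around the best cell, and a fine grid one mid
    step wide at full resolution.  Each pass's grid contains the
    previous best, so with downsampling disabled the result never
    scores below any scanned grid point.
    """
    fa = np.asarray(fa_map.image, dtype=np.float64)
    slo = np.asarray(slo_map.image, dtype=np.float64)
    if len(grid.rotations) == 0 or len(grid.scales) == 0:
        raise ValueError("empty search grid")
    if np.ptp(fa) < 1e-12 or np.ptp(slo) < 1e-12:
        raise ValueError("no vessel signal in one of the maps")

    refs: dict[int, tuple[np.ndarray, _CorrReference]] = {}

    def level(f: int) -> tuple[np.ndarray, _CorrReference]:
        f = max(1, int(f))
        if f not in refs:
            if f == 1:
                fa_l, slo_l = fa, slo
            else:
                fa_l = downscale_local_mean(fa, (f, f))
                slo_l = downscale_local_mean(slo, (f, f))
            mt = None if grid.max_translation is None else grid.max_translation / f
            refs[f] = (fa_l, _CorrReference(slo_l, mt))
        return refs[f]

    fa_c, ref_c = level(grid.coarse_downsample)
    _, rot_c, sc_c, _, _ = _scan_grid(fa_c, ref_c, grid.rotations, grid.scales)

    rot_step = np.diff(grid.rotations).max() if len(grid.rotations) > 1 else grid.mid_rotation_step
    sc_step = np.diff(grid.scales).max() if len(grid.scales) > 1 else grid.mid_scale_step
    fa_m, ref_m = level(grid.mid_downsample)
    mid_scales = _centered_range(sc_c, sc_step, grid.mid_scale_step)
    _, rot_m, sc_m, _, _ = _scan_grid(
        fa_m,
        ref_m,
        _centered_range(rot_c, rot_step, grid.mid_rotation_step),
        mid_scales[mid_scales > 0],
    )

    fa_f, ref_f = level(1)
    fine_scales = _centered_range(sc_m, grid.mid_scale_step, grid.fine_scale_step)
    score, rot, sc, dx, dy = _scan_grid(
        fa_f,
        ref_f,
        _centered_range(rot_m, grid.mid_rotation_step, grid.fine_rotation_step),
        fine_scales[fine_scales > 0],
    )

    h, w = fa.shape
    return AffineParams(
        rotation=rot,
        scale=sc,
        translation=(float(dx), float(dy)),
        correlation_score=score,
        center=(w / 2.0, h / 2.0),
    )


def _zncc_patch(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.linalg.norm(a0) * np.linalg.norm(b0)
    if denom == 0:
        return 0.0
    return float(np.sum(a0 * b0) / denom)


def phase2_local(
    fa: np.ndarray,
    slo: np.ndarray,
    affine: AffineParams,
    ma_points,
    schedule: tuple[int, ...] = (4, 2, 1),
    patch_size: int = 64,
    search_radius: int = 8,
    invert_slo: bool = True,
) -> LocalRefinement:
    """Translation-only patch refinement at each MA point.

    The FA image is warped into the SLO frame by the phase-I affine;
    around each mapped point, the patch displacement maximizing ZNCC is
    searched at each step of the schedule (each pass scans multiples of
    its step within the reach of the previous pass, starting from the
    full search radius).  A patch falling outside either image is
    skipped with a logged warning.

    ``invert_slo`` flips the SLO intensities before matching, since SLO
    vessel contrast is inverted relative to FA (dark on bright); pass
    False when matching same-polarity inputs such as vessel maps.
    """
    fa = np.asarray(fa, dtype=np.float64)
    slo = np.asarray(slo, dtype=np.float64)
    if invert_slo:
        slo = slo.max() - slo
    if len(schedule) == 0:
        raise ValueError("empty refinement schedule")
    inv = np.linalg.inv(affine.matrix())
    fa_aligned = warp(fa, AffineTransform(matrix=inv), output_shape=slo.shape, order=1, mode="constant")

    half = patch_size // 2
    results: list[PatchResult] = []
    for pt in np.atleast_2d(np.asarray(ma_points, dtype=np.float64)):
        q = affine.forward(pt)
        cx, cy = int(round(q[0])), int(round(q[1]))
        r0, r1 = cy - half, cy + half
        c0, c1 = cx - half, cx + half
        pad = search_radius
        if (
            r0 < 0
            or c0 < 0
            or r1 > fa_aligned.shape[0]
            or c1 > fa_aligned.shape[1]
            or r0 - pad < 0
            or c0 - pad < 0
            or r1 + pad > slo.shape[0]
            or c1 + pad > slo.shape[1]
        ):
            logger.warning("refinement patch at %s falls outside the image; skipped", (cx, cy))
            results.append(
                PatchResult(tuple(pt), (float(q[0]), float(q[1])), patch_size, (0, 0), np.nan, skipped=True)
            )
            continue
        ref = fa_aligned[r0:r1, c0:c1]

        def score_at(dx: int, dy: int) -> float:
            return _zncc_patch(ref, slo[r0 + dy : r1 + dy, c0 + dx : c1 + dx])

        best_dx, best_dy = 0, 0
        best_score = score_at(0, 0)
        reach = search_radius
        for step in schedule:
            offsets = range(-(reach // step) * step, (reach // step) * step + 1, step)
            for ddy in offsets:
                for ddx in offsets:
                    dx = int(np.clip(best_dx + ddx, -search_radius, search_radius))
                    dy = int(np.clip(best_dy + ddy, -search_radius, search_radius))
                    s = score_at(dx, dy)
                    if s > best_score:
                        best_score, best_dx, best_dy = s, dx, dy
            reach = step
        results.append(
            PatchResult(
                fa_point=tuple(pt),
                center=(float(q[0]), float(q[1])),
                patch_size=patch_size,
                displacement=(best_dx, best_dy),
                score=best_score,
            )
        )
    return LocalRefinement(patches=results, resolution_schedule=tuple(schedule), search_radius=search_radius)


def map_fa_point_to_bscan(
    point,
    affine: AffineParams,
    refinement: LocalRefinement | None,
    stack_geometry: StackGeometry,
) -> MappedAnnotation:
    """Map an FA annotation to (B-scan index, column).

    The point is pushed through the affine plus its local refinement
    displacement; the nearest B-scan acquisition row is selected (ties
    break to the lower index) and the column is rounded to the nearest
    pixel.
    """
    pt = np.asarray(point, dtype=np.float64)
    q = affine.forward(pt)
    if refinement is not None:
        dx, dy = refinement.displacement_for(pt)
        q = q + np.array([dx, dy], dtype=np.float64)
    height, width = stack_geometry.image_shape
    rows = stack_geometry.bscan_rows
    spacing = np.diff(rows).mean() if rows.size > 1 else height
    if not (0 <= q[0] < width) or q[1] < rows.min() - spacing / 2 or q[1] > rows.max() + spacing / 2:
        raise ValueError(f"annotation outside stack: FA point {tuple(pt)} maps to {tuple(q)}")
    # np.argmin returns the first minimum: with ascending rows an
    # equidistant point resolves to the lower index
    index = int(np.argmin(np.abs(rows - q[1])))
    column = int(np.floor(q[0] + 0.5))
    return MappedAnnotation(fa_point=tuple(pt), bscan_index=index, column=column)
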