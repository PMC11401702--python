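"""Synthetic OCT / en-face data with known ground truth.

The generator renders the minimal image model that exhibits the
appearance facts the pipeline relies on:

* **B-scans** are stacks of horizontal Gaussian-profile reflectivity
  bands (bright/dark alternation mimicking NFL..RPE), deformed by a
  smooth cosine foveal dip that attenuates with depth, multiplied by
  Rayleigh-like speckle.  A microaneurysm is a hyperreflective filled
  disc implanted in a configurable band (emulating the inner nuclear
  layer) together with a local upward bulge of the overlying bands —
  MAs thicken the retina.  Bulge amplitude scales with lesion contrast
  (a faint lesion also deforms less).
* **En-face pairs** share one random branching vessel tree: the FA
  image shows bright vessels on a dark background with hyperfluorescent
  dots at MA sites; the SLO twin shows the same tree with inverted
  contrast, no dots, and its geometry transformed by a known affine
  (+ optional smooth local) warp.  The B-scan stack is pixel-aligned to
  the SLO, with the 31 scan rows uniformly spaced.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from octma.strips import (
    BSCANS_PER_EYE,
    BSCAN_HEIGHT,
    BSCAN_WIDTH,
    HALF_WIDTH,
    STRIP_WIDTH,
    BScan,
    Strip,
    trim_roi,
)

_BACKGROUND = 0.03
# Gaussian profile sigma of en-face vessel strokes; ~2.8 px gives the
# 6-10 px full width of major retinal vessels on SLO/FA
_VESSEL_SIGMA = 2.8


@dataclass(frozen=True)
class WarpParams:
    """Forward FA -> SLO warp: rotate/scale about the image center, then
    translate, plus an optional smooth sinusoidal local displacement."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)  # (dx, dy) pixels
    local_amplitude: float = 0.0  # pixels
    local_wavelength: float = 250.0  # pixels

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("degenerate warp: scale must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    image_height: int = BSCAN_HEIGHT
    image_width: int = BSCAN_WIDTH
    n_layers: int = 7
    layer_reflectivities: tuple[float, ...] = (0.55, 0.25, 0.50, 0.22, 0.45, 0.30, 0.85)
    retina_top: float = 175.0  # row of the innermost band's anchor
    retina_depth: float = 120.0  # pixels spanned by the band stack
    foveal_dip_depth: float = 30.0  # pixels
    speckle_sigma: float = 0.12  # multiplicative noise scale
    lesion_radius: float = 6.0  # pixels
    lesion_contrast: float = 0.30  # additive intensity in [0, 1]
    lesion_depth_band: int = 3  # band emulating the inner nuclear layer
    lesion_bulge: float | None = None  # pixels; None -> 20 * lesion_contrast
    # registration residual + crop quantization: lesions in training
    # strips sit up to this many pixels off the strip center
    lesion_jitter: float = 5.0
    # inter-eye heterogeneity of the strip dataset (the study pools
    # strips over 20 patients): per-strip coefficients of variation of
    # band reflectivity and of retinal thickness
    eye_reflectivity_cv: float = 0.15
    eye_geometry_cv: float = 0.10
    n_vessels: int = 3  # en-face vessel trunks
    vessel_branching: float = 0.03  # branching probability per walk step
    enface_noise: float = 0.01  # additive Gaussian noise on en-face images
    normal_strips_avoid_vessels: bool = True
    warp: WarpParams = field(default_factory=WarpParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not all(0.0 <= r <= 1.0 for r in self.layer_reflectivities):
            raise ValueError("layer reflectivities must lie in [0, 1]")
        if len(self.layer_reflectivities) != self.n_layers:
            raise ValueError("need one reflectivity per layer")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must lie in [0, 1]")
        if self.lesion_radius >= STRIP_WIDTH / 2:
            raise ValueError(
                f"lesion_radius must be < {STRIP_WIDTH / 2} (half the strip width)"
            )
        if not 0 <= self.lesion_depth_band < self.n_layers:
            raise ValueError("lesion_depth_band out of range")

    @property
    def bulge_amplitude(self) -> float:
        if self.lesion_bulge is not None:
            return self.lesion_bulge
        return 20.0 * self.lesion_contrast


@dataclass
class TrueWarp:
    """Realized warp relating FA and SLO coordinates (xy convention)."""

    params: WarpParams
    center: tuple[float, float]  # (cx, cy)
    local_phases: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.params.rotation_deg)
        s = self.params.scale
        cx, cy = self.center
        dx, dy = self.params.translation
        rs = np.array([[s * np.cos(th), -s * np.sin(th)], [s * np.sin(th), s * np.cos(th)]])
        m = np.eye(3)
        m[:2, :2] = rs
        m[:2, 2] = np.array([cx + dx, cy + dy]) - rs @ np.array([cx, cy])
        return m

    def local_displacement(self, xy: np.ndarray) -> np.ndarray:
        a = self.params.local_amplitude
        if a == 0:
            return np.zeros_like(xy, dtype=np.float64)
        w = 2 * np.pi / self.params.local_wavelength
        p1, p2, p3, p4 = self.local_phases
        x, y = xy[..., 0], xy[..., 1]
        dx = a * np.sin(w * x + p1) * np.sin(w * y + p2)
        dy = a * np.sin(w * x + p3) * np.sin(w * y + p4)
        return np.stack([dx, dy], axis=-1)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Forward map of FA points into SLO coordinates."""
        xy = np.asarray(xy, dtype=np.float64)
        moved = xy + self.local_displacement(xy)
        m = self.matrix()
        return moved @ m[:2, :2].T + m[:2, 2]

    def apply_inverse(self, xy: np.ndarray) -> np.ndarray:
        """SLO points back to FA coordinates (first-order in the smooth
        local field, exact when its amplitude is zero)."""
        xy = np.asarray(xy, dtype=np.float64)
        minv = np.linalg.inv(self.matrix())
        q = xy @ minv[:2, :2].T + minv[:2, 2]
        return q - self.local_displacement(q)


@dataclass
class GroundTruth:
    lesion_columns: list[int] = field(default_factory=list)
    true_warp: TrueWarp | None = None
    labels: dict[str, str] = field(default_factory=dict)
    band_extent: tuple[float, float] | None = None  # (top row, bottom row)
    fa_vessel_mask: np.ndarray | None = None
    slo_vessel_mask: np.ndarray | None = None
    ma_points: np.ndarray | None = None  # (n, 2) xy on FA
    ma_points_slo: np.ndarray | None = None  # forward-warped, xy on SLO
    bscan_rows: np.ndarray | None = None  # SLO row of each B-scan line


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _band_centers(config: SyntheticConfig, columns: np.ndarray, lesion_columns) -> np.ndarray:
    """Row position of each band center at each column, shape (n_layers, n_cols)."""
    n = config.n_layers
    cols = np.asarray(columns, dtype=np.float64)
    offsets = (np.arange(n) + 0.5) * config.retina_depth / n
    cx = config.image_width / 2.0
    w = 0.2 * config.image_width
    rel = np.clip(np.abs(cols - cx) / w, 0.0, 1.0)
    dip = config.foveal_dip_depth * np.cos(np.pi * rel / 2.0) ** 2
    depth_factor = 1.0 - np.arange(n) / max(n - 1, 1)
    centers = (
        config.retina_top
        + offsets[:, None]
        + dip[None, :] * depth_factor[:, None]
    )
    if lesion_columns:
        bulge = np.zeros_like(cols)
        for lc in lesion_columns:
            bulge += config.bulge_amplitude * np.exp(
                -((cols - lc) ** 2) / (2.0 * (2.0 * config.lesion_radius) ** 2)
            )
        above = np.arange(n) <= config.lesion_depth_band
        centers = centers - bulge[None, :] * above[:, None]
    return centers


def _render_columns(
    config: SyntheticConfig, columns: np.ndarray, lesion_columns=()
) -> tuple[np.ndarray, tuple[float, float]]:
    """Noiseless template restricted to the given absolute columns."""
    lesion_columns = list(lesion_columns)
    height = config.image_height
    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.asarray(columns, dtype=np.float64)[None, :]
    centers = _band_centers(config, np.asarray(columns), lesion_columns)
    sigma = 0.30 * config.retina_depth / config.n_layers
    template = np.full((height, cols.size), _BACKGROUND)
    for k in range(config.n_layers):
        template += config.layer_reflectivities[k] * np.exp(
            -((rows - centers[k][None, :]) ** 2) / (2.0 * sigma**2)
        )
    for lc in lesion_columns:
        ci = int(np.argmin(np.abs(np.asarray(columns) - lc)))
        r_l = centers[config.lesion_depth_band, ci]
        dist = np.sqrt((rows - r_l) ** 2 + (cols - lc) ** 2)
        disc = 1.0 / (1.0 + np.exp(np.clip((dist - config.lesion_radius) / 0.7, -60.0, 60.0)))
        template += config.lesion_contrast * disc
    extent = (float(centers.min() - 3 * sigma), float(centers.max() + 3 * sigma))
    return np.clip(template, 0.0, 1.0), extent


def _speckle(template: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return template.copy()
    # Rayleigh multiplier rescaled to unit mean, blended by sigma
    ray = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=template.shape)
    return np.clip(template * (1.0 + sigma * (ray - 1.0)), 0.0, 1.0)


def noiseless_template(config: SyntheticConfig, lesion_columns=()) -> np.ndarray:
    """Full-width layered template without speckle (reference image)."""
    img, _ = _render_columns(config, np.arange(config.image_width), lesion_columns)
    return img


def generate_bscan(
    config: SyntheticConfig,
    rng_state=None,
    lesion_columns=(),
    eye_id: str = "synthetic",
    index: int = 0,
) -> tuple[BScan, GroundTruth]:
    """Render one B-scan, optionally with implanted lesions.

    Each lesion is a hyperreflective disc of ``lesion_radius`` centered
    in the configured depth band at the given column, with a local
    upward bulge of the overlying bands.  Lesion columns must leave the
    disc fully inside the image.
    """
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    margin = int(np.ceil(config.lesion_radius))
    for lc in lesion_columns:
        if lc - margin < 0 or lc + margin >= config.image_width:
            raise ValueError(
                f"lesion at column {lc} falls outside the {config.image_width}-wide image"
            )
    template, extent = _render_columns(
        config, np.arange(config.image_width), lesion_columns
    )
    image = _speckle(template, config.speckle_sigma, rng)
    gt = GroundTruth(lesion_columns=[int(c) for c in lesion_columns], band_extent=extent)
    return BScan(image=image, eye_id=eye_id, index=index), gt


def _vessel_scene(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Soft vessel-tree intensity map in FA coordinates, values in [0, 1]."""
    height, width = config.image_height, config.image_width
    scene = np.zeros((height, width))
    if config.n_vessels == 0:
        return scene
    walkers = []
    for _ in range(config.n_vessels):
        edge = rng.integers(4)
        if edge == 0:  # left
            pos = np.array([0.0, rng.uniform(0.15, 0.85) * height])
            ang = rng.uniform(-0.5, 0.5)
        elif edge == 1:  # right
            pos = np.array([width - 1.0, rng.uniform(0.15, 0.85) * height])
            ang = np.pi + rng.uniform(-0.5, 0.5)
        elif edge == 2:  # top
            pos = np.array([rng.uniform(0.15, 0.85) * width, 0.0])
            ang = np.pi / 2 + rng.uniform(-0.5, 0.5)
        else:  # bottom
            pos = np.array([rng.uniform(0.15, 0.85) * width, height - 1.0])
            ang = -np.pi / 2 + rng.uniform(-0.5, 0.5)
        walkers.append((pos, ang))
    step = 1.5
    max_walkers = 32
    max_steps = int(1.5 * max(height, width) / step)
    for _ in range(max_steps):
        new_walkers = []
        for pos, ang in walkers:
            ang = ang + rng.normal(0.0, 0.08)
            pos = pos + step * np.array([np.cos(ang), np.sin(ang)])
            x, y = pos
            if not (0 <= x < width and 0 <= y < height):
                continue
            scene[int(y), int(x)] = 1.0
            if rng.random() < config.vessel_branching and len(walkers) + len(new_walkers) < max_walkers:
                new_walkers.append((pos.copy(), ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9)))
            new_walkers.append((pos, ang))
        walkers = new_walkers
        if not walkers:
            break
    scene = gaussian_filter(scene, _VESSEL_SIGMA)
    if scene.max() > 0:
        scene = scene / scene.max()
    return scene


def generate_enface_pair(
    config: SyntheticConfig,
    rng_state=None,
    n_ma_points: int = 5,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Paired FA / SLO en-face images related by a known warp.

    Both contain the same branching vessel tree.  The FA image shows
    bright vessels plus hyperfluorescent MA dots; the SLO twin shows
    the tree with inverted contrast, no dots, under ``config.warp``.
    """
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    height, width = config.image_height, config.image_width
    scene = _vessel_scene(config, rng)
    warp = TrueWarp(
        params=config.warp,
        center=(width / 2.0, height / 2.0),
        local_phases=tuple(rng.uniform(0, 2 * np.pi, size=4)),
    )

    # MA dots sit just off vessel centerlines
    vessel_mask = scene > 0.3
    ys, xs = np.nonzero(vessel_mask)
    ma_points = np.zeros((0, 2))
    if n_ma_points > 0 and xs.size > 0:
        pts = []
        # keep annotations inside the region the 31 B-scan lines cover
        margin = int(0.12 * min(height, width))
        interior = (xs > margin) & (xs < width - margin) & (ys > margin) & (ys < height - margin)
        xi, yi = xs[interior], ys[interior]
        if xi.size > 0:
            idx = rng.choice(xi.size, size=min(n_ma_points, xi.size), replace=False)
            for i in idx:
                off = rng.uniform(2.0, 5.0) * rng.choice([-1.0, 1.0], size=2)
                pts.append([xi[i] + off[0], yi[i] + off[1]])
        ma_points = np.array(pts) if pts else np.zeros((0, 2))

    fa = 0.12 + 0.75 * scene
    yy, xx = np.mgrid[0:height, 0:width]
    for x, y in ma_points:
        dist = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
        fa += 0.5 * np.exp(-(dist**2) / (2.0 * 2.0**2))

    # render the SLO by pulling the scene back through the inverse warp
    slo_xy = np.stack([xx.ravel(), yy.ravel()], axis=-1).astype(np.float64)
    fa_xy = warp.apply_inverse(slo_xy)
    coords = np.stack([fa_xy[:, 1].reshape(height, width), fa_xy[:, 0].reshape(height, width)])
    scene_slo = map_coordinates(scene, coords, order=1, mode="constant", cval=0.0)
    slo = 0.85 - 0.60 * scene_slo

    if config.enface_noise > 0:
        fa = fa + rng.normal(0.0, config.enface_noise, fa.shape)
        slo = slo + rng.normal(0.0, config.enface_noise, slo.shape)
    fa = np.clip(fa, 0.0, 1.0)
    slo = np.clip(slo, 0.0, 1.0)

    rows = np.linspace(height * 0.1, height * 0.9, BSCANS_PER_EYE)
    gt = GroundTruth(
        true_warp=warp,
        fa_vessel_mask=vessel_mask,
        slo_vessel_mask=scene_slo > 0.3,
        ma_points=ma_points,
        ma_points_slo=warp.apply(ma_points) if ma_points.size else np.zeros((0, 2)),
        bscan_rows=rows,
    )
    return fa, slo, gt


def _vary_eye(config: SyntheticConfig, rng: np.random.Generator) -> SyntheticConfig:
    """Per-strip eye-level variation: band reflectivities and retinal
    thickness drawn around the nominal values (the study pools strips
    from many patients, so strips are not renders of one fixed eye)."""
    if config.eye_reflectivity_cv == 0 and config.eye_geometry_cv == 0:
        return config
    refl = np.clip(
        np.asarray(config.layer_reflectivities)
        * rng.normal(1.0, config.eye_reflectivity_cv, size=config.n_layers),
        0.0,
        1.0,
    )
    depth = config.retina_depth * float(np.clip(rng.normal(1.0, config.eye_geometry_cv), 0.6, 1.4))
    return dataclasses.replace(
        config, layer_reflectivities=tuple(refl), retina_depth=depth
    )


def generate_strip_dataset(
    n_ma: int,
    n_normal: int,
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
) -> list[Strip]:
    """Labeled 170x30 strips: ``n_ma`` with one centered lesion each,
    ``n_normal`` lesion-free, with per-strip provenance.

    Strips are rendered as independent 30-column B-scan windows (full
    height, then ROI-trimmed), which is equivalent to cropping freshly
    generated full B-scans at the lesion columns but much cheaper.
    """
    if n_ma < 0 or n_normal < 0:
        raise ValueError("strip counts must be non-negative")
    rng = np.random.default_rng(seed)
    margin = HALF_WIDTH + 1
    strips: list[Strip] = []
    jitter = int(config.lesion_jitter)
    for i in range(n_ma + n_normal):
        is_ma = i < n_ma
        center = int(rng.integers(margin + jitter, config.image_width - margin - jitter))
        lesion_col = center + int(rng.integers(-jitter, jitter + 1)) if is_ma else None
        cols = np.arange(center - HALF_WIDTH, center + HALF_WIDTH)
        strip_config = _vary_eye(config, rng)
        template, _ = _render_columns(strip_config, cols, [lesion_col] if is_ma else [])
        window = _speckle(template, config.speckle_sigma, rng)
        roi, roi_top = trim_roi(window)
        strips.append(
            Strip(
                image=roi,
                label="MA" if is_ma else "normal",
                eye_id="synthetic",
                bscan_index=0,
                center_column=center,
                roi_top=roi_top,
                provenance={"seed": seed, "index": i, "lesion_column": lesion_col},
            )
        )
    return strips
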