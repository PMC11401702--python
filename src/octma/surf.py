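"""Dense SURF descriptors for OCT strips.

Each 170x30 strip is divided into an 8x8 grid and one SURF descriptor is
computed at the center of every cell (dense sampling at a fixed scale;
no Fast-Hessian interest-point detection).  The descriptor follows the
standard SURF construction: Haar wavelet responses read off an integral
image, a dominant orientation from a sliding pi/3 window over
Gaussian-weighted responses in a radius-6s neighbourhood, and a 4x4
subregion layout with (sum dx, sum |dx|, sum dy, sum |dy|) per
subregion, giving a 64-dimensional L2-normalized vector.

Everything here is deterministic: no randomness enters feature
extraction.

Coordinates are (row, col) with y increasing downward; orientations are
``atan2(dy, dx)`` in that frame, in ``[0, 2*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# standard SURF constants
_ORI_RADIUS = 6  # orientation neighbourhood radius, in units of s
_ORI_SIGMA = 2.0  # Gaussian sigma of orientation weights, in units of s
_ORI_WINDOW = np.pi / 3  # sliding orientation window width
_N_ORI_WINDOWS = 40
_DESC_HALF = 10  # descriptor square is 20s x 20s
_DESC_SIGMA = 3.3  # Gaussian sigma of descriptor weights, in units of s
_N_SUB = 4  # 4x4 subregions, 5x5 samples each
# responses below this are summation noise of a constant patch, not signal
_DEGENERATE_EPS = 1e-8


@dataclass(frozen=True)
class SurfParams:
    """Dense-SURF extraction parameters.

    scale: keypoint scale ``s`` in pixels (Haar filter sides and window
        extents are multiples of it).
    grid: keypoints per strip, rows x cols.
    upright: skip orientation assignment (orientation fixed to 0).
    """

    scale: float = 1.6
    grid: tuple[int, int] = (8, 8)
    upright: bool = False


@dataclass
class Keypoint:
    row: float
    col: float
    scale: float
    orientation: float = 0.0


@dataclass
class Descriptor:
    vector: np.ndarray
    keypoint: Keypoint
    degenerate: bool = False


@dataclass
class DescriptorSet:
    descriptors: list[Descriptor]
    grid_shape: tuple[int, int] = (8, 8)

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def matrix(self) -> np.ndarray:
        """All descriptor vectors stacked, shape (n_keypoints, 64)."""
        return np.stack([d.vector for d in self.descriptors])


@dataclass
class IntegralImage:
    """Summed-area table; box sums of half-open rectangles in 4 lookups.

    ``pad`` rows/cols of edge-replicated padding may surround the source
    so that Haar windows of boundary keypoints stay fully inside the
    table; box coordinates are always in the unpadded image frame.
    """

    table: np.ndarray
    pad: int = 0
    source_shape: tuple[int, int] = (0, 0)

    def box_sum(self, r0, c0, r1, c1) -> np.ndarray:
        """Sum of the source over rows [r0, r1), cols [c0, c1)."""
        t = self.table
        p = self.pad
        r0 = np.clip(np.asarray(r0) + p, 0, t.shape[0] - 1)
        r1 = np.clip(np.asarray(r1) + p, 0, t.shape[0] - 1)
        c0 = np.clip(np.asarray(c0) + p, 0, t.shape[1] - 1)
        c1 = np.clip(np.asarray(c1) + p, 0, t.shape[1] - 1)
        return t[r1, c1] - t[r0, c1] - t[r1, c0] + t[r0, c0]


def integral_image(image: np.ndarray, pad: int = 0) -> IntegralImage:
    """Build a summed-area table, optionally over edge-replicated padding."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("integral image requires a non-empty 2-D image")
    if pad:
        img = np.pad(img, pad, mode="edge")
    table = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    table[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    return IntegralImage(table=table, pad=pad, source_shape=image.shape)


def _haar(ii: IntegralImage, rows, cols, size: int):
    """Axis-aligned Haar responses at integer sample centers.

    ``size`` is the full filter side; the x-filter is [-1 | +1] left to
    right, the y-filter [-1 / +1] top to bottom (y increases downward).
    """
    h = size // 2
    r, c = np.asarray(rows), np.asarray(cols)
    dx = ii.box_sum(r - h, c, r + h, c + h) - ii.box_sum(r - h, c - h, r + h, c)
    dy = ii.box_sum(r, c - h, r + h, c + h) - ii.box_sum(r - h, c - h, r, c + h)
    return dx, dy


def dense_keypoints(
    strip_shape: tuple[int, int], grid: tuple[int, int] = (8, 8), scale: float = 1.6
) -> list[Keypoint]:
    """One keypoint at each cell center of a grid covering the strip.

    170 and 30 are not divisible by 8, so cell boundaries are rounded
    cumulative splits (cells differ by at most one pixel); the keypoint
    sits at the center of its cell.
    """
    height, width = strip_shape
    grows, gcols = grid
    if grows > height or gcols > width:
        raise ValueError(f"grid {grid} larger than strip {strip_shape}")
    rsplit = np.round(np.arange(grows + 1) * height / grows).astype(int)
    csplit = np.round(np.arange(gcols + 1) * width / gcols).astype(int)
    kps = []
    for i in range(grows):
        rc = (rsplit[i] + rsplit[i + 1] - 1) / 2.0
        for j in range(gcols):
            cc = (csplit[j] + csplit[j + 1] - 1) / 2.0
            kps.append(Keypoint(row=rc, col=cc, scale=scale))
    return kps


def _orientation_offsets() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ij = [
        (i, j)
        for i in range(-_ORI_RADIUS, _ORI_RADIUS + 1)
        for j in range(-_ORI_RADIUS, _ORI_RADIUS + 1)
        if i * i + j * j <= _ORI_RADIUS * _ORI_RADIUS
    ]
    di = np.array([p[0] for p in ij], dtype=float)  # row offset, units of s
    dj = np.array([p[1] for p in ij], dtype=float)  # col offset, units of s
    g = np.exp(-(di**2 + dj**2) / (2.0 * _ORI_SIGMA**2))
    return di, dj, g


def _assign_orientations(ii: IntegralImage, rows, cols, scale: float) -> np.ndarray:
    """Dominant orientations for keypoints at (rows, cols), vectorized."""
    di, dj, g = _orientation_offsets()
    rows = np.atleast_1d(np.asarray(rows, dtype=float))
    cols = np.atleast_1d(np.asarray(cols, dtype=float))
    sr = np.rint(rows[:, None] + di[None, :] * scale).astype(int)
    sc = np.rint(cols[:, None] + dj[None, :] * scale).astype(int)
    size = max(2, 2 * int(round(2 * scale)))  # Haar side 4s
    dx, dy = _haar(ii, sr, sc, size)
    wx = dx * g
    wy = dy * g
    phi = np.arctan2(wy, wx)  # (K, Ns)

    anchors = np.arange(_N_ORI_WINDOWS) * (2 * np.pi / _N_ORI_WINDOWS)
    # membership of each sample in each sliding window [theta, theta + pi/3)
    rel = np.mod(phi[:, None, :] - anchors[None, :, None], 2 * np.pi)
    mask = rel < _ORI_WINDOW
    sx = np.einsum("kws,ks->kw", mask.astype(float), wx)
    sy = np.einsum("kws,ks->kw", mask.astype(float), wy)
    norm2 = sx**2 + sy**2
    best = np.argmax(norm2, axis=1)
    idx = np.arange(rows.size)
    ori = np.arctan2(sy[idx, best], sx[idx, best]) % (2 * np.pi)
    ori[norm2[idx, best] < _DEGENERATE_EPS**2] = 0.0  # zero response: orientation 0
    return ori


def assign_orientation(ii: IntegralImage, kp: Keypoint) -> Keypoint:
    """Return a copy of ``kp`` with its dominant orientation assigned.

    Haar responses (filter side 4s) at samples within radius 6s of the
    keypoint are Gaussian-weighted (sigma 2s); a pi/3 window slides over
    their angles and the orientation of the maximal summed response
    vector wins.  Constant neighbourhoods yield orientation 0.
    """
    ori = _assign_orientations(ii, [kp.row], [kp.col], kp.scale)[0]
    return Keypoint(row=kp.row, col=kp.col, scale=kp.scale, orientation=float(ori))


def _descriptor_offsets() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    coords = np.arange(2 * _DESC_HALF) - (_DESC_HALF - 0.5)  # -9.5 .. 9.5
    u, v = np.meshgrid(coords, coords, indexing="xy")  # u: x-dir, v: y-dir
    u, v = u.ravel(), v.ravel()
    g = np.exp(-(u**2 + v**2) / (2.0 * _DESC_SIGMA**2))
    sub = (
        ((v + _DESC_HALF) // (2 * _DESC_HALF // _N_SUB)).astype(int) * _N_SUB
        + ((u + _DESC_HALF) // (2 * _DESC_HALF // _N_SUB)).astype(int)
    )
    onehot = np.zeros((u.size, _N_SUB * _N_SUB))
    onehot[np.arange(u.size), sub] = 1.0
    return u, v, g, onehot


def _describe_many(ii: IntegralImage, rows, cols, orientations, scale: float):
    """64-d descriptors for keypoints at (rows, cols), vectorized.

    Returns ``(vectors, degenerate)`` with shapes (K, 64) and (K,).
    """
    u, v, g, onehot = _descriptor_offsets()
    rows = np.atleast_1d(np.asarray(rows, dtype=float))
    cols = np.atleast_1d(np.asarray(cols, dtype=float))
    theta = np.atleast_1d(np.asarray(orientations, dtype=float))
    ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]

    # rotate the sampling grid into the keypoint frame
    x = scale * (u[None, :] * ct - v[None, :] * st)
    y = scale * (u[None, :] * st + v[None, :] * ct)
    sr = np.rint(rows[:, None] + y).astype(int)
    sc = np.rint(cols[:, None] + x).astype(int)
    size = max(2, 2 * int(round(scale)))  # Haar side 2s
    dx, dy = _haar(ii, sr, sc, size)
    # rotate responses into the keypoint frame and weight
    du = (ct * dx + st * dy) * g[None, :]
    dv = (-st * dx + ct * dy) * g[None, :]

    feats = np.stack(
        [du @ onehot, np.abs(du) @ onehot, dv @ onehot, np.abs(dv) @ onehot], axis=2
    )  # (K, 16, 4)
    vec = feats.reshape(rows.size, 64)
    norms = np.linalg.norm(vec, axis=1)
    degenerate = norms < _DEGENERATE_EPS
    vec = np.where(degenerate[:, None], np.zeros_like(vec), vec / np.where(degenerate, 1.0, norms)[:, None])
    return vec, degenerate


def describe(ii: IntegralImage, kp: Keypoint) -> Descriptor:
    """SURF descriptor of one oriented keypoint.

    A 20s-sided square aligned with the keypoint orientation is sampled
    on a 20x20 grid (5x5 per subregion); Haar responses (side 2s,
    Gaussian sigma 3.3s) are rotated into the keypoint frame and summed
    per subregion as (sum dx, sum |dx|, sum dy, sum |dy|), then the 64-d
    concatenation is L2-normalized.  An all-constant patch yields the
    zero vector, flagged degenerate.
    """
    vec, degen = _describe_many(ii, [kp.row], [kp.col], [kp.orientation], kp.scale)
    return Descriptor(vector=vec[0], keypoint=kp, degenerate=bool(degen[0]))


def extract_strip_features(strip, params: SurfParams = SurfParams()) -> DescriptorSet:
    """Dense SURF descriptors for a strip: one per cell of the grid.

    Accepts a :class:`~octma.strips.Strip` or a bare 2-D array.  The
    integral image is built over an edge-replicated padding wide enough
    that every Haar window stays inside it, so descriptors are exactly
    invariant to adding a constant to the strip.
    """
    image = getattr(strip, "image", strip)
    image = np.asarray(image, dtype=np.float64)
    s = params.scale
    pad = int(np.ceil(_DESC_HALF * s * np.sqrt(2) + 2 * s + 2))
    ii = integral_image(image, pad=pad)
    kps = dense_keypoints(image.shape, params.grid, s)
    rows = np.array([k.row for k in kps])
    cols = np.array([k.col for k in kps])
    if params.upright:
        oris = np.zeros(len(kps))
    else:
        oris = _assign_orientations(ii, rows, cols, s)
    vecs, degen = _describe_many(ii, rows, cols, oris, s)
    descriptors = [
        Descriptor(
            vector=vecs[i],
            keypoint=Keypoint(row=kps[i].row, col=kps[i].col, scale=s, orientation=float(oris[i])),
            degenerate=bool(degen[i]),
        )
        for i in range(len(kps))
    ]
    return DescriptorSet(descriptors=descriptors, grid_shape=params.grid)
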