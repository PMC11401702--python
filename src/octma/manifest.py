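"""Dataset manifests and image I/O.

A manifest is a JSON table describing one eye: paths of the FA and SLO
images and the ordered B-scan stack, the MA annotation points on the
FA image, and the SLO rows of the B-scan acquisition lines.  The
synthetic simulator writes manifests in the same form as one would
prepare for exported device data.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from octma.registration import StackGeometry
from octma.strips import BSCANS_PER_EYE
from octma.synthetic import SyntheticConfig, generate_bscan, generate_enface_pair


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG (or float32 TIFF)."""
    path = Path(path)
    img = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, img.astype(np.float32))
    else:
        iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))


def load_image(path) -> np.ndarray:
    """Read a grayscale image, rescaled to [0, 1] floats."""
    img = np.asarray(iio.imread(path), dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def write_synthetic_eye(
    outdir,
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    eye_id: str = "eye01",
    n_ma_points: int = 5,
) -> Path:
    """Render one synthetic eye to disk and return the manifest path.

    The FA/SLO pair shares a vessel tree under the configured warp; the
    true SLO position of every MA dot decides which B-scan receives a
    lesion and at which column, so the written stack is consistent with
    the annotations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    fa, slo, gt = generate_enface_pair(config, rng, n_ma_points=n_ma_points)

    lesions_per_scan: dict[int, list[int]] = {}
    for x, y in np.asarray(gt.ma_points_slo).reshape(-1, 2):
        idx = int(np.argmin(np.abs(gt.bscan_rows - y)))
        lesions_per_scan.setdefault(idx, []).append(int(round(x)))

    fa_path, slo_path = outdir / "fa.png", outdir / "slo.png"
    save_image(fa_path, fa)
    save_image(slo_path, slo)
    bscan_paths = []
    for i in range(BSCANS_PER_EYE):
        bscan, _ = generate_bscan(
            config, rng, lesion_columns=lesions_per_scan.get(i, []), eye_id=eye_id, index=i
        )
        p = outdir / f"bscan_{i:02d}.png"
        save_image(p, bscan.image)
        bscan_paths.append(p.name)

    manifest = {
        "eye_id": eye_id,
        "fa": fa_path.name,
        "slo": slo_path.name,
        "bscans": bscan_paths,
        "ma_points": np.asarray(gt.ma_points).tolist(),
        "bscan_rows": np.asarray(gt.bscan_rows).tolist(),
        "true_warp": {
            "rotation_deg": config.warp.rotation_deg,
            "scale": config.warp.scale,
            "translation": list(config.warp.translation),
            "local_amplitude": config.warp.local_amplitude,
        },
        "ma_columns_slo": {str(k): v for k, v in lesions_per_scan.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_manifest(path) -> dict:
    """Load a manifest and its images into arrays.

    Returns a dict with keys ``eye_id, fa, slo, bscans (list of 2-D
    arrays), ma_points (n, 2), stack_geometry``.
    """
    path = Path(path)
    meta = json.loads(path.read_text())
    base = path.parent
    slo = load_image(base / meta["slo"])
    return {
        "eye_id": meta["eye_id"],
        "fa": load_image(base / meta["fa"]),
        "slo": slo,
        "bscans": [load_image(base / p) for p in meta["bscans"]],
        "ma_points": np.asarray(meta["ma_points"], dtype=np.float64).reshape(-1, 2),
        "stack_geometry": StackGeometry(
            bscan_rows=np.asarray(meta["bscan_rows"], dtype=np.float64),
            image_shape=slo.shape,
        ),
        "meta": meta,
    }
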