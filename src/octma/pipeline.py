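"""End-to-end orchestration: training pipeline and sliding-strip detector.

Training follows the study design: register FA to the SLO (synthetic
data may shortcut straight to labeled strips), cut 170x30 strips, pool
dense-SURF descriptors of the training split into a 100-word k-means++
vocabulary, encode every strip as a term vector, and train the MLP with
validation-driven early stopping; baselines and a PCA feature path give
the comparison table.

At test time a B-scan is tiled into consecutive 30-px vertical strips
(stride 30 by default, the last strip right-aligned), each trimmed,
encoded against the trained vocabulary and classified MA / normal.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from octma import bof, classify, registration, surf
from octma.classify import MLPSpec, SplitSpec
from octma.strips import STRIP_WIDTH, BScan, Strip, crop_strip, sample_normal_columns, trim_roi
from octma.surf import SurfParams
from octma.synthetic import SyntheticConfig, generate_strip_dataset

METHODS = ("mlp", "gaussian_svm", "linear_svm", "knn", "naive_bayes")
FEATURES = ("bof", "pca")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline parameters in one declarative document."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    manifest: str | None = None  # path to a real/simulated eye manifest
    n_ma: int = 92
    n_normal: int = 110
    vocab_size: int = 100
    mlp: MLPSpec = field(default_factory=MLPSpec)
    surf: SurfParams = field(default_factory=SurfParams)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    feature: str = "bof"
    classifier: str = "mlp"
    pca_components: int = 50
    detect_stride: int = STRIP_WIDTH
    score_threshold: float = 0.5
    seed: int = 0

    @property
    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        canon = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    metrics: classify.EvalMetrics
    split: SplitSpec
    model: object
    vocab: bof.Vocabulary | None
    pca: object | None
    features: np.ndarray
    labels: np.ndarray
    strip_ids: list[str]


@dataclass
class TrainedBundle:
    vocab: bof.Vocabulary
    model: classify.MLPModel
    surf_params: SurfParams
    score_threshold: float
    config_hash: str
    report: dict

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bof.save_vocabulary(self.vocab, outdir / "vocabulary.json")
        joblib.dump(self.model, outdir / "mlp.joblib")
        meta = {
            "surf": dataclasses.asdict(self.surf_params),
            "score_threshold": self.score_threshold,
            "config_hash": self.config_hash,
            "report": self.report,
        }
        (outdir / "bundle.json").write_text(json.dumps(meta, indent=2, default=str))
        return outdir

    @classmethod
    def load(cls, outdir) -> "TrainedBundle":
        outdir = Path(outdir)
        meta = json.loads((outdir / "bundle.json").read_text())
        vocab = bof.load_vocabulary(outdir / "vocabulary.json")
        surf_meta = dict(meta["surf"])
        surf_meta["grid"] = tuple(surf_meta["grid"])
        return cls(
            vocab=vocab,
            model=joblib.load(outdir / "mlp.joblib"),
            surf_params=SurfParams(**surf_meta),
            score_threshold=meta["score_threshold"],
            config_hash=meta["config_hash"],
            report=meta["report"],
        )


@dataclass
class DetectionResult:
    eye_id: str
    bscan_index: int
    strips: list[dict]  # {center_column, label, score}

    @property
    def ma_columns(self) -> list[int]:
        return [s["center_column"] for s in self.strips if s["label"] == "MA"]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def extract_features(strip_list: list[Strip], params: SurfParams = SurfParams()):
    """Dense-SURF descriptor sets for every strip."""
    return [surf.extract_strip_features(s, params) for s in strip_list]


def run_strip_experiment(
    strip_list: list[Strip],
    seed: int = 0,
    feature: str = "bof",
    classifier: str = "mlp",
    vocab_size: int = 100,
    pca_components: int = 50,
    surf_params: SurfParams = SurfParams(),
    mlp_spec: MLPSpec | None = None,
    descriptor_sets=None,
    split: SplitSpec | None = None,
) -> ExperimentResult:
    """Split, featurize, train and evaluate one classifier on strips.

    The vocabulary (or the PCA basis) is fitted on the training split
    only.  Precomputed descriptor sets / splits may be passed when
    comparing several classifiers on the same data.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature path {feature!r}")
    if classifier not in METHODS:
        raise ValueError(f"unknown classifier {classifier!r}")
    ids = [f"strip{i:04d}" for i in range(len(strip_list))]
    labels = np.array([s.label for s in strip_list])
    if descriptor_sets is None:
        descriptor_sets = extract_features(strip_list, surf_params)
    if split is None:
        split = classify.make_splits(ids, list(labels), SplitSpec(seed=seed))
    masks = {name: np.array([split.assignment[i] == name for i in ids]) for name in classify.SPLIT_NAMES}

    vocab = None
    pca = None
    if feature == "bof":
        train_desc = np.vstack([descriptor_sets[i].matrix for i in range(len(ids)) if masks["train"][i]])
        vocab = bof.fit_vocabulary(train_desc, K=vocab_size, seed=seed)
        X = np.stack(
            [bof.encode(ds, vocab, normalize=True, strip_id=sid).counts for ds, sid in zip(descriptor_sets, ids)]
        )
    else:
        X, pca = classify.pca_feature_path(descriptor_sets, n_components=pca_components, train_mask=masks["train"])

    if classifier == "mlp":
        spec = mlp_spec or MLPSpec(seed=seed)
        if mlp_spec is not None and mlp_spec.seed != seed:
            spec = dataclasses.replace(mlp_spec, seed=seed)
        model = classify.train_mlp(
            X[masks["train"]], labels[masks["train"]], X[masks["validation"]], labels[masks["validation"]], spec
        )
    else:
        model = classify.train_baseline(classifier, X[masks["train"]], labels[masks["train"]], seed=seed)
    metrics = classify.evaluate(model, X[masks["test"]], labels[masks["test"]])
    return ExperimentResult(
        metrics=metrics, split=split, model=model, vocab=vocab, pca=pca,
        features=X, labels=labels, strip_ids=ids,
    )


def strips_from_manifest(manifest: dict, n_normal_per_eye: int = 10, seed: int = 0) -> list[Strip]:
    """Full preprocessing of one eye: register, map annotations, crop.

    Runs vessel extraction, phase-I rigid and phase-II local
    registration, maps each FA annotation to a (B-scan, column), crops
    MA strips there and samples non-overlapping normal strips.
    """
    fa, slo = manifest["fa"], manifest["slo"]
    geometry = manifest["stack_geometry"]
    fa_map = _stage("vessel extraction")(registration.extract_vessel_map)(fa, "FA")
    slo_map = _stage("vessel extraction")(registration.extract_vessel_map)(slo, "SLO")
    affine = _stage("phase-1 registration")(registration.phase1_rigid)(fa_map, slo_map)
    refinement = _stage("phase-2 registration")(registration.phase2_local)(
        fa, slo, affine, manifest["ma_points"]
    )
    out: list[Strip] = []
    ma_cols_by_scan: dict[int, list[int]] = {}
    for pt in manifest["ma_points"]:
        ann = registration.map_fa_point_to_bscan(pt, affine, refinement, geometry)
        bscan = BScan(manifest["bscans"][ann.bscan_index], eye_id=manifest["eye_id"], index=ann.bscan_index)
        out.append(_stage("strip extraction")(crop_strip)(bscan, ann.column, "MA"))
        ma_cols_by_scan.setdefault(ann.bscan_index, []).append(ann.column)
    rng = np.random.default_rng(seed)
    lesion_free = [i for i in range(len(manifest["bscans"])) if i not in ma_cols_by_scan]
    candidates = lesion_free or sorted(ma_cols_by_scan)
    for j in range(n_normal_per_eye):
        idx = candidates[j % len(candidates)]
        bscan = BScan(manifest["bscans"][idx], eye_id=manifest["eye_id"], index=idx)
        col = sample_normal_columns(bscan, ma_cols_by_scan.get(idx, []), 1, rng)[0]
        out.append(crop_strip(bscan, col, "normal"))
    return out


def run_training(config: RunConfig = RunConfig(), manifest: dict | None = None):
    """Train the full pipeline and return ``(TrainedBundle, report)``.

    With a manifest the registration/extraction stages run first;
    otherwise labeled strips are generated synthetically with the
    study's class sizes.
    """
    if manifest is not None:
        strip_list = strips_from_manifest(manifest, n_normal_per_eye=config.n_normal, seed=config.seed)
    else:
        strip_list = _stage("synthetic data")(generate_strip_dataset)(
            config.n_ma, config.n_normal, config.synthetic, seed=config.seed
        )
    result = _stage("training")(run_strip_experiment)(
        strip_list,
        seed=config.seed,
        feature="bof",
        classifier="mlp",
        vocab_size=config.vocab_size,
        surf_params=config.surf,
        mlp_spec=config.mlp,
    )
    report = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_strips": len(strip_list),
        "vocab_size": result.vocab.K,
        "metrics": result.metrics.as_dict(),
    }
    bundle = TrainedBundle(
        vocab=result.vocab,
        model=result.model,
        surf_params=config.surf,
        score_threshold=config.score_threshold,
        config_hash=config.config_hash,
        report=report,
    )
    return bundle, report


def tile_starts(width: int, stride: int = STRIP_WIDTH) -> list[int]:
    """Left edges of the detector strips covering ``[0, width)``; the
    last strip is right-aligned when the stride does not divide evenly."""
    if width < STRIP_WIDTH:
        raise ValueError(f"B-scan narrower than a strip ({width} < {STRIP_WIDTH})")
    starts = list(range(0, width - STRIP_WIDTH + 1, stride))
    if starts[-1] != width - STRIP_WIDTH:
        starts.append(width - STRIP_WIDTH)
    return starts


def detect(bscan: BScan, bundle: TrainedBundle, stride: int | None = None, threshold: float | None = None) -> DetectionResult:
    """Slide the trained classifier over a B-scan.

    Every 30-px strip is ROI-trimmed, encoded against the bundle
    vocabulary and scored by the MLP; a strip whose MA probability
    exceeds the threshold is labeled MA.
    """
    stride = stride or STRIP_WIDTH
    threshold = bundle.score_threshold if threshold is None else threshold
    width = bscan.shape[1]
    entries = []
    for start in tile_starts(width, stride):
        roi, _ = trim_roi(bscan.image[:, start : start + STRIP_WIDTH])
        ds = surf.extract_strip_features(roi, bundle.surf_params)
        tv = bof.encode(ds, bundle.vocab, normalize=True)
        score = float(bundle.model.predict_proba_positive(tv.counts[None, :])[0])
        entries.append(
            {
                "center_column": start + STRIP_WIDTH // 2,
                "label": "MA" if score >= threshold else "normal",
                "score": score,
            }
        )
    return DetectionResult(eye_id=bscan.eye_id, bscan_index=bscan.index, strips=entries)


def compare_methods(
    strip_list: list[Strip],
    seeds=(0, 1, 2, 3, 4),
    vocab_size: int = 100,
    pca_components: int = 50,
    surf_params: SurfParams = SurfParams(),
) -> list[dict]:
    """The 10-configuration comparison: {BOF, PCA} x 5 classifiers.

    Descriptors are extracted once.  Per seed, the split, the visual
    vocabulary and the PCA basis are fitted once (training strips only)
    and shared by all classifiers of the respective feature path.  Rows
    report mean metrics over seeds, BOF rows first.
    """
    descriptor_sets = extract_features(strip_list, surf_params)
    ids = [f"strip{i:04d}" for i in range(len(strip_list))]
    labels = np.array([s.label for s in strip_list])
    names = {
        "mlp": "MLP",
        "gaussian_svm": "Gaussian SVM",
        "linear_svm": "linear SVM",
        "knn": "KNN",
        "naive_bayes": "Naive Bayes",
    }
    per_config: dict[tuple[str, str], list[classify.EvalMetrics]] = {
        (f, m): [] for f in FEATURES for m in METHODS
    }
    for seed in seeds:
        split = classify.make_splits(ids, list(labels), SplitSpec(seed=seed))
        masks = {
            name: np.array([split.assignment[i] == name for i in ids])
            for name in classify.SPLIT_NAMES
        }
        train_desc = np.vstack([descriptor_sets[i].matrix for i in np.flatnonzero(masks["train"])])
        vocab = bof.fit_vocabulary(train_desc, K=vocab_size, seed=seed)
        X_by_feature = {
            "bof": np.stack([bof.encode(ds, vocab, normalize=True).counts for ds in descriptor_sets]),
            "pca": classify.pca_feature_path(
                descriptor_sets, n_components=pca_components, train_mask=masks["train"]
            )[0],
        }
        for feature, X in X_by_feature.items():
            for method in METHODS:
                if method == "mlp":
                    model = classify.train_mlp(
                        X[masks["train"]], labels[masks["train"]],
                        X[masks["validation"]], labels[masks["validation"]],
                        classify.MLPSpec(seed=seed),
                    )
                else:
                    model = classify.train_baseline(method, X[masks["train"]], labels[masks["train"]], seed=seed)
                per_config[(feature, method)].append(
                    classify.evaluate(model, X[masks["test"]], labels[masks["test"]])
                )

    def _mean(values):
        vals = [v for v in values if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    rows = []
    for feature in FEATURES:
        for method in METHODS:
            ms = per_config[(feature, method)]
            rows.append(
                {
                    "method": f"{feature.upper()}+{names[method]}",
                    "feature": feature,
                    "classifier": method,
                    "accuracy": _mean([m.accuracy for m in ms]),
                    "sensitivity": _mean([m.sensitivity for m in ms]),
                    "specificity": _mean([m.specificity for m in ms]),
                    "precision": _mean([m.precision for m in ms]),
                    "n_seeds": len(seeds),
                }
            )
    return rows


def write_comparison_csv(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["method", "accuracy", "sensitivity", "specificity", "precision"])
        for r in rows:
            w.writerow([r["method"], f"{r['accuracy']:.2f}", f"{r['sensitivity']:.2f}",
                        f"{r['specificity']:.2f}", f"{r['precision']:.2f}"])


def report(results: list[DetectionResult], fmt: str, outdir, bscans: dict | None = None) -> list[Path]:
    """Write detection results as CSV or JSON, plus overlay images
    marking MA strips when the source B-scans are provided."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "csv":
        p = outdir / "detections.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["eye_id", "bscan_index", "center_column", "label", "score"])
            for res in results:
                for s in res.strips:
                    w.writerow([res.eye_id, res.bscan_index, s["center_column"], s["label"], f"{s['score']:.4f}"])
        written.append(p)
    elif fmt == "json":
        p = outdir / "detections.json"
        p.write_text(json.dumps([dataclasses.asdict(r) for r in results], indent=2))
        written.append(p)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if bscans:
        import imageio.v3 as iio

        for res in results:
            key = (res.eye_id, res.bscan_index)
            if key not in bscans:
                continue
            img = np.asarray(bscans[key], dtype=np.float64)
            rgb = np.stack([img, img, img], axis=2)
            for s in res.strips:
                if s["label"] == "MA":
                    c0 = s["center_column"] - STRIP_WIDTH // 2
                    rgb[:, c0 : c0 + STRIP_WIDTH, 0] = np.clip(rgb[:, c0 : c0 + STRIP_WIDTH, 0] + 0.25, 0, 1)
            p = outdir / f"overlay_{res.eye_id}_{res.bscan_index:02d}.png"
            iio.imwrite(p, np.round(rgb * 255).astype(np.uint8))
            written.append(p)
    return written
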