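"""Visual vocabulary construction and bag-of-features encoding.

Descriptors pooled over the *training* strips are clustered with
k-means++ seeding followed by Lloyd iterations under the Euclidean
metric; the cluster centers are the visual words.  Each strip is then
encoded as a term vector: the histogram of nearest-word assignments of
its 64 descriptors (L1-normalized frequencies by default).

Lloyd is implemented here rather than delegated so that per-iteration
inertia is recorded (its monotone decrease is a tested invariant) and
the empty-cluster rule is explicit: an emptied center is re-seeded at
the point farthest from its assigned center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class Vocabulary:
    """K visual words: cluster centers in 64-d descriptor space."""

    centers: np.ndarray  # (K, dim)
    inertia: float
    seed: int
    n_iterations: int
    inertia_history: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.centers.shape[0]


@dataclass
class TermVector:
    """Visual-word histogram of one strip's descriptors."""

    counts: np.ndarray  # raw counts or L1-normalized frequencies
    strip_id: str = ""
    normalized: bool = False


def kmeanspp_init(descriptors: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ (D^2) seeding.

    The first center is uniform over the points; each subsequent center
    is drawn with probability proportional to the squared Euclidean
    distance to the nearest already-chosen center.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("descriptors must be a non-empty 2-D array")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < K:
        raise ValueError(f"need at least K={K} distinct points, have {n_distinct}")
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    first = rng.integers(n)
    centers[0] = X[first]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:  # cannot happen with >= K distinct points, guard anyway
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[k] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)  # ties resolve to the lowest index
    return labels, d2[np.arange(X.shape[0]), labels]


def fit_vocabulary(
    descriptors: np.ndarray,
    K: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Vocabulary:
    """Cluster pooled training descriptors into K visual words.

    Lloyd iterations from a k-means++ start until the assignment is
    stable, the relative inertia change drops below ``tol``, or
    ``max_iter`` is reached.  Inertia (within-cluster sum of squared
    distances) is recorded after every iteration.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty descriptor pool")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    centers = kmeanspp_init(X, K, rng)
    labels, _ = _assign(X, centers)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for k in range(K):
            members = X[labels == k]
            if members.shape[0] == 0:
                # re-seed the emptied word at the worst-fit point
                _, best_d2 = _assign(X, centers)
                centers[k] = X[np.argmax(best_d2)]
            else:
                centers[k] = members.mean(axis=0)
        new_labels, d2 = _assign(X, centers)
        inertia = float(d2.sum())
        history.append(inertia)
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        if converged:
            break
        if len(history) >= 2 and history[-2] > 0:
            if abs(history[-2] - history[-1]) / history[-2] < tol:
                break
    return Vocabulary(
        centers=centers,
        inertia=history[-1],
        seed=seed,
        n_iterations=n_iter,
        inertia_history=history,
    )


def encode(descriptor_set, vocab: Vocabulary, normalize: bool = True, strip_id: str = "") -> TermVector:
    """Encode a strip's descriptors as a visual-word histogram.

    Each descriptor is assigned to its nearest center (Euclidean; ties
    to the lowest word index).  Unnormalized counts sum to the number
    of descriptors; ``normalize`` divides by that sum (L1 frequencies).
    """
    X = getattr(descriptor_set, "matrix", None)
    if X is None:
        X = np.asarray(descriptor_set, dtype=np.float64)
    if X.shape[1] != vocab.centers.shape[1]:
        raise ValueError(
            f"descriptor dim {X.shape[1]} != vocabulary dim {vocab.centers.shape[1]}"
        )
    labels, _ = _assign(X, vocab.centers)
    counts = np.bincount(labels, minlength=vocab.K).astype(np.float64)
    if normalize:
        counts = counts / counts.sum()
    return TermVector(counts=counts, strip_id=strip_id, normalized=normalize)


def save_vocabulary(vocab: Vocabulary, path) -> None:
    """Serialize a vocabulary (K x dim centers + fit metadata) as JSON."""
    import json
    from pathlib import Path

    doc = {
        "centers": vocab.centers.tolist(),
        "inertia": vocab.inertia,
        "seed": vocab.seed,
        "n_iterations": vocab.n_iterations,
        "inertia_history": vocab.inertia_history,
    }
    Path(path).write_text(json.dumps(doc))


def load_vocabulary(path) -> Vocabulary:
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    return Vocabulary(
        centers=np.asarray(doc["centers"], dtype=np.float64),
        inertia=doc["inertia"],
        seed=doc["seed"],
        n_iterations=doc["n_iterations"],
        inertia_history=list(doc.get("inertia_history", [])),
    )


def write_term_vector_csv(term_vectors: list[TermVector], labels: list[str], path) -> None:
    """Term-vector table: strip_id, label, then one column per word."""
    import csv

    if len(term_vectors) != len(labels):
        raise ValueError("one label per term vector required")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        k = len(term_vectors[0].counts) if term_vectors else 0
        w.writerow(["strip_id", "label"] + [f"word{i:03d}" for i in range(k)])
        for tv, lab in zip(term_vectors, labels):
            w.writerow([tv.strip_id, lab] + list(tv.counts))


def class_word_profile(term_vectors: list[TermVector], labels: list[str]) -> dict[str, np.ndarray]:
    """Per-class summed visual-word histograms (for profile plots)."""
    if len(term_vectors) != len(labels):
        raise ValueError("one label per term vector required")
    known = {"MA", "normal"}
    profiles: dict[str, np.ndarray] = {}
    for tv, lab in zip(term_vectors, labels):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
        profiles.setdefault(lab, np.zeros_like(tv.counts, dtype=np.float64))
        profiles[lab] = profiles[lab] + tv.counts
    return profiles
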