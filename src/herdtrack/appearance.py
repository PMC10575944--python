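"""Per-track appearance classifier: embeddings, rolling buffers and a
periodically retrained multiclass SVM with calibrated posteriors.

Hand-crafted color/texture cues alone cannot separate animals with
near-identical coats, so each confidently matched crop is embedded into a
fixed-length vector and buffered per track. Once every active track has
``min_per_class`` crops (30 by default — enough history at 1 fps to cover
pose variation), a one-against-one SVM with probability calibration is
trained; it is then retrained every ``retrain_interval_frames`` frames
(30 frames = 30 s at 1 fps). The posterior P that a candidate crop belongs
to a given track is turned into the dissimilarity ``P_dist = 1 / P``.

The embedder is pluggable. The default ``stub`` backend is a deterministic
hand-crafted embedder (masked per-channel histograms plus co-occurrence
texture statistics); a pretrained deep CNN backend can be registered at run
time via :func:`register_backend` when a deep-learning stack is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .features import CMParams, cm_features, compute_cm, quantize_channel, \
    NoPairsError, convert_color

logger = logging.getLogger(__name__)

__all__ = [
    "EPS_POSTERIOR",
    "StubEmbedder",
    "get_embedder",
    "register_backend",
    "AppearanceBuffer",
    "ClassifierModel",
    "bootstrap_ready",
    "train_classifier",
    "classify",
    "posterior_for_class",
    "probability_distance",
    "maybe_retrain",
]

EPS_POSTERIOR = 1e-6


class StubEmbedder:
    """Deterministic hand-crafted embedder.

    Concatenates, over the mask pixels of a crop: 16-bin normalized
    histograms of the three RGB channels (48 dims) and the four
    co-occurrence statistics of the luma channel at the four orientation
    angles (16 dims) — 64 dimensions total. Texture statistics make
    same-color, different-coat animals separable, mirroring what a deep
    embedder provides.
    """

    name = "stub"
    dimension = 64

    def __init__(self, levels: int = 8):
        self.levels = levels

    def __call__(self, crop: np.ndarray, mask: np.ndarray | None = None
                 ) -> np.ndarray:
        crop = np.asarray(crop)
        if crop.size == 0:
            raise ValueError("empty crop")
        if mask is None:
            mask = np.ones(crop.shape[:2], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        px = crop[mask].astype(float)  # (N, 3)
        hists = []
        for c in range(3):
            h, _ = np.histogram(px[:, c], bins=16, range=(0, 256))
            hists.append(h / max(1, px.shape[0]))
        y = convert_color(crop, "ycbcr")[..., 0]
        q = quantize_channel(y, self.levels)
        tex = np.zeros(16)
        for a_idx, angle in enumerate((0, 45, 90, 135)):
            try:
                P = compute_cm(q, mask, self.levels, angle)
            except NoPairsError:
                continue
            tex[a_idx * 4:(a_idx + 1) * 4] = cm_features(P).as_array()
        return np.concatenate(hists + [tex])


_BACKENDS: dict[str, Callable[[], object]] = {"stub": StubEmbedder}


def register_backend(name: str, factory: Callable[[], object]) -> None:
    """Register an embedder backend (e.g. a pretrained CNN wrapper)."""
    _BACKENDS[name] = factory


def get_embedder(name: str = "stub"):
    """Instantiate an embedder backend by name.

    A deep backend (``densenet`` or similar) must be registered by the
    caller; requesting an unregistered backend raises with a pointer to the
    self-contained ``stub`` backend.
    """
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise RuntimeError(
            f"embedder backend {name!r} is not registered; use the 'stub' "
            "backend or register a pretrained-CNN backend via "
            "register_backend()") from None


@dataclass
class AppearanceBuffer:
    """Rolling per-track store of (frame_index, embedding), FIFO-capped.

    Only crops from unambiguous matches should be admitted, so a bad
    association cannot poison the classifier's training labels.
    """

    capacity: int = 200
    _store: dict[int, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def add(self, track_id: int, frame_index: int, embedding: np.ndarray) -> None:
        lst = self._store.setdefault(track_id, [])
        lst.append((frame_index, np.asarray(embedding, dtype=float)))
        if len(lst) > self.capacity:
            del lst[: len(lst) - self.capacity]

    def count(self, track_id: int) -> int:
        return len(self._store.get(track_id, []))

    def drop(self, track_id: int) -> None:
        self._store.pop(track_id, None)

    def relabel(self, old_id: int, new_id: int) -> None:
        if old_id in self._store:
            self._store.setdefault(new_id, []).extend(self._store.pop(old_id))

    def track_ids(self) -> list[int]:
        return sorted(self._store)

    def embeddings(self, track_id: int) -> np.ndarray:
        return np.array([e for _, e in self._store.get(track_id, [])])


@dataclass
class ClassifierModel:
    """A trained appearance classifier with calibrated posteriors."""

    svm: CalibratedClassifierCV
    classes: list[int]  # track ids, aligned with svm.classes_ order
    trained_at_frame: int

    def has_class(self, track_id: int) -> bool:
        return track_id in self.classes


def bootstrap_ready(buffer: AppearanceBuffer, active_ids,
                    min_per_class: int = 30) -> bool:
    """True once every active track has at least ``min_per_class`` crops."""
    active_ids = list(active_ids)
    if not active_ids:
        return False
    return all(buffer.count(t) >= min_per_class for t in active_ids)


def train_classifier(buffer: AppearanceBuffer, current_frame: int,
                     min_per_class: int = 30, seed: int = 0,
                     ) -> ClassifierModel:
    """Fit a one-against-one RBF SVM with probability calibration on every
    buffered track that has at least ``min_per_class`` embeddings."""
    ids = [t for t in buffer.track_ids() if buffer.count(t) >= min_per_class]
    if len(ids) < 2:
        raise ValueError("need at least two classes with enough samples")
    X = np.vstack([buffer.embeddings(t) for t in ids])
    y = np.concatenate([[t] * buffer.count(t) for t in ids])
    # OAO max-margin classifier with Platt-style sigmoid calibration;
    # non-shuffled stratified folds keep training deterministic
    base = SVC(kernel="rbf", gamma="scale", decision_function_shape="ovo",
               random_state=seed)
    svm = CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    svm.fit(X, y)
    acc = float(svm.score(X, y))
    logger.info("appearance classifier trained at frame %d: %d classes, "
                "%d samples, train accuracy %.3f",
                current_frame, len(ids), len(y), acc)
    return ClassifierModel(svm=svm, classes=[int(c) for c in svm.classes_],
                           trained_at_frame=current_frame)


def classify(model: ClassifierModel, embedding: np.ndarray
             ) -> tuple[int, float]:
    """Argmax-posterior track id and its posterior for one embedding."""
    if model is None:
        raise ValueError("classifier not trained; use the three-feature "
                         "cold-start mode")
    proba = model.svm.predict_proba(np.asarray(embedding)[None, :])[0]
    k = int(np.argmax(proba))
    return model.classes[k], float(proba[k])


def posterior_for_class(model: ClassifierModel, embedding: np.ndarray,
                        track_id: int) -> float:
    """Posterior probability that ``embedding`` belongs to ``track_id``."""
    proba = model.svm.predict_proba(np.asarray(embedding)[None, :])[0]
    return float(proba[model.classes.index(track_id)])


def probability_distance(P: float) -> float:
    """Posterior dissimilarity 1/P, clamped at P = 1e-6 for safety."""
    return 1.0 / max(float(P), EPS_POSTERIOR)


def maybe_retrain(model: ClassifierModel | None, buffer: AppearanceBuffer,
                  active_ids, current_frame: int,
                  interval_frames: int = 30, min_per_class: int = 30,
                  seed: int = 0) -> ClassifierModel | None:
    """Retrain on schedule: first when the buffer bootstraps, then every
    ``interval_frames`` frames; otherwise return the model unchanged."""
    if not bootstrap_ready(buffer, active_ids, min_per_class):
        return model
    if model is not None and current_frame - model.trained_at_frame < interval_frames:
        return model
    try:
        return train_classifier(buffer, current_frame, min_per_class, seed)
    except ValueError:
        return model
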