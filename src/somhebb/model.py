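"""The SOM-Hebb facial-gesture classifier as a Model/Results pair.

``FacialGestureSOM`` holds the training data and hyperparameters; its
``fit()`` runs the offline pipeline — band-power feature extraction (if
built from raw segments), unsupervised SOM training, Hebbian labeling —
and returns a ``SOMHebbResults`` carrying the trained weight map, the
neuron labels, diagnostics and the recall-phase operations (``predict``,
``evaluate``, ``summary``).

Recall is winner-search-only: a test vector is assigned the label of its
nearest *enabled* neuron; weights are never adjusted at recall time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import Band, DEFAULT_BANDS
from .features import (
    DEFAULT_OVERLAP,
    DEFAULT_WINDOW_LENGTH,
    build_feature_vector,
    features_from_segments,
)
from .gestures import GestureClass
from .labeling import LabelMap, accumulate_wins, assign_labels
from .simulate import EEGSegment
from .som import TrainingSchedule, WeightMap, find_winner, quantization_error, train_som


@dataclass
class ConfusionMatrix:
    """H x H table of trial counts: rows true class, columns predicted."""

    counts: np.ndarray
    class_order: tuple[GestureClass, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        H = len(self.class_order)
        if self.counts.shape != (H, H):
            raise ValueError("counts must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.class_order = tuple(GestureClass(c) for c in self.class_order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Percent correct: 100 * trace / total."""
        if self.total == 0:
            raise ValueError("no trials")
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_text(self) -> str:
        names = [c.name for c in self.class_order]
        width = max(4, max(len(n) for n in names))
        head = "true\\pred " + " ".join(n.rjust(width) for n in names)
        lines = [head]
        for i, n in enumerate(names):
            row = " ".join(str(int(v)).rjust(width) for v in self.counts[i])
            lines.append(f"{n.ljust(10)}{row}")
        lines.append(f"accuracy   {self.accuracy:.1f}%")
        return "\n".join(lines)


def evaluate(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    class_order = tuple(GestureClass(c) for c in class_order)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("paired-data mismatch: unequal label list lengths")
    index = {c: i for i, c in enumerate(class_order)}
    H = len(class_order)
    counts = np.zeros((H, H), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        t, p = GestureClass(t), GestureClass(p)
        if t not in index or p not in index:
            raise ValueError("label outside the declared class order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_order)


def accuracy(conf: ConfusionMatrix) -> float:
    """Overall accuracy of a confusion matrix, in percent."""
    return conf.accuracy


class FacialGestureSOM:
    """SOM-Hebb gesture classifier model.

    Parameters
    ----------
    features : (n, D) array
        Band-power feature vectors.
    labels : sequence of GestureClass
        One label per feature vector; every label must be in ``class_set``
        and every class must have at least one vector.
    class_set : sequence of GestureClass
        The classes the model will recognise (defines label-map columns).
    map_size : int
        Side M of the M x M neuron lattice (default 8).
    schedule : TrainingSchedule
        Learning-rate/radius schedule and seed for SOM training.
    bands : tuple of Band
        Feature bands, recorded for provenance and recall-time extraction.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels,
        class_set,
        map_size: int = 8,
        schedule: TrainingSchedule | None = None,
        bands: tuple[Band, ...] = DEFAULT_BANDS,
        window_length: float = DEFAULT_WINDOW_LENGTH,
        overlap_fraction: float = DEFAULT_OVERLAP,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] == 0:
            raise ValueError("features must be a non-empty (n, D) matrix")
        self.labels = [GestureClass(l) for l in labels]
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("paired-data mismatch: features vs labels")
        self.class_set = tuple(GestureClass(c) for c in class_set)
        if len(set(self.class_set)) != len(self.class_set):
            raise ValueError("duplicate class in class_set")
        present = set(self.labels)
        for c in self.class_set:
            if c not in present:
                raise ValueError(f"empty class: no training vectors for {c.name}")
        for l in self.labels:
            if l not in self.class_set:
                raise ValueError(f"unknown class: label {l.name} not in class_set")
        self.map_size = int(map_size)
        self.schedule = schedule or TrainingSchedule()
        self.bands = tuple(bands)
        self.window_length = window_length
        self.overlap_fraction = overlap_fraction

    @classmethod
    def from_segments(
        cls,
        segments,
        class_set=None,
        map_size: int = 8,
        schedule: TrainingSchedule | None = None,
        bands: tuple[Band, ...] = DEFAULT_BANDS,
        window_length: float = DEFAULT_WINDOW_LENGTH,
        overlap_fraction: float = DEFAULT_OVERLAP,
    ) -> "FacialGestureSOM":
        """Build the model from labeled EEG segments (features extracted here)."""
        X, labels = features_from_segments(
            segments, bands, window_length, overlap_fraction
        )
        if any(l is None for l in labels):
            raise ValueError("every segment must carry a label")
        if class_set is None:
            class_set = sorted(set(labels))
        return cls(
            X,
            labels,
            class_set,
            map_size=map_size,
            schedule=schedule,
            bands=bands,
            window_length=window_length,
            overlap_fraction=overlap_fraction,
        )

    @property
    def D(self) -> int:
        return self.features.shape[1]

    def fit(self) -> "SOMHebbResults":
        """Run offline training: SOM learning, then Hebbian labeling."""
        wm = train_som(self.features, self.map_size, self.schedule)
        table = accumulate_wins(wm, self.features, self.labels, self.class_set)
        lm = assign_labels(table)
        if lm.n_enabled() == 0:
            raise ValueError("no enabled neurons after labeling")
        qe = quantization_error(self.features, wm)
        return SOMHebbResults(self, wm, lm, qe)


@dataclass
class SOMHebbResults:
    """Fitted SOM-Hebb classifier: weights, neuron labels, diagnostics."""

    model: FacialGestureSOM
    weight_map: WeightMap
    label_map: LabelMap
    training_quantization_error: float

    @property
    def class_set(self) -> tuple[GestureClass, ...]:
        return self.model.class_set

    def _features_of(self, item) -> np.ndarray:
        if isinstance(item, EEGSegment):
            return build_feature_vector(
                item,
                self.model.bands,
                self.model.window_length,
                self.model.overlap_fraction,
            ).values
        return np.asarray(item, dtype=float)

    def predict(self, item) -> tuple[GestureClass, tuple[int, int]]:
        """Classify one segment or feature vector.

        Returns the predicted gesture and the winning neuron's lattice
        coordinate (row, col).  Only enabled neurons take part in the
        winner search; weights are not modified.
        """
        x = self._features_of(item)
        C = find_winner(x, self.weight_map, self.label_map.enabled)
        return self.label_map.label_of(C), self.weight_map.coord_of(C)

    def predict_many(self, items) -> list[GestureClass]:
        return [self.predict(item)[0] for item in items]

    def evaluate(self, items, true_labels=None) -> ConfusionMatrix:
        """Confusion matrix of predictions against true labels.

        ``items`` may be segments (labels taken from them when
        ``true_labels`` is omitted) or feature vectors.
        """
        if true_labels is None:
            true_labels = [getattr(s, "label", None) for s in items]
            if any(t is None for t in true_labels):
                raise ValueError("true labels required for unlabeled inputs")
        if len(true_labels) != len(items):
            raise ValueError("paired-data mismatch: items vs true labels")
        for t in true_labels:
            if GestureClass(t) not in self.class_set:
                raise ValueError(
                    f"class-set mismatch: {GestureClass(t).name} not in model classes"
                )
        preds = self.predict_many(items)
        return evaluate(true_labels, preds, self.class_set)

    def neuron_map_text(self) -> str:
        return self.label_map.to_text_grid(self.weight_map.M)

    def per_class_neuron_counts(self) -> dict[GestureClass, int]:
        out = {}
        for j, c in enumerate(self.class_set):
            out[c] = int(np.sum(self.label_map.labels[self.label_map.enabled] == j))
        return out

    def summary(self) -> str:
        """Human-readable report of the fitted classifier."""
        m = self.model
        lines = [
            "SOM-Hebb facial gesture classifier",
            "==================================",
            f"map size:            {self.weight_map.M} x {self.weight_map.M} "
            f"({self.weight_map.n_neurons} neurons)",
            f"feature dimension:   {self.weight_map.D}",
            f"classes:             {', '.join(c.name for c in self.class_set)}",
            f"training vectors:    {m.features.shape[0]}",
            f"enabled neurons:     {self.label_map.n_enabled()}"
            f" / {self.weight_map.n_neurons}",
            f"quantization error:  {self.training_quantization_error:.4f}",
            "neurons per class:   "
            + ", ".join(
                f"{c.name}:{n}" for c, n in self.per_class_neuron_counts().items()
            ),
            "",
            "neuron map (class id, x = disabled):",
            self.neuron_map_text(),
        ]
        return "\n".join(lines)
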