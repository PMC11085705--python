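"""Hebbian labeling: attach gesture classes to trained SOM neurons.

After unsupervised training, the labeled training vectors are fed through
the map once more.  Each vector's winner gets a win recorded under the
vector's class; a neuron is then associated with the class that made it
win most often.  Neurons that never win get no class and are disabled —
excluded from the recall-phase winner search so they can never produce a
false recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gestures import GestureClass
from .som import WeightMap, find_winner


@dataclass
class WinCountTable:
    """Per-neuron, per-class win counts from one pass of the training set."""

    counts: np.ndarray  # (n_neurons, H) non-negative ints
    class_order: tuple[GestureClass, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.class_order):
            raise ValueError("counts must have shape (n_neurons, n_classes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.class_order = tuple(GestureClass(c) for c in self.class_order)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LabelMap:
    """Per-neuron class assignment and enabled flag.

    ``labels[k]`` is the index into ``class_order`` of neuron k's class,
    or -1 for a disabled neuron.  A neuron is enabled iff it won at least
    once during labeling.
    """

    labels: np.ndarray  # (n_neurons,) int, -1 = disabled
    enabled: np.ndarray  # (n_neurons,) bool
    source_counts: WinCountTable

    @property
    def class_order(self) -> tuple[GestureClass, ...]:
        return self.source_counts.class_order

    def label_of(self, k: int) -> GestureClass | None:
        return self.class_order[self.labels[k]] if self.enabled[k] else None

    def n_enabled(self) -> int:
        return int(self.enabled.sum())

    def to_text_grid(self, M: int) -> str:
        """Neuron map as text: the class id per neuron, 'x' if disabled."""
        cells = [
            str(int(self.class_order[self.labels[k]])) if self.enabled[k] else "x"
            for k in range(self.labels.size)
        ]
        width = max(len(c) for c in cells)
        rows = [
            " ".join(c.rjust(width) for c in cells[r * M : (r + 1) * M])
            for r in range(M)
        ]
        return "\n".join(rows)


def accumulate_wins(
    weight_map: WeightMap,
    features: np.ndarray,
    labels,
    class_order,
) -> WinCountTable:
    """One supervised pass: each vector's winner gets +1 in its class column.

    All neurons participate in the winner search here (disabling happens
    only afterwards).  The result is independent of presentation order.
    """
    class_order = tuple(GestureClass(c) for c in class_order)
    index = {c: j for j, c in enumerate(class_order)}
    X = np.asarray(features, dtype=float)
    if X.shape[0] != len(labels):
        raise ValueError("features and labels must have equal length")
    counts = np.zeros((weight_map.n_neurons, len(class_order)), dtype=int)
    for x, lab in zip(X, labels):
        lab = GestureClass(lab)
        if lab not in index:
            raise ValueError(f"unknown class: {lab!r} not in class order")
        counts[find_winner(x, weight_map), index[lab]] += 1
    return WinCountTable(counts, class_order)


def assign_labels(table: WinCountTable) -> LabelMap:
    """Label each winning neuron with its majority class; disable the rest.

    Ties are broken toward the lowest class index, which makes the
    assignment deterministic.
    """
    row_totals = table.counts.sum(axis=1)
    labels = np.where(row_totals > 0, np.argmax(table.counts, axis=1), -1)
    enabled = row_totals > 0
    return LabelMap(labels.astype(int), enabled, table)
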