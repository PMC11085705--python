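"""File formats, experiment configuration and the experiment runner.

Segments are stored as delimited text — one file per segment with '#'
key-value metadata lines (label, sample rate, seed) followed by a
``ch1,...,ch16`` header and one row per sample — so round-trips preserve
values to full precision.  Fitted models are stored as a single JSON
document (weights, labels, enabled flags, configuration, seeds); JSON
float serialisation round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bands import Band, DEFAULT_BANDS
from .features import DEFAULT_OVERLAP, DEFAULT_WINDOW_LENGTH, features_from_segments
from .gestures import CLASS_SUBSETS, GestureClass
from .labeling import LabelMap, WinCountTable
from .model import ConfusionMatrix, FacialGestureSOM, SOMHebbResults
from .simulate import (
    DEFAULT_AMPLITUDE_JITTER,
    DEFAULT_BASE_AMPLITUDE,
    DEFAULT_DURATION,
    DEFAULT_NOISE_SD,
    DEFAULT_SAMPLE_RATE,
    EEGSegment,
    generate_dataset,
)
from .som import TrainingSchedule, WeightMap

logger = logging.getLogger("somhebb")

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# segment I/O


def save_segments(segments, path) -> None:
    """Write segments as one CSV file each under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, seg in enumerate(segments):
        fname = path / f"segment_{i:04d}.csv"
        with open(fname, "w") as fh:
            if seg.label is not None:
                fh.write(f"# label: {GestureClass(seg.label).name}\n")
            fh.write(f"# sample_rate: {seg.sample_rate!r}\n")
            if seg.seed is not None:
                fh.write(f"# seed: {seg.seed}\n")
            fh.write(",".join(f"ch{c}" for c in seg.channel_ids) + "\n")
            for row in seg.samples.T:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _load_one_segment(fname: Path) -> EEGSegment | None:
    label = None
    sample_rate = None
    seed = None
    header = None
    rows = []
    with open(fname) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key == "label":
                        label = GestureClass[val]
                    elif key == "sample_rate":
                        sample_rate = float(val)
                    elif key == "seed":
                        seed = int(val)
                continue
            cols = line.split(",")
            if header is None:
                header = cols
                continue
            if len(cols) != len(header):
                raise ValueError(
                    f"parse error at {fname.name}:{lineno}: expected "
                    f"{len(header)} columns, got {len(cols)}"
                )
            try:
                rows.append([float(v) for v in cols])
            except ValueError as exc:
                raise ValueError(
                    f"parse error at {fname.name}:{lineno}: {exc}"
                ) from None
    if header is None:
        raise ValueError(f"parse error at {fname.name}: no header row")
    if not rows:
        logger.warning("header-only segment file %s skipped", fname.name)
        return None
    if sample_rate is None:
        sample_rate = DEFAULT_SAMPLE_RATE
        logger.warning(
            "%s: no sample_rate metadata, default %.0f Hz applied",
            fname.name,
            sample_rate,
        )
    channel_ids = tuple(int(h[2:]) for h in header)
    samples = np.asarray(rows, dtype=float).T
    return EEGSegment(
        samples,
        sample_rate=sample_rate,
        channel_ids=channel_ids,
        label=label,
        seed=seed,
    )


def load_segments(path) -> list[EEGSegment]:
    """Read segments written by :func:`save_segments` (or one single file)."""
    path = Path(path)
    files = [path] if path.is_file() else sorted(path.glob("segment_*.csv"))
    segments = []
    for fname in files:
        seg = _load_one_segment(fname)
        if seg is not None:
            segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# model I/O


def save_model(results: SOMHebbResults, path) -> None:
    """Persist a fitted classifier as one JSON document."""
    m = results.model
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "map_size": results.weight_map.M,
        "D": results.weight_map.D,
        "class_set": [c.name for c in m.class_set],
        "bands": [[b.name, b.lo, b.hi] for b in m.bands],
        "window_length": m.window_length,
        "overlap_fraction": m.overlap_fraction,
        "schedule": asdict(m.schedule),
        "weights": results.weight_map.weights.tolist(),
        "labels": results.label_map.labels.tolist(),
        "enabled": results.label_map.enabled.astype(int).tolist(),
        "win_counts": results.label_map.source_counts.counts.tolist(),
        "training_quantization_error": results.training_quantization_error,
        "n_training_vectors": int(m.features.shape[0]),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SOMHebbResults:
    """Load a classifier saved by :func:`save_model`.

    The returned results object predicts identically to the original; the
    embedded model carries the configuration but only a placeholder
    training set (one centroid per class) for provenance.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"incompatible model file: {exc}") from None
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("incompatible model file: unknown format version")
    class_set = tuple(GestureClass[n] for n in doc["class_set"])
    bands = tuple(Band(n, lo, hi) for n, lo, hi in doc["bands"])
    schedule = TrainingSchedule(**doc["schedule"])
    weights = np.asarray(doc["weights"], dtype=float)
    wm = WeightMap(weights, doc["map_size"])
    table = WinCountTable(np.asarray(doc["win_counts"], dtype=int), class_set)
    lm = LabelMap(
        np.asarray(doc["labels"], dtype=int),
        np.asarray(doc["enabled"], dtype=bool),
        table,
    )
    # Placeholder training features: enabled-neuron weights, one per class,
    # just enough for the model object's validation to hold.
    feats, labs = [], []
    for c in class_set:
        j = class_set.index(c)
        idx = np.nonzero(lm.enabled & (lm.labels == j))[0]
        k = idx[0] if idx.size else 0
        feats.append(weights[k])
        labs.append(c)
    model = FacialGestureSOM(
        np.asarray(feats),
        labs,
        class_set,
        map_size=doc["map_size"],
        schedule=schedule,
        bands=bands,
        window_length=doc["window_length"],
        overlap_fraction=doc["overlap_fraction"],
    )
    return SOMHebbResults(model, wm, lm, doc["training_quantization_error"])


# ---------------------------------------------------------------------------
# experiment configuration and runner


@dataclass
class RunConfig:
    """Everything needed to reproduce one recognition experiment.

    Defaults mirror the acquisition and training protocol: 16 channels at
    125 Hz for 2 s, an 8 x 8 map, 30 training vectors per class, and a
    held-out test set of 30 trials per class (50 for the two-class
    experiment).  All randomness flows from the named seeds.
    """

    n_classes: int = 7
    n_train_per_class: int = 30
    n_test_per_class: int | None = None  # None -> 50 if 2 classes else 30
    map_size: int = 8
    sample_rate: float = DEFAULT_SAMPLE_RATE
    duration: float = DEFAULT_DURATION
    noise_sd: float = DEFAULT_NOISE_SD
    amplitude_jitter: float = DEFAULT_AMPLITUDE_JITTER
    base_amplitude: float = DEFAULT_BASE_AMPLITUDE
    window_length: float = DEFAULT_WINDOW_LENGTH
    overlap_fraction: float = DEFAULT_OVERLAP
    epochs: int = 100
    alpha0: float = 0.5
    alpha_final: float = 0.01
    sigma0: float | None = None
    sigma_final: float = 0.5
    decay: str = "linear"
    train_seed: int = 0
    test_seed: int = 1
    som_seed: int = 2

    def classes(self) -> tuple[GestureClass, ...]:
        if self.n_classes not in CLASS_SUBSETS:
            raise ValueError("n_classes must be one of 2, 4, 5, 7")
        return CLASS_SUBSETS[self.n_classes]

    def resolved_n_test(self) -> int:
        if self.n_test_per_class is not None:
            return self.n_test_per_class
        return 50 if self.n_classes == 2 else 30

    def schedule(self) -> TrainingSchedule:
        return TrainingSchedule(
            epochs=self.epochs,
            alpha0=self.alpha0,
            alpha_final=self.alpha_final,
            sigma0=self.sigma0,
            sigma_final=self.sigma_final,
            decay=self.decay,
            seed=self.som_seed,
        )


@dataclass
class ExperimentReport:
    """Outcome of one full train/test experiment replica."""

    confusion: ConfusionMatrix
    results: SOMHebbResults
    config: RunConfig
    predictions: list[GestureClass]
    winner_coords: list[tuple[int, int]]

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    def to_text(self) -> str:
        lines = [
            self.results.summary(),
            "",
            "held-out confusion matrix:",
            self.confusion.to_text(),
        ]
        return "\n".join(lines)


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Run one seeded experiment: simulate, train, classify held-out trials."""
    classes = config.classes()
    gen = dict(
        duration=config.duration,
        sample_rate=config.sample_rate,
        noise_sd=config.noise_sd,
        amplitude_jitter=config.amplitude_jitter,
        base_amplitude=config.base_amplitude,
    )
    train = generate_dataset(
        classes, config.n_train_per_class, seed=config.train_seed, **gen
    )
    test = generate_dataset(
        classes, config.resolved_n_test(), seed=config.test_seed, **gen
    )
    logger.info(
        "experiment: %d classes, %d train + %d test per class",
        len(classes),
        config.n_train_per_class,
        config.resolved_n_test(),
    )
    model = FacialGestureSOM.from_segments(
        train,
        class_set=classes,
        map_size=config.map_size,
        schedule=config.schedule(),
        window_length=config.window_length,
        overlap_fraction=config.overlap_fraction,
    )
    results = model.fit()
    preds, coords = [], []
    X_test, true_labels = features_from_segments(
        test,
        model.bands,
        config.window_length,
        config.overlap_fraction,
    )
    for x in X_test:
        p, rc = results.predict(x)
        preds.append(p)
        coords.append(rc)
    from .model import evaluate as _evaluate

    conf = _evaluate(true_labels, preds, classes)
    return ExperimentReport(conf, results, config, preds, coords)
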