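"""Self-organizing map: geometry, winner search, neighborhood, training.

The map is an M x M lattice of neurons, each holding a D-dimensional
weight vector m_k.  For an input x the winner C minimises the Euclidean
distance d_k = ||x - m_k||; every neuron is then pulled toward x by

    m_k(t+1) = m_k(t) + h_Ck * (x - m_k(t)),
    h_Ck     = alpha(t) * exp(-||r_C - r_k||^2 / sigma(t)^2),

where r_k is the neuron's lattice coordinate.  The neighborhood is
evaluated for all neurons (no cutoff radius), and t counts individual
vector presentations, not epochs.  Ties in the winner search are broken
by the lowest neuron index; neuron index k maps row-major onto (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrainingSchedule:
    """Learning-rate and neighborhood-radius schedule for SOM training.

    Both alpha (learning rate) and sigma (neighborhood radius, in lattice
    units) decay from their initial to final values over all presentations.
    ``sigma0=None`` means M/2, resolved when training starts.
    """

    epochs: int = 100
    alpha0: float = 0.5
    alpha_final: float = 0.01
    sigma0: float | None = None
    sigma_final: float = 0.5
    decay: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_final <= self.alpha0 <= 1:
            raise ValueError("need 0 < alpha_final <= alpha0 <= 1")
        if self.sigma0 is not None and not 0 < self.sigma_final <= self.sigma0:
            raise ValueError("need 0 < sigma_final <= sigma0")
        if self.sigma_final <= 0:
            raise ValueError("sigma_final must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")

    def resolve_sigma0(self, M: int) -> float:
        return self.sigma0 if self.sigma0 is not None else M / 2.0

    def at(self, t: int, total: int, M: int) -> tuple[float, float]:
        """(alpha, sigma) at presentation t of ``total`` presentations."""
        s0 = self.resolve_sigma0(M)
        frac = t / (total - 1) if total > 1 else 0.0
        if self.decay == "linear":
            alpha = self.alpha0 + (self.alpha_final - self.alpha0) * frac
            sigma = s0 + (self.sigma_final - s0) * frac
        else:
            alpha = self.alpha0 * (self.alpha_final / self.alpha0) ** frac
            sigma = s0 * (self.sigma_final / s0) ** frac
        return alpha, sigma


def grid_coordinates(M: int) -> np.ndarray:
    """Row-major lattice coordinates (row, col) for the M x M map."""
    rows, cols = np.divmod(np.arange(M * M), M)
    return np.stack([rows, cols], axis=1)


@dataclass
class WeightMap:
    """M x M grid of D-dimensional weight vectors with lattice coordinates."""

    weights: np.ndarray  # (M*M, D)
    M: int
    grid_coords: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.M * self.M:
            raise ValueError("weights must have shape (M*M, D)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.grid_coords is None:
            self.grid_coords = grid_coordinates(self.M)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def D(self) -> int:
        return self.weights.shape[1]

    def coord_of(self, k: int) -> tuple[int, int]:
        r, c = self.grid_coords[k]
        return int(r), int(c)


def init_map(M: int, D: int, training_set: np.ndarray, seed: int = 0) -> WeightMap:
    """Seeded uniform initialisation within the data's per-dimension range."""
    X = np.asarray(training_set, dtype=float)
    if M < 1 or D < 1:
        raise ValueError("M and D must be >= 1")
    if X.size == 0:
        raise ValueError("cannot initialize from an empty training set")
    if X.shape[1] != D:
        raise ValueError("dimension mismatch between D and training set")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(seed)
    weights = rng.uniform(lo, hi, size=(M * M, D))
    return WeightMap(weights, M)


def distance(x: np.ndarray, m: np.ndarray) -> float:
    """Euclidean distance between a feature vector and a weight vector."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(x - m))


def find_winner(
    x: np.ndarray, weight_map: WeightMap, enabled: np.ndarray | None = None
) -> int:
    """Index of the nearest enabled neuron; ties go to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (weight_map.D,):
        raise ValueError("dimension mismatch")
    d = np.linalg.norm(weight_map.weights - x, axis=1)
    if enabled is not None:
        enabled = np.asarray(enabled, dtype=bool)
        if not enabled.any():
            raise ValueError("no enabled neurons")
        d = np.where(enabled, d, np.inf)
    return int(np.argmin(d))


def neighborhood(
    C: int, k: int, alpha_t: float, sigma_t: float, grid_coords: np.ndarray
) -> float:
    """Gaussian lattice-distance kernel h_Ck; equals alpha_t at k == C."""
    if sigma_t <= 0:
        raise ValueError("invalid radius: sigma_t must be positive")
    diff = grid_coords[C] - grid_coords[k]
    return float(alpha_t * np.exp(-float(diff @ diff) / sigma_t**2))


def _neighborhood_all(
    C: int, alpha_t: float, sigma_t: float, grid_coords: np.ndarray
) -> np.ndarray:
    diff = grid_coords - grid_coords[C]
    sq = np.einsum("ij,ij->i", diff, diff).astype(float)
    return alpha_t * np.exp(-sq / sigma_t**2)


def update_weights(
    weight_map: WeightMap,
    x: np.ndarray,
    C: int,
    alpha_t: float,
    sigma_t: float,
    inplace: bool = False,
) -> WeightMap:
    """Pull every neuron toward x by its neighborhood weight.

    Each updated component is the convex combination (1-h) m + h x with
    h in (0, alpha_t], so no weight moves past the input.
    """
    if sigma_t <= 0:
        raise ValueError("invalid radius: sigma_t must be positive")
    x = np.asarray(x, dtype=float)
    if x.shape != (weight_map.D,):
        raise ValueError("dimension mismatch")
    h = _neighborhood_all(C, alpha_t, sigma_t, weight_map.grid_coords)
    w = weight_map.weights if inplace else weight_map.weights.copy()
    w += h[:, None] * (x - w)
    if inplace:
        return weight_map
    return WeightMap(w, weight_map.M, weight_map.grid_coords)


def train_som(
    training_set: np.ndarray,
    M: int,
    schedule: TrainingSchedule | None = None,
) -> WeightMap:
    """Train an M x M map on a feature matrix.

    Each epoch presents all vectors in a seeded shuffled order; alpha and
    sigma are interpolated over the total number of presentations.  The
    result is fully determined by (data, M, schedule).
    """
    X = np.asarray(training_set, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty matrix")
    schedule = schedule or TrainingSchedule()
    wm = init_map(M, X.shape[1], X, seed=schedule.seed)
    rng = np.random.default_rng(schedule.seed + 1)
    n = X.shape[0]
    total = schedule.epochs * n
    t = 0
    for _ in range(schedule.epochs):
        order = rng.permutation(n)
        for i in order:
            alpha_t, sigma_t = schedule.at(t, total, M)
            C = find_winner(X[i], wm)
            update_weights(wm, X[i], C, alpha_t, sigma_t, inplace=True)
            t += 1
    return wm


def quantization_error(
    X: np.ndarray, weight_map: WeightMap, enabled: np.ndarray | None = None
) -> float:
    """Mean distance from each vector to its (enabled) winner."""
    X = np.asarray(X, dtype=float)
    return float(
        np.mean(
            [
                distance(x, weight_map.weights[find_winner(x, weight_map, enabled)])
                for x in X
            ]
        )
    )
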