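"""Recurring connectivity states via k-means under Manhattan distance.

Windowed connectivity vectors (one sample per window, one feature per ROI
pair) are clustered with a k-means variant that uses the L1 norm as its
distance function.  Because the coordinate-wise median — not the mean —
minimises total L1 distance within a cluster, the centroid update is the
median (true k-medians); a ``update="mean"`` compatibility switch reproduces
the common mean-update behaviour.  Initial centroids are spread k-means++
style with selection probability proportional to L1 distance from the chosen
set, and the best of ``n_init`` restarts by total L1 cost is returned.

The number of states is selected by the elbow criterion on the ratio of
within-cluster to between-cluster distance, with the elbow located as the
point of maximal deviation below the chord joining the curve's endpoints.
States are then ordered by centroid strength (mean edge value): lowest mean
-> "low", highest -> "high".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StateModel",
    "kmeans_l1",
    "elbow_ratio",
    "elbow_point",
    "KScanResult",
    "select_k",
    "order_states",
    "assign_windows",
    "filter_incomplete_subjects",
    "state_names",
]

DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 300


@dataclass
class StateModel:
    """A fitted state-clustering model.

    ``order`` maps raw centroid index -> strength rank (0 = weakest).  Until
    :func:`order_states` is applied it is the identity permutation of fitting
    order.
    """

    k: int
    centroids: np.ndarray  # k x E
    cost: float  # total L1 distance of training samples to assigned centroids
    labels: np.ndarray  # raw training labels
    n_iter: int
    n_init: int
    seed: int | None
    metric: str = "l1"
    cost_history: np.ndarray | None = None  # per-iteration cost of the winning restart
    order: np.ndarray | None = None

    @property
    def strengths(self) -> np.ndarray:
        """Mean edge value of each centroid, in raw centroid order."""
        return self.centroids.mean(axis=1)

    @property
    def ordered(self) -> bool:
        return self.order is not None


def state_names(k: int) -> list[str]:
    """Human-readable names by strength rank: low < (middle...) < high."""
    if k == 1:
        return ["state"]
    if k == 2:
        return ["low", "high"]
    if k == 3:
        return ["low", "middle", "high"]
    return ["low"] + [f"middle_{i}" for i in range(1, k - 1)] + ["high"]


def _l1(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b, metric="cityblock")


def _kmeanspp_init(samples: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding with selection probability proportional to L1 distance."""
    n = samples.shape[0]
    idx = [int(rng.integers(n))]
    dist = _l1(samples, samples[idx[-1:]])[:, 0]
    for _ in range(k - 1):
        total = dist.sum()
        if total <= 0:  # all remaining points coincide with a chosen centre
            probs = np.full(n, 1.0 / n)
        else:
            probs = dist / total
        idx.append(int(rng.choice(n, p=probs)))
        dist = np.minimum(dist, _l1(samples, samples[idx[-1:]])[:, 0])
    return samples[idx].astype(float, copy=True)


def _single_run(
    samples: np.ndarray,
    k: int,
    max_iter: int,
    rng: np.random.Generator,
    update: str = "median",
) -> tuple[np.ndarray, np.ndarray, float, int, np.ndarray]:
    reduce = np.median if update == "median" else np.mean
    centroids = _kmeanspp_init(samples, k, rng)
    labels = np.full(samples.shape[0], -1)
    costs: list[float] = []
    for it in range(1, max_iter + 1):
        dist = _l1(samples, centroids)
        new_labels = dist.argmin(axis=1)
        sample_cost = dist[np.arange(len(new_labels)), new_labels]
        # Re-seed any emptied cluster with the sample farthest from its centroid.
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(sample_cost.argmax())
                centroids[c] = samples[far]
                new_labels[far] = c
                sample_cost[far] = 0.0
        costs.append(float(sample_cost.sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = reduce(samples[labels == c], axis=0)
    dist = _l1(samples, centroids)
    labels = dist.argmin(axis=1)
    cost = float(dist[np.arange(len(labels)), labels].sum())
    costs.append(cost)
    return centroids, labels, cost, it, np.array(costs)


def kmeans_l1(
    samples: np.ndarray,
    k: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    update: str = "median",
) -> StateModel:
    """Best-of-``n_init`` k-means clustering under Manhattan distance.

    Iterates nearest-centroid assignment (L1) and coordinate-wise-median
    centroid update until the labelling reaches a fixpoint or ``max_iter``;
    the restart with the lowest total L1 cost wins.  ``update="mean"``
    switches to the arithmetic-mean centroid update for compatibility with
    conventional k-means implementations; only the median update guarantees
    a non-increasing L1 objective.
    """
    if update not in ("median", "mean"):
        raise ValueError("update must be 'median' or 'mean'")
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (n_samples x n_features)")
    if not np.isfinite(samples).all():
        raise ValueError("samples contain non-finite values")
    n = samples.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_init):
        run = _single_run(samples, k, max_iter, rng, update=update)
        if best is None or run[2] < best[2]:
            best = run
    centroids, labels, cost, n_iter, history = best
    return StateModel(
        k=k,
        centroids=centroids,
        cost=cost,
        labels=labels,
        n_iter=n_iter,
        n_init=n_init,
        seed=seed,
        cost_history=history,
    )


def elbow_ratio(samples: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Within-to-between cluster distance ratio for the elbow criterion.

    Mean L1 distance of samples to their assigned centroid, divided by the
    mean pairwise L1 distance among centroids.  Undefined at k = 1.
    """
    samples = np.asarray(samples, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("elbow ratio needs at least 2 clusters")
    within = _l1(samples, centroids)[np.arange(len(labels)), labels].mean()
    pair = _l1(centroids, centroids)
    between = pair[np.triu_indices(k, k=1)].mean()
    return float(within / between)


def elbow_point(ks, values, flat_tol: float = 0.1) -> tuple[int, bool]:
    """Locate the elbow of a fit-quality curve by maximal discrete curvature.

    The curve is min-max normalised (making the rule invariant to affine
    rescaling of the fit measure) and the k with the largest second
    difference — the sharpest downward bend — is returned.  A curve whose
    maximal normalised curvature falls below ``flat_tol`` has no pronounced
    elbow: the first k is returned with ``flat=True``.

    Endpoints of the scanned range cannot be selected; scan a range that
    brackets the candidate values.
    """
    ks = np.asarray(ks)
    values = np.asarray(values, dtype=float)
    if ks.size != values.size or ks.size < 3:
        raise ValueError("need at least 3 (k, value) points")
    if np.any(np.diff(ks) != ks[1] - ks[0]):
        raise ValueError("k grid must be evenly spaced")
    span = values.max() - values.min()
    if span <= 0:
        return int(ks[0]), True
    y = (values - values.min()) / span
    curvature = y[:-2] - 2.0 * y[1:-1] + y[2:]
    if curvature.max() < flat_tol:
        return int(ks[0]), True
    return int(ks[1:-1][curvature.argmax()]), False


@dataclass
class KScanResult:
    """Outcome of an elbow scan over candidate state counts."""

    best_k: int
    cost_curve: dict[int, float]  # k -> mean within-cluster L1 distance
    ratio_curve: dict[int, float]  # k -> within/between distance ratio
    models: dict[int, StateModel]
    flat: bool = False


def select_k(
    samples: np.ndarray,
    k_range: range | tuple[int, int] = (2, 8),
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    flat_tol: float = 0.1,
) -> KScanResult:
    """Choose the number of states by the elbow criterion.

    Fits :func:`kmeans_l1` for each candidate k and records two fit-quality
    curves: the mean within-cluster distance (the quantity whose bend
    locates the elbow) and the within/between distance ratio (reported for
    inspection).  The elbow is the k of maximal curvature of the
    within-cluster curve (:func:`elbow_point`); strength-ordered states are
    nearly collinear in edge space, which makes the mean pairwise
    between-centroid distance collapse as k grows, so the ratio curve is
    not used for detection.  A curve with no pronounced elbow triggers a
    warning and returns the smallest candidate k.
    """
    if isinstance(k_range, tuple):
        ks = np.arange(k_range[0], k_range[1] + 1)
    else:
        ks = np.array(list(k_range))
    if ks.min() < 2:
        raise ValueError("k_range must start at 2 or above")
    samples = np.asarray(samples, dtype=float)
    if ks.max() > samples.shape[0] - 1:
        raise ValueError("k_range exceeds n_samples - 1")
    rng = np.random.default_rng(seed)
    models: dict[int, StateModel] = {}
    costs = np.empty(len(ks))
    ratios = np.empty(len(ks))
    for i, k in enumerate(ks):
        model = kmeans_l1(
            samples, int(k), n_init=n_init, max_iter=max_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
        models[int(k)] = model
        costs[i] = model.cost / samples.shape[0]
        ratios[i] = elbow_ratio(samples, model.labels, model.centroids)
    best_k, flat = elbow_point(ks, costs, flat_tol=flat_tol)
    if flat:
        warnings.warn(
            "no pronounced elbow in the within-cluster distance curve; "
            "returning the smallest k",
            stacklevel=2,
        )
    return KScanResult(
        best_k=best_k,
        cost_curve={int(k): float(c) for k, c in zip(ks, costs)},
        ratio_curve={int(k): float(r) for k, r in zip(ks, ratios)},
        models=models,
        flat=flat,
    )


def order_states(model: StateModel) -> StateModel:
    """Relabel states in ascending order of centroid strength.

    The centroid with the lowest mean edge value becomes rank 0 ("low"), the
    highest becomes rank k-1 ("high"); ties break by raw centroid index.
    Returns a new model whose ``order`` array maps raw index -> rank.
    """
    strengths = model.strengths
    # argsort is stable, so equal strengths keep raw-index order
    ranks = np.empty(model.k, dtype=int)
    ranks[np.argsort(strengths, kind="stable")] = np.arange(model.k)
    return StateModel(
        k=model.k,
        centroids=model.centroids,
        cost=model.cost,
        labels=model.labels,
        n_iter=model.n_iter,
        n_init=model.n_init,
        seed=model.seed,
        metric=model.metric,
        cost_history=model.cost_history,
        order=ranks,
    )


def assign_windows(model: StateModel, windowed: np.ndarray) -> np.ndarray:
    """Assign each window to its nearest centroid by L1 distance.

    Returns strength-rank labels (0 = low) if the model has been ordered,
    otherwise raw labels.  Ties go to the lowest (ordered) label.
    """
    windowed = np.asarray(windowed, dtype=float)
    if windowed.ndim == 1:
        windowed = windowed[None, :]
    if windowed.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature count {windowed.shape[1]} does not match model "
            f"({model.centroids.shape[1]})"
        )
    order = model.order if model.order is not None else np.arange(model.k)
    # Reorder centroid columns by rank so argmin's first-match rule
    # implements the tie-break toward the lower ordered label.
    rank_to_raw = np.argsort(order)
    dist = _l1(windowed, model.centroids[rank_to_raw])
    return dist.argmin(axis=1)


def filter_incomplete_subjects(
    assignments: dict[str, np.ndarray], k: int
) -> tuple[list[str], dict[str, list[int]]]:
    """Keep subjects whose window labels visit all k states.

    Subjects expressing only a subset of the states during the scan cannot
    contribute a mean connectivity matrix for every state and are excluded.
    Returns ``(kept_ids, excluded)`` where ``excluded`` maps subject id to
    the sorted list of states it did visit.
    """
    if not assignments:
        raise ValueError("no assignments given")
    kept: list[str] = []
    excluded: dict[str, list[int]] = {}
    for subject, labels in assignments.items():
        present = set(int(v) for v in np.unique(labels))
        if present >= set(range(k)):
            kept.append(subject)
        else:
            excluded[subject] = sorted(present)
    return kept, excluded
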