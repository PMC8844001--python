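"""Connectivity-state detection by cityblock k-means over coupling vectors.

Windowed coupling vectors from all subjects and runs are concatenated
and clustered with Lloyd-style alternation under the Manhattan
(cityblock) distance.  The objective-consistent centroid update for L1
is the component-wise median, so this is k-medians; the best of
``n_restarts`` seeded initialisations by total within-cluster cityblock
distance (inertia) is kept.

State labels are 1-based throughout (states 1..k), matching the way
brain states are named in the dynamic-connectivity literature.

Fitted centroids are matched to reference centroids (e.g. canonical
task-ready / high-arousal / low-arousal patterns from earlier studies)
by maximising total Spearman concordance under a one-to-one assignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

__all__ = [
    "ConnectivityStateModel",
    "ConnectivityStateResults",
    "CentroidMatch",
    "fit_states",
    "assign_labels",
    "match_centroids",
]


def assign_labels(vectors: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (1-based) under cityblock distance.

    Ties are broken toward the lowest state index.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if vectors.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"vector length {vectors.shape[1]} != centroid length {centroids.shape[1]}"
        )
    d = cdist(vectors, centroids, metric="cityblock")
    return d.argmin(axis=1) + 1  # argmin takes the lowest index on ties


def _inertia(vectors: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(
        np.abs(vectors - centroids[labels - 1]).sum()
    )


@dataclass
class ConnectivityStateResults:
    """Fitted connectivity-state solution.

    Attributes
    ----------
    centroids : (k, p) component-wise median centroid vectors.
    labels : (n,) 1-based state index per input window.
    inertia : total within-cluster cityblock distance.
    """

    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    k: int
    seed: int | None
    n_restarts: int
    n_iter: int
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.state_names:
            self.state_names = [f"state_{s}" for s in range(1, self.k + 1)]

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Out-of-sample assignment of new coupling vectors."""
        return assign_labels(vectors, self.centroids)

    def match(self, reference: np.ndarray, rho_floor: float = 0.5) -> "CentroidMatch":
        """Match fitted centroids against a reference centroid set."""
        return match_centroids(self.centroids, reference, rho_floor=rho_floor)

    def summary(self) -> str:
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        lines = [
            "Connectivity-state k-medians (cityblock) fit",
            f"  windows: {len(self.labels)}   k: {self.k}   "
            f"restarts: {self.n_restarts}   iterations: {self.n_iter}",
            f"  inertia (total within-cluster L1): {self.inertia:.4g}",
            "  state  n_windows  occupancy",
        ]
        for s in range(self.k):
            lines.append(
                f"  {s + 1:>5d}  {counts[s]:>9d}  {counts[s] / len(self.labels):>9.4f}"
            )
        return "\n".join(lines)

    def plot_centroid(self, state: int, n_roi: int | None = None, ax=None):
        """Heatmap of one state's centroid as a coupling matrix."""
        from .plotting import plot_centroid_matrix

        return plot_centroid_matrix(self.centroids[state - 1], n_roi=n_roi, ax=ax)


class ConnectivityStateModel:
    """k-medians model over concatenated window coupling vectors.

    Parameters
    ----------
    vectors : (n_windows_total, p) coupling vectors, concatenated over
        all subjects and runs in a fixed order.
    k : number of states (default 5).
    n_restarts : independent seeded initialisations; best inertia wins.
    max_iter : Lloyd iteration cap per restart.
    """

    def __init__(
        self,
        vectors: np.ndarray,
        k: int = 5,
        n_restarts: int = 10,
        max_iter: int = 300,
    ) -> None:
        self.vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        if not np.isfinite(self.vectors).all():
            raise ValueError("coupling vectors contain non-finite values")
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.vectors.shape[0] < k:
            raise ValueError(
                f"need at least k={k} vectors, got {self.vectors.shape[0]}"
            )
        self.k = k
        self.n_restarts = max(1, int(n_restarts))
        self.max_iter = max_iter

    def fit(self, seed: int | None = 0) -> ConnectivityStateResults:
        """Run all restarts and return the best solution by inertia."""
        seed_seq = np.random.SeedSequence(seed)
        best: tuple[float, np.ndarray, np.ndarray, int] | None = None
        for child in seed_seq.spawn(self.n_restarts):
            rng = np.random.default_rng(child)
            inertia, centroids, labels, n_iter = self._fit_once(rng)
            if best is None or inertia < best[0]:
                best = (inertia, centroids, labels, n_iter)
        assert best is not None
        inertia, centroids, labels, n_iter = best
        return ConnectivityStateResults(
            centroids=centroids,
            labels=labels,
            inertia=inertia,
            k=self.k,
            seed=seed,
            n_restarts=self.n_restarts,
            n_iter=n_iter,
        )

    def _init_centroids(self, rng: np.random.Generator) -> np.ndarray:
        """k-means++-style seeding under cityblock distance: each new
        centre is drawn with probability proportional to its distance
        from the nearest centre chosen so far.  Far more robust against
        merged/split clusters than uniform sampling."""
        x = self.vectors
        n = x.shape[0]
        # single windows are noisy centre estimates, so consider many
        # candidates per step; best-of-restarts by inertia does the rest
        n_candidates = 4 * self.k
        centres = [x[int(rng.integers(n))]]
        d = cdist(x, centres[-1][None], metric="cityblock")[:, 0]
        for _ in range(1, self.k):
            total = d.sum()
            if total == 0:  # all points identical to chosen centres
                centres.append(x[int(rng.integers(n))])
                continue
            # greedy variant: try a few distance-proportional candidates
            # and keep the one that shrinks the total distance most
            idx = rng.choice(n, size=n_candidates, p=d / total)
            cand_d = cdist(x, x[idx], metric="cityblock")
            best = int(np.minimum(cand_d, d[:, None]).sum(axis=0).argmin())
            centres.append(x[idx[best]])
            d = np.minimum(d, cand_d[:, best])
        return np.array(centres, dtype=float)

    def _fit_once(self, rng: np.random.Generator):
        x = self.vectors
        centroids = self._init_centroids(rng)
        labels = assign_labels(x, centroids)
        prev_inertia = _inertia(x, centroids, labels)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # median update (L1-optimal), re-seeding empty clusters from
            # the point farthest from its assigned centroid
            for s in range(1, self.k + 1):
                members = x[labels == s]
                if len(members) == 0:
                    dists = np.abs(x - centroids[labels - 1]).sum(axis=1)
                    centroids[s - 1] = x[int(dists.argmax())]
                else:
                    centroids[s - 1] = np.median(members, axis=0)
            new_labels = assign_labels(x, centroids)
            inertia = _inertia(x, centroids, new_labels)
            if inertia > prev_inertia + 1e-8 * max(1.0, prev_inertia):
                raise AssertionError(
                    "k-medians inertia increased across an iteration "
                    f"({prev_inertia} -> {inertia})"
                )
            converged = np.array_equal(new_labels, labels)
            labels = new_labels
            prev_inertia = inertia
            if converged:
                break
        return prev_inertia, centroids, labels, n_iter


def fit_states(
    vectors: np.ndarray,
    k: int = 5,
    n_restarts: int = 10,
    seed: int | None = 0,
    max_iter: int = 300,
) -> ConnectivityStateResults:
    """Functional front end to :class:`ConnectivityStateModel`."""
    return ConnectivityStateModel(
        vectors, k=k, n_restarts=n_restarts, max_iter=max_iter
    ).fit(seed=seed)


@dataclass
class CentroidMatch:
    """One-to-one match between two centroid sets.

    ``mapping`` pairs 1-based indices (index_in_a, index_in_b); ``rho``
    is the Spearman concordance per matched pair (NaN when a centroid is
    constant and ranks are undefined); ``unmatched`` lists 1-based
    indices, from the larger set, left without a partner or whose best
    rho fell below the floor.
    """

    mapping: list[tuple[int, int]]
    rho: np.ndarray
    unmatched: list[tuple[str, int]]
    rho_floor: float

    @property
    def min_rho(self) -> float:
        finite = self.rho[np.isfinite(self.rho)]
        return float(finite.min()) if len(finite) else float("nan")

    def permutation(self) -> dict[int, int]:
        """mapping as a dict a-index -> b-index (both 1-based)."""
        return dict(self.mapping)


def match_centroids(
    set_a: np.ndarray, set_b: np.ndarray, rho_floor: float = 0.5
) -> CentroidMatch:
    """Optimal one-to-one Spearman matching of two centroid sets.

    All pairwise Spearman correlations between centroid vectors are
    computed (average ranks for ties); the assignment minimising total
    cost 1 - rho is found with the Hungarian algorithm.  Pairs whose
    rho is below ``rho_floor`` (or undefined) are reported as
    unmatched, as are surplus centroids when the sets differ in size.
    """
    a = np.atleast_2d(np.asarray(set_a, dtype=float))
    b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both centroid sets must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("centroid sets must share vector length")
    ka, kb = a.shape[0], b.shape[0]
    rho_mat = np.full((ka, kb), np.nan)
    for i in range(ka):
        if np.ptp(a[i]) == 0:
            continue
        for j in range(kb):
            if np.ptp(b[j]) == 0:
                continue
            rho_mat[i, j] = spearmanr(a[i], b[j]).statistic
    cost = 1.0 - np.where(np.isfinite(rho_mat), rho_mat, -1.0)
    rows, cols = linear_sum_assignment(cost)
    mapping: list[tuple[int, int]] = []
    rhos: list[float] = []
    unmatched: list[tuple[str, int]] = []
    for i, j in zip(rows, cols):
        r = rho_mat[i, j]
        if np.isfinite(r) and r >= rho_floor:
            mapping.append((i + 1, j + 1))
            rhos.append(float(r))
        else:
            unmatched.append(("a", i + 1))
            unmatched.append(("b", j + 1))
    matched_a = {i for i, _ in mapping} | {i for s, i in unmatched if s == "a"}
    matched_b = {j for _, j in mapping} | {j for s, j in unmatched if s == "b"}
    unmatched.extend(("a", i + 1) for i in range(ka) if i + 1 not in matched_a)
    unmatched.extend(("b", j + 1) for j in range(kb) if j + 1 not in matched_b)
    return CentroidMatch(
        mapping=mapping, rho=np.array(rhos), unmatched=unmatched, rho_floor=rho_floor
    )
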