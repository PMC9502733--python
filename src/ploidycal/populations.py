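"""Population identification: fuzzy c-means with uncertainty filtering.

DNA content is a noisy biochemical measurement, so populations are
identified with a soft classifier: fuzzy c-means with c = 3 clusters
(debris, 2N, 4N) on the denoised (area, DNA-content) plane. Objects whose
maximum cluster membership falls below a threshold are treated as
unassignable and excluded from peak estimation. Clusters are named by
their DNA-content coordinate in ascending order, with a sanity check that
the 4N/2N center ratio is near its theoretical value of 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)


class PopulationRatioError(ValueError):
    """4N/2N cluster-center ratio outside the plausible range; the sample
    is likely mis-clustered and should be quarantined."""


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek's alternating optimization).

    Memberships and centers are iterated as

        u_ij = 1 / sum_k (||x_j - v_i|| / ||x_j - v_k||)^(2/(m-1))
        v_i  = sum_j u_ij^m x_j / sum_j u_ij^m

    until the maximum center shift drops below ``tol`` or ``max_iter`` is
    reached. A point coinciding with a center receives membership 1 for
    that center. Centers are initialized from ``c`` distinct data points
    drawn with the seeded generator.

    Parameters
    ----------
    c : number of clusters (default 3: debris, 2N, 4N).
    m : fuzzifier > 1; m -> 1 recovers hard k-means, larger m softens
        memberships (default 2, the standard choice).
    tol, max_iter : convergence controls.
    random_state : seed for center initialization.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (c, p) center coordinates.
    membership_ : (n, c) matrix U, rows summing to 1.
    labels_ : argmax-membership hard labels.
    n_iter_, converged_ : iteration count and convergence flag.
    """

    def __init__(
        self,
        c: int = 3,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        random_state: int = 0,
    ) -> None:
        self.c = c
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d = cdist(X, centers)
        zero = d <= 0.0
        with np.errstate(divide="ignore"):
            inv = d ** (-2.0 / (self.m - 1.0))
        u = np.where(np.isfinite(inv), inv, 0.0)
        u = u / u.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            u[hit, np.argmax(zero[hit], axis=1)] = 1.0
        return u

    def fit(self, X: np.ndarray, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if n <= self.c:
            raise ValueError(f"need more than c={self.c} points, got {n}")

        rng = np.random.default_rng(self.random_state)
        centers = X[rng.choice(n, size=self.c, replace=False)].copy()
        # collapse-proof init: perturb duplicated starting centers
        for i in range(1, self.c):
            while any(np.allclose(centers[i], centers[j]) for j in range(i)):
                centers[i] = X[rng.integers(n)] + rng.normal(0, 1e-9, X.shape[1])

        converged = False
        for it in range(1, self.max_iter + 1):
            u = self._memberships(X, centers)
            um = u**self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = float(np.abs(new_centers - centers).max())
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("fuzzy c-means did not converge in %d iterations", self.max_iter)

        self.cluster_centers_ = centers
        self.membership_ = self._memberships(X, centers)
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def predict_membership(self, X: np.ndarray) -> np.ndarray:
        """Membership matrix of new points against the fitted centers."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._memberships(X, self.cluster_centers_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_membership(X), axis=1)


def fuzzy_cmeans(
    points: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyCMeans:
    """Cluster points with fuzzy c-means (see FuzzyCMeans)."""
    return FuzzyCMeans(c=c, m=m, tol=tol, max_iter=max_iter, random_state=seed).fit(
        points
    )


def filter_uncertain(clustering: FuzzyCMeans, threshold: float = 0.6) -> np.ndarray:
    """Keep flags: True where the maximum membership reaches ``threshold``.

    ``threshold`` must exceed 1/c (below that every point qualifies
    trivially) and be at most 1.
    """
    c = clustering.membership_.shape[1]
    if not (1.0 / c < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (1/{c}, 1], got {threshold}")
    return clustering.membership_.max(axis=1) >= threshold


def label_populations(
    clustering: FuzzyCMeans,
    dna_per_center: np.ndarray,
    threshold: float = 0.6,
    ratio_bounds: tuple[float, float] = (1.5, 2.5),
) -> pd.DataFrame:
    """Name the c = 3 clusters (debris, 2N, 4N) by ascending DNA coordinate.

    ``dna_per_center`` gives each cluster center's DNA-content coordinate
    in original units (the clustering itself may run in standardized
    space). Objects failing the membership threshold are 'unassigned'.

    Returns a frame with columns ``population``, ``max_membership``,
    ``cluster``.

    Raises
    ------
    PopulationRatioError
        If the 4N/2N center ratio falls outside ``ratio_bounds`` — the
        sample is mis-clustered and must be excluded downstream.
    """
    dna_per_center = np.asarray(dna_per_center, dtype=float)
    if dna_per_center.shape[0] != clustering.cluster_centers_.shape[0]:
        raise ValueError("need one DNA coordinate per cluster center")
    if dna_per_center.shape[0] != 3:
        raise ValueError("population labeling expects exactly 3 clusters")

    order = np.argsort(dna_per_center)
    names = np.empty(3, dtype=object)
    names[order] = ["debris", "2N", "4N"]
    ratio = dna_per_center[order[2]] / dna_per_center[order[1]]
    if not ratio_bounds[0] <= ratio <= ratio_bounds[1]:
        raise PopulationRatioError(
            f"4N/2N center ratio {ratio:.3f} outside {ratio_bounds}; sample "
            "flagged as mis-clustered"
        )

    kept = filter_uncertain(clustering, threshold)
    pop = names[clustering.labels_].copy()
    pop[~kept] = "unassigned"
    return pd.DataFrame(
        {
            "population": pop,
            "max_membership": clustering.membership_.max(axis=1),
            "cluster": clustering.labels_,
        }
    )
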