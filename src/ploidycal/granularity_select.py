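"""Granularity-operator selection: gap statistic and majority-vote scoring.

The image-cytometry model of the flow cytometer's side-scatter channel is
one of five candidate texture measures (discrete morphological gradient,
Roberts, Prewitt, Sobel, Canny). Candidates are compared by how robustly
they let k-means recover the object populations in the area-granularity
plane across a cohort: for every sample and operator the best cluster
count is estimated with the gap statistic, each operator's count is
compared with the per-sample majority vote over operators, a disagreement
counts as a fault, and the operator with the fewest faults (highest match
ratio) wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: tie-break precedence when several operators share the best match ratio
OPERATOR_PRECEDENCE = ("DMG", "Prewitt", "Roberts", "Sobel", "Canny")


@dataclass
class GapResult:
    """Gap-statistic curve and the selected cluster count."""

    k_values: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    best_k: int
    log_wk: np.ndarray


def _within_dispersion(X: np.ndarray, k: int, seed: int, n_init: int) -> float:
    """Total within-cluster sum of squared distances of seeded k-means."""
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


class GapStatistic(BaseEstimator):
    """Cluster-count selection by the gap statistic.

    Compares the log within-cluster dispersion ``log W_k`` of k-means on
    the data against its expectation under ``B`` reference datasets drawn
    uniformly over the data's bounding box:

        Gap(k) = (1/B) * sum_b log W_kb* - log W_k

    with ``s_k`` the reference-dispersion standard error inflated by
    ``sqrt(1 + 1/B)``. The selected count is the smallest ``k`` with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` (the one-standard-error rule),
    falling back to ``k_max`` when no ``k`` qualifies.

    Attributes (after ``fit``)
    --------------------------
    best_k_ : selected cluster count.
    gap_, s_k_, log_wk_ : per-k curves over ``k_values_``.
    """

    def __init__(
        self,
        k_max: int = 6,
        B: int = 50,
        n_init: int = 10,
        random_state: int = 0,
    ) -> None:
        self.k_max = k_max
        self.B = B
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "GapStatistic":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if X.shape[0] < self.k_max + 1:
            raise ValueError(
                f"need at least k_max+1={self.k_max + 1} points, got {X.shape[0]}"
            )
        self.k_values_ = np.arange(1, self.k_max + 1)

        if np.allclose(X, X[0]):
            logger.warning("gap statistic: all points identical; best_k = 1")
            z = np.zeros(self.k_max)
            self.gap_, self.s_k_, self.log_wk_ = z, z.copy(), z.copy()
            self.best_k_ = 1
            return self

        rng = np.random.default_rng(self.random_state)
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)

        log_wk = np.array(
            [
                np.log(_within_dispersion(X, k, self.random_state, self.n_init))
                for k in self.k_values_
            ]
        )
        log_wkb = np.empty((self.B, self.k_max))
        for b in range(self.B):
            ref = lo + span * rng.random(X.shape)
            seed = int(rng.integers(0, 2**31 - 1))
            for j, k in enumerate(self.k_values_):
                log_wkb[b, j] = np.log(_within_dispersion(ref, k, seed, self.n_init))

        self.log_wk_ = log_wk
        self.gap_ = log_wkb.mean(axis=0) - log_wk
        self.s_k_ = log_wkb.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / self.B)

        best = self.k_max
        for j in range(self.k_max - 1):
            if self.gap_[j] >= self.gap_[j + 1] - self.s_k_[j + 1]:
                best = int(self.k_values_[j])
                break
        self.best_k_ = best
        return self

    def result_(self) -> GapResult:
        return GapResult(self.k_values_, self.gap_, self.s_k_, self.best_k_, self.log_wk_)


def gap_statistic(
    points: np.ndarray, k_max: int = 6, B: int = 50, seed: int = 0
) -> GapResult:
    """Estimate the best cluster count of a point set (see GapStatistic)."""
    return GapStatistic(k_max=k_max, B=B, random_state=seed).fit(points).result_()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def score_operators(
    feature_tables: list[pd.DataFrame],
    operators: tuple[str, ...] = OPERATOR_PRECEDENCE,
    k_max: int = 6,
    B: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Fault-count scoring of granularity operators across a cohort.

    For every sample and operator, the best cluster count is estimated by
    the gap statistic in the standardized (area, granularity) plane; the
    per-sample majority is the mode of the counts over operators (ties
    resolved toward the smallest count, logged); an operator's fault count
    is the number of samples where it disagrees with the majority.

    Each ``feature_tables`` entry needs columns ``area_px`` and
    ``gran_<op>`` for every operator (tables from
    :class:`~ploidycal.features.NucleusFeatureExtractor` qualify).

    Returns a table indexed by operator with columns ``best_k_per_sample``
    (list), ``fault_count``, ``match_ratio`` and ``selected`` (True for
    the winning operator; ties broken by the fixed precedence
    DMG > Prewitt > Roberts > Sobel > Canny).
    """
    if len(operators) < 2:
        raise ValueError("need at least 2 operators to vote")
    if len(feature_tables) < 1:
        raise ValueError("need at least 1 sample")

    best_k = {op: [] for op in operators}
    evaluated = 0
    for s_idx, table in enumerate(feature_tables):
        per_op = {}
        for op in operators:
            col = f"gran_{op}"
            if col not in table.columns or "area_px" not in table.columns:
                continue
            pts = np.column_stack(
                [
                    _standardize(table["area_px"].to_numpy(float)),
                    _standardize(table[col].to_numpy(float)),
                ]
            )
            try:
                per_op[op] = gap_statistic(pts, k_max=k_max, B=B, seed=seed).best_k
            except ValueError as exc:
                logger.warning("sample %d operator %s failed: %s", s_idx, op, exc)
        if not per_op:
            logger.warning("sample %d: all operators failed; excluded", s_idx)
            continue
        evaluated += 1
        for op in operators:
            best_k[op].append(per_op.get(op))

    if evaluated == 0:
        raise ValueError("no sample could be scored")

    rows = {}
    for i in range(evaluated):
        counts = [best_k[op][i] for op in operators if best_k[op][i] is not None]
        vals, freq = np.unique(counts, return_counts=True)
        winners = vals[freq == freq.max()]
        if len(winners) > 1:
            logger.info("sample %d: majority tie %s; taking smallest", i, winners)
        rows.setdefault("majority", []).append(int(winners.min()))

    majority = rows["majority"]
    records = []
    for op in operators:
        matches = sum(
            1 for i in range(evaluated)
            if best_k[op][i] is not None and best_k[op][i] == majority[i]
        )
        records.append(
            {
                "operator": op,
                "best_k_per_sample": best_k[op],
                "majority_per_sample": majority,
                "fault_count": evaluated - matches,
                "match_ratio": matches / evaluated,
            }
        )
    table = pd.DataFrame(records).set_index("operator")
    best_ratio = table["match_ratio"].max()
    tied = [op for op in OPERATOR_PRECEDENCE if op in table.index
            and table.loc[op, "match_ratio"] == best_ratio]
    tied += [op for op in table.index if op not in tied
             and table.loc[op, "match_ratio"] == best_ratio]
    table["selected"] = [op == tied[0] for op in table.index]
    return table
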