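"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package: background sets
are found by enumerating all pixel-pair distances, gradient operators by
explicit clamped-index loops, and the gap statistic by a separate k-means
implementation (scipy's kmeans2). They define the expected values the
package must reproduce.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist


def annulus_pixels_bruteforce(labels: np.ndarray, object_id: int, D: float, d: float):
    """Coordinates of background pixels with dist(obj) <= D and
    dist(any object) > d, by full pairwise-distance enumeration."""
    bg = np.argwhere(labels == 0)
    obj = np.argwhere(labels == object_id)
    anyobj = np.argwhere(labels > 0)
    d_self = cdist(bg, obj).min(axis=1)
    d_any = cdist(bg, anyobj).min(axis=1)
    keep = (d_self <= D) & (d_any > d)
    return bg[keep]


def iod_bruteforce(
    intensity: np.ndarray, labels: np.ndarray, object_id: int, D: float, d: float
) -> float:
    """Integrated density via the enumerated annulus; falls back to the
    global >d background mean when the annulus is empty."""
    sel = annulus_pixels_bruteforce(labels, object_id, D, d)
    if len(sel) == 0:
        bg = np.argwhere(labels == 0)
        anyobj = np.argwhere(labels > 0)
        keep = cdist(bg, anyobj).min(axis=1) > d
        sel = bg[keep]
    bkg_mean = intensity[sel[:, 0], sel[:, 1]].mean()
    obj = labels == object_id
    return float(intensity[obj].sum() - obj.sum() * bkg_mean)


def _clamped(img: np.ndarray, i: int, j: int) -> float:
    h, w = img.shape
    return img[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]


def gradient_bruteforce(intensity: np.ndarray, operator: str) -> np.ndarray:
    """Explicit-loop gradient magnitude with clamped-edge handling."""
    h, w = intensity.shape
    out = np.zeros((h, w))
    ky = {
        "Prewitt": np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], float),
        "Sobel": np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float),
    }
    for i in range(h):
        for j in range(w):
            if operator == "DMG":
                vals = [
                    _clamped(intensity, i + u, j + v)
                    for u in (-1, 0, 1)
                    for v in (-1, 0, 1)
                ]
                out[i, j] = max(vals) - min(vals)
            elif operator == "Roberts":
                g1 = intensity[i, j] - _clamped(intensity, i + 1, j + 1)
                g2 = _clamped(intensity, i, j + 1) - _clamped(intensity, i + 1, j)
                out[i, j] = np.hypot(g1, g2)
            else:
                k = ky[operator]
                gy = sum(
                    k[u + 1, v + 1] * _clamped(intensity, i + u, j + v)
                    for u in (-1, 0, 1)
                    for v in (-1, 0, 1)
                )
                gx = sum(
                    k.T[u + 1, v + 1] * _clamped(intensity, i + u, j + v)
                    for u in (-1, 0, 1)
                    for v in (-1, 0, 1)
                )
                out[i, j] = np.hypot(gy, gx)
    return out


def _wk_kmeans2(X: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    centroids, lab = kmeans2(X, k, minit="++", seed=seed, iter=50)
    return float(((X - centroids[lab]) ** 2).sum())


def gap_bruteforce(X: np.ndarray, k_max: int, B: int, seed: int) -> int:
    """Gap-statistic best_k with an independent k-means (scipy kmeans2)."""
    rng = np.random.default_rng(seed + 99991)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    ks = range(1, k_max + 1)
    log_wk = np.array([np.log(_wk_kmeans2(X, k, seed)) for k in ks])
    ref = np.empty((B, k_max))
    for b in range(B):
        Xb = lo + span * rng.random(X.shape)
        sb = int(rng.integers(0, 2**31 - 1))
        ref[b] = [np.log(_wk_kmeans2(Xb, k, sb)) for k in ks]
    gap = ref.mean(axis=0) - log_wk
    s_k = ref.std(axis=0) * np.sqrt(1 + 1 / B)
    for j in range(k_max - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            return j + 1
    return k_max


def random_labeled_scene(rng: np.random.Generator, size: int = 64, max_objects: int = 4):
    """A random small scene (disks and rectangles) independent of the
    package's generator: returns (intensity, labels)."""
    h = w = size
    labels = np.zeros((h, w), dtype=np.int32)
    intensity = rng.integers(90, 111, size=(h, w)).astype(float)
    n_obj = int(rng.integers(1, max_objects + 1))
    yy, xx = np.mgrid[0:h, 0:w]
    k = 0
    for _ in range(n_obj):
        if rng.random() < 0.5:
            r = rng.integers(2, 7)
            cy, cx = rng.integers(r, h - r), rng.integers(r, w - r)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            ry, rx = rng.integers(2, 7, size=2)
            cy, cx = rng.integers(ry, h - ry), rng.integers(rx, w - rx)
            mask = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
        mask &= labels == 0
        if mask.sum() == 0:
            continue
        k += 1
        labels[mask] = k
        intensity[mask] += rng.integers(50, 400)
    if k == 0:  # guarantee at least one object
        labels[5:9, 5:9] = 1
        intensity[5:9, 5:9] += 100
    return intensity, labels
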