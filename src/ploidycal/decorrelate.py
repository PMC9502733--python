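"""Per-sample PCA over (area, DNA content, granularity).

On well-behaved samples the three measurements are nearly uncorrelated,
so each principal component aligns almost perfectly with one feature axis
(dominant loadings close to 1). Fitting the PCA per sample serves two
purposes: it verifies this near-independence, and its component scores —
mapped back to the original feature units — provide noise-filtered DNA
content and area coordinates for population identification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class PCADenoiser(TransformerMixin, BaseEstimator):
    """PCA with axis-aligned component mapping and unit back-scaling.

    Columns are centered and (by default) divided by their standard
    deviation when requested; the loading matrix is the eigenvector
    basis of the resulting covariance, with a deterministic sign convention (each
    component's largest-magnitude loading is positive). Components are
    identified with features by their dominant absolute loading — not by
    index — so the mapping is robust to explained-variance reordering.

    Parameters
    ----------
    scaling : "none" (default) or "unit_variance". The default works on
        the raw covariance: DNA-content variance exceeds granularity and
        area variance by orders of magnitude, so with weak correlation
        each eigenvector aligns with one feature axis. Unit-variance
        scaling equalizes the spectrum and makes the eigenbasis of
        correlated features unstable (degenerate eigenvalues), so it is
        offered only for exploratory use.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (p, p) matrix, columns = components, orthonormal.
    explained_variance_ : per-component variance of the scaled data.
    mapping_ : dict feature name -> component index (by dominant loading).
    bijective_ : whether the mapping assigns each feature a distinct
        component.
    mean_, scale_ : per-feature centering and scaling constants.
    """

    def __init__(self, scaling: str = "none") -> None:
        self.scaling = scaling

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "PCADenoiser":
        if self.scaling not in ("unit_variance", "none"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{i}" for i in range(X.shape[1])]
        if X.shape[0] < 3:
            raise ValueError("need at least 3 observations")
        if not np.isfinite(X).all():
            raise ValueError("input contains non-finite values")

        self.mean_ = X.mean(axis=0)
        if self.scaling == "unit_variance":
            sd = X.std(axis=0, ddof=1)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            if (sd == 0).any():
                logger.warning("constant feature column(s); left unscaled")
        else:
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_

        cov = np.cov(Z, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # sign convention: dominant loading of each component is positive
        for j in range(evecs.shape[1]):
            i = int(np.argmax(np.abs(evecs[:, j])))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]

        self.loadings_ = evecs
        self.explained_variance_ = evals
        # feature -> component carrying its largest absolute loading
        row_best = np.argmax(np.abs(evecs), axis=1)
        self.mapping_ = {
            name: int(row_best[i]) for i, name in enumerate(self.feature_names_in_)
        }
        col_dominant = np.argmax(np.abs(evecs), axis=0)
        self.bijective_ = (
            len(set(self.mapping_.values())) == evecs.shape[1]
            and len(set(col_dominant.tolist())) == evecs.shape[1]
        )
        if not self.bijective_:
            logger.warning(
                "component-feature mapping is not bijective (correlated "
                "features); dominant rows per component: %s", col_dominant,
            )
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Component scores of (scaled, centered) observations."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.loadings_

    def correct(
        self,
        X: pd.DataFrame | np.ndarray,
        dna_feature: str = "dna",
        area_feature: str = "area",
    ) -> pd.DataFrame:
        """Noise-filtered DNA content and area in original units.

        Takes the score coordinate of the component mapped to each feature
        and rescales it back (times the feature's scaling factor, plus its
        mean). With perfectly uncorrelated input this is the identity; in
        general it drops the variance the other components carried.
        """
        for name in (dna_feature, area_feature):
            if name not in self.mapping_:
                raise ValueError(
                    f"unknown feature {name!r}; fitted on {self.feature_names_in_}"
                )
        if self.mapping_[dna_feature] == self.mapping_[area_feature]:
            raise ValueError(
                f"features {dna_feature!r} and {area_feature!r} map to the same "
                f"component (mapping: {self.mapping_}); inspect loadings_ — the "
                "two measurements are too correlated to separate"
            )
        scores = self.transform(X)
        out = {}
        for label, name in (("dna_denoised", dna_feature), ("area_denoised", area_feature)):
            j = self.mapping_[name]
            i = self.feature_names_in_.index(name)
            out[label] = scores[:, j] * self.scale_[i] + self.mean_[i]
        return pd.DataFrame(out)


def fit_pca(features: pd.DataFrame, scaling: str = "none") -> PCADenoiser:
    """Fit a per-sample PCA over a feature table (see PCADenoiser)."""
    return PCADenoiser(scaling=scaling).fit(features)


def correct(features: pd.DataFrame, pca: PCADenoiser, **kw) -> pd.DataFrame:
    """Denoised (dna, area) coordinates of a fitted PCA (see PCADenoiser.correct)."""
    return pca.correct(features, **kw)
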