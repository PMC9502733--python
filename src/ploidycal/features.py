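"""Per-nucleus measurements: integrated density, area, granularity.

The DNA-content proxy is the integrated optical density (IOD): the sum of
an object's pixel intensities minus its pixel count times the mean of a
local background annulus,

    ID = sum_{p in O} I(p) - |O| * mean(B),

where the background set ``B`` collects intensities of non-object pixels
whose Euclidean distance to the measured object is at most ``D`` and whose
distance to *every* object exceeds ``d`` (the proximity halo around any
neighboring object is excluded as well, so object adjacency cannot bias
the estimate). ``D`` defaults to 35 px — the average object size at the
source magnification, keeping whole neighboring objects out of the
neighborhood — and ``d`` to 5 px, the distance at which the bulk of the
object-proximity intensity effect has decayed.

Area is the raw pixel count of the object's label. Granularity — the ICM
model of the flow cytometer's side-scatter signal — is the sum of a
gradient-magnitude (or Canny edge) image over the object after eroding
its mask by the operator's kernel radius, so the value reflects internal
texture rather than the object's outline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .datatypes import (
    GRANULARITY_OPERATORS,
    BackgroundConfig,
    EmptyAnnulusError,
    LabeledImage,
)

logger = logging.getLogger(__name__)

_ROBERTS_K1 = np.array([[1.0, 0.0], [0.0, -1.0]])
_ROBERTS_K2 = np.array([[0.0, 1.0], [-1.0, 0.0]])
_PREWITT_KY = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]])
_SOBEL_KY = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])

#: mask-erosion radius per operator (kernel support; Canny's Gaussian
#: smoothing at sigma=1 spreads edges ~2 px)
_EROSION_RADIUS = {"DMG": 1, "Roberts": 1, "Prewitt": 1, "Sobel": 1, "Canny": 2}

CANNY_SIGMA = 1.0


def _distance_to_objects(labels: np.ndarray) -> np.ndarray:
    """Euclidean distance from every pixel to the nearest object pixel."""
    return ndimage.distance_transform_edt(labels == 0)


def background_annulus(
    image: LabeledImage, object_id: int, cfg: BackgroundConfig | None = None
) -> np.ndarray:
    """Background pixel intensities in the annulus around one object.

    Returns the intensities of pixels that belong to no object, lie within
    Euclidean distance ``D`` of the measured object, and lie farther than
    ``d`` from every object.

    Raises
    ------
    KeyError
        If ``object_id`` is absent from the label raster.
    EmptyAnnulusError
        If no pixel satisfies the constraints (e.g. the object is fully
        enclosed by neighbors within distance ``d``).
    """
    cfg = cfg or BackgroundConfig()
    obj = image.labels == object_id
    if not obj.any():
        raise KeyError(f"object {object_id} not present in label raster")
    dist_self = ndimage.distance_transform_edt(~obj)
    dist_any = _distance_to_objects(image.labels)
    sel = (image.labels == 0) & (dist_any > cfg.d) & (dist_self <= cfg.D)
    if not sel.any():
        raise EmptyAnnulusError(
            f"no background pixel in ({cfg.d}, {cfg.D}] around object {object_id}"
        )
    return image.intensity[sel]


def global_background(
    image: LabeledImage, cfg: BackgroundConfig | None = None
) -> float:
    """Tile-level fallback background: mean of all pixels > d from any object."""
    cfg = cfg or BackgroundConfig()
    sel = (image.labels == 0) & (_distance_to_objects(image.labels) > cfg.d)
    if not sel.any():
        raise EmptyAnnulusError("no background pixel > d from every object")
    return float(image.intensity[sel].mean())


def object_area(image: LabeledImage, object_id: int) -> int:
    """Pixel count of one labeled object."""
    area = int((image.labels == object_id).sum())
    if area == 0:
        raise KeyError(f"object {object_id} not present in label raster")
    return area


def integrated_density(
    image: LabeledImage, object_id: int, cfg: BackgroundConfig | None = None
) -> float:
    """Background-corrected integrated density of one object.

    May legitimately be negative for objects dimmer than their local
    background; the value is not clipped. When the annulus is empty the
    tile-level background mean is substituted (logged).
    """
    cfg = cfg or BackgroundConfig()
    obj = image.labels == object_id
    if not obj.any():
        raise KeyError(f"object {object_id} not present in label raster")
    try:
        bkg = background_annulus(image, object_id, cfg)
        bkg_mean = float(bkg.mean())
    except EmptyAnnulusError:
        logger.warning(
            "object %d: empty background annulus, falling back to tile-level "
            "background",
            object_id,
        )
        bkg_mean = global_background(image, cfg)
    return float(image.intensity[obj].sum() - obj.sum() * bkg_mean)


def _gradient_image(intensity: np.ndarray, operator: str) -> np.ndarray:
    """Edge-strength raster for one operator over the whole frame.

    Linear operators use clamped-edge (nearest) boundary handling; DMG is
    the grey-scale dilation minus erosion over a 3x3 square.
    """
    if operator == "DMG":
        dil = ndimage.grey_dilation(intensity, size=(3, 3), mode="nearest")
        ero = ndimage.grey_erosion(intensity, size=(3, 3), mode="nearest")
        return dil - ero
    if operator == "Roberts":
        padded = np.pad(intensity, ((0, 1), (0, 1)), mode="edge")
        g1 = padded[:-1, :-1] - padded[1:, 1:]
        g2 = padded[:-1, 1:] - padded[1:, :-1]
        return np.hypot(g1, g2)
    if operator in ("Prewitt", "Sobel"):
        ky = _PREWITT_KY if operator == "Prewitt" else _SOBEL_KY
        gy = ndimage.correlate(intensity, ky, mode="nearest")
        gx = ndimage.correlate(intensity, ky.T, mode="nearest")
        return np.hypot(gy, gx)
    if operator == "Canny":
        mag = _gradient_image(intensity, "Sobel")
        if np.ptp(mag) == 0:
            return np.zeros_like(intensity)
        high = float(threshold_otsu(mag))
        edges = canny(
            intensity, sigma=CANNY_SIGMA, low_threshold=0.5 * high,
            high_threshold=high,
        )
        return edges.astype(np.float64)
    raise ValueError(
        f"unknown granularity operator {operator!r}; expected one of "
        f"{GRANULARITY_OPERATORS}"
    )


def granularity(
    image: LabeledImage,
    object_id: int,
    operator: str = "DMG",
    _gradient: np.ndarray | None = None,
) -> float:
    """Granularity of one object under a named operator.

    The gradient image is computed over the whole raster; the object's
    value is the sum over its mask eroded by the operator's kernel radius
    (boundary suppression — the perimeter edge would otherwise dominate
    the internal texture). An object with no interior after erosion
    scores 0.
    """
    obj = image.labels == object_id
    if not obj.any():
        raise KeyError(f"object {object_id} not present in label raster")
    grad = _gradient_image(image.intensity, operator) if _gradient is None else _gradient
    r = _EROSION_RADIUS[operator]
    interior = ndimage.binary_erosion(
        obj, structure=np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    )
    if not interior.any():
        logger.warning(
            "object %d has no interior after erosion (radius %d); granularity 0",
            object_id, r,
        )
        return 0.0
    return float(grad[interior].sum())


class NucleusFeatureExtractor(BaseEstimator):
    """Per-object feature measurement over a labeled fluorescence image.

    A stateless transformer in the scikit-learn idiom: ``fit`` validates
    parameters, ``transform`` maps a :class:`LabeledImage` to a feature
    table with one row per label (ordered by label), columns
    ``object_id, area_px, iod, bkg_mean, bkg_n, status`` plus one
    granularity column per requested operator (``gran_<op>``).

    Parameters
    ----------
    D, d : background annulus geometry (see :class:`BackgroundConfig`).
    operators : granularity operators to evaluate.
    """

    def __init__(
        self,
        D: float = 35.0,
        d: float = 5.0,
        operators: tuple[str, ...] = GRANULARITY_OPERATORS,
    ) -> None:
        self.D = D
        self.d = d
        self.operators = operators

    def fit(self, X: LabeledImage | None = None, y=None) -> "NucleusFeatureExtractor":
        self.config_ = BackgroundConfig(D=self.D, d=self.d)
        for op in self.operators:
            if op not in GRANULARITY_OPERATORS:
                raise ValueError(f"unknown granularity operator {op!r}")
        return self

    def transform(self, X: LabeledImage) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit()
        image = X
        ids = image.object_ids
        if ids.size == 0:
            raise ValueError("label raster contains no objects")
        gradients = {
            op: _gradient_image(image.intensity, op) for op in self.operators
        }
        dist_any = _distance_to_objects(image.labels)
        glob_sel = (image.labels == 0) & (dist_any > self.config_.d)
        glob_bkg = float(image.intensity[glob_sel].mean()) if glob_sel.any() else np.nan

        rows = []
        for oid in ids:
            obj = image.labels == oid
            status = "ok"
            dist_self = ndimage.distance_transform_edt(~obj)
            sel = glob_sel & (dist_self <= self.config_.D)
            if sel.any():
                bkg_vals = image.intensity[sel]
                bkg_mean, bkg_n = float(bkg_vals.mean()), int(sel.sum())
            elif np.isfinite(glob_bkg):
                bkg_mean, bkg_n = glob_bkg, 0
                status = "fallback_background"
                logger.warning("object %d: empty annulus, tile background used", oid)
            else:
                rows.append({"object_id": int(oid), "status": "no_background"})
                continue
            row = {
                "object_id": int(oid),
                "area_px": int(obj.sum()),
                "iod": float(image.intensity[obj].sum() - obj.sum() * bkg_mean),
                "bkg_mean": bkg_mean,
                "bkg_n": bkg_n,
                "status": status,
            }
            for op in self.operators:
                row[f"gran_{op}"] = granularity(image, int(oid), op, gradients[op])
            rows.append(row)
        table = pd.DataFrame(rows).sort_values("object_id", ignore_index=True)
        return table

    def fit_transform(self, X: LabeledImage, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def extract_features(
    image: LabeledImage,
    cfg: BackgroundConfig | None = None,
    operators: tuple[str, ...] = GRANULARITY_OPERATORS,
) -> pd.DataFrame:
    """Measure every object in a labeled image (see NucleusFeatureExtractor)."""
    cfg = cfg or BackgroundConfig()
    return NucleusFeatureExtractor(D=cfg.D, d=cfg.d, operators=operators).fit_transform(
        image
    )
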