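"""Shared domain types for the ploidy-analysis pipeline.

All types are plain dataclasses validated at construction time. Measurement
units follow cytometry convention: image intensities are arbitrary
fluorescence units (a.u.), areas are pixel counts, and flow-cytometry
values are detector channel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class EmptyAnnulusError(RuntimeError):
    """Raised when no background pixel survives the annulus constraints.

    Callers fall back to the image-level background estimate (and log
    the occurrence); see :func:`ploidycal.features.integrated_density`.
    """


@dataclass(frozen=True)
class SampleSpec:
    """Parameters of one synthetic healthy-blood sample.

    A healthy sample contains two nuclear populations whose DNA contents
    stand in an exact 1:2 relation (G0/G1 "2N" cells and G2/M "4N" cells)
    plus a low-intensity debris fraction. The same underlying cells are
    rendered both as flow-cytometry (FCM) events and image-cytometry (ICM)
    measurements, related by global instrument scale factors.

    Parameters
    ----------
    n_cells : total number of objects (cells plus debris), >= 50.
    mu_2N : mean ICM DNA-content intensity of the 2N population (a.u.).
    cv : within-population coefficient of variation (fraction).
    frac_4N : fraction of cells in the 4N population.
    frac_debris : fraction of low-intensity debris objects.
    fcm_scale : factor mapping true DNA content to FCM channel units.
    icm_scale : per-sample global ICM intensity multiplier; models
        exposure / dye-bleaching differences between slides.
    seed : seed for the sample's random stream.
    """

    n_cells: int = 2000
    mu_2N: float = 5000.0
    cv: float = 0.03
    frac_4N: float = 0.25
    frac_debris: float = 0.10
    fcm_scale: float = 0.04
    icm_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 50:
            raise ValueError(
                "n_cells must be >= 50: fewer objects cannot support the "
                f"downstream histogram stages (got {self.n_cells})"
            )
        if self.mu_2N <= 0:
            raise ValueError("mu_2N must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not (0 <= self.frac_4N and 0 <= self.frac_debris):
            raise ValueError("population fractions must be non-negative")
        if self.frac_4N + self.frac_debris >= 1:
            raise ValueError("frac_4N + frac_debris must be < 1")
        if self.fcm_scale <= 0 or self.icm_scale <= 0:
            raise ValueError("scale factors must be positive")


@dataclass(frozen=True)
class ImageSceneSpec:
    """Geometry and noise of a rendered fluorescence image scene.

    Objects are disks with sinusoidal internal texture placed on a
    (optionally ramped) background; nuclei on PI-stained slides appear as
    cohesive, well-separated round objects, so disk geometry is adequate
    for the intensity/area/granularity measurements exercised here.

    Attributes
    ----------
    image_size : (height, width) in pixels.
    radius_range : (min, max) object radius in pixels.
    texture_amplitude : relative amplitude of the internal sinusoidal
        intensity modulation (drives the granularity measures).
    background_level : base background intensity (a.u.).
    background_gradient : total linear intensity ramp across the frame
        (a.u. from left edge to right edge); models uneven illumination
        and dye accumulation.
    noise_sd : additive Gaussian pixel noise standard deviation.
    min_separation : minimum gap between object borders, pixels.
    seed : seed for object placement and noise.
    """

    image_size: tuple[int, int] = (256, 256)
    radius_range: tuple[float, float] = (8.0, 14.0)
    texture_amplitude: float = 0.3
    background_level: float = 200.0
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    min_separation: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least 16x16")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if self.noise_sd < 0 or self.min_separation < 0:
            raise ValueError("noise_sd and min_separation must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")


@dataclass
class LabeledImage:
    """An intensity raster paired with an integer label raster.

    ``labels`` uses 0 for background and k > 0 for object k; both rasters
    share dimensions. Intensities are stored as float64 internally (16-bit
    rasters on disk); label values need not be consecutive.
    """

    intensity: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.intensity.ndim != 2 or self.labels.ndim != 2:
            raise ValueError("intensity and labels must be 2-D rasters")
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                "intensity and labels must share dimensions: "
                f"{self.intensity.shape} vs {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass(frozen=True)
class BackgroundConfig:
    """Local-background annulus geometry.

    ``D`` is the neighborhood radius (default 35 px, the average object
    size at the source magnification, chosen so whole neighboring objects
    fall outside the neighborhood); ``d`` is the proximity exclusion
    distance (default 5 px, the distance at which the bulk of the
    object-proximity effect on intensity has decayed).
    """

    D: float = 35.0
    d: float = 5.0

    def __post_init__(self) -> None:
        if not (self.D > self.d > 0):
            raise ValueError(f"require D > d > 0, got D={self.D}, d={self.d}")


GRANULARITY_OPERATORS = ("DMG", "Roberts", "Prewitt", "Sobel", "Canny")


@dataclass(frozen=True)
class HistogramSpec:
    """Binning used for DNA-content histograms.

    256 bins over the per-sample data range by default, mirroring typical
    flow-cytometer channel resolution. Bins are half-open ``[lo, hi)``
    except the last, which is closed.
    """

    bin_count: int = 256
    range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.bin_count < 32:
            raise ValueError("bin_count must be >= 32")
        if self.range is not None and not self.range[0] < self.range[1]:
            raise ValueError("range must satisfy lo < hi")


@dataclass
class PeakEstimate:
    """A single population's DNA-content peak location.

    ``method`` is ``"bin_peak"`` (center of the modal histogram bin) or
    ``"gauss_fit"`` (mean of a least-squares normal curve fitted to the
    binned counts). For ``gauss_fit``, ``amplitude``/``mu``/``sigma`` hold
    the fitted curve parameters and ``converged`` records whether the
    optimizer succeeded (on failure ``location`` falls back to the inner-90%
    trimmed mean).
    """

    sample_id: str
    population: str
    method: str
    location: float
    n_members: int
    amplitude: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.population not in ("2N", "4N", "debris"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.method not in ("bin_peak", "gauss_fit"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.location > 0:
            raise ValueError("peak location must be positive")
        if self.method == "gauss_fit" and self.converged and not self.sigma > 0:
            raise ValueError("sigma must be positive for a converged fit")


@dataclass(frozen=True)
class PeakPair:
    """Matched ICM and FCM 2N/4N peak locations for one sample."""

    sample_id: str
    icm_2N: float
    icm_4N: float
    fcm_2N: float
    fcm_4N: float
    method: str = "gauss_fit"

    def __post_init__(self) -> None:
        for name in ("icm_2N", "icm_4N", "fcm_2N", "fcm_4N"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
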