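"""Synthetic paired FCM/ICM samples with known ground truth.

Real PI-stained blood slides and their matched flow-cytometry list files
are not redistributable, so the generator emulates the relevant structure:
two nuclear populations whose true DNA contents stand in an exact 1:2
relation with small coefficients of variation, a low-intensity debris
population, and per-sample global ICM intensity scaling that models
exposure and dye-bleaching differences between slides. The same underlying
cells are rendered in both modalities, making every downstream stage
testable against ground truth.

Generative model
----------------
Each cell carries an exact true DNA content: ``mu_2N`` for 2N cells,
``2 * mu_2N`` for 4N cells, and a Uniform(0, 0.7 * mu_2N) draw for debris.
Each modality observes ``scale * content * (1 + eps)`` with independent
``eps ~ N(0, cv)`` truncated so values stay positive — i.e. within each
population the observed values are Normal(mu, cv * mu). The population
mean ratio E[4N]/E[2N] is therefore exactly 2 regardless of either scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import ImageSceneSpec, LabeledImage, SampleSpec

logger = logging.getLogger(__name__)

# Morphology of the non-DNA features. Projected nuclear area and chromatin
# texture shift only mildly between populations and carry broad biological
# scatter, so — as in real stained-slide data, where the three measurements
# correlate weakly — area and granularity are weakly informative: useful to
# a clusterer, but far from separating populations on their own.
AREA_2N_PX = 350.0
AREA_RATIO_4N = 1.3
AREA_RATIO_DEBRIS = 0.5
AREA_CV = 0.15
TEXTURE_RATIO_4N = 1.5
TEXTURE_RATIO_DEBRIS = 0.6
GRANULARITY_BASE = 400.0
GRANULARITY_CV = 0.35
DEBRIS_MAX_FRACTION = 0.7  # debris contents are Uniform(0, 0.7 * mu_2N)


@dataclass
class PairedSample:
    """One sample rendered in both modalities plus per-cell ground truth.

    ``truth`` has one row per object (object_id, population, true_content);
    ``fcm_events`` holds (event_id, fsc_area); ``icm_features`` holds
    (object_id, dna, area, granularity) in ICM units.
    """

    sample_id: str
    spec: SampleSpec
    truth: pd.DataFrame
    fcm_events: pd.DataFrame
    icm_features: pd.DataFrame


def _population_labels(spec: SampleSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_cells
    n_debris = int(round(spec.frac_debris * n))
    n_4n = int(round(spec.frac_4N * n))
    labels = np.array(
        ["debris"] * n_debris + ["4N"] * n_4n + ["2N"] * (n - n_debris - n_4n),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _positive_noise(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative factors 1 + N(0, cv), redrawn while non-positive."""
    if cv == 0:
        return np.ones(n)
    f = 1.0 + rng.normal(0.0, cv, size=n)
    while (bad := f <= 0).any():  # truncation at zero; negligible for small cv
        f[bad] = 1.0 + rng.normal(0.0, cv, size=int(bad.sum()))
    return f


def generate_event_sample(spec: SampleSpec, sample_id: str = "s0") -> PairedSample:
    """Draw one paired FCM/ICM sample from the generative model.

    Returns a :class:`PairedSample` whose FCM ``fsc_area`` values equal
    ``fcm_scale * content * (1 + eps)`` and whose ICM ``dna`` values equal
    ``icm_scale * content * (1 + eps')`` with independent noise draws, so
    both modalities measure the same cells.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _population_labels(spec, rng)
    n = spec.n_cells

    content = np.full(n, spec.mu_2N)
    content[labels == "4N"] = 2.0 * spec.mu_2N
    n_debris = int((labels == "debris").sum())
    content[labels == "debris"] = rng.uniform(
        0.0, DEBRIS_MAX_FRACTION * spec.mu_2N, size=n_debris
    )

    fcm = spec.fcm_scale * content * _positive_noise(n, spec.cv, rng)
    icm = spec.icm_scale * content * _positive_noise(n, spec.cv, rng)

    area = np.full(n, AREA_2N_PX)
    area[labels == "4N"] = AREA_2N_PX * AREA_RATIO_4N
    area[labels == "debris"] = AREA_2N_PX * AREA_RATIO_DEBRIS
    area = area * _positive_noise(n, AREA_CV, rng)

    texture = np.where(
        labels == "4N", TEXTURE_RATIO_4N,
        np.where(labels == "debris", TEXTURE_RATIO_DEBRIS, 1.0),
    )
    granularity = (
        GRANULARITY_BASE
        * spec.icm_scale
        * texture
        * _positive_noise(n, GRANULARITY_CV, rng)
    )

    ids = np.arange(1, n + 1)
    truth = pd.DataFrame(
        {"object_id": ids, "population": labels, "true_content": content}
    )
    fcm_events = pd.DataFrame({"event_id": ids, "fsc_area": fcm})
    icm_features = pd.DataFrame(
        {"object_id": ids, "dna": icm, "area": area, "granularity": granularity}
    )
    return PairedSample(sample_id, spec, truth, fcm_events, icm_features)


def generate_image_sample(
    spec: SampleSpec,
    scene: ImageSceneSpec,
    max_placement_tries: int = 200,
) -> tuple[LabeledImage, pd.DataFrame]:
    """Render one sample as an intensity raster plus labeled mask.

    Each cell becomes a disk whose added intensity (above the local
    background) sums exactly to its ICM DNA value: the per-pixel increments
    carry a zero-mean sinusoidal texture, are rounded to integers, and the
    recorded ground-truth integrated density is their exact integer sum.
    The background is an integer base level plus an optional left-to-right
    linear ramp. Ground-truth columns: object_id, population, true_iod,
    true_area, row, col.

    Raises
    ------
    RuntimeError
        If an object cannot be placed at ``min_separation`` from all
        previously placed objects within ``max_placement_tries`` draws.
    """
    paired = generate_event_sample(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, scene.seed, 1]))
    h, w = scene.image_size
    n = spec.n_cells

    radii = rng.uniform(*scene.radius_range, size=n)
    centers = np.empty((n, 2))
    for i in range(n):
        r = radii[i]
        for _ in range(max_placement_tries):
            pos = rng.uniform([r + 1, r + 1], [h - r - 1, w - r - 1])
            if i == 0:
                break
            gaps = (
                np.hypot(*(centers[:i] - pos).T) - radii[:i] - r
            )
            if (gaps >= scene.min_separation).all():
                break
        else:
            raise RuntimeError(
                f"could not place object {i + 1}/{n} with min_separation="
                f"{scene.min_separation} in a {h}x{w} frame; enlarge the "
                "frame or reduce n_cells/min_separation"
            )
        centers[i] = pos

    cols = np.arange(w, dtype=float)
    ramp = scene.background_gradient * (cols / max(w - 1, 1))
    background = np.rint(scene.background_level + ramp)
    intensity = np.tile(background, (h, 1))
    labels = np.zeros((h, w), dtype=np.int32)

    rows = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(n):
        cy, cx = centers[i]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radii[i] ** 2
        area = int(mask.sum())
        dna = float(paired.icm_features["dna"].iloc[i])
        # zero-mean texture over the disk so the painted sum stays = dna
        phase = rng.uniform(0, 2 * np.pi, size=2)
        freq = 2 * np.pi / max(radii[i] / 1.5, 1.0)
        tex = np.sin(freq * yy[mask] + phase[0]) * np.sin(freq * xx[mask] + phase[1])
        tex = tex - tex.mean()
        amp = scene.texture_amplitude
        if paired.truth["population"].iloc[i] == "4N":
            amp *= TEXTURE_RATIO_4N
        inc = np.rint((dna / area) * (1.0 + amp * tex)).astype(np.int64)
        intensity[mask] += inc
        labels[mask] = i + 1
        rows.append(
            {
                "object_id": i + 1,
                "population": paired.truth["population"].iloc[i],
                "true_iod": int(inc.sum()),
                "true_area": area,
                "row": cy,
                "col": cx,
            }
        )

    if scene.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, scene.noise_sd, size=(h, w))
    intensity = np.clip(intensity, 0.0, 65535.0)
    return LabeledImage(intensity, labels), pd.DataFrame(rows)


def generate_cohort(
    n_samples: int,
    base_spec: SampleSpec,
    icm_scale_jitter: float = 0.0,
    outlier_indices: tuple[int, ...] = (),
    outlier_scale: float = 0.3,
    seed: int | None = None,
) -> tuple[list[PairedSample], pd.DataFrame]:
    """Generate a cohort of paired samples sharing one FCM reference scale.

    Per-sample ICM scales are ``base_spec.icm_scale * (1 + jitter)`` with
    jitter drawn Uniform(-icm_scale_jitter, +icm_scale_jitter); samples at
    ``outlier_indices`` (0-based) are additionally multiplied by
    ``outlier_scale`` < 1, emulating slides dimmed by repeated exposure
    during scanner-parameter tuning. The FCM scale is held fixed across
    the cohort (the flow cytometer is the unaltered reference).

    Returns the sample list and a cohort-truth table with one row per
    sample: (sample_id, icm_scale, is_outlier).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for idx in outlier_indices:
        if not 0 <= idx < n_samples:
            raise IndexError(f"outlier index {idx} out of range 0..{n_samples - 1}")
    if outlier_indices and not outlier_scale < 1:
        raise ValueError("outlier_scale must be < 1 for low-intensity outliers")

    root = base_spec.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    sample_seeds = [int(s) for s in jitter_rng.integers(0, 2**31 - 1, size=n_samples)]

    samples, rows = [], []
    outliers = set(outlier_indices)
    for i in range(n_samples):
        scale = base_spec.icm_scale
        if icm_scale_jitter > 0:
            scale *= 1.0 + jitter_rng.uniform(-icm_scale_jitter, icm_scale_jitter)
        if i in outliers:
            scale *= outlier_scale
        spec_i = replace(base_spec, icm_scale=scale, seed=sample_seeds[i])
        sid = f"sample_{i + 1:02d}"
        samples.append(generate_event_sample(spec_i, sample_id=sid))
        rows.append(
            {"sample_id": sid, "icm_scale": scale, "is_outlier": i in outliers}
        )
    return samples, pd.DataFrame(rows)
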