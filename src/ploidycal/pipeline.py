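"""End-to-end orchestration: features to populations to peaks to calibration.

Per sample: a per-sample PCA decorrelates (area, DNA content, granularity)
and yields denoised DNA/area coordinates; fuzzy c-means with c = 3
identifies debris/2N/4N on the standardized denoised plane; objects with
uncertain classification are dropped; each population's peak is estimated
both as the modal histogram bin and as a fitted normal mean. The matched
flow-cytometry events go through the same population-gating and peak
stages in one dimension. Cohort-wide, the per-sample 4N/2N peak ratios
are summarized per method variant and the ICM-to-FCM transfer function is
fitted (naive mean scale and pooled regression, before and after
intensity-outlier exclusion).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CohortCalibrator, ratio_stats
from .datatypes import HistogramSpec, PeakPair, SampleSpec
from .decorrelate import PCADenoiser
from .peaks import fit_normal_peak, histogram_peak, peak_ratio
from .populations import FuzzyCMeans, PopulationRatioError, label_populations
from .synthetic import PairedSample, generate_cohort

logger = logging.getLogger(__name__)

MIN_SURVIVING_SAMPLES = 3


@dataclass(frozen=True)
class PipelineSettings:
    """Tunables of the analysis stages (defaults per module contracts)."""

    cmeans_c: int = 3
    cmeans_m: float = 2.0
    cmeans_tol: float = 1e-5
    cmeans_max_iter: int = 300
    membership_threshold: float = 0.6
    bin_count: int = 256
    pca_scaling: str = "none"
    pooling: str = "both_peaks"
    manual_exclusions: tuple[int, ...] = ()
    seed: int = 0


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    sd = sd if sd > 0 else 1.0
    return (x - mu) / sd, mu, sd


def _gate_populations(
    points: np.ndarray,
    dna_original: np.ndarray,
    settings: PipelineSettings,
    seed: int,
) -> pd.DataFrame:
    """Cluster standardized points, label clusters by original-unit DNA."""
    clust = FuzzyCMeans(
        c=settings.cmeans_c,
        m=settings.cmeans_m,
        tol=settings.cmeans_tol,
        max_iter=settings.cmeans_max_iter,
        random_state=seed,
    ).fit(points)
    # each center's DNA coordinate in original units = membership-weighted mean
    um = clust.membership_ ** settings.cmeans_m
    dna_centers = (um * dna_original[:, None]).sum(axis=0) / um.sum(axis=0)
    return label_populations(
        clust, dna_centers, threshold=settings.membership_threshold
    )


def _population_peaks(
    values_by_pop: dict[str, np.ndarray],
    sample_id: str,
    settings: PipelineSettings,
) -> dict:
    spec = HistogramSpec(bin_count=settings.bin_count)
    out = {}
    for pop in ("2N", "4N"):
        vals = values_by_pop[pop]
        out[pop] = {
            "bin_peak": histogram_peak(vals, spec, sample_id, pop),
            "gauss_fit": fit_normal_peak(vals, spec, sample_id, pop),
            "n_members": int(vals.size),
        }
    ratios = {
        method: peak_ratio(out["4N"][method], out["2N"][method])
        for method in ("bin_peak", "gauss_fit")
    }
    return {"peaks": out, "ratios": ratios}


def analyze_icm_sample(
    icm_features: pd.DataFrame,
    sample_id: str,
    settings: PipelineSettings,
    seed: int,
) -> dict:
    """Full ICM stage for one sample: PCA, gating, peak estimation.

    ``icm_features`` needs columns ``dna``, ``area``, ``granularity``.
    Raises :class:`PopulationRatioError` for mis-clustered samples.
    """
    feats = icm_features[["area", "dna", "granularity"]]
    pca = PCADenoiser(scaling=settings.pca_scaling).fit(feats)
    den = pca.correct(feats, dna_feature="dna", area_feature="area")
    dna = den["dna_denoised"].to_numpy()
    area = den["area_denoised"].to_numpy()
    # one shared scale: preserves the plane's aspect ratio (DNA content
    # dominates the metric, as it does in raw IOD-area units) while
    # keeping coordinates O(1) for the convergence tolerance
    scale = dna.std(ddof=0) or 1.0
    pts = np.column_stack([(area - area.mean()) / scale, (dna - dna.mean()) / scale])
    assign = _gate_populations(pts, dna, settings, seed)
    values_by_pop = {
        pop: dna[(assign["population"] == pop).to_numpy()] for pop in ("2N", "4N")
    }
    result = _population_peaks(values_by_pop, sample_id, settings)
    result["assignment"] = assign
    result["pca_loadings"] = pca.loadings_.tolist()
    result["pca_mapping"] = pca.mapping_
    result["n_unassigned"] = int((assign["population"] == "unassigned").sum())
    return result


def analyze_fcm_sample(
    events: np.ndarray,
    sample_id: str,
    settings: PipelineSettings,
    seed: int,
) -> dict:
    """Population gating and peak estimation on 1-D FCM event values."""
    events = np.asarray(events, dtype=float)
    z, *_ = _zscore(events)
    assign = _gate_populations(z[:, None], events, settings, seed)
    values_by_pop = {
        pop: events[(assign["population"] == pop).to_numpy()] for pop in ("2N", "4N")
    }
    result = _population_peaks(values_by_pop, sample_id, settings)
    result["assignment"] = assign
    return result


def _peak_json(entry: dict) -> dict:
    return {
        pop: {
            "bin_peak": entry["peaks"][pop]["bin_peak"].location,
            "gauss_fit": entry["peaks"][pop]["gauss_fit"].location,
            "gauss_sigma": entry["peaks"][pop]["gauss_fit"].sigma,
            "fit_converged": entry["peaks"][pop]["gauss_fit"].converged,
            "n_members": entry["peaks"][pop]["n_members"],
        }
        for pop in ("2N", "4N")
    }


def run_cohort(samples: list[PairedSample], settings: PipelineSettings) -> dict:
    """Analyze a cohort of paired samples and fit the calibration.

    Samples whose population structure cannot be resolved are quarantined
    (logged) and the run continues; the run fails only when fewer than
    three samples survive.
    """
    if len(samples) < MIN_SURVIVING_SAMPLES:
        raise RuntimeError(
            f"cohort too small: need at least {MIN_SURVIVING_SAMPLES} samples, "
            f"got {len(samples)}"
        )
    child_seeds = np.random.SeedSequence(settings.seed).generate_state(
        2 * len(samples)
    ) % (2**31 - 1)

    per_sample: dict[str, dict] = {}
    quarantined: list[str] = []
    for i, sample in enumerate(samples):
        try:
            icm = analyze_icm_sample(
                sample.icm_features, sample.sample_id, settings, int(child_seeds[2 * i])
            )
            fcm = analyze_fcm_sample(
                sample.fcm_events["fsc_area"].to_numpy(),
                sample.sample_id,
                settings,
                int(child_seeds[2 * i + 1]),
            )
        except (PopulationRatioError, ValueError) as exc:
            logger.warning("sample %s quarantined: %s", sample.sample_id, exc)
            quarantined.append(sample.sample_id)
            continue
        per_sample[sample.sample_id] = {"icm": icm, "fcm": fcm}

    if len(per_sample) < MIN_SURVIVING_SAMPLES:
        raise RuntimeError(
            f"only {len(per_sample)} samples survived analysis "
            f"(min {MIN_SURVIVING_SAMPLES}); quarantined: {quarantined}"
        )

    variants = {
        "fcm_hist": [r["fcm"]["ratios"]["bin_peak"] for r in per_sample.values()],
        "icm_hist": [r["icm"]["ratios"]["bin_peak"] for r in per_sample.values()],
        "icm_fit": [r["icm"]["ratios"]["gauss_fit"] for r in per_sample.values()],
    }
    stats = {
        name: dict(zip(("mean", "sd"), ratio_stats(vals)))
        for name, vals in variants.items()
    }

    calibrations = {}
    for method_name, icm_method in (("ICM", "bin_peak"), ("ICM-fit", "gauss_fit")):
        pairs = [
            PeakPair(
                sample_id=sid,
                icm_2N=r["icm"]["peaks"]["2N"][icm_method].location,
                icm_4N=r["icm"]["peaks"]["4N"][icm_method].location,
                fcm_2N=r["fcm"]["peaks"]["2N"]["bin_peak"].location,
                fcm_4N=r["fcm"]["peaks"]["4N"]["bin_peak"].location,
                method=icm_method,
            )
            for sid, r in per_sample.items()
        ]
        cal = CohortCalibrator(
            pooling=settings.pooling, manual_exclusions=settings.manual_exclusions
        ).fit(pairs)
        calibrations[method_name] = cal.report()

    return {
        "n_samples": len(samples),
        "n_analyzed": len(per_sample),
        "quarantined": quarantined,
        "samples": {
            sid: {
                "icm": {
                    "peaks": _peak_json(r["icm"]),
                    "ratios": r["icm"]["ratios"],
                    "n_unassigned": r["icm"]["n_unassigned"],
                },
                "fcm": {"peaks": _peak_json(r["fcm"]), "ratios": r["fcm"]["ratios"]},
            }
            for sid, r in per_sample.items()
        },
        "ratio_stats": stats,
        "calibration": calibrations,
    }


def _settings_from_config(config: dict) -> PipelineSettings:
    cm = config.get("cmeans", {})
    cal = config.get("calibration", {})
    return PipelineSettings(
        cmeans_c=cm.get("c", 3),
        cmeans_m=cm.get("m", 2.0),
        cmeans_tol=cm.get("tol", 1e-5),
        cmeans_max_iter=cm.get("max_iter", 300),
        membership_threshold=cm.get("threshold", 0.6),
        bin_count=config.get("histogram", {}).get("bin_count", 256),
        pca_scaling=config.get("pca", {}).get("scaling", "none"),
        pooling=cal.get("pooling", "both_peaks"),
        manual_exclusions=tuple(cal.get("manual_exclusions", ())),
        seed=config.get("seed", 0),
    )


def simulate_cohort_from_config(config: dict) -> tuple[list[PairedSample], pd.DataFrame]:
    """Build a synthetic cohort from the config's ``synthetic`` block."""
    syn = dict(config.get("synthetic", {}))
    n_samples = syn.pop("n_samples", 17)
    jitter = syn.pop("icm_scale_jitter", 0.0)
    outlier_indices = tuple(syn.pop("outlier_indices", ()))
    outlier_scale = syn.pop("outlier_scale", 0.3)
    spec = SampleSpec(**{**syn, "seed": syn.get("seed", config.get("seed", 0))})
    return generate_cohort(
        n_samples,
        spec,
        icm_scale_jitter=jitter,
        outlier_indices=outlier_indices,
        outlier_scale=outlier_scale,
    )


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a configuration mapping.

    The cohort comes either from the ``synthetic`` block (generated
    in-process) or from per-sample CSV paths under ``samples``
    (``icm_features`` with dna/area/granularity columns, ``fcm_events``
    with an fsc_area column). The returned report is JSON-ready; when
    ``output_dir`` is given, the report and per-sample tables are
    persisted there.
    """
    settings = _settings_from_config(config)
    if "synthetic" in config:
        samples, cohort_truth = simulate_cohort_from_config(config)
    elif "samples" in config:
        from .io import read_events

        samples = []
        for i, entry in enumerate(config["samples"]):
            sid = entry.get("id", f"sample_{i + 1:02d}")
            icm = pd.read_csv(entry["icm_features"])
            fcm = pd.DataFrame(
                {"fsc_area": read_events(entry["fcm_events"], entry.get("channel"))}
            )
            fcm.insert(0, "event_id", np.arange(1, len(fcm) + 1))
            samples.append(PairedSample(sid, None, None, fcm, icm))
        cohort_truth = None
    else:
        raise ValueError("config needs a 'synthetic' or 'samples' section")

    report = run_cohort(samples, settings)
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["manifest"] = {
        "package_version": __version__,
        "seed": settings.seed,
        "config_hash": digest,
    }
    if cohort_truth is not None:
        report["cohort_truth"] = cohort_truth.to_dict(orient="records")

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        logger.info("report written to %s", out / "report.json")
    return report
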