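"""End-to-end orchestration from one declarative configuration.

``run_pipeline`` executes simulate -> preprocess -> connectivity -> compare
-> metrics -> group stats -> classification, writing every stage's artifact
under the output directory plus a run manifest (parameters, seeds, outputs),
and returns the in-memory results. Reruns with the same configuration are
byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import build_feature_matrix, crossvalidated_svm, select_features_by_ttest
from .compare import DEFAULT_COMPARISON_GRID, distance_profile, similarity_map
from .config import GroupEffect, SimulationConfig
from .connectivity import correlation_map, sparsify, total_connectivity_strength
from .exceptions import ConfigurationError, EmptySelectionError, PipelineError
from .graphs import DEFAULT_METRIC_GRID, louvain_partition, metric_profile, nodal_features
from .io import write_cohort_csv, write_map_csv, write_recording_text
from .preprocess import average_by_lobe, bandpass_filter
from .stats import covariate_adjusted_regression, groupwise_metric_comparison, within_group_consistency
from .synthetic import SubjectRecord, cohort_frame, simulate_cohort

logger = logging.getLogger(__name__)


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("neoconn")
    except Exception:
        return "unknown"

FNIRS_BAND = (0.01, 0.1)
FMRI_BAND = (0.01, 0.2)  # upper edge clamped to what TR supports


@dataclass(frozen=True)
class RunConfig:
    """One declarative configuration for the whole analysis."""

    simulation: SimulationConfig = SimulationConfig()
    comparison_grid: Tuple[float, ...] = DEFAULT_COMPARISON_GRID
    metric_grid: Tuple[float, ...] = DEFAULT_METRIC_GRID
    binarized_metrics: bool = True
    feature_sparsity: float = 0.30
    alpha: float = 0.05
    folds: int = 4
    seed: int = 0
    write_recordings: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.folds < 2:
            raise ConfigurationError("need at least 2 CV folds")
        if self.feature_sparsity not in self.metric_grid:
            raise ConfigurationError("feature_sparsity must be a metric-grid point")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig, out_dir) -> Dict[str, object]:
    """Run every stage; write artifacts + manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "neoconn_version": _version(),
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=_json_default)),
        "stages": {},
    }
    results: Dict[str, object] = {}

    def record(stage: str, *paths):
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]
        logger.info("stage %s complete (%d artifacts)", stage, len(paths))

    # 1. simulate -------------------------------------------------------
    try:
        subjects = simulate_cohort(config.simulation)
        cohort = cohort_frame(subjects)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(cohort, cohort_path)
        artifacts = [cohort_path]
        if config.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for s in subjects:
                for rec, tag in ((s.hbo, "hbo"), (s.hbr, "hbr"), (s.bold, "bold")):
                    p = rec_dir / f"{s.subject_id}_{tag}.tsv"
                    write_recording_text(rec, p)
                    artifacts.append(p)
        record("simulate", *artifacts)
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise PipelineError("simulate", str(exc)) from exc
    results["cohort"] = cohort
    results["subjects"] = subjects

    # 2. preprocess -----------------------------------------------------
    try:
        preprocessed = []
        for s in subjects:
            hbo = bandpass_filter(s.hbo, *FNIRS_BAND)
            hbr = bandpass_filter(s.hbr, *FNIRS_BAND)
            bold = bandpass_filter(s.bold, *FMRI_BAND, clamp=True)
            preprocessed.append((s.subject_id, hbo, hbr, bold))
        pre_path = out / "preprocess.json"
        pre_path.write_text(
            json.dumps({"fnirs_band_hz": FNIRS_BAND, "fmri_band_hz": FMRI_BAND,
                        "filter": "butterworth order 4, zero phase"})
        )
        record("preprocess", pre_path)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    # 3. connectivity ---------------------------------------------------
    try:
        maps_lobe: Dict[str, Dict[str, object]] = {"HbO": {}, "Hbr": {}, "BOLD": {}}
        maps_channel: Dict[str, Dict[str, object]] = {"HbO": {}, "Hbr": {}}
        for sid, hbo, hbr, bold in preprocessed:
            maps_channel["HbO"][sid] = correlation_map(hbo)
            maps_channel["Hbr"][sid] = correlation_map(hbr)
            maps_lobe["HbO"][sid] = correlation_map(average_by_lobe(hbo))
            maps_lobe["Hbr"][sid] = correlation_map(average_by_lobe(hbr))
            maps_lobe["BOLD"][sid] = correlation_map(bold)
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        written = []
        for sig, by_subject in maps_lobe.items():
            for sid, cmap in by_subject.items():
                p = map_dir / f"{sid}_{sig.lower()}_lobe.csv"
                write_map_csv(cmap, p)
                written.append(p)
        record("connectivity", *written)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("connectivity", str(exc)) from exc
    results["maps_lobe"] = maps_lobe
    results["maps_channel"] = maps_channel

    # 4. cross-modal comparison ----------------------------------------
    try:
        sids = [s.subject_id for s in subjects]
        profiles = []
        for sig in ("HbO", "Hbr"):
            pairs = [(maps_lobe[sig][sid], maps_lobe["BOLD"][sid]) for sid in sids]
            for metric in ("euclidean", "jaccard"):
                for weighted in (False, True):
                    prof = distance_profile(pairs, config.comparison_grid, metric, weighted)
                    df = prof.to_frame()
                    df.insert(0, "signal_type", sig)
                    profiles.append(df)
        profile_frame = pd.concat(profiles, ignore_index=True)
        prof_path = out / "distance_profiles.csv"
        profile_frame.to_csv(prof_path, index=False)

        mid = config.comparison_grid[len(config.comparison_grid) // 2]
        sim_paths = []
        for sig in ("HbO", "Hbr"):
            ca = [sparsify(maps_lobe[sig][sid], mid, binarized=True) for sid in sids]
            cb = [sparsify(maps_lobe["BOLD"][sid], mid, binarized=True) for sid in sids]
            sim = similarity_map(ca, cb, "binarized_shared_fraction")
            p = out / f"similarity_{sig.lower()}_bold.csv"
            pd.DataFrame(sim.values, index=sim.node_labels, columns=sim.node_labels).to_csv(p)
            sim_paths.append(p)
        record("compare", prof_path, *sim_paths)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc
    results["distance_profiles"] = profile_frame

    # 5. graph metrics --------------------------------------------------
    try:
        sparsified: Dict[str, Dict[str, Dict[float, object]]] = {}
        all_maps = []
        for sig in ("HbO", "Hbr"):
            sparsified[sig] = {}
            for sid, cmap in maps_channel[sig].items():
                sparsified[sig][sid] = {
                    s: sparsify(cmap, s, binarized=config.binarized_metrics)
                    for s in config.metric_grid
                }
                all_maps.extend(sparsified[sig][sid].values())
        metrics = metric_profile(all_maps, seed=config.seed)
        metrics_path = out / "metrics.csv"
        metrics.to_csv(metrics_path, index=False)
        record("metrics", metrics_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("metrics", str(exc)) from exc
    results["metrics"] = metrics

    # 6. group statistics ----------------------------------------------
    try:
        comparison = groupwise_metric_comparison(metrics, cohort, alpha=config.alpha)
        comp_path = out / "group_comparison.csv"
        comparison.to_csv(comp_path, index=False)

        partitions = {
            sid: louvain_partition(sparsified["HbO"][sid][config.feature_sparsity], config.seed)
            for sid in sids
        }
        consistency = within_group_consistency(partitions, cohort)

        strengths = {
            sig: [total_connectivity_strength(maps_lobe[sig][sid]) for sid in sids]
            for sig in ("HbO", "Hbr", "BOLD")
        }
        regressions = [
            covariate_adjusted_regression(cohort, strengths[sig], predictor, outcome=f"{sig} strength")
            for sig in ("HbO", "Hbr", "BOLD")
            for predictor in ("gm_volume", "wm_volume")
        ]
        reg_report = {
            f"{r.outcome}~{r.predictor}": {"slope": r.slope, "p": r.slope_p, "n": r.n}
            for r in regressions
        }
        stats_path = out / "group_stats.json"
        stats_path.write_text(
            json.dumps(
                {
                    "consistency": {
                        "mean_case": consistency.mean_case,
                        "mean_control": consistency.mean_control,
                        "t": consistency.t_statistic,
                        "p": consistency.p_value,
                    },
                    "regressions": reg_report,
                },
                indent=2,
                default=_json_default,
            )
        )
        record("groupstats", comp_path, stats_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("groupstats", str(exc)) from exc
    results["group_comparison"] = comparison
    results["consistency"] = consistency
    results["regressions"] = regressions

    # 7. classification -------------------------------------------------
    try:
        groups = dict(zip(cohort.subject_id, cohort.group))
        features = {
            sid: nodal_features(sparsified["HbO"][sid][config.feature_sparsity])
            for sid in sids
        }
        reports = {}
        for family in (
            "connectivity",
            "degree_centrality",
            "closeness_centrality",
            "clustering_coefficient",
            "nodal_efficiency",
        ):
            fm = build_feature_matrix(features, groups, family, "HbO")
            try:
                selected = select_features_by_ttest(fm, alpha=config.alpha)
            except EmptySelectionError:
                reports[family] = None
                continue
            reports[family] = crossvalidated_svm(
                selected, folds=config.folds, seed=config.seed
            )
        class_path = out / "classification.json"
        class_path.write_text(
            json.dumps(
                {
                    fam: (rep.to_dict() if rep is not None else None)
                    for fam, rep in reports.items()
                },
                indent=2,
                default=_json_default,
            )
        )
        roc_rows = []
        for fam, rep in reports.items():
            if rep is None:
                continue
            for fpr, tpr in rep.roc_points:
                roc_rows.append({"feature_family": fam, "fpr": fpr, "tpr": tpr})
        roc_path = out / "roc_points.csv"
        pd.DataFrame(roc_rows).to_csv(roc_path, index=False)
        record("classify", class_path, roc_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    results["classification"] = reports

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    results["manifest"] = manifest
    return results
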