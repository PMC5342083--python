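"""End-to-end orchestration: weights -> fit -> filter -> cluster -> age-position.

Every stage's output can be materialized to disk so that the re-analyses the
protocol calls for (weighted vs unweighted, age-matched, age-split) are
cheap re-invocations. A run is a pure function of (inputs, config): output
files carry the config hash and seed in a header comment, and reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .clustering import (
    AgePosition,
    TrendCluster,
    clusters_from_labels,
    detect_age_position,
    kmeans_trends,
    label_inclinations,
    merge_redundant_clusters,
    standardize_trajectories,
)
from .datamodel import (
    AnalysisConfig,
    ExpressionDataset,
    write_results_table,
)
from .trendfit import (
    FitResult,
    filter_probes,
    fit_dataset,
    tabulate_directions,
    volcano_table,
)
from .weighting import SampleWeights, sample_weights

logger = logging.getLogger("agecurve")

__all__ = ["PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    config: AnalysisConfig
    weights: Optional[SampleWeights]
    fit: FitResult
    significant: pd.DataFrame
    clusters: List[TrendCluster]
    age_position: Optional[AgePosition]
    summary: Dict
    clustered_probe_ids: Optional[object] = None  # ids matching cluster indices

    def cluster_assignment(self) -> Dict[str, int]:
        """probe_id -> merged cluster id for the clustered probes."""
        if self.clustered_probe_ids is None:
            return {}
        ids = self.clustered_probe_ids
        out: Dict[str, int] = {}
        for cluster in self.clusters:
            for idx in cluster.member_indices:
                out[str(ids[idx])] = cluster.cluster_id
        return out


def run_pipeline(
    dataset: ExpressionDataset,
    config: Optional[AnalysisConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full trend analysis on one cohort.

    Stages, in protocol order: moving-window sample weighting (if enabled),
    per-probe weighted quadratic fits with the age-association test, BH
    adjustment, fold changes from the smoothed trajectories, the joint
    FDR + |FC| filter, standardization of the significant smoothed
    trajectories, Euclidean K-means with redundant-cluster merging and
    singleton exclusion, and absolute-correlation clustering for the
    age-position.
    """
    config = config or AnalysisConfig()
    logger.info(
        "pipeline start: %d probes x %d samples, seed=%d, config=%s",
        dataset.n_probes,
        dataset.n_samples,
        config.random_seed,
        config.config_hash(),
    )

    weights = (
        sample_weights(dataset.ages, config.window_halfwidth)
        if config.weighting_enabled
        else None
    )
    fit = fit_dataset(dataset, weights=weights, config=config)
    significant, filter_summary = filter_probes(
        fit.table, config.fdr_threshold, config.abs_fc_threshold
    )
    directions = tabulate_directions(significant)

    clusters: List[TrendCluster] = []
    age_position: Optional[AgePosition] = None
    sig_mask = fit.table.index.isin(significant.index)
    sig_traj = standardize_trajectories(fit.smoothed[sig_mask])
    nonflat = sig_traj.std(axis=1) > 0
    clustered_ids = fit.table.index.to_numpy()[sig_mask][nonflat]
    if nonflat.sum() >= 2:
        traj = sig_traj[nonflat]
        k = min(config.kmeans_k, traj.shape[0])
        labels, _, _ = kmeans_trends(
            traj,
            k,
            metric="euclidean",
            seed=config.random_seed,
            n_restarts=config.kmeans_restarts,
        )
        raw_clusters = clusters_from_labels(labels, traj, metric="euclidean")
        clusters = label_inclinations(
            merge_redundant_clusters(raw_clusters, traj, config.merge_corr_threshold)
        )
        age_position = detect_age_position(
            traj,
            fit.age_grid,
            k=config.kmeans_k,
            seed=config.random_seed,
            n_restarts=config.kmeans_restarts,
        )

    summary = {
        "n_probes_in": dataset.n_probes,
        "n_samples": dataset.n_samples,
        "age_range": list(dataset.age_range),
        "weighted": fit.weighted,
        "fc_mode": fit.fc_mode,
        **filter_summary,
        "directions": directions,
        "n_clusters": len(clusters),
        "cluster_inclinations": [c.inclination for c in clusters],
        "cluster_sizes": [c.size for c in clusters],
        "age_position": None
        if age_position is None
        else {
            "age": age_position.age,
            "decade": age_position.decade,
            "method": age_position.method,
            "secondary": age_position.secondary,
            "n_positive": age_position.n_positive,
            "n_negative": age_position.n_negative,
        },
        "config_hash": config.config_hash(),
        "random_seed": config.random_seed,
    }

    result = PipelineResult(
        config=config,
        weights=weights,
        fit=fit,
        significant=significant,
        clusters=clusters,
        age_position=age_position,
        summary=summary,
        clustered_probe_ids=clustered_ids,
    )
    if out_dir is not None:
        _write_outputs(result, dataset, Path(out_dir))
    logger.info("pipeline done: %s", json.dumps(filter_summary))
    return result


def _write_outputs(result: PipelineResult, dataset: ExpressionDataset, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config
    stamp = f"config_hash={config.config_hash()} seed={config.random_seed}"

    write_results_table(
        result.fit.table.drop(columns=["perfect_fit"]),
        clusters=result.cluster_assignment(),
        path=out_dir / "results.tsv",
        header_comment=stamp,
    )

    volcano = volcano_table(
        result.fit.table, config.fdr_threshold, config.abs_fc_threshold
    )
    _write_tsv(volcano.reset_index(), out_dir / "volcano.tsv", stamp)

    if result.weights is not None:
        wtab = result.weights.to_frame(dataset.sample_ids, dataset.ages)
        _write_tsv(wtab, out_dir / "weights.tsv", stamp)

    rows = []
    ids = result.clustered_probe_ids
    for cluster in result.clusters:
        for idx in cluster.member_indices:
            rows.append(
                {
                    "probe_id": ids[idx],
                    "cluster_id": cluster.cluster_id,
                    "inclination": cluster.inclination,
                }
            )
    _write_tsv(pd.DataFrame(rows, columns=["probe_id", "cluster_id", "inclination"]),
               out_dir / "clusters.tsv", stamp)

    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )


def _write_tsv(frame: pd.DataFrame, path: Path, stamp: str):
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
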