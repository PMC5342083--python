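"""Cross-dataset and cross-condition comparisons.

Covers the replication machinery around the core fit: overlapping two
cohorts' significant gene sets with direction concordance, comparing
weighted against unweighted runs, trimming two cohorts to their common age
range, splitting a cohort at a cutoff age for subgroup re-analysis, and
exporting ranked gene lists for external enrichment tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, ExpressionDataset, ValidationError
from .trendfit import filter_probes, fit_dataset
from .weighting import sample_weights

__all__ = [
    "OverlapResult",
    "collapse_to_genes",
    "overlap_significant",
    "compare_weighting_modes",
    "match_age_range",
    "split_by_age",
    "export_gene_lists",
]


@dataclass
class OverlapResult:
    """Intersection of two significant gene sets with direction concordance."""

    shared: List[str]
    overlap_count: int
    percentage: Optional[float]  # vs the reference set; None if undefined
    reference: str
    concordant_count: int
    discordant_genes: List[str]
    size_a: int
    size_b: int
    unique_to_a: int = 0
    unique_to_b: int = 0


def collapse_to_genes(
    table: pd.DataFrame, gene_ids: pd.Series
) -> Tuple[Dict[str, int], List[str]]:
    """Collapse significant probes to genes by majority direction.

    Unannotated probes are dropped. A gene whose significant probes tie on
    direction is excluded and reported (internal discordance), never
    silently kept.
    """
    genes = gene_ids.reindex(table.index)
    sub = pd.DataFrame(
        {"gene": genes, "direction": table["direction"]}
    ).dropna(subset=["gene"])
    mapping: Dict[str, int] = {}
    ties: List[str] = []
    for gene, grp in sub.groupby("gene", sort=True):
        pos = int((grp["direction"] > 0).sum())
        neg = int((grp["direction"] < 0).sum())
        if pos > neg:
            mapping[str(gene)] = 1
        elif neg > pos:
            mapping[str(gene)] = -1
        else:
            ties.append(str(gene))
    return mapping, ties


def overlap_significant(
    set_a: Mapping[str, int],
    set_b: Mapping[str, int],
    reference: str = "a",
) -> OverlapResult:
    """Overlap two gene -> direction maps and tabulate concordance."""
    if reference not in ("a", "b"):
        raise ValidationError("reference must be 'a' or 'b'")
    genes_a, genes_b = set(set_a), set(set_b)
    shared = sorted(genes_a & genes_b)
    concordant = [g for g in shared if np.sign(set_a[g]) == np.sign(set_b[g])]
    discordant = [g for g in shared if g not in set(concordant)]
    ref_size = len(genes_a) if reference == "a" else len(genes_b)
    pct = 100.0 * len(shared) / ref_size if ref_size else None
    return OverlapResult(
        shared=shared,
        overlap_count=len(shared),
        percentage=pct,
        reference=reference,
        concordant_count=len(concordant),
        discordant_genes=discordant,
        size_a=len(genes_a),
        size_b=len(genes_b),
        unique_to_a=len(genes_a - genes_b),
        unique_to_b=len(genes_b - genes_a),
    )


def compare_weighting_modes(
    dataset: ExpressionDataset, config: Optional[AnalysisConfig] = None
) -> OverlapResult:
    """Run fit+filter with and without sample weighting and overlap the calls.

    The unweighted significant set is the reference denominator ('b'). Probe
    ids stand in for genes here; annotation-level collapsing is a separate
    concern.
    """
    config = config or AnalysisConfig()
    weights = sample_weights(dataset.ages, config.window_halfwidth)
    fit_w = fit_dataset(dataset, weights=weights, config=config)
    fit_u = fit_dataset(dataset, weights=None, config=config)
    sig_w, _ = filter_probes(fit_w.table, config.fdr_threshold, config.abs_fc_threshold)
    sig_u, _ = filter_probes(fit_u.table, config.fdr_threshold, config.abs_fc_threshold)
    map_w = {str(p): int(d) for p, d in sig_w["direction"].items()}
    map_u = {str(p): int(d) for p, d in sig_u["direction"].items()}
    return overlap_significant(map_w, map_u, reference="b")


def match_age_range(
    dataset_a: ExpressionDataset, dataset_b: ExpressionDataset
) -> Tuple[ExpressionDataset, ExpressionDataset, Tuple[float, float]]:
    """Restrict both cohorts to their common (inclusive) age range."""
    lo = max(dataset_a.ages.min(), dataset_b.ages.min())
    hi = min(dataset_a.ages.max(), dataset_b.ages.max())
    if lo > hi:
        raise ValidationError(
            f"age ranges are disjoint: no common interval (computed [{lo}, {hi}])"
        )
    a = dataset_a.subset_samples((dataset_a.ages >= lo) & (dataset_a.ages <= hi))
    b = dataset_b.subset_samples((dataset_b.ages >= lo) & (dataset_b.ages <= hi))
    return a, b, (float(lo), float(hi))


def split_by_age(
    dataset: ExpressionDataset, cutoff: float
) -> Tuple[ExpressionDataset, ExpressionDataset]:
    """Partition a cohort at a cutoff age: younger (< cutoff), older (>= cutoff).

    Both subsets are meant to re-enter the full pipeline independently
    (weights recomputed within each subset). Subsets below 5 samples are an
    error; below 10 a warning.
    """
    lo, hi = dataset.age_range
    if not (lo < cutoff <= hi):
        raise ValidationError(
            f"cutoff {cutoff} lies outside the observed age range [{lo}, {hi}]"
        )
    younger = dataset.subset_samples(dataset.ages < cutoff)
    older = dataset.subset_samples(dataset.ages >= cutoff)
    for name, sub in (("younger", younger), ("older", older)):
        if sub.n_samples < 5:
            raise ValidationError(
                f"{name} subset has only {sub.n_samples} samples; fit unidentifiable"
            )
        if sub.n_samples < 10:
            warnings.warn(
                f"{name} subset has only {sub.n_samples} samples", stacklevel=2
            )
    return younger, older


def export_gene_lists(
    table: pd.DataFrame, gene_ids: pd.Series, out_dir
) -> Dict[str, Path]:
    """Write ranked gene lists (all / up / down) ordered by q-value.

    Input is a significant (filtered) probe table; probes are collapsed to
    genes keeping each gene's best q-value and majority direction.
    Unannotated probes never appear. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = gene_ids.reindex(table.index)
    sub = pd.DataFrame(
        {
            "gene": genes,
            "qvalue": table["qvalue"],
            "direction": table["direction"],
        }
    ).dropna(subset=["gene"])
    mapping, _ties = collapse_to_genes(table, gene_ids)
    best_q = sub.groupby("gene", sort=False)["qvalue"].min()
    ranked = best_q.loc[best_q.index.isin(mapping)].sort_values(kind="mergesort")
    paths = {}
    lists = {
        "all": list(ranked.index),
        "up": [g for g in ranked.index if mapping[str(g)] > 0],
        "down": [g for g in ranked.index if mapping[str(g)] < 0],
    }
    for name, genes_list in lists.items():
        path = out_dir / f"genes_{name}.txt"
        path.write_text("".join(f"{g}\n" for g in genes_list))
        paths[name] = path
    return paths
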