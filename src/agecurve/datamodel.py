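"""Core data containers and tabular I/O.

The exchange format throughout is plain TSV (UTF-8, header row):

* expression matrix  -- first column ``probe_id``, one column per sample,
  values on a log2 intensity scale after preprocessing;
* sample metadata    -- columns ``sample_id``, ``age`` and optionally ``sex``;
* detection p-values -- same shape/layout as the expression matrix;
* annotation         -- columns ``probe_id``, ``gene_id``.

Samples are keyed by id, never by position: the loader reorders expression
columns to match the metadata row order, and every downstream per-sample
vector (ages, weights) aligns with that order by index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("agecurve")

__all__ = [
    "ValidationError",
    "LoadError",
    "ExpressionDataset",
    "AnalysisConfig",
    "AnnotationJoin",
    "read_expression_matrix",
    "read_annotation",
    "join_annotation",
    "load_config",
    "write_results_table",
    "read_results_table",
]


class ValidationError(ValueError):
    """A container or configuration violates one of its invariants."""


class LoadError(ValueError):
    """An input file could not be reconciled into a valid dataset."""


# Text float format that round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"

RESULT_COLUMNS = [
    "probe_id",
    "alpha",
    "beta",
    "gamma",
    "pvalue",
    "qvalue",
    "fold_change",
    "direction",
    "cluster_id",
]


@dataclass
class ExpressionDataset:
    """A probe x sample log2 intensity matrix with per-sample age metadata.

    Parameters
    ----------
    probe_ids, sample_ids
        Unique text identifiers for rows and columns of ``values``.
    ages
        Age in years per sample; finite and strictly positive.
    values
        ``(n_probes, n_samples)`` array of finite log2 intensities.
    sex
        Optional per-sample categorical labels.
    detection_p
        Optional matrix of detection p-values in [0, 1], same shape
        as ``values``.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    ages: np.ndarray
    values: np.ndarray
    sex: Optional[np.ndarray] = None
    detection_p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=object)
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=float)
        self.validate()

    def validate(self) -> None:
        p, s = self.values.shape if self.values.ndim == 2 else (None, None)
        if p is None:
            raise ValidationError("expression values must be a 2-D matrix")
        if len(self.probe_ids) != p:
            raise ValidationError(
                f"matrix has {p} rows but {len(self.probe_ids)} probe ids"
            )
        if len(self.sample_ids) != s:
            raise ValidationError(
                f"matrix has {s} columns but {len(self.sample_ids)} sample ids"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                dups = uniq[counts > 1]
                raise ValidationError(f"duplicated {name} ids: {list(dups[:5])}")
        if len(self.ages) != s:
            raise ValidationError("ages must have one entry per sample")
        if not np.all(np.isfinite(self.ages)) or not np.all(self.ages > 0):
            raise ValidationError("ages must be finite and positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if self.sex is not None and len(self.sex) != s:
            raise ValidationError("sex must have one entry per sample")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValidationError("detection_p must match the value matrix shape")
            if np.nanmin(self.detection_p) < 0 or np.nanmax(self.detection_p) > 1:
                raise ValidationError("detection p-values must lie in [0, 1]")

    # -- basic descriptors -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.ages.min()), float(self.ages.max())

    def age_grid(self, step: float = 1.0) -> np.ndarray:
        """Grid of ages spanning the observed range (inclusive bounds)."""
        lo, hi = self.age_range
        grid = np.arange(lo, hi + step * 0.5, step, dtype=float)
        if grid[-1] < hi:
            grid = np.append(grid, hi)
        return grid

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return ExpressionDataset(
            probe_ids=self.probe_ids.copy(),
            sample_ids=self.sample_ids[idx],
            ages=self.ages[idx],
            values=self.values[:, idx],
            sex=None if self.sex is None else self.sex[idx],
            detection_p=None if self.detection_p is None else self.detection_p[:, idx],
        )

    def subset_probes(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionDataset(
            probe_ids=self.probe_ids[idx],
            sample_ids=self.sample_ids.copy(),
            ages=self.ages.copy(),
            values=self.values[idx, :],
            sex=None if self.sex is None else self.sex.copy(),
            detection_p=None if self.detection_p is None else self.detection_p[idx, :],
        )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        """Copy of the dataset with the value matrix replaced."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=list(self.sample_ids),
        )

    def write(self, expression_path, metadata_path, detection_path=None) -> None:
        self.to_frame().to_csv(expression_path, sep="\t", float_format=_FLOAT_FMT)
        meta = pd.DataFrame({"sample_id": self.sample_ids, "age": self.ages})
        if self.sex is not None:
            meta["sex"] = self.sex
        meta.to_csv(metadata_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        if detection_path is not None and self.detection_p is not None:
            pd.DataFrame(
                self.detection_p,
                index=pd.Index(self.probe_ids, name="probe_id"),
                columns=list(self.sample_ids),
            ).to_csv(detection_path, sep="\t", float_format=_FLOAT_FMT)


def read_expression_matrix(
    path, metadata_path, detection_path=None
) -> ExpressionDataset:
    """Load an expression TSV plus its sample metadata into a dataset.

    Samples end up ordered as in the metadata file regardless of the
    column order of the expression matrix.

    Raises
    ------
    LoadError
        If the sample ids in the two files do not match one-to-one.
    ValidationError
        If ages are non-numeric/non-positive or probe ids are duplicated.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "age"):
        if col not in meta.columns:
            raise LoadError(f"metadata file lacks required column {col!r}")
    ages = pd.to_numeric(meta["age"], errors="coerce")
    if ages.isna().any():
        bad = meta.loc[ages.isna(), "sample_id"].tolist()
        raise ValidationError(f"non-numeric age for samples: {bad[:5]}")

    matrix_ids = [str(c) for c in expr.columns]
    meta_ids = [str(s) for s in meta["sample_id"]]
    missing_in_meta = sorted(set(matrix_ids) - set(meta_ids))
    missing_in_matrix = sorted(set(meta_ids) - set(matrix_ids))
    if missing_in_meta or missing_in_matrix:
        raise LoadError(
            "sample ids do not match between expression matrix and metadata; "
            f"absent from metadata: {missing_in_meta[:5]}; "
            f"absent from matrix: {missing_in_matrix[:5]}"
        )
    expr = expr[meta_ids]

    detection = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
        det = det[meta_ids]
        if not det.index.astype(str).equals(expr.index.astype(str)):
            raise LoadError("detection matrix probe ids differ from expression matrix")
        detection = det.to_numpy(dtype=float)

    sex = meta["sex"].to_numpy(dtype=object) if "sex" in meta.columns else None
    return ExpressionDataset(
        probe_ids=expr.index.to_numpy(dtype=object),
        sample_ids=np.asarray(meta_ids, dtype=object),
        ages=ages.to_numpy(dtype=float),
        values=expr.to_numpy(dtype=float),
        sex=sex,
        detection_p=detection,
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.Series:
    """Read a probe -> gene annotation TSV into a Series indexed by probe_id.

    Probes may be unannotated (empty gene_id); a probe may appear once only.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in tab.columns:
            raise LoadError(f"annotation file lacks required column {col!r}")
    if tab["probe_id"].duplicated().any():
        dups = tab.loc[tab["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"annotation lists probes more than once: {dups[:5]}")
    return tab.set_index("probe_id")["gene_id"]


@dataclass
class AnnotationJoin:
    """Per-probe gene ids aligned with a dataset's probe order."""

    gene_ids: pd.Series  # indexed by probe_id; NaN/None where unannotated
    n_unannotated: int
    unannotated_fraction: float

    def annotated_mask(self) -> np.ndarray:
        return self.gene_ids.notna().to_numpy()


def join_annotation(dataset: ExpressionDataset, annotation: pd.Series) -> AnnotationJoin:
    """Attach gene ids to a dataset's probes; missing probes stay unannotated."""
    idx = pd.Index(dataset.probe_ids.astype(str), name="probe_id")
    genes = annotation.reindex(idx)
    genes = genes.where(genes.notna() & (genes.astype(str).str.len() > 0))
    n_un = int(genes.isna().sum())
    frac = n_un / len(idx) if len(idx) else 0.0
    logger.info("annotation join: %d/%d probes unannotated (%.3f)", n_un, len(idx), frac)
    return AnnotationJoin(gene_ids=genes, n_unannotated=n_un, unannotated_fraction=frac)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the trend analysis.

    Defaults follow the source protocol: BH FDR threshold 0.05, absolute
    fold-change threshold 1.2, a +/-5-year moving age window for sample
    weighting, k=10 clusters before merging, centroid-correlation merge
    threshold 0.9 and a 1-year age grid.
    """

    fdr_threshold: float = 0.05
    abs_fc_threshold: float = 1.2
    window_halfwidth: float = 5.0
    kmeans_k: int = 10
    merge_corr_threshold: float = 0.9
    age_grid_step: float = 1.0
    random_seed: int = 0
    weighting_enabled: bool = True
    fc_mode: str = "endpoints"  # or "amplitude"
    kmeans_restarts: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must lie strictly between 0 and 1")
        if self.abs_fc_threshold < 1.0:
            raise ValidationError("abs_fc_threshold must be >= 1")
        if self.window_halfwidth <= 0:
            raise ValidationError("window_halfwidth must be > 0")
        if self.kmeans_k < 2:
            raise ValidationError("kmeans_k must be >= 2")
        if not (0.0 < self.merge_corr_threshold <= 1.0):
            raise ValidationError("merge_corr_threshold must lie in (0, 1]")
        if self.age_grid_step <= 0:
            raise ValidationError("age_grid_step must be > 0")
        if self.fc_mode not in ("endpoints", "amplitude"):
            raise ValidationError("fc_mode must be 'endpoints' or 'amplitude'")
        if self.kmeans_restarts < 1:
            raise ValidationError("kmeans_restarts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path=None, overrides: Optional[Mapping] = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML key-value file.

    Missing keys take their defaults; an empty (or absent) file yields the
    default configuration. Unknown keys raise, as do out-of-range values.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a key-value mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

def write_results_table(fits, clusters=None, path=None, header_comment: str = ""):
    """Write per-probe fit results (and optional cluster labels) to TSV.

    ``fits`` is a DataFrame carrying at least the columns
    alpha/beta/gamma/pvalue/qvalue/fold_change/direction, indexed or keyed by
    probe_id. ``clusters`` maps probe_id -> cluster_id; probes without a
    cluster get an empty field. Round-trips losslessly through
    :func:`read_results_table`.
    """
    frame = fits.copy()
    if frame.index.name == "probe_id":
        frame = frame.reset_index()
    if "probe_id" not in frame.columns:
        raise ValidationError("results table needs a probe_id column or index")
    cluster_map = dict(clusters) if clusters else {}
    frame["cluster_id"] = [
        cluster_map.get(p, "") for p in frame["probe_id"].astype(str)
    ]
    frame = frame[RESULT_COLUMNS]
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    frame.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue())
    return path


def read_results_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str}, float_precision="round_trip")
    return tab.set_index("probe_id")
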