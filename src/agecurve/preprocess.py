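"""Preprocessing: quantile normalization, log2 transform, double centering,
detection-based probe prefiltering and a PCA outlier screen.

All operations are pure; dataset-level helpers return filtered/transformed
copies and never mutate their input. The detection prefilter mirrors the
array-study convention of keeping probes whose detection p-value beats the
background threshold in strictly more than a given fraction of samples; the
PCA screen is advisory only and removes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, ValidationError

__all__ = [
    "quantile_normalize",
    "log2_transform",
    "double_center",
    "detection_filter",
    "pca_outlier_screen",
    "DetectionFilterReport",
    "PcaScreenResult",
]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the common (row-mean-of-sorted) distribution.

    Ties within a column receive the mean of the reference values at the
    tied ranks, so tied entries stay tied.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    if not np.all(np.isfinite(values)):
        raise ValidationError("quantile normalization requires finite values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values across tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return out


def log2_transform(values: np.ndarray, probe_ids=None, sample_ids=None) -> np.ndarray:
    """Elementwise base-2 logarithm of positive intensities."""
    values = np.asarray(values, dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        probe = probe_ids[i] if probe_ids is not None else f"row {i}"
        sample = sample_ids[j] if sample_ids is not None else f"column {j}"
        raise ValidationError(
            f"non-positive intensity at probe {probe}, sample {sample}"
        )
    return np.log2(values)


def double_center(values: np.ndarray) -> np.ndarray:
    """Center probe (row) means, then sample (column) means, to zero.

    Idempotent and linear; after the operation every row and column mean is
    zero to numerical precision.
    """
    values = np.asarray(values, dtype=float)
    out = values - values.mean(axis=1, keepdims=True)
    out -= out.mean(axis=0, keepdims=True)
    return out


@dataclass
class DetectionFilterReport:
    n_in: int
    n_kept: int
    removed_probe_ids: np.ndarray


def detection_filter(
    dataset: ExpressionDataset,
    p_cut: float = 0.05,
    sample_frac: float = 0.10,
) -> tuple[ExpressionDataset, DetectionFilterReport]:
    """Keep probes detected (p < ``p_cut``) in strictly more than
    ``sample_frac`` of samples.

    The boundary is strict: a probe detected in exactly 10% of samples is
    removed under the defaults. Surviving values are untouched.
    """
    if dataset.detection_p is None:
        raise ValidationError(
            "dataset has no detection p-values; skip the detection filter stage"
        )
    detected = (dataset.detection_p < p_cut).mean(axis=1)
    keep = detected > sample_frac
    report = DetectionFilterReport(
        n_in=dataset.n_probes,
        n_kept=int(keep.sum()),
        removed_probe_ids=dataset.probe_ids[~keep],
    )
    return dataset.subset_probes(keep), report


@dataclass
class PcaScreenResult:
    flags: np.ndarray        # per-sample advisory outlier flags
    scores: np.ndarray       # (n_samples, n_components) PC scores
    sd_limit: float


def pca_outlier_screen(
    values: np.ndarray, n_components: int = 2, sd_limit: float = 4.0
) -> PcaScreenResult:
    """Flag samples scoring beyond ``sd_limit`` SDs on any leading PC.

    Components come from an SVD of the sample-by-probe matrix centered over
    samples. Flags are advisory; nothing is removed.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise ValidationError("PCA screen needs at least 3 samples")
    X = values.T - values.T.mean(axis=0, keepdims=True)  # samples x probes
    n_components = min(n_components, min(X.shape))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    sd = scores.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    dev = np.abs(scores - scores.mean(axis=0)) / sd
    flags = (dev > sd_limit).any(axis=1)
    return PcaScreenResult(flags=flags, scores=scores, sd_limit=sd_limit)
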