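"""Moving-window sample weighting for skewed age distributions.

Cross-sectional cohorts rarely sample age evenly; a cohort skewed toward
younger subjects lets the dense ages dominate any per-probe regression. To
compensate, every sample is weighted inversely to the number of samples
falling within a closed +/- ``halfwidth``-year window around its own age
(the sample itself included), so over-represented ages are downsized and
sparse ages are emphasized. The raw ``1/N_i`` weights are deliberately not
renormalized: every downstream use is invariant to a global weight scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

__all__ = ["SampleWeights", "neighborhood_counts", "compute_weights", "sample_weights"]


@dataclass
class SampleWeights:
    """Per-sample window counts ``N_i`` and weights ``w_i = 1/N_i``."""

    counts: np.ndarray
    weights: np.ndarray
    halfwidth: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.counts < 1).any():
            raise ValidationError("every neighborhood count must be >= 1")
        if not np.allclose(self.weights, 1.0 / self.counts, rtol=0, atol=0):
            raise ValidationError("weights must equal 1/count exactly")

    def to_frame(self, sample_ids=None, ages=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"neighborhood_count": self.counts, "weight": self.weights}
        )
        if ages is not None:
            frame.insert(0, "age", np.asarray(ages, dtype=float))
        if sample_ids is not None:
            frame.insert(0, "sample_id", np.asarray(sample_ids, dtype=object))
        return frame


def neighborhood_counts(ages, halfwidth: float = 5.0) -> np.ndarray:
    """Count, for each sample, the samples within ``|age_j - age_i| <= halfwidth``.

    The window is closed on both sides and always contains the sample itself,
    so every count is at least 1. Ages are used as given (real-valued ages
    are not rounded).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValidationError("cannot compute neighborhood counts of an empty cohort")
    if not np.all(np.isfinite(ages)):
        raise ValidationError("ages must be finite")
    if halfwidth <= 0:
        raise ValidationError("halfwidth must be > 0")
    srt = np.sort(ages)
    hi = np.searchsorted(srt, ages + halfwidth, side="right")
    lo = np.searchsorted(srt, ages - halfwidth, side="left")
    return (hi - lo).astype(int)


def compute_weights(counts) -> SampleWeights:
    """Turn window counts into weights ``w_i = 1/N_i``."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("empty count vector")
    if (counts < 1).any() or not np.all(np.isfinite(counts)):
        raise ValidationError("counts must be integers >= 1")
    return SampleWeights(
        counts=counts.astype(int), weights=1.0 / counts, halfwidth=float("nan")
    )


def sample_weights(ages, halfwidth: float = 5.0) -> SampleWeights:
    """Convenience: counts plus weights in one call."""
    counts = neighborhood_counts(ages, halfwidth)
    sw = compute_weights(counts)
    sw.halfwidth = float(halfwidth)
    return sw
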