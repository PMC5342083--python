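"""Synthetic cross-sectional cohort generator with known ground truth.

Emulates the statistical structure the trend analysis assumes: a cohort of
blood expression profiles over a broad adult age range, most probes flat
(null), a minority carrying monotone or hinge-shaped log2 trajectories whose
change concentrates at a planted change-point age, plus homoscedastic
Gaussian noise. Two presets mirror the demographics of the studies the
method was built for: an RS-like cohort (n=762, ages 46-89, right-skewed
toward younger ages) and a SHIP-like cohort (n=991, ages 21-81, even).

Archetypes (trajectory means over age x in [lo, hi], baseline b, effect
size Delta in log2 units, change point c):

* ``null``        : b
* ``linear-up``   : b + Delta (x - lo)/(hi - lo)       (``-down`` mirrored)
* ``hinge-up``    : b for x <= c, then rising linearly to b + Delta at hi
* ``quadratic``   : vertex at c, total excursion Delta over the range

The generator is a stated world, not a tuning dial: defaults encode the
cohort demographics above, Delta = log2(1.5), noise SD 0.5 and a
change point of 65 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, ValidationError

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "ARCHETYPES",
    "sample_ages",
    "simulate_dataset",
    "simulate_platform_pair",
]

ARCHETYPES = ("null", "linear-up", "linear-down", "hinge-up", "hinge-down", "quadratic")

DEFAULT_MIX: Dict[str, float] = {
    "hinge-up": 0.3,
    "hinge-down": 0.3,
    "linear-up": 0.15,
    "linear-down": 0.15,
    "quadratic": 0.1,
}


@dataclass
class CohortSpec:
    """What cohort to simulate: demographics, probe count and signal mix."""

    n_samples: int = 500
    age_range: Tuple[float, float] = (46.0, 89.0)
    age_distribution: str = "uniform"  # or "skewed"
    skew: float = 1.0
    n_probes: int = 1000
    frac_signal: float = 0.2
    archetype_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if self.n_samples < 10:
            raise ValidationError("n_samples must be >= 10")
        if hi <= lo or lo <= 0:
            raise ValidationError("age_range must satisfy 0 < lo < hi")
        if not (0.0 <= self.frac_signal <= 1.0):
            raise ValidationError("frac_signal must lie in [0, 1]")
        if self.age_distribution not in ("uniform", "skewed"):
            raise ValidationError("age_distribution must be 'uniform' or 'skewed'")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes in mix: {sorted(unknown)}")
        total = sum(self.archetype_mix.values())
        if self.archetype_mix and abs(total - 1.0) > 1e-9:
            raise ValidationError("archetype mix fractions must sum to 1")

    @classmethod
    def rs_like(cls, **overrides) -> "CohortSpec":
        """Rotterdam-Study-like cohort: n=762, ages 46-89, right-skewed."""
        base = dict(
            n_samples=762,
            age_range=(46.0, 89.0),
            age_distribution="skewed",
            skew=1.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def ship_like(cls, **overrides) -> "CohortSpec":
        """SHIP-TREND-like cohort: n=991, ages 21-81, even age coverage."""
        base = dict(
            n_samples=991,
            age_range=(21.0, 81.0),
            age_distribution="uniform",
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Planted per-probe ground truth for parameter-recovery tests."""

    table: pd.DataFrame  # probe_id, archetype, change_point, delta, noise_sd, baseline
    seed: int

    def nonnull_probes(self) -> pd.Index:
        return self.table.index[self.table["archetype"] != "null"]


def sample_ages(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw the cohort's ages.

    ``uniform`` draws uniformly over the range. ``skewed`` draws from a
    Beta(1, 1 + skew) rescaled to the range: right-skewed (elderly
    under-represented) for skew > 0 and exactly uniform at skew = 0.
    """
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    if spec.age_distribution == "uniform" or spec.skew == 0:
        u = rng.uniform(0.0, 1.0, spec.n_samples)
    else:
        u = rng.beta(1.0, 1.0 + spec.skew, spec.n_samples)
    return lo + (hi - lo) * u


def _archetype_counts(spec: CohortSpec) -> Dict[str, int]:
    """Integer probe counts per archetype by largest-remainder rounding."""
    n_signal = int(round(spec.frac_signal * spec.n_probes))
    mix = spec.archetype_mix or DEFAULT_MIX
    raw = {a: f * n_signal for a, f in mix.items()}
    counts = {a: int(np.floor(v)) for a, v in raw.items()}
    short = n_signal - sum(counts.values())
    # distribute the remainder by descending fractional part, mix order breaking ties
    order = sorted(raw, key=lambda a: (-(raw[a] - np.floor(raw[a])), list(mix).index(a)))
    for a in order[:short]:
        counts[a] += 1
    counts["null"] = spec.n_probes - n_signal
    return counts


def _archetype_layout(spec: CohortSpec) -> np.ndarray:
    """Deterministic per-probe archetype assignment (signal first, then null)."""
    counts = _archetype_counts(spec)
    archetypes = []
    for a in list(spec.archetype_mix or DEFAULT_MIX) + ["null"]:
        archetypes.extend([a] * counts.get(a, 0))
    return np.asarray(archetypes[: spec.n_probes], dtype=object)


def _trajectory(archetype, ages, lo, hi, c, delta, baseline):
    x = np.asarray(ages, dtype=float)
    if archetype == "null":
        return np.full_like(x, baseline)
    if archetype == "linear-up":
        return baseline + delta * (x - lo) / (hi - lo)
    if archetype == "linear-down":
        return baseline - delta * (x - lo) / (hi - lo)
    if archetype == "hinge-up":
        return baseline + np.where(x <= c, 0.0, delta * (x - c) / (hi - c))
    if archetype == "hinge-down":
        return baseline - np.where(x <= c, 0.0, delta * (x - c) / (hi - c))
    if archetype == "quadratic":
        half = max(hi - c, c - lo)
        return baseline + delta * ((x - c) / half) ** 2
    raise ValidationError(f"unknown archetype {archetype!r}")


def simulate_dataset(
    spec: CohortSpec,
    change_point: float = 65.0,
    delta: float = float(np.log2(1.5)),
    noise_sd: float = 0.5,
    baseline_mean: float = 7.5,
    baseline_sd: float = 0.5,
    with_detection_p: bool = False,
    gene_ids=None,
    probe_prefix: str = "P",
    archetypes=None,
) -> Tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate one cohort and return it with its planted ground truth.

    Fully reproducible from ``spec.seed``. ``gene_ids`` (optional) assigns
    probes to an external gene namespace and fixes the archetype order so
    two platforms can share truth (see :func:`simulate_platform_pair`).
    """
    lo, hi = spec.age_range
    if not (lo <= change_point <= hi):
        raise ValidationError("change_point must lie inside the age range")
    rng = np.random.default_rng(spec.seed)
    ages = sample_ages(spec, rng)

    if archetypes is None:
        archetypes = _archetype_layout(spec)
    else:
        archetypes = np.asarray(archetypes, dtype=object)
        if archetypes.shape != (spec.n_probes,):
            raise ValidationError("archetypes must list one archetype per probe")

    probe_ids = np.array(
        [f"{probe_prefix}{i:06d}" for i in range(spec.n_probes)], dtype=object
    )
    baselines = rng.normal(baseline_mean, baseline_sd, spec.n_probes)
    values = np.empty((spec.n_probes, spec.n_samples))
    for i, (arch, b) in enumerate(zip(archetypes, baselines)):
        mean = _trajectory(arch, ages, lo, hi, change_point, delta, b)
        values[i] = mean + rng.normal(0.0, noise_sd, spec.n_samples)

    detection = None
    if with_detection_p:
        detection = rng.uniform(0.0, 0.04, size=values.shape)

    sample_ids = np.array([f"S{j:05d}" for j in range(spec.n_samples)], dtype=object)
    dataset = ExpressionDataset(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        ages=ages,
        values=values,
        detection_p=detection,
    )
    is_hinge_or_quad = np.isin(archetypes, ["hinge-up", "hinge-down", "quadratic"])
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "change_point": np.where(is_hinge_or_quad, change_point, np.nan),
            "delta": np.where(archetypes == "null", 0.0, delta)
            * np.where(np.isin(archetypes, ["linear-down", "hinge-down"]), -1.0, 1.0),
            "noise_sd": noise_sd,
            "baseline": baselines,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    if gene_ids is not None:
        truth["gene_id"] = np.asarray(gene_ids, dtype=object)
    return dataset, SyntheticTruth(table=truth, seed=spec.seed)


def simulate_platform_pair(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    shared_gene_fraction: float = 0.9,
    **sim_kwargs,
):
    """Simulate two cohorts measuring overlapping genes on distinct probes.

    A common gene namespace is laid over both platforms: the first
    ``shared_gene_fraction`` of each platform's probes (after rounding)
    measure the same genes in the same archetype order, so shared non-null
    genes carry identical planted trends in both cohorts. Returns
    ``(dataset_a, truth_a, annotation_a, dataset_b, truth_b, annotation_b)``
    where each annotation is a probe_id -> gene_id Series.
    """
    if not (0.0 <= shared_gene_fraction <= 1.0):
        raise ValidationError("shared_gene_fraction must lie in [0, 1]")
    n_shared = int(round(shared_gene_fraction * min(spec_a.n_probes, spec_b.n_probes)))

    def gene_namespace(n_probes, tag):
        genes = [f"G{i:06d}" for i in range(n_shared)]
        genes += [f"G_{tag}_{i:06d}" for i in range(n_probes - n_shared)]
        return np.asarray(genes, dtype=object)

    genes_a = gene_namespace(spec_a.n_probes, "A")
    genes_b = gene_namespace(spec_b.n_probes, "B")
    # shared genes must carry identical planted trends in both platforms:
    # copy A's archetype layout onto B's shared prefix
    arch_a = _archetype_layout(spec_a)
    arch_b = _archetype_layout(spec_b)
    arch_b[:n_shared] = arch_a[:n_shared]
    ds_a, truth_a = simulate_dataset(
        spec_a, gene_ids=genes_a, probe_prefix="A", archetypes=arch_a, **sim_kwargs
    )
    ds_b, truth_b = simulate_dataset(
        spec_b, gene_ids=genes_b, probe_prefix="B", archetypes=arch_b, **sim_kwargs
    )
    annot_a = pd.Series(genes_a, index=pd.Index(ds_a.probe_ids, name="probe_id"), name="gene_id")
    annot_b = pd.Series(genes_b, index=pd.Index(ds_b.probe_ids, name="probe_id"), name="gene_id")
    return ds_a, truth_a, annot_a, ds_b, truth_b, annot_b
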