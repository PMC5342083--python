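"""Per-probe weighted quadratic age-trend fitting, testing and filtering.

Model
-----
For probe *i* with log2 intensity ``y_ij`` of sample *j* at age ``x_j``,

    y_ij = alpha_i + beta_i x_j + gamma_i x_j^2 + eps_ij,

fitted by (weighted) least squares, with per-sample weights entering the
loss. The age-association test compares this quadratic model against the
intercept-only null through the F ratio

    F = ((RSS0 - RSS1) / 2) / (RSS1 / (n - 3)),

using weighted residual sums of squares when weights are supplied.

P-value calibration under weighting
-----------------------------------
When weights are 1/N_i window counts (not inverse error variances) and the
noise is homoscedastic, the weighted F ratio is *not* F(2, n-3) distributed:
the weighted projections concentrate on sparsely sampled ages whose
(unweighted) errors are not shrunk accordingly, which inflates the numerator
and makes the naive reference badly anti-conservative. The statistic is kept
exactly as above, but its p-value is taken from the statistic's exact
finite-sample null law under i.i.d. Gaussian errors, which depends only on
the fixed design/weight geometry and is shared by all probes; it is
evaluated once per design by seeded Monte Carlo (a Satterthwaite
moment-matched F covers the extreme tail beyond the Monte Carlo range).
Unweighted or constant-weight fits use the classical exact F(2, n-3)
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnalysisConfig, ExpressionDataset, ValidationError
from .weighting import SampleWeights

__all__ = [
    "fit_quadratic",
    "smooth_trajectory",
    "age_association_test",
    "FTestCalibration",
    "bh_adjust",
    "fold_change",
    "fit_dataset",
    "FitResult",
    "filter_probes",
    "tabulate_directions",
    "volcano_table",
]

_TINY_P = float(np.nextafter(0, 1))


def _as_weight_vector(weights, n: int) -> Optional[np.ndarray]:
    """Normalize the accepted weight spellings; constant weights -> None."""
    if weights is None:
        return None
    if isinstance(weights, SampleWeights):
        w = np.asarray(weights.weights, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValidationError(f"expected {n} weights, got shape {w.shape}")
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValidationError("weights must be finite and strictly positive")
    if np.all(w == w[0]):
        # A flat weight vector is the unweighted problem; routing it through
        # the unweighted path makes the equivalence bit-exact.
        return None
    return w / w.mean()  # global scale is irrelevant; normalize for hygiene


def _design(ages: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(ages), ages, ages**2])


def fit_quadratic(y, ages, weights=None):
    """Weighted least-squares fit of a quadratic age trend to one probe.

    Returns ``(alpha, beta, gamma, residuals)`` minimizing
    ``sum_j w_j (y_j - alpha - beta x_j - gamma x_j^2)^2`` (ordinary least
    squares when ``weights`` is None or constant).
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if y.shape != ages.shape:
        raise ValidationError("y and ages must have the same length")
    if y.size < 4:
        raise ValidationError("quadratic fit needs at least 4 samples")
    if np.unique(ages).size < 3:
        raise ValidationError("quadratic fit needs at least 3 distinct ages")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    w = _as_weight_vector(weights, y.size)
    X = _design(ages)
    if w is None:
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    else:
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise ValidationError("design is rank-deficient (need 3 distinct ages)")
    residuals = y - X @ coef
    return float(coef[0]), float(coef[1]), float(coef[2]), residuals


def smooth_trajectory(alpha: float, beta: float, gamma: float, age_grid) -> np.ndarray:
    """Evaluate the fitted quadratic ``alpha + beta x + gamma x^2`` on a grid."""
    g = np.asarray(age_grid, dtype=float)
    return alpha + beta * g + gamma * g**2


# ---------------------------------------------------------------------------
# Null calibration of the weighted F ratio
# ---------------------------------------------------------------------------

class FTestCalibration:
    """Exact null law of the weighted quadratic-vs-intercept F ratio.

    For a fixed design (ages) and weight vector, the null distribution of
    the weighted F under i.i.d. N(0, sigma^2) errors is the same for every
    probe. It is estimated once by Monte Carlo (``n_mc`` draws, seeded) and
    queried per probe; statistics beyond the simulated range fall back to a
    Satterthwaite moment-matched F tail.
    """

    def __init__(self, ages, weights, n_mc: int = 100_000, seed: int = 0):
        ages = np.asarray(ages, dtype=float)
        w = np.asarray(weights, dtype=float)
        w = w / w.mean()
        n = ages.size
        self.n = n
        sw = np.sqrt(w)
        SX = _design(ages) * sw[:, None]
        U, _ = np.linalg.qr(SX)  # z-space basis of the quadratic model
        u0 = sw / np.linalg.norm(sw)  # intercept-only direction (in span(U))
        self._U, self._u0, self._sw = U, u0, sw

        # Moment quantities for the Satterthwaite tail.
        D = w
        B = U - np.outer(u0, u0 @ U)
        Ub, sv, _ = np.linalg.svd(B, full_matrices=False)
        U2 = Ub[:, :2]  # numerator (age-contrast) subspace
        C2 = U2.T @ (U2 * D[:, None])
        a = np.linalg.eigvalsh(C2)
        M1 = U.T @ (U * D[:, None])
        trP1D = float(np.trace(M1))
        trP1DP1D = float(np.sum(M1 * M1.T))
        M2 = U.T @ (U * (D**2)[:, None])
        trRD = float(D.sum() - trP1D)
        trRD2 = float(np.sum(D**2) - 2 * np.trace(M2) + trP1DP1D)
        self._trAD = float(a.sum())
        self._d1 = float(a.sum() ** 2 / np.sum(a**2))
        self._trRD = trRD
        self._d2 = trRD**2 / trRD2

        rng = np.random.default_rng(seed)
        null = np.empty(n_mc)
        chunk = max(1, int(2e7) // n)
        for lo in range(0, n_mc, chunk):
            m = min(chunk, n_mc - lo)
            Zw = rng.standard_normal((m, n)) * sw
            P = Zw @ U
            zz = np.einsum("ij,ij->i", Zw, Zw)
            q1 = np.einsum("ij,ij->i", P, P)
            q0 = (Zw @ u0) ** 2
            null[lo : lo + m] = ((q1 - q0) / 2) / ((zz - q1) / (n - 3))
        null.sort()
        self._null = null
        self.n_mc = n_mc

    def _tail_sf(self, f):
        """Satterthwaite moment-matched F survival beyond the MC range."""
        fs = np.asarray(f, dtype=float) * (2.0 / self._trAD) * (
            self._trRD / (self.n - 3)
        )
        return stats.f.sf(fs, self._d1, self._d2)

    def pvalue(self, f):
        """Null p-value(s) of observed F statistic(s)."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        idx = np.searchsorted(self._null, f, side="left")
        p = (self.n_mc - idx + 1.0) / (self.n_mc + 1.0)
        beyond = f > self._null[-1]
        if beyond.any():
            floor = 1.0 / (self.n_mc + 1.0)
            p[beyond] = np.minimum(floor, self._tail_sf(f[beyond]))
        return p if p.size > 1 else float(p[0])


def _f_statistic(Y, ages, w):
    """Vectorized weighted F ratio for a (n_probes, n_samples) matrix."""
    n = ages.size
    X = _design(ages)
    if w is None:
        coef, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y - (X @ coef).T
        rss1 = np.einsum("ij,ij->i", resid, resid)
        mu = Y.mean(axis=1)
        dev = Y - mu[:, None]
        rss0 = np.einsum("ij,ij->i", dev, dev)
    else:
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], (Y * sw).T, rcond=None)
        resid = Y - (X @ coef).T
        rss1 = (w * resid**2).sum(axis=1)
        mu = (w * Y).sum(axis=1) / w.sum()
        dev = Y - mu[:, None]
        rss0 = (w * dev**2).sum(axis=1)
    if rank < 3:
        raise ValidationError("design is rank-deficient (need 3 distinct ages)")
    # Distinguish a perfect quadratic fit (rss1 ~ 0 with real signal, F -> inf)
    # from a constant probe (rss0 ~ rss1 ~ 0, no association at all, F = 0).
    ss = np.einsum("ij,ij->i", Y, Y) + np.finfo(float).tiny
    rss1_tiny = rss1 <= 1e-20 * ss
    constant = rss1_tiny & (rss0 <= 1e-12 * ss)
    perfect = rss1_tiny & ~constant
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (np.maximum(rss0 - rss1, 0.0) / 2.0) / (rss1 / (n - 3))
    F = np.where(constant, 0.0, np.where(perfect, np.inf, np.nan_to_num(F, nan=0.0)))
    return coef, resid, F, rss1


def age_association_test(y, ages, weights=None, calibration=None):
    """P-value for age association of one probe (quadratic vs intercept).

    A perfect fit (zero residual sum of squares) is reported as the smallest
    representable positive p-value.
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if y.size < 5:
        raise ValidationError("age-association test needs at least 5 samples")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    w = _as_weight_vector(weights, y.size)
    _, _, F, rss1 = _f_statistic(y[None, :], ages, w)
    if not np.isfinite(F[0]):
        return _TINY_P
    if w is None:
        return float(stats.f.sf(F[0], 2, y.size - 3))
    if calibration is None:
        calibration = FTestCalibration(ages, w)
    return float(calibration.pvalue(F[0]))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(smoothed, mode: str = "endpoints"):
    """Signed fold change of a smoothed log2 trajectory.

    ``endpoints`` takes the net change Delta between the oldest and youngest
    grid age; ``amplitude`` uses the max-min excursion instead (direction
    still from the endpoint difference). Returns ``(signed_fc, direction)``
    with ``|FC| = 2**|Delta| >= 1`` and ``direction in {-1, 0, +1}``.
    """
    traj = np.asarray(smoothed, dtype=float)
    d_end = traj[-1] - traj[0]
    direction = int(np.sign(d_end))
    if mode == "endpoints":
        delta = abs(d_end)
    elif mode == "amplitude":
        delta = float(traj.max() - traj.min())
    else:
        raise ValidationError("fc mode must be 'endpoints' or 'amplitude'")
    magnitude = 2.0**delta
    signed = -magnitude if direction < 0 else magnitude
    return float(signed), direction


@dataclass
class FitResult:
    """Per-probe quadratic fits, tests and fold changes for a dataset.

    ``table`` is indexed by probe_id with columns alpha, beta, gamma,
    pvalue, qvalue, fold_change, direction, perfect_fit; ``smoothed`` holds
    the fitted trajectories evaluated on ``age_grid`` (one row per probe).
    """

    table: pd.DataFrame
    smoothed: np.ndarray
    age_grid: np.ndarray
    fc_mode: str
    weighted: bool
    n_samples: int

    def significant(self, fdr_threshold: float, abs_fc_threshold: float):
        keep = (self.table["qvalue"] < fdr_threshold) & (
            self.table["fold_change"].abs() >= abs_fc_threshold
        )
        return keep.to_numpy()


def fit_dataset(
    dataset: ExpressionDataset,
    weights=None,
    config: Optional[AnalysisConfig] = None,
    age_grid=None,
    n_null_mc: int = 100_000,
) -> FitResult:
    """Fit, test and summarize every probe of a dataset in one pass.

    The calibration seed for the weighted null is derived from
    ``config.random_seed`` so a run is a pure function of (data, config).
    """
    config = config or AnalysisConfig()
    ages = dataset.ages
    Y = dataset.values
    if Y.shape[1] < 5:
        raise ValidationError("need at least 5 samples to fit and test")
    if np.unique(ages).size < 3:
        raise ValidationError("need at least 3 distinct ages")
    w = _as_weight_vector(weights, ages.size)

    coef, resid, F, rss1 = _f_statistic(Y, ages, w)
    alpha, beta, gamma = coef[0], coef[1], coef[2]

    perfect = ~np.isfinite(F)
    if w is None:
        pvals = stats.f.sf(np.where(perfect, 0.0, F), 2, ages.size - 3)
    else:
        cal = FTestCalibration(
            ages, w, n_mc=n_null_mc, seed=(config.random_seed * 7919 + 17) % (2**31)
        )
        pvals = np.atleast_1d(cal.pvalue(np.where(perfect, 0.0, F)))
    pvals = np.where(perfect, _TINY_P, pvals)
    qvals = bh_adjust(pvals)

    grid = np.asarray(age_grid, dtype=float) if age_grid is not None else dataset.age_grid(
        config.age_grid_step
    )
    smoothed = alpha[:, None] + beta[:, None] * grid[None, :] + gamma[:, None] * grid[None, :] ** 2

    fcs = np.empty(len(alpha))
    dirs = np.empty(len(alpha), dtype=int)
    for i in range(len(alpha)):
        fcs[i], dirs[i] = fold_change(smoothed[i], mode=config.fc_mode)

    table = pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
            "pvalue": pvals,
            "qvalue": qvals,
            "fold_change": fcs,
            "direction": dirs,
            "perfect_fit": perfect,
        },
        index=pd.Index(dataset.probe_ids, name="probe_id"),
    )
    return FitResult(
        table=table,
        smoothed=smoothed,
        age_grid=grid,
        fc_mode=config.fc_mode,
        weighted=w is not None,
        n_samples=ages.size,
    )


def filter_probes(table: pd.DataFrame, fdr_threshold: float, abs_fc_threshold: float):
    """Apply the joint FDR + fold-change filter.

    Returns the significant subset plus a summary of the volcano partition:
    counts passing the FDR filter alone, the FC filter alone, and both.
    """
    pass_fdr = table["qvalue"] < fdr_threshold
    pass_fc = table["fold_change"].abs() >= abs_fc_threshold
    keep = pass_fdr & pass_fc
    summary = {
        "n_total": int(len(table)),
        "n_pass_fdr": int(pass_fdr.sum()),
        "n_pass_fc": int(pass_fc.sum()),
        "n_pass_both": int(keep.sum()),
    }
    return table.loc[keep].copy(), summary


def tabulate_directions(table: pd.DataFrame) -> dict:
    """Count positively/negatively regulated probes (and flat ones)."""
    d = table["direction"] if "direction" in table else pd.Series(dtype=int)
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    zero = int((d == 0).sum())
    return {"positive": pos, "negative": neg, "zero": zero, "total": pos + neg + zero}


def volcano_table(
    table: pd.DataFrame, fdr_threshold: float = 0.05, abs_fc_threshold: float = 1.2
) -> pd.DataFrame:
    """Per-probe volcano coordinates with the three-way filter category."""
    log2fc = np.sign(table["fold_change"]) * np.log2(table["fold_change"].abs())
    minus_log10_p = -np.log10(np.maximum(table["pvalue"].to_numpy(), _TINY_P))
    pass_fdr = table["qvalue"] < fdr_threshold
    pass_fc = table["fold_change"].abs() >= abs_fc_threshold
    category = np.where(pass_fdr & pass_fc, "fdr_fc", np.where(pass_fdr, "fdr", "ns"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "minus_log10_p": minus_log10_p,
            "category": category,
        },
        index=table.index,
    )
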