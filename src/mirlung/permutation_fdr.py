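"""Permutation null for the count of CI-significant features, and FDR from it.

Each iteration shuffles the phenotype labels once (the Ct matrix stays fixed),
reruns the per-feature CI-exclusion test, and records how many features come
out significant — false positives by construction, since shuffling breaks any
real Ct-phenotype link. The median/mean of these counts divided by the
observed significant count estimates the false discovery rate of the
CI-exclusion strategy.

The per-iteration test is algebraically identical to the OLS t test in
:mod:`mirlung.association`: with r the Pearson correlation between Ct and the
permuted phenotype on a feature's complete cases, the slope's t statistic is
t = r*sqrt(n-2)/sqrt(1-r^2), so "CI excludes zero at level alpha" reduces to
r^2 > r_alpha^2 with r_alpha = t_crit/sqrt(n-2+t_crit^2). That lets the whole
null be computed as a handful of matrix products; tests assert exact agreement
with the per-feature statsmodels fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import Cohort

logger = logging.getLogger(__name__)


@dataclass
class PermutationNullSummary:
    """Null distribution of the significant-feature count."""

    counts: np.ndarray
    n_iter: int
    seed: int
    observed_significant: int
    median_fp: float = field(init=False)
    mean_fp: float = field(init=False)
    fdr_from_median: float = field(init=False)
    fdr_from_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != self.n_iter:
            raise ValueError("counts length must equal n_iter")
        self.median_fp = float(np.median(self.counts))
        self.mean_fp = float(np.mean(self.counts))
        self.fdr_from_median = estimate_fdr(self.median_fp, self.observed_significant)
        self.fdr_from_mean = estimate_fdr(self.mean_fp, self.observed_significant)


def estimate_fdr(fp_summary: float, observed_significant: int) -> float:
    """False-discovery-rate estimate: expected false positives / observed hits.

    Returns nan (with a warning) when nothing was observed significant, since
    0/0 is neither 0 nor an error.
    """
    if fp_summary < 0:
        raise ValueError("false-positive summary must be >= 0")
    if observed_significant == 0:
        warnings.warn("no observed significant features; FDR undefined")
        return float("nan")
    return float(fp_summary) / observed_significant


@dataclass
class _NullEngine:
    """Precomputed per-feature quantities for the vectorized CI test."""

    mask: np.ndarray       # F x S boolean complete-case masks
    xc: np.ndarray         # F x S masked-centered Ct (zeros off-mask)
    sxx: np.ndarray        # F
    n: np.ndarray          # F
    r2_crit: np.ndarray    # F
    testable: np.ndarray   # F boolean

    @classmethod
    def build(cls, values: np.ndarray, y_finite: np.ndarray, alpha: float) -> "_NullEngine":
        mask = np.isfinite(values) & y_finite[None, :]
        n = mask.sum(axis=1)
        x0 = np.where(mask, values, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            xbar = x0.sum(axis=1) / n
        xc = np.where(mask, values - xbar[:, None], 0.0)
        sxx = (xc ** 2).sum(axis=1)
        testable = (n >= 3) & (sxx > 0)
        r2_crit = np.full(values.shape[0], np.inf)
        dof = n[testable] - 2
        t_crit = stats.t.ppf(1 - alpha / 2, dof)
        r2_crit[testable] = t_crit ** 2 / (dof + t_crit ** 2)
        return cls(mask, xc, sxx, n, r2_crit, testable)

    def count_significant(self, Y: np.ndarray) -> np.ndarray:
        """Significant-feature count for each column of Y (S x B phenotypes)."""
        M = self.mask.astype(float)
        sy = M @ Y
        sy2 = M @ (Y ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            syy = sy2 - sy ** 2 / self.n[:, None]
            sxy = self.xc @ Y
            r2 = sxy ** 2 / (self.sxx[:, None] * syy)
        crit = np.broadcast_to(self.r2_crit[:, None], r2.shape)
        with np.errstate(invalid="ignore"):
            sig = self.testable[:, None] & (syy > 0) & (r2 > crit)
        return sig.sum(axis=0)


def permutation_null(
    cohort: Cohort,
    phenotype_name: str,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    observed_significant: int | None = None,
    level: str = "sample",
    batch_size: int = 500,
) -> PermutationNullSummary:
    """Monte-Carlo permutation null of the significant-feature count.

    Each of ``n_iter`` iterations draws one uniform random permutation of the
    phenotype vector (sampled with replacement across iterations), reruns the
    CI-exclusion test at ``alpha`` for every feature, and records the count.
    ``level='sample'`` permutes sample labels directly (the study's stated
    matrix dimensions); ``level='subject'`` permutes phenotype values between
    subjects so technical replicates stay tied together. Fully reproducible
    from ``seed``. Samples with missing phenotype are excluded up front.

    If ``observed_significant`` is omitted it is computed from the unpermuted
    phenotype with the same engine.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if level not in ("sample", "subject"):
        raise ValueError("level must be 'sample' or 'subject'")
    y_all = cohort.samples.frame[phenotype_name].to_numpy(dtype=float)
    keep = np.isfinite(y_all)
    y = y_all[keep]
    values = cohort.ct.values[:, keep]
    if y.size < 3:
        raise ValueError("fewer than 3 samples with a phenotype value")
    if np.ptp(y) == 0:
        raise ValueError(f"phenotype {phenotype_name!r} is constant")

    engine = _NullEngine.build(values, np.ones(y.size, dtype=bool), alpha)
    if observed_significant is None:
        observed_significant = int(engine.count_significant(y[:, None])[0])

    subjects = cohort.samples.frame.loc[keep, "subject_id"].to_numpy()
    uniq, inverse = np.unique(subjects, return_inverse=True)
    # one representative phenotype value per subject (replicates share it)
    subj_y = np.empty(uniq.size)
    subj_y[inverse] = y

    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=int)
    done = 0
    while done < n_iter:
        b = min(batch_size, n_iter - done)
        if level == "sample":
            Y = np.empty((y.size, b))
            for k in range(b):
                Y[:, k] = y[rng.permutation(y.size)]
        else:
            Y = np.empty((y.size, b))
            for k in range(b):
                Y[:, k] = subj_y[rng.permutation(uniq.size)][inverse]
        counts[done:done + b] = engine.count_significant(Y)
        done += b

    return PermutationNullSummary(
        counts=counts, n_iter=n_iter, seed=seed,
        observed_significant=observed_significant,
    )


def count_significant_once(cohort: Cohort, phenotype: np.ndarray,
                           alpha: float = 0.05) -> int:
    """Significant-feature count for one phenotype vector (no permutation)."""
    y = np.asarray(phenotype, dtype=float)
    engine = _NullEngine.build(cohort.ct.values, np.isfinite(y), alpha)
    y0 = np.where(np.isfinite(y), y, 0.0)
    return int(engine.count_significant(y0[:, None])[0])
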