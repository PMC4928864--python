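"""Well-level QC, detection filtering, replicate handling and normalization.

The preprocessing chain mirrors a standard qPCR array workflow: wells failing
the instrument's amplification-score (>1.24) or Cq-confidence (>0.80) gates
are blanked to missing; features detected in fewer than 75% of samples (or
subjects) are dropped; the surviving matrix is quantile normalized sample-wise
to the mean of the samples' order statistics, so every complete sample shares
one distribution while each sample's internal ranking is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Cohort, CtMatrix, SampleTable, WellQC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Detection gates for qPCR wells and features.

    amp_threshold, cq_threshold
        Strict lower bounds on the instrument's amplification score and Cq
        confidence for a well to count as detected.
    detection_fraction
        Minimum fraction of the denominator in which a feature must be
        detected to survive filtering.
    detection_denominator
        ``samples`` counts every profiled sample (replicates included);
        ``subjects`` counts distinct subjects with >=1 detected well.
    """

    amp_threshold: float = 1.24
    cq_threshold: float = 0.80
    detection_fraction: float = 0.75
    detection_denominator: str = "samples"

    def __post_init__(self) -> None:
        if not (0 < self.detection_fraction <= 1):
            raise ValueError("detection_fraction must be in (0, 1]")
        if self.detection_denominator not in ("samples", "subjects"):
            raise ValueError("detection_denominator must be 'samples' or 'subjects'")
        if not (np.isfinite(self.amp_threshold) and np.isfinite(self.cq_threshold)):
            raise ValueError("thresholds must be finite")


def apply_well_qc(
    ct: CtMatrix, qc: list[WellQC], thresholds: QCThresholds | None = None
) -> CtMatrix:
    """Blank wells whose QC metrics fail the detection gates.

    A well is retained only if amp_score > amp_threshold AND
    cq_conf > cq_threshold (strict inequalities: a score exactly at the
    threshold fails). Cells without a QC row are treated as detected whenever
    a Ct value is present. QC rows referencing unknown cells are skipped with
    a warning.
    """
    thresholds = thresholds or QCThresholds()
    out = ct.copy()
    f_idx = {f: i for i, f in enumerate(ct.feature_ids)}
    s_idx = {s: j for j, s in enumerate(ct.sample_ids)}
    skipped = 0
    for row in qc:
        i = f_idx.get(row.feature_id)
        j = s_idx.get(row.sample_id)
        if i is None or j is None:
            skipped += 1
            continue
        if not (row.amp_score > thresholds.amp_threshold
                and row.cq_conf > thresholds.cq_threshold):
            out.values[i, j] = np.nan
    if skipped:
        logger.warning("apply_well_qc skipped %d QC row(s) for unknown cells", skipped)
    return out


def detection_filter(
    ct: CtMatrix,
    thresholds: QCThresholds | None = None,
    samples: SampleTable | None = None,
) -> tuple[CtMatrix, pd.DataFrame]:
    """Drop features detected in less than ``detection_fraction`` of the cohort.

    Returns the filtered matrix plus a per-feature report with columns
    ``feature_id``, ``detection_fraction``, ``kept``. In ``subjects`` mode a
    sample table mapping samples to subjects is required; a subject counts as
    detected if any of its samples has a non-missing Ct.
    """
    thresholds = thresholds or QCThresholds()
    present = np.isfinite(ct.values)
    if thresholds.detection_denominator == "samples":
        frac = present.sum(axis=1) / ct.n_samples
    else:
        if samples is None:
            raise ValueError("subjects mode requires a sample table")
        subj = pd.Series(
            samples.frame.set_index("sample_id").loc[ct.sample_ids, "subject_id"].values
        )
        n_subjects = subj.nunique()
        grouped = pd.DataFrame(present.T).groupby(subj.values).any()
        frac = grouped.sum(axis=0).values / n_subjects
    kept = frac >= thresholds.detection_fraction
    report = pd.DataFrame({
        "feature_id": ct.feature_ids,
        "detection_fraction": frac,
        "kept": kept,
    })
    if not kept.any():
        raise ValueError(
            "detection_filter dropped every feature; review detection_fraction"
        )
    filtered = CtMatrix(
        [f for f, k in zip(ct.feature_ids, kept) if k],
        list(ct.sample_ids),
        ct.values[kept, :],
    )
    return filtered, report


def collapse_replicates(cohort: Cohort, mode: str = "keep_all") -> Cohort:
    """Handle technical replicates.

    ``keep_all`` returns the cohort unchanged (replicate samples enter the
    analysis as separate columns). ``mean_per_subject`` averages non-missing
    Ct per (feature, subject) and keeps one column per subject, labelled by
    the subject's first sample id.
    """
    if mode == "keep_all":
        return cohort
    if mode != "mean_per_subject":
        raise ValueError(f"unknown replicate mode {mode!r}")
    df = cohort.samples.frame
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, subject in enumerate(df["subject_id"]):
        if subject not in groups:
            groups[subject] = []
            order.append(subject)
        groups[subject].append(j)
    new_cols = np.full((cohort.ct.n_features, len(order)), np.nan)
    keep_rows = []
    for k, subject in enumerate(order):
        idx = groups[subject]
        with np.errstate(invalid="ignore"):
            new_cols[:, k] = np.nanmean(cohort.ct.values[:, idx], axis=1)
        keep_rows.append(idx[0])
    new_samples = df.iloc[keep_rows].copy()
    new_samples["is_replicate"] = False
    sample_ids = new_samples["sample_id"].astype(str).tolist()
    ct = CtMatrix(list(cohort.ct.feature_ids), sample_ids, new_cols)
    return Cohort(ct, SampleTable(new_samples.reset_index(drop=True)))


def replicate_concordance(cohort: Cohort) -> pd.DataFrame:
    """Spearman rank correlation across features for each replicate pair.

    For every subject profiled more than once, all sample pairs are compared
    over the features non-missing in both profiles (average-tie ranks). Pairs
    sharing fewer than 3 features get a missing correlation. Returns a frame
    with columns subject_id, sample_a, sample_b, n_features, spearman; the
    median is ``frame["spearman"].median()``.
    """
    df = cohort.samples.frame
    rows = []
    for subject, grp in df.groupby("subject_id", sort=False):
        ids = grp["sample_id"].astype(str).tolist()
        if len(ids) < 2:
            continue
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a = cohort.ct.values[:, cohort.ct.sample_ids.index(ids[a_i])]
                b = cohort.ct.values[:, cohort.ct.sample_ids.index(ids[b_i])]
                mask = np.isfinite(a) & np.isfinite(b)
                if mask.sum() < 3:
                    rho = np.nan
                else:
                    rho = stats.spearmanr(a[mask], b[mask]).statistic
                rows.append((subject, ids[a_i], ids[b_i], int(mask.sum()), rho))
    if not rows:
        raise ValueError("no subject has two or more samples")
    return pd.DataFrame(
        rows, columns=["subject_id", "sample_a", "sample_b", "n_features", "spearman"]
    )


def quantile_normalize_to_mean(ct: CtMatrix) -> CtMatrix:
    """Quantile normalize sample-wise to the mean of the samples' order statistics.

    Complete columns are replaced rank-for-rank by the across-sample mean of
    sorted values, so afterwards every complete column has identical sorted
    values while each column's internal ordering is untouched. Columns with
    missing cells are mapped through the mean empirical quantile function:
    the value of within-column rank r among m non-missing values sits at
    p = (r - 0.5) / m and receives the reference quantile there by linear
    interpolation. Ties receive the mean of the reference values their tied
    ranks would map to. Missing cells stay missing; a column with fewer than
    two non-missing values is left unchanged with a warning.
    """
    values = ct.values
    n_feat, n_samp = values.shape
    counts = np.isfinite(values).sum(axis=0)
    usable = counts >= 2
    if not usable.any():
        logger.warning("quantile normalization skipped: no column has >=2 values")
        return ct.copy()
    if (~usable).any():
        logger.warning(
            "quantile normalization left %d column(s) with <2 values unchanged",
            int((~usable).sum()),
        )

    # reference quantile function on a grid of K = max column count points
    K = int(counts[usable].max())
    grid = (np.arange(1, K + 1) - 0.5) / K
    ref = np.zeros(K)
    for j in np.flatnonzero(usable):
        col = values[:, j]
        srt = np.sort(col[np.isfinite(col)])
        m = srt.size
        p = (np.arange(1, m + 1) - 0.5) / m
        ref += np.interp(grid, p, srt)
    ref /= usable.sum()

    out = values.copy()
    for j in np.flatnonzero(usable):
        col = values[:, j]
        mask = np.isfinite(col)
        x = col[mask]
        m = x.size
        order = np.argsort(x, kind="mergesort")
        # per-rank mapped values, then average within tie groups
        p = (np.arange(1, m + 1) - 0.5) / m
        mapped_sorted = np.interp(p, grid, ref)
        mapped = np.empty(m)
        i = 0
        while i < m:
            k = i
            while k + 1 < m and x[order[k + 1]] == x[order[i]]:
                k += 1
            mapped[order[i:k + 1]] = mapped_sorted[i:k + 1].mean()
            i = k + 1
        new_col = col.copy()
        new_col[mask] = mapped
        out[:, j] = new_col
    return CtMatrix(list(ct.feature_ids), list(ct.sample_ids), out)


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Replace non-missing entries by average ranks 1..m; missing stay missing."""
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if not mask.any():
        raise ValueError("rank_normalize: all values missing")
    out = np.full(values.shape, np.nan)
    out[mask] = stats.rankdata(values[mask], method="average")
    return out
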