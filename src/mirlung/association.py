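"""Per-feature linear association of lung-function phenotypes with Ct.

For each microRNA the model is the simple regression

    phenotype = B0 + B1 * Ct + error

fit by ordinary least squares over complete cases. A feature is called
significant when the 95% confidence interval of B1 excludes zero — exactly
equivalent to a two-sided t test of B1 = 0 at alpha = 0.05. Because Ct is on
the cycle scale, +1 Ct is roughly a two-fold *decrease* in abundance, so B1 is
the phenotype change per halving of the microRNA.

Also provided: Benjamini-Hochberg (default) or Storey q-value adjustment,
covariate-adjusted multivariable fits, sex-stratified calls, and the fetal
gestational-age variant (same engine with age in days as the response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .data_model import Cohort, CtMatrix, FetalSampleTable


@dataclass
class AssociationResult:
    """One feature's regression output (a row of the association tables)."""

    feature_id: str
    phenotype_name: str
    n_used: int
    b0: float = np.nan
    b1: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    p_adjusted: float = np.nan
    significant: bool = False
    usable: bool = True
    reason: str = ""


@dataclass
class StratifiedCall:
    """Sex-stratified significance for one feature."""

    feature_id: str
    male_p: float
    female_p: float
    male_significant: bool
    female_significant: bool
    male_b1: float = np.nan
    female_b1: float = np.nan

    @property
    def call_class(self) -> str:
        if self.male_significant and self.female_significant:
            return "both"
        if self.male_significant:
            return "male_only"
        if self.female_significant:
            return "female_only"
        return "neither"


def significant_by_ci(ci_low: float, ci_high: float) -> bool:
    """CI-exclusion rule: significant iff the interval excludes zero.

    An endpoint exactly at zero counts as containing zero.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    return ci_low > 0 or ci_high < 0


def fit_feature(
    ct_values: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
    feature_id: str = "",
    phenotype_name: str = "",
) -> AssociationResult:
    """OLS of phenotype on Ct for one feature, with CI-exclusion significance.

    Complete cases only (pairwise deletion). Requires >=3 complete cases and
    non-constant Ct; otherwise the result is flagged unusable with a reason
    rather than dropped.
    """
    x = np.asarray(ct_values, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    res = AssociationResult(feature_id, phenotype_name, n)
    if n < 3:
        res.usable = False
        res.reason = f"only {n} complete cases (need >=3)"
        return res
    xm, ym = x[mask], y[mask]
    if np.ptp(xm) == 0:
        res.usable = False
        res.reason = "constant Ct"
        return res
    fit = sm.OLS(ym, sm.add_constant(xm)).fit()
    res.b0, res.b1 = fit.params
    res.ci_low, res.ci_high = fit.conf_int(alpha=alpha)[1]
    res.p_value = float(fit.pvalues[1])
    res.significant = significant_by_ci(res.ci_low, res.ci_high)
    return res


def bh_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment across the tested features.

    ``bh`` is Benjamini-Hochberg step-up (default, deterministic); ``storey``
    is a pFDR-style q-value with the smoothed pi0 estimate, closer in spirit
    to Matlab's ``mafdr``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown adjustment method {method!r}")


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with cubic-smoother pi0 estimation (pi0 capped at 1)."""
    m = p.size
    if m < 2:
        return p.copy()
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    # smooth with a cubic polynomial and take the value at the largest lambda
    coef = np.polyfit(lambdas, pi0_hat, deg=3)
    pi0 = float(np.clip(np.polyval(coef, lambdas[-1]), 0.0, 1.0))
    if pi0 == 0.0:
        pi0 = 1.0 / m
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return q


def associate_all(
    cohort: Cohort,
    phenotype_name: str,
    alpha: float = 0.05,
    adjust_method: str = "bh",
) -> list[AssociationResult]:
    """Fit every feature against one phenotype and adjust p-values.

    Output is ordered by feature_id; adjustment spans the usable fits only.
    """
    y = cohort.samples.frame[phenotype_name].to_numpy(dtype=float)
    results = []
    for fid in sorted(cohort.ct.feature_ids):
        i = cohort.ct.feature_ids.index(fid)
        results.append(
            fit_feature(cohort.ct.values[i], y, alpha, fid, phenotype_name)
        )
    usable = [r for r in results if r.usable]
    if usable:
        adj = bh_adjust(np.array([r.p_value for r in usable]), method=adjust_method)
        for r, a in zip(usable, adj):
            r.p_adjusted = float(a)
    return results


def fit_multivariable(
    cohort: Cohort,
    response: str,
    covariates: tuple[str, ...] = ("age", "sex", "height"),
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """OLS with intercept, Ct, and covariates; CI and p for the Ct term only.

    Sex enters as an indicator (female = 1). Requires n >= number of
    covariates + 3; rank-deficient designs are flagged unusable.
    """
    df = cohort.samples.frame
    cov_cols = []
    for c in covariates:
        if c == "sex":
            cov_cols.append((df["sex"] == "female").astype(float).to_numpy())
        else:
            cov_cols.append(df[c].to_numpy(dtype=float))
    cov = np.column_stack(cov_cols) if cov_cols else np.empty((len(df), 0))
    y = df[response].to_numpy(dtype=float)
    results = []
    for fid in sorted(cohort.ct.feature_ids):
        i = cohort.ct.feature_ids.index(fid)
        x = cohort.ct.values[i]
        mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
        n = int(mask.sum())
        res = AssociationResult(fid, response, n)
        if n < cov.shape[1] + 3:
            res.usable = False
            res.reason = f"only {n} complete cases (need >={cov.shape[1] + 3})"
            results.append(res)
            continue
        cov_m = cov[mask]
        # constant covariates carry no information beyond the intercept; drop
        # them so the fit degenerates cleanly to the simple model
        varying = [c for c in range(cov_m.shape[1]) if np.ptp(cov_m[:, c]) > 0]
        cov_m = cov_m[:, varying]
        X = np.column_stack([x[mask], cov_m])
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            res.usable = False
            res.reason = "rank-deficient design"
            results.append(res)
            continue
        fit = sm.OLS(y[mask], X).fit()
        res.b0 = float(fit.params[0])
        res.b1 = float(fit.params[1])
        res.ci_low, res.ci_high = fit.conf_int(alpha=alpha)[1]
        res.p_value = float(fit.pvalues[1])
        res.significant = significant_by_ci(res.ci_low, res.ci_high)
        results.append(res)
    usable = [r for r in results if r.usable]
    if usable:
        adj = bh_adjust(np.array([r.p_value for r in usable]))
        for r, a in zip(usable, adj):
            r.p_adjusted = float(a)
    return results


def stratify_by_sex(
    cohort: Cohort,
    features: list[str],
    phenotype_name: str = "fev1_fvc",
    alpha: float = 0.05,
) -> list[StratifiedCall]:
    """Refit the given features separately in males and females.

    Significance per stratum uses the same CI-exclusion rule; a stratum with
    too few complete cases yields an unusable (non-significant) call there.
    """
    df = cohort.samples.frame
    calls = []
    for fid in features:
        i = cohort.ct.feature_ids.index(fid)
        x = cohort.ct.values[i]
        y = df[phenotype_name].to_numpy(dtype=float)
        per_sex = {}
        for sex in ("male", "female"):
            sel = (df["sex"] == sex).to_numpy()
            per_sex[sex] = fit_feature(x[sel], y[sel], alpha, fid, phenotype_name)
        calls.append(StratifiedCall(
            feature_id=fid,
            male_p=per_sex["male"].p_value,
            female_p=per_sex["female"].p_value,
            male_significant=per_sex["male"].usable and per_sex["male"].significant,
            female_significant=(per_sex["female"].usable
                                and per_sex["female"].significant),
            male_b1=per_sex["male"].b1,
            female_b1=per_sex["female"].b1,
        ))
    return calls


def fetal_age_association(
    fetal_ct: CtMatrix,
    fetal_ages: FetalSampleTable,
    features: list[str] | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Associate fetal-lung Ct with gestational age (days post conception).

    Same per-feature engine with age as the response; the fetal-associated
    set is ``[r.feature_id for r in results if r.significant]``.
    """
    ages = (
        fetal_ages.frame.set_index("sample_id")
        .loc[fetal_ct.sample_ids, "gestational_age"]
        .to_numpy(dtype=float)
    )
    wanted = features if features is not None else sorted(fetal_ct.feature_ids)
    results = []
    for fid in wanted:
        if fid not in fetal_ct.feature_ids:
            continue
        i = fetal_ct.feature_ids.index(fid)
        results.append(
            fit_feature(fetal_ct.values[i], ages, alpha, fid, "gestational_age")
        )
    usable = [r for r in results if r.usable]
    if usable:
        adj = bh_adjust(np.array([r.p_value for r in usable]))
        for r, a in zip(usable, adj):
            r.p_adjusted = float(a)
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into the canonical TSV column layout."""
    return pd.DataFrame([
        {
            "feature_id": r.feature_id,
            "phenotype": r.phenotype_name,
            "n": r.n_used,
            "beta": r.b1,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "usable": r.usable,
            "reason": r.reason,
        }
        for r in results
    ])
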