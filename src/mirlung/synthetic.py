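"""Synthetic serum-cohort and fetal-lung generators.

These generators emulate the statistical structure the analysis assumes, so
every pipeline stage is testable without the deposited expression data: a
pediatric asthma cohort of 160 subjects (13 profiled twice, 173 samples in
all) with lung-function phenotypes drawn at the published cohort moments; 738
assayed microRNAs of which 108 sit in the detectable Ct range while the rest
are censored at the limit of detection; block-correlated inter-feature noise;
optional planted Ct-phenotype effects (overall or in one sex); and well-level
QC scores that agree with the censoring.

Effects are planted in the generative direction (Ct varies with the
standardized phenotype); the pipeline regresses phenotype on Ct, so the truth
record carries both the planted coefficient and the implied regression slope
for like-with-like recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CtMatrix, FetalSampleTable, SampleTable, WellQC

#: published cohort phenotype moments (mean, sd)
DEFAULT_PHENOTYPES: dict[str, tuple[float, float]] = {
    "fev1_fvc": (78.73, 8.71),
    "fev1_pct": (93.35, 14.72),
    "fvc_pct": (106.13, 13.51),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A planted Ct-phenotype association.

    ``slope_ct`` is in Ct cycles per phenotype standard deviation, applied in
    the generative direction; ``sex`` restricts the effect to one sex
    (``both`` applies it everywhere).
    """

    feature_index: int
    slope_ct: float
    sex: str = "both"           # both | male | female
    phenotype: str = "fev1_fvc"


@dataclass
class SyntheticParams:
    """Study-design parameters for the synthetic serum cohort."""

    n_features_total: int = 738
    n_features_detectable: int = 108
    n_subjects: int = 160
    n_replicate_subjects: int = 13
    male_fraction: float = 0.544
    phenotypes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    age_mean: float = 8.83
    age_sd: float = 2.12
    ct_mean_range: tuple[float, float] = (18.0, 32.0)
    undetectable_ct_range: tuple[float, float] = (34.0, 40.0)
    ct_noise_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    lod_ct: float = 33.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    block_size: int = 6
    block_rho: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must be in [0, 1]")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must be in [0, 1)")
        for name, (_, sd) in self.phenotypes.items():
            if sd <= 0:
                raise ValueError(f"phenotype {name!r} sd must be > 0")
        for e in self.planted_effects:
            if not np.isfinite(e.slope_ct):
                raise ValueError("planted slope must be finite")
            if not (0 <= e.feature_index < self.n_features_detectable):
                raise ValueError(
                    f"planted feature index {e.feature_index} out of range "
                    f"[0, {self.n_features_detectable})"
                )


def _block_noise(rng: np.random.Generator, n_features: int, n_draws: int,
                 block_size: int, rho: float, sd: float) -> np.ndarray:
    """Exchangeable within-block correlated Gaussian noise, features x draws."""
    z = rng.standard_normal((n_features, n_draws))
    if rho == 0:
        return sd * z
    n_blocks = int(np.ceil(n_features / block_size))
    shared = rng.standard_normal((n_blocks, n_draws))
    shared_full = np.repeat(shared, block_size, axis=0)[:n_features]
    return sd * (np.sqrt(rho) * shared_full + np.sqrt(1 - rho) * z)


def generate_cohort(
    params: SyntheticParams,
) -> tuple[CtMatrix, list[WellQC], SampleTable, pd.DataFrame]:
    """Generate a synthetic serum cohort; bit-identical for a fixed seed.

    Returns the censored Ct matrix, well-level QC rows consistent with the
    censoring, the sample/phenotype table, and the truth record of planted
    effects (with implied phenotype-on-Ct regression slopes).
    """
    rng = np.random.default_rng(params.seed)
    n_sub = params.n_subjects

    # --- subjects & phenotypes ------------------------------------------------
    subject_ids = [f"SUBJ{i + 1:04d}" for i in range(n_sub)]
    n_male = int(round(params.male_fraction * n_sub))
    sex = np.array(["male"] * n_male + ["female"] * (n_sub - n_male))
    rng.shuffle(sex)
    age = params.age_mean + params.age_sd * rng.standard_normal(n_sub)
    age = np.clip(age, 4.0, 18.0)
    height = 80.0 + 6.0 * age + 5.0 * rng.standard_normal(n_sub)

    pheno: dict[str, np.ndarray] = {}
    z_pheno: dict[str, np.ndarray] = {}
    for name, (mu, sd) in params.phenotypes.items():
        z = rng.standard_normal(n_sub)
        vals = mu + sd * z
        if name == "fev1_fvc":
            vals = np.clip(vals, 30.0, 149.0)
        pheno[name] = vals
        z_pheno[name] = (vals - mu) / sd

    # raw volumes: FVC scaled to height, FEV1 consistent with the ratio
    fvc_l = (height / 100.0) ** 2 * (pheno.get("fvc_pct", np.full(n_sub, 100.0)) / 100.0)
    fev1_l = pheno["fev1_fvc"] / 100.0 * fvc_l

    # --- latent subject-level Ct ---------------------------------------------
    F, D = params.n_features_total, params.n_features_detectable
    feature_ids = [f"syn-miR-{i + 1:04d}" for i in range(F)]
    means = np.empty(F)
    means[:D] = rng.uniform(*params.ct_mean_range, size=D)
    means[D:] = rng.uniform(*params.undetectable_ct_range, size=F - D)
    latent = means[:, None] + _block_noise(
        rng, F, n_sub, params.block_size, params.block_rho, params.ct_noise_sd
    )
    for eff in params.planted_effects:
        z = z_pheno[eff.phenotype]
        if eff.sex == "both":
            sel = np.ones(n_sub, dtype=bool)
        else:
            sel = sex == eff.sex
        latent[eff.feature_index, sel] += eff.slope_ct * z[sel]

    # --- samples (replicates = subject value + replicate noise) ---------------
    rep_subjects = list(range(params.n_replicate_subjects))
    sample_rows = []
    cols = []
    for i in range(n_sub):
        sample_rows.append((f"{subject_ids[i]}_a", subject_ids[i], False))
        cols.append(latent[:, i])
    for i in rep_subjects:
        noise = params.replicate_noise_sd * rng.standard_normal(F)
        sample_rows.append((f"{subject_ids[i]}_b", subject_ids[i], True))
        cols.append(latent[:, i] + noise)
    raw = np.column_stack(cols)
    sample_ids = [r[0] for r in sample_rows]

    # --- censoring at the limit of detection + agreeing well QC ---------------
    censored = raw > params.lod_ct
    values = np.where(censored, np.nan, np.clip(raw, 0.0, params.lod_ct))
    qc_rows: list[WellQC] = []
    amp_pass = rng.uniform(1.30, 2.00, size=raw.shape)
    amp_fail = rng.uniform(0.50, 1.24, size=raw.shape)
    cq_pass = rng.uniform(0.85, 1.00, size=raw.shape)
    cq_fail = rng.uniform(0.30, 0.80, size=raw.shape)
    amp = np.where(censored, amp_fail, amp_pass)
    cq = np.where(censored, cq_fail, cq_pass)
    for fi in range(F):
        for sj in range(len(sample_ids)):
            qc_rows.append(WellQC(feature_ids[fi], sample_ids[sj],
                                  float(amp[fi, sj]), float(cq[fi, sj])))

    ct = CtMatrix(feature_ids, sample_ids, values)

    # --- sample table ---------------------------------------------------------
    sub_idx = {s: i for i, s in enumerate(subject_ids)}
    rows = []
    for sid, subj, is_rep in sample_rows:
        i = sub_idx[subj]
        rows.append({
            "sample_id": sid, "subject_id": subj, "sex": sex[i],
            "age": age[i], "height": height[i],
            "fev1_pct": pheno.get("fev1_pct", [np.nan] * n_sub)[i],
            "fvc_pct": pheno.get("fvc_pct", [np.nan] * n_sub)[i],
            "fev1_fvc": pheno["fev1_fvc"][i],
            "fev1_l": fev1_l[i], "fvc_l": fvc_l[i],
            "is_replicate": is_rep,
        })
    samples = SampleTable(pd.DataFrame(rows))

    # --- truth record ---------------------------------------------------------
    truth_rows = []
    for eff in params.planted_effects:
        _, sd_y = params.phenotypes[eff.phenotype]
        s2 = params.ct_noise_sd ** 2
        implied_b1 = sd_y * eff.slope_ct / (eff.slope_ct ** 2 + s2)
        truth_rows.append({
            "feature_id": feature_ids[eff.feature_index],
            "phenotype": eff.phenotype,
            "sex": eff.sex,
            "planted_slope_ct": eff.slope_ct,
            "implied_b1": implied_b1,
        })
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "phenotype", "sex", "planted_slope_ct", "implied_b1"],
    )
    return ct, qc_rows, samples, truth


@dataclass
class FetalParams:
    """Parameters for the synthetic fetal-lung set (ages in days post conception)."""

    n_samples: int = 30
    n_features: int = 22
    age_range: tuple[float, float] = (67.0, 115.0)
    ct_mean_range: tuple[float, float] = (18.0, 32.0)
    ct_noise_sd: float = 1.0
    planted_age_slopes: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 fetal samples")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("empty gestational-age range")
        for i in self.planted_age_slopes:
            if not (0 <= i < self.n_features):
                raise ValueError(f"planted feature index {i} out of range")


def generate_fetal(
    params: FetalParams,
) -> tuple[CtMatrix, FetalSampleTable, pd.DataFrame]:
    """Generate fetal-lung Ct with optional linear age trends.

    Planted slopes are in Ct cycles per day post conception; ages are uniform
    on the configured range. The truth record includes the implied
    age-on-Ct regression slope for recovery checks.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.age_range
    ages = rng.uniform(lo, hi, size=params.n_samples)
    feature_ids = [f"syn-miR-{i + 1:04d}" for i in range(params.n_features)]
    means = rng.uniform(*params.ct_mean_range, size=params.n_features)
    values = (means[:, None]
              + params.ct_noise_sd * rng.standard_normal(
                  (params.n_features, params.n_samples)))
    age_c = ages - ages.mean()
    for i, slope in params.planted_age_slopes.items():
        values[i, :] += slope * age_c
    values = np.clip(values, 0.0, 45.0)
    sample_ids = [f"FETAL{j + 1:03d}" for j in range(params.n_samples)]
    ct = CtMatrix(feature_ids, sample_ids, values)
    table = FetalSampleTable(pd.DataFrame(
        {"sample_id": sample_ids, "gestational_age": ages}))
    var_age = np.var(age_c)
    truth = pd.DataFrame([
        {
            "feature_id": feature_ids[i],
            "planted_slope_ct_per_day": s,
            "implied_b1": (s * var_age) / (s ** 2 * var_age + params.ct_noise_sd ** 2),
        }
        for i, s in params.planted_age_slopes.items()
    ], columns=["feature_id", "planted_slope_ct_per_day", "implied_b1"])
    return ct, table, truth
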