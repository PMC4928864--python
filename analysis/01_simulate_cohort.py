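#!/usr/bin/env python
"""Simulate the study-sized serum cohort and fetal-lung set.

Generates a 738-feature x 173-sample cohort (160 subjects, 13 technical
replicates) with 22 planted Ct-FEV1/FVC effects on the scale of the reported
associations (about 0.8-2.0 ratio points per Ct cycle): 10 present in both
sexes, 8 in boys only, 4 in girls only. Also plants 2 FEV1% and 3 FVC%
effects, and a 22-feature fetal-lung set with 7 gestational-age trends.

Full matrices are large and go to scratch/cohort/ (regenerable); the truth
records (what was planted, and the implied regression slopes the analysis
should recover) go to results/.
"""

from pathlib import Path

from mirlung.data_model import write_ct_matrix, write_sample_table, write_well_qc
from mirlung.synthetic import (
    FetalParams,
    PlantedEffect,
    SyntheticParams,
    generate_cohort,
    generate_fetal,
)

SEED = 20260920
SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")

# slope_ct ~ 0.12-0.35 Ct per phenotype-SD implies regression slopes of about
# 1.0-2.6 ratio points per Ct at sd_y = 8.71, matching the reported effect range
EFFECTS = (
    [PlantedEffect(i, 0.12 + 0.02 * i, "both") for i in range(10)]
    + [PlantedEffect(10 + i, 0.30 + 0.03 * i, "male") for i in range(8)]
    + [PlantedEffect(18 + i, 0.30 + 0.03 * i, "female") for i in range(4)]
    + [PlantedEffect(30, 0.30, "both", "fev1_pct"),
       PlantedEffect(31, 0.30, "both", "fev1_pct"),
       PlantedEffect(40, 0.30, "both", "fvc_pct"),
       PlantedEffect(41, 0.30, "both", "fvc_pct"),
       PlantedEffect(42, 0.35, "both", "fvc_pct")]
)

FETAL_SLOPES = {i: s for i, s in zip(range(7), (-0.06, -0.05, 0.05, 0.06,
                                                -0.07, 0.07, 0.06))}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    params = SyntheticParams(seed=SEED, planted_effects=EFFECTS)
    ct, qc_rows, samples, truth = generate_cohort(params)
    write_ct_matrix(ct, SCRATCH / "ct.tsv")
    write_well_qc(qc_rows, SCRATCH / "well_qc.tsv")
    write_sample_table(samples, SCRATCH / "samples.tsv")
    truth.to_csv(RESULTS / "planted_truth.tsv", sep="\t", index=False)

    fct, ftable, ftruth = generate_fetal(
        FetalParams(seed=SEED + 1, planted_age_slopes=FETAL_SLOPES))
    write_ct_matrix(fct, SCRATCH / "fetal_ct.tsv")
    ftable.frame.to_csv(SCRATCH / "fetal_samples.tsv", sep="\t", index=False)
    ftruth.to_csv(RESULTS / "fetal_truth.tsv", sep="\t", index=False)

    print(f"cohort: {ct.n_features} features x {ct.n_samples} samples "
          f"({samples.frame['is_replicate'].sum()} replicates); "
          f"{len(truth)} planted serum effects, {len(ftruth)} fetal trends")
    print(f"matrices -> {SCRATCH}/, truth -> {RESULTS}/planted_truth.tsv")


if __name__ == "__main__":
    main()
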