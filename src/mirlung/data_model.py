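"""Domain containers and TSV I/O shared by every pipeline stage.

The central object is the :class:`CtMatrix`, a feature x sample grid of qPCR
cycle-threshold (Ct) values. Ct is the PCR cycle at which fluorescence crosses
the instrument threshold; lower Ct means more template, and +1 Ct corresponds
to roughly a two-fold drop in abundance. Missing cells represent wells where
the target was not detected or failed quality control.

All on-disk formats are plain TSV: a wide matrix (features in rows, samples in
columns, ``NA`` for missing), a long well-level QC table, and flat tables for
sample phenotypes, fetal gestational ages, and annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_MIN = 0.0
#: conventional maximum qPCR cycle count
CT_MAX = 45.0

#: tokens read as missing; the writer always emits "NA"
NA_TOKENS = ("", "NA")

_SEX_TOKENS = {
    "m": "male", "male": "male", "0": "male",
    "f": "female", "female": "female", "1": "female",
}


class DataModelError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class CtMatrix:
    """Feature x sample cycle-threshold matrix with missingness.

    Parameters
    ----------
    feature_ids : list of str
        Unique miRBase-style symbols (treated as opaque strings).
    sample_ids : list of str
        Unique sample identifiers.
    values : ndarray of shape (n_features, n_samples)
        Ct values in PCR cycles; ``nan`` marks missing wells.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataModelError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) == 0 or len(self.sample_ids) == 0:
            raise DataModelError("CtMatrix needs at least one feature and one sample")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < CT_MIN or finite.max() > CT_MAX):
            bad = finite[(finite < CT_MIN) | (finite > CT_MAX)][0]
            raise DataModelError(
                f"Ct value {bad} outside [{CT_MIN}, {CT_MAX}]"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)

    def copy(self) -> "CtMatrix":
        return CtMatrix(list(self.feature_ids), list(self.sample_ids), self.values.copy())

    def subset_features(self, keep: list[str]) -> "CtMatrix":
        idx = [self.feature_ids.index(f) for f in keep]
        return CtMatrix(list(keep), list(self.sample_ids), self.values[idx, :])

    def subset_samples(self, keep: list[str]) -> "CtMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return CtMatrix(list(self.feature_ids), list(keep), self.values[:, idx])


@dataclass(frozen=True)
class WellQC:
    """Per-well instrument quality metrics.

    ``detected`` is derived downstream: a well counts as detected when its
    amplification score and Cq confidence both exceed the configured
    thresholds and a Ct value is present.
    """

    feature_id: str
    sample_id: str
    amp_score: float
    cq_conf: float


@dataclass
class SampleTable:
    """Per-sample covariates and lung-function phenotypes.

    One row per profiled sample; a subject may own several samples (technical
    replicates). Phenotypes: FEV1% and FVC% are percent of the predicted value
    for age/sex/height; FEV1/FVC is the ratio x 100; the raw volumes are in
    liters.
    """

    frame: pd.DataFrame

    PHENOTYPES = ("fev1_pct", "fvc_pct", "fev1_fvc", "fev1_l", "fvc_l")
    REQUIRED = ("sample_id", "subject_id", "sex")

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise DataModelError(f"sample table missing required column {col!r}")
        _check_unique(df["sample_id"].astype(str).tolist(), "sample id")
        bad = set(df["sex"]) - {"male", "female"}
        if bad:
            raise DataModelError(f"unknown sex token(s): {sorted(bad)}")
        if "fev1_fvc" in df.columns:
            r = df["fev1_fvc"].dropna()
            if ((r <= 0) | (r > 150)).any():
                raise DataModelError("fev1_fvc outside (0, 150]")
        if "is_replicate" not in df.columns:
            df["is_replicate"] = False
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].astype(str).tolist()

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        df = self.frame.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleTable(df)


@dataclass
class FetalSampleTable:
    """Fetal-lung samples with gestational age in days post conception."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("sample_id", "gestational_age"):
            if col not in df.columns:
                raise DataModelError(f"fetal table missing column {col!r}")
        _check_unique(df["sample_id"].astype(str).tolist(), "sample id")
        ga = df["gestational_age"]
        if ((ga < 50) | (ga > 200)).any():
            raise DataModelError("gestational_age outside [50, 200] days")
        self.frame = df.reset_index(drop=True)


@dataclass
class AnnotationTables:
    """Literature membership, target-gene, and GWAS-trait maps.

    literature: study_id -> set of feature_ids reported in that study
    targets: feature_id -> set of functionally validated target gene symbols
    gwas_traits: gene symbol -> set of GWAS-mapped trait strings
    """

    literature: dict[str, set[str]] = field(default_factory=dict)
    targets: dict[str, set[str]] = field(default_factory=dict)
    gwas_traits: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.literature, self.targets, self.gwas_traits):
            for k in m:
                if not k:
                    raise DataModelError("empty key in annotation map")


@dataclass
class Cohort:
    """A Ct matrix and sample table aligned over the same samples, same order."""

    ct: CtMatrix
    samples: SampleTable

    def __post_init__(self) -> None:
        if self.ct.sample_ids != self.samples.sample_ids:
            raise DataModelError("cohort Ct matrix and sample table are not aligned")


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataModelError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_ct_matrix(path: str | Path, dialect: str = "wide_tsv") -> CtMatrix:
    """Read a wide TSV Ct matrix (first column feature ids, header sample ids).

    Empty cells and ``NA`` are read as missing. Any other non-numeric token is
    a hard error naming its row and column.
    """
    if dialect != "wide_tsv":
        raise DataModelError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample id")  # pandas would silently mangle dups
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     skiprows=1, names=header)
    feature_ids = df.iloc[:, 0].tolist()
    _check_unique(feature_ids, "feature id")
    _check_unique(sample_ids, "sample id")
    values = np.full((len(feature_ids), len(sample_ids)), np.nan)
    for j, s in enumerate(sample_ids):
        col = df.iloc[:, j + 1]
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok in NA_TOKENS:
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise DataModelError(
                    f"non-numeric Ct token {tok!r} at feature {feature_ids[i]!r}, "
                    f"sample {s!r}"
                ) from None
    return CtMatrix(feature_ids, sample_ids, values)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    """Write a CtMatrix as wide TSV; missing cells become ``NA``.

    Uses repr-precision floats so read_ct_matrix round-trips bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(ct.sample_ids) + "\n")
        for i, fid in enumerate(ct.feature_ids):
            row = [
                "NA" if not np.isfinite(v) else repr(float(v))
                for v in ct.values[i]
            ]
            fh.write(fid + "\t" + "\t".join(row) + "\n")


def read_well_qc(path: str | Path) -> list[WellQC]:
    """Read long-format well QC (feature_id, sample_id, amp_score, cq_conf)."""
    df = pd.read_csv(path, sep="\t")
    seen: set[tuple[str, str]] = set()
    rows: list[WellQC] = []
    for rec in df.itertuples(index=False):
        key = (str(rec.feature_id), str(rec.sample_id))
        if key in seen:
            raise DataModelError(f"duplicate QC row for {key}")
        seen.add(key)
        rows.append(WellQC(key[0], key[1], float(rec.amp_score), float(rec.cq_conf)))
    return rows


def write_well_qc(rows: list[WellQC], path: str | Path) -> None:
    pd.DataFrame(
        [(r.feature_id, r.sample_id, r.amp_score, r.cq_conf) for r in rows],
        columns=["feature_id", "sample_id", "amp_score", "cq_conf"],
    ).to_csv(path, sep="\t", index=False)


def normalize_sex(token: str) -> str:
    """Map {M/F, male/female, 0/1} onto {male, female}; 0=male, 1=female."""
    t = str(token).strip().lower()
    if t not in _SEX_TOKENS:
        raise DataModelError(f"unknown sex token {token!r}")
    return _SEX_TOKENS[t]


def read_sample_table(path: str | Path) -> SampleTable:
    """Read and type the per-sample phenotype table.

    Sex tokens are normalized; if ``fev1_fvc`` is absent but the raw liter
    volumes are present it is derived as 100 * fev1_l / fvc_l.
    """
    df = pd.read_csv(path, sep="\t")
    df["sex"] = df["sex"].map(normalize_sex)
    df["sample_id"] = df["sample_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    if "fev1_fvc" not in df.columns and {"fev1_l", "fvc_l"} <= set(df.columns):
        df["fev1_fvc"] = 100.0 * df["fev1_l"] / df["fvc_l"]
    if "is_replicate" in df.columns:
        df["is_replicate"] = df["is_replicate"].astype(bool)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_fetal_table(path: str | Path) -> FetalSampleTable:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return FetalSampleTable(df)


def read_annotations(
    literature_path: str | Path | None = None,
    targets_path: str | Path | None = None,
    gwas_path: str | Path | None = None,
) -> AnnotationTables:
    """Read annotation TSVs: (study_id, feature_id), (feature_id, gene), (gene, trait)."""

    def _pairs(path, kcol, vcol) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        if path is None:
            return out
        df = pd.read_csv(path, sep="\t", comment="#")
        for k, v in zip(df[kcol].astype(str), df[vcol].astype(str)):
            out.setdefault(k, set()).add(v)
        return out

    return AnnotationTables(
        literature=_pairs(literature_path, "study_id", "feature_id"),
        targets=_pairs(targets_path, "feature_id", "gene"),
        gwas_traits=_pairs(gwas_path, "gene", "trait"),
    )


def join_cohort(ct: CtMatrix, samples: SampleTable) -> Cohort:
    """Align a Ct matrix with a sample table over their shared samples.

    Samples present in only one input are dropped with a logged count; sample
    order follows the Ct matrix. Empty intersection is a hard error.
    """
    table_ids = set(samples.sample_ids)
    shared = [s for s in ct.sample_ids if s in table_ids]
    if not shared:
        raise DataModelError("no samples shared between Ct matrix and sample table")
    dropped = (ct.n_samples - len(shared)) + (len(table_ids) - len(shared))
    if dropped:
        logger.warning("join_cohort dropped %d unmatched sample(s)", dropped)
    return Cohort(ct.subset_samples(shared), samples.subset(shared))
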