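"""Annotation joins: literature flags, miRTarBase/GWAS joins, overlap sets.

These pure-table operations connect the association results to prior
knowledge: how often each microRNA was reported in earlier asthma
case-control studies (flag ``Y`` for >=1 study, ``Y2`` for >=2), which of its
functionally validated target genes carry GWAS asthma/lung-function traits,
and how the significant, sex-specific and fetal-development sets overlap.
Feature-id matching is exact string match, optionally after trimming the
``hsa-`` species prefix; no fuzzy miRBase-version mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FeatureAnnotation:
    """Cross-reference record for one microRNA."""

    feature_id: str
    literature_flag: str = "none"  # none | Y | Y2
    fetal_flag: bool = False
    target_genes: set[str] = field(default_factory=set)
    gwas_genes: set[str] = field(default_factory=set)
    traits_by_gene: dict[str, set[str]] = field(default_factory=dict)


def _strip(fid: str, trim_prefix: bool) -> str:
    return fid.removeprefix("hsa-") if trim_prefix else fid


def literature_flags(
    features: list[str],
    literature: dict[str, set[str]],
    trim_prefix: bool = True,
) -> dict[str, str]:
    """Flag each feature by how many literature studies report it."""
    counts: dict[str, int] = {}
    for members in literature.values():
        for f in members:
            key = _strip(f, trim_prefix)
            counts[key] = counts.get(key, 0) + 1
    out = {}
    for f in features:
        c = counts.get(_strip(f, trim_prefix), 0)
        out[f] = "Y2" if c >= 2 else ("Y" if c == 1 else "none")
    return out


def gwas_target_join(
    features: list[str],
    targets: dict[str, set[str]],
    gwas: dict[str, set[str]],
    trim_prefix: bool = True,
) -> dict[str, FeatureAnnotation]:
    """Intersect each feature's target genes with GWAS trait-bearing genes.

    Genes absent from the GWAS map simply contribute no traits.
    """
    tgt = {_strip(k, trim_prefix): v for k, v in targets.items()}
    out = {}
    for f in features:
        genes = set(tgt.get(_strip(f, trim_prefix), set()))
        gwas_genes = {g for g in genes if gwas.get(g)}
        out[f] = FeatureAnnotation(
            feature_id=f,
            target_genes=genes,
            gwas_genes=gwas_genes,
            traits_by_gene={g: set(gwas[g]) for g in gwas_genes},
        )
    return out


@dataclass
class OverlapReport:
    """Counts, percentages and memberships of the sex/fetal overlap regions."""

    n_significant: int
    regions: dict[str, list[str]]
    counts: dict[str, int] = field(init=False)
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {k: len(v) for k, v in self.regions.items()}
        self.percentages = {
            k: 100.0 * len(v) / self.n_significant for k, v in self.regions.items()
        }


def overlap_sets(
    significant: set[str],
    male_only: set[str],
    female_only: set[str],
    fetal: set[str],
) -> OverlapReport:
    """Overlap report for the significant / sex-specific / fetal sets.

    All inputs except ``significant`` must be subsets of it; percentages are
    relative to the significant set and re-derivable from the sorted
    membership lists.
    """
    for name, s in (("male_only", male_only), ("female_only", female_only),
                    ("fetal", fetal)):
        extra = s - significant
        if extra:
            raise ValueError(f"{name} not a subset of significant: {sorted(extra)}")
    if not significant:
        raise ValueError("significant set is empty")
    regions = {
        "significant": sorted(significant),
        "male_only": sorted(male_only),
        "female_only": sorted(female_only),
        "fetal": sorted(fetal),
        "male_only_and_fetal": sorted(male_only & fetal),
        "female_only_and_fetal": sorted(female_only & fetal),
    }
    return OverlapReport(n_significant=len(significant), regions=regions)
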