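"""Reduction of flagged tumor-only calls to putative somatic variants.

The funnel applies, in order: the technical depth/allele-fraction filter,
removal of database-common positions (CO flag), restriction to moderate/high
predicted impact, masking of manually curated trouble regions, removal of
recurrent positions whose across-sample allele-fraction distribution is
centered on 0.5 (a germline heterozygous signature), a benign-significance
filter, an optional rs-id blocklist, and finally removal of genes mutated in
fewer than a minimum number of samples.  Each stage's input/output counts
are recorded in a :class:`FilterFunnel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MaskRegion",
    "FilterFunnel",
    "FilterConfig",
    "default_mask",
    "database_filter",
    "impact_filter",
    "mask_filter",
    "germline_aaf_test",
    "germline_aaf_filter",
    "classify_germline_groups",
    "benign_filter",
    "blocklist_filter",
    "gene_recurrence_filter",
    "run_funnel",
    "germline_recovery_report",
]


@dataclass(frozen=True)
class MaskRegion:
    """A manually curated region to exclude (1-based, inclusive ends).

    ``start``/``end`` of ``None`` masks every variant annotated to ``label``
    (a whole-gene mask), used for genes whose repeat architecture makes
    calls unreliable along their entire length.
    """

    chrom: str | None
    start: int | None
    end: int | None
    label: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start >= self.end:
            raise ValueError(f"malformed mask region {self.label}: start >= end")

    @property
    def whole_gene(self) -> bool:
        return self.start is None or self.end is None


def default_mask() -> list[MaskRegion]:
    """The four curated default masks (GRCh38 coordinates).

    Three interval masks cover homopolymeric G/S and Q repeat tracts and a
    common in-frame deletion, and one whole-gene mask covers a pentameric
    amino-acid repeat gene whose repeat count varies between individuals.
    The TBP interval end is corrected from a typographic truncation in the
    original curation (170561960, not 17561960).
    """
    return [
        MaskRegion("6", 170561916, 170561960, "TBP", "G/S repeat tract"),
        MaskRegion("9", 12775850, 12775885, "LURAP1L", "Q repeat tract"),
        MaskRegion("13", 45596547, 45596602, "ERICH6B", "common in-frame deletion"),
        MaskRegion(None, None, None, "KRTAP4-5", "pentameric AA repeat gene"),
    ]


@dataclass
class FilterFunnel:
    """Ordered per-stage accounting of the filtering cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, before: int, after: int) -> None:
        self.stages.append((name, after, before - after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "remaining", "removed"])

    def validate(self) -> None:
        prev = None
        for name, remaining, removed in self.stages:
            if prev is not None and remaining > prev:
                raise AssertionError(f"funnel stage {name} gained variants")
            if prev is not None and removed != prev - remaining:
                raise AssertionError(f"funnel stage {name} does not conserve counts")
            prev = remaining


def _has_flag(df: pd.DataFrame, flag: str) -> pd.Series:
    return df["flags"].map(lambda fl: flag in fl)


def database_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop variants carrying the CO flag (common in any filtering database).

    CO subsumes G5/DK/EG/EE, so this single flag implements "found in at
    least one of the genomic databases".
    """
    return variants[~_has_flag(variants, "CO")]


def impact_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep only variants of moderate or high predicted impact (I2/I3).

    Variants with no qualifying allele carry no impact flag and are removed:
    their biological effect cannot be evaluated.
    """
    keep = _has_flag(variants, "I2") | _has_flag(variants, "I3")
    return variants[keep]


def mask_filter(variants: pd.DataFrame, regions: list[MaskRegion]) -> pd.DataFrame:
    """Remove variants inside interval masks or annotated to masked genes."""
    drop = pd.Series(False, index=variants.index)
    for region in regions:
        if region.whole_gene:
            if "gene" in variants:
                drop |= variants["gene"] == region.label
        else:
            drop |= (
                (variants["chrom"].astype(str) == str(region.chrom))
                & (variants["pos"] >= region.start)
                & (variants["pos"] <= region.end)
            )
    return variants[~drop]


def germline_aaf_test(
    aafs: np.ndarray | list[float],
    *,
    min_samples: int = 4,
    median_window: tuple[float, float] = (0.40, 0.60),
    bulk_window: tuple[float, float] = (0.30, 0.70),
    bulk_fraction: float = 0.70,
) -> str:
    """Classify a recurrent position from its across-sample allele fractions.

    Positions (or rs-ids) seen in at least ``min_samples`` samples are called
    ``"germline"`` when the allele-fraction distribution is centered on 0.5:
    the median lies in ``median_window`` and at least ``bulk_fraction`` of
    the observations lie in ``bulk_window``.  Anything else — including
    groups too small to evaluate — is ``"not-classified"``.  The rule
    operationalizes the heterozygous-germline signature that tumor-content
    dilution denies to somatic variants.
    """
    values = np.asarray(aafs, dtype=float)
    if len(values) < min_samples:
        return "not-classified"
    med = float(np.median(values))
    lo, hi = bulk_window
    frac = float(np.mean((values >= lo) & (values <= hi)))
    if median_window[0] <= med <= median_window[1] and frac >= bulk_fraction:
        return "germline"
    return "not-classified"


def _group_key(variants: pd.DataFrame) -> pd.Series:
    key = variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
    if "rsid" in variants:
        rs = variants["rsid"]
        key = key.where(rs.isna(), rs.astype("string").astype(object))
    return key


def classify_germline_groups(variants: pd.DataFrame, **params) -> pd.Series:
    """Per-group classification from :func:`germline_aaf_test`.

    Groups are keyed by rs-id when present, otherwise by genomic position.
    Returns a Series indexed by group key.
    """
    key = _group_key(variants)
    return variants.groupby(key)["aaf"].apply(
        lambda v: germline_aaf_test(v.to_numpy(), **params)
    )


def germline_aaf_filter(variants: pd.DataFrame, **params) -> pd.DataFrame:
    """Remove all observations of groups classified as germline."""
    if variants.empty:
        return variants
    classes = classify_germline_groups(variants, **params)
    germline_keys = set(classes[classes == "germline"].index)
    key = _group_key(variants)
    return variants[~key.isin(germline_keys)]


def benign_filter(variants: pd.DataFrame, clinvar: pd.DataFrame) -> pd.DataFrame:
    """Drop rs-ids annotated Benign without any cancer connotation."""
    if variants.empty or clinvar.empty or "rsid" not in variants:
        return variants
    benign = set(
        clinvar[
            (clinvar["significance"] == "Benign") & (~clinvar["cancer_related"])
        ]["rsid"]
    )
    return variants[~variants["rsid"].isin(benign)]


def blocklist_filter(variants: pd.DataFrame, blocklist: set[str]) -> pd.DataFrame:
    """Drop rs-ids on a user-supplied curation blocklist."""
    if not blocklist or "rsid" not in variants:
        return variants
    return variants[~variants["rsid"].isin(blocklist)]


def gene_recurrence_filter(variants: pd.DataFrame, min_samples: int = 5) -> pd.DataFrame:
    """Keep genes mutated in at least ``min_samples`` distinct samples.

    Operates on the surviving (moderate/high-impact) variant set; a gene's
    count is the number of distinct samples with at least one variant.
    """
    if variants.empty:
        return variants
    counts = variants.groupby("gene")["sample_id"].nunique()
    keep = set(counts[counts >= min_samples].index)
    return variants[variants["gene"].isin(keep)]


@dataclass
class FilterConfig:
    """Switches and parameters of the somatic filtering cascade."""

    exclude_lq: bool = True
    technical: bool = True
    database: bool = True
    impact: bool = True
    mask_regions: list[MaskRegion] | None = None
    germline_aaf: bool = True
    germline_params: dict = field(default_factory=dict)
    clinvar: pd.DataFrame | None = None
    blocklist: set[str] = field(default_factory=set)
    min_gene_samples: int | None = 5

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """A configuration under which the funnel is the identity."""
        return cls(
            exclude_lq=False,
            technical=False,
            database=False,
            impact=False,
            mask_regions=None,
            germline_aaf=False,
            clinvar=None,
            blocklist=set(),
            min_gene_samples=None,
        )


def run_funnel(
    variants: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterFunnel]:
    """Run the full filtering cascade on a flagged call table.

    ``variants`` must carry the columns produced by
    :func:`tumoronly.flags.flag_dataframe` (``flags``, ``aaf``,
    ``tech_pass``) plus ``sample_id``/``gene``/``rsid``.  Returns the final
    somatic set and the stage-by-stage funnel.
    """
    cfg = config or FilterConfig()
    funnel = FilterFunnel()
    df = variants
    funnel.stages.append(("input", len(df), 0))

    if cfg.exclude_lq:
        before = len(df)
        df = df[~_has_flag(df, "LQ")]
        funnel.record("site-quality", before, len(df))
    if cfg.technical:
        before = len(df)
        df = df[df["tech_pass"]]
        funnel.record("technical", before, len(df))
    if cfg.database:
        before = len(df)
        df = database_filter(df)
        funnel.record("database", before, len(df))
    if cfg.impact:
        before = len(df)
        df = impact_filter(df)
        funnel.record("impact", before, len(df))
    if cfg.mask_regions:
        before = len(df)
        df = mask_filter(df, cfg.mask_regions)
        funnel.record("mask", before, len(df))
    if cfg.germline_aaf:
        before = len(df)
        df = germline_aaf_filter(df, **cfg.germline_params)
        funnel.record("germline-aaf", before, len(df))
    if cfg.clinvar is not None:
        before = len(df)
        df = benign_filter(df, cfg.clinvar)
        funnel.record("benign", before, len(df))
    if cfg.blocklist:
        before = len(df)
        df = blocklist_filter(df, cfg.blocklist)
        funnel.record("blocklist", before, len(df))
    if cfg.min_gene_samples is not None:
        before = len(df)
        df = gene_recurrence_filter(df, cfg.min_gene_samples)
        funnel.record("gene-recurrence", before, len(df))
    funnel.validate()
    return df, funnel


def germline_recovery_report(
    final: pd.DataFrame, truth_variants: pd.DataFrame
) -> pd.Series:
    """Audit the cascade against generator ground truth.

    Joins on (sample, position, alt) and reports the fraction of
    common-germline variants removed, the somatic fraction of the final set
    (its purity), and somatic sensitivity.
    """
    key = ["sample_id", "chrom", "pos", "alt"]
    truth = truth_variants.set_index(key)["origin"]
    final_idx = pd.MultiIndex.from_frame(final[key])
    final_origins = truth.loc[final_idx]
    n_common = int((truth == "germline-common").sum())
    common_kept = int((final_origins == "germline-common").sum())
    n_somatic = int((truth == "somatic").sum())
    somatic_kept = int((final_origins == "somatic").sum())
    return pd.Series(
        {
            "common_germline_removed": 1.0 - common_kept / max(n_common, 1),
            "final_somatic_purity": somatic_kept / max(len(final_origins), 1),
            "somatic_sensitivity": somatic_kept / max(n_somatic, 1),
            "n_final": len(final_origins),
        }
    )
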