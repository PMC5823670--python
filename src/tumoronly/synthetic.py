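"""Synthetic tumor-only sequencing study with known ground truth.

Generates everything a tumor-only somatic analysis consumes — per-sample
variant calls (VCF-serializable), population allele-frequency tables
emulating 1000 Genomes/dbSNP, a Danish reference panel, and ExAC
(global + European), a ClinVar-like significance table, gene models with a
deterministic codon <-> genomic mapping, and a clinical outcome table — while
recording the origin of every emitted variant (common germline, rare
germline, somatic, or FFPE-like artifact) and the hotspot carrier status of
every patient.  Because the true labels are known, the sensitivity and
specificity of every downstream filtering stage can be audited exactly.

Model choices
-------------
* Germline heterozygous allele fractions are Beta(20, 20): symmetric about
  0.5, the signature the manual germline filter keys on.
* Somatic allele fractions are Beta with mean purity/2 (a diploid
  heterozygous mutation diluted by normal-cell content) and concentration 20.
* Artifacts (FFPE-type damage) have true allele fractions below 0.05.
* Survival follows a proportional-hazards model: an exponential baseline
  hazard multiplied, for carriers of each planted hotspot, by that hotspot's
  hazard ratio; censoring is independent and uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PlantedHotspot",
    "CohortSpec",
    "GeneModels",
    "GroundTruth",
    "SyntheticCohort",
    "generate_gene_models",
    "build_allele_catalog",
    "generate_frequency_db",
    "generate_cohort",
]

_BASES = np.array(list("ACGT"))

#: impact-category probabilities (modifier, low, moderate, high) per origin
IMPACT_PROBS: Mapping[str, tuple[float, float, float, float]] = {
    "germline-common": (0.55, 0.25, 0.17, 0.03),
    "germline-rare": (0.55, 0.25, 0.17, 0.03),
    "somatic": (0.10, 0.15, 0.55, 0.20),
    "artifact": (0.25, 0.25, 0.30, 0.20),
}
_IMPACTS = ("modifier", "low", "moderate", "high")

STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class PlantedHotspot:
    """A recurrent somatic locus planted with a known prognostic effect.

    ``aa_width`` > 1 spreads carrier mutations uniformly over
    ``aa_position .. aa_position + aa_width - 1``, emulating a short spatial
    cluster rather than a single recurrent codon.
    """

    gene: str
    aa_position: int
    prevalence: float
    hazard_ratio: float
    aa_width: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.aa_position < 1 or self.aa_width < 1:
            raise ValueError("aa_position and aa_width must be >= 1")

    @property
    def positions(self) -> range:
        return range(self.aa_position, self.aa_position + self.aa_width)

    @property
    def label(self) -> str:
        if self.aa_width == 1:
            return f"{self.gene}:{self.aa_position}"
        return f"{self.gene}:{self.aa_position}-{self.aa_position + self.aa_width - 1}"


def _default_hotspots() -> tuple[PlantedHotspot, ...]:
    return (
        PlantedHotspot("G001", 10, prevalence=0.15, hazard_ratio=2.5, aa_width=3),
        PlantedHotspot("G002", 25, prevalence=0.10, hazard_ratio=3.0),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the synthetic study.

    Defaults describe a mid-sized colorectal-type cohort: 200 patients,
    stage mix and colon/rectal split matching a stage I-IV surgical cohort,
    tumor purity uniform on [0.3, 0.9] (specimens below 30% tumor nuclei
    would have been excluded), mean high-quality depth 120x, and per-sample
    expected counts of 30 common germline, 3 rare germline and 12 somatic
    variants plus 10 low-fraction artifact calls inside the ~60-gene target
    region.
    """

    n_patients: int = 200
    stage_probs: tuple[float, float, float, float] = (0.08, 0.41, 0.39, 0.12)
    cc_fraction: float = 0.634
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 120.0
    n_genes: int = 60
    germline_common_rate: float = 30.0
    germline_rare_rate: float = 3.0
    somatic_rate: float = 12.0
    hotspots: tuple[PlantedHotspot, ...] = field(default_factory=_default_hotspots)
    noise_rate: float = 10.0
    seed: int = 0

    # sizes of the underlying allele catalogs (shared across samples)
    common_catalog_size: int = 240
    rare_catalog_size: int = 600
    somatic_catalog_size: int = 1800
    #: fraction of common alleles observed in all four populations; the rest
    #: are common in exactly one, creating CO-without-G5 opportunities
    shared_common_fraction: float = 0.7
    #: fraction of common alleles paired with a second alternative allele at
    #: the same position that is common in a *different* population
    multiallelic_fraction: float = 0.05

    # survival model (time unit: months)
    os_baseline_hazard: float = np.log(2) / 60.0
    pfs_baseline_hazard: float = np.log(2) / 48.0
    censor_max: float = 120.0
    died_within_month_prob: float = 0.02
    neoadjuvant_prob: float = 0.015

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be >= 1")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.stage_probs
        ):
            raise ValueError("stage_probs must be a probability vector")
        if not 0 <= self.cc_fraction <= 1:
            raise ValueError("cc_fraction must be in [0, 1]")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        for r in (
            self.germline_common_rate,
            self.germline_rare_rate,
            self.somatic_rate,
            self.noise_rate,
        ):
            if r < 0:
                raise ValueError("rates must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        """Build a spec from plain mappings (e.g. parsed YAML); hotspots may
        be given as lists of mappings, interval fields as 2-lists."""
        data = dict(data)
        if "hotspots" in data:
            data["hotspots"] = tuple(
                h if isinstance(h, PlantedHotspot) else PlantedHotspot(**h)
                for h in data["hotspots"]
            )
        for key in ("stage_probs", "purity_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class GeneModels:
    """Canonical-transcript gene models with codon <-> genomic mapping.

    Backed by an exon table with columns ``gene, transcript, chrom, strand,
    exon_rank, n_exons, start, end`` (1-based, inclusive; ``exon_rank`` in
    transcription order).  The coding frame runs across exons in
    transcription order, so amino-acid position ``a`` covers coding offsets
    ``3(a-1) .. 3a-1``.
    """

    def __init__(self, exons: pd.DataFrame):
        required = {"gene", "chrom", "strand", "exon_rank", "n_exons", "start", "end"}
        missing = required - set(exons.columns)
        if missing:
            raise ValueError(f"exon table lacks columns: {sorted(missing)}")
        self.exons = exons.sort_values(["gene", "exon_rank"]).reset_index(drop=True)
        self._by_gene = {g: sub for g, sub in self.exons.groupby("gene")}

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def _gene(self, gene: str) -> pd.DataFrame:
        try:
            return self._by_gene[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in gene models") from None

    def coding_length(self, gene: str) -> int:
        sub = self._gene(gene)
        return int((sub["end"] - sub["start"] + 1).sum())

    def n_codons(self, gene: str) -> int:
        return self.coding_length(gene) // 3

    def n_exons(self, gene: str) -> int:
        return int(self._gene(gene)["n_exons"].iloc[0])

    def chrom(self, gene: str) -> str:
        return self._gene(gene)["chrom"].iloc[0]

    def _cum_lengths(self, gene: str) -> np.ndarray:
        sub = self._gene(gene)
        lens = (sub["end"] - sub["start"] + 1).to_numpy()
        return np.concatenate([[0], np.cumsum(lens)])

    def aa_to_exon(self, gene: str, aa_pos: int) -> int:
        """Exon rank (1-based) containing the first base of codon ``aa_pos``."""
        offset = 3 * (aa_pos - 1)
        cum = self._cum_lengths(gene)
        if not 0 <= offset < cum[-1]:
            raise ValueError(f"amino acid {aa_pos} outside {gene}")
        return int(np.searchsorted(cum, offset, side="right"))

    def coding_offset_to_genomic(self, gene: str, offset: int) -> tuple[str, int]:
        """Genomic coordinate of 0-based coding offset ``offset``."""
        sub = self._gene(gene)
        cum = self._cum_lengths(gene)
        if not 0 <= offset < cum[-1]:
            raise ValueError(f"coding offset {offset} outside {gene}")
        rank = int(np.searchsorted(cum, offset, side="right"))
        row = sub.iloc[rank - 1]
        within = offset - cum[rank - 1]
        if row["strand"] == "+":
            pos = int(row["start"]) + within
        else:
            pos = int(row["end"]) - within
        return row["chrom"], pos

    def aa_to_genomic(self, gene: str, aa_pos: int, codon_offset: int = 0) -> tuple[str, int]:
        if not 0 <= codon_offset <= 2:
            raise ValueError("codon_offset must be 0, 1 or 2")
        return self.coding_offset_to_genomic(gene, 3 * (aa_pos - 1) + codon_offset)

    def genomic_to_aa(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene, amino-acid position) at a genomic coordinate, or None."""
        hit = self.exons[
            (self.exons["chrom"] == chrom)
            & (self.exons["start"] <= pos)
            & (self.exons["end"] >= pos)
        ]
        if hit.empty:
            return None
        row = hit.iloc[0]
        gene = row["gene"]
        cum = self._cum_lengths(gene)
        if row["strand"] == "+":
            within = pos - int(row["start"])
        else:
            within = int(row["end"]) - pos
        offset = cum[int(row["exon_rank"]) - 1] + within
        return gene, int(offset) // 3 + 1

    def lengths(self) -> pd.Series:
        """Total coding length (nt) per gene."""
        lens = (self.exons["end"] - self.exons["start"] + 1).groupby(
            self.exons["gene"]
        ).sum()
        lens.name = "coding_length"
        return lens

    def to_bed(self) -> pd.DataFrame:
        """Exon intervals as 0-based half-open BED records."""
        bed = pd.DataFrame(
            {
                "chrom": self.exons["chrom"],
                "start": self.exons["start"] - 1,
                "end": self.exons["end"],
                "name": self.exons["gene"]
                + "_exon"
                + self.exons["exon_rank"].astype(str),
                "score": 0,
                "strand": self.exons["strand"],
            }
        )
        return bed


def _rng(stage: int, spec: CohortSpec) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([stage, spec.seed])


def generate_gene_models(spec: CohortSpec) -> GeneModels:
    """Draw ``spec.n_genes`` canonical-transcript gene models.

    Genes are laid out on chromosomes chr1..chr22 with generous spacing;
    exon counts are 1 + Poisson(3), exon lengths are multiples of 3 between
    60 and 600 nt, and strand is random.  The same spec (including seed)
    always yields byte-identical models.
    """
    rng = _rng(1, spec)
    rows = []
    cursor: dict[str, int] = {}
    for gi in range(spec.n_genes):
        gene = f"G{gi + 1:03d}"
        chrom = f"chr{gi % 22 + 1}"
        n_ex = 1 + int(rng.poisson(3))
        ex_lens = 3 * rng.integers(20, 201, size=n_ex)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor.get(chrom, 10_000) + int(rng.integers(5_000, 20_000))
        genomic_exons = []
        pos = start
        for length in ex_lens:
            genomic_exons.append((pos, pos + int(length) - 1))
            pos = pos + int(length) + int(rng.integers(500, 5_000))
        cursor[chrom] = pos
        # transcription order: genomic order on +, reversed on -
        ordered = genomic_exons if strand == "+" else genomic_exons[::-1]
        for rank, (s, e) in enumerate(ordered, start=1):
            rows.append(
                {
                    "gene": gene,
                    "transcript": f"{gene}.t1",
                    "chrom": chrom,
                    "strand": strand,
                    "exon_rank": rank,
                    "n_exons": n_ex,
                    "start": s,
                    "end": e,
                }
            )
    return GeneModels(pd.DataFrame(rows))


def _draw_allele(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _random_coding_site(
    rng: np.random.Generator, models: GeneModels, lengths: pd.Series
) -> tuple[str, str, int, int]:
    """(gene, chrom, genomic pos, aa position) uniform over coding bases."""
    genes = lengths.index.to_numpy()
    weights = lengths.to_numpy() / lengths.sum()
    gene = str(rng.choice(genes, p=weights))
    offset = int(rng.integers(0, lengths[gene]))
    chrom, pos = models.coding_offset_to_genomic(gene, offset)
    return gene, chrom, pos, offset // 3 + 1


def build_allele_catalog(spec: CohortSpec, models: GeneModels | None = None) -> pd.DataFrame:
    """The shared catalog of alleles samples draw from.

    Columns: ``chrom, pos, ref, alt, gene, aa_pos, kind, rsid, impact,
    multi_group, pop_pattern`` where ``kind`` is one of ``germline-common``,
    ``germline-rare``, ``somatic`` or ``hotspot``; ``pop_pattern`` lists the
    populations the allele is common in (germline-common only) and
    ``multi_group`` links alternative alleles sharing a position.
    """
    if models is None:
        models = generate_gene_models(spec)
    rng = _rng(2, spec)
    lengths = models.lengths()
    rows = []
    used: set[tuple[str, int]] = set()
    for h in spec.hotspots:
        if h.gene not in models:
            raise ValueError(f"hotspot gene {h.gene!r} not in gene models")
        if h.positions[-1] > models.n_codons(h.gene):
            raise ValueError(
                f"hotspot {h.label} beyond {h.gene} "
                f"({models.n_codons(h.gene)} codons)"
            )
    hotspot_sites = {
        models.aa_to_genomic(h.gene, p, codon_offset=off)
        for h in spec.hotspots
        for p in h.positions
        for off in (0, 1, 2)
    }

    def fresh_site() -> tuple[str, str, int, int]:
        while True:
            gene, chrom, pos, aa = _random_coding_site(rng, models, lengths)
            if (chrom, pos) not in used and (chrom, pos) not in hotspot_sites:
                used.add((chrom, pos))
                return gene, chrom, pos, aa

    def impact_for(kind: str) -> str:
        return str(rng.choice(_IMPACTS, p=IMPACT_PROBS[kind]))

    rsid_counter = 1
    group_counter = 0
    for _ in range(spec.common_catalog_size):
        gene, chrom, pos, aa = fresh_site()
        ref, alt = _draw_allele(rng)
        if rng.random() < spec.shared_common_fraction:
            pattern = ",".join(("kg", "danish", "exac", "exac_eur"))
        else:
            pattern = str(rng.choice(["kg", "danish", "exac", "exac_eur"]))
        multi = -1
        if rng.random() < spec.multiallelic_fraction:
            multi = group_counter
            group_counter += 1
        rows.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, aa_pos=aa,
                kind="germline-common", rsid=f"rs{rsid_counter:07d}",
                impact=impact_for("germline-common"), multi_group=multi,
                pop_pattern=pattern,
            )
        )
        rsid_counter += 1
        if multi >= 0:
            # partner allele at the same position, common in one other source
            others = [p for p in ("kg", "danish", "exac", "exac_eur") if p != pattern]
            partner_pop = str(rng.choice(others)) if pattern in (
                "kg", "danish", "exac", "exac_eur"
            ) else str(rng.choice(["kg", "danish", "exac", "exac_eur"]))
            alt2 = str(rng.choice([b for b in "ACGT" if b not in (ref, alt)]))
            rows.append(
                dict(
                    chrom=chrom, pos=pos, ref=ref, alt=alt2, gene=gene, aa_pos=aa,
                    kind="germline-common", rsid=f"rs{rsid_counter:07d}",
                    impact=impact_for("germline-common"), multi_group=multi,
                    pop_pattern=partner_pop,
                )
            )
            rsid_counter += 1
    for _ in range(spec.rare_catalog_size):
        gene, chrom, pos, aa = fresh_site()
        ref, alt = _draw_allele(rng)
        rows.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, aa_pos=aa,
                kind="germline-rare", rsid=f"rs{rsid_counter:07d}",
                impact=impact_for("germline-rare"), multi_group=-1, pop_pattern="",
            )
        )
        rsid_counter += 1
    for _ in range(spec.somatic_catalog_size):
        gene, chrom, pos, aa = fresh_site()
        ref, alt = _draw_allele(rng)
        rows.append(
            dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, aa_pos=aa,
                kind="somatic", rsid=None,
                impact=impact_for("somatic"), multi_group=-1, pop_pattern="",
            )
        )
    for h in spec.hotspots:
        for aa in h.positions:
            chrom, pos = models.aa_to_genomic(h.gene, aa, codon_offset=1)
            ref, alt = _draw_allele(rng)
            rows.append(
                dict(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=h.gene, aa_pos=aa,
                    kind="hotspot", rsid=None,
                    impact="moderate" if rng.random() < 0.7 else "high",
                    multi_group=-1, pop_pattern="",
                )
            )
    cat = pd.DataFrame(rows)
    cat.index.name = "allele_id"
    return cat.reset_index()


def generate_frequency_db(
    spec: CohortSpec,
    models: GeneModels | None = None,
    catalog: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Population allele-frequency tables for the four filtering sources.

    Keys ``kg`` (1000 Genomes-like), ``danish``, ``exac``, ``exac_eur``;
    each table has columns ``chrom, pos, ref, alt, af``.  Common germline
    alleles receive AF >= 0.05 in every population of their pattern; rare
    germline alleles appear (when present at all) with AF < 0.05; somatic
    and hotspot alleles are absent from all four tables.
    """
    if catalog is None:
        catalog = build_allele_catalog(spec, models)
    rng = _rng(3, spec)
    tables: dict[str, list[dict]] = {p: [] for p in ("kg", "danish", "exac", "exac_eur")}
    for _, row in catalog.iterrows():
        if row["kind"] == "germline-common":
            pops = row["pop_pattern"].split(",")
            for pop in ("kg", "danish", "exac", "exac_eur"):
                if pop in pops:
                    af = float(rng.uniform(0.05, 0.5))
                elif rng.random() < 0.5:
                    af = float(rng.uniform(0.001, 0.049))
                else:
                    continue
                tables[pop].append(
                    dict(chrom=row["chrom"], pos=row["pos"], ref=row["ref"],
                         alt=row["alt"], af=af)
                )
        elif row["kind"] == "germline-rare":
            for pop in ("kg", "danish", "exac", "exac_eur"):
                if rng.random() < 0.4:
                    tables[pop].append(
                        dict(chrom=row["chrom"], pos=row["pos"], ref=row["ref"],
                             alt=row["alt"], af=float(rng.uniform(0.0001, 0.049)))
                    )
    return {
        pop: pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])
        for pop, rows in tables.items()
    }


def generate_clinvar_table(spec: CohortSpec, catalog: pd.DataFrame) -> pd.DataFrame:
    """ClinVar-like significance table keyed by rs-id.

    About a quarter of cataloged germline rs-ids are annotated Benign; a
    small minority of those carry a cancer connotation (and are therefore
    protected from the benign filter).
    """
    rng = _rng(5, spec)
    rows = []
    for _, row in catalog.iterrows():
        if row["rsid"] is None or pd.isna(row["rsid"]):
            continue
        if rng.random() < 0.25:
            rows.append(
                dict(
                    rsid=row["rsid"],
                    significance="Benign",
                    cancer_related=bool(rng.random() < 0.15),
                )
            )
    return pd.DataFrame(rows, columns=["rsid", "significance", "cancer_related"])


@dataclass
class GroundTruth:
    """True origin of every emitted variant and hotspot carrier status."""

    #: one row per emitted call row: sample_id, chrom, pos, alt, gene, aa_pos, origin
    variants: pd.DataFrame
    #: patients x hotspot-label boolean carrier matrix
    carriers: pd.DataFrame
    #: realized draw counts per origin label
    origin_counts: pd.Series

    def __post_init__(self) -> None:
        emitted = self.variants["origin"].value_counts()
        if not emitted.sort_index().equals(self.origin_counts.sort_index()):
            raise AssertionError("origin label bookkeeping out of sync")


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    gene_models: GeneModels
    freq_db: dict[str, pd.DataFrame]
    catalog: pd.DataFrame
    calls: pd.DataFrame
    clinical: pd.DataFrame
    clinvar: pd.DataFrame
    truth: GroundTruth


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1 - mean) * concentration


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate the full study: variants, outcomes, and ground truth.

    The emitted call table is long-format (one row per sample/position/alt)
    with columns ``sample_id, chrom, pos, ref, alt, gene, aa_pos, qual,
    hq_depth, alt_count, rsid, impact``; allele fractions follow the origin
    models described in the module docstring.  Survival times follow the
    proportional-hazards generator; OS and PFS events are censored
    independently.
    """
    models = generate_gene_models(spec)
    catalog = build_allele_catalog(spec, models)
    freq_db = generate_frequency_db(spec, models, catalog)
    clinvar = generate_clinvar_table(spec, catalog)
    rng = _rng(4, spec)

    by_kind = {k: sub for k, sub in catalog.groupby("kind")}
    multi_partner: dict[int, list[int]] = {}
    common = by_kind.get("germline-common", pd.DataFrame())
    if len(common):
        for gid, sub in common[common["multi_group"] >= 0].groupby("multi_group"):
            multi_partner[int(gid)] = list(sub.index)

    hotspot_alleles: dict[str, pd.DataFrame] = {}
    hs_cat = by_kind.get("hotspot", pd.DataFrame())
    for h in spec.hotspots:
        sel = hs_cat[(hs_cat["gene"] == h.gene) & hs_cat["aa_pos"].isin(list(h.positions))]
        hotspot_alleles[h.label] = sel

    call_rows: list[dict] = []
    truth_rows: list[dict] = []
    carrier_rows: list[dict] = []
    clinical_rows: list[dict] = []
    origin_counts: dict[str, int] = {}

    def emit(sample: str, allele: Mapping, origin: str, p_true: float, qual: float,
             depth: int, alt_count: int) -> None:
        call_rows.append(
            dict(
                sample_id=sample, chrom=allele["chrom"], pos=int(allele["pos"]),
                ref=allele["ref"], alt=allele["alt"], gene=allele["gene"],
                aa_pos=int(allele["aa_pos"]), qual=round(float(qual), 1),
                hq_depth=int(depth), alt_count=int(alt_count),
                rsid=allele["rsid"], impact=allele["impact"],
            )
        )
        truth_rows.append(
            dict(
                sample_id=sample, chrom=allele["chrom"], pos=int(allele["pos"]),
                alt=allele["alt"], gene=allele["gene"], aa_pos=int(allele["aa_pos"]),
                origin=origin, true_fraction=p_true,
            )
        )
        origin_counts[origin] = origin_counts.get(origin, 0) + 1

    def depth_and_qual(artifact: bool = False) -> tuple[int, float]:
        depth = max(1, int(rng.poisson(spec.depth_mean)))
        if artifact:
            qual = float(rng.gamma(3.0, 8.0))
        else:
            qual = float(rng.gamma(6.0, 10.0))
        return depth, qual

    lengths = models.lengths()

    for i in range(spec.n_patients):
        sample = f"P{i + 1:04d}"
        purity = float(rng.uniform(*spec.purity_range))
        stage = str(rng.choice(STAGES, p=spec.stage_probs))
        ctype = "CC" if rng.random() < spec.cc_fraction else "RC"

        # --- germline variants (common then rare) --------------------------
        for kind, rate, label in (
            ("germline-common", spec.germline_common_rate, "germline-common"),
            ("germline-rare", spec.germline_rare_rate, "germline-rare"),
        ):
            pool = by_kind.get(kind)
            if pool is None or not len(pool):
                continue
            n = min(int(rng.poisson(rate)), len(pool))
            chosen = rng.choice(pool.index.to_numpy(), size=n, replace=False)
            seen_groups: set[int] = set()
            for idx in chosen:
                allele = pool.loc[idx]
                gid = int(allele.get("multi_group", -1))
                if gid >= 0:
                    if gid in seen_groups:
                        continue
                    seen_groups.add(gid)
                    # emit both alleles of the multi-allelic pair sharing
                    # one depth/qual draw: two het alleles on the two
                    # haplotypes, fractions from a flat Dirichlet
                    depth, qual = depth_and_qual()
                    fracs = rng.dirichlet((12.0, 12.0, 12.0))
                    members = multi_partner[gid]
                    counts = rng.multinomial(depth, [fracs[0], fracs[1],
                                                     1 - fracs[0] - fracs[1]])
                    for j, member in enumerate(members[:2]):
                        emit(sample, pool.loc[member], label, float(fracs[j]),
                             qual, depth, counts[j])
                    continue
                p = float(rng.beta(20, 20))
                depth, qual = depth_and_qual()
                alt_count = int(rng.binomial(depth, p))
                emit(sample, allele, label, p, qual, depth, alt_count)

        # --- somatic background -------------------------------------------
        pool = by_kind.get("somatic")
        if pool is not None and len(pool):
            n = min(int(rng.poisson(spec.somatic_rate)), len(pool))
            chosen = rng.choice(pool.index.to_numpy(), size=n, replace=False)
            a, b = _beta_params(purity / 2.0, 20.0)
            for idx in chosen:
                p = float(rng.beta(a, b))
                depth, qual = depth_and_qual()
                alt_count = int(rng.binomial(depth, p))
                emit(sample, pool.loc[idx], "somatic", p, qual, depth, alt_count)

        # --- planted hotspots ---------------------------------------------
        carrier_status = {}
        for h in spec.hotspots:
            carrier = bool(rng.random() < h.prevalence)
            carrier_status[h.label] = carrier
            if not carrier:
                continue
            options = hotspot_alleles[h.label]
            allele = options.loc[rng.choice(options.index.to_numpy())]
            a, b = _beta_params(purity / 2.0, 20.0)
            p = float(rng.beta(a, b))
            depth, qual = depth_and_qual()
            alt_count = int(rng.binomial(depth, p))
            emit(sample, allele, "somatic", p, qual, depth, alt_count)
        carrier_rows.append(dict(patient_id=sample, **carrier_status))

        # --- FFPE-like artifacts (fresh random sites, low fraction) --------
        n_art = int(rng.poisson(spec.noise_rate))
        for _ in range(n_art):
            gene, chrom, pos, aa = _random_coding_site(rng, models, lengths)
            ref, alt = _draw_allele(rng)
            impact = str(rng.choice(_IMPACTS, p=IMPACT_PROBS["artifact"]))
            allele = dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                          aa_pos=aa, rsid=None, impact=impact)
            p = float(rng.uniform(0.005, 0.045))
            depth, qual = depth_and_qual(artifact=True)
            alt_count = int(rng.binomial(depth, p))
            emit(sample, allele, "artifact", p, qual, depth, alt_count)

        # --- outcomes ------------------------------------------------------
        hr = 1.0
        for h in spec.hotspots:
            if carrier_status[h.label]:
                hr *= h.hazard_ratio
        t_os = float(rng.exponential(1.0 / (spec.os_baseline_hazard * hr)))
        c_os = float(rng.uniform(0, spec.censor_max))
        t_pfs = float(rng.exponential(1.0 / (spec.pfs_baseline_hazard * hr)))
        c_pfs = float(rng.uniform(0, spec.censor_max))
        clinical_rows.append(
            dict(
                patient_id=sample,
                cancer_type=ctype,
                stage=stage,
                purity=round(purity, 3),
                os_time=round(max(min(t_os, c_os), 0.01), 2),
                os_event=int(t_os <= c_os),
                pfs_time=round(max(min(t_pfs, c_pfs), 0.01), 2),
                pfs_event=int(t_pfs <= c_pfs),
                died_within_month=bool(rng.random() < spec.died_within_month_prob),
                neoadjuvant=bool(rng.random() < spec.neoadjuvant_prob),
            )
        )

    calls = pd.DataFrame(call_rows)
    clinical = pd.DataFrame(clinical_rows)
    truth = GroundTruth(
        variants=pd.DataFrame(truth_rows),
        carriers=pd.DataFrame(carrier_rows).set_index("patient_id"),
        origin_counts=pd.Series(origin_counts, dtype=int),
    )
    counts = ", ".join(f"{k}={v}" for k, v in sorted(origin_counts.items()))
    logging.getLogger(__name__).info("generated cohort: %s", counts)
    return SyntheticCohort(
        spec=spec,
        gene_models=models,
        freq_db=freq_db,
        catalog=catalog,
        calls=calls,
        clinical=clinical,
        clinvar=clinvar,
        truth=truth,
    )
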