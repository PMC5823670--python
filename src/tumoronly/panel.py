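"""Gene-panel construction from feature-membership evidence.

A core panel is scored by summing a gene's memberships across a set of
curated evidence features (mutation-frequency lists, database annotations,
known disease associations), with ties broken by the gene's COSMIC-style
colorectal mutation frequency.  The core is then extended with genes from
text-mining co-occurrence (Fisher's exact test on abstract counts), pathway
membership, drug-target lists, a top-k length-normalized mutation ranking
from an external tumor cohort, and hand-picked genes — with an
interaction-network filter keeping only genes plausibly connected to the
most mutated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelGene",
    "normalize_gene_names",
    "score_genes",
    "select_core_panel",
    "fisher_cooccurrence",
    "network_filter",
    "tcga_top_genes",
    "merge_panel",
]


@dataclass
class PanelGene:
    """A panel member with its score and inclusion evidence."""

    gene: str
    score: int
    provenance: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be nonempty")


def normalize_gene_names(
    genes: Iterable[str], synonym_map: Mapping[str, str] | None = None
) -> list[str]:
    """Map gene identifiers to canonical symbols via a synonym table.

    Synonym keys are matched case-insensitively; unmapped names are
    upper-cased.  Raises when two input names collapse onto the same
    canonical symbol (the caller's lists disagree about identity).
    """
    lookup = {k.upper(): v for k, v in (synonym_map or {}).items()}
    out: list[str] = []
    seen: dict[str, str] = {}
    for g in genes:
        canon = lookup.get(g.upper(), g.upper())
        if canon in seen and seen[canon] != g:
            raise ValueError(
                f"gene identifiers {seen[canon]!r} and {g!r} both normalize "
                f"to {canon!r}"
            )
        seen[canon] = g
        out.append(canon)
    return out


def score_genes(
    feature_matrix: pd.DataFrame, cosmic_freq: pd.Series | None = None
) -> pd.DataFrame:
    """Rank genes by the number of evidence features containing them.

    ``feature_matrix`` is a gene x feature 0/1 membership table; the score
    is the row sum.  Ranking is by descending score, ties resolved by the
    highest COSMIC colorectal mutation frequency, residual ties
    alphabetically.  Column order of the matrix never affects the result.
    """
    if not feature_matrix.isin([0, 1]).all().all():
        raise ValueError("feature matrix must contain only 0/1 indicators")
    scores = feature_matrix.sum(axis=1).astype(int)
    freq = (
        cosmic_freq.reindex(feature_matrix.index).fillna(0.0)
        if cosmic_freq is not None
        else pd.Series(0.0, index=feature_matrix.index)
    )
    out = pd.DataFrame(
        {"gene": feature_matrix.index, "score": scores.to_numpy(),
         "cosmic_freq": freq.to_numpy()}
    )
    return (
        out.sort_values(["score", "cosmic_freq", "gene"],
                        ascending=[False, False, True])
        .reset_index(drop=True)
    )


def select_core_panel(
    ranked: pd.DataFrame, min_score: int = 1, freq_threshold: float = 7.0
) -> list[PanelGene]:
    """Core panel: positively scored genes plus high-frequency add-ins.

    Takes genes with score >= ``min_score`` (tagged ``core-score``) and, in
    addition, genes whose COSMIC colorectal mutation frequency is strictly
    greater than ``freq_threshold`` percent (tagged ``freq-addin``).
    """
    members: dict[str, PanelGene] = {}
    for _, row in ranked.iterrows():
        tags = set()
        if row["score"] >= min_score:
            tags.add("core-score")
        if row["cosmic_freq"] > freq_threshold:
            tags.add("freq-addin")
        if tags:
            members[row["gene"]] = PanelGene(row["gene"], int(row["score"]), tags)
    return list(members.values())


def fisher_cooccurrence(
    n_both: int,
    n_gene_only: int,
    n_disease_only: int,
    n_neither: int,
    bonferroni_alpha: float = 5e-7,
) -> tuple[float, bool]:
    """One-sided enrichment test for gene/disease co-mention in abstracts.

    The 2x2 table counts abstracts mentioning both the gene and the disease,
    only one, or neither; the p-value is the upper hypergeometric tail
    (Fisher's exact test, enrichment alternative).  Significance is strict:
    ``p < bonferroni_alpha``, with the default threshold already
    Bonferroni-scaled for a genome-wide screen.
    """
    table = np.array([[n_both, n_gene_only], [n_disease_only, n_neither]])
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return p, bool(p < bonferroni_alpha)


def network_filter(
    candidate_genes: Iterable[str],
    interactions: pd.DataFrame,
    anchor_set: Iterable[str],
    min_fraction: float = 0.10,
) -> list[str]:
    """Keep genes connected to the most-mutated genes in a protein network.

    ``interactions`` has columns ``gene_a, gene_b, high_confidence``; only
    high-confidence edges count.  A candidate is retained if it belongs to
    ``anchor_set`` (the top mutated genes), or if at least ``min_fraction``
    (inclusive) of its high-confidence interactors are anchors.  Genes with
    no high-confidence interactors fail the fraction branch.
    """
    anchors = set(anchor_set)
    hc = interactions[interactions["high_confidence"].astype(bool)]
    neighbors: dict[str, set[str]] = {}
    for a, b in zip(hc["gene_a"], hc["gene_b"]):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    kept = []
    for gene in candidate_genes:
        if gene in anchors:
            kept.append(gene)
            continue
        inter = neighbors.get(gene, set())
        if inter and len(inter & anchors) / len(inter) >= min_fraction:
            kept.append(gene)
    return kept


def tcga_top_genes(
    mutation_table: pd.DataFrame,
    gene_lengths: pd.Series,
    k: int = 50,
    discard_impacts: tuple[str, ...] = ("modifier", "low"),
) -> list[str]:
    """Top-k genes by length-normalized mutation rate in an external cohort.

    ``mutation_table`` has one row per mutation with ``gene`` and ``impact``
    columns; low-impact records are discarded before counting.  Rate =
    count / gene length; ties broken by raw count, then alphabetically.
    """
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    kept = mutation_table[~mutation_table["impact"].isin(discard_impacts)]
    if kept.empty:
        return []
    counts = kept.groupby("gene").size()
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise KeyError(f"no length for genes: {missing}")
    rates = counts / lengths
    order = pd.DataFrame(
        {"gene": counts.index, "rate": rates.to_numpy(), "count": counts.to_numpy()}
    ).sort_values(["rate", "count", "gene"], ascending=[False, False, True])
    return list(order["gene"].head(k))


def merge_panel(
    core: list[PanelGene],
    extensions: Mapping[str, Iterable[str]] | None = None,
    handpicked: Iterable[str] = (),
    synonym_map: Mapping[str, str] | None = None,
) -> list[PanelGene]:
    """Union the core panel with tagged extension lists.

    ``extensions`` maps a provenance tag (``textmining``, ``pathway``,
    ``drugtarget``, ``tcga`` ...) to a gene list; ``handpicked`` genes are
    always retained under the ``handpicked`` tag.  Gene names are normalized
    before merging, provenance accumulates across sources, and the result is
    ordered by descending score then gene name — so merging is idempotent
    and independent of extension order.
    """
    panel: dict[str, PanelGene] = {}

    def add(gene: str, score: int, tags: set[str]) -> None:
        canon = normalize_gene_names([gene], synonym_map)[0]
        if canon in panel:
            panel[canon].provenance |= tags
            panel[canon].score = max(panel[canon].score, score)
        else:
            panel[canon] = PanelGene(canon, score, set(tags))

    for pg in core:
        add(pg.gene, pg.score, set(pg.provenance))
    for tag, genes in (extensions or {}).items():
        for gene in genes:
            add(gene, 0, {tag})
    for gene in handpicked:
        add(gene, 0, {"handpicked"})
    return sorted(panel.values(), key=lambda p: (-p.score, p.gene))
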