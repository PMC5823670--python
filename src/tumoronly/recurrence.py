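"""Mutation recurrence statistics: genes, exons, and amino-acid positions.

All counts are *distinct-sample* counts: a sample contributes at most once
per gene (or exon, or codon) however many variants it carries there.
Percentages are rounded half-up to one decimal, matching how recurrence
tables are conventionally printed.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .synthetic import GeneModels

__all__ = [
    "percent_of_gene",
    "mutation_matrix",
    "gene_counts",
    "weighted_frequency",
    "exon_burden",
    "position_burden",
]


def percent_of_gene(n_locus: int, n_gene: int) -> float:
    """Share (%) of a gene's mutated samples hitting one locus, 1 decimal.

    Rounds half-up (97.85 -> 97.9), not banker's rounding.
    """
    if n_gene <= 0:
        raise ValueError("n_gene must be > 0")
    if not 0 <= n_locus <= n_gene:
        raise ValueError("need 0 <= n_locus <= n_gene")
    pct = Decimal(100 * n_locus) / Decimal(n_gene)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _round1(x: float) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def mutation_matrix(
    variants: pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Gene x sample 0/1 indicator matrix from a variant table.

    ``samples`` fixes the column set (samples with no surviving variant
    still get a column of zeros); by default columns are the samples present
    in ``variants``.
    """
    if variants.empty:
        cols = samples or []
        return pd.DataFrame(0, index=pd.Index([], name="gene"), columns=cols)
    mat = (
        variants.assign(one=1)
        .pivot_table(index="gene", columns="sample_id", values="one", aggfunc="max")
        .fillna(0)
        .astype(int)
    )
    if samples is not None:
        mat = mat.reindex(columns=samples, fill_value=0)
    mat.index.name = "gene"
    return mat


def gene_counts(matrix: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Ranked per-gene mutated-sample counts and frequencies.

    Frequency is ``100 * count / n_samples`` (the number of analyzed
    samples, passed explicitly).  Sorted by descending count, ties broken
    alphabetically; genes with zero mutated samples are excluded.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    counts = matrix.sum(axis=1)
    counts = counts[counts > 0]
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "sample_count": counts.to_numpy(),
            "sample_freq_pct": [
                _round1(100.0 * c / n_samples) for c in counts.to_numpy()
            ],
        }
    )
    return (
        out.sort_values(["sample_count", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def weighted_frequency(
    matrix: pd.DataFrame,
    lengths: pd.Series,
    n_samples: int,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Length-corrected mutation frequency per gene.

    Long genes accumulate mutations by chance alone, so raw counts are
    normalized:

        weighted = scale * count / (length_kb) / n_samples

    with ``lengths`` the targeted coding length in nucleotides.  The scale
    in use is recorded in the ``scale`` column attribute of the result so
    that downstream output states its own units.  At fixed count the value
    is strictly decreasing in length.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    counts = matrix.sum(axis=1)
    genes = counts.index
    kb = lengths.reindex(genes) / 1000.0
    weighted = scale * counts / kb / n_samples
    out = pd.DataFrame(
        {"gene": genes, "weighted_frequency": weighted.to_numpy()}
    ).sort_values(["weighted_frequency", "gene"], ascending=[False, True])
    out.attrs["formula"] = (
        f"weighted = {scale} * mutated_sample_count / coding_length_kb / n_samples"
    )
    return out.reset_index(drop=True)


def exon_burden(variants: pd.DataFrame, models: GeneModels) -> pd.DataFrame:
    """Distinct samples mutated per exon of each gene's canonical transcript.

    Exon ranks are reported in transcription order as ``"k/total"``.
    Variants whose position maps into no exon of their annotated gene signal
    an annotation mismatch.
    """
    if variants.empty:
        return pd.DataFrame(columns=["gene", "exon_rank", "sample_count"])
    rows = []
    for (gene, aa), sub in variants.groupby(["gene", "aa_pos"]):
        rank = models.aa_to_exon(gene, int(aa))
        rows.append((gene, rank, set(sub["sample_id"])))
    agg: dict[tuple[str, int], set] = {}
    for gene, rank, sample_set in rows:
        agg.setdefault((gene, rank), set()).update(sample_set)
    out = pd.DataFrame(
        {
            "gene": [g for g, _ in agg],
            "exon_rank": [f"{r}/{models.n_exons(g)}" for g, r in agg],
            "sample_count": [len(s) for s in agg.values()],
        }
    )
    return (
        out.sort_values(["sample_count", "gene", "exon_rank"],
                        ascending=[False, True, True])
        .reset_index(drop=True)
    )


def position_burden(
    variants: pd.DataFrame, models: GeneModels | None = None
) -> pd.DataFrame:
    """Distinct samples mutated per amino-acid position (hotspot table).

    ``pct_of_gene`` is the share of the gene's mutated samples hitting the
    position, via :func:`percent_of_gene`.
    """
    if variants.empty:
        return pd.DataFrame(
            columns=["gene", "aa_pos", "sample_count", "pct_of_gene"]
        )
    per_gene = variants.groupby("gene")["sample_id"].nunique()
    counts = variants.groupby(["gene", "aa_pos"])["sample_id"].nunique()
    out = counts.reset_index().rename(columns={"sample_id": "sample_count"})
    out["pct_of_gene"] = [
        percent_of_gene(int(c), int(per_gene[g]))
        for g, c in zip(out["gene"], out["sample_count"])
    ]
    return (
        out.sort_values(["sample_count", "gene", "aa_pos"],
                        ascending=[False, True, True])
        .reset_index(drop=True)
    )
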