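"""Spatial clustering of mutations along protein coordinates.

Recurrently mutated codons are grouped into contiguous amino-acid intervals
(seed positions extended across small gaps), scored by the fraction of the
gene's mutations they capture, and tested against a background model in
which the same number of mutations is placed at random positions — uniform
over the coding sequence, or drawn from observed silent-mutation positions
when those are available (silent changes being the best available readout of
a gene's baseline mutability).  The resulting per-patient cluster-membership
indicators are the covariates of the downstream survival models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterParams",
    "find_clusters",
    "clusters_to_frame",
    "cluster_covariates",
]


@dataclass(frozen=True)
class Cluster:
    """A gene-anchored amino-acid interval with its mutation burden."""

    gene: str
    aa_start: int
    aa_end: int
    sample_count: int
    score: float
    zscore: float
    p_value: float

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ValueError("aa_start must be <= aa_end")
        if self.sample_count < 1:
            raise ValueError("sample_count must be >= 1")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must be in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.aa_start}:{self.aa_end}"

    def contains(self, aa_pos: int) -> bool:
        return self.aa_start <= aa_pos <= self.aa_end


@dataclass(frozen=True)
class ClusterParams:
    """Tuning of the seed/extend/score procedure.

    ``seed_min_samples``: mutated-sample count a codon needs to seed a
    cluster.  ``max_gap``: largest codon gap bridged while extending a seed.
    ``min_cluster_fraction``: minimum score for a cluster to be reported.
    ``background_source``: ``"synonymous"`` uses supplied silent-mutation
    positions for the background placement (falling back to uniform per gene
    when none exist); ``"uniform"`` always places uniformly.
    ``p_method``: ``"empirical"`` reports the Monte-Carlo tail rank of the
    cluster score within the simulated background, with ties broken
    uniformly at random — cluster scores are highly discrete (small-integer
    mutation counts over a fixed total), and randomized tie-breaking is what
    makes a discrete Monte-Carlo p-value exactly uniform under the null;
    ``"normal"`` reports the upper tail of a normal fitted to the background
    scores.  The z-score against the background is reported either way.
    """

    seed_min_samples: int = 2
    max_gap: int = 5
    min_cluster_fraction: float = 0.0
    background_source: str = "synonymous"
    n_background: int = 200
    p_method: str = "empirical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_min_samples < 1 or self.max_gap < 0:
            raise ValueError("seed_min_samples >= 1 and max_gap >= 0 required")
        if self.background_source not in ("synonymous", "uniform"):
            raise ValueError("background_source must be 'synonymous' or 'uniform'")
        if self.p_method not in ("empirical", "normal"):
            raise ValueError("p_method must be 'empirical' or 'normal'")


def _raw_clusters(
    position_counts: dict[int, int], seed_min: int, max_gap: int
) -> list[tuple[int, int, float]]:
    """(aa_start, aa_end, score) for runs of mutated codons holding a seed.

    Mutated codons whose successive gaps are all <= ``max_gap`` form a run;
    a run is reported iff it contains a seed codon.  The score is the
    fraction of the gene's mutations (sample-position pairs) inside the run.
    """
    total = sum(position_counts.values())
    if total == 0:
        return []
    positions = sorted(position_counts)
    out = []
    run = [positions[0]]
    for p in positions[1:]:
        if p - run[-1] <= max_gap:
            run.append(p)
        else:
            out.append(run)
            run = [p]
    out.append(run)
    clusters = []
    for run in out:
        if not any(position_counts[p] >= seed_min for p in run):
            continue
        score = sum(position_counts[p] for p in run) / total
        clusters.append((run[0], run[-1], score))
    return clusters


def _position_counts(sub: pd.DataFrame) -> dict[int, int]:
    return sub.groupby("aa_pos")["sample_id"].nunique().to_dict()


def _background_scores(
    sub: pd.DataFrame,
    gene_length: int,
    params: ClusterParams,
    rng: np.random.Generator,
    silent_positions: np.ndarray | None,
) -> np.ndarray:
    """Cluster scores from random placements of the same mutation events."""
    events = sub[["sample_id", "aa_pos"]].to_numpy()
    n_events = len(events)
    samples = sub["sample_id"].to_numpy()
    scores: list[float] = []
    use_silent = (
        params.background_source == "synonymous"
        and silent_positions is not None
        and len(silent_positions) > 0
    )
    for _ in range(params.n_background):
        if use_silent:
            pos = rng.choice(silent_positions, size=n_events, replace=True)
        else:
            pos = rng.integers(1, gene_length + 1, size=n_events)
        counts: dict[int, set] = {}
        for s, p in zip(samples, pos):
            counts.setdefault(int(p), set()).add(s)
        pc = {p: len(s) for p, s in counts.items()}
        for _, _, score in _raw_clusters(pc, params.seed_min_samples, params.max_gap):
            scores.append(score)
    return np.asarray(scores)


def find_clusters(
    mutations: pd.DataFrame,
    gene_lengths: pd.Series | dict,
    params: ClusterParams | None = None,
    silent_mutations: pd.DataFrame | None = None,
) -> list[Cluster]:
    """Detect amino-acid mutation clusters per gene.

    ``mutations``: per-sample events with columns ``gene, sample_id,
    aa_pos``.  ``gene_lengths``: codon count per gene (every mutated gene
    must be present).  ``silent_mutations``: optional table of silent events
    (``gene, aa_pos``) feeding the background model.  Returns clusters
    sorted by descending mutated-sample count.
    """
    params = params or ClusterParams()
    lengths = pd.Series(gene_lengths)
    rng = np.random.default_rng(params.seed)
    silent_by_gene: dict[str, np.ndarray] = {}
    if silent_mutations is not None and len(silent_mutations):
        silent_by_gene = {
            g: sub["aa_pos"].to_numpy() for g, sub in silent_mutations.groupby("gene")
        }

    clusters: list[Cluster] = []
    for gene in sorted(mutations["gene"].unique()):
        if gene not in lengths.index:
            raise KeyError(f"gene {gene!r} absent from gene lengths/models")
        sub = mutations[mutations["gene"] == gene]
        pc = _position_counts(sub)
        raw = _raw_clusters(pc, params.seed_min_samples, params.max_gap)
        raw = [c for c in raw if c[2] >= params.min_cluster_fraction]
        if not raw:
            continue
        bg = _background_scores(
            sub, int(lengths[gene]), params, rng, silent_by_gene.get(gene)
        )
        mu = float(bg.mean()) if len(bg) else 0.0
        sd = float(bg.std(ddof=1)) if len(bg) > 1 else 0.0
        for aa_start, aa_end, score in raw:
            z = (score - mu) / sd if sd > 0 else np.inf
            if params.p_method == "normal":
                p = float(stats.norm.sf(z)) if np.isfinite(z) else 0.0
            else:
                n_above = float((bg > score).sum())
                n_tied = float((bg == score).sum())
                p = (n_above + (1.0 + n_tied) * rng.uniform()) / (len(bg) + 1.0)
            in_interval = sub[(sub["aa_pos"] >= aa_start) & (sub["aa_pos"] <= aa_end)]
            clusters.append(
                Cluster(
                    gene=gene,
                    aa_start=int(aa_start),
                    aa_end=int(aa_end),
                    sample_count=int(in_interval["sample_id"].nunique()),
                    score=float(score),
                    zscore=float(z),
                    p_value=float(min(p, 1.0)),
                )
            )
    clusters.sort(key=lambda c: (-c.sample_count, c.gene, c.aa_start))
    return clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    from .recurrence import percent_of_gene  # gene-share column, same rounding

    rows = []
    for c in clusters:
        rows.append(
            dict(
                gene=c.gene,
                interval=f"{c.aa_start}-{c.aa_end}" if c.aa_start != c.aa_end
                else str(c.aa_start),
                aa_start=c.aa_start,
                aa_end=c.aa_end,
                sample_count=c.sample_count,
                score=c.score,
                zscore=c.zscore,
                p_value=c.p_value,
            )
        )
    return pd.DataFrame(rows)


def cluster_covariates(
    clusters: list[Cluster],
    somatic_variants: pd.DataFrame,
    min_samples: int = 5,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Patient x cluster membership indicators for survival modelling.

    The indicator is 1 iff the patient carries at least one somatic variant
    inside the cluster interval (inclusive ends).  Clusters mutated in
    ``min_samples`` or fewer patients are dropped — only regions recurrent
    in more than ``min_samples`` samples enter model selection.
    """
    if samples is None:
        samples = sorted(somatic_variants["sample_id"].unique())
    data = {}
    for c in clusters:
        hits = somatic_variants[
            (somatic_variants["gene"] == c.gene)
            & (somatic_variants["aa_pos"] >= c.aa_start)
            & (somatic_variants["aa_pos"] <= c.aa_end)
        ]["sample_id"].unique()
        col = pd.Series(0, index=samples, dtype=int)
        col.loc[[s for s in hits if s in col.index]] = 1
        if int(col.sum()) > min_samples:
            data[c.label] = col
    out = pd.DataFrame(data, index=pd.Index(samples, name="patient_id"))
    return out
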