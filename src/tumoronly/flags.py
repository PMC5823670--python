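"""Per-sample variant flagging for tumor-only calling.

Without a matched normal, somatic status is approximated by annotating every
variant position in every sample with a set of flags describing call quality,
allele fraction, population-database membership and predicted impact.  The
allele fraction (AAF) of an alternative allele is the number of high-quality
bases supporting it divided by the total number of high-quality bases at the
position.

Flags
-----
``LQ``  site quality (Phred QUAL) below 20
``LD``  fewer than 10 high-quality bases at the position
``HF``  an allele fraction above 0.95, or fewer than 5 high-quality
        non-alternative bases — too high to be somatic at realistic tumor
        content
``LF``  every alternative allele below 5% or supported by fewer than 5
        high-quality bases
``G5``/``DK``/``EG``/``EE``
        all *qualifying* alternative alleles (AAF >= 5% and support >= 5) are
        common (population AF >= 5%) in, respectively, a 1000 Genomes
        population, the Danish reference panel, ExAC globally, or the ExAC
        European subpopulation
``CO``  every qualifying allele is common in at least one (possibly
        different) of those four sources; implied by any of G5/DK/EG/EE
``I0``–``I3``
        maximum predicted impact (modifier/low/moderate/high, canonical
        transcript) among the qualifying alleles
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POPULATIONS",
    "DB_FLAGS",
    "IMPACT_FLAGS",
    "VariantCall",
    "AnnotationIncompleteError",
    "UndefinedAlleleFrequencyError",
    "allele_frequency",
    "qualifying_alts",
    "assign_flags",
    "technical_filter",
    "format_flags",
    "flag_dataframe",
]

#: population keys, in the order their database flags are listed
POPULATIONS: tuple[str, ...] = ("kg", "danish", "exac", "exac_eur")

#: population -> flag raised when ALL qualifying alleles are common there
DB_FLAGS: Mapping[str, str] = {
    "kg": "G5",
    "danish": "DK",
    "exac": "EG",
    "exac_eur": "EE",
}

#: impact category -> flag, ordered from least to most severe
IMPACT_FLAGS: Mapping[str, str] = {
    "modifier": "I0",
    "low": "I1",
    "moderate": "I2",
    "high": "I3",
}

_IMPACT_ORDER = {name: i for i, name in enumerate(IMPACT_FLAGS)}


class AnnotationIncompleteError(ValueError):
    """A qualifying alternative allele has no impact annotation."""


class UndefinedAlleleFrequencyError(ZeroDivisionError):
    """Allele frequency requested at a position with no high-quality bases."""


@dataclass(frozen=True)
class VariantCall:
    """All alternative-allele observations at one position in one sample.

    Multi-allelic positions are represented jointly: the CO flag depends on
    every alternative allele at the position, so flag logic cannot operate on
    bi-allelic rows in isolation.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    hq_depth: int
    hq_alt_counts: tuple[int, ...]
    #: per-alt mapping population -> allele frequency; a missing key means the
    #: allele was never observed in that population
    pop_afs: tuple[Mapping[str, float], ...] = field(default=())
    #: per-alt impact category (``None`` = unannotated)
    impacts: tuple[str | None, ...] = field(default=())
    rsid: str | None = None

    def __post_init__(self) -> None:
        if not self.alts:
            raise ValueError("alts must be nonempty")
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if len(self.hq_alt_counts) != len(self.alts):
            raise ValueError("one high-quality count required per alt")
        if sum(self.hq_alt_counts) > self.hq_depth:
            raise ValueError("alt support exceeds total high-quality depth")
        if not self.pop_afs:
            object.__setattr__(self, "pop_afs", tuple({} for _ in self.alts))
        if not self.impacts:
            object.__setattr__(self, "impacts", tuple(None for _ in self.alts))


def allele_frequency(call: VariantCall) -> np.ndarray:
    """Per-alt alternative allele fraction: support / high-quality depth."""
    if call.hq_depth == 0:
        raise UndefinedAlleleFrequencyError(
            f"{call.chrom}:{call.pos} has no high-quality bases"
        )
    return np.asarray(call.hq_alt_counts, dtype=float) / call.hq_depth


def qualifying_alts(
    call: VariantCall, *, min_aaf: float = 0.05, min_support: int = 5
) -> list[int]:
    """Indices of alleles with AAF >= 5% and support from >= 5 HQ bases.

    Qualifying alleles gate the database (G5/DK/EG/EE/CO) and impact flags:
    alleles below these thresholds are treated as noise.
    """
    if call.hq_depth == 0:
        return []
    aaf = allele_frequency(call)
    return [
        i
        for i, (f, n) in enumerate(zip(aaf, call.hq_alt_counts))
        if f >= min_aaf and n >= min_support
    ]


def assign_flags(
    call: VariantCall,
    *,
    min_qual: float = 20.0,
    min_depth: int = 10,
    min_aaf: float = 0.05,
    min_support: int = 5,
    max_aaf: float = 0.95,
    common_af: float = 0.05,
) -> frozenset[str]:
    """Assign the full flag taxonomy to one position in one sample.

    Boundary semantics follow the definitions literally: "below 20"/"below
    10" are strict, "5% or more"/"5 or more bases" are inclusive, and "more
    than 95%" is strict.  The support requirement of HF applies to the allele
    whose fraction exceeds 95%; when HF is triggered only by a shortage of
    non-alternative bases, any qualifying allele satisfies it.
    """
    flags: set[str] = set()
    if call.qual < min_qual:
        flags.add("LQ")
    if call.hq_depth < min_depth:
        flags.add("LD")
    if call.hq_depth == 0:
        # no AAF is defined; nothing can qualify
        flags.add("LF")
        return frozenset(flags)

    aaf = allele_frequency(call)
    counts = call.hq_alt_counts
    qual_idx = qualifying_alts(call, min_aaf=min_aaf, min_support=min_support)

    non_alt = call.hq_depth - sum(counts)
    hf_by_fraction = any(
        aaf[i] > max_aaf and counts[i] >= min_support for i in range(len(aaf))
    )
    hf_by_ref_shortage = non_alt < min_support and bool(qual_idx)
    if hf_by_fraction or hf_by_ref_shortage:
        flags.add("HF")

    if not qual_idx:
        flags.add("LF")
        return frozenset(flags)

    for pop, flag in DB_FLAGS.items():
        if all(call.pop_afs[i].get(pop, 0.0) >= common_af for i in qual_idx):
            flags.add(flag)
    if all(
        any(call.pop_afs[i].get(p, 0.0) >= common_af for p in POPULATIONS)
        for i in qual_idx
    ):
        flags.add("CO")

    impacts = []
    for i in qual_idx:
        if call.impacts[i] is None:
            raise AnnotationIncompleteError(
                f"no impact annotation for qualifying alt "
                f"{call.alts[i]} at {call.chrom}:{call.pos}"
            )
        impacts.append(call.impacts[i])
    worst = max(impacts, key=_IMPACT_ORDER.__getitem__)
    flags.add(IMPACT_FLAGS[worst])
    return frozenset(flags)


def technical_filter(
    call: VariantCall,
    *,
    min_depth: int = 10,
    aaf_range: tuple[float, float] = (0.05, 0.95),
) -> bool:
    """Depth/allele-fraction filter applied before any biological filtering.

    Passes when the position has >= 10 high-quality bases and at least one
    alternative allele fraction inside [0.05, 0.95] (both ends inclusive).
    """
    if call.hq_depth < min_depth:
        return False
    lo, hi = aaf_range
    aaf = allele_frequency(call)
    return bool(np.any((aaf >= lo) & (aaf <= hi)))


def format_flags(flags: frozenset[str]) -> str:
    """Stable, alphabetically ordered ';'-joined rendering of a flag set."""
    return ";".join(sorted(flags))


def _call_from_group(group: pd.DataFrame, populations: Sequence[str]) -> VariantCall:
    first = group.iloc[0]
    return VariantCall(
        sample_id=first["sample_id"],
        chrom=first["chrom"],
        pos=int(first["pos"]),
        ref=first["ref"],
        alts=tuple(group["alt"]),
        qual=float(first["qual"]),
        hq_depth=int(first["hq_depth"]),
        hq_alt_counts=tuple(int(c) for c in group["alt_count"]),
        pop_afs=tuple(
            {
                p: row[f"af_{p}"]
                for p in populations
                if pd.notna(row.get(f"af_{p}", np.nan))
            }
            for _, row in group.iterrows()
        ),
        impacts=tuple(
            None if pd.isna(v) else v for v in group["impact"]
        ),
        rsid=None if pd.isna(first.get("rsid")) else first["rsid"],
    )


def flag_dataframe(
    calls: pd.DataFrame,
    freq_db: Mapping[str, pd.DataFrame] | None = None,
    **thresholds,
) -> pd.DataFrame:
    """Flag a long-format call table (one row per sample/position/alt).

    Expects columns ``sample_id, chrom, pos, ref, alt, qual, hq_depth,
    alt_count`` plus optional ``impact`` and ``rsid``.  ``freq_db`` maps
    population keys (see :data:`POPULATIONS`) to tables with columns
    ``chrom, pos, ref, alt, af``; database frequencies may instead be
    supplied directly as ``af_<population>`` columns.  Returns a copy with
    ``aaf``, ``flags`` (frozenset), ``flags_str`` and ``tech_pass`` columns;
    rows from the same sample and position are flagged jointly.
    """
    df = calls.copy()
    if "impact" not in df:
        df["impact"] = None
    if "rsid" not in df:
        df["rsid"] = None
    if freq_db is not None:
        for pop in POPULATIONS:
            table = freq_db.get(pop)
            if table is None:
                df[f"af_{pop}"] = np.nan
                continue
            merged = df.merge(
                table[["chrom", "pos", "ref", "alt", "af"]],
                on=["chrom", "pos", "ref", "alt"],
                how="left",
            )
            df[f"af_{pop}"] = merged["af"].to_numpy()
    for pop in POPULATIONS:
        if f"af_{pop}" not in df:
            df[f"af_{pop}"] = np.nan

    df["aaf"] = np.where(
        df["hq_depth"] > 0, df["alt_count"] / df["hq_depth"].replace(0, 1), np.nan
    )
    flag_col: list[frozenset[str]] = [frozenset()] * len(df)
    tech_col = np.zeros(len(df), dtype=bool)
    df = df.reset_index(drop=True)
    for _, group in df.groupby(["sample_id", "chrom", "pos"], sort=False):
        call = _call_from_group(group, POPULATIONS)
        fl = assign_flags(call, **thresholds)
        ok = call.hq_depth > 0 and technical_filter(call)
        for idx in group.index:
            flag_col[idx] = fl
            tech_col[idx] = ok
    df["flags"] = flag_col
    df["flags_str"] = [format_flags(f) for f in flag_col]
    df["tech_pass"] = tech_col
    return df
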