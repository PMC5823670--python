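"""Reading and writing the pipeline's on-disk formats.

One VCF 4.2 file per tumor sample (sites-only records; depth, per-allele
high-quality support, gene/codon annotation and impact travel in INFO),
population allele-frequency tables, clinical and ground-truth TSVs, and BED
exports of gene models.  Rows sharing a genomic position are emitted as one
multi-allelic record so that joint flag semantics survive a round trip.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam

from .flags import format_flags
from .synthetic import GeneModels, SyntheticCohort

__all__ = [
    "write_sample_vcf",
    "read_sample_vcf",
    "write_cohort",
    "read_gene_models",
    "write_gene_models",
    "read_mask_bed",
    "write_mask_bed",
]

_INFO_FIELDS = [
    ("HQDP", "1", "Integer", "Total high-quality base depth at the position"),
    ("HQAC", "A", "Integer", "High-quality bases supporting each alternative allele"),
    ("GENE", "1", "String", "Gene symbol (canonical transcript annotation)"),
    ("AAPOS", "1", "Integer", "Amino-acid position on the canonical transcript"),
    ("IMPACT", "A", "String", "Predicted impact per alternative allele"),
    ("RSID", "A", "String", "dbSNP-style identifier per alternative allele"),
    ("FLAGS", ".", "String", "Assigned filter flags (alphabetical)"),
]


def _build_header(sample_id: str, contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name, number, typ, desc in _INFO_FIELDS:
        header.info.add(name, number, typ, desc)
    header.add_meta("sample_id", sample_id)
    return header


def _contigs_from_models(models: GeneModels) -> dict[str, int]:
    ends = models.exons.groupby("chrom")["end"].max()
    return {c: int(e) + 100_000 for c, e in ends.sort_index().items()}


def write_sample_vcf(
    calls: pd.DataFrame,
    sample_id: str,
    path: str | os.PathLike,
    contigs: dict[str, int],
    with_flags: bool = False,
) -> None:
    """Write one sample's calls (long-format rows) as an uncompressed VCF."""
    sub = calls[calls["sample_id"] == sample_id]
    header = _build_header(sample_id, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        grouped = sub.sort_values(["chrom", "pos"]).groupby(
            ["chrom", "pos"], sort=False
        )
        for (chrom, pos), rows in grouped:
            rec = vf.new_record(
                contig=str(chrom),
                start=int(pos) - 1,
                stop=int(pos),
                alleles=[rows.iloc[0]["ref"], *rows["alt"]],
            )
            rec.qual = float(rows.iloc[0]["qual"])
            rsids = ["." if pd.isna(r) or r is None else str(r)
                     for r in rows["rsid"]]
            first = next((r for r in rsids if r != "."), None)
            if first is not None:
                rec.id = first
            rec.info["HQDP"] = int(rows.iloc[0]["hq_depth"])
            rec.info["HQAC"] = tuple(int(c) for c in rows["alt_count"])
            rec.info["GENE"] = str(rows.iloc[0]["gene"])
            rec.info["AAPOS"] = int(rows.iloc[0]["aa_pos"])
            rec.info["IMPACT"] = tuple(str(i) for i in rows["impact"])
            rec.info["RSID"] = tuple(rsids)
            if with_flags and "flags" in rows:
                fl = format_flags(rows.iloc[0]["flags"])
                if fl:
                    rec.info["FLAGS"] = tuple(fl.split(";"))
            vf.write(rec)


def read_sample_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample VCF back into the long-format call table."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        sample_id = Path(path).stem
        for record in vf.header.records:
            if record.key == "sample_id":
                sample_id = record.value
        for rec in vf:
            alts = rec.alts or ()
            hqac = rec.info.get("HQAC", ())
            impacts = rec.info.get("IMPACT", ())
            rsids = rec.info.get("RSID", ())
            for i, alt in enumerate(alts):
                rsid = rsids[i] if i < len(rsids) else rec.id
                rows.append(
                    dict(
                        sample_id=sample_id,
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        hq_depth=int(rec.info["HQDP"]),
                        alt_count=int(hqac[i]),
                        gene=rec.info.get("GENE"),
                        aa_pos=int(rec.info.get("AAPOS", 0)),
                        rsid=None if rsid in (".", None) else rsid,
                        impact=impacts[i] if i < len(impacts) else None,
                    )
                )
    return pd.DataFrame(rows)


def write_gene_models(models: GeneModels, path: str | os.PathLike) -> None:
    models.exons.to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> GeneModels:
    return GeneModels(pd.read_csv(path, sep="\t"))


def write_mask_bed(regions, path: str | os.PathLike) -> None:
    """Mask regions as BED (0-based half-open); whole-gene masks use '*'."""
    with open(path, "w") as fh:
        for r in regions:
            if r.whole_gene:
                fh.write(f"*\t0\t0\t{r.label}\t{r.reason}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\t{r.reason}\n")


def read_mask_bed(path: str | os.PathLike):
    from .filters import MaskRegion

    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            reason = parts[4] if len(parts) > 4 else ""
            if chrom == "*":
                regions.append(MaskRegion(None, None, None, label, reason))
            else:
                regions.append(MaskRegion(chrom, start + 1, end, label, reason))
    return regions


def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> Path:
    """Serialize a synthetic study: per-sample VCFs plus all side tables."""
    out = Path(outdir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    contigs = _contigs_from_models(cohort.gene_models)
    for sample_id in cohort.clinical["patient_id"]:
        write_sample_vcf(
            cohort.calls, sample_id, out / "vcf" / f"{sample_id}.vcf", contigs
        )
    for pop, table in cohort.freq_db.items():
        table.to_csv(out / f"af_{pop}.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.clinvar.to_csv(out / "clinvar.tsv", sep="\t", index=False)
    cohort.truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    cohort.truth.carriers.to_csv(out / "truth_carriers.tsv", sep="\t")
    write_gene_models(cohort.gene_models, out / "gene_models.tsv")
    cohort.gene_models.to_bed().to_csv(
        out / "exons.bed", sep="\t", index=False, header=False
    )
    return out
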