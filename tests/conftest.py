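import pandas as pd
import pytest

from tumoronly.flags import flag_dataframe
from tumoronly.synthetic import CohortSpec, GeneModels, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study (200 patients) used across modules."""
    return generate_cohort(CohortSpec(n_patients=200, seed=1))


@pytest.fixture(scope="session")
def flagged_default(default_cohort):
    return flag_dataframe(default_cohort.calls, default_cohort.freq_db)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_patients=60, seed=7))


def make_gene_models(exon_lengths, strand="+", gene="TG1", chrom="chrT"):
    """A single-gene model with the given exon lengths (nt, transcription
    order) and spaced introns."""
    rows = []
    pos = 1_000
    genomic = []
    layout = exon_lengths if strand == "+" else list(exon_lengths)[::-1]
    for length in layout:
        genomic.append((pos, pos + length - 1))
        pos += length + 2_000
    ordered = genomic if strand == "+" else genomic[::-1]
    for rank, (s, e) in enumerate(ordered, start=1):
        rows.append(
            dict(gene=gene, transcript=f"{gene}.t1", chrom=chrom, strand=strand,
                 exon_rank=rank, n_exons=len(exon_lengths), start=s, end=e)
        )
    return GeneModels(pd.DataFrame(rows))
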