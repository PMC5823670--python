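import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from tumoronly.synthetic import (
    CohortSpec,
    PlantedHotspot,
    build_allele_catalog,
    generate_cohort,
    generate_frequency_db,
    generate_gene_models,
)

from .conftest import make_gene_models


class TestGeneModels:
    def test_single_exon_identity(self):
        models = make_gene_models([300])
        assert models.n_codons("TG1") == 100
        assert models.coding_length("TG1") == 300
        assert models.aa_to_exon("TG1", 1) == 1
        assert models.aa_to_exon("TG1", 100) == 1

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_three_exon_codon_mapping(self, strand):
        # cumulative exon lengths 90/150/60 nt = codons 1-30 / 31-80 / 81-100
        models = make_gene_models([90, 150, 60], strand=strand)
        assert models.n_codons("TG1") == 100
        for aa, exon in [(1, 1), (30, 1), (31, 2), (80, 2), (81, 3), (100, 3)]:
            assert models.aa_to_exon("TG1", aa) == exon
        with pytest.raises(ValueError):
            models.aa_to_exon("TG1", 101)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_genomic_round_trip(self, strand):
        models = make_gene_models([90, 150, 60], strand=strand)
        for aa in (1, 30, 31, 55, 80, 81, 100):
            for off in (0, 1, 2):
                chrom, pos = models.aa_to_genomic("TG1", aa, off)
                assert models.genomic_to_aa(chrom, pos) == ("TG1", aa)

    def test_generated_models_are_deterministic(self):
        spec = CohortSpec(n_patients=5, n_genes=20, seed=11)
        a = generate_gene_models(spec)
        b = generate_gene_models(spec)
        pdt.assert_frame_equal(a.exons, b.exons)

    def test_rejects_nonpositive_gene_count(self):
        with pytest.raises(ValueError):
            CohortSpec(n_genes=0)

    def test_bed_export_is_half_open(self):
        models = make_gene_models([300])
        bed = models.to_bed()
        assert (bed["end"] - bed["start"]).iloc[0] == 300
        assert bed["start"].iloc[0] == models.exons["start"].iloc[0] - 1


@pytest.fixture(scope="module")
def catalog_and_db():
    spec = CohortSpec(n_patients=5, seed=3)
    models = generate_gene_models(spec)
    catalog = build_allele_catalog(spec, models)
    return catalog, generate_frequency_db(spec, models, catalog)


class TestFrequencyDb:
    def test_common_alleles_common_somewhere(self, catalog_and_db):
        catalog, db = catalog_and_db
        common = catalog[catalog["kind"] == "germline-common"]
        for _, row in common.iterrows():
            afs = []
            for table in db.values():
                hit = table[
                    (table["chrom"] == row["chrom"]) & (table["pos"] == row["pos"])
                    & (table["alt"] == row["alt"])
                ]
                afs.extend(hit["af"])
            assert max(afs) >= 0.05

    def test_rare_alleles_below_threshold_everywhere(self, catalog_and_db):
        catalog, db = catalog_and_db
        rare = catalog[catalog["kind"] == "germline-rare"]
        keys = set(zip(rare["chrom"], rare["pos"], rare["alt"]))
        for table in db.values():
            hits = table[
                [tuple(k) in keys for k in zip(table["chrom"], table["pos"], table["alt"])]
            ]
            assert (hits["af"] < 0.05).all()

    def test_somatic_alleles_absent_from_all_tables(self, catalog_and_db):
        catalog, db = catalog_and_db
        som = catalog[catalog["kind"].isin(["somatic", "hotspot"])]
        keys = set(zip(som["chrom"], som["pos"], som["alt"]))
        for table in db.values():
            assert not any(
                tuple(k) in keys
                for k in zip(table["chrom"], table["pos"], table["alt"])
            )

    def test_single_population_common_alleles_exist(self, catalog_and_db):
        # these create positions that are common (CO) without being common
        # in every source individually
        catalog, _ = catalog_and_db
        common = catalog[catalog["kind"] == "germline-common"]
        single = common[~common["pop_pattern"].str.contains(",")]
        assert len(single) > 0


class TestCohortGeneration:
    def test_determinism(self):
        spec = CohortSpec(n_patients=20, seed=5)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        pdt.assert_frame_equal(a.calls, b.calls)
        pdt.assert_frame_equal(a.clinical, b.clinical)
        pdt.assert_frame_equal(a.truth.variants, b.truth.variants)

    def test_label_conservation(self, default_cohort):
        c = default_cohort
        emitted = c.truth.variants["origin"].value_counts().sort_index()
        assert emitted.equals(c.truth.origin_counts.sort_index())
        assert len(c.truth.variants) == len(c.calls)
        assert set(emitted.index) <= {
            "germline-common", "germline-rare", "somatic", "artifact"
        }

    def test_germline_het_aaf_centered_on_half(self, default_cohort):
        # bi-allelic het sites only: the two alleles of a multi-allelic pair
        # split the non-reference fraction and sit near 1/3 by design
        calls = default_cohort.calls
        truth = default_cohort.truth.variants
        germ = truth["origin"].str.startswith("germline").to_numpy()
        n_at_pos = calls.groupby(["sample_id", "chrom", "pos"])["alt"].transform(
            "size"
        )
        sel = germ & (n_at_pos == 1).to_numpy()
        aaf = (calls["alt_count"] / calls["hq_depth"])[sel]
        assert len(aaf) > 1000
        assert abs(aaf.mean() - 0.5) < 0.02

    def test_somatic_aaf_tracks_purity(self):
        spec = CohortSpec(n_patients=120, seed=9, purity_range=(0.4, 0.4))
        c = generate_cohort(spec)
        som = c.truth.variants["origin"] == "somatic"
        aaf = (c.calls["alt_count"] / c.calls["hq_depth"])[som.to_numpy()]
        assert len(aaf) > 1000
        assert abs(aaf.mean() - 0.2) < 0.03

    def test_artifact_fraction_below_five_percent(self, default_cohort):
        art = default_cohort.truth.variants["origin"] == "artifact"
        assert (default_cohort.truth.variants.loc[art, "true_fraction"] < 0.05).all()

    def test_hotspot_prevalence_within_binomial_bounds(self, default_cohort):
        spec = default_cohort.spec
        carriers = default_cohort.truth.carriers
        n = spec.n_patients
        for h in spec.hotspots:
            k = int(carriers[h.label].sum())
            lo, hi = stats.binom.ppf([0.005, 0.995], n, h.prevalence)
            assert lo <= k <= hi

    def test_unknown_hotspot_gene_rejected(self):
        spec = CohortSpec(
            n_patients=5, n_genes=3,
            hotspots=(PlantedHotspot("NOPE", 5, prevalence=0.1, hazard_ratio=2.0),),
        )
        with pytest.raises(ValueError, match="NOPE"):
            generate_cohort(spec)

    def test_null_hazard_ratio_gives_flat_logrank(self):
        """With hazard_ratio=1 carriers and non-carriers are exchangeable."""
        ps = []
        for seed in range(12):
            spec = CohortSpec(
                n_patients=80, seed=100 + seed, n_genes=20,
                hotspots=(
                    PlantedHotspot("G001", 10, prevalence=0.3, hazard_ratio=1.0),
                ),
            )
            c = generate_cohort(spec)
            carrier = c.truth.carriers["G001:10"].to_numpy()
            t = c.clinical["os_time"].to_numpy()
            e = c.clinical["os_event"].to_numpy()
            if carrier.sum() < 3:
                continue
            ps.append(
                logrank_test(
                    t[carrier], t[~carrier],
                    event_observed_A=e[carrier], event_observed_B=e[~carrier],
                ).p_value
            )
        # null p-values should not pile up near zero
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25
        assert max(ps) > 0.2


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(stage_probs=(0.5, 0.5, 0.2, 0.0)),
            dict(purity_range=(0.0, 0.5)),
            dict(purity_range=(0.5, 1.2)),
            dict(germline_common_rate=-1),
            dict(n_patients=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)

    def test_invalid_hotspots_rejected(self):
        with pytest.raises(ValueError):
            PlantedHotspot("G", 1, prevalence=0.0, hazard_ratio=1.0)
        with pytest.raises(ValueError):
            PlantedHotspot("G", 1, prevalence=0.5, hazard_ratio=0.0)
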