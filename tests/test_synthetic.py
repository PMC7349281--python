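"""Tests of the synthetic-data generators: planted structure, provenance
bookkeeping, determinism, and the statistical shape of the cohort."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promsnp import datasets, synthetic
from promsnp.assoc import allele_table, allelic_chisq
from promsnp.pwm import parse_transfac, write_transfac
from promsnp.sequtils import apply_transform, invert_transform


def small_genome_spec(**kw):
    defaults = dict(n_chromosomes=1, chrom_length=30_000, n_genes=10, seed=0)
    defaults.update(kw)
    return synthetic.SyntheticGenomeSpec(**defaults)


class TestGenerateAnnotatedGenome:
    def test_inclusion_one_plants_motif_in_every_promoter(self):
        spec = small_genome_spec(promoter_motifs=(("TATAAA", -30, 1.0),))
        g = synthetic.generate_annotated_genome(spec)
        windows = datasets.extract_promoter_windows(g.chromosomes, g.genes)
        assert len(windows) == 10
        # relative -200 maps to window index 0, so offset -30 sits at index 170
        for w in windows:
            assert w.seq[170:176] == "TATAAA"
        assert len(g.motif_registry) == 10

    def test_inclusion_zero_plants_nothing(self):
        spec = small_genome_spec(promoter_motifs=(("TATAAA", -30, 0.0),))
        g = synthetic.generate_annotated_genome(spec)
        assert len(g.motif_registry) == 0
        windows = datasets.extract_promoter_windows(g.chromosomes, g.genes)
        planted_at_offset = sum(w.seq[170:176] == "TATAAA" for w in windows)
        # background chance of TATAAA at one fixed position is ~(1/4)^6
        assert planted_at_offset <= 1

    def test_fixed_seed_is_byte_identical(self):
        out = []
        for _ in range(2):
            g = synthetic.generate_annotated_genome(small_genome_spec(seed=7))
            buf = io.StringIO()
            g.motif_registry.to_csv(buf, sep="\t")
            out.append((g.chromosomes, [a.tss for a in g.genes], buf.getvalue()))
        assert out[0] == out[1]

    def test_gene_density_too_high_raises(self):
        with pytest.raises(synthetic.SizingError):
            synthetic.generate_annotated_genome(
                small_genome_spec(chrom_length=5_000, n_genes=10)
            )

    def test_promoter_window_always_inside_chromosome(self):
        g = synthetic.generate_annotated_genome(small_genome_spec(seed=3))
        for gene in g.genes:
            s, e = datasets.relative_window(gene.tss, gene.strand, -200, 50)
            assert 0 <= s < e <= len(g.chromosomes[gene.chrom])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            small_genome_spec(promoter_motifs=(("TATAAA", -300, 1.0),))
        with pytest.raises(ValueError):
            small_genome_spec(promoter_motifs=(("TATAAA", -30, 1.5),))
        with pytest.raises(ValueError):
            small_genome_spec(background_composition=(0.5, 0.5, 0.5, 0.5))


@pytest.fixture(scope="module")
def genome():
    return synthetic.generate_annotated_genome(small_genome_spec(seed=1)).chromosomes


class TestGenerateContigs:

    def test_provenance_inverts_to_source_substring(self, genome):
        contigs, prov = synthetic.generate_contigs(genome, 50, (100, 200), seed=0)
        assert len(contigs) == 50
        for row in prov.itertuples():
            source = genome[row.chrom][row.start : row.end]
            assert invert_transform(contigs[row.contig_id], row.transform) == source
            # and the forward direction reproduces the stored contig
            assert apply_transform(source, row.transform) == contigs[row.contig_id]

    def test_orientation_frequencies_uniform(self, genome):
        _, prov = synthetic.generate_contigs(genome, 4000, (40, 60), seed=5)
        counts = prov["transform"].value_counts()
        sd = np.sqrt(4000 * 0.25 * 0.75)
        for t in ("identity", "complement", "reverse", "reverse_complement"):
            assert abs(counts[t] - 1000) < 3 * sd

    def test_zero_contigs(self, genome):
        contigs, prov = synthetic.generate_contigs(genome, 0, (100, 200), seed=0)
        assert contigs == {} and len(prov) == 0

    def test_oversized_length_range_raises(self, genome):
        with pytest.raises(synthetic.SizingError):
            synthetic.generate_contigs(genome, 5, (100, 10**7), seed=0)

    def test_must_cover_interval_contained(self, genome):
        interval = ("chr1", 5000, 5100)
        contigs, prov = synthetic.generate_contigs(
            genome, 10, (200, 400), seed=0, must_cover=[interval]
        )
        row = prov.iloc[0]
        assert row["start"] <= interval[1] - 25 and row["end"] >= interval[2] + 25

    def test_fixed_seed_identical(self, genome):
        a = synthetic.generate_contigs(genome, 20, (100, 200), seed=9)
        b = synthetic.generate_contigs(genome, 20, (100, 200), seed=9)
        assert a[0] == b[0] and a[1].equals(b[1])


@pytest.fixture(scope="module")
def cohort_setup():
    spec = small_genome_spec(n_chromosomes=1, chrom_length=60_000, n_genes=20,
                             promoter_motifs=(("TATAAA", -30, 1.0),), seed=4)
    g = synthetic.generate_annotated_genome(spec)
    occ = g.motif_registry.iloc[0]
    must = [(occ["chrom"], int(occ["start"]) - 100, int(occ["end"]) + 60)]
    contigs, prov = synthetic.generate_contigs(
        g.chromosomes, 30, (300, 500), seed=1, must_cover=must
    )
    return g, contigs, prov


class TestGenerateCohort:
    def test_one_exception_allele_table(self, cohort_setup):
        g, contigs, prov = cohort_setup
        spec = synthetic.SyntheticCohortSpec(n_snps=30, seed=0)
        cohort = synthetic.generate_cohort(spec, contigs, prov, g.motif_registry)
        causal = cohort.causal["snp_id"]
        table = allele_table(cohort.genotypes.loc[causal], cohort.phenotype)
        # 6 low lines all hom ref; 1 exception high line hom ref; 13 hom alt
        assert table.tolist() == [[12, 0], [2, 26]]
        # the alternate allele never appears in low lines
        assert table[0, 1] == 0

    def test_zero_exceptions_complete_separation(self, cohort_setup):
        g, contigs, prov = cohort_setup
        spec = synthetic.SyntheticCohortSpec(
            n_snps=5, seed=0,
            causal_config=synthetic.CausalConfig(exceptions=0),
        )
        cohort = synthetic.generate_cohort(spec, contigs, prov, g.motif_registry)
        table = allele_table(cohort.genotypes.loc[cohort.causal["snp_id"]], cohort.phenotype)
        chi2, _ = allelic_chisq(table)
        assert chi2 == pytest.approx(40.0)  # chi2 = N for a zero off-diagonal table

    def test_all_genotypes_homozygous(self, cohort_setup):
        g, contigs, prov = cohort_setup
        cohort = synthetic.generate_cohort(
            synthetic.SyntheticCohortSpec(n_snps=40, seed=2), contigs, prov, g.motif_registry
        )
        assert set(np.unique(cohort.genotypes.to_numpy())) <= {0, 2}

    def test_quality_scores_bimodal_around_threshold(self, cohort_setup):
        g, contigs, prov = cohort_setup
        mixture = (0.636, 200.0, 60.0, 800.0, 120.0)
        spec = synthetic.SyntheticCohortSpec(n_snps=2000, qual_mixture=mixture, seed=3)
        cohort = synthetic.generate_cohort(spec, contigs, prov, g.motif_registry)
        quals = cohort.snps["qual"].to_numpy()
        # mixture-CDF oracle for P(qual < 400)
        w, mu1, sd1, mu2, sd2 = mixture
        expected = w * stats.norm.cdf(400, mu1, sd1) + (1 - w) * stats.norm.cdf(400, mu2, sd2)
        observed = np.mean(quals[1:] < 400)  # causal SNP intentionally high-quality
        se = np.sqrt(expected * (1 - expected) / len(quals))
        assert abs(observed - expected) < 4 * se

    def test_causal_ref_matches_contig_base(self, cohort_setup):
        g, contigs, prov = cohort_setup
        cohort = synthetic.generate_cohort(
            synthetic.SyntheticCohortSpec(n_snps=10, seed=5), contigs, prov, g.motif_registry
        )
        c = cohort.causal
        assert contigs[c["contig"]][c["pos"] - 1] == c["ref"]
        assert c["ref"] != c["alt"]

    def test_uncovered_causal_raises_configuration_error(self, cohort_setup):
        g, contigs, prov = cohort_setup
        spec = synthetic.SyntheticCohortSpec(
            n_snps=5, causal_config=synthetic.CausalConfig(gene_id="no_such_gene")
        )
        with pytest.raises(synthetic.ConfigurationError):
            synthetic.generate_cohort(spec, contigs, prov, g.motif_registry)

    def test_vcf_round_trips_through_cyvcf2(self, cohort_setup, tmp_path):
        from promsnp.assoc import GenotypeMatrix

        g, contigs, prov = cohort_setup
        cohort = synthetic.generate_cohort(
            synthetic.SyntheticCohortSpec(n_snps=25, seed=6), contigs, prov, g.motif_registry
        )
        path = tmp_path / "cohort.vcf"
        synthetic.write_vcf(cohort, contigs, path)
        gm = GenotypeMatrix.from_vcf(path)
        assert len(gm.genotypes) == 25
        assert list(gm.genotypes.columns) == list(cohort.genotypes.columns)
        causal = cohort.causal["snp_id"]
        assert gm.genotypes.loc[causal].tolist() == cohort.genotypes.loc[causal].tolist()
        assert gm.qual.loc[causal] == pytest.approx(cohort.snps.loc[causal, "qual"], abs=0.05)


class TestGeneratePwmLibrary:
    def test_consensus_spells_motif(self):
        lib = synthetic.generate_pwm_library(["TATAAA"], pseudocount=0.0, n_decoys=0)
        assert len(lib) == 1 and lib[0].consensus == "TATAAA"

    def test_library_size_counts_decoys(self):
        lib = synthetic.generate_pwm_library(["TATAAA", "CCAAT"], n_decoys=5, seed=0)
        assert len(lib) == 7

    def test_round_trip_through_transfac(self, tmp_path):
        lib = synthetic.generate_pwm_library(["TATAAA", "CCAAT"], n_decoys=2, seed=1)
        path = tmp_path / "lib.transfac"
        write_transfac(lib, path)
        back = parse_transfac(path)
        assert [p.name for p in back] == [p.name for p in lib]
        for a, b in zip(lib, back):
            np.testing.assert_allclose(a.counts, b.counts, rtol=1e-6)
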