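"""Synthetic-data generators: determinism, dimensions, planted structure."""

import numpy as np
import pandas as pd
import pytest

from ethylome import catalog, io, synthetic
from ethylome.methylome import region_level


class TestGenome:
    def test_dimensions_and_determinism(self, tmp_path):
        g1 = synthetic.generate_genome(1, n_chrom=2, chrom_length=10_000)
        g2 = synthetic.generate_genome(1, n_chrom=2, chrom_length=10_000)
        assert list(g1) == ["chr1", "chr2"]
        assert all(len(s) == 10_000 for s in g1.values())
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        io.write_fasta(g1, p1)
        io.write_fasta(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert io.read_fasta(str(p1)) == g1

    def test_gc_fraction_concentrates(self):
        g = synthetic.generate_genome(3, n_chrom=1, chrom_length=1_000_000,
                                      gc_fraction=0.5)
        s = g["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.49 <= gc <= 0.51

    @pytest.mark.parametrize("kwargs", [
        {"n_chrom": 0}, {"chrom_length": -5}, {"gc_fraction": 0.0},
        {"gc_fraction": 1.0},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.generate_genome(1, **{"n_chrom": 1, "chrom_length": 100,
                                            "gc_fraction": 0.4, **kwargs})


class TestAnnotation:
    def test_counts_exons_and_gaps(self, toy_genome):
        ann = synthetic.generate_annotation(
            toy_genome, 5, n_genes=20, exons_per_gene=(3, 3),
            intergenic_gap=400)
        assert len(ann) == 20
        for gene in ann:
            (t,) = gene.transcripts
            assert len(t.exons) == 3
            assert list(t.exons) == sorted(t.exons)
        for genes in ann.by_chrom.values():
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end >= 400
        strands = {g.strand for g in ann}
        assert strands == {"+", "-"}

    def test_infeasible_packing_names_chromosome(self):
        tiny = {"chr1": "A" * 2000}
        with pytest.raises(ValueError, match="chr1"):
            synthetic.generate_annotation(tiny, 1, n_genes=10)

    def test_gff3_round_trip(self, toy_genome, toy_annotation, tmp_path):
        path = tmp_path / "ann.gff3"
        io.write_gff3(toy_annotation, path)
        back = io.read_gff3(str(path))
        assert sorted(back.genes) == sorted(toy_annotation.genes)
        for gid, gene in back.genes.items():
            orig = toy_annotation.genes[gid]
            assert (gene.start, gene.end, gene.strand) == \
                (orig.start, orig.end, orig.strand)
            assert gene.transcripts[0].exons == orig.transcripts[0].exons


class TestIsoformReads:
    def test_no_perturbation_means_reference_chains(self, toy_annotation):
        models, truth = synthetic.generate_isoform_reads(
            toy_annotation, 7, as_rates={}, apa_rate=0.0)
        assert truth.planted_as_events == [] and truth.planted_apa == []
        ref_chains = {t.introns for g in toy_annotation for t in g.transcripts}
        assert {m.introns for m in models} <= ref_chains

    def test_forced_exon_skipping_removes_middle_exon(self, toy_genome):
        ann = synthetic.generate_annotation(toy_genome, 5, n_genes=10,
                                            exons_per_gene=(3, 3))
        models, truth = synthetic.generate_isoform_reads(
            ann, 8, as_rates={"ES": 1.0})
        assert len(truth.planted_as_events) == 10
        by_id = {m.id: m for m in models}
        for mid, etype, gid, s, e in truth.planted_as_events:
            assert etype == "ES"
            middle = ann.genes[gid].transcripts[0].exons[1]
            assert (s, e) == middle
            assert middle not in by_id[mid].exons

    def test_apa_positions_separated_beyond_shift(self, toy_annotation):
        models, truth = synthetic.generate_isoform_reads(
            toy_annotation, 9, apa_rate=1.0, apa_shift=60)
        assert len(truth.planted_apa) == len(toy_annotation.genes)
        for gid, positions in truth.planted_apa:
            assert len(positions) >= 2
            assert min(np.diff(positions)) >= 61

    def test_every_planted_isoform_references_an_emitted_model(self, toy_annotation):
        models, truth = synthetic.generate_isoform_reads(
            toy_annotation, 10,
            as_rates={"ES": 0.5, "IR": 0.5, "A3S": 0.5, "A5S": 0.5, "IESC": 0.5})
        ids = {m.id for m in models}
        assert all(mid in ids for mid, *_ in truth.planted_as_events)

    def test_gtf_round_trip(self, toy_annotation, tmp_path):
        models, _ = synthetic.generate_isoform_reads(
            toy_annotation, 13, as_rates={"IR": 0.5})
        path = tmp_path / "models.gtf"
        io.write_transcript_gtf(models, path)
        back = io.read_transcript_gtf(str(path))
        assert sorted(m.id for m in back) == sorted(m.id for m in models)
        exons = {m.id: m.exons for m in models}
        assert all(m.exons == exons[m.id] for m in back)

    def test_intronic_lncrna_requires_a_wide_intron(self, toy_genome):
        ann = synthetic.generate_annotation(
            toy_genome, 5, n_genes=5, exons_per_gene=(1, 1))
        with pytest.raises(ValueError, match="intronic"):
            synthetic.generate_isoform_reads(ann, 1, lncrna_spec={"intronic": 1})


class TestMethylome:
    def test_zero_delta_means_no_planted_dmrs(self, toy_genome):
        calls, truth = synthetic.generate_methylome(
            toy_genome, None, 2, coverage=5)
        assert truth.planted_dmrs == []

    def test_chh_level_ordering_follows_profiles(self, toy_genome):
        profiles = {"CK": {"CG": 0.3, "CHG": 0.1, "CHH": 0.05},
                    "HE": {"CG": 0.3, "CHG": 0.1, "CHH": 0.15}}
        calls, _ = synthetic.generate_methylome(
            toy_genome, None, 3, condition_profiles=profiles, coverage=10)
        lo = region_level(calls["CK"], "CHH")
        hi = region_level(calls["HE"], "CHH")
        assert lo < hi

    def test_zero_level_zero_error_gives_zero_counts(self, toy_genome):
        profiles = {"CK": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0}}
        calls, _ = synthetic.generate_methylome(
            toy_genome, None, 4, condition_profiles=profiles,
            conversion_error=0.0, coverage=5)
        assert (calls["CK"]["m_count"] == 0).all()

    def test_methylation_table_round_trip(self, toy_genome, tmp_path):
        calls, _ = synthetic.generate_methylome(toy_genome, None, 5, coverage=5)
        path = tmp_path / "meth.tsv"
        io.write_methylation(calls["CK"], path)
        back = io.read_methylation(str(path))
        pd.testing.assert_frame_equal(back, calls["CK"][io.METH_COLUMNS])

    def test_level_plus_delta_validated(self, toy_genome):
        spec = synthetic.DMRSpec(count=1, length=200, context="CG", delta=0.9,
                                 pair=("CK", "HE"))
        with pytest.raises(ValueError, match="delta"):
            synthetic.generate_methylome(toy_genome, None, 6,
                                         planted_dmrs=[spec])


class TestExpression:
    def test_matrix_shape_and_sample_names(self, toy_annotation):
        matrix, _ = synthetic.generate_expression(toy_annotation, 1,
                                                  module_size=10)
        assert matrix.shape[1] == 9
        assert list(matrix.columns)[:3] == ["CK_1", "CK_2", "CK_3"]
        assert (matrix.values >= 0).all()

    def test_low_noise_makes_module_rows_near_perfectly_correlated(self, toy_annotation):
        matrix, truth = synthetic.generate_expression(
            toy_annotation, 2, n_modules=1, module_size=8, noise_sd=1e-6)
        members, cond, sign = truth.planted_modules[0]
        sub = matrix.loc[list(members)]
        corr = np.corrcoef(sub.to_numpy())
        assert corr.min() > 0.999

    def test_planted_up_module_separates_condition_means(self, toy_annotation):
        matrix, truth = synthetic.generate_expression(
            toy_annotation, 3, n_modules=1, module_size=8,
            condition_effects=[("HE", 1)])
        members, *_ = truth.planted_modules[0]
        sub = matrix.loc[list(members)]
        he = sub[[c for c in sub if c.startswith("HE")]].to_numpy().mean()
        ck = sub[[c for c in sub if c.startswith("CK")]].to_numpy().mean()
        assert he > 2 * ck

    def test_too_few_replicates_rejected(self, toy_annotation):
        with pytest.raises(ValueError, match="n_reps"):
            synthetic.generate_expression(toy_annotation, 1, n_reps=1)

    def test_module_budget_validated(self, toy_annotation):
        with pytest.raises(ValueError):
            synthetic.generate_expression(toy_annotation, 1, n_modules=100,
                                          module_size=50)


def test_fixed_seed_reproduces_all_generators(toy_genome, toy_annotation):
    """Byte-level determinism across the five generators."""
    a1 = synthetic.generate_annotation(toy_genome, 21, n_genes=10)
    a2 = synthetic.generate_annotation(toy_genome, 21, n_genes=10)
    assert [(g.id, g.start, g.strand) for g in a1] == \
        [(g.id, g.start, g.strand) for g in a2]
    m1, t1 = synthetic.generate_isoform_reads(toy_annotation, 22,
                                              as_rates={"ES": 0.5})
    m2, t2 = synthetic.generate_isoform_reads(toy_annotation, 22,
                                              as_rates={"ES": 0.5})
    assert [(m.id, m.exons) for m in m1] == [(m.id, m.exons) for m in m2]
    assert t1.planted_as_events == t2.planted_as_events
    c1, _ = synthetic.generate_methylome(toy_genome, None, 23, coverage=3)
    c2, _ = synthetic.generate_methylome(toy_genome, None, 23, coverage=3)
    for cond in c1:
        pd.testing.assert_frame_equal(c1[cond], c2[cond])
    e1, _ = synthetic.generate_expression(toy_annotation, 24, module_size=10)
    e2, _ = synthetic.generate_expression(toy_annotation, 24, module_size=10)
    pd.testing.assert_frame_equal(e1, e2)
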