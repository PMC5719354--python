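"""Methylome stage: context assignment, mC calling, categories, profiles,
DMR calling and annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from _oracles import binom_tail_oracle, context_oracle, fisher_oracle, revcomp

from ethylome import methylome, synthetic
from ethylome.types import Annotation
from conftest import make_gene


def meth_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "context",
                                       "m_count", "total_count"])


class TestContext:
    def test_plus_strand_examples(self):
        assert methylome.assign_context({"c": "ACGTA"}, "c", 1, "+") == "CG"
        assert methylome.assign_context({"c": "ACTGA"}, "c", 1, "+") == "CHG"
        assert methylome.assign_context({"c": "ACTTA"}, "c", 1, "+") == "CHH"

    def test_minus_strand_reads_complement_leftward(self):
        # G at position 2 of TCGA pairs with a C on '-'; 5'->3' on '-' is CG
        assert methylome.assign_context({"c": "TCGA"}, "c", 2, "-") == "CG"

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not a cytosine"):
            methylome.assign_context({"c": "AAAA"}, "c", 0, "+")

    def test_all_64_trinucleotides_both_strands(self):
        """Exhaustive enumeration against the reverse-complement oracle."""
        for tri in map("".join, itertools.product("ACGT", repeat=3)):
            if tri[0] == "C":
                assert methylome.assign_context({"c": tri}, "c", 0, "+") == \
                    context_oracle(tri)
            rc = revcomp(tri)
            if rc[2] == "G":  # '-'-strand cytosine at the right edge
                assert methylome.assign_context({"c": rc}, "c", 2, "-") == \
                    context_oracle(tri)

    def test_vectorised_sites_agree_with_scalar(self, toy_genome):
        sites = methylome.cytosine_sites(
            {"chr1": toy_genome["chr1"][:2000]})
        assert len(sites) > 0
        for row in sites.sample(50, random_state=0).itertuples():
            assert methylome.assign_context(
                {"chr1": toy_genome["chr1"][:2000]}, "chr1", row.pos0,
                row.strand) == row.context


class TestCallMethylated:
    def test_statuses_follow_binomial_tail(self):
        df = meth_df([
            ("c", 0, "+", "CG", 0, 20),    # tail prob 1 -> unmethylated
            ("c", 1, "+", "CG", 10, 10),   # ~1e-20 -> methylated
            ("c", 2, "+", "CG", 1, 30),    # tail ~= 0.26 -> unmethylated
            ("c", 3, "+", "CG", 2, 2),     # below min coverage
        ])
        status = methylome.call_methylated(df, error_rate=0.01, alpha=0.01,
                                           min_cov=4)
        assert list(status) == ["unmethylated", "methylated", "unmethylated",
                                "no-data"]
        # frozen oracle values for the two informative rows
        assert binom_tail_oracle(10, 10, 0.01) == pytest.approx(1e-20, rel=1e-6)
        assert binom_tail_oracle(1, 30, 0.01) == pytest.approx(0.26030, abs=1e-4)

    def test_error_rate_validated(self):
        with pytest.raises(ValueError):
            methylome.call_methylated(meth_df([]), error_rate=0.0)


class TestCategories:
    def test_all_status_patterns_partition(self):
        """The 2^3 methylated/unmethylated patterns map onto the four-way
        partition of the 7 methylated-somewhere patterns."""
        seen = {}
        for pattern in itertools.product(["methylated", "unmethylated"],
                                         repeat=3):
            statuses = dict(zip(("CK", "LE", "HE"), pattern))
            seen[pattern] = methylome.classify_mc_across_conditions(statuses)
        m, u = "methylated", "unmethylated"
        assert seen[(m, m, m)] == "constitutive"
        assert seen[(u, m, u)] == "LE-specific"
        assert seen[(u, u, m)] == "HE-specific"
        assert seen[(u, u, u)] is None
        varied = [p for p, c in seen.items() if c == "varied"]
        assert len(varied) == 4  # CK-only and the three two-condition patterns

    def test_no_data_excludes_site(self):
        assert methylome.classify_mc_across_conditions(
            {"CK": "methylated", "LE": "no-data", "HE": "methylated"}) is None

    def test_unknown_control_label_rejected(self):
        with pytest.raises(KeyError):
            methylome.classify_mc_across_conditions(
                {"LE": "methylated", "HE": "methylated"}, control="CK")

    def test_bulk_categorisation_counts(self):
        dfs = {}
        base = [("c", i, "+", "CG") for i in range(3)]
        statuses = {"CK": ["methylated", "unmethylated", "methylated"],
                    "LE": ["methylated", "methylated", "unmethylated"],
                    "HE": ["methylated", "unmethylated", "unmethylated"]}
        for cond, st in statuses.items():
            df = meth_df([b + (5, 10) for b in base])
            df["status"] = st
            dfs[cond] = df
        out = methylome.categorize_sites(dfs)
        assert list(out.sort_values("pos0")["category"]) == \
            ["constitutive", "LE-specific", "varied"]


class TestRegionLevel:
    def test_pooled_arithmetic(self):
        df = meth_df([("c", 0, "+", "CG", 3, 10), ("c", 5, "+", "CG", 7, 10)])
        assert methylome.region_level(df) == pytest.approx(0.5)

    def test_empty_region_is_null(self):
        assert methylome.region_level(meth_df([])) is None

    def test_concatenation_conserves_weighted_level(self, toy_genome):
        calls, _ = synthetic.generate_methylome(toy_genome, None, 31,
                                                coverage=5)
        df = calls["CK"]
        half = df["pos0"].median()
        left, right = df[df["pos0"] <= half], df[df["pos0"] > half]
        la, lb = methylome.region_level(left), methylome.region_level(right)
        wa, wb = left["total_count"].sum(), right["total_count"].sum()
        combined = (la * wa + lb * wb) / (wa + wb)
        assert combined == pytest.approx(methylome.region_level(df), abs=1e-12)


class TestGeneProfiles:
    def _uniform_calls(self, gene, level=0.4):
        rows = []
        for pos in range(gene.start - 2000, gene.end + 2000, 7):
            ctx = ["CG", "CHG", "CHH"][pos % 3]
            rows.append(("chr1", pos, "+", ctx, int(level * 10), 10))
        return meth_df(rows)

    def test_uniform_methylome_fills_all_nine_slots(self):
        gene = make_gene("g1", exons=((3000, 3400), (3600, 4000)))
        ann = Annotation([gene])
        prof = methylome.gene_profiles(ann, self._uniform_calls(gene))
        assert prof.shape == (1, 9)
        assert np.allclose(prof.loc["g1"].to_numpy(), 0.4)

    def test_minus_strand_mirrors_plus_strand_regions(self):
        plus = make_gene("gp", strand="+", exons=((5000, 5400), (5600, 6000)))
        minus = make_gene("gm", strand="-", exons=((5000, 5400), (5600, 6000)))
        rows = [("chr1", pos, "+", "CG", 8 if pos < 5000 else 2, 10)
                for pos in range(3000, 9000, 11)]
        calls = meth_df(rows)
        ann = Annotation([plus, minus])
        prof = methylome.gene_profiles(ann, calls)
        # high methylation left of the gene: upstream for '+', downstream for '-'
        assert prof.loc["gp", "upstream_CG"] > 0.7
        assert prof.loc["gm", "downstream_CG"] > 0.7
        assert prof.loc["gm", "upstream_CG"] < 0.3

    def test_planted_promoter_hypomethylation_is_visible(self):
        gene = make_gene("g1", exons=((3000, 3600),))
        rows = [("chr1", pos, "+", "CG", 1 if pos < 3000 else 8, 10)
                for pos in range(1000, 3600, 5)]
        prof = methylome.gene_profiles(Annotation([gene]), meth_df(rows))
        assert prof.loc["g1", "upstream_CG"] < prof.loc["g1", "body_CG"]


class TestProfileClustering:
    def test_planted_archetypes_recovered_exactly(self):
        # genes spaced beyond 2x the flank so upstream regions stay clean
        genome = synthetic.generate_genome(40, n_chrom=1, chrom_length=160_000)
        ann = synthetic.generate_annotation(genome, 40, n_genes=20,
                                            intergenic_gap=4200)
        gene_ids = sorted(ann.genes)
        truth = {g: (i % 4) + 1 for i, g in enumerate(gene_ids)}
        calls, _ = synthetic.generate_methylome(
            genome, ann, 41, coverage=30, gene_archetypes=truth)
        prof = methylome.gene_profiles(ann, calls["CK"])
        labels, means = methylome.cluster_gene_profiles(prof, k=4, seed=0)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score([truth[g] for g in labels.index], labels)
        assert ari == 1.0
        # cluster 1 is the highest-upstream-CG archetype, reproducibly
        assert means.loc[1, "upstream_CG"] == means["upstream_CG"].max()
        for _ in range(3):
            again, _means = methylome.cluster_gene_profiles(prof, k=4, seed=0)
            assert (again == labels).all()

    def test_k_beyond_usable_genes_rejected(self):
        prof = pd.DataFrame({f"{r}_{c}": [0.1, 0.2]
                             for r in ("upstream", "body", "downstream")
                             for c in ("CG", "CHG", "CHH")},
                            index=["a", "b"])
        with pytest.raises(ValueError):
            methylome.cluster_gene_profiles(prof, k=4)


class TestFisher:
    def test_matches_binomial_coefficient_oracle_on_small_margins(self):
        rng = np.random.default_rng(0)
        tables = rng.integers(0, 16, size=(300, 4))
        mine = methylome.fisher_exact_two_sided(*tables.T)
        for (a, b, c, d), p in zip(tables, mine):
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_matches_scipy_definition(self):
        rng = np.random.default_rng(1)
        tables = rng.integers(0, 25, size=(100, 4))
        mine = methylome.fisher_exact_two_sided(*tables.T)
        for (a, b, c, d), p in zip(tables, mine):
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(ref, abs=1e-10)


class TestCallDMRs:
    def _calls(self, m, t, cond_positions=range(0, 200, 40)):
        return meth_df([("c", p, "+", "CG", m, t) for p in cond_positions])

    def test_strong_difference_called_hypo(self):
        a = self._calls(18, 20)
        b = self._calls(2, 20)
        (dmr,) = methylome.call_dmrs(a, b, "CG", pair=("A", "B"),
                                     chrom_sizes={"c": 250})
        assert dmr.direction == "hypo"
        assert dmr.delta == pytest.approx(-0.8)
        assert dmr.q_value < 1e-10

    def test_identical_counts_yield_nothing(self):
        a = self._calls(10, 20)
        assert methylome.call_dmrs(a, a.copy(), "CG",
                                   chrom_sizes={"c": 250}) == []

    def test_delta_below_context_threshold_filtered(self):
        a = self._calls(100, 200)
        b = self._calls(160, 200)  # delta 0.3 < CG threshold 0.4
        assert methylome.call_dmrs(a, b, "CG", chrom_sizes={"c": 250}) == []

    def test_condition_swap_flips_direction_and_sign(self, toy_genome):
        spec = synthetic.DMRSpec(count=5, length=300, context="CG", delta=0.5,
                                 pair=("A", "B"))
        profiles = {"A": {"CG": 0.2, "CHG": 0.1, "CHH": 0.05},
                    "B": {"CG": 0.2, "CHG": 0.1, "CHH": 0.05}}
        calls, _ = synthetic.generate_methylome(
            toy_genome, None, 51, condition_profiles=profiles,
            planted_dmrs=[spec], coverage=30)
        sizes = {k: len(v) for k, v in toy_genome.items()}
        fwd = methylome.call_dmrs(calls["A"], calls["B"], "CG",
                                  pair=("A", "B"), chrom_sizes=sizes)
        rev = methylome.call_dmrs(calls["B"], calls["A"], "CG",
                                  pair=("B", "A"), chrom_sizes=sizes)
        assert len(fwd) == len(rev) > 0
        flip = {"hyper": "hypo", "hypo": "hyper"}
        for f, r in zip(fwd, rev):
            assert (f.chrom, f.start, f.end) == (r.chrom, r.start, r.end)
            assert r.direction == flip[f.direction]
            assert r.delta == pytest.approx(-f.delta)
            assert r.p_value == pytest.approx(f.p_value, rel=1e-9)

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            methylome.call_dmrs(self._calls(1, 2), self._calls(1, 2), "CNN")


class TestAnnotateOverlap:
    def _dmr(self, start, end, chrom="chr1"):
        from ethylome.types import DMR

        return DMR(chrom=chrom, start=start, end=end, context="CG",
                   pair=("A", "B"), direction="hyper", level_a=0.1,
                   level_b=0.6, delta=0.5, p_value=1e-9, q_value=1e-8,
                   n_cytosines=5)

    def test_precedence_and_strand_aware_upstream(self, mini_annotation):
        te = [("chr1", 150, 260)]
        tagged = methylome.annotate_dmrs(
            [self._dmr(180, 240),      # inside geneA body (and a TE)
             self._dmr(5700, 5900),    # right of '-' geneB end: its upstream
             self._dmr(30_000, 30_100)],
            mini_annotation, te, flank=2000)
        assert [d.annotation for d in tagged] == \
            ["gene-body", "gene-upstream", "intergenic"]
        assert tagged[0].gene_ids == ("geneA",)
        assert tagged[1].gene_ids == ("geneB",)

    def test_te_tag_when_outside_genes(self, mini_annotation):
        te = [("chr1", 40_000, 41_000)]
        (tagged,) = methylome.annotate_dmrs([self._dmr(40_500, 40_600)],
                                            mini_annotation, te)
        assert tagged.annotation == "TE"

    def test_overlap_fractions(self):
        xs = [self._dmr(0, 100), self._dmr(200, 300), self._dmr(400, 500),
              self._dmr(600, 700)]
        ys = [self._dmr(50, 120), self._dmr(250, 260)]
        fx, fy, pairs = methylome.overlap_dmrs(xs, ys)
        assert fx == 0.5 and fy == 1.0 and len(pairs) == 2
        assert methylome.overlap_dmrs(xs, xs)[0] == 1.0
        assert methylome.overlap_dmrs(xs, [])[0] == 0.0
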