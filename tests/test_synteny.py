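"""BLAST chain resolution and hypergeometric enrichment.

The hypergeometric upper tail is checked against two independent oracles:
exhaustive enumeration of draws at tiny sizes, and exact integer-arithmetic
pmf summation via math.comb (scipy.stats.hypergeom as a third cross-check).
"""

from __future__ import annotations

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from radsexmark import (
    AnnotationTable,
    HitChain,
    enrichment_table,
    hypergeom_sf,
    resolve_hits,
    simulate_synteny_inputs,
)
from radsexmark.synteny import read_blast6


def sf_oracle(k, N, K, n):
    """Exact upper tail from integer pmf summation (independent route)."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, 0, n + K - N), min(K, n) + 1)
    )
    return total / denom


class TestHypergeomSF:
    def test_k_zero_is_one(self):
        assert hypergeom_sf(0, 50, 10, 5) == 1.0

    def test_k_beyond_support_is_zero(self):
        assert hypergeom_sf(4, 10, 3, 4) == 0.0  # k > K
        assert hypergeom_sf(5, 10, 8, 4) == 0.0  # k > n

    def test_worked_value_by_exhaustive_enumeration(self):
        """P(X>=2 | N=10, K=3, n=4): count draws directly.

        Of the C(10,4)=210 equally likely draws from a 10-item population
        with 3 marked items, exactly 70 contain >=2 marked: p = 1/3.
        """
        marked = {0, 1, 2}
        draws = list(itertools.combinations(range(10), 4))
        assert len(draws) == 210
        hits = sum(1 for d in draws if len(marked & set(d)) >= 2)
        assert hits == 70
        assert hypergeom_sf(2, 10, 3, 4) == pytest.approx(hits / 210, rel=1e-12)

    def test_certain_event(self):
        # all N genes are in the category: every draw scores n
        assert hypergeom_sf(4, 10, 10, 4) == 1.0

    def test_matches_integer_oracle_on_sample_grid(self):
        for N in (5, 17, 40):
            for K in range(N + 1):
                for n in (0, 1, N // 2, N):
                    for k in range(min(K, n) + 2):
                        assert hypergeom_sf(k, N, K, n) == pytest.approx(
                            sf_oracle(k, N, K, n), rel=1e-9, abs=1e-300)

    def test_matches_scipy_cross_check(self):
        # second independent route, including a deep tail
        cases = [(2, 10, 3, 4), (19, 15200, 400, 38), (7, 100, 30, 20)]
        for k, N, K, n in cases:
            assert hypergeom_sf(k, N, K, n) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    @given(st.integers(1, 40), st.data())
    def test_non_increasing_in_k(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        values = [hypergeom_sf(k, N, K, n) for k in range(min(K, n) + 2)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_precondition_violations_raise(self):
        with pytest.raises(ValueError):
            hypergeom_sf(-1, 10, 3, 4)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 10, 11, 4)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 10, 3, 11)


def blast_line(q, s, evalue, bitscore):
    return (f"{q}\t{s}\t99.0\t100\t1\t0\t1\t100\t1\t100\t{evalue}\t{bitscore}")


class TestResolveHits:
    GENE_MAP = {"g1": "c1", "g2": "c2"}

    def write(self, tmp_path, name, lines):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_best_transcript_hit_wins(self, tmp_path):
        m2t = self.write(tmp_path, "m2t.tsv", [
            blast_line("mk1", "t_weak", "1e-5", "50"),
            blast_line("mk1", "t_strong", "1e-30", "200"),
        ])
        t2g = self.write(tmp_path, "t2g.tsv", [
            blast_line("t_strong", "g1", "1e-20", "150"),
            blast_line("t_weak", "g2", "1e-20", "150"),
        ])
        (chain,) = resolve_hits(m2t, t2g, self.GENE_MAP)
        assert chain.transcript_id == "t_strong"
        assert chain.gene_id == "g1"
        assert chain.chromosome == "c1"

    def test_evalue_threshold_drops_chain_at_second_step(self, tmp_path):
        m2t = self.write(tmp_path, "m2t.tsv",
                         [blast_line("mk1", "t1", "1e-30", "200")])
        t2g = self.write(tmp_path, "t2g.tsv",
                         [blast_line("t1", "g1", "1e-3", "40")])
        assert resolve_hits(m2t, t2g, self.GENE_MAP, evalue_max=1e-10) == []

    def test_two_markers_one_gene_collapse(self, tmp_path):
        m2t = self.write(tmp_path, "m2t.tsv", [
            blast_line("mk1", "t1", "1e-30", "200"),
            blast_line("mk2", "t1", "1e-25", "180"),
        ])
        t2g = self.write(tmp_path, "t2g.tsv",
                         [blast_line("t1", "g1", "1e-20", "150")])
        chains = resolve_hits(m2t, t2g, self.GENE_MAP)
        assert len(chains) == 1
        assert chains[0].marker_id == "mk1"  # best marker e-value kept

    def test_tie_breaks_by_bitscore_then_subject(self, tmp_path):
        m2t = self.write(tmp_path, "m2t.tsv", [
            blast_line("mk1", "t_b", "1e-30", "100"),
            blast_line("mk1", "t_a", "1e-30", "200"),
        ])
        t2g = self.write(tmp_path, "t2g.tsv", [
            blast_line("t_a", "g1", "1e-20", "150"),
            blast_line("t_b", "g2", "1e-20", "150"),
        ])
        (chain,) = resolve_hits(m2t, t2g, self.GENE_MAP)
        assert chain.transcript_id == "t_a"

    def test_gene_missing_from_annotation_hard_error(self, tmp_path):
        m2t = self.write(tmp_path, "m2t.tsv",
                         [blast_line("mk1", "t1", "1e-30", "200")])
        t2g = self.write(tmp_path, "t2g.tsv",
                         [blast_line("t1", "g_unknown", "1e-20", "150")])
        with pytest.raises(ValueError, match="absent from the annotation"):
            resolve_hits(m2t, t2g, self.GENE_MAP)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(blast_line("a", "b", "1e-5", "10") + "\nonly\tthree\tcols\n")
        with pytest.raises(ValueError, match="line 2"):
            read_blast6(path)


def chains_on(chrom_counts):
    """HitChains with the given per-chromosome gene tallies."""
    chains = []
    for chrom, count in chrom_counts.items():
        for i in range(count):
            gene = f"{chrom}_g{i}"
            chains.append(HitChain(f"mk_{gene}", f"t_{gene}", gene, chrom,
                                   1e-30, 1e-20))
    return chains


class TestEnrichmentTable:
    def test_expected_counts_proportional_to_annotation(self):
        annotation = AnnotationTable({"c1": 10, "c2": 90})
        result = enrichment_table(chains_on({"c1": 2, "c2": 18}), annotation)
        by_chrom = {r.chromosome: r for r in result.rows}
        assert by_chrom["c1"].expected == pytest.approx(2.0)
        assert by_chrom["c2"].expected == pytest.approx(18.0)

    def test_expected_sums_to_n(self):
        annotation = AnnotationTable({"c1": 13, "c2": 29, "c3": 58})
        result = enrichment_table(chains_on({"c1": 4, "c2": 1, "c3": 2}),
                                  annotation)
        assert sum(r.expected for r in result.rows) == pytest.approx(7, abs=1e-9)
        assert sum(r.observed for r in result.rows) == 7

    def test_certain_event_p_one(self):
        annotation = AnnotationTable({"c1": 10})
        result = enrichment_table(chains_on({"c1": 4}), annotation)
        assert result.rows[0].p == 1.0

    def test_worked_p_one_third(self):
        """annotation {c1:3, c2:7}, n=4 drawn, 2 on c1: p(c1)=1/3 by the
        same exhaustive enumeration as the scalar test."""
        annotation = AnnotationTable({"c1": 3, "c2": 7})
        result = enrichment_table(chains_on({"c1": 2, "c2": 2}), annotation)
        assert result.top_chromosome == "c1"
        assert result.top_p == pytest.approx(1 / 3, rel=1e-12)

    def test_bonferroni_flag_adjusts_significance_only(self):
        annotation = AnnotationTable({"c1": 5, "c2": 95, "c3": 100})
        chains = chains_on({"c1": 4, "c2": 1})
        raw = enrichment_table(chains, annotation, alpha=0.05)
        adj = enrichment_table(chains, annotation, alpha=0.05, bonferroni=True)
        assert [r.p for r in raw.rows] == [r.p for r in adj.rows]
        assert sum(r.significant for r in adj.rows) <= sum(
            r.significant for r in raw.rows)

    def test_unknown_chromosome_hard_error(self):
        annotation = AnnotationTable({"c1": 10})
        with pytest.raises(ValueError, match="missing from the annotation"):
            enrichment_table(chains_on({"cX": 1}), annotation)

    def test_empty_chains_rejected(self):
        with pytest.raises(ValueError, match="no resolved"):
            enrichment_table([], AnnotationTable({"c1": 1}))


class TestAnnotationTable:
    def test_gene_level_tsv(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text("gene_id\tchromosome\ng1\tc1\ng2\tc1\ng3\tc2\n")
        table = AnnotationTable.from_tsv(path)
        assert table.counts == {"c1": 2, "c2": 1}
        assert table.gene_to_chromosome["g3"] == "c2"

    def test_counts_tsv(self, tmp_path):
        path = tmp_path / "annot.tsv"
        path.write_text("chromosome\tgene_count\nc1\t10\nc2\t90\n")
        table = AnnotationTable.from_tsv(path)
        assert table.total == 100
        assert table.gene_to_chromosome is None

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="zero genes"):
            AnnotationTable({"c1": 0})


class TestSyntheticSyntenyInputs:
    def test_end_to_end_resolution(self, tmp_path):
        paths = simulate_synteny_inputs(tmp_path, seed=4)
        annotation = AnnotationTable.from_tsv(paths["annotation"])
        chains = resolve_hits(
            paths["markers_vs_transcripts"], paths["transcripts_vs_genes"],
            annotation.gene_to_chromosome)
        assert len(chains) == 38  # unique genes
        on_target = sum(c.chromosome == "chr10" for c in chains)
        assert on_target == 19
        assert annotation.counts["chr10"] == 400
        assert annotation.total == 15200
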