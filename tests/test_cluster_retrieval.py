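import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgc_ecoscreen.cluster_retrieval import (
    ClusterModel,
    RetrievalParams,
    chain_and_consolidate,
    classify_and_prune,
    filter_homologs,
    retrieve_clusters,
    tabulate_counts,
)
from mgc_ecoscreen.core_io import GeneRecord, GenomeAnnotation, HomologyHit

from oracles import chain_brute_force

PARAMS = RetrievalParams()


def make_hit(query="q1", gene="g0", genome="G", bitscore=100.0, identity=50.0,
             aln=100, qlen=100):
    return HomologyHit(query, genome, gene, identity, aln, bitscore, qlen)


def make_genome(starts_ends, genome="G", contig="c1"):
    """Genome from a list of (start, end) pairs; gene ids g0, g1, ... in
    input (rank) order."""
    records = [
        GeneRecord(f"g{i}", contig, s, e, "+")
        for i, (s, e) in enumerate(starts_ends)
    ]
    return GenomeAnnotation.from_records(genome, records)


def uniform_genome(n, gene_len=1000, gap=500, **kw):
    starts = [1 + i * (gene_len + gap) for i in range(n)]
    return make_genome([(s, s + gene_len - 1) for s in starts], **kw)


class TestFilterHomologs:
    @pytest.mark.parametrize(
        "bitscore,identity,aln,qlen,accepted",
        [
            (49.9, 80.0, 100, 100, False),   # below minimum bitscore
            (50.0, 30.0, 50, 100, True),     # all boundaries inclusive
            (100.0, 29.9, 100, 100, False),  # below identity floor
            (100.0, 80.0, 160, 100, False),  # coverage 1.6 > 1.5
            (100.0, 80.0, 150, 100, True),   # coverage exactly 1.5
            (100.0, 80.0, 49, 100, False),   # coverage 0.49 < 0.5
        ],
    )
    def test_threshold_boundaries(self, bitscore, identity, aln, qlen, accepted):
        hit = make_hit(bitscore=bitscore, identity=identity, aln=aln, qlen=qlen)
        assert bool(filter_homologs([hit], PARAMS)) is accepted

    def test_multiple_queries_per_gene_retained(self):
        hits = [make_hit(query="q1"), make_hit(query="q2")]
        assert len(filter_homologs(hits, PARAMS)) == 2


class TestChaining:
    def _clusters_for_ranks(self, ranks, n_genes=20, gene_len=1000, gap=500):
        genome = uniform_genome(n_genes, gene_len, gap)
        hits = [make_hit(gene=f"g{r}") for r in ranks]
        return chain_and_consolidate(genome, hits, PARAMS)

    def test_six_intervening_joins(self):
        # ranks 0 and 7: exactly 6 intervening genes -> one cluster
        clusters = self._clusters_for_ranks([0, 7])
        assert len(clusters) == 1

    def test_seven_intervening_with_large_gap_splits(self):
        # ranks 0 and 8 (7 intervening) on a sparse contig where the
        # genomic gap also exceeds the consolidation limit
        genome = uniform_genome(10, gene_len=1000, gap=5000)
        hits = [make_hit(gene="g0"), make_hit(gene="g8")]
        clusters = chain_and_consolidate(genome, hits, PARAMS)
        assert len(clusters) == 2

    @pytest.mark.parametrize("gap_bp,n_expected", [(29_999, 1), (30_000, 2)])
    def test_consolidation_strictly_below_30kb(self, gap_bp, n_expected):
        # two chains of two adjacent genes each, separated by 8 intervening
        # genes; the genomic gap between spans is exactly gap_bp
        gene_len, small_gap = 100, 10
        coords = []
        cursor = 1
        for i in range(12):
            coords.append((cursor, cursor + gene_len - 1))
            cursor += gene_len + small_gap
        # shift the last two genes so that the inter-chain span gap is gap_bp
        chain1_end = coords[1][1]
        shift_start = chain1_end + gap_bp + 1
        width = coords[11][1] - coords[10][0]
        coords[10] = (shift_start, shift_start + gene_len - 1)
        coords[11] = (shift_start + gene_len + small_gap,
                      shift_start + gene_len + small_gap + gene_len - 1)
        genome = make_genome(coords)
        hits = [make_hit(gene=g) for g in ("g0", "g1", "g10", "g11")]
        clusters = chain_and_consolidate(genome, hits, PARAMS)
        assert len(clusters) == n_expected

    def test_empty_input(self):
        genome = uniform_genome(5)
        assert chain_and_consolidate(genome, [], PARAMS) == []

    def test_members_ordered_and_span_covers(self):
        clusters = self._clusters_for_ranks([3, 1, 5])
        (c,) = clusters
        assert c.member_gene_ids == ["g1", "g3", "g5"]
        assert c.span_start <= 1 * 1500 + 1 and c.span_end >= 5 * 1500


class TestClassify:
    MODEL = ClusterModel(
        "m", frozenset({"q_core_a", "q_core_b", "q_acc"}),
        {"q_core_a": "CCH", "q_core_b": "PMO"},
    )

    def _cluster(self, matched):
        genome = uniform_genome(len(matched))
        hits = [
            make_hit(query=q, gene=f"g{i}")
            for i, qs in enumerate(matched) for q in qs
        ]
        chained = chain_and_consolidate(genome, hits, PARAMS)
        return classify_and_prune(chained, self.MODEL, PARAMS)

    def test_hybrid_label_sorted_hyphenated(self):
        retained = self._cluster([["q_core_b"], ["q_acc"], ["q_core_a"]])
        assert [c.class_label for c in retained] == ["CCH-PMO"]

    def test_no_core_dropped(self):
        assert self._cluster([["q_acc"], ["q_acc"], ["q_acc"]]) == []

    def test_lone_core_dropped_at_default_min_size(self):
        assert self._cluster([["q_core_a"]]) == []


class TestTabulate:
    def test_counts_and_zero_rows(self):
        # two well-separated planted clusters (17 intervening genes, > 30 kb)
        genomes = [uniform_genome(30, gap=5000, genome=g) for g in ("G1", "G2")]
        model = ClusterModel("m", frozenset({"qc", "qa"}), {"qc": "SAH"})
        hits = [
            make_hit(query="qc", gene="g1", genome="G1"),
            make_hit(query="qa", gene="g2", genome="G1"),
            make_hit(query="qc", gene="g20", genome="G1"),
            make_hit(query="qa", gene="g21", genome="G1"),
        ]
        clusters = []
        for g in genomes:
            clusters.extend(retrieve_clusters(g, hits, model))
        counts = tabulate_counts(clusters, genomes, by="class")
        assert counts.loc["G1", "SAH"] == 2
        assert counts.loc["G2", "SAH"] == 0
        assert counts.loc["G1", "SAH__prop"] == pytest.approx(2 / 30)

    def test_unknown_genome_rejected(self):
        genome = uniform_genome(10, genome="G1")
        model = ClusterModel("m", frozenset({"qc"}), {"qc": "SAH"})
        hits = [make_hit(query="qc", gene="g1", genome="G1"),
                make_hit(query="qc", gene="g2", genome="G1")]
        clusters = retrieve_clusters(genome, hits, model)
        with pytest.raises(KeyError):
            tabulate_counts(clusters, [uniform_genome(5, genome="G9")])


@st.composite
def contig_scenario(draw):
    n_genes = draw(st.integers(4, 12))
    gaps = draw(st.lists(st.integers(1, 40_000), min_size=n_genes, max_size=n_genes))
    lengths = draw(st.lists(st.integers(50, 2000), min_size=n_genes, max_size=n_genes))
    coords = []
    cursor = 1
    for length, gap in zip(lengths, gaps):
        coords.append((cursor, cursor + length - 1))
        cursor += length + gap
    k = draw(st.integers(1, n_genes))
    homolog_ranks = sorted(draw(st.permutations(range(n_genes)))[:k])
    return coords, homolog_ranks


class TestChainingProperties:
    @settings(max_examples=120, deadline=None)
    @given(contig_scenario())
    def test_agrees_with_brute_force_and_partitions(self, scenario):
        coords, ranks = scenario
        genome = make_genome(coords)
        hits = [make_hit(gene=f"g{r}") for r in ranks]
        clusters = chain_and_consolidate(genome, hits, PARAMS)
        # partition: each homolog in exactly one cluster
        members = [g for c in clusters for g in c.member_gene_ids]
        assert sorted(members) == sorted(f"g{r}" for r in ranks)
        # brute-force fixed-point oracle
        rp = [(r, coords[r][0], coords[r][1]) for r in ranks]
        expected = chain_brute_force(rp, PARAMS.max_intervening, PARAMS.max_gap_bp)
        got = [
            [ranks.index(int(g[1:])) for g in c.member_gene_ids]
            for c in clusters
        ]
        assert got == expected

    @settings(max_examples=60, deadline=None)
    @given(contig_scenario(), st.integers(0, 3), st.integers(0, 20_000))
    def test_monotone_in_thresholds(self, scenario, extra_intervening, extra_gap):
        coords, ranks = scenario
        genome = make_genome(coords)
        hits = [make_hit(gene=f"g{r}") for r in ranks]
        tight = chain_and_consolidate(genome, hits, PARAMS)
        loose_params = RetrievalParams(
            max_intervening=PARAMS.max_intervening + extra_intervening,
            max_gap_bp=PARAMS.max_gap_bp + extra_gap,
        )
        loose = chain_and_consolidate(genome, hits, loose_params)
        assert len(loose) <= len(tight)
        assert (sum(c.n_members for c in loose)
                == sum(c.n_members for c in tight))

    @settings(max_examples=60, deadline=None)
    @given(contig_scenario())
    def test_consolidation_idempotent(self, scenario):
        coords, ranks = scenario
        genome = make_genome(coords)
        hits = [make_hit(gene=f"g{r}") for r in ranks]
        once = chain_and_consolidate(genome, hits, PARAMS)
        # re-run on the member genes of the consolidated output
        again_hits = [
            make_hit(gene=g) for c in once for g in c.member_gene_ids
        ]
        again = chain_and_consolidate(genome, again_hits, PARAMS)
        assert [c.member_gene_ids for c in again] == [c.member_gene_ids for c in once]
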