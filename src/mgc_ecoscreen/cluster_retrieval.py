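"""Core-gene-anchored metabolic gene cluster retrieval.

Homologs of a cluster model's query genes are filtered on bitscore, percent
identity and query coverage, then chained along each contig: two homologs
join one chain when at most ``max_intervening`` annotated genes lie between
them (measured in contig gene rank, not base pairs). Chains on one contig
are consolidated when the genomic gap between their spans is strictly less
than ``max_gap_bp``. Retained clusters must contain a homolog of at least
one *core* query — the signature catabolic enzyme that defines a cluster
class — and at least ``min_cluster_genes`` members. A cluster matching core
genes of several classes gets a hybrid class label (e.g. ``CCH-PMO``).

All score/identity/coverage thresholds are inclusive ("minimum" read as >=);
the consolidation gap is strict ("less than").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import GenomeAnnotation, HomologyHit

logger = logging.getLogger("mgc_ecoscreen")


@dataclass(frozen=True)
class RetrievalParams:
    min_bitscore: float = 50.0
    min_identity: float = 30.0
    min_coverage: float = 0.5
    max_coverage: float = 1.5
    max_intervening: int = 6
    max_gap_bp: int = 30_000
    min_cluster_genes: int = 2

    def __post_init__(self) -> None:
        if not self.min_coverage < self.max_coverage:
            raise ValueError("min_coverage must be < max_coverage")
        if min(
            self.min_bitscore, self.min_identity, self.min_coverage,
            self.max_intervening, self.max_gap_bp, self.min_cluster_genes,
        ) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class ClusterModel:
    """A query-gene model: member queries plus core queries labelled with
    their cluster class (core type)."""

    model_id: str
    member_queries: frozenset[str]
    core_queries: dict[str, str]  # query_id -> core_type label

    def __post_init__(self) -> None:
        if not self.core_queries:
            raise ValueError("model must declare at least one core query")
        if not set(self.core_queries) <= set(self.member_queries):
            raise ValueError("core queries must be a subset of member queries")


@dataclass
class RetrievedCluster:
    cluster_id: str
    genome_id: str
    contig_id: str
    member_gene_ids: list[str]           # ordered by contig rank
    matched_queries: dict[str, set[str]]  # gene_id -> query ids matched
    core_types: set[str]
    span_start: int
    span_end: int
    class_label: str = ""

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


def filter_homologs(
    hits: list[HomologyHit], params: RetrievalParams
) -> list[HomologyHit]:
    """Keep hits with bitscore >= min, identity >= min, and query coverage
    (alignment_length / query_length) inside [min_coverage, max_coverage],
    all boundaries inclusive. A subject gene may retain hits to several
    queries."""
    kept: list[HomologyHit] = []
    for hit in hits:
        if hit.query_length <= 0:
            logger.warning(
                "hit %s->%s has query_length %d — rejected",
                hit.query_id, hit.subject_gene_id, hit.query_length,
            )
            continue
        coverage = hit.alignment_length / hit.query_length
        if (
            hit.bitscore >= params.min_bitscore
            and hit.percent_identity >= params.min_identity
            and params.min_coverage <= coverage <= params.max_coverage
        ):
            kept.append(hit)
    return kept


def chain_and_consolidate(
    genome: GenomeAnnotation,
    hits: list[HomologyHit],
    params: RetrievalParams,
) -> list[RetrievedCluster]:
    """Chain accepted homologs per contig and consolidate nearby chains.

    Per contig, homolog genes sorted by rank join one chain when the count of
    intervening genes (rank difference - 1) is at most ``max_intervening``.
    Adjacent chains merge when the genomic gap between spans
    (next span_start - previous span_end - 1) is < ``max_gap_bp``; merging is
    applied left-to-right to a fixed point. Class assignment and pruning are
    left to :func:`classify_and_prune`.
    """
    gene_index = genome.gene_index()
    per_contig: dict[str, dict[str, set[str]]] = {}
    for hit in hits:
        if hit.subject_genome_id != genome.genome_id:
            continue
        gene = gene_index.get(hit.subject_gene_id)
        if gene is None:
            raise KeyError(
                f"hit references gene {hit.subject_gene_id!r} absent from "
                f"genome {genome.genome_id!r}"
            )
        per_contig.setdefault(gene.contig_id, {}).setdefault(
            gene.gene_id, set()
        ).add(hit.query_id)

    clusters: list[RetrievedCluster] = []
    for contig_id in sorted(per_contig):
        matched = per_contig[contig_id]
        genes = sorted(
            (gene_index[g] for g in matched), key=lambda g: g.rank
        )
        # chaining by intervening-gene count
        chains: list[list] = []
        for gene in genes:
            if chains and gene.rank - chains[-1][-1].rank - 1 <= params.max_intervening:
                chains[-1].append(gene)
            else:
                chains.append([gene])
        # left-to-right consolidation to a fixed point (single pass suffices:
        # merging only moves the right boundary rightwards)
        consolidated: list[list] = []
        for chain in chains:
            if consolidated:
                prev = consolidated[-1]
                gap = chain[0].start - max(g.end for g in prev) - 1
                if gap < params.max_gap_bp:
                    prev.extend(chain)
                    continue
            consolidated.append(chain)
        for members in consolidated:
            clusters.append(
                RetrievedCluster(
                    cluster_id="",  # assigned after pruning
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    member_gene_ids=[g.gene_id for g in members],
                    matched_queries={g.gene_id: set(matched[g.gene_id]) for g in members},
                    core_types=set(),
                    span_start=min(g.start for g in members),
                    span_end=max(g.end for g in members),
                )
            )
    return clusters


def classify_and_prune(
    clusters: list[RetrievedCluster],
    model: ClusterModel,
    params: RetrievalParams,
) -> list[RetrievedCluster]:
    """Drop clusters lacking a core-query homolog or with too few members;
    label the rest by the core types present (lexicographic, hyphen-joined;
    multi-core clusters get hybrid labels)."""
    retained: list[RetrievedCluster] = []
    for cluster in clusters:
        core_types: set[str] = set()
        for queries in cluster.matched_queries.values():
            for q in queries:
                if q in model.core_queries:
                    core_types.add(model.core_queries[q])
        if not core_types or cluster.n_members < params.min_cluster_genes:
            continue
        cluster.core_types = core_types
        cluster.class_label = "-".join(sorted(core_types))
        retained.append(cluster)
    for i, cluster in enumerate(retained):
        cluster.cluster_id = (
            f"{cluster.genome_id}|{model.model_id}|{i:03d}"
        )
    return retained


def retrieve_clusters(
    genome: GenomeAnnotation,
    hits: list[HomologyHit],
    model: ClusterModel,
    params: RetrievalParams | None = None,
) -> list[RetrievedCluster]:
    """Full retrieval for one genome and one cluster model: filter hits to
    the model's queries, chain, consolidate, classify, prune."""
    params = params or RetrievalParams()
    model_hits = [h for h in hits if h.query_id in model.member_queries]
    accepted = filter_homologs(model_hits, params)
    chained = chain_and_consolidate(genome, accepted, params)
    return classify_and_prune(chained, model, params)


def tabulate_counts(
    clusters: list[RetrievedCluster],
    genomes: list[GenomeAnnotation],
    by: str = "class",
    family_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genome cluster counts by class or family, plus proportion columns.

    Returns one row per genome (zero rows included) with one count column per
    class/family and, for each, a ``<name>__prop`` column giving
    count / total_gene_count.
    """
    genome_ids = [g.genome_id for g in genomes]
    totals = {g.genome_id: g.total_gene_count for g in genomes}
    known = set(genome_ids)
    for c in clusters:
        if c.genome_id not in known:
            raise KeyError(f"cluster genome {c.genome_id!r} absent from genome list")

    if by == "class":
        key = lambda c: c.class_label
    elif by == "family":
        if family_of is None:
            raise ValueError("by='family' requires a cluster_id -> family map")
        key = lambda c: family_of[c.cluster_id]
    else:
        raise ValueError("by must be 'class' or 'family'")

    labels = sorted({key(c) for c in clusters})
    counts = pd.DataFrame(0, index=pd.Index(genome_ids, name="genome_id"),
                          columns=labels, dtype=float)
    for c in clusters:
        counts.loc[c.genome_id, key(c)] += 1
    for label in labels:
        counts[f"{label}__prop"] = counts[label] / pd.Series(totals)
    return counts
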