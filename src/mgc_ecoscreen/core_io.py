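"""Input/output layer: trees, gene tables, homology hit tables, metadata.

All coordinates are 1-based inclusive (GFF3 convention). Strand is read and
stored but plays no role in downstream clustering, which is strand-agnostic.

The trait matrix is a plain :class:`pandas.DataFrame` (rows = genomes,
columns = traits, nonnegative counts); the ecology table is a DataFrame
indexed by genome with ``endophyte`` and ``nutritional_mode`` columns drawn
from fixed vocabularies.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("mgc_ecoscreen")

ENDOPHYTE_STATES = ("yes", "no", "potential", "unknown")
NUTRITIONAL_MODES = ("mycotroph", "saprotroph", "unknown")

#: Case-insensitive normalization applied to ecology metadata. Strings not
#: in this table are errors, never silent unknowns.
ECOLOGY_VOCABULARY: dict[str, str] = {
    "yes": "yes",
    "endophyte": "yes",
    "no": "no",
    "non-endophyte": "no",
    "nonendophyte": "no",
    "potential": "potential",
    "potential endophyte": "potential",
    "unknown": "unknown",
    "na": "unknown",
}

MODE_VOCABULARY: dict[str, str] = {
    "mycotroph": "mycotroph",
    "mycotrophic": "mycotroph",
    "saprotroph": "saprotroph",
    "saprotrophic": "saprotroph",
    "unknown": "unknown",
    "na": "unknown",
}


# ---------------------------------------------------------------------------
# Gene and genome records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene on one contig; ``rank`` is its 0-based position among the
    contig's genes ordered by ascending start (ties: end, then gene_id)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    """Ordered gene coordinates for one genome, grouped by contig."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)

    @property
    def total_gene_count(self) -> int:
        return sum(len(g) for g in self.contigs.values())

    def gene_index(self) -> dict[str, GeneRecord]:
        idx: dict[str, GeneRecord] = {}
        for genes in self.contigs.values():
            for g in genes:
                if g.gene_id in idx:
                    raise ValueError(
                        f"duplicate gene_id {g.gene_id!r} in genome "
                        f"{self.genome_id!r}"
                    )
                idx[g.gene_id] = g
        return idx

    @classmethod
    def from_records(
        cls, genome_id: str, records: Iterable[GeneRecord]
    ) -> "GenomeAnnotation":
        """Group records by contig and (re)assign per-contig ranks."""
        by_contig: dict[str, list[GeneRecord]] = {}
        for rec in records:
            by_contig.setdefault(rec.contig_id, []).append(rec)
        contigs: dict[str, list[GeneRecord]] = {}
        for contig_id in sorted(by_contig):
            genes = sorted(
                by_contig[contig_id], key=lambda g: (g.start, g.end, g.gene_id)
            )
            contigs[contig_id] = [
                GeneRecord(g.gene_id, g.contig_id, g.start, g.end, g.strand, r)
                for r, g in enumerate(genes)
            ]
        ann = cls(genome_id=genome_id, contigs=contigs)
        ann.gene_index()  # uniqueness check
        return ann


@dataclass(frozen=True)
class HomologyHit:
    """One similarity-search hit of a model query against a genome gene."""

    query_id: str
    subject_genome_id: str
    subject_gene_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, flattened to index arrays.

    Nodes ``0..n_tips-1`` are tips (in ``tip_labels`` order); internal nodes
    follow. ``parent[root] == -1`` and ``edge_length[root] == 0``. The
    flattened form makes covariance construction and post-order sweeps over
    many trait columns a handful of numpy operations.
    """

    tip_labels: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]]
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for node in reversed(self.postorder()):  # preorder
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.edge_length[node]
        return depth[: self.n_tips]

    def is_binary(self) -> bool:
        return all(
            len(c) in (0, 2) for c in self.children
        )

    def resolve_polytomies(self) -> "Phylogeny":
        """Deterministically resolve multifurcations into zero-length binary
        splits, left-to-right by child order. Returns self if already binary."""
        if self.is_binary():
            return self
        parent = list(self.parent)
        edge = list(self.edge_length)
        children = [list(c) for c in self.children]
        node = 0
        while node < len(children):
            while len(children[node]) > 2:
                kids = children[node]
                new = len(parent)
                parent.append(node)
                edge.append(0.0)
                a, b = kids[0], kids[1]
                children.append([a, b])
                parent[a] = parent[b] = new
                children[node] = [new] + kids[2:]
            node += 1
        return Phylogeny(
            tip_labels=list(self.tip_labels),
            parent=np.asarray(parent, dtype=np.int64),
            edge_length=np.asarray(edge, dtype=float),
            children=children,
            root=self.root,
        )

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if not self.children[node]:
                label = self.tip_labels[node]
            else:
                label = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            if node == self.root:
                return label
            return f"{label}:{self.edge_length[node]:.10g}"

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths into a Phylogeny.

    A missing root edge length is treated as 0; any other missing or negative
    branch length, a duplicate tip label, or malformed Newick is rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    droot = dtree.seed_node
    tips = [nd for nd in dnodes if nd.is_leaf()]
    labels = [
        (nd.taxon.label if nd.taxon is not None else None) for nd in tips
    ]
    if any(lbl is None for lbl in labels):
        raise ValueError("tip without label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")

    index = {id(nd): i for i, nd in enumerate(tips)}
    internals = [nd for nd in dnodes if not nd.is_leaf()]
    for nd in internals:
        index[id(nd)] = len(index)

    n_nodes = len(dnodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    edge = np.zeros(n_nodes, dtype=float)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for nd in dnodes:
        i = index[id(nd)]
        if nd is droot:
            edge[i] = nd.edge.length or 0.0
            continue
        parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is None:
            raise ValueError(f"missing branch length above node {i}")
        if nd.edge.length < 0:
            raise ValueError(f"negative branch length {nd.edge.length}")
        edge[i] = float(nd.edge.length)
        children[parent[i]].append(i)
    # restore child order as written
    for nd in internals:
        children[index[id(nd)]] = [index[id(c)] for c in nd.child_nodes()]
    root = index[id(droot)]
    edge[root] = 0.0  # missing root edge length treated as 0
    return Phylogeny(
        tip_labels=[str(l) for l in labels],
        parent=parent,
        edge_length=edge,
        children=children,
        root=root,
    )


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

_TSV_GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand"]


def read_gene_table(
    path: str | Path,
    format: str = "tsv",
    genome_id: str | None = None,
    gff_type: str = "gene",
) -> GenomeAnnotation:
    """Read a gene coordinate table (TSV dialect or GFF3) into an annotation.

    TSV columns: gene_id, contig_id, start, end, strand (header required).
    GFF3: records whose feature type equals ``gff_type`` are used; the gene
    identifier is the ``ID`` attribute. Records with start > end are skipped
    with a warning; overlapping genes are allowed.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records: list[GeneRecord] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _TSV_GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gene table {path} missing columns {missing}")
        rows = (
            (r.gene_id, r.contig_id, int(r.start), int(r.end), r.strand)
            for r in df.itertuples()
        )
    elif format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        rows = (
            (f.id, f.seqid, f.start, f.end, f.strand if f.strand in "+-" else "+")
            for f in db.features_of_type(gff_type)
        )
    else:
        raise ValueError(f"unknown gene table format {format!r}")

    for gene_id, contig_id, start, end, strand in rows:
        if start > end:
            logger.warning(
                "gene %s on %s: start %d > end %d — record skipped",
                gene_id, contig_id, start, end,
            )
            continue
        records.append(GeneRecord(gene_id, contig_id, start, end, strand))
    if not records:
        logger.warning("gene table %s yielded no records", path)
    return GenomeAnnotation.from_records(genome_id, records)


#: column names of 12-column tabular similarity-search output
HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_separator: str = "|",
) -> list[HomologyHit]:
    """Read 12-column tabular similarity-search output into HomologyHit rows.

    The subject field is parsed as ``genome_id<sep>gene_id``. Query lengths
    (amino acids) come from the companion ``query_lengths`` table; rows whose
    query is absent from it are dropped with a warning. An empty file yields
    an empty list.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line and len(line.split("\t")) < 12:
            raise ValueError(
                f"{path}:{lineno}: fewer than 12 tab-separated columns"
            )
    df = pd.read_csv(
        io.StringIO(text), sep="\t", names=HIT_TABLE_COLUMNS, header=None
    )
    hits: list[HomologyHit] = []
    for row in df.itertuples():
        query = str(row.qseqid)
        if query not in query_lengths:
            logger.warning("query %s missing from length table — row dropped", query)
            continue
        qlen = int(query_lengths[query])
        if qlen <= 0:
            logger.warning("query %s has non-positive length — row dropped", query)
            continue
        subject = str(row.sseqid)
        if subject_separator not in subject:
            raise ValueError(
                f"subject {subject!r} lacks separator {subject_separator!r}"
            )
        genome, gene = subject.split(subject_separator, 1)
        hits.append(
            HomologyHit(
                query_id=query,
                subject_genome_id=genome,
                subject_gene_id=gene,
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                bitscore=float(row.bitscore),
                query_length=qlen,
            )
        )
    return hits


def write_hit_table(
    hits: Iterable[HomologyHit], path: str | Path, subject_separator: str = "|"
) -> None:
    """Write hits as 12-column tabular similarity-search output (no header),
    the exact dialect :func:`read_hit_table` consumes. Placeholder columns
    (mismatch, gapopen, coordinates, evalue) are synthesized."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            subject = f"{h.subject_genome_id}{subject_separator}{h.subject_gene_id}"
            fh.write(
                "\t".join(str(v) for v in (
                    h.query_id, subject, f"{h.percent_identity:.2f}",
                    h.alignment_length, 0, 0, 1, h.alignment_length,
                    1, h.alignment_length, "1e-20", f"{h.bitscore:.1f}",
                )) + "\n"
            )


def read_query_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (query_id, amino-acid length) -> mapping; a header
    row is detected and skipped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query_id", "length"],
                     dtype=str)
    rows = list(df.itertuples())
    if rows and not str(rows[0].length).isdigit():
        rows = rows[1:]
    return {str(r.query_id): int(r.length) for r in rows}


def read_trait_matrix(traits_path: str | Path) -> pd.DataFrame:
    """Genome × trait count TSV -> validated nonnegative float DataFrame."""
    traits = pd.read_csv(traits_path, sep="\t", index_col=0)
    if traits.index.has_duplicates:
        raise ValueError("duplicate genome ids in trait matrix")
    try:
        traits = traits.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric trait cell: {exc}") from exc
    if (traits.to_numpy() < 0).any():
        raise ValueError("negative trait counts")
    traits.index = traits.index.astype(str)
    return traits


def read_ecology(
    ecology_path: str | Path, genome_ids: Iterable[str]
) -> pd.DataFrame:
    """Read and normalize the ecology table, aligned to ``genome_ids``.

    Ecology strings are normalized case-insensitively through the fixed
    vocabularies; anything outside them is an error. Genomes absent from the
    file get ``unknown`` labels with a warning.
    """
    eco_raw = pd.read_csv(ecology_path, sep="\t", index_col=0, dtype=str)
    if eco_raw.index.has_duplicates:
        raise ValueError("genome appears more than once in ecology table")
    eco_raw.index = eco_raw.index.astype(str)

    def normalize(value: str, vocab: Mapping[str, str], what: str) -> str:
        key = str(value).strip().lower()
        if key not in vocab:
            raise ValueError(f"{what} value {value!r} outside vocabulary")
        return vocab[key]

    rows = {}
    for genome in genome_ids:
        if genome in eco_raw.index:
            rec = eco_raw.loc[genome]
            rows[genome] = (
                normalize(rec["endophyte"], ECOLOGY_VOCABULARY, "endophyte"),
                normalize(rec["nutritional_mode"], MODE_VOCABULARY, "nutritional_mode"),
            )
        else:
            logger.warning(
                "genome %s absent from ecology table — labels set to unknown",
                genome,
            )
            rows[genome] = ("unknown", "unknown")
    ecology = pd.DataFrame.from_dict(
        rows, orient="index", columns=["endophyte", "nutritional_mode"]
    )
    ecology.index.name = "genome_id"
    return ecology


def read_metadata(
    traits_path: str | Path, ecology_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the genome × trait count matrix and the ecology table joined to
    its genomes (TSVs with a header row; first column genome_id)."""
    traits = read_trait_matrix(traits_path)
    return traits, read_ecology(ecology_path, traits.index)


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with header, UTF-8, LF endings; floats are
    rendered with 6 significant digits. ``columns`` fixes the column order
    (required for an empty record list)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
        if columns is not None:
            df = df[list(columns)]
    else:
        if columns is None:
            if not rows:
                raise ValueError("empty record list requires an explicit schema")
            columns = list(rows[0].keys())
        df = pd.DataFrame(list(rows), columns=list(columns))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def validate_identifiers(
    tree: Phylogeny,
    traits: pd.DataFrame | None = None,
    ecology: pd.DataFrame | None = None,
    genomes: Iterable[str] | None = None,
) -> None:
    """Cross-check that tree tips, trait rows, ecology rows, and genome ids
    refer to the same set of genomes; raise listing every mismatch."""
    tips = set(tree.tip_labels)
    problems: list[str] = []
    for name, ids in (
        ("trait matrix", None if traits is None else set(traits.index)),
        ("ecology table", None if ecology is None else set(ecology.index)),
        ("genome list", None if genomes is None else set(genomes)),
    ):
        if ids is None:
            continue
        extra_tips = sorted(tips - ids)
        extra_ids = sorted(ids - tips)
        if extra_tips:
            problems.append(f"tree tips missing from {name}: {extra_tips}")
        if extra_ids:
            problems.append(f"{name} ids missing from tree: {extra_ids}")
    if problems:
        raise ValueError("; ".join(problems))
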