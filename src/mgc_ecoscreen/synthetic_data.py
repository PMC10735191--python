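"""Synthetic inputs with the statistical structure the analysis assumes.

Calibration phylogenies are Yule (pure-birth) trees, so they are ultrametric
and time-like, matching the intuition behind the Brownian covariance C.
Continuous traits are simulated under Brownian motion, a lambda-scaled
covariance, or white noise; binary traits either by thresholding a Brownian
trait at the observed-prevalence quantile or by placing a fixed number of 1s
uniformly at random (exact counts, not per-tip Bernoulli, so dispersion
calibration is not confounded by prevalence variance).

The genome benchmark plants homolog clusters whose hits clear the retrieval
thresholds by a configurable margin (default 20%) and decoy hits that fail
at least one threshold by the same margin, each planted cluster on its own
contig so ground truth is unambiguous. The screen benchmark adds a trait
matrix with Brownian control traits and one phylogeny-free trait enriched in
randomly labelled "endophyte" genomes.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .core_io import GeneRecord, GenomeAnnotation, HomologyHit, Phylogeny, parse_newick
from .cluster_retrieval import ClusterModel, RetrievalParams
from .phylo_signal import lambda_transform, phylo_vcv

DEFAULT_CORE_TYPES = (
    "SAH", "QDH", "ARD", "NAD", "FAD", "PMO", "CCH",
    "BPH", "PAH", "SDO", "VAO", "CAE", "ECL",
)


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, birth_rate: float = 1.0, seed: int | None = None) -> Phylogeny:
    """Yule tree with ``n_tips`` extant tips, relabelled G001..Gnnn.

    Ultrametric by construction; byte-identical Newick under a fixed seed.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; run the clock forward by the Exp(n*birth) waiting
    # time to the next (unrealized) event so the covariance is nonsingular
    extension = rng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"G{i + 1:03d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    newick = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip()
    return parse_newick(newick)


def sim_traits(
    tree: Phylogeny,
    model: str = "brownian",
    sigma2: float = 1.0,
    seed: int | np.random.Generator | None = None,
    lam: float = 1.0,
) -> np.ndarray:
    """One continuous trait vector (ordered as tree.tip_labels).

    ``brownian``: MVN(0, sigma2*C); ``lambda``: MVN(0, sigma2*C(lam));
    ``white``: independent N(0, sigma2) per tip.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_tips
    if model == "white":
        return rng.normal(0.0, np.sqrt(sigma2), n)
    C = phylo_vcv(tree).C
    if model == "lambda":
        C = lambda_transform(C, lam)
    elif model != "brownian":
        raise ValueError("model must be 'brownian', 'lambda', or 'white'")
    L = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def sim_binary_trait(
    tree: Phylogeny,
    prevalence: float,
    mode: str = "brownian_threshold",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Binary trait with exactly ceil(prevalence * n) ones.

    ``brownian_threshold`` thresholds a simulated Brownian trait at the
    matching quantile (clumped states); ``shuffle`` places the 1s uniformly
    at random (no phylogenetic structure).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_tips
    k = int(np.ceil(prevalence * n))
    if k <= 0 or k >= n:
        raise ValueError(f"prevalence {prevalence} leaves {k} of {n} tips in one state")
    x = np.zeros(n)
    if mode == "shuffle":
        x[rng.choice(n, size=k, replace=False)] = 1.0
    elif mode == "brownian_threshold":
        z = sim_traits(tree, "brownian", 1.0, rng)
        x[np.argsort(z)[-k:]] = 1.0
    else:
        raise ValueError("mode must be 'brownian_threshold' or 'shuffle'")
    return x


# ---------------------------------------------------------------------------
# Genome benchmark with planted clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Configuration of the planted-cluster genome benchmark.

    Planted hits are drawn from ranges clearing every retrieval threshold by
    ``margin``; decoy hits fail at least one threshold by the same margin,
    so at default parameters the benchmark's ground truth is exactly
    recoverable.
    """

    seed: int = 0
    n_genomes: int = 12
    clusters_per_genome: tuple[int, int] = (2, 4)
    cluster_size: tuple[int, int] = (3, 5)
    filler_genes_per_contig: tuple[int, int] = (20, 40)
    gene_length_bp: tuple[int, int] = (900, 1800)
    intergenic_bp: tuple[int, int] = (200, 2000)
    decoys_per_genome: int = 25
    margin: float = 0.2
    core_types: tuple[str, ...] = DEFAULT_CORE_TYPES
    accessory_queries_per_type: int = 4
    query_length_aa: int = 400
    endophyte_fraction: float = 0.5
    mycotroph_fraction: float = 0.5
    params: RetrievalParams = field(default_factory=RetrievalParams)


def benchmark_model(config: SimConfig) -> ClusterModel:
    """The retrieval model matching the benchmark: one core query per
    cluster class plus shared accessory queries."""
    members: set[str] = set()
    cores: dict[str, str] = {}
    for t in config.core_types:
        cores[f"Q_{t}_core"] = t
        members.add(f"Q_{t}_core")
        for a in range(config.accessory_queries_per_type):
            members.add(f"Q_{t}_acc{a}")
    return ClusterModel(
        model_id="dgc-benchmark",
        member_queries=frozenset(members),
        core_queries=cores,
    )


def benchmark_query_lengths(config: SimConfig) -> dict[str, int]:
    return {q: config.query_length_aa for q in benchmark_model(config).member_queries}


def _planted_hit(
    rng: np.random.Generator, query: str, genome: str, gene: str, config: SimConfig
) -> HomologyHit:
    p = config.params
    m = config.margin
    qlen = config.query_length_aa
    cov = rng.uniform(p.min_coverage * (1 + m), p.max_coverage * (1 - m))
    return HomologyHit(
        query_id=query,
        subject_genome_id=genome,
        subject_gene_id=gene,
        percent_identity=float(rng.uniform(p.min_identity * (1 + m), 95.0)),
        alignment_length=max(1, int(round(cov * qlen))),
        bitscore=float(rng.uniform(p.min_bitscore * (1 + m), 400.0)),
        query_length=qlen,
    )


def _decoy_hit(
    rng: np.random.Generator, query: str, genome: str, gene: str, config: SimConfig
) -> HomologyHit:
    """A hit guaranteed to fail at least one acceptance threshold."""
    p = config.params
    m = config.margin
    qlen = config.query_length_aa
    bitscore = rng.uniform(p.min_bitscore * (1 + m), 400.0)
    identity = rng.uniform(p.min_identity * (1 + m), 95.0)
    cov = rng.uniform(p.min_coverage * (1 + m), p.max_coverage * (1 - m))
    fail = rng.integers(0, 3)
    if fail == 0:
        bitscore = rng.uniform(5.0, p.min_bitscore * (1 - m))
    elif fail == 1:
        identity = rng.uniform(5.0, p.min_identity * (1 - m))
    else:
        cov = (
            rng.uniform(0.05, p.min_coverage * (1 - m))
            if rng.integers(0, 2) == 0
            else rng.uniform(p.max_coverage * (1 + m), 2.5)
        )
    return HomologyHit(
        query_id=query,
        subject_genome_id=genome,
        subject_gene_id=gene,
        percent_identity=float(identity),
        alignment_length=max(1, int(round(cov * qlen))),
        bitscore=float(bitscore),
        query_length=qlen,
    )


@dataclass
class BenchmarkBundle:
    annotations: list[GenomeAnnotation]
    hits: list[HomologyHit]
    ecology: pd.DataFrame
    truth: pd.DataFrame
    model: ClusterModel
    query_lengths: dict[str, int]


def sim_genome_benchmark(config: SimConfig | None = None) -> BenchmarkBundle:
    """Annotated genomes with planted homolog clusters, decoy hits, ecology
    labels, and a ground-truth table (one row per planted cluster).

    Each planted cluster occupies consecutive genes in the middle of its own
    contig, so clusters never chain across contigs or merge with each other.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    annotations: list[GenomeAnnotation] = []
    hits: list[HomologyHit] = []
    truth_rows: list[dict] = []

    for gi in range(config.n_genomes):
        genome_id = f"G{gi + 1:03d}"
        n_clusters = int(rng.integers(config.clusters_per_genome[0],
                                      config.clusters_per_genome[1] + 1))
        records: list[GeneRecord] = []
        all_gene_ids: list[str] = []
        gene_serial = 0

        def make_contig(contig_id: str, n_genes: int, planted: range | None,
                        core_type: str | None):
            nonlocal gene_serial
            cursor = 1
            contig_genes: list[str] = []
            for i in range(n_genes):
                length = int(rng.integers(*config.gene_length_bp))
                gene_id = f"gene_{gene_serial:05d}"
                gene_serial += 1
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                records.append(
                    GeneRecord(gene_id, contig_id, cursor, cursor + length - 1, strand)
                )
                contig_genes.append(gene_id)
                all_gene_ids.append(gene_id)
                cursor += length + int(rng.integers(*config.intergenic_bp))
            if planted is not None:
                member_ids = [contig_genes[i] for i in planted]
                queries = [f"Q_{core_type}_core"] + [
                    f"Q_{core_type}_acc{a % config.accessory_queries_per_type}"
                    for a in range(len(member_ids) - 1)
                ]
                for gene_id, query in zip(member_ids, queries):
                    hits.append(_planted_hit(rng, query, genome_id, gene_id, config))
                truth_rows.append({
                    "genome_id": genome_id,
                    "contig_id": contig_id,
                    "class_label": core_type,
                    "member_gene_ids": ";".join(member_ids),
                    "n_members": len(member_ids),
                })

        for ci in range(n_clusters):
            n_filler = int(rng.integers(*config.filler_genes_per_contig))
            size = int(rng.integers(config.cluster_size[0], config.cluster_size[1] + 1))
            offset = n_filler // 2
            core_type = str(rng.choice(config.core_types))
            make_contig(f"{genome_id}_ctg{ci + 1}", n_filler + size,
                        range(offset, offset + size), core_type)
        # one decoy-only contig
        make_contig(f"{genome_id}_ctg{n_clusters + 1}",
                    int(rng.integers(*config.filler_genes_per_contig)), None, None)

        annotations.append(GenomeAnnotation.from_records(genome_id, records))

        planted_genes = {
            g for row in truth_rows if row["genome_id"] == genome_id
            for g in row["member_gene_ids"].split(";")
        }
        decoy_targets = [g for g in all_gene_ids if g not in planted_genes]
        queries = sorted(benchmark_model(config).member_queries)
        for _ in range(config.decoys_per_genome):
            gene = decoy_targets[int(rng.integers(len(decoy_targets)))]
            query = queries[int(rng.integers(len(queries)))]
            hits.append(_decoy_hit(rng, query, genome_id, gene, config))

    genome_ids = [a.genome_id for a in annotations]
    n = len(genome_ids)
    endo = np.array(["no"] * n, dtype=object)
    endo[rng.choice(n, size=int(round(config.endophyte_fraction * n)),
                    replace=False)] = "yes"
    mode = np.array(["saprotroph"] * n, dtype=object)
    mode[rng.choice(n, size=int(round(config.mycotroph_fraction * n)),
                    replace=False)] = "mycotroph"
    ecology = pd.DataFrame(
        {"endophyte": endo, "nutritional_mode": mode},
        index=pd.Index(genome_ids, name="genome_id"),
    )
    truth = pd.DataFrame.from_records(truth_rows)
    return BenchmarkBundle(
        annotations=annotations,
        hits=hits,
        ecology=ecology,
        truth=truth,
        model=benchmark_model(config),
        query_lengths=benchmark_query_lengths(config),
    )


# ---------------------------------------------------------------------------
# Screen benchmark
# ---------------------------------------------------------------------------

def sim_ecology(
    genome_ids: list[str],
    endophyte_fraction: float = 0.5,
    mycotroph_fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ecology labels assigned uniformly at random (independent of any
    phylogeny), with fixed group sizes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(genome_ids)
    endo = np.array(["no"] * n, dtype=object)
    endo[rng.choice(n, size=int(round(endophyte_fraction * n)), replace=False)] = "yes"
    mode = np.array(["saprotroph"] * n, dtype=object)
    mode[rng.choice(n, size=int(round(mycotroph_fraction * n)), replace=False)] = "mycotroph"
    return pd.DataFrame(
        {"endophyte": endo, "nutritional_mode": mode},
        index=pd.Index(list(genome_ids), name="genome_id"),
    )


def sim_screen_dataset(
    n_tips: int = 64,
    n_control: int = 5,
    seed: int | None = None,
    planted_fold: float = 3.0,
    base_mean: float = 10.0,
    noise_sd: float = 1.0,
    control_offset: float = 100.0,
    control_sigma2: float = 4.0,
) -> tuple[Phylogeny, pd.DataFrame, pd.DataFrame]:
    """(tree, traits, ecology) with one planted candidate trait.

    The planted trait has no phylogenetic structure (white noise) and a
    ``planted_fold``-times higher mean in endophyte genomes; the control
    traits evolve by Brownian motion around ``control_offset`` and are
    blind to ecology. Labels are assigned at random, independent of the
    tree. Counts are clipped at 0.
    """
    rng = np.random.default_rng(seed)
    tree = sim_tree(n_tips, seed=int(rng.integers(2**31)))
    ecology = sim_ecology(tree.tip_labels, seed=rng)
    is_endo = (ecology["endophyte"] == "yes").to_numpy()
    traits = {}
    mean = np.where(is_endo, base_mean * planted_fold, base_mean)
    traits["planted"] = np.clip(mean + rng.normal(0, noise_sd, n_tips), 0, None)
    for j in range(n_control):
        x = control_offset + sim_traits(tree, "brownian", control_sigma2, rng)
        traits[f"control_{j + 1}"] = np.clip(x, 0, None)
    trait_df = pd.DataFrame(traits, index=pd.Index(tree.tip_labels, name="genome_id"))
    return tree, trait_df, ecology
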