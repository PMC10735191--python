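"""One-command orchestration: retrieval -> families -> counts -> signal ->
ratios -> screen, from a single TOML configuration.

Stages are individually skippable: a trait matrix supplied directly in the
config bypasses retrieval entirely, so count tables from any source
(cluster classes, chitinase classes, orthogroup counts) can enter at the
signal stage. Identical configuration and seeds produce identical outputs;
the run log records the resolved parameter set, a hash of the config file,
and every seed used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, eco_screen, family_network, phylo_signal
from .cluster_retrieval import (
    ClusterModel,
    RetrievalParams,
    RetrievedCluster,
    retrieve_clusters,
    tabulate_counts,
)
from .eco_screen import ScreenThresholds
from .family_network import DomainCopy, DomainProfile, FamilyWeights, WEIGHT_PRESETS

logger = logging.getLogger("mgc_ecoscreen")


@dataclass
class PipelineConfig:
    tree_path: str
    ecology_path: str
    out_dir: str
    traits_path: str | None = None
    gene_tables: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    gene_table_format: str = "tsv"
    hit_table: str | None = None
    query_lengths: str | None = None
    model_path: str | None = None
    retrieval: RetrievalParams = field(default_factory=RetrievalParams)
    weights: FamilyWeights = WEIGHT_PRESETS["dgc"]
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    ratio_column: str = "ratio_e_ne"
    potential_policy: str = "include"
    n_perm: int = 999
    n_sim: int = 1000
    seed: int = 0
    compute_d: bool = True
    config_hash: str = ""

    def __post_init__(self) -> None:
        if self.traits_path is None and not self.gene_tables:
            raise ValueError("either a trait matrix or gene tables must be supplied")


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    raw = path.read_bytes()
    data = tomllib.loads(raw.decode())
    inputs = data.get("inputs", {})
    run = data.get("run", {})

    def sub(name: str, cls):
        return cls(**data[name]) if name in data else cls()

    weights_cfg = data.get("weights", {})
    if "preset" in weights_cfg:
        weights = WEIGHT_PRESETS[weights_cfg["preset"]]
    elif weights_cfg:
        weights = FamilyWeights(**weights_cfg)
    else:
        weights = WEIGHT_PRESETS["dgc"]

    base = path.parent

    def resolve(p):
        return str(base / p) if p is not None else None

    return PipelineConfig(
        tree_path=resolve(inputs["tree"]),
        ecology_path=resolve(inputs["ecology"]),
        traits_path=resolve(inputs.get("traits")),
        gene_tables={k: resolve(v) for k, v in inputs.get("gene_tables", {}).items()},
        gene_table_format=inputs.get("gene_table_format", "tsv"),
        hit_table=resolve(inputs.get("hit_table")),
        query_lengths=resolve(inputs.get("query_lengths")),
        model_path=resolve(inputs.get("model")),
        retrieval=sub("retrieval", RetrievalParams),
        weights=weights,
        thresholds=sub("thresholds", ScreenThresholds),
        ratio_column=run.get("ratio_column", "ratio_e_ne"),
        potential_policy=run.get("potential_policy", "include"),
        n_perm=int(run.get("n_perm", 999)),
        n_sim=int(run.get("n_sim", 1000)),
        seed=int(run.get("seed", 0)),
        compute_d=bool(run.get("compute_d", True)),
        out_dir=resolve(run.get("out_dir", "results")),
        config_hash=hashlib.sha256(raw).hexdigest(),
    )


def read_cluster_model(path: str | Path, model_id: str | None = None) -> ClusterModel:
    """TSV with columns query_id, is_core (0/1), core_type (blank unless core)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cores = {
        str(r.query_id): str(r.core_type)
        for r in df.itertuples()
        if str(r.is_core) in ("1", "True", "true", "yes")
    }
    return ClusterModel(
        model_id=model_id or Path(path).stem,
        member_queries=frozenset(df["query_id"].astype(str)),
        core_queries=cores,
    )


def profile_from_cluster(cluster: RetrievedCluster, model: ClusterModel) -> DomainProfile:
    """Summarise a retrieved cluster as a domain profile: its matched query
    ids, in member rank order, stand in for domain copies; core queries are
    core domain types."""
    copies = [
        DomainCopy(domain_type=q)
        for gene in cluster.member_gene_ids
        for q in sorted(cluster.matched_queries.get(gene, ()))
    ]
    present = {c.domain_type for c in copies}
    return DomainProfile(
        cluster_id=cluster.cluster_id,
        copies=copies,
        core_types=present & set(model.core_queries),
    )


def run_screen_pipeline(
    config: PipelineConfig,
    annotations: list | None = None,
    hits: list | None = None,
    model: ClusterModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute the full screen; write TSV outputs plus a JSON run log to
    ``config.out_dir`` and return the result tables.

    In-memory inputs (annotations, hits, model) override the corresponding
    config paths, letting synthetic bundles run without touching disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = core_io.parse_newick(Path(config.tree_path).read_text())

    clusters: list[RetrievedCluster] = []
    outputs: dict[str, pd.DataFrame] = {}
    if config.gene_tables or annotations is not None:
        if annotations is None:
            annotations = [
                core_io.read_gene_table(p, config.gene_table_format, genome_id=g)
                for g, p in sorted(config.gene_tables.items())
            ]
        if model is None:
            if config.model_path is None:
                raise ValueError("retrieval stage requires a cluster model")
            model = read_cluster_model(config.model_path)
        if hits is None:
            qlens = core_io.read_query_lengths(config.query_lengths)
            hits = core_io.read_hit_table(config.hit_table, qlens)
        for ann in annotations:
            clusters.extend(retrieve_clusters(ann, hits, model, config.retrieval))
        profiles = [profile_from_cluster(c, model) for c in clusters]
        if profiles:
            assignment = family_network.group_families(profiles, config.weights)
            fam_df = pd.DataFrame(
                [
                    {"cluster_id": cid, "family": assignment.family_of[cid],
                     "clan": assignment.clan_of[cid]}
                    for cid in sorted(assignment.family_of)
                ]
            )
        else:
            fam_df = pd.DataFrame(columns=["cluster_id", "family", "clan"])
        outputs["families"] = fam_df
        traits = tabulate_counts(clusters, annotations, by="class")
        member_rows = [
            {"cluster_id": c.cluster_id, "genome_id": c.genome_id,
             "contig_id": c.contig_id, "class_label": c.class_label,
             "span_start": c.span_start, "span_end": c.span_end,
             "n_members": c.n_members,
             "member_gene_ids": ";".join(c.member_gene_ids)}
            for c in clusters
        ]
        outputs["clusters"] = pd.DataFrame(
            member_rows,
            columns=["cluster_id", "genome_id", "contig_id", "class_label",
                     "span_start", "span_end", "n_members", "member_gene_ids"],
        )
    else:
        traits = core_io.read_trait_matrix(config.traits_path)

    ecology = core_io.read_ecology(config.ecology_path, traits.index)
    core_io.validate_identifiers(tree, traits=traits, ecology=ecology)

    signal_traits = traits[[c for c in traits.columns if not c.endswith("__prop")]]
    signal = phylo_signal.compute_signal(
        signal_traits, tree, n_perm=config.n_perm, seed=config.seed
    )
    d_results = None
    if config.compute_d:
        d_rows = {}
        rng = np.random.default_rng(config.seed + 1)
        for trait in signal_traits.columns:
            presence = (signal_traits[trait].loc[tree.tip_labels] > 0).astype(float)
            k = presence.sum()
            if 0 < k < len(presence):
                res = phylo_signal.fritz_purvis_d(
                    presence.to_numpy(), tree, n_sim=config.n_sim, seed=rng
                )
                d_rows[trait] = (res.D, res.p_random, res.p_brownian)
        d_results = pd.DataFrame.from_dict(
            d_rows, orient="index", columns=["D", "p_random", "p_brownian"]
        )
        d_results.index.name = "trait_id"

    # degenerate traits were skipped by the signal stage; screen the rest
    ratios = eco_screen.enrichment_ratios(
        signal_traits[list(signal.index)], ecology, config.potential_policy
    )
    screen = eco_screen.screen_candidates(
        signal, ratios, config.thresholds,
        ratio_column=config.ratio_column, d_results=d_results,
    )
    outputs["counts"] = traits
    outputs["signal"] = signal
    outputs["screen"] = screen

    for name, df in outputs.items():
        core_io.write_table(
            df.reset_index() if df.index.name or name in ("counts", "signal", "screen") else df,
            out_dir / f"{name}.tsv",
        )
    log = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_sim": config.n_sim,
        "retrieval": asdict(config.retrieval),
        "thresholds": asdict(config.thresholds),
        "weights": asdict(config.weights),
        "n_clusters": len(clusters),
        "n_traits": int(signal_traits.shape[1]),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return outputs
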