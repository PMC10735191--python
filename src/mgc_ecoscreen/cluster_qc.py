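"""Quality filters for matching candidate clusters against reference
cluster entries (the screening applied to reference-database lookups of
biosynthetic clusters).

A candidate-vs-reference pairing survives when enough distinct reference
genes are matched (>= ``min_gene_fraction`` of the reference's gene count)
and the aggregate bitscore of the retained hits is at least
``per_gene_multiplier`` per matched gene. References with fewer than
``min_ref_genes`` genes are ignored outright, as are individual hits below
``hit_floor`` bits. Boundary equality passes on both rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger("mgc_ecoscreen")


@dataclass(frozen=True)
class ReferenceCluster:
    accession: str
    gene_ids: tuple[str, ...]

    @property
    def gene_count(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class QCParams:
    min_ref_genes: int = 3
    hit_floor: float = 100.0
    per_gene_multiplier: float = 100.0
    min_gene_fraction: float = 0.6
    #: if True, the aggregate-bitscore rule multiplies by the reference's
    #: full gene count instead of the number of matched genes
    aggregate_vs_reference_count: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_gene_fraction <= 1.0:
            raise ValueError("min_gene_fraction must be in (0, 1]")
        if min(self.min_ref_genes, self.hit_floor, self.per_gene_multiplier) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class ReferenceHit:
    """One candidate-gene vs reference-gene hit."""

    candidate_id: str       # candidate cluster
    candidate_gene_id: str
    accession: str          # reference cluster
    ref_gene_id: str
    bitscore: float


@dataclass(frozen=True)
class MatchDiagnostics:
    candidate_id: str
    accession: str
    n_matched: int
    aggregate_bits: float
    bits_threshold: float
    genes_threshold: float
    passed: bool


def prepare_reference_hits(
    hits: list[ReferenceHit],
    refs: dict[str, ReferenceCluster],
    params: QCParams | None = None,
) -> list[ReferenceHit]:
    """Clean the hit list: drop hits to references below ``min_ref_genes``,
    hits under ``hit_floor`` bits, and redundant hits.

    Redundancy means several candidate genes hitting one reference gene
    within a (candidate, reference) pairing; only the highest-bitscore hit
    per reference gene is kept (ties: lexicographically first candidate
    gene). The symmetric case — one candidate gene hitting several reference
    genes — is kept, since gene fission/fusion in the candidate is
    legitimate. Idempotent.
    """
    params = params or QCParams()
    best: dict[tuple[str, str, str], ReferenceHit] = {}
    for hit in hits:
        ref = refs.get(hit.accession)
        if ref is None:
            logger.warning("hit to unknown reference %s — rejected", hit.accession)
            continue
        if ref.gene_count < params.min_ref_genes:
            continue
        if hit.bitscore < params.hit_floor:
            continue
        key = (hit.candidate_id, hit.accession, hit.ref_gene_id)
        prev = best.get(key)
        if (
            prev is None
            or hit.bitscore > prev.bitscore
            or (hit.bitscore == prev.bitscore
                and hit.candidate_gene_id < prev.candidate_gene_id)
        ):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def evaluate_cluster_match(
    cleaned_hits: list[ReferenceHit],
    ref: ReferenceCluster,
    params: QCParams | None = None,
) -> MatchDiagnostics:
    """Pass/fail one candidate-reference pairing from its cleaned hits.

    With n distinct reference genes matched and S the aggregate bitscore:
    pass iff S >= per_gene_multiplier * n (or * ref.gene_count under the
    alternative reading) and n >= min_gene_fraction * ref.gene_count.
    """
    params = params or QCParams()
    candidates = {h.candidate_id for h in cleaned_hits}
    accessions = {h.accession for h in cleaned_hits}
    if len(candidates) > 1 or len(accessions) > 1:
        raise ValueError("hits must belong to a single candidate-reference pair")
    if accessions and accessions != {ref.accession}:
        raise ValueError("hits do not reference the given reference cluster")
    n = len({h.ref_gene_id for h in cleaned_hits})
    s = sum(h.bitscore for h in cleaned_hits)
    multiplier_base = ref.gene_count if params.aggregate_vs_reference_count else n
    bits_threshold = params.per_gene_multiplier * multiplier_base
    genes_threshold = params.min_gene_fraction * ref.gene_count
    passed = n > 0 and s >= bits_threshold and n >= genes_threshold
    return MatchDiagnostics(
        candidate_id=next(iter(candidates), ""),
        accession=ref.accession,
        n_matched=n,
        aggregate_bits=s,
        bits_threshold=bits_threshold,
        genes_threshold=genes_threshold,
        passed=passed,
    )


def qc_matches(
    hits: list[ReferenceHit],
    refs: dict[str, ReferenceCluster],
    params: QCParams | None = None,
) -> list[MatchDiagnostics]:
    """Clean all hits, then evaluate every (candidate, reference) pairing."""
    params = params or QCParams()
    cleaned = prepare_reference_hits(hits, refs, params)
    pairs: dict[tuple[str, str], list[ReferenceHit]] = {}
    for hit in cleaned:
        pairs.setdefault((hit.candidate_id, hit.accession), []).append(hit)
    return [
        evaluate_cluster_match(pair_hits, refs[accession], params)
        for (candidate, accession), pair_hits in sorted(pairs.items())
    ]
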