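# mgc-ecoscreen

Comparative-genomics screening for metabolic gene clusters and other genomic
traits enriched in a focal fungal ecology (endophyte vs non-endophyte,
mycotroph vs saprotroph), with explicit phylogenetic correction.

The package is aimed at comparative genomicists working with sets of
annotated fungal genomes (e.g. *Trichoderma*) who want to ask: *which
genomic traits — degradative or biosynthetic gene cluster classes, cluster
families, chitinase classes, orthogroup counts — are over-represented in
genomes of one lifestyle, beyond what shared ancestry alone would
produce?*

## What it does

1. **Cluster retrieval** (`cluster_retrieval`). Homologs of "core"
   catabolic genes (SAH, CCH, PMO, … — the signature enzymes that define a
   degradative cluster class) are filtered on similarity-search scores
   (bitscore ≥ 50, identity ≥ 30 %, query coverage 50–150 %, all
   inclusive), chained along each contig when at most 6 annotated genes
   intervene, and chains on one contig are consolidated when separated by
   < 30 kb. Clusters with core genes of several classes get hybrid labels
   (`CCH-PMO`).
2. **Reference-match QC** (`cluster_qc`). Candidate clusters matched
   against reference cluster entries must hit ≥ 60 % of the reference's
   genes with an aggregate bitscore ≥ 100 per matched gene (hits < 100
   bits, references with < 3 genes, and redundant hits are removed first).
3. **Family grouping** (`family_network`). Clusters are grouped into
   families and clans by connected components of a weighted domain-profile
   distance: 63 % domain sequence similarity, 35 % domain
   presence–absence, 2 % conserved synteny, with core domains boosted 2×.
4. **Phylogenetic signal** (`phylo_signal`). For a trait vector x on a
   rooted tree with Brownian covariance **C** (C_ij = shared root-path
   branch length):
   * **Blomberg's K** = (MSE₀/MSE) / E[MSE₀/MSE], 1 under Brownian motion,
     with a one-sided permutation p-value;
   * **Pagel's λ** by maximum likelihood over C(λ) (off-diagonals scaled),
     with a Monte-Carlo calibrated likelihood-ratio test against λ = 0;
   * **Fritz & Purvis' D** for binary traits, scaled so a random trait
     gives D = 1 and a Brownian-threshold trait D = 0;
   * **phylogenetic PCA** of the GLS-centered, phylogeny-corrected trait
     covariance.
5. **Ecology screen** (`eco_screen`). A trait is a candidate when it shows
   weak phylogenetic signal (K or λ ≤ 0.8), is not significantly Brownian
   (signal p > 0.05), **and** is > 2-fold enriched in the focal group
   (E:NE or M:S mean-count ratio). Group comparisons use t / Wilcoxon
   rank-sum tests with Holm correction.
6. **Synthetic data** (`synthetic_data`). Yule trees, Brownian / λ-scaled /
   white-noise traits, exact-prevalence binary traits, and annotated
   genomes with planted clusters and sub-threshold decoys, so the entire
   pipeline is testable without external downloads.

## Worked example

```python
from mgc_ecoscreen import (sim_screen_dataset, compute_signal,
                           enrichment_ratios, screen_candidates)

tree, traits, ecology = sim_screen_dataset(n_tips=64, n_control=3, seed=7)
signal = compute_signal(traits, tree, n_perm=999, seed=7)
ratios = enrichment_ratios(traits, ecology)
screen = screen_candidates(signal, ratios)
print(screen[["K", "p_K", "lambda_hat", "p_lambda",
              "ratio_e_ne", "flagged_any"]].round(3).to_string())
```

```
               K    p_K  lambda_hat  p_lambda  ratio_e_ne  flagged_any
trait_id
planted    0.073  0.758       0.000     1.000       3.060         True
control_1  0.949  0.001       0.997     0.001       0.999        False
control_2  2.398  0.001       0.995     0.001       0.999        False
control_3  0.924  0.001       1.004     0.001       1.002        False
```

The planted trait was generated without phylogenetic structure and with a
3× higher mean in "endophyte" genomes: both signal statistics are near 0,
neither test rejects the no-signal null (p_K = 0.758, p_λ = 1.0), and the
E:NE ratio exceeds 2 — so it is flagged. The Brownian controls have
K ≈ λ ≈ 1 with highly significant signal and ratios ≈ 1, and are not
flagged.

The same screen runs from the shell over files:

```bash
mgc-ecoscreen simulate --n-genomes 12 --seed 1 --out-dir fixtures/
mgc-ecoscreen run --config fixtures/run.toml
```

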