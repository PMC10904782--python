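# vamp

**V**irus-encoded **A**uxiliary **M**etabolic gene **P**ipeline — a tested,
reusable implementation of the post-annotation inference chain used to
discover and curate virus-encoded methane-metabolism (MM) auxiliary
metabolic genes (AMGs) in metagenomes.

Viruses of bacteria and archaea sometimes carry host-derived metabolic genes
("AMGs") that can modulate host metabolism during infection — including genes
touching methanogenesis and methane oxidation, processes with direct climate
relevance. Identifying such genes from assembled metagenomes requires a long
chain of filters after the heavy lifting (assembly, gene annotation, virus
prediction) is done by external tools. `vamp` implements that chain as a
library + CLI for microbial ecologists and viromics researchers:

1. **Ensemble virus calling** — a contig is viral if it meets at least one of
   four criteria: (i) VirSorter category ∈ {1, 2, 4, 5}; (ii) DeepVirFinder
   score ≥ 0.9 and p < 0.05; (iii) MARVEL probability ≥ 90%; (iv) DeepVirFinder
   score ≥ 0.7 and p < 0.05 **and** MARVEL ≥ 70%. Laboratory-contaminant
   genomes are screened out by canonical k-mer containment.
2. **vOTU clustering** — alignment fragments are merged into pairwise
   ANI / aligned-fraction estimates; contigs sharing ≥ 95% identity across
   ≥ 80% of the shorter contig's length are linked, then clustered greedily
   longest-first with the longest contig as each vOTU's seed.
3. **Abundance ecology** — mean depths are normalized to *coverage per
   gigabase* (depth × 10⁹ / library bases); occupancy is partitioned by
   site/depth/metagenome type; communities are compared by Bray–Curtis
   dissimilarity, classical PCoA, and distance-based PERMANOVA
   (999 label permutations, pseudo-F = (SS_among/(a−1))/(SS_within/(n−a))).
4. **AMG curation** — host-like contig ends are trimmed; a candidate AMG is
   accepted only if it is flanked by phage/hallmark genes on both sides, has
   no transposon gene in its window, has mutually consistent KEGG-KO/PFAM
   annotations, and lies inside the virus-like region. Accepted AMGs are
   classified **exclusive-MM** (all KEGG modules are MM modules), **shared-MM**,
   or **non-MM**, and cross-tabulated by habitat.
5. **Virus–host linkage** — four evidence types (CRISPR spacer match, tRNA
   carry-over, k-mer sequence similarity, tetranucleotide composition) are
   combined into a weighted score (3, 2, 2, 1; threshold 3), plus
   lineage-level virus/host abundance ratios.
6. **Selection screening** — gene-level pN/pS with NG86-style fractional
   expected-site counting; pN/pS = (N_obs/N_sites)/(S_obs/S_sites), < 1
   indicating purifying selection.

A first-class **synthetic community generator** plants ground truth for every
stage (true viruses and decoys, vOTU families with analytic ANI, AMG contexts
forcing each curation outcome, virus–host pairs, per-gene variant counts), so
the whole chain is testable end-to-end without external data.

## Worked example

```bash
# 1. simulate a community: 12 viruses, 6 decoys, one AMG planted in a clean
#    phage context with 2 synonymous + 1 nonsynonymous variants
vamp simulate --seed 4 --out demo_bundle --amg K00577:flanked:2:1

# 2. run every stage
vamp run-all --bundle demo_bundle --out demo_out --seed 4
```

which prints:

```
contigs_in: 22
viruses_called: 16
votus: 14
ecology_features: 14
amg_candidates: 1
amgs_accepted: 1
host_links: 13
pnps_genes: 1
```

Reading: of 22 input contigs, the 16 planted viruses (12 plain + 1 AMG
carrier + 3 cluster-family members) pass the four-criterion ensemble and all
6 decoys fail; the 3-member family collapses into one vOTU (16 → 14); the
planted *mtrA*-like candidate (KO K00577, an exclusively-MM methyl-transferase
subunit) survives curation; the 13 viruses carrying planted host evidence
(the cluster-family copies carry none) are linked back to their donor MAGs; and
`demo_out/pnps.tsv` reports the planted gene's pN/pS from its 3 variants.
Per-stage tables (`virus_calls.tsv`, `votus.tsv`, `votu_abundance.tsv`,
`ecology_summary.tsv`, `amg_calls.tsv`, `host_predictions.tsv`, `pnps.tsv`)
and a checksummed `manifest.json` land in `demo_out/`.

Each stage is also exposed on its own (`vamp screen|cluster|ecology|amg|
hostlink|pnps`) over plain TSV/FASTA files, so real tool outputs (VirSorter
score tables, BLAST fragment tables, MetaPop SNP tables) can be substituted
for the synthetic ones at any point.

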