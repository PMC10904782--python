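# Methods

This note documents the models and procedures `vamp` implements, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic communities do and do not emulate.

## Ensemble virus calling

A contig is classified viral when it meets **any** of four criteria over the
outputs of three predictors:

| criterion | rule |
|---|---|
| i | VirSorter category ∈ {1, 2, 4, 5} |
| ii | DeepVirFinder score ≥ 0.9 **and** p < 0.05 |
| iii | MARVEL probability ≥ 90% |
| iv | DeepVirFinder score ≥ 0.7 **and** p < 0.05 **and** MARVEL ≥ 70% |

Boundary semantics are literal: score cuts are inclusive (≥), the p-value cut
is strict, so p = 0.05 exactly fails. A score a tool did not report fails that
tool's criteria rather than raising an error — the rule was designed to pool
predictors over heterogeneous datasets where not every tool ran everywhere.
Size eligibility is tracked separately: linear contigs ≥ 5 kb, or circular
contigs of 1.5–5.0 kb.

The laboratory-contaminant screen is a canonical k-mer containment test
(defaults k = 21, τ = 0.5): a contig is flagged when at least a fraction τ of
its canonical k-mers occur in some blocklist genome. This is a presence
screen standing in for a nucleotide-BLAST comparison against cultivated
phage genomes; both parameters are exposed, and contigs shorter than k are
never flagged (warning logged).

## vOTU clustering

Pairwise local-alignment fragments (BLAST outfmt-6 style) are merged per
contig pair: fragments are sorted by query start, overlapping query bases are
credited once to the earlier-sorted fragment, ANI is the length-weighted mean
identity over the trimmed fragments, and each contig's aligned fraction (AF)
is its merged covered bases over its length.

An edge requires ANI ≥ 95 **and** max(AF_query, AF_target) ≥ 0.80 — i.e. the
80%-of-length requirement is evaluated on the shorter contig, the
MIUViG-style convention. "80% of their lengths" is genuinely ambiguous
(shorter contig vs both); we fix the community-default reading explicitly
rather than guessing authorial intent, and both thresholds are parameters.

Clustering is greedy and longest-first: contigs are visited by decreasing
length (ties broken lexicographically by id); each joins the first (longest)
existing centroid it has an edge to, else founds a new cluster. This matches
the seed/representative semantics of selecting the longest contig in a vOTU
as its representative; single-linkage (connected components) is available as
`single_linkage_cluster` for sensitivity analysis. The output always
partitions the input, and no member is longer than its representative.

## Abundance ecology

Abundances are *coverage per gigabase*: mean mapped depth × 10⁹ / library
bases, so unequal library sizes are comparable. Occupancy partitions count
features (presence = abundance > 0) found in all groups vs exactly one group
of a sample grouping (site, depth, metagenome type); reported percentages
use one-decimal half-up rounding, the convention of published
community-overlap figures.

Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) is computed per sample pair; a
pair of all-zero samples is reported as 0 with a warning (degenerate fixture
guard) rather than NaN. PCoA is classical scaling: Gower double-centering of
−½d², eigendecomposition, axes ordered by descending eigenvalue,
negative-eigenvalue axes dropped and counted (Bray–Curtis is not Euclidean,
so small negative eigenvalues are expected).

PERMANOVA uses the distance-based pseudo-F
F = (SS_among/(a−1)) / (SS_within/(n−a)) with SS terms computed directly from
squared distances. The permutation p-value is the unbiased +1/+1 estimate,
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), with 999 seeded label
permutations by default, so p can never fall below 1/(n_perm+1). For n ≤ 8 an
exhaustive mode enumerates all distinct label orderings and returns the exact
permutation p (the identity ordering counts on both sides). Whether raw or
normalized abundances enter the distance matrix is the caller's choice; the
pipeline default is the normalized coverage produced above.

## AMG curation

Host–virus boundary trimming removes, from each contig end, the maximal
terminal run of ≥ `min_run` (default 3) genes that contains no hallmark gene
and has a cellular-gene fraction ≥ `host_frac` (default 0.7). A run must end
on a cellular gene, so trailing virus-like genes are never trimmed; interior
genes are never trimmed; if the two trims meet, the whole contig is flagged
host-like.

A candidate is accepted iff none of these independent rejection reasons
apply:

* `not_flanked` — no phage/hallmark gene within `window` (default 5) kept
  genes on *each* side, or the candidate is the first/last kept gene. The
  window size operationalizes "surrounded by phage genes", which has no
  standard numeric definition; it is configurable.
* `transposon_context` — a transposon-category gene within the window
  (transposon "region" is operationalized as gene-level category).
* `annotation_inconsistent` — KO present but PFAM absent or not among the
  PFAMs cross-mapped to that KO (missing PFAM counts as inconsistent —
  conservative).
* `no_ko` — no KEGG KO assigned.
* `in_host_region` — candidate outside the kept interval after trimming
  (such candidates also lack usable kept-gene flanks, so they carry
  `not_flanked` as well).

Pathway classification is a trichotomy over the KO's module memberships:
**exclusive_mm** when all modules are methane-metabolism modules,
**shared_mm** when MM and non-MM modules both occur, **non_mm** otherwise
(unknown KOs classify non_mm with a warning). The bundled KO→module and
KO→PFAM maps are a minimal curated table covering methanogenesis from
CO₂/acetate/methylamines, methane oxidation, and coenzyme F420 biosynthesis
plus common non-MM modules; accessions follow KEGG/PFAM naming style but the
file is this package's own curation — users with a KEGG license can supply a
full map in the same two-column TSV format. Distinct-AMG identity is the KO
accession, so the same gene on many contigs counts once in habitat
summaries; habitat matrices count carrying contigs per KO × habitat.

## Virus–host linkage

Four self-contained evidence signals per virus × MAG pair:

| evidence | definition | default gate | weight |
|---|---|---|---|
| CRISPR spacer | spacer (≥ 25 nt, either strand) occurs in virus with ≤ 1 substitution | boolean | 3 |
| tRNA | exact full-length occurrence of a MAG tRNA (≥ 60 nt), either strand | boolean | 2 |
| similarity | canonical k-mer containment of virus in MAG (k = 21) | ≥ 0.5 | 2 |
| composition | L1 distance between canonical tetranucleotide frequencies | ≤ 0.25 | 1 |

Pairs with weighted aggregate ≥ 3 are reported best-first (ties broken by
composition distance, then MAG id). The spacer stringency (≥ 25 nt, ≤ 1
mismatch) is conventional; the similarity gate 0.5 corresponds to roughly
half the virus being present in the host genome (a prophage-like signal);
the composition gate 0.25 is loose by design — two sequences of similar base
composition pass, which is why composition alone (weight 1) can never reach
the reporting threshold. This scorer is a declared, self-contained
re-implementation of the four-evidence idea used by aggregate host
predictors; it is not a reproduction of any trained model, and all weights,
gates, and the threshold are configuration.

Lineage ratios: per sample, ratio = Σ abundance of viruses linked to a
lineage / Σ abundance of the lineage's MAGs; a lineage with zero host
abundance yields an explicitly flagged undefined ratio, never infinity.

## pN/pS

Expected site counts are NG86-style fractional counts: for each codon, all
nine single-nucleotide changes are classified by translation (table 11);
each position contributes syn/3 synonymous and (3−syn)/3 nonsynonymous
sites, so N_sites + S_sites equals gene length. Changes to or from stop
codons count nonsynonymous (stop→stop is synonymous); codons containing
ambiguous bases contribute whole nonsynonymous sites with a warning.
Observed SNPs are applied one at a time against the reference codon (no
haplotype phasing; read-level linkage is not modeled); duplicate
(position, alt) records count once. Then

pN/pS = (N_obs/N_sites) / (S_obs/S_sites)

with explicit statuses: `no_snps`, `zero_syn_undefined` (S_obs = 0 with
N_obs > 0 — reported as undefined, not infinity), `no_sites` (a gene with no
expected sites of one class), and pN/pS = 0 exactly when only synonymous
variation is observed. Under uniform random mutation the statistic calibrates
to ≈ 1 (tested: mean within [0.9, 1.1] at 10⁴ draws on a 999-codon gene).
Cross-lineage dN/dS (codon-model maximum likelihood) is out of scope; the
variant reader accepts an external dN/dS column for reporting only.

## Synthetic communities

The generator plants ground truth for every stage from a single seed
(`numpy.random.default_rng`; fixed seed ⇒ byte-identical files):

* **Sequences** are i.i.d. uniform nucleotide backbones. vOTU families are a
  parent contig plus copies mutated by per-site substitution at a stated
  rate with **no indels**, so true pairwise identity is analytic and exact
  full-length alignment fragments can be emitted (default family: 3 members
  at substitution rate 0.013, giving within-family identities around
  97.4–98.7%, a realistic within-population spread).
* **Predictor scores**: planted viruses draw scores passing exactly one
  chosen criterion (cycling i–iv); decoys draw scores failing all four.
  Optional score jitter perturbs scores (and can flip calls); the default is
  zero noise.
* **AMG contexts**: each planted AMG gets a dedicated contig whose gene
  layout forces one documented curation outcome (flanked/accepted, terminal,
  unflanked, transposon-in-window, KO↔PFAM inconsistent, KO-less, or inside
  a trimmable host region). AMG genes are random stop-free coding sequences;
  requested synonymous/nonsynonymous variant counts are realized by sampling
  without replacement from the enumerated single-nucleotide changes of each
  gene.
* **Virus–host pairs** are marked by copying a 32-nt spacer from the virus
  into the host MAG's CRISPR table and embedding one host tRNA in the virus
  (aggregate 3+2 ≥ threshold, plus composition).
* **Samples** default to the two-site × three-depth paired bulk/virome design
  with one bulk library missing (11 samples), library sizes log-uniform in
  [3×10⁹, 1.5×10¹⁰] bases so per-gigabase normalization is exercised with
  unequal libraries. Feature occupancy is drawn with 4.2% of viruses shared
  between sites, 75% unique to one depth, 5.7% present at all depths, and a
  strong bulk bias — the occupancy structure of a site- and
  depth-differentiated sediment community.

What the generator does **not** emulate: read-level data (FASTQ, quality,
assembly artifacts), chimeric contigs, annotation error beyond simple
KO/PFAM dropout, compositional signal differences between hosts (backbones
are uniform, so composition distance is uninformative between planted and
decoy MAGs — by design the composition weight alone cannot create a link),
and real phylogenetic structure. Passing the planted-truth suites therefore
demonstrates that the decision rules are implemented exactly as specified,
not that the rules themselves are robust to real-data noise.

## Problem sizes and numerical choices

Tests and the acceptance script use communities of tens to a few hundred
contigs, MAGs of 20 kb, and PERMANOVA calibration with 200 null datasets ×
999 permutations at n = 8 samples — sizes chosen so the full suite documents
the statistical behavior (type-I error inside the binomial envelope,
exhaustive-enumeration agreement) while remaining quick to run on one CPU.
Floating-point ties in permutation tests are counted with a 10⁻¹² tolerance
toward "≥ observed". Percentages are rounded half-up to one decimal.
Deterministic tie-breaks throughout: lexicographic contig ids (clustering),
composition distance then MAG id (host ranking).

## Known limitations

* The contaminant screen and similarity evidence are k-mer containment, not
  alignment; highly repetitive sequences inflate containment.
* The AMG flanking window is a gene-count heuristic; no strandedness or
  intergenic-distance information is used.
* PERMANOVA assumes exchangeable samples under the null; nested designs
  (cores within sites) are not modeled.
* pN/pS treats SNPs independently and ignores allele frequencies beyond
  presence; genes with zero synonymous observations are undefined rather
  than assigned a pseudocount.
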