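"""Gene-level pN/pS from per-site variant tables.

Expected synonymous/nonsynonymous site counts use NG86-style fractional
counting: each codon position contributes syn_changes/3 synonymous and
nonsyn_changes/3 nonsynonymous "sites", judged by translating all nine
single-nucleotide changes of the codon (changes creating a stop codon count
nonsynonymous). Observed SNPs are classified one at a time against the
reference codon background (no haplotype phasing). Then

    pN/pS = (N_obs / N_sites) / (S_obs / S_sites)

A value < 1 indicates purifying selection on the gene within the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"


def _codon_maps(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    return fwd


@dataclass(frozen=True)
class CodingGene:
    """An in-frame, 5'->3' oriented coding sequence."""

    gene_id: str
    sequence: str
    codon_table: int = 11

    def __post_init__(self):
        if len(self.sequence) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {len(self.sequence)} not divisible by 3")

    @property
    def codons(self) -> list[str]:
        s = self.sequence.upper()
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    position: int   # 1-based within the gene
    ref: str
    alt: str


@dataclass(frozen=True)
class PnPsResult:
    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pnps: float | None
    status: str   # defined | zero_syn_undefined | no_snps | no_sites


def expected_sites(gene: CodingGene) -> tuple[float, float]:
    """NG86 fractional (nonsynonymous, synonymous) site counts for a gene.

    Each position contributes nonsyn/3 + syn/3 = 1, so the two counts sum to
    the gene length. Positions in codons with ambiguous bases contribute a
    whole nonsynonymous site (with a warning); internal stop codons are
    tolerated with a warning (their changes are judged by translation).
    """
    codon_aa = _codon_maps(gene.codon_table)
    n_sites = s_sites = 0.0
    for ci, codon in enumerate(gene.codons):
        if any(b not in BASES for b in codon):
            logger.warning("%s codon %d contains ambiguous bases", gene.gene_id, ci + 1)
            n_sites += 3.0
            continue
        aa = codon_aa[codon]
        if aa == "*" and ci < len(gene.codons) - 1:
            logger.warning("%s has an internal stop at codon %d", gene.gene_id, ci + 1)
        for pos in range(3):
            syn = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                mut_aa = codon_aa[mut]
                if mut_aa == aa and mut_aa != "*" or (aa == "*" and mut_aa == "*"):
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites


def classify_snps(gene: CodingGene, snps: Sequence[SnpRecord]) -> tuple[int, int]:
    """(N_obs, S_obs): observed SNPs split by effect against the reference.

    A SNP is synonymous iff the mutated codon translates to the same amino
    acid (changes to or from stop are nonsynonymous unless both are stops).
    Duplicate (position, alt) records are counted once.
    """
    codon_aa = _codon_maps(gene.codon_table)
    seq = gene.sequence.upper()
    seen: set[tuple[int, str]] = set()
    n_obs = s_obs = 0
    for snp in snps:
        if snp.gene_id != gene.gene_id:
            continue
        if not 1 <= snp.position <= len(seq):
            raise ValueError(f"{gene.gene_id}: SNP position {snp.position} outside gene")
        if seq[snp.position - 1] != snp.ref.upper():
            raise ValueError(
                f"{gene.gene_id}: reference mismatch at position {snp.position} "
                f"(gene has {seq[snp.position - 1]}, record says {snp.ref})"
            )
        if snp.alt.upper() == snp.ref.upper():
            raise ValueError(f"{gene.gene_id}: alt equals ref at position {snp.position}")
        key = (snp.position, snp.alt.upper())
        if key in seen:
            continue
        seen.add(key)
        ci = (snp.position - 1) // 3
        off = (snp.position - 1) % 3
        codon = seq[ci * 3 : ci * 3 + 3]
        mut = codon[:off] + snp.alt.upper() + codon[off + 1 :]
        if any(b not in BASES for b in codon + mut):
            n_obs += 1
            continue
        ref_aa, mut_aa = codon_aa[codon], codon_aa[mut]
        if ref_aa == mut_aa and mut_aa != "*" or (ref_aa == "*" and mut_aa == "*"):
            s_obs += 1
        else:
            n_obs += 1
    return n_obs, s_obs


def pnps(gene: CodingGene, snps: Sequence[SnpRecord]) -> PnPsResult:
    """Gene-level pN/pS with explicit degenerate statuses.

    * no SNPs at all -> status no_snps (value None)
    * S_obs = 0 with N_obs > 0 -> zero_syn_undefined (value None)
    * N_obs = 0 with S_obs > 0 -> pnps = 0 exactly
    * zero expected sites of either class -> no_sites
    """
    n_sites, s_sites = expected_sites(gene)
    n_obs, s_obs = classify_snps(gene, snps)
    if n_sites == 0 or s_sites == 0:
        return PnPsResult(gene.gene_id, n_obs, s_obs, n_sites, s_sites, None, "no_sites")
    if n_obs == 0 and s_obs == 0:
        return PnPsResult(gene.gene_id, 0, 0, n_sites, s_sites, None, "no_snps")
    if s_obs == 0:
        return PnPsResult(gene.gene_id, n_obs, 0, n_sites, s_sites, None, "zero_syn_undefined")
    value = (n_obs / n_sites) / (s_obs / s_sites)
    return PnPsResult(gene.gene_id, n_obs, s_obs, n_sites, s_sites, value, "defined")


def read_variant_table(path) -> list[SnpRecord]:
    """Minimal VCF-compatible variant table: CHROM(=gene_id), POS, REF, ALT.

    Accepts either a headered TSV with those columns or a VCF-style file whose
    header line starts with #CHROM.
    """
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("##")]
    if not lines:
        return []
    header = lines[0].lstrip("#").split("\t")
    col = {name.upper(): i for i, name in enumerate(header)}
    need = ["CHROM", "POS", "REF", "ALT"]
    if not all(c in col for c in need):
        raise ValueError(f"variant table must have columns {need}")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(
            SnpRecord(
                gene_id=f[col["CHROM"]],
                position=int(f[col["POS"]]),
                ref=f[col["REF"]],
                alt=f[col["ALT"]],
            )
        )
    return out


def results_to_frame(results: Iterable[PnPsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": r.gene_id,
            "n_obs": r.n_obs,
            "s_obs": r.s_obs,
            "n_sites": r.n_sites,
            "s_sites": r.s_sites,
            "pnps": "" if r.pnps is None else r.pnps,
            "status": r.status,
        }
        for r in results
    )
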