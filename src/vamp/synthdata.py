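"""Synthetic metagenome communities with planted ground truth.

Generates internally consistent fixtures for the whole pipeline: contig
sequences, predictor-score tables, gene annotations, alignment fragments for
planted vOTU families, per-sample depth tables with unequal library sizes,
MAG bundles (taxonomy, genomes, tRNAs, CRISPR spacers), per-gene variant
tables, and truth tables naming every planted virus, cluster, AMG and
virus-host link.

Default community parameters emulate a two-site, three-depth freshwater
sediment study: paired bulk metagenome / virome samples per site and depth
(with one bulk library missing), library sizes drawn log-uniform between
3e9 and 1.5e10 bases, and occupancy structure in which only a few percent
of viruses are shared between sites while most are unique to a single depth.

Sequence model: i.i.d. uniform nucleotide backbones; vOTU families are built
by per-site substitution of a parent contig at a stated rate with no indels,
so true ANI is analytic and exact alignment fragments can be emitted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from vamp.amg import GeneAnnotation, PathwayMap, load_default_pathway_map

BASES = np.array(list("ACGT"))

#: planted AMG genomic contexts and the curation outcome each one forces
AMG_CONTEXTS = {
    "flanked": ("accepted", frozenset()),
    "terminal": ("rejected", frozenset({"not_flanked"})),
    "not_flanked": ("rejected", frozenset({"not_flanked"})),
    "transposon": ("rejected", frozenset({"transposon_context"})),
    "inconsistent": ("rejected", frozenset({"annotation_inconsistent"})),
    "no_ko": ("rejected", frozenset({"no_ko"})),
    "host_region": ("rejected", frozenset({"in_host_region", "not_flanked"})),
}

PHYLA = [
    ("d__Archaea", "p__Thermoproteota"),
    ("d__Bacteria", "p__Chloroflexota"),
    ("d__Archaea", "p__Halobacteriota"),
    ("d__Archaea", "p__Methanobacteriota"),
    ("d__Bacteria", "p__Desulfobacterota"),
    ("d__Bacteria", "p__Proteobacteria"),
]


class ConfigError(ValueError):
    """Contradictory or out-of-range community configuration."""


@dataclass(frozen=True)
class PlantedAmg:
    """One AMG to plant: KEGG KO, genomic context, and per-gene SNP counts."""

    ko: str
    context: str = "flanked"
    n_syn: int = 0
    n_nonsyn: int = 0

    def __post_init__(self):
        ctx = self.context
        if not isinstance(ctx, str):
            ctxs = set(ctx)
            if len(ctxs) != 1:
                raise ConfigError(f"contradictory AMG contexts for {self.ko}: {sorted(ctxs)}")
            object.__setattr__(self, "context", next(iter(ctxs)))
        if self.context not in AMG_CONTEXTS:
            raise ConfigError(f"unknown AMG context {self.context!r}")
        if self.n_syn < 0 or self.n_nonsyn < 0:
            raise ConfigError("SNP counts must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    site: str
    depth_cm: int
    mtype: str = "bulk"          # bulk | virome
    library_bases: float | None = None   # None -> drawn log-uniform


def default_samples() -> tuple[SampleSpec, ...]:
    """Two sites x three depths x (bulk + virome), with the muddy 50 cm bulk
    library missing — the sampling design the generator emulates."""
    out = []
    for site, tag in (("muddy", "M"), ("sandy", "S")):
        for depth in (50, 100, 225):
            for mtype, suf in (("bulk", "M"), ("virome", "V")):
                if site == "muddy" and depth == 50 and mtype == "bulk":
                    continue
                out.append(SampleSpec(f"{tag}{depth}_{suf}", site, depth, mtype))
    return tuple(out)


@dataclass(frozen=True)
class Noise:
    score_jitter: float = 0.0        # sd of predictor-score perturbation
    annotation_dropout: float = 0.0  # prob. a non-planted gene loses its KO/PFAM

    def __post_init__(self):
        for name in ("score_jitter", "annotation_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CommunityConfig:
    seed: int = 0
    n_mags: int = 4
    n_viral_contigs: int = 12
    n_decoy_contigs: int = 6
    habitats: tuple[str, ...] = ("lake_sediment",)
    planted_amgs: tuple[PlantedAmg, ...] = ()
    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    cluster_families: tuple[tuple[int, float], ...] = ((3, 0.013),)
    noise: Noise = field(default_factory=Noise)
    library_bases_range: tuple[float, float] = (3e9, 1.5e10)
    mag_length: int = 20_000
    occupancy: tuple[float, float, float] = (0.042, 0.75, 0.057)
    # (P(shared between both sites), P(unique to one depth), P(present at all depths))

    def __post_init__(self):
        for name in ("n_mags", "n_viral_contigs", "n_decoy_contigs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.planted_amgs and self.n_mags == 0:
            raise ConfigError("planted AMGs need at least one MAG to act as gene donor")
        for n, rate in self.cluster_families:
            if n < 1 or not 0.0 <= rate <= 1.0:
                raise ConfigError(f"bad cluster family spec ({n}, {rate})")
        if not self.habitats:
            raise ConfigError("at least one habitat label required")


@dataclass(eq=False)
class FixtureBundle:
    """Everything one pipeline run consumes, plus truth tables."""

    contigs: dict[str, str]
    genes: pd.DataFrame
    scores: pd.DataFrame
    fragments: pd.DataFrame
    sample_metadata: pd.DataFrame          # sample_id site depth_cm type library_bases
    depth: dict[str, pd.DataFrame]         # sample -> (feature_id, mean_depth)
    mag_taxonomy: pd.DataFrame
    mag_seqs: dict[str, str]
    mag_trnas: dict[str, list[str]]
    mag_spacers: dict[str, list[str]]
    variants: pd.DataFrame                 # CHROM POS REF ALT
    amg_gene_seqs: dict[str, str]          # gene_id -> coding sequence
    contig_habitats: dict[str, str]
    truth: dict[str, pd.DataFrame]

    def gene_annotations(self) -> list[GeneAnnotation]:
        out = []
        for r in self.genes.itertuples(index=False):
            out.append(
                GeneAnnotation(
                    contig_id=str(r.contig_id),
                    gene_index=int(r.gene_index),
                    start=int(r.start),
                    end=int(r.end),
                    strand=str(r.strand),
                    category=str(r.category),
                    kegg_ko=None if r.kegg_ko == "" or pd.isna(r.kegg_ko) else str(r.kegg_ko),
                    pfam_acc=None if r.pfam_acc == "" or pd.isna(r.pfam_acc) else str(r.pfam_acc),
                    product=str(r.product),
                )
            )
        return out

    def equals(self, other: "FixtureBundle") -> bool:
        if self.contigs != other.contigs or self.mag_seqs != other.mag_seqs:
            return False
        if self.mag_trnas != other.mag_trnas or self.mag_spacers != other.mag_spacers:
            return False
        if self.amg_gene_seqs != other.amg_gene_seqs:
            return False
        if self.contig_habitats != other.contig_habitats:
            return False
        if set(self.depth) != set(other.depth) or set(self.truth) != set(other.truth):
            return False
        frames = [
            (self.genes, other.genes),
            (self.scores, other.scores),
            (self.fragments, other.fragments),
            (self.sample_metadata, other.sample_metadata),
            (self.mag_taxonomy, other.mag_taxonomy),
            (self.variants, other.variants),
        ]
        frames += [(self.depth[s], other.depth[s]) for s in self.depth]
        frames += [(self.truth[k], other.truth[k]) for k in self.truth]
        return all(_frames_equal(a, b) for a, b in frames)


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    for c in a.columns:
        av, bv = a[c].to_numpy(), b[c].to_numpy()
        if np.issubdtype(np.asarray(av).dtype, np.floating):
            if not np.allclose(av.astype(float), bv.astype(float), equal_nan=True):
                return False
        elif not all(str(x) == str(y) for x, y in zip(av, bv)):
            return False
    return True


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution at the given rate; no indels, so ANI is analytic."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame coding sequence without internal stops."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    codons.append("ATG")
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def _enumerate_changes(cds: str) -> tuple[list[tuple[int, str, str]], list[tuple[int, str, str]]]:
    """All single-nucleotide changes of a CDS split into (synonymous,
    nonsynonymous) lists of (1-based position, ref, alt); stop-creating
    changes are nonsynonymous."""
    syn, nonsyn = [], []
    for ci in range(0, len(cds), 3):
        codon = cds[ci : ci + 3]
        aa = str(Seq(codon).translate(table=11))
        for off in range(3):
            for b in "ACGT":
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1 :]
                maa = str(Seq(mut).translate(table=11))
                rec = (ci + off + 1, codon[off], b)
                if maa == aa and maa != "*":
                    syn.append(rec)
                else:
                    nonsyn.append(rec)
    return syn, nonsyn


def _context_layout(context: str) -> list[str]:
    """Gene-category layout for a planted AMG contig; 'AMG' marks the candidate."""
    if context == "flanked":
        return ["hallmark", "phage", "phage", "AMG", "phage", "phage", "hypothetical", "phage"]
    if context == "terminal":
        return ["hallmark", "phage", "phage", "phage", "phage", "phage", "AMG"]
    if context == "not_flanked":
        return (
            ["phage"] + ["hypothetical"] * 6 + ["AMG"] + ["hypothetical"] * 6 + ["phage"]
        )
    if context == "transposon":
        return ["hallmark", "phage", "transposon", "AMG", "phage", "phage", "phage"]
    if context in ("inconsistent", "no_ko"):
        return ["hallmark", "phage", "phage", "AMG", "phage", "phage", "phage"]
    if context == "host_region":
        # the candidate sits inside a terminal cellular run, so boundary
        # trimming removes it along with the flanking host genes
        return [
            "cellular",
            "cellular",
            "AMG",
            "cellular",
            "cellular",
            "phage",
            "hallmark",
            "phage",
            "phage",
            "phage",
        ]
    raise ConfigError(f"unknown AMG context {context!r}")


def _passing_scores(rng: np.random.Generator, criterion: str) -> dict:
    """Predictor scores guaranteed to satisfy exactly the chosen criterion."""
    s = {"virsorter_category": 3, "dvf_score": None, "dvf_p": None, "marvel_prob": None}
    if criterion == "i":
        s["virsorter_category"] = int(rng.choice([1, 2, 4, 5]))
    elif criterion == "ii":
        s["dvf_score"] = float(rng.uniform(0.90, 0.999))
        s["dvf_p"] = float(rng.uniform(0.0, 0.049))
    elif criterion == "iii":
        s["marvel_prob"] = float(rng.uniform(90.0, 100.0))
    elif criterion == "iv":
        s["dvf_score"] = float(rng.uniform(0.70, 0.89))
        s["dvf_p"] = float(rng.uniform(0.0, 0.049))
        s["marvel_prob"] = float(rng.uniform(70.0, 89.0))
    return s


def _failing_scores(rng: np.random.Generator) -> dict:
    return {
        "virsorter_category": int(rng.choice([3, 6])),
        "dvf_score": float(rng.uniform(0.0, 0.65)),
        "dvf_p": float(rng.uniform(0.06, 1.0)),
        "marvel_prob": float(rng.uniform(0.0, 65.0)),
    }


def generate_community(
    config: CommunityConfig, pathway_map: PathwayMap | None = None
) -> FixtureBundle:
    """Build a complete fixture bundle from a community configuration.

    With zero noise the truth tables are exactly recoverable downstream:
    planted viral contigs pass at least one ensemble criterion, decoys fail
    all four, each planted AMG's context forces its documented curation
    outcome, cluster families have analytic ANI above (or construction keeps
    them above) the clustering thresholds, variant tables realize the
    requested synonymous/nonsynonymous counts, and every planted virus-host
    pair is marked by a CRISPR spacer and a shared tRNA.
    """
    rng = np.random.default_rng(config.seed)
    pmap = pathway_map or load_default_pathway_map()

    # ---- MAGs -------------------------------------------------------------
    mag_ids = [f"MAG_{i:03d}" for i in range(config.n_mags)]
    mag_seqs = {m: _random_seq(rng, config.mag_length) for m in mag_ids}
    mag_trnas: dict[str, list[str]] = {}
    mag_spacers: dict[str, list[str]] = {m: [] for m in mag_ids}
    tax_rows = []
    for i, m in enumerate(mag_ids):
        dom, phy = PHYLA[i % len(PHYLA)]
        tax_rows.append(
            {
                "mag_id": m,
                "domain": dom,
                "phylum": phy,
                "class": f"c__clade{i}",
                "order": f"o__clade{i}",
                "family": f"f__clade{i}",
                "genus": f"g__clade{i}",
                "species": f"s__clade{i}",
            }
        )
        trnas = []
        for _ in range(2):
            start = int(rng.integers(0, config.mag_length - 80))
            trnas.append(mag_seqs[m][start : start + 72])
        mag_trnas[m] = trnas
    mag_taxonomy = pd.DataFrame(
        tax_rows,
        columns=["mag_id", "domain", "phylum", "class", "order", "family", "genus", "species"],
    )

    # ---- viral contigs, genes, scores --------------------------------------
    contigs: dict[str, str] = {}
    gene_rows: list[dict] = []
    score_rows: list[dict] = []
    contig_habitats: dict[str, str] = {}
    truth_virus_rows: list[dict] = []
    truth_host_rows: list[dict] = []
    truth_amg_rows: list[dict] = []
    truth_cluster_rows: list[dict] = []
    amg_gene_seqs: dict[str, str] = {}
    variant_rows: list[dict] = []

    criteria_cycle = ["i", "ii", "iii", "iv"]

    def _plant_host_evidence(vid: str, vseq: str, host: str) -> str:
        """Record a CRISPR spacer from the virus in the host MAG and embed one
        host tRNA in the virus; returns the virus sequence with the tRNA."""
        start = int(rng.integers(0, len(vseq) - 40))
        mag_spacers[host].append(vseq[start : start + 32])
        trna = mag_trnas[host][int(rng.integers(0, len(mag_trnas[host])))]
        truth_host_rows.append({"virus_id": vid, "mag_id": host})
        return vseq + trna

    def _add_score(cid: str, length: int, passing: bool, criterion: str | None) -> None:
        s = _passing_scores(rng, criterion) if passing else _failing_scores(rng)
        if config.noise.score_jitter > 0:
            for key, scale, lo, hi in (
                ("dvf_score", 1.0, 0.0, 1.0),
                ("dvf_p", 1.0, 0.0, 1.0),
                ("marvel_prob", 100.0, 0.0, 100.0),
            ):
                if s[key] is not None:
                    s[key] = float(
                        np.clip(s[key] + rng.normal(0, config.noise.score_jitter * scale), lo, hi)
                    )
        score_rows.append(
            {"contig_id": cid, "length": length, "circular": False, **s}
        )
        truth_virus_rows.append(
            {"contig_id": cid, "is_virus": passing, "criterion": criterion or ""}
        )

    def _tile_genes(cid: str, layout: Sequence[str], amg: PlantedAmg | None) -> tuple[str, dict]:
        """Lay genes end-to-end; returns (contig sequence, planted-AMG info)."""
        pos = 1
        seq_parts: list[str] = []
        amg_info: dict = {}
        for gi, cat in enumerate(layout, start=1):
            if cat == "AMG":
                assert amg is not None
                cds = _random_cds(rng, 100)
                glen = len(cds)
                gseq = cds
                category = "amg_candidate"
                ko: str | None = amg.ko
                pfam: str | None = None
                if amg.context == "no_ko":
                    ko = None
                elif amg.context == "inconsistent":
                    others = sorted(
                        p for k, ps in pmap.ko_to_pfams.items() if k != amg.ko for p in ps
                    )
                    allowed = pmap.ko_to_pfams.get(amg.ko, frozenset())
                    pfam = next(p for p in others if p not in allowed)
                else:
                    allowed = sorted(pmap.ko_to_pfams.get(amg.ko, frozenset()))
                    if not allowed:
                        raise ConfigError(f"KO {amg.ko} has no PFAM in the pathway map")
                    pfam = allowed[0]
                gene_id = f"{cid}|g{gi}"
                amg_gene_seqs[gene_id] = cds
                amg_info = {"gene_index": gi, "gene_id": gene_id, "ko": ko, "cds": cds}
            else:
                glen = int(rng.choice([300, 450, 600]))
                gseq = _random_seq(rng, glen)
                category = cat
                ko = pfam = None
                if config.noise.annotation_dropout > 0 and rng.random() < config.noise.annotation_dropout:
                    ko = pfam = None
            gene_rows.append(
                {
                    "contig_id": cid,
                    "gene_index": gi,
                    "start": pos,
                    "end": pos + glen - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "category": category,
                    "kegg_ko": ko or "",
                    "pfam_acc": pfam or "",
                    "product": category,
                }
            )
            seq_parts.append(gseq)
            pos += glen
        seq = "".join(seq_parts)
        if len(seq) < 5000:  # keep contigs size-eligible
            seq += _random_seq(rng, 5000 - len(seq))
        return seq, amg_info

    def _plain_layout(n_genes: int) -> list[str]:
        cats = []
        for gi in range(n_genes):
            if gi in (1, n_genes - 2):
                cats.append("hallmark")
            else:
                cats.append("phage" if rng.random() < 0.7 else "hypothetical")
        return cats

    # plain viral contigs
    for i in range(config.n_viral_contigs):
        cid = f"vir_{i:04d}"
        layout = _plain_layout(int(rng.integers(10, 16)))
        seq, _ = _tile_genes(cid, layout, None)
        if config.n_mags:
            host = mag_ids[i % config.n_mags]
            seq = _plant_host_evidence(cid, seq, host)
        contigs[cid] = seq
        _add_score(cid, len(seq), True, criteria_cycle[i % 4])
        contig_habitats[cid] = config.habitats[i % len(config.habitats)]
        truth_cluster_rows.append({"contig_id": cid, "representative_id": cid})

    # planted-AMG contigs
    for j, amg in enumerate(config.planted_amgs):
        cid = f"amgv_{j:04d}"
        layout = _context_layout(amg.context)
        seq, info = _tile_genes(cid, layout, amg)
        if config.n_mags:
            host = mag_ids[(config.n_viral_contigs + j) % config.n_mags]
            seq = _plant_host_evidence(cid, seq, host)
        contigs[cid] = seq
        _add_score(cid, len(seq), True, criteria_cycle[j % 4])
        contig_habitats[cid] = config.habitats[j % len(config.habitats)]
        truth_cluster_rows.append({"contig_id": cid, "representative_id": cid})
        status, reasons = AMG_CONTEXTS[amg.context]
        truth_amg_rows.append(
            {
                "contig_id": cid,
                "gene_index": info["gene_index"],
                "gene_id": info["gene_id"],
                "ko": info["ko"] or "",
                "context": amg.context,
                "expected_status": status,
                "expected_reasons": ",".join(sorted(reasons)),
                "n_syn": amg.n_syn,
                "n_nonsyn": amg.n_nonsyn,
            }
        )
        # realize the requested SNP counts on the AMG coding sequence
        syn_pool, nonsyn_pool = _enumerate_changes(info["cds"])
        if amg.n_syn > len(syn_pool) or amg.n_nonsyn > len(nonsyn_pool):
            raise ConfigError(
                f"AMG {amg.ko}: requested SNP counts exceed available changes "
                f"({len(syn_pool)} syn, {len(nonsyn_pool)} nonsyn)"
            )
        for pool, count in ((syn_pool, amg.n_syn), (nonsyn_pool, amg.n_nonsyn)):
            idx = rng.choice(len(pool), size=count, replace=False) if count else []
            for pi in sorted(int(x) for x in np.atleast_1d(idx)):
                p, ref, alt = pool[pi]
                variant_rows.append(
                    {"CHROM": info["gene_id"], "POS": p, "REF": ref, "ALT": alt}
                )

    # cluster families (parent + mutated copies, exact fragments emitted)
    fragment_rows: list[dict] = []
    for fi, (n_members, rate) in enumerate(config.cluster_families):
        parent_id = f"fam{fi}_{0:02d}"
        layout = _plain_layout(12)
        pseq, _ = _tile_genes(parent_id, layout, None)
        fam = {parent_id: pseq}
        for mi in range(1, n_members):
            mid = f"fam{fi}_{mi:02d}"
            fam[mid] = _mutate(rng, pseq, rate)
            # copies reuse the parent's gene layout
            for row in [r for r in gene_rows if r["contig_id"] == parent_id]:
                gene_rows.append({**row, "contig_id": mid})
        for cid, seq in fam.items():
            contigs[cid] = seq
            _add_score(cid, len(seq), True, criteria_cycle[fi % 4])
            contig_habitats[cid] = config.habitats[fi % len(config.habitats)]
            truth_cluster_rows.append({"contig_id": cid, "representative_id": parent_id})
        ids = sorted(fam)
        L = len(pseq)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                sa, sb = fam[ids[a]], fam[ids[b]]
                mism = sum(x != y for x, y in zip(sa, sb))
                pid = 100.0 * (1 - mism / L)
                fragment_rows.append(
                    {
                        "qseqid": ids[a],
                        "sseqid": ids[b],
                        "pident": round(pid, 4),
                        "length": L,
                        "qstart": 1,
                        "qend": L,
                        "sstart": 1,
                        "send": L,
                    }
                )

    # decoys: fail all four criteria
    for i in range(config.n_decoy_contigs):
        cid = f"decoy_{i:04d}"
        seq = _random_seq(rng, int(rng.integers(5000, 9000)))
        contigs[cid] = seq
        _add_score(cid, len(seq), False, None)
        contig_habitats[cid] = config.habitats[i % len(config.habitats)]

    # ---- per-sample depth tables -------------------------------------------
    meta_rows = []
    lo, hi = config.library_bases_range
    for sp in config.samples:
        lb = sp.library_bases
        if lb is None:
            lb = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        meta_rows.append(
            {
                "sample_id": sp.sample_id,
                "site": sp.site,
                "depth_cm": sp.depth_cm,
                "type": sp.mtype,
                "library_bases": lb,
            }
        )
    sample_metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "site", "depth_cm", "type", "library_bases"]
    )

    sites = sorted({sp.site for sp in config.samples})
    depths = sorted({sp.depth_cm for sp in config.samples})
    types = sorted({sp.mtype for sp in config.samples})
    p_shared, p_one_depth, p_all_depths = config.occupancy

    viral_ids = [c for c in contigs if not c.startswith("decoy_")]
    feature_presence: dict[str, dict] = {}
    for cid in viral_ids:
        f_sites = (
            set(sites)
            if len(sites) > 1 and rng.random() < p_shared
            else {sites[int(rng.integers(0, len(sites)))]}
        )
        u = rng.random()
        if u < p_one_depth or len(depths) == 1:
            f_depths = {depths[int(rng.integers(0, len(depths)))]}
        elif u < p_one_depth + p_all_depths or len(depths) == 2:
            f_depths = set(depths)
        else:
            pick = rng.choice(len(depths), size=2, replace=False)
            f_depths = {depths[int(pick[0])], depths[int(pick[1])]}
        if len(types) > 1:
            t = rng.random()
            f_types = {"bulk"} if t < 0.90 else (set(types) if t < 0.96 else {"virome"})
        else:
            f_types = set(types)
        feature_presence[cid] = {"sites": f_sites, "depths": f_depths, "types": f_types}

    depth_tables: dict[str, pd.DataFrame] = {}
    for sp in config.samples:
        rows = []
        for cid in viral_ids:
            pres = feature_presence[cid]
            present = (
                sp.site in pres["sites"]
                and sp.depth_cm in pres["depths"]
                and sp.mtype in pres["types"]
            )
            d = float(rng.lognormal(np.log(8.0), 0.8)) if present else 0.0
            rows.append({"feature_id": cid, "mean_depth": round(d, 4)})
        for m in mag_ids:
            d = float(rng.lognormal(np.log(15.0), 0.6)) if sp.mtype == "bulk" else float(
                rng.lognormal(np.log(1.5), 0.6)
            )
            rows.append({"feature_id": m, "mean_depth": round(d, 4)})
        depth_tables[sp.sample_id] = pd.DataFrame(rows, columns=["feature_id", "mean_depth"])

    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "contig_id",
            "gene_index",
            "start",
            "end",
            "strand",
            "category",
            "kegg_ko",
            "pfam_acc",
            "product",
        ],
    )
    scores = pd.DataFrame(
        score_rows,
        columns=[
            "contig_id",
            "length",
            "circular",
            "virsorter_category",
            "dvf_score",
            "dvf_p",
            "marvel_prob",
        ],
    )
    fragments = pd.DataFrame(
        fragment_rows,
        columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send"],
    )
    variants = pd.DataFrame(variant_rows, columns=["CHROM", "POS", "REF", "ALT"])

    truth = {
        "true_viruses": pd.DataFrame(
            truth_virus_rows, columns=["contig_id", "is_virus", "criterion"]
        ),
        "true_clusters": pd.DataFrame(
            truth_cluster_rows, columns=["contig_id", "representative_id"]
        ),
        "true_amgs": pd.DataFrame(
            truth_amg_rows,
            columns=[
                "contig_id",
                "gene_index",
                "gene_id",
                "ko",
                "context",
                "expected_status",
                "expected_reasons",
                "n_syn",
                "n_nonsyn",
            ],
        ),
        "true_hosts": pd.DataFrame(truth_host_rows, columns=["virus_id", "mag_id"]),
    }

    return FixtureBundle(
        contigs=contigs,
        genes=genes,
        scores=scores,
        fragments=fragments,
        sample_metadata=sample_metadata,
        depth=depth_tables,
        mag_taxonomy=mag_taxonomy,
        mag_seqs=mag_seqs,
        mag_trnas=mag_trnas,
        mag_spacers=mag_spacers,
        variants=variants,
        amg_gene_seqs=amg_gene_seqs,
        contig_habitats=contig_habitats,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: FixtureBundle, directory) -> dict[str, str]:
    """Write all bundle files under `directory`; returns and writes a manifest
    of relative path -> sha256 checksums (manifest.txt, key: value lines)."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        (d / "depth").mkdir(exist_ok=True)
        (d / "truth").mkdir(exist_ok=True)

        _write_fasta(d / "contigs.fasta", bundle.contigs)
        _write_fasta(d / "mags.fasta", bundle.mag_seqs)
        _write_fasta(
            d / "trnas.fasta",
            {f"{m}|trna{i}": t for m, ts in bundle.mag_trnas.items() for i, t in enumerate(ts)},
        )
        _write_fasta(
            d / "spacers.fasta",
            {f"{m}|spacer{i}": s for m, ss in bundle.mag_spacers.items() for i, s in enumerate(ss)},
        )
        _write_fasta(d / "amg_genes.fasta", bundle.amg_gene_seqs)

        bundle.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
        bundle.scores.to_csv(d / "scores.tsv", sep="\t", index=False)
        bundle.fragments.to_csv(d / "fragments.tsv", sep="\t", index=False)
        bundle.sample_metadata.to_csv(d / "samples.tsv", sep="\t", index=False)
        bundle.mag_taxonomy.to_csv(d / "mag_taxonomy.tsv", sep="\t", index=False)
        bundle.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"contig_id": c, "habitat": h} for c, h in bundle.contig_habitats.items()],
            columns=["contig_id", "habitat"],
        ).to_csv(d / "contig_habitats.tsv", sep="\t", index=False)
        for s, df in bundle.depth.items():
            df.to_csv(d / "depth" / f"{s}.tsv", sep="\t", index=False)
        for name, df in bundle.truth.items():
            df.to_csv(d / "truth" / f"{name}.tsv", sep="\t", index=False)

        manifest: dict[str, str] = {}
        for p in sorted(d.rglob("*")):
            if p.is_file() and p.name != "manifest.txt":
                manifest[str(p.relative_to(d))] = _sha256(p)
        with open(d / "manifest.txt", "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}: {v}\n")
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing bundle file: {exc.filename or directory}") from exc


def read_bundle(directory) -> FixtureBundle:
    """Read a bundle previously written with write_bundle."""
    d = Path(directory)
    str_cols = {"kegg_ko": str, "pfam_acc": str, "product": str}
    genes = pd.read_csv(d / "genes.tsv", sep="\t", dtype=str_cols, keep_default_na=False)
    if len(genes):
        for c in ("gene_index", "start", "end"):
            genes[c] = genes[c].astype(int)
    scores = pd.read_csv(d / "scores.tsv", sep="\t")
    fragments = pd.read_csv(d / "fragments.tsv", sep="\t")
    sample_metadata = pd.read_csv(d / "samples.tsv", sep="\t")
    mag_taxonomy = pd.read_csv(d / "mag_taxonomy.tsv", sep="\t")
    variants = pd.read_csv(d / "variants.tsv", sep="\t")
    hab_df = pd.read_csv(d / "contig_habitats.tsv", sep="\t")
    contig_habitats = dict(zip(hab_df["contig_id"], hab_df["habitat"]))

    depth = {
        p.stem: pd.read_csv(p, sep="\t") for p in sorted((d / "depth").glob("*.tsv"))
    }
    truth = {
        p.stem: pd.read_csv(p, sep="\t", keep_default_na=False)
        for p in sorted((d / "truth").glob("*.tsv"))
    }
    if "true_viruses" in truth and len(truth["true_viruses"]):
        tv = truth["true_viruses"]
        if tv["is_virus"].dtype == object:
            tv["is_virus"] = tv["is_virus"].map({"True": True, "False": False})

    trnas: dict[str, list[str]] = {}
    for rid, seq in _read_fasta(d / "trnas.fasta").items():
        trnas.setdefault(rid.split("|")[0], []).append(seq)
    spacers: dict[str, list[str]] = {}
    for rid, seq in _read_fasta(d / "spacers.fasta").items():
        spacers.setdefault(rid.split("|")[0], []).append(seq)
    mag_seqs = _read_fasta(d / "mags.fasta")
    for m in mag_seqs:
        trnas.setdefault(m, [])
        spacers.setdefault(m, [])

    return FixtureBundle(
        contigs=_read_fasta(d / "contigs.fasta"),
        genes=genes,
        scores=scores,
        fragments=fragments,
        sample_metadata=sample_metadata,
        depth=depth,
        mag_taxonomy=mag_taxonomy,
        mag_seqs=mag_seqs,
        mag_trnas=trnas,
        mag_spacers=spacers,
        variants=variants,
        amg_gene_seqs=_read_fasta(d / "amg_genes.fasta"),
        contig_habitats=contig_habitats,
        truth=truth,
    )
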