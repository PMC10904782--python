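"""Curation of putative auxiliary metabolic genes (AMGs) on viral contigs.

A candidate AMG is accepted only when it survives every check designed to
rule out residual host sequence and mis-annotation:

  * it lies inside the virus-like region of the contig after host-boundary
    trimming (terminal runs of cellular-looking genes are removed);
  * it is flanked by virus-like genes (phage or hallmark category) within a
    configurable gene window on BOTH sides, and is not itself terminal;
  * no transposon-category gene occurs within the window;
  * its KEGG KO and PFAM annotations are mutually consistent.

Accepted AMGs are then classified by KEGG-module membership: exclusive to
the methane-metabolism (MM) modules, shared between MM and other pathways,
or not MM at all; and cross-tabulated against the habitats of the contigs
carrying them. A minimal curated KO->module / KO->PFAM map covering
methanogenesis, methane oxidation and coenzyme F420 biosynthesis ships with
the package; users may substitute a full KEGG-derived map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENE_CATEGORIES = frozenset(
    {"hallmark", "phage", "cellular", "hypothetical", "transposon", "amg_candidate"}
)
VIRUS_LIKE = frozenset({"phage", "hallmark"})


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene on a contig (1-based inclusive coordinates)."""

    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    category: str
    kegg_ko: str | None = None
    pfam_acc: str | None = None
    product: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.contig_id} gene {self.gene_index}: start > end")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")


@dataclass(frozen=True)
class PathwayMap:
    """KO -> pathway-module and KO -> PFAM cross-maps plus the MM module set."""

    ko_to_modules: Mapping[str, frozenset[str]]
    mm_modules: frozenset[str]
    ko_to_pfams: Mapping[str, frozenset[str]]

    def __post_init__(self):
        all_modules = set().union(*self.ko_to_modules.values()) if self.ko_to_modules else set()
        if not self.mm_modules <= all_modules:
            raise ValueError("mm_modules must be a subset of the modules in ko_to_modules")


def load_pathway_map(module_path, pfam_path) -> PathwayMap:
    """Load KO->module (columns ko, module_id, is_mm) and KO->PFAM (ko, pfam) TSVs."""
    mod = pd.read_csv(module_path, sep="\t")
    pfam = pd.read_csv(pfam_path, sep="\t")
    ko_to_modules = {
        ko: frozenset(sub["module_id"]) for ko, sub in mod.groupby("ko")
    }
    mm = frozenset(mod.loc[mod["is_mm"].astype(int) == 1, "module_id"])
    ko_to_pfams = {ko: frozenset(sub["pfam"]) for ko, sub in pfam.groupby("ko")}
    return PathwayMap(ko_to_modules=ko_to_modules, mm_modules=mm, ko_to_pfams=ko_to_pfams)


def load_default_pathway_map() -> PathwayMap:
    """The bundled minimal methane-metabolism pathway map."""
    data = resources.files("vamp") / "data"
    return load_pathway_map(data / "ko_modules.tsv", data / "ko_pfam.tsv")


@dataclass(frozen=True)
class BoundaryTrim:
    contig_id: str
    kept_start: int      # first kept gene_index; 0 when whole contig host-like
    kept_end: int        # last kept gene_index (inclusive)
    trimmed_left: int
    trimmed_right: int

    @property
    def whole_contig_host_like(self) -> bool:
        return self.kept_start == 0

    def contains(self, gene_index: int) -> bool:
        return not self.whole_contig_host_like and self.kept_start <= gene_index <= self.kept_end


def _terminal_host_run(categories: Sequence[str], min_run: int, host_frac: float) -> int:
    """Length of the maximal terminal prefix (>= min_run genes) with no hallmark
    gene and a cellular fraction >= host_frac; 0 when none qualifies. A run
    must end on a cellular gene so trailing virus-like genes are never trimmed."""
    best = 0
    n_cellular = 0
    for i, cat in enumerate(categories):
        if cat == "hallmark":
            break
        if cat == "cellular":
            n_cellular += 1
        run = i + 1
        if cat == "cellular" and run >= min_run and n_cellular / run >= host_frac:
            best = run
    return best


def trim_host_boundary(
    genes: Sequence[GeneAnnotation], min_run: int = 3, host_frac: float = 0.7
) -> BoundaryTrim:
    """Mark terminal host-like gene runs of one contig for removal.

    Interior genes are never trimmed. If the trims from the two ends meet or
    cross, the whole contig is flagged host-like (empty kept interval).
    """
    if not genes:
        raise ValueError("trim_host_boundary needs at least one gene")
    ordered = sorted(genes, key=lambda g: g.gene_index)
    cats = [g.category for g in ordered]
    left = _terminal_host_run(cats, min_run, host_frac)
    right = _terminal_host_run(cats[::-1], min_run, host_frac)
    contig_id = ordered[0].contig_id
    n = len(ordered)
    if left + right >= n:
        return BoundaryTrim(contig_id, 0, -1, left, right)
    return BoundaryTrim(
        contig_id,
        kept_start=ordered[left].gene_index,
        kept_end=ordered[n - 1 - right].gene_index,
        trimmed_left=left,
        trimmed_right=right,
    )


REJECTION_REASONS = frozenset(
    {"not_flanked", "transposon_context", "annotation_inconsistent", "in_host_region", "no_ko"}
)


@dataclass(frozen=True)
class AmgCall:
    contig_id: str
    gene_index: int
    kegg_ko: str | None
    status: str                       # accepted | rejected
    rejection_reasons: frozenset[str] = field(default_factory=frozenset)
    mm_class: str = "non_mm"          # exclusive_mm | shared_mm | non_mm

    def __post_init__(self):
        if self.status == "accepted" and self.rejection_reasons:
            raise ValueError("accepted call cannot carry rejection reasons")


def classify_mm(ko: str | None, pathway_map: PathwayMap) -> str:
    """Classify a KO's pathway membership relative to the MM module set.

    exclusive_mm: every module of the KO is an MM module (and there is one);
    shared_mm: the KO sits in MM and non-MM modules; non_mm otherwise.
    Unknown KOs classify as non_mm with a warning.
    """
    if ko is None or ko not in pathway_map.ko_to_modules:
        if ko is not None:
            logger.warning("KO %s not in pathway map; classified non_mm", ko)
        return "non_mm"
    modules = pathway_map.ko_to_modules[ko]
    mm = modules & pathway_map.mm_modules
    if not mm:
        return "non_mm"
    return "exclusive_mm" if modules <= pathway_map.mm_modules else "shared_mm"


def curate_amg(
    candidate: GeneAnnotation,
    contig_genes: Sequence[GeneAnnotation],
    trim: BoundaryTrim,
    pathway_map: PathwayMap,
    window: int = 5,
) -> AmgCall:
    """Apply the full acceptance rule to one AMG candidate.

    Rejection reasons are accumulated independently; a call is accepted iff
    none apply. Flanking and transposon context are evaluated over the genes
    kept after boundary trimming, within `window` gene positions on each side.
    """
    if candidate.category != "amg_candidate":
        raise ValueError("curate_amg expects an amg_candidate gene")
    ordered = sorted(contig_genes, key=lambda g: g.gene_index)
    try:
        pos = next(i for i, g in enumerate(ordered) if g.gene_index == candidate.gene_index)
    except StopIteration:
        raise ValueError(
            f"candidate gene {candidate.gene_index} not found on contig {candidate.contig_id}"
        ) from None

    reasons: set[str] = set()

    if not trim.contains(candidate.gene_index):
        reasons.add("in_host_region")

    kept = [g for g in ordered if trim.contains(g.gene_index)]
    kept_pos = next(
        (i for i, g in enumerate(kept) if g.gene_index == candidate.gene_index), None
    )
    if kept_pos is None:
        reasons.add("not_flanked")  # outside the kept region there are no usable flanks
        left_window: list[GeneAnnotation] = []
        right_window: list[GeneAnnotation] = []
    else:
        left_window = kept[max(0, kept_pos - window) : kept_pos]
        right_window = kept[kept_pos + 1 : kept_pos + 1 + window]
        terminal = kept_pos == 0 or kept_pos == len(kept) - 1
        left_ok = any(g.category in VIRUS_LIKE for g in left_window)
        right_ok = any(g.category in VIRUS_LIKE for g in right_window)
        if terminal or not (left_ok and right_ok):
            reasons.add("not_flanked")

    if any(g.category == "transposon" for g in left_window + right_window):
        reasons.add("transposon_context")

    if candidate.kegg_ko is None:
        reasons.add("no_ko")
    else:
        allowed = pathway_map.ko_to_pfams.get(candidate.kegg_ko, frozenset())
        if candidate.pfam_acc is None or candidate.pfam_acc not in allowed:
            reasons.add("annotation_inconsistent")

    status = "accepted" if not reasons else "rejected"
    return AmgCall(
        contig_id=candidate.contig_id,
        gene_index=candidate.gene_index,
        kegg_ko=candidate.kegg_ko,
        status=status,
        rejection_reasons=frozenset(reasons),
        mm_class=classify_mm(candidate.kegg_ko, pathway_map),
    )


def curate_contig(
    genes: Sequence[GeneAnnotation],
    pathway_map: PathwayMap,
    window: int = 5,
    min_run: int = 3,
    host_frac: float = 0.7,
) -> list[AmgCall]:
    """Trim one contig's boundaries and curate all its AMG candidates."""
    trim = trim_host_boundary(genes, min_run=min_run, host_frac=host_frac)
    return [
        curate_amg(g, genes, trim, pathway_map, window=window)
        for g in sorted(genes, key=lambda x: x.gene_index)
        if g.category == "amg_candidate"
    ]


@dataclass(frozen=True)
class HabitatSummary:
    matrix: pd.DataFrame          # distinct KO x habitat, counts of carrying contigs
    amgs_per_habitat: pd.Series   # distinct KOs detected per habitat
    habitat_breadth: pd.Series    # habitats per KO
    n_single_habitat: int
    n_multi_habitat: int


def habitat_association(
    calls: Iterable[AmgCall], contig_habitats: Mapping[str, str], mm_only: bool = True
) -> HabitatSummary:
    """Cross-tabulate accepted AMGs (identity = KO) against contig habitats.

    Cells count viral contigs carrying the AMG in the habitat (a contig with
    two copies of the same KO counts once). mm_only restricts to AMGs whose
    KO touches a methane-metabolism module.
    """
    accepted = [
        c
        for c in calls
        if c.status == "accepted" and (not mm_only or c.mm_class in ("exclusive_mm", "shared_mm"))
    ]
    missing = sorted({c.contig_id for c in accepted} - set(contig_habitats))
    if missing:
        raise KeyError(f"contigs with no habitat label: {missing}")

    pairs = sorted({(c.kegg_ko, contig_habitats[c.contig_id], c.contig_id) for c in accepted})
    if pairs:
        df = pd.DataFrame(pairs, columns=["ko", "habitat", "contig_id"])
        matrix = df.pivot_table(
            index="ko", columns="habitat", values="contig_id", aggfunc="nunique", fill_value=0
        ).sort_index()
    else:
        matrix = pd.DataFrame(dtype=int)
    breadth = (matrix > 0).sum(axis=1) if not matrix.empty else pd.Series(dtype=int)
    per_habitat = (matrix > 0).sum(axis=0) if not matrix.empty else pd.Series(dtype=int)
    return HabitatSummary(
        matrix=matrix,
        amgs_per_habitat=per_habitat,
        habitat_breadth=breadth,
        n_single_habitat=int((breadth == 1).sum()),
        n_multi_habitat=int((breadth > 1).sum()),
    )


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read the gene-annotation TSV (contig_id, gene_index, start, end, strand,
    category, kegg_ko, pfam_acc, product; empty = absent)."""
    df = pd.read_csv(path, sep="\t", dtype={"kegg_ko": "string", "pfam_acc": "string"})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            GeneAnnotation(
                contig_id=str(r.contig_id),
                gene_index=int(r.gene_index),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                category=str(r.category),
                kegg_ko=None if pd.isna(r.kegg_ko) else str(r.kegg_ko),
                pfam_acc=None if pd.isna(r.pfam_acc) else str(r.pfam_acc),
                product="" if pd.isna(getattr(r, "product", None)) else str(r.product),
            )
        )
    return out


def calls_to_frame(calls: Iterable[AmgCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": c.contig_id,
            "gene_index": c.gene_index,
            "kegg_ko": c.kegg_ko or "",
            "status": c.status,
            "rejection_reasons": ",".join(sorted(c.rejection_reasons)),
            "mm_class": c.mm_class,
        }
        for c in calls
    )
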