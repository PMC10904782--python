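"""vOTU clustering from local-alignment fragments.

Pairwise fragments (BLAST outfmt-6 style) are merged into a single ANI /
aligned-fraction estimate per contig pair; pairs sharing >= 95% identity
across >= 80% of the shorter contig's length become edges; a greedy
longest-first centroid pass then partitions contigs into vOTUs, each
represented by its longest member (the "seed").

Aligned fraction is evaluated on each contig; the edge rule uses the larger
of the two fractions, i.e. coverage of the shorter contig — the
MIUViG-style convention for "80% of their lengths".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_MIN_ANI = 95.0
DEFAULT_MIN_AF = 0.80


@dataclass(frozen=True)
class AlignmentFragment:
    """One local alignment between a query and target contig (1-based, inclusive)."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    percent_identity: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity {self.percent_identity} outside [0, 100]")


@dataclass(frozen=True)
class PairwiseAni:
    """Merged alignment summary for one contig pair."""

    query_id: str
    target_id: str
    ani: float
    af_query: float
    af_target: float


@dataclass(frozen=True)
class VOtuCluster:
    representative_id: str
    member_ids: tuple[str, ...]


def _merge_intervals(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by a union of 1-based inclusive intervals."""
    covered = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


def merge_fragments(
    fragments: Sequence[AlignmentFragment], len_q: int, len_t: int
) -> PairwiseAni | None:
    """Collapse all fragments of one ordered (query, target) pair.

    Fragments are sorted by query start; overlapping query bases are counted
    once, with the overlap trimmed from the later-sorted fragment so that the
    identity weighting never double-counts a base. ANI is the length-weighted
    mean identity over the trimmed fragments; aligned fractions are the merged
    covered bases over each contig's length.

    Returns None for an empty fragment list (no edge can be formed).
    """
    if not fragments:
        return None
    qids = {f.query_id for f in fragments}
    tids = {f.target_id for f in fragments}
    if len(qids) != 1 or len(tids) != 1:
        raise ValueError("fragments must all reference one (query, target) pair")

    ordered = sorted(fragments, key=lambda f: (min(f.q_start, f.q_end), -abs(f.q_end - f.q_start)))
    weighted = 0.0
    total = 0
    frontier = 0  # rightmost query base already credited
    for f in ordered:
        s, e = min(f.q_start, f.q_end), max(f.q_start, f.q_end)
        s = max(s, frontier + 1)
        if s > e:
            continue  # fully inside an earlier fragment
        flen = e - s + 1
        weighted += flen * f.percent_identity
        total += flen
        frontier = max(frontier, e)
    if total == 0:
        return None
    ani = weighted / total

    q_cov = _merge_intervals([(min(f.q_start, f.q_end), max(f.q_start, f.q_end)) for f in fragments])
    t_cov = _merge_intervals([(min(f.t_start, f.t_end), max(f.t_start, f.t_end)) for f in fragments])
    return PairwiseAni(
        query_id=fragments[0].query_id,
        target_id=fragments[0].target_id,
        ani=ani,
        af_query=q_cov / len_q,
        af_target=t_cov / len_t,
    )


def build_edges(
    anis: Iterable[PairwiseAni],
    min_ani: float = DEFAULT_MIN_ANI,
    min_af: float = DEFAULT_MIN_AF,
) -> set[frozenset[str]]:
    """Edges between contig pairs passing both thresholds.

    The aligned-fraction requirement is met when the better-covered contig
    (always the shorter one for a given merged alignment length) reaches
    min_af. Self-pairs are ignored; a contig is always linked to itself
    implicitly during clustering.
    """
    edges: set[frozenset[str]] = set()
    for rec in anis:
        if rec is None or rec.query_id == rec.target_id:
            continue
        if rec.ani >= min_ani and max(rec.af_query, rec.af_target) >= min_af:
            edges.add(frozenset((rec.query_id, rec.target_id)))
    return edges


def greedy_cluster(
    lengths: Mapping[str, int], edges: set[frozenset[str]]
) -> list[VOtuCluster]:
    """Longest-first greedy centroid clustering.

    Contigs are visited by decreasing length (ties broken by id). Each contig
    joins the first (i.e. longest) existing centroid it has an edge to, or
    founds a new cluster. The output partitions the input; every
    representative is the longest member of its cluster.
    """
    order = sorted(lengths, key=lambda c: (-lengths[c], c))
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for cid in order:
        for cen in centroids:
            if frozenset((cid, cen)) in edges:
                members[cen].append(cid)
                break
        else:
            centroids.append(cid)
            members[cid] = [cid]
    return [
        VOtuCluster(representative_id=cen, member_ids=tuple(members[cen])) for cen in centroids
    ]


def single_linkage_cluster(
    lengths: Mapping[str, int], edges: set[frozenset[str]]
) -> list[VOtuCluster]:
    """Connected-component (single-linkage) alternative for sensitivity analysis."""
    parent = {c: c for c in lengths}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in edges:
        pair = sorted(edge)
        if len(pair) == 2 and pair[0] in parent and pair[1] in parent:
            ra, rb = find(pair[0]), find(pair[1])
            if ra != rb:
                parent[rb] = ra

    comps: dict[str, list[str]] = {}
    for c in lengths:
        comps.setdefault(find(c), []).append(c)
    clusters = []
    for mem in comps.values():
        mem.sort(key=lambda c: (-lengths[c], c))
        clusters.append(VOtuCluster(representative_id=mem[0], member_ids=tuple(mem)))
    clusters.sort(key=lambda cl: (-lengths[cl.representative_id], cl.representative_id))
    return clusters


def read_fragment_table(path) -> list[AlignmentFragment]:
    """Read BLAST outfmt-6-style TSV (qseqid sseqid pident length qstart qend sstart send)."""
    cols = ["qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send"]
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"fragment table missing columns: {missing}")
    return [
        AlignmentFragment(
            query_id=str(r.qseqid),
            target_id=str(r.sseqid),
            q_start=int(r.qstart),
            q_end=int(r.qend),
            t_start=int(r.sstart),
            t_end=int(r.send),
            percent_identity=float(r.pident),
        )
        for r in df.itertuples(index=False)
    ]


def pairwise_ani_from_fragments(
    fragments: Sequence[AlignmentFragment], lengths: Mapping[str, int]
) -> list[PairwiseAni]:
    """Group fragments by unordered pair and merge each group.

    When a pair is reported in both orientations (exact all-vs-all searches
    emit (a, b) and (b, a) with identical content), the lexicographically
    first orientation is used and the other dropped.
    """
    by_pair: dict[tuple[str, str], list[AlignmentFragment]] = {}
    for f in fragments:
        by_pair.setdefault((f.query_id, f.target_id), []).append(f)

    seen: set[frozenset[str]] = set()
    out: list[PairwiseAni] = []
    for (q, t), frags in sorted(by_pair.items()):
        key = frozenset((q, t))
        if q == t or key in seen:
            continue
        seen.add(key)
        rec = merge_fragments(frags, lengths[q], lengths[t])
        if rec is not None:
            out.append(rec)
    return out


def clusters_to_frame(clusters: Sequence[VOtuCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "representative_id": cl.representative_id,
            "member_ids": ",".join(cl.member_ids),
        }
        for cl in clusters
    )
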