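"""Virus -> MAG host linkage from four evidence types.

The four signals follow the classic in-silico host-prediction repertoire:
(i) exact tRNA carry-over, (ii) tetranucleotide composition similarity,
(iii) nucleotide sequence similarity (k-mer containment of the virus in the
MAG), and (iv) CRISPR spacer matches. Evidence is combined into a weighted
aggregate score; pairs at or above a threshold are reported best-first.
This is a self-contained scorer with exposed weights and gates, not a
reproduction of any trained host-prediction model.

Lineage-level virus/host abundance ratios compare the summed abundance of
viruses linked to a lineage against the summed abundance of that lineage's
MAGs, per sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from vamp._seq import containment, exact_occurs, find_with_mismatches, kmer_codes, revcomp

#: evidence weights (crispr, trna, similarity, composition) and report threshold
DEFAULT_WEIGHTS = {"crispr": 3.0, "trna": 2.0, "similarity": 2.0, "composition": 1.0}
DEFAULT_THRESHOLD = 3.0
DEFAULT_SIM_MIN = 0.5      # virus-in-MAG k-mer containment gate
DEFAULT_COMP_MAX = 0.25    # tetranucleotide L1 distance gate


def match_crispr(
    virus_seq: str,
    spacers: Sequence[str],
    max_mismatch: int = 1,
    min_len: int = 25,
) -> tuple[bool, list[int]]:
    """CRISPR spacer match: some spacer (either orientation) occurs in the
    virus with at most `max_mismatch` substitutions. Spacers shorter than
    `min_len` are ignored (too unspecific). Returns (hit, matched spacer indices).
    """
    hits = []
    for i, sp in enumerate(spacers):
        if len(sp) < min_len:
            continue
        if find_with_mismatches(sp, virus_seq, max_mismatch) or find_with_mismatches(
            revcomp(sp), virus_seq, max_mismatch
        ):
            hits.append(i)
    return bool(hits), hits


def match_trna(virus_seq: str, trnas: Sequence[str], min_len: int = 60) -> bool:
    """Exact full-length tRNA occurrence in the virus, either strand."""
    return any(len(t) >= min_len and exact_occurs(t, virus_seq) for t in trnas)


def similarity_score(virus_seq: str, mag_seq: str, k: int = 21) -> float:
    """Fraction of the virus's canonical k-mers contained in the MAG."""
    return containment(virus_seq, mag_seq, k)


def _tetra_freqs(seq: str) -> np.ndarray:
    """Normalized canonical tetranucleotide frequency vector (256 slots; a
    4-mer and its reverse complement share the smaller code's slot)."""
    codes = kmer_codes(seq, 4)
    if codes.size == 0:
        return np.zeros(256)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(4):
        rc = rc * 4 + (3 - (tmp & 3))
        tmp >>= 2
    canon = np.minimum(codes, rc)
    freq = np.bincount(canon, minlength=256).astype(float)
    return freq / freq.sum()


def composition_distance(virus_seq: str, mag_seq: str) -> float:
    """L1 distance between canonical tetranucleotide frequency vectors."""
    return float(np.abs(_tetra_freqs(virus_seq) - _tetra_freqs(mag_seq)).sum())


@dataclass(frozen=True)
class HostPrediction:
    virus_id: str
    mag_id: str
    trna_match: bool
    crispr_match: bool
    similarity_score: float
    composition_distance: float
    aggregate_score: float
    rank: int


def aggregate_predictions(
    evidence: Iterable[Mapping],
    weights: Mapping[str, float] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    sim_min: float = DEFAULT_SIM_MIN,
    comp_max: float = DEFAULT_COMP_MAX,
) -> dict[str, list[HostPrediction]]:
    """Combine per-pair evidence into ranked host predictions per virus.

    aggregate = w_crispr*[crispr] + w_trna*[trna] + w_sim*[similarity >= sim_min]
              + w_comp*[composition_distance <= comp_max]

    Each evidence mapping needs keys virus_id, mag_id, crispr_match,
    trna_match, similarity_score, composition_distance. Pairs with aggregate
    >= threshold are reported best-first; ties break by composition distance
    then mag_id.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValueError("evidence weights must be non-negative")

    per_virus: dict[str, list[HostPrediction]] = {}
    rows: dict[str, list[dict]] = {}
    for ev in evidence:
        rows.setdefault(str(ev["virus_id"]), []).append(dict(ev))
    for vid, evs in rows.items():
        scored = []
        for ev in evs:
            agg = (
                w["crispr"] * bool(ev["crispr_match"])
                + w["trna"] * bool(ev["trna_match"])
                + w["similarity"] * (float(ev["similarity_score"]) >= sim_min)
                + w["composition"] * (float(ev["composition_distance"]) <= comp_max)
            )
            if agg >= threshold:
                scored.append((agg, ev))
        scored.sort(key=lambda t: (-t[0], t[1]["composition_distance"], t[1]["mag_id"]))
        per_virus[vid] = [
            HostPrediction(
                virus_id=vid,
                mag_id=str(ev["mag_id"]),
                trna_match=bool(ev["trna_match"]),
                crispr_match=bool(ev["crispr_match"]),
                similarity_score=float(ev["similarity_score"]),
                composition_distance=float(ev["composition_distance"]),
                aggregate_score=float(agg),
                rank=i + 1,
            )
            for i, (agg, ev) in enumerate(scored)
        ]
    return per_virus


def score_pairs(
    viruses: Mapping[str, str],
    mags: Mapping[str, Mapping],
    k: int = 21,
    max_mismatch: int = 1,
    spacer_min_len: int = 25,
) -> list[dict]:
    """Compute all four evidence signals for every virus x MAG pair.

    Each MAG mapping needs keys: sequence, trnas (list), spacers (list).
    """
    out = []
    for vid, vseq in viruses.items():
        for mid, mag in mags.items():
            crispr, _ = match_crispr(
                vseq, mag.get("spacers", []), max_mismatch=max_mismatch, min_len=spacer_min_len
            )
            out.append(
                {
                    "virus_id": vid,
                    "mag_id": mid,
                    "crispr_match": crispr,
                    "trna_match": match_trna(vseq, mag.get("trnas", [])),
                    "similarity_score": similarity_score(vseq, mag["sequence"], k=k),
                    "composition_distance": composition_distance(vseq, mag["sequence"]),
                }
            )
    return out


@dataclass(frozen=True)
class RatioRecord:
    lineage: str
    sample_id: str
    virus_abundance: float
    host_abundance: float
    ratio: float | None   # None when host abundance is zero (flagged, not infinite)

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def virus_host_ratio(
    virus_abundance: pd.DataFrame,
    virus_to_lineage: Mapping[str, str],
    mag_abundance: pd.DataFrame,
    mag_to_lineage: Mapping[str, str],
) -> list[RatioRecord]:
    """Lineage-specific virus/host abundance ratios per sample.

    ratio = sum of abundances of viruses linked to the lineage / sum of
    abundances of the lineage's MAGs, computed per sample on matrices with
    features as rows and samples as columns. A lineage with zero host
    abundance in a sample yields an undefined (flagged) ratio.
    """
    lineages = sorted(set(mag_to_lineage.values()) | set(virus_to_lineage.values()))
    samples = [s for s in virus_abundance.columns if s in mag_abundance.columns]
    out = []
    for lin, s in itertools.product(lineages, samples):
        v_ids = [v for v, l in virus_to_lineage.items() if l == lin and v in virus_abundance.index]
        m_ids = [m for m, l in mag_to_lineage.items() if l == lin and m in mag_abundance.index]
        v_ab = float(virus_abundance.loc[v_ids, s].sum()) if v_ids else 0.0
        h_ab = float(mag_abundance.loc[m_ids, s].sum()) if m_ids else 0.0
        ratio = None if h_ab == 0 else v_ab / h_ab
        out.append(RatioRecord(lin, s, v_ab, h_ab, ratio))
    return out


def predictions_to_frame(per_virus: Mapping[str, Sequence[HostPrediction]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "virus_id": p.virus_id,
            "mag_id": p.mag_id,
            "crispr_match": p.crispr_match,
            "trna_match": p.trna_match,
            "similarity_score": p.similarity_score,
            "composition_distance": p.composition_distance,
            "aggregate_score": p.aggregate_score,
            "rank": p.rank,
        }
        for vid in sorted(per_virus)
        for p in per_virus[vid]
    )
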