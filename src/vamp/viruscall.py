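"""Ensemble virus calling from per-contig predictor scores.

A contig is called viral when it satisfies at least one of four criteria
combining VirSorter categories, DeepVirFinder score/p-value, and MARVEL
probability:

  (i)   VirSorter category in {1, 2, 4, 5}
  (ii)  DeepVirFinder score >= 0.9 and p < 0.05
  (iii) MARVEL probability >= 90%
  (iv)  DeepVirFinder score >= 0.7 and p < 0.05 and MARVEL probability >= 70%

A score a tool did not report simply fails that tool's criteria; the ensemble
was designed for heterogeneous datasets where not every predictor ran on
every contig. Called contigs are additionally screened against a blocklist
of putative laboratory-contaminant genomes by canonical k-mer containment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from vamp._seq import containment

logger = logging.getLogger(__name__)

#: Default ensemble thresholds; keys mirror the criterion they parametrize.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "virsorter_categories": frozenset({1, 2, 4, 5}),
    "dvf_score_strict": 0.9,
    "dvf_p": 0.05,
    "marvel_strict": 90.0,
    "dvf_score_relaxed": 0.7,
    "marvel_relaxed": 70.0,
}

#: Size-eligibility rule for assembled contigs entering virus discovery.
MIN_LINEAR_LENGTH = 5000
CIRCULAR_RANGE = (1500, 5000)


class ScoreValidationError(ValueError):
    """A predictor score fell outside its documented range."""


@dataclass(frozen=True)
class ToolScoreRecord:
    """Per-contig output of the three virus predictors (absent = None)."""

    contig_id: str
    length: int
    circular: bool = False
    virsorter_category: int | None = None
    dvf_score: float | None = None
    dvf_p: float | None = None
    marvel_prob: float | None = None

    def validate(self) -> None:
        if self.length < 0:
            raise ScoreValidationError(f"{self.contig_id}: negative length")
        if self.virsorter_category is not None and not 1 <= self.virsorter_category <= 6:
            raise ScoreValidationError(
                f"{self.contig_id}: virsorter_category {self.virsorter_category} not in 1..6"
            )
        for name, val, lo, hi in (
            ("dvf_score", self.dvf_score, 0.0, 1.0),
            ("dvf_p", self.dvf_p, 0.0, 1.0),
            ("marvel_prob", self.marvel_prob, 0.0, 100.0),
        ):
            if val is not None and not (lo <= val <= hi):
                raise ScoreValidationError(f"{self.contig_id}: {name}={val} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class VirusCall:
    """Decision for one contig: ensemble membership and downstream eligibility."""

    contig_id: str
    is_virus: bool
    criteria_met: frozenset[str] = field(default_factory=frozenset)
    contaminant: bool = False
    eligible: bool = True


def _eligible(length: int, circular: bool) -> bool:
    if length >= MIN_LINEAR_LENGTH:
        return True
    return circular and CIRCULAR_RANGE[0] <= length <= CIRCULAR_RANGE[1]


def classify_virus(
    record: ToolScoreRecord, thresholds: Mapping[str, object] | None = None
) -> VirusCall:
    """Evaluate the four ensemble criteria independently and take their union.

    Boundary semantics are literal: score thresholds are inclusive (>=), the
    DeepVirFinder p-value cut is strict (<), so p = 0.05 exactly fails.
    """
    record.validate()
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    met: set[str] = set()
    if record.virsorter_category in th["virsorter_categories"]:
        met.add("i")
    dvf_ok_p = record.dvf_p is not None and record.dvf_p < th["dvf_p"]
    if record.dvf_score is not None and record.dvf_score >= th["dvf_score_strict"] and dvf_ok_p:
        met.add("ii")
    if record.marvel_prob is not None and record.marvel_prob >= th["marvel_strict"]:
        met.add("iii")
    if (
        record.dvf_score is not None
        and record.dvf_score >= th["dvf_score_relaxed"]
        and dvf_ok_p
        and record.marvel_prob is not None
        and record.marvel_prob >= th["marvel_relaxed"]
    ):
        met.add("iv")

    return VirusCall(
        contig_id=record.contig_id,
        is_virus=bool(met),
        criteria_met=frozenset(met),
        eligible=_eligible(record.length, record.circular),
    )


def screen_contaminants(
    contigs: Mapping[str, str],
    blocklist: Mapping[str, str] | Iterable[str],
    k: int = 21,
    tau: float = 0.5,
) -> dict[str, bool]:
    """Flag contigs contained in putative laboratory-contaminant genomes.

    A contig is flagged when, for some blocklist genome, the fraction of the
    contig's canonical k-mers shared with that genome is >= tau. Contigs
    shorter than k are never flagged (warning logged).
    """
    if k < 11:
        raise ValueError(f"k-mer size {k} too small for a containment screen (need >= 11)")
    block_seqs = list(blocklist.values()) if isinstance(blocklist, Mapping) else list(blocklist)
    flags: dict[str, bool] = {}
    for cid, seq in contigs.items():
        if len(seq) < k:
            logger.warning("contig %s shorter than k=%d; contaminant screen skipped", cid, k)
            flags[cid] = False
            continue
        flags[cid] = any(containment(seq, g, k) >= tau for g in block_seqs)
    return flags


def _opt(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_score_table(path) -> list[ToolScoreRecord]:
    """Read the predictor-score TSV (empty field = tool did not report)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        vs = _opt(row.virsorter_category)
        records.append(
            ToolScoreRecord(
                contig_id=str(row.contig_id),
                length=int(row.length),
                circular=bool(row.circular),
                virsorter_category=None if vs is None else int(vs),
                dvf_score=_opt(row.dvf_score),
                dvf_p=_opt(row.dvf_p),
                marvel_prob=_opt(row.marvel_prob),
            )
        )
    return records


def calls_to_frame(calls: Iterable[VirusCall]) -> pd.DataFrame:
    """Tabulate calls for the output TSV (criteria comma-joined, sorted)."""
    return pd.DataFrame(
        {
            "contig_id": c.contig_id,
            "is_virus": c.is_virus,
            "criteria_met": ",".join(sorted(c.criteria_met)),
            "contaminant": c.contaminant,
            "eligible": c.eligible,
        }
        for c in calls
    )
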