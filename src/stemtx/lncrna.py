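"""lncRNA candidate filtering.

The cascade applied to each transcript model:

1. length     — spliced length strictly greater than ``min_length`` nt;
2. exon count — at least ``min_exons`` exons;
3. ORF        — longest ATG-initiated forward-frame ORF no longer than
   ``max_orf`` nt (start through stop codon inclusive);
4. consensus  — external coding-potential predictors (e.g. CPC, CNCI, CPAT,
   Pfam), consumed as an evidence table, must agree the transcript is
   non-coding (``all_noncoding``) or a majority must (``majority``);
   missing predictor verdicts do not veto.

A transcript is called lncRNA only when all four stages pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .models import TranscriptModel

STOP_CODONS = ("TAA", "TAG", "TGA")
PREDICTORS = ("CPC", "CNCI", "CPAT", "Pfam")
VERDICTS = ("coding", "noncoding", "missing")
CONSENSUS_RULES = ("all_noncoding", "majority")


@dataclass(frozen=True)
class CodingEvidence:
    """Per-predictor coding/noncoding verdicts for one transcript."""

    transcript_id: str
    verdicts: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, v in self.verdicts.items():
            if name not in PREDICTORS:
                raise ValueError(f"unknown predictor {name!r}")
            if v not in VERDICTS:
                raise ValueError(f"unknown verdict {v!r} for {name}")

    @classmethod
    def empty(cls, transcript_id: str) -> "CodingEvidence":
        return cls(transcript_id, {p: "missing" for p in PREDICTORS})


@dataclass(frozen=True)
class LncRNACall:
    """Per-stage decision record for one transcript."""

    transcript_id: str
    passed_length: bool
    passed_exons: bool
    longest_orf_nt: int
    passed_orf: bool
    predictor_consensus: bool
    final: bool


def longest_orf(seq: str) -> int:
    """Length (nt) of the longest complete ORF in the three forward frames.

    An ORF runs from an ATG to the first in-frame stop codon, inclusive of
    the stop. Codons containing ambiguity characters never match start or
    stop. Returns 0 when no complete ORF exists.
    """
    seq = seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        open_start = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = p
            elif codon in STOP_CODONS:
                best = max(best, p + 3 - open_start)
                open_start = None
    return best


def _consensus(ev: CodingEvidence, rule: str) -> bool:
    if rule not in CONSENSUS_RULES:
        raise ValueError(f"unknown consensus rule {rule!r}")
    available = [v for v in ev.verdicts.values() if v != "missing"]
    if not available:
        return True  # no evidence available -> nothing vetoes
    noncoding = sum(1 for v in available if v == "noncoding")
    if rule == "all_noncoding":
        return noncoding == len(available)
    return noncoding > len(available) / 2


def classify_lncrna(
    t: TranscriptModel,
    seq: str,
    ev: CodingEvidence | None = None,
    min_length: int = 200,
    min_exons: int = 1,
    max_orf: int = 300,
    consensus_rule: str = "all_noncoding",
) -> LncRNACall:
    """Run the full lncRNA cascade for one transcript."""
    if len(seq) != t.length:
        raise ValueError(
            f"{t.transcript_id}: sequence length {len(seq)} does not match "
            f"transcript length {t.length}"
        )
    if ev is None:
        ev = CodingEvidence.empty(t.transcript_id)
    orf = longest_orf(seq)
    passed_length = t.length > min_length
    passed_exons = t.exon_count >= min_exons
    passed_orf = orf <= max_orf
    consensus = _consensus(ev, consensus_rule)
    return LncRNACall(
        transcript_id=t.transcript_id,
        passed_length=passed_length,
        passed_exons=passed_exons,
        longest_orf_nt=orf,
        passed_orf=passed_orf,
        predictor_consensus=consensus,
        final=passed_length and passed_exons and passed_orf and consensus,
    )


def classify_lncrnas(
    transcripts: Sequence[TranscriptModel],
    seqs: Mapping[str, str],
    evidence: Mapping[str, CodingEvidence] | None = None,
    **params,
) -> list[LncRNACall]:
    evidence = evidence or {}
    return [
        classify_lncrna(t, seqs[t.transcript_id], evidence.get(t.transcript_id), **params)
        for t in transcripts
    ]


def lncrna_summary(
    calls: Sequence[LncRNACall],
    transcripts: Sequence[TranscriptModel],
    mrna_ids: Iterable[str] | None = None,
) -> dict:
    """Summary statistics of the final lncRNA set, with an mRNA comparison.

    ``mrna_ids`` names the transcripts to treat as the mRNA reference set
    for the exon-count comparison; defaults to all transcripts not called
    lncRNA.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    finals = [c for c in calls if c.final]
    final_ids = {c.transcript_id for c in finals}
    if mrna_ids is None:
        mrna_ids = [tid for tid in by_id if tid not in final_ids]
    mrna_models = [by_id[tid] for tid in mrna_ids if tid in by_id]
    lnc_models = [by_id[c.transcript_id] for c in finals if c.transcript_id in by_id]
    out: dict = {"n_final": len(finals)}
    if lnc_models:
        lengths = [t.length for t in lnc_models]
        out["mean_length"] = sum(lengths) / len(lengths)
        out["length_range"] = (min(lengths), max(lengths))
        out["mean_exons_lncrna"] = sum(t.exon_count for t in lnc_models) / len(
            lnc_models
        )
    else:
        out["mean_length"] = float("nan")
        out["length_range"] = None
        out["mean_exons_lncrna"] = float("nan")
    out["mean_exons_mrna"] = (
        sum(t.exon_count for t in mrna_models) / len(mrna_models)
        if mrna_models
        else float("nan")
    )
    return out
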