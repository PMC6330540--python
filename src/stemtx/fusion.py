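"""Fusion transcript detection from multi-locus alignments.

A full-length transcript is a fusion candidate when

(a) it maps to two or more loci in the genome,
(b) each mapped locus covers at least ``min_locus_cov`` of the transcript,
(c) the combined alignment coverage is at least ``min_combined_cov``, and
(d) mapped loci are at least ``min_separation`` bp apart (different
    chromosomes satisfy this unconditionally).

Coverage is computed on the query (read) axis with interval unions, so
overlapping alignment blocks are never double-counted. Candidates can then
be validated with short-read evidence: junction-spanning reads and uniquely
mapping discordant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import (
    AlignmentRecordSet,
    GenomicInterval,
    interval_union_len,
    merge_intervals,
)

logger = logging.getLogger(__name__)

CRITERIA = ("a", "b", "c", "d")

READ_COLUMNS = ["read_id", "mate", "query_id", "start", "end", "unique_flag"]


@dataclass(frozen=True)
class FusionLocus:
    """A merged alignment locus with its query-side coverage."""

    interval: GenomicInterval
    query_segments: tuple[tuple[int, int], ...]
    coverage: float
    unique: bool


@dataclass(frozen=True)
class FusionCandidate:
    query_id: str
    query_length: int
    loci: tuple[FusionLocus, ...]
    combined_coverage: float
    separation_class: str  # "inter_chromosome" | "intra_chromosome" | "na"
    separation_bp: int | None  # minimal pairwise gap for intra, None for inter
    junctions: tuple[int, ...]  # query coordinates between consecutive loci
    spanning_support: int = 0
    discordant_support: int = 0
    status: str = "candidate"  # candidate | validated | rejected
    rejected_criterion: str | None = None

    @property
    def is_candidate(self) -> bool:
        return self.status != "rejected"


def _merge_loci(record: AlignmentRecordSet, require_unique: bool):
    """Merge alignment rows whose genomic intervals overlap into loci.

    Rows are merged only on genomic overlap (same chromosome); nearby but
    non-overlapping loci stay separate so that criterion (d) remains a real
    test. Returns None when unique-filtering leaves nothing.
    """
    rows = [loc for loc in record.loci if (loc.unique or not require_unique)]
    if not rows:
        return []
    rows = sorted(rows, key=lambda l: (l.interval.chrom, l.interval.start))
    merged: list[dict] = []
    for loc in rows:
        last = merged[-1] if merged else None
        if (
            last is not None
            and loc.interval.chrom == last["chrom"]
            and loc.interval.start < last["end"]
        ):
            last["end"] = max(last["end"], loc.interval.end)
            last["segs"].append((loc.query_start, loc.query_end))
            last["unique"] = last["unique"] and loc.unique
        else:
            merged.append(
                {
                    "chrom": loc.interval.chrom,
                    "start": loc.interval.start,
                    "end": loc.interval.end,
                    "strand": loc.interval.strand,
                    "segs": [(loc.query_start, loc.query_end)],
                    "unique": loc.unique,
                }
            )
    loci = []
    for m in merged:
        segs = merge_intervals(m["segs"])
        if len(segs) < len(m["segs"]):
            logger.warning(
                "%s: overlapping query intervals at locus %s:%d-%d merged",
                record.query_id,
                m["chrom"],
                m["start"],
                m["end"],
            )
        loci.append(
            FusionLocus(
                interval=GenomicInterval(m["chrom"], m["start"], m["end"], m["strand"]),
                query_segments=tuple(segs),
                coverage=interval_union_len(segs) / record.query_length,
                unique=m["unique"],
            )
        )
    return loci


def _separation(loci: Sequence[FusionLocus]) -> tuple[str, int | None, int | None]:
    """(class, min intra gap, min gap across all pairs incl. inter=inf)."""
    chroms = {l.interval.chrom for l in loci}
    min_gap: int | None = None
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i].interval, loci[j].interval
            if a.chrom != b.chrom:
                continue
            gap = max(0, max(a.start, b.start) - min(a.end, b.end))
            min_gap = gap if min_gap is None else min(min_gap, gap)
    if len(chroms) > 1 and min_gap is None:
        return "inter_chromosome", None, None
    cls = "inter_chromosome" if len(chroms) > 1 else "intra_chromosome"
    return cls, min_gap, min_gap


def detect_fusions(
    alignments: Iterable[AlignmentRecordSet],
    min_locus_cov: float = 0.05,
    min_combined_cov: float = 0.95,
    min_separation: int = 10_000,
    require_unique: bool = False,
) -> list[FusionCandidate]:
    """Apply the four fusion criteria to each query's alignment record set.

    Every query yields a :class:`FusionCandidate`; failures carry the first
    violated criterion in printed order (a, b, c, d).
    """
    out: list[FusionCandidate] = []
    for record in sorted(alignments, key=lambda r: r.query_id):
        loci = tuple(_merge_loci(record, require_unique))
        combined = (
            interval_union_len(
                seg for l in loci for seg in l.query_segments
            )
            / record.query_length
            if loci
            else 0.0
        )
        sep_class, intra_gap, _ = (
            _separation(loci) if len(loci) >= 2 else ("na", None, None)
        )
        rejected = None
        if len(loci) < 2:
            rejected = "a"
        elif any(l.coverage < min_locus_cov for l in loci):
            rejected = "b"
        elif combined < min_combined_cov:
            rejected = "c"
        elif intra_gap is not None and intra_gap < min_separation:
            rejected = "d"

        ordered = sorted(loci, key=lambda l: l.query_segments[0][0])
        junctions = tuple(
            ordered[k].query_segments[-1][1] for k in range(len(ordered) - 1)
        )
        out.append(
            FusionCandidate(
                query_id=record.query_id,
                query_length=record.query_length,
                loci=tuple(ordered),
                combined_coverage=combined,
                separation_class=sep_class,
                separation_bp=intra_gap,
                junctions=junctions,
                status="rejected" if rejected else "candidate",
                rejected_criterion=rejected,
            )
        )
    return out


def validate_fusions(
    candidates: Sequence[FusionCandidate],
    short_reads: pd.DataFrame,
    min_overhang: int = 10,
    min_support: int = 1,
) -> list[FusionCandidate]:
    """Validate candidates with short reads mapped to the query transcripts.

    ``short_reads`` columns: read_id, mate (1/2), query_id, start, end
    (0-based half-open on the transcript), unique_flag. A candidate is
    validated when junction-spanning reads (>= ``min_overhang`` aligned on
    each side of a fusion junction, uniquely mapping) plus uniquely mapping
    discordant pairs (mates entirely on the two sides) reach
    ``min_support``. Rejected inputs pass through unchanged.
    """
    missing = [c for c in READ_COLUMNS if c not in short_reads.columns]
    if missing:
        raise ValueError(f"short-read table missing columns {missing}")
    by_query = dict(tuple(short_reads.groupby("query_id", sort=False)))
    out: list[FusionCandidate] = []
    for cand in candidates:
        if not cand.is_candidate:
            out.append(cand)
            continue
        if not cand.junctions:
            raise ValueError(f"{cand.query_id}: candidate without junction position")
        reads = by_query.get(cand.query_id)
        spanning = 0
        discordant = 0
        if reads is not None:
            uniq = reads[reads["unique_flag"].astype(int) == 1]
            for j in cand.junctions:
                spanning += int(
                    (
                        (uniq["start"] <= j - min_overhang)
                        & (uniq["end"] >= j + min_overhang)
                    ).sum()
                )
                for _rid, pair in uniq.groupby("read_id", sort=False):
                    if len(pair) != 2:
                        continue
                    lo = pair["end"].min()
                    hi = pair["start"].max()
                    if lo <= j <= hi:
                        discordant += 1
        status = (
            "validated" if spanning + discordant >= min_support else "candidate"
        )
        out.append(
            replace(
                cand,
                spanning_support=spanning,
                discordant_support=discordant,
                status=status,
            )
        )
    return out


def fusion_summary(
    candidates: Sequence[FusionCandidate],
    samples_by_query: Mapping[str, frozenset] | None = None,
) -> dict:
    """Tallies of non-rejected candidates by locus-separation class, plus an
    optional per-sample Venn breakdown."""
    kept = [c for c in candidates if c.is_candidate]
    counts = {"inter": 0, "intra": 0}
    for c in kept:
        if c.separation_class == "inter_chromosome":
            counts["inter"] += 1
        elif c.separation_class == "intra_chromosome":
            counts["intra"] += 1
    out: dict = {
        "n_candidates": len(kept),
        "n_validated": sum(1 for c in kept if c.status == "validated"),
        "by_class": counts,
    }
    if samples_by_query is not None:
        venn: dict[frozenset, int] = {}
        for c in kept:
            key = frozenset(samples_by_query.get(c.query_id, frozenset()))
            if key:
                venn[key] = venn.get(key, 0) + 1
        out["by_sample_region"] = venn
    return out
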