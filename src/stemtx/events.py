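"""Pairwise alternative-splicing event detection and typing.

Five canonical event types are recognised between two isoforms of a locus:

* ``IR``  — intron retention: an intron of one isoform lies fully within an
  exon of the other.
* ``SE``  — exon skipping: one isoform carries consecutive introns
  (d1,a1),(d2,a2) where the other has the single intron (d1,a2); the exon
  (a1,d2) is skipped.
* ``A5``/``A3`` — alternative 5'/3' splice site: two introns share one
  boundary and differ at the other; donor/acceptor identity is resolved in
  transcription orientation, so labels swap between strands.
* ``MEX`` — mutually exclusive exons: two non-overlapping internal exons
  with shared flanking junctions, each present in exactly one isoform.

Splice-chain differences not explained by any of these patterns are counted
under an ``other`` bucket (reported, untyped). Events are reported in
genomic coordinates and are symmetric in the order of the two isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .models import TranscriptModel

EVENT_TYPES = ("IR", "SE", "A3", "A5", "MEX")
ALL_EVENT_TYPES = EVENT_TYPES + ("other",)


@dataclass(frozen=True)
class ASEvent:
    """One typed splicing difference between two isoforms.

    ``coords`` is type-dependent: one (start, end) interval for IR (the
    retained intron) and SE (the skipped exon); the two alternative boundary
    positions for A5/A3; the two exon intervals for MEX. ``inclusion_id`` is
    the isoform carrying more exonic sequence at the event.
    """

    event_type: str
    chrom: str
    strand: str
    coords: tuple
    inclusion_id: str
    exclusion_id: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.event_type not in ALL_EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")

    @property
    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.strand, self.coords)


@dataclass(frozen=True)
class DedupedEvent:
    """A locus-level event with the isoform pairs supporting it."""

    event_type: str
    chrom: str
    strand: str
    coords: tuple
    gene_id: str | None
    provenance: tuple[tuple[str, str], ...]


def _exon_containing(t: TranscriptModel, start: int, end: int):
    for e in t.exons:
        if e.start <= start and end <= e.end:
            return e
    return None


def pairwise_events(
    a: TranscriptModel, b: TranscriptModel, gene_id: str | None = None
) -> list[ASEvent]:
    """Typed AS events between two isoforms of one locus."""
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError(
            f"{a.transcript_id}/{b.transcript_id}: isoforms must share "
            "chromosome and strand"
        )
    chrom, strand = a.chrom, a.strand
    events: list[ASEvent] = []
    explained: set[tuple[int, int]] = set()
    introns_a, introns_b = a.introns, b.introns
    set_a, set_b = set(introns_a), set(introns_b)

    def ev(etype, coords, inclusion, exclusion, involved_introns):
        events.append(
            ASEvent(
                event_type=etype,
                chrom=chrom,
                strand=strand,
                coords=coords,
                inclusion_id=inclusion.transcript_id,
                exclusion_id=exclusion.transcript_id,
                gene_id=gene_id,
            )
        )
        explained.update(involved_introns)

    # intron retention: intron of the spliced isoform inside an exon of the
    # retaining isoform
    for spliced, retainer, introns in ((a, b, introns_a), (b, a, introns_b)):
        for s, e in introns:
            if _exon_containing(retainer, s, e) is not None:
                ev("IR", ((s, e),), retainer, spliced, [(s, e)])

    # exon skipping: consecutive introns vs their fused single intron
    for incl, excl, introns, other_set in (
        (a, b, introns_a, set_b),
        (b, a, introns_b, set_a),
    ):
        for (d1, a1), (d2, a2) in zip(introns, introns[1:]):
            if (d1, a2) in other_set and (d1, a1) not in other_set:
                ev("SE", ((a1, d2),), incl, excl, [(d1, a1), (d2, a2), (d1, a2)])

    # alternative donor/acceptor: intron pairs sharing one boundary
    for i in introns_a:
        for j in introns_b:
            if i == j or i[1] <= j[0] or j[1] <= i[0]:
                continue
            shared_start = i[0] == j[0] and i[1] != j[1]
            shared_end = i[1] == j[1] and i[0] != j[0]
            if not (shared_start or shared_end):
                continue
            if shared_start:
                lo, hi = sorted((i[1], j[1]))
                short, long_ = (a, b) if i[1] < j[1] else (b, a)
                # genomic start side shared: differing boundary is the
                # acceptor on + (A3), the donor on - (A5)
                etype = "A3" if strand == "+" else "A5"
            else:
                lo, hi = sorted((i[0], j[0]))
                short, long_ = (a, b) if i[0] > j[0] else (b, a)
                etype = "A5" if strand == "+" else "A3"
            # the alternative region must be exonic in the shorter-intron
            # isoform; otherwise the difference is a skipped exon or more
            if _exon_containing(short, lo, hi) is None:
                continue
            ev(etype, (lo, hi), short, long_, [i, j])

    # mutually exclusive exons: internal exons with shared flanking junctions
    for (d1, xs), (xe, a2) in zip(introns_a, introns_a[1:]):
        for (e1, ys), (ye, e2) in zip(introns_b, introns_b[1:]):
            if d1 != e1 or a2 != e2:
                continue
            if xe <= ys or ye <= xs:  # non-overlapping internal exons
                x_iv, y_iv = (xs, xe), (ys, ye)
                first, second = sorted((x_iv, y_iv))
                incl = a if x_iv == first else b
                excl = b if incl is a else a
                ev(
                    "MEX",
                    (first, second),
                    incl,
                    excl,
                    [(d1, xs), (xe, a2), (e1, ys), (ye, e2)],
                )

    # dedupe within the pair (IR loops can only produce distinct keys, but
    # A5/A3/MEX scans may revisit the same configuration)
    seen: set[tuple] = set()
    uniq: list[ASEvent] = []
    for e in events:
        if e.key not in seen:
            seen.add(e.key)
            uniq.append(e)
    events = uniq

    # 'other' bucket: differing introns in the shared span not explained by
    # any typed event
    span_lo = max(a.start, b.start)
    span_hi = min(a.end, b.end)
    if span_lo < span_hi:
        unexplained = False
        for s, e_ in set_a.symmetric_difference(set_b):
            if s < span_lo or e_ > span_hi:
                continue
            if (s, e_) not in explained:
                unexplained = True
                break
        if unexplained:
            incl, excl = sorted((a, b), key=lambda t: t.transcript_id)
            events.append(
                ASEvent(
                    event_type="other",
                    chrom=chrom,
                    strand=strand,
                    coords=((span_lo, span_hi),),
                    inclusion_id=incl.transcript_id,
                    exclusion_id=excl.transcript_id,
                    gene_id=gene_id,
                )
            )
    return sorted(events, key=lambda e: (e.key, e.inclusion_id))


def locus_events(
    isoforms: Sequence[TranscriptModel], gene_id: str | None = None
) -> list[DedupedEvent]:
    """Union of pairwise events over all isoform pairs, deduplicated.

    Events are merged by (type, coordinates); the supporting isoform pairs
    are retained as provenance.
    """
    merged: dict[tuple, list[tuple[str, str]]] = {}
    order: list[tuple] = []
    meta: dict[tuple, ASEvent] = {}
    iso = sorted(isoforms, key=lambda t: t.transcript_id)
    for i in range(len(iso)):
        for j in range(i + 1, len(iso)):
            for e in pairwise_events(iso[i], iso[j], gene_id=gene_id):
                if e.key not in merged:
                    merged[e.key] = []
                    order.append(e.key)
                    meta[e.key] = e
                merged[e.key].append((e.inclusion_id, e.exclusion_id))
    out = []
    for key in sorted(order):
        e = meta[key]
        out.append(
            DedupedEvent(
                event_type=e.event_type,
                chrom=e.chrom,
                strand=e.strand,
                coords=e.coords,
                gene_id=gene_id,
                provenance=tuple(sorted(set(merged[key]))),
            )
        )
    return out


def event_type_summary(events: Iterable) -> pd.DataFrame:
    """Counts and proportions per event type.

    Proportions are over the five canonical types plus 'other'; NA when the
    event list is empty.
    """
    counts = {t: 0 for t in ALL_EVENT_TYPES}
    for e in events:
        counts[e.event_type] += 1
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "event_type": list(ALL_EVENT_TYPES),
            "count": [counts[t] for t in ALL_EVENT_TYPES],
        }
    )
    df["proportion"] = df["count"] / total if total else float("nan")
    return df


def transcript_event_summary(events: Iterable[DedupedEvent]) -> pd.DataFrame:
    """Per-type counts of distinct transcripts carrying at least one event.

    The alternatively spliced unit here is the transcript rather than the
    event; both summaries are provided because either counting convention is
    seen in practice.
    """
    carriers: dict[str, set[str]] = {t: set() for t in ALL_EVENT_TYPES}
    all_carriers: set[str] = set()
    for e in events:
        for pair in e.provenance:
            carriers[e.event_type].update(pair)
            all_carriers.update(pair)
    df = pd.DataFrame(
        {
            "event_type": list(ALL_EVENT_TYPES),
            "n_transcripts": [len(carriers[t]) for t in ALL_EVENT_TYPES],
        }
    )
    df["proportion"] = (
        df["n_transcripts"] / len(all_carriers) if all_carriers else float("nan")
    )
    return df
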