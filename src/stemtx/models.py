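"""Core genomic data model.

All coordinates are 0-based half-open throughout the package; conversion to
the 1-based inclusive convention of GTF/GFF3 happens exactly once, inside
:mod:`stemtx.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _strand_compatible(a: str, b: str) -> bool:
    """Strand match treating '.' (unstranded) as a wildcard."""
    return a == b or a == "." or b == "."


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript model.

    ``exons`` must be sorted by start, non-overlapping and share one
    chromosome and strand. Spliced models (>= 2 exons) must be stranded;
    strand '.' is tolerated only on single-exon models, where junction
    orientation is undefined anyway.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str | None = None
    samples_detected: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if len(self.exons) == 0:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chromosome and strand"
            )
        for prev, cur in zip(exons, exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping at "
                    f"{prev.end}/{cur.start}"
                )
        if len(exons) > 1 and exons[0].strand == ".":
            raise ValueError(
                f"{self.transcript_id}: spliced transcript requires strand + or -"
            )
        if not isinstance(self.samples_detected, frozenset):
            object.__setattr__(
                self, "samples_detected", frozenset(self.samples_detected)
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Spliced length in nt (sum of exon lengths)."""
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron (donor-side start, acceptor-side end) gaps between exons."""
        return tuple(
            (prev.end, cur.start) for prev, cur in zip(self.exons, self.exons[1:])
        )

    def with_gene(self, gene_id: str) -> "TranscriptModel":
        return TranscriptModel(
            transcript_id=self.transcript_id,
            exons=self.exons,
            gene_id=gene_id,
            samples_detected=self.samples_detected,
        )


def merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) half-open intervals, sorted and merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_union_len(ivals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivals))


def intersect_unions(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Overlap in bp between two already-merged interval unions."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


class GenomeAnnotation:
    """Indexed collection of reference genes and their transcript models.

    Provides the three lookups the pipeline needs: splice-chain identity,
    exonic interval overlap by gene, and mono-exonic transcript retrieval.
    """

    def __init__(self, genes: Mapping[str, Sequence[TranscriptModel]]):
        self._genes: dict[str, list[TranscriptModel]] = {}
        self._tx: dict[str, TranscriptModel] = {}
        self._tx_gene: dict[str, str] = {}
        for gene_id in sorted(genes):
            txs = []
            for t in genes[gene_id]:
                if t.transcript_id in self._tx:
                    raise ValueError(
                        f"duplicate transcript id {t.transcript_id!r} in annotation"
                    )
                if t.gene_id is not None and t.gene_id != gene_id:
                    raise ValueError(
                        f"{t.transcript_id}: gene_id {t.gene_id!r} does not match "
                        f"containing gene {gene_id!r}"
                    )
                t = t if t.gene_id == gene_id else t.with_gene(gene_id)
                txs.append(t)
                self._tx[t.transcript_id] = t
                self._tx_gene[t.transcript_id] = gene_id
            if not txs:
                raise ValueError(f"gene {gene_id!r} has no transcripts")
            self._genes[gene_id] = sorted(txs, key=lambda t: (t.start, t.transcript_id))
        self._build_indexes()

    def _build_indexes(self) -> None:
        self._splice_index: dict[tuple, list[str]] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._gene_exon_union: dict[str, list[tuple[int, int]]] = {}
        for gene_id, txs in self._genes.items():
            ivals = [(e.start, e.end) for t in txs for e in t.exons]
            self._gene_exon_union[gene_id] = merge_intervals(ivals)
            for t in txs:
                if t.exon_count > 1:
                    key = (t.chrom, t.strand, t.introns)
                    self._splice_index.setdefault(key, []).append(t.transcript_id)
                tree = self._exon_trees.setdefault(t.chrom, IntervalTree())
                for e in t.exons:
                    tree.addi(e.start, e.end, (gene_id, t.transcript_id, t.strand))
        for ids in self._splice_index.values():
            ids.sort()

    # -- basic access ------------------------------------------------------

    @property
    def genes(self) -> dict[str, list[TranscriptModel]]:
        return self._genes

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._tx)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene_id in self._genes:
            yield from self._genes[gene_id]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._tx[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self._tx_gene[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._tx

    def gene_exon_union(self, gene_id: str) -> list[tuple[int, int]]:
        return self._gene_exon_union[gene_id]

    # -- lookups -----------------------------------------------------------

    def match_splice_chain(
        self, chrom: str, strand: str, introns: tuple[tuple[int, int], ...]
    ) -> list[str]:
        """Transcript ids with exactly this intron chain (sorted)."""
        return list(self._splice_index.get((chrom, strand, introns), []))

    def overlapping_transcripts(
        self, t: TranscriptModel, same_strand: bool = True
    ) -> set[str]:
        tree = self._exon_trees.get(t.chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for e in t.exons:
            for iv in tree.overlap(e.start, e.end):
                gene_id, tid, strand = iv.data
                if same_strand and not _strand_compatible(strand, t.strand):
                    continue
                hits.add(tid)
        return hits

    def exonic_overlap_by_gene(
        self, t: TranscriptModel, same_strand: bool = True
    ) -> dict[str, int]:
        """bp of overlap between ``t``'s exon union and each gene's exon union."""
        tree = self._exon_trees.get(t.chrom)
        if tree is None:
            return {}
        candidates: set[str] = set()
        for e in t.exons:
            for iv in tree.overlap(e.start, e.end):
                gene_id, _tid, strand = iv.data
                if same_strand and not _strand_compatible(strand, t.strand):
                    continue
                candidates.add(gene_id)
        t_union = merge_intervals((e.start, e.end) for e in t.exons)
        out: dict[str, int] = {}
        for gene_id in candidates:
            bp = intersect_unions(t_union, self._gene_exon_union[gene_id])
            if bp > 0:
                out[gene_id] = bp
        return out

    def mono_exonic_matches(self, t: TranscriptModel) -> list[TranscriptModel]:
        """Mono-exonic reference isoforms exon-overlapping ``t`` (strand aware)."""
        tree = self._exon_trees.get(t.chrom)
        if tree is None:
            return []
        hits: dict[str, TranscriptModel] = {}
        for e in t.exons:
            for iv in tree.overlap(e.start, e.end):
                _gene_id, tid, strand = iv.data
                ref = self._tx[tid]
                if ref.exon_count != 1:
                    continue
                if not _strand_compatible(strand, t.strand):
                    continue
                hits[tid] = ref
        return [hits[k] for k in sorted(hits)]


@dataclass(frozen=True)
class AlignmentLocus:
    """One mapped locus of a query transcript."""

    query_start: int
    query_end: int
    interval: GenomicInterval
    unique: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError(
                f"invalid query interval {self.query_start}-{self.query_end}"
            )


@dataclass
class AlignmentRecordSet:
    """All mapped loci of one query transcript."""

    query_id: str
    query_length: int
    loci: list[AlignmentLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError(f"{self.query_id}: query_length must be positive")
        if not self.loci:
            raise ValueError(f"{self.query_id}: loci list must be non-empty")
        for loc in self.loci:
            if loc.query_end > self.query_length:
                raise ValueError(
                    f"{self.query_id}: query_end {loc.query_end} exceeds "
                    f"query_length {self.query_length}"
                )
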