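"""Classify transcript models against a reference annotation.

Each full-length transcript model falls into exactly one of three groups:

* ``known`` — its intron chain exactly matches a reference isoform on the
  same chromosome and strand (mono-exonic models instead require reciprocal
  exonic overlap with a mono-exonic reference isoform);
* ``novel_isoform`` — not known, but exon-overlapping an annotated gene on
  the same strand (assigned to the gene with maximal overlap);
* ``novel_locus`` — no same-strand exonic overlap with any annotated gene.

Novel models can then be merged back into the reference to produce an
updated annotation: novel isoforms join their matched gene, novel loci are
clustered into fresh genes by single-linkage exonic overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .models import GenomeAnnotation, TranscriptModel

logger = logging.getLogger(__name__)

CATEGORIES = ("known", "novel_isoform", "novel_locus")


@dataclass(frozen=True)
class SpliceChain:
    """The comparison key for isoform identity: the ordered intron chain."""

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    category: str
    matched_gene_id: str | None = None
    matched_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "known" and self.matched_transcript_id is None:
            raise ValueError("known requires matched_transcript_id")
        if self.category == "novel_locus" and (
            self.matched_gene_id or self.matched_transcript_id
        ):
            raise ValueError("novel_locus must carry no matched ids")


def splice_chain(t: TranscriptModel) -> SpliceChain:
    """Intron chain of a transcript; empty for mono-exonic models."""
    return SpliceChain(chrom=t.chrom, strand=t.strand, introns=t.introns)


def _chains_match_fuzzy(
    a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...], tol: int
) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x[0] - y[0]) <= tol and abs(x[1] - y[1]) <= tol for x, y in zip(a, b)
    )


def classify_isoform(
    t: TranscriptModel,
    ref: GenomeAnnotation,
    mono_exon_reciprocal_overlap: float = 0.9,
    strand_aware: bool = True,
    junction_tolerance: int = 0,
) -> ClassificationResult:
    """Classify one transcript model against the reference.

    ``junction_tolerance`` permits +/- bp slack per splice site when matching
    intron chains (default 0: exact identity). ``strand_aware=False`` relaxes
    the same-strand requirement of the gene-overlap test only; splice-chain
    matching is always stranded.
    """
    if t.exon_count > 1:
        if junction_tolerance == 0:
            hits = ref.match_splice_chain(t.chrom, t.strand, t.introns)
        else:
            hits = sorted(
                rid
                for rid in ref.overlapping_transcripts(t, same_strand=True)
                if _chains_match_fuzzy(
                    t.introns, ref.transcript(rid).introns, junction_tolerance
                )
            )
        if hits:
            tid = hits[0]
            return ClassificationResult(
                transcript_id=t.transcript_id,
                category="known",
                matched_gene_id=ref.gene_of(tid),
                matched_transcript_id=tid,
            )
    else:
        best = None
        t_len = t.length
        for cand in ref.mono_exonic_matches(t):
            ov = t.exons[0].overlap_len(cand.exons[0])
            recip = min(ov / t_len, ov / cand.length)
            if recip >= mono_exon_reciprocal_overlap:
                key = (-recip, cand.transcript_id)
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is not None:
            cand = best[1]
            return ClassificationResult(
                transcript_id=t.transcript_id,
                category="known",
                matched_gene_id=ref.gene_of(cand.transcript_id),
                matched_transcript_id=cand.transcript_id,
            )

    overlaps = ref.exonic_overlap_by_gene(t, same_strand=strand_aware)
    if overlaps:
        gene_id = min(overlaps, key=lambda g: (-overlaps[g], g))
        return ClassificationResult(
            transcript_id=t.transcript_id,
            category="novel_isoform",
            matched_gene_id=gene_id,
        )
    if t.chrom not in {rt.chrom for rt in ref.transcripts()}:
        logger.warning(
            "%s: chromosome %s absent from reference; classified novel_locus",
            t.transcript_id,
            t.chrom,
        )
    return ClassificationResult(transcript_id=t.transcript_id, category="novel_locus")


def classify_isoforms(
    transcripts: Iterable[TranscriptModel],
    ref: GenomeAnnotation,
    **params,
) -> list[ClassificationResult]:
    return [classify_isoform(t, ref, **params) for t in transcripts]


def _novel_locus_clusters(
    models: Sequence[TranscriptModel],
) -> list[list[int]]:
    """Single-linkage clusters by same-strand exonic overlap (union-find)."""
    parent = list(range(len(models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, t in enumerate(models):
        strands = ("+", "-") if t.strand == "." else (t.strand, ".")
        for e in t.exons:
            for strand in strands:
                tree = trees.get((t.chrom, strand))
                if tree is not None:
                    for iv in tree.overlap(e.start, e.end):
                        union(idx, iv.data)
            trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                e.start, e.end, idx
            )
    clusters: dict[int, list[int]] = {}
    for idx in range(len(models)):
        clusters.setdefault(find(idx), []).append(idx)
    out = list(clusters.values())
    out.sort(key=lambda idxs: min((models[i].chrom, models[i].start) for i in idxs))
    return out


def update_annotation(
    ref: GenomeAnnotation,
    results: Sequence[ClassificationResult],
    transcripts: Sequence[TranscriptModel],
    novel_gene_prefix: str = "NOVELG",
) -> GenomeAnnotation:
    """Merge novel transcript models into the reference annotation.

    Known transcripts are dropped (already represented); novel isoforms are
    appended under their matched gene; novel loci are clustered into new
    genes by single-linkage same-strand exonic overlap.
    """
    by_id = {r.transcript_id: r for r in results}
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in by_id]
    if missing:
        raise ValueError(f"results missing for transcripts: {missing[:5]}")

    genes: dict[str, list[TranscriptModel]] = {
        g: list(txs) for g, txs in ref.genes.items()
    }
    novel_locus_models: list[TranscriptModel] = []
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        r = by_id[t.transcript_id]
        if t.transcript_id in ref:
            raise ValueError(
                f"transcript id {t.transcript_id!r} collides with reference"
            )
        if r.category == "known":
            continue
        if r.category == "novel_isoform":
            genes[r.matched_gene_id].append(t.with_gene(r.matched_gene_id))
        else:
            novel_locus_models.append(t)

    existing = set(genes)
    counter = 0
    for idxs in _novel_locus_clusters(novel_locus_models):
        counter += 1
        gid = f"{novel_gene_prefix}{counter:05d}"
        while gid in existing:
            counter += 1
            gid = f"{novel_gene_prefix}{counter:05d}"
        existing.add(gid)
        genes[gid] = [novel_locus_models[i].with_gene(gid) for i in idxs]
    return GenomeAnnotation(genes)


def sample_presence_summary(
    transcripts: Iterable[TranscriptModel], samples: Sequence[str]
) -> dict[frozenset, int]:
    """Counts for every non-empty region of the sample-set Venn diagram."""
    sample_set = set(samples)
    counts: dict[frozenset, int] = {}
    for t in transcripts:
        if not t.samples_detected <= sample_set:
            raise ValueError(
                f"{t.transcript_id}: samples {sorted(t.samples_detected - sample_set)}"
                " not in the declared sample list"
            )
        if not t.samples_detected:
            continue
        key = frozenset(t.samples_detected)
        counts[key] = counts.get(key, 0) + 1
    return counts


def exon_length_stats(transcripts: Sequence[TranscriptModel]) -> dict:
    """Mean length/exon count plus histograms over a transcript set.

    The exon-count histogram has one bin per integer exon count; the length
    histogram uses 500-nt bins from 0 to the maximum length.
    """
    if not transcripts:
        raise ValueError("exon_length_stats requires a non-empty transcript list")
    lengths = np.array([t.length for t in transcripts])
    n_exons = np.array([t.exon_count for t in transcripts])
    exon_bins = np.arange(1, n_exons.max() + 2)
    exon_hist, _ = np.histogram(n_exons, bins=exon_bins)
    len_edges = np.arange(0, lengths.max() + 500, 500)
    len_hist, _ = np.histogram(lengths, bins=len_edges)
    return {
        "mean_length": float(lengths.mean()),
        "mean_exons": float(n_exons.mean()),
        "exon_count_histogram": {
            int(k): int(v) for k, v in zip(exon_bins[:-1], exon_hist)
        },
        "length_histogram": {
            (int(a), int(b)): int(v)
            for a, b, v in zip(len_edges[:-1], len_edges[1:], len_hist)
        },
    }
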