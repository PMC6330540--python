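from __future__ import annotations

import numpy as np
import pytest

from stemtx import GenomeAnnotation, GenomicInterval, TranscriptModel


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str | None = None,
    samples=(),
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        gene_id=gene_id,
        samples_detected=frozenset(samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Two spliced genes on opposite strands plus a mono-exonic gene."""
    g1 = [
        make_transcript("g1.t1", [(100, 200), (300, 400), (500, 600)], gene_id="g1"),
        make_transcript("g1.t2", [(100, 200), (500, 600)], gene_id="g1"),
    ]
    g2 = [
        make_transcript(
            "g2.t1", [(5000, 5200), (5400, 5600)], strand="-", gene_id="g2"
        )
    ]
    g3 = [make_transcript("g3.t1", [(9000, 9800)], gene_id="g3")]
    return GenomeAnnotation({"g1": g1, "g2": g2, "g3": g3})


def random_annotation(rng: np.random.Generator, n_genes: int = 10):
    """Small random annotation built directly (independent of the simulator)."""
    genes = {}
    pos = 100
    for g in range(n_genes):
        chrom = f"chr{1 + g % 2}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gid = f"rg{g}"
        txs = []
        for k in range(int(rng.integers(1, 4))):
            n_ex = int(rng.integers(1, 6))
            exons = []
            p = pos + int(rng.integers(0, 50))
            for _ in range(n_ex):
                ln = int(rng.integers(50, 200))
                exons.append((p, p + ln))
                p += ln + int(rng.integers(60, 400))
            if n_ex > 1:
                s = strand
            else:
                s = strand
            txs.append(make_transcript(f"{gid}.t{k}", exons, chrom, s, gene_id=gid))
        genes[gid] = txs
        pos = max(t.end for t in txs) + int(rng.integers(2000, 6000))
    return GenomeAnnotation(genes)
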