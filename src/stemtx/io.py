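"""Readers and writers for the formats every pipeline stage touches.

GTF and GFF3 carry 1-based inclusive coordinates; everything in memory is
0-based half-open. The conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .models import (
    AlignmentLocus,
    AlignmentRecordSet,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTRYSWKMBDHVN")

ALIGNMENT_COLUMNS = [
    "query_id",
    "query_length",
    "query_start",
    "query_end",
    "chrom",
    "ref_start",
    "ref_end",
    "strand",
    "unique_flag",
]


def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("gtf", "gff3"):
            raise ValueError(f"unknown annotation dialect {dialect!r}")
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix == ".gtf":
        return "gtf"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise ValueError(f"cannot infer dialect from {path}; pass dialect=...")


def _prevalidate_feature_lines(path: Path) -> int:
    """Check tabular shape and coordinate sanity; returns feature-line count.

    gffutils reports parse failures without positions, so malformed rows are
    caught here with their line number.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValueError(
                    f"{path}: malformed line {lineno}: end {end} < start {start}"
                )
            n += 1
    return n


def read_annotation(path: str | Path, dialect: str | None = None) -> GenomeAnnotation:
    """Read a GTF or GFF3 annotation into a :class:`GenomeAnnotation`.

    Only exon features are used; transcript and gene identity come from
    ``transcript_id``/``gene_id`` attributes (GTF) or the exon→mRNA→gene
    Parent chain (GFF3). Exon rows out of positional order are sorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if _prevalidate_feature_lines(path) == 0:
        return GenomeAnnotation({})

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}

    if dialect == "gtf":
        for f in db.features_of_type("exon"):
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
            tx_exons.setdefault(tid, []).append(
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            )
            tx_gene[tid] = gid
    else:
        mrna_gene: dict[str, str] = {}
        for ftype in ("mRNA", "transcript"):
            for f in db.features_of_type(ftype):
                mrna_gene[f.id] = f.attributes["Parent"][0]
        for f in db.features_of_type("exon"):
            parent = f.attributes["Parent"][0]
            if parent not in mrna_gene:
                raise ValueError(
                    f"{path}: exon Parent {parent!r} has no mRNA/transcript feature"
                )
            tx_exons.setdefault(parent, []).append(
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
            )
            tx_gene[parent] = mrna_gene[parent]

    genes: dict[str, list[TranscriptModel]] = {}
    for tid in sorted(tx_exons):
        exons = tuple(sorted(tx_exons[tid], key=lambda e: e.start))
        t = TranscriptModel(transcript_id=tid, exons=exons, gene_id=tx_gene[tid])
        genes.setdefault(tx_gene[tid], []).append(t)
    return GenomeAnnotation(genes)


def _gene_sort_key(txs: Sequence[TranscriptModel], gene_id: str):
    start = min(t.start for t in txs)
    return (txs[0].chrom, start, gene_id)


def write_annotation(
    ann: GenomeAnnotation, path: str | Path, dialect: str | None = None
) -> None:
    """Serialize an annotation as GTF or GFF3 (1-based inclusive coordinates).

    Output order is deterministic: genes by (chrom, start, gene_id),
    transcripts by (start, transcript_id).
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    gene_items = sorted(
        ann.genes.items(), key=lambda kv: _gene_sort_key(kv[1], kv[0])
    )
    lines: list[str] = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
    else:
        lines.append("#!annotation produced by stemtx")
    for gene_id, txs in gene_items:
        txs = sorted(txs, key=lambda t: (t.start, t.transcript_id))
        chrom = txs[0].chrom
        strand = txs[0].strand
        g_start = min(t.start for t in txs) + 1
        g_end = max(t.end for t in txs)
        if dialect == "gff3":
            lines.append(
                f"{chrom}\tstemtx\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene_id}"
            )
        for t in txs:
            if dialect == "gtf":
                attrs = f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}";'
                lines.append(
                    f"{t.chrom}\tstemtx\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}"
                )
                for e in t.exons:
                    lines.append(
                        f"{e.chrom}\tstemtx\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}"
                    )
            else:
                lines.append(
                    f"{t.chrom}\tstemtx\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id}"
                )
                for e in t.exons:
                    lines.append(
                        f"{e.chrom}\tstemtx\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\tParent={t.transcript_id}"
                    )
    path.write_text("\n".join(lines) + "\n")


def transcripts_to_annotation(
    transcripts: Iterable[TranscriptModel],
) -> GenomeAnnotation:
    """Wrap loose transcript models (e.g. long-read isoforms) as an annotation.

    Models without a gene_id get a singleton gene named after the transcript,
    which lets the GTF/GFF3 writers serialize them losslessly.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        gid = t.gene_id or t.transcript_id
        genes.setdefault(gid, []).append(t if t.gene_id else t.with_gene(gid))
    return GenomeAnnotation(genes)


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; uppercased, U converted to T."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# -- alignment TSV / BED12 ---------------------------------------------------


def read_alignment_sets(path: str | Path) -> list[AlignmentRecordSet]:
    """Read split alignments (TSV) or single-locus spliced records (BED12).

    The TSV columns are documented in :data:`ALIGNMENT_COLUMNS`; query
    coordinates are 0-based half-open on the read. Records are grouped by
    query_id (sorted for determinism).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return [
            AlignmentRecordSet(
                query_id=t.transcript_id,
                query_length=t.length,
                loci=[
                    AlignmentLocus(
                        0, t.length, GenomicInterval(t.chrom, t.start, t.end, t.strand)
                    )
                ],
            )
            for t in read_bed12_transcripts(path)
        ]
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "chrom": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing alignment columns {missing}")
    sets: list[AlignmentRecordSet] = []
    for qid, grp in df.groupby("query_id", sort=True):
        qlen = int(grp["query_length"].iloc[0])
        if (grp["query_length"] != qlen).any():
            raise ValueError(f"{path}: inconsistent query_length for {qid!r}")
        loci = []
        for row in grp.itertuples(index=False):
            if row.query_end > qlen:
                raise ValueError(
                    f"{path}: {qid!r} query_end {row.query_end} > "
                    f"query_length {qlen}"
                )
            loci.append(
                AlignmentLocus(
                    query_start=int(row.query_start),
                    query_end=int(row.query_end),
                    interval=GenomicInterval(
                        str(row.chrom), int(row.ref_start), int(row.ref_end),
                        str(row.strand),
                    ),
                    unique=bool(int(row.unique_flag)),
                )
            )
        sets.append(AlignmentRecordSet(query_id=str(qid), query_length=qlen, loci=loci))
    return sets


def write_alignment_sets(
    sets: Iterable[AlignmentRecordSet], path: str | Path
) -> None:
    rows = []
    for s in sets:
        for loc in s.loci:
            rows.append(
                {
                    "query_id": s.query_id,
                    "query_length": s.query_length,
                    "query_start": loc.query_start,
                    "query_end": loc.query_end,
                    "chrom": loc.interval.chrom,
                    "ref_start": loc.interval.start,
                    "ref_end": loc.interval.end,
                    "strand": loc.interval.strand,
                    "unique_flag": int(loc.unique),
                }
            )
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed12_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read spliced transcript models from BED12."""
    path = Path(path)
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED columns")
            chrom, chrom_start, name = fields[0], int(fields[1]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple(
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            )
            out.append(TranscriptModel(transcript_id=name, exons=exons))
    return out
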