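"""Synthetic transcriptome generator with planted ground truth.

Every input the pipeline consumes can be generated here: a multi-gene,
multi-isoform reference annotation; full-length transcript models planted
as known / novel-isoform / novel-locus at chosen fractions, with a single
alternative-splicing edit of a chosen type behind every novel isoform;
multi-locus alignment record sets satisfying or violating each fusion
criterion; transcript sequences with controlled ORF content and a matching
coding-potential evidence table; and negative-binomial count matrices with
planted temporal profiles across developmental zones.

All generators are deterministic under a fixed seed, and every simulated
object carries exactly one truth record, so downstream modules can be
tested by planted-truth recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lncrna import PREDICTORS, CodingEvidence
from .models import (
    AlignmentLocus,
    AlignmentRecordSet,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)

AS_TYPES = ("IR", "SE", "A3", "A5", "MEX")
DEFAULT_AS_MIX = {"IR": 0.60, "SE": 0.10, "A3": 0.10, "A5": 0.10, "MEX": 0.10}
DEFAULT_FRACTIONS = {"known": 0.30, "novel_isoform": 0.50, "novel_locus": 0.20}
DEFAULT_SAMPLES = ("Apex", "IN1-3", "IN4-5")
DEFAULT_ZONES = ("Apex", "IN1", "IN2", "IN3", "IN4", "IN5")


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulation.

    Which frames are populated depends on the generator: transcript
    categories and AS edits, fusion verdicts, expression DE flags and
    cluster memberships, lncRNA flags.
    """

    seed: int
    genes: pd.DataFrame | None = None
    transcripts: pd.DataFrame | None = None
    fusions: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    lncrna: pd.DataFrame | None = None

    def to_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("genes", "transcripts", "fusions", "expression", "lncrna"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference annotation
# ---------------------------------------------------------------------------


def _random_exon_chain(
    rng: np.random.Generator,
    start: int,
    n_exons: int,
    chrom: str,
    strand: str,
    exon_range: tuple[int, int] = (80, 300),
    intron_range: tuple[int, int] = (80, 2000),
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
    return tuple(exons)


def _derive_isoform(
    rng: np.random.Generator, exons: tuple[GenomicInterval, ...], tid: str
) -> tuple[GenomicInterval, ...] | None:
    """A sibling isoform sharing at least one junction with the template."""
    if len(exons) < 3:
        return None
    choice = rng.integers(0, 2)
    if choice == 0 and len(exons) >= 4:
        # drop one internal exon; >= 4 exons keeps a shared intact intron
        k = int(rng.integers(1, len(exons) - 1))
        return exons[:k] + exons[k + 1 :]
    # shorten the terminal exon (alternative start/end, junctions shared)
    delta = int(rng.integers(20, 60))
    if rng.integers(0, 2) == 0:
        first = exons[0]
        if first.length - delta < 30:
            return None
        return (
            GenomicInterval(first.chrom, first.start + delta, first.end, first.strand),
        ) + exons[1:]
    last = exons[-1]
    if last.length - delta < 30:
        return None
    return exons[:-1] + (
        GenomicInterval(last.chrom, last.start, last.end - delta, last.strand),
    )


def simulate_annotation(
    n_genes: int,
    isoforms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
    n_chroms: int = 5,
    chrom_length: int | None = None,
    mono_exon_fraction: float = 0.1,
) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Reference annotation with non-overlapping genes.

    Genes are laid out sequentially per chromosome (round robin) with
    5-20 kb gaps, so no two genes overlap on either strand; isoforms of one
    gene share at least one splice junction. Deterministic under ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = isoforms_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("isoforms_per_gene must be a (low, high) range with low >= 1")
    rng = np.random.default_rng(seed)
    cursors = {f"chr{i + 1}": 1000 for i in range(n_chroms)}
    chrom_names = list(cursors)
    genes: dict[str, list[TranscriptModel]] = {}
    rows = []
    for g in range(n_genes):
        chrom = chrom_names[g % n_chroms]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_iso = int(rng.integers(lo, hi + 1))
        if n_iso > 1 or rng.random() > mono_exon_fraction:
            n_exons = int(rng.integers(3, 11)) if n_iso > 1 else int(rng.integers(2, 11))
        else:
            n_exons = 1
        start = cursors[chrom]
        template = _random_exon_chain(rng, start, n_exons, chrom, strand)
        gid = f"G{g + 1:05d}"
        txs = [TranscriptModel(f"{gid}.1", template, gene_id=gid)]
        chains = {tuple((e.start, e.end) for e in template)}
        attempts = 0
        while len(txs) < n_iso and attempts < 50:
            attempts += 1
            alt = _derive_isoform(rng, template, gid)
            if alt is None:
                break
            key = tuple((e.start, e.end) for e in alt)
            if key in chains:
                continue
            chains.add(key)
            txs.append(TranscriptModel(f"{gid}.{len(txs) + 1}", alt, gene_id=gid))
        gene_end = max(t.end for t in txs)
        cursors[chrom] = gene_end + int(rng.integers(5000, 20001))
        if chrom_length is not None and gene_end > chrom_length:
            raise ValueError(
                f"cannot place gene {gid} on {chrom}: exceeds chrom_length "
                f"{chrom_length}"
            )
        genes[gid] = txs
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": min(t.start for t in txs),
                "end": gene_end,
                "strand": strand,
                "n_isoforms": len(txs),
            }
        )
    truth = SimulationTruth(seed=seed, genes=pd.DataFrame(rows))
    return GenomeAnnotation(genes), truth


# ---------------------------------------------------------------------------
# isoform set with planted categories and AS edits
# ---------------------------------------------------------------------------


def _shift_interval(iv: GenomicInterval, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def _apply_ir(rng, t: TranscriptModel):
    """Retain one intron: merge two adjacent exons. Needs >= 3 exons."""
    if t.exon_count < 3:
        return None
    k = int(rng.integers(0, t.exon_count - 1))
    merged = _shift_interval(t.exons[k], t.exons[k].start, t.exons[k + 1].end)
    exons = t.exons[:k] + (merged,) + t.exons[k + 2 :]
    intron = t.introns[k]
    return exons, ("IR", (intron,))


def _apply_se(rng, t: TranscriptModel):
    """Skip one internal exon. Needs >= 3 exons."""
    if t.exon_count < 3:
        return None
    k = int(rng.integers(1, t.exon_count - 1))
    exon = t.exons[k]
    exons = t.exons[:k] + t.exons[k + 1 :]
    return exons, ("SE", ((exon.start, exon.end),))


def _alt_site(rng, t: TranscriptModel, site: str):
    """Shift a donor or acceptor; ``site`` in transcription orientation."""
    if t.exon_count < 2:
        return None
    order = list(rng.permutation(t.exon_count - 1))
    for k in order:
        s, e = t.introns[k]
        left, right = t.exons[k], t.exons[k + 1]
        # genomic side to move: donor is the genomic start of the intron on
        # +, the genomic end on -; acceptor is the mirror
        move_start = (site == "donor") == (t.strand == "+")
        max_into_exon = (left.length if move_start else right.length) - 30
        max_into_intron = (e - s) - 30
        lim = min(60, max_into_exon, max_into_intron)
        if lim < 6:
            continue
        delta = int(rng.integers(6, lim + 1))
        sign = -1 if rng.integers(0, 2) == 0 else 1
        if move_start:
            new_s = s + sign * delta
            exons = (
                t.exons[:k]
                + (_shift_interval(left, left.start, new_s),)
                + t.exons[k + 1 :]
            )
            sites = tuple(sorted((s, new_s)))
        else:
            new_e = e + sign * delta
            exons = (
                t.exons[: k + 1]
                + (_shift_interval(right, new_e, right.end),)
                + t.exons[k + 2 :]
            )
            sites = tuple(sorted((e, new_e)))
        etype = (
            "A5" if site == "donor" else "A3"
        )
        return exons, (etype, sites)
    return None


def _apply_mex(rng, t: TranscriptModel):
    """Replace an internal exon with a new exon inside a flanking intron."""
    if t.exon_count < 3:
        return None
    order = list(rng.permutation(range(1, t.exon_count - 1)))
    for k in order:
        d, y1 = t.introns[k - 1]  # upstream intron (shared donor side)
        y2, a2 = t.introns[k]  # downstream intron (shared acceptor side)
        y = t.exons[k]
        x_len = int(rng.integers(60, 101))
        margin = 10
        if (y1 - d) >= x_len + 2 * margin:  # place X inside the upstream intron
            xs = d + margin
        elif (a2 - y2) >= x_len + 2 * margin:  # or the downstream intron
            xs = y2 + margin
        else:
            continue
        x = GenomicInterval(t.chrom, xs, xs + x_len, t.strand)
        exons = t.exons[:k] + (x,) + t.exons[k + 1 :]
        coords = tuple(sorted(((x.start, x.end), (y.start, y.end))))
        return exons, ("MEX", coords)
    return None


_EDITORS = {
    "IR": _apply_ir,
    "SE": _apply_se,
    "A5": lambda rng, t: _alt_site(rng, t, "donor"),
    "A3": lambda rng, t: _alt_site(rng, t, "acceptor"),
    "MEX": _apply_mex,
}


def simulate_isoform_set(
    ann: GenomeAnnotation,
    n_transcripts: int,
    fractions: Mapping[str, float] | None = None,
    as_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    sample_names: Sequence[str] = DEFAULT_SAMPLES,
) -> tuple[list[TranscriptModel], SimulationTruth]:
    """Full-length transcript models with planted classification categories.

    Novel isoforms are built from a reference isoform by one AS edit of a
    type sampled from ``as_mix``; novel loci are placed with no same-strand
    exonic overlap with any gene (a quarter of them antisense within a gene
    span, to exercise the strand-aware boundary).
    """
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    as_mix = dict(as_mix or DEFAULT_AS_MIX)
    if any(v < 0 for v in as_mix.values()):
        raise ValueError("as_mix entries must be non-negative")
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be non-negative")
    if not np.isclose(sum(fractions.values()), 1.0):
        raise ValueError("fractions must sum to 1")
    if not np.isclose(sum(as_mix.values()), 1.0):
        raise ValueError("as_mix must sum to 1")

    rng = np.random.default_rng(seed)
    cats = list(fractions)
    cat_draw = rng.choice(len(cats), size=n_transcripts, p=[fractions[c] for c in cats])
    as_types = [t for t in AS_TYPES if as_mix.get(t, 0) > 0]
    as_p = np.array([as_mix[t] for t in as_types])

    ref_txs = list(ann.transcripts())
    spliced = [t for t in ref_txs if t.exon_count >= 2]
    editable = {
        etype: [t for t in spliced if _edit_feasible(etype, t)] for etype in AS_TYPES
    }
    for etype in as_types:
        if not editable[etype]:
            raise ValueError(f"annotation has no isoform usable for {etype} edits")

    # per-chromosome cursor beyond all annotated genes, for novel loci
    cursors: dict[str, int] = {}
    for t in ref_txs:
        cursors[t.chrom] = max(cursors.get(t.chrom, 0), t.end) + 1
    for c in cursors:
        cursors[c] += 5000
    chroms = sorted(cursors)

    models: list[TranscriptModel] = []
    rows = []
    for i in range(n_transcripts):
        cat = cats[int(cat_draw[i])]
        tid = f"PB.{i + 1}"
        samples = _random_sample_subset(rng, sample_names)
        if cat == "known":
            src = ref_txs[int(rng.integers(0, len(ref_txs)))]
            model = TranscriptModel(tid, src.exons, samples_detected=samples)
            rows.append(
                _truth_row(tid, "known", src, None, None, samples)
            )
        elif cat == "novel_isoform":
            etype = as_types[int(rng.choice(len(as_types), p=as_p))]
            model = None
            for _ in range(100):
                src = editable[etype][int(rng.integers(0, len(editable[etype])))]
                res = _EDITORS[etype](rng, src)
                if res is None:
                    continue
                exons, (planted_type, coords) = res
                chain = tuple((prev.end, cur.start) for prev, cur in zip(exons, exons[1:]))
                if len(exons) >= 2 and ann.match_splice_chain(
                    exons[0].chrom, exons[0].strand, chain
                ):
                    continue  # accidental identity with a reference chain
                model = TranscriptModel(tid, exons, samples_detected=samples)
                rows.append(
                    _truth_row(tid, "novel_isoform", src, planted_type, coords, samples)
                )
                break
            if model is None:
                raise RuntimeError(f"could not plant a {etype} edit after 100 tries")
        else:  # novel_locus
            antisense = rng.random() < 0.25
            if antisense:
                src = ref_txs[int(rng.integers(0, len(ref_txs)))]
                strand = "-" if src.strand == "+" else "+"
                span = src.end - src.start
                if span < 400:
                    antisense = False
                else:
                    start = src.start + int(rng.integers(0, span // 4))
                    n_ex = 1
                    exons = (_random_exon_chain(rng, start, n_ex, src.chrom, strand))
            if not antisense:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                n_ex = int(rng.integers(1, 7))
                exons = _random_exon_chain(rng, cursors[chrom], n_ex, chrom, strand)
                cursors[chrom] = exons[-1].end + int(rng.integers(2000, 8001))
            model = TranscriptModel(tid, exons, samples_detected=samples)
            rows.append(_truth_row(tid, "novel_locus", None, None, None, samples))
        models.append(model)

    truth = SimulationTruth(seed=seed, transcripts=pd.DataFrame(rows))
    return models, truth


def _edit_feasible(etype: str, t: TranscriptModel) -> bool:
    if etype in ("IR", "SE"):
        return t.exon_count >= 3
    if etype == "MEX":
        if t.exon_count < 3:
            return False
        return any(
            (t.introns[k - 1][1] - t.introns[k - 1][0]) >= 120
            or (t.introns[k][1] - t.introns[k][0]) >= 120
            for k in range(1, t.exon_count - 1)
        )
    # A5/A3 need one intron with slack on both sides
    return t.exon_count >= 2 and any(
        (e - s) >= 36 for s, e in t.introns
    )


def _random_sample_subset(rng, sample_names: Sequence[str]) -> frozenset:
    mask = rng.random(len(sample_names)) < 0.5
    if not mask.any():
        mask[int(rng.integers(0, len(sample_names)))] = True
    return frozenset(s for s, m in zip(sample_names, mask) if m)


def _truth_row(tid, category, src, as_type, coords, samples):
    return {
        "transcript_id": tid,
        "category": category,
        "source_transcript_id": src.transcript_id if src is not None else "",
        "source_gene_id": (src.gene_id or "") if src is not None else "",
        "as_type": as_type or "",
        "event_coords": repr(coords) if coords is not None else "",
        "samples": ",".join(sorted(samples)),
    }


# ---------------------------------------------------------------------------
# transcript sequences + coding evidence (lncRNA stage inputs)
# ---------------------------------------------------------------------------

_STOP_BLOCK = "TTAATTAATTAA"  # stop codons in all three frames


def _noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence whose longest forward ORF stays well under 300 nt.

    Stop-codon blocks covering all three frames are inserted every 150 nt,
    bounding any ATG-initiated ORF to the inter-block spacing.
    """
    parts = [_STOP_BLOCK]
    bases = np.array(list("ACGT"))
    while sum(len(p) for p in parts) < length:
        parts.append("".join(rng.choice(bases, size=150)))
        parts.append(_STOP_BLOCK)
    return "".join(parts)[:length]


def _coding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence carrying a planted ORF of ~400 nt (> 300)."""
    bases = np.array(list("ACGT"))
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    orf = "ATG" + "".join(
        non_stop[int(i)] for i in rng.integers(0, len(non_stop), size=130)
    ) + "TAA"
    prefix = "".join(rng.choice(bases, size=20))
    rest = length - len(prefix) - len(orf)
    if rest < 0:
        raise ValueError("transcript too short for a planted long ORF")
    suffix = "".join(rng.choice(bases, size=rest))
    return prefix + orf + suffix


def simulate_sequences(
    transcripts: Sequence[TranscriptModel],
    lncrna_fraction: float = 0.2,
    evidence_missing_rate: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, CodingEvidence], SimulationTruth]:
    """Sequences and coding-potential evidence with planted lncRNA flags.

    Planted lncRNAs (a random fraction of transcripts longer than 200 nt)
    get ORF-free sequences and unanimous non-coding verdicts; the rest get
    a long planted ORF where length permits and at least one coding verdict.
    """
    if not (0 <= lncrna_fraction <= 1):
        raise ValueError("lncrna_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    evidence: dict[str, CodingEvidence] = {}
    rows = []
    min_coding_len = 20 + 3 + 130 * 3 + 3  # prefix + planted ORF
    for t in transcripts:
        is_lnc = t.length > 200 and rng.random() < lncrna_fraction
        if is_lnc:
            seq = _noncoding_sequence(rng, t.length)
            verdicts = {
                p: ("missing" if rng.random() < evidence_missing_rate else "noncoding")
                for p in PREDICTORS
            }
        else:
            if t.length >= min_coding_len:
                seq = _coding_sequence(rng, t.length)
            else:
                seq = _noncoding_sequence(rng, t.length)
            verdicts = {
                p: ("missing" if rng.random() < evidence_missing_rate else "coding")
                for p in PREDICTORS
            }
            if all(v == "missing" for v in verdicts.values()):
                verdicts[PREDICTORS[0]] = "coding"
        seqs[t.transcript_id] = seq
        evidence[t.transcript_id] = CodingEvidence(t.transcript_id, verdicts)
        rows.append({"transcript_id": t.transcript_id, "is_lncrna": is_lnc})
    truth = SimulationTruth(seed=seed, lncrna=pd.DataFrame(rows))
    return seqs, evidence, truth


# ---------------------------------------------------------------------------
# fusion queries
# ---------------------------------------------------------------------------


def simulate_fusion_queries(
    ann: GenomeAnnotation,
    n_true: int,
    n_decoys: int,
    seed: int = 0,
    support_reads: int = 3,
    unsupported_fraction: float = 0.25,
    sample_names: Sequence[str] = DEFAULT_SAMPLES,
) -> tuple[list[AlignmentRecordSet], pd.DataFrame, SimulationTruth]:
    """Multi-locus alignment record sets with planted fusion verdicts.

    True fusions satisfy all four criteria; each decoy violates exactly one
    (cycling a, b, c, d). A fraction of true fusions get zero short-read
    support (the validation-fail class); the rest get ``support_reads``
    junction-spanning read pairs. Returns (alignments, short reads, truth).
    """
    genes = sorted(ann.genes)
    if n_true > 0 and len(genes) < 2:
        raise ValueError("true fusions require an annotation with >= 2 loci")
    rng = np.random.default_rng(seed)
    gene_anchor = {
        g: (
            ann.genes[g][0].chrom,
            min(t.start for t in ann.genes[g]),
            ann.genes[g][0].strand,
        )
        for g in genes
    }

    sets: list[AlignmentRecordSet] = []
    read_rows: list[dict] = []
    truth_rows: list[dict] = []
    decoy_cycle = ["a", "b", "c", "d"]

    def pick_two_far_anchors():
        """Two anchor points guaranteed >= 12 kb apart or cross-chromosome."""
        for _ in range(200):
            ga, gb = rng.choice(len(genes), size=2, replace=False)
            ca, sa, _ = gene_anchor[genes[ga]]
            cb, sb, _ = gene_anchor[genes[gb]]
            if ca != cb or abs(sa - sb) >= 20_000:
                return (ca, sa), (cb, sb)
        raise ValueError("annotation too small to place separated fusion loci")

    n_total = n_true + n_decoys
    for i in range(n_total):
        qid = f"FUS.{i + 1}"
        L = int(rng.integers(800, 3001))
        samples = _random_sample_subset(rng, sample_names)
        is_true = i < n_true
        if is_true:
            (ca, sa), (cb, sb) = pick_two_far_anchors()
            split = int(L * rng.uniform(0.25, 0.75))
            loci = [
                AlignmentLocus(0, split, GenomicInterval(ca, sa, sa + split, "+")),
                AlignmentLocus(split, L, GenomicInterval(cb, sb, sb + (L - split), "+")),
            ]
            supported = rng.random() >= unsupported_fraction
            truth_rows.append(
                {
                    "query_id": qid,
                    "verdict": "fusion",
                    "violated_criterion": "",
                    "expect_validated": supported,
                    "samples": ",".join(sorted(samples)),
                }
            )
            if supported:
                for r in range(support_reads):
                    rid = f"{qid}.sr{r + 1}"
                    read_rows.append(
                        {
                            "read_id": rid,
                            "mate": 1,
                            "query_id": qid,
                            "start": max(0, split - 40),
                            "end": min(L, split + 40),
                            "unique_flag": 1,
                        }
                    )
                    read_rows.append(
                        {
                            "read_id": rid,
                            "mate": 2,
                            "query_id": qid,
                            "start": min(L - 20, split + 60),
                            "end": min(L, split + 140),
                            "unique_flag": 1,
                        }
                    )
        else:
            crit = decoy_cycle[(i - n_true) % len(decoy_cycle)]
            (ca, sa), (cb, sb) = pick_two_far_anchors()
            if crit == "a":
                loci = [AlignmentLocus(0, L, GenomicInterval(ca, sa, sa + L, "+"))]
            elif crit == "b":
                small = max(1, int(L * rng.uniform(0.02, 0.045)))
                loci = [
                    AlignmentLocus(
                        0, L - small, GenomicInterval(ca, sa, sa + L - small, "+")
                    ),
                    AlignmentLocus(
                        L - small, L, GenomicInterval(cb, sb, sb + small, "+")
                    ),
                ]
            elif crit == "c":
                s1 = int(L * 0.50)
                s2 = int(L * 0.55)
                e2 = int(L * 0.90)
                loci = [
                    AlignmentLocus(0, s1, GenomicInterval(ca, sa, sa + s1, "+")),
                    AlignmentLocus(
                        s2, e2, GenomicInterval(cb, sb, sb + (e2 - s2), "+")
                    ),
                ]
            else:  # d: same chromosome, gap below 10 kb
                split = int(L * 0.5)
                gap = int(rng.integers(1000, 9001))
                loci = [
                    AlignmentLocus(0, split, GenomicInterval(ca, sa, sa + split, "+")),
                    AlignmentLocus(
                        split,
                        L,
                        GenomicInterval(
                            ca, sa + split + gap, sa + split + gap + (L - split), "+"
                        ),
                    ),
                ]
            truth_rows.append(
                {
                    "query_id": qid,
                    "verdict": f"rejected:{crit}",
                    "violated_criterion": crit,
                    "expect_validated": False,
                    "samples": ",".join(sorted(samples)),
                }
            )
        sets.append(AlignmentRecordSet(query_id=qid, query_length=L, loci=loci))

    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "mate", "query_id", "start", "end", "unique_flag"],
    )
    truth = SimulationTruth(seed=seed, fusions=pd.DataFrame(truth_rows))
    return sets, reads, truth


# ---------------------------------------------------------------------------
# expression counts with planted temporal profiles
# ---------------------------------------------------------------------------


def profile_shapes(zones: Sequence[str], n_clusters: int) -> np.ndarray:
    """Mean-profile shapes (multiplicative, min 1, max 8-16) per cluster.

    The family mirrors the profile types seen along a developmental
    gradient: one peak per zone, then gradual-up, up-then-plateau and
    down-then-plateau shapes; every shape has at least one adjacent-zone
    fold change of 4 or more.
    """
    z = len(zones)
    shapes: list[list[float]] = []
    for i in range(z):
        s = [1.0] * z
        s[i] = 8.0
        shapes.append(s)
    ramp_up = [1.0] * z
    for j in range(z):
        ramp_up[j] = [1, 1, 2, 8, 16, 16][j] if z == 6 else 1.0 + 15.0 * j / (z - 1)
    shapes.append(ramp_up)
    plateau_up = [1.0] * z
    for j in range(z):
        plateau_up[j] = [1, 2, 8, 8, 8, 8][j] if z == 6 else min(8.0, 1 + 7 * 2 * j / z)
    shapes.append(plateau_up)
    shapes.append(list(reversed(plateau_up)))
    shapes.append(list(reversed(ramp_up)))
    while len(shapes) < n_clusters:  # rare: more clusters than stock shapes
        k = len(shapes) - z - 4
        s = [1.0] * z
        s[k % z] = 8.0
        s[(k + 2) % z] = 8.0
        shapes.append(s)
    return np.array(shapes[:n_clusters])


def simulate_expression(
    n_transcripts: int,
    zones: Sequence[str] = DEFAULT_ZONES,
    replicates: int = 3,
    n_clusters: int = 9,
    de_fraction: float = 0.3,
    dispersion: float = 0.05,
    seed: int = 0,
    mean_log: float = 5.0,
    sd_log: float = 0.8,
) -> tuple["ExpressionMatrix", SimulationTruth]:
    """Negative-binomial counts around cluster-specific zone profiles.

    DE transcripts follow one of ``n_clusters`` planted shapes scaled by a
    lognormal baseline; non-DE transcripts are flat. ``dispersion`` is the
    NB alpha (variance = mu + alpha mu^2); values below 1e-8 fall back to
    Poisson sampling.
    """
    from .expression import ExpressionMatrix  # local import to avoid a cycle

    if len(zones) < 2:
        raise ValueError("need >= 2 zones")
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    shapes = profile_shapes(zones, n_clusters)

    tids = [f"T{i + 1:05d}" for i in range(n_transcripts)]
    is_de = rng.random(n_transcripts) < de_fraction
    clusters = np.where(is_de, rng.integers(0, n_clusters, size=n_transcripts), -1)
    baseline = np.exp(rng.normal(mean_log, sd_log, size=n_transcripts))
    lengths = rng.integers(500, 5001, size=n_transcripts)

    mu = np.empty((n_transcripts, len(zones)))
    for i in range(n_transcripts):
        mu[i] = baseline[i] * (shapes[clusters[i]] if is_de[i] else 1.0)

    samples = [f"{z}_r{r + 1}" for z in zones for r in range(replicates)]
    counts = np.empty((n_transcripts, len(samples)), dtype=np.int64)
    col = 0
    for zi in range(len(zones)):
        for _r in range(replicates):
            m = mu[:, zi]
            if dispersion < 1e-8:
                counts[:, col] = rng.poisson(m)
            else:
                n_param = 1.0 / dispersion
                p_param = n_param / (n_param + m)
                counts[:, col] = rng.negative_binomial(n_param, p_param)
            col += 1

    counts_df = pd.DataFrame(counts, index=tids, columns=samples)
    design = pd.DataFrame(
        {
            "zone": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=samples,
    )
    expr = ExpressionMatrix(
        counts=counts_df,
        lengths=pd.Series(lengths, index=tids, dtype=float),
        design=design,
    )
    truth_df = pd.DataFrame(
        {
            "transcript_id": tids,
            "is_de": is_de,
            "cluster": [int(c) + 1 if c >= 0 else 0 for c in clusters],
        }
    )
    truth = SimulationTruth(seed=seed, expression=truth_df)
    return expr, truth
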