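"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most direct possible method
(exhaustive enumeration, set algebra, closed form), deliberately sharing no
code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

STOPS = ("TAA", "TAG", "TGA")


def brute_longest_orf(seq: str) -> int:
    """Exhaustive (start, stop) codon-pair scan over the three forward frames."""
    seq = seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        codons = [seq[p : p + 3] for p in range(frame, n - 2, 3)]
        for i, c in enumerate(codons):
            if c != "ATG":
                continue
            for j in range(i, len(codons)):
                if codons[j] in STOPS:
                    best = max(best, (j - i + 1) * 3)
                    break
    return best


def brute_bh(pvalues) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_pos, m)
        ]
        q[idx] = min(candidates)
    return q


def brute_fusion_verdict(
    record,
    min_locus_cov=0.05,
    min_combined_cov=0.95,
    min_separation=10_000,
) -> str:
    """Direct evaluation of the four fusion criteria in order a, b, c, d.

    Loci are alignment rows merged on genomic overlap, as documented for
    the detector; coverage unions are recomputed from scratch here.
    """

    def union_len(segs):
        points = set()
        for s, e in segs:
            points.update(range(s, e))
        return len(points)

    rows = sorted(record.loci, key=lambda l: (l.interval.chrom, l.interval.start))
    loci: list[dict] = []
    for loc in rows:
        placed = False
        for m in loci:
            if m["chrom"] == loc.interval.chrom and not (
                loc.interval.end <= m["start"] or loc.interval.start >= m["end"]
            ):
                m["start"] = min(m["start"], loc.interval.start)
                m["end"] = max(m["end"], loc.interval.end)
                m["segs"].append((loc.query_start, loc.query_end))
                placed = True
                break
        if not placed:
            loci.append(
                {
                    "chrom": loc.interval.chrom,
                    "start": loc.interval.start,
                    "end": loc.interval.end,
                    "segs": [(loc.query_start, loc.query_end)],
                }
            )
    if len(loci) < 2:
        return "rejected:a"
    for m in loci:
        if union_len(m["segs"]) / record.query_length < min_locus_cov:
            return "rejected:b"
    all_segs = [seg for m in loci for seg in m["segs"]]
    if union_len(all_segs) / record.query_length < min_combined_cov:
        return "rejected:c"
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if a["chrom"] != b["chrom"]:
                continue
            gap = max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]))
            if gap < min_separation:
                return "rejected:d"
    return "fusion"


def brute_venn_counts(memberships: list[frozenset]) -> dict[frozenset, int]:
    """Set-algebra recount of Venn region occupancies."""
    out: dict[frozenset, int] = {}
    for m in memberships:
        if m:
            out[m] = out.get(m, 0) + 1
    return out


def brute_gene_overlap_pairs(ann) -> list[tuple[str, str]]:
    """All-pairs scan for same-strand exonic overlap between genes."""
    genes = []
    for gid, txs in ann.genes.items():
        exons = [(e.start, e.end) for t in txs for e in t.exons]
        genes.append((gid, txs[0].chrom, txs[0].strand, exons))
    pairs = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            ga, gb = genes[i], genes[j]
            if ga[1] != gb[1] or ga[2] != gb[2]:
                continue
            if any(
                s1 < e2 and s2 < e1 for s1, e1 in ga[3] for s2, e2 in gb[3]
            ):
                pairs.append((ga[0], gb[0]))
    return pairs


def brute_novel_locus_components(models) -> int:
    """Connected components of the same-strand exonic overlap graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(models)))
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            a, b = models[i], models[j]
            if a.chrom != b.chrom:
                continue
            if a.strand != b.strand and "." not in (a.strand, b.strand):
                continue
            if any(
                ea.start < eb.end and eb.start < ea.end
                for ea in a.exons
                for eb in b.exons
            ):
                g.add_edge(i, j)
    return nx.number_connected_components(g)
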