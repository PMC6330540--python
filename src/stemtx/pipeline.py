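"""End-to-end orchestration of the synthetic-data pipeline.

Runs simulate → classify → AS events → lncRNA → fusions → FPKM → DET →
cluster with a single config; every stage communicates through files in the
output directory so each is independently re-runnable, and a manifest
records all parameter values and input checksums. Re-running with the same
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import events as _events
from . import expression as _expression
from . import fusion as _fusion
from . import io as _io
from . import lncrna as _lncrna
from . import simulate as _simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus the master seed."""

    outdir: str = "stemtx_out"
    seed: int = 0
    # simulation sizes
    n_genes: int = 150
    isoforms_per_gene: tuple[int, int] = (1, 3)
    n_transcripts: int = 1000
    fraction_known: float = 0.30
    fraction_novel_isoform: float = 0.50
    fraction_novel_locus: float = 0.20
    as_mix: dict = field(default_factory=lambda: dict(_simulate.DEFAULT_AS_MIX))
    lncrna_fraction: float = 0.2
    n_true_fusions: int = 30
    n_decoy_fusions: int = 40
    n_expr_transcripts: int = 1000
    zones: tuple = tuple(_simulate.DEFAULT_ZONES)
    replicates: int = 3
    n_clusters: int = 9
    de_fraction: float = 0.3
    dispersion: float = 0.05
    # stage thresholds (defaults are the published values where one exists)
    mono_exon_reciprocal_overlap: float = 0.9
    junction_tolerance: int = 0
    min_locus_cov: float = 0.05
    min_combined_cov: float = 0.95
    min_separation: int = 10_000
    min_overhang: int = 10
    min_support: int = 1
    lnc_min_length: int = 200
    lnc_min_exons: int = 1
    lnc_max_orf: int = 300
    consensus_rule: str = "all_noncoding"
    det_fdr: float = 0.01
    det_fc: float = 2.0
    pseudocount: float = 0.1
    kmeans_n_init: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "isoforms_per_gene" in raw:
            raw["isoforms_per_gene"] = tuple(raw["isoforms_per_gene"])
        if "zones" in raw:
            raw["zones"] = tuple(raw["zones"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isoforms_per_gene"] = list(self.isoforms_per_gene)
        d["zones"] = list(self.zones)
        return d

    @property
    def fractions(self) -> dict:
        return {
            "known": self.fraction_known,
            "novel_isoform": self.fraction_novel_isoform,
            "novel_locus": self.fraction_novel_locus,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the summary report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=8
    )
    report: dict = {"seed": config.seed}

    # 1. reference annotation ------------------------------------------------
    ann, ann_truth = _simulate.simulate_annotation(
        n_genes=config.n_genes,
        isoforms_per_gene=config.isoforms_per_gene,
        seed=int(stage_seeds[0]),
    )
    _io.write_annotation(ann, out / "reference.gtf")
    report["reference"] = {"genes": ann.n_genes, "isoforms": ann.n_transcripts}

    # 2. isoform set ---------------------------------------------------------
    models, iso_truth = _simulate.simulate_isoform_set(
        ann,
        n_transcripts=config.n_transcripts,
        fractions=config.fractions,
        as_mix=config.as_mix,
        seed=int(stage_seeds[1]),
    )
    _io.write_annotation(
        _io.transcripts_to_annotation(models), out / "isoforms.gtf"
    )
    iso_truth.to_tsv(out / "truth")

    # 3. classification + annotation update ----------------------------------
    results = _classify.classify_isoforms(
        models,
        ann,
        mono_exon_reciprocal_overlap=config.mono_exon_reciprocal_overlap,
        junction_tolerance=config.junction_tolerance,
    )
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "category": r.category,
                "matched_gene_id": r.matched_gene_id or "",
                "matched_transcript_id": r.matched_transcript_id or "",
            }
            for r in results
        ]
    ).to_csv(out / "classification.tsv", sep="\t", index=False)
    cat_counts = pd.Series([r.category for r in results]).value_counts().to_dict()
    updated = _classify.update_annotation(ann, results, models)
    _io.write_annotation(updated, out / "updated.gtf")
    report["classification"] = {c: int(cat_counts.get(c, 0)) for c in _classify.CATEGORIES}
    report["updated_annotation"] = {
        "genes": updated.n_genes,
        "isoforms": updated.n_transcripts,
    }

    # 4. AS events on the updated annotation ----------------------------------
    all_events = []
    for gene_id in sorted(updated.genes):
        isoforms = updated.genes[gene_id]
        if len(isoforms) < 2:
            continue
        all_events.extend(_events.locus_events(isoforms, gene_id=gene_id))
    ev_rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "coords": repr(e.coords),
            "provenance": ";".join(f"{i}|{x}" for i, x in e.provenance),
        }
        for e in all_events
    ]
    pd.DataFrame(
        ev_rows,
        columns=["gene_id", "event_type", "chrom", "strand", "coords", "provenance"],
    ).to_csv(out / "as_events.tsv", sep="\t", index=False)
    summary = _events.event_type_summary(all_events)
    summary.to_csv(out / "as_summary.tsv", sep="\t", index=False)
    report["as_events"] = {
        row.event_type: int(row.count) for row in summary.itertuples(index=False)
    }

    # 5. lncRNA filter on the simulated isoform set ---------------------------
    seqs, evidence, lnc_truth = _simulate.simulate_sequences(
        models, lncrna_fraction=config.lncrna_fraction, seed=int(stage_seeds[2])
    )
    _io.write_fasta(seqs, out / "isoforms.fasta")
    lnc_truth.to_tsv(out / "truth")
    calls = _lncrna.classify_lncrnas(
        models,
        seqs,
        evidence,
        min_length=config.lnc_min_length,
        min_exons=config.lnc_min_exons,
        max_orf=config.lnc_max_orf,
        consensus_rule=config.consensus_rule,
    )
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        out / "lncrna.tsv", sep="\t", index=False
    )
    report["lncrna"] = {"n_final": int(sum(c.final for c in calls))}

    # 6. fusions ---------------------------------------------------------------
    aln_sets, short_reads, fus_truth = _simulate.simulate_fusion_queries(
        ann,
        n_true=config.n_true_fusions,
        n_decoys=config.n_decoy_fusions,
        seed=int(stage_seeds[3]),
    )
    _io.write_alignment_sets(aln_sets, out / "fusion_alignments.tsv")
    short_reads.to_csv(out / "fusion_short_reads.tsv", sep="\t", index=False)
    fus_truth.to_tsv(out / "truth")
    candidates = _fusion.detect_fusions(
        aln_sets,
        min_locus_cov=config.min_locus_cov,
        min_combined_cov=config.min_combined_cov,
        min_separation=config.min_separation,
    )
    candidates = _fusion.validate_fusions(
        candidates,
        short_reads,
        min_overhang=config.min_overhang,
        min_support=config.min_support,
    )
    pd.DataFrame(
        [
            {
                "query_id": c.query_id,
                "status": c.status,
                "rejected_criterion": c.rejected_criterion or "",
                "combined_coverage": round(c.combined_coverage, 6),
                "separation_class": c.separation_class,
                "spanning_support": c.spanning_support,
                "discordant_support": c.discordant_support,
            }
            for c in candidates
        ]
    ).to_csv(out / "fusions.tsv", sep="\t", index=False)
    fsum = _fusion.fusion_summary(candidates)
    report["fusions"] = {
        "candidates": fsum["n_candidates"],
        "validated": fsum["n_validated"],
        "inter": fsum["by_class"]["inter"],
        "intra": fsum["by_class"]["intra"],
    }

    # 7. expression: FPKM, DET calls, clustering ------------------------------
    expr, expr_truth = _simulate.simulate_expression(
        n_transcripts=config.n_expr_transcripts,
        zones=config.zones,
        replicates=config.replicates,
        n_clusters=config.n_clusters,
        de_fraction=config.de_fraction,
        dispersion=config.dispersion,
        seed=int(stage_seeds[4]),
    )
    expr.counts.to_csv(out / "counts.tsv", sep="\t")
    expr.lengths.rename("length").to_frame().rename_axis("transcript_id").to_csv(
        out / "lengths.tsv", sep="\t"
    )
    expr.design.rename_axis("sample").to_csv(out / "design.tsv", sep="\t")
    expr_truth.to_tsv(out / "truth")
    expr.fpkm().round(6).to_csv(out / "fpkm.tsv", sep="\t")
    det_calls = _expression.call_dets(
        expr,
        fdr=config.det_fdr,
        fc=config.det_fc,
        pseudocount=config.pseudocount,
    )
    det_calls.round(6).to_csv(out / "det_calls.tsv", sep="\t", index=False)
    det_ids = _expression.det_transcripts(det_calls)
    per_contrast = (
        det_calls[det_calls["is_det"]]
        .groupby(["zone_a", "zone_b"], sort=True)
        .size()
    )
    report["dets"] = {
        "total": len(det_ids),
        "per_contrast": {f"{a}~{b}": int(n) for (a, b), n in per_contrast.items()},
    }
    profiles = expr.zone_mean_fpkm().loc[det_ids]
    k = min(config.n_clusters, max(1, len(profiles)))
    assignment = _expression.kmeans_profiles(
        profiles, k=k, seed=int(stage_seeds[5]), n_init=config.kmeans_n_init
    )
    assignment.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    report["clusters"] = {
        str(c): int(n) for c, n in assignment.labels.value_counts().sort_index().items()
    }

    # consistency + manifest ---------------------------------------------------
    assert sum(report["classification"].values()) == config.n_transcripts
    manifest = {
        "config": config.to_dict(),
        "checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        }
        | {p.name: _sha256(p) for p in sorted(out.glob("*.gtf"))}
        | {p.name: _sha256(p) for p in sorted(out.glob("*.fasta"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
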