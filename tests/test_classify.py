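import numpy as np
import pytest

from stemtx import (
    classify_isoform,
    classify_isoforms,
    exon_length_stats,
    sample_presence_summary,
    splice_chain,
    update_annotation,
)
from stemtx.simulate import simulate_annotation, simulate_isoform_set

from conftest import make_transcript
from oracles import brute_novel_locus_components, brute_venn_counts


class TestSpliceChain:
    def test_gaps_between_exons(self):
        t = make_transcript("t", [(0, 100), (200, 300)])
        assert splice_chain(t).introns == ((100, 200),)

    def test_mono_exonic_is_empty(self):
        assert splice_chain(make_transcript("t", [(0, 100)])).introns == ()

    def test_matches_brute_force_consecutive_gaps(self, rng):
        bounds = np.cumsum(rng.integers(50, 200, size=20))
        exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, 18, 2)]
        t = make_transcript("t", exons)
        expected = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        assert splice_chain(t).introns == expected


class TestClassifyIsoform:
    def test_exact_copy_is_known(self, tiny_annotation):
        t = make_transcript("q", [(100, 200), (300, 400), (500, 600)])
        r = classify_isoform(t, tiny_annotation)
        assert r.category == "known"
        assert r.matched_transcript_id == "g1.t1"
        assert r.matched_gene_id == "g1"

    def test_retained_intron_is_novel_isoform(self, tiny_annotation):
        # g1.t1 with the first intron retained
        t = make_transcript("q", [(100, 400), (500, 600)])
        r = classify_isoform(t, tiny_annotation)
        assert r.category == "novel_isoform"
        assert r.matched_gene_id == "g1"

    def test_intergenic_is_novel_locus(self, tiny_annotation):
        t = make_transcript("q", [(20000, 20500)])
        assert classify_isoform(t, tiny_annotation).category == "novel_locus"

    def test_antisense_overlap_is_novel_locus_when_strand_aware(
        self, tiny_annotation
    ):
        t = make_transcript("q", [(5000, 5200), (5400, 5600)], strand="+")
        assert classify_isoform(t, tiny_annotation).category == "novel_locus"
        r = classify_isoform(t, tiny_annotation, strand_aware=False)
        assert r.category == "novel_isoform" and r.matched_gene_id == "g2"

    def test_mono_exonic_reciprocal_overlap(self, tiny_annotation):
        # g3.t1 spans 9000-9800 (800 nt); 95% reciprocal copy is known
        t = make_transcript("q", [(9020, 9780)])
        assert classify_isoform(t, tiny_annotation).category == "known"
        # a shifted fragment below the threshold is a novel isoform of g3
        t2 = make_transcript("q2", [(9600, 10400)])
        r = classify_isoform(t2, tiny_annotation)
        assert r.category == "novel_isoform" and r.matched_gene_id == "g3"

    def test_unknown_chromosome_is_novel_locus(self, tiny_annotation):
        t = make_transcript("q", [(0, 500)], chrom="chrUn")
        assert classify_isoform(t, tiny_annotation).category == "novel_locus"

    def test_junction_tolerance_recovers_jittered_chain(self, tiny_annotation):
        t = make_transcript("q", [(100, 203), (300, 400), (500, 600)])
        assert classify_isoform(t, tiny_annotation).category == "novel_isoform"
        r = classify_isoform(t, tiny_annotation, junction_tolerance=5)
        assert r.category == "known" and r.matched_transcript_id == "g1.t1"

    def test_planted_category_recovery(self):
        """Planted known/novel-isoform/novel-locus labels recovered exactly."""
        ann, _ = simulate_annotation(60, (1, 3), seed=11)
        models, truth = simulate_isoform_set(ann, 500, seed=12)
        results = classify_isoforms(models, ann)
        want = dict(zip(truth.transcripts.transcript_id, truth.transcripts.category))
        assert all(r.category == want[r.transcript_id] for r in results)

    def test_order_invariance(self):
        ann, _ = simulate_annotation(20, (1, 3), seed=13)
        models, _ = simulate_isoform_set(ann, 100, seed=14)
        fwd = {r.transcript_id: r for r in classify_isoforms(models, ann)}
        rev = {r.transcript_id: r for r in classify_isoforms(models[::-1], ann)}
        assert fwd == rev


class TestUpdateAnnotation:
    def test_no_novel_results_identity(self, tiny_annotation):
        t = make_transcript("q", [(100, 200), (300, 400), (500, 600)])
        res = classify_isoforms([t], tiny_annotation)
        updated = update_annotation(tiny_annotation, res, [t])
        assert updated.n_genes == tiny_annotation.n_genes
        assert updated.n_transcripts == tiny_annotation.n_transcripts

    def test_overlapping_novel_loci_form_one_gene(self, tiny_annotation):
        a = make_transcript("qa", [(30000, 30500)])
        b = make_transcript("qb", [(30400, 30900)])
        res = classify_isoforms([a, b], tiny_annotation)
        updated = update_annotation(tiny_annotation, res, [a, b])
        assert updated.n_genes == tiny_annotation.n_genes + 1
        new_gene = updated.gene_of("qa")
        assert updated.gene_of("qb") == new_gene

    def test_id_collision_rejected(self, tiny_annotation):
        clash = make_transcript("g1.t1", [(30000, 30500)])
        res = classify_isoforms([clash], tiny_annotation)
        with pytest.raises(ValueError, match="collides"):
            update_annotation(tiny_annotation, res, [clash])

    def test_gene_count_equals_connected_components(self):
        """New-gene count matches brute-force components of the overlap graph."""
        ann, _ = simulate_annotation(40, (1, 2), seed=21)
        models, truth = simulate_isoform_set(
            ann, 300, fractions={"known": 0.2, "novel_isoform": 0.3,
                                "novel_locus": 0.5}, seed=22
        )
        results = classify_isoforms(models, ann)
        updated = update_annotation(ann, results, models)
        novel = [
            m
            for m, r in zip(models, results)
            if r.category == "novel_locus"
        ]
        expected_new = brute_novel_locus_components(novel)
        assert updated.n_genes == ann.n_genes + expected_new

    def test_idempotent_on_own_output(self):
        ann, _ = simulate_annotation(20, (1, 2), seed=31)
        models, _ = simulate_isoform_set(ann, 100, seed=32)
        results = classify_isoforms(models, ann)
        updated = update_annotation(ann, results, models)
        reclassified = classify_isoforms(models, updated)
        assert all(r.category == "known" for r in reclassified)
        # merging again adds nothing (known transcripts are not duplicated)
        models2 = [
            make_transcript(
                m.transcript_id + "_b",
                [(e.start, e.end) for e in m.exons],
                m.chrom,
                m.strand,
            )
            for m in models
        ]
        res2 = classify_isoforms(models2, updated)
        updated2 = update_annotation(updated, res2, models2)
        assert updated2.n_genes == updated.n_genes


class TestSummaries:
    def test_center_region_of_venn(self):
        samples = ["Apex", "IN1-3", "IN4-5"]
        t = make_transcript("t", [(0, 100)], samples=samples)
        counts = sample_presence_summary([t], samples)
        assert counts == {frozenset(samples): 1}

    def test_disjoint_singletons(self):
        samples = ["A", "B", "C"]
        ts = [
            make_transcript(f"t{i}", [(i * 1000, i * 1000 + 100)], samples=[s])
            for i, s in enumerate(samples)
        ]
        counts = sample_presence_summary(ts, samples)
        assert counts == {frozenset([s]): 1 for s in samples}

    def test_unknown_sample_rejected(self):
        t = make_transcript("t", [(0, 100)], samples=["X"])
        with pytest.raises(ValueError):
            sample_presence_summary([t], ["A"])

    def test_venn_counts_equal_set_algebra(self, rng):
        samples = ["A", "B", "C"]
        ts = []
        for i in range(1000):
            mask = rng.random(3) < 0.5
            members = [s for s, m in zip(samples, mask) if m]
            ts.append(
                make_transcript(f"t{i}", [(i * 10, i * 10 + 5)], samples=members)
            )
        got = sample_presence_summary(ts, samples)
        want = brute_venn_counts([t.samples_detected for t in ts])
        assert got == want
        assert sum(got.values()) == sum(
            1 for t in ts if t.samples_detected
        )

    def test_exon_length_stats_small_cases(self):
        t1 = make_transcript("t1", [(0, 100), (200, 300)])
        s = exon_length_stats([t1])
        assert s["mean_length"] == 200 and s["mean_exons"] == 2
        t2 = make_transcript("t2", [(0, 300)])
        s2 = exon_length_stats([make_transcript("a", [(0, 100)]), t2])
        assert s2["mean_length"] == 200

    def test_exon_length_stats_match_brute_force(self, rng):
        ts = []
        for i in range(500):
            n = int(rng.integers(1, 8))
            p = 0
            exons = []
            for _ in range(n):
                ln = int(rng.integers(50, 400))
                exons.append((p, p + ln))
                p += ln + 100
            ts.append(make_transcript(f"t{i}", exons))
        s = exon_length_stats(ts)
        assert s["mean_length"] == pytest.approx(
            sum(t.length for t in ts) / len(ts)
        )
        assert s["mean_exons"] == pytest.approx(
            sum(t.exon_count for t in ts) / len(ts)
        )
        assert sum(s["exon_count_histogram"].values()) == len(ts)
        assert sum(s["length_histogram"].values()) == len(ts)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            exon_length_stats([])
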