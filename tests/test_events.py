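import pytest

from stemtx import (
    event_type_summary,
    locus_events,
    pairwise_events,
    transcript_event_summary,
)
from stemtx.simulate import simulate_annotation, simulate_isoform_set

from conftest import make_transcript


def _mirror(exons, origin=100_000):
    """Reflect exon coordinates so a plus-strand case maps onto minus."""
    return sorted((origin - e, origin - s) for s, e in exons)


class TestPairwiseConstructed:
    def test_intron_retention(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 300)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["IR"]
        assert evs[0].coords == ((100, 200),)
        assert evs[0].inclusion_id == "b" and evs[0].exclusion_id == "a"

    def test_exon_skipping(self):
        a = make_transcript("a", [(0, 100), (150, 200), (250, 300)])
        b = make_transcript("b", [(0, 100), (250, 300)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["SE"]
        assert evs[0].coords == ((150, 200),)
        assert evs[0].inclusion_id == "a"

    def test_alternative_acceptor_plus_strand(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 100), (240, 300)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["A3"]
        assert evs[0].coords == (200, 240)
        assert evs[0].inclusion_id == "a"  # shorter intron, more exon

    def test_alternative_donor_plus_strand(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 60), (200, 300)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["A5"]
        assert evs[0].coords == (60, 100)

    def test_mutually_exclusive_exons(self):
        a = make_transcript("a", [(0, 100), (150, 200), (400, 500)])
        b = make_transcript("b", [(0, 100), (250, 300), (400, 500)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["MEX"]
        assert evs[0].coords == ((150, 200), (250, 300))

    def test_different_strand_rejected(self):
        a = make_transcript("a", [(0, 100), (200, 300)], strand="+")
        b = make_transcript("b", [(0, 100), (200, 300)], strand="-")
        with pytest.raises(ValueError):
            pairwise_events(a, b)

    def test_identical_chains_no_events(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(10, 100), (200, 290)])
        assert pairwise_events(a, b) == []

    def test_unmatched_difference_lands_in_other(self):
        # two introns differing at both boundaries: none of the five types
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 120), (230, 300)])
        evs = pairwise_events(a, b)
        assert [e.event_type for e in evs] == ["other"]


class TestPairwiseProperties:
    def test_symmetry_in_argument_order(self):
        cases = [
            ([(0, 100), (200, 300)], [(0, 300)]),
            ([(0, 100), (150, 200), (250, 300)], [(0, 100), (250, 300)]),
            ([(0, 100), (200, 300)], [(0, 100), (240, 300)]),
            ([(0, 100), (150, 200), (400, 500)], [(0, 100), (250, 300), (400, 500)]),
        ]
        for ex_a, ex_b in cases:
            a, b = make_transcript("a", ex_a), make_transcript("b", ex_b)
            ab = {(e.event_type, e.coords, e.inclusion_id) for e in pairwise_events(a, b)}
            ba = {(e.event_type, e.coords, e.inclusion_id) for e in pairwise_events(b, a)}
            assert ab == ba

    def test_a5_a3_labels_are_strand_resolved(self):
        """Flipping the strand label at fixed coordinates swaps A5 and A3;
        genomic reflection plus strand flip maps donors to donors and so
        preserves the type at mirrored coordinates."""
        a_ex = [(0, 100), (200, 300)]
        b_ex = [(0, 60), (200, 300)]
        a = make_transcript("a", a_ex)
        b = make_transcript("b", b_ex)
        (plus_ev,) = pairwise_events(a, b)
        assert plus_ev.event_type == "A5" and plus_ev.coords == (60, 100)
        # same genomic configuration, minus strand: the shared boundary is
        # now the donor, so the differing one is the acceptor
        (flip_ev,) = pairwise_events(
            make_transcript("af", a_ex, strand="-"),
            make_transcript("bf", b_ex, strand="-"),
        )
        assert flip_ev.event_type == "A3" and flip_ev.coords == (60, 100)
        # reflection + strand flip preserves transcription geometry
        (mirror_ev,) = pairwise_events(
            make_transcript("am", _mirror(a_ex), strand="-"),
            make_transcript("bm", _mirror(b_ex), strand="-"),
        )
        assert mirror_ev.event_type == "A5"
        assert mirror_ev.coords == tuple(sorted(100_000 - c for c in plus_ev.coords))

    def test_planted_single_edit_recovery_all_types(self):
        """Each planted AS edit is recovered as exactly one event of its type."""
        ann, _ = simulate_annotation(60, (1, 1), seed=41)
        mix = {"IR": 0.2, "SE": 0.2, "A3": 0.2, "A5": 0.2, "MEX": 0.2}
        models, truth = simulate_isoform_set(
            ann, 600, fractions={"known": 0, "novel_isoform": 1, "novel_locus": 0},
            as_mix=mix, seed=42,
        )
        by_id = {m.transcript_id: m for m in models}
        ref = {t.transcript_id: t for t in ann.transcripts()}
        seen = set()
        for row in truth.transcripts.itertuples(index=False):
            evs = pairwise_events(by_id[row.transcript_id], ref[row.source_transcript_id])
            assert len(evs) == 1
            assert evs[0].event_type == row.as_type
            assert evs[0].coords == eval(row.event_coords)
            seen.add(row.as_type)
        assert seen == set(mix)


class TestLocusEvents:
    def test_single_isoform_empty(self):
        assert locus_events([make_transcript("a", [(0, 100), (200, 300)])]) == []

    def test_shared_event_merges_provenance(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 300)])
        c = make_transcript("c", [(0, 350)])
        evs = locus_events([a, b, c])
        ir = [e for e in evs if e.event_type == "IR"]
        assert len(ir) == 1
        assert set(ir[0].provenance) == {("b", "a"), ("c", "a")}

    def test_equals_brute_force_all_pairs(self, rng):
        """Deduplicated locus events equal direct all-pairs enumeration."""
        for rep in range(10):
            ann, _ = simulate_annotation(5, (1, 3), seed=100 + rep)
            models, truth = simulate_isoform_set(
                ann, int(rng.integers(10, 25)),
                fractions={"known": 0.2, "novel_isoform": 0.8, "novel_locus": 0},
                seed=200 + rep,
            )
            src_gene = dict(
                zip(truth.transcripts.transcript_id, truth.transcripts.source_gene_id)
            )
            gene_id = next(g for g in src_gene.values() if g)
            iso = list(ann.genes[gene_id]) + [
                m for m in models if src_gene[m.transcript_id] == gene_id
            ]
            if len(iso) < 2:
                continue
            got = locus_events(iso)
            expected: dict[tuple, set] = {}
            for i in range(len(iso)):
                for j in range(i + 1, len(iso)):
                    for e in pairwise_events(iso[i], iso[j]):
                        expected.setdefault(e.key, set()).add(
                            (e.inclusion_id, e.exclusion_id)
                        )
            assert {e.event_type for e in got} == {k[0] for k in expected}
            assert len(got) == len(expected)
            for e in got:
                key = (e.event_type, e.chrom, e.strand, e.coords)
                assert set(e.provenance) == expected[key]


class TestSummaries:
    def test_proportions(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 300)])
        evs = locus_events([a, b]) * 3  # 3 IR
        se_a = make_transcript("c", [(0, 100), (150, 200), (250, 300)])
        se_b = make_transcript("d", [(0, 100), (250, 300)])
        evs = evs + locus_events([se_a, se_b])
        df = event_type_summary(evs).set_index("event_type")
        assert df.loc["IR", "count"] == 3 and df.loc["SE", "count"] == 1
        assert df.loc["IR", "proportion"] == pytest.approx(0.75)

    def test_empty_summary_is_nan(self):
        df = event_type_summary([])
        assert (df["count"] == 0).all()
        assert df["proportion"].isna().all()

    def test_planted_mix_recovered_within_3_se(self):
        """IR share of planted events lands within 3 binomial SE of 0.6."""
        ann, _ = simulate_annotation(80, (1, 1), seed=51)
        n = 2000
        models, truth = simulate_isoform_set(
            ann, n, fractions={"known": 0, "novel_isoform": 1, "novel_locus": 0},
            seed=52,
        )
        p = (truth.transcripts.as_type == "IR").mean()
        se = (0.6 * 0.4 / n) ** 0.5
        assert abs(p - 0.6) <= 3 * se

    def test_transcript_level_summary_counts_carriers(self):
        a = make_transcript("a", [(0, 100), (200, 300)])
        b = make_transcript("b", [(0, 300)])
        c = make_transcript("c", [(0, 350)])
        df = transcript_event_summary(locus_events([a, b, c])).set_index("event_type")
        assert df.loc["IR", "n_transcripts"] == 3
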