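"""Non-reference extraction: hit filtering, interval arithmetic,
contamination screening, identity/redundancy and pangenome assembly."""

import numpy as np
import pytest

from panpav import (
    AlignmentHit,
    NonrefSegment,
    TaxonHit,
    build_pangenome,
    classify_contamination,
    covered_intervals,
    extract_nonref,
    extract_unaligned,
    filter_hits,
    pairwise_identity,
    remove_redundancy,
    simulate_contigs_and_hits,
)
from conftest import brute_force_uncovered_runs


def hit(length, identity, qid="q", qlen=100000, start=0):
    end = min(start + length, qlen)
    return AlignmentHit(qid, qlen, start, end, "ref", identity, length)


class TestFilterHits:
    @pytest.mark.parametrize(
        "length,identity,kept",
        [
            (250, 95.0, False),   # below length threshold
            (300, 90.0, True),    # both boundaries inclusive
            (10000, 89.9, False), # below identity threshold
            (301, 90.1, True),
        ],
    )
    def test_thresholds(self, length, identity, kept):
        out = filter_hits([hit(length, identity)])
        assert (len(out) == 1) == kept

    def test_order_preserved_and_monotone(self):
        rng = np.random.default_rng(0)
        hits = [
            hit(int(rng.integers(100, 1000)), float(rng.uniform(80, 100)), start=i)
            for i in range(200)
        ]
        base = filter_hits(hits)
        assert base == [h for h in hits if h in set(base)]  # order preserved
        # raising either threshold never adds hits
        for min_len, min_id in [(400, 90.0), (300, 95.0), (500, 97.0)]:
            stricter = set(filter_hits(hits, min_len, min_id))
            assert stricter <= set(base)


class TestCoveredIntervals:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([(0, 700), (600, 900)], [(0, 900)]),   # overlap merge
            ([(0, 100), (100, 200)], [(0, 200)]),   # adjacency merge
            ([], []),
            ([(50, 60), (0, 10)], [(0, 10), (50, 60)]),
        ],
    )
    def test_merge(self, raw, expected):
        assert covered_intervals(raw) == expected

    def test_rejects_mixed_queries(self):
        hits = [hit(300, 95, qid="a"), hit(300, 95, qid="b")]
        with pytest.raises(ValueError, match="multiple queries"):
            covered_intervals(hits)


class TestExtractUnaligned:
    def test_interval_complement(self):
        seq = "A" * 2000
        segs = extract_unaligned("c", seq, [(0, 700), (1300, 2000)])
        assert [(s.start, s.end) for s in segs] == [(700, 1300)]
        assert len(segs[0].sequence) == 600

    def test_short_contig_without_hits_dropped(self):
        assert extract_unaligned("c", "A" * 400, []) == []

    def test_whole_contig_when_no_hits(self):
        segs = extract_unaligned("c", "A" * 600, [])
        assert [(s.start, s.end) for s in segs] == [(0, 600)]

    def test_fully_covered_contig_yields_nothing(self):
        assert extract_unaligned("c", "A" * 2000, [(0, 2000)]) == []

    def test_out_of_bounds_interval(self):
        with pytest.raises(ValueError, match="out of bounds"):
            extract_unaligned("c", "A" * 100, [(0, 200)])

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            length = int(rng.integers(1, 10000))
            seq = "A" * length
            n_hits = int(rng.integers(0, 8))
            covered = []
            for _ in range(n_hits):
                s = int(rng.integers(0, length))
                e = int(rng.integers(s + 1, length + 1))
                covered.append((s, e))
            merged = covered_intervals(covered)
            got = [(s.start, s.end) for s in extract_unaligned("c", seq, merged)]
            assert got == brute_force_uncovered_runs(length, covered, 500)


class TestContamination:
    def test_mixed_hits_ratio(self):
        hits = [
            TaxonHit("c", 0, 920, "green_plant"),
            TaxonHit("c", 0, 1000, "other"),
        ]
        assert classify_contamination("c", hits) == "keep"  # 920/1000 >= 0.90
        hits[0] = TaxonHit("c", 0, 880, "green_plant")
        assert classify_contamination("c", hits) == "remove"

    def test_only_other_removed(self):
        assert classify_contamination("c", [TaxonHit("c", 0, 100, "other")]) == "remove"

    def test_no_hits_kept(self):
        assert classify_contamination("c", []) == "keep"

    def test_only_green_kept(self):
        assert classify_contamination("c", [TaxonHit("c", 0, 50, "green_plant")]) == "keep"


class TestPairwiseIdentity:
    def test_identical(self):
        seq = "ACGT" * 25
        assert pairwise_identity(seq, seq) == (100.0, 100.0)

    def test_single_substitution(self):
        a = "ACGT" * 25
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        identity, coverage = pairwise_identity(a, b)
        assert identity == pytest.approx(99.0)
        assert coverage == pytest.approx(100.0)

    def test_containment_covers_shorter(self):
        rng = np.random.default_rng(1)
        nucs = np.array(list("ACGT"))
        long = "".join(nucs[rng.integers(0, 4, 1000)])
        short = long[200:700]
        identity, coverage = pairwise_identity(short, long)
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(100.0)

    def test_unrelated_sequences_below_threshold(self):
        rng = np.random.default_rng(2)
        nucs = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(nucs[rng.integers(0, 4, 500)])
            b = "".join(nucs[rng.integers(0, 4, 500)])
            identity, _ = pairwise_identity(a, b)
            assert identity < 95.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_identity("", "ACGT")


class TestRemoveRedundancy:
    def seg(self, name, seq, start=0):
        return NonrefSegment(name, start, start + len(seq), seq)

    def test_identical_pair_collapses(self):
        seq = "ACGT" * 200
        a, b = self.seg("a", seq), self.seg("b", seq)
        reps, cmap = remove_redundancy([a, b])
        assert len(reps) == 1
        assert set(cmap.values()) == {reps[0].segment_id}

    def test_containment_clusters_under_longer(self):
        rng = np.random.default_rng(3)
        nucs = np.array(list("ACGT"))
        long = "".join(nucs[rng.integers(0, 4, 1200)])
        short = long[100:1150]
        reps, cmap = remove_redundancy([self.seg("short", short), self.seg("long", long)])
        assert [r.source_contig for r in reps] == ["long"]
        assert cmap[self.seg("short", short).segment_id] == reps[0].segment_id

    def test_distinct_segments_stay(self):
        rng = np.random.default_rng(4)
        nucs = np.array(list("ACGT"))
        segs = [self.seg(f"s{i}", "".join(nucs[rng.integers(0, 4, 600)])) for i in range(3)]
        reps, cmap = remove_redundancy(segs)
        assert len(reps) == 3
        assert len(set(cmap.values())) == 3

    def test_idempotent_and_total(self):
        rng = np.random.default_rng(5)
        nucs = np.array(list("ACGT"))
        base = "".join(nucs[rng.integers(0, 4, 800)])
        segs = [
            self.seg("a", base),
            self.seg("b", base[:780]),
            self.seg("c", "".join(nucs[rng.integers(0, 4, 700)])),
        ]
        reps, cmap = remove_redundancy(segs)
        assert set(cmap) == {s.segment_id for s in segs}  # total map
        reps2, cmap2 = remove_redundancy(reps)
        assert [r.segment_id for r in reps2] == [r.segment_id for r in reps]
        assert all(cmap2[r.segment_id] == r.segment_id for r in reps)


class TestBuildPangenome:
    def test_counts_and_manifest(self):
        ref = {"chr1": "A" * 100, "chr2": "C" * 80}
        segs = [NonrefSegment(f"c{i}", 0, 500, "G" * 500) for i in range(3)]
        pangenome, manifest = build_pangenome(ref, segs)
        assert len(pangenome) == 5
        assert len(manifest) == 5
        assert manifest["kind"].tolist() == ["reference"] * 2 + ["nonref"] * 3
        # every pangenome base has a manifest entry
        assert manifest["length"].sum() == sum(len(s) for s in pangenome.values())

    def test_identity_case(self):
        ref = {"chr1": "A" * 100}
        pangenome, manifest = build_pangenome(ref, [])
        assert pangenome == ref
        assert len(manifest) == 1

    def test_duplicate_id_rejected(self):
        seg = NonrefSegment("s", 0, 500, "G" * 500)
        with pytest.raises(ValueError, match="duplicate"):
            build_pangenome({"nonref_00001": "A" * 10}, [seg])

    def test_planted_fixture_added_length(self):
        sim = simulate_contigs_and_hits(seed=9)
        reps, cmap, removed = extract_nonref(sim.contigs, sim.hits, sim.taxon_hits)
        pangenome, manifest = build_pangenome(sim.reference, reps)
        added = manifest.loc[manifest["kind"] == "nonref", "length"].sum()
        expected = sum(e - s for s, e in sim.planted_inserts.values()) + sum(
            len(sim.contigs[kept]) for kept, _ in sim.redundant_pairs
        )
        assert added == expected


class TestEndToEndExtraction:
    def test_planted_structure_recovered(self):
        sim = simulate_contigs_and_hits(seed=1)
        reps, cmap, removed = extract_nonref(sim.contigs, sim.hits, sim.taxon_hits)
        # contaminants removed
        assert set(removed) == {c for c, l in sim.labels.items() if l == "contaminant"}
        # each planted insert recovered at its coordinates
        rep_keys = {(r.source_contig, r.start, r.end) for r in reps}
        for contig, (s, e) in sim.planted_inserts.items():
            assert (contig, s, e) in rep_keys
        # exactly one representative per redundant pair, and it is the longer one
        for kept, dup in sim.redundant_pairs:
            assert any(r.source_contig == kept for r in reps)
            assert not any(r.source_contig == dup for r in reps)
        # fully aligned contigs contribute nothing
        full = {c for c, l in sim.labels.items() if l == "reference-derived"}
        assert not any(r.source_contig in full for r in reps)
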