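"""Copy numbers, cycle-cover enumeration, and conformation export."""

import random

import pytest

from conftest import (
    brute_force_cycle_covers,
    make_graph,
    random_conformation_graph,
    random_dna,
)
from mitograph.conform import (
    Conformation,
    CopyNumberTable,
    canonical_conformation,
    canonical_cycle,
    cycle_sequence,
    enumerate_conformations,
    estimate_copy_numbers,
    export_conformations,
    select_target_contigs,
    validate_conformation,
)
from mitograph.core import HEAD, TAIL, GraphError, NoSeedsError, revcomp
from mitograph.seeds import SeedHit


def hit(cid):
    return SeedHit(cid, "g", 100.0, 100.0, 500)


def direct_repeat_graph(u1_depth=30.0, u2_depth=30.0, r_depth=60.0):
    """U1 and U2 single-copy, R twice: the canonical direct-repeat wiring."""
    return make_graph(
        [("U1", 100, u1_depth), ("U2", 80, u2_depth), ("R", 20, r_depth)],
        [
            ("U1", TAIL, "R", HEAD, 30),
            ("R", TAIL, "U2", HEAD, 30),
            ("U2", TAIL, "R", HEAD, 30),
            ("R", TAIL, "U1", HEAD, 30),
        ],
    )


def inverted_repeat_graph():
    return make_graph(
        [("U1", 100, 30.0), ("U2", 80, 30.0), ("R", 20, 60.0)],
        [
            ("U1", TAIL, "R", HEAD, 30),
            ("R", TAIL, "U2", HEAD, 30),
            ("U2", TAIL, "R", TAIL, 30),
            ("R", HEAD, "U1", HEAD, 30),
        ],
    )


class TestTargetSelection:
    def test_median_spread_gate(self):
        g = make_graph(
            [("a", 10, 29.0), ("b", 10, 30.0), ("c", 10, 31.0), ("d", 10, 300.0),
             ("x", 10, 300.0)],
        )
        hits = [hit("a"), hit("b"), hit("c"), hit("d")]
        out, med = select_target_contigs(g, hits, spread=4.0)
        assert med == pytest.approx(30.5)
        assert "x" not in out.contigs       # non-hit at 300 > 4 x median
        assert "d" in out.contigs           # hit contigs exempt

    def test_equal_depths_remove_nothing(self):
        g = make_graph([("a", 10, 30.0), ("b", 10, 30.0)])
        out, med = select_target_contigs(g, [hit("a")])
        assert set(out.contigs) == {"a", "b"} and med == 30.0

    def test_single_hit_contig_median_is_its_depth(self):
        g = make_graph([("a", 10, 42.0)])
        _, med = select_target_contigs(g, [hit("a")])
        assert med == 42.0

    def test_no_hit_contigs_directs_to_manual_seeding(self):
        g = make_graph([("a", 10, 30.0)])
        with pytest.raises(NoSeedsError, match="graphBuild"):
            select_target_contigs(g, [])


class TestCopyNumbers:
    def test_depth_rounding_without_links(self):
        g = make_graph([("a", 10, 30.0), ("b", 10, 29.0), ("c", 10, 61.0)])
        cnt = estimate_copy_numbers(g, 30.0)
        assert cnt.copies == {"a": 1, "b": 1, "c": 2}

    def test_low_depth_floors_at_one(self):
        g = make_graph([("a", 10, 10.0)])
        assert estimate_copy_numbers(g, 30.0).copies == {"a": 1}

    def test_degree_raises_underestimated_repeat(self):
        # depth ratio 1.4 but two distinct links on each end: raised to 2
        g = direct_repeat_graph(r_depth=42.0)
        cnt = estimate_copy_numbers(g, 30.0)
        assert cnt.copies["R"] == 2

    def test_degree_caps_depth_stacked_insertion(self):
        # MTPT-like contig: mito+plastid depths stack to ~6x baseline but a
        # single link per end means a single pass through it
        g = make_graph(
            [("a", 10, 30.0), ("m", 10, 180.0), ("b", 10, 30.0)],
            [("a", TAIL, "m", HEAD, 30), ("m", TAIL, "b", HEAD, 30)],
        )
        assert estimate_copy_numbers(g, 30.0).copies["m"] == 1

    def test_self_linked_tandem_keeps_depth_estimate(self):
        g = make_graph(
            [("u", 10, 30.0), ("r", 10, 90.0)],
            [("u", TAIL, "r", HEAD, 30), ("r", TAIL, "r", HEAD, 30),
             ("r", TAIL, "u", HEAD, 30)],
        )
        assert estimate_copy_numbers(g, 30.0).copies["r"] == 3


class TestEnumeration:
    def test_single_self_circular_contig_one_conformation(self):
        g = make_graph([("a", 50, 30.0)], [("a", HEAD, "a", TAIL, 20)])
        confs = enumerate_conformations(g, CopyNumberTable({"a": 1}, 30.0))
        assert len(confs) == 1
        assert confs[0].cycles == [[("a", "+")]]

    def test_direct_repeat_master_plus_subcircles(self):
        g = direct_repeat_graph()
        cnt = CopyNumberTable({"U1": 1, "U2": 1, "R": 2}, 30.0)
        confs = enumerate_conformations(g, cnt)
        assert len(confs) == 2
        by_cycles = sorted(confs, key=lambda c: len(c.cycles))
        master, decomp = by_cycles
        assert [len(c) for c in master.cycles] == [4]       # U1 R U2 R
        assert sorted(len(c) for c in decomp.cycles) == [2, 2]  # {U1 R} + {U2 R}
        for conf in confs:
            validate_conformation(conf, g, cnt)

    def test_inverted_repeat_two_single_circle_isomers(self):
        g = inverted_repeat_graph()
        cnt = CopyNumberTable({"U1": 1, "U2": 1, "R": 2}, 30.0)
        confs = enumerate_conformations(g, cnt)
        assert len(confs) == 2
        assert all(len(c.cycles) == 1 for c in confs)
        # the two isomers differ by reversal of the U2 segment
        strands = sorted(
            tuple(o for cid, o in conf.cycles[0] if cid == "U2") for conf in confs
        )
        assert strands == [("+",), ("-",)]

    def test_disconnected_copies_have_no_cover(self):
        g = make_graph([("a", 10, 30.0), ("b", 10, 30.0)])
        confs = enumerate_conformations(g, CopyNumberTable({"a": 1, "b": 1}, 30.0))
        assert confs == []

    def test_master_listed_before_decompositions(self):
        g = direct_repeat_graph()
        cnt = CopyNumberTable({"U1": 1, "U2": 1, "R": 2}, 30.0)
        confs = enumerate_conformations(g, cnt)
        assert len(confs[0].cycles) == 1

    def test_truncation_at_max_out(self, caplog):
        g = direct_repeat_graph()
        cnt = CopyNumberTable({"U1": 1, "U2": 1, "R": 2}, 30.0)
        with caplog.at_level("WARNING"):
            confs = enumerate_conformations(g, cnt, max_out=1)
        assert len(confs) == 1
        assert any("truncated" in r.message for r in caplog.records)


class TestCanonicalisation:
    def test_rotation_invariance(self):
        cyc = [("a", "+"), ("b", "-"), ("c", "+")]
        assert canonical_cycle(cyc) == canonical_cycle(cyc[1:] + cyc[:1])

    def test_reverse_complement_invariance(self):
        cyc = [("a", "+"), ("b", "-"), ("c", "+")]
        rc = [("c", "-"), ("b", "+"), ("a", "-")]
        assert canonical_cycle(cyc) == canonical_cycle(rc)

    def test_conformation_ignores_cycle_order(self):
        c1, c2 = [("a", "+")], [("b", "-")]
        assert canonical_conformation([c1, c2]) == canonical_conformation([c2, c1])


class TestOracleEquivalence:
    def test_enumerator_matches_slot_matching_oracle(self):
        rng = random.Random(20260930)
        for _ in range(40):
            g, copies = random_conformation_graph(rng)
            got = {
                conf.canonical()
                for conf in enumerate_conformations(
                    g, CopyNumberTable(copies, 10.0), max_out=100_000
                )
            }
            want = brute_force_cycle_covers(g, copies)
            assert got == want


class TestExport:
    def seq_graph(self):
        rng = random.Random(9)
        seqs = {
            "U1": random_dna(rng, 10_000),
            "R": random_dna(rng, 2_000),
            "U2": random_dna(rng, 8_000),
        }
        g = make_graph(
            [(cid, len(s), 30.0 if cid != "R" else 60.0, s) for cid, s in seqs.items()],
            [
                ("U1", TAIL, "R", HEAD, 30),
                ("R", TAIL, "U2", HEAD, 30),
                ("U2", TAIL, "R", HEAD, 30),
                ("R", TAIL, "U1", HEAD, 30),
            ],
        )
        return g, seqs

    def test_cycle_length_is_sum_of_contig_lengths(self, tmp_path):
        g, seqs = self.seq_graph()
        cnt = CopyNumberTable({"U1": 1, "U2": 1, "R": 2}, 30.0)
        confs = enumerate_conformations(g, cnt)
        master = confs[0]
        seq = cycle_sequence(master.cycles[0], g)
        assert len(seq) == 10_000 + 2_000 + 8_000 + 2_000
        df = export_conformations(confs, g, tmp_path)
        assert (tmp_path / "conformation_1.fasta").exists()
        assert (tmp_path / "conformation_1.gfa").exists()
        assert set(df["conformation"]) == {1, 2}

    def test_minus_strand_step_contributes_reverse_complement(self):
        rng = random.Random(10)
        a, b = random_dna(rng, 300), random_dna(rng, 200)
        g = make_graph(
            [("a", 300, 30.0, a), ("b", 200, 30.0, b)],
            [("a", TAIL, "b", TAIL, 30), ("b", HEAD, "a", HEAD, 30)],
        )
        confs = enumerate_conformations(g, CopyNumberTable({"a": 1, "b": 1}, 30.0))
        assert len(confs) == 1
        assert cycle_sequence(confs[0].cycles[0], g) == a + revcomp(b)

    def test_fallback_exports_graph_without_cycles(self, tmp_path, caplog):
        g = make_graph(
            [("a", 10, 30.0, "ACGTACGTAC"), ("b", 12, 30.0, "ACGTACGTACGT")],
            [("a", TAIL, "b", HEAD, 30)],  # dangling ends: no cycle cover
        )
        with caplog.at_level("WARNING"):
            df = export_conformations([], g, tmp_path)
        assert (tmp_path / "fallback_graph.gfa").exists()
        assert not list(tmp_path.glob("conformation_*.fasta"))
        assert not df["circular"].any()
        assert any("conservatively" in r.message for r in caplog.records)

    def test_conformation_referencing_missing_contig_errors(self, tmp_path):
        g, _ = self.seq_graph()
        bad = Conformation([[("nope", "+")]])
        with pytest.raises(GraphError, match="nope"):
            export_conformations([bad], g, tmp_path)

    def test_conservation_every_contig_used_exactly_copies_times(self):
        rng = random.Random(21)
        for _ in range(25):
            g, copies = random_conformation_graph(rng)
            cnt = CopyNumberTable(copies, 10.0)
            for conf in enumerate_conformations(g, cnt, max_out=10_000):
                usage = conf.contig_usage()
                assert all(usage.get(cid, 0) == c for cid, c in copies.items())
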