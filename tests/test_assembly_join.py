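"""Assembly reconstruction and the read-pair joining algorithm."""

import random

import pytest

from orphan_transcripts import (
    ReadPair,
    Transcript,
    build_join_graph,
    greedy_assemble,
    join_transcripts,
    map_pairs_to_transcripts,
    validate_joins,
)
from orphan_transcripts._seq import revcomp
from orphan_transcripts.assembly_join import LinkRecord
from orphan_transcripts.synthetic_data import simulate_junction_pairs


def tiling_pairs(seq, read_len=100, step=50):
    """Deterministic error-free reads tiling a sequence end to end."""
    starts = list(range(0, len(seq) - read_len, step)) + [len(seq) - read_len]
    return [
        ReadPair(f"t{i}", seq[s : s + read_len], revcomp(seq[s : s + read_len]),
                 (40,) * read_len, (40,) * read_len)
        for i, s in enumerate(starts)
    ]


def random_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestGreedyAssemble:
    def test_reconstructs_a_single_transcript(self):
        seq = random_seq(400, 1)
        contigs = greedy_assemble(tiling_pairs(seq))
        assert len(contigs) == 1
        assert contigs[0].seq in (seq, revcomp(seq))

    def test_contig_of_exactly_200_is_excluded(self):
        seq = random_seq(200, 2)
        p = ReadPair("a", seq, revcomp(seq), (40,) * 200, (40,) * 200)
        assert greedy_assemble([p]) == []
        seq2 = random_seq(201, 3)
        p2 = ReadPair("b", seq2, revcomp(seq2), (40,) * 201, (40,) * 201)
        assert len(greedy_assemble([p2])) == 1

    def test_two_transcripts_give_two_contigs(self):
        a, b = random_seq(350, 4), random_seq(350, 5)
        contigs = greedy_assemble(tiling_pairs(a) + tiling_pairs(b))
        assert len(contigs) == 2
        rec = {min(c.seq, revcomp(c.seq)) for c in contigs}
        assert rec == {min(a, revcomp(a)), min(b, revcomp(b))}

    def test_empty_input(self):
        assert greedy_assemble([]) == []

    def test_min_overlap_floor(self):
        with pytest.raises(ValueError):
            greedy_assemble([], min_overlap=8)


def fragments_of(seq, cuts):
    bounds = [0] + cuts + [len(seq)]
    return [seq[s:e] for s, e in zip(bounds, bounds[1:])]


def bridging_pairs(seq, junction, n, read_len=100, insert=300, prefix="j"):
    pairs = []
    for i in range(n):
        s = junction - insert + read_len + (i % (insert - 2 * read_len + 1))
        frag = seq[s : s + insert]
        pairs.append(
            ReadPair(f"{prefix}{junction}_{i}", frag[:read_len], revcomp(frag[-read_len:]),
                     (40,) * read_len, (40,) * read_len)
        )
    return pairs


class TestMapPairs:
    def setup_method(self):
        self.seq = random_seq(900, 10)
        self.frags = fragments_of(self.seq, [450])
        self.transcripts = [Transcript(id=f"t{i}", seq=f) for i, f in enumerate(self.frags)]

    def test_bridging_pair_links_two_transcripts(self):
        links = map_pairs_to_transcripts(bridging_pairs(self.seq, 450, 6), self.transcripts)
        assert len(links) == 6
        assert {(l.transcript_a, l.transcript_b) for l in links} == {("t0", "t1")}

    def test_same_transcript_pair_makes_no_link(self):
        frag = self.seq[100:400]
        p = ReadPair("p", frag[:100], revcomp(frag[-100:]), (40,) * 100, (40,) * 100)
        assert map_pairs_to_transcripts([p], self.transcripts) == []

    def test_unmappable_mate_makes_no_link(self):
        p = ReadPair("p", "A" * 100, revcomp(self.seq[500:600]), (40,) * 100, (40,) * 100)
        assert map_pairs_to_transcripts([p], self.transcripts) == []

    def test_ambiguous_mate_is_skipped(self):
        twins = [Transcript(id="a", seq=self.frags[0]), Transcript(id="b", seq=self.frags[0]),
                 Transcript(id="c", seq=self.frags[1])]
        links = map_pairs_to_transcripts(bridging_pairs(self.seq, 450, 4), twins)
        assert links == []


class TestBuildJoinGraph:
    def make_links(self, n, flip=0):
        links = []
        for i in range(n):
            sa, sb = ("+", "-") if i >= flip else ("-", "+")
            links.append(LinkRecord(f"p{i}", "a", "b", "3p", "5p", sa, sb))
        return links

    def test_six_supporting_pairs_make_an_edge(self):
        g = build_join_graph(self.make_links(6), min_support=5)
        assert ("a", "b") in g.edges and g.edges[("a", "b")].support == 6

    def test_exactly_five_pairs_make_no_edge(self):
        g = build_join_graph(self.make_links(5), min_support=5)
        assert g.edges == {}

    def test_duplicate_pair_ids_count_once(self):
        links = self.make_links(6)
        links.append(links[0])
        g = build_join_graph(links[:5] + [links[0]], min_support=5)
        assert g.edges == {}

    def test_orientation_tie_drops_edge(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_join_graph(self.make_links(6, flip=3), min_support=5)
        assert g.edges == {} and "orientation tie" in caplog.text

    @pytest.mark.parametrize("low,high", [(0, 3), (3, 7), (5, 6)])
    def test_support_threshold_is_monotone(self, low, high):
        links = self.make_links(7)
        edges_low = set(build_join_graph(links, min_support=low).edges)
        edges_high = set(build_join_graph(links, min_support=high).edges)
        assert edges_high <= edges_low


class TestJoinTranscripts:
    def chain_fixture(self, n_members=3, seed=20, n_pairs=7):
        seq = random_seq(300 * n_members, seed)
        cuts = [300 * i for i in range(1, n_members)]
        frags = fragments_of(seq, cuts)
        transcripts = [Transcript(id=f"m{i}", seq=f) for i, f in enumerate(frags)]
        pairs = []
        for c in cuts:
            pairs.extend(bridging_pairs(seq, c, n_pairs))
        return seq, transcripts, pairs

    def test_chain_of_three_joins_in_order(self):
        seq, transcripts, pairs = self.chain_fixture()
        graph = build_join_graph(map_pairs_to_transcripts(pairs, transcripts))
        joined = join_transcripts(graph, transcripts)
        multi = [t for t in joined if len(t.members) > 1]
        assert len(multi) == 1
        assert multi[0].members in (["m0", "m1", "m2"], ["m2", "m1", "m0"])
        assert validate_joins(joined, {"truth": seq}) == 1.0
        # the joined sequence carries the 50-N spacer between members
        assert "N" * 50 in multi[0].seq

    def test_empty_graph_is_identity(self):
        from orphan_transcripts.assembly_join import JoinGraph

        transcripts = [Transcript(id="x", seq=random_seq(250, 1))]
        assert join_transcripts(JoinGraph(), transcripts) == transcripts

    def test_star_component_is_left_unjoined(self, caplog):
        seq = random_seq(1200, 30)
        frags = fragments_of(seq, [300, 600, 900])
        transcripts = [Transcript(id=f"s{i}", seq=f) for i, f in enumerate(frags)]
        links = []
        for i, other in enumerate(("s1", "s2", "s3")):
            for j in range(6):
                links.append(LinkRecord(f"x{i}_{j}", "s0", other, "3p", "5p", "+", "-"))
        graph = build_join_graph(links)
        with caplog.at_level("WARNING"):
            joined = join_transcripts(graph, transcripts)
        assert all(len(t.members) == 1 for t in joined)
        assert "branch or cycle" in caplog.text

    def test_join_is_a_fixed_point(self):
        seq, transcripts, pairs = self.chain_fixture()
        graph = build_join_graph(map_pairs_to_transcripts(pairs, transcripts))
        joined = join_transcripts(graph, transcripts)
        links2 = map_pairs_to_transcripts(pairs, joined)
        graph2 = build_join_graph(links2)
        assert graph2.edges == {}
        assert join_transcripts(graph2, joined) == joined

    def test_result_invariant_under_id_relabeling(self):
        seq, transcripts, pairs = self.chain_fixture()
        relabeled = [Transcript(id=f"zz{9 - i}", seq=t.seq) for i, t in enumerate(transcripts)]
        g1 = build_join_graph(map_pairs_to_transcripts(pairs, transcripts))
        g2 = build_join_graph(map_pairs_to_transcripts(pairs, relabeled))
        j1 = join_transcripts(g1, transcripts)
        j2 = join_transcripts(g2, relabeled)
        seqs1 = sorted(min(t.seq, revcomp(t.seq)) for t in j1)
        seqs2 = sorted(min(t.seq, revcomp(t.seq)) for t in j2)
        assert seqs1 == seqs2


class TestValidateJoins:
    def test_no_joins_is_vacuously_correct(self):
        assert validate_joins([Transcript(id="a", seq="ACGT" * 60)], {"t": "A" * 500}) == 1.0

    def test_shuffled_member_order_counts_incorrect(self):
        seq = random_seq(900, 40)
        frags = fragments_of(seq, [300, 600])
        good = Transcript(id="g", seq=("N" * 50).join(frags), members=["a", "b", "c"],
                          member_seqs=list(frags))
        bad_order = [frags[1], frags[0], frags[2]]
        bad = Transcript(id="b", seq=("N" * 50).join(bad_order), members=["b", "a", "c"],
                         member_seqs=bad_order)
        assert validate_joins([good], {"t": seq}) == 1.0
        assert validate_joins([bad], {"t": seq}) == 0.0
        assert validate_joins([good, bad], {"t": seq}) == 0.5

    def test_reverse_complement_chain_is_correct(self):
        seq = random_seq(600, 41)
        frags = fragments_of(seq, [300])
        rc_members = [revcomp(frags[1]), revcomp(frags[0])]
        t = Transcript(id="r", seq=("N" * 50).join(rc_members), members=["b", "a"],
                       member_seqs=rc_members)
        assert validate_joins([t], {"t": seq}) == 1.0


def test_junction_pairs_from_world_support_their_junctions(world):
    """World-planted chains reassemble from their own bridging evidence."""
    tid = next(t for t in sorted(world.planted) if len(world.planted[t].fragments) == 3)
    planted = world.planted[tid]
    transcripts = [
        Transcript(id=f"{tid}.f{i}", seq=planted.seq[s:e])
        for i, (s, e) in enumerate(planted.fragments)
    ]
    pairs = simulate_junction_pairs(world, tid, n_per_junction=8, seed=6)
    graph = build_join_graph(map_pairs_to_transcripts(pairs, transcripts))
    joined = join_transcripts(graph, transcripts)
    assert validate_joins(joined, world.truth_sequences) == 1.0
    assert sum(len(t.members) > 1 for t in joined) == 1
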