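"""Discordant-pair pairing, clustering, validation, TSD/strand inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltrburst.annotation import TEAnnotation
from ltrburst.caller import (
    DiscordantPair,
    InsertionCall,
    InsertionCluster,
    classify_location,
    cluster_reads,
    detect_tsd,
    filter_calls,
    find_discordant,
    find_hairpins,
    find_nested,
    infer_site,
    infer_strand_and_ltr,
    split_cluster,
    validate_cluster,
)
from ltrburst.records import AlignedRead


def g_read(name, start, strand, contig="chr1", length=100, left_clip=0, right_clip=0, read1=True):
    cigar = []
    if left_clip:
        cigar.append(("S", left_clip))
    cigar.append(("M", length))
    if right_clip:
        cigar.append(("S", right_clip))
    n = length + left_clip + right_clip
    return AlignedRead(name, contig, start, strand, cigar, "A" * n, read1)


def t_read(name, start=100, strand="-", read1=False):
    return AlignedRead(name, "TE", start, strand, [("M", 100)], "A" * 100, read1)


def pair(name, gstart, gstrand, te_strand="-", **kw):
    return DiscordantPair(
        name, g_read(name, gstart, gstrand, **kw), t_read(name, strand=te_strand)
    )


def make_cluster(strands, starts=None, te_strands=None):
    starts = starts or [i * 10 for i in range(len(strands))]
    te_strands = te_strands or [("-" if s == "+" else "+") for s in strands]
    pairs = [
        pair(f"p{i}", starts[i], strands[i], te_strand=te_strands[i])
        for i in range(len(strands))
    ]
    return InsertionCluster(contig="chr1", pairs=pairs)


ANNOT = TEAnnotation(
    te_name="TE",
    te_length=5000,
    ltr_length=400,
    masked=(4700, 4800),
    ref_contig="chr1",
    ref_span=(20_000, 25_000),
    depth_interval=(20_400, 24_600),
    flanks=((9_000, 19_000), (26_000, 36_000)),
    pericentromeres={"chr1": [(40_000, 60_000)]},
)


class TestFindDiscordant:
    def test_one_mate_each_reference_is_retained(self):
        g = [g_read("a", 100, "+", read1=True)]
        t = [t_read("a", read1=False)]
        pairs, stats = find_discordant(g, t)
        assert len(pairs) == 1 and stats["discordant"] == 1

    def test_both_mates_on_genome_not_discordant(self):
        g = [g_read("a", 100, "+", read1=True), g_read("a", 400, "-", read1=False)]
        pairs, _ = find_discordant(g, [])
        assert pairs == []

    def test_read_on_both_references_discards_whole_pair(self):
        g = [g_read("a", 100, "+", read1=True), g_read("a", 400, "-", read1=False)]
        t = [t_read("a", read1=True)]  # read1 maps to both -> pair dropped
        pairs, stats = find_discordant(g, t)
        assert pairs == [] and stats["both_refs_discarded"] == 1

    def test_unpaired_records_are_counted(self):
        pairs, stats = find_discordant([g_read("solo", 5, "+")], [])
        assert pairs == [] and stats["unpaired_skipped"] == 1


class TestClustering:
    def test_reads_within_gap_share_cluster(self):
        pairs = [pair(f"p{i}", 100 + i * 50, "+") for i in range(6)]
        clusters = cluster_reads(pairs, max_gap=700)
        assert len(clusters) == 1 and len(clusters[0].pairs) == 6

    def test_gap_splits_clusters(self):
        pairs = [pair("a", 0, "+"), pair("b", 100, "+"), pair("c", 5000, "+")]
        clusters = cluster_reads(pairs, max_gap=700)
        assert [len(c.pairs) for c in clusters] == [2, 1]

    def test_contigs_never_share_clusters(self):
        pairs = [pair("a", 0, "+"), DiscordantPair("b", g_read("b", 10, "+", contig="chr2"), t_read("b"))]
        clusters = cluster_reads(pairs, max_gap=700)
        assert len(clusters) == 2


class TestValidation:
    def test_three_up_three_down_valid(self):
        c = validate_cluster(make_cluster(list("+++---")))
        assert c.valid and (c.m, c.n) == (3, 3)

    def test_two_five_split_invalid(self):
        assert not validate_cluster(make_cluster(list("++-----"))).valid

    def test_interleaved_directions_invalid(self):
        assert not validate_cluster(make_cluster(list("+-+-+-"))).valid

    def test_wrong_order_invalid(self):
        assert not validate_cluster(make_cluster(list("---+++"))).valid

    @given(st.lists(st.sampled_from("+-"), min_size=1, max_size=12))
    @settings(max_examples=300, derandomize=True)
    def test_validity_matches_prefix_suffix_oracle(self, strands):
        """Brute force: some split m >= 3, n >= 3 with all '+' before and
        all '-' after, covering the whole cluster."""
        oracle = any(
            all(s == "+" for s in strands[:m]) and all(s == "-" for s in strands[m:])
            for m in range(3, len(strands) - 2)
        )
        assert validate_cluster(make_cluster(strands)).valid == oracle

    def test_split_cluster_recovers_two_insertions(self):
        c = make_cluster(list("+++---+++---"))
        subs = [validate_cluster(s) for s in split_cluster(c)]
        assert len(subs) == 2 and all(s.valid for s in subs)


class TestSiteAndTsd:
    def test_disjoint_boundary_reads(self):
        c = validate_cluster(
            make_cluster(list("+++---"), starts=[700, 800, 900, 1005, 1100, 1200])
        )
        # m-th read ends 900+100=1000; (m+1)-st starts 1005
        assert infer_site(c) == (1000, 1005, 0)
        assert detect_tsd(c) is None

    def test_overlapping_boundary_reads_give_overlap(self):
        c = validate_cluster(
            make_cluster(list("+++---"), starts=[700, 800, 900, 996, 1100, 1200])
        )
        start, end, overlap = infer_site(c)
        assert (start, end, overlap) == (996, 1000, 4)

    def test_tsd_requires_soft_clip_pattern(self):
        pairs = [
            pair("a", 700, "+"),
            pair("b", 800, "+"),
            DiscordantPair("c", g_read("c", 900, "+", right_clip=50), t_read("c")),
            DiscordantPair("d", g_read("d", 995, "-", left_clip=50), t_read("d", strand="+")),
            pair("e", 1100, "-"),
            pair("f", 1200, "-"),
        ]
        c = validate_cluster(InsertionCluster("chr1", pairs))
        assert detect_tsd(c) == 5  # ends 1000, starts 995 -> overlap 5
        # same geometry without clips: overlap but no TSD call
        c2 = validate_cluster(
            make_cluster(list("+++---"), starts=[700, 800, 900, 995, 1100, 1200])
        )
        assert infer_site(c2)[2] == 5 and detect_tsd(c2) is None

    def test_tsd_overlap_of_eight(self):
        pairs = [
            pair("a", 700, "+"),
            pair("b", 800, "+"),
            DiscordantPair("c", g_read("c", 900, "+", right_clip=30), t_read("c")),
            DiscordantPair("d", g_read("d", 992, "-", left_clip=30), t_read("d", strand="+")),
            pair("e", 1100, "-"),
            pair("f", 1200, "-"),
        ]
        assert detect_tsd(validate_cluster(InsertionCluster("chr1", pairs))) == 8


class TestStrandAndLtr:
    def test_sense_insertion_labels(self):
        # genome + with te - (and genome - with te +) -> sense
        c = validate_cluster(make_cluster(list("+++---")))
        strand, labels = infer_strand_and_ltr(c)
        assert strand == "+"
        assert [labels[f"p{i}"] for i in range(6)] == ["5p"] * 3 + ["3p"] * 3

    def test_antisense_insertion_swaps_labels(self):
        c = validate_cluster(
            make_cluster(list("+++---"), te_strands=list("+++---"))
        )
        strand, labels = infer_strand_and_ltr(c)
        assert strand == "-"
        assert [labels[f"p{i}"] for i in range(6)] == ["3p"] * 3 + ["5p"] * 3

    def test_mixed_orientations_ambiguous(self):
        c = validate_cluster(
            make_cluster(list("+++---"), te_strands=list("-+-+-+"))
        )
        strand, labels = infer_strand_and_ltr(c)
        assert strand == "ambiguous"
        assert all(v is None for v in labels.values())


def make_call(start=100, end=None, up=3, down=3, contig="chr1"):
    return InsertionCall(
        contig=contig,
        start=start,
        end=end if end is not None else start + 5,
        overlap=0,
        tsd=None,
        strand="+",
        support_up=up,
        support_down=down,
    )


class TestLocationAndFilter:
    def test_location_classes(self):
        assert classify_location(make_call(50_000, 50_005), ANNOT.pericentromeres) == "pericentromeric"
        assert classify_location(make_call(1_000, 1_005), ANNOT.pericentromeres) == "arm"
        assert classify_location(make_call(10, 15, contig="chrX"), ANNOT.pericentromeres) == "arm"

    def test_arm_proportion_summary(self):
        calls = [make_call(1000), make_call(2000), make_call(3000), make_call(50_000)]
        locs = [classify_location(c, ANNOT.pericentromeres) for c in calls]
        assert locs.count("arm") / len(locs) == 0.75

    def test_filter_boundaries(self):
        assert filter_calls([make_call(up=3, down=3)]) != []
        assert filter_calls([make_call(up=2, down=4)]) == []
        assert filter_calls([]) == []


def inverted_te_pair(name, pos_a, pos_b, strand="+"):
    return [
        AlignedRead(name, "TE", pos_a, strand, [("M", 100)], "A" * 100, True),
        AlignedRead(name, "TE", pos_b, strand, [("M", 100)], "A" * 100, False),
    ]


def proper_te_pair(name, pos_a, pos_b):
    return [
        AlignedRead(name, "TE", pos_a, "+", [("M", 100)], "A" * 100, True),
        AlignedRead(name, "TE", pos_b, "-", [("M", 100)], "A" * 100, False),
    ]


class TestNestedAndHairpins:
    def test_two_mates_each_ltr_is_confident(self):
        reads = (
            inverted_te_pair("a", 100, 2000)  # mate on 5' LTR
            + inverted_te_pair("b", 150, 2100)
            + inverted_te_pair("c", 4700, 2000)  # mate on 3' LTR
            + inverted_te_pair("d", 4650, 2100)
        )
        rep = find_nested(reads, ANNOT)
        assert rep.status == "Y" and rep.counts == {"5p": 2, "3p": 2}

    def test_single_mate_is_lowercase_y(self):
        rep = find_nested(inverted_te_pair("a", 100, 2000), ANNOT)
        assert rep.status == "y"

    def test_one_mate_per_ltr_below_threshold(self):
        reads = inverted_te_pair("a", 100, 2000) + inverted_te_pair("b", 4700, 2100)
        assert find_nested(reads, ANNOT).status == "y"

    def test_no_evidence_is_n(self):
        assert find_nested(proper_te_pair("a", 100, 400), ANNOT).status == "N"

    def test_hairpin_requires_inverted_orientation(self):
        assert find_hairpins(proper_te_pair("a", 100, 200), ANNOT) == []
        assert len(find_hairpins(inverted_te_pair("a", 100, 200), ANNOT)) == 1

    def test_hairpin_requires_both_mates_on_ltr(self):
        assert find_hairpins(inverted_te_pair("a", 100, 2000), ANNOT) == []
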