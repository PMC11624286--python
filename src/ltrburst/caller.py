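"""Calling new element insertions from discordant read mates.

A discordant pair has one mate placed on the genome and the other on the
extracted element sequence.  Genome-side mates near a true non-reference
insertion all point toward the insertion site: sorted by start coordinate,
a valid cluster is a prefix of ``m`` reads pointing toward the contig
3' end followed by a suffix of ``n`` reads pointing toward the 5' end
(``m >= 3``, ``n >= 3``), with a single direction switch.  The insertion
site is the interval between the end of the ``m``-th read and the start of
the ``m+1``-st; when the two boundary reads overlap and are soft-clipped on
their insertion-proximal ends, the overlap length is the target-site
duplication (TSD).

The insertion strand is deduced from the relative orientation of the
element-side mates: for a sense insertion the upstream-border mates
originate from the 5' LTR and the downstream-border mates from the 3' LTR;
reversed for antisense.  Mixed orientations within one border flag the
strand as ambiguous.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ltrburst.annotation import TEAnnotation
from ltrburst.records import AlignedRead

logger = logging.getLogger(__name__)


@dataclass
class DiscordantPair:
    name: str
    genome: AlignedRead
    te: AlignedRead

    @property
    def direction(self) -> str:
        """'3p' if the genome mate points toward the contig 3' end else '5p'."""
        return "3p" if self.genome.strand == "+" else "5p"


@dataclass
class InsertionCluster:
    contig: str
    pairs: list[DiscordantPair]  # sorted by genome-mate start
    m: int = 0
    n: int = 0
    valid: bool = False
    reason: str = ""


@dataclass
class InsertionCall:
    contig: str
    start: int  # 0-based half-open site interval on the genome
    end: int
    overlap: int  # boundary-read overlap length (0 when reads do not overlap)
    tsd: int | None
    strand: str  # '+', '-' or 'ambiguous'
    support_up: int
    support_down: int
    ltr_labels: dict[str, str | None] = field(default_factory=dict)  # pair -> 5p/3p
    location: str = ""
    pairs: list[DiscordantPair] = field(default_factory=list)

    @property
    def site(self) -> int:
        """Point estimate of the insertion site (interval start)."""
        return self.start


def find_discordant(
    genome_alignments: Iterable[AlignedRead],
    te_alignments: Iterable[AlignedRead],
) -> tuple[list[DiscordantPair], dict[str, int]]:
    """Pair genome-side with element-side mates by read name.

    A pair is discordant iff exactly one mate maps (only) to the genome and
    the other (only) to the element.  Any read mapping to both references
    discards its whole pair; unpaired records are skipped and tallied.
    """
    gmap: dict[tuple[str, bool], AlignedRead] = {}
    tmap: dict[tuple[str, bool], AlignedRead] = {}
    for r in genome_alignments:
        gmap[(r.name, r.is_read1)] = r
    for r in te_alignments:
        tmap[(r.name, r.is_read1)] = r

    stats = {"both_refs_discarded": 0, "unpaired_skipped": 0, "discordant": 0}
    names = {n for n, _ in gmap} | {n for n, _ in tmap}
    pairs: list[DiscordantPair] = []
    for name in sorted(names):
        keys = [(name, True), (name, False)]
        if any(k in gmap and k in tmap for k in keys):
            stats["both_refs_discarded"] += 1
            continue
        g = [gmap[k] for k in keys if k in gmap]
        t = [tmap[k] for k in keys if k in tmap]
        if len(g) == 1 and len(t) == 1:
            pairs.append(DiscordantPair(name=name, genome=g[0], te=t[0]))
            stats["discordant"] += 1
        elif len(g) + len(t) == 1:
            stats["unpaired_skipped"] += 1
    if stats["unpaired_skipped"]:
        logger.info("skipped %d unpaired records", stats["unpaired_skipped"])
    return pairs, stats


def cluster_reads(
    pairs: Sequence[DiscordantPair], max_gap: int = 700
) -> list[InsertionCluster]:
    """Group genome-side mates by contig and start proximity.

    Successive mates on the same contig whose start coordinates differ by
    at most ``max_gap`` share a cluster.
    """
    ordered = sorted(pairs, key=lambda p: (p.genome.ref, p.genome.start))
    clusters: list[InsertionCluster] = []
    for p in ordered:
        if (
            clusters
            and clusters[-1].contig == p.genome.ref
            and p.genome.start - clusters[-1].pairs[-1].genome.start <= max_gap
        ):
            clusters[-1].pairs.append(p)
        else:
            clusters.append(InsertionCluster(contig=p.genome.ref, pairs=[p]))
    return clusters


def _direction_runs(cluster: InsertionCluster) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for p in cluster.pairs:
        d = p.direction
        if runs and runs[-1][0] == d:
            runs[-1] = (d, runs[-1][1] + 1)
        else:
            runs.append((d, 1))
    return runs


def validate_cluster(
    cluster: InsertionCluster, min_support: int = 3
) -> InsertionCluster:
    """Flag a cluster valid iff it splits into m 3'-pointing then n
    5'-pointing reads with a single direction switch and m, n >= 3."""
    runs = _direction_runs(cluster)
    if len(runs) != 2 or runs[0][0] != "3p" or runs[1][0] != "5p":
        cluster.valid = False
        cluster.reason = "direction pattern"
        return cluster
    m, n = runs[0][1], runs[1][1]
    cluster.m, cluster.n = m, n
    if m < min_support or n < min_support:
        cluster.valid = False
        cluster.reason = f"support ({m},{n})"
        return cluster
    cluster.valid = True
    cluster.reason = ""
    return cluster


def split_cluster(cluster: InsertionCluster) -> list[InsertionCluster]:
    """Split a multi-switch cluster into consecutive (3'-run, 5'-run) pairs.

    Two nearby insertions produce a + - + - direction sequence within one
    proximity cluster; each (3p run, 5p run) couple becomes a candidate.
    Leading 5'-runs and trailing 3'-runs cannot support a site on their own
    and are dropped (logged).
    """
    runs = _direction_runs(cluster)
    if len(runs) <= 2:
        return [cluster]
    out: list[InsertionCluster] = []
    idx = 0
    i = 0
    while i < len(runs):
        if runs[i][0] == "3p" and i + 1 < len(runs) and runs[i + 1][0] == "5p":
            size = runs[i][1] + runs[i + 1][1]
            out.append(
                InsertionCluster(
                    contig=cluster.contig, pairs=cluster.pairs[idx : idx + size]
                )
            )
            idx += size
            i += 2
        else:
            logger.info(
                "dropping %d reads in unpaired direction run on %s",
                runs[i][1],
                cluster.contig,
            )
            idx += runs[i][1]
            i += 1
    return out


def infer_site(cluster: InsertionCluster) -> tuple[int, int, int]:
    """Site interval between the m-th read end and the (m+1)-st read start.

    Returns ``(start, end, overlap)`` with 0-based half-open bounds.  When
    the boundary reads overlap (end of the m-th past the start of the
    m+1-st) the interval is the overlapped stretch and ``overlap`` is its
    length — the TSD candidate.
    """
    if not cluster.valid:
        raise ValueError("site inference requires a valid cluster")
    up_end = cluster.pairs[cluster.m - 1].genome.end
    down_start = cluster.pairs[cluster.m].genome.start
    if up_end >= down_start:
        return (down_start, up_end, up_end - down_start)
    return (up_end, down_start, 0)


def detect_tsd(cluster: InsertionCluster) -> int | None:
    """TSD length from the boundary reads' soft-clips, or None.

    Present iff the m-th read is soft-clipped on its insertion-proximal
    (reference-right) end, the m+1-st on its insertion-proximal
    (reference-left) end, and the two aligned spans overlap; the overlap
    length is the TSD size.
    """
    start, end, overlap = infer_site(cluster)
    if overlap <= 0:
        return None
    up = cluster.pairs[cluster.m - 1].genome
    down = cluster.pairs[cluster.m].genome
    if up.right_clip > 0 and down.left_clip > 0:
        return overlap
    return None


def infer_strand_and_ltr(
    cluster: InsertionCluster,
) -> tuple[str, dict[str, str | None]]:
    """Insertion strand and per-pair LTR-of-origin from mate orientations.

    A pair whose genome and element mates map on opposite strands reflects
    a sense insertion; equal strands an antisense one.  All pairs must
    agree, otherwise the strand is 'ambiguous' and no labels are assigned.
    For a sense insertion the upstream border is fed by the 5' LTR and the
    downstream border by the 3' LTR; swapped for antisense.
    """
    if not cluster.valid:
        raise ValueError("strand inference requires a valid cluster")
    votes = {
        p.name: ("+" if p.genome.strand != p.te.strand else "-")
        for p in cluster.pairs
    }
    distinct = set(votes.values())
    if len(distinct) != 1:
        return "ambiguous", {p.name: None for p in cluster.pairs}
    strand = distinct.pop()
    labels: dict[str, str | None] = {}
    for i, p in enumerate(cluster.pairs):
        upstream = i < cluster.m
        if strand == "+":
            labels[p.name] = "5p" if upstream else "3p"
        else:
            labels[p.name] = "3p" if upstream else "5p"
    return strand, labels


def classify_location(
    call: InsertionCall, pericentromeres: Mapping[str, Sequence[tuple[int, int]]]
) -> str:
    """'pericentromeric' iff the site midpoint falls in an annotated
    interval, else 'arm' (contigs absent from the annotation are arms)."""
    mid = (call.start + call.end) // 2
    if call.contig not in pericentromeres:
        logger.info("contig %s absent from pericentromere annotation", call.contig)
        return "arm"
    for s, e in pericentromeres[call.contig]:
        if s <= mid < e:
            return "pericentromeric"
    return "arm"


def filter_calls(
    calls: Sequence[InsertionCall], min_support_per_border: int = 3
) -> list[InsertionCall]:
    """Retain calls supported by >= ``min_support_per_border`` discordant
    mates at both borders."""
    return [
        c
        for c in calls
        if c.support_up >= min_support_per_border
        and c.support_down >= min_support_per_border
    ]


def call_insertions(
    genome_alignments: Iterable[AlignedRead],
    te_alignments: Iterable[AlignedRead],
    annotation: TEAnnotation | None = None,
    max_gap: int = 700,
    min_support_per_border: int = 3,
    split_clusters: bool = True,
) -> tuple[list[InsertionCall], dict[str, int]]:
    """Full discordant-pair pipeline: pair, cluster, validate, call.

    When two retained calls claim overlapping site intervals on one contig
    the better-supported one wins (ties: the leftmost); the loser is logged.
    """
    pairs, stats = find_discordant(genome_alignments, te_alignments)
    clusters = cluster_reads(pairs, max_gap=max_gap)
    if split_clusters:
        clusters = [sub for c in clusters for sub in split_cluster(c)]
    calls: list[InsertionCall] = []
    stats["clusters"] = len(clusters)
    stats["invalid_clusters"] = 0
    for cluster in clusters:
        validate_cluster(cluster, min_support=min_support_per_border)
        if not cluster.valid:
            stats["invalid_clusters"] += 1
            logger.info(
                "discarded cluster on %s (%d reads): %s",
                cluster.contig,
                len(cluster.pairs),
                cluster.reason,
            )
            continue
        start, end, overlap = infer_site(cluster)
        strand, labels = infer_strand_and_ltr(cluster)
        call = InsertionCall(
            contig=cluster.contig,
            start=start,
            end=end,
            overlap=overlap,
            tsd=detect_tsd(cluster),
            strand=strand,
            support_up=cluster.m,
            support_down=cluster.n,
            ltr_labels=labels,
            pairs=list(cluster.pairs),
        )
        if annotation is not None:
            call.location = classify_location(call, annotation.pericentromeres)
        calls.append(call)
    calls = filter_calls(calls, min_support_per_border)
    calls = _resolve_site_ties(calls, stats)
    stats["calls"] = len(calls)
    return calls, stats


def _resolve_site_ties(
    calls: list[InsertionCall], stats: dict[str, int]
) -> list[InsertionCall]:
    kept: list[InsertionCall] = []
    dropped = 0
    for call in sorted(
        calls,
        key=lambda c: (-(c.support_up + c.support_down), c.contig, c.start),
    ):
        clash = any(
            k.contig == call.contig and call.start <= k.end and k.start <= call.end
            for k in kept
        )
        if clash:
            dropped += 1
            logger.info(
                "dropping lower-support call at %s:%d-%d", call.contig, call.start, call.end
            )
        else:
            kept.append(call)
    stats["site_tie_dropped"] = dropped
    return sorted(kept, key=lambda c: (c.contig, c.start))


@dataclass
class NestedReport:
    """Occurrence of antisense nested-insertion evidence in one sample.

    ``status``: 'Y' = at least ``min_mates_per_ltr`` qualifying mates at
    each LTR; 'y' = at least one anywhere; 'N' = none.
    """

    status: str
    counts: dict[str, int]
    n_pairs: int


def _te_pairs(te_alignments: Iterable[AlignedRead]):
    by_name: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in te_alignments:
        by_name[r.name].append(r)
    for name, reads in sorted(by_name.items()):
        if len(reads) == 2:
            yield name, reads[0], reads[1]


def find_nested(
    te_alignments: Iterable[AlignedRead],
    annotation: TEAnnotation,
    min_mates_per_ltr: int = 2,
) -> NestedReport:
    """Screen element-side pairs for antisense nested-insertion evidence.

    Qualifying pairs have both mates on the element in the same reference
    orientation (the inverted signature of sequence antisense to itself)
    with at least one mate overlapping an LTR.  Mates are counted per
    overlapped LTR; the status is 'Y' when both LTRs reach the threshold.
    """
    counts = {"5p": 0, "3p": 0}
    n_pairs = 0
    for name, a, b in _te_pairs(te_alignments):
        if a.strand != b.strand:
            continue
        ltrs = [
            annotation.ltr_of_te_position(r.start, r.end) for r in (a, b)
        ]
        hit = [l for l in ltrs if l is not None]
        if not hit:
            continue
        n_pairs += 1
        for l in hit:
            counts[l] += 1
    if counts["5p"] >= min_mates_per_ltr and counts["3p"] >= min_mates_per_ltr:
        status = "Y"
    elif n_pairs >= 1:
        status = "y"
    else:
        status = "N"
    return NestedReport(status=status, counts=counts, n_pairs=n_pairs)


def find_hairpins(
    te_alignments: Iterable[AlignedRead],
    annotation: TEAnnotation,
    max_insert: int = 700,
) -> list[tuple[str, AlignedRead, AlignedRead]]:
    """Pairs with both mates on LTR sequence in inverted relative orientation.

    Evidence of two LTR copies in antisense proximity (a potential hairpin
    template).  Detection is inherently limited by the library insert size
    (``max_insert``): inverted copies farther apart than one insert never
    co-occur in a pair and are invisible to this screen.
    """
    out = []
    for name, a, b in _te_pairs(te_alignments):
        if a.strand != b.strand:  # proper FR pairs are not inverted
            continue
        la = annotation.ltr_of_te_position(a.start, a.end)
        lb = annotation.ltr_of_te_position(b.start, b.end)
        if la is None or lb is None:
            continue
        out.append((name, a, b))
    return out
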