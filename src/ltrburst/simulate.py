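"""Synthetic EM-seq data with planted LTR-retrotransposon insertions.

The simulator builds a miniature multi-contig genome (plus an unmethylated
chloroplast-like control contig), embeds one reference copy of an LTR
element, plants additional insertions with target-site duplications (TSDs)
and random strands, assigns context-dependent methylation levels per region
class, and draws converted paired-end fragments.  Alignment records are
derived from the planted truth rather than an external aligner, but
preserve the record semantics downstream stages consume: reads fully inside
planted elements are placed on the extracted element sequence (or, for
concordant interior pairs, projected onto the reference genomic copy),
reads straddling an element boundary are placed on the genome with the
element-derived portion soft-clipped, and pairs spanning a boundary become
discordant (one mate genome, one mate element).

Multi-mapping suppression is emulated in two places: element-side
placements falling entirely inside the masked 3'-LTR sub-interval are
dropped, and genome-side placements fully contained in an LTR of the
reference copy are dropped (two identical LTRs make them ambiguous).

Coordinates are 0-based half-open throughout; text writers convert.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ltrburst.annotation import TEAnnotation
from ltrburst.methylation import revcomp
from ltrburst.pileup import context_codes, emit_cytosine_report, encode_seq
from ltrburst.records import AlignedRead

logger = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

# region classes for the methylation profile
DEFAULT_PROFILE: dict[str, tuple[float, float, float]] = {
    # (mCG %, mCHG %, mCHH %) per region class; levels emulate euchromatic
    # arms, heterochromatic pericentromeres and a silenced element
    "arm": (15.0, 5.0, 2.0),
    "pericentromere": (80.0, 55.0, 15.0),
    "te_ltr": (85.0, 60.0, 12.0),
    "te_internal": (90.0, 65.0, 10.0),
    "chloroplast": (0.0, 0.0, 0.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic sample.

    ``contig_lengths`` covers every contig including the chloroplast-like
    control (named by ``chloroplast_name``).  ``seed`` drives all
    randomness of the sample; ``genome_seed`` (defaulting to ``seed``)
    drives only the genome sequence, so several samples can share one
    genome while differing in insertions and reads.
    """

    seed: int = 0
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000, "chloro": 10_000}
    )
    chloroplast_name: str = "chloro"
    te_name: str = "TE"
    te_length: int = 5_000
    ltr_length: int = 400
    mask_offset: tuple[int, int] | None = None  # TE coords, inside 3' LTR
    n_insertions: int = 20
    tsd_range: tuple[int, int] = (5, 8)
    strand_prob_plus: float = 0.5
    nested_insertion: bool = False
    nested_spacings: tuple[int, int] = (2562, 1942)
    coverage: float = 30.0
    read_length: int = 150
    insert_size_range: tuple[int, int] = (300, 700)
    conversion_failure: float = 0.001
    methylation_profile: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE)
    )
    # optional overrides / extra structure
    insertion_sites: list[tuple] | None = None  # (contig, site[, strand[, tsd]])
    solo_ltrs: list[tuple[str, int, str]] | None = None
    ltr_profiles: list[tuple[tuple, tuple]] | None = None  # per insertion (5', 3')
    flank_perturbation: tuple[int, tuple[float, float, float]] | None = None
    min_insertion_spacing: int = 2_000
    edge_margin: int = 2_000
    min_anchor: int = 25  # smallest aligned block a local aligner would report
    genome_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.tsd_range
        if not (0 <= lo <= hi <= 50):
            raise ValueError("tsd_range must lie within [0, 50]")
        if not 0.0 <= self.conversion_failure <= 1.0:
            raise ValueError("conversion_failure must lie in [0, 1]")
        if self.insert_size_range[0] > self.insert_size_range[1]:
            raise ValueError("malformed insert_size_range")
        if self.insert_size_range[0] < self.read_length:
            raise ValueError("insert size must be at least one read length")
        prof = self.methylation_profile
        if "chloroplast" not in prof:
            prof["chloroplast"] = (0.0, 0.0, 0.0)
        if any(prof["chloroplast"]):
            raise ValueError("chloroplast profile must be (0, 0, 0)")
        if self.mask_offset is None:
            # a ~quarter-LTR window in the middle of the 3' LTR
            ltr3_start = self.te_length - self.ltr_length
            width = max(self.ltr_length // 4, 10)
            mid = ltr3_start + self.ltr_length // 2
            self.mask_offset = (mid - width // 2, mid - width // 2 + width)
        m0, m1 = self.mask_offset
        if not (self.te_length - self.ltr_length <= m0 < m1 <= self.te_length):
            raise ValueError("mask_offset must lie inside the 3' LTR")

    @property
    def main_contig(self) -> str:
        for name in self.contig_lengths:
            if name != self.chloroplast_name:
                return name
        raise ValueError("no non-chloroplast contig configured")


@dataclass
class Insertion:
    id: int
    contig: str
    site: int  # 0-based position on the original genome
    strand: str
    tsd: int
    kind: str = "full"  # 'full' or 'solo_ltr'
    parent: int | None = None
    ltr_spacings: tuple[int, int] | None = None  # realized, for nested children


@dataclass
class TruthTable:
    insertions: list[Insertion] = field(default_factory=list)
    region_profile: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def sites(self, contig: str | None = None) -> list[tuple[str, int]]:
        return [
            (i.contig, i.site)
            for i in self.insertions
            if i.parent is None and (contig is None or i.contig == contig)
        ]


@dataclass
class Segment:
    """One block of a mutated contig, mapped back to its source."""

    mut_start: int
    mut_end: int
    kind: str  # 'genome' or 'te'
    orig_start: int = 0  # genome segments: original coordinate at mut_start
    elem_id: int = -1
    orient: str = "+"
    te_lo: int = 0  # element-coordinate range covered
    te_hi: int = 0

    def te_interval(self, a: int, b: int) -> tuple[int, int]:
        """Element coordinates of mutated sub-interval [a, b)."""
        if self.orient == "+":
            return (self.te_lo + a - self.mut_start, self.te_lo + b - self.mut_start)
        return (self.te_hi - (b - self.mut_start), self.te_hi - (a - self.mut_start))


@dataclass
class MutatedContig:
    name: str
    seq: str
    segments: list[Segment]
    codes: np.ndarray = field(repr=False, default=None)
    p_top: np.ndarray = field(repr=False, default=None)  # methylation prob at C
    p_bottom: np.ndarray = field(repr=False, default=None)  # ... at G (bottom C)


@dataclass
class GenomeBundle:
    contigs: dict[str, str]
    te_seq: str
    annotation: TEAnnotation


@dataclass
class SimulatedSample:
    config: SimulationConfig
    bundle: GenomeBundle
    mutated: dict[str, MutatedContig]
    truth: TruthTable
    genome_alignments: list[AlignedRead]
    te_alignments: list[AlignedRead]
    stats: dict[str, int]
    _genome_report=None
    _te_report=None

    def genome_report(self):
        """CX report of the genome-side alignments vs the original genome."""
        if self._genome_report is None:
            self._genome_report = emit_cytosine_report(
                self.genome_alignments, self.bundle.contigs
            )
        return self._genome_report

    def te_report(self):
        """CX report of the element-side alignments vs the element sequence."""
        if self._te_report is None:
            self._te_report = emit_cytosine_report(
                self.te_alignments, {self.bundle.annotation.te_name: self.bundle.te_seq}
            )
        return self._te_report


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _DECODE[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_genome(config: SimulationConfig) -> GenomeBundle:
    """Generate contigs, the element sequence and its annotation (seeded).

    The element is built as LTR + internal + identical LTR and embedded
    once in the first non-chloroplast contig as the reference copy, with
    flanking normalization windows on either side.  Pericentromeres are
    declared as the central fifth of each non-chloroplast contig.
    """
    rng = np.random.default_rng([config.genome_seed if config.genome_seed is not None else config.seed, 11])
    main = config.main_contig
    if config.contig_lengths[main] < 10 * config.te_length:
        raise ValueError(
            f"main contig {main} too short: need >= 10 x te_length "
            f"({10 * config.te_length} bp)"
        )
    ltr = _random_seq(rng, config.ltr_length)
    internal = _random_seq(rng, config.te_length - 2 * config.ltr_length)
    te_seq = ltr + internal + ltr

    contigs: dict[str, str] = {}
    for name, length in config.contig_lengths.items():
        contigs[name] = _random_seq(rng, length)

    # embed the reference copy at 1/4 of the main contig
    L = config.contig_lengths[main]
    ref_start = L // 4
    ref_end = ref_start + config.te_length
    contigs[main] = contigs[main][:ref_start] + te_seq + contigs[main][ref_end:]

    flank_len = min(10_000, L // 20)
    gap = 700
    flanks = (
        (ref_start - gap - flank_len, ref_start - gap),
        (ref_end + gap, ref_end + gap + flank_len),
    )
    peri = {
        name: [(int(0.4 * ln), int(0.6 * ln))]
        for name, ln in config.contig_lengths.items()
        if name != config.chloroplast_name
    }
    annotation = TEAnnotation(
        te_name=config.te_name,
        te_length=config.te_length,
        ltr_length=config.ltr_length,
        masked=config.mask_offset,
        ref_contig=main,
        ref_span=(ref_start, ref_end),
        depth_interval=(ref_start + config.ltr_length, ref_end - config.ltr_length),
        flanks=flanks,
        pericentromeres=peri,
    )
    return GenomeBundle(contigs=contigs, te_seq=te_seq, annotation=annotation)


def _draw_sites(
    config: SimulationConfig, bundle: GenomeBundle, rng: np.random.Generator
) -> list[tuple[str, int, str, int]]:
    ann = bundle.annotation
    lo, hi = config.tsd_range
    sites: list[tuple[str, int, str, int]] = []
    if config.insertion_sites is not None:
        for entry in config.insertion_sites:
            contig, pos = entry[0], int(entry[1])
            strand = entry[2] if len(entry) > 2 else ("+" if rng.random() < config.strand_prob_plus else "-")
            tsd = int(entry[3]) if len(entry) > 3 else int(rng.integers(lo, hi + 1))
            sites.append((contig, pos, strand, tsd))
        return sites

    candidates = [
        n for n in config.contig_lengths if n != config.chloroplast_name
    ]
    # exclusion zones on the main contig: reference copy and flank windows
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in candidates}
    excl[ann.ref_contig].append((ann.ref_span[0] - 1_000, ann.ref_span[1] + 1_000))
    for f in ann.flanks:
        excl[ann.ref_contig].append((f[0] - 500, f[1] + 500))

    attempts, max_attempts = 0, 200 * max(config.n_insertions, 1)
    taken: list[tuple[str, int]] = []
    while len(sites) < config.n_insertions:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place requested insertions without overlap; "
                "contigs too short for n_insertions at the configured spacing"
            )
        contig = candidates[int(rng.integers(0, len(candidates)))]
        ln = config.contig_lengths[contig]
        pos = int(rng.integers(config.edge_margin, ln - config.edge_margin))
        if any(s <= pos < e for s, e in excl[contig]):
            continue
        if any(
            c == contig and abs(p - pos) < config.min_insertion_spacing
            for c, p in taken
        ):
            continue
        strand = "+" if rng.random() < config.strand_prob_plus else "-"
        tsd = int(rng.integers(lo, hi + 1))
        sites.append((contig, pos, strand, tsd))
        taken.append((contig, pos))
    return sites


def _element_piece(
    elem_id: int,
    strand: str,
    te_seq: str,
    te_lo: int = 0,
    te_hi: int | None = None,
) -> tuple[str, list[Segment]]:
    """Sequence + local segments of one (possibly partial) element copy."""
    te_hi = len(te_seq) if te_hi is None else te_hi
    sub = te_seq[te_lo:te_hi]
    if strand == "-":
        sub = revcomp(sub)
    seg = Segment(
        mut_start=0,
        mut_end=len(sub),
        kind="te",
        elem_id=elem_id,
        orient=strand,
        te_lo=te_lo,
        te_hi=te_hi,
    )
    return sub, [seg]


def _nested_element(
    parent_id: int,
    child_id: int,
    te_seq: str,
    spacings: tuple[int, int],
    ltr_length: int,
    tsd: int,
) -> tuple[str, list[Segment], tuple[int, int]]:
    """A sense parent with an antisense child planted in its internal region.

    ``spacings`` = (gap between the parent 5' LTR and the child's proximal
    LTR, gap between the child's distal LTR and the parent 3' LTR).  The
    first gap fixes the child offset; the second is realized exactly when
    the element length matches, otherwise the realized value is returned.
    """
    L = len(te_seq)
    d5 = spacings[0]
    q = d5 + ltr_length - tsd  # parent TE coordinate of the child site
    if not (ltr_length < q < L - ltr_length - tsd):
        raise ValueError("nested spacing places the child outside the internal region")
    child_seq = revcomp(te_seq)
    seq = te_seq[: q + tsd] + child_seq + te_seq[q:]
    segments = [
        Segment(0, q + tsd, "te", elem_id=parent_id, orient="+", te_lo=0, te_hi=q + tsd),
        Segment(q + tsd, q + tsd + L, "te", elem_id=child_id, orient="-", te_lo=0, te_hi=L),
        Segment(q + tsd + L, len(seq), "te", elem_id=parent_id, orient="+", te_lo=q, te_hi=L),
    ]
    realized = (q + tsd - ltr_length, (L - ltr_length) - q)
    return seq, segments, realized


def plant_insertions(
    bundle: GenomeBundle, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, MutatedContig], TruthTable]:
    """Insert elements into the genome, duplicating the TSD on both sides.

    An insertion at site ``s`` with TSD length ``t`` produces
    ``genome[:s+t] + element + genome[s:]`` so the bases ``genome[s:s+t]``
    flank the element on both sides.  Removing the element and one TSD copy
    restores the original contig exactly.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 23])
    truth = TruthTable(region_profile=dict(config.methylation_profile))

    planted = _draw_sites(config, bundle, rng)
    solo = list(config.solo_ltrs or [])

    # one record per planted element (children appended when nesting)
    events: list[tuple[str, int, Insertion]] = []  # (contig, site, insertion)
    next_id = 0
    for contig, pos, strand, tsd in planted:
        ins = Insertion(next_id, contig, pos, strand, tsd, kind="full")
        events.append((contig, pos, ins))
        truth.insertions.append(ins)
        next_id += 1
    for contig, pos, strand in solo:
        ins = Insertion(next_id, contig, pos, strand, 0, kind="solo_ltr")
        events.append((contig, pos, ins))
        truth.insertions.append(ins)
        next_id += 1

    nested_child: Insertion | None = None
    if config.nested_insertion:
        full = [i for i in truth.insertions if i.kind == "full"]
        if not full:
            raise ValueError("nested_insertion requires at least one full insertion")
        parent = full[0]
        parent.strand = "+"  # the nested construction is built on a sense parent
        lo, hi = config.tsd_range
        child_tsd = int(rng.integers(lo, hi + 1))
        nested_child = Insertion(
            next_id,
            parent.contig,
            parent.site,
            "-",
            child_tsd,
            kind="full",
            parent=parent.id,
        )
        truth.insertions.append(nested_child)

    # overlap check (site +/- tsd must not collide)
    by_contig: dict[str, list[tuple[int, Insertion]]] = {}
    for contig, pos, ins in events:
        by_contig.setdefault(contig, []).append((pos, ins))
    for contig, items in by_contig.items():
        items.sort(key=lambda x: x[0])
        for (p1, i1), (p2, i2) in zip(items, items[1:]):
            if p2 < p1 + max(i1.tsd, 1):
                raise ValueError(f"overlapping insertion sites on {contig}: {p1}, {p2}")

    mutated: dict[str, MutatedContig] = {}
    for name, seq in bundle.contigs.items():
        items = sorted(by_contig.get(name, []), key=lambda x: x[0])
        pieces: list[str] = []
        segments: list[Segment] = []
        cursor = 0  # original coordinate
        out = 0  # mutated coordinate
        for pos, ins in items:
            t = ins.tsd
            # genome up to and including the first TSD copy
            g_end = pos + t
            pieces.append(seq[cursor:g_end])
            segments.append(
                Segment(out, out + (g_end - cursor), "genome", orig_start=cursor)
            )
            out += g_end - cursor
            if ins.kind == "solo_ltr":
                esq, esegs = _element_piece(
                    ins.id, ins.strand, bundle.te_seq, 0, config.ltr_length
                )
            elif config.nested_insertion and nested_child is not None and ins.id == nested_child.parent:
                esq, esegs, realized = _nested_element(
                    ins.id,
                    nested_child.id,
                    bundle.te_seq,
                    config.nested_spacings,
                    config.ltr_length,
                    nested_child.tsd,
                )
                nested_child.ltr_spacings = realized
            else:
                esq, esegs = _element_piece(ins.id, ins.strand, bundle.te_seq)
            pieces.append(esq)
            for s in esegs:
                segments.append(
                    replace(s, mut_start=s.mut_start + out, mut_end=s.mut_end + out)
                )
            out += len(esq)
            cursor = pos  # resume at the site: second TSD copy follows
        pieces.append(seq[cursor:])
        segments.append(Segment(out, out + len(seq) - cursor, "genome", orig_start=cursor))
        mseq = "".join(pieces)
        mc = MutatedContig(name=name, seq=mseq, segments=segments)
        mutated[name] = mc

    _assign_methylation(mutated, bundle, truth, config)
    return mutated, truth


def _orig_class_array(
    name: str, length: int, bundle: GenomeBundle, config: SimulationConfig
) -> np.ndarray:
    """Region class per original-genome base: index into the profile table."""
    ann = bundle.annotation
    cls = np.zeros(length, dtype=np.int8)  # 0 = arm
    if name == config.chloroplast_name:
        cls[:] = 4
        return cls
    for s, e in ann.pericentromeres.get(name, []):
        cls[s:e] = 1
    if name == ann.ref_contig:
        (l5s, l5e), (l3s, l3e) = ann.ref_ltr_intervals
        s, e = ann.ref_span
        cls[s:e] = 3  # te_internal
        cls[l5s:l5e] = 2  # te_ltr
        cls[l3s:l3e] = 2
    return cls


_CLASS_NAMES = ["arm", "pericentromere", "te_ltr", "te_internal", "chloroplast"]


def _assign_methylation(
    mutated: dict[str, MutatedContig],
    bundle: GenomeBundle,
    truth: TruthTable,
    config: SimulationConfig,
) -> None:
    """Fill per-base methylation probability arrays on each mutated contig."""
    prof = config.methylation_profile
    table = np.array([prof[c] for c in _CLASS_NAMES], dtype=np.float32)  # class x ctx
    rows = [table[i] for i in range(len(_CLASS_NAMES))]

    ltr_override: dict[tuple[int, str], int] = {}
    if config.ltr_profiles:
        full = [i for i in truth.insertions if i.kind == "full"]
        for ins, (p5, p3) in zip(full, config.ltr_profiles):
            rows.append(np.asarray(p5, dtype=np.float32))
            ltr_override[(ins.id, "5p")] = len(rows) - 1
            rows.append(np.asarray(p3, dtype=np.float32))
            ltr_override[(ins.id, "3p")] = len(rows) - 1

    perturb_rows: dict[int, int] = {}
    if config.flank_perturbation:
        _, deltas = config.flank_perturbation
        for base_idx in range(len(_CLASS_NAMES)):
            shifted = np.clip(
                table[base_idx] + np.asarray(deltas, dtype=np.float32), 0.0, 100.0
            )
            rows.append(shifted)
            perturb_rows[base_idx] = len(rows) - 1

    full_table = np.vstack(rows)

    ltr_len, te_len = config.ltr_length, config.te_length
    for name, mc in mutated.items():
        orig_cls = _orig_class_array(
            name, len(bundle.contigs[name]), bundle, config
        )
        cls = np.empty(len(mc.seq), dtype=np.int16)
        for seg in mc.segments:
            if seg.kind == "genome":
                n = seg.mut_end - seg.mut_start
                cls[seg.mut_start : seg.mut_end] = orig_cls[
                    seg.orig_start : seg.orig_start + n
                ]
            else:
                te_pos = np.arange(seg.te_lo, seg.te_hi)
                if seg.orient == "-":
                    te_pos = te_pos[::-1]
                in_ltr5 = te_pos < ltr_len
                in_ltr3 = te_pos >= te_len - ltr_len
                block = np.where(in_ltr5 | in_ltr3, 2, 3).astype(np.int16)
                for which, mask in (("5p", in_ltr5), ("3p", in_ltr3)):
                    row = ltr_override.get((seg.elem_id, which))
                    if row is not None:
                        block[mask] = row
                cls[seg.mut_start : seg.mut_end] = block

        if config.flank_perturbation:
            radius, _ = config.flank_perturbation
            for seg in mc.segments:
                if seg.kind != "genome":
                    continue
                for contig, site in truth.sites(name):
                    lo = max(seg.mut_start + (site - radius - seg.orig_start), seg.mut_start)
                    hi = min(seg.mut_start + (site + radius - seg.orig_start), seg.mut_end)
                    if hi <= lo:
                        continue
                    view = cls[lo:hi]
                    for base_idx, row in perturb_rows.items():
                        view[view == base_idx] = row
                    cls[lo:hi] = view

        codes = encode_seq(mc.seq)
        top, bottom = context_codes(codes)
        p_top = np.zeros(len(codes), dtype=np.float32)
        p_bottom = np.zeros(len(codes), dtype=np.float32)
        has_top = top >= 0
        has_bottom = bottom >= 0
        p_top[has_top] = full_table[cls[has_top], top[has_top]] / 100.0
        p_bottom[has_bottom] = full_table[cls[has_bottom], bottom[has_bottom]] / 100.0
        mc.codes = codes
        mc.p_top = p_top
        mc.p_bottom = p_bottom


@dataclass
class _Placement:
    material: str  # 'genome' or 'te'
    ref: str
    start: int
    cigar: list[tuple[str, int]]
    strand: str
    conv: str
    seq: str
    elem_id: int | None = None

    @property
    def end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op == "M")


def _place_mate(
    contig: str,
    mc: MutatedContig,
    a: int,
    b: int,
    strand: str,
    conv: str,
    seq: str,
    annotation: TEAnnotation,
    stats: dict[str, int],
    min_anchor: int = 25,
) -> _Placement | None:
    starts = [s.mut_start for s in mc.segments]
    i = bisect.bisect_right(starts, a) - 1
    portions: list[tuple[Segment, int, int]] = []
    while i < len(mc.segments) and mc.segments[i].mut_start < b:
        seg = mc.segments[i]
        lo, hi = max(a, seg.mut_start), min(b, seg.mut_end)
        if hi > lo:
            portions.append((seg, lo, hi))
        i += 1

    # a local aligner only anchors on a block it can seed; shorter blocks
    # end up soft-clipped on whichever reference hosts the anchor
    anchorable = [p for p in portions if p[2] - p[1] >= min_anchor]
    if not anchorable:
        anchorable = portions
    genome_portions = [p for p in anchorable if p[0].kind == "genome"]
    pool = genome_portions if genome_portions else anchorable
    seg, lo, hi = max(pool, key=lambda p: p[2] - p[1])
    left_clip, right_clip = lo - a, b - hi

    def with_clips(m: int, left: int, right: int) -> list[tuple[str, int]]:
        cigar: list[tuple[str, int]] = []
        if left:
            cigar.append(("S", left))
        cigar.append(("M", m))
        if right:
            cigar.append(("S", right))
        return cigar

    if seg.kind == "genome":
        return _Placement(
            material="genome",
            ref=contig,
            start=seg.orig_start + (lo - seg.mut_start),
            cigar=with_clips(hi - lo, left_clip, right_clip),
            strand=strand,
            conv=conv,
            seq=seq,
        )
    te_lo, te_hi = seg.te_interval(lo, hi)
    if seg.orient == "-":
        seq = revcomp(seq)
        conv = "GA" if conv == "CT" else "CT"
        strand = "-" if strand == "+" else "+"
        left_clip, right_clip = right_clip, left_clip
    if te_lo >= annotation.masked[0] and te_hi <= annotation.masked[1]:
        stats["dropped_masked"] = stats.get("dropped_masked", 0) + 1
        return None
    return _Placement(
        material="te",
        ref=annotation.te_name,
        start=te_lo,
        cigar=with_clips(te_hi - te_lo, left_clip, right_clip),
        strand=strand,
        conv=conv,
        seq=seq,
        elem_id=seg.elem_id,
    )


def _in_ref_ltr(p: _Placement, annotation: TEAnnotation) -> bool:
    if p.ref != annotation.ref_contig:
        return False
    for s, e in annotation.ref_ltr_intervals:
        if p.start >= s and p.end <= e:
            return True
    return False


def _to_read(p: _Placement, name: str, is_read1: bool) -> AlignedRead:
    return AlignedRead(
        name=name,
        ref=p.ref,
        start=p.start,
        strand=p.strand,
        cigar=p.cigar,
        seq=p.seq,
        is_read1=is_read1,
        conv=p.conv,
    )


def simulate_emseq_reads(
    mutated: dict[str, MutatedContig],
    annotation: TEAnnotation,
    config: SimulationConfig,
) -> tuple[list[AlignedRead], list[AlignedRead], dict[str, int]]:
    """Draw converted paired-end fragments and derive alignments from truth.

    Returns (genome_alignments, te_alignments, stats).  Fragment starts are
    uniform per contig; insert sizes uniform in ``insert_size_range``; each
    fragment carries one conversion view (top or bottom strand, 50/50).
    Unmethylated cytosines convert at rate ``1 - conversion_failure``.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng([config.seed, 37])
    rl = config.read_length
    ins_lo, ins_hi = config.insert_size_range
    fail = config.conversion_failure

    genome_set: list[AlignedRead] = []
    te_set: list[AlignedRead] = []
    stats: dict[str, int] = {
        "n_fragments": 0,
        "n_discordant": 0,
        "n_te_only_pairs": 0,
        "dropped_multimap_ltr": 0,
        "dropped_masked": 0,
    }

    frag_no = 0
    for name, mc in mutated.items():
        L = len(mc.seq)
        max_ins = min(ins_hi, L)
        if max_ins < ins_lo:
            raise ValueError(f"contig {name} shorter than the minimum insert size")
        n_frag = int(round(config.coverage * L / (2.0 * rl)))
        if n_frag == 0:
            raise ValueError("coverage too low: zero fragments drawn")
        inserts = rng.integers(ins_lo, max_ins + 1, size=n_frag)
        starts = rng.integers(0, L - inserts + 1)
        top_view = rng.random(n_frag) < 0.5

        for k in range(n_frag):
            a, insert = int(starts[k]), int(inserts[k])
            b = a + insert
            frag = mc.codes[a:b].copy()
            if top_view[k]:
                conv = "CT"
                cidx = np.nonzero(frag == _C)[0]
                if cidx.size:
                    methylated = rng.random(cidx.size) < mc.p_top[a:b][cidx]
                    converted = ~methylated & (rng.random(cidx.size) >= fail)
                    frag[cidx[converted]] = _T
            else:
                conv = "GA"
                gidx = np.nonzero(frag == _G)[0]
                if gidx.size:
                    methylated = rng.random(gidx.size) < mc.p_bottom[a:b][gidx]
                    converted = ~methylated & (rng.random(gidx.size) >= fail)
                    frag[gidx[converted]] = _A
            frag_str = _DECODE[frag].tobytes().decode()
            pair_name = f"frag{frag_no:07d}"
            frag_no += 1
            stats["n_fragments"] += 1

            left_seq = frag_str[:rl]
            right_seq = frag_str[-rl:]
            p_left = _place_mate(
                name, mc, a, a + rl, "+", conv, left_seq, annotation, stats,
                min_anchor=config.min_anchor,
            )
            p_right = _place_mate(
                name, mc, b - rl, b, "-", conv, right_seq, annotation, stats,
                min_anchor=config.min_anchor,
            )
            # read1 is the left mate for top-strand views, right otherwise
            r1_left = conv == "CT"

            placements = [
                (p_left, r1_left),
                (p_right, not r1_left),
            ]
            present = [(p, r1) for p, r1 in placements if p is not None]
            if not present:
                continue
            materials = {p.material for p, _ in present}
            if materials == {"genome"}:
                for p, r1 in present:
                    _emit_genome(p, pair_name, r1, annotation, genome_set, stats)
            elif materials == {"te"}:
                ids = {p.elem_id for p, _ in present}
                if len(present) == 2 and len(ids) == 1:
                    # concordant interior pair: project onto the reference copy
                    for p, r1 in present:
                        proj = replace(
                            p,
                            material="genome",
                            ref=annotation.ref_contig,
                            start=annotation.ref_span[0] + p.start,
                        )
                        _emit_genome(proj, pair_name, r1, annotation, genome_set, stats)
                else:
                    # junction-spanning / improper element pairs stay on the
                    # element reference (nested / hairpin evidence)
                    stats["n_te_only_pairs"] += 1
                    for p, r1 in present:
                        te_set.append(_to_read(p, pair_name, r1))
            else:
                stats["n_discordant"] += 1
                for p, r1 in present:
                    if p.material == "genome":
                        _emit_genome(p, pair_name, r1, annotation, genome_set, stats)
                    else:
                        te_set.append(_to_read(p, pair_name, r1))
    logger.info("simulated %d fragments: %s", stats["n_fragments"], stats)
    return genome_set, te_set, stats


def _emit_genome(
    p: _Placement,
    name: str,
    is_read1: bool,
    annotation: TEAnnotation,
    out: list[AlignedRead],
    stats: dict[str, int],
) -> None:
    if _in_ref_ltr(p, annotation):
        stats["dropped_multimap_ltr"] += 1
        return
    out.append(_to_read(p, name, is_read1))


def simulate_sample(config: SimulationConfig) -> SimulatedSample:
    """End-to-end convenience: genome -> insertions -> reads -> sample."""
    bundle = simulate_genome(config)
    mutated, truth = plant_insertions(bundle, config)
    genome_alns, te_alns, stats = simulate_emseq_reads(
        mutated, bundle.annotation, config
    )
    return SimulatedSample(
        config=config,
        bundle=bundle,
        mutated=mutated,
        truth=truth,
        genome_alignments=genome_alns,
        te_alignments=te_alns,
        stats=stats,
    )
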