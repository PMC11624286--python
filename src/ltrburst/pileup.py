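"""Per-cytosine methylation pile-up from converted-read alignments.

A read from a top-strand (Watson) conversion view informs the cytosines on
the top strand of its reference: at reference C positions a read C is a
methylated call and a read T an unmethylated call.  A bottom-strand (Crick)
view informs the complementary-strand cytosines, which appear as G on the
top-strand reference: read G is methylated, read A unmethylated.  Reads are
stored forward-reference-oriented, so both cases reduce to direct
positionwise comparison.

Overlapping mate pairs are counted once: within a pair, reference positions
already observed by the first-processed mate are skipped for the second
(mirroring the ``--no_overlap`` convention of standard extractors).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ltrburst.records import AlignedRead

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_A, _C, _G, _T = 0, 1, 2, 3


def encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE.items():
        out[arr == ord(base)] = code
    return out


def context_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Context per position for both strands: 0=CG, 1=CHG, 2=CHH, -1=no C.

    Top strand evaluated at C positions reading rightwards, bottom strand
    at G positions reading leftwards on the complement.  Positions too
    close to the sequence edge are padded with N (counts as H).
    """
    n = len(codes)
    nxt = np.full(n, 4, dtype=np.int8)
    nxt2 = np.full(n, 4, dtype=np.int8)
    nxt[:-1] = codes[1:]
    nxt2[:-2] = codes[2:]
    prv = np.full(n, 4, dtype=np.int8)
    prv2 = np.full(n, 4, dtype=np.int8)
    prv[1:] = codes[:-1]
    prv2[2:] = codes[:-2]

    top = np.full(n, -1, dtype=np.int8)
    is_c = codes == _C
    top[is_c & (nxt == _G)] = 0
    top[is_c & (nxt != _G) & (nxt2 == _G)] = 1
    top[is_c & (nxt != _G) & (nxt2 != _G)] = 2

    bottom = np.full(n, -1, dtype=np.int8)
    is_g = codes == _G
    # complement of the base to the left is G iff that base is C
    bottom[is_g & (prv == _C)] = 0
    bottom[is_g & (prv != _C) & (prv2 == _C)] = 1
    bottom[is_g & (prv != _C) & (prv2 != _C)] = 2
    return top, bottom


_CTX_NAME = np.array(["CG", "CHG", "CHH"])


def _trinucleotides(seq: str, positions: np.ndarray, strand: str) -> list[str]:
    padded = "NN" + seq + "NN"
    if strand == "+":
        return [padded[p + 2 : p + 5] for p in positions]
    from ltrburst.methylation import revcomp

    return [revcomp(padded[p : p + 3]) for p in positions]


def emit_cytosine_report(
    alignments: Iterable[AlignedRead],
    references: Mapping[str, str],
) -> pd.DataFrame:
    """Build a CX-style per-cytosine report (0-based ``pos`` in memory).

    Every cytosine position of every reference appears, on both strands,
    with methylated/unmethylated counts from the read pile-up (zero when
    uncovered), its context and trinucleotide.
    """
    ref_codes = {name: encode_seq(seq) for name, seq in references.items()}
    meth = {name: np.zeros(len(c), dtype=np.int64) for name, c in ref_codes.items()}
    unmeth = {name: np.zeros(len(c), dtype=np.int64) for name, c in ref_codes.items()}
    meth_b = {name: np.zeros(len(c), dtype=np.int64) for name, c in ref_codes.items()}
    unmeth_b = {name: np.zeros(len(c), dtype=np.int64) for name, c in ref_codes.items()}

    # per-pair intervals already observed, for mate-overlap deduplication
    seen: dict[str, list[tuple[str, int, int]]] = defaultdict(list)

    for read in alignments:
        if read.ref not in ref_codes:
            continue
        codes = ref_codes[read.ref]
        read_codes = encode_seq(read.seq)
        prior = seen[read.name]
        for ref_s, ref_e, read_s in read.aligned_blocks():
            ref_e = min(ref_e, len(codes))
            if ref_e <= ref_s:
                continue
            idx = np.arange(ref_s, ref_e)
            rb = read_codes[read_s : read_s + (ref_e - ref_s)]
            keep = np.ones(len(idx), dtype=bool)
            for pref, plo, phi in prior:
                if pref == read.ref:
                    keep &= (idx < plo) | (idx >= phi)
            idx, rb = idx[keep], rb[keep]
            refb = codes[idx]
            if read.conv == "CT":
                at_c = refb == _C
                m = at_c & (rb == _C)
                u = at_c & (rb == _T)
                np.add.at(meth[read.ref], idx[m], 1)
                np.add.at(unmeth[read.ref], idx[u], 1)
            else:
                at_g = refb == _G
                m = at_g & (rb == _G)
                u = at_g & (rb == _A)
                np.add.at(meth_b[read.ref], idx[m], 1)
                np.add.at(unmeth_b[read.ref], idx[u], 1)
            seen[read.name].append((read.ref, ref_s, ref_e))

    frames = []
    for name, codes in ref_codes.items():
        top, bottom = context_codes(codes)
        seq = references[name]
        for strand, ctx_arr, m_arr, u_arr in (
            ("+", top, meth[name], unmeth[name]),
            ("-", bottom, meth_b[name], unmeth_b[name]),
        ):
            pos = np.nonzero(ctx_arr >= 0)[0]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "pos": pos,
                        "strand": strand,
                        "count_methylated": m_arr[pos],
                        "count_unmethylated": u_arr[pos],
                        "context": _CTX_NAME[ctx_arr[pos]],
                        "trinucleotide": _trinucleotides(seq, pos, strand),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos",
                "strand",
                "count_methylated",
                "count_unmethylated",
                "context",
                "trinucleotide",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)
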