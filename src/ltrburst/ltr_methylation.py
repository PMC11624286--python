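"""Per-insertion, per-LTR methylation from cluster-assigned reads.

Each validated insertion call carries per-pair LTR-of-origin labels; only
the element-side mates carry methylation evidence over the element
sequence, so the 5' and 3' subsets consist of those mates.  Weighted
methylation is computed per context over the cytosines of the
corresponding LTR interval on the extracted element coordinate system,
with the masked 3'-LTR sub-interval excluded from the denominator (no read
can be placed there by construction).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ltrburst.annotation import TEAnnotation
from ltrburst.caller import InsertionCall
from ltrburst.methylation import CONTEXTS, ContextSummary, weighted_methylation
from ltrburst.pileup import emit_cytosine_report
from ltrburst.records import AlignedRead


def subset_reads_by_ltr(
    call: InsertionCall,
    te_alignments: Sequence[AlignedRead] | None = None,
) -> dict[str, list[AlignedRead]]:
    """Split the call's element-side mates into disjoint 5'/3' subsets.

    Reads with an ambiguous (None) label fall in neither subset.  The
    element-side mates are taken from the call's own pairs;
    ``te_alignments`` is accepted for interface symmetry and unused.
    """
    subsets: dict[str, list[AlignedRead]] = {"5p": [], "3p": []}
    for pair in call.pairs:
        label = call.ltr_labels.get(pair.name)
        if label in subsets:
            subsets[label].append(pair.te)
    return subsets


def per_ltr_methylation(
    reads: Sequence[AlignedRead],
    annotation: TEAnnotation,
    te_seq: str,
    ltr: str,
) -> dict[str, ContextSummary]:
    """Weighted methylation per context over one LTR from a read subset.

    ``ltr`` is '5p' or '3p'.  Contexts with zero covered cytosines are
    undefined (NaN percentage), not 0.
    """
    if ltr not in ("5p", "3p"):
        raise ValueError("ltr must be '5p' or '3p'")
    interval = annotation.ltr5 if ltr == "5p" else annotation.ltr3
    report = emit_cytosine_report(reads, {annotation.te_name: te_seq})
    if ltr == "3p":
        m0, m1 = annotation.masked
        report = report[(report["pos"] < m0) | (report["pos"] >= m1)]
    return weighted_methylation(
        report, contig=annotation.te_name, interval=interval
    )


def insertion_ltr_table(
    calls: Sequence[InsertionCall],
    annotation: TEAnnotation,
    te_seq: str,
) -> pd.DataFrame:
    """Per-insertion, per-LTR, per-context methylation table."""
    rows = []
    for call in calls:
        subsets = subset_reads_by_ltr(call)
        for ltr, reads in subsets.items():
            if not reads:
                continue
            per_ctx = per_ltr_methylation(reads, annotation, te_seq, ltr)
            for ctx in CONTEXTS:
                s = per_ctx[ctx]
                rows.append(
                    (
                        f"{call.contig}:{call.start}",
                        ltr,
                        ctx,
                        s.pct,
                        s.meth,
                        s.total,
                        len(reads),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "insertion",
            "ltr",
            "context",
            "weighted_pct",
            "meth_count",
            "total_count",
            "n_reads",
        ],
    )


def ltr_concordance(
    five_values: Sequence[float], three_values: Sequence[float]
) -> float | None:
    """Squared Pearson correlation of paired 5' vs 3' LTR methylation.

    Pairs with an undefined (NaN) side are dropped; fewer than 3 complete
    pairs yield None.
    """
    a = np.asarray(five_values, dtype=float)
    b = np.asarray(three_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        return None
    if np.std(a) == 0 or np.std(b) == 0:
        # degenerate: constant vector; correlation undefined unless identical
        return 1.0 if np.allclose(a, b) and np.std(a) == np.std(b) == 0 else None
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def concordance_table(ltr_table: pd.DataFrame, context: str) -> pd.DataFrame:
    """Scatter-ready paired 5'/3' percentages for one context."""
    sub = ltr_table[ltr_table["context"] == context]
    wide = sub.pivot_table(
        index="insertion", columns="ltr", values="weighted_pct", aggfunc="first"
    )
    wide = wide.dropna(subset=[c for c in ("5p", "3p") if c in wide.columns])
    return wide.reset_index()
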