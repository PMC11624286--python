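"""Element copy-number estimation: coverage ratios and qPCR delta-delta-Ct.

Coverage route: the mean per-base depth over the internal region of the
reference element copy is divided by the mean depth over two flanking
normalization windows (pooled base-wise over their union).  The mean
inverse ratio across control samples carrying only the reference insertion
is the normalization factor; a sample's normalized copy number is its
ratio times that factor, so controls land at 1.

qPCR route: copies = 2^(-ddCt) * 2, where ddCt is the element/reference-
gene dCt of the sample minus that of the calibrator and the factor 2 is
the inherent diploid copy number of both loci in wild-type plants.
Technical replicates are averaged on the Ct scale; primer efficiency is
assumed to be 100% (exact doubling per cycle).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ltrburst.records import AlignedRead

Interval = tuple[int, int]


def depth_from_alignments(
    alignments: Iterable[AlignedRead], contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base depth arrays (zero-filled over full contigs) from aligned
    blocks; soft-clipped bases contribute nothing."""
    depth = {n: np.zeros(l, dtype=np.int64) for n, l in contig_lengths.items()}
    for read in alignments:
        arr = depth.get(read.ref)
        if arr is None:
            continue
        for s, e, _ in read.aligned_blocks():
            arr[s : min(e, len(arr))] += 1
    return depth


def coverage_ratio(
    depth: Mapping[str, np.ndarray],
    te_interval: tuple[str, int, int],
    flank_intervals: Sequence[tuple[str, int, int]],
) -> float:
    """Mean depth on the element interval over mean depth on the pooled
    flank bases."""
    contig, s, e = te_interval
    if e <= s:
        raise ValueError("empty element interval")
    te_mean = float(depth[contig][s:e].mean())
    flank_bases = np.concatenate(
        [depth[c][fs:fe] for c, fs, fe in flank_intervals]
    )
    if flank_bases.size == 0:
        raise ValueError("empty flank intervals")
    flank_mean = float(flank_bases.mean())
    if flank_mean == 0:
        raise ValueError("zero depth on flanking intervals")
    return te_mean / flank_mean


def normalization_factor(control_ratios: Sequence[float]) -> float:
    """Mean inverse ratio over control samples carrying one reference copy."""
    if len(control_ratios) == 0:
        raise ValueError("at least one control ratio required")
    if any(r <= 0 for r in control_ratios):
        raise ValueError("control ratios must be positive")
    return float(np.mean([1.0 / r for r in control_ratios]))


def estimate_copies_coverage(sample_ratio: float, factor: float) -> float:
    """Normalized copy number relative to the single reference insertion."""
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return sample_ratio * factor


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct table TSV with columns sample, target, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table must carry columns {sorted(required)}")
    return df


def _mean_ct(ct_table: pd.DataFrame, sample: str, target: str) -> float:
    sub = ct_table[(ct_table["sample"] == sample) & (ct_table["target"] == target)]
    if sub.empty:
        raise ValueError(f"no Ct values for sample={sample!r} target={target!r}")
    vals = sub["ct"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite Ct for sample={sample!r} target={target!r}")
    return float(vals.mean())


def qpcr_copy_number(
    ct_table: pd.DataFrame,
    sample: str,
    calibrator: str,
    target: str = "TE",
    reference_gene: str = "ACT2",
    wt_copies: float = 2.0,
) -> float:
    """Absolute copy number by delta-delta-Ct against a calibrator sample.

    ``copies = 2^(-ddCt) * wt_copies`` with
    ``ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator``;
    a calibrator-identical sample therefore reports ``wt_copies``.
    """
    d_sample = _mean_ct(ct_table, sample, target) - _mean_ct(
        ct_table, sample, reference_gene
    )
    d_cal = _mean_ct(ct_table, calibrator, target) - _mean_ct(
        ct_table, calibrator, reference_gene
    )
    return float(2.0 ** (-(d_sample - d_cal)) * wt_copies)


def qpcr_relative_expression(
    ct_table: pd.DataFrame,
    sample: str,
    target: str,
    reference_gene: str = "ACT2",
    calibrator: str | None = None,
) -> float:
    """Fold change of target over the reference gene (2^-dCt), optionally
    relative to a calibrator sample (2^-ddCt)."""
    d_sample = _mean_ct(ct_table, sample, target) - _mean_ct(
        ct_table, sample, reference_gene
    )
    if calibrator is None:
        return float(2.0 ** (-d_sample))
    d_cal = _mean_ct(ct_table, calibrator, target) - _mean_ct(
        ct_table, calibrator, reference_gene
    )
    return float(2.0 ** (-(d_sample - d_cal)))
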