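"""Weighted-methylation statistics on per-cytosine reports.

The per-cytosine report is the seven-column CX dialect emitted by standard
bisulfite/EM-seq extractors: chromosome, 1-based position, strand,
count methylated, count unmethylated, context (CG/CHG/CHH), trinucleotide.
In memory it is a pandas DataFrame with 0-based positions (column ``pos``);
the TSV reader/writer convert to/from the 1-based text convention.

Weighted methylation of a region is the coverage-weighted ratio
``100 * sum(methylated) / sum(methylated + unmethylated)`` over its
cytosines — never a mean of per-site fractions.  Cytosines with zero
coverage contribute nothing to either sum; a region with zero total
coverage is flagged undefined rather than reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTEXTS = ("CG", "CHG", "CHH")

REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(sequence: str, position: int, strand: str) -> str:
    """Classify the cytosine at ``position`` (0-based) into CG/CHG/CHH.

    On the minus strand the base must be a G on the given (top-strand)
    sequence; the context is evaluated on the reverse complement reading
    leftwards.  H is any base other than G (N counts as H).
    """
    if strand == "+":
        if sequence[position] != "C":
            raise ValueError(f"no cytosine on + strand at {position}")
        nxt = sequence[position + 1] if position + 1 < len(sequence) else "N"
        nxt2 = sequence[position + 2] if position + 2 < len(sequence) else "N"
    elif strand == "-":
        if sequence[position] != "G":
            raise ValueError(f"no cytosine on - strand at {position}")
        nxt = revcomp(sequence[position - 1]) if position >= 1 else "N"
        nxt2 = revcomp(sequence[position - 2]) if position >= 2 else "N"
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class ContextSummary:
    """Weighted methylation of one context over one record subset."""

    context: str
    meth: int
    total: int
    n_cytosines: int

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def pct(self) -> float:
        """Weighted percentage in [0, 100]; NaN when coverage is zero."""
        if not self.defined:
            return math.nan
        return 100.0 * self.meth / self.total


def _subset(
    report: pd.DataFrame,
    contig: str | None = None,
    interval: tuple[int, int] | None = None,
    context: str | None = None,
) -> pd.DataFrame:
    sub = report
    if contig is not None:
        sub = sub[sub["chrom"] == contig]
    if interval is not None:
        s, e = interval
        sub = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
    if context is not None:
        sub = sub[sub["context"] == context]
    return sub


def weighted_methylation(
    report: pd.DataFrame,
    contig: str | None = None,
    interval: tuple[int, int] | None = None,
    contexts: tuple[str, ...] = CONTEXTS,
) -> dict[str, ContextSummary]:
    """Per-context weighted methylation over an optional contig/interval."""
    out: dict[str, ContextSummary] = {}
    sub = _subset(report, contig, interval)
    for ctx in contexts:
        s = sub[sub["context"] == ctx]
        cov = s["count_methylated"] + s["count_unmethylated"]
        out[ctx] = ContextSummary(
            context=ctx,
            meth=int(s["count_methylated"].sum()),
            total=int(cov.sum()),
            n_cytosines=int((cov > 0).sum()),
        )
    return out


def weighted_pct(
    report: pd.DataFrame,
    contig: str | None = None,
    interval: tuple[int, int] | None = None,
    context: str | None = None,
) -> float:
    """Scalar weighted percentage over all (or one) contexts; NaN if empty."""
    sub = _subset(report, contig, interval, context)
    total = int((sub["count_methylated"] + sub["count_unmethylated"]).sum())
    if total == 0:
        return math.nan
    return 100.0 * int(sub["count_methylated"].sum()) / total


def conversion_rate(report: pd.DataFrame, control_contig: str) -> float:
    """Conversion rate (%) from an unmethylated control contig.

    Estimated as 100 minus the weighted methylation over all contexts on
    the chloroplast-like control, whose true methylation is zero, so any
    residual methylated call reflects failed conversion.
    """
    if control_contig not in set(report["chrom"]):
        raise ValueError(f"control contig {control_contig!r} absent from report")
    pct = weighted_pct(report, contig=control_contig)
    if math.isnan(pct):
        raise ValueError(f"control contig {control_contig!r} has zero coverage")
    return 100.0 - pct


def compare_methylation(
    group_a: dict[str, "np.ndarray | list[float]"],
    group_b: dict[str, "np.ndarray | list[float]"],
    contexts: tuple[str, ...] = CONTEXTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided rank-sum comparison of per-cytosine methylation fractions.

    One Wilcoxon rank-sum (Mann-Whitney) test per context, tie-corrected
    normal approximation, Benjamini-Hochberg adjusted across the contexts
    tested in this invocation.  Groups with fewer than two values yield NA
    for that context.
    """
    rows = []
    for ctx in contexts:
        a = np.asarray(group_a.get(ctx, []), dtype=float)
        b = np.asarray(group_b.get(ctx, []), dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append((ctx, len(a), len(b), math.nan))
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        rows.append((ctx, len(a), len(b), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["context", "n_a", "n_b", "p_raw"])
    tested = df["p_raw"].notna()
    df["p_adj"] = math.nan
    if tested.any():
        df.loc[tested, "p_adj"] = multipletests(
            df.loc[tested, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    df["significant"] = df["p_adj"] < alpha
    return df


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    phat = successes / trials
    denom = 1.0 + z * z / trials
    center = (phat + z * z / (2 * trials)) / denom
    half = (z / denom) * math.sqrt(
        phat * (1 - phat) / trials + z * z / (4 * trials * trials)
    )
    return (center - half, center + half)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a seven-column CX report TSV (1-based positions in the file)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=REPORT_COLUMNS,
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "count_methylated": np.int64,
            "count_unmethylated": np.int64,
            "context": str,
            "trinucleotide": str,
        },
    )
    df["pos"] -= 1  # to 0-based
    return df


def write_cytosine_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the seven-column CX report TSV; positions emitted 1-based."""
    out = report[REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def summaries_to_frame(
    summaries: dict[str, dict[str, ContextSummary]]
) -> pd.DataFrame:
    """Flatten {region: {context: summary}} into the per-region TSV layout."""
    rows = []
    for region, per_ctx in summaries.items():
        for ctx, s in per_ctx.items():
            rows.append(
                (region, ctx, s.pct, s.meth, s.total, s.n_cytosines)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "context",
            "weighted_pct",
            "meth_count",
            "total_count",
            "n_cytosines",
        ],
    )
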