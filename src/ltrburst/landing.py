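"""Pre-insertion (landing-site) methylation state of new insertions.

The methylation a landing site carried *before* transposition is read from
same-genotype individuals that do not carry the insertion: a site is
informative only when it is polymorphic within its genotype (present in at
least one and absent in at least one individual).  Sites present in every
same-genotype individual are non-informative and discarded.

Classification follows fixed 10% thresholds on the three contexts:
unmethylated (all < 10%), mCG-only (mCG > 10%, mCHG and mCHH < 10%), or
non-CG methylated (mCHG or mCHH > 10%); non-CG sites are subclassified as
RdDM- or CMT2-dependent (or independent) by overlap with an external
pathway annotation BED.  Values exactly at 10% fall to the less-methylated
class and are flagged borderline.

The methylation-shift metaplot bins the flanking sequence of each site (on
the insertion-free coordinate system, where carrier reads map with the
element-derived bases soft-clipped) and reports the mean carrier-minus-
non-carrier weighted methylation per bin, context, and sample group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ltrburst.caller import InsertionCall
from ltrburst.methylation import CONTEXTS, ContextSummary

logger = logging.getLogger(__name__)


@dataclass
class LandingSiteRecord:
    contig: str
    position: int  # 0-based representative site position
    genotype: str
    carriers: list[str]
    informative: list[str]  # same-genotype non-carriers
    window: int = 200
    percentages: dict[str, float] = field(default_factory=dict)
    site_class: str | None = None  # unmethylated | mCG_only | nonCG
    pathway: str | None = None  # RdDM | CMT2 | independent | None
    borderline: bool = False


def polymorphic_sites(
    calls_by_sample: Mapping[str, Sequence[InsertionCall]],
    genotype_map: Mapping[str, str],
    match_tolerance: int = 100,
) -> list[LandingSiteRecord]:
    """Collapse per-sample calls into polymorphic landing sites.

    Calls across samples within ``match_tolerance`` bp on one contig are
    one site.  A site is retained iff, within its genotype, at least one
    sample carries it and at least one does not; sites carried by every
    same-genotype sample are discarded as non-informative.  Genotypes with
    a single sample cannot be informative (logged).
    """
    events: list[tuple[str, int, str]] = []  # (contig, pos, sample)
    for sample, calls in calls_by_sample.items():
        for call in calls:
            events.append((call.contig, (call.start + call.end) // 2, sample))
    events.sort()

    # cluster events into sites by proximity
    sites: list[tuple[str, list[int], set[str]]] = []
    for contig, pos, sample in events:
        if (
            sites
            and sites[-1][0] == contig
            and pos - sites[-1][1][-1] <= match_tolerance
        ):
            sites[-1][1].append(pos)
            sites[-1][2].add(sample)
        else:
            sites.append((contig, [pos], {sample}))

    by_genotype: dict[str, list[str]] = {}
    for sample, genotype in genotype_map.items():
        by_genotype.setdefault(genotype, []).append(sample)

    out: list[LandingSiteRecord] = []
    for contig, positions, carriers in sites:
        pos = int(np.median(positions))
        genotypes = {genotype_map[s] for s in carriers if s in genotype_map}
        for genotype in sorted(genotypes):
            cohort = by_genotype.get(genotype, [])
            if len(cohort) < 2:
                logger.info(
                    "genotype %s has a single sample; site %s:%d non-informative",
                    genotype,
                    contig,
                    pos,
                )
                continue
            geno_carriers = sorted(s for s in carriers if genotype_map.get(s) == genotype)
            informative = sorted(set(cohort) - set(geno_carriers))
            if not informative:
                logger.info(
                    "site %s:%d fixed within genotype %s; discarded",
                    contig,
                    pos,
                    genotype,
                )
                continue
            out.append(
                LandingSiteRecord(
                    contig=contig,
                    position=pos,
                    genotype=genotype,
                    carriers=geno_carriers,
                    informative=informative,
                )
            )
    return out


def _pooled_counts(
    reports: Sequence[pd.DataFrame],
    contig: str,
    interval: tuple[int, int],
) -> dict[str, tuple[int, int]]:
    """(meth, total) per context pooled across reports over an interval."""
    out = {ctx: [0, 0] for ctx in CONTEXTS}
    s, e = interval
    for rep in reports:
        sub = rep[(rep["chrom"] == contig) & (rep["pos"] >= s) & (rep["pos"] < e)]
        grouped = sub.groupby("context")[["count_methylated", "count_unmethylated"]].sum()
        for ctx in CONTEXTS:
            if ctx in grouped.index:
                m = int(grouped.loc[ctx, "count_methylated"])
                u = int(grouped.loc[ctx, "count_unmethylated"])
                out[ctx][0] += m
                out[ctx][1] += m + u
    return {ctx: (m, t) for ctx, (m, t) in out.items()}


def preinsertion_methylation(
    record: LandingSiteRecord,
    reports_by_sample: Mapping[str, pd.DataFrame],
    window: int = 200,
) -> dict[str, float]:
    """Weighted methylation per context around the site, pooled across the
    informative (non-carrier, same-genotype) samples.

    The window is +/- ``window`` bp around the site position.  Zero pooled
    coverage in every context leaves the record unclassifiable (all NaN).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not record.informative:
        raise ValueError("record has no informative samples")
    reports = [reports_by_sample[s] for s in record.informative]
    counts = _pooled_counts(
        reports, record.contig, (record.position - window, record.position + window)
    )
    pct = {
        ctx: (100.0 * m / t if t > 0 else math.nan) for ctx, (m, t) in counts.items()
    }
    record.window = window
    record.percentages = pct
    return pct


def classify_site(
    percentages: Mapping[str, float],
    pathway_intervals: Mapping[str, Sequence[tuple[int, int, str]]] | None = None,
    contig: str | None = None,
    window_interval: tuple[int, int] | None = None,
    threshold: float = 10.0,
) -> tuple[str, str | None, bool]:
    """Classify a percentage triple; returns (class, pathway, borderline).

    unmethylated iff all three contexts < threshold; mCG_only iff
    mCG > threshold with both non-CG contexts < threshold; nonCG iff
    mCHG or mCHH > threshold.  Equality with the threshold resolves to the
    less-methylated side and flags the call borderline.  Pathway labels
    (RdDM/CMT2/independent) apply to nonCG sites via any-overlap of the
    window with the annotation intervals; the largest overlap wins.
    """
    cg = percentages["CG"]
    chg = percentages["CHG"]
    chh = percentages["CHH"]
    if any(math.isnan(v) for v in (cg, chg, chh)):
        raise ValueError("percentages must be defined for classification")
    borderline = any(v == threshold for v in (cg, chg, chh))
    if chg > threshold or chh > threshold:
        cls = "nonCG"
    elif cg > threshold:
        cls = "mCG_only"
    else:
        cls = "unmethylated"
    pathway: str | None = None
    if cls == "nonCG":
        pathway = "independent"
        if pathway_intervals is not None and contig is not None and window_interval:
            s, e = window_interval
            best = 0
            for is_, ie, label in pathway_intervals.get(contig, []):
                ov = min(e, ie) - max(s, is_)
                if ov > 0 and ov > best:
                    best = ov
                    pathway = label
    return cls, pathway, borderline


def classify_records(
    records: Sequence[LandingSiteRecord],
    reports_by_sample: Mapping[str, pd.DataFrame],
    pathway_intervals: Mapping[str, Sequence[tuple[int, int, str]]] | None = None,
    window: int = 200,
    threshold: float = 10.0,
) -> list[LandingSiteRecord]:
    """Fill pre-insertion percentages, class and pathway on each record."""
    for rec in records:
        pct = preinsertion_methylation(rec, reports_by_sample, window=window)
        if any(math.isnan(v) for v in pct.values()):
            logger.info(
                "site %s:%d unclassifiable (zero coverage)", rec.contig, rec.position
            )
            continue
        cls, pathway, borderline = classify_site(
            pct,
            pathway_intervals,
            rec.contig,
            (rec.position - window, rec.position + window),
            threshold=threshold,
        )
        rec.site_class, rec.pathway, rec.borderline = cls, pathway, borderline
    return list(records)


def class_counts(records: Sequence[LandingSiteRecord]) -> pd.DataFrame:
    """Counts per class (and pathway within nonCG) — pie-chart table."""
    rows = []
    for rec in records:
        if rec.site_class is None:
            continue
        rows.append((rec.genotype, rec.site_class, rec.pathway or ""))
    df = pd.DataFrame(rows, columns=["genotype", "site_class", "pathway"])
    return (
        df.groupby(["genotype", "site_class", "pathway"])
        .size()
        .reset_index(name="n")
    )


def methylation_shift_metaplot(
    records: Sequence[LandingSiteRecord],
    reports_by_sample: Mapping[str, pd.DataFrame],
    group_map: Mapping[str, str],
    window: int = 2000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Mean methylation shift (carrier minus non-carrier) around sites.

    For each site, each distance bin in [-window, window) and each context,
    the weighted methylation of the pooled carrier reports minus that of
    the pooled informative non-carrier reports; averaged across the sites
    of each sample group.  Bins with no coverage on either side are NA for
    that site.  Flank coordinates are on the insertion-free genome.
    """
    if bin_size <= 0 or window <= 0:
        raise ValueError("window and bin_size must be positive")
    edges = np.arange(-window, window + 1, bin_size)
    rows = []
    for rec in records:
        group = group_map.get(rec.carriers[0], "all") if rec.carriers else "all"
        carrier_reports = [reports_by_sample[s] for s in rec.carriers]
        control_reports = [reports_by_sample[s] for s in rec.informative]
        for lo, hi in zip(edges[:-1], edges[1:]):
            interval = (rec.position + int(lo), rec.position + int(hi))
            car = _pooled_counts(carrier_reports, rec.contig, interval)
            con = _pooled_counts(control_reports, rec.contig, interval)
            for ctx in CONTEXTS:
                cm, ct = car[ctx]
                nm, nt = con[ctx]
                if ct == 0 or nt == 0:
                    shift = math.nan
                else:
                    shift = 100.0 * cm / ct - 100.0 * nm / nt
                rows.append((int(lo), ctx, group, rec.contig, rec.position, shift))
    per_site = pd.DataFrame(
        rows, columns=["bin", "context", "group", "contig", "position", "shift"]
    )
    agg = (
        per_site.groupby(["bin", "context", "group"])["shift"]
        .agg(mean_shift="mean", n="count", sem=lambda x: x.sem())
        .reset_index()
    )
    return agg
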