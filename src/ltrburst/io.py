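"""File formats: FASTA, SAM, BED, TSV tables, config serialization.

Conventions: SAM and the cytosine-report TSV are 1-based in text (pysam
and the report writer handle the shift); BED is 0-based half-open.  All
in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ltrburst.caller import InsertionCall
from ltrburst.records import AlignedRead, cigar_from_string

logger = logging.getLogger(__name__)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sam(
    alignments: Sequence[AlignedRead],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignment records as SAM; the conversion view goes to the XG
    tag ('CT'/'GA') as converted-read aligners do."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in reference_lengths.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name
            seg.reference_name = read.ref
            seg.reference_start = read.start
            seg.cigarstring = read.cigar_string
            seg.query_sequence = read.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            flag = 0x1  # paired
            flag |= 0x40 if read.is_read1 else 0x80
            if read.strand == "-":
                flag |= 0x10
            seg.flag = flag
            seg.mapping_quality = 42
            seg.set_tag("XG", read.conv)
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignedRead]:
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            out.append(
                AlignedRead(
                    name=seg.query_name,
                    ref=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=cigar_from_string(seg.cigarstring),
                    seq=seg.query_sequence,
                    is_read1=not seg.is_read2,
                    conv=seg.get_tag("XG") if seg.has_tag("XG") else "CT",
                )
            )
    return out


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """BED (0-based half-open) -> {contig: [(start, end, name), ...]}."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            name = parts[3] if len(parts) > 3 else ""
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2]), name))
    return out


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, str, str]], path: str | Path
) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand), 0-based."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def calls_to_bed(calls: Sequence[InsertionCall]) -> list[tuple]:
    return [
        (
            c.contig,
            c.start,
            max(c.end, c.start + 1),
            f"insertion_{i}",
            str(c.support_up + c.support_down),
            c.strand if c.strand in "+-" else ".",
        )
        for i, c in enumerate(calls)
    ]


def calls_to_frame(calls: Sequence[InsertionCall]) -> pd.DataFrame:
    """Detailed call table; positions 1-based in the ``pos_1based`` column,
    0-based half-open in start/end."""
    rows = []
    for c in calls:
        rows.append(
            (
                c.contig,
                c.start,
                c.end,
                c.start + 1,
                c.strand,
                c.tsd if c.tsd is not None else -1,
                c.overlap,
                c.support_up,
                c.support_down,
                c.location,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "start",
            "end",
            "pos_1based",
            "strand",
            "tsd",
            "overlap",
            "support_5p_border",
            "support_3p_border",
            "location",
        ],
    )


def truth_to_frame(truth) -> pd.DataFrame:
    rows = [
        (
            i.id,
            i.contig,
            i.site,
            i.strand,
            i.tsd,
            i.kind,
            i.parent if i.parent is not None else -1,
        )
        for i in truth.insertions
    ]
    return pd.DataFrame(
        rows, columns=["id", "contig", "site", "strand", "tsd", "kind", "parent"]
    )


def save_config(config, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    text = Path(path)
    if text.suffix in (".yml", ".yaml"):
        text.write_text(yaml.safe_dump(_jsonable(d), sort_keys=False))
    else:
        text.write_text(json.dumps(_jsonable(d), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_config(path: str | Path, cls):
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    field_types = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in d.items():
        if key not in field_types:
            raise ValueError(f"unknown config key {key!r} in {path}")
        kwargs[key] = _retuple(value)
    return cls(**kwargs)


def _retuple(value):
    # YAML/JSON have no tuples; restore them for interval-like lists
    if isinstance(value, list):
        if all(isinstance(v, (int, float)) for v in value) and len(value) in (2, 3):
            return tuple(value)
        return [_retuple(v) for v in value]
    if isinstance(value, dict):
        return {k: _retuple(v) for k, v in value.items()}
    return value
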