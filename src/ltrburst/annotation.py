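"""Annotation of the reference transposable element and its genomic context.

The element of interest is an LTR retrotransposon: two identical long
terminal repeats (LTRs) flanking an internal coding region.  The annotation
carries two coordinate systems:

* the extracted element sequence ("TE coordinates", 0-based over
  ``te_length``), with the 5'/3' LTR spans and the masked sub-interval of
  the 3' LTR that suppresses exact two-LTR multi-mapping;
* the single reference genomic copy (contig + span), with the
  internal-region interval used for depth-of-coverage copy-number
  estimation and two flanking normalization windows.

All intervals are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

Interval = tuple[int, int]


@dataclass(frozen=True)
class TEAnnotation:
    te_name: str
    te_length: int
    ltr_length: int
    masked: Interval  # on TE coordinates, inside the 3' LTR
    ref_contig: str
    ref_span: Interval  # full element span on the genome
    depth_interval: Interval  # internal region used for coverage ratio
    flanks: tuple[Interval, Interval]  # upstream/downstream normalization windows
    pericentromeres: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (s, e) in (
            ("masked", self.masked),
            ("ref_span", self.ref_span),
            ("depth_interval", self.depth_interval),
        ):
            if not 0 <= s < e:
                raise ValueError(f"malformed interval {name}={s, e}")
        if not (self.ltr3[0] <= self.masked[0] < self.masked[1] <= self.ltr3[1]):
            raise ValueError("masked interval must lie inside the 3' LTR")

    @property
    def ltr5(self) -> Interval:
        """5' LTR span on TE coordinates."""
        return (0, self.ltr_length)

    @property
    def ltr3(self) -> Interval:
        """3' LTR span on TE coordinates."""
        return (self.te_length - self.ltr_length, self.te_length)

    def ltr_of_te_position(self, start: int, end: int) -> str | None:
        """Which LTR a TE-coordinate interval overlaps ('5p'/'3p'), else None."""
        if start < self.ltr5[1] and end > self.ltr5[0]:
            return "5p"
        if start < self.ltr3[1] and end > self.ltr3[0]:
            return "3p"
        return None

    @property
    def ref_ltr_intervals(self) -> tuple[Interval, Interval]:
        """Genome-coordinate spans of the two LTRs of the reference copy."""
        s, e = self.ref_span
        return ((s, s + self.ltr_length), (e - self.ltr_length, e))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TEAnnotation":
        d = json.loads(Path(path).read_text())
        d["masked"] = tuple(d["masked"])
        d["ref_span"] = tuple(d["ref_span"])
        d["depth_interval"] = tuple(d["depth_interval"])
        d["flanks"] = tuple(tuple(f) for f in d["flanks"])
        d["pericentromeres"] = {
            k: [tuple(i) for i in v] for k, v in d["pericentromeres"].items()
        }
        return cls(**d)
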