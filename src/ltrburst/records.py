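"""Light-weight alignment records shared by the simulator and the callers.

``AlignedRead`` mirrors the subset of a SAM record the pipeline consumes:
reference placement, mapping strand, a cigar restricted to M/S operations
(aligned blocks and end soft-clips), the forward-reference-oriented read
sequence, and the conversion strand of the underlying EM-seq fragment
("CT" for top/Watson-strand conversion views, "GA" for bottom/Crick).
Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AlignedRead:
    name: str
    ref: str
    start: int
    strand: str  # mapping strand: '+' or '-'
    cigar: list[tuple[str, int]]  # ops limited to 'M' and 'S'
    seq: str  # forward-reference orientation (as in SAM SEQ)
    is_read1: bool = True
    conv: str = "CT"  # conversion strand: 'CT' or 'GA'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.conv not in ("CT", "GA"):
            raise ValueError(f"bad conversion strand {self.conv!r}")
        for op, _ in self.cigar:
            if op not in "MS":
                raise ValueError(f"unsupported cigar op {op!r}")

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    @property
    def end(self) -> int:
        """Reference end, half-open (start + aligned bases)."""
        return self.start + self.aligned_length

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def aligned_blocks(self):
        """Yield (ref_start, ref_end, read_start) per M block."""
        refpos, readpos = self.start, 0
        for op, n in self.cigar:
            if op == "M":
                yield refpos, refpos + n, readpos
                refpos += n
                readpos += n
            else:  # S
                readpos += n


def cigar_from_string(text: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out
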