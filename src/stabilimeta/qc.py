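"""Quality trimming and length filtering of single-end reads.

The rule mirrors a PRINSEQ-style end trim: bases are removed from the 5'
end while their quality is below ``q_left`` and from the 3' end while below
``q_right`` (single-base window, strict ``<``), then reads shorter than
``min_len`` are dropped.  Interior bases are never altered, so the
operation is idempotent.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class QCReport:
    input: int = 0
    trimmed: int = 0   # reads that lost >=1 base but survived
    dropped: int = 0   # reads below min_len after trimming

    @property
    def output(self) -> int:
        return self.input - self.dropped


def trim_read(read: ReadRecord, q_left: int, q_right: int) -> ReadRecord:
    """End-trim a single read; may return an empty read."""
    quals = read.qualities
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < q_left:
        lo += 1
    while hi > lo and quals[hi - 1] < q_right:
        hi -= 1
    if lo == 0 and hi == len(quals):
        return read
    return ReadRecord(read.id, read.sequence[lo:hi], quals[lo:hi])


def trim_and_filter(
    reads: Iterable[ReadRecord],
    q_left: int = 20,
    q_right: int = 20,
    min_len: int = 200,
    report: QCReport | None = None,
) -> Iterator[ReadRecord]:
    """Stream reads through end-trimming and a length filter.

    Surviving reads keep their input order.  If ``report`` is supplied its
    counters are updated in place as the stream is consumed.
    """
    if q_left < 0 or q_right < 0:
        raise ValueError("quality thresholds must be >= 0")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    for read in reads:
        if report is not None:
            report.input += 1
        trimmed = trim_read(read, q_left, q_right)
        if len(trimmed) < min_len:
            if report is not None:
                report.dropped += 1
            continue
        if report is not None and len(trimmed) < len(read):
            report.trimmed += 1
        yield trimmed
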