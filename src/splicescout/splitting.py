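"""Enumeration of two-part splits of unmapped reads.

A read of length L with minimum split size m yields, for every prefix
length p in [m, L-m], a (left, right) pair with left = read[:p] and
right = read[p:].  Total parts emitted: 2*(L - 2m + 1) when L >= 2m,
otherwise none (short reads are skipped, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .seqio import ReadRecord

__all__ = ["SplitPart", "SplitConfig", "select_min_split_size", "enumerate_splits", "part_id"]

# read-length threshold at which the automatic rule switches from 15 to 30 nt
_AUTO_THRESHOLD = 75
_AUTO_SHORT = 15
_AUTO_LONG = 30


@dataclass(frozen=True)
class SplitPart:
    read_id: str
    split_position: int  # prefix length p
    side: str  # 'L' or 'R'
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SplitConfig:
    """min_split_size=None selects the automatic per-read rule."""

    min_split_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_split_size is not None and self.min_split_size < 1:
            raise ValueError("min_split_size must be >= 1")

    def resolve(self, read_length: int) -> int:
        if self.min_split_size is not None:
            return self.min_split_size
        return select_min_split_size(read_length)


def select_min_split_size(read_length: int) -> int:
    """Automatic minimum split size: 15 nt for reads shorter than 75 nt,
    30 nt for reads of 75 nt and longer."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    return _AUTO_SHORT if read_length < _AUTO_THRESHOLD else _AUTO_LONG


def enumerate_splits(read: ReadRecord, min_split: int) -> Iterator[SplitPart]:
    """Yield every admissible (left, right) split of ``read``.

    Output order is deterministic: split position ascending, left before
    right.  Reads shorter than 2*min_split yield nothing.
    """
    if min_split < 1:
        raise ValueError("min_split must be >= 1")
    L = len(read.bases)
    for p in range(min_split, L - min_split + 1):
        yield SplitPart(read.read_id, p, "L", read.bases[:p])
        yield SplitPart(read.read_id, p, "R", read.bases[p:])


def part_id(part: SplitPart) -> str:
    """Identifier grammar for emitted part files: <read_id>|p=<p>|<L|R>."""
    return f"{part.read_id}|p={part.split_position}|{part.side}"


def parse_part_id(pid: str) -> tuple[str, int, str]:
    read_id, p_field, side = pid.rsplit("|", 2)
    return read_id, int(p_field[2:]), side
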