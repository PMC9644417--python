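"""Shared I/O helpers: BED intervals and call table serialisation.

Coordinate conventions are centralised here: everything in memory is
1-based inclusive (SAM-style); all BED input/output is 0-based
half-open. Conversions happen at the file boundary and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

__all__ = [
    "GenomicIntervals",
    "parse_bed",
    "write_bed",
    "write_tsv",
]


def parse_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Parse a BED file into (chrom, start, end, name) tuples (0-based half-open).

    Raises ``ValueError`` naming the offending line number on malformed rows.
    """
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: bad interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], start, end, name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n" if name else f"{chrom}\t{start}\t{end}\n")


@dataclass
class GenomicIntervals:
    """Interval set supporting 1-based point containment queries.

    Built from BED (0-based half-open); queries take SAM-style 1-based
    positions.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicIntervals":
        obj = cls()
        for chrom, start, end, name in parse_bed(path):
            obj.add(chrom, start, end, name)
        return obj

    @classmethod
    def empty(cls) -> "GenomicIntervals":
        return cls()

    def add(self, chrom: str, start0: int, end0: int, name: str = "") -> None:
        if end0 > start0:
            self.trees.setdefault(chrom, IntervalTree()).addi(start0, end0, name)

    def contains(self, chrom: str, pos1: int) -> bool:
        """True if the 1-based position lies inside any interval."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos1 - 1))

    def __bool__(self) -> bool:
        return any(len(t) for t in self.trees.values())


def write_tsv(rows: list[dict], path: str | Path, columns: list[str], header_comment: str = "") -> None:
    """Write dict rows to TSV with a fixed column order and optional # header."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
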