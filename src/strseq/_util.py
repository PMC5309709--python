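"""Small shared helpers: sequence ops and genomic interval sets.

All coordinates package-wide are 0-based, half-open (BED convention).
SAM positions are converted on ingest/egress by the I/O layer.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class IntervalSet:
    """A queryable collection of named intervals (per-chromosome, sorted)."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[str, list[Interval]] = {}
        self._starts: dict[str, list[int]] = {}
        self._rebuild()

    def _rebuild(self):
        self._index.clear()
        self._starts.clear()
        for iv in sorted(self.intervals, key=lambda i: (i.chrom, i.start, i.end)):
            self._index.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._index.items():
            self._starts[chrom] = [iv.start for iv in ivs]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def add(self, iv: Interval):
        self.intervals.append(iv)
        self._rebuild()

    def contains(self, chrom: str, pos: int) -> bool:
        return self.at(chrom, pos) is not None

    def at(self, chrom: str, pos: int) -> Interval | None:
        """Return an interval containing ``pos`` (linear in local overlap depth)."""
        ivs = self._index.get(chrom)
        if not ivs:
            return None
        i = bisect_right(self._starts[chrom], pos)
        # intervals are short in this package; scan left while starts <= pos
        for iv in reversed(ivs[:i]):
            if iv.end > pos:
                return iv
            # allow a bounded backwards scan over nested/short intervals
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        return [iv for iv in self._index.get(chrom, []) if iv.overlap(chrom, start, end) > 0]

    def by_name(self, name: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.name == name]

    def self_overlaps(self) -> list[tuple[Interval, Interval]]:
        """Pairs of distinct same-name intervals that overlap (should be empty)."""
        bad = []
        for chrom, ivs in self._index.items():
            for a, b in zip(ivs, ivs[1:]):
                if a.name == b.name and a.overlap(b.chrom, b.start, b.end) > 0:
                    bad.append((a, b))
        return bad


def read_bed(path) -> IntervalSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            ivs.append(Interval(chrom, start, end, name))
    return IntervalSet(ivs)


def write_bed(ivset: IntervalSet, path):
    with open(path, "w") as fh:
        for iv in sorted(ivset.intervals, key=lambda i: (i.chrom, i.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
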