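"""Target regions: normalized genomic interval sets and consensus derivation.

Coordinate conventions follow the field's standards: BED intervals are
0-based half-open; VCF positions are 1-based. All internal interval math is
0-based half-open.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np


class TargetRegions:
    """A normalized (sorted, overlap-free) set of genomic intervals.

    Overlapping or touching intervals on the same chromosome are merged on
    construction, so equality of region sets is equality of their covered
    bases.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.asarray([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.asarray([m[1] for m in merged], dtype=np.int64)
        # cumulative base offsets give every targeted base a global index,
        # used by callability masks
        self._offsets: dict[str, np.ndarray] = {}
        total = 0
        for chrom in self._starts:
            lengths = self._ends[chrom] - self._starts[chrom]
            self._offsets[chrom] = total + np.concatenate(
                ([0], np.cumsum(lengths)[:-1])) if len(lengths) else np.empty(0, int)
            total += int(lengths.sum())
        self._total = total

    # -- basic queries ---------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    @property
    def total_length(self) -> int:
        """Number of bases covered."""
        return self._total

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self._starts:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield chrom, int(s), int(e)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TargetRegions):
            return NotImplemented
        return list(self) == list(other)

    def contains(self, chrom: str, pos0: int) -> bool:
        """True iff 0-based position falls in a half-open interval."""
        starts = self._starts.get(str(chrom))
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return bool(i >= 0 and pos0 < self._ends[str(chrom)][i])

    def base_index(self, chrom: str, pos0: int) -> int:
        """Global index of a targeted base (row of a per-base matrix), or -1."""
        starts = self._starts.get(str(chrom))
        if starts is None or len(starts) == 0:
            return -1
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i < 0 or pos0 >= self._ends[str(chrom)][i]:
            return -1
        return int(self._offsets[str(chrom)][i] + (pos0 - starts[i]))

    # -- set algebra -----------------------------------------------------
    def union(self, other: "TargetRegions") -> "TargetRegions":
        return TargetRegions([*self, *other])

    def intersection(self, other: "TargetRegions") -> "TargetRegions":
        out: list[tuple[str, int, int]] = []
        for chrom in self._starts:
            if chrom not in other._starts:
                continue
            a = list(zip(self._starts[chrom], self._ends[chrom]))
            b = list(zip(other._starts[chrom], other._ends[chrom]))
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    out.append((chrom, int(lo), int(hi)))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return TargetRegions(out)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_bed(cls, path) -> "TargetRegions":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    from .errors import ParseError
                    raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def consensus_targets(designs: Sequence[TargetRegions],
                      exons: TargetRegions) -> TargetRegions:
    """Consensus capture targets: union of the designs, intersected with exons.

    Mirrors how a multi-center capture study reconciles heterogeneous array
    designs against a common exon annotation; the result never exceeds either
    the pooled designs or the exon set.
    """
    if not designs:
        raise ValueError("at least one design set is required")
    pooled = designs[0]
    for d in designs[1:]:
        pooled = pooled.union(d)
    return pooled.intersection(exons)


def in_target(site, targets: TargetRegions) -> bool:
    """True iff a variant site (1-based pos) lies inside the target set."""
    return targets.contains(site.chrom, site.pos - 1)
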