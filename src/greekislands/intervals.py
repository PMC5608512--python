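"""Genomic interval arithmetic shared by every pipeline stage.

Coordinates are 0-based, half-open ``[start, end)`` everywhere, matching BED.
Any 1-based table is converted at the I/O boundary, never here.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "OverlapResult",
    "CoboundPeak",
    "intersect_classify",
    "consensus_peaks",
    "cobound_peaks",
    "nearest_distance",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> float:
        """Edge-to-edge bp gap; 0 for overlapping intervals, inf across chromosomes."""
        if self.chrom != other.chrom:
            return math.inf
        return max(0, other.start - self.end, self.start - other.end)

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """A named collection of intervals, e.g. one factor's peaks in one replicate.

    Intervals are kept sorted by (chrom, start, end); ids, where present,
    must be unique.  ``library_size`` carries sequencing depth for
    normalisation downstream.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    library_size: int | None = None

    def __post_init__(self) -> None:
        keys = [iv.sort_key() for iv in self.intervals]
        if keys != sorted(keys):
            raise ValueError(
                f"PeakSet {self.name!r}: intervals must be sorted by (chrom, start)"
            )
        ids = [iv.id for iv in self.intervals if iv.id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError(f"PeakSet {self.name!r}: duplicate interval ids")

    @classmethod
    def from_intervals(
        cls,
        name: str,
        intervals: Iterable[GenomicInterval],
        library_size: int | None = None,
        autoname: bool = False,
    ) -> "PeakSet":
        """Build a PeakSet, sorting the intervals (and id-ing them if asked)."""
        ivs = sorted(intervals, key=GenomicInterval.sort_key)
        if autoname:
            ivs = [
                GenomicInterval(
                    iv.chrom, iv.start, iv.end, iv.strand, iv.score, f"{name}_{i}"
                )
                for i, iv in enumerate(ivs)
            ]
        return cls(name=name, intervals=ivs, library_size=library_size)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        return dict(out)


@dataclass(frozen=True)
class GeneModel:
    """Gene as TSS/TES points on a strand, labelled OR or non-OR."""

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str
    gene_class: str  # "OR" | "non-OR"

    def __post_init__(self) -> None:
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss must differ from tes")
        if self.gene_class not in ("OR", "non-OR"):
            raise ValueError(f"{self.gene_id}: gene_class must be OR or non-OR")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi, self.strand, id=self.gene_id)


@dataclass
class OverlapResult:
    """Per-interval co-binding labels plus the overlapping pairs themselves."""

    labels_a: list[str]  # one of "co-bound", "A-only" per interval of set A
    labels_b: list[str]  # one of "co-bound", "B-only" per interval of set B
    pairs: list[tuple[int, int]]  # (index into A, index into B) of overlaps

    def counts(self) -> dict[str, int]:
        return {
            "co-bound-A": self.labels_a.count("co-bound"),
            "A-only": self.labels_a.count("A-only"),
            "co-bound-B": self.labels_b.count("co-bound"),
            "B-only": self.labels_b.count("B-only"),
        }


def intersect_classify(set_a: PeakSet, set_b: PeakSet) -> OverlapResult:
    """Label every peak of two factors as co-bound or factor-only.

    A peak is co-bound when it shares >= 1 bp with any peak of the other
    set.  Chromosome names absent from the other set simply never overlap.
    """
    b_by_chrom = set_b.by_chrom()
    b_index: dict[str, list[int]] = {}
    pos = 0
    for iv in set_b:
        b_index.setdefault(iv.chrom, []).append(pos)
        pos += 1

    trees: dict[str, IntervalTree] = {
        chrom: IntervalTree.from_tuples(
            (iv.start, iv.end, b_index[chrom][j]) for j, iv in enumerate(ivs)
        )
        for chrom, ivs in b_by_chrom.items()
    }

    labels_a = ["A-only"] * len(set_a)
    labels_b = ["B-only"] * len(set_b)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(set_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(h.data for h in tree.overlap(iv.start, iv.end))
        if hits:
            labels_a[i] = "co-bound"
            for j in hits:
                labels_b[j] = "co-bound"
                pairs.append((i, j))
    pairs.sort()
    return OverlapResult(labels_a=labels_a, labels_b=labels_b, pairs=pairs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cross_components(
    set_a: PeakSet, set_b: PeakSet
) -> list[tuple[list[int], list[int]]]:
    """Connected components of the cross-set overlap graph.

    Chained overlaps (A1-B1-A2) land in one component; components touching
    only one of the two sets are dropped.  Returned sorted by the leftmost
    coordinate of the component.
    """
    res = intersect_classify(set_a, set_b)
    n_a, n_b = len(set_a), len(set_b)
    uf = _UnionFind(n_a + n_b)
    for i, j in res.pairs:
        uf.union(i, n_a + j)
    comps: dict[int, tuple[list[int], list[int]]] = defaultdict(lambda: ([], []))
    for i, j in res.pairs:
        root = uf.find(i)
        a_side, b_side = comps[root]
        if i not in a_side:
            a_side.append(i)
        if j not in b_side:
            b_side.append(j)

    def comp_key(c: tuple[list[int], list[int]]) -> tuple:
        ivs = [set_a.intervals[i] for i in c[0]] + [set_b.intervals[j] for j in c[1]]
        return min(iv.sort_key() for iv in ivs)

    return sorted(comps.values(), key=comp_key)


def consensus_peaks(rep1: PeakSet, rep2: PeakSet, name: str | None = None) -> PeakSet:
    """Reproducible peaks across two replicates, extended to their combined size.

    Every overlapping rep1/rep2 pair yields one interval spanning
    min(starts)..max(ends); peaks seen in only one replicate are dropped and
    chained overlaps collapse to a single span.  Symmetric in its arguments.
    """
    name = name or f"{rep1.name}.consensus"
    out: list[GenomicInterval] = []
    for a_idx, b_idx in _cross_components(rep1, rep2):
        members = [rep1.intervals[i] for i in a_idx] + [rep2.intervals[j] for j in b_idx]
        chrom = members[0].chrom
        out.append(
            GenomicInterval(chrom, min(m.start for m in members), max(m.end for m in members))
        )
    out.sort(key=GenomicInterval.sort_key)
    ivs = [
        GenomicInterval(iv.chrom, iv.start, iv.end, id=f"{name}_{i}")
        for i, iv in enumerate(out)
    ]
    return PeakSet(name=name, intervals=ivs)


@dataclass(frozen=True)
class CoboundPeak:
    """A co-bound span with provenance back to the component factor peaks."""

    interval: GenomicInterval
    peak_a_ids: tuple[str, ...]
    peak_b_ids: tuple[str, ...]


def cobound_peaks(set_a: PeakSet, set_b: PeakSet) -> list[CoboundPeak]:
    """Co-bound spans of two factors' (consensus) peaks, with provenance.

    Each connected component of cross-factor overlaps becomes one span from
    the leftmost member start to the rightmost member end.
    """
    out: list[CoboundPeak] = []
    for k, (a_idx, b_idx) in enumerate(_cross_components(set_a, set_b)):
        a_ivs = [set_a.intervals[i] for i in a_idx]
        b_ivs = [set_b.intervals[j] for j in b_idx]
        members = a_ivs + b_ivs
        span = GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
        )
        out.append(
            CoboundPeak(
                interval=span,
                peak_a_ids=tuple(iv.id or f"{set_a.name}[{i}]" for i, iv in zip(a_idx, a_ivs)),
                peak_b_ids=tuple(iv.id or f"{set_b.name}[{j}]" for j, iv in zip(b_idx, b_ivs)),
            )
        )
    out.sort(key=lambda cb: cb.interval.sort_key())
    relabel = [
        CoboundPeak(
            GenomicInterval(cb.interval.chrom, cb.interval.start, cb.interval.end,
                            id=f"cobound_{i}"),
            cb.peak_a_ids,
            cb.peak_b_ids,
        )
        for i, cb in enumerate(out)
    ]
    return relabel


def nearest_distance(
    points: Sequence[tuple[str, int]],
    targets: Sequence[GenomicInterval],
) -> np.ndarray:
    """bp distance from each point to the nearest target edge on its chromosome.

    0 when the point lies inside a target; ``inf`` when no target shares the
    point's chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in targets:
        by_chrom[iv.chrom].append(iv)
    # merged, sorted edges per chromosome; merging cannot change distances
    edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=GenomicInterval.sort_key)
        starts: list[int] = []
        ends: list[int] = []
        for iv in ivs:
            if starts and iv.start <= ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        edges[chrom] = (np.asarray(starts), np.asarray(ends))

    out = np.full(len(points), np.inf)
    for k, (chrom, bp) in enumerate(points):
        if chrom not in edges:
            continue
        starts, ends = edges[chrom]
        i = int(np.searchsorted(starts, bp, side="right"))
        best = math.inf
        if i > 0:
            # gap past the right edge: bp - end (0 when inside)
            best = 0.0 if bp < ends[i - 1] else float(bp - ends[i - 1])
        if i < len(starts):
            best = min(best, float(starts[i] - bp))
        out[k] = best
    return out
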