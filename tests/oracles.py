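"""Brute-force reference implementations used to validate the fast paths.

Everything here is deliberately naive (all-pairs loops, direct PMF sums,
per-bp accumulation) and shares no code with the package internals.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from greekislands.intervals import GenomicInterval, PeakSet


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def classify_bruteforce(set_a: PeakSet, set_b: PeakSet):
    labels_a = []
    for iv in set_a:
        labels_a.append("co-bound" if any(overlaps(iv, jv) for jv in set_b) else "A-only")
    labels_b = []
    for jv in set_b:
        labels_b.append("co-bound" if any(overlaps(iv, jv) for iv in set_a) else "B-only")
    return labels_a, labels_b


def consensus_bruteforce(rep1: PeakSet, rep2: PeakSet) -> list[tuple[str, int, int]]:
    """Union-span components of the cross-replicate overlap graph."""
    items = [(iv, 0) for iv in rep1] + [(iv, 1) for iv in rep2]
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if items[i][1] != items[j][1] and overlaps(items[i][0], items[j][0]):
                parent[find(j)] = find(i)
    comps: dict[int, list[tuple[GenomicInterval, int]]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    spans = []
    for members in comps.values():
        sides = {side for _, side in members}
        if sides == {0, 1}:
            ivs = [iv for iv, _ in members]
            spans.append((ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)))
    return sorted(spans)


def nearest_bruteforce(points, targets) -> list[float]:
    out = []
    for chrom, bp in points:
        best = math.inf
        for t in targets:
            if t.chrom != chrom:
                continue
            if t.start <= bp < t.end:
                best = 0.0
            elif bp >= t.end:
                best = min(best, bp - t.end)
            else:
                best = min(best, t.start - bp)
        out.append(best)
    return out


def binom_tail_oracle(k: int, n: int, p0: float) -> float:
    """Upper tail P(X >= k) by direct PMF summation."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return total


def hypergeom_tail_oracle(x: int, M: int, K: int, N: int) -> float:
    """P(overlap >= x) drawing N from a universe of M with K category members."""
    total = Fraction(0)
    denom = math.comb(M, N)
    for i in range(x, min(K, N) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, N - i), denom)
    return float(total)


def scan_bruteforce(seq: str, weights: np.ndarray, threshold: float):
    """Per-position, per-strand scoring with explicit complement lookup."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = weights.shape[1]
    hits = []
    for strand in "+-":
        for o in range(len(seq) - L + 1):
            window = seq[o : o + L].upper()
            if strand == "-":
                window = "".join(comp.get(b, "N") for b in reversed(window))
            score = 0.0
            for j, b in enumerate(window):
                score += weights[code[b], j] if b in code else -math.inf
            if score >= threshold:
                hits.append((o, strand, score))
    hits.sort(key=lambda h: (h[0], h[1] != "+", -h[2]))
    return hits


def min_pair_bruteforce(hits_a, hits_b):
    """All-pairs minimum edge-to-edge gap (None when either list is empty)."""
    if not hits_a or not hits_b:
        return None
    best = None
    for a in hits_a:
        for b in hits_b:
            a_lo, a_hi = a.offset, a.offset + a.length
            b_lo, b_hi = b.offset, b.offset + b.length
            if a_lo < b_hi and b_lo < a_hi:
                gap = 0
            else:
                gap = b_lo - a_hi if b_lo >= a_hi else a_lo - b_hi
            if best is None or gap < best:
                best = gap
    return best


def region_counts_bruteforce(fragments, peaks) -> list[int]:
    counts = [0] * len(peaks.intervals)
    for fr in fragments:
        for i, pk in enumerate(peaks.intervals):
            if overlaps(fr, pk):
                counts[i] += 1
    return counts


def coverage_bruteforce(fragments, sizes: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n) for c, n in sizes.items()}
    for fr in fragments:
        for bp in range(fr.start, fr.end):
            if bp < sizes.get(fr.chrom, 0):
                out[fr.chrom][bp] += 1
    return out


def random_peakset(rng: np.random.Generator, name: str, n: int,
                   chrom_span: int = 10_000, chroms=("chrT",),
                   max_len: int = 400) -> PeakSet:
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_span - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length, id=f"{name}_{i}"))
    return PeakSet.from_intervals(name, ivs)
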