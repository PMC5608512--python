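"""PWM scanning and the composite Lhx2/Ebf motif grammar.

Scores are natural-log log-odds against a configurable background
(uniform 0.25 by default) with a small pseudocount, so a perfectly
informative column contributes ln(1/bg) and a background column
contributes 0.  On this scale the stringent/permissive thresholds used for
composite-site identification are 10 and 5; "scoring over 10" is a strict
inequality.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALPHABET",
    "PositionFrequencyMatrix",
    "LogOddsMatrix",
    "MotifHit",
    "CompositeMotif",
    "build_logodds",
    "scan_sequence",
    "best_match_score",
    "assemble_composite",
    "min_pair_distance",
    "pair_distances_by_region",
    "ks_one_sided",
    "score_cdf",
    "nucleotide_class_matrix",
]

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base probabilities, rows A,C,G,T; columns positions."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] < 1:
            raise ValueError("probs must be a 4 x L matrix with L >= 1")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each column must sum to 1 (±1e-9)")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_sites(cls, name: str, sites: Sequence[str],
                   pseudocount: float = 0.0) -> "PositionFrequencyMatrix":
        """Estimate a PFM from equal-length aligned binding sites."""
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("sites must have equal length")
        counts = np.full((4, L), pseudocount, dtype=float)
        for s in sites:
            for j, b in enumerate(s.upper()):
                counts[_CODE[b], j] += 1
        return cls(name=name, probs=counts / counts.sum(axis=0, keepdims=True))


@dataclass(frozen=True)
class LogOddsMatrix:
    name: str
    weights: np.ndarray  # 4 x L
    background: np.ndarray  # length-4, sums to 1
    pseudocount: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        # -inf marks impossible bases (zero probability, no pseudocount)
        if np.any(np.isnan(w)) or np.any(w == np.inf):
            raise ValueError("weights must be finite or -inf")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def reverse_complement(self) -> "LogOddsMatrix":
        w = self.weights[::-1, ::-1]  # complement rows (A<->T, C<->G) + reverse cols
        return LogOddsMatrix(self.name + ".rc", w, self.background, self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int
    strand: str
    score: float
    motif_name: str
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass(frozen=True)
class CompositeMotif:
    """Two half-site matrices joined by a fixed-width background spacer."""

    part_a: PositionFrequencyMatrix  # Lhx2 homeodomain site
    part_b: PositionFrequencyMatrix  # Ebf half-site
    spacer_bp: int = 0

    def __post_init__(self) -> None:
        if self.spacer_bp < 0:
            raise ValueError("spacer_bp must be >= 0")

    @property
    def length(self) -> int:
        return self.part_a.length + self.spacer_bp + self.part_b.length


def build_logodds(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> LogOddsMatrix:
    """Natural-log log-odds: ln((p + c*bg) / ((1 + c) * bg))."""
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background entries must be positive")
    with np.errstate(divide="ignore"):  # zero cells at pseudocount 0 -> -inf
        w = np.log((pfm.probs + pseudocount * bg[:, None])
                   / ((1 + pseudocount) * bg[:, None]))
    return LogOddsMatrix(pfm.name, w, bg, pseudocount)


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; anything outside ACGT (e.g. N) becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score of every length-L window; N positions contribute -inf."""
    L = weights.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    ext = np.vstack([weights, np.full(L, -np.inf)])  # row 4 = N
    scores = np.zeros(n_win)
    for j in range(L):
        scores = scores + ext[codes[j : j + n_win], j]
    return scores


def scan_sequence(
    seq: str,
    lom: LogOddsMatrix,
    threshold: float = -math.inf,
    region_id: str = "",
) -> list[MotifHit]:
    """All matches of a motif on both strands of a sequence.

    A minus-strand hit at offset ``o`` means the reverse complement of
    ``seq[o:o+L]`` matches the motif; its score equals the score of the
    reverse-complement matrix on the forward window.  Hits are returned
    sorted by offset, plus strand first on ties.
    """
    codes = encode(seq)
    hits: list[MotifHit] = []
    for strand, mat in (("+", lom), ("-", lom.reverse_complement())):
        scores = _window_scores(codes, mat.weights)
        for o in np.flatnonzero(scores >= threshold):
            hits.append(
                MotifHit(region_id, int(o), strand, float(scores[o]), lom.name, lom.length)
            )
    hits.sort(key=lambda h: (h.offset, h.strand != "+", -h.score))
    return hits


def best_match_score(seq: str, lom: LogOddsMatrix) -> float:
    """Highest score over all positions and strands; -inf if no window fits."""
    codes = encode(seq)
    best = -math.inf
    for mat in (lom, lom.reverse_complement()):
        scores = _window_scores(codes, mat.weights)
        if scores.size:
            best = max(best, float(scores.max()))
    return best


def assemble_composite(
    part_a: PositionFrequencyMatrix,
    part_b: PositionFrequencyMatrix,
    spacer_bp: int = 0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    name: str | None = None,
) -> PositionFrequencyMatrix:
    """Concatenate A ++ spacer ++ B into one scannable matrix.

    Spacer columns equal the background distribution, so after
    :func:`build_logodds` they contribute exactly zero to any score.
    """
    bg = np.asarray(background, dtype=float)
    spacer = np.tile(bg[:, None], (1, spacer_bp)) if spacer_bp else np.empty((4, 0))
    probs = np.hstack([part_a.probs, spacer, part_b.probs])
    name = name or f"{part_a.name}+{spacer_bp}+{part_b.name}"
    return PositionFrequencyMatrix(name=name, probs=probs)


def min_pair_distance(
    hits_ebf: Sequence[MotifHit],
    hits_lhx2: Sequence[MotifHit],
) -> int | None:
    """Closest Ebf–Lhx2 motif-pair gap in one region, or None.

    For each Ebf hit, the edge-to-edge bp gap to its nearest Lhx2 hit
    (overlapping hits count as 0); the region's value is the minimum over
    Ebf hits.  Regions without an Ebf hit are excluded (None); a region
    with Ebf hits but no Lhx2 hit likewise has no defined pair.
    """
    if not hits_ebf or not hits_lhx2:
        return None
    best = None
    for e in hits_ebf:
        for l in hits_lhx2:
            gap = max(0, l.offset - e.end, e.offset - l.end)
            if best is None or gap < best:
                best = gap
    return best


def pair_distances_by_region(
    hits_ebf: Iterable[MotifHit],
    hits_lhx2: Iterable[MotifHit],
) -> dict[str, int]:
    """Per-region closest-pair distances, dropping regions without an Ebf hit."""
    by_e: dict[str, list[MotifHit]] = {}
    by_l: dict[str, list[MotifHit]] = {}
    for h in hits_ebf:
        by_e.setdefault(h.region_id, []).append(h)
    for h in hits_lhx2:
        by_l.setdefault(h.region_id, []).append(h)
    out: dict[str, int] = {}
    for rid, ehits in by_e.items():
        d = min_pair_distance(ehits, by_l.get(rid, []))
        if d is not None:
            out[rid] = d
    return out


def _dplus(s1: np.ndarray, s2: np.ndarray) -> float:
    """sup_x (F1(x) - F2(x)) over the pooled support."""
    grid = np.union1d(s1, s2)
    f1 = np.searchsorted(np.sort(s1), grid, side="right") / len(s1)
    f2 = np.searchsorted(np.sort(s2), grid, side="right") / len(s2)
    return float(np.max(f1 - f2))


def ks_one_sided(
    sample1: Sequence[float],
    sample2: Sequence[float],
    alternative: str = "smaller",
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov–Smirnov test.

    ``alternative='smaller'`` tests whether sample1 is stochastically
    smaller than sample2 (its CDF lies above): D = sup_x (F1 - F2).  The
    p-value is the asymptotic tail exp(-2 m D^2) with m = n1*n2/(n1+n2);
    for n1+n2 <= 12 the exact permutation null is enumerated instead.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative == "greater":
        s1, s2 = s2, s1
    elif alternative != "smaller":
        raise ValueError("alternative must be 'smaller' or 'greater'")
    n1, n2 = len(s1), len(s2)
    d = _dplus(s1, s2)
    if n1 + n2 <= 12:
        pooled = np.concatenate([s1, s2])
        idx = range(n1 + n2)
        count = 0
        total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            if _dplus(pooled[mask], pooled[~mask]) >= d - 1e-12:
                count += 1
            total += 1
        return d, count / total
    m = n1 * n2 / (n1 + n2)
    return d, float(min(1.0, math.exp(-2.0 * m * d * d)))


def score_cdf(
    scores: Sequence[float],
    thresholds: Sequence[float] = (10.0, 5.0),
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Empirical CDF of per-region best composite scores.

    Returns the step table (score, cumulative fraction <= score) and, for
    each threshold, the fraction of regions scoring strictly above it
    (regions with no scannable site, score -inf, never exceed any
    threshold).
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores supplied")
    finite = np.sort(s)
    cdf = pd.DataFrame(
        {"score": finite, "cum_fraction": np.arange(1, s.size + 1) / s.size}
    )
    above = {float(t): float(np.mean(s > t)) for t in thresholds}
    return cdf, above


def nucleotide_class_matrix(seqs: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
    """Purine/pyrimidine class view of an alignment.

    Returns a rows x positions character matrix over {R, Y, N} (R=purine
    A/G, Y=pyrimidine C/T, N=other) plus per-column class frequencies
    computed over classified bases.
    """
    if not seqs:
        raise ValueError("empty alignment")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    mat = np.empty((len(seqs), L), dtype="<U1")
    for i, s in enumerate(seqs):
        for j, b in enumerate(s.upper()):
            mat[i, j] = "R" if b in PURINES else ("Y" if b in PYRIMIDINES else "N")
    rows = []
    for j in range(L):
        col = mat[:, j]
        n_r = int(np.sum(col == "R"))
        n_y = int(np.sum(col == "Y"))
        tot = n_r + n_y
        rows.append(
            {
                "position": j,
                "purine": n_r / tot if tot else np.nan,
                "pyrimidine": n_y / tot if tot else np.nan,
            }
        )
    return mat, pd.DataFrame(rows)
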