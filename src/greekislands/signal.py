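"""Fragment-level accessibility signal: insertion sites, tracks, profiles.

ATAC fragments are intervals whose two ends mark transposase insertion
events; each end is shifted 4 bp toward the fragment interior to recover
the true insertion site.  All tracks are normalised to a library size of
10 million reads (values are "reads per 10 million").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "FragmentSet",
    "InsertionSites",
    "SignalTrack",
    "ProfileMatrix",
    "shift_to_insertions",
    "coverage_track",
    "end_density_profile",
    "region_count_matrix",
    "profile_heatmap",
    "subtract_tracks",
]

INSERTION_SHIFT = 4  # bp moved toward the fragment interior, per end
MIN_SHIFTABLE = 2 * INSERTION_SHIFT + 1  # shorter fragments collapse to midpoint


@dataclass
class FragmentSet:
    """Paired-end fragments for one sample plus the sample's library size."""

    name: str
    fragments: list[GenomicInterval]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.fragments):
            raise ValueError("library_size must be >= number of fragments")


@dataclass
class InsertionSites:
    """Per-end insertion positions; two per fragment."""

    sites: list[tuple[str, int]]
    n_clamped: int = 0  # fragments too short to shift, collapsed to midpoint

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for chrom, bp in self.sites:
            out.setdefault(chrom, []).append(bp)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}


def shift_to_insertions(fragments: FragmentSet) -> InsertionSites:
    """Shift both fragment ends 4 bp inward to the Tn5 insertion sites.

    A fragment [start, end) yields sites at start+4 and end-4.  Fragments
    shorter than 9 bp cannot hold two shifted ends; both sites clamp to
    the midpoint and the fragment is counted as flagged.
    """
    sites: list[tuple[str, int]] = []
    clamped = 0
    for fr in fragments.fragments:
        if fr.length < MIN_SHIFTABLE:
            mid = (fr.start + fr.end) // 2
            sites.append((fr.chrom, mid))
            sites.append((fr.chrom, mid))
            clamped += 1
        else:
            sites.append((fr.chrom, fr.start + INSERTION_SHIFT))
            sites.append((fr.chrom, fr.end - INSERTION_SHIFT))
    return InsertionSites(sites=sites, n_clamped=clamped)


@dataclass
class SignalTrack:
    """Per-bp signal per chromosome, normalised to reads per 10 million."""

    values: dict[str, np.ndarray]
    norm_factor: float  # 1e7 / library_size

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Window extraction padded with zeros outside the chromosome."""
        out = np.zeros(end - start)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


def coverage_track(
    items: FragmentSet | InsertionSites,
    library_size: int | None = None,
    extend: str = "full",
    chrom_sizes: dict[str, int] | None = None,
) -> SignalTrack:
    """Per-bp coverage normalised to 10 million reads.

    ``extend='full'`` adds 1 over each full fragment [start, end);
    ``extend='1bp'`` adds 1 only at each insertion site.  Chromosome array
    lengths come from ``chrom_sizes`` or from the rightmost item.
    """
    if extend not in ("full", "1bp"):
        raise ValueError("extend must be 'full' or '1bp'")
    if isinstance(items, FragmentSet):
        lib = library_size if library_size is not None else items.library_size
    else:
        if library_size is None:
            raise ValueError("library_size required for insertion-site input")
        lib = library_size
    if lib <= 0:
        raise ValueError("library size must be positive")
    factor = 1e7 / lib

    sizes: dict[str, int] = dict(chrom_sizes or {})
    values: dict[str, np.ndarray] = {}

    def arr_for(chrom: str, needed: int) -> np.ndarray:
        if chrom not in values:
            values[chrom] = np.zeros(max(sizes.get(chrom, 0), needed))
        elif len(values[chrom]) < needed:
            values[chrom] = np.pad(values[chrom], (0, needed - len(values[chrom])))
        return values[chrom]

    if extend == "full":
        if not isinstance(items, FragmentSet):
            raise ValueError("full-fragment extension needs a FragmentSet")
        for fr in items.fragments:
            arr = arr_for(fr.chrom, fr.end)
            arr[fr.start : fr.end] += 1.0
    else:
        sites = (
            shift_to_insertions(items).sites
            if isinstance(items, FragmentSet)
            else items.sites
        )
        for chrom, bp in sites:
            arr = arr_for(chrom, bp + 1)
            arr[bp] += 1.0
    for chrom in values:
        values[chrom] *= factor
    for chrom, size in sizes.items():
        values.setdefault(chrom, np.zeros(size))
    return SignalTrack(values=values, norm_factor=factor)


def end_density_profile(
    sites: InsertionSites,
    centers: Sequence[tuple[str, int]],
    flank_bp: int = 100,
    bin_bp: int = 5,
) -> pd.DataFrame:
    """Mean insertion-site density around motif centers, in 5 bp windows.

    For every center, insertion sites in [center - flank, center + flank)
    are histogrammed at ``bin_bp`` resolution; the across-center mean and
    standard error are reported per bin (SEM is 0 with a single center).
    Returned frame columns: bin_start (bp relative to center), mean, sem.
    """
    if not centers:
        raise ValueError("at least one center is required")
    if 2 * flank_bp % bin_bp != 0:
        raise ValueError("2*flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    by_chrom = sites.by_chrom()
    counts = np.zeros((len(centers), n_bins))
    for i, (chrom, c) in enumerate(centers):
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, c - flank_bp, side="left")
        hi = np.searchsorted(arr, c + flank_bp, side="left")
        rel = (arr[lo:hi] - (c - flank_bp)) // bin_bp
        counts[i] = np.bincount(rel, minlength=n_bins)[:n_bins]
    mean = counts.mean(axis=0)
    if len(centers) > 1:
        sem = counts.std(axis=0, ddof=1) / np.sqrt(len(centers))
    else:
        sem = np.zeros(n_bins)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_bp - flank_bp,
            "mean": mean,
            "sem": sem,
        }
    )


def region_count_matrix(
    fragment_sets: dict[str, FragmentSet],
    peaks: PeakSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment counts per peak per sample, raw and per-10-million normalised.

    A fragment is counted in every peak it overlaps by >= 1 bp (a fragment
    spanning two adjacent peaks contributes to both).
    """
    peak_ids = [iv.id or f"{peaks.name}_{i}" for i, iv in enumerate(peaks)]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(peaks):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    starts = {c: np.array([t[0] for t in v]) for c, v in by_chrom.items()}

    counts = pd.DataFrame(0, index=peak_ids, columns=list(fragment_sets), dtype=int)
    for sample, fs in fragment_sets.items():
        col = np.zeros(len(peak_ids), dtype=int)
        for fr in fs.fragments:
            entries = by_chrom.get(fr.chrom)
            if not entries:
                continue
            # peaks are sorted; only those starting before fragment end can overlap
            j = np.searchsorted(starts[fr.chrom], fr.end, side="left")
            for s, e, idx in entries[:j]:
                if e > fr.start:
                    col[idx] += 1
        counts[sample] = col
    norm = counts.astype(float)
    for sample, fs in fragment_sets.items():
        if fs.library_size <= 0:
            raise ValueError(f"{sample}: library size must be positive")
        norm[sample] = counts[sample] * (1e7 / fs.library_size)
    return counts, norm


@dataclass
class ProfileMatrix:
    """Region x position matrix of normalised signal, deterministically ordered."""

    values: np.ndarray
    row_ids: list[str]
    col_coords: np.ndarray  # bp offsets relative to region anchor
    sort_order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def profile_heatmap(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    flank_bp: int,
    scale_body: int | None = None,
    sort_order: Sequence[int] | None = None,
) -> ProfileMatrix:
    """Per-region signal rows for heatmap display.

    Without ``scale_body`` each row is the window center±flank at 1 bp
    resolution.  With it, the region body is linearly rescaled to
    ``scale_body`` bp and flanked by fixed ``flank_bp`` margins.  Rows of
    minus-strand regions are reversed so all rows read 5'→3'.  Rows are
    sorted by descending mean signal over the row unless an explicit order
    is supplied; ties keep input order (stable sort).
    """
    rows = []
    ids = []
    for i, reg in enumerate(regions):
        if scale_body is None:
            center = (reg.start + reg.end) // 2
            row = track.get(reg.chrom, center - flank_bp, center + flank_bp)
        else:
            body = track.get(reg.chrom, reg.start, reg.end)
            if len(body) == scale_body:
                scaled = body
            else:
                src = np.linspace(0, len(body) - 1, num=scale_body)
                scaled = np.interp(src, np.arange(len(body)), body)
            left = track.get(reg.chrom, reg.start - flank_bp, reg.start)
            right = track.get(reg.chrom, reg.end, reg.end + flank_bp)
            row = np.concatenate([left, scaled, right])
        if reg.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(reg.id or f"region_{i}")
    values = np.vstack(rows) if rows else np.empty((0, 0))
    if sort_order is None:
        order = np.argsort(-values.mean(axis=1), kind="stable") if rows else np.empty(0, int)
    else:
        order = np.asarray(sort_order, dtype=int)
    width = values.shape[1] if rows else 0
    if scale_body is None:
        coords = np.arange(width) - flank_bp
    else:
        coords = np.arange(width) - flank_bp  # 0 marks the (scaled) body start
    return ProfileMatrix(
        values=values[order] if rows else values,
        row_ids=[ids[i] for i in order],
        col_coords=coords,
        sort_order=order,
    )


def subtract_tracks(signal: SignalTrack, control: SignalTrack) -> SignalTrack:
    """Display-only input subtraction, clipped at zero."""
    out: dict[str, np.ndarray] = {}
    for chrom, arr in signal.values.items():
        ctl = control.values.get(chrom, np.zeros_like(arr))
        n = min(len(arr), len(ctl))
        diff = arr.copy()
        diff[:n] = np.clip(arr[:n] - ctl[:n], 0.0, None)
        out[chrom] = diff
    return SignalTrack(values=out, norm_factor=signal.norm_factor)
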