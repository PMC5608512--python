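"""RNA-seq post-processing: normalisation, fold changes, island distance.

Counts are normalised with median-of-ratios size factors; differential
expression is summarised as base mean and log2 fold change (genes with
normalised base mean < 5 are flagged for exclusion from density/scatter
views).  OR genes are stratified by their distance to the nearest Greek
Island, with two sentinel conventions: distance 1 for genes overlapping an
island and 1e8 for genes on a chromosome carrying no island at all.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, PeakSet, nearest_distance

__all__ = [
    "size_factors",
    "fold_changes",
    "fpkm",
    "distance_to_island",
    "group_by_promoter_binding",
    "topk_category_enrichment",
    "NO_ISLAND_ON_CHROM",
    "OVERLAPS_ISLAND",
    "BASE_MEAN_FLOOR",
]

OVERLAPS_ISLAND = 1.0
NO_ISLAND_ON_CHROM = 1e8
BASE_MEAN_FLOOR = 5.0  # normalised base mean below which genes are flagged


def size_factors(
    counts: pd.DataFrame,
    control_genes: Sequence[str] | None = None,
) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Each sample's factor is the median, over genes expressed in every
    sample, of that sample's count divided by the gene's geometric mean
    across samples.

    When a large, known fraction of the transcriptome changes between
    conditions (here: a global OR knockdown), the all-gene median absorbs
    part of the shift; pass ``control_genes`` (e.g. the non-OR genes) to
    estimate depth from genes expected to be stable, the usual
    control-gene normalisation.
    """
    if control_genes is not None:
        counts = counts.loc[counts.index.intersection(list(control_genes))]
        if counts.empty:
            raise ValueError("no control genes present in the count matrix")
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def fold_changes(
    counts: pd.DataFrame,
    factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-gene base mean and log2 fold change (B over A) from normalised counts.

    base_mean is the mean normalised count over *all* samples; log2fc is
    log2((mean_B + pseudo) / (mean_A + pseudo)).  Genes whose base mean
    falls below 5 get ``excluded=True`` for downstream density/scatter use.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    norm = counts / factors
    base_mean = norm.mean(axis=1)
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "excluded": base_mean < BASE_MEAN_FLOOR,
        }
    )


def fpkm(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene_lengths: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase per million factor-normalised library fragments."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    norm = counts / factors
    lib = norm.sum(axis=0)  # factor-normalised library size per sample
    if (lib <= 0).any():
        raise ValueError("zero normalised library size")
    return norm.mul(1e9).div(lib, axis=1).div(lengths, axis=0)


def distance_to_island(
    genes: Sequence[GeneModel],
    islands: Sequence[GenomicInterval],
) -> pd.Series:
    """bp distance from each gene span to the nearest island, with sentinels.

    Overlapping an island → 1; a chromosome with no island → 1e8;
    otherwise the edge-to-edge gap (floored at 1 so the overlap sentinel
    stays unambiguous).
    """
    island_chroms = {iv.chrom for iv in islands}
    out = {}
    for g in genes:
        span = g.span
        if g.chrom not in island_chroms:
            out[g.gene_id] = NO_ISLAND_ON_CHROM
            continue
        best = np.inf
        for iv in islands:
            if iv.chrom != g.chrom:
                continue
            if span.overlaps(iv):
                best = 0.0
                break
            best = min(best, span.gap_to(iv))
        out[g.gene_id] = OVERLAPS_ISLAND if best == 0.0 else max(best, 1.0)
    return pd.Series(out, name="distance_to_island")


def group_by_promoter_binding(
    genes: Sequence[GeneModel],
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    window_bp: int = 1000,
) -> pd.Series:
    """Group genes by which factors bind within ``window_bp`` of the TSS.

    Returns per-gene labels in {both, A-only, B-only, none}; a factor
    counts as bound when any of its peaks lies within the window of the
    TSS point (overlap distance 0 included).
    """
    tss_points = [(g.chrom, g.tss) for g in genes]
    dist_a = nearest_distance(tss_points, peaks_a.intervals)
    dist_b = nearest_distance(tss_points, peaks_b.intervals)
    labels = []
    for da, db in zip(dist_a, dist_b):
        a = da <= window_bp
        b = db <= window_bp
        labels.append("both" if a and b else "A-only" if a else "B-only" if b else "none")
    return pd.Series(labels, index=[g.gene_id for g in genes], name="promoter_group")


def topk_category_enrichment(
    ranked_genes: Sequence[str],
    k: int,
    category_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of a category among the top k.

    ``ranked_genes`` is the full ranking (most extreme first, e.g. most
    downregulated).  Returns (overlap count, p-value) where p is
    P(X >= overlap) for X ~ Hypergeom(|universe|, |category|, k).
    """
    if not category_set <= universe:
        raise ValueError("category_set must be a subset of the universe")
    if k > len(universe):
        raise ValueError("k cannot exceed the universe size")
    top = list(ranked_genes)[:k]
    if len(top) < k:
        raise ValueError("ranking shorter than k")
    x = sum(1 for g in top if g in category_set)
    p = float(stats.hypergeom.sf(x - 1, len(universe), len(category_set), k))
    return x, p
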