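"""Synthetic genomes with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study system:

* OR gene clusters scattered over a few chromosomes, one of which carries
  clusters but no enhancer (exercising the "no island on this chromosome"
  distance sentinel);
* transcription-factor peaks whose co-occurrence rate is high at planted
  island sites and low elsewhere, observed through two jittered replicates
  per factor;
* broad repressive-mark (H3K9me3-like) coverage elevated ~4x over clusters
  with local dips at islands;
* region sequences carrying composite Lhx2+Ebf motifs at controlled
  spacing versus dispersed or single half-sites;
* ATAC-like fragments whose insertion ends are depleted around occupied
  motifs (the footprint);
* negative-binomial expression counts with a condition-specific OR
  knockdown.

Every stage draws from its own seeded stream (config seed + stage tag), so
stages can be regenerated independently and reruns are byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet
from .islands import BinnedCoverage
from .motifs import (
    ALPHABET,
    PositionFrequencyMatrix,
    assemble_composite,
)
from .signal import FragmentSet

__all__ = [
    "SimulationConfig",
    "Annotation",
    "SimulatedPeaks",
    "SimulatedSequences",
    "default_lhx2_pfm",
    "default_ebf_pfm",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_domain_bins",
    "simulate_sequences",
    "simulate_fragments",
    "simulate_counts",
]

# genome-wide peak-label composition: co-bound, Lhx2-only, Ebf-only tallies
# (4729 / 11468 / 4230 loci)
_BG_CO, _BG_A_ONLY, _BG_B_ONLY = 4729, 11468, 4230
_BG_TOTAL = _BG_CO + _BG_A_ONLY + _BG_B_ONLY


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study conditions as defaults."""

    seed: int = 0
    # genome & annotation
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 8_000_000, "chr3": 4_000_000}
    )
    clusters_per_chrom: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5, "chr2": 4, "chr3": 1}
    )
    island_free_chroms: tuple[str, ...] = ("chr3",)
    cluster_length_range: tuple[int, int] = (200_000, 400_000)
    n_islands: int = 63
    n_genes: int = 1000
    or_fraction: float = 0.3
    gene_length_range: tuple[int, int] = (1_000, 10_000)
    # peaks
    peak_width_range: tuple[int, int] = (150, 300)
    replicate_jitter_bp: int = 30
    n_background_peaks: int = 5000
    p_co_out: float = _BG_CO / _BG_TOTAL       # ~0.2315
    p_a_only_out: float = _BG_A_ONLY / _BG_TOTAL
    p_co_in: float = 0.0  # non-island in-cluster peaks are singly bound
    n_a_only_in: int = 51  # Lhx2-only peaks inside clusters
    n_b_only_in: int = 2   # Ebf-only peaks inside clusters
    # repressive-mark coverage
    window_bp: int = 2000
    step_bp: int = 1000
    input_mean_per_window: float = 50.0
    cluster_fold: float = 4.0
    island_dip_factor: float = 0.25
    # sequences & motifs
    region_length: int = 200
    n_composite_regions: int = 100
    n_dispersed_regions: int = 100
    n_single_site_regions: int = 20
    composite_spacer_bp: int = 0
    dispersed_gap_range: tuple[int, int] = (40, 120)
    # fragments / footprint
    n_footprint_sites: int = 500
    fragments_per_site: int = 20
    footprint_depletion: float = 0.5
    footprint_halfwidth: int = 10
    site_flank: int = 200
    # expression counts
    n_samples_per_condition: int = 3
    nb_dispersion: float = 0.1
    knockdown_fold: float = 0.25
    mean_log_mu: float = float(np.log(200.0))
    mean_log_sigma: float = 1.0
    depth_factor_range: tuple[float, float] = (0.8, 1.2)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream per generator stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("island_free_chroms",):
            if key in d:
                d[key] = tuple(d[key])
        for key in (
            "cluster_length_range", "gene_length_range", "peak_width_range",
            "dispersed_gap_range", "depth_factor_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sharp_col(base: str, p: float = 0.997) -> np.ndarray:
    col = np.full(4, (1 - p) / 3)
    col[ALPHABET.index(base)] = p
    return col


def _soft_col(base: str, p: float = 0.28) -> np.ndarray:
    col = np.full(4, (1 - p) / 3)
    col[ALPHABET.index(base)] = p
    return col


def default_lhx2_pfm() -> PositionFrequencyMatrix:
    """Synthetic 6-mer homeodomain-like site with a sharp TAATT core."""
    cols = [_soft_col("C")] + [_sharp_col(b) for b in "TAATT"]
    return PositionFrequencyMatrix("Lhx2", np.column_stack(cols))


def default_ebf_pfm() -> PositionFrequencyMatrix:
    """Synthetic 10-mer Ebf-like half site, palindromic TCCC..GGGA flavour."""
    cols = [
        _soft_col("T"),
        _sharp_col("C"),
        _sharp_col("C"),
        _sharp_col("C"),
        _soft_col("T"),
        _soft_col("A"),
        _sharp_col("G"),
        _sharp_col("G"),
        _soft_col("G"),
        _soft_col("A"),
    ]
    return PositionFrequencyMatrix("Ebf", np.column_stack(cols))


@dataclass
class Annotation:
    clusters: list[GenomicInterval]
    genes: list[GeneModel]
    islands: list[GenomicInterval]  # planted truth


def _place_in_slots(rng: np.random.Generator, chrom: str, size: int, n: int,
                    lengths: np.ndarray, margin: int) -> list[tuple[int, int]]:
    """Place n non-overlapping intervals by jittering one per equal slot."""
    slot = (size - 2 * margin) // n
    out = []
    for i in range(n):
        length = int(lengths[i])
        if length >= slot:
            raise ValueError(
                f"{chrom}: cannot pack {n} features of length {length} (slot {slot})"
            )
        lo = margin + i * slot
        start = int(rng.integers(lo, lo + slot - length))
        out.append((start, start + length))
    return out


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Clusters, genes (ORs inside clusters) and planted island truth."""
    rng = config.rng("annotation")
    clusters: list[GenomicInterval] = []
    for chrom, n in config.clusters_per_chrom.items():
        if n == 0:
            continue
        size = config.chrom_sizes[chrom]
        lengths = rng.integers(*config.cluster_length_range, size=n)
        for start, end in _place_in_slots(rng, chrom, size, n, lengths, margin=100_000):
            clusters.append(GenomicInterval(chrom, start, end))
    clusters.sort(key=GenomicInterval.sort_key)
    clusters = [
        GenomicInterval(c.chrom, c.start, c.end, id=f"cluster_{i}")
        for i, c in enumerate(clusters)
    ]

    # distribute islands round-robin over clusters on island-bearing chromosomes
    eligible = [c for c in clusters if c.chrom not in config.island_free_chroms]
    if config.n_islands > 0 and not eligible:
        raise ValueError("no eligible clusters to host islands")
    islands: list[GenomicInterval] = []
    per_cluster = [0] * len(eligible)
    for k in range(config.n_islands):
        per_cluster[k % len(eligible)] += 1
    for c, n_isl in zip(eligible, per_cluster):
        if n_isl == 0:
            continue
        # 5 kb grid inside the cluster, 5 kb margins: guaranteed separation
        grid = np.arange(c.start + 5_000, c.end - 5_000, 5_000)
        if len(grid) < n_isl:
            raise ValueError(f"{c.id}: cluster too small for {n_isl} islands")
        centers = np.sort(rng.choice(grid, size=n_isl, replace=False))
        widths = rng.integers(*config.peak_width_range, size=n_isl)
        for ctr, w in zip(centers, widths):
            islands.append(GenomicInterval(c.chrom, int(ctr - w // 2), int(ctr - w // 2 + w)))
    islands.sort(key=GenomicInterval.sort_key)
    islands = [
        GenomicInterval(iv.chrom, iv.start, iv.end, id=f"island_{i}")
        for i, iv in enumerate(islands)
    ]

    # genes: ORs uniformly over clusters, non-ORs over inter-cluster space
    n_or = int(round(config.n_genes * config.or_fraction))
    genes: list[GeneModel] = []
    glengths = rng.integers(*config.gene_length_range, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    cluster_cycle = [clusters[i % len(clusters)] for i in range(n_or)]
    for i in range(n_or):
        c = cluster_cycle[i]
        length = int(glengths[i])
        start = int(rng.integers(c.start, c.end - length))
        tss, tes = (start, start + length) if strands[i] == "+" else (start + length, start)
        genes.append(GeneModel(f"OR_{i:04d}", c.chrom, tss, tes, strands[i], "OR"))
    free = _non_cluster_space(config, clusters)
    free_chrom, free_start, free_len = free
    cum = np.cumsum(free_len)
    for i in range(n_or, config.n_genes):
        length = int(glengths[i])
        # pick a free segment weighted by length, then a position inside it
        r = rng.integers(0, cum[-1])
        seg = int(np.searchsorted(cum, r, side="right"))
        lo = free_start[seg]
        hi = free_start[seg] + free_len[seg] - length
        start = int(rng.integers(lo, max(lo + 1, hi)))
        tss, tes = (start, start + length) if strands[i] == "+" else (start + length, start)
        genes.append(
            GeneModel(f"gene_{i:04d}", free_chrom[seg], tss, tes, strands[i], "non-OR")
        )
    return Annotation(clusters=clusters, genes=genes, islands=islands)


def _non_cluster_space(
    config: SimulationConfig, clusters: Sequence[GenomicInterval], margin: int = 50_000
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Free segments (chrom, start, length) outside clusters, with margins."""
    chroms: list[str] = []
    starts: list[int] = []
    lens: list[int] = []
    for chrom, size in config.chrom_sizes.items():
        edges = [(c.start, c.end) for c in clusters if c.chrom == chrom]
        edges.sort()
        prev = margin
        for s, e in edges + [(size - margin, size - margin)]:
            if s - margin - prev > 100_000:
                chroms.append(chrom)
                starts.append(prev)
                lens.append(s - margin - prev)
            prev = e + margin
    return chroms, np.asarray(starts), np.asarray(lens)


@dataclass
class SimulatedPeaks:
    replicates: dict[str, PeakSet]  # lhx2_rep1/2, ebf_rep1/2
    chip_bins: BinnedCoverage
    input_bins: BinnedCoverage
    background_labels: pd.DataFrame  # locus position + label truth


def _jitter(rng: np.random.Generator, start: int, end: int, j: int) -> tuple[int, int]:
    s = start + int(rng.integers(-j, j + 1))
    e = end + int(rng.integers(-j, j + 1))
    if e - s < 20:  # keep a sliver of peak even under extreme jitter
        e = s + 20
    return max(0, s), e


def simulate_peaks(config: SimulationConfig, ann: Annotation) -> SimulatedPeaks:
    """Factor peaks in two replicates plus binned repressive-mark coverage.

    Islands yield co-bound peaks (both factors, both replicates, ±jitter);
    clusters additionally hold singly bound peaks; outside clusters,
    background loci draw their label (co-bound / Lhx2-only / Ebf-only)
    from the configured genome-wide frequencies.  Loci are laid out on a
    1 kb grid so that distinct loci can never collide into accidental
    co-binding.
    """
    rng = config.rng("peaks")
    j = config.replicate_jitter_bp
    peaks: dict[str, list[GenomicInterval]] = {
        "lhx2_rep1": [], "lhx2_rep2": [], "ebf_rep1": [], "ebf_rep2": []
    }

    def add_locus(chrom: str, start: int, end: int, factors: Sequence[str]) -> None:
        for factor in factors:
            if factor == "ebf":
                # slight offset between the two factors' summits, overlap kept
                shift = int(rng.integers(-40, 41))
                s, e = start + shift, end + shift
            else:
                s, e = start, end
            for rep in ("rep1", "rep2"):
                rs, re = _jitter(rng, s, e, j)
                peaks[f"{factor}_{rep}"].append(GenomicInterval(chrom, rs, re))

    for isl in ann.islands:
        add_locus(isl.chrom, isl.start, isl.end, ("lhx2", "ebf"))

    # singly bound loci inside clusters, kept clear of islands
    island_centers = {
        c.id: [
            (iv.start + iv.end) // 2 for iv in ann.islands if c.overlaps(iv)
        ]
        for c in ann.clusters
    }
    single_specs = [("lhx2",)] * config.n_a_only_in + [("ebf",)] * config.n_b_only_in
    co_in = [("lhx2", "ebf")] * int(round(config.p_co_in * len(single_specs)))
    in_specs = single_specs + co_in
    for k, factors in enumerate(in_specs):
        c = ann.clusters[k % len(ann.clusters)]
        taken = island_centers[c.id]
        width = int(rng.integers(*config.peak_width_range))
        for _ in range(200):
            ctr = int(rng.integers(c.start + 2_000, c.end - 2_000))
            if all(abs(ctr - t) > 2_000 for t in taken):
                break
        else:
            raise RuntimeError("could not place in-cluster background peak")
        taken.append(ctr)
        add_locus(c.chrom, ctr - width // 2, ctr - width // 2 + width, factors)

    # background loci outside clusters on a 1 kb grid (no accidental overlap)
    free_chrom, free_start, free_len = _non_cluster_space(config, ann.clusters)
    grid_chrom: list[str] = []
    grid_pos: list[np.ndarray] = []
    for chrom, start, length in zip(free_chrom, free_start, free_len):
        pts = np.arange(start + 500, start + length - 500, 1_000)
        grid_chrom.extend([chrom] * len(pts))
        grid_pos.append(pts)
    grid_pos_arr = np.concatenate(grid_pos)
    if len(grid_pos_arr) < config.n_background_peaks:
        raise ValueError("genome too small for the requested background peaks")
    pick = np.sort(rng.choice(len(grid_pos_arr), size=config.n_background_peaks,
                              replace=False))
    u = rng.random(config.n_background_peaks)
    widths = rng.integers(*config.peak_width_range, size=config.n_background_peaks)
    rows = []
    for idx, pu, w in zip(pick, u, widths):
        chrom, ctr = grid_chrom[idx], int(grid_pos_arr[idx])
        if pu < config.p_co_out:
            label, factors = "co-bound", ("lhx2", "ebf")
        elif pu < config.p_co_out + config.p_a_only_out:
            label, factors = "lhx2-only", ("lhx2",)
        else:
            label, factors = "ebf-only", ("ebf",)
        add_locus(chrom, ctr - int(w) // 2, ctr - int(w) // 2 + int(w), factors)
        rows.append({"chrom": chrom, "center": ctr, "label": label})
    background = pd.DataFrame(rows)

    replicate_sets = {
        name: PeakSet.from_intervals(name, ivs, autoname=True)
        for name, ivs in peaks.items()
    }

    chip_bins, input_bins = _repressive_coverage(config, ann, rng)
    return SimulatedPeaks(
        replicates=replicate_sets,
        chip_bins=chip_bins,
        input_bins=input_bins,
        background_labels=background,
    )


def _overlap_fractions(
    config: SimulationConfig,
    sizes: dict[str, int],
    elevated: Sequence[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Per-window fraction of each window covered by elevated features."""
    win, step = config.window_bp, config.step_bp
    out: dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        n = (size - win) // step + 1
        starts = np.arange(n) * step
        ends = starts + win
        frac = np.zeros(n)
        for iv in elevated:
            if iv.chrom != chrom:
                continue
            ov = np.clip(np.minimum(ends, iv.end) - np.maximum(starts, iv.start), 0, None)
            frac += ov / win
        out[chrom] = np.clip(frac, 0, 1)
    return out


def _raw_fold(config: SimulationConfig, fracs: dict[str, np.ndarray]) -> float:
    """Raw per-window fold producing ``cluster_fold`` after library normalisation.

    Total-count normalisation deflates enrichment by the enriched mass in
    the chip library: a raw fold f over a fraction phi of windows shows as
    f / (1 + (f-1)*phi).  Invert so the configured fold is the one the
    caller actually sees.
    """
    n = sum(len(a) for a in fracs.values())
    phi = sum(float(a.sum()) for a in fracs.values()) / n
    denom = 1.0 - config.cluster_fold * phi
    if denom <= 0:
        raise ValueError(
            f"enriched fraction {phi:.2f} too large for normalised fold "
            f"{config.cluster_fold}; enlarge the genome or shrink the domains"
        )
    return config.cluster_fold * (1.0 - phi) / denom


def _binned_tracks(
    config: SimulationConfig,
    rng: np.random.Generator,
    sizes: dict[str, int],
    elevated: Sequence[GenomicInterval],
    dips: Sequence[GenomicInterval],
) -> tuple[BinnedCoverage, BinnedCoverage]:
    fracs = _overlap_fractions(config, sizes, elevated)
    f_raw = _raw_fold(config, fracs)
    win, step = config.window_bp, config.step_bp
    chip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for chrom, frac in fracs.items():
        means = config.input_mean_per_window * (1 + (f_raw - 1) * frac)
        starts = np.arange(len(frac)) * step
        ends = starts + win
        for iv in dips:
            if iv.chrom != chrom:
                continue
            hit = (starts < iv.end) & (ends > iv.start)
            means[hit] *= config.island_dip_factor
        chip[chrom] = rng.poisson(means).astype(np.int64)
        inp[chrom] = rng.poisson(
            np.full(len(frac), config.input_mean_per_window)
        ).astype(np.int64)
    lib_chip = int(sum(a.sum() for a in chip.values()))
    lib_inp = int(sum(a.sum() for a in inp.values()))
    return (
        BinnedCoverage(win, step, chip, lib_chip),
        BinnedCoverage(win, step, inp, lib_inp),
    )


def _repressive_coverage(
    config: SimulationConfig, ann: Annotation, rng: np.random.Generator
) -> tuple[BinnedCoverage, BinnedCoverage]:
    return _binned_tracks(config, rng, config.chrom_sizes, ann.clusters, ann.islands)


def simulate_domain_bins(
    config: SimulationConfig,
    domains: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[BinnedCoverage, BinnedCoverage]:
    """Binned chip/input coverage with given enriched domains (no dips).

    A standalone fixture for exercising the region caller against an
    arbitrary truth set of domains.
    """
    rng = config.rng("domain-bins")
    sizes = dict(chrom_sizes or config.chrom_sizes)
    return _binned_tracks(config, rng, sizes, domains, dips=())


@dataclass
class SimulatedSequences:
    sequences: dict[str, str]
    truth: pd.DataFrame  # region_id, label, lhx2_offset, ebf_offset, gap, strand


def _sample_site(rng: np.random.Generator, pfm: PositionFrequencyMatrix) -> str:
    return "".join(
        ALPHABET[rng.choice(4, p=pfm.probs[:, j])] for j in range(pfm.length)
    )


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def simulate_sequences(
    config: SimulationConfig,
    lhx2: PositionFrequencyMatrix | None = None,
    ebf: PositionFrequencyMatrix | None = None,
) -> SimulatedSequences:
    """Regions with planted composite, dispersed, or single motif sites.

    Composite regions embed Lhx2+spacer+Ebf sampled from the composite
    matrix; dispersed regions carry both half-sites >= 40 bp apart;
    single-site regions carry only an Lhx2 site (no Ebf motif), the case
    the proximity analysis excludes.  Sites land on a random strand.
    """
    rng = config.rng("sequences")
    lhx2 = lhx2 or default_lhx2_pfm()
    ebf = ebf or default_ebf_pfm()
    composite = assemble_composite(lhx2, ebf, config.composite_spacer_bp)
    L = config.region_length
    seqs: dict[str, str] = {}
    rows = []

    def random_seq(n: int) -> str:
        return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))

    def plant(seq: str, site: str, offset: int) -> str:
        return seq[:offset] + site + seq[offset + len(site):]

    for i in range(config.n_composite_regions):
        rid = f"composite_{i:03d}"
        seq = random_seq(L)
        site = _sample_site(rng, composite)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = site if strand == "+" else _revcomp(site)
        off = int(rng.integers(0, L - composite.length + 1))
        seqs[rid] = plant(seq, placed, off)
        if strand == "+":
            lhx2_off, ebf_off = off, off + lhx2.length + config.composite_spacer_bp
        else:
            ebf_off = off
            lhx2_off = off + ebf.length + config.composite_spacer_bp
        rows.append({"region_id": rid, "label": "composite", "lhx2_offset": lhx2_off,
                     "ebf_offset": ebf_off, "gap": config.composite_spacer_bp,
                     "strand": strand})

    for i in range(config.n_dispersed_regions):
        rid = f"dispersed_{i:03d}"
        seq = random_seq(L)
        gap = int(rng.integers(*config.dispersed_gap_range))
        first_is_lhx2 = rng.random() < 0.5
        len1 = lhx2.length if first_is_lhx2 else ebf.length
        len2 = ebf.length if first_is_lhx2 else lhx2.length
        span = len1 + gap + len2
        off1 = int(rng.integers(0, L - span + 1))
        off2 = off1 + len1 + gap
        s1 = _sample_site(rng, lhx2 if first_is_lhx2 else ebf)
        s2 = _sample_site(rng, ebf if first_is_lhx2 else lhx2)
        if rng.random() < 0.5:
            s1 = _revcomp(s1)
        if rng.random() < 0.5:
            s2 = _revcomp(s2)
        seq = plant(plant(seq, s1, off1), s2, off2)
        seqs[rid] = seq
        rows.append({"region_id": rid, "label": "dispersed",
                     "lhx2_offset": off1 if first_is_lhx2 else off2,
                     "ebf_offset": off2 if first_is_lhx2 else off1,
                     "gap": gap, "strand": "+"})

    for i in range(config.n_single_site_regions):
        rid = f"single_{i:03d}"
        seq = random_seq(L)
        off = int(rng.integers(0, L - lhx2.length + 1))
        site = _sample_site(rng, lhx2)
        if rng.random() < 0.5:
            site = _revcomp(site)
        seqs[rid] = plant(seq, site, off)
        rows.append({"region_id": rid, "label": "single-lhx2",
                     "lhx2_offset": off, "ebf_offset": -1, "gap": -1, "strand": "+"})

    return SimulatedSequences(sequences=seqs, truth=pd.DataFrame(rows))


def simulate_fragments(config: SimulationConfig) -> tuple[FragmentSet, list[tuple[str, int]]]:
    """ATAC-like fragments with a footprint at occupied motif sites.

    Sites sit 1 kb apart on a toy chromosome; per site, insertion ends are
    drawn from a flat density over ±site_flank that is multiplied by the
    depletion factor within ±footprint_halfwidth of the site center.
    Returns the fragments plus the site centers (profile anchors).
    """
    rng = config.rng("fragments")
    chrom = "chrF"
    centers = [(chrom, 500 + i * 1_000) for i in range(config.n_footprint_sites)]
    flank = config.site_flank
    hw = config.footprint_halfwidth
    dep = config.footprint_depletion
    frags: list[GenomicInterval] = []
    for _, c in centers:
        ends: list[int] = []
        need = 2 * config.fragments_per_site
        while len(ends) < need:
            x = int(rng.integers(c - flank, c + flank))
            if abs(x - c) <= hw and rng.random() >= dep:
                continue
            ends.append(x)
        for k in range(config.fragments_per_site):
            a, b = ends[2 * k], ends[2 * k + 1]
            lo, hi = min(a, b), max(a, b)
            # ends recoverable after the 4 bp interior shift
            frags.append(GenomicInterval(chrom, lo - 4, hi + 4))
    frags.sort(key=GenomicInterval.sort_key)
    fs = FragmentSet("footprint_sim", frags, library_size=len(frags))
    return fs, centers


def simulate_counts(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts with OR knockdown in the perturbed condition.

    Returns (counts genes x samples, condition labels per sample, true
    per-gene fold change).  Variance follows mean + dispersion * mean^2.
    """
    rng = config.rng("counts")
    n = config.n_samples_per_condition
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"pert_{i+1}" for i in range(n)]
    condition = pd.Series(["control"] * n + ["perturbed"] * n, index=samples,
                          name="condition")
    mu = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, size=len(genes))
    depth = rng.uniform(*config.depth_factor_range, size=len(samples))
    fold = pd.Series(
        [config.knockdown_fold if g.gene_class == "OR" else 1.0 for g in genes],
        index=[g.gene_id for g in genes],
        name="true_fold",
    )
    alpha = config.nb_dispersion
    r = 1.0 / alpha
    mat = np.empty((len(genes), len(samples)), dtype=np.int64)
    for s, d in enumerate(depth):
        m = mu * d * np.where(condition.iloc[s] == "perturbed", fold.to_numpy(), 1.0)
        p = r / (r + m)
        mat[:, s] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=fold.index, columns=samples)
    return counts, condition, fold
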