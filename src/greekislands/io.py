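"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open; gene annotation, fragments, counts and window
coverage travel as TSV; motif matrices as MEME minimal text; sequences as
FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval, PeakSet
from .islands import BinnedCoverage
from .motifs import ALPHABET, PositionFrequencyMatrix
from .signal import FragmentSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_genes",
    "write_genes",
    "read_fragments",
    "write_fragments",
    "read_fasta",
    "write_fasta",
    "read_meme",
    "write_meme",
    "read_binned_coverage",
    "write_binned_coverage",
    "write_bedgraph",
]


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or f'feature_{i}'}"
                f"\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            iv_id = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 else None
            strand = f[5] if len(f) > 5 else "."
            ivs.append(GenomicInterval(chrom, start, end, strand, score, iv_id))
    return PeakSet.from_intervals(name or Path(path).stem, ivs)


def write_genes(path: str | Path, genes: Sequence[GeneModel]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tss": g.tss,
                "tes": g.tes,
                "strand": g.strand,
                "gene_class": g.gene_class,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(r.gene_id, r.chrom, int(r.tss), int(r.tes), r.strand, r.gene_class)
        for r in df.itertuples()
    ]


def write_fragments(path: str | Path, frags: FragmentSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_size={frags.library_size}\n")
        for fr in frags.fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\n")


def read_fragments(path: str | Path, name: str | None = None) -> FragmentSet:
    lib = None
    frs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#library_size="):
                lib = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            frs.append(GenomicInterval(chrom, int(start), int(end)))
    return FragmentSet(name or Path(path).stem, frs, lib if lib is not None else len(frs))


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_meme(path: str | Path, pfms: Sequence[PositionFrequencyMatrix],
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal motif format (letter-probability matrices)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, background)) + "\n\n")
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.length} "
                f"nsites= 20 E= 0\n"
            )
            for col in pfm.probs.T:
                fh.write(" " + " ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[PositionFrequencyMatrix]:
    pfms = []
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                expect = int(line.split("w=")[1].split()[0])
                rows = []
            elif expect and line and name is not None:
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    probs = np.asarray(rows).T
                    # renormalise: MEME files are often printed at low precision
                    probs = probs / probs.sum(axis=0, keepdims=True)
                    pfms.append(PositionFrequencyMatrix(name, probs))
                    name, expect = None, 0
    return pfms


def write_binned_coverage(path: str | Path, bins: BinnedCoverage) -> None:
    with open(path, "w") as fh:
        fh.write(f"#window_bp={bins.window_bp}\t"
                 f"step_bp={bins.step_bp}\tlibrary_size={bins.library_size}\n")
        fh.write("chrom\twindow_index\tcount\n")
        for chrom in sorted(bins.counts):
            for i, c in enumerate(bins.counts[chrom]):
                fh.write(f"{chrom}\t{i}\t{int(c)}\n")


def read_binned_coverage(path: str | Path) -> BinnedCoverage:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(kv.split("=") for kv in header.split("\t"))
        df = pd.read_csv(fh, sep="\t")
    counts = {
        chrom: grp.sort_values("window_index")["count"].to_numpy()
        for chrom, grp in df.groupby("chrom")
    }
    return BinnedCoverage(
        window_bp=int(meta["window_bp"]),
        step_bp=int(meta["step_bp"]),
        counts=counts,
        library_size=int(meta["library_size"]),
    )


def write_bedgraph(path: str | Path, values: dict[str, np.ndarray]) -> None:
    """Run-length-encoded per-bp track as bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(values):
            arr = np.asarray(values[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
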