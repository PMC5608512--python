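"""End-to-end orchestration: simulate -> consensus -> regions -> islands ->
enrichment -> motifs -> proximity -> signal -> expression.

Each stage reads its inputs from the run directory (or from memory when
run in sequence) and writes deterministic text outputs, so partial reruns
work as long as the upstream files exist.  A manifest records the config
hash, seed, stage list and every output path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .expression import (
    distance_to_island,
    fold_changes,
    group_by_promoter_binding,
    size_factors,
    topk_category_enrichment,
)
from .intervals import GenomicInterval, PeakSet, cobound_peaks, consensus_peaks, intersect_classify
from .islands import (
    call_enriched_regions,
    call_greek_islands,
    classify_island_peak_types,
    cobinding_enrichment,
)
from .motifs import (
    best_match_score,
    build_logodds,
    ks_one_sided,
    pair_distances_by_region,
    scan_sequence,
    score_cdf,
    assemble_composite,
)
from .signal import end_density_profile, shift_to_insertions
from .simulate import (
    SimulationConfig,
    default_ebf_pfm,
    default_lhx2_pfm,
    simulate_annotation,
    simulate_counts,
    simulate_fragments,
    simulate_peaks,
    simulate_sequences,
)

__all__ = ["RunManifest", "STAGES", "run_pipeline", "load_config"]

log = logging.getLogger("greekislands")

STAGES = (
    "simulate",
    "consensus",
    "regions",
    "islands",
    "enrich",
    "motif-scan",
    "proximity",
    "signal-profile",
    "expression",
)

STRINGENT_THRESHOLD = 10.0
PERMISSIVE_THRESHOLD = 5.0
HALF_SITE_THRESHOLD = 5.0


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = "0.1.0"

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "outputs": self.outputs,
            "version": self.version,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def config_hash(config: SimulationConfig) -> str:
    canon = yaml.safe_dump(json.loads(json.dumps(config.to_dict())), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """Raised when a stage's upstream outputs are missing."""


def _need(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} needs {path.name}, produced by stage {produced_by!r}; "
            f"run that stage first"
        )
    return path


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run the requested stages (all by default) in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed,
                           stages=wanted)
    out: dict[str, str] = manifest.outputs

    def emit(key: str, path: Path) -> Path:
        out[key] = str(path)
        return path

    for stage in wanted:
        log.info("stage=%s seed=%d config=%s", stage, config.seed, manifest.config_hash)
        if stage == "simulate":
            ann = simulate_annotation(config)
            gio.write_bed(emit("clusters", outdir / "clusters.bed"), ann.clusters)
            gio.write_bed(emit("islands_truth", outdir / "islands_truth.bed"), ann.islands)
            gio.write_genes(emit("genes", outdir / "genes.tsv"), ann.genes)
            sim = simulate_peaks(config, ann)
            for name, ps in sim.replicates.items():
                gio.write_bed(emit(f"peaks_{name}", outdir / f"peaks_{name}.bed"),
                              ps.intervals)
            gio.write_binned_coverage(emit("chip_bins", outdir / "h3k9me3_bins.tsv"),
                                      sim.chip_bins)
            gio.write_binned_coverage(emit("input_bins", outdir / "input_bins.tsv"),
                                      sim.input_bins)
            sim.background_labels.to_csv(
                emit("background_labels", outdir / "background_labels.tsv"),
                sep="\t", index=False)
            seqs = simulate_sequences(config)
            gio.write_fasta(emit("sequences", outdir / "regions.fa"), seqs.sequences)
            seqs.truth.to_csv(emit("sequence_truth", outdir / "sequence_truth.tsv"),
                              sep="\t", index=False)
            frags, centers = simulate_fragments(config)
            gio.write_fragments(emit("fragments", outdir / "fragments.tsv"), frags)
            pd.DataFrame(centers, columns=["chrom", "center"]).to_csv(
                emit("footprint_centers", outdir / "footprint_centers.tsv"),
                sep="\t", index=False)
            counts, condition, fold = simulate_counts(config, ann.genes)
            counts.to_csv(emit("counts", outdir / "counts.tsv"), sep="\t")
            condition.to_frame().to_csv(emit("conditions", outdir / "conditions.tsv"),
                                        sep="\t")
            fold.to_frame().to_csv(emit("true_fold", outdir / "true_fold.tsv"), sep="\t")
            gio.write_meme(emit("motifs", outdir / "motifs.meme"),
                           [default_lhx2_pfm(), default_ebf_pfm()])

        elif stage == "consensus":
            for factor in ("lhx2", "ebf"):
                rep1 = gio.read_bed(
                    _need(outdir / f"peaks_{factor}_rep1.bed", stage, "simulate"))
                rep2 = gio.read_bed(
                    _need(outdir / f"peaks_{factor}_rep2.bed", stage, "simulate"))
                cons = consensus_peaks(rep1, rep2, name=f"{factor}_consensus")
                gio.write_bed(emit(f"consensus_{factor}",
                                   outdir / f"consensus_{factor}.bed"),
                              cons.intervals)

        elif stage == "regions":
            chip = gio.read_binned_coverage(
                _need(outdir / "h3k9me3_bins.tsv", stage, "simulate"))
            inp = gio.read_binned_coverage(
                _need(outdir / "input_bins.tsv", stage, "simulate"))
            regions = call_enriched_regions(chip, inp)
            gio.write_bed(
                emit("enriched_regions", outdir / "enriched_regions.bed"),
                [GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                                 score=round(r.fold_enrichment, 3), id=r.interval.id)
                 for r in regions])

        elif stage == "islands":
            cons_a = gio.read_bed(_need(outdir / "consensus_lhx2.bed", stage, "consensus"))
            cons_b = gio.read_bed(_need(outdir / "consensus_ebf.bed", stage, "consensus"))
            domains_bed = gio.read_bed(
                _need(outdir / "enriched_regions.bed", stage, "regions"))
            clusters = gio.read_bed(_need(outdir / "clusters.bed", stage, "simulate"))
            from .islands import EnrichedRegion
            domains = [EnrichedRegion(iv, iv.score or 0.0) for iv in domains_bed]
            cb = cobound_peaks(cons_a, cons_b)
            islands = call_greek_islands(cb, domains, clusters.intervals)
            gio.write_bed(emit("islands", outdir / "islands.bed"),
                          [isl.interval for isl in islands])
            pd.DataFrame(
                [{"island_id": isl.interval.id, "chrom": isl.interval.chrom,
                  "start": isl.interval.start, "end": isl.interval.end,
                  "peak_lhx2": isl.peak_a_id, "peak_ebf": isl.peak_b_id,
                  "domain_id": isl.domain_id, "cluster_id": isl.cluster_id}
                 for isl in islands]
            ).to_csv(emit("islands_provenance", outdir / "islands_provenance.tsv"),
                     sep="\t", index=False)

        elif stage == "enrich":
            cons_a = gio.read_bed(_need(outdir / "consensus_lhx2.bed", stage, "consensus"))
            cons_b = gio.read_bed(_need(outdir / "consensus_ebf.bed", stage, "consensus"))
            clusters = gio.read_bed(_need(outdir / "clusters.bed", stage, "simulate"))
            res = intersect_classify(cons_a, cons_b)
            table = classify_island_peak_types(res, cons_a, cons_b, clusters.intervals)
            table.to_csv(emit("peak_type_table", outdir / "peak_type_table.tsv"),
                         sep="\t", index=False)
            rows = []
            for factor in (cons_a.name, cons_b.name):
                sub = table[table.factor == factor]
                co = sub[sub.category == "co-bound"].iloc[0]
                single = sub[sub.category != "co-bound"].iloc[0]
                k_in = int(co.in_clusters)
                n_in = int(co.in_clusters + single.in_clusters)
                k_bg = int(co.outside)
                n_bg = int(co.outside + single.outside)
                r = cobinding_enrichment(k_in, n_in, k_bg, n_bg, "greater")
                rows.append({"factor": factor, "k": r.k, "n": r.n, "p0": r.p0,
                             "alternative": r.alternative, "p_value": r.p_value})
            pd.DataFrame(rows).to_csv(
                emit("cobinding_enrichment", outdir / "cobinding_enrichment.tsv"),
                sep="\t", index=False)

        elif stage == "motif-scan":
            seqs = gio.read_fasta(_need(outdir / "regions.fa", stage, "simulate"))
            pfms = {p.name: p for p in
                    gio.read_meme(_need(outdir / "motifs.meme", stage, "simulate"))}
            comp = assemble_composite(pfms["Lhx2"], pfms["Ebf"],
                                      config.composite_spacer_bp)
            lom = build_logodds(comp)
            scores = {rid: best_match_score(s, lom) for rid, s in seqs.items()}
            cdf, above = score_cdf(list(scores.values()),
                                   (STRINGENT_THRESHOLD, PERMISSIVE_THRESHOLD))
            pd.DataFrame(
                [{"region_id": rid, "best_composite_score": sc}
                 for rid, sc in sorted(scores.items())]
            ).to_csv(emit("composite_scores", outdir / "composite_scores.tsv"),
                     sep="\t", index=False)
            cdf.to_csv(emit("score_cdf", outdir / "score_cdf.tsv"), sep="\t",
                       index=False)
            (outdir / "score_fractions.json").write_text(
                json.dumps({str(k): v for k, v in above.items()}, indent=2) + "\n")
            out["score_fractions"] = str(outdir / "score_fractions.json")

        elif stage == "proximity":
            seqs = gio.read_fasta(_need(outdir / "regions.fa", stage, "simulate"))
            truth = pd.read_csv(
                _need(outdir / "sequence_truth.tsv", stage, "simulate"), sep="\t")
            pfms = {p.name: p for p in
                    gio.read_meme(_need(outdir / "motifs.meme", stage, "simulate"))}
            lom_l = build_logodds(pfms["Lhx2"])
            lom_e = build_logodds(pfms["Ebf"])
            hits_l, hits_e = [], []
            for rid, s in seqs.items():
                hits_l.extend(scan_sequence(s, lom_l, HALF_SITE_THRESHOLD, rid))
                hits_e.extend(scan_sequence(s, lom_e, HALF_SITE_THRESHOLD, rid))
            dists = pair_distances_by_region(hits_e, hits_l)
            dist_df = pd.DataFrame(
                [{"region_id": rid, "min_pair_distance": d}
                 for rid, d in sorted(dists.items())])
            dist_df.to_csv(emit("pair_distances", outdir / "pair_distances.tsv"),
                           sep="\t", index=False)
            labels = truth.set_index("region_id")["label"]
            comp = [d for r, d in dists.items() if labels.get(r) == "composite"]
            disp = [d for r, d in dists.items() if labels.get(r) == "dispersed"]
            if comp and disp:
                d_stat, p = ks_one_sided(comp, disp, "smaller")
                (outdir / "proximity_ks.json").write_text(json.dumps(
                    {"D": d_stat, "p_value": p, "n_composite": len(comp),
                     "n_dispersed": len(disp)}, indent=2) + "\n")
                out["proximity_ks"] = str(outdir / "proximity_ks.json")

        elif stage == "signal-profile":
            frags = gio.read_fragments(_need(outdir / "fragments.tsv", stage, "simulate"))
            centers_df = pd.read_csv(
                _need(outdir / "footprint_centers.tsv", stage, "simulate"), sep="\t")
            centers = list(zip(centers_df.chrom, centers_df.center.astype(int)))
            sites = shift_to_insertions(frags)
            profile = end_density_profile(sites, centers,
                                          flank_bp=config.site_flank, bin_bp=5)
            profile.to_csv(emit("footprint_profile", outdir / "footprint_profile.tsv"),
                           sep="\t", index=False)

        elif stage == "expression":
            counts = pd.read_csv(_need(outdir / "counts.tsv", stage, "simulate"),
                                 sep="\t", index_col=0)
            condition = pd.read_csv(
                _need(outdir / "conditions.tsv", stage, "simulate"),
                sep="\t", index_col=0)["condition"]
            genes = gio.read_genes(_need(outdir / "genes.tsv", stage, "simulate"))
            islands_path = outdir / "islands.bed"
            islands = (gio.read_bed(islands_path).intervals
                       if islands_path.exists() else [])
            counts = counts.loc[counts.sum(axis=1) > 0]
            non_or = [g.gene_id for g in genes if g.gene_class == "non-OR"]
            factors = size_factors(counts, control_genes=non_or)
            ctrl = list(condition[condition == "control"].index)
            pert = list(condition[condition == "perturbed"].index)
            fc = fold_changes(counts, factors, ctrl, pert)
            dist = distance_to_island(genes, islands)
            cons_a_p = outdir / "consensus_lhx2.bed"
            cons_b_p = outdir / "consensus_ebf.bed"
            if cons_a_p.exists() and cons_b_p.exists():
                groups = group_by_promoter_binding(
                    genes, gio.read_bed(cons_a_p), gio.read_bed(cons_b_p))
            else:
                groups = pd.Series("none", index=[g.gene_id for g in genes],
                                   name="promoter_group")
            gene_class = pd.Series({g.gene_id: g.gene_class for g in genes},
                                   name="gene_class")
            records = fc.join(dist, how="left").join(groups, how="left").join(
                gene_class, how="left")
            records.index.name = "gene_id"
            records.to_csv(emit("expression_records", outdir / "expression_records.tsv"),
                           sep="\t")
            ranked = fc.sort_values("log2fc").index.tolist()
            or_genes = {g.gene_id for g in genes if g.gene_class == "OR"}
            universe = set(fc.index)
            k = min(500, len(ranked))
            overlap, p = topk_category_enrichment(ranked, k, or_genes & universe,
                                                  universe)
            (outdir / "topk_enrichment.json").write_text(json.dumps(
                {"k": k, "overlap": overlap, "p_value": p,
                 "category_size": len(or_genes & universe),
                 "universe_size": len(universe)}, indent=2) + "\n")
            out["topk_enrichment"] = str(outdir / "topk_enrichment.json")

    manifest.write(outdir / "manifest.json")
    out["manifest"] = str(outdir / "manifest.json")
    return manifest
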