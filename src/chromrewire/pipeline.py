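"""End-to-end orchestration of the chromatin-rewiring analyses.

Stages run in dependency order on a generated synthetic study:

    simulate -> cluster -> diff -> se -> loops -> ep -> report

Every stage is also callable as a library function and reruns in isolation
from the persisted intermediates.  All randomness derives from the single
config seed (expanded per stage by fixed offsets), all tables are written
atomically with a fixed float format, so identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import differential, ep_assignment, hic, signal_clustering, superenhancers
from .genomic_core import PeakSet, atomic_write, write_bed, write_segmentation
from .synthetic_data import SimConfig, simulate_contact_map, simulate_ep_truth, \
    simulate_landscape, simulate_two_timepoints

logger = logging.getLogger("chromrewire")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

FLOAT_FORMAT = "%.6g"

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the output directory."""

    outdir: str = "chromrewire_run"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "cluster", "diff", "se", "loops", "ep", "report"]
    )
    # simulation scale (None -> SimConfig defaults)
    sim: dict = field(default_factory=dict)
    # stage parameters
    k: int = 3
    stitch_gap: int = 12_500
    se_affect_threshold: float = 0.5
    fold: float = 1.5
    p: int = 2
    w: int = 5
    apa_w: int = 10
    apa_p: int = 3
    oe_threshold: float = 2.0
    min_count: float = 5.0
    ep_max_dist: int = 2_000_000
    alpha: float = 0.05
    lfc_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with atomic_write(path) as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Static consistency checks; an empty list means ready to run."""
    issues: list[str] = []
    try:
        sim = config.sim_config()
    except Exception as exc:  # config errors are reported, not raised
        issues.append(f"simulation config: {exc}")
        return issues
    if sim.chrom_length % sim.hic_resolution != 0:
        issues.append("hic_resolution does not divide chrom_length")
    if sim.chrom_length % sim.ep_resolution != 0:
        issues.append("ep_resolution does not divide chrom_length")
    if sim.n_replicates < 2:
        issues.append("need >= 2 replicates per condition for the differential test")
    if config.fold <= 1:
        issues.append("loop-class fold cutoff must exceed 1")
    if config.p >= config.w:
        issues.append("local window w must exceed peak radius p")
    known = {"simulate", "cluster", "diff", "se", "loops", "ep", "report"}
    for s in config.stages:
        if s not in known:
            issues.append(f"unknown stage {s!r}")
    loops_bedpe = os.path.join(config.outdir, "data", "loops.bedpe")
    if os.path.exists(loops_bedpe):
        loops = hic.read_bedpe(loops_bedpe)
        if (loops["chrom1"] != loops["chrom2"]).any():
            issues.append("loop list contains a trans loop; contact maps are cis-only")
    return issues


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        logger.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False


def _require(path: str, stage: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"missing intermediate {path}; run stage '{stage}' first"
        )


def stage_simulate(config: PipelineConfig) -> None:
    sim = config.sim_config()
    out = os.path.join(config.outdir, "data")
    os.makedirs(out, exist_ok=True)
    with _Stage("simulate"):
        land = simulate_landscape(sim)
        land.genome.to_file(os.path.join(out, "genome.chrom.sizes"))
        write_bed(land.peaks, os.path.join(out, "peaks.bed"))
        gene_rows = [
            (g.gene_id, g.chrom, g.strand, g.tss, g.body.start, g.body.end)
            for g in land.genes
        ]
        _write_tsv(
            pd.DataFrame(
                gene_rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
            ).set_index("gene_id"),
            os.path.join(out, "genes.tsv"),
        )
        _write_tsv(land.signal, os.path.join(out, "signal.tsv"))
        _write_tsv(land.counts, os.path.join(out, "counts.tsv"))
        write_segmentation(land.segmentation, os.path.join(out, "segmentation.bed"))
        _write_tsv(land.truth, os.path.join(out, "truth_peaks.tsv"))
        for cond in ("control", "mutant"):
            track = signal_clustering.SignalTrack.from_peak_values(
                land.peaks, land.signal[cond]
            )
            track.write_bedgraph(os.path.join(out, f"signal_{cond}.bedGraph"))

        maps = {c: simulate_contact_map(sim, c) for c in ("control", "mutant")}
        loops = maps["control"].loops
        hic.write_bedpe(loops, os.path.join(out, "loops.bedpe"))
        _write_tsv(
            loops.set_index("loop_id")[["weakened_truth"]],
            os.path.join(out, "truth_loops.tsv"),
        )
        for cond, res in maps.items():
            hic.write_contacts(res.matrices, os.path.join(out, f"contacts_{cond}.coo"))

        ep = simulate_ep_truth(sim, land)
        _write_tsv(ep.truth, os.path.join(out, "truth_ep.tsv"))
        _write_tsv(ep.gene_truth, os.path.join(out, "truth_genes.tsv"))
        for cond, mats in ep.matrices.items():
            hic.write_contacts(mats, os.path.join(out, f"ep_contacts_{cond}.coo"))

        tp = simulate_two_timepoints(sim)
        write_bed(tp.regions, os.path.join(out, "timepoint_regions.bed"))
        for genotype, counts in tp.counts.items():
            _write_tsv(counts, os.path.join(out, f"timepoint_counts_{genotype}.tsv"))
        _write_tsv(tp.truth, os.path.join(out, "truth_timepoints.tsv"))


def _load_data(config: PipelineConfig):
    from .genomic_core import read_bed, read_chrom_sizes, read_segmentation

    out = os.path.join(config.outdir, "data")
    _require(os.path.join(out, "peaks.bed"), "simulate")
    genome = read_chrom_sizes(os.path.join(out, "genome.chrom.sizes"))
    peaks = read_bed(os.path.join(out, "peaks.bed"))
    genes_df = pd.read_csv(os.path.join(out, "genes.tsv"), sep="\t")
    from .genomic_core import GeneAnnotation, GenomicInterval

    genes = [
        GeneAnnotation(
            r.gene_id, r.chrom, r.strand, int(r.tss),
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
        )
        for r in genes_df.itertuples()
    ]
    signal = pd.read_csv(os.path.join(out, "signal.tsv"), sep="\t", index_col=0)
    counts = pd.read_csv(os.path.join(out, "counts.tsv"), sep="\t", index_col=0)
    seg = read_segmentation(os.path.join(out, "segmentation.bed"))
    return genome, peaks, genes, signal, counts, seg


def stage_cluster(config: PipelineConfig) -> None:
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)
    genome, peaks, genes, signal, counts, seg = _load_data(config)
    with _Stage("cluster"):
        labels = signal_clustering.kmeans_partition(
            signal, k=config.k, seed=config.seed, order_by=["control"]
        )
        _write_tsv(labels.to_frame(), os.path.join(res_dir, "clusters.tsv"))
        from .genomic_core import annotate_genomic_category

        cats = annotate_genomic_category(peaks, genes)
        _write_tsv(cats.to_frame(), os.path.join(res_dir, "peak_categories.tsv"))
        cluster3 = peaks.subset(labels.index[labels == config.k])
        enr = signal_clustering.state_enrichment(cluster3, seg, genome)
        _write_tsv(enr, os.path.join(res_dir, "cluster3_state_enrichment.tsv"), index=False)


def stage_diff(config: PipelineConfig) -> None:
    out = os.path.join(config.outdir, "data")
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)
    _require(os.path.join(out, "timepoint_counts_control.tsv"), "simulate")
    from .genomic_core import read_bed

    regions = read_bed(os.path.join(out, "timepoint_regions.bed"))
    with _Stage("diff"):
        gains = {}
        for genotype in ("control", "mutant"):
            counts = pd.read_csv(
                os.path.join(out, f"timepoint_counts_{genotype}.tsv"),
                sep="\t", index_col=0,
            )
            prog = [c for c in counts.columns if c.startswith("progenitor_")]
            neu = [c for c in counts.columns if c.startswith("neuron_")]
            res = differential.differential_test(
                counts, prog, neu,
                lfc_threshold=config.lfc_threshold, alpha=config.alpha,
            )
            _write_tsv(res, os.path.join(res_dir, f"differential_{genotype}.tsv"))
            gain, loss = differential.gain_loss_sets(res, regions)
            gains[genotype] = gain
            write_bed(gain, os.path.join(res_dir, f"gain_{genotype}.bed"))
            write_bed(loss, os.path.join(res_dir, f"loss_{genotype}.bed"))
        venn = differential.cross_genotype_overlap(gains["control"], gains["mutant"])
        _write_tsv(
            pd.DataFrame(
                [(k, venn[k]) for k in ("n_shared_a", "n_shared_b", "n_a_only", "n_b_only")],
                columns=["quantity", "value"],
            ).set_index("quantity"),
            os.path.join(res_dir, "gain_overlap_venn.tsv"),
        )

        # developmental quartile atlas (control genotype, progenitor vs neuron)
        counts_c = pd.read_csv(
            os.path.join(out, "timepoint_counts_control.tsv"), sep="\t", index_col=0
        )
        peaks_a = PeakSet(regions.df.assign(peak_id="A|" + regions.df["peak_id"]))
        peaks_b = PeakSet(regions.df.assign(peak_id="B|" + regions.df["peak_id"]))
        dup = pd.concat(
            [counts_c.set_index("A|" + counts_c.index), counts_c.set_index("B|" + counts_c.index)]
        )
        prog = [c for c in counts_c.columns if c.startswith("progenitor_")]
        neu = [c for c in counts_c.columns if c.startswith("neuron_")]
        atlas = signal_clustering.build_quartile_atlas(
            peaks_a, peaks_b, dup, {"A": prog, "B": neu}
        )
        _write_tsv(atlas.table.set_index("region_id"), os.path.join(res_dir, "quartile_atlas.tsv"))


def stage_se(config: PipelineConfig) -> None:
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)
    genome, peaks, genes, signal, counts, seg = _load_data(config)
    _require(os.path.join(res_dir, "clusters.tsv"), "cluster")
    with _Stage("se"):
        track = signal_clustering.SignalTrack.read_bedgraph(
            os.path.join(config.outdir, "data", "signal_control.bedGraph")
        )
        stitched = superenhancers.stitch(peaks, config.stitch_gap)
        ranked = superenhancers.rank_regions(stitched, track)
        cutoff, ranked = superenhancers.find_cutoff(ranked)
        labels = pd.read_csv(
            os.path.join(res_dir, "clusters.tsv"), sep="\t", index_col=0
        )["cluster"]
        cluster3_ids = set(labels.index[labels == config.k])
        table = superenhancers.se_affectedness(
            ranked, peaks, cluster3_ids, config.se_affect_threshold
        )
        _write_tsv(table.set_index("region_id"), os.path.join(res_dir, "superenhancers.tsv"))
        _write_tsv(
            pd.DataFrame(
                {
                    "quantity": ["x_scaled", "y_scaled", "threshold", "n_super"],
                    "value": [cutoff.x_scaled, cutoff.y_scaled, cutoff.threshold, cutoff.n_super],
                }
            ).set_index("quantity"),
            os.path.join(res_dir, "se_cutoff.tsv"),
        )


def stage_loops(config: PipelineConfig) -> None:
    out = os.path.join(config.outdir, "data")
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)
    _require(os.path.join(out, "contacts_control.coo"), "simulate")
    from .genomic_core import read_chrom_sizes

    genome = read_chrom_sizes(os.path.join(out, "genome.chrom.sizes"))
    sim = config.sim_config()
    with _Stage("loops"):
        mats = {
            c: hic.load_contacts(
                os.path.join(out, f"contacts_{c}.coo"), genome, sim.hic_resolution
            )
            for c in ("control", "mutant")
        }
        loops = hic.read_bedpe(os.path.join(out, "loops.bedpe"))
        records, fractions = hic.compare_conditions(
            loops, mats["control"], mats["mutant"],
            fold=config.fold, p=config.p, w=config.w,
        )
        _write_tsv(records.set_index("loop_id"), os.path.join(res_dir, "loop_classes.tsv"))
        _write_tsv(
            pd.DataFrame(fractions.items(), columns=["quantity", "value"]).set_index("quantity"),
            os.path.join(res_dir, "loop_fractions.tsv"),
        )
        decay = hic.distance_decay(mats["control"]["chr1"])
        _write_tsv(decay.set_index("distance_bins"), os.path.join(res_dir, "distance_decay.tsv"))
        apa_res = hic.apa(loops, mats["control"], w=config.apa_w, p=config.apa_p)
        _write_tsv(
            pd.DataFrame(
                {
                    "quantity": ["center", "p2ll", "n_used", "n_excluded"],
                    "value": [apa_res.center, apa_res.p2ll, apa_res.n_used, apa_res.n_excluded],
                }
            ).set_index("quantity"),
            os.path.join(res_dir, "apa.tsv"),
        )


def stage_ep(config: PipelineConfig) -> None:
    out = os.path.join(config.outdir, "data")
    res_dir = os.path.join(config.outdir, "results")
    os.makedirs(res_dir, exist_ok=True)
    _require(os.path.join(out, "ep_contacts_control.coo"), "simulate")
    genome, peaks, genes, signal, counts, seg = _load_data(config)
    sim = config.sim_config()
    with _Stage("ep"):
        index = ep_assignment.build_promoter_bins(genes, sim.ep_resolution)
        assignments = {}
        for cond in ("control", "mutant"):
            mats = hic.load_contacts(
                os.path.join(out, f"ep_contacts_{cond}.coo"), genome, sim.ep_resolution
            )
            assign = ep_assignment.assign_peaks(
                peaks, index, mats,
                oe_threshold=config.oe_threshold,
                min_count=config.min_count,
                max_dist=config.ep_max_dist,
            )
            assignments[cond] = assign
            _write_tsv(assign, os.path.join(res_dir, f"ep_assignment_{cond}.tsv"))
        reg = ep_assignment.classify_gene_regulation(
            assignments["control"], assignments["mutant"], peaks, peaks
        )
        _write_tsv(reg, os.path.join(res_dir, "gene_regulation.tsv"))


def stage_report(config: PipelineConfig) -> None:
    res_dir = os.path.join(config.outdir, "results")
    report_lines: list[str] = []
    summary: dict[str, float] = {}
    with _Stage("report"):
        clusters = pd.read_csv(os.path.join(res_dir, "clusters.tsv"), sep="\t", index_col=0)
        sizes = clusters["cluster"].value_counts().sort_index()
        for c, n in sizes.items():
            summary[f"cluster{c}_size"] = int(n)
        se = pd.read_csv(os.path.join(res_dir, "superenhancers.tsv"), sep="\t", index_col=0)
        summary["n_superenhancers"] = int(se["is_super"].sum())
        summary["n_affected_superenhancers"] = int((se["is_super"] & se["affected"]).sum())
        frac = pd.read_csv(
            os.path.join(res_dir, "loop_fractions.tsv"), sep="\t", index_col=0
        )["value"]
        summary["weakened_loop_fraction"] = float(frac["weakened"])
        summary["strengthened_loop_fraction"] = float(frac["strengthened"])
        reg = pd.read_csv(os.path.join(res_dir, "gene_regulation.tsv"), sep="\t", index_col=0)
        summary["n_genes_with_regulatory_peaks"] = int(len(reg))
        summary["n_differential_genes"] = int(reg["differential"].sum())
        for genotype in ("control", "mutant"):
            d = pd.read_csv(
                os.path.join(res_dir, f"differential_{genotype}.tsv"), sep="\t", index_col=0
            )
            summary[f"n_gain_{genotype}"] = int((d["call"] == "gain").sum())
            summary[f"n_loss_{genotype}"] = int((d["call"] == "loss").sum())
        for key in sorted(summary):
            report_lines.append(f"{key}\t{summary[key]}")
        with atomic_write(os.path.join(res_dir, "summary.tsv")) as fh:
            fh.write("quantity\tvalue\n")
            fh.write("\n".join(report_lines) + "\n")
        with atomic_write(os.path.join(res_dir, "summary.json")) as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


_STAGES = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "diff": stage_diff,
    "se": stage_se,
    "loops": stage_loops,
    "ep": stage_ep,
    "report": stage_report,
}
_ORDER = ["simulate", "cluster", "diff", "se", "loops", "ep", "report"]


def run_pipeline(config: PipelineConfig) -> dict[str, float]:
    """Run the requested stages in dependency order; returns the summary."""
    issues = validate_inputs(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    os.makedirs(config.outdir, exist_ok=True)
    cfg_path = os.path.join(config.outdir, "config.yaml")
    config.to_yaml(cfg_path)
    logger.info("config %s (sha256 %s), seed %d", cfg_path, _file_hash(cfg_path), config.seed)
    t0 = time.time()
    for stage in _ORDER:
        if stage in config.stages:
            _STAGES[stage](config)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    summary_path = os.path.join(config.outdir, "results", "summary.json")
    if os.path.exists(summary_path):
        with open(summary_path) as fh:
            return json.load(fh)
    return {}
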