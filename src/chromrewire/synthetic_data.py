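"""Synthetic multi-omics generator with planted ground truth.

Emulates the statistical structure of a two-condition (control vs mutant)
regulatory-genomics experiment in a neural-progenitor-like system:

* an accessibility landscape with three planted peak classes — strongly
  accessible promoter peaks, moderately accessible stable distal peaks, and a
  modestly accessible distal subset whose signal is multiplicatively lost in
  the mutant condition;
* negative-binomial replicate count tables over peaks;
* a reduced six-state chromatin segmentation placing Promoter states over
  promoter peaks and Enhancer states over distal peaks;
* cis contact maps with power-law distance decay, Poisson counting noise and
  planted point loops, a subset of which is weakened in the mutant;
* a planted enhancer→gene map realised as excess promoter-bin contact, with
  per-gene rewiring (condition-exclusive regulatory peaks) at a set rate;
* paired progenitor/neuron count tables per genotype with planted gain/loss
  region sets and recorded shared subsets.

All outputs are reproducible from ``(config, seed)``; truth tables index the
generated entities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .genomic_core import (
    ChromStateSegmentation,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    PeakSet,
)
from .hic import ContactMatrix

__all__ = [
    "SimConfig",
    "Landscape",
    "ContactMapResult",
    "EPTruthResult",
    "TimepointResult",
    "simulate_landscape",
    "simulate_contact_map",
    "simulate_ep_truth",
    "simulate_two_timepoints",
]

# fixed stream ids so each generated entity has its own reproducible RNG
_STREAM_GENOME = 1
_STREAM_SIGNAL = 2
_STREAM_COUNTS = 3
_STREAM_SEGMENT = 4
_STREAM_LOOPS = 5
_STREAM_HIC_CONTROL = 6
_STREAM_HIC_MUTANT = 7
_STREAM_EP = 8
_STREAM_TIMEPOINTS = 9


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions every planted-truth recovery test runs
    under: 2 chromosomes x 20 Mb, ~3,000 peaks, ~300 genes, 3 replicates per
    condition, 10 kb loop-level contact maps and 50 kb enhancer-promoter maps.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 300
    n_peaks: int = 3_000
    fraction_promoter_peaks: float = 0.3
    fraction_gene_body_peaks: float = 0.2
    fraction_distal_affected: float = 0.5
    signal_means: tuple[float, float, float] = (10.0, 3.0, 0.5)  # high/mid/low
    signal_sd: float = 0.2
    mutant_effect: float = 0.5  # multiplicative loss on affected distal peaks
    n_replicates: int = 3
    nb_dispersion: float = 0.05  # variance = mu + alpha * mu^2
    count_depth: float = 10.0  # counts mean = depth * signal
    # contact maps
    hic_resolution: int = 10_000  # loop-level maps
    ep_resolution: int = 50_000  # enhancer-promoter maps
    decay_exponent: float = 1.0
    base_contacts: float = 1_000.0  # expected count at distance 0 (10 kb maps)
    ep_base_contacts: float = 2_000.0  # expected count at distance 0 (50 kb maps)
    n_loops: int = 200
    loop_enrichment: float = 5.0
    fraction_loops_weakened: float = 0.2
    weakening_fold: float = 3.0
    loop_min_sep_bins: int = 20
    loop_max_sep_bins: int = 100
    # enhancer-promoter truth
    ep_max_dist_bins: int = 40  # 2 Mb at 50 kb
    ep_ambiguity_rate: float = 0.0
    fraction_genes_rewired: float = 0.3
    # two-timepoint design
    fraction_gain: float = 0.1
    fraction_loss: float = 0.1
    fraction_shared_dynamic: float = 0.4
    timepoint_effect_fold: float = 4.0
    timepoint_mean_depth: float = 100.0

    def __post_init__(self) -> None:
        fracs = {
            "fraction_promoter_peaks": self.fraction_promoter_peaks,
            "fraction_gene_body_peaks": self.fraction_gene_body_peaks,
            "fraction_distal_affected": self.fraction_distal_affected,
            "fraction_loops_weakened": self.fraction_loops_weakened,
            "ep_ambiguity_rate": self.ep_ambiguity_rate,
            "fraction_genes_rewired": self.fraction_genes_rewired,
            "fraction_gain": self.fraction_gain,
            "fraction_loss": self.fraction_loss,
            "fraction_shared_dynamic": self.fraction_shared_dynamic,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.fraction_promoter_peaks + self.fraction_gene_body_peaks > 1.0:
            raise ConfigError("promoter + gene-body peak fractions exceed 1")
        if self.loop_enrichment <= 1.0:
            raise ConfigError("loop_enrichment must exceed 1")
        if self.weakening_fold < 1.0:
            raise ConfigError("weakening_fold must be >= 1")
        if not (0.0 < self.mutant_effect <= 1.0):
            raise ConfigError("mutant_effect must be in (0, 1]")
        for res in (self.hic_resolution, self.ep_resolution):
            if self.chrom_length % res != 0:
                raise ConfigError(
                    f"chrom_length {self.chrom_length} not divisible by resolution {res}"
                )
        n_prom = round(self.n_peaks * self.fraction_promoter_peaks)
        if self.n_peaks < self.n_genes or n_prom < 1:
            raise ConfigError("n_peaks too small for the requested design")
        if self.fraction_gain + self.fraction_loss > 1.0:
            raise ConfigError("fraction_gain + fraction_loss exceed 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Landscape:
    """Everything the peak-level stages consume, plus the planted truth."""

    config: SimConfig
    genome: Genome
    genes: list[GeneAnnotation]
    peaks: PeakSet
    signal: pd.DataFrame  # peaks x {control, mutant} normalized signal
    counts: pd.DataFrame  # peaks x replicate columns "control_1", ...
    segmentation: ChromStateSegmentation
    truth: pd.DataFrame  # peak_id, planted_class, category, affected, means

    def condition_samples(self, condition: str) -> list[str]:
        return [c for c in self.counts.columns if c.startswith(condition + "_")]


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    """Genes spread over chromosomes; each promoter occupies a distinct
    ep-resolution bin so a promoter bin maps to a single gene."""
    genes: list[GeneAnnotation] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        n_bins = config.chrom_length // config.ep_resolution
        # leave the first and last bins clear of promoters
        usable = np.arange(1, n_bins - 1)
        bins = rng.choice(usable, size=n_here, replace=False)
        bins.sort()
        for b in bins:
            offset = rng.integers(5_000, config.ep_resolution - 5_000)
            tss = int(b) * config.ep_resolution + int(offset)
            strand = "+" if rng.random() < 0.5 else "-"
            body_len = int(rng.integers(5_000, 50_000))
            if strand == "+":
                body = GenomicInterval(chrom, tss, min(tss + body_len, config.chrom_length))
            else:
                body = GenomicInterval(chrom, max(0, tss - body_len), tss + 1)
            gid += 1
            genes.append(GeneAnnotation(f"gene_{gid:04d}", chrom, strand, tss, body))
    return genes


def _interval_clear(masks: dict[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    return not masks[chrom][start:end].any()


def simulate_landscape(config: SimConfig) -> Landscape:
    """Generate the two-condition accessibility landscape with planted truth."""
    rng = config.rng(_STREAM_GENOME)
    genome = Genome({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})
    genes = _place_genes(config, rng)

    # occupancy masks to plant clean genomic categories
    prom_mask = {c: np.zeros(genome[c], dtype=bool) for c in genome}
    body_mask = {c: np.zeros(genome[c], dtype=bool) for c in genome}
    for g in genes:
        w = g.promoter_window()
        prom_mask[g.chrom][w.start : w.end] = True
        body_mask[g.chrom][g.body.start : g.body.end] = True

    n_prom = round(config.n_peaks * config.fraction_promoter_peaks)
    n_body = round(config.n_peaks * config.fraction_gene_body_peaks)
    n_distal = config.n_peaks - n_prom - n_body

    rows: list[tuple[str, int, int]] = []
    categories: list[str] = []
    # promoter peaks sit on gene TSSs (genes cycled in shuffled order)
    order = rng.permutation(len(genes))
    for k in range(n_prom):
        g = genes[order[k % len(genes)]]
        width = int(rng.integers(400, 800))
        jitter = int(rng.integers(-500, 500))
        center = g.tss + jitter
        start = max(0, center - width // 2)
        rows.append((g.chrom, start, start + width))
        categories.append("promoter")
    # gene-body peaks: inside a body, outside every promoter window
    chroms = list(genome)
    placed = 0
    while placed < n_body:
        g = genes[rng.integers(len(genes))]
        if len(g.body) < 2_000:
            continue
        width = int(rng.integers(300, 700))
        lo = g.body.start
        hi = g.body.end - width
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        if prom_mask[g.chrom][start : start + width].any():
            continue
        rows.append((g.chrom, start, start + width))
        categories.append("gene_body")
        placed += 1
    # distal peaks: outside promoter windows and gene bodies
    placed = 0
    while placed < n_distal:
        chrom = chroms[rng.integers(len(chroms))]
        width = int(rng.integers(300, 700))
        start = int(rng.integers(0, genome[chrom] - width))
        if prom_mask[chrom][start : start + width].any():
            continue
        if body_mask[chrom][start : start + width].any():
            continue
        rows.append((chrom, start, start + width))
        categories.append("distal_intergenic")
        placed += 1

    peaks = PeakSet.from_intervals(rows, ids=[f"peak_{i + 1:05d}" for i in range(len(rows))])
    # PeakSet sorts by position; carry categories through the sort
    cat_by_id = {f"peak_{i + 1:05d}": c for i, c in enumerate(categories)}
    cat = np.array([cat_by_id[p] for p in peaks.ids()])

    # planted classes: 1 = promoter/high, 2 = stable mid, 3 = affected distal/low
    srng = config.rng(_STREAM_SIGNAL)
    planted_class = np.where(cat == "promoter", 1, 2)
    distal_idx = np.flatnonzero(cat == "distal_intergenic")
    n_aff = round(len(distal_idx) * config.fraction_distal_affected)
    affected_idx = srng.choice(distal_idx, size=n_aff, replace=False)
    planted_class[affected_idx] = 3
    affected = np.zeros(len(peaks), dtype=bool)
    affected[affected_idx] = True

    hi, mid, lo = config.signal_means
    base_mean = np.select(
        [planted_class == 1, planted_class == 2, planted_class == 3], [hi, mid, lo]
    ).astype(float)
    control_mean = base_mean
    mutant_mean = np.where(affected, base_mean * config.mutant_effect, base_mean)

    signal = pd.DataFrame(
        {
            "control": np.clip(control_mean + srng.normal(0, config.signal_sd, len(peaks)), 0, None),
            "mutant": np.clip(mutant_mean + srng.normal(0, config.signal_sd, len(peaks)), 0, None),
        },
        index=pd.Index(peaks.ids(), name="peak_id"),
    )

    crng = config.rng(_STREAM_COUNTS)
    counts = {}
    for cond, mu_sig in (("control", control_mean), ("mutant", mutant_mean)):
        mu = config.count_depth * np.maximum(mu_sig, 0.05)
        for rep in range(1, config.n_replicates + 1):
            counts[f"{cond}_{rep}"] = _nb_draw(crng, mu, config.nb_dispersion)
    counts = pd.DataFrame(counts, index=pd.Index(peaks.ids(), name="peak_id"))

    segmentation = _build_segmentation(config, genome, genes, peaks, cat)

    truth = pd.DataFrame(
        {
            "peak_id": peaks.ids(),
            "planted_class": planted_class,
            "category": cat,
            "affected": affected,
            "control_mean": control_mean,
            "mutant_mean": mutant_mean,
        }
    ).set_index("peak_id")

    return Landscape(config, genome, genes, peaks, signal, counts, segmentation, truth)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; variance = mu + alpha*mu^2."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


_STATES = ("Promoter", "Enhancer", "Transcribed", "Heterochromatin", "Polycomb", "Quiescent")


def _build_segmentation(
    config: SimConfig,
    genome: Genome,
    genes: list[GeneAnnotation],
    peaks: PeakSet,
    categories: np.ndarray,
) -> ChromStateSegmentation:
    """Six-state segmentation: Promoter over promoter peaks, Enhancer over
    distal peaks, Transcribed over gene bodies, and random
    Heterochromatin/Polycomb blocks over a Quiescent background."""
    rng = config.rng(_STREAM_SEGMENT)
    code = {s: i for i, s in enumerate(_STATES)}
    rows = []
    for chrom in genome:
        arr = np.full(genome[chrom], code["Quiescent"], dtype=np.uint8)
        # random repressive blocks (~25% of the chromosome)
        n_blocks = genome[chrom] // 400_000
        for _ in range(n_blocks):
            s = int(rng.integers(0, genome[chrom] - 100_000))
            ln = int(rng.integers(20_000, 100_000))
            state = "Heterochromatin" if rng.random() < 0.5 else "Polycomb"
            arr[s : s + ln] = code[state]
        for g in genes:
            if g.chrom == chrom:
                arr[g.body.start : g.body.end] = code["Transcribed"]
        df = peaks.df
        for (c, s, e), cat in zip(df[["chrom", "start", "end"]].itertuples(index=False), categories):
            if c != chrom:
                continue
            pad = 500
            state = "Promoter" if cat == "promoter" else "Enhancer"
            if cat == "gene_body":  # keep bodies transcribed
                continue
            arr[max(0, s - pad) : min(genome[chrom], e + pad)] = code[state]
        # run-length extract
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate(([0], change, [len(arr)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(e), _STATES[arr[s]]))
    return ChromStateSegmentation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


# ---------------------------------------------------------------------------
# Contact maps with planted loops


@dataclass
class ContactMapResult:
    condition: str
    matrices: dict[str, ContactMatrix]
    loops: pd.DataFrame  # BEDPE-style + loop_id, weakened truth flag


def _plant_loops(config: SimConfig, genome: Genome) -> pd.DataFrame:
    """Loop anchor pairs shared by both conditions; a deterministic subset is
    flagged to be weakened in the mutant map."""
    rng = config.rng(_STREAM_LOOPS)
    res = config.hic_resolution
    chroms = list(genome)
    rows = []
    for k in range(config.n_loops):
        chrom = chroms[k % len(chroms)]
        n_bins = genome[chrom] // res
        d = int(rng.integers(config.loop_min_sep_bins, config.loop_max_sep_bins + 1))
        i = int(rng.integers(8, n_bins - d - 8))
        j = i + d
        rows.append((chrom, i * res, (i + 1) * res, chrom, j * res, (j + 1) * res, i, j))
    df = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "bin1", "bin2"],
    )
    df["loop_id"] = [f"loop_{k + 1:04d}" for k in range(len(df))]
    n_weak = round(config.n_loops * config.fraction_loops_weakened)
    weakened = np.zeros(len(df), dtype=bool)
    weakened[rng.permutation(len(df))[:n_weak]] = True
    df["weakened_truth"] = weakened
    min_sep = config.loop_min_sep_bins
    if min_sep < 2 * (2 + 5 + 1):  # default local window p=2, w=5
        raise ConfigError(
            "loop anchors closer than 2*(p+w+1) bins: local expected window must fit"
        )
    return df


def _decayed_counts(
    rng: np.random.Generator,
    n_bins: int,
    base: float,
    exponent: float,
    boosts: dict[tuple[int, int], float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson counts around a (d+1)^-exponent expectation, with per-pixel
    multiplicative boosts; returns upper-triangle COO arrays (i, j, value)."""
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    boost_arr: dict[int, dict[int, float]] = {}
    for (i, j), f in boosts.items():
        boost_arr.setdefault(j - i, {})[i] = f
    for d in range(n_bins):
        mu = base * (d + 1.0) ** (-exponent)
        m = n_bins - d
        means = np.full(m, mu)
        for i, f in boost_arr.get(d, {}).items():
            means[i] *= f
        draw = rng.poisson(means)
        nz = np.flatnonzero(draw)
        if nz.size:
            rows_i.append(nz)
            rows_j.append(nz + d)
            vals.append(draw[nz])
    i = np.concatenate(rows_i) if rows_i else np.array([], dtype=int)
    j = np.concatenate(rows_j) if rows_j else np.array([], dtype=int)
    v = np.concatenate(vals) if vals else np.array([], dtype=int)
    return i, j, v


def simulate_contact_map(
    config: SimConfig,
    condition: Literal["control", "mutant"],
    loops: pd.DataFrame | None = None,
) -> ContactMapResult:
    """Loop-resolution contact maps for one condition.

    Expected count at bin distance d is ``base_contacts * (d+1)^-decay_exponent``;
    planted loop pixels carry a ``loop_enrichment``-fold excess, divided by
    ``weakening_fold`` for the weakened subset in the mutant map.
    """
    if condition not in ("control", "mutant"):
        raise ConfigError(f"unknown condition {condition!r}")
    genome = Genome({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})
    if loops is None:
        loops = _plant_loops(config, genome)
    stream = _STREAM_HIC_CONTROL if condition == "control" else _STREAM_HIC_MUTANT
    rng = config.rng(stream)
    res = config.hic_resolution
    matrices: dict[str, ContactMatrix] = {}
    for chrom in genome:
        n_bins = genome[chrom] // res
        boosts: dict[tuple[int, int], float] = {}
        sub = loops[loops["chrom1"] == chrom]
        for _, row in sub.iterrows():
            fold = config.loop_enrichment
            if condition == "mutant" and row["weakened_truth"]:
                fold = fold / config.weakening_fold
            boosts[(int(row["bin1"]), int(row["bin2"]))] = fold
        i, j, v = _decayed_counts(
            rng, n_bins, config.base_contacts, config.decay_exponent, boosts
        )
        matrices[chrom] = ContactMatrix.from_coo(chrom, res, n_bins, i, j, v)
    return ContactMapResult(condition, matrices, loops)


# ---------------------------------------------------------------------------
# Enhancer-promoter truth


@dataclass
class EPTruthResult:
    truth: pd.DataFrame  # peak_id, gene_id, in_control, in_mutant
    gene_truth: pd.DataFrame  # gene_id, n_common, n_unique_*, differential truth
    matrices: dict[str, dict[str, ContactMatrix]]  # condition -> chrom -> matrix


def simulate_ep_truth(config: SimConfig, landscape: Landscape) -> EPTruthResult:
    """Plant a distal-peak -> gene map as excess promoter-bin contact.

    Every used distal peak bin gains ``loop_enrichment``-fold contact with
    exactly one promoter bin (the true gene).  A ``fraction_genes_rewired``
    subset of genes swaps three control-only peaks for three mutant-only
    peaks, planting per-gene differential regulation; with
    ``ep_ambiguity_rate`` > 0 a second promoter receives a half-strength
    decoy contact.
    """
    rng = config.rng(_STREAM_EP)
    res = config.ep_resolution
    genome = landscape.genome
    prom_bin = {g.gene_id: (g.chrom, g.tss // res) for g in landscape.genes}
    genes_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in landscape.genes:
        genes_by_chrom.setdefault(g.chrom, []).append((g.tss // res, g.gene_id))
    for lst in genes_by_chrom.values():
        lst.sort()

    distal = landscape.truth[landscape.truth["category"] == "distal_intergenic"]
    mids = landscape.peaks.midpoints().set_index("peak_id")
    promoter_bins = {(c, gb) for c, gb in prom_bin.values()}
    # group distal peaks by (chrom, bin); all peaks of one bin share a target;
    # peaks sharing a bin with a promoter are the resident gene's territory
    # already, so they carry no planted long-range truth
    records: list[tuple[str, str, str, int, int]] = []  # peak, gene, chrom, pbin, gbin
    bin_target: dict[tuple[str, int], str | None] = {}
    for pid in distal.index:
        chrom = mids.loc[pid, "chrom"]
        b = int(mids.loc[pid, "pos"]) // res
        key = (chrom, b)
        if key in promoter_bins:
            continue
        if key not in bin_target:
            cands = [
                gid
                for gb, gid in genes_by_chrom.get(chrom, [])
                if 1 <= abs(gb - b) <= config.ep_max_dist_bins
            ]
            bin_target[key] = None
            if cands:
                bin_target[key] = cands[int(rng.integers(len(cands)))]
        gid = bin_target[key]
        if gid is not None:
            records.append((pid, gid, chrom, b, prom_bin[gid][1]))
    truth = pd.DataFrame(
        records, columns=["peak_id", "gene_id", "chrom", "peak_bin", "promoter_bin"]
    )

    # Rewiring operates on whole (gene, bin) units because contact boosts act
    # per pixel: a rewired gene loses units (>=3 peaks) in the mutant and
    # adopts nearby reserve units (unboosted in control) as mutant-only.
    truth["in_control"] = True
    truth["in_mutant"] = True
    units: dict[tuple[str, str, int], list[int]] = {}
    for ridx, row in truth.iterrows():
        units.setdefault((row["gene_id"], row["chrom"], int(row["peak_bin"])), []).append(ridx)
    unit_keys = sorted(units)
    n_reserve = round(len(unit_keys) * 0.15)
    reserve_keys = [
        unit_keys[i] for i in rng.permutation(len(unit_keys))[:n_reserve]
    ]
    reserve = set(reserve_keys)
    for key in reserve_keys:
        truth.loc[units[key], ["in_control", "in_mutant"]] = False

    active_units_of: dict[str, list[tuple[str, str, int]]] = {}
    for key in unit_keys:
        if key not in reserve:
            active_units_of.setdefault(key[0], []).append(key)
    eligible = sorted(
        g
        for g, keys in active_units_of.items()
        if sum(len(units[k]) for k in keys) >= 3
    )
    n_rewired = round(len(active_units_of) * config.fraction_genes_rewired)
    rewired = [
        eligible[i]
        for i in rng.permutation(len(eligible))[: min(n_rewired, len(eligible))]
    ]
    free_reserve = list(reserve_keys)
    for gid in sorted(rewired):
        # control-only: flip units until >= 3 peaks are condition-exclusive
        flipped = 0
        for key in active_units_of[gid]:
            if flipped >= 3:
                break
            idxs = units[key]
            truth.loc[idxs, "in_mutant"] = False
            flipped += len(idxs)
        # mutant-only: adopt reserve units near this gene's promoter
        chrom, pbin = prom_bin[gid]
        adopted = 0
        remaining = []
        for key in free_reserve:
            _, r_chrom, r_bin = key
            if (
                adopted < 3
                and r_chrom == chrom
                and 1 <= abs(r_bin - pbin) <= config.ep_max_dist_bins
            ):
                idxs = units[key]
                truth.loc[idxs, "gene_id"] = gid
                truth.loc[idxs, "promoter_bin"] = pbin
                truth.loc[idxs, "in_mutant"] = True
                adopted += len(idxs)
            else:
                remaining.append(key)
        free_reserve = remaining
    # unadopted reserve units carry no planted contact: drop them from truth
    truth = truth[truth["in_control"] | truth["in_mutant"]].copy()

    # decoy second-promoter contacts
    truth["decoy_bin"] = -1
    if config.ep_ambiguity_rate > 0:
        for ridx in truth.index:
            if rng.random() >= config.ep_ambiguity_rate:
                continue
            chrom, b = truth.loc[ridx, "chrom"], int(truth.loc[ridx, "peak_bin"])
            pb = int(truth.loc[ridx, "promoter_bin"])
            cands = [
                gb
                for gb, _ in genes_by_chrom.get(chrom, [])
                if 1 <= abs(gb - b) <= config.ep_max_dist_bins and gb != pb
            ]
            if cands:
                truth.loc[ridx, "decoy_bin"] = cands[int(rng.integers(len(cands)))]

    matrices: dict[str, dict[str, ContactMatrix]] = {}
    for cond, flag in (("control", "in_control"), ("mutant", "in_mutant")):
        boosts_by_chrom: dict[str, dict[tuple[int, int], float]] = {
            c: {} for c in genome
        }
        sub = truth[truth[flag]]
        for _, row in sub.iterrows():
            i, j = sorted((int(row["peak_bin"]), int(row["promoter_bin"])))
            boosts_by_chrom[row["chrom"]][(i, j)] = config.loop_enrichment
            if row["decoy_bin"] >= 0:
                i2, j2 = sorted((int(row["peak_bin"]), int(row["decoy_bin"])))
                boosts_by_chrom[row["chrom"]].setdefault(
                    (i2, j2), 1.0 + (config.loop_enrichment - 1.0) / 2.0
                )
        crng = config.rng(_STREAM_EP + (10 if cond == "control" else 20))
        mats: dict[str, ContactMatrix] = {}
        for chrom in genome:
            n_bins = genome[chrom] // res
            i, j, v = _decayed_counts(
                crng, n_bins, config.ep_base_contacts, config.decay_exponent,
                boosts_by_chrom[chrom],
            )
            mats[chrom] = ContactMatrix.from_coo(chrom, res, n_bins, i, j, v)
        matrices[cond] = mats

    gene_rows = []
    for gid, sub in truth.groupby("gene_id"):
        n_common = int((sub["in_control"] & sub["in_mutant"]).sum())
        n_a = int((sub["in_control"] & ~sub["in_mutant"]).sum())
        n_b = int((~sub["in_control"] & sub["in_mutant"]).sum())
        gene_rows.append((gid, n_common, n_a, n_b, n_a > 2 or n_b > 2))
    gene_truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "n_common", "n_unique_control", "n_unique_mutant", "differential"],
    ).set_index("gene_id")
    return EPTruthResult(truth.set_index("peak_id"), gene_truth, matrices)


# ---------------------------------------------------------------------------
# Two-timepoint (progenitor -> neuron) design


@dataclass
class TimepointResult:
    regions: PeakSet
    counts: dict[str, pd.DataFrame]  # genotype -> regions x sample columns
    truth: pd.DataFrame  # region_id, label per genotype, shared flags

    def samples(self, genotype: str, timepoint: str) -> list[str]:
        return [c for c in self.counts[genotype].columns if c.startswith(timepoint + "_")]


def simulate_two_timepoints(config: SimConfig) -> TimepointResult:
    """Paired progenitor/neuron counts per genotype with planted dynamics.

    A ``fraction_gain`` (resp. ``fraction_loss``) subset of regions changes
    accessibility ``timepoint_effect_fold``-fold between the timepoints; a
    ``fraction_shared_dynamic`` share of each dynamic set is common to both
    genotypes, the rest is split genotype-specifically.
    """
    rng = config.rng(_STREAM_TIMEPOINTS)
    genome = Genome({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})
    n = config.n_peaks
    rows = []
    for k in range(n):
        chrom = f"chr{k % config.n_chroms + 1}"
        width = int(rng.integers(300, 700))
        start = int(rng.integers(0, genome[chrom] - width))
        rows.append((chrom, start, start + width))
    regions = PeakSet.from_intervals(rows, ids=[f"region_{k + 1:05d}" for k in range(n)])
    ids = np.array(regions.ids())

    n_gain = round(n * config.fraction_gain)
    n_loss = round(n * config.fraction_loss)
    perm = rng.permutation(n)
    gain_pool, loss_pool = perm[:n_gain], perm[n_gain : n_gain + n_loss]

    def split(pool: np.ndarray) -> tuple[set, set, set]:
        n_shared = round(len(pool) * config.fraction_shared_dynamic)
        rest = pool[n_shared:]
        half = len(rest) // 2
        return set(pool[:n_shared]), set(rest[:half]), set(rest[half:])

    gain_shared, gain_ctrl, gain_mut = split(gain_pool)
    loss_shared, loss_ctrl, loss_mut = split(loss_pool)

    labels = {}
    for genotype, g_extra, l_extra in (
        ("control", gain_ctrl, loss_ctrl),
        ("mutant", gain_mut, loss_mut),
    ):
        lab = np.full(n, "stable", dtype=object)
        for s in (gain_shared, g_extra):
            lab[list(s)] = "gain"
        for s in (loss_shared, l_extra):
            lab[list(s)] = "loss"
        labels[genotype] = lab

    fold = config.timepoint_effect_fold
    counts: dict[str, pd.DataFrame] = {}
    for genotype in ("control", "mutant"):
        base = config.timepoint_mean_depth * np.exp(rng.normal(0, 0.2, n))
        mu_prog = base.copy()
        mu_neu = base.copy()
        lab = labels[genotype]
        mu_neu[lab == "gain"] *= fold
        mu_neu[lab == "loss"] /= fold
        cols = {}
        for tp, mu in (("progenitor", mu_prog), ("neuron", mu_neu)):
            for rep in range(1, config.n_replicates + 1):
                cols[f"{tp}_{rep}"] = _nb_draw(rng, mu, config.nb_dispersion)
        counts[genotype] = pd.DataFrame(cols, index=pd.Index(ids, name="region_id"))

    truth = pd.DataFrame(
        {
            "region_id": ids,
            "label_control": labels["control"],
            "label_mutant": labels["mutant"],
        }
    ).set_index("region_id")
    truth["shared_gain"] = (truth["label_control"] == "gain") & (
        truth["label_mutant"] == "gain"
    )
    truth["shared_loss"] = (truth["label_control"] == "loss") & (
        truth["label_mutant"] == "loss"
    )
    return TimepointResult(regions, counts, truth)
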