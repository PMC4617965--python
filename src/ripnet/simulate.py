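"""Seeded synthetic fixtures with known ground truth.

Generates a multi-isoform transcriptome with planted sequence motifs,
negative-binomial RIP count tables (gene- and intron-level) with planted
enriched targets, protein-interaction complexes whose preys' mRNAs are
co-targets, and gene sets enriched for planted high-occupancy RNAs. One
``numpy`` Generator seeded from the config drives everything; reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeAccessor,
    RegionPartition,
    TranscriptModel,
    collapse_regions,
    reverse_complement,
)
from .diffbind import CountTable

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def consensus_pwm(consensus: str, concentration: float = 0.85) -> np.ndarray:
    """L x 4 PWM with ``concentration`` mass on the consensus base."""
    L = len(consensus)
    m = np.full((L, 4), (1 - concentration) / 3)
    for i, c in enumerate(consensus):
        m[i, _BASE_IDX[c]] = concentration
    return m


@dataclass
class PlantedMotif:
    consensus: str
    region: str = "three_utr"
    insertions_per_gene: float = 3.0
    concentration: float = 0.85

    @property
    def pwm(self) -> np.ndarray:
        return consensus_pwm(self.consensus, self.concentration)


@dataclass
class ComplexPlan:
    bait: str
    size: int  # members incl. the bait


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 300
    n_rbps: int = 20
    n_replicates: int = 2
    n_controls: int = 4
    # gene structure
    max_transcripts: int = 4
    exon_count_range: Tuple[int, int] = (1, 4)
    exon_length_range: Tuple[int, int] = (150, 400)
    intron_length_range: Tuple[int, int] = (80, 250)
    intergenic_gap: Tuple[int, int] = (200, 500)
    # counts
    log_mu_loc: float = 5.0
    log_mu_scale: float = 0.8
    mu_floor: float = 20.0
    dispersion_mean: float = 0.05
    dispersion_shape: float = 2.0
    size_factor_range: Tuple[float, float] = (0.5, 2.0)
    # planted signal
    target_fraction: float = 0.12
    fc_min: float = 1.5
    fc_max: float = 8.0
    hot_fraction: float = 0.03
    # introns
    intron_target_fraction: float = 0.5
    intron_mu_scale: float = 0.3
    # motifs
    planted_motifs: Dict[str, PlantedMotif] = field(default_factory=dict)
    # networks
    complexes: List[ComplexPlan] = field(default_factory=list)
    cross_regulation_fraction: float = 0.5
    n_go_sets: int = 10
    go_set_size: int = 25
    go_hot_odds: float = 8.0

    def __post_init__(self) -> None:
        for frac in (
            self.target_fraction,
            self.hot_fraction,
            self.intron_target_fraction,
            self.cross_regulation_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fc_min < 1:
            raise ValueError("fold changes must be >= 1")

    @property
    def baits(self) -> List[str]:
        return [f"RBP{i + 1:02d}" for i in range(self.n_rbps)]

    @property
    def hot_threshold(self) -> int:
        return math.ceil(self.n_rbps / 2)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config with motifs planted for three baits and five complexes."""
    cfg = SimulationConfig(seed=seed, **overrides)
    if not cfg.planted_motifs:
        # UTRs are short relative to the CDS, so planted concentration there
        # is detectable against the length-fraction null
        cfg.planted_motifs = {
            cfg.baits[0]: PlantedMotif("TGCATGC", "three_utr", 12.0),
            cfg.baits[1]: PlantedMotif("GACTAGT", "five_utr", 12.0),
            cfg.baits[2]: PlantedMotif("CCATTCC", "three_utr", 12.0),
        }
    if not cfg.complexes:
        cfg.complexes = [ComplexPlan(b, 5) for b in cfg.baits[:5]]
    return cfg


@dataclass
class SyntheticTruth:
    gene_ids: List[str]
    baits: List[str]
    targets: Dict[str, Dict[str, float]]  # bait -> gene -> fold change
    intron_targets: Dict[str, Dict[str, float]]  # bait -> intron feature -> fc
    hot_genes: Set[str]
    motifs: Dict[str, PlantedMotif]
    planted_hits: Dict[str, List[Tuple[str, int, str]]]  # bait -> (gene, gpos, region)
    complexes: List[Tuple[str, List[str]]]  # (bait, prey genes)
    go_sets: Dict[str, Set[str]]
    bait_gene: Dict[str, str]

    def target_set(self, bait: str) -> Set[str]:
        return set(self.targets.get(bait, {}))

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "baits": self.baits,
            "targets": {b: dict(v) for b, v in self.targets.items()},
            "intron_targets": {b: dict(v) for b, v in self.intron_targets.items()},
            "hot_genes": sorted(self.hot_genes),
            "motifs": {
                b: {
                    "consensus": m.consensus,
                    "region": m.region,
                    "insertions_per_gene": m.insertions_per_gene,
                    "concentration": m.concentration,
                }
                for b, m in self.motifs.items()
            },
            "planted_hits": self.planted_hits,
            "complexes": [[b, list(p)] for b, p in self.complexes],
            "go_sets": {k: sorted(v) for k, v in self.go_sets.items()},
            "bait_gene": self.bait_gene,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _plan_targets(cfg: SimulationConfig, rng: np.random.Generator,
                  gene_ids: List[str]) -> Tuple[Dict[str, Dict[str, float]], Set[str]]:
    """Per-bait target sets with fold changes, plus forced HOT genes."""
    def draw_fc(size=None):
        return np.exp(
            rng.uniform(math.log(cfg.fc_min), math.log(cfg.fc_max), size)
        )

    targets: Dict[str, Dict[str, float]] = {b: {} for b in cfg.baits}
    n_base = max(1, round(cfg.target_fraction * cfg.n_genes))
    for b in cfg.baits:
        chosen = rng.choice(gene_ids, size=n_base, replace=False)
        for g, fc in zip(chosen, draw_fc(n_base)):
            targets[b][str(g)] = float(fc)

    n_hot = round(cfg.hot_fraction * cfg.n_genes)
    hot = set(map(str, rng.choice(gene_ids, size=n_hot, replace=False)))
    t = cfg.hot_threshold
    # plant occupancy above the threshold and with strong fold changes so
    # the HOT status survives per-pair detection noise
    occ_lo = min(t + 2, cfg.n_rbps)
    fc_lo = min(max(cfg.fc_min, 3.0), cfg.fc_max)
    for g in sorted(hot):
        occ = int(rng.integers(occ_lo, cfg.n_rbps + 1))
        chosen = rng.choice(cfg.baits, size=occ, replace=False)
        for b in chosen:
            targets[str(b)].setdefault(
                g, float(np.exp(rng.uniform(math.log(fc_lo), math.log(cfg.fc_max))))
            )
    return targets, hot


def simulate_transcriptome(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[GeneModel], GenomeAccessor, SyntheticTruth]:
    """Gene models + genome with planted targets, HOT genes and motifs."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    targets, hot = _plan_targets(cfg, rng, gene_ids)

    genes: List[GeneModel] = []
    cursor = 0
    chrom = "chrS"
    for gid in gene_ids:
        cursor += int(rng.integers(*cfg.intergenic_gap))
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(*cfg.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*cfg.intron_length_range, size=max(0, n_exons - 1))
        exons, pos = [], cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        cursor = pos
        strand = "+" if rng.random() < 0.5 else "-"
        L = int(exon_lens.sum())
        utr5_max = min(120, int(exon_lens[0]) - 10, L // 3)
        utr5 = int(rng.integers(min(40, utr5_max - 1), utr5_max))
        utr3_max = min(250, int(exon_lens[-1]) - 10, L - utr5 - 30)
        utr3 = int(rng.integers(min(80, utr3_max - 1), utr3_max))
        master = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons)
        coords = master.genomic_positions()
        cds_pos = coords[utr5: L - utr3]
        cds = (int(cds_pos.min()), int(cds_pos.max()) + 1)
        master = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons, cds)
        transcripts = [master]
        # extra isoforms: skip one internal exon fully inside the CDS span
        skippable = [
            i for i in range(1, n_exons - 1)
            if exons[i][0] >= cds[0] and exons[i][1] <= cds[1]
        ]
        n_extra = int(rng.integers(0, cfg.max_transcripts))
        rng.shuffle(skippable)
        for j, idx in enumerate(skippable[:n_extra]):
            iso_exons = [e for i, e in enumerate(exons) if i != idx]
            transcripts.append(
                TranscriptModel(f"{gid}.t{j + 2}", gid, chrom, strand, iso_exons, cds)
            )
        genes.append(GeneModel(gid, transcripts))

    contig = BASES[rng.integers(0, 4, size=cursor + 500)].copy()

    planted_hits: Dict[str, List[Tuple[str, int, str]]] = {
        b: [] for b in cfg.planted_motifs
    }
    partitions = {g.gene_id: collapse_regions(g) for g in genes}
    gene_by_id = {g.gene_id: g for g in genes}
    for bait, plan in cfg.planted_motifs.items():
        k = len(plan.consensus)
        pwm = plan.pwm
        for gid in sorted(targets.get(bait, {})):
            part = partitions[gid]
            gene = gene_by_id[gid]
            segs = _insertable_segments(part, gene, plan.region, k)
            if not segs:
                log.info("no %s segment >= %d bp in %s; skipping insertion",
                         plan.region, k, gid)
                continue
            if plan.insertions_per_gene <= 0:
                continue
            n_ins = max(1, int(rng.poisson(plan.insertions_per_gene)))
            lens = np.array([b - a - k + 1 for a, b in segs], dtype=float)
            for _ in range(n_ins):
                si = int(rng.choice(len(segs), p=lens / lens.sum()))
                a, b = segs[si]
                start = int(rng.integers(a, b - k + 1))
                kmer = "".join(
                    "ACGT"[int(rng.choice(4, p=pwm[i]))] for i in range(k)
                )
                genomic = kmer if gene.strand == "+" else reverse_complement(kmer)
                contig[start: start + k] = np.frombuffer(
                    genomic.encode(), dtype="S1"
                )
                # genomic coordinate of the 5'-most transcript base
                gpos = start if gene.strand == "+" else start + k - 1
                planted_hits[bait].append((gid, gpos, plan.region))

    genome = GenomeAccessor.from_dict({chrom: contig.tobytes().decode()})

    intron_targets = _plan_intron_targets(cfg, rng, targets, partitions)
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        baits=cfg.baits,
        targets=targets,
        intron_targets=intron_targets,
        hot_genes=hot,
        motifs=dict(cfg.planted_motifs),
        planted_hits=planted_hits,
        complexes=[],
        go_sets={},
        bait_gene={b: gene_ids[i] for i, b in enumerate(cfg.baits)},
    )
    return genes, genome, truth


def _insertable_segments(
    part: RegionPartition, gene: GeneModel, region: str, k: int
) -> List[Tuple[int, int]]:
    """Clean segments of the requested label long enough for a k-mer.

    Exonic labels additionally require the segment to sit inside a single
    exon of the first transcript so the planted k-mer is junction-free.
    """
    segs = [s for s in part.segments(region) if s[1] - s[0] >= k]
    if region == "intron":
        return segs
    master_exons = gene.transcripts[0].exons
    out = []
    for a, b in segs:
        for ea, eb in master_exons:
            lo, hi = max(a, ea), min(b, eb)
            if hi - lo >= k:
                out.append((lo, hi))
    return out


def intron_features(
    partitions: Dict[str, RegionPartition]
) -> Dict[str, Tuple[str, int, int]]:
    """Feature id -> (gene, start, end) for every collapsed intron segment."""
    out: Dict[str, Tuple[str, int, int]] = {}
    for gid in sorted(partitions):
        for i, (a, b) in enumerate(partitions[gid].segments("intron")):
            out[f"{gid}:intron{i}"] = (gid, a, b)
    return out


def _plan_intron_targets(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    targets: Dict[str, Dict[str, float]],
    partitions: Dict[str, RegionPartition],
) -> Dict[str, Dict[str, float]]:
    feats = intron_features(partitions)
    by_gene: Dict[str, List[str]] = {}
    for fid, (gid, _, _) in feats.items():
        by_gene.setdefault(gid, []).append(fid)
    out: Dict[str, Dict[str, float]] = {b: {} for b in cfg.baits}
    for bait, tgt in targets.items():
        candidates = [g for g in sorted(tgt) if g in by_gene]
        for g in candidates:
            if rng.random() < cfg.intron_target_fraction:
                fid = str(rng.choice(by_gene[g]))
                fc = float(
                    np.exp(rng.uniform(math.log(max(cfg.fc_min, 2.0)),
                                       math.log(cfg.fc_max)))
                )
                out[bait][fid] = fc
    return out


def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty(mean.shape, dtype=np.int64)
    poi = alpha < 1e-8
    if poi.any():
        out[poi] = rng.poisson(mean[poi])
    if (~poi).any():
        n = 1.0 / alpha[~poi]
        p = n / (n + mean[~poi])
        out[~poi] = rng.negative_binomial(n, p)
    return out


def simulate_rip_counts(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
    feature_mu: Optional[pd.Series] = None,
    feature_targets: Optional[Dict[str, Dict[str, float]]] = None,
    features: Optional[List[str]] = None,
) -> CountTable:
    """Negative-binomial count table for the shared-control IP design.

    By default simulates gene-level features from ``truth.targets``; pass
    ``features``/``feature_targets``/``feature_mu`` for intron-level tables.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if features is None:
        features = list(truth.gene_ids)
    if feature_targets is None:
        feature_targets = truth.targets
    n = len(features)
    if feature_mu is None:
        mu = np.maximum(
            rng.lognormal(cfg.log_mu_loc, cfg.log_mu_scale, n), cfg.mu_floor
        )
        feature_mu = pd.Series(mu, index=features)
    alpha = rng.gamma(
        cfg.dispersion_shape, cfg.dispersion_mean / cfg.dispersion_shape, n
    )
    lo, hi = cfg.size_factor_range
    sample_rows = []
    data: Dict[str, np.ndarray] = {}
    mu_vec = feature_mu[features].to_numpy()

    for c in range(cfg.n_controls):
        sid = f"control{c + 1:02d}"
        s = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        data[sid] = _nb_draw(rng, s * mu_vec, alpha)
        sample_rows.append((sid, "", 0, True))
    for bait in cfg.baits:
        fc = np.ones(n)
        tgt = feature_targets.get(bait, {})
        for i, fid in enumerate(features):
            if fid in tgt:
                fc[i] = tgt[fid]
        for r in range(cfg.n_replicates):
            sid = f"{bait}_rep{r + 1}"
            s = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            data[sid] = _nb_draw(rng, s * mu_vec * fc, alpha)
            sample_rows.append((sid, bait, r + 1, False))

    counts = pd.DataFrame(data, index=features)
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "bait", "replicate", "is_control"]
    )
    return CountTable(counts, samples)


def simulate_intron_counts(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    partitions: Dict[str, RegionPartition],
    rng: Optional[np.random.Generator] = None,
) -> CountTable:
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    feats = sorted(intron_features(partitions))
    n = len(feats)
    mu = np.maximum(
        rng.lognormal(cfg.log_mu_loc, cfg.log_mu_scale, n) * cfg.intron_mu_scale,
        cfg.mu_floor * cfg.intron_mu_scale,
    )
    return simulate_rip_counts(
        cfg,
        truth,
        rng=rng,
        feature_mu=pd.Series(mu, index=feats),
        feature_targets=truth.intron_targets,
        features=feats,
    )


def simulate_networks(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, Dict[str, str], Dict[str, Set[str]]]:
    """Plant protein complexes and GO sets; extend RNA truth with cross-regulation.

    Returns (ppi edge list, prey->gene map, GO sets). For the configured
    fraction of preys, the prey's encoding gene is added to the bait's true
    RNA-target set, so counts simulated afterwards carry the signal.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    bait_genes = set(truth.bait_gene.values())
    pool = [g for g in truth.gene_ids if g not in bait_genes]
    rows, gene_map = [], {}
    complexes: List[Tuple[str, List[str]]] = []
    for plan in cfg.complexes:
        preys = [str(g) for g in rng.choice(pool, size=plan.size - 1, replace=False)]
        members = []
        for g in preys:
            prey = f"P_{g}"
            gene_map[prey] = g
            rows.append((plan.bait, prey))
            members.append(g)
            if rng.random() < cfg.cross_regulation_fraction:
                if g not in truth.targets[plan.bait]:
                    fc = float(
                        np.exp(rng.uniform(math.log(max(cfg.fc_min, 2.0)),
                                           math.log(cfg.fc_max)))
                    )
                    truth.targets[plan.bait][g] = fc
        complexes.append((plan.bait, members))
    ppi = pd.DataFrame(rows, columns=["bait", "prey"])

    hot = truth.hot_genes
    weights = np.array(
        [cfg.go_hot_odds if g in hot else 1.0 for g in truth.gene_ids]
    )
    go_sets: Dict[str, Set[str]] = {}
    for i in range(cfg.n_go_sets):
        chosen = rng.choice(
            truth.gene_ids,
            size=min(cfg.go_set_size, len(truth.gene_ids)),
            replace=False,
            p=weights / weights.sum(),
        )
        go_sets[f"GO:{i + 1:07d}"] = set(map(str, chosen))
    truth.complexes = complexes
    truth.go_sets = go_sets
    return ppi, gene_map, go_sets


@dataclass
class SimBundle:
    cfg: SimulationConfig
    genes: List[GeneModel]
    genome: GenomeAccessor
    partitions: Dict[str, RegionPartition]
    truth: SyntheticTruth
    gene_counts: CountTable
    intron_counts: CountTable
    ppi: pd.DataFrame
    gene_map: Dict[str, str]
    go_sets: Dict[str, Set[str]]


def simulate_all(cfg: SimulationConfig) -> SimBundle:
    """Run the full generator in its canonical order under one seed."""
    rng = np.random.default_rng(cfg.seed)
    genes, genome, truth = simulate_transcriptome(cfg, rng)
    partitions = {g.gene_id: collapse_regions(g) for g in genes}
    ppi, gene_map, go_sets = simulate_networks(cfg, truth, rng)
    gene_counts = simulate_rip_counts(cfg, truth, rng)
    intron_counts = simulate_intron_counts(cfg, truth, partitions, rng)
    return SimBundle(
        cfg, genes, genome, partitions, truth, gene_counts, intron_counts,
        ppi, gene_map, go_sets,
    )


def write_fasta(genome: GenomeAccessor, path, width: int = 80) -> None:
    contigs = genome._source
    if not isinstance(contigs, dict):
        raise TypeError("write_fasta expects an in-memory genome")
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Exon/CDS features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                for a, b in t.exons:
                    fh.write(
                        f"{t.chrom}\tripnet\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
                if t.cds is not None:
                    c0, c1 = t.cds
                    for a, b in t.exons:
                        lo, hi = max(a, c0), min(b, c1)
                        if hi > lo:
                            fh.write(
                                f"{t.chrom}\tripnet\tCDS\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n"
                            )


def write_ppi(ppi: pd.DataFrame, gene_map: Dict[str, str], path) -> None:
    out = ppi.copy()
    out["prey_gene"] = out["prey"].map(gene_map)
    out.to_csv(path, sep="\t", index=False)


def write_go(go_sets: Dict[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(go_sets):
            for g in sorted(go_sets[term]):
                fh.write(f"{term}\t{g}\n")
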