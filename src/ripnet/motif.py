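"""Isoform-aware k-mer motif discovery and gene-region enrichment.

Per-bait 7-mer enrichment (target genes vs expressed non-targets,
hypergeometric on gene presence), a weighted position-frequency summary of
the top k-mers, transcriptome scanning with the top-quantile k-mers under
the PWM, and per-locus region z-scores against length-fraction nulls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import KmerIndex, RegionPartition

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class KmerStats:
    kmer: str
    n_target: int
    n_background: int
    p_value: float

    @property
    def weight(self) -> float:
        """-log10 p, the transformed enrichment weight."""
        return -math.log10(max(self.p_value, 1e-300))


@dataclass
class PWM:
    """Column-stochastic L x 4 matrix over (A, C, G, U/T)."""

    matrix: np.ndarray
    source_kmers: List[Tuple[str, float]]
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if (self.matrix <= 0).any():
            raise ValueError("PWM entries must be positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_likelihood(self, kmer: str) -> float:
        return float(
            sum(math.log(self.matrix[i, _BASE_IDX[c]]) for i, c in enumerate(kmer))
        )

    def to_meme(self, name: str = "motif") -> str:
        """MEME minimal text format (RNA alphabet for display)."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGU",
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.length}",
        ]
        for row in self.matrix:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class MotifHit:
    gene_id: str
    gpos: int
    kmer: str
    region: Optional[str]


@dataclass
class MotifHitSet:
    bait: str
    hits: List[MotifHit]
    top_kmers: frozenset

    def hits_per_gene(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for h in self.hits:
            out[h.gene_id] = out.get(h.gene_id, 0) + 1
        return out


@dataclass
class RegionEnrichment:
    gene_id: str
    region: str
    hits_in_region: int
    total_hits: int
    length_fraction: float
    z_score: float
    p_value: float


def kmer_enrichment(
    index: KmerIndex,
    targets: set,
    expressed_nontargets: set,
) -> List[KmerStats]:
    """Hypergeometric k-mer presence enrichment in targets vs background.

    A gene counts once per k-mer regardless of how many locations carry it;
    the universe is targets plus expressed non-targets.
    """
    if not targets:
        raise ValueError("empty target set")
    if targets & expressed_nontargets:
        raise ValueError("target and background sets must be disjoint")
    universe = targets | expressed_nontargets
    U, nT = len(universe), len(targets)
    counts: Dict[str, Tuple[int, int]] = {}
    for gid in universe:
        in_t = gid in targets
        for kmer in index.gene_kmers(gid):
            t, b = counts.get(kmer, (0, 0))
            counts[kmer] = (t + 1, b) if in_t else (t, b + 1)
    out = []
    for kmer, (t, b) in counts.items():
        # draw nT genes from U of which (t + b) carry the k-mer
        p = float(stats.hypergeom.sf(t - 1, U, t + b, nT))
        out.append(KmerStats(kmer, t, b, min(max(p, 0.0), 1.0)))
    out.sort(key=lambda s: (s.p_value, s.kmer))
    return out


def _align_offset(seed: str, kmer: str, max_shift: int = 2) -> int:
    """Offset of ``kmer`` relative to ``seed`` maximizing matching bases."""
    best_shift, best_score = 0, -1
    for shift in range(-max_shift, max_shift + 1):
        score = sum(
            1
            for i in range(len(seed))
            if 0 <= i + shift < len(kmer) and seed[i] == kmer[i + shift]
        )
        if score > best_score:
            best_shift, best_score = shift, score
    return best_shift


def build_pwm(
    top_kmers: Sequence[KmerStats],
    n_top: int = 50,
    pseudocount: float = 0.25,
    max_shift: int = 2,
) -> PWM:
    """Weighted seed-alignment position frequency matrix.

    The most enriched k-mer seeds the alignment; every other k-mer is placed
    at the shift (within +/- ``max_shift``, no reverse complement) that best
    matches the seed, contributing its -log10 p weight to the aligned
    columns. Columns are pseudocounted and normalized.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    best: Dict[str, KmerStats] = {}
    for s in top_kmers:  # duplicates collapse to their best p-value
        if s.kmer not in best or s.p_value < best[s.kmer].p_value:
            best[s.kmer] = s
    chosen = sorted(best.values(), key=lambda s: (s.p_value, s.kmer))[:n_top]
    chosen = [s for s in chosen if s.weight > 0]
    L = len(top_kmers[0].kmer)
    freq = np.zeros((L, 4))
    sources: List[Tuple[str, float]] = []
    if not chosen:
        log.warning("all k-mer weights are zero; returning uniform PWM")
        freq += 1.0
    else:
        seed = chosen[0].kmer
        for s in chosen:
            shift = _align_offset(seed, s.kmer, max_shift)
            for i in range(L):
                j = i + shift
                if 0 <= j < len(s.kmer):
                    freq[i, _BASE_IDX[s.kmer[j]]] += s.weight
            sources.append((s.kmer, s.weight))
    freq += pseudocount
    freq /= freq.sum(axis=1, keepdims=True)
    return PWM(freq, sources, pseudocount)


def score_and_select(pwm: PWM, quantile: float = 0.01) -> List[str]:
    """Top ceil(q * 4^L) k-mers by PWM log-likelihood, ties lexicographic."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    L = pwm.length
    logm = np.log(pwm.matrix)
    # vectorized enumeration of all 4^L scores
    scores = np.zeros(1)
    for i in range(L):
        scores = (scores[:, None] + logm[i][None, :]).ravel()
    n_keep = math.ceil(quantile * 4**L)
    # lexicographic index order == enumeration order; stable sort by -score
    order = np.argsort(-scores, kind="stable")[:n_keep]
    kmers = []
    for idx in order:
        chars = []
        rem = int(idx)
        for _ in range(L):
            chars.append(BASES[rem % 4])
            rem //= 4
        kmers.append("".join(reversed(chars)))
    return kmers


def scan_transcriptome(
    index: KmerIndex,
    top_kmers: Sequence[str],
    partitions: Dict[str, RegionPartition],
    bait: str = "",
) -> MotifHitSet:
    """All indexed locations whose k-mer is in the top set, region-labeled.

    Hits take the label of their 5'-most base; hits in ambiguous regions are
    retained but excluded from region tests downstream.
    """
    top = frozenset(top_kmers)
    hits: List[MotifHit] = []
    for gid, locs in index.locations.items():
        part = partitions.get(gid)
        for loc in locs:
            if loc.kmer not in top:
                continue
            region = part.label_at(loc.gpos) if part is not None else None
            hits.append(MotifHit(gid, loc.gpos, loc.kmer, region))
    return MotifHitSet(bait, hits, top)


def region_zscore(
    hit_set: MotifHitSet,
    partitions: Dict[str, RegionPartition],
    min_hits: int = 20,
    apply_min_hits: bool = True,
) -> List[RegionEnrichment]:
    """Binomial region enrichment per (locus, region).

    Hits come from mature-transcript k-mer locations, so only the exonic
    structure labels (5'UTR / CDS / 3'UTR) are reachable; the length
    baseline is restricted to those labels accordingly. n = unambiguous
    exonic hits at the locus; p0 = the region's share of the locus's
    unambiguous exonic length; z = (x - n p0) / sqrt(n p0 (1 - p0)).
    Loci with n < ``min_hits`` are dropped unless ``apply_min_hits`` is off.
    """
    exonic = ("five_utr", "cds", "three_utr")
    by_gene: Dict[str, List[MotifHit]] = {}
    for h in hit_set.hits:
        if h.region in exonic:
            by_gene.setdefault(h.gene_id, []).append(h)
    out: List[RegionEnrichment] = []
    for gid, hits in by_gene.items():
        n = len(hits)
        if apply_min_hits and n < min_hits:
            continue
        part = partitions[gid]
        clean_total = sum(part.label_lengths.get(k, 0) for k in exonic)
        if clean_total == 0:
            continue
        region_counts: Dict[str, int] = {}
        for h in hits:
            region_counts[h.region] = region_counts.get(h.region, 0) + 1
        for region in exonic:
            length = part.label_lengths.get(region, 0)
            p0 = length / clean_total
            if p0 <= 0 or p0 >= 1:
                continue
            x = region_counts.get(region, 0)
            z = (x - n * p0) / math.sqrt(n * p0 * (1 - p0))
            p = float(stats.binom.sf(x - 1, n, p0)) if x > 0 else 1.0
            out.append(RegionEnrichment(gid, region, x, n, p0, z, min(p, 1.0)))
    return out


def kmer_stats_frame(stats_list: Sequence[KmerStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kmer": [s.kmer for s in stats_list],
            "n_target": [s.n_target for s in stats_list],
            "n_background": [s.n_background for s in stats_list],
            "p_value": [s.p_value for s in stats_list],
            "weight": [s.weight for s in stats_list],
        }
    )


def region_enrichment_frame(rows: Sequence[RegionEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "region": [r.region for r in rows],
            "hits_in_region": [r.hits_in_region for r in rows],
            "total_hits": [r.total_hits for r in rows],
            "length_fraction": [r.length_fraction for r in rows],
            "z_score": [r.z_score for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )


def write_hits_bed(hit_set: MotifHitSet, chrom_of: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for h in hit_set.hits:
            k = len(h.kmer)
            fh.write(
                f"{chrom_of[h.gene_id]}\t{h.gpos}\t{h.gpos + k}\t{h.kmer}\t0\t.\n"
            )
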