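"""Integration of protein-interaction and RNA-binding layers per bait.

Edges from a bait to a gene are typed ``rna`` (RNA target only),
``protein`` (encodes an interacting protein only) or ``both``. A bait's own
gene is excluded from its RNA edges (unobservable against the
overexpressed background). Cross-regulation is the per-bait hypergeometric
overlap of the two layers, combined across baits with Fisher's method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class Edge:
    bait: str
    gene: str
    kind: str  # rna | protein | both
    strength: float = 0.0  # -log10 local idr for rna/both edges


@dataclass
class IntegratedNetwork:
    edges: List[Edge]
    rna_targets: Dict[str, Set[str]]
    partner_genes: Dict[str, Set[str]]

    @property
    def baits(self) -> List[str]:
        return sorted(set(self.rna_targets) | set(self.partner_genes))

    def edge_counts(self) -> Dict[str, int]:
        out = {"rna": 0, "protein": 0, "both": 0}
        for e in self.edges:
            out[e.kind] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bait": [e.bait for e in self.edges],
                "gene": [e.gene for e in self.edges],
                "kind": [e.kind for e in self.edges],
                "strength": [e.strength for e in self.edges],
            }
        )


@dataclass
class CrossRegulationResult:
    per_bait: pd.DataFrame  # bait, n_partners, n_targets, overlap, p_value
    chi2: float
    df: int
    combined_p: float


def integrate(
    calls_by_bait: Dict[str, Sequence],
    ppi: pd.DataFrame,
    gene_map: Dict[str, str],
    bait_gene: Optional[Dict[str, str]] = None,
    exclude_baits: Optional[Set[str]] = None,
) -> IntegratedNetwork:
    """Build the typed bait -> gene edge set from both layers.

    ``ppi`` needs columns ``bait`` and ``prey``; preys are mapped to their
    encoding genes through ``gene_map`` (unmapped preys are logged and
    dropped). ``bait_gene`` maps each bait to its own gene, excluded from
    that bait's RNA edges. ``exclude_baits`` removes bait-bait PPI pairs
    (cross-contamination filter).
    """
    bait_gene = bait_gene or {}
    rna: Dict[str, Dict[str, float]] = {}
    for bait, calls in calls_by_bait.items():
        own = bait_gene.get(bait)
        rna[bait] = {
            c.feature_id: getattr(c, "strength", 0.0)
            for c in calls
            if getattr(c, "passed", True) and c.feature_id != own
        }
    partners: Dict[str, Set[str]] = {}
    for _, row in ppi.iterrows():
        bait, prey = row["bait"], row["prey"]
        if exclude_baits and prey in exclude_baits:
            continue
        if prey not in gene_map:
            log.warning("prey %s not mappable to a gene; dropped", prey)
            continue
        partners.setdefault(bait, set()).add(gene_map[prey])
    for bait in partners:
        if bait not in rna:
            log.warning("bait %s absent from binding calls; protein-only", bait)

    edges: List[Edge] = []
    for bait in sorted(set(rna) | set(partners)):
        r = rna.get(bait, {})
        p = partners.get(bait, set())
        for gene in sorted(set(r) | p):
            if gene in r and gene in p:
                edges.append(Edge(bait, gene, "both", r[gene]))
            elif gene in r:
                edges.append(Edge(bait, gene, "rna", r[gene]))
            else:
                edges.append(Edge(bait, gene, "protein"))
    return IntegratedNetwork(
        edges,
        {b: set(v) for b, v in rna.items()},
        partners,
    )


def fisher_combine(pvalues: Sequence[float]) -> Tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2m."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    chi2 = float(-2.0 * np.log(np.maximum(p, 1e-300)).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def cross_regulation_test(
    network: IntegratedNetwork, universe: Set[str], midp: bool = True
) -> CrossRegulationResult:
    """Per-bait protein/RNA target overlap and Fisher-combined evidence.

    Baits lacking either layer are excluded from the combination (undefined
    is not null evidence). Reported per-bait p-values are exact
    hypergeometric upper tails; with ``midp`` (default) the Fisher
    combination uses Lancaster's mid-p correction so the combined statistic
    is calibrated despite the discreteness of the per-bait tests.
    """
    rows = []
    pvals = []
    for bait in network.baits:
        targets = network.rna_targets.get(bait, set()) & universe
        partner = network.partner_genes.get(bait, set()) & universe
        if not targets or not partner:
            rows.append((bait, len(partner), len(targets), 0, math.nan))
            continue
        k = len(targets & partner)
        U, n1, n2 = len(universe), len(partner), len(targets)
        p = float(stats.hypergeom.sf(k - 1, U, n1, n2))
        p = min(max(p, 0.0), 1.0)
        rows.append((bait, n1, n2, k, p))
        if midp:
            # drop half the atom at the observed overlap before combining
            p_comb = p - 0.5 * float(stats.hypergeom.pmf(k, U, n1, n2))
        else:
            p_comb = p
        pvals.append(min(max(p_comb, 1e-300), 1.0))
    if not pvals:
        raise ValueError("no bait has both protein partners and RNA targets")
    chi2, df, combined = fisher_combine(pvals)
    table = pd.DataFrame(
        rows, columns=["bait", "n_partners", "n_targets", "overlap", "p_value"]
    )
    return CrossRegulationResult(table, chi2, df, combined)


def gene_intron_concordance(
    gene_calls: Dict[str, Sequence],
    intron_calls: Dict[str, Sequence],
    parent_of=None,
) -> pd.DataFrame:
    """Per-bait locus-level Jaccard of gene vs intron targets + Spearman rho.

    ``parent_of`` maps an intron feature id to its parent gene (defaults to
    the '<gene>:intron<i>' convention). The returned frame carries per-bait
    Jaccard values and the cross-bait Spearman correlation between gene- and
    intron-target counts in ``attrs['spearman_rho']``.
    """
    if parent_of is None:
        from .diffbind import parent_gene as parent_of  # noqa: PLC0415
    baits = sorted(set(gene_calls) | set(intron_calls))
    rows = []
    for bait in baits:
        g = {
            c.feature_id
            for c in gene_calls.get(bait, [])
            if getattr(c, "passed", True)
        }
        i = {
            parent_of(c.feature_id)
            for c in intron_calls.get(bait, [])
            if getattr(c, "passed", True)
        }
        union = g | i
        jac = len(g & i) / len(union) if union else math.nan
        rows.append((bait, len(g), len(i), jac))
    df = pd.DataFrame(
        rows, columns=["bait", "n_gene_targets", "n_intron_targets", "jaccard"]
    )
    if len(df) >= 3:
        rho = float(
            stats.spearmanr(df["n_gene_targets"], df["n_intron_targets"]).statistic
        )
    else:
        rho = math.nan
    df.attrs["spearman_rho"] = rho
    return df


def write_graphml(network: IntegratedNetwork, path) -> None:
    """Minimal GraphML export of the typed edge set."""
    from xml.sax.saxutils import escape

    nodes = sorted(
        {e.bait for e in network.edges} | {e.gene for e in network.edges}
    )
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write('<graphml xmlns="http://graphml.graphdrawing.org/xmlns">\n')
        fh.write('  <key id="kind" for="edge" attr.name="kind" attr.type="string"/>\n')
        fh.write('  <key id="strength" for="edge" attr.name="strength" attr.type="double"/>\n')
        fh.write('  <graph edgedefault="directed">\n')
        for n in nodes:
            fh.write(f'    <node id="{escape(n)}"/>\n')
        for e in network.edges:
            fh.write(
                f'    <edge source="{escape(e.bait)}" target="{escape(e.gene)}">'
                f'<data key="kind">{e.kind}</data>'
                f'<data key="strength">{e.strength:.4f}</data></edge>\n'
            )
        fh.write("  </graph>\n</graphml>\n")
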