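"""Gene x RBP occupancy matrix and the statistics built on top of it.

High-occupancy-target (HOT) RNAs are genes bound by at least half the
baits; their excess over a Poisson-binomial independence null (conditioned
on being bound at least once) is the headline statistic. Also provides
pairwise target-set overlap, generic set enrichment, class rank-sum
comparisons and down-the-rank-list enrichment curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class BindingMatrix:
    """Boolean occupancy and -log10(local idr) strengths, genes x baits."""

    occupancy: pd.DataFrame  # bool
    strength: pd.DataFrame  # float, 0 where unbound

    def __post_init__(self) -> None:
        occ = self.occupancy.to_numpy()
        stg = self.strength.to_numpy()
        if occ.shape != stg.shape:
            raise ValueError("occupancy and strength shapes differ")
        if not ((stg > 0) == occ).all():
            raise ValueError("strength > 0 must coincide with occupancy")

    @property
    def genes(self) -> List[str]:
        return list(self.occupancy.index)

    @property
    def baits(self) -> List[str]:
        return list(self.occupancy.columns)

    @property
    def n_baits(self) -> int:
        return self.occupancy.shape[1]

    @property
    def bait_target_counts(self) -> pd.Series:
        return self.occupancy.sum(axis=0)

    @property
    def gene_occupancy(self) -> pd.Series:
        return self.occupancy.sum(axis=1)

    @property
    def bound_universe(self) -> List[str]:
        return list(self.occupancy.index[self.gene_occupancy >= 1])

    def targets(self, bait: str) -> set:
        return set(self.occupancy.index[self.occupancy[bait]])


@dataclass
class HotSet:
    threshold: int
    genes: List[str]
    observed: int
    expected: float
    fold: float
    p_value: float
    conditioned: bool


@dataclass
class SetEnrichment:
    query_size: int
    reference_size: int
    universe_size: int
    overlap: int
    test: str
    p_value: float
    fold: float


def build_binding_matrix(calls_by_bait: Dict[str, Sequence]) -> BindingMatrix:
    """Assemble the occupancy/strength matrices from per-bait binding calls.

    Accepts passing :class:`~ripnet.diffbind.BindingCall` objects (or any
    object with ``feature_id``, ``local_idr``, ``passed``, ``strength``).
    Duplicate (gene, bait) entries keep the smallest local idr.
    """
    baits = sorted(calls_by_bait)
    best: Dict[Tuple[str, str], float] = {}
    for bait, calls in calls_by_bait.items():
        for c in calls:
            if not getattr(c, "passed", True):
                continue
            key = (c.feature_id, bait)
            if key in best:
                log.warning("duplicate call for %s/%s; keeping min idr", *key)
                best[key] = min(best[key], c.local_idr)
            else:
                best[key] = c.local_idr
    genes = sorted({g for g, _ in best})
    occ = pd.DataFrame(False, index=genes, columns=baits, dtype=bool)
    stg = pd.DataFrame(0.0, index=genes, columns=baits)
    for (g, b), idr in best.items():
        occ.loc[g, b] = True
        stg.loc[g, b] = min(-math.log10(max(idr, 1e-12)), 12.0)
    return BindingMatrix(occ, stg)


def poisson_binomial_pmf(p: Sequence[float]) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_j), by DP convolution."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for j, pj in enumerate(p):
        pmf[1: j + 2] = pmf[1: j + 2] * (1 - pj) + pmf[: j + 1] * pj
        pmf[0] *= 1 - pj
    return pmf


def poisson_binomial_tail(p: Sequence[float], t: int) -> float:
    """q = P(X >= t) for the Poisson-binomial sum."""
    p = np.asarray(p, dtype=float)
    if not 0 <= t <= p.size:
        raise ValueError("t out of range")
    if t == 0:
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        return 1.0
    pmf = poisson_binomial_pmf(p)
    return float(min(1.0, pmf[t:].sum()))


def occupancy_null(matrix: BindingMatrix) -> np.ndarray:
    """Per-bait binding probabilities n_j / |bound universe|."""
    universe = len(matrix.bound_universe)
    if universe == 0:
        raise ValueError("bound universe is empty")
    return matrix.bait_target_counts.to_numpy(dtype=float) / universe


def hot_test(matrix: BindingMatrix, conditioned: bool = True) -> HotSet:
    """HOT RNA excess over the Poisson-binomial independence null.

    The null is conditioned on a gene being bound by at least one bait
    (tail divided by 1 - P(X=0)); the observed HOT count is compared with a
    binomial over the bound universe at the conditioned per-gene tail.
    """
    p = occupancy_null(matrix)
    if (p == 0).all():
        raise ValueError("all per-bait probabilities are zero")
    t = math.ceil(matrix.n_baits / 2)
    occ = matrix.gene_occupancy
    hot = sorted(occ.index[occ >= t])
    universe = len(matrix.bound_universe)
    pmf = poisson_binomial_pmf(p)
    q = float(pmf[t:].sum())
    if conditioned:
        q = q / (1.0 - float(pmf[0])) if pmf[0] < 1 else 0.0
    expected = universe * q
    observed = len(hot)
    fold = observed / expected if expected > 0 else math.inf
    pval = float(stats.binom.sf(observed - 1, universe, min(q, 1.0))) if q > 0 else (
        0.0 if observed > 0 else 1.0
    )
    return HotSet(t, hot, observed, expected, fold, max(pval, 0.0), conditioned)


def max_occupancy_test(matrix: BindingMatrix, m: int) -> float:
    """P(max gene occupancy >= m) under bait-independence across genes."""
    if m > matrix.n_baits:
        raise ValueError("m exceeds the number of baits")
    p = occupancy_null(matrix)
    q = poisson_binomial_tail(p, m)
    N = len(matrix.bound_universe)
    if q == 0:
        return 0.0
    return float(1.0 - (1.0 - q) ** N)


def set_enrichment(
    query: set,
    reference: set,
    universe: set,
    test: str = "hypergeometric",
) -> SetEnrichment:
    """Upper-tail enrichment of ``query`` for ``reference`` within ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not (query <= universe and reference <= universe):
        raise ValueError("query/reference must be subsets of the universe")
    U, nq, nr = len(universe), len(query), len(reference)
    k = len(query & reference)
    rate = nr / U
    if test == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, U, nr, nq)) if nq else 1.0
    elif test == "binomial":
        p = float(stats.binom.sf(k - 1, nq, rate)) if nq else 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    fold = (k / nq) / rate if nq and rate > 0 else math.nan
    return SetEnrichment(nq, nr, U, k, test, min(max(p, 0.0), 1.0), fold)


def pairwise_overlap(
    matrix: BindingMatrix,
    universe: set,
    alpha: float = 0.01,
) -> Tuple[pd.DataFrame, int]:
    """Hypergeometric overlap of every unordered bait pair's target sets.

    Returns the per-pair table and the count significant at ``alpha``.
    """
    if matrix.n_baits < 2:
        raise ValueError("need >=2 baits")
    rows = []
    for b1, b2 in combinations(matrix.baits, 2):
        t1 = matrix.targets(b1) & universe
        t2 = matrix.targets(b2) & universe
        if not t1 or not t2:
            rows.append((b1, b2, len(t1), len(t2), 0, 1.0))
            continue
        res = set_enrichment(t1, t2, universe)
        rows.append((b1, b2, len(t1), len(t2), res.overlap, res.p_value))
    df = pd.DataFrame(
        rows, columns=["bait1", "bait2", "n1", "n2", "overlap", "p_value"]
    )
    return df, int((df["p_value"] < alpha).sum())


def class_rank_sum(
    statistic: pd.Series, class_labels: pd.Series
) -> pd.DataFrame:
    """Two-sided rank-sum test of each class against the rest.

    Exact enumeration when both groups have <= 10 members and no ties;
    normal approximation with tie correction otherwise.
    """
    classes = sorted(class_labels.unique())
    if len(classes) < 2:
        raise ValueError("need >=2 classes")
    rows = []
    for cls in classes:
        grp = statistic[class_labels == cls].to_numpy(dtype=float)
        rest = statistic[class_labels != cls].to_numpy(dtype=float)
        if grp.size < 2 or rest.size < 2:
            rows.append((cls, grp.size, math.nan, False))
            continue
        pooled = np.concatenate([grp, rest])
        if np.ptp(pooled) == 0:
            rows.append((cls, grp.size, 1.0, True))
            continue
        has_ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (grp.size <= 10 and rest.size <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(grp, rest, alternative="two-sided", method=method)
        rows.append((cls, grp.size, float(res.pvalue), True))
    return pd.DataFrame(rows, columns=["class", "n", "p_value", "defined"])


def rank_list_enrichment(
    matrix: BindingMatrix,
    bait: str,
    gene_set: set,
    universe: set,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Per-bin -log10 hypergeometric p down a bait's idr-ranked target list."""
    stg = matrix.strength[bait]
    targets = stg[matrix.occupancy[bait]]
    ranked = targets.sort_values(ascending=False).index.tolist()  # idr ascending
    if len(ranked) < bin_size:
        log.warning("bait %s has fewer targets than one bin", bait)
    ref = gene_set & universe
    rows = []
    for i, start in enumerate(range(0, len(ranked), bin_size)):
        binned = set(ranked[start: start + bin_size]) & universe
        if binned and ref:
            res = set_enrichment(binned, ref, universe)
            p = res.p_value
        else:
            p = 1.0
        rows.append((i, len(binned), -math.log10(max(p, P_FLOOR))))
    return pd.DataFrame(rows, columns=["bin", "n", "neg_log10_p"])


def median_rank_curve(
    matrix: BindingMatrix, gene_set: set, universe: set, bin_size: int = 100
) -> pd.DataFrame:
    """Median across baits of the per-bin rank-list enrichment curves."""
    curves = []
    for bait in matrix.baits:
        df = rank_list_enrichment(matrix, bait, gene_set, universe, bin_size)
        curves.append(df.set_index("bin")["neg_log10_p"])
    wide = pd.concat(curves, axis=1)
    return wide.median(axis=1).rename("median_neg_log10_p").reset_index()
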