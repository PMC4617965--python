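"""Per-replicate negative-binomial enrichment testing and target calling.

The machinery mirrors the classic count-based differential test: median-of-
ratios size factors, method-of-moments dispersions shrunk toward a fitted
mean-dispersion trend, and a conditional exact-style NB test per feature.
Target calls combine a two-replicate reproducibility model (see
:mod:`ripnet.idr`) with a fold-change requirement in every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .idr import IdrResult, fit_idr

log = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
STRENGTH_CAP = 12.0  # local idr floored at 1e-12 before -log10
FC_PSEUDOCOUNT = 0.5


@dataclass
class CountTable:
    """Integer count matrix (features x samples) plus a sample sheet.

    The sample sheet has columns ``sample_id``, ``bait``, ``replicate``,
    ``is_control``; controls carry an empty bait.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.samples["sample_id"]) <= set(self.counts.columns):
            raise ValueError("sample sheet references samples absent from counts")
        vals = self.counts[self.samples["sample_id"].tolist()].to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if int(self.samples["is_control"].sum()) < 2:
            raise ValueError("need >=2 control samples")

    @property
    def feature_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def control_ids(self) -> List[str]:
        return self.samples.loc[self.samples["is_control"], "sample_id"].tolist()

    @property
    def baits(self) -> List[str]:
        m = ~self.samples["is_control"]
        return sorted(self.samples.loc[m, "bait"].unique())

    def ip_samples(self, bait: str) -> pd.DataFrame:
        m = (~self.samples["is_control"]) & (self.samples["bait"] == bait)
        return self.samples.loc[m].sort_values("replicate")

    @classmethod
    def read(cls, counts_tsv, samples_tsv) -> "CountTable":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(
            samples_tsv, sep="\t", dtype={"sample_id": str, "bait": str}
        )
        samples["bait"] = samples["bait"].fillna("")
        samples["is_control"] = samples["is_control"].astype(bool)
        return cls(counts, samples)

    def write(self, counts_tsv, samples_tsv) -> None:
        self.counts.to_csv(counts_tsv, sep="\t")
        self.samples.to_csv(samples_tsv, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    feature_id: str
    bait: str
    replicate: int
    base_mean: float
    fold_change: float
    p_value: float
    fc_defined: bool = True


@dataclass
class BindingCall:
    feature_id: str
    bait: str
    local_idr: float
    min_fold_change: float
    passed: bool

    @property
    def strength(self) -> float:
        return min(-np.log10(max(self.local_idr, 1e-12)), STRENGTH_CAP)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "cannot normalize (check library depth / feature filtering)"
        )
    logmat = np.log(mat[positive])
    loggeo = logmat.mean(axis=1)
    factors = np.exp(np.median(logmat - loggeo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _raw_dispersions(
    counts: pd.DataFrame, control_ids: Sequence[str], size_factors: pd.Series
) -> Tuple[np.ndarray, np.ndarray]:
    """Method-of-moments dispersion per feature from control samples.

    For normalized counts w_ij = k_ij / s_j: E w = mu, Var w_j = mu/s_j +
    alpha mu^2, so alpha = (s2 - mu * mean(1/s)) / mu^2.
    """
    if len(control_ids) < 2:
        raise ValueError("need >=2 control samples for dispersion estimation")
    s = size_factors[list(control_ids)].to_numpy()
    w = counts[list(control_ids)].to_numpy(dtype=float) / s
    mu = w.mean(axis=1)
    s2 = w.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu * np.mean(1.0 / s)) / mu**2
    alpha[~np.isfinite(alpha)] = 0.0
    return mu, alpha


def _fit_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> Tuple[float, float]:
    """Gamma-family regression of dispersion on base mean: a0 + a1/mu."""
    import statsmodels.api as sm

    keep = (mu > 0) & (alpha_raw > 1e-6)
    if keep.sum() < 10:
        med = float(np.median(np.maximum(alpha_raw[mu > 0], ALPHA_FLOOR)))
        return max(med, ALPHA_FLOOR), 0.0
    X = np.column_stack([np.ones(keep.sum()), 1.0 / mu[keep]])
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                alpha_raw[keep],
                X,
                family=sm.families.Gamma(link=sm.families.links.Identity()),
            ).fit(maxiter=100)
        a0, a1 = float(fit.params[0]), float(fit.params[1])
        if not np.isfinite(a0) or a0 <= 0:
            raise ValueError
    except Exception:
        coef, *_ = np.linalg.lstsq(X, alpha_raw[keep], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, ALPHA_FLOOR), max(a1, 0.0)


def estimate_dispersions(
    counts: pd.DataFrame,
    control_ids: Sequence[str],
    size_factors: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-feature dispersion: raw MoM shrunk (log-space) toward the trend."""
    mu, alpha_raw = _raw_dispersions(counts, control_ids, size_factors)
    a0, a1 = _fit_trend(mu, alpha_raw)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-12)
    trend = np.maximum(trend, ALPHA_FLOOR)
    raw = np.maximum(alpha_raw, ALPHA_FLOOR)
    alpha = np.exp(
        (1.0 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    alpha[mu <= 0] = trend[mu <= 0] if np.ndim(trend) else trend
    return pd.Series(np.maximum(alpha, ALPHA_FLOOR), index=counts.index, name="dispersion")


def _nb_r_p(mean: float, var: float) -> Tuple[float, float]:
    """scipy (n, p) parameters for an NB with the given mean and variance."""
    var = max(var, mean * (1 + 1e-8))
    r = mean**2 / (var - mean)
    return r, r / (r + mean)


def nb_test_counts(
    k_a: int,
    k_b: int,
    s_a: np.ndarray,
    s_b: np.ndarray,
    alpha: float,
) -> float:
    """Two-sided conditional NB test on pooled group counts.

    Conditions on the total count N = k_a + k_b; the p-value is the summed
    conditional probability of splits (a, N - a) no more likely than the
    observed one, where each group total is NB with mean proportional to its
    summed size factors and variance from the mu + alpha mu^2 model.
    """
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    N = int(k_a + k_b)
    if N == 0:
        return 1.0
    S = s_a.sum() + s_b.sum()
    mu = N / S  # shared per-unit mean under the null
    mean_a, var_a = mu * s_a.sum(), float((mu * s_a + alpha * (mu * s_a) ** 2).sum())
    mean_b, var_b = mu * s_b.sum(), float((mu * s_b + alpha * (mu * s_b) ** 2).sum())
    r_a, p_a = _nb_r_p(mean_a, var_a)
    r_b, p_b = _nb_r_p(mean_b, var_b)
    a = np.arange(N + 1)
    logp = stats.nbinom.logpmf(a, r_a, p_a) + stats.nbinom.logpmf(N - a, r_b, p_b)
    m = logp.max()
    probs = np.exp(logp - m)
    total = probs.sum()
    obs = probs[k_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum() / total))


def enrichment_test(
    table: CountTable,
    bait: str,
    size_factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
) -> List[EnrichmentResult]:
    """Per-replicate IP-vs-pooled-controls NB test for one bait."""
    if size_factors is None:
        size_factors = estimate_size_factors(table.counts)
    if dispersions is None:
        dispersions = estimate_dispersions(
            table.counts, table.control_ids, size_factors
        )
    ctrl = table.control_ids
    s_b = size_factors[ctrl].to_numpy()
    ctrl_norm = (table.counts[ctrl].to_numpy(dtype=float) / s_b).mean(axis=1)
    out: List[EnrichmentResult] = []
    for _, row in table.ip_samples(bait).iterrows():
        sid, rep = row["sample_id"], int(row["replicate"])
        s_a = np.array([size_factors[sid]])
        ip_counts = table.counts[sid].to_numpy()
        ctrl_counts = table.counts[ctrl].to_numpy()
        for i, fid in enumerate(table.feature_ids):
            k_a = int(ip_counts[i])
            k_b = int(ctrl_counts[i].sum())
            ip_norm = k_a / s_a[0]
            fc_defined = (k_a + k_b) > 0
            fc = (ip_norm + FC_PSEUDOCOUNT) / (ctrl_norm[i] + FC_PSEUDOCOUNT)
            p = (
                nb_test_counts(k_a, k_b, s_a, s_b, float(dispersions.iloc[i]))
                if fc_defined
                else 1.0
            )
            base = (ip_norm + ctrl_norm[i] * len(ctrl)) / (1 + len(ctrl))
            out.append(
                EnrichmentResult(fid, bait, rep, base, fc, p, fc_defined)
            )
    return out


def call_targets(
    enrichments: Sequence[EnrichmentResult],
    idr_results: Dict[str, IdrResult],
    idr_threshold: float = 0.10,
    fc_threshold: float = 1.5,
) -> List[BindingCall]:
    """Combine per-replicate fold changes with local IDR into target calls."""
    by_feat: Dict[str, List[EnrichmentResult]] = {}
    bait = enrichments[0].bait if enrichments else ""
    for e in enrichments:
        by_feat.setdefault(e.feature_id, []).append(e)
    calls = []
    for fid, reps in by_feat.items():
        if fid not in idr_results:
            continue
        fcs = [e.fold_change for e in reps]
        local = idr_results[fid].local_idr
        passed = local <= idr_threshold and all(fc >= fc_threshold for fc in fcs)
        calls.append(BindingCall(fid, bait, local, min(fcs), passed))
    calls.sort(key=lambda c: (c.local_idr, c.feature_id))
    return calls


def run_bait(
    table: CountTable,
    bait: str,
    size_factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
    idr_threshold: float = 0.10,
    fc_threshold: float = 1.5,
) -> Tuple[List[EnrichmentResult], Dict[str, IdrResult], List[BindingCall]]:
    """Full per-bait pipeline: NB tests per replicate, IDR, target calls."""
    if size_factors is None:
        size_factors = estimate_size_factors(table.counts)
    if dispersions is None:
        dispersions = estimate_dispersions(
            table.counts, table.control_ids, size_factors
        )
    enr = enrichment_test(table, bait, size_factors, dispersions)
    reps = sorted({e.replicate for e in enr})
    if len(reps) != 2:
        log.warning("bait %s has %d replicates; IDR needs 2", bait, len(reps))
    p1 = {e.feature_id: e.p_value for e in enr if e.replicate == reps[0]}
    p2 = {e.feature_id: e.p_value for e in enr if e.replicate == reps[-1]}
    feats = [f for f in table.feature_ids if f in p1 and f in p2]
    idr_res = fit_idr(
        np.array([p1[f] for f in feats]),
        np.array([p2[f] for f in feats]),
        feature_ids=feats,
        bait=bait,
    )
    calls = call_targets(enr, idr_res, idr_threshold, fc_threshold)
    return enr, idr_res, calls


def filter_introns(
    intron_spans: Dict[str, Tuple[str, int, int]],
    exon_spans: Sequence[Tuple[str, int, int]],
) -> List[str]:
    """Keep intron features whose span intersects no exon of any gene.

    ``intron_spans`` maps feature_id -> (chrom, start, end).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, a, b in exon_spans:
        by_chrom.setdefault(chrom, []).append((a, b))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    kept = []
    for fid, (chrom, a, b) in intron_spans.items():
        ivs = by_chrom.get(chrom, [])
        # binary search over sorted exon starts
        import bisect

        i = bisect.bisect_left(ivs, (b, b))
        hit = any(iv[1] > a for iv in ivs[max(0, i - 50): i])
        if not hit:
            kept.append(fid)
    if not kept:
        log.warning("no intron features survive the exon-overlap filter")
    return kept


def intron_mode(
    intron_table: CountTable,
    bait: str,
    keep_features: Optional[Sequence[str]] = None,
    parent_of: Optional[Dict[str, str]] = None,
    **kwargs,
) -> Tuple[List[EnrichmentResult], Dict[str, IdrResult], List[BindingCall]]:
    """Run the gene-mode machinery on (pre-filtered) intron-level counts."""
    if keep_features is not None:
        table = CountTable(
            intron_table.counts.loc[list(keep_features)], intron_table.samples
        )
    else:
        table = intron_table
    return run_bait(table, bait, **kwargs)


def parent_gene(feature_id: str) -> str:
    """Parent gene of an intron feature named '<gene>:intron<i>'."""
    return feature_id.split(":", 1)[0]


def calls_to_frame(calls: Sequence[BindingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "bait": [c.bait for c in calls],
            "local_idr": [c.local_idr for c in calls],
            "min_fold_change": [c.min_fold_change for c in calls],
            "passed": [c.passed for c in calls],
            "strength": [c.strength for c in calls],
        }
    )


def write_calls_bed(
    calls: Sequence[BindingCall],
    spans: Dict[str, Tuple[str, int, int]],
    path,
) -> None:
    """Passing calls as BED6; score = round(1000 * min(1, strength/12))."""
    with open(path, "w") as fh:
        for c in calls:
            if not c.passed or c.feature_id not in spans:
                continue
            chrom, a, b = spans[c.feature_id]
            score = int(round(1000 * min(1.0, c.strength / STRENGTH_CAP)))
            fh.write(f"{chrom}\t{a}\t{b}\t{c.feature_id}\t{score}\t.\n")
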