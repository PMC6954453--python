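"""Internally weighted genetic-risk-score interaction tests (GRS-M, GRS-I).

GRS-M weights each SNP by its marginal effect estimate and selects SNPs by
marginal P-value; because the selection statistic is independent of the
interaction statistic under the null, no sample splitting is needed.
GRS-I weights by the SNP-by-exposure interaction estimate itself, so the
sample is split 1:1 into a training half (weights and selection P-values)
and a testing half (score construction and the interaction test).

Each test is run over ten selection P-value thresholds; the combined
statistic (M* or I*) is Bonferroni: min(1, 10 * min per-threshold P).
Pre-scores are rescaled so the score reads as a calibrated count of
phenotype-increasing (or synergistic) alleles: score = pre-score * (number
of available SNPs) / (sum of |weights| of available SNPs), with
"available" evaluated per subject (selected and non-missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .genotype_io import GenotypeMatrix
from .glm_engine import fit_glm, fit_interaction_scan, fit_marginal_scan
from .phenotype import SampleTable

__all__ = [
    "DEFAULT_THRESHOLDS",
    "GRSWeights",
    "GRSTestResult",
    "build_grs",
    "grs_interaction_test",
    "bonferroni_combine",
    "split_sample",
    "run_grs_m",
    "run_grs_i",
]

DEFAULT_THRESHOLDS = (
    0.0001,
    0.00025,
    0.0005,
    0.001,
    0.0025,
    0.005,
    0.01,
    0.025,
    0.05,
    0.1,
)


@dataclass
class GRSWeights:
    """Per-SNP score weights and the selection P-values that gate them."""

    weights: np.ndarray
    select_p: np.ndarray
    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if not (np.all(np.diff(t) > 0) and np.all((t > 0) & (t < 1))):
            raise ValueError("thresholds must be strictly increasing within (0, 1)")


@dataclass
class GRSTestResult:
    """Per-threshold interaction tests and the Bonferroni-combined P."""

    method: str
    thresholds: np.ndarray
    n_snps: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    combined_p: float
    skipped: list = field(default_factory=list)


def build_grs(g: GenotypeMatrix, w: GRSWeights, t: float) -> np.ndarray:
    """Per-subject rescaled genetic risk score at selection threshold ``t``.

    A SNP contributes when its selection P-value is strictly below ``t`` and
    the subject's genotype is non-missing.  A subject with no available SNP
    gets a score of 0.
    """
    sel = np.nan_to_num(w.select_p, nan=1.0) < t
    if not sel.any():
        raise ValueError(f"no SNP passes the selection threshold {t}")
    d = g.dosages[:, sel]
    wt = w.weights[sel]
    miss = np.isnan(d)
    d0 = np.where(miss, 0.0, d)
    pre = d0 @ wt
    n_avail = (~miss).sum(axis=1)
    denom = (~miss) @ np.abs(wt)
    score = np.zeros(g.n_samples)
    ok = denom > 0
    score[ok] = pre[ok] * n_avail[ok] / denom[ok]
    return score


def grs_interaction_test(score: np.ndarray, s: SampleTable):
    """Wald test of the score-by-exposure term in trait ~ score + E + score*E + X.

    Returns ``(coef, se, p)`` or ``None`` when the model is degenerate
    (constant score or constant exposure).
    """
    if not s.prepared:
        raise ValueError("SampleTable must be prepared before testing")
    if np.std(score) == 0 or np.std(s.e) == 0:
        return None
    n = s.n
    X = np.column_stack([np.ones(n), s.x, score, s.e, score * s.e])
    coef, cov, converged, df = fit_glm(X, s.y, s.y_family)
    if not converged or not cov[-1, -1] > 0:
        return None
    b = coef[-1]
    se = np.sqrt(cov[-1, -1])
    if s.y_family == "gaussian":
        p = 2.0 * stats.t.sf(abs(b / se), df)
    else:
        p = 2.0 * stats.norm.sf(abs(b / se))
    return float(b), float(se), float(p)


def bonferroni_combine(pvals, n_thresholds: Optional[int] = None) -> float:
    """min(1, T * min(pvals)) with T the full threshold count.

    Thresholds skipped for lack of selected SNPs drop out of the minimum but
    still count toward T (conservative).
    """
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[~np.isnan(pvals)]
    if pvals.size == 0:
        raise ValueError("no per-threshold P-values to combine")
    T = n_thresholds if n_thresholds is not None else pvals.size
    return min(1.0, T * float(pvals.min()))


def split_sample(n: int, seed=None):
    """Random 1:1 split into training and testing index arrays.

    Odd n puts the extra subject in the training half.
    """
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = (n + 1) // 2
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _threshold_sweep(g, weights, s_test, method):
    thresholds = np.asarray(weights.thresholds, dtype=float)
    T = thresholds.size
    n_snps = np.zeros(T, dtype=int)
    coef = np.full(T, np.nan)
    se = np.full(T, np.nan)
    p = np.full(T, np.nan)
    skipped = []
    for i, t in enumerate(thresholds):
        sel = np.nan_to_num(weights.select_p, nan=1.0) < t
        n_snps[i] = int(sel.sum())
        if n_snps[i] == 0:
            skipped.append((float(t), "no SNP passes the threshold"))
            continue
        score = build_grs(g, weights, t)
        res = grs_interaction_test(score, s_test)
        if res is None:
            skipped.append((float(t), "degenerate interaction model"))
            continue
        coef[i], se[i], p[i] = res
    if np.isnan(p).all():
        combined = 1.0
    else:
        combined = bonferroni_combine(p, n_thresholds=T)
    return GRSTestResult(
        method=method,
        thresholds=thresholds,
        n_snps=n_snps,
        coef=coef,
        se=se,
        p=p,
        combined_p=combined,
        skipped=skipped,
    )


def run_grs_m(
    g: GenotypeMatrix,
    s: SampleTable,
    thresholds=DEFAULT_THRESHOLDS,
    marginal=None,
) -> GRSTestResult:
    """GRS weighted by marginal SNP effects, tested on the full sample.

    Deterministic given the data: selection by marginal association does not
    bias the interaction test, so no sample splitting (and no RNG) is used.
    ``marginal`` may carry a precomputed marginal scan on the same sample.
    """
    if not s.prepared:
        s = s.prepare(standardize=False)
    scan = marginal if marginal is not None else fit_marginal_scan(g, s)
    select_p = np.where(scan.converged, scan.p_g, np.nan)
    weights = GRSWeights(
        weights=np.nan_to_num(scan.beta_g),
        select_p=select_p,
        thresholds=tuple(thresholds),
    )
    return _threshold_sweep(g, weights, s, method="GRS-M")


def run_grs_i(
    g: GenotypeMatrix,
    s: SampleTable,
    thresholds=DEFAULT_THRESHOLDS,
    seed=None,
) -> GRSTestResult:
    """GRS weighted by interaction effects estimated on a training half.

    The interaction scan runs on the training subset only; scores and the
    final interaction test use the disjoint testing subset, preserving the
    type I error rate.
    """
    if not s.prepared:
        s = s.prepare(standardize=False)
    train, test = split_sample(s.n, seed=seed)
    scan = fit_interaction_scan(g.take_samples(train), s.subset(train))
    select_p = np.where(scan.converged, scan.p_ge, np.nan)
    weights = GRSWeights(
        weights=np.nan_to_num(scan.beta_ge),
        select_p=select_p,
        thresholds=tuple(thresholds),
    )
    return _threshold_sweep(g.take_samples(test), weights, s.subset(test), method="GRS-I")
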