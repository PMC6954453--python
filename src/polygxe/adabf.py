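"""Adaptive combination of Bayes factors (ADABF) polygenic interaction test.

For each screened SNP the interaction coefficient estimate and its variance
feed a Wakefield approximate Bayes factor with a N(0, W) prior on the
interaction effect (default W = 0.2^2 = 0.04).  The log-BFs are sorted in
decreasing order and aggregated into cumulative scores S_k; each S_k is
calibrated against B resampled score profiles drawn from the multivariate
normal null of the coefficient estimates, whose covariance couples the
per-SNP variances through the genotype correlation matrix.  The overall
P-value recalibrates the minimum per-k P-value (min-P) against its own
resampling distribution, so no multiple-testing correction over k is
needed.  The same resamples yield a resampling false-discovery-rate curve
used to pinpoint individual SNP-by-exposure interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genotype_io import GenotypeMatrix, genotype_correlation
from .glm_engine import fit_interaction_scan, fit_marginal_scan, screen_snps
from .phenotype import SampleTable

__all__ = [
    "BayesFactorSet",
    "NullEnsemble",
    "ADABFResult",
    "log_bayes_factor",
    "summary_scores",
    "draw_null",
    "overall_p",
    "resampling_fdr",
    "run_adabf",
]

DEFAULT_PRIOR_W = 0.04


@dataclass
class BayesFactorSet:
    """Per-SNP natural-log Bayes factors and their descending sort order."""

    log_bf: np.ndarray
    order: np.ndarray
    prior_w: float = DEFAULT_PRIOR_W

    @classmethod
    def from_scan(cls, beta_ge, var_ge, prior_w=DEFAULT_PRIOR_W):
        lbf = log_bayes_factor(beta_ge, var_ge, prior_w)
        # stable mergesort on -log_bf: ties broken by original SNP index
        order = np.argsort(-lbf, kind="stable")
        return cls(log_bf=lbf, order=order, prior_w=prior_w)


@dataclass
class NullEnsemble:
    """B resampled log-BF vectors and score profiles under the global null."""

    b: int
    null_log_bf: np.ndarray  # (B, L)
    null_scores: np.ndarray  # (B, L), row-wise cumulative sorted log-BFs
    seed: Optional[int]
    cov: np.ndarray  # (L, L) repaired covariance of the coefficient MLEs


@dataclass
class ADABFResult:
    """Overall test outcome plus the per-SNP selection by resampling FDR."""

    s_obs: np.ndarray
    p_k: np.ndarray
    min_p: float
    p_overall: float
    below_resolution: bool  # True when no resample was as extreme: report "< 1/B"
    fdr_curve: np.ndarray
    selected: np.ndarray  # SNP ids, a prefix of the BF-descending order
    selected_idx: np.ndarray  # indices into the screened panel
    screened: np.ndarray  # indices of screened SNPs in the input panel
    log_bf: np.ndarray
    b: int

    @property
    def p_display(self) -> str:
        return f"< {1.0 / self.b:g}" if self.below_resolution else f"{self.p_overall:g}"


def log_bayes_factor(beta_ge, v, w=DEFAULT_PRIOR_W):
    """Natural-log Wakefield Bayes factor for H1: beta != 0 vs H0: beta = 0.

    log BF = 0.5*log(v/(v+w)) + beta^2 * w / (2 v (v+w)), computed in log
    space so z-scores up to |beta|/sqrt(v) ~ 40 do not overflow.  ``v`` is
    the estimated variance of the coefficient MLE and ``w`` the prior
    variance of the true effect.
    """
    beta_ge = np.asarray(beta_ge, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("coefficient variance must be positive")
    if w < 0:
        raise ValueError("prior variance must be nonnegative")
    return 0.5 * np.log(v / (v + w)) + beta_ge**2 * w / (2.0 * v * (v + w))


def summary_scores(log_bf: np.ndarray) -> np.ndarray:
    """Cumulative sums S_1..S_L of the log-BFs sorted in decreasing order."""
    log_bf = np.asarray(log_bf, dtype=float)
    if log_bf.size < 1:
        raise ValueError("need at least one log Bayes factor")
    return np.cumsum(np.sort(log_bf)[::-1])


def _repair_psd(cov: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues, then rescale to the original diagonal."""
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-6 * max(vals.max(), 1e-30):
        raise ValueError("covariance is far from positive semidefinite")
    if vals.min() >= clip:
        return cov
    fixed = (vecs * np.maximum(vals, clip)) @ vecs.T
    d_orig = np.sqrt(np.diag(cov))
    d_new = np.sqrt(np.diag(fixed))
    scale = d_orig / d_new
    return fixed * np.outer(scale, scale)


def draw_null(
    cov: np.ndarray,
    b: int,
    w: float = DEFAULT_PRIOR_W,
    seed=None,
) -> NullEnsemble:
    """Draw B null coefficient vectors ~ N(0, cov) and score each one.

    Each resampled vector is converted entry-wise to a log Bayes factor
    using the corresponding diagonal variance, then sorted and accumulated
    into a score profile.
    """
    cov = np.asarray(cov, dtype=float)
    L = cov.shape[0]
    if b < 100:
        import warnings

        warnings.warn("fewer than 100 resamples: P-value resolution is coarse")
    cov = _repair_psd(cov)
    rng = np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.diag(np.diag(cov)))
        draws = rng.standard_normal((b, L)) @ chol.T
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        factor = vecs * np.sqrt(np.maximum(vals, 0.0))
        draws = rng.standard_normal((b, L)) @ factor.T
    v_diag = np.diag(cov)
    null_log_bf = log_bayes_factor(draws, v_diag[None, :], w)
    null_scores = np.cumsum(np.sort(null_log_bf, axis=1)[:, ::-1], axis=1)
    return NullEnsemble(
        b=b, null_log_bf=null_log_bf, null_scores=null_scores, seed=seed, cov=cov
    )


def _p_profiles(s_obs: np.ndarray, null_scores: np.ndarray):
    """Observed p_k plus leave-one-out p_k^(b) for every resample.

    p_k       = (1/B)     * #{b : S_k^(b) >= S_k}
    p_k^(b)   = (1/(B-1)) * #{b' != b : S_k^(b') >= S_k^(b)}

    The leave-one-out count is obtained by ranking each column: for a value
    v in a column, #{others >= v} = #{all >= v} - 1, computed with a sort
    per k (O(B log B)), exactly equivalent to the double sum.
    """
    B, L = null_scores.shape
    p_obs = np.empty(L)
    p_null = np.empty((B, L))
    for k in range(L):
        col = null_scores[:, k]
        srt = np.sort(col)
        # #{values >= v} = B - (index of first element >= v)
        p_obs[k] = (B - np.searchsorted(srt, s_obs[k], side="left")) / B
        cnt_ge = B - np.searchsorted(srt, col, side="left")
        p_null[:, k] = (cnt_ge - 1) / (B - 1)
    return p_obs, p_null


def overall_p(s_obs: np.ndarray, ensemble: NullEnsemble):
    """Min-P combination of the S_k scores against the resampling null.

    Returns ``(p_k, min_p, p_overall, below_resolution)``.  ``p_overall`` is
    the fraction of resamples whose own min-P is at most the observed one;
    when that count is zero the flag signals the "< 1/B" display convention.
    """
    s_obs = np.asarray(s_obs, dtype=float)
    if s_obs.shape[0] != ensemble.null_scores.shape[1]:
        raise ValueError("observed scores and null ensemble have different L")
    p_k, p_null = _p_profiles(s_obs, ensemble.null_scores)
    min_p = float(p_k.min())
    min_p_null = p_null.min(axis=1)
    count = int((min_p_null <= min_p).sum())
    return p_k, min_p, count / ensemble.b, count == 0


def resampling_fdr(bf: BayesFactorSet, ensemble: NullEnsemble, q: float = 0.05):
    """Resampling false-discovery-rate curve and the selected SNP prefix.

    FP_(k) = (1/B) * sum_b sum_l I(BF_l^(b) >= BF_(k)) estimates the
    expected number of null SNPs scoring at least as high as the k-th
    largest observed BF; FDR_(k) = FP_(k) / k.  The selection is the
    largest k with FDR_(k) < q (possibly empty).
    """
    sorted_lbf = bf.log_bf[bf.order]
    flat = np.sort(ensemble.null_log_bf.ravel())
    # count of null log-BFs >= threshold, vectorized over all k
    cnt = flat.size - np.searchsorted(flat, sorted_lbf, side="left")
    fp = cnt / ensemble.b
    k = np.arange(1, sorted_lbf.size + 1)
    fdr_curve = fp / k
    passing = np.nonzero(fdr_curve < q)[0]
    k_star = int(passing.max()) + 1 if passing.size else 0
    return fdr_curve, bf.order[:k_star]


def run_adabf(
    g: GenotypeMatrix,
    s: SampleTable,
    w: float = DEFAULT_PRIOR_W,
    b: int = 1000,
    screen_alpha: float = 0.05,
    seed=None,
    fdr_q: float = 0.05,
    marginal=None,
) -> ADABFResult:
    """Full ADABF pipeline: screen, interaction scan, BFs, resampling null.

    ``marginal`` may carry a precomputed marginal scan (on the same prepared
    sample) so simulation harnesses can share it with the GRS-M test.  An
    empty screened set yields P = 1 and an empty selection.
    """
    if not s.prepared:
        s = s.prepare(standardize=True)
    marginal = marginal if marginal is not None else fit_marginal_scan(g, s)
    screened = screen_snps(marginal, screen_alpha)
    if screened.size == 0:
        return ADABFResult(
            s_obs=np.empty(0),
            p_k=np.empty(0),
            min_p=1.0,
            p_overall=1.0,
            below_resolution=False,
            fdr_curve=np.empty(0),
            selected=np.empty(0, dtype=g.snp_ids.dtype),
            selected_idx=np.empty(0, dtype=int),
            screened=screened,
            log_bf=np.empty(0),
            b=b,
        )
    scan = fit_interaction_scan(g, s, screened)
    usable = scan.converged
    screened = screened[usable]
    beta_ge = scan.beta_ge[usable]
    var_ge = scan.var_ge[usable]
    bfset = BayesFactorSet.from_scan(beta_ge, var_ge, prior_w=w)
    s_obs = summary_scores(bfset.log_bf)
    R = genotype_correlation(g, screened)
    cov = R * np.sqrt(np.outer(var_ge, var_ge))
    ensemble = draw_null(cov, b=b, w=w, seed=seed)
    p_k, min_p, p_ov, below = overall_p(s_obs, ensemble)
    fdr_curve, sel_local = resampling_fdr(bfset, ensemble, q=fdr_q)
    return ADABFResult(
        s_obs=s_obs,
        p_k=p_k,
        min_p=min_p,
        p_overall=p_ov,
        below_resolution=below,
        fdr_curve=fdr_curve,
        selected=g.snp_ids[screened[sel_local]],
        selected_idx=screened[sel_local],
        screened=screened,
        log_bf=bfset.log_bf,
        b=b,
    )
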