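"""Synthetic genotype/exposure/trait generator and the experiment harness.

Genotypes are drawn in Hardy-Weinberg proportions with minor-allele
frequencies uniform over a configurable interval; optional linkage
disequilibrium comes from thresholding two AR(1) latent Gaussian haplotypes
per subject.  The binary exposure is Bernoulli with prevalence 0.248 (the
smoking rate in the cohort the method was developed on).  Traits follow
logistic or linear models with a 5% disease prevalence intercept
(log(0.05/0.95)), D interacting SNPs whose |interaction effects| are drawn
uniformly from configurable intervals with exactly half positive signs,
and, optionally, SNP main effects arranged so that of 1.5*D causal SNPs the
first half-D have main effects only, the middle half-D both, and the last D
interactions only.

The harness measures per-method type I error, power, sensitivity, positive
predictive value, and false discovery proportion over seeded replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import expit

from .adabf import run_adabf
from .genotype_io import GenotypeMatrix
from .glm_engine import fit_interaction_scan, fit_marginal_scan
from .grs import DEFAULT_THRESHOLDS, run_grs_i, run_grs_m
from .phenotype import SampleTable
from .single_marker import bh_select, bonferroni_select

__all__ = [
    "ScenarioSpec",
    "ExperimentResult",
    "REFERENCE_EFFECT_RANGES",
    "desk_scaled_range",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_traits",
    "run_type1_study",
    "run_power_study",
    "sensitivity_ppv",
]

#: |effect| intervals used in the original full-scale study (n = 16555)
REFERENCE_EFFECT_RANGES = {
    ("binomial", "smaller"): (math.log(1.2), math.log(1.4)),
    ("binomial", "larger"): (math.log(1.4), math.log(1.6)),
    ("gaussian", "smaller"): (0.05, 0.07),
    ("gaussian", "larger"): (0.07, 0.09),
}

REFERENCE_N = 16555  # sample size the effect intervals above were tuned for

PREVALENCE_5PCT_INTERCEPT = math.log(0.05 / 0.95)  # -2.944, prints as -2.94


def desk_scaled_range(family: str, size: str, n: int, n_ref: int = REFERENCE_N):
    """Effect interval rescaled by sqrt(n_ref/n) to preserve per-SNP power.

    The per-SNP interaction z-score scales as |beta|*sqrt(n); shrinking the
    sample while keeping the original intervals would push every method to
    the null and make power comparisons uninformative.  Multiplying the
    interval bounds by sqrt(n_ref/n) keeps each causal SNP's non-centrality
    at the full-scale study's operating point.
    """
    lo, hi = REFERENCE_EFFECT_RANGES[(family, size)]
    f = math.sqrt(n_ref / n)
    return (lo * f, hi * f)


@dataclass
class ScenarioSpec:
    """Design of one simulation scenario.

    ``d = 0`` is the global null.  With ``main_effects = "present"`` the
    scenario places 1.5*d causal SNPs (main-only / both / interaction-only
    thirds); ``main_effect_range`` defaults to ``effect_range``.
    """

    family: str = "gaussian"
    n: int = 2000
    l_snps: int = 300
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    e_prevalence: float = 0.248
    d: int = 0
    #: |interaction effect| interval; a tuple, or a preset name:
    #: "smaller"/"larger" (reference intervals) or "smaller_scaled"/
    #: "larger_scaled" (reference intervals times sqrt(REFERENCE_N/n))
    effect_range: Optional[object] = None
    main_effect_range: Optional[object] = None
    main_effects: str = "absent"
    prevalence_intercept: float = PREVALENCE_5PCT_INTERCEPT
    reps: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if self.main_effects not in ("absent", "present"):
            raise ValueError("main_effects must be 'absent' or 'present'")
        lo, hi = self.maf_range
        if not (0.01 < lo < hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.d < 0:
            raise ValueError("d must be nonnegative")
        if self.d:
            self.effect_range = self._resolve_range(self.effect_range)
            if self.main_effect_range is not None:
                self.main_effect_range = self._resolve_range(self.main_effect_range)
            if self.main_effects == "present":
                if self.d % 2:
                    raise ValueError("d must be even when main effects are present")
                if self.main_effect_range is None:
                    self.main_effect_range = self.effect_range
                if 3 * self.d // 2 > self.l_snps:
                    raise ValueError("need 1.5*d <= l_snps with main effects")
            elif self.d > self.l_snps:
                raise ValueError("need d <= l_snps")

    def _resolve_range(self, rng_spec):
        if rng_spec is None:
            rng_spec = "smaller"
        if isinstance(rng_spec, str):
            size, _, scaled = rng_spec.partition("_")
            if (self.family, size) not in REFERENCE_EFFECT_RANGES or scaled not in ("", "scaled"):
                raise ValueError(f"unknown effect-range preset {rng_spec!r}")
            if scaled:
                return desk_scaled_range(self.family, size, self.n)
            return REFERENCE_EFFECT_RANGES[(self.family, size)]
        rng_spec = tuple(float(v) for v in rng_spec)
        known = [v for k, v in REFERENCE_EFFECT_RANGES.items() if k[0] == self.family]
        if rng_spec not in [tuple(v) for v in known]:
            warnings.warn(
                "effect_range differs from the reference intervals "
                f"{known}; using user-supplied {rng_spec}"
            )
        return rng_spec


@dataclass
class ExperimentResult:
    """Replicate-level P-values/selections plus aggregated rates."""

    spec: ScenarioSpec
    pvalues: dict  # method -> (reps,) array of overall/combined P-values
    per_threshold: dict  # method -> (reps, T) array (GRS methods only)
    findings: dict  # method -> list of selected-SNP index arrays
    truth: list  # list of true interacting-SNP index arrays
    rates: dict = field(default_factory=dict)  # (method, alpha) -> rate

    def rejection_rate(self, method: str, alpha: float = 0.05):
        p = self.pvalues[method]
        rate = float(np.mean(p < alpha))
        se = math.sqrt(rate * (1 - rate) / p.size) if p.size else float("nan")
        return rate, se


def simulate_genotypes(spec: ScenarioSpec, rng=None) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes, optionally with AR(1) linkage disequilibrium.

    MAFs are uniform over ``spec.maf_range``.  With ``ld_rho > 0`` each of
    the two haplotypes per subject is an AR(1) latent Gaussian thresholded
    at the MAF quantile, which keeps single-SNP genotype frequencies in
    Hardy-Weinberg proportion while correlating neighbouring SNPs.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    n, L = spec.n, spec.l_snps
    maf = rng.uniform(*spec.maf_range, size=L)
    if spec.ld_rho == 0.0:
        dosages = rng.binomial(2, maf, size=(n, L)).astype(float)
    else:
        rho = spec.ld_rho
        cuts = stats.norm.ppf(maf)
        dosages = np.zeros((n, L))
        for _ in range(2):  # two independent haplotypes -> HWE marginally
            z = np.empty((n, L))
            z[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, L - 1)) * math.sqrt(1 - rho**2)
            for l in range(1, L):
                z[:, l] = rho * z[:, l - 1] + innov[:, l - 1]
            dosages += (z < cuts).astype(float)
    ids = np.array([f"snp{j+1}" for j in range(L)])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=ids,
        chrom=np.ones(L, dtype=int),
        pos=np.arange(1, L + 1) * 1000,
        alleles=np.tile(np.array([["A", "G"]]), (L, 1)),
    )


def simulate_environment(n: int, prevalence: float = 0.248, seed=None) -> np.ndarray:
    """Independent Bernoulli binary exposure."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(1, prevalence, size=n).astype(float)


def _signed_effects(rng, d, effect_range):
    """|beta| ~ U(effect_range) with exactly ceil(d/2) positive signs."""
    mag = rng.uniform(*effect_range, size=d)
    signs = np.ones(d)
    signs[math.ceil(d / 2):] = -1.0
    return mag * rng.permutation(signs)


def simulate_traits(
    g: GenotypeMatrix, e: np.ndarray, spec: ScenarioSpec, rng=None,
    return_effects: bool = False,
):
    """Simulate a trait vector; returns ``(y, truth)``.

    ``truth`` is the index array of SNPs with nonzero interaction effects
    (empty under the null).  Causal positions are redrawn on every call.
    With ``return_effects=True`` a third element carries the drawn effect
    sizes and their positions.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    n, L = g.dosages.shape
    lin = np.zeros(n)
    truth = np.empty(0, dtype=int)
    effects = {"beta_ge": np.empty(0), "inter_pos": np.empty(0, dtype=int),
               "beta_g": np.empty(0), "main_pos": np.empty(0, dtype=int)}
    if spec.d:
        if spec.main_effects == "present":
            half = spec.d // 2
            pos = rng.choice(L, size=3 * half, replace=False)
            main_pos = pos[: 2 * half]  # main-only + both
            inter_pos = pos[half:]  # both + interaction-only
            beta_g = _signed_effects(rng, 2 * half, spec.main_effect_range)
            beta_ge = np.empty(2 * half)
            mag = rng.uniform(*spec.effect_range, size=2 * half)
            # "both" SNPs: concordant with the main effect for ~half
            conc = rng.permutation(np.r_[np.ones(half - half // 2), -np.ones(half // 2)])
            beta_ge[:half] = mag[:half] * np.sign(beta_g[half:]) * conc
            # interaction-only SNPs: top up positives to ceil(d/2) overall
            n_pos_needed = math.ceil(spec.d / 2) - int((beta_ge[:half] > 0).sum())
            n_pos_needed = min(max(n_pos_needed, 0), half)
            s = np.r_[np.ones(n_pos_needed), -np.ones(half - n_pos_needed)]
            beta_ge[half:] = mag[half:] * rng.permutation(s)
            lin = g.dosages[:, main_pos] @ beta_g
            lin += (g.dosages[:, inter_pos] * e[:, None]) @ beta_ge
            truth = np.sort(inter_pos)
            effects = {"beta_ge": beta_ge, "inter_pos": inter_pos,
                       "beta_g": beta_g, "main_pos": main_pos}
        else:
            pos = rng.choice(L, size=spec.d, replace=False)
            beta_ge = _signed_effects(rng, spec.d, spec.effect_range)
            lin = (g.dosages[:, pos] * e[:, None]) @ beta_ge
            truth = np.sort(pos)
            effects = {"beta_ge": beta_ge, "inter_pos": pos,
                       "beta_g": np.empty(0), "main_pos": np.empty(0, dtype=int)}
    if spec.family == "gaussian":
        y = lin + rng.standard_normal(n)
    else:
        y = rng.binomial(1, expit(spec.prevalence_intercept + lin)).astype(float)
    if return_effects:
        return y, truth, effects
    return y, truth


def _replicate(spec, methods, b_resamples, thresholds, rep_rng):
    """One simulated dataset analysed by every requested method."""
    g = simulate_genotypes(spec, rng=rep_rng)
    e = simulate_environment(spec.n, spec.e_prevalence, seed=rep_rng)
    y, truth = simulate_traits(g, e, spec, rng=rep_rng)
    s_raw = SampleTable(y=y, e=e, y_family=spec.family).prepare(standardize=False)
    out = {"truth": truth}
    marginal = None
    if "adabf" in methods or "grs_m" in methods:
        marginal = fit_marginal_scan(g, s_raw)  # P-values are scale-invariant
    if "adabf" in methods:
        s_ada = SampleTable(y=y, e=e, y_family=spec.family).prepare(standardize=True)
        seed = int(rep_rng.integers(2**31 - 1))
        res = run_adabf(g, s_ada, b=b_resamples, seed=seed, marginal=marginal)
        out["adabf_p"] = res.p_overall
        out["adabf_found"] = res.selected_idx
    if "grs_m" in methods:
        res_m = run_grs_m(g, s_raw, thresholds=thresholds, marginal=marginal)
        out["grs_m_p"] = res_m.combined_p
        out["grs_m_pt"] = res_m.p
    if "grs_i" in methods:
        seed = int(rep_rng.integers(2**31 - 1))
        res_i = run_grs_i(g, s_raw, thresholds=thresholds, seed=seed)
        out["grs_i_p"] = res_i.combined_p
        out["grs_i_pt"] = res_i.p
    if "bon" in methods or "bh" in methods:
        scan = fit_interaction_scan(g, s_raw)
        pvals = np.where(scan.converged, scan.p_ge, np.nan)
        if "bon" in methods:
            out["bon_found"] = bonferroni_select(pvals).selected
        if "bh" in methods:
            out["bh_found"] = bh_select(pvals).selected
    return out


def _run_study(spec, methods, b_resamples, thresholds):
    root = np.random.default_rng(spec.seed)
    reps = spec.reps
    logs = []
    for _ in range(reps):
        logs.append(_replicate(spec, methods, b_resamples, thresholds, root))
    T = len(thresholds)
    pvalues, per_threshold, findings = {}, {}, {}
    for m in ("adabf", "grs_m", "grs_i"):
        if m in methods:
            pvalues[m] = np.array([lg[f"{m}_p"] for lg in logs])
    for m in ("grs_m", "grs_i"):
        if m in methods:
            per_threshold[m] = np.vstack([lg[f"{m}_pt"] for lg in logs]).reshape(reps, T)
    for m in ("adabf", "bon", "bh"):
        key = f"{m}_found"
        if any(key in lg for lg in logs):
            findings[m] = [lg.get(key, np.empty(0, dtype=int)) for lg in logs]
    return ExperimentResult(
        spec=spec,
        pvalues=pvalues,
        per_threshold=per_threshold,
        findings=findings,
        truth=[lg["truth"] for lg in logs],
    )


def run_type1_study(
    spec: ScenarioSpec,
    methods=("adabf", "grs_m", "grs_i"),
    b_resamples: int = 500,
    thresholds=DEFAULT_THRESHOLDS,
    nominal=(0.05, 0.01),
) -> ExperimentResult:
    """Null-trait study: empirical rejection rates at the nominal levels."""
    if spec.d != 0:
        raise ValueError("type I error study requires d = 0")
    result = _run_study(spec, methods, b_resamples, thresholds)
    for m in result.pvalues:
        for a in nominal:
            result.rates[(m, a)] = result.rejection_rate(m, a)
    return result


def run_power_study(
    spec: ScenarioSpec,
    methods=("adabf", "grs_m", "grs_i", "bon", "bh"),
    b_resamples: int = 500,
    thresholds=DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
) -> ExperimentResult:
    """Alternative-trait study: power, sensitivity, PPV per method.

    Polygenic methods reject when the overall/combined P is below ``alpha``;
    the single-marker comparators reject when their selected set is
    nonempty (any declared SNP, as conventionally reported; the true-only
    variant is available from the logs).
    """
    if spec.d <= 0:
        raise ValueError("power study requires d > 0")
    result = _run_study(spec, methods, b_resamples, thresholds)
    for m in result.pvalues:
        result.rates[(m, alpha)] = result.rejection_rate(m, alpha)
    for m, found in result.findings.items():
        if m in ("bon", "bh"):
            hits = np.array([f.size > 0 for f in found], dtype=float)
            rate = float(hits.mean())
            se = math.sqrt(rate * (1 - rate) / hits.size)
            result.rates[(m, alpha)] = (rate, se)
    return result


def sensitivity_ppv(findings, truth, d: int):
    """Pooled sensitivity, PPV, and FDP over replicates.

    sensitivity = total true findings / (reps * d); ppv = total true
    findings / total findings (nan when nothing was found); fdp = 1 - ppv.
    """
    n_true = 0
    n_found = 0
    for f, t in zip(findings, truth):
        n_found += len(f)
        n_true += len(np.intersect1d(f, t))
    sens = n_true / (len(truth) * d) if d else float("nan")
    if n_found == 0:
        return sens, float("nan"), float("nan")
    ppv = n_true / n_found
    return sens, ppv, 1.0 - ppv
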