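"""Per-SNP interaction scan with Bonferroni (FWER) and BH (FDR) control.

These are the conventional single-marker comparators: every SNP's
interaction P-value enters one multiplicity correction, with m counting
only SNPs whose fit converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["MultiplicityDecision", "bonferroni_select", "bh_select"]


@dataclass
class MultiplicityDecision:
    """Selected SNP indices under one multiplicity rule."""

    method: str
    level: float
    selected: np.ndarray  # indices into the input P list
    cutoff: float  # realized P cutoff (largest selected P, or the bound)
    m: int  # number of tests entering the correction


def _valid(pvals):
    pvals = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(pvals)
    if np.any((pvals[ok] < 0) | (pvals[ok] > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    return pvals, np.nonzero(ok)[0]


def bonferroni_select(pvals, level: float = 0.05) -> MultiplicityDecision:
    """Select SNPs with P strictly below level/m (m = converged tests)."""
    pvals, idx = _valid(pvals)
    m = idx.size
    if m == 0:
        return MultiplicityDecision("BON", level, np.empty(0, dtype=int), 0.0, 0)
    cutoff = level / m
    selected = idx[pvals[idx] < cutoff]
    return MultiplicityDecision("BON", level, selected, cutoff, m)


def bh_select(pvals, q: float = 0.05) -> MultiplicityDecision:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Selects the k* smallest P-values where k* = max{i : P_(i) <= i*q/m}.
    """
    pvals, idx = _valid(pvals)
    m = idx.size
    if m == 0:
        return MultiplicityDecision("BH", q, np.empty(0, dtype=int), 0.0, 0)
    reject, _, _, _ = multipletests(pvals[idx], alpha=q, method="fdr_bh")[:4]
    selected = idx[reject]
    cutoff = float(pvals[selected].max()) if selected.size else 0.0
    return MultiplicityDecision("BH", q, selected, cutoff, m)
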