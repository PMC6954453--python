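"""Trait, exposure, and covariate preparation.

The interaction prior assumes the SNP-by-exposure product lives on the same
0..2 scale as a minor-allele dosage, so a continuous exposure is affinely
rescaled to [0, 1].  On the Bayes-factor testing path a continuous trait is
additionally standardized to mean 0 / SD 1 so that the prior variance
W = 0.04 is on the right scale; the genetic-risk-score tests keep the trait
on its raw scale so their coefficients stay interpretable in trait units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SampleTable", "scale_environment", "standardize_trait", "read_sample_table"]


def scale_environment(e: np.ndarray) -> np.ndarray:
    """Rescale an exposure to [0, 1].

    Binary 0/1 input is returned unchanged.  A continuous exposure is mapped
    affinely so its minimum becomes 0 and its maximum 1.  Missing entries
    (nan) stay missing and are excluded from the min/max.
    """
    e = np.asarray(e, dtype=np.float64)
    obs = e[~np.isnan(e)]
    if np.isin(obs, (0.0, 1.0)).all():
        return e.copy()
    lo, hi = obs.min(), obs.max()
    if hi == lo:
        raise ValueError("constant continuous exposure: interaction inestimable")
    return (e - lo) / (hi - lo)


def standardize_trait(y: np.ndarray) -> np.ndarray:
    """Standardize a continuous trait to mean 0 and sample SD 1 (n-1)."""
    y = np.asarray(y, dtype=np.float64)
    sd = y.std(ddof=1)
    if not sd > 0:
        raise ValueError("trait has zero variance; cannot standardize")
    return (y - y.mean()) / sd


@dataclass
class SampleTable:
    """Per-subject trait, exposure, and covariate block.

    ``y_family`` is "gaussian" or "binomial".  ``x`` may be an (n, 0) array
    when there are no covariates.  ``prepare`` performs listwise deletion of
    subjects missing Y, E, or any covariate, then rescales a continuous
    exposure using the min/max of the retained analysis sample and (on the
    ADABF path only) standardizes a gaussian trait.
    """

    y: np.ndarray
    e: np.ndarray
    y_family: str = "gaussian"
    x: Optional[np.ndarray] = None
    sample_ids: Optional[np.ndarray] = None
    n_dropped: int = field(default=0)
    prepared: bool = field(default=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.e = np.asarray(self.e, dtype=np.float64)
        n = self.y.shape[0]
        if self.e.shape[0] != n:
            raise ValueError("y and e lengths differ")
        if self.x is None:
            self.x = np.empty((n, 0))
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape[0] != n:
            raise ValueError("covariate block row count differs from y")
        if self.y_family not in ("gaussian", "binomial"):
            raise ValueError("y_family must be 'gaussian' or 'binomial'")
        obs_y = self.y[~np.isnan(self.y)]
        if self.y_family == "binomial" and not np.isin(obs_y, (0.0, 1.0)).all():
            raise ValueError("binomial trait must take values in {0, 1}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i+1}" for i in range(n)])

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def prepare(self, standardize: bool = False) -> "SampleTable":
        """Listwise-delete incomplete subjects, scale E, optionally standardize Y.

        ``standardize=True`` is the Bayes-factor path for gaussian traits;
        GRS and single-marker paths call with the default (raw trait).
        """
        keep = ~(np.isnan(self.y) | np.isnan(self.e))
        if self.x.shape[1]:
            keep &= ~np.isnan(self.x).any(axis=1)
        y = self.y[keep]
        e = scale_environment(self.e[keep])
        if standardize and self.y_family == "gaussian":
            y = standardize_trait(y)
        return replace(
            self,
            y=y,
            e=e,
            x=self.x[keep],
            sample_ids=self.sample_ids[keep],
            n_dropped=int((~keep).sum()),
            prepared=True,
        )

    def subset(self, idx) -> "SampleTable":
        idx = np.asarray(idx)
        return replace(
            self,
            y=self.y[idx],
            e=self.e[idx],
            x=self.x[idx],
            sample_ids=self.sample_ids[idx],
        )


def read_sample_table(
    path,
    y_col: str,
    e_col: str,
    covar_cols=(),
    family: str = "gaussian",
    iid_order: Optional[np.ndarray] = None,
) -> SampleTable:
    """Read a tab-separated sample table (FID IID Y E covariates...).

    If ``iid_order`` is given (e.g. the fam-file order of a genotype file),
    rows are aligned to it by IID; subjects absent from the table become
    all-missing rows so listwise deletion in :meth:`SampleTable.prepare`
    handles them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if iid_order is not None:
        df = df.set_index("IID").reindex(np.asarray(iid_order, dtype=str))
        ids = df.index.to_numpy()
    else:
        ids = df["IID"].to_numpy()
    cols = list(covar_cols)
    return SampleTable(
        y=df[y_col].to_numpy(dtype=float),
        e=df[e_col].to_numpy(dtype=float),
        y_family=family,
        x=df[cols].to_numpy(dtype=float) if cols else None,
        sample_ids=ids,
    )
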