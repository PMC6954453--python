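"""PLINK-1 genotype input/output, quality control, and LD pruning.

Genotypes are held as an ``n x L`` minor-allele dosage matrix (float64 with
``nan`` marking missing calls) plus per-SNP metadata.  The orientation is
decided per SNP from the loaded sample: dosages always count the *minor*
allele, so a SNP whose bim A1 allele turns out to be the major allele in the
sample is recoded as ``2 - g`` and its allele labels swapped.  Ties at a
frequency of exactly 0.5 keep the bim A1 as "minor".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "hwe_test",
    "qc_filter",
    "vif_prune",
    "genotype_correlation",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit bed codes, SNP-major: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Dosage counts copies of A1, so 00 -> 2, 10 -> 1, 11 -> 0, 01 -> nan.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised for malformed or inconsistent PLINK bed/bim/fam triplets."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-SNP metadata.

    Attributes
    ----------
    dosages : (n, L) float64 array; entries in {0, 1, 2} or nan for missing.
    snp_ids : length-L array of SNP identifiers.
    chrom : length-L array of chromosome codes (int).
    pos : length-L array of 1-based base-pair positions.
    alleles : (L, 2) array of (minor, major) allele labels.
    maf : length-L minor-allele frequency in [0, 0.5].
    call_rate : length-L fraction of non-missing calls.
    sample_ids : length-n array of (FID, IID)-style identifiers (IID used for
        joins against sample tables).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, L = self.dosages.shape
        for name in ("snp_ids", "chrom", "pos"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != L:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {L}")
            setattr(self, name, arr)
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (L, 2):
            raise ValueError("alleles must have shape (L, 2)")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i+1}" for i in range(n)])
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must lie in {0, 1, 2} or be nan")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            alleles=self.alleles[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosages=self.dosages[idx],
            sample_ids=self.sample_ids[idx],
        )


def _orient_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip SNPs whose counted allele is the major one in the sample."""
    freq = g.maf  # frequency of the currently counted allele
    flip = freq > 0.5  # ties at exactly 0.5 keep A1 as minor
    if flip.any():
        d = g.dosages.copy()
        d[:, flip] = 2.0 - d[:, flip]
        al = g.alleles.copy()
        al[flip] = al[flip][:, ::-1]
        return replace(g, dosages=d, alleles=al)
    return g


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK-1 binary triplet ``prefix.bed/.bim/.fam``.

    Dosages are oriented samples x SNPs and count the minor allele as
    observed in the loaded sample.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, L = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not in SNP-major (v1) mode")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * L:
        raise PlinkFormatError(
            f"{prefix}.bed payload has {payload.size} bytes, expected "
            f"{bytes_per_snp * L} for {n} samples x {L} SNPs"
        )
    blocks = payload.reshape(L, bytes_per_snp)
    codes = np.empty((L, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # counts A1 copies
    g = GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        alleles=bim[["a1", "a2"]].to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
    )
    return _orient_minor(g)


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a PLINK-1 bed/bim/fam triplet (A1 = stored minor allele)."""
    prefix = Path(prefix)
    n, L = g.dosages.shape
    d = g.dosages
    code = np.full((L, n), 1, dtype=np.uint8)  # 01 = missing
    dT = d.T
    code[dT == 2.0] = 0b00
    code[dT == 1.0] = 0b10
    code[dT == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.hstack([code, np.full((L, pad), 0, dtype=np.uint8)])
    packed = (
        code[:, 0::4]
        | (code[:, 1::4] << 2)
        | (code[:, 2::4] << 4)
        | (code[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())
    bim = pd.DataFrame(
        {
            "chrom": g.chrom,
            "snp": g.snp_ids,
            "cm": 0,
            "pos": g.pos,
            "a1": g.alleles[:, 0],
            "a2": g.alleles[:, 1],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.sample_ids,
            "iid": g.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def hwe_test(n_aa_minor: int, n_het: int, n_aa_major: int) -> float:
    """1-df chi-square goodness-of-fit P-value against Hardy-Weinberg.

    Parameters are genotype counts (hom-minor, het, hom-major).  A
    monomorphic SNP (one allele absent) returns P = 1 by convention.
    """
    counts = np.array([n_aa_minor, n_het, n_aa_major], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        out[j] = hwe_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return out


def qc_filter(
    g: GenotypeMatrix,
    min_call_rate: float = 0.95,
    hwe_p: float = 5.7e-7,
    min_maf: float = 0.01,
):
    """Apply call-rate, Hardy-Weinberg, and MAF quality-control filters.

    Keeps SNPs with call_rate >= ``min_call_rate`` AND HWE P >= ``hwe_p``
    AND MAF >= ``min_maf``.  Returns ``(filtered GenotypeMatrix, removal
    log)`` where the log is a DataFrame listing every removed SNP and the
    rule(s) it violated.
    """
    for name, val in (("min_call_rate", min_call_rate), ("min_maf", min_maf),
                      ("hwe_p", hwe_p)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {val}")
    cr = g.call_rate
    maf = g.maf
    hwe = _hwe_pvalues(g)
    bad_cr = cr < min_call_rate
    bad_hwe = hwe < hwe_p
    bad_maf = maf < min_maf
    drop = bad_cr | bad_hwe | bad_maf
    records = []
    for j in np.nonzero(drop)[0]:
        rules = []
        if bad_cr[j]:
            rules.append("call_rate")
        if bad_hwe[j]:
            rules.append("hwe")
        if bad_maf[j]:
            rules.append("maf")
        records.append(
            {
                "snp": g.snp_ids[j],
                "rules": ",".join(rules),
                "call_rate": cr[j],
                "hwe_p": hwe[j],
                "maf": maf[j],
            }
        )
    log = pd.DataFrame(records, columns=["snp", "rules", "call_rate", "hwe_p", "maf"])
    keep = np.nonzero(~drop)[0]
    if keep.size == 0:
        raise ValueError("qc_filter removed every SNP: empty panel")
    return g.take_snps(keep), log


def _vif_all(cols: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """VIF = 1/(1-R^2) for each column regressed on all the others.

    Ridge-stabilised least squares keeps the computation defined when a
    window holds more SNPs than samples or collinear columns.  Columns are
    centred; a zero-variance column gets an infinite VIF so it is pruned
    first.
    """
    X = cols - cols.mean(axis=0)
    n, m = X.shape
    var = (X**2).sum(axis=0)
    out = np.empty(m)
    for j in range(m):
        if var[j] <= 0:
            out[j] = np.inf
            continue
        others = np.delete(X, j, axis=1)
        A = others.T @ others + ridge * np.eye(m - 1)
        b = others.T @ X[:, j]
        coef = np.linalg.solve(A, b)
        rss = var[j] - b @ coef
        r2 = max(0.0, min(1.0 - rss / var[j], 1.0 - 1e-12))
        out[j] = 1.0 / (1.0 - r2)
    return out


def vif_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> np.ndarray:
    """Windowed variance-inflation-factor pruning (PLINK ``--indep`` style).

    Within each sliding window the SNP with the largest VIF is removed
    (iteratively, recomputing after each removal) until all VIFs are
    <= ``vif_max``; the window then slides by ``step`` SNPs.  Pruning never
    crosses a chromosome boundary.  Ties at the maximal VIF are broken by
    lower MAF, then by higher index.  Returns indices of surviving SNPs in
    original order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    order = np.lexsort((g.pos, g.chrom))
    if not np.array_equal(order, np.arange(g.n_snps)):
        raise ValueError("SNPs must be ordered by (chrom, pos) before pruning")
    maf = g.maf
    # mean-impute missing dosages for the regression only
    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]

    alive = np.ones(g.n_snps, dtype=bool)
    for chrom in np.unique(g.chrom):
        idx_chr = np.nonzero(g.chrom == chrom)[0]
        start = 0
        while True:
            win = idx_chr[start : start + window]
            if win.size >= 2:
                while True:
                    cur = win[alive[win]]
                    if cur.size < 2:
                        break
                    vifs = _vif_all(d[:, cur])
                    worst = vifs.max()
                    if worst <= vif_max:
                        break
                    cand = np.nonzero(vifs == worst)[0]
                    if cand.size > 1:
                        cand = cand[np.lexsort((-cand, maf[cur[cand]]))][:1]
                    alive[cur[cand[0]]] = False
            if start + window >= idx_chr.size:
                break
            start += step
    return np.nonzero(alive)[0]


def genotype_correlation(g: GenotypeMatrix, subset) -> np.ndarray:
    """Pearson correlation of dosages over pairwise-complete samples.

    Raises if any SNP in ``subset`` has zero variance (naming the SNP).
    """
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    d = g.dosages[:, subset]
    with np.errstate(invalid="ignore"):
        var = np.nanvar(d, axis=0)
    bad = np.nonzero(var <= 0)[0]
    if bad.size:
        names = ", ".join(str(s) for s in g.snp_ids[subset[bad]])
        raise ValueError(f"zero-variance SNP(s) in correlation subset: {names}")
    corr = pd.DataFrame(d).corr(min_periods=2).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0
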