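"""Variant-level quality control and ancestry principal components.

Filters follow the standard PLINK-style exclusion triple: low call rate,
deviation from Hardy-Weinberg equilibrium (1-df Pearson chi-square), and low
minor allele frequency. Ancestry PCs are computed EIGENSTRAT-style: dosages
centred by twice the allele frequency and scaled by the binomial standard
deviation sqrt(2 f (1 - f)) before the SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix

DEFAULT_CALL_RATE = 0.99
DEFAULT_HWE_P = 1e-6
DEFAULT_MAF = 0.05


def call_rate(dosages) -> float:
    """Fraction of non-missing calls in a per-variant dosage vector."""
    arr = np.asarray(dosages, dtype=float)
    if arr.size == 0:
        raise ValueError("empty dosage vector")
    return 1.0 - np.isnan(arr).sum() / arr.size


def minor_allele_frequency(dosages) -> float:
    """MAF = min(f, 1-f) where f is the ALT-dosage allele frequency."""
    arr = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(arr)
    if not ok.any():
        raise ValueError("all dosages missing")
    f = arr[ok].sum() / (2.0 * ok.sum())
    return min(f, 1.0 - f)


def hwe_chi2(n_ref_hom: int, n_het: int, n_alt_hom: int) -> tuple[float, float]:
    """1-df Pearson chi-square test against Hardy-Weinberg proportions.

    Expected counts use the sample allele frequency; monomorphic variants
    return (0.0, 1.0) by convention. Returns ``(chi2, p)`` with the upper-tail
    p-value on 1 df. No continuity correction is applied.
    """
    counts = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotype required")
    f_alt = (counts[1] + 2 * counts[2]) / (2 * n)
    if f_alt in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([(1 - f_alt) ** 2, 2 * f_alt * (1 - f_alt), f_alt**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_counts(dosages) -> tuple[int, int, int]:
    """Hard-call genotype counts (ref-hom, het, alt-hom), rounding dosages.

    Fractional (imputed) dosages are rounded to the nearest genotype; missing
    entries are skipped.
    """
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    g = np.clip(np.rint(arr), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


class QCFilter(BaseEstimator, TransformerMixin):
    """Variant-level QC filter (call rate / HWE / MAF) as a transformer.

    Parameters
    ----------
    min_call_rate : float
        Variants with call rate strictly below this are excluded.
    min_hwe_p : float
        Variants with HWE p strictly below this are excluded.
    min_maf : float
        Variants with MAF strictly below this are excluded.

    Attributes (after fit)
    ----------------------
    report_ : DataFrame indexed by variant id with call_rate, maf, hwe_chi2,
        hwe_p, the three fail flags, monomorphic flag and overall ``pass_qc``.
    retained_ : list of variant ids passing every filter, input order kept.
    """

    def __init__(
        self,
        min_call_rate: float = DEFAULT_CALL_RATE,
        min_hwe_p: float = DEFAULT_HWE_P,
        min_maf: float = DEFAULT_MAF,
    ):
        self.min_call_rate = min_call_rate
        self.min_hwe_p = min_hwe_p
        self.min_maf = min_maf

    def fit(self, X: GenotypeMatrix, y=None) -> "QCFilter":
        rows = {}
        for vid in X.variant_ids:
            d = X.dosage[vid].to_numpy(dtype=float)
            cr = call_rate(d)
            if np.isnan(d).all():
                maf, chi2, p, mono = np.nan, 0.0, 1.0, True
            else:
                maf = minor_allele_frequency(d)
                chi2, p = hwe_chi2(*genotype_counts(d))
                mono = maf == 0.0
            rows[vid] = dict(call_rate=cr, maf=maf, hwe_chi2=chi2, hwe_p=p, monomorphic=mono)
        report = pd.DataFrame.from_dict(rows, orient="index")
        report["fail_call_rate"] = report["call_rate"] < self.min_call_rate
        report["fail_hwe"] = report["hwe_p"] < self.min_hwe_p
        report["fail_maf"] = report["maf"].isna() | (report["maf"] < self.min_maf)
        report["pass_qc"] = ~(
            report["fail_call_rate"] | report["fail_hwe"] | report["fail_maf"]
        )
        self.report_ = report
        self.retained_ = [v for v in X.variant_ids if report.loc[v, "pass_qc"]]
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        keep = [v for v in self.retained_ if v in X.dosage.columns]
        return X.select_variants(keep)


def apply_qc_filters(
    matrix: GenotypeMatrix,
    min_call_rate: float = DEFAULT_CALL_RATE,
    min_hwe_p: float = DEFAULT_HWE_P,
    min_maf: float = DEFAULT_MAF,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Functional wrapper: returns (filtered matrix, per-variant QC report)."""
    qc = QCFilter(min_call_rate, min_hwe_p, min_maf).fit(matrix)
    return qc.transform(matrix), qc.report_


@dataclass
class PCAResult:
    components: pd.DataFrame  # subjects x PC1..PCk
    explained_variance: np.ndarray
    degenerate: bool
    k_effective: int


class GenotypePCA(BaseEstimator, TransformerMixin):
    """EIGENSTRAT-style genotype PCA for ancestry covariates.

    Missing dosages are mean-imputed per variant; each column is centred by
    2f and scaled by sqrt(2 f (1-f)); monomorphic columns are dropped. The
    subject-coordinate sign of each PC is fixed so the loading of largest
    magnitude is positive.

    Attributes: ``components_`` (subjects x k DataFrame, columns PC1..PCk),
    ``explained_variance_``, ``degenerate_``, ``k_effective_``.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypePCA":
        k = self.n_components
        if X.n_subjects < k + 1:
            raise ValueError(f"need at least {k + 1} subjects for {k} components")
        D = X.dosage.to_numpy(dtype=float).copy()
        # per-variant mean imputation
        col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        inds = np.where(np.isnan(D))
        D[inds] = col_mean[inds[1]]
        f = D.mean(axis=0) / 2.0
        sd = np.sqrt(2.0 * f * (1.0 - f))
        keep = sd > 0
        Z = (D[:, keep] - 2.0 * f[keep]) / sd[keep]
        degenerate = False
        if Z.shape[1] == 0:
            coords = np.zeros((X.n_subjects, k))
            sv = np.zeros(k)
            degenerate = True
            k_eff = 0
        else:
            U, S, Vt = np.linalg.svd(Z, full_matrices=False)
            rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
            k_eff = min(k, rank)
            if k_eff < k:
                degenerate = True
            coords = np.zeros((X.n_subjects, k))
            sv = np.zeros(k)
            for j in range(k_eff):
                load = Vt[j]
                sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
                coords[:, j] = sign * U[:, j] * S[j]
                sv[j] = S[j] ** 2 / max(X.n_subjects - 1, 1)
        self.components_ = pd.DataFrame(
            coords, index=X.subjects, columns=[f"PC{j + 1}" for j in range(k)]
        )
        self.explained_variance_ = sv
        self.degenerate_ = degenerate
        self.k_effective_ = k_eff
        return self

    def transform(self, X: GenotypeMatrix) -> pd.DataFrame:
        return self.components_


def genotype_pca(matrix: GenotypeMatrix, k: int = 5) -> PCAResult:
    """Functional wrapper around :class:`GenotypePCA`."""
    est = GenotypePCA(n_components=k).fit(matrix)
    return PCAResult(
        components=est.components_,
        explained_variance=est.explained_variance_,
        degenerate=est.degenerate_,
        k_effective=est.k_effective_,
    )
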