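"""Greedy LD clumping: keep independent index variants, drop correlated
neighbours within a physical window (PLINK/PRSice convention).

The algorithm sorts variants by ascending source p-value (ties broken by
chromosome, position, then id), repeatedly promotes the best unassigned
variant to index status and removes every unassigned variant on the same
chromosome within ``window_kb`` of it whose in-sample dosage r-squared with
the index reaches ``r2_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def pairwise_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing pairs are dropped (pairwise-complete); a constant vector yields
    0.0 (undefined correlation treated as no LD).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("need at least 2 paired non-missing entries")
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ClumpResult:
    retained: list
    removed: dict  # variant id -> (index id, r2)
    r2_threshold: float
    window_kb: float
    p_threshold: float
    parameters: dict = field(init=False)

    def __post_init__(self):
        self.parameters = {
            "r2_threshold": self.r2_threshold,
            "window_kb": self.window_kb,
            "p_threshold": self.p_threshold,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant": v, "status": "retained", "index": "", "r2": ""} for v in self.retained]
        rows += [
            {"variant": v, "status": "removed", "index": idx, "r2": f"{r2:.6g}"}
            for v, (idx, r2) in self.removed.items()
        ]
        return pd.DataFrame(rows, columns=["variant", "status", "index", "r2"])


def clump(
    matrix: GenotypeMatrix,
    pvalues: pd.Series | dict,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p_threshold: float = 1.0,
) -> ClumpResult:
    """Greedy clumping of ``matrix`` variants using ``pvalues`` for priority.

    ``p_threshold`` = 1 makes every variant index-eligible (variants with
    p above the threshold are still removable by a nearby index). Duplicate
    variant ids raise; positions are interpreted in base pairs.
    """
    pvalues = pd.Series(pvalues)
    ids = matrix.variant_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids")
    missing_p = [v for v in ids if v not in pvalues.index]
    if missing_p:
        raise ValueError(f"missing p-values for: {missing_p[:5]}")
    if ((pvalues.loc[ids] < 0) | (pvalues.loc[ids] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")

    var = matrix.variants
    order = sorted(
        ids,
        key=lambda v: (pvalues[v], str(var.loc[v, "chrom"]), int(var.loc[v, "pos"]), str(v)),
    )
    window_bp = window_kb * 1000.0
    unassigned = set(ids)
    retained: list = []
    removed: dict = {}
    for v in order:
        if v not in unassigned:
            continue
        if pvalues[v] > p_threshold:
            continue
        unassigned.discard(v)
        retained.append(v)
        chrom, pos = var.loc[v, "chrom"], int(var.loc[v, "pos"])
        if window_bp <= 0:
            continue
        for u in list(unassigned):
            if str(var.loc[u, "chrom"]) != str(chrom):
                continue
            if abs(int(var.loc[u, "pos"]) - pos) > window_bp:
                continue
            r2 = pairwise_r2(matrix.dosage[v], matrix.dosage[u])
            if r2 >= r2_threshold:
                unassigned.discard(u)
                removed[u] = (v, r2)
    # index-ineligible leftovers (p > p_threshold, never absorbed) stay retained
    leftovers = [v for v in order if v in unassigned]
    retained.extend(leftovers)
    retained = [v for v in ids if v in set(retained)]  # restore input order
    return ClumpResult(retained, removed, r2_threshold, window_kb, p_threshold)


class LDClumper:
    """Estimator-style wrapper: ``fit`` runs :func:`clump`, ``transform``
    restricts a matrix to the retained index variants.

    Attributes after fit: ``result_`` (:class:`ClumpResult`), ``retained_``.
    """

    def __init__(self, r2_threshold: float = 0.1, window_kb: float = 250.0, p_threshold: float = 1.0):
        self.r2_threshold = r2_threshold
        self.window_kb = window_kb
        self.p_threshold = p_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            "r2_threshold": self.r2_threshold,
            "window_kb": self.window_kb,
            "p_threshold": self.p_threshold,
        }

    def set_params(self, **params) -> "LDClumper":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: GenotypeMatrix, pvalues) -> "LDClumper":
        self.result_ = clump(X, pvalues, self.r2_threshold, self.window_kb, self.p_threshold)
        self.retained_ = self.result_.retained
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        return X.select_variants([v for v in self.retained_ if v in X.dosage.columns])
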