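"""Polygenic score construction by the standard weighted-allele method.

score_i = sum_j beta_j * d_ij over panel variants, where d_ij is subject i's
effect-allele dosage. A score file row is aligned against the genotype file's
REF/ALT pair: used as-is, dosage-swapped (d -> 2 - d), strand-flipped, or
dropped (palindromic A/T-C/G ambiguity, or no match). Missing genotypes are
handled by policy: in-sample mean-dosage imputation (default), per-subject
variant omission, or hard failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

SCORE_FILE_COLUMNS = ["snp_id", "chr", "pos", "effect_allele", "other_allele", "weight", "p"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

USE_AS_IS = "use_as_is"
SWAP = "swap"
FLIP = "strand_flip"
FLIP_SWAP = "strand_flip_swap"
DROP_AMBIGUOUS = "drop_ambiguous_strand"
DROP_MISMATCH = "drop_allele_mismatch"


def read_score_file(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated score file with the canonical 7-column header."""
    panel = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str})
    missing = set(SCORE_FILE_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"score file lacks columns: {sorted(missing)}")
    if (panel["effect_allele"] == panel["other_allele"]).any():
        raise ValueError("effect allele must differ from other allele")
    if not np.isfinite(panel["weight"]).all():
        raise ValueError("weights must be finite")
    return panel


def response_panel() -> pd.DataFrame:
    """The packaged 11-SNP antipsychotic-response panel (dummy weights of 1)."""
    with resources.as_file(
        resources.files("prsresponse.data") / "panel_response.tsv"
    ) as p:
        return read_score_file(p)


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper())


def _is_palindromic(a1: str, a2: str) -> bool:
    return a1.upper() == _complement(a2)


def align_alleles(
    effect_allele: str,
    other_allele: str,
    ref: str,
    alt: str,
    allow_palindromic: bool = False,
) -> str:
    """Decide how a score-file allele pair maps onto a VCF REF/ALT pair.

    Returns one of USE_AS_IS (ALT dosage counts the effect allele), SWAP
    (effect allele is REF: use 2 - dosage), FLIP / FLIP_SWAP (same after
    A<->T / C<->G complementation), DROP_AMBIGUOUS (palindromic variant,
    strand unresolvable) or DROP_MISMATCH.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    ref, alt = ref.upper(), alt.upper()
    if _is_palindromic(ea, oa) and not allow_palindromic:
        return DROP_AMBIGUOUS
    if (ea, oa) == (alt, ref):
        return USE_AS_IS
    if (ea, oa) == (ref, alt):
        return SWAP
    fea, foa = _complement(ea), _complement(oa)
    if (fea, foa) == (alt, ref):
        return FLIP
    if (fea, foa) == (ref, alt):
        return FLIP_SWAP
    return DROP_MISMATCH


@dataclass
class PRSResult:
    scores: pd.Series  # per-subject score
    n_variants_used: pd.Series
    n_missing_imputed: pd.Series
    alignment: pd.DataFrame  # per panel row: outcome, used flag
    missing_policy: str
    panel_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.scores.index,
                "score": self.scores.values,
                "n_used": self.n_variants_used.values,
                "n_imputed": self.n_missing_imputed.values,
            }
        )


class PRSScorer:
    """Weighted-allele PRS as a fit/transform estimator.

    ``fit`` aligns the panel against the genotype matrix and learns in-sample
    effect-allele frequencies (for mean imputation); ``transform`` returns the
    per-subject score vector. Attributes after fit: ``alignment_``,
    ``aligned_panel_``, ``effect_freq_``.
    """

    def __init__(self, panel: pd.DataFrame, missing_policy: str = "mean", allow_palindromic: bool = False):
        self.panel = panel
        self.missing_policy = missing_policy
        self.allow_palindromic = allow_palindromic

    def get_params(self, deep: bool = True) -> dict:
        return {
            "panel": self.panel,
            "missing_policy": self.missing_policy,
            "allow_palindromic": self.allow_palindromic,
        }

    def set_params(self, **params) -> "PRSScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: GenotypeMatrix, y=None) -> "PRSScorer":
        if self.missing_policy not in ("mean", "omit", "fail"):
            raise ValueError(f"unknown missing policy: {self.missing_policy!r}")
        if len(self.panel) == 0:
            raise ValueError("empty score panel")
        outcomes = []
        for _, row in self.panel.iterrows():
            vid = row["snp_id"]
            if vid not in X.dosage.columns:
                outcomes.append((vid, "drop_not_genotyped", False))
                continue
            spec = X.variants.loc[vid]
            out = align_alleles(
                row["effect_allele"], row["other_allele"], spec["ref"], spec["alt"],
                allow_palindromic=self.allow_palindromic,
            )
            outcomes.append((vid, out, out in (USE_AS_IS, SWAP, FLIP, FLIP_SWAP)))
        self.alignment_ = pd.DataFrame(outcomes, columns=["snp_id", "outcome", "used"])
        used = self.alignment_[self.alignment_["used"]]
        if len(used) == 0:
            raise ValueError("no panel variant could be aligned to the genotypes")
        self.aligned_panel_ = self.panel.set_index("snp_id").loc[used["snp_id"]]
        # effect-allele dosage matrix for the aligned subset
        self._swap = {
            vid: out in (SWAP, FLIP_SWAP)
            for vid, out in zip(used["snp_id"], used["outcome"])
        }
        eff = self._effect_dosage(X)
        self.effect_freq_ = eff.mean(axis=0) / 2.0  # in-sample, missing skipped
        return self

    def _effect_dosage(self, X: GenotypeMatrix) -> pd.DataFrame:
        eff = X.dosage[list(self.aligned_panel_.index)].astype(float).copy()
        for vid, swap in self._swap.items():
            if swap:
                eff[vid] = 2.0 - eff[vid]
        return eff

    def transform(self, X: GenotypeMatrix) -> PRSResult:
        eff = self._effect_dosage(X)
        weights = self.aligned_panel_["weight"].astype(float)
        miss = eff.isna()
        if self.missing_policy == "fail" and miss.to_numpy().any():
            raise ValueError("missing genotypes present under policy 'fail'")
        if self.missing_policy == "mean":
            filled = eff.fillna(2.0 * self.effect_freq_)
            scores = filled.mul(weights, axis=1).sum(axis=1)
            n_used = pd.Series(len(weights), index=eff.index)
        else:  # omit
            scores = eff.mul(weights, axis=1).sum(axis=1, skipna=True)
            n_used = (~miss).sum(axis=1)
        n_imputed = miss.sum(axis=1) if self.missing_policy == "mean" else pd.Series(0, index=eff.index)
        return PRSResult(
            scores=scores,
            n_variants_used=n_used,
            n_missing_imputed=n_imputed,
            alignment=self.alignment_,
            missing_policy=self.missing_policy,
            panel_size=len(self.panel),
        )

    def fit_transform(self, X: GenotypeMatrix, y=None) -> PRSResult:
        return self.fit(X).transform(X)


def compute_prs(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    missing_policy: str = "mean",
    allow_palindromic: bool = False,
) -> PRSResult:
    """Functional wrapper around :class:`PRSScorer`."""
    return PRSScorer(panel, missing_policy, allow_palindromic).fit_transform(matrix)
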