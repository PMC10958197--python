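"""Core in-memory containers shared across pipeline stages.

Genotypes are held as a subjects x variants dosage matrix (pandas DataFrame,
``NaN`` marking missing calls) plus a variant metadata table. Dosages count
copies of the ALT allele and live in [0, 2]; fractional values are allowed
(imputed genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Subjects x variants ALT-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosage : DataFrame
        Index: subject ids; columns: variant ids; values in [0, 2] or NaN.
    variants : DataFrame
        Index: variant ids (same order as ``dosage`` columns); columns
        ``chrom`` (str), ``pos`` (int), ``ref``, ``alt`` (allele strings).
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.variants = self.variants.copy()
        self.variants["pos"] = self.variants["pos"].astype(int)
        if list(self.dosage.columns) != list(self.variants.index):
            raise ValueError("dosage columns and variant index must match in order")
        if self.variants.index.has_duplicates:
            dupes = self.variants.index[self.variants.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dupes}")
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {sorted(missing_cols)}")
        if (self.variants["pos"] < 0).any():
            raise ValueError("variant positions must be non-negative")
        vals = self.dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 2)
        if np.nansum(bad) > 0:
            raise ValueError("dosages must lie in [0, 2] or be missing (NaN)")

    @property
    def subjects(self) -> list:
        return list(self.dosage.index)

    @property
    def variant_ids(self) -> list:
        return list(self.dosage.columns)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def select_variants(self, ids) -> "GenotypeMatrix":
        """Sub-matrix keeping ``ids`` in the given order."""
        ids = list(ids)
        return GenotypeMatrix(self.dosage[ids], self.variants.loc[ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.dosage.equals(other.dosage) and self.variants.equals(other.variants)


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces.

    ``subjects``: id, age_years, sex, diagnosis (ICD-10 code), diagnostic_group,
    admissions, substance_abuse, socioeconomic_index.
    ``cgi``: subject_id, date, scale (CGI-S / CGI-I), value (int 1..7).
    ``events``: subject_id, date, kind, drug, dose_mg_day, reason.
    ``truth``: subject_id, true_prs, liability, true_responder, degraded.
    """

    genotypes: GenotypeMatrix
    subjects: pd.DataFrame
    cgi: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set(self.subjects["subject_id"])
        for name in ("cgi", "events", "truth"):
            tab = getattr(self, name)
            extra = set(tab["subject_id"]) - ids
            if extra:
                raise ValueError(f"{name} table has unknown subject ids: {sorted(extra)[:5]}")
        if len(self.cgi) and not self.cgi["value"].isin(range(1, 8)).all():
            raise ValueError("CGI values must be integers in 1..7")
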