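"""VCF input/output for dosage matrices.

Reading goes through cyvcf2 (htslib); the DS FORMAT field is preferred when
present, otherwise hard GT calls are converted to 0/1/2 ALT-dosages. Writing
emits plain-text VCF v4.2 with both GT (hard calls where the dosage is
integral, ``./.`` otherwise) and DS.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeMatrix


def read_vcf(path: str | Path, prefer_ds: bool = True) -> GenotypeMatrix:
    """Load a (single-ALT) VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected; records without an ID get a
    ``chrom:pos`` synthetic id.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, meta, rows = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}; split first")
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        try:
            ds = v.format("DS") if prefer_ds else None
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
            row = np.where((row < 0) | (row > 2), np.nan, row)
        else:
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(v.gt_types)
            row = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        ids.append(vid)
        meta.append((str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        rows.append(row)
    dosage = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    variants = pd.DataFrame(meta, index=ids, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosage, variants)


def _format_entry(d: float) -> str:
    if math.isnan(d):
        return "./.:."
    ds = f"{d:.6g}"
    if float(d).is_integer():
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
        return f"{gt}:{ds}"
    return f"./.:{ds}"


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a v4.2 text VCF with GT and DS FORMAT fields."""
    path = Path(path)
    variants = matrix.variants
    dosage = matrix.dosage.to_numpy(dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT allele dosage">\n'
        )
        for chrom in variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in matrix.subjects)
            + "\n"
        )
        for j, (vid, row) in enumerate(variants.iterrows()):
            entries = "\t".join(_format_entry(dosage[i, j]) for i in range(dosage.shape[0]))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT:DS\t{entries}\n"
            )
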