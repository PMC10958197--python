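import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # shared trajectory_cases helper

from prsresponse.containers import GenotypeMatrix


def matrix_from_counts(spec: dict) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-variant genotype count triples.

    ``spec`` maps variant id -> (n_ref_hom, n_het, n_alt_hom, n_missing).
    All variants must imply the same subject count.
    """
    cols = {}
    meta = []
    n_total = None
    for vid, (aa, ab, bb, miss) in spec.items():
        col = np.concatenate(
            [np.zeros(aa), np.ones(ab), np.full(bb, 2.0), np.full(miss, np.nan)]
        )
        if n_total is None:
            n_total = len(col)
        assert len(col) == n_total, "inconsistent subject counts"
        cols[vid] = col
        meta.append(("1", 1000 * (len(meta) + 1), "A", "G"))
    dosage = pd.DataFrame(cols, index=[f"s{i}" for i in range(n_total)])
    variants = pd.DataFrame(meta, index=list(spec), columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosage, variants)


@pytest.fixture
def small_cohort():
    """200-subject synthetic cohort with default (study-like) parameters."""
    from prsresponse.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_subjects=200, n_background_variants=40, seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def random_matrix():
    """60 subjects x 8 variants random HWE genotypes on two chromosomes."""
    rng = np.random.default_rng(5)
    ids = [f"v{j}" for j in range(8)]
    dosage = pd.DataFrame(
        rng.binomial(2, 0.3, size=(60, 8)).astype(float),
        index=[f"s{i}" for i in range(60)],
        columns=ids,
    )
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * 4 + ["2"] * 4,
            "pos": [10_000, 50_000, 400_000, 900_000] * 2,
            "ref": "A",
            "alt": "G",
        },
        index=ids,
    )
    return GenotypeMatrix(dosage, variants)
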