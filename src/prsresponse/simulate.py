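"""Seeded synthetic cohort generator with known ground truth.

The generator emulates a naturalistic antipsychotic-treated cohort: a small
panel of response-associated SNPs (default: the packaged 11-SNP panel with
effect-allele frequencies mirroring the source cohort's pooled genotype
counts), background variants carrying mild two-deme population structure
(Balding-Nichols allele-frequency drift) for ancestry PCs, demographics, and
longitudinal CGI-S/CGI-I observations plus treatment events constructed so
the rule-based response classifier recovers the latent responder status.

Responder status is drawn from a logistic liability

    logit P(response) = intercept + b_prs (PRS - E[PRS]) + b_age (age - mean)
                        + b_pop (deme - mean deme)

so the generative model is the exact inverse of the downstream association
model. PRS and age are centred by their theoretical means, making the
intercept directly interpretable: intercept = logit(target responder
fraction), up to the (small) nonlinearity of the logistic mean.

Defaults mirror the study conditions: 460 subjects, responder fraction
~0.54 (intercept logit(249/211)), per-PRS-unit OR 1.14, a negative age
effect, ages uniform on 18-80, a 1-year observation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import CohortBundle, GenotypeMatrix
from .response import MIN_TREATMENT_DAYS, N3_MIN_SPAN_DAYS

# effect-allele (risk-allele) frequencies matching the source cohort's pooled
# per-SNP genotype counts; implied expected PRS mean 5.95
DEFAULT_EFFECT_FREQS = {
    "rs6688363": 0.1996,
    "rs10170310": 0.1562,
    "rs2133450": 0.4848,
    "rs1875705": 0.5521,
    "rs10023464": 0.0770,
    "rs7668556": 0.4176,
    "rs17382202": 0.1985,
    "rs12767583": 0.1594,
    "rs7395555": 0.1876,
    "rs711355": 0.3840,
    "rs2980976": 0.1584,
}

DIAGNOSIS_GROUPS = {
    "SCZ": ("F20.0", 149),
    "SA": ("F25.0", 27),
    "BD": ("F31.0", 59),
    "DEP": ("F32.0", 42),
    "NCD": ("F03.0", 17),
    "SUD": ("F10.2", 9),
    "MISC": ("F99", 28),
}

RESPONDER_FRACTION_TARGET = 249 / 460  # 0.5413


@dataclass
class PanelVariant:
    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    weight: float = 1.0
    effect_is_minor: bool = True

    @property
    def effect_freq(self) -> float:
        return self.maf if self.effect_is_minor else 1.0 - self.maf


@dataclass
class LDBlock:
    variant_ids: list
    target_r2: float


def default_panel() -> list[PanelVariant]:
    """Panel variant specs built from the packaged score file + frequencies."""
    from .scoring import response_panel

    panel = []
    for _, row in response_panel().iterrows():
        f = DEFAULT_EFFECT_FREQS[row["snp_id"]]
        panel.append(
            PanelVariant(
                snp_id=row["snp_id"],
                chrom=str(row["chr"]),
                pos=int(row["pos"]),
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                maf=min(f, 1 - f),
                weight=float(row["weight"]),
                effect_is_minor=f <= 0.5,
            )
        )
    return panel


def score_frame(panel: list[PanelVariant]) -> pd.DataFrame:
    """Panel specs as a canonical 7-column score-file DataFrame."""
    return pd.DataFrame(
        [
            {"snp_id": v.snp_id, "chr": v.chrom, "pos": v.pos,
             "effect_allele": v.effect_allele, "other_allele": v.other_allele,
             "weight": v.weight, "p": 1e-8}
            for v in panel
        ]
    )


@dataclass
class SimulationConfig:
    n_subjects: int = 460
    panel: list = field(default_factory=default_panel)
    ld_blocks: list = field(default_factory=list)
    n_background_variants: int = 200
    n_subpopulations: int = 2
    fst: float = 0.05
    structured_panel: bool = False
    true_log_or_per_prs_unit: float = math.log(1.14)
    age_log_or_per_year: float = -0.02
    ancestry_log_or: float = 0.0
    intercept: float = float(logit(RESPONDER_FRACTION_TARGET))
    missing_rate: float = 0.002
    observation_window_days: int = 365
    age_range: tuple = (18.0, 80.0)
    label_fidelity: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for v in self.panel:
            if not (0.0 < v.maf <= 0.5):
                raise ValueError(f"MAF for {v.snp_id} must lie in (0, 0.5], got {v.maf}")
        if not (0.0 <= self.missing_rate <= 0.1):
            raise ValueError("missing_rate must lie in [0, 0.1]")
        if not (0.0 <= self.fst <= 0.2):
            raise ValueError("fst must lie in [0, 0.2]")
        if not (0.0 <= self.label_fidelity <= 1.0):
            raise ValueError("label_fidelity must lie in [0, 1]")
        if not (0.0 < expit(self.intercept) < 1.0):
            raise ValueError("intercept implies a degenerate responder fraction")
        by_id = {v.snp_id: v for v in self.panel}
        for block in self.ld_blocks:
            if not (0.0 <= block.target_r2 <= 1.0):
                raise ValueError("target r2 must lie in [0, 1]")
            freqs = {round(by_id[vid].effect_freq, 12) for vid in block.variant_ids}
            if len(freqs) > 1 and block.target_r2 > 0:
                raise ValueError(
                    "target r2 incompatible with differing MAFs inside an LD block"
                )

    def expected_prs_mean(self) -> float:
        return sum(2.0 * v.effect_freq * v.weight for v in self.panel)

    def to_dict(self) -> dict:
        d = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in asdict(self).items()
        }
        d["panel"] = [asdict(v) for v in self.panel]
        d["ld_blocks"] = [asdict(b) for b in self.ld_blocks]
        d["age_range"] = list(self.age_range)
        return d


def _background_specs(n: int) -> list[tuple[str, int]]:
    # background variants live on chromosomes 19-22, 1 Mb apart: never inside
    # a clumping window of a panel variant
    return [(str(19 + j % 4), 1_000_000 * (1 + j // 4)) for j in range(n)]


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw the subjects x variants dosage matrix.

    Panel variants are Binomial(2, effect frequency) under HWE; background
    variants get subpopulation-specific frequencies via Balding-Nichols drift
    (Beta(f(1-F)/F, (1-f)(1-F)/F) around a Uniform(0.05, 0.5) ancestral
    frequency). LD blocks copy the block's first variant with a random mask
    of share sqrt(target r2). Missing entries are masked at ``missing_rate``;
    the complete matrix is kept on the returned object as
    ``complete_dosage`` for ground-truth use.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_subjects

    subpop = rng.integers(0, max(config.n_subpopulations, 1), size=n)

    cols, ids, meta = [], [], []
    panel_by_id = {v.snp_id: v for v in config.panel}
    block_of = {}
    for block in config.ld_blocks:
        for vid in block.variant_ids[1:]:
            block_of[vid] = block

    def _draw_panel(freq: float) -> np.ndarray:
        if config.structured_panel and config.n_subpopulations > 1 and config.fst > 0:
            fk = _drift_freqs(freq, config, rng)
            return rng.binomial(2, fk[subpop]).astype(float)
        return rng.binomial(2, freq, size=n).astype(float)

    drawn: dict[str, np.ndarray] = {}
    for v in config.panel:
        if v.snp_id in block_of:
            block = block_of[v.snp_id]
            ref = drawn[block.variant_ids[0]]
            mask = rng.random(n) < math.sqrt(block.target_r2)
            fresh = _draw_panel(v.effect_freq)
            col = np.where(mask, ref, fresh)
        else:
            col = _draw_panel(v.effect_freq)
        drawn[v.snp_id] = col
        cols.append(col)
        ids.append(v.snp_id)
        meta.append((v.chrom, v.pos, v.other_allele, v.effect_allele))

    alleles = ["A", "C", "G", "T"]
    for j, (chrom, pos) in enumerate(_background_specs(config.n_background_variants)):
        f0 = rng.uniform(0.05, 0.5)
        if config.n_subpopulations > 1 and config.fst > 0:
            fk = _drift_freqs(f0, config, rng)
            col = rng.binomial(2, fk[subpop]).astype(float)
        else:
            col = rng.binomial(2, f0, size=n).astype(float)
        ref, alt = rng.choice(alleles, size=2, replace=False)
        cols.append(col)
        ids.append(f"bg{j}")
        meta.append((chrom, pos, ref, alt))

    complete = np.column_stack(cols) if cols else np.empty((n, 0))
    released = complete.copy()
    if config.missing_rate > 0:
        released[rng.random(released.shape) < config.missing_rate] = np.nan

    subjects = [f"S{i + 1:04d}" for i in range(n)]
    dosage = pd.DataFrame(released, index=subjects, columns=ids)
    variants = pd.DataFrame(meta, index=ids, columns=["chrom", "pos", "ref", "alt"])
    matrix = GenotypeMatrix(dosage, variants)
    matrix.complete_dosage = pd.DataFrame(complete, index=subjects, columns=ids)
    matrix.subpopulation = pd.Series(subpop, index=subjects, name="subpopulation")
    return matrix


def _drift_freqs(f0: float, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    F = config.fst
    a, b = f0 * (1 - F) / F, (1 - f0) * (1 - F) / F
    return np.clip(rng.beta(a, b, size=config.n_subpopulations), 0.01, 0.99)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> CohortBundle:
    """Draw demographics, latent responder status and clinical trajectories.

    True responder status comes from the logistic liability; CGI/treatment
    records are then constructed so the rule engine recovers it for a
    ``label_fidelity`` fraction of subjects (the rest get deliberately
    uninformative records that classify as unknown, flagged ``degraded`` in
    the ground-truth table).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    subjects = genotypes.subjects
    n = len(subjects)

    panel_ids = [v.snp_id for v in config.panel if v.snp_id in genotypes.dosage.columns]
    weights = pd.Series({v.snp_id: v.weight for v in config.panel})[panel_ids]
    complete = getattr(genotypes, "complete_dosage", None)
    if complete is not None:
        eff = complete[panel_ids]
    else:
        eff = genotypes.dosage[panel_ids]
        eff = eff.fillna(eff.mean())
    true_prs = eff.mul(weights, axis=1).sum(axis=1)

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    subpop = getattr(genotypes, "subpopulation", pd.Series(np.zeros(n, dtype=int), index=subjects))
    deme = subpop.to_numpy().astype(float)

    liability = (
        config.intercept
        + config.true_log_or_per_prs_unit * (true_prs.to_numpy() - config.expected_prs_mean())
        + config.age_log_or_per_year * (age - (lo + hi) / 2.0)
        + config.ancestry_log_or * (deme - deme.mean())
    )
    p = expit(liability)
    responder = rng.random(n) < p

    warnings = []
    if p.mean() > 0.99 or p.mean() < 0.01:
        warnings.append("degenerate_config: implied responder fraction near 0 or 1")
    if responder.all() or not responder.any():
        warnings.append("single_class_outcome")

    degraded = rng.random(n) >= config.label_fidelity

    groups = list(DIAGNOSIS_GROUPS)
    weights_dx = np.array([DIAGNOSIS_GROUPS[g][1] for g in groups], dtype=float)
    dx_idx = rng.choice(len(groups), size=n, p=weights_dx / weights_dx.sum())
    sex = rng.choice(["F", "M"], size=n)
    admissions = rng.poisson(2.5, size=n)
    substance = rng.random(n) < 0.163
    ses = np.clip(rng.normal(58.0, 12.0, size=n), 14.0, 81.0)

    start_dates = pd.Timestamp("2015-01-01") + pd.to_timedelta(
        rng.integers(0, 1095, size=n), unit="D"
    )

    subj_rows, cgi_rows, ev_rows, truth_rows = [], [], [], []
    for i, sid in enumerate(subjects):
        g = groups[dx_idx[i]]
        subj_rows.append(
            {"subject_id": sid, "age_years": round(float(age[i]), 1), "sex": sex[i],
             "diagnosis": DIAGNOSIS_GROUPS[g][0], "diagnostic_group": g,
             "admissions": int(admissions[i]), "substance_abuse": bool(substance[i]),
             "socioeconomic_index": round(float(ses[i]), 1)}
        )
        start = start_dates[i]
        cgi_i, ev_i = _trajectory(
            bool(responder[i]), bool(degraded[i]), start, config.observation_window_days, rng
        )
        for day, scale, value in cgi_i:
            cgi_rows.append(
                {"subject_id": sid, "date": (start + pd.Timedelta(days=int(day))).date().isoformat(),
                 "scale": scale, "value": int(value)}
            )
        for day, kind, drug, dose, reason in ev_i:
            ev_rows.append(
                {"subject_id": sid, "date": (start + pd.Timedelta(days=int(day))).date().isoformat(),
                 "kind": kind, "drug": drug, "dose_mg_day": dose, "reason": reason}
            )
        truth_rows.append(
            {"subject_id": sid, "true_prs": float(true_prs.iloc[i]),
             "liability": float(liability[i]), "true_responder": bool(responder[i]),
             "degraded": bool(degraded[i]), "subpopulation": int(deme[i])}
        )

    bundle = CohortBundle(
        genotypes=genotypes,
        subjects=pd.DataFrame(subj_rows),
        cgi=pd.DataFrame(cgi_rows, columns=["subject_id", "date", "scale", "value"]),
        events=pd.DataFrame(ev_rows, columns=["subject_id", "date", "kind", "drug", "dose_mg_day", "reason"]),
        truth=pd.DataFrame(truth_rows),
        warnings=warnings,
    )
    return bundle


_DRUGS = ["quetiapine", "risperidone", "aripiprazole", "olanzapine", "amisulpride", "clozapine"]


def _trajectory(responder: bool, degraded: bool, start, window: int, rng) -> tuple[list, list]:
    """One subject's CGI observations and treatment events, in day offsets.

    Responders carry one of the three response signals (a >=2-point CGI-S
    drop over >=30 days, a CGI-S of 1, or a CGI-I <= 2) and none of the
    disqualifiers. Non-responders trigger one of the explicit non-response
    rules (post-90-day dose increase / add-on, discontinuation for
    inefficacy, or a flat adequate-observation trajectory). Degraded records
    are truncated to a lone baseline visit (classifies unknown).
    """
    drug = _DRUGS[rng.integers(0, len(_DRUGS))]
    dose = float(rng.choice([5, 10, 200, 400]))
    baseline = int(rng.integers(4, 7))  # CGI-S 4..6 at intake
    events = [(0, "start", drug, dose, "")]
    obs_end = int(rng.integers(min(160, window), window + 1))

    if degraded:
        return [(0, "CGI-S", baseline)], events

    cgi = [(0, "CGI-S", baseline)]
    if responder:
        mode = rng.random()
        d_sig = int(rng.integers(40, 150))
        if mode < 0.7:  # R1: >=2-point CGI-S improvement
            cgi.append((d_sig, "CGI-S", max(1, baseline - int(rng.integers(2, 4)))))
        elif mode < 0.85:  # R2: CGI-S reaches 1
            cgi.append((d_sig, "CGI-S", 1))
        else:  # R3: CGI-I much improved
            cgi.append((d_sig, "CGI-I", int(rng.integers(1, 3))))
        cgi.append((obs_end, "CGI-S", max(1, baseline - 2)))
        if rng.random() < 0.2:  # early titration does not disqualify
            events.append((int(rng.integers(7, 60)), "dose_increase", drug, dose * 1.5, ""))
    else:
        mode = rng.random()
        flat = [(int(d), "CGI-S", min(7, baseline + int(rng.integers(0, 2))))
                for d in (45, MIN_TREATMENT_DAYS + 10, N3_MIN_SPAN_DAYS + 10, obs_end)
                if d <= obs_end]
        cgi.extend(flat)
        if mode < 0.35:  # N1: dose increase after day 90
            events.append((int(rng.integers(95, max(obs_end, 96))), "dose_increase", drug, dose * 2, ""))
        elif mode < 0.5:  # N1: add-on
            kind = "addon_antipsychotic" if rng.random() < 0.5 else "addon_mood_stabilizer"
            events.append((int(rng.integers(30, obs_end)), kind, "addon_drug", 100.0, ""))
        elif mode < 0.7 or obs_end < N3_MIN_SPAN_DAYS + 10:
            # N2: stopped for inefficacy (also the fallback when the
            # observation span is too short for the flat-trajectory rule)
            events.append((int(rng.integers(30, obs_end)), "discontinuation", drug, 0.0, "inefficacy"))
        # else N3: flat trajectory only (span >= 180 via the obs_end visit)
    return cgi, events


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Genotypes + phenotypes in one seeded call."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng=rng)
    return simulate_phenotypes(genotypes, config, rng=rng)


def write_bundle(bundle: CohortBundle, out_dir, config: SimulationConfig | None = None) -> dict:
    """Write a cohort to disk: VCF genotypes, TSV tables, YAML config echo."""
    import yaml
    from pathlib import Path

    from .vcfio import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "subjects": out / "subjects.tsv",
        "cgi": out / "cgi.tsv",
        "events": out / "events.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(bundle.genotypes, paths["vcf"])
    bundle.subjects.to_csv(paths["subjects"], sep="\t", index=False)
    bundle.cgi.to_csv(paths["cgi"], sep="\t", index=False)
    bundle.events.to_csv(paths["events"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    if config is not None:
        paths["config"] = out / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
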