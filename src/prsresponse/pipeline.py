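"""End-to-end pipeline: simulate/load -> QC -> PCA -> clump -> score ->
classify -> associate -> ROC, with a structured, regenerable run report.

A run is driven by one config mapping (YAML on disk for the CLI). Either a
``simulate`` section (synthetic cohort, the default demo) or an ``inputs``
section (VCF + score file + clinical TSVs) provides the data; stage
parameters sit under ``qc``, ``clump``, ``score``, ``classify``, ``pca``
and ``strata``. Subjects labelled unknown are excluded from association and
ROC, and the exclusion count is reported.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_strata, per_snp_table, univariate_screen
from .clump import LDClumper
from .containers import GenotypeMatrix
from .qc import GenotypePCA, QCFilter
from .response import classify_response
from .roc import summary_dict, youden_cutoff
from .scoring import PRSScorer, read_score_file, response_panel
from .simulate import LDBlock, PanelVariant, SimulationConfig, simulate_cohort, write_bundle
from .vcfio import read_vcf

DEFAULT_STRATA = {
    "all": [],
    "SCZ_SA_BD": ["SCZ", "SA", "BD"],
    "SCZ_SA": ["SCZ", "SA"],
    "SCZ": ["SCZ"],
    "SA": ["SA"],
    "BD": ["BD"],
    "others": ["DEP", "NCD", "SUD", "MISC"],
}


@dataclass
class RunReport:
    config: dict
    seed: int
    counts: dict
    per_snp: pd.DataFrame
    association: pd.DataFrame
    roc: dict
    univariate: pd.DataFrame
    version: str = __version__
    wall_clock_s: float = 0.0
    artifacts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "counts": self.counts,
            "roc": self.roc,
            "wall_clock_s": self.wall_clock_s,
            "artifacts": self.artifacts,
        }


def _sim_config_from(section: dict, seed: int | None) -> SimulationConfig:
    section = dict(section or {})
    if "panel" in section:
        section["panel"] = [PanelVariant(**v) for v in section["panel"]]
    if "ld_blocks" in section:
        section["ld_blocks"] = [LDBlock(**b) for b in section["ld_blocks"]]
    if "age_range" in section:
        section["age_range"] = tuple(section["age_range"])
    cfg = SimulationConfig(**section)
    if seed is not None:
        cfg.seed = seed
    return cfg


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> RunReport:
    """Execute every stage and write all artifacts under ``out_dir``."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # ---- stage: inputs -------------------------------------------------
    if "inputs" in config:
        inp = config["inputs"]
        genotypes = read_vcf(inp["vcf"])
        panel = read_score_file(inp["score_file"]) if inp.get("score_file") else response_panel()
        cgi = pd.read_csv(inp["cgi"], sep="\t")
        events = pd.read_csv(inp["events"], sep="\t")
        subjects = pd.read_csv(inp["subjects"], sep="\t")
        sim_cfg = None
    else:
        sim_cfg = _sim_config_from(config.get("simulate", {}), seed)
        bundle = simulate_cohort(sim_cfg)
        artifacts.update(write_bundle(bundle, out / "cohort", config=sim_cfg))
        genotypes = bundle.genotypes
        panel = response_panel()
        cgi, events, subjects = bundle.cgi, bundle.events, bundle.subjects
    used_seed = seed if seed is not None else (sim_cfg.seed if sim_cfg else 0)

    # ---- stage: QC -----------------------------------------------------
    qc_cfg = config.get("qc", {})
    qc = QCFilter(
        min_call_rate=qc_cfg.get("min_call_rate", 0.99),
        min_hwe_p=qc_cfg.get("min_hwe_p", 1e-6),
        min_maf=qc_cfg.get("min_maf", 0.05),
    ).fit(genotypes)
    filtered = qc.transform(genotypes)
    qc.report_.to_csv(out / "qc_report.tsv", sep="\t")
    artifacts["qc_report"] = str(out / "qc_report.tsv")

    # ---- stage: ancestry PCA ------------------------------------------
    k = config.get("pca", {}).get("n_components", 5)
    pcs = GenotypePCA(n_components=k).fit(filtered).components_

    # ---- stage: clumping ----------------------------------------------
    clump_cfg = config.get("clump", {})
    panel_ids = [v for v in panel["snp_id"] if v in filtered.dosage.columns]
    panel_matrix = filtered.select_variants(panel_ids)
    pvals = panel.set_index("snp_id")["p"]
    clumper = LDClumper(
        r2_threshold=clump_cfg.get("r2_threshold", 0.1),
        window_kb=clump_cfg.get("window_kb", 250.0),
        p_threshold=clump_cfg.get("p_threshold", 1.0),
    ).fit(panel_matrix, pvals)
    clumped = clumper.transform(panel_matrix)
    clumper.result_.to_frame().to_csv(out / "clump.tsv", sep="\t", index=False)
    artifacts["clump"] = str(out / "clump.tsv")

    # ---- stage: PRS ----------------------------------------------------
    score_cfg = config.get("score", {})
    scorer = PRSScorer(
        panel[panel["snp_id"].isin(clumped.variant_ids)],
        missing_policy=score_cfg.get("missing_policy", "mean"),
        allow_palindromic=score_cfg.get("allow_palindromic", True),
    )
    prs = scorer.fit_transform(clumped)
    prs.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
    artifacts["scores"] = str(out / "scores.tsv")

    # ---- stage: response labels ---------------------------------------
    window = config.get("classify", {}).get("window_days", 365)
    labels = classify_response(cgi, events, window_days=window)
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    artifacts["labels"] = str(out / "labels.tsv")

    # ---- stage: merge + association -----------------------------------
    data = (
        labels.merge(prs.to_frame(), on="subject_id")
        .merge(subjects, on="subject_id")
        .merge(pcs.rename_axis("subject_id").reset_index(), on="subject_id")
    )
    known = data[data["label"] != "unknown"].copy()
    known["responder"] = (known["label"] == "responder").astype(int)

    strata = config.get("strata", DEFAULT_STRATA)
    pc_cols = tuple(f"PC{j + 1}" for j in range(k))
    association = fit_strata(
        known.rename(columns={"age_years": "age"}),
        strata,
        covariate_cols=("age", *pc_cols),
    )
    association.to_csv(out / "association.tsv", sep="\t", index=False)
    artifacts["association"] = str(out / "association.tsv")

    snp_table = per_snp_table(
        clumped.dosage.loc[known["subject_id"]], known.set_index("subject_id")["responder"]
    )
    snp_table.to_csv(out / "per_snp.tsv", sep="\t", index=False)
    artifacts["per_snp"] = str(out / "per_snp.tsv")

    screen_cols = [c for c in ("age_years", "socioeconomic_index", "admissions") if c in known.columns]
    screen = univariate_screen(known[screen_cols], known["responder"]) if screen_cols else pd.DataFrame()
    if len(screen):
        screen.to_csv(out / "univariate_screen.tsv", sep="\t", index=False)
        artifacts["univariate_screen"] = str(out / "univariate_screen.tsv")

    # ---- stage: ROC ----------------------------------------------------
    roc_out = {}
    for name, groups in strata.items():
        sub = known if not groups else known[known["diagnostic_group"].isin(groups)]
        if sub["responder"].nunique() < 2 or len(sub) < 4:
            roc_out[name] = {"error": "insufficient or single-class data"}
            continue
        roc_out[name] = summary_dict(youden_cutoff(sub["score"], sub["responder"]))
    with open(out / "roc.json", "w") as fh:
        json.dump(roc_out, fh, indent=2)
    artifacts["roc"] = str(out / "roc.json")

    counts = {
        "variants_in": genotypes.n_variants,
        "variants_qc_retained": filtered.n_variants,
        "variants_qc_removed": genotypes.n_variants - filtered.n_variants,
        "panel_variants_in": len(panel_ids),
        "panel_variants_clump_retained": clumped.n_variants,
        "panel_variants_clump_removed": len(panel_ids) - clumped.n_variants,
        "subjects": int(len(labels)),
        "responders": int((labels["label"] == "responder").sum()),
        "non_responders": int((labels["label"] == "non_responder").sum()),
        "unknown_excluded": int((labels["label"] == "unknown").sum()),
    }

    report = RunReport(
        config=config,
        seed=used_seed,
        counts=counts,
        per_snp=snp_table,
        association=association,
        roc=roc_out,
        univariate=screen,
        wall_clock_s=round(time.time() - t0, 3),
        artifacts=artifacts,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=str)
    return report
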