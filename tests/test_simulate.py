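"""Synthetic cohort generator: determinism, allele-frequency convergence,
LD-block construction, calibration and label fidelity."""

import numpy as np
import pandas as pd
import pytest

from prsresponse.response import classify_response
from prsresponse.simulate import (
    LDBlock,
    PanelVariant,
    SimulationConfig,
    default_panel,
    simulate_cohort,
    simulate_genotypes,
    write_bundle,
)


def _one_variant_config(maf=0.5, n=10_000, **kw):
    panel = [PanelVariant("v1", "1", 100_000, "G", "A", maf)]
    return SimulationConfig(
        n_subjects=n, panel=panel, n_background_variants=0,
        n_subpopulations=1, missing_rate=0.0, **kw,
    )


class TestGenotypes:
    def test_empirical_maf_within_binomial_error(self):
        cfg = _one_variant_config(maf=0.5, n=10_000, seed=31)
        m = simulate_genotypes(cfg)
        f = m.dosage["v1"].mean() / 2
        assert abs(f - 0.5) < 3 * np.sqrt(0.5 * 0.5 / (2 * 10_000))

    def test_zero_missing_rate_is_complete(self):
        cfg = SimulationConfig(n_subjects=100, n_background_variants=20,
                               missing_rate=0.0, seed=32)
        assert not simulate_genotypes(cfg).dosage.isna().any().any()

    def test_missing_rate_respected(self):
        cfg = SimulationConfig(n_subjects=500, n_background_variants=100,
                               missing_rate=0.05, seed=33)
        rate = simulate_genotypes(cfg).dosage.isna().to_numpy().mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_perfect_ld_block_duplicates_dosages(self):
        panel = [
            PanelVariant("a", "1", 100_000, "G", "A", 0.3),
            PanelVariant("b", "1", 150_000, "T", "C", 0.3),
        ]
        cfg = SimulationConfig(
            n_subjects=300, panel=panel, ld_blocks=[LDBlock(["a", "b"], 1.0)],
            n_background_variants=0, n_subpopulations=1, missing_rate=0.0, seed=34,
        )
        m = simulate_genotypes(cfg)
        assert (m.dosage["a"] == m.dosage["b"]).all()

    def test_partial_ld_block_hits_target_r2(self):
        panel = [
            PanelVariant("a", "1", 100_000, "G", "A", 0.4),
            PanelVariant("b", "1", 150_000, "T", "C", 0.4),
        ]
        cfg = SimulationConfig(
            n_subjects=20_000, panel=panel, ld_blocks=[LDBlock(["a", "b"], 0.5)],
            n_background_variants=0, n_subpopulations=1, missing_rate=0.0, seed=35,
        )
        m = simulate_genotypes(cfg)
        r2 = np.corrcoef(m.dosage["a"], m.dosage["b"])[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ValueError, match="MAF"):
            simulate_genotypes(_one_variant_config(maf=maf, n=100))

    def test_incompatible_block_mafs_rejected(self):
        panel = [
            PanelVariant("a", "1", 100_000, "G", "A", 0.1),
            PanelVariant("b", "1", 150_000, "T", "C", 0.4),
        ]
        cfg = SimulationConfig(n_subjects=100, panel=panel,
                               ld_blocks=[LDBlock(["a", "b"], 0.9)],
                               n_background_variants=0, missing_rate=0.0)
        with pytest.raises(ValueError, match="incompatible"):
            simulate_genotypes(cfg)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(SimulationConfig(n_subjects=1))


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        cfg = SimulationConfig(n_subjects=80, n_background_variants=20, seed=36)
        b1 = simulate_cohort(cfg)
        b2 = simulate_cohort(cfg)
        assert b1.genotypes == b2.genotypes
        for name in ("subjects", "cgi", "events", "truth"):
            pd.testing.assert_frame_equal(getattr(b1, name), getattr(b2, name))

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_subjects=40, n_background_variants=10, seed=37)
        p1 = write_bundle(simulate_cohort(cfg), tmp_path / "a", config=cfg)
        p2 = write_bundle(simulate_cohort(cfg), tmp_path / "b", config=cfg)
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read(), key

    def test_different_seed_differs(self):
        cfg_a = SimulationConfig(n_subjects=80, n_background_variants=0, seed=1)
        cfg_b = SimulationConfig(n_subjects=80, n_background_variants=0, seed=2)
        assert not simulate_cohort(cfg_a).genotypes.dosage.equals(
            simulate_cohort(cfg_b).genotypes.dosage
        )


class TestPhenotypes:
    def test_responder_fraction_calibrated_to_logistic_mean(self):
        # >=200 replicates at n=1000: pooled empirical responder fraction
        # within 3 Monte-Carlo SEs of the mean implied probability
        from scipy.special import expit

        total_resp, sum_p, sum_var, total_n = 0, 0.0, 0.0, 0
        for rep in range(200):
            cfg = SimulationConfig(n_subjects=1000, n_background_variants=0,
                                   n_subpopulations=1, missing_rate=0.0, seed=1000 + rep)
            b = simulate_cohort(cfg)
            p = expit(b.truth["liability"].to_numpy())
            total_resp += int(b.truth["true_responder"].sum())
            sum_p += p.sum()
            sum_var += (p * (1 - p)).sum()
            total_n += len(p)
        emp = total_resp / total_n
        implied = sum_p / total_n
        se = np.sqrt(sum_var) / total_n
        assert abs(emp - implied) < 3 * se
        # and the configured intercept lands near the target cohort fraction
        assert implied == pytest.approx(0.5413, abs=0.01)

    def test_null_effects_give_null_auc(self):
        from prsresponse.roc import roc_curve

        aucs = []
        for rep in range(60):
            cfg = SimulationConfig(
                n_subjects=400, n_background_variants=0, n_subpopulations=1,
                true_log_or_per_prs_unit=0.0, age_log_or_per_year=0.0,
                missing_rate=0.0, seed=2000 + rep,
            )
            b = simulate_cohort(cfg)
            y = b.truth["true_responder"].astype(int)
            if y.min() == y.max():
                continue
            aucs.append(roc_curve(b.truth["true_prs"], y).auc)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3

    def test_label_fidelity_degrades_to_unknown(self):
        cfg = SimulationConfig(n_subjects=300, n_background_variants=0,
                               label_fidelity=0.5, seed=38)
        b = simulate_cohort(cfg)
        labels = classify_response(b.cgi, b.events)
        m = labels.merge(b.truth, on="subject_id")
        assert (m.loc[m["degraded"], "label"] == "unknown").all()
        complete = m[~m["degraded"]]
        assert ((complete["label"] == "responder") == complete["true_responder"]).all()

    def test_degenerate_intercept_flagged(self):
        cfg = SimulationConfig(n_subjects=50, n_background_variants=0,
                               intercept=12.0, seed=39)
        b = simulate_cohort(cfg)
        assert any("degenerate" in w or "single_class" in w for w in b.warnings)

    def test_cgi_values_and_dates_valid(self, small_cohort):
        _, b = small_cohort
        assert b.cgi["value"].between(1, 7).all()
        assert set(b.cgi["scale"]) <= {"CGI-S", "CGI-I"}
        # every subject appears in all tables
        ids = set(b.subjects["subject_id"])
        assert set(b.truth["subject_id"]) == ids
        assert set(b.events["subject_id"]) == ids

    def test_expected_prs_mean_matches_panel(self):
        cfg = SimulationConfig(seed=40)
        assert cfg.expected_prs_mean() == pytest.approx(5.95, abs=0.01)
        m = simulate_genotypes(SimulationConfig(n_subjects=5000, n_background_variants=0,
                                                n_subpopulations=1, missing_rate=0.0, seed=41))
        panel_ids = [v.snp_id for v in default_panel()]
        emp = m.dosage[panel_ids].sum(axis=1).mean()
        assert emp == pytest.approx(cfg.expected_prs_mean(), abs=0.1)
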