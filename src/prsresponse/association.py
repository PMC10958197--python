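"""Per-SNP association tests and the covariate-adjusted logistic model.

The per-SNP battery mirrors a standard pharmacogenetic workup: a 1-df
Cochran-Armitage trend test on the 3x2 genotype-by-response table, a
genotypic Fisher exact test by complete enumeration, and an allelic odds
ratio with a Woolf (log-OR +/- 1.96 SE) confidence interval. The cohort-level
model is a maximum-likelihood logistic regression of responder status on the
PRS plus age and the first five ancestry principal components, reported as
OR with Wald 95% CI and two-sided p per predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

GENOTYPE_SCORES = np.array([0.0, 1.0, 2.0])


@dataclass
class AssociationResult:
    predictor: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple = ()
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "beta": self.beta,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "covariates": ",".join(self.covariates),
            "flags": ",".join(self.flags),
        }


class SeparationError(RuntimeError):
    """Raised when the logistic MLE diverges (perfectly separable outcome)."""


def trend_test(case_counts, control_counts) -> tuple[float, float]:
    """Cochran-Armitage test for trend on a 3x2 genotype table, scores 0/1/2.

    ``case_counts`` / ``control_counts`` are (n_AA, n_Aa, n_aa) per group.
    Returns (chi-square statistic on 1 df, two-sided p).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.shape != (3,) or s.shape != (3,):
        raise ValueError("expected 3 genotype counts per group")
    R, S = r.sum(), s.sum()
    if R < 1 or S < 1:
        raise ValueError("both groups need at least one subject")
    n_i = r + s
    N = R + S
    w = GENOTYPE_SCORES
    T = float(w @ r - (R / N) * (w @ n_i))
    var = (R * S / N**2) * float((w**2 @ n_i) - (w @ n_i) ** 2 / N)
    if var == 0:
        return 0.0, 1.0
    chi2 = T**2 / var  # plain Cochran-Armitage, no small-sample correction
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _table_logprob(table: np.ndarray, lgamma_margins: float) -> float:
    from scipy.special import gammaln

    return lgamma_margins - gammaln(table + 1).sum()


def fisher_exact_genotypic(case_counts, control_counts, max_n: int = 5000) -> float:
    """Fisher exact p for a 3x2 genotype table by complete enumeration.

    All tables with the observed margins are enumerated; the p-value sums the
    conditional (multivariate hypergeometric) probabilities of tables no more
    probable than the observed one (within a small numerical tolerance).
    """
    from scipy.special import gammaln

    obs = np.array([case_counts, control_counts], dtype=int).T  # 3 rows x 2 cols
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    if n > max_n:
        raise ValueError(
            f"table total {n} exceeds enumeration limit {max_n}; use a Monte-Carlo test"
        )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    lg_m = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    p_obs = _table_logprob(obs, lg_m)
    total = 0.0
    for a in range(min(row[0], col[0]) + 1):
        b_max = min(row[1], col[0] - a)
        for b in range(b_max + 1):
            c = col[0] - a - b
            if c > row[2]:
                continue
            t = np.array([[a, row[0] - a], [b, row[1] - b], [c, row[2] - c]])
            lp = _table_logprob(t, lg_m)
            if lp <= p_obs + 1e-9:
                total += np.exp(lp)
    return float(min(total, 1.0))


def allelic_odds_ratio(case_counts, control_counts) -> AssociationResult:
    """Allelic OR from a 3x2 genotype table collapsed to a 2x2 allele table.

    Allele counts per group: a = 2*hom_alt + het alternate alleles versus
    b = 2*hom_ref + het reference alleles. Zero cells get the
    Haldane-Anscombe 0.5 correction (flagged).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    a, b = 2 * r[2] + r[1], 2 * r[0] + r[1]  # case alt / ref alleles
    c, d = 2 * s[2] + s[1], 2 * s[0] + s[1]
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("a group has no alleles")
    flags = []
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("haldane_correction")
    beta = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = beta / se
    return AssociationResult(
        predictor="allele",
        beta=float(beta),
        se=float(se),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        n=int(r.sum() + s.sum()),
        flags=tuple(flags),
    )


def fit_logistic(
    outcome,
    design: pd.DataFrame,
    max_iter: int = 100,
) -> dict[str, AssociationResult]:
    """Covariate-adjusted logistic regression; one result per predictor.

    ``design`` holds the predictors (an intercept is added); ``outcome`` is a
    0/1 vector with both classes present. Wald SEs come from the observed
    information at the MLE. Raises :class:`SeparationError` on perfect
    separation or non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(design).astype(float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("design/outcome contain missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=max_iter)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(f"logistic fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if np.abs(fit.params.drop("const", errors="ignore")).max() > 30:
        raise SeparationError("diverging coefficients: outcome is (quasi-)separable")
    covars = tuple(c for c in X.columns)
    out = {}
    ci = fit.conf_int(alpha=0.05)
    for name in Xc.columns:
        if name == "const":
            continue
        beta = float(fit.params[name])
        out[name] = AssociationResult(
            predictor=name,
            beta=beta,
            se=float(fit.bse[name]),
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(ci.loc[name, 0])),
            ci_high=float(np.exp(ci.loc[name, 1])),
            p=float(fit.pvalues[name]),
            n=int(len(y)),
            covariates=tuple(c for c in covars if c != name),
        )
    return out


def univariate_screen(candidates: pd.DataFrame, outcome, alpha: float = 0.05) -> pd.DataFrame:
    """Screen candidate covariates one at a time against a binary outcome.

    Each candidate gets a linear-probability OLS fit and a univariate
    logistic fit; candidates reaching p <= alpha (logistic Wald) are flagged
    for inclusion in the multivariate model. Constant candidates are skipped.
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    for name in candidates.columns:
        x = candidates[name].astype(float)
        if x.nunique() <= 1:
            rows.append(
                {"covariate": name, "beta_linear": np.nan, "p_linear": np.nan,
                 "beta_logistic": np.nan, "p_logistic": np.nan,
                 "selected": False, "flag": "constant_skipped"}
            )
            continue
        Xc = sm.add_constant(x.to_numpy())
        ols = sm.OLS(y, Xc).fit()
        logit = sm.Logit(y, Xc).fit(disp=0)
        p_log = float(logit.pvalues[1])
        rows.append(
            {"covariate": name, "beta_linear": float(ols.params[1]),
             "p_linear": float(ols.pvalues[1]),
             "beta_logistic": float(logit.params[1]), "p_logistic": p_log,
             "selected": bool(p_log <= alpha), "flag": ""}
        )
    return pd.DataFrame(rows)


def per_snp_table(
    matrix_dosage: pd.DataFrame,
    labels: pd.Series,
    fisher_max_n: int = 5000,
) -> pd.DataFrame:
    """Per-variant genotype-by-response summary with trend/Fisher/allelic OR.

    ``labels`` is a 0/1 responder indicator aligned to the dosage index.
    Dosages are rounded to hard genotypes for the counts.
    """
    y = labels.astype(int)
    rows = []
    for vid in matrix_dosage.columns:
        d = matrix_dosage[vid]
        cases = _hard_counts(d[y == 1])
        controls = _hard_counts(d[y == 0])
        try:
            chi2, p_trend = trend_test(cases, controls)
        except ValueError:
            chi2, p_trend = np.nan, np.nan
        p_fisher = fisher_exact_genotypic(cases, controls, max_n=fisher_max_n)
        try:
            orr = allelic_odds_ratio(cases, controls)
            or_val, ci_l, ci_h = orr.odds_ratio, orr.ci_low, orr.ci_high
        except ValueError:
            or_val = ci_l = ci_h = np.nan
        rows.append(
            {"snp_id": vid,
             "resp_hom_ref": cases[0], "resp_het": cases[1], "resp_hom_alt": cases[2],
             "nonresp_hom_ref": controls[0], "nonresp_het": controls[1], "nonresp_hom_alt": controls[2],
             "trend_chi2": chi2, "p_trend": p_trend, "p_fisher": p_fisher,
             "allelic_or": or_val, "or_ci_low": ci_l, "or_ci_high": ci_h,
             "p_bonferroni": min(1.0, p_trend * matrix_dosage.shape[1]) if np.isfinite(p_trend) else np.nan}
        )
    return pd.DataFrame(rows)


def _hard_counts(dosages: pd.Series) -> tuple[int, int, int]:
    arr = dosages.to_numpy(dtype=float)
    arr = arr[~np.isnan(arr)]
    g = np.clip(np.rint(arr), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def fit_strata(
    data: pd.DataFrame,
    strata: dict[str, list[str]],
    prs_col: str = "score",
    outcome_col: str = "responder",
    covariate_cols: tuple = ("age", "PC1", "PC2", "PC3", "PC4", "PC5"),
    group_col: str = "diagnostic_group",
) -> pd.DataFrame:
    """Fit the adjusted logistic model within each diagnostic stratum.

    ``strata`` maps stratum name -> list of diagnostic-group values (an empty
    list means all subjects). Reports N, PRS mean +/- SD and range by
    response group, and the PRS OR / CI / p from the adjusted model.
    """
    rows = []
    for name, groups in strata.items():
        sub = data if not groups else data[data[group_col].isin(groups)]
        row: dict = {"stratum": name, "n": int(len(sub))}
        for grp, lab in ((1, "responders"), (0, "non_responders")):
            sc = sub.loc[sub[outcome_col] == grp, prs_col]
            row[f"{lab}_n"] = int(len(sc))
            row[f"{lab}_prs_mean"] = float(sc.mean()) if len(sc) else np.nan
            row[f"{lab}_prs_sd"] = float(sc.std(ddof=1)) if len(sc) > 1 else np.nan
            row[f"{lab}_prs_min"] = float(sc.min()) if len(sc) else np.nan
            row[f"{lab}_prs_max"] = float(sc.max()) if len(sc) else np.nan
        try:
            design = sub[[prs_col, *covariate_cols]]
            res = fit_logistic(sub[outcome_col], design)[prs_col]
            row.update(
                or_=res.odds_ratio, ci_low=res.ci_low, ci_high=res.ci_high, p=res.p, fit_flag=""
            )
        except (ValueError, SeparationError) as err:
            row.update(or_=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan, fit_flag=str(err))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.rename(columns={"or_": "odds_ratio"})
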