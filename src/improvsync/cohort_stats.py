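"""Diagnosis statistics: screening, logistic regression, LOOCV, baselines.

The modelling question is whether timing features of a participant's playing
predict group membership (patient = 1, control = 0).  The stage mirrors a
standard small-sample workflow: a per-variable Welch t screen, a stepwise
logistic regression (AIC forward steps, Wald-p backward steps), model
diagnostics (deviances, AIC, Nagelkerke R², Hosmer–Lemeshow calibration),
leave-one-out cross-validation at a 0.5 probability cut, and an exact
binomial tail as the guessing baseline.  Maximum-likelihood fits go through
statsmodels GLM (binomial family); Nagelkerke R² and Hosmer–Lemeshow are
computed here because no installed package exposes them directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

GROUP_COL = "group"


@dataclass
class LogisticFit:
    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    null_deviance: float
    null_df: int
    deviance: float
    df: int
    aic: float
    nagelkerke_r2: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    fitted: pd.Series
    n: int
    separation_flag: bool = False


@dataclass
class ValidationReport:
    error: float
    n: int
    confusion: dict[str, int]
    n_failed_folds: int = 0

    @property
    def n_correct(self) -> int:
        return self.confusion["tp"] + self.confusion["tn"]


@dataclass
class StepwiseResult:
    terms: list[str]
    path: list[str] = field(default_factory=list)  # human-readable step log
    fit: LogisticFit | None = None


def screen_variables(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Welch two-sample t-test per feature, ranked by raw p.

    Returns columns variable, t, df, p, p_bonferroni, n_patient, n_control.
    Features that are all-missing or zero-variance in both groups are skipped
    (logged), and the Bonferroni factor counts only the tested features.
    """
    rows = []
    for feat in features:
        sub = table[[GROUP_COL, feat]].dropna()
        a = sub.loc[sub[GROUP_COL] == 1, feat].to_numpy(float)
        b = sub.loc[sub[GROUP_COL] == 0, feat].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            log.info("screen: %s skipped (too few complete observations)", feat)
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            log.info("screen: %s skipped (zero variance in both groups)", feat)
            continue
        with warnings.catch_warnings():
            # near-constant features trip scipy's precision-loss warning
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "variable": feat, "t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue), "n_patient": len(a), "n_control": len(b),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out


def _design(table: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    sub = table[[GROUP_COL] + list(terms)].dropna()
    X = sm.add_constant(sub[list(terms)].astype(float), has_constant="add")
    X = X.rename(columns={"const": "Intercept"})
    return X, sub[GROUP_COL].astype(float)


def fit_logistic(table: pd.DataFrame, terms: list[str]) -> LogisticFit:
    """Maximum-likelihood logistic regression of group on the given terms.

    Complete-case per model.  Perfect or quasi-separation is detected from
    fitted probabilities hugging 0/1 and reported via ``separation_flag``
    (the fit is still returned for inspection).
    """
    X, y = _design(table, terms)
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    fitted = res.fittedvalues
    separated = bool(np.all((fitted < 1e-6) | (fitted > 1 - 1e-6))) and len(terms) > 0
    if separated:
        log.warning("fit_logistic(%s): separation detected, coefficients unreliable", terms)

    ll_model = float(res.llf)
    ll_null = float(
        sm.GLM(y, X[["Intercept"]], family=sm.families.Binomial()).fit().llf
    )
    denom = 1 - np.exp(2 * ll_null / n)
    nagelkerke = float((1 - np.exp(2 * (ll_null - ll_model) / n)) / denom) if denom > 0 else 0.0

    hl_chi2, hl_df, hl_p = hosmer_lemeshow(y.to_numpy(), fitted.to_numpy())
    names = list(X.columns)
    return LogisticFit(
        terms=list(terms),
        coef={k: float(res.params[k]) for k in names},
        se={k: float(res.bse[k]) for k in names},
        z={k: float(res.tvalues[k]) for k in names},
        p={k: float(res.pvalues[k]) for k in names},
        null_deviance=float(res.null_deviance),
        null_df=n - 1,
        deviance=float(res.deviance),
        df=int(res.df_resid),
        aic=float(res.aic),
        nagelkerke_r2=max(0.0, nagelkerke),
        hl_chi2=hl_chi2, hl_df=hl_df, hl_p=hl_p,
        fitted=fitted, n=n, separation_flag=separated,
    )


def hosmer_lemeshow(y: np.ndarray, p_hat: np.ndarray, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow calibration χ² over predicted-probability deciles (df = g − 2)."""
    order = np.argsort(p_hat, kind="stable")
    bins = np.array_split(order, groups)
    bins = [b for b in bins if len(b)]
    chi2 = 0.0
    for idx in bins:
        obs, exp = y[idx].sum(), p_hat[idx].sum()
        n_g = len(idx)
        denom = exp * (1 - exp / n_g)
        if denom <= 0:
            denom = 1e-12
        chi2 += (obs - exp) ** 2 / denom
    df = max(1, len(bins) - 2)
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def stepwise(
    table: pd.DataFrame,
    candidates: list[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    seed_terms: list[str] | None = None,
    max_terms: int = 5,
) -> StepwiseResult:
    """Stepwise selection: screen-based entry, AIC forward steps, Wald-p backward steps.

    Stage 1 admits the best-screening variable only if its Welch p < entry_p
    (or starts from ``seed_terms`` when given).  Later stages add the candidate
    minimizing AIC when it improves on the current AIC, then drop any term
    whose Wald p exceeds removal_p.  The full path is logged for audit.
    """
    result = StepwiseResult(terms=[])
    if seed_terms:
        result.terms = list(seed_terms)
        result.path.append(f"seeded with {seed_terms}")
    else:
        screen = screen_variables(table, candidates)
        if screen.empty or screen.iloc[0]["p"] >= entry_p:
            result.path.append("no variable passed the screening entry criterion")
            return result
        first = str(screen.iloc[0]["variable"])
        result.terms = [first]
        result.path.append(f"enter {first} (screen p={screen.iloc[0]['p']:.4g})")

    current = fit_logistic(table, result.terms)
    changed = True
    while changed and len(result.terms) < max_terms:
        changed = False
        # forward: best AIC improvement
        best_term, best_fit = None, None
        for cand in candidates:
            if cand in result.terms:
                continue
            trial = fit_logistic(table, result.terms + [cand])
            if trial.separation_flag:
                continue
            if trial.aic < current.aic - 1e-9 and (best_fit is None or trial.aic < best_fit.aic):
                best_term, best_fit = cand, trial
        if best_term is not None:
            result.terms.append(best_term)
            result.path.append(f"add {best_term} (AIC {current.aic:.2f} -> {best_fit.aic:.2f})")
            current = best_fit
            changed = True
        # backward: drop worst Wald p above threshold
        droppable = [(t, current.p[t]) for t in result.terms if current.p[t] > removal_p]
        if droppable and len(result.terms) > 1:
            worst = max(droppable, key=lambda kv: kv[1])[0]
            result.terms.remove(worst)
            result.path.append(f"remove {worst} (Wald p={current.p[worst]:.4g})")
            current = fit_logistic(table, result.terms)
            changed = True
    result.fit = current
    return result


def loocv(table: pd.DataFrame, terms: list[str], threshold: float = 0.5) -> ValidationReport:
    """Leave-one-out cross-validation: refit without each subject, classify at 0.5."""
    X, y = _design(table, terms)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    conf = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    failed = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y[mask], X[mask], family=sm.families.Binomial()).fit(maxiter=200)
            p_hat = float(res.predict(X.iloc[[i]]).iloc[0])
            if not np.isfinite(p_hat):
                raise ValueError("non-finite prediction")
        except Exception:
            failed += 1
            p_hat = 1.0 - y.iloc[i]  # non-convergent fold counts as misclassified
            log.warning("loocv: fold %d failed to converge, counted as misclassified", i)
        pred = 1.0 if p_hat > threshold else 0.0
        truth = y.iloc[i]
        key = ("t" if pred == truth else "f") + ("p" if pred == 1 else "n")
        conf[key] += 1
    error = (conf["fp"] + conf["fn"]) / n
    return ValidationReport(error=error, n=n, confusion=conf, n_failed_folds=failed)


def binomial_baseline(n: int, k: int, p: float) -> float:
    """Exact upper tail P(X > k) for X ~ Binomial(n, p) — the guessing baseline."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in 0..n")
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability")
    return float(stats.binom.sf(k, n, p))


def improvement_variable(table: pd.DataFrame) -> pd.Series:
    """MD_m_B1 − MD_m_B2: positive = deviations shrink over B = improving IPS."""
    for col in ("MD_m_B1", "MD_m_B2"):
        if col not in table.columns:
            raise KeyError(f"missing feature column {col}")
    return table["MD_m_B1"] - table["MD_m_B2"]


def covariate_screen(
    table: pd.DataFrame,
    target: pd.Series,
    covariates: list[str],
) -> dict:
    """Pearson screen of covariates against a target, per group, plus follow-ups.

    Reports r with df = n − 2 and the two-sided p per covariate within each
    group, a two-predictor OLS of the target on avoidance + anxiety in the
    patient group (R², F), a Welch t on the full groups, and a paired t
    restricted to matched pairs.  Constant covariates are skipped.
    """
    out: dict = {"correlations": [], "group_tests": {}}
    work = table.copy()
    work["_target"] = target
    for group, label in ((1, "patient"), (0, "control")):
        sub = work[work[GROUP_COL] == group]
        for cov in covariates:
            pair = sub[[cov, "_target"]].dropna()
            if len(pair) < 4:
                continue
            x = pair[cov].to_numpy(float)
            if np.std(x) == 0:
                log.info("covariate_screen: %s constant in %s group, skipped", cov, label)
                continue
            r, p = stats.pearsonr(x, pair["_target"].to_numpy(float))
            out["correlations"].append({
                "group": label, "covariate": cov, "r": float(r),
                "df": len(pair) - 2, "p": float(p), "n": len(pair),
            })

    pat = (
        work[work[GROUP_COL] == 1][["avoidance", "anxiety", "_target"]].dropna()
        if {"avoidance", "anxiety"}.issubset(work.columns)
        else pd.DataFrame()
    )
    if len(pat) >= 4:
        X = sm.add_constant(pat[["avoidance", "anxiety"]].astype(float))
        ols = sm.OLS(pat["_target"].astype(float), X).fit()
        out["attachment_regression"] = {
            "r_squared": float(ols.rsquared),
            "f": float(ols.fvalue), "df_model": int(ols.df_model),
            "df_resid": int(ols.df_resid), "p": float(ols.f_pvalue),
            "n": len(pat),
        }

    a = work.loc[work[GROUP_COL] == 1, "_target"].dropna()
    b = work.loc[work[GROUP_COL] == 0, "_target"].dropna()
    if len(a) >= 2 and len(b) >= 2:
        welch = stats.ttest_ind(a, b, equal_var=False)
        out["group_tests"]["welch"] = {
            "t": float(welch.statistic), "df": float(welch.df), "p": float(welch.pvalue),
        }
    if "matched_pair" in work.columns:
        paired = work.dropna(subset=["matched_pair", "_target"]).pivot_table(
            index="matched_pair", columns=GROUP_COL, values="_target"
        ).dropna()
        if len(paired) >= 2 and {0, 1}.issubset(paired.columns):
            tt = stats.ttest_rel(paired[1], paired[0])
            out["group_tests"]["paired"] = {
                "t": float(tt.statistic), "df": len(paired) - 1, "p": float(tt.pvalue),
            }
    return out


def regression_table_text(fits: dict[str, LogisticFit]) -> str:
    """Human-readable model summaries in the three-regression layout."""
    lines = []
    for label, fit in fits.items():
        lines.append(f"({label})")
        lines.append(f"{'Variable':<12}{'B':>10}{'SE B':>10}{'z':>8}{'P':>8}")
        for term in ["Intercept"] + fit.terms:
            lines.append(
                f"{term:<12}{fit.coef[term]:>10.2f}{fit.se[term]:>10.2f}"
                f"{fit.z[term]:>8.2f}{fit.p[term]:>8.3f}"
            )
        lines.append(f"Null deviance: {fit.null_deviance:.2f} on {fit.null_df} degrees of freedom")
        lines.append(f"Residual deviance: {fit.deviance:.2f} on {fit.df} degrees of freedom")
        lines.append(f"AIC: {fit.aic:.2f}")
        lines.append(
            f"Nagelkerke R2: {fit.nagelkerke_r2:.2f}; "
            f"Hosmer-Lemeshow chi2({fit.hl_df}) = {fit.hl_chi2:.2f}, p = {fit.hl_p:.2f}"
        )
        lines.append("")
    return "\n".join(lines)
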