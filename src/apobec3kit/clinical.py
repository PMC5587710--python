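"""Survival and association statistics for expression-stratified cohorts:
median-split grouping, Kaplan-Meier curves, log-rank tests, Cox
proportional-hazards regression, 2x2 contingency tests and the
differential-expression filter chain.

Kaplan-Meier estimation and the log-rank test are delegated to
lifelines, Cox regression to statsmodels (which exposes both Efron and
Breslow tie handling); the 2x2 tests are computed in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests


def median_split(values) -> tuple[np.ndarray, dict]:
    """Split a vector at its median: strictly above -> ``high``,
    at or below -> ``low`` (ties at the median go to ``low``)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2 or not np.isfinite(v).all():
        raise ValueError("need at least 2 finite values")
    med = float(np.median(v))
    labels = np.where(v > med, "high", "low")
    degenerate = len(np.unique(v)) == 1
    return labels, {"median": med, "degenerate": degenerate}


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set
    without contributing an event term."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    ev = tab[tab.observed > 0]
    d = ev.observed.to_numpy(dtype=float)
    n = ev.at_risk.to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    terms = np.divide(d, n * (n - d), out=np.zeros_like(d), where=(n - d) > 0)
    gw = surv**2 * np.cumsum(terms)
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        n_at_risk=n,
        n_events=d,
        survival=surv,
        greenwood_var=gw,
        n_subjects=len(t),
    )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-sided log-rank comparison of survival across groups."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("every group needs at least one subject")
    if len(labels) == 2:
        m = g == labels[0]
        res = _ll_logrank(t[m], t[~m], e[m], e[~m])
        return LogRankResult(float(res.test_statistic), 1, float(res.p_value))
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(float(res.test_statistic), len(labels) - 1, float(res.p_value))


@dataclass
class CoxModel:
    covariates: list
    beta: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    ties: str
    converged: bool
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "HR": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.covariates,
        )


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxModel:
    """Cox proportional hazards via partial likelihood (Efron tie
    handling by default; Breslow available), with Wald CIs and p-values.

    Zero-variance covariates carry no information and are reported with
    beta = 0 (HR = 1) and a flag; collinearity among the remaining
    covariates is detected by the conditioning of the design and
    flagged.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    X = records[list(covariates)].to_numpy(dtype=float)
    flags = []
    var = X.var(axis=0)
    keep = var > 0
    dropped = [c for c, k in zip(covariates, keep) if not k]
    if dropped:
        flags.append(f"constant covariate(s) {dropped}: beta fixed at 0")
    k = len(covariates)
    beta = np.zeros(k)
    se = np.full(k, np.inf)
    pvals = np.ones(k)
    loglik = float("nan")
    converged = True
    if keep.any():
        Xk = X[:, keep]
        if Xk.shape[1] > 1 and np.linalg.cond(Xk - Xk.mean(0)) > 1e10:
            flags.append("collinear covariates: information matrix ill-conditioned")
        model = PHReg(t, Xk, status=e, ties=ties)
        try:
            res = model.fit(disp=False)
            b, s = np.asarray(res.params), np.asarray(res.bse)
            if not np.all(np.isfinite(b)) or np.any(np.abs(b) > 30):
                converged = False
                flags.append("monotone likelihood or non-convergence")
            beta[keep], se[keep] = b, s
            pvals[keep] = 2 * stats.norm.sf(np.abs(b / s))
            loglik = float(model.loglike(b))
        except Exception as exc:  # singular information matrix etc.
            converged = False
            flags.append(f"fit failed: {exc}")
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # infinite SE of dropped covariates
        ci_low, ci_high = np.exp(beta - z * se), np.exp(beta + z * se)
    return CoxModel(
        covariates=list(covariates),
        beta=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        loglik=loglik,
        ties=ties,
        converged=converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class ContingencyResult:
    method: str
    statistic: float
    p: float
    degenerate: bool = False


def contingency_test(table, method: str = "chi2_yates") -> ContingencyResult:
    """2x2 association test.

    ``chi2_yates``: continuity-corrected chi-square with the correction
    clipped at zero, chi2 = sum(max(0, |O-E|-0.5)^2 / E) on 1 df;
    ``chi2``: uncorrected Pearson; ``fisher``: exact two-sided by the
    point-probability rule.  A zero margin makes the test degenerate and
    returns p = 1.
    """
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2) or (T < 0).any() or not np.allclose(T, np.round(T)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    rows, cols, n = T.sum(1), T.sum(0), T.sum()
    if (rows == 0).any() or (cols == 0).any():
        return ContingencyResult(method, 0.0, 1.0, degenerate=True)
    E = np.outer(rows, cols) / n
    if method == "chi2_yates":
        stat = float((np.maximum(np.abs(T - E) - 0.5, 0.0) ** 2 / E).sum())
        return ContingencyResult(method, stat, float(stats.chi2.sf(stat, 1)))
    if method == "chi2":
        stat = float(((T - E) ** 2 / E).sum())
        return ContingencyResult(method, stat, float(stats.chi2.sf(stat, 1)))
    if method == "fisher":
        odds, p = stats.fisher_exact(T.astype(int), alternative="two-sided")
        return ContingencyResult(method, float(odds), float(p))
    raise ValueError(f"unknown method {method!r}")


def crosstab_report(table, method: str = "chi2_yates", decimals: int = 3) -> dict:
    """Report-layer rounding of a contingency test (3 decimals)."""
    res = contingency_test(table, method)
    return {
        "method": res.method,
        "statistic": round(res.statistic, decimals),
        "p": round(res.p, decimals),
        "degenerate": res.degenerate,
    }


# ---------------------------------------------------------------------------
# differential expression filter chain


def deg_select(
    tpm_normal: pd.DataFrame,
    tpm_tumor: pd.DataFrame,
    paired: bool = True,
    tpm_threshold: float = 0.5,
    alpha: float = 0.05,
    fold_change: float = 2.0,
    method: str = "ttest",
) -> pd.DataFrame:
    """Differential expression with the three-filter chain.

    Genes (rows) with median TPM above ``tpm_threshold`` across all
    libraries are tested — paired t-test (default) or paired Wilcoxon on
    log2(TPM + 1) — then Benjamini-Hochberg adjusted; a gene passes when
    adjusted p < ``alpha`` and |fold change| > ``fold_change``.
    """
    if paired and list(tpm_normal.columns) != list(tpm_tumor.columns):
        raise ValueError("paired analysis requires matched sample columns")
    if not tpm_normal.index.equals(tpm_tumor.index):
        raise ValueError("gene indexes differ between normal and tumor")
    both = pd.concat([tpm_normal, tpm_tumor], axis=1)
    med = both.median(axis=1)
    tested = med > tpm_threshold
    ln = np.log2(tpm_normal + 1.0)
    lt = np.log2(tpm_tumor + 1.0)
    log2fc = (lt.mean(axis=1) - ln.mean(axis=1)).to_numpy()
    pvals = np.full(len(med), np.nan)
    for i, g in enumerate(tpm_normal.index):
        if not tested.iloc[i]:
            continue
        a, b = lt.loc[g].to_numpy(), ln.loc[g].to_numpy()
        if np.allclose(a, b):
            pvals[i] = 1.0
        elif method == "ttest":
            pvals[i] = stats.ttest_rel(a, b).pvalue
        elif method == "wilcoxon":
            pvals[i] = stats.wilcoxon(a, b).pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    padj = np.full(len(med), np.nan)
    mask = np.isfinite(pvals)
    if mask.any():
        padj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "median_tpm": med.to_numpy(),
            "log2_fold_change": log2fc,
            "p": pvals,
            "p_adj": padj,
            "pass_tpm": tested.to_numpy(),
        },
        index=tpm_normal.index,
    )
    out["pass_padj"] = out.p_adj < alpha
    out["pass_fc"] = np.abs(out.log2_fold_change) > np.log2(fold_change)
    out["is_deg"] = out.pass_tpm & out.pass_padj & out.pass_fc
    out.attrs["n_deg"] = int(out.is_deg.sum())
    out.attrs["n_up"] = int((out.is_deg & (out.log2_fold_change > 0)).sum())
    out.attrs["n_down"] = int((out.is_deg & (out.log2_fold_change < 0)).sum())
    return out
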