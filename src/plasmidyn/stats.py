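"""Comparative statistics on normalized extinction times and outcome tables.

Three families of analyses summarize the sweeps:

* rank-based comparisons of normalized extinction-time ratios across the
  levels of an interaction parameter (Kruskal-Wallis with Dunn-Bonferroni
  follow-up; Wilcoxon signed-rank for paired two-group designs),
* contingency analyses of the increase/decrease/null outcome tables
  (chi-squared with continuity correction, pairwise exact tests between
  strata with Bonferroni adjustment), and
* logistic regression of the benefit outcome on the six interaction
  parameters treated as continuous covariates.

All tests are deterministic given their inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "rank_compare",
    "paired_rank_compare",
    "dunn_posthoc",
    "contingency_compare",
    "fisher_exact_rxc",
    "outcome_regression",
    "RegressionReport",
    "anova_partial_eta_squared",
]


@dataclass
class TestReport:
    """Result of one hypothesis test with optional pairwise follow-up."""

    test_name: str
    grouping: str
    statistic: float
    df: float | None
    p_value: float
    posthoc: pd.DataFrame | None = None
    group_descriptors: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"{self.test_name} on groups of {self.grouping!r}: "
            f"statistic={self.statistic:.4g}"
            + (f", df={self.df:g}" if self.df is not None else "")
            + f", p={self.p_value:.3g}"
        ]
        if self.group_descriptors is not None:
            lines.append(self.group_descriptors.to_string())
        if self.posthoc is not None:
            lines.append("pairwise (adjusted p):")
            lines.append(self.posthoc.to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "grouping": self.grouping,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.reset_index().to_dict(orient="records")
        if self.group_descriptors is not None:
            out["groups"] = (
                self.group_descriptors.reset_index().to_dict(orient="records")
            )
        return out


def _descriptors(groups: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n": {k: len(v) for k, v in groups.items()},
            "median": {k: float(np.median(v)) for k, v in groups.items()},
            "sd": {k: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
                   for k, v in groups.items()},
        }
    )


def dunn_posthoc(groups: dict[object, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks with Bonferroni adjustment.

    Uses the tie-corrected large-sample normal approximation; adjusted
    p-values are capped at 1.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for k in labels:
        n_k = len(groups[k])
        mean_ranks[k] = ranks[i : i + n_k].mean()
        i += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows).set_index(["group_a", "group_b"])


def rank_compare(
    records: pd.DataFrame,
    grouping: str,
    value: str = "ratio",
) -> TestReport:
    """Kruskal-Wallis test of ``value`` across the levels of ``grouping``,
    followed by Dunn-Bonferroni pairwise comparisons.

    Ratio records flagged ``excluded`` (survival in either member) are
    dropped before testing.
    """
    data = records
    if "excluded" in data.columns:
        data = data[~data["excluded"]]
    groups = {
        k: np.asarray(v, dtype=float)
        for k, v in data.groupby(grouping)[value]
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups for a k-sample rank test")
    for k, v in groups.items():
        if v.size == 0:
            raise ValueError(f"empty group {k!r}")
    arrays = list(groups.values())
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # identical samples carry no rank information; report the null
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    return TestReport(
        test_name="Kruskal-Wallis",
        grouping=grouping,
        statistic=float(stat),
        df=float(len(groups) - 1),
        p_value=float(p),
        posthoc=dunn_posthoc(groups),
        group_descriptors=_descriptors(groups),
    )


def paired_rank_compare(
    values_a: np.ndarray, values_b: np.ndarray, label: str = "paired"
) -> TestReport:
    """Wilcoxon signed-rank test with continuity correction on paired samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align one-to-one")
    if np.array_equal(a, b):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.wilcoxon(a, b, correction=True)
    groups = {"a": a, "b": b}
    return TestReport(
        test_name="Wilcoxon signed-rank",
        grouping=label,
        statistic=float(stat),
        df=None,
        p_value=float(p),
        group_descriptors=_descriptors(groups),
    )


def fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Exact conditional (hypergeometric) test for an r x c count table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed table, the
    standard two-sided convention.  Feasible for the small tables that
    arise here (margins of a few hundred, (r-1)(c-1) <= 4); raises if the
    enumeration would exceed ``max_tables``.
    """
    from scipy.special import gammaln

    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if rows.min() == 0 or cols.min() == 0:
        raise ValueError("degenerate table: a margin is zero")
    n = obs.sum()
    lgam_row = gammaln(rows + 1.0).sum()
    lgam_col = gammaln(cols + 1.0).sum()
    lgam_n = gammaln(n + 1.0)
    # hypergeometric log-probability of a table conditional on the margins
    logp_obs = float(lgam_row + lgam_col - lgam_n - gammaln(obs + 1.0).sum())

    r, c = obs.shape
    total_prob = 0.0
    count = 0

    def recurse(i, j, current, row_rem, col_rem, logfact):
        nonlocal total_prob, count
        if count > max_tables:
            raise RuntimeError("exact enumeration limit exceeded")
        if i == r - 1:
            # last row forced by column remainders
            tail = col_rem.copy()
            logp = (
                lgam_row + lgam_col - lgam_n - logfact
                - gammaln(tail + 1.0).sum()
            )
            count += 1
            if logp <= logp_obs + 1e-7:
                total_prob += math.exp(logp)
            return
        if j == c - 1:
            v = row_rem[i]
            if v > col_rem[j]:
                return
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            recurse(i + 1, 0, current, row_rem, col_rem2,
                    logfact + gammaln(v + 1.0))
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            row_rem2 = row_rem.copy()
            row_rem2[i] -= v
            recurse(i, j + 1, current, row_rem2, col_rem2,
                    logfact + gammaln(v + 1.0))

    recurse(0, 0, obs, rows.copy(), cols.copy(), 0.0)
    return min(1.0, total_prob)


def contingency_compare(
    outcome_table: pd.DataFrame, grouping: str = "stratum"
) -> TestReport:
    """Chi-squared test on an outcome-count table with exact pairwise follow-up.

    Rows are strata (e.g. values of an interaction parameter), columns
    outcome categories.  The omnibus test applies the Yates continuity
    correction (which only acts on 2x2 tables); pairwise stratum
    comparisons use the exact conditional test with Bonferroni
    adjustment.  Columns that are zero across all strata are dropped
    before testing; a table with fewer than two non-degenerate rows or
    columns raises.
    """
    table = outcome_table.loc[:, outcome_table.sum(axis=0) > 0]
    table = table.loc[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: need >= 2 informative rows and columns")
    chi2, p, dof, _ = sps.chi2_contingency(table.values, correction=True)
    strata = list(table.index)
    n_pairs = len(strata) * (len(strata) - 1) // 2
    rows = []
    for a, b in itertools.combinations(strata, 2):
        pair = table.loc[[a, b]]
        pair = pair.loc[:, pair.sum(axis=0) > 0]
        try:
            p_raw = fisher_exact_rxc(pair.values)
        except RuntimeError:
            p_raw = sps.chi2_contingency(pair.values, correction=True)[1]
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            }
        )
    return TestReport(
        test_name="chi-squared (Yates) + pairwise exact",
        grouping=grouping,
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        posthoc=pd.DataFrame(rows).set_index(["group_a", "group_b"]),
    )


@dataclass
class RegressionReport:
    """Maximum-likelihood logistic fit of a binary outcome."""

    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    llf: float
    llnull: float
    deviance_explained: float
    mcfadden_r2: float
    nagelkerke_r2: float
    n_obs: int
    converged: bool
    separation_detected: bool
    per_covariate_r2: pd.Series = field(default_factory=pd.Series)

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.p_values}
        )
        return (
            f"logistic regression, n={self.n_obs}, converged={self.converged}, "
            f"separation={self.separation_detected}\n"
            f"McFadden R2={self.mcfadden_r2:.4f}  "
            f"Nagelkerke R2={self.nagelkerke_r2:.4f}\n" + tab.to_string()
        )


def _fit_logit(endog: np.ndarray, exog: pd.DataFrame):
    import statsmodels.api as sm

    model = sm.Logit(endog, sm.add_constant(exog, has_constant="add"))
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, maxiter=200)
            return res, False
        except Exception:
            # perfect separation or failure to converge under Newton;
            # retry with a gradient method and report the separation
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            return res, True


def outcome_regression(
    cases: pd.DataFrame,
    outcome: str,
    covariates: list[str],
) -> RegressionReport:
    """Logistic regression of a binary outcome on interaction covariates.

    ``outcome`` names a boolean/0-1 column; covariates enter as
    continuous variables.  Reports per-covariate significance, the
    deviance explained relative to the intercept-only model, and both
    McFadden and Nagelkerke pseudo-R2.  Perfect separation is flagged
    explicitly (coefficients are then not interpretable).
    """
    y = np.asarray(cases[outcome], dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    X = cases[list(covariates)].astype(float)
    degenerate = [c for c in covariates if X[c].nunique() <= 1]
    if degenerate:
        raise ValueError(f"covariate(s) with no variance: {degenerate}")
    if y.min() == y.max():
        # constant outcome: null model is the fit
        k = len(covariates)
        zeros = pd.Series(0.0, index=["const"] + list(covariates))
        return RegressionReport(
            params=zeros,
            bse=zeros,
            p_values=pd.Series(1.0, index=zeros.index),
            llf=0.0,
            llnull=0.0,
            deviance_explained=0.0,
            mcfadden_r2=0.0,
            nagelkerke_r2=0.0,
            n_obs=len(y),
            converged=True,
            separation_detected=False,
            per_covariate_r2=pd.Series(0.0, index=list(covariates)),
        )
    res, separation = _fit_logit(y, X)
    n = len(y)
    llf, llnull = float(res.llf), float(res.llnull)
    mcfadden = 1.0 - llf / llnull
    cox_snell = 1.0 - math.exp((2.0 / n) * (llnull - llf))
    nagelkerke = cox_snell / (1.0 - math.exp(2.0 * llnull / n))
    per_cov = {}
    for c in covariates:
        res_c, _ = _fit_logit(y, X[[c]])
        per_cov[c] = 1.0 - float(res_c.llf) / llnull
    # flag separation also when fitted probabilities are saturated
    fitted = res.predict()
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        separation = True
    return RegressionReport(
        params=res.params,
        bse=res.bse,
        p_values=res.pvalues,
        llf=llf,
        llnull=llnull,
        deviance_explained=2.0 * (llf - llnull),
        mcfadden_r2=mcfadden,
        nagelkerke_r2=nagelkerke,
        n_obs=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_detected=separation,
        per_covariate_r2=pd.Series(per_cov),
    )


def anova_partial_eta_squared(
    frame: pd.DataFrame,
    response: str = "toe_X",
    log_response: bool = True,
) -> pd.DataFrame:
    """Factorial ANOVA of single-plasmid extinction times with partial eta^2.

    Fits the full factorial model of fitness, log10 conjugation rate and
    log10 loss rate as continuous predictors (3 main effects, 3 two-way
    and 1 three-way interaction, 7 model df) on log10 extinction time,
    and reports each term's partial eta^2 = SS_term/(SS_term + SS_resid).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = pd.DataFrame(
        {
            "y": np.log10(frame[response].astype(float))
            if log_response
            else frame[response].astype(float),
            "omega": frame["omega_X"].astype(float),
            "log_gamma": np.log10(frame["gamma_X"].astype(float)),
            "log_delta": np.log10(frame["delta"].astype(float)),
        }
    )
    fit = smf.ols("y ~ omega * log_gamma * log_delta", data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_resid = anova.loc["Residual", "sum_sq"]
    anova["partial_eta_sq"] = anova["sum_sq"] / (anova["sum_sq"] + ss_resid)
    anova.loc["Residual", "partial_eta_sq"] = np.nan
    return anova
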