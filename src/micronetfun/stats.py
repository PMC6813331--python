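"""Regression and ANOVA surface for the diversity–multifunctionality analysis.

* ``regress`` — simple OLS of one z-scored variable on another: the
  standardized slope (SES) equals the Pearson correlation, with its standard
  error, two-sided P and R².
* ``detrended_regress`` — the same after residualizing both variables on a
  covariate (typically richness), isolating the association not explained by
  the covariate.
* ``sequential_anova`` — Type-I (sequential) decomposition of a response on
  an ordered list of community characteristics, with block first, an
  optional sterile-vs-rest contrast, and the treatment factor last; each
  term's share of the total sum of squares (%SS) plus its F-test.
* ``treatment_anova_tukey`` — one-way (plus block) ANOVA across the gradient
  with Tukey HSD pairwise tests and a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class RegressionResult:
    """Standardized simple-regression summary."""

    SES: float
    SE: float
    P: float
    R2: float
    n: int
    degenerate: bool = False

    def summary(self) -> str:
        if self.degenerate:
            return "Regression degenerate: a variable has (near-)zero variance"
        stars = ("***" if self.P < 0.001 else "**" if self.P < 0.01
                 else "*" if self.P < 0.05 else "")
        return (f"SES = {self.SES:.3f} (SE {self.SE:.3f}), "
                f"P = {self.P:.4g}{stars}, R2 = {self.R2:.3f}, n = {self.n}")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input")
    return (v - v.mean()) / sd


def regress(y, x) -> RegressionResult:
    """OLS of z-scored y on z-scored x: SES (= Pearson r), SE, P, R²."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("y and x must have equal length")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    yz, xz = _zscore(y), _zscore(x)
    fit = sm.OLS(yz, sm.add_constant(xz)).fit()
    return RegressionResult(
        SES=float(fit.params[1]),
        SE=float(fit.bse[1]),
        P=float(fit.pvalues[1]),
        R2=float(fit.rsquared),
        n=n,
    )


def detrended_regress(y, x, covariate) -> RegressionResult:
    """Regression of y on x after residualizing both on a covariate.

    If x is (nearly) an exact linear function of the covariate, its residual
    carries no information; the result is flagged degenerate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    C = sm.add_constant(cov)
    ry = sm.OLS(y, C).fit().resid
    rx = sm.OLS(x, C).fit().resid
    if rx.std(ddof=1) < 1e-8 * max(x.std(ddof=1), 1e-30) or rx.std(ddof=1) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, len(y),
                                degenerate=True)
    return regress(ry, rx)


@dataclass
class AnovaTable:
    """Sequential (Type-I) ANOVA with %SS per term."""

    table: pd.DataFrame  # columns: df, sum_sq, pct_ss, F, P

    @property
    def pct_ss(self) -> pd.Series:
        return self.table["pct_ss"]

    def summary(self) -> str:
        lines = ["Sequential (Type-I) ANOVA", "=" * 56,
                 f"{'term':<28s}{'df':>4s}{'%SS':>9s}{'P':>12s}"]
        for term, row in self.table.iterrows():
            p = "" if np.isnan(row["P"]) else f"{row['P']:.4g}"
            lines.append(f"{term:<28s}{int(row['df']):>4d}{row['pct_ss']:>9.2f}"
                         f"{p:>12s}")
        return "\n".join(lines)


def _clean_name(name: str) -> str:
    out = "".join(ch if ch.isalnum() else "_" for ch in str(name))
    return ("t_" + out) if not out or not out[0].isalpha() else out


def sequential_anova(
    y,
    terms: pd.DataFrame,
    treatment=None,
    block=None,
    sterile_contrast: bool = False,
    sterile_label: str = "sterile",
) -> AnovaTable:
    """Type-I decomposition of y on ordered community characteristics.

    Fitting order: block (factor, first), then each column of ``terms`` in
    its given order, then optionally a sterile-vs-rest contrast, then the
    treatment factor.  %SS is each term's sequential sum of squares as a
    percent of the total; the table includes block and residual so the
    shares sum to 100.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    groups: list[tuple[str, np.ndarray]] = []
    if block is not None:
        groups.append(("block", _dummies(block)))
    for col in terms.columns:
        v = terms[col].to_numpy(dtype=float)[:, None]
        groups.append((str(col), v))
    if treatment is not None:
        tr = np.asarray(treatment).astype(str)
        if sterile_contrast:
            groups.append(
                ("sterile_vs_rest", (tr == sterile_label).astype(float)[:, None]))
        groups.append(("treatment", _dummies(tr)))
    if not groups:
        raise ValueError("no model terms")
    # sequential decomposition by nested OLS fits, in the given order
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("constant response")
    X = np.ones((n, 1))
    rss_prev, rank_prev = ss_total, 1
    rows = []
    for name, cols in groups:
        X = np.hstack([X, cols])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        df_term = rank - rank_prev
        if df_term == 0:
            warnings.warn(f"term {name!r} adds no rank (collinear design)")
        rows.append({"term": name, "df": df_term, "sum_sq": rss_prev - rss})
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    ms_resid = rss_prev / df_resid if df_resid > 0 else np.nan
    out_rows = []
    for r in rows:
        if r["df"] > 0 and df_resid > 0 and ms_resid > 0:
            F = (r["sum_sq"] / r["df"]) / ms_resid
            P = float(sps.f.sf(F, r["df"], df_resid))
        else:
            F, P = np.nan, np.nan
        out_rows.append(
            {"df": r["df"], "sum_sq": r["sum_sq"],
             "pct_ss": 100.0 * r["sum_sq"] / ss_total, "F": F, "P": P})
    out = pd.DataFrame(out_rows, index=[r["term"] for r in rows])
    out.loc["residual"] = [df_resid, rss_prev, 100.0 * rss_prev / ss_total,
                           np.nan, np.nan]
    return AnovaTable(out)


def _dummies(values) -> np.ndarray:
    """Treatment-coded (first level dropped) indicator matrix."""
    s = pd.Series(np.asarray(values).astype(str))
    return pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)


def _letter_display(levels, means, ns_matrix: pd.DataFrame) -> dict:
    """Compact letter display: levels sorted by descending mean; maximal
    contiguous runs of mutually non-different levels share a letter."""
    order = list(pd.Series(means, index=levels).sort_values(ascending=False).index)
    k = len(order)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            ns_matrix.loc[order[a], order[b]]
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    # absorb runs contained in an earlier, longer run
    maximal = [r for r in runs if not any(
        o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    letters = {lv: "" for lv in order}
    for idx, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + idx)
        for t in range(i, j + 1):
            letters[order[t]] += ch
    return letters


@dataclass
class TukeyResult:
    """Treatment ANOVA with Tukey HSD letters."""

    anova: AnovaTable
    group_means: pd.Series
    group_se: pd.Series
    letters: dict
    pairwise: pd.DataFrame

    def summary(self) -> str:
        lines = ["Treatment ANOVA + Tukey HSD", "=" * 48,
                 f"{'level':<12s}{'mean':>10s}{'se':>10s}  letters"]
        for lv in self.group_means.index:
            lines.append(
                f"{lv:<12s}{self.group_means[lv]:>10.3f}"
                f"{self.group_se[lv]:>10.3f}  {self.letters[lv]}"
            )
        return "\n".join(lines)


def treatment_anova_tukey(y, treatment, block=None, alpha: float = 0.05) -> TukeyResult:
    """One-way (plus optional block) ANOVA with Tukey HSD letters at 0.05."""
    y = np.asarray(y, dtype=float)
    tr = pd.Series(np.asarray(treatment).astype(str), name="treatment")
    counts = tr.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"singleton treatment level(s): {counts.index[counts < 2].tolist()}")
    if counts.size < 2:
        raise ValueError("need at least two treatment levels")
    aov = sequential_anova(y, pd.DataFrame(index=tr.index), treatment=tr,
                           block=block)
    hsd = pairwise_tukeyhsd(y, tr.to_numpy(), alpha=alpha)
    pw = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    levels = list(hsd.groupsunique)
    ns = pd.DataFrame(True, index=levels, columns=levels)
    for _, row in pw.iterrows():
        ns.loc[row["group1"], row["group2"]] = not row["reject"]
        ns.loc[row["group2"], row["group1"]] = not row["reject"]
    means = pd.Series({lv: y[tr.to_numpy() == lv].mean() for lv in levels})
    se = pd.Series({
        lv: y[tr.to_numpy() == lv].std(ddof=1) / np.sqrt((tr == lv).sum())
        for lv in levels})
    letters = _letter_display(levels, means, ns)
    order = means.sort_values(ascending=False).index
    return TukeyResult(aov, means[order], se[order], letters, pw)


__all__ = [
    "RegressionResult",
    "AnovaTable",
    "TukeyResult",
    "regress",
    "detrended_regress",
    "sequential_anova",
    "treatment_anova_tukey",
]
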