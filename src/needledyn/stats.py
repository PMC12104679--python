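"""Statistical battery: mixed repeated-measures ANOVA, Bonferroni pairwise
t-tests with compact letter displays, Kruskal-Wallis / Mann-Whitney with
Bonferroni, stepwise multiple regression with collinearity and autocorrelation
diagnostics, and correlation-matrix PCA.

The repeated-measures decomposition is the classical univariate mixed
within-between layout on balanced complete designs: subjects nested in the
between factor form the error stratum for between effects; each within effect
is tested against its interaction with subjects-within-groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMAnovaTable",
    "GroupComparisonResult",
    "StepwiseModel",
    "PCAResult",
    "UnbalancedDesignError",
    "rm_anova",
    "pairwise_t_bonferroni",
    "compact_letter_display",
    "kw_mw_battery",
    "stepwise_regression",
    "durbin_watson",
    "pca",
]


class UnbalancedDesignError(ValueError):
    """Raised when the repeated-measures design has missing or unequal cells."""


@dataclass
class RMAnovaTable:
    """Effect rows (SS, df, MS, F, p) plus their error strata."""

    table: pd.DataFrame

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def _dev_ss(means: np.ndarray, weight: float) -> float:
    return float(weight * np.sum(means**2))


def _gg_epsilon(df, dv, between, subject, cell_factors) -> float:
    """Greenhouse-Geisser epsilon for one within stratum.

    Computed from the pooled within-group covariance of the subject x cell
    means, double-centered; epsilon = (sum lambda)^2 / (k-1) / sum(lambda^2),
    clamped to [1/(k-1), 1].
    """
    wide = df.pivot_table(index=subject, columns=cell_factors, values=dv)
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    centered = wide - wide.groupby(groups).transform("mean")
    k = wide.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(centered.to_numpy(), rowvar=False)
    J = np.eye(k) - np.ones((k, k)) / k
    Sc = J @ S @ J
    lam = np.linalg.eigvalsh(Sc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float((lam**2).sum())
    if denom <= 0:
        return 1.0
    eps = float(lam.sum() ** 2 / denom)
    return min(1.0, max(1.0 / (k - 1), eps))


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "treatment",
    within: Sequence[str] = ("day",),
    subject: str = "subject",
    gg_correction: bool = False,
) -> RMAnovaTable:
    """Univariate mixed ANOVA with one between factor and 1-2 within factors.

    Requires a balanced complete design: every subject appears in exactly one
    between-group and contributes exactly one observation per within-cell, and
    groups have equal sizes.  Missing cells raise
    :class:`UnbalancedDesignError` naming the offenders.

    With ``gg_correction`` the table gains ``eps`` and ``p_gg`` columns for the
    within-subject effects: Greenhouse-Geisser epsilon shrinks both degrees of
    freedom before the p-value is evaluated (no correction is the default).
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports exactly 1 or 2 within factors")
    cols = [subject, between, *within, dv]
    df = data[cols].copy()
    if df[dv].isna().any():
        raise UnbalancedDesignError("missing response values present")

    # design checks
    grp = df.groupby(subject)[between].nunique()
    if (grp > 1).any():
        raise UnbalancedDesignError(
            f"subjects in multiple groups: {list(grp[grp > 1].index)}"
        )
    counts = df.groupby([subject, *within]).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise UnbalancedDesignError(f"duplicated/missing subject x within cells: {bad}")
    levels = {f: sorted(df[f].unique()) for f in within}
    full = df.groupby(subject).size()
    expected = int(np.prod([len(levels[f]) for f in within]))
    if (full != expected).any():
        bad = full[full != expected].index.tolist()[:5]
        raise UnbalancedDesignError(f"subjects with incomplete within cells: {bad}")
    group_sizes = df.drop_duplicates(subject).groupby(between).size()
    if group_sizes.nunique() != 1:
        raise UnbalancedDesignError(f"unequal group sizes: {group_sizes.to_dict()}")

    a = df[between].nunique()
    n = int(group_sizes.iloc[0])
    gm = df[dv].mean()
    dvv = df[dv] - gm

    def marg(*factors):
        return df.assign(_d=dvv).groupby(list(factors), sort=True)["_d"].mean()

    N = len(df)
    ss_total = float((dvv**2).sum())
    w_levels = [len(levels[f]) for f in within]
    cells_per_subject = int(np.prod(w_levels))

    m_subj = marg(subject)
    m_T = marg(between)
    ss_between_subj = _dev_ss(m_subj.to_numpy(), cells_per_subject)
    ss_T = _dev_ss(m_T.to_numpy(), n * cells_per_subject)
    ss_subjT = ss_between_subj - ss_T

    rows = [
        {"effect": between, "SS": ss_T, "df": a - 1, "stratum": "subject"},
        {"effect": f"subject({between})", "SS": ss_subjT, "df": a * (n - 1),
         "stratum": "subject", "is_error": True},
    ]

    if len(within) == 1:
        w = within[0]
        d = w_levels[0]
        m_w = marg(w)
        m_aw = marg(between, w)
        ss_W = _dev_ss(m_w.to_numpy(), a * n)
        dev_aw = (
            m_aw
            - m_T.reindex(m_aw.index.get_level_values(0)).to_numpy()
            - m_w.reindex(m_aw.index.get_level_values(1)).to_numpy()
        )
        ss_WT = _dev_ss(dev_aw.to_numpy(), n)
        ss_err_W = ss_total - ss_between_subj - ss_W - ss_WT
        rows += [
            {"effect": w, "SS": ss_W, "df": d - 1, "stratum": w},
            {"effect": f"{w}:{between}", "SS": ss_WT, "df": (a - 1) * (d - 1),
             "stratum": w},
            {"effect": f"{w}:subject({between})", "SS": ss_err_W,
             "df": a * (n - 1) * (d - 1), "stratum": w, "is_error": True},
        ]
    else:
        w1, w2 = within
        d, t = w_levels
        m_w1, m_w2 = marg(w1), marg(w2)
        m_aw1, m_aw2 = marg(between, w1), marg(between, w2)
        m_w1w2 = marg(w1, w2)
        m_aw1w2 = marg(between, w1, w2)
        m_s_w1 = marg(subject, w1)
        m_s_w2 = marg(subject, w2)

        def dev2(m_ab, m_a, m_b):
            ia = m_ab.index.get_level_values(0)
            ib = m_ab.index.get_level_values(1)
            return m_ab - m_a.reindex(ia).to_numpy() - m_b.reindex(ib).to_numpy()

        ss_W1 = _dev_ss(m_w1.to_numpy(), a * n * t)
        ss_W1T = _dev_ss(dev2(m_aw1, m_T, m_w1).to_numpy(), n * t)
        ss_W2 = _dev_ss(m_w2.to_numpy(), a * n * d)
        ss_W2T = _dev_ss(dev2(m_aw2, m_T, m_w2).to_numpy(), n * d)
        ss_W1W2 = _dev_ss(dev2(m_w1w2, m_w1, m_w2).to_numpy(), a * n)

        # three-way deviation: cell - all two-way margins + all mains - gm
        ia = m_aw1w2.index.get_level_values(0)
        i1 = m_aw1w2.index.get_level_values(1)
        i2 = m_aw1w2.index.get_level_values(2)
        dev3 = (
            m_aw1w2
            - m_aw1.reindex(list(zip(ia, i1))).to_numpy()
            - m_aw2.reindex(list(zip(ia, i2))).to_numpy()
            - m_w1w2.reindex(list(zip(i1, i2))).to_numpy()
            + m_T.reindex(ia).to_numpy()
            + m_w1.reindex(i1).to_numpy()
            + m_w2.reindex(i2).to_numpy()
        )
        ss_W1W2T = _dev_ss(dev3.to_numpy(), n)

        # error strata: within-factor x subject(group) interactions
        subj_group = df.drop_duplicates(subject).set_index(subject)[between]
        isg1 = m_s_w1.index.get_level_values(0)
        iw1 = m_s_w1.index.get_level_values(1)
        dev_e1 = (
            m_s_w1
            - m_subj.reindex(isg1).to_numpy()
            - m_aw1.reindex(list(zip(subj_group.reindex(isg1), iw1))).to_numpy()
            + m_T.reindex(subj_group.reindex(isg1)).to_numpy()
        )
        ss_err_W1 = _dev_ss(dev_e1.to_numpy(), t)
        isg2 = m_s_w2.index.get_level_values(0)
        iw2 = m_s_w2.index.get_level_values(1)
        dev_e2 = (
            m_s_w2
            - m_subj.reindex(isg2).to_numpy()
            - m_aw2.reindex(list(zip(subj_group.reindex(isg2), iw2))).to_numpy()
            + m_T.reindex(subj_group.reindex(isg2)).to_numpy()
        )
        ss_err_W2 = _dev_ss(dev_e2.to_numpy(), d)
        explained = (
            ss_between_subj + ss_W1 + ss_W1T + ss_err_W1 + ss_W2 + ss_W2T
            + ss_err_W2 + ss_W1W2 + ss_W1W2T
        )
        ss_err_W1W2 = ss_total - explained
        rows += [
            {"effect": w1, "SS": ss_W1, "df": d - 1, "stratum": w1},
            {"effect": f"{w1}:{between}", "SS": ss_W1T, "df": (a - 1) * (d - 1),
             "stratum": w1},
            {"effect": f"{w1}:subject({between})", "SS": ss_err_W1,
             "df": a * (n - 1) * (d - 1), "stratum": w1, "is_error": True},
            {"effect": w2, "SS": ss_W2, "df": t - 1, "stratum": w2},
            {"effect": f"{w2}:{between}", "SS": ss_W2T, "df": (a - 1) * (t - 1),
             "stratum": w2},
            {"effect": f"{w2}:subject({between})", "SS": ss_err_W2,
             "df": a * (n - 1) * (t - 1), "stratum": w2, "is_error": True},
            {"effect": f"{w1}:{w2}", "SS": ss_W1W2, "df": (d - 1) * (t - 1),
             "stratum": f"{w1}:{w2}"},
            {"effect": f"{w1}:{w2}:{between}", "SS": ss_W1W2T,
             "df": (a - 1) * (d - 1) * (t - 1), "stratum": f"{w1}:{w2}"},
            {"effect": f"{w1}:{w2}:subject({between})", "SS": ss_err_W1W2,
             "df": a * (n - 1) * (d - 1) * (t - 1), "stratum": f"{w1}:{w2}",
             "is_error": True},
        ]

    tab = pd.DataFrame(rows)
    tab["SS"] = tab["SS"].clip(lower=0.0)  # guard tiny negative rounding
    tab["is_error"] = [bool(r.get("is_error", False)) for r in rows]
    tab["MS"] = np.where(tab["df"] > 0, tab["SS"] / tab["df"].replace(0, np.nan), np.nan)
    err_ms = tab[tab.is_error].set_index("stratum")["MS"]
    F, p = [], []
    for _, r in tab.iterrows():
        if r.is_error:
            F.append(np.nan)
            p.append(np.nan)
            continue
        ems = err_ms.get(r.stratum, np.nan)
        edf = tab[(tab.stratum == r.stratum) & tab.is_error]["df"]
        edf = int(edf.iloc[0]) if len(edf) else 0
        if not np.isfinite(ems) or ems <= 0 or edf <= 0 or not np.isfinite(r.MS):
            F.append(np.nan)
            p.append(np.nan)
        else:
            f = r.MS / ems
            F.append(f)
            p.append(float(sps.f.sf(f, r.df, edf)))
    tab["F"] = F
    tab["p"] = p
    if gg_correction:
        eps_by_stratum = {"subject": 1.0}
        for w in within:
            eps_by_stratum[w] = _gg_epsilon(df, dv, between, subject, [w])
        if len(within) == 2:
            eps_by_stratum[f"{within[0]}:{within[1]}"] = _gg_epsilon(
                df, dv, between, subject, list(within)
            )
        tab["eps"] = tab["stratum"].map(eps_by_stratum)
        p_gg = []
        for r in tab.itertuples():
            if r.is_error or not np.isfinite(r.F):
                p_gg.append(np.nan)
                continue
            edf = tab[(tab.stratum == r.stratum) & tab.is_error]["df"].iloc[0]
            p_gg.append(float(sps.f.sf(r.F, r.eps * r.df, r.eps * edf)))
        tab["p_gg"] = p_gg
    return RMAnovaTable(table=tab)


@dataclass
class GroupComparisonResult:
    """One family of pairwise tests with Bonferroni adjustment and letters."""

    test: str
    comparisons: pd.DataFrame  # group_a, group_b, statistic, df, p_raw, p_adj
    letters: dict = field(default_factory=dict)
    omnibus: dict = field(default_factory=dict)
    alpha: float = 0.05


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def pairwise_t_bonferroni(
    data: pd.DataFrame,
    dv: str = "value",
    group: str = "group",
    subject: str | None = None,
    paired: bool = False,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """All pairwise t-tests over ``group`` levels with Bonferroni correction.

    ``paired=True`` aligns observations on ``subject`` (across-days comparisons
    within a treatment reuse the same subjects); unpaired comparisons use
    two-sample t-tests.  Groups with n < 2 are excluded with a warning.
    """
    groups = {}
    for g, sub in data.groupby(group, sort=True):
        if len(sub) < 2:
            warnings.warn(f"group {g!r} has n < 2: excluded from pairwise tests")
            continue
        groups[g] = sub
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        if paired:
            if subject is None:
                raise ValueError("paired tests require a subject column")
            a = groups[ga].set_index(subject)[dv]
            b = groups[gb].set_index(subject)[dv]
            common = a.index.intersection(b.index)
            stat, praw = sps.ttest_rel(a.loc[common], b.loc[common])
            dof = len(common) - 1
        else:
            stat, praw = sps.ttest_ind(groups[ga][dv], groups[gb][dv])
            dof = len(groups[ga]) + len(groups[gb]) - 2
        if np.isnan(praw):  # identical constant groups
            stat, praw = 0.0, 1.0
        rows.append(
            {"group_a": ga, "group_b": gb, "statistic": float(stat), "df": dof,
             "p_raw": float(praw), "p_adj": _bonferroni(praw, m)}
        )
    comp = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "df",
                                       "p_raw", "p_adj"])
    sig = {(r.group_a, r.group_b): r.p_adj < alpha for r in comp.itertuples()}
    letters = compact_letter_display(names, sig)
    return GroupComparisonResult(
        test="paired t (Bonferroni)" if paired else "t (Bonferroni)",
        comparisons=comp, letters=letters, alpha=alpha,
    )


def compact_letter_display(
    groups: Sequence, significant: Mapping[tuple, bool]
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups share at least one letter iff their pairwise comparison is
    non-significant.  The letter count is not guaranteed minimal.
    """
    groups = list(groups)
    columns: list[set] = [set(groups)]
    for (ga, gb), sig in sorted(significant.items(), key=lambda kv: str(kv[0])):
        if not sig:
            continue
        for col in [c for c in columns if ga in c and gb in c]:
            columns.remove(col)
            columns.extend([col - {ga}, col - {gb}])
        columns = [c for c in columns if c]
        # absorb: drop columns contained in another
        columns = [
            c for i, c in enumerate(columns)
            if not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, col in enumerate(sorted(columns, key=lambda c: sorted(str(g) for g in c))):
        token = alphabet[idx] if idx < len(alphabet) else f"l{idx}"
        for g in col:
            letters[g] += token
    return letters


def kw_mw_battery(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    exact_max_n: int = 12,
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus; if significant, all pairwise Mann-Whitney tests
    with Bonferroni correction.

    Exact Mann-Whitney null distribution is used when the combined sample size
    is at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    names = [g for g in groups]
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = sps.kruskal(*arrays.values())
    omnibus = {"H": float(H), "p": float(p_kw)}
    rows = []
    letters = {g: "a" for g in names}
    if p_kw < alpha:
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for ga, gb in pairs:
            x, y = arrays[ga], arrays[gb]
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if (len(x) + len(y) <= exact_max_n and not ties) else "asymptotic"
            U, praw = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append(
                {"group_a": ga, "group_b": gb, "statistic": float(U), "df": np.nan,
                 "p_raw": float(praw), "p_adj": _bonferroni(praw, m)}
            )
        comp = pd.DataFrame(rows)
        sig = {(r.group_a, r.group_b): r.p_adj < alpha for r in comp.itertuples()}
        letters = compact_letter_display(names, sig)
    else:
        comp = pd.DataFrame(
            columns=["group_a", "group_b", "statistic", "df", "p_raw", "p_adj"]
        )
    return GroupComparisonResult(
        test="Kruskal-Wallis + Mann-Whitney (Bonferroni)",
        comparisons=comp, letters=letters, omnibus=omnibus, alpha=alpha,
    )


@dataclass
class StepwiseModel:
    """Stepwise regression result with the usual reporting diagnostics."""

    predictors: list  # in entry order
    coefficients: dict  # predictor -> unstandardized beta
    intercept: float
    std_beta: dict = field(default_factory=dict)
    r2: float = np.nan
    adj_r2: float = np.nan
    f_change: float = np.nan
    f_change_p: float = np.nan
    pvalues: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)
    tolerance: dict = field(default_factory=dict)
    vif: dict = field(default_factory=dict)
    durbin_watson: float = np.nan
    n: int = 0

    @classmethod
    def from_coefficients(cls, intercept: float, coefficients: Mapping[str, float]):
        """Build a model shell from published coefficients (no data refit)."""
        return cls(
            predictors=list(coefficients),
            coefficients=dict(coefficients),
            intercept=float(intercept),
        )

    def linear_predictor(self, x: Mapping[str, float]) -> float:
        """Evaluate intercept + sum(coef * x) at a predictor mapping."""
        return float(
            self.intercept
            + sum(self.coefficients[p] * float(x.get(p, 0.0)) for p in self.predictors)
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(
            self.intercept
            + sum(self.coefficients[p] * X[p].to_numpy(dtype=float) for p in self.predictors)
        )


def _ols(y: np.ndarray, X: np.ndarray):
    """Plain OLS with intercept: returns beta, residuals, rss, se, tstats, pvals."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    dof = n - A.shape[1]
    if dof <= 0:
        return beta, resid, rss, None, None, None
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tstats), dof)
    return beta, resid, rss, se, tstats, pvals


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic on residuals in supplied (time) order."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("Durbin-Watson needs at least two residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all-zero residuals: Durbin-Watson undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def _tolerance(Xcand: np.ndarray, Xin: np.ndarray) -> float:
    """1 - R^2 of the candidate column regressed on the entered columns."""
    if Xin.size == 0:
        return 1.0
    y = Xcand - Xcand.mean()
    tss = float(y @ y)
    if tss == 0:
        return 0.0
    _, resid, rss, *_ = _ols(Xcand, Xin)
    return max(0.0, min(1.0, rss / tss))


def stepwise_regression(
    y: Sequence[float],
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    tol_min: float = 1e-8,
) -> StepwiseModel:
    """Forward stepwise selection with backward elimination on partial-F p-values.

    At each step the not-yet-entered candidate with the smallest partial-F
    p-value enters if it beats ``entry_p``; entered predictors whose p-value
    rises above ``removal_p`` are then removed (worst first).  Candidates that
    are (near-)collinear with the entered set are skipped with a warning.
    Diagnostics follow the standard reporting layout: R-squared, adjusted
    R-squared, F-change of the final entry, per-predictor p, tolerance,
    VIF = 1/tolerance, Durbin-Watson on residuals in the supplied row order,
    and standardized betas from a refit on z-scored data.
    """
    yv = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    X = {c: candidates[c].to_numpy(dtype=float) for c in names}
    n = len(yv)
    if n <= len(names) + 1:
        raise ValueError("need n > number of candidates + 1")
    for c in names:
        if np.ptp(X[c]) == 0:
            raise ValueError(f"candidate {c!r} is constant")

    tss0 = float(((yv - yv.mean()) ** 2).sum())
    entered: list[str] = []
    f_change, f_change_p = np.nan, np.nan
    changed = True
    iterations = 0
    while changed and iterations < 4 * len(names) + 4:  # guard against cycling
        iterations += 1
        changed = False
        # perfect fit: remaining candidate p-values are numerical noise
        Xcur = np.column_stack([X[c] for c in entered]) if entered else np.empty((n, 0))
        _, _, rss_cur, *_ = _ols(yv, Xcur)
        if tss0 > 0 and rss_cur <= 1e-12 * tss0:
            break
        # forward step
        best = None
        Xin = np.column_stack([X[c] for c in entered]) if entered else np.empty((n, 0))
        for c in names:
            if c in entered:
                continue
            tol = _tolerance(X[c], Xin)
            if tol < tol_min:
                warnings.warn(f"candidate {c!r} skipped: tolerance ~ 0 (collinear)")
                continue
            Xtry = np.column_stack([Xin, X[c]])
            _, _, rss_full, se, tstats, pvals = _ols(yv, Xtry)
            if pvals is None:
                continue
            p_cand = float(pvals[-1])
            if best is None or p_cand < best[1]:
                _, _, rss_red, *_ = _ols(yv, Xin)
                dof = n - Xtry.shape[1] - 1
                fch = (rss_red - rss_full) / (rss_full / dof) if rss_full > 0 else np.inf
                best = (c, p_cand, fch)
        if best is not None and best[1] < entry_p:
            entered.append(best[0])
            f_change = float(best[2])
            dof = n - len(entered) - 1
            f_change_p = float(sps.f.sf(f_change, 1, dof)) if np.isfinite(f_change) else 0.0
            changed = True
        # backward step
        while len(entered) > 0:
            Xin = np.column_stack([X[c] for c in entered])
            _, _, _, se, tstats, pvals = _ols(yv, Xin)
            pv = dict(zip(entered, pvals[1:]))
            worst = max(pv, key=pv.get)
            if pv[worst] > removal_p:
                entered.remove(worst)
                changed = True
            else:
                break

    model = StepwiseModel(predictors=list(entered), coefficients={}, intercept=np.nan, n=n)
    Xin = np.column_stack([X[c] for c in entered]) if entered else np.empty((n, 0))
    beta, resid, rss, se, tstats, pvals = _ols(yv, Xin)
    tss = float(((yv - yv.mean()) ** 2).sum())
    model.intercept = float(beta[0])
    model.coefficients = {c: float(b) for c, b in zip(entered, beta[1:])}
    model.r2 = 1.0 - rss / tss if tss > 0 else np.nan
    k = len(entered)
    if n - k - 1 > 0 and tss > 0:
        model.adj_r2 = 1.0 - (1.0 - model.r2) * (n - 1) / (n - k - 1)
    model.f_change = f_change
    model.f_change_p = f_change_p
    if pvals is not None:
        model.pvalues = {c: float(p) for c, p in zip(entered, pvals[1:])}
        model.std_errors = {c: float(e) for c, e in zip(entered, se[1:])}
    for i, c in enumerate(entered):
        others = np.column_stack(
            [X[o] for o in entered if o != c]
        ) if k > 1 else np.empty((n, 0))
        tol = _tolerance(X[c], others)
        model.tolerance[c] = tol
        model.vif[c] = 1.0 / tol if tol > 0 else np.inf
    if np.any(resid != 0):
        model.durbin_watson = durbin_watson(resid)
    # standardized betas: refit on z-scored y and X
    if entered and np.std(yv) > 0:
        yz = (yv - yv.mean()) / yv.std(ddof=1)
        Xz = np.column_stack(
            [(X[c] - X[c].mean()) / X[c].std(ddof=1) for c in entered]
        )
        bz, *_ = _ols(yz, Xz)
        model.std_beta = {c: float(b) for c, b in zip(entered, bz[1:])}
    return model


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_vars, n_components), columns orthonormal
    scores: np.ndarray  # (n_obs, n_components)
    proportions: np.ndarray
    columns: list = field(default_factory=list)

    @property
    def cumulative_pc12(self) -> float:
        return float(self.proportions[: 2].sum())


def pca(X, standardize: bool = True, columns: Sequence[str] | None = None) -> PCAResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    Zero-variance columns are dropped with a warning.  Loading signs are fixed
    so each component's largest-magnitude loading is positive.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        columns = list(columns) if columns is not None else [f"v{i}" for i in range(M.shape[1])]
    if M.shape[0] < 3 or M.shape[1] < 2:
        raise ValueError("PCA needs at least 3 observations and 2 variables")
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"zero-variance columns dropped from PCA: {dropped}")
        M = M[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
        sd = sd[keep]
    Z = M - M.mean(axis=0)
    if standardize:
        Z = Z / sd
    C = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    proportions = evals / evals.sum() if evals.sum() > 0 else evals
    return PCAResult(
        loadings=evecs, scores=Z @ evecs, proportions=proportions, columns=columns
    )
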