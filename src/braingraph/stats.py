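"""Covariate-adjusted group statistics on AUC network metrics.

The inferential core is an ANCOVA-style omnibus test: for each metric, a
linear model with nuisance covariates (age, gender, mean FD) is compared to
the same model plus group indicators by an incremental F-test. Benjamini-
Hochberg FDR is applied within metric families (the 7 global AUC metrics as
one family; each nodal metric type corrected across its nodes). Pairwise
post-hoc contrasts — the group-indicator t in a two-group covariate-adjusted
model — are run only for metrics surviving the omnibus gate, then
FDR-corrected as their own family. Partial correlations between surviving
metrics and clinical variables remove the same covariates.

The module is organised as a model/results pair: build a
:class:`GroupComparison` from a subject metric table, call ``fit()``, and
read the omnibus/post-hoc tables and summary off the returned
:class:`GroupComparisonResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

DEFAULT_COVARIATES = ("age", "gender", "mean_fd")


def encode_gender(values) -> np.ndarray:
    """Deterministic 0/1 coding of a two-level label (alphabetical order)."""
    s = pd.Series(values)
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)
    levels = sorted(s.astype(str).unique())
    if len(levels) > 2:
        raise InputError(f"gender must have at most 2 levels, got {levels}")
    mapping = {lv: i for i, lv in enumerate(levels)}
    return s.astype(str).map(mapping).to_numpy(dtype=float)


def _covariate_matrix(covariates) -> np.ndarray:
    """Numeric covariate columns (gender label-encoded), no intercept."""
    if covariates is None:
        return np.empty((0, 0))
    if isinstance(covariates, pd.DataFrame):
        cols = []
        for c in covariates.columns:
            col = (encode_gender(covariates[c]) if c == "gender"
                   else covariates[c].to_numpy(dtype=float))
            cols.append(col)
        return np.column_stack(cols) if cols else np.empty((0, 0))
    x = np.asarray(covariates, dtype=float)
    return x if x.ndim == 2 else x[:, None]


def _check_design(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify columns that do not add rank
        keep, rank = [], 0
        bad = []
        for j in range(x.shape[1]):
            r = np.linalg.matrix_rank(x[:, keep + [j]])
            if r > rank:
                keep.append(j)
                rank = r
            else:
                bad.append(names[j])
        raise InputError(f"design is rank deficient; collinear columns: {bad}")


def ancova_group_test(metric, group, covariates=None) -> tuple[float, float]:
    """Incremental F-test of the group factor, adjusting for covariates.

    Fits the covariates-only model and the covariates+group-indicator model
    and compares residual sums of squares; with no covariates this reduces
    to the one-way ANOVA F. Returns (F, p).
    """
    y = np.asarray(metric, dtype=float)
    group = pd.Series(group).astype(str)
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise InputError("need at least 2 groups")
    if group.value_counts().min() < 3:
        raise InputError("every group needs >= 3 subjects for the F-test")
    n = y.size
    xc = _covariate_matrix(covariates)
    base = [np.ones(n)]
    names = ["intercept"]
    if xc.size:
        base.append(xc)
        names += [f"cov{j}" for j in range(xc.shape[1])]
    x_red = np.column_stack(base)
    dummies = np.column_stack([
        (group == lv).to_numpy(dtype=float) for lv in levels[1:]
    ])
    x_full = np.column_stack([x_red, dummies])
    _check_design(x_full, names + [f"group[{lv}]" for lv in levels[1:]])
    fit_red = sm.OLS(y, x_red).fit()
    fit_full = sm.OLS(y, x_full).fit()
    f, p, _ = fit_full.compare_f_test(fit_red)
    return float(f), float(p)


def posthoc_pairwise(metric, group, pair, covariates=None) -> tuple[float, float]:
    """Covariate-adjusted two-group contrast.

    t is the coefficient of the indicator of ``pair[0]`` in an OLS model on
    the subjects of the two groups, i.e. its sign follows
    mean(pair[0]) - mean(pair[1]); p is two-sided. With no covariates this
    equals the pooled-variance two-sample t-test.
    """
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ParameterError("pair must name two distinct groups")
    y = np.asarray(metric, dtype=float)
    group = pd.Series(group).astype(str).reset_index(drop=True)
    sel = group.isin(pair).to_numpy()
    if sel.sum() < 4:
        raise InputError("too few subjects in the selected pair")
    y = y[sel]
    g = group[sel]
    ind = (g == pair[0]).to_numpy(dtype=float)
    parts = [np.ones(y.size), ind]
    if covariates is not None:
        xc = _covariate_matrix(
            covariates.loc[sel.nonzero()[0]] if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates)[sel]
        )
        if xc.size:
            parts.append(xc)
    x = np.column_stack(parts)
    _check_design(x, [f"c{j}" for j in range(x.shape[1])])
    fit = sm.OLS(y, x).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    flags, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, p_adj


@dataclass
class PartialCorrResult:
    r: float
    p: float
    df: int
    n: int


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    p comes from t = r sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of
    freedom, k the number of covariates. With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and aligned")
    n = x.size
    xc = _covariate_matrix(covariates)
    k = xc.shape[1] if xc.size else 0
    if n <= k + 3:
        raise InputError(f"need n > k + 3 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n)] + ([xc] if k else []))
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() == 0 or ry.std() == 0:
        raise InputError("degenerate residual variance; partial r undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        return PartialCorrResult(r=r, p=0.0, df=df, n=n)
    t = r * np.sqrt(df / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, df=df, n=n)


def metric_families(metric_cols) -> dict[str, list[str]]:
    """Default FDR families.

    Global AUC metrics form one family; nodal AUC columns (named
    ``<M>_auc_node<i>``) are grouped per metric type so each type is
    corrected across its nodes.
    """
    families: dict[str, list[str]] = {}
    for c in metric_cols:
        if "_node" in c:
            fam = c.split("_auc_node")[0] + "_nodal"
        else:
            fam = "global"
        families.setdefault(fam, []).append(c)
    return families


class GroupComparison:
    """Model: covariate-adjusted comparison of AUC metrics across groups.

    Parameters
    ----------
    table
        One row per subject; must contain ``group_col``, the covariate
        columns, and every metric column.
    metric_cols
        Metric columns to test (default: every numeric column that is not a
        covariate or identifier).
    covariate_cols
        Nuisance covariates, default ``("age", "gender", "mean_fd")``.
    families
        Mapping family name -> metric columns for FDR correction; defaults
        to :func:`metric_families`.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metric_cols=None,
        group_col: str = "group",
        covariate_cols=DEFAULT_COVARIATES,
        families: dict | None = None,
    ):
        if group_col not in table.columns:
            raise InputError(f"table lacks group column {group_col!r}")
        self.table = table.reset_index(drop=True)
        self.group_col = group_col
        missing = set(covariate_cols) - set(table.columns)
        if missing:
            raise InputError(f"table lacks covariate columns {sorted(missing)}")
        self.covariate_cols = []
        for c in covariate_cols:
            if table[c].nunique() < 2:
                warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            else:
                self.covariate_cols.append(c)
        if table[list(covariate_cols)].isna().any().any() or table[group_col].isna().any():
            raise InputError("missing group or covariate values")
        if metric_cols is None:
            skip = set(covariate_cols) | {group_col, "subject_id"}
            metric_cols = [
                c for c in table.columns
                if c not in skip and pd.api.types.is_numeric_dtype(table[c])
            ]
        self.metric_cols = list(metric_cols)
        self.levels = sorted(self.table[group_col].astype(str).unique())
        if len(self.levels) < 2:
            raise InputError("need at least 2 groups")
        self.families = families or metric_families(self.metric_cols)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "GroupComparison":
        return cls(table, **kwargs)

    def _covariates(self, rows=None) -> pd.DataFrame | None:
        if not self.covariate_cols:
            return None
        df = self.table[self.covariate_cols]
        return df if rows is None else df.loc[rows]

    def fit(self, q: float = 0.05, run_posthoc: bool = True) -> "GroupComparisonResults":
        """Omnibus tests, per-family FDR, gated post-hoc contrasts."""
        rows = []
        fam_of = {m: f for f, ms in self.families.items() for m in ms}
        for m in self.metric_cols:
            f, p = ancova_group_test(
                self.table[m], self.table[self.group_col], self._covariates()
            )
            rows.append({"metric": m, "family": fam_of.get(m, "global"),
                         "F": f, "p": p})
        omnibus = pd.DataFrame(rows)
        omnibus["p_fdr"] = np.nan
        omnibus["significant"] = False
        for fam, sub in omnibus.groupby("family"):
            flags, p_adj = bh_fdr(sub["p"].to_numpy(), q)
            omnibus.loc[sub.index, "p_fdr"] = p_adj
            omnibus.loc[sub.index, "significant"] = flags

        posthoc = pd.DataFrame(
            columns=["metric", "group_a", "group_b", "t", "p", "p_fdr", "significant"]
        )
        if run_posthoc:
            ph_rows = []
            survivors = omnibus.loc[omnibus["significant"], "metric"]
            pairs = [
                (a, b)
                for i, a in enumerate(self.levels)
                for b in self.levels[i + 1:]
            ]
            for m in survivors:
                for a, b in pairs:
                    t, p = posthoc_pairwise(
                        self.table[m], self.table[self.group_col], (a, b),
                        self._covariates(),
                    )
                    ph_rows.append({"metric": m, "group_a": a, "group_b": b,
                                    "t": t, "p": p})
            if ph_rows:
                posthoc = pd.DataFrame(ph_rows)
                flags, p_adj = bh_fdr(posthoc["p"].to_numpy(), q)
                posthoc["p_fdr"] = p_adj
                posthoc["significant"] = flags
        return GroupComparisonResults(self, omnibus, posthoc, q)


class GroupComparisonResults:
    """Fitted omnibus + post-hoc tables and covariate-adjusted correlations."""

    def __init__(self, model: GroupComparison, omnibus: pd.DataFrame,
                 posthoc: pd.DataFrame, q: float):
        self.model = model
        self.omnibus = omnibus
        self.posthoc = posthoc
        self.q = q

    @property
    def significant_metrics(self) -> list[str]:
        return self.omnibus.loc[self.omnibus["significant"], "metric"].tolist()

    def partial_correlations(
        self,
        clinical_cols,
        groups=None,
        metrics=None,
        include_pooled: bool = True,
    ) -> pd.DataFrame:
        """Partial correlations of (surviving) metrics with clinical variables.

        Run within each listed group and, when ``include_pooled``, across
        those groups pooled; the same nuisance covariates are removed.
        """
        tab = self.model.table
        if groups is None:
            groups = self.model.levels
        if metrics is None:
            metrics = self.significant_metrics
        subsets = [(g, tab[self.model.group_col].astype(str) == g) for g in groups]
        if include_pooled and len(groups) > 1:
            pooled = tab[self.model.group_col].astype(str).isin(groups)
            subsets.append(("+".join(groups), pooled))
        rows = []
        for name, sel in subsets:
            idx = np.flatnonzero(sel.to_numpy())
            cov = self.model._covariates(idx)
            for m in metrics:
                for c in clinical_cols:
                    res = partial_correlation(
                        tab.loc[idx, m], tab.loc[idx, c], cov
                    )
                    rows.append({"group": name, "metric": m, "variable": c,
                                 "r": res.r, "p": res.p, "df": res.df, "n": res.n})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Group comparison of AUC network metrics",
            f"groups: {', '.join(self.model.levels)}   "
            f"covariates: {', '.join(self.model.covariate_cols) or 'none'}   "
            f"FDR q = {self.q}",
            "",
            "Omnibus (incremental F of the group factor):",
        ]
        om = self.omnibus.sort_values(["family", "p"])
        for _, r in om.iterrows():
            star = " *" if r["significant"] else ""
            lines.append(
                f"  {r['metric']:<28s} F = {r['F']:8.3f}  p = {r['p']:.4g}  "
                f"p_fdr = {r['p_fdr']:.4g}{star}"
            )
        if len(self.posthoc):
            lines.append("")
            lines.append("Post-hoc pairwise contrasts (gated by omnibus FDR):")
            for _, r in self.posthoc.iterrows():
                star = " *" if r["significant"] else ""
                lines.append(
                    f"  {r['metric']:<22s} {r['group_a']} vs {r['group_b']}: "
                    f"t = {r['t']:7.3f}  p = {r['p']:.4g}  p_fdr = {r['p_fdr']:.4g}{star}"
                )
        return "\n".join(lines)


def full_inference(
    table: pd.DataFrame,
    clinical_cols=(),
    patient_groups=None,
    q: float = 0.05,
    **kwargs,
) -> tuple[GroupComparisonResults, pd.DataFrame]:
    """Omnibus -> FDR -> gated post-hoc -> partial correlations, in one call.

    ``patient_groups`` selects the groups whose clinical correlations are of
    interest (run per group and pooled); defaults to every group.
    """
    model = GroupComparison(table, **kwargs)
    results = model.fit(q=q)
    if clinical_cols:
        corr = results.partial_correlations(clinical_cols, groups=patient_groups)
    else:
        corr = pd.DataFrame(columns=["group", "metric", "variable", "r", "p", "df", "n"])
    return results, corr
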