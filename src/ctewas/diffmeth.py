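"""Per-probe hypothesis tests for the sorted-cell EWAS.

Two families of tests:

* neuron-vs-glia two-sample t tests (Welch by default) with ct-DMCG
  calling: autosomal probes, Bonferroni-significant, absolute mean
  difference of at least 0.20 beta;
* covariate-adjusted per-probe linear regression of beta on age or Braak
  stage (model: beta ~ intercept + predictor + covariates among
  {age, braak, sex, pc1}), run separately inside each cell fraction.

Regressions operate on beta values directly.  Per-probe fits share one
design matrix, so the whole epigenome is solved with a single set of
matrix products (ordinary least squares via the normal equations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError
from .io_formats import REGION_CLASSES
from .meta_analysis import bh_fdr

log = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


def _rank_by_p(table: pd.DataFrame) -> pd.DataFrame:
    """Attach 1-based ranks: ascending p, ties broken by probe_id."""
    order = np.lexsort((table.index.to_numpy(), table["p"].to_numpy()))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table = table.copy()
    table["rank"] = ranks
    return table


def _finalize(table: pd.DataFrame) -> pd.DataFrame:
    m = len(table)
    table = table.copy()
    table["bonferroni_p"] = np.minimum(table["p"].to_numpy() * m, 1.0)
    table["fdr_q"] = bh_fdr(table["p"].to_numpy())
    return _rank_by_p(table)


# ---------------------------------------------------------------------------
# neuron vs glia t test


def celltype_ttest(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    controls_only: bool = True,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sided t test of neuron vs glia samples.

    Welch (unequal variances) by default; ``equal_var=True`` pools.
    Effect is mean(neuron) - mean(glia).  Returns a ranked table with
    columns effect, se, statistic, df, p, bonferroni_p, fdr_q, rank.
    """
    sub = sheet.loc[sheet.index.intersection(beta.columns)]
    if controls_only:
        sub = sub[sub["diagnosis"] == "control"]
    groups = {}
    for fraction in ("neuron", "glia"):
        ids = sub.index[sub["cell_fraction"] == fraction]
        if len(ids) < 2:
            raise ContractError(f"need >= 2 {fraction} samples, got {len(ids)}")
        groups[fraction] = beta[ids].to_numpy(dtype=float)
    xn, xg = groups["neuron"], groups["glia"]
    nn, ng = xn.shape[1], xg.shape[1]
    mn, mg = xn.mean(axis=1), xg.mean(axis=1)
    vn, vg = xn.var(axis=1, ddof=1), xg.var(axis=1, ddof=1)
    effect = mn - mg
    if equal_var:
        sp2 = ((nn - 1) * vn + (ng - 1) * vg) / (nn + ng - 2)
        se = np.sqrt(sp2 * (1.0 / nn + 1.0 / ng))
        df = np.full_like(se, float(nn + ng - 2))
    else:
        a, b = vn / nn, vg / ng
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (nn - 1) + b**2 / (ng - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = np.empty_like(se)
    ok = se > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # degenerate probes: zero variance in both groups
    zero_eq = ~ok & (effect == 0)
    t[zero_eq], p[zero_eq], df[zero_eq] = 0.0, 1.0, float(nn + ng - 2)
    zero_ne = ~ok & (effect != 0)
    t[zero_ne] = np.sign(effect[zero_ne]) * np.inf
    p[zero_ne], df[zero_ne] = _TINY_P, float(nn + ng - 2)
    p = np.clip(p, _TINY_P, 1.0)
    table = pd.DataFrame(
        {"effect": effect, "se": se, "statistic": t, "df": df, "p": p},
        index=beta.index,
    )
    return _finalize(table)


def call_ct_dmcgs(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    delta_min: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cell-type-different CpGs: autosomal, Bonferroni p < alpha and
    |effect| >= delta_min; labelled hyper/hypo (in neurons) by effect sign.
    """
    missing = results.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"annotation missing {len(missing)} tested probes")
    ann = annotation.reindex(results.index)
    mask = (
        ann["autosomal"].to_numpy()
        & (results["bonferroni_p"].to_numpy() < alpha)
        & (np.abs(results["effect"].to_numpy()) >= delta_min)
    )
    called = results.loc[mask].copy()
    called["direction"] = np.where(called["effect"] > 0, "hyper", "hypo")
    return called


# ---------------------------------------------------------------------------
# covariate-adjusted regression


@dataclass
class RegressionSpec:
    """One EWAS model: which predictor, which covariates, which samples.

    Sex is encoded female=0/male=1; Braak enters as a numeric 0-6 score.
    ``diagnoses`` filters samples (default controls only for the aging
    analysis; pass ("control", "ad") to include patients).
    """

    predictor: str
    cell_fraction: str
    covariates: tuple = ()
    diagnoses: tuple = ("control", "ad")

    def __post_init__(self):
        if self.predictor not in ("age", "braak"):
            raise ContractError(f"predictor must be age or braak, got {self.predictor!r}")
        allowed = {"age", "braak", "sex", "pc1"}
        bad = set(self.covariates) - allowed
        if bad:
            raise ContractError(f"unknown covariates {sorted(bad)}")
        if self.predictor in self.covariates:
            raise ContractError("predictor may not also be a covariate")

    @classmethod
    def aging(cls, cell_fraction: str, controls_only: bool = True) -> "RegressionSpec":
        diag = ("control",) if controls_only else ("control", "ad")
        cov = ("sex", "pc1") if controls_only else ("braak", "sex", "pc1")
        return cls("age", cell_fraction, cov, diag)

    @classmethod
    def braak(cls, cell_fraction: str) -> "RegressionSpec":
        return cls("braak", cell_fraction, ("age", "sex", "pc1"))


def _term_column(term: str, sheet: pd.DataFrame, pcs) -> np.ndarray:
    if term == "sex":
        return (sheet["sex"] == "male").to_numpy(dtype=float)
    if term == "pc1":
        if pcs is None:
            raise ValidationError("spec includes pc1 but no PC scores supplied")
        col = pcs.scores["PC1"].reindex(sheet.index)
        if col.isna().any():
            raise ValidationError("PC scores do not cover the selected samples")
        return col.to_numpy(dtype=float)
    return sheet[term].to_numpy(dtype=float)


def build_design_matrix(sheet: pd.DataFrame, spec: RegressionSpec, pcs=None) -> pd.DataFrame:
    """Design matrix (samples x terms) for the selected subset; the first
    column is the intercept, the second the predictor."""
    sub = sheet[
        (sheet["cell_fraction"] == spec.cell_fraction)
        & sheet["diagnosis"].isin(spec.diagnoses)
    ]
    if len(sub) == 0:
        raise ContractError("sample filter selects no samples")
    cols = {"intercept": np.ones(len(sub))}
    cols[spec.predictor] = _term_column(spec.predictor, sub, pcs)
    for term in spec.covariates:
        cols[term] = _term_column(term, sub, pcs)
    return pd.DataFrame(cols, index=sub.index)


def fit_cpg_regression(y: np.ndarray, X: np.ndarray, names=None) -> pd.DataFrame:
    """OLS for a single probe: coefficients, se, t and two-sided p per term.

    Raises :class:`ContractError` on a rank-deficient design or when the
    sample size leaves no residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise ContractError(f"need n >= k+2 samples (n={n}, k={k})")
    if np.linalg.matrix_rank(X) < k:
        raise ContractError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), np.nan)
    names = names if names is not None else [f"x{i}" for i in range(k)]
    return pd.DataFrame({"coef": coef, "se": se, "t": t, "p": p, "df": dof}, index=names)


def run_ewas(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    pcs,
    spec: RegressionSpec,
) -> pd.DataFrame:
    """Per-probe OLS within one cell fraction; ranked association table.

    The predictor's coefficient, se, t and p populate the result, with
    Bonferroni and BH adjustments over the probes tested.  Probes with
    zero variance in the subset keep p = 1 (preserving the multiple-
    testing denominator).
    """
    X_df = build_design_matrix(sheet, spec, pcs)
    missing = X_df.index.difference(beta.columns)
    if len(missing):
        raise ValidationError(f"beta matrix missing {len(missing)} selected samples")
    X = X_df.to_numpy(dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ContractError("design matrix is rank deficient")
    Y = beta[X_df.index].to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ (XtX_inv @ X.T).T  # probes x terms
    resid = Y - B @ X.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    j = 1  # predictor column
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, j] / se
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), 1.0)
    zero_var = Y.var(axis=1) == 0
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, np.clip(p, _TINY_P, 1.0))
    table = pd.DataFrame(
        {
            "effect": B[:, j],
            "se": se,
            "statistic": t,
            "df": float(dof),
            "p": p,
        },
        index=beta.index,
    )
    return _finalize(table)


# ---------------------------------------------------------------------------
# descriptive summaries


def classify_direction(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    probes,
    mode: str,
    n_extreme: int = 8,
) -> pd.Series:
    """Hypo/hyper label per probe from the contrast of extreme samples.

    ``mode="aging"``: 8 youngest vs 8 oldest controls; ``mode="braak"``:
    8 youngest controls vs 8 oldest Braak-VI samples.  If fewer than 8
    samples exist in an extreme group, all available are used (logged).
    Label is the sign of mean(old/high) - mean(young/low); exact zero
    difference maps to "unchanged".
    """
    sub = sheet.loc[sheet.index.intersection(beta.columns)]
    controls = sub[sub["diagnosis"] == "control"]
    if mode == "aging":
        low_pool, high_pool = controls, controls
    elif mode == "braak":
        low_pool, high_pool = controls, sub[sub["braak"] == 6]
    else:
        raise ContractError(f"unknown mode {mode!r}")
    if len(low_pool) == 0 or len(high_pool) == 0:
        raise ContractError("an extreme group is empty")
    for name, pool in (("low", low_pool), ("high", high_pool)):
        if len(pool) < n_extreme:
            log.info("only %d samples available for the %s group", len(pool), name)
    low_ids = low_pool.sort_values("age").index[: min(n_extreme, len(low_pool))]
    high_ids = high_pool.sort_values("age").index[-min(n_extreme, len(high_pool)):]
    probes = pd.Index(probes)
    diff = beta.loc[probes, high_ids].mean(axis=1) - beta.loc[probes, low_ids].mean(axis=1)
    return pd.Series(
        np.where(diff > 0, "hyper", np.where(diff < 0, "hypo", "unchanged")),
        index=probes,
        name="direction",
    )


def region_distribution(
    probes, annotation: pd.DataFrame, background
) -> pd.DataFrame:
    """Region-class composition of a probe set against a background.

    For each region class: count and fraction in the set, fraction in the
    background (all tested probes), and the enrichment ratio.
    """
    probes, background = pd.Index(probes), pd.Index(background)
    counts = annotation.loc[probes, "region"].value_counts().reindex(REGION_CLASSES, fill_value=0)
    bg = annotation.loc[background, "region"].value_counts().reindex(REGION_CLASSES, fill_value=0)
    frac = counts / max(len(probes), 1)
    bg_frac = bg / max(len(background), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac / bg_frac
    return pd.DataFrame(
        {
            "count": counts,
            "fraction": frac,
            "background_fraction": bg_frac,
            "ratio": ratio,
        }
    )
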