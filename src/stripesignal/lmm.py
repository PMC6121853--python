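"""Random-intercept linear mixed models with per-term F-tests.

Thin wrapper around ``statsmodels`` ``MixedLM`` (REML) that adds the pieces
the analyses need and statsmodels does not expose directly:

* marginal (Wald) F-tests per fixed-effect *term* (a term may span several
  design columns),
* denominator degrees of freedom by the containment method: effects that
  vary within the random-effect groups are tested against
  ``n_obs - n_groups - p_within`` while purely between-group effects are
  tested against ``n_groups - p_between``,
* a sequential (type-I) sum-of-squares decomposition of the fixed design,
  used for variance-explained percentages,
* a Shapiro-Wilk normality check of the residuals.

Callers build an explicit numeric design matrix (a DataFrame) and describe
which columns belong to which scientific term; this keeps coding schemes
and contrast construction unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["MixedModelFit", "fit_random_intercept_lmm", "sequential_ss"]


@dataclass
class MixedModelFit:
    """Results of a fitted random-intercept linear mixed model."""

    formula: str
    response_name: str
    transform: str | None
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    random_variances: dict[str, float]
    residual_variance: float
    anova: pd.DataFrame
    shapiro_statistic: float
    shapiro_p: float
    n_obs: int
    n_groups: int
    converged: bool
    # retained for variance partitioning and post-hoc contrasts
    response: np.ndarray = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)
    terms: dict[str, list[str]] = field(repr=False, default=None)

    def fixed_effect(self, name: str) -> float:
        return float(self.params[name])

    def term_f(self, term: str) -> tuple[float, float]:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"no F-test for term {term!r}")
        return float(row["F"].iloc[0]), float(row["p"].iloc[0])

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Point estimate and standard error of a linear contrast c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        var = float(c @ self.cov_params.to_numpy() @ c)
        return est, np.sqrt(max(var, 0.0))


def _column_varies_within(col: np.ndarray, groups: np.ndarray) -> bool:
    df = pd.DataFrame({"g": groups, "x": col})
    return bool((df.groupby("g")["x"].nunique() > 1).any())


def _containment_ddf(
    X: pd.DataFrame, groups: np.ndarray, terms: dict[str, list[str]]
) -> dict[str, float]:
    """Denominator df per term under the containment convention."""
    n = len(X)
    g = pd.unique(groups).size
    within_cols = {
        c for c in X.columns if c != "Intercept" and _column_varies_within(X[c].to_numpy(), groups)
    }
    p_within = len(within_cols)
    p_between = X.shape[1] - p_within
    ddf_within = max(n - g - p_within, 1)
    ddf_between = max(g - p_between, 1)
    out = {}
    for term, cols in terms.items():
        is_within = any(c in within_cols for c in cols)
        out[term] = float(ddf_within if is_within else ddf_between)
    return out


def sequential_ss(
    y: np.ndarray, X: pd.DataFrame, terms: dict[str, list[str]]
) -> pd.DataFrame:
    """Sequential (type-I) sums of squares of the fixed design.

    Terms are added in the given order on top of the intercept; returns per
    term the incremental SS and its share of the total (centred) SS.
    """
    y = np.asarray(y, dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    cols: list[str] = ["Intercept"] if "Intercept" in X.columns else []
    rss_prev = ss_total if cols == [] else _rss(y, X[cols].to_numpy())
    rows = []
    for term, tcols in terms.items():
        if term == "Intercept":
            continue
        cols = cols + list(tcols)
        rss = _rss(y, X[cols].to_numpy())
        rows.append(
            {
                "term": term,
                "ss": rss_prev - rss,
                "pct_of_total": 100.0 * (rss_prev - rss) / ss_total if ss_total > 0 else 0.0,
            }
        )
        rss_prev = rss
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = ss_total
    out.attrs["pct_explained_total"] = float(out["pct_of_total"].sum())
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    response: str,
    design: pd.DataFrame,
    terms: dict[str, list[str]],
    group: str,
    crossed: list[str] | None = None,
    transform: str | None = None,
    formula: str = "",
) -> MixedModelFit:
    """Fit a REML random-intercept LMM and build the per-term F table.

    Parameters
    ----------
    data
        Source frame; must contain ``response``, ``group`` and any columns
        named in ``crossed``.
    design
        Numeric fixed-effects design matrix (include an ``Intercept``
        column), row-aligned with ``data``.
    terms
        Ordered mapping of scientific term name -> design column names.
        Order defines the sequential-SS decomposition.
    group
        Column with the random-intercept grouping factor.  Also the
        containment grouping for denominator df.
    crossed
        Optional additional random-intercept factors (crossed with
        ``group``), fitted as variance components.
    transform
        ``None`` or ``"sqrt"`` applied to the response before fitting.
    """
    y = data[response].to_numpy(dtype=float)
    if transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative response")
        y = np.sqrt(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    groups = data[group].to_numpy()
    X = design.reset_index(drop=True)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("design matrix contains non-finite entries")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effects design")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if crossed:
            md_frame = X.copy()
            md_frame["_y"] = y
            md_frame["_one"] = 1
            md_frame["_g"] = groups
            vc = {"group": f"0 + C(_g)"}
            for i, c in enumerate(crossed):
                md_frame[f"_c{i}"] = data[c].to_numpy()
                vc[c] = f"0 + C(_c{i})"
            rhs = " + ".join(f"Q('{c}')" for c in X.columns)
            model = sm.MixedLM.from_formula(
                f"_y ~ 0 + {rhs}", md_frame, groups="_one", vc_formula=vc, re_formula="0"
            )
            res = model.fit(reml=True)
            fe_names = list(X.columns)
            rand_var = {"group": float(res.vcomp[0])}
            for i, c in enumerate(crossed):
                rand_var[c] = float(res.vcomp[1 + i])
            # statsmodels' cov_params for variance-component models comes from
            # the joint-likelihood Hessian and is unreliable near variance
            # boundaries; recompute the fixed-effect covariance by GLS from
            # the fitted variance components.
            n = len(y)
            V = float(res.scale) * np.eye(n)
            factors = [groups] + [data[c].to_numpy() for c in crossed]
            for sig2, fac in zip(rand_var.values(), factors):
                Z = pd.get_dummies(pd.Series(fac)).to_numpy(dtype=float)
                V += sig2 * (Z @ Z.T)
            Xm = X.to_numpy()
            Vi_X = np.linalg.solve(V, Xm)
            covm_fe = np.linalg.inv(Xm.T @ Vi_X)
            beta_gls = covm_fe @ (Vi_X.T @ y)
            params = pd.Series(beta_gls, index=fe_names)
            cov = pd.DataFrame(covm_fe, index=fe_names, columns=fe_names)
        else:
            model = sm.MixedLM(y, X.to_numpy(), groups=groups)
            res = model.fit(reml=True)
            fe_names = list(X.columns)
            params = pd.Series(res.fe_params, index=fe_names)
            cov = pd.DataFrame(
                np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
                index=fe_names,
                columns=fe_names,
            )
            rand_var = {"group": float(np.asarray(res.cov_re)[0, 0])}

    resid = y - X.to_numpy() @ params.to_numpy()
    ddfs = _containment_ddf(X, groups, terms)
    rows = []
    covm = cov.to_numpy()
    for term, tcols in terms.items():
        if term == "Intercept":
            continue
        idx = [fe_names.index(c) for c in tcols]
        L = np.zeros((len(idx), len(fe_names)))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        lb = L @ params.to_numpy()
        lvl = L @ covm @ L.T
        q = len(idx)
        try:
            fstat = float(lb @ np.linalg.solve(lvl, lb)) / q
        except np.linalg.LinAlgError:
            fstat = np.nan
        ddf = ddfs[term]
        p = float(st.f.sf(fstat, q, ddf)) if np.isfinite(fstat) else np.nan
        rows.append({"term": term, "F": fstat, "df_num": q, "df_den": ddf, "p": p})
    anova = pd.DataFrame(rows)

    if len(resid) >= 3 and np.ptp(resid) > 0:
        sw_stat, sw_p = st.shapiro(resid)
    else:
        sw_stat, sw_p = np.nan, np.nan

    return MixedModelFit(
        formula=formula or f"{response} ~ {' + '.join(t for t in terms if t != 'Intercept')}",
        response_name=response,
        transform=transform,
        params=params,
        bse=pd.Series(np.sqrt(np.diag(covm)), index=fe_names),
        cov_params=cov,
        random_variances=rand_var,
        residual_variance=float(res.scale),
        anova=anova,
        shapiro_statistic=float(sw_stat),
        shapiro_p=float(sw_p),
        n_obs=len(y),
        n_groups=int(pd.unique(groups).size),
        converged=bool(getattr(res, "converged", True)),
        response=y,
        design=X,
        terms={k: list(v) for k, v in terms.items()},
    )
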