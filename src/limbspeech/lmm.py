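"""Linear mixed models of 50 ms peak-window magnitudes, plus small-n tests.

Two models mirror the two acoustic measures.  For the z-scaled envelope the
only fixed predictor is the acceleration-peak magnitude, with a random
intercept per participant.  For F0 the fixed part is acceleration x day x
condition (all interactions), with a random intercept and random condition
slopes per participant and residual variance allowed to differ between days
(handled by one feasible-GLS reweighting pass, since the underlying REML
fitter assumes homoscedastic residuals).  Estimation is restricted maximum
likelihood via statsmodels' MixedLM; Wald inference uses the normal
approximation (the peak-level sample sizes run into the thousands).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class LmmFit:
    formula: str
    terms: pd.DataFrame  # name, estimate, se, statistic, p, ci_lo, ci_hi
    random_effects: dict
    residual_variance: dict  # possibly day-stratified
    selection_path: list = field(default_factory=list)
    converged: bool = True
    llf: float = float("nan")
    n_obs: int = 0
    warnings: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["name"].str.contains(name, regex=False)]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def _wald_table(res) -> pd.DataFrame:
    fe = res.fe_params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = res.bse_fe
    names = list(fe.index) if hasattr(fe, "index") else list(res.model.exog_names)
    fe = np.asarray(fe, dtype=float)
    se = np.asarray(se, dtype=float)
    z = fe / se
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "name": names,
            "estimate": fe,
            "se": se,
            "statistic": z,
            "p": p,
            "ci_lo": fe - 1.96 * se,
            "ci_hi": fe + 1.96 * se,
        }
    )


def _fit_mixedlm(formula, data, groups, re_formula=None, reml=True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        return model.fit(reml=reml)


def fit_peak_lmm_env(measures: pd.DataFrame) -> LmmFit:
    """env50 ~ acceleration + (1 | participant).

    ``measures`` is the peak-measures table (one row per retained
    acceleration peak); rows with missing env50 are dropped.
    """
    data = measures.dropna(subset=["env50", "acc_peak_magnitude"]).copy()
    if data["env50"].nunique() <= 1:
        raise ValueError("degenerate response: env50 has no variance")
    res = _fit_mixedlm("env50 ~ acc_peak_magnitude", data, "participant_id")
    return LmmFit(
        formula="env50 ~ acc_peak_magnitude + (1|participant)",
        terms=_wald_table(res),
        random_effects={"participant_intercept_var": float(res.cov_re.iloc[0, 0])},
        residual_variance={"pooled": float(res.scale)},
        converged=bool(res.converged),
        llf=float(res.llf),
        n_obs=int(res.nobs),
    )


def fit_peak_lmm_f0(
    measures: pd.DataFrame,
    day_weights: bool = True,
    formula: str | None = None,
) -> LmmFit:
    """f050 ~ acceleration * day * condition with per-participant condition slopes.

    Residual variance may differ between days; one reweighting pass scales
    each day's rows by its estimated residual SD and refits (feasible GLS).
    If the random condition-slope fit is singular, the model falls back to a
    random intercept only and records a warning.
    """
    data = measures.dropna(subset=["f050", "acc_peak_magnitude"]).copy()
    if data["f050"].nunique() <= 1:
        raise ValueError("degenerate response: f050 has no variance")
    data["day"] = data["day"].astype("category")
    data["condition"] = data["condition"].astype("category")
    if formula is None:
        formula = "f050 ~ acc_peak_magnitude * C(day) * C(condition)"
    notes: list[str] = []
    re_formula = "~C(condition)"
    try:
        res = _fit_mixedlm(formula, data, "participant_id", re_formula=re_formula)
        singular = not res.converged or np.any(np.linalg.eigvalsh(res.cov_re.to_numpy()) < 1e-10)
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        res = None
    if singular:
        notes.append("random condition slopes singular; refit with random intercept only")
        re_formula = None
        res = _fit_mixedlm(formula, data, "participant_id")

    resid_var = {"pooled": float(res.scale)}
    if day_weights and data["day"].nunique() > 1:
        resid = res.resid
        sds = resid.groupby(data["day"], observed=True).std()
        resid_var = {f"day{d}": float(s**2) for d, s in sds.items()}
        w = data["day"].map(sds).astype(float).to_numpy()
        w = w / np.sqrt(np.mean(w**2))
        # feasible GLS: divide every row of the response, the fixed design
        # and the random-effect design by that day's residual SD, then refit
        # on arrays (a formula cannot express row scaling of the intercept)
        import patsy
        import statsmodels.api as sm

        y_mat, X_mat = patsy.dmatrices(formula, data, return_type="dataframe")
        if re_formula is not None:
            Z_mat = patsy.dmatrix(re_formula, data, return_type="dataframe")
        else:
            Z_mat = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
        yw = y_mat.to_numpy().ravel() / w
        Xw = X_mat.to_numpy() / w[:, None]
        Zw = Z_mat.to_numpy() / w[:, None]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model2 = sm.MixedLM(
                    yw, Xw, groups=data["participant_id"].to_numpy(), exog_re=Zw
                )
                res2 = model2.fit(reml=True)
            if res2.converged:
                res2.model.exog_names[:] = list(X_mat.columns)
                res = res2
                notes.append("day-stratified residual reweighting applied")
        except (np.linalg.LinAlgError, ValueError):
            notes.append("day-stratified reweighting failed; unweighted fit kept")

    cov_re = np.asarray(res.cov_re)
    if re_formula is not None:
        re_dict = {"cov_re": cov_re.tolist()}
    else:
        re_dict = {"participant_intercept_var": float(cov_re[0, 0])}
    return LmmFit(
        formula=formula + " + (condition|participant)",
        terms=_wald_table(res),
        random_effects=re_dict,
        residual_variance=resid_var,
        converged=bool(res.converged),
        llf=float(res.llf),
        n_obs=int(res.nobs),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# backward selection
# ---------------------------------------------------------------------------

def _term_order(term: str) -> int:
    return term.count(":")


def _removable(terms: list[str]) -> list[str]:
    """Terms not marginal to any retained higher-order interaction."""
    out = []
    for t in terms:
        parts = set(t.split(":"))
        contained = any(
            t != other and parts < set(other.split(":")) for other in terms
        )
        if not contained:
            out.append(t)
    return out


def backward_select(
    measures: pd.DataFrame,
    response: str = "f050",
    terms: tuple[str, ...] = ("acc_peak_magnitude", "C(day)", "C(condition)"),
    alpha: float = 0.05,
    groups: str = "participant_id",
) -> LmmFit:
    """Backward elimination by likelihood-ratio tests, respecting marginality.

    Starts from the full factorial model over ``terms``; at each step the
    least significant removable term (interactions before the main effects
    they contain) is dropped if its LRT p-value exceeds ``alpha``.  ML (not
    REML) likelihoods are compared, as required for fixed-effect LRTs.
    """
    data = measures.dropna(subset=[response, "acc_peak_magnitude"]).copy()

    def expand(ts):
        from itertools import combinations

        full = []
        for r in range(1, len(ts) + 1):
            for combo in combinations(ts, r):
                full.append(":".join(combo))
        return full

    current = expand(terms)
    path = []
    while True:
        base_formula = f"{response} ~ " + " + ".join(current) if current else f"{response} ~ 1"
        full_fit = _fit_mixedlm(base_formula, data, groups, reml=False)
        candidates = _removable(current)
        best = None
        for cand in sorted(candidates, key=_term_order, reverse=True):
            reduced = [t for t in current if t != cand]
            red_formula = f"{response} ~ " + " + ".join(reduced) if reduced else f"{response} ~ 1"
            red_fit = _fit_mixedlm(red_formula, data, groups, reml=False)
            lr = 2 * (full_fit.llf - red_fit.llf)
            df = full_fit.df_modelwc - red_fit.df_modelwc
            df = max(int(df), 1)
            p = float(sps.chi2.sf(max(lr, 0.0), df))
            if best is None or p > best[1]:
                best = (cand, p, lr, df)
        if best is None or best[1] <= alpha:
            break
        current = [t for t in current if t != best[0]]
        path.append({"dropped": best[0], "p": best[1], "lr": best[2], "df": best[3]})
        if not current:
            break

    final_formula = f"{response} ~ " + " + ".join(current) if current else f"{response} ~ 1"
    res = _fit_mixedlm(final_formula, data, groups, reml=True)
    return LmmFit(
        formula=final_formula + f" + (1|{groups})",
        terms=_wald_table(res),
        random_effects={"participant_intercept_var": float(res.cov_re.iloc[0, 0])},
        residual_variance={"pooled": float(res.scale)},
        selection_path=path,
        converged=bool(res.converged),
        llf=float(res.llf),
        n_obs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# worked example: correlation test
# ---------------------------------------------------------------------------

def t_pvalue(t: float, df: int) -> float:
    """Two-sided p-value of a t statistic."""
    return float(2 * sps.t.sf(abs(t), df))


def correlation_test(x: np.ndarray, y: np.ndarray):
    """Pearson correlation with r^2, t statistic, df = n - 2, two-sided p."""
    from .gam import TestResult

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    df = n - 2
    denom = max(1.0 - r**2, 1e-300)
    t = r * np.sqrt(df) / np.sqrt(denom)
    return TestResult(
        name="pearson",
        statistic=float(t),
        df_num=1.0,
        df_den=float(df),
        p_parametric=t_pvalue(t, df),
        r2=r**2,
    )
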