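"""Factor-smooth additive models for peak-aligned epoch curves.

The response is the stack of per-(participant, condition, day) mean curves
over the -200..+200 ms epoch window.  Fixed structure: parametric intercepts
(sex/day/condition for F0; a lone intercept for the z-scaled envelope) plus
either one penalized smooth of time per condition ("by-condition" form, for
nonlinearity tests) or one shared smooth plus per-condition *difference*
smooths against a reference condition ("difference" form, for between-
condition tests).  Participant-by-condition random smooths -- penalized
spline deviations sharing a single smoothing parameter, shrunk all the way to
zero including their straight-line part -- absorb idiosyncratic curve shapes.
Residual dependence between consecutive samples of a curve is handled by an
AR(1) working model: rho is estimated from the lag-1 autocorrelation of a
preliminary fit's residuals, both sides are whitened, and the model is refit.

Smoothing parameters are chosen by generalized cross-validation (GCV) on the
whitened problem; effective degrees of freedom (edf) are traces of the
term-wise influence contributions.

Hypothesis tests are deliberately *not* read off the penalized fit: F ratios
built from GCV-adaptive fits with edf-based degrees of freedom are markedly
anticonservative (the smoothing parameter chases the same noise the test then
declares significant).  Instead, the parametric tests compare nested
*unpenalized* regression-spline fits -- classical F tests with fixed degrees
of freedom, exact under the whitened Gaussian null -- on the same design with
the random smooths excluded.  The penalized fit supplies the reported edf and
fitted curves; permutation p-values are available as a distribution-free
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .splines import SplineBasis, build_penalized_spline_basis, centering_transform

__all__ = [
    "GamFit",
    "TestResult",
    "fit_factor_smooth_gam",
    "test_smooth_nonlinearity",
    "test_smooth_difference",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df_num: float
    df_den: float
    p_parametric: float
    p_permutation: float | None = None
    edf: float | None = None
    r2: float | None = None


@dataclass
class _Term:
    name: str
    cols: slice
    penalty: np.ndarray | None  # full-size block penalty (None = unpenalized)
    lam_group: int | None  # index into the lambda vector, None = unpenalized


@dataclass
class GamFit:
    structure: str  # by_condition | difference
    measure: str
    conditions: list[str]
    reference: str | None
    terms: list[_Term]
    X: np.ndarray  # whitened design
    y: np.ndarray  # whitened response
    beta: np.ndarray
    lambdas: np.ndarray
    rho: float
    edf: dict[str, float]
    edf_total: float
    rss: float
    gcv: float
    basis: SplineBasis
    cells: pd.DataFrame
    curve_len: int
    meta: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------
    def condition_curve(self, condition: str, times_ms: np.ndarray | None = None) -> pd.DataFrame:
        """Fitted population curve for one condition with pointwise 95% bands."""
        times = np.asarray(times_ms if times_ms is not None else self.meta["grid"], dtype=float)
        Xp = self._predict_design(condition, times)
        mu = Xp @ self.beta
        A = self.meta["A"]
        cov = linalg.cho_solve(A, Xp.T)
        sigma2 = self.rss / max(self.y.size - self.edf_total, 1.0)
        se = np.sqrt(np.maximum(np.einsum("ij,ji->i", Xp, cov), 0.0) * sigma2)
        return pd.DataFrame(
            {"time_ms": times, "fit": mu, "lo": mu - 1.96 * se, "hi": mu + 1.96 * se}
        )

    def _predict_design(self, condition: str, times: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        Xp = np.zeros((times.size, p))
        B = self.basis.design(times)
        for term in self.terms:
            if term.name == "intercept":
                Xp[:, term.cols] = 1.0
            elif term.name == f"cond:{condition}":
                Xp[:, term.cols] = 1.0
            elif term.name == f"s({condition})":
                Xp[:, term.cols] = B @ self.meta[f"Z_{condition}"]
            elif term.name == "s(shared)":
                Xp[:, term.cols] = B @ self.meta["Z_shared"]
            elif term.name == f"sdiff({condition})" and condition != self.reference:
                Z = self.meta.get(f"Zdiff_{condition}")
                Xp[:, term.cols] = B @ Z if Z is not None else B
        return Xp


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _ar1_whiten(y: np.ndarray, X: np.ndarray, rho: float, curve_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact AR(1) whitening applied independently within each curve."""
    n = y.size
    yw = y.copy().astype(float)
    Xw = X.copy().astype(float)
    c = np.sqrt(1 - rho**2)
    for start in range(0, n, curve_len):
        sl = slice(start, start + curve_len)
        yb, Xb = y[sl], X[sl]
        yw[sl][1:] = yb[1:] - rho * yb[:-1]
        yw[sl][:1] = yb[:1] * c
        Xw[sl][1:] = Xb[1:] - rho * Xb[:-1]
        Xw[sl][:1] = Xb[:1] * c
    return yw, Xw


def _stationary_whiten(
    y: np.ndarray, X: np.ndarray, resid: np.ndarray, curve_len: int, order: int = 6
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """GLS whitening by a low-order AR model of the residual autocovariance.

    Epoch-averaged syllabic noise is damped-oscillatory, not AR(1).  An AR
    model of small order fitted by Yule-Walker to the pooled residual
    autocovariance captures such spectra with few parameters (an empirical
    full-lag covariance is too noisy to whiten with at study sizes).  The
    model's implied autocovariance extends recursively to the full curve
    length; whitening is exact via its Toeplitz Cholesky factor.
    """
    n = y.size
    R = resid.reshape(-1, curve_len)
    p = min(order, curve_len - 1)
    acov = np.empty(p + 1)
    for lag in range(p + 1):
        acov[lag] = (R[:, lag:] * R[:, : curve_len - lag]).mean()
    try:
        a = linalg.solve_toeplitz(acov[:p], acov[1 : p + 1])
    except linalg.LinAlgError:
        a = np.zeros(p)
    # model autocovariance extends recursively: gamma_k = sum_j a_j gamma_{k-j}
    gamma = np.empty(curve_len)
    gamma[: p + 1] = acov
    for k_ in range(p + 1, curve_len):
        gamma[k_] = a @ gamma[k_ - 1 : k_ - 1 - p : -1]
    Sigma = linalg.toeplitz(gamma)
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError:
        w, V = linalg.eigh(Sigma)
        w = np.clip(w, max(1e-3 * w.max(), 1e-12), None)
        Sigma = (V * w) @ V.T
        L = linalg.cholesky(Sigma, lower=True)
    yw = np.empty_like(y, dtype=float)
    Xw = np.empty_like(X, dtype=float)
    for start in range(0, n, curve_len):
        sl = slice(start, start + curve_len)
        yw[sl] = linalg.solve_triangular(L, y[sl], lower=True)
        Xw[sl] = linalg.solve_triangular(L, X[sl], lower=True)
    rho1 = float(acov[1] / acov[0]) if acov[0] > 0 else 0.0
    return yw, Xw, rho1, L


def _penalty_total(p: int, terms: list[_Term], lambdas: np.ndarray) -> np.ndarray:
    P = np.zeros((p, p))
    for term in terms:
        if term.penalty is not None and term.lam_group is not None:
            P[term.cols, term.cols] += lambdas[term.lam_group] * term.penalty
    return P


def _fit_at(
    XtX: np.ndarray, Xty: np.ndarray, yty: float, n: int, terms: list[_Term], lambdas: np.ndarray
):
    p = XtX.shape[0]
    A = XtX + _penalty_total(p, terms, lambdas)
    try:
        cho = linalg.cho_factor(A + 1e-10 * np.eye(p))
    except linalg.LinAlgError:
        cho = linalg.cho_factor(A + 1e-6 * np.eye(p))
    beta = linalg.cho_solve(cho, Xty)
    M = linalg.cho_solve(cho, XtX)  # A^-1 X'X: influence contributions
    edf_total = float(np.trace(M))
    rss = float(yty - 2 * beta @ Xty + beta @ XtX @ beta)
    rss = max(rss, 1e-300)
    gcv = n * rss / max(n - edf_total, 1e-6) ** 2
    return beta, M, edf_total, rss, gcv, cho


def _select_lambdas(XtX, Xty, yty, n, terms, n_lam) -> np.ndarray:
    if n_lam == 0:
        return np.empty(0)
    # scale-aware start: balance trace of the data part against the penalty
    lam0 = np.zeros(n_lam)
    for g in range(n_lam):
        tx = ts = 0.0
        for term in terms:
            if term.lam_group == g and term.penalty is not None:
                tx += np.trace(XtX[term.cols, term.cols])
                ts += np.trace(term.penalty)
        lam0[g] = np.log10(max(tx, 1e-12) / max(ts, 1e-12))

    def obj(loglam):
        lam = 10.0 ** np.clip(loglam, -8, 12)
        return _fit_at(XtX, Xty, yty, n, terms, lam)[4]

    res = optimize.minimize(
        obj, lam0, method="Nelder-Mead", options={"xatol": 0.1, "fatol": 1e-9, "maxiter": 60 * n_lam}
    )
    return 10.0 ** np.clip(res.x, -8, 12)


def _build_design(
    cells: pd.DataFrame,
    measure: str,
    structure: str,
    reference: str,
    basis: SplineBasis,
    basis_r: SplineBasis,
    grid: np.ndarray,
) -> tuple[np.ndarray, list[_Term], dict, int]:
    """Assemble the design matrix and term list for one model structure."""
    conditions = sorted(cells["condition"].unique())
    t = cells["time_ms"].to_numpy(dtype=float)
    n = t.size
    B = basis.design(t)
    Bg = basis.design(grid)
    meta: dict = {"grid": grid}

    blocks: list[np.ndarray] = []
    terms: list[_Term] = []
    col = 0
    lam_idx = 0

    def add(name, X, penalty=None, lam_group=None):
        nonlocal col
        blocks.append(X)
        terms.append(_Term(name, slice(col, col + X.shape[1]), penalty, lam_group))
        col += X.shape[1]

    add("intercept", np.ones((n, 1)))
    if measure == "f0":
        # factor intercepts (treatment coding, first level = reference)
        if cells["sex"].nunique() > 1:
            add("sex", (cells["sex"] == sorted(cells["sex"].unique())[1]).to_numpy(float)[:, None])
        if cells["day"].nunique() > 1:
            for d in sorted(cells["day"].unique())[1:]:
                add(f"day:{d}", (cells["day"] == d).to_numpy(float)[:, None])
        for c in conditions:
            if c != reference:
                add(f"cond:{c}", (cells["condition"] == c).to_numpy(float)[:, None])

    Zc = centering_transform(Bg)  # centre smooths over the epoch grid
    Sc = Zc.T @ basis.penalty @ Zc

    if structure == "by_condition":
        for c in conditions:
            mask = (cells["condition"] == c).to_numpy(float)[:, None]
            add(f"s({c})", (B @ Zc) * mask, Sc, lam_idx)
            meta[f"Z_{c}"] = Zc
            lam_idx += 1
    elif structure == "difference":
        add("s(shared)", B @ Zc, Sc, lam_idx)
        meta["Z_shared"] = Zc
        lam_idx += 1
        for c in conditions:
            if c == reference:
                continue
            mask = (cells["condition"] == c).to_numpy(float)[:, None]
            if measure == "f0":
                add(f"sdiff({c})", (B @ Zc) * mask, Sc, lam_idx)
                meta[f"Zdiff_{c}"] = Zc
            else:
                # envelope model has no condition intercepts, so the
                # difference smooth keeps its constant component
                add(f"sdiff({c})", B * mask, basis.penalty, lam_idx)
                meta[f"Zdiff_{c}"] = None
            lam_idx += 1
    else:
        raise ValueError(f"unknown structure {structure!r}")

    # random smooths per (participant, condition): fully shrinkable
    Br = basis_r.design(t)
    Sr = basis_r.penalty + np.eye(basis_r.k)
    groups = cells.groupby(["participant_id", "condition"], sort=True).ngroup().to_numpy()
    for g in range(groups.max() + 1):
        mask = (groups == g).astype(float)[:, None]
        add(f"rand{g}", Br * mask, Sr, lam_idx)
    lam_idx += 1

    X = np.hstack(blocks)
    return X, terms, meta, lam_idx


def fit_factor_smooth_gam(
    cells: pd.DataFrame,
    measure: str = "envelope_z",
    structure: str = "by_condition",
    reference: str = "armBlock",
    k: int = 10,
    k_random: int = 5,
    rho: str | float | None = "auto",
) -> GamFit:
    """Fit the factor-smooth model to cell-averaged epoch curves.

    ``cells`` is the output of ``coupling.average_epochs_by_cell`` (long
    format).  ``rho`` controls residual whitening: ``"auto"`` estimates an
    AR(1) coefficient from a preliminary fit, ``"toeplitz"`` whitens by the
    pooled stationary residual covariance (recommended when the epoch noise
    is oscillatory), a float fixes the AR(1) coefficient, ``None`` disables
    whitening.  F0 cells may contain missing samples; rows with missing
    values are interpolated within the curve before fitting so each curve
    keeps its full sample grid (curves with no finite values are dropped).
    """
    cells = cells.copy()
    if cells["value"].isna().any():
        curve_len0 = cells["time_ms"].nunique()
        filled = []
        for _, grp in cells.groupby(
            ["participant_id", "condition", "day"], sort=True
        ):
            v = grp["value"].to_numpy(dtype=float)
            ok = np.isfinite(v)
            if ok.sum() == 0:
                continue
            if ok.sum() < v.size:
                t = grp["time_ms"].to_numpy(dtype=float)
                v = np.interp(t, t[ok], v[ok])
            g = grp.copy()
            g["value"] = v
            filled.append(g)
        cells = pd.concat(filled, ignore_index=True) if filled else cells.dropna(subset=["value"])
        del curve_len0
    cells = cells.reset_index(drop=True)
    conditions = sorted(cells["condition"].unique())
    grid = np.sort(cells["time_ms"].unique()).astype(float)
    curve_len = grid.size
    basis = build_penalized_spline_basis(grid[0], grid[-1], k=k)
    basis_r = build_penalized_spline_basis(grid[0], grid[-1], k=k_random)

    X, terms, meta, n_lam = _build_design(
        cells, measure, structure, reference, basis, basis_r, grid
    )
    y = cells["value"].to_numpy(dtype=float)
    n = y.size

    def full_fit(yw, Xw):
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)
        lam = _select_lambdas(XtX, Xty, yty, n, terms, n_lam)
        beta, M, edf_total, rss, gcv, cho = _fit_at(XtX, Xty, yty, n, terms, lam)
        return beta, M, edf_total, rss, gcv, cho, lam, XtX, Xty, yty

    # preliminary residuals for covariance estimation come from the
    # *unpenalized* fixed design (random smooths excluded): the random
    # smooths absorb smooth noise components and would bias the estimated
    # autocovariance towards white
    fixed_cols = np.concatenate(
        [
            np.arange(t.cols.start, t.cols.stop)
            for t in terms
            if not t.name.startswith("rand")
        ]
    )

    def _prelim_resid(y_, X_):
        Xf = X_[:, fixed_cols]
        b, *_ = np.linalg.lstsq(Xf, y_, rcond=None)
        return y_ - Xf @ b

    rho_hat = 0.0
    toeplitz_L = None
    if rho == "toeplitz":
        resid = _prelim_resid(y, X)
        y, X, rho_hat, toeplitz_L = _stationary_whiten(y, X, resid, curve_len)
    elif rho == "auto" or isinstance(rho, (int, float)):
        if rho == "auto":
            resid = _prelim_resid(y, X)
            num = den = 0.0
            for start in range(0, n, curve_len):
                r = resid[start : start + curve_len]
                num += float(r[1:] @ r[:-1])
                den += float(r @ r)
            rho_hat = float(np.clip(num / den if den > 0 else 0.0, -0.98, 0.98))
        else:
            rho_hat = float(rho)
        if abs(rho_hat) > 1e-6:
            y, X = _ar1_whiten(y, X, rho_hat, curve_len)
    beta, M, edf_total, rss, gcv, cho, lam, XtX, Xty, yty = full_fit(y, X)

    # whitening hook for columns built later (test linear columns) and the
    # pre-whitening row masks of each condition smooth
    raw_masks = {}
    for c in conditions:
        raw_masks[f"s({c})"] = (cells["condition"] == c).to_numpy(bool)
    meta["raw_masks"] = raw_masks
    if toeplitz_L is not None:
        L_ = toeplitz_L

        def whitener(cols: np.ndarray) -> np.ndarray:
            out = np.empty_like(cols, dtype=float)
            for start in range(0, cols.shape[0], curve_len):
                sl = slice(start, start + curve_len)
                out[sl] = linalg.solve_triangular(L_, cols[sl], lower=True)
            return out

        meta["whitener"] = whitener
    elif abs(rho_hat) > 1e-6:

        def whitener(cols: np.ndarray) -> np.ndarray:
            _, Xw_ = _ar1_whiten(np.zeros(cols.shape[0]), cols, rho_hat, curve_len)
            return Xw_

        meta["whitener"] = whitener
    else:
        meta["whitener"] = None

    edf = {}
    for term in terms:
        edf[term.name] = float(np.trace(M[term.cols, term.cols]))
    edf["random_total"] = float(
        sum(v for k_, v in edf.items() if k_.startswith("rand"))
    )

    meta["A"] = cho
    meta["XtX"] = XtX
    meta["Xty"] = Xty
    meta["yty"] = yty
    return GamFit(
        structure=structure,
        measure=measure,
        conditions=conditions,
        reference=reference,
        terms=terms,
        X=X,
        y=y,
        beta=beta,
        lambdas=lam,
        rho=rho_hat,
        edf=edf,
        edf_total=edf_total,
        rss=rss,
        gcv=gcv,
        basis=basis,
        cells=cells,
        curve_len=curve_len,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# nested-model F tests (classical, on the unpenalized test design)
# ---------------------------------------------------------------------------

def _test_design(fit: GamFit) -> tuple[np.ndarray, dict[str, slice]]:
    """Whitened design without the random-smooth columns, with term slices."""
    cols = []
    slices = {}
    start = 0
    for term in fit.terms:
        if term.name.startswith("rand"):
            continue
        idx = np.arange(term.cols.start, term.cols.stop)
        cols.append(idx)
        slices[term.name] = slice(start, start + idx.size)
        start += idx.size
    return fit.X[:, np.concatenate(cols)], slices


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def _linear_column(fit: GamFit, rows: np.ndarray) -> np.ndarray:
    """Whitened centred-linear-in-time column restricted to given rows."""
    t = fit.cells["time_ms"].to_numpy(dtype=float)
    col = np.where(rows, t - t[rows].mean(), 0.0)[:, None]
    if fit.meta.get("whitener") is not None:
        col = fit.meta["whitener"](col)
    return col


def _nested_F(
    fit: GamFit, y: np.ndarray, drop: str, replace_linear: bool
) -> tuple[float, float, float]:
    """F statistic for dropping (or linearising) one term of the test design."""
    Xt, slices = _test_design(fit)
    n = y.size
    sl = slices[drop]
    keep = np.ones(Xt.shape[1], dtype=bool)
    keep[sl] = False
    X0 = Xt[:, keep]
    if replace_linear:
        rows = fit.meta["raw_masks"][drop]
        X0 = np.hstack([X0, _linear_column(fit, rows)])
    rss1, rank1 = _ols_rss(Xt, y)
    rss0, rank0 = _ols_rss(X0, y)
    q = max(rank1 - rank0, 1)
    df_den = max(n - rank1, 1)
    F = max(rss0 - rss1, 0.0) / q / (rss1 / df_den)
    return F, float(q), float(df_den)


def test_smooth_nonlinearity(
    fit: GamFit, condition: str, n_permutations: int = 0, rng: np.random.Generator | None = None
) -> TestResult:
    """Is the population curve for one condition more than a straight line?

    Classical nested F test: the condition's spline term is replaced by a
    centred linear trend, all other fixed terms retained, on the whitened
    unpenalized design (random smooths excluded).  The reported edf comes
    from the penalized fit and describes the fitted curve's flexibility.
    """
    if fit.structure != "by_condition":
        raise ValueError("nonlinearity test requires the by-condition structure")
    name = f"s({condition})"
    if name not in fit.edf:
        raise ValueError(f"no smooth for condition {condition!r}")
    F, q, df_den = _nested_F(fit, fit.y, name, replace_linear=True)
    res = TestResult(
        name=f"nonlinearity[{condition}]",
        statistic=float(F),
        df_num=q,
        df_den=df_den,
        p_parametric=float(sps.f.sf(F, q, df_den)),
        edf=float(fit.edf[name]),
    )
    if n_permutations > 0:
        res.p_permutation = _permute_nonlinearity(fit, name, F, n_permutations, rng)
    return res


def test_smooth_difference(
    fit: GamFit, condition: str, n_permutations: int = 0, rng: np.random.Generator | None = None
) -> TestResult:
    """Does one condition's curve differ in shape from the reference's?

    Classical nested F test dropping the condition's deviation-smooth block
    from the whitened unpenalized test design.
    """
    if fit.structure != "difference":
        raise ValueError("difference test requires the difference structure")
    if condition == fit.reference:
        return TestResult(
            name=f"difference[{condition}-{fit.reference}]",
            statistic=0.0,
            df_num=1.0,
            df_den=float(max(fit.y.size - fit.edf_total, 1.0)),
            p_parametric=1.0,
            edf=0.0,
        )
    name = f"sdiff({condition})"
    if name not in fit.edf:
        raise ValueError(f"no difference smooth for {condition!r}")
    F, q, df_den = _nested_F(fit, fit.y, name, replace_linear=False)
    res = TestResult(
        name=f"difference[{condition}-{fit.reference}]",
        statistic=float(F),
        df_num=q,
        df_den=df_den,
        p_parametric=float(sps.f.sf(F, q, df_den)),
        edf=float(fit.edf[name]),
    )
    if n_permutations > 0:
        res.p_permutation = _permute_difference(fit, condition, F, n_permutations, rng)
    return res


def _permute_nonlinearity(fit, name, F_obs, n_perm, rng) -> float:
    """Null resampling by per-curve time reversal and circular shifts."""
    rng = rng or np.random.default_rng(0)
    n = fit.y.size
    L = fit.curve_len
    count = 1
    for _ in range(n_perm):
        y = fit.y.copy()
        for start in range(0, n, L):
            seg = y[start : start + L]
            if rng.random() < 0.5:
                seg = seg[::-1]
            y[start : start + L] = np.roll(seg, int(rng.integers(0, L)))
        F, _, _ = _nested_F(fit, y, name, replace_linear=True)
        count += F >= F_obs
    return count / (n_perm + 1)


def _permute_difference(fit, condition, F_obs, n_perm, rng) -> float:
    """Null resampling by swapping condition labels within participant x day."""
    rng = rng or np.random.default_rng(0)
    cells = fit.cells
    L = fit.curve_len
    curve_meta = cells.iloc[::L][["participant_id", "condition", "day"]].reset_index(drop=True)
    ref, cond = fit.reference, condition
    idx_pairs = []
    for (pid, day), grp in curve_meta.groupby(["participant_id", "day"]):
        a = grp.index[grp["condition"] == ref]
        b = grp.index[grp["condition"] == cond]
        if len(a) and len(b):
            idx_pairs.append((int(a[0]), int(b[0])))
    count = 1
    name = f"sdiff({condition})"
    for _ in range(n_perm):
        y = fit.y.copy().reshape(-1, L)
        for a, b in idx_pairs:
            if rng.random() < 0.5:
                y[[a, b]] = y[[b, a]]
        F, _, _ = _nested_F(fit, y.ravel(), name, replace_linear=False)
        count += F >= F_obs
    return count / (n_perm + 1)
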