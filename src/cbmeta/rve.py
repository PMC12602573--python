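"""Robust-variance-estimation meta-analysis with correlated-effects weights.

When a study contributes several effect sizes, those estimates share
participants and procedures and are therefore dependent; ordinary
inverse-variance meta-analysis understates uncertainty. The
correlated-effects (CE) scheme handles this by giving each of a study's
``k_j`` effect sizes the weight ``w_j = 1 / (k_j (vbar_j + tau^2))``, where
``vbar_j`` is the study's mean sampling variance and ``tau^2`` the
between-study variance, and by estimating coefficient covariance with a
cluster-robust (sandwich) estimator over studies.

Small-sample machinery follows the CE methodology:

* ``tau^2`` is the method-of-moments estimator for the CE working model.
  With preliminary weights ``u_j = 1/(k_j vbar_j)`` and WLS residuals ``e``,
  ``QE = sum(u e^2)`` has expectation ``tr(A V0) + tau^2 tr(A Jb)`` under the
  working model with ``A = (I-H)' U (I-H)``, ``V0`` the block-diagonal
  sampling covariance ``vbar_j[(1-rho) I + rho J]`` and ``Jb`` the
  block-diagonal all-ones matrix, giving
  ``tau^2 = max(0, (QE - tr(A V0)) / tr(A Jb))``. The assumed within-study
  effect-size correlation ``rho`` (default 0.8) enters only here.
* The sandwich uses CR2-type adjustment matrices: per-study ``A_j`` chosen
  (symmetric Riccati solution of ``A_j G_j A_j = Phi_j`` with
  ``G_j = [(I-H) Phi (I-H)']_jj``) so the estimator is exactly unbiased when
  the true covariance equals the CE working model ``Phi``.
* Per-coefficient degrees of freedom are Satterthwaite approximations from
  the model-implied covariance of the robust variance estimate, and the
  omnibus Wald test for multi-coefficient hypotheses is the approximate
  Hotelling's T-squared test with Zhang-style degrees of freedom (the HTZ
  test). Coefficients with fewer than 4 degrees of freedom are flagged as
  unreliable.

Case-deletion influence diagnostics deliberately use an ordinary
(independence-assuming) random-effects model with REML ``tau^2``, mirroring
standard practice for outlier screening in this literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DF_UNRELIABLE = 4.0


def _group_indices(study_ids: np.ndarray) -> list[np.ndarray]:
    order: dict = {}
    for i, s in enumerate(study_ids):
        order.setdefault(s, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


def _sym_sqrt(mat: np.ndarray, inverse: bool = False,
              rel_floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    floor = max(vals.max(), 0.0) * rel_floor
    vals = np.clip(vals, floor, None)
    root = np.sqrt(vals)
    if inverse:
        root = 1.0 / root
    return (vecs * root) @ vecs.T


@dataclass
class RVEFit:
    """A fitted CE-weighted robust-variance meta-regression."""

    coefficients: np.ndarray
    robust_se: np.ndarray
    df: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    ci95: np.ndarray
    tau2: float
    rho: float
    weights: np.ndarray
    n_studies: int
    n_es: int
    labels: list[str]
    low_df: np.ndarray = field(default=None)
    # internals needed for omnibus Wald tests
    _M: np.ndarray = field(default=None, repr=False)
    _XWA: list = field(default=None, repr=False)
    _Qhalf: np.ndarray = field(default=None, repr=False)
    _groups: list = field(default=None, repr=False)
    _vcov: np.ndarray = field(default=None, repr=False)
    _e: np.ndarray = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.labels,
            "estimate": self.coefficients,
            "robust_se": self.robust_se,
            "t": self.t_values,
            "df": self.df,
            "p": self.p_values,
            "ci_low": self.ci95[:, 0],
            "ci_high": self.ci95[:, 1],
            "df_unreliable": self.low_df,
        })

    def report(self) -> str:
        lines = [
            f"CE-weighted RVE fit: {self.n_es} effect sizes in "
            f"{self.n_studies} studies; tau^2 = {self.tau2:.4f}, rho = {self.rho}",
            self.summary().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


@dataclass
class WaldResult:
    """HTZ-style omnibus F test of a coefficient subset."""

    F: float
    df1: float
    df2: float
    p: float


def fit_rve(g: np.ndarray, v: np.ndarray, study_ids: np.ndarray,
            X: np.ndarray | None = None, rho: float = 0.8,
            labels: list[str] | None = None) -> RVEFit:
    """Fit a CE-weighted robust-variance meta-regression.

    Parameters
    ----------
    g, v : effect sizes and their sampling variances, one row per effect.
    study_ids : cluster labels; rows sharing a label are one study.
    X : design matrix (default: intercept only; intercept must be first).
    rho : assumed within-study correlation of effect sizes (enters the
        tau^2 estimator only).
    """
    y = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    study_ids = np.asarray(study_ids)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if labels is None:
        labels = ["intercept"] + [f"x{i}" for i in range(1, p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns that are linearly dependent on earlier ones
        aliased = []
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                aliased.append(labels[j])
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    groups = _group_indices(study_ids)
    n_studies = len(groups)
    if n_studies < 2:
        warnings.warn("fewer than 2 studies: robust inference is degenerate")

    k = np.empty(n)
    vbar = np.empty(n)
    for idx in groups:
        k[idx] = len(idx)
        vbar[idx] = v[idx].mean()

    # --- method-of-moments tau^2 under the CE working model -------------
    u = 1.0 / (k * vbar)
    M0 = np.linalg.inv(X.T @ (u[:, None] * X))
    b0 = M0 @ (X.T @ (u * y))
    e0 = y - X @ b0
    QE = float(np.sum(u * e0**2))

    H0 = X @ M0 @ (X.T * u)          # X M0 X' U
    ImH0 = np.eye(n) - H0
    A = ImH0.T * u @ ImH0            # (I-H)' U (I-H)

    c0 = 0.0
    c1 = 0.0
    for idx in groups:
        Ablk = A[np.ix_(idx, idx)]
        kj = len(idx)
        vb = vbar[idx[0]]
        V0j = vb * ((1.0 - rho) * np.eye(kj) + rho * np.ones((kj, kj)))
        c0 += float(np.trace(Ablk @ V0j))
        c1 += float(Ablk.sum())      # tr(Ablk @ J) = sum of entries
    tau2 = max(0.0, (QE - c0) / c1) if c1 > 0 else 0.0

    # --- final CE-weighted fit ------------------------------------------
    w = 1.0 / (k * (vbar + tau2))
    M = np.linalg.inv(X.T @ (w[:, None] * X))
    b = M @ (X.T @ (w * y))
    e = y - X @ b

    # working covariance Phi (block diagonal) and its square root
    Phi = np.zeros((n, n))
    Phihalf = np.zeros((n, n))
    for idx in groups:
        kj = len(idx)
        vb = vbar[idx[0]]
        blk = vb * (1.0 - rho) * np.eye(kj) + (rho * vb + tau2) * np.ones((kj, kj))
        Phi[np.ix_(idx, idx)] = blk
        Phihalf[np.ix_(idx, idx)] = _sym_sqrt(blk)

    H = X @ M @ (X.T * w)
    ImH = np.eye(n) - H
    Q = ImH @ Phi @ ImH.T
    Qhalf = ImH @ Phihalf

    # CR2 adjustment matrices and the sandwich meat
    XWA = []           # per study: X_j' W_j A_j  (p x k_j)
    meat = np.zeros((p, p))
    for idx in groups:
        Gj = Q[np.ix_(idx, idx)]
        Phij = Phi[np.ix_(idx, idx)]
        if np.abs(Gj).max() < 1e-14 * np.abs(Phij).max():
            # saturated fit: residuals of this study are identically zero
            Aj = np.eye(len(idx))
        else:
            Ginvhalf = _sym_sqrt(Gj, inverse=True)
            Ghalf = _sym_sqrt(Gj)
            Bhalf = _sym_sqrt(Ghalf @ Phij @ Ghalf)
            Aj = Ginvhalf @ Bhalf @ Ginvhalf
        XWAj = (X[idx].T * w[idx]) @ Aj
        XWA.append(XWAj)
        uj = XWAj @ e[idx]
        meat += np.outer(uj, uj)
    vcov = M @ meat @ M
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    # Satterthwaite degrees of freedom per coefficient
    df = np.empty(p)
    for c in range(p):
        Z = np.stack([M[c] @ XWA[j] @ Qhalf[groups[j]] for j in range(n_studies)])
        O = Z @ Z.T
        denom = float((O**2).sum())
        df[c] = float(np.trace(O)) ** 2 / denom if denom > 0 else np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = np.c_[b - tcrit * se, b + tcrit * se]

    fit = RVEFit(
        coefficients=b, robust_se=se, df=df, t_values=t, p_values=pvals,
        ci95=ci, tau2=tau2, rho=rho, weights=w,
        n_studies=n_studies, n_es=n, labels=list(labels),
        low_df=df < DF_UNRELIABLE,
        _M=M, _XWA=XWA, _Qhalf=Qhalf, _groups=groups, _vcov=vcov, _e=e,
    )
    return fit


def wald_omnibus(fit: RVEFit, coefficient_subset: list[int]) -> WaldResult:
    """HTZ-style omnibus F test that a subset of coefficients is zero.

    For a single coefficient the statistic equals the squared t of the fit
    and the denominator df equals its Satterthwaite df.
    """
    idxs = list(coefficient_subset)
    if not idxs:
        raise ValueError("coefficient subset must be nonempty")
    if 0 in idxs and len(idxs) > 1:
        warnings.warn("coefficient subset includes the intercept; "
                      "omnibus moderator tests usually should not")
    q = len(idxs)
    C = np.zeros((q, len(fit.coefficients)))
    for r, c in enumerate(idxs):
        C[r, c] = 1.0

    groups = fit._groups
    CM = C @ fit._M
    Z = np.stack([CM @ fit._XWA[j] @ fit._Qhalf[groups[j]]
                  for j in range(len(groups))])          # (J, q, N)
    O = np.einsum("jqn,lrn->jlqr", Z, Z)                  # O_{jl} (q x q)
    # degrees of freedom from the model-implied covariance of the robust
    # variance estimate (consistent with the per-coefficient Satterthwaite)
    Omega_model = O[np.arange(len(groups)), np.arange(len(groups))].sum(axis=0)
    Om_ih = _sym_sqrt(Omega_model, inverse=True)
    Ot = np.einsum("ab,jlbc,cd->jlad", Om_ih, O, Om_ih)
    tr = np.trace(Ot, axis1=2, axis2=3)
    denom = float((tr**2).sum() + (Ot * np.transpose(Ot, (1, 0, 3, 2))).sum())
    eta = q * (q + 1) / denom
    bC = C @ fit.coefficients
    Omega = C @ fit._vcov @ C.T
    T2 = float(bC @ np.linalg.pinv(Omega) @ bC)
    df2 = eta - q + 1
    F = (df2 / (eta * q)) * T2
    pval = float(stats.f.sf(F, q, df2)) if df2 > 0 else np.nan
    return WaldResult(F=float(F), df1=float(q), df2=float(df2), p=pval)


def egger_rve(g: np.ndarray, v: np.ndarray, study_ids: np.ndarray,
              rho: float = 0.8) -> RVEFit:
    """Small-study (funnel asymmetry) test adjusted for dependent effects.

    A CE-weighted RVE meta-regression of effect size on its standard error;
    a significant slope indicates funnel-plot asymmetry and hence possible
    reporting bias.
    """
    se = np.sqrt(np.asarray(v, dtype=float))
    if np.ptp(se) < 1e-12:
        raise ValueError("all standard errors identical: slope not identifiable")
    X = np.c_[np.ones(len(se)), se]
    return fit_rve(g, v, study_ids, X=X, rho=rho, labels=["intercept", "se_g"])


# --------------------------------------------------------------------------
# Independence-model REML and case-deletion diagnostics
# --------------------------------------------------------------------------

def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    def neg_restricted_ll(tau2: float) -> float:
        wv = v + tau2
        w = 1.0 / wv
        XtWX = X.T @ (w[:, None] * X)
        b = np.linalg.solve(XtWX, X.T @ (w * y))
        e = y - X @ b
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (np.log(wv).sum() + logdet + float(np.sum(w * e**2)))

    upper = max(10.0 * float(np.var(y)), float(v.max()), 1e-3)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def _wls(y, v, X, tau2):
    w = 1.0 / (v + tau2)
    M = np.linalg.inv(X.T @ (w[:, None] * X))
    b = M @ (X.T @ (w * y))
    return b, M


def influence_diagnostics(g: np.ndarray, v: np.ndarray,
                          X: np.ndarray | None = None,
                          resid_cutoff: float = 3.0,
                          cooks_cutoff: float | None = None) -> pd.DataFrame:
    """Case-deletion diagnostics from an independence random-effects model.

    For each effect size: the leave-one-out shift of the (first)
    coefficient, the externally standardized deleted residual, and Cook's
    distance against the full fit's coefficient covariance. A case is
    flagged influential if ``|deleted residual| > 3`` or Cook's distance
    exceeds ``4 / n_es`` (conventional cutoffs).
    """
    y = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 effect sizes")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if cooks_cutoff is None:
        cooks_cutoff = 4.0 / n

    tau2 = _reml_tau2(y, v, X)
    b, M = _wls(y, v, X, tau2)

    rows = []
    cov_inv = np.linalg.inv(M)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        tau2_i = _reml_tau2(y[keep], v[keep], X[keep])
        b_i, M_i = _wls(y[keep], v[keep], X[keep], tau2_i)
        keep[i] = True
        pred = float(X[i] @ b_i)
        var_pred = float(X[i] @ M_i @ X[i])
        resid = (y[i] - pred) / np.sqrt(v[i] + tau2_i + var_pred)
        diff = b_i - b
        cooks = float(diff @ cov_inv @ diff)
        rows.append({
            "index": i,
            "estimate_shift": float(b_i[0] - b[0]),
            "deleted_residual": float(resid),
            "cooks_distance": cooks,
            "influential": abs(resid) > resid_cutoff or cooks > cooks_cutoff,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Sensitivity grids
# --------------------------------------------------------------------------

def sensitivity_grid(records, which: str, grid: list[float],
                     rho: float = 0.8) -> pd.DataFrame:
    """Intercept estimates across a grid of r or rho values.

    ``which == "r"``: restrict to experiments whose correlation is observed
    or derivable, then recompute effect sizes with each fixed r (replacing
    the real one) and refit the intercept-only model; the first row reports
    the fit at the real correlations.
    ``which == "rho"``: refit the same effect-size table at each assumed
    within-study correlation.
    """
    from cbmeta.effect_size import (build_es_table, es_table_to_frame,
                                    g_repeated_measures, observed_correlations)

    grid = [float(x) for x in grid]
    if any(not -1.0 < x < 1.0 for x in grid):
        raise ValueError("grid values must lie in (-1, 1)")

    rows = []
    if which == "r":
        with_r = [rec for rec in records
                  if rec.r is not None or rec.t_paired is not None
                  or rec.sd_diff is not None]
        if len(with_r) < 2:
            raise ValueError("need >= 2 experiments with an observed correlation")
        real = build_es_table(with_r, strategy="observed_plus_floor", floor=0.6)
        fits = [("real", real)]
        for x in grid:
            fits.append((x, [g_repeated_measures(rec, x, r_source="fixed")
                             for rec in with_r]))
        for value, table in fits:
            df = es_table_to_frame(table)
            fit = fit_rve(df["g"].to_numpy(), df["var_g"].to_numpy(),
                          df["study_id"].to_numpy(), rho=rho)
            rows.append({"grid": value, "intercept": fit.coefficients[0],
                         "robust_se": fit.robust_se[0],
                         "ci_low": fit.ci95[0, 0], "ci_high": fit.ci95[0, 1]})
    elif which == "rho":
        df = records if isinstance(records, pd.DataFrame) else es_table_to_frame(records)
        for x in grid:
            fit = fit_rve(df["g"].to_numpy(), df["var_g"].to_numpy(),
                          df["study_id"].to_numpy(), rho=x)
            rows.append({"grid": x, "intercept": fit.coefficients[0],
                         "robust_se": fit.robust_se[0],
                         "ci_low": fit.ci95[0, 0], "ci_high": fit.ci95[0, 1]})
    else:
        raise ValueError("which must be 'r' or 'rho'")
    return pd.DataFrame(rows)


def design_from_moderators(frame: pd.DataFrame, moderators: list[str],
                           ref_levels: dict[str, str] | None = None
                           ) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies for the given moderator columns."""
    ref_levels = ref_levels or {}
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for mod in moderators:
        series = frame[mod].astype(str)
        levels = sorted(series.unique())
        ref = ref_levels.get(mod, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in {mod}")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((series == lev).to_numpy(dtype=float))
            names.append(f"{mod}[{lev}]")
    return np.column_stack(cols), names
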