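"""Two-level hierarchical model with random intercepts and slopes, fit by REML.

The edge-direction model explains each connection z-score by indicators for
"exactly one abnormal endpoint" and "both endpoints abnormal"; the
volume-direction model explains the mean endpoint volume z-score by a single
binary edge-abnormality indicator.  Subjects are the grouping factor with an
unstructured random-effect covariance over intercept and slopes.

Estimation profiles out the fixed effects and the residual variance and
maximizes the restricted likelihood over a log-Cholesky parameterization of
the relative random-effect covariance, which is boundary-safe (variances may
shrink to zero).  Fixed effects come from generalized least squares at the
optimum; p-values are normal-approximation Wald by default with a
Satterthwaite degrees-of-freedom option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .normative import AbnormalityMask, ZTable, split_edge_name

__all__ = [
    "ModelFrame",
    "HierFit",
    "ContrastResult",
    "build_edge_model_frame",
    "build_volume_model_frame",
    "fit_reml",
    "reml_loglik",
    "contrast_one_vs_two",
    "shuffle_null",
    "threshold_scan",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelFrame:
    """Long-format rows (subject, edge) for one model direction."""

    y: np.ndarray                 # response, (n,)
    X: np.ndarray                 # fixed design incl. intercept, (n, p)
    subject: np.ndarray           # integer subject codes, (n,)
    subject_ids: list[str]
    predictor_names: list[str]    # names of X columns after the intercept
    direction: str                # "edge" | "volume"

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def category_counts(self) -> dict[str, int]:
        """Row counts per predictor category (categories are mutually exclusive)."""
        ind = self.X[:, 1:].astype(bool)
        counts = {"none_abnormal": int((~ind.any(axis=1)).sum())}
        for j, name in enumerate(self.predictor_names):
            counts[name] = int(ind[:, j].sum())
        return counts


def _endpoint_columns(edge_names: Sequence[str], node_columns: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    pos = {c: k for k, c in enumerate(node_columns)}
    ia, ib = [], []
    for name in edge_names:
        a, b = split_edge_name(name)
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise ValueError(f"edge {name!r} references region {missing!r} absent from the mask")
        ia.append(pos[a])
        ib.append(pos[b])
    return np.array(ia), np.array(ib)


def build_edge_model_frame(edge_z: ZTable, vol_mask: AbnormalityMask) -> ModelFrame:
    """One row per (subject, edge); V' / V'' derived from the endpoint node masks."""
    if vol_mask.kind != "node":
        raise ValueError("vol_mask must be a node-kind mask")
    if edge_z.frame != vol_mask.frame:
        raise ValueError("z-table and mask frames differ")
    mask = vol_mask.values.loc[edge_z.values.index]
    ia, ib = _endpoint_columns(edge_z.values.columns, mask.columns)
    M = mask.to_numpy(dtype=bool)
    Va, Vb = M[:, ia], M[:, ib]
    v1 = (Va != Vb).astype(float)   # exactly one abnormal endpoint
    v2 = (Va & Vb).astype(float)    # both abnormal
    S, E = v1.shape
    y = edge_z.values.to_numpy(dtype=float).ravel()
    X = np.column_stack([np.ones(S * E), v1.ravel(), v2.ravel()])
    subject = np.repeat(np.arange(S), E)
    return ModelFrame(
        y=y, X=X, subject=subject,
        subject_ids=list(edge_z.values.index),
        predictor_names=["one_abnormal", "two_abnormal"],
        direction="edge",
    )


def build_volume_model_frame(vol_z: ZTable, edge_mask: AbnormalityMask) -> ModelFrame:
    """Response = mean endpoint volume z; single binary edge-abnormality predictor."""
    if edge_mask.kind != "edge":
        raise ValueError("edge_mask must be an edge-kind mask")
    if vol_z.frame != edge_mask.frame:
        raise ValueError("z-table and mask frames differ")
    mask = edge_mask.values.loc[vol_z.values.index]
    ia, ib = _endpoint_columns(mask.columns, vol_z.values.columns)
    Z = vol_z.values.to_numpy(dtype=float)
    resp = (Z[:, ia] + Z[:, ib]) / 2.0
    A = mask.to_numpy(dtype=bool).astype(float)
    S, E = A.shape
    X = np.column_stack([np.ones(S * E), A.ravel()])
    subject = np.repeat(np.arange(S), E)
    return ModelFrame(
        y=resp.ravel(), X=X, subject=subject,
        subject_ids=list(vol_z.values.index),
        predictor_names=["edge_abnormal"],
        direction="volume",
    )


# ---------------------------------------------------------------------------
# REML machinery


def _lam_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    rows, cols = np.tril_indices(q)
    L[rows, cols] = theta
    d = np.arange(q)
    L[d, d] = np.exp(np.clip(np.diag(L), -30.0, 30.0))
    return L


def _precompute(y: np.ndarray, X: np.ndarray, subject: np.ndarray) -> dict:
    order = np.argsort(subject, kind="stable")
    y, X, subject = y[order], X[order], subject[order]
    codes, starts = np.unique(subject, return_index=True)
    bounds = np.append(starts, len(subject))
    XtX, Xty, yty = [], [], []
    for k in range(len(codes)):
        sl = slice(bounds[k], bounds[k + 1])
        Xk, yk = X[sl], y[sl]
        XtX.append(Xk.T @ Xk)
        Xty.append(Xk.T @ yk)
        yty.append(float(yk @ yk))
    XtX = np.stack(XtX)
    sign, logdet_xtx = np.linalg.slogdet(XtX.sum(axis=0))
    return {
        "XtX": XtX,
        "Xty": np.stack(Xty),
        "yty": np.array(yty),
        "n": len(y),
        "p": X.shape[1],
        "logdet_xtx": float(logdet_xtx),
    }


def _profiled(theta: np.ndarray, pre: dict) -> dict:
    """Profiled REML quantities for a given relative-covariance factor."""
    q = pre["p"]
    Lam = _lam_from_theta(theta, q)
    XtX, Xty = pre["XtX"], pre["Xty"]
    B = np.einsum("ab,kbc->kac", Lam.T, XtX)            # Lam' Z'X  (Z = X)
    M = np.einsum("kab,bc->kac", B, Lam) + np.eye(q)[None]
    cho = np.linalg.cholesky(M)
    logdet_m = 2.0 * np.log(np.diagonal(cho, axis1=1, axis2=2)).sum()
    u = np.einsum("ab,kb->ka", Lam.T, Xty)              # Lam' Z'y
    Minv_B = np.linalg.solve(M, B)
    Minv_u = np.linalg.solve(M, u[..., None])[..., 0]
    R_XX = XtX.sum(axis=0) - np.einsum("kap,kaq->pq", B, Minv_B)
    R_Xy = Xty.sum(axis=0) - np.einsum("kap,ka->p", B, Minv_u)
    r_yy = pre["yty"].sum() - np.einsum("ka,ka->", u, Minv_u)
    beta = np.linalg.solve(R_XX, R_Xy)
    r2 = max(float(r_yy - R_Xy @ beta), 1e-300)
    sign, logdet_r = np.linalg.slogdet(R_XX)
    return {
        "Lam": Lam, "M": M, "beta": beta, "r2": r2,
        "logdet_m": float(logdet_m), "logdet_r": float(logdet_r),
        "R_XX": R_XX,
    }


def _reml_ll_profiled(theta: np.ndarray, pre: dict) -> float:
    q = _profiled(theta, pre)
    n, p = pre["n"], pre["p"]
    sigma2 = q["r2"] / (n - p)
    return -0.5 * (
        (n - p) * (_LOG2PI + np.log(sigma2) + 1.0)
        + q["logdet_m"] + q["logdet_r"] - pre["logdet_xtx"]
    )


def _reml_ll_phi(theta: np.ndarray, log_s2: float, pre: dict) -> float:
    """REML log-likelihood with sigma^2 free (beta still profiled)."""
    q = _profiled(theta, pre)
    n, p = pre["n"], pre["p"]
    s2 = np.exp(log_s2)
    return -0.5 * (
        (n - p) * (_LOG2PI + np.log(s2)) + q["r2"] / s2
        + q["logdet_m"] + q["logdet_r"] - pre["logdet_xtx"]
    )


def reml_loglik(frame: ModelFrame, theta: np.ndarray) -> float:
    """Profiled REML log-likelihood of a frame at a given log-Cholesky parameter."""
    pre = _precompute(frame.y, frame.X, frame.subject)
    return _reml_ll_profiled(np.asarray(theta, dtype=float), pre)


@dataclass
class HierFit:
    """Result of a two-level REML fit."""

    direction: str
    fixed_names: list[str]
    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series            # normal-approximation Wald
    cov_beta: pd.DataFrame
    D: pd.DataFrame               # random-effect covariance (response scale)
    sigma2: float
    loglik: float                 # REML criterion at the optimum
    theta: np.ndarray
    converged: bool
    n_rows: int
    n_subjects: int
    counts: dict[str, int]
    random_effects: pd.DataFrame  # per-subject BLUPs
    dropped: list[str] = field(default_factory=list)
    _pre: dict | None = field(default=None, repr=False)

    def satterthwaite(self, contrast: np.ndarray) -> tuple[float, float, float]:
        """(estimate, df, p) for a fixed-effect contrast with Satterthwaite df."""
        if self._pre is None:
            raise ValueError("fit does not retain REML internals")
        kept = [n for n in self.fixed_names if n not in self.dropped]
        c = np.asarray(contrast, dtype=float)
        full_idx = [self.fixed_names.index(n) for n in kept]
        c_kept = c[full_idx]
        if np.any(np.delete(c, full_idx) != 0):
            raise ValueError("contrast involves a dropped fixed effect")
        pre = self._pre
        phi0 = np.append(self.theta, np.log(self.sigma2))

        def varfun(phi: np.ndarray) -> float:
            q = _profiled(phi[:-1], pre)
            s2 = np.exp(phi[-1])
            cov = s2 * np.linalg.inv(q["R_XX"])
            return float(c_kept @ cov @ c_kept)

        def negll(phi: np.ndarray) -> float:
            return -_reml_ll_phi(phi[:-1], phi[-1], pre)

        g = optimize.approx_fprime(phi0, varfun, 1e-5)
        H = _numeric_hessian(negll, phi0, 1e-4)
        try:
            A = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(H + 1e-8 * np.eye(len(phi0)))
        v = varfun(phi0)
        denom = float(g @ A @ g)
        df = 2.0 * v**2 / denom if denom > 0 else np.inf
        df = float(np.clip(df, 1.0, 1e7))
        est = float(c_kept @ self.beta[kept].to_numpy())
        se = np.sqrt(v)
        p = float(2.0 * stats.t.sf(abs(est) / se, df)) if se > 0 else (1.0 if est == 0 else 0.0)
        return est, df, p

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "beta": {k: _float_or_none(v) for k, v in self.beta.items()},
            "se": {k: _float_or_none(v) for k, v in self.se.items()},
            "pvalues": {k: _float_or_none(v) for k, v in self.pvalues.items()},
            "random_effect_covariance": self.D.to_numpy().tolist(),
            "sigma2": self.sigma2,
            "reml_loglik": self.loglik,
            "converged": self.converged,
            "n_rows": self.n_rows,
            "n_subjects": self.n_subjects,
            "counts": self.counts,
            "dropped": self.dropped,
        }


def _float_or_none(v) -> float | None:
    v = float(v)
    return None if np.isnan(v) else v


def _numeric_hessian(f, x0: np.ndarray, h: float) -> np.ndarray:
    m = len(x0)
    H = np.zeros((m, m))
    f0 = f(x0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h
            ej = np.zeros(m); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei) - f(x0 + ej) + f0
            ) / (h * h)
    return H


def fit_reml(
    frame: ModelFrame,
    tol: float = 1e-8,
    max_iter: int = 500,
    keep_internals: bool = True,
) -> HierFit:
    """Maximize the REML criterion and return fixed effects, variance components
    and per-subject BLUPs.

    All-zero predictor columns are dropped (the fit degenerates gracefully,
    e.g. to intercept-only, and the dropped names are reported).  A
    single-subject frame falls back to ordinary least squares with a warning.
    """
    names = ["intercept"] + list(frame.predictor_names)
    keep = [0] + [j + 1 for j in range(len(frame.predictor_names))
                  if frame.X[:, j + 1].any()]
    dropped = [names[j] for j in range(len(names)) if j not in keep]
    if dropped:
        logger.warning("dropping all-zero predictor column(s): %s", dropped)
    X = frame.X[:, keep]
    kept_names = [names[j] for j in keep]
    y = frame.y
    n, p = X.shape
    counts = frame.category_counts()

    if frame.n_subjects < 2:
        warnings.warn("single subject: random effects are inestimable; "
                      "falling back to ordinary least squares", stacklevel=2)
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_hat
        sigma2 = float(resid @ resid) / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return _assemble_fit(
            frame, names, kept_names, dropped, beta_hat, cov,
            D=np.zeros((p, p)), sigma2=sigma2,
            loglik=float("nan"), theta=np.zeros(p * (p + 1) // 2),
            converged=True, counts=counts,
            ranef=np.zeros((frame.n_subjects, p)), pre=None,
        )

    pre = _precompute(y, X, frame.subject)
    q = p
    n_theta = q * (q + 1) // 2
    rows, cols = np.tril_indices(q)

    def neg(theta: np.ndarray) -> float:
        return -_reml_ll_profiled(theta, pre)

    bounds = [(-12.0, 8.0) if r == c else (-60.0, 60.0) for r, c in zip(rows, cols)]
    # two gradient starts guard against the occasional local optimum in the
    # log-Cholesky surface; a single adaptive simplex polish then refines
    best = None
    converged = False
    for diag0 in (np.log(0.5), np.log(0.05)):
        theta0 = np.where(rows == cols, diag0, 0.0)
        res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": max_iter, "ftol": min(tol, 1e-12),
                                         "gtol": 1e-10})
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(neg, best.x, method="Nelder-Mead",
                               options={"maxiter": 300 * n_theta, "adaptive": True,
                                        "fatol": 1e-11, "xatol": 1e-9})
    converged = converged or bool(polish.success)
    if polish.fun < best.fun:
        best = polish
    if not converged:
        logger.warning("REML optimization did not fully converge: %s", best.message)

    theta = best.x
    prof = _profiled(theta, pre)
    sigma2 = prof["r2"] / (n - p)
    beta_hat = prof["beta"]
    cov = sigma2 * np.linalg.inv(prof["R_XX"])
    Lam = prof["Lam"]
    D = sigma2 * (Lam @ Lam.T)

    # per-subject BLUPs: b_k = Lam M_k^{-1} Lam' Z_k'(y_k - X_k beta)
    resid_xty = pre["Xty"] - np.einsum("kab,b->ka", pre["XtX"], beta_hat)
    u = np.einsum("ab,kb->ka", Lam.T, resid_xty)
    ranef = np.einsum(
        "ab,kb->ka", Lam, np.linalg.solve(prof["M"], u[..., None])[..., 0]
    )

    return _assemble_fit(
        frame, names, kept_names, dropped, beta_hat, cov, D, float(sigma2),
        float(-best.fun), theta, converged, counts, ranef,
        pre if keep_internals else None,
    )


def _assemble_fit(
    frame, names, kept_names, dropped, beta_hat, cov, D, sigma2,
    loglik, theta, converged, counts, ranef, pre,
) -> HierFit:
    beta = pd.Series(np.nan, index=names)
    se = pd.Series(np.nan, index=names)
    pvals = pd.Series(np.nan, index=names)
    beta[kept_names] = beta_hat
    se_kept = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se[kept_names] = se_kept
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_kept > 0, beta_hat / se_kept, np.inf * np.sign(beta_hat))
        z = np.where((se_kept == 0) & (beta_hat == 0), 0.0, z)
    pvals[kept_names] = 2.0 * stats.norm.sf(np.abs(z))
    return HierFit(
        direction=frame.direction,
        fixed_names=names,
        beta=beta,
        se=se,
        pvalues=pvals,
        cov_beta=pd.DataFrame(cov, index=kept_names, columns=kept_names),
        D=pd.DataFrame(D, index=kept_names, columns=kept_names),
        sigma2=sigma2,
        loglik=loglik,
        theta=np.asarray(theta, dtype=float),
        converged=converged,
        n_rows=frame.n_rows,
        n_subjects=frame.n_subjects,
        counts=counts,
        random_effects=pd.DataFrame(ranef, index=frame.subject_ids, columns=kept_names),
        dropped=dropped,
        _pre=pre,
    )


@dataclass
class ContrastResult:
    estimate: float
    se: float
    p_wald: float
    p_satterthwaite: float | None = None
    df_satterthwaite: float | None = None


def contrast_one_vs_two(fit: HierFit, satterthwaite: bool = False) -> ContrastResult:
    """Wald test of beta0 = gamma0 (one vs two abnormal endpoints)."""
    if fit.direction != "edge":
        raise ValueError("contrast requires an edge-direction fit")
    c = np.array([0.0, -1.0, 1.0])
    kept = list(fit.cov_beta.index)
    if "one_abnormal" not in kept or "two_abnormal" not in kept:
        raise ValueError("contrast involves a dropped fixed effect")
    est = float(fit.beta["two_abnormal"] - fit.beta["one_abnormal"])
    ck = np.array([c[fit.fixed_names.index(n)] for n in kept])
    var = float(ck @ fit.cov_beta.to_numpy() @ ck)
    se = float(np.sqrt(max(var, 0.0)))
    if se < 1e-10:
        # degenerate (zero-variance) fit: no evidence against equality unless
        # the estimated difference is itself non-negligible
        p = 1.0 if abs(est) < 1e-6 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    out = ContrastResult(estimate=est, se=se, p_wald=p)
    if satterthwaite:
        _, df, ps = fit.satterthwaite(c)
        out.p_satterthwaite, out.df_satterthwaite = ps, df
    return out


def shuffle_null(frame: ModelFrame, seed: int) -> ModelFrame:
    """Permute responses across rows within each subject; predictors untouched."""
    if frame.direction != "edge":
        raise ValueError("shuffle null is defined for the edge-direction frame")
    rng = np.random.default_rng(seed)
    y = frame.y.copy()
    for k in np.unique(frame.subject):
        rows = np.flatnonzero(frame.subject == k)
        y[rows] = y[rows][rng.permutation(rows.size)]
    return ModelFrame(
        y=y, X=frame.X, subject=frame.subject,
        subject_ids=frame.subject_ids,
        predictor_names=frame.predictor_names,
        direction=frame.direction,
    )


def threshold_scan(
    edge_z: ZTable,
    vol_z: ZTable,
    taus: Sequence[float],
    direction: str = "edge",
) -> pd.DataFrame:
    """Refit the requested model at each threshold; returns one summary row per tau."""
    from .normative import threshold_abnormal

    rows = []
    for tau in taus:
        if direction == "edge":
            mask = threshold_abnormal(vol_z, tau)
            frame = build_edge_model_frame(edge_z, mask)
        elif direction == "volume":
            mask = threshold_abnormal(edge_z, tau)
            frame = build_volume_model_frame(vol_z, mask)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        fit = fit_reml(frame, keep_internals=False)
        row = {"tau": float(tau), "converged": fit.converged, **{
            f"count_{k}": v for k, v in fit.counts.items()
        }}
        for name in fit.fixed_names:
            row[f"est_{name}"] = float(fit.beta[name])
            row[f"se_{name}"] = float(fit.se[name])
        rows.append(row)
    return pd.DataFrame(rows)
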