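"""Location/scale batch-effect harmonization with parametric empirical Bayes.

Per-feature batch location and scale effects are estimated after adjusting
for biological covariates, shrunk towards their batch-wide priors (normal
prior on locations, inverse-gamma on scales), and removed.  Covariate
effects are restored, so modelled biology is preserved.

Single-batch input short-circuits to the identity transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_apply", "combat_fit_transform"]


@dataclass
class CombatModel:
    """Fitted harmonization parameters (one location/scale pair per batch x feature)."""

    feature_names: list[str]
    covariate_names: list[str]
    batches: list[str]
    alpha: np.ndarray            # per-feature grand intercept, (f,)
    beta: np.ndarray             # covariate coefficients, (p, f)
    pooled_var: np.ndarray       # per-feature pooled variance, (f,)
    gamma_star: np.ndarray       # EB-shrunk locations, (b, f)
    delta2_star: np.ndarray      # EB-shrunk squared scales, (b, f)
    identity: bool = False       # single-batch no-op
    constant_features: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "covariate_names": self.covariate_names,
            "batches": self.batches,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "identity": self.identity,
            "constant_features": self.constant_features,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            covariate_names=d["covariate_names"],
            batches=d["batches"],
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            pooled_var=np.asarray(d["pooled_var"], dtype=float),
            gamma_star=np.asarray(d["gamma_star"], dtype=float),
            delta2_star=np.asarray(d["delta2_star"], dtype=float),
            identity=d["identity"],
            constant_features=d["constant_features"],
        )


def _design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    return X, ["intercept"] + list(covariates.columns)


def _postvar(sum2: np.ndarray, n: int, a: float, b: float) -> np.ndarray:
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(
    z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
    g_bar: float, t2: float, a: float, b: float, conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the EB posterior means for one batch.

    ``z`` is the (n_batch, f) standardized data, ``g_hat``/``d_hat`` the
    per-feature batch location/scale estimates.
    """
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.sum((z - g_new[None, :]) ** 2, axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def _aprior(d: np.ndarray) -> float:
    m, s2 = float(np.mean(d)), float(np.var(d))
    return (2.0 * s2 + m**2) / s2 if s2 > 0 else 100.0


def _bprior(d: np.ndarray) -> float:
    m, s2 = float(np.mean(d)), float(np.var(d))
    return (m * s2 + m**3) / s2 if s2 > 0 else 1.0


def combat_fit(
    features: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> CombatModel:
    """Fit the harmonization model on a subject x feature matrix.

    Covariates (if any) enter the standardization design so their effects are
    preserved.  Raises on batches with fewer than two subjects (when more than
    one batch is present) and on rank-deficient covariates.  Constant features
    fall back to a per-feature no-op with a warning.
    """
    Y = features.to_numpy(dtype=float)
    n, f = Y.shape
    batch = pd.Series(np.asarray(batch), index=features.index)
    levels = sorted(batch.unique().tolist())
    X_cov, cov_names = _design(covariates, n)

    if len(levels) == 1:
        model = CombatModel(
            feature_names=list(features.columns),
            covariate_names=cov_names[1:],
            batches=levels,
            alpha=np.zeros(f),
            beta=np.zeros((X_cov.shape[1] - 1, f)),
            pooled_var=np.ones(f),
            gamma_star=np.zeros((1, f)),
            delta2_star=np.ones((1, f)),
            identity=True,
        )
        return model

    counts = batch.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 subjects: {list(small.index)}")

    onehot = np.column_stack([(batch == b).to_numpy(dtype=float) for b in levels])
    X = np.column_stack([onehot, X_cov[:, 1:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design (batch + covariates) is rank deficient")

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nb = len(levels)
    batch_means = B[:nb, :]                                     # (b, f)
    w = counts.reindex(levels).to_numpy(dtype=float) / n
    alpha = w @ batch_means                                     # grand intercept
    beta = B[nb:, :]                                            # covariate coefs

    resid = Y - X @ B
    pooled_var = np.mean(resid**2, axis=0)
    constant = pooled_var <= 1e-12
    constant_names = [c for c, k in zip(features.columns, constant) if k]
    if constant_names:
        warnings.warn(
            f"{len(constant_names)} constant feature(s); harmonization is a "
            "no-op for them", stacklevel=2,
        )
    safe_var = np.where(constant, 1.0, pooled_var)

    stand = (Y - alpha[None, :] - X_cov[:, 1:] @ beta) / np.sqrt(safe_var)[None, :]

    gamma_star = np.zeros((nb, f))
    delta2_star = np.ones((nb, f))
    for bi, b in enumerate(levels):
        rows = (batch == b).to_numpy()
        z = stand[rows]
        g_hat = z.mean(axis=0)
        d_hat = z.var(axis=0, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar, t2 = float(np.mean(g_hat)), float(np.var(g_hat))
        t2 = max(t2, 1e-12)
        a, bprior = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(z, g_hat, d_hat, g_bar, t2, a, bprior)
        gamma_star[bi] = g_star
        delta2_star[bi] = np.maximum(d_star, 1e-12)
    gamma_star[:, constant] = 0.0
    delta2_star[:, constant] = 1.0

    return CombatModel(
        feature_names=list(features.columns),
        covariate_names=cov_names[1:],
        batches=levels,
        alpha=alpha,
        beta=beta,
        pooled_var=safe_var,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        constant_features=constant_names,
    )


def combat_apply(
    model: CombatModel,
    features: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a fitted harmonization model; batches must have been seen at fit time."""
    if list(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    Y = features.to_numpy(dtype=float)
    n = Y.shape[0]
    batch = pd.Series(np.asarray(batch), index=features.index)
    if model.identity:
        return features.copy()
    unseen = set(batch.unique()) - set(model.batches)
    if unseen:
        raise ValueError(f"unseen batch label(s): {sorted(unseen)}")
    X_cov, cov_names = _design(covariates, n)
    if cov_names[1:] != model.covariate_names:
        raise ValueError("covariate columns do not match the fitted model")

    cov_part = X_cov[:, 1:] @ model.beta if model.beta.size else 0.0
    stand = (Y - model.alpha[None, :] - cov_part) / np.sqrt(model.pooled_var)[None, :]
    bidx = np.array([model.batches.index(b) for b in batch])
    adj = (stand - model.gamma_star[bidx]) / np.sqrt(model.delta2_star[bidx])
    out = adj * np.sqrt(model.pooled_var)[None, :] + model.alpha[None, :] + cov_part
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def combat_fit_transform(
    features: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CombatModel]:
    model = combat_fit(features, batch, covariates)
    return combat_apply(model, features, batch, covariates), model
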