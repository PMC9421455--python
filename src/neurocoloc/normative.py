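"""Normative z-scoring against healthy controls.

Each feature (region volume or edge FA) is regressed on covariates in
controls with Huber M-estimation, residuals are scaled by the control
residual spread, and subjects are expressed as z-scores.  Z-tables can be
re-framed from anatomical left/right to ipsilateral/contralateral
coordinates by value-flipping right-lateralised patients (controls and
left-lateralised patients are relabelled only), and thresholded into
binary abnormality masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import EDGE_SEP, EdgeIndex, Parcellation

__all__ = [
    "NormativeModel",
    "ZTable",
    "AbnormalityMask",
    "fit_normative",
    "zscore",
    "flip_to_ipsicontra",
    "flip_to_anatomical",
    "threshold_abnormal",
    "percentile_threshold",
    "huber_regress",
    "split_edge_name",
    "DEFAULT_NODE_THRESHOLD",
    "DEFAULT_COLOC_THRESHOLD",
]

logger = logging.getLogger(__name__)

ANATOMICAL = "anatomical"
IPSICONTRA = "ipsicontra"

_SIDE_ORDER = {"ipsi": 0, "contra": 1}


def percentile_threshold(p: float, decimals: int) -> float:
    """Inverse standard-normal CDF at probability ``p``, rounded."""
    return float(np.round(stats.norm.ppf(p), decimals))


#: default region-abnormality cutoff (2.5th percentile of the standard normal)
DEFAULT_NODE_THRESHOLD = percentile_threshold(0.025, 2)
#: default co-localisation abnormality cutoff (5th percentile)
DEFAULT_COLOC_THRESHOLD = percentile_threshold(0.05, 3)


def split_edge_name(name: str) -> tuple[str, str]:
    a, b = name.split(EDGE_SEP)
    return a, b


@dataclass
class ZTable:
    """Subject x feature z-score matrix with a feature-kind and frame tag."""

    values: pd.DataFrame
    kind: str                 # "node" | "edge"
    frame: str = ANATOMICAL   # "anatomical" | "ipsicontra"

    def __post_init__(self) -> None:
        if self.kind not in ("node", "edge"):
            raise ValueError(f"kind must be 'node' or 'edge', got {self.kind!r}")
        if self.frame not in (ANATOMICAL, IPSICONTRA):
            raise ValueError(f"unknown frame {self.frame!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("z-scores must be finite")

    def loc_subjects(self, ids) -> "ZTable":
        return ZTable(self.values.loc[ids], self.kind, self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="subject_id")


@dataclass
class AbnormalityMask:
    """Boolean subject x feature matrix, true exactly where z < threshold."""

    values: pd.DataFrame
    threshold: float
    kind: str
    frame: str = ANATOMICAL

    def to_tsv(self, path: str | Path) -> None:
        self.values.astype(int).to_csv(path, sep="\t", index_label="subject_id")


@dataclass
class NormativeModel:
    """Per-feature robust regression coefficients and control residual scale."""

    coef: pd.DataFrame        # (p+1) x features, rows: intercept + covariates
    sigma: pd.Series          # per-feature residual scale, > 0
    covariate_names: list[str]
    scale: str = "sd"

    def predict(self, covariates: pd.DataFrame) -> pd.DataFrame:
        X = _design(covariates, self.covariate_names)
        return pd.DataFrame(
            X @ self.coef.to_numpy(), index=covariates.index, columns=self.coef.columns
        )


def _design(covariates: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    return np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(dtype=float) for c in names]
    )


def huber_regress(
    X: np.ndarray,
    Y: np.ndarray,
    tuning: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Huber M-estimation for many responses at once.

    ``X`` is (n, p), ``Y`` is (n, f); returns coefficients (p, f).  The scale
    is re-estimated each iteration from the median absolute deviation of the
    residuals; features with zero MAD fall back to the residual SD, and fully
    constant residuals get unit weights (ordinary least squares).
    """
    n, p = X.shape
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    for _ in range(max_iter):
        R = Y - X @ B
        med = np.median(R, axis=0)
        s = 1.4826 * np.median(np.abs(R - med[None, :]), axis=0)
        fallback = s <= 0
        if fallback.any():
            s = np.where(fallback, R.std(axis=0), s)
        s = np.where(s <= 0, 1.0, s)
        U = np.abs(R) / (s[None, :] * tuning)
        W = np.where(U <= 1.0, 1.0, 1.0 / np.maximum(U, 1e-300))
        A = np.einsum("ni,nf,nj->fij", X, W, X)
        b = np.einsum("ni,nf->fi", X, W * Y)
        B_new = np.linalg.solve(A, b[..., None])[..., 0].T
        if np.max(np.abs(B_new - B) / (np.abs(B) + 1.0)) < tol:
            B = B_new
            break
        B = B_new
    return B


def fit_normative(
    control_features: pd.DataFrame,
    control_covariates: pd.DataFrame,
    scale: str = "sd",
) -> NormativeModel:
    """Fit per-feature robust normative regressions on healthy controls.

    ``scale`` chooses the z denominator: plain SD of control residuals
    (default) or a robust MAD-based scale.
    """
    names = list(control_covariates.columns)
    X = _design(control_covariates, names)
    n, p = X.shape
    if n < p + 10:
        raise ValueError(f"need at least {p + 10} controls for {p - 1} covariates, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate design is rank deficient")
    Y = control_features.to_numpy(dtype=float)
    B = huber_regress(X, Y)
    R = Y - X @ B
    if scale == "sd":
        sigma = R.std(axis=0, ddof=1)
    elif scale == "mad":
        sigma = 1.4826 * np.median(np.abs(R - np.median(R, axis=0)[None, :]), axis=0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    bad = sigma <= 0
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} feature(s) have zero residual scale (constant in controls)"
        )
    coef = pd.DataFrame(B, index=["intercept"] + names, columns=control_features.columns)
    return NormativeModel(coef=coef, sigma=pd.Series(sigma, index=control_features.columns),
                          covariate_names=names, scale=scale)


def zscore(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    model: NormativeModel,
    kind: str,
) -> ZTable:
    """Express features as control-referenced z-scores: (observed - predicted) / sigma."""
    if list(features.columns) != list(model.coef.columns):
        raise ValueError("feature columns do not match the normative model")
    pred = model.predict(covariates.loc[features.index])
    z = (features.to_numpy(dtype=float) - pred.to_numpy()) / model.sigma.to_numpy()[None, :]
    return ZTable(pd.DataFrame(z, index=features.index, columns=features.columns), kind=kind)


def _ipsi_region_name(name: str) -> str:
    prefix, base = name.split("_", 1)
    return {"lh": "ipsi", "rh": "contra"}[prefix] + "_" + base


def _canon_ipsi_edge(a: str, b: str) -> str:
    def key(nm: str) -> tuple[int, str]:
        side, base = nm.split("_", 1)
        return _SIDE_ORDER[side], base

    lo, hi = sorted((a, b), key=key)
    return lo + EDGE_SEP + hi


def _flip_rows(subjects: pd.DataFrame, index: pd.Index) -> np.ndarray:
    sub = subjects.set_index("subject_id").loc[index]
    is_pat = (sub["group"] == "patient").to_numpy()
    lat = sub["laterality"].fillna("").to_numpy()
    if (is_pat & ~np.isin(lat, ["L", "R"])).any():
        bad = index[(is_pat & ~np.isin(lat, ["L", "R"]))][:3]
        raise ValueError(f"patients without laterality: {list(bad)}")
    return lat == "R"


def flip_to_ipsicontra(
    ztable: ZTable,
    subjects: pd.DataFrame,
    parcellation: Parcellation,
    edge_index: EdgeIndex | None = None,
) -> ZTable:
    """Re-frame an anatomical z-table into ipsilateral/contralateral coordinates.

    Right-lateralised patients have their hemispheres value-swapped; controls
    (assigned a left reference pseudo-laterality) and left-lateralised
    patients keep their values and are only relabelled.  Edge features whose
    mirrored pair is absent from the edge index are dropped (logged).
    """
    if ztable.frame != ANATOMICAL:
        raise ValueError("input z-table must be in the anatomical frame")
    flip = _flip_rows(subjects, ztable.values.index)
    Z = ztable.values.to_numpy(dtype=float)

    if ztable.kind == "node":
        cols_in = list(ztable.values.columns)
        pos = {c: k for k, c in enumerate(cols_in)}
        out_cols, out_vals = [], []
        for c in cols_in:
            mirror = parcellation.homologue(c).name
            if mirror not in pos:
                raise ValueError(f"region {c!r} has no homologue column {mirror!r}")
            out_cols.append(_ipsi_region_name(c))
            out_vals.append(np.where(flip, Z[:, pos[mirror]], Z[:, pos[c]]))
        df = pd.DataFrame(
            np.column_stack(out_vals), index=ztable.values.index, columns=out_cols
        )
        return ZTable(df, kind="node", frame=IPSICONTRA)

    if edge_index is None:
        raise ValueError("edge_index is required to flip an edge z-table")
    cols_in = list(ztable.values.columns)
    pos = {c: k for k, c in enumerate(cols_in)}
    kept, dropped = [], 0
    out_cols, out_vals = [], []
    for name in cols_in:
        k = edge_index.position_of_name(name)
        m = edge_index.mirror_edge(k)
        if m is None:
            dropped += 1
            continue
        mirror_name = edge_index.names[m]
        if mirror_name not in pos:
            dropped += 1
            continue
        a, b = split_edge_name(name)
        out_cols.append(_canon_ipsi_edge(_ipsi_region_name(a), _ipsi_region_name(b)))
        out_vals.append(np.where(flip, Z[:, pos[mirror_name]], Z[:, pos[name]]))
        kept.append(name)
    if dropped:
        logger.info("dropped %d edge(s) without a mirrored pair", dropped)
    df = pd.DataFrame(
        np.column_stack(out_vals), index=ztable.values.index, columns=out_cols
    )
    return ZTable(df, kind="edge", frame=IPSICONTRA)


def flip_to_anatomical(
    ztable: ZTable,
    subjects: pd.DataFrame,
    parcellation: Parcellation,
    edge_index: EdgeIndex | None = None,
) -> ZTable:
    """Inverse of :func:`flip_to_ipsicontra` on the retained feature set."""
    if ztable.frame != IPSICONTRA:
        raise ValueError("input z-table must be in the ipsi/contra frame")
    flip = _flip_rows(subjects, ztable.values.index)
    Z = ztable.values.to_numpy(dtype=float)
    pos = {c: k for k, c in enumerate(ztable.values.columns)}

    def _anat_to_ipsi_region(name: str) -> str:
        return _ipsi_region_name(name)

    if ztable.kind == "node":
        out_cols, out_vals = [], []
        for r in parcellation:
            ic = _anat_to_ipsi_region(r.name)
            mirror_ic = _anat_to_ipsi_region(parcellation.homologue(r.name).name)
            if ic not in pos:
                continue
            out_cols.append(r.name)
            out_vals.append(np.where(flip, Z[:, pos[mirror_ic]], Z[:, pos[ic]]))
        df = pd.DataFrame(
            np.column_stack(out_vals), index=ztable.values.index, columns=out_cols
        )
        return ZTable(df, kind="node", frame=ANATOMICAL)

    if edge_index is None:
        raise ValueError("edge_index is required to unflip an edge z-table")
    out_cols, out_vals = [], []
    for k, name in enumerate(edge_index.names):
        m = edge_index.mirror_edge(k)
        if m is None:
            continue
        a, b = split_edge_name(name)
        ic = _canon_ipsi_edge(_ipsi_region_name(a), _ipsi_region_name(b))
        am, bm = split_edge_name(edge_index.names[m])
        ic_m = _canon_ipsi_edge(_ipsi_region_name(am), _ipsi_region_name(bm))
        if ic not in pos:
            continue
        out_cols.append(name)
        out_vals.append(np.where(flip, Z[:, pos[ic_m]], Z[:, pos[ic]]))
    df = pd.DataFrame(
        np.column_stack(out_vals), index=ztable.values.index, columns=out_cols
    )
    return ZTable(df, kind="edge", frame=ANATOMICAL)


def threshold_abnormal(ztable: ZTable, tau: float) -> AbnormalityMask:
    """Binary abnormality mask: true exactly where z < tau (tau must be negative)."""
    if tau >= 0:
        raise ValueError(f"threshold must be negative, got {tau}")
    return AbnormalityMask(
        values=ztable.values < tau, threshold=float(tau),
        kind=ztable.kind, frame=ztable.frame,
    )
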