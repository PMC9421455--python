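"""Shared simulation helpers for hierarchical-model tests."""

import numpy as np

from neurocoloc.hlm import ModelFrame

EDGE_TRUTH = {"alpha": -0.38, "beta": -0.45, "gamma": -0.49}


def simulate_edge_frame(
    seed,
    n_subjects=100,
    n_edges=200,
    alpha=-0.38,
    beta=-0.45,
    gamma=-0.49,
    sd_u=0.3,
    sd_v=0.15,
    sd_w=0.2,
    sd_e=1.0,
    p_cat=(0.75, 0.2, 0.05),
):
    """Simulate directly from the two-level edge-direction model."""
    rng = np.random.default_rng(seed)
    ys, Xs, subj = [], [], []
    for k in range(n_subjects):
        u, v, w = rng.normal(0.0, [sd_u, sd_v, sd_w])
        cat = rng.choice([0, 1, 2], size=n_edges, p=p_cat)
        v1 = (cat == 1).astype(float)
        v2 = (cat == 2).astype(float)
        y = (alpha + u) + (beta + v) * v1 + (gamma + w) * v2 + rng.normal(0, sd_e, n_edges)
        ys.append(y)
        Xs.append(np.column_stack([np.ones(n_edges), v1, v2]))
        subj.append(np.full(n_edges, k))
    return ModelFrame(
        y=np.concatenate(ys), X=np.vstack(Xs), subject=np.concatenate(subj),
        subject_ids=[f"s{k}" for k in range(n_subjects)],
        predictor_names=["one_abnormal", "two_abnormal"], direction="edge",
    )


def simulate_volume_frame(
    seed,
    n_subjects=100,
    n_edges=200,
    alpha=-0.21,
    beta=-0.27,
    sd_u=0.25,
    sd_v=0.1,
    sd_e=1.0,
    p_abn=0.1,
):
    rng = np.random.default_rng(seed)
    ys, Xs, subj = [], [], []
    for k in range(n_subjects):
        u, v = rng.normal(0.0, [sd_u, sd_v])
        a = (rng.uniform(size=n_edges) < p_abn).astype(float)
        y = (alpha + u) + (beta + v) * a + rng.normal(0, sd_e, n_edges)
        ys.append(y)
        Xs.append(np.column_stack([np.ones(n_edges), a]))
        subj.append(np.full(n_edges, k))
    return ModelFrame(
        y=np.concatenate(ys), X=np.vstack(Xs), subject=np.concatenate(subj),
        subject_ids=[f"s{k}" for k in range(n_subjects)],
        predictor_names=["edge_abnormal"], direction="volume",
    )


def intercept_only_frame(y_groups):
    """Balanced one-way layout: list of per-subject response arrays."""
    ys, Xs, subj = [], [], []
    for k, y in enumerate(y_groups):
        ys.append(np.asarray(y, dtype=float))
        Xs.append(np.ones((len(y), 1)))
        subj.append(np.full(len(y), k))
    return ModelFrame(
        y=np.concatenate(ys), X=np.vstack(Xs), subject=np.concatenate(subj),
        subject_ids=[f"s{k}" for k in range(len(y_groups))],
        predictor_names=[], direction="edge",
    )


def naive_reml_loglik(frame, Lam, sigma2):
    """Independent dense-matrix REML log-likelihood oracle.

    Builds V = sigma^2 (I + Z Lam Lam' Z') block-per-subject with explicit
    matrices and evaluates the Harville restricted likelihood directly.
    """
    y, X, subject = frame.y, frame.X, frame.subject
    n, p = X.shape
    Psi = Lam @ Lam.T
    V = np.zeros((n, n))
    for k in np.unique(subject):
        rows = np.flatnonzero(subject == k)
        Zk = X[rows]
        V[np.ix_(rows, rows)] = Zk @ Psi @ Zk.T
    V += np.eye(n)
    V *= sigma2
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtVinvX)
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi) - logdet_xtx
        + logdet_v + logdet_x + float(r @ Vinv @ r)
    )
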