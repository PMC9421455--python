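"""Group-level effect-size maps (Cohen's d) and lobe-level aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .normative import ZTable, split_edge_name
from .parcellation import Parcellation

__all__ = ["EffectSizeResult", "cohens_d", "cohens_d_arrays", "lobe_summary"]

logger = logging.getLogger(__name__)


@dataclass
class EffectSizeResult:
    """Per-feature Cohen's d with group means, pooled SD and group sizes."""

    table: pd.DataFrame   # columns: d, mean_patient, mean_control, pooled_sd
    n_patients: int
    n_controls: int

    @property
    def d(self) -> pd.Series:
        return self.table["d"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def cohens_d_arrays(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical pooled-SD Cohen's d per column: (mean(x1) - mean(x2)) / s.

    Returns (d, pooled_sd); columns with zero pooled SD yield NaN d.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    s = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s > 0, (x1.mean(axis=0) - x2.mean(axis=0)) / s, np.nan)
    return d, s


def cohens_d(patient_z: ZTable, control_z: ZTable) -> EffectSizeResult:
    """Effect size per feature between patients and controls (negative = reduced)."""
    if list(patient_z.values.columns) != list(control_z.values.columns):
        raise ValueError("patient and control z-tables have mismatched feature columns")
    xp = patient_z.values.to_numpy(dtype=float)
    xc = control_z.values.to_numpy(dtype=float)
    d, s = cohens_d_arrays(xp, xc)
    table = pd.DataFrame(
        {
            "d": d,
            "mean_patient": xp.mean(axis=0),
            "mean_control": xc.mean(axis=0),
            "pooled_sd": s,
        },
        index=patient_z.values.columns,
    )
    n_undef = int(np.isnan(d).sum())
    if n_undef:
        logger.warning("%d feature(s) have zero pooled SD; d undefined", n_undef)
    return EffectSizeResult(table=table, n_patients=xp.shape[0], n_controls=xc.shape[0])


def _lobe_of(parcellation: Parcellation, framed_name: str) -> str:
    _, base = framed_name.split("_", 1)
    return parcellation["lh_" + base].lobe


def lobe_summary(
    vol_z_patients: ZTable,
    vol_z_controls: ZTable,
    edge_d: EffectSizeResult,
    parcellation: Parcellation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate edge effect sizes to mean-endpoint volume effect sizes, by lobe.

    Operates on ipsi/contra-framed tables.  For each within-lobe edge (both
    endpoints on the same side and in the same lobe), the subject-level mean
    of the two endpoint volume z-scores is computed first, then a Cohen's d
    between patients and controls; the edge pairs that with its own edge d.
    Returns (per-edge table, per-lobe means).  Lobes without within-lobe
    edges are omitted with a log line.
    """
    if vol_z_patients.frame != vol_z_controls.frame:
        raise ValueError("patient and control volume tables must share a frame")
    edge_names = list(edge_d.table.index)
    rows = []
    vp = vol_z_patients.values
    vc = vol_z_controls.values
    for name in edge_names:
        a, b = split_edge_name(name)
        side_a, side_b = a.split("_", 1)[0], b.split("_", 1)[0]
        lobe_a, lobe_b = _lobe_of(parcellation, a), _lobe_of(parcellation, b)
        if side_a != side_b or lobe_a != lobe_b:
            continue
        mean_p = (vp[a].to_numpy() + vp[b].to_numpy()) / 2.0
        mean_c = (vc[a].to_numpy() + vc[b].to_numpy()) / 2.0
        d_vol, _ = cohens_d_arrays(mean_p[:, None], mean_c[:, None])
        rows.append(
            {
                "edge": name,
                "side": side_a,
                "lobe": lobe_a,
                "edge_d": float(edge_d.d[name]),
                "endpoint_volume_d": float(d_vol[0]),
            }
        )
    per_edge = pd.DataFrame(rows, columns=["edge", "side", "lobe", "edge_d", "endpoint_volume_d"])
    per_lobe = (
        per_edge.groupby(["side", "lobe"], as_index=False)[["edge_d", "endpoint_volume_d"]]
        .mean()
        .assign(n_edges=per_edge.groupby(["side", "lobe"]).size().to_numpy())
    )
    seen = set(zip(per_lobe["side"], per_lobe["lobe"]))
    lobes = sorted(set(r.lobe for r in parcellation))
    for side in ("ipsi", "contra", "lh", "rh"):
        for lobe in lobes:
            if (side, lobe) not in seen and any(
                n.startswith(side + "_") for n in vp.columns
            ):
                logger.info("lobe %s/%s has no within-lobe edges; omitted", side, lobe)
    return per_edge, per_lobe
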