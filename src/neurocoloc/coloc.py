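"""Dice co-localisation of node and incident edge abnormalities.

The per-patient Dice similarity is computed exactly as printed in the source
analysis: DS_i = |V'_i ∩ C'| / (|V'_i| + |C'|) over the edge list (note the
conventional factor of 2 is absent, so the maximum is 0.5), DS = (DS_i +
DS_j) / 2.  The co-localisation score is the strict-inequality percentile of
the observed DS within a count-preserving permutation null of the edge
abnormalities; it is invariant to any monotone rescaling of DS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normative import AbnormalityMask, split_edge_name

__all__ = [
    "DiceResult",
    "ColocResult",
    "HemisphereComparison",
    "dice_similarity",
    "colocalisation_score",
    "hemispheric_scores",
    "cohort_colocalisation",
    "compare_hemispheres",
    "DEFAULT_N_PERM",
]

DEFAULT_N_PERM = 5000


@dataclass
class DiceResult:
    """Dice components for one subject (as-printed formula; max 0.5)."""

    ds_i: float
    ds_j: float
    ds: float
    n_vi: int
    n_c: int
    n_vj: int
    inter_i: int
    inter_j: int


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0  # 0/0 -> 0 policy


def _dice_arrays(vi: np.ndarray, c: np.ndarray, vj: np.ndarray) -> DiceResult:
    n_vi, n_c, n_vj = int(vi.sum()), int(c.sum()), int(vj.sum())
    inter_i = int((vi & c).sum())
    inter_j = int((c & vj).sum())
    ds_i = _ratio(inter_i, n_vi + n_c)
    ds_j = _ratio(inter_j, n_c + n_vj)
    return DiceResult(ds_i, ds_j, (ds_i + ds_j) / 2.0, n_vi, n_c, n_vj, inter_i, inter_j)


def _endpoint_vectors(
    vol_mask_row: pd.Series, edge_names: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    vi, vj, regions = [], [], []
    for name in edge_names:
        a, b = split_edge_name(name)
        for r in (a, b):
            if r not in vol_mask_row.index:
                raise ValueError(f"edge {name!r} references region {r!r} absent from the node mask")
        vi.append(bool(vol_mask_row[a]))
        vj.append(bool(vol_mask_row[b]))
        regions.extend((a, b))
    return np.array(vi, dtype=bool), np.array(vj, dtype=bool), sorted(set(regions))


def dice_similarity(vol_mask_row: pd.Series, edge_mask_row: pd.Series) -> DiceResult:
    """Dice similarity between node abnormalities and incident edge abnormalities.

    ``vol_mask_row`` is a boolean Series over region names, ``edge_mask_row``
    a boolean Series over canonical edge names; the nominal "region one" /
    "region two" of each edge follow the canonical edge-name order.
    """
    edge_names = list(edge_mask_row.index)
    vi, vj, _ = _endpoint_vectors(vol_mask_row, edge_names)
    c = edge_mask_row.to_numpy(dtype=bool)
    return _dice_arrays(vi, c, vj)


@dataclass
class ColocResult:
    """Permutation-percentile co-localisation score for one subject and scope."""

    score: float                # NaN when undefined
    defined: bool
    ds_actual: float
    n_perm: int
    seed: int
    scope: str
    n_abnormal_regions: int
    n_abnormal_edges: int
    n_edges: int
    null_ds: np.ndarray | None = None


def _score_arrays(
    vi: np.ndarray, c: np.ndarray, vj: np.ndarray,
    n_region_abn: int, n_perm: int, seed,
    scope: str, keep_null: bool = False,
) -> ColocResult:
    e = c.size
    m = int(c.sum())
    actual = _dice_arrays(vi, c, vj).ds
    if m == 0 or n_region_abn == 0 or e == 0:
        return ColocResult(np.nan, False, actual, n_perm, _seed_int(seed), scope,
                           n_region_abn, m, e)
    rng = np.random.default_rng(seed)
    a_tot, b_tot = int(vi.sum()), int(vj.sum())
    sel = np.argpartition(rng.random((n_perm, e)), m - 1, axis=1)[:, :m]
    inter_i = vi[sel].sum(axis=1)
    inter_j = vj[sel].sum(axis=1)
    ds_i = inter_i / (a_tot + m) if (a_tot + m) > 0 else np.zeros(n_perm)
    ds_j = inter_j / (b_tot + m) if (b_tot + m) > 0 else np.zeros(n_perm)
    null = (ds_i + ds_j) / 2.0
    score = float(np.mean(actual > null))
    return ColocResult(score, True, actual, n_perm, _seed_int(seed), scope,
                       n_region_abn, m, e, null if keep_null else None)


def _seed_int(seed) -> int:
    try:
        return int(seed)
    except (TypeError, ValueError):
        return -1


def colocalisation_score(
    vol_mask_row: pd.Series,
    edge_mask_row: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed=0,
    scope: str = "whole-brain",
    keep_null: bool = False,
) -> ColocResult:
    """Strict-inequality percentile of the observed Dice within the permutation null.

    Permutations resample which edges are abnormal uniformly, preserving the
    abnormal-edge count; node masks are never permuted.  Subjects with no
    abnormal edges or no abnormal regions (among the edges' endpoints) get an
    undefined score (NaN, ``defined=False``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    edge_names = list(edge_mask_row.index)
    vi, vj, regions = _endpoint_vectors(vol_mask_row, edge_names)
    c = edge_mask_row.to_numpy(dtype=bool)
    n_region_abn = int(vol_mask_row[regions].sum())
    return _score_arrays(vi, c, vj, n_region_abn, n_perm, seed, scope, keep_null)


def _scope_columns(edge_names: list[str], side: str) -> list[str]:
    prefix = side + "_"
    out = []
    for name in edge_names:
        a, b = split_edge_name(name)
        if a.startswith(prefix) and b.startswith(prefix):
            out.append(name)
    return out


def hemispheric_scores(
    vol_mask_row: pd.Series,
    edge_mask_row: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed=0,
) -> tuple[ColocResult, ColocResult]:
    """Co-localisation restricted to ipsilateral-only and contralateral-only edges.

    Requires ipsi/contra-framed feature names; interhemispheric edges are
    excluded from both scopes.  An empty scope yields an undefined score.
    """
    edge_names = list(edge_mask_row.index)
    results = []
    for side, scope in (("ipsi", "ipsilateral-only"), ("contra", "contralateral-only")):
        cols = _scope_columns(edge_names, side)
        if not cols:
            results.append(ColocResult(np.nan, False, 0.0, n_perm, _seed_int(seed),
                                       scope, 0, 0, 0))
            continue
        results.append(
            colocalisation_score(vol_mask_row, edge_mask_row[cols], n_perm,
                                 seed=seed, scope=scope)
        )
    return results[0], results[1]


def cohort_colocalisation(
    vol_mask: AbnormalityMask,
    edge_mask: AbnormalityMask,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    hemispheres: bool = True,
) -> pd.DataFrame:
    """Per-subject co-localisation table (whole brain plus per-hemisphere scopes).

    Per-subject random streams are spawned deterministically from ``seed``.
    """
    if vol_mask.kind != "node" or edge_mask.kind != "edge":
        raise ValueError("expected a node mask and an edge mask")
    rows = []
    ids = list(edge_mask.values.index)
    children = np.random.SeedSequence(seed).spawn(len(ids))
    for sid, child in zip(ids, children):
        vrow = vol_mask.values.loc[sid]
        erow = edge_mask.values.loc[sid]
        res = [colocalisation_score(vrow, erow, n_perm, seed=child, scope="whole-brain")]
        if hemispheres:
            res.extend(hemispheric_scores(vrow, erow, n_perm, seed=child))
        for r in res:
            rows.append(
                {
                    "subject_id": sid,
                    "scope": r.scope,
                    "score": r.score,
                    "defined": r.defined,
                    "ds": r.ds_actual,
                    "n_abnormal_regions": r.n_abnormal_regions,
                    "n_abnormal_edges": r.n_abnormal_edges,
                    "n_edges": r.n_edges,
                    "n_perm": n_perm,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HemisphereComparison:
    n_pairs: int
    statistic: float
    pvalue: float
    median_difference: float   # ipsi - contra
    direction: str             # "ipsi>contra" | "contra>ipsi" | "none"


def compare_hemispheres(
    ipsi_scores: np.ndarray | pd.Series,
    contra_scores: np.ndarray | pd.Series,
    min_pairs: int = 5,
) -> HemisphereComparison:
    """Paired rank test (Wilcoxon signed-rank) of ipsi vs contra scores."""
    ipsi = np.asarray(ipsi_scores, dtype=float)
    contra = np.asarray(contra_scores, dtype=float)
    if ipsi.shape != contra.shape:
        raise ValueError("paired score vectors must have the same length")
    ok = np.isfinite(ipsi) & np.isfinite(contra)
    ipsi, contra = ipsi[ok], contra[ok]
    if ipsi.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs, got {ipsi.size}")
    diff = ipsi - contra
    med = float(np.median(diff))
    if np.all(diff == 0):
        return HemisphereComparison(ipsi.size, 0.0, 1.0, 0.0, "none")
    res = stats.wilcoxon(ipsi, contra, zero_method="wilcox", method="auto")
    direction = "ipsi>contra" if med > 0 else ("contra>ipsi" if med < 0 else "none")
    if med == 0:
        mean_diff = float(np.mean(diff))
        direction = "ipsi>contra" if mean_diff > 0 else ("contra>ipsi" if mean_diff < 0 else "none")
    return HemisphereComparison(ipsi.size, float(res.statistic), float(res.pvalue),
                                med, direction)
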