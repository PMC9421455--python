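"""Associations between abnormality measures and clinical variables.

Builds the 3 x 3 grid relating {co-localisation, proportion of abnormal
regions, proportion of abnormal connections} to {epilepsy duration (Pearson
r), surgical outcome and secondary generalisation (Cohen's d plus
Mann-Whitney U p-value)}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import cohens_d_arrays
from .normative import AbnormalityMask

__all__ = [
    "abnormality_burden",
    "duration_correlation",
    "group_comparison",
    "association_table",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


def abnormality_burden(node_mask: AbnormalityMask, edge_mask: AbnormalityMask) -> pd.DataFrame:
    """Per-subject proportion of abnormal regions and abnormal connections."""
    if node_mask.kind != "node" or edge_mask.kind != "edge":
        raise ValueError("expected a node mask and an edge mask")
    if list(node_mask.values.index) != list(edge_mask.values.index):
        raise ValueError("masks cover different subjects")
    return pd.DataFrame(
        {
            "prop_abnormal_regions": node_mask.values.mean(axis=1),
            "prop_abnormal_connections": edge_mask.values.mean(axis=1),
        }
    )


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int


def duration_correlation(values: pd.Series | np.ndarray, duration: pd.Series | np.ndarray) -> CorrelationResult:
    """Two-sided Pearson correlation; incomplete pairs are dropped (logged)."""
    v = np.asarray(values, dtype=float)
    d = np.asarray(duration, dtype=float)
    ok = np.isfinite(v) & np.isfinite(d)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("duration correlation: dropped %d incomplete pair(s)", dropped)
    v, d = v[ok], d[ok]
    if v.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {v.size}")
    if v.std() == 0 or d.std() == 0:
        logger.warning("zero variance; correlation undefined")
        return CorrelationResult(np.nan, np.nan, int(v.size))
    r, p = stats.pearsonr(v, d)
    return CorrelationResult(float(r), float(p), int(v.size))


@dataclass
class GroupComparisonResult:
    d: float
    pvalue: float   # two-sided Mann-Whitney U
    n1: int
    n2: int


def group_comparison(values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> GroupComparisonResult:
    """Unpaired pooled-SD Cohen's d and two-sided Mann-Whitney U p between two groups.

    ``labels`` must be binary; d is mean(group True/1) - mean(group False/0)
    over the pooled SD.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    ok = np.isfinite(v) & ~pd.isna(lab)
    v, lab = v[ok], lab[ok]
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two groups, got {list(levels)}")
    lv = sorted(levels, key=str)
    x0, x1 = v[lab == lv[0]], v[lab == lv[1]]
    if x0.size < 2 or x1.size < 2:
        raise ValueError("need at least 2 subjects per group")
    d, _ = cohens_d_arrays(x1[:, None], x0[:, None])
    u = stats.mannwhitneyu(x1, x0, alternative="two-sided")
    return GroupComparisonResult(float(d[0]), float(u.pvalue), int(x1.size), int(x0.size))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def association_table(
    subjects: pd.DataFrame,
    coloc_scores: pd.Series,
    burden: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """Clinical-association grid for patients.

    Rows: clinical variable x measure.  Duration uses Pearson r; surgical
    outcome (ILAE 1 vs ILAE 2+) and secondary generalisation use Cohen's d
    with a Mann-Whitney U p-value.  No multiplicity correction by default;
    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values.
    """
    pat = subjects[subjects["group"] == "patient"].set_index("subject_id")
    measures = {
        "colocalisation": coloc_scores,
        "prop_abnormal_regions": burden["prop_abnormal_regions"],
        "prop_abnormal_connections": burden["prop_abnormal_connections"],
    }
    rows = []
    for mname, series in measures.items():
        vals = series.reindex(pat.index)
        res = duration_correlation(vals, pat["duration"])
        rows.append({"clinical": "duration", "measure": mname, "test": "pearson",
                     "effect_size": res.r, "pvalue": res.pvalue, "n": res.n})
        outcome_good = (pat["outcome"] == "ILAE1").astype(float)
        res2 = group_comparison(vals, outcome_good)
        rows.append({"clinical": "surgical_outcome", "measure": mname,
                     "test": "cohens_d_mannwhitney",
                     "effect_size": res2.d, "pvalue": res2.pvalue,
                     "n": res2.n1 + res2.n2})
        res3 = group_comparison(vals, pat["secondary_generalisation"])
        rows.append({"clinical": "secondary_generalisation", "measure": mname,
                     "test": "cohens_d_mannwhitney",
                     "effect_size": res3.d, "pvalue": res3.pvalue,
                     "n": res3.n1 + res3.n2})
    out = pd.DataFrame(rows)
    if adjust:
        out["pvalue_bh"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out
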