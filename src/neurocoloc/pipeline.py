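"""End-to-end orchestration: simulate -> validate -> harmonize -> z-score ->
group stats -> hierarchical models -> co-localisation -> associations.

Stages communicate only through serialized artifacts (TSV tables, JSON
models) in the output directory, so partial re-runs are possible.  All
randomness flows from seeds in the :class:`RunConfig`; re-running an
identical config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import abnormality_burden, association_table
from .cohort import CohortConfig, CohortTables, generate_cohort
from .coloc import DEFAULT_N_PERM, cohort_colocalisation, compare_hemispheres
from .combat import combat_fit_transform
from .effects import cohens_d, lobe_summary
from .hlm import (
    build_edge_model_frame,
    build_volume_model_frame,
    fit_reml,
    contrast_one_vs_two,
    shuffle_null,
)
from .normative import (
    DEFAULT_COLOC_THRESHOLD,
    DEFAULT_NODE_THRESHOLD,
    AbnormalityMask,
    ZTable,
    fit_normative,
    flip_to_ipsicontra,
    threshold_abnormal,
    zscore,
)
from .parcellation import EdgeIndex, Parcellation, default_edge_index, load_default_parcellation

__all__ = ["RunConfig", "ValidationReport", "validate_tables", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "harmonize", "zscore", "group-stats", "hlm",
          "coloc", "associations")

VOLUME_COVARIATES = ["age", "sex", "icv"]
EDGE_COVARIATES = ["age", "sex"]


@dataclass
class RunConfig:
    """Single-config description of a full analysis run."""

    outdir: str | Path
    cohort: CohortConfig | None = None     # simulate when set
    input_dir: str | Path | None = None    # else read tables from here
    tau_hlm: float = DEFAULT_NODE_THRESHOLD
    tau_coloc: float = DEFAULT_COLOC_THRESHOLD
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    eligibility_cutoff: float = 0.95

    def validate(self) -> None:
        if self.tau_hlm >= 0 or self.tau_coloc >= 0:
            raise ValueError("abnormality thresholds must be negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if tuple(self.stages) != STAGES[: len(self.stages)]:
            raise ValueError(
                f"stages must be a prefix of the dependency order {STAGES}"
            )
        if self.cohort is None and self.input_dir is None:
            raise ValueError("either a cohort config (simulate) or input_dir is required")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["outdir"] = None  # output location does not affect results
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["outdir"] = str(self.outdir)
        payload["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        cohort = d.get("cohort")
        if cohort is not None:
            for key in ("batch_fractions", "batch_shift_sd", "batch_scale"):
                if key in cohort and cohort[key] is not None:
                    cohort[key] = dict(cohort[key])
            for key in ("age_range", "duration_range", "atrophy_regions"):
                if key in cohort and cohort[key] is not None:
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        return cls(
            outdir=d["outdir"],
            cohort=cohort,
            input_dir=d.get("input_dir"),
            tau_hlm=d.get("tau_hlm", DEFAULT_NODE_THRESHOLD),
            tau_coloc=d.get("tau_coloc", DEFAULT_COLOC_THRESHOLD),
            n_perm=d.get("n_perm", DEFAULT_N_PERM),
            seed=d.get("seed", 0),
            stages=tuple(d.get("stages", STAGES)),
            eligibility_cutoff=d.get("eligibility_cutoff", 0.95),
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_tables(
    subjects: pd.DataFrame,
    volumes: pd.DataFrame,
    edges: pd.DataFrame,
) -> ValidationReport:
    """Structural validation of the three input tables."""
    rep = ValidationReport()
    ids = list(subjects.get("subject_id", []))
    if not ids:
        rep.errors.append("subjects table lacks a subject_id column")
        return rep
    if list(volumes.index) != ids:
        rep.errors.append("volumes rows do not match subjects.subject_id order")
    if list(edges.index) != ids:
        rep.errors.append("edges rows do not match subjects.subject_id order")

    vol = volumes.to_numpy(dtype=float)
    bad = np.argwhere(~(vol > 0))
    for r, c in bad[:10]:
        rep.errors.append(
            f"non-positive volume at subject {volumes.index[r]!r}, region {volumes.columns[c]!r}"
        )
    fa = edges.to_numpy(dtype=float)
    bad = np.argwhere((fa <= 0) | (fa >= 1))
    for r, c in bad[:10]:
        rep.errors.append(
            f"FA out of (0, 1) at subject {edges.index[r]!r}, edge {edges.columns[c]!r}"
        )

    for col in ("age", "sex", "icv", "batch", "group"):
        if col not in subjects.columns:
            rep.errors.append(f"subjects table lacks column {col!r}")
        elif subjects[col].isna().any():
            who = subjects.loc[subjects[col].isna(), "subject_id"].iloc[0]
            rep.errors.append(f"missing {col!r} for subject {who!r}")

    if "laterality" in subjects.columns and "group" in subjects.columns:
        pats = subjects[subjects["group"] == "patient"]
        lat = pats["laterality"].fillna("")
        for sid in pats.loc[~lat.isin(["L", "R"]), "subject_id"]:
            rep.errors.append(f"patient {sid!r} lacks laterality")
    if "duration" in subjects.columns:
        pats = subjects[subjects["group"] == "patient"]
        n_missing = int(pats["duration"].isna().sum())
        if n_missing:
            rep.warnings.append(f"{n_missing} patient(s) lack duration")
    return rep


def _write_fit(fit, contrast, path: Path) -> None:
    payload = fit.to_dict()
    if contrast is not None:
        payload["one_vs_two"] = {
            "estimate": contrast.estimate, "se": contrast.se, "p_wald": contrast.p_wald,
        }
    path.write_text(json.dumps(payload, indent=2))


def _shuffle_mask_within_subjects(mask: AbnormalityMask, seed: int) -> AbnormalityMask:
    """Permute each subject's edge abnormalities across edges (volume-direction null)."""
    rng = np.random.default_rng(seed)
    vals = mask.values.to_numpy(dtype=bool).copy()
    for r in range(vals.shape[0]):
        vals[r] = vals[r][rng.permutation(vals.shape[1])]
    return AbnormalityMask(
        pd.DataFrame(vals, index=mask.values.index, columns=mask.values.columns),
        threshold=mask.threshold, kind=mask.kind, frame=mask.frame,
    )


def run_pipeline(
    config: RunConfig,
    parcellation: Parcellation | None = None,
    edge_index: EdgeIndex | None = None,
) -> dict:
    """Execute the configured stages in dependency order; returns the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "version": __version__}
    report: dict = {"stamp": stamp, "stages": {}}
    stages = set(config.stages)

    if parcellation is None:
        parcellation = load_default_parcellation()
    if edge_index is None:
        edge_index = default_edge_index(parcellation)
    parcellation.to_tsv(outdir / "parcellation.tsv")
    edge_index.to_tsv(outdir / "edge_index.tsv")

    if "simulate" in stages:
        if config.cohort is None:
            raise ValueError("simulate stage requested without a cohort config")
        logger.info("simulate: generating cohort (seed=%d)", config.cohort.seed)
        tables = generate_cohort(config.cohort, parcellation, edge_index)
        tables.write(outdir)
        report["stages"]["simulate"] = {
            "n_subjects": len(tables.subjects),
            "n_regions": tables.volumes.shape[1],
            "n_edges": tables.edges.shape[1],
        }
    elif config.input_dir is not None and len(config.stages) > 0:
        tables = CohortTables.read(config.input_dir)
        tables.write(outdir)

    if "validate" in stages:
        tables = CohortTables.read(outdir)
        rep = validate_tables(tables.subjects, tables.volumes, tables.edges)
        report["stages"]["validate"] = {"errors": rep.errors, "warnings": rep.warnings}
        if not rep.ok:
            raise ValueError(f"input validation failed: {rep.errors[:5]}")
        logger.info("validate: ok (%d warnings)", len(rep.warnings))

    if "harmonize" in stages:
        tables = CohortTables.read(outdir)
        subs = tables.subjects
        batch = subs.set_index("subject_id")["batch"]
        cov_v = subs.set_index("subject_id")[VOLUME_COVARIATES]
        cov_e = subs.set_index("subject_id")[EDGE_COVARIATES]
        vols_h, model_v = combat_fit_transform(tables.volumes, batch, cov_v)
        edges_h, model_e = combat_fit_transform(tables.edges, batch, cov_e)
        vols_h.to_csv(outdir / "volumes_harmonized.tsv", sep="\t", index_label="subject_id")
        edges_h.to_csv(outdir / "edges_harmonized.tsv", sep="\t", index_label="subject_id")
        model_v.to_json(outdir / "combat_volumes.json")
        model_e.to_json(outdir / "combat_edges.json")
        report["stages"]["harmonize"] = {"batches": model_v.batches}
        logger.info("harmonize: %d batches", len(model_v.batches))

    if "zscore" in stages:
        subs = pd.read_csv(outdir / "subjects.tsv", sep="\t")
        vols = pd.read_csv(outdir / "volumes_harmonized.tsv", sep="\t", index_col="subject_id")
        edges = pd.read_csv(outdir / "edges_harmonized.tsv", sep="\t", index_col="subject_id")
        meta = subs.set_index("subject_id")
        controls = meta.index[meta["group"] == "control"]
        model_v = fit_normative(vols.loc[controls], meta.loc[controls, VOLUME_COVARIATES])
        model_e = fit_normative(edges.loc[controls], meta.loc[controls, EDGE_COVARIATES])
        zv = zscore(vols, meta[VOLUME_COVARIATES], model_v, kind="node")
        ze = zscore(edges, meta[EDGE_COVARIATES], model_e, kind="edge")
        zv_ic = flip_to_ipsicontra(zv, subs, parcellation)
        ze_ic = flip_to_ipsicontra(ze, subs, parcellation, edge_index)
        zv_ic.to_tsv(outdir / "volume_z.tsv")
        ze_ic.to_tsv(outdir / "edge_z.tsv")
        report["stages"]["zscore"] = {
            "n_node_features": zv_ic.values.shape[1],
            "n_edge_features": ze_ic.values.shape[1],
        }
        logger.info("zscore: %d node, %d edge features",
                    zv_ic.values.shape[1], ze_ic.values.shape[1])

    def _load_z() -> tuple[pd.DataFrame, ZTable, ZTable]:
        subs = pd.read_csv(outdir / "subjects.tsv", sep="\t")
        zv = ZTable(pd.read_csv(outdir / "volume_z.tsv", sep="\t", index_col="subject_id"),
                    kind="node", frame="ipsicontra")
        ze = ZTable(pd.read_csv(outdir / "edge_z.tsv", sep="\t", index_col="subject_id"),
                    kind="edge", frame="ipsicontra")
        return subs, zv, ze

    if "group-stats" in stages:
        subs, zv, ze = _load_z()
        pat = subs.loc[subs["group"] == "patient", "subject_id"]
        ctl = subs.loc[subs["group"] == "control", "subject_id"]
        region_d = cohens_d(zv.loc_subjects(pat), zv.loc_subjects(ctl))
        edge_d = cohens_d(ze.loc_subjects(pat), ze.loc_subjects(ctl))
        per_edge, per_lobe = lobe_summary(
            zv.loc_subjects(pat), zv.loc_subjects(ctl), edge_d, parcellation
        )
        region_d.to_tsv(outdir / "region_d.tsv")
        edge_d.to_tsv(outdir / "edge_d.tsv")
        per_lobe.to_csv(outdir / "lobe_summary.tsv", sep="\t", index=False)
        report["stages"]["group-stats"] = {
            "min_region_d": float(region_d.d.min()),
            "min_edge_d": float(edge_d.d.min()),
        }
        logger.info("group-stats: min region d %.3f", region_d.d.min())

    if "hlm" in stages:
        subs, zv, ze = _load_z()
        pat = subs.loc[subs["group"] == "patient", "subject_id"]
        ctl = subs.loc[subs["group"] == "control", "subject_id"]
        hlm_report = {}

        vol_mask = threshold_abnormal(zv, config.tau_hlm)
        edge_mask = threshold_abnormal(ze, config.tau_hlm)

        # edge direction: patients, shuffle null, healthy-control null
        frame = build_edge_model_frame(
            ze.loc_subjects(pat),
            AbnormalityMask(vol_mask.values.loc[pat], config.tau_hlm, "node", "ipsicontra"),
        )
        fit = fit_reml(frame, keep_internals=False)
        _write_fit(fit, contrast_one_vs_two(fit), outdir / "hlm_edge.json")
        hlm_report["edge"] = fit.to_dict()["beta"]
        fit_sh = fit_reml(shuffle_null(frame, config.seed), keep_internals=False)
        _write_fit(fit_sh, None, outdir / "hlm_edge_shuffle.json")
        frame_ctl = build_edge_model_frame(
            ze.loc_subjects(ctl),
            AbnormalityMask(vol_mask.values.loc[ctl], config.tau_hlm, "node", "ipsicontra"),
        )
        fit_ctl = fit_reml(frame_ctl, keep_internals=False)
        _write_fit(fit_ctl, None, outdir / "hlm_edge_controls.json")

        # volume direction
        em_pat = AbnormalityMask(edge_mask.values.loc[pat], config.tau_hlm, "edge", "ipsicontra")
        vframe = build_volume_model_frame(zv.loc_subjects(pat), em_pat)
        vfit = fit_reml(vframe, keep_internals=False)
        _write_fit(vfit, None, outdir / "hlm_volume.json")
        hlm_report["volume"] = vfit.to_dict()["beta"]
        em_sh = _shuffle_mask_within_subjects(em_pat, config.seed)
        vfit_sh = fit_reml(build_volume_model_frame(zv.loc_subjects(pat), em_sh),
                           keep_internals=False)
        _write_fit(vfit_sh, None, outdir / "hlm_volume_shuffle.json")
        em_ctl = AbnormalityMask(edge_mask.values.loc[ctl], config.tau_hlm, "edge", "ipsicontra")
        vfit_ctl = fit_reml(build_volume_model_frame(zv.loc_subjects(ctl), em_ctl),
                            keep_internals=False)
        _write_fit(vfit_ctl, None, outdir / "hlm_volume_controls.json")

        report["stages"]["hlm"] = hlm_report
        logger.info("hlm: edge fit %s", hlm_report["edge"])

    if "coloc" in stages:
        subs, zv, ze = _load_z()
        pat = subs.loc[subs["group"] == "patient", "subject_id"]
        vol_mask = threshold_abnormal(zv.loc_subjects(pat), config.tau_coloc)
        edge_mask = threshold_abnormal(ze.loc_subjects(pat), config.tau_coloc)
        table = cohort_colocalisation(vol_mask, edge_mask, config.n_perm, config.seed)
        table.to_csv(outdir / "coloc.tsv", sep="\t", index=False)

        whole = table[table["scope"] == "whole-brain"].set_index("subject_id")
        eligible = whole.index[whole["score"] >= config.eligibility_cutoff]
        ipsi = table[table["scope"] == "ipsilateral-only"].set_index("subject_id")
        contra = table[table["scope"] == "contralateral-only"].set_index("subject_id")
        hemi: dict = {"n_eligible": int(len(eligible))}
        try:
            cmp_res = compare_hemispheres(
                ipsi.loc[eligible, "score"], contra.loc[eligible, "score"]
            )
            hemi.update(
                n_pairs=cmp_res.n_pairs, statistic=cmp_res.statistic,
                pvalue=cmp_res.pvalue, median_difference=cmp_res.median_difference,
                direction=cmp_res.direction,
            )
        except ValueError as exc:
            hemi["refused"] = str(exc)
        (outdir / "hemisphere_test.json").write_text(json.dumps(hemi, indent=2))
        report["stages"]["coloc"] = {
            "n_defined": int(whole["defined"].sum()),
            "hemisphere_test": hemi,
        }
        logger.info("coloc: %d defined scores", int(whole["defined"].sum()))

    if "associations" in stages:
        subs, zv, ze = _load_z()
        pat = subs.loc[subs["group"] == "patient", "subject_id"]
        vol_mask = threshold_abnormal(zv.loc_subjects(pat), config.tau_coloc)
        edge_mask = threshold_abnormal(ze.loc_subjects(pat), config.tau_coloc)
        burden = abnormality_burden(vol_mask, edge_mask)
        coloc = pd.read_csv(outdir / "coloc.tsv", sep="\t")
        whole = coloc[coloc["scope"] == "whole-brain"].set_index("subject_id")["score"]
        assoc = association_table(subs, whole, burden)
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        report["stages"]["associations"] = {"n_cells": int(len(assoc))}
        logger.info("associations: %d cells", len(assoc))

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
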