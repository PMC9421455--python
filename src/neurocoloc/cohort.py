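"""Synthetic cohort generator.

Generates controls and patients with the statistical structure the pipeline
assumes: covariate effects on region volumes (age, sex, ICV) and edge FA
(age, sex), two-scanner location/scale batch effects, planted ipsilateral
atrophy and FA reductions with tunable node/edge coupling, and clinical
variables (duration weakly correlated with planted abnormality load,
surgical outcome, secondary generalisation, hippocampal sclerosis).

All randomness flows from ``CohortConfig.seed`` through fixed
``numpy.random.SeedSequence`` spawn order, so outputs are bit-reproducible
across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parcellation import EdgeIndex, Parcellation, default_edge_index, load_default_parcellation

__all__ = ["CohortConfig", "CohortTables", "PlantedTruth", "generate_cohort", "planted_truth"]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Effect sizes (``d_vol``, ``d_conn``, batch shifts, covariate slopes) are
    expressed in units of the per-feature noise standard deviation, so they
    translate directly into downstream z-score shifts.
    """

    n_controls: int = 96
    n_patients: int = 144
    batch_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"scannerA": 0.47, "scannerB": 0.53}
    )

    # covariates
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.5
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5

    # control feature baselines
    volume_baseline_mean: float = 4500.0
    volume_baseline_spread: float = 0.30   # lognormal sigma of per-region baselines
    volume_noise_frac: float = 0.08        # noise SD as fraction of baseline
    fa_baseline_mean: float = 0.45
    fa_baseline_sd: float = 0.05
    fa_noise_sd: float = 0.04

    # batch effects (per feature class, in noise-SD units / multiplicative)
    batch_shift_sd: Mapping[str, float] = field(
        default_factory=lambda: {"scannerA": 0.0, "scannerB": 0.5}
    )
    batch_scale: Mapping[str, float] = field(
        default_factory=lambda: {"scannerA": 1.0, "scannerB": 1.2}
    )

    # covariate slopes (noise-SD units)
    vol_age_slope_sd: float = -0.03        # per year
    vol_sex_shift_sd: float = 0.20
    vol_icv_slope_sd: float = 0.30         # per ICV SD
    fa_age_slope_sd: float = -0.02         # per year
    fa_sex_shift_sd: float = 0.10

    # planted abnormality plan (ipsilateral frame)
    atrophy_regions: Sequence[str] = (
        "hippocampus", "thalamus", "amygdala",
        "temporalpole", "superiortemporal", "middletemporal",
    )
    d_vol: float = -1.8
    n_edge_targets: int = 150
    d_conn: float = -1.4
    coupling: float = 0.9                  # kappa in [0, 1]
    p_region_involved: float = 0.9
    p_edge_involved: float = 0.9
    extra_region_rate: float = 2.0         # Poisson mean extra regions per patient
    extra_edge_rate: float = 10.0

    # clinical model
    rho_duration: float = 0.2
    duration_mean: float = 22.0
    duration_sd: float = 12.0
    duration_range: tuple[float, float] = (1.0, 60.0)
    p_ilae1: float = 0.57
    p_secondary_gen: float = 0.77
    p_hs: float = 0.51

    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be non-negative")
        tot = float(sum(self.batch_fractions.values()))
        if not np.isclose(tot, 1.0):
            raise ValueError(f"batch fractions must sum to 1, got {tot}")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        for name in ("icv_sd", "volume_noise_frac", "fa_noise_sd", "fa_baseline_sd", "duration_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for p in ("sex_ratio", "p_region_involved", "p_edge_involved",
                  "p_ilae1", "p_secondary_gen", "p_hs"):
            if not (0.0 <= getattr(self, p) <= 1.0):
                raise ValueError(f"{p} must lie in [0, 1]")
        if not (-1.0 <= self.rho_duration <= 1.0):
            raise ValueError("rho_duration must lie in [-1, 1]")


@dataclass
class PlantedTruth:
    """Per-subject ground-truth masks of planted abnormalities (anatomical frame)."""

    node_mask: pd.DataFrame   # subjects x regions, bool
    edge_mask: pd.DataFrame   # subjects x edges, bool


@dataclass
class CohortTables:
    """Raw pipeline input: subject metadata plus feature matrices."""

    subjects: pd.DataFrame    # one row per subject
    volumes: pd.DataFrame     # subject x region, mm^3
    edges: pd.DataFrame       # subject x edge, mean FA

    def validate(self) -> None:
        ids = list(self.subjects["subject_id"])
        if list(self.volumes.index) != ids or list(self.edges.index) != ids:
            raise ValueError("subject rows of the three tables do not agree")
        if (self.volumes.to_numpy() <= 0).any():
            raise ValueError("volumes must be positive")
        fa = self.edges.to_numpy()
        if (fa <= 0).any() or (fa >= 1).any():
            raise ValueError("FA values must lie in (0, 1)")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
        self.volumes.to_csv(outdir / "volumes.tsv", sep="\t", index_label="subject_id")
        self.edges.to_csv(outdir / "edges.tsv", sep="\t", index_label="subject_id")

    @classmethod
    def read(cls, outdir: str | Path) -> "CohortTables":
        outdir = Path(outdir)
        subjects = pd.read_csv(outdir / "subjects.tsv", sep="\t")
        volumes = pd.read_csv(outdir / "volumes.tsv", sep="\t", index_col="subject_id")
        edges = pd.read_csv(outdir / "edges.tsv", sep="\t", index_col="subject_id")
        return cls(subjects, volumes, edges)


def _spawned_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("subjects", "baselines", "truth", "noise", "clinical")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_subjects(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_controls + cfg.n_patients
    group = np.array(["control"] * cfg.n_controls + ["patient"] * cfg.n_patients)
    ids = [f"ctrl-{i+1:03d}" for i in range(cfg.n_controls)] + [
        f"pat-{i+1:03d}" for i in range(cfg.n_patients)
    ]
    batches = list(cfg.batch_fractions)
    probs = np.array([cfg.batch_fractions[b] for b in batches], dtype=float)
    batch = rng.choice(batches, size=n, p=probs / probs.sum())
    age = rng.uniform(*cfg.age_range, size=n)
    sex = (rng.uniform(size=n) < cfg.sex_ratio).astype(int)
    icv = rng.normal(cfg.icv_mean, cfg.icv_sd, size=n)
    laterality = np.where(
        group == "patient", np.where(rng.uniform(size=n) < 0.5, "L", "R"), ""
    )
    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "batch": batch,
            "age": age,
            "sex": sex,
            "icv": icv,
            "laterality": laterality,
        }
    )


def _target_plan(
    cfg: CohortConfig,
    parcellation: Parcellation,
    edge_index: EdgeIndex,
    rng: np.random.Generator,
) -> tuple[list[str], list[int]]:
    """Config-level targets in the left-as-ipsilateral orientation.

    Returns target region names (left hemisphere) and target edge positions.
    Only mirror-safe edges (whose mirrored pair exists) are eligible so that
    targets can be mapped to either anatomical hemisphere.
    """
    left_names = []
    for base in cfg.atrophy_regions:
        name = "lh_" + base
        if name not in parcellation:
            raise ValueError(f"unknown atrophy target region {base!r}")
        left_names.append(name)
    if len(left_names) > parcellation.n_regions:
        raise ValueError("more target regions than regions in the parcellation")

    safe = np.array(edge_index.mirror_symmetric_positions(), dtype=int)
    target_ids = {parcellation[nm].region_id for nm in left_names}
    incident = np.array(
        [k for k in safe if target_ids & set(edge_index.edges[k])], dtype=int
    )
    if cfg.n_edge_targets > safe.size:
        raise ValueError(
            f"n_edge_targets={cfg.n_edge_targets} exceeds the {safe.size} eligible edges"
        )
    n_coupled = rng.binomial(cfg.n_edge_targets, cfg.coupling)
    n_coupled = min(n_coupled, incident.size)
    chosen = list(rng.choice(incident, size=n_coupled, replace=False)) if n_coupled else []
    rest_pool = np.setdiff1d(safe, np.array(chosen, dtype=int))
    n_rest = cfg.n_edge_targets - n_coupled
    if n_rest:
        chosen.extend(rng.choice(rest_pool, size=n_rest, replace=False))
    return left_names, sorted(int(k) for k in chosen)


def _realize_truth(
    cfg: CohortConfig,
    subjects: pd.DataFrame,
    parcellation: Parcellation,
    edge_index: EdgeIndex,
    rng: np.random.Generator,
) -> PlantedTruth:
    target_regions, target_edges = _target_plan(cfg, parcellation, edge_index, rng)
    n = len(subjects)
    node = np.zeros((n, parcellation.n_regions), dtype=bool)
    edge = np.zeros((n, edge_index.n_edges), dtype=bool)

    # per-patient anatomical mapping of the left-oriented plan
    for row in range(n):
        if subjects["group"].iat[row] != "patient":
            continue
        flip = subjects["laterality"].iat[row] == "R"

        def _map_region(name: str) -> int:
            return (
                parcellation.homologue(name).region_id if flip
                else parcellation[name].region_id
            )

        def _map_edge(k: int) -> int:
            if not flip:
                return k
            m = edge_index.mirror_edge(k)
            assert m is not None  # targets restricted to mirror-safe edges
            return m

        keep_r = rng.uniform(size=len(target_regions)) < cfg.p_region_involved
        planted_regions = {
            _map_region(nm) for nm, kp in zip(target_regions, keep_r) if kp
        }
        keep_e = rng.uniform(size=len(target_edges)) < cfg.p_edge_involved
        planted_edges = {_map_edge(k) for k, kp in zip(target_edges, keep_e) if kp}

        n_extra_r = rng.poisson(cfg.extra_region_rate) if cfg.extra_region_rate > 0 else 0
        if n_extra_r:
            pool = np.setdiff1d(np.arange(parcellation.n_regions), list(planted_regions))
            n_extra_r = min(n_extra_r, pool.size)
            planted_regions.update(int(r) for r in rng.choice(pool, n_extra_r, replace=False))

        n_extra_e = rng.poisson(cfg.extra_edge_rate) if cfg.extra_edge_rate > 0 else 0
        if n_extra_e:
            incident = [
                k for k in range(edge_index.n_edges)
                if planted_regions & set(edge_index.edges[k]) and k not in planted_edges
            ]
            for _ in range(n_extra_e):
                use_coupled = incident and rng.uniform() < cfg.coupling
                pool = incident if use_coupled else [
                    k for k in range(edge_index.n_edges) if k not in planted_edges
                ]
                if not pool:
                    break
                k = int(rng.choice(pool))
                planted_edges.add(k)
                if k in incident:
                    incident.remove(k)

        node[row, sorted(planted_regions)] = True
        edge[row, sorted(planted_edges)] = True

    ids = subjects["subject_id"]
    return PlantedTruth(
        node_mask=pd.DataFrame(node, index=ids, columns=parcellation.names),
        edge_mask=pd.DataFrame(edge, index=ids, columns=edge_index.names),
    )


def _draw_clinical(
    cfg: CohortConfig,
    subjects: pd.DataFrame,
    truth: PlantedTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    out = subjects.copy()
    is_pat = (out["group"] == "patient").to_numpy()
    n_pat = int(is_pat.sum())

    counts = (
        truth.node_mask.to_numpy().sum(axis=1) + truth.edge_mask.to_numpy().sum(axis=1)
    )[is_pat].astype(float)
    if n_pat and counts.std() > 0:
        zc = (counts - counts.mean()) / counts.std()
        rho = cfg.rho_duration
    else:
        zc = np.zeros(n_pat)
        rho = 0.0
    zdur = rho * zc + np.sqrt(1.0 - rho**2) * rng.normal(size=n_pat)
    duration = np.clip(
        cfg.duration_mean + cfg.duration_sd * zdur, *cfg.duration_range
    )

    out["duration"] = np.nan
    out.loc[is_pat, "duration"] = duration
    outcome = np.where(rng.uniform(size=n_pat) < cfg.p_ilae1, "ILAE1", "ILAE2+")
    out["outcome"] = ""
    out.loc[is_pat, "outcome"] = outcome
    out["secondary_generalisation"] = np.nan
    out.loc[is_pat, "secondary_generalisation"] = (
        rng.uniform(size=n_pat) < cfg.p_secondary_gen
    ).astype(float)
    out["hs"] = np.nan
    out.loc[is_pat, "hs"] = (rng.uniform(size=n_pat) < cfg.p_hs).astype(float)
    return out


def _covariate_shift_volumes(cfg: CohortConfig, s: pd.DataFrame) -> np.ndarray:
    age_c = s["age"].to_numpy() - np.mean(cfg.age_range)
    icv_z = (s["icv"].to_numpy() - cfg.icv_mean) / cfg.icv_sd
    return (
        cfg.vol_age_slope_sd * age_c
        + cfg.vol_sex_shift_sd * s["sex"].to_numpy()
        + cfg.vol_icv_slope_sd * icv_z
    )


def _covariate_shift_edges(cfg: CohortConfig, s: pd.DataFrame) -> np.ndarray:
    age_c = s["age"].to_numpy() - np.mean(cfg.age_range)
    return cfg.fa_age_slope_sd * age_c + cfg.fa_sex_shift_sd * s["sex"].to_numpy()


def planted_truth(
    config: CohortConfig,
    parcellation: Parcellation | None = None,
    edge_index: EdgeIndex | None = None,
) -> PlantedTruth:
    """Ground-truth planted abnormality masks, consistent with ``generate_cohort``."""
    config.validate()
    if parcellation is None:
        parcellation = load_default_parcellation()
    if edge_index is None:
        edge_index = default_edge_index(parcellation)
    rngs = _spawned_rngs(config.seed)
    subjects = _draw_subjects(config, rngs["subjects"])
    return _realize_truth(config, subjects, parcellation, edge_index, rngs["truth"])


def generate_cohort(
    config: CohortConfig,
    parcellation: Parcellation | None = None,
    edge_index: EdgeIndex | None = None,
) -> CohortTables:
    """Generate the three cohort tables. Deterministic given ``config.seed``."""
    config.validate()
    if parcellation is None:
        parcellation = load_default_parcellation()
    if edge_index is None:
        edge_index = default_edge_index(parcellation)
    rngs = _spawned_rngs(config.seed)
    subjects = _draw_subjects(config, rngs["subjects"])
    truth = _realize_truth(config, subjects, parcellation, edge_index, rngs["truth"])
    subjects = _draw_clinical(config, subjects, truth, rngs["clinical"])

    n = len(subjects)
    rng = rngs["baselines"]
    vol_base = config.volume_baseline_mean * rng.lognormal(
        0.0, config.volume_baseline_spread, size=parcellation.n_regions
    )
    vol_sigma = config.volume_noise_frac * vol_base
    fa_base = np.clip(
        rng.normal(config.fa_baseline_mean, config.fa_baseline_sd, size=edge_index.n_edges),
        0.2, 0.7,
    )
    fa_sigma = np.full(edge_index.n_edges, config.fa_noise_sd)

    shift = np.array([config.batch_shift_sd[b] for b in subjects["batch"]])
    scale = np.array([config.batch_scale[b] for b in subjects["batch"]])

    rng_n = rngs["noise"]
    cov_v = _covariate_shift_volumes(config, subjects)
    eps_v = rng_n.normal(size=(n, parcellation.n_regions))
    vols = (
        vol_base[None, :]
        + vol_sigma[None, :]
        * (
            cov_v[:, None]
            + shift[:, None]
            + scale[:, None] * eps_v
            + config.d_vol * truth.node_mask.to_numpy()
        )
    )
    vols = np.maximum(vols, 1.0)

    cov_e = _covariate_shift_edges(config, subjects)
    eps_e = rng_n.normal(size=(n, edge_index.n_edges))
    fa = (
        fa_base[None, :]
        + fa_sigma[None, :]
        * (
            cov_e[:, None]
            + shift[:, None]
            + scale[:, None] * eps_e
            + config.d_conn * truth.edge_mask.to_numpy()
        )
    )
    clip_rate = float(np.mean((fa <= 0.01) | (fa >= 0.99)))
    if clip_rate >= 0.001:
        warnings.warn(
            f"FA clipping rate {clip_rate:.2%} exceeds 0.1%; "
            "check the configured baselines and effect sizes",
            stacklevel=2,
        )
    fa = np.clip(fa, 0.01, 0.99)

    ids = subjects["subject_id"]
    tables = CohortTables(
        subjects=subjects,
        volumes=pd.DataFrame(vols, index=ids, columns=parcellation.names),
        edges=pd.DataFrame(fa, index=ids, columns=edge_index.names),
    )
    tables.validate()
    return tables
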