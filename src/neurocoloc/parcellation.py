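"""Region catalogue and edge-index machinery.

The default catalogue holds 82 cortical and subcortical regions
(Desikan-Killiany cortex plus seven subcortical structures per hemisphere)
with lobar labels.  Edges are canonical unordered region pairs; a
deterministic pseudo-anatomical default adjacency at the scale of
tractography-atlas connectomes (1,289 edges) is provided for testing and
simulation, and arbitrary user adjacencies can be loaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionDef",
    "Parcellation",
    "EdgeIndex",
    "load_default_parcellation",
    "build_edge_index",
    "default_edge_index",
    "classify_edges",
    "EDGE_SEP",
]

#: separator used in edge column names ("<region_i>--<region_j>")
EDGE_SEP = "--"

LOBES = ("frontal", "temporal", "parietal", "occipital", "cingulate", "insula", "subcortical")
HEMISPHERES = ("left", "right")

_CORTICAL_LOBES: dict[str, tuple[str, ...]] = {
    "frontal": (
        "caudalmiddlefrontal", "frontalpole", "lateralorbitofrontal",
        "medialorbitofrontal", "paracentral", "parsopercularis",
        "parsorbitalis", "parstriangularis", "precentral",
        "rostralmiddlefrontal", "superiorfrontal",
    ),
    "temporal": (
        "bankssts", "entorhinal", "fusiform", "inferiortemporal",
        "middletemporal", "parahippocampal", "superiortemporal",
        "temporalpole", "transversetemporal",
    ),
    "parietal": (
        "inferiorparietal", "postcentral", "precuneus",
        "superiorparietal", "supramarginal",
    ),
    "occipital": ("cuneus", "lateraloccipital", "lingual", "pericalcarine"),
    "cingulate": (
        "caudalanteriorcingulate", "isthmuscingulate",
        "posteriorcingulate", "rostralanteriorcingulate",
    ),
    "insula": ("insula",),
}

_SUBCORTICAL = ("thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala", "accumbens")

_HEMI_PREFIX = {"left": "lh_", "right": "rh_"}


@dataclass(frozen=True)
class RegionDef:
    """One region of a parcellation."""

    region_id: int
    name: str
    hemisphere: str
    lobe: str
    subcortical: bool

    @property
    def base(self) -> str:
        """Region name without the hemisphere prefix."""
        return self.name.split("_", 1)[1]


class Parcellation:
    """Ordered catalogue of named regions with left/right homologous pairs."""

    def __init__(self, regions: Sequence[RegionDef]):
        regions = list(regions)
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for r in regions:
            if r.hemisphere not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {r.hemisphere!r} for {r.name}")
            if r.lobe not in LOBES:
                raise ValueError(f"unknown lobe {r.lobe!r} for {r.name}")
            if not (0 <= r.region_id < len(regions)):
                raise ValueError(f"region_id {r.region_id} out of range")
        if len(set(r.region_id for r in regions)) != len(regions):
            raise ValueError("region ids must be unique")
        # homologous pairing: every base name present exactly once per hemisphere
        by_hemi: dict[str, set[str]] = {"left": set(), "right": set()}
        for r in regions:
            if r.base in by_hemi[r.hemisphere]:
                raise ValueError(f"duplicate base name {r.base!r} in {r.hemisphere}")
            by_hemi[r.hemisphere].add(r.base)
        if by_hemi["left"] != by_hemi["right"]:
            raise ValueError("regions do not come in left/right homologous pairs")
        self.regions = regions
        self._by_name = {r.name: r for r in regions}
        self._by_id = {r.region_id: r for r in regions}

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return self.n_regions

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, key: int | str) -> RegionDef:
        if isinstance(key, str):
            return self._by_name[key]
        return self._by_id[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def homologue(self, name: str) -> RegionDef:
        """Return the region on the opposite hemisphere with the same base name."""
        r = self._by_name[name]
        other = "right" if r.hemisphere == "left" else "left"
        return self._by_name[_HEMI_PREFIX[other] + r.base]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "lobe": [r.lobe for r in self.regions],
                "subcortical": [r.subcortical for r in self.regions],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        regions = [
            RegionDef(int(row.region_id), str(row.name1), str(row.hemisphere),
                      str(row.lobe), bool(row.subcortical))
            for row in df.rename(columns={"name": "name1"}).itertuples(index=False)
        ]
        return cls(regions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def load_default_parcellation() -> Parcellation:
    """Return the packaged 82-region catalogue (41 homologous pairs).

    Region order is left hemisphere first (cortical by lobe, then
    subcortical), then the right hemisphere in the same base order.
    """
    bases: list[tuple[str, str, bool]] = []
    for lobe, names in _CORTICAL_LOBES.items():
        bases.extend((n, lobe, False) for n in names)
    bases.extend((n, "subcortical", True) for n in _SUBCORTICAL)
    regions = []
    rid = 0
    for hemi in HEMISPHERES:
        for base, lobe, sub in bases:
            regions.append(RegionDef(rid, _HEMI_PREFIX[hemi] + base, hemi, lobe, sub))
            rid += 1
    return Parcellation(regions)


def edge_name(name_i: str, name_j: str) -> str:
    return f"{name_i}{EDGE_SEP}{name_j}"


class EdgeIndex:
    """Canonical, duplicate-free list of unordered region pairs (i < j by id)."""

    def __init__(self, parcellation: Parcellation, pairs: Iterable[tuple[int, int]]):
        canon: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        n = parcellation.n_regions
        for i, j in pairs:
            if i == j:
                raise ValueError(f"self-loop edge ({i}, {j}) is not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) references an unknown region")
            pair = (min(i, j), max(i, j))
            if pair in seen:
                continue
            seen.add(pair)
            canon.append(pair)
        canon.sort()
        self.parcellation = parcellation
        self.edges = canon
        self._pos = {p: k for k, p in enumerate(canon)}
        self.names = [
            edge_name(parcellation[i].name, parcellation[j].name) for i, j in canon
        ]
        self._name_pos = {nm: k for k, nm in enumerate(self.names)}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __len__(self) -> int:
        return self.n_edges

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self._pos

    def position(self, i: int, j: int) -> int:
        return self._pos[(min(i, j), max(i, j))]

    def position_of_name(self, name: str) -> int:
        return self._name_pos[name]

    def endpoints(self, k: int) -> tuple[RegionDef, RegionDef]:
        i, j = self.edges[k]
        return self.parcellation[i], self.parcellation[j]

    def mirror_edge(self, k: int) -> int | None:
        """Position of the hemisphere-mirrored edge, or None if absent."""
        i, j = self.edges[k]
        mi = self.parcellation.homologue(self.parcellation[i].name).region_id
        mj = self.parcellation.homologue(self.parcellation[j].name).region_id
        pair = (min(mi, mj), max(mi, mj))
        return self._pos.get(pair)

    def mirror_symmetric_positions(self) -> list[int]:
        """Positions of edges whose mirror is also in the index."""
        return [k for k in range(self.n_edges) if self.mirror_edge(k) is not None]

    def to_frame(self) -> pd.DataFrame:
        p = self.parcellation
        return pd.DataFrame(
            {
                "edge_id": np.arange(self.n_edges),
                "region_i": [p[i].name for i, _ in self.edges],
                "region_j": [p[j].name for _, j in self.edges],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, parcellation: Parcellation) -> "EdgeIndex":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            (parcellation[str(a)].region_id, parcellation[str(b)].region_id)
            for a, b in zip(df["region_i"], df["region_j"])
        ]
        return cls(parcellation, pairs)


def build_edge_index(
    parcellation: Parcellation,
    adjacency: np.ndarray | Iterable[tuple[int, int] | tuple[str, str]],
) -> EdgeIndex:
    """Build a canonical edge index from a boolean adjacency matrix or pair list.

    The adjacency matrix must be symmetric with a false diagonal.  Pairs may
    be given as region ids or region names.
    """
    if isinstance(adjacency, np.ndarray):
        a = np.asarray(adjacency, dtype=bool)
        n = parcellation.n_regions
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            bad = int(np.flatnonzero(a.diagonal())[0])
            raise ValueError(f"self-loop at region {parcellation[bad].name!r}")
        ii, jj = np.nonzero(np.triu(a, 1))
        pairs = list(zip(ii.tolist(), jj.tolist()))
    else:
        pairs = []
        for a_, b_ in adjacency:
            if isinstance(a_, str):
                a_ = parcellation[a_].region_id
            if isinstance(b_, str):
                b_ = parcellation[b_].region_id
            pairs.append((int(a_), int(b_)))
    return EdgeIndex(parcellation, pairs)


def default_edge_index(
    parcellation: Parcellation | None = None,
    n_edges: int = 1289,
    seed: int = 82,
) -> EdgeIndex:
    """Deterministic pseudo-anatomical edge set, mirror-symmetric by construction.

    Candidate pairs are scored by anatomical plausibility (within-lobe and
    within-hemisphere pairs enriched, homologous interhemispheric pairs always
    present) plus a seeded jitter, and mirror-orbits are added in score order
    until exactly ``n_edges`` edges are reached.
    """
    if parcellation is None:
        parcellation = load_default_parcellation()
    p = parcellation
    rng = np.random.default_rng(seed)

    # homologous interhemispheric edges (self-mirroring orbits of size 1)
    left = [r for r in p if r.hemisphere == "left"]
    homologous = [(r.region_id, p.homologue(r.name).region_id) for r in left]

    # orbits of size 2: a pair plus its mirror
    orbits: list[tuple[float, tuple[int, int], tuple[int, int]]] = []
    seen: set[frozenset[tuple[int, int]]] = set()
    for i in range(p.n_regions):
        for j in range(i + 1, p.n_regions):
            ri, rj = p[i], p[j]
            mi = p.homologue(ri.name).region_id
            mj = p.homologue(rj.name).region_id
            if (min(mi, mj), max(mi, mj)) == (i, j):
                continue  # homologous pair, already included
            orbit = frozenset([(i, j), (min(mi, mj), max(mi, mj))])
            if orbit in seen:
                continue
            seen.add(orbit)
            same_hemi = ri.hemisphere == rj.hemisphere
            same_lobe = ri.lobe == rj.lobe
            if same_hemi and same_lobe:
                w = 3.0
            elif same_hemi:
                w = 1.0
            else:
                w = 0.25
            w += rng.uniform(0, 1)
            orbits.append((w, *sorted(orbit)))

    n_rest = n_edges - len(homologous)
    if n_rest < 0 or n_rest % 2 != 0:
        raise ValueError(
            f"n_edges={n_edges} incompatible with {len(homologous)} homologous edges"
        )
    orbits.sort(key=lambda t: (-t[0], t[1]))
    pairs = list(homologous)
    for _, e1, e2 in orbits[: n_rest // 2]:
        pairs.extend([e1, e2])
    return EdgeIndex(parcellation, pairs)


def classify_edges(
    edge_index: EdgeIndex,
    parcellation: Parcellation,
    ipsi_side: str,
) -> np.ndarray:
    """Label each edge 'ipsilateral-only', 'contralateral-only' or 'interhemispheric'.

    ``ipsi_side`` names the anatomical hemisphere playing the ipsilateral role.
    """
    if ipsi_side not in HEMISPHERES:
        raise ValueError(f"ipsi_side must be one of {HEMISPHERES}")
    labels = []
    for i, j in edge_index.edges:
        hi, hj = parcellation[i].hemisphere, parcellation[j].hemisphere
        if hi != hj:
            labels.append("interhemispheric")
        elif hi == ipsi_side:
            labels.append("ipsilateral-only")
        else:
            labels.append("contralateral-only")
    return np.array(labels)
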