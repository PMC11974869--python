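"""Initial-condition builder for the three resting-state layouts.

``disjoint``     NKG2D clusters first, then KIR2DL1 clusters forbidden
                 from touching them.
``overlapping``  every NKG2D cluster gets a KIR2DL1 cluster whose center
                 of mass coincides with its own; surplus KIR2DL1
                 clusters are placed away from the NKG2D clusters.
``homogeneous``  no clusters; receptors are scattered over the whole box
                 and every chamber is unmarked (free diffusion).

Receptors are placed uniformly at random within the chambers of their
own cluster mask; clusters that end up empty are removed.  Ligands
(NKG2DL, HLA-C) and the cytosolic/kinase pools (SFK, Vav1, SHP-1) are
always uniform over the whole box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryParams
from .maps import (BinaryMap, DEFAULT_N_CLUSTERS, MEAN_CLUSTER_SIZE,
                   generate_cluster_map)
from .network import CellCounts, ReactionNetwork

MODES = ("disjoint", "overlapping", "homogeneous")


def com_periodic(coords: np.ndarray, n: int) -> np.ndarray:
    """Center of mass of chamber coordinates on a periodic lattice,
    computed per axis via the circular mean."""
    coords = np.asarray(coords, dtype=float)
    out = np.empty(2)
    for ax in range(2):
        theta = coords[:, ax] * (2 * np.pi / n)
        mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        out[ax] = (mean * n / (2 * np.pi)) % n
    return out


@dataclass
class InitialConfig:
    """A fully specified initial state for the spatial simulation."""

    mode: str
    geom: GeometryParams
    nkg2d_map: BinaryMap
    kir_map: BinaryMap
    chamber_counts: np.ndarray            # (n_chambers, n_species) int32
    species_names: list[str]
    moiety_matrix: np.ndarray             # (n_moieties, n_species)
    cell_counts: CellCounts
    pruned_clusters: dict[str, int] = field(default_factory=dict)
    n_clusters: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    @property
    def mask_nkg2d(self) -> np.ndarray:
        return self.nkg2d_map.grid.ravel()

    @property
    def mask_kir(self) -> np.ndarray:
        return self.kir_map.grid.ravel()

    def species_totals(self) -> np.ndarray:
        return self.chamber_counts.sum(axis=0)

    def save_npz(self, path) -> None:
        """Single-archive serialization (masks + counts + mode + seed)
        for exact replay."""
        np.savez_compressed(
            path, mode=self.mode, n_side=self.geom.n_side,
            mask_nkg2d=self.nkg2d_map.grid, mask_kir=self.kir_map.grid,
            chamber_counts=self.chamber_counts,
            species_names=np.array(self.species_names),
            moiety_matrix=self.moiety_matrix,
            cell_counts=np.array([self.cell_counts.nkg2d,
                                  self.cell_counts.kir2dl1,
                                  self.cell_counts.nkg2dl,
                                  self.cell_counts.hlac,
                                  self.cell_counts.sfk,
                                  self.cell_counts.vav1,
                                  self.cell_counts.shp1]),
            seed=-1 if self.seed is None else self.seed)

    @classmethod
    def load_npz(cls, path) -> "InitialConfig":
        from .network import CellCounts
        z = np.load(path, allow_pickle=False)
        cc = CellCounts(*(int(v) for v in z["cell_counts"]))
        seed = int(z["seed"])
        return cls(mode=str(z["mode"]), geom=GeometryParams(n_side=int(z["n_side"])),
                   nkg2d_map=BinaryMap(grid=z["mask_nkg2d"], receptor_type="NKG2D"),
                   kir_map=BinaryMap(grid=z["mask_kir"], receptor_type="KIR2DL1"),
                   chamber_counts=z["chamber_counts"],
                   species_names=[str(s) for s in z["species_names"]],
                   moiety_matrix=z["moiety_matrix"], cell_counts=cc,
                   seed=None if seed < 0 else seed)

    def pruned_fraction(self, receptor_type: str) -> float:
        nucleated = self.n_clusters.get(receptor_type, 0)  # before pruning
        pruned = self.pruned_clusters.get(receptor_type, 0)
        return pruned / nucleated if nucleated else 0.0


def _place_uniform(rng: np.random.Generator, count: int,
                   allowed: np.ndarray, out: np.ndarray) -> None:
    """Scatter ``count`` molecules uniformly over ``allowed`` chamber
    indices, accumulating into the chamber-count column ``out``."""
    if count == 0:
        return
    chambers = rng.choice(allowed, size=count, replace=True)
    np.add.at(out, chambers, 1)


def _prune_empty(bmap: BinaryMap, occupancy: np.ndarray, n: int) -> int:
    """Remove clusters containing no receptor; returns how many."""
    kept, pruned = [], 0
    for cl in bmap.clusters:
        if occupancy[cl[:, 0] * n + cl[:, 1]].sum() == 0:
            bmap.grid[cl[:, 0], cl[:, 1]] = 0
            pruned += 1
        else:
            kept.append(cl)
    bmap.clusters = kept
    return pruned


def _paired_kir_clusters(nkg2d_map: BinaryMap, n_total: int,
                         geom: GeometryParams, rng: np.random.Generator,
                         mean_size: int) -> BinaryMap:
    """KIR2DL1 map for the fully overlapping mode: one cluster per NKG2D
    cluster, center of mass coincident, then the surplus placed without
    touching any NKG2D cluster."""
    n = geom.n_side
    n_pairs = len(nkg2d_map.clusters)
    if n_total < n_pairs:
        raise ValueError(
            f"overlapping mode needs at least as many KIR2DL1 clusters "
            f"({n_total}) as NKG2D clusters ({n_pairs})")
    grid = np.zeros((n, n), dtype=np.uint8)
    placed: list[np.ndarray] = []
    # each paired KIR2DL1 cluster adopts its partner's footprint: the
    # fully overlapped limit, in which the centers of mass coincide
    # exactly and the two receptor types share every chamber of the
    # cluster (an independently drawn shape overlaps its partner only
    # ~40% at the 40 nm chamber scale, which is not "fully overlapping"
    # at the SHP-1 interaction range)
    for cl in nkg2d_map.clusters:
        grid[cl[:, 0], cl[:, 1]] = 1
        placed.append(cl.copy())
    surplus = generate_cluster_map(
        n_total - n_pairs, geom=geom, rng=rng, receptor_type="KIR2DL1",
        mean_size=mean_size, forbidden=(nkg2d_map.grid | grid))
    grid |= surplus.grid
    return BinaryMap(grid=grid, receptor_type="KIR2DL1",
                     provenance="synthetic", clusters=placed + surplus.clusters)


def make_config(mode: str,
                cell_counts: CellCounts,
                network: ReactionNetwork,
                rng: np.random.Generator | int | None = None,
                geom: GeometryParams | None = None,
                n_clusters: dict[str, int] | None = None,
                mean_cluster_size: int = MEAN_CLUSTER_SIZE,
                maps: tuple[BinaryMap, BinaryMap] | None = None) -> InitialConfig:
    """Build an initial configuration in the requested layout mode.

    ``maps`` may supply pre-generated (NKG2D, KIR2DL1) binary maps (e.g.
    derived from images); otherwise synthetic maps are generated with
    ``n_clusters`` clusters per type (defaults tuned to the source-image
    cluster densities).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    geom = geom or network.geom
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = geom.n_side
    ncl = dict(DEFAULT_N_CLUSTERS)
    if n_clusters:
        ncl.update(n_clusters)

    if mode == "homogeneous":
        empty = np.zeros((n, n), dtype=np.uint8)
        nkg2d_map = BinaryMap(grid=empty.copy(), receptor_type="NKG2D")
        kir_map = BinaryMap(grid=empty.copy(), receptor_type="KIR2DL1")
    elif maps is not None:
        nkg2d_map, kir_map = maps
    elif mode == "disjoint":
        nkg2d_map = generate_cluster_map(ncl["NKG2D"], geom=geom, rng=rng,
                                         receptor_type="NKG2D",
                                         mean_size=mean_cluster_size)
        kir_map = generate_cluster_map(ncl["KIR2DL1"], geom=geom, rng=rng,
                                       receptor_type="KIR2DL1",
                                       mean_size=mean_cluster_size,
                                       forbidden=nkg2d_map.grid)
    else:  # overlapping
        nkg2d_map = generate_cluster_map(ncl["NKG2D"], geom=geom, rng=rng,
                                         receptor_type="NKG2D",
                                         mean_size=mean_cluster_size)
        kir_map = _paired_kir_clusters(nkg2d_map, ncl["KIR2DL1"], geom, rng,
                                       mean_cluster_size)

    placed_clusters = {"NKG2D": len(nkg2d_map.clusters),
                       "KIR2DL1": len(kir_map.clusters)}
    names = network.species_names()
    counts = np.zeros((geom.n_chambers, network.n_species), dtype=np.int32)
    all_chambers = np.arange(geom.n_chambers)

    def allowed_for(mask: np.ndarray) -> np.ndarray:
        if mode == "homogeneous" or mask.sum() == 0:
            return all_chambers
        return np.flatnonzero(mask.ravel())

    col = {s: names.index(s) for s in
           ("NKG2D", "KIR2DL1", "NKG2DL", "HLAC", "SFK", "Vav1", "SHP1")
           if s in names}
    _place_uniform(rng, cell_counts.nkg2d, allowed_for(nkg2d_map.grid),
                   counts[:, col["NKG2D"]])
    _place_uniform(rng, cell_counts.kir2dl1, allowed_for(kir_map.grid),
                   counts[:, col["KIR2DL1"]])
    for name, cnt in (("NKG2DL", cell_counts.nkg2dl), ("HLAC", cell_counts.hlac),
                      ("SFK", cell_counts.sfk), ("Vav1", cell_counts.vav1),
                      ("SHP1", cell_counts.shp1)):
        _place_uniform(rng, cnt, all_chambers, counts[:, col[name]])

    pruned = {"NKG2D": _prune_empty(nkg2d_map, counts[:, col["NKG2D"]], n),
              "KIR2DL1": _prune_empty(kir_map, counts[:, col["KIR2DL1"]], n)}

    if mode == "disjoint" and (nkg2d_map.grid & kir_map.grid).any():
        raise AssertionError("disjoint masks intersect")

    return InitialConfig(mode=mode, geom=geom, nkg2d_map=nkg2d_map,
                         kir_map=kir_map, chamber_counts=counts,
                         species_names=names,
                         moiety_matrix=network.moiety_matrix(),
                         cell_counts=cell_counts,
                         pruned_clusters=pruned, n_clusters=placed_clusters,
                         seed=seed)


def colocalization_fraction(config: InitialConfig) -> float:
    """Fraction of NKG2D-moiety molecules sharing a chamber with at
    least one KIR2DL1-moiety molecule."""
    from .network import MOIETIES
    nkg_w = config.moiety_matrix[MOIETIES.index("NKG2D")]
    kir_w = config.moiety_matrix[MOIETIES.index("KIR2DL1")]
    nkg = config.chamber_counts @ nkg_w
    kir = config.chamber_counts @ kir_w
    total = nkg.sum()
    if total == 0:
        raise ValueError("no NKG2D molecules in configuration")
    return float(nkg[kir > 0].sum() / total)
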