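"""Spatial kinetic Monte Carlo driver.

Wraps the compiled SSA kernel: reactions fire within a chamber,
diffusion is a hop to one of the four nearest neighbours at a
per-direction rate D/l0**2 (total 4D/l0**2, so a free molecule's mean
square displacement is 4*D*t), with periodic boundaries in x and y.
Cluster-confined species never cross the boundary of their own mask.

The observable followed throughout is the total phosphorylated Vav1 in
the box: free pVav1 plus pVav1 still docked on an NKG2D complex (or on
a ligand-free NKG2D when the activating proofreading reset is off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InitialConfig, make_config
from .geometry import GeometryParams
from .network import CellCounts, ReactionNetwork
from ._kernel import run_ssa, STATUS_NEGATIVE, STATUS_BUDGET

#: species whose copy numbers add up to total phosphorylated Vav1
PVAV1_SPECIES = ("pVav1", "A2P", "NKG2Dp2P")


class SimulationError(RuntimeError):
    pass


def _neighbors(n: int) -> np.ndarray:
    idx = np.arange(n * n).reshape(n, n)
    out = np.empty((n * n, 4), dtype=np.int32)
    out[:, 0] = np.roll(idx, -1, axis=0).ravel()   # +x
    out[:, 1] = np.roll(idx, 1, axis=0).ravel()    # -x
    out[:, 2] = np.roll(idx, -1, axis=1).ravel()   # +y
    out[:, 3] = np.roll(idx, 1, axis=1).ravel()    # -y
    return out


def _confinement_tables(masks: list[np.ndarray], neighbors: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per confinement class and chamber: which of the four hops stay on
    the same mask label, and how many."""
    n_ch = neighbors.shape[0]
    n_cls = len(masks)
    allow = np.zeros((n_cls, n_ch, 4), dtype=np.uint8)
    for c, mask in enumerate(masks):
        if mask is None:
            allow[c] = 1
        else:
            m = mask.ravel().astype(np.int8)
            for d in range(4):
                allow[c, :, d] = m == m[neighbors[:, d]]
    ndirs = allow.sum(axis=2).astype(np.int8)
    return ndirs, allow


def _compiled_arrays(network: ReactionNetwork) -> dict:
    cache = getattr(network, "_engine_arrays", None)
    if cache is not None:
        return cache
    idx = network.species_index
    n_rx = len(network.reactions)
    r1 = np.empty(n_rx, dtype=np.int32)
    r2 = np.full(n_rx, -1, dtype=np.int32)
    nprod = np.zeros(n_rx, dtype=np.int32)
    prods = np.zeros((n_rx, 4), dtype=np.int32)
    for j, r in enumerate(network.reactions):
        r1[j] = idx(r.reactants[0])
        if r.order == 2:
            r2[j] = idx(r.reactants[1])
        if len(r.products) > 4:
            raise SimulationError("more than 4 products not supported")
        nprod[j] = len(r.products)
        for p, name in enumerate(r.products):
            prods[j, p] = idx(name)
    # per-species list of reactions it participates in as a reactant
    n_sp = network.n_species
    by_sp: list[list[int]] = [[] for _ in range(n_sp)]
    for j in range(n_rx):
        by_sp[r1[j]].append(j)
        if r2[j] >= 0 and r2[j] != r1[j]:
            by_sp[r2[j]].append(j)
    rxs_ptr = np.zeros(n_sp + 1, dtype=np.int32)
    rxs_ptr[1:] = np.cumsum([len(b) for b in by_sp])
    rxs_idx = np.array([j for b in by_sp for j in b] or [0], dtype=np.int32)
    arrays = {
        "r1": r1, "r2": r2, "kprop": network.propensity_const.astype(float),
        "rxs_ptr": rxs_ptr, "rxs_idx": rxs_idx,
        "nprod": nprod, "prods": prods,
        "conf": network.confinement.astype(np.int64),
        "hop_dir_rate": (network.diffusion *
                         network.geom.hop_rate_per_direction).astype(float),
    }
    network._engine_arrays = arrays
    return arrays


@dataclass
class Trajectory:
    """Sampled time course of one stochastic realization."""

    times: np.ndarray
    species_totals: np.ndarray           # (n_times, n_species) int64
    species_names: list[str]
    seed: int
    n_events: int
    grids: np.ndarray | None = None      # (n_times, n_chambers, n_species)

    def total(self, name: str) -> np.ndarray:
        return self.species_totals[:, self.species_names.index(name)]

    @property
    def pvav1_total(self) -> np.ndarray:
        cols = [self.species_names.index(s) for s in PVAV1_SPECIES
                if s in self.species_names]
        return self.species_totals[:, cols].sum(axis=1)

    def moiety_totals(self, network: ReactionNetwork) -> np.ndarray:
        """(n_times, n_moieties); constant rows mean conservation holds."""
        return self.species_totals @ network.moiety_matrix().T


def simulate(config: InitialConfig, network: ReactionNetwork,
             t_end: float, sample_times=None, seed: int = 0,
             record_grid: bool = False,
             max_events: int = 2 ** 62) -> Trajectory:
    """Run one exact-SSA realization from an initial configuration."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if sample_times is None:
        sample_times = np.arange(0.0, t_end + 1e-9, 1.0)
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if sample_times[-1] > t_end:
        raise ValueError("sample times must not exceed t_end")

    arr = _compiled_arrays(network)
    geom = config.geom
    counts = np.ascontiguousarray(config.chamber_counts.copy())
    if counts.shape != (geom.n_chambers, network.n_species):
        raise SimulationError("configuration does not match network")
    neighbors = _neighbors(geom.n_side)
    ndirs, allow = _confinement_tables(
        [None, config.mask_nkg2d, config.mask_kir], neighbors)

    n_samp = len(sample_times)
    totals_out = np.zeros((n_samp, network.n_species), dtype=np.int64)
    if record_grid:
        grids_out = np.zeros((n_samp, geom.n_chambers, network.n_species),
                             dtype=np.int32)
    else:
        grids_out = np.zeros((1, 1, 1), dtype=np.int32)

    status, n_events = run_ssa(
        counts, neighbors, ndirs, allow, arr["conf"], arr["hop_dir_rate"],
        arr["r1"], arr["r2"], arr["kprop"], arr["nprod"], arr["prods"],
        arr["rxs_ptr"], arr["rxs_idx"],
        sample_times, np.uint64(seed) & np.uint64(0x7FFFFFFFFFFFFFFF),
        totals_out, grids_out, record_grid, np.int64(max_events))
    if status == STATUS_NEGATIVE:
        raise SimulationError("negative molecule count: internal inconsistency")
    if status == STATUS_BUDGET:
        raise SimulationError(f"event budget exceeded after {n_events} events")

    return Trajectory(times=sample_times, species_totals=totals_out,
                      species_names=network.species_names(), seed=int(seed),
                      n_events=int(n_events),
                      grids=grids_out if record_grid else None)


@dataclass
class EnsembleResult:
    """Replicate ensembles of pVav1 time courses across ligand doses."""

    mode: str
    hlac: int
    doses: np.ndarray                    # (n_doses,)
    times: np.ndarray                    # (n_times,)
    pvav1: np.ndarray                    # (n_doses, n_reps, n_times)
    seeds: np.ndarray                    # (n_doses, n_reps)
    kp_activating: bool = True
    kp_inhibitory: bool = True
    pruned_fraction_nkg2d: float = float("nan")

    @property
    def n_reps(self) -> int:
        return self.pvav1.shape[1]

    def responses_at(self, t: float) -> dict[int, np.ndarray]:
        """Per-dose samples of total pVav1 at the sample time nearest t."""
        ti = int(np.argmin(np.abs(self.times - t)))
        return {int(d): self.pvav1[i, :, ti] for i, d in enumerate(self.doses)}

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.doses):
            for ti, t in enumerate(self.times):
                x = self.pvav1[i, :, ti]
                rows.append({"mode": self.mode, "hlac": self.hlac,
                             "dose": int(d), "time": float(t),
                             "n": len(x), "mean": x.mean(),
                             "sd": x.std(ddof=1),
                             "se": x.std(ddof=1) / np.sqrt(len(x))})
        return pd.DataFrame(rows)

    def save_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["mode"] = self.mode
            f.attrs["hlac"] = self.hlac
            f.attrs["kp_activating"] = self.kp_activating
            f.attrs["kp_inhibitory"] = self.kp_inhibitory
            f.create_dataset("doses", data=self.doses)
            f.create_dataset("times", data=self.times)
            f.create_dataset("pvav1", data=self.pvav1)
            f.create_dataset("seeds", data=self.seeds)

    @classmethod
    def load_hdf5(cls, path) -> "EnsembleResult":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(mode=str(f.attrs["mode"]), hlac=int(f.attrs["hlac"]),
                       kp_activating=bool(f.attrs["kp_activating"]),
                       kp_inhibitory=bool(f.attrs["kp_inhibitory"]),
                       doses=f["doses"][:], times=f["times"][:],
                       pvav1=f["pvav1"][:], seeds=f["seeds"][:])


def run_ensemble(network: ReactionNetwork, mode: str, doses,
                 n_reps: int, t_end: float, sample_times=None,
                 seed: int = 0, hlac: int = 4213,
                 base_counts: CellCounts | None = None,
                 geom: GeometryParams | None = None,
                 n_clusters: dict[str, int] | None = None) -> EnsembleResult:
    """Simulate fresh initial configurations for every replicate.

    Each (dose, replicate) pair draws a brand-new cluster layout and
    molecule placement plus an independent SSA stream, all derived from
    the master seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    doses = np.asarray(list(doses), dtype=int)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if sample_times is None:
        sample_times = np.arange(0.0, t_end + 1e-9, 1.0)
    sample_times = np.asarray(sample_times, dtype=float)
    base = base_counts or CellCounts()

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(doses.size * n_reps)
    pvav = np.zeros((doses.size, n_reps, len(sample_times)))
    seeds = np.zeros((doses.size, n_reps), dtype=np.int64)
    pruned = []
    k = 0
    for i, dose in enumerate(doses):
        counts = CellCounts(nkg2d=base.nkg2d, kir2dl1=base.kir2dl1,
                            nkg2dl=int(dose), hlac=hlac, sfk=base.sfk,
                            vav1=base.vav1, shp1=base.shp1)
        for rep in range(n_reps):
            st = child[k].generate_state(2)
            k += 1
            cfg_rng = np.random.default_rng(int(st[0]))
            cfg = make_config(mode, counts, network, rng=cfg_rng, geom=geom,
                              n_clusters=n_clusters)
            sim_seed = int(st[1]) & 0x7FFFFFFFFFFFFFFF
            traj = simulate(cfg, network, t_end, sample_times, seed=sim_seed)
            pvav[i, rep] = traj.pvav1_total
            seeds[i, rep] = sim_seed
            pruned.append(cfg.pruned_fraction("NKG2D"))
    kp_act = bool(network.kp_reactions("activating"))
    kp_inh = bool(network.kp_reactions("inhibitory"))
    return EnsembleResult(mode=mode, hlac=int(hlac), doses=doses,
                          times=sample_times, pvav1=pvav, seeds=seeds,
                          kp_activating=kp_act, kp_inhibitory=kp_inh,
                          pruned_fraction_nkg2d=float(np.mean(pruned)))
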