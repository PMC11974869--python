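"""Deterministic limit of the activating module and diffusion-time
estimators.

The activating (NKG2D-only) part of the network closes on 14 state
variables: the free pools NKG2DL, NKG2D, SFK, Vav1, pVav1 and nine
ligand-bound complex states.  Treating the whole box as well mixed,
mass-action kinetics with per-pair rates ``propensity / n_chambers``
give the deterministic rate equations whose solution sets the local
biochemical time scale (~3-4 s) against which the diffusion-limited
ligand-encounter times are compared.

The encounter times use the classic distinct-sites-visited estimate for
an n-step random walk on the square lattice, ``pi*n / ln(5.692*n)``,
applied to the average Voronoi cell a ligand must explore before meeting
a receptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .geometry import GeometryParams
from .network import ReactionNetwork, build_network

#: number of state variables of the activating deterministic model
N_ACTIVATING_STATES = 14


class OdeError(RuntimeError):
    pass


def activating_subnetwork_indices(network: ReactionNetwork) -> tuple[list[int], list[int]]:
    """Indices of activating-arm species and of the reactions acting
    purely on them (no KIR2DL1 / HLA-C moiety involved)."""
    candidates = {s.name for s in network.species
                  if not (s.moieties.get("KIR2DL1") or s.moieties.get("HLAC")
                          or s.moieties.get("SHP1"))}
    keep_rx = [j for j, r in enumerate(network.reactions)
               if all(n in candidates for n in (*r.reactants, *r.products))]
    # only species the activating reactions actually touch (this drops
    # the proofreading-off receptor states from a KP-on network)
    touched = {n for j in keep_rx
               for n in (*network.reactions[j].reactants,
                         *network.reactions[j].products)}
    keep_sp = [i for i, s in enumerate(network.species) if s.name in touched]
    return keep_sp, keep_rx


@dataclass
class OdeSolution:
    times: np.ndarray
    states: np.ndarray            # (n_times, n_states)
    names: list[str]
    pvav1_total: np.ndarray
    steady_state_pvav1: float     # plateau value (max over the course)
    t95: float                    # first time reaching 95% of the plateau

    def conserved_totals(self, moiety_matrix: np.ndarray) -> np.ndarray:
        return self.states @ moiety_matrix.T

    def to_dataframe(self):
        """Time course as a tidy table (one column per state plus the
        pVav1 total); convenient for CSV export."""
        import pandas as pd
        df = pd.DataFrame(self.states, columns=self.names)
        df.insert(0, "time", self.times)
        df["pVav1_total"] = self.pvav1_total
        return df


def solve_activating_ode(network: ReactionNetwork | None = None,
                         initial_complexes: int = 1,
                         t_end: float = 40.0,
                         counts: dict[str, float] | None = None,
                         n_chambers: int | None = None,
                         rtol: float = 1e-8, atol: float = 1e-10) -> OdeSolution:
    """Integrate the deterministic activating module.

    ``initial_complexes`` freshly formed (unphosphorylated) complexes
    are placed in an otherwise resting box containing the default SFK
    and Vav1 pools; bimolecular propensities are scaled by 1/n_chambers
    (whole-box well-mixed limit).  Returns the full time course plus the
    plateau pVav1 per box and the time to reach 95% of it.
    """
    network = network or build_network()
    sp_idx, rx_idx = activating_subnetwork_indices(network)
    names = [network.species[i].name for i in sp_idx]
    if network.kp_reactions("activating") and len(names) != N_ACTIVATING_STATES:
        raise OdeError(
            f"activating module has {len(names)} states, expected "
            f"{N_ACTIVATING_STATES}; the reaction table is inconsistent")
    pos = {n: k for k, n in enumerate(names)}
    n_ch = n_chambers if n_chambers is not None else network.geom.n_chambers

    # stoichiometry and rates restricted to the activating arm
    n_rx = len(rx_idx)
    react = np.full((n_rx, 2), -1, dtype=int)
    rates = np.empty(n_rx)
    stoich = np.zeros((len(names), n_rx))
    for a, j in enumerate(rx_idx):
        r = network.reactions[j]
        k = network.propensity_const[j]
        if r.order == 2:
            k /= n_ch
        rates[a] = k
        for m, nm in enumerate(r.reactants):
            react[a, m] = pos[nm]
            stoich[pos[nm], a] -= 1
        for nm in r.products:
            stoich[pos[nm], a] += 1

    y0 = np.zeros(len(names))
    base = {"SFK": network.default_counts.get("SFK", 0),
            "Vav1": network.default_counts.get("Vav1", 0),
            "A0": initial_complexes}
    if counts:
        base.update(counts)
    for nm, v in base.items():
        if nm in pos:
            y0[pos[nm]] = v

    r1, r2 = react[:, 0], react[:, 1]
    bi = r2 >= 0

    def rhs(t, y):
        flux = rates * y[r1]
        flux[bi] *= y[r2[bi]]
        return stoich @ flux

    times = np.linspace(0.0, t_end, max(int(t_end * 20), 200))
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=times, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise OdeError(f"integration failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)

    phospho = np.array([nm in ("pVav1", "A2P", "NKG2Dp2P") for nm in names])
    pvav = states[:, phospho].sum(axis=1)
    plateau = float(pvav.max(initial=0.0))
    if plateau > 0:
        t95 = float(times[np.argmax(pvav >= 0.95 * plateau)])
    else:
        t95 = 0.0
    return OdeSolution(times=times, states=states, names=names,
                       pvav1_total=pvav, steady_state_pvav1=plateau, t95=t95)


# ---------------------------------------------------------------------
# random-walk coverage estimates
# ---------------------------------------------------------------------

def visited_sites(n: float) -> float:
    """Expected number of distinct sites visited by an n-step random
    walk on the square lattice: pi*n / ln(5.692*n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.pi * n / np.log(5.692 * n)


def visit_time(M: int, fraction_of_cell: float = 1.0,
               t_step: float = 1.0 / 6.0,
               geom: GeometryParams | None = None) -> float:
    """Time for a ligand to visit a fraction of its average Voronoi cell.

    With M ligands in the box the average Voronoi cell contains
    ``n_chambers / M`` chambers; the number of distinct chambers visited
    in time tau is ``visited_sites(tau / t_step)``.  Solves for tau by
    bracketing root-find.

    ``t_step`` is the mean hop time; the default 1/6 s corresponds to
    the slow (~0.01 um^2/s) membrane diffusion of NKG2DL.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 < fraction_of_cell <= 1:
        raise ValueError("fraction_of_cell must be in (0, 1]")
    if t_step <= 0:
        raise ValueError("t_step must be positive")
    geom = geom or GeometryParams()
    n_v = fraction_of_cell * geom.n_chambers / M

    def f(n):
        return visited_sites(n) - n_v

    lo, hi = 1.0 + 1e-9, 4.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e12:
            raise RuntimeError("no root found for visit time")
    if f(lo) > 0:
        # fewer than visited_sites(1) chambers requested: sub-step time
        return t_step * n_v / visited_sites(lo)
    n_steps = brentq(f, lo, hi)
    return float(n_steps * t_step)
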