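# nkrsim

Spatially resolved stochastic model of early NK-cell signaling: how the
submicron clustering of the activating receptor **NKG2D** and the
inhibitory receptor **KIR2DL1** in the *resting* membrane controls the
cell's ability to tell low from high doses of activating ligand within
the first minute of target-cell contact.

The package is for computational immunologists and systems biologists
who want to simulate membrane-proximal receptor signaling on a lattice,
reproduce the disjoint-vs-overlapping cluster comparison, or reuse the
building blocks (spatial SSA engine, binary-map spatial statistics,
channel-capacity machinery) on related problems.

## Model in brief

The NK/target interface is a 3.64 × 3.64 µm box of 91 × 91 chambers
(l₀ = 40 nm, 8281 chambers).  Reactions are same-chamber; diffusion is
a nearest-neighbour hop at per-direction rate D/l₀² (periodic in x–y).
NKG2D (53 copies) and KIR2DL1 (11,686 copies) live in submicron
clusters (mean 8 chambers) that are disjoint, fully overlapping, or
absent (homogeneous) at t = 0; confined species never leave their
cluster.  Signaling follows the canonical cascades — NKG2D:ligand →
SFK-phosphorylated DAP10 → Vav1 recruitment and phosphorylation;
KIR2DL1:HLA-C → phosphorylated ITIMs → SHP-1, which dephosphorylates
pVav1 within ≤ 40 nm — with irreversible kinetic-proofreading resets on
ligand unbinding.  Total phosphorylated Vav1 (free + complex-docked) is
the activation read-out.

Dose discrimination is quantified as a channel: input s = NKG2DL copy
number, output o = pVav1 at the read-out time,

    MI(o;s) = Σ_s Σ_o P(o,s) log₂ [P(o,s) / (R(o) Q(s))],
    CC      = max_Q MI(o;s)   (Blahut–Arimoto iteration),

with MI ≳ 1 bit meaning two dose levels (low vs high) are reliably
separable.  Gamma fits of the per-dose pVav1 distributions give
closed-form Kullback–Leibler separations between doses.

## Worked example

```python
from nkrsim import (build_network, solve_activating_ode, visit_time,
                    make_config, CellCounts, colocalization_fraction)
from nkrsim.engine import simulate

net = build_network()                       # packaged reaction table

sol = solve_activating_ode(net, initial_complexes=1)
print(sol.steady_state_pvav1, sol.t95)      # 0.382, 3.8 s
print(53 * sol.steady_state_pvav1)          # 20.2
print(visit_time(200, 1.0))                 # 13.5 s

counts = CellCounts.from_network(net, nkg2dl=400, hlac=4213)
cfg = make_config("disjoint", counts, net, rng=42)
traj = simulate(cfg, net, t_end=20.0, sample_times=[0, 5, 10, 15, 20],
                seed=43)
print(list(traj.pvav1_total))               # [0, 10, 20, 14, 22]
```

Reading the numbers: a single NKG2D–ligand complex drives pVav1 to a
deterministic plateau of **0.382** molecules within **3.8 s**, so a
fully engaged pool of 53 receptors supports about **20** pVav1 — and
indeed the stochastic disjoint-layout trajectory at the highest ligand
dose climbs to ~20 by 15–20 s, the time at which a ligand has covered
its average Voronoi cell (**13.5 s** at 400→200-scale ligand numbers)
and complex formation saturates.  At t = 0 a homogeneous placement
colocalizes ~70–76% of NKG2D with KIR2DL1 by chance alone
(`colocalization_fraction(make_config("homogeneous", ...))` → 0.70–0.76
across placements; Poisson expectation 1 − e^(−11686/8281) = 0.756).

The headline comparison runs from the command line:

```bash
nkrsim info --profile fast --seed 0 --out-dir out/   # MI & CC per layout
nkrsim dose-response --profile fast --seed 0
nkrsim kp-ablation --profile fast --seed 0           # proofreading variants
nkrsim generate-maps --n-clusters 120 --seed 1
nkrsim spatial-stats out/map_NKG2D_seed1.txt         # C(r) vs null maps
```

With the fast profile (four doses, 30 replicates, read-out 20 s) the
disjoint layout transmits **> 1 bit** of dose information at both
HLA-C levels while fully overlapping clusters stay **< 1 bit** in both
MI and capacity, with the homogeneous layout in between — the model's
central result.  Expect roughly 10–15 minutes on one core for the
`info` command; single trajectories take a couple of seconds.

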