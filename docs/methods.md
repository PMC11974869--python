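# Methods

## The model

`nkrsim` simulates membrane-proximal signaling at the contact interface
between a natural-killer (NK) cell and a target cell during the first
minute after contact.  The interface is a quasi-two-dimensional box of
3.64 × 3.64 µm divided into 91 × 91 chambers of side l₀ = 40 nm
(8281 chambers).  Molecules are well mixed within a chamber; reactions
are strictly same-chamber events; diffusion is a hop to one of the four
nearest-neighbour chambers.  Boundaries are periodic in x/y; the z
direction enters only through the reaction-volume factors below.

Two receptor systems compete:

* **Activating arm.**  NKG2D binds its ligand (NKG2DL, standing in for
  ULBP1–6 / MIC-A/B; k_on = 2.387 × 10⁻² µM⁻¹s⁻¹,
  k_off = 0.023 s⁻¹).  A Src-family kinase (SFK) docks on the complex
  and phosphorylates the two DAP10 adaptor tyrosines; fully
  phosphorylated DAP10 recruits Vav1, which the docked SFK
  phosphorylates (releasing the kinase).  Total phosphorylated Vav1 —
  complex-docked plus free — is the activation read-out.
* **Inhibitory arm.**  KIR2DL1 binds HLA-C (complex lifetime ≈ 0.7 s;
  K_D taken as 10 µM, hence k_on = 0.143 µM⁻¹s⁻¹).  SFK phosphorylates
  the two ITIM tyrosines catalytically; doubly phosphorylated ITIMs
  recruit SHP-1, and ITIM-docked SHP-1 dephosphorylates any pVav1 in
  the *same chamber* (interaction range ≤ 40 nm), whether free or still
  docked on an NKG2D complex.

**Kinetic proofreading (KP).**  Ligand unbinding from any *modified*
complex is an irreversible reset: the receptor returns to its basal
state and bound cytosolic proteins are released unmodified.  Disabling
KP in either arm replaces the reset with unbinding that preserves tail
phosphorylation, which makes ligand-free phosphorylated receptors (and,
in the inhibitory arm, free SHP-1-loaded KIR2DL1 — a persistent
phosphatase) part of the dynamics.  There is no phosphatase for the
receptor tails themselves, so without KP the primed states relax only
through rebinding and the normal reaction traffic.

**Propensities.**  A bimolecular rate k (µM⁻¹s⁻¹) becomes a per-pair
event rate k/(N_A·ν) with ν the volume of the region where the
encounter happens: receptor–ligand binding across the ~2 nm membrane
gap (ν = l₀·l₀·2 nm ⇒ 12.39 s⁻¹ for NKG2D–NKG2DL), membrane–membrane
encounters (ν = l₀³), and cytosolic-protein-to-receptor encounters
(ν = l₀²·z with z = 1 µm).

**Diffusion.**  A molecule with diffusion constant D hops to *each*
neighbour at rate D/l₀² (total 4D/l₀²), the mapping under which the
ensemble mean-square displacement is 4Dt.  Note the companion analytic
estimator (below) quotes a mean hop time of 1/6 s for NKG2DL
(D = 0.01 µm²/s), which corresponds to reading D/l₀² as the *total*
hop rate; the engine uses the 4Dt convention, the estimator keeps the
1/6 s figure as its default input.  Receptors and receptor complexes
inside a cluster never hop across the cluster boundary (chambers are
labelled 1 inside / 0 outside and hops only connect same-label
chambers); everything else diffuses freely.

## Resting-state geometries

Superresolution imaging shows both receptor types pre-clustered in
submicron domains placed uniformly at random.  The synthetic-map
generator reproduces that statistics: cluster shapes are grown by a
random aggregation walk with geometric sizes of mean 8 chambers,
placed uniformly with periodic wrap and no same-type overlap (largest
first, so the packing does not jam).  Defaults of 120 NKG2D and 350
KIR2DL1 clusters per box are calibration constants chosen so that,
after scattering 53 NKG2D and 11,686 KIR2DL1 receptors uniformly over
their cluster chambers, a large fraction of NKG2D clusters but
essentially no KIR2DL1 cluster ends up empty (empty clusters are
removed).  The three resting-state layouts are:

* **disjoint** — KIR2DL1 clusters forbidden from touching NKG2D
  clusters;
* **overlapping** — every NKG2D cluster is covered by a KIR2DL1
  cluster with the *same footprint* (centers of mass coincide
  exactly); surplus KIR2DL1 clusters avoid the NKG2D clusters.  We use
  identical footprints rather than independently drawn shapes because
  an independently drawn 8-chamber shape shares only ~40% of its
  chambers with its partner, which is not "fully overlapping" at the
  40 nm interaction range of SHP-1 and largely decouples the arms;
* **homogeneous** — no clusters; receptors anywhere, all chambers
  unlabelled.

Ligands (NKG2DL, HLA-C) and the SFK/Vav1/SHP-1 pools are always
uniform over the box.

## Parameters

| quantity | value | provenance |
|---|---|---|
| box, chamber | 91×91 chambers of 40 nm; z = 1 µm | model definition |
| NKG2D / KIR2DL1 copies | 53 / 11,686 (4 and 882 µm⁻²) | model definition |
| NKG2DL dose set | 20, 40, 100, 200, 400 | model definition |
| HLA-C | 4213 (low) / 11,686 (high) | model definition |
| NKG2D–NKG2DL | k_on 2.387e-2 µM⁻¹s⁻¹, k_off 0.023 s⁻¹ | literature values |
| KIR2DL1–HLA-C | k_off 1.43 s⁻¹ (0.7 s lifetime); K_D 10 µM | lifetime literature; affinity literature-scale |
| membrane D | 0.01 µm²/s (receptors, ligands, complexes) | literature scale |
| SFK: copies, D | 150, 0.1 µm²/s | reconstruction (calibrated) |
| Vav1: copies, D | 150, 0.15 µm²/s | reconstruction (calibrated) |
| SHP-1: copies, D | 1200, 0.05 µm²/s | reconstruction (calibrated) |
| SFK dock/undock (activating) | 2.0 µM⁻¹s⁻¹ / 0.5 s⁻¹ | reconstruction |
| DAP10/Vav1 phosphorylation | 10 s⁻¹ | reconstruction |
| Vav1 dock/undock | 40 µM⁻¹s⁻¹ / 0.2 s⁻¹ | reconstruction |
| pVav1 release / basal dephosphorylation | 0.7 s⁻¹ / 5 s⁻¹ | reconstruction |
| ITIM phosphorylation (catalytic) | 10 µM⁻¹s⁻¹ | reconstruction |
| SHP-1 recruitment / release | 20 µM⁻¹s⁻¹ / 0.2 s⁻¹ | reconstruction |
| SHP-1 catalysis, docked / free pVav1 | 2.0 (membrane ν) / 100 (cytosol ν) µM⁻¹s⁻¹ | reconstruction |

Only the geometry, copy numbers, the NKG2D binding constants, the
inhibitory complex lifetime and the membrane diffusion scale are
pinned by published values; every "reconstruction" entry was
calibrated **once**, against well-characterized behaviors of the
system rather than fitted to outputs of interest:

1. the deterministic activating module (single complex, whole box)
   reaches a steady state of slightly below 0.4 pVav1 in under 5 s,
   with near-steady behavior by 3–4 s, so a full load of 53 receptors
   yields ≈ 20 pVav1 (the package computes 0.382, t₉₅ = 3.8 s,
   53 × 0.382 = 20.2);
2. mean pVav1 at 20 s is ordered disjoint ≫ homogeneous > overlapping,
   with the disjoint response insensitive to HLA-C and the homogeneous
   response dropping at high HLA-C.

Two structural choices matter and are deliberate.  ITIM
phosphorylation is *catalytic* (SFK is not sequestered): with ~4 × 10³
short-lived inhibitory complexes, a docking formulation captures >80%
of any plausible kinase pool and couples the arms through kinase
competition — a mechanism the model deliberately excludes: its two
receptor arms interact only through SHP-1 acting on pVav1, which is
what makes the disjoint layout behave as an activating-only system.  And the SHP-1 pool must be
large enough that the SHP-1-loaded complex count (~700 at low HLA-C)
leaves few clusters without a phosphatase at any instant: the fraction
of zero-phosphatase clusters (Poisson in the per-cluster loading)
otherwise floors the overlapping-layout response regardless of the
catalytic rate.

## Deterministic limit and diffusion time scales

The activating arm closes on exactly 14 species (5 free pools + 9
complex states: DAP10 phosphosite count 0/1/2 × SFK docked or not,
with a Vav1/pVav1 slot on the fully phosphorylated state; SFK is
released upon phosphorylating Vav1 and does not re-dock on a
pVav1-loaded complex).  `solve_activating_ode` integrates mass-action
kinetics with per-pair rates propensity/n_chambers (whole-box
well-mixed limit) via LSODA and asserts the 14-state count.

Ligand–receptor encounter times are estimated by tessellating the box
into Voronoi cells of the M ligands (8281/M chambers each) and using
the distinct-sites-visited formula for an n-step square-lattice walk,
S(n) ≈ πn / ln(5.692 n) (natural log — the choice that reproduces both
quoted coverage times).  With a hop time of 1/6 s: full coverage of
the average cell by ≈ 13.5 s at M = 200 (hence response saturation
shortly after), and half coverage by ≈ 40 s at M = 40.

## Stochastic engine

Direct-method SSA over chambers: a binary sum tree samples the chamber,
a linear scan the channel.  Chamber totals are updated incrementally
from per-species propensity deltas with a full rebuild every 2²⁰
events to cancel floating-point drift; any residual inconsistency
(negative count, empty selection) aborts or self-heals conservatively.
The scheduler is statistically exact; the analytic two-state
equilibrium, the 4Dt mean-square-displacement law, and the well-mixed
ODE limit are enforced as tests.  A bespoke xorshift128+ generator
(seeded via splitmix64) makes trajectories bit-reproducible across
platforms for a given seed; replicate seeds are spawned from the
master seed with `numpy.random.SeedSequence`.

## Information analysis

The dose s (NKG2DL count) is the channel input, total pVav1 at the
read-out time the output o.  P(o|s) is estimated on integer count bins
either as the raw empirical histogram or smoothed by each dose's
maximum-likelihood Gamma fit (zero counts are handled by a recorded
+0.5 offset, since the Gamma support excludes zero).  MI is the
plug-in estimate in bits under a uniform dose prior; capacity is
computed by Blahut–Arimoto iteration with the standard
`max_s D(P(·|s)‖R) − I(Q)` stopping bound and a monotone
lower-bound trace.  Gamma–Gamma KL divergences use the closed form
(digamma/log-gamma), reported in bits.

## Problem sizes, estimator choice, and what the tests show

The analysis profiles are the package's own scaling choice: the
**fast** profile uses doses {20, 40, 100, 400}, 30 replicates/dose and
a 20 s horizon — enough to place MI above or below the 1-bit line —
while the **full** profile (5 doses, ≥200 replicates, 40 s) is the
setting for distribution-level quantities.  At 30 replicates the raw
histogram plug-in MI is upward-biased by ~0.2–0.3 bits, so the scaled
analyses default to the Gamma-smoothed channel; at a few hundred
replicates the two estimators agree (this convergence is itself
tested).

At the fast scale the package computes (read-out 20 s, master seed of
the test suite): MI(disjoint) = 1.08 / 1.30 bits at low / high HLA-C;
MI(overlapping) = 0.87 bits and capacity 0.91 bits; Gamma-KL between
doses 400 and 20 at low HLA-C of 17.3 (disjoint), 8.4 (homogeneous)
and 7.5 (overlapping) bits.  The disjoint value is far separated; the
homogeneous–overlapping gap is comparable to its own sampling noise at
30 replicates, so the reproducible statement at this scale is the
ordering (and the dominance of the disjoint layout), not the
magnitudes.  KL values are replicate- and horizon-sensitive point
estimates; pinning them requires the full profile.

The synthetic maps emulate the *statistics* of binarized
superresolution images (uniform random cluster placement, mean size,
receptor densities), not their actual shapes, cluster-number densities
or imaging noise; conclusions about real membranes inherit that caveat.
Passing tests show the pipeline reproduces the model's behavior under
these emulated resting-state statistics, not that any particular NK
cell's membrane is organized this way.

## Numerical choices and edge cases

* Two-point correlation: exact lattice distances up to r_max = 25
  chambers (1 µm); per-offset averages over valid pairs (pairs beyond
  the image edge are omitted unless periodic wrap is requested), so a
  checkerboard gives exactly −1 at r = 1 and C(0)/σ² = 1; uniform maps
  are rejected (σ² = 0).
* Cluster randomization re-places the connected components of a map
  uniformly without same-type overlap; occupied-site count and the
  placed size multiset are preserved exactly (adjacent clusters may
  merge under re-labelling of the output).
* Gamma fits require ≥10 samples and positive variance; channels
  require ≥2 doses; Blahut–Arimoto requires normalized rows and errors
  out if the gap bound fails to close.
* Packing clusters at the default densities fills ~45% of the box;
  rejection sampling places large clusters first and raises an error
  reporting the fill fraction if a cluster cannot be placed.
* The visit-time root-find brackets n in [1, ∞) by doubling and solves
  with Brent's method; requests below one step's coverage interpolate
  linearly.

## Known limitations

* Cytoskeletal forces, membrane deformation and >1 min receptor
  dynamics (including stimulation-induced microcluster growth) are
  outside the model's early-time scope.
* The quoted ~30 s NKG2D–ligand complex lifetime is inconsistent with
  1/k_off = 43 s at the quoted k_off = 0.023 s⁻¹; the package uses the
  rate constant and does not tune it.
* The binarization rule for intensity images ("≥ 100") is configurable
  because the source description is internally inconsistent.
* The unprinted constants are a calibrated reconstruction; quantities
  that depend on them only through the calibrated anchors (orderings,
  above/below-unity information values, time scales) are meaningful,
  individual rate values are not.
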