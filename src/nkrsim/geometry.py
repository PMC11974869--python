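"""Lattice geometry of the NK cell / target cell contact region.

The contact interface is modelled as a quasi-two-dimensional box divided
into square chambers of side ``l0`` (40 nm by default).  Molecules are
well mixed within a chamber; diffusion is a hop between nearest-neighbour
chambers.  The chamber height depends on where a species lives: membrane
species occupy a slab of height ``l0``, cytosolic species a column of
height ``z_cytosol`` (1 um), and receptor--ligand binding happens across
a ~2 nm gap between the apposed membranes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the simulation box and its chambers.

    Parameters
    ----------
    l0_nm : float
        Chamber side length in nm (default 40).
    n_side : int
        Number of chambers along each edge (default 91).
    d_contact_nm : float
        Membrane--membrane gap over which receptor--ligand binding
        occurs, in nm (default 2).
    z_cytosol_um : float
        Height of the cytosolic column above each chamber, in um
        (default 1.0).
    """

    l0_nm: float = 40.0
    n_side: int = 91
    d_contact_nm: float = 2.0
    z_cytosol_um: float = 1.0

    def __post_init__(self) -> None:
        if self.l0_nm <= 0 or self.d_contact_nm <= 0 or self.z_cytosol_um <= 0:
            raise ValueError("all lengths must be positive")
        if self.n_side < 1:
            raise ValueError("n_side must be >= 1")

    @property
    def n_chambers(self) -> int:
        """Total number of chambers (n_side**2; 8281 with defaults)."""
        return self.n_side * self.n_side

    @property
    def chamber_area_um2(self) -> float:
        return (self.l0_nm * 1e-3) ** 2

    @property
    def box_area_um2(self) -> float:
        """Area of the box in um^2 (13.2496 with defaults)."""
        return self.n_chambers * self.chamber_area_um2

    # -- reaction volumes (litres) -------------------------------------
    # 1 nm^3 = 1e-24 L
    @property
    def v_recep_lig_L(self) -> float:
        """Volume for receptor--ligand binding: l0 x l0 x d_contact."""
        return self.l0_nm * self.l0_nm * self.d_contact_nm * 1e-24

    @property
    def v_membrane_L(self) -> float:
        """Volume for membrane--membrane encounters (e.g. SFK with a
        receptor complex): l0 x l0 x l0."""
        return self.l0_nm ** 3 * 1e-24

    @property
    def v_cytosol_recep_L(self) -> float:
        """Volume for a cytosolic protein meeting a membrane receptor:
        l0 x l0 x z_cytosol."""
        return self.l0_nm * self.l0_nm * (self.z_cytosol_um * 1e3) * 1e-24

    @property
    def hop_rate_per_direction(self) -> float:
        """Conversion factor 1/l0^2 in um^-2: a molecule with diffusion
        constant D hops to each of its four neighbours at D/l0^2."""
        return 1.0 / self.chamber_area_um2
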