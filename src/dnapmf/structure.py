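"""Coarse-grained DNA structures, ionic inventories and system assembly.

One bead per base pair carries the charge of both strands' phosphates
(-2 e) and has radius 1.0 nm, so the linear charge density (-2 e per
0.34 nm) matches double-stranded DNA.  A linear duplex is a straight rod
of beads spaced by the B-DNA rise; a torsionally relaxed minicircle is a
planar regular polygon whose perimeter is ``n_bp * rise``.

The ionic inventory follows the construction used for 0.1 M NaCl / CaCl2
boxes: enough counterions to neutralise the DNA pair, then salt ion
pairs for the target molarity computed from the nominal cubic box
volume.  For divalent salt the anion count is rounded up to the nearest
even integer so that the CaCl2 units are integral.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, BDNA_RISE, BEAD_CHARGE, BEAD_RADIUS

__all__ = [
    "MoleculeModel",
    "SimulationBox",
    "IonInventory",
    "SystemState",
    "build_linear_duplex_model",
    "build_minicircle_model",
    "build_point_charge",
    "compose_ion_inventory",
    "place_pair_and_ions",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when random ion placement exhausts its attempt budget."""


@dataclass
class MoleculeModel:
    """A coarse-grained DNA molecule: bead positions, topology, charges.

    Parameters
    ----------
    topology : {"linear", "ring"}
        Chain topology; rings carry a closure bond between the last and
        first bead.
    n_bp : int
        Number of base pairs, i.e. number of beads.
    positions : (n_bp, 3) ndarray
        Bead coordinates in nm.
    charges : (n_bp,) ndarray
        Bead charges in units of e (zero or negative).
    bead_radius : float
        Excluded-volume radius of each bead in nm.
    """

    topology: str
    n_bp: int
    positions: np.ndarray
    charges: np.ndarray
    bead_radius: float = BEAD_RADIUS

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.positions = np.asarray(self.positions, dtype=float).reshape(self.n_bp, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(self.n_bp)
        if np.any(self.charges > 0):
            raise ValueError("DNA bead charges must be zero or negative")

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def com(self) -> np.ndarray:
        """Unweighted centroid of the beads, nm."""
        return self.positions.mean(axis=0)

    @property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded bead index pairs."""
        n = self.n_bp
        if n < 2:
            return np.empty((0, 2), dtype=int)
        pairs = [(i, i + 1) for i in range(n - 1)]
        if self.topology == "ring":
            pairs.append((n - 1, 0))
        return np.array(pairs, dtype=int)

    @property
    def angles(self) -> np.ndarray:
        """(n_angles, 3) array of consecutive bead triplets."""
        n = self.n_bp
        if n < 3:
            return np.empty((0, 3), dtype=int)
        triplets = [(i, i + 1, i + 2) for i in range(n - 2)]
        if self.topology == "ring":
            triplets.append((n - 2, n - 1, 0))
            triplets.append((n - 1, 0, 1))
        return np.array(triplets, dtype=int)

    @property
    def bond_length(self) -> float:
        """Equilibrium bond length from the constructed geometry, nm."""
        b = self.bonds
        if len(b) == 0:
            return 0.0
        d = self.positions[b[:, 0]] - self.positions[b[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    @property
    def equilibrium_angle(self) -> float:
        """Equilibrium bend angle in radians (pi for rods, the polygon
        interior angle for rings)."""
        if self.topology == "ring":
            return math.pi - 2.0 * math.pi / self.n_bp
        return math.pi

    def translated(self, shift: np.ndarray) -> "MoleculeModel":
        return MoleculeModel(
            self.topology,
            self.n_bp,
            self.positions + np.asarray(shift, dtype=float),
            self.charges.copy(),
            self.bead_radius,
        )


@dataclass
class SimulationBox:
    """Cubic periodic box with edge length in nm."""

    edge: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def volume(self) -> float:
        """Box volume in nm^3."""
        return self.edge**3

    @property
    def center(self) -> np.ndarray:
        return np.full(3, self.edge / 2.0)

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, edge)^3."""
        if not self.periodic:
            return np.asarray(positions, dtype=float)
        return np.mod(positions, self.edge)

    def min_image(self, displacement: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to displacement vectors."""
        if not self.periodic:
            return np.asarray(displacement, dtype=float)
        return displacement - self.edge * np.round(displacement / self.edge)


@dataclass
class IonInventory:
    """Counts of explicit cations and Cl- co-ions for one assembled box.

    ``residual_charge`` is the remainder of the DNA charge that is not an
    integer multiple of the counterion valence; assembly compensates it
    by adjusting a single counterion's charge so the final system is
    exactly neutral.
    """

    counterion_valence: int
    n_counterions: int
    n_coions: int
    coion_valence: int = -1
    residual_charge: float = 0.0

    def total_ion_charge(self) -> float:
        return (
            self.n_counterions * self.counterion_valence
            + self.n_coions * self.coion_valence
            - self.residual_charge
        )


@dataclass
class SystemState:
    """The unit of simulation: two DNA molecules, ions, a periodic box."""

    molecule_a: MoleculeModel
    molecule_b: MoleculeModel
    ion_positions: np.ndarray
    ion_charges: np.ndarray
    box: SimulationBox
    inventory: IonInventory | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ion_positions = np.asarray(self.ion_positions, dtype=float).reshape(-1, 3)
        self.ion_charges = np.asarray(self.ion_charges, dtype=float).reshape(-1)
        if len(self.ion_positions) != len(self.ion_charges):
            raise ValueError("ion positions and charges disagree in length")

    @property
    def n_particles(self) -> int:
        return self.molecule_a.n_bp + self.molecule_b.n_bp + len(self.ion_charges)

    @property
    def total_charge(self) -> float:
        return (
            self.molecule_a.total_charge
            + self.molecule_b.total_charge
            + float(self.ion_charges.sum())
        )

    def all_positions(self) -> np.ndarray:
        return np.vstack(
            [self.molecule_a.positions, self.molecule_b.positions, self.ion_positions]
        )

    def copy(self) -> "SystemState":
        return SystemState(
            MoleculeModel(
                self.molecule_a.topology,
                self.molecule_a.n_bp,
                self.molecule_a.positions.copy(),
                self.molecule_a.charges.copy(),
                self.molecule_a.bead_radius,
            ),
            MoleculeModel(
                self.molecule_b.topology,
                self.molecule_b.n_bp,
                self.molecule_b.positions.copy(),
                self.molecule_b.charges.copy(),
                self.molecule_b.bead_radius,
            ),
            self.ion_positions.copy(),
            self.ion_charges.copy(),
            SimulationBox(self.box.edge, self.box.periodic),
            self.inventory,
        )


def build_linear_duplex_model(
    n_bp: int, rise: float = BDNA_RISE, bead_radius: float = BEAD_RADIUS
) -> MoleculeModel:
    """Build a straight rod of ``n_bp`` beads spaced by ``rise`` nm.

    The rod lies along the x axis, centred at the origin.  Beads 2..n_bp
    carry -2 e and the first bead is neutral, giving a total charge of
    ``-2 (n_bp - 1)`` e — the phosphate count of a duplex with free 5'
    ends (23 phosphates per strand for a 24-bp duplex, hence -46 e).
    """
    if n_bp < 2:
        raise ValueError("a linear duplex needs at least 2 base pairs")
    if rise <= 0:
        raise ValueError("rise must be positive")
    x = np.arange(n_bp, dtype=float) * rise
    positions = np.column_stack([x - x.mean(), np.zeros(n_bp), np.zeros(n_bp)])
    charges = np.full(n_bp, BEAD_CHARGE)
    charges[0] = 0.0
    return MoleculeModel("linear", n_bp, positions, charges, bead_radius)


def build_minicircle_model(
    n_bp: int, rise: float = BDNA_RISE, bead_radius: float = BEAD_RADIUS
) -> MoleculeModel:
    """Build a planar regular ``n_bp``-gon with perimeter ``n_bp * rise``.

    The ring lies in the xy plane, centred at the origin, with circle
    radius ``n_bp * rise / (2 pi)``; every bead carries -2 e.  For the
    65-bp minicircle at the 0.338 nm rise this radius — which equals the
    radius of gyration of the ideal rigid ring — is 3.50 nm.
    """
    if n_bp < 3:
        raise ValueError("a minicircle needs at least 3 base pairs")
    if rise <= 0:
        raise ValueError("rise must be positive")
    radius = n_bp * rise / (2.0 * math.pi)
    phi = 2.0 * math.pi * np.arange(n_bp) / n_bp
    positions = np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), np.zeros(n_bp)]
    )
    charges = np.full(n_bp, BEAD_CHARGE)
    return MoleculeModel("ring", n_bp, positions, charges, bead_radius)


def build_point_charge(charge: float = BEAD_CHARGE, radius: float = 0.3) -> MoleculeModel:
    """A single charged bead as a degenerate one-bead 'molecule'.

    Used for analytic pair-potential checks where the distance-resolved
    free energy of two isolated charges has a closed form.
    """
    return MoleculeModel("linear", 1, np.zeros((1, 3)), np.array([charge]), radius)


def compose_ion_inventory(
    total_dna_charge: float,
    counterion_valence: int,
    salt_molar: float,
    box: SimulationBox,
) -> IonInventory:
    """Compute ion counts for neutralisation plus added salt.

    ``n_anions = round(salt_molar * V * N_A)``, rounded **up** to the
    nearest even integer for divalent counterions so the CaCl2 salt
    units are whole; counterions = neutralising ions plus one cation per
    ``valence`` anions.  For a 15.0 nm box at 0.1 M this yields 203
    anions (monovalent) or 204 (divalent), and 295 Na+ / 148 Ca2+ for a
    -92 e DNA pair.
    """
    if total_dna_charge >= 0:
        raise ValueError("total DNA charge must be negative")
    if counterion_valence not in (1, 2):
        raise ValueError("counterion valence must be 1 or 2")
    if salt_molar < 0:
        raise ValueError("salt molarity must be non-negative")

    # nm^3 -> litres is 1e-24
    n_anions_raw = salt_molar * box.volume * 1e-24 * AVOGADRO
    if counterion_valence == 2:
        n_anions = 2 * math.ceil(n_anions_raw / 2.0 - 1e-12)
    else:
        n_anions = int(math.floor(n_anions_raw + 0.5))

    q = abs(total_dna_charge)
    n_neutralising = int(q // counterion_valence)
    residue = q - n_neutralising * counterion_valence
    if residue:
        warnings.warn(
            f"DNA charge {total_dna_charge} e is not a multiple of the "
            f"counterion valence {counterion_valence}; residue {residue} e "
            "will be compensated by adjusting one counterion at assembly",
            stacklevel=2,
        )
    n_salt_cations = n_anions // counterion_valence
    return IonInventory(
        counterion_valence=counterion_valence,
        n_counterions=n_neutralising + n_salt_cations,
        n_coions=n_anions,
        residual_charge=residue,
    )


# exclusion distances for random ion placement, nm
ION_DNA_EXCLUSION = 0.5
ION_ION_EXCLUSION = 0.35


def place_pair_and_ions(
    a: MoleculeModel,
    b: MoleculeModel,
    inventory: IonInventory,
    box: SimulationBox,
    com_separation: float,
    seed: int,
    max_attempts_per_ion: int = 10_000,
) -> SystemState:
    """Assemble the parallel-oriented pair plus randomly placed ions.

    The two molecules are placed with their centres of mass on the box
    z axis, separated by ``com_separation`` and centred in the box:
    rods with parallel axes (perpendicular to z), rings with parallel,
    stacked planes.  Ions are inserted by rejection sampling honouring a
    0.5 nm exclusion from every DNA bead and 0.35 nm between ions; the
    result is deterministic under a fixed seed.
    """
    if com_separation >= box.edge / 2.0:
        raise ValueError("com_separation must be below half the box edge")
    rng = np.random.default_rng(seed)

    center = box.center
    mol_a = a.translated(center - a.com + np.array([0.0, 0.0, -com_separation / 2.0]))
    mol_b = b.translated(center - b.com + np.array([0.0, 0.0, +com_separation / 2.0]))
    dna_positions = np.vstack([mol_a.positions, mol_b.positions])

    n_ions = inventory.n_counterions + inventory.n_coions
    ion_positions = np.empty((n_ions, 3))
    placed = 0
    attempts = 0
    budget = max_attempts_per_ion * max(n_ions, 1)
    while placed < n_ions:
        if attempts >= budget:
            raise PlacementError(
                f"placed {placed}/{n_ions} ions in {attempts} attempts; "
                "the exclusion distances exceed the densest allowed packing "
                "for this box"
            )
        attempts += 1
        trial = rng.uniform(0.0, box.edge, size=3)
        d_dna = np.linalg.norm(box.min_image(dna_positions - trial), axis=1)
        if d_dna.min() < ION_DNA_EXCLUSION:
            continue
        if placed:
            d_ion = np.linalg.norm(
                box.min_image(ion_positions[:placed] - trial), axis=1
            )
            if d_ion.min() < ION_ION_EXCLUSION:
                continue
        ion_positions[placed] = trial
        placed += 1

    ion_charges = np.concatenate(
        [
            np.full(inventory.n_counterions, float(inventory.counterion_valence)),
            np.full(inventory.n_coions, float(inventory.coion_valence)),
        ]
    )
    state = SystemState(mol_a, mol_b, ion_positions, ion_charges, box, inventory)
    residual = state.total_charge
    if abs(residual) > 1e-9 and n_ions:
        # documented single-ion adjustment: absorb the valence residue into
        # the first counterion so the assembled system is exactly neutral
        ion_charges[0] -= residual
        state = SystemState(mol_a, mol_b, ion_positions, ion_charges, box, inventory)
    if n_ions:
        assert abs(state.total_charge) < 1e-9
    return state
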