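"""Metropolis Monte Carlo sampling of the DNA pair + ions at 300 K.

The coarse-grained Hamiltonian has four terms:

* harmonic bonds along each backbone (ring-closure bond included),
* harmonic bending on consecutive backbone triplets,
* WCA repulsion between sites of *different* molecules and between any
  pair involving an ion (contact distance is additive in the two site
  radii; intramolecular excluded volume is delegated to the bonded
  terms, since contour-neighbouring 1-nm beads overlap by design),
* screened Coulomb ``kT * l_B * z_i z_j * exp(-r/lambda_D) / r`` between
  all distinct charged pairs (``lambda_D = 0`` means bare Coulomb), with
  an optional spherical cutoff and energy shift.

Sampling targets ``exp(-[U + w]/kT)`` where ``w`` is a harmonic umbrella
bias on the centre-of-mass separation of the two molecules.  Only
equilibrium averages enter the downstream analyses, so a Metropolis
chain (single-ion displacements plus per-molecule bead, rigid-rotation
and rigid-translation moves) replaces molecular dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .constants import BJERRUM_LENGTH_WATER, TEMPERATURE, kT
from .structure import MoleculeModel, SystemState

__all__ = [
    "ForceFieldParams",
    "UmbrellaWindow",
    "WindowSchedule",
    "WindowRecord",
    "MoveAmplitudes",
    "MCSampler",
    "com_separation",
    "bias_energy",
    "coulomb_pair_energy",
    "wca_pair_energy",
    "total_energy",
    "mc_sweep",
    "make_schedule",
    "run_window",
]

_OVERLAP_GUARD = 1e-6  # nm; point charges closer than this are an error
_WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Coarse-grained force-field parameters (kJ/mol, nm, e, K).

    ``wca_sigma`` is the ion-ion contact diameter; pair contact
    distances are additive in the site radii (ions contribute
    ``wca_sigma / 2``, DNA beads their ``bead_radius``).
    ``debye_length = 0`` selects the bare Coulomb interaction between
    the explicit charges — counterion condensation and release must
    emerge from the explicit ions, not from a mean-field background.
    ``coulomb_cutoff``: ``None`` = half the box edge for periodic boxes
    (with energy shift), ``inf`` = no cutoff.
    """

    bond_k: float = 50_000.0
    bend_k: float = 369.0
    wca_sigma: float = 0.3
    wca_epsilon: float = 2.494
    bjerrum_length: float = BJERRUM_LENGTH_WATER
    debye_length: float = 0.0
    temperature: float = TEMPERATURE
    coulomb_cutoff: float | None = None

    def __post_init__(self) -> None:
        for name in ("bond_k", "bend_k", "wca_sigma", "wca_epsilon",
                     "bjerrum_length", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.debye_length < 0:
            raise ValueError("debye_length must be >= 0")

    @property
    def kT(self) -> float:
        return kT(self.temperature)


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic restraint ``(k/2)(r - center)^2`` on the COM distance.

    ``force_k = 0`` denotes an unbiased window (used by the WHAM
    exactness checks).
    """

    center: float
    force_k: float

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("window center must be positive")
        if self.force_k < 0:
            raise ValueError("force constant must be non-negative")


@dataclass(frozen=True)
class WindowSchedule:
    windows: tuple[UmbrellaWindow, ...]
    spacing: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> UmbrellaWindow:
        return self.windows[i]

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])


@dataclass
class WindowRecord:
    """Per-window umbrella output: metadata + reaction-coordinate series."""

    window: UmbrellaWindow
    rc_series: np.ndarray
    frames: list[SystemState] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.rc_series = np.asarray(self.rc_series, dtype=float).reshape(-1)
        if self.rc_series.size == 0:
            raise ValueError("rc_series must be nonempty")
        if np.any(self.rc_series <= 0):
            raise ValueError("reaction-coordinate values must be positive")


def com_separation(state: SystemState) -> float:
    """Distance between the two molecules' unweighted bead centroids.

    Computed on unwrapped molecular coordinates: no minimum image is
    applied along the reaction coordinate, which is safe because the
    largest sampled separation (7 nm) is below half the 15 nm box edge.
    """
    return float(np.linalg.norm(state.molecule_a.com - state.molecule_b.com))


def bias_energy(w: UmbrellaWindow, r: float) -> float:
    """Harmonic umbrella energy in kJ/mol."""
    return 0.5 * w.force_k * (r - w.center) ** 2


def make_schedule(
    r_min: float, r_max: float, spacing: float, force_k: float
) -> WindowSchedule:
    """Uniformly spaced window centres ``r_min, r_min+spacing, ..., r_max``."""
    if r_min >= r_max:
        raise ValueError("r_min must be below r_max")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    span = r_max - r_min
    n_steps = span / spacing
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"window range {span} nm is not an integer multiple of the "
            f"spacing {spacing} nm"
        )
    centers = r_min + spacing * np.arange(round(n_steps) + 1)
    windows = tuple(UmbrellaWindow(float(c), force_k) for c in centers)
    return WindowSchedule(windows, spacing)


def coulomb_pair_energy(
    r: float, z1: float, z2: float, ff: ForceFieldParams
) -> float:
    """Unshifted screened-Coulomb pair energy, kJ/mol."""
    if r < _OVERLAP_GUARD:
        raise FloatingPointError(f"charge separation {r} nm below overlap guard")
    screen = 1.0 if ff.debye_length == 0 else math.exp(-r / ff.debye_length)
    return ff.kT * ff.bjerrum_length * z1 * z2 * screen / r


def wca_pair_energy(r: float, sigma: float, epsilon: float) -> float:
    """WCA potential: LJ cut at its minimum ``2^(1/6) sigma`` and shifted."""
    if r >= _WCA_CUT_FACTOR * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon


class _ParticleSystem:
    """Flat-array view of a SystemState used by the sampler.

    Particle layout: beads of molecule A, beads of molecule B, ions.
    ``mol_id`` is 0/1 for the two molecules and -1 for ions.  The
    nonbonded sums are evaluated by the numba kernels in
    :mod:`dnapmf._kernels`.
    """

    def __init__(self, state: SystemState, ff: ForceFieldParams):
        self.ff = ff
        self.box = state.box
        a, b = state.molecule_a, state.molecule_b
        self.na, self.nb = a.n_bp, b.n_bp
        self.n_ions = len(state.ion_charges)
        self.n = self.na + self.nb + self.n_ions
        self.positions = state.all_positions().astype(float)
        self.charges = np.concatenate(
            [a.charges, b.charges, state.ion_charges]
        ).astype(float)
        ion_radius = ff.wca_sigma / 2.0
        self.radii = np.concatenate(
            [
                np.full(self.na, a.bead_radius),
                np.full(self.nb, b.bead_radius),
                np.full(self.n_ions, ion_radius),
            ]
        )
        self.mol_id = np.concatenate(
            [np.zeros(self.na, np.int64), np.ones(self.nb, np.int64),
             np.full(self.n_ions, -1, np.int64)]
        )
        self.mol_slices = (slice(0, self.na), slice(self.na, self.na + self.nb))
        self.molecules = (a, b)

        # bonded topology in global indices
        bonds, bond_r0 = [], []
        angles, angle_t0 = [], []
        for offset, mol in ((0, a), (self.na, b)):
            if len(mol.bonds):
                bonds.append(mol.bonds + offset)
                bond_r0.append(np.full(len(mol.bonds), mol.bond_length))
            if len(mol.angles):
                angles.append(mol.angles + offset)
                angle_t0.append(np.full(len(mol.angles), mol.equilibrium_angle))
        self.bonds = np.vstack(bonds) if bonds else np.empty((0, 2), int)
        self.bond_r0 = np.concatenate(bond_r0) if bond_r0 else np.empty(0)
        self.angles = np.vstack(angles) if angles else np.empty((0, 3), int)
        self.angle_t0 = np.concatenate(angle_t0) if angle_t0 else np.empty(0)

        # per-particle bonded-term membership for O(1) lookup in moves
        self._bonds_of = [[] for _ in range(self.n)]
        for bi, (i, j) in enumerate(self.bonds):
            self._bonds_of[i].append(bi)
            self._bonds_of[j].append(bi)
        self._angles_of = [[] for _ in range(self.n)]
        for ai, (i, j, k) in enumerate(self.angles):
            for p in (i, j, k):
                self._angles_of[p].append(ai)

        rc = ff.coulomb_cutoff
        if rc is None:
            rc = self.box.edge / 2.0 if self.box.periodic else math.inf
        self.rcut = rc
        self.coulomb_prefactor = ff.kT * ff.bjerrum_length
        if math.isfinite(rc):
            lam = ff.debye_length
            self._fshift = (math.exp(-rc / lam) / rc) if lam > 0 else 1.0 / rc
            self._rcut_kernel = rc
        else:
            self._fshift = 0.0
            self._rcut_kernel = _kernels.NO_CUTOFF
        self._edge_kernel = self.box.edge if self.box.periodic else -1.0

    def _kernel_args(self) -> tuple:
        return (
            self._edge_kernel,
            self.coulomb_prefactor,
            self.ff.wca_epsilon,
            self.ff.debye_length,
            self._rcut_kernel,
            self._fshift,
        )

    # -- bonded terms -------------------------------------------------------

    def bond_energy(self, indices=None) -> float:
        b = self.bonds if indices is None else self.bonds[indices]
        r0 = self.bond_r0 if indices is None else self.bond_r0[indices]
        if len(b) == 0:
            return 0.0
        d = self.positions[b[:, 0]] - self.positions[b[:, 1]]
        r = np.linalg.norm(d, axis=1)
        return float(0.5 * self.ff.bond_k * np.sum((r - r0) ** 2))

    def angle_energy(self, indices=None) -> float:
        a = self.angles if indices is None else self.angles[indices]
        t0 = self.angle_t0 if indices is None else self.angle_t0[indices]
        if len(a) == 0:
            return 0.0
        v1 = self.positions[a[:, 0]] - self.positions[a[:, 1]]
        v2 = self.positions[a[:, 2]] - self.positions[a[:, 1]]
        cos = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        theta = np.arccos(np.clip(cos, -1.0, 1.0))
        return float(0.5 * self.ff.bend_k * np.sum((theta - t0) ** 2))

    # -- nonbonded energies -------------------------------------------------

    def particle_delta_nb(self, i: int, new_pos: np.ndarray) -> float:
        """Nonbonded E(new) - E(old) for moving particle ``i``."""
        return _kernels.particle_delta(
            self.positions, self.charges, self.radii, self.mol_id,
            i, new_pos, *self._kernel_args(),
        )

    def group_delta_nb(self, sl: slice, new_group: np.ndarray) -> float:
        """Nonbonded E(new) - E(old) for rigidly moving one molecule."""
        return _kernels.group_delta(
            self.positions, self.charges, self.radii, self.mol_id,
            sl.start, sl.stop, new_group, *self._kernel_args(),
        )

    def nonbonded_energy(self) -> float:
        return float(_kernels.nonbonded_total(
            self.positions, self.charges, self.radii, self.mol_id,
            *self._kernel_args(),
        ))

    def total_energy(self) -> float:
        return self.bond_energy() + self.angle_energy() + self.nonbonded_energy()

    # -- geometry -----------------------------------------------------------

    def mol_com(self, m: int) -> np.ndarray:
        return self.positions[self.mol_slices[m]].mean(axis=0)

    def rc(self) -> float:
        return float(np.linalg.norm(self.mol_com(0) - self.mol_com(1)))

    def to_state(self) -> SystemState:
        a, b = self.molecules
        mol_a = MoleculeModel(
            a.topology, a.n_bp, self.positions[self.mol_slices[0]].copy(),
            a.charges.copy(), a.bead_radius,
        )
        mol_b = MoleculeModel(
            b.topology, b.n_bp, self.positions[self.mol_slices[1]].copy(),
            b.charges.copy(), b.bead_radius,
        )
        ion_pos = self.box.wrap(self.positions[self.na + self.nb:].copy())
        ion_q = self.charges[self.na + self.nb:].copy()
        return SystemState(mol_a, mol_b, ion_pos, ion_q, self.box)


def total_energy(state: SystemState, ff: ForceFieldParams) -> float:
    """Potential energy of a system state, kJ/mol (no umbrella bias)."""
    return _ParticleSystem(state, ff).total_energy()


@dataclass
class MoveAmplitudes:
    """Maximum displacements of the trial moves (nm, nm, rad, nm)."""

    ion: float = 0.35
    bead: float = 0.08
    rotation: float = 0.25
    translation: float = 0.05


_AMP_BOUNDS = {"ion": (0.01, 5.0), "bead": (0.005, 1.0),
               "rotation": (0.01, math.pi), "translation": (0.002, 1.0)}
_TARGET_ACC = (0.30, 0.50)


class MCSampler:
    """Metropolis chain over ion and molecule moves under an umbrella bias.

    One sweep = one trial displacement per ion plus, per molecule, one
    single-bead displacement, one rigid rotation about the COM and one
    rigid COM translation, each accepted with ``min(1, exp(-dE/kT))``
    where ``dE`` includes the bias energy.  Fixing the seed makes the
    chain bitwise reproducible.
    """

    def __init__(
        self,
        state: SystemState,
        ff: ForceFieldParams,
        window: UmbrellaWindow | None = None,
        seed: int = 0,
        amplitudes: MoveAmplitudes | None = None,
    ):
        self.ps = _ParticleSystem(state, ff)
        self.ff = ff
        self.window = window
        self.rng = np.random.default_rng(seed)
        self.amplitudes = amplitudes or MoveAmplitudes()
        self._acc = {k: [0, 0] for k in ("ion", "bead", "rotation", "translation")}

    # -- acceptance ---------------------------------------------------------

    def _accept(self, d_energy: float) -> bool:
        # always draw, so the random stream is move-count deterministic
        u = self.rng.random()
        if d_energy <= 0.0:
            return True
        x = d_energy / self.ff.kT
        if x > 700.0:
            return False
        return u < math.exp(-x)

    def _bias(self, r: float) -> float:
        return 0.0 if self.window is None else bias_energy(self.window, r)

    # -- individual moves ---------------------------------------------------

    def _move_ion(self, i: int) -> None:
        ps = self.ps
        amp = self.amplitudes.ion
        new = ps.positions[i] + self.rng.uniform(-amp, amp, 3)
        d_e = ps.particle_delta_nb(i, new)
        self._acc["ion"][1] += 1
        if self._accept(d_e):
            self._acc["ion"][0] += 1
            ps.positions[i] = ps.box.wrap(new) if ps.box.periodic else new

    def _move_bead(self, m: int) -> None:
        ps = self.ps
        sl = ps.mol_slices[m]
        i = sl.start + int(self.rng.integers(ps.molecules[m].n_bp))
        amp = self.amplitudes.bead
        new = ps.positions[i] + self.rng.uniform(-amp, amp, 3)
        bond_idx = ps._bonds_of[i]
        angle_idx = ps._angles_of[i]
        d_e = ps.particle_delta_nb(i, new)
        e_bonded_old = ps.bond_energy(bond_idx) + ps.angle_energy(angle_idx)
        r_old = ps.rc()
        old = ps.positions[i].copy()
        ps.positions[i] = new
        d_e += ps.bond_energy(bond_idx) + ps.angle_energy(angle_idx) - e_bonded_old
        d_e += self._bias(ps.rc()) - self._bias(r_old)
        self._acc["bead"][1] += 1
        if self._accept(d_e):
            self._acc["bead"][0] += 1
        else:
            ps.positions[i] = old

    def _move_rotation(self, m: int) -> None:
        ps = self.ps
        sl = ps.mol_slices[m]
        if ps.molecules[m].n_bp < 2:
            return
        axis = self.rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = self.rng.uniform(-self.amplitudes.rotation, self.amplitudes.rotation)
        rot = Rotation.from_rotvec(axis * angle)
        com = ps.mol_com(m)
        new = rot.apply(ps.positions[sl] - com) + com
        d_e = ps.group_delta_nb(sl, new)
        self._acc["rotation"][1] += 1
        if self._accept(d_e):
            self._acc["rotation"][0] += 1
            ps.positions[sl] = new

    def _move_translation(self, m: int) -> None:
        ps = self.ps
        sl = ps.mol_slices[m]
        amp = self.amplitudes.translation
        shift = self.rng.uniform(-amp, amp, 3)
        new = ps.positions[sl] + shift
        r_old = ps.rc()
        d_e = ps.group_delta_nb(sl, new)
        # COM displacement changes the bias
        com_other = ps.mol_com(1 - m)
        com_new = new.mean(axis=0)
        r_new = float(np.linalg.norm(com_new - com_other))
        d_e += self._bias(r_new) - self._bias(r_old)
        self._acc["translation"][1] += 1
        if self._accept(d_e):
            self._acc["translation"][0] += 1
            ps.positions[sl] = new

    # -- sweeps -------------------------------------------------------------

    def sweep(self) -> None:
        ps = self.ps
        for i in range(ps.na + ps.nb, ps.n):
            self._move_ion(i)
        for m in (0, 1):
            self._move_bead(m)
            self._move_rotation(m)
            self._move_translation(m)

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (acc / tot if tot else float("nan"))
            for k, (acc, tot) in self._acc.items()
        }

    def reset_acceptance(self) -> None:
        self._acc = {k: [0, 0] for k in self._acc}

    def tune(self) -> None:
        """Nudge move amplitudes toward 30-50 % acceptance.

        Only to be called during equilibration; amplitudes are frozen in
        production because tuning there would break detailed balance.
        """
        rates = self.acceptance_rates()
        for name, rate in rates.items():
            if math.isnan(rate):
                continue
            amp = getattr(self.amplitudes, name)
            lo, hi = _AMP_BOUNDS[name]
            if rate > _TARGET_ACC[1]:
                amp = min(amp * 1.2, hi)
            elif rate < _TARGET_ACC[0]:
                amp = max(amp * 0.8, lo)
            setattr(self.amplitudes, name, amp)
        self.reset_acceptance()

    def recenter(self) -> None:
        """Translate the whole system so the pair midpoint sits at the box
        centre, then wrap ions.  A uniform shift leaves every energy term
        and the reaction coordinate unchanged."""
        ps = self.ps
        mid = 0.5 * (ps.mol_com(0) + ps.mol_com(1))
        ps.positions += ps.box.center - mid
        ion_sl = slice(ps.na + ps.nb, ps.n)
        if ps.box.periodic:
            ps.positions[ion_sl] = ps.box.wrap(ps.positions[ion_sl])

    @property
    def state(self) -> SystemState:
        return self.ps.to_state()

    @property
    def rc(self) -> float:
        return self.ps.rc()


def mc_sweep(
    state: SystemState,
    ff: ForceFieldParams,
    w: UmbrellaWindow | None,
    rng_seed: int,
) -> SystemState:
    """One Metropolis sweep as a pure function of (state, seed)."""
    sampler = MCSampler(state, ff, w, seed=rng_seed)
    sampler.sweep()
    return sampler.state


def run_window(
    state0: SystemState,
    ff: ForceFieldParams,
    w: UmbrellaWindow,
    n_equil_sweeps: int,
    n_prod_sweeps: int,
    sample_stride: int,
    seed: int,
    frame_stride: int = 0,
    tune_interval: int = 50,
) -> WindowRecord:
    """Equilibrate (with amplitude tuning), then record the biased chain.

    The reaction coordinate is sampled every ``sample_stride`` sweeps;
    ``frame_stride > 0`` additionally stores full system snapshots.
    """
    if n_prod_sweeps % sample_stride != 0:
        raise ValueError("sample_stride must divide n_prod_sweeps")
    if frame_stride and frame_stride % sample_stride != 0:
        raise ValueError("frame_stride must be a multiple of sample_stride")
    sampler = MCSampler(state0, ff, w, seed=seed)
    for s in range(n_equil_sweeps):
        sampler.sweep()
        if (s + 1) % tune_interval == 0:
            sampler.tune()
            sampler.recenter()
    sampler.reset_acceptance()

    n_samples = n_prod_sweeps // sample_stride
    rc_series = np.empty(n_samples)
    frames: list[SystemState] | None = [] if frame_stride else None
    for s in range(n_prod_sweeps):
        sampler.sweep()
        if (s + 1) % sample_stride == 0:
            k = (s + 1) // sample_stride - 1
            rc_series[k] = sampler.rc
            if frame_stride and (s + 1) % frame_stride == 0:
                frames.append(sampler.state)
    return WindowRecord(w, rc_series, frames, seed)
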