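"""Conformational and ion-atmosphere observables.

Covers the analyses that explain the topology- and valence-dependent
repulsion between the DNA pair: the gyration tensor and its principal
axes, the mutual orientation angle of the two molecules, a 2D Gaussian
kernel density over (separation, angle), RMSF after optimal
superposition, ion-site radial distribution functions and first-shell
coordination numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import SimulationBox

__all__ = [
    "GyrationSpectrum",
    "OrientationSample",
    "KDEField",
    "RMSFProfile",
    "RDFCurve",
    "gyration_tensor",
    "principal_axes",
    "radius_of_gyration",
    "orientation_angle",
    "kde2d",
    "kabsch_align",
    "rmsf_profile",
    "rdf",
    "coordination_number",
    "first_shell_radius",
]


@dataclass
class GyrationSpectrum:
    """Eigen-decomposition of a gyration tensor.

    ``eigenvalues`` are the principal moments in nm^2, sorted
    descending; ``eigenvectors[:, k]`` is the unit axis of
    ``eigenvalues[k]``; ``r_g`` is the radius of gyration.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    r_g: float


@dataclass
class OrientationSample:
    """One (separation, mutual angle) observation: r in nm, theta in
    degrees folded into [0, 90]."""

    r: float
    theta: float


@dataclass
class KDEField:
    """Normalised 2D kernel density over the (r, theta) grid."""

    grid_r: np.ndarray
    grid_theta: np.ndarray
    density: np.ndarray
    bandwidth: tuple[float, float]


@dataclass
class RMSFProfile:
    site_index: np.ndarray
    rmsf: np.ndarray


@dataclass
class RDFCurve:
    """g(r) between two site groups plus the bulk density of group B."""

    r_centers: np.ndarray
    g: np.ndarray
    rho_b: float


def gyration_tensor(positions: np.ndarray) -> np.ndarray:
    """Unweighted gyration dyadic ``S = (1/N) sum_i r_i r_i^T`` in the
    centre-of-mass frame (all sites equal mass), nm^2."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(pos) < 1:
        raise ValueError("need at least one position")
    centered = pos - pos.mean(axis=0)
    return centered.T @ centered / len(centered)


def principal_axes(S: np.ndarray) -> GyrationSpectrum:
    """Diagonalise a gyration tensor: eigenvalues descending, unit
    eigenvectors with the first nonzero component made positive."""
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3) or np.max(np.abs(S - S.T)) > 1e-9:
        raise ValueError("input must be a symmetric 3x3 matrix")
    evals, evecs = np.linalg.eigh(0.5 * (S + S.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for k in range(3):
        v = evecs[:, k]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if len(nz) and v[nz[0]] < 0:
            evecs[:, k] = -v
    r_g = float(np.sqrt(max(evals.sum(), 0.0)))
    return GyrationSpectrum(evals, evecs, r_g)


def radius_of_gyration(positions: np.ndarray) -> float:
    """Radius of gyration, nm (square root of the tensor trace)."""
    return float(np.sqrt(np.trace(gyration_tensor(positions))))


def orientation_angle(
    positions_a: np.ndarray, positions_b: np.ndarray, mode: str = "largest"
) -> float:
    """Mutual orientation angle of two molecules in degrees.

    ``theta = arccos(|p1 . p2|)`` where ``p_k`` is the eigenvector of
    molecule k's gyration tensor selected by ``mode``: ``"largest"``
    (long axis; the convention for linear pairs) or ``"smallest"``
    (plane normal; the convention for ring pairs).  The absolute value
    folds the eigenvector sign ambiguity into [0, 90] degrees.  A
    near-degenerate selected eigenvalue triggers a warning.
    """
    if mode not in ("largest", "smallest"):
        raise ValueError("mode must be 'largest' or 'smallest'")
    k = 0 if mode == "largest" else 2
    axes = []
    for pos in (positions_a, positions_b):
        spec = principal_axes(gyration_tensor(pos))
        lam = spec.eigenvalues
        gap = lam[0] - lam[1] if mode == "largest" else lam[1] - lam[2]
        if gap < 1e-12:
            warnings.warn(
                f"degenerate gyration spectrum for mode {mode!r}: the "
                "selected axis is not unique", stacklevel=2,
            )
        axes.append(spec.eigenvectors[:, k])
    cos = abs(float(np.dot(axes[0], axes[1])))
    return float(np.degrees(np.arccos(min(cos, 1.0))))


def _scott_bandwidth(values: np.ndarray) -> float:
    # Scott's rule per dimension for a 2D product kernel: sigma * n^(-1/6)
    return float(np.std(values, ddof=1) * len(values) ** (-1.0 / 6.0))


def kde2d(
    samples: list[OrientationSample] | np.ndarray,
    grid_r: np.ndarray | None = None,
    grid_theta: np.ndarray | None = None,
    bandwidth: tuple[float, float] | None = None,
) -> KDEField:
    """Product-Gaussian kernel density of (r, theta) samples on a grid.

    Bandwidths default to Scott's rule per dimension; the density is
    normalised so its trapezoidal integral over the grid is 1.  The
    default grid is 101 x 91 points over [2, 7] nm x [0, 90] degrees.
    """
    if isinstance(samples, np.ndarray):
        data = np.asarray(samples, dtype=float).reshape(-1, 2)
    else:
        data = np.array([[s.r, s.theta] for s in samples], dtype=float)
    if len(data) < 2:
        raise ValueError("need at least two samples")
    if grid_r is None:
        grid_r = np.linspace(2.0, 7.0, 101)
    if grid_theta is None:
        grid_theta = np.linspace(0.0, 90.0, 91)
    if bandwidth is None:
        h_r = _scott_bandwidth(data[:, 0])
        h_t = _scott_bandwidth(data[:, 1])
        if h_r <= 0 or h_t <= 0:
            raise ValueError(
                "zero variance in one dimension: pass an explicit bandwidth"
            )
        bandwidth = (h_r, h_t)
    h_r, h_t = bandwidth
    if h_r <= 0 or h_t <= 0:
        raise ValueError("bandwidths must be positive")

    # separable kernel: (G x K) outer product of per-dimension Gaussians
    kr = np.exp(-0.5 * ((grid_r[:, None] - data[None, :, 0]) / h_r) ** 2)
    kt = np.exp(-0.5 * ((grid_theta[:, None] - data[None, :, 1]) / h_t) ** 2)
    density = kr @ kt.T  # (len(grid_r), len(grid_theta))
    norm = np.trapezoid(np.trapezoid(density, grid_theta, axis=1), grid_r)
    if norm <= 0:
        raise ValueError("all kernel mass falls outside the grid")
    return KDEField(np.asarray(grid_r), np.asarray(grid_theta),
                    density / norm, (h_r, h_t))


def kabsch_align(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the minimised RMSD (nm).
    The rotation is proper (determinant +1, reflections excluded).
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have equal shapes")
    if len(mob) < 3:
        raise ValueError("need at least three sites for superposition")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    aligned = rot.apply(mob_c) + ref.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return aligned, rmsd


def rmsf_profile(
    frames: list[np.ndarray] | np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> RMSFProfile:
    """Per-site RMSF after superposition of every frame to ``reference``.

    Each frame is Kabsch-aligned on the selected sites; the fluctuation
    is taken about the time-mean aligned position (the reference serves
    only for alignment).
    """
    frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    sel = (np.arange(len(ref)) if selection is None
           else np.asarray(selection, dtype=int))
    aligned = np.empty((len(frames), len(sel), 3))
    for t, frame in enumerate(frames):
        aligned[t], _ = kabsch_align(frame[sel], ref[sel])
    mean_pos = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    return RMSFProfile(sel, rmsf)


def rdf(
    frames_a: list[np.ndarray],
    frames_b: list[np.ndarray],
    box: SimulationBox,
    bin_width: float = 0.02,
    r_max: float | None = None,
    same_group: bool = False,
) -> RDFCurve:
    """Radial pair distribution function of group B sites around group A.

    Minimum-image pair binning normalised by the shell volume
    ``4 pi r^2 dr`` and the bulk density ``rho_B = N_B / V`` (finite-
    size convention), averaged over frames.  With ``same_group=True``
    self pairs are excluded, so an ideal gas plateaus at
    ``(N_B - 1)/N_B`` under this normalisation.
    """
    if r_max is None:
        r_max = box.edge / 2.0
    if box.periodic and r_max > box.edge / 2.0 + 1e-12:
        raise ValueError("r_max must not exceed half the box edge")
    if len(frames_a) != len(frames_b):
        raise ValueError("need matching frame lists for the two groups")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    n_a = n_b = None
    for pos_a, pos_b in zip(frames_a, frames_b):
        pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
        pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
        n_a, n_b = len(pos_a), len(pos_b)
        d = box.min_image(pos_b[None, :, :] - pos_a[:, None, :])
        r = np.linalg.norm(d, axis=2)
        if same_group:
            np.fill_diagonal(r, np.inf)
        r = r[r < r_max]
        counts += np.bincount(
            (r / bin_width).astype(int), minlength=n_bins
        )[:n_bins]
    rho_b = n_b / box.volume
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (len(frames_a) * n_a * rho_b * shell_volumes)
    return RDFCurve(centers, g, rho_b)


def coordination_number(curve: RDFCurve, r_cut: float) -> float:
    """Running coordination ``n(r_cut) = 4 pi rho_B int_0^r g r^2 dr``
    (trapezoidal, with the integrand anchored at zero at r = 0)."""
    spacing = (curve.r_centers[1] - curve.r_centers[0]
               if len(curve.r_centers) > 1 else 0.0)
    if r_cut > curve.r_centers[-1] + spacing / 2.0 + 1e-12:
        raise ValueError("r_cut beyond the curve range")
    mask = curve.r_centers <= r_cut
    r = np.concatenate([[0.0], curve.r_centers[mask]])
    integrand = np.concatenate([[0.0], curve.g[mask] * curve.r_centers[mask] ** 2])
    return float(4.0 * np.pi * curve.rho_b * np.trapezoid(integrand, r))


def first_shell_radius(curve: RDFCurve, min_g: float = 0.0) -> float:
    """Default integration cutoff: the first local minimum of g(r) after
    its first maximum."""
    g = curve.g
    r = curve.r_centers
    n = len(g)
    peak = None
    for i in range(1, n - 1):
        if g[i] > min_g and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            peak = i
            break
    if peak is None:
        raise ValueError("no first peak found in g(r)")
    for i in range(peak + 1, n - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            return float(r[i])
    raise ValueError("no minimum after the first peak of g(r)")
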