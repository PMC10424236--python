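"""Weighted histogram analysis method for umbrella-sampling windows.

Given biased histograms :math:`n_i(x_b)` from windows with bias
:math:`w_i(x) = \\tfrac{k_i}{2}(x - c_i)^2`, the self-consistent WHAM
equations

.. math::

    P(x_b) = \\frac{\\sum_i n_i(x_b)}
                  {\\sum_i N_i \\exp[(f_i - w_i(x_b))/kT]},
    \\qquad
    e^{-f_i/kT} = \\sum_b P(x_b)\\, e^{-w_i(x_b)/kT}

are iterated to convergence (log-sum-exp throughout, gauge fixed by
pinning the first window's free energy to zero).  The effective pair
potential is the Boltzmann inversion of the recovered density,
referenced to zero at a chosen separation (7.0 nm by default in the
pipeline).  No radial-entropy (``2 kT ln r``) correction is applied:
the profile is the standard distance-coordinate WHAM output, so for two
isolated particles it equals ``U(r) - 2 kT ln(r/r_ref)`` up to the
reference shift.

The estimation stage is exposed both as plain functions and as a
model/results pair (:class:`WHAM` / :class:`WHAMResults`) in the style
of statsmodels: construct the model from window records or histograms,
``fit()`` it, then query the results object for the profile, window
free energies, overlap diagnostics, bootstrap uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import TEMPERATURE, kT
from .simulate import UmbrellaWindow, WindowRecord, bias_energy

__all__ = [
    "WindowHistogram",
    "PMFProfile",
    "WHAM",
    "WHAMResults",
    "ConvergenceError",
    "histogram_window",
    "solve_wham",
    "pmf_from_density",
    "overlap_diagnostic",
    "bootstrap_pmf",
    "default_bin_edges",
]


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class WindowHistogram:
    """Counts of one window's reaction-coordinate samples on shared bins."""

    window: UmbrellaWindow
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts length must be len(bin_edges) - 1")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PMFProfile:
    """Binned effective potential with its reference convention.

    ``v_eff`` is NaN on empty (unsampled) bins — they are flagged, never
    interpolated — and exactly zero at the bin containing
    ``reference_r``.
    """

    bin_centers: np.ndarray
    v_eff: np.ndarray
    reference_r: float
    stderr: np.ndarray | None = None
    counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.v_eff = np.asarray(self.v_eff, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.v_eff)

    def plot(self, ax=None, **kwargs):
        """Plot V_eff(r); requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.occupied
        if self.stderr is not None:
            ax.errorbar(self.bin_centers[m], self.v_eff[m],
                        yerr=self.stderr[m], **kwargs)
        else:
            ax.plot(self.bin_centers[m], self.v_eff[m], **kwargs)
        ax.set_xlabel("r (nm)")
        ax.set_ylabel(r"$V_\mathrm{eff}(r)$ (kJ/mol)")
        return ax


def default_bin_edges(
    r_min: float = 1.8, r_max: float = 7.2, width: float = 0.05
) -> np.ndarray:
    """Default PMF bins: 0.05 nm over [1.8, 7.2] nm (half the window
    spacing of the production protocol)."""
    n = int(round((r_max - r_min) / width))
    return r_min + width * np.arange(n + 1)


def histogram_window(record: WindowRecord, bin_edges: np.ndarray) -> WindowHistogram:
    """Bin a window's samples with the left-closed right-open convention.

    A sample outside ``[bin_edges[0], bin_edges[-1])`` is an error that
    names the offending value — never silently clipped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    x = record.rc_series
    if x.size == 0:
        raise ValueError("empty reaction-coordinate series")
    bad = (x < edges[0]) | (x >= edges[-1])
    if np.any(bad):
        raise ValueError(
            f"sample {x[bad][0]:.6g} nm outside the histogram range "
            f"[{edges[0]:g}, {edges[-1]:g})"
        )
    idx = np.searchsorted(edges, x, side="right") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return WindowHistogram(record.window, edges, counts)


def _check_shared_bins(histograms: list[WindowHistogram]) -> np.ndarray:
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if len(h.bin_edges) != len(edges) or not np.allclose(h.bin_edges, edges):
            raise ValueError("all histograms must share one set of bin edges")
    return edges


def _check_overlap_connectivity(occ: np.ndarray) -> None:
    """Require the windows to form one chain of shared occupied bins.

    ``occ`` is the (n_windows, n_bins) boolean occupancy matrix.
    """
    n = occ.shape[0]
    adj = (occ.astype(int) @ occ.astype(int).T) > 0
    seen = np.zeros(n, bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~seen))
    if not seen.all():
        first_missing = int(np.flatnonzero(~seen)[0])
        raise ValueError(
            "zero-overlap gap: window group containing index "
            f"{first_missing} shares no occupied bin with window 0's group"
        )


def solve_wham(
    histograms: list[WindowHistogram],
    temperature: float = TEMPERATURE,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM solution.

    Returns ``(f, density)``: per-window free energies in kJ/mol with
    the first window pinned to zero, and the unbiased probability per
    bin (normalised to unit sum over occupied bins; zero on empty
    bins).  ``tol`` is the convergence threshold on ``max |df_i|`` in
    units of kT.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = _check_shared_bins(list(histograms))
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = kT(temperature)

    counts = np.array([h.counts for h in histograms], dtype=float)  # (W, B)
    n_tot = counts.sum(axis=1)  # N_i
    occ_bins = counts.sum(axis=0) > 0
    _check_overlap_connectivity(counts > 0)

    # bias matrix w_i(x_b) / kT
    w = np.array(
        [[bias_energy(h.window, c) for c in centers] for h in histograms]
    ) / kt

    with np.errstate(divide="ignore"):
        log_counts_tot = np.log(counts.sum(axis=0))  # -inf on empty bins
        log_n = np.log(n_tot)

    g = np.zeros(len(histograms))  # f_i / kT
    residual_history: list[float] = []
    for iteration in range(max_iter):
        # log P_b = log sum_i n_i(b) - logsumexp_i [log N_i + g_i - w_ib]
        denom = logsumexp(log_n[:, None] + g[:, None] - w, axis=0)
        log_p = log_counts_tot - denom
        # g_i = -logsumexp_b [log P_b - w_ib]
        g_new = -logsumexp(log_p[None, :] - w, axis=1)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)))
        residual_history.append(residual)
        g = g_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e} kT, tol {tol:g} kT)",
            residual,
        )
    tail = residual_history[-10:]
    if any(b > a * (1 + 1e-12) + 1e-300 for a, b in zip(tail, tail[1:])):
        warnings.warn(
            "WHAM residual was not monotonically non-increasing over the "
            "final iterations", stacklevel=2,
        )

    density = np.zeros_like(log_p)
    density[occ_bins] = np.exp(log_p[occ_bins] - logsumexp(log_p[occ_bins]))
    return g * kt, density


def pmf_from_density(
    density: np.ndarray,
    bin_centers: np.ndarray,
    reference_r: float,
    temperature: float = TEMPERATURE,
    counts: np.ndarray | None = None,
) -> PMFProfile:
    """Boltzmann inversion ``-kT ln density`` referenced to zero at the
    bin containing ``reference_r``.  Rescaling the density by any
    positive constant leaves the profile unchanged."""
    density = np.asarray(density, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    if len(centers) > 1:
        # bin containing reference_r under the half-open convention
        width = centers[1] - centers[0]
        ref_bin = int(np.floor((reference_r - (centers[0] - width / 2.0))
                               / width + 1e-9))
        ref_bin = min(max(ref_bin, 0), len(centers) - 1)
    else:
        ref_bin = 0
    if density[ref_bin] <= 0:
        raise ValueError(
            f"reference bin at r = {centers[ref_bin]:g} nm is empty"
        )
    kt = kT(temperature)
    with np.errstate(divide="ignore"):
        v = np.where(density > 0, -kt * np.log(np.where(density > 0, density, 1.0)),
                     np.nan)
    v = v - v[ref_bin]
    v[ref_bin] = 0.0  # exact by convention
    return PMFProfile(centers, v, reference_r, counts=counts)


def overlap_diagnostic(
    histograms: list[WindowHistogram], flag_threshold: float = 0.05
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Summed-min overlap of each adjacent window pair (sorted by centre).

    Returns the per-pair overlap fractions in [0, 1] and the list of
    adjacent index pairs whose overlap falls below ``flag_threshold``.
    """
    if len(histograms) < 2:
        raise ValueError("need at least two histograms")
    order = np.argsort([h.window.center for h in histograms])
    flagged: list[tuple[int, int]] = []
    overlaps = np.empty(len(order) - 1)
    for k in range(len(order) - 1):
        i, j = int(order[k]), int(order[k + 1])
        a = histograms[i].counts / max(histograms[i].n_total, 1)
        b = histograms[j].counts / max(histograms[j].n_total, 1)
        overlaps[k] = float(np.minimum(a, b).sum())
        if overlaps[k] < flag_threshold:
            flagged.append((i, j))
    return overlaps, flagged


def bootstrap_pmf(
    records: list[WindowRecord],
    bin_edges: np.ndarray,
    reference_r: float,
    temperature: float = TEMPERATURE,
    n_boot: int = 20,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFProfile:
    """PMF with per-bin standard errors from window-wise bootstrap.

    Each replicate resamples every window's series with replacement and
    re-solves WHAM; ``stderr`` is the per-bin standard deviation across
    replicates.  The central value is the full-data solution.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    hists = [histogram_window(r, bin_edges) for r in records]
    f, density = solve_wham(hists, temperature, tol, max_iter)
    centers = hists[0].bin_centers
    total_counts = np.sum([h.counts for h in hists], axis=0)
    profile = pmf_from_density(density, centers, reference_r, temperature,
                               counts=total_counts)

    rng = np.random.default_rng(seed)
    replicates = np.full((n_boot, len(centers)), np.nan)
    for b in range(n_boot):
        boot_records = []
        for rec in records:
            x = rec.rc_series
            resampled = x[rng.integers(0, len(x), size=len(x))]
            boot_records.append(WindowRecord(rec.window, resampled, seed=rec.seed))
        boot_hists = [histogram_window(r, bin_edges) for r in boot_records]
        try:
            _, d = solve_wham(boot_hists, temperature, tol, max_iter)
        except (ConvergenceError, ValueError):
            continue
        p = pmf_from_density(d, centers, reference_r, temperature)
        replicates[b] = p.v_eff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stderr = np.nanstd(replicates, axis=0, ddof=1)
    profile.stderr = stderr
    return profile


class WHAM:
    """WHAM estimation model over a set of umbrella-window histograms.

    Parameters
    ----------
    histograms : list of WindowHistogram
        Biased histograms on shared bins.
    temperature : float
        Temperature in K used for all Boltzmann factors.
    records : list of WindowRecord, optional
        The underlying sample series; required for bootstrap errors.
    """

    def __init__(
        self,
        histograms: list[WindowHistogram],
        temperature: float = TEMPERATURE,
        records: list[WindowRecord] | None = None,
    ):
        self.histograms = list(histograms)
        self.temperature = temperature
        self.records = records
        _check_shared_bins(self.histograms)

    @classmethod
    def from_records(
        cls,
        records: list[WindowRecord],
        bin_edges: np.ndarray | None = None,
        temperature: float = TEMPERATURE,
    ) -> "WHAM":
        """Build the model directly from window sample series."""
        if bin_edges is None:
            lo = min(r.rc_series.min() for r in records)
            hi = max(r.rc_series.max() for r in records)
            bin_edges = default_bin_edges(lo - 0.05, hi + 0.05)
        hists = [histogram_window(r, bin_edges) for r in records]
        return cls(hists, temperature, records=list(records))

    def fit(self, tol: float = 1e-7, max_iter: int = 100_000) -> "WHAMResults":
        f, density = solve_wham(self.histograms, self.temperature, tol, max_iter)
        return WHAMResults(self, f, density, tol=tol, max_iter=max_iter)


class WHAMResults:
    """Converged WHAM solution: window free energies and unbiased density."""

    def __init__(self, model: WHAM, free_energies: np.ndarray,
                 density: np.ndarray, tol: float, max_iter: int):
        self.model = model
        self.free_energies = free_energies
        self.density = density
        self._tol = tol
        self._max_iter = max_iter

    @property
    def bin_centers(self) -> np.ndarray:
        return self.model.histograms[0].bin_centers

    def pmf(self, reference_r: float) -> PMFProfile:
        """Effective potential referenced to zero at ``reference_r``."""
        counts = np.sum([h.counts for h in self.model.histograms], axis=0)
        return pmf_from_density(
            self.density, self.bin_centers, reference_r,
            self.model.temperature, counts=counts,
        )

    def overlap(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        return overlap_diagnostic(self.model.histograms)

    def bootstrap(self, reference_r: float, n_boot: int = 20,
                  seed: int = 0) -> PMFProfile:
        if self.model.records is None:
            raise ValueError("bootstrap requires the model to hold records")
        return bootstrap_pmf(
            self.model.records, self.model.histograms[0].bin_edges,
            reference_r, self.model.temperature, n_boot, seed,
            self._tol, self._max_iter,
        )

    def summary(self) -> str:
        """Per-window table: centre, force constant, samples, f_i, overlap."""
        hists = self.model.histograms
        overlaps = (
            list(overlap_diagnostic(hists)[0]) + [float("nan")]
            if len(hists) > 1 else [float("nan")]
        )
        lines = [
            "WHAM results",
            f"  temperature: {self.model.temperature:g} K   "
            f"windows: {len(hists)}   bins: {len(self.bin_centers)}",
            "",
            f"{'center(nm)':>10} {'k(kJ/mol/nm^2)':>15} {'n':>8} "
            f"{'f_i(kJ/mol)':>12} {'overlap->':>10}",
        ]
        for h, f, ov in zip(hists, self.free_energies, overlaps):
            lines.append(
                f"{h.window.center:>10.3f} {h.window.force_k:>15.1f} "
                f"{h.n_total:>8d} {f:>12.4f} {ov:>10.3f}"
            )
        return "\n".join(lines)
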