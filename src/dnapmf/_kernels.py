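"""Numba kernels for the nonbonded energy sums.

The documented interaction rules live here in one place:

* Coulomb ``pref * z_i z_j * [f(r) - f(r_cut)]`` for ``r < r_cut``,
  with ``f(r) = exp(-r/lambda)/r`` (``lambda = 0`` meaning bare
  ``1/r``) and ``pref = kT * l_B``.  ``r_cut >= 1e30`` disables the
  cutoff and the shift.
* WCA with additive contact distance ``sigma_ij = rad_i + rad_j``,
  active unless both sites belong to the same molecule
  (``mol_id >= 0`` marks molecule membership; ions carry -1).

All kernels use the minimum-image convention for a cubic box of edge
``edge`` (``edge <= 0`` disables periodicity).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared reduced cutoff (2^(1/6))^2
NO_CUTOFF = 1e30


@njit(cache=True)
def _pair_energy(r2, qq, sig, wca_on, pref, eps, lam, rcut, fshift):
    """Energy of one pair from its squared distance."""
    e = 0.0
    if r2 < 1e-12:
        # overlapping point charges / sites: numeric guard
        raise FloatingPointError("overlapping sites below 1e-6 nm")
    if qq != 0.0 and r2 < rcut * rcut:
        r = np.sqrt(r2)
        if lam > 0.0:
            f = np.exp(-r / lam) / r
        else:
            f = 1.0 / r
        e += pref * qq * (f - fshift)
    if wca_on and r2 < _WCA_CUT2 * sig * sig:
        sr2 = sig * sig / r2
        sr6 = sr2 * sr2 * sr2
        e += 4.0 * eps * (sr6 * sr6 - sr6) + eps
    return e


@njit(cache=True)
def _min_image2(dx, dy, dz, edge):
    if edge > 0.0:
        dx -= edge * np.round(dx / edge)
        dy -= edge * np.round(dy / edge)
        dz -= edge * np.round(dz / edge)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def particle_delta(pos, q, rad, mol_id, i, new_pos,
                   edge, pref, eps, lam, rcut, fshift):
    """E(new) - E(old) of particle ``i`` against all other particles."""
    n = pos.shape[0]
    qi = q[i]
    ri = rad[i]
    mi = mol_id[i]
    xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
    xn, yn, zn = new_pos[0], new_pos[1], new_pos[2]
    de = 0.0
    for j in range(n):
        if j == i:
            continue
        wca_on = not (mi == mol_id[j] and mi >= 0)
        qq = qi * q[j]
        sig = ri + rad[j]
        r2o = _min_image2(pos[j, 0] - xo, pos[j, 1] - yo, pos[j, 2] - zo, edge)
        r2n = _min_image2(pos[j, 0] - xn, pos[j, 1] - yn, pos[j, 2] - zn, edge)
        de += _pair_energy(r2n, qq, sig, wca_on, pref, eps, lam, rcut, fshift)
        de -= _pair_energy(r2o, qq, sig, wca_on, pref, eps, lam, rcut, fshift)
    return de


@njit(cache=True)
def group_delta(pos, q, rad, mol_id, start, stop, new_group,
                edge, pref, eps, lam, rcut, fshift):
    """E(new) - E(old) of a molecule (contiguous slice) against the rest."""
    n = pos.shape[0]
    de = 0.0
    for k in range(start, stop):
        qk = q[k]
        rk = rad[k]
        mk = mol_id[k]
        for j in range(n):
            if start <= j < stop:
                continue
            wca_on = not (mk == mol_id[j] and mk >= 0)
            qq = qk * q[j]
            sig = rk + rad[j]
            r2o = _min_image2(pos[j, 0] - pos[k, 0], pos[j, 1] - pos[k, 1],
                              pos[j, 2] - pos[k, 2], edge)
            kk = k - start
            r2n = _min_image2(pos[j, 0] - new_group[kk, 0],
                              pos[j, 1] - new_group[kk, 1],
                              pos[j, 2] - new_group[kk, 2], edge)
            de += _pair_energy(r2n, qq, sig, wca_on, pref, eps, lam, rcut, fshift)
            de -= _pair_energy(r2o, qq, sig, wca_on, pref, eps, lam, rcut, fshift)
    return de


@njit(cache=True)
def nonbonded_total(pos, q, rad, mol_id, edge, pref, eps, lam, rcut, fshift):
    """Full nonbonded sum over distinct pairs."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            wca_on = not (mol_id[i] == mol_id[j] and mol_id[i] >= 0)
            qq = q[i] * q[j]
            sig = rad[i] + rad[j]
            r2 = _min_image2(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                             pos[j, 2] - pos[i, 2], edge)
            e += _pair_energy(r2, qq, sig, wca_on, pref, eps, lam, rcut, fshift)
    return e
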