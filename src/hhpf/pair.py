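"""Direct pairwise MGCM engine.

Evaluates the multi-Gaussian core potential by explicit pair sums with the
periodic minimum-image convention.  Serves both as a standalone simulation
engine and as the independent cross-check for the field engine.  A
numba-compiled cell-list kernel handles production system sizes (cell
lists are rebuilt every evaluation); a vectorized numpy all-pairs routine
is retained as the O(N^2) oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .potentials import MGCMParams


@dataclass(frozen=True)
class NeighborScheme:
    """Cutoff plus derived cell-list geometry.

    The cutoff must swallow the Gaussian tails (>= 5 sigma_G,max keeps the
    truncation below 1e-5 of the well depth) and respect the minimum-image
    convention (<= half the smallest box edge).
    """

    cutoff: float

    def validate(self, params: MGCMParams, box) -> None:
        box = np.asarray(box, dtype=float)
        smax = float(params.sigma.max())
        if self.cutoff < 5.0 * smax:
            raise ValueError(
                f"cutoff {self.cutoff} < 5 x largest sigma_G ({5 * smax:.4g})"
            )
        if self.cutoff > 0.5 * float(box.min()):
            raise ValueError(
                f"cutoff {self.cutoff} exceeds half the smallest box edge "
                f"({0.5 * box.min():.4g})"
            )


@njit(cache=True)
def _pair_kernel_all(pos, box, a, sig, cutoff):
    n = pos.shape[0]
    energy = 0.0
    forces = np.zeros((n, 3))
    cut2 = cutoff * cutoff
    for k in range(n - 1):
        for l in range(k + 1, n):
            dx = pos[k, 0] - pos[l, 0]
            dy = pos[k, 1] - pos[l, 1]
            dz = pos[k, 2] - pos[l, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cut2:
                continue
            f_over_r = 0.0
            for t in range(a.shape[0]):
                e = a[t] * np.exp(-r2 / (sig[t] * sig[t]))
                energy += e
                f_over_r += 2.0 * e / (sig[t] * sig[t])
            forces[k, 0] += f_over_r * dx
            forces[k, 1] += f_over_r * dy
            forces[k, 2] += f_over_r * dz
            forces[l, 0] -= f_over_r * dx
            forces[l, 1] -= f_over_r * dy
            forces[l, 2] -= f_over_r * dz
    return energy, forces


@njit(cache=True)
def _pair_kernel_cells(pos, box, a, sig, cutoff, ncell, head, nxt):
    n = pos.shape[0]
    energy = 0.0
    forces = np.zeros((n, 3))
    cut2 = cutoff * cutoff
    ncx, ncy, ncz = ncell[0], ncell[1], ncell[2]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                k = head[c]
                while k >= 0:
                    # same cell: pairs with larger linked-list successors
                    l = nxt[k]
                    while l >= 0:
                        energy += _accumulate(pos, box, a, sig, cut2,
                                              forces, k, l)
                        l = nxt[l]
                    # half of the 26 neighbor cells
                    for off in range(13):
                        nx = (cx + _NEIGHBOR_OFFSETS[off, 0]) % ncx
                        ny = (cy + _NEIGHBOR_OFFSETS[off, 1]) % ncy
                        nz = (cz + _NEIGHBOR_OFFSETS[off, 2]) % ncz
                        c2 = (nx * ncy + ny) * ncz + nz
                        if c2 == c:
                            continue
                        l = head[c2]
                        while l >= 0:
                            energy += _accumulate(pos, box, a, sig, cut2,
                                                  forces, k, l)
                            l = nxt[l]
                    k = nxt[k]
    return energy, forces


_NEIGHBOR_OFFSETS = np.array(
    [(1, 0, 0), (0, 1, 0), (0, 0, 1),
     (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
     (0, 1, 1), (0, 1, -1),
     (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
)


@njit(cache=True, inline="always")
def _accumulate(pos, box, a, sig, cut2, forces, k, l):
    dx = pos[k, 0] - pos[l, 0]
    dy = pos[k, 1] - pos[l, 1]
    dz = pos[k, 2] - pos[l, 2]
    dx -= box[0] * np.rint(dx / box[0])
    dy -= box[1] * np.rint(dy / box[1])
    dz -= box[2] * np.rint(dz / box[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 > cut2:
        return 0.0
    e_sum = 0.0
    f_over_r = 0.0
    for t in range(a.shape[0]):
        e = a[t] * np.exp(-r2 / (sig[t] * sig[t]))
        e_sum += e
        f_over_r += 2.0 * e / (sig[t] * sig[t])
    forces[k, 0] += f_over_r * dx
    forces[k, 1] += f_over_r * dy
    forces[k, 2] += f_over_r * dz
    forces[l, 0] -= f_over_r * dx
    forces[l, 1] -= f_over_r * dy
    forces[l, 2] -= f_over_r * dz
    return e_sum


def _build_cells(pos, box, ncell):
    idx = np.floor(pos / box * ncell).astype(np.int64)
    idx = np.clip(idx, 0, np.asarray(ncell) - 1)
    flat = (idx[:, 0] * ncell[1] + idx[:, 1]) * ncell[2] + idx[:, 2]
    n_cells = int(np.prod(ncell))
    head = np.full(n_cells, -1, dtype=np.int64)
    nxt = np.full(len(pos), -1, dtype=np.int64)
    for k in range(len(pos)):
        nxt[k] = head[flat[k]]
        head[flat[k]] = k
    return head, nxt


def pair_energy_forces(system, params: MGCMParams, scheme: NeighborScheme):
    """Total truncated MGCM energy and per-particle forces (cell lists).

    Falls back to the all-pairs kernel when the box admits fewer than
    3 cells per axis (cell lists then degenerate).
    """
    pos = np.mod(np.asarray(system.positions, dtype=float),
                 np.asarray(system.box, dtype=float))
    box = np.asarray(system.box, dtype=float)
    scheme.validate(params, box)
    a = params.a.astype(float)
    sig = params.sigma.astype(float)
    ncell = np.floor(box / scheme.cutoff).astype(np.int64)
    if np.any(ncell < 3):
        return _pair_kernel_all(pos, box, a, sig, scheme.cutoff)
    head, nxt = _build_cells(pos, box, ncell)
    return _pair_kernel_cells(pos, box, a, sig, scheme.cutoff,
                              ncell, head, nxt)


def pair_energy_forces_bruteforce(system, params: MGCMParams,
                                  scheme: NeighborScheme):
    """Vectorized O(N^2) oracle: all pairs, minimum image, truncated."""
    pos = np.mod(np.asarray(system.positions, dtype=float),
                 np.asarray(system.box, dtype=float))
    box = np.asarray(system.box, dtype=float)
    scheme.validate(params, box)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.rint(d / box)
    r2 = (d * d).sum(axis=-1)
    n = len(pos)
    iu = np.triu_indices(n, k=1)
    mask = r2[iu] <= scheme.cutoff ** 2
    energy = 0.0
    f_over_r = np.zeros_like(r2)
    for aa, ss in params.terms:
        e = aa * np.exp(-r2 / (ss * ss))
        energy += float(e[iu][mask].sum())
        f_over_r += 2.0 * e / (ss * ss)
    f_over_r[r2 > scheme.cutoff ** 2] = 0.0
    np.fill_diagonal(f_over_r, 0.0)
    forces = (f_over_r[:, :, None] * d).sum(axis=1)
    return energy, forces


class PairForceProvider:
    """Force-provider facade matching the field engine's interface."""

    def __init__(self, params: MGCMParams, scheme: NeighborScheme):
        self.params = params
        self.scheme = scheme

    def __call__(self, system):
        return self.energy_forces(system)

    def energy_forces(self, system):
        return pair_energy_forces(system, self.params, self.scheme)
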