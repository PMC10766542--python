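"""Sparse Tucker-decomposed forward model of the diffusion signal.

A connectome's predicted (demeaned) diffusion signal is ``Y = Phi x1 D x2 S0
x3 w^T``: a sparse coefficient tensor ``Phi`` (voxel x atom x fiber), an
orientation dictionary ``D`` (direction x atom, demeaned columns), the
per-voxel baseline ``S0`` and the non-negative fiber weights ``w``. The tensor
is stored as a COO list sorted along the voxel dimension so the matrix-vector
kernels ``Mx`` and ``M^T y`` stream one voxel run at a time; entries whose
weight element is zero contribute nothing and are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, DiffusionVolume, GradientScheme
from .phantom import fibonacci_sphere

logger = logging.getLogger(__name__)

__all__ = [
    "OrientationDictionary",
    "SparseModel",
    "build_dictionary",
    "quantize_orientation",
    "build_sparse_model",
    "matvec_Mx",
    "rmatvec_MTy",
    "densify",
]


def hemisphere_atoms(n: int) -> np.ndarray:
    """n well-spread unit vectors on the upper hemisphere (z > 0).

    Deterministic Fibonacci-spiral tessellation; restricting to z > 0 makes the
    set antipodally unique, as orientations are sign-invariant.
    """
    k = np.arange(n)
    z = (k + 0.5) / n  # in (0, 1): strictly upper hemisphere
    r = np.sqrt(1.0 - z * z)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class OrientationDictionary:
    """Canonical orientation atoms and their demeaned stick-kernel responses.

    Column ``a`` of ``D`` is the signal attenuation profile of a stick (axially
    symmetric tensor) along atom ``a``, demeaned across gradient directions:
    ``exp(-b_i * ((d_ax - d_rad) (g_i . u_a)^2 + d_rad))`` minus its mean.
    """

    atoms: np.ndarray  # (n_atoms, 3) unit vectors, antipodally unique
    D: np.ndarray  # (n_dirs, n_atoms), zero-mean columns
    diffusivities: tuple = (1.0e-3, 0.0)  # (axial, radial) mm^2/s

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape[1] != self.atoms.shape[0]:
            raise ValueError("D columns must align with atoms")
        col_means = self.D.mean(axis=0)
        if np.any(np.abs(col_means) > 1e-12):
            raise ValueError("dictionary columns must be demeaned")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]


def build_dictionary(
    scheme: GradientScheme,
    n_atoms: int = 96,
    diffusivities: tuple = (1.0e-3, 0.0),
) -> OrientationDictionary:
    """Stick-kernel orientation dictionary for a gradient scheme."""
    d_ax, d_rad = diffusivities
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    if d_ax < d_rad:
        raise ValueError("axial diffusivity must be >= radial diffusivity")
    atoms = hemisphere_atoms(n_atoms)
    cos2 = (scheme.directions @ atoms.T) ** 2  # (n_dirs, n_atoms)
    adc = (d_ax - d_rad) * cos2 + d_rad
    raw = np.exp(-scheme.bvalues[:, None] * adc)
    D = raw - raw.mean(axis=0, keepdims=True)
    return OrientationDictionary(atoms, D, (d_ax, d_rad))


def quantize_orientation(direction: np.ndarray, dictionary: OrientationDictionary) -> int:
    """Index of the atom most parallel (up to sign) to ``direction``.

    Ties break toward the lowest atom index.
    """
    d = np.asarray(direction, dtype=float)
    if np.linalg.norm(d) == 0:
        raise ValueError("cannot quantize a zero direction")
    return int(np.argmax(np.abs(dictionary.atoms @ d)))


@dataclass
class SparseModel:
    """Voxel-sorted COO representation of the forward operator M.

    ``voxel_index`` addresses the model's own voxel list (0..n_voxels-1, in
    ascending grid linear index ``i + X*(j + Y*k)``); ``voxels`` maps back to
    grid linear indices. ``b`` is the per-voxel demeaned measured signal,
    concatenated voxel-block by voxel-block.
    """

    voxel_index: np.ndarray  # (n_entries,) int, non-decreasing
    atom_index: np.ndarray  # (n_entries,) int
    fiber_index: np.ndarray  # (n_entries,) int
    coeff: np.ndarray  # (n_entries,) float > 0 (segment lengths, mm)
    D: np.ndarray  # (n_dirs, n_atoms)
    s0: np.ndarray  # (n_voxels,)
    b: np.ndarray  # (n_voxels * n_dirs,)
    n_fibers: int
    voxels: np.ndarray  # (n_voxels,) grid linear indices
    grid_shape: tuple = (0, 0, 0)
    n_skipped_segments: int = 0
    atoms: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("voxel_index", "atom_index", "fiber_index"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.coeff = np.asarray(self.coeff, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if np.any(np.diff(self.voxel_index) < 0):
            raise ValueError("entries must be sorted by voxel index")
        if np.any(self.coeff <= 0):
            raise ValueError("coefficients must be positive")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("b must be finite")
        n_v, n_a = self.s0.shape[0], self.D.shape[1]
        if self.voxel_index.size and (
            self.voxel_index.min() < 0 or self.voxel_index.max() >= n_v
        ):
            raise ValueError("voxel index out of range")
        if self.atom_index.size and (
            self.atom_index.min() < 0 or self.atom_index.max() >= n_a
        ):
            raise ValueError("atom index out of range")
        if self.fiber_index.size and (
            self.fiber_index.min() < 0 or self.fiber_index.max() >= self.n_fibers
        ):
            raise ValueError("fiber index out of range")
        if self.b.shape[0] != n_v * self.n_dirs:
            raise ValueError("b length must be n_voxels * n_dirs")

    @property
    def n_voxels(self) -> int:
        return self.s0.shape[0]

    @property
    def n_dirs(self) -> int:
        return self.D.shape[0]

    @property
    def dims(self) -> tuple:
        return (self.n_voxels, self.n_dirs, self.n_fibers, self.D.shape[1])

    # -- voxel-sorted kernels -------------------------------------------------

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Mx: predicted demeaned signal for fiber weights x.

        Accumulates ``S0(v) * x_f * coeff * D[:, a]`` per sorted voxel run;
        entries whose weight element is zero are skipped outright.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_fibers,):
            raise ValueError("x must have one entry per fiber")
        if not np.all(np.isfinite(x)):
            raise ValueError("x must be finite")
        active = x[self.fiber_index] != 0.0
        G = np.zeros((self.n_voxels, self.D.shape[1]))
        np.add.at(
            G,
            (self.voxel_index[active], self.atom_index[active]),
            self.coeff[active] * x[self.fiber_index[active]],
        )
        return ((self.s0[:, None] * G) @ self.D.T).ravel()

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        """M^T y: per-fiber inner products with the dictionary columns."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_voxels * self.n_dirs,):
            raise ValueError("y must have n_voxels * n_dirs entries")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        # P[v, a] = D[:, a] . y_v-block
        P = y.reshape(self.n_voxels, self.n_dirs) @ self.D
        out = np.zeros(self.n_fibers)
        np.add.at(
            out,
            self.fiber_index,
            self.s0[self.voxel_index] * self.coeff * P[self.voxel_index, self.atom_index],
        )
        return out

    def densify(self, cap: int = 10_000_000) -> np.ndarray:
        """Explicit dense M, for small models and oracle checks only."""
        n_elem = self.n_voxels * self.n_dirs * self.n_fibers
        if n_elem > cap:
            raise ValueError(
                f"dense M would hold {n_elem} elements (cap {cap}); refusing"
            )
        M = np.zeros((self.n_voxels * self.n_dirs, self.n_fibers))
        for v, a, f, c in zip(
            self.voxel_index, self.atom_index, self.fiber_index, self.coeff
        ):
            M[v * self.n_dirs : (v + 1) * self.n_dirs, f] += self.s0[v] * c * self.D[:, a]
        return M


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return points[:1]
    n_steps = max(1, int(np.ceil(total / step)))
    t = np.linspace(0.0, total, n_steps + 1)
    out = np.empty((t.size, 3))
    for d in range(3):
        out[:, d] = np.interp(t, arc, points[:, d])
    return out


def build_sparse_model(
    c: Connectome,
    vol: DiffusionVolume,
    dictionary: OrientationDictionary,
    step_mm: float | None = None,
) -> SparseModel:
    """Encode a connectome against a diffusion volume.

    Each streamline is resampled at ``step_mm`` (default: half the voxel size);
    every inter-node segment contributes one COO entry at the voxel of its
    midpoint, with the atom nearest its direction and coefficient equal to the
    segment length in mm. Duplicate (voxel, atom, fiber) triplets are summed;
    segments falling outside the grid or mask are skipped and counted.
    """
    if len(c) == 0:
        raise ValueError("cannot encode an empty connectome")
    if step_mm is None:
        step_mm = 0.5 * float(np.abs(np.diag(vol.affine)[:3]).min())
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")

    dims = np.asarray(vol.grid_shape)
    inv = np.linalg.inv(vol.affine)
    vox_list, atom_list, fib_list, coeff_list = [], [], [], []
    n_skipped = 0
    for f, s in enumerate(c.streamlines):
        nodes = _resample_polyline(s, step_mm)
        if nodes.shape[0] < 2:
            n_skipped += 1
            continue
        deltas = np.diff(nodes, axis=0)
        lengths = np.linalg.norm(deltas, axis=1)
        keep = lengths > 0
        deltas, lengths = deltas[keep], lengths[keep]
        mids = 0.5 * (nodes[:-1] + nodes[1:])[keep]
        ijk = np.round(mids @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((ijk >= 0) & (ijk < dims), axis=1)
        if np.any(inside):
            ii, jj, kk = ijk[inside].T
            in_mask = vol.mask[ii, jj, kk]
            inside_idx = np.flatnonzero(inside)[in_mask]
        else:
            inside_idx = np.array([], dtype=int)
        n_skipped += lengths.size - inside_idx.size
        if inside_idx.size == 0:
            continue
        ii, jj, kk = ijk[inside_idx].T
        lin = ii + dims[0] * (jj + dims[1] * kk)
        atom = np.argmax(np.abs(deltas[inside_idx] @ dictionary.atoms.T), axis=1)
        vox_list.append(lin)
        atom_list.append(atom)
        fib_list.append(np.full(lin.size, f, dtype=np.int64))
        coeff_list.append(lengths[inside_idx])

    if not vox_list:
        raise ValueError("no streamline intersects the volume: empty model")
    if n_skipped:
        logger.info("build_sparse_model: skipped %d out-of-mask segments", n_skipped)

    lin = np.concatenate(vox_list)
    atom = np.concatenate(atom_list)
    fib = np.concatenate(fib_list)
    coeff = np.concatenate(coeff_list)

    # sum duplicate (voxel, atom, fiber) triplets
    order = np.lexsort((atom, fib, lin))
    lin, atom, fib, coeff = lin[order], atom[order], fib[order], coeff[order]
    new_run = np.concatenate(
        [[True], (np.diff(lin) != 0) | (np.diff(fib) != 0) | (np.diff(atom) != 0)]
    )
    group = np.cumsum(new_run) - 1
    coeff = np.bincount(group, weights=coeff)
    lin, atom, fib = lin[new_run], atom[new_run], fib[new_run]

    voxels = np.unique(lin)  # sorted grid linear indices of the model voxels
    vloc = np.searchsorted(voxels, lin)

    # stable sort by model voxel index (lexsort above already groups by lin,
    # but keep the contract explicit)
    order = np.argsort(vloc, kind="stable")
    vloc, atom, fib, coeff = vloc[order], atom[order], fib[order], coeff[order]

    ii, jj, kk = np.unravel_index(voxels, tuple(dims), order="F")
    s0 = vol.s0[ii, jj, kk]
    meas = vol.signal[ii, jj, kk, :]
    b = (meas - meas.mean(axis=1, keepdims=True)).ravel()

    return SparseModel(
        voxel_index=vloc,
        atom_index=atom,
        fiber_index=fib,
        coeff=coeff,
        D=dictionary.D,
        s0=s0,
        b=b,
        n_fibers=len(c),
        voxels=voxels,
        grid_shape=tuple(int(d) for d in dims),
        n_skipped_segments=int(n_skipped),
        atoms=dictionary.atoms,
    )


def matvec_Mx(model: SparseModel, x: np.ndarray) -> np.ndarray:
    return model.matvec(x)


def rmatvec_MTy(model: SparseModel, y: np.ndarray) -> np.ndarray:
    return model.rmatvec(y)


def densify(model: SparseModel, cap: int = 10_000_000) -> np.ndarray:
    return model.densify(cap)
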