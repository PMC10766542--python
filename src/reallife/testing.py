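"""Small synthetic models for oracle checks and benchmarks.

These build :class:`~reallife.encode.SparseModel` instances directly from
random or hand-chosen COO entries, bypassing streamline geometry, so kernel
and solver behavior can be checked against dense linear-algebra oracles.
"""

from __future__ import annotations

import numpy as np

from .encode import SparseModel

__all__ = ["random_sparse_model", "identity_model"]


def random_sparse_model(seed: int) -> SparseModel:
    """A small random COO model (<= 60 signal rows, <= 8 fibers)."""
    rng = np.random.default_rng(seed)
    n_voxels = int(rng.integers(2, 6))
    n_dirs = int(rng.integers(6, 12))
    n_fibers = int(rng.integers(2, 9))
    n_atoms = int(rng.integers(3, 10))
    vox, atom, fib, coeff = [], [], [], []
    for f in range(n_fibers):
        for _ in range(int(rng.integers(1, 5))):
            vox.append(int(rng.integers(n_voxels)))
            atom.append(int(rng.integers(n_atoms)))
            fib.append(f)
            coeff.append(float(rng.uniform(0.1, 2.0)))
    order = np.argsort(vox, kind="stable")
    D = rng.normal(size=(n_dirs, n_atoms))
    D -= D.mean(axis=0, keepdims=True)
    meas = rng.normal(size=(n_voxels, n_dirs))
    b = (meas - meas.mean(axis=1, keepdims=True)).ravel()
    return SparseModel(
        voxel_index=np.asarray(vox)[order],
        atom_index=np.asarray(atom)[order],
        fiber_index=np.asarray(fib)[order],
        coeff=np.asarray(coeff)[order],
        D=D,
        s0=rng.uniform(0.5, 2.0, n_voxels),
        b=b,
        n_fibers=n_fibers,
        voxels=np.arange(n_voxels),
        grid_shape=(n_voxels, 1, 1),
    )


def identity_model(b: np.ndarray, scale: float = 1.0) -> SparseModel:
    """A model whose dense M is ``scale * I_n`` (one voxel, n dirs = n fibers)."""
    b = np.asarray(b, dtype=float)
    n = b.size
    return SparseModel(
        voxel_index=np.zeros(n, dtype=int),
        atom_index=np.arange(n),
        fiber_index=np.arange(n),
        coeff=np.full(n, scale),
        D=np.eye(n),
        s0=np.ones(1),
        b=b,
        n_fibers=n,
        voxels=np.zeros(1, dtype=int),
        grid_shape=(1, 1, 1),
    )
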