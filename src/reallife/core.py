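"""Shared domain containers for diffusion data and streamline connectomes.

All world coordinates are in millimetres; voxel indices are 0-based and the
affine maps the voxel *center* ``(i, j, k, 1)`` to mm. Diffusion volumes hold
only the diffusion-weighted directions; the baseline (b=0) signal lives in a
separate per-voxel ``s0`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "Connectome", "DiffusionVolume"]


@dataclass
class GradientScheme:
    """Diffusion gradient table: unit directions and b-values (s/mm^2).

    Only diffusion-weighted volumes are listed; ``n_b0`` records how many
    baseline volumes the acquisition carried (they are averaged into S0).
    """

    directions: np.ndarray  # (n_dirs, 3) unit vectors
    bvalues: np.ndarray  # (n_dirs,) s/mm^2
    n_b0: int = 1

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if self.directions.shape[0] < 6:
            raise ValueError("a gradient scheme needs at least 6 directions")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("gradient directions must be unit vectors")
        if self.bvalues.shape != (self.directions.shape[0],):
            raise ValueError("bvalues must align with directions")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be non-negative")

    @property
    def n_dirs(self) -> int:
        return self.directions.shape[0]


@dataclass
class Connectome:
    """An ordered collection of streamlines (polylines in mm world space).

    ``labels``, when present, holds one ``(start_roi, end_roi)`` integer pair
    per streamline (endpoint parcellation region ids).
    """

    streamlines: list  # list of (n_i, 3) float arrays, n_i >= 2
    labels: np.ndarray | None = None  # (n_streamlines, 2) int

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for k, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {k} must be an (n>=2, 3) array")
            if np.any(np.all(np.diff(s, axis=0) == 0.0, axis=1)):
                raise ValueError(f"streamline {k} has consecutive duplicate nodes")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.streamlines), 2):
                raise ValueError("labels must be (n_streamlines, 2)")

    def __len__(self) -> int:
        return len(self.streamlines)

    def copy(self) -> "Connectome":
        labels = None if self.labels is None else self.labels.copy()
        return Connectome([s.copy() for s in self.streamlines], labels)


@dataclass
class DiffusionVolume:
    """4D diffusion-weighted signal with baseline, mask and voxel->mm affine."""

    signal: np.ndarray  # (X, Y, Z, n_dirs), non-negative
    s0: np.ndarray  # (X, Y, Z), > 0 inside mask
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # (4, 4), invertible
    scheme: GradientScheme | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (X, Y, Z, n_dirs)")
        if self.s0.shape != self.signal.shape[:3]:
            raise ValueError("s0 grid must match signal grid")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask grid must match signal grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if np.any(self.signal < 0):
            raise ValueError("signal intensities must be non-negative")
        if np.any(self.s0[self.mask] <= 0):
            raise ValueError("s0 must be positive inside the mask")

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.signal.shape[:3])

    @property
    def n_dirs(self) -> int:
        return self.signal.shape[3]

    def demeaned(self) -> np.ndarray:
        """Signal minus its per-voxel mean across gradient directions."""
        return self.signal - self.signal.mean(axis=3, keepdims=True)

    def voxel_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-space points (n, 3) to 0-based voxel indices (n, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = pts @ inv[:3, :3].T + inv[:3, 3]
        return np.round(ijk).astype(int)
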