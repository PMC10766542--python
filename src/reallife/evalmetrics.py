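"""Fit-quality and duplicate-fiber evaluation.

Three instruments: a per-pair uniqueness index for duplicated fibers
(``zeta = |w1 - w2| / (w1 + w2)``), voxel-wise cross-validated r.m.s.e. maps
between demeaned diffusion signals, and the two cross-validation protocols
(overfitting: fit on one acquisition, score against an independent one;
consistency: cross-fit two connectomes on swapped acquisitions and compare
their top-half predictions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome, DiffusionVolume
from .encode import OrientationDictionary, SparseModel, build_dictionary, build_sparse_model
from .phantom import jitter_connectome, trim_connectome
from .solver import SolverConfig, solve

__all__ = [
    "UniquenessReport",
    "RmseMap",
    "uniqueness_index",
    "duplicate_experiment",
    "voxel_rmse",
    "overfit_protocol",
    "consistency_protocol",
    "select_top_weights",
]


def uniqueness_index(w1: float, w2: float) -> float:
    """Normalized weight difference between two copies of a fiber, in [0, 1].

    0 means the copies kept identical weights; 1 means one copy was fully
    pruned. Undefined (raises) when both weights are zero.
    """
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    if w1 == 0 and w2 == 0:
        raise ValueError("uniqueness index undefined for a both-zero pair")
    return abs(w1 - w2) / (w1 + w2)


@dataclass
class UniquenessReport:
    zetas: np.ndarray  # per defined pair
    n_excluded: int  # both-zero pairs
    pair_weights: np.ndarray  # (n_pairs, 2) raw weights, all pairs

    @property
    def n_pairs(self) -> int:
        return self.pair_weights.shape[0]

    @property
    def mean(self) -> float:
        return float(np.mean(self.zetas)) if self.zetas.size else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.zetas)) if self.zetas.size else float("nan")


def duplicate_experiment(
    c: Connectome,
    vol: DiffusionVolume,
    cfg: SolverConfig | None = None,
    perturb: str = "jitter",
    seed: int = 0,
    dictionary: OrientationDictionary | None = None,
    node_fraction: float = 0.10,
    amplitude: float = 1.0e-4,
    end_fraction: float = 0.05,
) -> UniquenessReport:
    """Duplicate a connectome (optionally perturbed), fit, and score uniqueness.

    Two near-identical copies C1 and C2 are built by the chosen perturbation
    ("jitter": displace 10% of nodes by up to +/-0.01%; "trim": drop 5% of the
    nodes from each terminus of the second copy; "none": exact duplicates),
    concatenated, encoded against ``vol`` and solved with ``cfg``. Fiber i is
    paired with fiber i + N_f; both-zero pairs are excluded from the index.
    """
    if len(c) == 0:
        raise ValueError("connectome must be non-empty")
    if perturb not in ("jitter", "trim", "none"):
        raise ValueError("perturb must be one of jitter | trim | none")
    if perturb == "jitter":
        c1 = jitter_connectome(c, node_fraction, amplitude, seed=seed)
        c2 = jitter_connectome(c, node_fraction, amplitude, seed=seed + 1)
    elif perturb == "trim":
        c1 = c.copy()
        c2 = trim_connectome(c, end_fraction)
    else:
        c1, c2 = c.copy(), c.copy()

    combined = Connectome(c1.streamlines + c2.streamlines)
    if dictionary is None:
        if vol.scheme is None:
            raise ValueError("volume carries no gradient scheme; pass a dictionary")
        dictionary = build_dictionary(vol.scheme)
    model = build_sparse_model(combined, vol, dictionary)
    w, _ = solve(model, cfg)

    n = len(c)
    pairs = np.column_stack([w[:n], w[n:]])
    defined = pairs.sum(axis=1) > 0
    zetas = np.abs(pairs[defined, 0] - pairs[defined, 1]) / pairs[defined].sum(axis=1)
    return UniquenessReport(zetas, int(np.sum(~defined)), pairs)


@dataclass
class RmseMap:
    """Per-voxel r.m.s.e. over gradient directions, on the masked voxels."""

    values: np.ndarray  # (n_voxels,), >= 0
    voxel_ids: np.ndarray  # grid linear indices (i + X*(j + Y*k))
    grid_shape: tuple

    def median(self) -> float:
        return float(np.median(self.values))


def _demeaned_4d(x) -> np.ndarray:
    sig = x.signal if isinstance(x, DiffusionVolume) else np.asarray(x, dtype=float)
    if sig.ndim != 4:
        raise ValueError("expected a 4D signal (X, Y, Z, n_dirs)")
    return sig - sig.mean(axis=3, keepdims=True)


def voxel_rmse(pred, ref, mask: np.ndarray) -> RmseMap:
    """Voxel-wise r.m.s.e. between two demeaned diffusion signals."""
    p, r = _demeaned_4d(pred), _demeaned_4d(ref)
    if p.shape != r.shape:
        raise ValueError("signals must share a grid and direction count")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != p.shape[:3]:
        raise ValueError("mask grid must match the signals")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.sqrt(np.mean((p[mask] - r[mask]) ** 2, axis=1))
    dims = mask.shape
    ii, jj, kk = np.nonzero(mask)
    ids = ii + dims[0] * (jj + dims[1] * kk)
    order = np.argsort(ids)
    return RmseMap(vals[order], ids[order], dims)


def _scatter_prediction(model: SparseModel, w: np.ndarray) -> tuple:
    """Predicted demeaned signal as a full-grid 4D array + model-voxel mask."""
    pred = model.matvec(w).reshape(model.n_voxels, model.n_dirs)
    dims = model.grid_shape
    full = np.zeros(dims + (model.n_dirs,))
    ii, jj, kk = np.unravel_index(model.voxels, dims, order="F")
    full[ii, jj, kk, :] = pred
    mask = np.zeros(dims, dtype=bool)
    mask[ii, jj, kk] = True
    return full, mask


@dataclass
class OverfitResult:
    rmse_a: RmseMap
    rmse_b: RmseMap
    diff: np.ndarray  # rmse_b.values - rmse_a.values, per voxel


def overfit_protocol(
    c: Connectome,
    d1: DiffusionVolume,
    d2: DiffusionVolume,
    cfg_a: SolverConfig,
    cfg_b: SolverConfig,
    dictionary: OrientationDictionary | None = None,
) -> OverfitResult:
    """Fit on d1 under two solver configs, cross-validate both against d2.

    Returns the per-voxel r.m.s.e. of each config's prediction against the
    independent acquisition d2, and their per-voxel difference (B - A); a
    negative median difference means config B generalizes better.
    """
    if d1.grid_shape != d2.grid_shape:
        raise ValueError("d1 and d2 must share a grid")
    if dictionary is None:
        if d1.scheme is None:
            raise ValueError("d1 carries no gradient scheme; pass a dictionary")
        dictionary = build_dictionary(d1.scheme)
    model = build_sparse_model(c, d1, dictionary)
    maps = []
    for cfg in (cfg_a, cfg_b):
        w, _ = solve(model, cfg)
        pred, mask = _scatter_prediction(model, w)
        maps.append(voxel_rmse(pred, d2, mask))
    return OverfitResult(maps[0], maps[1], maps[1].values - maps[0].values)


def select_top_weights(w: np.ndarray) -> np.ndarray:
    """Mask of fibers in the top 50th percentile of the *nonzero* weights.

    The threshold is the median of the nonzero weights; fibers at or above it
    are kept (ceil(n_nonzero / 2) fibers when weights are distinct).
    """
    w = np.asarray(w, dtype=float)
    nz = w[w > 0]
    if nz.size == 0:
        return np.zeros_like(w, dtype=bool)
    return w >= np.median(nz)


def consistency_protocol(
    d1: DiffusionVolume,
    d2: DiffusionVolume,
    c1: Connectome,
    c2: Connectome,
    cfg: SolverConfig | None = None,
    dictionary: OrientationDictionary | None = None,
) -> RmseMap:
    """Cross-fit two connectomes on swapped acquisitions and compare them.

    C1 is fit against d2 and C2 against d1; each solution keeps only its
    top-half (by nonzero weight) fibers, predicts a signal, and the two
    predictions are compared voxel-wise over the union of their model voxels.
    """
    if d1.grid_shape != d2.grid_shape:
        raise ValueError("d1 and d2 must share a grid")
    if dictionary is None:
        if d1.scheme is None:
            raise ValueError("d1 carries no gradient scheme; pass a dictionary")
        dictionary = build_dictionary(d1.scheme)
    preds, masks = [], []
    for c, d in ((c1, d2), (c2, d1)):
        model = build_sparse_model(c, d, dictionary)
        w, _ = solve(model, cfg)
        w_sel = np.where(select_top_weights(w), w, 0.0)
        pred, mask = _scatter_prediction(model, w_sel)
        preds.append(pred)
        masks.append(mask)
    return voxel_rmse(preds[0], preds[1], masks[0] | masks[1])
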