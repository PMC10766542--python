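"""Readers and writers for the standard neuroimaging formats used here.

NIfTI-1 volumes and FSL-dialect bvals/bvecs (two whitespace-delimited text
files, bvecs as 3 x N) via nibabel; TCK/TRK streamline files via
nibabel.streamlines; fiber weights as CSV; sparse models as HDF5.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .core import Connectome, DiffusionVolume, GradientScheme
from .encode import SparseModel

__all__ = [
    "save_volume",
    "load_volume",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_streamlines",
    "load_streamlines",
    "save_weights",
    "load_weights",
    "save_model",
    "load_model",
]

_B0_THRESHOLD = 50.0  # s/mm^2: volumes at or below this count as baseline


def save_volume(vol: DiffusionVolume, prefix: str | Path) -> dict:
    """Write dwi.nii.gz (b0 volumes first), mask.nii.gz, bvals and bvecs.

    Returns the paths written. The baseline image is replicated ``n_b0``
    times (at least once) ahead of the diffusion-weighted volumes, matching
    the acquisition layout the gradient files describe.
    """
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    scheme = vol.scheme
    if scheme is None:
        raise ValueError("volume carries no gradient scheme")
    n_b0 = max(1, scheme.n_b0)
    b0 = np.repeat(vol.s0[..., None], n_b0, axis=3)
    data = np.concatenate([b0, vol.signal], axis=3)
    paths = {
        "dwi": prefix / "dwi.nii.gz",
        "mask": prefix / "mask.nii.gz",
        "bvals": prefix / "bvals",
        "bvecs": prefix / "bvecs",
    }
    nib.save(nib.Nifti1Image(data.astype(np.float32), vol.affine), paths["dwi"])
    nib.save(
        nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), paths["mask"]
    )
    save_bvals_bvecs(scheme, paths["bvals"], paths["bvecs"])
    return paths


def load_volume(prefix: str | Path) -> DiffusionVolume:
    """Read a volume written by :func:`save_volume`."""
    prefix = Path(prefix)
    img = nib.load(prefix / "dwi.nii.gz")
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = np.asarray(nib.load(prefix / "mask.nii.gz").get_fdata()) > 0
    scheme, b0_idx, dw_idx = load_bvals_bvecs(prefix / "bvals", prefix / "bvecs")
    s0 = data[..., b0_idx].mean(axis=3)
    return DiffusionVolume(
        data[..., dw_idx], s0, mask, np.asarray(img.affine, dtype=float), scheme=scheme
    )


def save_bvals_bvecs(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    n_b0 = max(1, scheme.n_b0)
    bvals = np.concatenate([np.zeros(n_b0), scheme.bvalues])
    bvecs = np.vstack([np.zeros((n_b0, 3)), scheme.directions]).T  # 3 x N
    np.savetxt(bvals_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, bvecs, fmt="%.9g")


def load_bvals_bvecs(bvals_path, bvecs_path) -> tuple:
    """Returns (scheme, b0 column indices, diffusion-weighted column indices)."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvecs must be 3 x N matching bvals")
    b0 = bvals <= _B0_THRESHOLD
    dirs = bvecs[~b0]
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    scheme = GradientScheme(dirs, bvals[~b0], n_b0=int(b0.sum()))
    return scheme, np.flatnonzero(b0), np.flatnonzero(~b0)


def save_streamlines(
    c: Connectome, path: str | Path, reference: DiffusionVolume | None = None
) -> None:
    """Write a connectome as TCK or TRK (by extension), coordinates in mm.

    TRK needs a reference volume for its voxel-grid header fields.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in c.streamlines], affine_to_rasmm=np.eye(4)
    )
    if path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    elif path.suffix == ".trk":
        if reference is None:
            raise ValueError("TRK output needs a reference volume for its header")
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: reference.affine.astype(
                np.float32
            ),
            nib.streamlines.trk.Field.VOXEL_SIZES: np.abs(
                np.diag(reference.affine)[:3]
            ).astype(np.float32),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(
                reference.grid_shape, dtype=np.int16
            ),
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        raise ValueError(f"unsupported streamline format: {path.suffix}")


def load_streamlines(path: str | Path) -> Connectome:
    """Read TCK/TRK streamlines back into world (mm) coordinates."""
    tractogram = nib.streamlines.load(str(path))
    return Connectome([np.asarray(s, dtype=float) for s in tractogram.streamlines])


def save_weights(w: np.ndarray, path: str | Path) -> None:
    w = np.asarray(w, dtype=float)
    out = np.column_stack([np.arange(w.size), w])
    np.savetxt(path, out, fmt=["%d", "%.17g"], delimiter=",", header="fiber,weight")


def load_weights(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)[..., 1].ravel()


def save_model(model: SparseModel, path: str | Path) -> None:
    """Serialize a sparse model (COO entries, dictionary, S0, b) to HDF5."""
    with h5py.File(path, "w") as f:
        for name in ("voxel_index", "atom_index", "fiber_index", "coeff", "s0", "b", "voxels"):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("D", data=model.D)
        if model.atoms is not None:
            f.create_dataset("atoms", data=model.atoms)
        f.attrs["n_fibers"] = model.n_fibers
        f.attrs["grid_shape"] = model.grid_shape
        f.attrs["n_skipped_segments"] = model.n_skipped_segments


def load_model(path: str | Path) -> SparseModel:
    with h5py.File(path, "r") as f:
        kwargs = {
            name: f[name][()]
            for name in (
                "voxel_index",
                "atom_index",
                "fiber_index",
                "coeff",
                "s0",
                "b",
                "voxels",
            )
        }
        return SparseModel(
            D=f["D"][()],
            atoms=f["atoms"][()] if "atoms" in f else None,
            n_fibers=int(f.attrs["n_fibers"]),
            grid_shape=tuple(int(d) for d in f.attrs["grid_shape"]),
            n_skipped_segments=int(f.attrs["n_skipped_segments"]),
            **kwargs,
        )
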