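"""Synthetic diffusion phantoms with known ground-truth fiber weights.

The generator lays smooth fiber bundles (plus spurious decoy streamlines) on a
small voxel grid and synthesizes the diffusion-weighted signal *through the
same stick-kernel forward model* the encoder uses, so that the demeaned signal
of a noise-free phantom equals ``M @ w_true`` exactly. Streamline geometry is a
deterministic function of the phantom description alone; the ``seed`` drives
only the measurement noise, so two phantoms that differ only in seed share the
same connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Connectome, DiffusionVolume, GradientScheme

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "make_gradient_scheme",
    "make_phantom",
    "jitter_connectome",
    "trim_connectome",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# fixed generator seed for streamline geometry; measurement noise uses
# PhantomSpec.seed so geometry is invariant across noise realizations
_GEOMETRY_SEED = 197312


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (deterministic)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_gradient_scheme(
    n_dirs: int, bval: float = 1000.0, seed: int = 0, n_b0: int = 1
) -> GradientScheme:
    """Approximately uniform gradient directions at a single b-value.

    A Fibonacci-spiral point set is rotated by a seeded random rotation, so
    schemes are well-spread, deterministic given the seed, and distinct across
    seeds.
    """
    if n_dirs < 6:
        raise ValueError("a gradient scheme needs at least 6 directions")
    rot = Rotation.random(random_state=np.random.default_rng(seed))
    dirs = fibonacci_sphere(n_dirs) @ rot.as_matrix().T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return GradientScheme(dirs, np.full(n_dirs, float(bval)), n_b0=n_b0)


@dataclass
class BundleSpec:
    """One coherent fiber bundle: a bowed centerline with a disk of offsets."""

    start: tuple  # mm
    end: tuple  # mm
    n_streamlines: int = 10
    curvature: float = 0.0  # lateral bow of the centerline midpoint, mm
    radius: float = 1.0  # bundle cross-section radius, mm
    n_nodes: int = 20


@dataclass
class PhantomSpec:
    grid_shape: tuple = (10, 10, 10)
    voxel_size: float = 2.0  # mm, isotropic
    bundles: list = field(default_factory=list)
    n_spurious: int = 0
    true_weights: np.ndarray | None = None  # per true streamline; None -> auto
    noise_sigma: float = 0.0  # noise s.d. as a fraction of S0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0
    n_dirs: int = 32
    bval: float = 1000.0
    s0_value: float = 100.0
    n_atoms: int = 96
    diffusivities: tuple = (1.0e-3, 0.0)  # (axial, radial) mm^2/s

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        if len(self.grid_shape) != 3 or any(d < 1 for d in self.grid_shape):
            raise ValueError("grid shape must be three dimensions, each >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.true_weights is not None:
            self.true_weights = np.asarray(self.true_weights, dtype=float)
            if np.any(self.true_weights < 0):
                raise ValueError("true_weights must be non-negative")


def _perpendicular_frame(direction: np.ndarray) -> tuple:
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _bundle_streamlines(bundle: BundleSpec) -> list:
    p0 = np.asarray(bundle.start, dtype=float)
    p2 = np.asarray(bundle.end, dtype=float)
    u, v = _perpendicular_frame(p2 - p0)
    mid = 0.5 * (p0 + p2) + bundle.curvature * u
    out = []
    n = bundle.n_streamlines
    for k in range(n):
        # sunflower pattern across the bundle cross-section
        rho = bundle.radius * np.sqrt((k + 0.5) / n)
        ang = k * _GOLDEN_ANGLE
        offset = rho * (np.cos(ang) * u + np.sin(ang) * v)
        out.append(_bezier(p0 + offset, mid + offset, p2 + offset, bundle.n_nodes))
    return out


def _spurious_streamlines(spec: PhantomSpec, rng: np.random.Generator) -> list:
    hi = (np.asarray(spec.grid_shape) - 1) * spec.voxel_size
    margin = 0.05 * hi
    lo, hi = margin, hi - margin
    out = []
    for _ in range(spec.n_spurious):
        while True:
            p0 = rng.uniform(lo, hi)
            p2 = rng.uniform(lo, hi)
            if np.linalg.norm(p2 - p0) > 2.0 * spec.voxel_size:
                break
        p1 = np.clip(0.5 * (p0 + p2) + rng.normal(0, 0.15 * hi.max(), 3), lo, hi)
        out.append(_bezier(p0, p1, p2, 16))
    return out


def _check_in_grid(points: np.ndarray, spec: PhantomSpec, name: str) -> None:
    # nodes must round into a valid voxel (centers at i * voxel_size)
    ijk = np.round(points / spec.voxel_size)
    dims = np.asarray(spec.grid_shape)
    if np.any(ijk < 0) or np.any(ijk >= dims):
        raise ValueError(f"{name} leaves the voxel grid")


def make_phantom(spec: PhantomSpec):
    """Build (volume, connectome, true weights) from a phantom description.

    The candidate connectome lists all bundle streamlines first (in bundle
    order) followed by the spurious streamlines; the returned weight vector is
    zero on every spurious entry. The volume's demeaned signal equals
    ``M @ w_true`` plus zero-mean noise of scale ``noise_sigma * S0``.
    """
    from . import encode  # deferred: encode imports core, not phantom

    geom_rng = np.random.default_rng(_GEOMETRY_SEED)
    streamlines: list = []
    for bi, bundle in enumerate(spec.bundles):
        lines = _bundle_streamlines(bundle)
        for s in lines:
            _check_in_grid(s, spec, f"bundle {bi}")
        streamlines.extend(lines)
    n_true = len(streamlines)
    if n_true == 0:
        raise ValueError("phantom needs at least one bundle streamline")
    streamlines.extend(_spurious_streamlines(spec, geom_rng))
    connectome = Connectome(streamlines)

    scheme = make_gradient_scheme(spec.n_dirs, spec.bval, seed=0)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    s0 = np.full(spec.grid_shape, float(spec.s0_value))
    mask = np.ones(spec.grid_shape, dtype=bool)
    placeholder = np.zeros(spec.grid_shape + (scheme.n_dirs,))
    vol = DiffusionVolume(placeholder, s0, mask, affine, scheme=scheme)

    dictionary = encode.build_dictionary(scheme, spec.n_atoms, spec.diffusivities)
    model = encode.build_sparse_model(connectome, vol, dictionary)

    if spec.true_weights is not None:
        if spec.true_weights.shape != (n_true,):
            raise ValueError("true_weights must have one entry per true streamline")
        w_true = spec.true_weights.copy()
    else:
        w_true = np.linspace(0.6, 1.4, n_true) if n_true > 1 else np.array([1.0])
    w_full = np.concatenate([w_true, np.zeros(len(connectome) - n_true)])

    pred = model.matvec(w_full)  # demeaned predicted signal, model voxels
    baseline = 0.5 * float(spec.s0_value)
    if spec.true_weights is None:
        # scale auto weights so the modeled deviation stays well inside the
        # positive-signal envelope around the baseline attenuation level
        peak = np.abs(pred).max()
        if peak > 0:
            scale = min(1.0, 0.4 * baseline / peak)
            w_true *= scale
            w_full *= scale
            pred *= scale
    elif np.abs(pred).max() >= baseline:
        raise ValueError(
            "true_weights produce a modeled signal exceeding the baseline; "
            "use smaller weights"
        )

    signal = np.full(spec.grid_shape + (scheme.n_dirs,), baseline)
    ii, jj, kk = np.unravel_index(model.voxels, spec.grid_shape, order="F")
    signal[ii, jj, kk, :] += pred.reshape(model.n_voxels, scheme.n_dirs)

    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * float(spec.s0_value)
        if spec.noise_model == "gaussian":
            signal = signal + noise_rng.normal(0.0, sigma, signal.shape)
        else:
            n1 = noise_rng.normal(0.0, sigma, signal.shape)
            n2 = noise_rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        signal = np.maximum(signal, 0.0)

    vol = DiffusionVolume(signal, s0, mask, affine, scheme=scheme)
    return vol, connectome, w_full


def two_bundle_spec(
    n_spurious: int = 5,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_streamlines: int = 10,
) -> PhantomSpec:
    """The package's standard small test-bed phantom.

    Two curved, interdigitating bundles of ``n_streamlines`` fibers each on a
    10x10x10 grid of 2 mm voxels, spread over a 4 mm cross-section so that
    individual fibers occupy distinguishable voxel sets (the encoded forward
    operator is well-conditioned and the true weights are identifiable).
    """
    return PhantomSpec(
        grid_shape=(10, 10, 10),
        voxel_size=2.0,
        bundles=[
            BundleSpec(
                start=(5.0, 5.0, 12.6),
                end=(13.0, 13.0, 12.6),
                n_streamlines=n_streamlines,
                curvature=2.0,
                radius=4.0,
            ),
            BundleSpec(
                start=(9.0, 5.0, 6.3),
                end=(9.0, 13.0, 6.3),
                n_streamlines=n_streamlines,
                curvature=-2.0,
                radius=4.0,
            ),
        ],
        n_spurious=n_spurious,
        noise_sigma=noise_sigma,
        # unit baseline: signal in arbitrary units so that L1 penalties in
        # the conventional [1e-8, 1] range are commensurate with the data term
        s0_value=1.0,
        seed=seed,
    )


def jitter_connectome(
    c: Connectome, node_fraction: float = 0.10, amplitude: float = 1.0e-4, seed: int = 0
) -> Connectome:
    """Multiplicatively perturb a fraction of each streamline's nodes.

    Exactly ``round(node_fraction * n_nodes)`` nodes per streamline have each
    coordinate x replaced by ``x * (1 + u)`` with u uniform in
    [-amplitude, +amplitude]. The defaults displace 10% of the nodes by up to
    +/-0.01% of their coordinate values.
    """
    if not 0.0 <= node_fraction <= 1.0:
        raise ValueError("node_fraction must be in [0, 1]")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for s in c.streamlines:
        s = s.copy()
        n = s.shape[0]
        k = int(np.floor(node_fraction * n + 0.5))  # round half up
        if k > 0:
            idx = rng.choice(n, size=min(k, n), replace=False)
            u = rng.uniform(-amplitude, amplitude, size=(len(idx), 3))
            s[idx] = s[idx] * (1.0 + u)
        out.append(s)
    labels = None if c.labels is None else c.labels.copy()
    return Connectome(out, labels)


def trim_connectome(c: Connectome, end_fraction: float = 0.05) -> Connectome:
    """Drop ``floor(end_fraction * n)`` nodes from each terminus of each fiber.

    Streamlines that would fall below 2 nodes are returned unchanged.
    """
    if not 0.0 <= end_fraction < 0.5:
        raise ValueError("end_fraction must be in [0, 0.5)")
    out = []
    for s in c.streamlines:
        n = s.shape[0]
        k = int(np.floor(end_fraction * n))
        if k > 0 and n - 2 * k >= 2:
            out.append(s[k : n - k].copy())
        else:
            out.append(s.copy())
    labels = None if c.labels is None else c.labels.copy()
    return Connectome(out, labels)
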