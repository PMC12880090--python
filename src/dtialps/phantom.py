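"""Synthetic DWI phantoms with known ground-truth diffusion tensors.

The default phantom mimics the periventricular geometry used for the ALPS
(along-the-perivascular-space) index at the lateral-ventricle-body level:
two mirror-image hemisphere blocks, each holding a projection-fiber slab
(diffusion dominant along z, the inferior-superior image axis) adjacent to
an association-fiber slab (dominant along y, anterior-posterior), separated
by a central "ventricle" gap. Perivascular water in this geometry moves
along x (left-right), so elevated Dxx against depressed Dyy/Dzz raises the
ALPS ratio.

Tensors are stored as the 6 unique elements (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
in mm^2/s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable

__all__ = [
    "Region",
    "PhantomSpec",
    "simulate_dwi",
    "alps_phantom_spec",
    "analytic_alps",
    "tensor6_to_matrix",
    "matrix_to_tensor6",
]

_TENSOR6_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric matrices."""
    t6 = np.asarray(t6, dtype=float)
    out = np.empty(t6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_TENSOR6_IDX):
        out[..., i, j] = t6[..., k]
        out[..., j, i] = t6[..., k]
    return out


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for (i, j) in _TENSOR6_IDX], axis=-1)


@dataclass(frozen=True)
class Region:
    """Axis-aligned box of voxels sharing one ground-truth tensor.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) in 0-based voxel coordinates,
    half-open on the upper end.
    """

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    tensor: np.ndarray  # 6 unique elements, mm^2/s

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: tuple[Region, ...] = ()
    s0: float = 1000.0
    noise_model: str = "none"  # none | gaussian | rician
    snr: float = 30.0
    seed: int = 0
    background_diffusivity: float = 0.8e-3  # isotropic, mm^2/s

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape extents must all be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise ValueError("snr must be > 0 when noise is enabled")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for r in self.regions:
            ev = np.linalg.eigvalsh(tensor6_to_matrix(r.tensor))
            if np.any(ev <= 0):
                raise ValueError(
                    f"region {r.name!r} tensor is not positive definite "
                    f"(eigenvalues {ev})"
                )
            for (lo, hi), n in zip(r.box, self.grid_shape):
                if not (0 <= lo < hi <= n):
                    raise ValueError(f"region {r.name!r} box {r.box} outside grid")
            sl = r.slices()
            if occupied[sl].any():
                raise ValueError(f"region {r.name!r} overlaps another region")
            occupied[sl] = True


def ground_truth_field(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel ground-truth tensor, shape grid + (6,)."""
    d = spec.background_diffusivity
    field6 = np.zeros(spec.grid_shape + (6,))
    field6[..., [0, 3, 5]] = d
    for r in spec.regions:
        field6[r.slices()] = np.asarray(r.tensor, dtype=float)
    return field6


def simulate_dwi(spec: PhantomSpec, gtab: GradientTable):
    """Forward-simulate a 4D DWI volume from the phantom's tensor field.

    Noiseless signal for entry i in a voxel with tensor D:
    ``S_i = s0 * exp(-b_i * g_i^T D g_i)``.  Gaussian noise adds N(0, sigma)
    to the signal; Rician noise takes the magnitude of the complex signal
    perturbed by independent N(0, sigma) on both channels, with
    ``sigma = s0 / snr``.

    Returns ``(dwi, truth6)`` where ``dwi`` is a :class:`~dtialps.tensor.DwiVolume`
    and ``truth6`` the per-voxel ground-truth tensor elements.
    """
    from .tensor import DwiVolume  # local import to avoid a cycle

    truth6 = ground_truth_field(spec)
    b = gtab.bvals
    g = gtab.bvecs
    # quadratic form g^T D g per voxel/entry via the 6-element expansion
    gx, gy, gz = g.T
    q = np.stack([gx * gx, 2 * gx * gy, 2 * gx * gz, gy * gy, 2 * gy * gz, gz * gz])
    qf = np.tensordot(truth6, q, axes=([3], [0]))  # grid + (n_entries,)
    signal = spec.s0 * np.exp(-b * qf)

    if spec.noise_model != "none":
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
            signal = np.maximum(signal, 0.0)
        else:  # rician: magnitude of complex Gaussian perturbation
            re = signal + rng.normal(0.0, sigma, signal.shape)
            im = rng.normal(0.0, sigma, signal.shape)
            signal = np.hypot(re, im)

    dwi = DwiVolume(signal, spec.voxel_size, gtab)
    return dwi, truth6


def _alps_region_tensors(target_alps: float) -> tuple[np.ndarray, np.ndarray]:
    """Projection/association slab tensors whose analytic ALPS is ``target_alps``.

    The denominator diffusivities are fixed (Dyy_proj = 0.4e-3,
    Dzz_assoc = 0.6e-3, mean 0.5e-3) and the x-axis diffusivity of both
    slabs is set to ``target_alps * 0.5e-3``, so
    mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc) = target_alps.
    """
    if target_alps <= 0:
        raise ValueError("target_alps must be positive")
    dxx = target_alps * 0.5e-3
    proj = np.array([dxx, 0, 0, 0.4e-3, 0, 1.6e-3])  # z-dominant
    assoc = np.array([dxx, 0, 0, 1.5e-3, 0, 0.6e-3])  # y-dominant
    return proj, assoc


def alps_phantom_spec(
    target_alps: float = 1.35,
    noise_model: str = "none",
    snr: float = 30.0,
    seed: int = 0,
    isotropic: bool = False,
) -> PhantomSpec:
    """Default bilateral ALPS phantom on a 40 x 40 x 20 grid (2 mm voxels).

    Left hemisphere occupies x < 18, right x >= 22, with a 4-voxel central
    ventricle gap.  Each hemisphere holds an association slab (outer) and a
    projection slab (inner, against the ventricle), mirror images of each
    other.  ``isotropic=True`` replaces every slab tensor with the isotropic
    background diffusivity (analytic ALPS exactly 1).
    """
    proj, assoc = _alps_region_tensors(target_alps)
    if isotropic:
        d = 0.8e-3
        proj = assoc = np.array([d, 0, 0, d, 0, d])
    yb, zb = (14, 26), (6, 14)
    regions = (
        Region("assoc_left", ((6, 12), yb, zb), assoc),
        Region("proj_left", ((12, 18), yb, zb), proj),
        Region("proj_right", ((22, 28), yb, zb), proj),
        Region("assoc_right", ((28, 34), yb, zb), assoc),
    )
    return PhantomSpec(
        regions=regions, noise_model=noise_model, snr=snr, seed=seed
    )


def analytic_alps(spec: PhantomSpec, hemisphere: str = "left") -> float:
    """Ground-truth ALPS index of one hemisphere from the region tensors."""
    by_name = {r.name: np.asarray(r.tensor) for r in spec.regions}
    proj = by_name[f"proj_{hemisphere}"]
    assoc = by_name[f"assoc_{hemisphere}"]
    num = 0.5 * (proj[0] + assoc[0])  # mean(Dxx_proj, Dxx_assoc)
    den = 0.5 * (proj[3] + assoc[5])  # mean(Dyy_proj, Dzz_assoc)
    return float(num / den)
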