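"""Per-voxel diffusion tensor estimation and scalar map derivation.

The signal model is the single-tensor log-linear one:

    ln S_i = ln S0 - b_i * g_i^T D g_i

fit per voxel by least squares over the 7-parameter design (ln S0 plus the
6 unique tensor elements).  ``wls`` re-weights the log-domain residuals by
the squared predicted signal in one refinement pass after an OLS start,
which counteracts the heteroscedasticity introduced by the log transform;
``ols`` stops after the unweighted pass.

Voxels with non-positive measurements on diffusion-weighted entries have
those entries dropped; if fewer than 7 usable entries (or no b=0 entry)
remain the voxel is marked invalid rather than crashing the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import GradientTable, design_matrix

__all__ = [
    "DwiVolume",
    "DiffusionTensorField",
    "ScalarMaps",
    "fit_tensor",
    "compute_scalar_maps",
]


@dataclass(frozen=True)
class DwiVolume:
    """4D diffusion-weighted image: (x, y, z, entry), arbitrary signal units."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    gradient_table: GradientTable

    def __post_init__(self) -> None:
        data = np.asarray(self.intensities, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"intensities must be 4D, got {data.ndim}D")
        if data.shape[3] != len(self.gradient_table):
            raise ValueError(
                f"4th axis ({data.shape[3]}) != gradient table length "
                f"({len(self.gradient_table)})"
            )
        if np.any(data < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive extents (mm)")
        object.__setattr__(self, "intensities", data)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


@dataclass(frozen=True)
class DiffusionTensorField:
    """Fitted tensors: (x, y, z, 6) unique elements (Dxx, Dxy, Dxz, Dyy,
    Dyz, Dzz) in mm^2/s, per-voxel log baseline signal, and a validity mask.
    """

    tensor6: np.ndarray
    log_s0: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensor6.shape[:3]


@dataclass(frozen=True)
class ScalarMaps:
    """Tensor-derived maps: FA, MD, directionally encoded color FA and the
    image-axis diffusivities (tensor diagonal, not eigenvalues)."""

    fa: np.ndarray
    md: np.ndarray
    color_fa: np.ndarray  # (..., 3), RGB = FA * |e1|
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float]


def fit_tensor(dwi: DwiVolume, method: str = "wls") -> DiffusionTensorField:
    if method not in ("ols", "wls"):
        raise ValueError(f"method must be 'ols' or 'wls', got {method!r}")
    gtab = dwi.gradient_table
    A = design_matrix(gtab)  # (m, 7)
    m = A.shape[0]
    data = dwi.intensities.reshape(-1, m)  # (n_vox, m)
    n_vox = data.shape[0]

    usable = data > 0
    # require a usable b=0 entry so ln S0 is anchored
    has_b0 = np.any(usable & gtab.b0_mask[None, :], axis=1)
    enough = (usable.sum(axis=1) >= 7) & has_b0

    logy = np.zeros_like(data)
    np.log(data, out=logy, where=usable)
    w0 = usable.astype(float)

    params = _solve_weighted(A, logy, w0, enough)
    if method == "wls":
        pred = np.exp(params @ A.T)  # predicted signal per entry
        w1 = w0 * pred**2
        params = _solve_weighted(A, logy, w1, enough)

    tensor6 = params[:, 1:].reshape(dwi.grid_shape + (6,))
    log_s0 = params[:, 0].reshape(dwi.grid_shape)
    valid = enough.reshape(dwi.grid_shape)
    tensor6[~valid] = 0.0
    log_s0[~valid] = 0.0
    return DiffusionTensorField(tensor6, log_s0, valid, dwi.voxel_size)


def _solve_weighted(
    A: np.ndarray, logy: np.ndarray, w: np.ndarray, enough: np.ndarray
) -> np.ndarray:
    """Batched weighted normal-equation solve; rows with zero weight drop out."""
    n_vox = logy.shape[0]
    params = np.zeros((n_vox, A.shape[1]))
    idx = np.flatnonzero(enough)
    if idx.size == 0:
        return params
    wv = w[idx]
    normal = np.einsum("mi,vm,mj->vij", A, wv, A, optimize=True)
    rhs = np.einsum("mi,vm->vi", A, wv * logy[idx], optimize=True)
    try:
        sol = np.linalg.solve(normal, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        sol = np.stack(
            [np.linalg.lstsq(nm, r, rcond=None)[0] for nm, r in zip(normal, rhs)]
        )
    params[idx] = sol
    return params


def compute_scalar_maps(field: DiffusionTensorField) -> ScalarMaps:
    """Eigen-decompose fitted tensors into FA/MD/color-FA plus the diagonal
    diffusivities.

    Negative eigenvalues are clamped to zero for FA/MD only; the diagonal
    maps (the ALPS inputs) report the fitted tensor elements untouched.
    """
    from .phantom import tensor6_to_matrix

    shape = field.grid_shape
    D = tensor6_to_matrix(field.tensor6.reshape(-1, 6))
    evals, evecs = np.linalg.eigh(D)  # ascending
    lam = np.maximum(evals, 0.0)
    md = lam.mean(axis=1)
    dev = lam - md[:, None]
    num = np.sqrt((dev**2).sum(axis=1))
    den = np.sqrt((lam**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa[den == 0] = 0.0
    fa = np.clip(fa, 0.0, 1.0)
    e1 = evecs[:, :, 2]  # principal eigenvector (largest eigenvalue)
    color = fa[:, None] * np.abs(e1)

    invalid = ~field.valid.ravel()
    for arr in (fa, md):
        arr[invalid] = 0.0
    color[invalid] = 0.0
    return ScalarMaps(
        fa=fa.reshape(shape),
        md=md.reshape(shape),
        color_fa=color.reshape(shape + (3,)),
        dxx=field.tensor6[..., 0].copy(),
        dyy=field.tensor6[..., 3].copy(),
        dzz=field.tensor6[..., 5].copy(),
        valid=field.valid.copy(),
        voxel_size=field.voxel_size,
    )
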