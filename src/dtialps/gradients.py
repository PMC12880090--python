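"""Diffusion gradient tables (b-values + unit encoding directions).

Directions live in the image coordinate frame, matching the FSL bvec
convention: row 0 = x (left-right), row 1 = y (anterior-posterior),
row 2 = z (inferior-superior) components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientTable", "make_gradient_table", "design_matrix"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one row per DWI entry."""

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals length {bvals.shape[0]} != bvecs length {bvecs.shape[0]}"
            )
        nz = bvals > 0
        if not np.any(~nz):
            raise ValueError("gradient table needs at least one b=0 entry")
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("nonzero-b directions must have unit norm (tol 1e-6)")
        # tensor identifiability: >= 6 distinct nonzero-b directions (up to sign)
        dirs = bvecs[nz]
        distinct = _count_distinct_axes(dirs)
        if distinct < 6:
            raise ValueError(
                f"only {distinct} distinct diffusion-encoding axes; "
                "at least 6 required to fit a tensor"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def _count_distinct_axes(dirs: np.ndarray, tol: float = 1e-8) -> int:
    kept: list[np.ndarray] = []
    for d in dirs:
        if not any(
            np.allclose(d, k, atol=tol) or np.allclose(d, -k, atol=tol) for k in kept
        ):
            kept.append(d)
    return len(kept)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the upper (z >= 0) hemisphere."""
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _electrostatic_repulsion(
    points: np.ndarray, n_iter: int = 200, step: float = 1e-3
) -> np.ndarray:
    """Spread encoding axes by Coulomb repulsion on antipodal point pairs.

    Deterministic (no randomness); the antipodal symmetrization treats g and
    -g as the same encoding axis, the usual DTI scheme-design criterion.
    """
    p = points.copy()
    n = len(p)
    for _ in range(n_iter):
        diff_plus = p[:, None, :] - p[None, :, :]
        diff_minus = p[:, None, :] + p[None, :, :]
        d2p = np.sum(diff_plus**2, axis=-1)
        d2m = np.sum(diff_minus**2, axis=-1)
        np.fill_diagonal(d2p, np.inf)
        np.fill_diagonal(d2m, np.inf)
        force = np.sum(
            diff_plus / d2p[..., None] ** 1.5 + diff_minus / d2m[..., None] ** 1.5,
            axis=1,
        )
        # project onto the tangent plane and take a small step
        force -= np.sum(force * p, axis=1, keepdims=True) * p
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        # keep the z >= 0 convention
        flip = p[:, 2] < 0
        p[flip] *= -1.0
    assert n == len(p)
    return p


def make_gradient_table(
    n_directions: int, b_value: float = 1000.0, n_b0: int = 1
) -> GradientTable:
    """Build a deterministic gradient table with ``n_b0`` b=0 entries followed
    by ``n_directions`` near-uniform unit directions at ``b_value``.

    The layout is a golden-angle hemisphere seeding refined by electrostatic
    repulsion over antipodally-symmetrized charges, so the same
    ``n_directions`` always yields the same table.
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions={n_directions} < 6: the 6-parameter diffusion tensor "
            "is not identifiable from fewer than 6 encoding directions"
        )
    if n_b0 < 1:
        raise ValueError("need at least one b=0 entry")
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    dirs = _electrostatic_repulsion(_fibonacci_hemisphere(n_directions))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear tensor design: columns (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).

    Row i encodes ln S_i = ln S0 - b_i * g_i^T D g_i.
    """
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -b * gy * gy,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ]
    )
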