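"""DTI-ALPS index from perivascular-space ROI diffusivities.

At the lateral-ventricle-body level, medullary veins and their perivascular
spaces run left-right (the image x-axis), perpendicular both to the
projection fibers beside the ventricle wall (z-oriented) and to the
association fibers lateral to them (y-oriented).  Water moving along the
perivascular space therefore elevates Dxx in both fiber ROIs relative to
the fiber-transverse diffusivities Dyy (projection) and Dzz (association),
and the index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

is a dimensionless proxy for glymphatic (perivascular) diffusion: ~1 when
no perivascular component is present, larger when x-axis diffusion is
elevated.

ROIs are circular in-plane disks (default diameter 5 mm) placed per
hemisphere on one axial slice.  A voxel belongs to the disk iff its center
lies within the radius of the ROI center — a deterministic rule that makes
masks reproducible and mirror-symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tensor import ScalarMaps

__all__ = [
    "RoiSpec",
    "HemisphereMeans",
    "AlpsResult",
    "HemisphereMap",
    "build_roi_mask",
    "extract_roi_means",
    "compute_alps",
    "map_hemispheres",
    "phantom_roi_specs",
]

logger = logging.getLogger(__name__)

ROLES = ("projection", "association")
SIDES = ("left", "right")


@dataclass(frozen=True)
class RoiSpec:
    role: str  # projection | association
    hemisphere: str  # left | right
    slice_index: int  # axial (z) slice at the lateral-ventricle-body level
    center: tuple[float, float]  # in-plane (x, y) voxel coordinates
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.hemisphere not in SIDES:
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    @property
    def name(self) -> str:
        return f"{self.role}_{self.hemisphere}"


@dataclass(frozen=True)
class HemisphereMeans:
    """ROI-mean diffusivities feeding the ALPS ratio for one hemisphere."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float


@dataclass(frozen=True)
class AlpsResult:
    means: dict[str, HemisphereMeans]  # keyed left/right
    alps: dict[str, float]  # keyed left/right
    total_cerebral: float  # arithmetic mean of the hemisphere indices
    labels: dict[str, str] | None = None  # stimulated/non_stimulated -> side

    @property
    def stimulated(self) -> float:
        if self.labels is None:
            raise ValueError("no stimulated/non-stimulated labelling attached")
        return self.alps[self.labels["stimulated"]]

    @property
    def non_stimulated(self) -> float:
        if self.labels is None:
            raise ValueError("no stimulated/non-stimulated labelling attached")
        return self.alps[self.labels["non_stimulated"]]


@dataclass(frozen=True)
class HemisphereMap:
    """Group + infarct side -> which hemisphere received the stimulation.

    High-frequency (excitatory) rTMS targets M1 of the infarcted hemisphere;
    low-frequency (inhibitory) rTMS targets M1 of the intact hemisphere.
    """

    group: str
    infarct_side: str
    stimulated_side: str
    non_stimulated_side: str


def map_hemispheres(group: str, infarct_side: str) -> HemisphereMap:
    if group not in ("HF", "LF"):
        raise ValueError(f"group must be 'HF' or 'LF', got {group!r}")
    if infarct_side not in SIDES:
        raise ValueError(f"infarct_side must be left/right, got {infarct_side!r}")
    other = "right" if infarct_side == "left" else "left"
    stim = infarct_side if group == "HF" else other
    non_stim = other if group == "HF" else infarct_side
    return HemisphereMap(group, infarct_side, stim, non_stim)


def build_roi_mask(
    roi: RoiSpec,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Boolean voxel mask of the in-plane circular ROI.

    A voxel (i, j) on the ROI slice is included iff its center is within
    ``diameter_mm / 2`` (in mm) of the ROI center.
    """
    nx, ny, nz = grid_shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError(f"ROI {roi.name}: slice {roi.slice_index} outside grid")
    cx, cy = roi.center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"ROI {roi.name}: center {roi.center} outside grid")
    dx, dy = voxel_size[0], voxel_size[1]
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]
    r = roi.diameter_mm / 2.0
    disk = ((ix - cx) * dx) ** 2 + ((iy - cy) * dy) ** 2 <= r**2
    if not disk.any():
        raise ValueError(
            f"ROI {roi.name}: radius {r} mm covers no voxel center "
            f"(voxel size {voxel_size[:2]} mm)"
        )
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :, roi.slice_index] = disk
    return mask


def extract_roi_means(
    maps: ScalarMaps,
    rois: list[RoiSpec],
    exclusion_mask: np.ndarray | None = None,
) -> dict[str, HemisphereMeans]:
    """ROI-mean Dxx/Dyy/Dzz per hemisphere.

    ``exclusion_mask`` (True = excluded, e.g. lesioned voxels) is honored
    per ROI: partial overlap shrinks the mean to the retained voxels with a
    logged warning; full exclusion is an error.
    """
    grid_shape = maps.dxx.shape
    seen: dict[tuple[str, str], dict[str, float]] = {}
    for roi in rois:
        key = (roi.hemisphere, roi.role)
        if key in seen:
            raise ValueError(f"duplicate ROI for {roi.name}")
        mask = build_roi_mask(roi, grid_shape, maps.voxel_size)
        n_total = int(mask.sum())
        mask &= maps.valid
        if exclusion_mask is not None:
            mask &= ~exclusion_mask
        n_kept = int(mask.sum())
        if n_kept == 0:
            raise ValueError(f"ROI {roi.name} fully excluded or invalid")
        if n_kept < n_total:
            logger.warning(
                "ROI %s: %d of %d voxels retained after exclusion",
                roi.name, n_kept, n_total,
            )
        seen[key] = {
            "dxx": float(maps.dxx[mask].mean()),
            "dyy": float(maps.dyy[mask].mean()),
            "dzz": float(maps.dzz[mask].mean()),
        }
    out: dict[str, HemisphereMeans] = {}
    for side in SIDES:
        if (side, "projection") in seen and (side, "association") in seen:
            proj, assoc = seen[(side, "projection")], seen[(side, "association")]
            out[side] = HemisphereMeans(
                dxx_proj=proj["dxx"],
                dxx_assoc=assoc["dxx"],
                dyy_proj=proj["dyy"],
                dzz_assoc=assoc["dzz"],
            )
    if not out:
        raise ValueError("no hemisphere has both a projection and an association ROI")
    return out


def _alps_ratio(m: HemisphereMeans) -> float:
    den = 0.5 * (m.dyy_proj + m.dzz_assoc)
    if den <= 0:
        raise ValueError(
            "non-positive ALPS denominator (degenerate Dyy_proj/Dzz_assoc means)"
        )
    return 0.5 * (m.dxx_proj + m.dxx_assoc) / den


def compute_alps(
    means: dict[str, HemisphereMeans], hemisphere_map: HemisphereMap | None = None
) -> AlpsResult:
    """ALPS index per hemisphere plus the total-cerebral summary.

    "Total cerebral" is the arithmetic mean of the two hemispheric indices
    (the simplest symmetric pooling; an index over pooled ROI means would
    differ slightly).  Stimulated/non-stimulated labels are attached only
    through an explicit :class:`HemisphereMap` — storage stays left/right.
    """
    alps = {side: _alps_ratio(m) for side, m in means.items()}
    if set(alps) != set(SIDES):
        raise ValueError("both hemispheres required for the total-cerebral index")
    total = 0.5 * (alps["left"] + alps["right"])
    labels = None
    if hemisphere_map is not None:
        labels = {
            "stimulated": hemisphere_map.stimulated_side,
            "non_stimulated": hemisphere_map.non_stimulated_side,
        }
    return AlpsResult(means=dict(means), alps=alps, total_cerebral=total, labels=labels)


def phantom_roi_specs(spec, diameter_mm: float = 5.0) -> list[RoiSpec]:
    """Auto-place ROIs at the centers of the phantom's fiber slabs.

    Only meaningful for the synthetic phantom, whose region boxes are known;
    ROI placement on real anatomy is config-driven (explicit RoiSpec list).
    """
    rois = []
    for region in spec.regions:
        role_key, side = region.name.split("_")
        role = "projection" if role_key == "proj" else "association"
        (x0, x1), (y0, y1), (z0, z1) = region.box
        rois.append(
            RoiSpec(
                role=role,
                hemisphere=side,
                slice_index=(z0 + z1) // 2,
                center=((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0),
                diameter_mm=diameter_mm,
            )
        )
    return rois
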