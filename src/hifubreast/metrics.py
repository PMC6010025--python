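"""Focal-quality metrics.

The three quantities this analysis revolves around:

* localized heating ratio  beta = int_{V_r} Q dV / int_{V_R} Q dV,
* focusing ratio           phi  = int_{V_r} p^2/(rho c) dV / int_{V_R} ...,
  normalized as Phi = phi / phi_0 against a free-field (water) reference,
* local acoustic inhomogeneity
  chi = sqrt( (1/V) int_V |grad(rho c)|^2 dV ) / (rho_w c_w / lambda_w),
  evaluated over the beam-path region between the transducer aperture and
  the target.

V_r and V_R are concentric spheres (disks in 2-D) of radius r = 2.5 mm and
R = 10 mm about the target; membership is by voxel center, without
partial-volume weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .segmentation import MediumField
from .volume import Tissue

__all__ = [
    "MetricRegions",
    "FocalMetrics",
    "InhomogeneityResult",
    "sphere_mask",
    "localized_heating_ratio",
    "focusing_ratio",
    "primary_peak",
    "local_acoustic_inhomogeneity",
    "pearson_correlation",
]


@dataclass
class MetricRegions:
    """Concentric evaluation spheres about the target (mm)."""

    target_mm: np.ndarray
    r_mm: float = 2.5
    R_mm: float = 10.0

    def __post_init__(self) -> None:
        self.target_mm = np.asarray(self.target_mm, dtype=float)
        if not 0 < self.r_mm < self.R_mm:
            raise ValueError("require 0 < r < R")


@dataclass
class FocalMetrics:
    beta: float
    phi: float
    phi0: float
    Phi: float
    peak_pressure: float  # normalized to the free-field peak
    peak_location_mm: np.ndarray
    peak_distance_mm: float


@dataclass
class InhomogeneityResult:
    chi: float
    n_voxels: int
    region: str


def _radius_map(shape, voxel_mm, origin_mm, center_mm) -> np.ndarray:
    axes = [
        origin_mm[i] + np.arange(shape[i]) * voxel_mm[i] - center_mm[i]
        for i in range(len(shape))
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g * g for g in grids))


def sphere_mask(shape, voxel_mm, center_mm, radius_mm, origin_mm=None) -> np.ndarray:
    """Voxel-center membership mask of a sphere/disk; works in 2-D and 3-D."""
    voxel_mm = np.broadcast_to(np.atleast_1d(voxel_mm), (len(shape),))
    if origin_mm is None:
        origin_mm = np.zeros(len(shape))
    return _radius_map(shape, voxel_mm, origin_mm, center_mm) <= radius_mm


def _sphere_sum_ratio(fieldv, voxel_mm, regions: MetricRegions, origin_mm, what):
    rr = _radius_map(
        fieldv.shape,
        np.broadcast_to(np.atleast_1d(voxel_mm), (fieldv.ndim,)),
        np.zeros(fieldv.ndim) if origin_mm is None else np.asarray(origin_mm),
        regions.target_mm,
    )
    num = float(fieldv[rr <= regions.r_mm].sum())
    den = float(fieldv[rr <= regions.R_mm].sum())
    if den <= 0:
        raise ValueError(
            f"{what}: field sums to zero over the R = {regions.R_mm} mm sphere "
            "(focus not insonified?)"
        )
    return num / den


def localized_heating_ratio(
    Q: np.ndarray, voxel_mm, regions: MetricRegions, origin_mm=None
) -> float:
    """beta: fraction of the deposited heat falling in the small target sphere."""
    if np.any(np.asarray(Q) < 0):
        raise ValueError("heat deposition must be non-negative")
    return _sphere_sum_ratio(np.asarray(Q), voxel_mm, regions, origin_mm, "heating ratio")


def focusing_ratio(
    msq_pressure: np.ndarray,
    medium: MediumField,
    regions: MetricRegions,
    origin_mm=None,
) -> float:
    """phi: sphere-sum ratio of the acoustic energy-flux density p^2/(rho c)."""
    integrand = np.asarray(msq_pressure) / (medium.rho * medium.c)
    return _sphere_sum_ratio(
        integrand, medium.voxel_mm, regions, origin_mm, "focusing ratio"
    )


def primary_peak(
    msq_pressure: np.ndarray,
    voxel_mm,
    target_mm,
    reference_peak: float = 1.0,
    origin_mm=None,
):
    """Global maximum of the field; ties resolve to the voxel nearest the target.

    Returns (location_mm, value / reference_peak, distance_to_target_mm).
    The value is the peak pressure amplitude sqrt(2 <p^2>).
    """
    f = np.asarray(msq_pressure)
    voxel_mm = np.broadcast_to(np.atleast_1d(voxel_mm), (f.ndim,))
    origin = np.zeros(f.ndim) if origin_mm is None else np.asarray(origin_mm)
    m = f.max()
    ties = np.argwhere(f >= m * (1 - 1e-12))
    pos = origin + ties * voxel_mm
    d = np.linalg.norm(pos - np.asarray(target_mm)[None, :], axis=1)
    kbest = int(np.argmin(d))
    amp = np.sqrt(2.0 * m)
    return pos[kbest], amp / reference_peak, float(d[kbest])


def beam_frustum_mask(
    medium: MediumField,
    target_mm,
    aperture_center_mm,
    aperture_radius_mm: float,
    apex_radius_mm: float = 2.5,
    origin_mm=None,
) -> np.ndarray:
    """Truncated cone (triangle in 2-D) from the active aperture to the target.

    Apex of radius ``apex_radius_mm`` at the target widening linearly to the
    aperture radius at the aperture center plane.
    """
    shape = medium.rho.shape
    ndim = len(shape)
    voxel = np.broadcast_to(np.atleast_1d(medium.voxel_mm), (ndim,))
    origin = np.zeros(ndim) if origin_mm is None else np.asarray(origin_mm)
    target = np.asarray(target_mm, dtype=float)
    apc = np.asarray(aperture_center_mm, dtype=float)
    axis = apc - target
    length = np.linalg.norm(axis)
    u = axis / length

    axes = [origin[i] + np.arange(shape[i]) * voxel[i] - target[i] for i in range(ndim)]
    grids = np.meshgrid(*axes, indexing="ij")
    s = sum(g * u[i] for i, g in enumerate(grids))  # along-axis coordinate
    perp2 = sum(g * g for g in grids) - s * s
    radius = apex_radius_mm + (aperture_radius_mm - apex_radius_mm) * np.clip(
        s / length, 0, 1
    )
    mask = (s >= 0) & (s <= length) & (perp2 <= radius**2)
    return mask


def local_acoustic_inhomogeneity(
    medium: MediumField,
    target_mm,
    aperture_center_mm,
    aperture_radius_mm: float,
    frequency_hz: float = 2e6,
    water_rho: float = 998.2,
    water_c: float = 1482.0,
    apex_radius_mm: float = 2.5,
    tissue_only: bool = False,
    origin_mm=None,
) -> InhomogeneityResult:
    """chi: RMS impedance gradient over the beam path, per water impedance/wavelength.

    grad(rho c) by central differences on the impedance map at the medium's
    own grid resolution (one-sided at domain edges); the RMS is taken over
    the whole beam-path frustum (water included — its interior gradient is
    zero, so the water fraction simply dilutes) and normalized by
    rho_w c_w / lambda_w with lambda_w = c_w / f.

    ``tissue_only=True`` instead averages over non-water voxels only.  That
    variant penalizes arrangements whose path holds little tissue: the
    skin/water interface shell then dominates the small region and chi
    *rises* for the cleanest paths, losing the anticorrelation with the
    focusing ratio that makes chi useful as an arrangement indicator.
    """
    mask = beam_frustum_mask(
        medium, target_mm, aperture_center_mm, aperture_radius_mm,
        apex_radius_mm=apex_radius_mm, origin_mm=origin_mm,
    )
    region = mask
    if tissue_only:
        tissue = (medium.rho != water_rho) | (medium.c != water_c)
        region = mask & tissue
    if not region.any():
        raise ValueError("inhomogeneity region is empty (no tissue on the beam path)")
    Z = medium.impedance
    spacing_m = [v * 1e-3 for v in medium.voxel_mm[: Z.ndim]]
    grads = np.gradient(Z, *spacing_m)
    if Z.ndim == 1:
        grads = [grads]
    g2 = sum(g * g for g in grads)
    lam_w = water_c / frequency_hz
    norm = water_rho * water_c / lam_w
    chi = float(np.sqrt(g2[region].mean()) / norm)
    return InhomogeneityResult(
        chi=chi,
        n_voxels=int(region.sum()),
        region=(
            f"frustum apex {apex_radius_mm} mm at target -> aperture radius "
            f"{aperture_radius_mm} mm"
            + (", tissue voxels only" if tissue_only else "")
        ),
    )


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series has no correlation")
    return float(stats.pearsonr(x, y)[0])
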