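"""Breast-phantom segmentation: brightness volume -> tissue labels -> acoustic maps.

The chain mirrors the image-based modelling procedure the pipeline exists to
study: 3x3x3 median denoise, air/breast split at the histogram valley,
interface detection by line scans at 50% of the mean breast brightness, a
1.5 mm skin shell grown into the air region, and a fat/fibroglandular split at
a prescribed fat fraction (default 66.5%) of the interior brightness
histogram.  Air is treated as water acoustically.

Working-volume conventions: 0 marks air/water, -1 marks skin, positive
brightness marks interior breast tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SKIN_SENTINEL, BrightnessVolume, Tissue, TissueLabelVolume

__all__ = [
    "median_filter_3x3x3",
    "air_breast_threshold",
    "apply_air_mask",
    "detect_interface",
    "add_skin",
    "fat_gland_threshold",
    "segment",
    "segment_pipeline",
    "TissueProperties",
    "MediumField",
    "assign_properties",
]

HISTOGRAM_BINS = 256
HISTOGRAM_SMOOTH = 5  # moving-average window (bins)


def median_filter_3x3x3(volume: BrightnessVolume) -> BrightnessVolume:
    """Denoise with a 3x3x3 median filter (edge replication at boundaries)."""
    out = ndimage.median_filter(volume.values, size=3, mode="nearest")
    return BrightnessVolume(out, volume.voxel_mm.copy(), volume.origin_mm.copy())


def _smoothed_histogram(values: np.ndarray):
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("air/breast threshold: constant volume has no histogram valley")
    counts, edges = np.histogram(values, bins=HISTOGRAM_BINS, range=(lo, hi))
    kernel = np.ones(HISTOGRAM_SMOOTH) / HISTOGRAM_SMOOTH
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return smooth, centers


def _local_maxima(smooth: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus resolve to their lowest bin."""
    n = len(smooth)
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[j + 1] if j + 1 < n else -np.inf
        if smooth[i] > left and smooth[i] > right:
            idx.append(i)
        i = j + 1
    return np.asarray(idx, dtype=int)


def air_breast_threshold(volume: BrightnessVolume) -> float:
    """Brightness separating air from breast.

    The smoothed 256-bin brightness histogram of the whole volume is scanned
    for its first two local maxima; the threshold is the brightness at the
    minimum bin strictly between them (ties toward the lower bin).  Voxels
    below the threshold are air.
    """
    smooth, centers = _smoothed_histogram(volume.values.ravel())
    maxima = _local_maxima(smooth)
    if len(maxima) < 2:
        raise ValueError(
            "air/breast threshold: smoothed brightness histogram is unimodal; "
            "cannot place the air/breast valley"
        )
    a, b = maxima[0], maxima[1]
    valley = a + 1 + int(np.argmin(smooth[a + 1 : b]))
    return float(centers[valley])


def apply_air_mask(volume: BrightnessVolume, threshold: float) -> BrightnessVolume:
    """Zero all voxels strictly below the air/breast threshold."""
    out = volume.values.copy()
    out[out < threshold] = 0.0
    return BrightnessVolume(out, volume.voxel_mm.copy(), volume.origin_mm.copy())


def detect_interface(volume: BrightnessVolume) -> np.ndarray:
    """Boolean mask of the breast/air interface.

    The threshold is 50% of the mean brightness over positive voxels.  Along
    every axis-aligned direction (both ways on each axis) each scan line is
    marched inward from the domain boundary; the first voxel at or above the
    threshold is marked.  Interior cavities not reachable from the boundary
    are therefore not marked.
    """
    vals = volume.values
    pos = vals > 0
    if not pos.any():
        raise ValueError("interface detection: breast region is empty")
    thr = 0.5 * float(vals[pos].mean())
    hit = vals >= thr

    iface = np.zeros(vals.shape, dtype=bool)
    for axis in range(vals.ndim):
        for flip in (False, True):
            h = np.flip(hit, axis=axis) if flip else hit
            # first True along the axis on each line; lines with no hit excluded
            first = np.argmax(h, axis=axis)
            any_hit = h.any(axis=axis)
            mark = np.zeros_like(h)
            grid = np.indices(any_hit.shape)
            sel = tuple(g[any_hit] for g in grid)
            idx = list(sel)
            idx.insert(axis, first[any_hit])
            mark[tuple(idx)] = True
            if flip:
                mark = np.flip(mark, axis=axis)
            iface |= mark
    return iface


def add_skin(
    volume: BrightnessVolume, interface: np.ndarray, thickness_mm: float = 1.5
) -> BrightnessVolume:
    """Grow a skin shell of the given thickness from the interface into air.

    Former-air voxels whose center lies within ``thickness_mm`` (Euclidean,
    via a distance transform from the interface set) are set to the skin
    sentinel -1.  A sub-voxel thickness still marks the air layer adjacent to
    the interface (skin is never empty next to a detected surface).
    """
    if thickness_mm <= 0:
        raise ValueError("skin thickness must be positive")
    if not interface.any():
        raise ValueError("add_skin: interface set is empty")
    ndim = volume.values.ndim
    dist = ndimage.distance_transform_edt(
        ~interface, sampling=volume.voxel_mm[:ndim]
    )
    air = volume.values == 0
    skin = air & (dist <= thickness_mm + 1e-9)
    # round a sub-voxel thickness up to at least one air layer
    adjacent = air & ndimage.binary_dilation(
        interface, structure=ndimage.generate_binary_structure(ndim, 1)
    )
    skin |= adjacent
    out = volume.values.copy()
    out[skin] = SKIN_SENTINEL
    return BrightnessVolume(out, volume.voxel_mm.copy(), volume.origin_mm.copy())


def fat_gland_threshold(volume: BrightnessVolume, fat_fraction: float = 0.665) -> float:
    """Brightness splitting fat (below) from fibroglandular tissue (at/above).

    Chosen among the distinct interior brightness values so that the fraction
    of interior voxels strictly below it is as close as possible to
    ``fat_fraction``.  Interior means positive brightness (air 0 and the skin
    sentinel -1 excluded).  The orientation — fat below, gland above — makes
    the fat fraction increase monotonically with the threshold.
    """
    if not 0.0 < fat_fraction < 1.0:
        raise ValueError("fat_fraction must lie in (0, 1)")
    interior = volume.values[volume.values > 0]
    if interior.size == 0:
        raise ValueError("fat/gland threshold: interior breast region is empty")
    uniq, counts = np.unique(interior, return_counts=True)
    below = np.concatenate([[0], np.cumsum(counts)[:-1]]) / interior.size
    # candidate cuts: each distinct value plus one above the maximum
    cand = np.concatenate([uniq, [uniq[-1] + 1.0]])
    frac = np.concatenate([below, [1.0]])
    k = int(np.argmin(np.abs(frac - fat_fraction)))
    return float(cand[k])


def segment(
    volume: BrightnessVolume, air_thr: float, fat_thr: float
) -> TissueLabelVolume:
    """Label the working volume: 0 -> WATER, -1 -> SKIN, else FAT/GLAND by fat_thr.

    The air region is labelled WATER because the treatment couples the breast
    through a water bath; every voxel receives exactly one label.
    """
    vals = volume.values
    labels = np.full(vals.shape, int(Tissue.GLAND), dtype=np.int16)
    labels[(vals > 0) & (vals < fat_thr)] = int(Tissue.FAT)
    labels[vals == SKIN_SENTINEL] = int(Tissue.SKIN)
    labels[vals == 0] = int(Tissue.WATER)
    return TissueLabelVolume(labels, volume.voxel_mm.copy(), volume.origin_mm.copy())


def segment_pipeline(
    volume: BrightnessVolume,
    fat_fraction: float = 0.665,
    skin_thickness_mm: float = 1.5,
) -> TissueLabelVolume:
    """Full segmentation chain on a raw brightness volume."""
    den = median_filter_3x3x3(volume)
    air_thr = air_breast_threshold(den)
    masked = apply_air_mask(den, air_thr)
    iface = detect_interface(masked)
    with_skin = add_skin(masked, iface, skin_thickness_mm)
    fat_thr = fat_gland_threshold(with_skin, fat_fraction)
    return segment(with_skin, air_thr, fat_thr)


# ---------------------------------------------------------------------------
# acoustic property assignment


@dataclass
class TissueProperties:
    """Density (kg/m^3), sound speed (m/s) and attenuation (dB/m/MHz) per tissue.

    Defaults are the measured values used throughout: skin 1090/1615, gland
    1032/1547/60, fat 985/1465/40, water 998.2/1482/0.22.  No skin
    attenuation was reported; the default borrows the fibroglandular value
    (the skin shell is thin and was found not to affect focusing) and is
    configurable.
    """

    density: dict = field(
        default_factory=lambda: {
            Tissue.WATER: 998.2,
            Tissue.SKIN: 1090.0,
            Tissue.FAT: 985.0,
            Tissue.GLAND: 1032.0,
        }
    )
    sound_speed: dict = field(
        default_factory=lambda: {
            Tissue.WATER: 1482.0,
            Tissue.SKIN: 1615.0,
            Tissue.FAT: 1465.0,
            Tissue.GLAND: 1547.0,
        }
    )
    attenuation_db_m_mhz: dict = field(
        default_factory=lambda: {
            Tissue.WATER: 0.22,
            Tissue.SKIN: 60.0,
            Tissue.FAT: 40.0,
            Tissue.GLAND: 60.0,
        }
    )

    def impedance(self, tissue: Tissue) -> float:
        """Characteristic impedance rho*c in Pa s/m."""
        return self.density[tissue] * self.sound_speed[tissue]


DB_TO_NP = np.log(10.0) / 20.0  # 1 dB = 0.1151 Np


@dataclass
class MediumField:
    """Acoustic maps on the simulation lattice.

    rho in kg/m^3, c in m/s, alpha0 in dB/m/MHz.  ``alpha_np(f)`` converts to
    Np/m at the driving frequency (attenuation linear in frequency).
    """

    rho: np.ndarray
    c: np.ndarray
    alpha0: np.ndarray
    voxel_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=np.float64).reshape(-1)
        if self.voxel_mm.size == 1:
            self.voxel_mm = np.repeat(self.voxel_mm, self.rho.ndim)
        if self.origin_mm is None:
            self.origin_mm = np.zeros(self.rho.ndim)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(-1)

    @property
    def impedance(self) -> np.ndarray:
        return self.rho * self.c

    def alpha_np(self, frequency_hz: float) -> np.ndarray:
        return self.alpha0 * (frequency_hz / 1e6) * DB_TO_NP


def assign_properties(
    labels: TissueLabelVolume, props: TissueProperties | None = None
) -> MediumField:
    """Look up per-voxel (rho, c, alpha0) from the tissue table."""
    props = props or TissueProperties()
    present = np.unique(labels.labels)
    known = {int(t) for t in Tissue}
    unknown = set(present.tolist()) - known
    if unknown:
        raise ValueError(f"assign_properties: unknown labels {unknown}")
    lut_rho = np.zeros(4)
    lut_c = np.zeros(4)
    lut_a = np.zeros(4)
    for t in Tissue:
        lut_rho[int(t)] = props.density[t]
        lut_c[int(t)] = props.sound_speed[t]
        lut_a[int(t)] = props.attenuation_db_m_mhz[t]
    lab = labels.labels
    return MediumField(
        rho=lut_rho[lab],
        c=lut_c[lab],
        alpha0=lut_a[lab],
        voxel_mm=labels.voxel_mm.copy(),
        origin_mm=labels.origin_mm.copy(),
        provenance="assign_properties(label volume)",
    )


def uniform_water_medium(
    shape, voxel_mm, props: TissueProperties | None = None
) -> MediumField:
    """A water-only medium covering the given lattice."""
    props = props or TissueProperties()
    shape = tuple(shape)
    return MediumField(
        rho=np.full(shape, props.density[Tissue.WATER]),
        c=np.full(shape, props.sound_speed[Tissue.WATER]),
        alpha0=np.full(shape, props.attenuation_db_m_mhz[Tissue.WATER]),
        voxel_mm=np.asarray(voxel_mm, dtype=float),
        provenance="uniform water",
    )
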