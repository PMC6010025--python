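"""Phased-array transducer model and time-reversal focus control.

The therapeutic array is a 256-element spherical cap (focal distance 100 mm,
aperture 120 mm, 35 mm imaging hole, f-number 5/6) tiled with equal-area
annular rings subdivided into sectors.  A 2-D arc analogue with the same
f-number serves the desk-scale cross-section simulations.  Time-reversal
drive parameters are recovered from element recordings of a point emitter at
the target by cross-correlating each element with a reference element.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .acoustics.solver import Probe, Source


@dataclass
class TransducerArray:
    """Spherical-cap phased array; element centers on the sphere about the focus."""

    focal_distance_mm: float = 100.0
    aperture_diameter_mm: float = 120.0
    hole_diameter_mm: float = 35.0
    n_elements: int = 256
    frequency_hz: float = 2e6
    centers_mm: np.ndarray = None  # type: ignore[assignment]  # (n, 3), focus at origin
    normals: np.ndarray = None  # type: ignore[assignment]
    areas_mm2: np.ndarray = None  # type: ignore[assignment]

    @property
    def f_number(self) -> float:
        return self.focal_distance_mm / self.aperture_diameter_mm


@dataclass
class DriveParameters:
    """Per-element phase shift (radians, wrapped to (-pi, pi]) and amplitude scale."""

    phase: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.phase = wrap_phase(np.asarray(self.phase, dtype=float))
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(self.amplitude < 0):
            raise ValueError("drive amplitudes must be non-negative")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"phase": self.phase.tolist(), "amplitude": self.amplitude.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "DriveParameters":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["phase"]), np.asarray(d["amplitude"]))


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    return np.pi - out


def build_array(
    focal_distance_mm: float = 100.0,
    aperture_diameter_mm: float = 120.0,
    hole_diameter_mm: float = 35.0,
    n_elements: int = 256,
    frequency_hz: float = 2e6,
) -> TransducerArray:
    """Tile the cap between hole rim and outer rim with equal-area elements.

    Rings are chosen with widths set by cumulative area so that every element
    has exactly the same area; the number of sectors per ring is proportional
    to the ring circumference.  Deterministic layout; the focus is at the
    origin and the beam axis is +z (apex of the cap at z = -focal_distance).
    """
    if hole_diameter_mm >= aperture_diameter_mm:
        raise ValueError("hole must be smaller than the aperture")
    if focal_distance_mm <= aperture_diameter_mm / 2.0:
        raise ValueError("focal distance must exceed the aperture radius")
    R = focal_distance_mm
    th_hole = np.arcsin((hole_diameter_mm / 2.0) / R)
    th_rim = np.arcsin((aperture_diameter_mm / 2.0) / R)
    cos_h, cos_r = np.cos(th_hole), np.cos(th_rim)
    area_total = 2.0 * np.pi * R * R * (cos_h - cos_r)

    elem_size = np.sqrt(area_total / n_elements)
    n_rings = max(1, int(round(R * (th_rim - th_hole) / elem_size)))
    # provisional equal-width rings to apportion sector counts by circumference
    edges_th = np.linspace(th_hole, th_rim, n_rings + 1)
    circ = np.sin(0.5 * (edges_th[:-1] + edges_th[1:]))
    counts = np.maximum(1, np.round(n_elements * circ / circ.sum()).astype(int))
    while counts.sum() != n_elements:
        if counts.sum() > n_elements:
            counts[np.argmax(counts)] -= 1
        else:
            counts[np.argmax(circ / counts)] += 1
    # ring boundaries in cos(theta) so each ring holds counts[i] equal areas
    cum = np.concatenate([[0], np.cumsum(counts)]) / n_elements
    cos_edges = cos_h - cum * (cos_h - cos_r)

    centers, normals = [], []
    for i, m in enumerate(counts):
        cos_mid = 0.5 * (cos_edges[i] + cos_edges[i + 1])
        th = np.arccos(cos_mid)
        offset = 0.5 * (i % 2)  # stagger alternate rings
        for j in range(m):
            ph = 2.0 * np.pi * (j + 0.5 + offset) / m
            c = R * np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), -np.cos(th)]
            )
            centers.append(c)
            normals.append(-c / R)
    centers = np.asarray(centers)
    return TransducerArray(
        focal_distance_mm=focal_distance_mm,
        aperture_diameter_mm=aperture_diameter_mm,
        hole_diameter_mm=hole_diameter_mm,
        n_elements=n_elements,
        frequency_hz=frequency_hz,
        centers_mm=centers,
        normals=np.asarray(normals),
        areas_mm2=np.full(n_elements, area_total / n_elements),
    )


@dataclass
class ArcArray:
    """2-D arc analogue of the cap array for cross-section simulations.

    Elements are equal-angle sub-arcs of the circle of radius
    ``focal_distance_mm`` about the target, split symmetrically about the
    beam axis with a central gap for the imaging hole.  ``rotation_deg``
    rotates the whole arc about the target in the plane.
    """

    focal_distance_mm: float = 45.0
    aperture_mm: float = 54.0
    hole_mm: float = 15.75
    n_elements: int = 64
    frequency_hz: float = 2e6
    target_mm: np.ndarray = None  # type: ignore[assignment]  # (x, z)
    rotation_deg: float = 0.0
    # per-element angular spans (psi measured from the beam axis), set by builder
    psi_edges: np.ndarray = None  # type: ignore[assignment]  # (n, 2)

    @property
    def f_number(self) -> float:
        return self.focal_distance_mm / self.aperture_mm

    def element_centers_mm(self) -> np.ndarray:
        psi = self.psi_edges.mean(axis=1)
        return self.target_mm[None, :] + self.focal_distance_mm * self._dir(psi).T

    def _dir(self, psi: np.ndarray) -> np.ndarray:
        """Unit vectors from target toward arc points at angle psi (axis +z)."""
        rot = np.deg2rad(self.rotation_deg)
        a = psi + rot
        return np.vstack([np.sin(a), np.cos(a)])


def build_arc_array(
    focal_distance_mm: float = 45.0,
    aperture_mm: float = 54.0,
    hole_mm: float = 15.75,
    n_elements: int = 64,
    frequency_hz: float = 2e6,
    target_mm=(0.0, 0.0),
    rotation_deg: float = 0.0,
) -> ArcArray:
    if hole_mm >= aperture_mm:
        raise ValueError("hole must be smaller than the aperture")
    psi_rim = np.arcsin((aperture_mm / 2.0) / focal_distance_mm)
    psi_hole = np.arcsin((hole_mm / 2.0) / focal_distance_mm)
    half = n_elements // 2
    if 2 * half != n_elements:
        raise ValueError("n_elements must be even (symmetric arc halves)")
    edges_pos = np.linspace(psi_hole, psi_rim, half + 1)
    spans = [(-b, -a) for a, b in zip(edges_pos[:-1], edges_pos[1:])][::-1]
    spans += [(a, b) for a, b in zip(edges_pos[:-1], edges_pos[1:])]
    return ArcArray(
        focal_distance_mm=focal_distance_mm,
        aperture_mm=aperture_mm,
        hole_mm=hole_mm,
        n_elements=n_elements,
        frequency_hz=frequency_hz,
        target_mm=np.asarray(target_mm, dtype=float),
        rotation_deg=rotation_deg,
        psi_edges=np.asarray(spans),
    )


def arc_element_footprints(
    arc: ArcArray, origin_mm: np.ndarray, dx_mm: float, shape: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rasterize each element sub-arc onto grid cells.

    Returns per element (flat cell indices, weights); weights are the number
    of fine arc samples landing in the cell, approximating uniform line
    density.  Raises if any element falls outside the grid.
    """
    out = []
    for a, b in arc.psi_edges:
        arclen = arc.focal_distance_mm * (b - a)
        n_samp = max(8, int(np.ceil(arclen / (dx_mm / 4.0))))
        psi = a + (np.arange(n_samp) + 0.5) * (b - a) / n_samp
        pts = arc.target_mm[None, :] + arc.focal_distance_mm * arc._dir(psi).T
        idx = np.round((pts - origin_mm[None, :]) / dx_mm).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)[None, :]):
            raise ValueError("arc element footprint falls outside the grid")
        flat = idx[:, 0] * shape[1] + idx[:, 1]
        uniq, counts = np.unique(flat, return_counts=True)
        out.append((uniq, counts.astype(float)))
    return out


def geometric_drive(array) -> DriveParameters:
    """Uniform in-phase drive; the cap/arc geometry supplies the focusing."""
    n = array.n_elements
    return DriveParameters(np.zeros(n), np.ones(n))


def drive_sources(
    footprints: list[tuple[np.ndarray, np.ndarray]], drive: DriveParameters
) -> list[Source]:
    """Per-element soft sources carrying the drive phase/amplitude."""
    return [
        Source(cells=c, weights=w / w.sum(), amplitude=float(a), phase=float(ph))
        for (c, w), a, ph in zip(footprints, drive.amplitude, drive.phase)
    ]


def element_probes(footprints: list[tuple[np.ndarray, np.ndarray]]) -> list[Probe]:
    return [Probe(cells=c, weights=w) for c, w in footprints]


def reference_element_index(array) -> int:
    """The element nearest the beam axis (smallest |psi| for arcs)."""
    if isinstance(array, ArcArray):
        return int(np.argmin(np.abs(array.psi_edges.mean(axis=1))))
    lateral = np.linalg.norm(array.centers_mm[:, :2], axis=1)
    return int(np.argmin(lateral))


def time_reversal_drive(
    recordings: np.ndarray,
    dt: float,
    frequency_hz: float,
    reference: int,
    amp_cap: float = 4.0,
    window_cycles: int = 8,
) -> DriveParameters:
    """Drive parameters from element recordings of a point emitter at the target.

    For each element the lag of the cross-correlation maximum against the
    reference element (searched over one drive period, refined by parabolic
    interpolation) gives the relative arrival delay; time reversal advances
    what arrived late, so the phase shift is +2 pi f lag.  The amplitude is
    the element-to-reference RMS ratio (capped at ``amp_cap``): true time
    reversal re-emits in proportion to what was received, so elements
    shadowed by strongly aberrating tissue contribute little.  (The inverse
    ratio — boosting shadowed channels — pumps energy into the scattering
    paths and measurably degrades refocusing.)  A dead element gets
    amplitude 0 with a warning.
    """
    rec = np.asarray(recordings, dtype=float)
    n_elem, n_t = rec.shape
    period = 1.0 / frequency_hz
    spp = int(round(period / dt))
    w = min(n_t, window_cycles * spp)
    tail = rec[:, n_t - w :]
    ref = tail[reference]
    rms_ref = float(np.sqrt(np.mean(ref**2)))
    if rms_ref == 0:
        raise ValueError("reference element recorded no energy")

    K = spp // 2
    phases = np.zeros(n_elem)
    amps = np.zeros(n_elem)
    for e in range(n_elem):
        sig = tail[e]
        rms = float(np.sqrt(np.mean(sig**2)))
        if rms < 1e-12 * rms_ref:
            warnings.warn(f"element {e} recorded no energy; amplitude set to 0")
            continue
        # c[k] = sum_t sig(t) ref(t - k): maximal where k equals sig's delay
        lags = np.arange(-K, K + 1)
        c = np.array([np.dot(sig[K + k : w - K + k], ref[K : w - K]) for k in lags])
        m = int(np.argmax(c))
        if 0 < m < len(c) - 1:
            denom = c[m - 1] - 2 * c[m] + c[m + 1]
            frac = 0.5 * (c[m - 1] - c[m + 1]) / denom if denom != 0 else 0.0
        else:
            frac = 0.0
        lag = (lags[m] + frac) * dt
        phases[e] = 2.0 * np.pi * frequency_hz * lag
        amps[e] = min(rms / rms_ref, amp_cap)
    return DriveParameters(phases, amps)
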