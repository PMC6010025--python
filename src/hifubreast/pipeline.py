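"""End-to-end orchestration: phantom -> segmentation -> simulation -> metrics.

Ensemble runs use 2-D cross-section simulations of a scaled-down arc
transducer with the production f-number (5/6); the full 3-D cap geometry and
the axisymmetric diffraction oracle provide the free-field reference values.
Every stage is deterministic given the phantom seeds, so duplicated cases
produce identical rows.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import acoustics, metrics, segmentation, synthbreast, transducer
from .acoustics.solver import SimulationConfig, Source
from .segmentation import MediumField, TissueProperties, assign_properties
from .volume import Tissue, TissueLabelVolume


@dataclass
class SimSettings:
    """Desk-scale 2-D simulation conditions for ensemble runs.

    The arc keeps the clinical f-number 5/6 and the hole-to-aperture ratio at
    a reduced focal distance so a case runs on a workstation; distances mm.
    """

    dx_mm: float = 0.12
    focal_distance_mm: float = 40.0
    aperture_mm: float = 48.0
    hole_mm: float = 14.0
    n_elements: int = 64
    frequency_hz: float = 2e6
    n_cycles: int = 85
    forward_cycles: int = 75
    avg_cycles: int = 5
    ramp_cycles: int = 3
    pml_cells: int = 20
    pad_mm: float = 2.0
    amp_cap: float = 4.0

    def config(self, n_cycles: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            dx_mm=self.dx_mm,
            frequency_hz=self.frequency_hz,
            n_cycles=n_cycles or self.n_cycles,
            avg_cycles=self.avg_cycles,
            ramp_cycles=self.ramp_cycles,
            pml_cells=self.pml_cells,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class Case:
    """One planned treatment simulation.

    ``target_mode`` places the focus either in fat clear of the gland or deep
    inside the gland network; ``rotation_deg`` rotates the transducer about
    the target (the arrangement freedom the analysis studies).
    """

    recipe: synthbreast.PhantomRecipe | None  # None -> water-only
    target_mode: str = "gland"  # 'gland' | 'fat'
    rotation_deg: float = 0.0
    drive: str = "geometric"  # 'geometric' | 'time_reversal'
    gland_removed: bool = False  # ablation: gland given fat properties
    fat_fraction: float = 0.665  # fat/gland segmentation threshold quantile
    label: str = ""


# phantom slices are deterministic per recipe; cache across cases
_slice_cache: dict = {}
_reference_cache: dict = {}


def phantom_slice_2d(
    recipe: synthbreast.PhantomRecipe, fat_fraction: float = 0.665
) -> TissueLabelVolume:
    """Synthesize, segment, and take the central coronal-plane (x, z) slice."""
    key = (json.dumps(asdict(recipe), sort_keys=True), fat_fraction)
    if key in _slice_cache:
        return _slice_cache[key]
    vol = synthbreast.synthesize_breast_mri(recipe)
    labels = segmentation.segment_pipeline(vol, fat_fraction)
    j = labels.shape[1] // 2
    sl = TissueLabelVolume(
        labels.labels[:, j, :],
        np.array([recipe.voxel_mm[0], recipe.voxel_mm[2]]),
    )
    _slice_cache[key] = sl
    return sl


def choose_target_2d(labels2d: TissueLabelVolume, mode: str, recipe) -> np.ndarray:
    """Pick a target voxel in the slice: max (gland) or min (fat) local gland density.

    The candidate window sits in the breast core (depth 30-62% of the breast
    height, within 40% of the radius laterally) so the focus stays clear of
    skin and chest plane; density is the gland fraction in a ~4 mm
    neighbourhood.
    """
    lab = labels2d.labels
    vox = labels2d.voxel_mm
    gland = (lab == int(Tissue.GLAND)).astype(float)
    size = tuple(max(3, int(round(8.0 / v)) | 1) for v in vox)
    dens = ndimage.uniform_filter(gland, size=size)
    xs = np.arange(lab.shape[0]) * vox[0]
    zs = np.arange(lab.shape[1]) * vox[1]
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    cx = recipe.domain_size_mm[0] / 2.0
    window = (
        (np.abs(X - cx) <= 0.4 * recipe.breast_radius_mm)
        & (Z >= 0.30 * recipe.nipple_height_mm)
        & (Z <= 0.62 * recipe.nipple_height_mm)
    )
    want = int(Tissue.GLAND) if mode == "gland" else int(Tissue.FAT)
    cand = window & (lab == want)
    if not cand.any():
        cand = window & ((lab == int(Tissue.GLAND)) | (lab == int(Tissue.FAT)))
    if not cand.any():
        raise ValueError("no interior voxel available for target placement")
    score = np.where(cand, dens, -np.inf if mode == "gland" else np.inf)
    idx = (
        np.unravel_index(np.argmax(score), score.shape)
        if mode == "gland"
        else np.unravel_index(np.argmin(score), score.shape)
    )
    return np.array([xs[idx[0]], zs[idx[1]]])


def _sim_domain(settings: SimSettings, target_mm, arc: transducer.ArcArray,
                phantom_extent_mm):
    """World extents of the simulation grid covering phantom, arc and PML."""
    pad = settings.pad_mm + settings.pml_cells * settings.dx_mm
    psi = np.linspace(arc.psi_edges.min(), arc.psi_edges.max(), 101)
    pts = arc.target_mm[None, :] + arc.focal_distance_mm * arc._dir(psi).T
    x_lo = min(0.0, pts[:, 0].min(), target_mm[0] - 11.0) - pad
    x_hi = max(phantom_extent_mm[0], pts[:, 0].max(), target_mm[0] + 11.0) + pad
    z_lo = min(0.0, target_mm[1] - 11.0) - pad
    z_hi = max(pts[:, 1].max(), phantom_extent_mm[1]) + pad
    return (x_lo, x_hi), (z_lo, z_hi)


def build_case_medium(
    case: Case, settings: SimSettings
) -> tuple[MediumField, np.ndarray, transducer.ArcArray, np.ndarray]:
    """2-D medium on the simulation grid, plus target, arc and grid origin."""
    props = TissueProperties()
    if case.recipe is None:
        target = np.array([0.0, 0.0])
        phantom_extent = (0.0, 0.0)
        labels2d = None
    else:
        labels2d = phantom_slice_2d(case.recipe, case.fat_fraction)
        target = choose_target_2d(labels2d, case.target_mode, case.recipe)
        phantom_extent = (
            (labels2d.shape[0] - 1) * labels2d.voxel_mm[0],
            (labels2d.shape[1] - 1) * labels2d.voxel_mm[1],
        )
    arc = transducer.build_arc_array(
        settings.focal_distance_mm,
        settings.aperture_mm,
        settings.hole_mm,
        settings.n_elements,
        settings.frequency_hz,
        target_mm=target,
        rotation_deg=case.rotation_deg,
    )
    (x_lo, x_hi), (z_lo, z_hi) = _sim_domain(settings, target, arc, phantom_extent)
    dx = settings.dx_mm
    nx = int(np.ceil((x_hi - x_lo) / dx)) + 1
    nz = int(np.ceil((z_hi - z_lo) / dx)) + 1
    origin = np.array([x_lo, z_lo])

    lab_grid = np.full((nx, nz), int(Tissue.WATER), dtype=np.int16)
    if labels2d is not None:
        xs = origin[0] + np.arange(nx) * dx
        zs = origin[1] + np.arange(nz) * dx
        ix = np.round(xs / labels2d.voxel_mm[0]).astype(int)
        iz = np.round(zs / labels2d.voxel_mm[1]).astype(int)
        okx = (ix >= 0) & (ix < labels2d.shape[0])
        okz = (iz >= 0) & (iz < labels2d.shape[1])
        sub = labels2d.labels[np.ix_(ix[okx], iz[okz])]
        if case.gland_removed:
            sub = np.where(sub == int(Tissue.GLAND), int(Tissue.FAT), sub)
        lab_grid[np.ix_(okx, okz)] = sub

    medium = assign_properties(
        TissueLabelVolume(lab_grid, np.array([dx, dx]), origin), props
    )
    return medium, target, arc, origin


def _point_source(target_mm, origin_mm, dx, shape) -> Source:
    idx = np.round((np.asarray(target_mm) - origin_mm) / dx).astype(int)
    flat = np.array([idx[0] * shape[1] + idx[1]])
    return Source(cells=flat, weights=np.ones(1))


def free_field_reference(settings: SimSettings) -> dict:
    """Free-field (water) run of the arc: phi_0 and the reference peak.

    Computed once per settings hash and cached; rotation-invariant, so a
    single canonical run serves every case.
    """
    key = settings.hash()
    if key in _reference_cache:
        return _reference_cache[key]
    case = Case(recipe=None, label="free-field")
    medium, target, arc, origin = build_case_medium(case, settings)
    foot = transducer.arc_element_footprints(arc, origin, settings.dx_mm, medium.rho.shape)
    drive = transducer.geometric_drive(arc)
    res = acoustics.run(
        settings.config(), medium, transducer.drive_sources(foot, drive)
    )
    regions = metrics.MetricRegions(target)
    phi0 = metrics.focusing_ratio(res.msq_pressure, medium, regions, origin_mm=origin)
    _, peak_amp, _ = metrics.primary_peak(
        res.msq_pressure, medium.voxel_mm, target, 1.0, origin_mm=origin
    )
    out = {"phi0": phi0, "peak": peak_amp}
    _reference_cache[key] = out
    return out


def run_case(
    case: Case, settings: SimSettings, reference: dict | None = None
) -> tuple[metrics.FocalMetrics, metrics.InhomogeneityResult]:
    """Execute one planned case end to end.

    Free-field reference -> phantom medium -> (optional time-reversal
    calibration) -> insonification -> focal metrics + beam-path
    inhomogeneity.
    """
    reference = reference or free_field_reference(settings)
    medium, target, arc, origin = build_case_medium(case, settings)
    shape = medium.rho.shape
    foot = transducer.arc_element_footprints(arc, origin, settings.dx_mm, shape)

    flight = settings.focal_distance_mm * 1e-3 / float(medium.c.min())
    if settings.n_cycles / settings.frequency_hz < flight:
        warnings.warn("simulated time shorter than the source-to-focus flight time")

    if case.drive == "time_reversal":
        fwd = acoustics.run(
            settings.config(settings.forward_cycles),
            medium,
            [_point_source(target, origin, settings.dx_mm, shape)],
            probes=transducer.element_probes(foot),
        )
        drive = transducer.time_reversal_drive(
            fwd.recordings,
            fwd.dt,
            settings.frequency_hz,
            transducer.reference_element_index(arc),
            amp_cap=settings.amp_cap,
        )
    elif case.drive == "geometric":
        drive = transducer.geometric_drive(arc)
    else:
        raise ValueError(f"unknown drive mode {case.drive!r}")

    res = acoustics.run(
        settings.config(), medium, transducer.drive_sources(foot, drive)
    )
    regions = metrics.MetricRegions(target)
    Q = acoustics.heat_deposition(res, medium)
    beta = metrics.localized_heating_ratio(Q, medium.voxel_mm, regions, origin_mm=origin)
    phi = metrics.focusing_ratio(res.msq_pressure, medium, regions, origin_mm=origin)
    loc, peak_norm, dist = metrics.primary_peak(
        res.msq_pressure, medium.voxel_mm, target, reference["peak"], origin_mm=origin
    )
    fm = metrics.FocalMetrics(
        beta=beta,
        phi=phi,
        phi0=reference["phi0"],
        Phi=phi / reference["phi0"],
        peak_pressure=peak_norm,
        peak_location_mm=loc,
        peak_distance_mm=dist,
    )
    apc = arc.target_mm + arc.focal_distance_mm * arc._dir(np.array([0.0]))[:, 0]
    if case.recipe is None:
        chi = metrics.InhomogeneityResult(chi=0.0, n_voxels=0, region="free field")
    else:
        chi = metrics.local_acoustic_inhomogeneity(
            medium,
            target,
            apc,
            settings.aperture_mm / 2.0,
            frequency_hz=settings.frequency_hz,
            origin_mm=origin,
        )
    return fm, chi


def default_ensemble_cases(n: int = 10) -> list[Case]:
    """Planned ensemble spanning gland morphology and transducer pose.

    Targets are lesion-like, i.e. placed in the fibroglandular class (benign
    or malignant lesions segment as fibroglandular tissue), at two poses per
    phantom plus morphology variants that widen the gland-burden range.
    """
    refs = synthbreast.reference_phantoms()
    cases = []
    rots = [0.0, 10.0, -12.0, 6.0]
    k = 0
    for recipe, desc in refs:
        for rot in (rots[k % 4], rots[(k + 1) % 4]):
            cases.append(
                Case(
                    recipe=recipe,
                    target_mode="gland",
                    rotation_deg=rot,
                    label=f"{desc} / rot {rot:+.0f}",
                )
            )
        k += 1
    extra = [
        Case(
            recipe=replace(refs[3][0], seed=21, gland_fraction_target=0.55,
                           gland_correlation_mm=1.0),
            target_mode="gland",
            rotation_deg=8.0,
            label="dense fine-grained variant / rot +8",
        ),
        Case(
            recipe=replace(refs[2][0], seed=22, gland_fraction_target=0.14),
            target_mode="gland",
            rotation_deg=-8.0,
            label="very sparse variant / rot -8",
        ),
    ]
    cases.extend(extra)
    return cases[:n] if n <= len(cases) else cases


def fixture_cases() -> list[Case]:
    """Four contrasting cases used for the time-reversal comparisons."""
    refs = synthbreast.reference_phantoms()
    return [
        Case(recipe=refs[0][0], target_mode="gland", rotation_deg=0.0,
             label="chest-wall gland / target gland"),
        Case(recipe=refs[1][0], target_mode="gland", rotation_deg=10.0,
             label="nipple gland / target gland"),
        Case(recipe=refs[2][0], target_mode="fat", rotation_deg=0.0,
             label="sparse gland / target fat"),
        Case(recipe=refs[3][0], target_mode="gland", rotation_deg=-10.0,
             label="dense gland / target gland"),
    ]


def run_ensemble(
    cases: list[Case], settings: SimSettings | None = None
) -> tuple[pd.DataFrame, dict]:
    """Run every case and correlate the focal metrics with the inhomogeneity.

    Returns the per-case table (sorted by label for order independence) and
    the Pearson correlations the analysis reports: corr(Phi, chi),
    corr(normalized peak, chi) and corr(beta, phi).
    """
    if len(cases) < 3:
        raise ValueError("ensemble needs at least 3 cases")
    settings = settings or SimSettings()
    reference = free_field_reference(settings)
    rows = []
    for case in cases:
        fm, chi = run_case(case, settings, reference)
        rows.append(
            {
                "label": case.label,
                "drive": case.drive,
                "rotation_deg": case.rotation_deg,
                "Phi": fm.Phi,
                "phi": fm.phi,
                "beta": fm.beta,
                "chi": chi.chi,
                "peak_norm": fm.peak_pressure,
                "peak_distance_mm": fm.peak_distance_mm,
            }
        )
    table = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    corr = {
        "corr_Phi_chi": metrics.pearson_correlation(table["Phi"], table["chi"]),
        "corr_peak_chi": metrics.pearson_correlation(table["peak_norm"], table["chi"]),
        "corr_beta_phi": metrics.pearson_correlation(table["beta"], table["phi"]),
        "corr_dist_chi": metrics.pearson_correlation(
            table["peak_distance_mm"], table["chi"]
        ),
    }
    return table, corr
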