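"""Shared fixtures: expensive simulation products computed once per session."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from hifubreast import metrics, pipeline, transducer
from hifubreast.acoustics import solver
from hifubreast.segmentation import TissueProperties, uniform_water_medium
from hifubreast.synthbreast import PhantomRecipe
from hifubreast.volume import Tissue

WATER_C = 1482.0
FREQ = 2e6


@pytest.fixture(scope="session")
def settings():
    return pipeline.SimSettings()


@pytest.fixture(scope="session")
def ff_ref(settings):
    return pipeline.free_field_reference(settings)


@pytest.fixture(scope="session")
def fixture_runs(settings, ff_ref):
    """Geometric and time-reversal runs for the four contrasting fixture cases."""
    out = []
    for case in pipeline.fixture_cases():
        fm_g, chi = pipeline.run_case(case, settings, ff_ref)
        fm_t, _ = pipeline.run_case(
            replace(case, drive="time_reversal"), settings, ff_ref
        )
        out.append({"case": case, "geom": fm_g, "chi": chi, "tr": fm_t})
    return out


@pytest.fixture(scope="session")
def ablation_runs(settings, ff_ref):
    """Phi with the fibroglandular tissue given fat properties (gland removal)."""
    cases = [pipeline.fixture_cases()[i] for i in (0, 3)]
    out = []
    for case in cases:
        fm, _ = pipeline.run_case(replace(case, gland_removed=True), settings, ff_ref)
        out.append({"case": case, "ablated": fm})
    return out


@pytest.fixture(scope="session")
def ensemble(settings):
    table, corr = pipeline.run_ensemble(
        pipeline.default_ensemble_cases(10), settings
    )
    return table, corr


@pytest.fixture
def small_recipe():
    """A fast-to-synthesize phantom for unit tests."""
    return PhantomRecipe(
        domain_size_mm=(40.0, 40.0, 26.0),
        breast_radius_mm=16.0,
        nipple_height_mm=21.0,
        seed=5,
    )


def _line_run(medium, cfg, src_cell, probe_cells):
    src = solver.Source(cells=np.array([src_cell]), weights=np.ones(1))
    probes = [
        solver.Probe(cells=np.array([c]), weights=np.ones(1)) for c in probe_cells
    ]
    return solver.run(cfg, medium, [src], probes=probes)


@pytest.fixture(scope="session")
def plane_wave_1d():
    """1-D water run at 15 points per wavelength, small CFL, two probes.

    Returns (measured phase speed, measured amplitude ratio over the probe
    separation, expected water attenuation factor).
    """
    dx = 0.05
    n = 2400
    med = uniform_water_medium((n,), (dx,))
    cfg = solver.SimulationConfig(
        dx_mm=dx, cfl=0.1, frequency_hz=FREQ, n_cycles=75, avg_cycles=5,
        ramp_cycles=3, pml_cells=20,
    )
    res = _line_run(med, cfg, 100, (600, 1000))
    a, b = res.recordings
    spp = int(round(1.0 / (FREQ * res.dt)))
    w = res.n_steps - 8 * spp
    t = np.arange(res.n_steps) * res.dt
    demod = np.exp(-2j * np.pi * FREQ * t)
    A = (a[w:] * demod[w:]).sum()
    B = (b[w:] * demod[w:]).sum()
    dist = 400 * dx * 1e-3
    k_exp = 2 * np.pi * FREQ / WATER_C
    n2pi = np.round((k_exp * dist + np.angle(B / A)) / (2 * np.pi))
    c_meas = 2 * np.pi * FREQ * dist / (2 * np.pi * n2pi - np.angle(B / A))
    expected_decay = float(np.exp(-med.alpha_np(FREQ)[0] * dist))
    return c_meas, float(np.abs(B / A)), expected_decay


@pytest.fixture(scope="session")
def fat_slab_transmission():
    """RMS transmission through 10 mm of fat relative to the lossless run."""
    dx = 0.05
    n = 1400
    props = TissueProperties()
    cfg = solver.SimulationConfig(
        dx_mm=dx, frequency_hz=FREQ, n_cycles=75, avg_cycles=5, ramp_cycles=3,
        pml_cells=20,
    )

    def slab(alpha_on):
        m = uniform_water_medium((n,), (dx,))
        m.alpha0[:] = 0.0
        sl = slice(500, 500 + int(10 / dx))
        m.rho[sl] = props.density[Tissue.FAT]
        m.c[sl] = props.sound_speed[Tissue.FAT]
        if alpha_on:
            m.alpha0[sl] = props.attenuation_db_m_mhz[Tissue.FAT]
        return _line_run(m, cfg, 100, (1100,))

    ra, rl = slab(True), slab(False)
    spp = int(round(1.0 / (FREQ * ra.dt)))
    w = ra.n_steps - 6 * spp
    return float(
        np.sqrt(np.mean(ra.recordings[0][w:] ** 2) / np.mean(rl.recordings[0][w:] ** 2))
    )


@pytest.fixture(scope="session")
def fresnel_reflection():
    """Measured pressure reflection coefficient at a flat water/fat interface."""
    dx = 0.05
    n = 1400
    props = TissueProperties()
    cfg = solver.SimulationConfig(
        dx_mm=dx, frequency_hz=FREQ, n_cycles=85, avg_cycles=5, ramp_cycles=3,
        pml_cells=20,
    )
    m = uniform_water_medium((n,), (dx,))
    m.alpha0[:] = 0.0
    m.rho[800:] = props.density[Tissue.FAT]
    m.c[800:] = props.sound_speed[Tissue.FAT]
    mh = uniform_water_medium((n,), (dx,))
    mh.alpha0[:] = 0.0
    rh = _line_run(mh, cfg, 100, (500,))
    rf = _line_run(m, cfg, 100, (500,))
    refl = rf.recordings[0] - rh.recordings[0]
    spp = int(round(1.0 / (FREQ * rf.dt)))
    seg = slice(rf.n_steps - 6 * spp, rf.n_steps)
    return float(
        np.sqrt(np.mean(refl[seg] ** 2) / np.mean(rh.recordings[0][seg] ** 2))
    )


@pytest.fixture(scope="session")
def oracle_field_rz():
    """Axisymmetric diffraction field of the clinical cap on an (r, z) grid."""
    from hifubreast.acoustics import cap_field_rz

    dr = 0.08
    r = (np.arange(int(10.4 / dr)) + 0.5) * dr
    z = (np.arange(-int(10.4 / dr), int(10.4 / dr)) + 0.5) * dr
    field = cap_field_rz(100.0, 120.0, 35.0, FREQ, WATER_C, r, z)
    return field, r, z


@pytest.fixture(scope="session")
def scaled_arc_freefield():
    """2-D free-field run of a scaled arc at 15 points per wavelength.

    Returns (result, medium, origin, arc, footprints, dx).
    """
    dx = 0.05
    arc = transducer.build_arc_array(25.0, 30.0, 8.75, 32, FREQ, target_mm=(0.0, 0.0))
    pad = 20 * dx + 2.0
    x_lo, z_lo = -17.0 - pad, -12.0 - pad
    nx = int(np.ceil((17.0 + pad - x_lo) / dx)) + 1
    nz = int(np.ceil((25.5 + pad - z_lo) / dx)) + 1
    origin = np.array([x_lo, z_lo])
    med = uniform_water_medium((nx, nz), (dx, dx))
    foot = transducer.arc_element_footprints(arc, origin, dx, (nx, nz))
    cfg = solver.SimulationConfig(
        dx_mm=dx, frequency_hz=FREQ, n_cycles=55, avg_cycles=5, ramp_cycles=3,
        pml_cells=20,
    )
    res = solver.run(cfg, med, transducer.drive_sources(foot, transducer.geometric_drive(arc)))
    return res, med, origin, arc, foot, dx
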