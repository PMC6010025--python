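import numpy as np
import pytest

from hifubreast import metrics, transducer
from hifubreast.acoustics import oracle, solver
from hifubreast.segmentation import TissueProperties, uniform_water_medium
from hifubreast.volume import Tissue

FREQ = 2e6


def test_stable_timestep_closed_form():
    med = uniform_water_medium((10, 10), (0.075, 0.075))
    cfg = solver.SimulationConfig(dx_mm=0.075, cfl=0.4)
    assert solver.stable_timestep(cfg, med) == pytest.approx(
        0.4 * 0.075e-3 / 1482.0, rel=1e-12
    )


def test_stable_timestep_monotone_in_cmax_and_dx():
    cfg = solver.SimulationConfig(cfl=0.4)
    med = uniform_water_medium((10, 10), (0.075, 0.075))
    dt_water = solver.stable_timestep(cfg, med)
    med.c[0, 0] = 1615.0  # add skin, the fastest tissue
    assert solver.stable_timestep(cfg, med) < dt_water
    med2 = uniform_water_medium((10, 10), (0.0375, 0.0375))
    assert solver.stable_timestep(cfg, med2) == pytest.approx(dt_water / 2, rel=1e-12)


def test_zero_field_stays_zero():
    med = uniform_water_medium((64, 64), (0.12, 0.12))
    cfg = solver.SimulationConfig(dx_mm=0.12, n_cycles=4, avg_cycles=2, ramp_cycles=1)
    res = solver.run(cfg, med)
    assert res.msq_pressure.max() == 0.0
    assert res.peak_pressure.max() == 0.0


def test_rejects_underresolved_grid():
    med = uniform_water_medium((32, 32), (0.3, 0.3))  # < 3 points per wavelength
    cfg = solver.SimulationConfig(dx_mm=0.3, n_cycles=4, avg_cycles=2)
    with pytest.raises(ValueError, match="points per wavelength"):
        solver.run(cfg, med)


def test_plane_wave_phase_speed(plane_wave_1d):
    """Numerical dispersion at 15 points per wavelength stays below 0.1%."""
    c_meas, _, _ = plane_wave_1d
    assert abs(c_meas / 1482.0 - 1.0) < 1e-3


def test_plane_wave_water_attenuation(plane_wave_1d):
    """The matched loss term reproduces Beer-Lambert decay in water."""
    _, measured, expected = plane_wave_1d
    assert measured == pytest.approx(expected, rel=2e-3)


def test_fresnel_reflection_water_fat(fresnel_reflection):
    """Normal-incidence reflection within 2% of |Zf - Zw| / (Zf + Zw)."""
    z_w = 998.2 * 1482.0
    z_f = 985.0 * 1465.0
    expected = abs(z_f - z_w) / (z_f + z_w)  # 0.0123
    assert fresnel_reflection == pytest.approx(expected, rel=0.02)


def test_fat_slab_attenuation_factor(fat_slab_transmission):
    """10 mm of fat at 2 MHz: amplitude factor 10^(-0.8/20) = 0.912."""
    assert fat_slab_transmission == pytest.approx(10 ** (-0.8 / 20), rel=0.01)


def test_linearity_doubling_amplitude():
    med = uniform_water_medium((96, 96), (0.12, 0.12))
    src = solver.Source(cells=np.array([40 * 96 + 48]), weights=np.ones(1))
    cfg1 = solver.SimulationConfig(dx_mm=0.12, n_cycles=10, avg_cycles=3,
                                   amplitude_pa=1.0)
    cfg2 = solver.SimulationConfig(dx_mm=0.12, n_cycles=10, avg_cycles=3,
                                   amplitude_pa=2.0)
    r1 = solver.run(cfg1, med, [src])
    r2 = solver.run(cfg2, med, [src])
    np.testing.assert_allclose(r2.msq_pressure, 4.0 * r1.msq_pressure, rtol=1e-9,
                               atol=1e-300)


def test_energy_conservation_lossless():
    """Closed lossless run conserves acoustic energy within 1%."""
    dx, n = 0.12, 256
    med = uniform_water_medium((n, n), (dx, dx))
    med.alpha0[:] = 0.0
    xs = (np.arange(n) - n / 2) * dx
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    p0 = np.exp(-(X**2 + Z**2) / (2 * 2.0**2))
    cfg = solver.SimulationConfig(dx_mm=dx, cfl=0.3, n_cycles=12, avg_cycles=2,
                                  ramp_cycles=1, pml_cells=0)
    res = solver.run(cfg, med, initial_pressure=p0, track_energy=True)
    E = res.energy
    assert (E.max() - E.min()) / E[0] < 0.01


def test_reciprocity_heterogeneous_lossless():
    """Swapping a water-sited point source and receiver gives the same signal."""
    dx, n = 0.12, 256
    props = TissueProperties()
    med = uniform_water_medium((n, n), (dx, dx))
    med.alpha0[:] = 0.0
    xs = (np.arange(n) - n / 2) * dx
    X, Z = np.meshgrid(xs, xs, indexing="ij")
    ell = ((X / 6.0) ** 2 + (Z / 3.5) ** 2) <= 1.0
    med.rho[ell] = props.density[Tissue.FAT]
    med.c[ell] = props.sound_speed[Tissue.FAT]
    fa = np.array([60 * n + 128])
    fb = np.array([196 * n + 110])
    cfg = solver.SimulationConfig(dx_mm=dx, n_cycles=30, avg_cycles=2, ramp_cycles=3)
    r1 = solver.run(cfg, med, [solver.Source(fa, np.ones(1))],
                    probes=[solver.Probe(fb, np.ones(1))])
    r2 = solver.run(cfg, med, [solver.Source(fb, np.ones(1))],
                    probes=[solver.Probe(fa, np.ones(1))])
    s1, s2 = r1.recordings[0], r2.recordings[0]
    assert np.linalg.norm(s1 - s2) <= 0.01 * np.linalg.norm(s1)


def test_nonlinear_term_perturbs_field():
    med = uniform_water_medium((400,), (0.05,))
    src = solver.Source(cells=np.array([60]), weights=np.ones(1))
    base = solver.SimulationConfig(dx_mm=0.05, frequency_hz=FREQ, n_cycles=12,
                                   avg_cycles=3, amplitude_pa=5e5)
    nl = solver.SimulationConfig(dx_mm=0.05, frequency_hz=FREQ, n_cycles=12,
                                 avg_cycles=3, amplitude_pa=5e5, nonlinear=True,
                                 b_over_a=5.2)
    r_lin = solver.run(base, med, [src])
    r_nl = solver.run(nl, med, [src])
    assert not np.allclose(r_lin.msq_pressure, r_nl.msq_pressure, rtol=1e-6)


def test_focused_arc_peak_at_geometric_focus(ff_ref, settings):
    """Free-field arc: <p^2> maximum within 2 grid cells of the focus."""
    from hifubreast import pipeline
    from hifubreast.pipeline import Case, build_case_medium
    from hifubreast.acoustics import run as arun

    case = Case(recipe=None)
    medium, target, arc, origin = build_case_medium(case, settings)
    foot = transducer.arc_element_footprints(arc, origin, settings.dx_mm,
                                             medium.rho.shape)
    res = arun(settings.config(), medium,
               transducer.drive_sources(foot, transducer.geometric_drive(arc)))
    loc, _, dist = metrics.primary_peak(res.msq_pressure, medium.voxel_mm, target,
                                        origin_mm=origin)
    assert dist <= 2 * settings.dx_mm + 1e-9


def test_fdtd_matches_linear_oracle_at_15ppw(scaled_arc_freefield):
    """Free-field focal amplitude profile vs the Hankel-superposition oracle."""
    res, med, origin, arc, foot, dx = scaled_arc_freefield
    nx, nz = med.rho.shape
    ix = np.arange(0, nx, 3)
    iz = np.arange(0, nz, 3)
    XX = origin[0] + ix[:, None] * dx
    ZZ = origin[1] + iz[None, :] * dx
    XXg, ZZg = np.broadcast_arrays(XX, ZZ)
    mask = (XXg**2 + ZZg**2) <= 100.0  # 10 mm disk about the focus
    amp_f = np.sqrt(2 * res.msq_pressure[np.ix_(ix, iz)])[mask]
    src_xy, wts = [], []
    for cells, w in foot:
        cx = origin[0] + (cells // nz) * dx
        cz = origin[1] + (cells % nz) * dx
        src_xy.append(np.column_stack([cx, cz]))
        wts.append(w / w.sum())
    po = oracle.line_source_field_2d(
        np.vstack(src_xy), np.concatenate(wts),
        np.column_stack([XXg[mask], ZZg[mask]]), FREQ, 1482.0,
    )
    amp_o = np.abs(po)
    amp_f = amp_f / amp_f.max()
    amp_o = amp_o / amp_o.max()
    err = np.linalg.norm(amp_f - amp_o) / np.linalg.norm(amp_o)
    assert err < 0.05


def test_grid_convergence_of_focusing_ratio(scaled_arc_freefield):
    """Halving dx changes the free-field focusing ratio by < 2%."""
    res, med, origin, arc, foot, dx_fine = scaled_arc_freefield
    reg = metrics.MetricRegions(np.zeros(2))
    phi_fine = metrics.focusing_ratio(res.msq_pressure, med, reg, origin_mm=origin)

    dx = 0.1  # twice the fixture's spacing
    pad = 20 * dx + 2.0
    x_lo, z_lo = -17.0 - pad, -12.0 - pad
    nx = int(np.ceil((17.0 + pad - x_lo) / dx)) + 1
    nz = int(np.ceil((25.5 + pad - z_lo) / dx)) + 1
    origin2 = np.array([x_lo, z_lo])
    med2 = uniform_water_medium((nx, nz), (dx, dx))
    foot2 = transducer.arc_element_footprints(arc, origin2, dx, (nx, nz))
    cfg = solver.SimulationConfig(dx_mm=dx, frequency_hz=FREQ, n_cycles=55,
                                  avg_cycles=5, ramp_cycles=3, pml_cells=20)
    res2 = solver.run(cfg, med2,
                      transducer.drive_sources(foot2, transducer.geometric_drive(arc)))
    phi_coarse = metrics.focusing_ratio(res2.msq_pressure, med2, reg, origin_mm=origin2)
    assert abs(phi_fine - phi_coarse) / phi_fine < 0.02


def test_heat_deposition_conventions():
    med = uniform_water_medium((8, 8), (0.12, 0.12))
    props = TissueProperties()
    med.rho[:] = props.density[Tissue.FAT]
    med.c[:] = props.sound_speed[Tissue.FAT]
    med.alpha0[:] = props.attenuation_db_m_mhz[Tissue.FAT]
    cfg = solver.SimulationConfig(dx_mm=0.12, frequency_hz=FREQ)
    p_amp = 2.0e5
    res = solver.SimulationResult(
        msq_pressure=np.full((8, 8), p_amp**2 / 2.0),
        peak_pressure=np.full((8, 8), p_amp),
        recordings=None, dt=1e-8, n_steps=1, config=cfg,
    )
    Q = solver.heat_deposition(res, med)
    alpha = med.alpha_np(FREQ)[0, 0]
    rho_c = props.density[Tissue.FAT] * props.sound_speed[Tissue.FAT]
    assert Q[0, 0] == pytest.approx(alpha * p_amp**2 / rho_c, rel=1e-12)
    # zero field -> zero heat
    res.msq_pressure[:] = 0.0
    assert solver.heat_deposition(res, med).max() == 0.0


def test_heat_ratio_between_tissues():
    """Equal <p^2> in water and fat: Q ratio equals (alpha/rho c) ratio."""
    props = TissueProperties()
    med = uniform_water_medium((2, 2), (0.12, 0.12))
    med.rho[1] = props.density[Tissue.FAT]
    med.c[1] = props.sound_speed[Tissue.FAT]
    med.alpha0[1] = props.attenuation_db_m_mhz[Tissue.FAT]
    cfg = solver.SimulationConfig(dx_mm=0.12, frequency_hz=FREQ)
    res = solver.SimulationResult(
        msq_pressure=np.ones((2, 2)), peak_pressure=np.ones((2, 2)),
        recordings=None, dt=1e-8, n_steps=1, config=cfg,
    )
    Q = solver.heat_deposition(res, med)
    expected = (40.0 / (985.0 * 1465.0)) / (0.22 / (998.2 * 1482.0))
    assert Q[1, 0] / Q[0, 0] == pytest.approx(expected, rel=1e-12)
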