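"""Heterogeneous-media FDTD driver.

The governing system is the standard first-order pressure-velocity
formulation of linear acoustics in an inhomogeneous fluid,

    rho dv/dt = -grad p,        dp/dt = -rho c^2 div v,

discretised with 6th-order central differences in space on a staggered
lattice and leapfrog time stepping, with a split-field PML at every domain
face and a matched loss term reproducing the tissue attenuation (Np/m,
calibrated at the drive frequency).  An optional quadratic (B/A)
nonlinearity scales the stiffness term with the local instantaneous
pressure; propagation is linear by default since every reported metric is a
field-ratio quantity.

Material maps are sampled on the staggered lattice: density is averaged
harmonically onto velocity nodes, rho*c^2 lives on pressure nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ..segmentation import MediumField
from . import _kernels
from ._kernels import STENCIL_L1

#: B/A nonlinearity parameters (literature values, configurable)
DEFAULT_B_OVER_A = {"water": 5.2, "fat": 9.9, "gland": 7.0, "skin": 7.9}


@dataclass
class SimulationConfig:
    """Run-level numerical parameters (distances in mm, frequency in Hz)."""

    dx_mm: float = 0.125
    cfl: float | None = None  # default 0.4 (1D/2D), 0.3 (3D)
    frequency_hz: float = 2e6
    amplitude_pa: float = 1.0
    n_cycles: int = 100
    avg_cycles: int = 5
    ramp_cycles: int = 3
    pml_cells: int = 20
    nonlinear: bool = False
    b_over_a: float = 0.0  # uniform B/A map when nonlinear
    min_ppw: float = 6.0

    def cfl_for(self, ndim: int) -> float:
        if self.cfl is not None:
            return self.cfl
        return 0.3 if ndim == 3 else 0.4


@dataclass
class Source:
    """Additive ("soft") pressure source on a set of grid cells.

    ``cells`` are flat indices into the grid, ``weights`` their relative
    strengths (e.g. arc-length coverage of a transducer element).  The
    emitted signal is ``amplitude * sin(2 pi f t + phase)`` under a cosine
    ramp.
    """

    cells: np.ndarray
    weights: np.ndarray
    amplitude: float = 1.0
    phase: float = 0.0


@dataclass
class Probe:
    """Area-weighted pressure receiver (a transducer element footprint)."""

    cells: np.ndarray
    weights: np.ndarray


@dataclass
class SimulationResult:
    msq_pressure: np.ndarray  # time-average of p^2 over the window (Pa^2)
    peak_pressure: np.ndarray  # max |p| over the window (Pa)
    recordings: np.ndarray | None  # (n_probes, n_steps)
    dt: float
    n_steps: int
    config: SimulationConfig
    energy: np.ndarray | None = None


def stable_timestep(config: SimulationConfig, medium: MediumField) -> float:
    """CFL time step dt = CFL * dx / c_max for the 6th-order staggered scheme."""
    c_max = float(np.max(medium.c))
    dx = float(medium.voxel_mm[0]) * 1e-3
    return config.cfl_for(medium.rho.ndim) * dx / c_max


def _pml_profiles(n: int, n_pml: int, dx: float, dt: float, c_max: float):
    """Cubic-graded split-field PML conductivities on full and half nodes."""
    sig_p = np.zeros(n)
    sig_v = np.zeros(n)
    if n_pml <= 0:
        return sig_p, sig_v
    L = n_pml * dx
    sig_max = 4.0 * np.log(1e6) * c_max / (2.0 * L)
    for arr, off in ((sig_p, 0.0), (sig_v, 0.5)):
        x = np.arange(n) + off
        left = (n_pml - x) / n_pml
        right = (x - (n - 1 - n_pml)) / n_pml
        g = np.maximum(0.0, np.maximum(left, right))
        arr[:] = sig_max * np.minimum(1.0, g) ** 3
    return sig_p, sig_v


def _harmonic_half(rho: np.ndarray, axis: int) -> np.ndarray:
    """Density on velocity half-nodes (harmonic mean of the two neighbours)."""
    out = rho.copy()
    a = rho
    b = np.roll(rho, -1, axis=axis)
    out = 2.0 / (1.0 / a + 1.0 / b)
    # last half-node along the axis has no right neighbour; replicate
    sl = [slice(None)] * rho.ndim
    sl[axis] = -1
    out[tuple(sl)] = rho[tuple(sl)]
    return out


def run(
    config: SimulationConfig,
    medium: MediumField,
    sources: list[Source] = (),
    probes: list[Probe] = (),
    initial_pressure: np.ndarray | None = None,
    track_energy: bool = False,
) -> SimulationResult:
    """Time-step the field and accumulate steady-state statistics.

    The time step is rounded so a drive period is an integer number of
    steps; <p^2> and peak |p| are accumulated over the final ``avg_cycles``
    full cycles.  Raises on NaN/overflow with a diagnostic.
    """
    ndim = medium.rho.ndim
    dx = float(medium.voxel_mm[0]) * 1e-3
    if not np.allclose(medium.voxel_mm, medium.voxel_mm[0]):
        raise ValueError("FDTD medium must have isotropic spacing")
    c_min = float(np.min(medium.c))
    ppw = c_min / (config.frequency_hz * dx)
    if ppw < config.min_ppw - 1e-9:
        raise ValueError(
            f"grid resolves only {ppw:.2f} points per wavelength in the slowest "
            f"medium; at least {config.min_ppw} required"
        )
    cfl = config.cfl_for(ndim)
    cfl_max = 1.0 / (STENCIL_L1 * np.sqrt(ndim))
    if cfl >= cfl_max:
        raise ValueError(f"CFL {cfl} exceeds the stability bound {cfl_max:.3f}")

    dt0 = stable_timestep(config, medium)
    period = 1.0 / config.frequency_hz
    spp = int(np.ceil(period / dt0))
    dt = period / spp
    n_steps = config.n_cycles * spp
    window = config.avg_cycles * spp
    if window > n_steps:
        raise ValueError("averaging window longer than the run")

    shape = medium.rho.shape
    c_max = float(np.max(medium.c))
    kap = medium.rho * medium.c**2
    att = medium.alpha_np(config.frequency_hz) * medium.c  # matched loss, 1/s
    bn = np.zeros(shape)
    if config.nonlinear:
        bn = (1.0 + 0.5 * config.b_over_a) / kap

    sig = [
        _pml_profiles(shape[ax], config.pml_cells, dx, dt, c_max)
        for ax in range(ndim)
    ]

    p = np.zeros(shape)
    if initial_pressure is not None:
        p[:] = initial_pressure
    split = [p.copy() / ndim for _ in range(ndim)] if ndim > 1 else []
    if ndim > 1:
        for s in split:
            s[:] = p / ndim
    vel = [np.zeros(shape) for _ in range(ndim)]
    rho_half = [_harmonic_half(medium.rho, ax) for ax in range(ndim)]

    msq = np.zeros(shape)
    peak = np.zeros(shape)
    rec = np.zeros((len(probes), n_steps)) if probes else None
    energies = [] if track_energy else None
    omega = 2.0 * np.pi * config.frequency_hz
    t_ramp = config.ramp_cycles * period

    probe_cells = [pr.cells for pr in probes]
    probe_w = [pr.weights / pr.weights.sum() for pr in probes]

    if ndim == 2:
        attxh = 0.5 * (att + np.roll(att, -1, axis=0))
        attzh = 0.5 * (att + np.roll(att, -1, axis=1))

    win_start = n_steps - window
    for n in range(n_steps):
        if ndim == 1:
            _kernels.step_1d(
                p, vel[0], rho_half[0], kap, att,
                0.5 * (att + np.roll(att, -1)), sig[0][0], sig[0][1], bn, dx, dt,
            )
        elif ndim == 2:
            _kernels.step_2d(
                p, split[0], split[1], vel[0], vel[1],
                rho_half[0], rho_half[1], kap, att, attxh, attzh,
                sig[0][0], sig[0][1], sig[1][0], sig[1][1], bn, dx, dt,
            )
        else:
            _kernels.step_3d(
                p, split[0], split[1], split[2], vel[0], vel[1], vel[2],
                rho_half[0], rho_half[1], rho_half[2], kap, att,
                sig[0][0], sig[0][1], sig[1][0], sig[1][1],
                sig[2][0], sig[2][1], bn, dx, dt,
            )

        t = (n + 1) * dt
        if sources:
            ramp = 1.0 if t >= t_ramp else 0.5 * (1.0 - np.cos(np.pi * t / t_ramp))
            for src in sources:
                s = src.amplitude * config.amplitude_pa * ramp * np.sin(
                    omega * t + src.phase
                )
                if ndim == 1:
                    p.ravel()[src.cells] += s * src.weights
                else:
                    contrib = (s / ndim) * src.weights
                    for comp in split:
                        comp.ravel()[src.cells] += contrib
                    p.ravel()[src.cells] += s * src.weights

        if rec is not None:
            for q, (cells, w) in enumerate(zip(probe_cells, probe_w)):
                rec[q, n] = float(np.dot(p.ravel()[cells], w))

        if n >= win_start:
            _kernels.accumulate_window(p, msq, peak)

        if energies is not None:
            e = np.sum(p * p / (2.0 * kap))
            for v, rh in zip(vel, rho_half):
                e += np.sum(0.5 * rh * v * v)
            energies.append(e * dx**ndim)

        if (n + 1) % 200 == 0 or n == n_steps - 1:
            m = float(np.abs(p).max())
            if not np.isfinite(m) or m > 1e12 * config.amplitude_pa:
                raise RuntimeError(
                    f"FDTD diverged at step {n + 1}/{n_steps} (max |p| = {m:g})"
                )

    msq /= window
    return SimulationResult(
        msq_pressure=msq,
        peak_pressure=peak,
        recordings=rec,
        dt=dt,
        n_steps=n_steps,
        config=config,
        energy=np.asarray(energies) if energies is not None else None,
    )


def heat_deposition(
    result: SimulationResult, medium: MediumField, frequency_hz: float | None = None
) -> np.ndarray:
    """Acoustic heat deposition Q = alpha * p_amp^2 / (rho c) in W/m^3.

    ``msq_pressure`` is a time average, so the squared amplitude of a
    monochromatic wave is 2 <p^2>; the factor is applied here once and the
    same convention feeds both the heating and focusing ratios (which are
    convention-invariant).
    """
    f = frequency_hz or result.config.frequency_hz
    alpha = medium.alpha_np(f)
    return 2.0 * alpha * result.msq_pressure / (medium.rho * medium.c)
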