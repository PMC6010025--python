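"""Linear diffraction references for free-field validation.

For the spherical-cap transducer the classical Rayleigh-type integral over
the radiating surface (O'Neil's approximation for a focused bowl) is
evaluated on an axisymmetric (r, z) half-plane around the focus; the
cap-with-hole field is the full-cap field minus the inner-cap field by
superposition, and the on-axis value has a closed form used as an
independent check.  A 2-D variant superposes line-source Green's functions
(Hankel H0) for cross-checking the 2-D FDTD solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import hankel1


@njit(cache=True, fastmath=True)
def _cap_field_kernel(r_obs, z_obs, R, th1, th2, k, n_theta, n_phi):
    """Rayleigh integral of a uniform spherical cap, focus at the origin.

    Cap of curvature radius R opening toward +z (apex at z = -R), polar
    angle th1..th2 measured from the axis.  Returns the complex field (up to
    a common constant) on the (r, z) observation grid, z relative to the
    focus.
    """
    nr = r_obs.shape[0]
    nz = z_obs.shape[0]
    out_re = np.zeros((nr, nz))
    out_im = np.zeros((nr, nz))
    dth = (th2 - th1) / n_theta
    dph = 2.0 * np.pi / n_phi
    for it in range(n_theta):
        th = th1 + (it + 0.5) * dth
        a_s = R * np.sin(th)
        z_s = -R * np.cos(th)
        w = R * R * np.sin(th) * dth * dph
        for ip in range(n_phi):
            ph = (ip + 0.5) * dph
            ac = a_s * np.cos(ph)
            for ir in range(nr):
                r = r_obs[ir]
                t1 = a_s * a_s + r * r - 2.0 * r * ac
                for iz in range(nz):
                    dz = z_obs[iz] - z_s
                    d = np.sqrt(t1 + dz * dz)
                    ph_k = k * d
                    out_re[ir, iz] += w * np.cos(ph_k) / d
                    out_im[ir, iz] += w * np.sin(ph_k) / d
    return out_re, out_im


def cap_field_rz(
    focal_distance_mm: float,
    aperture_mm: float,
    hole_mm: float,
    frequency_hz: float,
    sound_speed: float,
    r_mm: np.ndarray,
    z_mm: np.ndarray,
    n_theta: int = 256,
    n_phi: int = 96,
) -> np.ndarray:
    """Complex pressure (arbitrary units) on an (r, z) grid around the focus.

    ``hole_mm`` may be 0 for a full cap.  z is measured along the beam axis
    relative to the geometric focus.
    """
    R = focal_distance_mm * 1e-3
    th2 = np.arcsin((aperture_mm / 2.0) / focal_distance_mm)
    th1 = np.arcsin((hole_mm / 2.0) / focal_distance_mm) if hole_mm > 0 else 0.0
    if th1 >= th2:
        raise ValueError("hole must be smaller than the aperture")
    k = 2.0 * np.pi * frequency_hz / sound_speed
    re, im = _cap_field_kernel(
        np.asarray(r_mm, dtype=np.float64) * 1e-3,
        np.asarray(z_mm, dtype=np.float64) * 1e-3,
        R, th1, th2, k, n_theta, n_phi,
    )
    return re + 1j * im


def on_axis_cap_pressure(
    focal_distance_mm: float,
    aperture_mm: float,
    hole_mm: float,
    frequency_hz: float,
    sound_speed: float,
    z_mm: np.ndarray,
) -> np.ndarray:
    """Closed-form on-axis Rayleigh integral of the (annular) cap.

    With A the curvature radius and B = |z| the distance from the
    observation point to the centre of curvature, the surface integral of
    e^{ikd}/d collapses to (2 pi A / (i k B)) (e^{ik d2} - e^{ik d1}) where
    d1, d2 are the distances to the inner and outer rim circles; at the
    focus it degenerates to the cap area times e^{ikA}/A.  Units match
    :func:`cap_field_rz` (the common constant is omitted).
    """
    A = focal_distance_mm * 1e-3
    th2 = np.arcsin((aperture_mm / 2.0) / focal_distance_mm)
    th1 = np.arcsin((hole_mm / 2.0) / focal_distance_mm) if hole_mm > 0 else 0.0
    k = 2.0 * np.pi * frequency_hz / sound_speed
    z = np.atleast_1d(np.asarray(z_mm, dtype=np.float64)) * 1e-3
    out = np.empty(z.shape, dtype=complex)
    area = 2.0 * np.pi * A * A * (np.cos(th1) - np.cos(th2))
    for i, zi in enumerate(z):
        if abs(zi) < 1e-9:
            out[i] = area * np.exp(1j * k * A) / A
            continue
        # distance from (0,0,z) to the rim ring at polar angle th
        def dist(th):
            return np.sqrt(A * A + zi * zi + 2.0 * A * zi * np.cos(th))

        d1, d2 = dist(th1), dist(th2)
        out[i] = -(2.0 * np.pi * A / (1j * k * zi)) * (
            np.exp(1j * k * d2) - np.exp(1j * k * d1)
        )
    return out if np.ndim(z_mm) else out[0]


def line_source_field_2d(
    src_xy_mm: np.ndarray,
    weights: np.ndarray,
    obs_xy_mm: np.ndarray,
    frequency_hz: float,
    sound_speed: float,
) -> np.ndarray:
    """2-D free-field pressure from weighted monopole line sources.

    Superposition of (i/4) H0^(1)(k d) Green's functions; the independent
    reference for the 2-D FDTD arc source.
    """
    k = 2.0 * np.pi * frequency_hz / sound_speed
    src = np.asarray(src_xy_mm, dtype=float) * 1e-3
    obs = np.asarray(obs_xy_mm, dtype=float) * 1e-3
    out = np.zeros(obs.shape[0], dtype=complex)
    chunk = 200
    for i0 in range(0, src.shape[0], chunk):
        s = src[i0 : i0 + chunk]
        w = np.asarray(weights[i0 : i0 + chunk], dtype=float)
        d = np.sqrt(((obs[:, None, :] - s[None, :, :]) ** 2).sum(-1))
        d = np.maximum(d, 1e-9)
        out += (0.25j * hankel1(0, k * d) * w[None, :]).sum(axis=1)
    return out


def annular_sphere_ratio(
    values_rz: np.ndarray,
    r_mm: np.ndarray,
    z_mm: np.ndarray,
    r_small_mm: float = 2.5,
    r_big_mm: float = 10.0,
) -> float:
    """Sphere-integral ratio of an axisymmetric non-negative field.

    Rotates the (r, z) half-plane field to 3-D with annular volume weights
    2 pi r dr dz (cell-centred membership) and takes the ratio of the
    integrals over the small and large spheres about the focus.
    """
    r = np.asarray(r_mm, dtype=float)
    z = np.asarray(z_mm, dtype=float)
    dr = float(r[1] - r[0])
    dz = float(z[1] - z[0])
    w = 2.0 * np.pi * r * dr * dz  # annulus volume per (r, z) cell
    rr = np.sqrt(r[:, None] ** 2 + z[None, :] ** 2)
    v = np.asarray(values_rz, dtype=float) * w[:, None]
    num = float(v[rr <= r_small_mm].sum())
    den = float(v[rr <= r_big_mm].sum())
    if den == 0:
        raise ValueError("empty field: sphere integral denominator is zero")
    return num / den


def focal_sphere_ratio(
    field_rz: np.ndarray,
    r_mm: np.ndarray,
    z_mm: np.ndarray,
    r_small_mm: float = 2.5,
    r_big_mm: float = 10.0,
) -> float:
    """Sphere-integral ratio of |p|^2 around the focus from a complex (r, z) field.

    The focusing ratio of a uniform medium, where the rho*c factor cancels.
    """
    return annular_sphere_ratio(
        np.abs(field_rz) ** 2, r_mm, z_mm, r_small_mm, r_big_mm
    )
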