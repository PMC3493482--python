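"""Spectral time integration of the coupled gradient-descent dynamics.

    dz/dt = L_op z - |z|^2 z - dU/dconj(z)
    do/dt = L_od o - o^3 + gamma - dU/do,      L = r - (kc^2 + Lap)^2.

The diagonal linear operator is treated exactly in Fourier space
(exponential time differencing, first order: u_{n+1} = e^{L dt} u_n +
dt phi1(L dt) N(u_n)); the nonlinear terms are evaluated pseudo-spectrally
with dealiasing.  Because the dynamics is a gradient descent, the total
energy must be non-increasing along trajectories; an energy watchdog aborts
with a diagnostic when the time step is too large to respect this.

``freeze_od`` integrates the OP equation against a frozen OD field, the
effectively unidirectional limit in which the backreaction of the weak OP
modes on the OD map is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import ModelParams, coupling_gradients, dealiased_product, total_energy

__all__ = ["sh_spectrum", "Trajectory", "integrate", "relax_to_attractor",
           "noise_fields", "EnergyIncreaseError"]


class EnergyIncreaseError(RuntimeError):
    """The energy rose beyond tolerance: the time step is too large."""


def sh_spectrum(k, r: float, kc: float):
    """Growth rate of a Fourier mode: lambda(k) = r - (kc^2 - k^2)^2.

    Maximal (= r) on the critical circle k = kc; for r < 0 every mode is
    damped and only the homogeneous state is stable.
    """
    k = np.asarray(k, float)
    return r - (kc ** 2 - k ** 2) ** 2


@dataclass
class Trajectory:
    t: float
    z: np.ndarray
    o: np.ndarray
    grid: object
    energies: pd.DataFrame
    snapshots: list = field(default_factory=list)
    converged: bool = False
    residual: float = np.nan


def _lin_factors(grid, r, kc, dt):
    kx = 2.0 * np.pi * np.fft.fftfreq(grid.nx, d=grid.Lx / grid.nx)
    ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, d=grid.Ly / grid.ny)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    lam = sh_spectrum(np.sqrt(KX ** 2 + KY ** 2), r, kc)
    x = lam * dt
    E = np.exp(x)
    phi1 = np.where(np.abs(x) > 1e-8, (E - 1.0) / np.where(x == 0, 1.0, x),
                    1.0 + x / 2.0)
    return E, dt * phi1


def _nonlinear(z, o, params, grid, freeze_od):
    Nz = -dealiased_product((z, np.conj(z), z), grid, 1.5)
    No = None if freeze_od else -dealiased_product((o, o, o), grid, 1.5).real \
        + params.gamma
    if params.c != 0.0:
        tz, to = coupling_gradients(z, o, grid, params.coupling_kind, params.c)
        Nz = Nz + tz
        if not freeze_od:
            No = No + to
    return Nz, No


def integrate(z0, o0, params: ModelParams, grid, T: float, dt: float,
              freeze_od: bool = False, snapshot_every: float | None = None,
              energy_every: int = 10, energy_tol: float = 1e-6) -> Trajectory:
    """Advance the coupled dynamics for a time T with fixed step dt.

    Raises on NaN/blow-up and (via the energy watchdog) when the energy
    rises by more than ``energy_tol * max(1, |E|)`` between checks.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = np.asarray(z0, complex).copy()
    o = np.asarray(o0, float).copy()
    Ez, Pz = _lin_factors(grid, params.r_op, params.kc, dt)
    Eo, Po = _lin_factors(grid, params.r_od, params.kc, dt)
    nsteps = int(np.ceil(T / dt))
    erows, snaps = [], []
    e_prev = None
    t = 0.0
    e0 = total_energy(z, o, params, grid)
    erows.append({"t": 0.0, **e0})
    e_prev = e0["E_total"]
    next_snap = 0.0 if snapshot_every else np.inf
    for n in range(nsteps):
        if snapshot_every and t >= next_snap - 1e-12:
            snaps.append((t, z.copy(), o.copy()))
            next_snap += snapshot_every
        Nz, No = _nonlinear(z, o, params, grid, freeze_od)
        z = np.fft.ifft2(Ez * np.fft.fft2(z) + Pz * np.fft.fft2(Nz))
        if not freeze_od:
            o = np.fft.ifft2(Eo * np.fft.fft2(o) + Po * np.fft.fft2(No)).real
        t += dt
        if not (np.isfinite(z).all() and np.isfinite(o).all()):
            raise RuntimeError(
                f"field blow-up at t={t:.4g} (dt={dt}); reduce dt"
            )
        if (n + 1) % energy_every == 0 or n == nsteps - 1:
            e = total_energy(z, o, params, grid)
            erows.append({"t": t, **e})
            if e["E_total"] > e_prev + energy_tol * max(1.0, abs(e_prev)):
                raise EnergyIncreaseError(
                    f"energy rose from {e_prev:.6g} to {e['E_total']:.6g} "
                    f"at t={t:.4g}; dt={dt} is too large"
                )
            e_prev = e["E_total"]
    return Trajectory(t=t, z=z, o=o, grid=grid,
                      energies=pd.DataFrame(erows), snapshots=snaps)


def relax_to_attractor(z0, o0, params: ModelParams, grid, tol: float = 1e-7,
                       dt: float = 0.25, t_max: float = 5000.0,
                       check_interval: float = 25.0,
                       freeze_od: bool = False) -> Trajectory:
    """Integrate until the relative field change per unit time drops below tol.

    Non-convergence within ``t_max`` is reported through
    ``Trajectory.converged`` / ``residual``, not raised.
    """
    z = np.asarray(z0, complex).copy()
    o = np.asarray(o0, float).copy()
    t = 0.0
    erows = []
    converged, res = False, np.inf
    while t < t_max:
        tr = integrate(z, o, params, grid, check_interval, dt,
                       freeze_od=freeze_od)
        dz = np.linalg.norm(tr.z - z) / (np.linalg.norm(tr.z) + 1e-30)
        do = np.linalg.norm(tr.o - o) / (np.linalg.norm(tr.o) + 1e-30)
        res = (dz + do) / check_interval
        z, o = tr.z, tr.o
        e = tr.energies.copy()
        e["t"] += t
        erows.append(e)
        t += tr.t
        if res < tol:
            converged = True
            break
    energies = pd.concat(erows, ignore_index=True) if erows else pd.DataFrame()
    return Trajectory(t=t, z=z, o=o, grid=grid, energies=energies,
                      converged=converged, residual=res)


def noise_fields(grid, amplitude: float = 1e-3, seed: int = 0):
    """Zero-mean white-noise initial conditions (z complex, o real)."""
    rng = np.random.default_rng(seed)
    z = amplitude * (rng.standard_normal((grid.nx, grid.ny))
                     + 1j * rng.standard_normal((grid.nx, grid.ny)))
    o = amplitude * rng.standard_normal((grid.nx, grid.ny))
    z -= z.mean()
    o -= o.mean()
    return z, o
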