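"""Energy functionals of the coupled map dynamics.

The single-field part is of Swift-Hohenberg type for both the complex
orientation-preference field z and the real ocular-dominance field o,

    E_op = Int [ -conj(z) L z + |z|^4 / 2 ]
    E_od = Int [ -o L o / 2 + o^4 / 4 - gamma o ],       L = r - (kc^2 + Lap)^2,

so that dz/dt = -dE/dconj(z) and do/dt = -dE/do reproduce the gradient
descent.  The two maps interact through a positive-definite coupling energy;
the two lowest-order densities compatible with translation, rotation,
orientation-shift and eye-inversion symmetry are

    product_low :  c * o^2 |z|^2
    gradient_low:  c * |grad o . grad z|^2 ,

and their next higher order relatives (o^4 |z|^4 and |grad o . grad z|^4)
are supported at field level for simulation.  Energies are reported as mean
densities (per unit area), which makes values comparable across domain
sizes.

Derivatives are evaluated spectrally (exact for the band-limited planforms
used throughout); real-space products inside the functional derivatives are
formed on a padded grid (3/2 rule for cubic terms, 2x padding for the
higher-order couplings) to avoid aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import od_subsystem

__all__ = [
    "ModelParams", "sh_energy", "coupling_energy", "coupling_gradients",
    "total_energy", "COUPLING_KINDS",
]

COUPLING_KINDS = ("product_low", "gradient_low", "product_high", "gradient_high")


@dataclass
class ModelParams:
    """Control parameters of the coupled model.

    The bias can be given either directly as ``gamma`` or through the
    rescaled bias ``eta`` (see :mod:`corticalmaps.od_subsystem`); exactly one
    should be provided, the other is derived.  ``kc`` is the critical
    wavenumber; fields synthesized on the default grids use Lambda = 1, i.e.
    kc = 2 pi, while amplitude-level studies conventionally use kc = 1.
    """

    r_op: float = 0.1
    r_od: float = 0.2
    coupling_kind: str = "product_low"
    c: float = 0.0
    gamma: float | None = None
    eta: float | None = None
    kc: float = 2.0 * np.pi

    def __post_init__(self):
        if self.coupling_kind not in COUPLING_KINDS:
            raise ValueError(f"unknown coupling kind {self.coupling_kind!r}")
        if self.c < 0:
            raise ValueError("coupling constants are assumed non-negative")
        if self.gamma is None and self.eta is None:
            self.gamma = 0.0
        if self.gamma is None:
            self.gamma = od_subsystem.gamma_for_eta(self.eta, self.r_od, self.kc)
        if self.eta is None:
            self.eta = od_subsystem.rescaled_bias(self.gamma, self.r_od, self.kc)

    @property
    def delta(self) -> float:
        """Constant OD shift induced by the bias."""
        return od_subsystem.shift_delta(self.gamma, self.r_od, self.kc)[0]

    def od_branch(self, label: str) -> od_subsystem.ODBranch:
        return od_subsystem.stationary_branch(label, self.gamma, self.r_od, self.kc)

    @property
    def rescaled_coupling(self) -> float:
        """Coupling strength in the units used by the phase diagrams.

        product-type: c r_od / (3 r_op), so the bias-independent suppression
        border sits at 1; gradient-type: c kc^4 B_hex^2 / r_op, the
        OD-hexagon-amplitude rescaling that removes the bias dependence.
        """
        if self.coupling_kind.startswith("product"):
            return self.c * self.r_od / (3.0 * self.r_op)
        hexa = self.od_branch("hexagons")
        if not hexa.exists:
            raise ValueError("gradient rescaling needs an existing hexagon branch")
        return self.c * self.kc ** 4 * hexa.amplitude ** 2 / self.r_op


# ---------------------------------------------------------------------------
# spectral helpers (duck-typed grid: needs nx, ny, Lx, Ly)
# ---------------------------------------------------------------------------

def _kgrids(grid):
    kx = 2.0 * np.pi * np.fft.fftfreq(grid.nx, d=grid.Lx / grid.nx)
    ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, d=grid.Ly / grid.ny)
    return np.meshgrid(kx, ky, indexing="ij")


def apply_sh_operator(f, grid, r, kc):
    """L f = (r - (kc^2 - k^2)^2) f, evaluated spectrally."""
    KX, KY = _kgrids(grid)
    k2 = KX ** 2 + KY ** 2
    lam = r - (kc ** 2 - k2) ** 2
    return np.fft.ifft2(lam * np.fft.fft2(f))


def spectral_gradient(f, grid):
    KX, KY = _kgrids(grid)
    F = np.fft.fft2(f)
    return np.fft.ifft2(1j * KX * F), np.fft.ifft2(1j * KY * F)


def spectral_divergence(fx, fy, grid):
    KX, KY = _kgrids(grid)
    return np.fft.ifft2(1j * KX * np.fft.fft2(fx) + 1j * KY * np.fft.fft2(fy))


def _pad_spectrum(F, mx, my):
    nx, ny = F.shape
    G = np.zeros((mx, my), complex)
    hx, hy = nx // 2, ny // 2
    sx = np.r_[0:hx, mx - (nx - hx):mx]
    sy = np.r_[0:hy, my - (ny - hy):my]
    G[np.ix_(sx, sy)] = F
    return G


def _truncate_spectrum(G, nx, ny):
    mx, my = G.shape
    hx, hy = nx // 2, ny // 2
    sx = np.r_[0:hx, mx - (nx - hx):mx]
    sy = np.r_[0:hy, my - (ny - hy):my]
    return G[np.ix_(sx, sy)]


def dealiased_product(fields, grid, factor=1.5):
    """Pointwise product of fields computed on a padded grid (no aliasing)."""
    nx, ny = grid.nx, grid.ny
    mx = int(np.ceil(factor * nx / 2)) * 2
    my = int(np.ceil(factor * ny / 2)) * 2
    scale = (mx * my) / (nx * ny)
    padded = [np.fft.ifft2(_pad_spectrum(np.fft.fft2(f), mx, my)) * scale
              for f in fields]
    prod = padded[0]
    for p in padded[1:]:
        prod = prod * p
    return np.fft.ifft2(_truncate_spectrum(np.fft.fft2(prod), nx, ny)) / scale


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _as_field(obj):
    if hasattr(obj, "z"):
        return obj.z, obj.grid
    if hasattr(obj, "o"):
        return obj.o, obj.grid
    return np.asarray(obj), None


def sh_energy(field, r, grid=None, kc=None, gamma: float = 0.0) -> float:
    """Swift-Hohenberg energy density of a single field.

    Complex input uses the OP form, real input the OD form (with the bias
    term -gamma Int o).  ``field`` may be an OPMap / ODMap (grid taken from
    it) or a plain array with ``grid`` given explicitly.
    """
    f, g = _as_field(field)
    grid = grid or g
    kc = kc if kc is not None else grid.kc
    Lf = apply_sh_operator(f, grid, r, kc)
    if np.iscomplexobj(f):
        dens = -np.conj(f) * Lf + 0.5 * np.abs(f) ** 4
        return float(np.mean(dens.real))
    dens = -0.5 * f * Lf.real + 0.25 * f ** 4 - gamma * f
    return float(np.mean(dens))


def _grad_dot(z, o, grid):
    ox, oy = spectral_gradient(o, grid)
    zx, zy = spectral_gradient(z, grid)
    return ox.real * zx + oy.real * zy


def coupling_energy(z, o, grid, kind: str, c: float) -> float:
    """Positive-definite inter-map coupling energy density."""
    if kind == "product_low":
        dens = c * o ** 2 * np.abs(z) ** 2
    elif kind == "gradient_low":
        dens = c * np.abs(_grad_dot(z, o, grid)) ** 2
    elif kind == "product_high":
        dens = c * o ** 4 * np.abs(z) ** 4
    elif kind == "gradient_high":
        dens = c * np.abs(_grad_dot(z, o, grid)) ** 4
    else:
        raise ValueError(f"unknown coupling kind {kind!r}")
    return float(np.mean(dens))


def coupling_gradients(z, o, grid, kind: str, c: float):
    """Interaction terms of the dynamics: (-dU/dconj(z), -dU/do).

    Consistent with :func:`coupling_energy` through the gradient-descent
    identity; products are dealiased (3/2 rule, 2x for the high-order kinds).
    """
    pad = 2.0 if kind.endswith("high") else 1.5
    P = lambda *fs: dealiased_product(fs, grid, pad)
    if kind == "product_low":
        term_z = -c * P(o, o, z)
        term_o = -2.0 * c * P(o, z, np.conj(z)).real
        return term_z, term_o
    if kind == "product_high":
        term_z = -2.0 * c * P(o, o, o, o, z, z, np.conj(z))
        term_o = -4.0 * c * P(o, o, o, z, np.conj(z), z, np.conj(z)).real
        return term_z, term_o
    ox, oy = spectral_gradient(o, grid)
    ox, oy = ox.real, oy.real
    zx, zy = spectral_gradient(z, grid)
    if kind == "gradient_low":
        s = P(ox, zx) + P(oy, zy)               # grad o . grad z
        term_z = c * spectral_divergence(P(s, ox), P(s, oy), grid)
        fx = P(np.conj(s), zx) + P(s, np.conj(zx))
        fy = P(np.conj(s), zy) + P(s, np.conj(zy))
        term_o = c * spectral_divergence(fx, fy, grid).real
        return term_z, term_o
    if kind == "gradient_high":
        s = P(ox, zx) + P(oy, zy)
        s2 = P(s, np.conj(s)).real              # |s|^2
        term_z = 2.0 * c * spectral_divergence(P(s2, s, ox), P(s2, s, oy), grid)
        fx = P(s2, np.conj(s), zx) + P(s2, s, np.conj(zx))
        fy = P(s2, np.conj(s), zy) + P(s2, s, np.conj(zy))
        term_o = 2.0 * c * spectral_divergence(fx, fy, grid).real
        return term_z, term_o
    raise ValueError(f"unknown coupling kind {kind!r}")


def total_energy(z, o, params: ModelParams, grid) -> dict:
    """Energy decomposition: OP part, OD part, coupling, and their sum."""
    e_op = sh_energy(z, params.r_op, grid, params.kc)
    e_od = sh_energy(o, params.r_od, grid, params.kc, gamma=params.gamma)
    e_c = coupling_energy(z, o, grid, params.coupling_kind, params.c)
    return {"E_op": e_op, "E_od": e_od, "E_coupling": e_c,
            "E_total": e_op + e_od + e_c}
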