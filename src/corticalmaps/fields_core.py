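"""Grids, the two field types, planform synthesis and fixture solutions.

The periodic rectangular domain is chosen commensurate with the hexagonal
triad: with k1 = kc (1, 0) the domain lengths are Lx = n_cells_x * Lambda
and Ly = n_cells_y * 2 Lambda / sqrt(3), and every triad wavevector must
fall exactly on a discrete Fourier mode (this requires n_cells_x to be
even; a 2 x 1 cell grid covers exactly two hexagonal-lattice unit cells by
area).  Exact commensurability makes planform synthesis and mode projection
mutually inverse to round-off, which the amplitude-level tests rely on.

The orientation-preference map is a complex field z with preferred
orientation theta = arg(z)/2 in [0, pi) and selectivity |z|; the
ocular-dominance map is a real field o, positive for contralateral and
negative for ipsilateral eye dominance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import od_subsystem, op_amplitudes
from ._modes import TRIAD, triad_vector
from .energetics import ModelParams

__all__ = [
    "CommensurabilityError", "GridSpec", "OPMap", "ODMap",
    "PlanformAmplitudes", "make_grid", "rect_grid", "synthesize_planform",
    "project_planform", "apply_orientation_shift", "fixture",
    "save_fields", "load_fields", "FIXTURE_LABELS",
]

FIXTURE_LABELS = ("op_stripes", "op_rhombic", "op_scotoma", "hpwc_ipsi",
                  "hpwc_braitenberg", "od_stripes", "od_hexagons",
                  "od_constant")


class CommensurabilityError(ValueError):
    """A requested wavevector is not an exact Fourier mode of the grid."""


@dataclass(frozen=True)
class GridSpec:
    """Periodic rectangular grid in physical units of the wavelength Lambda."""

    nx: int
    ny: int
    Lx: float
    Ly: float
    lam: float = 1.0
    n_cells_x: int | None = None
    n_cells_y: int | None = None

    @property
    def kc(self) -> float:
        return 2.0 * np.pi / self.lam

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dy(self) -> float:
        return self.Ly / self.ny

    @property
    def cell_area(self) -> float:
        """Area of one hexagonal-lattice unit cell, 2 Lambda^2 / sqrt(3)."""
        return 2.0 * self.lam ** 2 / np.sqrt(3.0)

    @property
    def n_unit_cells(self) -> float:
        return self.Lx * self.Ly / self.cell_area

    def meshes(self):
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dy
        return np.meshgrid(x, y, indexing="ij")

    def triad_k(self, j: int) -> np.ndarray:
        """Physical wavevector of triad member j (0-based)."""
        return triad_vector(TRIAD[j], self.kc)

    def mode_indices(self, kvec) -> tuple[int, int]:
        """Integer Fourier indices of a wavevector; raises if off-grid."""
        mx = kvec[0] * self.Lx / (2.0 * np.pi)
        my = kvec[1] * self.Ly / (2.0 * np.pi)
        if abs(mx - round(mx)) > 1e-9 or abs(my - round(my)) > 1e-9:
            raise CommensurabilityError(
                f"wavevector {tuple(kvec)} is not a Fourier mode of the "
                f"{self.Lx:.4g} x {self.Ly:.4g} domain "
                f"(indices {mx:.4f}, {my:.4f})"
            )
        return int(round(mx)) % self.nx, int(round(my)) % self.ny


def make_grid(nx: int, ny: int, n_cells_x: int, n_cells_y: int,
              lam: float = 1.0) -> GridSpec:
    """Hexagonally commensurate grid: Lx = n_cells_x Lambda, Ly = n_cells_y 2 Lambda/sqrt(3)."""
    if nx < 32 or ny < 32:
        raise ValueError("grid needs at least 32 pixels per side")
    if n_cells_x < 1 or n_cells_y < 1:
        raise ValueError("need at least one cell in each direction")
    g = GridSpec(nx, ny, n_cells_x * lam, n_cells_y * 2.0 * lam / np.sqrt(3.0),
                 lam, n_cells_x, n_cells_y)
    for j in range(3):
        g.mode_indices(g.triad_k(j))   # raises CommensurabilityError if off
    return g


def rect_grid(nx: int, ny: int, Lx: float, Ly: float,
              lam: float = 1.0) -> GridSpec:
    """Plain periodic rectangle (no hexagonal commensurability enforced)."""
    return GridSpec(nx, ny, Lx, Ly, lam)


@dataclass
class OPMap:
    """Orientation-preference map: complex order parameter on a grid."""

    z: np.ndarray
    grid: GridSpec

    @property
    def theta(self) -> np.ndarray:
        """Preferred orientation, arg(z)/2 folded into [0, pi)."""
        return np.mod(np.angle(self.z) / 2.0, np.pi)

    @property
    def selectivity(self) -> np.ndarray:
        return np.abs(self.z)

    @classmethod
    def from_theta_selectivity(cls, theta, selectivity, grid) -> "OPMap":
        return cls(selectivity * np.exp(2j * theta), grid)


@dataclass
class ODMap:
    """Ocular-dominance map: o > 0 contralateral, o < 0 ipsilateral."""

    o: np.ndarray
    grid: GridSpec
    gamma: float = 0.0
    delta: float = 0.0


@dataclass
class PlanformAmplitudes:
    """Active triad modes and their complex amplitudes.

    OP modes: A_j on +k_j and A_opp_j on -k_j; OD modes: B_j on the triad
    (resonant, k1 + k2 + k3 = 0) plus the constant shift delta.  ``angle``
    rotates the whole mode frame (used for stripe solutions that do not run
    along k1); ``psi`` and ``theta_rhomb`` are bookkeeping for the uniform
    and rhombic families.
    """

    A: np.ndarray = field(default_factory=lambda: np.zeros(3, complex))
    A_opp: np.ndarray = field(default_factory=lambda: np.zeros(3, complex))
    B: np.ndarray = field(default_factory=lambda: np.zeros(3, complex))
    delta: float = 0.0
    psi: float | None = None
    theta_rhomb: float | None = None
    angle: float = 0.0

    def op_modes(self, kc: float):
        """Yield (wavevector, amplitude) for every nonzero OP mode."""
        rot = _rotation(self.angle)
        for j in range(3):
            k = rot @ triad_vector(TRIAD[j], kc)
            if self.A[j] != 0.0:
                yield k, self.A[j]
            if self.A_opp[j] != 0.0:
                yield -k, self.A_opp[j]

    def od_modes(self, kc: float):
        rot = _rotation(self.angle)
        for j in range(3):
            if self.B[j] != 0.0:
                yield rot @ triad_vector(TRIAD[j], kc), self.B[j]


def _rotation(angle):
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def synthesize_planform(grid: GridSpec, amps: PlanformAmplitudes
                        ) -> tuple[OPMap, ODMap]:
    """Exact synthesis of (z, o) from planform amplitudes.

    z = sum_j A_j e^{i k_j x} + A_opp_j e^{-i k_j x};
    o = delta + sum_j B_j e^{i k_j x} + c.c.
    Every active wavevector must be an exact grid mode.
    """
    X, Y = grid.meshes()
    z = np.zeros((grid.nx, grid.ny), complex)
    for k, a in amps.op_modes(grid.kc):
        grid.mode_indices(k)
        z += a * np.exp(1j * (k[0] * X + k[1] * Y))
    o = np.full((grid.nx, grid.ny), float(amps.delta))
    for k, b in amps.od_modes(grid.kc):
        grid.mode_indices(k)
        o += 2.0 * np.real(b * np.exp(1j * (k[0] * X + k[1] * Y)))
    return OPMap(z, grid), ODMap(o, grid, delta=amps.delta)


def project_planform(opmap: OPMap, odmap: ODMap | None = None,
                     angle: float = 0.0) -> PlanformAmplitudes:
    """Recover planform amplitudes by Fourier projection (synthesis inverse)."""
    grid = opmap.grid
    rot = _rotation(angle)
    Z = np.fft.fft2(opmap.z) / (grid.nx * grid.ny)
    out = PlanformAmplitudes(angle=angle)
    for j in range(3):
        k = rot @ triad_vector(TRIAD[j], grid.kc)
        ix, iy = grid.mode_indices(k)
        out.A[j] = Z[ix, iy]
        ix, iy = grid.mode_indices(-k)
        out.A_opp[j] = Z[ix, iy]
    if odmap is not None:
        O = np.fft.fft2(odmap.o) / (grid.nx * grid.ny)
        out.delta = float(O[0, 0].real)
        for j in range(3):
            k = rot @ triad_vector(TRIAD[j], grid.kc)
            ix, iy = grid.mode_indices(k)
            out.B[j] = O[ix, iy]
    return out


def apply_orientation_shift(opmap: OPMap, phi: float) -> OPMap:
    """Shift all preferred orientations by phi/2: z -> e^{i phi} z."""
    return OPMap(np.exp(1j * phi) * opmap.z, opmap.grid)


# ---------------------------------------------------------------------------
# fixtures: every named closed-form solution, synthesized on a grid
# ---------------------------------------------------------------------------

_OD_FOR_OP = {"op_scotoma": "stripes", "hpwc_ipsi": "hexagons",
              "hpwc_braitenberg": "hexagons"}


def _stable_od_label(params: ModelParams) -> str:
    for lab in ("hexagons", "stripes", "constant"):
        br = params.od_branch(lab)
        if br.exists and br.stable:
            return lab
    return "stripes"


def fixture(label: str, grid: GridSpec, params: ModelParams,
            theta_rhomb: float = np.pi / 3.0) -> tuple[OPMap, ODMap]:
    """Synthesize a named closed-form solution at the given parameter point.

    OP labels use the stationary amplitudes from
    :mod:`corticalmaps.op_amplitudes` together with the matching OD branch
    (product-type scotoma requires OD stripes, the two hexagonal pinwheel
    crystals require OD hexagons; plain stripes/rhombs use the stable OD
    branch at the given bias).  Requests outside a family's existence range
    raise with the name of the violated border.
    """
    if label not in FIXTURE_LABELS:
        raise ValueError(f"unknown fixture label {label!r}")
    if abs(params.kc - grid.kc) > 1e-9:
        raise ValueError(
            f"params.kc={params.kc:.6g} does not match grid.kc={grid.kc:.6g}"
        )

    if label.startswith("od_"):
        od = params.od_branch(label[3:])
        if not od.exists:
            raise ValueError(
                f"OD branch {label[3:]!r} does not exist at eta={od.eta:.3f} "
                f"(existence requires eta < {np.sqrt(5.0/4.0):.3f} for "
                "hexagons, r_tilde > 0 for stripes)"
            )
        amps = PlanformAmplitudes(B=od.B.copy(), delta=od.delta)
        return synthesize_planform(grid, amps)

    if label == "hpwc_ipsi" and params.coupling_kind != "product_low":
        raise ValueError("the ipsi-center crystal is the product-type family")
    if label == "hpwc_braitenberg" and params.coupling_kind != "gradient_low":
        raise ValueError("the Braitenberg crystal is the gradient-type family")

    od_label = _OD_FOR_OP.get(label) or _stable_od_label(params)
    od = params.od_branch(od_label)
    if not od.exists:
        raise ValueError(f"required OD branch {od_label!r} does not exist "
                         f"at eta={od.eta:.3f}")
    sol = op_amplitudes.stationary_branch(label, params, od,
                                          theta_rhomb=theta_rhomb)
    if not sol.exists:
        borders = op_amplitudes.existence_borders(
            params.coupling_kind, od_label, params)
        raise ValueError(
            f"{label} does not exist at c={params.c:.4g}; violated existence "
            f"border(s): {borders}"
        )
    amps = PlanformAmplitudes(A=sol.state.C[:3].copy(),
                              A_opp=sol.state.C[3:].copy(),
                              B=od.B.copy(), delta=od.delta,
                              psi=sol.psi, angle=sol.angle,
                              theta_rhomb=theta_rhomb if label == "op_rhombic"
                              else None)
    return synthesize_planform(grid, amps)


# ---------------------------------------------------------------------------
# HDF5 snapshots
# ---------------------------------------------------------------------------

def save_fields(path, opmap: OPMap, odmap: ODMap,
                params: ModelParams | None = None) -> None:
    grid = opmap.grid
    with h5py.File(path, "w") as f:
        f.create_dataset("op/real", data=opmap.z.real)
        f.create_dataset("op/imag", data=opmap.z.imag)
        f.create_dataset("od/values", data=odmap.o)
        f.attrs["nx"], f.attrs["ny"] = grid.nx, grid.ny
        f.attrs["Lx"], f.attrs["Ly"] = grid.Lx, grid.Ly
        f.attrs["kc"], f.attrs["lam"] = grid.kc, grid.lam
        f.attrs["gamma"] = odmap.gamma
        if params is not None:
            f.attrs["params"] = json.dumps({
                "r_op": params.r_op, "r_od": params.r_od,
                "coupling_kind": params.coupling_kind, "c": params.c,
                "gamma": params.gamma, "kc": params.kc})


def load_fields(path):
    """Read a snapshot; returns (OPMap, ODMap, params-or-None)."""
    with h5py.File(path, "r") as f:
        z = f["op/real"][...] + 1j * f["op/imag"][...]
        o = f["od/values"][...]
        grid = GridSpec(int(f.attrs["nx"]), int(f.attrs["ny"]),
                        float(f.attrs["Lx"]), float(f.attrs["Ly"]),
                        float(f.attrs["lam"]))
        gamma = float(f.attrs.get("gamma", 0.0))
        params = None
        if "params" in f.attrs:
            params = ModelParams(**json.loads(f.attrs["params"]))
    return OPMap(z, grid), ODMap(o, grid, gamma=gamma), params
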