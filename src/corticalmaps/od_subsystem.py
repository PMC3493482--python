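"""Ocular-dominance subsystem: the transition from OD stripes to OD blobs.

The OD map obeys a Swift-Hohenberg equation with a constant bias gamma that
favors the contralateral eye,

    do/dt = (r_od - (kc^2 + Lap)^2) o - o^3 + gamma .

Shifting the field by the constant delta that removes the constant term maps
this to a Swift-Hohenberg equation with a quadratic interaction term
-3*delta*o~^2 and a shifted control parameter r~ = r_od - 3 delta^2.  Near
threshold, a triad of modes k1 + k2 + k3 = 0 then obeys the amplitude
equations

    dB1/dt = r~ B1 - 6 delta conj(B2 B3)
             - 3 |B1|^2 B1 - 6 (|B2|^2 + |B3|^2) B1      (+ cyclic),

whose stationary solutions are stripes, hexagons (ipsilateral blobs in a sea
of contralateral dominance) and a spatially constant (monocular) state.  The
quadratic triad term makes the hexagon phase sum lock at pi for delta > 0.

All stability borders are expressed through the rescaled bias

    eta = |delta| * sqrt(3 / r_od),

which is the bias measured in units of the value at which the constant
solution becomes stable (eta = 1).  Closed-form borders, in delta^2 / r_od:
hexagons appear at 1/51, stripes destabilize at 1/15, the constant state
stabilizes at 1/3 and hexagons disappear (saddle-node) at 5/12.  A numerical
Jacobian / fold-finding oracle for the same borders is provided for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from ._modes import TRIAD, triad_vector

__all__ = [
    "ODBranch", "shift_delta", "delta_small_bias", "gamma_from_delta",
    "rescaled_bias", "gamma_for_eta", "od_amplitude_rhs", "stationary_branch",
    "od_stability_borders", "od_borders_numeric", "contra_fraction",
    "pixel_contra_fraction", "od_jacobian_eigenvalues", "hex_cell_area",
]

#: delta^2 / r_od at the four stability borders (closed forms)
_BORDER_FRACTIONS = {
    "hexagon_onset": 1.0 / 51.0,
    "stripe_loss": 1.0 / 15.0,
    "constant_onset": 1.0 / 3.0,
    "hexagon_loss": 5.0 / 12.0,
}


@dataclass
class ODBranch:
    """A stationary OD solution branch at one parameter point."""

    label: str                       # 'stripes' | 'hexagons' | 'constant'
    gamma: float
    r_od: float
    kc: float
    delta: float                     # constant shift / spatial average
    amplitude: float                 # B_st or B_hex (0 for constant)
    B: np.ndarray = field(default=None)  # complex triad amplitudes (3,)
    exists: bool = True
    stable: bool = True

    @property
    def r_tilde(self) -> float:
        return self.r_od - 3.0 * self.delta ** 2

    @property
    def eta(self) -> float:
        return rescaled_bias(self.gamma, self.r_od, self.kc)


def gamma_from_delta(delta: float, r_od: float, kc: float = 1.0) -> float:
    """Bias gamma producing a given constant shift delta (exact inverse)."""
    return (kc ** 4 - r_od) * delta + delta ** 3


def shift_delta(gamma: float, r_od: float, kc: float = 1.0):
    """Constant shift delta that removes the constant term of the dynamics.

    Solves delta^3 + (kc^4 - r_od) delta = gamma.  For r_od < kc^4 the cubic
    is strictly monotone and has a unique real root.  Returns
    ``(delta, r_tilde, quad_coeff)`` where ``r_tilde = r_od - 3 delta^2`` is
    the shifted control parameter and ``quad_coeff = -3 delta`` the
    coefficient of the quadratic term of the shifted dynamics.
    """
    if r_od >= kc ** 4:
        raise ValueError(
            f"no unique admissible shift: r_od={r_od} >= kc^4={kc**4}"
        )
    roots = np.roots([1.0, 0.0, kc ** 4 - r_od, -gamma])
    real = roots[np.abs(roots.imag) < 1e-12 * max(1.0, np.abs(roots).max())].real
    if real.size == 0:
        raise ValueError("no real root for the bias shift")
    delta = float(real[np.argmin(np.abs(real - gamma / (kc ** 4 - r_od)))])
    return delta, r_od - 3.0 * delta ** 2, -3.0 * delta


def delta_small_bias(gamma: float, r_od: float, kc: float = 1.0) -> float:
    """Small-bias expansion of the shift: gamma/K - gamma^3/K^4, K = kc^4 - r_od."""
    K = kc ** 4 - r_od
    return gamma / K - gamma ** 3 / K ** 4


def rescaled_bias(gamma: float, r_od: float, kc: float = 1.0) -> float:
    """The opaque rescaled bias eta = |delta| sqrt(3/r_od) (constant onset at 1)."""
    delta, _, _ = shift_delta(gamma, r_od, kc)
    return abs(delta) * np.sqrt(3.0 / r_od)


def gamma_for_eta(eta: float, r_od: float, kc: float = 1.0) -> float:
    """Bias gamma at a given rescaled bias eta >= 0."""
    delta = eta * np.sqrt(r_od / 3.0)
    return gamma_from_delta(delta, r_od, kc)


# ---------------------------------------------------------------------------
# amplitude equations and stationary solutions
# ---------------------------------------------------------------------------

def od_amplitude_rhs(B, r_tilde: float, delta: float) -> np.ndarray:
    """Time derivatives of the three OD mode amplitudes (shifted variables)."""
    B = np.asarray(B, complex)
    quad = -6.0 * delta * np.conj(np.roll(B, -1) * np.roll(B, -2))
    tot = np.sum(np.abs(B) ** 2)
    cub = 3.0 * np.abs(B) ** 2 * B + 6.0 * (tot - np.abs(B) ** 2) * B
    return r_tilde * B + quad - cub


def _hex_amplitude(r_tilde: float, delta: float) -> float:
    rad = 9.0 * delta ** 2 + 15.0 * r_tilde
    if rad < 0.0:
        return np.nan
    return (3.0 * abs(delta) + np.sqrt(rad)) / 15.0


def stationary_branch(label: str, gamma: float, r_od: float,
                      kc: float = 1.0) -> ODBranch:
    """Closed-form stationary OD solution of the given family.

    Stripes: B = (sqrt(r~/3), 0, 0).  Hexagons: |B_j| = B_hex with phase sum
    pi for delta > 0 (0 for delta < 0); the returned convention puts an
    ipsilateral blob at the origin for contralateral bias.  Constant: o =
    delta everywhere.
    """
    delta, r_t, _ = shift_delta(gamma, r_od, kc)
    eta = abs(delta) * np.sqrt(3.0 / r_od)
    f = _BORDER_FRACTIONS
    if label == "stripes":
        if r_t <= 0.0:
            return ODBranch(label, gamma, r_od, kc, delta, 0.0,
                            np.zeros(3, complex), exists=False, stable=False)
        B_st = np.sqrt(r_t / 3.0)
        stable = delta ** 2 < f["stripe_loss"] * r_od
        return ODBranch(label, gamma, r_od, kc, delta, B_st,
                        np.array([B_st, 0.0, 0.0], complex), True, stable)
    if label == "hexagons":
        B_hex = _hex_amplitude(r_t, delta)
        if not np.isfinite(B_hex) or B_hex <= 0.0:
            return ODBranch(label, gamma, r_od, kc, delta, 0.0,
                            np.zeros(3, complex), exists=False, stable=False)
        sgn = -1.0 if delta >= 0.0 else 1.0
        stable = f["hexagon_onset"] * r_od < delta ** 2 < f["hexagon_loss"] * r_od
        return ODBranch(label, gamma, r_od, kc, delta, B_hex,
                        sgn * B_hex * np.ones(3, complex), True, stable)
    if label == "constant":
        stable = r_t < 0.0
        return ODBranch(label, gamma, r_od, kc, delta, 0.0,
                        np.zeros(3, complex), True, stable)
    raise ValueError(f"unknown OD branch label: {label!r}")


# ---------------------------------------------------------------------------
# linear stability: numerical Jacobians with symmetry deflation
# ---------------------------------------------------------------------------

def _pack(B):
    return np.concatenate([B.real, B.imag])


def _unpack(x):
    return x[:3] + 1j * x[3:]


def _jacobian(B, r_tilde, delta, h: float = 1e-6):
    x0 = _pack(np.asarray(B, complex))
    J = np.zeros((6, 6))
    for i in range(6):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        fp = _pack(od_amplitude_rhs(_unpack(xp), r_tilde, delta))
        fm = _pack(od_amplitude_rhs(_unpack(xm), r_tilde, delta))
        J[:, i] = (fp - fm) / (2.0 * h)
    return J


def _translation_tangents(B):
    """Tangent vectors of the two translation symmetries, dB_j = i (k_j.e) B_j."""
    B = np.asarray(B, complex)
    tans = []
    for e in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
        phase = np.array([triad_vector(v) @ e for v in TRIAD])
        t = 1j * phase * B
        if np.linalg.norm(t) > 1e-14:
            tans.append(_pack(t))
    return tans


def od_jacobian_eigenvalues(B, r_tilde: float, delta: float) -> np.ndarray:
    """Eigenvalues of the amplitude Jacobian with translation modes deflated."""
    J = _jacobian(B, r_tilde, delta)
    tans = _translation_tangents(B)
    if tans:
        Q, _ = np.linalg.qr(np.array(tans).T)
        # restrict to the orthogonal complement of the symmetry directions
        full = np.linalg.qr(np.hstack([Q, np.eye(6)]))[0]
        Qc = full[:, Q.shape[1]:6]
        J = Qc.T @ J @ Qc
    return np.sort(np.linalg.eigvals(J).real)


def od_stability_borders(r_od: float, kc: float = 1.0) -> dict:
    """Closed-form stability borders of the OD solutions.

    Returns a dict border-name -> dict(delta, gamma, eta).  Order of
    appearance with growing bias: hexagon_onset < stripe_loss <
    constant_onset < hexagon_loss, giving two bistable transition regions.
    """
    if r_od <= 0.0:
        raise ValueError("r_od must be positive")
    out = {}
    for name, frac in _BORDER_FRACTIONS.items():
        d = np.sqrt(frac * r_od)
        out[name] = {
            "delta": d,
            "gamma": gamma_from_delta(d, r_od, kc),
            "eta": d * np.sqrt(3.0 / r_od),
        }
    return out


def _newton_branch_amplitude(label: str, gamma: float, r_od: float, kc: float):
    """Scalar Newton solve of the stationary amplitude (no closed form used)."""
    delta, r_t, _ = shift_delta(gamma, r_od, kc)
    s = -1.0 if delta >= 0.0 else 1.0

    if label == "stripes":
        def g(b):
            return od_amplitude_rhs([b, 0, 0], r_t, delta)[0].real
        b0 = 0.5 * np.sqrt(max(r_t, 1e-8))
    else:
        def g(b):
            return od_amplitude_rhs(s * b * np.ones(3), r_t, delta)[0].real * s
        b0 = 0.3 * np.sqrt(r_od)
    b = b0
    for _ in range(100):
        h = 1e-7 * max(1.0, abs(b))
        db = -g(b) / ((g(b + h) - g(b - h)) / (2 * h))
        b += db
        if abs(db) < 1e-14:
            break
    if not np.isfinite(b) or b < 1e-10:
        return None, delta, r_t
    return abs(b), delta, r_t


def od_borders_numeric(r_od: float, kc: float = 1.0) -> dict:
    """Stability borders located numerically from the amplitude equations.

    stripe_loss / hexagon_onset: bracketed sign change of the largest
    non-symmetry Jacobian eigenvalue along the Newton-continued branch;
    constant_onset: sign change of the growth rate at B = 0; hexagon_loss:
    fold point solved from (stationarity, marginality) with ``fsolve``.
    Independent of the closed forms in :func:`od_stability_borders`.
    """
    cf = od_stability_borders(r_od, kc)
    out = {}

    def max_eig(label, gamma):
        b, delta, r_t = _newton_branch_amplitude(label, gamma, r_od, kc)
        if b is None:
            return np.nan
        s = -1.0 if delta >= 0.0 else 1.0
        B = (np.array([b, 0, 0], complex) if label == "stripes"
             else s * b * np.ones(3, complex))
        return od_jacobian_eigenvalues(B, r_t, delta)[-1]

    g0 = cf["stripe_loss"]["gamma"]
    out["stripe_loss"] = {"gamma": brentq(
        lambda g: max_eig("stripes", g), 0.5 * g0, 1.8 * g0, xtol=1e-10)}

    g0 = cf["hexagon_onset"]["gamma"]
    out["hexagon_onset"] = {"gamma": brentq(
        lambda g: max_eig("hexagons", g), 0.3 * g0, 2.5 * g0, xtol=1e-10)}

    g0 = cf["constant_onset"]["gamma"]
    out["constant_onset"] = {"gamma": brentq(
        lambda g: shift_delta(g, r_od, kc)[1], 0.5 * g0, 1.5 * g0, xtol=1e-10)}

    # fold: stationarity g(b)=0 and dg/db=0 simultaneously
    def fold(x):
        b, gamma = x
        delta, r_t, _ = shift_delta(gamma, r_od, kc)
        s = -1.0 if delta >= 0.0 else 1.0

        def g(bb):
            return od_amplitude_rhs(s * bb * np.ones(3), r_t, delta)[0].real * s
        h = 1e-6
        return [g(b), (g(b + h) - g(b - h)) / (2 * h)]

    g0 = cf["hexagon_loss"]["gamma"]
    b_guess = 0.13 * np.sqrt(r_od)
    sol = fsolve(fold, [b_guess, 0.97 * g0], full_output=True, xtol=1e-12)
    x, ier = sol[0], sol[2]
    if ier != 1:
        raise RuntimeError("fold search for the hexagon existence border failed")
    out["hexagon_loss"] = {"gamma": float(x[1])}
    return out


# ---------------------------------------------------------------------------
# contralateral eye fraction
# ---------------------------------------------------------------------------

def hex_cell_area(kc: float) -> float:
    """Area of one hexagonal-lattice unit cell: 8 pi^2 / (sqrt(3) kc^2)."""
    return 8.0 * np.pi ** 2 / (np.sqrt(3.0) * kc ** 2)


def contra_fraction(label: str, gamma: float, r_od: float,
                    kc: float = 1.0) -> float:
    """Closed-form areal fraction of contralateral (o > 0) territory.

    Stripes: arccos(-delta / 2 B_st) / pi.  Hexagons: the ipsilateral blob is
    approximated by a circle whose radius is the zero of the field projected
    on the axis through the blob center; the approximation is poorest (but
    still sub-percent) at low bias where the blob is least circular.
    Independent of r_od when expressed in the rescaled bias.
    """
    br = stationary_branch(label, gamma, r_od, kc)
    if not br.exists:
        raise ValueError(f"branch {label!r} does not exist at gamma={gamma}")
    if label == "constant":
        return 1.0 if br.delta > 0 else (0.0 if br.delta < 0 else 0.5)
    if label == "stripes":
        x = np.clip(-br.delta / (2.0 * br.amplitude), -1.0, 1.0)
        return float(np.arccos(x) / np.pi)
    if label == "hexagons":
        d = abs(br.delta) / (2.0 * br.amplitude)
        cterm = (-1.0 + np.sqrt(3.0 + 2.0 * d)) / 2.0
        x0 = 2.0 / kc * np.arccos(np.clip(cterm, -1.0, 1.0))
        minority = np.pi * x0 ** 2 / hex_cell_area(kc)
        return float(1.0 - minority) if br.delta >= 0 else float(minority)
    raise ValueError(f"unknown OD branch label: {label!r}")


def pixel_contra_fraction(od) -> float:
    """Brute-force oracle: fraction of o > 0 pixels of a synthesized field."""
    o = od.o if hasattr(od, "o") else np.asarray(od)
    return float(np.mean(o > 0.0))
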