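"""Coupled amplitude equations for the orientation-preference planform.

Near threshold the OP field is a superposition of six critical modes,

    z(x) = sum_j A_j e^{i k_j x} + A_j^- e^{-i k_j x},   j = 1..3,

with the hexagonal triad k1 + k2 + k3 = 0.  In the backreaction-free limit
(OD modes much larger than OP modes) the OD amplitudes are frozen at their
stationary values from :mod:`corticalmaps.od_subsystem` and the OP modes obey

    dA/dt = r_op A - P_cubic[|z|^2 z] + coupling terms,

where the cubic projection and the interaction terms of the product- and
gradient-type coupling energies are evaluated exactly by resonant mode
enumeration (:mod:`corticalmaps._modes`).  The inter-map coupling both shifts
the effective bifurcation point and introduces resonant interactions between
opposite modes.

Stationary families
-------------------
* ``op_stripes`` -- single mode (deformed by product-type coupling to OD
  stripes into an A+/A- pair with relative phase pi whose amplitudes satisfy
  A+^2 + A-^2 = r - c (delta^2 + 2 B^2), A+ A- = c B^2).
* ``op_scotoma`` -- the collapsed equal-amplitude continuation of the
  deformed stripes, a = sqrt((r - c (delta^2 + B^2)) / 3); it represents
  only two orthogonal orientations.
* ``op_rhombic`` -- two mode pairs at a rhombic angle with a pi/2 relative
  phase, z = 2a (cos k x + i cos k' x); the resonant pair interaction gives
  the effective cubic coefficient 5, so a = sqrt(r/5) uncoupled; coupled
  variants follow by Newton continuation.
* ``hpwc_psi_a`` / ``hpwc_psi_b`` -- the uniform hexagonal pinwheel
  crystals z = 2 A sum_j w^{j-1} cos(k_j x + psi), w = e^{2 pi i / 3}, with
  the two stationary offsets psi = 0 (``a``) and psi = pi/2 (``b``).  The
  cubic coefficient of the uniform family is 9 and the coupling enters as a
  linear coefficient L, so A = sqrt((r_op + L) / 9); L is computed by
  projecting the interaction term onto the family.  For product-type
  coupling with contralateral-biased OD hexagons psi = pi/2 is the stable
  family (the ipsi-center crystal), for gradient-type coupling psi = 0
  (the Braitenberg crystal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._modes import (TRIAD_ANGLES, coupling_projection, project_cubic)
from .energetics import ModelParams
from .od_subsystem import ODBranch, stationary_branch as od_branch_for

__all__ = [
    "AmplitudeState", "StationarySolution", "StabilityReport",
    "op_amplitude_rhs", "uniform_state", "stationary_branch",
    "existence_borders", "newton_continue", "linear_stability",
    "potential_value", "OP_LABELS",
]

OP_LABELS = ("trivial", "op_stripes", "op_rhombic", "op_scotoma",
             "hpwc_psi_a", "hpwc_psi_b")

_PSI = {"hpwc_psi_a": 0.0, "hpwc_psi_b": np.pi / 2.0}


@dataclass
class AmplitudeState:
    """Six OP mode amplitudes plus the frozen OD branch they couple to."""

    C: np.ndarray                 # (6,) complex: A_1..A_3, A_1^-..A_3^-
    od: ODBranch
    params: ModelParams

    @property
    def A(self):
        return self.C[:3]

    @property
    def A_opp(self):
        return self.C[3:]


@dataclass
class StationarySolution:
    label: str
    state: AmplitudeState
    V: float = np.nan
    exists: bool = True
    stable: bool | None = None
    psi: float | None = None
    angle: float = 0.0            # stripe wavevector angle (rad, from k1)
    info: dict = field(default_factory=dict)


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    n_symmetry: int
    stable: bool
    tol: float


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def op_amplitude_rhs(C, params: ModelParams, od: ODBranch) -> np.ndarray:
    """Time derivatives of the six OP mode amplitudes."""
    C = np.asarray(C, complex)
    rhs = params.r_op * C - project_cubic(C)
    if params.c != 0.0:
        rhs = rhs + coupling_projection(C, params.coupling_kind, params.c,
                                        od.delta, od.B, params.kc)
    return rhs


def uniform_state(A: float, psi: float) -> np.ndarray:
    """Amplitude vector of the uniform ansatz z = 2A sum w^{1-j} cos(k_j x + psi).

    w = e^{2 pi i / 3}; the sign of the exponent fixes the handedness of the
    crystal (the mirror image is the equally valid conjugate solution) and is
    chosen so that the pinwheel at the ipsilateral blob center of the
    gradient-type crystal carries topological charge +1.
    """
    base = -np.asarray(TRIAD_ANGLES)
    return A * np.exp(1j * np.concatenate([base + psi, base - psi]))


def _coupling_linear_coefficient(psi, params, od):
    """L such that the interaction term on the uniform family equals L * C."""
    C1 = uniform_state(1.0, psi)
    cpl = coupling_projection(C1, params.coupling_kind, params.c,
                              od.delta, od.B, params.kc)
    L = np.vdot(C1, cpl) / np.vdot(C1, C1)
    resid = np.linalg.norm(cpl - L * C1)
    if resid > 1e-9 * max(1.0, np.linalg.norm(cpl)) or abs(L.imag) > 1e-9:
        raise ValueError(
            f"psi={psi} is not a stationary offset for this coupling"
        )
    return L.real


# ---------------------------------------------------------------------------
# stationary branches
# ---------------------------------------------------------------------------

def _resolve_od(params: ModelParams, od) -> ODBranch:
    if isinstance(od, ODBranch):
        return od
    return od_branch_for(od, params.gamma, params.r_od, params.kc)


def _sol(label, C, od, params, **kw):
    st = AmplitudeState(np.asarray(C, complex), od, params)
    sol = StationarySolution(label, st, **kw)
    if sol.exists:
        sol.V = potential_value(sol, params)
    return sol


def stationary_branch(label: str, params: ModelParams, od="hexagons",
                      theta_rhomb: float = np.pi / 3.0) -> StationarySolution:
    """Stationary OP solution of the given family at one parameter point.

    ``od`` selects the frozen OD branch (label or :class:`ODBranch`).
    Closed forms are returned where they exist; families with
    coupling-dependent phases (stripe-like / rhombic under OD hexagons) are
    obtained by :func:`newton_continue` from their uncoupled seed.  Aliases
    ``hpwc_ipsi`` (product-type stable family) and ``hpwc_braitenberg``
    (gradient-type stable family) resolve to psi_b and psi_a respectively.
    Solutions beyond their existence border are returned with
    ``exists=False``.
    """
    if label == "hpwc_ipsi":
        label = "hpwc_psi_b"
    elif label == "hpwc_braitenberg":
        label = "hpwc_psi_a"
    if label not in OP_LABELS:
        raise ValueError(f"unknown OP branch label {label!r}")
    od = _resolve_od(params, od)
    r, c, kind = params.r_op, params.c, params.coupling_kind
    if c != 0.0 and kind not in ("product_low", "gradient_low"):
        raise ValueError(
            "amplitude equations are implemented for the low-order couplings"
        )

    if label == "trivial":
        return _sol("trivial", np.zeros(6), od, params)

    uncoupled = (c == 0.0
                 or (kind == "gradient_low" and od.label == "constant"))

    if label in _PSI:
        psi = _PSI[label]
        L = 0.0 if uncoupled else _coupling_linear_coefficient(psi, params, od)
        A2 = (r + L) / 9.0
        if A2 <= 0.0:
            return _sol(label, np.zeros(6), od, params, exists=False, psi=psi)
        return _sol(label, uniform_state(np.sqrt(A2), psi), od, params, psi=psi)

    if label == "op_stripes":
        if uncoupled:
            return _sol(label, _stripe_vec(np.sqrt(r), 0.0), od, params)
        if kind == "gradient_low" and od.label == "stripes":
            # preferred stripes run perpendicular to the OD stripes (Ice-cube
            # layout); the coupling term vanishes identically on the solution,
            # so it is stored with c = 0 and a rotated mode frame.
            return _sol(label, _stripe_vec(np.sqrt(r), 0.0), od,
                        _with_c(params, 0.0), angle=np.pi / 2.0,
                        info={"note": "perpendicular to OD stripes"})
        if kind == "product_low" and od.label == "constant":
            A2 = r - c * od.delta ** 2
            if A2 <= 0.0:
                return _sol(label, np.zeros(6), od, params, exists=False)
            return _sol(label, _stripe_vec(np.sqrt(A2), 0.0), od, params)
        if kind == "product_low" and od.label == "stripes":
            B = od.amplitude
            rhat = r - c * (od.delta ** 2 + 2 * B ** 2)
            disc = rhat ** 2 - 4 * c ** 2 * B ** 4
            if disc < 0.0 or rhat <= 0.0:
                return _sol(label, np.zeros(6), od, params, exists=False,
                            info={"collapsed": disc < 0.0})
            Ap = np.sqrt((rhat + np.sqrt(disc)) / 2.0)
            Am = np.sqrt(max((rhat - np.sqrt(disc)) / 2.0, 0.0))
            return _sol(label, _stripe_vec(Ap, Am), od, params,
                        info={"A_plus": Ap, "A_minus": Am})
        # OD hexagons: coupling-dependent phases -> Newton from uncoupled seed
        seed = _sol(label, _stripe_vec(np.sqrt(r), 0.0), od, params)
        return _continue_to(seed, params, od)

    if label == "op_scotoma":
        if not (kind == "product_low" and od.label == "stripes"):
            raise ValueError(
                "the orientation-scotoma family requires product-type "
                "coupling with OD stripes"
            )
        B = od.amplitude
        a2 = (r - c * (od.delta ** 2 + B ** 2)) / 3.0
        if a2 <= 0.0:
            return _sol(label, np.zeros(6), od, params, exists=False)
        a = np.sqrt(a2)
        rhat = r - c * (od.delta ** 2 + 2 * B ** 2)
        return _sol(label, _stripe_vec(a, a), od, params,
                    info={"at_or_beyond_collapse": rhat <= 2 * c * B ** 2})

    if label == "op_rhombic":
        a = np.sqrt(r / 5.0)
        if uncoupled:
            return _sol(label, _rhombic_vec(a), od, params,
                        info={"theta_rhomb": theta_rhomb})
        if kind == "gradient_low" and od.label == "stripes":
            # only the diagonal suppression survives; amplitudes stay equal
            shift = _rhombic_gradient_shift(params, od)
            a2 = (r - shift) / 5.0
            if a2 <= 0.0:
                return _sol(label, np.zeros(6), od, params, exists=False)
            return _sol(label, _rhombic_vec(np.sqrt(a2)), od, params)
        if kind == "product_low" and od.label == "constant":
            a2 = (r - c * od.delta ** 2) / 5.0
            if a2 <= 0.0:
                return _sol(label, np.zeros(6), od, params, exists=False)
            return _sol(label, _rhombic_vec(np.sqrt(a2)), od, params)
        seed = _sol(label, _rhombic_vec(a), od, params)
        return _continue_to(seed, params, od)

    raise AssertionError("unreachable")


def _stripe_vec(Ap, Am):
    """Stripe/scotoma amplitudes along k1 with the relative phase pi."""
    C = np.zeros(6, complex)
    C[0] = Ap
    C[3] = -Am
    return C


def _rhombic_vec(a):
    """Rhombic pinwheel crystal on the pair (k1, -k3): z = 2a(cos k1 x + i cos k3 x)."""
    C = np.zeros(6, complex)
    C[0] = a
    C[3] = a
    C[2] = 1j * a
    C[5] = 1j * a
    return C


def _rhombic_gradient_shift(params, od):
    """Diagonal bifurcation-point shift of modes k2/k3 by gradient coupling to
    OD stripes along k1: c kc^4 * 2 (k1.k2/kc^2)^2 B^2 = c kc^4 B^2 / 2."""
    return params.c * params.kc ** 4 * od.amplitude ** 2 / 2.0


def _continue_to(seed: StationarySolution, params: ModelParams,
                 od: ODBranch) -> StationarySolution:
    p0 = _with_c(params, 0.0)
    samples = newton_continue(
        AmplitudeState(seed.state.C.copy(), od, p0), params,
        np.linspace(0.0, params.c, 21)[1:])
    if not samples or abs(samples[-1][0] - params.c) > 1e-12:
        return _sol(seed.label, np.zeros(6), od, params, exists=False,
                    info={"continuation_failed_at":
                          samples[-1][0] if samples else 0.0})
    return _sol(seed.label, samples[-1][1], od, params)


def _with_c(params: ModelParams, c: float) -> ModelParams:
    return ModelParams(r_op=params.r_op, r_od=params.r_od,
                       coupling_kind=params.coupling_kind, c=c,
                       gamma=params.gamma, kc=params.kc)


# ---------------------------------------------------------------------------
# existence borders
# ---------------------------------------------------------------------------

def existence_borders(kind: str, od_label: str, params: ModelParams) -> dict:
    """Coupling strengths at which branches vanish into the trivial state.

    For product-type coupling to OD stripes the final (scotoma) suppression
    border r / (delta^2 + B_st^2) = 3 r_op / r_od is independent of the OD
    bias; the same bias-independent value is the existence border of the
    stable uniform crystal under OD hexagons.
    """
    p = _with_c(params, 1.0)
    p = ModelParams(r_op=p.r_op, r_od=p.r_od, coupling_kind=kind, c=1.0,
                    gamma=p.gamma, kc=p.kc)
    od = _resolve_od(p, od_label)
    r = params.r_op
    out = {}
    if kind == "product_low" and od_label == "stripes":
        B, d = od.amplitude, od.delta
        out["stripe_collapse"] = r / (d ** 2 + 4 * B ** 2)
        out["suppression"] = r / (d ** 2 + B ** 2)
    elif kind == "product_low" and od_label == "constant":
        out["suppression"] = np.inf if od.delta == 0 else r / od.delta ** 2
    elif od_label == "hexagons":
        for lab, psi in _PSI.items():
            L1 = _coupling_linear_coefficient(psi, p, od)   # at c = 1
            out[f"suppression_{lab[-5:]}"] = np.inf if L1 >= 0 else -r / L1
    elif kind == "gradient_low":
        out = {}   # perpendicular stripes are never suppressed
    else:
        raise ValueError(f"unsupported combination ({kind}, {od_label})")
    return out


# ---------------------------------------------------------------------------
# Newton solver / continuation
# ---------------------------------------------------------------------------

def _pack(C):
    return np.concatenate([C.real, C.imag])


def _unpack(x):
    return x[:6] + 1j * x[6:]


def _newton(C0, params, od, tol=1e-12, maxit=60):
    x = _pack(np.asarray(C0, complex))

    def F(x):
        return _pack(op_amplitude_rhs(_unpack(x), params, od))

    for _ in range(maxit):
        r0 = F(x)
        if np.linalg.norm(r0) < tol:
            return _unpack(x), np.linalg.norm(r0)
        J = np.zeros((12, 12))
        h = 1e-7
        for i in range(12):
            xp = x.copy()
            xp[i] += h
            J[:, i] = (F(xp) - r0) / h
        dx = np.linalg.lstsq(J, -r0, rcond=None)[0]
        if not np.all(np.isfinite(dx)):
            break
        x = x + dx
        if np.linalg.norm(dx) < tol:
            break
    res = np.linalg.norm(F(x))
    return (_unpack(x), res) if res < 1e-9 else (None, res)


def newton_continue(seed: AmplitudeState, params: ModelParams, coupling_path,
                    tol: float = 1e-12, max_halvings: int = 12):
    """Natural-parameter continuation of a stationary state along coupling values.

    ``seed`` must be stationary at its own parameters (checked).  Steps are
    halved adaptively; continuation stops where Newton no longer converges.
    Returns a list of ``(c, C)`` samples (the seed is not included).
    """
    res0 = np.linalg.norm(op_amplitude_rhs(seed.C, seed.params, seed.od))
    if res0 > 1e-8:
        raise ValueError(f"seed is not stationary (residual {res0:.2e})")
    samples = []
    C = seed.C.copy()
    c_cur = seed.params.c
    targets = list(np.atleast_1d(coupling_path))
    for c_next in targets:
        step = c_next - c_cur
        halved = 0
        while abs(c_next - c_cur) > 1e-15:
            c_try = c_cur + step
            p = _with_c(params, c_try)
            Cn, _ = _newton(C, p, seed.od, tol=tol)
            if Cn is not None and np.max(np.abs(Cn)) > 1e-8:
                C, c_cur = Cn, c_try
                step = c_next - c_cur
            else:
                step *= 0.5
                halved += 1
                if halved > max_halvings:
                    return samples
        samples.append((c_cur, C.copy()))
    return samples


# ---------------------------------------------------------------------------
# stability and potential
# ---------------------------------------------------------------------------

def _symmetry_tangents(C, params, od):
    """Tangent vectors of continuous symmetries acting on the OP amplitudes."""
    from ._modes import OP_MODES, triad_vector
    tans = [_pack(1j * C)]                       # orientation shift
    # translations move the OP pattern relative to the frozen OD pattern; they
    # are symmetries only when the coupling term does not pin the phases
    # (uncoupled, or OD spatially constant).
    if params.c == 0.0 or od.label == "constant":
        for e in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
            phase = np.array([triad_vector(v) @ e for v in OP_MODES])
            tans.append(_pack(1j * phase * C))
    kept = []
    for t in tans:
        if np.linalg.norm(t) > 1e-14:
            kept.append(t / np.linalg.norm(t))
    return kept


def linear_stability(solution: StationarySolution, params: ModelParams,
                     tol: float = 1e-8) -> StabilityReport:
    """Numerical linear stability of a stationary amplitude state.

    Finite-difference Jacobian of the real-coordinate system; eigen-
    directions generated by the continuous symmetries (orientation shift,
    and translations where applicable) are deflated before the verdict.
    """
    od = solution.state.od
    C = solution.state.C
    res = np.linalg.norm(op_amplitude_rhs(C, params, od))
    if res > 1e-7:
        raise ValueError(f"state is not stationary (residual {res:.2e})")

    def F(x):
        return _pack(op_amplitude_rhs(_unpack(x), params, od))

    x0 = _pack(C)
    J = np.zeros((12, 12))
    h = 1e-6
    for i in range(12):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (F(xp) - F(xm)) / (2 * h)
    tans = _symmetry_tangents(C, params, od)
    n_sym = 0
    eig_full = np.sort(np.linalg.eigvals(J).real)
    if tans:
        T = np.array(tans).T
        Q, R = np.linalg.qr(T)
        keep = np.abs(np.diag(R)) > 1e-10
        Q = Q[:, keep]
        n_sym = Q.shape[1]
        # eigenvalues on the orthogonal complement of the symmetry directions
        full = np.linalg.qr(np.hstack([Q, np.eye(12)]))[0]
        Qc = full[:, n_sym:12]
        nonsym = np.sort(np.linalg.eigvals(Qc.T @ J @ Qc).real)
    else:
        nonsym = eig_full
    eig = np.concatenate([np.zeros(n_sym), nonsym])
    return StabilityReport(eigenvalues=eig, n_symmetry=n_sym,
                           stable=bool(np.all(nonsym < tol)), tol=tol)


def potential_value(solution, params: ModelParams = None) -> float:
    """Amplitude-equation potential V with dC/dt = -dV/dconj(C).

    V = -r sum|C|^2 + (1/2) Re<C, P[|z|^2 z]> + Re<C, dU/dconj(z)>; its
    gradient reproduces minus the right-hand side (checked in the tests).
    The trivial state has V = 0; uncoupled stripes give -r^2/2 and rhombs
    -2 r^2 / 9, so stripes are always preferred without coupling.
    """
    if isinstance(solution, StationarySolution):
        C, od = solution.state.C, solution.state.od
        params = params or solution.state.params
    else:
        C, od = solution.C, solution.od
        params = params or solution.params
    C = np.asarray(C, complex)
    V = -params.r_op * float(np.sum(np.abs(C) ** 2))
    V += 0.5 * float(np.vdot(C, project_cubic(C)).real)
    if params.c != 0.0:
        cpl = coupling_projection(C, params.coupling_kind, params.c,
                                  od.delta, od.B, params.kc)
        V -= float(np.vdot(C, cpl).real)
    return V
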