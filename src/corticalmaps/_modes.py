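"""Exact mode algebra on the hexagonal triad lattice.

Active wavevectors live on the critical circle |k| = kc and are indexed by
integer coordinates (n1, n2) -> n1*k1 + n2*k2 with

    k1 = kc (1, 0),  k2 = kc (-1/2, sqrt(3)/2),  k3 = -k1 - k2,

so the orientation-preference (OP) planform carries six modes
(+-k1, +-k2, +-k3) and the ocular-dominance (OD) planform the triad
k1 + k2 + k3 = 0 plus a constant offset.

Projecting the cubic and coupling nonlinearities of the coupled dynamics onto
these modes amounts to enumerating every ordered combination of active
wavevectors that sums to a given active mode.  Doing this enumeration exactly
(in integer arithmetic) yields the coupled amplitude equations, including all
configuration-dependent resonant contributions, without hand-transcribing
coefficients.  The closed-form stationary branches elsewhere in the package
are validated against these projections.
"""

from __future__ import annotations

import itertools

import numpy as np

# triad wavevectors in integer coordinates; k3 = -(k1 + k2)
TRIAD: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (-1, -1))
#: the six OP modes, order: k1, k2, k3, -k1, -k2, -k3
OP_MODES: tuple[tuple[int, int], ...] = TRIAD + tuple((-a, -b) for a, b in TRIAD)

#: unit-circle angles of the triad (k1 along +x, counterclockwise)
TRIAD_ANGLES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


def triad_vector(n: tuple[int, int], kc: float = 1.0) -> np.ndarray:
    """Physical wavevector for integer triad coordinates."""
    k1 = kc * np.array([1.0, 0.0])
    k2 = kc * np.array([-0.5, np.sqrt(3.0) / 2.0])
    return n[0] * k1 + n[1] * k2


def triad_dot(p: tuple[int, int], q: tuple[int, int]) -> float:
    """Euclidean dot product of two triad wavevectors, in units of kc**2."""
    return p[0] * q[0] + p[1] * q[1] - 0.5 * (p[0] * q[1] + p[1] * q[0])


def _vadd(*vs):
    return tuple(sum(c) for c in zip(*vs))


def _vneg(v):
    return (-v[0], -v[1])


# ---------------------------------------------------------------------------
# resonance tables, built once at import
# ---------------------------------------------------------------------------

#: the seven candidate OD planform wavevectors: constant, +-triad
_OD_VECS = ((0, 0),) + TRIAD + tuple(_vneg(v) for v in TRIAD)


def _build_cubic_table():
    """Ordered triples (a, b, c): q_a + q_b - q_c = q_m, for |z|^2 z."""
    rows = []
    for m, qm in enumerate(OP_MODES):
        for a, b, c in itertools.product(range(6), repeat=3):
            if _vadd(OP_MODES[a], OP_MODES[b], _vneg(OP_MODES[c])) == qm:
                rows.append((m, a, b, c))
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


_CUB_M, _CUB_A, _CUB_B, _CUB_C = _build_cubic_table()


def _build_coupling_table():
    """Quadruples (m, p1, p2, q): k_{p1} + k_{p2} + q_q = q_m, with the
    gradient-kind geometric factor (k_{p1}.q_q)(k_{p2}.q_m) precomputed."""
    rows, gfac = [], []
    for m, qm in enumerate(OP_MODES):
        for p1, p2 in itertools.product(range(7), repeat=2):
            for qi, q in enumerate(OP_MODES):
                if _vadd(_OD_VECS[p1], _OD_VECS[p2], q) == qm:
                    rows.append((m, p1, p2, qi))
                    gfac.append(triad_dot(_OD_VECS[p1], q)
                                * triad_dot(_OD_VECS[p2], qm))
    arr = np.array(rows)
    return (arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
            np.array(gfac, float))


_CPL_M, _CPL_P1, _CPL_P2, _CPL_Q, _CPL_G = _build_coupling_table()


def project_cubic(C: np.ndarray) -> np.ndarray:
    """Projection of |z|^2 z onto the six OP modes (exact for planforms)."""
    C = np.asarray(C, complex)
    terms = C[_CUB_A] * C[_CUB_B] * np.conj(C[_CUB_C])
    out = np.zeros(6, complex)
    np.add.at(out, _CUB_M, terms)
    return out


def _od_coeffs(delta: float, B) -> np.ndarray:
    B = np.asarray(B, complex)
    return np.concatenate([[complex(delta)], B, np.conj(B)])


def project_product_term(C: np.ndarray, delta: float, B: np.ndarray) -> np.ndarray:
    """Projection of o^2 z onto the OP modes (product-type interaction core)."""
    C = np.asarray(C, complex)
    b = _od_coeffs(delta, B)
    terms = b[_CPL_P1] * b[_CPL_P2] * C[_CPL_Q]
    out = np.zeros(6, complex)
    np.add.at(out, _CPL_M, terms)
    return out


def project_gradient_term(C: np.ndarray, B: np.ndarray, kc: float = 1.0) -> np.ndarray:
    """Projection of div[(grad o . grad z) grad o] onto the OP modes.

    The constant OD offset has zero gradient and drops out (its geometric
    factor vanishes), which is why the gradient-type interaction is
    independent of the OD shift.
    """
    C = np.asarray(C, complex)
    b = _od_coeffs(0.0, B)
    terms = _CPL_G * b[_CPL_P1] * b[_CPL_P2] * C[_CPL_Q]
    out = np.zeros(6, complex)
    np.add.at(out, _CPL_M, terms)
    return (kc ** 4) * out


def coupling_projection(C: np.ndarray, kind: str, c: float, delta: float,
                        B: np.ndarray, kc: float = 1.0) -> np.ndarray:
    """Inter-map interaction term of the OP amplitude equations.

    Returns the contribution to dC/dt (i.e. -dU/dconj(z) projected):
    product-type: -c o^2 z;  gradient-type: +c div[(grad o . grad z) grad o].
    """
    if kind == "product_low":
        return -c * project_product_term(C, delta, B)
    if kind == "gradient_low":
        return c * project_gradient_term(C, B, kc)
    raise ValueError(
        f"unsupported coupling kind for amplitude equations: {kind!r}"
    )


# ---------------------------------------------------------------------------
# OD amplitude projections (triad + constant, real field)
# ---------------------------------------------------------------------------

def project_od_quadratic(B: np.ndarray) -> np.ndarray:
    """Projection of o~^2 onto the triad modes: 2 conj(B_{j+1} B_{j+2})."""
    B = np.asarray(B, complex)
    return 2.0 * np.conj(np.roll(B, -1) * np.roll(B, -2))


def project_od_cubic(B: np.ndarray) -> np.ndarray:
    """Projection of o~^3 onto the triad modes: 3|B_j|^2 B_j + 6 sum_{l!=j}."""
    B = np.asarray(B, complex)
    tot = np.sum(np.abs(B) ** 2)
    return 3.0 * np.abs(B) ** 2 * B + 6.0 * (tot - np.abs(B) ** 2) * B
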