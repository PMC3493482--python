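"""Stability / existence diagrams in the (bias, coupling) plane.

The OD axis uses the rescaled bias eta (constant-solution onset at 1); the
coupling axis uses a rescaling that makes the diagram independent of the OP
bifurcation parameter: for the product-type energy chat = c r_od / (3 r_op)
(the bias-independent suppression border sits at chat = 1), for the
gradient-type energy chat = c kc^4 B_hex^2 / r_op with B_hex the stationary
OD hexagon amplitude (which also removes the bias dependence of all OP
borders inside the hexagon band).

Pinwheel-rich (crystal) phases occur only inside the OD-hexagon band: with
OD stripes or a constant OD map every stable OP solution is a stripe
pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import od_subsystem, op_amplitudes
from .energetics import ModelParams

__all__ = [
    "rescaled_coupling", "coupling_from_rescaled", "od_phase_diagram",
    "op_phase_diagram", "stable_op_labels", "hpwc_onset",
]


def rescaled_coupling(kind: str, c: float, r_op: float, r_od: float,
                      gamma: float = 0.0, kc: float = 1.0) -> float:
    if kind.startswith("product"):
        return c * r_od / (3.0 * r_op)
    hexa = od_subsystem.stationary_branch("hexagons", gamma, r_od, kc)
    if not hexa.exists:
        raise ValueError("gradient rescaling requires the hexagon branch")
    return c * kc ** 4 * hexa.amplitude ** 2 / r_op


def coupling_from_rescaled(kind: str, chat: float, r_op: float, r_od: float,
                           gamma: float = 0.0, kc: float = 1.0) -> float:
    unit = rescaled_coupling(kind, 1.0, r_op, r_od, gamma, kc)
    return chat / unit


def od_phase_diagram(r_od: float, eta_range=(0.0, 1.3), n: int = 261,
                     kc: float = 1.0) -> dict:
    """1-D sweep over the rescaled bias listing the stable OD solutions.

    Regions in order: stripes, stripes+hexagons, hexagons,
    hexagons+constant, constant -- two bistable transition regions.
    """
    borders = od_subsystem.od_stability_borders(r_od, kc)
    etas = np.linspace(*eta_range, n)
    rows = []
    for eta in etas:
        gamma = od_subsystem.gamma_for_eta(eta, r_od, kc)
        labels = [lab for lab in ("stripes", "hexagons", "constant")
                  if (br := od_subsystem.stationary_branch(lab, gamma, r_od, kc)
                      ).exists and br.stable]
        rows.append({"eta": eta, "gamma": gamma, "stable": "+".join(labels)})
    return {"table": pd.DataFrame(rows), "borders": borders}


def stable_op_labels(params: ModelParams, od_label: str) -> list[str]:
    """Labels of the stable OP solutions at one parameter point.

    Candidates are the closed-form / continued families supported for the
    given (coupling kind, OD branch) combination; each existing candidate is
    classified by numerical linear stability of the amplitude equations.
    """
    od = params.od_branch(od_label)
    if not (od.exists and np.isfinite(od.amplitude)):
        return []
    candidates = ["op_stripes", "op_rhombic"]
    if params.coupling_kind == "product_low" and od_label == "stripes":
        candidates.append("op_scotoma")
    if od_label == "hexagons":
        candidates += ["hpwc_psi_a", "hpwc_psi_b"]
    out = []
    for lab in candidates:
        try:
            sol = op_amplitudes.stationary_branch(lab, params, od)
        except ValueError:
            continue
        if not sol.exists:
            continue
        if sol.angle != 0.0:
            # perpendicular stripes: effectively uncoupled, always stable
            out.append(lab)
            continue
        try:
            rep = op_amplitudes.linear_stability(sol, sol.state.params)
        except ValueError:
            continue
        if rep.stable:
            out.append(lab)
    if not out:
        out = ["trivial"]
    return out


def op_phase_diagram(kind: str, eta_range=(0.05, 1.25),
                     chat_range=(0.02, 1.4), resolution=(21, 21),
                     r_op: float = 0.1, r_od: float = 0.2,
                     kc: float = 1.0) -> pd.DataFrame:
    """Long-format phase diagram: one row per (eta, chat, OD branch, OP label)."""
    if kind not in ("product_low", "gradient_low"):
        raise ValueError(f"unknown coupling kind {kind!r}")
    etas = np.linspace(*eta_range, resolution[0])
    chats = np.linspace(*chat_range, resolution[1])
    rows = []
    for eta in etas:
        gamma = od_subsystem.gamma_for_eta(eta, r_od, kc)
        od_stable = [lab for lab in ("stripes", "hexagons", "constant")
                     if (br := od_subsystem.stationary_branch(lab, gamma, r_od, kc)
                         ).exists and br.stable]
        for chat in chats:
            try:
                c = coupling_from_rescaled(kind, chat, r_op, r_od, gamma, kc)
            except ValueError:
                continue
            params = ModelParams(r_op=r_op, r_od=r_od, coupling_kind=kind,
                                 c=c, gamma=gamma, kc=kc)
            for od_label in od_stable:
                for lab in stable_op_labels(params, od_label):
                    rows.append({"eta": eta, "chat": chat, "c": c,
                                 "od_label": od_label, "op_label": lab,
                                 "stable": True})
    return pd.DataFrame(rows)


def hpwc_onset(kind: str, eta: float, r_op: float = 0.1, r_od: float = 0.2,
               kc: float = 1.0, chat_bracket=(0.02, 1.2),
               xtol: float = 1e-3) -> float:
    """Rescaled coupling at which the stable-psi uniform crystal becomes stable.

    Located by bisecting the largest non-symmetry eigenvalue of the crystal's
    perturbation matrix in the rescaled coupling at fixed bias.
    """
    gamma = od_subsystem.gamma_for_eta(eta, r_od, kc)
    label = "hpwc_psi_b" if kind == "product_low" else "hpwc_psi_a"

    def max_eig(chat):
        c = coupling_from_rescaled(kind, chat, r_op, r_od, gamma, kc)
        params = ModelParams(r_op=r_op, r_od=r_od, coupling_kind=kind,
                             c=c, gamma=gamma, kc=kc)
        sol = op_amplitudes.stationary_branch(label, params, "hexagons")
        if not sol.exists:
            return -1.0
        rep = op_amplitudes.linear_stability(sol, params)
        nonsym = rep.eigenvalues[rep.n_symmetry:]
        return float(np.max(nonsym))

    lo, hi = chat_bracket
    flo, fhi = max_eig(lo), max_eig(hi)
    if flo < 0 and fhi < 0:
        return lo      # stable throughout the bracket
    if flo > 0 and fhi > 0:
        raise ValueError("crystal not stable anywhere in the bracket")
    return brentq(max_eig, lo, hi, xtol=xtol)
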