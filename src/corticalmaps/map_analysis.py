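"""Geometry of orientation and ocular-dominance maps.

Pinwheels are zeros of the complex field z, detected as plaquettes around
which the wrapped phase of z winds by a nonzero multiple of 2 pi.  Since the
preferred orientation is theta = arg(z)/2, the topological charge is the
phase winding divided by 2: simple zeros carry +-1/2, and the double zero of
the Braitenberg crystal (two same-sign windings in adjacent plaquettes,
merged within a radius of Lambda/20) carries +-1.  On a periodic domain the
charges sum to zero.

OD critical points are zeros of the gradient field, found with the same
plaquette winding applied to the complex field d_x o + i d_y o (winding +1
at extrema, -1 at saddles) and classified by the Hessian.  Intersection
angles between iso-orientation contours and OD borders are sampled along
marching-squares segments of the o = 0 contour and weighted by the
magnitude of the continuous orientation gradient
|grad theta| = |Im(conj(z) grad z)| / (2 |z|^2), which emphasizes the
high-gradient regions that carry the reliable angle information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .energetics import spectral_gradient
from .fields_core import ODMap, OPMap

__all__ = [
    "PinwheelSet", "CriticalPointSet", "AngleHistogram",
    "find_pinwheels", "pinwheel_density", "od_critical_points",
    "classify_pinwheel_positions", "intersection_angles",
    "orientation_histogram",
]


@dataclass
class PinwheelSet:
    positions: np.ndarray          # (N, 2) physical coordinates
    charges: np.ndarray            # (N,) half-integers
    grid: object

    def __len__(self):
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))

    @property
    def density(self) -> float:
        """Pinwheels per Lambda^2 of cortical area."""
        g = self.grid
        return len(self) * g.lam ** 2 / (g.Lx * g.Ly)

    @property
    def per_unit_cell(self) -> float:
        """Pinwheels per hexagonal-lattice unit cell (area 2 Lambda^2/sqrt(3))."""
        g = self.grid
        return len(self) * g.cell_area / (g.Lx * g.Ly)


@dataclass
class CriticalPointSet:
    maxima: np.ndarray
    minima: np.ndarray
    saddles: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def counts(self):
        return {"maxima": len(self.maxima), "minima": len(self.minima),
                "saddles": len(self.saddles),
                "degenerate": len(self.degenerate)}


@dataclass
class AngleHistogram:
    bin_edges: np.ndarray          # degrees, over [0, 90]
    frequencies: np.ndarray        # weights, normalized to 1
    mean: float
    mode: float
    samples: np.ndarray = None
    weights: np.ndarray = None
    #: angles at the local maxima of the OP gradient along each border
    #: contour -- the crossings of the dominant iso-orientation lines; for
    #: the hexagonal crystals these are exactly perpendicular at any bias
    peak_angles: np.ndarray = None


# ---------------------------------------------------------------------------
# plaquette winding machinery
# ---------------------------------------------------------------------------

def _wrap(d):
    return (d + np.pi) % (2.0 * np.pi) - np.pi


def _crossings(f):
    """Plaquettes in which the real field f changes sign."""
    c = np.stack([f, np.roll(f, -1, 0), np.roll(f, -1, 1),
                  np.roll(np.roll(f, -1, 0), -1, 1)])
    amp = np.abs(f).max()
    return (c.min(0) < -1e-9 * amp) & (c.max(0) > 1e-9 * amp)


def _plaquette_winding(phase):
    """Winding number of a phase field around every grid plaquette."""
    d1 = _wrap(np.roll(phase, -1, 0) - phase)
    d2 = _wrap(np.roll(np.roll(phase, -1, 0), -1, 1) - np.roll(phase, -1, 0))
    d3 = _wrap(np.roll(phase, -1, 1) - np.roll(np.roll(phase, -1, 0), -1, 1))
    d4 = _wrap(phase - np.roll(phase, -1, 1))
    return np.rint((d1 + d2 + d3 + d4) / (2.0 * np.pi)).astype(int)


def _subpixel_zero(fre, fim, i, j, nx, ny):
    """Bilinear zero of (Re, Im) inside plaquette (i, j); offsets in [0, 1]^2."""
    def corners(f):
        return np.array([f[i, j], f[(i + 1) % nx, j],
                         f[i, (j + 1) % ny], f[(i + 1) % nx, (j + 1) % ny]])
    a = corners(fre)
    b = corners(fim)
    s = t = 0.5
    for _ in range(12):
        fs = np.array([(1 - s) * (1 - t), s * (1 - t), (1 - s) * t, s * t])
        F = np.array([a @ fs, b @ fs])
        Js = np.array([[-(1 - t) * a[0] + (1 - t) * a[1] - t * a[2] + t * a[3],
                        -(1 - s) * a[0] - s * a[1] + (1 - s) * a[2] + s * a[3]],
                       [-(1 - t) * b[0] + (1 - t) * b[1] - t * b[2] + t * b[3],
                        -(1 - s) * b[0] - s * b[1] + (1 - s) * b[2] + s * b[3]]])
        try:
            ds, dtt = np.linalg.solve(Js, -F)
        except np.linalg.LinAlgError:
            break
        s = float(np.clip(s + ds, 0.0, 1.0))
        t = float(np.clip(t + dtt, 0.0, 1.0))
        if abs(ds) + abs(dtt) < 1e-12:
            break
    return s, t


def _merge_periodic(pos, charge, Lx, Ly, radius):
    """Greedy merge of singularities closer than radius (periodic metric)."""
    n = len(charge)
    used = np.zeros(n, bool)
    out_p, out_q = [], []
    for i in range(n):
        if used[i]:
            continue
        cluster = [i]
        used[i] = True
        for j in range(i + 1, n):
            if used[j]:
                continue
            d = pos[i] - pos[j]
            d[0] -= Lx * np.round(d[0] / Lx)
            d[1] -= Ly * np.round(d[1] / Ly)
            if np.hypot(*d) < radius:
                cluster.append(j)
                used[j] = True
        q = float(np.sum(charge[cluster]))
        if abs(q) > 1e-12:
            out_p.append(np.mean(pos[cluster], axis=0))
            out_q.append(q)
    if not out_p:
        return np.empty((0, 2)), np.empty(0)
    return np.array(out_p), np.array(out_q)


def find_pinwheels(opmap: OPMap, merge_radius: float | None = None
                   ) -> PinwheelSet:
    """Detect phase singularities of the orientation map.

    Charges are the arg(z) plaquette windings divided by two (theta winds
    half as fast as arg z).  Windings closer than ``merge_radius`` (default
    Lambda/20) are merged into single pinwheels; opposite pairs that merge
    annihilate and are dropped.
    """
    z = opmap.z
    g = opmap.grid
    if np.max(np.abs(z)) == 0.0:
        raise ValueError("orientation field is identically zero")
    # phase-degenerate maps (z = e^{i alpha} * real field, e.g. the
    # orientation-scotoma states) represent only two orientations and have
    # zero *lines*, not point singularities
    M = np.array([[np.sum(z.real ** 2), np.sum(z.real * z.imag)],
                  [np.sum(z.real * z.imag), np.sum(z.imag ** 2)]])
    ev = np.linalg.eigvalsh(M)
    if ev[0] < 1e-12 * ev[1]:
        return PinwheelSet(np.empty((0, 2)), np.empty(0), g)
    off = 0.0
    if np.min(np.abs(z)) < 1e-9 * np.max(np.abs(z)):
        # a zero sits (numerically) on a grid node, where arg(z) is
        # undefined; sample the band-limited field on the half-shifted
        # lattice instead (exact spectral shift)
        off = 0.5
        kx = 2.0 * np.pi * np.fft.fftfreq(g.nx, d=g.dx)
        ky = 2.0 * np.pi * np.fft.fftfreq(g.ny, d=g.dy)
        KX, KY = np.meshgrid(kx, ky, indexing="ij")
        shift = np.exp(1j * (KX * g.dx + KY * g.dy) / 2.0)
        z = np.fft.ifft2(shift * np.fft.fft2(z))
    w = _plaquette_winding(np.angle(z))
    # an isolated zero requires sign changes of BOTH Re z and Im z inside
    # the plaquette; fields with zero *lines* (e.g. the orientation-scotoma
    # stripes, which are purely imaginary) otherwise produce spurious
    # windings from the +-pi phase-jump ambiguity across the line
    w = np.where(_crossings(z.real) & _crossings(z.imag), w, 0)
    if np.any(np.abs(w) > 1):
        raise ValueError(
            "more than one singularity per plaquette; refine the grid"
        )
    idx = np.argwhere(w != 0)
    pos, q = [], []
    for i, j in idx:
        s, t = _subpixel_zero(z.real, z.imag, i, j, g.nx, g.ny)
        pos.append([((i + off + s) * g.dx) % g.Lx,
                    ((j + off + t) * g.dy) % g.Ly])
        q.append(w[i, j] / 2.0)
    pos = np.array(pos) if pos else np.empty((0, 2))
    q = np.array(q)
    radius = merge_radius if merge_radius is not None else g.lam / 20.0
    pos, q = _merge_periodic(pos, q, g.Lx, g.Ly, radius)
    return PinwheelSet(pos, q, g)


def pinwheel_density(pws: PinwheelSet, grid=None) -> float:
    """Pinwheel count per Lambda^2 hypercolumn area."""
    g = grid if grid is not None else pws.grid
    return len(pws) * g.lam ** 2 / (g.Lx * g.Ly)


# ---------------------------------------------------------------------------
# OD critical points
# ---------------------------------------------------------------------------

def od_critical_points(odmap: ODMap, degenerate_tol: float = 1e-6
                       ) -> CriticalPointSet:
    """Sub-pixel critical points of the OD map, classified by the Hessian.

    Fields whose gradient vanishes identically (constant or effectively 1-D
    stripe fields, whose extrema are lines rather than isolated points)
    yield empty / degenerate sets.
    """
    g = odmap.grid
    o = odmap.o
    if np.ptp(o) < 1e-12 * max(1.0, np.abs(o).max()):
        raise ValueError("OD field is constant: critical points are degenerate everywhere")
    # evaluate the gradient on the half-shifted lattice (exact for the
    # band-limited field): critical points of lattice-aligned patterns sit
    # exactly on grid nodes, where the winding is ill-defined
    kx = 2.0 * np.pi * np.fft.fftfreq(g.nx, d=g.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(g.ny, d=g.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    F = np.fft.fft2(o) * np.exp(1j * (KX * g.dx + KY * g.dy) / 2.0)
    ox = np.fft.ifft2(1j * KX * F).real
    oy = np.fft.ifft2(1j * KY * F).real
    w = _plaquette_winding(np.angle(ox + 1j * oy + 1e-300))
    # a genuine isolated zero needs sign changes of BOTH gradient components
    # inside the plaquette; effectively 1-D fields (stripes, whose extrema
    # are lines) fail this and produce no isolated points
    w = np.where(_crossings(ox) & _crossings(oy), w, 0)
    oxx = np.fft.ifft2(-KX * KX * F).real
    oxy = np.fft.ifft2(-KX * KY * F).real
    oyy = np.fft.ifft2(-KY * KY * F).real
    hess_scale = np.abs([oxx, oxy, oyy]).max()
    maxima, minima, saddles, degen = [], [], [], []
    for i, j in np.argwhere(w != 0):
        s, t = _subpixel_zero(ox, oy, i, j, g.nx, g.ny)
        p = [((i + 0.5 + s) * g.dx) % g.Lx, ((j + 0.5 + t) * g.dy) % g.Ly]
        # Hessian samples live on the shifted lattice as well
        ps = [p[0] - g.dx / 2.0, p[1] - g.dy / 2.0]
        hxx = _bilinear(oxx, ps, g)
        hxy = _bilinear(oxy, ps, g)
        hyy = _bilinear(oyy, ps, g)
        det = hxx * hyy - hxy ** 2
        if abs(det) < degenerate_tol * hess_scale ** 2:
            degen.append(p)
        elif det < 0:
            saddles.append(p)
        elif hxx + hyy < 0:
            maxima.append(p)
        else:
            minima.append(p)
    arr = lambda v: np.array(v) if v else np.empty((0, 2))
    return CriticalPointSet(arr(maxima), arr(minima), arr(saddles), arr(degen))


def _bilinear(f, p, g):
    x, y = p[0] / g.dx, p[1] / g.dy
    i0, j0 = int(np.floor(x)) % g.nx, int(np.floor(y)) % g.ny
    s, t = x - np.floor(x), y - np.floor(y)
    i1, j1 = (i0 + 1) % g.nx, (j0 + 1) % g.ny
    return ((1 - s) * (1 - t) * f[i0, j0] + s * (1 - t) * f[i1, j0]
            + (1 - s) * t * f[i0, j1] + s * t * f[i1, j1])


def classify_pinwheel_positions(pws: PinwheelSet, odmap: ODMap,
                                tol: float | None = None) -> dict:
    """Match each pinwheel to the nearest OD critical point (within tol).

    Unmatched pinwheels closer than tol to the OD zero contour (estimated as
    |o| / |grad o|) are counted as ``near_border``, the rest as ``other``.
    Returns the counts plus a per-pinwheel label list.
    """
    g = odmap.grid
    tol = tol if tol is not None else g.lam / 20.0
    cps = od_critical_points(odmap)
    groups = {"at_max": cps.maxima, "at_min": cps.minima,
              "at_saddle": cps.saddles}
    ox, oy = (f.real for f in spectral_gradient(odmap.o, g))
    labels = []
    for p in pws.positions:
        best, bestd = None, np.inf
        for name, pts in groups.items():
            for q in pts:
                d = p - q
                d[0] -= g.Lx * np.round(d[0] / g.Lx)
                d[1] -= g.Ly * np.round(d[1] / g.Ly)
                dist = np.hypot(*d)
                if dist < bestd:
                    best, bestd = name, dist
        if best is not None and bestd <= tol:
            labels.append(best)
            continue
        oval = abs(_bilinear(odmap.o, p, g))
        gval = np.hypot(_bilinear(ox, p, g), _bilinear(oy, p, g))
        labels.append("near_border" if oval <= tol * max(gval, 1e-30)
                      else "other")
    counts = {k: labels.count(k)
              for k in ("at_max", "at_min", "at_saddle", "near_border", "other")}
    return {"counts": counts, "labels": labels}


# ---------------------------------------------------------------------------
# intersection angles and orientation statistics
# ---------------------------------------------------------------------------

def intersection_angles(opmap: OPMap, odmap: ODMap, nbins: int = 18,
                        min_selectivity: float = 1e-3) -> AngleHistogram:
    """Gradient-weighted intersection angles of iso-orientation lines with OD borders.

    The o = 0 contour is extracted with marching squares; at each segment
    midpoint the angle between the border tangent (perpendicular to the
    spectrally evaluated grad o, which is far more accurate than the
    discrete segment direction) and the local iso-orientation direction
    (perpendicular to grad theta) is folded into [0, 90] degrees and
    weighted by |grad theta|.
    """
    g = odmap.grid
    o = odmap.o
    if np.all(o > 0) or np.all(o < 0):
        raise ValueError("OD map has no zero contour")
    # pad one wrapped row/column so contours crossing the boundary are closed
    op = np.pad(o, ((0, 1), (0, 1)), mode="wrap")
    contours = measure.find_contours(op, 0.0)
    z = opmap.z
    zx, zy = spectral_gradient(z, g)
    gtx = (np.conj(z) * zx).imag / (2.0 * np.abs(z) ** 2 + 1e-300)
    gty = (np.conj(z) * zy).imag / (2.0 * np.abs(z) ** 2 + 1e-300)
    ox, oy = (f.real for f in spectral_gradient(o, g))
    sel = np.abs(z)
    selmax = sel.max()
    angles, weights, peak_angles = [], [], []
    for cont in contours:
        mids = 0.5 * (cont[1:] + cont[:-1])
        cont_ang, cont_w = [], []
        for mi, mj in mids:
            p = [(mi * g.dx) % g.Lx, (mj * g.dy) % g.Ly]
            if _bilinear(sel, p, g) < min_selectivity * selmax:
                cont_ang.append(np.nan)
                cont_w.append(0.0)
                continue
            gx = _bilinear(gtx, p, g)
            gy = _bilinear(gty, p, g)
            w = np.hypot(gx, gy)
            nx_, ny_ = _bilinear(ox, p, g), _bilinear(oy, p, g)
            if w < 1e-30 or np.hypot(nx_, ny_) < 1e-30:
                cont_ang.append(np.nan)
                cont_w.append(0.0)
                continue
            t = np.array([-ny_, nx_])          # OD border tangent
            iso = np.array([-gy, gx])          # iso-orientation direction
            ca = abs(t @ iso) / (np.linalg.norm(t) * np.linalg.norm(iso))
            a = np.degrees(np.arccos(np.clip(ca, -1.0, 1.0)))
            angles.append(a)
            weights.append(w)
            cont_ang.append(a)
            cont_w.append(w)
        # crossings of the dominant iso-orientation lines: circular local
        # maxima of the orientation gradient along this border contour
        cw = np.asarray(cont_w)
        if len(cw) >= 5 and np.all(cw > 0):
            closed = np.allclose(cont[0], cont[-1])
            left, right = np.roll(cw, 1), np.roll(cw, -1)
            for b in np.flatnonzero((cw > left) & (cw >= right)):
                if not closed and (b < 2 or b > len(cw) - 3):
                    continue        # endpoint artifacts on cut contours
                peak_angles.append(cont_ang[b])
    if not angles:
        raise ValueError("no usable intersection samples")
    angles = np.asarray(angles)
    weights = np.asarray(weights)
    edges = np.linspace(0.0, 90.0, nbins + 1)
    freq, _ = np.histogram(angles, bins=edges, weights=weights)
    freq = freq / freq.sum()
    mean = float(np.average(angles, weights=weights))
    mode = float(0.5 * (edges[np.argmax(freq)] + edges[np.argmax(freq) + 1]))
    return AngleHistogram(edges, freq, mean, mode, angles, weights,
                          np.asarray(peak_angles))


def orientation_histogram(opmap: OPMap, nbins: int = 36,
                          peak_rel_prominence: float = 0.3) -> dict:
    """Area-weighted distribution of preferred orientations over [0, pi).

    Peaks are circular local maxima whose prominence over the histogram
    floor exceeds ``peak_rel_prominence`` of the total range; a flat
    distribution (pure phase ramp) therefore reports no peaks.
    """
    th = opmap.theta.ravel()
    edges = np.linspace(0.0, np.pi, nbins + 1)
    hist, _ = np.histogram(th, bins=edges)
    hist = hist / hist.sum()
    lo, hi = hist.min(), hist.max()
    peaks = []
    if hi > lo * 1.05 + 1e-12:
        left = np.roll(hist, 1)
        right = np.roll(hist, -1)
        for b in range(nbins):
            if (hist[b] >= left[b] and hist[b] > right[b]
                    and hist[b] - lo > peak_rel_prominence * (hi - lo)):
                peaks.append(0.5 * (edges[b] + edges[b + 1]))
    return {"bin_edges": edges, "frequencies": hist,
            "peaks": np.array(peaks), "n_peaks": len(peaks)}
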