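"""Interstitial drug transport on the annular tumour-cord cross-section.

The cord is an annulus between the capillary wall (dimensionless radius
``x = R_C/R_T``) and the cord boundary (``x = 1``); all spatial variation is
radial.  Free drug diffuses, exchanges with cells through saturable
transmembrane pumps, and binds reversibly to albumin; bound drug diffuses
(slowly) and does not cross the capillary wall.  The wall itself follows a
Kedem-Katchalsky flux law: a permeability term proportional to the
concentration jump plus a lumped convective (Starling) term.

Spatial discretization is a conservative finite-volume scheme on a uniform
radial grid, so total drug changes only through the wall flux — the discrete
divergence-theorem property the conservation tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .parameters import DimensionlessModel, ModelParameters

__all__ = [
    "RadialGrid",
    "DoseProtocol",
    "FieldState",
    "build_grid",
    "radial_laplacian",
    "diffusion_matrix",
    "capillary_flux",
    "extracellular_rates",
    "intracellular_rate",
    "dose_concentration",
]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node placement on the dimensionless annulus [x_inner, 1]."""

    r: np.ndarray               # node positions, ascending
    x_inner: float
    n_nodes: int
    spacing: str = "uniform"

    @property
    def h(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def volumes(self) -> np.ndarray:
        """Finite-volume cell measures ``int r dr`` (half cells at the ends)."""
        h = self.h
        v = self.r * h
        v = v.copy()
        v[0] = ((self.r[0] + h / 2.0) ** 2 - self.r[0] ** 2) / 2.0
        v[-1] = (self.r[-1] ** 2 - (self.r[-1] - h / 2.0) ** 2) / 2.0
        return v


def build_grid(x_inner: float, n_nodes: int) -> RadialGrid:
    """Uniform grid with nodes at both boundaries.

    ``x_inner`` is the capillary-to-cord radius ratio R_C/R_T.
    """
    if not 0.0 < x_inner < 1.0:
        raise ValueError(f"radius ratio must lie in (0, 1), got {x_inner!r}")
    if n_nodes < 8:
        raise ValueError(f"need at least 8 radial nodes, got {n_nodes}")
    r = np.linspace(x_inner, 1.0, int(n_nodes))
    return RadialGrid(r=r, x_inner=float(x_inner), n_nodes=int(n_nodes))


@dataclass(frozen=True)
class FieldState:
    """Per-node drug fields: free (E), bound (B) extracellular; intracellular (I)."""

    E: np.ndarray
    B: np.ndarray
    I: np.ndarray


def radial_laplacian(f: np.ndarray, grid: RadialGrid) -> np.ndarray:
    """Discrete cylindrical-radial Laplacian ``(1/r) d/dr(r df/dr)``.

    Second-order conservative central differences at interior nodes;
    the boundary rows are zero — they belong to the boundary-condition
    handling, not to this operator.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (grid.n_nodes,):
        raise ValueError(f"field has shape {f.shape}, expected ({grid.n_nodes},)")
    r, h = grid.r, grid.h
    out = np.zeros_like(f)
    r_plus = (r[1:-1] + r[2:]) / 2.0
    r_minus = (r[:-2] + r[1:-1]) / 2.0
    out[1:-1] = (r_plus * (f[2:] - f[1:-1]) - r_minus * (f[1:-1] - f[:-2])) / (
        r[1:-1] * h * h)
    return out


def diffusion_matrix(
    grid: RadialGrid,
    diff: float,
    wall_permeability: float = 0.0,
) -> tuple[sp.csr_matrix, float]:
    """Finite-volume diffusion operator with boundary closures.

    Returns ``(L, w)`` such that the diffusive contribution to the field rate
    is ``L @ f + w * (S_effective)`` where ``S_effective = S + K1_term/kappa``
    for the free drug (``w = 0`` for a field with a sealed wall).  The outer
    boundary is always zero-flux.  The wall exchange enters node 0 as
    ``x0 * kappa * (S - f0) / V0``.
    """
    r, h = grid.r, grid.h
    n = grid.n_nodes
    vols = grid.volumes
    faces = (r[:-1] + r[1:]) / 2.0
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    for i in range(n):
        if i > 0:
            c = diff * faces[i - 1] / (h * vols[i])
            main[i] -= c
            lower[i - 1] += c
        if i < n - 1:
            c = diff * faces[i] / (h * vols[i])
            main[i] -= c
            upper[i] += c
    L = sp.diags([lower, main, upper], offsets=[-1, 0, 1], format="lil")
    w = 0.0
    if wall_permeability > 0.0:
        w = r[0] * wall_permeability / vols[0]
        L[0, 0] -= w
    return L.tocsr(), float(w)


def capillary_flux(S: float, E_wall: float, p: DimensionlessModel | ModelParameters):
    """Kedem-Katchalsky transcapillary flux ``K*(S - E(r_c)) + K1``.

    Dimensionless (per-``t_scale``) when given a :class:`DimensionlessModel`,
    dimensional (K in mm/hr) when given :class:`ModelParameters`.
    """
    S = np.asarray(S, dtype=float)
    E_wall = np.asarray(E_wall, dtype=float)
    if np.any(S < 0.0) or np.any(E_wall < 0.0):
        raise ValueError("concentrations must be non-negative")
    if isinstance(p, DimensionlessModel):
        K, K1 = p.wall_permeability, p.wall_convective
    else:
        K, K1 = p.K, p.K1
    out = K * (S - E_wall) + K1
    return out if out.ndim else float(out)


def _check_nonneg(name: str, arr: np.ndarray, slack: float = 1e-9) -> None:
    if np.any(np.asarray(arr) < -slack):
        raise ValueError(f"{name} must be non-negative")


def extracellular_rates(
    state: FieldState,
    c_t: np.ndarray,
    S: float,
    grid: RadialGrid,
    m: DimensionlessModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless rates (dE/dt, dB/dt) including both boundary closures.

    Interior balance: diffusion + cellular efflux - cellular uptake
    - albumin binding + dissociation; both cellular terms scale with the
    local cell density.  The capillary wall feeds node 0 through the
    Kedem-Katchalsky flux; the outer boundary and the bound-drug wall are
    sealed.
    """
    E, B, I = state.E, state.B, state.I
    for name, arr in (("E", E), ("B", B), ("I", I), ("c_t", c_t)):
        _check_nonneg(name, arr)
    if S < 0.0:
        raise ValueError("capillary concentration S must be non-negative")

    L_E, w = diffusion_matrix(grid, m.diff_free, m.wall_permeability)
    L_B, _ = diffusion_matrix(grid, m.diff_bound)
    Ec = np.maximum(E, 0.0)
    Ic = np.maximum(I, 0.0)
    efflux = c_t * m.efflux_vmax * Ic / (m.k2 + Ic)
    uptake = c_t * m.uptake_vmax * Ec / (m.k1 + Ec)
    dE = L_E @ E + efflux - uptake - m.bind_rate * E + m.unbind_rate * B
    if w > 0.0:
        dE[0] += w * S
    if m.wall_convective != 0.0:
        dE[0] += grid.r[0] * m.wall_convective / grid.volumes[0]
    dB = L_B @ B + m.bind_rate * E - m.unbind_rate * B
    return dE, dB


def intracellular_rate(E, I, p: DimensionlessModel | ModelParameters):
    """Per-cell drug balance ``V1*E/(k1+E) - V2*I/(k2+I)``.

    Dimensionless (per ``t_scale``) for a :class:`DimensionlessModel`;
    in ng/(10^5 cells)/min with E in ug/ml for dimensional parameters.
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    _check_nonneg("E", E)
    _check_nonneg("I", I)
    if isinstance(p, DimensionlessModel):
        out = (p.cell_uptake_vmax * E / (p.k1 + E)
               - p.cell_efflux_vmax * I / (p.k2 + I))
    else:
        out = p.V1 * E / (p.k1 + E) - p.V2 * I / (p.k2 + I)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseProtocol:
    """Piecewise-constant capillary drug concentration schedule S(t).

    ``segments`` are ``(start_h, end_h, S)`` triples in hours and E_ref
    units, closed at the left edge and open at the right; S = 0 outside all
    segments.  ``end_h = inf`` encodes a sustained infusion.
    """

    segments: tuple[tuple[float, float, float], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        segs = tuple(sorted((float(a), float(b), float(s))
                            for a, b, s in self.segments))
        for a, b, s in segs:
            if a < 0.0 or b <= a:
                raise ValueError(f"invalid dose segment ({a}, {b}, {s})")
            if s < 0.0:
                raise ValueError(f"negative dose concentration {s}")
        for (a0, b0, _), (a1, _, _) in zip(segs[:-1], segs[1:]):
            if a1 < b0:
                raise ValueError("dose segments overlap")
        object.__setattr__(self, "segments", segs)

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, S: float, name: str = "constant") -> "DoseProtocol":
        return cls(segments=((0.0, float("inf"), S),), name=name)

    @classmethod
    def single_pulse(cls, S: float, duration_h: float, start_h: float = 0.0,
                     name: str = "single_pulse") -> "DoseProtocol":
        return cls(segments=((start_h, start_h + duration_h, S),), name=name)

    @classmethod
    def pulse_train(cls, S: float, duration_h: float, gaps_h: Iterable[float],
                    name: str = "pulse_train") -> "DoseProtocol":
        """Pulses of equal height/duration separated by the given gaps."""
        segs = [(0.0, duration_h, S)]
        t = duration_h
        for gap in gaps_h:
            t += gap
            segs.append((t, t + duration_h, S))
            t += duration_h
        return cls(segments=tuple(segs), name=name)

    @classmethod
    def double_pulse(cls, S: float, duration_h: float, gap_h: float,
                     name: str = "double_pulse") -> "DoseProtocol":
        return cls.pulse_train(S, duration_h, [gap_h], name=name)

    # -- queries -----------------------------------------------------------
    def concentration(self, t_h: float) -> float:
        """S at time ``t_h`` (hours); piecewise-constant lookup."""
        if t_h < 0.0:
            raise ValueError("time must be non-negative")
        for a, b, s in self.segments:
            if a <= t_h < b:
                return s
        return 0.0

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Finite segment edges, ascending — integration restart points."""
        pts = {a for a, _, _ in self.segments}
        pts |= {b for _, b, _ in self.segments if np.isfinite(b)}
        return tuple(sorted(pts))

    @property
    def end_h(self) -> float:
        """Last finite edge, or inf for a sustained infusion."""
        return max(b for _, b, _ in self.segments)

    @property
    def total_dose(self) -> float:
        """Sum of height x duration over the segments (inf if sustained)."""
        return sum((b - a) * s for a, b, s in self.segments)


def dose_concentration(protocol: DoseProtocol, t_h: float) -> float:
    """Capillary concentration of ``protocol`` at time ``t_h`` (hours)."""
    return protocol.concentration(t_h)
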