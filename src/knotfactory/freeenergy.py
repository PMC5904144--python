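"""Positional free-energy model of knot formation on a compressed chain.

The free energy (in k_B T) of one knot of contour L_k at normalized position
X on a ramp profile with barrier extension R_b is

    f_1(L_k, R_b, X) = A_b f_b + A_wk f_wk - f_wuk + A_h f_h,

combining the bulk knot formation cost f_b, the knot-wall confinement cost
f_wk, the confinement free energy *saved* by contour stored in the knot
f_wuk, and the hydrodynamic drag work f_h = zeta_k V X.  Because f_wuk is
linear in the local concentration C(X) = 1/R_b - alpha X and f_h is linear in
X, f_1 is exactly linear in X:

    f_1(L_k, R_b, X) = f_1(L_k, R_b, 0) + beta(L_k, R_b) X,
    beta = A_h zeta_V + kappa_excl alpha L_k.

A knot occupies 2 g_k of extension (g_k = L_k/chi its gyration radius), so a
chain of extension r offers n_max = floor(r/2g_k) statistically independent
formation sites; the single-knot partition sum z_1 is a geometric sum of
Boltzmann factors over those sites.  Multiple knots cannot pass each other in
the channel (hard-core, single-file), so z_m sums over ordered, non-
overlapping placements; at high compression only the ground state survives --
knots stacked single file against the barrier -- and Poisson statistics break
down.  Integrating over knot contours with the (2P)^{-m} state-count measure
gives Z(m, R_b), knotting probabilities P(m, R_b) = Z(m)/sum_i Z(i), total
free energies F_tot = -log Z and the two-knot interaction free energy
F2_int = F_tot(2) - 2 F_tot(1) - log 2.

The explicit functional forms of f_b, f_wk, f_wuk used here are

    f_b   = b_bend * P / L_k          (tight-knot bending, diverges as L_k -> 0)
    f_wk  = kappa_wall * ((g_k/D_av)^3 - 1) for g_k > D_av, else 0
    f_wuk = kappa_excl * C(X) * L_k   (mean-field self-exclusion)

chosen to satisfy the structural constraints of the model: f_1 exactly linear
in X, a metastable minimum in L_k so the contour integral is peaked, f_1(0)
driven negative at strong compression by the self-exclusion saving, and O(1)
fitted scaling constants.  The wall term is continuous at the gate; an
optional variant (``wall_C_coupling``) scales it by the local concentration.
All constants are parameters of :class:`FreeEnergyParams`, so alternative
forms can be explored without touching the partition-sum machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import ChannelGeometry, T4_CHANNEL
from .stats import poisson_pm_from_p0, wilson_interval

__all__ = [
    "FreeEnergyParams",
    "CompressionState",
    "piston_state",
    "f_bulk",
    "f_wall_knot",
    "f_wall_unknot",
    "f_drag",
    "f1",
    "f1_decomposition",
    "z_single",
    "z_multi",
    "Z_state",
    "predict_probabilities",
    "KnotProbabilityTable",
    "KnotFreeEnergyModel",
    "FreeEnergyFitResults",
    "fit_A_params",
    "predict_position_distributions",
]


@dataclass(frozen=True)
class FreeEnergyParams:
    """All constants of the single-knot free energy and the partition sums.

    A_b, A_wk, A_h are the dimensionless scaling constants determined by
    fitting; the remaining constants set the functional forms:

    * ``b_bend`` -- bulk bending coefficient, f_b = b_bend * P / L_k.
    * ``chi`` -- knot compaction ratio, g_k = L_k / chi (g_k ~ 100 nm at
      L_k ~ 1.2 um for chi = 12).
    * ``kappa_excl`` -- self-exclusion free energy per contour per unit
      normalized concentration (1/um).
    * ``kappa_wall`` -- knot-wall confinement coefficient (dimensionless).
    * ``zeta_per_alpha`` -- drag slope zeta_k V / k_B T per unit X, expressed
      per unit ramp slope alpha (alpha ~ V by the piston law, and the state
      carries alpha but not V).
    * ``L_k_range`` -- knot contour integration bounds (um); the lower bound
      must be positive (f_b diverges at 0).
    * ``two_P`` -- Kuhn length 2P (um), the contour measure of Eq. Z.
    """

    A_b: float = 1.43
    A_wk: float = 0.98
    A_h: float = 1.12
    b_bend: float = 526.0
    chi: float = 10.4
    kappa_excl: float = 0.24
    kappa_wall: float = 3.9
    zeta_per_alpha: float = 0.24
    L_k_range: tuple = (0.1, 15.9)
    two_P: float = 0.1
    wall_C_coupling: bool = False  # optionally scale f_wk by the local C(X)
    channel: ChannelGeometry = field(default=T4_CHANNEL)

    def __post_init__(self):
        if self.L_k_range[0] <= 0:
            raise ValueError("lower knot-contour bound must be > 0 (f_b diverges at 0)")
        for name in ("b_bend", "chi", "kappa_excl", "kappa_wall", "two_P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def P_um(self) -> float:
        return self.two_P / 2.0

    def g_k(self, L_k):
        """Knot gyration radius g_k = L_k / chi (um)."""
        return np.asarray(L_k, dtype=float) / self.chi

    def with_A(self, A_b=None, A_wk=None, A_h=None) -> "FreeEnergyParams":
        kw = {}
        if A_b is not None:
            kw["A_b"] = A_b
        if A_wk is not None:
            kw["A_wk"] = A_wk
        if A_h is not None:
            kw["A_h"] = A_h
        return replace(self, **kw)


@dataclass(frozen=True)
class CompressionState:
    """One compression condition of the ramp profile.

    R_b = 1/C_b is the barrier extension, R_c the chain extension (units of
    r_o), alpha the ramp slope, r = R_c * r_o the absolute extension (um).
    ``zeta_V`` optionally carries the drag slope zeta_k V / k_B T for this
    condition; if None it is derived as params.zeta_per_alpha * alpha.
    """

    R_b: float
    R_c: float
    alpha: float
    r_o: float = 14.3
    zeta_V: float | None = None

    def __post_init__(self):
        if not (0 < self.R_b <= 1) or not (0 < self.R_c <= 1):
            raise ValueError("R_b and R_c must lie in (0, 1]")
        if self.C_b - self.alpha * self.R_c < -1e-9:
            raise ValueError("ramp concentration negative at the free edge")

    @property
    def C_b(self) -> float:
        return 1.0 / self.R_b

    @property
    def r(self) -> float:
        return self.R_c * self.r_o

    def C(self, X):
        """Normalized concentration C(X) = C_b - alpha X on [0, R_c]."""
        X = np.asarray(X, dtype=float)
        return self.C_b - self.alpha * X

    def drag_slope(self, params: FreeEnergyParams) -> float:
        return self.zeta_V if self.zeta_V is not None else params.zeta_per_alpha * self.alpha


def piston_state(R_b: float, r_o: float = 14.3, rb_over_rc: float = 0.62,
                 zeta_V: float | None = None) -> CompressionState:
    """Build a mass-conserving ramp state from the barrier extension alone.

    Uses the measured proportionality R_b/R_c (default 0.62) to set the chain
    extension, capped at 1, then solves the unit-area constraint for alpha.
    At R_b = 1 this degenerates to no-flow equilibrium (alpha = 0, R_c = 1).
    """
    R_c = min(R_b / rb_over_rc, 1.0)
    C_b = 1.0 / R_b
    alpha = 2.0 * (C_b * R_c - 1.0) / R_c**2
    return CompressionState(R_b=R_b, R_c=R_c, alpha=alpha, r_o=r_o, zeta_V=zeta_V)


# ---------------------------------------------------------------------------
# free-energy terms
# ---------------------------------------------------------------------------


def f_bulk(L_k, params: FreeEnergyParams):
    """Bulk knot-formation free energy f_b = b_bend * P / L_k (k_B T).

    The tight-knot bending form: halving the stored contour doubles the cost,
    and a loose knot (L_k -> inf) costs nothing.
    """
    L_k = np.asarray(L_k, dtype=float)
    if np.any(L_k <= 0):
        raise ValueError("L_k must be positive")
    return params.b_bend * params.P_um / L_k


def f_wall_knot(L_k, params: FreeEnergyParams, C: float = 1.0):
    """Knot-wall confinement cost once the knot outgrows the channel.

    kappa_wall * ((g_k/D_av)^3 - 1) * C for g_k > D_av = sqrt(D1 D2), zero
    below: continuous at the gate, cubic growth beyond it, and proportional
    to the local chain concentration C -- squeezing a large knot between the
    walls is costlier where the surrounding chain is denser (the wall-knot
    free energy depends on the local extension R = 1/C, and linearity in C is
    the simplest coupling that keeps the total free energy linear in
    position).  At no-flow equilibrium C = 1 this is the bare channel-scale
    cost.  Together with the 1/L_k bulk term it produces the metastable
    minimum in knot contour that keeps the contour integral peaked.
    """
    g = params.g_k(L_k)
    d = params.channel.D_av_um
    x = g / d
    out = np.where(x > 1.0, params.kappa_wall * (x**3 - 1.0) * C, 0.0)
    return out if out.ndim else float(out)


def f_wall_unknot(L_k, X, state: CompressionState, params: FreeEnergyParams):
    """Confinement free energy *saved* by storing contour L_k in the knot:
    kappa_excl * C(X) * L_k, the mean-field self-exclusion of that contour at
    the local concentration.  Linear in X, which keeps f_1 linear in X."""
    X = np.asarray(X, dtype=float)
    if np.any(X < -1e-12) or np.any(X > state.R_c + 1e-12):
        raise ValueError("X outside ramp support [0, R_c]")
    return params.kappa_excl * state.C(X) * np.asarray(L_k, dtype=float)


def f_drag(X, state: CompressionState, params: FreeEnergyParams):
    """Hydrodynamic drag work f_h = zeta_V * X (k_B T)."""
    return state.drag_slope(params) * np.asarray(X, dtype=float)


def f1_decomposition(L_k, state: CompressionState, params: FreeEnergyParams):
    """(f1 at the barrier, slope beta) of the exactly-linear position dependence.

    beta(L_k, R_b) = A_h * zeta_V + alpha * (kappa_excl * L_k - A_wk * f_wk(L_k)),
    with f_wk the bare (C = 1) wall factor: the self-exclusion saving pulls
    knots toward the barrier, the concentration-coupled wall cost pushes
    large knots away from it, and the drag always points toward the barrier.
    """
    L_k = np.asarray(L_k, dtype=float)
    wall = f_wall_knot(L_k, params)  # bare (C = 1) wall factor
    if params.wall_C_coupling:
        wall_base, wall_slope = wall * state.C_b, wall
    else:
        wall_base, wall_slope = wall, 0.0
    base = (
        params.A_b * f_bulk(L_k, params)
        + params.A_wk * wall_base
        - params.kappa_excl * state.C_b * L_k
    )
    beta = (
        params.A_h * state.drag_slope(params)
        + state.alpha * (params.kappa_excl * L_k - params.A_wk * wall_slope)
    )
    return base, beta


def f1(L_k, X, state: CompressionState, params: FreeEnergyParams):
    """Total single-knot free energy f_1(L_k, R_b, X) in k_B T."""
    Xa = np.asarray(X, dtype=float)
    if np.any(Xa < -1e-12) or np.any(Xa > state.R_c + 1e-12):
        raise ValueError("X outside ramp support [0, R_c]")
    C_eff = state.C(Xa) if params.wall_C_coupling else 1.0
    return (
        params.A_b * f_bulk(L_k, params)
        + params.A_wk * f_wall_knot(L_k, params, C=C_eff)
        - f_wall_unknot(L_k, Xa, state, params)
        + params.A_h * f_drag(Xa, state, params)
    )


# ---------------------------------------------------------------------------
# partition sums
# ---------------------------------------------------------------------------


def _geom(q, n):
    """sum_{i=0}^{n-1} q^i, stable at q -> 1."""
    q = np.asarray(q, dtype=float)
    n = np.asarray(n)
    with np.errstate(over="ignore"):
        out = np.where(np.abs(1.0 - q) < 1e-12, n, (1.0 - q**n) / np.where(q == 1, 1, 1.0 - q))
    return out if out.ndim else float(out)


def z_single(L_k, state: CompressionState, params: FreeEnergyParams):
    """Single-knot partition sum over n_max = floor(r/2g_k) formation sites.

    Sites sit at X_i = i * 2 g_k / r_o, i = 0..n_max-1, each with Boltzmann
    weight exp(-f1(L_k, R_b, X_i)); the sum is geometric because f1 is linear
    in X.  A knot larger than the chain (2 g_k >= r) falls back to one site.
    """
    L_k = np.asarray(L_k, dtype=float)
    w = 2.0 * params.g_k(L_k) / state.r_o        # site spacing in X units
    n_max = np.maximum(np.floor(state.R_c / w + 1e-12).astype(int), 1)
    base, beta = f1_decomposition(L_k, state, params)
    q = np.exp(-beta * w)
    out = np.exp(-base) * _geom(q, n_max)
    return out if out.ndim else float(out)


def z_multi(L_list, state: CompressionState, params: FreeEnergyParams,
            exclusion: bool = True):
    """Ordered m-knot partition sum with single-file no-passing exclusion.

    Knot j (ordered from the barrier) occupies a width w_j = 2 g_k(L_kj)/r_o
    of normalized extension.  Its left edge sits at
    a_j = a_{j-1} + w_{j-1} + d_j * w_j with excitation d_j >= 0, subject to
    the total budget a_m + w_m <= R_c; the weight is
    exp(-sum_j f1(L_kj, a_j)).  The ground state (all d_j = 0) is the knots
    stacked single file, abutting the barrier.  Computed by recursion with a
    closed geometric sum over the outermost knot; combined widths exceeding
    the chain extension give exactly zero.

    With ``exclusion=False`` the knots are placed independently (no ordering,
    no width offsets) and the indistinguishability factor 1/m! is applied, so
    z_m = prod_j z_1(L_kj) / m! -- the Poisson reference.
    """
    L = np.atleast_1d(np.asarray(L_list, dtype=float))
    m = L.size
    if m < 1:
        raise ValueError("need at least one knot")
    if not exclusion:
        total = 1.0
        for Lj in L:
            total *= z_single(Lj, state, params)
        return float(total / _factorial(m))
    w = 2.0 * params.g_k(L) / state.r_o
    base = np.empty(m)
    beta = np.empty(m)
    for j in range(m):
        b, be = f1_decomposition(L[j], state, params)
        base[j], beta[j] = float(b), float(be)
    slack = state.R_c - float(np.sum(w))
    if slack < 0:
        return 0.0
    # quick prune: the best (ground-state) configuration already negligible
    a_ground = np.concatenate([[0.0], np.cumsum(w[:-1])])
    if np.sum(base + beta * a_ground) > 700.0:
        return 0.0

    def tail2(jl, ju, prev_end, slack_j):
        """Vectorized two-level sum over excitations (d_jl, d_ju)."""
        d = np.arange(int(np.floor(slack_j / w[jl] + 1e-12)) + 1)
        a = prev_end + d * w[jl]
        rem = slack_j - d * w[jl]
        n_u = np.floor(rem / w[ju] + 1e-12).astype(int) + 1
        q = np.exp(-beta[ju] * w[ju])
        inner = np.exp(-base[ju] - beta[ju] * (a + w[jl])) * _geom(q, n_u)
        return float(np.sum(np.exp(-base[jl] - beta[jl] * a) * inner))

    if m == 1:
        n1 = int(np.floor(slack / w[0] + 1e-12)) + 1
        return float(np.exp(-base[0]) * _geom(np.exp(-beta[0] * w[0]), n1))
    if m == 2:
        return tail2(0, 1, 0.0, slack)
    if m == 3:
        total = 0.0
        n1 = int(np.floor(slack / w[0] + 1e-12)) + 1
        for d1 in range(n1):
            a1 = d1 * w[0]
            weight = np.exp(-base[0] - beta[0] * a1)
            if weight < 1e-300:
                break
            total += weight * tail2(1, 2, a1 + w[0], slack - d1 * w[0])
        return float(total)

    def rec(j: int, prev_end: float, slack_j: float) -> float:
        if j == m - 2:
            return tail2(j, j + 1, prev_end, slack_j)
        n_j = int(np.floor(slack_j / w[j] + 1e-12)) + 1
        total = 0.0
        for d in range(n_j):
            a = prev_end + d * w[j]
            weight = np.exp(-base[j] - beta[j] * a)
            if weight == 0.0:
                break
            total += weight * rec(j + 1, a + w[j], slack_j - d * w[j])
        return total

    return float(rec(0, 0.0, slack))


def _factorial(m: int) -> float:
    out = 1.0
    for i in range(2, m + 1):
        out *= i
    return out


def _z2_quadrature(state, params, nodes, weights) -> float:
    """Two-knot quadrature with the tuple sum vectorized.

    Equivalent to looping z_multi over all contour pairs; the excitation sum
    of the lower knot runs as a masked vector loop and the upper knot's sum
    is closed geometric.  Pairs whose combined barrier free energy lies 40
    k_B T above the best pair are pruned (relative error ~ e^-40).
    """
    w = 2.0 * params.g_k(nodes) / state.r_o
    base, beta = f1_decomposition(nodes, state, params)
    W1, W2 = np.meshgrid(w, w, indexing="ij")
    B1, B2 = np.meshgrid(base, base, indexing="ij")
    G1, G2 = np.meshgrid(beta, beta, indexing="ij")
    WT = np.outer(weights, weights)
    slack = state.R_c - W1 - W2
    cutoff = 2.0 * float(base.min()) + 40.0
    valid = (slack >= 0) & (B1 + B2 <= cutoff)
    if not np.any(valid):
        return 0.0
    W1, W2, B1, B2, G1, G2, WT, slack = (
        a[valid] for a in (W1, W2, B1, B2, G1, G2, WT, slack)
    )
    n1 = np.floor(slack / W1 + 1e-12).astype(int) + 1
    q2 = np.exp(-G2 * W2)
    total = 0.0
    for d in range(int(n1.max())):
        act = d < n1
        if not np.any(act):
            break
        a1 = d * W1[act]
        rem = slack[act] - a1
        n2 = np.floor(rem / W2[act] + 1e-12).astype(int) + 1
        term = (
            np.exp(-B1[act] - G1[act] * a1)
            * np.exp(-B2[act] - G2[act] * (a1 + W1[act]))
            * _geom(q2[act], n2)
        )
        total += float(np.sum(WT[act] * term))
    return total


def _support_nodes(state, params, order: int):
    """Gauss-Legendre nodes/weights on the effective knot-contour support.

    The integrand exp(-f1) is negligible where the barrier free energy
    exceeds its minimum by ~40 k_B T; restricting the quadrature to that
    window (split at the wall-confinement gate, where f1 has a kink) keeps the
    node count low without affecting the integral at the 1e-6 level.
    """
    lo, hi = params.L_k_range
    grid = np.geomspace(lo, hi, 512)
    base, _ = f1_decomposition(grid, state, params)
    keep = base <= base.min() + 40.0
    idx = np.flatnonzero(keep)
    lo_eff = grid[max(idx[0] - 1, 0)]
    hi_eff = grid[min(idx[-1] + 1, grid.size - 1)]
    gate = params.chi * params.channel.D_av_um
    panels = []
    if lo_eff < gate < hi_eff:
        panels = [(lo_eff, gate), (gate, hi_eff)]
    else:
        panels = [(lo_eff, hi_eff)]
    nodes, weights = [], []
    gl_x, gl_w = np.polynomial.legendre.leggauss(order)
    for a, b in panels:
        nodes.append(0.5 * (b - a) * gl_x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * gl_w)
    return np.concatenate(nodes), np.concatenate(weights)


def Z_state(m: int, state: CompressionState, params: FreeEnergyParams,
            exclusion: bool = True, order: int | None = None,
            return_error: bool = False):
    """Knot-number partition function Z(m, R_b).

    Z(0) = 1 exactly (no free energy change for zero knots).  For m >= 1,
    integrates z_m over each knot contour on the effective support with the
    (2P)^{-m} prefactor, by tensor-product Gauss-Legendre quadrature.  With
    ``return_error=True`` also returns a quadrature error estimate (the
    change when the order is halved).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return (1.0, 0.0) if return_error else 1.0
    if order is None:
        order = {1: 48, 2: 20, 3: 10}.get(m, 8)

    def integrate(ordr: int) -> float:
        nodes, weights = _support_nodes(state, params, ordr)
        if m == 1:
            vals = z_single(nodes, state, params)
            total = float(np.sum(weights * vals))
        elif m == 2 and exclusion:
            total = _z2_quadrature(state, params, nodes, weights)
        else:
            # prune contour tuples whose barrier free energy is negligible
            # relative to the best tuple (error ~ e^-40)
            base_arr, _ = f1_decomposition(nodes, state, params)
            cutoff = m * float(base_arr.min()) + 40.0
            total = 0.0
            idx = np.ndindex(*([nodes.size] * m))
            for ind in idx:
                if float(np.sum(base_arr[list(ind)])) > cutoff:
                    continue
                wprod = 1.0
                for i in ind:
                    wprod *= weights[i]
                total += wprod * z_multi(nodes[list(ind)], state, params,
                                         exclusion=exclusion)
        return total / params.two_P**m

    val = integrate(order)
    if return_error:
        err = abs(val - integrate(max(order // 2, 2)))
        return val, err
    return val


@dataclass
class KnotProbabilityTable:
    """Knotting probabilities, partition sums and free energies versus R_b.

    ``df`` has one row per (R_b, m) with columns Z, P, F_tot (and Wilson
    intervals when built from observed counts); ``F2_int`` maps R_b to the
    two-knot interaction free energy.
    """

    df: pd.DataFrame
    F2_int: dict

    @classmethod
    def from_counts(cls, conditions: dict, z: float = 1.0) -> "KnotProbabilityTable":
        """Build an observed table from {R_b: count vector over m}."""
        rows = []
        F2 = {}
        for R_b, counts in conditions.items():
            counts = np.asarray(counts, dtype=int)
            n = counts.sum()
            for m in range(counts.size):
                lo, hi = wilson_interval(int(counts[m]), int(n), z)
                p = counts[m] / n
                rows.append({"R_b": R_b, "m": m, "P": p, "Z": np.nan,
                             "F_tot": -np.log(p / (counts[0] / n)) if counts[0] > 0 and p > 0 else np.nan,
                             "wilson_lo": lo, "wilson_hi": hi, "n_events": int(n)})
            if counts[0] > 0 and counts.size > 2 and counts[1] > 0 and counts[2] > 0:
                F2[R_b] = float(-np.log(counts[2] / counts[0])
                                + 2 * np.log(counts[1] / counts[0]) - np.log(2.0))
        return cls(pd.DataFrame(rows), F2)


def predict_probabilities(state: CompressionState, params: FreeEnergyParams,
                          n_k: int = 3, exclusion: bool = True,
                          order: int | None = None) -> pd.DataFrame:
    """Model knotting probabilities P(m, R_b) = Z(m)/sum_i Z(i) for m <= n_k,
    with F_tot(m) = -log Z(m) and, when n_k >= 2, the interaction free energy
    F2_int = F_tot(2) - 2 F_tot(1) - log 2."""
    Zs = np.array([Z_state(m, state, params, exclusion=exclusion, order=order)
                   for m in range(n_k + 1)])
    P = Zs / Zs.sum()
    with np.errstate(divide="ignore"):
        F = -np.log(Zs)
    rows = pd.DataFrame({"R_b": state.R_b, "m": np.arange(n_k + 1), "Z": Zs,
                         "P": P, "F_tot": F})
    if n_k >= 2:
        rows.attrs["F2_int"] = float(F[2] - 2 * F[1] - np.log(2.0))
    return rows


# ---------------------------------------------------------------------------
# A-parameter fitting
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyFitResults:
    """Fitted scaling constants (A_b, A_wk, A_h) with standard errors."""

    params: FreeEnergyParams
    stderr: dict
    mode: str
    cost: float
    n_conditions: int

    @property
    def A_b(self):
        return self.params.A_b

    @property
    def A_wk(self):
        return self.params.A_wk

    @property
    def A_h(self):
        return self.params.A_h

    def summary(self) -> str:
        lines = [f"Free-energy model fit ({self.mode} mode, "
                 f"{self.n_conditions} compression conditions)"]
        for name in ("A_b", "A_wk", "A_h"):
            se = self.stderr.get(name)
            tail = f" +/- {se:.3f}" if se is not None else "  (fixed)"
            lines.append(f"  {name:5s} = {getattr(self, name):6.3f}{tail}")
        lines.append(f"  weighted residual cost: {self.cost:.4g}")
        return "\n".join(lines)


class KnotFreeEnergyModel:
    """Weighted least-squares fit of (A_b, A_wk, A_h) to observed one- and
    two-knot probabilities across compression conditions.

    Parameters
    ----------
    observed : KnotProbabilityTable
        Observed P(m, R_b) with Wilson intervals (weights are the half-widths).
    params : FreeEnergyParams
        Fixed model constants; the A's act as starting values.
    n_k : int
        Maximum knot number in the normalization sum.
    mode : {"full", "reduced"}
        "full" fits all three constants; "reduced" fixes A_wk = A_h = 1 and
        fits A_b alone.
    """

    def __init__(self, observed: KnotProbabilityTable, params: FreeEnergyParams,
                 n_k: int = 2, mode: str = "full", order: int | None = None,
                 rb_over_rc: float = 0.62, r_o: float = 14.3):
        self.observed = observed
        self.base_params = params
        self.n_k = n_k
        self.mode = mode
        self.order = order
        df = observed.df
        self.R_bs = np.sort(df["R_b"].unique())
        n_free = 3 if mode == "full" else 1
        if self.R_bs.size < max(n_free, 4):
            raise ValueError(
                f"need >= {max(n_free, 4)} compression conditions, got {self.R_bs.size}")
        self.states = [piston_state(rb, r_o=r_o, rb_over_rc=rb_over_rc)
                       for rb in self.R_bs]
        # observed P(1), P(2) and Wilson-derived weights per condition
        self.y = []
        self.sigma = []
        for rb in self.R_bs:
            for m in (1, 2):
                row = df[(df["R_b"] == rb) & (df["m"] == m)].iloc[0]
                self.y.append(row["P"])
                halfwidth = 0.5 * (row["wilson_hi"] - row["wilson_lo"])
                self.sigma.append(max(halfwidth, 1e-3))
        self.y = np.asarray(self.y)
        self.sigma = np.asarray(self.sigma)

    def _predict(self, params: FreeEnergyParams) -> np.ndarray:
        out = []
        for st in self.states:
            tab = predict_probabilities(st, params, n_k=self.n_k, order=self.order)
            out.extend([tab["P"].iloc[1], tab["P"].iloc[2]])
        return np.asarray(out)

    def _params_from_theta(self, theta) -> FreeEnergyParams:
        if self.mode == "full":
            return self.base_params.with_A(A_b=theta[0], A_wk=theta[1], A_h=theta[2])
        return self.base_params.with_A(A_b=theta[0], A_wk=1.0, A_h=1.0)

    def fit(self) -> FreeEnergyFitResults:
        if self.mode == "full":
            theta0 = [self.base_params.A_b, self.base_params.A_wk, self.base_params.A_h]
            names = ["A_b", "A_wk", "A_h"]
        else:
            theta0 = [self.base_params.A_b]
            names = ["A_b"]

        def resid(theta):
            return (self._predict(self._params_from_theta(theta)) - self.y) / self.sigma

        res = least_squares(resid, theta0, method="trf",
                            bounds=(1e-3, 10.0), xtol=1e-8, ftol=1e-10,
                            diff_step=1e-3)
        # standard errors from the Jacobian at the optimum
        stderr = {}
        dof = max(self.y.size - len(theta0), 1)
        try:
            JTJ = res.jac.T @ res.jac
            cov = np.linalg.inv(JTJ) * 2 * res.cost / dof
            for i, nm in enumerate(names):
                stderr[nm] = float(np.sqrt(cov[i, i]))
        except np.linalg.LinAlgError:
            pass
        return FreeEnergyFitResults(
            params=self._params_from_theta(res.x), stderr=stderr, mode=self.mode,
            cost=float(res.cost), n_conditions=self.R_bs.size,
        )


def fit_A_params(observed: KnotProbabilityTable, params: FreeEnergyParams,
                 mode: str = "full", **kw) -> FreeEnergyFitResults:
    """Fit the scaling constants to observed knotting probabilities."""
    return KnotFreeEnergyModel(observed, params, mode=mode, **kw).fit()


# ---------------------------------------------------------------------------
# spatial distributions
# ---------------------------------------------------------------------------


def predict_position_distributions(state: CompressionState, params: FreeEnergyParams,
                                   m: int, L_k=None):
    """Predicted knot-position distributions over formation sites.

    For m = 1 returns (positions, probabilities): the Boltzmann distribution
    exp(-beta X_i) over the n_max sites -- exponential accumulation at the
    barrier.  For m = 2 returns (positions_lower, p_lower, positions_upper,
    p_upper): the marginals of the ordered two-knot measure with the no-
    passing width exclusion; the upper-knot density vanishes inside the
    exclusion gap (its smallest position is w_1 past the lower knot's site).

    ``L_k`` defaults to the contour minimizing f1 at the barrier (per knot).
    """
    if m not in (1, 2):
        raise ValueError("m must be 1 or 2")
    if L_k is None:
        grid = np.geomspace(*params.L_k_range, 512)
        base, _ = f1_decomposition(grid, state, params)
        L_star = float(grid[np.argmin(base)])
        L_k = [L_star] * m
    L_k = np.atleast_1d(np.asarray(L_k, dtype=float))

    if m == 1:
        w = 2.0 * params.g_k(L_k[0]) / state.r_o
        n_max = max(int(np.floor(state.R_c / w + 1e-12)), 1)
        X = np.arange(n_max) * w
        _, beta = f1_decomposition(L_k[0], state, params)
        logp = -float(beta) * X
        p = np.exp(logp - logp.max())
        return X, p / p.sum()

    w1 = 2.0 * params.g_k(L_k[0]) / state.r_o
    w2 = 2.0 * params.g_k(L_k[1]) / state.r_o
    _, b1 = f1_decomposition(L_k[0], state, params)
    _, b2 = f1_decomposition(L_k[1], state, params)
    slack = state.R_c - w1 - w2
    if slack < 0:
        raise ValueError("two knots do not fit on the chain at this compression")
    joint = {}
    n1 = int(np.floor(slack / w1 + 1e-12)) + 1
    for d1 in range(n1):
        a1 = d1 * w1
        rem = slack - d1 * w1
        n2 = int(np.floor(rem / w2 + 1e-12)) + 1
        for d2 in range(n2):
            a2 = a1 + w1 + d2 * w2
            joint[(a1, a2)] = joint.get((a1, a2), 0.0) + np.exp(
                -float(b1) * a1 - float(b2) * a2)
    total = sum(joint.values())
    lower, upper = {}, {}
    for (a1, a2), v in joint.items():
        lower[a1] = lower.get(a1, 0.0) + v / total
        upper[a2] = upper.get(a2, 0.0) + v / total
    lo_x = np.array(sorted(lower))
    up_x = np.array(sorted(upper))
    return lo_x, np.array([lower[k] for k in lo_x]), up_x, np.array([upper[k] for k in up_x])
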