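"""Elastic energetics of membrane roll-up on a supported bilayer.

A planar bilayer patch adheres to an underlying primary membrane with
adhesion energy density ``w_ad`` (J/m^2).  Asymmetric protein binding
imposes a spontaneous curvature ``c_0`` (1/m) on the patch, whose bending
stiffness is the mean-curvature modulus ``k_c`` (J).  When the curvature
energy gain exceeds the adhesion penalty the free edge rolls up into an
archimedean spiral ``r(theta) = a + b*theta`` with inter-layer repeat
``d = 2*pi*b``.

The module provides the rolling criterion, the elastic energy change as a
function of rolling angle, closed-form expressions for the final roll
geometry (maximum radius, inner radius, maximal angle, rolled length), the
inverse map from a measured roll to the spiral pitch, parameter sweeps, and
a derivative-free numeric minimizer of the energy functional that serves as
an independent check on the closed forms.

All quantities are strict SI internally (metres, joules).  Constructors
accept common laboratory units (nm, um, per-nm, per-um^2) via explicitly
named keyword arguments so that unit mistakes fail loudly rather than
silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ElasticParams",
    "RollGeometry",
    "EnergyProfile",
    "NoRollError",
    "can_roll",
    "delta_E",
    "max_roll_radius",
    "inner_radius",
    "solve_roll",
    "spacing_from_roll",
    "sweep_rolled_length",
    "energy_profile",
    "minimize_energy_numeric",
]

NM = 1e-9
UM = 1e-6


class NoRollError(ValueError):
    """Raised when the spontaneous curvature cannot overcome adhesion.

    The rolling criterion (k_c/2) c_0^2 > w_ad is violated, so the
    quadratic for the maximum roll radius has no real root.
    """


@dataclass(frozen=True)
class ElasticParams:
    """Physical inputs of the rolling model, in SI units.

    Parameters
    ----------
    k_c : float
        Mean-curvature bending modulus, J.  Typical lipid bilayer value
        ~1e-19 J.
    w_ad : float
        Adhesion energy per unit area to the underlying membrane, J/m^2.
    c_0 : float
        Protein-induced spontaneous curvature, 1/m.
    b : float
        Slope of the archimedean spiral, m; the inter-layer repeat distance
        is ``d = 2*pi*b``.
    W : float
        Roll width, m.  A pure prefactor of the energy; geometry never
        depends on it.  Defaults to 1 m so energies are per unit width.
    """

    k_c: float
    w_ad: float
    c_0: float
    b: float
    W: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_c > 0):
            raise ValueError(f"k_c must be > 0, got {self.k_c}")
        if not (self.w_ad >= 0):
            raise ValueError(f"w_ad must be >= 0, got {self.w_ad}")
        if not (self.c_0 >= 0):
            raise ValueError(f"c_0 must be >= 0, got {self.c_0}")
        if not (self.b > 0):
            raise ValueError(f"b must be > 0, got {self.b}")
        if not (self.W > 0):
            raise ValueError(f"W must be > 0, got {self.W}")

    @property
    def w_tilde(self) -> float:
        """Reduced adhesion ``w_ad / k_c`` in 1/m^2 (always recomputed)."""
        return self.w_ad / self.k_c

    @property
    def d(self) -> float:
        """Inter-layer spacing ``2*pi*b`` in metres."""
        return 2.0 * math.pi * self.b

    @classmethod
    def from_units(
        cls,
        *,
        k_c_J: float = 1e-19,
        w_ad_J_per_m2: float | None = None,
        ratio_per_um2: float | None = None,
        c0_per_nm: float,
        b_nm: float | None = None,
        d_nm: float | None = None,
        W_m: float = 1.0,
    ) -> "ElasticParams":
        """Build parameters from laboratory units.

        Exactly one of ``w_ad_J_per_m2`` / ``ratio_per_um2`` (the reduced
        ratio w_ad/k_c in 1/um^2) and exactly one of ``b_nm`` / ``d_nm``
        (layer spacing d = 2*pi*b, nm) must be given.
        """
        if (w_ad_J_per_m2 is None) == (ratio_per_um2 is None):
            raise ValueError("give exactly one of w_ad_J_per_m2 or ratio_per_um2")
        if (b_nm is None) == (d_nm is None):
            raise ValueError("give exactly one of b_nm or d_nm")
        w_ad = w_ad_J_per_m2 if w_ad_J_per_m2 is not None else ratio_per_um2 / UM**2 * k_c_J
        b = b_nm * NM if b_nm is not None else d_nm * NM / (2.0 * math.pi)
        return cls(k_c=k_c_J, w_ad=w_ad, c_0=c0_per_nm / NM, b=b, W=W_m)


@dataclass(frozen=True)
class RollGeometry:
    """Final-state descriptors of a membrane roll (SI units).

    ``rolls`` is False for parameter sets below the rolling threshold, in
    which case the geometric fields are NaN.
    """

    rolls: bool
    r_m: float = math.nan  # maximum roll radius, m
    a: float = math.nan  # inner radius, m
    theta_m: float = math.nan  # maximal rolling angle, rad
    L: float = math.nan  # rolled distance, m
    d: float = math.nan  # inter-layer spacing 2*pi*b, m

    def __post_init__(self) -> None:
        if self.rolls:
            if not (0 < self.a <= self.r_m):
                raise ValueError("require 0 < a <= r_m")
            if self.theta_m < 0 or self.L < 0:
                raise ValueError("theta_m and L must be >= 0")


@dataclass(frozen=True)
class EnergyProfile:
    """Energy change versus rolling angle on a strictly increasing grid."""

    theta: np.ndarray  # rad
    delta_E: np.ndarray  # J

    def __post_init__(self) -> None:
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if abs(self.delta_E[0]) > 1e-30 and self.theta[0] == 0:
            raise ValueError("delta_E must vanish at theta = 0")


def can_roll(params: ElasticParams) -> bool:
    """Rolling criterion: spontaneous curvature beats adhesion.

    Returns True iff (k_c/2) c_0^2 > w_ad.
    """
    return 0.5 * params.k_c * params.c_0**2 > params.w_ad


def delta_E(theta, a: float, params: ElasticParams):
    """Elastic energy change of a spiral roll at rolling angle ``theta``.

    DeltaE = (W k_c / b) [ ln(1 + (b/a) theta)/2
                           + ((w_ad/k_c) a b - c_0 b) theta
                           + (w_ad/k_c) b^2 theta^2 / 2 ]

    ``theta`` may be a scalar or array (radians, >= 0); ``a`` is the inner
    radius in metres (> 0).  Returns joules.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    if not a > 0:
        raise ValueError("inner radius a must be > 0")
    b, wt, c0 = params.b, params.w_tilde, params.c_0
    val = (params.W * params.k_c / b) * (
        0.5 * np.log1p((b / a) * theta)
        + (wt * a * b - c0 * b) * theta
        + 0.5 * wt * b**2 * theta**2
    )
    return val if val.shape else float(val)


def max_roll_radius(params: ElasticParams) -> float:
    """Maximum roll radius r_m, the larger root of w~ r^2 - c_0 r + 1/2 = 0.

    Raises :class:`NoRollError` if the discriminant c_0^2 - 2 w_ad/k_c is
    negative (rolling criterion violated).
    """
    wt = params.w_tilde
    disc = params.c_0**2 - 2.0 * wt
    if disc < 0:
        raise NoRollError(
            "spontaneous curvature cannot overcome adhesion: "
            f"c_0^2 = {params.c_0**2:.4g} < 2 w_ad/k_c = {2*wt:.4g} (1/m^2)"
        )
    if wt == 0:
        raise NoRollError("w_ad = 0: roll radius unbounded (no adhesion limit)")
    return (params.c_0 + math.sqrt(disc)) / (2.0 * wt)


def inner_radius(r_m: float, params: ElasticParams) -> float:
    """Inner radius a = [2 (w_ad/k_c) r_m]^-1 of the spiral core."""
    if not r_m > 0:
        raise ValueError("r_m must be > 0")
    if params.w_ad == 0:
        raise ValueError("w_ad = 0: inner radius unbounded; rolling limited only by patch size")
    return 1.0 / (2.0 * params.w_tilde * r_m)


def solve_roll(params: ElasticParams) -> RollGeometry:
    """Closed-form final roll geometry from energy minimization.

    Composes the maximum radius, inner radius, maximal angle
    theta_m = (r_m - a)/b and rolled length L = a theta_m + b theta_m^2/2.
    Below the rolling threshold a flagged no-roll result is returned (so
    parameter sweeps can traverse the threshold without exceptions).
    """
    if not can_roll(params):
        return RollGeometry(rolls=False, d=params.d)
    r_m = max_roll_radius(params)
    a = inner_radius(r_m, params)
    theta_m = (r_m - a) / params.b
    L = a * theta_m + 0.5 * params.b * theta_m**2
    return RollGeometry(rolls=True, r_m=r_m, a=a, theta_m=theta_m, L=L, d=params.d)


def spacing_from_roll(r_m: float, a: float, L: float) -> tuple[float, float]:
    """Spiral slope and layer spacing from measured roll dimensions.

    b = (r_m^2 - a^2) / (2 L);  d = 2 pi b.  This inverts the closed-form
    geometry map: feeding solve_roll's (r_m, a, L) back recovers b exactly.
    """
    if not (r_m > a >= 0):
        raise ValueError("require r_m > a >= 0")
    if not L > 0:
        raise ValueError("require L > 0")
    b = (r_m**2 - a**2) / (2.0 * L)
    return b, 2.0 * math.pi * b


def sweep_rolled_length(
    ratios_per_um2: Sequence[float],
    c0_list_per_nm: Sequence[float],
    b_nm: float,
    k_c_J: float = 1e-19,
) -> pd.DataFrame:
    """Rolled length across a grid of reduced adhesion and curvature values.

    One row per (ratio, c_0) pair.  Columns: ``ratio_per_um2``,
    ``c0_per_nm``, ``r_m_nm``, ``a_nm``, ``theta_m_rad``, ``L_um``,
    ``rolls`` and ``threshold_ratio_per_um2`` (the per-c_0 rolling
    threshold c_0^2/2).  Geometry columns are NaN where rolling does not
    occur.
    """
    if len(ratios_per_um2) == 0 or len(c0_list_per_nm) == 0:
        raise ValueError("ratios and c0 lists must be non-empty")
    if any(r <= 0 for r in ratios_per_um2):
        raise ValueError("all ratios must be > 0")
    rows = []
    for c0 in c0_list_per_nm:
        c0_si = c0 / NM
        threshold = 0.5 * c0_si**2 * UM**2  # in 1/um^2
        for ratio in ratios_per_um2:
            p = ElasticParams.from_units(
                k_c_J=k_c_J, ratio_per_um2=ratio, c0_per_nm=c0, b_nm=b_nm
            )
            g = solve_roll(p)
            rows.append(
                {
                    "ratio_per_um2": ratio,
                    "c0_per_nm": c0,
                    "r_m_nm": g.r_m / NM,
                    "a_nm": g.a / NM,
                    "theta_m_rad": g.theta_m,
                    "L_um": g.L / UM,
                    "rolls": g.rolls,
                    "threshold_ratio_per_um2": threshold,
                }
            )
    return pd.DataFrame(rows)


def energy_profile(params: ElasticParams, theta_max: float, n_points: int) -> EnergyProfile:
    """Energy change on a uniform theta grid with the inner radius fixed.

    The inner radius is held at its optimal value a(r_m) so the profile is
    the one-dimensional curve whose interior minimum sits at theta_m when
    the rolling criterion holds.
    """
    if not theta_max > 0:
        raise ValueError("theta_max must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if can_roll(params):
        a = inner_radius(max_roll_radius(params), params)
    else:
        # below threshold there is no optimal radius; use the balance length
        # scale 1/c_0 (or b) as a physically sensible core size
        a = 1.0 / params.c_0 if params.c_0 > 0 else params.b
    theta = np.linspace(0.0, theta_max, n_points)
    return EnergyProfile(theta=theta, delta_E=delta_E(theta, a, params))


def minimize_energy_numeric(
    params: ElasticParams,
    n_theta: int = 20000,
    n_a: int = 200,
) -> tuple[float, float, float]:
    """Brute-force + local minimization of DeltaE over (theta, a).

    Independent of the closed forms except for using them to bracket the
    search window: theta on [0, 3*theta_m_closed], a log-spaced over two
    decades around the closed-form core radius.  A Nelder-Mead refinement
    polishes the best grid point.  Returns (theta_min, a_min, E_min).
    """
    g = solve_roll(params)
    if not g.rolls:
        raise NoRollError("numeric minimization requires the rolling regime")
    thetas = np.linspace(1e-12, 3.0 * g.theta_m, n_theta)
    a_grid = np.geomspace(g.a / 10.0, g.a * 10.0, n_a)
    best = (math.inf, 0.0, 0.0)
    for a in a_grid:
        e = delta_E(thetas, a, params)
        i = int(np.argmin(e))
        if e[i] < best[0]:
            best = (float(e[i]), float(thetas[i]), float(a))
    _, th0, a0 = best

    def f(x):
        u, la = x  # theta scaled by the grid optimum; a searched in log space
        if u <= 0:
            return math.inf
        return delta_E(u * th0, math.exp(la), params)

    res = optimize.minimize(
        f,
        x0=[1.0, math.log(a0)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-300, "maxiter": 20000},
    )
    u, la = res.x
    return float(u * th0), float(math.exp(la)), float(res.fun)
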