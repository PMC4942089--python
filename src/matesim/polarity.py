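"""Two-stage membrane polarity system with integral feedback.

Each cell carries four species on its membrane markers.  Stage 1 (u1,
representing free Gbeta-gamma) is activated by the normalized pheromone
input f~ and by cooperative positive feedback; stage 2 (u2, active Cdc42)
is driven by u1 with the same structure.  The species v1 and v2 implement
integral feedback: they scale the degradation of u1/u2 so that the membrane
means are driven to the setpoints k1ss/k2ss, which confers adaptation and
bounds the total amount of polarity factor.

    du1/dt = Ds lap_s(u1) + k10 H(beta1 f~; q1) + k11 H(gamma1 u1^p1; h1)
             - (k12 + k13 v1) u1 + kappa2 u1 dW3
    dv1/dt = k14 (mean(u1) - k1ss) v1 + kappa3 v1 dW4
    du2/dt = Ds lap_s(u2) + k20 H(beta2 u1; q2) + k21 H(gamma2 u2^p2; h2)
             - (k22 + k23 v2) u2
    dv2/dt = k24 (mean(u2) - k2ss) v2

with the saturating activation H(x; q) = 1/(1 + x^-q) = x^q/(1 + x^q) and
lap_s the 1D periodic Laplacian in arc length.  Noise acts multiplicatively
on u1 and v1 only (the second stage is deterministic); increments are
Normal(0, dt) i.i.d. per marker.

Time stepping is Euler-Maruyama for reactions/noise with the lateral
diffusion applied implicitly in Fourier space (the marker spacing is uniform
and the topology periodic), which removes the diffusive stability limit.

Numerical parameter values: the rate constants of this generic cascade are
calibration parameters of the package (see docs/methods.md); the defaults
below were fixed by requiring that a noise-free two-cell scenario polarizes
within a few hundred seconds, tracks the pheromone gradient, and mates, and
were frozen before any batch statistics were collected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from matesim.grid import Grid
from matesim.membrane import MembraneCurve


@dataclass
class PolarityParams:
    """Rate constants for the two-stage polarity cascade.

    beta1 is the reciprocal of the pheromone level giving half-maximal
    activation of stage 1: the default 0.92 places the working point of f~
    (which lives in [0.1, 1.1]) on the steep part of the activation curve,
    while the supersensitive value 2.5 saturates it.
    """

    Ds: float = 0.1          # lateral surface diffusion, um^2 per time unit
    # stage 1 (u1 / v1)
    k10: float = 3.0
    k11: float = 1.0
    k12: float = 0.5
    k13: float = 1.0
    k14: float = 2.0
    beta1: float = 0.92
    q1: float = 5.0
    gamma1: float = 1.0
    p1: float = 2.0          # cooperativity of the u1 positive feedback
    h1: float = 2.0
    k1ss: float = 0.5        # integral-feedback setpoint for mean(u1)
    # stage 2 (u2 / v2)
    k20: float = 8.0
    k21: float = 4.0
    k22: float = 0.15
    k23: float = 1.0
    k24: float = 2.0
    beta2: float = 1.2
    q2: float = 5.0
    gamma2: float = 0.02
    p2: float = 2.0
    h2: float = 4.0
    k2ss: float = 3.0        # setpoint for mean(u2)
    # noise amplitudes
    kappa2: float = 3.0      # multiplicative noise on u1
    kappa3: float = 0.1      # multiplicative noise on v1

    def __post_init__(self) -> None:
        for name in ("k10", "k11", "k12", "k13", "k14", "k20", "k21", "k22",
                     "k23", "k24", "beta1", "beta2", "gamma1", "gamma2",
                     "k1ss", "k2ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"polarity rate {name} must be positive")
        for name in ("q1", "q2", "h1", "h2", "p1", "p2"):
            if getattr(self, name) < 1:
                raise ValueError(f"exponent {name} must be >= 1")
        for name in ("Ds", "kappa2", "kappa3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PolarityState:
    """Per-marker concentrations, paired to a MembraneCurve of N markers."""

    u1: np.ndarray
    v1: np.ndarray
    u2: np.ndarray
    v2: np.ndarray
    clamp_events: int = 0

    @classmethod
    def uniform(cls, n: int, params: PolarityParams) -> "PolarityState":
        """Pre-stimulus state: species at their setpoints, feedbacks at 1."""
        return cls(
            u1=np.full(n, params.k1ss),
            v1=np.ones(n),
            u2=np.full(n, params.k2ss),
            v2=np.ones(n),
        )

    @property
    def n(self) -> int:
        return len(self.u1)

    def copy(self) -> "PolarityState":
        return PolarityState(self.u1.copy(), self.v1.copy(),
                             self.u2.copy(), self.v2.copy(), self.clamp_events)


def hill_activation(x: np.ndarray | float, q: float) -> np.ndarray | float:
    """Saturating activation 1/(1 + x^-q) = x^q/(1+x^q), safe at x = 0."""
    xq = np.power(np.maximum(x, 0.0), q)
    return xq / (1.0 + xq)


def _diffuse_periodic_implicit(u: np.ndarray, Ds: float, dt: float,
                               ds: float) -> np.ndarray:
    """Backward-Euler step of u_t = Ds u_ss on a uniform periodic grid.

    Uses the discrete eigenvalues lambda_m = (2 - 2 cos(2 pi m / N))/ds^2 of
    the periodic second-difference operator, so the scheme is the exact
    implicit counterpart of the standard 1D stencil and is unconditionally
    stable.
    """
    if Ds <= 0.0 or dt <= 0.0:
        return u
    n = len(u)
    lam = (2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(n) / n)) / (ds * ds)
    uhat = np.fft.rfft(u)
    uhat /= 1.0 + dt * Ds * lam[: len(uhat)]
    return np.fft.irfft(uhat, n=n)


def step_polarity(state: PolarityState, f_tilde: np.ndarray,
                  params: PolarityParams, ds: float, dt: float,
                  rng: np.random.Generator | None = None) -> PolarityState:
    """One Euler-Maruyama step of the polarity system (dt in time units).

    ``f_tilde`` is the normalized opposite-type pheromone at the markers.
    Negative excursions from the multiplicative noise are clamped to zero
    (and counted); values above 1e6 abort with a parameter report.
    """
    p = params
    u1, v1, u2, v2 = state.u1, state.v1, state.u2, state.v2
    n = state.n
    sdt = np.sqrt(dt)

    u1_mean = float(np.mean(u1))
    u2_mean = float(np.mean(u2))

    act1 = p.k10 * hill_activation(p.beta1 * f_tilde, p.q1)
    fb1 = p.k11 * hill_activation(p.gamma1 * np.power(u1, p.p1), p.h1)
    du1 = act1 + fb1 - (p.k12 + p.k13 * v1) * u1
    dv1 = p.k14 * (u1_mean - p.k1ss) * v1

    act2 = p.k20 * hill_activation(p.beta2 * u1, p.q2)
    fb2 = p.k21 * hill_activation(p.gamma2 * np.power(u2, p.p2), p.h2)
    du2 = act2 + fb2 - (p.k22 + p.k23 * v2) * u2
    dv2 = p.k24 * (u2_mean - p.k2ss) * v2

    nu1 = u1 + dt * du1
    nv1 = v1 + dt * dv1
    nu2 = u2 + dt * du2
    nv2 = v2 + dt * dv2

    if rng is not None and (p.kappa2 > 0.0 or p.kappa3 > 0.0):
        # noise only in the first stage: u1 (sensing) and v1 (feedback loop)
        nu1 = nu1 + p.kappa2 * u1 * rng.standard_normal(n) * sdt
        nv1 = nv1 + p.kappa3 * v1 * rng.standard_normal(n) * sdt

    clamped = 0
    for arr in (nu1, nv1, nu2, nv2):
        neg = arr < 0.0
        clamped += int(np.count_nonzero(neg))
        arr[neg] = 0.0

    nu1 = _diffuse_periodic_implicit(nu1, p.Ds, dt, ds)
    nu2 = _diffuse_periodic_implicit(nu2, p.Ds, dt, ds)

    hi = max(float(np.max(nu1)), float(np.max(nu2)),
             float(np.max(nv1)), float(np.max(nv2)))
    if not np.isfinite(hi) or hi > 1e6:
        raise FloatingPointError(
            f"polarity blow-up (max value {hi:.3g}) with params {params!r}"
        )
    return PolarityState(nu1, nv1, nu2, nv2, state.clamp_events + clamped)


@dataclass
class Polarisome:
    """Center of the minimal membrane interval holding >= tau of u2 mass."""

    s_center: float          # arc-length position of the interval midpoint
    point: np.ndarray        # (2,) position on the membrane, um
    direction: np.ndarray    # (2,) outward unit normal at the center
    interval: tuple[float, float]   # (a*, b*) arc-length span
    angle: float             # polar angle of `point` about the initial center
    tau: float = 0.4


def locate_polarisome(u2: np.ndarray, curve: MembraneCurve,
                      tau: float = 0.4) -> Polarisome | None:
    """Find the minimum-length wrapping interval [a*, b*] of the membrane
    containing at least the fraction ``tau`` of the total u2 mass; the
    polarisome is its arc-length midpoint.

    Marker masses are u2_i * ds (midpoint rule).  The minimal window length
    is generically degenerate on a marker grid (several windows of the same
    marker count reach the mass threshold), so ties are broken by the
    largest contained mass — which recovers the peak-centered continuum
    interval for unimodal profiles — and then by the smallest start index
    (fully deterministic; a uniform profile yields the window at marker 0).
    Returns None when u2 has no mass (pre-polarization sentinel).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    n = curve.n_markers
    ds = curve.ds
    mass = np.asarray(u2, dtype=float) * ds
    total = float(mass.sum())
    if total <= 0.0:
        return None
    need = tau * total

    # prefix sums over the doubled array; for each window start the minimal
    # end index is found in one vectorized searchsorted
    doubled = np.concatenate((mass, mass))
    csum = np.concatenate(([0.0], np.cumsum(doubled)))
    tol = 1e-15 * total
    j_plus1 = np.searchsorted(csum, csum[:n] + need - tol, side="left")
    lengths = j_plus1 - 1 - np.arange(n)  # marker gaps in window [i, j]
    ok = lengths <= n - 1
    if not ok.any():
        return None  # cannot happen for positive total, kept as a guard
    best_len = int(lengths[ok].min())

    # among windows of the minimal marker count, take the one holding the
    # most mass (then the smallest start index); masses equal up to float
    # round-off count as tied so a uniform profile deterministically yields
    # the window at marker 0
    starts = np.arange(n)
    masses = csum[starts + best_len + 1] - csum[starts]
    feasible = masses >= need - tol
    masses = np.where(feasible, masses, -np.inf)
    i = int(np.argmax(masses >= masses.max() - 1e-9 * total))
    s = curve.arc_lengths
    L = curve.perimeter
    a = float(s[i])
    s_center = (s[i] + best_len * ds / 2.0) % L
    b = (s[i] + best_len * ds) % L

    # interpolate position and normal at s_center along the marker polyline
    k = int(round(s_center / ds)) % n
    point = curve.points[k].copy()
    direction = curve.normals[k].copy()
    nrm = np.hypot(*direction)
    if nrm > 0:
        direction = direction / nrm
    rel = point - curve.center0
    angle = float(np.arctan2(rel[1], rel[0]))
    return Polarisome(
        s_center=float(s_center),
        point=point,
        direction=direction,
        interval=(a, float(b)),
        angle=angle,
        tau=tau,
    )


def circular_moving_average(u: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average on a periodic array (window forced odd >= 1)."""
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window == 1:
        return np.asarray(u, dtype=float).copy()
    half = window // 2
    padded = np.concatenate((u[-half:], u, u[:half]))
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def membrane_velocity(u2_filtered: np.ndarray, curve: MembraneCurve,
                      polarisome: Polarisome | None,
                      Vamp: float) -> np.ndarray:
    """Normal boundary speed V_i = Vamp * u2~_i * max(0, <n_i, d_max>).

    ``u2_filtered`` should be the smoothed u2 (see the simulation driver);
    d_max is the outward normal at the polarisome center, so markers whose
    normals point away from the growth direction do not move.  Without a
    polarisome (pre-polarization) the membrane is stationary.
    """
    if polarisome is None:
        return np.zeros(curve.n_markers)
    proj = curve.normals @ polarisome.direction
    return Vamp * np.asarray(u2_filtered, dtype=float) * np.maximum(proj, 0.0)


def extend_velocity(V_markers: np.ndarray, curve: MembraneCurve,
                    band: np.ndarray, grid: Grid,
                    band_nodes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                    ) -> np.ndarray:
    """Constant extension of the marker speeds onto the narrow band: each
    band node takes the speed of its nearest membrane marker.

    ``band_nodes`` may carry precomputed ``(iy, ix, xy)`` arrays for the band
    (the simulation driver caches them between reinitializations).
    """
    if band_nodes is None:
        if not band.any():
            raise ValueError("empty narrow band; cannot extend velocity")
        iy, ix = np.nonzero(band)
        nodes = np.column_stack((grid.x[ix], grid.y[iy]))
    else:
        iy, ix, nodes = band_nodes
        if iy.size == 0:
            raise ValueError("empty narrow band; cannot extend velocity")
    out = np.zeros(grid.shape)
    tree = cKDTree(curve.points)
    _, nearest = tree.query(nodes, k=1)
    out[iy, ix] = np.asarray(V_markers, dtype=float)[nearest]
    return out


def transport_marker_values(arrays: list[np.ndarray], old_curve: MembraneCurve,
                            new_curve: MembraneCurve) -> list[np.ndarray]:
    """Interpolate marker arrays from an old curve onto a new one.

    Each new marker is projected onto the nearest segment of the old marker
    polyline and values are linearly interpolated along it.
    """
    old_pts = old_curve.points
    n_old = len(old_pts)
    tree = cKDTree(old_pts)
    _, k = tree.query(new_curve.points, k=1)

    def _project(seg_a: np.ndarray, seg_b: np.ndarray,
                 p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = seg_b - seg_a
        den = np.einsum("ij,ij->i", d, d)
        t = np.einsum("ij,ij->i", p - seg_a, d) / np.maximum(den, 1e-30)
        t = np.clip(t, 0.0, 1.0)
        foot = seg_a + t[:, None] * d
        dist = np.hypot(*(p - foot).T)
        return t, dist

    p = new_curve.points
    k_next = (k + 1) % n_old
    k_prev = (k - 1) % n_old
    t_fwd, d_fwd = _project(old_pts[k], old_pts[k_next], p)
    t_bwd, d_bwd = _project(old_pts[k_prev], old_pts[k], p)
    use_fwd = d_fwd <= d_bwd

    idx_a = np.where(use_fwd, k, k_prev)
    idx_b = np.where(use_fwd, k_next, k)
    t = np.where(use_fwd, t_fwd, t_bwd)
    return [(1.0 - t) * a[idx_a] + t * a[idx_b] for a in arrays]


def resample_membrane_state(state: PolarityState, old_curve: MembraneCurve,
                            new_curve: MembraneCurve) -> PolarityState:
    """Transport the membrane species from an old marker set to a freshly
    extracted curve of the same cell.

    Successive extractions are close (the membrane moves a small fraction of
    h between resamplings), so the transport is nearly the identity and mass
    drift per resampling is far below 0.5%.
    """
    u1, v1, u2, v2 = transport_marker_values(
        [state.u1, state.v1, state.u2, state.v2], old_curve, new_curve
    )
    return PolarityState(u1=u1, v1=v1, u2=u2, v2=v2,
                         clamp_events=state.clamp_events)
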