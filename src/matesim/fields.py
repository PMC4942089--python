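"""Extracellular pheromone and protease fields.

The ligands alpha-factor (sensed by a-cells), a-factor (sensed by
alpha-cells) and the protease Bar1 (secreted by Bar1+ a-cells) diffuse and
decay in the extracellular space Omega_ex, the set of grid nodes outside
every cell:

    df/dt = D lap(f) + S(x, t) - k_eff(x) f + kappa1 f dW/dt

with no-flux boundary conditions at the outer rectangle and at every cell
membrane (the cell body excludes ligand).  Sources are membrane-localized
Gaussians in the level-set function, optionally modulated by the polarized
species u2 so that secretion is confined to the projection tip; a spatially
uniform background production rate C may be added for alpha-factor.

Bar1 enhances the local degradation of alpha-factor:

    k_eff(x) = k_alpha + k_bar1 * B(x) / (max B + eps)

Two solution modes are provided: explicit Euler-Maruyama time stepping (the
reference dynamics, including multiplicative noise), and a quasi-steady-state
(QSS) sparse solve of D lap(f) - k_eff f + S = 0 exploiting that the field
relaxes much faster than the membrane moves.

Internal units: lengths in micrometres, time in model time units
(1 time unit = 100 s), so D here is in um^2 per time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from matesim.grid import Grid
from matesim.levelset import LevelSetField, CFLViolationError
from matesim.membrane import MembraneCurve

#: Amplitude of the membrane-localized Gaussian source, 1000/sqrt(2*pi).
SOURCE_AMPLITUDE = 1000.0 / np.sqrt(2.0 * np.pi)

#: Ratio of Bar1 secretion to a-factor secretion for Bar1+ cells: S_B = S_a/50.
BAR1_SOURCE_RATIO = 1.0 / 50.0


@dataclass
class SourceSpec:
    """Membrane secretion profile for one cell.

    mode 'isotropic': S(x) = A exp(-100 phi(x)^2) — uniform along the
    membrane.  mode 'polarized': S(x) = A exp(-100 phi^2 - 20 (1 -
    u2(x)/u2max)^2) — confined near the polarisome, where u2(x) is taken from
    the nearest membrane marker.  Before polarization both modes secrete
    isotropically.
    """

    mode: str = "polarized"
    amplitude: float = SOURCE_AMPLITUDE
    background_C: float = 0.0
    bar1_ratio: float = BAR1_SOURCE_RATIO

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "polarized"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        if self.amplitude <= 0:
            raise ValueError("source amplitude must be positive")
        if self.background_C < 0:
            raise ValueError("background production rate C must be >= 0")


@dataclass
class ExtracellularField:
    """One scalar concentration field on the exterior nodes."""

    grid: Grid
    values: np.ndarray          # (ny, nx), zero outside Omega_ex
    D: float                    # um^2 per time unit
    k_decay: float              # per time unit
    kappa1: float = 0.0         # multiplicative noise amplitude
    species_tag: str = "alpha_factor"
    clamp_events: int = 0       # negatives clamped so far
    node_steps: int = 0         # node-updates performed so far

    def copy(self) -> "ExtracellularField":
        return ExtracellularField(
            self.grid, self.values.copy(), self.D, self.k_decay, self.kappa1,
            self.species_tag, self.clamp_events, self.node_steps,
        )


def membrane_source_field(phi: LevelSetField, curve: MembraneCurve | None,
                          u2: np.ndarray | None, spec: SourceSpec,
                          band: np.ndarray,
                          polarized_active: bool = True) -> np.ndarray:
    """Evaluate one cell's secretion source on the grid.

    Returns S(x) = A exp(-100 phi^2) (isotropic) or
    A exp(-100 phi^2 - 20 (1 - u2/u2max)^2) (polarized) on the narrow band,
    zero elsewhere.  Falls back to isotropic when the cell has not polarized
    yet, when no u2 is available, or when u2max <= 0.
    """
    S = np.zeros(phi.grid.shape)
    idx = np.nonzero(band)
    if idx[0].size == 0:
        return S
    pb = phi.phi[idx]
    vals = spec.amplitude * np.exp(-100.0 * pb**2)

    use_polarized = (
        spec.mode == "polarized"
        and polarized_active
        and curve is not None
        and u2 is not None
        and np.max(u2) > 0.0
    )
    if use_polarized:
        u2max = float(np.max(u2))
        X = phi.grid.x[idx[1]]
        Y = phi.grid.y[idx[0]]
        tree = cKDTree(curve.points)
        _, nearest = tree.query(np.column_stack((X, Y)), k=1)
        u2_node = u2[nearest]
        vals = vals * np.exp(-20.0 * (1.0 - u2_node / u2max) ** 2)
    S[idx] = vals
    return S


def _masked_laplacian_apply(f: np.ndarray, ext: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian on exterior nodes with reflecting (no-flux)
    conditions at the membrane and the domain boundary."""
    fc = f
    out = np.zeros_like(f)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(fc, shift, axis=axis)
        nb_ok = np.roll(ext, shift, axis=axis)
        # roll wraps around; the wrapped row/column must reflect instead
        if axis == 0 and shift == 1:
            nb_ok = nb_ok.copy(); nb_ok[0, :] = False
        elif axis == 0 and shift == -1:
            nb_ok = nb_ok.copy(); nb_ok[-1, :] = False
        elif axis == 1 and shift == 1:
            nb_ok = nb_ok.copy(); nb_ok[:, 0] = False
        else:
            nb_ok = nb_ok.copy(); nb_ok[:, -1] = False
        out += np.where(nb_ok, nb - fc, 0.0)
    out /= h * h
    out[~ext] = 0.0
    return out


def step_field(field: ExtracellularField, source: np.ndarray,
               exterior: np.ndarray, dt: float,
               rng: np.random.Generator | None = None,
               k_eff: np.ndarray | float | None = None) -> ExtracellularField:
    """One explicit Euler-Maruyama step of the field SPDE.

    The multiplicative noise increment is kappa1 * f * dW with dW ~
    Normal(0, dt) i.i.d. per node.  Negative values produced by the noise are
    clamped to zero and counted.  Raises :class:`CFLViolationError` when
    4 D dt / h^2 > 1.
    """
    h = field.grid.h
    if field.D > 0:
        dt_req = h * h / (4.0 * field.D)
        if dt > dt_req * (1 + 1e-12):
            raise CFLViolationError(
                f"diffusion CFL violated for {field.species_tag}: dt={dt:.3g} "
                f"> h^2/(4D) = {dt_req:.3g}",
                dt_required=dt_req,
            )
    if k_eff is None:
        k_eff = field.k_decay
    f = field.values
    lap = _masked_laplacian_apply(f, exterior, h)
    drift = field.D * lap + source - k_eff * f
    new = f + dt * drift
    if field.kappa1 > 0.0:
        if rng is None:
            raise ValueError("rng required when kappa1 > 0")
        dW = rng.standard_normal(f.shape) * np.sqrt(dt)
        new = new + field.kappa1 * f * dW
    new[~exterior] = 0.0
    neg = new < 0.0
    n_clamped = int(np.count_nonzero(neg & exterior))
    new[neg] = 0.0
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            f"non-finite values in field {field.species_tag} after step"
        )
    out = field.copy()
    out.values = new
    out.clamp_events += n_clamped
    out.node_steps += int(np.count_nonzero(exterior))
    return out


def effective_alpha_decay(k_alpha: float, k_bar1: float,
                          B: np.ndarray | None,
                          eps: float = 1e-6) -> np.ndarray | float:
    """Bar1-enhanced decay rate field k_alpha + k_bar1 * B/(max B + eps).

    With no Bar1 field (or B identically zero) the rate is the basal
    k_alpha everywhere.
    """
    if B is None:
        return k_alpha
    bmax = float(np.max(B))
    if bmax < 0:
        raise ValueError("Bar1 field must be nonnegative")
    return k_alpha + k_bar1 * B / (bmax + eps)


class QssSolver:
    """Sparse Helmholtz solver for the quasi-steady-state field.

    Solves D lap(f) - k_eff f + S = 0 on the exterior nodes with no-flux
    boundaries (dropped connections at masked neighbours).  The sparse
    Laplacian is rebuilt only when the exterior mask changes; the LU
    factorization is additionally reused across solves while k_eff is the
    same scalar.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self._mask_key: bytes | None = None
        self._idx: np.ndarray | None = None        # flat indices of unknowns
        self._lap: sp.csr_matrix | None = None     # Laplacian (1/h^2 units)
        self._lu = None
        self._lu_key: tuple | None = None

    def _build(self, exterior: np.ndarray) -> None:
        g = self.grid
        ny, nx = g.shape
        flat_ext = exterior.ravel()
        idx = np.flatnonzero(flat_ext)
        pos = -np.ones(ny * nx, dtype=np.intp)
        pos[idx] = np.arange(idx.size)

        rows, cols, vals = [], [], []
        iy, ix = np.unravel_index(idx, (ny, nx))
        diag = np.zeros(idx.size)
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jy, jx = iy + dy, ix + dx
            ok = (jy >= 0) & (jy < ny) & (jx >= 0) & (jx < nx)
            nb_flat = np.where(ok, jy * nx + jx, 0)
            nb_pos = np.where(ok, pos[nb_flat], -1)
            conn = nb_pos >= 0
            rows.append(np.arange(idx.size)[conn])
            cols.append(nb_pos[conn])
            vals.append(np.ones(int(conn.sum())))
            diag[conn] -= 1.0
        rows.append(np.arange(idx.size))
        cols.append(np.arange(idx.size))
        vals.append(diag)
        lap = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(idx.size, idx.size),
        ) / (g.h * g.h)
        self._idx = idx
        self._lap = lap.tocsc()
        self._lu = None
        self._lu_key = None

    def solve(self, exterior: np.ndarray, D: float,
              k_eff: np.ndarray | float, source: np.ndarray) -> np.ndarray:
        key = exterior.tobytes()
        if key != self._mask_key:
            self._build(exterior)
            self._mask_key = key
        idx = self._idx
        S = source.ravel()[idx]
        if np.isscalar(k_eff) or np.ndim(k_eff) == 0:
            k_vec = np.full(idx.size, float(k_eff))
            lu_key = ("scalar", float(k_eff), float(D))
        else:
            k_vec = np.asarray(k_eff).ravel()[idx]
            lu_key = None
        if np.any(k_vec <= 0.0):
            raise ValueError(
                "QSS solve requires k_eff > 0 everywhere (pure-Neumann "
                "problem is singular without decay)"
            )
        if lu_key is not None and lu_key == self._lu_key and self._lu is not None:
            lu = self._lu
        else:
            A = (-D) * self._lap + sp.diags(k_vec).tocsc()
            lu = splu(A.tocsc())
            if lu_key is not None:
                self._lu = lu
                self._lu_key = lu_key
        f = lu.solve(S)
        out = np.zeros(self.grid.shape)
        out.ravel()[idx] = np.maximum(f, 0.0)
        return out


def qss_solve(grid: Grid, exterior: np.ndarray, D: float,
              k_eff: np.ndarray | float, source: np.ndarray) -> np.ndarray:
    """One-shot quasi-steady-state solve (see :class:`QssSolver`)."""
    return QssSolver(grid).solve(exterior, D, k_eff, source)


def sample_membrane(field_values: np.ndarray, grid: Grid,
                    curve: MembraneCurve, exterior: np.ndarray) -> np.ndarray:
    """Sample a field at the markers using exterior-side nodes only."""
    return grid.interp(field_values, curve.points,
                       weights=exterior.astype(float))


def normalize_ligand(f_samples: np.ndarray) -> np.ndarray:
    """Adaptive-range normalization f~ = f / max_membrane(f) + 0.1.

    The sensing domain is the cell's own membrane; the offset 0.1 keeps the
    downstream activation term in its working range.  A zero field yields the
    guard value 0.1 everywhere.
    """
    fmax = float(np.max(f_samples)) if f_samples.size else 0.0
    if fmax <= 0.0:
        return np.full_like(np.asarray(f_samples, dtype=float), 0.1)
    return f_samples / fmax + 0.1


def sample_and_normalize(field: ExtracellularField, curve: MembraneCurve,
                         exterior: np.ndarray) -> np.ndarray:
    """Membrane sampling followed by the f~ normalization."""
    f = sample_membrane(field.values, field.grid, curve, exterior)
    return normalize_ligand(f)
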