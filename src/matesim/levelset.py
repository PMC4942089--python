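"""Per-cell level-set representation and its evolution.

Each cell carries a scalar field phi(x) on the shared grid with the signed
distance convention: phi < 0 inside the cell, phi > 0 outside, and the zero
contour Gamma is the plasma membrane.  The membrane moves with a prescribed
normal speed V by solving the Hamilton-Jacobi equation

    phi_t + V |grad phi| = 0

with a first-order Godunov upwind discretization.  Signed-distance character
(|grad phi| = 1) is restored periodically by an exact geometric
reinitialization: the zero contour is extracted as a polyline and phi is
recomputed as the distance to it, keeping the original sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from matesim.grid import Grid


class InterfaceVanishedError(RuntimeError):
    """The level-set field has no zero contour (the cell disappeared)."""


class CFLViolationError(RuntimeError):
    """A proposed time step violates the CFL stability constraint."""

    def __init__(self, msg: str, dt_required: float):
        super().__init__(msg)
        self.dt_required = dt_required


@dataclass
class LevelSetField:
    grid: Grid
    phi: np.ndarray  # shape grid.shape, micrometres
    cell_id: str = "cell"

    def copy(self) -> "LevelSetField":
        return LevelSetField(self.grid, self.phi.copy(), self.cell_id)

    def interior_mask(self) -> np.ndarray:
        return self.phi < 0.0

    def enclosed_area(self) -> float:
        """Node-counting estimate of the enclosed area (O(h) accurate)."""
        return float(np.count_nonzero(self.phi < 0.0)) * self.grid.h**2


def init_circle_levelset(center: tuple[float, float], radius: float,
                         grid: Grid, cell_id: str = "cell") -> LevelSetField:
    """Exact signed distance to a circle: phi(x) = |x - center| - radius.

    The circle must lie strictly inside the domain (it may not touch the
    boundary), otherwise the extracellular field around the cell would be
    truncated.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cx, cy = center
    if not (
        grid.x_min < cx - radius
        and cx + radius < grid.x_max
        and grid.y_min < cy - radius
        and cy + radius < grid.y_max
    ):
        raise ValueError(
            f"circle center={center} radius={radius} touches or leaves the "
            f"domain [{grid.x_min},{grid.x_max}]x[{grid.y_min},{grid.y_max}]"
        )
    X, Y = grid.meshgrid()
    phi = np.hypot(X - cx, Y - cy) - radius
    return LevelSetField(grid, phi, cell_id)


def _upwind_gradient_norm(phi: np.ndarray, V: np.ndarray, h: float) -> np.ndarray:
    """Godunov upwind approximation of |grad phi| for phi_t + V|grad phi| = 0."""
    # One-sided differences with edge replication at the domain boundary.
    dmx = np.empty_like(phi)
    dpx = np.empty_like(phi)
    dmy = np.empty_like(phi)
    dpy = np.empty_like(phi)
    dmx[:, 1:] = (phi[:, 1:] - phi[:, :-1]) / h
    dmx[:, 0] = dmx[:, 1]
    dpx[:, :-1] = (phi[:, 1:] - phi[:, :-1]) / h
    dpx[:, -1] = dpx[:, -2]
    dmy[1:, :] = (phi[1:, :] - phi[:-1, :]) / h
    dmy[0, :] = dmy[1, :]
    dpy[:-1, :] = (phi[1:, :] - phi[:-1, :]) / h
    dpy[-1, :] = dpy[-2, :]

    # Outward motion (V > 0) uses max(D-,0), min(D+,0); inward the reverse.
    plus = np.sqrt(
        np.maximum(dmx, 0.0) ** 2 + np.minimum(dpx, 0.0) ** 2
        + np.maximum(dmy, 0.0) ** 2 + np.minimum(dpy, 0.0) ** 2
    )
    minus = np.sqrt(
        np.minimum(dmx, 0.0) ** 2 + np.maximum(dpx, 0.0) ** 2
        + np.minimum(dmy, 0.0) ** 2 + np.maximum(dpy, 0.0) ** 2
    )
    return np.where(V > 0.0, plus, minus)


def advance_levelset(field: LevelSetField, V_grid: np.ndarray, dt: float,
                     cfl: float = 0.5) -> LevelSetField:
    """One explicit upwind step of phi_t + V |grad phi| = 0.

    ``V_grid`` is the normal speed (um per unit of ``dt``) defined on grid
    nodes; it only needs to be meaningful in a band around the zero contour
    and should be extended off the membrane (see
    :func:`matesim.polarity.extend_velocity`).  The step is refused if it
    violates the CFL constraint ``max|V| dt <= cfl * h``.
    """
    vmax = float(np.max(np.abs(V_grid))) if V_grid.size else 0.0
    if vmax * dt > cfl * field.grid.h * (1 + 1e-12):
        dt_req = cfl * field.grid.h / vmax
        raise CFLViolationError(
            f"level-set CFL violated: max|V|*dt = {vmax * dt:.3g} > "
            f"{cfl}*h = {cfl * field.grid.h:.3g}; require dt <= {dt_req:.3g}",
            dt_required=dt_req,
        )
    if vmax == 0.0:
        return field.copy()
    gnorm = _upwind_gradient_norm(field.phi, V_grid, field.grid.h)
    return LevelSetField(field.grid, field.phi - dt * V_grid * gnorm, field.cell_id)


def zero_contours(field: LevelSetField) -> list[np.ndarray]:
    """All zero contours as (m, 2) arrays of (x, y) points in micrometres."""
    segs = measure.find_contours(field.phi, 0.0)
    out = []
    for s in segs:
        xy = np.column_stack(
            (field.grid.x_min + s[:, 1] * field.grid.h,
             field.grid.y_min + s[:, 0] * field.grid.h)
        )
        out.append(xy)
    return out


def _densify(polyline: np.ndarray, max_seg: float) -> np.ndarray:
    """Insert points so that no segment of the polyline exceeds ``max_seg``."""
    p = polyline
    d = np.hypot(*(p[1:] - p[:-1]).T)
    nsub = np.maximum(1, np.ceil(d / max_seg).astype(int))
    pieces = []
    for i in range(len(p) - 1):
        t = np.linspace(0.0, 1.0, nsub[i], endpoint=False)
        pieces.append(p[i] + t[:, None] * (p[i + 1] - p[i]))
    pieces.append(p[-1:])
    return np.concatenate(pieces, axis=0)


def reinitialize_signed_distance(field: LevelSetField,
                                 band_width: float | None = None) -> LevelSetField:
    """Rebuild phi as the signed distance to its current zero contour.

    The contour is extracted by marching squares (which uses linear
    interpolation of phi along grid edges, so the zero crossing is preserved
    to O(h^2)), densified, and the distance of every node to the contour
    point cloud is computed with a KD-tree.  The sign is inherited from the
    input field, so the zero contour moves by far less than h/2.

    With ``band_width`` set, only nodes inside the bounding box of the
    contour padded by ``band_width`` are recomputed (the far field keeps its
    current values); every node within ``band_width`` of the interface lies
    in that box, and the simulation driver reads phi only near interfaces.
    """
    curves = zero_contours(field)
    if not curves:
        raise InterfaceVanishedError(
            f"cell {field.cell_id!r}: level set has no zero contour"
        )
    h = field.grid.h
    pts = np.concatenate([_densify(c, max_seg=h / 6.0) for c in curves], axis=0)
    tree = cKDTree(pts)
    X, Y = field.grid.meshgrid()
    if band_width is None:
        nodes = np.column_stack((X.ravel(), Y.ravel()))
        dist, _ = tree.query(nodes, k=1)
        sign = np.sign(field.phi.ravel())
        sign[sign == 0.0] = 1.0
        phi = (dist * sign).reshape(field.grid.shape)
    else:
        lo = pts.min(axis=0) - band_width
        hi = pts.max(axis=0) + band_width
        sel = (X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1])
        nodes = np.column_stack((X[sel], Y[sel]))
        dist, _ = tree.query(nodes, k=1)
        sign = np.sign(field.phi[sel])
        sign[sign == 0.0] = 1.0
        phi = field.phi.copy()
        phi[sel] = dist * sign
    return LevelSetField(field.grid, phi, field.cell_id)
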