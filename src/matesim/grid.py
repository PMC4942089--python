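"""Uniform Cartesian grid for the 2D computational domain.

All coordinates are in micrometres.  Scalar fields live on grid *nodes* and
are stored as arrays of shape ``(ny, nx)`` indexed ``[iy, ix]`` so that
``values[iy, ix]`` is the value at ``(x_min + ix*h, y_min + iy*h)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Axis-aligned rectangular domain with uniform node spacing ``h``.

    The domain extents must be integer multiples of ``h`` so that node
    coordinates are exactly reproducible from the bounds and the spacing.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    h: float = 0.04

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"grid spacing h must be positive, got {self.h}")
        for lo, hi, name in (
            (self.x_min, self.x_max, "x"),
            (self.y_min, self.y_max, "y"),
        ):
            if hi <= lo:
                raise ValueError(f"empty {name} extent [{lo}, {hi}]")
            n = (hi - lo) / self.h
            if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
                raise ValueError(
                    f"{name} extent {hi - lo} is not an integer multiple of h={self.h}"
                )

    @property
    def nx(self) -> int:
        return int(round((self.x_max - self.x_min) / self.h)) + 1

    @property
    def ny(self) -> int:
        return int(round((self.y_max - self.y_min) / self.h)) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.h * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y_min + self.h * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` node-coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Elementwise test that ``points`` (shape ``(n, 2)``) lie inside the
        domain shrunk by ``margin`` on every side."""
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.x_min + margin)
            & (p[:, 0] <= self.x_max - margin)
            & (p[:, 1] >= self.y_min + margin)
            & (p[:, 1] <= self.y_max - margin)
        )

    def interp(self, values: np.ndarray, points: np.ndarray,
               weights: np.ndarray | None = None) -> np.ndarray:
        """Bilinear interpolation of a node field at continuous points.

        ``points`` has shape ``(n, 2)`` in (x, y) micrometres.  If ``weights``
        (same shape as ``values``, e.g. a 0/1 mask of admissible nodes) is
        given, the four corner contributions are re-weighted so that masked
        nodes do not contribute; where all four corners are masked the result
        is 0.
        """
        p = np.atleast_2d(points)
        fx = np.clip((p[:, 0] - self.x_min) / self.h, 0.0, self.nx - 1 - 1e-12)
        fy = np.clip((p[:, 1] - self.y_min) / self.h, 0.0, self.ny - 1 - 1e-12)
        ix = fx.astype(np.intp)
        iy = fy.astype(np.intp)
        tx = fx - ix
        ty = fy - iy

        w00 = (1 - tx) * (1 - ty)
        w10 = tx * (1 - ty)
        w01 = (1 - tx) * ty
        w11 = tx * ty

        v00 = values[iy, ix]
        v10 = values[iy, ix + 1]
        v01 = values[iy + 1, ix]
        v11 = values[iy + 1, ix + 1]

        if weights is None:
            return w00 * v00 + w10 * v10 + w01 * v01 + w11 * v11

        m00 = weights[iy, ix]
        m10 = weights[iy, ix + 1]
        m01 = weights[iy + 1, ix]
        m11 = weights[iy + 1, ix + 1]
        num = w00 * m00 * v00 + w10 * m10 * v10 + w01 * m01 * v01 + w11 * m11 * v11
        den = w00 * m00 + w10 * m10 + w01 * m01 + w11 * m11
        out = np.zeros_like(num)
        ok = den > 1e-12
        out[ok] = num[ok] / den[ok]
        return out

    def gradient(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Central-difference gradient ``(d/dx, d/dy)`` with one-sided stencils
        at the domain boundary."""
        gy, gx = np.gradient(values, self.h)
        return gx, gy
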