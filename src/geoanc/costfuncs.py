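"""Cost-function algebra for generalized-parsimony migration fits.

A node's minimum migration cost function maps a candidate location ``x`` to
the smallest total migration cost over the tree achievable with the node
pinned at ``x``.  Three closed families are supported, one per cost model:

* :class:`DiscreteCost` — a vector over grid cells (arbitrary transition-cost
  matrix, the Sankoff setting);
* :class:`Quadratic1D` — ``a (x - m)^2 + c`` per axis (squared-Euclidean
  distance costs);
* :class:`PWL1D` — a convex piecewise-linear function per axis (Manhattan
  distance costs).

Each family is closed under the three operations the dynamic programme
needs: pointwise addition, positive scaling, and min-plus convolution with a
single-branch migration-cost kernel of weight ``w``:

    (K_w ⊗ f)(x) = min_y  w * d(x, y) + f(y)

where ``d`` is the transition cost (matrix entry, squared difference, or
absolute difference).  Sampled leaves are represented by :class:`PointCost`
(continuous) or a 0/inf indicator vector (discrete).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscreteCost",
    "Quadratic1D",
    "PWL1D",
    "SeparableCost",
    "PointCost",
    "discrete_pin",
]


# ---------------------------------------------------------------------------
# Discrete (Sankoff) cost vectors


@dataclass
class DiscreteCost:
    """Minimum migration cost of a node as a vector over grid cells."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    def add(self, other: "DiscreteCost") -> "DiscreteCost":
        return DiscreteCost(self.values + other.values)

    def scale(self, s: float) -> "DiscreteCost":
        return DiscreteCost(self.values * s)

    def convolve(self, cost_matrix: np.ndarray, w: float,
                 transpose: bool = False) -> "DiscreteCost":
        """Min-plus convolution: result[x] = min_y w*C[x, y] + f[y].

        ``transpose`` evaluates min over the first matrix index instead,
        which is what the outside (rootward-to-tipward) pass needs when the
        cost matrix is asymmetric.
        """
        C = cost_matrix.T if transpose else cost_matrix
        return DiscreteCost(np.min(w * C + self.values[np.newaxis, :], axis=1))

    def evaluate(self, state: int) -> float:
        return float(self.values[state])

    def minimize(self) -> tuple[float, np.ndarray]:
        """Return (min value, array of minimizing cell ids)."""
        vmin = float(np.min(self.values))
        return vmin, np.flatnonzero(self.values == vmin)


def discrete_pin(state: int, n_states: int) -> DiscreteCost:
    """Indicator cost vector for a sampled node: 0 at its cell, inf elsewhere."""
    v = np.full(n_states, np.inf)
    v[state] = 0.0
    return DiscreteCost(v)


# ---------------------------------------------------------------------------
# Quadratic (squared-Euclidean) cost functions, one axis


@dataclass
class Quadratic1D:
    """f(x) = a*(x - m)^2 + c with a >= 0; a == 0 encodes a constant."""

    a: float
    m: float
    c: float

    def add(self, other: "Quadratic1D") -> "Quadratic1D":
        a = self.a + other.a
        if a == 0.0:
            return Quadratic1D(0.0, 0.0, self.c + other.c)
        m = (self.a * self.m + other.a * other.m) / a
        c = (self.c + other.c
             + self.a * (m - self.m) ** 2
             + other.a * (m - other.m) ** 2)
        return Quadratic1D(a, m, c)

    def scale(self, s: float) -> "Quadratic1D":
        return Quadratic1D(self.a * s, self.m, self.c * s)

    def convolve(self, w: float) -> "Quadratic1D":
        """min_y w*(x-y)^2 + f(y): curvature shrinks to a*w/(a+w)."""
        if self.a == 0.0:
            return Quadratic1D(0.0, self.m, self.c)
        return Quadratic1D(self.a * w / (self.a + w), self.m, self.c)

    def evaluate(self, x):
        return self.a * (np.asarray(x, dtype=float) - self.m) ** 2 + self.c

    def minimize(self) -> tuple[float, tuple[float, float]]:
        """Return (min value, argmin interval); a point interval unless flat."""
        if self.a == 0.0:
            return self.c, (-np.inf, np.inf)
        return self.c, (self.m, self.m)


# ---------------------------------------------------------------------------
# Convex piecewise-linear (Manhattan) cost functions, one axis


@dataclass
class PWL1D:
    """Convex piecewise-linear function of one coordinate.

    ``xs`` are sorted breakpoints (possibly empty for a constant), ``slopes``
    has ``len(xs) + 1`` entries, non-decreasing; segment ``i`` covers
    ``(xs[i-1], xs[i])``.  ``y0`` is the value at ``xs[0]`` (or the constant
    value when there are no breakpoints).
    """

    xs: np.ndarray
    slopes: np.ndarray
    y0: float

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.slopes.shape[0] != self.xs.shape[0] + 1:
            raise ValueError("need len(xs) + 1 slopes")
        if np.any(np.diff(self.slopes) < 0):
            raise ValueError("slopes must be non-decreasing (convexity)")

    @classmethod
    def constant(cls, c: float) -> "PWL1D":
        return cls(np.empty(0), np.zeros(1), float(c))

    @classmethod
    def abs_kernel(cls, w: float, p: float) -> "PWL1D":
        """w * |x - p|: the single-branch Manhattan kernel to a pinned point."""
        return cls(np.array([p]), np.array([-w, w]), 0.0)

    # -- internals ---------------------------------------------------------

    def _breakpoint_values(self) -> np.ndarray:
        if self.xs.size == 0:
            return np.empty(0)
        steps = self.slopes[1:-1] * np.diff(self.xs)
        return self.y0 + np.concatenate([[0.0], np.cumsum(steps)])

    def _slope_at(self, x: float) -> float:
        return float(self.slopes[np.searchsorted(self.xs, x, side="left")])

    # -- algebra -----------------------------------------------------------

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        if self.xs.size == 0:
            return np.full_like(x, self.y0)
        ys = self._breakpoint_values()
        idx = np.searchsorted(self.xs, x, side="left")
        anchor = self.xs[np.maximum(idx - 1, 0)]
        yanchor = ys[np.maximum(idx - 1, 0)]
        out = yanchor + self.slopes[idx] * (x - anchor)
        # points left of the first breakpoint anchor on xs[0] instead
        left = idx == 0
        if np.any(left):
            out = np.where(left, ys[0] + self.slopes[0] * (x - self.xs[0]), out)
        return out

    def add(self, other: "PWL1D") -> "PWL1D":
        if self.xs.size == 0:
            return PWL1D(other.xs, other.slopes, other.y0 + self.y0)
        if other.xs.size == 0:
            return PWL1D(self.xs, self.slopes, self.y0 + other.y0)
        X = np.unique(np.concatenate([self.xs, other.xs]))
        # slope of the sum on each of the len(X)+1 open segments
        probes = np.concatenate([[X[0] - 1.0],
                                 (X[:-1] + X[1:]) / 2.0,
                                 [X[-1] + 1.0]])
        s = (self.slopes[np.searchsorted(self.xs, probes, side="left")]
             + other.slopes[np.searchsorted(other.xs, probes, side="left")])
        y0 = float(self.evaluate(X[0]) + other.evaluate(X[0]))
        return _pruned(X, s, y0)

    def scale(self, s: float) -> "PWL1D":
        if s < 0:
            raise ValueError("scale factor must be nonnegative")
        if s == 0:
            return PWL1D.constant(0.0)
        return PWL1D(self.xs, self.slopes * s, self.y0 * s)

    def convolve(self, w: float) -> "PWL1D":
        """Infimal convolution with w*|x - y|: clamp slopes to [-w, w].

        The result equals f on the region where |f'| <= w and extends
        linearly with slope -w / +w outside it.
        """
        if self.xs.size == 0:
            return PWL1D(self.xs, self.slopes, self.y0)
        if self.slopes[0] > 0 or self.slopes[-1] < 0:
            raise ValueError("convolution requires an attained minimum "
                             "(slopes must straddle zero)")
        s = np.clip(self.slopes, -w, w)
        keep = s[1:] != s[:-1]
        if not np.any(keep):
            return PWL1D.constant(float(self.evaluate(self.xs[0])))
        xs = self.xs[keep]
        slopes = np.concatenate([s[:1], s[1:][keep]])
        # kept breakpoints lie where the clamped function coincides with f
        return PWL1D(xs, slopes, float(self.evaluate(xs[0])))

    def minimize(self) -> tuple[float, tuple[float, float]]:
        if self.xs.size == 0:
            return self.y0, (-np.inf, np.inf)
        ys = self._breakpoint_values()
        ymin = float(np.min(ys))
        sel = np.flatnonzero(ys == ymin)
        lo, hi = self.xs[sel[0]], self.xs[sel[-1]]
        if self.slopes[0] == 0.0 and ys[0] == ymin:
            lo = -np.inf
        if self.slopes[-1] == 0.0 and ys[-1] == ymin:
            hi = np.inf
        return ymin, (float(lo), float(hi))


def _pruned(X: np.ndarray, slopes: np.ndarray, y0: float) -> PWL1D:
    """Drop breakpoints where the slope does not change."""
    keep = slopes[1:] != slopes[:-1]
    if not np.any(keep):
        return PWL1D.constant(y0)
    xs = X[keep]
    s = np.concatenate([slopes[:1], slopes[1:][keep]])
    # anchor value must be re-evaluated at the first kept breakpoint
    f = PWL1D(X, slopes, y0)
    return PWL1D(xs, s, float(f.evaluate(xs[0])))


# ---------------------------------------------------------------------------
# Two-dimensional wrappers


@dataclass
class SeparableCost:
    """A 2-D cost function that is a sum of independent per-axis functions.

    Both the squared-Euclidean and the Manhattan migration costs separate by
    axis, so every node cost function in the continuous modes has this form.
    """

    fx: object
    fy: object

    def add(self, other: "SeparableCost") -> "SeparableCost":
        return SeparableCost(self.fx.add(other.fx), self.fy.add(other.fy))

    def scale(self, s: float) -> "SeparableCost":
        return SeparableCost(self.fx.scale(s), self.fy.scale(s))

    def convolve(self, w: float) -> "SeparableCost":
        return SeparableCost(self.fx.convolve(w), self.fy.convolve(w))

    def evaluate(self, x, y):
        return self.fx.evaluate(x) + self.fy.evaluate(y)

    def minimize(self):
        """Return (min value, ((xlo, xhi), (ylo, yhi)) argmin box)."""
        vx, ix = self.fx.minimize()
        vy, iy = self.fy.minimize()
        return vx + vy, (ix, iy)


@dataclass
class PointCost:
    """Degenerate cost function of a sampled node: 0 at its own coordinates."""

    x: float
    y: float

    def add(self, other: "PointCost") -> "PointCost":
        if (other.x, other.y) != (self.x, self.y):
            raise ValueError("cannot add point costs at different locations")
        return self

    def scale(self, s: float) -> "PointCost":
        return self

    def minimize(self):
        return 0.0, ((self.x, self.x), (self.y, self.y))
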