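"""Penalized cubic B-spline bases with exact curvature penalties.

The smooth terms of the epoch models are built from cubic B-splines on an
evenly spaced knot grid over the epoch window, penalized by the integrated
squared second derivative.  Because second derivatives of cubic B-splines are
piecewise linear, the penalty integral is evaluated exactly with two-point
Gauss-Legendre quadrature per knot interval.  The penalty's null space is
{constant, linear}, which is what makes "nonlinearity" a testable quantity:
a smooth shrunk to its null space is a straight line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3


@dataclass
class SplineBasis:
    """Cubic B-spline basis on [lo, hi] with a curvature penalty.

    ``k`` is the basis dimension; ``penalty`` the k x k matrix of integrated
    products of second derivatives (symmetric PSD, null space = {1, x}).
    """

    lo: float
    hi: float
    k: int
    knots: np.ndarray
    penalty: np.ndarray

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi - 1e-12 * (self.hi - self.lo))
        return BSpline.design_matrix(x, self.knots, DEGREE).toarray()


def build_penalized_spline_basis(lo: float, hi: float, k: int = 10) -> SplineBasis:
    """Basis of dimension k with evenly spaced interior knots and exact penalty."""
    if k < DEGREE + 1:
        raise ValueError(f"k must be at least {DEGREE + 1}")
    n_interior = k - DEGREE - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (DEGREE + 1), interior, [hi] * (DEGREE + 1)])

    # exact integral of B_i'' * B_j'': integrand is piecewise quadratic, so
    # 2-point Gauss per inter-knot interval is exact
    edges = np.unique(knots)
    g = 1.0 / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        mid, halfw = (a + b) / 2, (b - a) / 2
        pts += [mid - halfw * g, mid + halfw * g]
        wts += [halfw, halfw]
    pts = np.asarray(pts)
    wts = np.asarray(wts)
    eye = np.eye(k)
    d2 = np.empty((pts.size, k))
    for j in range(k):
        d2[:, j] = BSpline(knots, eye[j], DEGREE).derivative(2)(pts)
    S = (d2 * wts[:, None]).T @ d2
    S = (S + S.T) / 2
    return SplineBasis(lo=lo, hi=hi, k=k, knots=knots, penalty=S)


def centering_transform(X: np.ndarray) -> np.ndarray:
    """Orthogonal basis of the sum-to-zero constraint null space.

    Returns Z with k-1 columns such that columns of X @ Z sum to zero over
    the rows of X; used to remove the confounding between a smooth's constant
    and separate intercept terms.
    """
    c = X.sum(axis=0)
    c = c / np.linalg.norm(c)
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(c.size)]))
    return q[:, 1 : c.size]


def centered(basis: SplineBasis, x_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered design/penalty for a smooth evaluated on reference points.

    Returns (Z, X_centered, S_centered) where Z maps centered coefficients
    back to the native basis.
    """
    X = basis.design(x_ref)
    Z = centering_transform(X)
    return Z, X @ Z, Z.T @ basis.penalty @ Z
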