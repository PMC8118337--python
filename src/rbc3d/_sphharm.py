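"""Real orthonormal spherical harmonics on a Gauss-Legendre quadrature grid.

Convention: real orthonormal basis built from the complex harmonics
Y_l^m (Condon-Shortley phase, as provided by scipy):

    m > 0:  sqrt(2) * (-1)^m * Re(Y_l^m)
    m = 0:  Y_l^0
    m < 0:  sqrt(2) * (-1)^m * Im(Y_l^|m|)

With this normalisation  integral(Y_i * Y_j dOmega) = delta_ij,  so
coefficients are a_i = integral(f * Y_i dOmega) and Parseval holds with
no extra factors.

The quadrature grid uses n_theta Gauss-Legendre nodes in cos(theta) and
n_phi equispaced azimuths; it integrates products of two band-limited
functions of degree <= n_theta - 1 exactly (up to rounding), so the
default n_theta = l_max + 1 is exact for analysis of band-limited input.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y


class QuadratureError(ValueError):
    """Raised when the angular grid is too coarse for the requested degree."""


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate one real orthonormal spherical harmonic."""
    if abs(m) > l:
        raise ValueError("|m| must be <= l")
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


class SphericalHarmonicsBasis:
    """Precomputed real-SH analysis/synthesis operators on a fixed grid.

    Parameters
    ----------
    l_max:
        Highest harmonic degree (inclusive).
    n_theta, n_phi:
        Quadrature grid size; defaults (l_max + 1, 2 * l_max + 2) are the
        smallest exact choices.
    """

    def __init__(self, l_max: int, n_theta: int | None = None, n_phi: int | None = None):
        if l_max < 0:
            raise ValueError("l_max must be >= 0")
        n_theta = n_theta or (l_max + 1)
        n_phi = n_phi or (2 * l_max + 2)
        if n_theta < l_max + 1 or n_phi < 2 * l_max + 1:
            raise QuadratureError(
                f"grid {n_theta}x{n_phi} too coarse for exact quadrature to degree {l_max}"
            )
        self.l_max = l_max
        self.n_theta = n_theta
        self.n_phi = n_phi

        nodes, gl_w = np.polynomial.legendre.leggauss(n_theta)
        theta_1d = np.arccos(nodes)
        phi_1d = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
        tt, pp = np.meshgrid(theta_1d, phi_1d, indexing="ij")
        self.theta = tt.ravel()
        self.phi = pp.ravel()
        ww = np.repeat(gl_w, n_phi) * (2 * np.pi / n_phi)
        self.weights = ww
        st = np.sin(self.theta)
        self.dirs = np.column_stack(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )

        self.lm: list[tuple[int, int]] = [
            (l, m) for l in range(l_max + 1) for m in range(-l, l + 1)
        ]
        self._index = {lm: i for i, lm in enumerate(self.lm)}
        Y = np.empty((len(self.lm), self.theta.size))
        for i, (l, m) in enumerate(self.lm):
            Y[i] = real_sph_harm(l, m, self.theta, self.phi)
        self.Y = Y
        self._YW = Y * self.weights  # analysis operator rows

        # least-squares design for fitting a quadratic form n^T Q n on the grid
        x, y, z = self.dirs.T
        M = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])
        self._quad_pinv = np.linalg.pinv(M)

    @property
    def n_coeff(self) -> int:
        return len(self.lm)

    @property
    def n_points(self) -> int:
        return self.theta.size

    def index(self, l: int, m: int) -> int:
        return self._index[(l, m)]

    def analyze(self, samples: np.ndarray) -> np.ndarray:
        """Coefficients a_lm = sum_i w_i f_i Y_lm(x_i).

        *samples* may be (n_points,) or (n_points, k) for batched input.
        """
        samples = np.asarray(samples, dtype=np.float64)
        if samples.shape[0] != self.n_points:
            raise ValueError("samples do not match the quadrature grid")
        return self._YW @ samples

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Evaluate sum a_lm Y_lm on the quadrature grid."""
        coeffs = np.asarray(coeffs, dtype=np.float64)
        return coeffs @ self.Y if coeffs.ndim == 1 else self.Y.T @ coeffs

    def band_energies(self, coeffs: np.ndarray, degrees) -> np.ndarray:
        """L2 norm over m of the degree-l coefficients, per requested degree."""
        out = []
        for l in degrees:
            i0 = self.index(l, -l)
            i1 = self.index(l, l) + 1
            out.append(np.sqrt((coeffs[i0:i1] ** 2).sum(axis=0)))
        return np.array(out)

    def fit_quadratic_form(self, samples_or_coeffs: np.ndarray, from_coeffs: bool = False) -> np.ndarray:
        """Fit the symmetric 3x3 matrix Q with n^T Q n matching samples on the grid.

        Exact whenever the sampled function is a quadratic form restricted
        to the unit sphere (i.e. lives in the l = 0 and l = 2 bands).
        """
        g = self.synthesize(samples_or_coeffs) if from_coeffs else np.asarray(samples_or_coeffs)
        q = self._quad_pinv @ g
        return np.array(
            [[q[0], q[3], q[4]], [q[3], q[1], q[5]], [q[4], q[5], q[2]]]
        )


@lru_cache(maxsize=8)
def get_basis(l_max: int, n_theta: int | None = None, n_phi: int | None = None) -> SphericalHarmonicsBasis:
    return SphericalHarmonicsBasis(l_max, n_theta, n_phi)
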