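"""Analytical potential of a current dipole in an N-shell concentric sphere.

The head is modeled as N nested spherical shells of isotropic conductivity
with an insulating exterior (zero radial current on the outermost boundary).
For a current dipole inside the innermost shell the quasi-static potential is
expanded in Legendre series: in the source shell the potential is the
infinite-homogeneous-medium dipole term plus a regular (r^n) correction; in
every outer shell it is a combination of r^n and r^-(n+1) harmonics.  The
per-degree radial coefficients follow from continuity of potential and of
radial current density across each interface plus the outer Neumann
condition, solved here as one small linear system per degree with per-layer
scaled basis functions (r/R_j)^n and (R_{j-1}/r)^(n+1), whose entries stay
O(n) at every degree — no overflow at high degree, no explicit transfer
products.

Units are SI internally (m, S/m, A*m, V); interfaces accept mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from seegvc.errors import SeriesConvergenceError, UnsupportedConfigurationError

_MM = 1e-3


@dataclass
class ShellModel:
    """Concentric-shell conductor.

    ``radii_mm`` are the shell outer boundaries, innermost first, strictly
    increasing; ``sigma`` the shell conductivities (S/m), innermost first.
    ``n_terms`` bounds the Legendre series degree and ``tol`` is the relative
    tail tolerance at which the series is truncated.
    """

    radii_mm: np.ndarray
    sigma: np.ndarray
    n_terms: int = 200
    tol: float = 1e-10

    def __post_init__(self):
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.radii_mm.ndim != 1 or len(self.radii_mm) != len(self.sigma):
            raise ValueError("radii_mm and sigma must be 1-D of equal length")
        if np.any(np.diff(self.radii_mm) <= 0) or self.radii_mm[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("conductivities must be strictly positive")

    @property
    def n_shells(self) -> int:
        return len(self.radii_mm)


@dataclass
class Dipole:
    """Point current dipole: position (mm) and moment (A*m)."""

    position_mm: np.ndarray
    moment_Am: np.ndarray

    def __post_init__(self):
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.moment_Am = np.asarray(self.moment_Am, dtype=float)


def _shell_coefficients(R: np.ndarray, sig: np.ndarray, b: float, src: np.ndarray, nmax: int):
    """Per-degree radial coefficients for both source modes.

    ``src`` holds the two source strengths [A_rad, A_tan] where the primary
    potential at radius x >= b is  A * f(n) * (b/x)^(n-1) / x^2  with
    f(n) = n for the radial mode and 1 for the tangential mode (the common
    1/(4*pi*sigma_1) is folded into A).  Returns arrays of shape
    (2, N, nmax+1): coefficient of (r/R_j)^n and of (R_{j-1}/r)^(n+1) per
    layer j (0-based), degree n, and mode (0 = radial, 1 = tangential).
    """
    N = len(R)
    M = 2 * N - 1
    ns = np.arange(1, nmax + 1, dtype=float)
    K = len(ns)
    A = np.zeros((K, M, M))
    rhs = np.zeros((K, M, 2))

    # unknown columns: a_1 -> 0 ; for layer j (1-based, j>=2): a_j -> 2j-3, b_j -> 2j-2
    def acol(j):
        return 0 if j == 1 else 2 * j - 3

    def bcol(j):
        return 2 * j - 2  # only j >= 2

    u = b / R[0]
    # primary term and derivative at x, scaled: S(x) = amp * (b/x)^(n-1) / x^2
    # with amp = src[mode] * f(n).  S'(x) = -(n+1)/x * S(x).
    def S_at(x):
        ratio = np.where(ns == 1.0, 1.0, (b / x) ** (ns - 1.0)) / x**2
        return np.stack([src[0] * ns * ratio, src[1] * ratio], axis=-1)  # (K, 2)

    row = 0
    for i in range(1, N):  # interface at R_i (1-based layer i | i+1)
        X = R[i - 1]
        # continuity of potential
        A[:, row, acol(i)] += 1.0  # (X/R_i)^n = 1
        if i >= 2:
            A[:, row, bcol(i)] += (R[i - 2] / X) ** (ns + 1.0)
        A[:, row, acol(i + 1)] -= (X / R[i]) ** ns
        A[:, row, bcol(i + 1)] -= 1.0  # (X/X)^(n+1)
        if i == 1:
            rhs[:, row, :] -= S_at(X)
        row += 1
        # continuity of radial current, scaled by X
        A[:, row, acol(i)] += sig[i - 1] * ns
        if i >= 2:
            A[:, row, bcol(i)] += sig[i - 1] * (-(ns + 1.0)) * (R[i - 2] / X) ** (ns + 1.0)
        A[:, row, acol(i + 1)] -= sig[i] * ns * (X / R[i]) ** ns
        A[:, row, bcol(i + 1)] -= sig[i] * (-(ns + 1.0))
        if i == 1:
            rhs[:, row, :] -= sig[0] * (-(ns[:, None] + 1.0)) * S_at(X)
        row += 1
    # outer boundary: zero radial current at R_N
    X = R[-1]
    A[:, row, acol(N)] += ns
    if N >= 2:
        A[:, row, bcol(N)] += (-(ns + 1.0)) * (R[-2] / X) ** (ns + 1.0)
    else:
        rhs[:, row, :] -= (-(ns[:, None] + 1.0)) * S_at(X)
    sol = np.linalg.solve(A, rhs)  # (K, M, 2)

    a = np.zeros((2, N, nmax + 1))
    bc = np.zeros((2, N, nmax + 1))
    for j in range(1, N + 1):
        a[:, j - 1, 1:] = sol[:, acol(j), :].T
        if j >= 2:
            bc[:, j - 1, 1:] = sol[:, bcol(j), :].T
    return a, bc


def _infinite_medium(dipole_m: np.ndarray, moment: np.ndarray, sigma: float, pts: np.ndarray):
    d = pts - dipole_m
    r3 = np.linalg.norm(d, axis=1) ** 3
    return (d @ moment) / (4.0 * np.pi * sigma * r3)


def analytic_dipole_potential(
    model: ShellModel, dipole: Dipole, points_mm: np.ndarray
) -> np.ndarray:
    """Potential (V) at interior/surface field points for a dipole in the
    innermost shell.

    Absolute potential with the primary term referenced at infinity; only
    differences are physically meaningful under the insulating boundary.
    Raises :class:`UnsupportedConfigurationError` for dipoles outside the
    innermost shell or points outside the conductor, and
    :class:`SeriesConvergenceError` when the Legendre tail estimate does not
    fall below ``model.tol`` within ``model.n_terms`` degrees.
    """
    R = model.radii_mm * _MM
    sig = model.sigma
    N = model.n_shells
    p0 = dipole.position_mm * _MM
    m = dipole.moment_Am.astype(float)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * _MM
    b = float(np.linalg.norm(p0))
    if b >= R[0]:
        raise UnsupportedConfigurationError(
            "dipole must lie strictly inside the innermost shell"
        )
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > R[-1] * (1 + 1e-9) + 1e-12):
        raise UnsupportedConfigurationError("field points outside the outer boundary")
    if np.any(np.linalg.norm(pts - p0, axis=1) < 1e-12):
        raise UnsupportedConfigurationError("field point coincides with the dipole")

    mnorm = float(np.linalg.norm(m))
    if mnorm == 0.0:
        return np.zeros(len(pts))

    # source-aligned frame
    if b > 0:
        zhat = p0 / b
    else:
        zhat = m / mnorm
    m_r = float(m @ zhat)
    mt_vec = m - m_r * zhat
    mt = float(np.linalg.norm(mt_vec))
    xhat = mt_vec / mt if mt > 0 else np.zeros(3)

    fourpi_s1 = 4.0 * np.pi * sig[0]
    src = np.array([m_r / fourpi_s1, mt / fourpi_s1])

    nmax = int(model.n_terms)
    a, bc = _shell_coefficients(R, sig, b, src, nmax)

    # layer of each point: r <= R[0] -> 0, (R[j-1], R[j]] -> j
    layer = np.searchsorted(R, r * (1 - 1e-12), side="left")
    layer = np.minimum(layer, N - 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        phat = np.where(r[:, None] > 0, pts / np.where(r[:, None] > 0, r[:, None], 1.0), 0.0)
    uu = np.clip(phat @ zhat, -1.0, 1.0)
    w = phat @ xhat

    R_out = R[layer]
    R_in = np.where(layer >= 1, R[np.maximum(layer - 1, 0)], 0.0)
    ratio_f = r / R_out
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_g = np.where((layer >= 1) & (r > 0), R_in / np.maximum(r, 1e-300), 0.0)

    # Legendre recurrences and running series
    k = len(pts)
    V = np.zeros(k)
    P_nm1 = np.ones(k)  # P_0
    P_n = uu.copy()  # P_1
    dP_nm1 = np.zeros(k)  # P_0'
    dP_n = np.ones(k)  # P_1'
    pf = ratio_f.copy()  # (r/R_j)^n at n=1
    pg = ratio_g**2  # (R_{j-1}/r)^(n+1) at n=1
    below = 0
    tail = np.inf
    converged = False
    for n in range(1, nmax + 1):
        ar = a[0, layer, n]
        br = bc[0, layer, n]
        at = a[1, layer, n]
        bt = bc[1, layer, n]
        term = (ar * pf + br * pg) * P_n + (at * pf + bt * pg) * w * dP_n
        V += term
        scale = max(float(np.max(np.abs(V))), 1e-290)
        tail = float(np.max(np.abs(term))) / scale
        if tail < model.tol:
            below += 1
            if below >= 3:
                converged = True
                break
        else:
            below = 0
        if n < nmax:
            P_np1 = ((2 * n + 1) * uu * P_n - n * P_nm1) / (n + 1)
            dP_np1 = dP_nm1 + (2 * n + 1) * P_n
            P_nm1, P_n = P_n, P_np1
            dP_nm1, dP_n = dP_n, dP_np1
            pf *= ratio_f
            pg *= ratio_g
    if not converged:
        raise SeriesConvergenceError(
            f"Legendre series tail {tail:.2e} above tol {model.tol:.1e} "
            f"after {nmax} terms",
            tail=tail,
        )

    # primary (infinite-medium) term for points in the source shell
    in_src = layer == 0
    if in_src.any():
        V[in_src] += _infinite_medium(p0, m, sig[0], pts[in_src])
    return V


def rdm_mag(v_ref: np.ndarray, v_test: np.ndarray) -> tuple[float, float]:
    """Relative difference measure and magnitude ratio of two potential vectors.

    RDM = || v_test/||v_test|| - v_ref/||v_ref|| ||  in [0, 2] (shape error);
    MAG = ||v_test|| / ||v_ref||  (amplitude error; 1 is perfect).
    """
    v_ref = np.asarray(v_ref, dtype=float)
    v_test = np.asarray(v_test, dtype=float)
    if v_ref.shape != v_test.shape or v_ref.ndim != 1 or len(v_ref) < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    nr = np.linalg.norm(v_ref)
    if nr == 0:
        raise ValueError("reference vector has zero norm")
    nt = np.linalg.norm(v_test)
    if nt == 0:
        raise ValueError("test vector has zero norm")
    rdm = float(np.linalg.norm(v_test / nt - v_ref / nr))
    return rdm, float(nt / nr)
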