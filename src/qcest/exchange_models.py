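"""Exchange networks: sites plus a first-order kinetic rate matrix.

A network couples N sites, each carrying a quadrupolar tensor orientation and
an equilibrium population.  The kinetic matrix K follows the generator
convention for population-like vectors: the off-diagonal element K[i, j] is
the rate of the jump j -> i (s^-1) and every column sums to zero, so that
dp/dt = K p conserves total population and K p_eq = 0.

Built-in models:

* ``two_site_flip`` -- slow rotameric flip reorienting the tensor by a fixed
  jump angle (DMS: 106 degrees between the two methyl-axis orientations).
* ``methyl_three_site`` -- fast methyl jumps among three equivalent cone
  positions.
* ``sphere_diffusion_plus_bound`` -- free-state isotropic rotational
  diffusion discretized on a near-uniform spherical grid, exchanging with a
  single rigid bound state (amyloid-fibril N-terminal domain model).

The exchange rate constant convention is k_ex = sum of the forward and
reverse inter-state rate constants (for the 2-site flip k_ex = 2 k_flip at
equal populations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .spin_core import QuadrupolarTensor, rotation_zyz

__all__ = [
    "Site",
    "ExchangeNetwork",
    "two_site_flip",
    "methyl_three_site",
    "sphere_diffusion_plus_bound",
    "MODEL_BUILDERS",
]


@dataclass(frozen=True)
class Site:
    tensor: QuadrupolarTensor
    population: float

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("population must be non-negative")


class ExchangeNetwork:
    """Ordered sites plus an N x N kinetic generator (column sums zero)."""

    def __init__(self, sites: list[Site], rates: np.ndarray):
        rates = np.asarray(rates, dtype=float)
        n = len(sites)
        if rates.shape != (n, n):
            raise ValueError("rates matrix must be N x N")
        pops = np.array([s.population for s in sites])
        if abs(pops.sum() - 1.0) > 1e-8:
            raise ValueError("site populations must sum to 1")
        off = rates - np.diag(np.diag(rates))
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        colsum = np.abs(rates.sum(axis=0)).max()
        scale = max(np.abs(rates).max(), 1.0)
        if colsum > 1e-9 * scale:
            raise ValueError("rate-matrix columns must sum to zero")
        self.sites = list(sites)
        self.rates = rates

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.sites])

    def scaled_tensors(self) -> np.ndarray:
        """(N, 3, 3) stack of scaled Cartesian tensors (crystallite frame)."""
        return np.array([s.tensor.scaled_cartesian() for s in self.sites])

    def check_detailed_balance(self, tol: float = 1e-9) -> bool:
        p = self.populations
        flux = self.rates * p[None, :]
        return bool(np.allclose(flux, flux.T, rtol=tol, atol=tol * max(np.abs(flux).max(), 1e-300)))


def _closed_columns(off: np.ndarray) -> np.ndarray:
    k = off.copy()
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=0))
    return k


def two_site_flip(
    cq_eff: float,
    eta: float,
    jump_angle: float,
    k_flip: float,
    populations: tuple[float, float] = (0.5, 0.5),
) -> ExchangeNetwork:
    """Two-site flip: tensor z axes subtend ``jump_angle``.

    k_flip is the flip rate constant at equal populations; the total exchange
    rate is k_ex = 2 k_flip.  For unequal populations the forward and reverse
    rates are k_ex p2 and k_ex p1 (detailed balance).
    """
    p1, p2 = populations
    if p1 < 0 or p2 < 0 or abs(p1 + p2 - 1.0) > 1e-8:
        raise ValueError("populations must be non-negative and sum to 1")
    half = jump_angle / 2.0
    sites = [
        Site(QuadrupolarTensor(cq_eff, eta, (0.0, +half, 0.0)), p1),
        Site(QuadrupolarTensor(cq_eff, eta, (0.0, -half, 0.0)), p2),
    ]
    k_ex = 2.0 * k_flip
    off = np.array([[0.0, k_ex * p1], [k_ex * p2, 0.0]])
    return ExchangeNetwork(sites, _closed_columns(off))


def methyl_three_site(
    cq_static: float, k3: float, cone_angle: float = np.deg2rad(109.47)
) -> ExchangeNetwork:
    """Three equally populated sites on a cone, all pairwise jump rates k3."""
    if k3 < 0:
        raise ValueError("k3 must be non-negative")
    sites = [
        Site(
            QuadrupolarTensor(cq_static, 0.0, (2 * np.pi * k / 3.0, cone_angle, 0.0)),
            1.0 / 3.0,
        )
        for k in range(3)
    ]
    off = k3 * (np.ones((3, 3)) - np.eye(3))
    return ExchangeNetwork(sites, _closed_columns(off))


def flip_with_explicit_methyl(
    cq_static: float,
    jump_angle: float,
    k_flip: float,
    k3: float,
    cone_angle: float = np.deg2rad(109.47),
) -> ExchangeNetwork:
    """Two-site flip with the fast methyl 3-site jumps as an explicit frame.

    Six sites (flip state x methyl position) carrying the static tensor on the
    methyl cone; methyl jumps at k3 within each flip state, flips at k_flip
    between matching methyl positions.  In the fast-k3 limit this reduces to
    ``two_site_flip`` built with the cone-averaged tensor.
    """
    from .spin_core import _euler_from_matrix, rotation_zyz

    half = jump_angle / 2.0
    sites = []
    for sgn in (+1.0, -1.0):
        for m in range(3):
            r = (
                rotation_zyz(0.0, sgn * half)
                @ rotation_zyz(2 * np.pi * m / 3.0, cone_angle)
            )
            sites.append(
                Site(QuadrupolarTensor(cq_static, 0.0, _euler_from_matrix(r)), 1.0 / 6.0)
            )
    off = np.zeros((6, 6))
    for f in range(2):
        for a in range(3):
            for b in range(3):
                if a != b:
                    off[3 * f + a, 3 * f + b] = k3
    for m in range(3):
        off[m, 3 + m] = off[3 + m, m] = k_flip
    return ExchangeNetwork(sites, _closed_columns(off))


def spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n)
    z = -1.0 + (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _surface_generator(points: np.ndarray, d_coeff: float) -> np.ndarray:
    """Symmetric jump generator approximating isotropic rotational diffusion.

    Nearest-neighbour adjacency comes from the convex hull (spherical
    Delaunay); per-edge rates D / d^2 (d = arc length) are rescaled globally
    so that the initial-slope relaxation rate of the rank-2 orientational
    correlation function equals exactly 6 D.
    """
    n = len(points)
    hull = ConvexHull(points)
    off = np.zeros((n, n))
    for simplex in hull.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            if off[i, j] == 0.0:
                d = np.arccos(np.clip(points[i] @ points[j], -1.0, 1.0))
                off[i, j] = off[j, i] = d_coeff / d**2
    k = _closed_columns(off)
    # rank-2 initial slope: r2 = -(1/n) sum_{s,s'} P2(u_s . u_s') K[s', s]
    cosij = np.clip(points @ points.T, -1.0, 1.0)
    p2 = 0.5 * (3.0 * cosij**2 - 1.0)
    r2 = -(p2 * k.T).sum() / n
    if r2 <= 0:
        raise RuntimeError("degenerate surface generator")
    return k * (6.0 * d_coeff / r2)


def sphere_diffusion_plus_bound(
    d_coeff: float,
    n_surface: int = 192,
    cq_free: float = 55.3e3,
    cq_bound: float = 55.3e3,
    k_ex: float = 0.0,
    p_bound: float = 0.08,
) -> ExchangeNetwork:
    """Isotropic diffusion on a sphere plus one rigid bound state.

    Surface sites carry equal populations (1 - p_bound)/n_surface with the
    tensor z axis along the site direction; the bound site (population
    p_bound) exchanges with every surface site with uniform on/off rates such
    that k_ex = k_on + k_off and k_on/k_off = p_bound/(1 - p_bound).
    """
    if not 0.0 < p_bound < 1.0:
        raise ValueError("p_bound must lie in (0, 1)")
    if n_surface < 12:
        raise ValueError("n_surface must be >= 12")
    pts = spiral_points(n_surface)
    k_surf = _surface_generator(pts, d_coeff)
    n = n_surface + 1
    off = np.zeros((n, n))
    off[:n_surface, :n_surface] = k_surf - np.diag(np.diag(k_surf))
    p_site = (1.0 - p_bound) / n_surface
    if k_ex > 0:
        off[n_surface, :n_surface] = k_ex * p_bound  # surface -> bound
        off[:n_surface, n_surface] = k_ex * p_site  # bound -> each surface site
    sites = []
    for u in pts:
        beta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
        alpha = float(np.arctan2(u[1], u[0]))
        sites.append(Site(QuadrupolarTensor(cq_free, 0.0, (alpha, beta, 0.0)), p_site))
    sites.append(Site(QuadrupolarTensor(cq_bound, 0.0, (0.0, 0.0, 0.0)), p_bound))
    return ExchangeNetwork(sites, _closed_columns(off))


#: builders addressable by name from configuration files
MODEL_BUILDERS = {
    "two_site_flip": two_site_flip,
    "methyl_three_site": methyl_three_site,
    "sphere_diffusion_plus_bound": sphere_diffusion_plus_bound,
}
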