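"""Liouvillian construction and propagation through the saturation period.

The density operator is expanded in the direct product {8 coherences} x
{N sites}; the state vector additionally carries one constant unit slot so
that the inhomogeneous Bloch-McConnell-style return of Zeeman order to its
site equilibrium becomes a plain matrix exponential (augmented-matrix form).
State ordering is site-major: element 8*i + a is coherence a of site i, with
coherence order (Sx, Sy, Jx, Jy, Jz, K, Sz, Q); the last element is the
constant slot.

Propagation over the saturation period follows the rotor-synchronized scheme:
the one-rotor-period propagator is a time-ordered product of n_rotor_steps
(default 20) matrix exponentials with the quadrupolar frequency held at its
mid-step value, exchange and coherent parts exponentiated together.  Times
that are not an integer number of rotor periods get an extra fractional-period
factor built from the same sub-step machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .exchange_models import ExchangeNetwork
from .spin_core import (
    CrystalliteOrientation,
    build_basis,
    quad_frequencies_mas,
)

__all__ = [
    "ExperimentParams",
    "SZ",
    "coherent_superoperators",
    "thermal_state",
    "build_liouvillian",
    "rotor_propagator",
    "evolve_saturation",
    "saturate",
    "total_sz",
]

#: index of the Sz coherence within a site block
SZ = 6
_SQ = (0, 1, 2, 3)  # single-quantum coherence indices


def coherent_superoperators() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """8x8 real commutator superoperators (A_Q, A_RF, A_Z).

    The coherent Liouvillian of one site is
    L = wQ * A_Q + wRF * A_RF + Omega * A_Z (all rad/s), i.e. the matrices
    are the commutator superoperators of sqrt(2/3) Q, sqrt(2) Sx and
    sqrt(2) Sz projected on the trace-orthonormal basis.
    """
    basis = build_basis().as_array()
    gens = (
        np.sqrt(2.0 / 3.0) * basis[7],  # Q
        np.sqrt(2.0) * basis[0],  # Sx
        np.sqrt(2.0) * basis[6],  # Sz
    )
    out = []
    for g in gens:
        # matrix element: Tr(O_a^dagger (-i)[G, O_b]); O_a Hermitian
        comm = g @ basis - basis @ g
        a = -1j * np.einsum("aij,bji->ab", basis, comm)
        if np.abs(a.imag).max() > 1e-12:
            raise RuntimeError("superoperator not real")
        out.append(np.ascontiguousarray(a.real))
    return tuple(out)


_A_Q, _A_RF, _A_Z = coherent_superoperators()


@dataclass(frozen=True)
class ExperimentParams:
    """Saturation/detection settings. All frequencies in Hz, times in s."""

    rf_hz: float
    offset_hz: float
    mas_hz: float
    sat_time: float = 0.0
    t1: float | None = None
    t1_mode: str = "all"  # decay applied to all 8 coherences, or "sz" only
    n_rotor_steps: int = 20
    dwell: float | None = None  # detection dwell; default rotor period / steps
    n_points: int = 2048
    apodization_hz: float = 500.0  # decays the default FID to ~2e-3, avoiding truncation ringing

    def __post_init__(self):
        if self.mas_hz < 0:
            raise ValueError("mas_hz must be >= 0")
        if self.n_rotor_steps < 4:
            raise ValueError("n_rotor_steps must be >= 4")
        if self.sat_time < 0:
            raise ValueError("sat_time must be >= 0")
        if self.t1_mode not in ("all", "sz"):
            raise ValueError("t1_mode must be 'all' or 'sz'")

    @property
    def omega_rf(self) -> float:
        return 2 * np.pi * self.rf_hz

    @property
    def offset(self) -> float:
        return 2 * np.pi * self.offset_hz

    @property
    def omega_mas(self) -> float:
        return 2 * np.pi * self.mas_hz

    @property
    def rotor_period(self) -> float:
        if self.mas_hz <= 0:
            raise ValueError("rotor period undefined for static mode")
        return 1.0 / self.mas_hz

    def replace(self, **kw) -> "ExperimentParams":
        return replace(self, **kw)


def _dim(network: ExchangeNetwork) -> int:
    return 8 * network.n_sites + 1


def thermal_state(network: ExchangeNetwork) -> np.ndarray:
    """Thermal start: only Sz populated, site-weighted by populations."""
    v = np.zeros(_dim(network))
    v[SZ::8][: network.n_sites] = network.populations
    v[-1] = 1.0
    return v


def total_sz(state: np.ndarray, network: ExchangeNetwork) -> float:
    """Site-summed Zeeman order (the all-bands detected amplitude)."""
    return float(np.real(state[SZ : 8 * network.n_sites : 8].sum()))


def _static_parts(network: ExchangeNetwork, params: ExperimentParams) -> np.ndarray:
    """Time-independent part of the Liouvillian (dim x dim)."""
    n = network.n_sites
    dim = _dim(network)
    lo = np.zeros((dim, dim))
    base = params.omega_rf * _A_RF + params.offset * _A_Z
    for i in range(n):
        lo[8 * i : 8 * i + 8, 8 * i : 8 * i + 8] = base
    # exchange: couples identical coherences across sites
    kron = np.kron(network.rates, np.eye(8))
    lo[: 8 * n, : 8 * n] += kron
    if params.t1 is not None:
        r1 = 1.0 / params.t1
        if params.t1_mode == "all":
            lo[: 8 * n, : 8 * n] -= r1 * np.eye(8 * n)
        else:
            idx = np.arange(SZ, 8 * n, 8)
            lo[idx, idx] -= r1
        # equilibrium drive for Zeeman order (constant unit slot)
        lo[np.arange(SZ, 8 * n, 8), -1] = r1 * network.populations
    return lo


def _omega_q_of_t(network, params, alphas, betas, times):
    return quad_frequencies_mas(
        network.scaled_tensors(), alphas, betas, np.asarray(times), params.omega_mas
    )


def _liouvillians(
    network: ExchangeNetwork,
    params: ExperimentParams,
    alphas: np.ndarray,
    betas: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Batched Liouvillians, shape (n_orient, n_times, dim, dim)."""
    n = network.n_sites
    dim = _dim(network)
    wq = _omega_q_of_t(network, params, alphas, betas, times)  # (o, t, n)
    lo = np.zeros((len(alphas), len(times), dim, dim))
    lo[:, :] = _static_parts(network, params)
    for i in range(n):
        sl = slice(8 * i, 8 * i + 8)
        lo[:, :, sl, sl] += wq[:, :, i, None, None] * _A_Q
    return lo


def build_liouvillian(
    network: ExchangeNetwork,
    params: ExperimentParams,
    orient: CrystalliteOrientation,
    t: float = 0.0,
) -> np.ndarray:
    """Full Liouvillian at time t for a single crystallite ((8N+1) square)."""
    return _liouvillians(
        network, params, np.array([orient.alpha]), np.array([orient.beta]), np.array([t])
    )[0, 0]


def _step_propagators(network, params, alphas, betas) -> np.ndarray:
    """Per-sub-step propagators over one rotor period, (n_o, n_steps, d, d).

    wQ(t) is evaluated at the mid-point of each sub-step.
    """
    ns = params.n_rotor_steps
    dt = params.rotor_period / ns
    mid = (np.arange(ns) + 0.5) * dt
    lo = _liouvillians(network, params, alphas, betas, mid)
    return expm(lo * dt)


def _ordered_product(steps: np.ndarray) -> np.ndarray:
    """Time-ordered product U = U_{k-1} ... U_1 U_0 along axis 1."""
    u = steps[:, 0]
    for k in range(1, steps.shape[1]):
        u = steps[:, k] @ u
    return u


def _matrix_power_batched(u: np.ndarray, m: int) -> np.ndarray:
    out = np.broadcast_to(np.eye(u.shape[-1]), u.shape).copy()
    base = u.copy()
    while m:
        if m & 1:
            out = base @ out
        m >>= 1
        if m:
            base = base @ base
    return out


def rotor_propagator(
    network: ExchangeNetwork,
    params: ExperimentParams,
    orient: CrystalliteOrientation,
) -> np.ndarray:
    """Evolution matrix over one full rotor period for a single crystallite."""
    steps = _step_propagators(
        network, params, np.array([orient.alpha]), np.array([orient.beta])
    )
    return _ordered_product(steps)[0]


def _fractional_propagator(network, params, alphas, betas, steps, frac):
    """Propagator over the fractional remainder [0, frac) of a rotor period."""
    dim = steps.shape[-1]
    ns = params.n_rotor_steps
    dt = params.rotor_period / ns
    k_full = int(frac / dt + 1e-9)
    rem = frac - k_full * dt
    u = np.broadcast_to(np.eye(dim), (len(alphas), dim, dim)).copy()
    for k in range(k_full):
        u = steps[:, k] @ u
    if rem > 1e-15:
        lo = _liouvillians(
            network, params, alphas, betas, np.array([k_full * dt + rem / 2.0])
        )[:, 0]
        u = expm(lo * rem) @ u
    return u


def saturate(
    network: ExchangeNetwork,
    params: ExperimentParams,
    alphas: np.ndarray,
    betas: np.ndarray,
    sat_times,
    rho0: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate the thermal state through saturation for many crystallites.

    Returns states of shape (n_sat_times, n_orient, dim).  Per-orientation
    computation is pure and the reduction order fixed, so results do not
    depend on execution order.
    """
    sat_times = np.atleast_1d(np.asarray(sat_times, dtype=float))
    if rho0 is None:
        rho0 = thermal_state(network)
    steps = _step_propagators(network, params, alphas, betas)
    u_rotor = _ordered_product(steps)
    tr = params.rotor_period
    out = np.empty((len(sat_times), len(alphas), steps.shape[-1]))
    for j, t_sat in enumerate(sat_times):
        m = int(t_sat / tr + 1e-9)
        frac = t_sat - m * tr
        u = _matrix_power_batched(u_rotor, m)
        if frac > 1e-15:
            u = _fractional_propagator(network, params, alphas, betas, steps, frac) @ u
        out[j] = u @ rho0
    return out


def evolve_saturation(
    rho0: np.ndarray,
    network: ExchangeNetwork,
    params: ExperimentParams,
    orient: CrystalliteOrientation,
) -> np.ndarray:
    """Single-crystallite saturation evolution over params.sat_time."""
    return saturate(
        network,
        params,
        np.array([orient.alpha]),
        np.array([orient.beta]),
        [params.sat_time],
        rho0=rho0,
    )[0, 0]
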