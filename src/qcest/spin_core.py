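"""Spin-1 operator algebra and quadrupolar frequencies.

The deuteron density matrix is expanded in eight trace-orthonormal Hermitian
operators (plus the identity): four single-quantum coherences (Sx, Sy, Jx, Jy),
two double-quantum coherences (Jz, K), Zeeman order Sz and quadrupolar order Q.
Normalization is fixed by Tr(O_i O_j) = delta_ij, which also fixes the
coefficients of the tilted-frame secular Hamiltonian

    H = sqrt(2/3) * wQ * Q + sqrt(2) * wRF * Sx + sqrt(2) * Omega * Sz.

Conventions used throughout the package:

* ZYZ Euler angles, active rotations; the magic angle is acos(1/sqrt(3)).
* All frequencies are stored internally in rad/s; public interfaces take Hz.
* Positive offset Omega means the RF carrier sits above the 2H Larmor
  frequency; profiles are reported versus Omega/2pi in kHz or Hz.
* Crystallite orientation (alpha, beta) enters through the composition
  R_lab(t) = Ry(theta_magic) . Rz(w_mas t) . Rz(alpha) . Ry(beta), so the
  closed-form MAS frequency below differs from an alternative azimuth origin
  only by a constant shift of alpha (immaterial under powder averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAGIC_ANGLE",
    "SpinBasisSet",
    "QuadrupolarTensor",
    "CrystalliteOrientation",
    "build_basis",
    "conventional_operators",
    "rotation_zyz",
    "quad_frequency_static",
    "quad_frequency_mas",
    "quad_frequencies_mas",
    "build_hamiltonian",
    "effective_field",
    "average_tensor_fast_rotation",
]

MAGIC_ANGLE = float(np.arccos(1.0 / np.sqrt(3.0)))

_SQRT2 = np.sqrt(2.0)
_SQRT6 = np.sqrt(6.0)

#: reduced (dimensionless) quadrupolar tensor in its principal-axis system for
#: asymmetry eta: eigenvalues (-(1-eta)/2, -(1+eta)/2, 1), so q_zz = 1 and
#: eta = (q_xx - q_yy)/q_zz with |q_zz| >= |q_yy| >= |q_xx|.
def _reduced_pas(eta: float) -> np.ndarray:
    return np.diag([-(1.0 - eta) / 2.0, -(1.0 + eta) / 2.0, 1.0])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(b: float) -> np.ndarray:
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_zyz(alpha: float, beta: float, gamma: float = 0.0) -> np.ndarray:
    """Active ZYZ rotation matrix Rz(alpha) @ Ry(beta) @ Rz(gamma)."""
    return _rz(alpha) @ _ry(beta) @ _rz(gamma)


# ---------------------------------------------------------------------------
# operator basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinBasisSet:
    """The eight trace-orthonormal spin-1 basis operators (identity excluded)."""

    Sx: np.ndarray
    Sy: np.ndarray
    Jx: np.ndarray
    Jy: np.ndarray
    Jz: np.ndarray
    K: np.ndarray
    Sz: np.ndarray
    Q: np.ndarray

    #: canonical ordering used for Liouville-space vectors
    names = ("Sx", "Sy", "Jx", "Jy", "Jz", "K", "Sz", "Q")

    def as_array(self) -> np.ndarray:
        """Stack the eight operators into shape (8, 3, 3)."""
        return np.array([getattr(self, n) for n in self.names])


def build_basis() -> SpinBasisSet:
    """Construct the spin-1 coherence basis, trace-orthonormalized."""
    half = 0.5
    Sx = half * np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=complex)
    Sy = half * np.array([[0, -1j, 0], [1j, 0, -1j], [0, 1j, 0]], dtype=complex)
    Jx = half * np.array([[0, -1j, 0], [1j, 0, 1j], [0, -1j, 0]], dtype=complex)
    Jy = half * np.array([[0, 1, 0], [1, 0, -1], [0, -1, 0]], dtype=complex)
    Jz = (1 / _SQRT2) * np.array([[0, 0, -1j], [0, 0, 0], [1j, 0, 0]], dtype=complex)
    K = (1 / _SQRT2) * np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]], dtype=complex)
    Sz = (1 / _SQRT2) * np.array([[1, 0, 0], [0, 0, 0], [0, 0, -1]], dtype=complex)
    Q = (1 / _SQRT6) * np.array([[1, 0, 0], [0, -2, 0], [0, 0, 1]], dtype=complex)
    return SpinBasisSet(Sx, Sy, Jx, Jy, Jz, K, Sz, Q)


def conventional_operators() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conventional spin-1 angular momentum matrices (Ix, Iy, Iz)."""
    Ix = (1 / _SQRT2) * np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=complex)
    Iy = (1 / _SQRT2) * np.array([[0, -1j, 0], [1j, 0, -1j], [0, 1j, 0]], dtype=complex)
    Iz = np.diag([1.0, 0.0, -1.0]).astype(complex)
    return Ix, Iy, Iz


# ---------------------------------------------------------------------------
# tensors and orientations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadrupolarTensor:
    """Electric-field-gradient tensor of one site.

    Parameters
    ----------
    cq : float
        Quadrupolar coupling constant e^2 q Q / h, in Hz. Non-negative.
    eta : float
        Asymmetry parameter in [0, 1].
    euler : tuple of float
        ZYZ Euler angles (rad) orienting the principal-axis system in the
        crystallite (molecular) frame.
    """

    cq: float
    eta: float = 0.0
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.cq < 0:
            raise ValueError("Cq must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def reduced_cartesian(self) -> np.ndarray:
        """Reduced Cartesian tensor in the crystallite frame (q_zz^PAS = 1)."""
        r = rotation_zyz(*self.euler)
        return r @ _reduced_pas(self.eta) @ r.T

    def scaled_cartesian(self) -> np.ndarray:
        """Cartesian tensor scaled such that wQ = v^T W v (rad/s) for a unit
        lab direction v expressed in the crystallite frame."""
        return (1.5 * np.pi * self.cq) * self.reduced_cartesian()


@dataclass(frozen=True)
class CrystalliteOrientation:
    """Orientation of one crystallite with respect to the rotor axis.

    alpha is the azimuthal and beta the polar angle of the crystallite frame
    relative to the rotor; weight is the powder weight of this orientation.
    """

    alpha: float
    beta: float
    weight: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.beta <= np.pi:
            raise ValueError("beta must lie in [0, pi]")


# ---------------------------------------------------------------------------
# quadrupolar frequencies
# ---------------------------------------------------------------------------

def quad_frequency_static(tensor: QuadrupolarTensor, theta: float, phi: float) -> float:
    """Secular quadrupolar frequency (rad/s) for a static crystallite.

    (theta, phi) are the polar coordinates of the magnetic field in the
    tensor's principal-axis system.  The two single-quantum lines of the
    eta = 0 spectrum appear at +-wQ/2pi Hz.
    """
    ang = (3 * np.cos(theta) ** 2 - 1) / 2.0 + (
        tensor.eta / 2.0
    ) * np.sin(theta) ** 2 * np.cos(2 * phi)
    return 1.5 * np.pi * tensor.cq * ang


def _b0_in_rotor_frame(t, omega_mas):
    """Unit vector of B0 expressed in the (spinning) rotor-fixed frame."""
    t = np.asarray(t, dtype=float)
    sm, cm = np.sin(MAGIC_ANGLE), np.cos(MAGIC_ANGLE)
    wt = omega_mas * t
    return np.stack(
        [-sm * np.cos(wt), sm * np.sin(wt), cm * np.ones_like(wt)], axis=-1
    )


def _b0_static(alphas, betas) -> np.ndarray:
    """Static mode: (alpha, beta) are the azimuthal/polar angles (phi, theta)
    of B0 in the crystallite frame; no magic-angle tilt applies."""
    return np.stack(
        [np.sin(betas) * np.cos(alphas), np.sin(betas) * np.sin(alphas), np.cos(betas)],
        axis=-1,
    )


def quad_frequency_mas(
    tensor: QuadrupolarTensor,
    orient: CrystalliteOrientation,
    t,
    omega_mas: float,
):
    """Time-dependent secular quadrupolar frequency (rad/s) under MAS.

    For an axially symmetric tensor aligned with the crystallite frame the
    closed form

        wQ(t) = (3 pi / 4) Cq [ -sqrt(2) sin(2 beta) cos(w t + alpha)
                                + sin^2(beta) cos(2 w t + 2 alpha) ]

    is used; otherwise the full second-rank tensor is rotated explicitly
    (crystallite -> rotor -> lab with the magic-angle tilt) and the lab-frame
    zz component is read off.  Both routes agree to machine precision.
    """
    t = np.asarray(t, dtype=float)
    if omega_mas == 0.0:
        v = _b0_static(np.asarray([orient.alpha]), np.asarray([orient.beta]))[0]
        return float(v @ tensor.scaled_cartesian() @ v) * np.ones_like(t)
    if tensor.eta == 0.0 and all(abs(a) < 1e-15 for a in tensor.euler):
        x = omega_mas * t + orient.alpha
        return (
            0.75
            * np.pi
            * tensor.cq
            * (
                -_SQRT2 * np.sin(2 * orient.beta) * np.cos(x)
                + np.sin(orient.beta) ** 2 * np.cos(2 * omega_mas * t + 2 * orient.alpha)
            )
        )
    w = tensor.scaled_cartesian()
    rc = rotation_zyz(orient.alpha, orient.beta)
    v = _b0_in_rotor_frame(t, omega_mas) @ rc  # = rc.T @ b0, batched over t
    return np.einsum("...a,ab,...b->...", v, w, v)


def quad_frequencies_mas(
    scaled_tensors: np.ndarray,
    alphas: np.ndarray,
    betas: np.ndarray,
    times: np.ndarray,
    omega_mas: float,
) -> np.ndarray:
    """Vectorized wQ(t): shape (n_orient, n_times, n_sites), rad/s.

    ``scaled_tensors`` is the (n_sites, 3, 3) stack of scaled Cartesian
    tensors in the crystallite frame (see QuadrupolarTensor.scaled_cartesian).
    With omega_mas = 0 (static mode) the orientation angles are interpreted
    as the polar coordinates of B0 in the crystallite frame.
    """
    if omega_mas == 0.0:
        v = _b0_static(alphas, betas)  # (n_o, 3), time-independent
        wq = np.einsum("oa,nab,ob->on", v, scaled_tensors, v)
        return np.broadcast_to(wq[:, None, :], (len(alphas), len(times), wq.shape[-1])).copy()
    ca, sa = np.cos(alphas), np.sin(alphas)
    cb, sb = np.cos(betas), np.sin(betas)
    # rows of Rc^T, shape (n_orient, 3, 3)
    rct = np.empty((len(alphas), 3, 3))
    rct[:, 0, 0] = ca * cb
    rct[:, 0, 1] = sa * cb
    rct[:, 0, 2] = -sb
    rct[:, 1, 0] = -sa
    rct[:, 1, 1] = ca
    rct[:, 1, 2] = 0.0
    rct[:, 2, 0] = ca * sb
    rct[:, 2, 1] = sa * sb
    rct[:, 2, 2] = cb
    b0 = _b0_in_rotor_frame(times, omega_mas)  # (n_t, 3)
    v = np.einsum("oab,tb->ota", rct, b0)  # (n_o, n_t, 3)
    return np.einsum("ota,nab,otb->otn", v, scaled_tensors, v)


# ---------------------------------------------------------------------------
# Hamiltonian
# ---------------------------------------------------------------------------

_BASIS = build_basis()


def build_hamiltonian(
    omega_q: float,
    omega_rf: float,
    offset: float,
    frame: str = "tilted",
    t: float = 0.0,
) -> np.ndarray:
    """Secular spin-1 Hamiltonian (rad/s) as a 3x3 Hermitian matrix.

    In the tilted frame H = sqrt(2/3) wQ Q + sqrt(2) wRF Sx + sqrt(2) Omega Sz.
    In the rotating frame the RF term carries the explicit time-dependent
    phase cos(Omega t) Sx - sin(Omega t) Sy and there is no Sz offset term.
    """
    b = _BASIS
    hq = np.sqrt(2.0 / 3.0) * omega_q * b.Q
    if frame == "tilted":
        return hq + _SQRT2 * omega_rf * b.Sx + _SQRT2 * offset * b.Sz
    if frame == "rotating":
        return hq + _SQRT2 * omega_rf * (
            np.cos(offset * t) * b.Sx - np.sin(offset * t) * b.Sy
        )
    raise ValueError(f"unknown frame {frame!r}")


def effective_field(omega_rf: float, offset: float) -> float:
    """Effective field magnitude sqrt(wRF^2 + Omega^2), rad/s."""
    return float(np.hypot(omega_rf, offset))


def rank2_spherical_components(q: np.ndarray) -> np.ndarray:
    """Spherical components (m = -2..2) of a symmetric traceless tensor.

    Only moduli enter relaxation rates, so the phase convention of the
    m = +-1 components is immaterial here.
    """
    return np.array(
        [
            0.5 * (q[0, 0] - q[1, 1]) - 1j * q[0, 1],
            q[0, 2] - 1j * q[1, 2],
            np.sqrt(1.5) * q[2, 2],
            -(q[0, 2] + 1j * q[1, 2]),
            0.5 * (q[0, 0] - q[1, 1]) + 1j * q[0, 1],
        ]
    )


# ---------------------------------------------------------------------------
# fast-rotation tensor averaging
# ---------------------------------------------------------------------------

def average_tensor_fast_rotation(
    tensor: QuadrupolarTensor, cone_angle: float, n_sites: int = 3
) -> QuadrupolarTensor:
    """Effective tensor after fast n-site hopping on a cone about the z axis.

    The tensor is tilted by ``cone_angle`` from the rotation axis and averaged
    over ``n_sites`` equally spaced azimuthal positions.  For an eta = 0 input
    and n >= 3 the result is axially symmetric along the axis with
    Cq_eff = Cq |3 cos^2(cone_angle) - 1| / 2.
    """
    if not 0.0 <= cone_angle <= np.pi:
        raise ValueError("cone_angle must lie in [0, pi]")
    if n_sites < 3:
        raise ValueError("n_sites must be >= 3")
    q = tensor.reduced_cartesian()
    acc = np.zeros((3, 3))
    for k in range(n_sites):
        r = _rz(2 * np.pi * k / n_sites) @ _ry(cone_angle)
        acc += r @ q @ r.T
    acc /= n_sites
    # diagonalize and re-express as (Cq_eff, eta_eff, orientation)
    vals, vecs = np.linalg.eigh((acc + acc.T) / 2.0)
    order = np.argsort(np.abs(vals))  # |q_xx| <= |q_yy| <= |q_zz|
    vals = vals[order]
    vecs = vecs[:, order]
    q_xx, q_yy, q_zz = vals
    cq_eff = tensor.cq * abs(q_zz)
    if cq_eff < 1e-12 * max(tensor.cq, 1.0):
        return QuadrupolarTensor(0.0, 0.0, (0.0, 0.0, 0.0))
    if (q_xx - q_yy) / q_zz < 0:  # enforce |q_yy| >= |q_xx| with eta >= 0
        vals = vals[[1, 0, 2]]
        vecs = vecs[:, [1, 0, 2]]
        q_xx, q_yy, q_zz = vals
    eta_eff = float(min(max((q_xx - q_yy) / q_zz, 0.0), 1.0))
    # PAS axes ordered (x, y, z); enforce a right-handed frame. The overall
    # sign of the tensor is not retained (Cq >= 0 convention).
    rot = vecs.copy()
    if np.linalg.det(rot) < 0:
        rot[:, 2] *= -1.0
    euler = _euler_from_matrix(rot)
    return QuadrupolarTensor(float(cq_eff), eta_eff, euler)


def _euler_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles of a proper rotation matrix."""
    beta = float(np.arccos(np.clip(r[2, 2], -1.0, 1.0)))
    if abs(np.sin(beta)) < 1e-10:
        alpha = float(np.arctan2(r[1, 0], r[0, 0]))
        gamma = 0.0
        if r[2, 2] < 0:
            beta = np.pi
    else:
        alpha = float(np.arctan2(r[1, 2], r[0, 2]))
        gamma = float(np.arctan2(r[2, 1], -r[2, 0]))
    return (alpha, beta, gamma)
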