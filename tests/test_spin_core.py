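"""Operator algebra, quadrupolar frequencies, tensor averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcest import (
    MAGIC_ANGLE,
    CrystalliteOrientation,
    QuadrupolarTensor,
    average_tensor_fast_rotation,
    build_basis,
    build_hamiltonian,
    effective_field,
    quad_frequency_mas,
    quad_frequency_static,
)
from qcest.spin_core import conventional_operators, rotation_zyz


class TestBasis:
    def test_trace_orthonormal_traceless_hermitian(self):
        ops = build_basis().as_array()
        gram = np.einsum("aij,bji->ab", ops, ops)
        assert np.abs(gram - np.eye(8)).max() < 1e-12
        assert max(abs(np.trace(o)) for o in ops) == 0.0
        assert max(np.abs(o - o.conj().T).max() for o in ops) == 0.0

    def test_quadrupolar_order_matrix(self):
        q = build_basis().Q
        assert np.allclose(q, np.diag([1, -2, 1]) / np.sqrt(6))
        assert abs(np.trace(q @ q) - 1.0) < 1e-14

    def test_conventional_commutator_recovered(self):
        # rescaling Sx,Sy by sqrt2 and Sz by sqrt2 gives conventional spin-1 ops
        b = build_basis()
        ix, iy, iz = conventional_operators()
        assert np.allclose(np.sqrt(2) * b.Sx, ix)
        assert np.allclose(np.sqrt(2) * b.Sz, iz)
        assert np.allclose(ix @ iy - iy @ ix, 1j * iz, atol=1e-14)


class TestStaticFrequency:
    @pytest.mark.parametrize(
        "theta,phi,eta,expected_hz",
        [
            (0.0, 0.0, 0.0, 0.75 * 55.3e3),  # parallel: 3/4 Cq
            (0.0, 0.3, 0.9, 0.75 * 55.3e3),  # eta irrelevant at theta = 0
            (MAGIC_ANGLE, 0.0, 0.0, 0.0),
            (np.pi / 2, 0.0, 1.0, 0.0),
        ],
    )
    def test_reference_angles(self, theta, phi, eta, expected_hz):
        t = QuadrupolarTensor(55.3e3, eta)
        wq = quad_frequency_static(t, theta, phi)
        assert wq / (2 * np.pi) == pytest.approx(expected_hz, abs=1e-6)


class TestFrequencyBounds:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0.0, np.pi),
        phi=st.floats(0.0, 2 * np.pi),
        eta=st.floats(0.0, 1.0),
    )
    def test_static_frequency_within_tensor_bounds(self, theta, phi, eta):
        """The secular frequency never leaves the principal-value range:
        the angular factor lies in [-(1+eta)/2, 1]."""
        t = QuadrupolarTensor(55.3e3, eta)
        wq = quad_frequency_static(t, theta, phi)
        scale = 1.5 * np.pi * t.cq
        assert -(1 + eta) / 2 * scale - 1e-6 <= wq <= scale + 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.0, 2 * np.pi),
        beta=st.floats(0.0, np.pi),
        tt=st.floats(0.0, 1e-4),
    )
    def test_mas_frequency_rotor_periodic(self, alpha, beta, tt):
        t = QuadrupolarTensor(55.3e3)
        o = CrystalliteOrientation(alpha, beta)
        wm = 2 * np.pi * 25e3
        a = float(quad_frequency_mas(t, o, tt, wm))
        b = float(quad_frequency_mas(t, o, tt + 1 / 25e3, wm))
        assert a == pytest.approx(b, abs=1e-6 * 1.5 * np.pi * t.cq)


class TestEffectiveField:
    def test_limits_and_pythagoras(self):
        assert effective_field(7.0, 0.0) == 7.0
        assert effective_field(0.0, -4.0) == 4.0
        w = effective_field(2 * np.pi * 3e3, 2 * np.pi * 4e3)
        assert w / (2 * np.pi) == pytest.approx(5e3)


class TestHamiltonian:
    def test_pure_quadrupolar_eigenvalues_and_transitions(self):
        wq = 2 * np.pi * 30e3
        h = build_hamiltonian(wq, 0.0, 0.0)
        ev = np.sort(np.linalg.eigvalsh(h))
        assert np.allclose(ev, np.sort(wq / 3 * np.array([1.0, -2.0, 1.0])))
        # single-quantum transition frequencies +-wQ
        assert ev[2] - ev[0] == pytest.approx(wq, rel=1e-12)

    def test_matches_conventional_operator_construction(self):
        rng = np.random.default_rng(3)
        ix, _, iz = conventional_operators()
        for _ in range(20):
            wq, wrf, off = rng.normal(scale=1e5, size=3)
            h = build_hamiltonian(wq, wrf, off)
            h_direct = (
                (wq / 3) * (3 * iz @ iz - 2 * np.eye(3)) + wrf * ix + off * iz
            )
            assert np.abs(h - h_direct).max() < 1e-12 * max(abs(wq), abs(wrf), abs(off))


def _oracle_wq_rotation(tensor, alpha, beta, t, omega_mas):
    """Independent route: rotate the full second-rank tensor into the lab frame
    (crystallite -> rotor -> magic-angle tilt) and read the zz component."""
    eta = tensor.eta
    qpas = np.diag([-(1 - eta) / 2, -(1 + eta) / 2, 1.0])
    r = (
        rotation_zyz(0.0, MAGIC_ANGLE)
        @ rotation_zyz(omega_mas * t, 0.0)
        @ rotation_zyz(alpha, beta)
        @ rotation_zyz(*tensor.euler)
    )
    qlab = r @ qpas @ r.T
    return 1.5 * np.pi * tensor.cq * qlab[2, 2]


class TestMASFrequency:
    def test_vanishes_on_rotor_axis(self):
        t = QuadrupolarTensor(55.3e3)
        o = CrystalliteOrientation(0.7, 0.0)
        ts = np.linspace(0, 4e-5, 17)
        assert np.abs(quad_frequency_mas(t, o, ts, 2 * np.pi * 25e3)).max() < 1e-6

    def test_zero_rotor_period_mean(self):
        t = QuadrupolarTensor(55.3e3)
        rng = np.random.default_rng(11)
        wm = 2 * np.pi * 25e3
        ts = (np.arange(2000) + 0.5) / 2000 / 25e3
        for _ in range(100):
            o = CrystalliteOrientation(rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi))
            mean = quad_frequency_mas(t, o, ts, wm).mean()
            assert abs(mean) < 1e-6 * 1.5 * np.pi * t.cq

    @pytest.mark.parametrize("eta,euler", [(0.0, (0.0, 0.0, 0.0)), (0.6, (0.4, 1.1, 2.2))])
    def test_agrees_with_rotation_matrix_oracle(self, eta, euler):
        t = QuadrupolarTensor(55.3e3, eta, euler)
        rng = np.random.default_rng(5)
        wm = 2 * np.pi * 25e3
        scale = 1.5 * np.pi * t.cq
        for _ in range(100):
            a, b = rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi)
            tt = rng.uniform(0, 1e-4)
            got = float(quad_frequency_mas(t, CrystalliteOrientation(a, b), tt, wm))
            want = _oracle_wq_rotation(t, a, b, tt, wm)
            assert abs(got - want) < 1e-9 * scale


class TestFastRotationAveraging:
    def test_zero_cone_is_identity(self):
        t = QuadrupolarTensor(55.3e3, 0.0)
        out = average_tensor_fast_rotation(t, 0.0, 3)
        assert out.cq == pytest.approx(t.cq, rel=1e-12)
        assert out.eta == pytest.approx(0.0, abs=1e-10)

    def test_magic_cone_annihilates(self):
        t = QuadrupolarTensor(55.3e3)
        out = average_tensor_fast_rotation(t, MAGIC_ANGLE, 3)
        assert out.cq < 1e-6 * t.cq

    def test_methyl_cone_oracle(self):
        # oracle: explicit average of three rotated Cartesian tensors
        t = QuadrupolarTensor(165.9e3)
        cone = np.deg2rad(109.47)
        acc = np.zeros((3, 3))
        for k in range(3):
            r = rotation_zyz(2 * np.pi * k / 3, cone)
            acc += r @ np.diag([-0.5, -0.5, 1.0]) @ r.T / 3
        lam = np.linalg.eigvalsh(acc)
        cq_expect = t.cq * np.abs(lam).max()
        out = average_tensor_fast_rotation(t, cone, 3)
        assert out.cq == pytest.approx(cq_expect, rel=1e-9)
        assert out.cq == pytest.approx(55.3e3, rel=5e-3)
        assert out.eta < 1e-9

    def test_idempotent_for_aligned_axial_tensor(self):
        t = QuadrupolarTensor(42e3, 0.0)
        out = average_tensor_fast_rotation(t, 0.0, 5)
        out2 = average_tensor_fast_rotation(out, 0.0, 5)
        assert out2.cq == pytest.approx(out.cq, rel=1e-12)
        assert out2.eta == pytest.approx(out.eta, abs=1e-10)

    def test_invalid_cone_angle(self):
        with pytest.raises(ValueError):
            average_tensor_fast_rotation(QuadrupolarTensor(1e3), -0.1, 3)
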