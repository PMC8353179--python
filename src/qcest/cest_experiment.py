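"""CEST experiment orchestration.

Generates offset schedules, simulates full CEST profiles I(T)/I(0) versus
offset (powder- and RF-inhomogeneity-averaged), extracts effective saturation
decay rates (R_CEST), and provides the closed-form/numerical map between the
methyl three-site jump rate k3 and the deuteron longitudinal relaxation time
T1 used to pin the fast-motion mode.

The T1 calculator works outside the secular Liouvillian (which conserves
total Zeeman order in the absence of RF): it evaluates Redfield-type
quadrupolar spectral densities at the 2H Larmor frequency and twice it,

    1/T1 = (pi Cq)^2 [ (1/2)(J_+1 + J_-1)(w0) + 2 (J_+2 + J_-2)(2 w0) ],

with J_m the cosine transforms of the lab-frame rank-2 EFG fluctuation
correlation functions computed from the 3-site jump generator.  The constant
was validated against a brute-force stochastic-jump density-matrix simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .detection_spectra import detect_fids, detection_step_propagators, integrate_bands
from .exchange_models import ExchangeNetwork, methyl_three_site
from .powder_rf import (
    RFInhomogeneityProfile,
    orientation_arrays,
    powder_orientations,
    rf_values_and_weights,
)
from .propagation import ExperimentParams, saturate, thermal_state, total_sz
from .spin_core import rank2_spherical_components, rotation_zyz

__all__ = [
    "LARMOR_2H_HZ",
    "CESTProfile",
    "RCESTResult",
    "offset_schedule",
    "simulate_cest_profile",
    "rcest",
    "fit_monoexponential",
    "t1_three_site_jumps",
    "k3_from_t1",
]

#: 2H Larmor frequencies (Hz) at the two field strengths used in this work
LARMOR_2H_HZ = {"14.1T": 92.1e6, "17.6T": 115.1e6}


@dataclass
class CESTProfile:
    """Normalized CEST intensities I(T)/I(0) on an offset grid."""

    offsets_hz: np.ndarray
    sat_times: np.ndarray
    intensities: np.ndarray  # shape (n_sat_times, n_offsets)
    band_mode: str = "all_bands"
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.sat_times = np.atleast_1d(np.asarray(self.sat_times, dtype=float))
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.offsets_hz) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.intensities.shape != (len(self.sat_times), len(self.offsets_hz)):
            raise ValueError("intensities must have shape (n_sat_times, n_offsets)")


@dataclass(frozen=True)
class RCESTResult:
    """Mono-exponential fit of band intensity versus saturation time."""

    rate: float
    amplitude: float
    rel_rms: float
    non_exponential: bool


def offset_schedule(
    mas_hz: float,
    span_hz: float,
    coarse_hz: float = 2500.0,
    dense_hz: float = 250.0,
    dense_halfwidth_hz: float = 1000.0,
) -> np.ndarray:
    """Symmetric offset list: coarse everywhere, dense near rotary resonances.

    Rotary resonances sit at every +-n * mas/2 (integer and half-integer
    multiples of the MAS rate); the returned schedule contains those offsets
    exactly, plus dense sampling within ``dense_halfwidth_hz`` of each.
    """
    if span_hz < mas_hz / 2.0:
        raise ValueError("span must reach at least the first rotary resonance")
    if not coarse_hz > dense_hz > 0:
        raise ValueError("need coarse > dense > 0")
    pos = [np.arange(0.0, span_hz + 1e-6, coarse_hz)]
    res = mas_hz / 2.0
    k = 1
    while k * res <= span_hz + 1e-6:
        r = k * res
        local = r + np.arange(-dense_halfwidth_hz, dense_halfwidth_hz + 1e-6, dense_hz)
        pos.append(local[(local >= 0) & (local <= span_hz + 1e-6)])
        k += 1
    pos = np.concatenate(pos)
    offs = np.unique(np.round(np.concatenate([-pos, pos]), 6))
    return offs


def simulate_cest_profile(
    network: ExchangeNetwork,
    params: ExperimentParams,
    offsets_hz,
    sat_times,
    band_mode: str = "all_bands",
    powder_n: int = 300,
    scheme: str = "spiral",
    rf_mode: str = "none",
    rf_profile: RFInhomogeneityProfile | str | None = None,
    orientations=None,
) -> CESTProfile:
    """Simulate a powder- and RF-averaged CEST profile.

    Every profile point is the band intensity after saturation time T divided
    by the matched T = 0 value obtained with the identical pipeline (same
    orientation set, same integration windows), so pipeline artifacts cancel.
    """
    offsets_hz = np.sort(np.asarray(offsets_hz, dtype=float))
    sat_times = np.atleast_1d(np.asarray(sat_times, dtype=float))
    if orientations is None:
        orientations = powder_orientations(powder_n, scheme)
    alphas, betas, weights = orientation_arrays(orientations)
    if band_mode not in ("all_bands", "central"):
        raise ValueError("band_mode must be 'all_bands' or 'central'")

    det_steps = None
    i0 = 1.0  # all-bands T=0 intensity: site populations sum to 1
    if band_mode == "central":
        det_steps = detection_step_propagators(network, params, alphas, betas)
        fids0 = detect_fids(
            thermal_state(network)[None, :].repeat(len(alphas), axis=0),
            network,
            params,
            alphas,
            betas,
            step_props=det_steps,
        )
        i0 = sum(
            w * integrate_bands(fid, params).central for w, fid in zip(weights, fids0)
        )

    intens = np.empty((len(sat_times), len(offsets_hz)))
    for k, off in enumerate(offsets_hz):
        rf_vals, rf_w = rf_values_and_weights(
            params.rf_hz, rf_mode, rf_profile, offset_hz=off
        )
        acc = np.zeros(len(sat_times))
        for rf, rw in zip(rf_vals, rf_w):
            p = params.replace(offset_hz=float(off), rf_hz=float(rf))
            states = saturate(network, p, alphas, betas, sat_times)
            if band_mode == "all_bands":
                vals = np.array(
                    [
                        weights @ states[j, :, 6 : 8 * network.n_sites : 8].sum(axis=1)
                        for j in range(len(sat_times))
                    ]
                )
            else:
                vals = np.empty(len(sat_times))
                for j in range(len(sat_times)):
                    fids = detect_fids(
                        states[j], network, p, alphas, betas, step_props=det_steps
                    )
                    vals[j] = sum(
                        w * integrate_bands(fid, p).central
                        for w, fid in zip(weights, fids)
                    )
            acc += rw * vals
        intens[:, k] = acc / i0
    return CESTProfile(
        offsets_hz,
        sat_times,
        intens,
        band_mode=band_mode,
        metadata={
            "rf_hz": params.rf_hz,
            "mas_hz": params.mas_hz,
            "t1": params.t1,
            "powder_n": len(alphas),
            "scheme": scheme,
            "rf_mode": rf_mode,
            "n_rotor_steps": params.n_rotor_steps,
        },
    )


def fit_monoexponential(times, values) -> RCESTResult:
    """Least-squares fit of A exp(-R t); flags clearly non-exponential decays."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("intensities must be positive for the R_CEST fit")
    coef = np.polyfit(times, np.log(values), 1)
    r0 = max(-coef[0], 0.0)
    a0 = float(np.exp(coef[1]))
    popt, _ = curve_fit(
        lambda t, a, r: a * np.exp(-r * t),
        times,
        values,
        p0=(a0, r0 if r0 > 0 else 1.0),
        maxfev=10000,
    )
    a, r = float(popt[0]), float(popt[1])
    resid = values - a * np.exp(-r * times)
    rel_rms = float(np.sqrt(np.mean(resid**2)) / np.mean(values))
    return RCESTResult(
        rate=max(r, 0.0), amplitude=a, rel_rms=rel_rms, non_exponential=rel_rms > 0.05
    )


def rcest(
    network: ExchangeNetwork,
    params: ExperimentParams,
    offset_hz: float,
    t_grid=None,
    powder_n: int = 100,
    scheme: str = "spiral",
    orientations=None,
) -> RCESTResult:
    """Effective mono-exponential saturation rate at one offset.

    Uses the all-bands intensity versus saturation time (default grid
    0.25-128 ms, logarithmic).
    """
    if t_grid is None:
        t_grid = np.geomspace(0.25e-3, 128e-3, 10)
    t_grid = np.asarray(t_grid, dtype=float)
    if orientations is None:
        orientations = powder_orientations(powder_n, scheme)
    alphas, betas, weights = orientation_arrays(orientations)
    p = params.replace(offset_hz=float(offset_hz))
    states = saturate(network, p, alphas, betas, t_grid)
    intens = np.array(
        [weights @ states[j, :, 6 : 8 * network.n_sites : 8].sum(axis=1) for j in range(len(t_grid))]
    )
    return fit_monoexponential(t_grid, intens)


# ---------------------------------------------------------------------------
# T1 from methyl three-site jumps
# ---------------------------------------------------------------------------

def _site_q2m_lab(cone_angle: float, theta: float, phi: float) -> np.ndarray:
    """Rank-2 spherical components (3 sites x 5 m) with lab z along B0."""
    r_lc = rotation_zyz(0.0, -theta, -phi)  # crystallite -> lab
    net = methyl_three_site(1.0, 1.0, cone_angle)
    out = []
    for s in net.sites:
        qc = s.tensor.reduced_cartesian()
        out.append(rank2_spherical_components(r_lc @ qc @ r_lc.T))
    return np.array(out)


_M_WEIGHTS = {1: 0.5, 2: 2.0}


def t1_three_site_jumps(
    cq_static_hz: float,
    k3: float,
    larmor_hz: float,
    cone_angle: float = np.deg2rad(109.47),
    powder_n: int = 256,
    method: str = "numerical",
) -> float:
    """Powder-averaged deuteron T1 (s) for 3-site jumps on a cone.

    method='numerical' integrates the correlation functions evaluated from
    the jump generator on a time grid; method='closed_form' uses their exact
    single-Lorentzian form (the symmetric 3-site generator has one non-zero
    relaxation eigenvalue, 3 k3).  The powder average is taken over 1/T1.
    """
    if k3 <= 0:
        raise ValueError("k3 must be positive")
    w0 = 2 * np.pi * larmor_hz
    pref = (np.pi * cq_static_hz) ** 2
    orients = powder_orientations(powder_n, "spiral")
    pops = np.full(3, 1.0 / 3.0)
    if method == "numerical":
        # correlation functions from expm of the generator on a time grid
        k_gen = k3 * (np.ones((3, 3)) - 3 * np.eye(3))
        t_max = 16.0 / (3.0 * k3)
        tgrid = np.linspace(0.0, t_max, 2048)
        evals, evecs = np.linalg.eigh(k_gen)
        props = np.einsum(
            "ab,tb,cb->tac", evecs, np.exp(np.outer(tgrid, evals)), evecs
        )
    r1_acc = 0.0
    for o in orients:
        q2 = _site_q2m_lab(cone_angle, o.beta, o.alpha)  # (3 sites, 5 m)
        mean = pops @ q2
        r1 = 0.0
        for mi, m in ((0, -2), (1, -1), (3, 1), (4, 2)):
            w = abs(m) * w0
            if method == "closed_form":
                a_m = float(pops @ np.abs(q2[:, mi]) ** 2 - abs(mean[mi]) ** 2)
                j_m = a_m * (3 * k3) / ((3 * k3) ** 2 + w**2)
            elif method == "numerical":
                corr = np.einsum(
                    "s,tps,p->t", pops * q2[:, mi], props, q2[:, mi].conj()
                ).real - abs(mean[mi]) ** 2
                j_m = np.trapezoid(corr * np.cos(w * tgrid), tgrid)
            else:
                raise ValueError(f"unknown method {method!r}")
            r1 += _M_WEIGHTS[abs(m)] * pref * j_m
        r1_acc += o.weight * r1
    return 1.0 / r1_acc


def k3_from_t1(
    t1: float,
    cq_static_hz: float,
    larmor_hz: float,
    cone_angle: float = np.deg2rad(109.47),
    bracket: tuple[float, float] = (1e8, 1e13),
    powder_n: int = 256,
) -> float:
    """Invert T1 -> k3 on the fast-motion branch by root finding."""

    def f(logk):
        return (
            t1_three_site_jumps(
                cq_static_hz,
                10.0**logk,
                larmor_hz,
                cone_angle,
                powder_n,
                method="closed_form",
            )
            - t1
        )

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    if f(lo) * f(hi) > 0:
        raise ValueError("no root in bracket on the fast-motion branch")
    return float(10.0 ** brentq(f, lo, hi, xtol=1e-10))
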