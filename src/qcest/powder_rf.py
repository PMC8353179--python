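"""Powder orientation sets and RF-field inhomogeneity handling.

Powder sets are deterministic (no RNG): a generalized spiral by default.
RF inhomogeneity is described by a normalized distribution of scale factors
wRF/<wRF> with weights; the two probe profiles measured by nutation
(1.3 mm and 2.5 mm Bruker probes) ship as built-in six-point grids at scales
0.25 ... 1.5 of the mean field.  Nutation decays can be converted into such
profiles by Fourier analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_core import CrystalliteOrientation

__all__ = [
    "RFInhomogeneityProfile",
    "powder_orientations",
    "rf_profile_from_nutation",
    "discretize_profile",
    "average_over_rf",
    "rf_values_and_weights",
    "BUILTIN_RF_PROFILES",
]

_SIX_SCALES = np.array([0.25, 0.5, 0.75, 1.0, 1.25, 1.5])


@dataclass(frozen=True)
class RFInhomogeneityProfile:
    """Distribution of RF field scales s = wRF/<wRF> with weights."""

    scales: np.ndarray
    weights: np.ndarray
    mean_rf_hz: float | None = None

    def __post_init__(self):
        scales = np.asarray(self.scales, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if scales.shape != weights.shape or scales.ndim != 1:
            raise ValueError("scales and weights must be 1-D of equal length")
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")
        if ((scales <= 0) & (weights > 0)).any():
            raise ValueError("scales must be positive where weight > 0")
        tot = weights.sum()
        if not 0.5 < tot < 1.5:
            raise ValueError("weights must sum to ~1 before renormalization")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "weights", weights / tot)

    @property
    def mean_scale(self) -> float:
        return float(self.scales @ self.weights)


#: printed six-point grids for the two probes (scales 0.25 ... 1.5)
BUILTIN_RF_PROFILES = {
    "bruker_1p3mm": RFInhomogeneityProfile(
        _SIX_SCALES, np.array([0.084, 0.143, 0.126, 0.176, 0.285, 0.187])
    ),
    "bruker_2p5mm": RFInhomogeneityProfile(
        _SIX_SCALES, np.array([0.065, 0.097, 0.103, 0.236, 0.499, 0.0])
    ),
}


def powder_orientations(n: int, scheme: str = "spiral") -> list[CrystalliteOrientation]:
    """Deterministic powder set of (alpha, beta, weight) covering the sphere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme == "spiral":
        k = np.arange(n)
        z = -1.0 + (2.0 * k + 1.0) / n
        beta = np.arccos(z)
        alpha = np.mod(k * np.pi * (3.0 - np.sqrt(5.0)), 2 * np.pi)
        w = np.full(n, 1.0 / n)
    elif scheme == "golden":
        k = np.arange(n)
        z = 1.0 - (2.0 * k + 1.0) / n
        beta = np.arccos(z)
        alpha = np.mod(2 * np.pi * k / ((1 + np.sqrt(5.0)) / 2.0), 2 * np.pi)
        w = np.full(n, 1.0 / n)
    elif scheme == "grid":
        nb = max(2, int(np.round(np.sqrt(n / 2))))
        na = max(1, int(np.round(n / nb)))
        b = (np.arange(nb) + 0.5) * np.pi / nb
        a = (np.arange(na) + 0.5) * 2 * np.pi / na
        alpha, beta = [x.ravel() for x in np.meshgrid(a, b)]
        w = np.sin(beta)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown powder scheme {scheme!r}")
    return [
        CrystalliteOrientation(float(al), float(be), float(we))
        for al, be, we in zip(alpha, beta, w)
    ]


def orientation_arrays(
    orientations: list[CrystalliteOrientation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alphas, betas, weights) arrays from an orientation list."""
    alphas = np.array([o.alpha for o in orientations])
    betas = np.array([o.beta for o in orientations])
    weights = np.array([o.weight for o in orientations])
    return alphas, betas, weights / weights.sum()


# ---------------------------------------------------------------------------
# nutation analysis
# ---------------------------------------------------------------------------

def rf_profile_from_nutation(
    curves: list[tuple[np.ndarray, np.ndarray]],
    n_scale_bins: int = 201,
    threshold: float = 0.05,
) -> RFInhomogeneityProfile:
    """RF inhomogeneity profile from nutation decays.

    Each curve is (pulse_lengths_s, intensities) sampled uniformly in pulse
    length.  Each curve is mean-subtracted, Hann-windowed, Fourier-transformed
    (zero padding x4), and its magnitude spectrum rescaled by its own
    weighted-mean frequency; the rescaled densities are averaged onto a common
    wRF/<wRF> axis.  <wRF> is reported as the average of the per-curve means.
    """
    grid = np.linspace(0.0, 2.0, n_scale_bins)
    dens_acc = np.zeros_like(grid)
    means = []
    for times, amp in curves:
        times = np.asarray(times, dtype=float)
        amp = np.asarray(amp, dtype=float)
        dt = np.diff(times)
        if dt.size == 0 or np.abs(dt - dt[0]).max() > 1e-9 * dt[0]:
            raise ValueError("nutation curves must be uniformly sampled")
        npad = 4 * len(amp)
        win = np.hanning(len(amp))
        mag = np.abs(np.fft.rfft((amp - amp.mean()) * win, n=npad))
        freq = np.fft.rfftfreq(npad, dt[0])
        mag[0] = 0.0
        mag[mag < threshold * mag.max()] = 0.0
        w = mag / mag.sum()
        mean_f = float(freq @ w)
        means.append(mean_f)
        scale = freq / mean_f
        # density per unit scale, interpolated onto the common grid
        d_scale = (freq[1] - freq[0]) / mean_f
        dens_acc += np.interp(grid, scale, w / d_scale, left=0.0, right=0.0)
    dens = dens_acc / len(curves)
    weights = dens * (grid[1] - grid[0])
    keep = weights > 0
    keep[np.argmax(weights)] = True
    return RFInhomogeneityProfile(
        np.maximum(grid[keep], 1e-9), weights[keep] / weights.sum(),
        mean_rf_hz=float(np.mean(means)),
    )


def discretize_profile(
    profile: RFInhomogeneityProfile, n_points: int = 6
) -> RFInhomogeneityProfile:
    """Reduce/expand a profile to the 6-point grid or its 30-point interpolation."""
    if n_points == 6:
        if profile.scales.shape == _SIX_SCALES.shape and np.allclose(
            profile.scales, _SIX_SCALES
        ):
            return profile
        edges = np.concatenate([[_SIX_SCALES[0] - 0.125], _SIX_SCALES + 0.125])
        w = np.array(
            [
                profile.weights[
                    (profile.scales >= lo) & (profile.scales < hi)
                ].sum()
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        if w.sum() <= 0:
            raise ValueError("profile has no weight in the 0.25-1.5 scale range")
        return RFInhomogeneityProfile(
            _SIX_SCALES, w / w.sum(), mean_rf_hz=profile.mean_rf_hz
        )
    if n_points == 30:
        six = discretize_profile(profile, 6)
        # spread each six-point mass uniformly over its 0.25-wide bin and
        # subdivide five-fold; symmetric subdivision preserves the mean scale
        scales = (six.scales[:, None] + 0.05 * np.array([-2, -1, 0, 1, 2])).ravel()
        w = np.repeat(six.weights / 5.0, 5)
        return RFInhomogeneityProfile(
            scales, w / w.sum(), mean_rf_hz=profile.mean_rf_hz
        )
    raise ValueError("n_points must be 6 or 30")


def rf_values_and_weights(
    mean_rf_hz: float,
    rf_mode: str,
    rf_profile: RFInhomogeneityProfile | str | None = None,
    offset_hz: float = np.inf,
    dense_offset_hz: float = 2000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """RF field values (Hz) and weights for a given averaging mode.

    'none'  -> the single mean value;
    'grid'  -> the discretized inhomogeneity grid (30 points when
               |offset| < dense_offset_hz, else 6 -- stronger coherent
               oscillations near zero offset need the denser grid);
    'pm500' -> five equally weighted values within +-500 Hz of the mean.
    """
    if rf_mode == "none":
        return np.array([mean_rf_hz]), np.array([1.0])
    if rf_mode == "pm500":
        vals = mean_rf_hz + np.array([-500.0, -250.0, 0.0, 250.0, 500.0])
        return vals, np.full(5, 0.2)
    if rf_mode == "grid":
        if isinstance(rf_profile, str):
            rf_profile = BUILTIN_RF_PROFILES[rf_profile]
        if rf_profile is None:
            raise ValueError("rf_mode='grid' requires an rf_profile")
        n_pts = 30 if abs(offset_hz) < dense_offset_hz else 6
        prof = discretize_profile(rf_profile, n_pts)
        keep = prof.weights > 0
        return mean_rf_hz * prof.scales[keep], prof.weights[keep] / prof.weights[keep].sum()
    raise ValueError(f"unknown rf_mode {rf_mode!r}")


def average_over_rf(
    profile_fn,
    rf_profile: RFInhomogeneityProfile | str | None,
    mode: str,
    mean_rf_hz: float,
    offset_hz: float = np.inf,
):
    """Weighted average of profile_fn(rf_hz) over the RF distribution."""
    vals, w = rf_values_and_weights(mean_rf_hz, mode, rf_profile, offset_hz)
    acc = None
    for v, wt in zip(vals, w):
        y = np.asarray(profile_fn(float(v)), dtype=float)
        acc = wt * y if acc is None else acc + wt * y
    return acc
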