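"""Grid-search fitting of simulated CEST profiles to data.

The objective is the mean absolute difference between data and simulation,
pooled over all (offset, saturation time) points of a dataset; a global fit
averages the per-dataset objectives.  The whole objective surface is part of
the result -- the minima are typically shallow and parameter pairs such as
(D, k_ex) are correlated, so the argmin alone under-reports what the data
constrain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cest_experiment import CESTProfile, simulate_cest_profile
from .exchange_models import MODEL_BUILDERS
from .propagation import ExperimentParams

__all__ = ["FitResult", "grid_search", "correlation_diagnostic"]

#: data offsets farther than this from any simulated offset are interpolated
MATCH_TOLERANCE_HZ = 50.0


@dataclass
class FitResult:
    """Objective surface over a named parameter grid."""

    axes: dict  # name -> 1-D array of grid values
    objective: np.ndarray  # shape = tuple of axis lengths
    best: dict  # name -> best-fit value
    best_objective: float
    per_dataset: bool = False
    node_profiles: dict = field(default_factory=dict)

    @property
    def axis_names(self) -> tuple:
        return tuple(self.axes.keys())


def _dataset_params(ds: CESTProfile) -> ExperimentParams:
    md = ds.metadata
    return ExperimentParams(
        rf_hz=float(md["rf_hz"]),
        offset_hz=0.0,
        mas_hz=float(md["mas_hz"]),
        t1=md.get("t1"),
    )


def _match(sim: CESTProfile, data_offsets: np.ndarray) -> np.ndarray:
    """Simulated intensities at the data offsets (nearest within tolerance,
    else linear interpolation), shape (n_sat_times, n_data_offsets)."""
    out = np.empty((len(sim.sat_times), len(data_offsets)))
    for j in range(len(sim.sat_times)):
        row = sim.intensities[j]
        idx = np.searchsorted(sim.offsets_hz, data_offsets)
        idx = np.clip(idx, 1, len(sim.offsets_hz) - 1)
        left = sim.offsets_hz[idx - 1]
        right = sim.offsets_hz[idx]
        nearest = np.where(data_offsets - left < right - data_offsets, idx - 1, idx)
        dist = np.abs(sim.offsets_hz[nearest] - data_offsets)
        interp = np.interp(data_offsets, sim.offsets_hz, row)
        out[j] = np.where(dist <= MATCH_TOLERANCE_HZ, row[nearest], interp)
    return out


def grid_search(
    datasets: list[CESTProfile],
    model_family,
    grid: dict,
    fixed: dict | None = None,
    shared: str = "global",
    offsets_subset=None,
    powder_n: int = 100,
    scheme: str = "spiral",
    rf_mode: str = "none",
    rf_profile=None,
    cache: dict | None = None,
) -> FitResult | list[FitResult]:
    """Mean-absolute-difference grid search.

    ``model_family`` is a builder name (see exchange_models.MODEL_BUILDERS) or
    a callable; ``grid`` maps builder keyword names to 1-D arrays of values;
    ``fixed`` carries the remaining builder keywords.  Each grid node is
    simulated with every dataset's (RF, MAS, T1, saturation times) settings at
    the dataset's offsets (optionally restricted to ``offsets_subset``).
    Ties are broken deterministically toward the smallest parameter values in
    axis order.  Passing a ``cache`` dict reuses node simulations across calls
    that share acquisition settings (simulation dominates the cost; noise
    realizations on the data do not enter the key).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if len({ds.band_mode for ds in datasets}) != 1:
        raise ValueError("datasets must share a band mode")
    builder = MODEL_BUILDERS[model_family] if isinstance(model_family, str) else model_family
    fixed = dict(fixed or {})
    axes = {k: np.asarray(v, dtype=float) for k, v in grid.items()}
    names = list(axes.keys())
    shape = tuple(len(axes[k]) for k in names)

    # per-dataset offsets actually used for the objective
    used_offsets = []
    for ds in datasets:
        offs = ds.offsets_hz
        if offsets_subset is not None:
            sel = np.isin(np.round(offs, 3), np.round(np.asarray(offsets_subset), 3))
            offs = offs[sel]
            if len(offs) == 0:
                raise ValueError("offsets_subset selects no data points")
        used_offsets.append(offs)

    per_ds_obj = np.empty((len(datasets),) + shape)
    if cache is None:
        cache = {}
    for node_idx in itertools.product(*(range(s) for s in shape)):
        kw = {k: float(axes[k][i]) for k, i in zip(names, node_idx)}
        network = builder(**{**fixed, **kw})
        for d, ds in enumerate(datasets):
            md = ds.metadata
            key = (
                tuple(sorted(kw.items())),
                repr(sorted(fixed.items())),
                ds.band_mode,
                float(md["rf_hz"]),
                float(md["mas_hz"]),
                md.get("t1"),
                used_offsets[d].tobytes(),
                ds.sat_times.tobytes(),
            )
            if key not in cache:
                sim = simulate_cest_profile(
                    network,
                    _dataset_params(ds),
                    used_offsets[d],
                    ds.sat_times,
                    band_mode=ds.band_mode,
                    powder_n=powder_n,
                    scheme=scheme,
                    rf_mode=rf_mode,
                    rf_profile=rf_profile,
                )
                cache[key] = sim
            sim = cache[key]
            simvals = _match(sim, used_offsets[d])
            sel = np.isin(np.round(ds.offsets_hz, 6), np.round(used_offsets[d], 6))
            datavals = ds.intensities[:, sel]
            per_ds_obj[(d,) + node_idx] = np.mean(np.abs(datavals - simvals))

    def _result(obj: np.ndarray, per_dataset: bool) -> FitResult:
        flat = np.argmin(obj)  # first occurrence = smallest params in axis order
        idx = np.unravel_index(flat, shape)
        best = {k: float(axes[k][i]) for k, i in zip(names, idx)}
        return FitResult(
            axes=axes,
            objective=obj,
            best=best,
            best_objective=float(obj[idx]),
            per_dataset=per_dataset,
        )

    if shared == "global":
        return _result(per_ds_obj.mean(axis=0), False)
    if shared == "per_dataset":
        return [_result(per_ds_obj[d], True) for d in range(len(datasets))]
    raise ValueError("shared must be 'global' or 'per_dataset'")


def correlation_diagnostic(result: FitResult) -> dict:
    """Ridge of a 2-D objective surface: best second-axis value per first-axis
    value.  A monotonic ridge exposes the correlated (D, k_ex)-type valley."""
    if result.objective.ndim != 2:
        raise ValueError("correlation diagnostic requires a 2-D grid")
    n0, n1 = result.objective.shape
    names = result.axis_names
    span = result.objective.max() - result.objective.min()
    flat = span <= 1e-12 * max(abs(result.objective.max()), 1.0)
    ridge_idx = np.argmin(result.objective, axis=1)
    ridge = result.axes[names[1]][ridge_idx]
    mono = bool(np.all(np.diff(ridge) >= 0)) if not flat else False
    return {
        "axis": names[0],
        "values": result.axes[names[0]].copy(),
        "ridge_axis": names[1],
        "ridge": ridge,
        "monotonic_nondecreasing": mono,
        "flat": flat,
    }
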