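"""Impedance-trace analysis for the label-free transport-activity assay.

Raw well impedance is converted to the dimensionless cell index
CI = (Z - Z0)/15, normalized to the sample just before substrate
addition, corrected by subtracting the vehicle/vehicle well, and
summarized as the net area under the curve over the first 30 minutes
after stimulation. Per-concentration responses, expressed as percent of
the reference-inhibitor window, are fit to a sigmoidal
concentration-inhibition curve with a fixed pseudo-Hill slope of 1 to
yield a pIC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

IMPEDANCE_DIVISOR_OHM = 15.0
AUC_WINDOW_MIN = 30.0


@dataclass
class ImpedanceTrace:
    """One well's time course: minutes vs impedance (ohms)."""

    well: str
    time_min: np.ndarray
    impedance_ohm: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.impedance_ohm = np.asarray(self.impedance_ohm, dtype=float)
        if self.time_min.size < 2:
            raise ValueError(f"well {self.well}: need at least 2 samples")
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError(f"well {self.well}: time must be strictly increasing")


@dataclass
class DoseResponseFit:
    pic50: float
    bottom: float
    top: float
    residual: float
    per_concentration: pd.DataFrame  # concentration_m, mean_response, sem


def cell_index(z: np.ndarray, z0: float) -> np.ndarray:
    """Dimensionless cell index: (Z - Z0) / 15 ohm."""
    return (np.asarray(z, dtype=float) - z0) / IMPEDANCE_DIVISOR_OHM


def normalize_trace(time_min: np.ndarray, ci: np.ndarray, t_ref: float) -> np.ndarray:
    """Normalized CI: divide by the last sample at or before substrate addition."""
    time_min = np.asarray(time_min, dtype=float)
    ci = np.asarray(ci, dtype=float)
    if t_ref < time_min[0] or t_ref > time_min[-1]:
        raise ValueError(f"reference time {t_ref} outside trace span")
    ref_idx = int(np.searchsorted(time_min, t_ref, side="right") - 1)
    ref = ci[ref_idx]
    if ref == 0:
        raise ValueError(f"zero cell index at reference time {time_min[ref_idx]}")
    return ci / ref


def vehicle_correct(
    time_min: np.ndarray,
    nci: np.ndarray,
    vehicle_time_min: np.ndarray,
    vehicle_nci: np.ndarray,
) -> np.ndarray:
    """Subtract the vehicle/vehicle trace, resampling it if grids differ."""
    time_min = np.asarray(time_min, dtype=float)
    vt = np.asarray(vehicle_time_min, dtype=float)
    if time_min[0] > vt[-1] or time_min[-1] < vt[0]:
        raise ValueError("vehicle trace does not overlap the sample trace")
    vehicle_on_grid = np.interp(time_min, vt, np.asarray(vehicle_nci, dtype=float))
    return np.asarray(nci, dtype=float) - vehicle_on_grid


def net_auc(
    time_min: np.ndarray,
    corrected: np.ndarray,
    t_start: float,
    window_min: float = AUC_WINDOW_MIN,
) -> float:
    """Signed trapezoidal area over [t_start, t_start + window] (nCI*min)."""
    time_min = np.asarray(time_min, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    t_end = t_start + window_min
    if t_start < time_min[0] or t_end > time_min[-1]:
        raise ValueError(f"window [{t_start}, {t_end}] exceeds trace span")
    grid = np.unique(np.concatenate([[t_start, t_end], time_min[(time_min > t_start) & (time_min < t_end)]]))
    values = np.interp(grid, time_min, corrected)
    return float(np.trapezoid(values, grid))


def percent_normalize(auc: float, auc_vehicle: float, auc_reference: float) -> float:
    """Percent response: vehicle/substrate = 0%, reference inhibitor = 100%."""
    denom = auc_reference - auc_vehicle
    if denom == 0:
        raise ValueError("degenerate normalization: reference equals vehicle AUC")
    return 100.0 * (auc - auc_vehicle) / denom


def _inhibition_curve(log_c: np.ndarray, pic50: float, bottom: float, top: float) -> np.ndarray:
    # fixed pseudo-Hill slope of 1; response rises with concentration
    expo = np.clip(-(log_c + pic50), -30.0, 30.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def fit_inhibition_curve(
    concentrations_m: Sequence[float],
    responses_pct: Sequence[Sequence[float]] | Sequence[float],
) -> DoseResponseFit:
    """Fit percent responses to the fixed-slope sigmoid and return the pIC50.

    ``responses_pct`` holds one value or a replicate list per
    concentration; replicates are averaged before fitting and their SEM is
    reported. The fit is least squares with multi-start initialization
    over a log-spaced pIC50 grid spanning the tested concentrations
    +/- 1 log unit.
    """
    conc = np.asarray(concentrations_m, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(set(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    log_c = np.log10(conc)
    if log_c.max() - log_c.min() < 2:
        raise ValueError("concentrations must span at least 2 log units")

    means, sems = [], []
    for resp in responses_pct:
        arr = np.atleast_1d(np.asarray(resp, dtype=float))
        means.append(arr.mean())
        sems.append(arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0)
    y = np.asarray(means)
    if np.ptp(y) < 1e-9:
        raise ValueError("no concentration dependence: responses are flat")

    span = float(np.ptp(y))
    starts = np.linspace(-log_c.max() - 1, -log_c.min() + 1, 13)
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _inhibition_curve, log_c, y,
                p0=[p0, float(y.min()), float(y.max())],
                maxfev=5000,
            )
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean((y - _inhibition_curve(log_c, *popt)) ** 2)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from any start")
    (pic50, bottom, top), resid = best
    if not (-log_c.max() - 1 <= pic50 <= -log_c.min() + 1):
        raise RuntimeError(
            f"fitted pIC50 {pic50:.2f} outside tested span +/- 1 log unit"
        )
    if resid > max(5.0, 0.25 * span):
        # poor fit usually means no sigmoidal dependence in range
        raise RuntimeError(f"dose-response fit residual too large ({resid:.1f}%)")
    table = pd.DataFrame(
        {"concentration_m": conc, "mean_response": y, "sem": sems}
    ).sort_values("concentration_m", ignore_index=True)
    return DoseResponseFit(
        pic50=float(pic50), bottom=float(bottom), top=float(top),
        residual=resid, per_concentration=table,
    )


def analyze_experiment(
    traces: pd.DataFrame,
    plate_map: pd.DataFrame,
    t_substrate_min: float,
    window_min: float = AUC_WINDOW_MIN,
) -> pd.DataFrame:
    """Per-well net AUCs from long-format traces plus a plate map.

    ``traces`` columns: well, time_min, impedance_ohm. ``plate_map``
    columns: well, role (sample | vehicle | ne_control | reference),
    compound_id, concentration_m. The vehicle/vehicle wells (role ==
    vehicle, no substrate) are averaged into the correction trace; the
    substrate-only wells (role == ne_control) anchor 0% and the
    reference-inhibitor wells (role == reference) anchor 100% of the
    percent response. One row per corrected well is returned with its
    net AUC and percent response.
    """
    wells = {}
    for well, group in traces.groupby("well"):
        group = group.sort_values("time_min")
        t = group["time_min"].to_numpy(dtype=float)
        z = group["impedance_ohm"].to_numpy(dtype=float)
        ci = cell_index(z, z0=z[0])
        nci = normalize_trace(t, ci, t_substrate_min)
        wells[well] = (t, nci)

    roles = plate_map.set_index("well")
    vehicle_wells = roles.index[roles["role"] == "vehicle"]
    if len(vehicle_wells) == 0:
        raise ValueError("plate map has no vehicle/vehicle wells")
    vt = wells[vehicle_wells[0]][0]
    vehicle_nci = np.mean(
        [np.interp(vt, *wells[w]) for w in vehicle_wells], axis=0
    )

    rows = []
    for well, (t, nci) in wells.items():
        if well not in roles.index or roles.loc[well, "role"] == "vehicle":
            continue
        corrected = vehicle_correct(t, nci, vt, vehicle_nci)
        auc = net_auc(t, corrected, t_start=t_substrate_min, window_min=window_min)
        rows.append(
            {
                "well": well,
                "role": roles.loc[well, "role"],
                "compound_id": roles.loc[well, "compound_id"],
                "concentration_m": roles.loc[well, "concentration_m"],
                "net_auc": auc,
            }
        )
    out = pd.DataFrame(rows)
    ref_auc = out.loc[out["role"] == "reference", "net_auc"].mean()
    ne_auc = out.loc[out["role"] == "ne_control", "net_auc"].mean()
    if np.isnan(ref_auc) or np.isnan(ne_auc):
        raise ValueError("plate map needs both ne_control and reference wells")
    out["percent_response"] = [
        percent_normalize(a, ne_auc, ref_auc) for a in out["net_auc"]
    ]
    return out


def fit_compound(
    responses: pd.DataFrame, compound_id: str
) -> DoseResponseFit:
    """Dose-response fit for one compound from an analyze_experiment table."""
    sub = responses[(responses["compound_id"] == compound_id) & (responses["role"] == "sample")]
    if sub.empty:
        raise KeyError(f"no sample wells for compound {compound_id!r}")
    grouped = sub.groupby("concentration_m")["percent_response"].apply(list)
    return fit_inhibition_curve(list(grouped.index), list(grouped.values))
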