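"""The four model studies: hydration range, thickness influence, frequency sweep
and electrode-dimension sensitivity.

The relative electrode sensitivity compares the capacitance at a hydration
level against the fully hydrated reference:

    r(aw) = (C(aw) - C(0.996)) / C(0.996)

so ``r`` vanishes at ``aw = 0.996`` by construction and is positive wherever
drying raises the capacitance.  Everything downstream of the sorption chain is
deterministic: identical configurations produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import ElectrodeSpec, build_skin_stack, circular_electrode, \
    interdigitated_electrode
from .quasistatic import electrode_admittance
from .sc_hydration import (
    DEFAULT_MODEL,
    SorptionModel,
    HUMIDITY_PROTOCOL,
    run_protocol,
)

__all__ = [
    "AW_GRID",
    "AW_REFERENCE",
    "SensitivityCurve",
    "default_electrodes",
    "hydration_range_experiment",
    "thickness_influence_experiment",
    "frequency_sweep_experiment",
    "relative_sensitivity",
    "dimension_sweep",
    "conductance_vs_capacitance_ratio",
]

#: Fully hydrated reference activity (sensitivity baseline).
AW_REFERENCE = 0.996

#: Default water-activity grid: spans the physiological range with refinement
#: around the swelling turning point near 0.95.
AW_GRID = (0.80, 0.85, 0.90, 0.925, 0.95, 0.97, 0.985, AW_REFERENCE)


def default_electrodes() -> dict[str, ElectrodeSpec]:
    """The three reference electrode geometries."""
    return {
        "circular_conductance": circular_electrode(rs=2.5, d=1.0),
        "interdigitated_conductance": interdigitated_electrode(w=0.1, d=0.1),
        "interdigitated_capacitance": interdigitated_electrode(w=0.1, d=0.1,
                                                               insulated=True),
    }


@dataclass
class SensitivityCurve:
    """Capacitance and relative sensitivity over an activity grid."""

    aw_grid: np.ndarray
    C: np.ndarray                     # F
    r: np.ndarray
    label: str = ""
    parameter: str = ""
    value: float = float("nan")

    def __post_init__(self) -> None:
        aw = np.asarray(self.aw_grid, dtype=float)
        idx = np.argmin(np.abs(aw - AW_REFERENCE))
        if abs(aw[idx] - AW_REFERENCE) > 1e-9:
            raise ValueError("sensitivity curve needs the aw=0.996 reference point")
        if abs(self.r[idx]) > 1e-12:
            raise ValueError("r must vanish at the reference activity")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("non-finite sensitivity values")


def relative_sensitivity(C_curve: Mapping[float, float] | pd.Series) -> pd.Series:
    """Relative sensitivity r(aw) of a capacitance-vs-activity curve.

    The curve must contain the fully hydrated reference ``aw = 0.996``.
    """
    s = pd.Series(dict(C_curve)).sort_index() if not isinstance(C_curve, pd.Series) \
        else C_curve.sort_index()
    ref_candidates = [a for a in s.index if abs(a - AW_REFERENCE) < 1e-9]
    if not ref_candidates:
        raise KeyError("capacitance curve lacks the aw=0.996 reference point")
    c0 = float(s[ref_candidates[0]])
    return (s - c0) / c0


# ----------------------------------------------------------------------------
# Study 1: hydration range of the transport model
# ----------------------------------------------------------------------------

def hydration_range_experiment(
    model: SorptionModel = DEFAULT_MODEL,
    n: int = 101,
    t_max: float = 1e6,
) -> dict[str, float]:
    """Physiological SC hydration range from the dynamic transport model.

    Dehydrates fully hydrated tissue at 30 % ambient humidity, then exposes
    that state to dry (0 %) and saturated (100 %) air until the concentration
    statistics settle.  Returns the bulk (depth-averaged) SC water
    concentration and its activity for both extremes, alongside the surface
    node values and convergence flags.
    """
    steps = (HUMIDITY_PROTOCOL[0], HUMIDITY_PROTOCOL[1], HUMIDITY_PROTOCOL[5])
    res = run_protocol(steps, model, n=n, t_max=t_max)
    dry, wet = res["step2_RH0"], res["step6_RH100"]
    return {
        "Cw_dry": dry.mean_Cw,
        "aw_dry": dry.mean_aw(model),
        "Cw_wet": wet.mean_Cw,
        "aw_wet": wet.mean_aw(model),
        "Cw_dry_surface": dry.surface_Cw,
        "Cw_wet_surface": wet.surface_Cw,
        "delta_dry_um": dry.delta,
        "delta_wet_um": wet.delta,
        "converged_dry": bool(dry.converged),
        "converged_wet": bool(wet.converged),
    }


# ----------------------------------------------------------------------------
# Study 2: swelling vs constant thickness
# ----------------------------------------------------------------------------

def _capacitance_curve(
    electrode: ElectrodeSpec,
    aw_grid: Sequence[float],
    f: float,
    constant_thickness: float | None,
    refinement: int,
    model: SorptionModel,
) -> pd.Series:
    out = {}
    for aw in aw_grid:
        stack = build_skin_stack(aw=aw, constant_thickness=constant_thickness,
                                 model=model)
        out[float(aw)] = electrode_admittance(stack, electrode, f, refinement).C
    return pd.Series(out).sort_index()


def thickness_influence_experiment(
    electrode: ElectrodeSpec,
    f: float = 1e6,
    aw_grid: Sequence[float] = AW_GRID,
    constant_thickness: float = 9.55,
    refinement: int = 1,
    model: SorptionModel = DEFAULT_MODEL,
) -> dict:
    """Capacitance vs activity with swelling enabled and with fixed SC thickness.

    Returns both curves plus the activity at which the swelling branch peaks
    (the turning point where thickness growth starts to outweigh the
    permittivity rise).
    """
    C_swell = _capacitance_curve(electrode, aw_grid, f, None, refinement, model)
    C_const = _capacitance_curve(electrode, aw_grid, f, constant_thickness,
                                 refinement, model)
    return {
        "C_swelling": C_swell,
        "C_constant": C_const,
        "argmax_aw_swelling": float(C_swell.idxmax()),
    }


# ----------------------------------------------------------------------------
# Study 3: frequency sweep
# ----------------------------------------------------------------------------

def frequency_sweep_experiment(
    electrode: ElectrodeSpec,
    aw_grid: Sequence[float] = AW_GRID,
    f_grid: Sequence[float] | None = None,
    refinement: int = 1,
    model: SorptionModel = DEFAULT_MODEL,
) -> pd.DataFrame:
    """C(aw, f) on a log-spaced frequency grid (default 10 kHz to 1 GHz)."""
    if f_grid is None:
        f_grid = np.logspace(4, 9, 11)
    rows = []
    for f in f_grid:
        C = _capacitance_curve(electrode, aw_grid, float(f), None, refinement, model)
        for aw, c in C.items():
            rows.append({"f_Hz": float(f), "aw": float(aw), "C_F": float(c)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# Study 4: dimension sensitivity
# ----------------------------------------------------------------------------

def _sweep_electrode(variant: str, parameter: str, value: float) -> ElectrodeSpec:
    if variant == "circular_conductance":
        if parameter == "gap":
            return circular_electrode(rs=2.5, d=value)
        if parameter == "radius":
            return circular_electrode(rs=value, d=1.0)
    else:
        insulated = variant == "interdigitated_capacitance"
        if parameter == "gap":
            return interdigitated_electrode(w=0.1, d=value, insulated=insulated)
        if parameter == "width":
            return interdigitated_electrode(w=value, d=0.1, insulated=insulated)
    raise ValueError(f"cannot sweep {parameter!r} on {variant!r}")


def dimension_sweep(
    variant: str,
    parameter: str,
    values: Sequence[float],
    aw_grid: Sequence[float] = AW_GRID,
    f: float = 1e6,
    refinement: int = 1,
    model: SorptionModel = DEFAULT_MODEL,
    reporting_aw: float = 0.90,
) -> dict:
    """Sweep one electrode dimension and report the sensitivity per value.

    For every swept value the capacitance curve C(aw) is computed with swelling
    enabled, converted to the relative sensitivity r, and summarized by |r| at
    ``reporting_aw``.  The location of an interior optimum of |r| is estimated
    by a quadratic fit through the best grid point and its neighbours.
    """
    curves: list[SensitivityCurve] = []
    for val in values:
        el = _sweep_electrode(variant, parameter, float(val))
        C = _capacitance_curve(el, aw_grid, f, None, refinement, model)
        r = relative_sensitivity(C)
        curves.append(SensitivityCurve(
            aw_grid=np.asarray(C.index, dtype=float), C=C.to_numpy(),
            r=r.to_numpy(), label=f"{variant}:{parameter}={val}",
            parameter=parameter, value=float(val)))
    vals = np.asarray(values, dtype=float)
    idx_rep = int(np.argmin(np.abs(curves[0].aw_grid - reporting_aw)))
    mag = np.array([abs(c.r[idx_rep]) for c in curves])
    # overall sensitivity of a geometry: the peak-to-peak span of its response
    # curve over the hydration range (r changes sign near the swelling turning
    # point, so a fixed-activity |r| is blind to the overall response swing)
    span = np.array([float(c.r.max() - c.r.min()) for c in curves])
    return {
        "curves": curves,
        "values": vals,
        "abs_r_at_reporting_aw": mag,
        "reporting_aw": float(curves[0].aw_grid[idx_rep]),
        "response_span": span,
        "optimum_value": _quadratic_peak(vals, span),
        "optimum_value_at_reporting_aw": _quadratic_peak(vals, mag),
    }


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak location by a quadratic through the best point and its neighbours.

    Falls back to the best grid point when the peak sits on the sweep boundary
    or the fit is degenerate.
    """
    order = np.argsort(x)
    x, y = x[order], y[order]
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    xs, ys = x[i - 1:i + 2], y[i - 1:i + 2]
    a, b, _ = np.polyfit(xs, ys, 2)
    if a >= 0:
        return float(x[i])
    peak = -b / (2 * a)
    return float(np.clip(peak, xs[0], xs[-1]))


def conductance_vs_capacitance_ratio(
    aw_grid: Sequence[float] = AW_GRID,
    f: float = 1e6,
    refinement: int = 1,
    model: SorptionModel = DEFAULT_MODEL,
    split_aw: float = 0.95,
) -> dict:
    """Sensitivity ratio of the conductance electrode families to the capacitance one.

    Computes r(aw) at the default geometries for the circular and
    interdigitated conductance electrodes and the interdigitated capacitance
    electrode.  Two comparisons are reported per conductance electrode:

    * ``char_ratio`` -- the ratio of characteristic sensitivities, i.e. the
      peak |r| over activities below ``split_aw`` (and separately above it as
      ``char_ratio_high``).  This is the robust headline number: every r curve
      crosses zero once below the swelling turning point, so a pointwise ratio
      is dominated by wherever a grid point lands relative to that zero.
    * ``ratios`` / ``min_pointwise_ratio`` -- the pointwise |r_cond|/|r_cap|
      per activity and its minimum below ``split_aw``, kept as a diagnostic.
    """
    electrodes = default_electrodes()
    r = {}
    for name, el in electrodes.items():
        C = _capacitance_curve(el, aw_grid, f, None, refinement, model)
        r[name] = relative_sensitivity(C)
    cap = r["interdigitated_capacitance"].abs()
    aw_idx = cap.index.to_numpy()
    not_ref = np.abs(aw_idx - AW_REFERENCE) > 1e-9
    low = (aw_idx < split_aw) & not_ref
    high = (aw_idx >= split_aw) & not_ref
    out = {"r": r, "ratios": {}, "min_pointwise_ratio": {},
           "char_ratio": {}, "char_ratio_high": {}}
    for name in ("circular_conductance", "interdigitated_conductance"):
        ratio = r[name].abs() / cap
        out["ratios"][name] = ratio
        out["min_pointwise_ratio"][name] = float(ratio[low].min())
        out["char_ratio"][name] = float(r[name].abs()[low].max() / cap[low].max())
        out["char_ratio_high"][name] = float(
            r[name].abs()[high].max() / cap[high].max())
    return out
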