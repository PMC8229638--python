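"""Stratum-corneum hydration: GAB sorption, swelling and moving-boundary water transport.

The stratum corneum (SC) is modelled as a one-dimensional slab of dry keratin
matrix plus sorbed water.  Three ingredients are combined:

* the Guggenheim--Anderson--deBoer (GAB) multilayer sorption isotherm, which maps
  water activity ``aw`` to an equilibrium sorbed-water volume per gram of dry
  tissue and, through volume additivity, to a water concentration ``Cw``
  (g water per cm^3 of swollen tissue);
* a swelling relation: assuming the partial molar volume of sorbed water equals
  that of bulk water, the slab thickness is ``delta_dry / (1 - Cw/rho_w)``;
* a convection--diffusion transport equation on the swelling slab.  Water enters
  at the lower (epidermal) boundary, which is held fully hydrated, and leaves
  through the skin surface by evaporation into ambient air at relative humidity
  ``RH``.  The net boundary-flux imbalance moves the free surface (a Stefan-type
  moving boundary).

All transport internals are CGS (g, cm, s); thickness crosses the public API in
micrometres.  The moving boundary is handled by the Landau front-fixing
transformation ``xi = z/delta(t)`` on a fixed normalized grid, with implicit
(BDF / backward-Euler) time stepping.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.sparse import lil_matrix

__all__ = [
    "SorptionModel",
    "TransportState",
    "FluxReport",
    "GabDomainError",
    "InversionRangeError",
    "gab_sorption_volume",
    "equilibrium_water_concentration",
    "water_activity_from_concentration",
    "equilibrium_thickness",
    "diffusivity",
    "surface_flux",
    "make_grid",
    "uniform_state",
    "step_transport",
    "run_to_equilibrium",
    "run_protocol",
    "dry_mass_per_area",
    "HUMIDITY_PROTOCOL",
    "INNER_CW",
]

#: Ideal gas constant in cm^3 Pa / (K mol) so that evaporative fluxes come out in
#: g/(cm^2 s) with the mass-transfer coefficient in cm/s.
R_GAS_CGS = 8.314e6

#: Water concentration held at the inner (epidermal) boundary, g/cm^3.
INNER_CW = 0.781


class GabDomainError(ValueError):
    """Water activity outside the GAB domain (``k*aw >= 1`` hits the isotherm pole)."""


class InversionRangeError(ValueError):
    """Concentration outside the invertible range of the sorption chain."""


@dataclass(frozen=True)
class SorptionModel:
    """GAB sorption and transport constants for human stratum corneum.

    Defaults are the published in-vivo parameter set: GAB constants
    ``c=4.39``, ``k=1/1.01``, monolayer volume ``Vm=0.0386`` g/g, water and dry
    tissue densities 1.0 and 1.3 g/cm^3, dry thickness 9.55 um, gas-side
    mass-transfer coefficient 0.318 cm/s, saturated vapour pressure 4.76 kPa at
    a skin surface temperature of 32 C.
    """

    c: float = 4.39
    k: float = 1.0 / 1.01
    Vm: float = 0.0386
    rho_w: float = 1.0
    rho_mem: float = 1.3
    delta_dry: float = 9.55          # um
    kg: float = 0.318                # cm/s
    p_sat: float = 4760.0            # Pa
    T: float = 305.2                 # K
    MW: float = 18.0                 # g/mol
    R: float = R_GAS_CGS             # cm^3 Pa / (K mol)
    #: Reading of the flattened printed diffusivity formula: "paren" treats the
    #: leading 0.433 as multiplying (1 - a e^- + b e^+); "flat" reads the terms
    #: as a plain sum 0.433 - a e^- + b e^+.
    d_reading: str = "paren"
    #: Multiplier converting the dimensionless diffusivity polynomial to cm^2/s.
    d_scale: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("rho_w", "rho_mem", "Vm", "delta_dry", "kg", "p_sat", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SorptionModel.{name} must be positive")
        if self.d_reading not in ("paren", "flat"):
            raise ValueError(f"unknown diffusivity reading {self.d_reading!r}")

    @property
    def aw_pole(self) -> float:
        """Water activity at which the GAB isotherm diverges (``k*aw = 1``)."""
        return 1.0 / self.k

    @property
    def vapor_density(self) -> float:
        """Saturated water-vapour density at skin temperature, g/cm^3."""
        return self.p_sat * self.MW / (self.R * self.T)


DEFAULT_MODEL = SorptionModel()


# ----------------------------------------------------------------------------
# Equilibrium sorption (GAB chain)
# ----------------------------------------------------------------------------

def gab_sorption_volume(aw, model: SorptionModel = DEFAULT_MODEL):
    """Equilibrium sorbed-water volume V (g water / g dry tissue) at activity ``aw``.

    ``V = Vm c k aw / ((1 - k aw)(1 - k aw + c k aw))``; strictly increasing on
    the physical branch ``0 <= k aw < 1``.
    """
    aw_arr = np.asarray(aw, dtype=float)
    if np.any(aw_arr < 0) or np.any(model.k * aw_arr >= 1.0):
        raise GabDomainError(
            f"water activity must satisfy 0 <= aw < {model.aw_pole:.4f} "
            "(GAB pole at k*aw = 1)"
        )
    x = model.k * aw_arr
    V = model.Vm * model.c * x / ((1.0 - x) * (1.0 - x + model.c * x))
    return V if V.shape else float(V)


def equilibrium_water_concentration(aw, model: SorptionModel = DEFAULT_MODEL):
    """Equilibrium water concentration Cw (g/cm^3) at activity ``aw``.

    Composes the GAB isotherm with volume additivity:
    ``Cw = rho_w rho_mem V / (rho_w + rho_mem V)``.
    """
    V = np.asarray(gab_sorption_volume(aw, model))
    Cw = model.rho_w * model.rho_mem * V / (model.rho_w + model.rho_mem * V)
    return Cw if Cw.shape else float(Cw)


def water_activity_from_concentration(Cw, model: SorptionModel = DEFAULT_MODEL):
    """Numerically invert the sorption chain: concentration -> water activity.

    The chain is strictly increasing in ``aw``, so the inverse is the unique
    root on the monotone branch below the GAB pole.
    """
    def _invert(cw: float) -> float:
        if cw < 0 or cw >= model.rho_w:
            raise InversionRangeError(f"Cw={cw} outside [0, rho_w)")
        if cw == 0.0:
            return 0.0
        hi = model.aw_pole * (1.0 - 1e-12)
        cw_hi = equilibrium_water_concentration(hi, model)
        if cw >= cw_hi:
            raise InversionRangeError(
                f"Cw={cw} above the largest invertible concentration {cw_hi:.6f}"
            )
        return brentq(
            lambda a: equilibrium_water_concentration(a, model) - cw,
            0.0, hi, xtol=1e-15, rtol=8.9e-16,
        )

    arr = np.asarray(Cw, dtype=float)
    if arr.shape:
        return np.array([_invert(float(v)) for v in arr.ravel()]).reshape(arr.shape)
    return _invert(float(arr))


def equilibrium_thickness(Cw, model: SorptionModel = DEFAULT_MODEL):
    """Swollen SC thickness (um) at water concentration ``Cw`` (g/cm^3)."""
    arr = np.asarray(Cw, dtype=float)
    if np.any(arr < 0) or np.any(arr >= model.rho_w):
        raise InversionRangeError("Cw must lie in [0, rho_w) (thickness pole at rho_w)")
    delta = model.delta_dry / (1.0 - arr / model.rho_w)
    return delta if delta.shape else float(delta)


def diffusivity(Cw, model: SorptionModel = DEFAULT_MODEL):
    """Hydration-dependent water diffusivity in the SC (cm^2/s).

    Empirical fit: under the default reading
    ``D = 0.433 (1 - 0.3765 e^{-9.6215 Cw} + 6.428e-5 e^{12.873 Cw}) * 1e-9``,
    ranging from 2.7e-10 cm^2/s dry to ~1.1e-9 cm^2/s fully hydrated.
    """
    arr = np.asarray(Cw, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1.0):
        raise ValueError("Cw must lie in [0, 1) for the diffusivity fit")
    terms = -0.3765 * np.exp(-9.6215 * arr) + 6.428e-5 * np.exp(12.873 * arr)
    if model.d_reading == "paren":
        D = 0.433 * (1.0 + terms) * model.d_scale
    else:  # "flat"
        D = (0.433 + terms) * model.d_scale
    return D if D.shape else float(D)


def surface_flux(aw_surface: float, RH: float, model: SorptionModel = DEFAULT_MODEL) -> float:
    """Evaporative water flux through the skin surface, g/(cm^2 s).

    ``f = kg (aw_surface - RH) p_sat MW / (R T)``: positive for evaporation
    (surface wetter than ambient), negative for condensation.  This is the
    transepidermal-water-loss boundary condition.
    """
    return model.kg * (aw_surface - RH) * model.vapor_density


# ----------------------------------------------------------------------------
# Transport state and dynamics
# ----------------------------------------------------------------------------

@dataclass
class TransportState:
    """Water concentration profile on the normalized (front-fixed) grid.

    ``xi_grid`` spans [0, 1] with 0 at the epidermal boundary and 1 at the skin
    surface; ``delta`` is the current slab thickness in micrometres.
    ``converged`` is set by :func:`run_to_equilibrium`.
    """

    xi_grid: np.ndarray
    Cw_profile: np.ndarray
    delta: float                      # um
    time: float = 0.0                 # s
    converged: bool | None = None

    def validate(self, model: SorptionModel = DEFAULT_MODEL) -> None:
        xi = np.asarray(self.xi_grid)
        if xi[0] != 0.0 or xi[-1] != 1.0 or np.any(np.diff(xi) <= 0):
            raise ValueError("xi_grid must increase strictly from 0 to 1")
        C = np.asarray(self.Cw_profile)
        if C.shape != xi.shape:
            raise ValueError("Cw_profile and xi_grid shapes differ")
        if np.any(C < 0) or np.any(C >= model.rho_w):
            raise ValueError("Cw_profile must lie in [0, rho_w)")
        if self.delta < model.delta_dry * (1.0 - 1e-12):
            raise ValueError("delta cannot be below the dry thickness")

    @property
    def surface_Cw(self) -> float:
        return float(self.Cw_profile[-1])

    @property
    def mean_Cw(self) -> float:
        """Depth-averaged water concentration (g/cm^3) of the slab."""
        return float(np.trapezoid(self.Cw_profile, self.xi_grid))

    def surface_aw(self, model: SorptionModel = DEFAULT_MODEL) -> float:
        return float(water_activity_from_concentration(self.surface_Cw, model))

    def mean_aw(self, model: SorptionModel = DEFAULT_MODEL) -> float:
        return float(water_activity_from_concentration(self.mean_Cw, model))


@dataclass(frozen=True)
class FluxReport:
    """Boundary fluxes (g/(cm^2 s)) and convective velocity (cm/s) of one step."""

    f0: float
    f_delta: float
    v: float


def make_grid(n: int = 101, grading: float = 2.5) -> np.ndarray:
    """Normalized grid on [0, 1], clustered toward the surface ``xi = 1``.

    ``grading`` > 1 compresses nodes toward the evaporating surface where the
    concentration boundary layer forms; 1 gives a uniform grid.
    """
    u = np.linspace(0.0, 1.0, n)
    xi = 1.0 - (1.0 - u) ** grading
    xi[0], xi[-1] = 0.0, 1.0
    return xi


def uniform_state(
    Cw: float = INNER_CW,
    model: SorptionModel = DEFAULT_MODEL,
    n: int = 101,
    grading: float = 2.5,
) -> TransportState:
    """Uniformly hydrated initial state with the equilibrium swollen thickness."""
    xi = make_grid(n, grading)
    return TransportState(xi, np.full(n, float(Cw)), equilibrium_thickness(Cw, model))


def dry_mass_per_area(state: TransportState, model: SorptionModel = DEFAULT_MODEL) -> float:
    """Dry-matrix mass per unit area (g/cm^2) -- a conservation diagnostic.

    The printed thickness-rate law is a water volume balance, not a dry-mass
    conservation law, so this quantity drifts during transients; it is exposed
    so that the drift can be monitored rather than silently hidden.
    """
    delta_cm = state.delta * 1e-4
    solid_frac = 1.0 - np.asarray(state.Cw_profile) / model.rho_w
    return float(model.rho_mem * delta_cm * np.trapezoid(solid_frac, state.xi_grid))


class _TransportRHS:
    """Semi-discrete front-fixed system: y = [C_1..C_N, delta_cm]."""

    def __init__(self, xi: np.ndarray, RH: float, model: SorptionModel,
                 inner_Cw: float = INNER_CW, freeze_boundary: bool = False):
        self.xi = np.asarray(xi, dtype=float)
        self.h = np.diff(self.xi)
        self.RH = float(RH)
        self.model = model
        self.inner_Cw = float(inner_Cw)
        self.freeze = freeze_boundary
        self.n_free = len(self.xi) - 1           # C_1..C_N
        # cap used when transiently clipping the surface value for inversion
        self._cw_cap = equilibrium_water_concentration(
            model.aw_pole * (1.0 - 1e-9), model) - 1e-12

    def fluxes(self, C: np.ndarray, delta: float) -> FluxReport:
        m = self.model
        h = self.h
        # second-order one-sided gradient at the inner boundary
        h0, h1 = h[0], h[1]
        dCdz0 = (
            -(2 * h0 + h1) / (h0 * (h0 + h1)) * C[0]
            + (h0 + h1) / (h0 * h1) * C[1]
            - h0 / (h1 * (h0 + h1)) * C[2]
        ) / delta
        if self.freeze:
            f0, v = 0.0, 0.0
        else:
            # f = -D dC/dz + v C with v = f0/rho_w gives f0 = -D dC/dz /(1-C/rho_w)
            f0 = -diffusivity(C[0], m) * dCdz0 / (1.0 - C[0] / m.rho_w)
            v = f0 / m.rho_w
        Cs = float(min(max(C[-1], 0.0), self._cw_cap))
        aw_s = water_activity_from_concentration(Cs, m)
        f_delta = surface_flux(aw_s, self.RH, m)
        return FluxReport(f0=f0, f_delta=f_delta, v=v)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        m = self.model
        xi, h = self.xi, self.h
        N = self.n_free
        C = np.empty(N + 1)
        C[0] = self.inner_Cw
        C[1:] = y[:-1]
        delta = float(y[-1])
        rep = self.fluxes(C, delta)
        ddelta = 0.0 if self.freeze else (rep.f0 - rep.f_delta) / m.rho_w

        Dh = diffusivity(np.clip(0.5 * (C[:-1] + C[1:]), 0.0, 0.999), m)
        dC = np.empty(N + 1)
        dC[0] = 0.0
        # interior nodes: grid-motion + convection advective term, conservative
        # diffusion on the nonuniform grid
        adv_coef = (xi[1:-1] * ddelta - rep.v) / delta
        dCdxi = (C[2:] - C[:-2]) / (h[:-1] + h[1:])
        diff = (Dh[1:] * (C[2:] - C[1:-1]) / h[1:]
                - Dh[:-1] * (C[1:-1] - C[:-2]) / h[:-1]) \
            / (0.5 * (h[:-1] + h[1:]) * delta * delta)
        dC[1:-1] = adv_coef * dCdxi + diff
        # surface node: Robin condition  -D dC/dz + v C = f_delta
        hN = h[-1]
        advN = (xi[-1] * ddelta - rep.v) / delta * (C[-1] - C[-2]) / hN
        bnd_grad_flux = rep.v * C[-1] - rep.f_delta       # = D dC/dz at surface
        dC[-1] = advN + (bnd_grad_flux - Dh[-1] * (C[-1] - C[-2]) / (hN * delta)) \
            / (0.5 * hN * delta)
        out = np.empty(N + 1)
        out[:-1] = dC[1:]
        out[-1] = ddelta
        return out

    def jac_sparsity(self) -> lil_matrix:
        N = self.n_free
        S = lil_matrix((N + 1, N + 1), dtype=float)
        for i in range(N):
            for j in (i - 1, i, i + 1):
                if 0 <= j < N:
                    S[i, j] = 1.0
        # every row depends on delta, on the inner-gradient nodes (through v)
        # and on the surface node (through f_delta / ddelta)
        S[:, N] = 1.0
        S[:, 0] = 1.0
        S[:, 1] = 1.0
        S[:, N - 1] = 1.0
        S[N, :] = 1.0
        return S


def _pack(state: TransportState) -> np.ndarray:
    return np.concatenate([state.Cw_profile[1:], [state.delta * 1e-4]])


def _unpack(y: np.ndarray, xi: np.ndarray, t: float, inner_Cw: float) -> TransportState:
    C = np.concatenate([[inner_Cw], y[:-1]])
    return TransportState(xi.copy(), C, float(y[-1]) * 1e4, time=t)


def step_transport(
    state: TransportState,
    dt: float,
    RH: float,
    model: SorptionModel = DEFAULT_MODEL,
    inner_Cw: float = INNER_CW,
    freeze_boundary: bool = False,
    dt_floor_ratio: float = 1e-6,
) -> tuple[TransportState, FluxReport]:
    """Advance one implicit (backward-Euler) step of the moving-boundary system.

    The nonlinear stage equation is solved with damped Newton on a
    finite-difference Jacobian; on failure (or an out-of-range concentration)
    the step is rejected and ``dt`` halved, down to ``dt * dt_floor_ratio``.
    Returns the new state and the boundary fluxes evaluated at the new state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate(model)
    rhs = _TransportRHS(state.xi_grid, RH, model, inner_Cw, freeze_boundary)
    y0 = _pack(state)
    t_target = state.time + dt
    t, y = state.time, y0.copy()
    sub_dt = dt
    while t < t_target - 1e-12 * dt:
        sub_dt = min(sub_dt, t_target - t)
        y_new = _backward_euler_step(rhs, y, sub_dt)
        if y_new is None:
            sub_dt *= 0.5
            if sub_dt < dt * dt_floor_ratio:
                raise RuntimeError("transport step rejected below the dt floor")
            continue
        y = y_new
        t += sub_dt
        sub_dt *= 2.0
    new_state = _unpack(y, state.xi_grid, t, inner_Cw)
    new_state.validate(model)
    C_full = np.concatenate([[inner_Cw], y[:-1]])
    return new_state, rhs.fluxes(C_full, float(y[-1]))


def _backward_euler_step(rhs: _TransportRHS, y0: np.ndarray, dt: float,
                         max_iter: int = 12, tol: float = 1e-11) -> np.ndarray | None:
    """One BE stage solved with Newton; returns None if it fails to converge."""
    n = len(y0)
    y = y0 + dt * rhs(0.0, y0)          # forward-Euler predictor
    y = np.clip(y, a_min=None, a_max=None)
    scale = np.maximum(np.abs(y0), 1e-6)
    for _ in range(max_iter):
        try:
            F = y - y0 - dt * rhs(0.0, y)
        except (InversionRangeError, ValueError):
            return None
        if np.max(np.abs(F) / scale) < tol:
            if np.any(y[:-1] < -1e-12) or np.any(y[:-1] >= 1.0) or y[-1] <= 0:
                return None
            return y
        J = np.eye(n)
        eps = 1e-8
        for j in range(n):
            dy = eps * max(abs(y[j]), 1e-8)
            yp = y.copy()
            yp[j] += dy
            try:
                Fp = yp - y0 - dt * rhs(0.0, yp)
            except (InversionRangeError, ValueError):
                return None
            J[:, j] = (Fp - F) / dy
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            return None
        y = y - step
    return None


def _integrate(
    state: TransportState,
    RH: float,
    duration: float,
    model: SorptionModel,
    inner_Cw: float = INNER_CW,
    freeze_boundary: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> TransportState:
    """Integrate the stiff semi-discrete system over ``duration`` seconds (BDF)."""
    rhs = _TransportRHS(state.xi_grid, RH, model, inner_Cw, freeze_boundary)
    sol = solve_ivp(
        rhs, (state.time, state.time + duration), _pack(state),
        method="BDF", rtol=rtol, atol=atol, jac_sparsity=rhs.jac_sparsity(),
    )
    if not sol.success:
        raise RuntimeError(f"transport integration failed: {sol.message}")
    return _unpack(sol.y[:, -1], state.xi_grid, sol.t[-1], inner_Cw)


def run_to_equilibrium(
    state: TransportState,
    RH: float,
    model: SorptionModel = DEFAULT_MODEL,
    tol_C: float = 1e-9,
    tol_delta: float = 1e-8,
    t_max: float = 1e6,
    inner_Cw: float = INNER_CW,
) -> TransportState:
    """Integrate until the state stops changing, or until ``t_max``.

    Convergence requires ``max |dCw/dt| < tol_C`` (g/(cm^3 s)) and
    ``|d delta/dt| < tol_delta`` (um/s).  Non-convergence is reported through
    ``state.converged = False``, never silently: with the inner boundary held
    fully hydrated, drying branches keep feeding water into the slab so the
    thickness creeps upward indefinitely even after the concentration profile
    has stopped evolving (see the package methods note).
    """
    if tol_C <= 0 or tol_delta <= 0:
        raise ValueError("tolerances must be positive")
    state.validate(model)
    current = replace(state, time=0.0)
    window = 10.0
    rhs = _TransportRHS(state.xi_grid, RH, model, inner_Cw)
    while current.time < t_max:
        window = min(window, t_max - current.time)
        current = _integrate(current, RH, window, model, inner_Cw)
        rate = rhs(current.time, _pack(current))
        max_dC = float(np.max(np.abs(rate[:-1])))
        ddelta_um = abs(float(rate[-1])) * 1e4
        if max_dC < tol_C and ddelta_um < tol_delta:
            current.converged = True
            return current
        window *= 10.0
    current.converged = False
    return current


#: Default drying/re-wetting protocol: dehydrate fully hydrated tissue at 30 %
#: ambient humidity until it settles, then expose that state to 0/40/60/80/100 %
#: humidity (the 40--80 % steps are 30-minute exposures mimicking measurement
#: sessions; the extremes run to their long-time state).
HUMIDITY_PROTOCOL: tuple[tuple[str, float, float | None], ...] = (
    ("step1_RH30", 0.30, None),
    ("step2_RH0", 0.00, None),
    ("step3_RH40", 0.40, 1800.0),
    ("step4_RH60", 0.60, 1800.0),
    ("step5_RH80", 0.80, 1800.0),
    ("step6_RH100", 1.00, None),
)


def run_protocol(
    steps: Sequence[tuple[str, float, float | None]] = HUMIDITY_PROTOCOL,
    model: SorptionModel = DEFAULT_MODEL,
    n: int = 101,
    grading: float = 2.5,
    t_max: float = 1e6,
    inner_Cw: float = INNER_CW,
) -> dict[str, TransportState]:
    """Run the multi-step humidity protocol and return the state after each step.

    The first step starts from uniformly fully hydrated tissue
    (``Cw = inner_Cw`` everywhere); every later step restarts from the first
    step's result, emulating repeated exposures of normally dried skin.  A step
    duration of ``None`` means run to (tolerance-detected) equilibrium.
    """
    if not steps:
        raise ValueError("protocol needs at least one step")
    results: dict[str, TransportState] = {}
    base: TransportState | None = None
    for i, (label, RH, duration) in enumerate(steps):
        start = uniform_state(inner_Cw, model, n, grading) if i == 0 else replace(
            base, Cw_profile=base.Cw_profile.copy(), time=0.0, converged=None)
        try:
            if duration is None:
                out = run_to_equilibrium(start, RH, model, t_max=t_max,
                                         inner_Cw=inner_Cw)
            else:
                out = _integrate(start, RH, float(duration), model, inner_Cw)
        except Exception as exc:
            raise RuntimeError(f"protocol step {label!r} failed: {exc}") from exc
        results[label] = out
        if i == 0:
            base = out
    return results
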