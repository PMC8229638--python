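"""Dispersive dielectric models of the skin layers.

Each skin layer is described by a complex relative permittivity in the
Cole--Cole form (convention ``eps_r = eps' - j eps''`` with time factor
``e^{+j w t}``):

    eps_r(w) = eps_inf + sum_n  d_eps_n / (1 + (j w tau_n)^(1-alpha_n))
                       + sigma_dc / (j w eps0)

The epidermis/dermis (approximated by blood) and hypodermis (infiltrated fat)
use fixed literature parameter sets.  The stratum corneum's parameters scale
linearly through the origin with its water concentration: a fast ("free
water") Debye term and a slower protein-polarization term, each with an
increment and relaxation time proportional to ``Cw`` in kg/m^3, plus an
optical permittivity that rises from the dry-protein value 3.3 with the free
water increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EPS0",
    "ColeColeParams",
    "SCDielectricBetas",
    "SCDielectricParams",
    "cole_cole_permittivity",
    "complex_conductivity",
    "sc_dielectric_params",
    "sc_permittivity",
    "fit_beta",
    "layer_params",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: Relative permittivity of free water (static) and of dry SC protein.
EPS_WATER = 73.2
EPS_DRY_SC = 3.3


@dataclass(frozen=True)
class ColeColeParams:
    """One layer's dispersive dielectric description."""

    eps_inf: float
    terms: tuple[tuple[float, float, float], ...]   # (delta_eps, tau_s, alpha)
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError("eps_inf must be >= 1")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be >= 0")
        for de, tau, alpha in self.terms:
            if de < 0 or tau <= 0 or not (0 <= alpha < 1):
                raise ValueError(f"invalid Cole-Cole term {(de, tau, alpha)}")


@dataclass(frozen=True)
class SCDielectricBetas:
    """Through-origin scalings of the SC dielectric parameters with Cw (kg/m^3).

    Defaults are the published regression values against bulk SC water
    concentration: increment and relaxation time of the free-water term and of
    the slow protein term.
    """

    beta_deps_free: float = 0.0557
    beta_tau_free: float = 1.551e-14
    beta_deps_slow: float = 0.432
    beta_tau_slow: float = 1.785e-11


@dataclass(frozen=True)
class SCDielectricParams:
    """Interpolated SC dielectric parameters at one hydration level."""

    deps_free: float
    tau_free: float
    deps_slow: float
    tau_slow: float
    eps_inf: float


DEFAULT_BETAS = SCDielectricBetas()


def cole_cole_permittivity(params: ColeColeParams, f) -> complex | np.ndarray:
    """Complex relative permittivity of a layer at frequency ``f`` (Hz)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f_arr
    eps = np.full(f_arr.shape, params.eps_inf, dtype=complex)
    for de, tau, alpha in params.terms:
        eps = eps + de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    if params.sigma_dc:
        eps = eps + params.sigma_dc / (1j * w * EPS0)
    return eps if eps.shape else complex(eps)


def complex_conductivity(eps_r, f) -> complex | np.ndarray:
    """Complex conductivity ``sigma = j w eps0 eps_r`` (S/m)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    sigma = 1j * 2.0 * np.pi * f_arr * EPS0 * np.asarray(eps_r, dtype=complex)
    return sigma if sigma.shape else complex(sigma)


def sc_eps_inf(deps_free: float) -> float:
    """Optical permittivity of the SC from the free-water increment.

    Dry protein contributes 3.3; sorbed free water raises it with slope
    2/73.2, the ratio of the optical-to-static gap of water mapped onto its
    static permittivity.
    """
    return EPS_DRY_SC + (2.0 / EPS_WATER) * deps_free


def sc_dielectric_params(
    Cw: float, betas: SCDielectricBetas = DEFAULT_BETAS
) -> SCDielectricParams:
    """SC dielectric parameters at water concentration ``Cw`` (g/cm^3).

    Each parameter is ``beta * Cw`` with ``Cw`` expressed in kg/m^3
    (1 g/cm^3 = 1000 kg/m^3), the unit regime in which the shipped betas are
    dimensionally consistent.
    """
    if not (0.0 <= Cw < 1.0):
        raise ValueError("Cw must lie in [0, 1) g/cm^3")
    cw_si = 1000.0 * Cw
    deps_free = betas.beta_deps_free * cw_si
    return SCDielectricParams(
        deps_free=deps_free,
        tau_free=betas.beta_tau_free * cw_si,
        deps_slow=betas.beta_deps_slow * cw_si,
        tau_slow=betas.beta_tau_slow * cw_si,
        eps_inf=sc_eps_inf(deps_free),
    )


def sc_permittivity(Cw: float, f, betas: SCDielectricBetas = DEFAULT_BETAS):
    """Hydration-dependent complex permittivity of the stratum corneum.

    Two-term Debye model (no broadening, no DC conductivity) with parameters
    proportional to the water concentration; at ``Cw = 0`` it reduces to the
    dry-protein value 3.3 at all frequencies.
    """
    p = sc_dielectric_params(Cw, betas)
    if Cw == 0.0:
        f_arr = np.asarray(f, dtype=float)
        if np.any(f_arr <= 0):
            raise ValueError("frequency must be positive")
        out = np.full(f_arr.shape, complex(p.eps_inf))
        return out if out.shape else complex(p.eps_inf)
    cc = ColeColeParams(
        eps_inf=p.eps_inf,
        terms=((p.deps_free, p.tau_free, 0.0), (p.deps_slow, p.tau_slow, 0.0)),
    )
    return cole_cole_permittivity(cc, f)


def fit_beta(y_samples: Sequence[float], Cw_samples: Sequence[float]) -> float:
    """Through-origin least squares: ``beta = sum(y Cw) / sum(Cw^2)``.

    ``Cw_samples`` in kg/m^3, matching the unit regime of the shipped betas.
    """
    y = np.asarray(y_samples, dtype=float)
    cw = np.asarray(Cw_samples, dtype=float)
    if y.size == 0 or y.shape != cw.shape:
        raise ValueError("samples must be equal-length and non-empty")
    denom = float(cw @ cw)
    if denom == 0.0:
        raise ValueError("degenerate design: all Cw samples are zero")
    return float(y @ cw) / denom


#: Fixed Cole-Cole parameter sets: epidermis/dermis approximated by blood,
#: hypodermis by infiltrated fat.
_LAYER_REGISTRY: dict[str, ColeColeParams] = {
    "E/D": ColeColeParams(
        eps_inf=4.0,
        terms=(
            (56.0, 8.38e-12, 0.10),
            (5200.0, 132.6e-12, 0.10),
        ),
        sigma_dc=0.7,
    ),
    "HYP": ColeColeParams(
        eps_inf=2.5,
        terms=(
            (9.0, 79.9e-12, 0.20),
            (35.0, 15.92e-12, 0.10),
            (33000.0, 159e-12, 0.05),
            (107.0, 15.9e-12, 0.01),
        ),
        sigma_dc=0.035,
    ),
}


def layer_params(name: str, Cw: float | None = None,
                 betas: SCDielectricBetas = DEFAULT_BETAS) -> ColeColeParams:
    """Cole-Cole parameters for a named skin layer.

    ``"E/D"`` (epidermis/dermis) and ``"HYP"`` (hypodermis) return fixed
    parameter sets; ``"SC"`` requires a water concentration and maps the
    hydration-scaled Debye parameters into the Cole-Cole container.
    """
    if name == "SC":
        if Cw is None:
            raise ValueError("layer 'SC' requires a water concentration Cw")
        p = sc_dielectric_params(Cw, betas)
        terms = tuple(
            (de, tau, 0.0)
            for de, tau in ((p.deps_free, p.tau_free), (p.deps_slow, p.tau_slow))
            if de > 0.0 and tau > 0.0
        )
        return ColeColeParams(eps_inf=p.eps_inf, terms=terms, sigma_dc=0.0)
    try:
        return _LAYER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown layer {name!r}; expected 'SC', 'E/D' or 'HYP'"
        ) from None


def layer_frequency_table(name: str, f_grid, Cw: float | None = None,
                          betas: SCDielectricBetas = DEFAULT_BETAS):
    """Frequency-sweep table for one layer: permittivity and conductivity.

    Returns a pandas DataFrame with columns ``f_Hz, eps_real, eps_imag,
    sigma_real, sigma_imag`` suitable for CSV export.
    """
    import pandas as pd
    f_arr = np.asarray(f_grid, dtype=float)
    eps = cole_cole_permittivity(layer_params(name, Cw, betas), f_arr)
    sigma = complex_conductivity(eps, f_arr)
    return pd.DataFrame({
        "f_Hz": f_arr,
        "eps_real": eps.real, "eps_imag": eps.imag,
        "sigma_real": sigma.real, "sigma_imag": sigma.imag,
    })


def layer_registry_dict() -> dict:
    """JSON-serializable snapshot of the fixed layer registry."""
    return {
        name: {
            "eps_inf": p.eps_inf,
            "sigma_dc": p.sigma_dc,
            "terms": [
                {"delta_eps": de, "tau_s": tau, "alpha": a} for de, tau, a in p.terms
            ],
        }
        for name, p in _LAYER_REGISTRY.items()
    }
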