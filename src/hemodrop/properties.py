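"""Thermophysical property models of sheep blood and water.

The thermal Marangoni number of an evaporating drop needs four material
properties: the surface-tension slope dσ/dT, the dynamic viscosity η, the
thermal diffusivity α = λ/(ρ·Cp), and the drop radius. This module holds the
property models:

* water viscosity from the classic Vogel-type correlation
  η_w(T) = 2.414×10⁻⁵ · 10^(247.8/(T+133)) Pa·s, T in °C;
* relative blood viscosity from an empirical hematocrit/temperature model,
  η_r(T, Ht) = 2.03 · exp[(0.0332 − 1.08×10⁻⁴·T)·Ht + 0.02·T];
* blood viscosity as the product η_r · η_w;
* a logarithmic surface-tension fit σ(T) = a·ln(T) + b (mN/m, T in °C), which
  is the tendency-curve family with the best correlation for blood over
  24–90 °C, and whose derivative dσ/dT = a/T feeds the Marangoni number.

Thermal diffusivity supports two modes. ``si`` converts the density from g/ml
to kg/m³ and returns m²/s. ``paper_numeric`` plugs the density numeral in g/ml
directly, which is dimensionally inconsistent but reproduces the α value
commonly quoted with these constants (1.37×10⁻⁴ for whole sheep blood); it is
kept as a regression anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LogFitModel",
    "BloodProperties",
    "water_viscosity",
    "blood_relative_viscosity",
    "blood_viscosity",
    "thermal_diffusivity",
    "fit_surface_tension",
    "dsigma_dT",
    "dsigma_dT_mean",
    "DEFAULT_SIGMA_FIT",
]


@dataclass(frozen=True)
class LogFitModel:
    """Logarithmic surface-tension model σ(T) = a·ln(T) + b.

    Parameters
    ----------
    a : float
        Slope coefficient, mN/m per ln-unit. Negative for ordinary liquids
        (surface tension falls with temperature).
    b : float
        Intercept, mN/m.
    r2 : float
        Coefficient of determination of the fit, in [0, 1].
    """

    a: float
    b: float
    r2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 or math.isnan(self.r2)):
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")

    def sigma(self, T):
        """Surface tension in mN/m at temperature ``T`` (°C, > 0)."""
        T = np.asarray(T, dtype=float)
        if np.any(T <= 0):
            raise ValueError("sigma(T) is defined for T > 0 (degC)")
        return self.a * np.log(T) + self.b


# Invented plausible default for sheep blood (the real fit coefficients are
# not tabulated anywhere public); gives sigma(24) ~ 51.5, sigma(90) ~ 36 mN/m.
DEFAULT_SIGMA_FIT = LogFitModel(a=-11.5, b=88.0, r2=1.0)


@dataclass
class BloodProperties:
    """Constants and models of whole sheep blood.

    Defaults are the measured constants for healthy sheep blood:
    λ = 0.52 W/(m·°C), ρ = 1.04873 g/ml, Cp = 3617 J/(kg·°C). The hematocrit
    default (35 %) is a typical ovine value, configurable — it is not a
    measured constant of the study material.
    """

    lambda_: float = 0.52  # thermal conductivity, W/(m.degC)
    rho: float = 1.04873  # density, g/ml
    cp: float = 3617.0  # specific heat capacity, J/(kg.degC)
    ht: float = 35.0  # hematocrit, %
    sigma_fit: LogFitModel | None = field(default_factory=lambda: DEFAULT_SIGMA_FIT)

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.rho <= 0 or self.cp <= 0:
            raise ValueError("lambda_, rho and cp must all be positive")
        if not 0.0 <= self.ht <= 100.0:
            raise ValueError(f"hematocrit must be in [0, 100] %, got {self.ht}")

    def alpha(self, mode: str = "si") -> float:
        """Thermal diffusivity λ/(ρ·Cp); see :func:`thermal_diffusivity`."""
        return thermal_diffusivity(self.lambda_, self.rho, self.cp, mode=mode)

    def viscosity(self, T) -> float:
        """Dynamic blood viscosity at ``T`` °C using this hematocrit, Pa·s."""
        return blood_viscosity(T, self.ht)

    # -- config round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "lambda_": self.lambda_,
            "rho": self.rho,
            "cp": self.cp,
            "ht": self.ht,
        }
        if self.sigma_fit is not None:
            d["sigma_fit"] = {
                "a": self.sigma_fit.a,
                "b": self.sigma_fit.b,
                "r2": self.sigma_fit.r2,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BloodProperties":
        d = dict(d)
        fit = d.pop("sigma_fit", None)
        sigma_fit = LogFitModel(**fit) if fit is not None else None
        return cls(sigma_fit=sigma_fit, **d)


def water_viscosity(T):
    """Dynamic viscosity of water, Pa·s.

    η_w(T) = 2.414×10⁻⁵ · 10^(247.8/(T+133)), T in °C. Valid (and strictly
    decreasing) for T > −133 °C; ≈ 1.005×10⁻³ Pa·s at 20 °C.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= -133.0):
        raise ValueError("water_viscosity requires T > -133 degC")
    out = 2.414e-5 * 10.0 ** (247.8 / (T + 133.0))
    return float(out) if out.ndim == 0 else out


def blood_relative_viscosity(T, ht: float):
    """Relative viscosity of whole blood (dimensionless).

    η_r = 2.03 · exp[(0.0332 − 1.08×10⁻⁴·T)·Ht + 0.02·T], with T in °C and
    hematocrit Ht in percent. The model is used verbatim, including its
    exp(0.02·T) factor that makes the *relative* viscosity rise with T (the
    absolute viscosity still falls because water viscosity drops faster).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("blood_relative_viscosity requires T >= 0 degC")
    if not 0.0 <= ht <= 100.0:
        raise ValueError(f"hematocrit must be in [0, 100] %, got {ht}")
    out = 2.03 * np.exp((0.0332 - 1.08e-4 * T) * ht + 0.02 * T)
    return float(out) if out.ndim == 0 else out


def blood_viscosity(T, ht: float):
    """Dynamic viscosity of whole blood, Pa·s: η_r(T, Ht) · η_water(T)."""
    return blood_relative_viscosity(T, ht) * water_viscosity(T)


def thermal_diffusivity(lambda_: float, rho: float, cp: float, mode: str = "si") -> float:
    """Thermal diffusivity α = λ/(ρ·Cp).

    Parameters
    ----------
    lambda_ : float
        Thermal conductivity, W/(m·°C).
    rho : float
        Density in g/ml.
    cp : float
        Specific heat capacity, J/(kg·°C).
    mode : {"si", "paper_numeric"}
        ``si`` converts ρ to kg/m³ and returns m²/s; ``paper_numeric`` plugs
        the g/ml numeral directly (a factor 10³ larger), reproducing the
        conventionally quoted 1.37×10⁻⁴ for these blood constants.
    """
    if lambda_ <= 0 or rho <= 0 or cp <= 0:
        raise ValueError("thermal_diffusivity requires positive inputs")
    if mode == "si":
        return lambda_ / (rho * 1000.0 * cp)
    if mode == "paper_numeric":
        return lambda_ / (rho * cp)
    raise ValueError(f"unknown mode {mode!r}; use 'si' or 'paper_numeric'")


def fit_surface_tension(T, sigma) -> LogFitModel:
    """Least-squares logarithmic fit σ = a·ln(T) + b.

    Requires at least 3 points with T > 0 (°C). Returns the fitted
    :class:`LogFitModel` with its coefficient of determination.
    """
    T = np.asarray(T, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if T.shape != sigma.shape or T.ndim != 1:
        raise ValueError("T and sigma must be 1-D arrays of equal length")
    if T.size < 3:
        raise ValueError("fit_surface_tension needs at least 3 points")
    if np.any(T <= 0):
        raise ValueError("all temperatures must be positive (degC)")
    x = np.log(T)
    a, b = np.polyfit(x, sigma, 1)
    resid = sigma - (a * x + b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LogFitModel(a=float(a), b=float(b), r2=float(min(max(r2, 0.0), 1.0)))


def dsigma_dT(model: LogFitModel, T):
    """Surface-tension slope dσ/dT = a/T, mN/(m·°C), for T > 0 °C."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("dsigma_dT requires T > 0 degC")
    out = model.a / T
    return float(out) if out.ndim == 0 else out


def dsigma_dT_mean(model: LogFitModel, T_tpcl, T_center):
    """Mean of dσ/dT evaluated at the contact line and at the drop center.

    The Marangoni number uses the average of the surface-tension derivative
    at the two reference temperatures: (a/T_tpcl + a/T_center)/2.
    """
    return 0.5 * (dsigma_dT(model, T_tpcl) + dsigma_dT(model, T_center))
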