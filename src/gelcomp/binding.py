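"""Competitive binding equilibria of reversible cross-links.

A dynamic network forms by association of complementary macromer end
groups (e.g. boronic acid + diol) with intrinsic association constant
``ka_xl`` (M^-1).  A monovalent small-molecule competitor that binds one
of the partners with constant ``ka_c`` reduces the effective cross-link
affinity exactly as a competitive inhibitor reduces a substrate's
apparent affinity in Michaelis-Menten kinetics:

    K_app = K_XL / (1 + K_C * [C])

The apparent constant sets the equilibrium cross-link conversion ``p``
(fraction of potential bonds formed) through the symmetric mass-action
relation  N_XL * K_app * (1 - p)^2 = p,  whose physical root is the
closed form  p = a - sqrt(a^2 - 1)  with  a = 1 + 1/(2 N_XL K_app).

Conversion against the Flory-Stockmayer gel point p_c = 1/(f-1) decides
whether the mixture is a percolated gel or a sol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, ValidationError

__all__ = [
    "BindingSystem",
    "NetworkSpec",
    "ConversionResult",
    "apparent_association",
    "conversion",
    "gel_state",
    "free_competitor",
    "equilibrium",
]


def _check_finite_nonneg(name: str, value: float, strict: bool = False) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class BindingSystem:
    """Molecular binding parameters of cross-link and competitor.

    Parameters
    ----------
    ka_xl : float
        Intrinsic association constant of the cross-link, M^-1.
    ka_c : float
        Association constant of the competitor for the shared binding
        partner, M^-1.  Zero models an inert additive.
    conc_c : float
        Total added competitor concentration, M.
    ka_xl_sd, ka_c_sd : float
        One-standard-deviation uncertainties of the constants (e.g. from
        ITC triplicates), M^-1.  Must be smaller than the central value.
    """

    ka_xl: float
    ka_c: float = 0.0
    conc_c: float = 0.0
    ka_xl_sd: float = 0.0
    ka_c_sd: float = 0.0

    def __post_init__(self) -> None:
        _check_finite_nonneg("ka_xl", self.ka_xl, strict=True)
        _check_finite_nonneg("ka_c", self.ka_c)
        _check_finite_nonneg("conc_c", self.conc_c)
        _check_finite_nonneg("ka_xl_sd", self.ka_xl_sd)
        _check_finite_nonneg("ka_c_sd", self.ka_c_sd)
        if self.ka_xl_sd >= self.ka_xl:
            raise ValidationError("ka_xl_sd must be smaller than ka_xl")
        if self.ka_c > 0 and self.ka_c_sd >= self.ka_c:
            raise ValidationError("ka_c_sd must be smaller than ka_c")

    def with_concentration(self, conc_c: float) -> "BindingSystem":
        """Return a copy at a different competitor concentration."""
        return BindingSystem(self.ka_xl, self.ka_c, conc_c,
                             self.ka_xl_sd, self.ka_c_sd)


@dataclass(frozen=True)
class NetworkSpec:
    """Formulation of a stoichiometric A_f + B_f network.

    ``n_xl`` is the concentration of reactive end groups of ONE type
    (equal to the maximum cross-link concentration at full conversion);
    with ``functionality`` arms per macromer the total macromer
    concentration (both species) is ``c_M = 2 n_xl / functionality``.
    """

    n_xl: float
    functionality: int = 4
    temperature: float = 298.15

    def __post_init__(self) -> None:
        _check_finite_nonneg("n_xl", self.n_xl, strict=True)
        if int(self.functionality) != self.functionality or self.functionality < 3:
            raise ValidationError(
                f"functionality must be an integer >= 3, got {self.functionality!r}")
        _check_finite_nonneg("temperature", self.temperature, strict=True)

    @property
    def macromer_conc(self) -> float:
        """Total macromer concentration c_M = 2 n_xl / f, M."""
        return 2.0 * self.n_xl / self.functionality


@dataclass(frozen=True)
class ConversionResult:
    """Apparent constant, conversion and sol/gel state for one condition."""

    ka_app: float
    p: float
    is_gel: bool
    free_conc_c: float | None = field(default=None)


def apparent_association(binding: BindingSystem, conc_c: float | None = None) -> float:
    """Apparent cross-link association constant under competition, M^-1.

    ``K_app = K_XL / (1 + K_C [C])``; equal to ``K_XL`` when either the
    competitor affinity or its concentration vanishes.  ``conc_c``
    overrides the concentration stored in ``binding`` (used internally
    for the free-concentration correction).
    """
    c = binding.conc_c if conc_c is None else conc_c
    _check_finite_nonneg("conc_c", c)
    return binding.ka_xl / (1.0 + binding.ka_c * c)


def conversion(ka_app: float, network: NetworkSpec) -> float:
    """Equilibrium cross-link conversion p from mass action.

    Physical root of ``n_xl * ka_app * (1-p)^2 = p``, clamped to [0, 1]
    against floating-point excursions.  ``ka_app = 0`` maps to ``p = 0``
    by continuity; ``ka_app = inf`` to 1.
    """
    if ka_app < 0 or math.isnan(ka_app):
        raise ValidationError(f"ka_app must be >= 0, got {ka_app!r}")
    if ka_app == 0.0:
        return 0.0
    if math.isinf(ka_app):
        return 1.0
    a = 1.0 + 1.0 / (2.0 * network.n_xl * ka_app)
    # p = a - sqrt(a^2-1), written as its reciprocal conjugate to avoid
    # catastrophic cancellation when a >> 1 (weak binding)
    p = 1.0 / (a + math.sqrt(a * a - 1.0))
    return min(1.0, max(0.0, p))


def gel_state(p: float, functionality: int = 4) -> bool:
    """Flory-Stockmayer sol/gel classification.

    True (gel) iff ``p > 1/(f-1)``.  The critical point itself is
    classified sol: an incipient network carries zero modulus.
    """
    if functionality < 3:
        raise ValidationError("functionality must be >= 3")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p!r}")
    return p > 1.0 / (functionality - 1)


def free_competitor(binding: BindingSystem, network: NetworkSpec) -> float:
    """Free competitor concentration after depletion by end-group binding.

    Solves the coupled 1:1 equilibria  A + B <-> AB (ka_xl)  and
    A + C <-> AC (ka_c)  with A_tot = B_tot = n_xl and C_tot = conc_c,
    where A is the partner shared by cross-link and competitor.  The
    three mass balances reduce to one monotone equation in free [A],
    bracketed on (0, A_tot] and solved with Brent's method.

    Returns ``conc_c`` unchanged when ka_c = 0 or conc_c = 0.
    """
    a_tot = network.n_xl
    c_tot = binding.conc_c
    if binding.ka_c == 0.0 or c_tot == 0.0 or a_tot == 0.0:
        return c_tot

    ka_xl, ka_c = binding.ka_xl, binding.ka_c

    def residual(a_free: float) -> float:
        b_free = a_tot / (1.0 + ka_xl * a_free)
        c_free = c_tot / (1.0 + ka_c * a_free)
        return a_free * (1.0 + ka_xl * b_free + ka_c * c_free) - a_tot

    try:
        a_free = brentq(residual, 0.0, a_tot, xtol=1e-18, rtol=1e-15,
                        maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails on a bracket
        raise ConvergenceError(f"free-competitor solve failed: {exc}",
                               residual=residual(a_tot / 2)) from exc
    res = residual(a_free)
    if abs(res) > 1e-9 * max(a_tot, 1.0):
        raise ConvergenceError(
            f"free-competitor mass balance residual {res:.3e} exceeds tolerance",
            residual=res)
    return c_tot / (1.0 + ka_c * a_free)


def equilibrium(binding: BindingSystem, network: NetworkSpec,
                deplete_competitor: bool = False) -> ConversionResult:
    """Full chain: apparent constant -> conversion -> sol/gel state.

    By default the apparent constant is evaluated at the TOTAL added
    competitor concentration (the convention under which the forward
    model reproduces measured moduli); ``deplete_competitor=True``
    evaluates it at the free concentration instead.
    """
    free_c: float | None = None
    if deplete_competitor:
        free_c = free_competitor(binding, network)
        ka_app = apparent_association(binding, conc_c=free_c)
    else:
        ka_app = apparent_association(binding)
    p = conversion(ka_app, network)
    return ConversionResult(ka_app=ka_app, p=p,
                            is_gel=gel_state(p, network.functionality),
                            free_conc_c=free_c)


def conversion_residual(p: float, ka_app: float, n_xl: float) -> float:
    """Mass-action residual n_xl*ka_app*(1-p)^2 - p (diagnostic)."""
    return n_xl * ka_app * (1.0 - p) ** 2 - p
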